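"""Per-miRNA differential expression against the reactive reference.

On the normalized -dCt scale one unit is one log2 fold change, so the
log2FC of a miRNA is simply the difference of group means.  Significance
uses the classic equal-variance two-sample Student's t-test with
Benjamini-Hochberg FDR adjustment per comparison; a miRNA is called
differentially expressed when its adjusted p falls below ``alpha``
(default 0.05), with no additional fold-change floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import require
from .io import SampleAnnotation
from .normalize import NormalizedMatrix


@dataclass
class DEResult:
    """One comparison's table: log2FC, t, p, BH q, direction per miRNA."""

    table: pd.DataFrame  # index mirna_id; columns log2fc, t, p, q, direction, significant
    comparison: str
    alpha: float

    @property
    def significant_ids(self) -> set[str]:
        return set(self.table.index[self.table["significant"]])

    @property
    def n_up(self) -> int:
        sig = self.table[self.table["significant"]]
        return int((sig["direction"] == "up").sum())

    @property
    def n_down(self) -> int:
        sig = self.table[self.table["significant"]]
        return int((sig["direction"] == "down").sum())

    def write_csv(self, path) -> None:
        self.table.rename_axis("mirna_id").to_csv(path, float_format="%.6g")


def _group_matrix(
    nm: NormalizedMatrix, ann: SampleAnnotation, classes
) -> pd.DataFrame:
    samples = [s for s in nm.sample_ids if s in set(ann.samples_of(classes))]
    require(len(samples) > 0, f"no samples for classes {classes}")
    return nm.values[samples]


def log2_fold_change(
    nm: NormalizedMatrix, ann: SampleAnnotation, group, ref
) -> pd.Series:
    """Mean normalized expression of ``group`` minus ``ref``, per miRNA."""
    g = _group_matrix(nm, ann, group)
    r = _group_matrix(nm, ann, ref)
    return (g.mean(axis=1) - r.mean(axis=1)).rename("log2fc")


def student_t_test(x, y, welch: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t-test (equal-variance Student by default;
    ``welch=True`` switches to the unequal-variance variant).

    Degenerate case of zero pooled variance: equal means give (0, 1)
    by convention; unequal means give the (+/-inf, 0) limit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    require(len(x) >= 2 and len(y) >= 2, "each group needs at least 2 observations")
    sx = x.var(ddof=1)
    sy = y.var(ddof=1)
    if sx == 0.0 and sy == 0.0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return (np.inf if x.mean() > y.mean() else -np.inf), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=not welch)
    return float(t), float(p)


def _t_test_matrix(
    gx: np.ndarray, gy: np.ndarray, welch: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sample t-test along rows (features)."""
    t, p = stats.ttest_ind(gx, gy, axis=1, equal_var=not welch)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    # zero pooled variance rows: nan from scipy; apply the same convention
    bad = ~np.isfinite(t)
    if bad.any():
        eq = np.isclose(gx.mean(axis=1), gy.mean(axis=1))
        t[bad & eq] = 0.0
        p[bad & eq] = 1.0
        up = gx.mean(axis=1) > gy.mean(axis=1)
        t[bad & ~eq] = np.where(up[bad & ~eq], np.inf, -np.inf)
        p[bad & ~eq] = 0.0
    return t, p


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    q_(i) = min_{j >= i} n * p_(j) / j, capped at 1, returned in the
    input order.
    """
    p = np.asarray(p, dtype=float)
    require(bool(np.all((p >= 0) & (p <= 1))), "p-values must lie in [0, 1]")
    n = len(p)
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def differential_expression(
    nm: NormalizedMatrix,
    ann: SampleAnnotation,
    group,
    ref,
    alpha: float = 0.05,
    comparison: str | None = None,
    welch: bool = False,
) -> DEResult:
    """Full per-miRNA DE table for one comparison, sorted by (q, p)."""
    g = _group_matrix(nm, ann, group)
    r = _group_matrix(nm, ann, ref)
    require(g.shape[1] >= 2 and r.shape[1] >= 2, "each group needs >= 2 samples")
    lfc = g.mean(axis=1) - r.mean(axis=1)
    t, p = _t_test_matrix(g.to_numpy(), r.to_numpy(), welch=welch)
    q = bh_adjust(p)
    label = comparison or (
        "+".join(sorted(group if not isinstance(group, str) else [group]))
        + "_vs_"
        + "+".join(sorted(ref if not isinstance(ref, str) else [ref]))
    )
    table = pd.DataFrame(
        {
            "log2fc": lfc,
            "t": t,
            "p": p,
            "q": q,
            "direction": np.where(lfc > 0, "up", "down"),
            "significant": q < alpha,
        },
        index=nm.values.index,
    ).sort_values(["q", "p"], kind="mergesort")
    return DEResult(table=table, comparison=label, alpha=alpha)


@dataclass
class DePartition:
    """Unique and shared significant miRNA sets across comparisons."""

    unique: dict[str, set[str]]
    shared: set[str]


def de_set_partition(results: list[DEResult]) -> DePartition:
    """Split significant calls into per-comparison unique sets and the
    intersection shared by all comparisons (pure set algebra)."""
    require(len(results) >= 2, "need at least 2 comparisons to partition")
    sig = {r.comparison: r.significant_ids for r in results}
    unique = {
        name: ids - set().union(*(v for k, v in sig.items() if k != name))
        for name, ids in sig.items()
    }
    shared = set.intersection(*sig.values())
    return DePartition(unique=unique, shared=shared)
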