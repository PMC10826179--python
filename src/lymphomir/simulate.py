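"""Synthetic cohorts, target maps and gene-set collections.

The generator emulates the statistical structure of an FFPE miRNA qPCR
panel study of nodal T-cell lymphoma: 88 subjects (19 reactive lymph
nodes, 49 nTFHL, 20 nPTCL) profiled on a 376-miRNA panel of which
roughly 130 fall below the detection-rate filter, with spike-in control
rows, per-sample technical offsets, and planted class effects that are
largely shared between the two lymphoma entities.

The model is additive Gaussian on the Ct scale (one Ct cycle is one log2
abundance unit):

    ct[i, j] = baseline[i] + class_shift(i, class[j]) + offset[j] + eps

Spike-in rows carry the technical offset only (no biological noise), so
spike-in normalization can recover the offsets exactly in the noise-free
limit.  Low-detection miRNAs get per-well dropout with rejection
resampling so the realized detection fraction is guaranteed below the
filter threshold in every realization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from ._utils import require
from .io import CLASS_LABELS, CtMatrix, GeneSetCollection, SampleAnnotation, TargetMap

#: Pseudo-label for effects applied to both lymphoma classes.
BOTH_LYMPHOMAS = "both-lymphomas"

_EFFECT_TARGETS = CLASS_LABELS + (BOTH_LYMPHOMAS,)


class Effect(NamedTuple):
    """A planted class effect: panel row ``index`` shifted by ``ct_shift``
    cycles in samples of ``target`` (a class label or "both-lymphomas").

    Positive ct_shift = later amplification = lower abundance; the
    implied log2 fold change is the negated shift.
    """

    index: int
    target: str
    ct_shift: float


@dataclass
class CohortConfig:
    """Generator settings; the defaults are the emulated study conditions."""

    n_per_class: dict[str, int] = field(
        default_factory=lambda: {"RLN": 19, "nTFHL": 49, "nPTCL": 20}
    )
    n_mirnas: int = 376
    n_low_detection: int = 130
    n_spike_ins: int = 3
    baseline_ct_range: tuple[float, float] = (22.0, 32.0)
    within_class_sd: float = 1.0  # Ct cycles
    technical_offset_sd: float = 0.5  # Ct cycles
    effects: Sequence[Effect] = ()
    dropout_prob: float = 0.95  # per-well dropout for low-detection miRNAs
    detection_max_fraction: float = 0.10
    max_ct: float = 35.0
    spike_in_ct: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        require(all(n > 0 for n in self.n_per_class.values()), "class counts must be positive")
        require(set(self.n_per_class) == set(CLASS_LABELS), f"classes must be {CLASS_LABELS}")
        require(self.n_mirnas > 0 and self.n_spike_ins >= 0, "counts must be positive")
        require(0 <= self.n_low_detection <= self.n_mirnas, "n_low_detection out of range")
        effects = [Effect(*e) for e in self.effects]
        for e in effects:
            require(0 <= e.index < self.n_mirnas, f"effect index {e.index} outside panel")
            require(e.target in _EFFECT_TARGETS, f"unknown effect target {e.target!r}")
            require(np.isfinite(e.ct_shift), "effect shift must be finite")
        self.effects = tuple(effects)


@dataclass
class GroundTruth:
    """What was planted, for recovery checks downstream.

    ``log2fc`` holds the expected log2 fold change (comparison group
    minus reactive reference) per panel miRNA for the three standard
    comparisons; subtype-specific effects appear diluted in the pooled
    column by their subtype's share of the pooled group.
    """

    log2fc: pd.DataFrame  # index: panel miRNA ids; columns: grouped/nTFHL/nPTCL
    low_detection_ids: list[str]
    offsets: pd.Series  # per-sample technical offset

    def effect_ids(self, comparison: str) -> list[str]:
        col = self.log2fc[comparison]
        return list(col.index[col != 0.0])


def _mirna_ids(n: int) -> list[str]:
    return [f"MIR_{i + 1:04d}" for i in range(n)]


def _spike_ids(n: int) -> list[str]:
    return [f"SPIKE_{i + 1}" for i in range(n)]


def _sample_ids(n_per_class: dict[str, int]) -> tuple[list[str], list[str]]:
    ids, labels = [], []
    for cls in CLASS_LABELS:
        for k in range(n_per_class[cls]):
            ids.append(f"{cls}_{k + 1:02d}")
            labels.append(cls)
    return ids, labels


def simulate_cohort(config: CohortConfig) -> tuple[CtMatrix, SampleAnnotation, GroundTruth]:
    """Generate one synthetic cohort; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    sample_ids, labels = _sample_ids(config.n_per_class)
    n_samples = len(sample_ids)
    panel_ids = _mirna_ids(config.n_mirnas)
    spike_ids = _spike_ids(config.n_spike_ins)

    baseline = rng.uniform(*config.baseline_ct_range, size=config.n_mirnas)
    offsets = rng.normal(0.0, config.technical_offset_sd, size=n_samples)

    # Effect rows must stay quantifiable: a planted upward Ct shift near the
    # detection limit would be censored at max_ct, breaking the guarantee
    # that the realized group difference equals the planted shift.  Redraw
    # their baselines so baseline + shift + 3 sd stays below the limit.
    lo_b, hi_b = config.baseline_ct_range
    up_shift: dict[int, float] = {}
    for e in config.effects:
        if e.ct_shift > 0:
            up_shift[e.index] = up_shift.get(e.index, 0.0) + e.ct_shift
    for i, s in up_shift.items():
        ceiling = config.max_ct - s - 3.0 * config.within_class_sd
        baseline[i] = rng.uniform(lo_b, max(lo_b, min(hi_b, ceiling)))

    # class shifts from planted effects
    shift = np.zeros((config.n_mirnas, n_samples))
    label_arr = np.asarray(labels)
    for e in config.effects:
        if e.target == BOTH_LYMPHOMAS:
            cols = np.isin(label_arr, ("nTFHL", "nPTCL"))
        else:
            cols = label_arr == e.target
        shift[e.index, cols] += e.ct_shift

    noise = rng.normal(0.0, config.within_class_sd, size=(config.n_mirnas, n_samples))
    ct_panel = baseline[:, None] + shift + offsets[None, :] + noise

    # dropout for designated low-detection miRNAs (never planted-effect rows)
    effect_rows = {e.index for e in config.effects}
    candidates = np.array([i for i in range(config.n_mirnas) if i not in effect_rows])
    require(
        len(candidates) >= config.n_low_detection,
        "not enough effect-free miRNAs for the requested low-detection count",
    )
    low_idx = np.sort(rng.choice(candidates, size=config.n_low_detection, replace=False))
    max_detected = int(np.ceil(config.detection_max_fraction * n_samples)) - 1
    for i in low_idx:
        while True:  # rejection resampling: guarantee fraction < threshold
            drop = rng.random(n_samples) < config.dropout_prob
            visible = ~drop & (ct_panel[i] <= config.max_ct)
            if visible.sum() <= max_detected:
                ct_panel[i, drop] = np.nan
                break

    ct_panel = np.clip(ct_panel, 0.0, 45.0)
    spikes = config.spike_in_ct + offsets[None, :] + np.zeros((config.n_spike_ins, 1))

    all_ids = panel_ids + spike_ids
    ct = pd.DataFrame(
        np.vstack([ct_panel, spikes]) if config.n_spike_ins else ct_panel,
        index=pd.Index(all_ids, name="mirna_id"),
        columns=sample_ids,
    )
    detected = ct.notna() & (ct <= config.max_ct)
    is_spike_in = pd.Series(
        [False] * config.n_mirnas + [True] * config.n_spike_ins, index=ct.index, dtype=bool
    )
    matrix = CtMatrix(ct=ct, detected=detected, is_spike_in=is_spike_in, max_ct=config.max_ct)
    ann = SampleAnnotation(labels=pd.Series(labels, index=sample_ids, name="class"))

    # ground truth log2FC (group mean minus reference mean, on -dCt scale)
    n_t, n_p = config.n_per_class["nTFHL"], config.n_per_class["nPTCL"]
    lfc = pd.DataFrame(
        0.0, index=panel_ids, columns=["grouped", "nTFHL", "nPTCL"]
    )
    for e in config.effects:
        mid = panel_ids[e.index]
        if e.target == BOTH_LYMPHOMAS:
            lfc.loc[mid, ["grouped", "nTFHL", "nPTCL"]] += -e.ct_shift
        elif e.target in ("nTFHL", "nPTCL"):
            lfc.loc[mid, e.target] += -e.ct_shift
            frac = n_t / (n_t + n_p) if e.target == "nTFHL" else n_p / (n_t + n_p)
            lfc.loc[mid, "grouped"] += -e.ct_shift * frac
        # RLN-targeted effects shift the reference instead
        else:
            lfc.loc[mid, ["grouped", "nTFHL", "nPTCL"]] += e.ct_shift

    truth = GroundTruth(
        log2fc=lfc,
        low_detection_ids=[panel_ids[i] for i in low_idx],
        offsets=pd.Series(offsets, index=sample_ids, name="offset"),
    )
    return matrix, ann, truth


def sample_effects(
    n_shared: int,
    n_ntfhl: int = 0,
    n_nptcl: int = 0,
    shift_range: tuple[float, float] = (1.0, 2.0),
    seed: int = 0,
    n_mirnas: int = 376,
    random_sign: bool = True,
) -> list[Effect]:
    """Draw a planted effect list with distinct panel rows.

    Shift magnitudes are uniform in ``shift_range``; with
    ``random_sign`` each effect is up- or downregulated with equal
    probability (a positive Ct shift is a downregulation).
    """
    rng = np.random.default_rng(seed)
    total = n_shared + n_ntfhl + n_nptcl
    require(total <= n_mirnas, "more effects than panel rows")
    idx = rng.choice(n_mirnas, size=total, replace=False)
    mags = rng.uniform(*shift_range, size=total)
    signs = rng.choice([-1.0, 1.0], size=total) if random_sign else np.ones(total)
    targets = [BOTH_LYMPHOMAS] * n_shared + ["nTFHL"] * n_ntfhl + ["nPTCL"] * n_nptcl
    return [
        Effect(int(i), t, float(m * s)) for i, t, m, s in zip(idx, targets, mags, signs)
    ]


def simulate_target_map(
    mirnas: int | Sequence[str],
    n_genes: int,
    targets_per_mirna: tuple[int, int] = (10, 50),
    seed: int = 0,
) -> TargetMap:
    """Random miRNA -> target-gene map; deterministic given ``seed``."""
    lo, hi = targets_per_mirna
    require(1 <= lo <= hi, "targets_per_mirna interval must be >= 1 and ordered")
    require(n_genes >= hi, "n_genes must cover the largest target-set size")
    mirna_ids = _mirna_ids(mirnas) if isinstance(mirnas, int) else list(mirnas)
    genes = np.array([f"GENE{g + 1:04d}" for g in range(n_genes)])
    rng = np.random.default_rng(seed)
    targets = {}
    for m in mirna_ids:
        size = int(rng.integers(lo, hi + 1))
        targets[m] = frozenset(rng.choice(genes, size=size, replace=False))
    return TargetMap(targets=targets)


def simulate_gene_sets(
    target_map: TargetMap,
    planted: Sequence[tuple[str, Sequence[str], float]] = (),
    n_null_sets: int = 50,
    set_size: tuple[int, int] = (15, 40),
    seed: int = 0,
) -> GeneSetCollection:
    """Build a gene-set collection with optional planted enrichment.

    Each planted entry ``(name, source_mirnas, strength)`` draws
    ``strength`` of its members from the union of the source miRNAs'
    targets and the rest uniformly from the universe; null sets are
    uniform draws from the universe.
    """
    rng = np.random.default_rng(seed)
    universe = np.array(sorted(target_map.all_genes()))
    lo, hi = set_size
    require(1 <= lo <= hi <= len(universe), "set_size interval infeasible")

    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for name, sources, strength in planted:
        require(0.0 <= strength <= 1.0, f"enrichment strength {strength} outside [0, 1]")
        missing = [m for m in sources if m not in target_map]
        require(not missing, f"source miRNAs absent from target map: {missing}")
        pool = np.array(sorted(set().union(*(target_map[m] for m in sources))))
        size = int(rng.integers(lo, hi + 1))
        n_from_pool = min(int(round(strength * size)), len(pool))
        members = set(rng.choice(pool, size=n_from_pool, replace=False))
        rest = np.array([g for g in universe if g not in members])
        members |= set(rng.choice(rest, size=size - n_from_pool, replace=False))
        sets[name] = (f"planted strength={strength}", frozenset(members))

    for k in range(n_null_sets):
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(rng.choice(universe, size=size, replace=False))
        sets[f"NULL_{k + 1:03d}"] = ("null set", members)

    return GeneSetCollection(sets=sets, universe=frozenset(universe))
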