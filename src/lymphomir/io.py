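"""Domain containers and file formats for the miRNA qPCR panel pipeline.

The pipeline touches four external formats, all plain text:

* a Ct matrix (CSV, miRNAs x samples, blank cell = undetected well),
* a sample annotation table (CSV, ``sample_id,class``),
* a miRNA -> target-gene table (TSV in the miRTarBase column layout),
* gene-set collections (standard GMT).

Matrices are oriented miRNAs x samples on disk and in memory; every
operation that cares about orientation states its axis explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._utils import require

#: The three diagnostic classes: reactive lymph node, nodal T-follicular
#: helper cell lymphoma, and nodal peripheral T-cell lymphoma NOS.
CLASS_LABELS = ("RLN", "nTFHL", "nPTCL")

#: Both lymphoma entities pooled against the reactive class.
LYMPHOMA_LABELS = ("nTFHL", "nPTCL")

DEFAULT_MAX_CT = 35.0
DEFAULT_SPIKE_IN_PREFIX = "SPIKE_"
DEFAULT_EVIDENCE = frozenset({"Functional MTI"})


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# Ct matrix
# ---------------------------------------------------------------------------


@dataclass
class CtMatrix:
    """Threshold-cycle values per (miRNA, sample) with detection flags.

    ``ct`` holds raw or adjusted Ct values (NaN = no amplification call);
    ``detected`` marks wells with a numeric Ct at or below ``max_ct``.
    Lower Ct means higher abundance; one cycle is one log2 unit.
    ``provenance`` is the append-only list of processing steps applied,
    starting at ``["raw"]``.
    """

    ct: pd.DataFrame
    detected: pd.DataFrame
    is_spike_in: pd.Series
    max_ct: float = DEFAULT_MAX_CT
    provenance: tuple[str, ...] = ("raw",)

    def __post_init__(self) -> None:
        require(self.ct.index.is_unique, "duplicate miRNA ids")
        require(self.ct.columns.is_unique, "duplicate sample ids")
        require(
            self.ct.shape == self.detected.shape
            and self.ct.index.equals(self.detected.index)
            and self.ct.columns.equals(self.detected.columns),
            "ct and detected must share shape and labels",
        )
        require(
            self.is_spike_in.index.equals(self.ct.index),
            "is_spike_in must be indexed by miRNA id",
        )
        self.provenance = tuple(self.provenance)
        if self.provenance == ("raw",):
            # raw matrices must satisfy: detected <=> numeric Ct <= max_ct
            expected = self.ct.notna() & (self.ct <= self.max_ct)
            require(
                bool((expected == self.detected).all().all()),
                "detection flags inconsistent with Ct values and max_ct",
            )

    # -- convenience -------------------------------------------------------

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.ct.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ct.columns)

    @property
    def n_mirnas(self) -> int:
        return self.ct.shape[0]

    @property
    def n_samples(self) -> int:
        return self.ct.shape[1]

    def spike_in_ids(self) -> list[str]:
        return list(self.is_spike_in.index[self.is_spike_in])

    def with_step(self, step: str, ct: pd.DataFrame | None = None) -> "CtMatrix":
        """Return a copy with ``step`` appended to the provenance."""
        return replace(
            self,
            ct=self.ct if ct is None else ct,
            provenance=self.provenance + (step,),
        )

    def detection_fraction(self) -> pd.Series:
        """Fraction of samples in which each miRNA is detected."""
        return self.detected.mean(axis=1)


def read_ct_matrix(
    path: str | Path,
    max_ct: float = DEFAULT_MAX_CT,
    spike_in_prefix: str = DEFAULT_SPIKE_IN_PREFIX,
) -> CtMatrix:
    """Read a raw Ct matrix from CSV.

    Header row carries sample ids, first column miRNA ids; cells are
    numeric Ct values or blank (undetected).  Rows whose id starts with
    ``spike_in_prefix`` are flagged as spike-in controls.  Cells above
    ``max_ct`` keep their value but are marked undetected.
    """
    raw = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate miRNA ids: {dupes}")
    if raw.columns.has_duplicates:
        dupes = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample ids: {dupes}")

    stripped = raw.apply(lambda col: col.str.strip())
    numeric = stripped.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & (stripped != "")
    if bad.any().any():
        rows, cols = np.nonzero(bad.to_numpy())
        where = [
            f"(row {raw.index[r]!r}, column {raw.columns[c]!r})"
            for r, c in zip(rows[:5], cols[:5])
        ]
        raise FormatError(f"non-numeric cells at {', '.join(where)}")

    ct = numeric.astype(float)
    ct.index.name = "mirna_id"
    detected = ct.notna() & (ct <= max_ct)
    is_spike_in = pd.Series(
        [str(m).startswith(spike_in_prefix) for m in ct.index],
        index=ct.index,
        dtype=bool,
    )
    if not is_spike_in.any():
        warnings.warn(
            "no spike-in rows found; spike-in normalization will fail",
            stacklevel=2,
        )
    return CtMatrix(ct=ct, detected=detected, is_spike_in=is_spike_in, max_ct=max_ct)


def write_ct_matrix(m: CtMatrix, path: str | Path) -> None:
    """Write a Ct matrix back to CSV (blank = undetected, 6 decimals)."""
    out = m.ct.copy()
    out.index.name = "mirna_id"
    out.to_csv(path, float_format="%.6f", na_rep="")


# ---------------------------------------------------------------------------
# Sample annotations
# ---------------------------------------------------------------------------


@dataclass
class SampleAnnotation:
    """Mapping sample id -> diagnostic class label."""

    labels: pd.Series  # index: sample_id, values in CLASS_LABELS

    def __post_init__(self) -> None:
        require(self.labels.index.is_unique, "duplicate sample ids")
        unknown = set(self.labels) - set(CLASS_LABELS)
        require(not unknown, f"unknown class labels: {sorted(unknown)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)

    def samples_of(self, classes: str | Iterable[str]) -> list[str]:
        if isinstance(classes, str):
            classes = {classes}
        classes = set(classes)
        return list(self.labels.index[self.labels.isin(classes)])

    def class_counts(self) -> dict[str, int]:
        return {c: int((self.labels == c).sum()) for c in CLASS_LABELS}

    def check_covers(self, sample_ids: Sequence[str]) -> None:
        missing = set(sample_ids) - set(self.labels.index)
        require(not missing, f"samples without class label: {sorted(missing)}")


def read_sample_annotations(
    path: str | Path,
    aliases: Mapping[str, str] | None = None,
) -> SampleAnnotation:
    """Read a two-column ``sample_id,class`` CSV.

    ``aliases`` optionally maps nonstandard labels (e.g. ``PTCL-NOS``)
    onto the three canonical classes before validation.
    """
    df = pd.read_csv(path, dtype=str)
    require(df.shape[1] >= 2, "annotation CSV needs columns sample_id,class")
    sample_col, class_col = df.columns[:2]
    labels = df[class_col].str.strip()
    if aliases:
        labels = labels.replace(dict(aliases))
    unknown = ~labels.isin(CLASS_LABELS)
    if unknown.any():
        row = df[unknown].iloc[0]
        raise FormatError(
            f"unknown class {row[class_col]!r} for sample {row[sample_col]!r}"
        )
    series = pd.Series(labels.to_numpy(), index=df[sample_col].str.strip(), name="class")
    if series.index.has_duplicates:
        dupes = series.index[series.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample ids: {dupes}")
    return SampleAnnotation(labels=series)


def write_sample_annotations(ann: SampleAnnotation, path: str | Path) -> None:
    out = ann.labels.rename_axis("sample_id").rename("class")
    out.to_frame().to_csv(path)


# ---------------------------------------------------------------------------
# miRNA -> target-gene map
# ---------------------------------------------------------------------------


@dataclass
class TargetMap:
    """miRNA id -> set of target gene symbols (upper-cased)."""

    targets: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for mirna, genes in self.targets.items():
            require(len(genes) > 0, f"empty target set for {mirna}")
        self.targets = {m: frozenset(g.upper() for g in gs) for m, gs in self.targets.items()}

    def __contains__(self, mirna: str) -> bool:
        return mirna in self.targets

    def __getitem__(self, mirna: str) -> frozenset[str]:
        return self.targets[mirna]

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.targets)

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.targets.values():
            out |= genes
        return frozenset(out)


def read_target_map(
    path: str | Path,
    allowed_evidence: Iterable[str] = DEFAULT_EVIDENCE,
) -> TargetMap:
    """Read a miRTarBase-style TSV of miRNA-target interactions.

    The header must contain columns whose names include ``miRNA``,
    ``Target Gene`` and ``Support Type`` (extra columns are ignored).
    Rows whose support type is not in ``allowed_evidence`` are dropped,
    keeping only interactions with strong experimental evidence by
    default.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)

    def find(fragment: str) -> str:
        for c in df.columns:
            if fragment.lower() in c.lower():
                return c
        raise FormatError(f"missing required column containing {fragment!r}")

    mirna_col = find("miRNA")
    gene_col = find("Target Gene")
    support_col = find("Support Type")

    allowed = set(allowed_evidence)
    kept = df[df[support_col].isin(allowed)]
    targets: dict[str, set[str]] = {}
    for mirna, gene in zip(kept[mirna_col], kept[gene_col]):
        targets.setdefault(mirna, set()).add(str(gene).upper())
    return TargetMap(targets={m: frozenset(g) for m, g in targets.items()})


def write_target_map(tm: TargetMap, path: str | Path) -> None:
    rows = [
        {"miRNA": m, "Target Gene": g, "Support Type": "Functional MTI"}
        for m in tm.mirna_ids
        for g in sorted(tm[m])
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named gene sets plus the universe they are tested against."""

    sets: dict[str, tuple[str, frozenset[str]]]  # name -> (description, genes)
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for name, (_, genes) in self.sets.items():
            require(len(genes) > 0, f"empty gene set {name!r}")
        if not self.universe:
            union: set[str] = set()
            for _, genes in self.sets.values():
                union |= genes
            self.universe = frozenset(union)

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def genes_of(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    def restrict_universe(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect every set (and the universe) with ``universe``.

        Sets that become empty are dropped rather than violating the
        non-empty invariant.
        """
        uni = frozenset(universe)
        kept = {}
        for name, (desc, genes) in self.sets.items():
            inter = genes & uni
            if inter:
                kept[name] = (desc, inter)
        return GeneSetCollection(sets=kept, universe=uni)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (``name<TAB>description<TAB>gene...`` per line)."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"line {lineno}: fewer than 3 tab-separated fields")
            name, desc = fields[0], fields[1]
            genes = frozenset(g.upper() for g in fields[2:] if g)
            if not genes:
                raise FormatError(f"line {lineno}: gene set {name!r} has no genes")
            sets[name] = (desc, genes)
    if not sets:
        raise FormatError("empty GMT file")
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, (desc, genes) in collection.sets.items():
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")
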