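"""Preprocessing chain for qPCR Ct matrices and exploratory summaries.

The chain, in order:

1. :func:`spikein_normalize` — remove per-sample technical offsets using
   the spike-in control rows;
2. :func:`filter_low_detection` — drop miRNAs expressed in less than 10%
   of samples (and the spike-in rows, which have served their purpose);
3. :func:`global_mean_normalize` — subtract each sample's mean Ct and
   flip sign, yielding a -dCt expression value where higher = more
   abundant.

Plus the exploratory views: complete-linkage hierarchical clustering and
a centered PCA of samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

from ._utils import require
from .io import CtMatrix

GLOBAL_MEAN_STEP = "global_mean"
SPIKEIN_STEP = "spikein"
FILTER_STEP = "low_detection_filter"


@dataclass
class NormalizedMatrix:
    """Globally normalized expression (-dCt), miRNAs x samples.

    No missing values; spike-in rows excluded; each sample's values
    average to zero by construction.
    """

    values: pd.DataFrame
    provenance: tuple[str, ...]

    def __post_init__(self) -> None:
        require(not self.values.isna().any().any(), "normalized matrix has missing values")
        col_means = self.values.mean(axis=0)
        require(
            bool((col_means.abs() < 1e-9).all()),
            "per-sample mean of normalized values must be 0",
        )

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def write_csv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "mirna_id"
        out.to_csv(path, float_format="%.6f")


@dataclass
class ClusterResult:
    """Agglomerative clustering output (scipy linkage encoding)."""

    merges: np.ndarray  # (n-1, 4) scipy linkage matrix
    heights: np.ndarray
    leaf_order: list[str]
    metric: str
    linkage: str


@dataclass
class PcaSummary:
    """Variance fractions (descending) and sample scores on PC1/PC2."""

    variance_fraction: np.ndarray
    scores: pd.DataFrame  # samples x [PC1, PC2]

    def __post_init__(self) -> None:
        vf = np.asarray(self.variance_fraction, dtype=float)
        require(bool(np.all((vf >= 0) & (vf <= 1))), "variance fractions outside [0, 1]")
        require(bool(np.all(np.diff(vf) <= 1e-12)), "variance fractions must descend")
        require(float(vf.sum()) <= 1 + 1e-9, "variance fractions sum above 1")


def spikein_normalize(m: CtMatrix) -> CtMatrix:
    """Remove per-sample technical offsets via the spike-in controls.

    The offset of sample j is its mean spike-in Ct minus the cohort
    median of those means (median for robustness to one bad sample);
    the offset is subtracted from every detected Ct of the sample.
    Idempotent: a second application finds all offsets zero.
    """
    spike_ids = m.spike_in_ids()
    require(len(spike_ids) > 0, "no spike-in rows: cannot spike-in normalize")
    spikes = m.ct.loc[spike_ids]
    undet = ~m.detected.loc[spike_ids]
    if undet.any().any():
        bad = [s for s in m.sample_ids if undet[s].any()]
        raise ValueError(f"spike-in undetected in samples: {bad}")
    sample_means = spikes.mean(axis=0)
    offsets = sample_means - sample_means.median()
    adjusted = m.ct.sub(offsets, axis=1).where(m.ct.notna())
    return m.with_step(SPIKEIN_STEP, ct=adjusted)


def filter_low_detection(
    m: CtMatrix, min_fraction: float = 0.10
) -> tuple[CtMatrix, list[str]]:
    """Drop miRNAs detected in less than ``min_fraction`` of samples.

    Strict "less than": a miRNA detected in exactly ``min_fraction`` of
    samples is retained.  Spike-in rows are always removed at this step.
    Returns the filtered matrix and the ids removed by the detection
    rule (spike-ins are not listed among them).
    """
    require(0 < min_fraction <= 1, "min_fraction must be in (0, 1]")
    frac = m.detection_fraction()
    low = (frac < min_fraction) & ~m.is_spike_in
    keep = ~low & ~m.is_spike_in
    removed = list(m.ct.index[low])
    kept = m.ct.index[keep]
    out = CtMatrix(
        ct=m.ct.loc[kept],
        detected=m.detected.loc[kept],
        is_spike_in=m.is_spike_in.loc[kept],
        max_ct=m.max_ct,
        provenance=m.provenance + (FILTER_STEP,),
    )
    return out, removed


def global_mean_normalize(m: CtMatrix, impute_ct: float = 35.0) -> NormalizedMatrix:
    """Normalize each sample to its global mean miRNA expression level.

    Residual undetected wells are imputed at the detection limit
    (``impute_ct``), then for each sample the mean Ct is subtracted and
    the sign flipped so that higher values mean higher abundance.  Must
    run after the low-detection filter (checked via provenance), else
    the mass of never-detected rows would drag the per-sample mean.
    """
    require(
        FILTER_STEP in m.provenance,
        "global_mean_normalize requires the low-detection filter first",
    )
    ct = m.ct.where(m.detected, other=impute_ct)
    values = -(ct - ct.mean(axis=0))
    return NormalizedMatrix(values=values, provenance=m.provenance + (GLOBAL_MEAN_STEP,))


def hierarchical_cluster(nm: NormalizedMatrix, axis: str = "samples") -> ClusterResult:
    """Complete-linkage agglomerative clustering with Euclidean distance.

    ``axis`` selects whether samples or miRNAs are clustered.  Merge
    heights are non-decreasing (a complete-linkage property); ordering
    of ties follows scipy's deterministic merge order.
    """
    require(axis in ("samples", "mirnas"), "axis must be 'samples' or 'mirnas'")
    X = nm.values.T if axis == "samples" else nm.values
    labels = list(X.index)
    require(len(labels) >= 2, f"need at least 2 {axis} to cluster")
    Z = hierarchy.linkage(X.to_numpy(), method="complete", metric="euclidean")
    order = [labels[i] for i in hierarchy.leaves_list(Z)]
    return ClusterResult(
        merges=Z,
        heights=Z[:, 2].copy(),
        leaf_order=order,
        metric="euclidean",
        linkage="complete",
    )


def pca_summary(nm: NormalizedMatrix, n_components: int = 10) -> PcaSummary:
    """Centered (not scaled) PCA with samples as observations.

    All variables share the Ct scale, so unit-variance scaling is not
    applied.  Requests for more components than the data support are
    truncated with a warning.
    """
    X = nm.values.T  # samples x miRNAs
    require(X.shape[0] >= 2, "need at least 2 samples for PCA")
    limit = min(X.shape[0] - 1, X.shape[1])
    if n_components > limit:
        warnings.warn(
            f"n_components={n_components} truncated to {limit}", stacklevel=2
        )
        n_components = limit
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X.to_numpy())
    score_df = pd.DataFrame(
        scores[:, : min(2, n_components)],
        index=X.index,
        columns=[f"PC{i + 1}" for i in range(min(2, n_components))],
    )
    return PcaSummary(variance_fraction=pca.explained_variance_ratio_, scores=score_df)
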