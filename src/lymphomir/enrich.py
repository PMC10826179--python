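"""Target-gene set enrichment for differentially expressed miRNA sets.

A DE miRNA set is mapped to the union of its target genes, then each
gene set in a collection is tested three ways:

* analytic hypergeometric over-representation of the overlap (upper
  tail, inclusive) — diagnostic output;
* a two-sample Kolmogorov-Smirnov statistic comparing per-gene scores
  (number of DE miRNAs targeting the gene) between set members and
  non-members;
* an empirical miRNA-permutation p-value — the primary reported p —
  built by resampling same-size miRNA sets from the measured panel and
  recomputing the statistic, which preserves the target-multiplicity
  bias of miRNA-level data that a gene-level null ignores.

Benjamini-Hochberg adjustment is applied over the permutation p-values
within a collection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import require
from .diffexpr import bh_adjust
from .io import GeneSetCollection, TargetMap

STAT_HYPERGEOM_K = "hypergeom-k"
STAT_KS_D = "ks-D"


@dataclass
class EnrichmentConfig:
    """Settings for the permutation-based enrichment test."""

    n_permutations: int = 1000
    seed: int = 0
    universe_policy: str = "all-target-map-genes"  # or "gmt-universe"
    alpha: float = 0.05
    statistic: str = STAT_HYPERGEOM_K

    def __post_init__(self) -> None:
        require(self.n_permutations >= 99, "need at least 99 permutations")
        require(
            self.universe_policy in ("all-target-map-genes", "gmt-universe"),
            "unknown universe policy",
        )
        require(self.statistic in (STAT_HYPERGEOM_K, STAT_KS_D), "unknown statistic")


@dataclass
class EnrichmentResult:
    """Per gene set: overlap, analytic p, KS D, permutation p, BH q."""

    table: pd.DataFrame
    # columns: k, set_size, n_targets, universe_size, hypergeom_p, ks_d,
    #          perm_p, q, overlap_genes
    config: EnrichmentConfig

    def write_csv(self, path) -> None:
        out = self.table.copy()
        out["overlap_genes"] = out["overlap_genes"].map(lambda g: "|".join(sorted(g)))
        out.rename_axis("gene_set").to_csv(path, float_format="%.6g")

    def long_format(self) -> pd.DataFrame:
        """Bar-chart-ready (set, count, q) long table."""
        return (
            self.table.reset_index()
            .rename(columns={"index": "gene_set", "k": "count"})[
                ["gene_set", "count", "q"]
            ]
        )


def targets_of(mirnas: Iterable[str], target_map: TargetMap) -> frozenset[str]:
    """Union of the target sets of ``mirnas``; unmapped ids are skipped."""
    out: set[str] = set()
    skipped = 0
    for m in mirnas:
        if m in target_map:
            out |= target_map[m]
        else:
            skipped += 1
    if skipped:
        import logging

        logging.getLogger(__name__).info("targets_of: skipped %d unmapped miRNAs", skipped)
    return frozenset(out)


def hypergeometric_test(
    targets: Iterable[str], pathway: Iterable[str], universe: Iterable[str]
) -> tuple[int, float]:
    """Upper-tail inclusive hypergeometric test of the overlap.

    Returns ``(k, P[X >= k])`` with X ~ Hypergeom(N=|universe|,
    K=|pathway|, n=|targets|); pathway and target sets are intersected
    with the universe first.
    """
    uni = frozenset(universe)
    require(len(uni) > 0, "empty universe")
    path_set = frozenset(pathway) & uni
    tgt = frozenset(targets) & uni
    k = len(tgt & path_set)
    p = float(stats.hypergeom.sf(k - 1, len(uni), len(path_set), len(tgt)))
    return k, p


def ks_enrichment(gene_scores: pd.Series, pathway: Iterable[str]) -> float | None:
    """Two-sample KS statistic: pathway members' scores vs non-members'.

    ``gene_scores`` covers the universe (e.g. the number of DE miRNAs
    targeting each gene).  Returns None when the pathway is empty after
    universe restriction (or covers the whole universe).
    """
    members = frozenset(pathway) & frozenset(gene_scores.index)
    if not members or len(members) == len(gene_scores):
        return None
    in_set = gene_scores.index.isin(members)
    d = stats.ks_2samp(
        gene_scores[in_set].to_numpy(), gene_scores[~in_set].to_numpy()
    ).statistic
    return float(d)


def _gene_scores(mirnas: Iterable[str], target_map: TargetMap, universe) -> pd.Series:
    """Per-gene count of DE miRNAs targeting the gene, over the universe."""
    uni = sorted(universe)
    idx = {g: i for i, g in enumerate(uni)}
    counts = np.zeros(len(uni))
    for m in mirnas:
        if m in target_map:
            for g in target_map[m]:
                if g in idx:
                    counts[idx[g]] += 1
    return pd.Series(counts, index=pd.Index(uni, name="gene"))


def _statistic(
    mirnas: Sequence[str],
    target_map: TargetMap,
    pathway: frozenset,
    universe: frozenset,
    statistic: str,
) -> float:
    if statistic == STAT_HYPERGEOM_K:
        return float(len(targets_of(mirnas, target_map) & pathway & universe))
    scores = _gene_scores(mirnas, target_map, universe)
    d = ks_enrichment(scores, pathway)
    return 0.0 if d is None else d


def permutation_null(
    observed_stat: float,
    mirna_set_size: int,
    panel: Sequence[str],
    target_map: TargetMap,
    pathway: Iterable[str],
    universe: Iterable[str],
    cfg: EnrichmentConfig,
    statistic: str | None = None,
) -> float:
    """miRNA-permutation p-value for one gene set.

    Draws ``cfg.n_permutations`` same-size miRNA sets uniformly without
    replacement from the measured panel, recomputes the statistic for
    each, and returns ``(1 + #{perm >= observed}) / (B + 1)``.
    Deterministic given ``cfg.seed``.
    """
    require(mirna_set_size <= len(panel), "miRNA set larger than measured panel")
    statistic = statistic or cfg.statistic
    rng = np.random.default_rng(cfg.seed)
    uni = frozenset(universe)
    path_set = frozenset(pathway) & uni
    panel = list(panel)
    count = 0
    for _ in range(cfg.n_permutations):
        draw = [panel[i] for i in rng.choice(len(panel), size=mirna_set_size, replace=False)]
        if _statistic(draw, target_map, path_set, uni, statistic) >= observed_stat:
            count += 1
    return (1 + count) / (cfg.n_permutations + 1)


def _resolve_universe(
    collection: GeneSetCollection, target_map: TargetMap, cfg: EnrichmentConfig
) -> frozenset[str]:
    if cfg.universe_policy == "all-target-map-genes":
        return target_map.all_genes()
    return collection.universe


def enrich_all(
    de_mirnas: Iterable[str],
    collection: GeneSetCollection,
    target_map: TargetMap,
    cfg: EnrichmentConfig | None = None,
    panel: Sequence[str] | None = None,
) -> EnrichmentResult:
    """Test every gene set in ``collection`` against a DE miRNA set.

    ``panel`` is the full list of measured miRNAs the permutation null
    resamples from (default: every miRNA in the target map).  The
    permutation draws are shared across gene sets — the null resamples
    miRNA sets once and each gene set is scored against the same draws,
    which is both faster and statistically equivalent.  BH adjustment
    runs over the permutation p-values within the collection.
    """
    cfg = cfg or EnrichmentConfig()
    de_list = sorted(set(de_mirnas))
    panel = list(panel) if panel is not None else sorted(target_map.mirna_ids)
    universe = _resolve_universe(collection, target_map, cfg)
    require(len(universe) > 0, "empty gene universe")
    restricted = collection.restrict_universe(universe)

    panel_set = set(panel)
    m_size = len([m for m in de_list if m in panel_set])
    require(m_size <= len(panel), "DE miRNA set larger than measured panel")

    de_targets = targets_of(de_list, target_map) & universe
    de_scores = _gene_scores(de_list, target_map, universe)

    # shared permutation draws, scored via a panel x universe incidence
    # matrix so the whole null is two BLAS products instead of set loops
    rng = np.random.default_rng(cfg.seed)
    uni_sorted = sorted(universe)
    gene_pos = {g: i for i, g in enumerate(uni_sorted)}
    incidence = np.zeros((len(panel), len(uni_sorted)), dtype=np.float32)
    for r, m in enumerate(panel):
        if m in target_map:
            for g in target_map[m]:
                j = gene_pos.get(g)
                if j is not None:
                    incidence[r, j] = 1.0
    pick = np.zeros((cfg.n_permutations, len(panel)), dtype=np.float32)
    if m_size > 0:
        for b in range(cfg.n_permutations):
            pick[b, rng.choice(len(panel), size=m_size, replace=False)] = 1.0
    draw_scores = pick @ incidence
    draw_masks = draw_scores > 0

    rows = []
    for name in restricted.names:
        genes = restricted.genes_of(name)
        k, hyp_p = hypergeometric_test(de_targets, genes, universe)
        ks_d = ks_enrichment(de_scores, genes)
        member_mask = np.array([g in genes for g in uni_sorted])
        if cfg.statistic == STAT_HYPERGEOM_K:
            observed = float(k)
            perm_stats = (draw_masks & member_mask).sum(axis=1).astype(float)
        else:
            observed = 0.0 if ks_d is None else ks_d
            perm_stats = _ks_batch(draw_scores, member_mask)
        perm_p = (1 + int((perm_stats >= observed).sum())) / (cfg.n_permutations + 1)
        rows.append(
            {
                "gene_set": name,
                "k": k,
                "set_size": len(genes),
                "n_targets": len(de_targets),
                "universe_size": len(universe),
                "hypergeom_p": hyp_p,
                "ks_d": np.nan if ks_d is None else ks_d,
                "perm_p": perm_p,
                "overlap_genes": frozenset(de_targets & genes),
            }
        )
    table = pd.DataFrame(rows).set_index("gene_set")
    table["q"] = bh_adjust(table["perm_p"].to_numpy()) if len(table) else []
    table = table.sort_values(["q", "perm_p"], kind="mergesort")
    return EnrichmentResult(table=table, config=cfg)


def _ks_batch(score_rows: np.ndarray, member_mask: np.ndarray) -> np.ndarray:
    """Two-sample KS statistic per row of integer-valued scores.

    Scores are per-gene counts of targeting miRNAs, so the supremum of
    the empirical-CDF gap is attained at an integer threshold; the
    computation runs over thresholds 0..max jointly for all rows, which
    is far cheaper than one generic KS call per permutation draw.
    """
    if member_mask.all() or not member_mask.any():
        return np.zeros(score_rows.shape[0])
    members = score_rows[:, member_mask]
    others = score_rows[:, ~member_mask]
    top = int(score_rows.max()) if score_rows.size else 0
    d = np.zeros(score_rows.shape[0])
    for t in range(top + 1):
        gap = np.abs(
            (members <= t).mean(axis=1) - (others <= t).mean(axis=1)
        )
        np.maximum(d, gap, out=d)
    return d
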