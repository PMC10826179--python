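"""End-to-end orchestration: one config, one reproducible report bundle.

``run_full_analysis`` drives the whole chain — cohort input (real files
or the synthetic generator), spike-in + global-mean normalization with
QC summaries, three differential-expression tables, three binary
logistic nested-CV runs, the three-class random forest with confusion
matrix and permutation importance, the common miRNA panel, the
unique/shared DE partition and per-subtype enrichment — and writes every
artifact as plain CSV/JSON plus a manifest with the config echo, seed
and per-file checksums.

Every stochastic stage draws its own seed deterministically from the
global seed and the stage name, so stages can be rerun in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from ._utils import derive_seed, require
from . import io as lio
from .classify import (
    CvSpec,
    LrGrid,
    RfGrid,
    common_panel,
    nested_cv_logistic,
    nested_cv_random_forest,
    rf_importance_table,
)
from .diffexpr import de_set_partition, differential_expression
from .enrich import EnrichmentConfig, enrich_all
from .normalize import (
    filter_low_detection,
    global_mean_normalize,
    hierarchical_cluster,
    pca_summary,
    spikein_normalize,
)
from .simulate import (
    CohortConfig,
    Effect,
    sample_effects,
    simulate_cohort,
    simulate_gene_sets,
    simulate_target_map,
)

log = logging.getLogger(__name__)

COMPARISONS = {
    "grouped": (("nTFHL", "nPTCL"), ("RLN",)),
    "nTFHL": (("nTFHL",), ("RLN",)),
    "nPTCL": (("nPTCL",), ("RLN",)),
}


@dataclass
class RunConfig:
    """Effective configuration of one full analysis run."""

    seed: int
    output_dir: Path
    inputs: dict[str, str] | None = None  # paths: ct_matrix, annotations, target_map, gene_sets
    synthetic: dict[str, Any] | None = None
    max_ct: float = 35.0
    detection_min_fraction: float = 0.10
    impute_ct: float = 35.0
    comparisons: tuple[str, ...] = ("grouped", "nTFHL", "nPTCL")
    lr_grid: LrGrid = field(default_factory=LrGrid)
    rf_grid: RfGrid = field(default_factory=RfGrid)
    outer_folds: int = 5
    inner_folds_lr: int = 10
    inner_folds_rf: int = 3
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    run_random_forest: bool = True
    importance_repeats: int = 20

    def __post_init__(self) -> None:
        require(self.seed is not None, "seed is mandatory")
        require(
            (self.inputs is None) != (self.synthetic is None),
            "config must provide either real input paths or a synthetic section, not both",
        )
        unknown = set(self.comparisons) - set(COMPARISONS)
        require(not unknown, f"unknown comparisons: {sorted(unknown)}")
        self.output_dir = Path(self.output_dir)

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None,
                  output_dir: str | Path | None = None) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict[str, Any] = {}
        kwargs["seed"] = seed if seed is not None else raw.get("seed")
        kwargs["output_dir"] = output_dir or raw.get("output_dir", "out")
        for key in ("inputs", "synthetic", "max_ct", "detection_min_fraction",
                    "impute_ct", "run_random_forest", "importance_repeats"):
            if key in raw:
                kwargs[key] = raw[key]
        if "comparisons" in raw:
            kwargs["comparisons"] = tuple(raw["comparisons"])
        if "lr_grid" in raw:
            g = raw["lr_grid"]
            kwargs["lr_grid"] = LrGrid(
                feature_percentages=tuple(g.get("feature_percentages", LrGrid().feature_percentages)),
                inv_regularization=tuple(g.get("inv_regularization", LrGrid().inv_regularization)),
                l1_ratios=tuple(g.get("l1_ratios", LrGrid().l1_ratios)),
            )
        if "rf_grid" in raw:
            g = raw["rf_grid"]
            defaults = RfGrid()
            kwargs["rf_grid"] = RfGrid(
                max_depths=tuple(g.get("max_depths", defaults.max_depths)),
                bootstrap=tuple(g.get("bootstrap", defaults.bootstrap)),
                max_features=tuple(
                    None if f in (None, "none") else f
                    for f in g.get("max_features", defaults.max_features)
                ),
                criterion=tuple(g.get("criterion", defaults.criterion)),
                n_trees=int(g.get("n_trees", defaults.n_trees)),
            )
        cv = raw.get("cv", {})
        kwargs["outer_folds"] = int(cv.get("outer_folds", 5))
        kwargs["inner_folds_lr"] = int(cv.get("inner_folds_lr", 10))
        kwargs["inner_folds_rf"] = int(cv.get("inner_folds_rf", 3))
        if "enrichment" in raw:
            e = raw["enrichment"]
            kwargs["enrichment"] = EnrichmentConfig(
                n_permutations=int(e.get("n_permutations", 1000)),
                seed=0,  # overwritten by the derived stage seed at run time
                universe_policy=e.get("universe_policy", "all-target-map-genes"),
                alpha=float(e.get("alpha", 0.05)),
                statistic=e.get("statistic", "hypergeom-k"),
            )
        return cls(**kwargs)


def _cohort_config(section: dict[str, Any], seed: int) -> CohortConfig:
    cohort = dict(section.get("cohort", {}))
    effects_cfg = cohort.pop("effects", None)
    cfg = CohortConfig(seed=derive_seed(seed, "cohort"), **cohort)
    if effects_cfg is None:
        effects: list[Effect] = []
    elif isinstance(effects_cfg, dict):
        effects = sample_effects(
            n_shared=int(effects_cfg.get("n_shared", 0)),
            n_ntfhl=int(effects_cfg.get("n_ntfhl", 0)),
            n_nptcl=int(effects_cfg.get("n_nptcl", 0)),
            shift_range=tuple(effects_cfg.get("shift_range", (1.0, 2.0))),
            seed=derive_seed(seed, "effects"),
            n_mirnas=cfg.n_mirnas,
            random_sign=bool(effects_cfg.get("random_sign", True)),
        )
    else:
        effects = [Effect(int(e[0]), str(e[1]), float(e[2])) for e in effects_cfg]
    return CohortConfig(
        **{**{f: getattr(cfg, f) for f in (
            "n_per_class", "n_mirnas", "n_low_detection", "n_spike_ins",
            "baseline_ct_range", "within_class_sd", "technical_offset_sd",
            "dropout_prob", "detection_max_fraction", "max_ct", "spike_in_ct", "seed",
        )}, "effects": effects}
    )


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_full_analysis(cfg: RunConfig) -> dict[str, Any]:
    """Execute the whole pipeline; returns the manifest dictionary.

    Any stage failure writes a ``FAILED`` marker naming the stage and
    re-raises; artifacts produced before the failure are retained.
    """
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    stage = "setup"

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        artifacts[name] = _checksum(path)
        log.info("wrote %s", path)

    try:
        # ------------------------------------------------------------ inputs
        stage = "inputs"
        t0 = time.time()
        if cfg.synthetic is not None:
            cohort_cfg = _cohort_config(cfg.synthetic, cfg.seed)
            matrix, ann, truth = simulate_cohort(cohort_cfg)
            tm_cfg = cfg.synthetic.get("target_map", {})
            target_map = simulate_target_map(
                mirnas=[m for m in matrix.mirna_ids if not matrix.is_spike_in[m]],
                n_genes=int(tm_cfg.get("n_genes", 2000)),
                targets_per_mirna=tuple(tm_cfg.get("targets_per_mirna", (10, 50))),
                seed=derive_seed(cfg.seed, "target_map"),
            )
            gs_cfg = cfg.synthetic.get("gene_sets", {})
            collection = simulate_gene_sets(
                target_map,
                planted=[
                    (p["name"], list(p["sources"]), float(p["strength"]))
                    for p in gs_cfg.get("planted", [])
                ],
                n_null_sets=int(gs_cfg.get("n_null_sets", 50)),
                set_size=tuple(gs_cfg.get("set_size", (15, 40))),
                seed=derive_seed(cfg.seed, "gene_sets"),
            )
            emit("ct_matrix.csv", lambda p: lio.write_ct_matrix(matrix, p))
            emit("annotations.csv", lambda p: lio.write_sample_annotations(ann, p))
            emit("target_map.tsv", lambda p: lio.write_target_map(target_map, p))
            emit("gene_sets.gmt", lambda p: lio.write_gmt(collection, p))
        else:
            matrix = lio.read_ct_matrix(cfg.inputs["ct_matrix"], max_ct=cfg.max_ct)
            ann = lio.read_sample_annotations(cfg.inputs["annotations"])
            target_map = lio.read_target_map(cfg.inputs["target_map"])
            collection = lio.read_gmt(cfg.inputs["gene_sets"])
        ann.check_covers(matrix.sample_ids)
        log.info("inputs: %d miRNAs x %d samples (%.1fs)",
                 matrix.n_mirnas, matrix.n_samples, time.time() - t0)

        # --------------------------------------------------------- normalize
        stage = "normalize"
        t0 = time.time()
        adjusted = spikein_normalize(matrix)
        filtered, removed = filter_low_detection(adjusted, cfg.detection_min_fraction)
        nm = global_mean_normalize(filtered, impute_ct=cfg.impute_ct)
        emit("normalized.csv", nm.write_csv)
        emit(
            "removed_low_detection.txt",
            lambda p: p.write_text("\n".join(removed) + "\n"),
        )
        clus = hierarchical_cluster(nm, axis="samples")
        emit(
            "cluster_samples.csv",
            lambda p: pd.DataFrame(
                clus.merges, columns=["left", "right", "height", "size"]
            ).to_csv(p, index=False),
        )
        pca = pca_summary(nm)
        emit(
            "pca.csv",
            lambda p: pca.scores.assign(
                **{"pc1_fraction": pca.variance_fraction[0],
                   "pc2_fraction": pca.variance_fraction[1]}
            ).to_csv(p),
        )
        log.info("normalize: %d retained, %d removed (%.1fs)",
                 len(nm.mirna_ids), len(removed), time.time() - t0)

        # ------------------------------------------------- differential expr
        stage = "diffexpr"
        de_results = {}
        for name in cfg.comparisons:
            group, ref = COMPARISONS[name]
            de = differential_expression(nm, ann, group, ref, comparison=name)
            de_results[name] = de
            emit(f"de_{name}.csv", de.write_csv)
            log.info("DE %s: %d significant (%d up / %d down)",
                     name, len(de.significant_ids), de.n_up, de.n_down)

        # -------------------------------------------------- logistic nested CV
        stage = "classify_lr"
        lr_results = {}
        for name in cfg.comparisons:
            t0 = time.time()
            group, ref = COMPARISONS[name]
            res = nested_cv_logistic(
                nm, ann, positive=group, negative=ref, grid=cfg.lr_grid,
                spec=CvSpec(cfg.outer_folds, cfg.inner_folds_lr,
                            seed=derive_seed(cfg.seed, "lr", name)),
                comparison=name,
            )
            lr_results[name] = res
            emit(f"lr_{name}.json",
                 lambda p, r=res: p.write_text(json.dumps(r.to_dict(), indent=1)))
            emit(f"lr_{name}_predictions.csv",
                 lambda p, r=res: r.oof_scores.to_csv(p))
            log.info("LR %s: AUC %.3f +/- %.3f (%.1fs)",
                     name, res.mean_auc, res.ci_halfwidth, time.time() - t0)
        panel: set[str] = common_panel(list(lr_results.values())) if lr_results else set()
        if lr_results:
            emit("common_panel.txt", lambda p: p.write_text("\n".join(sorted(panel)) + "\n"))

        # ------------------------------------------------------ random forest
        if cfg.run_random_forest:
            stage = "classify_rf"
            t0 = time.time()
            rf = nested_cv_random_forest(
                nm, ann, grid=cfg.rf_grid,
                spec=CvSpec(cfg.outer_folds, cfg.inner_folds_rf,
                            seed=derive_seed(cfg.seed, "rf")),
            )
            emit("rf_model.json",
                 lambda p: p.write_text(json.dumps(rf.model_result.to_dict(), indent=1)))
            emit("confusion_counts.csv", lambda p: rf.confusion.counts.to_csv(p))
            emit("confusion_fractions.csv",
                 lambda p: rf.confusion.fractions.to_csv(p, float_format="%.4f"))
            imp = rf_importance_table(
                rf, nm, ann, repeats=cfg.importance_repeats,
                seed=derive_seed(cfg.seed, "importance"),
            )
            emit("importance.csv",
                 lambda p: imp.ranked().to_csv(p, float_format="%.6g"))
            log.info("RF: macro AUC %.3f (%.1fs)",
                     rf.model_result.mean_auc, time.time() - t0)

        # --------------------------------------------------------- enrichment
        stage = "enrich"
        subtype_names = [n for n in cfg.comparisons if n in ("nTFHL", "nPTCL")]
        if len(de_results) >= 2:
            part = de_set_partition(list(de_results.values()))
            emit("de_partition.json", lambda p: p.write_text(json.dumps(
                {"unique": {k: sorted(v) for k, v in part.unique.items()},
                 "shared": sorted(part.shared)}, indent=1)))
            for name in subtype_names:
                t0 = time.time()
                ecfg = EnrichmentConfig(
                    n_permutations=cfg.enrichment.n_permutations,
                    seed=derive_seed(cfg.seed, "enrich", name),
                    universe_policy=cfg.enrichment.universe_policy,
                    alpha=cfg.enrichment.alpha,
                    statistic=cfg.enrichment.statistic,
                )
                res = enrich_all(
                    part.unique[name], collection, target_map, ecfg,
                    panel=[m for m in nm.mirna_ids],
                )
                emit(f"enrichment_{name}.csv", res.write_csv)
                log.info("enrichment %s: %d sets, %d at q<%.2f (%.1fs)",
                         name, len(res.table),
                         int((res.table["q"] < ecfg.alpha).sum()),
                         ecfg.alpha, time.time() - t0)

        # ----------------------------------------------------------- manifest
        stage = "manifest"
        manifest = {
            "seed": cfg.seed,
            "comparisons": list(cfg.comparisons),
            "config_hash": hashlib.sha256(
                repr(cfg).encode("utf-8")
            ).hexdigest()[:16],
            "artifacts": artifacts,
            "summary": {
                "n_mirnas_retained": len(nm.mirna_ids),
                "de_significant": {k: len(v.significant_ids) for k, v in de_results.items()},
                "lr_mean_auc": {k: v.mean_auc for k, v in lr_results.items()},
                "common_panel_size": len(panel),
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return manifest
    except Exception as exc:  # pragma: no cover - exercised via tests
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
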