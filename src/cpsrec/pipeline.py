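"""End-to-end pipeline orchestration.

``run_pipeline`` executes the full workflow into a run directory:
generate/load cohort -> stratified split -> hybrid feature selection ->
comparative augmentation fidelity -> per-family hyperparameter search ->
dynamic-augmentation CV -> final training (baseline and augmented arms) ->
hold-out evaluation -> per-individual recommendations for the hold-out set.
Every artifact is stamped with the config hash and seed; a rerun with the
same config reproduces all deterministic artifacts bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from cpsrec import augmentation, cohort, fidelity, modeling, partitioning, recommender, selection

log = logging.getLogger("cpsrec")


@dataclass
class RunConfig:
    seed: int = 42
    input_csv: str | None = None  # external cohort; None -> synthetic
    n_records: int = 231
    test_fraction: float = 0.20
    k_folds: int = 5
    correlation_threshold: float = selection.CORRELATION_THRESHOLD
    importance_floor: float = selection.IMPORTANCE_FLOOR
    keep: list = field(default_factory=list)
    drop: list = field(default_factory=list)
    selection_n_iter: int = 50
    families: list = field(default_factory=lambda: ["boosted-trees"])
    methods: list = field(default_factory=lambda: ["wgan-gp", "mixup", "noise"])
    n_fidelity: int = 2000
    hpo_n_iter: dict = field(default_factory=dict)  # family -> n_iter override
    wgan_preset: str = "test"  # "test" | "full"
    hpo_ratio: float = 1.0
    cv_ratio: float = 1.0
    final_ratio: float = 2.0
    augment: bool = True
    grid: dict = field(default_factory=lambda: {"cho_min": 0.50, "cho_max": 1.20, "step": 0.01})

    def wgan_config(self) -> augmentation.WganGpConfig:
        base = (
            augmentation.WGAN_FULL_PRESET
            if self.wgan_preset == "full"
            else augmentation.WGAN_TEST_PRESET
        )
        return dataclasses.replace(base, seed=self.seed)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _augmenter_factory(method: str, config: RunConfig):
    def make():
        return augmentation.make_augmenter(method, config.wgan_config())
    return make


def _metrics_dict(m: modeling.MetricsReport) -> dict:
    return {"mae": m.mae, "rmse": m.rmse, "r2": m.r2, "n": m.n}


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the full workflow; returns a summary dict (also written as
    ``summary.json`` in ``outdir``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}
    config.to_yaml(outdir / "config.yaml")
    t0 = time.time()

    def _stage(name):
        log.info("stage %-22s t=%.1fs", name, time.time() - t0)

    # 1. cohort ------------------------------------------------------------
    _stage("cohort")
    if config.input_csv:
        table = cohort.read_cohort(config.input_csv)
    else:
        table = cohort.generate_cohort(n=config.n_records, seed=config.seed)
        cohort.write_cohort(table, outdir / "cohort.csv")

    # 2. split -------------------------------------------------------------
    _stage("split")
    split = partitioning.stratified_split(table, config.test_fraction, seed=config.seed)
    folds = partitioning.make_folds(
        split.development_indices, config.k_folds, seed=config.seed,
        bin_labels=split.bin_labels,
    )
    split.manifest(folds).to_csv(outdir / "split_manifest.csv", index=False)
    dev = table.loc[split.development_indices]
    holdout = table.loc[split.holdout_indices]

    # 3. feature selection (on the development set only) --------------------
    _stage("selection")
    report = selection.correlation_report(dev, config.correlation_threshold)
    report.matrix.to_csv(outdir / "correlation_matrix.csv")
    importances = selection.importance_ranking(
        dev, {"n_iter": config.selection_n_iter}, seed=config.seed
    )
    decision = selection.integrate_selection(
        report, importances, keep=config.keep, drop=config.drop,
        importance_floor=config.importance_floor,
    )
    (outdir / "selection.json").write_text(
        json.dumps(
            {**stamp, "selected": decision.selected, "dropped": decision.dropped,
             "importances": decision.importance_scores},
            indent=2,
        )
    )
    columns = decision.selected + [cohort.OUTCOME]
    dev_sel = dev[columns]
    holdout_sel = holdout[columns]

    # 4. augmentation fidelity comparison -----------------------------------
    chosen_method = config.methods[0] if config.methods else "wgan-gp"
    fidelity_summary = {}
    if config.augment and len(config.methods) > 1:
        _stage("fidelity")
        reports = []
        for method in config.methods:
            aug = _augmenter_factory(method, config)().fit(dev_sel)
            synth = aug.sample(config.n_fidelity, seed=config.seed)
            reports.append(fidelity.evaluate_fidelity(dev_sel, synth, method))
        ranking = fidelity.rank_methods(reports)
        chosen_method = ranking[0]
        for rep in reports:
            fidelity_summary[rep.method] = {
                "n_passing": rep.n_passing,
                "n_columns": len(rep.per_feature),
                "corr_metrics": rep.corr_metrics,
                "mean_density_difference": rep.mean_density_difference(),
            }
            rep.per_feature.to_csv(
                outdir / f"fidelity_{rep.method}.csv", index=False
            )
        (outdir / "fidelity_summary.json").write_text(
            json.dumps({**stamp, "ranking": ranking, "reports": fidelity_summary}, indent=2)
        )

    # 5-8. per-family modeling, both arms -----------------------------------
    arms = {"baseline": None, "augmented": chosen_method} if config.augment else {
        "baseline": None
    }
    results: dict = {}
    for family in config.families:
        results[family] = {}
        for arm, method in arms.items():
            _stage(f"{family}/{arm}")
            n_iter = config.hpo_n_iter.get(family)
            if method is None:
                hpo_aug = None
            else:
                hpo_aug = _augmenter_factory(method, config)().fit(dev_sel)
            best, score = modeling.tune_hyperparameters(
                dev_sel, hpo_aug, family, n_iter=n_iter, seed=config.seed
            )
            spec = modeling.ModelSpec(family, best, seed=config.seed)
            cv = modeling.dynamic_cv(
                dev_sel, folds, spec,
                augmenter_factory=None if method is None else _augmenter_factory(method, config),
                augmentation_ratio=0.0 if method is None else config.cv_ratio,
                seed=config.seed,
            )
            final_aug = None
            if method is not None:
                final_aug = _augmenter_factory(method, config)().fit(dev_sel)
            predictor = modeling.train_final(
                dev_sel, final_aug, spec,
                augmentation_ratio=0.0 if method is None else config.final_ratio,
                seed=config.seed,
            )
            test_metrics = modeling.evaluate_holdout(predictor, holdout_sel)
            results[family][arm] = {
                "hyperparameters": best,
                "hpo_score_neg_mae": score,
                "cv_validation": _metrics_dict(cv.mean_validation),
                "cv_fold_sizes": cv.fold_sizes,
                "holdout": _metrics_dict(test_metrics),
                "n_training_rows": int(predictor.n_training_rows_),
            }
            results[family][arm]["_predictor"] = predictor

    # 9. recommendations for the hold-out individuals ------------------------
    _stage("recommend")
    best_family = config.families[0]
    best_arm = "augmented" if config.augment else "baseline"
    predictor = results[best_family][best_arm]["_predictor"]
    grid = recommender.build_grid(**config.grid)
    recs = []
    for idx, row in holdout_sel.drop(columns=[cohort.OUTCOME]).iterrows():
        r = recommender.recommend(predictor, row, grid)
        recs.append(
            {"record": int(idx), "strategy": r.strategy, "cho": r.cho,
             "pro": r.pro, "p1": r.p1, "p2": r.p2}
        )
    pd.DataFrame(recs).to_csv(outdir / "recommendations.csv", index=False)

    for family in results:
        for arm in results[family]:
            results[family][arm].pop("_predictor")
    summary = {
        **stamp,
        "n_records": len(table),
        "n_development": len(dev),
        "n_holdout": len(holdout),
        "selected_features": decision.selected,
        "chosen_augmentation": chosen_method if config.augment else None,
        "fidelity": fidelity_summary,
        "models": results,
        "n_recommendations": len(recs),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
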