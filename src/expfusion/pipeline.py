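"""End-to-end pipeline: configuration, stage orchestration and CSV artifacts.

Stages (each optional, gated by the config): simulate -> featurize/train ->
optimize -> evaluate -> ad -> explain -> ablate.  Every stochastic component
derives its seed from the single root seed, and each run writes a run log
recording the configuration and seeds so any run can be reproduced.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import simulate
from .bayesopt import Real, SearchSpace, optimize
from .interpret import importance_summary, shap_for_model
from .model import (
    DEFAULT_HYPERPARAMS,
    ExplosionConsequenceModel,
    ExplosionConsequenceResults,
)
from .validation import run_ablation

logger = logging.getLogger(__name__)


def write_csv(df: pd.DataFrame, path, index: bool = False) -> None:
    """Machine-output CSV with shortest round-trip float representation.

    Reading back with ``pd.read_csv(..., float_precision="round_trip")``
    reproduces the written doubles exactly.
    """
    df.to_csv(path, index=index, float_format=lambda v: repr(float(v)))

__all__ = ["PipelineConfig", "run_pipeline", "save_model", "load_model", "write_csv"]

EXIT_CONFIG, EXIT_DATA, EXIT_NUMERIC = 2, 3, 4


@dataclass
class PipelineConfig:
    """Flat pipeline configuration; loadable from YAML, overridable by CLI flags."""

    out_dir: str = "artifacts"
    chemicals_csv: str | None = None   # None -> synthesize
    dataset_csv: str | None = None
    n_chemicals: int = 40
    noise_sigma: float = 0.0
    split_ratio: float = 0.8
    log_base: float = 10.0
    corr_threshold: float = 0.95
    zero_fraction_threshold: float = 0.8
    seed: int = 0
    stages: tuple = ("simulate", "train", "evaluate", "ad", "explain", "ablate")
    optimize_budget: int = 0           # 0 disables Bayesian optimization
    hyperparams: dict = field(default_factory=dict)
    epochs: int | None = None
    shap_rows: int = 16
    shap_permutations: int = 8

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _tune_head(model: ExplosionConsequenceModel, cfg: PipelineConfig) -> dict:
    """Bayesian optimization of the SVR-head hyperparameters (C, epsilon,
    gamma, structure weight) against compound-grouped CV RMSE on frozen
    full-model features."""
    base = dict(DEFAULT_HYPERPARAMS)
    base.update(cfg.hyperparams)
    probe = model.fit(variant="full", hyperparams=base, seed=cfg.seed, epochs=cfg.epochs)
    space = SearchSpace(
        dimensions=(
            Real("C", 0.1, 100.0, log=True),
            Real("epsilon", 0.001, 0.5, log=True),
            Real("gamma", 1e-5, 1e-2, log=True),
            Real("structure_weight", 0.05, 1.0, log=True),
        )
    )

    def objective(point) -> float:
        hp = dict(base)
        hp.update(point)
        res = ExplosionConsequenceResults(
            model=model, variant="full", hyperparams=hp, seed=cfg.seed,
            trunk=probe.trunk, feat_scaler=probe.feat_scaler, svr=probe.svr,
        )
        q2 = res.q2_cv(folds=5, seed=cfg.seed)
        return 1.0 - q2  # proportional to PRESS: smaller is better

    result = optimize(objective, space, budget=cfg.optimize_budget,
                      n_init=min(5, cfg.optimize_budget), seed=cfg.seed)
    tuned = dict(base)
    tuned.update(result.best_point)
    logger.info("tuned hyperparameters: %s (cv objective %.4f)", result.best_point, result.best_value)
    return tuned


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the requested stages; returns the artifacts directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from . import __version__

    log: dict = {
        "package_version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(cfg).items()},
        "seed": cfg.seed,
    }

    if cfg.chemicals_csv and cfg.dataset_csv:
        chemicals = pd.read_csv(cfg.chemicals_csv)
        dataset = pd.read_csv(cfg.dataset_csv)
    else:
        chems = simulate.make_synthetic_chemicals(cfg.n_chemicals, seed=cfg.seed)
        sim_cfg = simulate.SurrogateConfig(noise_sigma=cfg.noise_sigma, seed=cfg.seed)
        records = simulate.generate_dataset(chems, simulate.standard_grid(), sim_cfg)
        chemicals = simulate.chemicals_to_frame(chems)
        dataset = simulate.dataset_to_frame(records)
        if "simulate" in cfg.stages:
            write_csv(chemicals, out / "chemicals.csv")
            write_csv(dataset, out / "dataset.csv")

    if set(cfg.stages) <= {"simulate"}:
        (out / "run_log.json").write_text(json.dumps(log, indent=1, default=str))
        return out

    model = ExplosionConsequenceModel(
        chemicals, dataset,
        split_ratio=cfg.split_ratio, split_seed=cfg.seed, log_base=cfg.log_base,
        corr_threshold=cfg.corr_threshold,
        zero_fraction_threshold=cfg.zero_fraction_threshold,
    )
    if "featurize" in cfg.stages:
        feat = {
            "kept_descriptors": model.kept_descriptors,
            "dropped_descriptors": [c for c in model.descriptor_columns
                                    if c not in model.kept_descriptors],
            "vocabulary_size": model.tokenizer.vocab_size,
            "train_chem_ids": list(model.split.train_chem_ids),
            "test_chem_ids": list(model.split.test_chem_ids),
        }
        (out / "featurization.json").write_text(json.dumps(feat, indent=1))

    hp = dict(DEFAULT_HYPERPARAMS)
    hp.update(cfg.hyperparams)
    if cfg.optimize_budget > 0 and "optimize" in cfg.stages:
        hp = _tune_head(model, cfg)
        log["tuned_hyperparams"] = {k: v for k, v in hp.items()}

    results = None
    if {"train", "evaluate", "ad", "explain"} & set(cfg.stages):
        results = model.fit(variant="full", hyperparams=hp, seed=cfg.seed, epochs=cfg.epochs)
        save_model(results, out / "model_bundle")

    if "evaluate" in cfg.stages and results is not None:
        trm, tem = results.train_metrics, results.test_metrics
        q2 = results.q2_cv(folds=5, seed=cfg.seed)
        write_csv(pd.DataFrame(
            [
                {"set": "train", **trm.as_dict()},
                {"set": "test", **tem.as_dict(), "q2_cv": q2},
            ]
        ), out / "metrics.csv")
        vr = results.validation_report(q2_loo=True)
        vrow = {k: getattr(vr, k) for k in
                ("r2", "r0_sq", "r0p_sq", "k", "k_prime", "ratio1", "ratio2", "abs_diff", "q2_loo")}
        vrow.update({f"pass_{k}": v for k, v in vr.passes.items()})
        write_csv(pd.DataFrame([vrow]), out / "validation.csv")
        log["test_metrics"] = tem.as_dict()
        log["validation_passes"] = vr.passes

    if "ad" in cfg.stages and results is not None:
        wr = results.williams()
        write_csv(wr.table, out / "williams.csv")
        log["h_star"] = wr.h_star
        log["fraction_in_domain"] = wr.fraction_in_domain

    if "explain" in cfg.stages and results is not None:
        rep = shap_for_model(
            results, explain_rows=cfg.shap_rows,
            n_permutations=cfg.shap_permutations, seed=cfg.seed,
        )
        write_csv(importance_summary(rep), out / "shap.csv", index=True)

    if "ablate" in cfg.stages:
        ab = run_ablation(model, hyperparams=hp, seed=cfg.seed, epochs=cfg.epochs)
        write_csv(ab.table, out / "ablation.csv", index=True)
        log["ablation"] = ab.table["r2"].to_dict()

    (out / "run_log.json").write_text(json.dumps(log, indent=1, default=str))
    return out


def save_model(results: ExplosionConsequenceResults, path) -> None:
    results.save(path)


def load_model(path, model: ExplosionConsequenceModel) -> ExplosionConsequenceResults:
    return ExplosionConsequenceResults.load(path, model)
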