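"""Model evaluation: fit metrics, cross-validated Q^2, the Golbraikh-Tropsha
external-validation battery, and the component-ablation experiment.

Conventions: y_sim are simulated (reference) log-diameters, y_pred model
predictions.  R^2 is (TSS - RSS) / TSS about the mean of y_sim; Q^2 is
1 - PRESS/TSS with PRESS summed over out-of-fold predictions and TSS taken
about the full-training-set mean; folds are always grouped by compound so a
chemical never predicts itself.  The Golbraikh-Tropsha quantities use the
standard origin-constrained regressions between predictions and reference
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PredictionSet",
    "MetricsReport",
    "ValidationReport",
    "AblationResult",
    "compute_metrics",
    "q2_cross_validated",
    "golbraikh_tropsha",
    "run_ablation",
]


@dataclass(frozen=True)
class PredictionSet:
    """Aligned reference / predicted vectors."""

    y_sim: np.ndarray
    y_pred: np.ndarray

    def __post_init__(self) -> None:
        ys = np.asarray(self.y_sim, dtype=float)
        yp = np.asarray(self.y_pred, dtype=float)
        if ys.shape != yp.shape or ys.ndim != 1:
            raise ValueError("y_sim and y_pred must be equal-length 1-D vectors")
        if ys.size < 2:
            raise ValueError("need n >= 2")
        if not (np.isfinite(ys).all() and np.isfinite(yp).all()):
            raise ValueError("non-finite values in prediction set")
        object.__setattr__(self, "y_sim", ys)
        object.__setattr__(self, "y_pred", yp)

    @property
    def n(self) -> int:
        return self.y_sim.size

    @property
    def mean_sim(self) -> float:
        return float(self.y_sim.mean())


@dataclass(frozen=True)
class MetricsReport:
    r2: float
    mse: float
    mae: float
    rmse: float
    q2_cv: float | None = None

    def as_dict(self) -> dict[str, float]:
        out = {"r2": self.r2, "mse": self.mse, "mae": self.mae, "rmse": self.rmse}
        if self.q2_cv is not None:
            out["q2_cv"] = self.q2_cv
        return out


def compute_metrics(p: PredictionSet, q2_cv: float | None = None) -> MetricsReport:
    """R^2 = (TSS - RSS)/TSS, RMSE = sqrt(mean squared error), MAE, MSE = RMSE^2."""
    resid = p.y_sim - p.y_pred
    tss = float(np.sum((p.y_sim - p.mean_sim) ** 2))
    if tss == 0:
        raise ValueError("zero variance in y_sim: R^2 undefined")
    rss = float(np.sum(resid**2))
    mse = rss / p.n
    return MetricsReport(
        r2=1.0 - rss / tss,
        mse=mse,
        mae=float(np.mean(np.abs(resid))),
        rmse=float(np.sqrt(mse)),
        q2_cv=q2_cv,
    )


def q2_cross_validated(
    model_factory,
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    folds: int | str = 5,
    seed: int = 0,
) -> float:
    """Compound-grouped cross-validated Q^2 = 1 - PRESS / TSS.

    model_factory(X_train, y_train) must return a callable predicting on a
    feature matrix.  folds="loo" leaves one compound out at a time.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if folds == "loo":
        fold_sets = [np.array([g]) for g in uniq]
    else:
        if not 2 <= int(folds) <= len(uniq):
            raise ValueError("folds must be between 2 and the number of compounds")
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(uniq))
        fold_sets = [uniq[order[i :: int(folds)]] for i in range(int(folds))]
    press = 0.0
    for held in fold_sets:
        test_mask = np.isin(groups, held)
        if test_mask.all():
            raise ValueError("a fold left zero training compounds")
        predictor = model_factory(X[~test_mask], y[~test_mask])
        press += float(np.sum((y[test_mask] - predictor(X[test_mask])) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / tss


@dataclass(frozen=True)
class ValidationReport:
    """Golbraikh-Tropsha external-validation quantities and pass flags.

    k, k_prime are slopes of the origin-constrained regressions
    (pred-on-sim and sim-on-pred); r0_sq / r0p_sq the corresponding
    origin-constrained determination coefficients.
    """

    r2: float
    r0_sq: float
    r0p_sq: float
    k: float
    k_prime: float
    ratio1: float
    ratio2: float
    abs_diff: float
    q2_loo: float | None = None
    passes: dict[str, bool] = field(default_factory=dict)

    @property
    def all_pass(self) -> bool:
        return all(self.passes.values())


def golbraikh_tropsha(p: PredictionSet, q2_loo: float | None = None) -> ValidationReport:
    """External-validation battery on a test-set prediction set.

    Criteria: R^2 > 0.6; slope/origin condition
    ((R^2 - R0^2)/R^2 < 0.1 and 0.85 <= k <= 1.15) or the primed variant;
    |R0^2 - R0'^2| < 0.3; and (when supplied) Q^2_LOO > 0.5.
    """
    ys, yp = p.y_sim, p.y_pred
    if p.n < 3:
        raise ValueError("need n >= 3")
    sum_pp = float(np.sum(yp**2))
    sum_ss = float(np.sum(ys**2))
    if sum_pp == 0 or sum_ss == 0:
        raise ValueError("degenerate all-zero vector")
    r2 = compute_metrics(p).r2
    k = float(np.sum(ys * yp) / sum_pp)
    k_prime = float(np.sum(ys * yp) / sum_ss)
    denom_s = float(np.sum((ys - ys.mean()) ** 2))
    denom_p = float(np.sum((yp - yp.mean()) ** 2))
    if denom_p == 0:
        import warnings

        warnings.warn("all predictions equal; validation flags forced false", stacklevel=2)
        return ValidationReport(
            r2=r2, r0_sq=np.nan, r0p_sq=np.nan, k=k, k_prime=k_prime,
            ratio1=np.nan, ratio2=np.nan, abs_diff=np.nan, q2_loo=q2_loo,
            passes={"r2": False, "slope_origin": False, "r0_gap": False},
        )
    r0_sq = 1.0 - float(np.sum((ys - k * yp) ** 2)) / denom_s
    r0p_sq = 1.0 - float(np.sum((yp - k_prime * ys) ** 2)) / denom_p
    ratio1 = (r2 - r0_sq) / r2
    ratio2 = (r2 - r0p_sq) / r2
    abs_diff = abs(r0_sq - r0p_sq)
    passes = {
        "r2": r2 > 0.6,
        "slope_origin": (ratio1 < 0.1 and 0.85 <= k <= 1.15)
        or (ratio2 < 0.1 and 0.85 <= k_prime <= 1.15),
        "r0_gap": abs_diff < 0.3,
    }
    if q2_loo is not None:
        passes["q2_loo"] = q2_loo > 0.5
    return ValidationReport(
        r2=r2, r0_sq=r0_sq, r0p_sq=r0p_sq, k=k, k_prime=k_prime,
        ratio1=ratio1, ratio2=ratio2, abs_diff=abs_diff, q2_loo=q2_loo, passes=passes,
    )


@dataclass(frozen=True)
class AblationResult:
    """Test metrics per model variant; deltas are (variant R^2 - full R^2) x 100 points."""

    table: pd.DataFrame

    def delta_r2_pct(self, variant: str) -> float:
        return float(self.table.loc[variant, "delta_r2_pct"])


def run_ablation(model, hyperparams=None, seed: int = 0, epochs: int | None = None) -> AblationResult:
    """Train full, no-cross-attention and no-transformer variants on the same
    data/split/seed and tabulate test R^2, RMSE and delta R^2 (percentage points).

    ``model`` is an ExplosionConsequenceModel; variant training errors are
    recorded per row, other variants still reported.
    """
    rows = {}
    errors = {}
    for variant in ("full", "no_cross_attention", "no_transformer"):
        try:
            res = model.fit(variant=variant, hyperparams=hyperparams, seed=seed, epochs=epochs)
            m = res.test_metrics
            rows[variant] = {"r2": m.r2, "rmse": m.rmse}
        except Exception as exc:  # noqa: BLE001 - per-variant isolation
            errors[variant] = str(exc)
    if "full" not in rows:
        raise RuntimeError(f"full-model training failed: {errors.get('full')}")
    full_r2 = rows["full"]["r2"]
    table = pd.DataFrame.from_dict(rows, orient="index")
    table["delta_r2_pct"] = (table["r2"] - full_r2) * 100.0
    for variant, msg in errors.items():
        table.loc[variant] = {"r2": np.nan, "rmse": np.nan, "delta_r2_pct": np.nan}
        table.loc[variant, "error"] = msg
    return AblationResult(table=table)
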