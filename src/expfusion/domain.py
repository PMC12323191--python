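"""Leverage-based applicability domain with Williams-plot export.

The applicability domain (AD) is defined on the standardized tabular feature
matrix (descriptors + scenario parameters) used by the model, augmented with
an intercept column.  A sample's leverage h_i = x_i (X'X)^-1 x_i' measures
its distance from the training centroid; samples with h above the warning
threshold h* = 3(k+1)/m are extrapolations, and samples with standardized
residuals beyond +/-3 are response outliers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["LeverageReport", "leverage", "warning_leverage", "williams_data"]


def _augment(X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.hstack([np.ones((X.shape[0], 1)), X])


def leverage(X_train: np.ndarray, X_query: np.ndarray | None = None, jitter: float = 0.0) -> np.ndarray:
    """h_i = x_i (X'X)^-1 x_i' with an intercept column appended.

    Training-row leverages lie in [0, 1] and sum to the rank of the augmented
    design; query rows may exceed 1.  A ridge jitter is added (and logged) if
    X'X is numerically singular.
    """
    Xa = _augment(X_train)
    m, k1 = Xa.shape
    if m <= k1 - 1 + 1:
        raise ValueError(f"need m > k+1 training rows (m={m}, k={k1 - 1})")
    G = Xa.T @ Xa
    if jitter:
        G = G + jitter * np.eye(k1)
    try:
        Ginv = np.linalg.inv(G)
    except np.linalg.LinAlgError:
        jit = 1e-8 * np.trace(G) / k1
        logger.warning("X'X singular; adding ridge jitter %.3e", jit)
        try:
            Ginv = np.linalg.inv(G + jit * np.eye(k1))
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"X'X singular beyond jitter; collinear columns suspected: {exc}"
            ) from exc
    Q = _augment(X_query) if X_query is not None else Xa
    return np.einsum("ij,jk,ik->i", Q, Ginv, Q)


def warning_leverage(k: int, m: int) -> float:
    """Warning leverage h* = 3 (k + 1) / m for k features and m training samples."""
    if m <= 0 or k < 0:
        raise ValueError("require m > 0 and k >= 0")
    return 3.0 * (k + 1) / m


@dataclass(frozen=True)
class LeverageReport:
    """Per-sample leverage, standardized residual and AD flags, plot-ready."""

    h_star: float
    table: pd.DataFrame  # columns: set, h, std_residual, high_leverage, outlier, in_domain

    @property
    def fraction_in_domain(self) -> float:
        return float(self.table["in_domain"].mean())

    def subset(self, which: str) -> pd.DataFrame:
        return self.table[self.table["set"] == which]


def williams_data(
    X_train: np.ndarray,
    y_train_sim: np.ndarray,
    y_train_pred: np.ndarray,
    X_test: np.ndarray | None = None,
    y_test_sim: np.ndarray | None = None,
    y_test_pred: np.ndarray | None = None,
) -> LeverageReport:
    """Williams-plot table: leverage vs standardized residual with AD flags.

    Residuals are standardized by the training RMSE; a row is an outlier if
    |standardized residual| > 3, a leverage point if h > h* = 3(k+1)/m, and
    in-domain otherwise.
    """
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    m, k = X_train.shape
    h_star = warning_leverage(k, m)
    res_train = np.asarray(y_train_sim, float) - np.asarray(y_train_pred, float)
    s = float(np.sqrt(np.mean(res_train**2)))
    if s == 0:
        raise ValueError("zero training residual spread: cannot standardize residuals")
    frames = []
    for name, Xq, resid in (
        ("train", None, res_train),
        ("test", X_test, None if y_test_sim is None else np.asarray(y_test_sim, float) - np.asarray(y_test_pred, float)),
    ):
        if name == "test" and (Xq is None or resid is None):
            continue
        h = leverage(X_train, Xq)
        std_res = resid / s
        frames.append(
            pd.DataFrame(
                {"set": name, "h": h, "std_residual": std_res}
            )
        )
    table = pd.concat(frames, ignore_index=True)
    table["high_leverage"] = table["h"] > h_star
    table["outlier"] = table["std_residual"].abs() > 3.0
    table["in_domain"] = ~(table["high_leverage"] | table["outlier"])
    return LeverageReport(h_star=h_star, table=table)
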