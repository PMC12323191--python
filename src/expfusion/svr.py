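"""Epsilon-insensitive support vector regression head on fused features.

The regression function is f(x) = sum_i beta_i K(x, x_i) + b with an RBF
kernel K(x, x') = exp(-gamma ||x - x'||^2) and dual coefficients
beta_i = alpha_i - alpha_i* bounded by the box constraint |beta_i| <= C with
sum_i beta_i = 0.  The quadratic program is solved by scikit-learn's SMO
implementation; this module fixes the package-facing contract (SVRSpec) and
keeps the solver swappable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVR as _SkSVR

__all__ = ["SVRSpec", "fit_svr", "svr_predict", "svr_dual_objective"]


@dataclass
class SVRSpec:
    """Fitted SVR head: kernel + dual solution.

    dual_coef holds beta_i = alpha_i - alpha_i* for the support vectors only;
    |beta_i| <= C and sum beta_i ~ 0 (KKT).
    """

    C: float
    epsilon: float
    gamma: float
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float

    def __post_init__(self) -> None:
        if not (self.C > 0 and self.gamma > 0 and self.epsilon >= 0):
            raise ValueError("require C > 0, gamma > 0, epsilon >= 0")
        if np.any(np.abs(self.dual_coef) > self.C * (1 + 1e-8)):
            raise ValueError("dual coefficients violate the box constraint |beta| <= C")


def _rbf(A: np.ndarray, B: np.ndarray, gamma: float) -> np.ndarray:
    d2 = (
        np.sum(A**2, axis=1)[:, None]
        + np.sum(B**2, axis=1)[None, :]
        - 2.0 * A @ B.T
    )
    return np.exp(-gamma * np.maximum(d2, 0.0))


def fit_svr(
    features: np.ndarray,
    targets: np.ndarray,
    C: float = 10.0,
    epsilon: float = 0.01,
    gamma: float | str = "scale",
    tol: float = 1e-6,
) -> SVRSpec:
    """Solve the epsilon-insensitive dual with an RBF kernel.

    gamma="scale" uses 1 / (p * var(features)), the common default for
    standardized inputs.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features must be (n, p) aligned with targets (n,)")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    model = _SkSVR(kernel="rbf", C=C, epsilon=epsilon, gamma=gamma, tol=tol, cache_size=256)
    model.fit(X, y)
    gamma_val = float(model._gamma) if hasattr(model, "_gamma") else float(gamma)
    return SVRSpec(
        C=float(C),
        epsilon=float(epsilon),
        gamma=gamma_val,
        support_vectors=np.asarray(model.support_vectors_, dtype=float),
        dual_coef=np.asarray(model.dual_coef_, dtype=float).ravel(),
        intercept=float(model.intercept_[0]),
    )


def svr_predict(spec: SVRSpec, X: np.ndarray) -> np.ndarray:
    """f(x) = sum_i beta_i K(x, x_i) + b, vectorized over query rows."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    K = _rbf(X, spec.support_vectors, spec.gamma)
    return K @ spec.dual_coef + spec.intercept


def svr_dual_objective(
    beta: np.ndarray, X: np.ndarray, y: np.ndarray, epsilon: float, gamma: float
) -> float:
    """Dual objective -1/2 b'Kb - eps*sum|b| + y'b for a feasible beta (maximized at optimum).

    Used to compare solver output against an independent QP on small problems.
    """
    beta = np.asarray(beta, dtype=float)
    K = _rbf(np.asarray(X, float), np.asarray(X, float), gamma)
    return float(-0.5 * beta @ K @ beta - epsilon * np.abs(beta).sum() + y @ beta)
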