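"""Shapley-value attribution for the fitted model over tabular features.

Model-agnostic estimator: the value of a feature coalition S is the model
output with features in S taken from the explained row and the rest drawn
from a background set (marginal expectation).  For p <= ``exact_max``
features the Shapley values are computed by exact coalition enumeration;
otherwise by permutation sampling.  Local accuracy
(base_value + sum_j phi_j = prediction) holds exactly under enumeration and
to Monte-Carlo tolerance under sampling.

The SMILES modality is attributed as one grouped "structure" feature: the
wrapper in :func:`shap_for_model` swaps the whole token sequence between the
explained row and background rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd

__all__ = ["ShapReport", "shap_values", "importance_summary", "shap_for_model"]


@dataclass(frozen=True)
class ShapReport:
    base_value: float
    values: np.ndarray  # (n_explain, p)
    feature_names: tuple[str, ...]
    predictions: np.ndarray  # (n_explain,)

    def summary(self) -> pd.DataFrame:
        tab = pd.DataFrame(
            {
                "mean_abs_shap": np.mean(np.abs(self.values), axis=0),
                "mean_shap": np.mean(self.values, axis=0),
                "std_shap": np.std(self.values, axis=0),
            },
            index=list(self.feature_names),
        )
        return tab.sort_values("mean_abs_shap", ascending=False)


def _coalition_matrix(predict_fn, background, x, subsets):
    """Mean prediction with coalition features from x, the rest from background rows."""
    out = {}
    for S in subsets:
        Z = background.copy()
        if S:
            Z[:, list(S)] = x[list(S)]
        out[S] = float(np.mean(predict_fn(Z)))
    return out


def _exact_shap_row(predict_fn, background, x, p):
    all_subsets = [S for r in range(p + 1) for S in combinations(range(p), r)]
    v = _coalition_matrix(predict_fn, background, x, all_subsets)
    phi = np.zeros(p)
    for j in range(p):
        others = [i for i in range(p) if i != j]
        for r in range(p):
            w = factorial(r) * factorial(p - r - 1) / factorial(p)
            for S in combinations(others, r):
                phi[j] += w * (v[tuple(sorted(S + (j,)))] - v[S])
    return phi, v[()]


def _sampled_shap_row(predict_fn, background, x, p, n_permutations, rng):
    phi = np.zeros(p)
    base = float(np.mean(predict_fn(background.copy())))
    for _ in range(n_permutations):
        perm = rng.permutation(p)
        Z = background.copy()
        prev = base
        for j in perm:
            Z[:, j] = x[j]
            cur = float(np.mean(predict_fn(Z)))
            phi[j] += cur - prev
            prev = cur
    return phi / n_permutations, base


def shap_values(
    predict_fn,
    background: np.ndarray,
    explain: np.ndarray,
    feature_names=None,
    n_permutations: int = 32,
    seed: int = 0,
    exact_max: int = 12,
) -> ShapReport:
    """Shapley attribution of predict_fn over rows of ``explain``.

    predict_fn maps an (n, p) array to (n,) predictions.  Exact enumeration
    is used automatically when p <= exact_max, permutation sampling
    otherwise.  Rows for which predict_fn raises are reported as NaN and the
    rest proceed.
    """
    background = np.atleast_2d(np.asarray(background, float))
    explain = np.atleast_2d(np.asarray(explain, float))
    if background.shape[0] == 0:
        raise ValueError("background must be non-empty")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    p = explain.shape[1]
    names = tuple(feature_names) if feature_names is not None else tuple(
        f"x{j}" for j in range(p)
    )
    rng = np.random.default_rng(seed)
    values = np.zeros((explain.shape[0], p))
    preds = np.zeros(explain.shape[0])
    base = float(np.mean(predict_fn(background.copy())))
    for i, x in enumerate(explain):
        try:
            if p <= exact_max:
                phi, b0 = _exact_shap_row(predict_fn, background, x, p)
            else:
                phi, b0 = _sampled_shap_row(predict_fn, background, x, p, n_permutations, rng)
            values[i] = phi
            preds[i] = float(predict_fn(x[None, :])[0])
            base = b0
        except Exception:  # noqa: BLE001 - per-row isolation
            values[i] = np.nan
            preds[i] = np.nan
    return ShapReport(base_value=base, values=values, feature_names=names, predictions=preds)


def importance_summary(report: ShapReport) -> pd.DataFrame:
    """Features ranked by mean |phi| with signed means and dispersion."""
    return report.summary()


def shap_for_model(
    results,
    background_rows: int = 32,
    explain_rows: int = 32,
    n_permutations: int = 16,
    seed: int = 0,
) -> ShapReport:
    """Shapley attribution for a fitted ExplosionConsequenceResults object.

    Tabular features are attributed individually; the SMILES sequence enters
    as one grouped "structure" feature carried through an index column that
    selects which chemical's tokens are used.
    """
    rng = np.random.default_rng(seed)
    X_tab, chem_idx, names = results.interpretation_matrix()
    n = X_tab.shape[0]
    bg = rng.choice(n, size=min(background_rows, n), replace=False)
    ex = rng.choice(n, size=min(explain_rows, n), replace=False)
    Z_bg = np.hstack([X_tab[bg], chem_idx[bg, None].astype(float)])
    Z_ex = np.hstack([X_tab[ex], chem_idx[ex, None].astype(float)])

    def predict_fn(Z):
        return results.predict_from_interpretation(Z[:, :-1], Z[:, -1].astype(int))

    return shap_values(
        predict_fn,
        Z_bg,
        Z_ex,
        feature_names=tuple(names) + ("structure",),
        n_permutations=n_permutations,
        seed=seed,
    )
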