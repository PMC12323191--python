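"""The fusion model, statsmodels-style: a data-bound Model whose fit() returns
a Results object carrying estimates, metrics, diagnostics and a summary table.

The model predicts log10 explosion diameter from three input modalities:

* the chemical's SMILES string (tokenized, transformer-encoded),
* its molecular-descriptor vector (pruned, standardized),
* the leak-scenario parameters (temperature, pressure, leak size, quantity;
  standardized together with the descriptors).

Training is two-stage: (1) the encoder/fusion trunk with a temporary linear
head is gradient-trained on MSE of the standardized log-diameter; (2) the
trunk is frozen, fused features are extracted for the training rows, and an
epsilon-insensitive RBF support vector regressor is fitted on them as the
final head.  Variants "no_cross_attention" (concatenation-only fusion) and
"no_transformer" (tabular features straight into the SVR) support the
ablation experiment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import simulate
from .domain import LeverageReport, williams_data
from .features import (
    DataSplit,
    SmilesTokenizer,
    Standardizer,
    log_transform,
    prune_descriptors,
    split_by_compound,
)
from .nn import AttentionConfig, FusionTrunk, train_trunk
from .svr import SVRSpec, fit_svr, svr_predict
from .validation import (
    MetricsReport,
    PredictionSet,
    ValidationReport,
    compute_metrics,
    golbraikh_tropsha,
    q2_cross_validated,
)

__all__ = ["ExplosionConsequenceModel", "ExplosionConsequenceResults", "fit_bts", "DEFAULT_HYPERPARAMS"]

SCENARIO_COLUMNS = ("temperature_c", "pressure_psi", "leak_size_in", "quantity_m3")


def _random_smiles_variants(smiles: str, n: int, seed: int) -> list[str]:
    """Non-canonical SMILES renderings of one molecule (augmentation views)."""
    if n <= 0:
        return []
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return []
    return list(Chem.MolToRandomSmilesVect(mol, n, randomSeed=seed))

_RESERVED = ("chem_id", "smiles", "density_kg_m3", "heat_of_combustion_mj_kg", "boiling_point_c")


def _apply_structure_weight(Z, trunk, alpha: float):
    """ARD-style modality weighting: scale the structure blocks of the
    standardized fused matrix by alpha so the SVR kernel weighs the clean
    tabular geometry against the noisier learned-structure view."""
    if trunk is None or trunk.variant == "tabular_only" or alpha == 1.0:
        return Z
    d = trunk.config.model_dim
    n_struct = {"full": 2, "no_cross_attention": 1}[trunk.variant]
    Z = Z.copy()
    Z[:, : n_struct * d] *= alpha
    return Z
BUNDLE_FORMAT = "expfusion-bundle-1"

#: Training defaults; every entry can be overridden per fit() call or tuned
#: by the Bayesian optimizer.  The head values (C, epsilon, gamma,
#: structure_weight) are the grouped-CV optimum plateau found by the
#: package's own Bayesian-optimization stage on the default synthetic study.
DEFAULT_HYPERPARAMS: dict = {
    "C": 1.0,
    "epsilon": 0.01,
    "gamma": 3e-4,
    "learning_rate": 2e-3,
    "model_dim": 64,
    "n_heads": 2,
    "n_layers": 2,
    "ff_dim": 128,
    "dropout": 0.1,
    "epochs": 12,
    "batch_size": 128,
    "weight_decay": 1e-4,
    "modality_dropout": 0.5,
    "structure_weight": 0.15,
}


class ExplosionConsequenceModel:
    """Multimodal consequence model bound to a chemicals table and a consequence table.

    Parameters
    ----------
    chemicals : DataFrame with chem_id, smiles, bulk-property columns and one
        column per molecular descriptor.
    dataset : long DataFrame with chem_id, the four scenario columns and
        diameter_m.
    split_ratio, split_seed : compound-grouped train/test split control.
    log_base : base of the target log transform (default 10).
    corr_threshold, zero_fraction_threshold : descriptor-pruning thresholds.
    """

    def __init__(
        self,
        chemicals: pd.DataFrame,
        dataset: pd.DataFrame,
        split_ratio: float = 0.8,
        split_seed: int = 0,
        log_base: float = 10.0,
        corr_threshold: float = 0.95,
        zero_fraction_threshold: float = 0.8,
        n_augment: int = 8,
    ):
        self.n_augment = int(n_augment)
        missing = [c for c in ("chem_id", "smiles") if c not in chemicals.columns]
        missing += [c for c in ("chem_id", "diameter_m") if c not in dataset.columns]
        missing += [c for c in SCENARIO_COLUMNS if c not in dataset.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        self.chemicals = chemicals.reset_index(drop=True)
        self.dataset = dataset.reset_index(drop=True)
        self.log_base = log_base
        self.descriptor_columns = [
            c for c in chemicals.columns if c not in _RESERVED
        ]
        self.split: DataSplit = split_by_compound(self.dataset, split_ratio, split_seed)
        self._prepare(corr_threshold, zero_fraction_threshold)

    # -- constructors --------------------------------------------------------

    @classmethod
    def from_synthetic(
        cls,
        n_chemicals: int = 40,
        noise_sigma: float = 0.0,
        seed: int = 0,
        split_seed: int | None = None,
        **kwargs,
    ) -> "ExplosionConsequenceModel":
        """Build the model on the default synthetic study: n chemicals x the
        standard 108-scenario factorial grid, surrogate consequences."""
        chems = simulate.make_synthetic_chemicals(n_chemicals, seed=seed)
        cfg = simulate.SurrogateConfig(noise_sigma=noise_sigma, seed=seed)
        records = simulate.generate_dataset(chems, simulate.standard_grid(), cfg)
        return cls(
            simulate.chemicals_to_frame(chems),
            simulate.dataset_to_frame(records),
            split_seed=seed if split_seed is None else split_seed,
            **kwargs,
        )

    # -- featurization state -------------------------------------------------

    def _prepare(self, corr_threshold: float, zero_fraction_threshold: float) -> None:
        chem_table = self.chemicals.set_index("chem_id")
        train_desc = chem_table.loc[list(self.split.train_chem_ids), self.descriptor_columns]
        self.keep_mask = prune_descriptors(
            train_desc, corr_threshold, zero_fraction_threshold
        )
        self.kept_descriptors = [c for c in self.descriptor_columns if self.keep_mask[c]]
        # row-level tabular matrix: kept descriptors (per chemical) + scenario
        desc_rows = chem_table.loc[self.dataset["chem_id"], self.kept_descriptors].to_numpy(float)
        scen_rows = self.dataset[list(SCENARIO_COLUMNS)].to_numpy(float)
        self._tab_raw = np.hstack([desc_rows, scen_rows])
        self.tabular_names = self.kept_descriptors + list(SCENARIO_COLUMNS)
        self.scaler = Standardizer().fit(self._tab_raw[self.split.train_rows])
        self._tab = self.scaler.transform(self._tab_raw)
        self._y = log_transform(self.dataset["diameter_m"].to_numpy(), base=self.log_base)
        # token batch per chemical, indexed by position in self._chem_ids
        self._chem_ids = list(chem_table.index)
        self._smiles = list(chem_table["smiles"])
        self._variants = [
            _random_smiles_variants(s, n=self.n_augment, seed=17) for s in self._smiles
        ]
        train_pos = {c for c in self.split.train_chem_ids}
        vocab_source = [
            s
            for cid, canon, var in zip(self._chem_ids, self._smiles, self._variants)
            if cid in train_pos
            for s in [canon, *var]
        ]
        self.tokenizer = SmilesTokenizer.fit(vocab_source)
        encoded = [self.tokenizer.encode(s) for s in self._smiles]
        enc_var = [[self.tokenizer.encode(s) for s in var] for var in self._variants]
        max_len = max(
            max(len(e) for e in encoded),
            max((len(e) for var in enc_var for e in var), default=0),
        )
        self._ids_all, self._mask_all = self.tokenizer.pad_batch(encoded, max_len)
        # (n_chem, n_variants + 1, L): slot 0 is the canonical form
        n_var = self.n_augment + 1
        self._ids_aug = np.tile(self._ids_all[:, None, :], (1, n_var, 1))
        self._mask_aug = np.tile(self._mask_all[:, None, :], (1, n_var, 1))
        for ci, var in enumerate(enc_var):
            if var:
                ids_v, mask_v = self.tokenizer.pad_batch(var, max_len)
                self._ids_aug[ci, 1 : 1 + len(var)] = ids_v
                self._mask_aug[ci, 1 : 1 + len(var)] = mask_v
        self._row_chem_idx = np.asarray(
            [self._chem_ids.index(c) for c in self.dataset["chem_id"]]
        )

    # -- fitting -------------------------------------------------------------

    def fit(
        self,
        variant: str = "full",
        hyperparams: dict | None = None,
        seed: int = 0,
        epochs: int | None = None,
    ) -> "ExplosionConsequenceResults":
        """Two-stage training of the requested variant; deterministic given the seed."""
        hp = dict(DEFAULT_HYPERPARAMS)
        hp.update(hyperparams or {})
        if epochs is not None:
            hp["epochs"] = epochs
        tr = self.split.train_rows
        y_scale = Standardizer().fit(self._y[tr, None])
        trunk = None
        if variant in ("full", "no_cross_attention"):
            config = AttentionConfig(
                model_dim=int(hp["model_dim"]),
                n_heads=int(hp["n_heads"]),
                n_layers=int(hp["n_layers"]),
                ff_dim=int(hp["ff_dim"]),
                dropout=float(hp["dropout"]),
            )
            trunk = FusionTrunk(
                vocab_size=self.tokenizer.vocab_size,
                n_tabular=self._tab.shape[1],
                config=config,
                variant=variant,
                seed=seed,
            )
            chem_tr = self._row_chem_idx[tr]
            n_var = self._ids_aug.shape[1]

            def sample_tokens(idx, rng):
                ci = chem_tr[idx]
                vi = rng.integers(0, n_var, size=len(idx))
                return self._ids_aug[ci, vi], self._mask_aug[ci, vi]

            train_trunk(
                trunk,
                self._ids_all[chem_tr],
                self._mask_all[chem_tr],
                self._tab[tr],
                y_scale.transform(self._y[tr, None])[:, 0],
                epochs=int(hp["epochs"]),
                batch_size=int(hp["batch_size"]),
                lr=float(hp["learning_rate"]),
                seed=seed,
                weight_decay=float(hp.get("weight_decay", 1e-4)),
                modality_dropout=float(hp.get("modality_dropout", 0.0)),
                sample_tokens=sample_tokens,
            )
        elif variant != "no_transformer":
            raise ValueError(f"unknown variant {variant!r}")
        feats_all = self._features(trunk, np.arange(len(self._y)))
        feat_scaler = Standardizer()
        mu = feats_all[tr].mean(axis=0)
        sd = feats_all[tr].std(axis=0)
        sd[sd == 0] = 1.0  # trunk features may contain flat columns; keep them inert
        feat_scaler.mean_, feat_scaler.std_ = mu, sd
        Z = _apply_structure_weight(
            feat_scaler.transform(feats_all), trunk, float(hp["structure_weight"])
        )
        spec = fit_svr(
            Z[tr], self._y[tr], C=float(hp["C"]), epsilon=float(hp["epsilon"]), gamma=hp["gamma"]
        )
        return ExplosionConsequenceResults(
            model=self,
            variant=variant,
            hyperparams=hp,
            seed=seed,
            trunk=trunk,
            feat_scaler=feat_scaler,
            svr=spec,
        )

    def _features(self, trunk: FusionTrunk | None, rows: np.ndarray) -> np.ndarray:
        """Fused (or tabular-only) features for dataset rows, evaluation mode.

        Fused features are averaged over the canonical and randomized SMILES
        renderings (test-time augmentation): the mean over views damps
        encoder noise on unseen structures while staying deterministic.
        """
        tab = self._tab[rows]
        if trunk is None:
            return tab
        idx = self._row_chem_idx[rows]
        n_var = self._ids_aug.shape[1]
        acc = None
        for v in range(n_var):
            out = []
            for start in range(0, len(rows), 512):
                sl = slice(start, start + 512)
                out.append(
                    trunk.features(
                        self._ids_aug[idx[sl], v], self._mask_aug[idx[sl], v], tab[sl]
                    )
                )
            F = np.vstack(out)
            acc = F if acc is None else acc + F
        return acc / n_var


@dataclass
class ExplosionConsequenceResults:
    """Fitted model state plus metrics, validation and diagnostic exports."""

    model: ExplosionConsequenceModel
    variant: str
    hyperparams: dict
    seed: int
    trunk: FusionTrunk | None
    feat_scaler: Standardizer
    svr: SVRSpec
    _cache: dict = field(default_factory=dict, repr=False)

    # -- prediction ----------------------------------------------------------

    def _design(self, feats: np.ndarray) -> np.ndarray:
        return _apply_structure_weight(
            self.feat_scaler.transform(feats),
            self.trunk,
            float(self.hyperparams.get("structure_weight", 1.0)),
        )

    def _predict_rows(self, rows: np.ndarray) -> np.ndarray:
        feats = self.model._features(self.trunk, rows)
        return svr_predict(self.svr, self._design(feats))

    def fittedvalues(self, which: str = "train") -> np.ndarray:
        rows = getattr(self.model.split, f"{which}_rows")
        key = f"pred_{which}"
        if key not in self._cache:
            self._cache[key] = self._predict_rows(rows)
        return self._cache[key]

    def predict(self, chemicals: pd.DataFrame, scenarios: pd.DataFrame) -> pd.DataFrame:
        """Predict log10 diameter (and diameter in metres) for new rows.

        ``chemicals`` needs chem_id, smiles and the kept descriptor columns;
        ``scenarios`` needs chem_id plus the four scenario columns.  Rows are
        matched on chem_id.
        """
        m = self.model
        unknown = [c for c in m.kept_descriptors if c not in chemicals.columns]
        if unknown:
            raise ValueError(f"missing descriptor columns: {unknown}")
        chem_table = chemicals.set_index("chem_id")
        desc = chem_table.loc[scenarios["chem_id"], m.kept_descriptors].to_numpy(float)
        scen = scenarios[list(SCENARIO_COLUMNS)].to_numpy(float)
        tab = m.scaler.transform(np.hstack([desc, scen]))
        if self.trunk is None:
            feats = tab
        else:
            encoded = [m.tokenizer.encode(s) for s in chem_table["smiles"]]
            ids, mask = m.tokenizer.pad_batch(encoded)
            pos = {c: i for i, c in enumerate(chem_table.index)}
            sel = np.asarray([pos[c] for c in scenarios["chem_id"]])
            feats = self.trunk.features(ids[sel], mask[sel], tab)
        y_log = svr_predict(self.svr, self._design(feats))
        return pd.DataFrame(
            {
                "chem_id": scenarios["chem_id"].to_numpy(),
                "log_diameter_pred": y_log,
                "diameter_m_pred": np.power(m.log_base, y_log),
            }
        )

    # -- metrics and validation ---------------------------------------------

    def prediction_set(self, which: str = "test") -> PredictionSet:
        rows = getattr(self.model.split, f"{which}_rows")
        return PredictionSet(y_sim=self.model._y[rows], y_pred=self.fittedvalues(which))

    @property
    def train_metrics(self) -> MetricsReport:
        return compute_metrics(self.prediction_set("train"))

    @property
    def test_metrics(self) -> MetricsReport:
        return compute_metrics(self.prediction_set("test"))

    def q2_cv(self, folds: int | str = 5, seed: int = 0) -> float:
        """Compound-grouped cross-validated Q^2 of the SVR head on frozen trunk features."""
        m = self.model
        tr = m.split.train_rows
        Z = self._design(m._features(self.trunk, tr))
        groups = m.dataset["chem_id"].to_numpy()[tr]
        hp = self.hyperparams

        def factory(Xf, yf):
            spec = fit_svr(Xf, yf, C=float(hp["C"]), epsilon=float(hp["epsilon"]), gamma=hp["gamma"])
            return lambda Xq: svr_predict(spec, Xq)

        return q2_cross_validated(factory, Z, m._y[tr], groups, folds=folds, seed=seed)

    def validation_report(self, q2_loo: bool = False) -> ValidationReport:
        """Golbraikh-Tropsha battery on the test set (optionally with Q^2_LOO)."""
        q2 = self.q2_cv(folds="loo") if q2_loo else self.q2_cv(folds=5)
        return golbraikh_tropsha(self.prediction_set("test"), q2_loo=q2)

    def williams(self) -> LeverageReport:
        """Leverage / standardized-residual table on the standardized tabular matrix."""
        m = self.model
        tr, te = m.split.train_rows, m.split.test_rows
        return williams_data(
            m._tab[tr], m._y[tr], self.fittedvalues("train"),
            m._tab[te], m._y[te], self.fittedvalues("test"),
        )

    # -- interpretation hooks (grouped-structure SHAP) ------------------------

    def interpretation_matrix(self):
        m = self.model
        return m._tab, m._row_chem_idx, list(m.tabular_names)

    def predict_from_interpretation(self, X_tab, chem_idx) -> np.ndarray:
        m = self.model
        X_tab = np.atleast_2d(np.asarray(X_tab, float))
        if self.trunk is None:
            feats = X_tab
        else:
            feats = self.trunk.features(
                m._ids_all[chem_idx], m._mask_all[chem_idx], X_tab
            )
        return svr_predict(self.svr, self._design(feats))

    # -- reporting ------------------------------------------------------------

    def summary(self) -> str:
        trm, tem = self.train_metrics, self.test_metrics
        lines = [
            "Explosion-consequence fusion model",
            "=" * 50,
            f"variant:            {self.variant}",
            f"chemicals:          {len(self.model._chem_ids)} "
            f"(train {len(self.model.split.train_chem_ids)} / test {len(self.model.split.test_chem_ids)})",
            f"rows:               {len(self.model.dataset)}",
            f"tabular features:   {len(self.model.tabular_names)} "
            f"({len(self.model.kept_descriptors)} descriptors + 4 scenario)",
            f"SVR: C={self.hyperparams['C']}, epsilon={self.hyperparams['epsilon']}, "
            f"gamma={self.svr.gamma:.4g}, support vectors={len(self.svr.dual_coef)}",
            "-" * 50,
            f"{'metric':<10}{'train':>12}{'test':>12}",
            f"{'R2':<10}{trm.r2:>12.4f}{tem.r2:>12.4f}",
            f"{'RMSE':<10}{trm.rmse:>12.4f}{tem.rmse:>12.4f}",
            f"{'MAE':<10}{trm.mae:>12.4f}{tem.mae:>12.4f}",
            f"{'MSE':<10}{trm.mse:>12.4f}{tem.mse:>12.4f}",
        ]
        return "\n".join(lines)

    # -- persistence -----------------------------------------------------------

    def save(self, path) -> None:
        """Write a portable bundle directory (manifest.json + weights.npz)."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        m = self.model
        manifest = {
            "format": BUNDLE_FORMAT,
            "variant": self.variant,
            "seed": self.seed,
            "hyperparams": {k: v for k, v in self.hyperparams.items()},
            "log_base": m.log_base,
            "vocabulary": m.tokenizer.vocabulary,
            "kept_descriptors": m.kept_descriptors,
            "tabular_names": m.tabular_names,
            "chem_ids": m._chem_ids,
            "svr": {"C": self.svr.C, "epsilon": self.svr.epsilon, "gamma": self.svr.gamma,
                    "intercept": self.svr.intercept},
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
        arrays = {
            "tab_mean": m.scaler.mean_, "tab_std": m.scaler.std_,
            "feat_mean": self.feat_scaler.mean_, "feat_std": self.feat_scaler.std_,
            "svr_support": self.svr.support_vectors, "svr_dual": self.svr.dual_coef,
        }
        if self.trunk is not None:
            arrays.update({f"trunk.{k}": v for k, v in self.trunk.state_dict().items()})
            manifest["trunk_config"] = vars(self.trunk.config) | {"variant": self.trunk.variant}
            (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
        np.savez(path / "weights.npz", **arrays)

    @staticmethod
    def load(path, model: ExplosionConsequenceModel) -> "ExplosionConsequenceResults":
        """Rebind a saved bundle to a model holding the same featurized data."""
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        if manifest.get("format") != BUNDLE_FORMAT:
            raise ValueError(f"incompatible bundle format {manifest.get('format')!r}")
        for key in ("vocabulary", "kept_descriptors", "svr"):
            if key not in manifest:
                raise ValueError(f"corrupt bundle: missing {key!r}")
        arrays = np.load(path / "weights.npz")
        trunk = None
        if "trunk_config" in manifest:
            cfgd = dict(manifest["trunk_config"])
            variant = cfgd.pop("variant")
            trunk = FusionTrunk(
                vocab_size=len(manifest["vocabulary"]),
                n_tabular=len(manifest["tabular_names"]),
                config=AttentionConfig(**cfgd),
                variant=variant,
                seed=manifest["seed"],
            )
            trunk.load_state_dict(
                {k[len("trunk."):]: arrays[k] for k in arrays.files if k.startswith("trunk.")}
            )
        feat_scaler = Standardizer(mean_=arrays["feat_mean"], std_=arrays["feat_std"])
        svr = SVRSpec(
            C=manifest["svr"]["C"], epsilon=manifest["svr"]["epsilon"],
            gamma=manifest["svr"]["gamma"], support_vectors=arrays["svr_support"],
            dual_coef=arrays["svr_dual"], intercept=manifest["svr"]["intercept"],
        )
        return ExplosionConsequenceResults(
            model=model, variant=manifest["variant"], hyperparams=manifest["hyperparams"],
            seed=manifest["seed"], trunk=trunk, feat_scaler=feat_scaler, svr=svr,
        )


def fit_bts(
    chemicals: pd.DataFrame,
    dataset: pd.DataFrame,
    hyperparams: dict | None = None,
    seed: int = 0,
    **model_kwargs,
) -> ExplosionConsequenceResults:
    """One-call convenience: build the model and fit the full variant."""
    model = ExplosionConsequenceModel(chemicals, dataset, **model_kwargs)
    return model.fit(variant="full", hyperparams=hyperparams, seed=seed)
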