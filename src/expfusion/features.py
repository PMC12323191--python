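"""Featurization: target transform, descriptor pruning, SMILES tokenization,
compound-grouped splitting, standardization and structural-diversity statistics.

All fitting-type operations (pruning masks, scaling statistics, the token
vocabulary) are learned on training rows only and then applied unchanged to
test rows, so no information leaks across the compound-level split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

__all__ = [
    "log_transform",
    "prune_descriptors",
    "SmilesTokenizer",
    "TokenizedSmiles",
    "DataSplit",
    "split_by_compound",
    "tanimoto_matrix",
    "Standardizer",
]

PAD, BOS, EOS, UNK = "<pad>", "<bos>", "<eos>", "<unk>"
_SPECIALS = (PAD, BOS, EOS, UNK)
# two-character organic-subset atoms merged into single tokens
_TWO_CHAR = ("Cl", "Br")


def log_transform(diameters, base: float = 10.0) -> np.ndarray:
    """Elementwise log of strictly positive consequence values (default base 10).

    Compresses the right-skewed raw diameter distribution toward symmetry
    before regression.
    """
    x = np.asarray(diameters, dtype=float)
    bad = np.flatnonzero(~(x > 0))
    if bad.size:
        raise ValueError(f"non-positive value at row(s) {bad.tolist()[:5]}: log undefined")
    return np.log(x) / np.log(base)


def prune_descriptors(
    matrix: pd.DataFrame,
    corr_threshold: float = 0.95,
    zero_fraction_threshold: float = 0.8,
    variance_floor: float = 1e-12,
) -> pd.Series:
    """Boolean keep-mask over descriptor columns, fitted on training rows.

    Drops (in order): near-zero-variance columns; columns that are zero in
    more than ``zero_fraction_threshold`` of rows; then scans column pairs in
    name order and drops the alphabetically later member of any pair with
    |Pearson r| >= ``corr_threshold``.  Deterministic.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 training rows to prune descriptors")
    if not (0 < corr_threshold <= 1 and 0 < zero_fraction_threshold <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    keep = pd.Series(True, index=matrix.columns)
    for col in matrix.columns:
        v = matrix[col].to_numpy(dtype=float)
        if np.var(v) <= variance_floor:
            keep[col] = False
        elif np.mean(v == 0.0) > zero_fraction_threshold:
            keep[col] = False
    ordered = sorted(c for c in matrix.columns if keep[c])
    for i, a in enumerate(ordered):
        if not keep[a]:
            continue
        va = matrix[a].to_numpy(dtype=float)
        for b in ordered[i + 1 :]:
            if not keep[b]:
                continue
            r = np.corrcoef(va, matrix[b].to_numpy(dtype=float))[0, 1]
            if np.abs(r) >= corr_threshold:
                keep[b] = False
    if not keep.any():
        raise ValueError("all descriptor columns were pruned")
    return keep


@dataclass(frozen=True)
class TokenizedSmiles:
    tokens: tuple[int, ...]
    smiles: str

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class SmilesTokenizer:
    """Character-level SMILES tokenizer with two-character halogens (Cl, Br)
    and bracket atoms ([...]) merged into single tokens.

    The vocabulary is built from training SMILES; encoding appends begin/end
    sentinels and maps unseen tokens to a reserved unknown id.  Decoding
    inverts encoding exactly for any string built from known tokens.
    """

    vocabulary: dict[str, int] = field(default_factory=dict)

    @property
    def pad_id(self) -> int:
        return self.vocabulary[PAD]

    @property
    def vocab_size(self) -> int:
        return len(self.vocabulary)

    @staticmethod
    def split(smiles: str) -> list[str]:
        if not smiles:
            raise ValueError("empty SMILES string")
        out: list[str] = []
        depth = 0
        i = 0
        while i < len(smiles):
            ch = smiles[i]
            if ch == "[":
                j = smiles.find("]", i)
                if j < 0:
                    raise ValueError(f"unclosed bracket atom at position {i} in {smiles!r}")
                out.append(smiles[i : j + 1])
                i = j + 1
                continue
            if ch == "]":
                raise ValueError(f"unmatched ']' at position {i} in {smiles!r}")
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    raise ValueError(f"unmatched ')' at position {i} in {smiles!r}")
            if smiles[i : i + 2] in _TWO_CHAR:
                out.append(smiles[i : i + 2])
                i += 2
            else:
                out.append(ch)
                i += 1
        if depth != 0:
            raise ValueError(f"unbalanced parentheses in {smiles!r}")
        return out

    @classmethod
    def fit(cls, smiles_list) -> "SmilesTokenizer":
        vocab = {tok: i for i, tok in enumerate(_SPECIALS)}
        for s in smiles_list:
            for tok in cls.split(s):
                vocab.setdefault(tok, len(vocab))
        return cls(vocabulary=vocab)

    def encode(self, smiles: str) -> TokenizedSmiles:
        unk = self.vocabulary[UNK]
        ids = [self.vocabulary[BOS]]
        ids += [self.vocabulary.get(tok, unk) for tok in self.split(smiles)]
        ids.append(self.vocabulary[EOS])
        return TokenizedSmiles(tokens=tuple(ids), smiles=smiles)

    def decode(self, token_ids) -> str:
        inv = {i: t for t, i in self.vocabulary.items()}
        return "".join(inv[i] for i in token_ids if inv[i] not in _SPECIALS)

    def pad_batch(self, encoded: list[TokenizedSmiles], max_len: int | None = None):
        """(ids, mask) arrays of shape (batch, L); mask is 1 on real tokens."""
        lengths = [len(e) for e in encoded]
        L = max_len or max(lengths)
        ids = np.full((len(encoded), L), self.pad_id, dtype=np.int64)
        mask = np.zeros((len(encoded), L), dtype=float)
        for r, e in enumerate(encoded):
            k = min(len(e), L)
            ids[r, :k] = e.tokens[:k]
            mask[r, :k] = 1.0
        return ids, mask


@dataclass(frozen=True)
class DataSplit:
    """Compound-grouped train/test partition: all rows of a chemical stay together."""

    train_chem_ids: tuple[str, ...]
    test_chem_ids: tuple[str, ...]
    train_rows: np.ndarray
    test_rows: np.ndarray


def split_by_compound(dataset: pd.DataFrame, ratio: float = 0.8, seed: int = 0) -> DataSplit:
    """Shuffle chemical ids with the seed and assign round(ratio * n) to training.

    Grouping by compound prevents a chemical's rows from leaking across the
    partition.  Depends only on the set of chemical ids and the seed, not on
    row order.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must lie in (0, 1)")
    chem_ids = sorted(dataset["chem_id"].unique())
    if len(chem_ids) < 2:
        raise ValueError("need at least 2 chemicals to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(chem_ids))
    n_train = round(ratio * len(chem_ids))
    if n_train == 0 or n_train == len(chem_ids):
        raise ValueError("split leaves a partition empty")
    train_ids = tuple(sorted(chem_ids[i] for i in order[:n_train]))
    test_ids = tuple(sorted(chem_ids[i] for i in order[n_train:]))
    in_train = dataset["chem_id"].isin(train_ids).to_numpy()
    return DataSplit(
        train_chem_ids=train_ids,
        test_chem_ids=test_ids,
        train_rows=np.flatnonzero(in_train),
        test_rows=np.flatnonzero(~in_train),
    )


def _morgan_fingerprints(smiles_list, radius: int = 2, n_bits: int = 2048):
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fps = []
    for s in smiles_list:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {s!r}")
        fps.append(gen.GetFingerprint(mol))
    return fps


def tanimoto_matrix(smiles_list, radius: int = 2, n_bits: int = 2048) -> np.ndarray:
    """Pairwise Tanimoto similarity on circular (Morgan) fingerprints.

    Radius-2, 2048-bit fingerprints; T(a, b) = |A n B| / |A u B| on the bit
    sets.  Symmetric with unit diagonal; values in [0, 1].
    """
    from rdkit import DataStructs

    fps = _morgan_fingerprints(smiles_list, radius=radius, n_bits=n_bits)
    n = len(fps)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = DataStructs.TanimotoSimilarity(fps[i], fps[j])
    return out


@dataclass
class Standardizer:
    """Per-column z-scoring with statistics fitted on training rows only."""

    mean_: np.ndarray | None = None
    std_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 training rows to standardize")
        self.mean_ = X.mean(axis=0)
        self.std_ = X.std(axis=0, ddof=0)
        zero = np.flatnonzero(self.std_ == 0)
        if zero.size:
            raise ValueError(
                f"zero-variance column(s) {zero.tolist()} reached the scaler; prune first"
            )
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("Standardizer not fitted")
        return (np.asarray(X, dtype=float) - self.mean_) / self.std_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("Standardizer not fitted")
        return np.asarray(Z, dtype=float) * self.std_ + self.mean_
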