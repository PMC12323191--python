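"""Target transform, descriptor pruning, tokenization, splitting, similarity."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import skew

from expfusion.features import (
    SmilesTokenizer,
    Standardizer,
    log_transform,
    prune_descriptors,
    split_by_compound,
    tanimoto_matrix,
)
from expfusion.simulate import TEMPLATE_LIBRARY


class TestLogTransform:
    def test_log10_identities(self):
        assert log_transform([100.0])[0] == pytest.approx(2.0)
        np.testing.assert_allclose(log_transform([1.0, 10.0, 100.0]), [0.0, 1.0, 2.0])

    def test_symmetrizes_lognormal_sample(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(0.0, 1.0, size=1000)
        assert skew(x) > 1
        assert abs(skew(log_transform(x))) < 0.15

    def test_nonpositive_value_names_row(self):
        with pytest.raises(ValueError, match=r"row\(s\) \[2\]"):
            log_transform([1.0, 2.0, -3.0])


class TestPruneDescriptors:
    def test_identical_columns_keep_exactly_one(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=30)
        df = pd.DataFrame({"a": a, "b": a})
        keep = prune_descriptors(df, 0.95, 0.8)
        assert keep.sum() == 1 and keep["a"] and not keep["b"]

    def test_mostly_zero_column_dropped(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"x": rng.normal(size=40), "sparse": np.zeros(40)})
        df.loc[:1, "sparse"] = 5.0  # zero in 95% of rows
        keep = prune_descriptors(df, 0.95, 0.8)
        assert not keep["sparse"] and keep["x"]

    def test_matches_exhaustive_pairwise_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 5))
        X[:, 3] = X[:, 1] + 1e-6 * rng.normal(size=50)  # planted duplicate pair
        df = pd.DataFrame(X, columns=list("abcde"))
        keep = prune_descriptors(df, 0.95, 0.8)
        # oracle: greedy scan over name-ordered pairs
        cols = list("abcde")
        kept = set(cols)
        for i, a in enumerate(cols):
            if a not in kept:
                continue
            for b in cols[i + 1 :]:
                if b in kept and abs(np.corrcoef(df[a], df[b])[0, 1]) >= 0.95:
                    kept.discard(b)
        assert {c for c in cols if keep[c]} == kept
        assert not keep["d"]

    def test_kept_columns_below_threshold(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(60, 8)), columns=[f"c{i}" for i in range(8)])
        keep = prune_descriptors(df, 0.5, 0.8)
        sub = df.loc[:, keep[keep].index]
        corr = np.corrcoef(sub.to_numpy().T)
        off = corr[~np.eye(len(corr), dtype=bool)]
        assert np.all(np.abs(off) < 0.5)

    def test_all_dropped_raises(self):
        df = pd.DataFrame({"a": np.ones(10), "b": np.zeros(10)})
        with pytest.raises(ValueError, match="pruned"):
            prune_descriptors(df, 0.95, 0.8)


class TestSmilesTokenizer:
    def test_simple_chain_token_count(self):
        tok = SmilesTokenizer.fit(["CCO"])
        assert len(tok.encode("CCO")) == 5  # bos C C O eos

    def test_chlorine_merged_to_single_token(self):
        tok = SmilesTokenizer.fit(["CC(Cl)=O"])
        enc = tok.encode("CC(Cl)=O")
        assert len(enc) == 9
        assert "Cl" in tok.vocabulary

    def test_bracket_atom_is_one_token(self):
        tok = SmilesTokenizer.fit(["C[NH4+]C"])
        assert "[NH4+]" in tok.vocabulary
        assert len(tok.encode("C[NH4+]C")) == 5

    @pytest.mark.parametrize("smiles", [t[1] for t in TEMPLATE_LIBRARY])
    def test_round_trip_on_template_library(self, smiles):
        tok = SmilesTokenizer.fit([smiles])
        assert tok.decode(tok.encode(smiles).tokens) == smiles

    def test_aromatic_ring_round_trip(self):
        tok = SmilesTokenizer.fit(["c1ccccc1"])
        assert tok.decode(tok.encode("c1ccccc1").tokens) == "c1ccccc1"

    def test_unknown_token_maps_to_reserved_id(self):
        tok = SmilesTokenizer.fit(["CCO"])
        enc = tok.encode("CCS")
        assert tok.vocabulary["<unk>"] in enc.tokens

    @pytest.mark.parametrize("bad", ["CC(C", "CC)C", "C[NH2", "C]C"])
    def test_unbalanced_input_raises_with_position(self, bad):
        with pytest.raises(ValueError):
            SmilesTokenizer.split(bad)

    def test_pad_batch_shapes_and_mask(self):
        tok = SmilesTokenizer.fit(["CCO", "C"])
        ids, mask = tok.pad_batch([tok.encode("CCO"), tok.encode("C")])
        assert ids.shape == mask.shape == (2, 5)
        assert mask[1].sum() == 3


class TestSplitByCompound:
    @staticmethod
    def _frame(n_chem=40, rows_per=3):
        return pd.DataFrame(
            {"chem_id": np.repeat([f"c{i:02d}" for i in range(n_chem)], rows_per)}
        )

    def test_40_chemicals_yield_32_8(self):
        split = split_by_compound(self._frame(), 0.8, seed=0)
        assert len(split.train_chem_ids) == 32
        assert len(split.test_chem_ids) == 8

    def test_same_seed_identical_partition(self):
        a = split_by_compound(self._frame(), 0.8, seed=5)
        b = split_by_compound(self._frame(), 0.8, seed=5)
        assert a.train_chem_ids == b.train_chem_ids
        np.testing.assert_array_equal(a.train_rows, b.train_rows)

    def test_rows_follow_their_chemical(self):
        df = self._frame(10, 4)
        split = split_by_compound(df, 0.7, seed=1)
        train_set = set(split.train_chem_ids)
        for r in split.train_rows:
            assert df.loc[r, "chem_id"] in train_set
        for r in split.test_rows:
            assert df.loc[r, "chem_id"] not in train_set
        assert len(split.train_rows) + len(split.test_rows) == len(df)

    def test_invariant_to_row_order(self):
        df = self._frame(12, 3)
        shuffled = df.sample(frac=1.0, random_state=9).reset_index(drop=True)
        a = split_by_compound(df, 0.75, seed=2)
        b = split_by_compound(shuffled, 0.75, seed=2)
        assert a.train_chem_ids == b.train_chem_ids


class TestTanimoto:
    def test_identical_molecules_unit_similarity(self):
        T = tanimoto_matrix(["CCO", "CCO"])
        assert T[0, 1] == pytest.approx(1.0)
        np.testing.assert_allclose(np.diag(T), 1.0)

    def test_symmetric_and_bounded(self):
        smiles = ["CCCCC", "c1ccccc1", "CCO", "CC(C)=O"]
        T = tanimoto_matrix(smiles)
        np.testing.assert_allclose(T, T.T)
        assert np.all((T >= 0) & (T <= 1))

    def test_matches_bit_set_oracle(self):
        """Ethane vs ethanol equals intersection-over-union on the raw bit sets."""
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator

        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
        bits = []
        for s in ("CC", "CCO"):
            fp = gen.GetFingerprint(Chem.MolFromSmiles(s))
            bits.append({i for i in fp.GetOnBits()})
        expected = len(bits[0] & bits[1]) / len(bits[0] | bits[1])
        T = tanimoto_matrix(["CC", "CCO"])
        assert T[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_unparseable_smiles_named(self):
        with pytest.raises(ValueError, match="xyz"):
            tanimoto_matrix(["CCO", "xyz("])


class TestStandardizer:
    def test_train_statistics_and_round_trip(self, rng):
        X = rng.normal(3.0, 2.5, size=(50, 4))
        sc = Standardizer().fit(X)
        Z = sc.transform(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-12)
        np.testing.assert_allclose(sc.inverse_transform(Z), X, atol=1e-10)

    def test_test_rows_use_train_statistics(self, rng):
        X = rng.normal(size=(20, 2))
        sc = Standardizer().fit(X)
        c = np.array([[7.0, 7.0]])
        np.testing.assert_allclose(sc.transform(c), (c - sc.mean_) / sc.std_)

    def test_zero_variance_column_rejected(self):
        X = np.column_stack([np.arange(10.0), np.ones(10)])
        with pytest.raises(ValueError, match="zero-variance"):
            Standardizer().fit(X)
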