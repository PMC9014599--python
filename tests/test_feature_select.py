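import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cernapert.delta_pcc import DeltaPccMatrix
from cernapert.feature_select import pca_reduce, rank_sum_test, select_pairs

from .conftest import make_samples


class TestRankSumTest:
    def test_exact_enumeration_value(self):
        # all 3 low ranks in one group: one-sided 1/20, two-sided 0.1
        assert rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_samples_give_p_one(self):
        assert rank_sum_test([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError, match="non-empty"):
            rank_sum_test([], [1.0])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.integers(-5000, 5000), min_size=3, max_size=10,
                    unique=True),
           st.lists(st.integers(-5000, 5000), min_size=3, max_size=10,
                    unique=True))
    def test_invariant_under_common_monotone_transform(self, a, b):
        # integer grid keeps exp() from collapsing distinct values into ties
        a = np.asarray(a, dtype=float) / 100.0
        b = np.asarray(b, dtype=float) / 100.0
        p1 = rank_sum_test(a, b)
        assert rank_sum_test(np.exp(a / 50), np.exp(b / 50)) == \
            pytest.approx(p1, abs=1e-12)


def _delta_fixture(rng, n_pairs=300, n_signal=10, n_pos=30, n_neg=30,
                   shift=1.0):
    samples = make_samples(5, n_pos, n_neg)
    ids = samples.ids_with_label("positive") + samples.ids_with_label("negative")
    delta = rng.normal(0, 0.1, (n_pairs, n_pos + n_neg))
    delta[:n_signal, :n_pos] += shift * 0.1  # planted group difference
    pairs = pd.DataFrame({
        "mirna_id": [f"m{i}" for i in range(n_pairs)],
        "rna_id": [f"r{i}" for i in range(n_pairs)],
        "rna_biotype": "mRNA",
    })
    dm = DeltaPccMatrix(pairs=pairs, sample_ids=ids,
                        pcc_normal=np.zeros(n_pairs), delta=delta)
    return dm, samples


class TestSelectPairs:
    def test_recovers_planted_differential_pairs(self, rng):
        dm, samples = _delta_fixture(rng, shift=3.0)
        fs = select_pairs(dm, samples)
        selected = set(fs.pairs["mirna_id"])
        assert len(selected & {f"m{i}" for i in range(10)}) >= 9
        assert (fs.pairs["p_value"] < 0.01).all()

    def test_null_selection_rate_near_alpha(self, rng):
        dm, samples = _delta_fixture(rng, n_pairs=2000, n_signal=0)
        fs = select_pairs(dm, samples, alpha=0.05)
        rate = len(fs.pairs) / 2000
        assert 0.02 <= rate <= 0.08

    def test_monotone_in_alpha(self, rng):
        dm, samples = _delta_fixture(rng, shift=2.0)
        lo = set(select_pairs(dm, samples, alpha=0.01).pair_ids)
        hi = set(select_pairs(dm, samples, alpha=0.1).pair_ids)
        assert lo <= hi

    def test_alpha_zero_is_error(self, rng):
        dm, samples = _delta_fixture(rng)
        with pytest.raises(ValueError, match="minimum observed p"):
            select_pairs(dm, samples, alpha=0.0)


class TestPcaReduce:
    def _reduced(self, rng, delta, n_pc=None, fit_ids=None):
        n_pairs = delta.shape[0]
        pairs = pd.DataFrame({"mirna_id": [f"m{i}" for i in range(n_pairs)],
                              "rna_id": [f"r{i}" for i in range(n_pairs)],
                              "rna_biotype": "mRNA", "p_value": 0.001,
                              "bh_fdr": 0.01})
        dm = DeltaPccMatrix(
            pairs=pairs[["mirna_id", "rna_id", "rna_biotype"]],
            sample_ids=[f"s{j}" for j in range(delta.shape[1])],
            pcc_normal=np.zeros(n_pairs), delta=delta)
        from cernapert.feature_select import FeatureSet
        fs = FeatureSet(pairs=pairs)
        return pca_reduce(fs, dm, n_pc=n_pc, fit_ids=fit_ids), dm

    def test_exact_low_rank_subspace_fully_explained(self, rng):
        basis = rng.normal(size=(20, 3))
        coords = rng.normal(size=(3, 40))
        fs, dm = self._reduced(rng, basis @ coords, n_pc=3)
        assert fs.explained_variance_ratio.sum() == pytest.approx(1.0)
        recon = fs.pca_components @ fs.scores.to_numpy().T + fs.pca_center[:, None]
        np.testing.assert_allclose(recon, dm.delta, atol=1e-8)

    def test_fit_sample_scores_are_centered(self, rng):
        fs, _ = self._reduced(rng, rng.normal(size=(15, 30)), n_pc=4)
        assert np.allclose(fs.scores.mean(axis=0), 0.0, atol=1e-10)

    def test_components_orthonormal_and_variance_non_increasing(self, rng):
        fs, _ = self._reduced(rng, rng.normal(size=(15, 30)), n_pc=5)
        gram = fs.pca_components.T @ fs.pca_components
        np.testing.assert_allclose(gram, np.eye(5), atol=1e-10)
        assert (np.diff(fs.explained_variance_ratio) <= 1e-12).all()

    def test_isotropic_noise_spreads_variance(self, rng):
        fs, _ = self._reduced(rng, rng.normal(size=(10, 500)), n_pc=1)
        assert fs.explained_variance_ratio[0] == pytest.approx(0.1, abs=0.05)

    def test_fit_subset_excludes_test_leakage(self, rng):
        delta = rng.normal(size=(12, 20))
        fit_ids = [f"s{j}" for j in range(14)]
        fs, dm = self._reduced(rng, delta, n_pc=3, fit_ids=fit_ids)
        fit_scores = fs.scores.loc[fit_ids]
        assert np.allclose(fit_scores.mean(axis=0), 0.0, atol=1e-10)
        # held-out projections need not be centered
        assert fs.scores.shape == (20, 3)

    def test_n_pc_too_large_is_error(self, rng):
        with pytest.raises(ValueError, match="n_pc"):
            self._reduced(rng, rng.normal(size=(5, 8)), n_pc=7)
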