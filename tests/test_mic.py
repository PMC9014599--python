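import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from cernapert.mic import (
    MicConfig,
    grid_mutual_information,
    mic,
    mic_brute_force,
    screen_pairs,
)

from .conftest import make_expression


class TestGridMutualInformation:
    def test_independent_uniform_grid_is_zero(self):
        mi = grid_mutual_information([0, 0, 1, 1], [0, 1, 0, 1], [0.5], [0.5])
        assert mi == pytest.approx(0.0, abs=1e-12)

    def test_perfect_two_symbol_dependence_is_one_bit(self):
        mi = grid_mutual_information([0, 0, 1, 1], [0, 0, 1, 1], [0.5], [0.5])
        assert mi == pytest.approx(1.0, abs=1e-12)

    def test_hand_evaluated_2x3_grid(self):
        # cells/6: c0r0=2, c1r1=1, c2r0=1, c2r1=2 -> 4/3 - log2(3)/2 bits
        x = [0, 0, 1, 2, 2, 2]
        y = [0, 0, 1, 0, 1, 1]
        mi = grid_mutual_information(x, y, [0.5, 1.5], [0.5])
        assert mi == pytest.approx(4 / 3 - np.log2(3) / 2, abs=1e-12)

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError, match="length"):
            grid_mutual_information([1, 2], [1, 2, 3], [0.5], [0.5])

    def test_bounded_by_log_min_grid_dim(self, rng):
        for _ in range(20):
            x = rng.normal(size=40)
            y = rng.normal(size=40)
            xe = np.quantile(x, [0.3, 0.6])
            ye = np.quantile(y, [0.5])
            assert grid_mutual_information(x, y, xe, ye) <= np.log2(2) + 1e-12


class TestMic:
    def test_noiseless_monotone_is_exactly_one(self, rng):
        x = rng.normal(size=50)
        assert mic(x, 2 * x + 1) == 1.0

    def test_constant_input_warns_and_returns_zero(self, rng):
        with pytest.warns(UserWarning, match="constant"):
            assert mic(rng.normal(size=20), np.ones(20)) == 0.0

    def test_symmetric_in_arguments(self, rng):
        for _ in range(10):
            x = rng.normal(size=35)
            y = x + rng.normal(size=35)
            assert mic(x, y) == pytest.approx(mic(y, x), abs=1e-12)

    def test_monotone_transform_invariance_exact(self, rng):
        for _ in range(10):
            x = rng.normal(size=40)
            y = 0.5 * x + rng.normal(size=40)
            assert mic(x, y) == mic(np.exp(x), rankdata(y))

    def test_never_exceeds_brute_force(self, rng):
        cfg = MicConfig()
        for _ in range(10):
            n = int(rng.integers(12, 28))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            assert mic(x, y, cfg) <= mic_brute_force(x, y, cfg) + 1e-9

    def test_equals_brute_force_on_clump_aligned_blocks(self, rng):
        # monotone block structure: optimum grid lies on clump boundaries
        x = np.arange(20.0)
        y = np.concatenate([rng.permutation(10),
                            10 + rng.permutation(10)]).astype(float)
        assert mic(x, y) == pytest.approx(mic_brute_force(x, y), abs=1e-9)

    def test_inclusive_b_admits_larger_grids(self):
        # n=24 -> B=6; strict < 6 searches only 2x2, inclusive adds 2x3/3x2,
        # which capture this three-level pattern exactly
        x = np.arange(24.0)
        y = np.concatenate([0.01 * np.arange(8), 5 + 0.01 * np.arange(8),
                            1 + 0.01 * np.arange(8)])
        strict = MicConfig(inclusive_b=False)
        incl = MicConfig(inclusive_b=True)
        assert mic(x, y, incl) > mic(x, y, strict)
        assert mic(x, y, incl) == pytest.approx(
            mic_brute_force(x, y, incl), abs=1e-9)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=12, max_size=40,
                    unique=True),
           st.integers(0, 2 ** 31 - 1))
    def test_score_in_unit_interval(self, xs, seed):
        x = np.array(xs)
        y = np.random.default_rng(seed).normal(size=x.size)
        s = mic(x, y)
        assert 0.0 <= s <= 1.0


class TestScreenPairs:
    def _matrices(self, rng, n_samples=30):
        # one strongly coupled pair, one independent
        x = rng.normal(size=n_samples)
        mirna = make_expression(np.vstack([x, rng.normal(size=n_samples)]),
                                gene_ids=["m1", "m2"], biotype="miRNA",
                                layer="tmm_logcpm")
        cerna = make_expression(
            np.vstack([2 * x + 0.01 * rng.normal(size=n_samples),
                       rng.normal(size=n_samples)]),
            gene_ids=["r1", "r2"], biotype=["mRNA", "lncRNA"],
            layer="tmm_logcpm")
        return mirna, cerna

    def test_keeps_pairs_passing_in_either_cohort(self, rng):
        mirna, cerna = self._matrices(rng)
        ids = mirna.sample_ids
        pairs = screen_pairs(mirna, cerna, ids[:15], ids[15:])
        tab = pairs.table.set_index(["mirna_id", "rna_id"])
        assert tab.loc[("m1", "r1"), "kept"]
        assert not tab.loc[("m2", "r2"), "kept"]
        assert len(pairs.table) == 4  # full miRNA x ceRNA universe
        # kept <=> max(mic_normal, mic_tumor) >= threshold, boundary inclusive
        mx = tab[["mic_normal", "mic_tumor"]].max(axis=1)
        assert (tab["kept"] == (mx >= 0.5)).all()

    def test_overlapping_cohorts_rejected(self, rng):
        mirna, cerna = self._matrices(rng)
        ids = mirna.sample_ids
        with pytest.raises(ValueError, match="overlap"):
            screen_pairs(mirna, cerna, ids[:15], ids[10:])

    def test_small_cohort_rejected(self, rng):
        mirna, cerna = self._matrices(rng)
        ids = mirna.sample_ids
        with pytest.raises(ValueError, match=">= 11"):
            screen_pairs(mirna, cerna, ids[:5], ids[5:])

    def test_deterministic_row_order(self, rng):
        mirna, cerna = self._matrices(rng)
        ids = mirna.sample_ids
        pairs = screen_pairs(mirna, cerna, ids[:15], ids[15:])
        assert list(pairs.table["mirna_id"]) == ["m1", "m1", "m2", "m2"]
        assert list(pairs.table["rna_id"]) == ["r1", "r2", "r1", "r2"]
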