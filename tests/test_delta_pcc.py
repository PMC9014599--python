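import numpy as np
import pandas as pd
import pytest

from cernapert.delta_pcc import DeltaPccMatrix, pcc, perturbation_matrix
from cernapert.mic import PairTable

from .conftest import make_expression


class TestPcc:
    def test_perfect_linear(self):
        assert pcc([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)

    def test_perfect_anti_linear(self):
        assert pcc([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_evaluated_value(self):
        assert pcc([1, 2, 3, 4], [1, 2, 3, 0]) == pytest.approx(-0.2)

    def test_constant_input_warns_nan(self):
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(pcc([1, 1, 1], [1, 2, 3]))

    def test_too_short_is_error(self):
        with pytest.raises(ValueError, match="three"):
            pcc([1, 2], [3, 4])


def _pair_table(mirna_ids, rna_ids):
    rows = [(m, r, "mRNA", 1.0, 1.0, True) for m in mirna_ids for r in rna_ids]
    return PairTable(pd.DataFrame(
        rows, columns=["mirna_id", "rna_id", "rna_biotype", "mic_normal",
                       "mic_tumor", "kept"]))


def _single_pair_setup(normals_x, normals_y, tumor_x, tumor_y):
    nx = len(normals_x)
    mirna = make_expression([list(normals_x) + list(tumor_x)],
                            gene_ids=["m"], biotype="miRNA",
                            layer="tmm_logcpm")
    cerna = make_expression([list(normals_y) + list(tumor_y)],
                            gene_ids=["r"], layer="tmm_logcpm")
    normal_ids = mirna.sample_ids[:nx]
    tumor_ids = mirna.sample_ids[nx:]
    return _pair_table(["m"], ["r"]), mirna, cerna, normal_ids, tumor_ids


class TestPerturbationMatrix:
    def test_tumor_point_on_reference_line_gives_zero(self):
        pairs, mirna, cerna, nids, tids = _single_pair_setup(
            [1, 2, 3], [2, 4, 6], [4], [8])
        d = perturbation_matrix(pairs, mirna, cerna, nids, tids)
        assert d.pcc_normal[0] == pytest.approx(1.0)
        assert d.delta[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_perturbation(self):
        # PCC_3([1,2,3],[1,2,3]) = 1; PCC_4 with (4,0) appended = -0.2
        pairs, mirna, cerna, nids, tids = _single_pair_setup(
            [1, 2, 3], [1, 2, 3], [4], [0])
        d = perturbation_matrix(pairs, mirna, cerna, nids, tids)
        assert d.delta[0, 0] == pytest.approx(-1.2)

    def test_incremental_matches_naive_recomputation(self, rng):
        n_mir, n_rna, n_norm, n_tum = 20, 10, 30, 10
        xm = rng.normal(size=(n_mir, n_norm + n_tum))
        ym = rng.normal(size=(n_rna, n_norm + n_tum))
        mirna = make_expression(xm, gene_ids=[f"m{i}" for i in range(n_mir)],
                                biotype="miRNA", layer="tmm_logcpm")
        cerna = make_expression(ym, gene_ids=[f"r{i}" for i in range(n_rna)],
                                layer="tmm_logcpm")
        pairs = _pair_table(mirna.gene_ids, cerna.gene_ids)
        nids = mirna.sample_ids[:n_norm]
        tids = mirna.sample_ids[n_norm:]
        d = perturbation_matrix(pairs, mirna, cerna, nids, tids)
        for p in range(0, n_mir * n_rna, 37):
            mi, ri = p // n_rna, p % n_rna
            base = np.corrcoef(xm[mi, :n_norm], ym[ri, :n_norm])[0, 1]
            for s in range(n_tum):
                ref = np.corrcoef(
                    np.append(xm[mi, :n_norm], xm[mi, n_norm + s]),
                    np.append(ym[ri, :n_norm], ym[ri, n_norm + s]))[0, 1]
                assert d.delta[p, s] == pytest.approx(ref - base, abs=1e-10)

    def test_delta_bounded_and_shrinks_with_reference_size(self, rng):
        # same tumor points against nested reference cohorts: the influence
        # of one added sample vanishes as the reference grows
        x = rng.normal(size=140)
        y = 0.8 * x + 0.6 * rng.normal(size=140)
        tx, ty = rng.normal(size=20), rng.normal(size=20)
        deltas = {}
        for n_norm in (30, 120):
            pairs, mirna, cerna, nids, tids = _single_pair_setup(
                x[:n_norm], y[:n_norm], tx, ty)
            d = perturbation_matrix(pairs, mirna, cerna, nids, tids)
            assert np.all(np.abs(d.delta) <= 2.0)
            deltas[n_norm] = np.median(np.abs(d.delta))
        assert deltas[120] < deltas[30]

    def test_tumor_column_permutation_permutes_delta(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        pairs, mirna, cerna, nids, tids = _single_pair_setup(
            x[:10], y[:10], x[10:], y[10:])
        d = perturbation_matrix(pairs, mirna, cerna, nids, tids)
        perm = [tids[i] for i in (3, 0, 4, 1, 2)]
        d2 = perturbation_matrix(pairs, mirna, cerna, nids, perm)
        for j, s in enumerate(perm):
            assert d2.delta[0, j] == d.delta[0, tids.index(s)]

    def test_too_few_normals_is_error(self):
        pairs, mirna, cerna, nids, tids = _single_pair_setup(
            [1, 2], [1, 2], [3], [3])
        with pytest.raises(ValueError, match="three normal"):
            perturbation_matrix(pairs, mirna, cerna, nids, tids)

    def test_degenerate_reference_pair_dropped(self, rng):
        xm = np.vstack([np.ones(12), rng.normal(size=12)])
        ym = rng.normal(size=(1, 12))
        mirna = make_expression(xm, gene_ids=["m0", "m1"], biotype="miRNA",
                                layer="tmm_logcpm")
        cerna = make_expression(ym, gene_ids=["r0"], layer="tmm_logcpm")
        pairs = _pair_table(["m0", "m1"], ["r0"])
        with pytest.warns(UserWarning, match="degenerate"):
            d = perturbation_matrix(pairs, mirna, cerna,
                                    mirna.sample_ids[:8], mirna.sample_ids[8:])
        assert list(d.pairs["mirna_id"]) == ["m1"]

    def test_long_tsv_round_trip(self, tmp_path, rng):
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        pairs, mirna, cerna, nids, tids = _single_pair_setup(
            x[:10], y[:10], x[10:], y[10:])
        d = perturbation_matrix(pairs, mirna, cerna, nids, tids)
        d.to_long_tsv(tmp_path / "d.tsv")
        d2 = DeltaPccMatrix.from_long_tsv(tmp_path / "d.tsv")
        assert d2.sample_ids == d.sample_ids
        np.testing.assert_allclose(d2.delta, d.delta)
        np.testing.assert_allclose(d2.pcc_normal, d.pcc_normal)
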