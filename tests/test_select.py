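"""Sub-ensemble averaging, quantization, mutual information, ranking."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import wavinfo as wi
from wavinfo import dwt
from wavinfo.select import (InformationTable, coefficient_information,
                            information_matrix, mutual_information, quantize,
                            rank_and_select, subensemble_averages)


class TestSubensembleAverages:
    def test_singleton_class_gives_constant_averages(self):
        X = np.array([[1.0, 2.0], [5.0, 6.0]])
        labels = np.array([1, 2])
        avgs, lab = subensemble_averages(X, labels, n_averages=10,
                                         trials_per_average=7,
                                         rng=np.random.default_rng(0))
        np.testing.assert_allclose(avgs[lab == 1], np.tile(X[0], (10, 1)))
        np.testing.assert_allclose(avgs[lab == 2], np.tile(X[1], (10, 1)))

    def test_default_parameters_give_800_labeled_averages(self, sim_small):
        feats = sim_small.data[0]
        avgs, lab = subensemble_averages(feats, sim_small.labels,
                                         rng=np.random.default_rng(1))
        assert avgs.shape == (800, sim_small.n_samples)
        assert all(np.sum(lab == c) == 200 for c in (1, 2, 3, 4))

    def test_bootstrap_variance_matches_theory(self):
        """Var of a 30-trial bootstrap mean ~ trial variance / 30."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 1))
        avgs, _ = subensemble_averages(X, np.ones(200, dtype=int),
                                       n_averages=4000, trials_per_average=30,
                                       rng=rng)
        # single-class input is allowed for averaging; MI would reject it
        expected = X.var() / 30
        assert avgs.var() == pytest.approx(expected, rel=0.15)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            subensemble_averages(np.zeros((0, 3)), np.array([]), rng=None)


class TestQuantize:
    def test_equal_width_bins(self):
        np.testing.assert_array_equal(quantize(np.array([0.0, 1.0, 2.0, 3.0])),
                                      [0, 1, 2, 3])

    def test_constant_input_all_bin_zero(self):
        np.testing.assert_array_equal(quantize(np.full(5, 2.5)), np.zeros(5))

    def test_uniform_draws_fill_bins_evenly(self):
        v = np.random.default_rng(3).uniform(size=10_000)
        occ = np.bincount(quantize(v), minlength=4) / 10_000
        np.testing.assert_allclose(occ, 0.25, atol=0.02)


class TestMutualInformation:
    def test_independent_is_zero(self):
        assert mutual_information(np.zeros(40, dtype=int),
                                  np.repeat([1, 2], 20)) == pytest.approx(0.0)

    def test_deterministic_four_class_is_two_bits(self):
        labels = np.repeat([1, 2, 3, 4], 25)
        bins = np.repeat([0, 1, 2, 3], 25)
        assert mutual_information(bins, labels) == pytest.approx(2.0)

    def test_matches_brute_force_formula(self):
        # joint counts [[3,1],[1,3]] over 2 classes x 2 bins
        labels = np.array([0] * 4 + [1] * 4)
        bins = np.array([0, 0, 0, 1, 0, 1, 1, 1])
        expected = 0.0
        n = 8.0
        joint = np.array([[3, 1], [1, 3]]) / n
        for s in range(2):
            for b in range(2):
                p = joint[s, b]
                expected += p * np.log2(p / (joint[s].sum() * joint[:, b].sum()))
        assert mutual_information(bins, labels) == pytest.approx(expected)
        # and the vectorized column path agrees with the scalar path
        rng = np.random.default_rng(4)
        V = rng.normal(size=(60, 5))
        lab = rng.integers(1, 4, size=60)
        cols = information_matrix(V, lab, n_bits=2)
        for j in range(5):
            assert cols[j] == pytest.approx(
                mutual_information(quantize(V[:, j]), lab))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mutual_information(np.zeros(3, dtype=int), np.zeros(4, dtype=int))

    @given(st.integers(0, 2 ** 31 - 1))
    def test_bounds_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 60))
        bins = rng.integers(0, 4, size=n)
        labels = rng.integers(0, 3, size=n)
        if len(np.unique(labels)) < 2:
            labels[: 2] = [0, 1]
        mi = mutual_information(bins, labels)
        upper = min(np.log2(len(np.unique(labels))), 2.0)
        assert -1e-12 <= mi <= upper + 1e-12


class TestRankAndSelect:
    def test_agrees_with_sort_oracle(self):
        rng = np.random.default_rng(5)
        info = InformationTable(info_bits=rng.uniform(size=50))
        sel = rank_and_select(info, k=10)
        oracle = np.sort(info.info_bits)[::-1][:10]
        np.testing.assert_allclose(np.sort(sel.info_bits)[::-1], oracle)

    def test_all_equal_uses_tie_break_order(self):
        ix = dwt.build_index(32, 256.0, n_levels=3)
        info = InformationTable(info_bits=np.ones(32), index=ix)
        sel = rank_and_select(info, k=4)
        # the 4 coarsest (A3) coefficients come first under the tie-break
        assert set(ix.level[sel.coeff_ids]) == {"A3"}

    def test_k_larger_than_pool_rejected(self):
        with pytest.raises(ValueError):
            rank_and_select(InformationTable(info_bits=np.ones(5)), k=6)


class TestInformationOnSimulation:
    def test_information_concentrates_on_component_window(self, sim_small):
        coeffs = dwt.decompose_matrix(sim_small.data[0])
        ix = dwt.build_index(128, 256.0)
        table = coefficient_information(coeffs, sim_small.labels,
                                        rng=np.random.default_rng(6), index=ix)
        overlaps = (ix.support_ms[:, 1] > 100.0) & (ix.support_ms[:, 0] < 300.0)
        assert table.info_bits[overlaps].mean() > table.info_bits[~overlaps].mean()

    def test_noise_information_bias_shrinks_with_more_averages(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(120, 1))
        labels = np.repeat([1, 2], 60)
        small = coefficient_information(X, labels, n_subaverages=25,
                                        rng=np.random.default_rng(0))
        big = coefficient_information(X, labels, n_subaverages=800,
                                      rng=np.random.default_rng(0))
        assert 0.0 <= big.info_bits[0]
        assert big.info_bits[0] < small.info_bits[0] + 0.05
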