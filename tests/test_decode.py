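"""Naive-Bayes decoding, leave-one-out protocol, channel pooling."""

import numpy as np
import pytest

import wavinfo as wi
from wavinfo import dwt
from wavinfo.decode import (WIConfig, fit_naive_bayes, fold_rng, loo_decode,
                            pool_channels, predict, select_and_fit)
from wavinfo.select import InformationTable


class TestNaiveBayes:
    def test_class_with_single_trial_rejected_by_name(self):
        X = np.array([[0.0], [1.0], [2.0]])
        with pytest.raises(ValueError, match="class 2"):
            fit_naive_bayes(X, np.array([1, 1, 2]))

    def test_identical_training_sets_tie_to_first_class(self):
        X = np.array([[1.0], [2.0], [1.0], [2.0]])
        model = fit_naive_bayes(X, np.array([1, 1, 2, 2]))
        label, post = predict(model, np.array([1.5]))
        assert label == 1
        np.testing.assert_allclose(post, [0.5, 0.5])

    def test_nearer_mean_wins_with_equal_spread(self):
        eps = 1e-3
        X = np.array([[-1.0], [-1.0], [-1.0 + eps], [1.0], [1.0], [1.0 + eps]])
        y = np.array(["A", "A", "A", "B", "B", "B"])
        model = fit_naive_bayes(X, y)
        label, _ = predict(model, np.array([0.9]))
        assert label == "B"

    def test_unequal_variances_match_closed_form_gaussian_comparison(self):
        rng = np.random.default_rng(0)
        xa = rng.normal(0.0, 0.5, size=30)
        xb = rng.normal(1.0, 2.0, size=30)
        X = np.concatenate([xa, xb])[:, None]
        y = np.repeat([1, 2], 30)
        model = fit_naive_bayes(X, y)

        def loglik(x, sample):
            m, v = sample.mean(), sample.var()
            return -0.5 * ((x - m) ** 2 / v + np.log(2 * np.pi * v))

        for x in np.linspace(-2, 4, 23):
            expected = 1 if loglik(x, xa) >= loglik(x, xb) else 2
            label, post = predict(model, np.array([x]))
            assert label == expected
            assert post.sum() == pytest.approx(1.0)

    def test_multifeature_matches_density_product_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 2)) + np.repeat([[0, 0], [2, -1], [-1, 2]],
                                                 10, axis=0)
        y = np.repeat([0, 1, 2], 10)
        model = fit_naive_bayes(X, y)

        def density(x, block):
            m, v = block.mean(axis=0), block.var(axis=0)
            return np.prod(np.exp(-((x - m) ** 2) / (2 * v))
                           / np.sqrt(2 * np.pi * v))

        for x in rng.normal(size=(10, 2)):
            dens = [density(x, X[y == c]) for c in (0, 1, 2)]
            label, _ = predict(model, x)
            assert label == int(np.argmax(dens))

    def test_feature_dimension_mismatch_rejected(self):
        model = fit_naive_bayes(np.zeros((4, 2)), np.array([1, 1, 2, 2]))
        with pytest.raises(ValueError, match="dimension"):
            predict(model, np.zeros(3))


class TestLooDecode:
    def test_noiseless_separable_classes_decode_perfectly(self):
        cfg = wi.SimulationConfig(trials_per_class=8, jitter_ms=0.0,
                                  snr=np.inf, seed=1)
        ts = wi.simulate_dataset(cfg)
        result = loo_decode(ts, WIConfig(n_subaverages=30, seed=1))
        assert result.performance == 1.0
        np.testing.assert_allclose(result.confusion, np.eye(4))

    def test_confusion_rows_sum_to_one(self, sim_small, cfg_small):
        result = loo_decode(sim_small, cfg_small)
        np.testing.assert_allclose(result.confusion.sum(axis=1), 1.0)
        assert 0.0 <= result.performance <= 1.0
        assert result.fold_selections.shape == (sim_small.n_trials, 25)

    def test_no_leakage_fold_is_bit_exact(self, sim_small, cfg_small):
        """Removing the held-out trial and rerunning selection + fit with the
        fold's RNG substream reproduces the recorded prediction exactly."""
        result = loo_decode(sim_small, cfg_small)
        i = 17
        feat_all = dwt.decompose_matrix(sim_small.data)  # (nch, ntr, F)
        feat = np.transpose(feat_all, (1, 0, 2)).reshape(sim_small.n_trials, -1)
        mask = np.arange(sim_small.n_trials) != i
        index = dwt.build_index_multichannel(128, 256.0, sim_small.channels)
        selection, model = select_and_fit(
            feat[mask], sim_small.labels[mask], index, cfg_small,
            fold_rng(cfg_small.seed, i))
        np.testing.assert_array_equal(selection.coeff_ids,
                                      result.fold_selections[i])
        label, _ = predict(model, feat[i, selection.coeff_ids])
        assert label == result.y_pred[i]

    def test_channel_order_permutation_invariance(self, cfg_small):
        ts = wi.simulate_dataset(wi.SimulationConfig(trials_per_class=10,
                                                     n_channels=2, seed=13))
        a = loo_decode(ts, cfg_small)
        b = loo_decode(ts.select_channels([1, 0]), cfg_small)
        assert a.performance == b.performance
        np.testing.assert_array_equal(a.y_pred, b.y_pred)

    def test_duplicated_channel_leaves_performance_stable(self, cfg_small):
        ts = wi.simulate_dataset(wi.SimulationConfig(trials_per_class=15,
                                                     seed=17))
        dup = ts.merge_channels(ts)
        a = loo_decode(ts, cfg_small)
        b = loo_decode(dup, cfg_small)
        assert abs(a.performance - b.performance) <= 0.05

    def test_too_few_trials_rejected(self):
        ts = wi.TrialSet(data=np.zeros((1, 4, 32)), labels=[1, 1, 1, 2],
                         fs_hz=256.0)
        with pytest.raises(ValueError, match="fewer than 3"):
            loo_decode(ts, WIConfig())


class TestPoolChannels:
    def _table(self, info, seed_idx=None):
        ix = dwt.build_index(32, 256.0, n_levels=3)
        return InformationTable(info_bits=np.asarray(info, dtype=float),
                                index=ix)

    def test_exact_cardinality_over_large_pool(self):
        rng = np.random.default_rng(2)
        tables = [self._table(rng.uniform(size=32)) for _ in range(8)]
        sel = pool_channels(tables, k=25)
        assert len(sel.coeff_ids) == 25
        assert len(np.unique(sel.coeff_ids)) == 25

    def test_informative_channel_dominates_selection(self):
        strong = self._table(np.linspace(0.5, 1.5, 32))
        noise = self._table(np.full(32, 0.01))
        sel = pool_channels([strong, noise], k=10)
        assert np.all(sel.coeff_ids < 32)

    def test_mismatched_parameters_rejected(self):
        a = self._table(np.ones(32))
        b = self._table(np.ones(32))
        b.n_subaverages = 99
        with pytest.raises(ValueError, match="parameters"):
            pool_channels([a, b], k=5)
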