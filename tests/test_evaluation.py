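"""Nested CV accounting, Bayesian search, statistics vs hand oracles."""

import numpy as np
import pytest
from scipy import stats

import gripdecode as gd
from gripdecode import evaluation as ev
from gripdecode.evaluation import (
    bayes_optimize,
    coefficient_maps,
    combine_channels,
    correlation,
    fdr_adjust,
    hyperparameter_space,
    lag_saturation_sweep,
    nested_cv,
    percentage_bend_correlation,
    permutation_pvalue,
    samplewise_cluster_correlation,
    select_best_channel,
)


class TestBayesOptimize:
    def test_quadratic_beats_chance_against_grid_oracle(self):
        hits = 0
        for seed in range(50):
            best, hist = bayes_optimize(
                {"x": ("uniform", 0.0, 1.0)}, lambda p: (p["x"] - 0.3) ** 2, rounds=10, seed=seed
            )
            assert len(hist) <= 10
            hits += abs(best["x"] - 0.3) < 0.1
        assert hits >= 45  # >= 90% of seeds

    def test_constant_objective_no_error(self):
        best, hist = bayes_optimize({"x": ("uniform", 0, 1)}, lambda p: 1.0, rounds=6, seed=0)
        assert 0 <= best["x"] <= 1 and len(hist) == 6

    def test_deterministic_evaluation_sequence(self):
        calls1, calls2 = [], []
        bayes_optimize({"x": ("uniform", 0, 1)}, lambda p: calls1.append(p["x"]) or p["x"] ** 2, rounds=8, seed=3)
        bayes_optimize({"x": ("uniform", 0, 1)}, lambda p: calls2.append(p["x"]) or p["x"] ** 2, rounds=8, seed=3)
        assert calls1 == calls2

    def test_nonfinite_objective_scored_worst(self):
        def obj(p):
            return np.nan if p["x"] > 0.5 else p["x"]

        best, hist = bayes_optimize({"x": ("uniform", 0, 1)}, obj, rounds=10, seed=1)
        assert best["x"] <= 0.5

    def test_samples_respect_bounds(self):
        space = hyperparameter_space("GBT")
        seen = []
        bayes_optimize(space, lambda p: seen.append(p) or p["eta"], rounds=10, seed=2)
        for p in seen:
            assert 1 <= p["depth"] <= 100
            assert 1e-5 <= p["eta"] <= 1.0
            assert 1.0 <= p["gamma"] <= 10.0


class TestNestedCV:
    def test_fold_sizes_two_thirds_one_third(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((300, 4))
        y = X @ np.ones(4) + 0.1 * rng.standard_normal(300)
        res = nested_cv(X, y, family="WIENER", seed=0)
        assert len(res.fold_r2_raw) == 3
        assert res.prediction.shape == (300,)

    def test_leakage_sentinel_test_labels_do_not_touch_training(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((300, 4))
        y = X @ np.ones(4) + 0.1 * rng.standard_normal(300)
        res1 = nested_cv(X, y, family="ENET", seed=5, bo_rounds=4)
        y2 = y.copy()
        y2[200:] = rng.standard_normal(100)  # corrupt the last outer test block
        res2 = nested_cv(X, y2, family="ENET", seed=5, bo_rounds=4)
        # fold 3 trains on rows 0..199 only: its model and prediction match
        np.testing.assert_array_equal(res1.prediction[200:], res2.prediction[200:])
        assert res1.fold_params[2] == res2.fold_params[2]

    def test_decodable_signal_recovered_with_enet(self, coupled_session):
        fs, tgt = coupled_session["features"], coupled_session["target"]
        res = gd.decode_channel(fs, tgt.y10, "ECOG_L_0", family="ENET", seed=0, bo_rounds=5)
        assert res.mean_r2 > 0.2

    def test_spoc_route_decodes_coupled_session(self, coupled_session):
        rec, force = coupled_session["rec"], coupled_session["force"]
        ref = gd.rereference(rec)
        z = gd.zscore_session(gd.clean_force(force))
        res = ev.spoc_nested_cv(ref, z, family="SPOC_ENET", seed=1, bo_rounds=5)
        assert res.family == "SPOC_ENET"
        assert res.mean_r2 > 0.2
        assert res.prediction.shape == (120,)  # one epoch per second

    def test_mlp_family_runs_under_nested_cv(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((240, 3))
        y = X @ np.array([1.0, -0.5, 0.2]) + 0.2 * rng.standard_normal(240)
        res = nested_cv(X, y, family="MLP", seed=0, bo_rounds=2)
        assert res.prediction.shape == (240,)
        assert len(res.fold_params) == 3 and "learning_rate" in res.fold_params[0]

    def test_mean_is_arithmetic_mean_of_folds(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((120, 3))
        y = rng.standard_normal(120)
        res = nested_cv(X, y, family="WIENER", seed=0)
        assert res.mean_r2 == pytest.approx(np.mean(res.fold_r2_raw))


class TestChannelSelection:
    def _result(self, mean):
        from gripdecode.evaluation import DecodingResult

        return DecodingResult("WIENER", None, [mean] * 3, [max(0, mean)] * 3, [{}] * 3, np.zeros(3), 0)

    def test_max_and_tie_rule(self):
        results = {"ch1": self._result(0.2), "ch2": self._result(0.5)}
        assert select_best_channel(results) == "ch2"
        tied = {"ch1": self._result(0.4), "ch2": self._result(0.4)}
        assert select_best_channel(tied) == "ch1"
        assert select_best_channel({"only": self._result(0.1)}) == "only"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best_channel({})

    def test_combine_channels_width_and_order(self, coupled_session):
        fs = coupled_session["features"]
        lagged = gd.concatenate_lags(fs, 5)
        three = combine_channels(lagged, lagged.channel_labels[:3])
        assert three.shape[1] == 120
        one = combine_channels(lagged, [lagged.channel_labels[0]])
        np.testing.assert_array_equal(one, lagged.values[:, 0, :])
        # subset order does not matter: series channel order rules
        a = combine_channels(lagged, lagged.channel_labels[:2])
        b = combine_channels(lagged, lagged.channel_labels[:2][::-1])
        np.testing.assert_array_equal(a, b)
        with pytest.raises(KeyError):
            combine_channels(lagged, ["nope"])


class TestCoefficientMaps:
    def test_planted_gamma_coupling_positive_coefficients(self):
        pos = 0
        for seed in range(10):
            cfg = gd.SimulationConfig(duration_s=90.0, n_movements=9, seed=200 + seed)
            rec, force, _ = gd.generate_recording(cfg)
            fs = gd.extract_feature_series(gd.rereference(rec))
            tgt = gd.ForceTarget.from_raw(force, fs.t_end)
            keep = ~fs.burn_in
            bv = fs.values[keep, 0, :]  # contralateral ECoG channel
            multi, uni = coefficient_maps(bv, tgt.y10[keep])
            gamma_ix = [i for i, b in enumerate(fs.bands) if b.name in ("low_gamma", "hfa", "gamma")]
            pos += all(uni[i, 0] > 0 for i in gamma_ix)
        assert stats.binomtest(pos, 10, 0.5, alternative="greater").pvalue < 0.05

    def test_pure_noise_coefficients_vanish(self):
        rng = np.random.default_rng(3)
        bv = rng.standard_normal((6000, 8))
        y = rng.standard_normal(6000)
        multi, uni = coefficient_maps(bv, y)
        assert np.abs(multi).mean() < 0.05

    def test_map_shape_eight_by_five(self):
        rng = np.random.default_rng(4)
        _, uni = coefficient_maps(rng.standard_normal((500, 8)), rng.standard_normal(500))
        assert uni.shape == (8, 5)

    def test_constant_column_zero_flagged(self):
        rng = np.random.default_rng(5)
        bv = rng.standard_normal((300, 8))
        bv[:, 2] = 1.0
        multi, _ = coefficient_maps(bv, rng.standard_normal(300))
        assert multi[2] == 0.0


class TestLagSweep:
    def test_planted_300ms_kernel_saturates_early(self):
        rng = np.random.default_rng(2)
        bv = rng.standard_normal((3000, 8))
        kernel = np.array([0.5, 0.3, 0.2])  # 3 feature samples = 300 ms
        y = np.convolve(bv[:, 6], kernel)[:3000] + 0.3 * rng.standard_normal(3000)
        curve = lag_saturation_sweep(bv, y, max_lags=10, seed=0)
        assert curve.shape == (10,)
        assert curve[3] - curve[0] > curve[9] - curve[4]

    def test_white_noise_target_flat_near_zero(self):
        rng = np.random.default_rng(3)
        bv = rng.standard_normal((1500, 8))
        y = rng.standard_normal(1500)
        curve = lag_saturation_sweep(bv, y, max_lags=5, seed=0)
        assert np.abs(curve).max() < 0.05


class TestPermutation:
    def test_perfect_association_extreme_p(self):
        x = np.arange(20.0)
        p = permutation_pvalue(
            lambda a, b: stats.spearmanr(a, b).statistic, x, x, n_perm=10_000, seed=0
        )
        assert p <= 0.001

    def test_constant_statistic_p_one(self):
        x = np.arange(10.0)
        p = permutation_pvalue(lambda a, b: 0.5, x, x, n_perm=200, seed=0)
        assert p == 1.0

    def test_type_I_calibration_null_pairs(self):
        rng = np.random.default_rng(0)
        rej = 0
        for i in range(200):
            x, y = rng.standard_normal(12), rng.standard_normal(12)
            p = permutation_pvalue(
                lambda a, b: stats.spearmanr(a, b).statistic, x, y, n_perm=199, seed=i
            )
            rej += p < 0.05
        assert 0.02 <= rej / 200 <= 0.08

    def test_circular_scheme_minimum_shift_enforced(self):
        x = np.sin(np.arange(400) / 7.0)
        p = permutation_pvalue(
            lambda a, b: np.corrcoef(a, b)[0, 1], x, x, n_perm=200, seed=1, scheme="circular"
        )
        assert 0 < p <= 1
        with pytest.raises(ValueError, match="shift"):
            permutation_pvalue(
                lambda a, b: 0.0, np.zeros(50), np.zeros(50), n_perm=100, seed=0, scheme="circular"
            )


class TestCorrelation:
    def test_monotone_extremes(self):
        a = np.array([1.0, 2, 3, 4, 5])
        assert correlation(a, a, n_perm=200).rho == pytest.approx(1.0)
        assert correlation(a, a[::-1], n_perm=200).rho == pytest.approx(-1.0)

    def test_percentage_bend_matches_pingouin_oracle(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        for _ in range(5):
            x = rng.standard_normal(40)
            y = 0.5 * x + rng.standard_normal(40)
            ours = percentage_bend_correlation(x, y)
            ref = float(pingouin.corr(x, y, method="percbend")["r"].iloc[0])
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_percentage_bend_robust_to_outlier(self):
        agree = moved_ok = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(200)
            y = 0.5 * x + np.sqrt(1 - 0.25) * rng.standard_normal(200)
            pb = percentage_bend_correlation(x, y)
            pearson = np.corrcoef(x, y)[0, 1]
            agree += abs(pb - pearson) < 0.05
            xo, yo = x.copy(), y.copy()
            xo[0], yo[0] = 30.0, -30.0  # gross outlier
            moved_ok += (
                abs(percentage_bend_correlation(xo, yo) - pb) < 0.1
                and abs(np.corrcoef(xo, yo)[0, 1] - pearson) > 0.2
            )
        assert agree >= 16 and moved_ok >= 16

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            correlation(np.ones(10), np.arange(10.0))


class TestClusterCorrelation:
    def test_null_rarely_significant(self):
        rng = np.random.default_rng(0)
        fp = 0
        for i in range(50):
            res = samplewise_cluster_correlation(
                rng.standard_normal((12, 40)), rng.standard_normal(12), n_perm=300, seed=i
            )
            fp += len(res.significant) > 0
        assert fp <= 5  # zero clusters in >= 90% of runs

    def test_planted_window_detected_with_majority_overlap(self):
        found = 0
        for i in range(20):
            rng = np.random.default_rng(100 + i)
            scores = rng.standard_normal(12)
            traces = rng.standard_normal((12, 50)) * 0.45
            traces[:, 10:20] += scores[:, None]
            res = samplewise_cluster_correlation(traces, scores, n_perm=500, seed=i)
            cov = sum(max(0, min(b, 20) - max(a, 10)) for a, b in res.significant)
            found += cov >= 5
        assert found >= 16  # >= 80% of runs

    def test_trace_length_preserved(self):
        rng = np.random.default_rng(1)
        res = samplewise_cluster_correlation(
            rng.standard_normal((8, 33)), rng.standard_normal(8), n_perm=300, seed=0
        )
        assert res.r.shape == (33,)


class TestFdr:
    def test_step_up_hand_oracle(self):
        # p(4)=0.05 <= 4/4*0.05 -> everything significant by step-up
        mask = fdr_adjust(np.array([0.01, 0.02, 0.04, 0.05]), alpha=0.05)
        assert mask.all()

    def test_all_ones_none_significant(self):
        assert not fdr_adjust(np.ones(6)).any()

    def test_single_p_reduces_to_raw_threshold(self):
        assert fdr_adjust(np.array([0.04])).all()
        assert not fdr_adjust(np.array([0.06])).any()

    def test_empty_input_empty_mask(self):
        assert fdr_adjust(np.array([])).size == 0
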