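import numpy as np
import pytest

from contrastpop.information import (ContrastPair, equalize_trials,
                                     fisher_info, fit_exponential_rank,
                                     population_info_curve,
                                     proportional_gain,
                                     shuffle_trials, single_channel_infos)


class TestContrastPair:
    def test_delta_scaling(self):
        assert ContrastPair(29, 31).delta_s == pytest.approx(np.pi / 25)
        assert ContrastPair(10, 60).delta_s == pytest.approx(np.pi)

    def test_order_enforced(self):
        with pytest.raises(ValueError):
            ContrastPair(31, 29)


class TestEqualize:
    def test_min_rule_per_day(self, rng):
        low = rng.poisson(5, (12, 3))
        high = rng.poisson(5, (9, 3))
        lo, hi = equalize_trials([(low, high)])
        assert lo.shape == hi.shape == (9, 3)

    def test_concatenated_count(self, rng):
        per_day = []
        for n_lo, n_hi in [(9, 12), (10, 15), (8, 9), (11, 20), (9, 9)]:
            per_day.append((rng.poisson(5, (n_lo, 2)),
                            rng.poisson(5, (n_hi, 2))))
        lo, hi = equalize_trials(per_day)
        assert lo.shape[0] == hi.shape[0] == 9 + 10 + 8 + 11 + 9

    def test_chronological_prefix_and_determinism(self):
        low = np.arange(12).reshape(12, 1)
        high = np.arange(100, 109).reshape(9, 1)
        lo1, hi1 = equalize_trials([(low, high)])
        lo2, hi2 = equalize_trials([(low, high)])
        assert np.array_equal(lo1, low[:9])       # prefix, not a subsample
        assert np.array_equal(lo1, lo2) and np.array_equal(hi1, hi2)

    def test_empty_day_dropped(self, rng):
        per_day = [(np.empty((0, 2)), rng.poisson(5, (5, 2))),
                   (rng.poisson(5, (4, 2)), rng.poisson(5, (6, 2)))]
        lo, hi = equalize_trials(per_day)
        assert lo.shape[0] == 4


class TestFisherEstimator:
    DS = ContrastPair(29, 31).delta_s

    def test_zero_information_unbiased(self, rng):
        vals = [fisher_info(rng.normal(10, 2, (60, 1)),
                            rng.normal(10, 2, (60, 1)), self.DS)
                for _ in range(3000)]
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * se

    def test_single_channel_closed_form(self, rng):
        # dmu = 2, sigma^2 = 4: I = (4/4) / ds^2 with ds = (pi/50)*2
        ds = ContrastPair(29, 31).delta_s
        true = 1.0 / ds**2
        vals = [fisher_info(rng.normal(10, 2, (400, 1)),
                            rng.normal(12, 2, (400, 1)), ds)
                for _ in range(300)]
        se = np.std(vals) / np.sqrt(len(vals))
        assert np.mean(vals) == pytest.approx(true, abs=3 * se)

    def test_two_channel_matrix_closed_form(self, rng):
        cov = np.array([[4.0, 1.2], [1.2, 2.0]])
        dmu = np.array([1.0, 0.5])
        ds = ContrastPair(28, 32).delta_s
        true = float(dmu @ np.linalg.solve(cov, dmu)) / ds**2
        chol = np.linalg.cholesky(cov)
        vals = []
        for _ in range(300):
            lo = 10.0 + rng.standard_normal((400, 2)) @ chol.T
            hi = 10.0 + dmu + rng.standard_normal((400, 2)) @ chol.T
            vals.append(fisher_info(lo, hi, ds))
        se = np.std(vals) / np.sqrt(len(vals))
        assert np.mean(vals) == pytest.approx(true, abs=3 * se)

    def test_delta_s_scaling_is_exact(self, rng):
        # same counts, half the contrast separation: 4x the information
        lo = rng.normal(10, 2, (100, 2))
        hi = rng.normal(11, 2, (100, 2))
        i_2pct = fisher_info(lo, hi, ContrastPair(29, 31).delta_s)
        i_4pct = fisher_info(lo, hi, ContrastPair(28, 32).delta_s)
        assert i_2pct == pytest.approx(4.0 * i_4pct, rel=1e-12)

    def test_validity_checks(self, rng):
        with pytest.raises(ValueError, match="N > T"):
            fisher_info(rng.normal(0, 1, (5, 3)), rng.normal(0, 1, (5, 3)),
                        self.DS)
        lo = np.column_stack([rng.normal(0, 1, 50), np.full(50, 2.0)])
        hi = np.column_stack([rng.normal(1, 1, 50), np.full(50, 2.0)])
        with pytest.raises(ValueError, match="singular"):
            fisher_info(lo, hi, self.DS)


class TestShuffle:
    DS = ContrastPair(29, 31).delta_s

    def test_single_channel_invariant(self, rng):
        lo = rng.poisson(10, (80, 1)).astype(float)
        hi = rng.poisson(12, (80, 1)).astype(float)
        slo, shi = shuffle_trials(lo, hi, rng=rng)
        assert fisher_info(slo, shi, self.DS) == \
            pytest.approx(fisher_info(lo, hi, self.DS), rel=1e-12)

    def test_marginals_preserved(self, rng):
        lo = rng.poisson(10, (80, 4)).astype(float)
        hi = rng.poisson(12, (80, 4)).astype(float)
        slo, shi = shuffle_trials(lo, hi, rng=rng)
        for j in range(4):
            assert sorted(slo[:, j]) == sorted(lo[:, j])
            assert sorted(shi[:, j]) == sorted(hi[:, j])

    def test_deterministic_given_seed(self, rng):
        lo = rng.poisson(10, (40, 3)).astype(float)
        hi = rng.poisson(12, (40, 3)).astype(float)
        a = shuffle_trials(lo, hi, rng=np.random.default_rng(5))
        b = shuffle_trials(lo, hi, rng=np.random.default_rng(5))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_removing_same_sign_correlations_raises_info(self, rng):
        # positive signal correlation (all means shift up) + positive noise
        # correlation: shuffling should increase information on average
        diffs = []
        for _ in range(60):
            z_lo = rng.standard_normal((200, 1))
            z_hi = rng.standard_normal((200, 1))
            lo = (np.array([10., 11., 12., 13.])
                  + 2.0 * (0.6 * z_lo + 0.8 * rng.standard_normal((200, 4))))
            hi = (np.array([10.5, 11.6, 12.7, 13.8])
                  + 2.0 * (0.6 * z_hi + 0.8 * rng.standard_normal((200, 4))))
            i_un = fisher_info(lo, hi, self.DS)
            slo, shi = shuffle_trials(lo, hi, rng=rng)
            diffs.append(fisher_info(slo, shi, self.DS) - i_un)
        assert np.mean(diffs) > 0
        assert np.mean(diffs) > 3 * np.std(diffs) / np.sqrt(len(diffs))


class TestPopulationCurve:
    DS = ContrastPair(29, 31).delta_s

    def test_size_one_equals_top_single_channel(self, rng):
        lo = rng.normal(10, 2, (200, 4))
        hi = rng.normal(10, 2, (200, 4)) + np.array([0.2, 1.0, 0.5, 0.1])
        singles = single_channel_infos(lo, hi, self.DS)
        curve = population_info_curve(lo, hi, self.DS)
        assert curve["info"].iloc[0] == pytest.approx(np.max(singles))
        assert curve["channels"].iloc[0][0] == int(np.argmax(singles))

    def test_independent_channels_near_additive(self, rng):
        lo = rng.normal(10, 2, (2000, 5))
        hi = rng.normal(11, 2, (2000, 5))
        singles = single_channel_infos(lo, hi, self.DS)
        curve = population_info_curve(lo, hi, self.DS)
        assert curve["info"].iloc[-1] == pytest.approx(np.sum(singles),
                                                       rel=0.10)


class TestExponentialRankFit:
    def test_exact_recovery(self):
        ranks = np.arange(1, 21)
        data = 0.1 + 2.0 * (1 - np.exp(-0.15 * ranks))
        fit = fit_exponential_rank(data)
        assert fit.c == pytest.approx(0.1, abs=1e-4)
        assert fit.b == pytest.approx(2.0, rel=1e-3)
        assert fit.lam == pytest.approx(-0.15, rel=1e-3)
        assert fit.vaf == pytest.approx(100.0, abs=1e-6)

    def test_constant_input_flagged(self):
        fit = fit_exponential_rank(np.full(10, 2.0))
        assert fit.flagged
        assert fit.b == 0.0
        assert np.isnan(fit.vaf)

    def test_noisy_data_high_vaf(self, rng):
        ranks = np.arange(1, 25)
        clean = 0.1 + 2.0 * (1 - np.exp(-0.15 * ranks))
        vafs = []
        for _ in range(50):
            noisy = clean + rng.normal(0, 0.05 * np.ptp(clean), clean.size)
            vafs.append(fit_exponential_rank(noisy).vaf)
        assert np.median(vafs) > 95.0


class TestProportionalGain:
    def test_arithmetic(self):
        res = proportional_gain([1.0, 2.0, 4.0], [1.5, 3.0, 6.0])
        assert np.allclose(res.gains["gain"], 0.5)
        assert res.constant    # gain constant -> correlation undefined

    def test_negative_dependence_recovered(self, rng):
        early = rng.uniform(1, 10, 40)
        gain = 2.0 - 0.15 * early + rng.normal(0, 0.1, 40)
        late = early * (1 + gain)
        res = proportional_gain(early, late)
        assert res.rho < 0 and res.p < 0.01

    def test_nonpositive_early_excluded(self):
        res = proportional_gain([0.0, 2.0, 3.0], [1.0, 4.0, 9.0])
        assert len(res.gains) == 2
        with pytest.raises(ValueError):
            proportional_gain([0.0, -1.0], [1.0, 1.0])
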