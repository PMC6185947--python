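import dataclasses

import numpy as np
import pytest

from contrastpop.discriminability import auroc
from contrastpop.synthetic_data import (GeneratorConfig, LearningTrajectory,
                                        ReadoutConfig, SessionData,
                                        config_from_yaml, config_to_yaml,
                                        generate_dataset,
                                        generate_population, read_sessions,
                                        simulate_choice, simulate_session,
                                        write_sessions)
from contrastpop.tuning import CRFParams, rectified_slope30


def _two_channel_init(c50=38.0):
    return (CRFParams(rmax=60.0, c50=c50, n=2.0, m=6.0),
            CRFParams(rmax=50.0, c50=34.0, n=2.0, m=8.0))


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"contrast_levels": (10.0, 20.0, 20.0, 30.0)},     # not increasing
        {"contrast_levels": (0.0, 10.0, 20.0)},            # outside (0,100]
        {"gain_sigma": -0.1},
        {"reversed_fraction": 1.5},
        {"adaptation": 0.0},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GeneratorConfig(**kwargs)

    def test_yaml_round_trip(self, tmp_path):
        cfg = GeneratorConfig(n_channels=4, n_days=3, trials_per_contrast=5,
                              crf_init=_two_channel_init() * 2, seed=9)
        path = tmp_path / "cfg.yaml"
        config_to_yaml(cfg, path)
        assert config_from_yaml(path) == cfg


class TestPopulationSchedule:
    def test_identity_trajectory_freezes_params(self):
        cfg = GeneratorConfig(
            n_channels=2, n_days=6, crf_init=_two_channel_init(),
            trajectory=LearningTrajectory(c50_step=0.0,
                                          exponent_growth=1.0))
        schedule = generate_population(cfg)
        for day_params in schedule[1:]:
            assert day_params == schedule[0]

    def test_c50_drift_clamps_at_boundary(self):
        # start 38%, 0.5%/day toward 30%: reaches 30 on day 17, clamped after
        cfg = GeneratorConfig(
            n_channels=2, n_days=20, crf_init=_two_channel_init(c50=38.0),
            trajectory=LearningTrajectory(c50_step=0.5,
                                          exponent_growth=1.0))
        schedule = generate_population(cfg)
        assert schedule[0][0].c50 == 38.0
        assert schedule[16][0].c50 == pytest.approx(30.0)
        assert schedule[19][0].c50 == 30.0

    def test_distance_non_increasing_and_slope_non_decreasing(self):
        cfg = GeneratorConfig(n_channels=20, n_days=15, seed=3)
        schedule = generate_population(cfg)
        for ch in range(cfg.n_channels):
            dists = [abs(day[ch].c50 - 30.0) for day in schedule]
            slopes = [rectified_slope30(day[ch], day[ch].reversed_tuning)
                      for day in schedule]
            assert np.all(np.diff(dists) <= 1e-12)
            assert np.all(np.diff(slopes) >= -1e-12)

    def test_reversed_channel_count_by_rounding(self):
        cfg = GeneratorConfig(n_channels=20, reversed_fraction=0.1, seed=1)
        schedule = generate_population(cfg)
        for day_params in schedule:
            negatives = sum(p.slope30 < 0 for p in day_params)
            assert negatives == 2


class TestSessionSimulation:
    def test_bit_identical_given_seed(self, small_config, small_dataset):
        again = generate_dataset(small_config)
        for a, b in zip(small_dataset, again):
            assert np.array_equal(a.counts, b.counts)
            assert np.array_equal(a.choice, b.choice)
            assert np.array_equal(a.correct, b.correct)

    def test_correct_label_consistency(self, small_dataset):
        for s in small_dataset:
            expect = (s.choice == "higher") == (s.test_contrast > 30.0)
            assert np.array_equal(s.correct, expect)

    def test_mean_count_recovery(self):
        # empirical mean test counts converge to adaptation*window*R(c)
        cfg = GeneratorConfig(n_channels=3, n_days=1,
                              trials_per_contrast=1500,
                              contrast_levels=(10.0, 30.0, 60.0),
                              crf_init=(CRFParams(60, 38, 2, 6),
                                        CRFParams(50, 34, 2, 8),
                                        CRFParams(40, 26, 3, 5)),
                              reversed_fraction=0.0, seed=5)
        s = simulate_session(generate_population(cfg), 1, cfg)
        win = cfg.window_ms / 1000.0
        for ch, p in enumerate(s.ground_truth["params"]):
            for c in cfg.contrast_levels:
                sel = s.test_contrast == c
                x = s.epoch("test")[sel, ch]
                expected = cfg.adaptation * win * float(p.rate(c))
                se = x.std(ddof=1) / np.sqrt(sel.sum())
                assert abs(x.mean() - expected) < 3 * se + 0.5  # rounding

    def test_independent_channels_without_latent_factor(self):
        cfg = GeneratorConfig(n_channels=6, n_days=1,
                              trials_per_contrast=500,
                              contrast_levels=(20.0, 30.0, 40.0, 50.0),
                              gain_sigma=0.0, noise_corr_early=0.0,
                              noise_corr_late=0.0, seed=7)
        s = simulate_session(generate_population(cfg), 1, cfg)
        from contrastpop.correlations import pairwise_noise_correlations
        means = [np.nanmean(pairwise_noise_correlations(
            s.epoch("test")[s.test_contrast == c]))
            for c in cfg.contrast_levels]
        assert abs(np.mean(means)) < 3.0 / np.sqrt(500)

    def test_configured_correlation_recovered(self):
        # correlation injection: targets hit within +/-0.02 at 2000 trials
        for target in (0.05, 0.15):
            cfg = GeneratorConfig(n_channels=6, n_days=1,
                                  trials_per_contrast=2000,
                                  contrast_levels=(25.0, 35.0),
                                  noise_corr_early=target,
                                  noise_corr_late=target, seed=17)
            s = simulate_session(generate_population(cfg), 1, cfg)
            from contrastpop.correlations import pairwise_noise_correlations
            means = [np.nanmean(pairwise_noise_correlations(
                s.epoch("test")[s.test_contrast == c]))
                for c in cfg.contrast_levels]
            assert np.mean(means) == pytest.approx(target, abs=0.02)

    def test_gain_couples_sample_and_test(self):
        base = dict(n_channels=2, n_days=1, trials_per_contrast=1200,
                    contrast_levels=(29.0, 31.0),
                    crf_init=_two_channel_init(), noise_corr_early=0.0,
                    noise_corr_late=0.0, reversed_fraction=0.0, seed=23)
        with_gain = simulate_session(
            generate_population(GeneratorConfig(gain_sigma=0.3, **base)), 1,
            GeneratorConfig(gain_sigma=0.3, **base))
        without = simulate_session(
            generate_population(GeneratorConfig(gain_sigma=0.0, **base)), 1,
            GeneratorConfig(gain_sigma=0.0, **base))
        r_with = np.corrcoef(with_gain.epoch("sample")[:, 0],
                             with_gain.epoch("test")[:, 0])[0, 1]
        r_without = np.corrcoef(without.epoch("sample")[:, 0],
                                without.epoch("test")[:, 0])[0, 1]
        assert r_with > 0.1
        assert abs(r_without) < 0.1

    def test_flat_tuning_gives_chance_auroc(self):
        flat = tuple(CRFParams(rmax=0.0, c50=30.0, n=1.0, m=25.0, flat=True)
                     for _ in range(2))
        cfg = GeneratorConfig(n_channels=2, n_days=1,
                              trials_per_contrast=800,
                              contrast_levels=(10.0, 30.0, 60.0),
                              crf_init=flat, adaptation=1.0,
                              readout=ReadoutConfig(weights=(1.0, 1.0)),
                              reversed_fraction=0.0, seed=29)
        s = simulate_session(generate_population(cfg), 1, cfg)
        for c in cfg.contrast_levels:
            sel = s.test_contrast == c
            a = auroc(s.epoch("sample")[sel, 0], s.epoch("test")[sel, 0])
            assert a == pytest.approx(0.5, abs=3.0 / np.sqrt(sel.sum()))


class TestChoices:
    def test_infinite_criterion_noise_is_guessing(self):
        cfg = GeneratorConfig(n_channels=4, n_days=1,
                              trials_per_contrast=600,
                              contrast_levels=(20.0, 40.0),
                              readout=ReadoutConfig(noise_early=1e6,
                                                    noise_late=1e6),
                              seed=31)
        s = simulate_session(generate_population(cfg), 1, cfg)
        frac_higher = np.mean(s.choice == "higher")
        assert frac_higher == pytest.approx(0.5, abs=0.05)
        for c in cfg.contrast_levels:
            sel = s.test_contrast == c
            assert np.mean(s.correct[sel]) == pytest.approx(0.5, abs=0.06)

    def test_zero_noise_is_deterministic_threshold(self):
        # single read-out channel, no criterion noise: choice is exactly
        # the indicator of the weighted count crossing the criterion
        cfg = GeneratorConfig(n_channels=2, n_days=1, trials_per_contrast=50,
                              crf_init=_two_channel_init(),
                              readout=ReadoutConfig(weights=(1.0, 0.0),
                                                    noise_early=0.0,
                                                    noise_late=0.0),
                              reversed_fraction=0.0, seed=37)
        schedule = generate_population(cfg)
        s = simulate_session(schedule, 1, cfg)
        win = cfg.window_ms / 1000.0
        criterion = cfg.adaptation * win * float(
            schedule[0][0].rate(cfg.sample_contrast))
        expect = s.epoch("test")[:, 0] >= criterion
        assert np.array_equal(s.choice == "higher", expect)

    def test_all_zero_weights_rejected(self, small_config):
        cfg = dataclasses.replace(
            small_config, readout=ReadoutConfig(weights=(0.0,) * 8))
        schedule = generate_population(cfg)
        with pytest.raises(ValueError):
            simulate_session(schedule, 1, cfg)

    def test_readout_weight_drives_cp_ranking(self):
        # the weighted channel carries choice information, the zero-weight
        # channel does not; verify the package CP against a brute-force
        # cross-pair enumeration of the choice-conditioned distributions
        from contrastpop.choice import choice_probability
        cfg = GeneratorConfig(n_channels=2, n_days=1,
                              trials_per_contrast=400,
                              contrast_levels=(29.0, 31.0),
                              crf_init=_two_channel_init(),
                              noise_corr_early=0.0, noise_corr_late=0.0,
                              gain_sigma=0.0,
                              readout=ReadoutConfig(weights=(1.0, 0.0),
                                                    noise_early=0.5,
                                                    noise_late=0.5),
                              reversed_fraction=0.0, seed=41)
        s = simulate_session(generate_population(cfg), 1, cfg)
        sel = s.test_contrast == 29.0
        choices = s.choice[sel] == "higher"
        cps = []
        for ch in range(2):
            x = s.epoch("test")[sel, ch]
            cp = choice_probability(x, choices)
            hi, lo = x[choices], x[~choices]
            wins = sum(1 for a in lo for b in hi if b > a)
            ties = sum(1 for a in lo for b in hi if b == a)
            brute = (wins + 0.5 * ties) / (len(lo) * len(hi))
            assert cp == pytest.approx(brute, abs=1e-12)
            cps.append(cp)
        assert cps[0] > cps[1]
        assert cps[1] == pytest.approx(0.5, abs=0.1)


class TestIO:
    def test_write_read_round_trip(self, tmp_path, small_dataset):
        write_sessions(small_dataset[:2], tmp_path)
        back = read_sessions(tmp_path)
        assert len(back) == 2
        for a, b in zip(small_dataset[:2], back):
            assert np.array_equal(a.counts, b.counts)
            assert np.array_equal(a.test_contrast, b.test_contrast)
            assert np.array_equal(a.choice, b.choice)
            assert np.array_equal(a.correct, b.correct)
            for pa, pb in zip(a.ground_truth["params"],
                              b.ground_truth["params"]):
                assert pa.c50 == pytest.approx(pb.c50)
                assert pa.reversed_tuning == pb.reversed_tuning
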