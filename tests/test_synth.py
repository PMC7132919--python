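"""Generator statistics: binomial moments, reproducibility, preset direction."""

import numpy as np
import pytest

from ctsyn import stp, synth, ultrastructure as us
from ctsyn.synth import release_params, simulate_release_amplitudes


def _no_depression(**kw):
    return release_params(
        "wt", q_shape=None, noise_sd=0.0, refill_tau=0.0, transmitter_fill_tau=0.0, **kw
    )


class TestReleaseModel:
    def test_single_pulse_binomial_mean_and_variance(self):
        # N=20, p=0.05, q=5 -> mean 5 pA, variance 23.75 pA^2
        p = _no_depression(p0=0.05, q_mean=5.0)
        amps = simulate_release_amplitudes(p, [0.05], 10000, seed=1)[:, 0]
        se_mean = np.sqrt(23.75 / amps.size)
        assert abs(amps.mean() - 5.0) < 3 * se_mean
        # variance of the sample variance ~ 2 sigma^4 / n for near-normal sums
        se_var = np.sqrt(2 * 23.75 ** 2 / amps.size) * 2
        assert abs(amps.var(ddof=1) - 23.75) < 3 * se_var

    def test_facilitation_ratio_matches_deterministic_model(self):
        p = _no_depression()
        stim = 0.05 + np.arange(5) / 20.0
        amps = simulate_release_amplitudes(p, stim, 10000, seed=2)
        F_mc = amps.mean(axis=0) / amps.mean(axis=0)[0]
        F_th = synth.expected_facilitation(p, stim)
        se = amps.std(axis=0, ddof=1) / np.sqrt(amps.shape[0]) / amps.mean(axis=0)[0]
        assert np.all(np.abs(F_mc - F_th) < 3 * (se + se[0] * F_th))

    def test_variance_mean_pairs_lie_on_binomial_parabola(self):
        p = _no_depression(p0=0.051, q_mean=5.0)
        stim = 0.05 + np.arange(5) / 20.0
        amps = simulate_release_amplitudes(p, stim, 4000, seed=3)
        F = synth.expected_facilitation(p, stim)
        for j in range(5):
            pj = min(1.0, 0.051 * F[j])
            mean_th = 20 * pj * 5.0
            var_th = 20 * pj * (1 - pj) * 25.0
            se_var = np.sqrt(2.0 / (amps.shape[0] - 1)) * var_th * 1.5
            assert amps[:, j].mean() == pytest.approx(mean_th, abs=3 * np.sqrt(var_th / amps.shape[0]))
            assert amps[:, j].var(ddof=1) == pytest.approx(var_th, abs=3 * se_var)

    def test_bit_reproducible_and_repeat_extension_stable(self):
        p = release_params("wt")
        a = synth.simulate_release_trains(p, [0.05, 0.1], 3, seed=9)
        b = synth.simulate_release_trains(p, [0.05, 0.1], 3, seed=9)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.current, sb.current)
        amps3 = simulate_release_amplitudes(p, [0.05, 0.1], 3, seed=9)
        amps6 = simulate_release_amplitudes(p, [0.05, 0.1], 6, seed=9)
        np.testing.assert_array_equal(amps3, amps6[:3])

    def test_wt_vs_hemi_first_epsc_ratio_near_printed_pr_ratio(self):
        stim = [0.05]
        wt = simulate_release_amplitudes(release_params("wt"), stim, 8000, seed=4)
        hemi = simulate_release_amplitudes(release_params("hemi"), stim, 8000, seed=5)
        ratio = hemi.mean() / wt.mean()
        assert ratio == pytest.approx(0.098 / 0.051, rel=0.06)

    def test_hemi_preset_shows_reduced_late_facilitation(self):
        stim = 0.05 + np.arange(400) / 20.0
        metrics = {}
        # the first-pulse normalizer averages ~1 vesicle per train, so many
        # repeats are needed for a stable facilitation denominator
        for preset, seed in (("wt", 11), ("hemi", 12)):
            amps = simulate_release_amplitudes(release_params(preset), stim, 48, seed=seed)
            F = amps.mean(axis=0) / amps.mean(axis=0)[0]
            metrics[preset] = stp.train_metrics(stim - stim[0], F)
        assert metrics["hemi"].steady_state < metrics["wt"].steady_state
        assert metrics["hemi"].final_facilitation < metrics["wt"].final_facilitation
        assert metrics["hemi"].depression_latency < metrics["wt"].depression_latency

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            release_params("wt", p0=1.5)
        with pytest.raises(ValueError):
            synth.simulate_release_trains(release_params("wt"), [0.1, 0.1], 1, seed=0)


class TestSpontaneous:
    def test_zero_rate_gives_empty_ground_truth(self):
        sw = synth.simulate_spontaneous(0.0, 5.0, noise_sd=0.0, seed=1)
        assert sw.meta["events"]["times"] == []
        assert np.allclose(sw.current, 0.0)

    @pytest.mark.parametrize("rate,expected", [(8.3, 498), (12.4, 744)])
    def test_event_count_matches_poisson_rate(self, rate, expected):
        counts = [
            len(synth.simulate_spontaneous(rate, 60.0, seed=s).meta["events"]["times"])
            for s in range(5)
        ]
        se = np.sqrt(expected / 5)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            synth.simulate_spontaneous(-1.0, 10.0, seed=0)


class TestBehaviorGenerator:
    def test_infinite_speed_means_all_correct(self):
        trials = synth.simulate_5csrtt(0.05, 1e6, 0.5, [0.25, 0.5, 1.0], 50, seed=3)
        assert (trials["outcome"] == "correct").all()

    def test_durations_below_t0_force_omissions(self):
        trials = synth.simulate_5csrtt(0.5, 1.3, 0.5, [0.1, 0.2, 0.4], 50, seed=3)
        assert (trials["outcome"] == "omission").all()

    def test_deterministic_given_seed(self):
        a = synth.simulate_5csrtt(0.2, 1.3, 0.8, [0.5, 1.0], 20, seed=7)
        b = synth.simulate_5csrtt(0.2, 1.3, 0.8, [0.5, 1.0], 20, seed=7)
        assert a.equals(b)


class TestColocGenerator:
    def test_uniform_partner_channel_matches_null_exactly(self):
        from ctsyn import imaging

        pair, truth = synth.simulate_coloc_images(
            60, overlap_fraction=0.0, uniform_b=True, noise_sd=0.0, seed=4
        )
        masked = imaging.masked_mean_intensity(truth["mask"], pair.channel_b)
        null = imaging.rotation_null(truth["mask"], pair.channel_b)
        assert masked == null

    def test_non_square_rejected_and_overlap_bounds(self):
        with pytest.raises(ValueError):
            synth.simulate_coloc_images(10, overlap_fraction=1.5, seed=0)


class TestTerminalGenerator:
    def test_zero_gold_density_gives_zero_gold_metric(self):
        terms = synth.simulate_terminals(5, gold_density=0.0, seed=1)
        for t in terms:
            assert t.points_of("gold").shape[0] == 0
            assert us.point_density(t.points_of("gold"), t.membrane) == 0.0

    def test_feret_calibrated_to_target(self):
        terms = synth.simulate_terminals(100, feret_target=677.0, seed=2)
        mean_feret = np.mean([us.max_feret(t.membrane) for t in terms])
        assert mean_feret == pytest.approx(677.0, rel=0.05)

    def test_point_density_recovers_generating_density(self):
        terms = synth.simulate_terminals(100, vesicle_density=150.0, seed=3)
        d = np.mean([us.point_density(t.points_of("vesicle"), t.membrane) for t in terms])
        assert d == pytest.approx(150.0, rel=0.10)
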