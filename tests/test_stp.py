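"""Amplitude measurement, facilitation normalization, and plasticity fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctsyn import stp, synth
from ctsyn.synth import release_params
from ctsyn.traceio import Sweep, SweepSet
from ctsyn.events import epsc_template


def _sweep_from_impulses(stim_times, amps, sample_rate=20000.0, kernel=(0.5, 5.0),
                         noise_sd=0.0, seed=0, post=0.1, meta=None):
    """Render a deterministic EPSC train from known quantal sums."""
    from ctsyn.synth import _render_trace

    rng = np.random.default_rng(seed)
    stim_times = np.asarray(stim_times, float)
    trace = _render_trace(
        sample_rate, stim_times[-1] + post, stim_times, np.asarray(amps, float),
        kernel, noise_sd, rng,
    )
    return Sweep(sample_rate=sample_rate, current=trace, stim_times=stim_times,
                 meta=meta or {})


class TestMeasureAmplitudes:
    def test_recovers_known_single_peak(self):
        sw = _sweep_from_impulses([0.05], [30.0])
        amp = stp.measure_epsc_amplitudes(sw)
        assert amp[0] == pytest.approx(-30.0, rel=0.01)

    def test_flat_trace_measures_near_zero(self, rng):
        sw = Sweep(sample_rate=20000.0, current=rng.normal(0, 0.5, 4000),
                   stim_times=[0.05, 0.1])
        amps = stp.measure_epsc_amplitudes(sw, subtract_tail=False)
        assert np.all(np.abs(amps) < 3 * 0.5)

    def test_tail_extrapolation_corrects_overlapping_epscs(self):
        # slow 15-ms decay at 50 Hz: second EPSC rides on ~26% of the first
        sw = _sweep_from_impulses([0.05, 0.07], [30.0, 30.0], kernel=(0.5, 15.0))
        corrected = stp.measure_epsc_amplitudes(
            sw, subtract_tail=True, search_window=(0.001, 0.015)
        )
        naive = stp.measure_epsc_amplitudes(
            sw, subtract_tail=False, search_window=(0.001, 0.015)
        )
        assert corrected[1] == pytest.approx(-30.0, rel=0.05)
        assert abs(naive[1]) < abs(corrected[1])  # baseline method underestimates here

    def test_stimulus_outside_trace_rejected(self):
        sw = _sweep_from_impulses([0.05], [30.0])
        with pytest.raises(ValueError):
            stp.measure_epsc_amplitudes(sw, stim_times=[10.0])


class TestFacilitationSeries:
    def _ppf_set(self, scale=1.0):
        sweeps = []
        for ppi, e2 in [(0.01, 30.0), (0.05, 25.0), (0.2, 18.0), (1.0, 12.0), (5.0, 10.0)]:
            sweeps.append(
                _sweep_from_impulses([0.05, 0.05 + ppi], [10.0 * scale, e2 * scale],
                                     meta={"ppi": ppi})
            )
        return SweepSet(sweeps)

    def test_ppf_normalizes_by_mean_first_amplitude(self):
        series = stp.ppf_series(self._ppf_set())
        # EPSC_m1 = -10 pA, so F = EPSC2 / 10
        np.testing.assert_allclose(series.values, [3.0, 2.5, 1.8, 1.2, 1.0], rtol=0.01)
        assert series.epsc_m1 == pytest.approx(-10.0, rel=0.01)

    def test_facilitation_invariant_under_amplitude_scaling(self):
        a = stp.ppf_series(self._ppf_set(scale=1.0))
        b = stp.ppf_series(self._ppf_set(scale=7.3))
        np.testing.assert_allclose(a.values, b.values, rtol=1e-6)

    def test_no_plasticity_simulator_gives_unity_facilitation(self):
        p = release_params("wt", facil_increments=(0.0, 0.0), q_shape=None,
                           noise_sd=0.0, refill_tau=0.0, transmitter_fill_tau=0.0,
                           p0=0.3)
        sweeps = []
        for ppi in (0.02, 0.1, 0.5, 1.0, 5.0):
            ss = synth.simulate_release_trains(
                p, [0.05, 0.05 + ppi], 60, seed=int(ppi * 1000),
                protocol_meta={"ppi": ppi},
            )
            sweeps.extend(ss.sweeps)
        series = stp.ppf_series(SweepSet(sweeps))
        assert np.all(np.abs(series.values - 1.0) < 0.15)


class TestPPFDecayFit:
    def test_round_trip_two_components_at_printed_values(self):
        ppi = stp.DEFAULT_PPI_GRID
        F = 1 + 2.75 * np.exp(-ppi / 0.099) + 0.56 * np.exp(-ppi / 1.0)
        fit = stp.fit_ppf_decay(ppi, F)
        assert fit.n_components == 2
        (a1, t1), (a2, t2) = fit.components
        assert a1 == pytest.approx(2.75, rel=0.01)
        assert t1 == pytest.approx(0.099, rel=0.01)
        assert a2 == pytest.approx(0.56, rel=0.01)
        assert t2 == pytest.approx(1.0, rel=0.01)

    def test_round_trip_single_component_at_printed_values(self):
        ppi = stp.DEFAULT_PPI_GRID
        F = 1 + 2.21 * np.exp(-ppi / 0.154)
        fit = stp.fit_ppf_decay(ppi, F)
        assert fit.n_components == 1
        a, tau = fit.components[0]
        assert a == pytest.approx(2.21, rel=0.01)
        assert tau == pytest.approx(0.154, rel=0.01)

    def test_constant_series_selects_one_flat_component(self):
        fit = stp.fit_ppf_decay(stp.DEFAULT_PPI_GRID, np.ones(9))
        assert fit.n_components == 1
        assert fit.components[0][0] == pytest.approx(0.0, abs=1e-3)

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(
        a1=st.floats(1.0, 5.0), a2=st.floats(0.3, 1.5),
        log_t1=st.floats(-3.0, -1.5), log_t2=st.floats(-0.5, 0.5),
    )
    def test_noiseless_round_trip_property(self, a1, a2, log_t1, log_t2):
        """Exact recovery (<=1e-6 relative) on noiseless model curves."""
        t1, t2 = 10.0 ** log_t1, 10.0 ** log_t2
        ppi = stp.DEFAULT_PPI_GRID
        F = 1 + a1 * np.exp(-ppi / t1) + a2 * np.exp(-ppi / t2)
        fit = stp.fit_ppf_decay(ppi, F)
        pred = np.ones_like(ppi)
        for a, tau in fit.components:
            pred = pred + a * np.exp(-ppi / tau)
        assert np.max(np.abs(pred - F) / F) < 1e-6

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            stp.fit_ppf_decay(np.array([0.01, 0.1, 1.0]), np.array([3.0, 2.0, 1.1]))


class TestTrainBuildupFit:
    def test_round_trip_at_printed_20hz_values(self):
        t = np.arange(0, 2.5001, 0.05)
        F = 1 + 5.11 * (1 - np.exp(-t / 0.099)) + 2.42 * (1 - np.exp(-t / 1.0))
        fit = stp.fit_train_buildup(t, F)
        assert fit.B1 == pytest.approx(5.11, rel=0.01)
        assert fit.B2 == pytest.approx(2.42, rel=0.01)

    def test_unity_series_gives_zero_amplitudes(self):
        t = np.arange(0, 2.5001, 0.05)
        fit = stp.fit_train_buildup(t, np.ones_like(t))
        assert fit.B1 == pytest.approx(0.0, abs=1e-9)
        assert fit.B2 == pytest.approx(0.0, abs=1e-9)

    def test_fast_only_simulator_gives_negligible_slow_component(self):
        p = release_params("wt", facil_increments=(3.3578, 0.0), q_shape=None,
                           noise_sd=0.0, refill_tau=0.0, transmitter_fill_tau=0.0)
        stim = 0.05 + np.arange(50) / 20.0
        amps = synth.simulate_release_amplitudes(p, stim, 12000, seed=8)
        F = amps.mean(axis=0) / amps.mean(axis=0)[0]
        fit = stp.fit_train_buildup(stim - stim[0], F)
        assert abs(fit.B2) < 0.1

    def test_too_few_pulses_rejected(self):
        with pytest.raises(ValueError):
            stp.fit_train_buildup(np.array([0.0, 0.05, 0.1]), np.array([1.0, 2.0, 3.0]))


class TestTrainMetrics:
    def test_constructed_plateau_and_crossing(self):
        t = np.arange(200) / 20.0  # 10 s at 20 Hz
        F = np.where(t < 2.0, 8.0, 8.0 * np.exp(-2.0 * (t - 1.95)))
        m = stp.train_metrics(t, F)
        assert m.steady_state == pytest.approx(8.0, rel=1e-6)
        assert m.depression_latency == pytest.approx(2.0)

    def test_final_facilitation_is_mean_of_last_ten(self):
        t = np.arange(40) / 20.0
        F = np.concatenate([np.linspace(1, 5, 30), np.full(10, 0.42)])
        m = stp.train_metrics(t, F)
        assert m.final_facilitation == pytest.approx(0.42)

    def test_monotone_rising_series_has_no_depression_latency(self):
        t = np.arange(60) / 20.0
        F = 1 + 5 * (1 - np.exp(-t / 0.5))
        m = stp.train_metrics(t, F)
        assert m.depression_latency is None
        run = m.plateau_indices
        assert m.steady_state == pytest.approx(np.mean(F[run[0] : run[1] + 1]))

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            stp.train_metrics(np.arange(10) / 20.0, np.ones(10))
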