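"""Short-term plasticity analysis of evoked EPSC trains.

Peak EPSC amplitudes are measured per stimulus (local-baseline or
decay-extrapolation corrected), normalized to the mean first-EPSC amplitude
(EPSC_m1) to give facilitation series, and fitted with either an exponential
decay of paired-pulse facilitation versus inter-pulse interval, or a
two-component saturating accumulation model for the buildup of facilitation
during high-frequency trains.  Long 20-s trains are summarized by three
metrics: steady-state facilitation (plateau mean), depression latency (final
downward crossing of the plateau level), and final facilitation (mean of the
last ten stimuli).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .traceio import Sweep, SweepSet

__all__ = [
    "FacilitationSeries",
    "ExpDecayFit",
    "TrainBuildupFit",
    "TrainMetrics",
    "measure_epsc_amplitudes",
    "average_sweeps",
    "ppf_series",
    "train_series",
    "fit_ppf_decay",
    "fit_train_buildup",
    "train_metrics",
    "DEFAULT_PPI_GRID",
]

#: Log-spaced paired-pulse intervals (s) spanning the 10 ms - 5 s protocol range.
DEFAULT_PPI_GRID = np.array([0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0, 2.0, 5.0])


@dataclass
class FacilitationSeries:
    """Per-pulse facilitation values normalized to the mean first-EPSC amplitude."""

    pulse_times: np.ndarray  # s, relative to train start (or PPI values for PPF)
    values: np.ndarray       # F_n, unitless
    epsc_m1: float           # signed pA normalizer
    frequency: float | None = None  # Hz (train protocols)
    ppi: np.ndarray | None = None   # s (paired-pulse protocols)

    def __post_init__(self) -> None:
        self.pulse_times = np.asarray(self.pulse_times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.epsc_m1 == 0:
            raise ValueError("EPSC_m1 normalizer is zero")


@dataclass
class ExpDecayFit:
    """F(PPI) = 1 + sum_i A_i exp(-PPI/tau_i); components sorted by tau."""

    components: list[tuple[float, float]]  # (A, tau_s)
    n_components: int
    rss: float


@dataclass
class TrainBuildupFit:
    """F(t) = 1 + B1 (1-exp(-t/tau1)) + B2 (1-exp(-t/tau2)), taus fixed."""

    B1: float
    B2: float
    tau1: float
    tau2: float
    sd_B1: float
    sd_B2: float
    rss: float


@dataclass
class TrainMetrics:
    steady_state: float
    depression_latency: float | None  # s; None if F never falls below steady state
    final_facilitation: float
    plateau_indices: tuple[int, int] = field(default=(0, 0))


# ---------------------------------------------------------------------------
# Amplitude measurement
# ---------------------------------------------------------------------------

def _fit_tail(t: np.ndarray, y: np.ndarray):
    """Fit y = A exp(-t/tau) + C to a decay segment; return predictor or None."""
    if t.size < 6:
        return None
    span = y[0] - y[-1]
    if abs(span) < 1e-12:
        c = float(np.mean(y))
        return lambda tt: np.full_like(np.asarray(tt, float), c)
    tau0 = max((t[-1] - t[0]) / 3.0, 1e-4)
    try:
        popt, _ = optimize.curve_fit(
            lambda tt, a, tau, c: a * np.exp(-tt / tau) + c,
            t - t[0],
            y,
            p0=[span, tau0, y[-1]],
            maxfev=2000,
        )
    except (RuntimeError, optimize.OptimizeWarning):
        return None
    a, tau, c = popt
    if tau <= 0:
        return None
    return lambda tt: a * np.exp(-(np.asarray(tt, float) - t[0]) / tau) + c


def measure_epsc_amplitudes(
    sweep: Sweep,
    stim_times: np.ndarray | None = None,
    *,
    search_window: tuple[float, float] = (0.001, 0.010),
    baseline_window: float = 0.002,
    blank: float = 0.0005,
    subtract_tail: bool | None = None,
    polarity: int = -1,
    return_flags: bool = False,
):
    """Measure the signed peak amplitude of each evoked EPSC.

    For every stimulus the extremum of the trace in the post-stimulus search
    window (default 1-10 ms, truncated at the next stimulus) is referenced to
    either the mean of the 2 ms pre-pulse baseline or, when ``subtract_tail``
    is active, the exponential extrapolation of the preceding EPSC's decay.
    Tail subtraction defaults to on for trains at >= 10 Hz (inter-stimulus
    interval <= 100 ms) where EPSCs can ride on the previous decay.

    Returns signed amplitudes in pA (inward events negative).  With
    ``return_flags`` a boolean array marks pulses whose search window was
    truncated by the following stimulus.
    """
    if stim_times is None:
        stim_times = sweep.stim_times
    stim_times = np.asarray(stim_times, dtype=float)
    if stim_times.size == 0:
        raise ValueError("no stimulus times supplied")
    if stim_times[-1] >= sweep.duration or stim_times[0] < 0:
        raise ValueError("stim_times outside trace")
    sr = sweep.sample_rate
    y = sweep.current
    if subtract_tail is None:
        iv = np.diff(stim_times)
        subtract_tail = bool(iv.size and np.min(iv) <= 0.1 + 1e-12)

    amps = np.empty(stim_times.size)
    truncated = np.zeros(stim_times.size, dtype=bool)
    prev_peak_idx: int | None = None
    for n, t in enumerate(stim_times):
        w0 = t + max(search_window[0], blank)
        w1 = t + search_window[1]
        if n + 1 < stim_times.size and w1 > stim_times[n + 1]:
            w1 = stim_times[n + 1]
            truncated[n] = True
        i0, i1 = int(round(w0 * sr)), int(round(w1 * sr))
        i1 = min(i1, y.size)
        if i1 <= i0:
            raise ValueError(f"empty search window for stimulus {n}")
        seg = y[i0:i1]
        pk_rel = int(np.argmin(seg)) if polarity < 0 else int(np.argmax(seg))
        pk_idx = i0 + pk_rel

        ref = None
        if subtract_tail and n > 0 and prev_peak_idx is not None:
            j0 = prev_peak_idx + int(round(0.002 * sr))
            j1 = int(round((t - blank) * sr))
            if j1 - j0 >= 6:
                tt = np.arange(j0, j1) / sr
                pred = _fit_tail(tt, y[j0:j1])
                if pred is not None:
                    ref = float(pred(pk_idx / sr))
        if ref is None:
            b0 = max(0, int(round((t - baseline_window) * sr)))
            b1 = int(round(t * sr))
            ref = float(np.mean(y[b0:b1])) if b1 > b0 else 0.0

        amps[n] = y[pk_idx] - ref
        prev_peak_idx = pk_idx
    if return_flags:
        return amps, truncated
    return amps


def average_sweeps(sweeps: list[Sweep]) -> Sweep:
    """Point-wise average of repeat sweeps sharing a protocol."""
    if not sweeps:
        raise ValueError("no sweeps to average")
    n = min(sw.current.size for sw in sweeps)
    cur = np.mean([sw.current[:n] for sw in sweeps], axis=0)
    first = sweeps[0]
    return Sweep(
        sample_rate=first.sample_rate,
        current=cur,
        stim_times=first.stim_times,
        meta=dict(first.meta, n_averaged=len(sweeps)),
    )


# ---------------------------------------------------------------------------
# Facilitation series
# ---------------------------------------------------------------------------

def ppf_series(sweepset: SweepSet, **measure_kwargs) -> FacilitationSeries:
    """Paired-pulse facilitation versus inter-pulse interval.

    Sweeps are grouped by their ``meta['ppi']``, repeats are averaged per PPI
    before measurement, and F(PPI) = EPSC2(PPI) / EPSC_m1 where EPSC_m1 is the
    mean first-EPSC amplitude across all PPI.
    """
    groups: dict[float, list[Sweep]] = {}
    for sw in sweepset:
        if "ppi" not in sw.meta:
            raise ValueError("sweep lacks meta['ppi']")
        groups.setdefault(float(sw.meta["ppi"]), []).append(sw)
    ppis = np.array(sorted(groups))
    e1, e2 = [], []
    for ppi in ppis:
        avg = average_sweeps(groups[ppi])
        a = measure_epsc_amplitudes(avg, **measure_kwargs)
        if a.size < 2:
            raise ValueError(f"PPI {ppi}: fewer than two pulses")
        e1.append(a[0])
        e2.append(a[1])
    epsc_m1 = float(np.mean(e1))
    if epsc_m1 == 0:
        raise ValueError("EPSC_m1 is zero")
    values = np.asarray(e2) / epsc_m1
    return FacilitationSeries(
        pulse_times=ppis, values=values, epsc_m1=epsc_m1, ppi=ppis
    )


def train_series(sweepset: SweepSet, **measure_kwargs) -> dict[float, FacilitationSeries]:
    """Facilitation series per train frequency.

    Sweeps are grouped by ``meta['frequency']``, repeats averaged per
    frequency, and every F_n = EPSC_n / EPSC_m1 with EPSC_m1 the mean
    first-EPSC amplitude across all frequency trains.
    """
    groups: dict[float, list[Sweep]] = {}
    for sw in sweepset:
        if "frequency" not in sw.meta:
            raise ValueError("sweep lacks meta['frequency']")
        groups.setdefault(float(sw.meta["frequency"]), []).append(sw)
    averaged = {f: average_sweeps(sws) for f, sws in groups.items()}
    amps = {f: measure_epsc_amplitudes(avg, **measure_kwargs) for f, avg in averaged.items()}
    epsc_m1 = float(np.mean([a[0] for a in amps.values()]))
    if epsc_m1 == 0:
        raise ValueError("EPSC_m1 is zero")
    out = {}
    for f, a in amps.items():
        t = averaged[f].stim_times - averaged[f].stim_times[0]
        out[f] = FacilitationSeries(
            pulse_times=t, values=a / epsc_m1, epsc_m1=epsc_m1, frequency=f
        )
    return out


# ---------------------------------------------------------------------------
# Model fits
# ---------------------------------------------------------------------------

def _exp_decay(ppi, *params):
    out = np.ones_like(np.asarray(ppi, float))
    for a, tau in zip(params[::2], params[1::2]):
        out = out + a * np.exp(-np.asarray(ppi, float) / tau)
    return out


def _fit_n_exp(ppi, F, n_comp, n_starts=8, rng_seed=0):
    """Multi-start bounded least squares for the 1- or 2-exponential decay."""
    ppi = np.asarray(ppi, float)
    F = np.asarray(F, float)
    a0 = max(float(np.max(F) - 1.0), 1e-3)
    taus = np.geomspace(max(ppi.min(), 1e-3), ppi.max(), n_starts)
    rng = np.random.default_rng(rng_seed)
    best = None
    for i in range(n_starts):
        if n_comp == 1:
            p0 = [a0, taus[i]]
        else:
            j = (i + n_starts // 2) % n_starts
            p0 = [a0 * 0.8, taus[i], a0 * 0.2, taus[j]]
        p0 = [p * (1 + 0.05 * rng.standard_normal()) for p in p0]
        p0 = [max(p, 1e-6) for p in p0]
        try:
            popt, _ = optimize.curve_fit(
                _exp_decay,
                ppi,
                F,
                p0=p0,
                bounds=(0, [np.inf, 100.0] * n_comp),
                maxfev=5000,
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((_exp_decay(ppi, *popt) - F) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        raise RuntimeError(f"{n_comp}-component exponential fit did not converge")
    return best


def _aicc(rss, n, k, scale):
    # rss floor keeps noiseless (machine-zero) fits finite while preserving ranking
    rss = max(rss, n * (1e-9 * scale) ** 2)
    if n - k - 1 <= 0:
        return np.inf
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def fit_ppf_decay(ppi: np.ndarray, F: np.ndarray) -> ExpDecayFit:
    """Fit F(PPI) = 1 + sum A_i exp(-PPI/tau_i) with AICc model selection.

    Both a one- and a two-component model are fitted by bounded multi-start
    least squares; the two-component model is preferred only when its
    corrected AIC improves on the single component's by more than 2.
    """
    ppi = np.asarray(ppi, float)
    F = np.asarray(F, float)
    if ppi.size < 5:
        raise ValueError("need at least 5 PPI points")
    scale = max(float(np.max(np.abs(F))), 1.0)
    p1, rss1 = _fit_n_exp(ppi, F, 1)
    p2, rss2 = _fit_n_exp(ppi, F, 2)
    n = ppi.size
    # k counts fitted parameters plus the residual variance
    use_two = _aicc(rss2, n, 5, scale) < _aicc(rss1, n, 3, scale) - 2.0
    if use_two:
        comps = sorted(
            [(float(p2[0]), float(p2[1])), (float(p2[2]), float(p2[3]))],
            key=lambda c: c[1],
        )
        return ExpDecayFit(components=comps, n_components=2, rss=rss2)
    return ExpDecayFit(
        components=[(float(p1[0]), float(p1[1]))], n_components=1, rss=rss1
    )


def fit_train_buildup(
    pulse_times: np.ndarray,
    F: np.ndarray,
    *,
    window: float = 2.5,
    tau1: float = 0.099,
    tau2: float = 1.0,
) -> TrainBuildupFit:
    """Fit the two-component facilitation buildup with fixed time constants.

    F(t) = 1 + B1 (1-exp(-t/tau1)) + B2 (1-exp(-t/tau2)) is linear in
    (B1, B2), so the bounded (B >= 0) fit over pulses with t <= ``window``
    reduces to non-negative least squares.  Time constants default to the
    paired-pulse decay values (99 ms and 1.0 s).
    """
    if not tau1 < tau2:
        raise ValueError("tau1 must be < tau2")
    t = np.asarray(pulse_times, float)
    F = np.asarray(F, float)
    m = t <= window + 1e-12
    t, F = t[m], F[m]
    if t.size < 4:
        raise ValueError("fewer than 4 pulses inside the fit window")
    G = np.column_stack([1.0 - np.exp(-t / tau1), 1.0 - np.exp(-t / tau2)])
    b, _ = optimize.nnls(G, F - 1.0)
    resid = F - 1.0 - G @ b
    rss = float(resid @ resid)
    dof = max(t.size - 2, 1)
    sigma2 = rss / dof
    try:
        cov = sigma2 * np.linalg.inv(G.T @ G)
        sd = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        sd = np.full(2, np.nan)
    return TrainBuildupFit(
        B1=float(b[0]), B2=float(b[1]), tau1=tau1, tau2=tau2,
        sd_B1=float(sd[0]), sd_B2=float(sd[1]), rss=rss,
    )


def train_metrics(
    pulse_times: np.ndarray,
    F: np.ndarray,
    *,
    plateau_tolerance: float = 0.10,
    min_run: int = 5,
    n_final: int = 10,
    smooth: int | None = None,
) -> TrainMetrics:
    """Steady-state facilitation, depression latency, and final facilitation.

    The plateau ("region of peak facilitation") is found from the highest
    facilitation level sustained for at least ``min_run`` consecutive pulses
    (the maximum over positions of the rolling ``min_run``-pulse minimum of
    lightly smoothed F): the plateau is the longest contiguous run of pulses
    whose smoothed F lies within ``plateau_tolerance`` of that sustained
    level, and steady state is the mean raw F over the run.  Anchoring on
    the sustained level rather than the single global maximum keeps a brief
    noise spike or an early 1-2 pulse transient from displacing the plateau.
    The smoothing window defaults to ~1/40 of the train (3-9 pulses), enough
    to keep trial-to-trial noise from fragmenting the plateau run on long
    trains.  Depression latency is the time of the
    first pulse of the final excursion below steady state (i.e. after the
    last pulse at or above it); if F never ends below steady state the
    latency is ``None``.  Final facilitation is the mean of the last
    ``n_final`` values.
    """
    t = np.asarray(pulse_times, float)
    F = np.asarray(F, float)
    if F.size < 2 * n_final:
        raise ValueError(f"need at least {2 * n_final} pulses")
    if smooth is None:
        smooth = int(np.clip(F.size // 40, 3, 9))
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        Fs = np.convolve(F, kernel, mode="same")
        # edges of 'same' convolution are biased low; fall back to raw there
        h = smooth // 2
        Fs[:h], Fs[-h:] = F[:h], F[-h:]
    else:
        Fs = F
    rolling_min = np.lib.stride_tricks.sliding_window_view(Fs, min_run).min(axis=1)
    sustained = float(rolling_min.max())
    good = Fs >= (1.0 - plateau_tolerance) * sustained
    # longest contiguous run of qualifying pulses, earliest on ties
    best_len, best_start, cur_start = 0, 0, None
    for i, g in enumerate(np.append(good, False)):
        if g and cur_start is None:
            cur_start = i
        elif not g and cur_start is not None:
            if i - cur_start > best_len:
                best_len, best_start = i - cur_start, cur_start
            cur_start = None
    run = (best_start, best_start + best_len - 1)
    steady = float(np.mean(F[run[0] : run[1] + 1]))

    above = np.nonzero(F >= steady)[0]
    last_above = int(above[-1]) if above.size else -1
    if last_above == F.size - 1:
        latency = None
    else:
        latency = float(t[last_above + 1])
    final = float(np.mean(F[-n_final:]))
    return TrainMetrics(
        steady_state=steady,
        depression_latency=latency,
        final_facilitation=final,
        plateau_indices=run,
    )
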