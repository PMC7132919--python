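"""Variance-mean (multiple-probability fluctuation) analysis.

Five-pulse 20-Hz trains drive the synapse from low release probability
(first pulse) to high (fifth pulse).  Across 20-25 stability-screened trains
the per-pulse mean amplitude and variance trace out the binomial parabola

    sigma^2 = Q * I - I^2 / N

whose origin slope gives the quantal size Q, whose curvature gives the
number of release sites N, and from which the initial release probability
P_R = I_1 / (N Q) follows.  The simplified parabola (no intrasite quantal
variance term) is the default; an optional quantal-CV correction divides the
fitted Q by (1 + CV^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .traceio import SweepSet
from .stp import measure_epsc_amplitudes

__all__ = [
    "VarianceMeanPoint",
    "QuantalEstimate",
    "variance_mean_points",
    "amplitude_matrix",
    "fit_parabola",
]


@dataclass
class VarianceMeanPoint:
    pulse_index: int     # 1-based
    mean_amp: float      # pA magnitude
    variance: float      # pA^2
    n_trials: int

    def __post_init__(self) -> None:
        if self.n_trials < 2:
            raise ValueError("variance needs at least 2 trials")
        if self.variance < 0:
            raise ValueError("variance must be non-negative")


@dataclass
class QuantalEstimate:
    Q: float                 # pA magnitude
    N: float                 # release sites, continuous
    P_R: float               # pulse-1 release probability
    per_pulse_P: np.ndarray
    rss: float
    flags: list[str] = field(default_factory=list)

    @property
    def q_signed(self) -> float:
        """Quantal size as recorded (inward currents negative)."""
        return -self.Q


def amplitude_matrix(
    sweepset: SweepSet,
    *,
    fixed_peak: bool = True,
    search_window: tuple[float, float] = (0.001, 0.010),
    baseline_window: float = 0.002,
    **measure_kwargs,
) -> np.ndarray:
    """Individually measured per-pulse amplitudes, shape (n_trains, n_pulses).

    With ``fixed_peak`` (default) the peak latency of each pulse is located
    once on the across-train average trace and every individual train is
    read at that fixed latency (minus its own pre-pulse baseline).  This
    avoids the extreme-value bias that per-train extremum picking adds to
    small-amplitude responses, which matters because the variance-mean
    parabola is anchored by the low-probability first pulse.  With
    ``fixed_peak=False`` each train is measured independently via
    :func:`ctsyn.stp.measure_epsc_amplitudes`.
    """
    from .stp import average_sweeps

    sizes = {sw.stim_times.size for sw in sweepset}
    if len(sizes) != 1:
        raise ValueError(f"unequal pulse counts across trains: {sorted(sizes)}")
    if not fixed_peak:
        rows = [
            measure_epsc_amplitudes(
                sw, search_window=search_window,
                baseline_window=baseline_window, **measure_kwargs,
            )
            for sw in sweepset
        ]
        return np.vstack(rows)

    avg = average_sweeps(list(sweepset))
    sr = avg.sample_rate
    stim = avg.stim_times
    peak_idx = []
    for n, t in enumerate(stim):
        w0 = t + search_window[0]
        w1 = t + search_window[1]
        if n + 1 < stim.size:
            w1 = min(w1, stim[n + 1])
        i0, i1 = int(round(w0 * sr)), int(round(w1 * sr))
        peak_idx.append(i0 + int(np.argmin(avg.current[i0:i1])))
    peak_idx = np.asarray(peak_idx)

    rows = []
    for sw in sweepset:
        amps = np.empty(stim.size)
        for n, t in enumerate(stim):
            b0 = max(0, int(round((t - baseline_window) * sr)))
            b1 = int(round(t * sr))
            base = float(np.mean(sw.current[b0:b1])) if b1 > b0 else 0.0
            amps[n] = sw.current[peak_idx[n]] - base
        rows.append(amps)
    return np.vstack(rows)


def variance_mean_points(
    sweepset_or_amps, min_trains: int = 3, **measure_kwargs
) -> list[VarianceMeanPoint]:
    """Per-pulse sample mean and unbiased variance across repeated trains.

    Accepts a stability-screened :class:`~ctsyn.traceio.SweepSet` (amplitudes
    measured individually per train) or a pre-measured amplitude matrix of
    shape (n_trains, n_pulses).  Amplitudes are converted to magnitudes.
    """
    if isinstance(sweepset_or_amps, SweepSet):
        amps = amplitude_matrix(sweepset_or_amps, **measure_kwargs)
    else:
        amps = np.asarray(sweepset_or_amps, dtype=float)
    if amps.ndim != 2:
        raise ValueError("expected a 2-D (trains x pulses) amplitude array")
    n_trains, n_pulses = amps.shape
    if n_trains < min_trains:
        raise ValueError(f"need at least {min_trains} trains, got {n_trains}")
    mags = np.abs(amps)
    return [
        VarianceMeanPoint(
            pulse_index=j + 1,
            mean_amp=float(np.mean(mags[:, j])),
            variance=float(np.var(mags[:, j], ddof=1)),
            n_trials=n_trains,
        )
        for j in range(n_pulses)
    ]


def fit_parabola(
    points: list[VarianceMeanPoint],
    *,
    weighted: bool = False,
    quantal_cv: float = 0.0,
) -> QuantalEstimate:
    """Least-squares fit of the variance-mean parabola through the origin.

    sigma^2 = Q I - I^2 / N is linear in (Q, 1/N), so the constrained fit is
    an ordinary linear least squares on the basis (I, -I^2).  With
    ``weighted`` the points are weighted by n / sigma^4 (inverse sampling
    variance of a normal sample variance, up to a constant).  ``quantal_cv``
    applies the intrasite quantal-variance correction Q -> Q / (1 + CV^2).

    A best-fit N <= 0 (super-Poissonian data) and the deterministic-release
    limit (all variances zero) are flagged rather than raised.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 variance-mean points")
    I = np.array([p.mean_amp for p in points], dtype=float)
    V = np.array([p.variance for p in points], dtype=float)
    if np.unique(np.round(I, 12)).size < 3:
        raise ValueError("need at least 3 distinct mean amplitudes")

    flags: list[str] = []
    if np.all(V == 0):
        # deterministic release: every site releases on every trial (P -> 1)
        flags.append("zero_variance_P1_limit")
        return QuantalEstimate(
            Q=float("nan"), N=float("nan"), P_R=1.0,
            per_pulse_P=np.ones_like(I), rss=0.0, flags=flags,
        )

    G = np.column_stack([I, -(I ** 2)])
    if weighted:
        w = np.array([p.n_trials for p in points]) / np.maximum(V, 1e-12) ** 2
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(G * sw[:, None], V * sw, rcond=None)
    else:
        coef, *_ = np.linalg.lstsq(G, V, rcond=None)
    q_raw, inv_n = float(coef[0]), float(coef[1])
    rss = float(np.sum((G @ coef - V) ** 2))

    Q = q_raw / (1.0 + quantal_cv ** 2)
    if inv_n <= 0:
        flags.append("super_poissonian_N_nonpositive")
        N = float("inf") if inv_n == 0 else 1.0 / inv_n
        per_p = np.full_like(I, np.nan)
        pr = float("nan")
    else:
        N = 1.0 / inv_n
        per_p = I / (N * Q)  # I = N p Q with Q the corrected quantal size
        pr = float(per_p[0])
    if Q <= 0:
        flags.append("nonpositive_Q")
    return QuantalEstimate(Q=Q, N=N, P_R=pr, per_pulse_P=per_p, rss=rss, flags=flags)
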