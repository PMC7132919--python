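"""Seeded synthetic-data generators for every analysis stage.

The centerpiece is a mechanistic binomial-release simulator for a
corticothalamic-style facilitating synapse: N independent release sites with
a low initial release probability p0, two additive facilitation components
(fast ~100 ms and slow ~1 s) that increment per pulse and decay
exponentially between pulses, stochastic site reoccupancy after release
(rate 1/refill_tau), and slow transmitter refilling of the reoccupying
vesicle (time constant transmitter_fill_tau).  During sustained
high-frequency stimulation, vesicle turnover outpaces transmitter refilling
and the synapse depresses; two depression mechanisms are selectable:

* ``partial_fill`` - under-filled vesicles release with proportionally
  smaller quantal amplitude;
* ``reluctant``   - under-filled vesicles are release-incompetent until
  essentially full (fill >= 0.95).

Genotype presets encode the hemizygous-VGluT1 phenotype relative to wild
type: initial release probability scaled up 1.92x (0.051 -> 0.098; less
"brake" on the release machinery), the slow facilitation increment scaled to
the observed slow-component ratio, and the transmitter refilling rate scaled
down to 71.1% (the measured 28.9% reduction in transporter level).

Further generators emulate the remaining inputs: Poisson spontaneous EPSC
trains with gamma amplitudes, TVA-governed 5CSRTT trial outcomes, dual
channel puncta images with controllable overlap, and annotated terminal
geometries for EM morphometrics.  Every generator is bit-reproducible given
(parameters, seed); repeats are seeded from independent spawned streams so
adding repeats never perturbs earlier ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal

from .events import epsc_template
from .imaging import ImagePair
from .traceio import Sweep, SweepSet
from .ultrastructure import TerminalAnnotation, max_feret, polygon_area

__all__ = [
    "ReleaseModelParams",
    "release_params",
    "expected_facilitation",
    "simulate_release_trains",
    "simulate_release_amplitudes",
    "simulate_membrane_test_sweep",
    "simulate_spontaneous",
    "simulate_5csrtt",
    "simulate_coloc_images",
    "simulate_terminals",
]


# ---------------------------------------------------------------------------
# Release model
# ---------------------------------------------------------------------------

@dataclass
class ReleaseModelParams:
    """Parameters of the binomial release simulator.

    ``facil_increments`` are the per-pulse additive gains of the fast and
    slow facilitation components; with decay constants ``facil_taus`` the
    pre-pulse steady state of component k at inter-stimulus interval D is
    a_k x/(1-x), x = exp(-D/tau_k).  The wild-type defaults are calibrated
    so the 20-Hz steady state matches the fitted buildup amplitudes
    (B1 = 5.11, B2 = 2.42).  ``q_shape`` is the gamma shape of quantal
    variability (None disables it, giving exactly q_mean per vesicle).
    ``refill_tau`` or ``transmitter_fill_tau`` of zero mean instantaneous
    recovery (depression disabled when both are zero).

    ``pool_size`` is the reserve of initially full vesicles beyond the
    docked ones: reoccupying sites draw full vesicles from the reserve, in
    order of reoccupancy, until it is exhausted; afterwards they dock
    recycled vesicles whose transmitter fill grows from the reoccupancy
    time.  The finite reserve produces the seconds-scale latency before
    depression during sustained high-frequency stimulation, and it drains
    faster at the higher release rates of the hemi preset, so depression
    starts earlier there even though the pool itself is genotype-independent
    (vesicle counts are unchanged ultrastructurally).  ``None`` means an
    unlimited full reserve (no fill-state depression).
    """

    n_sites: int = 20
    p0: float = 0.051
    facil_increments: tuple[float, float] = (3.3578, 0.12408)
    facil_taus: tuple[float, float] = (0.099, 1.0)
    refill_tau: float = 0.15
    transmitter_fill_tau: float = 0.5
    pool_size: int | None = 600
    q_mean: float = 5.0          # pA magnitude
    q_shape: float | None = 13.5
    depression_mode: str = "partial_fill"   # or "reluctant"
    noise_sd: float = 1.5        # pA
    kernel_taus: tuple[float, float] = (0.5, 5.0)  # ms rise/decay
    genotype_preset: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.p0 <= 1:
            raise ValueError("p0 must be in (0, 1]")
        if self.q_mean <= 0:
            raise ValueError("q_mean must be positive")
        if min(self.facil_taus) <= 0:
            raise ValueError("facilitation time constants must be positive")
        if self.refill_tau < 0 or self.transmitter_fill_tau < 0:
            raise ValueError("refill time constants must be non-negative")
        if self.depression_mode not in ("partial_fill", "reluctant"):
            raise ValueError("depression_mode must be 'partial_fill' or 'reluctant'")


#: Printed P_R ratio between genotypes (0.098 / 0.051).
PR_RATIO_HEMI = 0.098 / 0.051
#: Fractional reduction of transporter level in hemizygotes.
TRANSPORTER_REDUCTION = 0.289
#: Ratio of slow buildup amplitudes at 20 Hz (0.61 / 2.42).
B2_RATIO_HEMI = 0.61 / 2.42


def release_params(preset: str = "wt", **overrides) -> ReleaseModelParams:
    """Wild-type or hemizygous parameter presets, with overrides.

    ``hemi`` scales p0 by the printed release-probability ratio (x1.92),
    the slow facilitation increment by the printed slow-component ratio
    (x0.25), and slows transmitter refilling by 1/0.711 relative to wt.
    """
    base = ReleaseModelParams(genotype_preset=preset)
    if preset == "wt":
        params = base
    elif preset == "hemi":
        a1, a2 = base.facil_increments
        params = replace(
            base,
            p0=base.p0 * PR_RATIO_HEMI,
            facil_increments=(a1, a2 * B2_RATIO_HEMI),
            transmitter_fill_tau=base.transmitter_fill_tau
            / (1.0 - TRANSPORTER_REDUCTION),
        )
    else:
        raise ValueError(f"unknown preset {preset!r}")
    return replace(params, **overrides) if overrides else params


def expected_facilitation(
    params: ReleaseModelParams, stim_times: np.ndarray
) -> np.ndarray:
    """Deterministic per-pulse facilitation F_n of the model (depression off).

    F_n multiplies p0 at pulse n; where p0*F_n would exceed 1 the effective
    facilitation is clipped to 1/p0.  With depression and noise disabled,
    mean(EPSC_n)/mean(EPSC_1) of the simulator converges to this sequence.
    """
    a1, a2 = params.facil_increments
    tau1, tau2 = params.facil_taus
    f1 = f2 = 0.0
    out = np.empty(len(stim_times))
    t_prev = None
    for n, t in enumerate(np.asarray(stim_times, float)):
        if t_prev is not None:
            dt = t - t_prev
            f1 *= math.exp(-dt / tau1)
            f2 *= math.exp(-dt / tau2)
        out[n] = min(1.0 + f1 + f2, 1.0 / params.p0)
        f1 += a1
        f2 += a2
        t_prev = t
    return out


def _render_trace(
    sample_rate: float,
    duration: float,
    impulse_times: np.ndarray,
    impulse_amps: np.ndarray,
    kernel_taus: tuple[float, float],
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Convolve quantal impulses with the EPSC kernel and add Gaussian noise."""
    n = int(round(duration * sample_rate))
    trace = np.zeros(n)
    if impulse_times.size:
        idx = np.round(np.asarray(impulse_times) * sample_rate).astype(int)
        np.add.at(trace, idx[idx < n], np.asarray(impulse_amps)[idx < n])
        kernel = epsc_template(sample_rate, kernel_taus)  # peak -1
        trace = signal.fftconvolve(trace, kernel)[:n]
    if noise_sd > 0:
        trace = trace + rng.normal(0.0, noise_sd, n)
    return trace


def simulate_release_trains(
    params: ReleaseModelParams,
    stim_times: np.ndarray,
    n_repeats: int,
    seed: int,
    *,
    sample_rate: float = 20000.0,
    post: float = 0.1,
    protocol_meta: dict | None = None,
) -> SweepSet:
    """Simulate repeated stimulus trains through the binomial release model.

    Each repeat draws, per pulse, independent releases from the currently
    occupied-and-competent sites with probability min(1, p0 * F(t)), sums the
    (gamma-distributed, fill-scaled) quantal amplitudes, and renders the
    inward current trace by kernel convolution plus Gaussian noise.  Ground
    truth is stored in each sweep's ``meta``: per-pulse released quantal sum
    magnitudes (``released_amps``) and counts (``released_counts``).
    """
    stim_times = np.asarray(stim_times, dtype=float)
    if stim_times.size == 0 or np.any(np.diff(stim_times) <= 0):
        raise ValueError("stim_times must be nonempty and strictly increasing")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    N = params.n_sites
    a1, a2 = params.facil_increments
    tau1, tau2 = params.facil_taus
    duration = stim_times[-1] + post
    children = np.random.SeedSequence(seed).spawn(n_repeats)

    sweeps = []
    for child in children:
        rng = np.random.default_rng(child)
        pulse_amps, pulse_counts = _simulate_repeat(params, stim_times, rng)
        nz = pulse_amps > 0
        trace = _render_trace(
            sample_rate, duration, stim_times[nz], pulse_amps[nz],
            params.kernel_taus, params.noise_sd, rng,
        )
        meta = dict(protocol_meta or {})
        meta.update(
            released_amps=pulse_amps.tolist(),
            released_counts=pulse_counts.tolist(),
        )
        sweeps.append(
            Sweep(
                sample_rate=sample_rate,
                current=trace,
                stim_times=stim_times,
                meta=meta,
            )
        )
    return SweepSet(sweeps, meta={"seed": seed, "preset": params.genotype_preset})


def simulate_release_amplitudes(
    params: ReleaseModelParams,
    stim_times: np.ndarray,
    n_repeats: int,
    seed: int,
) -> np.ndarray:
    """Per-pulse released quantal-sum magnitudes, shape (n_repeats, n_pulses).

    Identical draws to :func:`simulate_release_trains` with the same seed
    (the trace rendering consumes its noise only after the release draws),
    but without building current traces - convenient for large Monte Carlo
    runs against analytic binomial expectations.
    """
    stim_times = np.asarray(stim_times, dtype=float)
    if stim_times.size == 0 or np.any(np.diff(stim_times) <= 0):
        raise ValueError("stim_times must be nonempty and strictly increasing")
    children = np.random.SeedSequence(seed).spawn(n_repeats)
    out = np.empty((n_repeats, stim_times.size))
    for r, child in enumerate(children):
        out[r], _ = _simulate_repeat(params, stim_times, np.random.default_rng(child))
    return out


def _simulate_repeat(
    params: ReleaseModelParams, stim_times: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One stochastic pass of the release model; returns per-pulse quantal
    sums (magnitudes) and released-vesicle counts."""
    N = params.n_sites
    a1, a2 = params.facil_increments
    tau1, tau2 = params.facil_taus
    next_ready = np.zeros(N)       # time a site becomes reoccupied
    fill_start = np.full(N, -1e9)  # docked vesicles start full
    pending = np.zeros(N, dtype=bool)  # reoccupied sites awaiting a vesicle
    reserve = np.inf if params.pool_size is None else int(params.pool_size)
    f1 = f2 = 0.0
    t_prev = None
    pulse_amps = np.empty(stim_times.size)
    pulse_counts = np.empty(stim_times.size, dtype=int)
    for n, t in enumerate(stim_times):
        if t_prev is not None:
            dt = t - t_prev
            f1 *= math.exp(-dt / tau1)
            f2 *= math.exp(-dt / tau2)
        p = min(1.0, params.p0 * (1.0 + f1 + f2))
        # settle reoccupancies due by now, drawing full vesicles from the
        # reserve in order of reoccupancy time
        due = np.nonzero(pending & (next_ready <= t))[0]
        if due.size:
            for i in due[np.argsort(next_ready[due])]:
                if reserve > 0:
                    fill_start[i] = -1e9  # full vesicle from the reserve
                    reserve -= 1
                else:
                    fill_start[i] = next_ready[i]  # recycled, refilling
                pending[i] = False
        available = next_ready <= t
        if params.transmitter_fill_tau > 0:
            fill = -np.expm1(-(t - fill_start) / params.transmitter_fill_tau)
            fill = np.clip(fill, 0.0, 1.0)
        else:
            fill = np.ones(N)
        if params.depression_mode == "reluctant":
            competent = available & (fill >= 0.95)
        else:
            competent = available
        released = competent & (rng.random(N) < p)
        k = int(released.sum())
        if k:
            if params.q_shape is not None:
                q = rng.gamma(params.q_shape, params.q_mean / params.q_shape, k)
            else:
                q = np.full(k, params.q_mean)
            if params.depression_mode == "partial_fill":
                q = q * fill[released]
            amp = float(np.sum(q))
            delays = (
                rng.exponential(params.refill_tau, k)
                if params.refill_tau > 0
                else np.zeros(k)
            )
            next_ready[released] = t + delays
            pending[released] = True
        else:
            amp = 0.0
        pulse_amps[n] = amp
        pulse_counts[n] = k
        f1 += a1
        f2 += a2
        t_prev = t
    return pulse_amps, pulse_counts


def simulate_membrane_test_sweep(
    access_mohm: float,
    input_mohm: float,
    *,
    delta_v: float = 5.0,
    tau: float = 0.002,
    step_window: tuple[float, float] = (0.01, 0.06),
    duration: float = 0.08,
    sample_rate: float = 50000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Sweep:
    """A voltage-step membrane-test sweep with known resistances.

    The step current is the classic single-compartment response
    I(t) = (dV/Ra - dV/Rin) exp(-t/tau) + dV/Rin inside the step window
    (currents in pA for dV in mV, R in MOhm).
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    i_peak = 1000.0 * delta_v / access_mohm
    i_ss = 1000.0 * delta_v / input_mohm
    cur = np.zeros(n)
    inside = (t >= step_window[0]) & (t < step_window[1])
    cur[inside] = (i_peak - i_ss) * np.exp(-(t[inside] - step_window[0]) / tau) + i_ss
    if noise_sd > 0:
        cur = cur + rng.normal(0, noise_sd, n)
    return Sweep(
        sample_rate=sample_rate,
        current=cur,
        membrane_step={"delta_v": delta_v, "window": list(step_window)},
    )


# ---------------------------------------------------------------------------
# Spontaneous events
# ---------------------------------------------------------------------------

def simulate_spontaneous(
    rate: float,
    duration: float,
    *,
    q_mean: float = 8.775,
    q_shape: float = 13.5,
    noise_sd: float = 1.0,
    seed: int = 0,
    sample_rate: float = 10000.0,
    kernel_taus: tuple[float, float] = (0.5, 5.0),
) -> Sweep:
    """Poisson spontaneous EPSCs with gamma amplitudes on a noisy baseline.

    Ground truth lives in ``meta['events']`` (onset times snapped to the
    sample grid, signed amplitudes).  The amplitude defaults reproduce the
    gamma fit of asynchronous-EPSC histograms (k = 13.5, mean ~8.8 pA).
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n_events = rng.poisson(rate * duration)
    times = np.sort(rng.uniform(0.0, duration, n_events))
    # snap to sample grid so ground truth matches renderable onsets
    times = np.round(times * sample_rate) / sample_rate
    times = times[times < duration - 10 * kernel_taus[1] / 1000.0]
    amps = rng.gamma(q_shape, q_mean / q_shape, times.size)
    trace = _render_trace(
        sample_rate, duration, times, amps, kernel_taus, noise_sd, rng
    )
    return Sweep(
        sample_rate=sample_rate,
        current=trace,
        meta={
            "rate": rate,
            "events": {"times": times.tolist(), "amplitudes": (-amps).tolist()},
        },
    )


# ---------------------------------------------------------------------------
# 5CSRTT behavior
# ---------------------------------------------------------------------------

def simulate_5csrtt(
    t0: float,
    v: float,
    b: float,
    durations: np.ndarray,
    trials_per_duration: int,
    *,
    lapse: float = 0.0,
    latency_noise_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """TVA-governed trial outcomes for a stimulus-duration test.

    Per trial the stimulus is encoded after t0 + X with X ~ Exp(v); if that
    happens before stimulus offset the trial is correct with latency
    b + t0 + X (+ Gaussian motor noise), otherwise an omission.  With
    probability ``lapse`` the animal instead touches a random window
    (correct 1/5 of the time) with a uniform latency.
    """
    if v <= 0:
        raise ValueError("v must be positive")
    if np.any(np.asarray(durations, float) <= 0):
        raise ValueError("durations must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for d in np.asarray(durations, dtype=float):
        for _ in range(trials_per_duration):
            window = int(rng.integers(1, 6))
            if lapse > 0 and rng.random() < lapse:
                touched = int(rng.integers(1, 6))
                rows.append(
                    {
                        "duration_s": d,
                        "outcome": "correct" if touched == window else "incorrect",
                        "latency_s": b + rng.uniform(0.0, max(d, 0.1)),
                        "window": window,
                        "condition": "none",
                    }
                )
                continue
            x = rng.exponential(1.0 / v)
            if t0 + x <= d:
                lat = b + t0 + x + rng.normal(0.0, latency_noise_sd)
                rows.append(
                    {
                        "duration_s": d,
                        "outcome": "correct",
                        "latency_s": max(lat, 0.0),
                        "window": window,
                        "condition": "none",
                    }
                )
            else:
                rows.append(
                    {
                        "duration_s": d,
                        "outcome": "omission",
                        "latency_s": float("nan"),
                        "window": window,
                        "condition": "none",
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Colocalization images
# ---------------------------------------------------------------------------

def _stamp_gaussians(img, positions, amps, sigma):
    half = max(3, int(round(4 * sigma)))
    ax = np.arange(-half, half + 1)
    gx, gy = np.meshgrid(ax, ax)
    for (r, c), a in zip(positions, amps):
        r, c = int(round(r)), int(round(c))
        stamp = a * np.exp(-((gx - (0)) ** 2 + (gy - 0) ** 2) / (2 * sigma ** 2))
        r0, r1 = r - half, r + half + 1
        c0, c1 = c - half, c + half + 1
        sr0, sc0 = max(0, -r0), max(0, -c0)
        r0, c0 = max(r0, 0), max(c0, 0)
        r1, c1 = min(r1, img.shape[0]), min(c1, img.shape[1])
        img[r0:r1, c0:c1] += stamp[sr0 : sr0 + (r1 - r0), sc0 : sc0 + (c1 - c0)]


def simulate_coloc_images(
    n_puncta: int,
    overlap_fraction: float,
    *,
    punctum_sigma: float = 1.5,
    image_size: int = 256,
    pixel_size: float = 0.156,
    amp_a: float = 8000.0,
    amp_b: float = 8000.0,
    background: float = 300.0,
    noise_sd: float = 30.0,
    n_independent_b: int | None = None,
    uniform_b: bool = False,
    seed: int = 0,
) -> tuple[ImagePair, dict]:
    """Dual-channel puncta images with controllable channel overlap.

    Channel A carries ``n_puncta`` Gaussian puncta on a flat background;
    channel B places puncta at ``overlap_fraction`` of the channel-A
    positions plus ``n_independent_b`` puncta at independent positions
    (default: the complement count, keeping total B intensity comparable).
    With ``uniform_b`` channel B is a constant background.  Returns the
    image pair and a ground-truth dict (positions and a boolean punctum
    mask of 2-sigma disks).
    """
    if not 0 <= overlap_fraction <= 1:
        raise ValueError("overlap_fraction must be in [0, 1]")
    if image_size <= 8 * punctum_sigma:
        raise ValueError("image too small for the punctum size")
    rng = np.random.default_rng(seed)
    margin = int(math.ceil(4 * punctum_sigma)) + 1
    pos_a = rng.uniform(margin, image_size - margin, (n_puncta, 2))
    amps_a = amp_a * rng.uniform(0.6, 1.4, n_puncta)

    a = np.full((image_size, image_size), background, dtype=float)
    _stamp_gaussians(a, pos_a, amps_a, punctum_sigma)

    b = np.full((image_size, image_size), background, dtype=float)
    n_overlap = int(round(overlap_fraction * n_puncta))
    overlap_idx = rng.choice(n_puncta, n_overlap, replace=False)
    if n_independent_b is None:
        n_independent_b = n_puncta - n_overlap
    pos_b_ind = rng.uniform(margin, image_size - margin, (n_independent_b, 2))
    if not uniform_b:
        _stamp_gaussians(b, pos_a[overlap_idx], amp_b * rng.uniform(0.6, 1.4, n_overlap), punctum_sigma)
        _stamp_gaussians(b, pos_b_ind, amp_b * rng.uniform(0.6, 1.4, n_independent_b), punctum_sigma)
    if noise_sd > 0:
        a += rng.normal(0, noise_sd, a.shape)
        b += rng.normal(0, noise_sd, b.shape)
    a = np.clip(a, 0, 65535)
    b = np.clip(b, 0, 65535)

    rr, cc = np.mgrid[0:image_size, 0:image_size]
    mask = np.zeros((image_size, image_size), dtype=bool)
    r_disk = 2.0 * punctum_sigma
    for r, c in pos_a:
        mask |= (rr - r) ** 2 + (cc - c) ** 2 <= r_disk ** 2
    truth = {
        "positions_a": pos_a,
        "positions_b_overlap": pos_a[overlap_idx],
        "positions_b_independent": pos_b_ind,
        "mask": mask,
    }
    return ImagePair(a, b, pixel_size=pixel_size), truth


# ---------------------------------------------------------------------------
# Terminal annotations
# ---------------------------------------------------------------------------

def _uniform_in_polygon(membrane, n, rng):
    from shapely import contains_xy
    from shapely.geometry import Polygon

    poly = Polygon(membrane)
    minx, miny, maxx, maxy = poly.bounds
    out = np.empty((0, 2))
    while out.shape[0] < n:
        m = max(4 * (n - out.shape[0]), 16)
        x = rng.uniform(minx, maxx, m)
        y = rng.uniform(miny, maxy, m)
        keep = contains_xy(poly, x, y)
        out = np.vstack([out, np.column_stack([x[keep], y[keep]])])
    return out[:n]


def simulate_terminals(
    n_terminals: int,
    *,
    feret_target: float = 677.0,
    vesicle_density: float = 150.0,   # per um^2
    gold_density: float = 40.0,       # per um^2
    az_fraction: float = 0.12,
    aspect: float = 0.7,
    perturbation: float = 0.03,
    feret_jitter: float = 0.02,
    n_vertices: int = 64,
    seed: int = 0,
) -> list[TerminalAnnotation]:
    """Annotated presynaptic terminals: perturbed-ellipse membranes with
    uniform interior point patterns and a contiguous active-zone polyline.

    Each membrane is an ellipse (aspect ratio ``aspect``) with smooth
    low-order radial perturbation, rotated randomly and rescaled so its
    maximum Feret diameter hits ``feret_target`` up to a lognormal jitter.
    Vesicle and gold counts are Poisson at the given densities (per um^2 of
    membrane area); the active zone is the membrane stretch covering
    ``az_fraction`` of the perimeter from a random start.
    """
    if vesicle_density < 0 or gold_density < 0:
        raise ValueError("densities must be non-negative")
    if not 0 < az_fraction < 1:
        raise ValueError("az_fraction must be in (0, 1)")
    children = np.random.SeedSequence(seed).spawn(n_terminals)
    out = []
    for child in children:
        rng = np.random.default_rng(child)
        theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
        radial = np.ones(n_vertices)
        for order in (2, 3, 4):
            radial += (
                perturbation / 3.0 * rng.uniform(0.3, 1.0)
                * np.sin(order * theta + rng.uniform(0, 2 * np.pi))
            )
        x = radial * np.cos(theta)
        y = aspect * radial * np.sin(theta)
        rot = rng.uniform(0, 2 * np.pi)
        R = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
        membrane = np.column_stack([x, y]) @ R.T
        target = feret_target * math.exp(rng.normal(0.0, feret_jitter))
        membrane *= target / max_feret(membrane)

        area_um2 = polygon_area(membrane)
        n_ves = rng.poisson(vesicle_density * area_um2)
        n_gold = rng.poisson(gold_density * area_um2)
        pts_v = _uniform_in_polygon(membrane, n_ves, rng)
        pts_g = _uniform_in_polygon(membrane, n_gold, rng)
        points = np.vstack([pts_v, pts_g]) if n_ves + n_gold else np.empty((0, 2))
        kinds = np.array(["vesicle"] * n_ves + ["gold"] * n_gold, dtype=object)

        seg = np.vstack([membrane, membrane[:1]])
        seg_len = np.sqrt((np.diff(seg, axis=0) ** 2).sum(1))
        perimeter = seg_len.sum()
        start = int(rng.integers(0, n_vertices))
        target_len = az_fraction * perimeter
        az_pts = [membrane[start]]
        acc = 0.0
        i = start
        while True:
            j = (i + 1) % n_vertices
            L = seg_len[i % n_vertices]
            if acc + L >= target_len:
                # interpolate the final point to land exactly on target length
                frac = (target_len - acc) / L
                az_pts.append(membrane[i % n_vertices] * (1 - frac) + membrane[j] * frac)
                break
            acc += L
            az_pts.append(membrane[j])
            i += 1
        active_zone = np.asarray(az_pts)

        out.append(
            TerminalAnnotation(
                membrane=membrane,
                points=points,
                kinds=kinds,
                active_zone=active_zone,
                meta={"feret_target": feret_target},
            )
        )
    return out
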