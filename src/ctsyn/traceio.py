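"""Sweep containers, membrane-test resistances, and recording-stability screening.

Voltage-clamp current sweeps are stored with their stimulus timestamps in a
simple HDF5 layout (``/sweeps/<i>/{current, stim_times}`` plus attributes), or
as a single-sweep CSV (``time_s,current_pA``) with a JSON sidecar carrying the
sample rate and stimulus times.  Access and input resistance are computed from
the small membrane-test voltage step that precedes each train, and a
consecutive window of 20-25 trains with stable access resistance is selected
before any quantal analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Sweep",
    "SweepSet",
    "MembraneTest",
    "FormatError",
    "StabilityError",
    "read_sweeps",
    "write_sweeps",
    "read_sweep_csv",
    "write_sweep_csv",
    "membrane_test",
    "stability_screen",
]


class FormatError(ValueError):
    """Raised when a sweep container is malformed."""


class StabilityError(RuntimeError):
    """Raised when no window of trains satisfies the stability criterion."""


@dataclass
class Sweep:
    """A single voltage-clamp current trace.

    Parameters
    ----------
    sample_rate : float
        Sampling rate in Hz.
    current : ndarray
        Membrane current in pA (inward currents negative).
    stim_times : ndarray
        Stimulus onset times in seconds, strictly increasing, within the trace.
    membrane_step : dict, optional
        ``{"delta_v": mV, "window": (t0, t1)}`` describing the membrane-test
        voltage step, if one was applied.
    meta : dict
        Free-form protocol descriptor (e.g. ``{"ppi": 0.1}`` or
        ``{"frequency": 20.0, "n_pulses": 400}``).
    """

    sample_rate: float
    current: np.ndarray
    stim_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    membrane_step: dict | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.sample_rate) or self.sample_rate <= 0:
            raise FormatError("sample_rate must be a positive finite number")
        self.current = np.asarray(self.current, dtype=float)
        self.stim_times = np.asarray(self.stim_times, dtype=float)
        if not np.all(np.isfinite(self.current)):
            raise FormatError("current trace contains non-finite samples")
        if self.stim_times.size:
            if np.any(np.diff(self.stim_times) <= 0):
                raise FormatError("stim_times must be strictly increasing")
            if self.stim_times[0] < 0 or self.stim_times[-1] >= self.duration:
                raise FormatError("stim_times must lie within the trace")

    @property
    def duration(self) -> float:
        return self.current.size / self.sample_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.current.size) / self.sample_rate


@dataclass
class SweepSet:
    sweeps: list[Sweep]
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sweeps)

    def __iter__(self):
        return iter(self.sweeps)

    def __getitem__(self, i: int) -> Sweep:
        return self.sweeps[i]


@dataclass
class MembraneTest:
    """Access and input resistance from a voltage-step membrane test (MΩ)."""

    access_resistance: float
    input_resistance: float
    delta_v: float

    def __post_init__(self) -> None:
        if self.access_resistance <= 0 or self.input_resistance <= 0:
            raise ValueError("resistances must be positive")


# ---------------------------------------------------------------------------
# Container I/O
# ---------------------------------------------------------------------------

def write_sweeps(sweepset: SweepSet, path: str | Path) -> None:
    """Write a :class:`SweepSet` to the HDF5 layout ``/sweeps/<i>/...``."""
    with h5py.File(path, "w") as f:
        f.attrs["meta"] = json.dumps(sweepset.meta)
        grp = f.create_group("sweeps")
        for i, sw in enumerate(sweepset.sweeps):
            g = grp.create_group(str(i))
            g.create_dataset("current", data=sw.current)
            g.create_dataset("stim_times", data=sw.stim_times)
            g.attrs["sample_rate"] = sw.sample_rate
            g.attrs["meta"] = json.dumps(sw.meta)
            if sw.membrane_step is not None:
                g.attrs["membrane_step"] = json.dumps(sw.membrane_step)


def read_sweeps(path: str | Path) -> SweepSet:
    """Read a :class:`SweepSet` written by :func:`write_sweeps`."""
    sweeps = []
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs.get("meta", "{}"))
        if "sweeps" not in f:
            raise FormatError(f"{path}: no /sweeps group")
        grp = f["sweeps"]
        for key in sorted(grp, key=int):
            g = grp[key]
            if "sample_rate" not in g.attrs:
                raise FormatError(f"{path}: sweep {key} lacks sample_rate")
            step = g.attrs.get("membrane_step")
            sweeps.append(
                Sweep(
                    sample_rate=float(g.attrs["sample_rate"]),
                    current=g["current"][...],
                    stim_times=g["stim_times"][...],
                    membrane_step=json.loads(step) if step is not None else None,
                    meta=json.loads(g.attrs.get("meta", "{}")),
                )
            )
    return SweepSet(sweeps, meta=meta)


def write_sweep_csv(sweep: Sweep, path: str | Path) -> None:
    """CSV fallback: one sweep per file plus a ``.json`` sidecar."""
    path = Path(path)
    pd.DataFrame({"time_s": sweep.time, "current_pA": sweep.current}).to_csv(
        path, index=False
    )
    sidecar = {
        "sample_rate": sweep.sample_rate,
        "stim_times": list(map(float, sweep.stim_times)),
        "meta": sweep.meta,
    }
    if sweep.membrane_step is not None:
        sidecar["membrane_step"] = sweep.membrane_step
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_sweep_csv(path: str | Path) -> Sweep:
    path = Path(path)
    df = pd.read_csv(path)
    if "current_pA" not in df.columns:
        raise FormatError(f"{path}: missing current_pA column")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FormatError(f"{path}: missing JSON sidecar with sample_rate")
    sidecar = json.loads(sidecar_path.read_text())
    if "sample_rate" not in sidecar:
        raise FormatError(f"{sidecar_path}: missing sample_rate")
    return Sweep(
        sample_rate=float(sidecar["sample_rate"]),
        current=df["current_pA"].to_numpy(float),
        stim_times=np.asarray(sidecar.get("stim_times", []), dtype=float),
        membrane_step=sidecar.get("membrane_step"),
        meta=sidecar.get("meta", {}),
    )


# ---------------------------------------------------------------------------
# Membrane test
# ---------------------------------------------------------------------------

def membrane_test(
    sweep: Sweep,
    *,
    baseline_window: float = 0.002,
    steady_fraction: float = 0.25,
) -> MembraneTest:
    """Compute access and input resistance from the membrane-test step.

    Access resistance is ``ΔV / I_peak`` with ``I_peak`` the peak
    baseline-subtracted capacitive transient inside the step window; input
    resistance is ``ΔV / I_ss`` with ``I_ss`` the baseline-subtracted mean
    current over the final ``steady_fraction`` of the step.  The baseline is
    the mean of the 2 ms immediately preceding the step.  With ΔV in mV and
    current in pA the ratio ``1000·ΔV/I`` is in MΩ.
    """
    if sweep.membrane_step is None:
        raise ValueError("sweep has no membrane_step")
    delta_v = float(sweep.membrane_step["delta_v"])
    t0, t1 = sweep.membrane_step["window"]
    sr = sweep.sample_rate
    i0, i1 = int(round(t0 * sr)), int(round(t1 * sr))
    if i0 < 0 or i1 > sweep.current.size or i1 <= i0:
        raise ValueError("membrane-test window outside trace")
    b0 = max(0, i0 - int(round(baseline_window * sr)))
    if b0 == i0:
        raise ValueError("no pre-step samples for baseline")
    baseline = float(np.mean(sweep.current[b0:i0]))
    step = sweep.current[i0:i1] - baseline
    peak = float(np.max(np.abs(step)))
    n_ss = max(1, int(round(steady_fraction * (i1 - i0))))
    steady = float(np.mean(step[-n_ss:]))
    if peak == 0 or steady == 0:
        raise ValueError("zero step current; cannot compute resistance")
    return MembraneTest(
        access_resistance=1000.0 * abs(delta_v) / peak,
        input_resistance=1000.0 * abs(delta_v) / abs(steady),
        delta_v=delta_v,
    )


# ---------------------------------------------------------------------------
# Stability screening
# ---------------------------------------------------------------------------

def stability_screen(
    tests: list[MembraneTest],
    *,
    window: tuple[int, int] = (20, 25),
    tolerance: float = 0.15,
) -> tuple[int, int]:
    """Select the most stable consecutive run of trains.

    Scans every consecutive window whose length lies in ``window`` (inclusive
    bounds), keeps those where every access resistance is within
    ``±tolerance`` of the window median, and returns the inclusive index
    interval ``(start, stop)`` of the qualifying window with the lowest
    coefficient of variation of access resistance.  Ties are broken by
    earliest start, then by longest window.

    Raises
    ------
    StabilityError
        If no window qualifies.
    """
    lo, hi = window
    if lo < 1 or hi < lo:
        raise ValueError("window bounds must satisfy 1 <= lo <= hi")
    r = np.array([t.access_resistance for t in tests], dtype=float)
    if r.size < lo:
        raise StabilityError(f"need at least {lo} membrane tests, got {r.size}")
    best: tuple | None = None  # (cv, start, -length)
    best_iv: tuple[int, int] | None = None
    for start in range(0, r.size - lo + 1):
        for length in range(lo, min(hi, r.size - start) + 1):
            w = r[start : start + length]
            med = np.median(w)
            if np.any(np.abs(w - med) > tolerance * med):
                continue
            cv = float(np.std(w) / np.mean(w))
            key = (cv, start, -length)
            if best is None or key < best:
                best = key
                best_iv = (start, start + length - 1)
    if best_iv is None:
        raise StabilityError(
            f"no consecutive window of {lo}-{hi} trains is stable "
            f"within ±{tolerance:.0%} of its median access resistance"
        )
    return best_iv
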