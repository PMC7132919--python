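"""5CSRTT session scoring and TVA attention-model fitting.

A session is a table of trials with a stimulus duration, an outcome among
{correct, incorrect, omission, premature}, a response latency for responded
trials, and optional window/distractor annotations.  Scoring uses the task's
standard formulas: % accuracy = C/(C+I), % omission = O/(O+C+I), and mean
score = C/(C+I+O); premature trials never enter these denominators (in the
task they trigger a repeat of the trial).

The theory-of-visual-attention (TVA) fit estimates three parameters by a
simultaneous least-squares fit of mean score and correct-response latency
versus stimulus duration: preprocessing time t0 (s), visual processing speed
v (Hz), and base reaction time b (s).  The default model treats stimulus
encoding as an exponential race at rate v starting after t0:

    MS(d) = s_max * (1 - exp(-v (d - t0)))            for d > t0, else 0
    L(d)  = b + t0 + E[X | X <= d - t0],  X ~ Exp(v)
          = b + t0 + 1/v - (d - t0) e^{-v(d-t0)} / (1 - e^{-v(d-t0)})

so v is a purely perceptual rate, b a purely motor offset, and t0 a blended
onset delay.  Residuals of the two curves are divided by each curve's
observed standard deviation before stacking, making the joint objective
dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "OUTCOMES",
    "SessionSummary",
    "TVAFit",
    "UnidentifiableError",
    "score_session",
    "mean_score_model",
    "latency_model",
    "tva_fit",
    "read_trials",
    "write_trials",
]

OUTCOMES = ("correct", "incorrect", "omission", "premature")


class UnidentifiableError(RuntimeError):
    """Raised when the session carries no information about the TVA parameters."""


@dataclass
class SessionSummary:
    per_duration: pd.DataFrame  # duration_s, C, I, O, accuracy_pct, omission_pct, mean_score, mean_correct_latency_s
    premature_by_condition: pd.Series
    n_trials: int
    n_premature: int


@dataclass
class TVAFit:
    t0: float      # s
    v: float       # Hz
    b: float       # s
    s_max: float   # asymptotic mean score
    rss: float
    model: str = "exponential-encoding"


def read_trials(path) -> pd.DataFrame:
    """Read a trial CSV (duration_s, outcome, latency_s, window, condition)."""
    df = pd.read_csv(path)
    return _validate_trials(df)


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def _validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    if "outcome" not in trials.columns or "duration_s" not in trials.columns:
        raise ValueError("trial table needs duration_s and outcome columns")
    bad = set(trials["outcome"]) - set(OUTCOMES)
    if bad:
        raise ValueError(f"unknown outcomes: {sorted(bad)}")
    responded = trials["outcome"].isin(["correct", "incorrect"])
    if "latency_s" in trials.columns:
        if trials.loc[responded, "latency_s"].isna().any():
            raise ValueError("responded trials must carry a latency")
    return trials


def score_session(trials: pd.DataFrame) -> SessionSummary:
    """Score a 5CSRTT session by stimulus duration.

    Premature trials (no stimulus shown) are tallied separately per
    distractor condition and excluded from all other denominators.
    """
    trials = _validate_trials(trials)
    if len(trials) == 0:
        raise ValueError("empty session")
    prem = trials[trials["outcome"] == "premature"]
    scored = trials[trials["outcome"] != "premature"]
    if len(scored) == 0:
        raise ValueError("no scoreable (non-premature) trials")

    rows = []
    for dur, grp in scored.groupby("duration_s"):
        c = int((grp["outcome"] == "correct").sum())
        i = int((grp["outcome"] == "incorrect").sum())
        o = int((grp["outcome"] == "omission").sum())
        total = c + i + o
        lat = (
            float(grp.loc[grp["outcome"] == "correct", "latency_s"].mean())
            if c and "latency_s" in grp.columns
            else float("nan")
        )
        rows.append(
            {
                "duration_s": dur,
                "C": c,
                "I": i,
                "O": o,
                "accuracy_pct": 100.0 * c / (c + i) if c + i else float("nan"),
                "omission_pct": 100.0 * o / total,
                "mean_score": c / total,
                "mean_correct_latency_s": lat,
            }
        )
    per_duration = pd.DataFrame(rows).sort_values("duration_s", ignore_index=True)
    if "condition" in prem.columns and len(prem):
        prem_counts = prem.groupby("condition").size()
    else:
        prem_counts = pd.Series(dtype=int)
    return SessionSummary(
        per_duration=per_duration,
        premature_by_condition=prem_counts,
        n_trials=len(trials),
        n_premature=len(prem),
    )


# ---------------------------------------------------------------------------
# TVA model
# ---------------------------------------------------------------------------

def mean_score_model(d, t0, v, s_max):
    d = np.asarray(d, dtype=float)
    w = d - t0
    out = np.where(w > 0, s_max * -np.expm1(-v * np.maximum(w, 0.0)), 0.0)
    return out


def latency_model(d, t0, v, b):
    d = np.asarray(d, dtype=float)
    w = np.maximum(d - t0, 0.0)
    vw = v * w
    small = vw < 1e-8
    denom = -np.expm1(-vw)
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = 1.0 / v - w * np.exp(-vw) / np.where(denom > 0, denom, 1.0)
    cond = np.where(small, w / 2.0, cond)
    return b + t0 + cond


def tva_fit(
    durations: np.ndarray,
    mean_scores: np.ndarray,
    latencies: np.ndarray,
    *,
    t0_starts=(0.0, 0.1, 0.3),
    v_starts=(0.5, 1.0, 2.0),
) -> TVAFit:
    """Joint least-squares TVA fit of mean score and correct latency curves.

    ``latencies`` may contain NaN for durations without correct responses;
    those points contribute only to the score curve.  Requires at least four
    distinct durations.  Raises :class:`UnidentifiableError` when all scores
    are zero (v and t0 carry no information).
    """
    d = np.asarray(durations, dtype=float)
    ms = np.asarray(mean_scores, dtype=float)
    lat = np.asarray(latencies, dtype=float)
    if np.unique(d).size < 4:
        raise ValueError("need at least 4 distinct stimulus durations")
    if np.all(ms <= 0):
        raise UnidentifiableError(
            "all mean scores are zero; v and t0 are unidentifiable"
        )
    has_lat = np.isfinite(lat)

    sd_ms = np.std(ms) or 1.0
    sd_lat = np.std(lat[has_lat]) if has_lat.sum() > 1 else 1.0
    sd_lat = sd_lat or 1.0

    def resid(p):
        t0, v, b, s_max = p
        r1 = (mean_score_model(d, t0, v, s_max) - ms) / sd_ms
        r2 = (latency_model(d[has_lat], t0, v, b) - lat[has_lat]) / sd_lat
        return np.concatenate([r1, r2])

    b0 = float(np.nanmean(lat[has_lat])) if has_lat.any() else 0.5
    lb = [0.0, 1e-3, 0.0, 1e-3]
    ub = [float(np.max(d)), 100.0, 10.0, 1.0]
    best = None
    for t0s in t0_starts:
        for vs in v_starts:
            p0 = np.clip([t0s, vs, max(b0 - t0s - 1.0 / vs, 0.05), min(max(ms.max(), 0.1), 1.0)], lb, ub)
            try:
                sol = optimize.least_squares(resid, p0, bounds=(lb, ub))
            except ValueError:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise RuntimeError("TVA fit did not converge from any start")
    t0, v, b, s_max = best.x
    return TVAFit(
        t0=float(t0), v=float(v), b=float(b), s_max=float(s_max),
        rss=float(2 * best.cost),
    )
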