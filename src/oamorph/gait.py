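"""Gait and hyperalgesia normalization.

Per session (one recording day) the three runs with the lowest run-speed
variation are kept. Gait metrics are reported as the within-day percent
asymmetry between injected and contralateral limbs, referenced to the
baseline session on day -7:

    d(t) = 100 * (I(t) - C(t)) / C(t)        value(t) = d(t) - d(b)

so the baseline maps to exactly 0 and negative values mean a deficit on the
injected limb (decreased weight bearing). A ratio-of-ratios variant is
available behind ``mode="ratio"``. Pressure-application (PAM) withdrawal
thresholds are expressed as percent of the day -7 baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SchemaError

__all__ = [
    "GaitSession",
    "NormalizedMetric",
    "select_runs",
    "session_metric",
    "normalize_gait",
    "normalize_pam",
    "deficit_trajectory",
    "duty_cycle_percent",
]

BASELINE_DAY = -7
_SIDES = {"left", "right"}


@dataclass
class GaitSession:
    """One gait recording day: per-run, per-paw metric rows.

    ``runs`` holds one row per (run, side) with columns ``run``, ``side``
    (left/right), ``run_speed_variation_percent`` and metric columns such as
    ``duty_cycle_percent``, ``swing_speed_mm_s``, ``stand_s``.
    """

    day: int
    injected_side: str
    runs: pd.DataFrame

    def __post_init__(self) -> None:
        if self.injected_side not in _SIDES:
            raise SchemaError(f"injected_side must be left/right, got {self.injected_side!r}")
        required = {"run", "side", "run_speed_variation_percent"}
        if not required.issubset(self.runs.columns):
            raise SchemaError(f"gait session needs columns {sorted(required)}")
        metrics = self.runs.drop(columns=["run", "side"]).select_dtypes("number")
        if not np.all(np.isfinite(metrics.to_numpy(float))):
            raise SchemaError("gait metrics must be finite")

    @property
    def contralateral_side(self) -> str:
        return "right" if self.injected_side == "left" else "left"

    @property
    def n_runs(self) -> int:
        return self.runs["run"].nunique()


@dataclass
class NormalizedMetric:
    day: int
    metric: str
    value_percent: float


def select_runs(session: GaitSession, n: int = 3) -> GaitSession:
    """Keep the n runs with the lowest run-speed variation.

    Ties are broken by recording order (first recorded kept); the selection
    is therefore independent of input row order except under exact ties.
    """
    per_run = (
        session.runs.groupby("run")["run_speed_variation_percent"].first().sort_index()
    )
    if per_run.size < n:
        raise SchemaError(f"session day {session.day}: {per_run.size} runs, need >= {n}")
    order = np.argsort(per_run.to_numpy(), kind="stable")  # stable: run order breaks ties
    keep = set(per_run.index.to_numpy()[order[:n]])
    filtered = session.runs[session.runs["run"].isin(keep)].reset_index(drop=True)
    return GaitSession(day=session.day, injected_side=session.injected_side, runs=filtered)


def session_metric(session: GaitSession, metric: str, side: str) -> float:
    """Mean of a per-paw metric over the session's runs for one side."""
    if metric not in session.runs.columns:
        raise SchemaError(f"metric {metric!r} not in gait table")
    sub = session.runs.loc[session.runs["side"] == side, metric]
    if sub.empty:
        raise SchemaError(f"no rows for side {side!r}")
    return float(sub.mean())


def normalize_gait(
    injected_t: float,
    contra_t: float,
    injected_b: float,
    contra_b: float,
    mode: str = "difference",
) -> float:
    """Baseline-referenced injected-vs-contralateral percent asymmetry."""
    if contra_t == 0 or contra_b == 0:
        raise ZeroDivisionError("contralateral metric is zero")
    if mode == "difference":
        d_t = 100.0 * (injected_t - contra_t) / contra_t
        d_b = 100.0 * (injected_b - contra_b) / contra_b
        return d_t - d_b
    if mode == "ratio":
        if injected_b == 0:
            raise ZeroDivisionError("baseline injected metric is zero")
        return 100.0 * ((injected_t / contra_t) / (injected_b / contra_b) - 1.0)
    raise ValueError(f"mode must be 'difference' or 'ratio', got {mode!r}")


def normalize_pam(peak_force_t: float, peak_force_baseline: float) -> float:
    """Withdrawal threshold as percent of the day -7 baseline."""
    if peak_force_baseline <= 0:
        raise ValueError(f"baseline peak force must be positive, got {peak_force_baseline}")
    return 100.0 * peak_force_t / peak_force_baseline


def deficit_trajectory(
    sessions: dict[int, GaitSession],
    metric: str,
    baseline_day: int = BASELINE_DAY,
    n_runs: int = 3,
    mode: str = "difference",
) -> pd.DataFrame:
    """Per-day normalized metric for one animal across sessions.

    Selects runs per session, averages the metric per side, and normalizes
    each day against the baseline day. Returns columns (day, metric,
    value_percent); the baseline row is exactly 0 by construction.
    """
    if baseline_day not in sessions:
        raise SchemaError(f"baseline day {baseline_day} missing from sessions")
    means = {}
    for day, sess in sessions.items():
        kept = select_runs(sess, n=n_runs)
        means[day] = (
            session_metric(kept, metric, kept.injected_side),
            session_metric(kept, metric, kept.contralateral_side),
        )
    ib, cb = means[baseline_day]
    rows = [
        {
            "day": day,
            "metric": metric,
            "value_percent": normalize_gait(it, ct, ib, cb, mode=mode),
        }
        for day, (it, ct) in sorted(means.items())
    ]
    return pd.DataFrame(rows)


def duty_cycle_percent(stand_s, swing_s):
    """Duty cycle: percent of the step cycle the paw bears weight."""
    stand = np.asarray(stand_s, dtype=float)
    swing = np.asarray(swing_s, dtype=float)
    total = stand + swing
    if np.any(total <= 0):
        raise ValueError("stand + swing must be positive")
    return 100.0 * stand / total
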