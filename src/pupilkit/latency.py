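"""Dilation-onset latency by 25/75% extrapolation, and movement latencies.

The dilation latency of a baseline-corrected mean trace is estimated by
finding the peak of the trace in a search window after cue onset (default
the first 3 s, the shortest trial length, which brackets the initial peak),
locating the first up-crossings of 25% and 75% of the peak before the peak
by linear interpolation, and extrapolating the straight line through those
two points down to zero.  The zero-intersection time is the latency.

If both crossings lie on a linear rising segment the estimate is exact
regardless of the peak value used, which is what makes the method robust to
modest peak misestimation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .epochs import ConditionAverage

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LatencyResult:
    latency: float          # s, NaN when failed
    peak_time: float
    peak_value: float
    t25: float
    t75: float
    status: str             # "estimated" | "failed"
    failure_reason: str = ""


def _first_upcrossing(t: np.ndarray, y: np.ndarray, level: float) -> float:
    """Time of the first below-to-at/above crossing of ``level``.

    Linear interpolation between adjacent finite samples; NaN if no
    crossing exists (including a trace that starts at/above the level).
    """
    finite = np.isfinite(y)
    idx = np.flatnonzero(finite)
    if len(idx) < 2:
        return np.nan
    if y[idx[0]] >= level:
        return np.nan
    for a, b in zip(idx[:-1], idx[1:]):
        if y[a] < level <= y[b]:
            frac = (level - y[a]) / (y[b] - y[a])
            return t[a] + frac * (t[b] - t[a])
    return np.nan


def estimate_dilation_latency(trace, config: PipelineConfig | None = None) -> LatencyResult:
    """Latency of pupil dilation from a baseline-corrected mean trace.

    ``trace`` is a :class:`ConditionAverage` or a ``(rel_time, values)``
    pair.  Fails (status "failed") when there is no apparent increase —
    peak not exceeding ``latency_peak_criterion_sd`` times the SD of the
    pre-cue segment — or when a required crossing cannot be located.
    """
    config = config or PipelineConfig()
    if isinstance(trace, ConditionAverage):
        t, y = trace.rel_time, trace.mean_trace
    else:
        t, y = np.asarray(trace[0], float), np.asarray(trace[1], float)

    lo, hi = config.latency_search_window
    win = (t >= lo) & (t <= hi)
    tw, yw = t[win], y[win]
    finite = np.isfinite(yw)

    def failed(reason):
        return LatencyResult(np.nan, np.nan, np.nan, np.nan, np.nan, "failed", reason)

    if not finite.any():
        return failed("search window fully missing")
    i_peak = int(np.nanargmax(yw))
    peak_value = float(yw[i_peak])
    peak_time = float(tw[i_peak])

    pre = y[(t < 0) & np.isfinite(y)]
    baseline_sd = float(np.std(pre)) if len(pre) else 0.0
    criterion = config.latency_peak_criterion_sd * baseline_sd
    if peak_value <= max(criterion, 0.0):
        return failed("no apparent increase")

    f_lo, f_hi = config.latency_fracs
    rising_t, rising_y = tw[: i_peak + 1], yw[: i_peak + 1]
    t_lo = _first_upcrossing(rising_t, rising_y, f_lo * peak_value)
    t_hi = _first_upcrossing(rising_t, rising_y, f_hi * peak_value)
    if not np.isfinite(t_lo) or not np.isfinite(t_hi):
        return failed("threshold crossing not found")
    if t_hi <= t_lo:
        return failed("degenerate crossing order")
    slope = (f_hi - f_lo) * peak_value / (t_hi - t_lo)
    latency = t_lo - f_lo * peak_value / slope
    return LatencyResult(float(latency), peak_time, peak_value,
                         float(t_lo), float(t_hi), "estimated")


def movement_latencies(events) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Button-press latency per trial: first press within the trial.

    Presses before a trial's onset are ignored (logged); trials without any
    press are flagged and excluded from the summary means.  Returns the
    per-trial table and a per-(session, drug) mean +/- SD summary.
    """
    trials = events.trials
    press_times = np.sort(np.asarray(events.presses["time"], float)) if len(events.presses) else np.array([])
    rows = []
    for row in trials.itertuples(index=False):
        offset = row.onset + row.duration
        in_trial = press_times[(press_times >= row.onset) & (press_times <= offset)]
        before = press_times[(press_times < row.onset) & (press_times > row.onset - 1.0)]
        if len(before):
            logger.debug("%d press(es) just before trial %s ignored", len(before), row.trial_id)
        latency = float(in_trial[0] - row.onset) if len(in_trial) else np.nan
        rows.append({"trial_id": row.trial_id, "session": row.session,
                     "drug": row.drug, "duration": row.duration,
                     "latency": latency, "has_press": bool(len(in_trial))})
    table = pd.DataFrame(rows)
    summary = (table[table["has_press"]]
               .groupby(["session", "drug"], as_index=False)["latency"]
               .agg(mean="mean", sd="std", n="count"))
    return table, summary
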