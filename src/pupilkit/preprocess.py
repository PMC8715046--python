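"""Signal conditioning: area-to-diameter conversion, smoothing, blink masking.

The measured quantity is pupil *area*; assuming a circular pupil the
diameter is ``sqrt(4 * area / pi)``.  The diameter trace is smoothed with a
20-ms centred moving average, then blinks are found as a rapid decrease
paired with a rapid increase within 500 ms and the surrounding samples
(40 ms before onset to 80 ms after offset) are set missing.  Missing data
are carried as a boolean mask; no value is ever interpolated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import ConfigError, PipelineConfig

logger = logging.getLogger(__name__)


class DataError(ValueError):
    """Raised when input data violate a stated precondition."""


@dataclass
class DiameterSeries:
    """Pupil diameter on the acquisition grid with a missing-data mask."""

    time: np.ndarray        # s, strictly increasing
    diameter: np.ndarray    # mm (or scaled device units)
    missing: np.ndarray     # True where masked or tracker-invalid
    participant_id: str = ""
    eye: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.diameter = np.asarray(self.diameter, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if not (len(self.time) == len(self.diameter) == len(self.missing)):
            raise DataError("time/diameter/missing lengths differ")

    def copy(self) -> "DiameterSeries":
        return DiameterSeries(self.time.copy(), self.diameter.copy(),
                              self.missing.copy(), self.participant_id, self.eye)


@dataclass(frozen=True)
class BlinkInterval:
    """One detected blink with its padded mask window (all in seconds)."""

    onset: float        # start of the rapid decrease
    offset: float       # end of the rapid increase
    mask_start: float   # onset - pad_pre
    mask_end: float     # offset + pad_post
    paired: bool = True  # False for an unclosed decrease masked precautionarily

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def area_to_diameter(area, missing=None):
    """Convert pupil area to diameter via ``sqrt(area * 4 / pi)``.

    Missing entries propagate as NaN; a negative area at a *valid* sample is
    a data error (negative areas under the mask are tolerated and ignored).
    """
    area = np.asarray(area, dtype=float)
    valid = np.ones(area.shape, dtype=bool) if missing is None else ~np.asarray(missing, bool)
    if np.any(area[valid] < 0):
        idx = int(np.argmax((area < 0) & valid))
        raise DataError(f"negative pupil area at index {idx}")
    diameter = np.full(area.shape, np.nan)
    diameter[valid] = np.sqrt(area[valid] * 4.0 / np.pi)
    return diameter if diameter.ndim else float(diameter)


def diameter_to_area(diameter):
    """Inverse map: ``area = pi * d^2 / 4`` (used by the simulator)."""
    diameter = np.asarray(diameter, dtype=float)
    area = np.pi * diameter ** 2 / 4.0
    return area if area.ndim else float(area)


def moving_average(values: np.ndarray, missing: np.ndarray, n: int):
    """Centred ``n``-sample mean over non-missing values.

    At the boundaries the window shrinks to the available samples; output is
    missing only where every sample in the window is missing.
    """
    filled = np.where(missing, 0.0, values)
    kernel = np.ones(n)
    total = np.convolve(filled, kernel, mode="same")
    count = np.convolve((~missing).astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore"):
        out = total / count
    out[count == 0] = np.nan
    return out, count == 0


def smooth_moving_average(series: DiameterSeries, window: float = 0.020,
                          fs: float | None = None) -> DiameterSeries:
    """Smooth with a centred moving average of ``window`` seconds.

    At 250 Hz the default 20-ms window spans 5 samples.
    """
    if fs is None:
        steps = np.diff(series.time)
        fs = 1.0 / float(np.median(steps)) if len(steps) else 0.0
    n = int(round(window * fs))
    if n < 1:
        raise ConfigError(f"smoothing window {window} s is shorter than one sample at {fs} Hz")
    smoothed, all_missing = moving_average(series.diameter, series.missing, n)
    return DiameterSeries(series.time, smoothed, series.missing | all_missing,
                          series.participant_id, series.eye)


def _runs(mask: np.ndarray):
    """Start/stop index pairs (half-open) of True runs in a boolean array."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def detect_and_mask_blinks(series: DiameterSeries, config: PipelineConfig):
    """Find blink artifacts and set the surrounding samples missing.

    A blink is a rapid decrease in the smoothed diameter paired with the
    first rapid increase completing within ``blink_pair_window`` (500 ms).
    "Rapid" means the sample-to-sample velocity exceeds ``blink_velocity_k``
    robust standard deviations (median absolute deviation x 1.4826) of the
    velocity over the whole recording.  Each blink masks
    ``[onset - blink_pad_pre, offset + blink_pad_post]``; an unclosed
    decrease is masked for a full pairing window as a precaution.
    Tracker-invalid samples stay missing.  Returns the masked series and the
    merged, time-sorted list of :class:`BlinkInterval`.
    """
    out = series.copy()
    t = out.time
    v = np.diff(out.diameter)
    finite = np.isfinite(v)
    if finite.sum() < 2:
        return out, []
    med = np.median(v[finite])
    mad = np.median(np.abs(v[finite] - med))
    sigma = 1.4826 * mad
    if sigma == 0:
        # noiseless recording: any nonzero velocity step is suspicious only
        # if large in absolute terms; fall back to zero detections unless
        # there are true discontinuities
        sigma = np.finfo(float).eps
    thr = config.blink_velocity_k * sigma
    dec = finite & (v < med - thr)
    inc = finite & (v > med + thr)

    dec_runs = _runs(dec)
    inc_runs = _runs(inc)
    intervals: list[BlinkInterval] = []
    j = 0
    used_until = -1
    for d0, d1 in dec_runs:
        if d0 <= used_until:
            continue  # inside a previously closed blink
        onset = t[d0]
        # velocity sample i spans t[i]..t[i+1]; the increase run (i0, i1)
        # ends at sample index i1 (time t[i1])
        while j < len(inc_runs) and inc_runs[j][1] <= d0:
            j += 1
        k = j
        close = None
        while k < len(inc_runs):
            i0, i1 = inc_runs[k]
            if t[i0] > onset + config.blink_pair_window:
                break
            if i0 >= d1 - 1:  # increase begins at/after the decrease ends
                close = (i0, i1)
                break
            k += 1
        if close is not None:
            offset = min(t[close[1]], onset + config.blink_pair_window)
            intervals.append(BlinkInterval(
                onset=onset, offset=offset,
                mask_start=onset - config.blink_pad_pre,
                mask_end=offset + config.blink_pad_post, paired=True))
            used_until = close[1]
        else:
            logger.debug("unpaired rapid decrease at t=%.3f s; masking %g s",
                         onset, config.blink_pair_window)
            offset = onset + config.blink_pair_window
            intervals.append(BlinkInterval(
                onset=onset, offset=offset,
                mask_start=onset - config.blink_pad_pre,
                mask_end=offset + config.blink_pad_post, paired=False))

    # merge overlapping padded windows
    merged: list[BlinkInterval] = []
    for iv in sorted(intervals, key=lambda iv: iv.mask_start):
        if merged and iv.mask_start <= merged[-1].mask_end:
            prev = merged[-1]
            merged[-1] = BlinkInterval(
                onset=prev.onset, offset=max(prev.offset, iv.offset),
                mask_start=prev.mask_start,
                mask_end=max(prev.mask_end, iv.mask_end),
                paired=prev.paired and iv.paired)
        else:
            merged.append(iv)

    for iv in merged:
        out.missing |= (t >= iv.mask_start) & (t <= iv.mask_end)
    return out, merged


def preprocess_samples(samples, config: PipelineConfig):
    """Full conditioning chain for one eye: convert, smooth, mask blinks.

    ``samples`` is a :class:`pupilkit.io.SampleSeries`.  Returns the masked
    :class:`DiameterSeries` and the blink intervals.
    """
    diameter = area_to_diameter(samples.area, missing=~samples.valid)
    series = DiameterSeries(samples.time, diameter, ~samples.valid,
                            samples.participant_id, samples.eye)
    series = smooth_moving_average(series, config.smooth_window, config.fs)
    return detect_and_mask_blinks(series, config)
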