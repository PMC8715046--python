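"""Reading and writing tracker exports and event tables.

Sample files are plain-text CSV/TSV with a one-line header and columns
``time, eye, area, valid`` — one block per eye, one file per participant
per session.  Event files carry one row per trial (``trial_id, onset,
duration, session, eye_treatment, drug``); button presses live in an
optional sidecar table (``time, button``).  Proprietary binary tracker
formats are out of scope; convert to text first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .preprocess import DataError

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when a file is structurally malformed (e.g. missing column)."""


@dataclass
class SampleSeries:
    """Raw per-eye pupil-area samples on a fixed-rate grid."""

    participant_id: str
    eye: str                  # "treated" | "control"
    time: np.ndarray          # s, strictly increasing
    area: np.ndarray          # mm^2 after area_unit_scale
    valid: np.ndarray         # tracker-reported validity

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        self.area = np.asarray(self.area, float)
        self.valid = np.asarray(self.valid, bool)
        if not (len(self.time) == len(self.area) == len(self.valid)):
            raise DataError("time/area/valid lengths differ")

    def check(self, fs: float | None = None):
        steps = np.diff(self.time)
        if np.any(steps <= 0):
            idx = int(np.argmax(steps <= 0)) + 1
            raise DataError(f"time not strictly increasing at index {idx}")
        if fs is not None and len(steps):
            nominal = 1.0 / fs
            if abs(np.median(steps) - nominal) > 0.01 * nominal:
                raise DataError(
                    f"median sample step {np.median(steps):.6g} s deviates >1% "
                    f"from nominal {nominal:.6g} s")
        if np.any(self.area[self.valid] < 0):
            idx = int(np.argmax((self.area < 0) & self.valid))
            raise DataError(f"negative area at valid sample index {idx}")
        return self


@dataclass
class EventLog:
    """Trial onsets/offsets with condition labels, plus button presses."""

    trials: pd.DataFrame      # trial_id, onset, duration, session, eye_treatment, drug, offset, nonstandard
    presses: pd.DataFrame     # time, button


def _read_table(path) -> pd.DataFrame:
    head = Path(path).open().readline()
    sep = "\t" if "\t" in head else ","
    return pd.read_csv(path, sep=sep)


def read_samples(path, config: PipelineConfig | None = None,
                 participant_id: str | None = None) -> dict[str, SampleSeries]:
    """Parse a sample file into one :class:`SampleSeries` per eye.

    Areas are multiplied by ``config.area_unit_scale``; tracker-invalid
    samples are flagged in ``valid``, never dropped.
    """
    config = config or PipelineConfig()
    path = Path(path)
    table = _read_table(path)
    for col in ("time", "eye", "area", "valid"):
        if col not in table.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    pid = participant_id or path.stem.split("_")[0]
    out = {}
    for eye, block in table.groupby("eye", sort=False):
        series = SampleSeries(
            participant_id=pid, eye=str(eye),
            time=block["time"].to_numpy(float),
            area=block["area"].to_numpy(float) * config.area_unit_scale,
            valid=block["valid"].to_numpy().astype(bool),
        )
        out[str(eye)] = series.check(fs=config.fs)
    return out


def write_samples(path, series_by_eye: dict[str, SampleSeries],
                  config: PipelineConfig | None = None) -> None:
    """Write per-eye sample blocks back to the on-disk dialect.

    Inverse of :func:`read_samples` (areas divided by ``area_unit_scale``),
    so a read/write round trip preserves the numeric content.
    """
    config = config or PipelineConfig()
    frames = []
    for eye, s in series_by_eye.items():
        frames.append(pd.DataFrame({
            "time": s.time, "eye": eye,
            "area": s.area / config.area_unit_scale,
            "valid": s.valid.astype(int),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.9g")


def read_events(path, presses_path=None,
                config: PipelineConfig | None = None) -> EventLog:
    """Parse an event table (and optional press table) into an EventLog.

    Trials come back sorted by onset; overlapping trials are a data error;
    a duration outside the configured set is kept but flagged
    ``nonstandard`` with a warning; inter-trial gaps outside the configured
    ITI bounds are warned about.
    """
    config = config or PipelineConfig()
    path = Path(path)
    trials = _read_table(path)
    for col in ("trial_id", "onset", "duration", "session", "eye_treatment", "drug"):
        if col not in trials.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    trials = trials.sort_values("onset", kind="stable").reset_index(drop=True)
    trials["onset"] = trials["onset"].astype(float)
    trials["duration"] = trials["duration"].astype(float)
    trials["offset"] = trials["onset"] + trials["duration"]
    overlap = trials["onset"].to_numpy()[1:] < trials["offset"].to_numpy()[:-1]
    if overlap.any():
        i = int(np.argmax(overlap))
        raise DataError(f"{path}: trials {trials['trial_id'][i]} and "
                        f"{trials['trial_id'][i + 1]} overlap")
    gaps = trials["onset"].to_numpy()[1:] - trials["offset"].to_numpy()[:-1]
    lo, hi = config.iti_bounds
    bad_gap = (gaps < lo) | (gaps > hi)
    if bad_gap.any():
        logger.warning("%s: %d inter-trial gap(s) outside [%g, %g] s",
                       path, int(bad_gap.sum()), lo, hi)
    nonstd = ~trials["duration"].isin(config.durations)
    if nonstd.any():
        logger.warning("%s: %d trial(s) with nonstandard duration retained (flagged)",
                       path, int(nonstd.sum()))
    trials["nonstandard"] = nonstd
    if presses_path is not None and Path(presses_path).exists():
        presses = _read_table(presses_path)
        for col in ("time", "button"):
            if col not in presses.columns:
                raise FormatError(f"{presses_path}: missing required column {col!r}")
        presses = presses.sort_values("time", kind="stable").reset_index(drop=True)
    else:
        presses = pd.DataFrame(columns=["time", "button"])
    return EventLog(trials=trials, presses=presses)
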