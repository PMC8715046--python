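"""Synthetic pupil recordings with the statistical structure of the study.

The generator emulates a two-eye pharmacological pupillometry experiment:
each participant performs sessions of 30 trials (10 each of 3/6/9 s, random
order, inter-trial interval uniform on 5-8 s) while pupil area is sampled
at 250 Hz from both eyes.  The evoked dilation has two additive components:

* a *fast* component — a linear ramp beginning ``fast_latency`` (0.6 s)
  after cue onset and peaking ``fast_rise`` (0.88 s) later, i.e. an initial
  peak 1.48 s post-cue, relaxing exponentially toward a plateau fraction;
* a *slow* sustained component — a saturating-exponential rise starting at
  the fast peak and held until cue offset, then decaying.

Drug presets modify the treated eye only: a tropicamide-like preset
attenuates and delays the fast component (sphincter block) and raises the
baseline; a phenylephrine-like preset removes the sustained component
(dilator saturation) and raises the baseline; the control preset leaves
both eyes statistically identical.  Hippus (~0.2 Hz), full-occlusion blink
collapses, Gaussian area noise, and truncated-normal button-press reaction
times (mean 0.56 s, SD 0.09 s) complete the trace.  Everything drawn is
recorded in a ground-truth manifest so recovery tests never re-simulate.

The default parameter table is shipped as a versioned fixture file
(``data/default_params.cfg``); a unit test pins the dataclass defaults to
it.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .config import _parse_value
from .io import EventLog, SampleSeries
from .preprocess import diameter_to_area

logger = logging.getLogger(__name__)

DEFAULT_PARAMS_FILE = "default_params.cfg"


@dataclass(frozen=True)
class SimParams:
    """Simulator parameters; defaults mirror ``data/default_params.cfg``."""

    n_participants: int = 14
    fs: float = 250.0
    sessions: int = 3
    trials_per_duration: int = 10
    durations: tuple[float, ...] = (3.0, 6.0, 9.0)
    iti_bounds: tuple[float, float] = (5.0, 8.0)
    lead_in: float = 5.0               # s of recording before the first trial
    lead_out: float = 4.0              # s after the last offset
    baseline_diameter: float = 4.7     # mm, untreated eye population mean
    baseline_sd: float = 0.5           # mm, between-participant SD
    fast_amplitude: float = 0.6        # mm
    fast_latency: float = 0.6          # s post-cue
    fast_rise: float = 0.88            # s from onset to initial peak (peak at 1.48)
    fast_plateau_frac: float = 0.6
    fast_decay_tau: float = 0.8        # s, post-peak relaxation
    slow_amplitude: float = 0.25       # mm
    slow_latency: float = 1.48         # s post-cue
    slow_tau: float = 1.5              # s, saturating rise
    offset_tau: float = 1.0            # s, return to baseline after cue offset
    amplitude_cv: float = 0.2          # between-participant amplitude CV
    latency_sd: float = 0.08           # s, between-participant latency SD
    blink_rate: float = 0.15           # events/s
    blink_duration: tuple[float, float] = (0.10, 0.25)  # s, uniform
    blink_edge: float = 0.008          # s, lid sweep (sharp edge)
    blink_collapse: float = 0.02       # residual area fraction when occluded
    hippus_amplitude: float = 0.05     # mm
    hippus_freq: float = 0.2           # Hz
    noise_sd_area: float = 0.3         # mm^2, additive Gaussian on area
    rt_mean: float = 0.56              # s
    rt_sd: float = 0.09                # s (truncated at 0)
    press_interval: float = 0.3        # s between repeated presses
    rng_seed: int = 0

    def replace(self, **changes) -> "SimParams":
        return dataclasses.replace(self, **changes)

    @classmethod
    def from_file(cls, path=None) -> "SimParams":
        if path is None:
            text = resources.files("pupilkit").joinpath(
                "data", DEFAULT_PARAMS_FILE).read_text()
        else:
            text = Path(path).read_text()
        values = {}
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, raw = line.split(":", 1)
            values[key.strip()] = _parse_value(raw)
        return cls(**values)


#: Treated-eye modifications per drug condition.  ``fast_scale``/``slow_scale``
#: multiply the component amplitudes, ``fast_delay`` shifts the fast onset,
#: ``baseline`` replaces the treated-eye resting diameter (mydriasis).
PRESETS: dict[str, dict] = {
    "control":       {"fast_scale": 1.0, "fast_delay": 0.0, "slow_scale": 1.0,
                      "baseline": None},
    "tropicamide":   {"fast_scale": 0.5, "fast_delay": 0.35, "slow_scale": 0.6,
                      "baseline": 7.0},
    "phenylephrine": {"fast_scale": 1.0, "fast_delay": 0.0, "slow_scale": 0.0,
                      "baseline": 6.4},
}


@dataclass
class EyeComponents:
    baseline: float
    a_fast: float
    l_fast: float
    rise: float
    plateau_frac: float
    decay_tau: float
    a_slow: float
    l_slow: float
    slow_tau: float
    offset_tau: float


@dataclass
class Recording:
    """One participant-session: both eyes' samples, events, and ground truth."""

    participant_id: str
    session: str
    drug: str
    samples: dict[str, SampleSeries]     # eye -> series
    events: EventLog
    truth: dict                          # see simulate_recording


def draw_participant(params: SimParams, rng) -> EyeComponents:
    """Population draw of one participant's untreated-eye response."""
    amp_mult = float(np.exp(rng.normal(0.0, params.amplitude_cv)))
    return EyeComponents(
        baseline=float(np.clip(rng.normal(params.baseline_diameter,
                                          params.baseline_sd), 2.5, 8.5)),
        a_fast=params.fast_amplitude * amp_mult,
        l_fast=float(np.clip(rng.normal(params.fast_latency, params.latency_sd),
                             0.25, 1.2)),
        rise=params.fast_rise,
        plateau_frac=params.fast_plateau_frac,
        decay_tau=params.fast_decay_tau,
        a_slow=params.slow_amplitude * amp_mult,
        l_slow=params.slow_latency,
        slow_tau=params.slow_tau,
        offset_tau=params.offset_tau,
    )


def apply_preset(base: EyeComponents, preset: str, rng,
                 baseline_sd: float = 0.4) -> EyeComponents:
    """Treated-eye components under a drug preset (control = unchanged)."""
    p = PRESETS[preset] if isinstance(preset, str) else dict(preset)
    comp = dataclasses.replace(base)
    comp.a_fast = base.a_fast * p["fast_scale"]
    comp.l_fast = base.l_fast + p["fast_delay"]
    comp.a_slow = base.a_slow * p["slow_scale"]
    if p["baseline"] is not None:
        comp.baseline = float(np.clip(rng.normal(p["baseline"], baseline_sd),
                                      4.5, 9.0))
    return comp


def evoked_diameter(t_rel: np.ndarray, duration: float,
                    comp: EyeComponents) -> np.ndarray:
    """Evoked dilation (mm above baseline) at times ``t_rel`` post-cue."""
    s = np.asarray(t_rel, float)
    out = np.zeros_like(s)
    peak_t = comp.l_fast + comp.rise
    plateau = comp.a_fast * comp.plateau_frac

    ramp = (s >= comp.l_fast) & (s < min(peak_t, duration))
    out[ramp] += comp.a_fast * (s[ramp] - comp.l_fast) / comp.rise
    if duration > peak_t:
        relax = (s >= peak_t) & (s < duration)
        out[relax] += plateau + (comp.a_fast - plateau) * np.exp(
            -(s[relax] - peak_t) / comp.decay_tau)
        fast_off = plateau + (comp.a_fast - plateau) * np.exp(
            -(duration - peak_t) / comp.decay_tau)
    else:
        fast_off = comp.a_fast * max(duration - comp.l_fast, 0.0) / comp.rise

    slow_rise = (s >= comp.l_slow) & (s < duration)
    out[slow_rise] += comp.a_slow * (1.0 - np.exp(
        -(s[slow_rise] - comp.l_slow) / comp.slow_tau))
    slow_off = comp.a_slow * (1.0 - np.exp(-max(duration - comp.l_slow, 0.0)
                                           / comp.slow_tau))
    post = s >= duration
    out[post] += (fast_off + slow_off) * np.exp(-(s[post] - duration)
                                                / comp.offset_tau)
    return out


def _draw_schedule(params: SimParams, rng):
    """Trial order, onsets and durations for one session (onsets from t=0)."""
    durations = np.repeat(params.durations, params.trials_per_duration)
    rng.shuffle(durations)
    onsets = np.empty(len(durations))
    t = params.lead_in
    for i, dur in enumerate(durations):
        onsets[i] = t
        t += dur + rng.uniform(*params.iti_bounds)
    total = onsets[-1] + durations[-1] + params.lead_out
    return onsets, durations, total


def _draw_blinks(params: SimParams, total: float, rng):
    n = rng.poisson(params.blink_rate * total)
    starts = np.sort(rng.uniform(0.5, total - 0.5, size=n))
    durs = rng.uniform(*params.blink_duration, size=n)
    blinks = []
    last_end = -np.inf
    for s, d in zip(starts, durs):
        if s < last_end + 0.5:     # keep blinks separable
            continue
        blinks.append((float(s), float(s + d)))
        last_end = s + d
    return blinks


def simulate_trace(params: SimParams, comp: EyeComponents,
                   onsets, durations, total: float, rng,
                   blinks=None):
    """One eye's area trace over a session plus its ground-truth record.

    The diameter is baseline + evoked + hippus; it is emitted as *area*
    (inverse of the circular-pupil conversion) with blink collapses and
    additive Gaussian sensor noise, so the pipeline's own conversion and
    masking are exercised end to end.
    """
    n = int(round(total * params.fs))
    t = np.arange(n) / params.fs
    diameter = np.full(n, comp.baseline)
    for onset, dur in zip(onsets, durations):
        i0 = int(np.searchsorted(t, onset))
        i1 = min(n, int(np.searchsorted(t, onset + dur + 6.0 * comp.offset_tau)))
        diameter[i0:i1] += evoked_diameter(t[i0:i1] - onset, float(dur), comp)
    if params.hippus_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        freq = params.hippus_freq * rng.uniform(0.9, 1.1)
        diameter = diameter + params.hippus_amplitude * np.sin(
            2 * np.pi * freq * t + phase)

    area = diameter_to_area(diameter)
    if blinks is None:
        blinks = _draw_blinks(params, total, rng)
    factor = np.ones(n)
    for b0, b1 in blinks:
        edge = params.blink_edge
        core = (t >= b0 + edge) & (t <= b1 - edge)
        factor[core] = params.blink_collapse
        down = (t >= b0) & (t < b0 + edge)
        factor[down] = 1.0 + (params.blink_collapse - 1.0) * (t[down] - b0) / edge
        up = (t > b1 - edge) & (t <= b1)
        factor[up] = params.blink_collapse + (1.0 - params.blink_collapse) * (
            1.0 - (b1 - t[up]) / edge)
    area = area * factor
    if params.noise_sd_area > 0:
        area = area + rng.normal(0.0, params.noise_sd_area, size=n)
    area = np.clip(area, 0.0, None)
    truth = {"blinks": blinks, "components": dataclasses.asdict(comp)}
    return t, area, truth


def simulate_recording(params: SimParams, participant_id: str, session: str,
                       drug: str, base: EyeComponents, rng) -> Recording:
    """Both eyes of one session under one drug condition."""
    onsets, durations, total = _draw_schedule(params, rng)
    treated = apply_preset(base, drug, rng)
    samples, truth = {}, {"onsets": onsets.tolist(),
                          "durations": durations.tolist(), "eyes": {}}
    for eye, comp in (("treated", treated), ("control", base)):
        t, area, eye_truth = simulate_trace(params, comp, onsets, durations,
                                            total, rng)
        samples[eye] = SampleSeries(participant_id, eye, t, area,
                                    np.ones(len(t), bool))
        truth["eyes"][eye] = eye_truth

    rts = np.maximum(rng.normal(params.rt_mean, params.rt_sd,
                                size=len(onsets)), 0.0)
    press_rows = []
    for onset, dur, rt in zip(onsets, durations, rts):
        pt = onset + rt
        while pt <= onset + dur:
            press_rows.append({"time": float(pt), "button": "any"})
            pt += params.press_interval * rng.uniform(0.8, 1.2)
    presses = pd.DataFrame(press_rows, columns=["time", "button"])
    truth["reaction_times"] = rts.tolist()

    trials = pd.DataFrame({
        "trial_id": [f"{session}_t{i:02d}" for i in range(len(onsets))],
        "onset": onsets, "duration": durations, "session": session,
        "eye_treatment": "nondominant", "drug": drug,
    })
    trials["offset"] = trials["onset"] + trials["duration"]
    trials["nonstandard"] = ~trials["duration"].isin(params.durations)
    return Recording(participant_id, session, drug, samples,
                     EventLog(trials, presses), truth)


def simulate_participant(params: SimParams, index: int, drug: str,
                         seed: int | None = None) -> list[Recording]:
    """All sessions for one participant; deterministic in (seed, index, drug)."""
    seed = params.rng_seed if seed is None else seed
    drug_code = zlib.crc32(drug.encode()) % (2 ** 31)
    rng = np.random.default_rng([seed, index, drug_code])
    base = draw_participant(params, rng)
    pid = f"p{index:02d}"
    return [simulate_recording(params, pid, f"s{s + 1}", drug, base, rng)
            for s in range(params.sessions)]


def simulate_dataset(params: SimParams, out_dir, drug: str = "control",
                     seed: int | None = None) -> dict:
    """Write a complete pipeline-ingestible dataset plus ground-truth manifest.

    One sample/event/press CSV triple per participant per session, and a
    flat ``manifest.txt`` recording every drawn value.  Identical seeds
    yield identical files.
    """
    from .io import write_samples  # local import keeps module load light

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_lines = [f"seed: {params.rng_seed if seed is None else seed}",
                      f"drug: {drug}",
                      f"n_participants: {params.n_participants}"]
    index = {"samples": [], "events": [], "presses": []}
    for i in range(params.n_participants):
        for rec in simulate_participant(params, i, drug, seed=seed):
            stem = f"{rec.participant_id}_{rec.session}"
            spath = out_dir / f"{stem}_samples.csv"
            epath = out_dir / f"{stem}_events.csv"
            ppath = out_dir / f"{stem}_presses.csv"
            write_samples(spath, rec.samples)
            rec.events.trials.drop(columns=["offset", "nonstandard"]).to_csv(
                epath, index=False, float_format="%.9g")
            rec.events.presses.to_csv(ppath, index=False, float_format="%.9g")
            index["samples"].append(spath)
            index["events"].append(epath)
            index["presses"].append(ppath)
            for eye, eye_truth in rec.truth["eyes"].items():
                key = f"{rec.participant_id}.{rec.session}.{eye}"
                for name, value in eye_truth["components"].items():
                    manifest_lines.append(f"{key}.{name}: {value!r}")
                for j, (b0, b1) in enumerate(eye_truth["blinks"]):
                    manifest_lines.append(f"{key}.blink_{j:03d}: ({b0!r}, {b1!r})")
            key = f"{rec.participant_id}.{rec.session}"
            manifest_lines.append(
                f"{key}.reaction_times: {[round(v, 6) for v in rec.truth['reaction_times']]}")
    (out_dir / "manifest.txt").write_text("\n".join(manifest_lines) + "\n")
    index["manifest"] = out_dir / "manifest.txt"
    return index


def read_manifest(path) -> dict:
    """Parse a ground-truth manifest back into a flat key -> value dict."""
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        key, raw = line.split(":", 1)
        out[key.strip()] = _parse_value(raw)
    return out
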