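"""End-to-end orchestration: preprocess -> epochs -> latency -> statistics.

``analyze`` runs the full analysis on in-memory units (one unit = one
participant-session: per-eye samples plus an event log); ``run_pipeline``
is the file-based wrapper that reads the on-disk dialect, runs ``analyze``
and writes the five result tables with a provenance sidecar.  Both are pure
functions of (inputs, config): repeated runs give identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .epochs import condition_average, extract_baseline_corrected_epochs
from .io import EventLog, read_events, read_samples
from .latency import estimate_dilation_latency, movement_latencies
from .preprocess import preprocess_samples
from .stats import (DesignError, oneway_anova, phase_means, rm_anova,
                    ryan_posthoc, simple_main_effects)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, participant: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for participant "
                         f"{participant!r}: {cause}")
        self.stage = stage
        self.participant = participant
        self.cause = cause


@dataclass
class ResultBundle:
    condition_means: pd.DataFrame   # participant, eye, drug, duration, rel_time, mean, n_trials
    latencies: pd.DataFrame         # participant, eye, drug, latency, peak_*, status
    movement: pd.DataFrame          # per-trial button-press latencies
    phase_summary: pd.DataFrame     # participant, eye, drug, duration, early, late
    anova_tables: pd.DataFrame
    posthoc: pd.DataFrame
    anova_results: dict = field(default_factory=dict)  # drug -> AnovaResult

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "condition_means": self.condition_means,
            "latencies": self.latencies,
            "movement": self.movement,
            "phase_summary": self.phase_summary,
            "anova": self.anova_tables,
            "posthoc": self.posthoc,
        }


def _stage(stage: str, participant: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(stage, participant, exc) from exc
            return False
    return _Ctx()


def analyze(config: PipelineConfig, units) -> ResultBundle:
    """Run the full analysis.

    ``units`` is an iterable of ``(participant_id, samples_by_eye,
    event_log)`` triples (one per participant-session); samples_by_eye maps
    "treated"/"control" to :class:`pupilkit.io.SampleSeries`.
    """
    epochs_by_participant: dict[str, list] = {}
    movement_rows = []
    for pid, samples_by_eye, events in units:
        with _stage("preprocess", pid):
            masked = {eye: preprocess_samples(s, config)[0]
                      for eye, s in samples_by_eye.items()}
        with _stage("epoching", pid):
            for eye, series in masked.items():
                eps = extract_baseline_corrected_epochs(series, events, config)
                epochs_by_participant.setdefault(pid, []).extend(eps)
        with _stage("movement-latency", pid):
            table, _ = movement_latencies(events)
            table.insert(0, "participant", pid)
            movement_rows.append(table)
    if not epochs_by_participant:
        raise PipelineError("epoching", "-", ValueError("no trials"))

    mean_rows, latency_rows, phase_rows = [], [], []
    for pid, epochs in sorted(epochs_by_participant.items()):
        with _stage("averaging", pid):
            per_dur = condition_average(
                epochs, group_by=("participant", "eye", "drug", "duration"),
                fs=config.fs)
            pooled = condition_average(
                epochs, group_by=("participant", "eye", "drug"), fs=config.fs)
        for avg in per_dur:
            mean_rows.append(pd.DataFrame({
                "participant": pid, "eye": avg.meta["eye"],
                "drug": avg.meta["drug"], "duration": avg.meta["duration"],
                "rel_time": avg.rel_time, "mean": avg.mean_trace,
                "n_trials": avg.n_trials}))
            with _stage("phase-summary", pid):
                phase_rows.append(phase_means(avg, config))
        with _stage("latency", pid):
            for avg in pooled:
                res = estimate_dilation_latency(avg, config)
                latency_rows.append({
                    "participant": pid, "eye": avg.meta["eye"],
                    "drug": avg.meta["drug"], "latency": res.latency,
                    "peak_time": res.peak_time, "peak_value": res.peak_value,
                    "t25": res.t25, "t75": res.t75, "status": res.status,
                    "failure_reason": res.failure_reason})

    condition_means = pd.concat(mean_rows, ignore_index=True)
    latencies = pd.DataFrame(latency_rows)
    movement = (pd.concat(movement_rows, ignore_index=True)
                if movement_rows else pd.DataFrame())
    phase_summary = pd.DataFrame(phase_rows)[
        ["participant", "eye", "drug", "duration", "early", "late"]]

    anova_frames, posthoc_rows, anova_results = [], [], {}
    for drug in sorted(phase_summary["drug"].unique()):
        sub = phase_summary[phase_summary["drug"] == drug]
        long = sub.melt(id_vars=["participant", "eye", "duration"],
                        value_vars=["early", "late"], var_name="phase",
                        value_name="dilation").dropna(subset=["dilation"])
        try:
            res = rm_anova(long, dv="dilation",
                           within=["phase", "eye", "duration"],
                           subject="participant")
        except DesignError as err:
            logger.warning("rm-ANOVA skipped for drug %s: %s", drug, err)
            continue
        anova_results[drug] = res
        frame = res.to_frame()
        frame.insert(0, "family", f"phase_anova[{drug}]")
        anova_frames.append(frame)
        # instillation (eye) within each phase, pooled error (F_{1,26} pattern)
        for eff in simple_main_effects(res, "eye", at={"phase": None}):
            posthoc_rows.append({
                "family": f"simple_effect[{drug}]",
                "pair": f"treated-vs-control @ phase={eff.at['phase']}",
                "statistic": eff.f, "df": f"({eff.df_num}, {eff.df_den})",
                "p": eff.p, "span": "", "nominal_level": config.alpha,
                "significant": eff.p < config.alpha})
        # durations within the late phase, pooled duration error (t_52 pattern)
        late = long[long["phase"] == "late"]
        dur_means = late.groupby("duration")["dilation"].mean()
        err_ss = res.error("subj x duration").ss + res.error("subj x phase x duration").ss
        err_df = res.error("subj x duration").df + res.error("subj x phase x duration").df
        n_per_mean = res.n_participants * len(res.levels["eye"])
        try:
            comps = ryan_posthoc(list(dur_means.index), dur_means.to_numpy(),
                                 [n_per_mean] * len(dur_means),
                                 err_ss / err_df, err_df, config.alpha)
        except DesignError:
            comps = []
        for c in comps:
            posthoc_rows.append({
                "family": f"late_phase_duration[{drug}]",
                "pair": f"{c.pair[0]}-vs-{c.pair[1]}", "statistic": c.statistic,
                "df": c.df, "p": c.p, "span": c.span,
                "nominal_level": c.nominal_level, "significant": c.significant})

    # latency comparison across treatments: control eyes pooled per participant
    est = latencies[latencies["status"] == "estimated"].copy()
    est["group"] = np.where((est["eye"] == "treated") & (est["drug"] != "control"),
                            est["drug"], "control")
    per_part = est.groupby(["participant", "group"], as_index=False)["latency"].mean()
    groups = {g: d["latency"].to_numpy() for g, d in per_part.groupby("group")}
    if len(groups) >= 2 and sum(len(g) for g in groups.values()) > len(groups):
        labels = sorted(groups)
        ow = oneway_anova([groups[g] for g in labels])
        anova_frames.append(pd.DataFrame([{
            "family": "latency_oneway", "effect": "treatment",
            "SS": ow.ss_between, "df": ow.df_num, "MS": ow.ss_between / ow.df_num,
            "F": ow.f, "p": ow.p, "error_term": f"within (df={ow.df_den})"}]))
        if ow.ms_within > 0:
            for c in ryan_posthoc(labels, [groups[g].mean() for g in labels],
                                  [len(groups[g]) for g in labels],
                                  ow.ms_within, ow.df_den, config.alpha):
                posthoc_rows.append({
                    "family": "latency_ryan",
                    "pair": f"{c.pair[0]}-vs-{c.pair[1]}",
                    "statistic": c.statistic, "df": c.df, "p": c.p,
                    "span": c.span, "nominal_level": c.nominal_level,
                    "significant": c.significant})

    anova_tables = (pd.concat(anova_frames, ignore_index=True)
                    if anova_frames else pd.DataFrame())
    posthoc = pd.DataFrame(posthoc_rows)
    return ResultBundle(condition_means, latencies, movement, phase_summary,
                        anova_tables, posthoc, anova_results)


def load_units(sample_paths, event_paths, config: PipelineConfig):
    """Read paired sample/event files into analysis units.

    Files are paired positionally; the participant id is the filename stem
    up to the first underscore.  A ``*_presses.csv`` sidecar next to each
    event file is picked up automatically.
    """
    units = []
    for spath, epath in zip(sample_paths, event_paths, strict=True):
        spath, epath = Path(spath), Path(epath)
        pid = spath.stem.split("_")[0]
        samples = read_samples(spath, config, participant_id=pid)
        ppath = Path(str(epath).replace("_events", "_presses"))
        events = read_events(epath, presses_path=ppath if ppath != epath else None,
                             config=config)
        units.append((pid, samples, events))
    return units


def run_pipeline(config: PipelineConfig, sample_paths, event_paths,
                 out_dir) -> dict[str, Path]:
    """File-based end-to-end run; writes the result tables under ``out_dir``.

    All tables are assembled in memory and written only on success, so a
    failed run leaves no partial outputs.
    """
    units = load_units(sample_paths, event_paths, config)
    bundle = analyze(config, units)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, table in bundle.tables().items():
        path = out_dir / f"{name}.csv"
        table.to_csv(path, index=False, float_format="%.9g")
        paths[name] = path
    prov = out_dir / "provenance.txt"
    prov.write_text(
        f"config_hash: {config.hash()}\nrng_seed: {config.rng_seed}\n"
        f"n_units: {len(units)}\n")
    paths["provenance"] = prov
    return paths
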