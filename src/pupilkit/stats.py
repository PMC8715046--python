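"""Phase-window summaries and within-subject factorial statistics.

The statistical layer mirrors classical repeated-measures practice:

* a fully-crossed within-subject factorial ANOVA in which every effect is
  tested against its own participant-by-effect interaction error term;
* simple main effects of one factor at fixed levels of others, using a
  *pooled* error term — the participant-interaction error terms of the
  tested factor and of its interactions with the fixed factors are summed,
  giving the familiar inflated denominator df (e.g. (n-1)*(1+1+3+3) = 104
  for one factor at fixed levels of the other two in a 2x2x4 design with
  n = 14);
* Ryan's sequentially rejective multiple-comparison procedure: ordered
  means, pairwise t tests on a shared error term, the comparison spanning
  r ordered means judged at nominal level alpha' = 2*alpha / (k*(r-1)),
  testing from the widest span inward, a pair declared significant only if
  every enclosing span's comparison was;
* classical one-way ANOVA, from raw samples or from per-group summary
  statistics (mean, SD, n), which determine the sums of squares exactly.

No sphericity correction is applied by default; Greenhouse-Geisser is
available via ``rm_anova(..., gg=True)``.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import PipelineConfig
from .epochs import ConditionAverage

logger = logging.getLogger(__name__)


class DesignError(ValueError):
    """Raised for incomplete or malformed statistical designs."""


# ---------------------------------------------------------------- phase means

def phase_means(average: ConditionAverage, config: PipelineConfig | None = None):
    """Time-means of a condition trace in the early and late phase windows.

    Early phase: ``config.early_phase`` (default [0.5, 1.48) s after cue
    onset, the window of rapid dilation).  Late phase:
    [``late_phase_start``, trial offset), the sustained-dilation window —
    clipped to the trial duration.  Means are over non-missing samples;
    a fully missing window yields NaN.
    """
    config = config or PipelineConfig()
    duration = average.meta.get("duration")
    if duration in (None, "pooled"):
        raise DesignError("phase means need a per-duration average (late window ends at offset)")
    duration = float(duration)
    t, y = average.rel_time, average.mean_trace

    def window_mean(lo, hi):
        sel = (t >= lo) & (t < hi) & np.isfinite(y)
        if not sel.any():
            logger.warning("phase window [%g, %g) fully missing for %s", lo, hi, average.meta)
            return np.nan
        return float(np.mean(y[sel]))

    e0, e1 = config.early_phase
    early = window_mean(e0, min(e1, duration))
    late = window_mean(config.late_phase_start, duration)
    return {"early": early, "late": late, **average.meta}


# --------------------------------------------------- repeated-measures ANOVA

@dataclass(frozen=True)
class EffectRow:
    name: str
    ss: float
    df: int
    ms: float
    f: float
    p: float
    error_term: str
    gg_eps: float = np.nan
    p_gg: float = np.nan


@dataclass(frozen=True)
class ErrorRow:
    name: str
    ss: float
    df: int
    ms: float


@dataclass
class AnovaResult:
    effects: list[EffectRow]
    error_terms: list[ErrorRow]
    factors: list[str]
    levels: dict[str, list]
    n_participants: int
    ss_subjects: float
    ss_total: float
    data: np.ndarray = field(repr=False, default=None)  # (n, l1, ..., lk)

    def effect(self, name: str) -> EffectRow:
        for row in self.effects:
            if row.name == name:
                return row
        raise KeyError(name)

    def error(self, name: str) -> ErrorRow:
        for row in self.error_terms:
            if row.name == name:
                return row
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"effect": e.name, "SS": e.ss, "df": e.df, "MS": e.ms,
                 "F": e.f, "p": e.p, "error_term": e.error_term}
                for e in self.effects]
        rows += [{"effect": e.name, "SS": e.ss, "df": e.df, "MS": e.ms,
                  "F": np.nan, "p": np.nan, "error_term": ""}
                 for e in self.error_terms]
        return pd.DataFrame(rows)


def _effect_ss(data: np.ndarray, keep: tuple[int, ...]):
    """Sum of squares of the pure interaction effect over axes ``keep``.

    Inclusion-exclusion over marginal means; replication is the product of
    the collapsed axis lengths.
    """
    all_axes = tuple(range(data.ndim))
    eff = 0.0
    for r in range(len(keep) + 1):
        for sub in itertools.combinations(keep, r):
            drop = tuple(ax for ax in all_axes if ax not in sub)
            m = data.mean(axis=drop, keepdims=True) if drop else data
            eff = eff + (-1) ** (len(keep) - len(sub)) * m
    reps = int(np.prod([data.shape[ax] for ax in all_axes if ax not in keep], dtype=int))
    return reps * float(np.sum(np.asarray(eff) ** 2))


def _pivot_balanced(table: pd.DataFrame, dv: str, within: list[str], subject: str):
    """Pivot a long table into an (n_subjects, l1, ..., lk) array.

    Factor levels keep their order of first appearance.  Missing or
    duplicated cells raise :class:`DesignError` naming the cells.
    """
    levels = {f: list(pd.unique(table[f])) for f in within}
    subjects = list(pd.unique(table[subject]))
    shape = (len(subjects),) + tuple(len(levels[f]) for f in within)
    expected = len(subjects) * int(np.prod(shape[1:], dtype=int))
    counts = table.groupby([subject] + within, sort=False, observed=True).size()
    if (counts > 1).any():
        bad = counts[counts > 1].index.tolist()[:5]
        raise DesignError(f"duplicated cells (subject, {within}): {bad}")
    if len(counts) != expected:
        full = set(itertools.product(subjects, *[levels[f] for f in within]))
        missing = sorted(full - set(counts.index), key=str)[:10]
        raise DesignError(f"incomplete design; missing cells (subject, {within}): {missing}")

    data = np.empty(shape)
    sub_idx = {s: i for i, s in enumerate(subjects)}
    lev_idx = [{l: i for i, l in enumerate(levels[f])} for f in within]
    cols = table[[subject] + within + [dv]].to_numpy(dtype=object)
    for row in cols:
        pos = (sub_idx[row[0]],) + tuple(lev_idx[i][row[1 + i]] for i in range(len(within)))
        data[pos] = float(row[-1])
    return data, subjects, levels


def _gg_epsilon(data: np.ndarray, keep: tuple[int, ...]) -> float:
    """Greenhouse-Geisser epsilon for the effect over factor axes ``keep``."""
    n = data.shape[0]
    # collapse non-involved factor axes, flatten involved ones -> (n, m)
    drop = tuple(ax for ax in range(1, data.ndim) if ax not in keep)
    y = data.mean(axis=drop) if drop else data
    y = y.reshape(n, -1)
    m = y.shape[1]
    if m < 3:
        return 1.0
    s = np.cov(y, rowvar=False)
    mean_diag = np.trace(s) / m
    mean_all = s.mean()
    num = (m * (mean_diag - mean_all)) ** 2
    den = (m - 1) * (np.sum(s ** 2) - 2 * m * np.sum(s.mean(axis=1) ** 2)
                     + m ** 2 * mean_all ** 2)
    return float(num / den) if den > 0 else 1.0


def rm_anova(table: pd.DataFrame, dv: str, within: list[str], subject: str,
             gg: bool = False) -> AnovaResult:
    """Fully within-subject factorial ANOVA on complete balanced data.

    Every effect (main effects and all interactions of ``within``) is
    tested against its participant-by-effect interaction with
    ``df = (n-1) * prod(levels-1)``.  With ``gg=True`` the
    Greenhouse-Geisser corrected p-value is reported alongside.
    """
    data, subjects, levels = _pivot_balanced(table, dv, within, subject)
    n = len(subjects)
    if n < 2:
        raise DesignError("need at least 2 participants")
    k = len(within)
    effects: list[EffectRow] = []
    errors: list[ErrorRow] = []
    for r in range(1, k + 1):
        for combo in itertools.combinations(range(1, k + 1), r):
            names = [within[ax - 1] for ax in combo]
            name = " x ".join(names)
            df_eff = int(np.prod([len(levels[f]) - 1 for f in names], dtype=int))
            ss_eff = _effect_ss(data, combo)
            ss_err = _effect_ss(data, (0,) + combo)
            df_err = (n - 1) * df_eff
            ms_eff = ss_eff / df_eff
            ms_err = ss_err / df_err
            if ms_err > 0:
                f = ms_eff / ms_err
                p = float(sps.f.sf(f, df_eff, df_err))
            else:
                f, p = (0.0, 1.0) if ss_eff == 0 else (np.inf, 0.0)
            eps = p_gg = np.nan
            if gg:
                eps = _gg_epsilon(data, combo)
                p_gg = float(sps.f.sf(f, df_eff * eps, df_err * eps)) if np.isfinite(f) else p
            err_name = f"subj x {name}"
            effects.append(EffectRow(name, ss_eff, df_eff, ms_eff, f, p,
                                     err_name, eps, p_gg))
            errors.append(ErrorRow(err_name, ss_err, df_err, ms_err))
    ss_sub = _effect_ss(data, (0,))
    ss_total = float(np.sum((data - data.mean()) ** 2))
    return AnovaResult(effects, errors, list(within), levels, n, ss_sub,
                       ss_total, data)


# ----------------------------------------------------- simple main effects

@dataclass(frozen=True)
class SimpleEffect:
    factor: str
    at: dict
    f: float
    df_num: int
    df_den: int
    p: float
    ss: float
    ms_error: float
    means: dict  # level -> cell mean of the tested factor at `at`


def simple_main_effects(result: AnovaResult, factor: str,
                        at: dict | None = None,
                        pooled_error: bool = True) -> list[SimpleEffect]:
    """Simple main effects of ``factor`` at fixed levels of other factors.

    ``at`` maps each fixed factor to a level, a list of levels, or None for
    all its levels; one record per combination is returned.  The error term
    pools the participant-interaction error terms of ``factor`` and of its
    interactions with the fixed factors (the convention that yields e.g.
    F(1, 104) in a 2x2x4 design with n = 14).  With ``pooled_error=False``
    a cell-wise error (participant x factor interaction within the fixed
    cell) is used instead.  With no fixed factors this reduces to the
    omnibus test of ``factor``.
    """
    if factor not in result.factors:
        raise DesignError(f"factor {factor!r} not in design {result.factors}")
    at = dict(at or {})
    for f in at:
        if f not in result.factors or f == factor:
            raise DesignError(f"invalid fixed factor {f!r}")
    fixed = list(at)
    # expand level lists
    def levels_of(f):
        v = at[f]
        if v is None:
            return result.levels[f]
        return list(v) if isinstance(v, (list, tuple)) else [v]

    data = result.data
    n = result.n_participants
    axis_of = {f: i + 1 for i, f in enumerate(result.factors)}
    a_ax = axis_of[factor]
    l_a = len(result.levels[factor])

    # pooled error: subj x (factor [x subset of fixed factors])
    if pooled_error:
        ss_err = df_err = 0.0
        for r in range(len(fixed) + 1):
            for sub in itertools.combinations(fixed, r):
                name = " x ".join(f for f in result.factors if f == factor or f in sub)
                err = result.error(f"subj x {name}")
                ss_err += err.ss
                df_err += err.df
        df_err = int(df_err)
        ms_err = ss_err / df_err

    out = []
    for combo in itertools.product(*[levels_of(f) for f in fixed]):
        idx = [slice(None)] * data.ndim
        for f, lev in zip(fixed, combo):
            idx[axis_of[f]] = result.levels[f].index(lev)
        cell = data[tuple(idx)]  # axes: subject, tested factor, remaining factors
        a_cell_ax = _axis_in_cell(result, factor, fixed)
        # average over subject and remaining (non-tested) factor axes
        other = tuple(ax for ax in range(cell.ndim) if ax != a_cell_ax)
        means = cell.mean(axis=other)
        reps = n * int(np.prod([cell.shape[ax] for ax in range(1, cell.ndim)
                                if ax != a_cell_ax], dtype=int))
        ss = reps * float(np.sum((means - means.mean()) ** 2))
        df_num = l_a - 1
        if not pooled_error:
            ss_e = _effect_ss(cell, (0, a_cell_ax))
            df_e = (n - 1) * df_num
            ms_err_c, df_err_c = ss_e / df_e, df_e
        else:
            ms_err_c, df_err_c = ms_err, df_err
        f_stat = (ss / df_num) / ms_err_c if ms_err_c > 0 else (0.0 if ss == 0 else np.inf)
        p = float(sps.f.sf(f_stat, df_num, df_err_c)) if np.isfinite(f_stat) else 0.0
        out.append(SimpleEffect(factor, dict(zip(fixed, combo)), float(f_stat),
                                df_num, int(df_err_c), p, ss, ms_err_c,
                                dict(zip(result.levels[factor], means))))
    return out


def _axis_in_cell(result: AnovaResult, factor: str, fixed: list[str]) -> int:
    """Axis index of ``factor`` after the fixed factors' axes were sliced away."""
    ax = 1
    for f in result.factors:
        if f == factor:
            return ax
        if f not in fixed:
            ax += 1
    raise KeyError(factor)


# --------------------------------------------------------- Ryan's procedure

@dataclass(frozen=True)
class ComparisonRecord:
    pair: tuple
    statistic: float
    df: int
    p: float
    span: int
    nominal_level: float
    significant: bool


def ryan_posthoc(labels, means, ns, error_ms: float, error_df: int,
                 alpha: float = 0.05) -> list[ComparisonRecord]:
    """Ryan's sequentially rejective pairwise comparisons.

    Means are ordered; the pair spanning ``r`` ordered means is judged at
    nominal level ``2*alpha / (k*(r-1))``, from the widest span inward, and
    a pair is significant only if its own p is below its nominal level AND
    every enclosing span's comparison was significant.  t statistics use
    the shared ``error_ms`` (e.g. the preceding ANOVA's error mean square)
    with ``error_df``.
    """
    means = np.asarray(means, float)
    ns = np.asarray(ns, float)
    k = len(means)
    if k < 2:
        raise DesignError("need at least 2 groups")
    if error_ms <= 0:
        raise DesignError("error variance must be positive")
    order = np.argsort(means, kind="stable")
    labels = list(labels)

    sig: dict[tuple[int, int], bool] = {}
    records = []
    for span in range(k, 1, -1):
        r = span
        nominal = 2.0 * alpha / (k * (r - 1))
        for i in range(0, k - span + 1):
            j = i + span - 1
            a, b = order[i], order[j]
            se = np.sqrt(error_ms * (1.0 / ns[a] + 1.0 / ns[b]))
            tval = float((means[b] - means[a]) / se)
            p = float(2.0 * sps.t.sf(abs(tval), error_df))
            gate = all(sig[(ii, jj)] for ii in range(0, i + 1)
                       for jj in range(j, k) if (ii, jj) != (i, j))
            significant = gate and (p < nominal)
            sig[(i, j)] = significant
            records.append(ComparisonRecord(
                pair=(labels[a], labels[b]), statistic=tval, df=int(error_df),
                p=p, span=r, nominal_level=nominal, significant=significant))
    return records


# ------------------------------------------------------------ one-way ANOVA

@dataclass(frozen=True)
class OneWayResult:
    f: float
    df_num: int
    df_den: int
    p: float
    ss_between: float
    ss_within: float
    ms_within: float
    group_means: tuple
    group_ns: tuple


def oneway_anova(groups) -> OneWayResult:
    """Classical one-way (between-groups) ANOVA on raw samples."""
    groups = [np.asarray(g, float) for g in groups]
    k = len(groups)
    if k < 2:
        raise DesignError("need at least 2 groups")
    ns = np.array([len(g) for g in groups])
    if ns.min() < 1 or ns.sum() <= k:
        raise DesignError("need n >= 1 per group and total N > k")
    means = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()
    ss_b = float(np.sum(ns * (means - grand) ** 2))
    ss_w = float(sum(np.sum((g - m) ** 2) for g, m in zip(groups, means)))
    return _oneway_from_ss(ss_b, ss_w, ns, means)


def oneway_anova_from_stats(means, sds, ns) -> OneWayResult:
    """One-way ANOVA reconstructed exactly from per-group (mean, SD, n).

    Sample SDs (ddof=1) determine the within-group sum of squares as
    ``sum((n_i - 1) * sd_i^2)``; means and ns determine the between-group
    sum of squares, so the F statistic is identical to the raw-data one.
    """
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    ns = np.asarray(ns, float)
    grand = float(np.sum(ns * means) / np.sum(ns))
    ss_b = float(np.sum(ns * (means - grand) ** 2))
    ss_w = float(np.sum((ns - 1) * sds ** 2))
    return _oneway_from_ss(ss_b, ss_w, ns, means)


def _oneway_from_ss(ss_b, ss_w, ns, means) -> OneWayResult:
    k = len(ns)
    df_b = k - 1
    df_w = int(np.sum(ns)) - k
    ms_w = ss_w / df_w
    if ms_w == 0:
        warnings.warn("zero within-group variance; F undefined (reported as 0)")
        f = 0.0
        p = 1.0
    else:
        f = (ss_b / df_b) / ms_w
        p = float(sps.f.sf(f, df_b, df_w))
    return OneWayResult(float(f), df_b, df_w, p, ss_b, ss_w, ms_w,
                        tuple(float(m) for m in means), tuple(int(n) for n in ns))
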