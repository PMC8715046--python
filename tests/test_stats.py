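"""Phase summaries, rm-ANOVA, simple effects, Ryan's procedure, one-way ANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from pupilkit import (ConditionAverage, DesignError, PipelineConfig,
                      oneway_anova, oneway_anova_from_stats, phase_means,
                      rm_anova, ryan_posthoc, simple_main_effects)

FS = 250.0


def _avg(values, duration, pre=1.0):
    n_pre = int(pre * FS)
    values = np.asarray(values, float)
    rel = np.arange(-n_pre, len(values) - n_pre) / FS
    return ConditionAverage(rel, values, np.ones(len(values), int),
                            {"participant": "p0", "eye": "control",
                             "drug": "control", "duration": duration})


def _rm_table(data, factors):
    """Long-format frame from an (n_subj, l1, ..., lk) array."""
    n = data.shape[0]
    levels = [list(range(s)) for s in data.shape[1:]]
    rows = []
    for s in range(n):
        for cell in itertools.product(*levels):
            rows.append({"subj": f"s{s}", "y": data[(s,) + cell],
                         **{f: f"{f}{c}" for f, c in zip(factors, cell)}})
    return pd.DataFrame(rows)


class TestPhaseMeans:
    def test_constant_trace(self, config):
        out = phase_means(_avg(np.full(int(5 * FS), 0.7), 3.0), config)
        assert out["early"] == pytest.approx(0.7)
        assert out["late"] == pytest.approx(0.7)

    def test_identity_ramp_gives_window_midpoint(self, config):
        n = int(5 * FS)
        rel = np.arange(-int(FS), n - int(FS)) / FS
        out = phase_means(_avg(np.clip(rel, 0, None), 3.0), config)
        # Riemann mean of t over [0.5, 1.48) on the 250-Hz grid ~ midpoint
        assert out["early"] == pytest.approx((0.5 + 1.48) / 2, abs=0.5 / FS)

    def test_late_window_ends_at_trial_offset(self, config):
        n = int(5 * FS)
        rel = np.arange(-int(FS), n - int(FS)) / FS
        values = np.where(rel < 3.0, 1.0, 99.0)  # post-offset values must not leak
        out = phase_means(_avg(values, 3.0), config)
        assert out["late"] == pytest.approx(1.0)

    def test_fully_missing_window_is_nan(self, config):
        n = int(5 * FS)
        values = np.full(n, np.nan)
        out = phase_means(_avg(values, 3.0), config)
        assert np.isnan(out["early"]) and np.isnan(out["late"])


class TestRmAnova:
    def test_constant_within_participant_gives_zero_f(self):
        data = np.tile(np.arange(4.0)[:, None, None], (1, 2, 3))  # subj offsets only
        res = rm_anova(_rm_table(data, ["a", "b"]), "y", ["a", "b"], "subj")
        for eff in res.effects:
            assert eff.ss == pytest.approx(0.0, abs=1e-12)
            assert eff.f == 0.0

    def test_two_level_f_equals_squared_paired_t(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(10, 2))
        res = rm_anova(_rm_table(x, ["a"]), "y", ["a"], "subj")
        t, _ = sps.ttest_rel(x[:, 0], x[:, 1])
        eff = res.effect("a")
        assert eff.f == pytest.approx(t ** 2, rel=1e-10)
        assert (eff.df, res.error("subj x a").df) == (1, 9)

    def test_matches_independent_oracle_on_toy_design(self):
        from statsmodels.stats.anova import AnovaRM
        rng = np.random.default_rng(7)
        data = rng.integers(0, 10, size=(3, 3, 2, 2)).astype(float)
        table = _rm_table(data, ["a", "b", "d"])
        res = rm_anova(table, "y", ["a", "b", "d"], "subj")
        oracle = AnovaRM(table, "y", "subj", within=["a", "b", "d"]).fit().anova_table
        key = {"a": "a", "b": "b", "d": "d", "a x b": "a:b", "a x d": "a:d",
               "b x d": "b:d", "a x b x d": "a:b:d"}
        for eff in res.effects:
            row = oracle.loc[key[eff.name]]
            assert eff.f == pytest.approx(row["F Value"], rel=1e-8)
            assert eff.df == row["Num DF"]
            assert eff.p == pytest.approx(row["Pr > F"], rel=1e-8)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_balanced_ss_conservation(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.normal(size=(5, 2, 3))
        res = rm_anova(_rm_table(data, ["a", "b"]), "y", ["a", "b"], "subj")
        parts = (sum(e.ss for e in res.effects)
                 + sum(e.ss for e in res.error_terms) + res.ss_subjects)
        assert parts == pytest.approx(res.ss_total, rel=1e-8)

    @given(st.integers(0, 2 ** 31 - 1),
           st.floats(-100, 100), st.floats(0.01, 100))
    def test_translation_and_scale_invariance_of_f(self, seed, shift, scale):
        rng = np.random.default_rng(seed)
        data = rng.normal(size=(4, 2, 2))
        f0 = [e.f for e in rm_anova(_rm_table(data, ["a", "b"]),
                                    "y", ["a", "b"], "subj").effects]
        f1 = [e.f for e in rm_anova(_rm_table(data * scale + shift, ["a", "b"]),
                                    "y", ["a", "b"], "subj").effects]
        np.testing.assert_allclose(f0, f1, rtol=1e-6, atol=1e-9)

    def test_incomplete_design_names_missing_cells(self):
        data = np.arange(12.0).reshape(3, 2, 2)
        table = _rm_table(data, ["a", "b"]).iloc[:-1]
        with pytest.raises(DesignError, match="missing cells"):
            rm_anova(table, "y", ["a", "b"], "subj")


class TestSimpleMainEffects:
    def _design(self, shape, factors, seed=0):
        rng = np.random.default_rng(seed)
        data = rng.normal(size=shape)
        return rm_anova(_rm_table(data, factors), "y", factors, "subj")

    def test_pooled_df_in_2x2x4_design_is_104(self):
        res = self._design((14, 2, 2, 4), ["drug", "inst", "session"])
        effs = simple_main_effects(res, "inst",
                                   at={"drug": "drug0", "session": None})
        assert len(effs) == 4
        assert all(e.df_den == 104 and e.df_num == 1 for e in effs)

    def test_pooled_df_in_2x2x3_design_is_26(self):
        res = self._design((14, 2, 2, 3), ["phase", "inst", "duration"])
        (eff,) = simple_main_effects(res, "inst", at={"phase": "phase1"})
        assert (eff.df_num, eff.df_den) == (1, 26)

    def test_single_factor_reduces_to_omnibus(self):
        res = self._design((6, 3), ["a"])
        (eff,) = simple_main_effects(res, "a")
        omnibus = res.effect("a")
        assert eff.f == pytest.approx(omnibus.f, rel=1e-10)
        assert eff.df_den == res.error("subj x a").df

    def test_cellwise_error_option(self):
        res = self._design((8, 2, 2), ["a", "b"], seed=3)
        (pooled,) = simple_main_effects(res, "a", at={"b": "b0"})
        (cellwise,) = simple_main_effects(res, "a", at={"b": "b0"},
                                          pooled_error=False)
        assert cellwise.df_den == 7      # (n-1)*(2-1) within the cell
        assert pooled.df_den == 14       # subj x a + subj x a x b
        assert pooled.ss == pytest.approx(cellwise.ss, rel=1e-10)

    def test_unknown_factor_rejected(self):
        res = self._design((4, 2), ["a"])
        with pytest.raises(DesignError):
            simple_main_effects(res, "zzz")


class TestRyan:
    def test_two_groups_reduce_to_plain_t(self):
        recs = ryan_posthoc(["a", "b"], [0.0, 1.0], [10, 10],
                            error_ms=1.0, error_df=18, alpha=0.05)
        (rec,) = recs
        assert rec.nominal_level == pytest.approx(0.05)
        t = 1.0 / np.sqrt(1.0 * (0.1 + 0.1))
        assert abs(rec.statistic) == pytest.approx(t)
        assert rec.p == pytest.approx(2 * sps.t.sf(t, 18))

    def test_three_group_nominal_levels(self):
        recs = ryan_posthoc(["a", "b", "c"], [0.0, 0.5, 1.0], [10] * 3,
                            error_ms=1.0, error_df=27, alpha=0.05)
        by_span = {r.span: r.nominal_level for r in recs}
        assert by_span[3] == pytest.approx(0.05 / 3)
        assert by_span[2] == pytest.approx(0.05 * 2 / 3)

    def test_gating_blocks_nested_pairs(self):
        # widest span not significant -> nested pairs forced non-significant
        recs = ryan_posthoc(["a", "b", "c"], [0.0, 0.01, 0.02], [3] * 3,
                            error_ms=1.0, error_df=6, alpha=0.05)
        assert not any(r.significant for r in recs)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_levels_non_increasing_and_gating_consistent(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 6))
        means = rng.normal(size=k)
        recs = ryan_posthoc([f"g{i}" for i in range(k)], means, [5] * k,
                            error_ms=float(rng.uniform(0.1, 2.0)),
                            error_df=4 * k, alpha=0.05)
        spans = sorted({r.span for r in recs})
        levels = {r.span: r.nominal_level for r in recs}
        assert all(levels[a] >= levels[b] for a, b in zip(spans, spans[1:]))
        sig = {tuple(sorted(r.pair)): r.significant for r in recs}
        # no pair is significant while an enclosing pair is not: re-derive order
        order = np.argsort(means, kind="stable")
        labels = [f"g{i}" for i in range(k)]
        for r in recs:
            if r.significant:
                i = [labels[x] for x in order].index(r.pair[0])
                j = [labels[x] for x in order].index(r.pair[1])
                for ii in range(0, i + 1):
                    for jj in range(j, k):
                        pair = tuple(sorted((labels[order[ii]], labels[order[jj]])))
                        if pair in sig:
                            assert sig[pair]

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DesignError):
            ryan_posthoc(["a"], [1.0], [5], 1.0, 4)
        with pytest.raises(DesignError):
            ryan_posthoc(["a", "b"], [1.0, 2.0], [5, 5], 0.0, 4)


class TestOneWay:
    def test_df_structure_for_unequal_groups(self):
        rng = np.random.default_rng(0)
        res = oneway_anova([rng.normal(size=12), rng.normal(size=11),
                            rng.normal(size=10)])
        assert (res.df_num, res.df_den) == (2, 30)

    def test_two_equal_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=8), rng.normal(1.0, 1.0, size=8)
        res = oneway_anova([a, b])
        t, p = sps.ttest_ind(a, b)
        assert res.f == pytest.approx(t ** 2, rel=1e-10)
        assert res.p == pytest.approx(p, rel=1e-10)

    def test_scipy_agreement(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(size=n) for n in (5, 7, 6)]
        res = oneway_anova(groups)
        f, p = sps.f_oneway(*groups)
        assert res.f == pytest.approx(f, rel=1e-12)
        assert res.p == pytest.approx(p, rel=1e-12)

    def test_summary_stats_path_matches_raw(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(size=n) for n in (12, 11, 10)]
        raw = oneway_anova(groups)
        summ = oneway_anova_from_stats([g.mean() for g in groups],
                                       [g.std(ddof=1) for g in groups],
                                       [len(g) for g in groups])
        assert summ.f == pytest.approx(raw.f, abs=1e-10)
        assert summ.p == pytest.approx(raw.p, abs=1e-10)

    def test_summary_stats_closed_form(self):
        """Group summaries (0.60/0.59/0.96 etc.) determine F exactly."""
        means, sds, ns = [0.60, 0.59, 0.96], [0.18, 0.28, 0.45], [12, 11, 10]
        res = oneway_anova_from_stats(means, sds, ns)
        # independent closed-form recomputation
        ns_, means_, sds_ = map(np.asarray, (ns, means, sds))
        grand = (ns_ * means_).sum() / ns_.sum()
        ssb = (ns_ * (means_ - grand) ** 2).sum()
        ssw = ((ns_ - 1) * sds_ ** 2).sum()
        f = (ssb / 2) / (ssw / 30)
        assert res.f == pytest.approx(f, rel=1e-12)
        assert (res.df_num, res.df_den) == (2, 30)

    def test_identical_values_give_zero_f_with_warning(self):
        with pytest.warns(UserWarning, match="zero within-group variance"):
            res = oneway_anova([[1.0, 1.0], [1.0, 1.0, 1.0]])
        assert res.f == 0.0
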