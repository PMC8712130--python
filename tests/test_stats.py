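"""Factorial ANOVA against brute-force and library oracles; Duncan; Pearson."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

from vwm import stats
from vwm.stats import (correlate, duncan_critical_range, duncan_posthoc,
                       factorial_anova, normality_check)

#: A fixed 3-subject toy table (subject x modality x level).
TOY_VALUES = {
    ("s1", "audio", 0): 4.0, ("s1", "audio", 1): 5.0, ("s1", "audio", 2): 7.0,
    ("s1", "video", 0): 3.0, ("s1", "video", 1): 4.0, ("s1", "video", 2): 6.0,
    ("s2", "audio", 0): 5.0, ("s2", "audio", 1): 6.0, ("s2", "audio", 2): 9.0,
    ("s2", "video", 0): 4.0, ("s2", "video", 1): 6.0, ("s2", "video", 2): 8.0,
    ("s3", "audio", 0): 3.0, ("s3", "audio", 1): 5.0, ("s3", "audio", 2): 6.0,
    ("s3", "video", 0): 2.0, ("s3", "video", 1): 3.0, ("s3", "video", 2): 7.0,
}


def toy_table():
    rows = [{"subject": s, "modality": m, "level": l, "value": v}
            for (s, m, l), v in TOY_VALUES.items()]
    return pd.DataFrame(rows)


def brute_force_rm_anova(table):
    """Literal sums-of-squares oracle via explicit loops over cells."""
    subjects = sorted(table["subject"].unique())
    mods = sorted(table["modality"].unique())
    lvls = sorted(table["level"].unique())
    y = {(r.subject, r.modality, r.level): r.value
         for r in table.itertuples()}
    s, a, b = len(subjects), len(mods), len(lvls)
    gm = sum(y.values()) / len(y)

    def mean(cond):
        vals = [v for k, v in y.items() if cond(k)]
        return sum(vals) / len(vals)

    ss_a = s * b * sum((mean(lambda k, m=m: k[1] == m) - gm) ** 2 for m in mods)
    ss_b = s * a * sum((mean(lambda k, l=l: k[2] == l) - gm) ** 2 for l in lvls)
    ss_ab = s * sum(
        (mean(lambda k, m=m, l=l: k[1] == m and k[2] == l)
         - mean(lambda k, m=m: k[1] == m)
         - mean(lambda k, l=l: k[2] == l) + gm) ** 2
        for m in mods for l in lvls)
    ss_subj = a * b * sum((mean(lambda k, u=u: k[0] == u) - gm) ** 2
                          for u in subjects)
    ss_err_a = b * sum(
        (mean(lambda k, u=u, m=m: k[0] == u and k[1] == m)
         - mean(lambda k, u=u: k[0] == u)
         - mean(lambda k, m=m: k[1] == m) + gm) ** 2
        for u in subjects for m in mods)
    ss_err_b = a * sum(
        (mean(lambda k, u=u, l=l: k[0] == u and k[2] == l)
         - mean(lambda k, u=u: k[0] == u)
         - mean(lambda k, l=l: k[2] == l) + gm) ** 2
        for u in subjects for l in lvls)
    ss_total = sum((v - gm) ** 2 for v in y.values())
    ss_err_ab = ss_total - ss_subj - ss_a - ss_b - ss_ab - ss_err_a - ss_err_b

    out = {}
    for name, ss_eff, ss_err, df_e, df_r in [
            ("modality", ss_a, ss_err_a, a - 1, (a - 1) * (s - 1)),
            ("level", ss_b, ss_err_b, b - 1, (b - 1) * (s - 1)),
            ("modality:level", ss_ab, ss_err_ab,
             (a - 1) * (b - 1), (a - 1) * (b - 1) * (s - 1))]:
        F = (ss_eff / df_e) / (ss_err / df_r)
        out[name] = {"F": F, "p": float(sst.f.sf(F, df_e, df_r)),
                     "eta": ss_eff / (ss_eff + ss_err),
                     "df": (df_e, df_r)}
    return out


class TestFactorialAnova:
    def test_matches_brute_force_oracle(self):
        table = toy_table()
        result = factorial_anova(table, method="parametric")
        oracle = brute_force_rm_anova(table)
        for name, exp in oracle.items():
            eff = result[name]
            assert eff.F == pytest.approx(exp["F"], abs=1e-10)
            assert eff.p == pytest.approx(exp["p"], abs=1e-10)
            assert eff.partial_eta_sq == pytest.approx(exp["eta"], abs=1e-10)
            assert (eff.df_effect, eff.df_error) == exp["df"]

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        table = toy_table()
        result = factorial_anova(table, method="parametric")
        pg = pingouin.rm_anova(data=table, dv="value",
                               within=["modality", "level"], subject="subject",
                               detailed=True)
        by_source = {r["Source"]: r for _, r in pg.iterrows()}
        assert result["modality"].F == pytest.approx(
            by_source["modality"]["F"], rel=1e-9)
        assert result["level"].F == pytest.approx(
            by_source["level"]["F"], rel=1e-9)
        assert result["modality:level"].F == pytest.approx(
            by_source["modality * level"]["F"], rel=1e-9)

    def test_ss_decomposition_complete(self):
        result = factorial_anova(toy_table(), method="parametric")
        parts = (result.ss_components["subject"]
                 + sum(e.ss_effect + e.ss_error for e in result.effects.values()))
        assert parts == pytest.approx(result.ss_total, abs=1e-10)

    def test_eta_f_identity(self):
        """F = (eta/(1-eta)) * (df_err/df_eff) on every effect."""
        rng = np.random.default_rng(0)
        table = toy_table()
        table["value"] += rng.normal(size=len(table))
        result = factorial_anova(table, method="parametric")
        for eff in result.effects.values():
            recon = (eff.partial_eta_sq / (1 - eff.partial_eta_sq)
                     * eff.df_error / eff.df_effect)
            assert recon == pytest.approx(eff.F, rel=1e-10)

    def test_rank_anova_monotone_invariant(self):
        rng = np.random.default_rng(1)
        table = toy_table()
        table["value"] += rng.normal(size=len(table), scale=0.1)
        r1 = factorial_anova(table, method="rank")
        table2 = table.assign(value=np.exp(table["value"]))
        r2 = factorial_anova(table2, method="rank")
        for name in r1.effects:
            assert r1[name].F == pytest.approx(r2[name].F, rel=1e-12)

    def test_constant_table_degenerate(self):
        table = toy_table().assign(value=1.0)
        result = factorial_anova(table)
        for eff in result.effects.values():
            assert eff.F == 0.0 and eff.p == 1.0

    def test_unbalanced_lists_missing_cells(self):
        table = toy_table().iloc[:-1]
        with pytest.raises(ValueError, match="s3"):
            factorial_anova(table)

    def test_auto_routes_to_rank_on_skewed_residuals(self):
        rng = np.random.default_rng(2)
        rows = []
        for s in range(8):
            for m in ("audio", "video"):
                for l in (0, 1, 2):
                    rows.append({"subject": f"s{s}", "modality": m,
                                 "level": l,
                                 "value": float(rng.exponential() ** 3)})
        result = factorial_anova(pd.DataFrame(rows), method="auto")
        assert result.method == "rank"
        assert result.normality_p < 0.05

    def test_between_design_single_error_term(self):
        result = factorial_anova(toy_table(), method="parametric",
                                 design="between")
        errs = {e.ss_error for e in result.effects.values()}
        assert len(errs) == 1
        dfs = {e.df_error for e in result.effects.values()}
        assert dfs == {2 * 3 * 2}


class TestNormalityCheck:
    def test_calibrated_under_null(self):
        rng = np.random.default_rng(3)
        rejections = sum(normality_check(rng.normal(size=50))[1] < 0.05
                         for _ in range(400))
        assert 0.02 <= rejections / 400 <= 0.09

    def test_power_against_exponential(self):
        rng = np.random.default_rng(4)
        rejections = sum(normality_check(rng.exponential(size=50))[1] < 0.05
                         for _ in range(200))
        assert rejections / 200 > 0.8

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            normality_check([1.0, 1.0])
        with pytest.raises(ValueError):
            normality_check(np.ones(10))


def noisy_table(level_means, n_subjects=8, sd=1.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        subj_off = rng.normal(scale=0.5)
        for m in ("audio", "video"):
            for l, mu in enumerate(level_means):
                rows.append({"subject": f"s{s:02d}", "modality": m, "level": l,
                             "value": mu + subj_off + rng.normal(scale=sd)})
    return pd.DataFrame(rows)


class TestDuncan:
    def test_identical_groups_no_pairs(self):
        table = noisy_table([0.0, 0.0], seed=5)
        an = factorial_anova(table, method="parametric")
        ph = duncan_posthoc(table, "level", an)
        assert ph.significant_pairs() == []

    def test_huge_separation_all_pairs(self):
        table = noisy_table([0.0, 20.0, 40.0], sd=1.0, seed=6)
        an = factorial_anova(table, method="parametric")
        ph = duncan_posthoc(table, "level", an)
        assert len(ph.significant_pairs()) == 3

    def test_critical_range_nondecreasing_in_span(self):
        crits = [duncan_critical_range(r, df_error=20, ms_error=1.0, n=10)
                 for r in range(2, 7)]
        assert all(b >= a for a, b in zip(crits[:-1], crits[1:]))

    def test_protection_rule_suppresses_nested_pair(self):
        """A pair exceeding its own critical range is still reported
        non-significant when the span containing it is non-significant."""
        # construct means 0 < d < d+eps with crit(2) < d and crit(3) > d+eps
        base = noisy_table([0.0, 0.0, 0.0], n_subjects=6, sd=1.0, seed=7)
        # make the base level means exactly zero so the constructed gaps
        # land where intended (level-wise centering leaves MS_error alone)
        base["value"] -= base.groupby("level")["value"].transform("mean")
        an0 = factorial_anova(base, method="parametric")
        eff = an0["level"]
        n_per = an0.n_subjects * 2
        c2 = duncan_critical_range(2, eff.df_error, eff.ms_error, n_per)
        c3 = duncan_critical_range(3, eff.df_error, eff.ms_error, n_per)
        assert c3 > c2
        d = (c2 + c3) / 2.0          # adjacent gap beats c2 ...
        eps = (c3 - d) / 2.0         # ... but the full span stays under c3
        shifted = base.copy()
        shifted["value"] += shifted["level"].map({0: 0.0, 1: d, 2: d + eps})
        an = factorial_anova(shifted, method="parametric")
        # adding level-wise constants leaves the level error term unchanged
        assert an["level"].ms_error == pytest.approx(eff.ms_error, rel=1e-9)
        ph = duncan_posthoc(shifted, "level", an)
        cmp01 = ph.comparisons.set_index(["group_1", "group_2"])
        assert not cmp01.loc[(0, 2), "significant"]
        raw_exceeds = cmp01.loc[(0, 1), "diff"] > cmp01.loc[(0, 1),
                                                            "critical_range"]
        assert raw_exceeds
        assert not cmp01.loc[(0, 1), "significant"]

    def test_interaction_compares_cells(self):
        table = noisy_table([0.0, 1.0, 2.0], seed=8)
        an = factorial_anova(table, method="parametric")
        ph = duncan_posthoc(table, "modality:level", an)
        assert len(ph.means) == 6
        assert len(ph.comparisons) == 15

    def test_unknown_effect(self):
        table = noisy_table([0.0, 1.0], seed=9)
        an = factorial_anova(table)
        with pytest.raises(KeyError):
            duncan_posthoc(table, "load", an)


class TestCorrelate:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert correlate(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert correlate(x, -x)[0] == pytest.approx(-1.0)

    def test_null_calibration(self):
        rng = np.random.default_rng(10)
        big = sum(abs(correlate(rng.normal(size=66),
                                rng.normal(size=66))[0]) >= 0.25
                  for _ in range(400))
        assert big / 400 <= 0.05

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            correlate([1, 2], [3, 4])
        with pytest.raises(ValueError):
            correlate(np.ones(10), np.arange(10.0))
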