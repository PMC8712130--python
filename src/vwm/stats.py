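"""Statistical design: normality gate, 2x3 factorial ANOVA, Duncan post hoc.

Every subject contributes one value to each of the six modality-by-load
cells, so the default model is a within-subject (repeated-measures)
factorial decomposition: each effect (modality, load, their interaction) is
tested against its own subject-by-effect interaction error term.  Effect
sizes are partial eta squared, SS_effect / (SS_effect + SS_error).

When Shapiro-Wilk rejects normality of the cell residuals, the values are
rank-transformed (ranks over all observations) and the identical
decomposition is applied — a rank-transform ANOVA, which preserves the full
factorial structure including the interaction.

Duncan's multiple range test compares ordered means; a pair spanning r
ranks is significant when its difference exceeds
q(1 - alpha_r, r, df_error) * sqrt(MS_error / n) with the protection level
alpha_r = 1 - (1 - alpha)^(r - 1), and no pair inside a non-significant
span is ever declared significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sst

FACTORS = ("modality", "level")


@dataclass(frozen=True)
class EffectResult:
    effect: str
    ss_effect: float
    ss_error: float
    df_effect: int
    df_error: int
    F: float
    p: float
    partial_eta_sq: float

    @property
    def ms_error(self) -> float:
        return self.ss_error / self.df_error


@dataclass
class AnovaResult:
    effects: dict                   # effect name -> EffectResult
    method: str                     # "parametric" | "rank"
    design: str                     # "within" | "between"
    n_subjects: int
    cell_counts: dict               # factor -> number of levels
    normality_p: Optional[float] = None
    ss_total: float = 0.0
    ss_components: dict = field(default_factory=dict)

    def __getitem__(self, effect: str) -> EffectResult:
        return self.effects[effect]

    def table(self) -> pd.DataFrame:
        rows = [{"effect": e.effect, "F": e.F, "df_effect": e.df_effect,
                 "df_error": e.df_error, "p": e.p,
                 "partial_eta_sq": e.partial_eta_sq}
                for e in self.effects.values()]
        return pd.DataFrame(rows)


def normality_check(sample) -> tuple[float, float]:
    """Shapiro-Wilk test; returns (W, p)."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if x.size > 5000:
        raise ValueError("Shapiro-Wilk is unreliable above 5000 observations")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    w, p = sst.shapiro(x)
    return float(w), float(p)


def _check_balanced(table: pd.DataFrame, dv: str, subject: str) -> tuple:
    subjects = sorted(table[subject].unique())
    a_levels = sorted(table[FACTORS[0]].unique())
    b_levels = sorted(table[FACTORS[1]].unique())
    counts = table.groupby([subject, *FACTORS], observed=True)[dv].count()
    expected = len(subjects) * len(a_levels) * len(b_levels)
    if len(counts) != expected or (counts != 1).any():
        missing = []
        for s in subjects:
            for a in a_levels:
                for b in b_levels:
                    if (s, a, b) not in counts.index or counts.get((s, a, b), 0) != 1:
                        missing.append((s, a, b))
        raise ValueError(f"unbalanced table: expected exactly one value per "
                         f"subject x cell; offending cells: {missing[:10]}")
    if len(subjects) < 2:
        raise ValueError("at least 2 subjects are required")
    return subjects, a_levels, b_levels


def _cell_array(table: pd.DataFrame, dv: str, subject: str,
                subjects, a_levels, b_levels) -> np.ndarray:
    """Arrange values as (subject, A, B)."""
    y = np.empty((len(subjects), len(a_levels), len(b_levels)))
    s_ix = {s: i for i, s in enumerate(subjects)}
    a_ix = {a: i for i, a in enumerate(a_levels)}
    b_ix = {b: i for i, b in enumerate(b_levels)}
    for _, row in table.iterrows():
        y[s_ix[row[subject]], a_ix[row[FACTORS[0]]], b_ix[row[FACTORS[1]]]] = row[dv]
    return y


def _within_decomposition(y: np.ndarray) -> dict:
    """Balanced two-way repeated-measures sums of squares.

    y has shape (s, a, b).  Effects are tested against their own
    subject-by-effect interactions.
    """
    s, a, b = y.shape
    gm = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss_subj = a * b * np.sum((m_s - gm) ** 2)
    ss_a = s * b * np.sum((m_a - gm) ** 2)
    ss_b = s * a * np.sum((m_b - gm) ** 2)
    ss_ab = s * np.sum((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2)
    ss_err_a = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + gm) ** 2)
    ss_err_b = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + gm) ** 2)
    ss_total = np.sum((y - gm) ** 2)
    ss_err_ab = ss_total - ss_subj - ss_a - ss_b - ss_ab - ss_err_a - ss_err_b

    return {
        "ss_total": float(ss_total),
        "ss_subject": float(ss_subj),
        FACTORS[0]: (float(ss_a), float(ss_err_a), a - 1, (a - 1) * (s - 1)),
        FACTORS[1]: (float(ss_b), float(ss_err_b), b - 1, (b - 1) * (s - 1)),
        "modality:level": (float(ss_ab), float(ss_err_ab),
                           (a - 1) * (b - 1), (a - 1) * (b - 1) * (s - 1)),
    }


def _between_decomposition(y: np.ndarray) -> dict:
    """Two-way ANOVA with a single residual error term (comparison mode)."""
    s, a, b = y.shape
    gm = y.mean()
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_ab = y.mean(axis=0)
    ss_a = s * b * np.sum((m_a - gm) ** 2)
    ss_b = s * a * np.sum((m_b - gm) ** 2)
    ss_ab = s * np.sum((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2)
    ss_err = np.sum((y - m_ab[None, :, :]) ** 2)
    ss_total = np.sum((y - gm) ** 2)
    df_err = a * b * (s - 1)
    return {
        "ss_total": float(ss_total),
        "ss_subject": 0.0,
        FACTORS[0]: (float(ss_a), float(ss_err), a - 1, df_err),
        FACTORS[1]: (float(ss_b), float(ss_err), b - 1, df_err),
        "modality:level": (float(ss_ab), float(ss_err), (a - 1) * (b - 1), df_err),
    }


def factorial_anova(table: pd.DataFrame, dv: str = "value",
                    subject: str = "subject", design: str = "within",
                    method: str = "auto", alpha: float = 0.05) -> AnovaResult:
    """Modality-by-load factorial ANOVA on a balanced cell table.

    ``table`` needs columns ``subject``, ``modality``, ``level`` and ``dv``
    with exactly one value per subject per cell.  ``method='auto'`` runs the
    parametric decomposition unless Shapiro-Wilk rejects normality of the
    cell residuals at ``alpha``, in which case all values are
    rank-transformed first.  ``design='between'`` pools a single residual
    error term instead of subject-by-effect interactions.
    """
    subjects, a_levels, b_levels = _check_balanced(table, dv, subject)
    y = _cell_array(table, dv, subject, subjects, a_levels, b_levels)

    normality_p = None
    if method not in ("auto", "parametric", "rank"):
        raise ValueError(f"unknown method {method!r}")
    use_rank = method == "rank"
    if method == "auto":
        residuals = (y - y.mean(axis=0, keepdims=True)).ravel()
        if np.ptp(residuals) == 0:
            normality_p = 1.0
        else:
            _, normality_p = normality_check(residuals)
            use_rank = normality_p < alpha

    yw = y
    if use_rank:
        yw = sst.rankdata(y.ravel()).reshape(y.shape)

    decomp = (_within_decomposition(yw) if design == "within"
              else _between_decomposition(yw))
    if design not in ("within", "between"):
        raise ValueError(f"unknown design {design!r}")

    effects = {}
    for name in (FACTORS[0], FACTORS[1], "modality:level"):
        ss_eff, ss_err, df_eff, df_err = decomp[name]
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err if df_err > 0 else np.nan
        if ss_err <= 0:
            f_val, p = (0.0, 1.0) if ss_eff <= 1e-300 else (np.inf, 0.0)
        else:
            f_val = ms_eff / ms_err
            p = float(sst.f.sf(f_val, df_eff, df_err))
        eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        effects[name] = EffectResult(effect=name, ss_effect=ss_eff,
                                     ss_error=ss_err, df_effect=df_eff,
                                     df_error=df_err, F=float(f_val), p=p,
                                     partial_eta_sq=float(eta))
    return AnovaResult(effects=effects,
                       method="rank" if use_rank else "parametric",
                       design=design, n_subjects=len(subjects),
                       cell_counts={FACTORS[0]: len(a_levels),
                                    FACTORS[1]: len(b_levels)},
                       normality_p=normality_p,
                       ss_total=decomp["ss_total"],
                       ss_components={"subject": decomp["ss_subject"]})


# ---------------------------------------------------------------------------
# Duncan's multiple range test

@dataclass
class PosthocResult:
    effect: str
    means: pd.Series                # group -> mean, ascending
    n_per_mean: int
    comparisons: pd.DataFrame       # pairwise table

    def significant_pairs(self) -> list:
        sig = self.comparisons[self.comparisons["significant"]]
        return list(zip(sig["group_1"], sig["group_2"]))


def duncan_critical_range(r: int, df_error: int, ms_error: float, n: int,
                          alpha: float = 0.05) -> float:
    """Critical range for a pair spanning ``r`` ordered means.

    Uses Duncan's special protection level alpha_r = 1 - (1-alpha)^(r-1)
    with the studentized-range distribution.
    """
    alpha_r = 1.0 - (1.0 - alpha) ** (r - 1)
    q = sst.studentized_range.ppf(1.0 - alpha_r, r, df_error)
    return float(q * np.sqrt(ms_error / n))


def duncan_posthoc(table: pd.DataFrame, effect: str, anova: AnovaResult,
                   dv: str = "value", alpha: float = 0.05) -> PosthocResult:
    """Duncan's multiple range test for one ANOVA effect.

    For a main effect the group means collapse over the other factor; for
    the interaction (``"modality:level"``) all six cells are compared.  Uses
    the ANOVA's error mean square and df for that effect, and applies the
    multiple-range protection rule: pairs inside a non-significant span are
    never declared significant.
    """
    if effect not in anova.effects:
        raise KeyError(f"effect {effect!r} not in the fitted model "
                       f"({list(anova.effects)})")
    eff = anova.effects[effect]
    if effect == "modality:level":
        groups = table.groupby([*FACTORS], observed=True)[dv].mean()
        groups.index = [f"{a}/{b}" for a, b in groups.index]
        n_per = anova.n_subjects
    else:
        groups = table.groupby(effect, observed=True)[dv].mean()
        other = FACTORS[1] if effect == FACTORS[0] else FACTORS[0]
        n_per = anova.n_subjects * anova.cell_counts[other]
    means = groups.sort_values()
    k = len(means)
    vals = means.to_numpy()
    names = list(means.index)

    sig = {}
    crit_used = {}
    nonsig_spans: list[tuple[int, int]] = []
    for r in range(k, 1, -1):
        for i in range(0, k - r + 1):
            j = i + r - 1
            crit = duncan_critical_range(r, eff.df_error, eff.ms_error,
                                         n_per, alpha)
            crit_used[(i, j)] = crit
            if any(i >= a and j <= b for a, b in nonsig_spans):
                sig[(i, j)] = False
                continue
            if vals[j] - vals[i] > crit:
                sig[(i, j)] = True
            else:
                sig[(i, j)] = False
                nonsig_spans.append((i, j))

    rows = []
    for (i, j), flag in sorted(sig.items()):
        rows.append({"group_1": names[i], "group_2": names[j],
                     "mean_1": vals[i], "mean_2": vals[j],
                     "diff": vals[j] - vals[i], "rank_span": j - i + 1,
                     "critical_range": crit_used[(i, j)],
                     "significant": flag})
    return PosthocResult(effect=effect, means=means, n_per_mean=n_per,
                         comparisons=pd.DataFrame(rows))


def correlate(x, y) -> tuple[float, float]:
    """Pearson correlation with a two-sided t-based p value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("correlation needs at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = sst.pearsonr(x, y)
    return float(r), float(p)
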