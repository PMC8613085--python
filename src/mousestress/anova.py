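"""Frequentist stage: 2×2 mixed ANOVA, post-hoc tests, alpha correction,
internal consistency and noncentral-F power.

The mixed design has one between-subjects factor (condition, two groups)
and one within-subjects factor (stage, two levels).  With two within
levels the whole ANOVA reduces to closed form via the difference-score /
participant-mean decomposition: the interaction and stage effects are
one-sample/two-sample tests on the per-participant difference scores
d_i = application − baseline, and the condition effect is a two-sample
test on the participant means.  This makes the interaction F exactly the
square of the pooled two-sample t on difference scores — an algebraic
identity that holds for unbalanced groups too.

Effect sizes are partial eta squared, SS_effect / (SS_effect + SS_error)
with the error term of the corresponding stratum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaResult",
    "PosthocResult",
    "MixedAnova",
    "MixedAnovaResults",
    "mixed_anova_2x2",
    "posthoc_between",
    "bonferroni",
    "cronbach_alpha",
    "f_test_power",
]


@dataclass(frozen=True)
class AnovaResult:
    """One effect line of a mixed ANOVA table."""

    effect: str  # condition | stage | interaction
    F: float
    df1: int
    df2: int
    p: float
    eta2_part: float


@dataclass(frozen=True)
class PosthocResult:
    """Two-sided pooled-variance t with Hedges' g effect size."""

    t: float
    df: int
    p: float
    hedges_g: float


class MixedAnova:
    """2×2 mixed-design ANOVA model.

    Parameters
    ----------
    baseline, application : array-like
        Per-participant responses at the two within-subject levels.
    group : array-like
        Between-subject group label per participant (exactly two
        distinct values; unequal group sizes allowed).

    Examples
    --------
    >>> m = MixedAnova([1, 2, 3, 4], [2, 3, 5, 7], ["a", "a", "b", "b"])
    >>> res = m.fit()
    >>> res.anova_table.shape
    (3, 6)
    """

    def __init__(self, baseline, application, group):
        self.baseline = np.asarray(baseline, dtype=float)
        self.application = np.asarray(application, dtype=float)
        self.group = np.asarray(group)
        if not (len(self.baseline) == len(self.application) == len(self.group)):
            raise ValueError("baseline, application and group must align")
        self.levels = sorted(pd.unique(self.group).tolist())
        if len(self.levels) != 2:
            raise ValueError(f"need exactly 2 groups, got {len(self.levels)}")
        for lev in self.levels:
            if np.sum(self.group == lev) < 2:
                raise ValueError(f"group {lev!r} has fewer than 2 participants")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, dv: str, subject: str, stage: str, group: str,
        baseline_level="baseline", application_level="application",
    ) -> "MixedAnova":
        """Build from a long-format table with one row per subject × stage."""
        wide = df.pivot_table(index=[subject, group], columns=stage, values=dv)
        wide = wide.dropna().reset_index()
        return cls(
            baseline=wide[baseline_level],
            application=wide[application_level],
            group=wide[group],
        )

    def fit(self) -> "MixedAnovaResults":
        b, a, g = self.baseline, self.application, self.group
        n = len(b)
        d = a - b          # difference scores carry stage + interaction
        m = (a + b) / 2.0  # participant means carry the condition effect
        g1, g2 = self.levels
        i1, i2 = g == g1, g == g2
        n1, n2 = int(i1.sum()), int(i2.sum())
        df2 = n - 2

        def one_way_ss(x: np.ndarray) -> tuple[float, float]:
            """(between-group SS, within-group SS) of a 2-group one-way layout."""
            xb = x.mean()
            ss_b = n1 * (x[i1].mean() - xb) ** 2 + n2 * (x[i2].mean() - xb) ** 2
            ss_w = ((x[i1] - x[i1].mean()) ** 2).sum() + ((x[i2] - x[i2].mean()) ** 2).sum()
            return float(ss_b), float(ss_w)

        def effect(name: str, ss_eff: float, ss_err: float) -> AnovaResult:
            ms_err = ss_err / df2
            F = ss_eff / ms_err if ms_err > 0 else (np.inf if ss_eff > 0 else 0.0)
            p = float(stats.f.sf(F, 1, df2)) if np.isfinite(F) else 0.0
            denom = ss_eff + ss_err
            eta = ss_eff / denom if denom > 0 else 0.0
            return AnovaResult(name, float(F), 1, df2, p, float(eta))

        # On the response scale, within-stratum SS are half the SS on d.
        ss_int_d, ss_err_d = one_way_ss(d)
        # Stage SS uses the overall (weighted) mean difference score.
        ss_stage = n * d.mean() ** 2 / 2.0
        interaction = effect("interaction", ss_int_d / 2.0, ss_err_d / 2.0)
        stage = effect("stage", ss_stage, ss_err_d / 2.0)
        ss_cond_m, ss_err_m = one_way_ss(m)
        condition = effect("condition", 2.0 * ss_cond_m, 2.0 * ss_err_m)
        return MixedAnovaResults(self, condition, stage, interaction)


class MixedAnovaResults:
    """Fitted effects of a :class:`MixedAnova`; ``summary()`` prints the table."""

    def __init__(self, model: MixedAnova, condition, stage, interaction):
        self.model = model
        self.condition: AnovaResult = condition
        self.stage: AnovaResult = stage
        self.interaction: AnovaResult = interaction

    @property
    def effects(self) -> dict[str, AnovaResult]:
        return {
            "condition": self.condition,
            "stage": self.stage,
            "interaction": self.interaction,
        }

    @property
    def anova_table(self) -> pd.DataFrame:
        rows = [
            {
                "effect": r.effect,
                "F": r.F,
                "df1": r.df1,
                "df2": r.df2,
                "p": r.p,
                "eta2_part": r.eta2_part,
            }
            for r in self.effects.values()
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["2x2 mixed ANOVA (between: condition, within: stage)", ""]
        for r in self.effects.values():
            lines.append(
                f"{r.effect:>12}: F({r.df1}, {r.df2}) = {r.F:.2f}, "
                f"p = {r.p:.4f}, eta2_part = {r.eta2_part:.3f}"
            )
        return "\n".join(lines)


def mixed_anova_2x2(
    baseline, application, group
) -> tuple[AnovaResult, AnovaResult, AnovaResult]:
    """Condition, stage and interaction effects of the 2×2 mixed design."""
    res = MixedAnova(baseline, application, group).fit()
    return res.condition, res.stage, res.interaction


def posthoc_between(group_a, group_b) -> PosthocResult:
    """Two-sided pooled-variance t-test between two groups with Hedges' g.

    g = (mean_b − mean_a) / s_pooled × J with the small-sample correction
    J = 1 − 3/(4·df − 1).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / df
    diff = b.mean() - a.mean()
    if sp2 == 0:
        if diff == 0:
            return PosthocResult(t=0.0, df=df, p=1.0, hedges_g=0.0)
        raise ValueError("zero pooled variance with unequal means")
    t = diff / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * float(stats.t.sf(abs(t), df))
    J = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = diff / np.sqrt(sp2) * J
    return PosthocResult(t=float(t), df=df, p=p, hedges_g=float(g))


def bonferroni(alpha: float, m: int) -> float:
    """Bonferroni-corrected alpha level, rounded to 4 decimals for reporting."""
    if m < 1:
        raise ValueError("m must be at least 1")
    return round(alpha / m, 4)


def cronbach_alpha(items) -> float:
    """Cronbach's alpha of a participants × items score matrix.

    alpha = k/(k−1) · (1 − Σ item variances / variance of item sums),
    with population (n) variances.
    """
    X = np.asarray(items, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 participants and 2 items")
    k = X.shape[1]
    item_vars = X.var(axis=0)
    total_var = X.sum(axis=1).var()
    if total_var == 0:
        raise ValueError("zero total-score variance")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def f_test_power(alpha: float, n_total: int, eta2: float) -> float:
    """Power of the F(1, N−2) test at effect size eta2_part.

    Uses the fixed-effects noncentral-F formulation with noncentrality
    λ = N · eta2 / (1 − eta2), i.e. λ = N·f² with Cohen's
    f² = eta2/(1 − eta2).
    """
    if not (0.0 < eta2 < 1.0):
        raise ValueError("eta2 must lie in (0, 1)")
    if n_total < 3:
        raise ValueError("need N >= 3")
    lam = n_total * eta2 / (1.0 - eta2)
    df2 = n_total - 2
    f_crit = stats.f.isf(alpha, 1, df2)
    return float(stats.ncf.sf(f_crit, 1, df2, lam))
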