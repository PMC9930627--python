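"""Group-level statistics shared by all analysis stages.

One-sample t tests against chance, Wilcoxon signed-rank tests (exact by
enumeration for small n), Bonferroni adjustment, a 2x2 repeated-measures
ANOVA with partial eta squared, and univariate ROI condition contrasts.

Conventions
-----------
* ``tail="one"`` always means "greater than the null value", matching the
  one-tailed tests against chance or zero used throughout the analyses;
  ``tail="two"`` is two-sided (used for pairwise contrasts).
* The signed-rank test drops zero differences (Wilcoxon's convention) and
  ranks ties with midranks.  For n <= 12 remaining differences the p-value
  is exact, from the full enumeration of the 2^n sign assignments; above
  that a normal approximation with continuity and tie correction is used.
* Degenerate inputs (zero variance, all-zero differences) return flagged
  results instead of raising, so batch runs over many ROIs complete.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .labels import CONDITIONS

EXACT_SIGNED_RANK_MAX_N = 12


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    tail: str
    df: float | None = None
    flagged: bool = False
    note: str = ""
    significant_bonferroni: bool | None = None
    alpha_corrected: float | None = None

    def with_bonferroni(self, m: int, alpha: float = 0.05) -> "TestResult":
        corrected = bonferroni_alpha(alpha, m)
        return replace(
            self,
            significant_bonferroni=bool(self.p < corrected),
            alpha_corrected=corrected,
        )


@dataclass(frozen=True)
class AnovaEffect:
    F: float
    df: tuple[int, int]
    p: float
    partial_eta_sq: float


@dataclass(frozen=True)
class AnovaResult:
    factor_a: AnovaEffect
    factor_b: AnovaEffect
    interaction: AnovaEffect
    factor_names: tuple[str, str] = ("A", "B")

    def effects(self) -> dict[str, AnovaEffect]:
        return {
            self.factor_names[0]: self.factor_a,
            self.factor_names[1]: self.factor_b,
            f"{self.factor_names[0]} x {self.factor_names[1]}": self.interaction,
        }


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Bonferroni-corrected alpha level: alpha / m (e.g. 0.05/8 = 0.00625)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def one_sample_t_vs_chance(
    values, chance: float = 0.5, tail: str = "one"
) -> TestResult:
    """One-sample t test of accuracies (or any values) against chance.

    With zero between-subject variance the t statistic is undefined; the
    result is flagged, with p forced to 0 (mean above chance, one-tailed)
    or 1 by the sign convention.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    diffs = values - chance
    df = values.size - 1
    if np.std(diffs, ddof=1) == 0:
        mean = float(np.mean(diffs))
        if mean == 0:
            return TestResult(0.0, 1.0, tail, df=df, flagged=True,
                              note="zero variance, mean at chance")
        p = 0.0 if (mean > 0 or tail == "two") else 1.0
        return TestResult(float(np.sign(mean)) * np.inf, p, tail, df=df,
                          flagged=True, note="zero variance")
    alternative = "greater" if tail == "one" else "two-sided"
    t, p = stats.ttest_1samp(values, chance, alternative=alternative)
    return TestResult(float(t), float(p), tail, df=df)


def _signed_rank_exact_p(ranks: np.ndarray, w_plus: float, tail: str) -> float:
    n = len(ranks)
    masks = (np.arange(2 ** n)[:, None] >> np.arange(n)) & 1  # (2^n, n)
    w_all = masks @ ranks
    p_ge = float(np.mean(w_all >= w_plus - 1e-12))
    p_le = float(np.mean(w_all <= w_plus + 1e-12))
    if tail == "one":
        return p_ge
    return min(1.0, 2.0 * min(p_ge, p_le))


def signed_rank_test(values, null_value: float = 0.0, tail: str = "one") -> TestResult:
    """Wilcoxon signed-rank test of paired differences against a null value.

    The statistic is W+, the sum of midranks of positive differences after
    dropping exact zeros.  Exact p by enumeration for n <= 12; normal
    approximation with continuity and tie corrections above.
    """
    d = np.asarray(values, dtype=float) - null_value
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(0.0, 1.0, tail, flagged=True,
                          note="all differences zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_SIGNED_RANK_MAX_N:
        p = _signed_rank_exact_p(ranks, w_plus, tail)
        return TestResult(w_plus, p, tail)
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts ** 3 - tie_counts).sum() / 48.0
    sd = np.sqrt(var)
    if tail == "one":
        z = (w_plus - mu - 0.5) / sd
        p = float(stats.norm.sf(z))
    else:
        z = (abs(w_plus - mu) - 0.5) / sd
        p = float(2 * stats.norm.sf(z))
    return TestResult(w_plus, min(1.0, p), tail)


def rm_anova_2x2(data, factor_names: tuple[str, str] = ("A", "B")) -> AnovaResult:
    """2x2 repeated-measures ANOVA from a (n_subjects, 2, 2) array.

    Explicit within-subject sums-of-squares decomposition; each effect is
    tested against its own subject-by-effect interaction error term, and
    partial eta squared is SS_effect / (SS_effect + SS_error).
    """
    y = np.asarray(data, dtype=float)
    if y.ndim != 3 or y.shape[1:] != (2, 2):
        raise ValueError("data must have shape (n_subjects, 2, 2)")
    if np.isnan(y).any():
        raise ValueError("design must be complete (no missing cells)")
    n = y.shape[0]
    if n < 3:
        raise ValueError("need >= 3 subjects")
    grand = y.mean()
    m_s = y.mean(axis=(1, 2))            # subject means
    m_a = y.mean(axis=(0, 2))            # factor A level means
    m_b = y.mean(axis=(0, 1))            # factor B level means
    m_ab = y.mean(axis=0)                # cell means (2, 2)
    m_as = y.mean(axis=2)                # (n, 2)
    m_bs = y.mean(axis=1)                # (n, 2)

    ss_a = n * 2 * ((m_a - grand) ** 2).sum()
    ss_b = n * 2 * ((m_b - grand) ** 2).sum()
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_as = 2 * ((m_as - m_a[None, :] - m_s[:, None] + grand) ** 2).sum()
    ss_bs = 2 * ((m_bs - m_b[None, :] - m_s[:, None] + grand) ** 2).sum()
    resid = (
        y
        - m_ab[None, :, :]
        - m_as[:, :, None]
        - m_bs[:, None, :]
        + m_a[None, :, None]
        + m_b[None, None, :]
        + m_s[:, None, None]
        - grand
    )
    ss_abs = (resid ** 2).sum()

    df_err = n - 1

    def effect(ss_eff: float, ss_err: float) -> AnovaEffect:
        ms_eff = ss_eff / 1.0
        ms_err = ss_err / df_err
        if ms_err == 0:
            f = 0.0 if ms_eff == 0 else np.inf
            p = 1.0 if ms_eff == 0 else 0.0
        else:
            f = ms_eff / ms_err
            p = float(stats.f.sf(f, 1, df_err))
        denom = ss_eff + ss_err
        eta = 0.0 if denom == 0 else ss_eff / denom
        return AnovaEffect(F=float(f), df=(1, df_err), p=p,
                           partial_eta_sq=float(eta))

    return AnovaResult(
        factor_a=effect(ss_a, ss_as),
        factor_b=effect(ss_b, ss_bs),
        interaction=effect(ss_ab, ss_abs),
        factor_names=tuple(factor_names),
    )


def univariate_contrast(cohort, alpha: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Univariate ROI analysis: mean beta per condition, plus paired contrasts.

    For every subject, ROI and condition, the beta estimates are averaged
    over voxels and runs; each condition pair is then compared with a paired
    two-tailed t test across subjects, Bonferroni-corrected over ROIs.
    Returns ``(means, tests)`` as tidy DataFrames.
    """
    rows = []
    for subject_id in cohort.subject_ids:
        for roi_name in cohort.roi_names:
            patterns = cohort.get(subject_id, roi_name)
            cond_means = patterns.values.mean(axis=(1, 2))  # (8,)
            for cond in CONDITIONS:
                rows.append(
                    {
                        "subject": subject_id,
                        "roi": roi_name,
                        "person": cond.person.label,
                        "valence": cond.valence.label,
                        "mean_beta": float(cond_means[cond.index]),
                    }
                )
    means = pd.DataFrame(rows)

    n_rois = len(cohort.roi_names)
    alpha_corrected = bonferroni_alpha(alpha, n_rois)
    test_rows = []
    wide = means.pivot_table(
        index=["roi", "subject"],
        columns=["person", "valence"],
        values="mean_beta",
    )
    for roi_name in cohort.roi_names:
        sub = wide.loc[roi_name]
        cols = [(c.person.label, c.valence.label) for c in CONDITIONS]
        for (col_a, col_b) in combinations(cols, 2):
            diffs = sub[col_a].to_numpy() - sub[col_b].to_numpy()
            if np.std(diffs, ddof=1) == 0:
                t_stat, p = 0.0, 1.0
            else:
                t_stat, p = stats.ttest_rel(sub[col_a], sub[col_b])
            test_rows.append(
                {
                    "roi": roi_name,
                    "condition_a": "/".join(col_a),
                    "condition_b": "/".join(col_b),
                    "t": float(t_stat),
                    "df": len(diffs) - 1,
                    "p": float(p),
                    "alpha_corrected": alpha_corrected,
                    "significant": bool(p < alpha_corrected),
                }
            )
    return means, pd.DataFrame(test_rows)
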