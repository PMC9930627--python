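"""Group statistics: t tests, signed-rank, Bonferroni, RM-ANOVA, univariate."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy import stats

from socialmvpa import (
    CohortSpec,
    GeometryParams,
    ROISpec,
    bonferroni_alpha,
    one_sample_t_vs_chance,
    rm_anova_2x2,
    signed_rank_test,
    simulate_cohort,
    univariate_contrast,
)


class TestOneSampleT:
    def test_hand_computed_accuracy_example(self):
        # diffs [.10,.05,.15,.10]: mean .1, sd sqrt(.005/3), t = 4.898979...
        result = one_sample_t_vs_chance([0.60, 0.55, 0.65, 0.60], 0.5)
        expected_t = 0.1 / (np.sqrt(0.005 / 3) / 2)
        assert result.statistic == pytest.approx(expected_t)
        assert result.df == 3
        assert result.p == pytest.approx(
            stats.t.sf(expected_t, 3)
        )

    def test_all_values_at_chance_flagged_degenerate(self):
        result = one_sample_t_vs_chance([0.5, 0.5, 0.5], 0.5)
        assert result.statistic == 0.0
        assert result.p == 1.0
        assert result.flagged

    def test_zero_variance_above_chance_sign_convention(self):
        result = one_sample_t_vs_chance([0.6, 0.6, 0.6], 0.5)
        assert result.flagged
        assert result.p == 0.0

    def test_quarter_chance_supported_for_four_way(self):
        result = one_sample_t_vs_chance([0.3, 0.35, 0.28, 0.4], 0.25)
        assert result.p < 0.05


class TestSignedRank:
    def test_five_positive_differences_exact(self):
        result = signed_rank_test([1, 2, 3, 4, 5], 0.0, tail="one")
        assert result.p == pytest.approx(1.0 / 32.0)
        assert result.statistic == pytest.approx(15.0)

    def test_all_zero_differences_degenerate(self):
        result = signed_rank_test([0.0, 0.0, 0.0], 0.0)
        assert result.p == 1.0
        assert result.flagged

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_p_matches_scipy_on_tie_free_data(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        values = rng.standard_normal(n) + 0.3
        if np.any(values == 0) or len(np.unique(np.abs(values))) < n:
            values = values + rng.uniform(0.001, 0.01, n)
        one = signed_rank_test(values, 0.0, tail="one")
        two = signed_rank_test(values, 0.0, tail="two")
        _, p_one = stats.wilcoxon(values, alternative="greater", method="exact")
        _, p_two = stats.wilcoxon(values, alternative="two-sided", method="exact")
        assert one.p == pytest.approx(p_one)
        assert two.p == pytest.approx(p_two)

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_p_by_independent_enumeration_with_ties(self, seed):
        rng = np.random.default_rng(100 + seed)
        values = rng.integers(-3, 5, 8).astype(float)
        values = values[values != 0]
        if len(values) < 3:
            values = np.array([1.0, 1.0, -2.0, 3.0])
        ranks = stats.rankdata(np.abs(values))
        w_obs = ranks[values > 0].sum()
        count = 0
        total = 0
        for signs in itertools.product([0, 1], repeat=len(values)):
            w = sum(r for s, r in zip(signs, ranks) if s)
            count += w >= w_obs - 1e-12
            total += 1
        result = signed_rank_test(values, 0.0, tail="one")
        assert result.p == pytest.approx(count / total)

    def test_large_n_normal_approximation_close_to_scipy(self):
        rng = np.random.default_rng(1)
        values = rng.standard_normal(30) + 0.4
        result = signed_rank_test(values, 0.0, tail="two")
        _, p_scipy = stats.wilcoxon(
            values, alternative="two-sided", method="approx", correction=True
        )
        assert result.p == pytest.approx(p_scipy, rel=0.05)


class TestBonferroni:
    def test_printed_study_value(self):
        assert bonferroni_alpha(0.05, 8) == pytest.approx(0.00625)

    @pytest.mark.parametrize("m,expected", [(1, 0.05), (5, 0.01)])
    def test_simple_cases(self, m, expected):
        assert bonferroni_alpha(0.05, m) == pytest.approx(expected)

    def test_strictly_decreasing_in_m(self):
        values = [bonferroni_alpha(0.05, m) for m in range(1, 20)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_zero_comparisons_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


def _brute_force_rm_anova(y):
    """Textbook SS decomposition computed from explicit means."""
    n = y.shape[0]
    g = y.mean()
    out = {}
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_s = y.mean(axis=(1, 2))
    ss_a = 2 * n * sum((m - g) ** 2 for m in m_a)
    ss_b = 2 * n * sum((m - g) ** 2 for m in m_b)
    ss_as = 2 * sum(
        (y[s, a, :].mean() - m_a[a] - m_s[s] + g) ** 2
        for s in range(n) for a in range(2)
    )
    ss_bs = 2 * sum(
        (y[s, :, b].mean() - m_b[b] - m_s[s] + g) ** 2
        for s in range(n) for b in range(2)
    )
    m_ab = y.mean(axis=0)
    ss_ab = n * sum(
        (m_ab[a, b] - m_a[a] - m_b[b] + g) ** 2
        for a in range(2) for b in range(2)
    )
    ss_abs = sum(
        (
            y[s, a, b]
            - m_ab[a, b]
            - y[s, a, :].mean()
            - y[s, :, b].mean()
            + m_a[a]
            + m_b[b]
            + m_s[s]
            - g
        )
        ** 2
        for s in range(n) for a in range(2) for b in range(2)
    )
    out["A"] = ss_a / (ss_as / (n - 1))
    out["B"] = ss_b / (ss_bs / (n - 1))
    out["AB"] = ss_ab / (ss_abs / (n - 1))
    return out


class TestRmAnova:
    def test_matches_brute_force_ss_decomposition(self):
        rng = np.random.default_rng(7)
        y = rng.standard_normal((4, 2, 2))
        result = rm_anova_2x2(y)
        expected = _brute_force_rm_anova(y)
        assert result.factor_a.F == pytest.approx(expected["A"])
        assert result.factor_b.F == pytest.approx(expected["B"])
        assert result.interaction.F == pytest.approx(expected["AB"])

    def test_matches_pingouin_two_way_rm(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(11)
        y = rng.standard_normal((10, 2, 2)) + np.array([[0.5, 0], [0, 0]])
        rows = [
            {"subject": s, "A": a, "B": b, "y": y[s, a, b]}
            for s in range(10) for a in range(2) for b in range(2)
        ]
        table = pingouin.rm_anova(
            data=pd.DataFrame(rows), dv="y", within=["A", "B"],
            subject="subject", detailed=True,
        )
        result = rm_anova_2x2(y)
        by_source = table.set_index("Source")
        assert result.factor_a.F == pytest.approx(by_source.loc["A", "F"])
        assert result.factor_b.F == pytest.approx(by_source.loc["B", "F"])
        assert result.interaction.F == pytest.approx(by_source.loc["A * B", "F"])
        assert result.factor_a.p == pytest.approx(by_source.loc["A", "p_unc"])
        assert result.factor_b.p == pytest.approx(by_source.loc["B", "p_unc"])
        # pingouin reports generalized (not partial) eta squared here, so the
        # effect size is cross-checked against the brute-force SS oracle only

    def test_no_mean_difference_between_factor_levels_gives_zero_f(self):
        rng = np.random.default_rng(2)
        base = rng.standard_normal((5, 1, 2))
        offsets = np.array([1.0, -1.0, 0.5, -0.5, 0.0])  # sums to zero
        shifted = base + offsets[:, None, None]
        y = np.concatenate([base, shifted], axis=1)  # A level means identical
        result = rm_anova_2x2(y)
        assert result.factor_a.F == pytest.approx(0.0, abs=1e-12)
        assert result.factor_a.partial_eta_sq == pytest.approx(0.0, abs=1e-12)

    def test_planted_membership_effect_power(self):
        # at the planted effect size the design detects the within-subject
        # effect in nearly every repetition
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(20):
            subject_offset = rng.standard_normal((24, 1, 1)) * 0.05
            y = rng.standard_normal((24, 2, 2)) * 0.05 + subject_offset
            y[:, 0, :] += 0.06  # membership effect
            if rm_anova_2x2(y).factor_a.p < 0.05:
                hits += 1
        assert hits >= 18

    def test_incomplete_design_rejected(self):
        y = np.full((4, 2, 2), np.nan)
        with pytest.raises(ValueError):
            rm_anova_2x2(y)
        with pytest.raises(ValueError):
            rm_anova_2x2(np.zeros((2, 2, 2)))


class TestUnivariate:
    def test_amplitude_matched_cohort_shows_no_reliable_contrasts(self):
        spec = CohortSpec(n_subjects=8, n_runs=4,
                          rois=(ROISpec("PCC", "DN", n_voxels=40),),
                          geometry=GeometryParams(seed=3))
        cohort = simulate_cohort(spec)
        means, tests = univariate_contrast(cohort)
        # decodable structure, but voxel-mean amplitudes stay matched
        assert tests["significant"].mean() < 0.05

    def test_planted_amplitude_offset_detected(self):
        spec = CohortSpec(n_subjects=8, n_runs=4,
                          rois=(ROISpec("PCC", "DN", n_voxels=40),),
                          geometry=GeometryParams(seed=3))
        cohort = simulate_cohort(spec)
        for subject in cohort.subject_ids:
            cohort.get(subject, "PCC").values[0] += 0.5  # boost one condition
        means, tests = univariate_contrast(cohort)
        boosted = tests[
            (tests["condition_a"] == "PresentSelf/Positive")
            | (tests["condition_b"] == "PresentSelf/Positive")
        ]
        assert boosted["significant"].all()

    def test_detection_power_at_planted_effect_size(self):
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(20):
            # per-subject condition means with one offset condition
            a = rng.standard_normal(24) * 0.1
            b = rng.standard_normal(24) * 0.1 + 0.15
            t, p = stats.ttest_rel(a, b)
            hits += p < bonferroni_alpha(0.05, 8)
        assert hits >= 18
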