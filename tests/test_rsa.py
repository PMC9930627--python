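"""Representational similarity analysis: first- and second-order measures."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy import stats

from socialmvpa import (
    CohortSpec,
    GeometryParams,
    Person,
    RatingMatrix,
    ROISpec,
    SimilarityMatrix,
    Valence,
    build_geometry,
    condition_rdm,
    cross_valence_consistency,
    hierarchical_clustering,
    kendall_tau_a,
    model_comparison,
    model_rdm,
    noise_ceiling,
    pairwise_person_accuracies,
    rank_correlation,
    second_order_region_similarity,
    similarity_accuracy_concordance,
    simulate_cohort,
    simulate_roi_patterns,
    within_between_network_effect,
)

from conftest import make_patterns, noiseless_roi


def _sim(values, labels=None, level="four_person"):
    values = np.asarray(values, float)
    labels = labels or tuple(p.label for p in Person)[: len(values)]
    return SimilarityMatrix(values=values, labels=tuple(labels), level=level)


class TestConditionRDM:
    def test_identical_and_reversed_patterns_hand_computed(self):
        # condition 0 averages to [1,2,3]; condition 1 to [3,2,1] -> r = -1;
        # condition 2 repeats condition 0 -> r = +1
        rng = np.random.default_rng(0)
        values = rng.standard_normal((8, 2, 3))
        values[0] = [[1, 2, 3], [1, 2, 3]]
        values[1] = [[3, 2, 1], [3, 2, 1]]
        values[2] = [[0, 1, 2], [2, 3, 4]]  # averages to [1,2,3]
        patterns = make_patterns(values)
        rdm = condition_rdm(patterns)
        assert rdm.values[0, 1] == pytest.approx(-1.0)
        assert rdm.values[0, 2] == pytest.approx(1.0)
        assert np.allclose(np.diag(rdm.values), 1.0)
        assert np.allclose(rdm.values, rdm.values.T)

    def test_lower_triangle_sizes(self):
        rng = np.random.default_rng(0)
        patterns = make_patterns(rng.standard_normal((8, 2, 10)))
        assert condition_rdm(patterns).lower_triangle.shape == (28,)
        assert condition_rdm(patterns, level="four_person").lower_triangle.shape == (6,)

    def test_distance_view_is_one_minus_r(self):
        rng = np.random.default_rng(1)
        rdm = condition_rdm(make_patterns(rng.standard_normal((8, 2, 10))))
        assert np.allclose(rdm.distance, 1.0 - rdm.values)

    def test_zero_variance_pattern_flagged(self):
        values = np.ones((8, 2, 4))
        rdm = condition_rdm(make_patterns(values))
        assert rdm.flagged

    def test_per_run_fisher_z_view_close_to_run_average_for_clean_data(self):
        patterns = simulate_roi_patterns(
            build_geometry(GeometryParams()), noiseless_roi(), 4, seed=0
        )
        a = condition_rdm(patterns, run_average=True)
        b = condition_rdm(patterns, run_average=False)
        assert np.allclose(a.values, b.values, atol=1e-6)


class TestRankCorrelation:
    def test_tau_a_small_example_by_pair_enumeration(self):
        assert kendall_tau_a([1, 2, 3], [1, 3, 2]) == pytest.approx(1.0 / 3.0)
        assert kendall_tau_a([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_tau_a_matches_brute_force_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        x = rng.integers(0, 5, n).astype(float)  # ties likely
        y = rng.integers(0, 5, n).astype(float)
        concordant = discordant = 0
        for i, j in itertools.combinations(range(n), 2):
            prod = (x[i] - x[j]) * (y[i] - y[j])
            concordant += prod > 0
            discordant += prod < 0
        expected = (concordant - discordant) / (n * (n - 1) / 2)
        assert kendall_tau_a(x, y) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_spearman_equals_pearson_on_midranks(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 6, 10).astype(float)
        y = rng.integers(0, 6, 10).astype(float)
        expected = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        assert rank_correlation(x, y, "spearman_rho") == pytest.approx(expected)

    def test_constant_vector_undefined(self):
        assert np.isnan(rank_correlation([1, 1, 1], [1, 2, 3]))

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            rank_correlation([1, 2, 3], [1, 2, 3], "pearson")


class TestCrossValence:
    def test_valence_free_noiseless_geometry_gives_unit_consistency(self):
        spec = CohortSpec(
            n_subjects=3,
            n_runs=4,
            rois=(noiseless_roi(),),
            geometry=GeometryParams(d_valence=0.0, subject_jitter_sd=0.0),
        )
        cohort = simulate_cohort(spec)
        # identical matrices: Spearman is exactly 1; tau-a stays below 1 only
        # by its tie convention (tied pairs count zero, never negative)
        _, per_subject = cross_valence_consistency(cohort, method="spearman_rho")
        assert np.allclose(per_subject["coefficient"], 1.0)
        group_tau, per_tau = cross_valence_consistency(cohort, method="kendall_tau_a")
        for subject in cohort.subject_ids:
            pos = condition_rdm(cohort.get(subject, "clean"), valence=Valence.POSITIVE)
            expected = kendall_tau_a(pos.lower_triangle, pos.lower_triangle)
            got = per_tau.query("subject == @subject")["coefficient"].iloc[0]
            assert got == pytest.approx(expected)

    def test_signal_free_cohort_has_near_zero_mean_consistency(self):
        spec = CohortSpec(
            n_subjects=12,
            n_runs=4,
            rois=(ROISpec("null", "control", n_voxels=30, info_scale=0.0),),
            geometry=GeometryParams(seed=5),
        )
        cohort = simulate_cohort(spec)
        _, per_subject = cross_valence_consistency(cohort)
        # 12 subjects x tau over 6 pairs: SE ~ 0.44/sqrt(12)
        assert abs(per_subject["coefficient"].mean()) < 0.4

    def test_planted_cohort_significant_in_dn_rois(self, small_cohort):
        group, _ = cross_valence_consistency(small_cohort)
        dn = group[group["roi"].isin(["PCC", "vmPFC"])]
        assert (dn["mean_coefficient"] > 0).all()
        assert (dn["p"] < 0.05).all()


class TestNoiseCeiling:
    def test_identical_subjects_reach_unit_ceiling(self):
        base = np.array(
            [[1, 0.5, 0.1, 0.0],
             [0.5, 1, 0.4, 0.2],
             [0.1, 0.4, 1, 0.6],
             [0.0, 0.2, 0.6, 1]]
        )
        mats = [_sim(base) for _ in range(5)]
        ceiling = noise_ceiling(mats)
        assert ceiling.lower == pytest.approx(1.0)
        assert ceiling.upper == pytest.approx(1.0)

    @pytest.mark.parametrize("noise_sd", [0.05, 0.3])
    def test_lower_below_upper_and_ceiling_decreases_with_noise(self, noise_sd):
        rng = np.random.default_rng(0)
        template = rng.standard_normal((4, 4))
        template = (template + template.T) / 2
        np.fill_diagonal(template, 1.0)
        lowers, uppers = [], []
        for _ in range(20):
            mats = []
            for _ in range(6):
                noise = rng.standard_normal((4, 4)) * noise_sd
                noisy = template + (noise + noise.T) / 2
                np.fill_diagonal(noisy, 1.0)
                mats.append(_sim(noisy))
            ceiling = noise_ceiling(mats)
            lowers.append(ceiling.lower)
            uppers.append(ceiling.upper)
        assert np.mean(np.array(uppers) - np.array(lowers)) >= 0
        if noise_sd == 0.05:
            TestNoiseCeiling._low_noise_mean = np.mean(lowers)
        else:
            assert np.mean(lowers) < TestNoiseCeiling._low_noise_mean

    def test_needs_three_subjects(self):
        with pytest.raises(ValueError):
            noise_ceiling([_sim(np.eye(4))] * 2)


def _brute_force_average_linkage(dist):
    """Reference agglomerative UPGMA: exhaustive nearest-pair merging."""
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    merges = []
    d = {frozenset((i, j)): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    next_id = n
    while len(clusters) > 1:
        (a, b), height = min(
            ((tuple(sorted(k)), v) for k, v in d.items()
             if all(x in clusters for x in k)),
            key=lambda kv: (kv[1], kv[0]),
        )
        members_a, members_b = clusters.pop(a), clusters.pop(b)
        merged = members_a + members_b
        merges.append((sorted(members_a), sorted(members_b), height))
        for other, members in clusters.items():
            pairs = [dist[i, j] for i in merged for j in members]
            d[frozenset((next_id, other))] = float(np.mean(pairs))
        clusters[next_id] = merged
        next_id += 1
    return merges


class TestClustering:
    def test_zero_distance_pair_merges_first(self):
        dist = np.array([[0, 0, 5], [0, 0, 5], [5, 5, 0]], float)
        tree = hierarchical_clustering(dist, labels=["A", "B", "C"])
        first_a, first_b, height = tree.merges[0]
        assert {first_a[0], first_b[0]} == {"A", "B"}
        assert height == 0.0

    def test_four_leaf_merges_match_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        raw = rng.uniform(1, 10, (4, 4))
        dist = (raw + raw.T) / 2
        np.fill_diagonal(dist, 0.0)
        tree = hierarchical_clustering(dist, labels=["0", "1", "2", "3"])
        expected = _brute_force_average_linkage(dist)
        assert len(tree.merges) == len(expected)
        for (got_a, got_b, got_h), (exp_a, exp_b, exp_h) in zip(tree.merges, expected):
            got = {frozenset(map(int, got_a)), frozenset(map(int, got_b))}
            exp = {frozenset(exp_a), frozenset(exp_b)}
            assert got == exp
            assert got_h == pytest.approx(exp_h)

    def test_merge_heights_nondecreasing(self):
        rng = np.random.default_rng(4)
        raw = rng.uniform(0.1, 5, (6, 6))
        dist = (raw + raw.T) / 2
        np.fill_diagonal(dist, 0.0)
        tree = hierarchical_clustering(dist)
        heights = [h for _, _, h in tree.merges]
        assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))

    def test_newick_output_parses_with_dendropy(self):
        dist = np.array([[0, 1, 4], [1, 0, 4], [4, 4, 0]], float)
        tree = hierarchical_clustering(dist, labels=["A", "B", "C"])
        newick = tree.to_newick()
        import dendropy

        parsed = dendropy.Tree.get(data=newick, schema="newick")
        assert {leaf.taxon.label for leaf in parsed.leaf_node_iter()} == {"A", "B", "C"}

    def test_asymmetric_input_rejected(self):
        bad = np.array([[0, 1], [2, 0]], float)
        with pytest.raises(ValueError):
            hierarchical_clustering(bad)

    def test_dn_like_cohort_first_split_is_self_vs_other(self, small_cohort):
        from socialmvpa.rsa import average_similarity

        mats = [
            condition_rdm(small_cohort.get(s, "PCC"), level="four_person")
            for s in small_cohort.subject_ids
        ]
        mean = average_similarity(mats)
        dist = mean.distance.copy()
        np.fill_diagonal(dist, 0.0)
        tree = hierarchical_clustering(dist, labels=mean.labels)
        assert set(tree.first_split()) == {
            frozenset({"PresentSelf", "PastSelf"}),
            frozenset({"Mother", "Queen"}),
        }


class TestModelRDM:
    def test_binary_model_entries(self):
        rdm = model_rdm("binary")
        assert rdm.values[Person.PRESENT_SELF, Person.PAST_SELF] == 0
        assert rdm.values[Person.PAST_SELF, Person.MOTHER] == 1
        assert rdm.values[Person.MOTHER, Person.QUEEN] == 0

    def test_graded_model_is_equidistant_spectrum(self):
        rdm = model_rdm("graded")
        near = rdm.values[Person.PRESENT_SELF, Person.PAST_SELF]
        far = rdm.values[Person.PRESENT_SELF, Person.QUEEN]
        assert far == pytest.approx(3 * near)

    def test_behavioral_model_transform_and_degenerate_flag(self):
        flat = RatingMatrix(values=np.full((4, 4), 50.0), subject_id="s")
        assert model_rdm("behavioral", flat).flagged
        varied = np.full((4, 4), 100.0)
        varied[0, 3] = varied[3, 0] = 20.0
        rdm = model_rdm("behavioral", RatingMatrix(values=varied, subject_id="s"))
        assert rdm.values[0, 3] == pytest.approx(0.8)
        assert not rdm.flagged

    def test_behavioral_requires_ratings(self):
        with pytest.raises(ValueError):
            model_rdm("behavioral")


class TestModelComparison:
    def test_data_generated_from_model_correlates_perfectly(self):
        binary = model_rdm("binary")
        neural = _sim(1.0 - binary.values + np.eye(4) * 0.0)
        mats = {"roi": [neural] * 4}
        result = model_comparison(
            mats, {"binary": binary}, [f"s{i}" for i in range(4)],
            method="spearman_rho",
        )
        assert result.table["mean_coefficient"].iloc[0] == pytest.approx(1.0)

    def test_degenerate_model_excluded(self):
        flat = RatingMatrix(values=np.full((4, 4), 50.0), subject_id="s0")
        models = {
            "binary": model_rdm("binary"),
            "behavioral": {f"s{i}": model_rdm("behavioral", flat) for i in range(4)},
        }
        neural = _sim(1.0 - model_rdm("binary").values)
        result = model_comparison(
            {"roi": [neural] * 4}, models, [f"s{i}" for i in range(4)]
        )
        assert result.excluded_models == ("behavioral",)
        assert set(result.table["model"]) == {"binary"}


class TestSecondOrder:
    def test_identical_region_matrices_fully_similar(self):
        rng = np.random.default_rng(0)
        raw = rng.standard_normal((8, 8))
        base = (raw + raw.T) / 2
        np.fill_diagonal(base, 1.0)
        labels = tuple(str(i) for i in range(8))
        mats = {f"r{i}": _sim(base, labels, "eight_condition") for i in range(3)}
        sim, _ = second_order_region_similarity(mats)
        off = sim.to_numpy()[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 1.0)

    def test_two_template_groups_cluster_by_construction(self):
        rng = np.random.default_rng(1)

        def noisy(template):
            noise = rng.standard_normal((8, 8)) * 0.1
            mat = template + (noise + noise.T) / 2
            np.fill_diagonal(mat, 1.0)
            return _sim(mat, tuple(str(i) for i in range(8)), "eight_condition")

        t1 = rng.standard_normal((8, 8))
        t1 = (t1 + t1.T) / 2
        t2 = rng.standard_normal((8, 8))
        t2 = (t2 + t2.T) / 2
        mats = {
            "a1": noisy(t1), "a2": noisy(t1), "a3": noisy(t1),
            "b1": noisy(t2), "b2": noisy(t2), "b3": noisy(t2),
        }
        sim, tree = second_order_region_similarity(mats)
        group_a = ["a1", "a2", "a3"]
        group_b = ["b1", "b2", "b3"]
        within = np.mean(
            [sim.loc[x, y] for g in (group_a, group_b)
             for x, y in itertools.combinations(g, 2)]
        )
        between = np.mean([sim.loc[x, y] for x in group_a for y in group_b])
        assert within > between
        assert set(tree.first_split()) == {frozenset(group_a), frozenset(group_b)}


@pytest.fixture(scope="module")
def anova_cohort():
    """Default 8-ROI geometry, 12 subjects (no decoding needed here)."""
    return simulate_cohort(CohortSpec(n_subjects=12, geometry=GeometryParams(seed=21)))


class TestNetworkAnova:
    def test_planted_cohort_membership_effect_valence_null(self, anova_cohort):
        anova, cells = within_between_network_effect(anova_cohort)
        effects = anova.effects()
        assert effects["membership"].p < 0.05
        assert effects["valence"].p > 0.05
        assert (cells.groupby("valence")["within"].mean()
                > cells.groupby("valence")["between"].mean()).all()

    def test_aggregations_agree_qualitatively(self, anova_cohort):
        a, _ = within_between_network_effect(anova_cohort, aggregation="pairs")
        b, _ = within_between_network_effect(anova_cohort, aggregation="network_balanced")
        assert (a.factor_a.F > 0) == (b.factor_a.F > 0)


class TestConcordance:
    def test_constant_accuracies_undefined(self):
        sim = _sim(np.eye(4))
        accs = {pair: 0.8 for pair in itertools.combinations(Person, 2)}
        assert np.isnan(similarity_accuracy_concordance(sim, accs))

    def test_graded_construction_yields_negative_coefficient(self, small_cohort):
        coefs = []
        for subject in small_cohort.subject_ids:
            patterns = small_cohort.get(subject, "PCC")
            sim = condition_rdm(patterns, level="four_person")
            accs = pairwise_person_accuracies(patterns)
            coefs.append(similarity_accuracy_concordance(sim, accs))
        assert np.nanmean(coefs) < 0
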