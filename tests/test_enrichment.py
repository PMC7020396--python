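"""Ranking, running-sum ES, bootstrap null, z/p scoring and FDR control."""

import numpy as np
import pytest
from scipy import stats

from gwaspath.enrichment import (
    DIRECTIONS,
    RankedGeneList,
    adjust_q,
    apply_min_genes,
    filter_pathways,
    rank_genes,
    running_sum,
    sample_null_es,
    score_pathway,
    score_pathways,
)
from gwaspath.models import GeneAssignment, PathwayDef, PathwayResult


def assignment(gene_id, effect, p=0.05, chrom="chr1", n_linked=1):
    return GeneAssignment(gene_id=gene_id, chromosome=chrom, effect=effect,
                          p_value=p, n_linked_snps=n_linked)


def ranked_from(effects_best_to_worst, direction="increase"):
    return RankedGeneList(
        gene_ids=[f"g{i}" for i in range(len(effects_best_to_worst))],
        effects=np.asarray(effects_best_to_worst, dtype=float),
        direction=direction,
    )


def brute_force_es(effects, hits):
    """Independent prefix-sum oracle: explicit loop, no vector tricks."""
    total_hit = sum(abs(e) for e, h in zip(effects, hits) if h)
    n_miss = sum(1 for h in hits if not h)
    s, prefix = 0.0, []
    for e, h in zip(effects, hits):
        if h:
            s += abs(e) / total_hit if total_hit > 0 else 1.0 / (len(hits) - n_miss)
        else:
            s -= 1.0 / n_miss
        prefix.append(s)
    return max(prefix), prefix


class TestRankGenes:
    def test_increase_puts_largest_first(self):
        a = [assignment("g1", 3.0), assignment("g2", -1.0), assignment("g3", 2.0)]
        assert rank_genes(a, "increase").gene_ids == ["g1", "g3", "g2"]

    def test_decrease_reverses(self):
        a = [assignment("g1", 3.0), assignment("g2", -1.0), assignment("g3", 2.0)]
        assert rank_genes(a, "decrease").gene_ids == ["g2", "g3", "g1"]

    def test_ties_broken_by_gene_id(self):
        a = [assignment(g, 1.0) for g in ("gb", "ga", "gc")]
        assert rank_genes(a, "increase").gene_ids == ["ga", "gb", "gc"]

    def test_rejects_unknown_direction_and_short_input(self):
        with pytest.raises(ValueError):
            rank_genes([assignment("g1", 1.0)] * 2, "sideways")
        with pytest.raises(ValueError):
            rank_genes([assignment("g1", 1.0)], "increase")


class TestRunningSum:
    def test_worked_example(self):
        ranked = ranked_from([3.0, 2.0, 1.0, 0.5])
        rs = running_sum(ranked, {"g0", "g1"})
        assert np.allclose(rs.values, [0.6, 1.0, 0.5, 0.0])
        assert rs.es == pytest.approx(1.0)
        assert rs.peak_rank == 2

    def test_all_but_last_hit_equal_effects(self):
        ranked = ranked_from([1.0, 1.0, 1.0, 1.0, 1.0])
        rs = running_sum(ranked, {"g0", "g1", "g2", "g3"})
        assert rs.es == pytest.approx(1.0)
        assert rs.peak_rank == 4

    def test_single_hit_at_bottom(self):
        n = 5
        ranked = ranked_from([5.0, 4.0, 3.0, 2.0, 1.0])
        rs = running_sum(ranked, {"g4"})
        expected = [-(i + 1) / (n - 1) for i in range(n - 1)] + [0.0]
        assert np.allclose(rs.values, expected)
        assert rs.es == pytest.approx(0.0)  # max prefix is the closing S_N = 0
        assert rs.peak_rank == n

    def test_zero_hit_effects_fall_back_to_uniform(self):
        ranked = ranked_from([2.0, 1.0, 0.0, 0.0])
        rs = running_sum(ranked, {"g2", "g3"})
        assert np.allclose(rs.values, [-0.5, -1.0, -0.5, 0.0])

    def test_rejects_degenerate_hit_sets(self):
        ranked = ranked_from([2.0, 1.0])
        with pytest.raises(ValueError):
            running_sum(ranked, {"absent"})
        with pytest.raises(ValueError):
            running_sum(ranked, {"g0", "g1"})

    def test_closure_and_oracle_agreement_on_random_instances(self, rng):
        for _ in range(300):
            n = int(rng.integers(4, 40))
            effects = np.sort(rng.normal(size=n))[::-1]
            n_hits = int(rng.integers(1, n))
            hit_idx = rng.choice(n, size=n_hits, replace=False)
            hits = np.zeros(n, dtype=bool)
            hits[hit_idx] = True
            ranked = ranked_from(effects.tolist())
            rs = running_sum(ranked, {f"g{i}" for i in hit_idx})
            es_oracle, prefix = brute_force_es(effects.tolist(), hits.tolist())
            assert abs(rs.values[-1]) < 1e-9           # sum closes to zero
            assert rs.es == pytest.approx(es_oracle)
            assert np.allclose(rs.values, prefix)
            assert -1.0 - 1e-9 <= rs.values.min() <= rs.es <= 1.0 + 1e-9


class TestApplyMinGenes:
    def pathway(self, pid, genes):
        return PathwayDef(pid, pid, frozenset(genes))

    def test_counts_after_intersection(self):
        assigned = [assignment(f"g{i}", 1.0) for i in range(3)]
        pw = self.pathway("P1", [f"g{i}" for i in range(10)])  # only 3 assigned
        assert apply_min_genes([pw], assigned, 5) == []
        assert apply_min_genes([pw], assigned, 3) == [pw]

    def test_min_genes_one_keeps_any_overlap(self):
        assigned = [assignment("g1", 1.0)]
        pws = [self.pathway("P1", ["g1", "x"]), self.pathway("P2", ["y"])]
        assert [p.pathway_id for p in apply_min_genes(pws, assigned, 1)] == ["P1"]

    def test_unreachable_min_genes_empties_result(self):
        assigned = [assignment("g1", 1.0), assignment("g2", 1.0)]
        assert apply_min_genes([self.pathway("P1", ["g1", "g2"])], assigned, 3) == []


class TestNullSampling:
    def setup_method(self):
        self.assignments = [
            assignment(f"g{i}", e)
            for i, e in enumerate([3.0, 2.0, 1.0, 0.5, -0.5, -1.0])
        ]
        self.pathways = [
            PathwayDef("P1", "one", frozenset({"g0", "g1"})),
            PathwayDef("P2", "two", frozenset({"g4", "g5"})),
        ]

    def test_same_seed_reproduces_null_matrix(self):
        a = sample_null_es(self.assignments, self.pathways, 50, 7, "increase")
        b = sample_null_es(self.assignments, self.pathways, 50, 7, "increase")
        assert np.array_equal(a, b)

    def test_different_seeds_differ(self):
        a = sample_null_es(self.assignments, self.pathways, 50, 7, "increase")
        b = sample_null_es(self.assignments, self.pathways, 50, 8, "increase")
        assert not np.array_equal(a, b)

    def test_single_replicate_shape(self):
        a = sample_null_es(self.assignments, self.pathways, 1, 0, "increase")
        assert a.shape == (2, 1)

    def test_identical_effects_give_constant_null(self):
        same = [assignment(f"g{i}", 2.0) for i in range(6)]
        null = sample_null_es(same, self.pathways, 20, 3, "increase")
        assert np.allclose(null, null[:, :1])
        z, p, degenerate = score_pathway(float(null[0, 0]), null[0])
        assert degenerate and p == 1.0

    def test_worker_count_does_not_change_results(self):
        a = sample_null_es(self.assignments, self.pathways, 40, 5, "increase", workers=1)
        b = sample_null_es(self.assignments, self.pathways, 40, 5, "increase", workers=2)
        assert np.array_equal(a, b)

    def test_permutation_mode_preserves_multiset(self):
        # with permutation (not bootstrap) every replicate reuses the same
        # effect multiset, so any pathway covering a fixed gene-count has a
        # null ES bounded by the full enumeration of that multiset
        null = sample_null_es(
            self.assignments, self.pathways, 30, 2, "increase", null_mode="permutation"
        )
        assert null.shape == (2, 30)
        assert np.all(null <= 1.0 + 1e-9)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            sample_null_es(self.assignments, self.pathways, 0, 0, "increase")
        with pytest.raises(ValueError):
            sample_null_es(self.assignments, self.pathways, 10, 0, "increase",
                           null_mode="jackknife")


class TestScorePathway:
    def test_es_at_null_mean_gives_half(self):
        null = np.array([0.1, 0.2, 0.3, 0.4])
        z, p, _ = score_pathway(float(null.mean()), null)
        assert (z, p) == (0.0, 0.5)

    def test_standard_normal_quantile(self):
        null = np.array([-1.0, 0.0, 1.0, 2.0])  # mean 0.5
        sd = float(null.std(ddof=1))
        z, p, _ = score_pathway(0.5 + 1.6449 * sd, null)
        assert z == pytest.approx(1.6449)
        assert p == pytest.approx(0.05, abs=1e-4)

    def test_below_all_null_samples(self):
        null = np.array([0.5, 0.6, 0.7])
        z, p, _ = score_pathway(0.1, null)
        assert z < 0 and p > 0.5

    def test_degenerate_sd_branches(self):
        null = np.array([0.3, 0.3, 0.3])
        _, p_low, flag_low = score_pathway(0.2, null)
        _, p_high, flag_high = score_pathway(0.9, null)
        assert flag_low and flag_high
        assert p_low == 1.0
        assert 0 < p_high <= np.finfo(float).tiny

    def test_requires_two_null_samples(self):
        with pytest.raises(ValueError):
            score_pathway(0.5, np.array([0.1]))

    def test_scale_equivariance_of_z(self):
        assignments = [
            assignment(f"g{i}", e)
            for i, e in enumerate([3.0, 1.5, 0.7, -0.2, -1.1, 2.2, 0.1, -3.0])
        ]
        pathways = [PathwayDef("P1", "one", frozenset({"g0", "g5", "g6"}))]
        zs = []
        for c in (1.0, 7.3):
            scaled = [
                assignment(a.gene_id, c * a.effect, a.p_value) for a in assignments
            ]
            res = score_pathways(scaled, pathways, min_genes=1, n_perm=100, seed=11)
            zs.append(res[0].z)
        assert zs[0] == pytest.approx(zs[1], rel=1e-12)


class TestAdjustQ:
    def test_single_p_is_its_own_q(self):
        assert adjust_q([0.03]) == pytest.approx([0.03])

    def test_bh_step_up_hand_example(self):
        assert adjust_q([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_ones(self):
        assert adjust_q([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_matches_statsmodels_bh_below_storey_threshold(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=60)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(adjust_q(p), q_sm)

    def test_storey_pi0_never_exceeds_bh(self, rng):
        from statsmodels.stats.multitest import multipletests

        # mixture: many uniform nulls + some small p → pi0 < 1
        p = np.concatenate([rng.uniform(size=150), rng.uniform(0, 0.001, size=30)])
        q = adjust_q(p)
        _, q_bh, _, _ = multipletests(p, method="fdr_bh")
        assert np.all(q <= q_bh + 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)  # monotone in p-rank

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            adjust_q([0.5, 1.2])


class TestFilterPathways:
    def make_results(self, n=10):
        results = []
        for i in range(n):
            results.append(
                PathwayResult(
                    pathway_id=f"P{i:02d}", pathway_name=f"p{i}", n_genes=5,
                    es_observed=0.5, null_mean=0.3, null_sd=0.1, z=1.0,
                    p_value=(i + 1) / 20, q_value=(i + 1) / 10,
                )
            )
        return results

    def test_q_threshold(self):
        kept = filter_pathways(self.make_results(), "q", 0.3)
        assert [r.pathway_id for r in kept] == ["P00", "P01", "P02"]

    def test_top_n_smallest_p(self):
        kept = filter_pathways(self.make_results(), "top_n", 2)
        assert [r.pathway_id for r in kept] == ["P00", "P01"]

    def test_all_returns_p_sorted(self):
        results = self.make_results()[::-1]
        kept = filter_pathways(results, "all", 0)
        assert [r.pathway_id for r in kept] == sorted(r.pathway_id for r in results)

    def test_top_n_larger_than_results_returns_all(self):
        assert len(filter_pathways(self.make_results(3), "top_n", 10)) == 3


class TestScorePathwaysEndToEnd:
    def test_toy_pathway_scoring(self, toy_dataset):
        from gwaspath.pipeline import analyse_dataset

        results, assignments, tags, n_prob = analyse_dataset(
            toy_dataset, min_genes=2, n_perm=100, seed=5
        )
        assert n_prob == 0
        assert len(assignments) == 4
        by_id = {r.pathway_id: r for r in results}
        assert by_id["TOY_UP"].es_observed == pytest.approx(1.0)
        assert by_id["TOY_UP"].p_value < by_id["TOY_BG"].p_value
        # p must be the upper normal tail of z for every pathway
        for r in results:
            assert r.p_value == pytest.approx(float(stats.norm.sf(r.z)))
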