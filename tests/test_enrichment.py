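import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest
from scipy.stats import norm

from tests.oracles import brute_force_es
from trailkit.enrichment import (
    CategorySkipped,
    OraInput,
    RankedList,
    adjust_pvalues,
    fcs_mean,
    fcs_ttest,
    fcs_wilcoxon,
    gsea_es,
    gsea_pvalue,
    ora,
    run_enrichment,
)
from trailkit.types import (
    ComputationError,
    GeneSet,
    GeneSetCollection,
    ScoreList,
    ValidationError,
)


def make_ranked(n, scores=None, prefix="g"):
    scores = scores if scores is not None else list(range(n, 0, -1))
    return RankedList(ScoreList([(f"{prefix}{i}", s) for i, s in enumerate(scores)]))


def geneset(members, name="cat"):
    return GeneSet(name, "", frozenset(members))


class TestOra:
    def test_closed_form_example(self):
        # N=10, K=4, n=5, k=4: p = C(4,4)C(6,1)/C(10,5) = 6/252
        ref = [f"g{i}" for i in range(10)]
        test = [f"g{i}" for i in range(5)]
        cat = geneset([f"g{i}" for i in range(4)])
        rec = ora(OraInput.from_sets(test, ref), cat, sided="enrichment")
        assert rec.p_raw == pytest.approx(6 / 252, abs=1e-12)
        assert rec.hits == 4
        assert rec.direction == "enriched"

    def test_category_equals_reference_forces_p_one(self):
        ref = [f"g{i}" for i in range(10)]
        rec = ora(OraInput.from_sets(ref[:5], ref), geneset(ref), sided="enrichment")
        assert rec.hits == 5
        assert rec.p_raw == pytest.approx(1.0, abs=1e-12)

    def test_tail_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            N = int(rng.integers(5, 200))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            from scipy.stats import hypergeom

            hg = hypergeom(N, K, n)
            k = int(rng.integers(max(0, n + K - N), min(n, K) + 1))
            total = hg.sf(k - 1) + hg.cdf(k) - hg.pmf(k)
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_exact_against_subset_enumeration(self):
        # enumeration oracle: count test sets of size n with overlap >= k
        N, K, n = 9, 4, 4
        ref = [f"g{i}" for i in range(N)]
        cat = geneset(ref[:K])
        for k in range(0, min(K, n) + 1):
            test = ref[:k] + ref[K : K + (n - k)]
            rec = ora(OraInput.from_sets(test, ref), cat, sided="enrichment")
            count = sum(
                1 for s in combinations(range(N), n) if len(set(s) & set(range(K))) >= k
            )
            exact = Fraction(count, math.comb(N, n))
            assert rec.p_raw == pytest.approx(float(exact), abs=1e-12)

    def test_two_sided_is_doubled_smaller_tail_capped(self):
        ref = [f"g{i}" for i in range(10)]
        test = ref[:5]
        cat = geneset(ref[:4])
        e = ora(OraInput.from_sets(test, ref), cat, "enrichment").p_raw
        d = ora(OraInput.from_sets(test, ref), cat, "depletion").p_raw
        t = ora(OraInput.from_sets(test, ref), cat, "two_sided").p_raw
        assert t == pytest.approx(min(1.0, 2 * min(e, d)), abs=1e-15)

    def test_disjoint_category_skipped(self):
        ref = ["g1", "g2"]
        with pytest.raises(CategorySkipped):
            ora(OraInput.from_sets(["g1"], ref), geneset(["x1"]))

    def test_test_set_must_be_subset(self):
        with pytest.raises(ValidationError, match="subset"):
            OraInput.from_sets(["g1", "zz"], ["g1", "g2"])


class TestGseaEs:
    def test_hand_stepped_weighted_example(self):
        # scores (3,2,1), members ranks 1 and 3, weight_p=1, N_R=4:
        # running sum 3/4, 3/4-1, 3/4-1+1/4 -> ES = 0.75
        r = make_ranked(3, [3.0, 2.0, 1.0])
        es, lead, hits = gsea_es(r, geneset(["g0", "g2"]), weight_p=1.0)
        assert es == pytest.approx(0.75, abs=1e-12)
        assert hits == [1, 3]
        assert lead == ["G0"]

    def test_head_loaded_category_attains_es_one(self):
        r = make_ranked(10)
        es, _, _ = gsea_es(r, geneset([f"g{i}" for i in range(4)]), weight_p=0.0)
        assert es == pytest.approx(1.0, abs=1e-12)

    def test_reversal_negates_unweighted_es(self):
        scores = [5.0, 4.0, 3.0, 2.0, 1.0]
        r = make_ranked(5, scores)
        members = ["g0", "g2"]
        es_fwd, _, _ = gsea_es(r, geneset(members), weight_p=0.0)
        # reversed list: same genes, reversed order (mirror positions)
        rev = RankedList(
            ScoreList([(f"g{4 - i}", s) for i, s in enumerate(scores)])
        )
        es_rev, _, _ = gsea_es(rev, geneset(members), weight_p=0.0)
        assert es_rev == pytest.approx(-es_fwd, abs=1e-12)

    @pytest.mark.parametrize("weight_p", [0.0, 1.0, 1.5])
    def test_matches_brute_force_oracle(self, weight_p):
        rng = np.random.default_rng(11)
        for _ in range(60):
            N = int(rng.integers(5, 60))
            scores = np.sort(rng.normal(size=N))[::-1]
            r = make_ranked(N, scores.tolist())
            h = int(rng.integers(1, N))
            pos = rng.choice(N, size=h, replace=False)
            es, _, _ = gsea_es(r, geneset([f"g{i}" for i in pos]), weight_p)
            oracle = brute_force_es(scores, pos, weight_p)
            assert es == pytest.approx(oracle, abs=1e-12)
            assert abs(es) <= 1 + 1e-12

    def test_full_coverage_rejected(self):
        r = make_ranked(4)
        with pytest.raises(ValidationError, match="whole ranked list"):
            gsea_es(r, geneset([f"g{i}" for i in range(4)]))


class TestGseaPvalue:
    def test_add_one_lower_bound(self):
        r = make_ranked(30)
        rec = gsea_pvalue(r, geneset([f"g{i}" for i in range(5)]), B=200, seed=0)
        assert rec.p_raw >= 1 / 201

    def test_head_loaded_category_is_significant(self):
        r = make_ranked(200)
        rec = gsea_pvalue(r, geneset([f"g{i}" for i in range(15)]), B=1000, seed=3)
        assert rec.p_raw < 0.05
        assert rec.direction == "enriched"

    def test_seeded_determinism(self):
        r = make_ranked(50)
        cat = geneset([f"g{i}" for i in range(0, 50, 7)])
        a = gsea_pvalue(r, cat, B=300, seed=9)
        b = gsea_pvalue(r, cat, B=300, seed=9)
        assert (a.p_raw, a.statistic) == (b.p_raw, b.statistic)

    def test_random_category_calibration(self):
        # quick calibration check; the full 200-repeat sweep runs in the
        # acceptance suite
        rng = np.random.default_rng(5)
        ps = []
        for i in range(40):
            scores = np.sort(rng.normal(size=80))[::-1]
            r = make_ranked(80, scores.tolist())
            pos = rng.choice(80, size=10, replace=False)
            rec = gsea_pvalue(r, geneset([f"g{j}" for j in pos]), B=500, seed=100 + i)
            ps.append(rec.p_raw)
        assert 0.35 < float(np.mean(ps)) < 0.65


class TestFcsWilcoxon:
    def test_top_half_extremal(self):
        r = make_ranked(8)
        members = [f"g{i}" for i in range(4)]
        z_top = fcs_wilcoxon(r, geneset(members)).statistic
        # any other placement of 4 members gives |z| <= z_top
        rng = np.random.default_rng(2)
        for _ in range(20):
            pos = rng.choice(8, size=4, replace=False)
            z = fcs_wilcoxon(r, geneset([f"g{i}" for i in pos])).statistic
            assert abs(z) <= z_top + 1e-12
        assert z_top > 0

    def test_complement_swap_negates_z(self):
        r = make_ranked(10)
        members = [f"g{i}" for i in (0, 3, 4)]
        rest = [f"g{i}" for i in range(10) if i not in (0, 3, 4)]
        z1 = fcs_wilcoxon(r, geneset(members)).statistic
        z2 = fcs_wilcoxon(r, geneset(rest)).statistic
        assert z2 == pytest.approx(-z1, abs=1e-12)

    def test_normal_p_tracks_exact_enumeration(self):
        # N=6, members at ranks {1,2}: compare against the exact permutation
        # two-sided mid-p over all C(6,2) placements; the normal
        # approximation is documented, so agreement is approximate
        r = make_ranked(6)
        rec = fcs_wilcoxon(r, geneset(["g0", "g1"]))
        obs = rec.statistic
        zs = []
        for pos in combinations(range(6), 2):
            w = sum(6 - p for p in pos)
            zs.append((w - 7) / math.sqrt(2 * 4 * 7 / 12.0))
        exact = (
            sum(1 for z in zs if abs(z) > abs(obs) + 1e-12)
            + sum(1 for z in zs if abs(abs(z) - abs(obs)) <= 1e-12)
        ) / len(zs)
        assert rec.p_raw == pytest.approx(2 * norm.sf(abs(obs)), abs=1e-12)
        assert abs(rec.p_raw - exact) < 0.08


class TestFcsTtest:
    def test_hand_applied_welch(self):
        # scores (5,4,1,0), members = top two: t = 4/sqrt(0.25+0.25)
        r = make_ranked(4, [5.0, 4.0, 1.0, 0.0])
        rec = fcs_ttest(r, geneset(["g0", "g1"]))
        assert rec.statistic == pytest.approx(4 / math.sqrt(0.5), abs=1e-12)
        assert rec.direction == "enriched"

    def test_shift_invariance(self):
        r1 = make_ranked(6, [5.0, 4.0, 3.0, 2.0, 1.0, 0.0])
        r2 = make_ranked(6, [15.0, 14.0, 13.0, 12.0, 11.0, 10.0])
        cat = geneset(["g0", "g2"])
        assert fcs_ttest(r1, cat).statistic == pytest.approx(
            fcs_ttest(r2, cat).statistic, abs=1e-12
        )

    def test_degenerate_variance_skipped(self):
        r = make_ranked(6, [1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        with pytest.raises(CategorySkipped, match="degenerate"):
            fcs_ttest(r, geneset(["g0", "g1"]))


class TestFcsMean:
    def test_members_top_k_statistic(self):
        r = make_ranked(8)
        rec = fcs_mean(r, geneset(["g0", "g1", "g2"]), stat="mean", B=200, seed=1)
        assert rec.statistic == pytest.approx(np.mean([8, 7, 6]), abs=1e-12)

    def test_all_equal_scores_give_p_one(self):
        r = make_ranked(6, [2.0] * 6)
        rec = fcs_mean(r, geneset(["g0", "g3"]), stat="mean", B=200, seed=1)
        assert rec.statistic == pytest.approx(2.0)
        assert rec.p_raw == pytest.approx(1.0)

    def test_median_variant(self):
        r = make_ranked(5, [9.0, 7.0, 5.0, 3.0, 1.0])
        rec = fcs_mean(r, geneset(["g0", "g2", "g4"]), stat="median", B=200, seed=1)
        assert rec.statistic == pytest.approx(5.0)


class TestAdjustPvalues:
    def test_bh_worked_case(self):
        assert adjust_pvalues([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04], abs=1e-12
        )

    def test_single_p_unchanged(self):
        assert adjust_pvalues([0.37]) == pytest.approx([0.37], abs=1e-15)

    def test_bonferroni(self):
        assert adjust_pvalues([0.02, 0.5], method="bonferroni") == pytest.approx(
            [0.04, 1.0], abs=1e-12
        )

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            adjust_pvalues([0.5, 1.5])

    def test_bh_monotone_and_dominates_raw(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            adj = np.asarray(adjust_pvalues(p.tolist()))
            assert np.all(adj >= p - 1e-15)
            order = np.argsort(p)
            assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_matches_step_up_oracle(self):
        def oracle(p):
            m = len(p)
            order = np.argsort(p, kind="stable")
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                adj[i] = running
            return adj

        rng = np.random.default_rng(8)
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 30)))
            assert adjust_pvalues(p.tolist()) == pytest.approx(oracle(p), abs=1e-12)


class TestRunEnrichment:
    @pytest.fixture
    def collection(self):
        sets = [geneset([f"g{i}" for i in range(5)], "head")]
        sets.append(geneset([f"g{i}" for i in (7, 11, 15, 19)], "spread"))
        sets.append(geneset(["g1", "g2"], "tiny"))
        return GeneSetCollection(sets)

    def test_single_category_adj_equals_raw(self):
        r = make_ranked(20)
        coll = GeneSetCollection([geneset([f"g{i}" for i in range(5)], "head")])
        records, _ = run_enrichment(r, coll, "wilcoxon", min_size=2)
        assert records[0].p_adj == pytest.approx(records[0].p_raw)

    def test_min_size_filter_matches_direct_count(self, collection):
        r = make_ranked(20)
        records, skipped = run_enrichment(r, collection, "wilcoxon", min_size=3)
        assert len(records) == 2
        assert [name for name, _ in skipped] == ["tiny"]

    def test_planted_category_ranks_first(self, collection):
        r = make_ranked(20)
        records, _ = run_enrichment(r, collection, "wilcoxon", min_size=3)
        assert records[0].category == "head"

    def test_empty_survivors_is_error(self, collection):
        r = make_ranked(20)
        with pytest.raises(ComputationError):
            run_enrichment(r, collection, "wilcoxon", min_size=10, max_size=12)

    def test_ora_mode_uses_reference_sizes(self, collection):
        ref = [f"g{i}" for i in range(20)]
        oin = OraInput.from_sets([f"g{i}" for i in range(4)], ref)
        records, _ = run_enrichment(oin, collection, "ora", min_size=2)
        rec = {r.category: r for r in records}
        assert rec["head"].category_size == 5
        assert rec["head"].hits == 4
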