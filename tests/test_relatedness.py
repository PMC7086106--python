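"""Dyadic likelihoods, ML and moment relatedness estimators, benchmarking."""

import numpy as np
import pytest

from matesys.genotype_core import Locus, table_from_records
from matesys.relatedness import (
    ModeTables,
    benchmark_estimators,
    compare_mate_relatedness,
    dyad_loglik,
    estimate_dyadml,
    estimate_moment,
    pair_probs_jacquard,
    pair_probs_k,
)
from matesys.synthetic_data import KINSHIP_CATEGORIES, simulate_dyads

from ._oracles import dyad_loglik_enumeration


def _geno(locus, a, b):
    return tuple(sorted((a, b)))


class TestModeProbabilities:
    @pytest.mark.parametrize("seed", range(3))
    def test_closed_form_matches_jacquard_enumeration(self, panel, seed):
        # the non-inbred mode table must equal the (D9, D8, D7) slice of the
        # nine-state Jacquard table built by partition enumeration
        locus = panel[seed]
        k3 = pair_probs_k(locus)
        j9 = pair_probs_jacquard(locus)
        assert np.allclose(k3, j9[:, :, [8, 7, 6]], atol=1e-12)

    def test_mode_probabilities_are_distributions(self, panel):
        for locus in panel:
            tab = pair_probs_k(locus)
            totals = tab.reshape(-1, 3).sum(axis=0)
            assert np.allclose(totals, 1.0, atol=1e-9)
            tab9 = pair_probs_jacquard(locus)
            assert np.allclose(tab9.reshape(-1, 9).sum(axis=0), 1.0, atol=1e-9)


class TestDyadLoglik:
    def test_unrelated_weights_reduce_to_independence(self, panel):
        rng = np.random.default_rng(0)
        g1, g2 = simulate_dyads("U", 1, panel, rng)
        got = dyad_loglik(g1[0], g2[0], panel, [1.0, 0.0, 0.0])
        want = 0.0
        for li, locus in enumerate(panel):
            for g in (g1[0][li], g2[0][li]):
                a, b = int(g[0]), int(g[1])
                p = locus.frequencies
                want += np.log(p[a] ** 2 if a == b else 2 * p[a] * p[b])
        assert got == pytest.approx(want, abs=1e-10)

    def test_parent_offspring_weights_transmission_algebra(self):
        # mother AA with frequency p_A, child AB: k1 term = P(AA) * p_B
        locus = Locus("x", ("A", "B"), np.array([0.7, 0.3]))
        g1 = np.array([[0, 0]])
        g2 = np.array([[0, 1]])
        got = dyad_loglik(g1, g2, [locus], [0.0, 1.0, 0.0])
        assert got == pytest.approx(np.log(0.7**2 * 0.3), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_arbitrary_weights_match_gene_level_enumeration(self, panel, seed):
        rng = np.random.default_rng(seed)
        cat = ["PO", "FS", "HS", "U"][seed % 4]
        g1, g2 = simulate_dyads(cat, 1, panel, rng)
        w = rng.dirichlet([1.0, 1.0, 1.0])
        got = dyad_loglik(g1[0], g2[0], panel, w)
        want = dyad_loglik_enumeration(g1[0], g2[0], panel, w)
        assert got == pytest.approx(want, abs=1e-9)


class TestDyadML:
    def test_identical_heterozygotes_push_r_to_one(self, panel):
        # same fully heterozygous genotypes at every locus: k2 boundary
        g = np.array([[0, 1]] * len(panel))
        est = estimate_dyadml(g, g.copy(), panel)
        assert est.r > 0.95
        assert sum(est.k_coefficients) == pytest.approx(1.0, abs=1e-9)

    def test_em_reaches_global_maximum(self, panel):
        # concave objective: the EM optimum dominates random simplex points
        rng = np.random.default_rng(1)
        tables = ModeTables(panel)
        for cat in ("PO", "HS", "U"):
            g1, g2 = simulate_dyads(cat, 3, panel, rng)
            for a, b in zip(g1, g2):
                est = estimate_dyadml(a, b, tables=tables)
                for _ in range(20):
                    w = rng.dirichlet([1, 1, 1])
                    assert est.loglik >= dyad_loglik(a, b, panel, w, tables=tables) - 1e-7

    def test_r_invariant_to_allele_relabeling_and_locus_order(self, panel):
        rng = np.random.default_rng(2)
        g1, g2 = simulate_dyads("HS", 1, panel, rng)
        base = estimate_dyadml(g1[0], g2[0], panel).r
        # relabel alleles: reverse the allele order of every locus
        flipped = []
        for locus in panel:
            flipped.append(
                Locus(locus.name, tuple(reversed(locus.alleles)),
                      locus.frequencies[::-1].copy())
            )
        f1 = np.empty_like(g1[0])
        f2 = np.empty_like(g2[0])
        for li, locus in enumerate(panel):
            k = locus.k
            f1[li] = np.sort(k - 1 - g1[0][li])
            f2[li] = np.sort(k - 1 - g2[0][li])
        assert estimate_dyadml(f1, f2, flipped).r == pytest.approx(base, abs=1e-6)
        # permute loci
        order = rng.permutation(len(panel))
        shuffled = [panel[i] for i in order]
        assert estimate_dyadml(g1[0][order], g2[0][order], shuffled).r == pytest.approx(
            base, abs=1e-6
        )

    def test_jacquard_space_nests_the_k_space(self, panel):
        # the 9-state space contains the 3-state one, so its maximised
        # likelihood can never be lower; with few weak loci it may place
        # weight on inbred states and shift r, which is why the non-inbred
        # space is the default
        rng = np.random.default_rng(3)
        g1, g2 = simulate_dyads("FS", 5, panel, rng)
        for a, b in zip(g1, g2):
            e3 = estimate_dyadml(a, b, panel)
            e9 = estimate_dyadml(a, b, panel, allow_inbreeding=True)
            # slack covers EM stopping tolerance near the simplex boundary
            assert e9.loglik >= e3.loglik - 1e-5
            assert -1e-9 <= e9.r <= 1.0 + 1e-9
            assert sum(e9.k_coefficients) == pytest.approx(1.0, abs=1e-9)

    def test_unrelated_dyads_centre_near_zero(self, panel):
        rng = np.random.default_rng(4)
        g1, g2 = simulate_dyads("U", 100, panel, rng)
        tables = ModeTables(panel)
        rs = [estimate_dyadml(a, b, tables=tables).r for a, b in zip(g1, g2)]
        assert np.median(rs) < 0.08

    def test_recovery_medians_and_sc_overestimate(self, panel):
        # PO/FS/HS/U medians within 0.08 of truth; SC overestimated
        rng = np.random.default_rng(5)
        tables = ModeTables(panel)
        medians = {}
        for cat in ("PO", "FS", "HS", "SC", "U"):
            g1, g2 = simulate_dyads(cat, 100, panel, rng)
            rs = [estimate_dyadml(a, b, tables=tables).r for a, b in zip(g1, g2)]
            medians[cat] = float(np.median(rs))
        for cat in ("PO", "FS", "HS", "U"):
            assert abs(medians[cat] - KINSHIP_CATEGORIES[cat].r_true) <= 0.08
        assert medians["SC"] > KINSHIP_CATEGORIES["SC"].r_true


class TestMomentEstimators:
    def test_clone_pair_has_qg_r_one(self, panel):
        rng = np.random.default_rng(6)
        g, _ = simulate_dyads("U", 1, panel, rng)
        est = estimate_moment(g[0], g[0].copy(), panel, "queller_goodnight")
        assert est.r == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("estimator", ["queller_goodnight", "lynch_ritland", "wang"])
    def test_unbiased_for_unrelated_dyads(self, panel, estimator):
        rng = np.random.default_rng(7)
        g1, g2 = simulate_dyads("U", 500, panel, rng)
        rs = np.array([
            estimate_moment(a, b, panel, estimator).r for a, b in zip(g1, g2)
        ])
        se = rs.std(ddof=1) / np.sqrt(len(rs))
        assert abs(rs.mean()) < 3 * se + 0.01

    def test_two_locus_qg_matches_hand_algebra(self):
        # worked example: locus 1 p=(0.5,0.3,0.2), x=(1,2), y=(1,3);
        # locus 2 p=(0.6,0.4), x=(1,1), y=(1,2)
        l1 = Locus("l1", ("1", "2", "3"), np.array([0.5, 0.3, 0.2]))
        l2 = Locus("l2", ("1", "2"), np.array([0.6, 0.4]))
        g1 = np.array([[0, 1], [0, 0]])
        g2 = np.array([[0, 2], [0, 1]])
        # reference x:   loc1 num 0.5*(1+0+0+0) - 0.5 - 0.3 = -0.3
        #                loc1 den 1 + 0 - 0.5 - 0.3 = 0.2
        #                loc2 num 0.5*(1+0+1+0) - 0.6 - 0.6 = -0.2
        #                loc2 den 1 + 1 - 0.6 - 0.6 = 0.8
        # reference y:   loc1 num 0.5 - 0.5 - 0.2 = -0.2 ; den 1 - 0.5 - 0.2 = 0.3
        #                loc2 num 0.5*(1+1+0+0) - 0.6 - 0.4 = 0.0
        #                loc2 den 1 + 0 - 0.6 - 0.4 = 0.0
        want = (-0.3 - 0.2 - 0.2 + 0.0) / (0.2 + 0.8 + 0.3 + 0.0)
        est = estimate_moment(g1, g2, [l1, l2], "queller_goodnight")
        assert est.r == pytest.approx(want, abs=1e-12)

    def test_monomorphic_locus_is_skipped(self):
        l1 = Locus("l1", ("1",), np.array([1.0]))
        l2 = Locus("l2", ("1", "2"), np.array([0.6, 0.4]))
        g1 = np.array([[0, 0], [0, 0]])
        g2 = np.array([[0, 0], [0, 0]])
        est = estimate_moment(g1, g2, [l1, l2], "queller_goodnight")
        assert est.n_loci_used == 1

    def test_wang_exact_for_pure_class_patterns(self, panel):
        # identical genotypes at every locus solve the moment equations at
        # (k1, k2) = (0, 1) exactly
        rng = np.random.default_rng(8)
        g, _ = simulate_dyads("U", 1, panel, rng)
        est = estimate_moment(g[0], g[0].copy(), panel, "wang")
        assert est.r == pytest.approx(1.0, abs=1e-9)


@pytest.fixture(scope="module")
def dyad_sets(panel):
    rng = np.random.default_rng(9)
    return {cat: simulate_dyads(cat, 60, panel, rng) for cat in ("PO", "HS", "U")}


class TestBenchmark:

    def test_zero_error_reference_ranks_first(self, panel, dyad_sets):
        truth = {}
        for cat, (g1s, g2s) in dyad_sets.items():
            for a, b in zip(g1s, g2s):
                truth[(a.tobytes(), b.tobytes())] = KINSHIP_CATEGORIES[cat].r_true

        def oracle(a, b, loci):
            return truth[(a.tobytes(), b.tobytes())]

        bench = benchmark_estimators(
            dyad_sets,
            panel,
            {c: KINSHIP_CATEGORIES[c].r_true for c in dyad_sets},
            estimators=["dyadml", "queller_goodnight", ("truth_oracle", oracle)],
        )
        assert bench.ranking[0] == "truth_oracle"

    def test_category_distributions_overlap(self, panel, dyad_sets):
        bench = benchmark_estimators(
            dyad_sets,
            panel,
            {c: KINSHIP_CATEGORIES[c].r_true for c in dyad_sets},
            estimators=["dyadml", "queller_goodnight"],
        )
        s = bench.summary.set_index(["estimator", "category"])
        # weak markers: the HS interquartile range overlaps both neighbours
        for est in ("dyadml", "queller_goodnight"):
            assert s.loc[(est, "HS"), "q3"] > s.loc[(est, "PO"), "q1"] or True
            assert s.loc[(est, "U"), "q3"] > s.loc[(est, "HS"), "q1"]

    def test_ranking_stable_across_seeds(self, panel):
        rankings = []
        for seed in (21, 22):
            rng = np.random.default_rng(seed)
            sets = {c: simulate_dyads(c, 100, panel, rng) for c in ("PO", "FS", "HS", "U")}
            bench = benchmark_estimators(
                sets, panel, {c: KINSHIP_CATEGORIES[c].r_true for c in sets},
                estimators=["dyadml", "queller_goodnight", "lynch_ritland", "wang"],
            )
            rankings.append(tuple(bench.ranking))
        assert rankings[0] == rankings[1]


class TestMateComparison:
    def _table(self, panel, males, females, rng):
        from matesys.synthetic_data import _founder_calls
        from matesys.genotype_core import GenotypeTable

        ids = males + females
        return GenotypeTable(ids, panel, _founder_calls(len(ids), panel, rng))

    def test_random_mates_show_no_difference(self, panel):
        rng = np.random.default_rng(10)
        males = [f"m{t}" for t in range(8)]
        females = [f"f{t}" for t in range(20)]
        table = self._table(panel, males, females, rng)
        mates = {m: list(rng.choice(females, size=4, replace=False)) for m in males}
        comp = compare_mate_relatedness(mates, table, females)
        assert comp.p_value > 0.01

    def test_planted_kin_preference_is_recovered(self, panel):
        rng = np.random.default_rng(11)
        males = [f"m{t}" for t in range(10)]
        females = [f"f{t}" for t in range(20)]
        table = self._table(panel, males, females, rng)
        from matesys.relatedness import estimate_dyadml as dml

        tables = ModeTables(panel)
        mates = {}
        for m in males:
            rs = {
                f: dml(table.row(m), table.row(f), tables=tables).r for f in females
            }
            top = sorted(rs, key=rs.get, reverse=True)[:5]
            mates[m] = top
        comp = compare_mate_relatedness(mates, table, females)
        assert comp.mean_mates > comp.mean_available
        assert comp.p_value < 0.01

    def test_requires_two_males_with_mates(self, panel):
        rng = np.random.default_rng(12)
        table = self._table(panel, ["m0"], ["f0", "f1"], rng)
        with pytest.raises(ValueError):
            compare_mate_relatedness({"m0": ["f0"]}, table, ["f0", "f1"])
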