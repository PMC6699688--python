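import numpy as np
import pytest

from linetester.markers import (
    DistanceMatrix,
    allele_frequencies,
    bootstrap_support,
    evanno_delta_k,
    locus_stats,
    nj_tree,
    pic_class,
    simple_matching_distance,
    summarize_panel,
    to_newick,
    upgma_tree,
)
from linetester.simulate import MarkerSimConfig, simulate_markers
from linetester.study_io import GenotypeMatrix


def panel_from_calls(call_rows, loci=None):
    """Build a GenotypeMatrix from {individual: [call, ...]} row dicts."""
    inds = list(call_rows)
    n_loci = len(next(iter(call_rows.values())))
    loci = loci or [f"m{j}" for j in range(n_loci)]
    calls = {}
    for ind, row in call_rows.items():
        for loc, call in zip(loci, row):
            calls[(ind, loc)] = call
    return GenotypeMatrix(inds, loci, calls)


class TestAlleleFrequencies:
    def test_counting(self):
        gm = panel_from_calls({"I1": [("A", "A")], "I2": [("A", "B")]})
        assert allele_frequencies(gm, "m0") == {"A": 0.75, "B": 0.25}

    def test_monomorphic(self):
        gm = panel_from_calls({"I1": [("A", "A")], "I2": [("A", "A")]})
        assert allele_frequencies(gm, "m0") == {"A": 1.0}

    def test_entirely_missing_locus_rejected(self):
        gm = panel_from_calls({"I1": [None], "I2": [None]})
        with pytest.raises(ValueError, match="no typed"):
            allele_frequencies(gm, "m0")

    def test_estimates_within_sampling_error_of_generating_frequencies(self):
        n = 500
        cfg = MarkerSimConfig(n_individuals=n, n_loci=5, n_subpops=1,
                              dh_flags=[False] * n, seed=21)
        gm, truth = simulate_markers(cfg)
        for j, loc in enumerate(gm.locus_ids):
            gen = truth["pop_freqs"][j][0]
            est = allele_frequencies(gm, loc)
            for a, p in enumerate(gen):
                phat = est.get(str(a), 0.0)
                bound = 3 * np.sqrt(p * (1 - p) / (2 * n)) + 1e-12
                assert abs(phat - p) <= bound, (loc, a)


class TestLocusStats:
    def test_biallelic_half_half_closed_forms(self):
        gm = panel_from_calls({"I1": [("A", "A")], "I2": [("B", "B")],
                               "I3": [("A", "B")], "I4": [("A", "B")]})
        st_b = locus_stats(gm, "m0")
        assert st_b.He == pytest.approx(0.5)
        assert st_b.PIC == pytest.approx(0.375)   # Botstein form
        assert st_b.Ho == pytest.approx(0.5)
        st_s = locus_stats(gm, "m0", pic_form="simple")
        assert st_s.PIC == pytest.approx(0.5)

    def test_all_homozygote_panel_has_zero_ho(self):
        gm, _ = simulate_markers(MarkerSimConfig(n_individuals=10, n_loci=6, seed=2))
        for loc in gm.locus_ids:
            assert locus_stats(gm, loc).Ho == 0.0

    def test_unbiased_he_correction_factor(self):
        gm = panel_from_calls({"I1": [("A", "A")], "I2": [("B", "B")]})
        plain = locus_stats(gm, "m0").He
        unbiased = locus_stats(gm, "m0", he_form="unbiased").He
        assert unbiased == pytest.approx(plain * 4 / 3)

    def test_botstein_matches_closed_form_oracle(self):
        # independent route: 1 - S2 - (S2^2 - S4), with S2 = sum p^2, S4 = sum p^4
        rng = np.random.default_rng(5)
        p = rng.dirichlet(np.ones(6))
        counts = np.round(p * 1000).astype(int)
        calls = {}
        k = 0
        for a, c in enumerate(counts):
            for _ in range(c // 2):
                calls[f"I{k}"] = [(str(a), str(a))]
                k += 1
        gm = panel_from_calls(calls)
        st = locus_stats(gm, "m0")
        freqs = np.array(list(allele_frequencies(gm, "m0").values()))
        s2, s4 = (freqs**2).sum(), (freqs**4).sum()
        assert st.PIC == pytest.approx(1 - s2 - (s2**2 - s4), abs=1e-12)

    def test_pic_never_exceeds_he_on_simulated_loci(self):
        gm, _ = simulate_markers(MarkerSimConfig(n_individuals=30, n_loci=40, seed=8))
        for loc in gm.locus_ids:
            st = locus_stats(gm, loc)
            assert st.PIC <= st.He + 1e-12
            if st.N == 1:
                assert st.He == st.PIC == st.Ho == 0

    def test_informativeness_classes(self):
        assert pic_class(0.63) == "highly informative"
        assert pic_class(0.4) == "reasonably informative"
        assert pic_class(0.2) == "slightly informative"


class TestPanelSummary:
    def test_published_panel_summaries(self):
        from linetester.datasets import load_locus_stats

        s = summarize_panel(load_locus_stats())
        assert s["total_alleles"] == 511
        assert round(s["mean_N"], 2) == 5.87
        assert round(s["mean_PIC"], 2) == 0.63
        assert round(s["mean_He"], 2) == 0.68
        assert s["min_PIC"] == 0.24 and s["argmin_PIC"] == "cnu107"
        assert (s["min_N"], s["max_N"]) == (2, 10)

    def test_locus_order_invariance_and_single_locus(self):
        from linetester.datasets import load_locus_stats

        df = load_locus_stats()
        shuffled = df.sample(frac=1, random_state=3)
        assert summarize_panel(df) == summarize_panel(shuffled)
        one = summarize_panel(df.iloc[[0]])
        assert one["mean_PIC"] == df.iloc[0]["PIC"]

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            summarize_panel([])


class TestSimpleMatching:
    def test_enumerated_shared_allele_cases(self):
        gm = panel_from_calls({
            "same": [("A", "B")],
            "half": [("A", "C")],
            "disjoint": [("D", "E")],
            "same2": [("A", "B")],
        })
        d = simple_matching_distance(gm)
        assert d.between("same", "same2") == 0.0
        assert d.between("same", "disjoint") == 1.0
        assert d.between("same", "half") == 0.5

    def test_missing_handled_by_pairwise_deletion(self):
        gm = panel_from_calls({
            "a": [("A", "A"), ("B", "B")],
            "b": [None, ("B", "B")],
        })
        assert simple_matching_distance(gm).between("a", "b") == 0.0

    def test_no_cotyped_loci_rejected(self):
        gm = panel_from_calls({"a": [("A", "A"), None], "b": [None, ("B", "B")]})
        with pytest.raises(ValueError, match="co-typed"):
            simple_matching_distance(gm)

    def test_triangle_inequality_on_random_triples(self):
        gm, _ = simulate_markers(MarkerSimConfig(n_individuals=12, n_loci=25, seed=17))
        d = simple_matching_distance(gm).data
        n = d.shape[0]
        rng = np.random.default_rng(0)
        for _ in range(200):
            i, j, k = rng.choice(n, size=3, replace=False)
            assert d[i, k] <= d[i, j] + d[j, k] + 1e-12


class TestTrees:
    def hand_matrix(self):
        return DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 0.2, 0.8], [0.2, 0, 0.8], [0.8, 0.8, 0]]),
            kind="simple_matching",
        )

    def test_hand_upgma_topology_and_heights(self):
        tree = upgma_tree(self.hand_matrix())
        ab = tree.lca(["A", "B"])
        assert {t.name for t in ab.tips()} == {"A", "B"}
        assert tree.distance(tree.find("A")) == pytest.approx(0.4)  # root height
        assert ab.distance(ab.find("A")) == pytest.approx(0.1)      # merge height

    def test_ultrametric_input_is_a_fixed_point(self):
        ids = ["A", "B", "C", "D"]
        m = np.array([
            [0.0, 0.2, 0.6, 0.6],
            [0.2, 0.0, 0.6, 0.6],
            [0.6, 0.6, 0.0, 0.4],
            [0.6, 0.6, 0.4, 0.0],
        ])
        tree = upgma_tree(DistanceMatrix(ids, m, "simple_matching"))
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                if i < j:
                    got = tree.find(a).distance(tree.find(b))
                    assert got == pytest.approx(m[i, j], abs=1e-12)

    def test_single_leaf_rejected(self):
        with pytest.raises(ValueError):
            upgma_tree(DistanceMatrix(["A"], np.zeros((1, 1)), "euclidean"))

    def test_bootstrap_on_duplicated_loci_gives_full_support(self):
        base = {
            "a": [("A", "A")], "b": [("A", "B")], "c": [("C", "C")], "d": [("C", "D")],
        }
        rows = {ind: calls * 10 for ind, calls in base.items()}
        gm = panel_from_calls(rows)
        tree = bootstrap_support(gm, n_reps=30, seed=1)
        for node in tree.non_tips():
            if node.parent is not None:
                assert node.support == 1.0
        assert "1.00" in to_newick(tree)

    def test_bootstrap_deterministic_given_seed(self):
        gm, _ = simulate_markers(MarkerSimConfig(n_individuals=10, n_loci=15, seed=4))
        t1 = bootstrap_support(gm, n_reps=25, seed=9)
        t2 = bootstrap_support(gm, n_reps=25, seed=9)
        assert to_newick(t1) == to_newick(t2)
        with pytest.raises(ValueError, match="seed"):
            bootstrap_support(gm, n_reps=5, seed=None)

    def test_nj_tree_has_all_leaves(self):
        tree = nj_tree(self.hand_matrix())
        assert {t.name for t in tree.tips()} == {"A", "B", "C"}


class TestEvannoDeltaK:
    @staticmethod
    def runs_with_unit_sd(mean):
        d = 1 / np.sqrt(2)
        return [mean - d, mean + d]

    def test_hand_arithmetic(self):
        loglik = {k: self.runs_with_unit_sd(m)
                  for k, m in zip(range(1, 5), (-100, -80, -75, -74))}
        res = evanno_delta_k(loglik)
        assert res.table.loc[2, "delta_k"] == pytest.approx(15.0)
        assert res.table.loc[3, "delta_k"] == pytest.approx(4.0)
        assert res.best_k == 2

    def test_linear_profile_has_zero_second_difference(self):
        loglik = {k: self.runs_with_unit_sd(-100 + 10 * k) for k in range(1, 6)}
        res = evanno_delta_k(loglik)
        inner = res.table["delta_k"].dropna()
        assert np.allclose(inner, 0.0, atol=1e-9)

    def test_zero_sd_at_interior_k_rejected(self):
        loglik = {1: [-100, -99], 2: [-80.0, -80.0], 3: [-75, -74]}
        with pytest.raises(ValueError, match="zero standard deviation"):
            evanno_delta_k(loglik)

    @pytest.mark.parametrize("bad", [
        {1: [-1, -2], 2: [-1, -2]},               # too few K
        {1: [-1, -2], 3: [-1, -2], 4: [-1, -2]},  # non-consecutive
        {1: [-1, -2], 2: [-1], 3: [-1, -2]},      # single run
    ])
    def test_malformed_profiles_rejected(self, bad):
        with pytest.raises(ValueError):
            evanno_delta_k(bad)
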