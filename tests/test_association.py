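import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from linetester.anova import lt_anova
from linetester.association import (
    association_matrix,
    cross_distance_lookup,
    pca_variance_shares,
    pearson_correlation,
    phenotypic_distance,
)
from linetester.combining import estimate_gca_sca
from linetester.heterosis import heterosis, heterosis_significance
from linetester.markers import DistanceMatrix
from linetester.simulate import TrialSimConfig, simulate_trial
from linetester.study_io import EntryMeans, TrialDesign, entry_means


def make_means(trait, values):
    return EntryMeans(trait, dict(values), {k: 1 for k in dict(values)})


class TestPhenotypicDistance:
    def test_identical_profiles_give_zero(self):
        means = {
            "t1": make_means("t1", {"A": 3.0, "B": 3.0, "C": 9.0}),
            "t2": make_means("t2", {"A": 5.0, "B": 5.0, "C": 1.0}),
        }
        d = phenotypic_distance(means, ["A", "B", "C"])
        assert d.between("A", "B") == 0.0

    def test_two_entry_two_trait_hand_case(self):
        # two entries one (population) SD apart in each trait: z-scores are
        # +/-1, per-trait difference 2, distance sqrt(4 + 4) = 2*sqrt(2)
        means = {
            "t1": make_means("t1", {"A": 10.0, "B": 20.0}),
            "t2": make_means("t2", {"A": 5.0, "B": 1.0}),
        }
        d = phenotypic_distance(means, ["A", "B"])
        assert d.between("A", "B") == pytest.approx(2 * np.sqrt(2))

    def test_affine_rescaling_invariance_under_standardization(self):
        rng = np.random.default_rng(3)
        raw = rng.normal(50, 5, size=(10, 4))
        entries = [f"P{i}" for i in range(10)]
        m1 = {f"t{j}": make_means(f"t{j}", dict(zip(entries, raw[:, j]))) for j in range(4)}
        m2 = {f"t{j}": make_means(f"t{j}", dict(zip(entries, 100 * raw[:, j] - 7)))
              for j in range(4)}
        d1 = phenotypic_distance(m1, entries)
        d2 = phenotypic_distance(m2, entries)
        assert d1.data == pytest.approx(d2.data, abs=1e-9)

    def test_zero_variance_trait_dropped_with_warning(self):
        means = {
            "flat": make_means("flat", {"A": 1.0, "B": 1.0, "C": 1.0}),
            "ok": make_means("ok", {"A": 1.0, "B": 2.0, "C": 3.0}),
        }
        with pytest.warns(UserWarning, match="flat"):
            d = phenotypic_distance(means, ["A", "B", "C"])
        assert d.between("A", "C") > 0

    def test_mean_distance_magnitude_for_standard_vectors(self):
        # E||z1 - z2|| ~ sqrt(2 * n_traits) for independent standard traits
        rng = np.random.default_rng(11)
        entries = [f"P{i}" for i in range(26)]
        means = {
            f"t{j}": make_means(f"t{j}", dict(zip(entries, rng.normal(size=26))))
            for j in range(16)
        }
        d = phenotypic_distance(means, entries)
        upper = d.data[np.triu_indices(26, 1)]
        assert upper.mean() == pytest.approx(np.sqrt(32), abs=0.5)


@pytest.fixture(scope="module")
def matrix():
    ids = [f"L{i}" for i in range(1, 21)] + [f"T{j}" for j in range(1, 7)]
    rng = np.random.default_rng(0)
    m = rng.uniform(0.3, 1.0, size=(26, 26))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    return DistanceMatrix(ids, m, "simple_matching")


class TestCrossDistanceLookup:

    def test_full_design_gives_120_values(self, matrix):
        design = TrialDesign([f"L{i}" for i in range(1, 21)],
                             [f"T{j}" for j in range(1, 7)], 3)
        v = cross_distance_lookup(matrix, design.cross_ids())
        assert len(v) == 120
        assert v["L1 x T1"] == matrix.between("L1", "T1")

    def test_self_cross_is_zero(self, matrix):
        assert cross_distance_lookup(matrix, [("L1", "L1")]).iloc[0] == 0.0

    def test_label_based_access_survives_reordering(self, matrix):
        perm = np.random.default_rng(1).permutation(26)
        ids2 = [matrix.ids[i] for i in perm]
        m2 = matrix.data[np.ix_(perm, perm)]
        d2 = DistanceMatrix(ids2, m2, "simple_matching")
        crosses = [("L3", "T2"), ("L10", "T6")]
        pd.testing.assert_series_equal(
            cross_distance_lookup(matrix, crosses), cross_distance_lookup(d2, crosses))

    def test_missing_parent_rejected(self, matrix):
        with pytest.raises(KeyError, match="Z9"):
            cross_distance_lookup(matrix, [("Z9", "T1")])


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        res = pearson_correlation(x, 2 * x + 1)
        assert res.r == 1.0 and res.p == 0.0

    def test_orthogonal_after_centring(self):
        x = np.array([-1.0, 0.0, 1.0, 0.0])
        y = np.array([0.0, 1.0, 0.0, -1.0])
        assert pearson_correlation(x, y).r == pytest.approx(0.0, abs=1e-15)

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=120), rng.normal(size=120)
        res = pearson_correlation(x, y)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert res.r == pytest.approx(r_ref, abs=1e-12)
        assert res.p == pytest.approx(p_ref, rel=1e-9)
        assert res.t == pytest.approx(res.r * np.sqrt(118 / (1 - res.r**2)))

    def test_affine_invariance_and_sign_flip(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=50), rng.normal(size=50)
        base = pearson_correlation(x, y).r
        assert pearson_correlation(3 * x + 2, y).r == pytest.approx(base)
        assert pearson_correlation(-3 * x + 2, y).r == pytest.approx(-base)

    @pytest.mark.parametrize("x,y,err", [
        ([1, 2], [1, 2], "3 pairs"),
        ([1, 1, 1], [1, 2, 3], "zero variance"),
        ([1, np.nan, 3], [1, 2, 3], "non-finite"),
    ])
    def test_invalid_inputs_rejected(self, x, y, err):
        with pytest.raises(ValueError, match=err):
            pearson_correlation(np.array(x, float), np.array(y, float))


def sca_driven_association(seed, gd_rng=None):
    """One simulated trial with SCA-driven heterosis plus an independent GD."""
    cfg = TrialSimConfig(var_gca_line=4.0, var_gca_tester=4.0, var_sca=30.0,
                         var_error=2.0, seed=seed)
    design, records, _ = simulate_trial(cfg)
    anova = lt_anova(records, design, "y")
    cm = entry_means([r for r in records if r.role == "cross"], "y")
    pm = entry_means([r for r in records if r.role in ("line_parent", "tester_parent")], "y")
    het = heterosis_significance(heterosis(cm, pm, design), anova.error_ms,
                                 design.r, anova.error_df)
    sca = estimate_gca_sca(cm, design)
    labels = [design.cross_label(li, tj) for li, tj in design.cross_ids()]
    gd_rng = gd_rng or np.random.default_rng(seed + 10_000)
    gd = pd.Series(gd_rng.uniform(0.4, 1.0, size=len(labels)), index=labels)
    return design, het, sca, gd


class TestAssociationMatrix:
    def test_sca_correlates_with_heterosis_under_nonadditive_architecture(self):
        design, het, sca, gd = sca_driven_association(seed=1)
        out = association_matrix(het, sca, design, gd_per_cross=gd)
        row = out[(out.x == "SCA") & (out.y == "MPH")].iloc[0]
        assert row.n == 120
        assert row.r > 0.5 and row.sig == "**"

    def test_independent_gd_is_uncorrelated(self):
        rs = []
        for seed in range(8):
            design, het, sca, gd = sca_driven_association(seed=seed)
            out = association_matrix(het, sca, design, gd_per_cross=gd)
            rs.append(out[(out.x == "GD") & (out.y == "MPH")].iloc[0].r)
        assert abs(np.mean(rs)) < 0.1

    def test_grid_layout_and_pairwise_deletion(self):
        design, het, sca, gd = sca_driven_association(seed=2)
        het.loc[het.index[0], "MPH_pct"] = np.nan
        pdv = gd * 0.5 + 3
        out = association_matrix(het, sca, design, gd_per_cross=gd, pd_per_cross=pdv)
        assert [tuple(x) for x in out[["x", "y"]].to_numpy()] == [
            ("GD", "MPH"), ("GD", "BPH"), ("GD", "SCA"),
            ("PD", "MPH"), ("PD", "BPH"), ("PD", "SCA"),
            ("SCA", "MPH"), ("SCA", "BPH")]
        assert out[(out.x == "GD") & (out.y == "MPH")].iloc[0].n == 119
        assert out[(out.x == "GD") & (out.y == "SCA")].iloc[0].n == 120

    def test_constant_distance_vector_rejected(self):
        design, het, sca, gd = sca_driven_association(seed=3)
        with pytest.raises(ValueError, match="zero variance"):
            association_matrix(het, sca, design, gd_per_cross=gd * 0 + 0.8)


class TestPCAShares:
    def test_perfectly_correlated_traits_load_on_pc1(self):
        entries = [f"P{i}" for i in range(8)]
        v = np.arange(8.0)
        means = {
            "a": make_means("a", dict(zip(entries, v))),
            "b": make_means("b", dict(zip(entries, 3 * v + 1))),
        }
        shares = pca_variance_shares(means, entries)
        assert shares[0] == pytest.approx(1.0)

    def test_independent_traits_share_roughly_equally(self):
        rng = np.random.default_rng(6)
        entries = [f"P{i}" for i in range(2000)]
        means = {f"t{j}": make_means(f"t{j}", dict(zip(entries, rng.normal(size=2000))))
                 for j in range(4)}
        shares = pca_variance_shares(means, entries)
        assert shares == pytest.approx(np.full(4, 0.25), abs=0.03)

    def test_spectral_contract(self):
        rng = np.random.default_rng(7)
        entries = [f"P{i}" for i in range(20)]
        means = {f"t{j}": make_means(f"t{j}", dict(zip(entries, rng.normal(size=20))))
                 for j in range(5)}
        shares = pca_variance_shares(means, entries)
        assert (np.diff(shares) <= 1e-12).all()
        assert shares.sum() == pytest.approx(1.0)
        assert len(pca_variance_shares(means, entries, n_components=2)) == 2

    def test_single_entry_rejected(self):
        means = {"a": make_means("a", {"P1": 1.0})}
        with pytest.raises(ValueError):
            pca_variance_shares(means, ["P1"])
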