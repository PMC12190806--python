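"""Alpha-diversity estimators, Bray-Curtis, PERMANOVA and ordination.

The PIE tests use an exhaustive pair-count oracle in exact rational
arithmetic; the PERMANOVA and PCoA tests cross-check against independent
implementations (scikit-bio at run time; values from vegan's adonis2 and
cmdscale, computed on the identical reconstructed census matrix, are frozen
here).
"""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from effscape import diversity as dv
from effscape.core import AssemblageTable, ValidationError

# ---------------------------------------------------------------------------
# Hurlbert PIE
# ---------------------------------------------------------------------------


def pie_pair_oracle(counts) -> Fraction:
    """Probability two individuals drawn without replacement differ in group,
    by exact enumeration of pairs."""
    n = sum(counts)
    same = sum(Fraction(x * (x - 1), 2) for x in counts)
    total = Fraction(n * (n - 1), 2)
    return 1 - same / total


class TestHurlbertPie:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((10, 10), 100 / 190),
            ((2, 2), Fraction(2, 3)),
            ((5,), 0.0),
            ((1, 1, 1), 1.0),
        ],
    )
    def test_closed_forms(self, counts, expected):
        assert dv.hurlbert_pie(counts) == pytest.approx(float(expected), abs=1e-12)

    def test_matches_pair_count_oracle_on_random_tables(self, rng):
        for _ in range(1000):
            k = int(rng.integers(1, 6))
            counts = rng.integers(0, 12, size=k)
            if counts.sum() < 2:
                continue
            assert dv.hurlbert_pie(counts) == pytest.approx(
                float(pie_pair_oracle(counts.tolist())), abs=1e-12
            )

    def test_permutation_invariance_and_singleton_growth(self):
        assert dv.hurlbert_pie([3, 9, 1]) == dv.hurlbert_pie([9, 1, 3])
        assert dv.hurlbert_pie([10, 1]) > dv.hurlbert_pie([10]) == 0.0

    def test_undefined_below_two(self):
        with pytest.raises(ValidationError):
            dv.hurlbert_pie([1])


class TestPieBootstrap:
    def test_balanced_sample_ci_covers_truth(self):
        est = dv.pie_bootstrap([500, 500], b=1000, seed=7)
        assert est.ci_low <= 0.5 <= est.ci_high
        assert est.ci_high - est.ci_low < 0.05

    def test_degenerate_single_group(self):
        est = dv.pie_bootstrap([100, 0], b=200, seed=1)
        assert est.pie == est.ci_low == est.ci_high == 0.0

    def test_deterministic_under_seed(self):
        a = dv.pie_bootstrap([30, 20, 10], seed=42)
        b = dv.pie_bootstrap([30, 20, 10], seed=42)
        assert a == b

    def test_small_b_warns(self):
        with pytest.warns(UserWarning, match="unstable"):
            dv.pie_bootstrap([10, 10], b=50, seed=0)

    def test_overlap_verdict(self):
        a = dv.DiversityEstimate(0.5, 0.01, 0.45, 0.55, 100)
        b = dv.DiversityEstimate(0.6, 0.01, 0.54, 0.66, 100)
        c = dv.DiversityEstimate(0.8, 0.01, 0.75, 0.85, 100)
        assert dv.compare_estimates(a, b) == "not different"
        assert dv.compare_estimates(a, c) == "different"


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------


def _table(rows, seasons=None):
    rows = np.atleast_2d(rows)
    n = rows.shape[0]
    return AssemblageTable(
        [f"s{i}" for i in range(n)],
        seasons or ["spring"] * n,
        list(range(1, rows.shape[1] + 1)),
        rows,
    )


class TestBrayCurtis:
    @pytest.mark.parametrize(
        "rows,expected",
        [
            ([[3, 1], [3, 1]], 0.0),
            ([[1, 0], [0, 1]], 1.0),
            ([[2, 1], [1, 1]], 0.2),
        ],
    )
    def test_hand_values(self, rows, expected):
        d = dv.bray_curtis(_table(rows))
        assert d[0, 1] == pytest.approx(expected, abs=1e-12)
        assert d[0, 0] == d[1, 1] == 0.0

    def test_all_zero_unit_rejected(self):
        with pytest.raises(ValidationError, match="all-zero"):
            dv.bray_curtis(_table([[1, 2], [0, 0]]))

    def test_proportion_scale_is_row_normalised(self):
        t = _table([[20, 10], [2, 1]])
        assert dv.bray_curtis(t, scale="proportions")[0, 1] == pytest.approx(0.0)
        assert dv.bray_curtis(t, scale="counts")[0, 1] > 0.5


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

# Frozen from vegan 2.7-1 adonis2 (sequential SS, population then season) on
# the identical reconstructed count matrix, Baza-summer dropped.
VEGAN_F_POPULATION_COUNTS = 0.9633664
VEGAN_F_SEASON_COUNTS = 3.7743461
VEGAN_F_POPULATION_REL = 1.071936
VEGAN_F_SEASON_REL = 8.542778


class TestPermanova:
    def test_matches_vegan_on_census_counts(self, table2_clean):
        d = dv.bray_curtis(table2_clean, scale="counts")
        res = dv.permanova(
            d, {"population": table2_clean.sites, "season": table2_clean.seasons},
            n_perm=99, seed=0,
        )
        assert res.f["population"] == pytest.approx(VEGAN_F_POPULATION_COUNTS, rel=1e-6)
        assert res.f["season"] == pytest.approx(VEGAN_F_SEASON_COUNTS, rel=1e-6)
        assert res.df == {"population": 5, "season": 1}
        assert res.residual_df == 4

    def test_matches_vegan_on_census_proportions(self, table2_clean):
        d = dv.bray_curtis(table2_clean, scale="proportions")
        res = dv.permanova(
            d, {"population": table2_clean.sites, "season": table2_clean.seasons},
            n_perm=99, seed=0,
        )
        assert res.f["population"] == pytest.approx(VEGAN_F_POPULATION_REL, rel=1e-6)
        assert res.f["season"] == pytest.approx(VEGAN_F_SEASON_REL, rel=1e-6)

    def test_single_factor_matches_skbio(self, table2_clean):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as sk_permanova

        d = dv.bray_curtis(table2_clean)
        mine = dv.permanova(d, {"season": table2_clean.seasons}, n_perm=99, seed=0)
        theirs = sk_permanova(
            DistanceMatrix(d, ids=[str(i) for i in range(len(d))]),
            grouping=list(table2_clean.seasons),
            permutations=99,
        )
        assert mine.f["season"] == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_identical_groups_give_zero_f(self, rng):
        rows = rng.integers(1, 20, size=(4, 5))
        rows = np.vstack([rows, rows])  # group B duplicates group A exactly
        t = _table(rows, seasons=["spring"] * 4 + ["summer"] * 4)
        d = dv.bray_curtis(t)
        res = dv.permanova(d, {"season": t.seasons}, n_perm=199, seed=0)
        assert res.f["season"] == pytest.approx(0.0, abs=1e-10)
        assert res.p["season"] > 0.95

    def test_separated_clusters_reach_minimum_p(self, rng):
        a = rng.integers(50, 60, size=(10, 3)) * [1, 0, 0] + [0, 1, 1]
        b = rng.integers(50, 60, size=(10, 3)) * [0, 0, 1] + [1, 1, 0]
        t = _table(np.vstack([a, b]), seasons=["spring"] * 10 + ["summer"] * 10)
        d = dv.bray_curtis(t)
        res = dv.permanova(d, {"season": t.seasons}, n_perm=999, seed=3)
        assert res.p["season"] == pytest.approx(1 / 1000)

    def test_unit_order_invariance(self, table2_clean, rng):
        d = dv.bray_curtis(table2_clean)
        perm = rng.permutation(table2_clean.n_units)
        res1 = dv.permanova(
            d, {"population": table2_clean.sites, "season": table2_clean.seasons},
            n_perm=99, seed=0,
        )
        res2 = dv.permanova(
            d[np.ix_(perm, perm)],
            {
                "population": [table2_clean.sites[i] for i in perm],
                "season": [table2_clean.seasons[i] for i in perm],
            },
            n_perm=99, seed=0,
        )
        for term in ("population", "season"):
            assert res1.ss[term] == pytest.approx(res2.ss[term], rel=1e-9)
            assert res1.f[term] == pytest.approx(res2.f[term], rel=1e-9)

    def test_single_level_term_rejected(self):
        t = _table([[1, 2], [2, 1]], seasons=["spring", "spring"])
        with pytest.raises(ValidationError, match="single level"):
            dv.permanova(dv.bray_curtis(t), {"season": t.seasons}, n_perm=99)

    def test_confounded_terms_rejected(self):
        t = _table(np.eye(4, dtype=int) + 1, seasons=["spring"] * 2 + ["summer"] * 2)
        with pytest.raises(ValidationError, match="confounded"):
            dv.permanova(
                dv.bray_curtis(t),
                {"season": t.seasons, "copy": list(t.seasons)},
                n_perm=99,
            )

    def test_sums_of_squares_partition_total(self, table2_clean):
        d = dv.bray_curtis(table2_clean)
        res = dv.permanova(
            d, {"population": table2_clean.sites, "season": table2_clean.seasons},
            n_perm=99, seed=0,
        )
        parts = sum(res.ss.values()) + res.residual_ss
        assert parts == pytest.approx(res.total_ss, rel=1e-9)


# ---------------------------------------------------------------------------
# PCoA and group scores
# ---------------------------------------------------------------------------

VEGAN_PCOA_TWO_AXIS_PCT = 61.13731  # cmdscale on the same Bray-Curtis matrix


class TestPcoa:
    def test_two_units(self):
        res = dv.pcoa(np.array([[0.0, 1.0], [1.0, 0.0]]), k=1)
        assert np.allclose(np.abs(res.coordinates[:, 0]), 0.5)
        assert res.proportions[0] == pytest.approx(1.0)

    def test_equilateral_triangle_splits_evenly(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = dv.pcoa(d, k=2)
        assert res.proportions == pytest.approx([0.5, 0.5])

    def test_euclidean_distances_recovered_exactly(self, rng):
        pts = rng.standard_normal((6, 3))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        res = dv.pcoa(d, k=3)
        c = res.coordinates
        rec = np.sqrt(((c[:, None, :] - c[None, :, :]) ** 2).sum(-1))
        assert np.allclose(rec, d, atol=1e-9)

    def test_matches_skbio_on_census(self, table2_clean):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.ordination import pcoa as sk_pcoa

        d = dv.bray_curtis(table2_clean)
        mine = dv.pcoa(d, k=2)
        theirs = sk_pcoa(DistanceMatrix(d, ids=[str(i) for i in range(len(d))]))
        assert np.allclose(
            np.abs(mine.coordinates), np.abs(theirs.samples.values[:, :2]), atol=1e-8
        )
        assert 100 * mine.proportions.sum() == pytest.approx(
            VEGAN_PCOA_TWO_AXIS_PCT, abs=1e-4
        )

    def test_k_truncated_with_warning(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.warns(UserWarning, match="positive eigenvalues"):
            res = dv.pcoa(d, k=5)
        assert res.coordinates.shape[1] == 1


class TestGroupScores:
    def test_sign_consistency_and_constant_group(self, rng):
        rows = np.array([[9, 1, 5], [8, 2, 5], [1, 9, 5], [2, 8, 5]])
        t = _table(rows)
        res = dv.pcoa(dv.bray_curtis(t, scale="proportions"), k=2)
        with pytest.warns(UserWarning, match="constant"):
            scores = dv.group_scores(res, t)
        # groups 1 and 2 separate along axis 1 with opposite signs
        assert scores[0, 0] * scores[1, 0] < 0
        assert scores[2, 0] == 0.0

    def test_reflection_flips_scores(self, table2_clean):
        res = dv.pcoa(dv.bray_curtis(table2_clean), k=2)
        import warnings as w

        with w.catch_warnings():
            w.simplefilter("ignore")
            scores = dv.group_scores(res, table2_clean)
            reflected = dv.OrdinationResult(
                res.coordinates * np.array([-1.0, 1.0]),
                res.eigenvalues,
                res.proportions,
            )
            scores_r = dv.group_scores(reflected, table2_clean)
        assert np.allclose(scores[:, 0], -scores_r[:, 0], atol=1e-12)
        assert np.allclose(scores[:, 1], scores_r[:, 1], atol=1e-12)


@settings(max_examples=50, deadline=None)
@given(
    st.lists(st.integers(min_value=0, max_value=30), min_size=2, max_size=8).filter(
        lambda c: sum(c) >= 2
    )
)
def test_pie_bounds_property(counts):
    v = dv.hurlbert_pie(counts)
    assert 0.0 <= v <= 1.0 + 1e-12
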