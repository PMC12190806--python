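"""Quantity/quality components, seed shares, GLM deviance, and the
visitation- vs seed-weighted generalisation comparison."""

import numpy as np
import pytest

from effscape import effectiveness as eff
from effscape.core import EffectivenessPoint, SingleVisitRecord, SurveyRecord, ValidationError


def make_surveys(n, minutes, visits_per_survey, group=1, morph="spring"):
    return [
        SurveyRecord(f"p{i}", "d0", morph, minutes, {group: visits_per_survey})
        for i in range(n)
    ]


class TestQtc:
    def test_rate_arithmetic(self):
        # 12 five-minute watches = 1 plant-hour; 6 visits total
        surveys = make_surveys(12, 5.0, 0)
        surveys[0].visits[1] = 6
        assert eff.qtc(surveys, 1, "spring") == pytest.approx(6.0)

    def test_no_visits_zero(self):
        assert eff.qtc(make_surveys(4, 15.0, 0), 1, "spring") == 0.0

    def test_doubling_duration_halves_rate(self):
        a = eff.qtc(make_surveys(10, 5.0, 2), 1, "spring")
        b = eff.qtc(make_surveys(10, 10.0, 2), 1, "spring")
        assert a == pytest.approx(2 * b)

    def test_zero_effort_rejected(self):
        with pytest.raises(ValidationError, match="effort"):
            eff.qtc(make_surveys(3, 5.0, 1, morph="summer"), 1, "spring")


def make_visits(seed_list, group=1, morph="spring", m=20):
    return [
        SingleVisitRecord(f"f{i}", morph, group, s > 0, s, m - s, 0)
        for i, s in enumerate(seed_list)
    ]


class TestQlc:
    def test_mean_over_visited_flowers(self):
        recs = make_visits([3, 5, 0, 0, 0, 0, 0, 0, 0, 0])
        assert eff.qlc(recs, 1, "spring") == pytest.approx(0.8)

    def test_all_failures_zero(self):
        assert eff.qlc(make_visits([0, 0, 0]), 1, "spring") == 0.0

    def test_empty_cell_rejected(self):
        with pytest.raises(ValidationError, match="no single-visit"):
            eff.qlc(make_visits([1]), 2, "spring")

    def test_unbiased_for_two_stage_model(self):
        """QLC estimate is unbiased for f*m*q (bias under 2 SE over replicates)."""
        from effscape import synthetic as syn

        cfg = syn.paper_like(seed=0)
        truth = cfg.qlc["spring"][1].expected_qlc
        ests = []
        for rep in range(200):
            recs = [
                r
                for r in syn.gen_single_visits(cfg, n_flowers=30, seed=1000 + rep)
                if r.group == 1 and r.morph == "spring"
            ]
            ests.append(sum(r.viable_seeds for r in recs) / len(recs))
        ests = np.array(ests)
        se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean() - truth) < 2 * se


class TestEffectiveness:
    def test_product_and_bilinearity(self):
        assert eff.effectiveness(2.0, 3.0) == 6.0
        assert eff.effectiveness(0.0, 9.9) == 0.0
        assert eff.effectiveness(4.0, 3.0) == 2 * eff.effectiveness(2.0, 3.0)

    def test_build_points_omits_groups_without_quality_data(self):
        surveys = make_surveys(12, 5.0, 2, group=1) + make_surveys(12, 5.0, 1, group=2)
        recs = make_visits([4, 2], group=1)
        pts = eff.build_points(surveys, recs, "spring")
        assert [p.group for p in pts] == [1]
        # 24 visits by group 1 over 24 five-minute watches = 2 plant-hours
        assert pts[0].qtc == pytest.approx(12.0)
        assert pts[0].qlc == pytest.approx(3.0)


class TestSeedShares:
    def test_normalisation(self):
        pts = [EffectivenessPoint(1, "spring", 2, 3), EffectivenessPoint(2, "spring", 1, 2)]
        shares = eff.seed_shares(pts, "spring")
        assert [s.share for s in shares] == pytest.approx([0.75, 0.25])
        assert sum(s.share for s in shares) == pytest.approx(1.0)

    def test_single_group(self):
        pts = [EffectivenessPoint(1, "spring", 2, 3), EffectivenessPoint(2, "spring", 0, 5)]
        shares = eff.seed_shares(pts, "spring")
        assert shares[0].share == 1.0

    def test_rescale_invariance(self):
        pts = [EffectivenessPoint(1, "spring", 2, 3), EffectivenessPoint(2, "spring", 4, 1)]
        scaled = [EffectivenessPoint(p.group, p.morph, 10 * p.qtc, p.qlc) for p in pts]
        s1 = [s.share for s in eff.seed_shares(pts, "spring")]
        s2 = [s.share for s in eff.seed_shares(scaled, "spring")]
        assert s1 == pytest.approx(s2)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            eff.seed_shares([EffectivenessPoint(1, "spring", 0, 5)], "spring")


def closed_form_two_level_deviance(s1, n1, s2, n2):
    """-2[l(null) - l(two levels)] from binomial log-likelihoods at the MLEs."""

    def ll(s, n, p):
        out = 0.0
        if s > 0:
            out += s * np.log(p)
        if n - s > 0:
            out += (n - s) * np.log(1 - p)
        return out

    p0 = (s1 + s2) / (n1 + n2)
    l_null = ll(s1, n1, p0) + ll(s2, n2, p0)
    l_full = ll(s1, n1, s1 / n1) + ll(s2, n2, s2 / n2)
    return -2 * (l_null - l_full)


class TestBinomialGlm:
    def test_equal_levels_no_signal(self):
        res = eff.binomial_glm_lrt([10, 10], [20, 20], ["a", "b"])
        assert res.lrt_deviance == pytest.approx(0.0, abs=1e-10)
        assert res.p == pytest.approx(1.0)

    def test_complete_separation_closed_form(self):
        res = eff.binomial_glm_lrt([20, 0], [20, 20], ["a", "b"])
        assert res.lrt_deviance == pytest.approx(-2 * 40 * np.log(0.5), rel=1e-6)

    def test_matches_closed_form_on_random_two_level_inputs(self, rng):
        for _ in range(25):
            n1, n2 = rng.integers(5, 40, size=2)
            s1 = int(rng.integers(1, n1))
            s2 = int(rng.integers(1, n2))
            res = eff.binomial_glm_lrt([s1, s2], [n1, n2], ["a", "b"])
            expected = closed_form_two_level_deviance(s1, n1, s2, n2)
            assert res.lrt_deviance == pytest.approx(expected, abs=1e-8)

    def test_fitted_levels_equal_pooled_proportions(self):
        res = eff.binomial_glm_lrt([5, 12, 3], [10, 20, 30], ["a", "b", "c"])
        inv = lambda z: 1 / (1 + np.exp(-z))
        c = res.coefficients
        assert inv(c["intercept"]) == pytest.approx(0.5, abs=1e-6)
        assert inv(c["intercept"] + c["level[b]"]) == pytest.approx(0.6, abs=1e-6)
        assert inv(c["intercept"] + c["level[c]"]) == pytest.approx(0.1, abs=1e-6)

    def test_single_level_rejected(self):
        with pytest.raises(ValidationError):
            eff.binomial_glm_lrt([1], [2], ["a"])


class TestLargestRemainder:
    def test_exact_apportionment(self, rng):
        for _ in range(50):
            w = rng.random(6)
            total = int(rng.integers(10, 5000))
            alloc = eff.largest_remainder_round(w, total)
            assert alloc.sum() == total
            assert np.all(np.abs(alloc - w / w.sum() * total) < 1.0)


class TestWeightedPieComparison:
    def test_proportional_seeds_not_different(self):
        v = np.array([40, 30, 20, 10])
        est_v, est_s, verdict = eff.weighted_pie_comparison(v, v, seed=0)
        assert est_v.pie == pytest.approx(est_s.pie)
        assert verdict == "not different"

    def test_concentration_lowers_pie(self):
        visits = np.array([25, 25, 25, 25])
        seeds = np.array([97, 1, 1, 1])
        est_v, est_s, verdict = eff.weighted_pie_comparison(visits, seeds, seed=0)
        assert est_s.pie < est_v.pie
        assert verdict == "different"

    def test_verdict_symmetric(self):
        a = np.array([50, 30, 20])
        b = np.array([5, 90, 5])
        _, _, v1 = eff.weighted_pie_comparison(a, b, seed=1)
        _, _, v2 = eff.weighted_pie_comparison(b, a, seed=1)
        assert v1 == v2

    def test_too_few_seeds_rejected(self):
        with pytest.raises(ValidationError):
            eff.weighted_pie_comparison([10, 10], [1, 0], seed=0)
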