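"""Pollination effectiveness: quantity (QTC), quality (QLC), their product,
seed-share attribution, binomial-GLM deviance tests, and the comparison of
visitation- versus effectiveness-weighted generalisation.

A functional group's quantity component is its visitation rate (visits per
plant per hour over timed surveys); its quality component is the mean number
of viable seeds resulting from a single visit to a virgin flower, counting
fruitless visits as zeros.  Effectiveness = QTC x QLC estimates seeds per
plant per hour attributable to the group — its contribution to female
fitness.  Only female function is scored; pollen export is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .core import EffectivenessPoint, SingleVisitRecord, SurveyRecord, ValidationError
from .diversity import DiversityEstimate, compare_estimates, hurlbert_pie, pie_bootstrap

__all__ = [
    "GlmResult",
    "SeedShare",
    "qtc",
    "qlc",
    "effectiveness",
    "build_points",
    "seed_shares",
    "binomial_glm_lrt",
    "largest_remainder_round",
    "weighted_pie_comparison",
]


def qtc(surveys: Sequence[SurveyRecord], group: int, morph: str) -> float:
    """Visits per plant per hour by ``group`` on plants displaying ``morph``."""
    hours = 0.0
    visits = 0
    for s in surveys:
        if s.morph != morph:
            continue
        hours += s.duration_min / 60.0
        visits += s.visits.get(group, 0)
    if hours <= 0:
        raise ValidationError(f"no survey effort for morph {morph!r}")
    return visits / hours


def qlc(records: Sequence[SingleVisitRecord], group: int, morph: str) -> float:
    """Viable seeds per visit: total seeds over all visited flowers.

    Flowers that set no fruit contribute 0 to the numerator but still count
    one visit in the denominator — a failed visit is part of the group's
    per-visit performance.
    """
    seeds = 0
    flowers = 0
    for r in records:
        if r.group != group or r.morph != morph:
            continue
        flowers += 1
        seeds += r.viable_seeds
    if flowers == 0:
        raise ValidationError(f"no single-visit records for group {group}, morph {morph!r}")
    return seeds / flowers


def effectiveness(qtc_value: float, qlc_value: float) -> float:
    """Seeds per plant per hour: the exact product of the two components."""
    if qtc_value < 0 or qlc_value < 0:
        raise ValidationError("components must be non-negative")
    return qtc_value * qlc_value


def build_points(
    surveys: Sequence[SurveyRecord],
    records: Sequence[SingleVisitRecord],
    morph: str,
    groups: Sequence[int] | None = None,
) -> list[EffectivenessPoint]:
    """Assemble effectiveness points for every group estimable on ``morph``.

    A group needs both components: visits observed in at least one survey
    window and at least one single-visit record.  Groups missing either are
    omitted (they cannot be placed on the landscape).
    """
    if groups is None:
        groups = sorted(
            {g for s in surveys for g in s.visits} | {r.group for r in records}
        )
    points = []
    recorded = {(r.group, r.morph) for r in records}
    for g in groups:
        if (g, morph) not in recorded:
            continue
        points.append(
            EffectivenessPoint(g, morph, qtc(surveys, g, morph), qlc(records, g, morph))
        )
    return points


@dataclass(frozen=True)
class SeedShare:
    group: int
    morph: str
    share: float


def seed_shares(points: Sequence[EffectivenessPoint], morph: str) -> list[SeedShare]:
    """Proportion of the morph's seed production attributed to each group.

    share_i = E_i / sum_j E_j over the morph's points; invariant under any
    common rescaling of effectiveness.
    """
    pts = [p for p in points if p.morph == morph]
    total = sum(p.effectiveness for p in pts)
    if total <= 0:
        raise ValidationError("all effectiveness values are zero; shares undefined")
    return [SeedShare(p.group, morph, p.effectiveness / total) for p in pts]


# ---------------------------------------------------------------------------
# Binomial GLM deviance test
# ---------------------------------------------------------------------------


@dataclass
class GlmResult:
    terms: list[str]
    null_deviance: float
    residual_deviance: float
    lrt_deviance: float
    df: int
    p: float
    coefficients: dict[str, float]


def binomial_glm_lrt(successes, totals, factor) -> GlmResult:
    """Likelihood-ratio deviance test of a single categorical predictor.

    Fits logit-link binomial GLMs (IRLS) with and without the factor and
    reports the deviance drop with a chi-square p on (levels - 1) df.  With a
    single categorical predictor the fitted level proportions equal the
    pooled observed proportions, which gives the closed-form deviance used in
    the tests.  Coefficients are clipped (+/-30 on the logit scale) under
    complete separation.
    """
    succ = np.asarray(successes, dtype=float)
    tot = np.asarray(totals, dtype=float)
    fac = np.asarray(factor)
    if np.any(succ < 0) or np.any(tot < succ):
        raise ValidationError("need 0 <= successes <= totals")
    levels = sorted(set(fac.tolist()))
    if len(levels) < 2:
        raise ValidationError("factor needs at least two levels")
    endog = np.column_stack([succ, tot - succ])
    x_full = np.column_stack(
        [np.ones_like(succ)] + [(fac == lv).astype(float) for lv in levels[1:]]
    )
    null = sm.GLM(endog, np.ones((len(succ), 1)), family=sm.families.Binomial()).fit()
    full = sm.GLM(endog, x_full, family=sm.families.Binomial()).fit(maxiter=200)
    if not full.converged:
        raise RuntimeError("binomial GLM did not converge")
    coefs = np.clip(full.params, -30.0, 30.0)
    names = ["intercept"] + [f"level[{lv}]" for lv in levels[1:]]
    lrt = float(null.deviance - full.deviance)
    df = len(levels) - 1
    return GlmResult(
        terms=["factor"],
        null_deviance=float(null.deviance),
        residual_deviance=float(full.deviance),
        lrt_deviance=lrt,
        df=df,
        p=float(stats.chi2.sf(lrt, df)),
        coefficients=dict(zip(names, coefs)),
    )


# ---------------------------------------------------------------------------
# Generalisation under visitation vs effectiveness weighting
# ---------------------------------------------------------------------------


def largest_remainder_round(weights, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` proportional to ``weights``."""
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValidationError("weights must have a positive sum")
    quota = w / w.sum() * total
    base = np.floor(quota).astype(np.int64)
    short = total - int(base.sum())
    if short:
        order = np.argsort(-(quota - base))
        base[order[:short]] += 1
    return base


def weighted_pie_comparison(
    visit_counts,
    seed_counts,
    b: int = 1000,
    seed=None,
) -> tuple[DiversityEstimate, DiversityEstimate, str]:
    """Compare generalisation measured on visits versus on seeds.

    Both vectors run over the same functional groups.  Each weighting gets a
    Hurlbert-PIE point estimate and a multinomial bootstrap CI; the verdict
    is ``'different'`` iff the two 95 % CIs do not overlap.  Seed counts are
    expected as integers (attribute shares to a seed total with
    :func:`largest_remainder_round` first).
    """
    v = np.asarray(visit_counts)
    s = np.asarray(seed_counts)
    if v.shape != s.shape:
        raise ValidationError("visit and seed vectors must cover the same groups")
    if s.sum() < 2:
        raise ValidationError("need at least 2 seeds for a seed-weighted PIE")
    rng = np.random.default_rng(seed)
    est_v = pie_bootstrap(v, b=b, seed=rng, weighting="visits")
    est_s = pie_bootstrap(s, b=b, seed=rng, weighting="seeds")
    return est_v, est_s, compare_estimates(est_v, est_s)
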