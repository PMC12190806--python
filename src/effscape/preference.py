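"""Electivity analysis of two-morph preference trials.

Preference is availability-corrected: a group's share of visits to one morph
is compared with that morph's share of open flowers.  Jacobs' D,

    D = (r - p) / (r + p - 2 r p),

where ``r`` is the proportion of the group's visits going to the focal morph
and ``p`` the proportion of available flowers of that morph, is 0 under
random visitation and saturates at +/-1 for exclusive preference/avoidance;
unlike Ivlev's E = (r - p)/(r + p) it is robust to changes in availability.
Significance comes from a goodness-of-fit test of the observed visit split
against the split expected to be directly proportional to morph availability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core import PreferenceTrial, ValidationError

__all__ = [
    "PreferenceResult",
    "jacobs_d",
    "ivlev_e",
    "preference_gof",
    "trial_aggregate",
]

MIN_VISITS_DEFAULT = 20


def _check_prop(v: float, name: str) -> None:
    if not 0.0 <= v <= 1.0:
        raise ValidationError(f"{name} must be in [0, 1], got {v}")


def jacobs_d(r: float, p: float) -> float:
    """Jacobs' electivity index for a two-resource environment."""
    _check_prop(r, "r")
    _check_prop(p, "p")
    # r + p - 2rp, written to avoid cancellation near r = p = 1
    denom = r * (1.0 - p) + p * (1.0 - r)
    if denom == 0.0:
        # r = p = 0 or r = p = 1: no information; random feeding by continuity
        warnings.warn("degenerate (r, p); returning D = 0 by continuity")
        return 0.0
    return (r - p) / denom


def ivlev_e(r: float, p: float) -> float:
    """Ivlev's electivity index E = (r - p)/(r + p)."""
    _check_prop(r, "r")
    _check_prop(p, "p")
    if r + p == 0.0:
        raise ValidationError("Ivlev's E undefined for r = p = 0")
    return (r - p) / (r + p)


def preference_gof(
    visits: tuple[int, int], availability: tuple[float, float]
) -> tuple[float, float]:
    """Goodness of fit of a visit split against availability proportions.

    Chi-square with 1 df against expected counts proportional to open-flower
    availability; when any expected count is below 5 the exact binomial test
    is substituted (statistic reported as NaN in that case).
    """
    v = np.asarray(visits, dtype=float)
    a = np.asarray(availability, dtype=float)
    if np.any(a <= 0):
        raise ValidationError("both morph availabilities must be positive")
    if v.sum() < 1:
        raise ValidationError("need at least one visit")
    p_exp = a / a.sum()
    expected = v.sum() * p_exp
    if np.any(expected < 5):
        res = stats.binomtest(int(v[0]), int(v.sum()), p_exp[0])
        return float("nan"), float(res.pvalue)
    chi2 = float(np.sum((v - expected) ** 2 / expected))
    return chi2, float(stats.chi2.sf(chi2, df=1))


@dataclass(frozen=True)
class PreferenceResult:
    """Pooled electivity of one functional group for the spring morph."""

    group: int
    r: float
    p: float
    d: float
    e: float
    n_visits: int
    gof_statistic: float
    gof_p: float
    sufficient: bool


def trial_aggregate(
    trials: Sequence[PreferenceTrial],
    group: int,
    season: str | None = None,
    min_visits: int = MIN_VISITS_DEFAULT,
) -> PreferenceResult | None:
    """Pool a group's visits over trials and compute its electivity.

    Pooling is by summing counts (ratio of sums), not by averaging per-trial
    indices: per-trial visit counts are tiny and the pooled ratio is the
    stable estimator.  Availability is pooled as the flower-weighted share of
    spring-morph flowers over the trials in which the group was recorded.
    Returns ``None`` when the group made no visits in the selected trials;
    groups below ``min_visits`` are flagged ``sufficient=False``.
    """
    vis_spring = vis_summer = 0
    fl_spring = fl_summer = 0
    seen = False
    for t in trials:
        if season is not None and t.season != season:
            continue
        if group not in t.visits:
            continue
        seen = True
        vs, vu = t.visits[group]
        vis_spring += vs
        vis_summer += vu
        fl_spring += t.flowers_spring
        fl_summer += t.flowers_summer
    if not seen:
        raise ValidationError(f"group {group} absent from every selected trial")
    n = vis_spring + vis_summer
    if n == 0:
        return None
    r = vis_spring / n
    p = fl_spring / (fl_spring + fl_summer)
    stat, pval = preference_gof((vis_spring, vis_summer), (fl_spring, fl_summer))
    return PreferenceResult(
        group=group,
        r=r,
        p=p,
        d=jacobs_d(r, p),
        e=ivlev_e(r, p),
        n_visits=n,
        gof_statistic=stat,
        gof_p=pval,
        sufficient=n >= min_visits,
    )
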