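"""Interaction diversity: Hurlbert's PIE, bootstrap CIs, and assemblage
composition (Bray-Curtis, sequential-SS permutational MANOVA, principal
coordinates with functional-group score projection).

Hurlbert's PIE (probability of interspecific encounter) is the probability
that two individuals drawn at random without replacement from an assemblage
belong to different functional groups,

    PIE = N/(N-1) * (1 - sum_i p_i^2),

with ``N`` the total count and ``p_i`` the relative abundance of group ``i``.
On counts this plug-in form is algebraically identical to the unbiased
pair-count (Simpson-type) estimator ``1 - sum_i X_i (X_i - 1) / (N (N-1))``,
so a single implementation serves both names.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core import AssemblageTable, ValidationError

__all__ = [
    "DiversityEstimate",
    "PermanovaResult",
    "OrdinationResult",
    "hurlbert_pie",
    "pie_bootstrap",
    "compare_estimates",
    "bray_curtis",
    "permanova",
    "pcoa",
    "group_scores",
]


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------


def hurlbert_pie(counts) -> float:
    """Probability that two randomly drawn individuals differ in group.

    Requires a total count of at least 2 (no pair can be drawn otherwise).
    """
    x = np.asarray(counts, dtype=float)
    if np.any(x < 0):
        raise ValidationError("counts must be non-negative")
    n = x.sum()
    if n < 2:
        raise ValidationError("PIE is undefined for fewer than 2 individuals")
    p = x / n
    return float(n / (n - 1.0) * (1.0 - np.sum(p**2)))


@dataclass(frozen=True)
class DiversityEstimate:
    """PIE point estimate with bootstrap SE and percentile CI."""

    pie: float
    se: float
    ci_low: float
    ci_high: float
    n: int
    weighting: str = "visits"

    def overlaps(self, other: "DiversityEstimate") -> bool:
        return self.ci_low <= other.ci_high and other.ci_low <= self.ci_high


def pie_bootstrap(
    counts,
    b: int = 1000,
    level: float = 0.95,
    seed=None,
    weighting: str = "visits",
) -> DiversityEstimate:
    """Multinomial bootstrap of Hurlbert's PIE.

    ``b`` resamples of ``N`` individuals are drawn from the observed relative
    abundances; the SE is the SD of the replicate PIEs and the CI is the
    percentile interval at ``level``.
    """
    if b < 100:
        warnings.warn("fewer than 100 bootstrap replicates gives an unstable CI")
    x = np.asarray(counts, dtype=np.int64)
    n = int(x.sum())
    point = hurlbert_pie(x)
    if np.count_nonzero(x) <= 1:
        # degenerate single-group sample: every resample is identical
        return DiversityEstimate(point, 0.0, point, point, n, weighting)
    rng = np.random.default_rng(seed)
    p = x / n
    res = rng.multinomial(n, p, size=b)
    sq = (res.astype(float) / n) ** 2
    reps = n / (n - 1.0) * (1.0 - sq.sum(axis=1))
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
    return DiversityEstimate(point, float(reps.std(ddof=1)), float(lo), float(hi), n, weighting)


def compare_estimates(a: DiversityEstimate, b: DiversityEstimate) -> str:
    """Overlap verdict on two bootstrap CIs: 'different' iff they are disjoint."""
    return "not different" if a.overlaps(b) else "different"


# ---------------------------------------------------------------------------
# Beta diversity
# ---------------------------------------------------------------------------


def bray_curtis(table: AssemblageTable, scale: str = "counts") -> np.ndarray:
    """Symmetric Bray-Curtis dissimilarity matrix between units.

    ``scale='counts'`` uses the raw count rows; ``scale='proportions'``
    row-normalises first.  All-zero units are rejected (the dissimilarity is
    undefined for an empty assemblage) — drop them first with
    :meth:`AssemblageTable.drop_empty`.
    """
    if table.empty_units.any():
        raise ValidationError("Bray-Curtis undefined for all-zero units; drop them first")
    if table.n_units < 2:
        raise ValidationError("need at least two units")
    if scale == "counts":
        x = table.counts.astype(float)
    elif scale == "proportions":
        x = table.relative()
    else:
        raise ValueError(f"unknown scale {scale!r}")
    return squareform(pdist(x, metric="braycurtis"))


def _gower_center(dist: np.ndarray) -> np.ndarray:
    """Gower-centred inner-product matrix -1/2 J D^2 J."""
    d2 = np.asarray(dist, dtype=float) ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d2 @ j


@dataclass
class PermanovaResult:
    """Sequential (entry-order) partition of a dissimilarity matrix."""

    terms: list[str]
    df: dict[str, int]
    ss: dict[str, float]
    f: dict[str, float]
    p: dict[str, float]
    residual_df: int
    residual_ss: float
    total_ss: float
    n_permutations: int
    seed: object = None


def _design_matrices(factors: dict[str, list]) -> list[np.ndarray]:
    """Cumulative full-rank design matrices: intercept, +term1, +term1+term2, ..."""
    n = len(next(iter(factors.values())))
    blocks = [np.ones((n, 1))]
    mats = []
    for name, levels in factors.items():
        labels = sorted(set(levels))
        if len(labels) < 2:
            raise ValidationError(f"term {name!r} has a single level")
        # treatment-coded dummies (drop first level)
        dm = np.array([[1.0 if lv == lab else 0.0 for lab in labels[1:]] for lv in levels])
        blocks.append(dm)
        mats.append(np.hstack(blocks))
    return mats


def _hat(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(x)
    rank = np.sum(np.abs(np.diag(r)) > 1e-10 * max(x.shape))
    q = q[:, :rank]
    return q @ q.T


def permanova(
    dist: np.ndarray,
    factors: dict[str, list],
    n_perm: int = 999,
    seed=None,
) -> PermanovaResult:
    """Permutational multivariate ANOVA with sequential sums of squares.

    ``factors`` is an ordered mapping term -> per-unit labels; terms are
    added in entry order, so a covariate listed first is controlled for when
    the later terms are assessed.  Pseudo-F per term uses the residual mean
    square of the full model; significance comes from ``n_perm`` free row
    permutations of the units, ``p = (1 + #{F* >= F}) / (1 + n_perm)``.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n):
        raise ValidationError("distance matrix must be square")
    if n_perm < 99:
        raise ValidationError("need at least 99 permutations")
    for name, levels in factors.items():
        if len(levels) != n:
            raise ValidationError(f"term {name!r} does not cover all units")
    names = list(factors)
    mats = _design_matrices(factors)
    hats = [_hat(m) for m in mats]
    h0 = np.ones((n, n)) / n  # intercept-only hat
    dfs = []
    prev_rank = 1
    for m in mats:
        rank = np.linalg.matrix_rank(m)
        d = rank - prev_rank
        if d == 0:
            raise ValidationError("confounded terms: a term adds no degrees of freedom")
        dfs.append(d)
        prev_rank = rank
    res_df = n - prev_rank
    if res_df <= 0:
        raise ValidationError("no residual degrees of freedom")

    g = _gower_center(dist)
    total_ss = float(np.trace(g))

    def term_stats(gmat: np.ndarray):
        ss, prev = [], h0
        for h in hats:
            ss.append(float(np.trace((h - prev) @ gmat)))
            prev = h
        res_ss = float(np.trace((np.eye(n) - hats[-1]) @ gmat))
        ms_res = res_ss / res_df
        fstats = [s / d / ms_res if ms_res > 0 else 0.0 for s, d in zip(ss, dfs)]
        return ss, res_ss, fstats

    ss_obs, res_ss, f_obs = term_stats(g)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(names))
    for _ in range(n_perm):
        idx = rng.permutation(n)
        gp = g[np.ix_(idx, idx)]
        _, _, f_perm = term_stats(gp)
        exceed += np.asarray(f_perm) >= np.asarray(f_obs)
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    return PermanovaResult(
        terms=names,
        df=dict(zip(names, dfs)),
        ss=dict(zip(names, ss_obs)),
        f=dict(zip(names, f_obs)),
        p=dict(zip(names, pvals)),
        residual_df=res_df,
        residual_ss=res_ss,
        total_ss=total_ss,
        n_permutations=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Ordination
# ---------------------------------------------------------------------------


@dataclass
class OrdinationResult:
    """Principal-coordinates embedding of a dissimilarity matrix."""

    coordinates: np.ndarray  # (n_units, k)
    eigenvalues: np.ndarray  # all eigenvalues, decreasing
    proportions: np.ndarray  # per retained axis, over positive eigenvalues


def pcoa(dist: np.ndarray, k: int = 2) -> OrdinationResult:
    """Classical metric scaling of a dissimilarity matrix.

    Eigendecomposition of the Gower-centred matrix; coordinates are
    eigenvectors scaled by the square root of their (positive) eigenvalues.
    Negative eigenvalues — possible for non-Euclidean input such as
    Bray-Curtis — are reported but excluded from the variation denominator,
    and no correction is applied.
    """
    g = _gower_center(dist)
    vals, vecs = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = 1e-9 * max(abs(vals[0]), 1.0)
    n_pos = int(np.sum(vals > tol))
    if k > n_pos:
        warnings.warn(f"only {n_pos} positive eigenvalues; truncating k={k}")
        k = n_pos
    coords = vecs[:, :k] * np.sqrt(vals[:k])
    props = vals[:k] / vals[vals > tol].sum()
    return OrdinationResult(coords, vals, props)


def group_scores(ordination: OrdinationResult, table: AssemblageTable) -> np.ndarray:
    """Project functional groups onto ordination axes (correlation method).

    The score of group *i* on axis *a* is the Pearson correlation between the
    group's abundance across units and the unit coordinates on that axis,
    scaled by the axis standard deviation.  Groups with zero variance across
    units get a zero score (with a warning).
    """
    coords = ordination.coordinates
    if coords.shape[0] != table.n_units:
        raise ValidationError("ordination and table unit counts differ")
    abund = table.relative()
    k = coords.shape[1]
    scores = np.zeros((len(table.groups), k))
    axis_sd = coords.std(axis=0, ddof=1)
    for i in range(abund.shape[1]):
        col = abund[:, i]
        if np.std(col) == 0:
            warnings.warn(f"group {table.groups[i]} constant across units; score 0")
            continue
        for a in range(k):
            if axis_sd[a] == 0:
                continue
            r = np.corrcoef(col, coords[:, a])[0, 1]
            scores[i, a] = r * axis_sd[a]
    return scores
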