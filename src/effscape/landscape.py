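"""Effectiveness-landscape diagnostics.

The landscape places each functional group at (quantity, quality) after
min-max scaling both axes to [0, 1], so nearest-neighbour distances are
computed in comparable units inside the unit square.  Diagnostics:

* **Clark-Evans R** (observed mean nearest-neighbour distance over its
  expectation under complete spatial randomness), with the Donnelly edge
  correction that inflates the CSR expectation by a window perimeter term.
  R < 1 indicates clumping, R > 1 regularity.
* **Hopkins-Skellam A** — the ratio of summed squared event-to-event
  nearest-neighbour distances to summed squared distances from random
  sampling origins to their nearest event.  A ~ 1 under CSR and A < 1 for
  clustered patterns; being a ratio of local distances it is less sensitive
  to large-scale intensity gradients than R.
* Significance for both by Monte-Carlo rank against CSR simulations in the
  same window (two-sided).
* The number of functionally equivalent pollinator clusters by majority vote
  of a fixed panel of ten cluster-validity indices over Ward-linkage
  partitions.
* Pearson correlation between the raw quantity and quality components
  (positive correlation flags functionally specialised systems).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .core import EffectivenessPoint, ValidationError

__all__ = [
    "Window",
    "LandscapePoint",
    "SpatialPatternResult",
    "ClusterVote",
    "build_landscape",
    "clark_evans",
    "hopkins_skellam",
    "majority_cluster_count",
    "qtc_qlc_correlation",
    "VALIDITY_INDICES",
]

UNIT_SQUARE = (0.0, 1.0, 0.0, 1.0)
Window = tuple[float, float, float, float]


@dataclass(frozen=True)
class LandscapePoint:
    group: int
    x: float  # scaled quantity in [0, 1]
    y: float  # scaled quality in [0, 1]
    qtc: float
    qlc: float


def build_landscape(
    points: Sequence[EffectivenessPoint],
) -> tuple[list[LandscapePoint], Window]:
    """Min-max scale both effectiveness components onto the unit square."""
    if len(points) < 3:
        raise ValidationError("need at least 3 points to build a landscape")
    q = np.array([p.qtc for p in points], dtype=float)
    l = np.array([p.qlc for p in points], dtype=float)
    for arr, name in ((q, "quantity"), (l, "quality")):
        if arr.max() == arr.min():
            raise ValidationError(f"{name} axis has zero range; landscape degenerate")
    x = (q - q.min()) / (q.max() - q.min())
    y = (l - l.min()) / (l.max() - l.min())
    return (
        [LandscapePoint(p.group, xi, yi, p.qtc, p.qlc)
         for p, xi, yi in zip(points, x, y)],
        UNIT_SQUARE,
    )


def _as_xy(points) -> np.ndarray:
    if isinstance(points[0], LandscapePoint):
        return np.array([(p.x, p.y) for p in points], dtype=float)
    return np.asarray(points, dtype=float)


def _nn_distances(xy: np.ndarray) -> np.ndarray:
    d = squareform(pdist(xy))
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


@dataclass(frozen=True)
class SpatialPatternResult:
    statistic: float
    p: float
    n_points: int
    window: Window
    n_mc: int


def _mc_pvalue(obs: float, sims: np.ndarray) -> float:
    """Two-sided Monte-Carlo rank p-value."""
    n = len(sims)
    lo = (1 + np.sum(sims <= obs)) / (n + 1)
    hi = (1 + np.sum(sims >= obs)) / (n + 1)
    return float(min(1.0, 2.0 * min(lo, hi)))


def _csr(rng, n: int, window: Window) -> np.ndarray:
    x0, x1, y0, y1 = window
    pts = rng.random((n, 2))
    pts[:, 0] = x0 + pts[:, 0] * (x1 - x0)
    pts[:, 1] = y0 + pts[:, 1] * (y1 - y0)
    return pts


def _clark_evans_stat(xy: np.ndarray, window: Window, correction: str) -> float:
    n = len(xy)
    x0, x1, y0, y1 = window
    area = (x1 - x0) * (y1 - y0)
    expected = 0.5 * np.sqrt(area / n)
    if correction == "donnelly":
        perimeter = 2.0 * ((x1 - x0) + (y1 - y0))
        expected += (0.0514 + 0.041 / np.sqrt(n)) * perimeter / n
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")
    return float(_nn_distances(xy).mean() / expected)


def clark_evans(
    points,
    window: Window = UNIT_SQUARE,
    correction: str = "donnelly",
    n_mc: int = 1000,
    seed=None,
) -> SpatialPatternResult:
    """Clark-Evans aggregation index with Monte-Carlo CSR significance."""
    xy = _as_xy(points)
    n = len(xy)
    if n < 3:
        raise ValidationError("need at least 3 points")
    r_obs = _clark_evans_stat(xy, window, correction)
    rng = np.random.default_rng(seed)
    sims = np.array(
        [_clark_evans_stat(_csr(rng, n, window), window, correction) for _ in range(n_mc)]
    )
    return SpatialPatternResult(r_obs, _mc_pvalue(r_obs, sims), n, window, n_mc)


def _hopkins_stat(xy: np.ndarray, window: Window, rng, m: int) -> float:
    origins = _csr(rng, m, window)
    d_event = _nn_distances(xy)
    d_origin = cdist(origins, xy).min(axis=1)
    denom = float(np.sum(d_origin**2))
    if denom == 0.0:
        return np.inf
    return float(np.sum(d_event**2) / denom)


def hopkins_skellam(
    points,
    window: Window = UNIT_SQUARE,
    m: int | None = None,
    n_mc: int = 1000,
    seed=None,
) -> SpatialPatternResult:
    """Hopkins-Skellam clustering index with Monte-Carlo CSR significance.

    ``m`` sampling origins (default: as many as there are events) are drawn
    uniformly in the window for the observed statistic and afresh for every
    CSR simulation.
    """
    xy = _as_xy(points)
    n = len(xy)
    if n < 3:
        raise ValidationError("need at least 3 points")
    if m is None:
        m = n
    rng = np.random.default_rng(seed)
    a_obs = _hopkins_stat(xy, window, rng, m)
    sims = np.array(
        [_hopkins_stat(_csr(rng, n, window), window, rng, m) for _ in range(n_mc)]
    )
    return SpatialPatternResult(a_obs, _mc_pvalue(a_obs, sims), n, window, n_mc)


# ---------------------------------------------------------------------------
# Cluster-count majority vote
# ---------------------------------------------------------------------------

VALIDITY_INDICES = (
    "silhouette",
    "calinski_harabasz",
    "davies_bouldin",
    "dunn",
    "c_index",
    "mcclain_rao",
    "point_biserial",
    "gap",
    "hartigan",
    "krzanowski_lai",
)

_GAP_SEED = 1914  # fixed internal seed: the vote must be deterministic
_GAP_B = 20
_HARTIGAN_THRESHOLD = 10.0


def _within_dispersion(x: np.ndarray, labels: np.ndarray) -> float:
    """Total within-cluster sum of squared distances to centroids."""
    w = 0.0
    for lab in np.unique(labels):
        pts = x[labels == lab]
        w += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return w


def _pair_masks(labels: np.ndarray) -> np.ndarray:
    n = len(labels)
    same = np.zeros(n * (n - 1) // 2, dtype=bool)
    k = 0
    for i in range(n - 1):
        m = n - i - 1
        same[k : k + m] = labels[i + 1 :] == labels[i]
        k += m
    return same


def _dunn(dvec: np.ndarray, same: np.ndarray) -> float:
    max_intra = dvec[same].max() if same.any() else 0.0
    min_inter = dvec[~same].min() if (~same).any() else 0.0
    return min_inter / max_intra if max_intra > 0 else np.inf


def _c_index(dvec: np.ndarray, same: np.ndarray) -> float:
    nw = int(same.sum())
    if nw == 0:
        return np.nan
    s = float(dvec[same].sum())
    d_sorted = np.sort(dvec)
    s_min = float(d_sorted[:nw].sum())
    s_max = float(d_sorted[-nw:].sum())
    if s_max == s_min:
        return 0.0
    return (s - s_min) / (s_max - s_min)


def _mcclain_rao(dvec: np.ndarray, same: np.ndarray) -> float:
    if not same.any() or same.all():
        return np.nan
    return float(dvec[same].mean() / dvec[~same].mean())


def _point_biserial(dvec: np.ndarray, same: np.ndarray) -> float:
    nw, nb = int(same.sum()), int((~same).sum())
    nt = nw + nb
    sd = dvec.std()
    if nw == 0 or nb == 0 or sd == 0:
        return np.nan
    return float(
        (dvec[~same].mean() - dvec[same].mean()) * np.sqrt(nw * nb / nt**2) / sd
    )


def _ward_labels(x: np.ndarray, ks: Sequence[int]) -> dict[int, np.ndarray]:
    z = linkage(x, method="ward")
    return {k: fcluster(z, t=k, criterion="maxclust") for k in ks}


def _gap_vote(x: np.ndarray, ks: Sequence[int]) -> int:
    """Tibshirani gap statistic with the one-standard-error rule."""
    rng = np.random.default_rng(_GAP_SEED)
    lo, hi = x.min(axis=0), x.max(axis=0)
    ks_ext = list(ks) + [max(ks) + 1]
    labels = _ward_labels(x, ks_ext)
    logw = {k: np.log(max(_within_dispersion(x, labels[k]), 1e-300)) for k in ks_ext}
    ref_logw = {k: [] for k in ks_ext}
    for _ in range(_GAP_B):
        xr = lo + rng.random(x.shape) * (hi - lo)
        lr = _ward_labels(xr, ks_ext)
        for k in ks_ext:
            ref_logw[k].append(np.log(max(_within_dispersion(xr, lr[k]), 1e-300)))
    gap = {k: float(np.mean(ref_logw[k]) - logw[k]) for k in ks_ext}
    sk = {
        k: float(np.std(ref_logw[k]) * np.sqrt(1.0 + 1.0 / _GAP_B)) for k in ks_ext
    }
    for k in ks:
        if gap[k] >= gap[k + 1] - sk[k + 1]:
            return k
    return max(ks, key=lambda k: gap[k])


def _hartigan_vote(x: np.ndarray, ks: Sequence[int]) -> int:
    n = len(x)
    ks_ext = list(ks) + [max(ks) + 1]
    labels = _ward_labels(x, ks_ext)
    w = {k: _within_dispersion(x, labels[k]) for k in ks_ext}
    for k in ks:
        if w[k + 1] <= 0:
            return k
        h = (w[k] / w[k + 1] - 1.0) * (n - k - 1)
        if h <= _HARTIGAN_THRESHOLD:
            return k
    return max(ks)


def _krzanowski_lai_vote(x: np.ndarray, ks: Sequence[int]) -> int:
    p = x.shape[1]
    ks_ext = sorted({min(ks) - 1, max(ks) + 1} | set(ks))
    ks_ext = [k for k in ks_ext if k >= 1]
    labels = _ward_labels(x, [k for k in ks_ext if k >= 2])
    w = {k: _within_dispersion(x, labels[k]) for k in labels}
    if 1 in ks_ext:
        w[1] = float(((x - x.mean(axis=0)) ** 2).sum())

    def diff(k):
        return (k - 1) ** (2.0 / p) * w[k - 1] - k ** (2.0 / p) * w[k]

    scores = {}
    for k in ks:
        d_next = diff(k + 1)
        scores[k] = abs(diff(k)) / abs(d_next) if d_next != 0 else np.inf
    return max(ks, key=lambda k: (scores[k], -k))


@dataclass
class ClusterVote:
    k_range: list[int]
    votes: dict[str, int]  # index name -> voted k
    tally: dict[int, int]  # k -> number of votes
    majority_k: int
    tie: bool
    labels: np.ndarray  # Ward labels at the majority k


def majority_cluster_count(points, k_range: Sequence[int] = range(2, 9)) -> ClusterVote:
    """Estimate the number of clusters by majority vote of validity indices.

    Every candidate ``k`` gets a Ward-linkage partition; each index in
    :data:`VALIDITY_INDICES` votes for its optimal ``k``; the most frequent
    vote wins, ties broken toward the smaller ``k`` (and recorded).  The
    whole procedure is deterministic — the gap statistic's reference draws
    use a fixed internal seed.
    """
    x = _as_xy(points)
    n = len(x)
    ks = sorted(k_range)
    if n < max(ks) + 1:
        ks = [k for k in ks if k <= n - 1]
        if not ks:
            raise ValidationError("too few points for any candidate k")
        warnings.warn(f"too few points; candidate range truncated to {ks}")
    labels = _ward_labels(x, ks)
    dvec = pdist(x)

    per_k: dict[str, dict[int, float]] = {name: {} for name in VALIDITY_INDICES}
    for k in ks:
        lab = labels[k]
        same = _pair_masks(lab)
        per_k["silhouette"][k] = silhouette_score(x, lab)
        per_k["calinski_harabasz"][k] = calinski_harabasz_score(x, lab)
        per_k["davies_bouldin"][k] = -davies_bouldin_score(x, lab)  # minimise
        per_k["dunn"][k] = _dunn(dvec, same)
        per_k["c_index"][k] = -_c_index(dvec, same)  # minimise
        per_k["mcclain_rao"][k] = -_mcclain_rao(dvec, same)  # minimise
        per_k["point_biserial"][k] = _point_biserial(dvec, same)

    votes: dict[str, int] = {}
    for name in (
        "silhouette",
        "calinski_harabasz",
        "davies_bouldin",
        "dunn",
        "c_index",
        "mcclain_rao",
        "point_biserial",
    ):
        vals = per_k[name]
        votes[name] = max(ks, key=lambda k: (np.nan_to_num(vals[k], nan=-np.inf), -k))
    votes["gap"] = _gap_vote(x, ks)
    votes["hartigan"] = _hartigan_vote(x, ks)
    votes["krzanowski_lai"] = _krzanowski_lai_vote(x, ks)

    tally = {k: sum(1 for v in votes.values() if v == k) for k in ks}
    best = max(tally.values())
    winners = [k for k in ks if tally[k] == best]
    return ClusterVote(
        k_range=ks,
        votes=votes,
        tally=tally,
        majority_k=winners[0],
        tie=len(winners) > 1,
        labels=labels[winners[0]],
    )


def qtc_qlc_correlation(points: Sequence[EffectivenessPoint]) -> tuple[float, float]:
    """Pearson correlation between raw QTC and QLC with a two-sided t-test."""
    q = np.array([p.qtc for p in points], dtype=float)
    l = np.array([p.qlc for p in points], dtype=float)
    if len(q) < 3:
        raise ValidationError("need at least 3 points")
    if q.std() == 0 or l.std() == 0:
        raise ValidationError("zero variance in a component; correlation undefined")
    r, p = stats.pearsonr(q, l)
    return float(r), float(p)
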