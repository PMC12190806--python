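"""Domain tables, validation and CSV I/O shared by every analysis stage.

Four kinds of raw data enter the pipeline:

* an **assemblage table** — pollinator counts per functional group for each
  site x season census unit (the alpha/beta-diversity input);
* **preference trials** — five-minute two-morph offerings recording per-group
  visits to each floral morph plus open-flower availability;
* **single-visit records** — one virgin flower, one visit: morph, visiting
  group, and the fruit/seed outcome (the per-visit quality input);
* **survey records** — timed per-plant visitation watches (the visit-rate
  input).

Counts are the canonical in-memory representation; percentage tables (the
form in which census data are usually published) are converted to counts at
the I/O boundary, because the diversity estimators and their bootstrap need
integer totals.  Seasons and morphs are closed two-level vocabularies and
unknown labels are rejected outright — silently recoded factor levels are
the classic ecological-data bug.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SEASONS = ("spring", "summer")
MORPHS = ("spring", "summer")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _check_season(label: str) -> str:
    if label not in SEASONS:
        raise ValidationError(f"unknown season {label!r}; expected one of {SEASONS}")
    return label


def _check_morph(label: str) -> str:
    if label not in MORPHS:
        raise ValidationError(f"unknown morph {label!r}; expected one of {MORPHS}")
    return label


@dataclass(frozen=True)
class FunctionalGroup:
    """A set of pollinator taxa treated as one interaction unit."""

    code: int
    name: str
    guild: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("functional group name must be non-empty")


# ---------------------------------------------------------------------------
# Assemblage table
# ---------------------------------------------------------------------------


@dataclass
class AssemblageTable:
    """Counts of insects per functional group for each site x season unit.

    Parameters
    ----------
    sites, seasons :
        Unit metadata, one entry per row.
    groups :
        Functional-group codes, one per column.
    counts :
        Non-negative integer matrix, shape ``(n_units, n_groups)``.
    """

    sites: list[str]
    seasons: list[str]
    groups: list[int]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        n, k = self.counts.shape
        if not (len(self.sites) == len(self.seasons) == n):
            raise ValidationError("unit metadata length does not match count rows")
        if len(self.groups) != k:
            raise ValidationError("group codes do not match count columns")
        if len(set(self.groups)) != len(self.groups):
            raise ValidationError("functional-group codes must be unique")
        for s in self.seasons:
            _check_season(s)
        if np.any(self.counts < 0):
            raise ValidationError("negative count cell")
        if not np.allclose(self.counts, np.round(self.counts)):
            raise ValidationError("non-integral count cell")
        self.counts = self.counts.astype(np.int64)

    # -- basic views --------------------------------------------------------

    @property
    def n_units(self) -> int:
        return self.counts.shape[0]

    @property
    def unit_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def empty_units(self) -> np.ndarray:
        """Boolean mask of all-zero (unsampled) units."""
        return self.unit_totals == 0

    def relative(self) -> np.ndarray:
        """Row-wise relative abundances; all-zero rows yield NaN."""
        totals = self.unit_totals.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.counts / totals[:, None]

    def drop_empty(self) -> "AssemblageTable":
        """Return a copy without all-zero units, warning if any were dropped."""
        mask = ~self.empty_units
        if not mask.all():
            dropped = [f"{s}/{t}" for s, t, m in zip(self.sites, self.seasons, mask) if not m]
            warnings.warn(f"dropping all-zero assemblage unit(s): {', '.join(dropped)}")
        return AssemblageTable(
            [s for s, m in zip(self.sites, mask) if m],
            [s for s, m in zip(self.seasons, mask) if m],
            list(self.groups),
            self.counts[mask],
        )

    def pooled(self, season: str | None = None) -> np.ndarray:
        """Counts pooled over units, optionally restricted to one season."""
        if season is None:
            return self.counts.sum(axis=0)
        _check_season(season)
        mask = np.array([s == season for s in self.seasons])
        return self.counts[mask].sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=[f"g{c}" for c in self.groups])
        df.insert(0, "season", self.seasons)
        df.insert(0, "site", self.sites)
        return df

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AssemblageTable):
            return NotImplemented
        return (
            self.sites == other.sites
            and self.seasons == other.seasons
            and self.groups == other.groups
            and np.array_equal(self.counts, other.counts)
        )


def read_assemblage(path) -> AssemblageTable:
    """Read an assemblage CSV, auto-detecting percentage tables.

    The schema is ``site,season[,total],g<code>,...``.  If every sampled
    row's group columns sum to ~100 and a ``total`` column is present, cells
    are interpreted as percentages and converted to counts by rounding
    ``total * pct / 100``.  A percentage table without a ``total`` column is
    a hard error, because the counts cannot be recovered.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValidationError("no observation units")
    group_cols = [c for c in df.columns if c.startswith("g") and c[1:].isdigit()]
    if not group_cols:
        raise ValidationError("no functional-group columns (expected g<code>)")
    groups = [int(c[1:]) for c in group_cols]
    cells = df[group_cols].fillna(0.0).to_numpy(dtype=float)
    if np.any(cells < 0):
        raise ValidationError("negative cell")

    row_sums = cells.sum(axis=1)
    sampled = row_sums > 0
    looks_pct = sampled.any() and np.allclose(row_sums[sampled], 100.0, atol=1.5)
    integral = np.allclose(cells, np.round(cells))
    if looks_pct and not integral or (looks_pct and "total" in df.columns):
        if "total" not in df.columns:
            raise ValidationError(
                "percentage rows without a total column: counts cannot be recovered"
            )
        totals = df["total"].fillna(0).to_numpy(dtype=float)
        counts = np.round(cells * totals[:, None] / 100.0)
        # report (never fail on) disagreements between reconstructed row sums
        # and the recorded totals: published tables round each cell.
        mismatch = np.abs(counts.sum(axis=1) - totals)
        bad = mismatch > np.maximum(1, 0.01 * np.maximum(totals, 1))
        if bad.any():
            warnings.warn(
                "reconstructed counts deviate from recorded totals for "
                f"{int(bad.sum())} unit(s) (max {int(mismatch.max())} insects); "
                "keeping the reconstruction"
            )
    else:
        counts = cells
    return AssemblageTable(
        [str(s) for s in df["site"]], [str(s) for s in df["season"]], groups, counts
    )


def write_assemblage(table: AssemblageTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def load_table2() -> AssemblageTable:
    """Packaged census fixture: six SE-Spain populations x two seasons.

    The packaged file stores the table as published — per-population
    percentage columns plus each unit's total insect count — and this loader
    converts it to counts.  One cell (small beetles, Olula, spring) is
    truncated in the published text and was reconstructed as 0.6 % from the
    row's printed season-wide share.  The Baza summer unit was not sampled
    and is kept as an all-zero row (flagged, not dropped, at this stage).
    """
    ref = resources.files("effscape.data") / "seSpain_census_pct.csv"
    with resources.as_file(ref) as p, warnings.catch_warnings():
        warnings.simplefilter("ignore")  # known totals mismatch in the source table
        return read_assemblage(p)


# ---------------------------------------------------------------------------
# Preference trials
# ---------------------------------------------------------------------------


@dataclass
class PreferenceTrial:
    """One five-minute two-morph offering.

    ``visits`` maps functional-group code to ``(visits to spring morph,
    visits to summer morph)``.
    """

    trial_id: str
    site: str
    season: str
    flowers_spring: int
    flowers_summer: int
    visits: dict[int, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_season(self.season)
        if self.flowers_spring <= 0 or self.flowers_summer <= 0:
            raise ValidationError("open-flower counts must be positive for both morphs")
        for g, (vs, vu) in self.visits.items():
            if vs < 0 or vu < 0:
                raise ValidationError(f"negative visit count for group {g}")

    @property
    def availability_spring(self) -> float:
        """Proportion of available open flowers that are the spring morph."""
        return self.flowers_spring / (self.flowers_spring + self.flowers_summer)


def write_trials(trials: Sequence[PreferenceTrial], path) -> None:
    rows = []
    for t in trials:
        if not t.visits:
            rows.append((t.trial_id, t.site, t.season, t.flowers_spring,
                         t.flowers_summer, "", "", ""))
        for g in sorted(t.visits):
            vs, vu = t.visits[g]
            rows.append((t.trial_id, t.site, t.season, t.flowers_spring,
                         t.flowers_summer, g, vs, vu))
    pd.DataFrame(
        rows,
        columns=["trial_id", "site", "season", "flowers_spring", "flowers_summer",
                 "group", "visits_spring", "visits_summer"],
    ).to_csv(path, index=False)


def read_trials(path) -> list[PreferenceTrial]:
    df = pd.read_csv(path, dtype={"trial_id": str})
    trials: dict[str, PreferenceTrial] = {}
    for _, row in df.iterrows():
        tid = str(row["trial_id"])
        if tid not in trials:
            trials[tid] = PreferenceTrial(
                tid, str(row["site"]), str(row["season"]),
                int(row["flowers_spring"]), int(row["flowers_summer"]),
            )
        if not pd.isna(row["group"]) and str(row["group"]) != "":
            trials[tid].visits[int(row["group"])] = (
                int(row["visits_spring"]), int(row["visits_summer"])
            )
    return list(trials.values())


# ---------------------------------------------------------------------------
# Single-visit records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SingleVisitRecord:
    """Outcome of exposing one virgin flower to a single visit."""

    flower_id: str
    morph: str
    group: int
    fruit_set: bool
    viable_seeds: int
    unfertilised_ovules: int
    aborted_seeds: int

    def __post_init__(self) -> None:
        _check_morph(self.morph)
        if min(self.viable_seeds, self.unfertilised_ovules, self.aborted_seeds) < 0:
            raise ValidationError("ovule outcome counts must be non-negative")
        if not self.fruit_set and self.viable_seeds != 0:
            raise ValidationError("viable seeds recorded on a flower without fruit set")

    @property
    def ovule_total(self) -> int:
        return self.viable_seeds + self.unfertilised_ovules + self.aborted_seeds


def write_single_visits(records: Sequence[SingleVisitRecord], path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(path, index=False)


def read_single_visits(path) -> list[SingleVisitRecord]:
    df = pd.read_csv(path, dtype={"flower_id": str})
    return [
        SingleVisitRecord(
            str(r.flower_id), str(r.morph), int(r.group), bool(r.fruit_set),
            int(r.viable_seeds), int(r.unfertilised_ovules), int(r.aborted_seeds),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Visitation surveys
# ---------------------------------------------------------------------------


@dataclass
class SurveyRecord:
    """One timed watch of one plant: visits per functional group."""

    plant_id: str
    date: str
    morph: str
    duration_min: float
    visits: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_morph(self.morph)
        if self.duration_min <= 0:
            raise ValidationError("survey duration must be positive")
        if any(v < 0 for v in self.visits.values()):
            raise ValidationError("negative visit count")


def write_surveys(surveys: Sequence[SurveyRecord], path) -> None:
    rows = []
    for s in surveys:
        if not s.visits:
            rows.append((s.plant_id, s.date, s.morph, s.duration_min, "", ""))
        for g in sorted(s.visits):
            rows.append((s.plant_id, s.date, s.morph, s.duration_min, g, s.visits[g]))
    pd.DataFrame(
        rows, columns=["plant_id", "date", "morph", "duration_min", "group", "visits"]
    ).to_csv(path, index=False)


def read_surveys(path) -> list[SurveyRecord]:
    df = pd.read_csv(path, dtype={"plant_id": str, "date": str})
    out: dict[tuple, SurveyRecord] = {}
    for _, row in df.iterrows():
        key = (str(row["plant_id"]), str(row["date"]), str(row["morph"]))
        if key not in out:
            out[key] = SurveyRecord(key[0], key[1], key[2], float(row["duration_min"]))
        if not pd.isna(row["group"]) and str(row["group"]) != "":
            out[key].visits[int(row["group"])] = int(row["visits"])
    return list(out.values())


# ---------------------------------------------------------------------------
# Effectiveness points
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EffectivenessPoint:
    """One functional group's position on the effectiveness landscape.

    ``qtc`` is visits per plant per hour, ``qlc`` is viable seeds per visit,
    and effectiveness is their product (seeds per plant per hour).
    """

    group: int
    morph: str
    qtc: float
    qlc: float

    def __post_init__(self) -> None:
        _check_morph(self.morph)
        if self.qtc < 0 or self.qlc < 0:
            raise ValidationError("QTC and QLC must be non-negative")

    @property
    def effectiveness(self) -> float:
        return self.qtc * self.qlc


def write_points(points: Sequence[EffectivenessPoint], path) -> None:
    pd.DataFrame(
        [(p.group, p.morph, p.qtc, p.qlc, p.effectiveness) for p in points],
        columns=["group", "morph", "qtc", "qlc", "effectiveness"],
    ).to_csv(path, index=False)


def read_points(path) -> list[EffectivenessPoint]:
    df = pd.read_csv(path)
    return [
        EffectivenessPoint(int(r.group), str(r.morph), float(r.qtc), float(r.qlc))
        for r in df.itertuples()
    ]
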