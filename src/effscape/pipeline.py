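"""End-to-end orchestration: run every analysis stage on a set of input
tables (real or synthetic) and write per-stage CSV outputs plus one
structured JSON summary.

The pipeline is a pure function of (inputs, config): every stochastic stage
(bootstraps, permutation tests, Monte-Carlo spatial tests) derives its random
stream from the config seed, so a rerun with the same config is
bit-identical.  Logging goes to stderr; results never interleave with logs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import core, diversity, effectiveness, landscape, preference

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("effscape")

EXIT_VALIDATION = 2
EXIT_STATISTICAL = 3


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str, exit_code: int = EXIT_STATISTICAL):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.exit_code = exit_code


@dataclass
class PipelineConfig:
    assemblage_csv: str
    trials_csv: str
    surveys_csv: str
    single_visits_csv: str
    out_dir: str
    bootstrap: int = 1000
    n_perm: int = 999
    n_mc: int = 1000
    k_range: tuple[int, int] = (2, 8)
    min_visits: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("bootstrap", "n_perm", "n_mc", "min_visits"):
            if getattr(self, name) < 1:
                raise core.ValidationError(f"{name} must be >= 1")


def _load(config: PipelineConfig):
    stage = "load"
    for name, path in (
        ("assemblage", config.assemblage_csv),
        ("preference", config.trials_csv),
        ("effectiveness", config.surveys_csv),
        ("effectiveness", config.single_visits_csv),
    ):
        if not Path(path).exists():
            raise PipelineError(name, f"missing input file {path}", EXIT_VALIDATION)
    try:
        table = core.read_assemblage(config.assemblage_csv)
        trials = core.read_trials(config.trials_csv)
        surveys = core.read_surveys(config.surveys_csv)
        visits = core.read_single_visits(config.single_visits_csv)
    except core.ValidationError as exc:
        raise PipelineError(stage, str(exc), EXIT_VALIDATION) from exc
    return table, trials, surveys, visits


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the summary dict (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    table, trials, surveys, visits = _load(config)
    log.info("loaded inputs (%.2fs)", time.perf_counter() - t0)

    summary: dict = {"seed": config.seed, "stages": {}}
    rng = np.random.default_rng(config.seed)
    stage_seeds = {name: int(s) for name, s in zip(
        ("diversity", "permanova", "spatial", "generalisation"),
        rng.integers(0, 2**31 - 1, size=4),
    )}
    summary["stage_seeds"] = stage_seeds

    # --- diversity -------------------------------------------------------
    stage = "diversity"
    try:
        div_rows = []
        for season in ("spring", "summer"):
            counts = table.pooled(season)
            est = diversity.pie_bootstrap(
                counts, b=config.bootstrap, seed=stage_seeds["diversity"]
            )
            div_rows.append((season, "visits", est.pie, est.se, est.ci_low, est.ci_high, est.n))
        pd.DataFrame(
            div_rows, columns=["season", "weighting", "pie", "se", "ci_low", "ci_high", "n"]
        ).to_csv(out / "diversity.csv", index=False)
        summary["stages"]["diversity"] = {r[0]: {"pie": r[2], "ci": [r[4], r[5]]} for r in div_rows}

        clean = table.drop_empty()
        dist = diversity.bray_curtis(clean)
        perm = diversity.permanova(
            dist,
            {"population": clean.sites, "season": clean.seasons},
            n_perm=config.n_perm,
            seed=stage_seeds["permanova"],
        )
        ordn = diversity.pcoa(dist, k=2)
        scores = diversity.group_scores(ordn, clean)
        pd.DataFrame(
            {
                "site": clean.sites,
                "season": clean.seasons,
                "axis1": ordn.coordinates[:, 0],
                "axis2": ordn.coordinates[:, 1],
            }
        ).to_csv(out / "ordination_units.csv", index=False)
        pd.DataFrame(
            {"group": clean.groups, "axis1": scores[:, 0], "axis2": scores[:, 1]}
        ).to_csv(out / "ordination_groups.csv", index=False)
        summary["stages"]["composition"] = {
            "permanova": {
                t: {"df": perm.df[t], "ss": perm.ss[t], "F": perm.f[t], "p": perm.p[t]}
                for t in perm.terms
            },
            "pcoa_axis_pct": [float(100 * p) for p in ordn.proportions],
        }
    except core.ValidationError as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- preference ------------------------------------------------------
    stage = "preference"
    try:
        groups_in_trials = sorted({g for t in trials for g in t.visits})
        pref_rows = []
        for g in groups_in_trials:
            res = preference.trial_aggregate(trials, g, min_visits=config.min_visits)
            if res is None:
                continue
            pref_rows.append(
                (g, res.r, res.p, res.d, res.e, res.n_visits,
                 res.gof_statistic, res.gof_p, res.sufficient)
            )
        pref_df = pd.DataFrame(
            pref_rows,
            columns=["group", "r", "p_avail", "jacobs_d", "ivlev_e", "n_visits",
                     "gof_statistic", "gof_p", "sufficient"],
        )
        pref_df.to_csv(out / "preference.csv", index=False)
        summary["stages"]["preference"] = {
            int(r[0]): {"D": r[3], "p": r[7]} for r in pref_rows if r[8]
        }
    except core.ValidationError as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- effectiveness + landscape ---------------------------------------
    stage = "effectiveness"
    try:
        all_points = []
        summary["stages"]["landscape"] = {}
        for morph in ("spring", "summer"):
            points = effectiveness.build_points(surveys, visits, morph)
            all_points.extend(points)
            shares = effectiveness.seed_shares(points, morph)
            land, window = landscape.build_landscape(points)
            ce = landscape.clark_evans(
                land, window, n_mc=config.n_mc, seed=stage_seeds["spatial"]
            )
            hs = landscape.hopkins_skellam(
                land, window, n_mc=config.n_mc, seed=stage_seeds["spatial"]
            )
            vote = landscape.majority_cluster_count(
                land, k_range=range(config.k_range[0], config.k_range[1] + 1)
            )
            corr, corr_p = landscape.qtc_qlc_correlation(points)
            summary["stages"]["landscape"][morph] = {
                "clark_evans_R": ce.statistic, "p_R": ce.p,
                "hopkins_skellam_A": hs.statistic, "p_A": hs.p,
                "n_clusters": vote.majority_k, "tie": vote.tie,
                "qtc_qlc_r": corr, "qtc_qlc_p": corr_p,
                "seed_shares": {s.group: s.share for s in shares},
            }
        core.write_points(all_points, out / "effectiveness_points.csv")
    except core.ValidationError as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- generalisation: visits vs seeds ---------------------------------
    stage = "generalisation"
    try:
        gen: dict = {}
        for morph in ("spring", "summer"):
            season = morph  # morphs are displayed in their own season
            vcounts = table.pooled(season)
            points = [p for p in all_points if p.morph == morph]
            idx = {g: i for i, g in enumerate(table.groups)}
            eff = np.zeros(len(table.groups))
            for p in points:
                if p.group in idx:
                    eff[idx[p.group]] = p.effectiveness
            if eff.sum() <= 0 or vcounts.sum() < 2:
                gen[morph] = "insufficient data"
                continue
            seeds = effectiveness.largest_remainder_round(eff, int(vcounts.sum()))
            est_v, est_s, verdict = effectiveness.weighted_pie_comparison(
                vcounts, seeds, b=config.bootstrap, seed=stage_seeds["generalisation"]
            )
            gen[morph] = {
                "visits": {"pie": est_v.pie, "ci": [est_v.ci_low, est_v.ci_high]},
                "seeds": {"pie": est_s.pie, "ci": [est_s.ci_low, est_s.ci_high]},
                "verdict": verdict,
            }
        summary["stages"]["generalisation"] = gen
    except core.ValidationError as exc:
        raise PipelineError(stage, str(exc)) from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True,
                  default=lambda o: o.item() if isinstance(o, np.generic) else str(o))
    log.info("pipeline done (%.2fs)", time.perf_counter() - t0)
    return summary
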