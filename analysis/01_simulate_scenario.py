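#!/usr/bin/env python
"""Generate the default synthetic study: census, preference trials, timed
surveys and single-visit seed-set records, written as CSV under
results/synthetic/.

The scenario encodes the study system's structure as ground truth: a spring
assemblage dominated by long-tongued large bees that also concentrate seed
production, a more even summer assemblage, bee/beefly preference for the
spring morph and fly/butterfly preference for the summer morph.
"""

from pathlib import Path

from effscape import core, synthetic

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = synthetic.paper_like(seed=seed)
    census = synthetic.gen_census(cfg, seed=seed + 1)
    trials = synthetic.gen_trials(cfg, seed=seed + 2)
    surveys = synthetic.gen_surveys(cfg, seed=seed + 3)
    visits = synthetic.gen_single_visits(cfg, seed=seed + 4)

    core.write_assemblage(census, OUT / "assemblage.csv")
    core.write_trials(trials, OUT / "trials.csv")
    core.write_surveys(surveys, OUT / "surveys.csv")
    core.write_single_visits(visits, OUT / "single_visits.csv")

    print(f"wrote 4 tables to {OUT}")
    print(f"  census units: {census.n_units}, insects: {census.counts.sum()}")
    print(f"  trials: {len(trials)}, surveys: {len(surveys)}, flowers: {len(visits)}")
    print(f"  true spring-morph D targets: {cfg.jacobs_d_spring}")


if __name__ == "__main__":
    main()
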