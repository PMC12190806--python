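#!/usr/bin/env python
"""Alpha and beta diversity of the field census.

Loads the packaged six-population x two-season census, estimates Hurlbert's
PIE per season with bootstrap CIs, tests whether assemblage composition
differs between seasons once population is controlled for (sequential-SS
permutational MANOVA on Bray-Curtis dissimilarities), and ordinates the
units by principal coordinates with functional-group score projections.

Writes results/field/diversity.csv, permanova.csv, ordination_*.csv and an
ordination figure.
"""

import warnings
from pathlib import Path

import pandas as pd

from effscape import diversity as dv
from effscape.core import load_table2

OUT = Path(__file__).resolve().parents[1] / "results" / "field"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = load_table2()
        clean = table.drop_empty()

    rows = []
    for season in ("spring", "summer"):
        est = dv.pie_bootstrap(table.pooled(season), b=1000, seed=SEED)
        rows.append((season, est.pie, est.se, est.ci_low, est.ci_high, est.n))
        print(f"{season}: PIE = {est.pie:.3f} [{est.ci_low:.3f}, {est.ci_high:.3f}]"
              f" (N = {est.n})")
    pd.DataFrame(rows, columns=["season", "pie", "se", "ci_low", "ci_high", "n"]).to_csv(
        OUT / "diversity.csv", index=False
    )

    dist = dv.bray_curtis(clean, scale="counts")
    res = dv.permanova(
        dist, {"population": clean.sites, "season": clean.seasons}, n_perm=999, seed=SEED
    )
    print("\ncomposition (sequential SS, population first):")
    perm_rows = []
    for term in res.terms:
        print(f"  {term}: F = {res.f[term]:.3f}, p = {res.p[term]:.3f} "
              f"(df = {res.df[term]})")
        perm_rows.append((term, res.df[term], res.ss[term], res.f[term], res.p[term]))
    perm_rows.append(("residual", res.residual_df, res.residual_ss, None, None))
    pd.DataFrame(perm_rows, columns=["term", "df", "ss", "F", "p"]).to_csv(
        OUT / "permanova.csv", index=False
    )

    ordn = dv.pcoa(dist, k=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores = dv.group_scores(ordn, clean)
    pct = 100 * ordn.proportions
    print(f"\nPCoA: axis 1 {pct[0]:.1f} %, axis 2 {pct[1]:.1f} % "
          f"(together {pct.sum():.1f} % of variation)")
    pd.DataFrame({
        "site": clean.sites, "season": clean.seasons,
        "axis1": ordn.coordinates[:, 0], "axis2": ordn.coordinates[:, 1],
    }).to_csv(OUT / "ordination_units.csv", index=False)
    pd.DataFrame({
        "group": clean.groups, "axis1": scores[:, 0], "axis2": scores[:, 1],
    }).to_csv(OUT / "ordination_groups.csv", index=False)

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        for season, marker, color in (("spring", "o", "purple"), ("summer", "s", "0.7")):
            m = [s == season for s in clean.seasons]
            ax.scatter(ordn.coordinates[m, 0], ordn.coordinates[m, 1],
                       marker=marker, c=color, label=season, edgecolor="k", zorder=3)
        for g, (x, y) in zip(clean.groups, scores):
            if abs(x) + abs(y) > 0.05:
                ax.annotate(str(g), (x, y), color="0.4", fontsize=8)
        ax.axhline(0, lw=0.5, c="0.8")
        ax.axvline(0, lw=0.5, c="0.8")
        ax.set_xlabel(f"PCo 1 ({pct[0]:.1f} %)")
        ax.set_ylabel(f"PCo 2 ({pct[1]:.1f} %)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(OUT / "ordination.png", dpi=150)
        print(f"figure: {OUT / 'ordination.png'}")
    except Exception as exc:  # plotting is a convenience, never a failure
        print(f"(skipped figure: {exc})")


if __name__ == "__main__":
    main()
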