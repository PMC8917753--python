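#!/usr/bin/env python
"""Adjusted entry means, variance components and entry-mean heritability.

Reads the simulated panel from results/panel/, fits the multi-environment
mixed model per trait and the single-environment model per metabolite, and
writes the entry means, the per-metabolite H2 with its nested threshold
groups, and the trait-metabolite correlation matrix with significance
stars.  Run analysis/01_simulate_panel.py first.
"""

import json
from pathlib import Path

import pandas as pd

import omicpred as op
from omicpred import io as oio

PANEL = Path("results/panel")
OUT = Path("results/heritability")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    pheno = oio.read_long_phenotypes(PANEL / "phenotypes.tsv")
    mets = oio.read_long_phenotypes(PANEL / "metabolites.tsv")

    trait_rows, entry_means = {}, {}
    for t in sorted(pheno["trait"].unique()):
        h2, vc, em = op.heritability_from_observations(pheno, t)
        entry_means[t] = em.means
        trait_rows[t] = {
            "H2": h2, "sigma2_G": vc.sigma2_G, "sigma2_E": vc.sigma2_E,
            "sigma2_GxE": vc.sigma2_GxE, "sigma2_e": vc.sigma2_e,
            "nu_bar": vc.nu_bar,
        }
    traits = pd.DataFrame(trait_rows).T
    traits.to_csv(OUT / "trait_heritability.tsv", sep="\t")
    pd.DataFrame(entry_means).to_csv(OUT / "trait_entry_means.tsv", sep="\t")

    met_means, met_h2 = {}, {}
    for m in sorted(mets["trait"].unique()):
        h2, _, em = op.heritability_from_observations(mets, m)
        met_means[m] = em.means
        met_h2[m] = h2
    met_means = pd.DataFrame(met_means)
    met_h2 = pd.Series(met_h2, name="H2")
    met_h2.to_csv(OUT / "metabolite_h2.tsv", sep="\t")
    groups = op.filter_metabolites(met_means, met_h2)
    sizes = {k: v.shape[1] for k, v in groups.items()}
    (OUT / "metabolite_groups.json").write_text(json.dumps(sizes, indent=2))
    groups["M"].to_csv(OUT / "metabolite_entry_means.tsv", sep="\t")

    both = pd.concat([pd.DataFrame(entry_means), met_means], axis=1)
    r, p, stars = op.correlate(both)
    r.to_csv(OUT / "correlations_r.tsv", sep="\t")
    stars.to_csv(OUT / "correlations_stars.tsv", sep="\t")

    print("trait heritabilities:")
    print(traits["H2"].round(3).to_string())
    print(f"metabolite H2: mean {met_h2.mean():.3f}, "
          f"range {met_h2.min():.2f}-{met_h2.max():.2f}")
    print("group sizes:", sizes)


if __name__ == "__main__":
    main()
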