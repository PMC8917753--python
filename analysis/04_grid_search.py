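#!/usr/bin/env python
"""Joined weighted relationship matrix: 286-point grid search.

Selects one representative kernel per omic group (sequence variants, ePAV,
expression, metabolites) by the most-stable-rank rule across the three
traits, then scans all 286 weight combinations on the 0.1 simplex lattice
with shared CV partitions and reports the optimum per trait.  Run 01-03
first.
"""

import json
from pathlib import Path

import pandas as pd

import omicpred as op
from omicpred.pipeline import _select_representative

PANEL = Path("results/panel")
HER = Path("results/heritability")
PRED = Path("results/prediction")
OUT = Path("results/grid")
N_REPLICATES = 50
BASE_SEED = 7

GROUPS = {
    "SNP": ["SV", "dSV", "tSV"],
    "ePAV": ["ePAV_s", "ePAV_l", "ePAV_ls"],
    "expression": ["GE_s", "GE_l", "TE_s", "TE_l"],
    "M": ["M"],
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    import runpy
    load = runpy.run_path("analysis/03_kernels_and_cv.py")["load_matrices"]
    matrices = load()
    entry_means = pd.read_csv(HER / "trait_entry_means.tsv", sep="\t", index_col=0)
    ability = pd.read_csv(PRED / "single_predictor_abilities.tsv", sep="\t", index_col=0)

    reps = {g: _select_representative(ability, members)
            for g, members in GROUPS.items()}
    (OUT / "representatives.json").write_text(json.dumps(reps, indent=2))
    kernels = [op.kernel_from_features(matrices[reps[g]])[0]
               for g in ("SNP", "ePAV", "expression", "M")]

    grid = op.enumerate_weight_grid(4, 0.1)
    optima = {}
    for t in entry_means.columns:
        gs = op.grid_search(
            kernels, entry_means[t].loc[kernels[0].sample_ids], grid=grid,
            n_replicates=N_REPLICATES, base_seed=BASE_SEED,
        )
        gs.table.to_csv(OUT / f"grid_{t}.tsv", sep="\t", index=False)
        optima[t] = {
            "weights": dict(zip([reps[g] for g in GROUPS], gs.best_weights)),
            "ability": gs.best_ability,
            "best_single": float(ability[t].max()),
        }
    (OUT / "optima.json").write_text(json.dumps(optima, indent=2))
    print(f"representatives: {reps}")
    print(f"grid: {len(grid)} weight combinations per trait")
    for t, o in optima.items():
        print(f"{t}: best ability {o['ability']:.3f} "
              f"(best single predictor {o['best_single']:.3f}) at {o['weights']}")


if __name__ == "__main__":
    main()
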