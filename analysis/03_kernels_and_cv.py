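#!/usr/bin/env python
"""Relationship kernels per omic layer and single-predictor GBLUP CV.

Builds the twelve per-layer kernels (SV, dSV, tSV, ePAV in two tissues and
combined, gene/transcript expression in two tissues, metabolites), runs
replicated five-fold cross-validation for the three traits, and writes the
median-of-medians prediction abilities.  Run 01 and 02 first.
"""

import json
from pathlib import Path

import pandas as pd

import omicpred as op
from omicpred import io as oio
from omicpred.datatypes import FeatureMatrix

PANEL = Path("results/panel")
HER = Path("results/heritability")
OUT = Path("results/prediction")
N_REPLICATES = 50
BASE_SEED = 7


def load_matrices() -> dict[str, FeatureMatrix]:
    sv = oio.read_feature_matrix_with_meta(PANEL / "SV.tsv", "SV")
    dsv, tsv, _ = op.classify_sift(sv)
    expr = {t: oio.read_feature_matrix_with_meta(PANEL / f"{t}.tsv", t)
            for t in ("GE_s", "GE_l", "TE_s", "TE_l")}
    ep_s = op.call_epav(expr["GE_s"], "s")
    ep_l = op.call_epav(expr["GE_l"], "l")
    met = pd.read_csv(HER / "metabolite_entry_means.tsv", sep="\t", index_col=0)
    return {
        "SV": sv, "dSV": dsv, "tSV": tsv,
        "ePAV_s": op.epav_to_numeric(ep_s),
        "ePAV_l": op.epav_to_numeric(ep_l),
        "ePAV_ls": op.epav_to_numeric(op.combine_epav(ep_s, ep_l)),
        **expr,
        "M": FeatureMatrix(met.loc[sv.sample_ids], "M"),
    }


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    matrices = load_matrices()
    entry_means = pd.read_csv(HER / "trait_entry_means.tsv", sep="\t", index_col=0)

    kernels, counts = {}, {}
    for name, fm in matrices.items():
        kern, rep = op.kernel_from_features(fm)
        kernels[name] = kern
        counts[name] = {"m_input": fm.n_features, "m_used": kern.m}
    (OUT / "feature_counts.json").write_text(json.dumps(counts, indent=2))

    ability = pd.DataFrame(index=list(kernels), columns=entry_means.columns,
                           dtype=float)
    for name, kern in kernels.items():
        for t in entry_means.columns:
            cv = op.cross_validate(
                kern, entry_means[t].loc[kern.sample_ids],
                n_replicates=N_REPLICATES, base_seed=BASE_SEED,
            )
            ability.loc[name, t] = cv.median_of_medians
    ability.to_csv(OUT / "single_predictor_abilities.tsv", sep="\t")
    print(f"median prediction abilities ({N_REPLICATES} five-fold CV replicates):")
    print(ability.round(3).to_string())


if __name__ == "__main__":
    main()
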