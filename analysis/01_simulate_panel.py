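#!/usr/bin/env python
"""Simulate the multi-omic inbred panel and write every layer to disk.

Generates a 22-line panel (one line of the emulated 23 is conventionally
dropped for genotyping problems, so downstream analyses use n = 22):
sequence variants in linkage blocks with SIFT-like scores, two-tissue
gene/transcript expression, replicated greenhouse metabolites, and
multi-environment replicated phenotypes for three traits (LA, PH, HT).
Writes TSV/VCF/GFF3 artifacts plus the ground-truth sidecar under
results/panel/.
"""

import json
from pathlib import Path

import omicpred as op
from omicpred import io as oio

OUT = Path("results/panel")
SEED = 2024

CONFIG = op.SimConfig(
    n_inbreds=22, n_variants=400, n_genes=80, n_metabolites=40,
    n_environments=7, reps_per_env=10, seed=SEED,
)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ds = op.simulate_dataset(CONFIG)
    oio.write_feature_matrix_tsv(ds.genotypes, OUT / "SV.tsv")
    oio.write_vcf(ds.genotypes, OUT / "SV.vcf")
    oio.write_gff3(ds.truth.gene_models, OUT / "genes.gff3")
    for tag, fm in ds.expression.items():
        oio.write_feature_matrix_tsv(fm, OUT / f"{tag}.tsv")
    oio.write_long_phenotypes(ds.phenotype_obs, OUT / "phenotypes.tsv")
    oio.write_long_phenotypes(ds.metabolite_obs, OUT / "metabolites.tsv")
    oio.write_json(ds.truth.to_json_dict(), OUT / "truth.json")
    (OUT / "seed.json").write_text(json.dumps({"seed": SEED}))
    n_del = int(ds.truth.deleterious_flags.sum())
    print(f"panel: {CONFIG.n_inbreds} inbreds, {CONFIG.n_variants} variants "
          f"({n_del} deleterious), {CONFIG.n_genes} genes, "
          f"{CONFIG.n_metabolites} metabolites -> {OUT}/")


if __name__ == "__main__":
    main()
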