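#!/usr/bin/env python
"""Dataset (di)similarity: per-layer PCA -> GPA -> PCoA, and the
correlation-based distance between predictors' hold-out predictions.

Writes the GPA dissimilarity matrix with its PCoA map (which layers carry
similar information) and, per trait, the median correlation-based distance
between predicted-value vectors across CV replicates.  Run 01-03 first.
"""

from pathlib import Path

import pandas as pd

import omicpred as op

HER = Path("results/heritability")
OUT = Path("results/similarity")
N_REPLICATES = 50
BASE_SEED = 7


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    import runpy
    load = runpy.run_path("analysis/03_kernels_and_cv.py")["load_matrices"]
    matrices = load()
    entry_means = pd.read_csv(HER / "trait_entry_means.tsv", sep="\t", index_col=0)

    configs = []
    for name, fm in matrices.items():
        filt, _ = op.qc_filter(fm)
        configs.append(op.pca_scores(op.impute_mean(filt), 10))
    aligned, _ = op.gpa_align(configs)
    d = op.procrustes_dissimilarity(aligned)
    d.to_frame().to_csv(OUT / "gpa_dissimilarity.tsv", sep="\t")
    coords, percent = op.pcoa(d, n_axes=2)
    coords.to_csv(OUT / "gpa_pcoa.tsv", sep="\t")
    percent.to_csv(OUT / "gpa_pcoa_percent.tsv", sep="\t")
    print(f"GPA-PCoA: PCo1 {percent.iloc[0]:.2f}%, PCo2 {percent.iloc[1]:.2f}% "
          "of total variability")

    for t in entry_means.columns:
        cvs = {}
        for name, fm in matrices.items():
            kern, _ = op.kernel_from_features(fm)
            cvs[name] = op.cross_validate(
                kern, entry_means[t].loc[kern.sample_ids],
                n_replicates=N_REPLICATES, base_seed=BASE_SEED,
                keep_predictions=True,
            )
        pv = op.predicted_value_distance(cvs)
        pv.to_frame().to_csv(OUT / f"predicted_value_distance_{t}.tsv", sep="\t")
        c2, p2 = op.pcoa(pv, n_axes=2)
        c2.to_csv(OUT / f"predicted_value_pcoa_{t}.tsv", sep="\t")
        print(f"{t}: predicted-value PCoA PCo1 {p2.iloc[0]:.2f}%")


if __name__ == "__main__":
    main()
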