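"""End-to-end orchestration: simulate -> QC -> kernels -> entry means ->
single-predictor CV -> representative selection -> weighted-kernel grid
search -> dataset similarity -> 3'end study.

Every stage is deterministic given the config seeds; the output directory
receives per-stage TSV/JSON artifacts plus a manifest (config hash and all
seeds used) sufficient to reproduce any artifact.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as io_formats
from .datatypes import Kernel
from .kernels import (
    call_epav, classify_sift, combine_epav, epav_to_numeric, kernel_from_features,
)
from .phenostats import filter_metabolites, fit_entry_means, heritability_from_observations
from .prediction import cross_validate, enumerate_weight_grid, grid_search
from .similarity import (
    gpa_align, pca_scores, pcoa, predicted_value_distance, procrustes_dissimilarity,
)
from .simulate import SimConfig, simulate_dataset
from .threeprime import three_prime_study

__all__ = ["PipelineConfig", "run_pipeline", "make_demo"]


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    layers: Sequence[str] = (
        "SV", "dSV", "tSV", "ePAV_s", "ePAV_l", "ePAV_ls",
        "GE_s", "GE_l", "TE_s", "TE_l", "M",
    )
    n_folds: int = 5
    n_replicates: int = 200
    cv_seed: int = 0
    grid_step: float = 0.1
    h2_thresholds: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)
    threeprime_lengths: Sequence[float] = (200, 250, 300, 350, 400, 450, 500)
    threeprime_depth: float = 50.0
    run_grid: bool = True
    run_similarity: bool = True
    run_threeprime: bool = True
    out_dir: str = "results/pipeline"

    def to_yaml(self) -> str:
        d = asdict(self)
        d["sim"]["metabolite_h2_range"] = list(d["sim"]["metabolite_h2_range"])
        for key in ("layers", "h2_thresholds", "threeprime_lengths"):
            d[key] = list(d[key])
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text)
        sim = d.pop("sim", {})
        if "metabolite_h2_range" in sim:
            sim["metabolite_h2_range"] = tuple(sim["metabolite_h2_range"])
        if "trait_h2" in sim:
            sim["trait_h2"] = dict(sim["trait_h2"])
        return cls(sim=SimConfig(**sim), **d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _select_representative(ability: pd.DataFrame, members: Sequence[str]) -> str:
    """Most stable member across traits: within each trait, members are
    ranked by median ability (higher ability = higher rank); the member
    maximizing the minimum rank across traits wins, ties broken by mean
    rank, then by name for determinism."""
    sub = ability.loc[list(members)]
    ranks = sub.rank(axis=0, method="average")
    key = pd.DataFrame({
        "min_rank": ranks.min(axis=1), "mean_rank": ranks.mean(axis=1)
    })
    ordered = key.sort_values(
        by=["min_rank", "mean_rank"], ascending=False, kind="mergesort"
    )
    best = ordered.index[0]
    tied = ordered[(ordered["min_rank"] == ordered.loc[best, "min_rank"])
                   & (ordered["mean_rank"] == ordered.loc[best, "mean_rank"])]
    return sorted(tied.index)[0]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every requested stage; returns the result bundle (also written
    under ``config.out_dir``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(config.to_yaml())
    bundle: dict = {"config_hash": config.config_hash()}

    # --- stage 1: simulate -------------------------------------------------
    ds = simulate_dataset(config.sim)
    io_formats.write_feature_matrix_tsv(ds.genotypes, out / "SV.tsv")
    io_formats.write_vcf(ds.genotypes, out / "SV.vcf")
    io_formats.write_gff3(ds.truth.gene_models, out / "genes.gff3")
    for tag, fm in ds.expression.items():
        io_formats.write_feature_matrix_tsv(fm, out / f"{tag}.tsv")
    io_formats.write_long_phenotypes(ds.phenotype_obs, out / "phenotypes.tsv")
    io_formats.write_long_phenotypes(ds.metabolite_obs, out / "metabolites.tsv")
    io_formats.write_json(ds.truth.to_json_dict(), out / "truth.json")

    # --- stage 2: entry means, heritability, metabolite groups -------------
    traits = list(config.sim.trait_h2)
    entry_means: dict[str, pd.Series] = {}
    trait_h2: dict[str, float] = {}
    for t in traits:
        h2, _, em = heritability_from_observations(ds.phenotype_obs, t)
        entry_means[t] = em.means
        trait_h2[t] = h2
    bundle["trait_h2"] = trait_h2

    met_means, met_h2 = {}, {}
    for met in ds.metabolite_target_h2.index:
        h2, _, em = heritability_from_observations(ds.metabolite_obs, met)
        met_means[met] = em.means
        met_h2[met] = h2
    met_means = pd.DataFrame(met_means)
    met_h2 = pd.Series(met_h2)
    met_groups = filter_metabolites(met_means, met_h2, thresholds=config.h2_thresholds)
    bundle["metabolite_h2_mean"] = float(met_h2.mean())
    bundle["metabolite_group_sizes"] = {k: v.shape[1] for k, v in met_groups.items()}
    pd.DataFrame({"h2": met_h2}).to_csv(out / "metabolite_h2.tsv", sep="\t")
    pd.DataFrame(entry_means).to_csv(out / "entry_means.tsv", sep="\t")

    # --- stage 3: feature matrices and kernels per layer -------------------
    dsv, tsv_fm, _ = classify_sift(ds.genotypes)
    epav_s = call_epav(ds.expression["GE_s"], "s")
    epav_l = call_epav(ds.expression["GE_l"], "l")
    epav_ls = combine_epav(epav_s, epav_l)
    matrices = {
        "SV": ds.genotypes, "dSV": dsv, "tSV": tsv_fm,
        "ePAV_s": epav_to_numeric(epav_s),
        "ePAV_l": epav_to_numeric(epav_l),
        "ePAV_ls": epav_to_numeric(epav_ls),
        "GE_s": ds.expression["GE_s"], "GE_l": ds.expression["GE_l"],
        "TE_s": ds.expression["TE_s"], "TE_l": ds.expression["TE_l"],
    }
    from .datatypes import FeatureMatrix
    matrices["M"] = FeatureMatrix(met_groups["M"], "M")
    for name, grp in met_groups.items():
        if name != "M" and grp.shape[1] >= 2:
            matrices[name] = FeatureMatrix(grp, f"{name}")
    matrices = {k: v for k, v in matrices.items()
                if k in config.layers
                or (k.startswith("M_") and "M" in config.layers)}

    kernels: dict[str, Kernel] = {}
    qc_reports = {}
    feature_counts = {}
    for name, fm in matrices.items():
        try:
            kern, rep = kernel_from_features(fm)
        except ValueError as e:
            warnings.warn(f"layer {name} skipped: {e}", stacklevel=2)
            continue
        kernels[name] = kern
        qc_reports[name] = rep.to_dict()
        feature_counts[name] = kern.m
    io_formats.write_json(qc_reports, out / "qc_reports.json")
    bundle["feature_counts"] = feature_counts

    # align all kernels on the common sample set (metabolite panel may differ)
    common = [s for s in ds.genotypes.sample_ids
              if all(s in k.sample_ids for k in kernels.values())]
    kernels = {name: k.restrict(common) for name, k in kernels.items()}

    # --- stage 4: single-predictor CV --------------------------------------
    single_layers = [l for l in config.layers if l in kernels] + \
                    [l for l in kernels if l.startswith("M_")]
    ability = pd.DataFrame(index=single_layers, columns=traits, dtype=float)
    cv_store: dict[str, dict] = {t: {} for t in traits}
    for layer in single_layers:
        for t in traits:
            cv = cross_validate(
                kernels[layer], entry_means[t].loc[common],
                n_folds=config.n_folds, n_replicates=config.n_replicates,
                base_seed=config.cv_seed, keep_predictions=config.run_similarity,
            )
            ability.loc[layer, t] = cv.median_of_medians
            cv_store[t][layer] = cv
    ability.to_csv(out / "single_predictor_abilities.tsv", sep="\t")
    bundle["single_predictor_abilities"] = {
        t: ability[t].to_dict() for t in traits
    }

    # --- stage 5: grid search on representative layers ----------------------
    if config.run_grid and len(kernels) >= 4:
        groups = {
            "SNP": [l for l in ("SV", "dSV", "tSV") if l in kernels],
            "ePAV": [l for l in ("ePAV_s", "ePAV_l", "ePAV_ls") if l in kernels],
            "expression": [l for l in ("GE_s", "GE_l", "TE_s", "TE_l") if l in kernels],
            "M": [l for l in kernels if l == "M" or l.startswith("M_")],
        }
        reps = {
            g: _select_representative(ability, members)
            for g, members in groups.items() if members
        }
        bundle["representatives"] = reps
        grid = enumerate_weight_grid(4, config.grid_step)
        bundle["n_grid_combinations"] = len(grid)
        grid_results = {}
        rep_kernels = [kernels[reps[g]] for g in ("SNP", "ePAV", "expression", "M")]
        for t in traits:
            gs = grid_search(
                rep_kernels, entry_means[t].loc[common], grid=grid,
                n_folds=config.n_folds, n_replicates=config.n_replicates,
                base_seed=config.cv_seed,
            )
            gs.table.to_csv(out / f"grid_{t}.tsv", sep="\t", index=False)
            grid_results[t] = {
                "best_weights": dict(zip(
                    [f"w_{reps[g]}" for g in ("SNP", "ePAV", "expression", "M")],
                    gs.best_weights,
                )),
                "best_ability": gs.best_ability,
            }
        bundle["grid_search"] = grid_results

    # --- stage 6: similarity ------------------------------------------------
    if config.run_similarity:
        k_scores = min(len(common) - 1, 10)
        configs = []
        for layer in single_layers:
            fm = matrices[layer]
            from .kernels import impute_mean, qc_filter
            filt, _ = qc_filter(fm)
            filt = impute_mean(filt)
            filt = FeatureMatrix(filt.values.loc[common], filt.layer, filt.feature_meta)
            configs.append(pca_scores(filt, k_scores))
        aligned, _ = gpa_align(configs)
        gpa_d = procrustes_dissimilarity(aligned)
        gpa_d.to_frame().to_csv(out / "gpa_dissimilarity.tsv", sep="\t")
        coords, percent = pcoa(gpa_d, n_axes=2)
        coords.to_csv(out / "gpa_pcoa.tsv", sep="\t")
        bundle["gpa_pcoa_percent"] = percent.to_dict()

        pv_percent = {}
        for t in traits:
            pv_d = predicted_value_distance(cv_store[t])
            pv_d.to_frame().to_csv(out / f"predicted_value_distance_{t}.tsv", sep="\t")
            c2, p2 = pcoa(pv_d, n_axes=2)
            c2.to_csv(out / f"predicted_value_pcoa_{t}.tsv", sep="\t")
            pv_percent[t] = p2.to_dict()
        bundle["predicted_value_pcoa_percent"] = pv_percent

    # --- stage 7: 3'end study ----------------------------------------------
    if config.run_threeprime:
        table = three_prime_study(
            ds.genotypes, ds.expression["GE_s"], ds.truth.gene_models,
            {t: entry_means[t].loc[common] for t in traits},
            n_list=config.threeprime_lengths,
            depth=config.threeprime_depth,
            n_folds=config.n_folds, n_replicates=config.n_replicates,
            base_seed=config.cv_seed,
            requant_seed=(config.sim.seed + 505) % 2**31,
        )
        table.to_csv(out / "threeprime_study.tsv", sep="\t", index=False)
        bundle["threeprime"] = {
            "n_rows": len(table),
            "baseline_mean_ability": float(
                table.loc[table.window_bp == "full", "ability"].mean()
            ),
            "windowed_mean_ability": float(
                table.loc[table.window_bp != "full", "ability"].mean()
            ),
        }

    manifest = {
        "config_hash": bundle["config_hash"],
        "sim_seed": config.sim.seed,
        "cv_seed": config.cv_seed,
        "cv_replicate_seeds": [
            (config.cv_seed + r) % 2**31 for r in range(config.n_replicates)
        ],
        "requant_seed": (config.sim.seed + 505) % 2**31,
        "stages": ["simulate", "phenostats", "kernels", "cv"]
        + (["grid"] if config.run_grid else [])
        + (["similarity"] if config.run_similarity else [])
        + (["threeprime"] if config.run_threeprime else []),
    }
    io_formats.write_json(manifest, out / "manifest.json")
    io_formats.write_json(bundle, out / "summary.json")
    return bundle


def make_demo(seed: int = 0, out_dir: str = "results/demo") -> PipelineConfig:
    """A small configuration that runs end to end in about a minute."""
    sim = SimConfig(
        n_inbreds=22, n_variants=300, n_genes=60, n_metabolites=24,
        n_environments=3, reps_per_env=4, seed=seed,
    )
    return PipelineConfig(
        sim=sim, n_replicates=10, grid_step=0.5,
        threeprime_lengths=(200, 500), out_dir=out_dir,
    )
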