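"""Synthetic multi-omic panel generator with known genetic architecture.

The generator emulates the structure of a small spring-barley inbred panel:
fully homozygous biallelic genotypes arranged in within-gene linkage
blocks, a deleterious variant subset (SIFT-like scores <= 0.05) carrying
larger effects, two-tissue gene- and transcript-level expression driven by
the genotypes, metabolites downstream of expression with per-metabolite
target entry-mean heritabilities, and multi-environment replicated
phenotypes with genotype-by-environment and residual noise calibrated to a
target entry-mean heritability.

Every quantity a downstream estimator should recover (variant effects,
genetic values, heritabilities, gene models) is recorded in a
:class:`TruthRecord`, so the whole pipeline can be tested against ground
truth.  A single integer seed fans out to fixed per-stage child seeds, so
each stage is individually reproducible and identical configurations give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import FeatureMatrix, GeneModel

__all__ = [
    "SimConfig",
    "TruthRecord",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_metabolites",
    "simulate_phenotypes",
    "simulate_dataset",
    "SimulatedDataset",
]

# fixed per-stage child-seed offsets (all results stay < 2^31)
_STAGE_OFFSETS = {
    "genotypes": 101,
    "expression": 202,
    "metabolites": 303,
    "phenotypes": 404,
}


def _stage_seed(seed: int, stage: str) -> int:
    return (int(seed) + _STAGE_OFFSETS[stage]) % 2**31


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic panel.

    Defaults mirror the emulated design: 23 inbreds, 7 environments with
    replicated checks, metabolite quadruplicates with target heritabilities
    spanning 0-0.98, three traits with entry-mean heritabilities around
    0.83-0.91, and a deleterious variant fraction of ~12% of scored
    variants.  Feature counts are scaled down from the real panel (which
    carries 10^5-scale variant and transcript sets) to sizes where every
    stage runs in seconds; the kernel estimators under test are
    insensitive to this scale.
    """

    n_inbreds: int = 23
    n_variants: int = 1000
    n_genes: int = 120
    max_transcripts_per_gene: int = 4
    fraction_deleterious: float = 0.12
    n_metabolites: int = 144
    metabolite_h2_range: tuple[float, float] = (0.0, 0.98)
    n_environments: int = 7
    reps_per_env: int = 10
    metabolite_reps: int = 4
    trait_h2: dict = field(
        default_factory=lambda: {"LA": 0.91, "PH": 0.83, "HT": 0.90}
    )
    trait_causal_overlap: float = 0.5
    tissue_divergence: float = 0.3
    block_correlation: float = 0.9
    missing_rate: float = 0.02
    epav_zero_rate: float = 0.10
    expression_noise_sd: float = 0.2
    n_causal_per_trait: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_inbreds": self.n_inbreds, "n_variants": self.n_variants,
            "n_genes": self.n_genes, "n_metabolites": self.n_metabolites,
            "n_environments": self.n_environments, "reps_per_env": self.reps_per_env,
            "metabolite_reps": self.metabolite_reps,
            "max_transcripts_per_gene": self.max_transcripts_per_gene,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        props = {
            "fraction_deleterious": self.fraction_deleterious,
            "tissue_divergence": self.tissue_divergence,
            "block_correlation": self.block_correlation,
            "missing_rate": self.missing_rate,
            "epav_zero_rate": self.epav_zero_rate,
            "trait_causal_overlap": self.trait_causal_overlap,
        }
        for name, v in props.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        lo, hi = self.metabolite_h2_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"metabolite_h2_range must be within [0,1], got {(lo, hi)}")
        for t, h in self.trait_h2.items():
            if not 0.0 <= h <= 1.0:
                raise ValueError(f"trait_h2[{t!r}] must be in [0,1], got {h}")
        if self.n_variants < self.n_genes:
            raise ValueError(
                f"n_variants ({self.n_variants}) < n_genes ({self.n_genes}): "
                "each gene needs at least one variant"
            )


@dataclass
class TruthRecord:
    """Ground truth paired with a simulated dataset."""

    true_variant_effects: pd.Series = None            # variant -> effect size
    deleterious_flags: pd.Series = None               # variant -> bool
    gene_models: list[GeneModel] = field(default_factory=list)
    variant_positions: pd.DataFrame = None            # variant -> gene, genomic pos
    true_genetic_values: Optional[pd.DataFrame] = None   # inbred x trait
    true_metabolite_h2: Optional[pd.Series] = None
    tissue_shift_genes: Optional[list[str]] = None
    trait_causal_variants: Optional[dict] = None

    def to_json_dict(self) -> dict:
        out = {
            "true_variant_effects": self.true_variant_effects.to_dict(),
            "deleterious_flags": {k: bool(v) for k, v in self.deleterious_flags.items()},
            "gene_models": [asdict(g) for g in self.gene_models],
        }
        if self.true_genetic_values is not None:
            out["true_genetic_values"] = self.true_genetic_values.to_dict()
        if self.true_metabolite_h2 is not None:
            out["true_metabolite_h2"] = self.true_metabolite_h2.to_dict()
        return out


# ---------------------------------------------------------------------------
# Genotypes, gene models, variant effects
# ---------------------------------------------------------------------------

def simulate_genotypes(config: SimConfig) -> tuple[FeatureMatrix, TruthRecord]:
    """Homozygous biallelic genotypes ({0,1}) in within-gene linkage blocks.

    Variants inside a gene copy a shared gene haplotype with probability
    ``block_correlation`` and segregate independently otherwise.  A
    ``fraction_deleterious`` subset gets SIFT-like scores <= 0.05 and
    effect sizes five times larger on average than tolerant variants; a
    small fraction of genotype calls is set missing.
    """
    rng = np.random.default_rng(_stage_seed(config.seed, "genotypes"))
    n, v, g = config.n_inbreds, config.n_variants, config.n_genes

    # gene models on 7 chromosome-like scaffolds, lengths ~ 0.5-5 kb
    lengths = rng.integers(500, 5001, size=g)
    chroms = [f"chr{(i % 7) + 1}H" for i in range(g)]
    gene_models, cursor = [], {}
    for i in range(g):
        c = chroms[i]
        start = cursor.get(c, 1000)
        gene_models.append(
            GeneModel(
                gene_id=f"gene{i:04d}", chrom=c,
                strand="+" if rng.random() < 0.5 else "-",
                start=int(start), end=int(start + lengths[i] - 1),
            )
        )
        cursor[c] = start + lengths[i] + rng.integers(200, 2000)

    # each gene gets >= 1 variant; the remainder multinomial across genes
    gene_of = np.concatenate([np.arange(g), rng.integers(0, g, size=v - g)])
    gene_of.sort()
    variant_ids = [f"var{i:05d}" for i in range(v)]
    positions = np.empty(v, dtype=int)
    for i, gi in enumerate(gene_of):
        gm = gene_models[gi]
        positions[i] = rng.integers(gm.start, gm.end + 1)

    freqs = rng.uniform(0.1, 0.9, size=g)
    hap = (rng.random((n, g)) < freqs).astype(float)        # gene haplotype
    X = np.empty((n, v))
    for i, gi in enumerate(gene_of):
        copy = rng.random(n) < config.block_correlation
        indep = (rng.random(n) < freqs[gi]).astype(float)
        X[:, i] = np.where(copy, hap[:, gi], indep)

    n_del = int(round(config.fraction_deleterious * v))
    del_idx = rng.choice(v, size=n_del, replace=False)
    deleterious = np.zeros(v, dtype=bool)
    deleterious[del_idx] = True
    sift = rng.uniform(0.05 + 1e-6, 1.0, size=v)
    sift[deleterious] = rng.uniform(0.0, 0.05, size=n_del)

    effects = rng.normal(0.0, 0.2, size=v)
    effects[deleterious] = rng.normal(0.0, 1.0, size=n_del)

    if config.missing_rate > 0:
        X[rng.random((n, v)) < config.missing_rate] = np.nan

    inbreds = [f"inbred{i:02d}" for i in range(n)]
    values = pd.DataFrame(
        X, index=pd.Index(inbreds, name="sample"),
        columns=pd.Index(variant_ids, name="feature"),
    )
    meta = pd.DataFrame(
        {
            "chrom": [gene_models[gi].chrom for gi in gene_of],
            "pos": positions,
            "gene": [gene_models[gi].gene_id for gi in gene_of],
            "sift_score": sift,
        },
        index=values.columns,
    )
    truth = TruthRecord(
        true_variant_effects=pd.Series(effects, index=variant_ids),
        deleterious_flags=pd.Series(deleterious, index=variant_ids),
        gene_models=gene_models,
        variant_positions=meta[["gene", "pos"]].copy(),
    )
    return FeatureMatrix(values, "SV", meta), truth


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def simulate_expression(
    genotypes: FeatureMatrix, truth: TruthRecord, config: SimConfig
) -> dict[str, FeatureMatrix]:
    """Two-tissue gene- and transcript-level FPKM-like expression.

    Per gene, expression is softplus(cis variant effects + a few trans
    effects + tissue shift + noise); a ``tissue_divergence`` fraction of
    genes carries a leaf-specific shift.  Transcript values are a Dirichlet
    isoform split of the gene value, so gene expression equals the sum of
    its transcript expressions exactly.  A fraction of (inbred, gene) pairs
    is zeroed with probability decreasing in the gene's genetic value,
    creating presence/absence structure that carries signal.

    Returns a dict with keys ``GE_s``, ``GE_l``, ``TE_s``, ``TE_l``.
    """
    rng = np.random.default_rng(_stage_seed(config.seed, "expression"))
    X = genotypes.values.to_numpy(float)
    X = np.where(np.isnan(X), np.nanmean(X, axis=0), X)  # truth side: fill gaps
    inbreds = genotypes.sample_ids
    n = len(inbreds)
    genes = [g.gene_id for g in truth.gene_models]
    gene_idx = {g: i for i, g in enumerate(genes)}
    var_gene = truth.variant_positions["gene"].to_numpy()
    effects = truth.true_variant_effects.to_numpy()

    n_genes = len(genes)
    base = rng.uniform(0.5, 3.0, size=n_genes)
    shift_mask = rng.random(n_genes) < config.tissue_divergence
    shift = np.where(shift_mask, rng.normal(0.0, 2.0, size=n_genes), 0.0)

    # cis genetic value per gene
    Gval = np.zeros((n, n_genes))
    for j, gname in enumerate(var_gene):
        Gval[:, gene_idx[gname]] += X[:, j] * effects[j]
    # sparse trans contributions
    n_trans = min(2, n_genes - 1)
    for gi in range(n_genes):
        partners = rng.choice(n_genes, size=n_trans, replace=False)
        for p in partners:
            if p != gi:
                Gval[:, gi] += 0.1 * (Gval[:, p] - Gval[:, p].mean())

    zstd = Gval.std(axis=0)
    z = (Gval - Gval.mean(axis=0)) / np.where(zstd == 0, 1.0, zstd)

    tpg = rng.integers(1, config.max_transcripts_per_gene + 1, size=n_genes)
    out: dict[str, FeatureMatrix] = {}
    for tissue, tag in (("s", "seedling"), ("l", "leaf")):
        noise = rng.normal(0.0, config.expression_noise_sd, size=(n, n_genes))
        lin = base + Gval + (shift if tissue == "l" else 0.0) + noise
        expr = _softplus(lin)
        # presence/absence: zeroing probability decreasing in genetic value
        if config.epav_zero_rate > 0:
            p_zero = config.epav_zero_rate * 2.0 / (1.0 + np.exp(z))
            expr = np.where(rng.random((n, n_genes)) < p_zero, 0.0, expr)
        ge = pd.DataFrame(
            expr, index=pd.Index(inbreds, name="sample"),
            columns=pd.Index(genes, name="feature"),
        )
        # isoform split conserving the gene total
        t_cols, t_vals, t_gene = [], [], []
        for gi, gname in enumerate(genes):
            k = tpg[gi]
            frac = rng.dirichlet(np.ones(k) * 2.0, size=n) if k > 1 else np.ones((n, 1))
            for t in range(k):
                t_cols.append(f"{gname}.t{t + 1}")
                t_vals.append(expr[:, gi] * frac[:, t])
                t_gene.append(gname)
        te = pd.DataFrame(
            np.column_stack(t_vals), index=ge.index,
            columns=pd.Index(t_cols, name="feature"),
        )
        te_meta = pd.DataFrame({"gene": t_gene}, index=te.columns)
        ge_meta = pd.DataFrame({"gene": genes}, index=ge.columns)
        out[f"GE_{tissue}"] = FeatureMatrix(ge, f"GE_{tissue}", ge_meta)
        out[f"TE_{tissue}"] = FeatureMatrix(te, f"TE_{tissue}", te_meta)
    truth.tissue_shift_genes = [genes[i] for i in np.flatnonzero(shift_mask)]
    return out


# ---------------------------------------------------------------------------
# Metabolites
# ---------------------------------------------------------------------------

def simulate_metabolites(
    expression: FeatureMatrix, config: SimConfig, truth: Optional[TruthRecord] = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Replicated single-environment metabolite observations.

    Each metabolite is a sparse linear combination of gene expressions,
    standardized and rescaled so that with ``metabolite_reps`` replicates
    its entry-mean heritability matches a target drawn uniformly from
    ``metabolite_h2_range``: the genetic component has variance h and the
    replicate noise variance r*(1-h), giving H^2 = h exactly in
    expectation.  Returns the long-format observations and the per-
    metabolite target heritabilities.
    """
    lo, hi = config.metabolite_h2_range
    if hi >= 1.0 and lo >= 1.0:
        raise ValueError("target heritability 1 is unreachable with finite replicates")
    rng = np.random.default_rng(_stage_seed(config.seed, "metabolites"))
    E = expression.values.to_numpy(float)
    inbreds = expression.sample_ids
    n, p = E.shape
    r = config.metabolite_reps
    targets = rng.uniform(lo, min(hi, 1.0 - 1e-9), size=config.n_metabolites)
    if np.any(targets >= 1.0):
        raise ValueError("target heritability 1 is unreachable with finite replicates")

    rows = []
    met_ids = [f"met{k:03d}" for k in range(config.n_metabolites)]
    for k, met in enumerate(met_ids):
        h = targets[k]
        n_src = min(3, p)
        src = rng.choice(p, size=n_src, replace=False)
        w = rng.normal(0.0, 1.0, size=n_src)
        gval = E[:, src] @ w
        sd = gval.std(ddof=1)
        if sd == 0 or h == 0:
            gval = np.zeros(n)
        else:
            gval = (gval - gval.mean()) / sd * np.sqrt(h)
        noise_sd = np.sqrt(r * (1.0 - h))
        obs = gval[:, None] + rng.normal(0.0, noise_sd, size=(n, r))
        for i, inbred in enumerate(inbreds):
            for rep in range(r):
                rows.append((inbred, rep + 1, met, obs[i, rep]))
    df = pd.DataFrame(rows, columns=["genotype", "replicate", "trait", "value"])
    h2 = pd.Series(targets, index=met_ids, name="target_h2")
    if truth is not None:
        truth.true_metabolite_h2 = h2
    return df, h2


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def _trait_genetic_values(
    genotypes: FeatureMatrix, truth: TruthRecord, config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-trait additive values from (partially shared) causal variant sets."""
    X = genotypes.values.to_numpy(float)
    X = np.where(np.isnan(X), np.nanmean(X, axis=0), X)
    v = X.shape[1]
    traits = list(config.trait_h2)
    k = min(config.n_causal_per_trait, v)
    shared = rng.choice(v, size=int(round(config.trait_causal_overlap * k)), replace=False)
    gvals, causal_sets = {}, {}
    effects = truth.true_variant_effects.to_numpy()
    for t in traits:
        rest_pool = np.setdiff1d(np.arange(v), shared)
        own = rng.choice(rest_pool, size=k - shared.size, replace=False)
        idx = np.concatenate([shared, own])
        # shared causal variants keep their sign across traits, so overlap
        # translates into positive genetic correlation
        sign = np.concatenate([
            np.ones(shared.size), rng.choice([-1.0, 1.0], size=own.size)
        ])
        g = X[:, idx] @ (effects[idx] * sign)
        gvals[t] = g
        causal_sets[t] = [genotypes.feature_ids[i] for i in idx]
    gdf = pd.DataFrame(gvals, index=genotypes.sample_ids)
    truth.true_genetic_values = gdf
    truth.trait_causal_variants = causal_sets
    return gdf


def simulate_phenotypes(
    truth: TruthRecord,
    config: SimConfig,
    genotypes: Optional[FeatureMatrix] = None,
) -> pd.DataFrame:
    """Balanced multi-environment replicated phenotypes, long format.

    y_ijk = mu + G_i + E_j + (GxE)_ij + e_ijk.  For each trait the
    genotype-by-environment and residual variances are calibrated against
    the realized genetic variance so the entry-mean heritability matches
    the target:  nu_bar/2 = s2_G (1-h)/h is split evenly between the GxE
    term (contributing s2_GxE/J) and the residual (s2_e/(J r)).
    """
    rng = np.random.default_rng(_stage_seed(config.seed, "phenotypes"))
    if truth.true_genetic_values is None:
        if genotypes is None:
            raise ValueError("need true genetic values or genotypes to derive them")
        _trait_genetic_values(genotypes, truth, config, rng)
    gdf = truth.true_genetic_values
    inbreds = list(gdf.index)
    n, J, r = len(inbreds), config.n_environments, config.reps_per_env
    rows = []
    for t in gdf.columns:
        h = config.trait_h2[t]
        g = gdf[t].to_numpy(float)
        s2g = g.var(ddof=1)
        if s2g == 0:
            g = np.zeros(n)
            s2g = 0.0
        if h >= 1.0 or s2g == 0:
            s2_ge = s2_e = 0.0
        else:
            half_nu = s2g * (1.0 - h) / h
            s2_ge = J * half_nu / 2.0
            s2_e = J * r * half_nu / 2.0
        mu = 10.0
        env_eff = rng.normal(0.0, np.sqrt(s2g) if s2g > 0 else 1.0, size=J)
        ge_eff = rng.normal(0.0, np.sqrt(s2_ge), size=(n, J)) if s2_ge > 0 else np.zeros((n, J))
        eps = rng.normal(0.0, np.sqrt(s2_e), size=(n, J, r)) if s2_e > 0 else np.zeros((n, J, r))
        for i, inbred in enumerate(inbreds):
            for j in range(J):
                for rep in range(r):
                    rows.append((
                        inbred, f"env{j + 1}", rep + 1, t,
                        mu + g[i] + env_eff[j] + ge_eff[i, j] + eps[i, j, rep],
                    ))
    return pd.DataFrame(
        rows, columns=["genotype", "environment", "replicate", "trait", "value"]
    )


# ---------------------------------------------------------------------------
# Whole-panel convenience
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: SimConfig
    genotypes: FeatureMatrix
    expression: dict[str, FeatureMatrix]
    metabolite_obs: pd.DataFrame
    metabolite_target_h2: pd.Series
    phenotype_obs: pd.DataFrame
    truth: TruthRecord


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Run every stage with the config's fanned-out child seeds."""
    genotypes, truth = simulate_genotypes(config)
    expression = simulate_expression(genotypes, truth, config)
    met_obs, met_h2 = simulate_metabolites(expression["GE_l"], config, truth)
    pheno = simulate_phenotypes(truth, config, genotypes=genotypes)
    return SimulatedDataset(
        config=config, genotypes=genotypes, expression=expression,
        metabolite_obs=met_obs, metabolite_target_h2=met_h2,
        phenotype_obs=pheno, truth=truth,
    )
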