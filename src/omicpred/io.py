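"""Readers and writers for the formats the pipeline touches.

Feature matrices travel as TSV with features in rows and samples in
columns (header row = sample ids, first column = feature ids); empty cells
and ``NA`` are missing.  Variants come from VCF 4.x (biallelic, inbred
samples), gene models from GFF3 (1-based inclusive coordinates), and
replicated phenotypes/metabolites from long-format TSV.

All readers validate eagerly and raise located errors; write followed by
read is the identity on the in-memory data model.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .datatypes import FeatureMatrix, GeneModel

__all__ = [
    "read_feature_matrix_tsv",
    "write_feature_matrix_tsv",
    "read_vcf_genotypes",
    "write_vcf",
    "read_gff3_genes",
    "write_gff3",
    "read_long_phenotypes",
    "write_long_phenotypes",
]

MISSING_TOKENS = ("", "NA")

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# Feature-matrix TSV
# ---------------------------------------------------------------------------

def read_feature_matrix_tsv(
    path: PathLike, layer: str, meta_columns: Sequence[str] = ()
) -> FeatureMatrix:
    """Read a features x samples TSV into a samples x features FeatureMatrix.

    ``meta_columns`` names leading columns (after the feature id) holding
    per-feature metadata rather than sample values.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ValueError(f"{path}:1: header must name at least one sample")
        sample_ids = header[1 + len(meta_columns):]
        ncol = len(header)
        feature_ids: list[str] = []
        meta_rows: list[list[str]] = []
        data_rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != ncol:
                raise ValueError(
                    f"{path}:{lineno}: expected {ncol} columns, found {len(fields)}"
                )
            feature_ids.append(fields[0])
            meta_rows.append(fields[1:1 + len(meta_columns)])
            row = np.empty(len(sample_ids))
            for j, cell in enumerate(fields[1 + len(meta_columns):]):
                if cell in MISSING_TOKENS:
                    row[j] = np.nan
                else:
                    try:
                        row[j] = float(cell)
                    except ValueError:
                        raise ValueError(
                            f"{path}:{lineno}: non-numeric cell {cell!r} "
                            f"for sample {sample_ids[j]!r}"
                        ) from None
            data_rows.append(row)
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError(f"{path}: duplicate sample ids in header")
    if len(set(feature_ids)) != len(feature_ids):
        raise ValueError(f"{path}: duplicate feature ids")
    values = pd.DataFrame(
        np.vstack(data_rows).T if data_rows else np.empty((len(sample_ids), 0)),
        index=pd.Index(sample_ids, name="sample"),
        columns=pd.Index(feature_ids, name="feature"),
    )
    meta = None
    if meta_columns:
        meta = pd.DataFrame(
            meta_rows, index=values.columns, columns=list(meta_columns)
        ).replace(dict.fromkeys(MISSING_TOKENS, np.nan))
        for c in meta.columns:
            conv = pd.to_numeric(meta[c], errors="coerce")
            if conv.notna().sum() == meta[c].notna().sum():
                meta[c] = conv
    return FeatureMatrix(values, layer, meta)


def write_feature_matrix_tsv(fm: FeatureMatrix, path: PathLike) -> None:
    """Inverse of :func:`read_feature_matrix_tsv` (metadata written alongside
    as ``<path>.meta.tsv`` when present)."""
    path = Path(path)
    out = fm.values.T
    out.index.name = "feature"
    out.to_csv(path, sep="\t", na_rep="NA")
    if fm.feature_meta is not None:
        fm.feature_meta.to_csv(path.with_suffix(path.suffix + ".meta.tsv"), sep="\t")


def read_feature_matrix_with_meta(path: PathLike, layer: str) -> FeatureMatrix:
    """Read a matrix written by :func:`write_feature_matrix_tsv`, restoring the
    metadata sidecar when it exists."""
    path = Path(path)
    fm = read_feature_matrix_tsv(path, layer)
    meta_path = path.with_suffix(path.suffix + ".meta.tsv")
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        meta.index = meta.index.astype(str)
        fm = FeatureMatrix(fm.values, layer, meta.loc[fm.feature_ids])
    return fm


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf_genotypes(
    path: PathLike,
    sift_info_key: str = "SIFT",
    het_policy: str = "missing",
    split_multiallelic: bool = False,
) -> FeatureMatrix:
    """Genotypes of homozygous inbreds from a VCF as a {0,1} feature matrix.

    0/0 -> 0, 1/1 -> 1, ./. -> missing.  Heterozygous calls follow
    ``het_policy``: ``"missing"`` (default; a summary warning reports the
    count) or ``"error"``.  Multi-allelic records raise unless
    ``split_multiallelic`` is set, in which case only the first alternate
    allele is scored.  A per-variant SIFT score is read from the INFO field
    ``sift_info_key`` when present, alongside gene id (``GENE``) and the
    record position.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variant_ids, rows, meta = [], [], []
    n_het = 0
    for rec in vcf:
        if len(rec.ALT) > 1 and not split_multiallelic:
            raise ValueError(
                f"{path}: multi-allelic record at {rec.CHROM}:{rec.POS} "
                "(set split_multiallelic to score the first ALT only)"
            )
        vid = rec.ID or f"{rec.CHROM}_{rec.POS}"
        row = np.empty(len(samples))
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt(=3 in cyvcf2>=0.30 is unknown)
        for j, gt in enumerate(rec.gt_types):
            if gt == 0:
                row[j] = 0.0
            elif gt == 3:
                row[j] = 1.0
            elif gt == 2:
                row[j] = np.nan
            else:  # heterozygous
                if het_policy == "error":
                    raise ValueError(
                        f"{path}: heterozygous call at {rec.CHROM}:{rec.POS} "
                        f"sample {samples[j]}"
                    )
                n_het += 1
                row[j] = np.nan
        variant_ids.append(vid)
        rows.append(row)
        meta.append({
            "chrom": rec.CHROM,
            "pos": rec.POS,
            "gene": rec.INFO.get("GENE"),
            "sift_score": rec.INFO.get(sift_info_key),
        })
    if n_het:
        warnings.warn(
            f"{n_het} heterozygous calls set to missing (inbred panel expected)",
            stacklevel=2,
        )
    values = pd.DataFrame(
        np.vstack(rows).T if rows else np.empty((len(samples), 0)),
        index=pd.Index(samples, name="sample"),
        columns=pd.Index(variant_ids, name="feature"),
    )
    meta_df = pd.DataFrame(meta, index=values.columns)
    meta_df["sift_score"] = pd.to_numeric(meta_df["sift_score"], errors="coerce")
    return FeatureMatrix(values, "SV", meta_df)


def write_vcf(fm: FeatureMatrix, path: PathLike, sift_info_key: str = "SIFT") -> None:
    """Write a {0,1,missing} inbred genotype matrix as an uncompressed VCF.

    Plain-text emitter (cyvcf2 is read-only without a template); alleles are
    placeholder A/T, positions and gene ids come from ``feature_meta``.
    """
    vals = fm.values
    meta = fm.feature_meta if fm.feature_meta is not None else pd.DataFrame(index=vals.columns)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f'##INFO=<ID={sift_info_key},Number=1,Type=Float,Description="SIFT score">\n')
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = meta["chrom"].unique() if "chrom" in meta else ["1"]
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(vals.index) + "\n")
        for k, vid in enumerate(vals.columns):
            chrom = meta["chrom"].get(vid, "1") if "chrom" in meta else "1"
            pos = int(meta["pos"].get(vid, k + 1)) if "pos" in meta else k + 1
            info = []
            if "gene" in meta and pd.notna(meta["gene"].get(vid)):
                info.append(f"GENE={meta['gene'][vid]}")
            if "sift_score" in meta and pd.notna(meta["sift_score"].get(vid)):
                info.append(f"{sift_info_key}={meta['sift_score'][vid]:.8g}")
            gts = [
                "./." if np.isnan(v) else ("1/1" if v == 1 else "0/0")
                for v in vals[vid].to_numpy(float)
            ]
            fh.write(
                f"{chrom}\t{pos}\t{vid}\tA\tT\t.\tPASS\t{';'.join(info) or '.'}\tGT\t"
                + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3_genes(path: PathLike) -> list[GeneModel]:
    """Gene features from a GFF3 file as :class:`GeneModel` records.

    Coordinates are 1-based inclusive per the GFF3 standard; a gene without
    a strand is rejected because 3'end windowing is strand-dependent.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="error",
    )
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        if feat.strand not in ("+", "-"):
            raise ValueError(
                f"{path}: gene {feat.id} at {feat.seqid}:{feat.start} lacks a "
                "strand (3'end windowing is strand-dependent)"
            )
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        genes.append(
            GeneModel(
                gene_id=gene_id, chrom=feat.seqid, strand=feat.strand,
                start=feat.start, end=feat.end,
            )
        )
    return genes


def write_gff3(genes: Sequence[GeneModel], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tomicpred\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# Long-format phenotypes / metabolites
# ---------------------------------------------------------------------------

def read_long_phenotypes(path: PathLike) -> pd.DataFrame:
    """Long-format replicated observations.

    Requires ``genotype``, ``replicate``, ``value`` columns (plus ``trait``
    when several traits share the file).  A missing ``environment`` column is
    accepted as a single implicit environment — the single-environment model
    path used for greenhouse metabolites.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"genotype", "replicate", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "environment" not in df.columns:
        df["environment"] = "env1"
    try:
        df["value"] = pd.to_numeric(df["value"])
    except (ValueError, TypeError) as e:
        raise ValueError(f"{path}: non-numeric value column: {e}") from None
    keys = ["genotype", "environment", "replicate"]
    if "trait" in df.columns:
        keys.append("trait")
    dup = df.duplicated(subset=keys)
    if dup.any():
        first = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate observation row for "
            + ", ".join(f"{k}={first[k]}" for k in keys)
        )
    return df


def write_long_phenotypes(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def completeness_report(df: pd.DataFrame) -> pd.DataFrame:
    """Per-trait observation counts and genotype/environment coverage."""
    if "trait" not in df.columns:
        df = df.assign(trait="trait")
    return df.groupby("trait").agg(
        n_obs=("value", "size"),
        n_genotypes=("genotype", "nunique"),
        n_environments=("environment", "nunique"),
        n_missing=("value", lambda s: int(s.isna().sum())),
    )


def write_json(obj, path: PathLike) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
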