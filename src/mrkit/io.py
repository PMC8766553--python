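"""Readers and writers for the pipeline's tab-separated and VCF formats.

Missing values are empty fields in every TSV; allele strings are upper-cased
on read; dropped rows are counted and logged. Variant IDs are opaque
strings — no positional arithmetic anywhere.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SUMMARY_MANDATORY = ["snp", "effect_allele", "other_allele", "beta", "se"]
SUMMARY_OPTIONAL = ["eaf", "pval", "n"]

_FLOAT_FMT = "%.10g"


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[""], keep_default_na=False)


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, na_rep="")


def read_summary_stats(path) -> pd.DataFrame:
    """GWAS summary statistics TSV with columns snp/effect_allele/other_allele/beta/se.

    Header matching is case-insensitive ('SNP' == 'snp'). Rows missing any
    mandatory field are dropped with a count; alleles are upper-cased.
    """
    df = _read_tsv(path)
    df.columns = [c.lower() for c in df.columns]
    for col in SUMMARY_MANDATORY:
        if col not in df.columns:
            raise ValueError(f"missing column: {col}")
    before = len(df)
    df = df.dropna(subset=SUMMARY_MANDATORY)
    dropped = before - len(df)
    if dropped:
        log.warning("%s: dropped %d rows with missing mandatory fields",
                    path, dropped)
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    for col in ["beta", "se"] + [c for c in SUMMARY_OPTIONAL if c in df.columns]:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df.reset_index(drop=True)


def write_summary_stats(df: pd.DataFrame, path) -> None:
    _write_tsv(df, path)


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype TSV keyed by participant_id; empty fields are missing."""
    df = _read_tsv(path)
    if "participant_id" not in df.columns:
        raise ValueError("missing column: participant_id")
    df["participant_id"] = df["participant_id"].astype(str)
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    _write_tsv(out, path)


def read_dosages_tsv(path):
    """Dosage matrix TSV: first column participant id, one column per variant.

    Returns (participant ids, matrix, variant ids). Any dosage outside
    [0, 2] is an error naming the row and column.
    """
    df = _read_tsv(path)
    ids = df.iloc[:, 0].astype(str).to_numpy()
    variant_ids = list(df.columns[1:])
    mat = df.iloc[:, 1:].to_numpy(dtype=float)
    bad = np.argwhere(np.isfinite(mat) & ((mat < 0) | (mat > 2)))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"dosage out of [0,2] at participant {ids[i]}, variant "
            f"{variant_ids[j]}: {mat[i, j]}")
    return ids, mat, variant_ids


def write_dosages_tsv(ids, matrix, variant_ids, path) -> None:
    df = pd.DataFrame(np.asarray(matrix, dtype=float), columns=list(variant_ids))
    df.insert(0, "participant_id", list(ids))
    _write_tsv(df, path)


def read_vcf_dosages(path):
    """Genotypes from a VCF: DS FORMAT field preferred, else GT -> {0,1,2}.

    Half-calls and missing genotypes become NaN. Returns
    (sample ids, matrix, variant_meta DataFrame).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, meta = [], []
    for var in vcf:
        if "DS" in (var.FORMAT or []):
            ds = np.asarray(var.format("DS"), dtype=float).reshape(-1)
        else:
            gt = np.asarray(var.genotype.array())
            alleles = gt[:, :2].astype(float)
            alleles[alleles < 0] = np.nan  # missing / half calls
            ds = alleles.sum(axis=1)
        cols.append(ds)
        meta.append({"snp": var.ID or f"{var.CHROM}:{var.POS}",
                     "effect_allele": var.ALT[0], "other_allele": var.REF,
                     "eaf": np.nan})
    mat = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return samples, mat, pd.DataFrame(meta)


def write_vcf_dosages(ids, matrix, variant_meta: pd.DataFrame, path) -> None:
    """Minimal single-chromosome VCF with a DS FORMAT field."""
    ids = list(ids)
    matrix = np.asarray(matrix, dtype=float)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ids) + "\n")
        for j, (_, var) in enumerate(variant_meta.iterrows()):
            vals = "\t".join(
                "." if not np.isfinite(d) else f"{d:g}" for d in matrix[:, j])
            fh.write(f"1\t{j + 1}\t{var['snp']}\t{var['other_allele']}\t"
                     f"{var['effect_allele']}\t.\tPASS\t.\tDS\t{vals}\n")


def read_instruments(path) -> pd.DataFrame:
    """Instrument weight list: snp, effect_allele, other_allele, beta[, eaf]."""
    df = _read_tsv(path)
    df.columns = [c.lower() for c in df.columns]
    for col in ("snp", "effect_allele", "other_allele", "beta"):
        if col not in df.columns:
            raise ValueError(f"missing column: {col}")
    before = len(df)
    df = df.dropna(subset=["snp", "effect_allele", "other_allele", "beta"])
    if before - len(df):
        log.warning("%s: dropped %d instrument rows with missing fields",
                    path, before - len(df))
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    df["beta"] = pd.to_numeric(df["beta"], errors="coerce")
    if "eaf" in df.columns:
        df["eaf"] = pd.to_numeric(df["eaf"], errors="coerce")
    return df.rename(columns={"beta": "weight"}).reset_index(drop=True)


def format_p(p: float) -> str:
    """Scientific notation with 3 significant digits (results-table style)."""
    return f"{p:.2E}"
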