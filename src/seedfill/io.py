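"""Readers and writers for the delimited-text formats of the pipeline.

All tabular inputs are comma- or tab-separated text with explicit headers
(the delimiter is sniffed from the header line).  Readers validate and
refuse rather than coerce: duplicated keys, negative weights, unknown
genotype codes and missing columns are errors naming the offence.  Bulk
allele depths may also come from a VCF (the only standard bioinformatics
format consumed) whose per-sample AD subfields carry ref/alt read counts;
VCF positions are 1-based per the standard.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .bsa import BULK_COUNT_COLS
from .growth import WeightSeries
from .linkage import MAP_COLS

__all__ = [
    "read_weight_table",
    "write_weight_table",
    "read_genotypes",
    "write_genotypes",
    "read_map",
    "write_map",
    "read_counts",
    "read_bulk_table",
    "read_bulk_vcf",
    "write_table",
]

GENO_CODES = {"A": -1.0, "B": 1.0, "NA": np.nan}
WEIGHT_COLS = ["line_id", "environment", "dap", "weight_g"]


def _read_delim(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a delimited table, sniffing comma vs tab from the header."""
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    return pd.read_csv(path, sep=sep, **kwargs)


def _require(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def read_weight_table(path: str | Path) -> list[WeightSeries]:
    """Long-format dry-weight table -> list of WeightSeries.

    Columns: line_id, environment, dap, weight_g.  Duplicate
    (line, environment, dap) rows and negative weights are errors.
    """
    df = _read_delim(path)
    _require(df, WEIGHT_COLS, path)
    dup = df.duplicated(["line_id", "environment", "dap"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicated measurement for "
            f"({row['line_id']}, {row['environment']}, dap={row['dap']})"
        )
    neg = df.index[df["weight_g"] < 0]
    if len(neg):
        raise ValueError(f"{path}: negative weight at row {neg[0] + 2} (1-based, incl. header)")
    series = []
    for (line, env), sub in df.groupby(["line_id", "environment"], sort=True):
        sub = sub.sort_values("dap")
        series.append(
            WeightSeries(
                line_id=str(line),
                environment=str(env),
                times=sub["dap"].to_numpy(dtype=float),
                weights=sub["weight_g"].to_numpy(dtype=float),
            )
        )
    return series


def write_weight_table(series: list[WeightSeries], path: str | Path, sep: str = "\t") -> None:
    rows = [
        {"line_id": s.line_id, "environment": s.environment, "dap": t, "weight_g": w}
        for s in series
        for t, w in zip(s.times, s.weights)
    ]
    pd.DataFrame(rows, columns=WEIGHT_COLS).to_csv(path, sep=sep, index=False)


def read_genotypes(path: str | Path) -> pd.DataFrame:
    """Lines x markers genotype matrix coded A/B/NA -> -1/+1/NaN.

    Heterozygote codes ("H") are recoded to missing with a warning and
    count (RILs carry no heterozygotes); any other symbol is an error
    listing the offending codes.
    """
    df = _read_delim(path, index_col=0, dtype=str)
    vals = df.to_numpy(dtype=object)
    flat = pd.unique(vals.ravel())
    known = set(GENO_CODES) | {"H"}
    bad = [v for v in flat if not (isinstance(v, float) and np.isnan(v)) and v not in known]
    if bad:
        raise ValueError(f"{path}: unknown genotype code(s) {sorted(map(str, bad))}")
    n_het = int(np.sum(vals == "H"))
    if n_het:
        warnings.warn(f"{path}: {n_het} heterozygote call(s) recoded to missing")
    lut = {"H": np.nan, **GENO_CODES}
    coded = pd.DataFrame(
        np.vectorize(lambda v: lut.get(v, np.nan))(vals).astype(float),
        index=df.index, columns=df.columns,
    )
    coded.index.name = "line_id"
    return coded


def write_genotypes(geno: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    mapping = {-1.0: "A", 1.0: "B"}
    out = geno.copy()
    out = out.map(lambda v: mapping.get(v, "NA") if not pd.isna(v) else "NA")
    out.index.name = "line_id"
    out.to_csv(path, sep=sep)


def read_map(path: str | Path) -> pd.DataFrame:
    """Genetic map table with columns marker, chrom, cm (sorted, unique ids)."""
    df = _read_delim(path)
    _require(df, MAP_COLS, path)
    if df["marker"].duplicated().any():
        dup = df.loc[df["marker"].duplicated(), "marker"].iloc[0]
        raise ValueError(f"{path}: duplicated marker id {dup!r}")
    if (df["cm"] < 0).any():
        raise ValueError(f"{path}: negative cM position")
    for chrom, sub in df.groupby("chrom", sort=False):
        if np.any(np.diff(sub["cm"].to_numpy()) < 0):
            raise ValueError(f"{path}: cM positions on {chrom} are not non-decreasing")
    return df[MAP_COLS]


def write_map(gmap: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    gmap[MAP_COLS].to_csv(path, sep=sep, index=False)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Gene x sample read-count table (first column = gene id)."""
    df = _read_delim(path, index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative read counts")
    arr = df.to_numpy(dtype=float)
    if not np.allclose(arr, np.round(arr)):
        raise ValueError(f"{path}: read counts must be integers")
    df.index.name = "gene"
    return df.astype(int)


def read_bulk_table(path: str | Path) -> pd.DataFrame:
    """Per-SNP bulk allele depths from a delimited table.

    Columns: site, chrom, pos, ref_high, alt_high, ref_low, alt_low.
    """
    df = _read_delim(path)
    _require(df, BULK_COUNT_COLS, path)
    counts = df[["ref_high", "alt_high", "ref_low", "alt_low"]]
    if (counts.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative allele depth")
    return df[BULK_COUNT_COLS]


def read_bulk_vcf(
    path: str | Path, high_sample: str, low_sample: str
) -> pd.DataFrame:
    """Per-SNP bulk allele depths from the AD fields of a two-sample VCF.

    Only biallelic SNP records with AD present in both samples are kept;
    skipped records are counted in the result's ``.attrs["n_skipped"]``.
    Positions are 1-based per the VCF standard.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for s in (high_sample, low_sample):
        if s not in samples:
            raise ValueError(f"{path}: sample {s!r} not in VCF (has {samples})")
    ih, il = samples.index(high_sample), samples.index(low_sample)
    rows, skipped = [], 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            skipped += 1
            continue
        ad = rec.format("AD")
        if ad is None:
            skipped += 1
            continue
        rows.append(
            {
                "site": rec.ID or f"{rec.CHROM}:{rec.POS}",
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref_high": int(ad[ih][0]),
                "alt_high": int(ad[ih][1]),
                "ref_low": int(ad[il][0]),
                "alt_low": int(ad[il][1]),
            }
        )
    out = pd.DataFrame(rows, columns=BULK_COUNT_COLS)
    out.attrs["n_skipped"] = skipped
    out.attrs["coord_units"] = "bp"
    return out


def write_table(df: pd.DataFrame, path: str | Path, sep: str = "\t", index: bool = False) -> None:
    """Idempotent delimited-text writer used by every pipeline stage."""
    df.to_csv(path, sep=sep, index=index)
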