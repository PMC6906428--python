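"""Bulked-segregant expression and allele-frequency analysis.

Two extreme pools of RILs are selected on the maximum filling rate v_max
(BLUP values), optionally restricted to lines that reach v_max at a similar
time.  Each pool is sequenced as a single bulked mRNA sample; the expression
contrast is a TMM-normalized negative-binomial exact test at a fixed
dispersion of BCV^2 = 0.2^2 = 0.04, with Bonferroni-adjusted p < 0.05 and
|log2 fold change| > 2 defining differential expression.

Per-SNP bulk allele counts feed three statistics: the SNP index (alternate
read fraction per bulk) and its difference between bulks, the G statistic
2*sum(n*ln(n/e)) on the 2x2 bulk x allele table, and a two-sided Fisher
exact test; Benjamini-Hochberg FDR at 0.05 flags associated SNPs.  Candidate
genes are differentially expressed genes inside a QTL support interval that
carry at least one significant SNP (and, when supplied, appear in an
externally derived enriched-gene list).
"""

from __future__ import annotations

import math
import warnings
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

__all__ = [
    "select_pools",
    "tmm_factors",
    "nb_exact_test",
    "deg_filter",
    "snp_index",
    "g_statistic",
    "fisher_per_snp",
    "fdr_adjust",
    "candidate_genes",
]

BULK_COUNT_COLS = ["site", "chrom", "pos", "ref_high", "alt_high", "ref_low", "alt_low"]


# ---------------------------------------------------------------------------
# pool construction

def select_pools(
    values: pd.Series,
    n_per_pool: int = 13,
    t_mid: pd.Series | None = None,
    t_mid_tolerance: float | None = None,
) -> tuple[list, list]:
    """Top and bottom ``n_per_pool`` lines ranked by (BLUP) v_max.

    When ``t_mid`` (per-line time of maximum rate) is given, only lines
    within ``t_mid_tolerance`` DAP of the population median t_mid are
    eligible, so both pools reach v_max at a similar time.  Ties are broken
    deterministically by line id.  Returns (high lines, low lines).
    """
    v = values.dropna()
    if t_mid is not None:
        if t_mid_tolerance is None:
            raise ValueError("t_mid_tolerance is required when t_mid is supplied")
        med = float(t_mid.median())
        eligible = t_mid.index[(t_mid - med).abs() <= t_mid_tolerance]
        v = v.loc[v.index.intersection(eligible)]
    if len(v) < 2 * n_per_pool:
        raise ValueError(
            f"only {len(v)} eligible lines; need {2 * n_per_pool} for two pools"
        )
    if float(v.max()) == float(v.min()):
        raise ValueError("all values are equal; no phenotypic contrast to pool on")
    # sort on value with a deterministic line-id tiebreak
    order = sorted(v.index, key=lambda i: (v.loc[i], str(i)))
    low = list(order[:n_per_pool])
    high = list(order[-n_per_pool:])
    return high, low


# ---------------------------------------------------------------------------
# TMM normalization

def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref_column: str | None = None,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, one per sample.

    The reference sample is the one whose upper-quartile count/library-size
    ratio is closest to the mean of that ratio.  For every sample, gene-wise
    M (log2 expression ratio vs the reference) and A (average log2
    abundance) values are computed over genes expressed in both, doubly
    trimmed (``trim_m`` of the M tails, ``trim_a`` of the A tails), and the
    factor is 2**(weighted mean of the surviving M values) with inverse
    asymptotic-binomial-variance weights.  Factors are rescaled to geometric
    mean 1.
    """
    X = counts.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    if np.any(X < 0) or not np.allclose(X, np.round(X)):
        raise ValueError("counts must be non-negative integers")
    lib = X.sum(axis=0)
    f75 = np.array(
        [np.quantile(X[:, j], 0.75) / lib[j] for j in range(X.shape[1])]
    )
    if ref_column is None:
        ref = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref = counts.columns.get_loc(ref_column)

    factors = np.ones(X.shape[1])
    for j in range(X.shape[1]):
        factors[j] = _tmm_pair(
            X[:, j], X[:, ref], lib[j], lib[ref], trim_m, trim_a
        )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def _tmm_pair(
    y: np.ndarray, yr: np.ndarray, N: float, Nr: float,
    trim_m: float, trim_a: float,
) -> float:
    keep = (y > 0) & (yr > 0)
    if not keep.any():
        raise ValueError("sample shares no expressed genes with the reference")
    y, yr = y[keep], yr[keep]
    M = np.log2((y / N) / (yr / Nr))
    A = 0.5 * np.log2((y / N) * (yr / Nr))
    v = (N - y) / (N * y) + (Nr - yr) / (Nr * yr)
    if np.max(np.abs(M)) < 1e-6:
        return 1.0
    n = len(M)
    lo_m = math.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    from scipy.stats import rankdata

    rm = rankdata(M)
    ra = rankdata(A)
    sel = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not sel.any():
        return 1.0
    f = np.sum(M[sel] / v[sel]) / np.sum(1.0 / v[sel])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


# ---------------------------------------------------------------------------
# negative-binomial exact test (one sample per bulk)

def _nb_logpmf(x: np.ndarray, mean: float, dispersion: float) -> np.ndarray:
    """Negative-binomial log pmf with mean/dispersion parameterisation."""
    size = 1.0 / dispersion
    p = size / (size + mean)
    return (
        gammaln(x + size) - gammaln(size) - gammaln(x + 1.0)
        + size * math.log(p) + x * np.log1p(-p)
    )


def nb_exact_test(
    counts_high,
    counts_low,
    lib_high: float,
    lib_low: float,
    dispersion: float = 0.04,
    prior_count: float = 0.125,
) -> pd.DataFrame:
    """Gene-wise exact test between two single-bulk negative-binomial counts.

    Both samples are rescaled to the common effective library size (the
    geometric mean of the two TMM-adjusted sizes) and rounded to the nearest
    integer.  Conditional on each gene's rescaled total s, the probabilities
    of every split (j, s-j) under equal means s/2 and the fixed dispersion
    are enumerated; the two-sided p-value is the total conditional
    probability of splits no more likely than the observed one (capped at 1;
    a 1e-12 relative tolerance guards float ties).  log2 fold change
    (high vs low) uses a ``prior_count`` per group to avoid infinities.

    Genes with zero total count get p=1, log2FC=0 and ``tested=False``.
    """
    yh = np.asarray(counts_high, dtype=float)
    yl = np.asarray(counts_low, dtype=float)
    if yh.shape != yl.shape:
        raise ValueError("count vectors must have equal length")
    common = math.sqrt(lib_high * lib_low)
    sh = np.rint(yh * common / lib_high)
    sl = np.rint(yl * common / lib_low)
    total = sh + sl

    p = np.ones(len(yh))
    tested = total > 0
    for i in np.flatnonzero(tested):
        s = int(total[i])
        j = np.arange(s + 1)
        logp = _nb_logpmf(j, s / 2.0, dispersion) + _nb_logpmf(
            (s - j).astype(float), s / 2.0, dispersion
        )
        probs = np.exp(logp - logp.max())
        probs /= probs.sum()
        obs = probs[int(sh[i])]
        p[i] = min(float(probs[probs <= obs * (1.0 + 1e-12)].sum()), 1.0)

    lfc = np.log2((sh + prior_count) / (sl + prior_count))
    lfc[~tested] = 0.0
    logcpm = np.log2(1e6 * (total / 2.0 + 0.25) / common)
    return pd.DataFrame(
        {"p": p, "log2fc": lfc, "logcpm": logcpm, "tested": tested}
    )


def deg_filter(
    records: pd.DataFrame,
    alpha: float = 0.05,
    min_abs_log2fc: float = 2.0,
    method: str = "bonferroni",
) -> pd.DataFrame:
    """Multiple-testing adjustment and the DEG rule.

    Adjusts the raw p of tested genes (Bonferroni by default, Hochberg
    step-up via ``method="hochberg"``) and flags genes with adjusted p <
    ``alpha`` and |log2FC| > ``min_abs_log2fc``.  Adds columns ``p_adj``,
    ``deg`` and ``direction`` ("up" = higher in the high pool).
    """
    out = records.copy()
    tested = out["tested"].to_numpy() if "tested" in out else np.ones(len(out), bool)
    m = int(tested.sum())
    padj = np.ones(len(out))
    if m:
        if method == "bonferroni":
            padj[tested] = np.minimum(out.loc[tested, "p"].to_numpy() * m, 1.0)
        elif method == "hochberg":
            padj[tested] = multipletests(
                out.loc[tested, "p"].to_numpy(), method="simes-hochberg"
            )[1]
        else:
            raise ValueError(f"unknown adjustment method {method!r}")
    out["p_adj"] = padj
    out["deg"] = (out["p_adj"] < alpha) & (out["log2fc"].abs() > min_abs_log2fc)
    out["direction"] = np.where(
        ~out["deg"], "", np.where(out["log2fc"] > 0, "up", "down")
    )
    return out


# ---------------------------------------------------------------------------
# per-SNP bulk statistics

def snp_index(sites: pd.DataFrame) -> pd.DataFrame:
    """SNP index per bulk and the delta SNP index.

    index = alt/(ref+alt) within each bulk; delta = index_high - index_low.
    Sites with a zero-depth bulk are flagged untestable (NaN indices).
    """
    out = sites.copy()
    th = out["ref_high"] + out["alt_high"]
    tl = out["ref_low"] + out["alt_low"]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["index_high"] = np.where(th > 0, out["alt_high"] / th, np.nan)
        out["index_low"] = np.where(tl > 0, out["alt_low"] / tl, np.nan)
    out["delta_index"] = out["index_high"] - out["index_low"]
    out["testable"] = (th > 0) & (tl > 0)
    return out


def g_statistic(sites: pd.DataFrame) -> np.ndarray:
    """Likelihood-ratio G on each site's 2x2 bulk x allele table.

    G = 2 * sum(n * ln(n / e)) over the four cells, with expected counts
    e = row_total * col_total / N and the 0*ln(0) convention.  Tables with a
    zero row or column margin give G = 0.
    """
    obs = sites[["ref_high", "alt_high", "ref_low", "alt_low"]].to_numpy(dtype=float)
    rh = obs[:, 0] + obs[:, 1]
    rl = obs[:, 2] + obs[:, 3]
    cref = obs[:, 0] + obs[:, 2]
    calt = obs[:, 1] + obs[:, 3]
    N = rh + rl
    with np.errstate(invalid="ignore", divide="ignore"):
        exp = np.column_stack(
            [rh * cref / N, rh * calt / N, rl * cref / N, rl * calt / N]
        )
        terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
    G = 2.0 * np.nansum(terms, axis=1)
    degenerate = (rh == 0) | (rl == 0) | (cref == 0) | (calt == 0) | (N == 0)
    G[degenerate] = 0.0
    return G


def _fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact hypergeometric enumeration.

    Sums the probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's, using exact integer
    arithmetic (no floating-point tie ambiguity).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo = max(0, c1 - r2)
    hi = min(c1, r1)
    weights = [math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)]
    obs_w = math.comb(r1, a) * math.comb(r2, c)
    num = sum(w for w in weights if w <= obs_w)
    return float(Fraction(num, math.comb(n, c1)))


def fisher_per_snp(sites: pd.DataFrame) -> np.ndarray:
    """Two-sided Fisher exact p for each site's 2x2 bulk x allele table."""
    obs = sites[["ref_high", "alt_high", "ref_low", "alt_low"]].to_numpy()
    return np.array(
        [_fisher_two_sided(int(a), int(b), int(c), int(d)) for a, b, c, d in obs]
    )


def fdr_adjust(pvalues, method: str = "fdr_bh") -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, >= p)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p
    return multipletests(p, method=method)[1]


# ---------------------------------------------------------------------------
# candidate-gene intersection

def candidate_genes(
    degs: pd.DataFrame,
    qtl_intervals: pd.DataFrame,
    snp_sites: pd.DataFrame,
    gene_coords: pd.DataFrame,
    enriched: set | list | None = None,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Intersect DEGs, QTL support intervals and FDR-significant SNPs.

    A candidate is a DEG whose gene interval lies inside a QTL support
    interval and carries at least one SNP with q < ``q_threshold``; when an
    externally derived enriched-gene list is supplied, membership in it is
    also required.  Coordinates of the three inputs must declare the same
    unit via a ``coord_units`` entry in each frame's ``.attrs``; a mismatch
    is a hard error (no silent cM/bp guessing).  Provenance (matched QTL
    index and SNP positions) is recorded per candidate.

    ``degs`` needs gene + deg columns; ``qtl_intervals`` chrom/ci_lo/ci_hi;
    ``snp_sites`` chrom/pos/q; ``gene_coords`` gene/chrom/start/end.
    """
    units = {
        name: df.attrs.get("coord_units")
        for name, df in (
            ("qtl_intervals", qtl_intervals),
            ("snp_sites", snp_sites),
            ("gene_coords", gene_coords),
        )
    }
    declared = set(units.values())
    if len(declared) > 1:
        raise ValueError(f"coordinate-system mismatch across inputs: {units}")

    deg_set = set(degs.loc[degs["deg"], "gene"]) if "gene" in degs else set()
    sig = snp_sites[snp_sites["q"] < q_threshold]
    rows = []
    for g in gene_coords.itertuples():
        if g.gene not in deg_set:
            continue
        if enriched is not None and g.gene not in set(enriched):
            continue
        hits_qtl = qtl_intervals[
            (qtl_intervals["chrom"] == g.chrom)
            & (qtl_intervals["ci_lo_cm"] <= g.end)
            & (qtl_intervals["ci_hi_cm"] >= g.start)
        ]
        if hits_qtl.empty:
            continue
        in_gene = sig[
            (sig["chrom"] == g.chrom) & (sig["pos"] >= g.start) & (sig["pos"] <= g.end)
        ]
        if in_gene.empty:
            continue
        rows.append(
            {
                "gene": g.gene,
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "qtl_indices": list(hits_qtl.index),
                "snp_positions": list(in_gene["pos"]),
                "n_significant_snps": len(in_gene),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "chrom", "start", "end",
            "qtl_indices", "snp_positions", "n_significant_snps",
        ],
    )
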