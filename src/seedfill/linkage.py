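"""Marker QC, bin-map construction, genetic distances and composite interval mapping.

Genotypes of a recombinant inbred line (RIL) population are held as a pandas
DataFrame of lines x markers coded -1 (parent-1 homozygote, "A"), +1
(parent-2 homozygote, "B") or NaN (missing); RILs carry no heterozygotes.
Marker metadata (id, chromosome, physical order) travels in a separate frame.

The map pipeline is: chi-square segregation-distortion filtering against the
expected 1:1 ratio, sliding-window binning of redundant SNPs into bin
markers, recombination-fraction estimation between adjacent bins with the
RIL-by-selfing correction R = 2r/(1+2r), and cumulative Kosambi distances.

QTL scans use Haley-Knott style composite interval mapping (CIM): background
cofactor markers are chosen by forward stepwise regression, every 1-cM step
position receives an expected genotype score from its flanking bins via
Kosambi-based RIL conditional probabilities, and the position is tested by
comparing residual sums of squares with and without the position term while
cofactors within half a window of the tested position are excluded,

    LOD = (n/2) * log10(RSS0 / RSS1).

The genome-wide threshold is a Bonferroni correction on the effective number
of independent markers Meff (Li & Ji eigenvalue decomposition of the marker
correlation matrix): threshold = -log10(alpha / Meff) on the LOD scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "segregation_filter",
    "bin_map",
    "kosambi_cm",
    "kosambi_r",
    "ril_observed_from_r",
    "ril_r_from_observed",
    "estimate_recomb",
    "meff_threshold",
    "ScanGrid",
    "prepare_scan",
    "cim_scan",
    "call_qtl",
    "merge_loci",
]

MAP_COLS = ["marker", "chrom", "cm"]


# ---------------------------------------------------------------------------
# map functions

def kosambi_cm(r) -> float | np.ndarray:
    """Kosambi map distance (cM) for recombination fraction r in [0, 0.5)."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_r(d) -> float | np.ndarray:
    """Inverse Kosambi: recombination fraction for a distance d (cM) >= 0."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    x = np.exp(d / 25.0)
    r = (x - 1.0) / (2.0 * (x + 1.0))
    return float(r) if r.ndim == 0 else r


def ril_observed_from_r(r):
    """Expected discordance R between loci in a selfed RIL: R = 2r/(1+2r)."""
    r = np.asarray(r, dtype=float)
    R = 2.0 * r / (1.0 + 2.0 * r)
    return float(R) if R.ndim == 0 else R


def ril_r_from_observed(R):
    """Meiotic r from an observed RIL discordance R: r = R/(2(1-R))."""
    R = np.asarray(R, dtype=float)
    r = R / (2.0 * (1.0 - R))
    return float(r) if r.ndim == 0 else r


# ---------------------------------------------------------------------------
# marker QC

def segregation_filter(
    geno: pd.DataFrame,
    alpha: float = 0.001,
    min_informative: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove markers with distorted segregation (chi-square vs 1:1, 1 df).

    Markers with fewer than ``min_informative`` non-missing calls are not
    tested (retained, flagged).  Returns (filtered genotype frame, report)
    where the report lists per marker the counts, chi-square, p and status
    in {"retained", "removed", "untested"}.
    """
    X = geno.to_numpy(dtype=float)
    n_a = np.sum(X == -1, axis=0)
    n_b = np.sum(X == 1, axis=0)
    n = n_a + n_b
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = (n_a - n / 2.0) ** 2 / (n / 2.0) + (n_b - n / 2.0) ** 2 / (n / 2.0)
    p = stats.chi2.sf(chi2, df=1)
    testable = n >= min_informative
    removed = testable & (p < alpha)
    status = np.where(~testable, "untested", np.where(removed, "removed", "retained"))
    report = pd.DataFrame(
        {
            "marker": geno.columns,
            "n_A": n_a,
            "n_B": n_b,
            "chi2": np.where(testable, chi2, np.nan),
            "p": np.where(testable, p, np.nan),
            "status": status,
        }
    )
    return geno.loc[:, ~removed], report


# ---------------------------------------------------------------------------
# bin map

def bin_map(
    geno: pd.DataFrame,
    meta: pd.DataFrame,
    window: int = 15,
    min_call: int = 11,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse redundant SNPs into bin markers with a sliding window.

    Per line and chromosome a ``window``-SNP window slides one SNP at a time;
    the window is called A (resp. B) when at least ``min_call`` informative
    SNPs agree, otherwise it is ambiguous and later resolved to the nearest
    unambiguous call (breakpoints thereby land midway between the flanking
    discordant windows).  Window columns identical across all lines collapse
    into one bin.  Chromosomes shorter than the window fall back to a single
    majority-call bin, with a warning.

    ``meta`` needs columns marker/chrom and markers ordered by physical
    position within chromosome.  Returns (bin genotype frame, bin metadata
    with chrom and the first/last SNP index spanned).
    """
    meta = meta.set_index("marker").loc[list(geno.columns)].reset_index()
    bins: list[np.ndarray] = []
    bin_meta: list[dict] = []
    for chrom, idx in meta.groupby("chrom", sort=False).groups.items():
        cols = meta.loc[idx, "marker"].tolist()
        X = geno[cols].to_numpy(dtype=float)  # lines x m
        n, m = X.shape
        if m < window:
            warnings.warn(
                f"chromosome {chrom} has {m} SNPs < window {window}; "
                "falling back to a single majority-call bin"
            )
            calls = _majority_call(X)
            bins.append(calls)
            bin_meta.append({"chrom": chrom, "snp_start": 0, "snp_end": m - 1})
            continue
        wins = _window_calls(X, window, min_call)  # lines x (m - window + 1)
        wins = _fill_ambiguous(wins)
        # collapse identical adjacent window columns into bins
        change = np.any(wins[:, 1:] != wins[:, :-1], axis=0)
        starts = np.concatenate([[0], np.flatnonzero(change) + 1])
        ends = np.concatenate([np.flatnonzero(change), [wins.shape[1] - 1]])
        for s, e in zip(starts, ends):
            bins.append(wins[:, s])
            bin_meta.append(
                {"chrom": chrom, "snp_start": int(s), "snp_end": int(e + window - 1)}
            )
    bm = pd.DataFrame(bin_meta)
    bm["marker"] = [
        f"bin_{row.chrom}_{i}" for i, row in enumerate(bm.itertuples())
    ]
    binned = pd.DataFrame(
        np.column_stack(bins), index=geno.index, columns=bm["marker"]
    )
    return binned, bm[["marker", "chrom", "snp_start", "snp_end"]]


def _window_calls(X: np.ndarray, window: int, min_call: int) -> np.ndarray:
    isA = np.where(np.isnan(X), 0.0, (X == -1).astype(float))
    isB = np.where(np.isnan(X), 0.0, (X == 1).astype(float))
    kern = np.ones(window)
    nA = np.apply_along_axis(lambda v: np.convolve(v, kern, "valid"), 1, isA)
    nB = np.apply_along_axis(lambda v: np.convolve(v, kern, "valid"), 1, isB)
    out = np.zeros_like(nA)
    out[nA >= min_call] = -1.0
    out[nB >= min_call] = 1.0
    return out


def _fill_ambiguous(wins: np.ndarray) -> np.ndarray:
    """Resolve 0 (ambiguous) window calls to the nearest unambiguous call."""
    out = wins.copy()
    m = out.shape[1]
    col = np.arange(m)
    for i in range(out.shape[0]):
        row = out[i]
        known = row != 0
        if not known.any():
            continue  # a fully ambiguous line stays ambiguous (NaN downstream)
        pos = col[known]
        # nearest known index for every column (ties go left, i.e. midpoint split)
        j = np.searchsorted(pos, col)
        j_right = np.clip(j, 0, len(pos) - 1)
        j_left = np.clip(j - 1, 0, len(pos) - 1)
        d_right = np.abs(pos[j_right] - col)
        d_left = np.abs(col - pos[j_left])
        nearest = np.where(d_left <= d_right, pos[j_left], pos[j_right])
        out[i] = row[nearest]
    out[out == 0] = np.nan
    return out


def _majority_call(X: np.ndarray) -> np.ndarray:
    nA = np.nansum(X == -1, axis=1)
    nB = np.nansum(X == 1, axis=1)
    out = np.where(nB > nA, 1.0, np.where(nA > nB, -1.0, np.nan))
    return out.astype(float)


# ---------------------------------------------------------------------------
# genetic map estimation

def estimate_recomb(
    binned: pd.DataFrame, bin_meta: pd.DataFrame, max_r: float = 0.49
) -> pd.DataFrame:
    """Adjacent-bin recombination fractions and cumulative Kosambi map.

    The observed discordant-line fraction R between adjacent bins is
    corrected for recombinant accumulation over RIL selfing generations,
    r = R/(2(1-R)), then converted to cM with the Kosambi function and
    accumulated within each chromosome.  R at or beyond the unlinked limit
    is capped (r = ``max_r``) with a warning.

    Returns a genetic map frame with columns marker, chrom, cm.
    """
    X = binned.to_numpy(dtype=float)
    rows = []
    for chrom, idx in bin_meta.groupby("chrom", sort=False).groups.items():
        markers = bin_meta.loc[idx, "marker"].tolist()
        pos = 0.0
        rows.append({"marker": markers[0], "chrom": chrom, "cm": 0.0})
        for m1, m2 in zip(markers[:-1], markers[1:]):
            x1 = binned[m1].to_numpy(dtype=float)
            x2 = binned[m2].to_numpy(dtype=float)
            ok = ~np.isnan(x1) & ~np.isnan(x2)
            if ok.sum() == 0:
                R = 0.0
            else:
                R = float(np.mean(x1[ok] != x2[ok]))
            r = ril_r_from_observed(min(R, 0.999))
            if r >= max_r:
                warnings.warn(
                    f"bins {m1}/{m2} look unlinked (R={R:.3f}); capping r at {max_r}"
                )
                r = max_r
            pos += kosambi_cm(r)
            rows.append({"marker": m2, "chrom": chrom, "cm": pos})
    return pd.DataFrame(rows, columns=MAP_COLS)


# ---------------------------------------------------------------------------
# Meff threshold

def meff_threshold(
    geno_or_corr: pd.DataFrame | np.ndarray,
    alpha: float = 0.05,
    per_chromosome: pd.Series | None = None,
) -> tuple[float, float]:
    """Li-Ji effective number of markers and the Bonferroni LOD threshold.

    Eigen-decomposes the marker-marker correlation matrix and sums
    f(lambda) = I(lambda >= 1) + (lambda - floor(lambda)) over eigenvalues;
    the genome-wide threshold is -log10(alpha / Meff).  Pass either a
    genotype frame (lines x markers; constant/all-missing markers dropped,
    missing calls mean-imputed) or a precomputed correlation matrix.  With
    ``per_chromosome`` (a marker -> chromosome mapping), Meff is computed per
    chromosome and summed.
    """
    if isinstance(geno_or_corr, pd.DataFrame) or (
        isinstance(geno_or_corr, np.ndarray) and geno_or_corr.shape[0] != geno_or_corr.shape[1]
    ):
        geno = pd.DataFrame(geno_or_corr)
        if per_chromosome is not None:
            meff = 0.0
            for chrom in pd.unique(per_chromosome):
                cols = per_chromosome.index[per_chromosome == chrom]
                meff += _meff_from_corr(_marker_corr(geno[cols]))
            thresh = -math.log10(alpha / meff)
            return meff, thresh
        corr = _marker_corr(geno)
    else:
        corr = np.asarray(geno_or_corr, dtype=float)
    meff = _meff_from_corr(corr)
    return meff, -math.log10(alpha / meff)


def _marker_corr(geno: pd.DataFrame) -> np.ndarray:
    X = geno.to_numpy(dtype=float)
    mu = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), mu, X)
    keep = X.std(axis=0) > 1e-12
    if keep.sum() < 2:
        raise ValueError("need >= 2 markers with variance for Meff")
    return np.corrcoef(X[:, keep], rowvar=False)


def _meff_from_corr(corr: np.ndarray) -> float:
    lam = np.linalg.eigvalsh(corr)
    lam = np.clip(lam, 0.0, None)
    return float(np.sum((lam >= 1.0).astype(float) + (lam - np.floor(lam))))


# ---------------------------------------------------------------------------
# composite interval mapping

@dataclass
class ScanGrid:
    """Precomputed evaluation grid for CIM: positions and expected scores."""

    chrom: np.ndarray      # grid chromosome labels (object)
    cm: np.ndarray         # grid positions (cM)
    scores: np.ndarray     # lines x positions expected genotype scores in [-1, 1]
    marker_chrom: np.ndarray  # per marker
    marker_cm: np.ndarray
    X: np.ndarray          # lines x markers, mean-imputed


def prepare_scan(geno: pd.DataFrame, gmap: pd.DataFrame, step: float = 1.0) -> ScanGrid:
    """Build the step-position grid and expected genotype scores once.

    At each grid position the expected score E[x] in [-1, 1] is computed per
    line from the flanking bin genotypes via the two-state RIL Markov chain
    whose flip probability between loci d cM apart is R = 2r/(1+2r) with r
    the inverse-Kosambi fraction.  Missing flanks fall back to single-flank
    conditioning, or to 0 (the population mean) when both are missing.
    """
    gmap = gmap.set_index("marker").loc[list(geno.columns)].reset_index()
    X = geno.to_numpy(dtype=float)
    n = X.shape[0]
    mu = np.nanmean(X, axis=0)
    X_imp = np.where(np.isnan(X), mu, X)

    grid_chrom, grid_cm, score_cols = [], [], []
    for chrom, idx in gmap.groupby("chrom", sort=False).groups.items():
        pos = gmap.loc[idx, "cm"].to_numpy(dtype=float)
        cols = [geno.columns.get_loc(m) for m in gmap.loc[idx, "marker"]]
        Xc = X[:, cols]
        if np.all(np.isnan(Xc)) or np.nanstd(Xc) < 1e-12:
            warnings.warn(f"chromosome {chrom} has no polymorphic markers; skipped")
            continue
        # step grid plus the observed marker positions themselves
        grid = np.union1d(np.arange(pos[0], pos[-1] + step / 2.0, step), pos)
        for p in grid:
            score_cols.append(_expected_score(Xc, pos, p))
            grid_chrom.append(chrom)
            grid_cm.append(p)
    return ScanGrid(
        chrom=np.asarray(grid_chrom, dtype=object),
        cm=np.asarray(grid_cm, dtype=float),
        scores=np.column_stack(score_cols) if score_cols else np.empty((n, 0)),
        marker_chrom=gmap["chrom"].to_numpy(dtype=object),
        marker_cm=gmap["cm"].to_numpy(dtype=float),
        X=X_imp,
    )


def _expected_score(Xc: np.ndarray, pos: np.ndarray, p: float) -> np.ndarray:
    """E[x_p | flanking genotypes] per line for one grid position."""
    iR = int(np.searchsorted(pos, p))
    iL = iR - 1
    if iR < len(pos) and abs(pos[iR] - p) < 1e-9:
        iL = iR
    iL = max(iL, 0)
    iR = min(iR, len(pos) - 1)
    gL, gR = Xc[:, iL], Xc[:, iR]
    RL = ril_observed_from_r(kosambi_r(max(p - pos[iL], 0.0)))
    RR = ril_observed_from_r(kosambi_r(max(pos[iR] - p, 0.0)))
    # P(x=+1 | flank) for each flank; 0.5 when the flank is missing
    pL = np.where(np.isnan(gL), 0.5, (1.0 + np.nan_to_num(gL) * (1.0 - 2.0 * RL)) / 2.0)
    pR = np.where(np.isnan(gR), 0.5, (1.0 + np.nan_to_num(gR) * (1.0 - 2.0 * RR)) / 2.0)
    num = pL * pR
    den = num + (1.0 - pL) * (1.0 - pR)
    prob = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.5)
    return 2.0 * prob - 1.0


def _forward_select(
    X: np.ndarray,
    y: np.ndarray,
    entry_p: float,
    max_terms: int,
    marker_chrom: np.ndarray | None = None,
    marker_cm: np.ndarray | None = None,
    min_spacing: float = 0.0,
) -> list[int]:
    """Forward stepwise marker selection (partial-F entry test).

    With ``min_spacing`` > 0, once a marker enters, markers closer than that
    many cM on the same chromosome are barred from entering: tightly linked
    cofactor pairs jointly overfit noise (the ghost-QTL mechanism) and would
    later leak into the scan when one of the pair is window-excluded.
    """
    n = len(y)
    ry = y - y.mean()
    RX = X - X.mean(axis=0)
    rss = float(ry @ ry)
    selected: list[int] = []
    allowed = np.ones(X.shape[1], dtype=bool)
    for _ in range(max_terms):
        sxx = np.einsum("ij,ij->j", RX, RX)
        sxy = RX.T @ ry
        valid = allowed & (sxx > 1e-10)
        if not valid.any() or rss <= 1e-30:
            break
        gain = np.where(valid, sxy**2 / np.where(sxx > 0, sxx, 1.0), -np.inf)
        j = int(np.argmax(gain))
        rss_new = rss - gain[j]
        df_resid = n - 2 - len(selected)
        if df_resid <= 0 or rss_new <= 0:
            break
        F = gain[j] / (rss_new / df_resid)
        if stats.f.sf(F, 1, df_resid) >= entry_p:
            break
        selected.append(j)
        if min_spacing > 0 and marker_chrom is not None:
            allowed &= ~(
                (marker_chrom == marker_chrom[j])
                & (np.abs(marker_cm - marker_cm[j]) < min_spacing)
            )
        else:
            allowed[j] = False
        xj = RX[:, j].copy()
        nrm = float(xj @ xj)
        ry = ry - xj * float(xj @ ry) / nrm
        RX = RX - np.outer(xj, (xj @ RX) / nrm)
        rss = float(ry @ ry)
    return selected


def cim_scan(
    geno: pd.DataFrame,
    gmap: pd.DataFrame,
    trait: pd.Series | np.ndarray,
    window: float = 10.0,
    step: float = 1.0,
    n_cofactors: int = 5,
    entry_p: float = 0.01,
    grid: ScanGrid | None = None,
) -> pd.DataFrame:
    """Composite interval mapping scan of one trait.

    Cofactors are chosen by forward stepwise regression on the bin markers
    (entry p < ``entry_p``, at most ``n_cofactors``).  Each step position is
    tested by Haley-Knott regression of the trait on its expected genotype
    score, on top of the cofactors, excluding any cofactor within
    ``window``/2 cM of the tested position on the same chromosome:

        LOD = (n/2) * log10(RSS0 / RSS1)

    where RSS0 is the cofactors-only residual sum of squares and RSS1 adds
    the position term.  The additive effect is the position coefficient
    (half the parent-2 minus parent-1 genotypic difference under -1/+1
    coding) and PVE = 100*(1 - RSS1/RSS0).

    Pass a precomputed ``grid`` from :func:`prepare_scan` when scanning many
    traits on the same genotypes.  Returns a frame with columns chrom, cm,
    lod, effect, pve and the selected cofactors in ``.attrs["cofactors"]``.
    """
    if grid is None:
        grid = prepare_scan(geno, gmap, step=step)
    if isinstance(trait, pd.Series):
        trait = trait.loc[geno.index]
    y = np.asarray(trait, dtype=float)
    n = len(y)
    if n != grid.X.shape[0]:
        raise ValueError("trait length does not match the genotype line count")

    cof = _forward_select(
        grid.X, y, entry_p, n_cofactors,
        marker_chrom=grid.marker_chrom, marker_cm=grid.marker_cm,
        min_spacing=window,
    )
    cof_chrom = grid.marker_chrom[cof] if cof else np.empty(0, dtype=object)
    cof_cm = grid.marker_cm[cof] if cof else np.empty(0)

    P = grid.scores.shape[1]
    lod = np.zeros(P)
    effect = np.zeros(P)
    pve = np.zeros(P)
    # group positions by which cofactors stay in the model
    masks: dict[tuple, list[int]] = {}
    for j in range(P):
        if cof:
            near = (cof_chrom == grid.chrom[j]) & (
                np.abs(cof_cm - grid.cm[j]) <= window / 2.0
            )
            key = tuple(np.flatnonzero(~near))
        else:
            key = ()
        masks.setdefault(key, []).append(j)

    for key, cols in masks.items():
        C = np.column_stack(
            [np.ones(n)] + [grid.X[:, cof[i]] for i in key]
        )
        Q, _ = np.linalg.qr(C)
        ry = y - Q @ (Q.T @ y)
        rss0 = float(ry @ ry)
        G = grid.scores[:, cols]
        RG = G - Q @ (Q.T @ G)
        sxx = np.einsum("ij,ij->j", RG, RG)
        sxy = RG.T @ ry
        ok = sxx > 1e-10
        beta = np.where(ok, sxy / np.where(ok, sxx, 1.0), 0.0)
        rss1 = np.where(ok, rss0 - sxy * beta, rss0)
        rss1 = np.maximum(rss1, 1e-300)
        lod[cols] = np.where(rss0 > 0, (n / 2.0) * np.log10(rss0 / rss1), 0.0)
        effect[cols] = beta
        pve[cols] = np.where(rss0 > 0, 100.0 * (1.0 - rss1 / rss0), 0.0)

    out = pd.DataFrame(
        {"chrom": grid.chrom, "cm": grid.cm, "lod": lod, "effect": effect, "pve": pve}
    )
    out.attrs["cofactors"] = [
        {"marker_index": int(j), "chrom": grid.marker_chrom[j], "cm": float(grid.marker_cm[j])}
        for j in cof
    ]
    return out


# ---------------------------------------------------------------------------
# QTL calling

def call_qtl(
    scan: pd.DataFrame,
    threshold: float,
    merge_cm: float = 10.0,
    lod_drop: float = 1.5,
) -> pd.DataFrame:
    """Call QTL from a scan: supra-threshold segments, peaks and support intervals.

    Contiguous runs of positions with LOD >= ``threshold`` become one QTL
    each; the peak is the maximum-LOD position and the support interval
    extends from the peak until the LOD falls ``lod_drop`` below it (or the
    chromosome ends).  Peaks within ``merge_cm`` on the same chromosome are
    collapsed into one nonredundant locus (highest peak wins).
    """
    peaks = []
    for chrom, sub in scan.groupby("chrom", sort=False):
        sub = sub.sort_values("cm").reset_index(drop=True)
        above = sub["lod"].to_numpy() >= threshold
        if not above.any():
            continue
        edges = np.diff(above.astype(int))
        starts = list(np.flatnonzero(edges == 1) + 1)
        ends = list(np.flatnonzero(edges == -1))
        if above[0]:
            starts = [0] + starts
        if above[-1]:
            ends = ends + [len(above) - 1]
        lods = sub["lod"].to_numpy()
        cms = sub["cm"].to_numpy()
        for s, e in zip(starts, ends):
            ipk = s + int(np.argmax(lods[s : e + 1]))
            peak_lod = lods[ipk]
            # positions within lod_drop of the peak, expanded one position
            # outward (the usual support-interval convention)
            lo = ipk
            while lo > 0 and lods[lo - 1] > peak_lod - lod_drop:
                lo -= 1
            hi = ipk
            while hi < len(lods) - 1 and lods[hi + 1] > peak_lod - lod_drop:
                hi += 1
            lo = max(lo - 1, 0)
            hi = min(hi + 1, len(lods) - 1)
            peaks.append(
                {
                    "chrom": chrom,
                    "peak_cm": float(cms[ipk]),
                    "lod": float(peak_lod),
                    "effect": float(sub["effect"].iloc[ipk]),
                    "pve": float(sub["pve"].iloc[ipk]),
                    "ci_lo_cm": float(cms[lo]),
                    "ci_hi_cm": float(cms[hi]),
                }
            )
    qtl = pd.DataFrame(
        peaks,
        columns=["chrom", "peak_cm", "lod", "effect", "pve", "ci_lo_cm", "ci_hi_cm"],
    )
    return merge_loci(qtl, merge_cm)


def merge_loci(qtl: pd.DataFrame, merge_cm: float = 10.0) -> pd.DataFrame:
    """Collapse peaks within ``merge_cm`` on a chromosome into nonredundant loci.

    Works across traits/environments when passed a concatenation of per-scan
    QTL tables; the representative row of each cluster is its highest-LOD
    peak, and ``n_merged`` counts the collapsed peaks.
    """
    if qtl.empty:
        out = qtl.copy()
        out["n_merged"] = pd.Series(dtype=int)
        return out
    rows = []
    for chrom, sub in qtl.groupby("chrom", sort=False):
        sub = sub.sort_values("peak_cm").reset_index(drop=True)
        cluster = [0]
        for i in range(1, len(sub)):
            if sub["peak_cm"].iloc[i] - sub["peak_cm"].iloc[cluster[-1]] <= merge_cm:
                cluster.append(i)
            else:
                rows.append(_cluster_rep(sub, cluster))
                cluster = [i]
        rows.append(_cluster_rep(sub, cluster))
    return pd.DataFrame(rows).reset_index(drop=True)


def _cluster_rep(sub: pd.DataFrame, cluster: list[int]) -> dict:
    block = sub.iloc[cluster]
    rep = block.loc[block["lod"].idxmax()].to_dict()
    rep["n_merged"] = len(cluster)
    return rep
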