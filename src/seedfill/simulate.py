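"""Synthetic RIL study generator: every input the analysis pipeline consumes.

Emulates a biparental maize RIL population phenotyped for seed filling in
several environments:

* genotypes: per line and chromosome, a two-state Markov chain along the
  marker positions whose flip probability between adjacent markers is the
  RIL-by-selfing discordance R = 2r/(1+2r), with r the inverse-Kosambi
  fraction of the cM gap.  Lines are homozygous everywhere; optional
  per-call error and missingness.
* phenotypes: each logistic parameter (k, a, b) is the parental midpoint
  plus additive QTL effects, plus per-environment main effects and G x E
  deviates; 50-seed dry weights are the logistic curve evaluated on the
  sampling schedule (14 time points, 10-61 days after pollination) plus
  Gaussian measurement noise.
* bulk allele depths: binomial reads at each SNP with the bulk's true
  parent-2 allele frequency.
* expression: negative-binomial counts (dispersion = BCV^2 = 0.04) with a
  designated set of differentially expressed genes.

Defaults mirror the study conditions: 208 lines, 3 environments, a
desk-scale genome of 10 chromosomes (~160 cM each, 32 markers per
chromosome) standing in for the full 3227-bin, 2450-cM map.  All draws come
from one numpy Generator, so a fixed seed reproduces every table bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .growth import WeightSeries, logistic_weight
from .linkage import MAP_COLS, kosambi_r, ril_observed_from_r

__all__ = [
    "SimConfig",
    "simulate_ril_genotypes",
    "simulate_filling_phenotypes",
    "simulate_bulk_counts",
    "simulate_expression",
]

#: the field sampling schedule (days after pollination)
DAP_SCHEDULE = (10, 15, 20, 25, 30, 35, 40, 43, 46, 49, 52, 55, 58, 61)


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic RIL experiment.

    QTL are given per logistic parameter as (chromosome index from 1, cM
    position, additive effect in parameter units); a line's parameter is the
    parental midpoint plus the sum of effect * genotype(+-1) at the marker
    nearest each QTL.  Parent 1 mimics a small-seeded fast filler, parent 2
    a large-seeded slow filler (midpoint k = 12 g, b = 0.14/DAP, a = 67 so
    the inflexion sits near 30 DAP and v_max near 0.42 g/DAP).
    """

    n_lines: int = 208
    n_env: int = 3
    chrom_lengths_cm: tuple[float, ...] = (
        200.0, 140.0, 170.0, 160.0, 180.0, 150.0, 160.0, 145.0, 170.0, 155.0
    )
    markers_per_chrom: int = 32
    genotype_error_rate: float = 0.0
    genotype_missing_rate: float = 0.0
    parent1: tuple[float, float, float] = (10.5, 88.0, 0.16)  # (k, a, b)
    parent2: tuple[float, float, float] = (13.5, 46.0, 0.12)
    qtl: dict[str, list[tuple[int, float, float]]] = field(
        default_factory=lambda: {
            "k": [(1, 50.0, 0.40), (3, 80.0, 0.30), (7, 40.0, 0.30)],
            "b": [(2, 60.0, 0.008), (5, 100.0, 0.006)],
            "a": [(4, 30.0, 8.0), (9, 70.0, 6.0)],
        }
    )
    env_effect_sd: dict[str, float] = field(
        default_factory=lambda: {"k": 0.40, "a": 4.0, "b": 0.004}
    )
    gxe_sd: dict[str, float] = field(
        default_factory=lambda: {"k": 0.50, "a": 5.0, "b": 0.005}
    )
    weight_noise_sd: float = 0.35  # g, on each 50-seed dry weight
    proportional_noise: bool = False
    dap_schedule: tuple[float, ...] = DAP_SCHEDULE
    read_depth: int = 40       # per SNP site and bulk
    n_genes: int = 2000
    n_de_genes: int = 30
    de_fold_change: float = 8.0
    expression_lib_size: float = 2e6
    expression_dispersion: float = 0.04

    def marker_map(self) -> pd.DataFrame:
        """True genetic map: evenly spaced markers along each chromosome."""
        rows = []
        for c, length in enumerate(self.chrom_lengths_cm, start=1):
            pos = np.linspace(0.0, length, self.markers_per_chrom)
            for j, p in enumerate(pos):
                rows.append({"marker": f"m{c}_{j}", "chrom": f"chr{c}", "cm": float(p)})
        return pd.DataFrame(rows, columns=MAP_COLS)


def simulate_ril_genotypes(
    config: SimConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """RIL genotypes (lines x markers, +-1) and the true genetic map."""
    gmap = config.marker_map()
    n = config.n_lines
    cols = []
    for chrom, idx in gmap.groupby("chrom", sort=False).groups.items():
        pos = gmap.loc[idx, "cm"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"map positions on {chrom} are not non-decreasing")
        flip = ril_observed_from_r(kosambi_r(np.diff(pos)))
        g = np.empty((n, len(pos)))
        g[:, 0] = rng.choice([-1.0, 1.0], size=n)
        for j, R in enumerate(flip, start=1):
            switch = rng.random(n) < R
            g[:, j] = np.where(switch, -g[:, j - 1], g[:, j - 1])
        cols.append(g)
    X = np.hstack(cols)
    if config.genotype_error_rate > 0:
        err = rng.random(X.shape) < config.genotype_error_rate
        X = np.where(err, -X, X)
    if config.genotype_missing_rate > 0:
        X = np.where(rng.random(X.shape) < config.genotype_missing_rate, np.nan, X)
    lines = [f"RIL{i + 1:03d}" for i in range(n)]
    geno = pd.DataFrame(X, index=lines, columns=gmap["marker"])
    return geno, gmap


def _nearest_marker(gmap: pd.DataFrame, chrom_index: int, cm: float) -> str:
    chrom = f"chr{chrom_index}"
    sub = gmap[gmap["chrom"] == chrom]
    if sub.empty:
        raise ValueError(f"QTL placed on unknown chromosome {chrom}")
    j = (sub["cm"] - cm).abs().idxmin()
    return gmap.loc[j, "marker"]


def true_genetic_values(
    geno: pd.DataFrame, gmap: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """Per-line true (k, a, b): parental midpoint plus additive QTL effects."""
    mid = {
        p: (config.parent1[i] + config.parent2[i]) / 2.0
        for i, p in enumerate(("k", "a", "b"))
    }
    out = pd.DataFrame(index=geno.index)
    for param in ("k", "a", "b"):
        vals = np.full(len(geno), mid[param])
        for chrom_index, cm, effect in config.qtl.get(param, []):
            marker = _nearest_marker(gmap, chrom_index, cm)
            x = geno[marker].to_numpy(dtype=float)
            vals = vals + effect * np.nan_to_num(x)
        out[param] = vals
    return out


def simulate_filling_phenotypes(
    geno: pd.DataFrame,
    gmap: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
    max_resample: int = 20,
) -> tuple[list[WeightSeries], pd.DataFrame]:
    """Dry-weight trajectories for every line x environment, plus the truth.

    Returns (series list, truth table).  The truth table is long format with
    the genetic values and the per-environment realized (k, a, b) actually
    used to draw the weights, for recovery tests.  Negative realized
    parameters are resampled (up to ``max_resample`` times, then a config
    error is raised).
    """
    genetic = true_genetic_values(geno, gmap, config)
    t = np.asarray(config.dap_schedule, dtype=float)
    series: list[WeightSeries] = []
    truth_rows = []
    envs = [f"env{j + 1}" for j in range(config.n_env)]
    env_eff = {
        p: rng.normal(0.0, config.env_effect_sd.get(p, 0.0), size=config.n_env)
        for p in ("k", "a", "b")
    }
    for ei, env in enumerate(envs):
        for line in geno.index:
            realized = {}
            for p in ("k", "a", "b"):
                base = genetic.loc[line, p] + env_eff[p][ei]
                sd = config.gxe_sd.get(p, 0.0)
                val = base + rng.normal(0.0, sd)
                tries = 0
                while val <= 0:
                    tries += 1
                    if tries > max_resample:
                        raise ValueError(
                            f"parameter {p} persistently non-positive for {line}/{env}; "
                            "check QTL effects and noise scales"
                        )
                    val = base + rng.normal(0.0, sd)
                realized[p] = float(val)
            w = logistic_weight(t, realized["k"], realized["a"], realized["b"])
            if config.weight_noise_sd > 0:
                if config.proportional_noise:
                    noise = rng.normal(0.0, config.weight_noise_sd * w)
                else:
                    noise = rng.normal(0.0, config.weight_noise_sd, size=len(t))
                w = np.maximum(w + noise, 0.0)
            series.append(
                WeightSeries(line_id=line, environment=env, times=t, weights=w)
            )
            truth_rows.append(
                {
                    "line_id": line,
                    "environment": env,
                    "k_genetic": genetic.loc[line, "k"],
                    "a_genetic": genetic.loc[line, "a"],
                    "b_genetic": genetic.loc[line, "b"],
                    "k": realized["k"],
                    "a": realized["a"],
                    "b": realized["b"],
                }
            )
    return series, pd.DataFrame(truth_rows)


def simulate_bulk_counts(
    geno: pd.DataFrame,
    gmap: pd.DataFrame,
    high_lines: list,
    low_lines: list,
    depth: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Binomial bulk allele depths at every marker site.

    The alternate allele is the parent-2 allele; each bulk's true frequency
    is the fraction of its lines carrying parent-2 at the site, and read
    counts are binomial(depth, frequency) independently per bulk.
    """
    if len(high_lines) == 0 or len(low_lines) == 0:
        raise ValueError("both pools must be non-empty")
    rows = []
    for marker, chrom, cm in gmap[["marker", "chrom", "cm"]].itertuples(index=False):
        for pool, tag in ((high_lines, "high"), (low_lines, "low")):
            x = geno.loc[pool, marker].to_numpy(dtype=float)
            freq = float(np.mean(x[~np.isnan(x)] == 1)) if (~np.isnan(x)).any() else 0.5
            alt = int(rng.binomial(depth, freq))
            if tag == "high":
                alt_h, ref_h = alt, depth - alt
            else:
                alt_l, ref_l = alt, depth - alt
        rows.append(
            {
                "site": marker,
                "chrom": chrom,
                "pos": cm,
                "ref_high": ref_h,
                "alt_high": alt_h,
                "ref_low": ref_l,
                "alt_low": alt_l,
            }
        )
    return pd.DataFrame(rows)


def simulate_expression(
    config: SimConfig,
    rng: np.random.Generator,
    de_genes: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x sample counts for the two bulks, plus truth labels.

    Baseline expression levels are log-normal; the designated DE genes have
    their mean multiplied by ``de_fold_change`` in the high bulk (half up,
    half down).  Counts are negative binomial with the configured
    dispersion; library sizes jitter around ``expression_lib_size``.
    """
    G = config.n_genes
    genes = [f"gene{g + 1:05d}" for g in range(G)]
    rel = rng.lognormal(mean=0.0, sigma=1.2, size=G)
    rel /= rel.sum()
    if de_genes is None:
        de_idx = rng.choice(G, size=config.n_de_genes, replace=False)
    else:
        de_idx = np.array([genes.index(g) for g in de_genes])
    direction = np.ones(G)
    half = len(de_idx) // 2
    direction[de_idx[half:]] = -1.0

    fold = np.ones(G)
    fold[de_idx] = config.de_fold_change ** direction[de_idx]
    libs = {
        "bulk_high": config.expression_lib_size * rng.uniform(0.8, 1.2),
        "bulk_low": config.expression_lib_size * rng.uniform(0.8, 1.2),
    }
    mean_high = rel * fold
    mean_high = mean_high / mean_high.sum() * libs["bulk_high"]
    mean_low = rel / rel.sum() * libs["bulk_low"]

    size = 1.0 / config.expression_dispersion
    counts = pd.DataFrame(
        {
            "bulk_high": rng.negative_binomial(size, size / (size + mean_high)),
            "bulk_low": rng.negative_binomial(size, size / (size + mean_low)),
        },
        index=pd.Index(genes, name="gene"),
    )
    truth = pd.DataFrame(
        {
            "gene": genes,
            "is_de": np.isin(np.arange(G), de_idx),
            "true_fold_change": fold,
        }
    )
    return counts, truth
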