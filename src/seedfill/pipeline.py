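"""End-to-end pipeline: simulate or load inputs, then fit -> derive -> stats
-> bin map -> CIM scan -> QTL calls -> pools -> expression contrast -> bulk
SNP statistics -> candidate genes.

Every stage persists its table to the output directory as delimited text and
a resolved copy of the configuration is written next to the outputs, so a
run is reproducible from its own artefacts.  Unknown configuration keys are
rejected.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bsa, io, linkage, simulate, traitstats
from .growth import (
    PARAMETER_COLUMNS,
    WeightSeries,
    derive_parameters,
    fit_logistic,
)

__all__ = ["PipelineConfig", "run_pipeline", "fit_all"]

log = logging.getLogger("seedfill")


@dataclass
class PipelineConfig:
    """Resolved parameters for one pipeline run."""

    outdir: str = "seedfill_run"
    seed: int = 1
    # inputs; when None, the synthetic generator supplies them
    weights_path: str | None = None
    genotypes_path: str | None = None
    map_path: str | None = None
    counts_path: str | None = None
    bulk_path: str | None = None
    # stage toggles
    run_qtl: bool = True
    run_bsa: bool = True
    # stage parameters
    completion_fraction: float = 0.99
    min_points: int = 4
    seg_alpha: float = 0.001
    bin_window: int = 15
    bin_min_call: int = 11
    cim_window_cm: float = 10.0
    cim_step_cm: float = 1.0
    n_cofactors: int = 5
    qtl_alpha: float = 0.05
    merge_cm: float = 10.0
    pool_size: int = 13
    dispersion: float = 0.04
    trim_m: float = 0.30
    trim_a: float = 0.05
    deg_alpha: float = 0.05
    min_abs_log2fc: float = 2.0
    fdr_q: float = 0.05
    # synthetic-data overrides (passed through to SimConfig)
    sim: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        return cls(**raw)

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


def fit_all(
    series: list[WeightSeries],
    completion_fraction: float = 0.99,
) -> pd.DataFrame:
    """Fit every trajectory and derive the 12 traits; one row per line x env."""
    rows = []
    for s in series:
        fit = fit_logistic(s)
        row = {"line_id": s.line_id, "environment": s.environment}
        if fit.converged:
            row.update(derive_parameters(fit, completion_fraction).as_dict())
        else:
            row.update({c: np.nan for c in PARAMETER_COLUMNS})
        row["r_squared"] = fit.r_squared
        row["converged"] = fit.converged
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the in-memory result bundle.

    Stage order mirrors the study: curve fitting, trait derivation,
    multi-environment statistics and BLUP, marker QC and bin map, CIM scans
    of the across-environment trait means, QTL calling at the Meff
    threshold, extreme-pool construction on BLUP v_max, the bulked
    expression contrast and per-SNP bulk statistics, and the candidate-gene
    intersection.  Any stage failure aborts with the stage name; partial
    outputs are already on disk.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    config.dump(out / "resolved_config.yaml")
    results: dict = {}
    stage = "setup"
    try:
        # ---- inputs ---------------------------------------------------
        stage = "inputs"
        sim_cfg = simulate.SimConfig(**config.sim)
        if config.genotypes_path and config.map_path:
            geno = io.read_genotypes(config.genotypes_path)
            gmap = io.read_map(config.map_path)
        else:
            geno, gmap = simulate.simulate_ril_genotypes(sim_cfg, rng)
            io.write_genotypes(geno, out / "genotypes.tsv")
            io.write_map(gmap, out / "map_true.tsv")
        if config.weights_path:
            series = io.read_weight_table(config.weights_path)
        else:
            series, truth = simulate.simulate_filling_phenotypes(
                geno, gmap, sim_cfg, rng
            )
            io.write_weight_table(series, out / "weights.tsv")
            io.write_table(truth, out / "truth_parameters.tsv")

        # ---- growth-model stage --------------------------------------
        stage = "fit"
        params = fit_all(series, config.completion_fraction)
        io.write_table(params, out / "filling_parameters.tsv")
        results["parameters"] = params

        # ---- trait statistics ----------------------------------------
        stage = "trait_stats"
        fitted = params[params["converged"]]
        summary = traitstats.trait_summary(
            fitted, [c for c in PARAMETER_COLUMNS]
        )
        io.write_table(summary.reset_index(), out / "trait_summary.tsv")
        corr_r, corr_p = traitstats.correlation_matrix(fitted, PARAMETER_COLUMNS)
        io.write_table(corr_r.reset_index(), out / "trait_correlations.tsv")
        vmax_blup = traitstats.blup(fitted, "v_max")
        io.write_table(vmax_blup.reset_index(), out / "vmax_blup.tsv")
        results["summary"] = summary
        results["correlations"] = (corr_r, corr_p)
        results["vmax_blup"] = vmax_blup

        # ---- linkage map + QTL ---------------------------------------
        if config.run_qtl:
            stage = "binmap"
            filtered, seg_report = linkage.segregation_filter(geno, config.seg_alpha)
            io.write_table(seg_report, out / "segregation_report.tsv")
            meta = gmap.rename(columns={"cm": "pos"})[["marker", "chrom"]]
            meta = meta[meta["marker"].isin(filtered.columns)]
            binned, bin_meta = linkage.bin_map(
                filtered, meta, config.bin_window, config.bin_min_call
            )
            est_map = linkage.estimate_recomb(binned, bin_meta)
            io.write_map(est_map, out / "map_estimated.tsv")

            stage = "scan"
            meff, threshold = linkage.meff_threshold(binned, config.qtl_alpha)
            grid = linkage.prepare_scan(binned, est_map, step=config.cim_step_cm)
            trait_means = (
                fitted.groupby("line_id")[PARAMETER_COLUMNS].mean().loc[binned.index]
            )
            scans, qtl_tables = {}, []
            for trait in PARAMETER_COLUMNS:
                scan = linkage.cim_scan(
                    binned, est_map, trait_means[trait],
                    window=config.cim_window_cm, step=config.cim_step_cm,
                    n_cofactors=config.n_cofactors, grid=grid,
                )
                scan.insert(0, "trait", trait)
                scans[trait] = scan
                q = linkage.call_qtl(scan, threshold, config.merge_cm)
                q.insert(0, "trait", trait)
                qtl_tables.append(q)
            all_scans = pd.concat(scans.values(), ignore_index=True)
            io.write_table(all_scans, out / "cim_scans.tsv")
            per_trait_qtl = pd.concat(qtl_tables, ignore_index=True)
            nonredundant = linkage.merge_loci(
                per_trait_qtl.drop(columns="trait"), config.merge_cm
            )
            io.write_table(per_trait_qtl, out / "qtl_per_trait.tsv")
            io.write_table(nonredundant, out / "qtl_nonredundant.tsv")
            results.update(
                meff=meff, threshold=threshold, scans=scans,
                qtl=per_trait_qtl, qtl_nonredundant=nonredundant,
            )

        # ---- BSA ------------------------------------------------------
        if config.run_bsa:
            stage = "pools"
            high, low = bsa.select_pools(results["vmax_blup"], config.pool_size)
            io.write_table(
                pd.DataFrame({"line_id": high + low,
                              "pool": ["high"] * len(high) + ["low"] * len(low)}),
                out / "pools.tsv",
            )

            stage = "deg"
            if config.counts_path:
                counts = io.read_counts(config.counts_path)
                expr_truth = None
            else:
                counts, expr_truth = simulate.simulate_expression(sim_cfg, rng)
                io.write_table(counts.reset_index(), out / "expression_counts.tsv")
                io.write_table(expr_truth, out / "truth_expression.tsv")
            factors = bsa.tmm_factors(counts, config.trim_m, config.trim_a)
            lib = counts.sum(axis=0) * factors
            tests = bsa.nb_exact_test(
                counts["bulk_high"], counts["bulk_low"],
                lib["bulk_high"], lib["bulk_low"], config.dispersion,
            )
            tests.insert(0, "gene", counts.index)
            degs = bsa.deg_filter(tests, config.deg_alpha, config.min_abs_log2fc)
            io.write_table(degs, out / "deg_table.tsv")
            results["degs"] = degs

            stage = "bsa"
            if config.bulk_path:
                sites = io.read_bulk_table(config.bulk_path)
            else:
                sites = simulate.simulate_bulk_counts(
                    geno, gmap, high, low, sim_cfg.read_depth, rng
                )
                io.write_table(sites, out / "bulk_counts.tsv")
            sites = bsa.snp_index(sites)
            sites["g_stat"] = bsa.g_statistic(sites)
            sites["fisher_p"] = bsa.fisher_per_snp(sites)
            sites["q"] = bsa.fdr_adjust(sites["fisher_p"])
            io.write_table(sites, out / "bsa_sites.tsv")
            results["bsa_sites"] = sites

            stage = "candidates"
            if config.run_qtl and expr_truth is not None:
                # synthetic gene placement: genes tile the genetic map so the
                # intersection stage is exercised end to end (cM coordinates)
                coords = _synthetic_gene_coords(expr_truth["gene"], gmap, rng)
                qtl_iv = results["qtl_nonredundant"].copy()
                qtl_iv.attrs["coord_units"] = "cM"
                sites.attrs["coord_units"] = "cM"
                cands = bsa.candidate_genes(degs, qtl_iv, sites, coords, None, config.fdr_q)
                io.write_table(cands, out / "candidate_genes.tsv")
                results["candidates"] = cands
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "run_log.json").write_text(
        json.dumps({"seed": config.seed, "stages_completed": list(results)}, indent=2)
    )
    return results


def _synthetic_gene_coords(
    genes: pd.Series, gmap: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Place genes uniformly on the genetic map (cM), 0.5 cM long each."""
    chroms = gmap["chrom"].unique()
    ends = gmap.groupby("chrom")["cm"].max()
    chosen = rng.choice(len(chroms), size=len(genes))
    starts = rng.uniform(0, 1, size=len(genes)) * ends.to_numpy()[chosen]
    out = pd.DataFrame(
        {
            "gene": genes.to_numpy(),
            "chrom": chroms[chosen],
            "start": starts,
            "end": starts + 0.5,
        }
    )
    out.attrs["coord_units"] = "cM"
    return out
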