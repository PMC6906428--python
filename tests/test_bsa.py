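"""Pool selection, TMM, the NB exact test, bulk SNP statistics and candidates."""

import math
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import rankdata

from seedfill import (
    candidate_genes,
    deg_filter,
    fdr_adjust,
    fisher_per_snp,
    g_statistic,
    nb_exact_test,
    select_pools,
    snp_index,
    tmm_factors,
)


def sites_frame(rows):
    return pd.DataFrame(
        rows, columns=["site", "chrom", "pos", "ref_high", "alt_high", "ref_low", "alt_low"]
    )


class TestSelectPools:
    def test_pools_are_extreme_and_disjoint(self, rng):
        v = pd.Series(rng.normal(size=208), index=[f"L{i:03d}" for i in range(208)])
        high, low = select_pools(v, 13)
        assert len(high) == len(low) == 13
        assert not set(high) & set(low)
        assert v[low].max() < v[high].min()

    def test_tie_break_is_deterministic(self):
        v = pd.Series([1.0] * 5 + [2.0] * 5, index=[f"L{i}" for i in range(10)])
        h1, l1 = select_pools(v, 2)
        h2, l2 = select_pools(v.sample(frac=1, random_state=3), 2)
        assert (h1, l1) == (h2, l2)
        assert l1 == ["L0", "L1"]  # lexical tiebreak within the tied block

    def test_all_equal_rejected(self):
        v = pd.Series(np.ones(30), index=[f"L{i}" for i in range(30)])
        with pytest.raises(ValueError, match="equal"):
            select_pools(v, 5)

    def test_t_mid_filter_shortfall_named(self, rng):
        v = pd.Series(rng.normal(size=30), index=[f"L{i}" for i in range(30)])
        t_mid = pd.Series(np.linspace(20, 40, 30), index=v.index)
        with pytest.raises(ValueError, match="eligible"):
            select_pools(v, 13, t_mid=t_mid, t_mid_tolerance=1.0)

    def test_t_mid_filter_restricts_candidates(self, rng):
        v = pd.Series(rng.normal(size=100), index=[f"L{i:03d}" for i in range(100)])
        t_mid = pd.Series(
            np.r_[np.full(60, 30.0), np.full(40, 50.0)], index=v.index
        )
        high, low = select_pools(v, 10, t_mid=t_mid, t_mid_tolerance=5.0)
        eligible = set(t_mid.index[(t_mid - t_mid.median()).abs() <= 5.0])
        assert set(high) <= eligible and set(low) <= eligible


class TestTmm:
    def test_identical_samples(self):
        counts = pd.DataFrame({"a": [10, 50, 200, 3], "b": [10, 50, 200, 3]})
        assert np.allclose(tmm_factors(counts), 1.0)

    def test_pure_depth_difference_absorbed_by_library_size(self):
        counts = pd.DataFrame({"a": [10, 50, 200, 3, 77], "b": [20, 100, 400, 6, 154]})
        assert np.allclose(tmm_factors(counts), 1.0)

    def test_amplified_subset_shrinks_factor(self, rng):
        base = rng.poisson(rng.lognormal(4, 1, 400)) + 1
        amp = base.copy()
        amp[:20] *= 16  # 5% of genes amplified in sample b
        counts = pd.DataFrame({"a": base, "b": amp})
        f = tmm_factors(counts)
        assert f["b"] < 1.0 < f["a"]
        # brute-force recomputation of the trim/weight arithmetic (ref = a)
        y, yr = amp.astype(float), base.astype(float)
        N, Nr = y.sum(), yr.sum()
        keep = (y > 0) & (yr > 0)
        M = np.log2((y / N) / (yr / Nr))[keep]
        A = 0.5 * np.log2((y / N) * (yr / Nr))[keep]
        w = ((N - y) / (N * y) + (Nr - yr) / (Nr * yr))[keep]
        n = len(M)
        loM, hiM = math.floor(n * 0.3) + 1, n - math.floor(n * 0.3)
        loA, hiA = math.floor(n * 0.05) + 1, n - math.floor(n * 0.05)
        rm, ra = rankdata(M), rankdata(A)
        sel = (rm >= loM) & (rm <= hiM) & (ra >= loA) & (ra <= hiA)
        fb = 2 ** (np.sum(M[sel] / w[sel]) / np.sum(1.0 / w[sel]))
        expected = np.array([1.0, fb])
        expected /= np.exp(np.mean(np.log(expected)))
        assert f["b"] == pytest.approx(expected[1], rel=1e-10)

    def test_matches_edger_reference(self, rng):
        # independent oracle: Bioconductor edgeR::calcNormFactors via Rscript
        counts = pd.DataFrame(
            {
                "s1": rng.poisson(rng.lognormal(4, 1, 300)),
                "s2": rng.poisson(rng.lognormal(4, 1, 300) * 2.0),
                "s3": rng.poisson(rng.lognormal(4, 1, 300) * 0.5),
            }
        )
        csv = "gene," + ",".join(counts.columns) + "\n" + "\n".join(
            f"g{i}," + ",".join(str(v) for v in row)
            for i, row in enumerate(counts.to_numpy())
        )
        script = (
            "suppressMessages(library(edgeR));"
            "x <- read.csv('stdin', row.names=1);"
            "f <- calcNormFactors(DGEList(counts=as.matrix(x)));"
            "cat(sprintf('%.12f\\n', f$samples$norm.factors))"
        )
        res = subprocess.run(
            ["Rscript", "-e", script], input=csv, capture_output=True, text=True,
            timeout=300,
        )
        assert res.returncode == 0, res.stderr
        expected = [float(v) for v in res.stdout.split()]
        np.testing.assert_allclose(tmm_factors(counts).to_numpy(), expected, rtol=1e-8)

    def test_geometric_mean_one_and_scale_invariance(self, rng):
        counts = pd.DataFrame(rng.poisson(50, size=(200, 4)), columns=list("abcd"))
        f1 = tmm_factors(counts)
        assert np.prod(f1) == pytest.approx(1.0, abs=1e-12)
        f2 = tmm_factors(counts * 3)
        np.testing.assert_allclose(f1, f2, rtol=1e-12)


def nb_oracle_p(yh, yl, disp=0.04):
    """Direct split-enumeration oracle built from log-gamma arithmetic."""
    s = yh + yl
    if s == 0:
        return 1.0
    size = 1.0 / disp
    mu = s / 2.0
    q = size / (size + mu)

    def logpmf(x):
        return (
            math.lgamma(x + size) - math.lgamma(size) - math.lgamma(x + 1)
            + size * math.log(q) + x * math.log(1 - q)
        )

    lp = [logpmf(j) + logpmf(s - j) for j in range(s + 1)]
    mx = max(lp)
    pr = [math.exp(v - mx) for v in lp]
    obs = pr[yh]
    return min(sum(v for v in pr if v <= obs * (1 + 1e-12)) / sum(pr), 1.0)


class TestNbExactTest:
    def test_symmetric_counts_not_significant(self):
        res = nb_exact_test([500], [500], 1e6, 1e6)
        assert res.p.iloc[0] >= 0.99

    def test_extreme_separation(self):
        res = nb_exact_test([1000], [0], 1e6, 1e6)
        assert res.p.iloc[0] < 1e-6

    def test_matches_enumeration_oracle_on_toy_table(self, rng):
        yh = rng.integers(0, 400, 50)
        yl = rng.integers(0, 400, 50)
        res = nb_exact_test(yh, yl, 1e6, 1e6)
        expected = [nb_oracle_p(int(a), int(b)) for a, b in zip(yh, yl)]
        np.testing.assert_allclose(res.p, expected, atol=1e-10)

    def test_label_swap_symmetry(self, rng):
        yh = rng.integers(0, 300, 30)
        yl = rng.integers(0, 300, 30)
        r1 = nb_exact_test(yh, yl, 2e6, 2e6)
        r2 = nb_exact_test(yl, yh, 2e6, 2e6)
        np.testing.assert_allclose(r1.p, r2.p, atol=1e-12)
        np.testing.assert_allclose(r1.log2fc, -r2.log2fc, atol=1e-12)

    def test_zero_total_flagged_untested(self):
        res = nb_exact_test([0], [0], 1e6, 1e6)
        assert not res.tested.iloc[0]
        assert res.p.iloc[0] == 1.0
        assert res.log2fc.iloc[0] == 0.0


class TestDegFilter:
    def _records(self, p, lfc):
        return pd.DataFrame({"p": p, "log2fc": lfc, "tested": True})

    def test_bonferroni_arithmetic(self):
        rec = self._records([0.04] + [0.5] * 9, [3.0] * 10)
        out = deg_filter(rec)
        assert out.p_adj.iloc[0] == pytest.approx(0.4)
        assert not out.deg.iloc[0]

    def test_fold_change_rule(self):
        rec = self._records([1e-6, 1e-6], [1.5, 2.5])
        out = deg_filter(rec)
        assert not out.deg.iloc[0]  # adjusted p fine but |log2FC| <= 2
        assert out.deg.iloc[1]
        assert out.direction.iloc[1] == "up"

    def test_planted_de_recovery(self, rng):
        from seedfill import SimConfig
        from seedfill.simulate import simulate_expression

        cfg = SimConfig(n_genes=1030, n_de_genes=30)
        counts, truth = simulate_expression(cfg, rng)
        f = tmm_factors(counts)
        lib = counts.sum(0) * f
        res = nb_exact_test(
            counts.bulk_high, counts.bulk_low, lib.bulk_high, lib.bulk_low
        )
        res["gene"] = counts.index
        out = deg_filter(res)
        called = set(out.loc[out.deg, "gene"])
        planted = set(truth.loc[truth.is_de, "gene"])
        assert len(called & planted) >= 27
        assert len(called - planted) == 0

    def test_hochberg_option(self):
        rec = self._records([0.01, 0.02, 0.04], [3.0] * 3)
        out = deg_filter(rec, method="hochberg")
        assert np.all(out.p_adj >= rec.p)


class TestSnpIndex:
    def test_arithmetic(self):
        out = snp_index(sites_frame([["s1", "c1", 1, 0, 20, 10, 10]]))
        assert out.index_high.iloc[0] == 1.0
        assert out.index_low.iloc[0] == 0.5
        assert out.delta_index.iloc[0] == 0.5

    def test_equal_counts_zero_delta(self):
        out = snp_index(sites_frame([["s1", "c1", 1, 15, 25, 15, 25]]))
        assert out.delta_index.iloc[0] == 0.0

    def test_null_mean_delta_near_zero(self, rng):
        alt_h = rng.binomial(40, 0.5, 10_000)
        alt_l = rng.binomial(40, 0.5, 10_000)
        df = sites_frame(
            [
                [f"s{i}", "c1", i, 40 - alt_h[i], alt_h[i], 40 - alt_l[i], alt_l[i]]
                for i in range(10_000)
            ]
        )
        out = snp_index(df)
        assert abs(out.delta_index.mean()) < 0.01

    def test_zero_depth_untestable(self):
        out = snp_index(sites_frame([["s1", "c1", 1, 0, 0, 10, 10]]))
        assert not out.testable.iloc[0]
        assert np.isnan(out.index_high.iloc[0])


class TestGStatistic:
    def test_independent_table_zero(self):
        assert g_statistic(sites_frame([["s", "c", 1, 20, 10, 20, 10]]))[0] == pytest.approx(0.0)

    def test_hand_value(self):
        g = g_statistic(sites_frame([["s", "c", 1, 20, 0, 10, 10]]))[0]
        hand = 2 * (20 * math.log(20 / 15) + 10 * math.log(10 / 15) + 10 * math.log(10 / 5))
        assert g == pytest.approx(hand, rel=1e-12)
        assert g == pytest.approx(17.26, abs=0.005)

    def test_zero_margin_convention(self):
        assert g_statistic(sites_frame([["s", "c", 1, 0, 0, 10, 10]]))[0] == 0.0

    def test_asymptotically_matches_chi2(self, rng):
        rows = []
        for i in range(300):
            rows.append(["s", "c", i, *rng.integers(40, 200, size=4)])
        df = sites_frame(rows)
        g = g_statistic(df)
        obs = df[["ref_high", "alt_high", "ref_low", "alt_low"]].to_numpy(float)
        chi2 = np.array(
            [
                stats.chi2_contingency(o.reshape(2, 2), correction=False)[0]
                for o in obs
            ]
        )
        ok = chi2 > 1.0  # avoid ratios of near-zero statistics
        assert np.all(np.abs(g[ok] - chi2[ok]) / chi2[ok] < 0.10)


class TestFisher:
    def test_balanced_table(self):
        assert fisher_per_snp(sites_frame([["s", "c", 1, 10, 10, 10, 10]]))[0] == 1.0

    def test_perfect_separation_value(self):
        p = fisher_per_snp(sites_frame([["s", "c", 1, 20, 0, 0, 20]]))[0]
        assert p == pytest.approx(2 / math.comb(40, 20), rel=1e-12)

    def test_matches_scipy_on_random_tables(self, rng):
        rows = [["s", "c", i, *rng.integers(0, 60, size=4)] for i in range(100)]
        df = sites_frame(rows)
        mine = fisher_per_snp(df)
        obs = df[["ref_high", "alt_high", "ref_low", "alt_low"]].to_numpy()
        for i, (a, b, c, d) in enumerate(obs):
            ref = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
            assert mine[i] == pytest.approx(ref, rel=1e-8)

    def test_degenerate_margin(self):
        assert fisher_per_snp(sites_frame([["s", "c", 1, 0, 10, 0, 10]]))[0] == 1.0

    def test_rank_agreement_with_g(self, rng):
        rows = [["s", "c", i, *rng.integers(10, 400, size=4)] for i in range(1000)]
        df = sites_frame(rows)
        g = g_statistic(df)
        p = fisher_per_snp(df)
        rho = stats.spearmanr(g, -np.log10(np.maximum(p, 1e-300))).statistic
        assert rho > 0.99


class TestFdr:
    def test_single_p(self):
        assert fdr_adjust([0.37])[0] == pytest.approx(0.37)

    def test_step_up_arithmetic(self):
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_monotone_and_dominating(self, rng):
        p = np.sort(rng.uniform(size=200))
        q = fdr_adjust(p)
        assert np.all(q >= p)
        assert np.all(np.diff(q) >= -1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])


class TestCandidateGenes:
    def _inputs(self):
        degs = pd.DataFrame({"gene": ["g1", "g2", "g3"], "deg": [True, True, False]})
        qtl = pd.DataFrame({"chrom": ["chr1"], "ci_lo_cm": [10.0], "ci_hi_cm": [30.0]})
        snps = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [15.0, 50.0], "q": [0.01, 0.01]})
        coords = pd.DataFrame(
            {
                "gene": ["g1", "g2", "g3"],
                "chrom": ["chr1", "chr1", "chr1"],
                "start": [14.0, 45.0, 14.0],
                "end": [16.0, 55.0, 16.0],
            }
        )
        for df in (qtl, snps, coords):
            df.attrs["coord_units"] = "cM"
        return degs, qtl, snps, coords

    def test_intersection_rule(self):
        degs, qtl, snps, coords = self._inputs()
        out = candidate_genes(degs, qtl, snps, coords)
        # g1: DEG, inside QTL, has significant SNP -> candidate
        # g2: DEG but outside every QTL interval -> never a candidate
        # g3: inside QTL with SNP but not a DEG -> excluded
        assert out.gene.tolist() == ["g1"]
        assert out.n_significant_snps.iloc[0] == 1

    def test_empty_significant_snps(self):
        degs, qtl, snps, coords = self._inputs()
        snps["q"] = 0.5
        assert candidate_genes(degs, qtl, snps, coords).empty

    def test_enriched_list_restricts(self):
        degs, qtl, snps, coords = self._inputs()
        out = candidate_genes(degs, qtl, snps, coords, enriched={"g2"})
        assert out.empty

    def test_coordinate_mismatch_is_hard_error(self):
        degs, qtl, snps, coords = self._inputs()
        snps.attrs["coord_units"] = "bp"
        with pytest.raises(ValueError, match="coordinate"):
            candidate_genes(degs, qtl, snps, coords)

    def test_planted_causal_genes_recovered(self, rng):
        # three causal genes: strong DEGs sitting on QTL intervals with
        # fully separated bulk allele counts
        genes = [f"g{i}" for i in range(10)]
        causal = ["g0", "g4", "g7"]
        degs = pd.DataFrame({"gene": genes, "deg": [g in causal for g in genes]})
        qtl = pd.DataFrame(
            {"chrom": ["chr1", "chr2", "chr3"], "ci_lo_cm": [0.0] * 3, "ci_hi_cm": [100.0] * 3}
        )
        coords = pd.DataFrame(
            {
                "gene": genes,
                "chrom": [f"chr{i % 3 + 1}" for i in range(10)],
                "start": np.linspace(5, 90, 10),
                "end": np.linspace(6, 91, 10),
            }
        )
        snp_rows = []
        for g, c, s in zip(coords.gene, coords.chrom, coords.start):
            q = 1e-6 if g in causal else 0.9
            snp_rows.append({"chrom": c, "pos": s + 0.5, "q": q})
        snps = pd.DataFrame(snp_rows)
        for df in (qtl, snps, coords):
            df.attrs["coord_units"] = "cM"
        out = candidate_genes(degs, qtl, snps, coords)
        assert sorted(out.gene) == sorted(causal)
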