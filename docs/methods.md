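# Methods

This note records the models implemented, the defaults and why, the design
choices made where the design was genuinely open, and what the synthetic
data do and do not establish about real field data.

## Logistic seed-filling model

Dry weight accumulation is modelled as w(t) = k/(1 + a·e^(−bt)); the rate
curve v = dw/dt is symmetric about the inflexion (ln a/b, k/2). One curve is
fitted per line × environment. Fitting is damped (Levenberg–Marquardt)
nonlinear least squares with the analytic Jacobian, tolerances 1e−10 and a
generous evaluation budget; if LM leaves the positive-parameter domain the
fit is retried with a bounded trust-region solver, and a fit that still
fails is returned with `converged=False` — downstream stages drop
unconverged rows rather than consuming garbage. Start values are
self-generated from the logit transform: k₀ = 1.05·max(w), then
ln(k₀/w − 1) regressed on t gives b₀ = −slope and a₀ = e^intercept. This is
robust for any S-shaped series and needs no user input.

Derived traits use the closed forms listed in the README. The completion
fraction defining t3 and w3 is 0.99 by default and exposed as a parameter
(values must exceed (3+√3)/6 ≈ 0.789 for w3 to stay positive). For fits
with a ≤ 2+√3 the first inflexion falls at or before pollination; values
are still returned, flagged `pre_pollination_inflexion`. The average rate is
the tabulated closed form v̄ = kb/6 — equivalently the mean rate over the
active period T = 6/b, since k = v̄·T; we implement the closed form and do
not re-derive the integral interpretation.

## Multi-environment statistics

With one observation per line × environment, genotype-by-environment
interaction and measurement error are confounded; the error variance δ² is
therefore the interaction mean square of the two-way method-of-moments
ANOVA, and H² = σ²_g/(σ²_g + δ²/e) is an entry-mean heritability. Negative
moment estimates are truncated at zero and flagged. Up to 20% missing cells
are imputed additively (line + environment effects); beyond that the layout
is rejected rather than silently re-weighted.

BLUPs use the closed-form shrinkage λ = σ²_g/(σ²_g + δ²/e_i) applied to
environment-centred line means (e_i = environments observed for line i).
Under a balanced layout this equals a genotype-random-intercept mixed model;
we prefer the closed form because it is deterministic, dependency-free and
exactly reproducible. Pool comparisons use the Welch (unequal-variance)
two-sample t-test, the common default of interactive statistics
environments.

## Linkage map and CIM

Markers are chi-squared against the 1:1 RIL expectation (1 df); markers
with p < 0.001 are removed, markers with fewer than 20 informative calls
are flagged untested. The bin map slides a 15-SNP window one SNP at a time
and calls it for a parent when ≥ 11 informative SNPs agree (the published
settings of the sliding-window binning approach, exposed as options);
ambiguous windows inherit the nearest unambiguous call, which places
breakpoints midway between discordant windows, and identical adjacent
window columns collapse into bins. Observed adjacent-bin discordance R is
corrected for recombinant accumulation over selfing, r = R/(2(1−R)), and
accumulated into Kosambi cM. Input marker order is trusted (no marker-order
re-optimisation).

The CIM scan is Haley–Knott regression on expected genotype scores: at each
position (1-cM grid plus the marker positions) the conditional expectation
of the ±1 genotype given the flanking bins comes from the two-state RIL
Markov chain with flip probability R(d) = 2r(d)/(1+2r(d)), r from inverse
Kosambi. Background cofactors are chosen by forward stepwise regression
(partial-F entry p < 0.01, at most 5), and a position is tested by
LOD = (n/2)·log₁₀(RSS₀/RSS₁) with cofactors within ±window/2 (window 10 cM)
of the position excluded from both models; PVE = 100·(1 − RSS₁/RSS₀) at the
peak. Meff is the Li–Ji eigenvalue sum of the bin-marker correlation matrix
(genome-wide by default; per-chromosome-summed available), and the
genome-wide threshold is −log₁₀(α/Meff) on the LOD scale.

One selection detail matters for error control: plain stepwise selection on
a dense RIL map happily admits *tightly linked cofactor pairs* that jointly
overfit noise (the ghost-QTL mechanism); when the scan later excludes one
member of such a pair near its own location, the position term recaptures
the selected effect with the partner still in the model, inflating the
genome-wide null exceedance rate at the Meff threshold (~0.15 measured on
pure-noise traits). We therefore require selected cofactors to be at least
one window apart on a chromosome — a safeguard used by established CIM
implementations — which brings the null rate to ~0.12, close to the ~0.1
expected from the threshold's construction. Residual inflation is inherent
to scanning with selected cofactors and, in field practice, is the reason
permutation thresholds exist; permutation is deliberately out of scope here.

QTL are contiguous supra-threshold runs; support intervals are 1.5-LOD
drops expanded one grid position outward (the usual convention), and peaks
within 10 cM on a chromosome — within or across traits/environments —
collapse into one nonredundant locus represented by its strongest peak.
Combined-environment scans use per-line trait means across environments.

## Bulked-segregant stage

Pools are the top and bottom 13 lines by BLUP v_max (deterministic line-id
tie-break), optionally restricted to lines whose inflexion time lies within
a tolerance of the population median so both pools peak at a similar time.
Each pool is one bulked RNA sample, so the expression contrast is a
one-vs-one negative-binomial exact test at the fixed dispersion
BCV² = 0.2² = 0.04 — the only regime in which a fixed dispersion makes the
test well defined. Counts are TMM-normalized (reference = sample whose
upper-quartile/library-size ratio is closest to the mean; 30%/5% double
trim; inverse asymptotic-binomial-variance weights; geometric-mean-1
rescale), then both samples are rescaled to the geometric mean of the
TMM-adjusted library sizes and rounded to integers — a simpler equalization
than the reference implementation's quantile-pseudocount scheme, validated
against a split-enumeration oracle. Conditional on each gene's total, all
splits are enumerated and the two-sided p is the conditional probability of
splits no more likely than the observed one (1e−12 relative tolerance on
ties). log₂FC uses a 0.125 prior count per group. DEGs require Bonferroni
p < 0.05 and |log₂FC| > 2; Hochberg step-up is available by flag.

Per-SNP bulk statistics: SNP index = alt/(ref+alt) per bulk and its
difference; G = 2·Σn·ln(n/ê) on the 2×2 bulk × allele table (0·ln 0 ≡ 0,
zero margins give G = 0, reported unsmoothed per site); the two-sided Fisher
p is computed by exact integer hypergeometric enumeration (no floating-point
tie ambiguity), with Benjamini–Hochberg FDR at 0.05 (Hochberg step-up
optional). Candidate genes are DEGs inside a QTL support interval carrying
at least one FDR-significant SNP and, when supplied, present in an
externally derived enriched-gene list; all three positional inputs must
declare the same coordinate unit — the package refuses to guess a cM↔bp
projection and requires an explicit lookup instead.

## Synthetic study generator

The generator draws the RIL population directly at the selfed-line limit: a
two-state Markov chain along each chromosome with flip probability
R = 2r/(1+2r) between adjacent markers, matching the analysis model exactly
and avoiding meiosis-by-meiosis simulation. Defaults mirror the study
conditions: 208 lines, 3 environments, the 14-point 10–61 DAP schedule, and
a desk-scale genome of 10 chromosomes (~160 cM, 32 markers each; ~1600 cM
total) standing in for a full 3000-bin map. Parents bracket a midpoint of
k = 12 g, a = 67, b = 0.14/DAP, so the inflexion sits near 30 DAP and
v_max near 0.42 g/DAP — the scale of real 50-seed weights. QTL act
additively on (k, a, b); every derived trait inherits their effects through
the closed forms, which reproduces pleiotropy (one locus moving both weight
and duration) by construction. Environment main effects and G×E deviates
are Gaussian per parameter; at the defaults the realized H² of k falls
around 0.75, inside the 0.6–0.85 band typical of such trials.

Measurement noise on each 50-seed weight is additive Gaussian with
sd 0.35 g (heteroscedastic noise available by flag), a realistic
balance-and-drying error for a 50-seed sample; negative draws are clipped
at zero. Because this noise is iid and the generating curve is exactly
logistic, simulated fits reach R² ≈ 0.99 — cleaner than the ~0.95 seen in
field data, where model misfit and biological deviations add to the
residual. Passing recovery tests on these data therefore demonstrates
correctness of the estimators, not robustness to model misspecification.
Bulk allele depths are binomial at the pool's true parent-2 frequency
(depth 40 per site); expression counts are negative binomial at dispersion
0.04 with log-normal baselines, ~2M reads per bulk, and 30 designated DE
genes at 8-fold change by default. All draws come from a single seeded
generator; a fixed seed reproduces every table byte for byte.

## Problem sizes used in the checks

The statistical checks run at deliberately desk-scale sizes chosen to make
their Monte-Carlo error small relative to the asserted bands: 1000 random
parameter draws for the closed-form/oracle agreement; 100 lines for noisy
parameter recovery; 50 replicates of 500 lines × 3 environments for
heritability recovery; one 208-line population × 200 pure-noise traits for
null scan calibration and 50 fresh 208-line populations for localization
power; 50-gene tables for the exact-test oracle and 2000 sites/genes for
the null error-control checks.

## Known limitations

* No alternative growth laws (Gompertz, Richards, segmented/bilinear):
  the logistic family is the model, by design.
* The ANOVA/H² machinery assumes a near-balanced layout; heavily
  unbalanced trials need a REML mixed model, which is out of scope.
* CIM here is single-QTL-at-a-time with cofactors: no multi-QTL model
  fitting, no epistasis, no permutation thresholds.
* The ΔSNP-index statistic is reported without simulation-based
  confidence bands; significance rests on the Fisher/FDR route.
* GO/KEGG enrichment is not computed (external databases); the candidate
  intersection accepts an externally supplied enriched-gene list.
* No read alignment or FPKM quantification: the expression stage starts
  from a count table.
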