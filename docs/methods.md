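# Methods

This note documents the statistical models and procedures implemented in
`hepamir`, the choices made where the design was genuinely open, and what
the synthetic-data tests do and do not establish about real data.

## Study design being modelled

The package targets a two-diet (chronic ethanol vs. pair-fed carbohydrate)
liver-regeneration time course in rat: 70% partial hepatectomy, liver
collected at 0, 6, 24 and 72 h, 3 animals per condition, miRNA measured as
counts on a 420-miRNA panel.  Two treatment arms (anti-miR-21 LNA "AM21"
and saline) exist only at 0 and 24 h.  `StudyDesign` encodes these as
defaults; all analyses take the sample table as data, so other factorial
time courses work unchanged.

## Normalization

**TMM scaling factors.**  For sample j against a reference sample r, each
shared nonzero miRNA contributes a log-ratio M = log2((y_j/N_j)/(y_r/N_r))
and average abundance A = ½·log2((y_j/N_j)(y_r/N_r)).  The factor is
2^(Σ w·M / Σ w) over the doubly trimmed set (central 70% by M rank,
central 95% by A rank), with w the inverse delta-method binomial variance
of M: (N_j−y_j)/(N_j·y_j) + (N_r−y_r)/(N_r·y_r).  The reference is the
column whose upper-quartile count fraction is closest to the mean upper
quartile (overridable), factors are rescaled to geometric mean 1, and a
sample sharing no nonzero miRNAs with the reference receives factor 1 with
a warning.  Trim fractions are the published defaults (30% M, 5% A); the
implementation agrees with the Bioconductor reference implementation to
machine precision on random count matrices (development cross-check) and
with a plain step-by-step oracle to 1e-10 in the test suite.

**log-cpm.**  value = log2((count + prior)/(N·factor + 2·prior) · 1e6) with
prior 0.5, so the library offset is the conventional +1.  The transform is
finite for zero counts and monotone within a sample.

**Precision weights.**  Per-miRNA linear models are fitted to log-cpm; the
lowess trend (span 0.5) of √(residual SD) on average log2 count is
evaluated at each observation's fitted log-count (clamped to the trend
range) and inverted as weight = SD⁻⁴.  Weights require at least one
residual degree of freedom.  They are computed but optional downstream:
the COMPACT and correlation stages use unweighted log-cpm, matching plain
Pearson analysis of normalized expression; the DE model accepts either.

## Differential expression

Each miRNA is fitted by (weighted) least squares against one shared design
matrix; contrasts are linear combinations of coefficients, parsed from
expressions such as `"EtOH_72_untreated - EtOH_0_untreated"` over
group-mean columns.  Residual variances s² (d residual df each) are shrunk
by empirical Bayes: with e = log s² − ψ(d/2) + log(d/2), the moment
estimator solves ψ′(d₀/2) = (excess variance of e)/2 by Newton inversion of
the trigamma function and sets s₀² accordingly; when the variance of e does
not exceed ψ′(d/2) the prior df is infinite and s₀² is the mean of the s²
(complete pooling).  The moderated t uses posterior variance
(d₀s₀² + d·s²)/(d₀ + d) on d₀ + d degrees of freedom.  Forcing d₀ = 0
recovers the ordinary t exactly, which the tests assert.  Zero-variance
miRNAs are excluded from hyperparameter estimation but still shrunk; if
every variance is zero, moderation is skipped with a warning.

Benjamini–Hochberg adjustment is implemented in-package (step-up, monotone,
capped at 1) because the signature-derivation rule depends on it; the
statsmodels implementation serves as an independent oracle in tests only.

**DE calling.**  up = {log2FC ≥ 1.5 and BH p ≤ 0.05}, down symmetric, with
boundary equality included.  The fold-change threshold is read as |log2FC|
≥ 1.5 (≈ 2.8-fold linear), the literal reading of the study's rule; a
fold-change-only switch exists because the rule as stated mentions only
fold change.  Whether the headline in-vivo DE count used adjusted p, raw p
or fold change alone is not recoverable from the text, so both paths are
exposed.

## COMPACT pattern counting

Within each condition, log2FC at every non-baseline time is the difference
of replicate-mean log-cpm from the same-condition baseline (0 h).  Values
≥ τ map to U, ≤ −τ to D, else 0 (τ = 1.5 log2 units by default; equality is
regulated).  The per-condition code strings are cross-tabulated into a
3^T × 3^T count matrix with full membership lists; cells partition the
analyzed set exactly, swapping conditions transposes the matrix, and
raising τ can only move miRNAs toward the all-zero code — all asserted as
properties.  Replicate aggregation is the arithmetic mean of log-cpm
(geometric mean in linear space); no variance weighting is applied inside
COMPACT.  The input universe is whatever the caller passes (panel after
the expression filter by default); restricting to DE-called miRNAs is a
caller decision, since "differentially expressed" is not precisely defined
for this purpose.  Patterns are computed on normalized means rather than
per-animal votes; the per-animal alternative is not implemented.

## Correlation screen

Pearson r of every miRNA against the reference on log-cpm across a chosen
sample subset; two-sided p from t = r√((n−2)/(1−r²)) with n−2 df.
Zero-variance vectors get undefined r, are flagged, and are excluded from
BH adjustment.  The headline significance rule is raw p < 0.05 — the rule
the study states — with BH-adjusted p carried in the result table and a
multiplicity caveat in the summary.  The default subset for the AM21
question is all samples collected at 0 and 24 h, pooling diets and
treatments; the study does not enumerate which groups entered its
correlations, and this pooling choice is recorded in the CLI manifest.

## Signature enrichment

The enrichment score of set S in a ranked list of N scored miRNAs is the
extremum by absolute value of a running sum that rises by |score|^p / Σ_hits
|score|^p at members and falls by 1/(N−|S|) at non-members (p = 1 by
default); the leading edge is the members at or before (positive ES) / at
or after (negative ES) the extremum.  Ties in the ranking are broken
lexicographically so results are deterministic.

Permutation nulls: `gene_set` mode (default) redraws |S∩panel| member
positions uniformly; `phenotype` mode permutes sample labels and re-ranks
by signal-to-noise (μ₁−μ₂)/(σ₁+σ₂), falling back to exact enumeration with
a warning when fewer than 10 distinct relabellings exist.  Gene-set mode is
the default because with n = 3 per group the phenotype null is far too
coarse for p < 0.05.  The nominal p conditions on the observed sign:
p = (1 + #{same-sign |ES_perm| ≥ |ES_obs|}) / (1 + #same-sign perms), which
is uniform under the null (asserted by a 200-signature KS test); NES is
ES divided by the mean same-sign permuted |ES| and is reported as an
auxiliary quantity.  The packaged signatures (HSC 16 up / 26 down, LSEC 66,
KC 20) are shipped as a GMT file with cell-type and direction tags, next to
a synthetic pseudo-panel — the union of the signature members known to
overlap the study's bulk data — that supports offline overlap arithmetic; a
real count matrix replaces it whenever one is supplied.  miRNA ids are
matched exactly after trimming and case-folding the miR/let prefix, with a
small curated alias table for typographical variants; unresolved ids are
reported, never silently dropped.  `derive_signature` implements the
KC-style rule: BH-adjusted p < 0.1, top 20 by |log2FC|.

## qPCR ΔΔCT

Per replicate, ΔCT = CT_target − mean(CT of the endogenous references)
(arithmetic mean of CTs = geometric-mean normalization in linear space;
defaults are the three stable references hsa-miR-99b-5p, hsa-miR-23a-3p,
hsa-miR-100-5p).  ΔΔCT is the difference of group-mean ΔCT from the control
group; relative expression is 2^(−ΔΔCT), exactly 1 for the control itself,
and invariant to any per-well constant CT offset.  Statistics are computed
on the ΔCT (cycle) scale — the standard choice — with a pooled-variance
Student t by default (Welch optional) and the usual star map; the fold
change SE uses the delta method (ln2 · FC · SE(ΔΔCT)).  Whether published
error bars of this kind live on the cycle or fold-change scale is generally
ambiguous; both are reported.

## Synthetic data generator

Counts are gamma–Poisson: conditional on a per-sample latent factor z_s,
the expected count of miRNA i in sample s is N_s · p_i · 2^(δ_is + λ_i z_s)
with negative-binomial dispersion φ (variance μ + φμ²; φ = 0 is Poisson).
Defaults, chosen once as the study conditions the package emulates:

- panel 420 miRNAs; baseline log2 abundances ~ Normal(6, 2.5), spanning
  roughly five orders of magnitude as miRNA panels do;
- library sizes uniform on [5e5, 1.5e6] total counts;
- dispersion φ = 0.05, a mild overdispersion typical of technical-replicate
  count platforms;
- planted trajectories with per-step effect δ = 2 log2 units: 25
  EtOH-upregulated miRNAs at 24–72 h (10 of them additionally dipping at
  6 h in CHO) and 6 EtOH-downregulated, the miR-21 analog among the
  upregulated set — the effect structure the analysis is meant to find;
- a latent N(0, 1) factor per sample with loading 1 on miR-21 and ±0.9 on
  1 positively (miR-340-5p) and 4 negatively (miR-365, let-7a, miR-1224,
  miR-146a) coupled partners;
- AM21 modelled as a −2 log2 shift entering through the latent channel, so
  the knockdown propagates to partners with their loadings (no quantitative
  in-vivo knockdown efficiency is available; −2 is a strong but not
  complete inhibition);
- qPCR CT tables with base CTs uniform on [22, 30], one cycle per planted
  log2 unit, Gaussian cycle noise (default SD 0.2), and three planted-stable
  reference miRNAs.

A single integer seed drives everything through deterministically spawned
substreams, so equal (design, config, seed) give byte-identical output.
The generator does not simulate cartridge-level artifacts (spike-in probes,
fields of view), cross-hybridization, batch effects, or cell-type mixture
composition; passing recovery tests on these data therefore demonstrates
the correctness and calibration of the statistical machinery under the
assumed count model, not robustness to platform-specific artifacts in real
NanoString data.

## Numerical choices and degenerate inputs

Trigamma inversion by Newton iteration (tolerance 1e-10) with asymptotic
endpoints; lowess trend clamped at its range ends; TMM returns factor 1
when no informative miRNAs survive trimming; correlation of zero-variance
vectors is undefined rather than 0; the degenerate equal-mean zero-variance
t-test reports p = 1 with a flag; rank ties in GSEA break lexicographically;
BH caps at 1 and is monotone by construction.  Problem sizes in the test
and acceptance runs (e.g. 10,000 null miRNAs for calibration, 20 seeds for
recovery rates, 80–400-miRNA panels for repeated simulations) were chosen
as the smallest sizes at which the binomial noise of the measured rates is
comfortably inside the asserted bands.

## Known limitations

No spline or trend tests for time courses; no random-effect or
duplicate-correlation modelling; no quantile/cyclic-loess normalization or
positive-control NanoString normalization; no amplification-efficiency
correction in qPCR; no statistical test on COMPACT cell occupancy; no
FDR across signature collections (only four signatures in scope).  The
in-vivo headline counts depend on the deposited accession data and are
re-computable only through `hepamir reproduce` once those tables are
downloaded; the package's own guarantees are the ones its tests and
acceptance script compute.
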