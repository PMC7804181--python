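# Methods

## The problem

Self-reported behaviours (alcohol consumption is the motivating case) enter
GWAS as noisy, *systematically* distorted phenotypes. Two distortions matter
here. Misreports: some participants report zero consumption while being
current consumers, and some skip the quantitative question altogether, both
at rates that rise with disease burden. Longitudinal change driven by
disease ascertainment: participants who develop (or are warned about) a
disease reduce the behaviour, so the reported value is shifted downward
precisely in the high-liability stratum. Both mechanisms manufacture a
negative behaviour–disease association with no causal basis, and the bias
propagates into every downstream analysis that consumes the GWAS summary
statistics.

The MLC (misreports and longitudinal changes) correction studied here is a
two-step procedure: (1) phenotype QC removing suspect reporters (never
consumers, zero-consumption current consumers, non-responders, and — within
the reduced-consumption group — those who reduced because of illness or a
doctor's advice); (2) stratifying the remaining sample by self-reported
longitudinal change (LESS / SAME / MORE), scanning each stratum on
within-stratum standardised phenotypes, and combining the scans by
fixed-effect inverse-variance-weighted (IVW) meta-analysis. Standardising
within strata removes the mean and variance differences the ascertainment
shift creates between groups, which is what de-biases the combined scan.

## Simulation model

One synthetic chromosome, m SNPs at 100 kb spacing (1-based positions).
Genotypes are binomial(2, MAF) in Hardy–Weinberg and linkage equilibrium,
MAF ~ U(maf_range); an optional AR(1)-within-block latent-Gaussian generator
provides LD for clumping tests. The behaviour is

    Y = Σⱼ xⱼβⱼ + e_y,   var(genetic) = h²_y (centred in-sample), var(Y) = 1,

with β drawn N(0,1) over the causal set and rescaled. The disease liability
is

    D = b_yd·Y·[II,IV] + Σⱼ xⱼγⱼ·[III,IV] + e_d,   var(D) = 1,

and disease status is D above Φ⁻¹(1 − prevalence) (liability-threshold
model; both liability and status are exposed). The four scenarios: (I) Y
genetic only, D pure noise; (II) Y genetic, Y causal for D; (III) D genetic
only; (IV) Y genetic and causal for D, plus a disjoint direct-effect set
for D.

Ascertainment: exactly ⌈q·n⌉ individuals with the highest liability (ties by
index) get reported_Y = Y − c·SD(Y), change_group = LESS, and an
illness-or-doctor reason for a configurable sub-fraction (default all).
Misreports: underreporting (reported value forced to 0) and non-response
(missing) are Bernoulli with logistic-in-liability probabilities whose
intercept is calibrated by root-finding so the marginal rate equals the
configured fraction.

### Default parameters

| parameter | default | meaning |
|---|---|---|
| n_individuals | 10,000 | cohort size |
| n_snps | 1,000 | SNPs on the synthetic chromosome |
| n_causal_y / n_causal_d | 100 / 100 | causal-set sizes |
| h2_y, h2_d | 0.3 | variance of the direct genetic components |
| b_yd | 0.3 | liability-scale effect of Y on D per SD of Y |
| disease_prevalence | 0.15 | liability-threshold quantile |
| maf_range | (0.01, 0.5) | uniform MAF support |
| threshold_q grid | 0.10–0.40 | ascertained top-liability fraction |
| shift_c grid | 1–5 | reduction of reported Y, in SDs of Y |

The grids are the study conditions of the bias experiments; the cohort-level
defaults (n, m, h², b_yd, prevalence) are this package's choices of a
realistic desk-scale regime and are exposed as configuration, not asserted
as anyone's empirical values. One root seed drives deterministic per-stage
substreams (genotypes, effects, noise, demographics), so any stage can be
re-run independently and full runs are bit-reproducible.

## Estimators and numerical choices

**Association scan.** Per-SNP OLS of the phenotype on allele count with
shared covariates and intercept, computed for all SNPs at once by
Frisch–Waugh–Lovell residualisation (exactly equivalent to the per-SNP full
design; verified against normal-equations and statsmodels oracles at 1e-8).
A mixed model would be the field tool on real cohorts with relatedness;
simulated individuals are unrelated, so the mixed model degenerates to OLS
and the substitution is exact in expectation. p-values use the normal
approximation (exact t via flag); monomorphic SNPs are flagged, not
estimated. Binary outcomes are scanned on the 0–1 scale; odds-ratio
transformations are out of scope.

**Standardisation.** Within each group (sex within change-group stratum):
drop values outside mean ± 7 SD of the (transformed) raw values, regress out
covariates, z-score, mask |z| > 5, then re-standardise the retained values
so retained group mean/variance are exactly 0/1. The ±7 SD screen operates
on the transformed consumption scale (whether it precedes or follows the
log₂ transform is ambiguous in the field; post-transform is this package's
documented choice, switchable by transforming before calling). Percentages
in filter reports are printed at one decimal with half-up rounding.

**IVW meta-analysis.** Fixed effects only: β = Σ wᵍβᵍ/Σ wᵍ, w = 1/se²,
se = (Σ w)^(−1/2); Cochran's Q reported per SNP, never used to filter.
Swapped-allele rows are harmonised by sign flip; any other mismatch raises.
Precision additivity 1/se² = Σ 1/seᵍ² holds to machine precision and is
asserted in tests.

**Clumping.** Greedy: lowest-p SNP passing the threshold becomes a lead;
SNPs within the window (≤ 1 Mb) or with sample allele-count r² ≥ 0.01 to
the lead are removed; ties on p break by position then id. Defaults are the
standard genome-wide criteria (5×10⁻⁸, 1 Mb, 0.01).

**SNP-effect correlation r_b.** The published estimator corrects the naive
correlation of two GWAS beta vectors for estimation error; the exact formula
lives in prior literature, so this package implements the canonical
method-of-moments version: var_true = var(b̂) − mean(se²) per trait,
cov_true = cov(b̂₁,b̂₂) − overlap term, r_b = cov_true/√(var₁var₂). The
overlap term (correlated errors in shared samples) is zero by default and
otherwise estimated from the mean product of z-scores at SNPs null in both
scans (|z| < 2). SE by delete-one-SNP jackknife. When either trait's effect
variance does not exceed its error variance the estimate is undefined and an
`UnstableEstimateError` carries diagnostics — this is why "Y ⊥ D" null
experiments use scenario IV with b_yd = 0 (both traits polygenic,
independent effects) rather than scenario I, where the disease side has no
genetic variance at all and r_b is not estimable. Estimates are reported raw
and clamped to [−1, 1] with a flag. In simulations r_b is evaluated at the
known causal union by default; a clumped-significant-SNP mode is provided.

**Mendelian randomisation.** Wald ratio b_out/b_exp per instrument; IVW with
weights b_exp²/se_out² (single instrument reduces exactly to Wald); simple
and interpolated weighted medians with parametric-bootstrap SEs (1,000 reps,
seeded). An optional one-pass outlier screen (|ratio − IVW| > 3 ratio-SEs)
approximates HEIDI-style instrument filtering; it is an approximation, not
that method, and refuses to empty the instrument set. Reverse analyses swap
the roles and record the direction.

**Down-sampling excess test.** To ask whether the loci lost (or gained) by
the correction exceed what the smaller sample alone explains, individuals
are removed uniformly at random before QC, the scan and clumping are re-run,
and lost/gained loci are counted by lead-SNP window matching (a baseline
locus is lost when no down-sampled lead falls within the clump window — the
matching rule is a documented choice). The summary z = (observed −
mean)/s.e.m. with a two-sided normal p reproduces the conventional printed
arithmetic, e.g. (16 − 10.03)/0.85 ≈ 7.02. That statistic treats the
replicate-mean uncertainty as the only noise; under the resampling null the
observed count is a single draw, so the z-based p is not uniform (its
variance is ≈ reps + 1). The result therefore also carries an exact
randomized-rank empirical p — (#{ref > obs} + U·(#{ref = obs}+1))/(reps+1) —
which is uniform by construction under exchangeability and is the quantity
to use for calibration claims. Both are reported; they answer different
questions.

**Risk curves.** Bins are left-open right-closed; each bin's OR comes from
the bin-vs-reference 2×2 table ((a·d)/(b·c), Woolf CI, Haldane–Anscombe 0.5
correction when a cell is zero). Group exclusions apply to the reference
side of every comparison only. The reference defaults to the lowest bin,
matching the epidemiological convention in which the wide
moderate-consumption band anchors the curve. Polygenic-score curves enforce
a seeded disjoint train/evaluation split and score with clumped
genome-wide-significant training betas.

## The simulated correction and its experiments

In simulations the ascertained set *is* the LESS group, so the correction
under study is the two-group (LESS/SAME) split with within-group
standardisation and IVW meta-analysis (`mlc.SIMULATION_RULES`); reason-based
removal of illness reducers is a real-data refinement which, at the
simulation defaults (every ascertained individual carries the illness
reason), would simply delete the whole LESS stratum — also unbiased, at a
power cost, and the stratified scan skips a stratum the rules empty.

The grid experiments contrast uncorrected and corrected scans through r̂_b
and the IVW b̂_xy. Two architectures matter:

- *Independent-effects null* (scenario IV, b_yd = 0): true r_b = 0.
  Uncorrected r̂_b collapses to ≈ −1 at strong ascertainment (every disease
  SNP acquires a spurious negative behaviour effect); the corrected scan
  restores |mean r̂_b| within noise of zero.
- *Causal world* (scenario IV, b_yd = 0.3): the uncorrected r̂_b and IVW
  b̂_xy fall with ascertainment strength and flip sign at the strongest
  settings; after correction b̂_xy returns to ≈ 0.3 at every grid point.
  Scenario II alone (no direct disease genetics) cannot produce the MR
  attenuation: there the shift is collinear with the Y genetics, every
  exposure beta shrinks by the same factor, and the Wald ratios *inflate* —
  the bias mechanism runs through disease-specific loci contaminating the
  instrument set, which is exactly the real-data narrative.

A residual effect remains after correction: conditioning on the
liability-defined strata induces a small Berkson-type (explaining-away)
correlation between disease genotypes and the behaviour within strata, so
corrected r̂_b is somewhat below its no-ascertainment value (direction always
preserved, and the IVW causal estimate is unaffected because those SNPs
carry negligible instrument weight). This is the package's concrete
realisation of "slightly underestimated, with no directional bias".

The J-shape demonstration (`jshape.ascertained_risk_world`) draws the
observed disease from a latent correlated 0.7 with the ascertainment
liability, so the LESS group is case-enriched without coinciding with the
case set (with deterministic top-q ascertainment and q ≥ prevalence the two
sets would nest and the reference-exclusion contrast would degenerate). A
wide lowest reference bin (bottom 40 %) absorbs the shifted LESS group, the
uncorrected OR curve attains an interior minimum, and excluding LESS from
the reference restores a nondecreasing curve in most replicates. In the
genetic-predictor world, the dose–response curve's minimum must lie within
the span of the genetic component (x_min = 0.5 with h² = 0.5 here);
a minimum at 1 SD of the phenotype sits beyond the predictor's quantile
range and the binned predictor curve is then monotone.

## Problem sizes

Unit tests run on cohorts of 300–8,000 individuals and 60–500 SNPs. The
study-scale property tests use n = 10,000, m = 1,000, 100 causal SNPs with
100 replicates for the null-world sign flip, 6 replicates across the full
4×5 ascertainment grid, 50 paired replicates at n = 6,000 for
power/spurious-locus contrasts, 200 trials (13 down-sample replicates each)
at n = 2,000 for the calibration check, and 50 replicates for the J-shape
fractions. `scripts/acceptance.py` re-runs the same experiments at reduced
replicate counts (30/6/15/100/20) chosen so the whole script completes in a
few minutes on one CPU; all replicate seeds derive from the single `--seed`.

## What the generator does and does not emulate

It reproduces the statistical structure the analyses assume: polygenicity,
liability-threshold disease, deterministic top-quantile ascertainment with a
constant shift, calibrated liability-dependent misreporting, change-group
labels. It does not emulate realistic human LD maps, MAF spectra,
relatedness/population structure, chip or imputation error, dosage data,
age/cohort effects on the behaviour, or reasons for reduction beyond the
illness/other dichotomy. Passing tests therefore certify the estimators and
the correction logic under the assumed structure, not robustness to
structured confounding absent from the generator.

## Known limitations

- The correction relies on the change-group labels being correct; mislabeled
  longitudinal change (acknowledged in the field) is not simulated.
- The within-stratum Berkson effect above means corrected r̂_b is
  conservative; a selection-aware estimator is out of scope.
- The excess test's window-based locus matching is one of several defensible
  matching rules; counts can shift by ±1–2 under alternatives.
- Fixed-effect IVW only; random-effects meta-analysis is not implemented.
- The uncorrected IVW estimate can be non-estimable at the strongest
  ascertainment settings (no SNP passes 5×10⁻⁸ once the phenotype variance
  is inflated ~7-fold); grid summaries report the replicate count per cell.
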