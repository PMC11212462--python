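# Methods

## Setting and assumptions

The package implements summary-data two-sample Mendelian randomization:
genetic variants serve as instruments for an exposure (here typically a
gut-microbial abundance trait) whose causal effect θ on a binary outcome is
wanted. Validity rests on the three IV assumptions — the variant is
associated with the exposure, independent of confounders, and affects the
outcome only through the exposure — plus no sample overlap between the two
GWAS. Effects for binary outcomes are treated on the log-odds scale
throughout; odds ratios are exp(θ).

## Instrument selection and harmonization

Candidates are exposure SNPs with p below a threshold (default 1 × 10⁻⁵,
the relaxed threshold used for exposures with few genome-wide hits).
Greedy clumping keeps the best-p SNP and discards any remaining SNP on the
same chromosome within 1,000 kb *and* with r² ≥ 0.01 to a kept SNP (the
joint rule; ties on p break by chromosome, position, rsid, making the
output independent of input row order). SNPs absent from the outcome may
be replaced by the best outcome-present proxy with r² > 0.8 (ties: nearest
position, then smallest rsid); a proxy's own associations and alleles are
used directly — no haplotype phasing is attempted, since the LD reference
carries r² only.

Outcome alleles are aligned to the exposure by direct match, effect/other
swap (negating β_Y), or strand complement followed by either. Palindromic
SNPs (A/T, C/G) carry the same allele set on both strands, so orientation
is inferred from effect-allele frequencies; if either study's EAF falls in
the intermediate window (default [0.42, 0.58], configurable — no standard
definition exists, this matches common practice) the SNP is dropped.
Missing EAF makes a SNP ineligible rather than imputed. Irreconcilable
allele sets are dropped as incompatible. Every drop carries a
machine-readable reason code.

Instrument strength uses the full textbook form
R² = 2β²q(1−q) / [2β²q(1−q) + 2σ²Nq(1−q)] with q the EAF; the 2q(1−q)
factor cancels algebraically, which the implementation asserts at run time,
so R² = β²/(β² + Nσ²) exactly and the result is EAF-invariant.
F = R²(N−2)/(1−R²); instruments with F ≤ 10 are discarded (the
conventional weak-instrument cutoff). Retained instruments are re-signed
so β_X ≥ 0 (exposure-increasing orientation); all estimators first apply
this orientation internally, so estimates are invariant to jointly
re-signing any instrument.

## Estimators

* IVW is the zero-intercept WLS of β_Y on β_X with weights 1/σ_Y². The
  default model is multiplicative random effects: SE_fixed scaled by
  max(1, √(Q/(k−1))). The floor keeps the random-effects SE from ever
  undercutting the fixed-effect SE — conservative under heterogeneity,
  identical under homogeneity. A single instrument falls back to the Wald
  ratio.
* MR-Egger adds a free intercept; inference for slope and intercept uses
  the t distribution with k−2 df (small-k regression), and the residual
  scale is likewise floored at 1. A design with no spread in β_X is
  rejected as degenerate. Note the exact-fit case: with zero residuals the
  floor keeps the intercept SE positive, so "intercept 0, p = 1" rather
  than 0/0.
* The weighted median sorts Wald ratios, forms standardized midpoint
  cumulative weights s_j = (cum_j − w_j/2)/Σw with w_j = β_Xj²/σ_Yj² (the
  first-order ratio precision; no standard weight definition exists, this
  is the delta-method choice), and interpolates at 0.5.
* The mode estimators maximize a normal-kernel density of the ratios with
  bandwidth φ·0.9·min(sd, IQR/1.349)·k^(−1/5) (φ = 1 by default); the
  maximizer is located on a 512-point grid and refined by bounded scalar
  optimization to ~1e-10, so results agree with a brute-force grid search
  at its own resolution. Simple mode weights are 1, weighted-mode weights
  inverse ratio variances.
* Bootstrap SEs (median, modes) use a parametric bootstrap — β* drawn
  normally around the observed effects with the observed SEs — with 1,000
  replicates by default and a mandatory seed; CIs and p-values are
  normal-theory except Egger's t.

## Diagnostics

Cochran's Q uses the ratio form Q = Σ w_j(θ̂_j − θ̂_fixed)² with
w_j = β_Xj²/σ_Yj², referred to χ²(k−1); this is the IVW-companion form
(algebraically the weighted RSS of the fixed-effect fit). A delta-method
variant adding the exposure-side variance is available (`method="delta"`).
Leave-one-out re-estimates IVW without each SNP and flags omissions that
flip the sign or exit the full-set CI.

MR-PRESSO computes the leave-one-out weighted RSS and compares it with
parametric simulations (β_X* ~ N(β_X, σ_X), β_Y* ~ N(θ̂₍₋ⱼ₎β_X, σ_Y));
the global p uses the add-one Monte-Carlo estimator, so it is never
exactly zero. Per-SNP residual terms are compared with their simulated
distributions and flagged at the Bonferroni level 0.05/k (the reference
convention for this test family). The distortion test compares the
observed shift between all-SNP and outlier-free IVW with shifts from
removing equally many random SNPs. All stochastic diagnostics are
bit-reproducible given (seed, n_sim). When IVW and the weighted median
disagree in sign, an optional fallback re-selects instruments at the
genome-wide 5 × 10⁻⁸ threshold (off by default).

## Multiple testing, classification, power, reverse MR

Across a panel of exposures the primary (IVW) p-values are converted to
Benjamini–Hochberg step-up q-values (monotone; implemented via
statsmodels, cross-checked in the tests against a hand-written step-up
oracle). Storey-type π₀ estimation is deliberately not used — BH with an
explicit q < 0.1 threshold is the named procedure. FDR is computed across
exposures within one outcome, one test per trait. Classification:
significant (p < 0.05, q < 0.1), nominal/indicative (p < 0.05, q ≥ 0.1),
null, or not_evaluable (no surviving instruments; traits with fewer than
3 instruments are reported but flagged as insufficient for the regression
-based sensitivity analyses).

Post-hoc power for a binary outcome with case fraction K uses
power = Φ(−z_{1−α/2} + b√v) + Φ(−z_{1−α/2} − b√v), b = |log OR|,
v = N·R²·K(1−K), with R² the sum of retained instruments' variance
explained (a per-SNP alternative would simply substitute a single R²).
At OR = 1 this reduces to α.

Reverse MR reuses the same pipeline with the disease as exposure and each
trait as outcome, selecting instruments at p < 10⁻⁴ (the relaxed threshold
appropriate to a small-case-count GWAS), and reports a batch-level
"no significant reverse causal relationship" flag.

An rsID blocklist stands in for an external confounder screen
(e.g. variants known to act through reticulocyte count or hemoglobin):
listed instruments are removed and all estimates recomputed. Live web
lookups are out of scope by design.

## Synthetic data generator

The generator works directly on the summary-statistic scale. For SNP j
with MAF p_j ~ U(0.05, 0.5): γ_j ~ N(0, γ_sd²) for causal SNPs,
σ_Xj = 1/√(2N_X p_j(1−p_j)), β̂_Xj ~ N(γ_j, σ_Xj²);
σ_Yj = 1/√(2N_Y K(1−K) p_j(1−p_j)) (log-odds approximation),
β̂_Yj ~ N(θγ_j + α_j, σ_Yj²). Defaults mirror the motivating study shape:
N_X = 18,340, N_Y = 218,792, K = 598/218,792. Pleiotropy regimes: none,
balanced (α mean-zero), directional (nonzero mean along sign(γ) — i.e.
relative to the exposure-increasing allele, the orientation estimators
work in; a fixed mean in the arbitrary generator coding would be scrambled
into balanced pleiotropy by harmonization and undetectable by
construction), and correlated (corr(α, γ) = 0.5, violating InSIDE). LD is
block-exchangeable (blocks 2 Mb apart, SNPs 5 kb apart within), sufficient
to exercise clumping and proxy logic deterministically; real panels have
richer decay structure. Allele coding is randomized (effect/other swaps,
strand flips for non-palindromic SNPs, a 15 % palindromic fraction) so
harmonization is exercised non-trivially. Binary-outcome effects are
generated directly on the log-odds scale rather than via individual-level
genotypes, which keeps 211-trait batches at desk scale; consequences such
as case-control ascertainment, allele-frequency spectra, and population
stratification are not emulated, so passing tests validate the estimators'
statistical behaviour under the stated model, not robustness to those
real-data features. Batches give each trait its own SNP panel and share
one outcome study, mirroring a single-disease screen.

## Problem sizes and calibration scenarios

The calibration studies use instrument strength chosen a priori from the
attenuation analysis: regression-dilution bias of IVW is
≈ γ_sd²/(γ_sd² + σ_X²), so the "valid instruments" scenarios use
γ_sd = 0.1 at N_X = 18,340 (mean F ≈ 70, attenuation < 2 %), making
"mean estimate near truth" a property of the estimator rather than of
weak-instrument bias. With the sparser default γ_sd = 0.05 the generator
reproduces the 3–22 instruments-per-trait regime of microbiome GWAS.
Batch scenarios use 60 SNPs / 25 causal per trait with γ_sd = 0.15 so a
planted θ = log 1.7 signal has expected |z| ≈ 5 and is separable from the
210 null traits; a weaker, field-realistic |z| ≈ 3 signal cannot rank
first among 211 traits with high probability, which is a statement about
multiplicity, not about the estimators.

Monte-Carlo sizes (tests and acceptance script): 1,000 replicates for
type-I error, 500 for coverage and the MR-PRESSO null, 200 for outlier
power and the Egger regimes, 10–40 runs for 211-trait batch properties;
MR-PRESSO uses n_sim = 1,000. One full-null caveat: under a global null
the probability that BH at q < 0.1 makes at least one call is exactly 0.1
(Simes), so "zero false discoveries" holds in ~90 % of batches by
construction — the random-effects SE floor nudges this a few points higher.

## Known limitations

No multivariable MR, contamination-mixture or CAUSE estimators, Steiger
filtering, radial MR, or sample-overlap corrections. Positions are
1-based within a single genome build; no liftover. The LD reference is
pairwise r² only. Power assumes the aggregate-R² normal approximation.
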