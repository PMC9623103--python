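# Methods

## Setting and assumptions

The package performs two-sample Mendelian randomization between two binary
traits using GWAS summary statistics only. The causal parameter θ is the
log-odds ratio of the outcome per unit log-odds of the exposure; all input
betas are assumed to be on the log-odds scale (the only scale consistent
with case/control GWAS meta-analyses), and odds ratios are reported as
exp(β). The usual instrumental-variable assumptions apply per variant:
association with the exposure (relevance), no association with
confounders, and no effect on the outcome except through the exposure
(exclusion restriction). The estimator suite exists because the last
assumption is fragile: MR-Egger, the weighted median, the weighted mode
and MR-PRESSO each tolerate a different pattern of violation.

Positions are 1-based and strand is assumed forward; strand differences
between studies are expressed only through allele complementarity. Only
single-base biallelic variants are handled (no indels, no multi-allelics,
no liftover).

## Harmonization

The outcome study's effect allele is aligned to the exposure study's.
Swapped alleles negate the outcome beta and mirror its frequency;
complementary codings are mapped to the forward strand before matching;
pairs irreconcilable by swap or complement are dropped with a logged
reason rather than raised. Palindromic variants (A/T, C/G) cannot be
resolved by allele matching and are oriented by allele frequency. The
default policy (`drop-ambiguous`, band 0.08) drops a palindromic variant
when either study's frequency lies in [0.42, 0.58] and otherwise orients
by which side of 0.5 the frequencies fall on; `eaf-infer` always orients
by frequency. A missing outcome frequency makes a palindromic variant
non-inferable and it is dropped. Both the policy and the band are
configuration, not constants: the upstream tooling conventions they mimic
vary, and the defaults here are the conservative common choice.

## Instrument selection

The cascade runs: p < 5×10⁻⁸ (strict inequality) → greedy LD clumping →
shared-locus exclusion → confounder exclusion list → MAF ≥ 0.01.
Clumping visits candidates by ascending p (ties: chromosome, position,
then variant id, making the survivor set invariant to input row order) and
removes variants on the same chromosome within 5,000 kb at r² ≥ 0.01.
Shared-locus screening removes identity matches and variants with r² >
0.01 to any shared locus — the two boundary conventions (≥ for clumping,
> for the shared-locus screen) mirror how the respective rules are usually
stated, and both are covered by boundary tests. The LD matrix is always an
explicit input (or clumping is skipped with an `assume-preclumped` flag);
the package never derives LD from genotypes or downloads reference panels.

Instrument strength uses, per variant with effect-allele frequency p,
effect b, standard error s and study size n:

    r²_j = 2p(1−p)b² / (2p(1−p)b² + 2p(1−p)·n·s²),  F_j = r²_j(n−2)/(1−r²_j)

with the cruder F = (b/s)² exposed as an alternative (`formula="t-ratio"`);
the two agree to first order at small r², and since published analyses
rarely print which variant they used, total variance explained is a soft
descriptive quantity rather than a contract.

## Estimators

All estimators consume Wald ratios β̂_j = β̂_Yj/β̂_Xj with first-order SEs
σ_Yj/|β̂_Xj| and weights w_j equal to the inverse squared SE, which makes
IVW identical to origin-constrained WLS with weights σ_Yj⁻² (asserted
against statsmodels to 1e-10 in the tests). Choices worth recording:

- **Random-effects IVW** is multiplicative: SE_fixed × max(1, √(Q/(J−1))).
  The clamp never rewards underdispersion. The automatic model switch uses
  the Cochran Q p-value against 0.05 (random iff p strictly below).
- **MR-Egger** first orients every instrument to positive exposure effect
  (the intercept is not meaningful under arbitrary allele coding). Its
  p-values use t distributions with J−2 df — at the J of 4–5 typical here,
  normal tails would be materially anti-conservative. The coefficient SEs
  scale by max(1, σ̂) for symmetry with the IVW clamp.
- **Weighted median**: interpolated at normalized cumulative weight 0.5;
  SE by seeded parametric bootstrap (default 1,000 replicates) resampling
  both betas from normals at their observed SEs. A closed-form SE variant
  exists in the literature; the bootstrap was chosen because it extends
  unchanged to the weighted mode and its determinism is guaranteed by the
  seed.
- **Weighted mode**: Gaussian kernel density over the ratios with
  bandwidth h = φ·0.9·min(sd, IQR/1.34)·J^(−1/5) (φ configurable,
  default 1), maximized on a fixed 2,001-point grid padded by 3h. When all
  ratios coincide the bandwidth is zero and the common value is returned.
  Grid resolution bounds the quantization error at (range+6h)/2000, far
  below the estimator's sampling noise at any realistic J.
- 95% intervals use 1.96 throughout; p-values are two-sided.

## Sensitivity suite

Cochran Q is computed around the fixed-effects IVW estimate with a
chi-square(J−1) upper tail. MR-PRESSO standardizes leave-one-out residuals
by outcome SEs only, consistent with the package-wide weighting
convention; published MR-PRESSO runs differ in this dialect choice, so
observed-RSS values are not comparable across implementations and are
treated as descriptive. The global p carries the add-one Monte-Carlo
correction; per-variant outlier p-values are raw replicate exceedance
fractions, Bonferroni-multiplied by J. One behavior is worth flagging: a
very large planted outlier contaminates the leave-one-out slopes of the
valid variants, so their residuals can also exceed the clean simulated
null and collect collateral flags. The planted variant still carries the
minimum outlier p in every tested configuration; users should treat the
flag set as ranked, not as a partition. When flags occur the estimate is
recomputed without them and a distortion p compares the shift against
random same-size exclusions.

## The simulator

Summary statistics are generated directly at the summary level — no
individual-level genotypes — because the analysis consumes nothing finer.
Per variant: MAF ~ U(maf_low, maf_high); true exposure effect γ_j uniform
in magnitude with random sign; SEs follow (2p(1−p)n)^(−1/2); observed
betas are normal around γ_j (exposure) and θγ_j + sign(γ_j)·α_j (outcome).
Pleiotropic effects α_j act on the exposure-increasing allele — without
the sign alignment, "directional" pleiotropy would cancel in the mean once
estimators orient instruments, and the regime would be indistinguishable
from balanced. Regimes: none (α = 0), balanced (α ~ N(0, σ_α²); InSIDE
holds by construction), directional (α ~ N(μ_α, σ_α²)), outlier (α = 0
except for planted variants at outlier_scale·θ·mean|γ|). Variants are
placed on cycling chromosomes at 20-Mb spacing with non-palindromic
alleles, so selection and harmonization are exercised without incidental
drops; LD structure is supplied separately by a block-diagonal fixture
generator, keeping LD handling independently testable.

The presets encode the application's study conditions: `paper-forward`
(5 instruments, exposure n = 58,284, outcome n = 15,283, planted OR 1.46)
and `paper-reverse` (4 instruments, roles swapped, planted OR 1.05), with
γ ranges (0.10–0.16 and 0.18–0.26) chosen so instrument F statistics land
in the low hundreds and total variance explained near 3% and 7% — the
regime the RA/CD instruments occupy. What the simulator does *not*
emulate: LD between instruments, sample overlap between studies,
population stratification, winner's-curse bias in instrument effects, and
case/control ascertainment; passing tests therefore demonstrate
correctness of the estimators and pipeline under the stated generative
model, not robustness to those real-data complications.

## Pipeline and bidirectional design

Each direction runs the full cascade and all estimators; estimators whose
minimum instrument count is not met (Egger/median/mode need 3, MR-PRESSO
4) are carried as explicit not-applicable markers rather than omitted. The
two directions are fully independent runs with roles swapped, and one
direction failing for lack of instruments does not abort the other. A
genuine subtlety of the bidirectional design: when A truly causes B, A's
instruments are significantly associated with B as well, so a naive
reverse analysis inherits a spurious 1/θ-flavored signal. The
outcome-association exclusion screen (the cascade's manual phenome-scan
stage) is the intended remedy, and the bidirectional demonstration and
acceptance study apply it by passing each trait's known instruments as the
opposite direction's exclusion list.

## Problem sizes

Replicated studies use desk-scale sizes chosen once: 500 replicates for
effect recovery and null calibration (Monte-Carlo SE of a rejection rate
at 0.05 is ≈ 1%), 1,000 Monte-Carlo draws inside each MR-PRESSO call, 200
replicates per arm for outlier power/specificity, and J = 50 for
calibration runs where the preset J of 4–5 would make single-replicate
noise dominate. Bootstrap SEs use 1,000 replicates by default; analysis
drivers and end-to-end tests reduce to 200–500 where the quantity under
test is a point estimate.

## Known limitations

Single-base biallelic variants only; no Steiger filtering, radial MR,
I²/Rucker framework or multivariable MR (out of scope by design); the
MR-PRESSO residual-weighting dialect makes its RSS incomparable with other
implementations; frequency-based palindrome orientation is fallible near
MAF 0.5 regardless of the band chosen; and the F-statistic formula choice
shifts variance-explained totals by a few percent relative.
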