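# tsmr — bidirectional two-sample Mendelian randomization

`tsmr` implements a complete bidirectional two-sample Mendelian
randomization (MR) analysis between two binary traits, built around the
question of whether genetic liability to rheumatoid arthritis (RA) causally
raises the risk of celiac disease (CD), and vice versa. It is aimed at
genetic epidemiologists who work with GWAS summary statistics: it covers
instrument selection, effect-allele harmonization, five causal estimators,
the standard sensitivity suite, and a summary-level simulator with known
causal truth so the whole chain can be validated without any external
downloads.

## The statistical model

Each genetic instrument *j* carries an exposure association estimate
β̂<sub>Xj</sub> (SE σ<sub>Xj</sub>) from one study and an outcome
association β̂<sub>Yj</sub> (SE σ<sub>Yj</sub>) from an independent study,
both on the log-odds scale. The per-variant causal estimate is the Wald
ratio β̂<sub>j</sub> = β̂<sub>Yj</sub>/β̂<sub>Xj</sub> with first-order SE
σ<sub>Yj</sub>/|β̂<sub>Xj</sub>| and inverse-variance weight
w<sub>j</sub>. The estimators pooled over J instruments:

- **IVW**: β̂ = Σw<sub>j</sub>β̂<sub>j</sub> / Σw<sub>j</sub>, equivalent to
  weighted least squares of β̂<sub>Y</sub> on β̂<sub>X</sub> through the
  origin. Fixed-effects SE (Σw<sub>j</sub>)<sup>−1/2</sup>; the
  multiplicative random-effects SE inflates it by √(Q/(J−1)), clamped below
  at 1, and is selected automatically when the Cochran Q p-value is < 0.05.
- **MR-Egger**: the same weighted regression with a free intercept; a
  non-zero intercept estimates average directional pleiotropy (t tests,
  J−2 df).
- **Weighted median**: the 50% point of the weight-ordered Wald ratios;
  consistent when valid instruments hold a majority of the weight.
- **Weighted mode**: the maximizer of a weighted Gaussian kernel density
  over the ratios; consistent when the largest cluster of agreeing
  instruments is valid.
- **MR-PRESSO**: a seeded Monte-Carlo test on leave-one-out residual sums
  of squares, flagging pleiotropic outlier instruments and re-estimating
  without them.

Instrument selection applies, in order: genome-wide significance
(p < 5×10⁻⁸), greedy LD clumping (r² < 0.01 within a 5,000-kb window),
exclusion of loci shared between the two traits (identity and LD overlap),
a confounder-association exclusion list, a minor-allele-frequency floor
(MAF ≥ 0.01), and allele harmonization (swap-aware, strand-aware, with
frequency-based orientation of palindromic A/T and C/G variants).
Instrument strength is reported as per-variant variance explained
r²<sub>j</sub> and F statistics.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic
cohorts shaped like the RA and CD GWAS meta-analyses (58,284 and 15,283
subjects; planted causal ORs of 1.46 forward and 1.05 reverse):

```bash
python analysis/01_simulate_cohorts.py   # write the four summary-stat tables
python analysis/02_select_instruments.py # walk the selection cascade
python analysis/03_bidirectional_mr.py   # both directions, all estimators
python analysis/04_calibration.py        # replicated calibration study
```

`01` reports the planted instruments explain 3.2% (forward) and 6.5%
(reverse) of exposure variance with F statistics between 175 and 478 —
comfortably past the F ≫ 10 weak-instrument rule of thumb. `03` prints the
forest-style estimate table; at the default seed:

```
direction          method  n_snps    or  or_ci_low  or_ci_high     pval
   RA->CD       ivw-fixed       5  1.51       1.39        1.66 4.45e-20
   RA->CD weighted-median       5  1.55       1.38        1.73 5.42e-14
   CD->RA       ivw-fixed       4  1.01       0.98        1.04     0.49
   CD->RA weighted-median       4  1.00       0.97        1.04     0.85
```

i.e. the forward direction recovers an odds ratio near the planted 1.46
with a decisive p-value while the reverse direction is null — the
asymmetry the bidirectional design is meant to expose. The diagnostics row
(Cochran Q, Egger intercept, MR-PRESSO global test) shows no heterogeneity
or directional pleiotropy, so the fixed-effects IVW is retained. `04`
confirms calibration over replicates: mean recovered OR 1.453 against the
planted 1.46, 94% CI coverage, and null rejection rates near the nominal
5% for IVW, the Egger intercept and MR-PRESSO.

A thin CLI wraps the same pipeline for file-based use:

```bash
tsmr simulate --preset paper-forward --outdir sim/
tsmr run --exposure sim/exposure.tsv --outcome sim/outcome.tsv \
         --preclumped --outdir out/ --direction forward
```

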