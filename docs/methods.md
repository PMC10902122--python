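# Methods

## Model and assumptions

The package implements two-sample summary-level Mendelian randomization.
Per-variant associations with an exposure X and an outcome Y come from
non-overlapping GWAS cohorts. A variant j is a valid instrument when it is
(i) associated with X, (ii) affects Y only through X, and (iii) shares no
confounder with Y. Under these assumptions each Wald ratio β̂ᵧⱼ/β̂ₓⱼ
estimates the causal effect of X on Y, and the inverse-variance-weighted
(IVW) combination is a weighted regression of β̂ᵧ on β̂ₓ through the
origin.

First-order weights `wⱼ = 1/se(β̂ᵧⱼ)²` are used throughout (exposure-side
uncertainty is ignored in the weights; second-order weights are not
implemented). The multiplicative random-effects variant inflates the
fixed-effect slope SE by `√φ` with `φ = max(1, Q/(J−1))`: heterogeneity
widens the interval and underdispersion is never allowed to narrow it.
P-values are two-sided standard normal, not t — matching the convention
of the standard two-sample MR software this mirrors.

Instruments for a drug target are cis variants: exposure-significant
(`p < 5e-8`), within the target gene ± 100 kb (1 kb = exactly 1000 bp,
bounds inclusive), non-palindromic, LD-pruned greedily at `r² < 0.3`
(most significant kept first; p-value ties broken by lower genomic
position, for determinism). Pruning at 0.3 leaves residual correlation;
standard IVW is still applied — as the mirrored study design does — and
the maximum retained pairwise r² is logged so users can see it.
Variants genome-wide significant for the outcome are excluded up front
as likely exclusion-restriction violations. Trait-wide (genome-wide)
instruments use no window and `r² < 0.001`.

Harmonization matches variants across datasets by rsID only, aligns
outcome alleles to the exposure's effect allele (swap → negate beta and
mirror the frequency; strand mismatch → complement first), and always
drops palindromic (A/T, C/G) variants — no frequency-based rescue is
attempted, and no allele-frequency concordance check is applied.
Coordinates are 1-based inclusive.

Directionality: estimation is per 1-unit exposure increase internally;
reporting adds `exp(−b)` with its transformed CI, the OR per 1-unit
exposure *decrease*, because drug-target studies of lowering therapies
report on that scale. The exposure unit (SD, mmol/L, ...) is an opaque
label; no rescaling is performed.

## Sensitivity battery

- **MR-Egger**: weighted regression with a free intercept after orienting
  all β̂ₓ ≥ 0; the intercept estimates the average directional pleiotropic
  effect under InSIDE. Coefficient SEs are inflated by `√max(1, s²)` with
  s² the weighted residual mean square on J−2 df. Requires J ≥ 3.
- **Weighted median**: ratio estimates ordered, midpoint-adjusted
  cumulative weights `βₓ²/seᵧ²` interpolated at ½; consistent when valid
  instruments carry > 50% of weight. SE by parametric bootstrap (default
  5,000 draws, seeded).
- **Weighted mode**: argmax of a normal-kernel weighted density over the
  ratios; bandwidth = `bandwidth_factor × 0.9 × (1.4826·MAD) × J^(−1/5)`
  (factor defaults to 1) on a 1,024-point grid padded by 3 bandwidths.
  Identical ratios short-circuit to the common value.
- **Leave-one-out**: J re-runs of IVW; an omission is flagged when it
  flips the slope's sign or moves p across 0.05.
- **Power**: `power = Φ(ncp − z_{1−α/2}) + Φ(−ncp − z_{1−α/2})` with
  `ncp = |log OR| √(n·r²·k(1−k))` for a binary outcome (continuous:
  drop k(1−k)). Both rejection tails are kept so the size is exactly α
  at the null; away from the null the second term is negligible and the
  value matches the published single-tail approximation used by the
  standard online calculator.

## Colocalization

Per-variant Wakefield log-ABFs (`½[log(1−r) + r z²]`, `r = W/(V+W)`) are
combined over a window by log-sum-exp into the five-hypothesis posterior
with priors p1 = p2 = 1e-4, p12 = 1e-5 (the cited method's documented
defaults; the source study says only that defaults were used). Prior
effect SDs √W default to 0.15 for quantitative traits (standardized
effects) and 0.2 for case-control traits on the log-odds scale. The H3
mass `p1·p2·(S1·S2 − S12)` is mathematically non-negative; floating-point
negatives are clamped to zero (and are exactly zero for a single shared
variant). When a record lacks a standard error, V is approximated from
sample size and allele frequency (`1/(2·n·p·q)`, scaled by k(1−k) for
case-control traits). Decision thresholds (PP.H4 > 0.8; conditional ratio
\> 0.75) are reported as flags, never enforced. The single-causal-variant
assumption per trait is inherited from the ABF enumeration; multi-signal
extensions are out of scope.

## Mediation

Product of coefficients: `indirect = β1·β2` (exposure→mediator times
mediator→outcome), `direct = β0 − β1·β2`, `proportion = β1·β2/β0`.
Delta-method variances treat the three estimates as independent
(non-overlapping cohorts; all covariances zero):
`var(indirect) = β2²se1² + β1²se2²`, and the proportion variance is
written in gradient form
`(β2/β0)²se1² + (β1/β0)²se2² + (β1β2/β0²)²se0²` so zero component
effects never divide by zero. The β0 term is included by default and can
be switched off (the variant without it is also exposed, since published
proportion CIs do not always propagate β0's uncertainty). A zero total
effect leaves the proportion undefined rather than raising. The biomarker
screen runs IVW per biomarker against a Bonferroni threshold whose
denominator is the configured family size, held fixed regardless of
harmonization failures; direction counts follow the per-exposure-decrease
convention. β0 and β1 use the drug-target cis instruments, β2 the
mediator's own genome-wide-preset instruments, univariable throughout.

## Synthetic-data generator

What it emulates: haplotypes drawn by thresholding blockwise AR(1) latent
Gaussians (correlation ρ within a block, independence across blocks) at
per-variant MAF quantiles, giving realistic block LD on the dosage scale
(dichotomization attenuates the latent correlation, so dosage r² sits
well below ρ²); a standardized quantitative exposure with a configurable
set of causal cis variants whose per-allele effects are scaled — using
the bivariate-normal orthant probability for the dosage covariance — so
the population explained variance hits the target h²; a binary outcome
generated on the log-odds scale (`logit = α + b·X + pleiotropy + mediator
terms`, with α solved numerically so the expected case fraction matches);
an optional standardized mediator with its own causal variants; and
strictly non-overlapping cohorts, enforced by spawning one RNG stream per
cohort from the scenario seed (the child keys are recorded in the truth
file). Summary statistics are produced the way a GWAS would produce them:
per-variant simple linear regression for quantitative traits,
per-variant logistic regression (vectorized Newton-Raphson, cross-checked
against statsmodels) for the binary outcome.

What it does not emulate: demographic history and realistic recombination
maps, genome-wide polygenic background, population stratification,
imputation error, sample overlap, or linear-mixed-model association
testing of binary codings. Passing tests therefore demonstrate that the
estimators behave correctly under the stated statistical model, not that
any particular real-data result is right.

Defaults (the desk-scale scenario): 200 variants in 4 blocks, ρ = 0.9,
MAF ~ U(0.1, 0.5), 10 causal variants with weights spread 0.5–1.5 (so
MR-Egger has exposure-effect spread to work with), h² = 0.1, reference
panel n = 2,000, 10,000 individuals per cohort, case fraction 0.1; all
stages complete in seconds. Binary traits use per-variant logistic
regression so `exp(β)` is an OR; a linear-model-on-binary toggle is not
provided — the generator sticks to the interpretable model.

## Validation experiments (study conditions)

The experiments in `drugmr.experiments` fix these conditions once:

- **Calibration / recovery / robustness**: 10 variants in 10 blocks —
  J = 10 mutually independent instruments (each ~F ≈ 100 at n = 10,000)
  explaining h² = 0.1 together. Independent instruments make the nominal
  IVW calibration claim well-posed; the LD-rich 200-variant window is
  exercised by the colocalization experiments and the pipeline
  integration test instead. Null calibration: 1,000 replicates; recovery
  at b = −0.3: 500; Egger recovery of planted directional pleiotropy
  (mean 0.05 per allele on all instruments): 300.
- **Invalid-instrument stress**: 40% of instruments carry directional
  pleiotropy ~ U(0, 0.5) (mean 0.25 log-odds per allele), putting the
  planted IVW bias at several sampling SEs — the regime in which the
  majority-valid weighted median's robustness claim applies. The
  outcome-significance exclusion is switched off here so the planted
  invalid share stays in the set. 500 replicates.
- **Colocalization**: 200-variant window, one causal variant explaining
  1% of each quantitative trait, n = 10,000 per trait; distinct-variant
  scenarios place the two causal variants in different LD blocks
  (r² ≈ 0). 100 replicates per scenario.
- **Mediation**: 20 independent variants (10 exposure-, 10
  mediator-specific), h²(exposure) = 0.1, h²(mediator) = 0.3 (a strongly
  heritable biomarker, keeping the mediator→outcome step well powered so
  the small-proportion chains are estimable), chains with total log-odds
  effect −0.5 and mediated proportions 2%, 5%, 20%; 200 replicates each.

`scripts/acceptance.py` reruns all of the above from a single `--seed`
and writes the summary JSON.

## Numerical choices and edge cases

- Log-sum-exp for all colocalization mass accumulation; posterior sums
  are exact to ≤ 1e-12.
- Greedy pruning is deterministic given the input and the position tie
  rule; LD uses plain Pearson correlation of panel dosages (no
  HWE-standardized or composite LD).
- `wald_ratio` refuses β̂ₓ = 0; IVW refuses an all-zero exposure design;
  Egger/median/mode require J ≥ 3, leave-one-out J ≥ 2.
- F = 10 exactly is flagged weak ("exceeding 10" indicates strength).
- The logistic scan starts at the marginal log-odds, runs Newton updates
  to 1e-10, and fails loudly on degenerate (all-case/all-control)
  outcomes; monomorphic dosage columns yield infinite SEs in the linear
  scan rather than crashing.
- Bootstrap SEs are seeded; pipeline reruns with the same config and seed
  are byte-identical (report files carry no timestamps).

## Known limitations

- Correlation-aware IVW (generalized least squares with the LD matrix) is
  not implemented; with cis instruments pruned at r² < 0.3 the reported
  SEs inherit the residual-correlation optimism of standard IVW. The
  maximum retained r² is logged precisely so this is visible.
- No Steiger filtering, MR-PRESSO, multivariable MR, or proxy-variant
  lookup; no liftover; positional variant matching is not attempted.
- The power formula is an asymptotic approximation; simulation puts it
  within a few percentage points at moderate case fractions.
- Mediation assumes non-overlapping cohorts; overlapping-sample
  covariance corrections are out of scope.
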