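# Methods

## Traits and data model

Seven phenological traits span the selfing annual's life cycle: GERM
(germination timing), BT (bolting), INT (bolting-to-anthesis interval),
ANT (= BT + INT), FLO (flowering duration), RP (reproductive period) and
FRR (= FLO/RP). ANT and FRR are exact functions of the others, so the
generator draws the five base traits and derives the rest; every table the
package writes satisfies both identities to machine precision. Fitness is
total silique length (mm), a seed-count proxy, constrained non-negative.
Under water-stress treatments plants often die before the last fruit
matures, so RP and FRR are structurally missing there and every model is
fitted complete-case.

## Synthetic RIL families

`make_ril_family` draws genotypic values for n lines from a multivariate
normal with user-specified means, among-line SDs and a genetic correlation
matrix (validated symmetric, unit-diagonal, PSD). Bimodality and
transgressive segregation of real RIL families are not modelled: all
downstream estimators consume only first and second moments. The per-trait
residual SD is derived from the targeted broad-sense heritability,
`σ_E = σ_G √((1−H²)/H²)`, so the realized H² of a simulated experiment
matches the target in expectation. Environmental noise is independent
across traits and plants (environmental covariances are not modelled).

Default study conditions: 160 lines, 3 blocks per treatment, trait means
(GERM 3.5, BT 25, INT 5, FLO 20, RP 30 days), genetic SDs (0.8, 4, 1.5, 4,
4 days), per-trait H² between 0.20 and 0.51, and a genetic correlation
matrix with the qualitative structure typical of such families (BT–INT
negative, FLO–RP strongly positive, GERM weakly negatively correlated with
the post-anthesis traits).

## Fitness surfaces

Expected relative fitness is `w(z) = 1 + Σ_k b_k z_k + ½ Σ_k g_k z_k²` on
within-treatment standardized traits; realized fitness is
`max(0, W0·w(z) + ε)` with Gaussian noise. The ½ makes the generative `g`
live on the same scale as the reported (doubled) quadratic coefficient γ.
Two distortions of this generative model are worth knowing:

- **Truncation at 0.** Clamping attenuates strong directional gradients:
  at b = −0.6 with noise giving R² ≈ 0.5, the expected fitted β is ≈
  −0.50 (bias ≈ 0.1); at moderate |b| ≤ 0.3 the bias is negligible. The
  clamp is kept (rather than resampling) because zero seed set is exactly
  what strong selection against late phenotypes means biologically.
- **Relativization.** The estimator divides by the sample mean fitness,
  so when Σ_k g_k ≠ 0 the recovered coefficients are rescaled by
  `1/(1 + ½Σg)`. Mean-preserving surface pairs (e.g. g = +0.3/−0.3) avoid
  this in calibration runs.

Defaults per treatment mirror the sign structure of selection on
phenology under stress (stronger selection for earliness under water
stress; weak, partly reversed selection on post-anthesis traits under
competition), with baseline fitness W0 = 300–1000 mm and noise chosen so
the polynomial model explains roughly 15–80% of fitness variance across
treatments — W0 and the noise level are the package's own choices, as is
everything about the surfaces' magnitudes.

## Selection analysis

Standardization uses the sample (n−1) SD, which makes the selection
differential equal the sample covariance of relative fitness and the
standardized trait exactly (asserted to 1e−10 in the tests). β and γ come
from one multiple regression per treatment on all z_k and z_k² without
cross-products; quadratic coefficients *and their SEs* are doubled, which
preserves t statistics and hence p-values. ANT is refused in the
polynomial model (perfectly collinear with BT + INT); a condition-number
guard (10⁸) catches other collinear designs. The genotypic level collapses
to unweighted line means within treatment (lines are equally replicated by
design) and relativizes by the grand mean of line means. Cross-treatment
comparisons pool two already-standardized treatments and test trait×
treatment and trait²×treatment interactions in one OLS fit. Holm's
step-down controls multiplicity within treatment at k = 7.

## Quantitative genetics

H² uses the classical balanced mean-squares estimator
`σ̂²_G = (MS_G − MS_E)/r`, `H² = σ̂²_G/(σ̂²_G + MS_E)` clamped to [0, 1],
with the block term included in the model and excluded from the error
(with unbalanced replication r is the effective replicate number
`(N − Σn_i²/N)/(a−1)`). Negative variance estimates clamp to zero. The
treatment×genotype GLM Box-Cox-transforms the response, fits the
marginality-respecting ladder intercept → +treatment → +block(treatment)
→ +genotype → +interaction, and retains the smallest model within 2 AIC
points of the minimum; significance comes from the retained model's
Type-I ANOVA.

Genotypic correlations are Pearson correlations of line means. Note the
line mean over r replicates carries `σ²_E/r` of environmental variance,
so its correlation estimates `r_g · σ²_G/(σ²_G + σ²_E/r)` per trait — at
H² = 0.5 and r = 3 that is a 25% attenuation per trait. Calibration
checks therefore run in the high-heritability regime (H² ≈ 0.85), where
line means are reliable genotypic proxies; with real moderate-H² traits
the genotypic correlations should be read as attenuated lower bounds.

A trait pair is flagged as a genetic constraint when both directional
gradients and the genotypic correlation are significant and
`β_i·β_j·r_g < 0`: joint selection in directions the genetic covariance
resists. The rule is symmetric and relabeling-invariant.

## Forward LNS simulator

Populations of selfing lines evolve in discrete, non-overlapping
generations at census 160 (per the seed-sampling protocol; realized seed
numbers do not alter the census). Each individual's phenotype is its
line's genotypic value plus environmental noise; fitness comes from the
treatment's surface evaluated at the phenotype standardized by the
*founding family's* moments (a fixed reference, so surfaces keep their
meaning across generations); the next generation is a multinomial draw
with line probabilities proportional to summed line fitness (equivalent
to seed-count-proportional sampling). Selfing means exact line
inheritance: a line lost from a population never returns. Per-population
random streams are spawned from one master seed.

`expected_response` gives the breeder's-equation prediction
`Δz̄ = H²·S·sd_P` with `S = Σ_k b_k ρ_P(t,k)/(1 + ½Σ_k g_k)` from family
moments; it ignores fitness truncation and noise, so the simulator is
validated against the *realized* parental-generation differential
`S = cov(w, z)` (the tests verify agreement within 3 Monte-Carlo SEs over
1000 replicates, plus the neutral-drift variance `σ²_line/census` and the
neutral martingale property).

Default LNS surfaces impose directional selection for earliness that is
weak in the two mild water-stress intensities and strong in the two
severe ones (the watering-stop schedule barely stresses mild-intensity
plants), and neutrality in the competition intensities, where selection
on unmeasured traits plausibly dominates.

## Resampled-G0 inference

The baseline generation is phenotyped as one replicate per line per block,
not as 12-plant populations, so 25 "theoretical G0" pseudo-populations are
assembled per repeat: 25 disjoint 4-line sub-populations per block
(sampled without replacement from the ≥ 100 required distinct lines),
concatenated one-per-block under the no-duplicate-line constraint via a
randomized greedy matching (up to 1000 restarts, then a full redraw;
seed-stable), then randomly mapped onto the 25 real
(intensity, population) labels.

The five-factor ANOVA treats population as random: treatment intensity is
tested over MS[population(intensity)], generation and generation×intensity
over MS[population(intensity)×generation], block and the population terms
over the residual. For the balanced phenotyping design (every
population×generation×block cell equal) the sums of squares are computed
exactly from group means; unbalanced tables fall back to a sequential
least-squares decomposition (the two agree to 1e−7 on balanced data, and
both are tested against an independent projection oracle). The response is
Box-Cox transformed once per trait on the pooled data of each repeat
(profile-ML λ on [−2, 2] in 0.05 steps; shift 1 − min(y) when needed).

The 95% criterion is count-based: a factor is significant when ≥ 95% of
its P-values over the repeats are strictly below 0.05. The reported 95th
percentile is the order statistic at rank ⌈0.95 n⌉, chosen so that
`p95 < 0.05` is exactly equivalent to the count rule (property-tested).
Under fully null data the criterion's verdict rate is bounded by the
underlying test's α, because only the G0 portion varies across repeats; a
marginal signal residing in the fixed evolved-generation data passes or
fails nearly deterministically across repeats.

Tukey multiple comparisons use the studentized range (Tukey–Kramer SE for
unequal n) with a compact letter display assembled from maximal runs of
mutually non-significant groups along the mean ordering.

## Problem sizes and calibration runs

Monte-Carlo calibrations use the design's own sizes: gradient recovery at
n = 480 (160 lines × 3 blocks) over 50 replicates, H² recovery over 100,
breeder's-equation and drift checks over 1000–2000 one-generation
replicates at census 160, procedure-level null rates over 50 datasets ×
100 G0 repeats, and the positive control over 20 end-to-end pipeline
replicates × 100 repeats. The positive control imposes a strong
bolting-time decline concentrated in the two severest intensities
(b_BT = −1.2 and −2.5); under the moderate default surfaces the
generation×intensity interaction sits near the significance boundary
(F ≈ 1.8 with 12 plants per population×generation cell against a
≈ 3.9-day residual SD), which is a power statement about the design, not
an estimator defect.

## Limitations

- The generator produces Gaussian, environmentally uncorrelated traits;
  real phenology is right-skewed and spatially autocorrelated within
  flats. Passing recovery tests show estimator correctness under the
  generative model, not robustness to those features.
- Maternal environmental carryover between LNS generations is not
  modelled (an optional one-generation carryover hook exists but defaults
  to 0); with real data it is confounded with the genetic response.
- Competition dynamics enter only through treatment shifts and fitness
  surfaces; no competitor growth model or within-flat density variation.
- Genotypic correlations from 3-replicate line means are attenuated at
  moderate H² (see above).
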