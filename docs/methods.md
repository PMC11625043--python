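# Methods

## Scientific setting

Resting-state functional connectivity (FC) between cortical locations is
commonly summarized per *homotopic pair* — two mirror-symmetric vertices, one
per hemisphere. Hemispheric specialization declines in aging ("hemispheric
asymmetry reduction in older adults"), and the degree to which an older
person's lateralization pattern still resembles that of young adults is a
candidate marker of functional preservation. `hemilat` implements the full
measurement chain for this question and a synthetic data source that makes
every stage testable without MRI data.

## Measures

For vertex time series `x_v` (vertices × time), FC is the Pearson correlation
`r(u, v)`, Fisher-transformed `z = atanh(r)`. Per vertex two strengths are
summed over the z matrix:

* `intra(v)` — sum of z to all other vertices in v's hemisphere
  (self-correlation excluded: atanh(1) is infinite and would dominate);
* `he(v)` — sum of z to all vertices of the opposite hemisphere except v's
  homotopic partner (heterotopic connectivity).

Correlations are clipped to ±(1 − 1e−7) before atanh so degenerate inputs
stay finite. For each homotopic pair with left/right values `L`, `R`:

    LI = (L − R) / |L + R|

computed separately for the two strengths (`LI_intra`, `LI_he`). Positive LI
= stronger left-hemisphere involvement. The denominator may vanish; a pair
with |L + R| < ε (default ε = 1e−8) is marked *invalid* rather than clipped —
clipping would bias network averages, masking does not. |LI| > 1 is possible
when L and R differ in sign and is kept as computed.

Network-based LI is the unweighted mean of pair LIs over pairs whose two
members share the same (non-NONE) network label, excluding invalid pairs per
LI kind. Alignment-to-young is the cosine similarity between a subject's
vector of pair LIs in one network and the young-group mean vector over the
same pairs. The template index set is *listwise* within network (a pair must
be valid in every young subject), so all subjects of a study are compared on
one fixed index set; by default a young subject's own alignment uses the full
young template (a leave-one-out mode exists).

Group-mean LI maps are compared by Pearson correlation over shared valid
pairs; two such correlations sharing the young map are compared with
Steiger's z using the back-transformed mean correlation in the pooled term.

## Motion quality control

Frames with framewise displacement strictly above 0.5 mm are censored before
correlation (scrubbing, optional but on by default); a subject whose outlier
fraction strictly exceeds 20% is excluded. Both inequalities are strict,
matching the usual phrasing "greater than 0.5 mm" / "more than 20%". mFD, the
subject-level motion covariate, is the mean over *all* frames (pre-scrubbing);
a config option can restrict it to retained frames.

## Statistical battery

* One-sample t per group × network × LI kind (is the network lateralized?).
* One-way ANOVA across groups. In `auto` mode a mean-centered Levene test at
  α = 0.05 gates the omnibus: heterogeneous variances → Welch's F with
  Welch–Satterthwaite df2 and Games–Howell post hocs (Welch t against the
  studentized range with q = t·√2); homogeneous → classic F with pooled
  pairwise t and Benjamini–Hochberg FDR. Partial eta squared is always
  SSB/(SSB + SSW) from the classic decomposition on the same data, also next
  to Welch's F — the only convention that reproduces published effect sizes
  alongside Welch statistics. Both ANOVA forms are also available directly
  from printed group summaries (mean, SD, n); raw-data and summary forms agree
  to 1e−10 on exact summaries.
* Jonckheere–Terpstra for an ordered trend (young > older-musician >
  older-non-musician), normal approximation with tie-corrected variance,
  one-sided and directional; a fully tied sample is defined as z = 0. Exact
  enumeration is deliberately not implemented — group sizes in the intended
  use are ≥ 20 where the normal approximation is accurate.
* Partial correlation by least-squares residualization of both variables on
  an intercept plus covariates; t = r·√((n−k−2)/(1−r²)) with df = n−k−2.
  Default covariates: age, gender (0/1 indicator, M = 1), education, hearing
  level, MoCA, digit span, Stroop, mFD, mean global FC (mean z over the
  strict upper triangle of the whole-brain matrix).
* BH-FDR is applied within each family of seven network tests per measure,
  group and test type. Note the step-up adjustment is monotone and
  order-preserving but not idempotent.
* Demographic battery on a cohort table: χ² (no continuity correction) on the
  gender × group table; pooled two-sample t between the older groups on age,
  education, MoCA and hearing; Levene-gated ANOVA on the four behavioral
  scores.

## Psychometrics

Speech reception thresholds come from a two-parameter logistic
`P(snr) = 1/(1 + exp(−(snr − α)/β))` fitted by least squares on observed
proportions with Levenberg–Marquardt (β kept positive via log
parameterization; initialization α₀ = SNR level with proportion nearest 0.5,
β₀ = 1 dB; tolerances 1e−10). Guess and lapse rates are fixed at 0 — the
minimal model; fits whose proportions never leave [0.35, 0.65] are flagged as
poorly covered. The masker-type threshold averages the two spatial-condition
α values; fitting a single pooled function is a reasonable alternative
reading and can be had by pooling trials before fitting. Digit span scores
the longest list length with ≥ 1 correct trial before the first length where
both trials fail (forward + backward summed by the caller); Stroop
interference is asynchronous minus synchronous response time.

## Synthetic cohorts

The generator emulates the study conditions: three groups (24 young
non-musicians, 23 older musicians, 23 older non-musicians), 750 timepoints
per subject, a bilateral atlas of 888 homotopic pairs (120 per network × 7
networks + 48 unlabeled) with an exact bijection, fixed female counts
12/9/14, and covariates drawn from independent normals truncated to plausible
ranges with the published per-group means and SDs (education ≥ 0, MoCA and
digit span rounded to integer scores, Stroop > 0). Older-musician training
onset/years use the analyzed-sample values (11.17 ± 4.66, 49.84 ± 8.26).

Time series are zero-mean multivariate normal with a latent-factor
covariance: per network, one intra factor per hemisphere (loading √intra_H on
that hemisphere's network vertices), one cross-hemisphere hetero factor
(√hetero_L left / √hetero_R right), one homotopic factor per pair
(√homotopic on both members), one optional whole-brain global factor
(√global_coupling on every vertex), plus noise variance noise_sd².
Cov = WWᵀ + D is
positive semidefinite for any nonnegative weights — the reason for a factor
construction rather than direct block filling — and expected correlations are
closed-form in the loadings (see `expected_correlations`), so recovery tests
have an analytic target.

Planting `intra_L > intra_R` raises within-left correlations and produces a
positive network LI_intra. The cross-hemisphere covariance block of this
model is symmetric (row sums equal column sums within a network), so LI_he
has expectation zero under any single-network plan: heterotopic asymmetry
would require cross-network heterotopic coupling, which the model omits for
tractability. LI_he is therefore exercised as a null measure (centering,
sign flips, validity handling), while effect-recovery claims are made for
LI_intra and alignment.

The global factor plays a structural role beyond realism: LI's denominator
|L + R| sums strengths over a whole hemisphere, and with purely per-network
factors that sum has expectation near zero outside a vertex's own network, so
the ratio becomes heavy-tailed and a single pair can dominate a group-mean
map. A positive FC background — which real cortex shows — keeps the
denominators bounded away from zero and the LI maps well-conditioned.

Default coupling magnitudes are calibration choices (the study does not
publish per-network FC distributions): baseline intra 0.2, hetero 0.1,
homotopic 0.25, global 0.12, noise SD 1.0, giving within-network correlations
≈ 0.26, homotopic correlations ≈ 0.28 and a global background ≈ 0.07. The
young plan carries a right-lateralized
cingulo-opercular network (intra 0.10/0.30) and mildly left-lateralized
language (0.28/0.16) and default-mode (0.26/0.18) networks; the
older-non-musician plan shrinks all asymmetries to 25% of the young ones; the
older-musician plan keeps 90% (preservation). FD traces place a configurable
fraction of frames above the 0.5 mm threshold (defaults 1%/2%/4% per group);
mFD and mean global FC in the cohort table are the realized values from each
subject's generated trace and matrix, not redrawn numbers.

Behavior (SIN/SIS thresholds) is the published group mean plus, when a
linear-Gaussian link is configured, `slope × realized network LI + covariate
effects + N(0, noise_sd)` — giving the planted LI–behavior partial
correlation a closed form for recovery tests. The default slope is 0, so the
default cohort reproduces the published behavioral summaries with no
brain–behavior coupling.

What the generator does *not* emulate: hemodynamic autocorrelation,
non-Gaussian noise, spatial smoothness along a cortical surface, realistic
motion artifacts coupled to the signal, and cross-network FC structure.
Passing tests therefore validate the measurement and inference chain, not
claims about real cohorts.

## Problem sizes and numerical choices

Simulation-based tests and the acceptance script run scaled-down versions of
the study conditions chosen to keep Monte-Carlo error small relative to the
assertions: null calibration uses 200 replicate cohorts (one 40-pair network,
300 timepoints, 24 subjects each) for LI centering, and 2000
exchangeable-null resamples of the pooled subject LIs (24/23/23 splits) for
ANOVA/Jonckheere–Terpstra type-I error; recovery uses three asymmetry levels
× 30 subjects; alignment separation uses a 12-subject template and 100
subjects per plan; psychometric recovery uses 500 binomial replicates at 20
trials/level. The default full-size cohort (1776 vertices × 750 timepoints ×
70 subjects) runs in about a minute and is exercised in the examples.

Other numerics: covariance sampling uses an eigendecomposition with
eigenvalues clipped at 0 (tolerance −1e−8, below which the input is
rejected); FC matrices are symmetrized after `corrcoef` to remove float
asymmetry; text formats write floats as `%.17g` and are parsed with Python's
exact strtod so write→load round-trips are bit-exact; all randomness flows
through explicit integer seeds (package default 20240605) and generated
datasets are byte-identical across reruns.

## Known limitations

* Heterotopic lateralization cannot be planted (see above); the LI_he
  inference path is validated only under the null and by algebraic
  properties.
* The variance-heterogeneity gate (Levene at 0.05) and the pooled-vs-Welch
  choice for classic-F post hocs are conventions; both are configurable.
* Covariates are generated independently, so synthetic partial correlations
  lack the covariate collinearity real cohorts would show.
* The psychometric fit is least squares on proportions, not binomial
  likelihood; at asymptotic SNR levels the variance weighting is mildly
  wrong, which is visible as a small-sample bias well below 0.1 dB in the
  recovery simulations.
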