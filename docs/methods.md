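# Methods

## Data model

The unit of analysis is a long-format record (subject, site, scanner
type, visit, measure, value). Visits are 1-based integers; the analyses
use visit index only, so calendar dates are never modelled. Each subject
belongs to exactly one site and each site to exactly one scanner type
(sites are *nested* in scanner — the design cannot separate a site effect
from its scanner, which is why between-scanner comparisons are reported
with that caveat). Values stay in measure-native units; units are
metadata and are never converted.

Missing-case bookkeeping is roster-based: a `MeasurementTable` carries an
explicit cohort roster (defaulting to every subject appearing anywhere in
the table), and a measure's missing-case count is `len(roster) −
n_complete`. This makes subjects who contribute no record at all for a
measure count as missing, which is how per-measure "missing cases"
columns in multi-site reliability reports are conventionally tallied, and
it ties the ANOVA degrees of freedom directly to the printed counts
(e.g. a 112-subject roster with 48 incomplete cases gives a time-effect
error df of (3−1)(64−2) = 124).

## Reliability

For a complete n×k matrix the two-way decomposition uses row (subject),
column (visit) and residual mean squares; sums of squares are additive to
1e−9 relative tolerance by construction. The absolute-agreement
intraclass correlations are the standard two-way random-effects forms

    ICC(2,1) = (MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE))
    ICC(2,k) = (MSR − MSE) / (MSR + (MSC − MSE)/n)

The average-measure form equals the Spearman–Brown step-up of the single
form at k; the test suite asserts this identity to 1e−12 and checks both
estimators against pingouin's implementation to 1e−10. Negative
estimates are reported as computed (with a flag), never clipped —
near-zero reliability should be visible, not masked. Confidence
intervals are not implemented; the reporting convention is 2-dp point
estimates with a stability cutpoint of ICC(2,k) ≥ 0.80 (boundary
inclusive). A constant matrix has zero total variance and raises a
degenerate-input error rather than returning an arbitrary value.

## Mixed time × scanner ANOVA

The split-plot model has one within factor (visit) and one between
factor (scanner type), with unbalanced group sizes allowed:

* the between effect is a one-way ANOVA on per-subject visit means
  (scaled by k; all SS types coincide for a single between factor);
* within effects are *averaged univariate* tests on orthonormal contrast
  scores over visits. With unbalanced groups the time effect tests the
  unweighted mean of group means (the Type-III hypothesis), and the
  interaction the usual group contrasts, both against the pooled contrast
  residual with df = (k−1)(N−g).

This matches the repeated-measures GLM convention of the major
statistical packages; the suite pins the unbalanced behaviour to a frozen
oracle computed with R `car::Anova(type = 3)` under sum-to-zero
contrasts (agreement to the printed precision of the R output) and the
balanced behaviour to a from-scratch cell-means decomposition and to
pingouin, both at 1e−9.

Sphericity: Mauchly's W is computed from the pooled within-group
covariance of the contrast scores (df = N − g), with the first-order
chi-square approximation χ² = −(N−g − (2d²+d+2)/(6d))·ln W,
d = k−1. Greenhouse–Geisser ε is (Σλ)²/((k−1)Σλ²) over that
covariance's eigenvalues, clipped to [1/(k−1), 1]. The correction is
*gated*: within-subject dfs are multiplied by ε and p-values recomputed
only when Mauchly's p < 0.05 (the gate threshold is a convention choice;
no universal standard exists). For k = 2 sphericity holds trivially
(W = 1, ε = 1).

Multiplicity: Bonferroni is applied per effect as an adjusted α = 0.05/c
(not adjusted p-values), with the family size c given by the measure
family (defaults: connectivity c = 16, thickness and volume c = 14). A
significant time main effect is flagged as superseded when the
time × scanner interaction is itself significant at the family-adjusted
α. Site comparisons within a scanner use Fisher's LSD collapsed across
visits: with exactly two sites per scanner this is an unprotected
pooled-variance two-sample t-test on across-visit subject means
(pooled, not Welch, per LSD convention).

Degenerate inputs: a group with fewer than two subjects raises; zero
within-subject error variance yields an infinite-F flag with p = 0 (or a
NaN F when the effect SS is also zero) rather than a silent exception.

## Synthetic cohorts

The generator emulates a 4-site, 2-scanner, 3-annual-visit design of 112
healthy volunteers (28 Leiden, 29 London, 29 Paris, 26 Vancouver; Philips
at Leiden/Vancouver, Siemens at London/Paris). Per measure,

    Y_ij = μ + scanner_offset·[Siemens] + site_offset + slope·(j−1)
         + interaction_slope·(j−1)·[Siemens] + b_i + t_j + e_ij

with b_i ~ N(0, σ_p²) a stable subject effect, t_j ~ N(0, σ_t²) a visit
effect **shared across subjects** (the two-way random-effects sampling
assumption: timepoints, like people, are draws from a population), and
e_ij ~ N(0, σ_e²) residual noise. Within a scanner group the implied
population ICC(2,1) is σ_p²/(σ_p²+σ_t²+σ_e²) and ICC(2,k) its
Spearman–Brown step-up; group-constant offsets leave within-group ICCs
untouched while inducing a scanner main effect downstream. Note two
deliberate biases: the fixed time slope inflates MSC (not MSE), and
pooling scanner groups with a nonzero offset inflates between-subject
variance above the within-group target — recovery tests therefore use
offset-free configurations.

Missingness is missing-completely-at-random at subject×visit granularity
(a dropped visit removes every measure at that visit), with default drop
rates of 7% at visit 2 and 13% at visit 3, matching the emulated cohort's
93%/87% retention. Real attrition is rarely MCAR; nothing here models
informative dropout.

Default measure presets carry the magnitudes typical of each family —
axial diffusivity μ = 1.18e−3 mm²/s (total SD 4.1e−5), cortical
thickness μ = 2.35 mm (SD 0.18), cortical volume μ = 1860 mm³ (SD 264) —
with Siemens offsets (+3e−5, +0.19 mm, +200 mm³), a −27.5 mm³/visit
volume trend (≈3% over two follow-ups) and a −0.005 mm/visit thickness
trend. The subject/time/error variance split behind each preset is
**synthetic**: real reports print only total dispersions, so the splits
were chosen once to land the population ICC(2,1) at 0.87 / 0.86 / 0.92
(diffusivity / thickness / volume) with 1% of variance assigned to the
shared visit effect. Passing recovery tests therefore demonstrate that
the estimators invert this generative model, not that real MRI measures
obey it — real data add QC-driven exclusions, non-Gaussian tails,
site-by-time drifts and informative dropout that the generator does not
emulate.

All randomness flows through `numpy.random.default_rng(seed)`; identical
config and seed give bit-identical tables, and the missingness stream is
derived from a separate seed so record counts do not depend on how many
measures are simulated.

## Power

Attenuation is d = δ·√r with r the single-occasion reliability
(ICC(2,1) approximates the true-score variance ratio var(T)/var(X)).
Power for the two-sided two-sample equal-n t-test is exact noncentral-t
(df = 2n−2, ncp = d·√(n/2)); the required n is found by doubling +
bisection on the monotone power curve and is minimal by construction
(power(n) ≥ target, power(n−1) < target). The exact engine matters at
the margins: at d = 0.75·√0.68 it requires 43 per group where the normal
approximation gives 42. Sample sizes are always ceilinged, never
rounded. statsmodels' independent power engine is used as a test oracle,
never as the implementation.

## Problem sizes in the test and acceptance runs

Simulation-backed checks use sizes chosen to make Monte-Carlo error
comfortably smaller than the asserted tolerances on a single CPU:
parameter recovery uses 200 replicates of n = 100 cohorts per reliability
level (±0.02 bands vs. Monte-Carlo SE ≈ 0.002–0.007); Mauchly-p
uniformity uses 500 null datasets of n = 200 (KS test at α = 0.01);
type-I calibrations use 1000 (LSD) and 500 (scanner effect) null
replicates judged against 99% binomial bands around 0.05. All stochastic
tests are seeded and deterministic.

## Known limitations

* No ICC confidence intervals, no ICC(1,·)/ICC(3,·) variants, no REML
  mixed-effects estimation.
* No Huynh–Feldt correction and no post-hoc pairwise time tests.
* No covariate adjustment (age, sex, intracranial volume).
* Exactly two sites per scanner are supported for LSD comparisons; the
  between factor in the mixed model is scanner type, not site.
* Power planning covers the two-sided, two-sample, equal-allocation
  design only.
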