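# Methods

This note documents the models, conventions and parameter choices behind
`netswitch`, in the order the pipeline runs, together with what the
synthetic-data experiments can and cannot show about real data.

## Windowing and connectivity transforms

Windows are rectangular (no taper), half-open `[start, start + width)`
volume intervals at stride `step`; a run of V volumes yields
`floor((V − width)/step) + 1` windows, so the default 300-volume run with
width 27 and step 1 yields 274 windows and 273 window transitions.

Static FC applies, in order: Pearson correlation over the whole series,
Fisher r-to-z (`arctanh`) with |r| clipped to 1 − 1e−7 so saturated
correlations stay finite, absolute value, and division by the off-diagonal
maximum.  The resulting matrix has off-diagonal entries in [0, 1] with
maximum exactly 1; the diagonal is excluded from every summary.  Note the
order matters: max-normalising a correlation matrix *before* r-to-z would
send the maximal element to arctanh(1) = ∞, so the bounded order
(z → abs → max-normalise) is the default; each `FCMatrix` records its chain
in `transform_log`.

Windowed FC applies the same chain **without** max-normalisation.
Allegiance assignment takes an argmax of mean connectivity, which is
invariant to a global positive rescaling, so the omission is consequence-
free downstream while keeping per-window matrices comparable across
windows.

Open choice, flagged: whether a max-normalisation of this kind should
divide by the maximum of |r| or of |z| changes values slightly; the
implementation divides the |z| matrix by its off-diagonal maximum and the
order is configurable only by composing the primitives directly.

## Allegiance assignment

Each region carries a fixed RSN label (7 cortical networks + deep gray
matter, K = 8).  In each window, a region's allegiance is the RSN whose
members (excluding the region itself — self-connectivity would trivially
favour the home network) have the largest mean windowed FC to it.  Exact
ties keep the previous window's label when it is among the tied maxima and
otherwise take the lowest label index; this avoids spurious switch counts
from ties and is fully deterministic.  An RSN needs at least 2 members for
its own members to be assignable.

## Reconfiguration statistics

Over the W − 1 transitions of the allegiance matrix, per region:

- **flexibility** = switches / (W − 1);
- **promiscuity** = distinct labels visited / K (denominator K = 8 by
  default, configurable);
- a switch is **cohesive** iff at least one other region switches at the
  same transition to the same destination label (source labels are
  irrelevant), else **disjoint**; cohesion and disjointedness are the
  corresponding counts / (W − 1).

Under this reading every switch is exactly one of cohesive/disjoint, so
flexibility = cohesion + disjointedness holds identically — consistent
with reported global values where cohesion and disjointedness add up to
flexibility.  Circuit values are unweighted means over member regions;
"global" is the unweighted mean over all retained regions (not just
circuit members).

## Circuit delineation

Densities are normalised by their maximum (so max = 1), restricted to the
QC-retained regions, sorted descending, and cut at the elbow: the point of
maximum perpendicular distance from the chord joining the first and last
sorted values (kneedle-style).  The elbow point itself is included when its
value lies nearer the top of the curve than the bottom (a kink ending a
steep high segment) and excluded when it lies nearer the bottom (the first
point after a cliff); this makes both a two-slope curve and a step function
cut exactly at the planted membership.  When the maximum chord distance is
below 2% of the value range (`linearity_threshold = 0.02`) the curve is
declared linear and the top 5% of regions is selected instead, with
ceiling rounding (ceil(0.05 × 224) = 12) and ties broken by region id.
Maps selecting identical member sets are merged under a joint
"/"-separated name.

A caveat found while testing: randomly deleting regions from an exactly
linear ramp (as coverage QC does) bows the remaining curve relative to its
new chord, and a thinned ramp can exceed the 2% linearity threshold.  The
linearity test is therefore meaningful only for densities evaluated on the
region set actually being ranked.

## Quality control and screening

Participants with more than 12 zero-coverage regions are excluded; then
regions with coverage below 30% in more than 10% of the retained
participants are excluded (all three comparisons strict, as printed in the
source conventions).  Participant screening drops anyone with HADS-D ≥ 11
(clinically relevant depression) and healthy controls with FSMC total ≥ 43
(any reported fatigue).  Records with missing screening scores are
excluded and logged rather than raising.  FSMC severity cut-offs are
inclusive: 43/53/63 (total), 22/28/34 (cognitive), 22/27/32 (motor); the
analysis grouping merges mild and moderate.  Percentages in group tables
are rounded half-up to one decimal.

## Statistics

ANCOVA: ordinary least squares of the outcome on intercept, sex (binary
indicator), age, years of education, then group dummies.  The group F uses
sequential (Type I, covariates-first) sums of squares — equivalently the
nested-model RSS comparison of covariates-only vs covariates+group — which
is what "group effect adjusted for covariates" means in a single-formula
fit.  Pairwise contrasts are adjusted-mean differences (covariates held at
their sample means) tested with the full-model residual variance,
uncorrected across the six group pairs; a Tukey-style correction is a
deliberate non-default because per-contrast p values are reported raw in
the source conventions.  Benjamini–Hochberg correction is applied within
outcome families (one family per measure class across circuits); family
membership is configuration (`AnalysisPlan.families`), not code.  The gate:
cohesion/disjointedness are analysed only for units whose BH-adjusted
flexibility p falls below α = 0.05, because the nature of a switch is
informative only where switching frequency differs; gated rows are flagged
`post_hoc`.

## The synthetic cohort generator

The generator's role is to make every pipeline stage testable against
ground truth; it emulates the structure of the study data, not its
physiology.

**Signal model.** Each RSN has an independent unit-variance white-noise
latent signal per volume; a region's series is the latent of its *current*
allegiance plus independent N(0, `noise_sd`) noise, `noise_sd = 0.5` by
default (within-network correlation 0.8 in expectation — a deliberately
clean regime; see limitations).  This is the weakest model under which
within-network correlation exceeds between-network correlation, which is
all the argmax assignment assumes.  No hemodynamic convolution, temporal
autocorrelation, head motion or scanner drift is simulated.

**Switch realisation.** A switch planted at window transition k becomes
real at volume k + width, so window k is the last window fully before the
change and windows ≥ k + width are fully after; the straddling windows in
between have mixed content and are excluded from ground-truth comparisons
(`SwitchSchedule.interior_mask`).

**Excursion scheduling.** Switching is drawn as excursions: a region (or a
cohesive wave of 3 regions with pairwise-distinct home networks) departs to
a shared destination and returns home one window width later, each leg one
switch.  Wave departures are cohesive; solo departures and all returns are
disjoint.  `cohesive_fraction = 0.88` is the probability that an excursion
is a wave, chosen to mimic the reported dominance of coordinated over
independent switching.  Three structural constraints keep every planted
switch recoverable by the fixed-membership argmax: (i) a region's
successive switches are ≥ width apart; (ii) at most
`max(1, min(size − 3, size // 2))` members of a network may be *disturbed*
(away, or within one window width of a switch) at once, so at least half of
each network is settled at home and the home network always keeps the
largest mean connectivity; (iii) destinations are unique within a
transition, at most `max(1, size // 10)` members of one home network may
visit the same destination simultaneously, and networks with fewer than 4
regions are never destinations — so no foreign network accumulates enough
same-latent signal to overtake a region's true network.  A deficit
scheduler launches excursions so the cumulative switch count tracks
`rate × R × t`; when the caps bind (high rates, small parcellations) the
realised rate falls below nominal, which is why recovery is always judged
against the realised schedule stored in the cohort's `truth`.

**Defaults as study conditions.** Group sizes 60/87/77/53 (HC /
non-fatigued / mild-moderate / severe), 224 regions (210 cortical + 14
deep-gray), 300 volumes, width 27.  Planted switch rates per region per
transition: 0.008 / 0.010 / 0.015 / 0.023, i.e. a severe − HC difference of
0.015 — the order of magnitude of the reported group differences; the
absolute level is constrained to be well below 1/width so that planted
epochs are long enough to be recoverable (reported flexibilities around
0.2 arise from estimator dynamics, not from 0.2 planted events per
transition; see next paragraph).  Covariate distributions (age, sex,
education per group) and FSMC bands follow the reference sample table;
FSMC cognitive/motor are derived as halves of the total since the pipeline
consumes totals per scheme only.  Coverage defaults to 1.0; QC fixtures
set it explicitly.

**What recovery does and does not show.** Because windows overlap, a
single planted switch smears over `width` windows; the *raw* flexibility
estimator counts extra label changes inside those straddle zones (chatter)
and overshoots the planted rate by roughly 1.5× at the default noise.  The
boundary-corrected estimator in `netswitch.evaluation` counts label
changes on the interior-window subsequence per region, which is exact on
noiseless data and recovers the realised planted rate within Monte-Carlo
error at study scale (224 regions, 20 subjects, noise 0.5).  Group
*comparisons* use the raw estimator, as a real analysis must — chatter
inflates all groups monotonically, preserving ordering and power.  Under
noise, the recovered switch window of co-moving wave members jitters
independently by ±1 window, desynchronising planted cohesive waves;
cohesive/disjoint *mode* recovery is therefore demonstrated on noiseless
cohorts and on ground-truth label matrices, not under noise — a genuine
fragility of simultaneity-based cohesion with sliding windows.

## Problem sizes used in tests and acceptance

Recovery: 20 subjects × 224 regions × 300 volumes at the severe rate.
Power: 200 replicate two-group cohorts (10 + 10 subjects, 40 regions),
severe-vs-HC contrast at α = 0.05.  Calibration: 1000 null ANCOVA datasets
(4 × 12 subjects).  Decomposition/oracle: 1000 random label matrices up to
10 regions × 12 windows.  These sizes keep the full suite within a few
minutes while leaving the Monte-Carlo bands meaningful.

## Known limitations

- The latent-signal model has no spatial autocorrelation, no hemodynamics,
  and white temporal noise; passing recovery here shows the estimators are
  correct, not that they are robust to realistic BOLD confounds.
- Realised planted rates saturate below nominal when the recoverability
  caps bind; the generator records, and all checks use, the realised
  schedule.
- The elbow detector reproduces planted kinks and cliffs but, like any
  chord-distance rule, is sensitive to region-set thinning near the
  linearity threshold.
- PET/SPECT density maps and real atlases are out of scope; densities
  enter as pre-aggregated per-region numbers.
- Descriptive nonparametric sample statistics (Wilcoxon/Kruskal–Wallis
  tables) are not implemented; the statistical scope is the ANCOVA family
  machinery.
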