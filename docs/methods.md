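# Methods

## The workflow in brief

A single spheroid per U-bottom well is imaged daily in one 896.6 µm ×
896.6 µm bright-field view (4×4 binning, 552×552 px ≈ 1.624 µm/px), with
two optional fluorescence channels: a caspase-3/7 apoptosis reporter and a
lysosomal vital dye.  Per-well morphometrics and fluorescence totals feed
dose–response fits, whose EC50s are dissected against a static
ATP-viability threshold into cytostatic vs cytotoxic drug actions.

## Plate model

Standard 8×12 plates with edge wells (row A, row H, columns 1 and 12)
excluded by default against uneven evaporation, leaving a 6×10 block of 60
usable wells; with six replicate spheroids per condition and a reserved
vehicle control, nine drug concentrations fit on one plate.  Dilution
arithmetic assumes half-volume medium replacement (100 of 200 µL replaced
with a 2× working solution), so the working concentration is twice the
final one and the carried-over solvent fraction is halved; a warning is
raised when the final DMSO/DMF fraction exceeds 0.5%.  Full-volume and
additive modes are available behind a `mode` flag.  The layout order of
conditions within the usable block is user-defined (column-major by
default); no spatial convention is imposed.

## Synthetic image generator

The generator's purpose is ground truth: every rendered frame carries its
exact object mask and true feature record.

* **Size law.** Initial equivalent-sphere volume is `seeded_cells ×
  volume_per_cell` with 12 pL per seeded cell by default; volume grows
  exponentially at `growth_rate` (default 0.10/day).  Over the few-day
  windows analyzed this approximates the near-linear area growth of
  untreated spheroids.  Spheroids wider than 800 µm trigger an
  out-of-field warning (one field of view cannot contain them reliably).
* **Bright field.** Bright background (32000 of the 16-bit range), dark
  3-px rim, mid-gray interior textured with band-limited Gaussian noise.
  Instrument contrast and texture are not measured quantities; these are
  free parameters chosen to exercise a realistic segmentation path without
  modelling optics.
* **Apoptosis channel.** Above a 450 µm equivalent-diameter threshold the
  nutrient-deprived core (everything deeper than a 225 µm viable rim)
  turns positive regardless of treatment — the confounder that motivates
  normalizing apoptosis signal to spheroid area.  Drug-induced signal is
  rendered peripherally (halo) or throughout, with a Hill-scaled
  amplitude.
* **Lysosomal dye.** Signal concentrates in a 75 µm outer shell with
  saturating uptake I(t) = plateau·(1 − e^(−kt)); the default rate
  k = ln(20)/8 h⁻¹ reaches 95% of plateau at 8 h.
* **Drug phenotypes.** Hill functions of concentration drive four response
  modes: growth arrest (growth rate ↓), disruption (boundary roughening;
  above half-occupancy a unilateral off-center bleb), apoptosis (signal ↑,
  viability ↓) and uptake suppression (dye plateau ↓, viability ↓).
  Fragmentation adds satellite objects below the debris filter to
  exercise multi-object handling.
* **ATP endpoint.** Luminescence is proportional to viable volume with
  multiplicative noise (CV 5% by default), plus blank wells and an
  optional plate-format scale factor (flat-bottom remeasurement ≈ 3× the
  U-bottom signal).
* **Determinism.** All randomness flows from explicit seeds through
  `numpy.random.SeedSequence`; identical seeds give bit-identical images.

What the generator does **not** emulate: optical point-spread functions,
z-gradients and 3D structure, well-edge vignetting, debris and dust,
multi-spheroid wells, and focus drift.  Tests passing on these synthetics
therefore demonstrate correctness of the measurement and inference chain
on idealized inputs, not robustness to every instrument artifact.

## Segmentation and morphometry

Bright-field segmentation: Gaussian smoothing (σ = 2 px) → Otsu threshold
(objects darker than background) → morphological closing (disk radius 3)
→ hole filling → connected components → area filter (minimum object area
1000 px² by default; 3000 px² for large fast-growing lines whose debris
runs bigger).  A blank guard requires the Otsu split to separate class
means by at least 6 robust noise SDs (noise estimated from the
median-absolute-deviation of a high-pass residual); uniform or empty
images return an empty mask rather than thresholding read noise.  After
drug-induced disruption the spheroid may split; the default measures the
largest surviving object, and a `union` mode measures all retained objects
as one irregular aggregate.

Features per object: area (pixel count, calibrated to µm²), perimeter,
Shape P2A = P²/(4πA), equivalent circular diameter d = 2√(A/π), sphere
volume (π/6)d³ (in pL; 1 pL = 1000 µm³), and the length-to-width ratio of
the moment-matched ellipse (a convention — the instrument software's LWR
definition is proprietary).

**Perimeter estimator.** P2A is only interpretable if the estimator is
calibrated so a rasterized disk scores ≈ 1.  Naive boundary tracing
(marching-squares polygon length on the binary mask) overestimates the
perimeter of a digitized disk by ~5.7%, which inflates P2A to ~1.12 and
never converges to 1.  The 4-direction Crofton formula converges for
digitized convex shapes and is used throughout: a disk of radius 100 px
scores ≈ 1.006, the error shrinks monotonically with radius, and
elongation ordering (circle < 2:1 ellipse < 4:1 ellipse, with the 2:1
ellipse at its analytic ≈ 1.19) is preserved.

## Fluorescence quantification

Background is the median intensity outside a 10-px-dilated copy of the
bright-field mask (robust to the small bright footprint); the fluorescence
mask is `background + 6·1.4826·MAD` and totals are accumulated on
background-subtracted, zero-clipped intensities (raw totals are emitted
alongside, since whether published totals were background-subtracted is
generally unstated).  Signal may extend beyond the bright-field mask
(apoptotic halo), so the area fraction can exceed 1.  An optional annular
mode restricts the dye channel to an outer shell of configurable depth.
Normalization to spheroid area (area fraction; intensity per µm²)
separates drug-specific apoptosis from the size-driven core signal.

## Kinetics

* **Assembly time** is the minimum of the Shape P2A series (loose
  aggregates are irregular; compact spheroids round), optionally smoothed
  by a centered 3-point moving average since daily sampling is noisy.
  Ties break toward the earliest time; a minimum at the final timepoint is
  flagged `unassembled`, a tied flat stretch `ambiguous`.
* **Dye uptake** is fitted as a saturating mono-exponential
  I(t) = plateau·(1 − e^(−kt)) by nonlinear least squares; t95 = ln(20)/k.
  The mono-exponential is a pragmatic choice for "rise then plateau"
  kinetics, not a transport model.
* **Volume per seeded cell** is the OLS slope of estimated sphere volume
  on seeded cell number (statsmodels, with confidence interval); at least
  two distinct seeding densities are required.

## Dose–response models

Fits run on log10 concentration; the vehicle (0) anchors normalization
(every replicate divided by the vehicle mean) but is excluded from the
fit.  Both mean functions run between a zero-dose asymptote `left` and a
saturating asymptote `right`:

* **Monophasic 4PL**: y = left + (right − left)/(1 + (EC50/c)^h).
* **Biphasic double-Hill mixture**: shared asymptotes, the span split by a
  mixing fraction f ∈ (0,1) between two Hill terms with ordered EC50s
  (enforced by parameterizing the second as an offset ≥ 0 in log10).
  Sharing the asymptotes stabilizes 8–9-point fits at plate-scale
  replication.

Numerics: `scipy.optimize.least_squares` (trust-region reflective) with
bounded parameters (hill ∈ [0.2, 6]) and seeded multi-start (default 8
starts: one heuristic start from the data plus random log-EC50/hill
draws).  Covariance from the Gauss–Newton approximation gives Wald CIs on
log10 EC50.  An EC50 outside the tested range is reported censored
(">top" / "<bottom"), stored as the boundary value with a flag.  A fitted
response span across the tested range smaller than twice the residual RMSE
flags `no_effect` (flat curve) and censors the EC50 above the range.

**Model choice** uses AICc, ties resolved toward the monophasic model; a
biphasic fit whose phases are separated by less than 0.5 log10 units falls
back to monophasic (not identifiable at this replication).  Under
simulated monophasic truth (EC50 100, h = 1, span 0.75, 10% noise) the
selector keeps the monophasic model in ~95 of 100 curves; under a clearly
expressed biphasic truth (EC50s 20/200, h = 3 per phase, span 0.8, 5%
noise) it picks the biphasic model in ~99 of 100.  With shallow
(h ≤ 1) phases separated by one log unit, a free-slope 4PL fits the
compound curve almost as well and AICc correctly prefers it — biphasicity
must be expressed in the data to be selected.

Per-concentration significance versus vehicle uses Welch's t-test (the
rank-based alternative is available), starred at 0.05/0.01/0.001 without
multiplicity correction by default, matching the per-concentration stars
convention; a Holm adjustment is provided.

**Recovery benchmark.** The growth-arrest scenario simulates biphasic Area
curves with EC50s 18/600 nM over nine log-spaced concentrations spanning
1–1000 nM, six replicates and additive noise of SD 0.10 (control scale),
with per-phase Hill slope 2 so the inter-phase quiescent plateau
(flat response between roughly 25 and 100 nM) is actually present in the
simulated curves, as it is in measured ones; shallower slopes would merge
the phases into a single quasi-monophasic curve with no plateau.  Over 200
Monte-Carlo repeats the median recovered lower EC50 is ~17 nM
(median |log10 error| ≈ 0.09).

## ATP endpoint and static threshold

Raw RLU values are blank-subtracted (mean of blank wells; negatives
clipped to zero with a logged count) and divided by the vehicle mean;
processing is invariant to overall gain, so U-bottom and flat-bottom
measurements of the same lysates give matching normalized curves.  The
flat/U scale factor is estimated as the median of per-well ratios.

The **static threshold** is the highest tested concentration c such that
no concentration ≤ c differs significantly from vehicle (Welch, α = 0.05,
Holm-adjusted across the tested concentrations — "no change observed" is a
statement about the whole series, and uncorrected 9-way testing would
declare a change somewhere on almost every flat curve).  All
concentrations significant → censored below the lowest; none → censored
above the highest.  An equivalence-band alternative (|normalized mean − 1|
< 10%) is available behind a flag.  Thresholds are always recomputed from
data; published threshold lines are drawn, not printed, and are never used
as fixtures.

Classification: an EC50 is cytostatic iff decidably below the threshold;
a censored ">X" bound is cytotoxic when X is already at/above the
threshold and indeterminate otherwise.  Profile classes over decidable
assignments: `purely_cytotoxic` (all above), `mostly_cytostatic` (≥ 80%
below; the cutoff is a configurable convention approximating the verbal
grouping), else `transition`.

## Problem sizes

The shipped benchmarks use desk-scale sizes chosen to characterize the
estimators well: 5 seeding densities × 4 replicate wells for the
volume-slope round trip (20 rendered and segmented 552×552 frames), 200
Monte-Carlo curves for EC50 recovery, and 100-curve selection studies.
Integration tests run reduced plates (two replicates, two timepoints) —
layout, replication and noise settings are configuration, not code.

## Known limitations

* Segmentation is tuned for one dark object on a bright background; it is
  not a general bright-field cell segmenter, and strong vignetting or
  debris above the area filter would be measured as object.
* The biphasic fit assumes monotone responses sharing one span; genuinely
  non-monotone curves (e.g. transient apoptosis peaks) will be summarized
  by whichever phases approximate them.
* Censored EC50s carry no information beyond their bound; profile classes
  treat them conservatively (indeterminate when undecidable).
* The uptake and growth laws are phenomenological; no diffusion–reaction
  transport or 3D reconstruction is attempted.
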