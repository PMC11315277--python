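# Methods

This note records the model assumptions, parameter choices and numerical
conventions behind `kinectqa`, and what the synthetic validation does and
does not demonstrate about real recordings.

## Setting and data model

The package targets static-scene precision assessment of a time-of-flight
depth camera (nominally Azure Kinect DK, NFOV unbinned, 640×576 at
30 fps) and its markerless body tracking (32 named joints, positions in
mm, camera space: x right, y down, z forward).  Two kinds of input are
handled:

* **Body-tracking JSON** in the dialect of the SDK's `offline_processor`
  sample: a top-level `frames` list, each frame holding `bodies`, each
  body a `joint_positions` list of `[x, y, z]` mm triples.  A top-level
  `joint_names` list is optional; without it the SDK's 32-joint index
  order is assumed, and the joint count must then be exactly 32.  Frames
  with no body are recorded as gaps and excluded from all statistics;
  with several bodies, body 0 is used and a warning logged (the intended
  scene holds one subject).  All indices are 0-based internally;
  "cut the first 60 frames" means dropping indices 0–59.
* **Depth stacks** as ordered 16-bit grayscale PNG files plus a JSON
  manifest (`width`, `height`, `fps`, `invalid_sentinel`, file list).
  PNG is lossless and bit-exact; on read, the sentinel is normalized to
  0.  Video-container decoding is out of scope.

## Depth random error

For pixels p in a rectangular region of interest and analyzed frames t,

    re[p] = sqrt( Σ_t∈valid(p) (d[p,t] − mean_valid(p))² / n_valid(p) ).

Conventions and their rationale:

* **Invalid samples** are excluded from both the mean and the sum.  The
  default divisor is `n_valid(p)` so that a pixel with one valid sample
  has re = 0 and a pixel with none is undefined (NaN, excluded from
  summaries); this keeps re an honest per-pixel dispersion even where
  dropouts are common (object boundaries).  A strict mode
  (`denominator="analyzed"`) divides by the fixed analyzed-frame count
  instead; it deflates re in proportion to the dropout rate and exists
  because some published pipelines normalize that way.
* **Population variance** (÷n, not ÷(n−1)).
* **Summaries** (min, max, median, interquartile range) are order
  statistics over defined pixels, quartiles by linear interpolation
  (`numpy.quantile(..., method="linear")`).  The same convention is used
  everywhere quartiles appear.
* ROI placement is user input (the canonical region sizes for a standing
  subject are 57×57 for the torso, 15×15 for a knee, 25×25 for an ankle
  with surrounding area); `largest_square_roi` automates the
  maximize-a-square-on-the-object procedure given an object mask.

## Joint jitter: mean distance error

For joint j with trajectory x[j,t], the centroid c[j,t] is the
coordinate-wise mean over frames [t−N, t+N]; the per-frame distance is
se[j,t] = ‖x[j,t] − c[j,t]‖ and MDE[j] is the mean of se over analyzed
frames.  Choices:

* **N = 30** by default, coupled to the frame rate (one-second half
  window), overridable.
* **Clipped end windows are renormalized** by their actual size.  The
  1/(2N+1) variant (`end_mode="full"`) is provided for comparison only:
  it shrinks end-of-sequence centroids toward the coordinate origin,
  which is clearly undesirable for positions ~2 m from the camera.
* **Root, not squared, distances** are canonical (mm units; the mean of
  the Euclidean distances).  `squared=True` gives the squared-error
  variant of both the distance-to-centroid and inter-joint distances.
* **Closed form** used for validation: for i.i.d. isotropic Gaussian
  jitter with per-axis SD σ, the residual x[j,t] − c[j,t] on interior
  frames is Gaussian with per-axis SD σ·√(2N/(2N+1)), so
  E[MDE] = σ·√(8/π)·√(2N/(2N+1)) ≈ 1.5827 σ at N = 30.  The acceptance
  suite asserts MDE/σ ∈ [1.57, 1.62] at ~9,000 frames.
* The 60-frame cut removes the tracker's converging start-up transient;
  the cut is applied before any metric.

The 18-joint analysis selection (pelvis/spine/neck, shoulders, elbows,
wrists, hips, knees, ankles, feet) reflects the joints relevant for gait
and posture; hand, thumb and face joints are excluded from summaries by
default but fully supported.

## Statistical comparison protocol

* **Normality screen**: Lilliefors-corrected Kolmogorov–Smirnov per
  group (mean and SD estimated from the data); the naive fixed-parameter
  KS variant is exposed because common GUI packages offer both.  Pixel
  random errors are strongly non-normal, so the protocol proceeds
  nonparametrically.
* **Independent conditions**: tie-corrected Kruskal–Wallis; if
  significant at α = 0.05, Dunn's pairwise z-tests on mean ranks with
  tie-corrected pooled variance, Bonferroni-multiplied by the number of
  pairs.
* **Repeated recordings**: tie-corrected Friedman over the
  pixels × recordings matrix (rows with missing values dropped and
  counted); if significant, pairwise z-tests on mean within-row ranks
  with SE √(k(k+1)/(6n)), Bonferroni-corrected.  These are the
  procedures large statistics GUIs document for their "pairwise
  comparison with Bonferroni correction"; exact replication of any
  particular implementation's p-values is not promised.
* **Caveat**: pixels are treated as independent observations.  Spatial
  autocorrelation between neighbouring pixels makes these tests
  anticonservative for depth data; that is a property of the protocol
  being reproduced, stated rather than corrected.
* Calibration: both omnibus tests hold their 5% size within ±1.5
  percentage points over 2,000 null replications (4 groups × 50, and
  30 rows × 4 columns), and the Kruskal–Wallis chi-square p agrees with
  an exact enumeration of all 34,650 assignments of a 3×4 fixture to
  within 0.05 (measured approximation gap ≈ 0.03 at that size).

## Synthetic-data generator

The generator defines the conditions under which the pipeline is
validated.

**Depth**: value = round(base[p] + ε), ε ~ N(0, σ[p]²), independent per
pixel and frame; with probability q[p] the pixel is invalid instead;
negative simulated depths are clamped to invalid and counted.  Rounding
to integer mm adds quantization variance ≈ 1/12 mm², so the marginal SD
of simulated samples is √(σ² + 1/12) — at σ = 1.2 mm a 2.9% inflation
that the tests account for explicitly.  The ROI scene helper emulates a
flat object patch with an optional boundary band (background ~0.5 m
behind, inflated σ, elevated dropout probability) reproducing the
empirical pattern that invalid values and high random errors concentrate
at object boundaries; defaults place ~1% of samples invalid in the
ankle-style region.  An optional moving disk of invalid pixels emulates
the dust-particle "black spot" artifact that crosses the image over a
few hundred frames.

**Tracking**: position[j,t] = true[j] + transient(t) + peak(j,t) + η,
η ~ N(0, σ_j² I₃).  The transient is an exponential decay of a fixed
offset vector reaching < 1% of its initial size within its length
(default 60 frames — the converging start-up the 60-frame cut removes);
the peak adds a constant offset to one joint for a bounded frame window
(the black-spot aftermath on a nearby joint).  Noise is drawn before
artifacts are applied, so toggling an artifact never changes another
joint's noise stream.  Jitter is independent across frames by default —
the summary statistics being reproduced constrain only marginal SDs — and
an optional AR(1) coefficient (marginal-SD-preserving) is available
because real tracking jitter is autocorrelated; it defaults to off.

**Default magnitudes** are the study conditions for a static mannequin
~1.9 m in front of the camera: 9,002-frame recordings at 30 fps;
per-joint jitter σ_j obtained by inverting the chi-3 relation from the
baseline per-joint MDE values (pelvis 0.62 mm … right foot 3.31 mm →
σ from 0.39 to 2.09 mm); per-condition jitter scale factors
{1.00, 1.07, 1.19, 1.34} for ambient/infrared light combinations
(infrared on inflates jitter); depth noise σ of 1.20/1.44/2.5 mm for the
torso/knee/ankle-scale regions.  The Gaussian form of the jitter is an
assumption — only dispersions, not distributions, are constrained by the
emulated measurements.

**What passing tests show**: that the metrics, their invariances
(translation/rotation, end-window handling, invalid exclusion) and the
statistical protocol are implemented correctly, and that injected
noise-level differences of 15% are reliably recovered in the MDE
ordering at study-scale frame counts.  They do not show anything about
tracker accuracy against ground truth, about non-Gaussian or spatially
structured sensor noise, or about moving subjects.

## Problem sizes

Tests and the acceptance script simulate full-length (9,002-frame)
sequences for the tracking metrics but ROI-sized depth patches (57×57,
15×15, 25×25) rather than full 640×576 frames; the depth metrics are
per-pixel and independent of the surrounding frame, so patch simulations
are statistically equivalent for every quantity reported.  The
repeated-recording agreement bound used in validation is the
delta-method SE of a per-joint MDE, SE ≈ σ·√(3 − 8/π)·√(2N/(2N+1))/√n
(≈ 0.0046 mm at the median jitter level and n = 8,942), with a ×6 margin
for the max–min spread of five medians-of-18; a Monte-Carlo check during
development put the observed spread at about half that bound.

## Known limitations

* The JSON reader accepts only the documented dialect (plus the
  permissive explicit-`joint_names` mode); other serializations of SDK
  output need conversion.
* Quaternion joint orientations are not carried through the containers.
* No effect sizes, mixed models, or spatial-autocorrelation-aware
  inference; two-group comparisons are out of scope (the protocol is
  defined for ≥ 3 conditions).
* Gait-event detection and dynamic step-width analysis are out of scope;
  the inter-joint distance series is the static building block only.
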