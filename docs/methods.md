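# Methods

`vmatqa` implements an unsupervised error-detection workflow for
patient-specific VMAT QA and benchmarks it against a supervised CNN and
gamma-index analysis.  Because no clinical dose measurements ship with the
package, a synthetic simulator stands in for the treatment planning system,
the linac and the two-plane diode phantom.  This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## The detection problem

A QA measurement compares the dose a plan *should* deliver (calculated) with
the dose it *does* deliver (measured on a cylindrical phantom with two
inclined diode planes).  Both distributions are normalized by the measured
isocenter dose and differenced at the diode positions; the difference is
rasterized onto a 5 mm in-plane lattice, cropped to the central
13 × 13 cm (27 × 27 nodes) and clipped to ±0.2.  These DD maps are the unit
of analysis.  For an error-free delivery the map is almost plain — about 1 %
residual structure from measurement noise and calculation limits — while
delivery errors (MLC offsets, gantry rotation, output changes, setup shifts)
each leave a characteristic spatial signature.

Three detectors operate on the same test cases (one case = one beam × one
dose condition, two plane maps):

1. **VAE + Mahalanobis distance.**  A variational autoencoder is trained on
   error-free maps only.  Each map is summarized by the 30-dimensional
   encoder mean μ; the training-set μ vectors define a reference Gaussian
   (mean x̄, sample covariance Σ), and a test map's anomaly is
   MD = √((μ−x̄) Σ⁻¹ (μ−x̄)ᵀ).  A case is scored by the mean MD of its two
   planes.  The latent σ is not used for scoring.
2. **Supervised CNN.**  A small convolutional classifier trained on labelled
   error-free and error maps of all nine simulated kinds; a case is scored by
   the mean error probability of its planes.
3. **Gamma analysis.**  Global DD/DTA gamma pass rate (3%/2 mm and 2%/1 mm,
   10 % low-dose cutoff, planes pooled); lower pass rate = more anomalous.

Per error type, ROC curves are computed with error-free cases as negatives,
the operating point is the curve point closest to (0, 1), and paired AUC
differences are tested with the DeLong method (the choice of test was open;
a paired nonparametric test on the same cases is the natural default).

## Synthetic data generator

The generator's defaults define the study conditions; they are fixed, not
tuning knobs.

**Detector.**  Two planes through the couch axis, inclined +50° and −40°
from vertical; square diode lattice with 5 mm pitch in the central 6 × 6 cm
and 10 mm pitch outside to ±10 cm (561 diodes per plane, ~1100 total),
clipped to a 110 mm phantom radius.  The exact commercial layout is not
public; only the pitch structure and two-plane geometry matter downstream.

**Plans.**  Full-arc plans with 24 control points, 28 leaf pairs at 5 mm
pitch.  Apertures are ellipses (radius 28–40 mm) with smooth per-leaf
sinusoidal modulation, a drifting center and per-leaf noise; MU weights vary
smoothly over the arc.  The prescription is calibrated per plan so the
error-free isocenter dose is 2 Gy.

**Dose engine.**  An analytic model chosen to preserve the geometric and
scaling structure that each error type perturbs, not to be dosimetrically
accurate: per control point, beam's-eye-view fluence is rasterized from the
leaf tips with partial-cell coverage (so sub-cell leaf moves always change
the fluence), 1.5 % MLC transmission, a 3 mm Gaussian penumbra blur, and
parallel-beam exponential attenuation (0.004 mm⁻¹, an effective 10 MV value)
with depth measured from the cylindrical phantom surface.  Doses accumulate
on a 2.5 mm isocenter-centered 3D grid; planar doses are trilinear samples at
the diode positions.  No buildup region, scatter, divergence, or
couch/collimator modeling.  The model is exactly linear in MU.

**Errors** (defaults: 2 mm MLC, 2° gantry, 3 % output, 1 mm setup):

- *MLC systematic*: both leaf banks shifted +2 mm in the same direction
  (aperture translation + width change on one side) and the dose recomputed —
  the "single direction" of the protocol is ambiguous between translating and
  widening; translation was chosen.
- *MLC random*: independent Gaussian (σ = 2 mm) offsets per leaf per control
  point, dose recomputed.  Redrawing per control point emulates delivery
  jitter over the arc; freezing one draw would act like a second systematic
  error and make this condition much easier to detect than intended.
- *Gantry ±2°*: the error-free dose grid is rotated about the couch axis and
  resampled (a dose edit, mirroring how such errors are produced without
  re-planning); MLC errors, in contrast, go through the dose engine again.
- *Output ±3 %*: uniform rescaling.
- *Setup 1 mm (lateral / longitudinal / vertical)*: the grid is resampled
  after translation.

Rotation and translation resampling use an exact y-separable bilinear kernel
(the rotation axis coincides with a grid axis), verified against
`scipy.ndimage` in the tests.  For train/validation beams, whose 3D grids are
never needed downstream, the pipeline evaluates the same analytic model
directly at (transformed) diode positions — identical model, one less
interpolation.

**Measurement noise.**  measured = true × daily_factor × (1 + correlated
field + iid noise), then corrected by an imperfectly measured daily output
factor: iid per-diode sd 0.7 %, Gaussian-random-field component sd 0.5 % with
20 mm correlation length (independent per plane), daily factor sd 0.3 %,
calibration error sd 0.05 %.  These amplitudes were chosen so error-free DD
maps show ~1 % residual structure.  The simulator reproduces *random*
error components only; it does not emulate systematic TPS beam-model bias,
detector miscalibration patterns, angular response, or intra-fraction drift.
Passing tests therefore demonstrate the machinery and the relative behavior
of the methods under controlled conditions, not clinical performance.

**Reproducibility.**  All randomness derives from one root seed through
`numpy.random.SeedSequence` children per beam and stream; datasets regenerate
bit-identically and every artifact records the configuration hash.

## VAE details

Encoder: three 3 × 3 stride-2 convolution blocks (16/32/64 filters, batch
norm, ReLU), then dense heads for μ and log-variance (latent dimension 30).
Decoder mirrors it with transposed convolutions (27→14→7→4→7→14→27) and a
linear output, since DD values live in [−0.2, 0.2].  Training: 200 epochs
(50 in the scaled-down studies), minibatch 64, Adam at 1e-3, standard-normal
reparameterization noise, no early stopping (validation loss is logged only).

The training objective is the Gaussian-likelihood ELBO
`SSE/(2 σ_obs²) + kl_weight · KL` with observation scale σ_obs = 0.01 — the
residual level of error-free maps — and kl_weight 1.  With a pixel-mean MSE
and unit KL weight the reconstruction term would be ~1e-4 and the posterior
would collapse to the prior, leaving μ uninformative; anchoring the
reconstruction term to the physical noise scale is the principled fix and was
fixed before any end-to-end evaluation.  `kl_loss` implements the standard
closed form −½ Σ (1 + log v − μ² − v) with v the latent variance (the
commonly printed variant writes the last term as σ² with σ the standard
deviation — the same function).  The reparameterization noise ε is standard
normal; a literal "between 0 and 1" uniform reading of the usual formula
would not match the cited estimator and is not used.

The networks run on an in-repo numpy layer library with manual
backpropagation (`vmatqa.nn`) — the models are small enough (≈1e5
parameters, 27 × 27 inputs) that no external NN framework is required.
Every layer's gradient is checked against central finite differences in the
test suite.  Training is bit-deterministic for a fixed seed.

## Anomaly reference

The reference set is the augmented (800-map) training encodings.  Σ is the
sample covariance (denominator n−1) with a default ridge of
1e-6 · trace(Σ)/30 added before inversion, guarding against ill-conditioned
finite-sample covariances; the ridge is recorded in the model and can be set
to 0 (full-rank data) or larger.  Score ties at the threshold classify as
error-free (gamma mirrors this: a pass rate equal to the threshold classifies
as any-error), so the boundary always favors the "no detection" side of the
anomaly scale.

## Supervised CNN details

Conv blocks 16/32/64 (3 × 3, batch norm, ReLU, 2 × 2 max-pool), dense
256 → 32 → 2 with dropout 0.2/0.5, softmax.  Error-free training maps are
expanded 9-fold to balance the classes: the four flips, the four flips
rescaled alternately by 0.95 and 1.05, and the identity rescaled by 1.05
(rescale factors configurable; the exact augmentation recipe was open).
Training uses cross-entropy, Adam 1e-3, batch 64, and keeps the
best-validation-accuracy checkpoint; epochs default to 200 (15 in the
scaled-down studies — the supervised problem converges quickly at these map
sizes).

## Gamma analysis details

γ(p) = min over in-plane offsets r (lattice step DTA/10, radius 3 × DTA) of
√((Δd(r)/(dd% · D_norm))² + (‖r‖/DTA)²), with the calculated in-plane field
bilinearly interpolated and D_norm = its maximum (global normalization; the
isocenter dose is the configurable alternative).  The low-dose cutoff (10 %)
applies to the measured reference doses; both planes are pooled.  The DTA
search is 2D in-plane — the measured data exist only on the planes.
Against a DTA/50 brute-force search the DTA/10 lattice agrees within 0.02 γ
on smooth fields (tested).

The phantom-position optimization searches 3D translations (±3 mm at 0.5 mm,
then a local 0.1 mm refinement) maximizing the 3%/1 mm pass rate, evaluated
on per-plane slab interpolators of the calculated dose.  Pure translations
within one DTA leave the pass rate at 100 % everywhere, so the pass rate
alone cannot localize the optimum; mean gamma is the secondary objective and
the smallest shift norm the final tie-break.  The returned "corrected"
measurement resamples the measured plane values at the in-plane projection of
the recovered shift; the out-of-plane component is reported but cannot be
corrected from planar samples.  In the simulated pipeline measurements carry
no setup offset, so this step is a preprocessing no-op and is exercised by
its own tests rather than the default pipeline.

## Problem sizes

The full protocol sizes (161 beams split 100/25/36, 200 epochs) are the
package defaults.  The bundled end-to-end studies (acceptance script and
test suite) run a reduced configuration chosen as the smallest study that
still exercises every method at realistic case counts: 98 beams split
50/12/36 — keeping the full 36-beam test arm — with 50 VAE epochs and 15
CNN epochs, repeated over three seeds where a tendency is asserted.
Structural dataset counts are always computed on the full split.

## Known limitations

- The dose engine is a geometric surrogate; absolute dose accuracy, buildup,
  scatter and beam divergence are out of scope, so gamma pass rates are not
  clinically calibrated.
- Error magnitudes are fixed at their protocol values; mixed, sub-millimeter
  or single-leaf errors are not simulated.
- The gantry-rotation signature is intrinsically weak on full arcs (rotation
  preserves radius and the arc smears tangential gradients); its detection
  AUC is correspondingly the lowest of all error types, for every method.
- The two detector planes share one noise model; real diode arrays show
  per-diode calibration structure that the simulator does not reproduce.
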