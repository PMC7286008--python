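# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `protonsct`: a desk-scale implementation of MRI-to-synthetic-CT
(sCT) synthesis with a mutual-information (MI) conditional GAN, followed by a
dosimetric robustness evaluation of the synthesised images for scanned proton
therapy.

## 1. The problem

Proton treatment planning needs CT Hounsfield units (HU) to compute stopping
powers, but tumour delineation is done on MRI.  Synthesising a CT directly
from MRI removes the MRI-to-CT registration step and its systematic ~2 mm
error.  The difficulty is that MRI intensity is not a function of HU: cortical
bone and air are both dark on a T1-weighted image yet sit at opposite ends of
the HU scale.  A synthesis model must therefore learn a spatially informed,
non-monotonic intensity mapping — and because proton range is exquisitely
sensitive to HU errors along the beam path, image-domain accuracy must be
propagated to dose to be meaningful.  The dosimetric question is answered with
a scenario-based robustness protocol: dose is recomputed under sampled setup
and range errors, the most extreme scenarios are discarded, and DVH metrics
are compared between CT and sCT in the nominal and worst retained scenario.

## 2. Paired head phantoms (`protonsct.phantom`)

All components are exercised on procedurally generated paired head phantoms:
a circular head (radius 80 mm) with a cortical skull shell (7 mm), two
sinus-like internal air cavities, soft-tissue interior, and a spherical tumour
(radius 10 mm, jittered across subjects).  Default grid: one 64x64 slice at
3 mm spacing — a single-slice stack, matching the per-slice 2D synthesis
model; multi-slice volumes are supported.

Tissue intensity model (mean +/- SD):

| class        | HU            | MRI (a.u.)  |
|--------------|---------------|-------------|
| air          | -1000 +/- 10  | 30 +/- 10   |
| soft tissue  |    30 +/- 20  | 400 +/- 30  |
| bone         |  1000 +/- 50  | 60 +/- 20   |
| tumor        |    60 +/- 20  | 550 +/- 40  |

The MRI anchors put bone and air both near the dark end: the MRI-to-HU map is
non-monotonic, reproducing the clinically hard bone/air ambiguity.  Each MRI
is additionally perturbed by a random in-plane rigid transform (shift up to
6 mm = 2 voxels per axis, rotation up to 3 degrees) so that training pairs are
*not* aligned; the drawn parameters are recorded in the sample.  What the
phantoms do **not** emulate: MR physics (bias fields, sequence contrast),
anatomical variability beyond tumour jitter, partial-volume effects, CT
artefacts.  Tests passing on phantoms show the algorithms are implemented
correctly and behave as designed under controlled conditions; they do not
certify clinical accuracy on patient data.

## 3. Mutual information loss (`protonsct.mi`)

MI(X,Y) = H(X) + H(Y) - H(X,Y), estimated from a joint intensity histogram
over the normalised range [0,1] and reported in bits.  Two binning modes:

* **hard** (`smoothing_bandwidth=0`): exact cell counting, used as the test
  oracle and for analysis;
* **soft**: each voxel spreads its mass linearly over the two neighbouring
  bins (triangular kernel, bandwidth one bin).  The histogram is then
  piecewise-linear in every voxel intensity, so the gradient of MI (or of the
  joint entropy) with respect to the synthesised image is exact and cheap;
  `mi_loss_and_grad` returns both and is verified against finite differences.

Choices: `epsilon = 1e-10` inside logarithms; default 64 bins module-wide (a
standard choice in registration); **16 bins inside GAN training at 64x64**,
because a slice has only 4096 voxels and a 64x64-cell joint table would hold
~1 count per cell — the bin count must scale with the sample count for the
gradient to be informative.  Two loss modes are provided: `-MI` (default) and
joint entropy `H(a,b)`; maximising MI equals minimising joint entropy only
when the marginals are fixed, so the default is the better-behaved objective.

A caveat on an exact identity: MI(a,a) = H(a) holds for hard binning; under
the soft kernel the joint histogram of an image with itself spreads
off-diagonal, so the smooth loss at b = a is above -H(a) while still being the
minimum over intensity-preserving competitors.

## 4. Synthesis model (`protonsct.gan`, `protonsct.nn`)

**Generator** — a 2D U-Net (default depth 3, base 8 filters, input 64x64):
per encoder level three 3x3 convolutions, each with batch normalisation and
ReLU, then 2x2 max pooling; decoder levels use a 2x2 transposed convolution,
skip concatenation, two 3x3 convolutions with dropout (rate 0.5) on the
first; final 1x1 convolution with sigmoid.  **Discriminator** — six stride-2
3x3 convolutions with filter progression 2, 4, 8, 16, 32, 64 (batch
normalisation from the second on), flattened into five fully connected layers
with light dropout (0.1) and a sigmoid output; the paper-scale 352x352 input
is supported.  All layers are implemented in numpy with explicit backward
passes (`protonsct.nn`) and validated against finite differences; all
randomness flows through seeded generators, so training is bit-reproducible.

**Conditioning.** The discriminator scores the *pair* (MRI, CT candidate) as
two input channels, the standard conditional-GAN design.  This matters: an
unconditional discriminator can only communicate marginal intensity
statistics to the generator, and since the MI term is invariant to any
relabelling of intensities, the class-to-HU assignment would be left to
chance.  A pair discriminator penalises joint MRI/CT combinations that never
occur in real pairs, which breaks that symmetry per pixel.

**Stability at desk scale.** Three measured failure modes shaped the
implementation: (i) plain ReLU in a discriminator whose first layer has only
2 filters frequently dies on smooth generator outputs, making the adversarial
gradient exactly zero — discriminator activations default to LeakyReLU(0.2);
(ii) gradients taken through the clamped sigmoid probabilities underflow or
explode once the discriminator saturates — all adversarial gradients are
taken at the logit level (binary cross-entropy with logits), where they are
bounded; (iii) batch normalisation computed separately on all-real and
all-fake batches cancels exactly the global intensity differences the
discriminator must detect — real and fake slices are scored in one
concatenated batch, and the generator step uses the discriminator in
evaluation mode (running statistics).

**Normalisation.** CT volumes are shifted by +1000 HU (so signed HU become
nonnegative) and divided by their per-image maximum; MRI by its maximum.  The
training-set maximum of the offset CT is stored in the fitted model and used
to restore HU at inference (`HU = sigmoid_output * scale - 1000`), because a
paired CT maximum does not exist in MRI-only deployment.

**Losses and optimisation.**  Discriminator: `-log D(real) - log(1-D(fake))`.
Generator: `mi_weight * MIloss(ct, G(mri)) + adversarial_weight *
(-log D(mri, G(mri)))`, weights 1/1 by default; `adversarial_weight = 0`
gives the documented pure-MI mode.  Adam with the stock rates (generator
2e-4, beta1 0.5; discriminator 5e-5) is kept as the default configuration;
`TrainConfig.phantom_scale()` raises the step sizes (1e-2 / 2e-3) and lowers
the batch to 4 for desk-scale runs, which perform only a few hundred
optimiser steps rather than the tens of thousands of a GPU-scale training —
with Adam's per-parameter step bounded by the learning rate, total parameter
motion must stay commensurate with the optimisation budget.

**Cross-validation protocol.**  Subject-level: a holdout fraction (15%) is
isolated first; the development set is split into k folds with disjoint
validation chunks (counts floor(0.15 n) held out, round(0.70 n) training —
for 77 subjects: 11 held out, per fold 54/12).  The selected model is the
fold with the lowest final validation MI loss.

## 5. Image evaluation (`protonsct.sct_eval`)

MAE in HU over the external body contour: largest connected component of
HU > -400, hole-filled per slice and in 3D so internal air cavities belong to
the body, as in a clinical external contour.  Reported metric uses the
intersection of the CT- and sCT-derived contours (symmetric in the two
images).  Cohort aggregation is mean +/- sample SD; a singleton cohort
reports SD 0 with a warning.

## 6. Analytic proton dose model (`protonsct.dose`)

Deliberately *not* a clinical engine — no Monte-Carlo transport, scatter,
nuclear interactions or oblique beams — but it preserves the HU-to-range
chain that makes proton dose sensitive to sCT errors:

* **HU to RSP**: piecewise-linear calibration through (-1000, 0.001),
  (0, 1.0), (1000, 1.6), (2000, 2.2) — representative of published
  stoichiometric fits; clamped at the ends.
* **WEPL**: running sum of RSP x voxel length along the (axis-aligned) beam.
* **Bragg curve**: rising entrance plateau gated off past the nominal range
  plus a Gaussian peak of width 3 mm at the range; peak-to-entrance ~5, dose
  -> 0 within a few widths beyond the peak.
* **Spots**: dose = weight x Bragg(depth) x lateral Gaussian (sigma 6 mm,
  truncated at 5 sigma).
* **Plans**: two opposed beams (90/270 degrees); spot ranges span the
  target's WEPL extent in 3 mm steps with a 4 mm margin and mild distal
  weighting; lateral spots cover the target cross-section with a 6 mm margin
  at 4 mm spacing; one global weight scale sets mean CTV dose =
  prescription (60 Gy) on the planning image.  On the default phantom this
  yields CTV D95 ~ 91% of prescription.
* **Scenarios**: a setup shift s displaces the patient: image and
  anatomy-fixed ROI masks are translated by -s relative to the fixed beams
  (linear interpolation with air fill for the image, nearest-neighbour for
  masks); range error scales RSP multiplicatively (the standard reading of
  "3% range uncertainty").  Shift components along single-voxel axes are not
  representable on a 2D slice stack and are ignored.

## 7. DVH metrics (`protonsct.dvh`)

Cumulative DVHs on a fixed 0.1 Gy grid; D_X by linear interpolation of the
curve with ties toward the higher dose (conservative for coverage); Dmean as
the arithmetic mask mean.  CT-vs-sCT tables hold |difference| / prescription
x 100 per (organ, metric), with cohort mean +/- SD skipping NA entries
(organ not contoured).

## 8. Robustness evaluation (`protonsct.robust`)

* Worst-case grid: nominal + 6 one-axis shifts (+/-3 mm) x 3 range scalings
  (0, +/-3%) = 21 scenarios.
* Monte-Carlo test: 100 scenarios; per-axis setup shift ~ N(0, 1.2 mm)
  (Van Herk m = Sigma sigma with m = 3 mm, Sigma = 2.5), range error
  ~ N(0, 1.6%) (2.4% recommended error at 1.5 sigma); setup and range errors
  sampled independently.
* Rejection: scenarios ranked by |CTV D95 - nominal CTV D95|; the top 10%
  are discarded (count rounded, ties toward keeping more; the nominal
  scenario is never discarded).  "Discard the 10% most extreme" admits two
  readings, both implemented: outcome-based (the default above) and
  probability-based (`mode="error_magnitude"`: sigma-scaled norm of the
  sampled error vector, which retains the identical scenario subset for a
  CT and an sCT evaluated over the same scenario list).
* DVH-band: pointwise min/max envelopes of the retained DVHs on a common
  dose axis; worst-case metrics read the band borders — minimum over
  scenarios for D95 (coverage), maximum for D5/D2/Dmean (overdose).

`RobustnessEvaluation(plan, image, rois, settings).run()` returns a results
object with nominal and worst-case `MetricTable`s, the band (with a
matplotlib `plot`), the retained scenario list and a text `summary()`.

## 9. Pipeline and reproducibility

`run_pipeline` chains phantoms -> training -> synthesis -> MAE -> planning ->
robustness -> CSV tables.  One global seed fans out through SHA-256-derived
per-stage sub-seeds; a manifest records versions, seeds and timings, and a
rerun with the same configuration reproduces every output byte-for-byte.
Problem sizes used in the shipped configuration: 22 subjects (20 training /
2 held out), 64x64 slices, 30 training epochs, 100 robustness scenarios —
sizes chosen so the full study runs on a laptop-class CPU in minutes.

## 10. Known limitations

* The dose engine is a stand-in; absolute dose values are not clinically
  meaningful, only CT-vs-sCT *differences* under identical transport are.
* Beams are axis-aligned; lateral-posterior beam arrangements are not
  modelled.
* The robustness test collapses systematic and random setup errors into one
  Gaussian per scenario (single-fraction model); fractionation effects are
  out of scope.
* GAN training at desk scale is necessarily short; the shipped configuration
  trades the paper-scale capacity (352x352, tens of hours on GPU) for a
  reproducible minutes-long CPU run on 64x64 phantoms.
* A one-signed HU perturbation (e.g. the whole skull shifted +200 HU) acts
  on this dose model like a systematic range offset.  Sampled range errors
  of the opposite sign partially cancel it, so the worst-retained-scenario
  CT-vs-sCT difference is *not* reliably larger than the nominal difference:
  measured over 10 phantoms x 10 robustness seeds, the worst-case D95
  difference magnitude meets or exceeds the nominal one in only ~55% of
  repeats (~75% with scenario rejection disabled), under either rejection
  rule.  Real synthetic CTs carry spatially heterogeneous errors of both
  signs, for which this cancellation channel is much weaker; conclusions
  about worst-case-versus-nominal behaviour on real data should not be drawn
  from single-signed phantom perturbations.
* Phantom realism limits: see section 2.
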