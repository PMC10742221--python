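# Methods

`skillstate` implements a two-branch analysis of multichannel scalp EEG for
binary expertise classification (expert vs. novice performers of a bimanual
surgical training task), together with a synthetic-data generator that
plants recoverable ground truth so every stage can be validated end to end
without access to human recordings.

## Signal model and synthetic cohorts

The generator emulates the acquisition protocol the package targets:
32-channel EEG at 500 Hz, one recording per subject-trial consisting of a
pre-trigger baseline (default 5 s), a 180 s task marked by a `start`
trigger, and a 120 s rest; 8 experts and 13 novices with three trials each
(63 recordings).

The scalp signal is a piecewise-constant *microstate* sequence: dwell
times are uniform on 50–150 ms (the typical literature range; no value is
prescribed by the protocol itself), and each segment expresses one of K=6
unit-norm, average-referenced prototype topographies scaled by a random
lognormal amplitude, a random polarity, and a slow strictly-positive
envelope at a 10 µV scale.  During the task the prototype is drawn from a
group-specific probability vector (default: 60% weight on the group's own
prototype — a left-posterior map for experts, a right-frontal/left-posterior
dipole for novices, echoing the canonical microstate maps this kind of
study reports); during rest all prototypes are equiprobable, so rest
periods carry no group information.

Background noise is 1/f (power exponent 1) and *spatially correlated*
across the scalp with a squared-exponential covariance over inter-electrode
angle (length-scale 0.5 rad) plus a 5% channel-independent sensor
component.  Spatial correlation matters: a neighbour-agreement bad-channel
detector is only meaningful when genuine channels co-vary, as they do in
real recordings through volume conduction.  SNR is defined on
average-referenced broadband power; the default 0 dB keeps classification
nontrivial but achievable.  Mains interference is a 60 Hz sinusoid with a
shared phase and per-channel amplitude/phase jitter, scaled to half the
noise RMS.  Optional extras exercise specific cleaning stages:
`bad_channel_prob` replaces channels with white noise, and
`burst_prob_per_min` injects 200 µV half-second bursts for the artifact
subspace reconstruction stage.

Two special regimes isolate mechanisms:

* **Confined difference** (`confined_state`): both groups share identical
  occurrence statistics; the two groups express slightly different
  topographic variants (default perturbation 0.2 in map norm) of one state
  only.  This is the regime where conditioning CSP on that microstate's
  samples should beat plain CSP — the group difference is invisible in the
  other ~70% of samples that plain CSP averages over.  The perturbation is
  deliberately weak so plain CSP degrades measurably while the conditioned
  variant does not.
* **Transient signature** (`make_transient_channel_epochs`): both groups
  receive the same oscillatory topography at *equal total energy*; experts
  concentrate it in a random 20% sub-window, novices spread it uniformly.
  Whole-window log-variance features are blind to this by construction
  (the expected projected variance is identical), so any separation must
  come from temporal modelling — the regime motivating temporal attentive
  pooling.  The default amplitude (8× noise RMS) sets the CNN's
  difficulty; the CSP control is at chance at any amplitude.

What the generator does **not** model: biophysical forward solutions from
cortical sources, realistic ocular/muscle artifact morphology, electrode
drift, impedance changes, or inter-subject anatomical variability.
Passing tests on these cohorts therefore demonstrate that the algorithms
recover what they claim to recover under their own assumptions — not
clinical-grade performance on human data.

## Preprocessing

The cleaning chain runs in a fixed order (asserted from the run manifest):
polyphase resampling to 250 Hz → zero-phase FIR high-pass at 1 Hz
(Hamming design, 1 Hz transition, DC tap-sum nulled exactly) → mains
removal → bad-channel detection/interpolation → common average reference →
task-onset epoching → artifact subspace reconstruction → average reference
again → spherical-spline surface Laplacian.

*Mains removal* is sliding-window sinusoid regression: in 4 s
Hann-weighted windows (50% overlap, overlap-add), a sine/cosine pair at
the line frequency and its first harmonic is projected out of every
channel.  Only ~2 degrees of freedom per window and harmonic are removed,
giving ≥20 dB narrowband suppression with <5% broadband power change.

*Bad channels* are flagged by (a) flatline runs ≥5 s, or (b) best
(maximum) 1 s-windowed correlation with a leave-one-out spherical-spline
estimate below 0.45.  The threshold is calibrated to this statistic: on
synthetic cohorts at 0 dB SNR, connected peripheral channels bottom out
near 0.55 while disconnected channels stay below 0.1, so 0.45 splits the
two populations with a wide margin on both sides.  Subjects with ≥5
flagged channels are excluded.  Interpolation and the surface Laplacian
both use Perrin-style spherical splines (order m=4, ridge 1e-5, 50
Legendre terms).  The Laplacian uses the current-source-density sign
convention — a degree-n spherical-harmonic topography maps to +n(n+1)/r²
times itself — with a 9 cm head radius, giving µV/m².

*ASR* is the offline Euclidean calibrate-then-clean form.  Calibration
(≥30 s of rest, by default the final 60 s of the recording) yields the
covariance square root and per-principal-component RMS ceilings
`median + cutoff × 1.4826·MAD` over 0.5 s windows (cutoff 20, the common
default; robust location/scale stand in for the usual truncated-Gaussian
fit, which needs far more calibration data than these cohorts provide).
Processing eigendecomposes each 0.5 s window (50% overlap, raised-cosine
blending), rejects components whose variance exceeds the calibration
ceiling along their direction, and reconstructs the window through the
retained subspace.  An infinite cutoff is exactly the identity.

## Microstate analysis

Global field power (GFP) is the per-sample population SD across channels.
Clustering operates on GFP peak maps: local maxima ≥10 ms apart, with
peaks above `mean + 1 SD` of the peak GFPs rejected as artifacts, and at
most 1000 peaks retained by seeded subsampling.

The modified K-means is polarity-invariant: similarity is the squared
spatial Pearson correlation, each state's prototype is the dominant
eigenvector of its members' outer-product sum, seeding is k-means++ under
the sign-invariant distance `2 − 2|x·a|`, and the best of `n_init` runs by
global explained variance (GEV) is kept.  GEV is
`Σ_t (GFP_t · corr(x_t, a_{L_t}))² / Σ_t GFP_t²`; the model-selection
criterion is the predictive residual variance with the small-sample
correction `((C−1)/(C−1−K))²` (C channels), minimized over K∈2..8.
Backfitting labels every sample by maximum squared correlation; temporal
smoothing is small-segment rejection — runs shorter than 30 ms are
reassigned to the better-correlated neighbouring state, iterated to a
fixed point.  The 30 ms default is our choice; nothing in the protocol
prescribes it.

Group-level prototypes are fitted on the *aggregated* cohort (all
subjects' task epochs concatenated), so both groups are labelled in one
shared state space.

## Regularized CSP + LDA

With class scatter matrices `C1 = Σ X₁ᵀX₁` (experts) and `C2` (novices),
the filters are the eigenvectors of `M1 = (C2+αK)⁻¹C1` and
`M2 = (C1+αK)⁻¹C2`, K the identity — solved as symmetric-definite
generalized eigenproblems, so the eigenvalues are exactly the projected
variance ratios and the filters are guaranteed real (asymmetric input is
rejected).  α defaults to `0.1·trace(C2)/n_channels` (no value is
prescribed; this scales with the data).  Filters are unit-norm with the
largest-magnitude entry positive; features are log-variances of the
projections on the top filter of each problem (one pair by default).
Classification is a linear discriminant (optional shrinkage), evaluated
by stratified 10-fold cross-validation with CSP and LDA re-fit inside
every training fold.

*Microstate conditioning* retains only the samples backfitted to one
state before computing scatters and features.  The workflow default picks
each epoch's **modal** state rather than the literal first sample: at
realistic SNR the first sample occasionally backfits to a spurious
state and then conditions the whole epoch on a few unrepresentative
samples; the modal state reads "the state active at task onset" robustly.
The first-sample rule remains available (`state="auto"`), as does
GFP-weighting of retained samples.

## Tensorization

Recordings cleaned through the average-reference stage are resampled to
120 Hz and cut from 2 s before the trigger through the task into 3 s
windows with a 1 s step (a span of S seconds yields ⌊S−3⌋+1 windows; the
protocol-scale trial gives 180 per trial and 21×3×180 = 11,340 per
cohort).  The montage is flattened by an azimuthal equidistant projection
centred at the vertex — planar radius equal to polar angle, azimuth
preserved — scaled isotropically into a 16×16 grid with a one-cell
margin.  Each time sample's channel vector is interpolated over the grid
by biharmonic (Green's function `r²(log r − 1)`) collocation augmented
with a constant term, which keeps the interpolant exact at the electrode
coordinates *and* reproduces spatially uniform fields exactly; cells
outside the electrodes' convex hull are zero-filled, since the biharmonic
interpolant diverges when extrapolated toward the grid corners.  The
interpolation is a precomputed linear operator, so tensorization is
linear in the signal and fast.

## The 3-D CNN

Input tensors are 16×16×360 (height × width × time).  Three valid
(unpadded) convolutions with kernel/stride (2,2,10)/(2,2,4),
(2,2,2)/(2,2,2), (2,2,3)/(2,2,2) and widths 16→32→64, each followed by
batch normalization and ReLU, give feature shapes 8×8×88×16, 4×4×44×32,
2×2×21×64.  The temporal length is *derived*, not fixed: the stated
kernels and strides on a 360-deep input give 88→44→21 under valid
convolution (90→45→23 under same-padding), and the shape trace is
recorded so it can be asserted.  Temporal attentive pooling (TAP) then
collapses time: the feature is weighted elementwise by a trainable tensor
φ and summed over space (spatial attentive pooling), channels are
averaged to a length-t vector, a dense t→t map plus softmax yields
attention weights that sum to one over time, and the output is the
attention-weighted temporal sum (2×2×1×64).  The attention FC is t→t
because its natural input is the temporal profile of the SAP summary; φ
is initialized to ones (a neutral start that makes SAP an ordinary
spatial sum before training).  The head is dense(256→64) → batch norm →
ReLU → dropout(0.5) → dense(64→2) → softmax.

Training minimizes cross-entropy plus L2 (weight 0.01) on the dense
layers' kernels and biases (including the TAP FC) with Adam at learning
rate 0.001 and batch size 32; weights are Glorot-uniform initialized.
The optimizer and dropout rate are our choices (Adam, 0.5); the
protocol's stated epoch count is 200, but reduced-scale experiments in
the tests and acceptance script use 15–40 epochs on ~300–400 tensors,
which this architecture needs to converge on the planted signatures.
Everything — convolutions (im2col + BLAS matmul forward, kernel-offset
scatter backward), batch norm, TAP, dropout, Adam — is implemented
directly in numpy with hand-written backward passes; every gradient is
validated against central finite differences (in float64, tolerance
1e-4) in the test suite.

The evaluation protocol fixes one holdout split (10% by default), then
repeats: a fresh fold partition of the remaining 90%, one freshly
initialized model per fold, each evaluated on the holdout; per-repeat
results are summarized as mean ± SD (over folds) and max.  Splits are at
the window level by default, matching the protocol the package mirrors —
windows of one subject may land in train and validation, which inflates
absolute numbers relative to a subject-level split; the subject identity
is carried in the dataset annotations so a leakage-safe grouping can be
constructed from them.

Grad-CAM saliency at any conv layer or the TAP output: channel weights
are the global-average gradients of the target-class logit with respect
to the layer's (post-ReLU) feature map; the heatmap is the ReLU of the
weight-summed features, bilinearly upsampled to the 16×16 input grid.
At the TAP layer the 2×2 spatial map corresponds exactly to the four
input quadrants (each cell's receptive field is one 8×8 quadrant), which
is what the planted-quadrant recovery check exploits.

## Numerical choices and degenerate inputs

* Confusion-matrix metrics with zero denominators are defined as 0 and
  flagged, keeping repeated-CV summaries finite.  MCC follows the product
  formula; kappa is `(p_o − p_e)/(1 − p_e)`.
* Eigenvector sign/scale ambiguity is fixed by unit norm and a positive
  largest-magnitude entry everywhere eigenvectors are compared.
* Empty K-means states are re-seeded at the worst-fit map.
* EDF+ is written with a symmetric 16-bit physical range (quantization
  `max|x|/32767`); BrainVision as IEEE float32.  Reading goes through MNE,
  so round-trip tests cross two independent code paths.
* The EDF+ writer pads the final one-second record with zeros; epochs
  should be cut before writing if exact length matters.

## Problem sizes

Tests and the acceptance script run on one CPU at reduced scale: cohorts
use 12 s tasks and 35 s rests (long enough for the 10 s task-onset epoch
and a 30 s ASR calibration tail), CNN experiments use ~400 tensors and
15–40 epochs, and the protocol-scale structural counts (2500-sample
epochs, 180 windows/trial, 11,340 tensors) are measured on one
full-length simulated trial plus the cohort manifest.  These sizes are
the package's own test-design choices; the library itself has no
scale-dependent switches.

## Known limitations

* ASR uses Euclidean statistics and robust thresholds; it is not the
  Riemannian or online variant, and its behaviour on real artifact
  morphologies is untested here.
* The surface Laplacian assumes a spherical head and unit-sphere
  electrode positions.
* The microstate smoothing window, CSP α, dropout rate, optimizer, TAP FC
  dimensionality, and the CNN hidden width are defaults chosen here, not
  protocol constants; all are exposed in configs.
* Window-level splits leak subject identity between train and validation
  by design fidelity; use the subject annotations for deployment-grade
  evaluation.
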