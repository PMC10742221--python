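# skillstate

EEG-based classification of surgical expertise, for researchers studying
psychomotor skill acquisition with portable brain imaging.  Two
complementary branches operate on the same multichannel scalp EEG from a
bimanual laparoscopic training task:

1. **Microstate-conditioned regularized CSP + LDA.**  Scalp topographies
   are summarized by *microstates* — quasi-stable prototype maps fitted
   with a polarity-invariant modified K-means (model order chosen by the
   cross-validation criterion, goodness of fit by global explained
   variance).  With class scatter matrices C₁ (experts) and C₂ (novices),
   regularized common spatial patterns solve

       M₁ = (C₂ + αK)⁻¹C₁,   M₂ = (C₁ + αK)⁻¹C₂,   K = I,

   and the log-variances of the leading filters' projections feed a
   linear discriminant under 10-fold cross-validation.  Conditioning the
   scatter estimation on the samples of the microstate active at task
   onset is what makes the variant "microstate-based".

2. **Topography-preserving 3-D CNN with temporal attentive pooling.**
   Recordings at 120 Hz are flattened by an azimuthal equidistant
   projection onto a 16×16 grid, interpolated by biharmonic splines, and
   cut into 3 s windows: tensors X ∈ ℝ^{16×16×360}.  Three strided 3-D
   convolutions (+ batch norm, ReLU), a learned softmax attention over
   the temporal axis (TAP), and a dense head classify each tensor;
   Grad-CAM localizes the class-discriminative scalp regions.  The whole
   network — including backprop and Adam — is implemented in numpy and
   gradient-checked against finite differences.

Because comparable human recordings are not openly available, the package
ships a first-class synthetic-data generator
(`skillstate.synth`) that emulates the acquisition protocol (32 channels,
500 Hz, 8 experts / 13 novices × 3 trials, 180 s task + 120 s rest,
`start` triggers) with planted group-specific topographies over spatially
correlated 1/f noise — so every stage, and the package's acceptance
checks, run end to end from a seed.  See `docs/methods.md` for the full
model description and its limitations.

## Worked example

```python
import numpy as np
from skillstate import workflows as wf
from skillstate.io import default_montage
from skillstate.preprocess import PreprocessConfig
from skillstate.synth import SimulationSpec, simulate_cohort

montage = default_montage()
spec = SimulationSpec(task_s=12, rest_s=35, pre_trigger_s=3,
                      snr_db=6.0, dominance=1.0, seed=0)
cohort = wf.load_cohort(simulate_cohort(spec))          # 63 recordings
entries, qc = wf.preprocess_cohort(
    cohort, montage, PreprocessConfig(calibration_s=30))
model = wf.fit_cohort_microstates(entries, K=6, n_init=10, seed=0)
report = wf.csp_branch(entries, model, conditioned=True, folds=10, seed=0)
print(len(entries), round(model.gev_total, 3),
      round(report.accuracy, 3), round(report.kappa, 3))
```

prints

```
63 0.576 1.0 1.0
```

— all 63 simulated subject-trials survive QC, the six fitted microstate
prototypes explain 58% of the GFP-weighted variance, and the
microstate-conditioned CSP+LDA branch separates the two groups perfectly
on this high-SNR cohort (kappa 1.0).  At the generator's default 0 dB SNR
with overlapping group weights the same pipeline lands well below that,
which is the point of the controls.

The CNN branch mirrors it at tensor level:

```python
from skillstate.cnn import ESNetConfig, train, gradcam
from skillstate.evaluate import make_splits
from skillstate.synth import make_planted_tensor_dataset

ds = make_planted_tensor_dataset(n_per_class=200, signal_amp=2.0, seed=0)
plan = make_splits(len(ds), holdout=0.2, folds=2, seed=0)
holdout = ds.subset(plan.holdout)
model, curves = train(ds.subset(plan.trainval),
                      ESNetConfig(epochs=30, seed=0), val=holdout)
expert_tensor = holdout.tensors[holdout.y == 1][0]
sal = gradcam(model, expert_tensor, target_class=1, layer="tap")
print(round(curves.val_acc.iloc[-1], 3), max(sal.quadrant_means(),
                                             key=sal.quadrant_means().get))
```

```
1.0 lower-left
```

— the network reaches perfect hold-out accuracy on the planted-signature
dataset and Grad-CAM at the TAP layer points at the quadrant where the
signature was planted.

## Command line

Each stage is a subcommand reading a YAML config plus flags, and logs its
parameters to a run manifest:

```bash
skillstate simulate out/sim --seed 0
skillstate preprocess --in out/sim/manifest.tsv --out out/clean
skillstate microstate --in out/clean/epochs.tsv --out out/ms.h5 --k 6
skillstate csp --in out/clean/epochs.tsv --microstates out/ms.h5 --out out/csp.json
skillstate tensorize --in out/sim/manifest.tsv --out out/tensors.h5
skillstate train-cnn --in out/tensors.h5 --out out/cnn
skillstate gradcam --in out/tensors.h5 --weights out/cnn/weights.npz --out out/gc --layer tap
skillstate evaluate --in out/tensors.h5 --out out/eval.csv
```

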