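# epifuse

Multi-channel 3D deep-network fusion of structural MRI, FDG-PET and
clinical data for identifying mesial temporal lobe epilepsy (MTLE).

MTLE — most often hippocampal sclerosis — is the leading cause of
refractory focal epilepsy, and no single examination diagnoses it
reliably: some patients are MRI-negative but show unilateral
hypometabolism on interictal FDG-PET, and typical semiology (epigastric
aura, ictal fear) carries signal of its own. `epifuse` implements an
integrated classifier for this setting, aimed at researchers studying
multi-modal fusion for neuroimaging diagnosis:

* **SUVR normalisation** of PET against the cerebellar reference:
  SUVR_i = SUV_i / SUV_cerebellum for each of the R parcellation regions,
  removing inter-subject tracer/scanner scale.
* **48³ cube partitioning** of both image volumes, each modality feeding
  its own 3D-convolutional branch (3 conv + 3 pool + dropout); branch
  outputs are concatenated and pass a shared stage (2 conv + 3 pool +
  dropout). A 1D clinical branch (2 conv + 2 pool + dropout) processes
  the symptom/demographic vector (abdominal-aura flag, fear flag, age,
  sex, education). An integrated head (2 conv with batch norm, dropout,
  dense readout) yields one EP/HC probability per subject; per-cube
  logits are averaged before the sigmoid.
* **A PET bilateral-asymmetry pre-training block**: the volume is split
  at the midsagittal plane, mirrored cube pairs are differenced, a small
  3D CNN classifies each difference cube, and a majority vote produces a
  per-subject "PET-positive" flag appended to the clinical vector.
* **Stratified five-fold cross-validated evaluation** reporting accuracy,
  sensitivity Sen = TP/(TP+FN), the as-printed "specificity"
  Spe = TP/(TP+FP) (algebraically precision; the standard TN/(TN+FP) is
  reported alongside), F1 = 2·Sen·Spe/(Sen+Spe), and rank-based AUC —
  with every fitted statistic recomputed per fold.
* **A synthetic brain-phantom generator** (bilateral mirrored
  "hippocampal" structures, cerebellar reference, planted unilateral
  hypometabolism, MRI atrophy with densification, class-correlated
  symptom flags) so the whole pipeline runs and is tested without any
  clinical data.

The neural-network engine (3D/1D convolution, pooling, batch norm,
dropout, Adam/SGD, backprop) is implemented in numpy inside the package
(`epifuse.nnet`) and is fully seeded: build + train + predict is
bit-reproducible at a fixed seed.

See `docs/methods.md` for the model, its assumptions, defaults and
limitations.

## Worked example

Generate a phantom cohort, train the asymmetry block, and cross-validate
the fused network from the command line:

```
epifuse synth --out-dir cohort --seed 3 --regions 6
epifuse asym  --manifest cohort/manifest.csv --atlas cohort/atlas.nii.gz \
              --epochs 10 --seed 1 --out flags.csv
epifuse eval  --manifest cohort/manifest.csv --atlas cohort/atlas.nii.gz \
              --small --epochs 12 --use-asymmetry --seed 1 --out report.json
```

or drive the library directly:

```python
import numpy as np
from epifuse import (PhantomSpec, make_atlas, generate_records,
                     PipelineConfig, ModelConfig, TrainConfig, cross_validate)

atlas = make_atlas((48, 48, 48), R=6, seed=0)
spec = PhantomSpec(dims=(48, 48, 48), n_ep=15, n_hc=15, seed=15)
records, truth = generate_records(spec, atlas)

cfg = PipelineConfig(channels=("mri", "pet", "clinical"), use_asymmetry=True,
                     model=ModelConfig(dropout=0.3).small(),
                     training=TrainConfig(epochs=12))
report = cross_validate(records, atlas, cfg, k=5, seed=1)
s = report["summary"]
print(f"accuracy {100*s['accuracy']['mean']:.1f}% +/- {100*s['accuracy']['sd']:.1f}%")
print(f"auc      {s['auc']['mean']:.2f}")
```

which prints (exactly reproducible at these seeds):

```
accuracy 73.3% +/- 9.1%
auc      0.78
```

Here 73.3% is the mean held-out accuracy over the five stratified folds of
the 30-subject phantom cohort and 0.78 the mean fold AUC; with a planted
30% unilateral PET deficit, 30% hippocampal atrophy and symptom flags at
0.8 vs 0.1, the fused-plus-asymmetry pipeline recovers most of the planted
separation at this small sample size.

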