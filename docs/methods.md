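# Methods

## Problem and model

`epifuse` classifies mesial temporal lobe epilepsy (MTLE) patients (EP = 1)
against healthy controls (HC = 0) from three co-registered inputs per
subject: a structural T1-like MRI volume, an FDG-PET-like volume, and a
short clinical/demographic vector (two typical-symptom flags, age, sex,
years of education). The pathological signature it targets is the classic
hippocampal-sclerosis pattern: reduced hippocampal volume with increased
tissue density on MRI, and unilateral interictal hypometabolism on PET.

The classifier is a multi-channel 3D convolutional network with two main
blocks:

* **Image-data block.** MRI and PET volumes are partitioned into
  non-overlapping 48×48×48 cubes and each modality passes through its own
  branch of three 3×3×3 convolutions, each followed by 2³ max-pooling, with
  a dropout layer at the end (48³ → 6³ per branch). The two branch outputs
  are concatenated along the channel axis and pass through a shared stage of
  two further 3D convolutions with three pools and dropout (6³ → 1³).
* **Clinical-information block.** The 1D clinical vector (length 5, or 6
  once the PET-positivity flag exists) passes through two 1D convolutions
  with two poolings and dropout.
* **Integrated head.** Both block outputs are stretched and concatenated
  into one vector, treated as a one-channel sequence, and passed through two
  1D convolutions each followed by batch normalisation and ReLU, dropout,
  and a position-specific dense readout producing one logit. When a subject
  contributes several cubes, per-cube logits are averaged before the
  sigmoid, so every subject yields exactly one probability; label 1 is
  assigned at probability ≥ 0.5 (ties positive, by convention).

Any subset of {mri, pet, clinical} can be enabled; disabling an input
removes its branch. This is how the single-channel and image-only
comparisons are run.

### Head readout

An earlier head design ended in global average pooling over the feature
sequence. Because the head convolutions share weights across positions,
that readout cannot weight individual feature positions, and on fused
inputs (image features next to clinical features) it demonstrably failed
to learn even in-sample. The head therefore keeps the two conv + batch-norm
stages and reads out with a dense layer over all positions. The dense
readout is zero-initialised so training starts from an uncommitted logit;
with ~1.5k inputs of order-1 magnitude, a random-init readout starts deep
in sigmoid saturation.

## PET asymmetry pre-training block

MTLE hypometabolism is usually unilateral, so a left/right asymmetry is a
diagnostic signal in its own right, and it rescues the MRI-negative,
PET-positive case. The block:

1. SUVR-normalises PET (configurable; on by default — the block is also
   usable on merely spatially normalised PET, which the source protocol
   leaves ambiguous).
2. Splits the volume at the geometric midplane of the left–right axis
   (axis 0 after canonical reorientation; inputs are template-registered by
   contract, so no per-subject midline estimation). Odd widths drop the
   single midline plane.
3. Tiles each hemisphere block into 48-cubes and mirrors the right
   hemisphere so anatomically homologous cubes align, then forms
   `diff = left − mirrored right`. Two identities are property-tested:
   a perfectly symmetric volume gives all-zero difference cubes, and
   swapping hemispheres negates every difference cube exactly.
4. Trains a small 3D CNN (average-pool 2, then two conv+max-pool stages of
   8 and 16 maps, dropout 0.3, dense logit) on difference cubes. Every pair
   inherits its subject's label, accepted label noise included — patient
   hemifields contain healthy tissue, and cube boundaries can split an
   epileptogenic zone.
5. Aggregates pair probabilities to one subject flag. Default rule:
   strict majority of pairs above threshold 0.5; an "any pair above
   threshold" rule is available. The flag is appended as the sixth element
   of the clinical vector.

## SUVR normalisation

For atlas region *i*, SUVR_i = (mean PET intensity over region *i*) /
(mean PET intensity over the cerebellar reference voxels). The reference
region's own SUVR is identically 1 and the statistic is invariant under
global positive rescaling of the image — both hold to floating tolerance by
construction and are asserted in tests. Regional statistics are arithmetic
voxel means computed in float64. A non-positive reference mean or an empty
declared region is an error, never silently patched.

## ROI pair features

The regional feature matrix is defined as the log-ratio
M[i,j] = log(SUVR_i / SUVR_j), which is antisymmetric, so only the strict
upper triangle (length R(R−1)/2; 4005 for a 90-region parcellation) is
kept, in row-major order. This is a documented package choice: ratio-type
pair matrices use only quantities the pipeline already defines. The feature
vector is exposed as an optional extra input and is off by default; nothing
in the default network consumes it.

## Cube partitioning

`extract_cubes` zero-pads each axis on the high side up to the next stride
multiple and enumerates cubes in lexicographic origin order, so at stride
48 every padded voxel is covered exactly once and the voxel sum is
conserved — both are exact tests, not approximations.

## Clinical standardisation

Binary fields pass through; age and education are z-scored with mean/sd
computed **from the training fold only** (a zero-variance fold falls back
to centering, logged). The PET flag, when present, is appended last.

## Training protocol

Batch size 1, binary cross-entropy, ReLU activations. The historical
protocol (500 epochs, SGD, learning rate 0.1, early stop after 1000
iterations without improvement) is preserved verbatim as
`TrainConfig.published()`; at batch size 1 it is prone to divergence, which the
trainer surfaces as an explicit error naming the iteration. The package
default is Adam at learning rate 1e-3 (the source protocol names only a
learning rate, not an optimiser): in experiments on the phantom cohorts,
batch-1 SGD — plain or with momentum — either oscillated without learning
or collapsed the integrated head to a constant output, while Adam trains
all channel subsets reliably. Per-iteration losses are traced; early
stopping monitors the training loss with a patience counter.

Default widths are (8, 16, 32) per image branch, (32, 32) post-concat,
(8, 16) clinical, head width 16, dropout 0.5; a `small()` preset
(4, 8, 8 / 8, 8 / 4, 8 / 8, dropout per config) with dropout 0.3 is used
for the desk-scale test and acceptance runs. Multiple cubes per subject
average their logits (the published pipeline feeds cubes "separately" but
reports subject-level decisions).

Optional augmentation (off by default): random flips along the two
non-lateral axes plus additive Gaussian intensity noise. The lateral axis
is never flipped — that would relabel the lateralization the asymmetry
block depends on.

## Evaluation

Stratified, seeded five-fold cross-validation. Everything fitted from
data — clinical standardisation statistics, the asymmetry classifier,
network weights — is refit inside each training fold; the report carries a
fingerprint (SHA-256 over fold statistics and final weights) per fold so
identical fold states, i.e. leakage, would be visible. The historical
fixed design (10 + 10 training, remainder test) is available as
`fixed_split`.

Two printed metric formulas are nonstandard and are reported **as printed**
alongside the standard definitions:

* "specificity" = TP/(TP+FP), which is algebraically precision (PPV);
  standard specificity TN/(TN+FP) is reported as
  `specificity_standard`.
* F1 = 2·Sen·Spe/(Sen+Spe) over that printed "specificity", which makes it
  identical to the standard F1; the identity is asserted in tests rather
  than silently corrected.

Zero-denominator metrics are reported as undefined (NaN → JSON null),
never clamped. AUC is the rank-based Mann–Whitney statistic with ties
counted one half.

## Synthetic phantom cohorts

The generator emulates the study's data conditions without any clinical
data: an ellipsoidal brain mask, exactly mirrored bilateral "hippocampal"
ellipsoids, a midline "cerebellar" reference region, and equal-count filler
parcels. Defaults follow the study cohort: 15 EP + 15 HC, with ~30%
unilateral hippocampal SUV reduction and ~30% hippocampal volume loss
(with a compensatory intensity increase inside the shrunken structure) in
patients, symptom-flag rates 0.8 (EP) vs 0.1 (HC), ages and education drawn
from one shared distribution (age-matched classes), additive Gaussian
noise sd 0.05, and a per-subject log-normal global PET scale factor
(sd 0.2) so the SUVR step does real work. Lateralization is random by
default. Default grid 96³; tests and the acceptance script use 48³ grids —
one cube per modality and one symmetric pair per subject — purely as a
problem-size choice, since the pipeline is dimension-agnostic.

What the phantom does **not** model: MRI/PET physics (partial-volume,
scanner noise spectra, reconstruction artefacts), cortical folding,
anatomical variability, registration error. Passing recovery tests on the
phantom therefore demonstrates that the pipeline's machinery is correct and
sensitive to the planted effect classes, not that the reported clinical
accuracies transfer.

## Known limitations

* The published headline numbers were computed on a private 30-subject
  clinical cohort; they are not reproducible from synthetic data, and some
  of their printed dispersions are internally inconsistent. The package
  reproduces the *procedure* and its qualitative behaviour (fusion tracks
  or beats the best single channel; the asymmetry flag recovers planted
  lateralized deficits), not the clinical values.
* Kernel sizes, channel widths, pooling and dropout rates are not specified
  by the source description; the defaults here are documented choices
  exposed in `ModelConfig`.
* At phantom desk scale with tens of subjects, held-out AUCs of individual
  weak channels have high seed-to-seed variance; conclusions in tests are
  therefore taken as medians over seeds or with wide null bands.
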