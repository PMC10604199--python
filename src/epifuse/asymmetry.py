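"""Bilateral PET asymmetry pre-training block.

Interictal hypometabolism in mesial temporal lobe epilepsy is usually
unilateral, so a left/right metabolic asymmetry is itself a diagnostic
signal.  This stage splits the (SUVR-normalised) PET volume at the
midsagittal plane, mirrors the right hemisphere onto the left, tiles
both halves into 48-cubes, and forms the voxelwise difference cube of
each anatomically matched pair.  A small 3D convolutional classifier is
trained on the difference cubes (pairs inherit their subject's EP/HC
label), and the per-pair probabilities are aggregated into one binary
"PET-positive" flag per subject which the fusion network receives as an
extra clinical-channel element.

A perfectly midline-symmetric volume yields all-zero difference cubes;
swapping hemispheres negates every difference cube exactly.  Both are
structural identities of the construction and are property-tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import nnet
from .io_manifest import SubjectRecord, ValidationError, Volume3D
from .preprocess import CUBE_SIZE, ParcellationAtlas, extract_cubes, normalize_pet_suvr

log = logging.getLogger(__name__)


@dataclass
class SymmetricCubePair:
    """A left-hemisphere cube, its mirrored right counterpart and their difference."""

    left_cube: np.ndarray
    right_cube_mirrored: np.ndarray
    diff_cube: np.ndarray
    origin: tuple[int, int, int]
    subject_label: int | None = None

    def __post_init__(self) -> None:
        if not (
            self.left_cube.shape == self.right_cube_mirrored.shape == self.diff_cube.shape
        ):
            raise ValidationError("pair cubes must share one shape")


@dataclass
class AsymmetryDecision:
    """Per-pair probabilities and the aggregated subject-level flag."""

    pair_scores: list[float]
    subject_flag: int
    threshold: float
    rule: str


def split_and_pair(
    pet: Volume3D | np.ndarray,
    midline: int | str = "auto",
    size: int = CUBE_SIZE,
) -> list[SymmetricCubePair]:
    """Mirror-matched cube pairs about the midsagittal plane.

    The left–right axis is axis 0 (canonical orientation contract).
    ``midline="auto"`` uses the geometric midplane; an odd-width volume
    drops its single midline plane.  Both hemisphere blocks are tiled
    with the standard cube extractor so pairs match by origin.
    """
    data = pet.data if isinstance(pet, Volume3D) else np.asarray(pet)
    w = data.shape[0]
    if w < 2:
        raise ValidationError(f"left-right width must be >= 2 for splitting, got {w}")
    mid = w // 2 if midline == "auto" else int(midline)
    if not 1 <= mid <= w - 1:
        raise ValidationError(f"midline {mid} outside volume of width {w}")
    left = data[:mid]
    right_start = mid + 1 if (midline == "auto" and w % 2 == 1) else mid
    right_mirrored = data[right_start:][::-1]
    if left.shape != right_mirrored.shape:
        raise ValidationError(
            f"hemisphere blocks differ in shape: {left.shape} vs {right_mirrored.shape}"
        )
    left_cubes = extract_cubes(left, size=size)
    right_cubes = extract_cubes(right_mirrored, size=size)
    pairs = []
    for lc, rc, origin in zip(left_cubes.cubes, right_cubes.cubes, left_cubes.origins):
        pairs.append(
            SymmetricCubePair(
                left_cube=lc,
                right_cube_mirrored=rc,
                diff_cube=lc - rc,
                origin=tuple(int(o) for o in origin),
            )
        )
    return pairs


def subject_pairs(
    subject: SubjectRecord,
    atlas: ParcellationAtlas | None = None,
    suvr_normalize: bool = True,
    size: int = CUBE_SIZE,
) -> list[SymmetricCubePair]:
    """Labelled symmetric pairs from one subject's PET volume."""
    pet = subject.pet
    if suvr_normalize and atlas is not None:
        pet = normalize_pet_suvr(pet, atlas)
    pairs = split_and_pair(pet, size=size)
    for p in pairs:
        p.subject_label = subject.label
    return pairs


# ---------------------------------------------------------------- classifier


@dataclass
class AsymmetryConfig:
    """Training configuration of the pair classifier.

    The network is deliberately small: average-pool 2 to halve the
    grid, two 3x3x3 convolution + max-pool stages (8 and 16 feature
    maps), dropout, and a dense logit.  Batch size is 1 throughout the
    pipeline.
    """

    epochs: int = 30
    learning_rate: float = 0.001
    optimizer: str = "adam"
    momentum: float = 0.0
    dropout: float = 0.3
    widths: tuple[int, int] = (8, 16)
    seed: int = 0
    early_stop_patience: int | None = None


class AsymmetryClassifier:
    """Seeded 3D CNN scoring difference cubes with an asymmetry probability."""

    def __init__(self, config: AsymmetryConfig, cube_size: int = CUBE_SIZE):
        self.config = config
        self.cube_size = cube_size
        rng = np.random.default_rng(config.seed)
        w1, w2 = config.widths
        grid = cube_size // 8  # avg-pool 2 then two max-pools of 2
        self.net = nnet.Sequential(
            nnet.AvgPool3d(2),
            nnet.Conv3d(1, w1, 3, rng),
            nnet.ReLU(),
            nnet.MaxPool3d(2),
            nnet.Conv3d(w1, w2, 3, rng),
            nnet.ReLU(),
            nnet.MaxPool3d(2),
            nnet.Dropout(config.dropout, rng),
            nnet.Flatten(),
            nnet.Dense(w2 * grid ** 3, 1, rng),
        )
        self._train_rng = np.random.default_rng(config.seed + 1)
        self.loss_trace: list[float] = []

    def _logit(self, diff_cube: np.ndarray, training: bool) -> float:
        x = np.asarray(diff_cube, dtype=nnet.DTYPE)[None]  # add channel axis
        return float(self.net.forward(x, training=training)[0])

    def fit(self, diff_cubes: np.ndarray, labels: np.ndarray) -> "AsymmetryClassifier":
        labels = np.asarray(labels, dtype=int)
        if len(diff_cubes) != len(labels):
            raise ValidationError("cubes and labels must have equal length")
        classes = set(labels.tolist())
        if classes != {0, 1}:
            raise ValidationError(
                f"training needs both classes (0 and 1), got labels {sorted(classes)}"
            )
        opt = nnet.make_optimizer(self.config.optimizer, self.net.params(),
                                  self.config.learning_rate, self.config.momentum)
        patience = self.config.early_stop_patience
        best, since_best = np.inf, 0
        idx = np.arange(len(labels))
        for _epoch in range(self.config.epochs):
            self._train_rng.shuffle(idx)
            for i in idx:
                opt.zero_grad()
                x = np.asarray(diff_cubes[i], dtype=nnet.DTYPE)[None]
                z = float(self.net.forward(x, training=True)[0])
                p = float(nnet.sigmoid(z))
                self.loss_trace.append(nnet.bce_from_logit(z, int(labels[i])))
                self.net.backward(np.array([p - labels[i]], dtype=nnet.DTYPE))
                opt.step()
                if patience is not None:
                    if self.loss_trace[-1] < best - 1e-6:
                        best, since_best = self.loss_trace[-1], 0
                    else:
                        since_best += 1
                        if since_best >= patience:
                            log.info("early stop after %d iterations", len(self.loss_trace))
                            return self
        return self

    def predict_proba(self, diff_cubes: np.ndarray) -> np.ndarray:
        return np.array(
            [float(nnet.sigmoid(self._logit(c, training=False))) for c in diff_cubes]
        )


def train_asymmetry_classifier(
    pairs: list[SymmetricCubePair],
    config: AsymmetryConfig | None = None,
) -> AsymmetryClassifier:
    """Train the pair classifier on labelled symmetric cube pairs."""
    config = config or AsymmetryConfig()
    if not pairs:
        raise ValidationError("no pairs to train on")
    if any(p.subject_label is None for p in pairs):
        raise ValidationError("every training pair must carry its subject's label")
    cubes = np.stack([p.diff_cube for p in pairs])
    labels = np.array([p.subject_label for p in pairs], dtype=int)
    clf = AsymmetryClassifier(config, cube_size=pairs[0].diff_cube.shape[0])
    return clf.fit(cubes, labels)


# ---------------------------------------------------------------- aggregation


def aggregate_subject_flag(
    pair_scores: list[float] | np.ndarray,
    threshold: float = 0.5,
    rule: str = "majority",
) -> AsymmetryDecision:
    """Collapse per-pair probabilities into one PET-positivity flag.

    ``majority``: flag 1 iff strictly more than half of the pairs score
    above the threshold.  ``any``: flag 1 iff any pair does.
    """
    scores = [float(s) for s in np.atleast_1d(np.asarray(pair_scores, dtype=float))]
    if not scores:
        raise ValidationError("need at least one pair score")
    if rule not in ("majority", "any"):
        raise ValidationError(f"unknown aggregation rule {rule!r}")
    above = sum(s > threshold for s in scores)
    if rule == "majority":
        flag = int(above > len(scores) / 2)
    else:
        flag = int(above >= 1)
    return AsymmetryDecision(
        pair_scores=scores, subject_flag=flag, threshold=threshold, rule=rule
    )


def score_subject(
    clf: AsymmetryClassifier,
    subject: SubjectRecord,
    atlas: ParcellationAtlas | None = None,
    suvr_normalize: bool = True,
    threshold: float = 0.5,
    rule: str = "majority",
) -> AsymmetryDecision:
    pairs = subject_pairs(subject, atlas, suvr_normalize=suvr_normalize)
    scores = clf.predict_proba(np.stack([p.diff_cube for p in pairs]))
    return aggregate_subject_flag(scores, threshold=threshold, rule=rule)


def fit_asymmetry_block(
    train_subjects: list[SubjectRecord],
    atlas: ParcellationAtlas | None = None,
    config: AsymmetryConfig | None = None,
    suvr_normalize: bool = True,
) -> AsymmetryClassifier:
    """Train the block on a training cohort (pairs inherit subject labels)."""
    pairs: list[SymmetricCubePair] = []
    for s in train_subjects:
        pairs.extend(subject_pairs(s, atlas, suvr_normalize=suvr_normalize))
    return train_asymmetry_classifier(pairs, config)


def annotate_pet_flags(
    clf: AsymmetryClassifier,
    subjects: list[SubjectRecord],
    atlas: ParcellationAtlas | None = None,
    suvr_normalize: bool = True,
    threshold: float = 0.5,
    rule: str = "majority",
) -> dict[str, int]:
    """Attach the PET-positive flag to each subject's clinical vector in place."""
    flags = {}
    for s in subjects:
        decision = score_subject(
            clf, s, atlas, suvr_normalize=suvr_normalize, threshold=threshold, rule=rule
        )
        s.clinical = s.clinical.with_pet_flag(decision.subject_flag)
        flags[s.subject_id] = decision.subject_flag
    return flags
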