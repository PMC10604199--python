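"""Multi-channel fusion network: MRI + PET 3D branches and a clinical branch.

The classifier has two main blocks.  The image-data block runs the
structural-MRI and PET 48-cubes through independent 3D convolutional
branches (three conv + three pool stages and dropout each), concatenates
their feature maps, and applies a shared stage of two further 3D
convolutions with three pools and dropout.  The clinical-information
block runs the 1D symptom/demographic vector through two 1D
convolutions with two pools and dropout.  Both outputs are stretched,
concatenated, and an integrated head of two convolutions with batch
normalisation and dropout produces one EP-vs-HC logit.

Subjects larger than one cube contribute several cubes; their per-cube
logits are averaged before the sigmoid so each subject yields exactly
one probability.  Any subset of the three inputs can be enabled, which
is how the single-channel and image-only ablations are run.

Training runs at batch size 1 on binary cross-entropy with ReLU
activations throughout.  The historical configuration (500 epochs, SGD
at learning rate 0.1, early stop after 1000 iterations without
improvement) is available as ``TrainConfig.published()``; the package
default optimiser is Adam at 1e-3, because batch-size-1 SGD at 0.1 is
highly divergence-prone on this architecture and the source protocol
names only the learning rate, not the optimiser.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from . import nnet
from .io_manifest import SubjectRecord, ValidationError
from .preprocess import (
    CUBE_SIZE,
    CohortStats,
    ParcellationAtlas,
    standardize_clinical,
    subject_cubes,
)

log = logging.getLogger(__name__)

CHANNELS = ("mri", "pet", "clinical")


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    The ``published`` preset fixes the layer counts of the four stages
    (the only architectural quantities the published description pins down);
    kernel size, channel widths, pooling and dropout are this package's
    defaults and are all adjustable.
    """

    preset: str = "published"
    image_widths: tuple[int, int, int] = (8, 16, 32)
    post_widths: tuple[int, int] = (32, 32)
    clinical_widths: tuple[int, int] = (8, 16)
    head_width: int = 16
    kernel: int = 3
    pool: int = 2
    dropout: float = 0.5
    cube_size: int = CUBE_SIZE

    def small(self) -> "ModelConfig":
        """A narrow variant for quick experiments; same layer counts."""
        return replace(self, image_widths=(4, 8, 8), post_widths=(8, 8),
                       clinical_widths=(4, 8), head_width=8)


@dataclass
class TrainConfig:
    """Optimisation settings; batch size is 1 throughout."""

    epochs: int = 20
    batch_size: int = 1
    learning_rate: float = 0.001
    optimizer: str = "adam"
    momentum: float = 0.0
    early_stop_patience: int | None = 1000
    seed: int = 0
    augment: bool = False
    augment_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size != 1 or self.learning_rate <= 0:
            raise ValidationError("epochs >= 1, batch_size == 1, learning_rate > 0 required")

    @classmethod
    def published(cls, seed: int = 0) -> "TrainConfig":
        """The published training protocol (learning rate 0.1 included)."""
        return cls(epochs=500, batch_size=1, learning_rate=0.1, optimizer="sgd",
                   early_stop_patience=1000, seed=seed)


@dataclass
class Prediction:
    subject_id: str
    probability: float
    predicted_label: int


@dataclass
class PreparedSubject:
    """Network-ready tensors for one subject."""

    subject_id: str
    label: int
    mri_cubes: np.ndarray | None
    pet_cubes: np.ndarray | None
    clinical: np.ndarray | None


def prepare_subject(
    subject: SubjectRecord,
    channels: tuple[str, ...],
    stats: CohortStats | None,
    atlas: ParcellationAtlas | None = None,
    suvr_normalize: bool = True,
    cube_size: int = CUBE_SIZE,
) -> PreparedSubject:
    """Cube and standardise one subject for the enabled channels."""
    mri_cubes = pet_cubes = clin = None
    if "mri" in channels or "pet" in channels:
        mc, pc = subject_cubes(subject, atlas, suvr_normalize=suvr_normalize, size=cube_size)
        if "mri" in channels:
            mri_cubes = mc.cubes
        if "pet" in channels:
            pet_cubes = pc.cubes
    if "clinical" in channels:
        if stats is None:
            raise ValidationError("clinical channel needs training-fold cohort stats")
        clin = standardize_clinical(subject.clinical, stats)
    return PreparedSubject(subject.subject_id, subject.label, mri_cubes, pet_cubes, clin)


class FusionModel:
    """The multi-channel classifier over any subset of the three inputs."""

    def __init__(
        self,
        cfg: ModelConfig,
        channels: tuple[str, ...] = CHANNELS,
        clinical_len: int = 5,
        seed: int = 0,
    ):
        channels = tuple(c for c in CHANNELS if c in channels)
        if not channels:
            raise ValidationError("at least one input channel must be enabled")
        unknown = set(channels) - set(CHANNELS)
        if unknown:
            raise ValidationError(f"unknown channels: {sorted(unknown)}")
        self.cfg, self.channels, self.clinical_len, self.seed = cfg, channels, clinical_len, seed
        rng = np.random.default_rng(seed)
        k, pool, drop = cfg.kernel, cfg.pool, cfg.dropout
        w1, w2, w3 = cfg.image_widths
        p1, p2 = cfg.post_widths
        c1, c2 = cfg.clinical_widths
        h = cfg.head_width

        def image_branch() -> nnet.Sequential:
            return nnet.Sequential(
                nnet.Conv3d(1, w1, k, rng), nnet.ReLU(), nnet.MaxPool3d(pool),
                nnet.Conv3d(w1, w2, k, rng), nnet.ReLU(), nnet.MaxPool3d(pool),
                nnet.Conv3d(w2, w3, k, rng), nnet.ReLU(), nnet.MaxPool3d(pool),
                nnet.Dropout(drop, rng),
            )

        self.mri_branch = image_branch() if "mri" in channels else None
        self.pet_branch = image_branch() if "pet" in channels else None
        self._image_on = self.mri_branch is not None or self.pet_branch is not None
        if self._image_on:
            n_in = w3 * (("mri" in channels) + ("pet" in channels))
            self.post = nnet.Sequential(
                nnet.Conv3d(n_in, p1, k, rng), nnet.ReLU(), nnet.MaxPool3d(pool),
                nnet.Conv3d(p1, p2, k, rng), nnet.ReLU(), nnet.MaxPool3d(pool),
                nnet.MaxPool3d(pool), nnet.Dropout(drop, rng),
            )
        else:
            self.post = None
        if "clinical" in channels:
            self.clinical_branch = nnet.Sequential(
                nnet.Conv1d(1, c1, k, rng), nnet.ReLU(), nnet.MaxPool1d(pool),
                nnet.Conv1d(c1, c2, k, rng), nnet.ReLU(), nnet.MaxPool1d(pool),
                nnet.Dropout(drop, rng),
            )
        else:
            self.clinical_branch = None

        self._img_len, self._clin_len = self._feature_lengths()
        feat_len = self._img_len + self._clin_len
        self.head = nnet.Sequential(
            nnet.Conv1d(1, h, k, rng), nnet.BatchNorm1d(h), nnet.ReLU(),
            nnet.Conv1d(h, h, k, rng), nnet.BatchNorm1d(h), nnet.ReLU(),
            nnet.Dropout(drop, rng),
            nnet.Flatten(), nnet.Dense(h * feat_len, 1, rng, scale=0.0),
        )

    # -- shapes

    def _feature_lengths(self) -> tuple[int, int]:
        s = self.cfg.cube_size
        img_len = 0
        if self._image_on:
            zero = np.zeros((1, s, s, s), dtype=nnet.DTYPE)
            branch = self.mri_branch or self.pet_branch
            f = branch.forward(zero)
            if self.mri_branch is not None and self.pet_branch is not None:
                f = np.concatenate([f, f], axis=0)
            img_len = self.post.forward(f).size
        clin_len = 0
        if self.clinical_branch is not None:
            zero = np.zeros((1, self.clinical_len), dtype=nnet.DTYPE)
            clin_len = self.clinical_branch.forward(zero).size
        return img_len, clin_len

    def modules(self) -> list[nnet.Sequential]:
        return [
            m
            for m in (self.mri_branch, self.pet_branch, self.post, self.clinical_branch, self.head)
            if m is not None
        ]

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        out = []
        for m in self.modules():
            out.extend(m.params())
        return out

    def n_parameters(self) -> int:
        return int(sum(p.size for p, _ in self.params()))

    def state_bytes(self) -> bytes:
        return b"".join(np.ascontiguousarray(p).tobytes() for p, _ in self.params())

    # -- forward / backward

    def _n_cubes(self, ex: PreparedSubject) -> int:
        if not self._image_on:
            return 1
        cubes = ex.mri_cubes if ex.mri_cubes is not None else ex.pet_cubes
        return len(cubes)

    def _check(self, ex: PreparedSubject) -> None:
        s = self.cfg.cube_size
        for name, cubes in (("mri", ex.mri_cubes), ("pet", ex.pet_cubes)):
            need = name in self.channels
            if need and cubes is None:
                raise ValidationError(f"{name} cubes required but absent for {ex.subject_id}")
            if need and cubes.shape[1:] != (s, s, s):
                raise ValidationError(
                    f"{name} cubes must be {s}^3, got {cubes.shape[1:]} for {ex.subject_id}"
                )
        if ex.mri_cubes is not None and ex.pet_cubes is not None:
            if len(ex.mri_cubes) != len(ex.pet_cubes):
                raise ValidationError("MRI and PET cube counts differ (co-registration contract)")
        if self.clinical_branch is not None:
            if ex.clinical is None:
                raise ValidationError(f"clinical vector required but absent for {ex.subject_id}")
            if ex.clinical.shape != (self.clinical_len,):
                raise ValidationError(
                    f"clinical vector must have length {self.clinical_len}, "
                    f"got {ex.clinical.shape[0]} for {ex.subject_id}"
                )

    def _cube_forward(self, ex: PreparedSubject, i: int, training: bool) -> float:
        feats = []
        if self._image_on:
            parts = []
            if self.mri_branch is not None:
                parts.append(self.mri_branch.forward(ex.mri_cubes[i][None], training))
            if self.pet_branch is not None:
                parts.append(self.pet_branch.forward(ex.pet_cubes[i][None], training))
            x = parts[0] if len(parts) == 1 else np.concatenate(parts, axis=0)
            y = self.post.forward(x, training)
            self._post_out_shape = y.shape
            feats.append(y.reshape(-1))
        if self.clinical_branch is not None:
            cf = self.clinical_branch.forward(
                ex.clinical[None].astype(nnet.DTYPE), training
            )
            self._clin_out_shape = cf.shape
            feats.append(cf.reshape(-1))
        f = np.concatenate(feats)[None]  # 1-channel sequence for the head
        return float(self.head.forward(f, training)[0])

    def _cube_backward(self, dlogit: float) -> None:
        """Backprop one cube pass; call immediately after its forward."""
        df = self.head.backward(np.array([dlogit], dtype=nnet.DTYPE))[0]
        pos = 0
        if self._image_on:
            dimg = df[pos : pos + self._img_len]
            pos += self._img_len
            # recover the post-stage output shape from its dropout cache
            dpost_in = self.post.backward(dimg.reshape(self._post_out_shape))
            if self.mri_branch is not None and self.pet_branch is not None:
                half = dpost_in.shape[0] // 2
                self.mri_branch.backward(dpost_in[:half])
                self.pet_branch.backward(dpost_in[half:])
            elif self.mri_branch is not None:
                self.mri_branch.backward(dpost_in)
            else:
                self.pet_branch.backward(dpost_in)
        if self.clinical_branch is not None:
            dclin = df[pos : pos + self._clin_len]
            self.clinical_branch.backward(dclin.reshape(self._clin_out_shape))

    def subject_logit(self, ex: PreparedSubject, training: bool = False) -> float:
        self._check(ex)
        n = self._n_cubes(ex)
        return float(
            np.mean([self._cube_forward(ex, i, training) for i in range(n)])
        )

    def predict_proba(self, ex: PreparedSubject) -> float:
        return float(nnet.sigmoid(self.subject_logit(ex, training=False)))

    # -- training

    def _train_step(self, ex: PreparedSubject, opt: nnet.SGD) -> float:
        """One batch-size-1 SGD step; returns the subject loss."""
        self._check(ex)
        n = self._n_cubes(ex)
        opt.zero_grad()
        logits = []
        for i in range(n):
            z = self._cube_forward(ex, i, training=True)
            self._cube_backward(1.0 / n)  # linear pass; scaled by dL/dz below
            logits.append(z)
        zbar = float(np.mean(logits))
        p = float(nnet.sigmoid(zbar))
        dz = p - ex.label  # d BCE / d logit
        for _, g in self.params():
            g *= dz
        opt.step()
        return nnet.bce_from_logit(zbar, ex.label)


def _augment(ex: PreparedSubject, rng: np.random.Generator, noise_sd: float) -> PreparedSubject:
    """Random flips along the non-lateral axes plus additive intensity noise."""

    def flip(cubes):
        if cubes is None:
            return None
        out = cubes
        for ax in (2, 3):  # never the left-right axis
            if rng.random() < 0.5:
                out = np.flip(out, axis=ax)
        if noise_sd > 0:
            out = out + rng.normal(0.0, noise_sd, out.shape).astype(nnet.DTYPE)
        return np.ascontiguousarray(out, dtype=nnet.DTYPE)

    return PreparedSubject(ex.subject_id, ex.label, flip(ex.mri_cubes), flip(ex.pet_cubes), ex.clinical)


def build_model(
    cfg: ModelConfig,
    inputs_enabled: tuple[str, ...] = CHANNELS,
    clinical_len: int = 5,
    seed: int = 0,
) -> FusionModel:
    """Construct the network for the enabled input subset (seeded init)."""
    return FusionModel(cfg, channels=inputs_enabled, clinical_len=clinical_len, seed=seed)


def train(
    model: FusionModel,
    subjects: list[PreparedSubject],
    cfg: TrainConfig,
) -> tuple[FusionModel, list[float]]:
    """SGD training with per-iteration loss trace and patience-based early stop.

    Raises ``DivergenceError`` (reporting the iteration) if the loss
    goes non-finite — which the historical learning rate of 0.1 at
    batch size 1 can do — and a class-balance error when only one class
    is present.
    """
    labels = {s.label for s in subjects}
    if labels != {0, 1}:
        raise ValidationError(f"training needs both classes, got labels {sorted(labels)}")
    opt = nnet.make_optimizer(cfg.optimizer, model.params(), cfg.learning_rate, cfg.momentum)
    rng = np.random.default_rng(cfg.seed)
    trace: list[float] = []
    best, since_best = np.inf, 0
    idx = np.arange(len(subjects))
    for _epoch in range(cfg.epochs):
        rng.shuffle(idx)
        for i in idx:
            ex = subjects[i]
            if cfg.augment:
                ex = _augment(ex, rng, cfg.augment_noise_sd)
            loss = model._train_step(ex, opt)
            trace.append(loss)
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"non-finite training loss at iteration {len(trace)} "
                    f"(learning rate {cfg.learning_rate})"
                )
            if cfg.early_stop_patience is not None:
                if loss < best - 1e-6:
                    best, since_best = loss, 0
                else:
                    since_best += 1
                    if since_best >= cfg.early_stop_patience:
                        log.info("early stop after %d iterations", len(trace))
                        return model, trace
    return model, trace


def predict(
    model: FusionModel,
    subjects: list[PreparedSubject],
    threshold: float = 0.5,
) -> list[Prediction]:
    """One probability per subject; label 1 at probability >= threshold."""
    out = []
    for ex in subjects:
        p = model.predict_proba(ex)
        out.append(Prediction(ex.subject_id, p, int(p >= threshold)))
    return out
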