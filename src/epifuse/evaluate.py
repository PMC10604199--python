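"""Metrics and stratified five-fold cross-validated evaluation.

Two of the published metric formulas are nonstandard: the printed
"specificity" TP/(TP+FP) is algebraically the positive predictive value
(precision), and consequently the printed F1 (harmonic mean of
sensitivity and that "specificity") is identical to the standard F1.
Both the as-printed and the standard definitions are always reported
side by side, and the identity f1_as_printed == f1_standard is asserted
as a cross-check rather than silently corrected.

Cross-validation is stratified and seeded.  Everything learned from
data — clinical standardisation statistics, the PET asymmetry
classifier, model weights — is refit inside each training fold, and a
fingerprint of the fold-local state is included in the report so
leakage would be visible.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .asymmetry import AsymmetryConfig, annotate_pet_flags, fit_asymmetry_block
from .fusion_model import (
    CHANNELS,
    ModelConfig,
    Prediction,
    TrainConfig,
    build_model,
    predict,
    prepare_subject,
    train,
)
from .io_manifest import SubjectRecord, ValidationError
from .preprocess import CohortStats, ParcellationAtlas

log = logging.getLogger(__name__)

METRIC_NAMES = (
    "accuracy",
    "sensitivity",
    "specificity_as_printed",
    "f1_as_printed",
    "specificity_standard",
    "f1_standard",
    "auc",
)


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValidationError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion(predicted: list[int] | np.ndarray, labels: list[int] | np.ndarray) -> ConfusionCounts:
    """Count TP/TN/FP/FN under the EP=1 positive convention."""
    predicted = np.asarray(predicted, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if predicted.shape != labels.shape:
        raise ValidationError(
            f"prediction/label length mismatch: {predicted.shape} vs {labels.shape}"
        )
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValidationError("labels must be binary")
    return ConfusionCounts(
        TP=int(np.sum((predicted == 1) & (labels == 1))),
        TN=int(np.sum((predicted == 0) & (labels == 0))),
        FP=int(np.sum((predicted == 1) & (labels == 0))),
        FN=int(np.sum((predicted == 0) & (labels == 1))),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        log.warning("metric %s undefined (zero denominator); reporting NaN", name)
        return float("nan")
    return num / den


def metrics_from_counts(c: ConfusionCounts) -> dict[str, float]:
    """All rate metrics, as-printed and standard variants side by side.

    Undefined ratios (zero denominators) are NaN, never clamped to 0.
    """
    acc = _ratio(c.TP + c.TN, c.total, "accuracy")
    sen = _ratio(c.TP, c.TP + c.FN, "sensitivity")  # recall
    spe_printed = _ratio(c.TP, c.TP + c.FP, "specificity_as_printed")  # = precision
    spe_std = _ratio(c.TN, c.TN + c.FP, "specificity_standard")
    f1_printed = _ratio(2 * sen * spe_printed, sen + spe_printed, "f1_as_printed")
    f1_std = _ratio(2 * spe_printed * sen, spe_printed + sen, "f1_standard")
    return {
        "accuracy": acc,
        "sensitivity": sen,
        "specificity_as_printed": spe_printed,
        "f1_as_printed": f1_printed,
        "specificity_standard": spe_std,
        "f1_standard": f1_std,
    }


def roc_auc(scores: list[float] | np.ndarray, labels: list[int] | np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC; ties count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)  # average ranks handle ties
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def fold_metrics(preds: list[Prediction], labels: list[int]) -> dict[str, float]:
    c = confusion([p.predicted_label for p in preds], labels)
    m = metrics_from_counts(c)
    m["auc"] = roc_auc([p.probability for p in preds], labels)
    m["counts"] = {"TP": c.TP, "TN": c.TN, "FP": c.FP, "FN": c.FN}
    return m


# ---------------------------------------------------------------- pipeline


@dataclass
class PipelineConfig:
    """Everything one evaluation run needs, bundled."""

    channels: tuple[str, ...] = CHANNELS
    use_asymmetry: bool = False
    suvr_normalize: bool = True
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    asymmetry: AsymmetryConfig = field(default_factory=AsymmetryConfig)
    asym_threshold: float = 0.5
    asym_rule: str = "majority"
    threshold: float = 0.5


def _clone(subject: SubjectRecord) -> SubjectRecord:
    """Fold-local copy: volumes shared read-only, clinical vector fresh."""
    return replace(subject, clinical=replace(subject.clinical))


def _fingerprint(stats: CohortStats, model) -> str:
    h = hashlib.sha256()
    h.update(np.array(
        [stats.age_mean, stats.age_sd, stats.education_mean, stats.education_sd]
    ).tobytes())
    h.update(model.state_bytes())
    return h.hexdigest()[:16]


def fit_and_score_fold(
    train_subjects: list[SubjectRecord],
    test_subjects: list[SubjectRecord],
    atlas: ParcellationAtlas | None,
    cfg: PipelineConfig,
    seed: int,
) -> dict:
    """Fit preprocessing + optional asymmetry block + model on the training
    subjects only, then score the held-out subjects."""
    train_s = [_clone(s) for s in train_subjects]
    test_s = [_clone(s) for s in test_subjects]
    if cfg.use_asymmetry:
        asym_cfg = replace(cfg.asymmetry, seed=seed)
        clf = fit_asymmetry_block(
            train_s, atlas, asym_cfg, suvr_normalize=cfg.suvr_normalize
        )
        annotate_pet_flags(
            clf, train_s + test_s, atlas,
            suvr_normalize=cfg.suvr_normalize,
            threshold=cfg.asym_threshold, rule=cfg.asym_rule,
        )
    stats = CohortStats.fit([s.clinical for s in train_s])
    clin_len = 6 if cfg.use_asymmetry else 5

    def prep(subjects):
        return [
            prepare_subject(
                s, cfg.channels, stats, atlas,
                suvr_normalize=cfg.suvr_normalize, cube_size=cfg.model.cube_size,
            )
            for s in subjects
        ]

    model = build_model(cfg.model, cfg.channels, clinical_len=clin_len, seed=seed)
    tr_cfg = replace(cfg.training, seed=seed)
    model, trace = train(model, prep(train_s), tr_cfg)
    preds = predict(model, prep(test_s), threshold=cfg.threshold)
    labels = [s.label for s in test_s]
    return {
        "metrics": fold_metrics(preds, labels),
        "predictions": [
            {"subject_id": p.subject_id, "probability": p.probability,
             "predicted_label": p.predicted_label}
            for p in preds
        ],
        "labels": labels,
        "n_train": len(train_s),
        "n_test": len(test_s),
        "final_loss": trace[-1],
        "fingerprint": _fingerprint(stats, model),
    }


def stratified_folds(
    labels: np.ndarray, k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified k-fold index pairs (train, test)."""
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels, minlength=2)
    if counts.min() < k:
        raise ValidationError(
            f"stratified {k}-fold needs >= {k} subjects per class, got {counts.tolist()}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(labels)), labels)]


def _summarise(folds: list[dict]) -> dict:
    out = {}
    for name in METRIC_NAMES:
        vals = np.array([f["metrics"][name] for f in folds], dtype=float)
        out[name] = {
            "mean": float(np.nanmean(vals)),
            "sd": float(np.nanstd(vals, ddof=1)) if len(vals) > 1 else 0.0,
            "per_fold": vals.tolist(),
        }
    return out


def cross_validate(
    subjects: list[SubjectRecord],
    atlas: ParcellationAtlas | None,
    cfg: PipelineConfig,
    k: int = 5,
    seed: int = 0,
) -> dict:
    """Stratified k-fold cross-validation; returns the full metrics report."""
    labels = np.array([s.label for s in subjects], dtype=int)
    folds = stratified_folds(labels, k, seed)
    fold_reports = []
    for fold_idx, (tr, te) in enumerate(folds):
        fold_seed = (seed * 1009 + fold_idx) % (2**31)
        rep = fit_and_score_fold(
            [subjects[i] for i in tr], [subjects[i] for i in te], atlas, cfg, fold_seed
        )
        rep["fold"] = fold_idx
        rep["test_indices"] = [int(i) for i in te]
        fold_reports.append(rep)
        log.info("fold %d: %s", fold_idx, rep["metrics"])
    return {
        "k": k,
        "seed": seed,
        "channels": list(cfg.channels),
        "use_asymmetry": cfg.use_asymmetry,
        "n_subjects": len(subjects),
        "folds": fold_reports,
        "summary": _summarise(fold_reports),
    }


def fixed_split(
    subjects: list[SubjectRecord],
    atlas: ParcellationAtlas | None,
    cfg: PipelineConfig,
    n_train_per_class: int = 10,
    seed: int = 0,
) -> dict:
    """The historical fixed design: a seeded random split with a fixed
    per-class training count (10 + 10 train, remainder test by default)."""
    rng = np.random.default_rng(seed)
    labels = np.array([s.label for s in subjects], dtype=int)
    tr_idx: list[int] = []
    for cls in (0, 1):
        cls_idx = np.flatnonzero(labels == cls)
        if len(cls_idx) <= n_train_per_class:
            raise ValidationError(
                f"need more than {n_train_per_class} subjects of class {cls}"
            )
        tr_idx.extend(rng.permutation(cls_idx)[:n_train_per_class].tolist())
    te_idx = [i for i in range(len(subjects)) if i not in set(tr_idx)]
    rep = fit_and_score_fold(
        [subjects[i] for i in tr_idx], [subjects[i] for i in te_idx], atlas, cfg, seed
    )
    rep["design"] = f"fixed split, {n_train_per_class} per class in training"
    return rep


ABLATION_CONFIGS: dict[str, dict] = {
    "pet_only": {"channels": ("pet",), "use_asymmetry": False},
    "mri_only": {"channels": ("mri",), "use_asymmetry": False},
    "pet_mri": {"channels": ("mri", "pet"), "use_asymmetry": False},
    "all_information": {"channels": CHANNELS, "use_asymmetry": False},
    "improved": {"channels": CHANNELS, "use_asymmetry": True},
}


def run_ablation(
    subjects: list[SubjectRecord],
    atlas: ParcellationAtlas | None,
    base_cfg: PipelineConfig,
    k: int = 5,
    seed: int = 0,
    configs: dict[str, dict] | None = None,
) -> dict:
    """Cross-validate each input configuration (the published comparison set)."""
    configs = configs or ABLATION_CONFIGS
    out = {}
    for name, overrides in configs.items():
        cfg = replace(base_cfg, **overrides)
        out[name] = cross_validate(subjects, atlas, cfg, k=k, seed=seed)
        log.info("ablation %s: %s", name, out[name]["summary"]["auc"]["mean"])
    return out
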