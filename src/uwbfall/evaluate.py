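"""Evaluation protocols and fall-detection metrics.

Fall counting convention (falling is the positive class, all other
activities are non-falls):

* TP — fall samples predicted as falls;
* FN — fall samples predicted as any non-fall class (missed falls);
* FP — non-fall samples predicted as falls;
* TN — non-fall samples predicted as *their own* class.  A non-fall sample
  predicted as a different non-fall class counts toward neither TN nor FP —
  it simply drops out of the accuracy denominator.

With those counts: accuracy = (TP+TN)/(TP+FP+TN+FN),
sensitivity = TP/(TP+FN), specificity = TN/(TN+FP).  Sensitivity is
invariant to how non-fall errors are distributed among non-fall classes;
specificity and accuracy are not.

Protocols: stratified per-(subject, activity) split, leave-one-subject-out
cross-validation, cross-environment transfer without retraining, a
frames-per-sample sweep, and a subject-identification control that retrains
the same architecture on subject labels to check the model is not a covert
person identifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np

from .preprocess import PreprocessConfig, preprocess_dataset, trim_frames
from .network import ModelConfig, TrainedModel, build_model, train
from .radar_sim import FALL_CLASS, N_CLASSES, RawRecording


@dataclass
class FallCounts:
    tp: int
    fp: int
    tn: int
    fn: int


class MetricResult(NamedTuple):
    accuracy: float
    sensitivity: float
    specificity: float
    undefined: frozenset


@dataclass
class EvalReport:
    """Confusion matrix with fall metrics and protocol metadata."""

    confusion: np.ndarray  # (K, K), rows = true, cols = predicted
    accuracy: float
    sensitivity: float
    specificity: float
    multiclass_accuracy: float
    metadata: dict = field(default_factory=dict)


def confusion(true_labels, predicted_labels, k: int = N_CLASSES) -> np.ndarray:
    """K x K count matrix; rows index true class, columns predicted class."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    if t.size and (t.min() < 1 or t.max() > k or p.min() < 1 or p.max() > k):
        raise ValueError(f"labels must lie in 1..{k}")
    mat = np.zeros((k, k), dtype=int)
    np.add.at(mat, (t - 1, p - 1), 1)
    return mat


def fall_counts(conf: np.ndarray, fall_class: int = FALL_CLASS) -> FallCounts:
    """Extract TP/FP/TN/FN from a confusion matrix (1-based fall class)."""
    conf = np.asarray(conf)
    fc = fall_class - 1
    tp = int(conf[fc, fc])
    fn = int(conf[fc].sum() - tp)
    fp = int(conf[:, fc].sum() - tp)
    tn = int(np.trace(conf) - tp)
    return FallCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(counts: FallCounts) -> MetricResult:
    """Accuracy, sensitivity, specificity; zero denominators are flagged."""
    undefined = set()

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.add(name)
            return float("nan")
        return num / den

    acc = ratio(counts.tp + counts.tn, counts.tp + counts.fp + counts.tn + counts.fn, "accuracy")
    sens = ratio(counts.tp, counts.tp + counts.fn, "sensitivity")
    spec = ratio(counts.tn, counts.tn + counts.fp, "specificity")
    return MetricResult(acc, sens, spec, frozenset(undefined))


def evaluate_predictions(
    true_labels,
    predicted_labels,
    k: int = N_CLASSES,
    fall_class: int = FALL_CLASS,
    metadata: dict | None = None,
) -> EvalReport:
    conf = confusion(true_labels, predicted_labels, k)
    m = metrics(fall_counts(conf, fall_class))
    total = conf.sum()
    return EvalReport(
        confusion=conf,
        accuracy=m.accuracy,
        sensitivity=m.sensitivity,
        specificity=m.specificity,
        multiclass_accuracy=float(np.trace(conf) / total) if total else float("nan"),
        metadata=dict(metadata or {}),
    )


def _report_from_confusion(conf: np.ndarray, fall_class: int, metadata: dict) -> EvalReport:
    m = metrics(fall_counts(conf, fall_class))
    total = conf.sum()
    return EvalReport(
        confusion=conf,
        accuracy=m.accuracy,
        sensitivity=m.sensitivity,
        specificity=m.specificity,
        multiclass_accuracy=float(np.trace(conf) / total) if total else float("nan"),
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# dataset splitting


def _cell_key(item) -> tuple:
    return (item.subject_id, int(item.label))


def split_dataset(
    samples: Sequence,
    per_cell: dict | None = None,
    seed: int = 0,
) -> tuple[list, list, list]:
    """Stratified train/val/test split per (subject, activity) cell.

    ``per_cell`` gives the counts drawn from each cell, default
    {"train": 62, "val": 20, "test": 20} (the 102-sample campaign layout).
    Deterministic given the seed; the three sets are disjoint.
    """
    per_cell = per_cell or {"train": 62, "val": 20, "test": 20}
    need = per_cell["train"] + per_cell["val"] + per_cell["test"]
    cells: dict[tuple, list] = {}
    for item in samples:
        cells.setdefault(_cell_key(item), []).append(item)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 53]))
    train_set: list = []
    val_set: list = []
    test_set: list = []
    for key in sorted(cells):
        items = cells[key]
        if len(items) < need:
            raise ValueError(f"cell {key} has {len(items)} samples, needs >= {need}")
        order = rng.permutation(len(items))
        chosen = [items[i] for i in order]
        a = per_cell["train"]
        b = a + per_cell["val"]
        train_set += chosen[:a]
        val_set += chosen[a:b]
        test_set += chosen[b:need]
    return train_set, val_set, test_set


def proportional_cell_counts(cell_size: int) -> dict:
    """Scale the 62/20/20 split ratios to a smaller per-cell sample count."""
    train = round(cell_size * 62 / 102)
    val = round(cell_size * 20 / 102)
    return {"train": train, "val": val, "test": cell_size - train - val}


# ---------------------------------------------------------------------------
# protocols that train models


def _fit_and_eval(
    train_recs: list[RawRecording],
    val_recs: list[RawRecording],
    test_recs: list[RawRecording],
    preprocess_cfg: PreprocessConfig,
    model_cfg: ModelConfig,
    seed: int,
    metadata: dict,
    augment: bool = True,
    relabel=None,
) -> tuple[EvalReport, TrainedModel]:
    def prep(recs, aug):
        samples = preprocess_dataset(recs, preprocess_cfg, augment=aug)
        if relabel is not None:
            samples = [replace(s, label=relabel(s)) for s in samples]
        return samples

    tr = prep(train_recs, augment)
    va = prep(val_recs, False)
    te = prep(test_recs, False)
    cfg = replace(model_cfg, seed=seed)
    net = build_model(cfg)
    model = train(net, tr, va, cfg)
    if train_recs:
        model.environment_id = train_recs[0].environment_id
    y_true = np.array([int(s.label) for s in te])
    y_pred = model.predict(te)
    report = evaluate_predictions(y_true, y_pred, k=cfg.n_classes, metadata=metadata)
    return report, model


@dataclass
class LosoResult:
    folds: list
    pooled: EvalReport


def loso_cv(
    recordings: Sequence[RawRecording],
    preprocess_cfg: PreprocessConfig,
    model_cfg: ModelConfig,
    seed: int = 0,
    augment: bool = True,
) -> LosoResult:
    """Leave-one-subject-out cross-validation.

    One fold per subject: that subject's recordings form the test set; each
    remaining subject's recordings are divided into four folds, three for
    training and one for validation.  Pooled metrics are micro-averaged
    from the summed confusion matrices.
    """
    subjects = sorted({r.subject_id for r in recordings})
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least two subjects")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 59]))
    folds = []
    pooled_conf = np.zeros((model_cfg.n_classes, model_cfg.n_classes), dtype=int)
    for fold_i, test_subject in enumerate(subjects):
        test_recs = [r for r in recordings if r.subject_id == test_subject]
        train_recs: list[RawRecording] = []
        val_recs: list[RawRecording] = []
        for other in subjects:
            if other == test_subject:
                continue
            theirs = [r for r in recordings if r.subject_id == other]
            order = rng.permutation(len(theirs))
            quarter = len(theirs) // 4
            val_idx = set(order[:quarter].tolist())
            for i, rec in enumerate(theirs):
                (val_recs if i in val_idx else train_recs).append(rec)
        report, _ = _fit_and_eval(
            train_recs,
            val_recs,
            test_recs,
            preprocess_cfg,
            model_cfg,
            seed=seed + fold_i,
            metadata={"protocol": "loso", "test_subject": test_subject, "seed": seed},
            augment=augment,
        )
        folds.append(report)
        pooled_conf += report.confusion
    pooled = _report_from_confusion(pooled_conf, FALL_CLASS, {"protocol": "loso-pooled", "seed": seed})
    return LosoResult(folds=folds, pooled=pooled)


def transfer_eval(
    model: TrainedModel,
    target_recordings: Sequence[RawRecording],
    preprocess_cfg: PreprocessConfig,
) -> EvalReport:
    """Evaluate a trained model on another environment without retraining."""
    if not target_recordings:
        raise ValueError("target environment sample set is empty")
    target_env = target_recordings[0].environment_id
    if model.environment_id is not None and model.environment_id == target_env:
        warnings.warn("target environment equals the training environment", stacklevel=2)
    samples = preprocess_dataset(list(target_recordings), preprocess_cfg, augment=False)
    y_true = np.array([int(s.label) for s in samples])
    y_pred = model.predict(samples)
    return evaluate_predictions(
        y_true,
        y_pred,
        k=model.config.n_classes,
        metadata={
            "protocol": "transfer",
            "train_environment": model.environment_id,
            "test_environment": target_env,
        },
    )


def frames_sweep(
    recordings: Sequence[RawRecording],
    frame_counts: Sequence[int],
    preprocess_cfg: PreprocessConfig,
    model_cfg: ModelConfig,
    seed: int = 0,
    per_cell: dict | None = None,
    augment: bool = True,
) -> dict[int, EvalReport]:
    """Retrain and evaluate at each frames-per-sample count.

    Shorter samples are derived from the full-length ones by alternately
    removing frames from the two ends.
    """
    m = recordings[0].n_frames if recordings else 0
    for c in frame_counts:
        if not (1 <= c <= m):
            raise ValueError(f"frame count {c} outside [1, {m}]")
    train_recs, val_recs, test_recs = split_dataset(recordings, per_cell, seed=seed)
    out: dict[int, EvalReport] = {}
    for count in frame_counts:
        def relabel(_s):
            return _s.label

        def prep_trim(recs, aug):
            samples = preprocess_dataset(recs, preprocess_cfg, augment=aug)
            return [trim_frames(s, count) for s in samples]

        tr = prep_trim(train_recs, augment)
        va = prep_trim(val_recs, False)
        te = prep_trim(test_recs, False)
        cfg = replace(model_cfg, n_frames=count, seed=seed)
        net = build_model(cfg)
        model = train(net, tr, va, cfg)
        y_true = np.array([int(s.label) for s in te])
        y_pred = model.predict(te)
        out[count] = evaluate_predictions(
            y_true, y_pred, k=cfg.n_classes, metadata={"protocol": "frames-sweep", "frames": count, "seed": seed}
        )
    return out


@dataclass
class SubjectIdResult:
    accuracy: float
    chance_level: float
    n_subjects: int
    confusion: np.ndarray


def subject_id_control(
    recordings: Sequence[RawRecording],
    preprocess_cfg: PreprocessConfig,
    model_cfg: ModelConfig,
    seed: int = 0,
    per_cell: dict | None = None,
    augment: bool = True,
) -> SubjectIdResult:
    """Privacy control: retrain the architecture on subject-identity labels.

    Reports plain multiclass accuracy against the 1/n_subjects chance
    level; accuracy near chance means the learned features do not expose
    who the person is.
    """
    subjects = sorted({r.subject_id for r in recordings})
    if len(subjects) < 2:
        raise ValueError("subject identification control needs >= 2 subjects")
    serial = {s: i + 1 for i, s in enumerate(subjects)}
    train_recs, val_recs, test_recs = split_dataset(recordings, per_cell, seed=seed)
    cfg = replace(model_cfg, n_classes=len(subjects), seed=seed)

    def prep(recs, aug):
        samples = preprocess_dataset(recs, preprocess_cfg, augment=aug)
        return [replace(s, label=serial[s.subject_id]) for s in samples]

    tr, va, te = prep(train_recs, augment), prep(val_recs, False), prep(test_recs, False)
    net = build_model(cfg)
    model = train(net, tr, va, cfg)
    y_true = np.array([int(s.label) for s in te])
    y_pred = model.predict(te)
    conf = confusion(y_true, y_pred, k=len(subjects))
    return SubjectIdResult(
        accuracy=float(np.trace(conf) / conf.sum()),
        chance_level=1.0 / len(subjects),
        n_subjects=len(subjects),
        confusion=conf,
    )
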