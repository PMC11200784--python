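"""Training protocol and stratified cross-validated evaluation.

Training uses Adam (initial learning rate 0.001, batch size 32) with softmax
cross-entropy.  Evaluation follows ten-fold cross-validation with stratified
sampling at the *subject* level: all breaths of a subject share a fold, the
training folds alone are augmented (3×), and held-out subjects are scored by
majority vote over their breaths.  Metrics come from the pooled confusion
matrix: accuracy = trace/total; precision TP/(TP+FP); recall TP/(TP+FN);
F1 = 2·P·R/(P+R).  Multiclass metrics are macro-averaged one-vs-rest, with
F1 averaged per class (not recomputed from the averaged P and R).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import augment as aug
from . import gaf
from . import preprocess
from .model import CapnoNet, ModelConfig, build_capnonet
from .nn import Adam, softmax_cross_entropy

__all__ = [
    "CVConfig",
    "MetricsReport",
    "CVResult",
    "stratified_subject_folds",
    "train_model",
    "compute_metrics",
    "binary_f1",
    "run_cv",
]


@dataclasses.dataclass(frozen=True)
class CVConfig:
    """Cross-validation run parameters."""

    task: str = "detect"  # 'detect' (normal vs COPD) or 'grade' (GOLD classes)
    encoding: str = "gasf"
    k: int = 10
    epochs: int = 30
    lr: float = 0.001
    batch_size: int = 32
    augment: bool = True
    seed: int = 0


@dataclasses.dataclass(frozen=True)
class MetricsReport:
    """Confusion matrix (rows = truth, columns = prediction) plus summary metrics."""

    confusion: np.ndarray
    classes: tuple[str, ...]
    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class: dict[str, dict[str, float]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.confusion,
            index=[f"true_{c}" for c in self.classes],
            columns=[f"pred_{c}" for c in self.classes],
        )


@dataclasses.dataclass(frozen=True)
class CVResult:
    fold_reports: list[MetricsReport]
    pooled: MetricsReport
    pooled_breath: MetricsReport
    fold_plan: dict[str, int]
    fold_train_subjects: list[set[str]]
    fold_test_subjects: list[set[str]]


def stratified_subject_folds(
    manifest: pd.DataFrame, k: int = 10, seed: int = 0, label_col: str = "label"
) -> dict[str, int]:
    """Assign subjects (not breaths) to k folds, stratified by class.

    Within each class, subjects are shuffled with the seeded generator and
    dealt round-robin, so per-fold class counts differ from the global
    proportions by at most one subject.
    """
    subjects = manifest.drop_duplicates("subject_id")[["subject_id", label_col]]
    if len(subjects) < k:
        raise ValueError(f"need at least {k} subjects, got {len(subjects)}")
    rng = np.random.default_rng(seed)
    plan: dict[str, int] = {}
    next_fold = 0  # continue the deal across classes to balance fold sizes
    for cls in sorted(subjects[label_col].unique()):
        ids = sorted(subjects.loc[subjects[label_col] == cls, "subject_id"])
        rng.shuffle(ids)
        for sid in ids:
            plan[sid] = next_fold % k
            next_fold += 1
    return plan


def images_to_tensor(images: Sequence[np.ndarray]) -> np.ndarray:
    """uint8 grayscale images → float32 batch in [-1, 1], shape (N, 1, H, W)."""
    x = np.stack(images).astype(np.float32)
    return (x / 127.5 - 1.0)[:, None, :, :]


def _recalibrate_bn(model: CapnoNet, x: np.ndarray, batch_size: int) -> None:
    """Replace BN running statistics by exact averages over the training set.

    With few optimizer steps the momentum-tracked running estimates lag the
    true activation statistics, which distorts inference-mode predictions.
    One forward sweep with a cumulative-average momentum schedule sets each
    BN layer's running mean/variance to the mean of its batch statistics
    ("precise BN").
    """
    bns = [l for l in model.param_layers() if hasattr(l, "running_mean")]
    saved = [l.momentum for l in bns]
    for l in bns:
        l.running_mean[:] = 0.0
        l.running_var[:] = 0.0
    for i, start in enumerate(range(0, len(x), batch_size)):
        for l in bns:
            l.momentum = 1.0 / (i + 1)
        model.forward(x[start : start + batch_size], train=True)
    for l, m in zip(bns, saved):
        l.momentum = m


def train_model(
    model: CapnoNet,
    images: Sequence[np.ndarray],
    labels: Sequence[int],
    lr: float = 0.001,
    batch_size: int = 32,
    epochs: int = 30,
    seed: int = 0,
) -> tuple[CapnoNet, list[float]]:
    """Train in place with Adam + cross-entropy; returns per-epoch mean loss."""
    if len(images) == 0:
        raise ValueError("training set is empty")
    y = np.asarray(labels, dtype=np.int64)
    if len(y) != len(images):
        raise ValueError("images and labels must have equal length")
    x = images_to_tensor(images)
    rng = np.random.default_rng(seed)
    opt = Adam(model.param_layers(), lr=lr)
    history: list[float] = []
    n = len(y)
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            logits = model.forward(x[idx], train=True)
            loss, dlogits = softmax_cross_entropy(logits, y[idx])
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    if epochs > 0:
        _recalibrate_bn(model, x, batch_size)
    return model, history


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def compute_metrics(
    confusion: np.ndarray, classes: Sequence[str] | None = None
) -> MetricsReport:
    """Accuracy/precision/recall/F1 from a confusion matrix.

    Binary case: metrics of the positive class (index 1) from TP/FP/TN/FN.
    Multiclass: accuracy = trace/total; precision/recall/F1 macro-averaged
    one-vs-rest, with F1 averaged per class.
    """
    conf = np.asarray(confusion)
    if conf.ndim != 2 or conf.shape[0] != conf.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(conf < 0):
        raise ValueError("confusion matrix entries must be non-negative")
    total = conf.sum()
    if total == 0:
        raise ValueError("confusion matrix is all zeros")
    c = conf.shape[0]
    names = tuple(classes) if classes is not None else tuple(str(i) for i in range(c))
    accuracy = float(np.trace(conf) / total)
    per_class: dict[str, dict[str, float]] = {}
    for i, name in enumerate(names):
        tp = float(conf[i, i])
        fp = float(conf[:, i].sum() - tp)
        fn = float(conf[i, :].sum() - tp)
        p = _safe_div(tp, tp + fp)
        r = _safe_div(tp, tp + fn)
        f1 = _safe_div(2 * p * r, p + r)
        per_class[name] = {"precision": p, "recall": r, "f1": f1}
    if c == 2:
        pos = names[1]
        precision = per_class[pos]["precision"]
        recall = per_class[pos]["recall"]
        f1 = per_class[pos]["f1"]
    else:
        precision = float(np.mean([m["precision"] for m in per_class.values()]))
        recall = float(np.mean([m["recall"] for m in per_class.values()]))
        f1 = float(np.mean([m["f1"] for m in per_class.values()]))
    return MetricsReport(
        confusion=conf.copy(),
        classes=names,
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        per_class=per_class,
    )


def binary_f1(precision: float, recall: float) -> float:
    """F1 = 2·P·R / (P + R), the harmonic mean of precision and recall."""
    return _safe_div(2 * precision * recall, precision + recall)


def _class_order(labels: Sequence[str]) -> list[str]:
    """'normal' first (negative class), remaining classes sorted."""
    uniq = sorted(set(labels))
    if "normal" in uniq:
        uniq.remove("normal")
        return ["normal"] + uniq
    return uniq


def encode_cohort(
    manifest: pd.DataFrame,
    records: Mapping[str, pd.DataFrame],
    encoding: str = "gasf",
    label_col: str = "label",
) -> tuple[dict[str, list[np.ndarray]], dict[str, str]]:
    """Preprocess and GAF-encode every breath, grouped by subject.

    Returns (subject → list of images, subject → class label).  Records that
    yield no valid breath contribute nothing.
    """
    by_subject: dict[str, list[np.ndarray]] = {}
    subject_label: dict[str, str] = {}
    for row in manifest.itertuples(index=False):
        raw = records[row.record_path]
        for series in preprocess.preprocess_record(raw):
            img = gaf.encode_image(series, kind=encoding)
            by_subject.setdefault(row.subject_id, []).append(img)
        subject_label[row.subject_id] = getattr(row, label_col)
    return by_subject, subject_label


def run_cv(
    manifest: pd.DataFrame,
    records: Mapping[str, pd.DataFrame],
    cfg: CVConfig = CVConfig(),
) -> CVResult:
    """Stratified k-fold cross-validation of CapnoNet on a cohort.

    For each fold: augment the training folds (3× when enabled), train a
    freshly initialized model, predict every held-out breath, aggregate to
    subjects by majority vote, and pool confusion matrices across folds.
    """
    label_col = "label" if cfg.task == "detect" else "grade"
    by_subject, subject_label = encode_cohort(
        manifest, records, encoding=cfg.encoding, label_col=label_col
    )
    classes = _class_order(list(subject_label.values()))
    cls_idx = {c: i for i, c in enumerate(classes)}
    plan = stratified_subject_folds(
        manifest, k=cfg.k, seed=cfg.seed, label_col=label_col
    )

    n_cls = len(classes)
    pooled_subj = np.zeros((n_cls, n_cls), dtype=np.int64)
    pooled_breath = np.zeros((n_cls, n_cls), dtype=np.int64)
    fold_reports: list[MetricsReport] = []
    fold_train: list[set[str]] = []
    fold_test: list[set[str]] = []

    for fold in range(cfg.k):
        test_subjects = {s for s, f in plan.items() if f == fold and s in by_subject}
        train_subjects = {s for s in plan if s not in test_subjects and s in by_subject}
        fold_train.append(train_subjects)
        fold_test.append(test_subjects)

        train_imgs: list[np.ndarray] = []
        train_labels: list[int] = []
        for sid in sorted(train_subjects):
            for img in by_subject[sid]:
                train_imgs.append(img)
                train_labels.append(cls_idx[subject_label[sid]])
        if cfg.augment:
            train_imgs, train_labels = aug.expand_training_set(
                train_imgs, train_labels, seed=cfg.seed * 1000 + fold
            )

        model = build_capnonet(
            ModelConfig(n_classes=n_cls), seed=cfg.seed * 1000 + fold
        )
        train_model(
            model,
            train_imgs,
            train_labels,
            lr=cfg.lr,
            batch_size=cfg.batch_size,
            epochs=cfg.epochs,
            seed=cfg.seed * 1000 + fold,
        )

        conf = np.zeros((n_cls, n_cls), dtype=np.int64)
        for sid in sorted(test_subjects):
            imgs = by_subject[sid]
            preds = []
            x = images_to_tensor(imgs)
            for start in range(0, len(imgs), cfg.batch_size):
                preds.extend(model.predict(x[start : start + cfg.batch_size]))
            truth = cls_idx[subject_label[sid]]
            for p in preds:
                pooled_breath[truth, int(p)] += 1
            vote = int(np.bincount(preds, minlength=n_cls).argmax())
            conf[truth, vote] += 1
        pooled_subj += conf
        if conf.sum() > 0:
            fold_reports.append(compute_metrics(conf, classes))

    return CVResult(
        fold_reports=fold_reports,
        pooled=compute_metrics(pooled_subj, classes),
        pooled_breath=compute_metrics(pooled_breath, classes),
        fold_plan=plan,
        fold_train_subjects=fold_train,
        fold_test_subjects=fold_test,
    )
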