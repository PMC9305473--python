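"""Classification metrics and the desk-scale ablation harness.

Metrics follow the macro-averaging convention used throughout the tables this
package reports: per-class precision/recall from one-vs-rest confusion
counts, macro precision/recall as their unweighted class means, and macro-F1
as the harmonic mean *of the two macro averages* (not the mean of per-class
F1 scores — the two differ). Accuracy is the proportion of correctly
classified samples (confusion-matrix trace over total). Percentages round
half-up to two decimals in reports.

Zero-denominator ratios are reported as 0 with an explicit ``undefined`` flag
so macro averages stay defined on degenerate confusion matrices.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "MacroMetrics",
    "confusion",
    "class_metrics",
    "macro_metrics",
    "f1_score",
    "round2",
    "run_ablation",
    "PAPER_ABLATION_VARIANTS",
]


def round2(x: float) -> float:
    """Round half-up to 2 decimals (table formatting convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """K x K counts; rows = actual class, columns = predicted class."""

    counts: np.ndarray

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ClassMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float  # percent
    recall: float  # percent
    f1: float  # percent
    undefined: set = field(default_factory=set)


@dataclass
class MacroMetrics:
    accuracy: float  # percent
    precision_macro: float
    recall_macro: float
    f1_macro: float


def confusion(y_true, y_pred, n_classes: int) -> ConfusionMatrix:
    """Confusion matrix over labels 0..K-1."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences differ in length")
    for arr in (y_true, y_pred):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError("label out of range")
    counts = _sk_confusion(y_true, y_pred, labels=np.arange(n_classes))
    return ConfusionMatrix(counts=counts.astype(np.int64))


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (percent in, percent out)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def class_metrics(cm: ConfusionMatrix, k: int) -> ClassMetrics:
    """One-vs-rest metrics of class k, as percentages."""
    c = cm.counts
    tp = int(c[k, k])
    fp = int(c[:, k].sum() - tp)
    fn = int(c[k, :].sum() - tp)
    tn = int(c.sum() - tp - fp - fn)
    undefined = set()
    if tp + fp == 0:
        precision = 0.0
        undefined.add("precision")
    else:
        precision = 100.0 * tp / (tp + fp)
    if tp + fn == 0:
        recall = 0.0
        undefined.add("recall")
    else:
        recall = 100.0 * tp / (tp + fn)
    if precision + recall == 0:
        undefined.add("f1")
    return ClassMetrics(
        tp=tp, fp=fp, fn=fn, tn=tn,
        precision=precision, recall=recall, f1=f1_score(precision, recall),
        undefined=undefined,
    )


def macro_metrics(cm: ConfusionMatrix) -> MacroMetrics:
    """Accuracy plus macro precision/recall/F1, as percentages."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    if cm.n_classes < 1:
        raise ValueError("need at least one class")
    per_class = [class_metrics(cm, k) for k in range(cm.n_classes)]
    p_macro = float(np.mean([m.precision for m in per_class]))
    r_macro = float(np.mean([m.recall for m in per_class]))
    accuracy = 100.0 * float(np.trace(cm.counts)) / cm.total
    return MacroMetrics(
        accuracy=accuracy,
        precision_macro=p_macro,
        recall_macro=r_macro,
        f1_macro=f1_score(p_macro, r_macro),
    )


# ---------------------------------------------------------------------------
# Ablation harness
# ---------------------------------------------------------------------------

# The five structural variants of the ablation table: backbone alone, each
# front-end branch alone, attention alone, and the full model.
PAPER_ABLATION_VARIANTS: tuple[tuple[str, dict], ...] = (
    ("backbone", dict(use_color_branch=False, use_texture_branch=False, use_mdam=False)),
    ("backbone+correlogram", dict(use_color_branch=True, use_texture_branch=False, use_mdam=False)),
    ("backbone+acri_lbp", dict(use_color_branch=False, use_texture_branch=True, use_mdam=False)),
    ("backbone+mdam", dict(use_color_branch=False, use_texture_branch=False, use_mdam=True)),
    ("full", dict(use_color_branch=True, use_texture_branch=True, use_mdam=True)),
)


@dataclass
class AblationRow:
    variant: str
    accuracy: float | None
    precision_macro: float | None
    recall_macro: float | None
    f1_macro: float | None
    n_parameters: int | None
    wall_time_s: float | None
    error: str | None = None


def run_ablation(
    dataset,
    variants=PAPER_ABLATION_VARIANTS,
    base_config=None,
    epochs: int = 1,
    batch_size: int = 8,
    lr: float = 1e-3,
    seed: int = 0,
) -> list[AblationRow]:
    """Train/evaluate each structural variant with an identical seed/budget.

    ``dataset`` is a :class:`~mdam_drnet.fixtures.SyntheticDataset`; every
    variant shares the same split, seed and epoch budget. A variant that
    fails to construct is reported in its row and the run continues.
    """
    from .drnet import NetworkConfig, build_network, train_network
    from dataclasses import replace

    if len(variants) < 2:
        raise ValueError("need at least two variants")
    if base_config is None:
        base_config = NetworkConfig()
    train_imgs, train_y = dataset.subset("train")
    test_imgs, test_y = dataset.subset("test")
    n_classes = len(dataset.class_names)
    rows: list[AblationRow] = []
    for name, flags in variants:
        t0 = time.perf_counter()
        try:
            cfg = replace(base_config, seed=seed, num_classes=n_classes, **flags)
            net = build_network(cfg)
            n_params = net.n_parameters()
            if epochs > 0:
                train_network(net, train_imgs, train_y, epochs=epochs,
                              batch_size=batch_size, lr=lr, seed=seed)
            pred = net.predict(test_imgs)
            mm = macro_metrics(confusion(test_y, pred, n_classes))
            rows.append(AblationRow(
                variant=name,
                accuracy=round2(mm.accuracy),
                precision_macro=round2(mm.precision_macro),
                recall_macro=round2(mm.recall_macro),
                f1_macro=round2(mm.f1_macro),
                n_parameters=n_params,
                wall_time_s=time.perf_counter() - t0,
            ))
        except Exception as exc:  # noqa: BLE001 - per-row error reporting
            rows.append(AblationRow(
                variant=name, accuracy=None, precision_macro=None,
                recall_macro=None, f1_macro=None, n_parameters=None,
                wall_time_s=time.perf_counter() - t0, error=str(exc),
            ))
    return rows


def ablation_table(rows: list[AblationRow]) -> str:
    """TSV rendering of an ablation run."""
    header = "variant\taccuracy\tprecision_macro\trecall_macro\tf1_macro\tparameters\twall_time_s\terror"
    lines = [header]
    for r in rows:
        fmt = lambda v: "" if v is None else (f"{v:.2f}" if isinstance(v, float) else str(v))
        lines.append("\t".join([
            r.variant, fmt(r.accuracy), fmt(r.precision_macro), fmt(r.recall_macro),
            fmt(r.f1_macro), fmt(r.n_parameters),
            "" if r.wall_time_s is None else f"{r.wall_time_s:.2f}",
            r.error or "",
        ]))
    return "\n".join(lines)
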