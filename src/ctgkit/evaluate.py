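"""Training harness and the full metric suite for the CTG classifier.

Conventions follow the clinical read-out: the *normal* CTG class is the
positive category, so TP counts correctly predicted normals and TN
correctly predicted abnormals. The ROC/AUC sweep, by contrast, scores
the abnormal-class probability (AUC is invariant to which class anchors
the sweep). GDR (generalization decay rate) is the relative AUC drop
from the training site to an external site, in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layout import ChartImage
from .model import DenseNetSK
from .nn import Adam, Tensor, focal_loss_logits, softmax
from .nn import core as F
from .records import BinaryLabel, CTGRecord

__all__ = [
    "TrainConfig",
    "EvalReport",
    "split_dataset",
    "prepare_inputs",
    "labels_to_ints",
    "train",
    "predict_logits",
    "predict",
    "compute_metrics",
    "roc_auc",
    "gdr",
]

#: GDR above this percentage flags the need for domain adaptation.
GDR_ADAPTATION_THRESHOLD = 15.0


@dataclass
class TrainConfig:
    epochs: int = 100
    learning_rate: float = 0.001
    batch_size: int = 32
    optimizer: str = "adam"
    loss: str = "focal"
    gamma: float = 2.0
    alpha: float = 0.25
    split: tuple[float, float] = (0.7, 0.3)
    seed: int = 0

    def __post_init__(self):
        if not np.isclose(sum(self.split), 1.0):
            raise ValueError("split fractions must sum to 1")
        if self.optimizer != "adam":
            raise ValueError("only the Adam optimizer is supported")


@dataclass
class EvalReport:
    confusion: np.ndarray  # [[TP, FN], [FP, TN]], normal = positive
    precision_normal: float
    precision_abnormal: float
    recall_normal: float
    recall_abnormal: float
    f1_normal: float
    f1_abnormal: float
    accuracy: float
    n: int
    roc: list[tuple[float, float]] | None = None
    auc: float | None = None

    def to_dict(self) -> dict:
        d = {
            "confusion": np.asarray(self.confusion).tolist(),
            "precision_normal": self.precision_normal,
            "precision_abnormal": self.precision_abnormal,
            "recall_normal": self.recall_normal,
            "recall_abnormal": self.recall_abnormal,
            "f1_normal": self.f1_normal,
            "f1_abnormal": self.f1_abnormal,
            "accuracy": self.accuracy,
            "n": self.n,
            "auc": self.auc,
        }
        if self.roc is not None:
            d["roc"] = [list(p) for p in self.roc]
        return d


# ----------------------------------------------------------------------
def _binary_int(label) -> int:
    """0 = normal, 1 = abnormal."""
    if isinstance(label, BinaryLabel):
        return 0 if label == BinaryLabel.NORMAL else 1
    if isinstance(label, str):
        return 0 if label == "normal" else 1
    return int(label)


def labels_to_ints(items) -> np.ndarray:
    out = []
    for item in items:
        if isinstance(item, CTGRecord):
            out.append(_binary_int(item.binary_label))
        elif isinstance(item, tuple):
            out.append(_binary_int(item[1].binary_label))
        else:
            out.append(_binary_int(item))
    return np.asarray(out, dtype=int)


def _largest_remainder(total: int, fractions: np.ndarray) -> np.ndarray:
    raw = fractions * total
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts))[: total - counts.sum()]:
        counts[i] += 1
    return counts


def split_dataset(records, fractions=(0.7, 0.3), seed: int = 0, stratify: bool = True,
                  labels=None):
    """Disjoint, exhaustive train/test partition, stratified by binary label.

    Counts use largest-remainder rounding (326 records at 7:3 give
    228/98). With stratification, each class is split at the same ratio;
    a class that would vanish from a non-empty side is rejected.
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.shape != (2,) or np.any(fractions < 0) or not np.isclose(fractions.sum(), 1.0):
        raise ValueError("fractions must be two non-negative values summing to 1")
    n = len(records)
    if n == 0:
        raise ValueError("cannot split an empty dataset")
    y = labels_to_ints(records) if labels is None else np.asarray([_binary_int(v) for v in labels])
    rng = np.random.default_rng(seed)
    n_train = int(_largest_remainder(n, fractions)[0])

    if not stratify:
        order = rng.permutation(n)
        tr, te = order[:n_train], order[n_train:]
    else:
        classes = np.unique(y)
        raw = np.array([fractions[0] * (y == c).sum() for c in classes])
        per_class = np.floor(raw).astype(int)
        for i in np.argsort(-(raw - per_class))[: n_train - per_class.sum()]:
            per_class[i] += 1
        tr_idx, te_idx = [], []
        for c, k in zip(classes, per_class):
            idx = rng.permutation(np.where(y == c)[0])
            if fractions[0] > 0 and fractions[1] > 0 and (k == 0 or k == len(idx)):
                raise ValueError(
                    f"class {c} would be absent from one side of the stratified split"
                )
            tr_idx.append(idx[:k])
            te_idx.append(idx[k:])
        tr = np.concatenate(tr_idx) if tr_idx else np.array([], int)
        te = np.concatenate(te_idx) if te_idx else np.array([], int)
        tr, te = rng.permutation(tr), rng.permutation(te)
    return [records[i] for i in tr], [records[i] for i in te]


# ----------------------------------------------------------------------
def prepare_inputs(images, size: tuple[int, int] | None = None,
                   mask_uc: bool = False) -> np.ndarray:
    """Charts -> normalized (N, 1, H, W) float32 batch (ink ~ 1, paper ~ 0).

    ``mask_uc`` blanks the UC band (plus a small margin) before
    normalization — the FHR-only ablation input.
    """
    batch = []
    for img in images:
        if isinstance(img, ChartImage):
            px = img.pixels if img.pixels.ndim == 2 else img.pixels.mean(axis=2)
            px = px.astype(np.float32)
            if mask_uc:
                a, b = img.layout.uc_band
                px = px.copy()
                px[max(a - 2, 0) : b + 3, :] = img.layout.background_intensity
        else:
            px = np.asarray(img, dtype=np.float32)
        x = 1.0 - px / 255.0
        if size is not None and x.shape != tuple(size):
            from skimage.transform import resize

            x = resize(x, size, anti_aliasing=True).astype(np.float32)
        batch.append(x)
    return np.stack(batch)[:, None, :, :].astype(np.float32)


def recalibrate_bn(model: DenseNetSK, X: np.ndarray, batch_size: int = 32) -> None:
    """Re-estimate BN running statistics as the population average over X.

    After short, fast-moving training runs the exponentially averaged
    statistics trail the current weights badly enough to wreck eval-mode
    predictions; a calibration sweep fixes the mismatch.
    """
    from .nn.layers import BatchNorm

    bns = [m for m in model.walk() if isinstance(m, BatchNorm)]
    if not bns:
        return
    for bn in bns:
        bn.running_mean[...] = 0.0
        bn.running_var[...] = 0.0
    momenta = [bn.momentum for bn in bns]
    model.train()
    with F.no_grad():
        for k, i in enumerate(range(0, len(X), batch_size)):
            for bn in bns:
                bn.momentum = 1.0 / (k + 1)  # cumulative average
            model(Tensor(X[i : i + batch_size]))
    for bn, m in zip(bns, momenta):
        bn.momentum = m
    model.eval()


def predict_logits(model: DenseNetSK, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
    model.eval()
    out = []
    with F.no_grad():
        for i in range(0, len(X), batch_size):
            out.append(model(Tensor(X[i : i + batch_size])).data)
    return np.concatenate(out) if out else np.zeros((0, model.config.num_classes))


def predict(model: DenseNetSK, X: np.ndarray, batch_size: int = 64):
    """Return (predicted class ints, abnormal-class probabilities)."""
    logits = predict_logits(model, X, batch_size)
    probs = softmax(logits)
    return logits.argmax(axis=1), probs[:, 1]


def train(model: DenseNetSK, data, cfg: TrainConfig, val_data=None):
    """Fit with Adam + focal loss; keep the best-validation-accuracy state.

    ``data`` and ``val_data`` are (X, y) arrays. Returns (model, history)
    where history records per-epoch mean loss and validation accuracy.
    Diverging (NaN) loss aborts with a diagnostic.
    """
    X, y = data
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    history = {"loss": [], "val_accuracy": []}
    best = (-1.0, None)
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(len(X))
        losses = []
        for i in range(0, len(X), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            opt.zero_grad()
            logits = model(Tensor(X[idx]))
            loss = focal_loss_logits(logits, y[idx], cfg.gamma, cfg.alpha)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, batch {i // cfg.batch_size}"
                )
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            del logits, loss  # free this batch's graph before the next forward
        history["loss"].append(float(np.mean(losses)))
        if val_data is not None:
            recalibrate_bn(model, X, cfg.batch_size)
            pred, _ = predict(model, val_data[0], cfg.batch_size)
            acc = float((pred == np.asarray(val_data[1], int)).mean())
            history["val_accuracy"].append(acc)
            if acc > best[0]:
                best = (acc, model.state_dict())
    if cfg.epochs > 0 and val_data is None:
        recalibrate_bn(model, X, cfg.batch_size)
    if best[1] is not None:
        model.load_state_dict(best[1])
    return model, history


# ----------------------------------------------------------------------
def compute_metrics(labels, predictions, scores=None) -> EvalReport:
    """Confusion matrix and per-class precision/recall/F1 plus accuracy.

    ``labels``/``predictions`` are normal/abnormal (ints 0/1, strings or
    BinaryLabel). Normal is the positive category. With ``scores``
    (abnormal-class probability) the ROC curve and AUC are included.
    """
    y = np.asarray([_binary_int(v) for v in labels])
    p = np.asarray([_binary_int(v) for v in predictions])
    if len(y) == 0:
        raise ValueError("empty input")
    if len(y) != len(p):
        raise ValueError("labels and predictions must have equal length")
    tp = int(((y == 0) & (p == 0)).sum())
    fn = int(((y == 0) & (p == 1)).sum())
    fp = int(((y == 1) & (p == 0)).sum())
    tn = int(((y == 1) & (p == 1)).sum())

    def _div(a, b):
        return a / b if b else 0.0

    prec_n = _div(tp, tp + fp)
    prec_a = _div(tn, tn + fn)
    rec_n = _div(tp, tp + fn)
    rec_a = _div(tn, tn + fp)
    f1_n = _div(2 * prec_n * rec_n, prec_n + rec_n)
    f1_a = _div(2 * prec_a * rec_a, prec_a + rec_a)
    roc = auc = None
    if scores is not None and len(np.unique(y)) == 2:
        roc, auc = roc_auc(y, np.asarray(scores, float))
    return EvalReport(
        confusion=np.array([[tp, fn], [fp, tn]]),
        precision_normal=prec_n,
        precision_abnormal=prec_a,
        recall_normal=rec_n,
        recall_abnormal=rec_a,
        f1_normal=f1_n,
        f1_abnormal=f1_a,
        accuracy=_div(tp + tn, len(y)),
        n=len(y),
        roc=roc,
        auc=auc,
    )


def roc_auc(labels, scores):
    """ROC by descending-threshold sweep; AUC by the trapezoid rule.

    ``labels`` mark the positive class with 1; higher scores mean more
    positive. Tied scores cross their threshold simultaneously, which
    makes the trapezoid AUC equal the pairwise-comparison probability
    with ties counted 1/2. Requires both classes present.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tps = np.cumsum(y_sorted == 1)
    fps = np.cumsum(y_sorted == 0)
    last = np.r_[np.diff(s_sorted) != 0, True]  # keep one point per distinct score
    tpr = np.r_[0.0, tps[last] / n_pos]
    fpr = np.r_[0.0, fps[last] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def gdr(auc_train: float, auc_external: float) -> tuple[float, bool]:
    """Generalization decay rate, percent, with the >15% adaptation flag."""
    if auc_train <= 0:
        raise ValueError("auc_train must be positive")
    value = (auc_train - auc_external) / auc_train * 100.0
    return value, value > GDR_ADAPTATION_THRESHOLD
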