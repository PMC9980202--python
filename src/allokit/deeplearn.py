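"""Contact-image classification, gradient saliency, and contact selection.

The classifier is a small 2D CNN over contact-map images, one class per
condition label. Attribution uses vanilla input gradients: the absolute
gradient of the target-class logit with respect to each contact pixel,
computed on the contact map of the most populated conformational cluster,
symmetrized and max-normalized to [0, 1]. Characteristic contacts are the
pairs with normalized gradient >= 0.7 whose BOTH residues show a
significant flexibility change upon modulator binding; a pair with a
non-significant member is dropped regardless of gradient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._nn import Adam, SmallCNN, softmax_cross_entropy
from .contacts import ContactImageSet, ContactMap, map_to_image
from .errors import ConfigurationError, ValidationError

__all__ = [
    "ClassifierModel",
    "SaliencyMap",
    "ContactSelection",
    "train_classifier",
    "compute_saliency",
    "compute_saliency_averaged",
    "select_contacts",
]


@dataclass
class ClassifierModel:
    """Trained CNN with its class list and per-epoch accuracy curve."""

    net: SmallCNN
    classes: list[str]
    history: pd.DataFrame        # epoch, train_loss, train_acc, val_loss, val_acc
    seed: int

    @property
    def architecture(self) -> dict:
        return self.net.describe()

    @property
    def final_val_accuracy(self) -> float:
        return float(self.history["val_acc"].iloc[-1])

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        logits = self.net.forward(np.asarray(images, dtype=float))
        shifted = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(shifted)
        return p / p.sum(axis=1, keepdims=True)


@dataclass
class SaliencyMap:
    """Symmetric max-normalized |input gradient| over residue pairs."""

    values: np.ndarray           # (n_res, n_res) in [0, 1]
    target_class: str
    reference_source: str = "cluster-representative"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.allclose(v, v.T):
            raise ValidationError("saliency map must be symmetric")
        if v.min() < 0:
            raise ValidationError("saliency values must be non-negative")
        self.values = v

    @property
    def n_res(self) -> int:
        return self.values.shape[0]


@dataclass
class ContactSelection:
    """Characteristic contacts: high gradient AND both residues significant."""

    pairs: list[tuple[int, int, float]]   # (res_i, res_j, gradient), sorted desc
    threshold: float
    rejected_nonsignificant: list[tuple[int, int, float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"res_i": i, "res_j": j, "gradient": g, "significant": True}
                for i, j, g in self.pairs]
        rows += [{"res_i": i, "res_j": j, "gradient": g, "significant": False}
                 for i, j, g in self.rejected_nonsignificant]
        return pd.DataFrame(rows, columns=["res_i", "res_j", "gradient", "significant"])


# --------------------------------------------------------------------------


def _accuracy(net: SmallCNN, images: np.ndarray, labels: np.ndarray,
              batch: int = 256) -> tuple[float, float]:
    losses, correct = [], 0
    for b0 in range(0, len(images), batch):
        x = images[b0:b0 + batch]
        y = labels[b0:b0 + batch]
        logits = net.forward(x)
        loss, _ = softmax_cross_entropy(logits, y)
        losses.append(loss * len(x))
        correct += int((logits.argmax(axis=1) == y).sum())
    return float(np.sum(losses) / len(images)), correct / len(images)


def train_classifier(dataset: ContactImageSet, epochs: int = 15, seed: int = 0,
                     lr: float = 1e-3, batch_size: int = 64,
                     weight_decay: float = 1e-3) -> ClassifierModel:
    """Train the contact-image CNN; deterministic for a fixed seed.

    The seed controls parameter initialization and per-epoch shuffling;
    the train/val split is owned by the dataset (its own seed).
    """
    tr = dataset.train_indices
    va = dataset.val_indices
    if len(tr) == 0 or len(va) == 0:
        raise ValidationError("dataset must contain both train and val splits")
    counts = np.bincount(dataset.labels[tr], minlength=len(dataset.class_names))
    pos = counts[counts > 0]
    if pos.max() > 10 * pos.min():
        warnings.warn(f"class imbalance exceeds 10:1 in training split: {counts.tolist()}")

    x_tr = dataset.images[tr].astype(float)
    y_tr = dataset.labels[tr]
    x_va = dataset.images[va].astype(float)
    y_va = dataset.labels[va]

    net = SmallCNN(input_hw=dataset.images.shape[1],
                   n_classes=len(dataset.class_names), seed=seed)
    opt = Adam(net.params, lr=lr, weight_decay=weight_decay)
    rng = np.random.default_rng(seed)

    rows = []
    for epoch in range(epochs):
        order = rng.permutation(len(x_tr))
        for b0 in range(0, len(order), batch_size):
            idx = order[b0:b0 + batch_size]
            logits, cache = net.forward(x_tr[idx], need_cache=True)
            loss, dlogits = softmax_cross_entropy(logits, y_tr[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}, batch {b0 // batch_size}; "
                    f"lr={lr}, batch={batch_size} — lower the learning rate")
            grads, _ = net.backward(dlogits, cache)
            opt.step(net.params, grads)
        tr_loss, tr_acc = _accuracy(net, x_tr, y_tr)
        va_loss, va_acc = _accuracy(net, x_va, y_va)
        rows.append({"epoch": epoch + 1, "train_loss": tr_loss, "train_acc": tr_acc,
                     "val_loss": va_loss, "val_acc": va_acc})
    history = pd.DataFrame(rows)
    return ClassifierModel(net=net, classes=list(dataset.class_names),
                           history=history, seed=seed)


def compute_saliency(model: ClassifierModel, reference_map: ContactMap,
                     target_class: str) -> SaliencyMap:
    """Vanilla-gradient attribution on a cluster-representative contact map.

    |d logit(target) / d pixel|, symmetrized by averaging (i,j) and (j,i),
    zeroed on the padding region, and divided by its maximum (unless the
    gradient is identically zero, which yields a zero map with a warning).
    """
    if target_class not in model.classes:
        raise ConfigurationError(f"unknown target class {target_class!r}")
    image = map_to_image(reference_map, pad_to=model.net.input_hw)
    grad = model.net.input_gradient(image, model.classes.index(target_class))
    n = reference_map.n_res
    grad = np.abs(grad)
    grad[n:, :] = 0.0
    grad[:, n:] = 0.0
    grad = 0.5 * (grad + grad.T)
    peak = grad.max()
    if peak == 0:
        warnings.warn("all-zero saliency gradient; returning zero map")
        return SaliencyMap(values=grad[:n, :n], target_class=target_class,
                           reference_source=reference_map.source)
    return SaliencyMap(values=grad[:n, :n] / peak, target_class=target_class,
                       reference_source=reference_map.source)


def compute_saliency_averaged(model: ClassifierModel,
                              reference_maps: dict[str, ContactMap],
                              target_class: str) -> SaliencyMap:
    """Average the target-class saliency over per-class representative maps,
    then renormalize to max 1. Useful when no single system's cluster
    representative should dominate the attribution."""
    if not reference_maps:
        raise ConfigurationError("no reference maps given")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        parts = [compute_saliency(model, m, target_class).values
                 for m in reference_maps.values()]
    n = min(p.shape[0] for p in parts)
    mean = np.mean([p[:n, :n] for p in parts], axis=0)
    peak = mean.max()
    if peak == 0:
        warnings.warn("all-zero averaged saliency; returning zero map")
        return SaliencyMap(values=mean, target_class=target_class,
                           reference_source="per-class-average")
    return SaliencyMap(values=mean / peak, target_class=target_class,
                       reference_source="per-class-average")


def select_contacts(saliency: SaliencyMap, flex_profile, threshold: float = 0.7
                    ) -> ContactSelection:
    """Keep pairs with gradient >= threshold whose both residues changed
    flexibility significantly; sort by descending gradient.

    ``flex_profile`` needs a boolean per-residue ``significant`` array
    aligned with the saliency's residue indexing (extra residues beyond
    the profile, e.g. ligand entities, count as non-significant).
    """
    significant = np.asarray(flex_profile.significant, dtype=bool)
    kept, rejected = [], []
    n = saliency.n_res
    for i in range(n):
        for j in range(i + 1, n):
            g = saliency.values[i, j]
            if g < threshold:
                continue
            ok_i = i < len(significant) and significant[i]
            ok_j = j < len(significant) and significant[j]
            if ok_i and ok_j:
                kept.append((i, j, float(g)))
            else:
                rejected.append((i, j, float(g)))
    kept.sort(key=lambda t: (-t[2], t[0], t[1]))
    rejected.sort(key=lambda t: (-t[2], t[0], t[1]))
    return ContactSelection(pairs=kept, threshold=threshold,
                            rejected_nonsignificant=rejected)
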