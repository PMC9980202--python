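"""Classifier training, gradient saliency and the contact-selection rule."""

import numpy as np
import pytest

from allokit._nn import SmallCNN, softmax_cross_entropy
from allokit.contacts import ContactImageSet, ContactMap
from allokit.deeplearn import (ClassifierModel, compute_saliency, select_contacts,
                               train_classifier)

import pandas as pd


def make_dataset(images, labels, class_names, train_frac=0.8, seed=0):
    rng = np.random.default_rng(seed)
    split = np.array(["train"] * len(labels), dtype=object)
    for ci in range(len(class_names)):
        idx = np.nonzero(labels == ci)[0]
        val = rng.permutation(idx)[: max(1, int(round((1 - train_frac) * len(idx))))]
        split[val] = "val"
    return ContactImageSet(images=images.astype(np.float32), labels=labels,
                           class_names=list(class_names), split=split.astype(str),
                           seed=seed, n_res=images.shape[1])


def planted_pixel_dataset(n_per_class=120, hw=16, seed=0, p_on=(0.0, 1.0)):
    """Pixel (2, 8) is on with per-class probability ``p_on`` over background
    noise; the default plants a perfectly separating pixel."""
    rng = np.random.default_rng(seed)
    images, labels = [], []
    for k in range(2):
        for _ in range(n_per_class):
            img = np.zeros((hw, hw), dtype=np.float32)
            noise = rng.random((hw, hw)) < 0.02
            img[noise] = 1.0
            img[2, 8] = img[8, 2] = float(rng.random() < p_on[k])
            images.append(img)
            labels.append(k)
    return make_dataset(np.stack(images), np.asarray(labels), ["A", "B"], seed=seed)


class TestGradients:
    def test_input_gradient_matches_finite_differences(self):
        """The backprop input gradient is the derivative saliency relies on."""
        net = SmallCNN(input_hw=10, n_classes=3, channels=(4, 4), hidden=8, seed=1)
        rng = np.random.default_rng(0)
        img = rng.random((10, 10))
        grad = net.input_gradient(img, target_class=2)
        eps = 1e-6
        for (i, j) in [(0, 0), (3, 7), (9, 9), (5, 2)]:
            plus, minus = img.copy(), img.copy()
            plus[i, j] += eps
            minus[i, j] -= eps
            num = (net.forward(plus[None])[0, 2] - net.forward(minus[None])[0, 2]) / (2 * eps)
            assert grad[i, j] == pytest.approx(num, abs=1e-5)

    def test_parameter_gradients_match_finite_differences(self):
        net = SmallCNN(input_hw=8, n_classes=2, channels=(2, 2), hidden=4, seed=2)
        rng = np.random.default_rng(3)
        x = rng.random((4, 8, 8))
        y = np.array([0, 1, 1, 0])
        logits, cache = net.forward(x, need_cache=True)
        _, dlogits = softmax_cross_entropy(logits, y)
        grads, _ = net.backward(dlogits, cache)
        eps = 1e-6
        for key in ("w1", "w3", "b4"):
            flat_index = 1 if net.params[key].size > 1 else 0
            orig = net.params[key].flat[flat_index]
            net.params[key].flat[flat_index] = orig + eps
            lp, _ = softmax_cross_entropy(net.forward(x), y)
            net.params[key].flat[flat_index] = orig - eps
            lm, _ = softmax_cross_entropy(net.forward(x), y)
            net.params[key].flat[flat_index] = orig
            assert grads[key].flat[flat_index] == pytest.approx((lp - lm) / (2 * eps),
                                                                abs=1e-5)


class TestTraining:
    def test_perfectly_separable_dataset_reaches_high_accuracy(self):
        """One planted pixel perfectly separates the classes: >= 0.95
        validation accuracy after 15 epochs."""
        ds = planted_pixel_dataset()
        model = train_classifier(ds, epochs=15, seed=0)
        assert model.final_val_accuracy >= 0.95
        assert len(model.history) == 15

    def test_shuffled_labels_give_chance_accuracy(self):
        ds = planted_pixel_dataset(seed=1)
        rng = np.random.default_rng(5)
        ds.labels = rng.permutation(ds.labels)
        model = train_classifier(ds, epochs=5, seed=0)
        # two balanced classes: chance is 0.5; allow a generous binomial band
        assert 0.3 <= model.final_val_accuracy <= 0.7

    def test_same_seed_same_parameters(self):
        ds = planted_pixel_dataset(n_per_class=40)
        m1 = train_classifier(ds, epochs=2, seed=7)
        m2 = train_classifier(ds, epochs=2, seed=7)
        for key in m1.net.params:
            assert np.array_equal(m1.net.params[key], m2.net.params[key])

    def test_class_imbalance_warns(self):
        ds = planted_pixel_dataset(n_per_class=60)
        keep = np.concatenate([np.nonzero(ds.labels == 0)[0][:55],
                               np.nonzero(ds.labels == 1)[0][:5]])
        ds2 = make_dataset(ds.images[keep], ds.labels[keep], ds.class_names, seed=0)
        with pytest.warns(UserWarning, match="imbalance"):
            train_classifier(ds2, epochs=1, seed=0)

    def test_checkpoint_round_trip(self, tmp_path):
        ds = planted_pixel_dataset(n_per_class=30)
        model = train_classifier(ds, epochs=1, seed=0)
        path = tmp_path / "model.npz"
        model.net.save(path)
        back = SmallCNN.load(path)
        x = ds.images[:8].astype(float)
        assert np.allclose(back.forward(x), model.net.forward(x))


class _OnePixelNet:
    """Stub with logit(target) = x[2, 3]: saliency must be 1 there, 0 elsewhere."""

    input_hw = 8

    def input_gradient(self, image, target_class):
        g = np.zeros((8, 8))
        g[2, 3] = 5.0
        return g


class _ZeroNet:
    input_hw = 8

    def input_gradient(self, image, target_class):
        return np.zeros((8, 8))


def _refmap(n=6):
    m = np.zeros((n, n), dtype=np.uint8)
    m[0, 3] = m[3, 0] = 1
    return ContactMap(matrix=m, cutoff=4.5, min_seq_sep=0,
                      source="cluster-representative")


def _model(net, classes=("A", "B")):
    return ClassifierModel(net=net, classes=list(classes),
                           history=pd.DataFrame({"epoch": [1], "train_loss": [0.0],
                                                 "train_acc": [1.0], "val_loss": [0.0],
                                                 "val_acc": [1.0]}), seed=0)


class TestSaliency:
    def test_single_pixel_gradient_normalizes_and_symmetrizes(self):
        sal = compute_saliency(_model(_OnePixelNet()), _refmap(), "B")
        assert sal.values[2, 3] == 1.0
        assert sal.values[3, 2] == 1.0
        assert sal.values.sum() == 2.0

    def test_zero_gradient_warns_and_returns_zero_map(self):
        with pytest.warns(UserWarning, match="zero"):
            sal = compute_saliency(_model(_ZeroNet()), _refmap(), "A")
        assert sal.values.max() == 0.0

    def test_padding_region_zeroed(self):
        sal = compute_saliency(_model(_OnePixelNet()), _refmap(n=5), "A")
        assert sal.n_res == 5   # trimmed to the data block

    def test_per_class_average_renormalizes(self):
        from allokit.deeplearn import compute_saliency_averaged
        maps = {"A": _refmap(), "B": _refmap()}
        sal = compute_saliency_averaged(_model(_OnePixelNet()), maps, "B")
        assert sal.values.max() == 1.0
        assert sal.values[2, 3] == 1.0
        assert sal.reference_source == "per-class-average"

    def test_trained_saliency_max_is_one(self):
        ds = planted_pixel_dataset(n_per_class=60, hw=16)
        model = train_classifier(ds, epochs=5, seed=3)
        ref = ContactMap(matrix=np.zeros((16, 16), dtype=np.uint8),
                         cutoff=4.5, min_seq_sep=0)
        sal = compute_saliency(model, ref, "B")
        assert sal.values.max() == pytest.approx(1.0)


class _Profile:
    def __init__(self, significant):
        self.significant = np.asarray(significant, dtype=bool)


class TestSelectionRule:
    def _saliency(self, entries, n=6):
        from allokit.deeplearn import SaliencyMap
        v = np.zeros((n, n))
        for (i, j), g in entries.items():
            v[i, j] = v[j, i] = g
        return SaliencyMap(values=v, target_class="B")

    def test_above_threshold_both_significant_selected(self):
        sal = self._saliency({(0, 3): 0.71})
        sel = select_contacts(sal, _Profile([1, 0, 0, 1, 0, 0]), 0.7)
        assert sel.pairs == [(0, 3, 0.71)]

    def test_high_gradient_one_nonsignificant_rejected(self):
        sal = self._saliency({(0, 3): 0.90})
        sel = select_contacts(sal, _Profile([1, 0, 0, 0, 0, 0]), 0.7)
        assert sel.pairs == []
        assert (0, 3, 0.90) in sel.rejected_nonsignificant

    def test_below_threshold_rejected(self):
        sal = self._saliency({(0, 3): 0.69})
        sel = select_contacts(sal, _Profile([1, 1, 1, 1, 1, 1]), 0.7)
        assert sel.pairs == []

    def test_sorted_by_descending_gradient(self):
        sal = self._saliency({(0, 3): 0.75, (1, 4): 0.95, (2, 5): 0.85})
        sel = select_contacts(sal, _Profile([1] * 6), 0.7)
        assert [g for _, _, g in sel.pairs] == sorted(
            [g for _, _, g in sel.pairs], reverse=True)

    def test_selection_independent_of_class_order(self):
        """Selection consumes only the saliency map and significance flags,
        so permuting the classifier's class order cannot change it."""
        sal = self._saliency({(0, 3): 0.8, (1, 4): 0.9})
        prof = _Profile([1, 1, 0, 1, 1, 0])
        a = select_contacts(sal, prof, 0.7)
        sal2 = self._saliency({(1, 4): 0.9, (0, 3): 0.8})
        b = select_contacts(sal2, prof, 0.7)
        assert a.pairs == b.pairs
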