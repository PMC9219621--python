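"""Deep branch (Model-II): a backbone-agnostic finetuning protocol.

The protocol mirrors standard transfer-learning practice for grayscale
patches: bilinear resize to 224x224, replication of the single channel into
three, intensities scaled to [0, 1], light train-time augmentation (random
centred crop, random horizontal and vertical flips with p = 0.5), and
10-fold cross-validated finetuning of *all* layers with Adam at an initial
learning rate of 1e-4 decayed exponentially (gamma 0.4) after every epoch,
for 10 epochs with batch size 4.  The held-out fold is scored with the
softmax malignancy probability.

Backbones satisfy a minimal contract (forward to 2-class probabilities,
loss gradients, parameter access); the built-in SurrogateCNN is a small
numpy convolutional network that makes the protocol executable at desk
scale.  An externally supplied backbone (e.g. a pretrained residual
network) can be plugged in through the same factory interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import resize

from .scores import FoldAssignment, ScoreTable, label_to_int

MODEL_II = "Model-II"


@dataclass(frozen=True)
class DLConfig:
    input_size: int = 224
    channels: int = 3
    batch_size: int = 4
    initial_learning_rate: float = 1e-4
    lr_decay_gamma: float = 0.4
    epochs: int = 10
    augmentation_flip_prob: float = 0.5
    crop_scale_range: tuple[float, float] = (0.9, 1.0)
    backbone: str = "surrogate_cnn"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.input_size, self.channels, self.batch_size,
               self.epochs) <= 0:
            raise ValueError("size/batch/epoch parameters must be positive")
        if self.initial_learning_rate <= 0 or self.lr_decay_gamma <= 0:
            raise ValueError("learning-rate parameters must be positive")
        if not 0.0 <= self.augmentation_flip_prob <= 1.0:
            raise ValueError("augmentation_flip_prob must be in [0, 1]")


def lr_schedule(config: DLConfig) -> list[float]:
    """Learning rate used in each epoch: lr0 * gamma^(epoch-1)."""
    return [config.initial_learning_rate * config.lr_decay_gamma ** e
            for e in range(config.epochs)]


def preprocess_patch(roi, config: DLConfig = DLConfig()) -> np.ndarray:
    """Bilinear resize to the network input size, scale to [0, 1] by the
    patch maximum, and replicate the grayscale patch into all three
    channels -> (3, H, W)."""
    image = np.asarray(roi.image, dtype=float)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("ROI image must be square 2-D")
    out = resize(image, (config.input_size, config.input_size), order=1,
                 mode="reflect", anti_aliasing=False, preserve_range=True)
    peak = out.max()
    if peak > 0:
        out = out / peak
    out = np.clip(out, 0.0, 1.0)
    return np.repeat(out[None, :, :], config.channels, axis=0)


def augment(image: np.ndarray, rng: np.random.Generator,
            crop_scale_range: tuple[float, float] = (0.9, 1.0),
            flip_prob: float = 0.5) -> np.ndarray:
    """Random centred crop (resized back) then random H/V flips.

    Training-time only; deterministic given the generator state.
    """
    c, h, w = image.shape
    scale = rng.uniform(*crop_scale_range)
    out = image
    if scale < 1.0:
        ch = max(1, int(round(h * scale)))
        cw = max(1, int(round(w * scale)))
        r0 = (h - ch) // 2
        c0 = (w - cw) // 2
        crop = image[:, r0:r0 + ch, c0:c0 + cw]
        out = np.stack([
            resize(crop[i], (h, w), order=1, mode="reflect",
                   anti_aliasing=False, preserve_range=True)
            for i in range(c)])
    if rng.uniform() < flip_prob:
        out = out[:, :, ::-1]
    if rng.uniform() < flip_prob:
        out = out[:, ::-1, :]
    return np.ascontiguousarray(out)


# ---------------------------------------------------------------------------
# surrogate backbone: a small numpy CNN trained with Adam
# ---------------------------------------------------------------------------

def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """3x3 same-padding convolution; x (B,C,H,W), W (F,C,3,3)."""
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = sliding_window_view(xp, (3, 3), axis=(2, 3))
    out = np.einsum("bchwij,fcij->bfhw", cols, W, optimize=True)
    return out + b[None, :, None, None], cols


def _conv_backward(dout: np.ndarray, cols: np.ndarray, W: np.ndarray):
    dW = np.einsum("bchwij,bfhw->fcij", cols, dout, optimize=True)
    db = dout.sum(axis=(0, 2, 3))
    dp = np.pad(dout, ((0, 0), (0, 0), (1, 1), (1, 1)))
    dcols = sliding_window_view(dp, (3, 3), axis=(2, 3))
    Wf = W[:, :, ::-1, ::-1]
    dx = np.einsum("bfhwij,fcij->bchw", dcols, Wf, optimize=True)
    return dx, dW, db


def _avgpool(x: np.ndarray, k: int) -> np.ndarray:
    b, c, h, w = x.shape
    return x.reshape(b, c, h // k, k, w // k, k).mean(axis=(3, 5))


def _avgpool_backward(dout: np.ndarray, k: int) -> np.ndarray:
    return np.repeat(np.repeat(dout, k, axis=2), k, axis=3) / (k * k)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SurrogateCNN:
    """Small trainable CNN: fixed 8x stem pool, two 3x3 conv+ReLU stages,
    global average pooling, and a 2-way softmax head.

    The head starts at zero so untrained outputs are exactly (0.5, 0.5) and
    every departure from chance is learned signal.  All layers are trainable,
    matching the protocol's finetune-everything policy.  ``logit_gain`` is a
    fixed output gain that makes the small network responsive under the
    protocol's conservative learning-rate schedule at desk-scale iteration
    counts (a few hundred optimiser steps per fold).
    """

    def __init__(self, rng: np.random.Generator, input_size: int = 224,
                 width: int = 8, logit_gain: float = 300.0):
        self.stem_pool = max(1, input_size // 28)
        self.pool2 = 2
        self.logit_gain = logit_gain
        f1, f2 = width, width * 2
        W1 = rng.normal(0, np.sqrt(2.0 / (3 * 9)), (f1, 3, 3, 3))
        W2 = rng.normal(0, np.sqrt(2.0 / (f1 * 9)), (f2, f1, 3, 3))
        # inputs are strictly positive, so a filter with a negative weight
        # sum starts (and with this little training, stays) dead behind its
        # ReLU; flipping signs keeps every channel alive at init
        W1 *= np.where(W1.sum(axis=(1, 2, 3)) < 0, -1.0, 1.0)[:, None, None, None]
        W2 *= np.where(W2.sum(axis=(1, 2, 3)) < 0, -1.0, 1.0)[:, None, None, None]
        self.params = {
            "W1": W1,
            "b1": np.zeros(f1),
            "W2": W2,
            "b2": np.zeros(f2),
            "Wf": np.zeros((2, f2)),
            "bf": np.zeros(2),
        }
        # mean-only feature normalisation (batch mean in training, running
        # mean at inference) so the head sees centred features and the
        # decision boundary stays near the data
        self.running_mu = np.zeros(f2)
        self._mu_initialised = False

    def forward(self, x: np.ndarray, cache: dict | None = None,
                train: bool = False) -> np.ndarray:
        p = self.params
        s = _avgpool(x, self.stem_pool)
        z1, cols1 = _conv_forward(s, p["W1"], p["b1"])
        a1 = np.maximum(z1, 0.0)
        a1p = _avgpool(a1, self.pool2)
        z2, cols2 = _conv_forward(a1p, p["W2"], p["b2"])
        a2 = np.maximum(z2, 0.0)
        feat = a2.mean(axis=(2, 3))
        if train:
            mu = feat.mean(axis=0)
            if self._mu_initialised:
                self.running_mu = 0.9 * self.running_mu + 0.1 * mu
            else:
                self.running_mu = mu.copy()
                self._mu_initialised = True
        else:
            mu = self.running_mu
        feat_c = feat - mu
        logits = self.logit_gain * (feat_c @ p["Wf"].T + p["bf"])
        probs = _softmax(logits)
        if cache is not None:
            cache.update(cols1=cols1, z1=z1, cols2=cols2, z2=z2, a2=a2,
                         feat=feat_c, feat_raw=feat, probs=probs)
        return probs

    def recalibrate_features(self, batches) -> None:
        """Reset the inference-time feature mean from unaugmented data.

        The EMA accumulated over augmented training batches is systematically
        offset from clean inputs; with the small margins of desk-scale
        training that offset would shift every score to one side of 0.5.
        """
        feats = []
        for x in batches:
            cache: dict = {}
            self.forward(x, cache)
            feats.append(cache["feat_raw"])
        self.running_mu = np.concatenate(feats).mean(axis=0)
        self._mu_initialised = True

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray
                       ) -> tuple[float, dict]:
        p = self.params
        cache: dict = {}
        probs = self.forward(x, cache, train=True)
        B = x.shape[0]
        eps = 1e-12
        loss = float(-np.mean(np.log(probs[np.arange(B), y] + eps)))
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits *= self.logit_gain / B
        grads = {
            "Wf": dlogits.T @ cache["feat"],
            "bf": dlogits.sum(axis=0),
        }
        dfeat = dlogits @ p["Wf"]
        dfeat = dfeat - dfeat.mean(axis=0)   # through the batch-mean centring
        _, _, h2, w2 = cache["a2"].shape
        da2 = dfeat[:, :, None, None] * np.ones((1, 1, h2, w2)) / (h2 * w2)
        dz2 = da2 * (cache["z2"] > 0)
        da1p, grads["W2"], grads["b2"] = _conv_backward(dz2, cache["cols2"],
                                                        p["W2"])
        da1 = _avgpool_backward(da1p, self.pool2)
        dz1 = da1 * (cache["z1"] > 0)
        _, grads["W1"], grads["b1"] = _conv_backward(dz1, cache["cols1"],
                                                     p["W1"])
        return loss, grads


class Adam:
    """Adam optimiser over a dict of parameter arrays."""

    def __init__(self, params: dict, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def surrogate_backbone_factory(config: DLConfig):
    """Returns a factory producing a fresh seeded SurrogateCNN per fold."""

    def factory(fold: int) -> SurrogateCNN:
        rng = np.random.default_rng((config.rng_seed * 1000003 + fold)
                                    % (2 ** 31))
        return SurrogateCNN(rng, input_size=config.input_size)

    return factory


def _eval_loss(net, pre: dict, labels: dict, ids: list,
               chunk: int = 32) -> float:
    losses = []
    eps = 1e-12
    for start in range(0, len(ids), chunk):
        sub = ids[start:start + chunk]
        x = np.stack([pre[sid] for sid in sub])
        y = np.array([labels[sid] for sid in sub])
        probs = net.forward(x)
        losses.extend(-np.log(probs[np.arange(len(sub)), y] + eps))
    return float(np.mean(losses))


def finetune_cv(dataset, folds: FoldAssignment,
                config: DLConfig = DLConfig(), backbone_factory=None
                ) -> tuple[ScoreTable, dict]:
    """Cross-validated finetuning of a backbone on lesion ROIs.

    Per fold: a fresh backbone is trained on the nine training folds for
    ``config.epochs`` epochs with Adam, the learning rate multiplied by
    ``lr_decay_gamma`` after each epoch, augmentation applied to training
    images only; the held-out fold is then scored with the softmax
    malignancy probability.  Returns the ScoreTable and the per-fold
    training-loss history {fold: [epoch mean losses]}.
    """
    if backbone_factory is None:
        backbone_factory = surrogate_backbone_factory(config)
    rois = {getattr(r, "sample_id") or str(i): r
            for i, r in enumerate(dataset)}
    if set(rois) != set(folds.assignments):
        raise ValueError("fold assignment does not cover the dataset")
    pre = {sid: preprocess_patch(r, config) for sid, r in rois.items()}
    labels = {sid: int(label_to_int([r.label])[0]) for sid, r in rois.items()}

    out_ids, out_folds, out_labels, out_scores = [], [], [], []
    history: dict[int, list[float]] = {}
    schedule = lr_schedule(config)
    for fold in range(1, folds.k + 1):
        test_ids = folds.test_ids(fold)
        train_ids = folds.train_ids(fold)
        if not test_ids or not train_ids:
            raise ValueError(f"fold {fold} is empty")
        net = backbone_factory(fold)
        opt = Adam(net.params, lr=schedule[0])
        rng = np.random.default_rng((config.rng_seed * 2000003 + fold)
                                    % (2 ** 31))
        losses = []
        for epoch in range(config.epochs):
            opt.lr = schedule[epoch]
            order = rng.permutation(len(train_ids))
            epoch_losses = []
            for start in range(0, len(order), config.batch_size):
                batch = [train_ids[i]
                         for i in order[start:start + config.batch_size]]
                x = np.stack([
                    augment(pre[sid], rng, config.crop_scale_range,
                            config.augmentation_flip_prob)
                    for sid in batch])
                y = np.array([labels[sid] for sid in batch])
                loss, grads = net.loss_and_grads(x, y)
                opt.step(grads)
                epoch_losses.append(loss)
            # post-epoch monitoring pass: recalibrate the feature mean on
            # the unaugmented training set, then log its loss in eval mode
            if hasattr(net, "recalibrate_features"):
                net.recalibrate_features(
                    np.stack([pre[sid] for sid in train_ids[i:i + 32]])
                    for i in range(0, len(train_ids), 32))
            losses.append(_eval_loss(net, pre, labels, train_ids))
        history[fold] = losses
        x_test = np.stack([pre[sid] for sid in test_ids])
        probs = net.forward(x_test)
        out_ids.extend(test_ids)
        out_folds.extend([fold] * len(test_ids))
        out_labels.extend(labels[sid] for sid in test_ids)
        out_scores.extend(np.clip(probs[:, 1], 0.0, 1.0))
    table = ScoreTable.from_arrays(out_ids, MODEL_II, out_folds, out_labels,
                                   out_scores)
    return table, history
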