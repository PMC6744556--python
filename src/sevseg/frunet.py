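"""Fully residual U-Net (FRU-Net) for per-pixel vesicle probability maps.

The network is a U-shaped encoder-decoder whose every level carries a
pre-activation residual layer (ELU - 3x3 conv - dropout - ELU - 3x3 conv,
summed with its input without scaling).  Compared with the classic U-Net
it halves the number of feature maps (32..256 along the contracting path),
uses 2x2 *average* pooling -- vesicles are smooth round objects, so mean
downsampling propagates their features better than max pooling -- and ELU
activations throughout.  All convolutions are zero padded, so the output
probability map has exactly the shape of the input patch.

Architecture layout (base width ``b``, three poolings):

* contracting level ``i`` (channels ``b * 2**i``, i = 0..2): a 3x3
  convolution that sets the level width, a residual layer, then 2x2
  average pooling;
* connection step: 3x3 convolution to ``8b`` channels plus a residual
  layer (no pooling);
* expanding level ``i``: 2x2 nearest-neighbour upsampling, concatenation
  with the same-level contracting features, then a residual layer that
  takes the concatenation directly -- a 1x1 convolution projects the
  concatenated maps for the residual sum while the first 3x3 convolution
  of the branch performs the matching channel reduction;
* head: 3x3 convolution to refine the feature vectors, then a 1x1
  convolution with sigmoid giving the vesicle probability.

The output 1x1 convolution is zero-initialised, so an untrained network
predicts 0.5 everywhere and the first gradient steps are well scaled.

The public entry point is :class:`FRUNet`, a scikit-learn style estimator
(``fit`` / ``predict`` / ``get_params``) operating on stacks of normalized
patches in ``[0, 1]`` and binary masks.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from ._nn import (F32, Adam, AvgPool2, Conv2D, Dropout, ELU, UpsampleNN2,
                  bce_with_logits, sigmoid)

__all__ = ["FRUNet", "augment", "load_model"]

_N_POOLINGS = 3


class _ResidualLayer:
    """ELU-Conv-Dropout-ELU-Conv with an unscaled sum connection.

    When the input channel count differs from the output one (expanding
    path, where the input is a concatenation), the sum path goes through
    an independent 1x1 convolution and the first 3x3 convolution of the
    branch reduces the channels; otherwise the sum connection is the
    identity.
    """

    def __init__(self, c_in, c_out, dropout_rate, alpha, rng):
        self.elu1 = ELU(alpha)
        self.conv1 = Conv2D(c_in, c_out, 3, rng)
        self.drop = Dropout(dropout_rate, rng)
        self.elu2 = ELU(alpha)
        self.conv2 = Conv2D(c_out, c_out, 3, rng)
        self.proj = Conv2D(c_in, c_out, 1, rng) if c_in != c_out else None

    @property
    def params(self):
        out = self.conv1.params + self.conv2.params
        if self.proj is not None:
            out += self.proj.params
        return out

    def forward(self, x, train=False):
        h = self.elu1.forward(x, train)
        h = self.conv1.forward(h, train)
        h = self.drop.forward(h, train)
        h = self.elu2.forward(h, train)
        h = self.conv2.forward(h, train)
        s = x if self.proj is None else self.proj.forward(x, train)
        return s + h

    def backward(self, gy):
        gh = self.conv2.backward(gy)
        gh = self.elu2.backward(gh)
        gh = self.drop.backward(gh)
        gh = self.conv1.backward(gh)
        gh = self.elu1.backward(gh)
        gs = gy if self.proj is None else self.proj.backward(gy)
        return gh + gs


class _FRUCore:
    """The bare network: parameter store plus forward/backward."""

    def __init__(self, base_features, dropout_rate, elu_alpha, rng):
        b = int(base_features)
        self.base_features = b
        enc_c = [b * 2 ** i for i in range(_N_POOLINGS)]      # 32, 64, 128
        bott_c = b * 2 ** _N_POOLINGS                         # 256
        self.enc_entry, self.enc_res, self.pools = [], [], []
        c_prev = 1
        for c in enc_c:
            self.enc_entry.append(Conv2D(c_prev, c, 3, rng))
            self.enc_res.append(_ResidualLayer(c, c, dropout_rate, elu_alpha, rng))
            self.pools.append(AvgPool2())
            c_prev = c
        self.bott_entry = Conv2D(c_prev, bott_c, 3, rng)
        self.bott_res = _ResidualLayer(bott_c, bott_c, dropout_rate, elu_alpha, rng)
        self.ups, self.dec_res = [], []
        c_prev = bott_c
        for c in reversed(enc_c):                             # 128, 64, 32
            self.ups.append(UpsampleNN2())
            self.dec_res.append(
                _ResidualLayer(c + c_prev, c, dropout_rate, elu_alpha, rng))
            c_prev = c
        self.head_elu1 = ELU(elu_alpha)
        self.head_conv = Conv2D(b, b, 3, rng)
        self.head_elu2 = ELU(elu_alpha)
        self.out_conv = Conv2D(b, 1, 1, rng, zero_init=True)
        self._skip_channels = list(reversed(enc_c))

    @property
    def params(self):
        out = []
        for entry, res in zip(self.enc_entry, self.enc_res):
            out += entry.params + res.params
        out += self.bott_entry.params + self.bott_res.params
        for res in self.dec_res:
            out += res.params
        out += self.head_conv.params + self.out_conv.params
        return out

    def forward_logits(self, x, train=False):
        skips = []
        h = x
        for entry, res, pool in zip(self.enc_entry, self.enc_res, self.pools):
            h = entry.forward(h, train)
            h = res.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
        h = self.bott_entry.forward(h, train)
        h = self.bott_res.forward(h, train)
        for up, res, skip in zip(self.ups, self.dec_res, reversed(skips)):
            h = up.forward(h, train)
            h = np.concatenate([skip, h], axis=1)
            h = res.forward(h, train)
        h = self.head_elu1.forward(h, train)
        h = self.head_conv.forward(h, train)
        h = self.head_elu2.forward(h, train)
        return self.out_conv.forward(h, train)

    def backward(self, gz):
        g = self.out_conv.backward(gz)
        g = self.head_elu2.backward(g)
        g = self.head_conv.backward(g)
        g = self.head_elu1.backward(g)
        skip_grads = []
        for up, res, c_skip in zip(reversed(self.ups), reversed(self.dec_res),
                                   reversed(self._skip_channels)):
            g = res.backward(g)
            skip_grads.append(np.ascontiguousarray(g[:, :c_skip]))
            g = up.backward(np.ascontiguousarray(g[:, c_skip:]))
        g = self.bott_res.backward(g)
        g = self.bott_entry.backward(g)
        for entry, res, pool, gskip in zip(reversed(self.enc_entry),
                                           reversed(self.enc_res),
                                           reversed(self.pools),
                                           reversed(skip_grads)):
            g = pool.backward(g)
            g = g + gskip
            g = res.backward(g)
            g = entry.backward(g)
        return g

    def parameter_count(self):
        return int(sum(p.value.size for p in self.params))

    def get_weights(self):
        return [p.value.copy() for p in self.params]

    def set_weights(self, weights):
        own = self.params
        if len(own) != len(weights):
            raise ValueError("weight list does not match the architecture")
        for p, w in zip(own, weights):
            if p.value.shape != w.shape:
                raise ValueError("weight shape mismatch")
            p.value = np.ascontiguousarray(w, dtype=F32)

    def manifest(self):
        layers = []

        def conv_entry(name, conv):
            layers.append({"name": name, "type": f"conv{conv.kernel}x{conv.kernel}",
                           "in": conv.c_in, "out": conv.c_out})

        for i, (entry, res) in enumerate(zip(self.enc_entry, self.enc_res)):
            conv_entry(f"enc{i}.entry", entry)
            conv_entry(f"enc{i}.res.conv1", res.conv1)
            conv_entry(f"enc{i}.res.conv2", res.conv2)
            layers.append({"name": f"enc{i}.pool", "type": "avgpool2x2"})
        conv_entry("connection.entry", self.bott_entry)
        conv_entry("connection.res.conv1", self.bott_res.conv1)
        conv_entry("connection.res.conv2", self.bott_res.conv2)
        for i, res in enumerate(self.dec_res):
            level = _N_POOLINGS - 1 - i
            layers.append({"name": f"dec{level}.up", "type": "upsample_nn2x2"})
            layers.append({"name": f"dec{level}.concat", "type": "concat"})
            conv_entry(f"dec{level}.res.proj", res.proj)
            conv_entry(f"dec{level}.res.conv1", res.conv1)
            conv_entry(f"dec{level}.res.conv2", res.conv2)
        conv_entry("head.conv", self.head_conv)
        conv_entry("head.out", self.out_conv)
        return {"base_features": self.base_features,
                "contracting_channels": [b["out"] for b in layers
                                         if b["name"].endswith(".entry")],
                "n_poolings": _N_POOLINGS,
                "parameter_count": self.parameter_count(),
                "layers": layers}


def _random_transform(rng):
    """Draw one augmentation: flips, quarter rotations and +-10% zoom."""
    return {"flip_h": bool(rng.random() < 0.5),
            "flip_v": bool(rng.random() < 0.5),
            "rot90": int(rng.integers(0, 4)),
            "zoom": float(rng.uniform(0.9, 1.1)) if rng.random() < 0.5 else 1.0}


def _apply_transform(arr, t, order):
    out = arr
    if t["flip_h"]:
        out = out[:, ::-1]
    if t["flip_v"]:
        out = out[::-1, :]
    if t["rot90"]:
        out = np.rot90(out, t["rot90"])
    if t["zoom"] != 1.0:
        shape = out.shape
        z = ndi.zoom(out, t["zoom"], order=order, prefilter=False)
        out = np.zeros(shape, dtype=z.dtype)
        h = min(shape[0], z.shape[0])
        w = min(shape[1], z.shape[1])
        oy, ox = (shape[0] - h) // 2, (shape[1] - w) // 2
        zy, zx = (z.shape[0] - h) // 2, (z.shape[1] - w) // 2
        out[oy:oy + h, ox:ox + w] = z[zy:zy + h, zx:zx + w]
    return np.ascontiguousarray(out)


def augment(patch, mask, n_aug, seed=None):
    """Return ``[(patch, mask)]`` plus ``n_aug`` jointly transformed pairs.

    The transform family -- horizontal/vertical flips, quarter-turn
    rotations and +-10% zoom -- suits orientation-free round objects.
    Geometric transforms are applied identically to patch and mask; the
    mask is warped with nearest-neighbour interpolation so it stays binary.
    """
    patch = np.asarray(patch)
    mask = np.asarray(mask)
    if patch.shape != mask.shape:
        raise ValueError("patch and mask shapes differ")
    rng = np.random.default_rng(seed)
    pairs = [(patch, mask)]
    for _ in range(int(n_aug)):
        t = _random_transform(rng)
        pairs.append((_apply_transform(patch, t, order=1),
                      _apply_transform(mask, t, order=0)))
    return pairs


class FRUNet(BaseEstimator):
    """Fully residual U-Net estimator for vesicle probability maps.

    Parameters
    ----------
    base_features : int, default 32
        Channel width of the first level; widths double per level down to
        ``8 * base_features`` at the connection step.
    dropout_rate : float, default 0.1
        Dropout inside every residual layer (training only).
    elu_alpha : float, default 1.0
        ELU saturation parameter.
    learning_rate, epochs, batch_size :
        Adam step size and training schedule (defaults follow the
        reference training regime: 1e-4, 100 epochs, batches of 10).
    validation_fraction : float, default 0.1
        Fraction of the *real* patches set aside before augmentation; the
        held-out patches are never augmented nor trained on, and the
        checkpoint with the lowest validation loss is kept.
    n_aug : int, default 0
        Number of augmented copies generated per training patch.
    random_state : int or None
        Seed for weight initialisation, the validation split, shuffling,
        dropout and augmentation.

    Attributes
    ----------
    core_ : the built network (parameter store with forward/backward).
    history_ : DataFrame with per-epoch ``train_loss`` / ``val_loss``.
    n_parameters_ : trainable parameter count.
    """

    def __init__(self, base_features=32, dropout_rate=0.1, elu_alpha=1.0,
                 learning_rate=1e-4, epochs=100, batch_size=10,
                 validation_fraction=0.1, n_aug=0, random_state=None):
        self.base_features = base_features
        self.dropout_rate = dropout_rate
        self.elu_alpha = elu_alpha
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.validation_fraction = validation_fraction
        self.n_aug = n_aug
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _validate_patches(self, X, y=None):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 2:
            X = X[None]
        if X.ndim != 3:
            raise ValueError("X must be (n_patches, height, width)")
        if X.shape[1] % 2 ** _N_POOLINGS or X.shape[2] % 2 ** _N_POOLINGS:
            raise ValueError(
                f"patch size must be divisible by {2 ** _N_POOLINGS} "
                f"for the pooling pyramid, got {X.shape[1:]}")
        if X.size and (X.min() < 0 or X.max() > 1):
            raise ValueError("patches must be normalized to [0, 1]")
        if y is None:
            return X
        y = np.asarray(y)
        if y.shape != X.shape:
            raise ValueError("masks must match the patch stack shape")
        vals = np.unique(y)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("masks must be binary (0/1)")
        return X, y.astype(np.float32)

    def _build(self, rng):
        return _FRUCore(self.base_features, self.dropout_rate,
                        self.elu_alpha, rng)

    def fit(self, X, y):
        """Train on normalized patches ``X`` and binary masks ``y``."""
        X, y = self._validate_patches(X, y)
        n = X.shape[0]
        if n == 0:
            raise ValueError("empty training set")
        rng = np.random.default_rng(self.random_state)
        self.core_ = self._build(rng)
        self.n_parameters_ = self.core_.parameter_count()

        n_val = int(np.floor(n * self.validation_fraction))
        perm = rng.permutation(n)
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        self.n_validation_ = n_val
        self.n_training_real_ = n - n_val
        X_val, y_val = X[val_idx], y[val_idx]
        X_tr = [X[i] for i in train_idx]
        y_tr = [y[i] for i in train_idx]
        if self.n_aug:
            aug_X, aug_y = [], []
            for xi, yi in zip(X_tr, y_tr):
                for pa, ma in augment(xi, yi, self.n_aug,
                                      seed=int(rng.integers(2 ** 31)))[1:]:
                    aug_X.append(np.clip(pa, 0, 1))
                    aug_y.append(ma)
            X_tr += aug_X
            y_tr += aug_y
        X_tr = np.stack(X_tr) if X_tr else np.empty((0,) + X.shape[1:], F32)
        y_tr = np.stack(y_tr) if y_tr else np.empty((0,) + X.shape[1:], F32)
        self.n_training_total_ = X_tr.shape[0]

        params = self.core_.params
        opt = Adam(params, lr=self.learning_rate)
        history = []
        best_val = np.inf
        best_weights = None
        n_tr = X_tr.shape[0]
        for epoch in range(int(self.epochs)):
            order = rng.permutation(n_tr)
            losses = []
            for start in range(0, n_tr, int(self.batch_size)):
                idx = order[start:start + int(self.batch_size)]
                xb = X_tr[idx][:, None]
                yb = y_tr[idx][:, None]
                z = self.core_.forward_logits(xb, train=True)
                loss, gz = bce_with_logits(z, yb)
                opt.zero_grad()
                self.core_.backward(gz)
                opt.step()
                losses.append(loss)
            train_loss = float(np.mean(losses)) if losses else np.nan
            val_loss = (self._loss(X_val, y_val) if n_val else np.nan)
            history.append({"epoch": epoch + 1, "train_loss": train_loss,
                            "val_loss": val_loss})
            if n_val and val_loss < best_val:
                best_val = val_loss
                best_weights = self.core_.get_weights()
        if best_weights is not None:
            self.core_.set_weights(best_weights)
        self.history_ = pd.DataFrame(
            history, columns=["epoch", "train_loss", "val_loss"])
        return self

    def _loss(self, X, y):
        total, npx = 0.0, 0
        for start in range(0, X.shape[0], int(self.batch_size)):
            xb = X[start:start + int(self.batch_size)][:, None]
            yb = y[start:start + int(self.batch_size)][:, None]
            z = self.core_.forward_logits(xb, train=False)
            loss, _ = bce_with_logits(z, yb)
            total += loss * xb.size
            npx += xb.size
        return total / max(npx, 1)

    def predict(self, X):
        """Per-pixel vesicle probabilities for a stack of patches.

        Deterministic: dropout is disabled at inference.  Output values
        lie strictly inside (0, 1) (sigmoid of finite logits).
        """
        check_is_fitted(self, "core_")
        X = self._validate_patches(X)
        out = np.empty(X.shape, dtype=np.float32)
        for start in range(0, X.shape[0], int(self.batch_size)):
            xb = X[start:start + int(self.batch_size)][:, None]
            z = self.core_.forward_logits(xb, train=False)
            out[start:start + xb.shape[0]] = sigmoid(z)[:, 0]
        return out

    def predict_patch(self, patch):
        """Probability map for a single 2-D patch."""
        return self.predict(np.asarray(patch)[None])[0]

    # ------------------------------------------------------------------
    @staticmethod
    def _checkpoint_paths(path):
        p = Path(path)
        if p.suffix != ".npz":
            p = Path(str(p) + ".npz")
        return p, Path(str(p) + ".manifest.json")

    def save(self, path):
        """Write weights (NumPy ``.npz``) plus a JSON architecture manifest."""
        check_is_fitted(self, "core_")
        weights_path, manifest_path = self._checkpoint_paths(path)
        weights = {f"w{i:03d}": w for i, w in
                   enumerate(self.core_.get_weights())}
        np.savez(weights_path, **weights)
        manifest = self.core_.manifest()
        manifest["hyperparameters"] = self.get_params()
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2)

    @classmethod
    def load(cls, path):
        weights_path, manifest_path = cls._checkpoint_paths(path)
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        est = cls(**manifest["hyperparameters"])
        est.core_ = est._build(np.random.default_rng(0))
        with np.load(weights_path) as npz:
            weights = [npz[k] for k in sorted(npz.files)]
        est.core_.set_weights(weights)
        est.n_parameters_ = est.core_.parameter_count()
        est.history_ = pd.DataFrame(columns=["epoch", "train_loss", "val_loss"])
        return est


def load_model(path):
    """Load a saved :class:`FRUNet` checkpoint."""
    return FRUNet.load(path)
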