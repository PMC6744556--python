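"""Reproducible synthetic validation protocols.

Training the full-width network on the real benchmark takes GPU-hours;
these protocols exercise the complete pipeline end to end at desk scale
instead: a reduced network (base width 8) is trained for a few epochs on
synthetic scenes and scored on held-out synthetic images with the same
detection/segmentation measures used for real data.  All randomness
derives from a single seed, so a protocol run is a deterministic
function of its arguments.

The reduced training schedule compensates for the small step count
(40 patches x 15 epochs at batch 2 is 300 updates) with a larger Adam
step size (1e-3) than the full training regime's 1e-4.
"""

from __future__ import annotations

import numpy as np

from .evaluate import det_score, match, seg_score
from .frunet import FRUNet
from .pipeline import segment_array
from .preprocess import stretch_intensity
from .synthgen import SceneConfig, generate_scene

__all__ = ["train_synthetic_model", "score_on_heldout_scenes",
           "scaled_end_to_end"]

_TRAIN_SCENE = dict(image_size_px=400, pixel_size_nm=1.56, n_vesicles=6,
                    cluster_fraction=0.25, background="grainy")
_HELDOUT_SCENE = dict(image_size_px=512, pixel_size_nm=1.56, n_vesicles=8,
                      cluster_fraction=0.25, background="grainy")


def _scene_seeds(seed: int, n: int, salt: int) -> np.ndarray:
    return np.random.default_rng([seed, salt]).integers(0, 2 ** 31, size=n)


def train_synthetic_model(seed: int = 0, n_train: int = 40,
                          base_features: int = 8, epochs: int = 15,
                          batch_size: int = 2, learning_rate: float = 1e-3)\
        -> FRUNet:
    """Train a reduced FRU-Net on synthetic 400x400 scenes."""
    patches, masks = [], []
    for s in _scene_seeds(seed, n_train, salt=1):
        scene = generate_scene(SceneConfig(seed=int(s), **_TRAIN_SCENE))
        patches.append(stretch_intensity(scene.image))
        masks.append((scene.gt.labels > 0).astype(np.float32))
    est = FRUNet(base_features=base_features, epochs=epochs,
                 batch_size=batch_size, learning_rate=learning_rate,
                 validation_fraction=0.1, random_state=int(seed))
    est.fit(np.stack(patches), np.stack(masks))
    return est


def score_on_heldout_scenes(model: FRUNet, seed: int = 0, n_images: int = 10,
                            tau: float = 0.5) -> dict:
    """Segment held-out synthetic images and score them against GT.

    Returns mean DET / SEG / SEG* across images plus pooled counts.
    """
    dets, segs, seg_stars = [], [], []
    tp = fp = fn = 0
    for s in _scene_seeds(seed, n_images, salt=2):
        scene = generate_scene(SceneConfig(seed=int(s), **_HELDOUT_SCENE))
        result = segment_array(scene.image, scene.gt.pixel_size_nm, model,
                               tau=tau)
        m = match(scene.gt, result.mask)
        det = det_score(m)
        seg = seg_score(m)
        dets.append(det.DET)
        segs.append(seg.SEG)
        seg_stars.append(seg.SEG_star)
        tp += det.TP
        fp += det.FP
        fn += det.FN
    return {"DET": float(np.mean(dets)), "SEG": float(np.mean(segs)),
            "SEG_star": float(np.mean(seg_stars)),
            "TP": tp, "FP": fp, "FN": fn, "n_images": n_images}


def scaled_end_to_end(seed: int = 0, n_train: int = 40, n_heldout: int = 10,
                      **train_kwargs) -> dict:
    """Full scaled-down protocol: train, segment held-out scenes, score."""
    model = train_synthetic_model(seed=seed, n_train=n_train, **train_kwargs)
    scores = score_on_heldout_scenes(model, seed=seed, n_images=n_heldout)
    scores["n_train"] = n_train
    scores["final_train_loss"] = (float(model.history_.train_loss.iloc[-1])
                                  if len(model.history_) else None)
    return scores
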