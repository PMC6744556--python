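"""End-to-end segmentation: image in, labeled mask and measurements out.

Chains the pipeline stages: physical-scale normalization, patch tiling,
FRU-Net prediction, probability-map stitching, thresholding and
morphological cleaning, Radon-transform cluster splitting, restoration
to the original scale with boundary smoothing, and per-vesicle
morphometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import preprocess, postprocess, radon_split
from .frunet import FRUNet
from .morphometry import measure, measurements_to_frame
from .postprocess import LabeledMask, PostprocessConfig, ProbabilityMap

__all__ = ["SegmentationResult", "segment_array", "segment_image"]


@dataclass
class SegmentationResult:
    mask: LabeledMask                       # original scale
    mask_working: LabeledMask               # working (1.56 nm/px) scale
    probability_map: ProbabilityMap
    measurements: pd.DataFrame
    source_id: str = ""


def predict_probability_map(model: FRUNet, normalized: preprocess.NormalizedImage,
                            patch: int = 400, stride: int = 200) -> ProbabilityMap:
    """Tile a normalized image, predict every patch and stitch the map."""
    tiles = preprocess.tile(normalized, patch=patch, stride=stride)
    probs = model.predict(np.stack(tiles.patches))
    pmap = postprocess.stitch(tiles, probabilities=list(probs))
    pmap.scale_factor = normalized.scale_factor
    pmap.original_shape = normalized.original_shape
    pmap.source_id = normalized.source_id
    return pmap


def segment_array(pixels: np.ndarray, pixel_size_nm: float, model: FRUNet,
                  tau: float = 0.5, stride: int = 200, patch: int = 400,
                  split: bool = True, smooth: bool = True,
                  source_id: str = "") -> SegmentationResult:
    """Segment one grayscale image array into labeled vesicle instances."""
    raw = preprocess.RawImage(pixels=pixels, pixel_size_nm=pixel_size_nm,
                              source_id=source_id)
    normalized = preprocess.normalize_scale(raw)
    pmap = predict_probability_map(model, normalized, patch=patch,
                                   stride=stride)
    cfg = PostprocessConfig(tau=tau)
    working = postprocess.binarize_and_clean(pmap, cfg)
    if split:
        split_cfg = radon_split.RadonSplitConfig(
            min_area_px=cfg.min_area_px(working.pixel_size_nm))
        working = radon_split.split_all(working, split_cfg)
    if smooth or normalized.scale_factor != 1.0:
        mask = postprocess.restore_scale_and_smooth(
            working, normalized.original_shape, normalized.scale_factor, cfg)
    else:
        mask = LabeledMask(labels=working.labels.copy(),
                           pixel_size_nm=pixel_size_nm)
    measurements = measurements_to_frame(measure(mask), image_id=source_id)
    return SegmentationResult(mask=mask, mask_working=working,
                              probability_map=pmap,
                              measurements=measurements, source_id=source_id)


def segment_image(path, pixel_size_nm: float, model: FRUNet,
                  **kwargs) -> SegmentationResult:
    """Segment a TIFF image from disk; see :func:`segment_array`."""
    raw = preprocess.read_image(path, pixel_size_nm)
    return segment_array(raw.pixels, raw.pixel_size_nm, model,
                         source_id=raw.source_id, **kwargs)
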