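"""Reading, physical-scale normalization and patch tiling of TEM images.

Vesicles occupy a fixed physical size range (~30-200 nm), so the network
is shown images at a single reference pixel size of 1.56 nm: rescaling by
nearest-neighbour resampling lets it learn the absolute object scale and
preserves the original intensity values exactly.  The rescaled image is
cut into overlapping fixed-size patches (default 400 x 400, stride 200);
each patch is contrast-normalized independently by linearly stretching
its intensity histogram to [0, 1].

Pixel sizes are supplied explicitly per image (CLI flag or CSV manifest)
rather than parsed from TIFF tags, because TEM vendors store calibration
metadata in incompatible dialects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "REFERENCE_PIXEL_SIZE_NM", "RawImage", "NormalizedImage", "PatchSet",
    "read_image", "normalize_scale", "tile", "stretch_intensity",
    "read_manifest",
]

REFERENCE_PIXEL_SIZE_NM = 1.56


class ImageLayoutError(ValueError):
    """Raised for images that are not single-plane grayscale."""


@dataclass
class RawImage:
    """A grayscale TEM image with its physical pixel size."""

    pixels: np.ndarray
    pixel_size_nm: float
    source_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ImageLayoutError("unsupported image layout: expected a "
                                   "non-empty single-plane grayscale image")
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel size must be positive")


@dataclass
class NormalizedImage:
    """An image resampled to the 1.56 nm/px reference scale."""

    pixels: np.ndarray
    scale_factor: float
    original_shape: tuple
    source_id: str = ""
    pixel_size_nm: float = REFERENCE_PIXEL_SIZE_NM


@dataclass
class PatchSet:
    """Overlapping tiles plus the layout needed for exact stitching."""

    patches: list = field(default_factory=list)
    offsets: list = field(default_factory=list)
    padded_shape: tuple = (0, 0)
    image_shape: tuple = (0, 0)
    patch_size: int = 400
    stride: int = 200


def read_image(path, pixel_size_nm: float, source_id: str | None = None) -> RawImage:
    """Load a single-plane grayscale TIFF (8- or 16-bit) with its pixel size.

    Raises
    ------
    FileNotFoundError : missing file.
    ImageLayoutError : RGB / multi-channel / stacked TIFF.
    ValueError : non-positive pixel size.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    if not pixel_size_nm > 0:
        raise ValueError("pixel size must be positive")
    pixels = tifffile.imread(path)
    if pixels.ndim != 2:
        raise ImageLayoutError(
            f"unsupported image layout: expected single-plane grayscale, "
            f"got shape {pixels.shape}")
    return RawImage(pixels=pixels, pixel_size_nm=float(pixel_size_nm),
                    source_id=source_id or path.stem)


def read_manifest(path) -> list:
    """Read a CSV manifest with columns ``path`` and ``pixel_size_nm``."""
    import pandas as pd

    df = pd.read_csv(path)
    missing = {"path", "pixel_size_nm"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest misses columns: {sorted(missing)}")
    base = Path(path).parent
    out = []
    for row in df.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = base / p
        out.append((p, float(row.pixel_size_nm)))
    return out


def _round_half_up(x: np.ndarray | float):
    return np.floor(np.asarray(x) + 0.5).astype(int)


def nearest_neighbor_indices(n_in: int, n_out: int) -> np.ndarray:
    """Source index for each output pixel under pixel-center mapping.

    Output pixel ``i`` samples the input pixel whose center is nearest to
    the back-projected center ``(i + 0.5) * n_in / n_out``, i.e.
    ``floor((i + 0.5) * n_in / n_out)`` clipped to the valid range.
    """
    idx = np.floor((np.arange(n_out) + 0.5) * (n_in / n_out)).astype(int)
    return np.clip(idx, 0, n_in - 1)


def resize_nearest(pixels: np.ndarray, out_shape: tuple) -> np.ndarray:
    """Nearest-neighbour resampling to an explicit output shape."""
    rows = nearest_neighbor_indices(pixels.shape[0], out_shape[0])
    cols = nearest_neighbor_indices(pixels.shape[1], out_shape[1])
    return pixels[np.ix_(rows, cols)]


def normalize_scale(img: RawImage,
                    reference_nm: float = REFERENCE_PIXEL_SIZE_NM) -> NormalizedImage:
    """Resample an image to the reference pixel size by nearest neighbour.

    The output dimensions are ``round_half_up(shape * factor)`` per axis
    with ``factor = pixel_size_nm / reference_nm``.  Nearest-neighbour
    sampling never interpolates, so output intensities are a subset of
    the input intensities.
    """
    factor = img.pixel_size_nm / reference_nm
    out_shape = tuple(int(v) for v in _round_half_up(np.array(img.pixels.shape) * factor))
    if min(out_shape) < 1:
        raise ValueError(f"image degenerates to {out_shape} at the "
                         f"reference scale {reference_nm} nm/px")
    if out_shape == img.pixels.shape:
        resized = img.pixels.copy()
    else:
        resized = resize_nearest(img.pixels, out_shape)
    return NormalizedImage(pixels=resized, scale_factor=factor,
                           original_shape=tuple(img.pixels.shape),
                           source_id=img.source_id,
                           pixel_size_nm=reference_nm)


def _grid_starts(extent: int, patch: int, stride: int) -> np.ndarray:
    if extent <= patch:
        return np.array([0])
    n = int(np.ceil((extent - patch) / stride)) + 1
    return np.arange(n) * stride


def tile(img: NormalizedImage | np.ndarray, patch: int = 400,
         stride: int = 200, normalize: bool = True) -> PatchSet:
    """Cut an image into overlapping ``patch`` x ``patch`` tiles.

    The image is mirror-padded (bottom/right) to the smallest canvas on
    which a stride grid of full patches covers every original pixel:
    symmetric padding keeps edge tiles statistically indistinguishable
    from interior ones, so their contrast stretch and the network's
    predictions stay meaningful (zero padding would fill edge tiles with
    content unlike anything in the training distribution).  With
    ``normalize=True`` each tile is independently contrast-stretched to
    [0, 1] (the network's expected input).
    """
    if patch < stride or stride < 1:
        raise ValueError("need patch >= stride >= 1")
    pixels = img.pixels if isinstance(img, NormalizedImage) else np.asarray(img)
    H, W = pixels.shape
    rows = _grid_starts(H, patch, stride)
    cols = _grid_starts(W, patch, stride)
    padded_shape = (int(rows[-1] + patch), int(cols[-1] + patch))
    canvas = np.pad(pixels, ((0, padded_shape[0] - H),
                             (0, padded_shape[1] - W)), mode="symmetric")
    patches, offsets = [], []
    for r in rows:
        for c in cols:
            p = canvas[r:r + patch, c:c + patch]
            patches.append(stretch_intensity(p) if normalize
                           else p.astype(np.float32))
            offsets.append((int(r), int(c)))
    return PatchSet(patches=patches, offsets=offsets,
                    padded_shape=padded_shape, image_shape=(H, W),
                    patch_size=patch, stride=stride)


def stretch_intensity(patch: np.ndarray) -> np.ndarray:
    """Linearly stretch a patch's intensity histogram to [0, 1].

    A constant patch maps to all zeros (the stretch is undefined there,
    and zero is the conventional background level).
    """
    patch = np.asarray(patch, dtype=np.float32)
    lo = float(patch.min())
    hi = float(patch.max())
    if hi == lo:
        return np.zeros_like(patch)
    return (patch - lo) / (hi - lo)
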