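"""Whole-volume prediction: sliding window, probability map, binarization.

Large volumes are tiled with overlapping 128-cube windows (stride 25 in X
and Y; the Z extent equals the window after preprocessing).  Per-voxel
outputs, mapped from the generator's [-1, 1] range to [0, 1], are summed
together with visit counts and averaged, giving a probability map.  The
map is cubic-resampled along Z back to the acquisition depth (140 voxels)
and thresholded on its intensity histogram (Otsu's criterion by default)
to produce the final binary vessel mask.

The volume is symmetrically padded in X/Y for full-overlap tiling (each
side by at least ``window - stride``, rounded up so the stride tiles the
padded extent exactly), so border voxels are visited by as many windows as
interior ones; per-voxel counts are tracked explicitly and are exactly
uniform whenever the stride divides the window.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Tuple

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .emulator import IntensityVolume3D
from .vessel_synth import BinaryMask3D

__all__ = ["ProbabilityMap3D", "coverage_counts", "symmetric_pad_amount",
           "sliding_window_predict", "binarize"]

DEFAULT_WINDOW = 128
DEFAULT_STRIDE = 25
ACQUISITION_Z = 140


@dataclass
class ProbabilityMap3D:
    """Accumulated sliding-window output: sum, count and mean grids."""
    sum: np.ndarray
    count: np.ndarray
    voxel_size_um: float = 20.0

    def __post_init__(self):
        if self.sum.shape != self.count.shape:
            raise ValueError("sum and count grids must share a shape")
        if (self.count < 1).any():
            raise ValueError("every voxel must be covered at least once")

    @property
    def mean(self) -> np.ndarray:
        return (self.sum / self.count).astype(np.float32)


def symmetric_pad_amount(extent: int, window: int, stride: int
                         ) -> Tuple[int, int]:
    """Symmetric (lo, hi) padding for full-overlap tiling.

    Each side is padded by at least ``window - stride`` so that border
    voxels are visited by as many windows as interior ones (no edge
    deficit), then the total is rounded up so ``padded - window`` is a
    multiple of ``stride``; an odd remainder goes to the trailing side.
    With this rule the per-voxel visit count is exactly uniform whenever
    the stride divides the window.
    """
    side = max(window - stride, 0)
    if extent + 2 * side < window:
        side = -(-(window - extent) // 2)
    total = 2 * side + ((-(extent + 2 * side - window)) % stride)
    return total // 2, total - total // 2


def coverage_counts(extent: int, window: int, stride: int) -> np.ndarray:
    """Per-voxel window-visit counts along one padded axis, by explicit
    enumeration of window placements."""
    lo, hi = symmetric_pad_amount(extent, window, stride)
    padded = extent + lo + hi
    counts = np.zeros(padded, dtype=int)
    for start in range(0, padded - window + 1, stride):
        counts[start:start + window] += 1
    return counts[lo:lo + extent]


def sliding_window_predict(vol, model: Callable,
                           window: int = DEFAULT_WINDOW,
                           stride_xy: int = DEFAULT_STRIDE,
                           batch_size: int = 1) -> ProbabilityMap3D:
    """Tile a preprocessed volume and average model outputs per voxel.

    ``vol`` is (X, Y, Z) with Z equal to ``window``; ``model`` maps a
    (N, X, Y, Z, 1) array in [-1, 1] to same-shape output in [-1, 1]
    (anything exposing ``predict_volume`` or plain ``__call__`` on numpy
    arrays works).  Outputs are mapped to [0, 1] before accumulation.
    """
    if stride_xy <= 0:
        raise ValueError("stride must be positive")
    voxel_size = vol.voxel_size_um if isinstance(vol, IntensityVolume3D) \
        else 20.0
    data = vol.values if isinstance(vol, IntensityVolume3D) \
        else np.asarray(vol, dtype=np.float32)
    X, Y, Z = data.shape
    if Z != window:
        raise ValueError(f"Z extent ({Z}) must equal the window ({window})")
    (xl, xh) = symmetric_pad_amount(X, window, stride_xy)
    (yl, yh) = symmetric_pad_amount(Y, window, stride_xy)
    padded = np.pad(data, ((xl, xh), (yl, yh), (0, 0)), mode="symmetric")
    PX, PY = padded.shape[:2]
    acc = np.zeros(padded.shape, dtype=np.float64)
    cnt = np.zeros(padded.shape, dtype=np.int64)
    starts = [(sx, sy)
              for sx in range(0, PX - window + 1, stride_xy)
              for sy in range(0, PY - window + 1, stride_xy)]
    for i in range(0, len(starts), batch_size):
        chunk = starts[i:i + batch_size]
        batch = np.stack([
            padded[sx:sx + window, sy:sy + window, :] for sx, sy in chunk])
        out = model(batch[..., None])
        out = np.asarray(getattr(out, "data", out))[..., 0]
        prob = (out + 1.0) * 0.5
        for (sx, sy), p in zip(chunk, prob):
            acc[sx:sx + window, sy:sy + window, :] += p
            cnt[sx:sx + window, sy:sy + window, :] += 1
    core = (slice(xl, xl + X), slice(yl, yl + Y), slice(None))
    return ProbabilityMap3D(acc[core], cnt[core], voxel_size)


def binarize(pmap, target_z: int = ACQUISITION_Z,
             threshold: float | None = None,
             voxel_size_um: float | None = None) -> BinaryMask3D:
    """Upsample the probability map along Z and threshold its histogram.

    Threshold selection defaults to Otsu's criterion; pass ``threshold``
    to override.  A constant map yields an empty mask with a warning.
    """
    if isinstance(pmap, ProbabilityMap3D):
        mean = pmap.mean
        voxel_size_um = voxel_size_um or pmap.voxel_size_um
    else:
        mean = np.asarray(pmap, dtype=np.float32)
        voxel_size_um = voxel_size_um or 20.0
    z = mean.shape[2]
    if z != target_z:
        up = ndimage.zoom(mean.astype(np.float64),
                          (1.0, 1.0, target_z / z), order=3,
                          mode="nearest", grid_mode=True)
        up = np.clip(up, 0.0, 1.0)
    else:
        up = mean.astype(np.float64)
    if threshold is None:
        if np.ptp(up) < 1e-9:
            warnings.warn("constant probability map; returning empty mask")
            return BinaryMask3D(np.zeros(up.shape, np.uint8), voxel_size_um)
        threshold = float(threshold_otsu(up))
    return BinaryMask3D((up > threshold).astype(np.uint8), voxel_size_um)
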