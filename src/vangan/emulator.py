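"""Synthetic photoacoustic-appearance emulator and the preprocessing chain.

``emulate_pai`` turns a binary vessel mask into a grayscale volume with the
hallmark artefacts of mesoscopic photoacoustic imaging: depth-dependent
signal decay, the limited-illumination artefact (only the upper surface of
a vessel is excited at full strength, so circular cross-sections appear as
arcs), point-spread blur and background noise.  It is a fast, synthetic
stand-in for full optical/acoustic simulation and makes no claim to
physical accuracy -- its role is to provide an imaging domain whose
statistics are qualitatively photoacoustic.

``preprocess`` implements the normalisation chain applied to every imaging
volume before training/inference: XY slice-wise z-scoring, two-sided
0.05% percentile clipping, cubic resampling of the Z axis to 128 voxels,
and an affine rescale to [-1, 1].
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage

from .vessel_synth import BinaryMask3D

__all__ = ["EmulatorParams", "IntensityVolume3D", "emulate_pai",
           "emulate_training_fixture", "preprocess", "TARGET_Z"]

TARGET_Z = 128  # Z extent after preprocessing (network input depth)


@dataclass
class EmulatorParams:
    """Knobs of the appearance model.

    surface_z: voxel index of the illuminated surface (Z=0 side).
    attenuation_per_mm: exponential decay of signal with depth below it.
    illum_arc_weight: fraction by which voxels below a vessel's own top
        surface are dimmed (0 = no artefact, 1 = only the arc survives).
    psf_sigma_vox: isotropic Gaussian blur emulating the system PSF.
    noise_sigma: additive Gaussian background noise level.
    """
    surface_z: int = 0
    attenuation_per_mm: float = 0.8
    illum_arc_weight: float = 0.6
    psf_sigma_vox: float = 1.0
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.attenuation_per_mm < 0:
            raise ValueError("attenuation_per_mm must be >= 0")
        if not 0.0 <= self.illum_arc_weight <= 1.0:
            raise ValueError("illum_arc_weight must be in [0, 1]")
        if self.psf_sigma_vox < 0 or self.noise_sigma < 0:
            raise ValueError("psf_sigma_vox and noise_sigma must be >= 0")


@dataclass
class IntensityVolume3D:
    """Scalar voxel grid in (X, Y, Z) order; Z is depth below the surface."""
    values: np.ndarray
    voxel_size_um: float = 20.0
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError("volume must be 3-D")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape


def emulate_pai(mask: BinaryMask3D, params: EmulatorParams | None = None
                ) -> IntensityVolume3D:
    """Render a binary mask as a synthetic photoacoustic intensity volume.

    Signal model, applied in order: unit vessel intensity, times
    ``exp(-attenuation * depth_mm)``, times the illumination factor (the
    top-surface voxel of each vertical vessel run keeps full strength,
    deeper voxels of the same run are scaled by ``1 - illum_arc_weight``),
    then Gaussian blur and additive Gaussian noise.  Deterministic given
    ``params.seed``.
    """
    params = params or EmulatorParams()
    m = mask.values.astype(np.float32)
    X, Y, Z = m.shape
    depth_vox = np.maximum(np.arange(Z) - params.surface_z, 0)
    depth_mm = depth_vox * mask.voxel_size_um / 1000.0
    signal = m * np.exp(-params.attenuation_per_mm * depth_mm)[None, None, :]
    if params.illum_arc_weight > 0:
        above = np.zeros_like(mask.values)
        above[:, :, 1:] = mask.values[:, :, :-1]
        top_surface = (mask.values == 1) & (above == 0)
        dim = np.where(top_surface, 1.0, 1.0 - params.illum_arc_weight)
        signal = signal * np.where(mask.values == 1, dim, 1.0)
    if params.psf_sigma_vox > 0:
        signal = ndimage.gaussian_filter(signal, params.psf_sigma_vox)
    if params.noise_sigma > 0:
        rng = np.random.default_rng(params.seed)
        signal = signal + rng.normal(
            0.0, params.noise_sigma, size=signal.shape).astype(np.float32)
    return IntensityVolume3D(signal, mask.voxel_size_um, normalized=False)


def emulate_training_fixture(mask: BinaryMask3D,
                             params: EmulatorParams | None = None
                             ) -> IntensityVolume3D:
    """Emulated volume mapped directly to the [-1, 1] network range.

    Unlike acquired data, emulated fixtures have a known physical scale, so
    they can enter the network input range by the affine map ``2 s - 1``
    (clipped) without the slice-normalisation chain that corrects real
    acquisitions.  Used for controlled desk-scale training studies where
    the signal-to-noise ratio of the inputs must be set exactly.
    """
    vol = emulate_pai(mask, params)
    signed = np.clip(vol.values * 2.0 - 1.0, -1.0, 1.0)
    return IntensityVolume3D(signed, vol.voxel_size_um, normalized=True)


def _resample_z_cubic(vol: np.ndarray, target_z: int) -> np.ndarray:
    """Cubic-spline resampling along Z only."""
    z = vol.shape[2]
    if z == target_z:
        return vol.astype(np.float32)
    out = ndimage.zoom(vol.astype(np.float64), (1.0, 1.0, target_z / z),
                       order=3, mode="nearest", grid_mode=True)
    if out.shape[2] != target_z:  # guard against rounding in zoom
        coords = np.linspace(0, z - 1, target_z)
        out = out[:, :, :target_z] if out.shape[2] > target_z else np.pad(
            out, ((0, 0), (0, 0), (0, target_z - out.shape[2])), mode="edge")
    return out.astype(np.float32)


def preprocess(vol, target_z: int = TARGET_Z,
               clip_percent: float = 0.05,
               voxel_size_um: float | None = None) -> IntensityVolume3D:
    """Normalise a raw imaging volume for the networks.

    Steps, in order: per-XY-slice z-score (constant slices map to zero),
    global clipping at the ``clip_percent``/``100 - clip_percent``
    percentiles, cubic Z-resampling to ``target_z``, affine rescale so
    min -> -1 and max -> +1.  A globally constant volume maps to all zeros.
    """
    if isinstance(vol, IntensityVolume3D):
        data = vol.values
        voxel_size_um = voxel_size_um or vol.voxel_size_um
    else:
        data = np.asarray(vol, dtype=np.float32)
        voxel_size_um = voxel_size_um or 20.0
    if data.ndim != 3:
        raise ValueError("expected a 3-D volume")
    if data.shape[2] < 2:
        raise ValueError("Z extent must be >= 2")
    data = data.astype(np.float64)
    mu = data.mean(axis=(0, 1), keepdims=True)
    sd = data.std(axis=(0, 1), keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (data - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    lo, hi = np.percentile(z, (clip_percent, 100.0 - clip_percent))
    z = np.clip(z, lo, hi)
    z = _resample_z_cubic(z, target_z)
    zmin, zmax = float(z.min()), float(z.max())
    if zmax - zmin <= 0:
        out = np.zeros_like(z, dtype=np.float32)
    else:
        out = (2.0 * (z - zmin) / (zmax - zmin) - 1.0).astype(np.float32)
    return IntensityVolume3D(out, voxel_size_um, normalized=True)
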