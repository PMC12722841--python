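"""Volumetric transmit-field (B1) mapping from an FSE double-angle pair.

The double-angle method (DAM) estimates kappa, the ratio of the actual to
the nominal flip angle, from two long-TR acquisitions at nominal angles
alpha and 2*alpha: cos(kappa*alpha) = S(2a) / (2 S(a)). Because the true
transmit field varies on centimeter scales, the raw map is optionally
smoothed (masked normalized convolution over valid voxels only, so invalid
rims do not bleed zeros into the brain edge) and resampled onto the qT1
acquisition grid by trilinear interpolation through the NIfTI affines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .relaxometry import dam_kappa_voxel

__all__ = ["B1Map", "compute_b1_map", "smooth_resample_b1"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class B1Map:
    """kappa field with a validity mask and grid metadata."""

    kappa: np.ndarray
    valid: np.ndarray
    affine: np.ndarray
    voxel_size: tuple[float, float, float]


def _voxel_size_from_affine(affine: np.ndarray) -> tuple[float, float, float]:
    return tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))


def compute_b1_map(
    vol_a: np.ndarray,
    vol_2a: np.ndarray,
    affine: np.ndarray,
    nominal_alpha: float = 60.0,
    scale_const: float = 1.0,
    signal_floor: float = 0.0,
    kappa_bounds: tuple[float, float] = (0.25, 2.0),
) -> B1Map:
    """Voxel-wise DAM inversion of the 60/120-degree FSE pair.

    Validity is false where the inversion is undefined (ratio outside
    arccos domain, non-positive low-angle signal), where the low-angle
    signal falls below ``signal_floor``, or where kappa leaves
    ``kappa_bounds`` (physically implausible transmit scaling).
    """
    if vol_a.shape != vol_2a.shape:
        raise ValueError(
            f"DAM volumes disagree on grid: {vol_a.shape} vs {vol_2a.shape}"
        )
    kappa, valid = dam_kappa_voxel(vol_a, vol_2a, nominal_alpha, scale_const)
    valid &= vol_a > signal_floor
    with np.errstate(invalid="ignore"):
        valid &= (kappa >= kappa_bounds[0]) & (kappa <= kappa_bounds[1])
    kappa = np.where(valid, kappa, np.nan)
    return B1Map(kappa, valid, np.asarray(affine, dtype=float),
                 _voxel_size_from_affine(affine))


def smooth_resample_b1(
    b1: B1Map,
    target_shape: tuple[int, int, int] | None = None,
    target_affine: np.ndarray | None = None,
    smoothing_fwhm: float = 8.0,
) -> B1Map:
    """Smooth the kappa field over valid voxels and resample to a target grid.

    Smoothing is normalized convolution: Gaussian-smooth kappa*mask and the
    mask separately and divide, which preserves constant fields exactly and
    fills isolated invalid voxels from their neighbourhood instead of
    pulling them toward zero. With ``smoothing_fwhm = 0`` and an identical
    grid the operation is the identity. Resampling is trilinear on kappa
    and nearest-neighbour on validity, composed through the affines
    (voxel_target -> world -> voxel_source).
    """
    if smoothing_fwhm < 0:
        raise ValueError("smoothing fwhm must be >= 0")
    if not b1.valid.any():
        raise ValueError("empty validity mask: no valid B1 voxels to smooth")
    if target_shape is None:
        target_shape = b1.kappa.shape
    if target_affine is None:
        target_affine = b1.affine
    target_affine = np.asarray(target_affine, dtype=float)

    mask = b1.valid.astype(float)
    kfill = np.where(b1.valid, b1.kappa, 0.0)
    if smoothing_fwhm > 0:
        sigma_mm = smoothing_fwhm * _FWHM_TO_SIGMA
        sigma_vox = [sigma_mm / vs for vs in b1.voxel_size]
        num = gaussian_filter(kfill, sigma_vox)
        den = gaussian_filter(mask, sigma_vox)
        with np.errstate(invalid="ignore", divide="ignore"):
            smoothed = np.where(den > 1e-8, num / np.where(den > 1e-8, den, 1.0), np.nan)
        smooth_valid = den > 1e-8
    else:
        smoothed = np.where(b1.valid, b1.kappa, np.nan)
        smooth_valid = b1.valid.copy()

    same_grid = (
        tuple(target_shape) == b1.kappa.shape
        and np.allclose(target_affine, b1.affine)
    )
    if same_grid:
        out_k, out_v = smoothed, smooth_valid
    else:
        # voxel coordinates of the target grid expressed in source voxel space
        tgt = np.indices(target_shape, dtype=float).reshape(3, -1)
        world = target_affine[:3, :3] @ tgt + target_affine[:3, 3:4]
        inv = np.linalg.inv(b1.affine)
        src = inv[:3, :3] @ world + inv[:3, 3:4]
        filled = np.where(smooth_valid, smoothed, 0.0)
        out_k = map_coordinates(filled, src, order=1, mode="nearest").reshape(target_shape)
        out_v = (
            map_coordinates(smooth_valid.astype(float), src, order=0, mode="nearest")
            .reshape(target_shape) > 0.5
        )
        out_k = np.where(out_v, out_k, np.nan)
    return B1Map(out_k, out_v, target_affine,
                 _voxel_size_from_affine(target_affine))
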