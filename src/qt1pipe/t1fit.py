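"""Per-subject quantitative T1 map production.

Echo handling (the multi-echo protocol averages its five echoes per flip
angle before fitting), B1-corrected two-point VFA fitting, QC masking, and
simple map arithmetic. Fitting is purely voxel-wise; acquisition voxel
anisotropy travels in the grid metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .b1map import B1Map
from .phantom import VolumeSet
from .relaxometry import DEFAULT_T1_BOUNDS, AcquisitionProtocol, vfa_fit_voxel

logger = logging.getLogger(__name__)

__all__ = ["T1Map", "average_echoes", "fit_t1_volume", "difference_map"]


@dataclass
class T1Map:
    """Fitted T1/M0 fields with a joint validity mask."""

    t1: np.ndarray        # ms, NaN where invalid
    m0: np.ndarray
    valid: np.ndarray
    protocol: str
    affine: np.ndarray
    qc: dict | None = None


def average_echoes(vols: VolumeSet, strategy: str = "mean", first_k: int | None = None) -> VolumeSet:
    """Collapse the echo dimension to one volume per flip angle.

    ``strategy``:
      - "mean": unweighted arithmetic mean over echoes (the default
        analysis choice),
      - "te_weighted": mean weighted by echo time, emphasizing late echoes,
      - "first_k": unweighted mean of the first ``first_k`` echoes —
        both alternatives trade T2* weighting against noise accumulation.

    Single-echo sets pass through unchanged. The output volume for each
    flip angle is keyed by the mean of the echo times it averaged.
    """
    by_alpha: dict[float, list[tuple[float, np.ndarray]]] = {}
    for (alpha, te), vol in sorted(vols.volumes.items()):
        by_alpha.setdefault(alpha, []).append((te, vol))
    counts = {len(v) for v in by_alpha.values()}
    if len(counts) != 1:
        raise ValueError(f"ragged echo structure across flip angles: {counts}")
    if counts == {1}:
        return vols

    out: dict[tuple[float, float], np.ndarray] = {}
    for alpha, echoes in by_alpha.items():
        tes = np.array([te for te, _ in echoes])
        stack = np.stack([v for _, v in echoes], axis=0)
        if strategy == "mean":
            avg = stack.mean(axis=0)
        elif strategy == "te_weighted":
            w = tes / tes.sum()
            avg = np.tensordot(w, stack, axes=1)
        elif strategy == "first_k":
            if not first_k or first_k < 1:
                raise ValueError("first_k strategy needs first_k >= 1")
            avg = stack[:first_k].mean(axis=0)
            tes = tes[:first_k]
        else:
            raise ValueError(f"unknown echo strategy: {strategy!r}")
        out[(alpha, float(tes.mean()))] = avg
    return VolumeSet(protocol=vols.protocol, volumes=out, affine=vols.affine)


def fit_t1_volume(
    vols: VolumeSet,
    protocol: AcquisitionProtocol | None = None,
    b1: B1Map | None = None,
    mask: np.ndarray | None = None,
    t1_bounds: tuple[float, float] = DEFAULT_T1_BOUNDS,
    echo_strategy: str = "mean",
    first_k: int | None = None,
) -> T1Map:
    """Voxel-wise B1-corrected VFA fit of a two-flip-angle acquisition.

    Echoes are collapsed first; exactly two flip-angle volumes must remain.
    Where the B1 map is invalid the fit falls back to kappa = 1 and the
    voxel is excluded from the validity mask (flagged, not clipped). The
    final mask combines fit validity, B1 validity, and the optional
    anatomical ``mask``. QC summary (fraction valid, median valid T1) is
    attached and logged.
    """
    protocol = protocol or vols.protocol
    avg = average_echoes(vols, strategy=echo_strategy, first_k=first_k)
    alphas = avg.flip_angles
    if len(alphas) != 2:
        raise ValueError(f"need exactly two flip angles after averaging, got {alphas}")
    a1, a2 = alphas
    s1 = avg.echoes(a1)[0]
    s2 = avg.echoes(a2)[0]
    if s1.shape != s2.shape:
        raise ValueError("flip-angle volumes disagree on grid")

    if b1 is not None:
        if b1.kappa.shape != s1.shape:
            raise ValueError(
                "B1 map grid does not match the acquisition; resample first "
                f"({b1.kappa.shape} vs {s1.shape})"
            )
        kappa = np.where(b1.valid, b1.kappa, 1.0)
        b1_ok = b1.valid
    else:
        kappa = np.ones_like(s1)
        b1_ok = np.ones(s1.shape, dtype=bool)

    t1, m0, fit_ok = vfa_fit_voxel(s1, s2, a1, a2, protocol.tr, kappa, t1_bounds)
    valid = fit_ok & b1_ok
    if mask is not None:
        if mask.shape != s1.shape:
            raise ValueError("mask grid does not match the acquisition")
        valid &= mask.astype(bool)
    t1 = np.where(valid, t1, np.nan)
    m0 = np.where(valid, m0, np.nan)

    frac = float(valid.mean())
    med = float(np.nanmedian(t1)) if valid.any() else np.nan
    qc = {"fraction_valid": frac, "median_t1_ms": med, "protocol": protocol.name}
    logger.info("fit %s: %.1f%% voxels valid, median T1 %.0f ms",
                protocol.name, 100 * frac, med)
    return T1Map(t1, m0, valid, protocol.name, avg.affine, qc)


def difference_map(t1_a: T1Map, t1_b: T1Map) -> np.ndarray:
    """Voxel-wise a - b (ms) where both maps are valid, NaN elsewhere."""
    if t1_a.t1.shape != t1_b.t1.shape:
        raise ValueError("difference requires a shared grid")
    both = t1_a.valid & t1_b.valid
    return np.where(both, t1_a.t1 - t1_b.t1, np.nan)
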