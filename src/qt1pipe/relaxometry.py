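"""Closed-form spoiled gradient-echo (SPGR) signal models and their inverses.

This is the mathematical core shared by the phantom simulator and the
voxel-wise fitting stage: the steady-state SPGR signal equation, its
echo-time (T2*) extension, the Ernst angle, the two-point variable
flip angle (VFA / DESPOT1) T1 solve, and the double-angle method (DAM)
inversion for the transmit-field ratio kappa.

All angles are degrees at every public interface (converted to radians
internally, once); all times are milliseconds. Every function accepts
scalars or numpy arrays and broadcasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AcquisitionProtocol",
    "RelaxationParams",
    "spgr_signal",
    "spgr_signal_echo",
    "ernst_angle",
    "vfa_fit_voxel",
    "vfa_fit_regression",
    "dam_kappa_voxel",
    "DEFAULT_T1_BOUNDS",
]

#: Plausibility bounds for fitted T1 (ms); fits outside are flagged invalid,
#: never clipped, so QC masks stay honest.
DEFAULT_T1_BOUNDS = (1.0, 10_000.0)

_ME_FIRST_TE = 3.36
_ME_ECHO_SPACING = 4.42
_ME_N_ECHOES = 5


@dataclass(frozen=True)
class AcquisitionProtocol:
    """One SPGR or FSE-DAM acquisition: flip angles, TR, echo times.

    ``flip_angles`` and ``echo_times`` are degrees and ms respectively;
    ``nominal_voxel`` is the acquired voxel size in mm and is metadata only
    (fitting is purely voxel-wise).
    """

    name: str
    flip_angles: tuple[float, ...]
    tr: float
    echo_times: tuple[float, ...]
    nominal_voxel: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if not self.flip_angles or not self.echo_times:
            raise ValueError("protocol needs >=1 flip angle and >=1 echo")
        if any(not 0.0 < a <= 180.0 for a in self.flip_angles):
            raise ValueError("flip angles must lie in (0, 180] degrees")
        if not self.tr > max(self.echo_times):
            raise ValueError("TR must exceed the longest echo time")
        if min(self.echo_times) < 0:
            raise ValueError("echo times must be >= 0")

    @classmethod
    def single_echo(cls, tr: float = 7.0) -> "AcquisitionProtocol":
        """Sagittal single-echo qT1 protocol: alpha = 3/14 deg, TE = 4.948 ms.

        The source protocol does not pin down TR, so it is a parameter here;
        simulation and fitting always use the same declared value.
        """
        return cls("SE-qT1", (3.0, 14.0), tr, (4.948,), (1.0, 1.0, 1.0))

    @classmethod
    def multi_echo(cls) -> "AcquisitionProtocol":
        """Axial fast-SPGR multi-echo qT1 protocol: alpha = 3/24 deg, TR = 28.5 ms,
        5 echoes at TE = 3.36 + 4.42 k ms."""
        tes = tuple(_ME_FIRST_TE + _ME_ECHO_SPACING * k for k in range(_ME_N_ECHOES))
        return cls("ME-qT1", (3.0, 24.0), 28.5, tes, (0.5, 0.5, 2.0))

    @classmethod
    def fse_dam(cls) -> "AcquisitionProtocol":
        """FSE double-angle B1 protocol at nominal 60/120 degrees."""
        return cls("FSE-DAM", (60.0, 120.0), 15_000.0, (14.0,), (1.0, 1.0, 1.0))


@dataclass(frozen=True)
class RelaxationParams:
    """Voxel relaxation parameters: T1 (ms), equilibrium magnetization M0
    (arbitrary units), and optionally T2* (ms, ``inf`` = no echo decay)."""

    t1: float
    m0: float = 1.0
    t2star: float = field(default=np.inf)

    def __post_init__(self) -> None:
        if self.t1 <= 0:
            raise ValueError("t1 must be > 0")
        if self.t2star <= 0:
            raise ValueError("t2star must be > 0")
        if self.m0 < 0:
            raise ValueError("m0 must be >= 0")


def spgr_signal(m0, t1, tr: float, alpha_deg):
    """Steady-state spoiled GRE magnitude S = M0 sin(a) (1-E1) / (1-cos(a) E1).

    E1 = exp(-TR/T1). Ideal spoiling, TE = 0. Broadcasts over arrays.
    """
    t1 = np.asarray(t1, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("t1 must be > 0")
    if tr <= 0:
        raise ValueError("tr must be > 0")
    a = np.deg2rad(np.asarray(alpha_deg, dtype=float))
    e1 = np.exp(-tr / t1)
    return np.asarray(m0) * np.sin(a) * (1.0 - e1) / (1.0 - np.cos(a) * e1)


def spgr_signal_echo(m0, t1, t2star, tr: float, alpha_deg, te):
    """SPGR signal at echo time ``te``: ``spgr_signal * exp(-TE/T2*)``.

    ``t2star = inf`` recovers the TE = 0 signal exactly.
    """
    te = np.asarray(te, dtype=float)
    if np.any(te >= tr):
        raise ValueError("te must be < tr")
    if np.any(te < 0):
        raise ValueError("te must be >= 0")
    t2star = np.asarray(t2star, dtype=float)
    if np.any(t2star <= 0):
        raise ValueError("t2star must be > 0")
    with np.errstate(divide="ignore"):
        decay = np.exp(-te / t2star)
    return spgr_signal(m0, t1, tr, alpha_deg) * decay


def ernst_angle(tr: float, t1) -> np.ndarray | float:
    """Flip angle (degrees) maximizing the SPGR signal: arccos(exp(-TR/T1))."""
    t1 = np.asarray(t1, dtype=float)
    if tr <= 0 or np.any(t1 <= 0):
        raise ValueError("tr and t1 must be > 0")
    out = np.rad2deg(np.arccos(np.exp(-tr / t1)))
    return float(out) if out.ndim == 0 else out


def vfa_fit_voxel(
    s1,
    s2,
    alpha1_deg: float,
    alpha2_deg: float,
    tr: float,
    kappa=1.0,
    t1_bounds: tuple[float, float] = DEFAULT_T1_BOUNDS,
):
    """Two-point VFA (DESPOT1) solve for T1 and M0 with B1 correction.

    The nominal angles are first corrected voxel-wise, a_i' = kappa * a_i,
    then the SPGR equation is linearized as y = E1 x + M0 (1 - E1) with
    y = S/sin(a'), x = S/tan(a'), giving the closed-form two-point slope

        E1 = (s1/sin a1' - s2/sin a2') / (s1/tan a1' - s2/tan a2')

    and T1 = -TR / ln(E1). Because both measurements share any multiplicative
    factor (receive gain, common T2* attenuation), the slope — hence T1 — is
    invariant to overall scaling; the factor is absorbed into M0.

    Returns ``(t1, m0, valid)``. Voxels where the solve is degenerate
    (zero denominator), E1 falls outside (0, 1), or T1 leaves ``t1_bounds``
    are flagged invalid (with NaN outputs), never clipped and never raised.
    """
    if alpha1_deg == alpha2_deg:
        raise ValueError("flip angles must differ")
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa <= 0):
        raise ValueError("kappa must be > 0")
    a1 = np.deg2rad(alpha1_deg) * kappa
    a2 = np.deg2rad(alpha2_deg) * kappa

    y1, y2 = s1 / np.sin(a1), s2 / np.sin(a2)
    x1, x2 = s1 / np.tan(a1), s2 / np.tan(a2)
    denom = x1 - x2
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = np.where(denom != 0, (y1 - y2) / np.where(denom != 0, denom, 1.0), np.nan)
        t1 = -tr / np.log(e1)
        # back-substitute the first point for M0
        m0 = s1 * (1.0 - np.cos(a1) * e1) / (np.sin(a1) * (1.0 - e1))

    lo, hi = t1_bounds
    valid = (
        np.isfinite(e1)
        & (e1 > 0.0)
        & (e1 < 1.0)
        & np.isfinite(t1)
        & (t1 >= lo)
        & (t1 <= hi)
        & np.isfinite(m0)
    )
    t1 = np.where(valid, t1, np.nan)
    m0 = np.where(valid, m0, np.nan)
    return t1, m0, valid


def vfa_fit_regression(
    signals,
    alphas_deg,
    tr: float,
    kappa=1.0,
    t1_bounds: tuple[float, float] = DEFAULT_T1_BOUNDS,
):
    """n-point generalization of :func:`vfa_fit_voxel` by least squares.

    ``signals`` is a sequence of n arrays (one per flip angle), n >= 2.
    Fits y = E1 x + b per voxel by ordinary least squares over the n
    linearized points; for n = 2 this reduces to the two-point solve.
    """
    alphas_deg = np.asarray(alphas_deg, dtype=float)
    if alphas_deg.size < 2 or np.unique(alphas_deg).size < alphas_deg.size:
        raise ValueError("need >=2 distinct flip angles")
    kappa = np.asarray(kappa, dtype=float)
    sig = np.stack([np.asarray(s, dtype=float) for s in signals], axis=0)
    a = np.deg2rad(alphas_deg).reshape((-1,) + (1,) * (sig.ndim - 1)) * kappa
    y = sig / np.sin(a)
    x = sig / np.tan(a)
    n = sig.shape[0]
    xm, ym = x.mean(axis=0), y.mean(axis=0)
    sxx = ((x - xm) ** 2).sum(axis=0)
    sxy = ((x - xm) * (y - ym)).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), np.nan)
        t1 = -tr / np.log(e1)
        b = ym - e1 * xm
        m0 = b / (1.0 - e1)
    lo, hi = t1_bounds
    valid = (
        np.isfinite(e1) & (e1 > 0) & (e1 < 1) & np.isfinite(t1) & (t1 >= lo) & (t1 <= hi)
    )
    return np.where(valid, t1, np.nan), np.where(valid, m0, np.nan), valid


def dam_kappa_voxel(s_a, s_2a, nominal_alpha_deg: float = 60.0, scale_const: float = 1.0):
    """Double-angle method (DAM) B1 inversion.

    From two acquisitions at nominal angles a and 2a with a common
    proportionality field, cos(kappa a) = S(2a) / (2 S(a)), so

        kappa = scale_const * arccos(S_2a / (2 S_a)) / a.

    ``scale_const`` is the scanner-specific calibration factor (default 1).
    Returns ``(kappa, valid)``; voxels with non-positive S_a or a ratio
    outside [-1, 1] are flagged invalid with NaN kappa.
    """
    if not 0.0 < nominal_alpha_deg < 90.0:
        raise ValueError("nominal alpha must lie in (0, 90) degrees")
    s_a = np.asarray(s_a, dtype=float)
    s_2a = np.asarray(s_2a, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = s_2a / (2.0 * s_a)
    valid = (s_a > 0) & np.isfinite(ratio) & (np.abs(ratio) <= 1.0)
    with np.errstate(invalid="ignore"):
        kappa = scale_const * np.rad2deg(np.arccos(np.where(valid, ratio, 0.0))) / nominal_alpha_deg
    kappa = np.where(valid, kappa, np.nan)
    return kappa, valid
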