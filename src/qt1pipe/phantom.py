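"""Synthetic phantoms and multi-subject cohorts with known ground truth.

Real cortical qT1 studies start from scanner data that cannot be shipped
with a pipeline; this module generates stand-ins with fully known truth so
every downstream stage (B1 mapping, VFA fitting, ROI statistics) is
testable end to end. The phantom is an ellipsoidal shell parcellated into
hemisphere-aware angular sectors (a deliberately simple stand-in for a
cortical parcellation such as Desikan-Killiany); acquisitions are simulated
from the closed-form SPGR/FSE signal models with Rician magnitude noise and
a smooth multiplicative transmit (B1) field.

The cohort generator plants group, sex, age and antipsychotic-dose (CPZe)
effects on regional T1 with a configurable between-subject spread, and
emits the covariate table and ground-truth ROI means alongside the images.
Defaults mirror a small case-control design: 14 patients (SSD) vs 7
controls (HC), patients older (47 +/- 14 vs 28 +/- 9.3 years), 57% male in
both groups, CPZe 548 +/- 320 mg in patients only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .relaxometry import AcquisitionProtocol, spgr_signal_echo

logger = logging.getLogger(__name__)

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "VolumeSet",
    "SubjectRecord",
    "CohortEffectSpec",
    "CohortResult",
    "DK_PARCELS",
    "TABLE2_ROIS",
    "default_roi_catalog",
    "make_phantom",
    "simulate_spgr",
    "simulate_dam",
    "make_cohort",
]

#: The 34 cortical parcels of the Desikan-Killiany atlas, used as default
#: ROI names when 34 ROIs per hemisphere are requested.
DK_PARCELS = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "fusiform", "inferiorparietal", "inferiortemporal",
    "isthmuscingulate", "lateraloccipital", "lateralorbitofrontal", "lingual",
    "medialorbitofrontal", "middletemporal", "parahippocampal", "paracentral",
    "parsopercularis", "parsorbitalis", "parstriangularis", "pericalcarine",
    "postcentral", "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "temporalpole",
    "transversetemporal", "insula", "frontalpole",
)

#: (name, hemisphere) pairs where the reference case-control analysis found
#: elevated single-echo qT1; the default planted group effect targets these.
TABLE2_ROIS = (
    ("temporalpole", "right"), ("superiorparietal", "right"),
    ("inferiorparietal", "right"), ("parstriangularis", "right"),
    ("parsorbitalis", "right"), ("precuneus", "right"), ("cuneus", "right"),
    ("superiorparietal", "left"), ("parstriangularis", "left"),
    ("parsorbitalis", "left"), ("parsopercularis", "left"),
    ("paracentral", "left"), ("medialorbitofrontal", "left"),
)


def default_roi_catalog(n_per_hemisphere: int) -> dict[int, tuple[str, str]]:
    """ROI id -> (name, hemisphere). Left hemisphere ids 1..K, right K+1..2K.

    With 34 ROIs per hemisphere the names are the Desikan-Killiany parcels;
    otherwise generic sector names are used.
    """
    if n_per_hemisphere < 1:
        raise ValueError("need >=1 ROI per hemisphere")
    if n_per_hemisphere == len(DK_PARCELS):
        names = DK_PARCELS
    else:
        names = tuple(f"sector{i + 1:02d}" for i in range(n_per_hemisphere))
    catalog: dict[int, tuple[str, str]] = {}
    for i, name in enumerate(names):
        catalog[i + 1] = (name, "left")
        catalog[n_per_hemisphere + i + 1] = (name, "right")
    return catalog


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue parameters and B1 model for one phantom."""

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    rois_per_hemisphere: int = 4
    t1: float = 1400.0          # ms, representative 3T cortex
    t2star: float = 50.0        # ms
    m0: float = 1.0
    b1_model: str = "polynomial"  # polynomial | random | uniform
    b1_range: tuple[float, float] = (0.85, 1.15)
    b1_bounds: tuple[float, float] = (0.5, 1.5)
    seed: int = 0


@dataclass
class PhantomTruth:
    """Ground-truth scalar fields and parcellation on a common grid."""

    grid_shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    t1_map: np.ndarray       # ms
    m0_map: np.ndarray       # a.u. >= 0
    t2star_map: np.ndarray   # ms
    b1_map: np.ndarray       # dimensionless kappa
    labels: np.ndarray       # int, 0 background
    roi_catalog: dict[int, tuple[str, str]]

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size) + [1.0])
        return aff

    def foreground(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class VolumeSet:
    """Acquired (simulated or loaded) magnitude volumes, indexed by
    (flip angle, echo time)."""

    protocol: AcquisitionProtocol
    volumes: dict[tuple[float, float], np.ndarray]
    affine: np.ndarray

    def get(self, alpha: float, te: float) -> np.ndarray:
        return self.volumes[(alpha, te)]

    def echoes(self, alpha: float) -> list[np.ndarray]:
        return [v for (a, _te), v in sorted(self.volumes.items()) if a == alpha]

    @property
    def flip_angles(self) -> tuple[float, ...]:
        return tuple(sorted({a for a, _ in self.volumes}))


def make_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Build an ellipsoidal-shell phantom with hemisphere-aware sector ROIs.

    The foreground is an ellipsoidal shell (a crude cortex); sectors are cut
    by azimuthal angle around the inferior-superior axis and split at the
    mid-sagittal plane into left (x < center) and right hemispheres. The
    default B1 field is a second-order polynomial bowl peaking mid-volume.
    Deterministic for a fixed spec (the only random element, the "random"
    B1 model, draws from ``spec.seed``).
    """
    nx, ny, nz = spec.grid_shape
    if min(nx, ny, nz) < 4:
        raise ValueError("grid dimensions must all be >= 4")
    if spec.t1 <= 0 or spec.t2star <= 0:
        raise ValueError("tissue T1 and T2* must be > 0")
    if spec.rois_per_hemisphere < 1:
        raise ValueError("need >=1 ROI per hemisphere")

    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    # normalized ellipsoid radius
    rho = np.sqrt(
        ((ii - cx) / (0.45 * nx)) ** 2
        + ((jj - cy) / (0.45 * ny)) ** 2
        + ((kk - cz) / (0.45 * nz)) ** 2
    )
    shell = (rho >= 0.35) & (rho <= 1.0)

    k = spec.rois_per_hemisphere
    theta = np.arctan2(kk - cz, jj - cy)  # azimuth around the x (L-R) axis
    sector = np.minimum((theta + np.pi) / (2 * np.pi) * k, k - 1e-9).astype(int)
    left = ii < cx
    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    labels[shell & left] = sector[shell & left] + 1
    labels[shell & ~left] = sector[shell & ~left] + 1 + k
    catalog = default_roi_catalog(k)

    present = set(np.unique(labels)) - {0}
    if present != set(catalog):
        raise ValueError(
            "ROI count exceeds resolvable foreground voxels: "
            f"missing ids {sorted(set(catalog) - present)}"
        )

    fg = labels > 0
    t1_map = np.where(fg, spec.t1, 0.0)
    t2s_map = np.where(fg, spec.t2star, np.inf)  # inf in background: no decay of zero signal
    m0_map = np.where(fg, spec.m0, 0.0)

    lo, hi = spec.b1_range
    if spec.b1_model == "uniform":
        b1 = np.full(spec.grid_shape, (lo + hi) / 2.0)
    elif spec.b1_model == "polynomial":
        # bowl: peak at volume center, quadratic fall-off to `lo` at rho_grid=1
        rho_grid = np.sqrt(
            ((ii - cx) / (nx / 2.0)) ** 2
            + ((jj - cy) / (ny / 2.0)) ** 2
            + ((kk - cz) / (nz / 2.0)) ** 2
        )
        b1 = hi - (hi - lo) * np.clip(rho_grid, 0.0, 1.0) ** 2
    elif spec.b1_model == "random":
        rng = np.random.default_rng(spec.seed)
        from scipy.ndimage import gaussian_filter

        raw = gaussian_filter(rng.standard_normal(spec.grid_shape), sigma=max(nx, ny, nz) / 6)
        raw = (raw - raw.min()) / max(raw.max() - raw.min(), 1e-12)
        b1 = lo + (hi - lo) * raw
    else:
        raise ValueError(f"unknown b1 model: {spec.b1_model!r}")
    b1 = np.clip(b1, *spec.b1_bounds)

    return PhantomTruth(
        grid_shape=spec.grid_shape,
        voxel_size=spec.voxel_size,
        t1_map=t1_map,
        m0_map=m0_map,
        t2star_map=t2s_map,
        b1_map=b1,
        labels=labels,
        roi_catalog=catalog,
    )


def _check_grids(truth: PhantomTruth) -> None:
    shapes = {
        truth.t1_map.shape, truth.m0_map.shape, truth.t2star_map.shape,
        truth.b1_map.shape, truth.labels.shape,
    }
    if shapes != {tuple(truth.grid_shape)}:
        raise ValueError(f"phantom fields disagree on grid shape: {shapes}")


def _add_noise(clean: np.ndarray, sigma: float, rng: np.random.Generator,
               model: str = "rician") -> np.ndarray:
    """Magnitude noise. Rician: |S + n1 + i n2| with n1, n2 ~ N(0, sigma)."""
    if sigma < 0:
        raise ValueError("noise sigma must be >= 0")
    if sigma == 0:
        return clean.copy()
    if model == "rician":
        re = clean + sigma * rng.standard_normal(clean.shape)
        im = sigma * rng.standard_normal(clean.shape)
        return np.sqrt(re * re + im * im)
    if model == "gaussian":
        return clean + sigma * rng.standard_normal(clean.shape)
    raise ValueError(f"unknown noise model: {model!r}")


def simulate_spgr(
    truth: PhantomTruth,
    protocol: AcquisitionProtocol,
    noise_sigma: float = 0.0,
    seed: int = 0,
    noise_model: str = "rician",
    m0_scale: float = 1.0,
) -> VolumeSet:
    """Simulate one magnitude volume per (flip angle, echo) of ``protocol``.

    The noiseless voxel value is the closed-form SPGR signal at the
    B1-corrected flip angle kappa*alpha with T2* decay at each TE;
    ``m0_scale`` rescales the whole acquisition (used to match signal
    budgets across protocols). Reproducible for a fixed seed.
    """
    _check_grids(truth)
    rng = np.random.default_rng(seed)
    fg = truth.foreground()
    t1 = np.where(fg, truth.t1_map, 1.0)  # placeholder T1 in background (M0=0 there)
    vols: dict[tuple[float, float], np.ndarray] = {}
    for alpha in protocol.flip_angles:
        eff_alpha = truth.b1_map * alpha
        for te in protocol.echo_times:
            clean = spgr_signal_echo(
                truth.m0_map * m0_scale, t1, truth.t2star_map, protocol.tr, eff_alpha, te
            )
            vols[(alpha, te)] = _add_noise(clean, noise_sigma, rng, noise_model)
    return VolumeSet(protocol=protocol, volumes=vols, affine=_affine(truth))


def simulate_dam(
    truth: PhantomTruth,
    nominal_alpha: float = 60.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    noise_model: str = "rician",
) -> VolumeSet:
    """Simulate the FSE double-angle pair at nominal ``alpha`` and ``2 alpha``.

    Noiseless values are M0 sin(kappa a) and M0 sin(2 kappa a): a long-TR
    FSE idealization in which the common proportionality field is M0.
    """
    if not 0.0 < nominal_alpha < 90.0:
        raise ValueError("nominal alpha must lie in (0, 90) degrees")
    _check_grids(truth)
    rng = np.random.default_rng(seed)
    protocol = AcquisitionProtocol(
        "FSE-DAM", (nominal_alpha, 2 * nominal_alpha), 15_000.0, (14.0,)
    )
    te = protocol.echo_times[0]
    vols = {}
    for alpha in protocol.flip_angles:
        clean = truth.m0_map * np.sin(np.deg2rad(truth.b1_map * alpha))
        vols[(alpha, te)] = _add_noise(clean, noise_sigma, rng, noise_model)
    return VolumeSet(protocol=protocol, volumes=vols, affine=_affine(truth))


def _affine(truth: PhantomTruth) -> np.ndarray:
    return np.diag(list(truth.voxel_size) + [1.0])


@dataclass(frozen=True)
class SubjectRecord:
    """One participant: group (SSD patient or HC control), age, sex, and
    chlorpromazine-equivalent dose (mg; defined only for SSD)."""

    subject_id: str
    group: str          # "SSD" | "HC"
    age: float          # years
    sex: str            # "M" | "F"
    cpze: float | None  # mg; None for HC

    def __post_init__(self) -> None:
        if self.group not in ("SSD", "HC"):
            raise ValueError("group must be SSD or HC")
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be M or F")
        if self.age <= 0:
            raise ValueError("age must be > 0")
        if self.group == "HC" and self.cpze is not None:
            raise ValueError("cpze must be absent for HC")
        if self.cpze is not None and self.cpze < 0:
            raise ValueError("cpze must be >= 0")


@dataclass(frozen=True)
class CohortEffectSpec:
    """Planted effect structure for a synthetic cohort.

    Regional true T1 for subject s in ROI r is

        T1[s, r] = baseline[r] + group_effect[r] * [SSD]
                   + sex_effect[r] * [female] + age_slope * age
                   + cpze_slope * cpze + N(0, between_subject_sd)

    Units: ms throughout; ``age_slope`` in ms/year, ``cpze_slope`` in ms/mg,
    ``noise_sigma`` is the Rician sigma of the simulated images in signal
    units. ``group_effect``/``sex_effect`` map ROI id -> ms (missing ids
    mean no effect); ``baseline_t1`` may be a scalar applied to all ROIs.
    The default between-subject spread of 50 ms reflects typical
    inter-subject variability of cortical T1 at 3T.
    """

    baseline_t1: float | dict[int, float] = 1400.0
    group_effect: dict[int, float] = field(default_factory=dict)
    sex_effect: dict[int, float] = field(default_factory=dict)
    age_slope: float = 0.0
    cpze_slope: float = 0.0
    between_subject_sd: float = 50.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.between_subject_sd < 0 or self.noise_sigma < 0:
            raise ValueError("spreads must be >= 0")


def default_effects(
    roi_catalog: dict[int, tuple[str, str]],
    group_effect_ms: float = 80.0,
    sex_effect_ms: float = -50.0,
    age_slope: float = -0.5,
    cpze_slope: float = -0.05,
    between_subject_sd: float = 50.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> CohortEffectSpec:
    """Study-shaped effect spec: +80 ms SSD elevation in the 13 reference
    ROIs (all ROIs when the catalog is not DK-named), females lower
    everywhere, a subtle negative age slope and CPZe modulation."""
    table2_ids = [
        rid for rid, (name, hemi) in roi_catalog.items() if (name, hemi) in TABLE2_ROIS
    ]
    if not table2_ids:
        table2_ids = list(roi_catalog)
    return CohortEffectSpec(
        baseline_t1=1400.0,
        group_effect={rid: group_effect_ms for rid in table2_ids},
        sex_effect={rid: sex_effect_ms for rid in roi_catalog},
        age_slope=age_slope,
        cpze_slope=cpze_slope,
        between_subject_sd=between_subject_sd,
        noise_sigma=noise_sigma,
        seed=seed,
    )


@dataclass
class CohortResult:
    """Synthetic cohort: covariates, ground-truth ROI means, and (optionally)
    the simulated acquisitions per subject per protocol."""

    subjects: list[SubjectRecord]
    covariates: pd.DataFrame          # subject_id, group, age, sex, cpze
    true_roi_means: pd.DataFrame      # subject_id x roi_id long table, ms
    roi_catalog: dict[int, tuple[str, str]]
    acquisitions: dict[str, dict[str, VolumeSet]]  # subject_id -> protocol name -> VolumeSet
    dam: dict[str, VolumeSet]                      # subject_id -> FSE-DAM VolumeSet
    truths: dict[str, PhantomTruth]                # subject_id -> per-subject truth


def _truncated_normal(
    mu: float, sd: float, lo: float, hi: float, rng: np.random.Generator
) -> float:
    """Rejection-sampled truncated normal (avoids the point masses clipping
    would create at the bounds)."""
    while True:
        x = rng.normal(mu, sd)
        if lo <= x <= hi:
            return float(x)


def _draw_subjects(n_ssd: int, n_hc: int, rng: np.random.Generator) -> list[SubjectRecord]:
    """Covariates shaped like the study: SSD 47 +/- 14 y, HC 28 +/- 9.3 y,
    57% male in both groups, CPZe 548 +/- 320 mg (SSD only, truncated >= 0)."""
    subjects = []
    for i in range(n_ssd + n_hc):
        is_ssd = i < n_ssd
        group = "SSD" if is_ssd else "HC"
        mu, sd = (47.0, 14.0) if is_ssd else (28.0, 9.3)
        age = _truncated_normal(mu, sd, 18.0, 90.0, rng)
        sex = "M" if rng.random() < 0.57 else "F"
        cpze = _truncated_normal(548.0, 320.0, 0.0, np.inf, rng) if is_ssd else None
        subjects.append(SubjectRecord(f"sub-{i + 1:03d}", group, age, sex, cpze))
    return subjects


def make_cohort(
    n_ssd: int = 14,
    n_hc: int = 7,
    truth_template: PhantomTruth | None = None,
    effects: CohortEffectSpec | None = None,
    protocols: tuple[AcquisitionProtocol, ...] = (),
    roi_catalog: dict[int, tuple[str, str]] | None = None,
    simulate_b1: bool = True,
) -> CohortResult:
    """Generate a case-control cohort with planted regional T1 effects.

    With ``protocols`` empty the cohort is ROI-level only (fast path for
    statistical simulations): the covariate table and true ROI means are
    produced without any image synthesis, and ``roi_catalog`` may be given
    directly instead of a phantom template. With protocols, each subject
    gets a per-subject phantom (template geometry, regional T1 overridden
    by that subject's true means) plus simulated SPGR acquisitions and,
    if ``simulate_b1``, an FSE-DAM pair.
    """
    if n_ssd < 1 or n_hc < 1:
        raise ValueError("need >=1 subject per group")
    if truth_template is None and protocols:
        raise ValueError("image simulation requires a truth template")
    if truth_template is not None:
        roi_catalog = truth_template.roi_catalog
    if roi_catalog is None:
        raise ValueError("provide a truth template or an ROI catalog")
    if effects is None:
        effects = default_effects(roi_catalog)
    unknown = (set(effects.group_effect) | set(effects.sex_effect)) - set(roi_catalog)
    if unknown:
        raise ValueError(f"effect spec references unknown ROI ids: {sorted(unknown)}")

    rng = np.random.default_rng(effects.seed)
    subjects = _draw_subjects(n_ssd, n_hc, rng)
    covariates = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "group": [s.group for s in subjects],
            "age": [s.age for s in subjects],
            "sex": [s.sex for s in subjects],
            "cpze": [s.cpze if s.cpze is not None else np.nan for s in subjects],
        }
    )

    roi_ids = sorted(roi_catalog)
    if isinstance(effects.baseline_t1, dict):
        missing = set(roi_ids) - set(effects.baseline_t1)
        if missing:
            raise ValueError(f"baseline_t1 missing ROI ids: {sorted(missing)}")
        baseline = np.array([effects.baseline_t1[r] for r in roi_ids])
    else:
        baseline = np.full(len(roi_ids), float(effects.baseline_t1))

    rows = []
    true_means: dict[str, dict[int, float]] = {}
    for s in subjects:
        dev = effects.between_subject_sd * rng.standard_normal(len(roi_ids))
        vals = baseline.copy()
        for j, rid in enumerate(roi_ids):
            vals[j] += effects.group_effect.get(rid, 0.0) * (s.group == "SSD")
            vals[j] += effects.sex_effect.get(rid, 0.0) * (s.sex == "F")
            vals[j] += effects.age_slope * s.age
            vals[j] += effects.cpze_slope * (s.cpze or 0.0)
            vals[j] += dev[j]
        if np.any(vals <= 0):
            raise ValueError("planted effects produced non-positive T1")
        true_means[s.subject_id] = dict(zip(roi_ids, vals))
        for rid, v in zip(roi_ids, vals):
            name, hemi = roi_catalog[rid]
            rows.append((s.subject_id, rid, name, hemi, v))
    true_df = pd.DataFrame(
        rows, columns=["subject_id", "roi_id", "roi_name", "hemisphere", "true_t1"]
    )

    acquisitions: dict[str, dict[str, VolumeSet]] = {}
    dam: dict[str, VolumeSet] = {}
    truths: dict[str, PhantomTruth] = {}
    if protocols:
        assert truth_template is not None
        for s in subjects:
            t1_map = truth_template.t1_map.copy()
            for rid, v in true_means[s.subject_id].items():
                t1_map[truth_template.labels == rid] = v
            subj_truth = replace(truth_template, t1_map=t1_map)
            truths[s.subject_id] = subj_truth
            sub_seed = int(rng.integers(0, 2**31 - 1))
            acquisitions[s.subject_id] = {
                p.name: simulate_spgr(
                    subj_truth, p, noise_sigma=effects.noise_sigma, seed=sub_seed + k
                )
                for k, p in enumerate(protocols)
            }
            if simulate_b1:
                dam[s.subject_id] = simulate_dam(
                    subj_truth, noise_sigma=effects.noise_sigma, seed=sub_seed + 101
                )
    return CohortResult(
        subjects=subjects,
        covariates=covariates,
        true_roi_means=true_df,
        roi_catalog=roi_catalog,
        acquisitions=acquisitions,
        dam=dam,
        truths=truths,
    )
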