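"""Synthetic paired test/retest DCE-MRI cohort generator.

Emulates a small-animal study design: an orthotopic glioma of a few mm in a
rat brain slab, imaged twice 24 h apart, with an anti-angiogenic drug given
before the second session at 2, 4, 8, 12 or 24 h. Each virtual animal
carries ground-truth kinetic parameter maps organized in concentric tumor
zones — a well-perfused leaky periphery, a strongly leaky body with
measurable backflux, and a vessel-poor necrotic core — surrounded by normal
brain with intact barrier (intravascular-only kinetics).

The treatment effect is a per-animal shift of the order-3 tumor voxels'
(vp, Ktrans, ve), drawn from group-specific Gaussians. The default group
means and SDs are the published pooled test-retest difference summaries for
the early (2 & 4 h) and late (12 & 24 h) cohorts, with the 8 h group
centered on zero; these defaults ARE the study conditions every cohort-level
statistic is validated against.

Signals are generated with standard spoiled gradient-echo and Look-Locker
physics (static R2*, time-varying R1 = R1pre + r1 Ct) and Rician noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict, Field
from scipy.integrate import cumulative_trapezoid

from .acquisition import AcquisitionSpec
from .aif import BolusParams, PlasmaCurve, make_aif
from .pk_models import _windowed_aif, exp_conv
from .signalmodel import look_locker_series, spgr_signal

__all__ = [
    "ZoneParams",
    "ZoneTable",
    "ShiftSpec",
    "GroupDesign",
    "CohortDesign",
    "GroundTruthMap",
    "DynamicStudy",
    "AnimalStudyPair",
    "make_ground_truth",
    "apply_retest_shift",
    "synthesize_signals",
    "simulate_animal",
    "simulate_cohort",
    "rician",
    "noise_sd_for_snr",
]

ZONE_BACKGROUND, ZONE_CONTRALATERAL, ZONE_PERIPHERY, ZONE_BODY, ZONE_CORE = 0, 1, 2, 3, 4
ZONE_NAMES = {
    ZONE_BACKGROUND: "background",
    ZONE_CONTRALATERAL: "contralateral",
    ZONE_PERIPHERY: "periphery",
    ZONE_BODY: "body",
    ZONE_CORE: "core",
}


class ZoneParams(BaseModel):
    """Ground-truth kinetics and relaxation for one tissue zone."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    order: int = Field(ge=1, le=3)
    vp: float = Field(ge=0, le=0.2)
    ktrans_per_min: float = Field(ge=0)
    kep_per_min: float = Field(ge=0)
    t1_s: float = Field(gt=0)
    adc_mm2_s: float = Field(gt=0)

    @property
    def ve(self) -> float:
        return self.ktrans_per_min / self.kep_per_min if self.kep_per_min > 0 else 0.0


class ZoneTable(BaseModel):
    """Per-zone parameters; defaults are plausible 7 T rat glioma values.

    The leaky-zone baselines are placed at least three shift-SDs above the
    physical floor so the Gaussian test->retest shift law can be realized
    without truncation; the core is distinguished by its reduced plasma
    volume (necrotic center), not by vanishing leakage.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    contralateral: ZoneParams = ZoneParams(
        order=1, vp=0.015, ktrans_per_min=0.0, kep_per_min=0.0, t1_s=1.9, adc_mm2_s=0.70e-3
    )
    periphery: ZoneParams = ZoneParams(
        order=2, vp=0.035, ktrans_per_min=0.012, kep_per_min=0.0, t1_s=2.1, adc_mm2_s=1.00e-3
    )
    body: ZoneParams = ZoneParams(
        order=3, vp=0.025, ktrans_per_min=0.030, kep_per_min=0.30, t1_s=2.2, adc_mm2_s=0.90e-3
    )
    core: ZoneParams = ZoneParams(
        order=3, vp=0.010, ktrans_per_min=0.025, kep_per_min=0.25, t1_s=2.4, adc_mm2_s=1.20e-3
    )

    def __getitem__(self, zone: int) -> ZoneParams:
        return getattr(self, ZONE_NAMES[zone])


class ShiftSpec(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)
    mean: float
    sd: float = Field(ge=0)


class GroupDesign(BaseModel):
    """One treatment-time cohort: size and true test->retest shift laws."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    n: int = Field(ge=1)
    ktrans: ShiftSpec
    ve: ShiftSpec
    vp: ShiftSpec


def _default_groups() -> dict[int, GroupDesign]:
    # Early and late groups carry the published pooled difference summaries;
    # the 8 h group is centred on zero with an SD midway between them.
    early = dict(
        ktrans=ShiftSpec(mean=0.0050, sd=0.0050),
        ve=ShiftSpec(mean=0.0005, sd=0.0166),
        vp=ShiftSpec(mean=0.0016, sd=0.0052),
    )
    late = dict(
        ktrans=ShiftSpec(mean=-0.0039, sd=0.0064),
        ve=ShiftSpec(mean=-0.0164, sd=0.0251),
        vp=ShiftSpec(mean=-0.0006, sd=0.0030),
    )
    mid = dict(
        ktrans=ShiftSpec(mean=0.0, sd=0.0057),
        ve=ShiftSpec(mean=0.0, sd=0.0209),
        vp=ShiftSpec(mean=0.0, sd=0.0041),
    )
    return {
        2: GroupDesign(n=7, **early),
        4: GroupDesign(n=6, **early),
        8: GroupDesign(n=6, **mid),
        12: GroupDesign(n=6, **late),
        24: GroupDesign(n=6, **late),
    }


class CohortDesign(BaseModel):
    """Full virtual-study design: five treatment-time cohorts, N = 31 default."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    groups: dict[int, GroupDesign] = Field(default_factory=_default_groups)
    grid: tuple[int, int, int] = (32, 32, 3)
    tumor_center: tuple[float, float] = (20.0, 15.5)
    tumor_radius_vox: float = 4.0
    brain_radius_vox: float = 14.0
    snr: float = Field(30.0, ge=0)
    baseline_jitter: float = Field(0.05, ge=0, description="per-animal multiplicative SD on zone kinetics")
    seed: int | None = None

    @property
    def n_total(self) -> int:
        return sum(g.n for g in self.groups.values())


@dataclass
class GroundTruthMap:
    """Voxelwise ground truth on the acquisition grid (flattened arrays)."""

    shape: tuple[int, int, int]
    zone: np.ndarray        # int codes, see ZONE_*
    order: np.ndarray       # 0..3
    vp: np.ndarray
    ktrans_per_min: np.ndarray
    kep_per_min: np.ndarray
    t1_s: np.ndarray
    r2star_per_s: np.ndarray
    m0: np.ndarray
    adc_mm2_s: np.ndarray

    @property
    def ve(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.kep_per_min > 0, self.ktrans_per_min / self.kep_per_min, 0.0)

    @property
    def n_vox(self) -> int:
        return int(np.prod(self.shape))

    def validate(self) -> None:
        if np.any(self.vp < 0) or np.any(self.vp > 0.2):
            raise ValueError("vp outside [0, 0.2]")
        if np.any(self.ktrans_per_min < 0):
            raise ValueError("negative Ktrans")
        m3 = self.order == 3
        if np.any(self.kep_per_min[m3] <= 0):
            raise ValueError("order-3 voxels need kep > 0")
        if np.any(self.ktrans_per_min[self.order == 1] != 0):
            raise ValueError("order-1 voxels must have Ktrans = 0")
        if np.any((self.vp + self.ve) >= 1):
            raise ValueError("vp + ve must stay below 1")


def make_truth_map(
    zones: ZoneTable | None = None,
    grid: tuple[int, int, int] = (32, 32, 3),
    tumor_center: tuple[float, float] = (20.0, 15.5),
    tumor_radius_vox: float = 4.0,
    brain_radius_vox: float = 14.0,
    m0: float = 1000.0,
    r2star_per_s: float = 40.0,
) -> GroundTruthMap:
    """Lay out zones on the grid and fill per-voxel ground truth.

    In-plane geometry: a circular brain slab, with the tumor a circle in the
    lateral half; core/body/periphery are concentric at 35% / 70% / 100% of
    the tumor radius. Identical across slices (slab phantom, not anatomy).
    """
    zones = zones or ZoneTable()
    nx, ny, nz = grid
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    c = ((nx - 1) / 2.0, (ny - 1) / 2.0)
    r_brain = np.hypot(x - c[0], y - c[1])
    r_tumor = np.hypot(x - tumor_center[0], y - tumor_center[1])
    zone2d = np.full((nx, ny), ZONE_BACKGROUND, dtype=int)
    zone2d[r_brain <= brain_radius_vox] = ZONE_CONTRALATERAL
    inside = r_tumor <= tumor_radius_vox
    zone2d[inside] = ZONE_PERIPHERY
    zone2d[r_tumor <= 0.70 * tumor_radius_vox] = ZONE_BODY
    zone2d[r_tumor <= 0.35 * tumor_radius_vox] = ZONE_CORE
    zone = np.repeat(zone2d[:, :, None], nz, axis=2).ravel()

    n = zone.size
    out = GroundTruthMap(
        shape=grid,
        zone=zone,
        order=np.zeros(n, dtype=int),
        vp=np.zeros(n),
        ktrans_per_min=np.zeros(n),
        kep_per_min=np.zeros(n),
        t1_s=np.full(n, 1.9),
        r2star_per_s=np.where(zone > 0, r2star_per_s, 0.0),
        m0=np.where(zone > 0, m0, 0.0),
        adc_mm2_s=np.zeros(n),
    )
    for code in (ZONE_CONTRALATERAL, ZONE_PERIPHERY, ZONE_BODY, ZONE_CORE):
        zp = zones[code]
        sel = zone == code
        out.order[sel] = zp.order
        out.vp[sel] = zp.vp
        out.ktrans_per_min[sel] = zp.ktrans_per_min
        out.kep_per_min[sel] = zp.kep_per_min
        out.t1_s[sel] = zp.t1_s
        out.adc_mm2_s[sel] = zp.adc_mm2_s
    out.validate()
    return out


_VP_LIM = (1e-4, 0.2)
_VE_MIN = 5e-3
_KT_MIN = 1e-4


def apply_retest_shift(
    truth: GroundTruthMap,
    shift: dict[str, float],
) -> GroundTruthMap:
    """Return the retest ground truth: order-3 voxels shifted in (vp, Ktrans, ve).

    The shift acts on ve (with kep recomputed as Ktrans/ve), because ve is
    the reported volume fraction whose group differences the design
    specifies. Shifts that would leave the physical domain are clipped with
    a warning.
    """
    m3 = truth.order == 3
    vp = truth.vp.copy()
    kt = truth.ktrans_per_min.copy()
    ve = truth.ve.copy()
    vp_new = vp[m3] + shift.get("vp", 0.0)
    kt_new = kt[m3] + shift.get("ktrans", 0.0)
    ve_new = ve[m3] + shift.get("ve", 0.0)
    ve_cap = 0.98 - np.clip(vp_new, *_VP_LIM)
    clipped = (
        np.any(vp_new < _VP_LIM[0]) or np.any(vp_new > _VP_LIM[1])
        or np.any(kt_new < _KT_MIN) or np.any(ve_new < _VE_MIN)
        or np.any(ve_new > ve_cap)
    )
    if clipped:
        warnings.warn("retest shift clipped to keep parameters physical", RuntimeWarning, stacklevel=2)
    vp[m3] = np.clip(vp_new, *_VP_LIM)
    kt[m3] = np.maximum(kt_new, _KT_MIN)
    ve_m3 = np.clip(ve_new, _VE_MIN, ve_cap)
    kep = truth.kep_per_min.copy()
    kep[m3] = kt[m3] / ve_m3
    out = GroundTruthMap(
        shape=truth.shape, zone=truth.zone, order=truth.order,
        vp=vp, ktrans_per_min=kt, kep_per_min=kep,
        t1_s=truth.t1_s, r2star_per_s=truth.r2star_per_s,
        m0=truth.m0, adc_mm2_s=truth.adc_mm2_s,
    )
    out.validate()
    return out


def _jittered_zones(zones: ZoneTable, rng: np.random.Generator, jitter: float) -> ZoneTable:
    """Per-animal biological variability: multiplicative noise on zone kinetics."""
    if jitter == 0:
        return zones
    fields = {}
    for name in ("contralateral", "periphery", "body", "core"):
        zp: ZoneParams = getattr(zones, name)
        fac = np.clip(1.0 + jitter * rng.standard_normal(3), 0.5, 1.5)
        fields[name] = zp.model_copy(
            update=dict(
                vp=float(np.clip(zp.vp * fac[0], 0.0, 0.2)),
                ktrans_per_min=zp.ktrans_per_min * fac[1],
                # scale ve via kep so the ve = Ktrans/kep identity is kept
                kep_per_min=zp.kep_per_min * fac[1] / fac[2] if zp.kep_per_min > 0 else 0.0,
            )
        )
    return ZoneTable(**fields)


def make_ground_truth(
    design: CohortDesign,
    zones: ZoneTable | None = None,
    rng: np.random.Generator | None = None,
):
    """Draw ground truth for every animal and session of the cohort.

    Yields ``(animal_id, group_h, truth_test, truth_retest, true_shift)``
    where ``true_shift`` is the realized per-animal (vp, Ktrans, ve) shift.
    With zero SDs and zero means the retest map equals the test map.
    """
    zones = zones or ZoneTable()
    rng = rng or np.random.default_rng(design.seed)
    animal_id = 0
    out = []
    for group_h in sorted(design.groups):
        g = design.groups[group_h]
        for _ in range(g.n):
            animal_id += 1
            z = _jittered_zones(zones, rng, design.baseline_jitter)
            test = make_truth_map(
                z, grid=design.grid, tumor_center=design.tumor_center,
                tumor_radius_vox=design.tumor_radius_vox,
                brain_radius_vox=design.brain_radius_vox,
            )
            shift = {
                "ktrans": g.ktrans.mean + g.ktrans.sd * rng.standard_normal(),
                "ve": g.ve.mean + g.ve.sd * rng.standard_normal(),
                "vp": g.vp.mean + g.vp.sd * rng.standard_normal(),
            }
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                retest = apply_retest_shift(test, shift)
            out.append((f"rat{animal_id:02d}", group_h, test, retest, shift))
    return out


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

def rician(signal: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Rician-distributed magnitude: |signal + complex Gaussian noise|."""
    if sd < 0:
        raise ValueError("noise sd must be nonnegative")
    if sd == 0:
        return np.asarray(signal, dtype=float).copy()
    re = signal + rng.normal(0.0, sd, size=np.shape(signal))
    im = rng.normal(0.0, sd, size=np.shape(signal))
    return np.hypot(re, im)


@dataclass
class DynamicStudy:
    """All raw series of one imaging session (flattened voxel axis)."""

    spec: AcquisitionSpec
    aif: PlasmaCurve
    shape: tuple[int, int, int]
    echo1: np.ndarray     # (n_vox, n_frames)
    echo2: np.ndarray
    ll_pre: np.ndarray    # (n_vox, n_ti)
    ll_post: np.ndarray
    dwi_b0: np.ndarray    # (n_vox,)
    dwi_b1: np.ndarray
    noise_sd: float


def true_concentration(truth: GroundTruthMap, aif: PlasmaCurve) -> np.ndarray:
    """Noise-free Ct(t) for every voxel, vectorized across the grid."""
    t_sub, cp, i0 = _windowed_aif(aif)
    icp = cumulative_trapezoid(cp, t_sub, initial=0.0)
    n_vox, n = truth.vp.size, len(aif)
    ct = np.zeros((n_vox, n))
    sub = ct[:, i0:]
    sub += truth.vp[:, None] * cp[None, :]
    o2 = truth.order == 2
    sub[o2] += truth.ktrans_per_min[o2, None] * icp[None, :]
    o3 = truth.order == 3
    if np.any(o3):
        conv = exp_conv(cp, t_sub, truth.kep_per_min[o3])
        sub[o3] += truth.ktrans_per_min[o3, None] * conv
    ct[:, i0:] = sub
    return ct


def noise_sd_for_snr(truth: GroundTruthMap, spec: AcquisitionSpec, snr: float) -> float:
    """Noise SD giving the requested baseline SNR in brain voxels (echo 1)."""
    if snr == 0:
        return 0.0
    brain = truth.zone > 0
    s = spgr_signal(truth.m0[brain], 1.0 / truth.t1_s[brain], spec.flip_angle_rad, spec.tr_s)
    s = s * np.exp(-spec.te1_s * truth.r2star_per_s[brain])
    return float(s.mean() / snr)


def synthesize_signals(
    truth: GroundTruthMap,
    aif: PlasmaCurve,
    spec: AcquisitionSpec,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> DynamicStudy:
    """Forward-generate every series of one session from ground truth.

    Dynamic dual-echo: time-varying R1(t) = R1pre + r1 Ct(t), static R2*,
    steady-state spoiled gradient-echo weighting, echo decay exp(-TE R2*).
    Look-Locker trains are generated pre-contrast (R1pre) and post-contrast
    (R1 at the final frame). Rician noise of the given SD corrupts every
    magnitude sample; sd = 0 returns the noiseless signals.
    """
    if noise_sd < 0:
        raise ValueError("noise sd must be nonnegative")
    rng = rng or np.random.default_rng()
    ct = true_concentration(truth, aif)
    r1_pre = np.where(truth.t1_s > 0, 1.0 / truth.t1_s, 0.0)
    r1_t = r1_pre[:, None] + spec.r1_relaxivity * ct
    s_te0 = spgr_signal(truth.m0[:, None], r1_t, spec.flip_angle_rad, spec.tr_s)
    att1 = np.exp(-spec.te1_s * truth.r2star_per_s)[:, None]
    att2 = np.exp(-spec.te2_s * truth.r2star_per_s)[:, None]
    echo1 = s_te0 * att1
    echo2 = s_te0 * att2

    ti = spec.inversion_times_s
    tau = spec.ll_tr_s / spec.ll_n_echoes
    ll_flip = float(np.deg2rad(spec.ll_flip_angle_deg))
    brain = truth.zone > 0
    ll_pre = np.zeros((truth.n_vox, ti.size))
    ll_post = np.zeros_like(ll_pre)
    t1_post = np.where(brain, 1.0 / np.maximum(r1_t[:, -1], 1e-9), 0.0)
    ll_pre[brain] = look_locker_series(truth.m0[brain], truth.t1_s[brain], ti, ll_flip, tau)
    ll_post[brain] = look_locker_series(truth.m0[brain], t1_post[brain], ti, ll_flip, tau)

    b0, b1 = spec.b_values_s_mm2
    dwi_b0 = truth.m0 * np.exp(-b0 * truth.adc_mm2_s)
    dwi_b1 = truth.m0 * np.exp(-b1 * truth.adc_mm2_s)

    return DynamicStudy(
        spec=spec, aif=aif, shape=truth.shape,
        echo1=rician(echo1, noise_sd, rng),
        echo2=rician(echo2, noise_sd, rng),
        ll_pre=rician(ll_pre, noise_sd, rng),
        ll_post=rician(ll_post, noise_sd, rng),
        dwi_b0=rician(dwi_b0, noise_sd, rng),
        dwi_b1=rician(dwi_b1, noise_sd, rng),
        noise_sd=noise_sd,
    )


@dataclass
class AnimalStudyPair:
    """Both sessions of one animal plus the generating truth."""

    animal_id: str
    group_h: int
    truth_test: GroundTruthMap
    truth_retest: GroundTruthMap
    true_shift: dict[str, float]
    study_test: DynamicStudy
    study_retest: DynamicStudy


def simulate_animal(
    animal_id: str,
    group_h: int,
    truth_test: GroundTruthMap,
    truth_retest: GroundTruthMap,
    true_shift: dict[str, float],
    spec: AcquisitionSpec,
    aif: PlasmaCurve,
    snr: float,
    rng: np.random.Generator,
) -> AnimalStudyPair:
    sd = noise_sd_for_snr(truth_test, spec, snr)
    return AnimalStudyPair(
        animal_id=animal_id,
        group_h=group_h,
        truth_test=truth_test,
        truth_retest=truth_retest,
        true_shift=true_shift,
        study_test=synthesize_signals(truth_test, aif, spec, sd, rng),
        study_retest=synthesize_signals(truth_retest, aif, spec, sd, rng),
    )


def simulate_cohort(
    design: CohortDesign,
    spec: AcquisitionSpec | None = None,
    zones: ZoneTable | None = None,
    bolus: BolusParams | None = None,
    seed: int | None = None,
) -> list[AnimalStudyPair]:
    """Generate the full virtual cohort: paired noisy studies per animal.

    ``seed`` overrides ``design.seed``; identical seed and design give
    bit-identical output.
    """
    spec = spec or AcquisitionSpec()
    aif = make_aif(spec, bolus)
    seed = design.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    truth_rng = np.random.default_rng(ss.spawn(1)[0])
    entries = make_ground_truth(design, zones, truth_rng)
    animal_seeds = ss.spawn(len(entries))
    return [
        simulate_animal(aid, gh, t_test, t_retest, shift, spec, aif, design.snr,
                        np.random.default_rng(s))
        for (aid, gh, t_test, t_retest, shift), s in zip(entries, animal_seeds)
    ]
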