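"""Digital knee-phantom and synthetic-cohort generation.

Real dynamic contrast-enhanced knee studies cannot be redistributed, so
every downstream stage is exercised on digital phantoms: small 3D grids
carrying seven synovial regions of interest (suprapatellar, Hoffa fat
pad, medial/lateral perimeniscal, intercondylar notch, posterior
medial/lateral femoral condyles) plus background, a central "bone" and a
"fluid" pocket.  Each synovial region has its own tissue parameters
(Ktrans, ve, vp, native T1, equilibrium magnetisation) and a configurable
fraction of enhancing voxels; non-enhancing voxels have Ktrans = vp = 0.

Acquisitions are forward-simulated with the SPGR signal model: a
variable-flip-angle stack for T1 mapping, a 35-phase dynamic series whose
tissue concentrations follow the extended Tofts model driven by the
haematocrit-corrected population AIF, and pre/post-contrast 3D images
taken as the last pre-bolus and the final dynamic frame.

A cohort generator emulates the two-group study design (OA and healthy
volunteers; baseline, 1-month test-retest and 6-month follow-up visits)
with subject levels drawn as group mean + N(0, sigma_b) and visit levels
adding N(0, sigma_w); subject images are calibrated so the whole-joint
median Ktrans of enhancing voxels equals the subject-visit true level.

The geometry is deliberately schematic: regions are ellipsoids on a ring.
Nothing anatomical is claimed — the phantom exists to carry known ground
truth through the full pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .aif import AIFParameters, haematocrit_correct, population_aif_blood
from .pk import TissueParams, extended_tofts_forward
from .relaxometry import DEFAULT_RELAXIVITY, concentration_to_signal, spgr_signal
from .segmentation import REGION_NAMES

__all__ = [
    "AcquisitionSpec", "RegionSpec", "PhantomSpec", "CohortSpec",
    "PhantomVolumes", "SubjectStudy",
    "generate_phantom", "generate_subject_images", "generate_cohort",
    "BONE_LABEL", "FLUID_LABEL",
]

BONE_LABEL = 8
FLUID_LABEL = 9


@dataclass(frozen=True)
class AcquisitionSpec:
    """Forward-simulated acquisition protocol.

    Times in seconds.  Defaults mirror a 3 T knee DCE protocol: 3D SPGR,
    TR 4 ms, VFA flip angles 2/6/14 deg, dynamic flip angle 14 deg,
    35 dynamic phases.  The frame interval is not part of the protocol
    table and defaults to 10 s (a typical 3D SPGR knee DCE resolution,
    ~5.8 min total).  The bolus arrives after ``baseline_frames`` frames
    so a pre-contrast baseline exists for concentration conversion.
    """

    repetition_time: float = 0.004
    flip_angles_vfa: tuple = (2.0, 6.0, 14.0)
    dynamic_flip_angle: float = 14.0
    n_phases: int = 35
    phase_interval: float = 10.0
    baseline_frames: int = 5
    voxel_size: tuple = (2.5, 2.5, 2.0)
    grid_shape: tuple = (64, 64, 16)
    noise_sd: float = 0.5
    noise_model: str = "gaussian"
    relaxivity: float = DEFAULT_RELAXIVITY

    def __post_init__(self) -> None:
        if self.repetition_time <= 0:
            raise ValueError("repetition_time must be > 0")
        for a in (*self.flip_angles_vfa, self.dynamic_flip_angle):
            if not 0 < a <= 90:
                raise ValueError(f"flip angle {a} outside (0, 90]")
        if self.n_phases < 2:
            raise ValueError("n_phases must be >= 2")
        if self.phase_interval <= 0:
            raise ValueError("phase_interval must be > 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")
        if not 1 <= self.baseline_frames < self.n_phases:
            raise ValueError("baseline_frames must be in [1, n_phases)")

    @property
    def frame_times_min(self) -> np.ndarray:
        """Mid-frame-free minute grid: frame k acquired at k*interval."""
        return np.arange(self.n_phases) * self.phase_interval / 60.0

    @property
    def bolus_arrival_min(self) -> float:
        return self.baseline_frames * self.phase_interval / 60.0


@dataclass(frozen=True)
class RegionSpec:
    """Tissue parameters of one labelled region (ktrans min⁻¹, t10 s)."""

    label: int
    name: str
    ktrans: float
    ve: float
    vp: float
    t10: float
    m0: float

    def __post_init__(self) -> None:
        if self.ktrans < 0 or not 0 <= self.vp <= 1 or self.t10 <= 0:
            raise ValueError(f"invalid tissue parameters for region {self.name}")
        if self.ktrans > 0 and self.ve <= 0:
            raise ValueError(f"ve must be > 0 in enhancing region {self.name}")


def _default_regions() -> tuple:
    # Region-to-region Ktrans spread around the OA whole-joint mean keeps
    # the whole-joint median well defined while giving per-region contrast.
    kt = {1: 0.050, 2: 0.030, 3: 0.045, 4: 0.040, 5: 0.055, 6: 0.035, 7: 0.039}
    return tuple(
        RegionSpec(label=lab, name=REGION_NAMES[lab], ktrans=kt[lab],
                   ve=0.30, vp=0.02, t10=1.2, m0=1000.0)
        for lab in sorted(REGION_NAMES)
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Digital phantom layout and tissue parameters.

    ``region_radius_frac`` scales the synovial ellipsoids relative to the
    grid; ``enhancing_fraction`` is the fraction of synovial voxels that
    actually enhance (the rest model fibrotic, non-perfused pannus).
    """

    grid_shape: tuple = (64, 64, 16)
    voxel_size: tuple = (2.5, 2.5, 2.0)
    regions: tuple = field(default_factory=_default_regions)
    enhancing_fraction: float = 0.7
    region_radius_frac: float = 0.09
    background_t10: float = 0.5
    background_m0: float = 100.0
    bone_t10: float = 0.3
    bone_m0: float = 300.0
    fluid_t10: float = 3.0
    fluid_m0: float = 1200.0

    def __post_init__(self) -> None:
        if any(s < 16 for s in self.grid_shape[:2]) or self.grid_shape[2] < 4:
            raise ValueError("grid_shape must be at least 16x16x4")
        if not 0 <= self.enhancing_fraction <= 1:
            raise ValueError("enhancing_fraction must be in [0, 1]")
        if len(self.regions) < 1:
            raise ValueError("at least one synovial region required")


@dataclass
class PhantomVolumes:
    """Labelled ground-truth parameter volumes."""

    labels: np.ndarray
    ktrans: np.ndarray
    ve: np.ndarray
    vp: np.ndarray
    t10: np.ndarray
    m0: np.ndarray
    enhancing: np.ndarray
    voxel_size: tuple

    def synovial_mask(self) -> np.ndarray:
        return (self.labels >= 1) & (self.labels <= 7)


@dataclass
class SubjectStudy:
    """All simulated images for one subject-visit plus ground truth."""

    subject_id: str
    visit: str
    acq: AcquisitionSpec
    vfa: np.ndarray          # (n_angles,) + grid
    dynamic: np.ndarray      # grid + (n_phases,)
    pre: np.ndarray          # last pre-bolus frame
    post: np.ndarray         # late frame
    roi_labels: np.ndarray
    haematocrit: float
    ground_truth: dict       # parameter volumes + per-subject medians


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return acc <= 1.0


def generate_phantom(spec: PhantomSpec, seed: int) -> PhantomVolumes:
    """Build labelled parameter volumes for one phantom.

    Synovial regions are ellipsoids on a ring around a central bone
    ellipsoid, with a fluid pocket above it.  A seeded random subset
    (``enhancing_fraction``) of each region's voxels enhances; the rest
    get ktrans = 0 and vp = 0.  Overlapping region definitions raise an
    error naming the offending labels.
    """
    nx, ny, nz = spec.grid_shape
    labels = np.zeros(spec.grid_shape, dtype=np.int16)

    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    bone = _ellipsoid_mask(spec.grid_shape, (cx, cy, cz),
                           (0.12 * nx, 0.12 * ny, 0.45 * nz))
    labels[bone] = BONE_LABEL
    # fluid pocket between bone and the synovial ring, offset off-axis
    f_r = 0.21 * min(nx, ny)
    f_ang = np.pi / len(spec.regions)
    fluid = _ellipsoid_mask(
        spec.grid_shape,
        (cx + f_r * np.cos(f_ang), cy + f_r * np.sin(f_ang), cz),
        (0.06 * nx, 0.06 * ny, 0.30 * nz))
    if (labels[fluid] != 0).any():
        raise ValueError("overlapping region definitions: fluid overlaps bone")
    labels[fluid] = FLUID_LABEL

    n_reg = len(spec.regions)
    ring = 0.33 * min(nx, ny)
    r_xy = spec.region_radius_frac * min(nx, ny)
    r_z = 0.28 * nz
    for i, reg in enumerate(spec.regions):
        ang = 2.0 * np.pi * i / n_reg
        center = (cx + ring * np.cos(ang), cy + ring * np.sin(ang), cz)
        m = _ellipsoid_mask(spec.grid_shape, center, (r_xy, r_xy, r_z))
        clash = np.unique(labels[m])
        clash = clash[clash != 0]
        if clash.size:
            raise ValueError(
                f"overlapping region definitions: label {reg.label} "
                f"({reg.name}) overlaps labels {clash.tolist()}")
        labels[m] = reg.label

    ktrans = np.zeros(spec.grid_shape)
    ve = np.full(spec.grid_shape, 0.3)
    vp = np.zeros(spec.grid_shape)
    t10 = np.full(spec.grid_shape, spec.background_t10)
    m0 = np.full(spec.grid_shape, spec.background_m0)
    t10[labels == BONE_LABEL] = spec.bone_t10
    m0[labels == BONE_LABEL] = spec.bone_m0
    t10[labels == FLUID_LABEL] = spec.fluid_t10
    m0[labels == FLUID_LABEL] = spec.fluid_m0

    rng = np.random.default_rng(seed)
    enhancing = np.zeros(spec.grid_shape, dtype=bool)
    for reg in spec.regions:
        m = labels == reg.label
        t10[m], m0[m], ve[m] = reg.t10, reg.m0, reg.ve
        idx = np.flatnonzero(m.ravel())
        n_enh = int(round(spec.enhancing_fraction * idx.size))
        chosen = rng.choice(idx, size=n_enh, replace=False) if n_enh else []
        flat_enh = np.zeros(labels.size, dtype=bool)
        flat_enh[chosen] = True
        region_enh = flat_enh.reshape(spec.grid_shape)
        enhancing |= region_enh
        ktrans[region_enh] = reg.ktrans
        vp[region_enh] = reg.vp

    return PhantomVolumes(labels=labels, ktrans=ktrans, ve=ve, vp=vp,
                          t10=t10, m0=m0, enhancing=enhancing,
                          voxel_size=spec.voxel_size)


def _tissue_concentration_volume(phantom: PhantomVolumes, cp_fine: np.ndarray,
                                 t_fine: np.ndarray, obs_idx: np.ndarray,
                                 ktrans_scale: float = 1.0) -> np.ndarray:
    """Ct over time for every voxel, exploiting region-constant parameters."""
    nt = obs_idx.size
    shape = phantom.labels.shape
    ct = np.zeros(shape + (nt,), dtype=np.float32)
    params = np.stack([phantom.ktrans.ravel() * ktrans_scale,
                       phantom.ve.ravel(), phantom.vp.ravel()], axis=1)
    uniq, inv = np.unique(params, axis=0, return_inverse=True)
    flat = ct.reshape(-1, nt)
    for k, (kt, ve, vp) in enumerate(uniq):
        if kt == 0 and vp == 0:
            continue
        p = TissueParams(ktrans=float(kt), ve=float(max(ve, 1e-6)), vp=float(vp))
        curve = extended_tofts_forward(p, cp_fine, t_fine)[obs_idx]
        flat[inv == k] = curve.astype(np.float32)
    return ct


def _add_noise(img: np.ndarray, sd: float, model: str,
               rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return img
    if model == "gaussian":
        return img + rng.normal(0.0, sd, size=img.shape)
    # magnitude MRI: Rician = |signal + complex Gaussian noise|
    re = img + rng.normal(0.0, sd, size=img.shape)
    im = rng.normal(0.0, sd, size=img.shape)
    return np.hypot(re, im)


def supersampled_time_grid(acq: AcquisitionSpec, factor: int = 10):
    """Fine minute grid subdividing each frame interval, plus frame indices."""
    n_fine = (acq.n_phases - 1) * factor + 1
    t_fine = np.linspace(0.0, acq.frame_times_min[-1], n_fine)
    obs_idx = np.arange(acq.n_phases) * factor
    return t_fine, obs_idx


def generate_subject_images(phantom: PhantomVolumes, acq: AcquisitionSpec,
                            aif_params: AIFParameters | None,
                            haematocrit: float, seed: int,
                            subject_id: str = "sub-01", visit: str = "baseline",
                            ktrans_scale: float = 1.0,
                            supersample: int = 10) -> SubjectStudy:
    """Forward-simulate the full acquisition set for one subject-visit.

    The dynamic series follows SPGR signals of extended-Tofts tissue
    concentrations driven by the haematocrit-corrected population AIF
    (bolus arriving after the configured baseline frames); the VFA stack
    follows the SPGR equation at each flip angle; pre/post 3D images are
    the last pre-bolus and the final dynamic frame.  Noise is added per
    the acquisition's noise model.
    """
    if not 0 < haematocrit < 1:
        raise ValueError(f"haematocrit must be in (0, 1), got {haematocrit}")
    if phantom.labels.shape != tuple(acq.grid_shape):
        raise ValueError("phantom and acquisition grids differ")
    if aif_params is None:
        aif_params = AIFParameters(bolus_arrival_offset=acq.bolus_arrival_min)

    rng = np.random.default_rng(seed)
    t_fine, obs_idx = supersampled_time_grid(acq, supersample)
    cp_fine = haematocrit_correct(population_aif_blood(t_fine, aif_params),
                                  haematocrit)

    ct = _tissue_concentration_volume(phantom, cp_fine, t_fine, obs_idx,
                                      ktrans_scale)
    dyn_clean = concentration_to_signal(
        ct, t10=phantom.t10[..., None], m0=phantom.m0[..., None],
        tr=acq.repetition_time, flip_angle=acq.dynamic_flip_angle,
        r1=acq.relaxivity).astype(np.float32)
    dynamic = _add_noise(dyn_clean, acq.noise_sd, acq.noise_model,
                         rng).astype(np.float32)

    vfa = np.stack([
        _add_noise(
            spgr_signal(m0=phantom.m0, t1=phantom.t10, flip_angle=fa,
                        tr=acq.repetition_time),
            acq.noise_sd, acq.noise_model, rng).astype(np.float32)
        for fa in acq.flip_angles_vfa
    ])

    pre = dynamic[..., acq.baseline_frames - 1]
    post = dynamic[..., -1]

    ktrans_true = phantom.ktrans * ktrans_scale
    syn_enh = phantom.enhancing & phantom.synovial_mask()
    gt = {
        "ktrans": ktrans_true, "ve": phantom.ve, "vp": phantom.vp,
        "t10": phantom.t10, "m0": phantom.m0, "enhancing": phantom.enhancing,
        "concentration": ct,
        "median_ktrans_enhancing": float(np.median(ktrans_true[syn_enh]))
        if syn_enh.any() else 0.0,
    }
    return SubjectStudy(subject_id=subject_id, visit=visit, acq=acq,
                        vfa=vfa, dynamic=dynamic, pre=pre, post=post,
                        roi_labels=phantom.labels, haematocrit=haematocrit,
                        ground_truth=gt)


@dataclass(frozen=True)
class CohortSpec:
    """Two-group, three-visit cohort design.

    Subject true biomarker levels are group_mean + N(0, between_subject_sd);
    baseline and month1 levels add N(0, within_subject_sd) (the test-retest
    structure).  Month-6 levels add a further within-subject draw unless
    ``six_month_changes`` assigns a subject a deterministic true change
    (used to construct responsiveness scenarios), in which case
    month6 = realised baseline level + assigned change, noise-free —
    a subject assigned 0 has exactly no true 6-month change.

    Defaults follow the study conditions: 14 OA / 6 HV; OA whole-joint
    mean Ktrans 0.039 min⁻¹ with between/within variances 2.1e-4 and
    2.4e-5; HV mean 0.025 min⁻¹ (true standardised mean difference ≈ 0.94
    at the between-subject SD); haematocrit 0.42 ± 0.03.
    """

    n_oa: int = 14
    n_hv: int = 6
    visits: tuple = ("baseline", "month1", "month6")
    mean_oa: float = 0.039
    mean_hv: float = 0.025
    between_subject_sd: float = float(np.sqrt(2.1e-4))
    within_subject_sd: float = float(np.sqrt(2.4e-5))
    haematocrit_mean: float = 0.42
    haematocrit_sd: float = 0.03
    seed: int = 0
    six_month_changes: tuple | None = None   # ((subject_id, delta), ...)
    level_floor: float = 1e-3                # keeps Ktrans physical

    def __post_init__(self) -> None:
        if self.n_oa < 0 or self.n_hv < 0:
            raise ValueError("group sizes must be >= 0")
        if self.n_oa + self.n_hv == 0:
            raise ValueError("cohort must contain at least one subject")
        if self.between_subject_sd < 0 or self.within_subject_sd < 0:
            raise ValueError("SDs must be >= 0")


def generate_cohort(cohort: CohortSpec, phantom_spec: PhantomSpec | None = None,
                    acq: AcquisitionSpec | None = None,
                    images: bool = False, writer=None):
    """Draw a synthetic cohort; optionally simulate all images.

    Returns ``(metadata, studies)``: a metadata table with one row per
    subject-visit (subject_id, group, visit, haematocrit, true biomarker
    level, seed) and — when ``images=True`` — a dict mapping
    ``(subject_id, visit)`` to :class:`SubjectStudy` whose whole-joint
    median enhancing-voxel Ktrans is calibrated to the true level
    (exactly, well within the 2% contract).  With ``images=False`` the
    dict is empty (statistics-only simulations).  If ``writer`` is given
    each study is passed to it and not retained (streaming large cohorts
    to disk).
    """
    if phantom_spec is None:
        phantom_spec = PhantomSpec()
    if acq is None:
        acq = AcquisitionSpec(grid_shape=phantom_spec.grid_shape,
                              voxel_size=phantom_spec.voxel_size)

    changes = dict(cohort.six_month_changes or ())
    rng = np.random.default_rng(cohort.seed)
    img_seeds = np.random.SeedSequence(cohort.seed).spawn(
        (cohort.n_oa + cohort.n_hv) * len(cohort.visits) + 1)
    phantom = generate_phantom(phantom_spec,
                               seed=int(img_seeds[-1].generate_state(1)[0] % 2**31))
    base_median = phantom.ktrans[phantom.enhancing & phantom.synovial_mask()]
    base_median = float(np.median(base_median)) if base_median.size else 0.0

    rows, studies = [], {}
    subjects = ([("OA", i) for i in range(cohort.n_oa)]
                + [("HV", i) for i in range(cohort.n_hv)])
    k = 0
    for group, i in subjects:
        sid = f"{group.lower()}{i + 1:02d}"
        mean = cohort.mean_oa if group == "OA" else cohort.mean_hv
        level = max(cohort.level_floor,
                    mean + rng.normal(0.0, cohort.between_subject_sd))
        hct = float(np.clip(rng.normal(cohort.haematocrit_mean,
                                       cohort.haematocrit_sd), 0.2, 0.6))
        baseline_true = None
        for visit in cohort.visits:
            if visit == "month6" and sid in changes:
                # deterministic assigned change relative to the realised
                # baseline level (responsiveness constructions)
                ref = baseline_true if baseline_true is not None else level
                true = max(cohort.level_floor, ref + changes[sid])
            else:
                true = max(cohort.level_floor,
                           level + rng.normal(0.0, cohort.within_subject_sd))
            if visit == "baseline":
                baseline_true = true
            seed_k = int(img_seeds[k].generate_state(1)[0] % 2**31)
            rows.append({"subject_id": sid, "group": group, "visit": visit,
                         "haematocrit": hct, "true_ktrans": true,
                         "seed": seed_k})
            if images:
                scale = true / base_median if base_median > 0 else 0.0
                study = generate_subject_images(
                    phantom, acq, None, hct, seed_k, subject_id=sid,
                    visit=visit, ktrans_scale=scale)
                if writer is not None:
                    writer(study)
                else:
                    studies[(sid, visit)] = study
            k += 1
    return pd.DataFrame(rows), studies
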