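"""Digital mouse-thorax phantom for dual-tracer longitudinal fibrosis studies.

The phantom emulates the bleomycin (BLM) mouse model of pulmonary fibrosis
as seen by a small-animal PET/CT: a soft-tissue body containing two aerated
lung fields, in which dense fibrotic consolidations grow from the end of the
inflammatory phase (day 7) through the fibrotic phase (to day 23).  For each
animal and imaging session it emits

* a CT volume in Hounsfield units (aerated lung around -600 HU, lesions in
  the -100..300 HU consolidation band, PSF-blurred, with noise),
* FDG and FMISO PET volumes as decay-uncorrected activity concentration at
  acquisition start (kBq/mL),
* scan metadata (dose, injection/acquisition times, body weight), and
* a ground-truth record (lesion/halo masks, fibrosis burden, true per-class
  uptake) that stands in for the terminal readouts of a real study
  (collagen histomorphometry, ex vivo gamma counting).

Disease model
-------------
Lesions are a small number of blob-shaped consolidations seeded in the lung
interior and grown day by day.  Ground truth is defined on the noiseless
PSF-blurred CT: a voxel is lesional iff it lies in the lung and its blurred
HU reaches the -100 HU consolidation band; blob radii are solved so that the
resulting burden matches the disease trajectory.  Each animal carries an
aggressiveness multiplier that scales its *post-day-9* lesion growth: early
(day 9) anatomy is identical across animals while outcomes diverge, which is
what makes early hypoxia (and not early CT) informative about progression.

The hypoxic halo is the peri-lesional, still-aerated territory destined to
consolidate: the vehicle-destined end-of-study lesion extent plus a 2-voxel
shell, minus the current lesion.  FMISO is avid in lesion and halo from day
9; FDG is avid in the lesion only, from day 15.  Halo intensity is coupled
to the aggressiveness multiplier, so day-9 FMISO uptake carries the
progression signal.

Therapy (pirfenidone or nintedanib, daily from day 9) multiplies post-day-9
lesion-volume growth by an arm-specific factor in [0, 1] and additionally
suppresses the disease-related tracer excess from the first post-treatment
session onwards.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .grids import VolumeGrid
from .meta import GROUPS, ScanMeta, default_scan_meta

TREATED_GROUPS = ("BLM+pirfenidone", "BLM+nintedanib")
#: Nominal imaging sessions (days); FDG is acquired the day before each
#: non-baseline session, FMISO and CT on the nominal day itself.
NOMINAL_DAYS = (0, 9, 16, 23)
STUDY_WINDOW = (0, 23)


@dataclass(frozen=True)
class TracerParams:
    """True-uptake model of one tracer, in %ID/g.

    ``lesion_mult`` and ``halo_mult`` scale the normal-lung value inside the
    lesion and halo once the tracer's uptake onset day is reached.
    """

    background_pid: float   # soft tissue / paraspinal muscle
    lung_pid: float         # normal aerated lung
    lesion_mult: float
    halo_mult: float
    onset_day: float
    blood_pid: float

    def __post_init__(self):
        if self.onset_day < STUDY_WINDOW[0] or self.onset_day > STUDY_WINDOW[1]:
            raise ValueError(f"tracer onset day {self.onset_day} outside study window {STUDY_WINDOW}")


def _default_tracers() -> Dict[str, TracerParams]:
    # Defaults calibrated so that the full image chain reproduces the
    # study-level fold changes (disease 1.4x MLD / 2.6x FDG / 3.2x FMISO at
    # the established-fibrosis session; see docs/methods.md).
    return {
        "FDG": TracerParams(background_pid=1.0, lung_pid=1.0,
                            lesion_mult=7.9, halo_mult=1.0,
                            onset_day=15.0, blood_pid=0.6),
        "FMISO": TracerParams(background_pid=0.5, lung_pid=0.5,
                              lesion_mult=8.9, halo_mult=3.55,
                              onset_day=9.0, blood_pid=0.35),
    }


def _default_growth_milestones() -> Dict[int, float]:
    # Fraction of the end-of-study lesion volume reached at each day
    # (linear in between): rapid rise to day 16, stabilisation to day 23.
    return {9: 0.25, 16: 0.9, 23: 1.0}


def _default_therapy_growth() -> Dict[str, float]:
    return {"BLM+pirfenidone": 0.172, "BLM+nintedanib": 0.172}


def _default_therapy_uptake() -> Dict[str, Dict[str, float]]:
    # Multiplier applied to the lesion/halo uptake multipliers from the
    # first post-treatment session; calibrated against the vehicle/treated
    # fold decreases (pirfenidone 1.2/2.9/2.6, nintedanib 1.2/2.3/2.5).
    return {
        "BLM+pirfenidone": {"FDG": 0.015, "FMISO": 0.22},
        "BLM+nintedanib": {"FDG": 0.33, "FMISO": 0.23},
    }


@dataclass
class PhantomSpec:
    """All tunable parameters of the synthetic study.

    Geometry is expressed in fractions of the grid so that the phantom
    scales with ``shape``; defaults give a 24 mm field of view at 0.25 mm
    isotropic voxels containing a mouse-sized thorax.
    """

    shape: Tuple[int, int, int] = (96, 96, 96)
    spacing_mm: Tuple[float, float, float] = (0.25, 0.25, 0.25)

    # Tissue HU (mean, SD of pre-blur voxel texture)
    body_hu: Tuple[float, float] = (40.0, 30.0)
    lung_hu: Tuple[float, float] = (-600.0, 50.0)
    lesion_hu: Tuple[float, float] = (-30.0, 60.0)

    # Disease trajectory
    onset_day: float = 7.0
    growth_milestones: Dict[int, float] = field(default_factory=_default_growth_milestones)
    burden_d23: float = 0.241         # mean end-of-study lesion fraction of lung (vehicle)
    burden_cap: float = 0.45
    aggressiveness_sigma: float = 0.25
    aggressiveness_bounds: Tuple[float, float] = (0.4, 1.8)

    # Therapy (daily dosing during the fibrotic phase, day 9 to 23)
    therapy_start_day: float = 9.0
    therapy_growth_multiplier: Dict[str, float] = field(default_factory=_default_therapy_growth)
    therapy_uptake_multiplier: Dict[str, Dict[str, float]] = field(default_factory=_default_therapy_uptake)

    # Tracer uptake model
    tracers: Dict[str, TracerParams] = field(default_factory=_default_tracers)
    halo_coupling: float = 0.5        # aggressiveness -> halo intensity coupling
    halo_shell_mm: float = 0.5

    # Lesion geometry
    n_blobs: int = 3
    lesion_margin_mm: float = 0.75    # lesions kept this far inside the pleura

    # Imaging chain (separate point-spread functions: preclinical CT
    # resolves ~0.4 mm, PET ~1.2 mm)
    psf_fwhm_mm: float = 1.2
    ct_psf_fwhm_mm: float = 0.4
    pet_noise_cv: float = 0.05        # multiplicative Gaussian, post-blur
    ct_noise_sd_hu: float = 30.0      # additive HU offset, post-blur
    scan_scale_cv: float = 0.0        # optional per-scan dose-calibration jitter (PET)

    weight_g: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be positive")
        for name, (_, sd) in (("body", self.body_hu), ("lung", self.lung_hu), ("lesion", self.lesion_hu)):
            if sd < 0:
                raise ValueError(f"{name} HU SD must be non-negative")
        if self.pet_noise_cv < 0 or self.ct_noise_sd_hu < 0 or self.scan_scale_cv < 0:
            raise ValueError("noise levels must be non-negative")
        if not 0 <= self.burden_d23 <= 1:
            raise ValueError("burden_d23 must be a fraction in [0, 1]")
        if not STUDY_WINDOW[0] <= self.onset_day <= STUDY_WINDOW[1]:
            raise ValueError(f"onset day {self.onset_day} outside study window {STUDY_WINDOW}")
        if not STUDY_WINDOW[0] <= self.therapy_start_day <= STUDY_WINDOW[1]:
            raise ValueError("therapy start day outside study window")
        for arm, m in self.therapy_growth_multiplier.items():
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"therapy growth multiplier for {arm} must be in [0, 1], got {m}")
        if any(v < 0 for v in self.growth_milestones.values()):
            raise ValueError("growth fractions must be non-negative")


@dataclass
class PhantomTruth:
    """Ground truth for one (animal, session): what a perfect reader would see.

    ``fibrosis_burden`` (lesion voxels / lung voxels) is the collagen
    surrogate; ``true_lung_activity_mbq`` and ``true_blood_kbq_ml`` stand in
    for terminal gamma-counting of lung and blood.
    """

    day: int
    lesion_mask: np.ndarray
    halo_mask: np.ndarray
    lung_mask: np.ndarray
    fibrosis_burden: float
    true_class_pid: Dict[str, Dict[str, float]]      # tracer -> class -> %ID/g
    true_lung_pid: Dict[str, float]                  # tracer -> lung-mean %ID/g
    true_lung_activity_mbq: Dict[str, float]
    true_blood_kbq_ml: Dict[str, float]

    def validate(self) -> None:
        if np.any(self.lesion_mask & self.halo_mask):
            raise AssertionError("lesion and halo masks overlap")
        if np.any(self.lesion_mask & ~self.lung_mask) or np.any(self.halo_mask & ~self.lung_mask):
            raise AssertionError("lesion/halo extend outside the lung")


@dataclass
class AnimalStudy:
    """Everything the phantom emits for one animal."""

    animal_id: str
    group: str
    aggressiveness: float
    ct: Dict[int, VolumeGrid]                        # nominal day -> CT
    pet: Dict[Tuple[int, str], Tuple[ScanMeta, VolumeGrid]]   # (nominal day, tracer)
    truth: Dict[int, PhantomTruth]
    lung_mask: np.ndarray                            # anatomical ground truth
    background_mask: np.ndarray                      # paraspinal muscle ROI


# ---------------------------------------------------------------------------
# Disease trajectory


def _growth_fraction(spec: PhantomSpec, day: float) -> float:
    """Vehicle-course lesion volume as a fraction of the day-23 volume."""
    if day <= spec.onset_day:
        return 0.0
    days = sorted(spec.growth_milestones)
    fracs = [spec.growth_milestones[d] for d in days]
    xs = [spec.onset_day] + list(days)
    ys = [0.0] + fracs
    if day >= xs[-1]:
        return ys[-1]
    return float(np.interp(day, xs, ys))


def disease_trajectory(group: str, day: float, spec: PhantomSpec | None = None,
                       aggressiveness: float = 1.0) -> float:
    """Ground-truth lesion burden (fraction of lung volume) for a group/day.

    Controls stay at zero; the BLM course is monotone non-decreasing from
    the onset day; treated arms follow the BLM course until treatment start
    (day 9) after which growth is multiplied by the arm's factor.  The
    aggressiveness multiplier scales post-day-9 growth only, so day-9
    burden is common to all animals of a group.
    """
    spec = spec or PhantomSpec()
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    if not STUDY_WINDOW[0] <= day <= STUDY_WINDOW[1]:
        raise ValueError(f"day {day} outside study window {STUDY_WINDOW}")
    if group == "NaCl":
        return 0.0
    g = _growth_fraction(spec, day)
    g_start = _growth_fraction(spec, spec.therapy_start_day)
    if group in TREATED_GROUPS and day > spec.therapy_start_day:
        m = spec.therapy_growth_multiplier.get(group, 1.0)
        g = g_start + m * (g - g_start)
    early = min(g, g_start)
    late = max(g - g_start, 0.0)
    return float(min(spec.burden_d23 * (early + aggressiveness * late), spec.burden_cap))


def vehicle_destiny_burden(spec: PhantomSpec, aggressiveness: float) -> float:
    """End-of-study burden this animal would reach without treatment."""
    return disease_trajectory("BLM", STUDY_WINDOW[1], spec, aggressiveness)


# ---------------------------------------------------------------------------
# Geometry & imaging engine


def _fwhm_to_sigma_vox(fwhm_mm: float, spacing: Sequence[float]) -> Tuple[float, ...]:
    sigma_mm = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return tuple(sigma_mm / s for s in spacing)


class PhantomEngine:
    """Holds the static geometry and blurred base fields for one spec.

    Instantiating the engine once per cohort avoids recomputing the
    body/lung masks and the blur of the lesion-free base images for every
    animal.
    """

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        nx, ny, nz = spec.shape
        if min(spec.shape) < 32:
            raise ValueError(f"grid {spec.shape} too small to contain two lung fields")
        idx = np.indices(spec.shape).astype(np.float32)

        def ellipsoid(center_frac, semi_frac):
            c = [f * n for f, n in zip(center_frac, spec.shape)]
            a = [f * n for f, n in zip(semi_frac, spec.shape)]
            return (((idx[0] - c[0]) / a[0]) ** 2 +
                    ((idx[1] - c[1]) / a[1]) ** 2 +
                    ((idx[2] - c[2]) / a[2]) ** 2) <= 1.0

        # Body: soft-tissue cylinder along z.
        cx, cy = 0.5 * nx, 0.5 * ny
        ax_, ay = 0.40 * nx, 0.36 * ny
        self.body = (((idx[0] - cx) / ax_) ** 2 + ((idx[1] - cy) / ay) ** 2) <= 1.0

        # Two lung fields.
        self.lung_semi_frac = (0.15, 0.19, 0.31)
        self.lung_centers_frac = [(0.30, 0.48, 0.5), (0.70, 0.48, 0.5)]
        self.lungs = [ellipsoid(c, self.lung_semi_frac) for c in self.lung_centers_frac]
        self.lung = self.lungs[0] | self.lungs[1]
        if min(f * n for f, n in zip(self.lung_semi_frac, spec.shape)) < 4:
            raise ValueError(f"grid {spec.shape} too small to contain two lung fields")

        # Paraspinal muscle background ROI: dorsal cylinder, central z half.
        mx, my, mr = 0.5 * nx, 0.78 * ny, 0.05 * nx
        muscle = (((idx[0] - mx)) ** 2 + ((idx[1] - my)) ** 2) <= mr ** 2
        zc = np.zeros(nz, dtype=bool)
        zc[nz // 4: 3 * nz // 4] = True
        self.muscle = muscle & zc[None, None, :] & self.body & ~self.lung

        # Region where lesions may live: comfortably inside the pleura.
        dist_in = ndimage.distance_transform_edt(self.lung, sampling=spec.spacing_mm)
        self.lesion_region = dist_in >= spec.lesion_margin_mm

        self.sigma_pet_vox = _fwhm_to_sigma_vox(spec.psf_fwhm_mm, spec.spacing_mm)
        self.sigma_ct_vox = _fwhm_to_sigma_vox(spec.ct_psf_fwhm_mm, spec.spacing_mm)
        self.voxvol_ml = float(np.prod(spec.spacing_mm)) / 1000.0
        self.n_lung = int(self.lung.sum())

        # Lesion-free blurred base fields.
        hu0 = np.full(spec.shape, -1000.0, dtype=np.float32)
        hu0[self.body] = spec.body_hu[0]
        hu0[self.lung] = spec.lung_hu[0]
        self.base_hu_blur = ndimage.gaussian_filter(hu0, self.sigma_ct_vox)
        self.base_pid_blur: Dict[str, np.ndarray] = {}
        for name, tp in spec.tracers.items():
            p0 = np.zeros(spec.shape, dtype=np.float32)
            p0[self.body] = tp.background_pid
            p0[self.lung] = tp.lung_pid
            self.base_pid_blur[name] = ndimage.gaussian_filter(p0, self.sigma_pet_vox)

        # Bounding box around the lung (padded for blur support).
        pad = int(np.ceil(4 * max(max(self.sigma_pet_vox), max(self.sigma_ct_vox)))) + 1
        ii = np.where(self.lung.any(axis=(1, 2)))[0]
        jj = np.where(self.lung.any(axis=(0, 2)))[0]
        kk = np.where(self.lung.any(axis=(0, 1)))[0]
        self.bbox = tuple(slice(max(0, a.min() - pad), min(n, a.max() + 1 + pad))
                          for a, n in zip((ii, jj, kk), spec.shape))

    # -- lesion geometry ----------------------------------------------------

    def _blob_fields(self, rng: np.random.Generator):
        """Per-blob distance fields (mm) over the lung bounding box."""
        spec = self.spec
        sub = np.indices([s.stop - s.start for s in self.bbox]).astype(np.float32)
        origin = np.array([s.start for s in self.bbox], dtype=np.float32)
        spacing = np.asarray(spec.spacing_mm, dtype=np.float32)
        dists, weights = [], rng.dirichlet(np.full(spec.n_blobs, 3.0))
        for b in range(spec.n_blobs):
            lung_i = b % 2
            c_frac = self.lung_centers_frac[lung_i]
            semi = np.array([f * n for f, n in zip(self.lung_semi_frac, spec.shape)])
            center = np.array([f * n for f, n in zip(c_frac, spec.shape)])
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            radial = rng.uniform(0.35, 0.75)
            c = center + radial * semi * u
            d = np.sqrt((((sub[0] + origin[0] - c[0]) * spacing[0]) ** 2) +
                        (((sub[1] + origin[1] - c[1]) * spacing[1]) ** 2) +
                        (((sub[2] + origin[2] - c[2]) * spacing[2]) ** 2))
            dists.append(d)
        return dists, weights

    def _lesion_mask_pre(self, dists, radii_mm) -> np.ndarray:
        """Pre-blur generating region (union of balls, clipped to interior)."""
        bb = self.bbox
        m = np.zeros(self.spec.shape, dtype=bool)
        sub = np.zeros_like(dists[0], dtype=bool)
        for d, r in zip(dists, radii_mm):
            if r > 0:
                sub |= d <= r
        m[bb] = sub
        return m & self.lesion_region

    def _lesion_truth(self, lesion_pre: np.ndarray) -> np.ndarray:
        """Post-blur ground truth: lung voxels reaching the -100 HU band."""
        spec = self.spec
        bb = self.bbox
        delta = spec.lesion_hu[0] - spec.lung_hu[0]
        bump = ndimage.gaussian_filter(lesion_pre[bb].astype(np.float32), self.sigma_ct_vox)
        hu = self.base_hu_blur[bb] + delta * bump
        truth = np.zeros(spec.shape, dtype=bool)
        truth[bb] = hu >= -100.0
        return truth & self.lung

    def solve_lesion(self, dists, weights, target_burden: float,
                     s_upper: float | None = None):
        """Blob scale s such that the post-blur truth burden matches target.

        Returns (truth mask, pre-blur mask, scale).  The realized burden is
        monotone in the common scale factor, so a bisection converges; if
        the interior region saturates before the target is reached the
        largest feasible lesion is used.  ``s_upper`` may supply a known
        upper bracket (the destiny scale); the solution is independent of
        which other sessions were generated.
        """
        target_vox = int(round(target_burden * self.n_lung))
        if target_vox <= 0:
            empty = np.zeros(self.spec.shape, dtype=bool)
            return empty, empty, 0.0
        vref = target_burden * self.n_lung * self.voxvol_ml * 1000.0  # mm^3
        base_r = np.array([(3.0 * w * vref / (4.0 * np.pi)) ** (1.0 / 3.0) for w in weights])

        def realized(s):
            pre = self._lesion_mask_pre(dists, s * base_r)
            return int(self._lesion_truth(pre).sum())

        lo, hi = 0.0, (s_upper or 1.0)
        n_hi = realized(hi)
        tries = 0
        while n_hi < target_vox and tries < 12:
            lo, hi = hi, hi * 1.6
            n_hi = realized(hi)
            tries += 1
        if n_hi < target_vox:   # interior saturated; accept the cap
            pre = self._lesion_mask_pre(dists, hi * base_r)
            return self._lesion_truth(pre), pre, hi
        for _ in range(14):
            mid = 0.5 * (lo + hi)
            if realized(mid) < target_vox:
                lo = mid
            else:
                hi = mid
        pre = self._lesion_mask_pre(dists, hi * base_r)
        return self._lesion_truth(pre), pre, hi

    def halo_region(self, destiny_truth: np.ndarray) -> np.ndarray:
        """Destined consolidation extent dilated by the halo shell, in-lung."""
        if not destiny_truth.any():
            return np.zeros(self.spec.shape, dtype=bool)
        bb = self.bbox
        dist = ndimage.distance_transform_edt(~destiny_truth[bb],
                                              sampling=self.spec.spacing_mm)
        region = np.zeros(self.spec.shape, dtype=bool)
        region[bb] = dist <= self.spec.halo_shell_mm
        return region & self.lung


# ---------------------------------------------------------------------------
# Animal generation


def _base_radii(engine: PhantomEngine, weights, burden: float) -> np.ndarray:
    vref = burden * engine.n_lung * engine.voxvol_ml * 1000.0
    return np.array([(3.0 * w * vref / (4.0 * np.pi)) ** (1.0 / 3.0) for w in weights])


def draw_aggressiveness(spec: PhantomSpec, rng: np.random.Generator) -> float:
    """Log-normal aggressiveness multiplier with unit mean, clipped to bounds."""
    s = spec.aggressiveness_sigma
    a = float(np.exp(rng.normal(-0.5 * s * s, s)))
    return float(np.clip(a, *spec.aggressiveness_bounds))


def stratified_aggressiveness(spec: PhantomSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Quantile-midpoint draws of the aggressiveness distribution.

    Used for cohort simulation: preserves the across-animal spread that
    drives the early-marker correlations while keeping the group mean free
    of sampling noise.  Order is shuffled so animal identity stays random.
    """
    from scipy.stats import norm
    s = spec.aggressiveness_sigma
    q = (np.arange(n) + 0.5) / n
    a = np.exp(norm.ppf(q) * s - 0.5 * s * s)
    a = np.clip(a, *spec.aggressiveness_bounds)
    rng.shuffle(a)
    return a


def generate_animal(spec: PhantomSpec, group: str, animal_seed: int,
                    animal_id: str | None = None,
                    days: Sequence[int] | None = None,
                    tracers: Sequence[str] = ("FDG", "FMISO"),
                    aggressiveness: float | None = None,
                    engine: PhantomEngine | None = None) -> AnimalStudy:
    """Simulate one animal's full longitudinal PET/CT study.

    ``days`` restricts the nominal sessions generated (default all four);
    volumes for a given (seed, day, channel) are bit-identical regardless of
    which subset is requested.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    engine = engine or PhantomEngine(spec)
    days = tuple(int(d) for d in (days if days is not None else NOMINAL_DAYS))
    animal_id = animal_id or f"{group}-{animal_seed}"

    rng_bio = np.random.default_rng(np.random.SeedSequence([int(animal_seed), 999]))
    a = aggressiveness if aggressiveness is not None else draw_aggressiveness(spec, rng_bio)
    dists, weights = engine._blob_fields(rng_bio)
    base_r = _base_radii(engine, weights, max(vehicle_destiny_burden(spec, a), 1e-9))

    diseased = group != "NaCl"
    # Destiny solve: the untreated end-of-study lesion extent.  Its dilation
    # is the halo region at every session; for vehicle animals it doubles as
    # the day-23 lesion itself.
    if diseased:
        destiny_burden = vehicle_destiny_burden(spec, a)
        destiny_truth, destiny_pre, s_dest = engine.solve_lesion(dists, weights, destiny_burden)
        halo_region = engine.halo_region(destiny_truth)
    else:
        destiny_truth = destiny_pre = np.zeros(spec.shape, dtype=bool)
        halo_region = np.zeros(spec.shape, dtype=bool)
        s_dest = 0.0
    halo_onset = spec.tracers["FMISO"].onset_day if "FMISO" in spec.tracers else 9.0

    ct_vols: Dict[int, VolumeGrid] = {}
    pet_vols: Dict[Tuple[int, str], Tuple[ScanMeta, VolumeGrid]] = {}
    truths: Dict[int, PhantomTruth] = {}
    for day in sorted(days):
        if diseased:
            target = disease_trajectory(group, day, spec, a)
            if abs(target - destiny_burden) < 1e-12:
                lesion, lesion_pre = destiny_truth, destiny_pre
            else:
                # destiny is an upper bracket: every session's lesion is
                # nested inside the untreated end-of-study extent
                lesion, lesion_pre, _ = engine.solve_lesion(
                    dists, weights, target, s_upper=s_dest if s_dest > 0 else None)
            halo = (halo_region & ~lesion) if day >= halo_onset else np.zeros(spec.shape, bool)
        else:
            lesion = lesion_pre = np.zeros(spec.shape, dtype=bool)
            halo = np.zeros(spec.shape, dtype=bool)

        ct_vols[day] = _emit_ct(spec, engine, lesion_pre, lesion, animal_seed, day)
        truth = _truth_record(spec, engine, group, day, a, lesion, halo)
        truths[day] = truth
        for tracer in tracers:
            meta, vol = _emit_pet(spec, engine, group, tracer, day, a,
                                  lesion, halo, animal_seed, animal_id)
            pet_vols[(day, tracer)] = (meta, vol)

    return AnimalStudy(animal_id=animal_id, group=group, aggressiveness=a,
                       ct=ct_vols, pet=pet_vols, truth=truths,
                       lung_mask=engine.lung, background_mask=engine.muscle)


def tracer_actual_day(day: int, tracer: str) -> int:
    """FDG sessions happen the day before the nominal (CT/FMISO) day."""
    return day - 1 if (tracer == "FDG" and day > 0) else day


def _therapy_uptake_mult(spec: PhantomSpec, group: str, tracer: str, day: float) -> float:
    if group in TREATED_GROUPS and day > spec.therapy_start_day:
        return spec.therapy_uptake_multiplier.get(group, {}).get(tracer, 1.0)
    return 1.0


def _tracer_class_pid(spec: PhantomSpec, group: str, tracer: str, day: int,
                      aggressiveness: float) -> Dict[str, float]:
    """True %ID/g by tissue class for one scan (pre-blur, noise-free)."""
    tp = spec.tracers[tracer]
    t = tracer_actual_day(day, tracer)
    lesion = halo = tp.lung_pid
    if t >= tp.onset_day:
        m = _therapy_uptake_mult(spec, group, tracer, t)
        # aggressiveness couples to the halo *excess*, so a tracer with no
        # halo avidity (halo_mult == 1) stays halo-silent for every animal
        halo_excess = (tp.halo_mult - 1.0) * (1.0 + spec.halo_coupling * (aggressiveness - 1.0))
        lesion = tp.lung_pid * max(tp.lesion_mult * m, 0.0)
        halo = tp.lung_pid * max(1.0 + halo_excess * m, 0.0)
    return {"normal": tp.lung_pid, "lesion": lesion, "halo": halo,
            "background": tp.background_pid, "blood": tp.blood_pid}


def _emit_ct(spec: PhantomSpec, engine: PhantomEngine, lesion_pre: np.ndarray,
             lesion_truth: np.ndarray, animal_seed: int, day: int) -> VolumeGrid:
    bb = engine.bbox
    hu = engine.base_hu_blur.copy()
    if lesion_pre.any():
        delta = spec.lesion_hu[0] - spec.lung_hu[0]
        hu[bb] = hu[bb] + delta * ndimage.gaussian_filter(
            lesion_pre[bb].astype(np.float32), engine.sigma_ct_vox)

    rng = np.random.default_rng(np.random.SeedSequence([int(animal_seed), int(day), 0]))
    sd = np.zeros(spec.shape, dtype=np.float32)
    sd[engine.body] = spec.body_hu[1]
    sd[engine.lung] = spec.lung_hu[1]
    sd[lesion_pre] = spec.lesion_hu[1]
    texture = rng.normal(size=spec.shape).astype(np.float32) * sd
    hu = hu + ndimage.gaussian_filter(texture, engine.sigma_ct_vox)
    if spec.ct_noise_sd_hu > 0:
        hu = hu + rng.normal(0.0, spec.ct_noise_sd_hu, size=spec.shape).astype(np.float32)
    # Consolidations stay in the high-density band after noise.
    hu[lesion_truth] = np.clip(hu[lesion_truth], -100.0, 300.0)
    return VolumeGrid(hu, spec.spacing_mm, "CT")


def _emit_pet(spec: PhantomSpec, engine: PhantomEngine, group: str, tracer: str,
              day: int, aggressiveness: float, lesion: np.ndarray, halo: np.ndarray,
              animal_seed: int, animal_id: str) -> Tuple[ScanMeta, VolumeGrid]:
    cls = _tracer_class_pid(spec, group, tracer, day, aggressiveness)
    tp = spec.tracers[tracer]
    bb = engine.bbox
    pid = engine.base_pid_blur[tracer].copy()
    for mask, value in ((lesion, cls["lesion"]), (halo, cls["halo"])):
        if mask.any() and value != tp.lung_pid:
            pid[bb] = pid[bb] + (value - tp.lung_pid) * ndimage.gaussian_filter(
                mask[bb].astype(np.float32), engine.sigma_pet_vox)

    ch = 1 if tracer == "FDG" else 2
    rng = np.random.default_rng(np.random.SeedSequence([int(animal_seed), int(day), ch]))
    scale = float(np.exp(rng.normal(-0.5 * spec.scan_scale_cv ** 2, spec.scan_scale_cv))) \
        if spec.scan_scale_cv > 0 else 1.0
    pid = pid * scale
    if spec.pet_noise_cv > 0:
        pid = pid * (1.0 + spec.pet_noise_cv * rng.normal(size=spec.shape).astype(np.float32))
    pid = np.clip(pid, 0.0, None)

    meta = default_scan_meta(animal_id, group, tracer_actual_day(day, tracer), tracer,
                             weight_g=spec.weight_g)
    # %ID/g -> activity concentration at injection (kBq/mL), decayed to
    # acquisition start: the emitted volume is decay-uncorrected.
    conc_inj = pid * meta.dose_mbq * 10.0
    decay = 2.0 ** (-meta.uptake_minutes / meta.half_life_min)
    return meta, VolumeGrid(conc_inj * decay, spec.spacing_mm, "PET")


def _truth_record(spec: PhantomSpec, engine: PhantomEngine, group: str, day: int,
                  aggressiveness: float, lesion: np.ndarray, halo: np.ndarray) -> PhantomTruth:
    n_lung = engine.n_lung
    n_les, n_halo = int(lesion.sum()), int(halo.sum())
    burden = n_les / n_lung
    class_pid, lung_pid, lung_act, blood = {}, {}, {}, {}
    lung_mass_g = n_lung * engine.voxvol_ml  # 1 g/mL
    for tracer, tp in spec.tracers.items():
        cls = _tracer_class_pid(spec, group, tracer, day, aggressiveness)
        class_pid[tracer] = cls
        mean_pid = ((n_lung - n_les - n_halo) * cls["normal"] +
                    n_les * cls["lesion"] + n_halo * cls["halo"]) / n_lung
        lung_pid[tracer] = float(mean_pid)
        from .meta import TRACER_DOSE_MBQ
        lung_act[tracer] = float(mean_pid / 100.0 * TRACER_DOSE_MBQ[tracer] * lung_mass_g)
        blood[tracer] = float(cls["blood"] * TRACER_DOSE_MBQ[tracer] * 10.0)
    truth = PhantomTruth(day=day, lesion_mask=lesion, halo_mask=halo,
                         lung_mask=engine.lung, fibrosis_burden=float(burden),
                         true_class_pid=class_pid, true_lung_pid=lung_pid,
                         true_lung_activity_mbq=lung_act, true_blood_kbq_ml=blood)
    truth.validate()
    return truth


# ---------------------------------------------------------------------------
# Cohort generation


def _per_group_counts(n_per_group) -> Dict[str, int]:
    if isinstance(n_per_group, Mapping):
        counts = {g: int(n) for g, n in n_per_group.items()}
    elif isinstance(n_per_group, (list, tuple)):
        counts = {g: int(n) for g, n in zip(GROUPS, n_per_group)}
    else:
        counts = {g: int(n_per_group) for g in GROUPS}
    for g, n in counts.items():
        if g not in GROUPS:
            raise ValueError(f"unknown group {g!r}")
        if n < 1:
            raise ValueError(f"need at least one animal per group, got {n} for {g}")
    return counts


def simulate_cohort(spec: PhantomSpec, n_per_group, seed: int,
                    days: Sequence[int] | None = None,
                    tracers: Sequence[str] = ("FDG", "FMISO"),
                    engine: PhantomEngine | None = None) -> Iterable[AnimalStudy]:
    """Yield simulated animals one at a time (memory-light streaming).

    Aggressiveness multipliers are drawn once per animal (stratified over
    the distribution within each group) and shared across timepoints, which
    is what couples early FMISO uptake to eventual progression.
    """
    counts = _per_group_counts(n_per_group)
    engine = engine or PhantomEngine(spec)
    master = np.random.default_rng(np.random.SeedSequence([int(seed), 77]))
    for group in GROUPS:
        if group not in counts:
            continue
        n = counts[group]
        seeds = master.integers(0, 2 ** 31 - 1, size=n)
        aggr = stratified_aggressiveness(spec, n, master)
        for i in range(n):
            yield generate_animal(spec, group, int(seeds[i]),
                                  animal_id=f"{group.replace('+', '-')}-{i + 1:02d}",
                                  days=days, tracers=tracers,
                                  aggressiveness=float(aggr[i]), engine=engine)


def generate_cohort(spec: PhantomSpec, n_per_group, seed: int, out_dir) -> "pd.DataFrame":
    """Simulate a cohort and write it as a study directory.

    Layout: one NIfTI volume per scan under ``volumes/``, a ``study.csv``
    metadata table (one row per scan), a ``truth/<animal>.json`` sidecar per
    animal, and the shared lung/background ground-truth masks.
    """
    import pandas as pd
    from . import io as fio

    out = Path(out_dir)
    try:
        (out / "volumes").mkdir(parents=True, exist_ok=True)
        (out / "truth").mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create study directory {out}: {e}") from e

    engine = PhantomEngine(spec)
    fio.write_volume(out / "lung_truth_mask.nii.gz",
                     VolumeGrid(engine.lung.astype(np.float32), spec.spacing_mm, "CT"))
    fio.write_volume(out / "background_mask.nii.gz",
                     VolumeGrid(engine.muscle.astype(np.float32), spec.spacing_mm, "CT"))

    rows = []
    for animal in simulate_cohort(spec, n_per_group, seed, engine=engine):
        sidecar = {"animal_id": animal.animal_id, "group": animal.group,
                   "aggressiveness": animal.aggressiveness, "days": {}}
        for day, ct in animal.ct.items():
            fname = f"volumes/{animal.animal_id}_D{day:02d}_CT.nii.gz"
            fio.write_volume(out / fname, ct)
            rows.append(dict(animal_id=animal.animal_id, group=animal.group, day=day,
                             tracer="CT", dose_MBq="", t_injection_ISO8601="",
                             t_scan_ISO8601="", weight_g=spec.weight_g, file=fname))
        for (day, tracer), (meta, vol) in animal.pet.items():
            fname = f"volumes/{animal.animal_id}_D{meta.day:02d}_{tracer}.nii.gz"
            fio.write_volume(out / fname, vol)
            rows.append(dict(animal_id=animal.animal_id, group=animal.group, day=meta.day,
                             tracer=tracer, dose_MBq=meta.dose_mbq,
                             t_injection_ISO8601=meta.t_injection.isoformat(),
                             t_scan_ISO8601=meta.t_scan.isoformat(),
                             weight_g=meta.weight_g, file=fname))
        for day, truth in animal.truth.items():
            sidecar["days"][str(day)] = {
                "fibrosis_burden": truth.fibrosis_burden,
                "true_lung_pid": truth.true_lung_pid,
                "true_lung_activity_mbq": truth.true_lung_activity_mbq,
                "true_blood_kbq_ml": truth.true_blood_kbq_ml,
                "lesion_voxels": int(truth.lesion_mask.sum()),
                "halo_voxels": int(truth.halo_mask.sum()),
            }
        with open(out / "truth" / f"{animal.animal_id}.json", "w") as fh:
            json.dump(sidecar, fh, indent=1, sort_keys=True)

    table = pd.DataFrame(rows).sort_values(["group", "animal_id", "day", "tracer"]).reset_index(drop=True)
    table.to_csv(out / "study.csv", index=False)
    return table
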