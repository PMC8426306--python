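"""PET uptake quantification: %ID/g, SUV, LTBR, MLV, HLV, density-gated uptake.

All activity quantities are decay-corrected back to the injection time using
the fluorine-18 half-life before normalisation.  Tissue density is taken as
1 g/mL (general soft-tissue convention), which gives the exact algebraic
identity ``SUV = %ID/g * body_weight_g / 100`` on every voxel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np

from .grids import VolumeGrid
from .meta import ScanMeta
from .segmentation import LungPartition


def decay_correct(activity, elapsed_min: float, half_life_min: float):
    """Reference measured activity back to an earlier time.

    Multiplies by ``2**(elapsed/half_life)``: an acquisition ``elapsed_min``
    after injection underestimates the injected-time activity by one factor
    of two per half-life.  ``elapsed_min == 0`` is the identity.
    """
    if half_life_min <= 0:
        raise ValueError("half-life must be positive")
    if elapsed_min < 0:
        raise ValueError(f"elapsed time must be non-negative, got {elapsed_min} min")
    return activity * 2.0 ** (elapsed_min / half_life_min)


def _check_pet(pet: VolumeGrid) -> None:
    if pet.modality != "PET":
        raise ValueError(f"expected a PET volume in kBq/mL, got {pet.modality}")


def percent_id_per_g(pet: VolumeGrid, meta: ScanMeta) -> np.ndarray:
    """Per-voxel percent injected dose per gram of tissue.

    The PET volume holds activity concentration (kBq/mL) at acquisition
    start; it is decay-corrected to injection time and normalised by the
    injected dose, with 1 mL == 1 g of tissue:

        %ID/g = 100 * C_inj(MBq/mL) / dose(MBq)
    """
    _check_pet(pet)
    if meta.dose_mbq <= 0:
        raise ValueError("injected dose must be positive")
    conc_inj_kbq = decay_correct(pet.data, meta.uptake_minutes, meta.half_life_min)
    return 100.0 * (conc_inj_kbq / 1000.0) / meta.dose_mbq


def suv_map(pet: VolumeGrid, meta: ScanMeta) -> np.ndarray:
    """Per-voxel standardized uptake value.

    SUV = decay-corrected concentration (kBq/mL) / (dose (kBq) / weight (g)),
    with 1 g/mL tissue density.
    """
    _check_pet(pet)
    if meta.weight_g <= 0:
        raise ValueError("body weight must be positive")
    conc_inj_kbq = decay_correct(pet.data, meta.uptake_minutes, meta.half_life_min)
    return conc_inj_kbq / (meta.dose_mbq * 1000.0 / meta.weight_g)


def suv(pet: VolumeGrid, meta: ScanMeta, mask: np.ndarray) -> Tuple[np.ndarray, float, float]:
    """SUV map plus SUVmean / SUVmax over a region."""
    smap = suv_map(pet, meta)
    vals = smap[mask]
    if vals.size == 0:
        raise ValueError("empty mask: no voxels for SUV statistics")
    return smap, float(vals.mean()), float(vals.max())


def lung_to_background_ratio(values: np.ndarray, lung_mask: np.ndarray,
                             background_mask: np.ndarray) -> float:
    """Ratio of lung mean to background mean of the same voxel quantity.

    Scale-invariant: identical whether computed on kBq/mL, %ID/g or SUV maps
    (the normalising factors cancel).
    """
    if background_mask.sum() == 0:
        raise ValueError("background mask is empty")
    if np.any(lung_mask & background_mask):
        raise ValueError("background mask overlaps the lung mask")
    bg = float(values[background_mask].mean())
    if bg == 0:
        raise ValueError("background mean is zero; LTBR undefined")
    return float(values[lung_mask].mean()) / bg


@dataclass(frozen=True)
class MLVThreshold:
    """Baseline-derived SUV threshold for the metabolic lung volume.

    threshold = baseline mean + 2 * baseline SD, where the SD scope is either
    the pooled voxel-level SUV distribution of the baseline scans (default;
    makes the threshold an honest 2-SD upper tail of healthy-lung voxels) or
    the across-animal SD of per-animal baseline SUVmean values.
    """

    tracer: str
    value: float
    baseline_mean: float
    baseline_sd: float
    n_baseline: int


def mlv_threshold(baseline: Sequence[np.ndarray] | Sequence[float], tracer: str = "FDG",
                  sd_scope: str = "voxel") -> MLVThreshold:
    """Threshold = baseline mean + 2 SD from day-0 scans.

    Parameters
    ----------
    baseline
        For ``sd_scope="voxel"``: one array of lung-voxel SUVs per baseline
        scan (pooled before taking mean/SD).  For ``sd_scope="animal"``:
        per-animal baseline SUVmean scalars (sample SD, ddof=1).
    """
    if len(baseline) < 2:
        raise ValueError(f"need >= 2 baseline scans for the MLV threshold, got {len(baseline)}")
    if sd_scope == "voxel":
        pooled = np.concatenate([np.ravel(np.asarray(b, dtype=float)) for b in baseline])
        mean, sd = float(pooled.mean()), float(pooled.std(ddof=1))
    elif sd_scope == "animal":
        vals = np.asarray([float(np.mean(b)) for b in baseline], dtype=float)
        mean, sd = float(vals.mean()), float(vals.std(ddof=1))
    else:
        raise ValueError(f"sd_scope must be 'voxel' or 'animal', got {sd_scope!r}")
    return MLVThreshold(tracer=tracer, value=mean + 2.0 * sd,
                        baseline_mean=mean, baseline_sd=sd, n_baseline=len(baseline))


def metabolic_lung_volume(suv_values: np.ndarray, lung_mask: np.ndarray,
                          threshold: MLVThreshold | float,
                          voxel_volume_ml: float) -> Tuple[float, float]:
    """Lung volume with SUV strictly above the baseline threshold.

    Returns (MLV in mL, MLV as % of lung volume).  The threshold is an
    exceedance bound, so the comparison is strict.
    """
    thr = threshold.value if isinstance(threshold, MLVThreshold) else float(threshold)
    n_lung = int(lung_mask.sum())
    if n_lung == 0:
        raise ValueError("empty lung mask")
    n_hot = int((suv_values[lung_mask] > thr).sum())
    return n_hot * voxel_volume_ml, 100.0 * n_hot / n_lung


def hypoxic_lung_volume(pet: VolumeGrid, meta: ScanMeta, lung_mask: np.ndarray,
                        background_mask: np.ndarray, multiplier: float = 1.4,
                        voxel_volume_ml: float | None = None) -> Tuple[float, float]:
    """Hypoxic lung volume on an FMISO scan.

    A voxel is hypoxic iff its voxel-to-background ratio is >= ``multiplier``
    (default 1.4, the conventional FMISO tissue-to-background cut-off), i.e.
    its value is at least 1.4 times the background-region mean.  Returns
    (HLV in mL, HLV as % of lung volume).

    Raises
    ------
    ValueError
        If applied to a non-FMISO scan: the hypoxic volume is defined for
        the hypoxia tracer only.
    """
    if meta.tracer != "FMISO":
        raise ValueError(f"hypoxic lung volume is defined on FMISO scans only, got {meta.tracer}")
    _check_pet(pet)
    if background_mask.sum() == 0:
        raise ValueError("background mask is empty")
    bg = float(pet.data[background_mask].mean())
    if bg <= 0:
        raise ValueError("background mean must be positive")
    vv = voxel_volume_ml if voxel_volume_ml is not None else pet.voxel_volume_ml
    n_lung = int(lung_mask.sum())
    if n_lung == 0:
        raise ValueError("empty lung mask")
    n_hyp = int((pet.data[lung_mask] >= multiplier * bg).sum())
    return n_hyp * vv, 100.0 * n_hyp / n_lung


def density_gated_uptake(pid_map: np.ndarray, partition: LungPartition) -> Tuple[float | None, float | None]:
    """Mean %ID/g separately over aerated and high-density lung voxels.

    An absent class yields ``None`` (flagged missing), never zero.
    """
    if pid_map.shape != partition.mask.shape:
        raise ValueError("uptake map and partition are on different grids")
    aer = partition.aerated
    dense = partition.high_density
    aer_mean = float(pid_map[aer].mean()) if aer.any() else None
    dense_mean = float(pid_map[dense].mean()) if dense.any() else None
    return aer_mean, dense_mean


@dataclass(frozen=True)
class UptakeMetrics:
    """Full per-scan PET quantification record."""

    animal_id: str
    group: str
    day: int
    tracer: str
    pid_lung: float               # mean lung %ID/g
    suv_mean: float
    suv_max: float
    ltbr: float
    mlv_ml: float | None = None   # FDG scans, needs a baseline threshold
    mlv_pct: float | None = None
    hlv_ml: float | None = None   # FMISO scans only
    hlv_pct: float | None = None
    pid_aerated: float | None = None
    pid_high_density: float | None = None


def quantify_scan(pet: VolumeGrid, meta: ScanMeta, partition: LungPartition,
                  background_mask: np.ndarray,
                  mlv_thr: MLVThreshold | None = None,
                  hlv_multiplier: float = 1.4) -> UptakeMetrics:
    """Compute every uptake metric for one PET scan against its CT partition."""
    if pet.shape != partition.mask.shape:
        raise ValueError("PET volume and lung partition are on different grids")
    lung = partition.mask
    pid = percent_id_per_g(pet, meta)
    smap, suv_mean, suv_max = suv(pet, meta, lung)
    ltbr = lung_to_background_ratio(pid, lung, background_mask)
    aer, dense = density_gated_uptake(pid, partition)
    vv = partition.voxel_volume_ml

    mlv_ml = mlv_pct = hlv_ml = hlv_pct = None
    if mlv_thr is not None:
        mlv_ml, mlv_pct = metabolic_lung_volume(smap, lung, mlv_thr, vv)
    if meta.tracer == "FMISO":
        hlv_ml, hlv_pct = hypoxic_lung_volume(pet, meta, lung, background_mask,
                                              multiplier=hlv_multiplier, voxel_volume_ml=vv)
    return UptakeMetrics(
        animal_id=meta.animal_id, group=meta.group, day=meta.day, tracer=meta.tracer,
        pid_lung=float(pid[lung].mean()), suv_mean=suv_mean, suv_max=suv_max, ltbr=ltbr,
        mlv_ml=mlv_ml, mlv_pct=mlv_pct, hlv_ml=hlv_ml, hlv_pct=hlv_pct,
        pid_aerated=aer, pid_high_density=dense,
    )
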