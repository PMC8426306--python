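"""CT lung segmentation and density-class quantification.

The lung region is recovered automatically from the Hounsfield-unit volume:
low-attenuation connected components inside the body are retained,
morphologically closed and hole-filled so that dense fibrotic consolidations
interior to the lung stay part of the lung region.  The region is then
partitioned by HU value into the two diagnostic density bands used for
quantification:

* aerated (normal) lung: ``[-800, -100)`` HU
* high-density (non-aerated / fibrotic) lung: ``[-100, 300]`` HU

The -100 HU boundary belongs to the high-density band (half-open split, so
the bands partition the lung).  Voxels outside ``[-800, 300]`` remain in the
lung region for mean-lung-density purposes but are classed out-of-band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
from scipy import ndimage

from .grids import VolumeGrid

#: Density-band edges in HU: [aerated_low, split, dense_high].
DEFAULT_BANDS = (-800.0, -100.0, 300.0)

#: Voxel class codes within the lung region.
CLASS_OUT_OF_BAND = 0
CLASS_AERATED = 1
CLASS_HIGH_DENSITY = 2


class LungFieldNotFoundError(RuntimeError):
    """Raised when no plausible lung field is present in the CT volume."""


@dataclass
class SegmentationParams:
    """Tunable knobs of the automatic lung mask.

    lung_threshold_hu
        Voxels below this HU value (inside the body) are lung candidates.
    body_threshold_hu
        Voxels above this HU value seed the body mask.
    closing_radius_vox
        Radius (voxels) of the binary closing that bridges over dense
        consolidations at the lung surface.
    min_component_ml
        Minimum volume of a retained lung field; smaller low-HU islands
        (airways, noise) are dropped.
    max_components
        Keep at most this many lung fields (two for separate left/right).
    """

    lung_threshold_hu: float = -300.0
    body_threshold_hu: float = -500.0
    closing_radius_vox: int = 4
    min_component_ml: float = 0.05
    max_components: int = 2


def _ball(radius: int) -> np.ndarray:
    if radius <= 0:
        return np.ones((1, 1, 1), dtype=bool)
    grid = np.indices((2 * radius + 1,) * 3) - radius
    return (grid ** 2).sum(axis=0) <= radius ** 2


def extract_lung_mask(ct: VolumeGrid, params: SegmentationParams | None = None) -> np.ndarray:
    """Automatic lung mask from a CT volume in HU.

    Returns a boolean mask containing the largest 1-2 low-attenuation
    connected components inside the body, closed and hole-filled so dense
    lesions interior to the lung are included.  Air outside the body is
    excluded by restricting candidates to the filled body silhouette.

    Raises
    ------
    LungFieldNotFoundError
        If no candidate component reaches ``min_component_ml``.
    """
    params = params or SegmentationParams()
    if ct.modality != "CT":
        raise ValueError(f"lung segmentation expects a CT volume, got {ct.modality}")
    hu = ct.data

    # Body silhouette: largest above-air component, holes (lungs) filled.
    body = hu > params.body_threshold_hu
    labels, n = ndimage.label(body)
    if n == 0:
        raise LungFieldNotFoundError("no lung field found: volume contains no body")
    sizes = ndimage.sum_labels(np.ones_like(labels, dtype=np.int64), labels, index=np.arange(1, n + 1))
    body = labels == (1 + int(np.argmax(sizes)))
    body = ndimage.binary_fill_holes(body)

    candidates = (hu < params.lung_threshold_hu) & body
    labels, n = ndimage.label(candidates)
    min_vox = max(1, int(round(params.min_component_ml / ct.voxel_volume_ml)))
    if n == 0:
        raise LungFieldNotFoundError("no lung field found: no low-attenuation region inside body")
    sizes = ndimage.sum_labels(np.ones_like(labels, dtype=np.int64), labels, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1]
    keep = [int(order[i]) + 1 for i in range(min(params.max_components, n))
            if sizes[order[i]] >= min_vox]
    if not keep:
        raise LungFieldNotFoundError(
            f"no lung field found: largest low-attenuation component is "
            f"{sizes.max() * ct.voxel_volume_ml:.3f} mL < {params.min_component_ml} mL")
    mask = np.isin(labels, keep)

    if params.closing_radius_vox > 0:
        mask = ndimage.binary_closing(mask, structure=_ball(params.closing_radius_vox))
    mask = ndimage.binary_fill_holes(mask)
    return mask & body


@dataclass
class LungPartition:
    """Lung mask plus per-voxel density class.

    ``classes`` is an integer volume: 0 outside the lung is not meaningful
    (use ``mask``); within the lung the codes are CLASS_AERATED,
    CLASS_HIGH_DENSITY, CLASS_OUT_OF_BAND.
    """

    mask: np.ndarray
    classes: np.ndarray
    bands: Tuple[float, float, float] = DEFAULT_BANDS
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def aerated(self) -> np.ndarray:
        return self.mask & (self.classes == CLASS_AERATED)

    @property
    def high_density(self) -> np.ndarray:
        return self.mask & (self.classes == CLASS_HIGH_DENSITY)

    @property
    def out_of_band(self) -> np.ndarray:
        return self.mask & (self.classes == CLASS_OUT_OF_BAND)


def partition_density(ct: VolumeGrid, lung_mask: np.ndarray,
                      bands: Tuple[float, float, float] = DEFAULT_BANDS) -> LungPartition:
    """Assign each lung voxel to a density class by its HU value.

    ``bands = (lo, split, hi)``: aerated is ``[lo, split)``, high-density is
    ``[split, hi]``, anything else in the lung is out-of-band.
    """
    lo, split, hi = (float(b) for b in bands)
    if not lo < split < hi:
        raise ValueError(f"density bands must be increasing and non-overlapping, got {bands}")
    if lung_mask.shape != ct.shape:
        raise ValueError("lung mask shape does not match CT volume")
    hu = ct.data
    classes = np.zeros(ct.shape, dtype=np.uint8)
    classes[(hu >= lo) & (hu < split)] = CLASS_AERATED
    classes[(hu >= split) & (hu <= hi)] = CLASS_HIGH_DENSITY
    classes[~lung_mask] = CLASS_OUT_OF_BAND
    return LungPartition(mask=lung_mask.astype(bool), classes=classes,
                         bands=(lo, split, hi), spacing=ct.spacing)


@dataclass(frozen=True)
class CTMetrics:
    """CT-side quantification of one scan."""

    mld_hu: float            # mean lung density over the whole lung region
    aerated_pct: float       # % of lung voxels in the aerated band
    high_density_pct: float  # % of lung voxels in the high-density band
    lung_volume_ml: float


def ct_metrics(ct: VolumeGrid, partition: LungPartition) -> CTMetrics:
    """Mean lung density, aerated percentage and lung volume."""
    n_lung = int(partition.mask.sum())
    if n_lung == 0:
        raise ValueError("empty lung mask: no voxels to quantify")
    mld = float(ct.data[partition.mask].mean())
    aer = 100.0 * float(partition.aerated.sum()) / n_lung
    dense = 100.0 * float(partition.high_density.sum()) / n_lung
    vol = n_lung * ct.voxel_volume_ml
    return CTMetrics(mld_hu=mld, aerated_pct=aer, high_density_pct=dense, lung_volume_ml=vol)
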