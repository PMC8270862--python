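"""Semiautomatic enhancing-synovium segmentation.

Enhancing voxels are found by subtracting the pre-contrast from the
post-contrast 3D image with a *shuffle transform*: for each voxel of the
post-contrast image the subtrahend is the pre-contrast voxel, within a
small neighbourhood around the same location, whose intensity is closest
to it.  This suppresses residual misregistration while leaving genuine
enhancement intact.  The shuffle-subtracted image is binarised by Otsu's
threshold (histogram sampled within the synovial ROI union) and
intersected with the synovial region-of-interest label map to yield the
"volume of enhancing pannus" (VEP) mask, from which per-region volumes
(mL) and median biomarker values are extracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

__all__ = [
    "REGION_NAMES", "ROILabelMap", "ShuffleDifference", "VEPResult",
    "shuffle_subtract", "otsu_threshold", "build_vep_mask",
    "extract_median_biomarkers",
]

#: The seven synovial regions of interest, label 1..7.
REGION_NAMES = {
    1: "suprapatellar",
    2: "hoffa_fat_pad",
    3: "medial_perimeniscal",
    4: "lateral_perimeniscal",
    5: "intercondylar_notch",
    6: "posterior_medial_femoral_condyle",
    7: "posterior_lateral_femoral_condyle",
}


@dataclass
class ROILabelMap:
    """Integer ROI volume with a label dictionary and voxel size in mm."""

    labels: np.ndarray
    label_names: dict = field(default_factory=lambda: dict(REGION_NAMES))
    voxel_size: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive per axis")
        present = set(np.unique(self.labels)) - {0}
        unknown = present - set(self.label_names)
        if unknown:
            raise ValueError(f"labels not in dictionary: {sorted(unknown)}")

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size)) / 1000.0

    def union_mask(self) -> np.ndarray:
        return np.isin(self.labels, list(self.label_names))


@dataclass
class ShuffleDifference:
    diff: np.ndarray       # signed, signal units
    neighbourhood: str     # "3x3" (in-plane) or "3x3x3"


@dataclass
class VEPResult:
    mask: np.ndarray               # binary enhancing-pannus mask
    volume_ml: dict                # region name -> mL, plus "whole_joint"
    threshold_used: float          # signal units


def _neighbourhood_offsets(neighbourhood: str):
    """Candidate offsets ordered by Euclidean distance then lexicographic.

    Ordering defines the tie-break: argmin over the stacked candidates
    returns the first minimiser, i.e. smallest offset, then lexicographic.
    """
    if neighbourhood == "3x3":
        offs = [(di, dj, 0) for di in (-1, 0, 1) for dj in (-1, 0, 1)]
    elif neighbourhood == "3x3x3":
        offs = [(di, dj, dk) for di in (-1, 0, 1) for dj in (-1, 0, 1)
                for dk in (-1, 0, 1)]
    else:
        raise ValueError("neighbourhood must be '3x3' or '3x3x3'")
    return sorted(offs, key=lambda o: (sum(x * x for x in o), o))


def shuffle_subtract(pre: np.ndarray, post: np.ndarray,
                     neighbourhood: str = "3x3") -> ShuffleDifference:
    """Shuffle-transform subtraction of 3D volumes (post minus pre).

    Output at voxel v is ``post(v) - pre(u*)`` where u* minimises
    |post(v) - pre(u)| over the neighbourhood of v in the pre image
    (ties: smallest spatial offset, then lexicographic order).  The
    in-plane "3x3" neighbourhood (9 candidates, slices = last axis)
    is the default; "3x3x3" searches through-plane too.  The
    neighbourhood is clipped at volume edges.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError(f"dimension mismatch: pre {pre.shape} vs post {post.shape}")
    if pre.ndim == 2:
        pre3, post3 = pre[..., None], post[..., None]
    elif pre.ndim == 3:
        pre3, post3 = pre, post
    else:
        raise ValueError("expected 2-D or 3-D volumes")

    offsets = _neighbourhood_offsets(neighbourhood)
    nx, ny, nz = pre3.shape
    best_abs = np.full(pre3.shape, np.inf)
    best_diff = np.zeros(pre3.shape)
    for di, dj, dk in offsets:
        # pre shifted so that candidate pre(v + offset) aligns with v
        shifted = np.full(pre3.shape, np.nan)
        src = (slice(max(di, 0), nx + min(di, 0)),
               slice(max(dj, 0), ny + min(dj, 0)),
               slice(max(dk, 0), nz + min(dk, 0)))
        dst = (slice(max(-di, 0), nx + min(-di, 0)),
               slice(max(-dj, 0), ny + min(-dj, 0)),
               slice(max(-dk, 0), nz + min(-dk, 0)))
        shifted[dst] = pre3[src]
        diff = post3 - shifted
        a = np.abs(diff)
        take = np.isfinite(a) & (a < best_abs)   # strict: earlier order wins ties
        best_abs[take] = a[take]
        best_diff[take] = diff[take]
    out = best_diff if pre.ndim == 3 else best_diff[..., 0]
    return ShuffleDifference(diff=out, neighbourhood=neighbourhood)


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu threshold of an intensity sample over an ``nbins`` histogram.

    Maximises between-class variance; returns a threshold strictly
    between the two classes.  Constant input is an error.
    """
    values = np.asarray(values, dtype=float).ravel()
    values = values[np.isfinite(values)]
    if np.unique(values).size < 2:
        raise ValueError("Otsu threshold undefined for constant input")
    return float(threshold_otsu(values, nbins=nbins))


def build_vep_mask(diff: ShuffleDifference, roi: ROILabelMap,
                   otsu_within_roi: bool = True) -> VEPResult:
    """Volume-of-enhancing-pannus mask and volumes.

    Threshold: Otsu over the shuffle-difference values sampled *inside*
    the ROI union by default (a phantom's empty background would
    otherwise dominate the histogram); ``otsu_within_roi=False`` samples
    the whole image instead.  Enhancing = diff > threshold;
    VEP = enhancing ∩ ROI.  Volumes are voxel counts × voxel volume,
    per region and whole joint.
    """
    if diff.diff.shape != roi.labels.shape:
        raise ValueError("difference image and ROI label map grids differ")
    union = roi.union_mask()
    if not union.any():
        raise ValueError("empty ROI")
    thr = otsu_threshold(diff.diff[union] if otsu_within_roi else diff.diff)
    vep = (diff.diff > thr) & union
    vv = roi.voxel_volume_ml
    volumes = {name: float(np.count_nonzero(vep & (roi.labels == lab)) * vv)
               for lab, name in roi.label_names.items()}
    volumes["whole_joint"] = float(np.count_nonzero(vep) * vv)
    return VEPResult(mask=vep, volume_ml=volumes, threshold_used=thr)


def extract_median_biomarkers(pk_maps, vep: VEPResult | None, roi: ROILabelMap,
                              subject_id: str = "", visit: str = "",
                              use_manual_mask: bool = False) -> pd.DataFrame:
    """Median biomarker values per synovial ROI and for the whole joint.

    For the semiautomatic arm the median is taken over VEP voxels; with
    ``use_manual_mask=True`` (or ``vep=None``) it is taken over the full
    manual ROI, reproducing the manual-segmentation analysis.  Regions
    with zero eligible voxels are recorded as missing (NaN), not zero.

    Returns a long-format table with columns
    subject, visit, region, biomarker, value, n_voxels.
    """
    if use_manual_mask or vep is None:
        sel = roi.union_mask()
    else:
        if vep.mask.shape != roi.labels.shape:
            raise ValueError("VEP mask and ROI label map grids differ")
        sel = vep.mask
    rows = []
    biomarkers = pk_maps.as_dict() if hasattr(pk_maps, "as_dict") else dict(pk_maps)
    region_masks = {name: sel & (roi.labels == lab)
                    for lab, name in roi.label_names.items()}
    region_masks["whole_joint"] = sel & roi.union_mask()
    for bio, vol in biomarkers.items():
        if vol.shape != roi.labels.shape:
            raise ValueError(f"biomarker map {bio} grid differs from ROI")
        for region, m in region_masks.items():
            vals = vol[m]
            vals = vals[np.isfinite(vals)]
            rows.append({"subject": subject_id, "visit": visit,
                         "region": region, "biomarker": bio,
                         "value": float(np.median(vals)) if vals.size else np.nan,
                         "n_voxels": int(vals.size)})
    return pd.DataFrame(rows)
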