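"""NIfTI-1 and sidecar I/O for subject-visit studies.

Layout per subject-visit directory::

    vfa.nii.gz        4-D (x, y, z, flip angle)
    dynamic.nii.gz    4-D (x, y, z, time)
    pre.nii.gz        3-D last pre-bolus frame
    post.nii.gz       3-D late frame
    roi_labels.nii.gz integer ROI label map
    gt_ktrans.nii.gz  ground-truth Ktrans (synthetic studies only)
    study.json        acquisition metadata, haematocrit, ground-truth scalars
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .synthetic import AcquisitionSpec, SubjectStudy

__all__ = ["write_study", "read_study", "write_nifti", "read_nifti"]

_REQUIRED_META = ["repetition_time", "flip_angles_vfa", "dynamic_flip_angle",
                  "n_phases", "phase_interval", "baseline_frames",
                  "voxel_size", "grid_shape"]


def _affine(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def write_nifti(path, arr: np.ndarray, voxel_size=(1, 1, 1),
                descrip: str = "") -> None:
    img = nib.Nifti1Image(np.asarray(arr), _affine(voxel_size))
    if descrip:
        img.header["descrip"] = descrip.encode()[:79]
    nib.save(img, str(path))


def read_nifti(path) -> np.ndarray:
    return np.asanyarray(nib.load(str(path)).dataobj)


def write_study(study: SubjectStudy, out_dir) -> Path:
    """Write one subject-visit study to ``out_dir`` (created if needed)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vs = study.acq.voxel_size
    # flip-angle axis last so NIfTI sees spatial dims first
    write_nifti(out / "vfa.nii.gz", np.moveaxis(study.vfa, 0, -1), vs,
                "VFA SPGR stack")
    write_nifti(out / "dynamic.nii.gz", study.dynamic, vs, "dynamic SPGR")
    write_nifti(out / "pre.nii.gz", study.pre, vs, "pre-contrast")
    write_nifti(out / "post.nii.gz", study.post, vs, "post-contrast")
    write_nifti(out / "roi_labels.nii.gz", study.roi_labels.astype(np.int16), vs)
    gt = study.ground_truth or {}
    if "ktrans" in gt:
        write_nifti(out / "gt_ktrans.nii.gz", gt["ktrans"].astype(np.float32),
                    vs, "ground-truth Ktrans (min^-1), synthetic")
    meta = {
        "subject_id": study.subject_id,
        "visit": study.visit,
        "haematocrit": study.haematocrit,
        "repetition_time": study.acq.repetition_time,
        "flip_angles_vfa": list(study.acq.flip_angles_vfa),
        "dynamic_flip_angle": study.acq.dynamic_flip_angle,
        "n_phases": study.acq.n_phases,
        "phase_interval": study.acq.phase_interval,
        "baseline_frames": study.acq.baseline_frames,
        "voxel_size": list(vs),
        "grid_shape": list(study.acq.grid_shape),
        "noise_sd": study.acq.noise_sd,
        "noise_model": study.acq.noise_model,
        "relaxivity": study.acq.relaxivity,
        "ground_truth_scalars": {
            k: v for k, v in gt.items() if np.isscalar(v)},
    }
    (out / "study.json").write_text(json.dumps(meta, indent=1))
    return out


def read_study(in_dir) -> SubjectStudy:
    """Load a subject-visit study, validating grids and metadata."""
    d = Path(in_dir)
    meta = json.loads((d / "study.json").read_text())
    for key in _REQUIRED_META:
        if key not in meta:
            raise ValueError(f"sidecar {d / 'study.json'} missing field '{key}'")
    acq = AcquisitionSpec(
        repetition_time=meta["repetition_time"],
        flip_angles_vfa=tuple(meta["flip_angles_vfa"]),
        dynamic_flip_angle=meta["dynamic_flip_angle"],
        n_phases=meta["n_phases"],
        phase_interval=meta["phase_interval"],
        baseline_frames=meta["baseline_frames"],
        voxel_size=tuple(meta["voxel_size"]),
        grid_shape=tuple(meta["grid_shape"]),
        noise_sd=meta.get("noise_sd", 0.0),
        noise_model=meta.get("noise_model", "gaussian"),
        relaxivity=meta.get("relaxivity", 3.5),
    )
    vols = {name: read_nifti(d / f"{name}.nii.gz")
            for name in ("vfa", "dynamic", "pre", "post", "roi_labels")}
    grid = tuple(meta["grid_shape"])
    bad = [f"{name}.nii.gz ({v.shape})" for name, v in vols.items()
           if v.shape[:3] != grid]
    if bad:
        raise ValueError(f"grid mismatch in {d}: " + ", ".join(bad))
    if vols["dynamic"].shape[-1] != acq.n_phases:
        raise ValueError(
            f"dynamic.nii.gz has {vols['dynamic'].shape[-1]} volumes, "
            f"sidecar says n_phases={acq.n_phases}")
    gt = dict(meta.get("ground_truth_scalars", {}))
    gtk = d / "gt_ktrans.nii.gz"
    if gtk.exists():
        gt["ktrans"] = read_nifti(gtk)
    return SubjectStudy(
        subject_id=meta.get("subject_id", d.parent.name),
        visit=meta.get("visit", d.name), acq=acq,
        vfa=np.moveaxis(vols["vfa"], -1, 0), dynamic=vols["dynamic"],
        pre=vols["pre"], post=vols["post"],
        roi_labels=vols["roi_labels"].astype(np.int16),
        haematocrit=meta.get("haematocrit", 0.42), ground_truth=gt)
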