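"""End-to-end orchestration: simulate → T1 map → concentration → fit →
segment → extract → stats.

Two layers are provided.  ``analyze_study`` / ``cohort_statistics`` work
on in-memory objects and are what the tests and examples use.  The
staged, disk-based pipeline (``run_pipeline`` and the per-stage
functions) reads and writes NIfTI/CSV/JSON under an output directory,
records a run manifest with config hash and per-file checksums, and can
resume: a stage whose outputs already exist for the same config hash is
skipped.  All randomness derives from the single configured seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aif import AIFParameters, haematocrit_correct, population_aif_blood
from .io import read_study, write_nifti, write_study
from .pk import PKMaps, fit_volume
from .relaxometry import fit_vfa_t1, signal_to_concentration
from .segmentation import (ROILabelMap, build_vep_mask,
                           extract_median_biomarkers, shuffle_subtract)
from .stats import (repeatability_summary, responsiveness_count,
                    standardized_mean_difference)
from .synthetic import (AcquisitionSpec, CohortSpec, PhantomSpec,
                        SubjectStudy, generate_cohort, supersampled_time_grid)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "analyze_study",
           "cohort_statistics", "load_config"]

log = logging.getLogger("synodce")

STAGES = ("simulate", "analyze", "stats")


@dataclass
class PipelineConfig:
    """Validated configuration for a full run.

    ``analyze`` covers the per-study chain (t1map → concentration → fit →
    segment → extract); its intermediate volumes are all written, so the
    CLI exposes them as one stage with per-study outputs.
    """

    out_dir: str = "synodce_out"
    seed: int = 0
    stages: tuple = STAGES
    cohort: CohortSpec = field(default_factory=CohortSpec)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    aif: AIFParameters | None = None
    supersample: int = 10
    fit_n_polish: int = 2
    fit_method: str = "varpro"   # variable-projection engine; "multistart" available
    shuffle_neighbourhood: str = "3x3"
    stats_alpha: float = 0.05

    def config_hash(self) -> str:
        def enc(o):
            if isinstance(o, tuple):
                return list(o)
            return str(o)
        payload = {k: v for k, v in asdict(self).items() if k != "stages"}
        return hashlib.sha256(
            json.dumps(payload, default=enc, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    started: float
    stages: dict = field(default_factory=dict)   # stage -> {files: {path: sha}, ...}

    def save(self, path: Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def load_config(path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file.

    Every paper-gap default (phase interval, baseline frames, noise
    model, haematocrit, AIF constants …) is an explicit named key, so
    assumptions are visible and overridable.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kw = {}
    for key, cls in (("cohort", CohortSpec), ("phantom", PhantomSpec),
                     ("acquisition", AcquisitionSpec), ("aif", AIFParameters)):
        if key in raw:
            section = raw.pop(key)
            for k, v in section.items():
                if isinstance(v, list):
                    section[k] = tuple(tuple(x) if isinstance(x, list) else x
                                       for x in v)
            kw[key] = cls(**section)
    unknown = set(raw) - {f.name for f in
                          PipelineConfig.__dataclass_fields__.values()}
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    return PipelineConfig(**raw, **kw)


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


# ---------------------------------------------------------------- analysis

def analyze_study(study: SubjectStudy, supersample: int = 10,
                  n_polish: int = 2, neighbourhood: str = "3x3",
                  aif_params: AIFParameters | None = None,
                  fit_method: str = "varpro") -> dict:
    """Run the full per-study analysis chain in memory.

    Returns a dict with the T1 map, concentration volume, fitted
    :class:`PKMaps`, the VEP segmentation result and the long-format
    biomarker table (semiautomatic and manual arms, plus the VEP-volume
    biomarker rows).
    """
    acq = study.acq
    # keep only the synovial labels; bone/fluid/background are not ROIs
    syn_labels = np.where(np.isin(study.roi_labels, list(range(1, 8))),
                          study.roi_labels, 0)
    roi = ROILabelMap(labels=syn_labels, voxel_size=acq.voxel_size)
    union = roi.union_mask()

    t1map = fit_vfa_t1(study.vfa, acq.flip_angles_vfa, acq.repetition_time)
    t10 = np.where(t1map.fit_ok, t1map.t1, np.nan)

    conc = signal_to_concentration(
        study.dynamic, acq.baseline_frames, t10,
        tr=acq.repetition_time, flip_angle=acq.dynamic_flip_angle,
        r1=acq.relaxivity)

    if aif_params is None:
        aif_params = AIFParameters(bolus_arrival_offset=acq.bolus_arrival_min)
    t_fine, obs_idx = supersampled_time_grid(acq, supersample)
    cp_fine = haematocrit_correct(population_aif_blood(t_fine, aif_params),
                                  study.haematocrit)

    pk_maps = fit_volume(conc.conc, cp_fine, t_fine, union,
                         baseline_frames=acq.baseline_frames,
                         n_polish=n_polish, obs_idx=obs_idx,
                         method=fit_method)
    n_implausible = int((~pk_maps.plausible & union).sum())
    log.info("fit %s/%s: %d voxels, %d flagged implausible",
             study.subject_id, study.visit, int(union.sum()), n_implausible)

    diff = shuffle_subtract(study.pre, study.post, neighbourhood)
    vep = build_vep_mask(diff, roi)

    semi = extract_median_biomarkers(pk_maps, vep, roi,
                                     subject_id=study.subject_id,
                                     visit=study.visit)
    semi["segmentation_method"] = "semiauto"
    manual = extract_median_biomarkers(pk_maps, None, roi,
                                       subject_id=study.subject_id,
                                       visit=study.visit,
                                       use_manual_mask=True)
    manual["segmentation_method"] = "manual"

    vol_rows = []
    for arm, vols in (("semiauto", vep.volume_ml),
                      ("manual", {**{n: float(np.count_nonzero(
                          roi.labels == lab) * roi.voxel_volume_ml)
                          for lab, n in roi.label_names.items()},
                          "whole_joint": float(np.count_nonzero(union)
                                               * roi.voxel_volume_ml)})):
        for region, ml in vols.items():
            vol_rows.append({"subject": study.subject_id, "visit": study.visit,
                             "region": region, "biomarker": "vep_volume_ml",
                             "value": ml, "n_voxels": np.nan,
                             "segmentation_method": arm})
    table = pd.concat([semi, manual, pd.DataFrame(vol_rows)],
                      ignore_index=True)
    return {"t1map": t1map, "conc": conc, "pk_maps": pk_maps, "vep": vep,
            "roi": roi, "biomarkers": table}


def cohort_statistics(biomarkers: pd.DataFrame, metadata: pd.DataFrame,
                      alpha: float = 0.05,
                      biomarker_names=("ktrans", "iauc60", "vep_volume_ml"),
                      region: str = "whole_joint") -> dict:
    """Repeatability, discrimination and responsiveness summaries.

    ``biomarkers`` is the long per-study table; ``metadata`` maps
    subject_id to group.  Test-retest uses baseline vs month1; group
    comparison uses baseline; responsiveness counts 6-month changes
    exceeding the SDD (per segmentation arm and biomarker).
    """
    group_of = dict(metadata.drop_duplicates("subject_id")
                    [["subject_id", "group"]].to_numpy())
    wj = biomarkers[biomarkers["region"] == region]
    wide = wj.pivot_table(index=["subject", "segmentation_method", "biomarker"],
                          columns="visit", values="value").reset_index()
    wide["group"] = wide["subject"].map(group_of)

    rep_rows, grp_rows, resp_rows = [], [], []
    for arm in sorted(wide["segmentation_method"].unique()):
        for bio in biomarker_names:
            sel = wide[(wide["segmentation_method"] == arm)
                       & (wide["biomarker"] == bio)]
            m = None
            if {"baseline", "month1"} <= set(sel.columns):
                tr = sel.dropna(subset=["baseline", "month1"])
                rec = pd.DataFrame({
                    "subject_id": tr["subject"], "group": tr["group"],
                    "value_visit1": tr["baseline"],
                    "value_visit2": tr["month1"]})
                oa_base = tr.loc[tr["group"] == "OA", "baseline"].to_numpy()
                try:
                    m = repeatability_summary(rec, oa_values=oa_base,
                                              alpha=alpha)
                except ValueError as err:
                    log.warning("repeatability skipped for %s/%s: %s",
                                bio, arm, err)
                    m = None
                if m is not None:
                    rep_rows.append({"biomarker": bio,
                                     "segmentation_method": arm,
                                     **{k: getattr(m, k) for k in
                                        ("sigma_b2", "sigma_w2", "icc",
                                         "icc_lo", "icc_hi", "scale",
                                         "wsd_or_wcv", "sdd", "oa_mean",
                                         "sdd_pct_of_mean")}})
            base = sel.dropna(subset=["baseline"])
            oa = base.loc[base["group"] == "OA", "baseline"].to_numpy()
            hv = base.loc[base["group"] == "HV", "baseline"].to_numpy()
            if oa.size >= 2 and hv.size >= 2:
                try:
                    g = standardized_mean_difference(oa, hv)
                except ValueError as err:   # e.g. degenerate zero-variance data
                    log.warning("group comparison skipped for %s/%s: %s",
                                bio, arm, err)
                else:
                    grp_rows.append({"biomarker": bio,
                                     "segmentation_method": arm,
                                     "mean_oa": g.mean_oa, "mean_hv": g.mean_hv,
                                     "pooled_sd": g.pooled_sd, "smd": g.smd})
            if m is not None and "month6" in sel.columns:
                six = sel.dropna(subset=["baseline", "month6"])
                for grp in ("OA", "HV"):
                    gsel = six[six["group"] == grp]
                    if not len(gsel):
                        continue
                    deltas = (gsel["month6"] - gsel["baseline"]).to_numpy()
                    cnt = responsiveness_count(
                        deltas, m.sdd, scale=m.scale,
                        baselines=gsel["baseline"].to_numpy())
                    resp_rows.append({"biomarker": bio,
                                      "segmentation_method": arm,
                                      "group": grp, "n": len(gsel),
                                      "n_exceeding_sdd": cnt,
                                      "sdd": m.sdd, "scale": m.scale})
    return {"repeatability": pd.DataFrame(rep_rows),
            "group_comparison": pd.DataFrame(grp_rows),
            "responsiveness": pd.DataFrame(resp_rows)}


# ---------------------------------------------------------------- stages

def _stage_done(out: Path, name: str, cfg_hash: str) -> bool:
    m = out / "manifest.json"
    if not m.exists():
        return False
    man = json.loads(m.read_text())
    return man.get("config_hash") == cfg_hash and name in man.get("stages", {})


def stage_simulate(config: PipelineConfig, out: Path) -> pd.DataFrame:
    cohort = replace(config.cohort, seed=config.seed)
    img_dir = out / "images"

    def writer(study: SubjectStudy):
        write_study(study, img_dir / study.subject_id / study.visit)

    metadata, _ = generate_cohort(cohort, config.phantom, config.acquisition,
                                  images=True, writer=writer)
    metadata.to_csv(out / "cohort.csv", index=False)
    return metadata


def stage_analyze(config: PipelineConfig, out: Path) -> pd.DataFrame:
    metadata = pd.read_csv(out / "cohort.csv")
    tables = []
    for _, row in metadata.iterrows():
        sdir = out / "images" / row["subject_id"] / row["visit"]
        study = read_study(sdir)
        res = analyze_study(study, supersample=config.supersample,
                            n_polish=config.fit_n_polish,
                            neighbourhood=config.shuffle_neighbourhood,
                            aif_params=config.aif,
                            fit_method=config.fit_method)
        vs = study.acq.voxel_size
        write_nifti(sdir / "t1_map.nii.gz", res["t1map"].t1, vs,
                    "native T1 (s)")
        for name in ("ktrans", "ve", "vp", "iauc60"):
            write_nifti(sdir / f"pk_{name}.nii.gz",
                        getattr(res["pk_maps"], name).astype(np.float32), vs)
        write_nifti(sdir / "vep_mask.nii.gz",
                    res["vep"].mask.astype(np.uint8), vs)
        pd.DataFrame([{"region": k, "volume_ml": v}
                      for k, v in res["vep"].volume_ml.items()]
                     ).to_csv(sdir / "vep_volumes.csv", index=False)
        tables.append(res["biomarkers"])
    biomarkers = pd.concat(tables, ignore_index=True)
    biomarkers.to_csv(out / "biomarkers.csv", index=False)
    return biomarkers


def stage_stats(config: PipelineConfig, out: Path) -> dict:
    biomarkers = pd.read_csv(out / "biomarkers.csv")
    metadata = pd.read_csv(out / "cohort.csv")
    results = cohort_statistics(biomarkers, metadata,
                                alpha=config.stats_alpha)
    for name, df in results.items():
        df.to_csv(out / f"{name}.csv", index=False)
    return results


_STAGE_FUNCS = {"simulate": stage_simulate, "analyze": stage_analyze,
                "stats": stage_stats}
_STAGE_OUTPUTS = {
    "simulate": ["cohort.csv"],
    "analyze": ["biomarkers.csv"],
    "stats": ["repeatability.csv", "group_comparison.csv",
              "responsiveness.csv"],
}
_STAGE_NEEDS = {"simulate": [], "analyze": ["cohort.csv"],
                "stats": ["biomarkers.csv", "cohort.csv"]}


def run_pipeline(config: PipelineConfig, resume: bool = True) -> RunManifest:
    """Execute the configured stages in dependency order.

    Raises if an enabled stage's upstream output is missing (naming the
    stage to run first); with ``resume`` a stage already completed for
    the identical config hash is skipped.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    (out / "config_used.yaml").write_text(
        yaml.safe_dump(json.loads(json.dumps(asdict(config), default=str))))

    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        prev = json.loads(manifest_path.read_text())
        manifest = RunManifest(config_hash=cfg_hash, version=__version__,
                               started=time.time(),
                               stages=prev.get("stages", {})
                               if prev.get("config_hash") == cfg_hash else {})
    else:
        manifest = RunManifest(config_hash=cfg_hash, version=__version__,
                               started=time.time())

    producer = {f: s for s, files in _STAGE_OUTPUTS.items() for f in files}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        for need in _STAGE_NEEDS[stage]:
            if not (out / need).exists():
                raise FileNotFoundError(
                    f"stage '{stage}' needs {need}; run stage "
                    f"'{producer[need]}' first")
        if resume and stage in manifest.stages and _stage_done(out, stage,
                                                               cfg_hash):
            log.info("stage %s: up to date, skipping", stage)
            continue
        t0 = time.time()
        log.info("stage %s: running", stage)
        _STAGE_FUNCS[stage](config, out)
        manifest.stages[stage] = {
            "seconds": round(time.time() - t0, 2),
            "files": {f: _sha(out / f) for f in _STAGE_OUTPUTS[stage]
                      if (out / f).exists()},
        }
        manifest.save(manifest_path)
    manifest.save(manifest_path)
    return manifest
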