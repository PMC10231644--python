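"""Atlas-overlap summaries and end-to-end pipeline orchestration."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import disconnectome as dcn
from . import lesion_prep, lnsm, network_damage, svr_mapping
from .io_model import (
    AnalysisConfig,
    CohortTable,
    LesionMask,
    StatMap,
    read_cohort_table,
    read_mask_volume,
    write_stat_volume,
)

logger = logging.getLogger("lsmpipe")


def atlas_overlap(cluster_voxels: np.ndarray, atlas: StatMap, label_names: dict = None) -> pd.DataFrame:
    """Per-label percentage composition of a cluster against an integer-labeled
    atlas volume; includes the unlabeled remainder.  Fractions sum to 100%."""
    vox = np.asarray(cluster_voxels)
    if vox.size == 0:
        raise ValueError("empty cluster")
    labels = atlas.grid[vox[:, 0], vox[:, 1], vox[:, 2]].astype(int)
    n = len(labels)
    rows = []
    for lab in np.unique(labels):
        frac = 100.0 * int((labels == lab).sum()) / n
        if lab == 0:
            name = "unlabeled"
        else:
            name = (label_names or {}).get(int(lab), f"label_{lab}")
        rows.append({"label": name, "percent": frac})
    df = pd.DataFrame(rows).sort_values("percent", ascending=False).reset_index(drop=True)
    return df


def _cluster_table(clusters: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster_id": c["cluster_id"],
                "size_vox": c["size_vox"],
                "size_ml": round(c["size_ml"], 4),
                "p_fwe": c["p_fwe"],
                "significant": c["significant"],
                "peak_x": c["peak_voxel"][0],
                "peak_y": c["peak_voxel"][1],
                "peak_z": c["peak_voxel"][2],
            }
            for c in clusters
        ],
        columns=["cluster_id", "size_vox", "size_ml", "p_fwe", "significant",
                 "peak_x", "peak_y", "peak_z"],
    )


def load_dataset(dataset_dir, config: AnalysisConfig):
    """Read a dataset directory in the `simulate` layout."""
    d = Path(dataset_dir)
    cohort_path = d / "cohort.csv"
    if not cohort_path.exists():
        raise FileNotFoundError(f"missing cohort file: {cohort_path}")
    cohort = read_cohort_table(cohort_path, cutoff=config.hads_cutoff)
    lesion_dir = d / "lesions"
    masks = [read_mask_volume(p) for p in sorted(lesion_dir.glob("*.nii*"))]
    if not masks:
        raise FileNotFoundError(f"no lesion masks in {lesion_dir}")
    ids = set(cohort.patient_ids)
    masks = [m for m in masks if m.patient_id in ids]
    order = {pid: i for i, pid in enumerate(cohort.patient_ids)}
    masks.sort(key=lambda m: order[m.patient_id])
    return cohort, masks


def load_connectome(dataset_dir):
    import nibabel as nib

    d = Path(dataset_dir)
    cdir = d / "connectome"
    runs = []
    gm = wm = csf = None
    for name in ("gm_prob", "wm_prob", "csf_prob"):
        p = d / f"{name}.nii.gz"
        if p.exists():
            img = nib.load(str(p))
            sm = StatMap(np.asanyarray(img.dataobj), np.ones(img.shape[:3]), "percent", img.affine)
            if name == "gm_prob":
                gm = sm
            elif name == "wm_prob":
                wm = sm
            else:
                csf = sm
    for bold in sorted(cdir.glob("*_bold.nii.gz")):
        stem = bold.name.replace("_bold.nii.gz", "")
        subject_id, run_id = stem.rsplit("_", 1)
        img = nib.load(str(bold))
        motion = np.loadtxt(cdir / f"{stem}_motion.txt")
        tr = float((cdir / f"{stem}_tr.txt").read_text())
        runs.append(
            lnsm.NormativeRun(
                subject_id=subject_id, run_id=run_id,
                data=np.asanyarray(img.dataobj).astype(np.float64),
                tr_s=tr, motion=motion, gm_prob=gm, wm_prob=wm, csf_prob=csf,
            )
        )
    if not runs:
        raise FileNotFoundError(f"no normative runs in {cdir}")
    return runs, gm


def _run_svr_stage(masks, cohort, config, out, stage_name, feature_masks=None,
                   covariates=None):
    """Shared SVR-LSM / SVR-SDSM driver.  `feature_masks` defaults to the
    lesions themselves (LSM); for SDSM pass the binary disconnectome masks."""
    out.mkdir(parents=True, exist_ok=True)
    inc = cohort.included()
    by_id = {m.patient_id: m for m in masks}
    feat_by_id = by_id if feature_masks is None else {m.patient_id: m for m in feature_masks}
    ids = [pid for pid in inc["patient_id"] if pid in feat_by_id]
    feats = [feat_by_id[pid] for pid in ids]
    coverage = lesion_prep.build_coverage_mask(feats, config.min_lesion_overlap)
    excluded = dict(coverage.excluded_ids)
    kept = [pid for pid in ids if pid not in excluded]
    sub = inc.set_index("patient_id").loc[kept]
    vols = np.array([lesion_prep.lesion_volume_ml(by_id[pid]) for pid in kept])
    cov_arr = None
    if covariates:
        cov_arr = sub[list(covariates)].to_numpy(dtype=float)
    fm, y = svr_mapping.prepare_svr_inputs(
        [feat_by_id[pid] for pid in kept], sub["hads_d"].to_numpy(float),
        coverage, vols, covariates=cov_arr, affine=masks[0].affine,
    )
    result = svr_mapping.permutation_cluster_inference(fm, y, config)
    write_stat_volume(result.beta_map, out / "beta.nii.gz", config)
    write_stat_volume(result.z_map, out / "z.nii.gz", config)
    write_stat_volume(result.voxel_p_map, out / "voxel_p.nii.gz", config)
    _cluster_table(result.clusters).to_csv(out / "clusters.csv", index=False)
    summary = {
        "stage": stage_name,
        "n_input": len(ids),
        "n_analyzed": len(kept),
        "n_excluded": len(excluded),
        "prediction_r": result.prediction_r,
        "prediction_p": result.prediction_p,
        "n_permutations": result.n_permutations,
        "n_significant_clusters": len(result.significant_clusters),
        "config": config.to_dict(),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return result, [(pid, reason) for pid, reason in coverage.excluded_ids]


def run_pipeline(config: AnalysisConfig, dataset_dir, which: str = "all", out_dir=None,
                 covariates=None):
    """Execute the requested stages in dependency order with a shared
    exclusion log; writes a JSON+CSV+NIfTI bundle plus a markdown summary."""
    if which not in ("svr-lsm", "svr-sdsm", "lnsm", "nds", "all"):
        raise ValueError(f"unknown stage {which!r}")
    dataset_dir = Path(dataset_dir)
    out = Path(out_dir) if out_dir else dataset_dir / "results"
    out.mkdir(parents=True, exist_ok=True)
    cohort, masks = load_dataset(dataset_dir, config)
    exclusions = {}
    bundle = {"config": config.to_dict(), "stages": {}}

    if which in ("svr-lsm", "all"):
        res, exc = _run_svr_stage(masks, cohort, config, out / "svr-lsm", "svr-lsm",
                                  covariates=covariates)
        exclusions["svr-lsm"] = exc
        bundle["stages"]["svr-lsm"] = json.loads((out / "svr-lsm" / "summary.json").read_text())

    if which in ("svr-sdsm", "all"):
        tdir = dataset_dir / "tractograms"
        tractograms = [dcn.read_tractogram(p) for p in sorted(tdir.glob("*.txt"))]
        if not tractograms:
            raise FileNotFoundError(f"no tractograms in {tdir}")
        binmasks, exc = [], []
        for m in masks:
            dm = dcn.patient_disconnectome(m, tractograms, config.disconnection_cutoff_percent)
            if dm.binary.grid.sum() == 0:
                exc.append((m.patient_id, "empty disconnectome"))
                continue
            binmasks.append(LesionMask(m.patient_id, dm.binary.grid.astype(np.uint8), m.affine))
        res, exc2 = _run_svr_stage(masks, cohort, config, out / "svr-sdsm", "svr-sdsm",
                                   feature_masks=binmasks, covariates=covariates)
        exclusions["svr-sdsm"] = exc + exc2
        bundle["stages"]["svr-sdsm"] = json.loads((out / "svr-sdsm" / "summary.json").read_text())

    need_connectome = which in ("lnsm", "nds", "all")
    if need_connectome:
        runs, gm = load_connectome(dataset_dir)
        cleaned = [lnsm.preprocess_run(r, config) for r in runs]

    if which in ("lnsm", "all"):
        stage_out = out / "lnsm"
        stage_out.mkdir(parents=True, exist_ok=True)
        inc = cohort.included()
        by_id = {m.patient_id: m for m in masks}
        nmaps, kept, exc = [], [], []
        for pid in inc["patient_id"]:
            m = by_id[pid]
            roi, excluded = lesion_prep.gray_matter_roi(m, gm, config.gm_probability_threshold)
            if excluded:
                exc.append((pid, "pure white matter lesion"))
                continue
            nm = lnsm.lesion_network_map(m, cleaned, config, affine=m.affine)
            write_stat_volume(nm.zmap, stage_out / f"{pid}_networkmap.nii.gz")
            nmaps.append(nm)
            kept.append(pid)
        y = cohort.df.set_index("patient_id").loc[kept, "hads_d"].to_numpy(float)
        tmap, clusters = lnsm.lnsm_glm_inference(nmaps, y, config, gm_prob=gm)
        write_stat_volume(tmap, stage_out / "group_t.nii.gz", config)
        _cluster_table(clusters).to_csv(stage_out / "clusters.csv", index=False)
        exclusions["lnsm"] = exc
        bundle["stages"]["lnsm"] = {
            "stage": "lnsm", "n_input": len(inc), "n_analyzed": len(kept),
            "n_excluded": len(exc),
            "n_significant_clusters": sum(c["significant"] for c in clusters),
        }

    if which in ("nds", "all"):
        stage_out = out / "nds"
        stage_out.mkdir(parents=True, exist_ok=True)
        center = masks[0].affine[:3, :3] @ (np.asarray(masks[0].grid.shape) / 2.0) \
            + masks[0].affine[:3, 3]
        circuit = network_damage.circuit_tmap(
            cleaned, center, config.sphere_diameter_mm, config, affine=masks[0].affine
        )
        write_stat_volume(circuit.tmap, stage_out / "circuit_t.nii.gz", config)
        inc = cohort.included()
        by_id = {m.patient_id: m for m in masks}
        lesions = [by_id[pid] for pid in inc["patient_id"]]
        vols = np.array([lesion_prep.lesion_volume_ml(m) for m in lesions])
        hads = inc["hads_d"].to_numpy(float)
        n_perm = min(config.n_permutations * 10, 100000)
        mode = "group" if len(np.unique(hads > config.hads_cutoff)) == 2 else "continuous"
        if mode == "continuous":
            logger.warning("nds: no patients above cutoff %d; using continuous statistic",
                           config.hads_cutoff)
        res = network_damage.nds_analysis(
            lesions, circuit, hads, vols, cutoff=config.hads_cutoff, n_perm=n_perm,
            seed=config.rng_seed, mode=mode, positive_only=config.nds_positive_only,
        )
        pd.DataFrame({
            "patient_id": res.patient_ids, "raw_nds": res.raw_scores,
            "residual_nds": res.residual_scores, "group": res.group_labels,
        }).to_csv(stage_out / "scores.csv", index=False)
        bundle["stages"]["nds"] = {
            "stage": "nds", "observed_stat": res.observed_stat,
            "p_value": res.p_value, "n_permutations": res.n_permutations,
            "n_analyzed": len(lesions),
        }
        (stage_out / "summary.json").write_text(json.dumps(bundle["stages"]["nds"], indent=2))

    lesion_prep.exclusion_report(exclusions).to_csv(out / "exclusions.csv", index=False)
    (out / "bundle.json").write_text(json.dumps(bundle, indent=2))
    _write_markdown_summary(bundle, out / "summary.md")
    return bundle


def _write_markdown_summary(bundle: dict, path) -> None:
    lines = ["# Pipeline summary", ""]
    cfg = bundle["config"]
    lines.append(f"- seed: {cfg['rng_seed']}, permutations: {cfg['n_permutations']}")
    lines.append(f"- voxel thresholds: SVR p<{cfg['svr_voxel_p']} (one-tailed), "
                 f"GLM p<{cfg['lnsm_voxel_p']} (two-tailed); cluster FWE alpha "
                 f"{cfg['cluster_fwe_alpha']}")
    lines.append(f"- lesion-overlap minimum: {cfg['min_lesion_overlap']} patients; "
                 f"disconnection cutoff: {cfg['disconnection_cutoff_percent']}%")
    lines.append("")
    for name, s in bundle["stages"].items():
        lines.append(f"## {name}")
        for k, v in s.items():
            if k in ("config", "stage"):
                continue
            lines.append(f"- {k}: {v}")
        lines.append("")
    Path(path).write_text("\n".join(lines))
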