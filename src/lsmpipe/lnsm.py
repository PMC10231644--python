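"""Lesion network-symptom mapping on a normative functional connectome.

Each run is smoothed, nuisance-regressed (motion, WM, CSF, global signal),
band-pass filtered and motion-censored; each patient's gray-matter lesion ROI
seeds a Fisher-z connectivity map per run, and the maps are averaged over all
subjects and runs.  Group inference is a mass-univariate GLM of the score on
map values with permutation cluster-level FWE correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal, stats

from .io_model import AnalysisConfig, LesionMask, StatMap
from .lesion_prep import gray_matter_roi
from .svr_mapping import _max_cluster_size, cluster_fwe_p, label_clusters

logger = logging.getLogger("lsmpipe")

_R_CLIP = 1.0 - 1e-7


@dataclass
class NormativeRun:
    """One normative subject/run: 4-D data, motion trace and tissue maps."""

    subject_id: str
    run_id: str
    data: np.ndarray          # (x, y, z, t)
    tr_s: float
    motion: np.ndarray        # (t, 6): translations mm, rotations rad
    gm_prob: StatMap = None
    wm_prob: StatMap = None
    csf_prob: StatMap = None

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D")
        t = self.data.shape[3]
        if t <= 20:
            raise ValueError("time axis length must be > 20")
        if self.motion.shape != (t, 6):
            raise ValueError(f"motion must be (t, 6) = ({t}, 6), got {self.motion.shape}")


@dataclass
class CleanedRun:
    """Preprocessed run: censored data plus the kept-frame index."""

    subject_id: str
    run_id: str
    data: np.ndarray
    tr_s: float
    kept_frames: np.ndarray
    gm_prob: StatMap = None
    steps: tuple = ()


@dataclass
class LesionNetworkMap:
    patient_id: str
    zmap: StatMap
    n_maps_averaged: int


def framewise_displacement(motion: np.ndarray, rotation_radius_mm: float = 50.0) -> np.ndarray:
    """Power-convention FD: sum of absolute backward differences of the six
    parameters, rotations converted to mm on a 50 mm sphere.  First frame = 0."""
    motion = np.asarray(motion, dtype=float)
    diffs = np.abs(np.diff(motion, axis=0))
    fd = diffs[:, :3].sum(axis=1) + rotation_radius_mm * diffs[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def _smooth(data: np.ndarray, fwhm_mm: float, voxel_mm: np.ndarray) -> np.ndarray:
    sigma_vox = (fwhm_mm / np.sqrt(8 * np.log(2))) / np.asarray(voxel_mm)
    return ndimage.gaussian_filter(data, sigma=tuple(sigma_vox) + (0.0,))


def preprocess_run(
    run: NormativeRun,
    config: AnalysisConfig,
    skip: tuple = (),
) -> CleanedRun:
    """Smoothing -> nuisance regression -> band-pass -> motion censoring.

    Nuisance regressors: intercept, 6 motion parameters, mean WM signal, mean
    CSF signal, global mean.  Band-pass is a zero-phase 2nd-order Butterworth.
    Frames with FD > config.fd_threshold_mm are dropped after filtering.
    Steps named in `skip` ({'smooth','nuisance','bandpass','censor'}) are
    bypassed; the applied order is recorded on the result.
    """
    data = np.asarray(run.data, dtype=np.float64)
    voxel_mm = (run.gm_prob.voxel_size_mm if run.gm_prob is not None
                else np.ones(3) * 2.0)
    steps = []
    if "smooth" not in skip:
        data = _smooth(data, config.smoothing_fwhm_mm, voxel_mm)
        steps.append("smooth")

    t = data.shape[3]
    flat = data.reshape(-1, t)
    if "nuisance" not in skip:
        regs = [np.ones(t), *np.asarray(run.motion, dtype=float).T]
        for prob in (run.wm_prob, run.csf_prob):
            if prob is not None:
                sel = prob.grid.reshape(-1) >= 0.5
                if sel.any():
                    regs.append(flat[sel].mean(axis=0))
        regs.append(flat.mean(axis=0))  # global signal
        X = np.column_stack(regs)
        # pinv-based projection tolerates rank-deficient designs (e.g. zero motion)
        flat = flat - (flat @ np.linalg.pinv(X).T) @ X.T
        steps.append("nuisance")

    if "bandpass" not in skip:
        nyq = 0.5 / run.tr_s
        lo, hi = config.bandpass_hz
        b, a = signal.butter(2, [lo / nyq, min(hi / nyq, 0.999)], btype="band")
        flat = signal.filtfilt(b, a, flat, axis=1)
        steps.append("bandpass")

    kept = np.arange(t)
    if "censor" not in skip:
        fd = framewise_displacement(run.motion)
        kept = np.flatnonzero(fd <= config.fd_threshold_mm)
        if kept.size == 0:
            raise ValueError("run unusable: all frames censored")
        flat = flat[:, kept]
        steps.append("censor")

    cleaned = flat.reshape(data.shape[:3] + (kept.size,))
    return CleanedRun(
        subject_id=run.subject_id, run_id=run.run_id, data=cleaned,
        tr_s=run.tr_s, kept_frames=kept, gm_prob=run.gm_prob, steps=tuple(steps),
    )


def roi_eigenvariate(cleaned: np.ndarray, roi: np.ndarray) -> np.ndarray:
    """First eigenvariate of the (time x roi-voxel) matrix: dominant left
    singular vector, unit variance, sign aligned with the ROI mean series."""
    roi = np.asarray(roi).astype(bool)
    if not roi.any():
        raise ValueError("empty ROI")
    M = cleaned[roi].T  # (time, n_roi)
    u, s, _ = np.linalg.svd(M - M.mean(axis=0), full_matrices=False)
    ev = u[:, 0]
    mean_ts = M.mean(axis=1)
    if np.dot(ev, mean_ts - mean_ts.mean()) < 0:
        ev = -ev
    sd = ev.std()
    return ev / sd if sd > 0 else ev


def seed_connectivity_map(cleaned: np.ndarray, seed: np.ndarray, affine: np.ndarray,
                          mask: np.ndarray = None) -> StatMap:
    """Fisher-z map of the Pearson correlation between the seed series and
    every voxel series; zero-variance voxels map to z=0 (logged)."""
    seed = np.asarray(seed, dtype=np.float64)
    if cleaned.shape[3] != seed.size:
        raise ValueError("seed length must equal kept-frame count")
    s = seed - seed.mean()
    s_norm = np.sqrt(s @ s)
    if s_norm == 0:
        raise ValueError("constant seed")
    flat = cleaned.reshape(-1, seed.size)
    flat = flat - flat.mean(axis=1, keepdims=True)
    v_norm = np.sqrt((flat**2).sum(axis=1))
    dead = v_norm == 0
    if dead.any():
        logger.info("seed map: %d zero-variance voxels set to z=0", int(dead.sum()))
    v_norm[dead] = 1.0
    r = (flat @ s) / (v_norm * s_norm)
    r[dead] = 0.0
    z = np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP)).reshape(cleaned.shape[:3])
    if mask is None:
        mask = np.ones(z.shape, dtype=np.uint8)
    return StatMap(z.astype(np.float32), mask, "z", affine)


def lesion_network_map(
    patient: LesionMask,
    runs: list,
    config: AnalysisConfig,
    affine: np.ndarray = None,
) -> LesionNetworkMap:
    """Average Fisher-z seed map over all subject/run maps, seeding from the
    gray-matter portion of the lesion.  `runs` may be NormativeRun (then
    preprocessed on the fly) or CleanedRun objects."""
    affine = patient.affine if affine is None else affine
    zmaps = []
    for run in runs:
        if isinstance(run, NormativeRun):
            run = preprocess_run(run, config)
        roi, excluded = gray_matter_roi(
            patient,
            run.gm_prob
            if run.gm_prob is not None
            else StatMap(np.ones(patient.grid.shape), np.ones(patient.grid.shape),
                         "percent", affine),
            config.gm_probability_threshold,
        )
        if excluded:
            raise ValueError(f"patient {patient.patient_id}: pure white matter lesion")
        ev = roi_eigenvariate(run.data, roi.grid)
        zmaps.append(seed_connectivity_map(run.data, ev, affine).grid.astype(np.float64))
    mean_z = np.mean(zmaps, axis=0)
    return LesionNetworkMap(
        patient_id=patient.patient_id,
        zmap=StatMap(mean_z, np.ones(mean_z.shape, dtype=np.uint8), "z", affine),
        n_maps_averaged=len(zmaps),
    )


def _glm_t(maps_2d: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-voxel slope t of `y ~ 1 + map_value`, vectorized via correlations."""
    n = y.size
    yc = y - y.mean()
    mc = maps_2d - maps_2d.mean(axis=0)
    sy = np.sqrt(yc @ yc)
    sm = np.sqrt((mc**2).sum(axis=0))
    r = (mc.T @ yc) / (sm * sy)
    r = np.clip(r, -_R_CLIP, _R_CLIP)
    return r * np.sqrt((n - 2) / (1.0 - r**2))


def lnsm_glm_inference(
    maps: list,
    behavior: np.ndarray,
    config: AnalysisConfig,
    gm_prob: StatMap = None,
    region_mask: np.ndarray = None,
    n_permutations: int = None,
):
    """Mass-univariate GLM with permutation cluster-level FWE.

    Voxelwise two-tailed parametric p < config.lnsm_voxel_p forms clusters;
    permuting behavior and recording the maximum suprathreshold cluster size
    yields p_fwe = (1 + #{perm max >= observed size}) / (P + 1).  The analysis
    is restricted to gm_prob >= threshold and the optional region mask;
    zero-variance voxels are dropped and logged.

    Returns (t StatMap, clusters list).
    """
    if len(maps) < 10:
        raise ValueError("need >= 10 patients")
    P = int(n_permutations if n_permutations is not None else config.n_permutations)
    y = np.asarray(behavior, dtype=np.float64)
    if y.size != len(maps):
        raise ValueError("behavior length must match number of maps")
    zgrids = np.stack([m.zmap.grid.astype(np.float64) for m in maps])  # (n, x, y, z)
    shape = zgrids.shape[1:]
    affine = maps[0].zmap.affine
    analysis = np.ones(shape, dtype=bool)
    if gm_prob is not None:
        analysis &= np.asarray(gm_prob.grid, dtype=float) >= config.gm_probability_threshold
    if region_mask is not None:
        analysis &= np.asarray(region_mask).astype(bool)
    vi = np.argwhere(analysis)
    M = zgrids[:, vi[:, 0], vi[:, 1], vi[:, 2]]  # (n, V)
    var_ok = M.std(axis=0) > 0
    if not var_ok.all():
        logger.info("GLM: dropping %d zero-variance voxels", int((~var_ok).sum()))
        vi = vi[var_ok]
        M = M[:, var_ok]
    if vi.shape[0] == 0:
        raise ValueError("no analyzable voxels")

    n = y.size
    dof = n - 2
    t_crit = stats.t.isf(config.lnsm_voxel_p / 2.0, dof)  # two-tailed

    def to_grid(vals):
        g = np.zeros(shape)
        g[vi[:, 0], vi[:, 1], vi[:, 2]] = vals
        return g

    t_obs = _glm_t(M, y)
    conn = config.cluster_connectivity
    obs_binary = to_grid((np.abs(t_obs) > t_crit).astype(float)) > 0
    clusters_vox = label_clusters(obs_binary, conn)

    rng = np.random.default_rng(config.rng_seed)
    null_max = np.empty(P, dtype=np.int64)
    for j in range(P):
        t_perm = _glm_t(M, rng.permutation(y))
        null_max[j] = _max_cluster_size(
            to_grid((np.abs(t_perm) > t_crit).astype(float)) > 0, conn
        )

    voxel_ml = float(np.prod(np.sqrt((affine[:3, :3] ** 2).sum(axis=0)))) / 1000.0
    t_grid = to_grid(t_obs)
    clusters = []
    for cid, vox in enumerate(clusters_vox, start=1):
        size = len(vox)
        p_fwe = cluster_fwe_p(null_max, size)
        peak = vox[np.argmax(np.abs(t_grid[vox[:, 0], vox[:, 1], vox[:, 2]]))]
        clusters.append({
            "cluster_id": cid, "voxels": vox, "size_vox": size,
            "size_ml": size * voxel_ml, "p_fwe": p_fwe,
            "significant": p_fwe < config.cluster_fwe_alpha,
            "peak_voxel": tuple(int(v) for v in peak),
        })
    mask_grid = np.zeros(shape, dtype=np.uint8)
    mask_grid[vi[:, 0], vi[:, 1], vi[:, 2]] = 1
    tmap = StatMap(t_grid, mask_grid, "t", affine)
    return tmap, clusters
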