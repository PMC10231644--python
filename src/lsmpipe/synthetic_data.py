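"""Synthetic cohorts with known ground truth.

Generates every input the pipelines consume — blob lesions with a planted
region->score effect, community-structured normative time series with motion
traces and tissue maps, and bundle-shaped streamline sets — so each stage can
be validated without any external data.  All generators are pure functions of
(parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .disconnectome import Tractogram, write_tractogram
from .io_model import AnalysisConfig, CohortTable, LesionMask, StatMap, write_mask_volume
from .lnsm import NormativeRun

import nibabel as nib
import pandas as pd


@dataclass
class GroundTruth:
    """Planted structure shared by all generators.

    critical_region: voxels whose damage raises the behavioral score.
    effect_size: score points added per unit damage fraction of that region.
    network_modules: integer community labels over gray-matter voxels
        (0 = not gray matter); community signals drive the synthetic BOLD.
    bundle_specs: (endpoint_a, endpoint_b, spread) triples, voxel coordinates.
    """

    grid_shape: tuple
    affine: np.ndarray
    critical_region: np.ndarray
    effect_size: float
    noise_sd: float
    base_score: float
    network_modules: np.ndarray
    gm_prob: np.ndarray
    wm_prob: np.ndarray
    csf_prob: np.ndarray
    bundle_specs: list

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.critical_region.shape != tuple(self.grid_shape):
            raise ValueError("critical_region outside simulation grid")
        if self.effect_size > 0 and self.critical_region.sum() == 0:
            raise ValueError("effect region empty while effect_size > 0")

    @property
    def n_communities(self) -> int:
        return int(self.network_modules.max())


def default_ground_truth(
    grid_shape=(24, 24, 24),
    voxel_size_mm: float = 2.0,
    effect_size: float = 0.0,
    noise_sd: float = 2.0,
    base_score: float = 4.0,
    region_radius_vox: float = 2.6,
) -> GroundTruth:
    """Desk-scale geometry: concentric GM ball / WM shell / CSF rim, an
    8-octant community partition of the GM, a small spherical critical region
    and three straight fiber bundles crossing the volume."""
    shape = tuple(int(s) for s in grid_shape)
    if min(shape) < 8:
        raise ValueError("degenerate grid")
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    center = (np.asarray(shape) - 1) / 2.0
    ii = np.indices(shape).astype(float)
    dist = np.sqrt(((ii - center.reshape(3, 1, 1, 1)) ** 2).sum(axis=0))
    r_gm = min(shape) * 0.38
    r_wm = min(shape) * 0.46
    gm = (dist <= r_gm).astype(float)
    wm = ((dist > r_gm) & (dist <= r_wm)).astype(float)
    csf = (dist > r_wm).astype(float)

    # 8 octant communities within GM
    octant = (
        (ii[0] > center[0]).astype(int)
        + 2 * (ii[1] > center[1]).astype(int)
        + 4 * (ii[2] > center[2]).astype(int)
    )
    modules = np.where(gm > 0, octant + 1, 0).astype(np.int32)

    region_center = center + np.array([r_gm * 0.4, 0.0, 0.0])
    region = (
        np.sqrt(((ii - region_center.reshape(3, 1, 1, 1)) ** 2).sum(axis=0))
        <= region_radius_vox
    ).astype(np.uint8)
    region &= gm.astype(np.uint8)

    m = np.asarray(shape, dtype=float)
    bundles = [
        (np.array([2.0, center[1], center[2]]), np.array([m[0] - 3.0, center[1], center[2]]), 0.8),
        (np.array([center[0], 2.0, center[2]]), np.array([center[0], m[1] - 3.0, center[2]]), 0.8),
        (np.array([3.0, 3.0, center[2]]), np.array([m[0] - 4.0, m[1] - 4.0, center[2]]), 0.8),
    ]
    return GroundTruth(
        grid_shape=shape,
        affine=affine,
        critical_region=region,
        effect_size=float(effect_size),
        noise_sd=float(noise_sd),
        base_score=float(base_score),
        network_modules=modules,
        gm_prob=gm,
        wm_prob=wm,
        csf_prob=csf,
        bundle_specs=bundles,
    )


def _grow_blob(rng: np.random.Generator, shape, seed_voxel, target_volume: int) -> np.ndarray:
    """Eden-style random growth: repeatedly add a random frontier neighbor.
    Always yields a 6-connected blob of exactly target_volume voxels (or fewer
    if the grid fills up)."""
    grid = np.zeros(shape, dtype=np.uint8)
    grid[tuple(seed_voxel)] = 1
    frontier = []
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]

    def push_neighbors(v):
        for off in offsets:
            w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
            if 0 <= w[0] < shape[0] and 0 <= w[1] < shape[1] and 0 <= w[2] < shape[2]:
                if not grid[w]:
                    frontier.append(w)

    push_neighbors(tuple(seed_voxel))
    size = 1
    while size < target_volume and frontier:
        k = rng.integers(len(frontier))
        v = frontier.pop(k)
        if grid[v]:
            continue
        grid[v] = 1
        size += 1
        push_neighbors(v)
    return grid


def generate_lesion_cohort(
    n_patients: int,
    grid_shape,
    truth: GroundTruth,
    seed: int,
    mean_volume_vox: float = 300.0,
    volume_sigma: float = 0.5,
) -> tuple:
    """Random connected blob lesions plus a cohort table whose HADS-D scores
    carry the planted region->score effect.

    score_i = round(clip(base + effect_size * overlap_frac_i + N(0, noise_sd), 0, 21))
    where overlap_frac is the damaged fraction of the critical region.
    """
    shape = tuple(int(s) for s in grid_shape)
    if shape != tuple(truth.grid_shape):
        raise ValueError("grid_shape disagrees with ground truth")
    if n_patients < 2:
        raise ValueError("n_patients must be >= 2")
    vol = float(np.prod(shape))
    if vol < 4 * mean_volume_vox:
        raise ValueError("degenerate grid: volume not >> mean lesion volume")
    rng = np.random.default_rng(seed)
    center = (np.asarray(shape) - 1) / 2.0
    region = truth.critical_region.astype(bool)
    region_size = max(int(region.sum()), 1)

    masks, rows = [], []
    for i in range(n_patients):
        # seeds cluster toward the middle of the volume, like vascular territories
        sv = np.clip(
            np.round(rng.normal(center, np.asarray(shape) / 6.0)).astype(int),
            1,
            np.asarray(shape) - 2,
        )
        target = int(np.clip(rng.lognormal(np.log(mean_volume_vox), volume_sigma), 8, vol * 0.2))
        grid = _grow_blob(rng, shape, sv, target)
        pid = f"sub-{i + 1:03d}"
        masks.append(LesionMask(patient_id=pid, grid=grid, affine=truth.affine.copy()))
        frac = float((grid.astype(bool) & region).sum()) / region_size
        raw = truth.base_score + truth.effect_size * frac + rng.normal(0.0, truth.noise_sd)
        score = int(np.round(np.clip(raw, 0, 21)))
        rows.append(
            {
                "patient_id": pid,
                "hads_d": score,
                "critical_overlap_frac": frac,
                "age": int(np.clip(np.round(rng.normal(68, 12)), 18, 90)),
                "sex": int(rng.integers(2)),
                "nihss": int(np.clip(np.round(rng.gamma(2.0, 2.0)), 0, 42)),
                "barthel": int(np.clip(5 * np.round(rng.normal(16, 4)), 0, 100)),
            }
        )
    table = CohortTable(pd.DataFrame(rows))
    return masks, table


def _bandlimited_noise(rng, n_timepoints, tr_s, band) -> np.ndarray:
    """Unit-variance Gaussian signal band-limited to `band` (Hz)."""
    x = rng.standard_normal(n_timepoints)
    nyq = 0.5 / tr_s
    lo, hi = band[0] / nyq, min(band[1] / nyq, 0.99)
    b, a = signal.butter(2, [lo, hi], btype="band")
    y = signal.filtfilt(b, a, x)
    sd = y.std()
    return y / sd if sd > 0 else y


def generate_normative_timeseries(
    n_subjects: int,
    n_runs: int,
    n_timepoints: int,
    tr_s: float,
    truth: GroundTruth,
    seed: int,
    signal_amplitude: float = 1.0,
    voxel_noise_sd: float = 0.3,
    n_high_motion_frames: int = 0,
    high_motion_mm: float = 1.0,
) -> list:
    """Low-rank, community-structured resting-state runs.

    Every gray-matter voxel follows its community's band-limited signal plus
    i.i.d. noise; WM/CSF voxels are pure noise.  Motion traces are smooth and
    small except for `n_high_motion_frames` injected step displacements of
    `high_motion_mm` per run, each of which raises framewise displacement at
    exactly one frame.
    """
    if n_timepoints <= 20:
        raise ValueError("n_timepoints must be > 20")
    rng = np.random.default_rng(seed)
    shape = tuple(truth.grid_shape)
    modules = truth.network_modules
    n_comm = truth.n_communities
    runs = []
    for s in range(n_subjects):
        for r in range(n_runs):
            comm_sig = np.stack(
                [
                    _bandlimited_noise(rng, n_timepoints, tr_s, (0.015, 0.07))
                    for _ in range(n_comm)
                ]
            )  # (n_comm, T)
            data = rng.normal(0.0, voxel_noise_sd, size=shape + (n_timepoints,))
            for c in range(1, n_comm + 1):
                sel = modules == c
                data[sel] += signal_amplitude * comm_sig[c - 1]

            # small smooth drift: translations in mm, rotations in rad (x50 in FD)
            step_sd = np.array([0.005] * 3 + [5e-5] * 3)
            motion = np.cumsum(rng.normal(0.0, step_sd, size=(n_timepoints, 6)), axis=0)
            if n_high_motion_frames:
                # persistent steps, spaced >= 2 frames apart so FD spikes once each
                candidates = np.arange(2, n_timepoints - 1, 2)
                frames = rng.choice(candidates, size=n_high_motion_frames, replace=False)
                for f in frames:
                    motion[f:, 0] += high_motion_mm
            aff = truth.affine
            runs.append(
                NormativeRun(
                    subject_id=f"con-{s + 1:03d}",
                    run_id=("RL", "LR")[r % 2] if n_runs <= 2 else f"run-{r + 1}",
                    data=data,
                    tr_s=float(tr_s),
                    motion=motion,
                    gm_prob=StatMap(truth.gm_prob, np.ones(shape), "percent", aff),
                    wm_prob=StatMap(truth.wm_prob, np.ones(shape), "percent", aff),
                    csf_prob=StatMap(truth.csf_prob, np.ones(shape), "percent", aff),
                )
            )
    return runs


def generate_normative_tractograms(
    n_subjects: int,
    truth: GroundTruth,
    streamlines_per_bundle: int = 20,
    seed: int = 0,
    points_per_streamline: int = 40,
) -> list:
    """Bundle-shaped streamline sets: polylines jittered around each bundle's
    straight A->B path with per-streamline smooth Gaussian offsets.  With
    spread=0 every subject traces the identical path."""
    if not truth.bundle_specs:
        raise ValueError("bundle_specs non-empty required")
    shape = np.asarray(truth.grid_shape, dtype=float)
    for a, b, _ in truth.bundle_specs:
        for p in (np.asarray(a), np.asarray(b)):
            if np.any(p < 0) or np.any(p > shape - 1):
                raise ValueError("endpoints outside grid")
    rng = np.random.default_rng(seed)
    A3 = truth.affine[:3, :3]
    t3 = truth.affine[:3, 3]
    u = np.linspace(0.0, 1.0, points_per_streamline)
    tractograms = []
    for s in range(n_subjects):
        lines = []
        for a, b, spread in truth.bundle_specs:
            a = np.asarray(a, dtype=float)
            b = np.asarray(b, dtype=float)
            base = a[None, :] + u[:, None] * (b - a)[None, :]
            for _ in range(streamlines_per_bundle):
                o0, o1, om = (rng.normal(0.0, spread, size=3) for _ in range(3))
                offset = (
                    o0[None, :] * (1 - u)[:, None]
                    + o1[None, :] * u[:, None]
                    + om[None, :] * (4 * u * (1 - u))[:, None]
                )
                pts_vox = np.clip(base + offset, 0.0, shape - 1.0)
                lines.append(pts_vox @ A3.T + t3)
        tractograms.append(Tractogram(subject_id=f"hc-{s + 1:02d}", streamlines=lines))
    return tractograms


def write_dataset(
    out_dir,
    truth: GroundTruth,
    masks,
    cohort: CohortTable,
    runs=None,
    tractograms=None,
    config: AnalysisConfig = None,
) -> Path:
    """Materialize a full dataset directory in the layout the CLI consumes."""
    out = Path(out_dir)
    (out / "lesions").mkdir(parents=True, exist_ok=True)
    cohort.to_csv(out / "cohort.csv")
    for m in masks:
        write_mask_volume(m, out / "lesions" / f"{m.patient_id}.nii.gz")
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    nib.save(nib.Nifti1Image(truth.critical_region.astype(np.uint8), truth.affine),
             str(truth_dir / "critical_region.nii.gz"))
    nib.save(nib.Nifti1Image(truth.network_modules.astype(np.int16), truth.affine),
             str(truth_dir / "network_modules.nii.gz"))
    for name in ("gm_prob", "wm_prob", "csf_prob"):
        nib.save(nib.Nifti1Image(getattr(truth, name).astype(np.float32), truth.affine),
                 str(out / f"{name}.nii.gz"))
    meta = {
        "effect_size": truth.effect_size,
        "noise_sd": truth.noise_sd,
        "base_score": truth.base_score,
        "grid_shape": list(truth.grid_shape),
    }
    (truth_dir / "truth.json").write_text(json.dumps(meta, indent=2))
    if runs is not None:
        cdir = out / "connectome"
        cdir.mkdir(exist_ok=True)
        for run in runs:
            stem = f"{run.subject_id}_{run.run_id}"
            nib.save(nib.Nifti1Image(run.data.astype(np.float32), truth.affine),
                     str(cdir / f"{stem}_bold.nii.gz"))
            np.savetxt(cdir / f"{stem}_motion.txt", run.motion)
            (cdir / f"{stem}_tr.txt").write_text(str(run.tr_s))
    if tractograms is not None:
        tdir = out / "tractograms"
        tdir.mkdir(exist_ok=True)
        for t in tractograms:
            write_tractogram(t, tdir / f"{t.subject_id}.txt")
    if config is not None:
        config.to_yaml(out / "config.yaml")
    return out
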