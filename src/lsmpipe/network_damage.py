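"""Depression-circuit map and the network damage score with its permutation
group test."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .io_model import AnalysisConfig, LesionMask, StatMap
from .lnsm import CleanedRun, NormativeRun, preprocess_run, roi_eigenvariate, seed_connectivity_map
from .svr_mapping import residualize

logger = logging.getLogger("lsmpipe")


@dataclass
class CircuitMap:
    """Voxelwise one-sample t over normative subjects' seed-sphere z-maps."""

    tmap: StatMap
    roi_center_world: np.ndarray
    roi_diameter_mm: float
    roi_mask: np.ndarray
    n_subjects: int


@dataclass
class NdsResult:
    patient_ids: list
    raw_scores: np.ndarray
    residual_scores: np.ndarray
    group_labels: np.ndarray
    observed_stat: float
    p_value: float
    n_permutations: int
    mode: str
    exhaustive: bool


def sphere_roi(center_world, diameter_mm: float, shape, affine: np.ndarray) -> np.ndarray:
    """Voxels whose centers lie within diameter/2 of the world-space center."""
    center_world = np.asarray(center_world, dtype=float)
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    world = idx @ affine[:3, :3].T + affine[:3, 3]
    d = np.sqrt(((world - center_world) ** 2).sum(axis=1))
    roi = (d <= diameter_mm / 2.0).reshape(shape)
    return roi.astype(np.uint8)


def circuit_tmap(
    runs: list,
    center_world,
    diameter_mm: float,
    config: AnalysisConfig,
    affine: np.ndarray = None,
) -> CircuitMap:
    """Seed a sphere in every normative subject, average that subject's
    run-level Fisher-z maps, and take the voxelwise one-sample t across
    subjects.  Zero-variance voxels get t=0 (logged)."""
    cleaned = [r if isinstance(r, CleanedRun) else preprocess_run(r, config) for r in runs]
    if affine is None:
        affine = cleaned[0].gm_prob.affine if cleaned[0].gm_prob is not None else np.eye(4)
    shape = cleaned[0].data.shape[:3]
    roi = sphere_roi(center_world, diameter_mm, shape, affine)
    if roi.sum() < 1:
        raise ValueError("sphere contains no voxel")
    by_subject: dict = {}
    for run in cleaned:
        ev = roi_eigenvariate(run.data, roi)
        z = seed_connectivity_map(run.data, ev, affine).grid.astype(np.float64)
        by_subject.setdefault(run.subject_id, []).append(z)
    if len(by_subject) < 3:
        raise ValueError("need >= 3 normative subjects")
    subj_maps = np.stack([np.mean(zs, axis=0) for zs in by_subject.values()])
    n = subj_maps.shape[0]
    mean = subj_maps.mean(axis=0)
    sd = subj_maps.std(axis=0, ddof=1)
    dead = sd == 0
    if dead.any():
        logger.info("circuit t-map: %d zero-variance voxels set to t=0", int(dead.sum()))
    sd[dead] = 1.0
    t = mean / (sd / math.sqrt(n))
    t[dead] = 0.0
    return CircuitMap(
        tmap=StatMap(t.astype(np.float32), np.ones(shape, dtype=np.uint8), "t", affine),
        roi_center_world=np.asarray(center_world, dtype=float),
        roi_diameter_mm=float(diameter_mm),
        roi_mask=roi,
        n_subjects=n,
    )


def network_damage_score(
    lesion: LesionMask, circuit: CircuitMap, positive_only: bool = False
) -> float:
    """Sum of circuit t-values over the patient's lesioned voxels
    (unthresholded by default; positive_only sums only t > 0)."""
    if lesion.grid.shape != circuit.tmap.grid.shape:
        raise ValueError("geometry mismatch")
    if not np.allclose(lesion.affine, circuit.tmap.affine, atol=1e-6):
        raise ValueError("geometry mismatch: affines differ")
    t = circuit.tmap.grid.astype(np.float64)
    if positive_only:
        t = np.where(t > 0, t, 0.0)
    # fsum: exactly rounded, so the result is independent of summation order
    return math.fsum(t[lesion.grid.astype(bool)].tolist())


def residualize_nds(scores: np.ndarray, lesion_volumes: np.ndarray) -> np.ndarray:
    """OLS residuals of the damage score on lesion volume (+ intercept)."""
    scores = np.asarray(scores, dtype=np.float64)
    vols = np.asarray(lesion_volumes, dtype=np.float64)
    if scores.size < 3:
        raise ValueError("need >= 3 patients")
    if np.std(vols) == 0:
        raise ValueError("constant lesion volumes")
    return residualize(scores, vols.reshape(-1, 1))


def _two_sample_t(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = x.size, y.size
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 == 0:
        return 0.0
    return float((x.mean() - y.mean()) / math.sqrt(sp2 * (1.0 / nx + 1.0 / ny)))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean(); b = b - b.mean()
    den = math.sqrt(float((a @ a) * (b @ b)))
    return float(a @ b) / den if den > 0 else 0.0


def permutation_group_test(
    residuals: np.ndarray,
    labels,
    n_perm: int = 1_000_000,
    seed: int = 0,
    continuous_scores: np.ndarray = None,
    exhaustive_limit: int = 1_000_000,
):
    """Permutation equivalent of a two-sample t-test (two-tailed).

    With `continuous_scores` the statistic is the Pearson correlation with
    those scores instead; labels are ignored then.  When the number of
    distinct group assignments is <= exhaustive_limit, the null is enumerated
    exhaustively (p = #{|stat| >= |observed|} / N); otherwise Monte-Carlo with
    p = (1 + #{perm |stat| >= |observed|}) / (n_perm + 1).

    Returns (observed_stat, p, exhaustive_flag).
    """
    x = np.asarray(residuals, dtype=np.float64)
    rng = np.random.default_rng(seed)
    tol = 1e-12

    if continuous_scores is not None:
        scores = np.asarray(continuous_scores, dtype=np.float64)
        obs = _pearson(x, scores)
        count = 0
        for _ in range(n_perm):
            if abs(_pearson(x, rng.permutation(scores))) >= abs(obs) - tol:
                count += 1
        return obs, (1 + count) / (n_perm + 1.0), False

    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError("two-sample mode requires exactly two non-empty groups")
    g1 = labels == uniq[0]
    n, n1 = x.size, int(g1.sum())
    obs = _two_sample_t(x[g1], x[~g1])

    total = math.comb(n, n1)
    if total <= exhaustive_limit:
        count = 0
        idx = np.arange(n)
        for comb in combinations(idx, n1):
            sel = np.zeros(n, dtype=bool)
            sel[list(comb)] = True
            if abs(_two_sample_t(x[sel], x[~sel])) >= abs(obs) - tol:
                count += 1
        return obs, count / total, True

    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        sel = np.zeros(n, dtype=bool)
        sel[perm[:n1]] = True
        if abs(_two_sample_t(x[sel], x[~sel])) >= abs(obs) - tol:
            count += 1
    return obs, (1 + count) / (n_perm + 1.0), False


def nds_analysis(
    lesions: list,
    circuit: CircuitMap,
    hads_d: np.ndarray,
    lesion_volumes_ml: np.ndarray,
    cutoff: int = 10,
    n_perm: int = 1_000_000,
    seed: int = 0,
    mode: str = "group",
    positive_only: bool = False,
) -> NdsResult:
    """Score every lesion, residualize against volume, and test group
    difference (HADS-D > cutoff vs rest) or the continuous correlation."""
    scores = np.array([network_damage_score(m, circuit, positive_only) for m in lesions])
    resid = residualize_nds(scores, lesion_volumes_ml)
    hads = np.asarray(hads_d, dtype=float)
    labels = np.where(hads > cutoff, "depressed", "not_depressed")
    if mode == "group":
        if len(set(labels)) < 2:
            raise ValueError("single-group input in two-sample mode")
        stat, p, exhaustive = permutation_group_test(resid, labels, n_perm=n_perm, seed=seed)
    elif mode == "continuous":
        stat, p, exhaustive = permutation_group_test(
            resid, None, n_perm=n_perm, seed=seed, continuous_scores=hads
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return NdsResult(
        patient_ids=[m.patient_id for m in lesions],
        raw_scores=scores, residual_scores=resid, group_labels=labels,
        observed_stat=stat, p_value=p, n_permutations=n_perm, mode=mode,
        exhaustive=exhaustive,
    )
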