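"""Multivariate SVR symptom mapping over binary voxel-feature maps.

The same machinery serves lesion maps (SVR-LSM) and binarized disconnection
maps (SVR-SDSM): an epsilon-SVR is fit on all patients, its dual coefficients
are back-projected onto voxels as a beta-map, and inference uses a
permutation null — one-tailed voxel p-values from permuted beta-maps,
cluster-level FWE from the null distribution of the maximum suprathreshold
cluster size.  In-sample prediction performance is ranked against the same
permuted models.

Sign convention follows the published maps: z-scored betas are flipped so
that NEGATIVE z marks damage associated with HIGHER symptom scores.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from skimage.measure import label as _cc_label
from sklearn.svm import SVR

from .io_model import AnalysisConfig, LesionMask, StatMap
from .lesion_prep import CoverageMask

logger = logging.getLogger("lsmpipe")

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class FeatureMatrix:
    """Patients x coverage-voxels feature matrix with its voxel bookkeeping."""

    data: np.ndarray              # (n_patients, n_voxels), float
    voxel_indices: np.ndarray     # (n_voxels, 3) int indices into the grid
    patient_ids: list
    grid_shape: tuple
    affine: np.ndarray

    @property
    def n_patients(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def to_grid(self, values: np.ndarray) -> np.ndarray:
        grid = np.zeros(self.grid_shape, dtype=np.float64)
        vi = self.voxel_indices
        grid[vi[:, 0], vi[:, 1], vi[:, 2]] = values
        return grid

    @property
    def mask_grid(self) -> np.ndarray:
        m = np.zeros(self.grid_shape, dtype=np.uint8)
        vi = self.voxel_indices
        m[vi[:, 0], vi[:, 1], vi[:, 2]] = 1
        return m


@dataclass
class SvrResult:
    beta_map: StatMap
    z_map: StatMap
    voxel_p_map: StatMap
    clusters: list                # dicts: voxels, size_vox, size_ml, p_fwe, peak_voxel
    prediction_r: float
    prediction_p: float
    n_permutations: int
    hyperparameters: dict
    null_max_cluster_sizes: np.ndarray = None

    @property
    def significant_clusters(self) -> list:
        return [c for c in self.clusters if c["significant"]]


def build_feature_matrix(masks: list, coverage: CoverageMask, affine: np.ndarray) -> FeatureMatrix:
    """Binary features restricted to the coverage mask; patients already
    flagged in the coverage step must be filtered by the caller."""
    vi = np.argwhere(coverage.mask > 0)
    data = np.stack(
        [m.grid[vi[:, 0], vi[:, 1], vi[:, 2]].astype(np.float64) for m in masks]
    )
    return FeatureMatrix(
        data=data, voxel_indices=vi, patient_ids=[m.patient_id for m in masks],
        grid_shape=masks[0].grid.shape, affine=np.asarray(affine, dtype=float),
    )


def residualize(values: np.ndarray, nuisance: np.ndarray) -> np.ndarray:
    """OLS residuals of each column of `values` on [1, nuisance].

    Used both for lesion-volume control (behavior and every feature column)
    and for the optional behavioral covariates.
    """
    values = np.asarray(values, dtype=np.float64)
    squeeze = values.ndim == 1
    V = values.reshape(len(values), -1)
    N = np.asarray(nuisance, dtype=np.float64).reshape(len(values), -1)
    X = np.column_stack([np.ones(len(values)), N])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient nuisance design")
    coef, *_ = np.linalg.lstsq(X, V, rcond=None)
    resid = V - X @ coef
    return resid.ravel() if squeeze else resid


def _make_svr(config: AnalysisConfig) -> SVR:
    return SVR(
        kernel="precomputed", C=config.svr_c, epsilon=config.svr_epsilon,
        tol=1e-3, max_iter=config.svr_max_iter,
    )


def _gram(X: np.ndarray, config: AnalysisConfig) -> np.ndarray:
    if config.svr_kernel == "linear":
        return X @ X.T
    sq = (X**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    return np.exp(-config.svr_gamma * np.maximum(d2, 0.0))


def _fit_betas(K: np.ndarray, X: np.ndarray, y: np.ndarray, config: AnalysisConfig):
    """Fit epsilon-SVR on a precomputed Gram matrix and back-project the dual
    coefficients onto voxels: beta_v = sum_i alpha_i * X_iv over support
    vectors.  For the RBF kernel this back-projection is the established
    approximation; for the linear kernel it equals the primal weights."""
    svr = _make_svr(config)
    with warnings.catch_warnings():
        # the iteration cap is intentional (see AnalysisConfig.svr_max_iter)
        warnings.filterwarnings("ignore", message="Solver terminated early")
        svr.fit(K, y)
    beta = svr.dual_coef_.ravel() @ X[svr.support_]
    pred = svr.predict(K)
    return beta, pred


def fit_svr_betamap(features: FeatureMatrix, behavior: np.ndarray, config: AnalysisConfig):
    """Observed beta-map, z-scored (and sign-flipped) map and predictions.

    Behavior is z-scored before fitting for hyperparameter comparability;
    features are used as-is (binary, or residualized upstream).
    """
    y = np.asarray(behavior, dtype=np.float64)
    if features.n_patients < 10:
        raise ValueError("need >= 10 patients")
    if features.n_voxels < 1:
        raise ValueError("need >= 1 voxel")
    if y.std() == 0:
        raise ValueError("degenerate behavior (zero variance)")
    y = (y - y.mean()) / y.std()
    X = features.data
    K = _gram(X, config)
    beta, pred = _fit_betas(K, X, y, config)
    sd = beta.std()
    z = -(beta - beta.mean()) / sd if sd > 0 else np.zeros_like(beta)
    return beta, z, pred


def label_clusters(binary_grid: np.ndarray, connectivity: int = 26) -> list:
    """Connected components of a binary 3-D map.  Returns one (n_i, 3) voxel
    index array per cluster, largest first."""
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError("connectivity must be 6, 18 or 26")
    lab = _cc_label(np.asarray(binary_grid) > 0, connectivity=_CONNECTIVITY_RANK[connectivity])
    clusters = [np.argwhere(lab == i) for i in range(1, lab.max() + 1)]
    clusters.sort(key=len, reverse=True)
    return clusters


def cluster_fwe_p(null_max_sizes: np.ndarray, observed_size: int) -> float:
    """Cluster-level FWE p from the permutation null of maximum cluster sizes:
    (1 + #{perm max >= observed}) / (P + 1)."""
    null = np.asarray(null_max_sizes)
    return (1 + int((null >= observed_size).sum())) / (null.size + 1.0)


def _max_cluster_size(binary_grid: np.ndarray, connectivity: int) -> int:
    lab = _cc_label(binary_grid, connectivity=_CONNECTIVITY_RANK[connectivity])
    if lab.max() == 0:
        return 0
    return int(np.bincount(lab.ravel())[1:].max())


def permutation_cluster_inference(
    features: FeatureMatrix,
    behavior: np.ndarray,
    config: AnalysisConfig,
    n_permutations: int = None,
) -> SvrResult:
    """Full SVR mapping with permutation voxel + cluster-FWE inference.

    The observed fit and P permuted fits (behavior shuffled) are pooled;
    one-tailed voxel p in the symptom-increasing direction is
    (1 + #{perm beta >= observed beta}) / (P + 1).  Observed voxel-p maps are
    thresholded at config.svr_voxel_p and clustered; each permutation is
    thresholded the same way and its maximum cluster size recorded, giving
    cluster p_fwe = (1 + #{perm max >= observed size}) / (P + 1).
    """
    P = int(n_permutations if n_permutations is not None else config.n_permutations)
    if P < 100:
        logger.warning("only %d permutations; p-value resolution is coarse", P)
    if 1.0 / (P + 1) >= config.svr_voxel_p:
        logger.warning(
            "voxel threshold p<%g is unattainable with %d permutations "
            "(minimum p = 1/%d)", config.svr_voxel_p, P, P + 1,
        )
    y = np.asarray(behavior, dtype=np.float64)
    if y.std() == 0:
        raise ValueError("degenerate behavior (zero variance)")
    y = (y - y.mean()) / y.std()
    X = features.data
    K = _gram(X, config)
    rng = np.random.default_rng(config.rng_seed)

    betas = np.empty((P + 1, features.n_voxels))
    preds = np.empty((P + 1, features.n_patients))
    ys = np.empty((P + 1, features.n_patients))
    ys[0] = y
    for j in range(1, P + 1):
        ys[j] = rng.permutation(y)
    for j in range(P + 1):
        betas[j], preds[j] = _fit_betas(K, X, ys[j], config)

    # Each beta map is standardized across voxels before ranking: the overall
    # beta scale varies strongly between fits (null fits saturate the dual
    # bounds), so only within-map standardized values are comparable across
    # permutations.  Pooled one-tailed voxel p in the symptom-increasing
    # direction (larger standardized beta): rank-from-top with max ties gives
    # p = count(>= value)/(P+1) with the observed row included, equal to the
    # (1 + #{perm >= obs})/(P+1) convention.
    sd = betas.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    zmaps = (betas - betas.mean(axis=1, keepdims=True)) / sd
    count_ge = stats.rankdata(-zmaps, axis=0, method="max")
    pvals = count_ge / (P + 1.0)

    conn = config.cluster_connectivity
    thresh = pvals < config.svr_voxel_p
    obs_binary = features.to_grid(thresh[0].astype(float)) > 0
    clusters_vox = label_clusters(obs_binary, conn)
    null_max = np.array(
        [_max_cluster_size(features.to_grid(thresh[j].astype(float)) > 0, conn)
         for j in range(1, P + 1)],
        dtype=np.int64,
    )
    voxel_ml = float(np.prod(np.sqrt((features.affine[:3, :3] ** 2).sum(axis=0)))) / 1000.0
    obs_p = features.to_grid(pvals[0])
    clusters = []
    for cid, vox in enumerate(clusters_vox, start=1):
        size = len(vox)
        p_fwe = cluster_fwe_p(null_max, size)
        peak = vox[np.argmin(obs_p[vox[:, 0], vox[:, 1], vox[:, 2]])]
        clusters.append({
            "cluster_id": cid, "voxels": vox, "size_vox": size,
            "size_ml": size * voxel_ml, "p_fwe": p_fwe,
            "significant": p_fwe < config.cluster_fwe_alpha,
            "peak_voxel": tuple(int(v) for v in peak),
        })

    # in-sample prediction performance ranked against the permuted models
    def _pearson(a, b):
        a = a - a.mean(); b = b - b.mean()
        den = np.sqrt((a @ a) * (b @ b))
        if den == 0:
            raise ValueError("zero-variance predictions; r undefined")
        return float((a @ b) / den)

    r_obs = _pearson(preds[0], ys[0])
    r_null = np.array([_pearson(preds[j], ys[j]) for j in range(1, P + 1)])
    pred_p = (1 + int((r_null >= r_obs).sum())) / (P + 1.0)

    mask = features.mask_grid
    beta0 = betas[0]
    sd = beta0.std()
    z0 = -(beta0 - beta0.mean()) / sd if sd > 0 else np.zeros_like(beta0)
    hyper = {"C": config.svr_c, "gamma": config.svr_gamma,
             "epsilon": config.svr_epsilon, "kernel": config.svr_kernel}
    return SvrResult(
        beta_map=StatMap(features.to_grid(beta0), mask, "beta", features.affine),
        z_map=StatMap(features.to_grid(z0), mask, "z", features.affine),
        voxel_p_map=StatMap(obs_p + (1 - mask), mask, "p", features.affine),
        clusters=clusters,
        prediction_r=r_obs,
        prediction_p=pred_p,
        n_permutations=P,
        hyperparameters=hyper,
        null_max_cluster_sizes=null_max,
    )


def prediction_performance(
    features: FeatureMatrix, behavior: np.ndarray, config: AnalysisConfig,
    n_permutations: int = None,
):
    """Standalone in-sample (r, permutation-rank p) without the voxel maps."""
    res = permutation_cluster_inference(features, behavior, config, n_permutations)
    return res.prediction_r, res.prediction_p


def prepare_svr_inputs(
    masks: list,
    behavior: np.ndarray,
    coverage: CoverageMask,
    lesion_volumes_ml: np.ndarray,
    covariates: np.ndarray = None,
    affine: np.ndarray = None,
):
    """Lesion-volume control as published: volume is regressed out of both the
    behavior and every feature column; optional covariates are regressed out
    of behavior only.  Returns (FeatureMatrix with residualized data, behavior
    residuals)."""
    fm = build_feature_matrix(masks, coverage, affine)
    vol = np.asarray(lesion_volumes_ml, dtype=np.float64).reshape(-1, 1)
    y = np.asarray(behavior, dtype=np.float64)
    if covariates is not None:
        y = residualize(y, np.column_stack([vol, np.asarray(covariates, dtype=np.float64)]))
    else:
        y = residualize(y, vol)
    fm.data = residualize(fm.data, vol)
    return fm, y
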