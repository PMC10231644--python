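"""Domain types and file I/O: lesion masks, statistic maps, cohort tables, run config.

All volumes are exchanged as NIfTI-1; cohort tables as CSV/TSV; configuration
as YAML.  Cross-map operations elsewhere in the package require identical
shape and affine — nothing here resamples implicitly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("lsmpipe")

STAT_KINDS = ("beta", "z", "t", "p", "percent", "overlap_count")


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is singular")
    return affine


@dataclass
class LesionMask:
    """Binary 3-D damage indicator for one patient, with its voxel->world transform."""

    patient_id: str
    grid: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 3:
            raise ValueError("non-3-D image")
        vals = np.unique(grid)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("lesion mask values must be in {0, 1}")
        self.grid = grid.astype(np.uint8)
        self.affine = _check_affine(self.affine)

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())

    @property
    def is_empty(self) -> bool:
        return self.n_voxels == 0


@dataclass
class StatMap:
    """Voxelwise statistic map with its analysis mask.

    Values outside the mask are zeroed on construction.  ``kind`` constrains
    the value range: ``p`` maps live in (0, 1], ``percent`` maps in [0, 100].
    """

    grid: np.ndarray
    mask: np.ndarray
    kind: str
    affine: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in STAT_KINDS:
            raise ValueError(f"unknown stat kind {self.kind!r}; expected one of {STAT_KINDS}")
        # float64 in memory for oracle-grade precision; cast to float32 on write
        grid = np.asarray(self.grid, dtype=np.float64)
        mask = np.asarray(self.mask)
        if grid.ndim != 3:
            raise ValueError("non-3-D image")
        if grid.shape != mask.shape:
            raise ValueError(f"grid shape {grid.shape} != mask shape {mask.shape}")
        mask = (mask != 0).astype(np.uint8)
        grid = np.where(mask > 0, grid, 0.0)
        inside = grid[mask > 0]
        if inside.size:
            if self.kind == "p" and (np.any(inside <= 0) or np.any(inside > 1)):
                raise ValueError("p-map values must lie in (0, 1]")
            if self.kind == "percent" and (np.any(inside < 0) or np.any(inside > 100)):
                raise ValueError("percent-map values must lie in [0, 100]")
        self.grid = grid
        self.mask = mask
        self.affine = _check_affine(self.affine)

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


@dataclass
class AnalysisConfig:
    """All tunable thresholds and hyperparameters of the pipelines.

    Defaults: one-tailed voxel p < 0.005 for SVR mapping, voxel p < 0.001
    for the network-map GLM, cluster FWE alpha 0.05 with 5000 permutations,
    lesion-overlap minimum of 5 patients, 60% disconnection cutoff, 10%
    gray-matter probability floor, 0.5 mm framewise-displacement censoring,
    a 0.01-0.08 Hz band-pass, 5 mm FWHM smoothing and a 9 mm seed sphere.
    SVR hyperparameters (C=30, gamma=5, epsilon=0.1, RBF) are conventional
    defaults for this method; a linear kernel is available for oracle tests.
    """

    svr_voxel_p: float = 0.005
    lnsm_voxel_p: float = 0.001
    cluster_fwe_alpha: float = 0.05
    n_permutations: int = 5000
    min_lesion_overlap: int = 5
    disconnection_cutoff_percent: float = 60.0
    gm_probability_threshold: float = 0.10
    fd_threshold_mm: float = 0.5
    bandpass_hz: tuple = (0.01, 0.08)
    smoothing_fwhm_mm: float = 5.0
    sphere_diameter_mm: float = 9.0
    hads_cutoff: int = 10
    hads_cutoff_secondary: int = 7
    svr_c: float = 30.0
    svr_gamma: float = 5.0
    svr_epsilon: float = 0.1
    svr_kernel: str = "rbf"
    svr_max_iter: int = 10000
    cluster_connectivity: int = 26
    nds_positive_only: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("svr_voxel_p", "lnsm_voxel_p", "cluster_fwe_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name}={v} outside (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.min_lesion_overlap < 1:
            raise ValueError("min_lesion_overlap must be >= 1")
        if not 0 < self.disconnection_cutoff_percent <= 100:
            raise ValueError("disconnection_cutoff_percent outside (0, 100]")
        if not 0 <= self.gm_probability_threshold <= 1:
            raise ValueError("gm_probability_threshold outside [0, 1]")
        lo, hi = self.bandpass_hz
        if not 0 < lo < hi:
            raise ValueError("bandpass_hz must satisfy 0 < low < high")
        self.bandpass_hz = (float(lo), float(hi))
        if self.cluster_connectivity not in (6, 18, 26):
            raise ValueError("cluster_connectivity must be 6, 18 or 26")
        if self.svr_kernel not in ("rbf", "linear"):
            raise ValueError("svr_kernel must be 'rbf' or 'linear'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bandpass_hz"] = list(d["bandpass_hz"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "bandpass_hz" in d:
            d["bandpass_hz"] = tuple(d["bandpass_hz"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


class CohortTable:
    """Per-patient behavioral table: HADS-D scores, covariates, exclusion flags."""

    REQUIRED = ("patient_id", "hads_d")
    COVARIATES = ("age", "sex", "nihss", "barthel")

    def __init__(self, df: pd.DataFrame, cutoff: int = 10):
        df = df.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"cohort table missing required column {col!r}")
        df["patient_id"] = df["patient_id"].astype(str)
        if df["patient_id"].duplicated().any():
            dup = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
            raise ValueError(f"duplicate patient_id: {dup}")
        if "excluded" not in df.columns:
            df["excluded"] = False
        if "exclusion_reason" not in df.columns:
            df["exclusion_reason"] = ""
        missing = df["hads_d"].isna()
        if missing.any():
            df.loc[missing, "excluded"] = True
            df.loc[missing, "exclusion_reason"] = "missing hads_d"
        scored = df.loc[~missing, "hads_d"]
        if len(scored) and ((scored < 0) | (scored > 21)).any():
            raise ValueError("hads_d out of range 0-21")
        df["group_label"] = np.where(
            df["hads_d"] > cutoff, "depressed", "not_depressed"
        )
        df.loc[missing, "group_label"] = ""
        self.df = df.reset_index(drop=True)
        self.cutoff = int(cutoff)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def patient_ids(self) -> list:
        return self.df["patient_id"].tolist()

    def included(self) -> pd.DataFrame:
        return self.df[~self.df["excluded"].astype(bool)].reset_index(drop=True)

    def exclude(self, patient_id: str, reason: str) -> None:
        sel = self.df["patient_id"] == str(patient_id)
        if not sel.any():
            raise KeyError(f"unknown patient_id {patient_id!r}")
        self.df.loc[sel, "excluded"] = True
        self.df.loc[sel, "exclusion_reason"] = reason

    def hads_d(self, ids=None) -> np.ndarray:
        df = self.df if ids is None else self.df.set_index("patient_id").loc[list(ids)].reset_index()
        return df["hads_d"].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def read_mask_volume(path) -> LesionMask:
    """Load a NIfTI lesion mask, binarizing any non-{0,1} values with a warning."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # noqa: BLE001 - rewrap for a uniform error surface
        raise IOError(f"unreadable file: {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim == 4 and data.shape[3] == 1 else data
    if data.ndim != 3:
        raise ValueError("non-3-D image")
    vals = np.unique(data)
    if not np.all(np.isin(vals, (0, 1))):
        logger.warning("mask %s has values outside {0,1}; binarizing (nonzero -> 1)", path)
    grid = (data != 0).astype(np.uint8)
    return LesionMask(patient_id=Path(path).name.split(".")[0], grid=grid, affine=img.affine)


def write_mask_volume(mask: LesionMask, path) -> None:
    img = nib.Nifti1Image(mask.grid.astype(np.uint8), mask.affine)
    img.header["descrip"] = b"lsmpipe lesion mask"
    nib.save(img, str(path))


def read_stat_volume(path, kind: str = None, mask: np.ndarray = None) -> StatMap:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim != 3:
        raise ValueError("non-3-D image")
    if kind is None:
        desc = img.header["descrip"].tobytes().decode("ascii", "ignore")
        for tok in desc.strip("\x00").split(";"):
            if tok.startswith("kind="):
                kind = tok[5:]
        if kind is None:
            raise ValueError(f"no stat kind in header of {path}; pass kind=")
    if mask is None:
        mask = np.ones(data.shape, dtype=np.uint8)
    return StatMap(grid=data, mask=mask, kind=kind, affine=img.affine)


def write_stat_volume(stat: StatMap, path, config: AnalysisConfig = None) -> None:
    """Write a StatMap as float32 NIfTI; kind (and seed) go into the header
    description, the full config into a JSON sidecar."""
    img = nib.Nifti1Image(stat.grid.astype(np.float32), stat.affine)
    desc = f"kind={stat.kind}"
    if config is not None:
        desc += f";seed={config.rng_seed}"
    img.header["descrip"] = desc.encode("ascii")[:79]
    try:
        nib.save(img, str(path))
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"unwritable path: {path}: {exc}") from exc
    if config is not None:
        sidecar = Path(str(path)).with_suffix("").with_suffix("")
        Path(str(sidecar) + ".json").write_text(json.dumps(config.to_dict(), indent=2))


def read_cohort_table(path, cutoff: int = 10) -> CohortTable:
    """Read a CSV/TSV cohort table; group label is depressed iff hads_d > cutoff."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    return CohortTable(df, cutoff=cutoff)


def require_same_geometry(*items) -> None:
    """Raise unless all grids share shape and affine (no implicit resampling)."""
    shapes = [np.asarray(i.grid).shape for i in items]
    affines = [i.affine for i in items]
    if any(s != shapes[0] for s in shapes):
        raise ValueError(f"geometry mismatch: shapes {shapes}")
    if any(not np.allclose(a, affines[0], atol=1e-6) for a in affines):
        raise ValueError("geometry mismatch: affines differ")
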