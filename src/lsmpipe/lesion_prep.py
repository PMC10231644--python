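"""Shared lesion preparation: resampling, coverage masking, volumes,
gray-matter restriction and exclusion accounting."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_model import LesionMask, StatMap, require_same_geometry

logger = logging.getLogger("lsmpipe")


@dataclass
class CoverageMask:
    """Voxels damaged in at least `min_overlap` patients, plus the patients
    excluded for lying entirely outside that mask."""

    mask: np.ndarray
    overlap_count: np.ndarray
    min_overlap: int
    n_input_masks: int
    excluded_ids: list = field(default_factory=list)  # (patient_id, reason)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def resample_mask(mask: LesionMask, target_voxel_mm: float) -> LesionMask:
    """Block-mean downsample to an integer multiple of the source voxel size,
    thresholding at 0.5 with ties -> 1 (majority rule preserving small lesions)."""
    src = mask.voxel_size_mm
    if not np.allclose(src, src[0], rtol=1e-4):
        raise ValueError("resample_mask requires isotropic source voxels")
    ratio = target_voxel_mm / src[0]
    f = int(round(ratio))
    if abs(ratio - f) > 1e-6 or f < 1:
        raise ValueError(f"non-integer ratio: {target_voxel_mm} / {src[0]:.4f}")
    if f == 1:
        return LesionMask(mask.patient_id, mask.grid.copy(), mask.affine.copy())
    grid = mask.grid
    pad = [(0, (-s) % f) for s in grid.shape]
    grid = np.pad(grid, pad)
    s = grid.shape
    blocks = grid.reshape(s[0] // f, f, s[1] // f, f, s[2] // f, f).astype(float)
    mean = blocks.mean(axis=(1, 3, 5))
    out = (mean >= 0.5).astype(np.uint8)
    affine = mask.affine.copy()
    affine[:3, :3] *= f
    # new voxel (0,0,0) center sits at the mean of the f^3 source centers
    affine[:3, 3] += mask.affine[:3, :3] @ (np.full(3, (f - 1) / 2.0))
    return LesionMask(mask.patient_id, out, affine)


def build_coverage_mask(masks: list, min_overlap: int) -> CoverageMask:
    """Threshold the lesion-overlap count map at min_overlap; flag patients
    whose lesion has no voxel inside the result."""
    if len(masks) < min_overlap:
        raise ValueError(f"need >= {min_overlap} masks, got {len(masks)}")
    require_same_geometry(*masks)
    count = np.zeros(masks[0].grid.shape, dtype=np.int32)
    for m in masks:
        count += m.grid
    cov = (count >= min_overlap).astype(np.uint8)
    excluded = []
    for m in masks:
        if not np.any(m.grid.astype(bool) & cov.astype(bool)):
            excluded.append((m.patient_id, "no voxels in coverage mask"))
    if excluded:
        logger.info("coverage mask: excluded %d of %d patients", len(excluded), len(masks))
    return CoverageMask(
        mask=cov, overlap_count=count, min_overlap=int(min_overlap),
        n_input_masks=len(masks), excluded_ids=excluded,
    )


def lesion_volume_ml(mask: LesionMask) -> float:
    """Set-voxel count times voxel volume, in milliliters."""
    voxel_mm3 = float(np.prod(mask.voxel_size_mm))
    return mask.n_voxels * voxel_mm3 / 1000.0


def gray_matter_roi(mask: LesionMask, gm_prob: StatMap, threshold: float = 0.10):
    """Restrict a lesion to voxels with gray-matter probability >= threshold.

    Returns (roi_mask, excluded) — an empty intersection marks the patient
    excluded as a pure white-matter lesion.
    """
    if mask.grid.shape != gm_prob.grid.shape:
        raise ValueError("geometry mismatch")
    if not np.allclose(mask.affine, gm_prob.affine, atol=1e-6):
        raise ValueError("geometry mismatch: affines differ")
    gm = np.asarray(gm_prob.grid, dtype=float)
    if gm.max() > 1.0 + 1e-6:
        raise ValueError("gm_prob must lie in [0, 1]")
    roi = (mask.grid.astype(bool) & (gm >= threshold)).astype(np.uint8)
    excluded = roi.sum() == 0
    if excluded:
        logger.info("patient %s: pure white matter lesion (empty GM ROI)", mask.patient_id)
    return LesionMask(mask.patient_id, roi, mask.affine.copy()) if not excluded else None, excluded


def exclusion_report(stages: dict) -> pd.DataFrame:
    """Flatten {stage: [(patient_id, reason), ...]} into a tidy CSV-ready table."""
    rows = [
        {"patient_id": pid, "stage": stage, "reason": reason}
        for stage, pairs in stages.items()
        for pid, reason in pairs
    ]
    return pd.DataFrame(rows, columns=["patient_id", "stage", "reason"])
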