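"""Structural disconnection maps from lesion masks and normative tractograms.

A lesion "disconnects" a streamline when the streamline passes through it;
the per-subject visitation maps of disconnected streamlines are overlapped
across normative subjects into a 0-100% map, then binarized at a cutoff
(default >= 60%).  The binary maps feed the same SVR mapping machinery as
raw lesions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_model import LesionMask, StatMap, require_same_geometry


@dataclass
class Tractogram:
    """One normative subject's streamlines: polylines of world-mm points."""

    subject_id: str
    streamlines: list

    def __post_init__(self) -> None:
        for i, line in enumerate(self.streamlines):
            pts = np.asarray(line, dtype=float)
            if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
                raise ValueError(f"streamline {i}: need >= 2 points of dim 3")
            if not np.all(np.isfinite(pts)):
                raise ValueError(f"streamline {i}: non-finite points")
            self.streamlines[i] = pts

    def __len__(self) -> int:
        return len(self.streamlines)


@dataclass
class DisconnectomeMap:
    """Percent-of-subjects disconnection map plus its binarized form."""

    patient_id: str
    percent: StatMap
    binary: StatMap = None
    n_subjects: int = 0
    excluded: bool = False
    exclusion_reason: str = ""


def write_tractogram(tract: Tractogram, path) -> None:
    """Whitespace-delimited point list: one `x y z` line per point, blank line
    between streamlines, `#` comment lines allowed."""
    with open(path, "w") as fh:
        fh.write(f"# tractogram subject={tract.subject_id} n={len(tract)}\n")
        for line in tract.streamlines:
            for p in line:
                fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
            fh.write("\n")


def read_tractogram(path) -> Tractogram:
    subject_id = Path(path).name.split(".")[0]
    streamlines, current = [], []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if line.startswith("#"):
            continue
        if not line:
            if current:
                streamlines.append(np.asarray(current, dtype=float))
                current = []
            continue
        current.append([float(tok) for tok in line.split()])
    if current:
        streamlines.append(np.asarray(current, dtype=float))
    if not streamlines:
        raise ValueError(f"empty tractogram file {path}")
    return Tractogram(subject_id=subject_id, streamlines=streamlines)


def _segment_voxels(p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    """All voxels a segment passes through, in continuous voxel coordinates
    where voxel i spans [i-0.5, i+0.5).  Found by splitting the segment at
    every half-integer plane crossing so no voxel is skipped."""
    d = p1 - p0
    ts = [0.0, 1.0]
    for ax in range(3):
        if abs(d[ax]) < 1e-12:
            continue
        lo, hi = sorted((p0[ax], p1[ax]))
        k = np.arange(np.ceil(lo - 0.5), np.floor(hi + 0.5) + 1) + 0.5
        ts.extend(((k - p0[ax]) / d[ax]).tolist())
    ts = np.unique(np.clip(np.asarray(ts), 0.0, 1.0))
    mids = (ts[:-1] + ts[1:]) / 2.0
    pts = p0[None, :] + mids[:, None] * d[None, :]
    vox = np.round(pts).astype(np.int64)
    return np.unique(vox, axis=0)


def streamline_voxels(points_world: np.ndarray, affine: np.ndarray, shape) -> np.ndarray:
    """Voxel indices traversed by a polyline (segment-grid traversal),
    restricted to the grid."""
    inv = np.linalg.inv(affine)
    vox_pts = points_world @ inv[:3, :3].T + inv[:3, 3]
    chunks = [_segment_voxels(vox_pts[i], vox_pts[i + 1]) for i in range(len(vox_pts) - 1)]
    vox = np.unique(np.concatenate(chunks, axis=0), axis=0)
    shape = np.asarray(shape)
    keep = np.all((vox >= 0) & (vox < shape), axis=1)
    return vox[keep]


def subject_disconnection(
    lesion: LesionMask, tract: Tractogram, mode: str = "traversal"
) -> np.ndarray:
    """Binary visitation map of all streamlines passing through the lesion.

    mode='traversal' (default) counts a streamline as hit if any traversed
    voxel is lesioned; mode='vertex' tests only the polyline vertices.
    Either way the output marks all voxels traversed by hit streamlines.
    """
    if len(tract) == 0:
        raise ValueError("empty tractogram")
    if mode not in ("traversal", "vertex"):
        raise ValueError(f"unknown mode {mode!r}")
    shape = lesion.grid.shape
    out = np.zeros(shape, dtype=np.uint8)
    lesioned = lesion.grid.astype(bool)
    inv = np.linalg.inv(lesion.affine)
    for line in tract.streamlines:
        vox = streamline_voxels(line, lesion.affine, shape)
        if vox.size == 0:
            continue
        if mode == "vertex":
            vpts = np.round(line @ inv[:3, :3].T + inv[:3, 3]).astype(np.int64)
            keep = np.all((vpts >= 0) & (vpts < np.asarray(shape)), axis=1)
            vpts = vpts[keep]
            hit = vpts.size > 0 and lesioned[vpts[:, 0], vpts[:, 1], vpts[:, 2]].any()
        else:
            hit = lesioned[vox[:, 0], vox[:, 1], vox[:, 2]].any()
        if hit:
            out[vox[:, 0], vox[:, 1], vox[:, 2]] = 1
    return out


def aggregate_percent(per_subject_maps: list, affine: np.ndarray, patient_id: str = "") -> DisconnectomeMap:
    """Overlap per-subject binary maps into percent-of-subjects values."""
    if len(per_subject_maps) < 2:
        raise ValueError("need >= 2 subjects")
    shapes = {np.asarray(m).shape for m in per_subject_maps}
    if len(shapes) != 1:
        raise ValueError(f"geometry mismatch: shapes {shapes}")
    stack = np.stack([np.asarray(m, dtype=bool) for m in per_subject_maps])
    percent = 100.0 * stack.sum(axis=0) / stack.shape[0]
    pm = StatMap(percent.astype(np.float32), np.ones(percent.shape, dtype=np.uint8),
                 "percent", affine)
    return DisconnectomeMap(patient_id=patient_id, percent=pm, n_subjects=stack.shape[0])


def binarize_cutoff(
    dmap: DisconnectomeMap, cutoff_percent: float, coverage_mask: np.ndarray = None
) -> DisconnectomeMap:
    """Binarize at percent >= cutoff (inclusive).  If a coverage mask is given
    and the binary map has no voxel inside it, the patient is flagged excluded
    (small lesions for which tracking yields no meaningful disconnectome)."""
    if not 0 < cutoff_percent <= 100:
        raise ValueError("cutoff must lie in (0, 100]")
    binary = (dmap.percent.grid >= cutoff_percent).astype(np.uint8)
    bm = StatMap(binary.astype(np.float32), np.ones(binary.shape, dtype=np.uint8),
                 "overlap_count", dmap.percent.affine)
    out = DisconnectomeMap(
        patient_id=dmap.patient_id, percent=dmap.percent, binary=bm,
        n_subjects=dmap.n_subjects,
    )
    if coverage_mask is not None and not np.any(binary.astype(bool) & coverage_mask.astype(bool)):
        out.excluded = True
        out.exclusion_reason = "no voxels in coverage mask"
    return out


def patient_disconnectome(
    lesion: LesionMask,
    tractograms: list,
    cutoff_percent: float = 60.0,
    mode: str = "traversal",
) -> DisconnectomeMap:
    """Full per-patient pipeline: per-subject disconnection -> percent overlap
    -> binarization."""
    maps = [subject_disconnection(lesion, t, mode=mode) for t in tractograms]
    agg = aggregate_percent(maps, lesion.affine, patient_id=lesion.patient_id)
    return binarize_cutoff(agg, cutoff_percent)
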