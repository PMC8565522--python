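"""From streamlines to per-network CC connection-count and probability maps.

A streamline contributes to network n's map iff (a) both endpoints fall in
(2-mm-dilated) label-n voxels, (b) its endpoints lie in opposite hemispheres
(world x sign, midsagittal plane at x = 0), and (c) its voxel path intersects
the CC mask — the homotopic reading of "connecting network n through the CC".
Heterotopic streamlines (endpoints in two different networks) are rejected
and tallied in the QC log, as are same-hemisphere and CC-missing ones.

For each accepted streamline, every *distinct* CC voxel on its path increments
the count FN(s, v, n) by one — a voxel visited twice by a looping streamline
counts once. Voxel traversal densifies the polyline to a point spacing of a
quarter of the smallest voxel dimension and maps points to nearest voxel
centers; this is checked against a brute-force oracle in the test suite.

Normalization divides the counts at each voxel by their sum over networks,
P(s, v, n) = FN(s, v, n) / sum_n FN(s, v, n), yielding a unit-sum probability
profile on the support (voxels any accepted streamline visited).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

from .grid import Grid

__all__ = [
    "ConnectionMap", "ProbabilityMap", "QCLog",
    "dilate_labels", "voxel_path", "assign_streamline",
    "count_connections", "normalize",
]


def dilate_labels(labels: np.ndarray, radius_mm: float,
                  voxel_size=(2.0, 2.0, 2.0)) -> np.ndarray:
    """Dilate every label by a Euclidean ball of physical radius ``radius_mm``.

    Overlapping dilations are resolved to the nearer original label, distance
    ties to the lower label index; original labels are always preserved.
    """
    if radius_mm < 0:
        raise ValueError("dilation radius must be nonnegative")
    labels = np.asarray(labels)
    out = labels.copy()
    if radius_mm == 0:
        return out
    present = np.unique(labels)
    present = present[present > 0]
    best = np.full(labels.shape, np.inf)
    assign = np.zeros(labels.shape, dtype=labels.dtype)
    for lab in present:  # ascending: ties keep the lower label
        dist = ndimage.distance_transform_edt(labels != lab, sampling=voxel_size)
        take = (dist <= radius_mm + 1e-9) & (dist < best)
        best[take] = dist[take]
        assign[take] = lab
    grow = (labels == 0) & (assign > 0)
    out[grow] = assign[grow]
    return out


def voxel_path(streamline: np.ndarray, grid: Grid) -> np.ndarray:
    """Distinct voxel indices traversed by one streamline, (m, 3) ints.

    The polyline is resampled to a spacing of a quarter of the smallest voxel
    dimension, points are mapped to nearest voxel centers (points outside the
    grid are clipped), and duplicates are removed.
    """
    pts = np.asarray(streamline, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
        raise ValueError("streamline must be an (n>=2, 3) array of world-mm points")
    step = 0.25 * grid.min_voxel_size
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if (seg > step).any():
        dense = [pts[:1]]
        for a, b, d in zip(pts[:-1], pts[1:], seg):
            n = max(1, int(np.ceil(d / step)))
            t = np.linspace(0.0, 1.0, n + 1)[1:, None]
            dense.append(a + t * (b - a))
        pts = np.vstack(dense)
    inv = np.linalg.inv(grid.affine)
    idx = np.rint(pts @ inv[:3, :3].T + inv[:3, 3]).astype(np.int64)
    np.clip(idx, 0, np.asarray(grid.shape) - 1, out=idx)
    return np.unique(idx, axis=0)


@dataclass
class QCLog:
    """Streamline acceptance tallies for one subject."""

    accepted: dict[int, int] = field(default_factory=dict)
    rejected_heterotopic: int = 0
    rejected_same_hemisphere: int = 0
    rejected_unlabeled_endpoint: int = 0
    rejected_no_cc: int = 0

    @property
    def n_accepted(self) -> int:
        return sum(self.accepted.values())

    @property
    def n_rejected(self) -> int:
        return (self.rejected_heterotopic + self.rejected_same_hemisphere
                + self.rejected_unlabeled_endpoint + self.rejected_no_cc)

    def as_dict(self) -> dict:
        return {
            "accepted_per_network": {str(k): v for k, v in sorted(self.accepted.items())},
            "n_accepted": self.n_accepted,
            "rejected": {
                "heterotopic": self.rejected_heterotopic,
                "same_hemisphere": self.rejected_same_hemisphere,
                "unlabeled_endpoint": self.rejected_unlabeled_endpoint,
                "no_cc_intersection": self.rejected_no_cc,
            },
        }


@dataclass
class ConnectionMap:
    """Per-subject, per-network CC streamline counts FN(s, v, n)."""

    subject_id: str
    counts: np.ndarray  # (nx, ny, nz, K) nonnegative ints
    k: int
    grid: Grid
    qc: QCLog = field(default_factory=QCLog)

    def __post_init__(self) -> None:
        if self.counts.ndim != 4 or self.counts.shape[3] != self.k:
            raise ValueError("counts must be (nx, ny, nz, K)")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")


@dataclass
class ProbabilityMap:
    """Per-subject connection probabilities P(s, v, n), unit-sum on support."""

    subject_id: str
    probs: np.ndarray  # (nx, ny, nz, K) in [0, 1]
    support_mask: np.ndarray  # (nx, ny, nz) bool, sum_n FN > 0
    k: int
    grid: Grid


def _assign(path_idx: np.ndarray, streamline: np.ndarray, cc_mask: np.ndarray,
            dilated_labels: np.ndarray, grid: Grid, qc: QCLog | None) -> int | None:
    pts = np.asarray(streamline, dtype=float)
    inv = np.linalg.inv(grid.affine)
    ends = np.rint(pts[[0, -1]] @ inv[:3, :3].T + inv[:3, 3]).astype(np.int64)
    inside = ((ends >= 0) & (ends < np.asarray(grid.shape))).all(axis=1)
    labs = [int(dilated_labels[tuple(e)]) if ok else 0 for e, ok in zip(ends, inside)]
    if labs[0] == 0 or labs[1] == 0:
        if qc:
            qc.rejected_unlabeled_endpoint += 1
        return None
    if labs[0] != labs[1]:
        if qc:
            qc.rejected_heterotopic += 1
        return None
    if pts[0, 0] * pts[-1, 0] >= 0:  # same world-x sign (or on the midplane)
        if qc:
            qc.rejected_same_hemisphere += 1
        return None
    if not cc_mask[tuple(path_idx.T)].any():
        if qc:
            qc.rejected_no_cc += 1
        return None
    return labs[0]


def assign_streamline(streamline: np.ndarray, cc_mask: np.ndarray,
                      dilated_labels: np.ndarray, grid: Grid) -> int | None:
    """Network id for one streamline under the homotopic rule, else None."""
    path = voxel_path(streamline, grid)  # validates the streamline
    return _assign(path, streamline, np.asarray(cc_mask, bool),
                   np.asarray(dilated_labels), grid, None)


def _as_volume(vol, grid: Grid, name: str) -> np.ndarray:
    if isinstance(vol, (nib.Nifti1Image, nib.Nifti2Image)):
        if not np.allclose(vol.affine, grid.affine, atol=1e-4):
            raise ValueError(f"{name}: affine does not match the tractogram grid")
        return np.asarray(vol.dataobj)
    return np.asarray(vol)


def count_connections(tractogram, cc_mask, dilated_labels, grid: Grid,
                      k: int | None = None, subject_id: str = "") -> ConnectionMap:
    """Count, per network, the distinct CC voxels each accepted streamline crosses.

    ``cc_mask`` and ``dilated_labels`` may be arrays on ``grid`` or NIfTI
    images (whose affines must then match the grid).
    """
    cc = _as_volume(cc_mask, grid, "cc_mask").astype(bool)
    labels = _as_volume(dilated_labels, grid, "dilated_labels")
    if cc.shape != tuple(grid.shape) or labels.shape != tuple(grid.shape):
        raise ValueError("mask/label volumes do not match the grid shape")
    if k is None:
        k = int(labels.max())
    qc = QCLog(accepted={n: 0 for n in range(1, k + 1)})
    counts = grid.new_volume(dtype=np.int32, channels=k)
    for sl in tractogram:
        path = voxel_path(sl, grid)
        label = _assign(path, sl, cc, labels, grid, qc)
        if label is None:
            continue
        qc.accepted[label] += 1
        on_cc = path[cc[tuple(path.T)]]
        counts[on_cc[:, 0], on_cc[:, 1], on_cc[:, 2], label - 1] += 1
    counts[~cc] = 0  # counts are defined over the CC mask only
    return ConnectionMap(subject_id=subject_id, counts=counts, k=k, grid=grid, qc=qc)


def normalize(cmap: ConnectionMap) -> ProbabilityMap:
    """P(s, v, n) = FN(s, v, n) / sum_n FN(s, v, n); zero off the support."""
    total = cmap.counts.sum(axis=3)
    support = total > 0
    probs = np.zeros(cmap.counts.shape, dtype=np.float64)
    np.divide(cmap.counts, total[..., None], out=probs, where=support[..., None])
    return ProbabilityMap(subject_id=cmap.subject_id, probs=probs,
                          support_mask=support, k=cmap.k, grid=cmap.grid)
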