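"""Synthetic common-space geometry: CC mask, network labels, crossing zones.

The phantom stands in for the anatomy the real analysis takes from structural
MRI: a binary corpus-callosum mask confined to a midsagittal slab, a bilateral
cortical label volume for the K functional networks (left/right decided by the
sign of world x, midsagittal plane at x = 0), and — as ground truth that real
data never provides — the per-network CC crossing zones, laid out
anterior->posterior along the callosal midline following the known topography
(limbic/default-mode through rostrum and genu, frontoparietal /
ventral-attention / somatomotor through the body, dorsal-attention and visual
through the splenium).

Construction is purely geometric and fully deterministic; the ``seed``
argument exists for interface symmetry with the other generators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import Grid
from .networks import anterior_order, network_names

__all__ = ["Phantom", "make_phantom"]

DEFAULT_GRID_SHAPE = (32, 44, 20)
DEFAULT_VOXEL_SIZE = 2.0


@dataclass(frozen=True)
class Phantom:
    """Common-space geometry for one synthetic study.

    Attributes
    ----------
    grid : Grid
        Shape, voxel size (mm) and voxel->world affine.
    k : int
        Number of functional networks (7 or 17).
    cc_mask : ndarray of bool
        Binary corpus-callosum mask (a slab around the midsagittal plane).
    network_labels : ndarray of int16
        Cortical target labels, 0 = background, 1..K = network; every label
        appears in both hemispheres (homotopic pairs).
    zone_labels : ndarray of int16
        Ground-truth CC crossing zones, 0 = no zone; nonzero only inside
        ``cc_mask``; zones are pairwise disjoint by construction.
    """

    grid: Grid
    k: int
    cc_mask: np.ndarray
    network_labels: np.ndarray
    zone_labels: np.ndarray

    @property
    def names(self) -> tuple[str, ...]:
        return network_names(self.k)

    def crossing_zone(self, label: int) -> np.ndarray:
        """Binary mask of network ``label``'s ground-truth crossing zone."""
        if not 1 <= label <= self.k:
            raise ValueError(f"label must be in 1..{self.k}, got {label}")
        return self.zone_labels == label

    def zone_union(self) -> np.ndarray:
        return self.zone_labels > 0

    def hemisphere_sign(self) -> np.ndarray:
        """Sign of world x per voxel (-1 left, +1 right)."""
        i = np.arange(self.grid.shape[0])
        x = (self.grid.affine[0, 0] * i + self.grid.affine[0, 3])
        return np.sign(x)[:, None, None] * np.ones(self.grid.shape)


def make_phantom(
    k: int = 7,
    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE,
    voxel_size: float | tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    seed: int | None = None,
) -> Phantom:
    """Build the synthetic CC/network geometry.

    Parameters
    ----------
    k : {7, 17}
        Number of functional networks.
    grid_shape : (nx, ny, nz)
        Grid size in voxels; nx must be even so the midsagittal plane falls
        between voxel columns. The grid must be large enough to hold K
        disjoint crossing zones with one-voxel anterior-posterior gaps.
    voxel_size : float or triple
        Physical voxel size in mm (default 2 mm isotropic).
    seed : int, optional
        Unused (construction is deterministic); accepted so all generators
        share one call signature.
    """
    if k not in (7, 17):
        raise ValueError(f"supported network counts are 7 and 17, got {k}")
    if isinstance(voxel_size, (int, float)):
        voxel_size = (float(voxel_size),) * 3
    grid = Grid(tuple(grid_shape), voxel_size)
    nx, ny, nz = grid.shape
    if nx % 2:
        raise ValueError("nx must be even so that no voxel center sits on x=0")
    if nx < 20 or nz < 14:
        raise ValueError(f"grid {grid.shape} too small for cortical targets and CC slab")

    # --- CC slab: the two voxel columns closest to the midsagittal plane ---
    slab_i = (nx // 2 - 1, nx // 2)
    y_margin = max(2, round(ny * 0.11))
    cc_j = np.arange(y_margin, ny - y_margin)
    cc_k = np.arange(nz // 2 - 3, nz // 2 + 3)

    cc_mask = np.zeros(grid.shape, dtype=bool)
    cc_mask[np.ix_(slab_i, cc_j, cc_k)] = True

    # --- crossing zones: K disjoint anterior->posterior blocks with 1-voxel gaps
    avail = len(cc_j)
    depth = (avail - (k - 1)) // k
    if depth < 1:
        raise ValueError(
            f"grid too small to place {k} disjoint crossing zones: "
            f"{avail} CC slices available, need at least {2 * k - 1}"
        )
    leftover = avail - (k * depth + k - 1)
    zone_k = cc_k[1:-1]  # zones sit in the central z band of the slab
    zone_labels = np.zeros(grid.shape, dtype=np.int16)
    # anterior = +y = high j; the first label in anterior_order gets the top block
    j_top = int(cc_j[-1]) - leftover // 2
    for label in anterior_order(k):
        block = np.arange(j_top - depth + 1, j_top + 1)
        zone_labels[np.ix_(slab_i, block, zone_k)] = label
        j_top -= depth + 1  # one-voxel gap between consecutive zones

    # --- bilateral cortical target blobs, homotopic in world x ---
    labels = np.zeros(grid.shape, dtype=np.int16)
    blob_x_left = np.arange(2, 5)
    blob_x_right = nx - 1 - blob_x_left[::-1]
    blob_k = np.arange(nz // 2 - 2, nz // 2 + 1)
    half_y = min(depth, 3)
    for label in range(1, k + 1):
        jz = np.argwhere(zone_labels == label)[:, 1]
        jc = int(np.round(jz.mean()))
        blob_j = np.arange(jc, jc + half_y) if half_y < 3 else np.arange(jc - 1, jc + 2)
        for bx in (blob_x_left, blob_x_right):
            labels[np.ix_(bx, blob_j, blob_k)] = label

    return Phantom(grid=grid, k=k, cc_mask=cc_mask,
                   network_labels=labels, zone_labels=zone_labels)
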