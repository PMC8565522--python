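"""Synthetic homotopic streamline bundles and TCK round-trip I/O.

Each on-target streamline of network n is a smooth polyline (point spacing at
most half the smallest voxel dimension) running from a left-hemisphere
network-n cortical blob, straight through one assigned voxel of network n's
ground-truth CC crossing zone, to the homotopic right-hemisphere blob.
Crossing voxels are cycled through a per-network shuffled list, so a bundle at
least as large as the zone covers every zone voxel.

Two jitters control realism. ``endpoint_jitter_mm`` (Gaussian SD) perturbs the
endpoints and so modulates how many streamlines survive endpoint/label
acceptance downstream — inter-subject variability shows up in the counts.
``crossing_jitter_mm`` (uniform, default a quarter voxel) wiggles the crossing
point *within* its assigned voxel, so the ground-truth topography itself stays
exact; pushing it past half a voxel deliberately blurs zone borders.

Off-target streamlines either arc within one hemisphere (never touching the
CC) or cross the CC but terminate outside every cortical label; both must be
rejected by streamline-to-network assignment.
"""

from __future__ import annotations

import numpy as np
import nibabel as nib

from .phantom import Phantom

__all__ = ["make_tractogram", "save_tck", "load_tck"]


def _densify(waypoints: np.ndarray, step: float) -> np.ndarray:
    """Piecewise-linear resampling with inter-point spacing <= step."""
    pts = [waypoints[:1]]
    for a, b in zip(waypoints[:-1], waypoints[1:]):
        seg = np.linalg.norm(b - a)
        n = max(1, int(np.ceil(seg / step)))
        t = np.linspace(0.0, 1.0, n + 1)[1:, None]
        pts.append(a + t * (b - a))
    return np.vstack(pts)


def _blob_voxels(phantom: Phantom, label: int, side: int) -> np.ndarray:
    """Voxel indices of the label blob in hemisphere ``side`` (-1 left, +1 right)."""
    idx = np.argwhere(phantom.network_labels == label)
    if idx.size == 0:
        raise ValueError(f"network label {label} absent from the phantom")
    x = phantom.grid.voxel_centers_world(idx)[:, 0]
    sel = idx[np.sign(x) == side]
    if sel.size == 0:
        raise ValueError(f"network label {label} has no voxels in hemisphere {side:+d}")
    return sel


def make_tractogram(
    phantom: Phantom,
    bundle_counts: dict[int, int],
    endpoint_jitter_mm: float = 1.0,
    off_target_fraction: float = 0.05,
    crossing_jitter_mm: float = 0.5,
    seed: int | np.random.SeedSequence | None = None,
) -> list[np.ndarray]:
    """Generate a subject tractogram (list of (n_points, 3) world-mm arrays)."""
    if endpoint_jitter_mm < 0:
        raise ValueError("endpoint jitter must be nonnegative")
    if not 0.0 <= off_target_fraction < 1.0:
        raise ValueError("off_target_fraction must lie in [0, 1)")
    for label in bundle_counts:
        if not 1 <= label <= phantom.k or not (phantom.network_labels == label).any():
            raise ValueError(f"requested bundle for label {label} absent from the phantom")

    rng = np.random.default_rng(seed)
    grid = phantom.grid
    vox = np.asarray(grid.voxel_size)
    step = 0.5 * grid.min_voxel_size

    cc_idx = np.argwhere(phantom.cc_mask)
    slab_x_max = np.abs(grid.voxel_centers_world(cc_idx)[:, 0]).max() + 0.5 * vox[0]
    x_edge = slab_x_max + vox[0]

    def endpoint(voxels: np.ndarray) -> np.ndarray:
        v = voxels[rng.integers(len(voxels))]
        center = grid.voxel_centers_world(v[None])[0]
        p = center + rng.uniform(-0.49, 0.49, 3) * vox
        if endpoint_jitter_mm > 0:
            p = p + rng.normal(0.0, endpoint_jitter_mm, 3)
        return p

    streamlines: list[np.ndarray] = []
    for label, count in sorted(bundle_counts.items()):
        left = _blob_voxels(phantom, label, -1)
        right = _blob_voxels(phantom, label, +1)
        zone_idx = np.argwhere(phantom.crossing_zone(label))
        # distinct (j, k) crossing columns; the x traversal covers the slab
        jk = np.unique(zone_idx[:, 1:], axis=0)
        order = rng.permutation(len(jk))
        for m in range(count):
            j, kk = jk[order[m % len(jk)]]
            cy, cz = grid.voxel_centers_world(np.array([[0, j, kk]]))[0][1:]
            if crossing_jitter_mm > 0:
                cy += rng.uniform(-crossing_jitter_mm, crossing_jitter_mm)
                cz += rng.uniform(-crossing_jitter_mm, crossing_jitter_mm)
            wp = np.array([
                endpoint(left),
                [-x_edge, cy, cz],
                [x_edge, cy, cz],
                endpoint(right),
            ])
            streamlines.append(_densify(wp, step))

    n_on = len(streamlines)
    n_off = int(round(off_target_fraction / (1.0 - off_target_fraction) * n_on))
    labels_present = sorted(bundle_counts)
    for m in range(n_off):
        if m % 2 == 0 and labels_present:
            # same-hemisphere arc between two blobs; bows laterally, misses the CC
            side = -1 if (m // 2) % 2 == 0 else 1
            l1, l2 = rng.choice(labels_present, 2)
            p1 = endpoint(_blob_voxels(phantom, l1, side))
            p2 = endpoint(_blob_voxels(phantom, l2, side))
            bow = (p1 + p2) / 2
            bow[0] = side * (abs(bow[0]) + 4 * vox[0])
            streamlines.append(_densify(np.array([p1, bow, p2]), step))
        else:
            # crosses the CC like a homotopic fiber but ends in background
            label = labels_present[m % len(labels_present)] if labels_present else 1
            zone_idx = np.argwhere(phantom.crossing_zone(label))
            j, kk = zone_idx[rng.integers(len(zone_idx))][1:]
            cy, cz = grid.voxel_centers_world(np.array([[0, j, kk]]))[0][1:]
            p1 = endpoint(_blob_voxels(phantom, label, -1))
            p2 = endpoint(_blob_voxels(phantom, label, +1))
            p2[2] += 6 * vox[2]  # shifted above the cortical blobs -> no label
            wp = np.array([p1, [-x_edge, cy, cz], [x_edge, cy, cz], p2])
            streamlines.append(_densify(wp, step))

    perm = rng.permutation(len(streamlines))
    return [streamlines[i] for i in perm]


def save_tck(streamlines: list[np.ndarray], path) -> None:
    """Write streamlines (world mm) to a TCK file."""
    tg = nib.streamlines.Tractogram(streamlines, affine_to_rasmm=np.eye(4))
    nib.streamlines.save(tg, str(path))


def load_tck(path) -> list[np.ndarray]:
    """Read a TCK file back into a list of float64 (n_points, 3) arrays."""
    tf = nib.streamlines.load(str(path))
    return [np.asarray(s, dtype=np.float64) for s in tf.streamlines]
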