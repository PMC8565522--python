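"""Label dilation, streamline assignment, counting and normalization."""

import numpy as np
import nibabel as nib
import pytest

from callosum.connectivity import (ConnectionMap, assign_streamline,
                                   count_connections, dilate_labels, normalize,
                                   voxel_path)
from callosum.grid import Grid


# ---------------------------------------------------------------- dilation

class TestDilateLabels:
    def test_zero_radius_is_identity(self, phantom):
        out = dilate_labels(phantom.network_labels, 0.0, phantom.grid.voxel_size)
        assert np.array_equal(out, phantom.network_labels)

    def test_single_voxel_grows_to_plus_shape(self):
        """2-mm ball around one labeled voxel at 2-mm spacing: exactly the
        center and its six face neighbors are within center distance <= 2."""
        labels = np.zeros((11, 11, 11), dtype=np.int16)
        labels[5, 5, 5] = 1
        out = dilate_labels(labels, 2.0, (2.0, 2.0, 2.0))
        expected = {(5, 5, 5), (4, 5, 5), (6, 5, 5), (5, 4, 5),
                    (5, 6, 5), (5, 5, 4), (5, 5, 6)}
        assert set(map(tuple, np.argwhere(out == 1))) == expected

    def test_original_labels_preserved(self):
        labels = np.zeros((8, 8, 8), dtype=np.int16)
        labels[2, 4, 4] = 2
        labels[3, 4, 4] = 1  # adjacent competing labels
        out = dilate_labels(labels, 4.0, (2.0, 2.0, 2.0))
        assert out[2, 4, 4] == 2 and out[3, 4, 4] == 1

    def test_distance_tie_goes_to_lower_label(self):
        labels = np.zeros((9, 5, 5), dtype=np.int16)
        labels[2, 2, 2] = 2
        labels[6, 2, 2] = 1
        out = dilate_labels(labels, 4.0, (2.0, 2.0, 2.0))
        assert out[4, 2, 2] == 1  # equidistant (4 mm) from both seeds

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            dilate_labels(np.zeros((3, 3, 3), int), -1.0)


# ----------------------------------------------------- helper constructions

def _blob_center(phantom, label, side):
    idx = np.argwhere(phantom.network_labels == label)
    x = phantom.grid.voxel_centers_world(idx)[:, 0]
    sel = idx[np.sign(x) == side]
    return phantom.grid.voxel_centers_world(sel[len(sel) // 2][None])[0]


def _zone_yz(phantom, label):
    idx = np.argwhere(phantom.crossing_zone(label))
    c = phantom.grid.voxel_centers_world(idx[len(idx) // 2][None])[0]
    return c[1], c[2]


def _homotopic(phantom, label, loop=False, dodge_cc=False):
    left = _blob_center(phantom, label, -1)
    right = _blob_center(phantom, label, +1)
    y, z = _zone_yz(phantom, label)
    if dodge_cc:
        z_high = 12.0  # above the CC slab
        wp = [left, [-4.0, y, z_high], [4.0, y, z_high], right]
    elif loop:
        wp = [left, [-4.0, y, z], [4.0, y, z], [-4.0, y, z], [4.0, y, z], right]
    else:
        wp = [left, [-4.0, y, z], [4.0, y, z], right]
    return np.asarray(wp, dtype=float)


# ---------------------------------------------------------------- assignment

class TestAssignStreamline:
    def test_homotopic_streamline_gets_its_network(self, phantom, dilated):
        for label in (1, 4, 7):
            sl = _homotopic(phantom, label)
            assert assign_streamline(sl, phantom.cc_mask, dilated, phantom.grid) == label

    def test_same_hemisphere_rejected(self, phantom, dilated):
        left1 = _blob_center(phantom, 1, -1)
        left2 = _blob_center(phantom, 2, -1)
        sl = np.array([left1, (left1 + left2) / 2 + [-6, 0, 0], left2])
        assert assign_streamline(sl, phantom.cc_mask, dilated, phantom.grid) is None

    def test_heterotopic_endpoints_rejected(self, phantom, dilated):
        left = _blob_center(phantom, 1, -1)
        right = _blob_center(phantom, 2, +1)
        y, z = _zone_yz(phantom, 1)
        sl = np.array([left, [-4.0, y, z], [4.0, y, z], right])
        assert assign_streamline(sl, phantom.cc_mask, dilated, phantom.grid) is None

    def test_path_missing_cc_rejected(self, phantom, dilated):
        sl = _homotopic(phantom, 1, dodge_cc=True)
        assert assign_streamline(sl, phantom.cc_mask, dilated, phantom.grid) is None

    def test_degenerate_streamline_rejected(self, phantom, dilated):
        with pytest.raises(ValueError):
            assign_streamline(np.array([[0.0, 0.0, 0.0]]), phantom.cc_mask,
                              dilated, phantom.grid)


# ------------------------------------------------------------------ counting

class TestCountConnections:
    def test_two_streamlines_increment_twice(self, phantom, dilated):
        sl = _homotopic(phantom, 1)
        cmap = count_connections([sl, sl.copy()], phantom.cc_mask, dilated,
                                 phantom.grid, k=7)
        assert cmap.counts[..., 0].max() == 2

    def test_looping_streamline_counts_each_voxel_once(self, phantom, dilated):
        loop = _homotopic(phantom, 1, loop=True)
        cmap = count_connections([loop], phantom.cc_mask, dilated, phantom.grid, k=7)
        assert cmap.counts.max() == 1

    def test_streamline_order_invariance(self, phantom, dilated, clean_tractogram):
        fwd = count_connections(clean_tractogram, phantom.cc_mask, dilated,
                                phantom.grid, k=7)
        rev = count_connections(clean_tractogram[::-1], phantom.cc_mask, dilated,
                                phantom.grid, k=7)
        assert np.array_equal(fwd.counts, rev.counts)

    def test_adding_a_streamline_never_decreases_counts(self, phantom, dilated,
                                                        clean_tractogram):
        base = count_connections(clean_tractogram, phantom.cc_mask, dilated,
                                 phantom.grid, k=7)
        more = count_connections([*clean_tractogram, _homotopic(phantom, 3)],
                                 phantom.cc_mask, dilated, phantom.grid, k=7)
        assert (more.counts >= base.counts).all()

    def test_counts_confined_to_cc_mask(self, phantom, dilated, clean_tractogram):
        cmap = count_connections(clean_tractogram, phantom.cc_mask, dilated,
                                 phantom.grid, k=7)
        assert (cmap.counts[~phantom.cc_mask] == 0).all()

    def test_mismatched_affine_rejected(self, phantom, dilated):
        bad_affine = phantom.grid.affine.copy()
        bad_affine[0, 3] += 5.0
        bad = nib.Nifti1Image(phantom.cc_mask.astype(np.uint8), bad_affine)
        with pytest.raises(ValueError, match="affine"):
            count_connections([_homotopic(phantom, 1)], bad, dilated,
                              phantom.grid, k=7)


# ------------------------------------------------------------- rasterization

def test_voxel_path_matches_brute_force_point_mapping(phantom):
    """Fast traversal equals nearest-voxel mapping of points densified at a
    quarter of the voxel size, over 100 random polylines."""
    grid = phantom.grid
    lo = grid.voxel_centers_world(np.array([[0, 0, 0]]))[0]
    hi = grid.voxel_centers_world(np.array([np.array(grid.shape) - 1]))[0]
    inv = np.linalg.inv(grid.affine)
    rng = np.random.default_rng(123)

    def brute(sl):
        step = 0.25 * grid.min_voxel_size
        pts = []
        for a, b in zip(sl[:-1], sl[1:]):
            n = max(1, int(np.ceil(np.linalg.norm(b - a) / step)))
            for t in np.linspace(0.0, 1.0, n + 1):
                pts.append(a + t * (b - a))
        cont = np.asarray(pts) @ inv[:3, :3].T + inv[:3, 3]
        idx = np.floor(cont + 0.5).astype(int)
        idx = np.clip(idx, 0, np.asarray(grid.shape) - 1)
        return set(map(tuple, idx))

    for _ in range(100):
        n_wp = rng.integers(2, 6)
        sl = rng.uniform(lo, hi, size=(n_wp, 3))
        fast = set(map(tuple, voxel_path(sl, grid)))
        assert fast == brute(sl)


# ---------------------------------------------------------------- normalize

class TestNormalize:
    @staticmethod
    def _map_from_counts(vec):
        grid = Grid((2, 2, 2), (2.0, 2.0, 2.0))
        counts = np.zeros((2, 2, 2, 7), dtype=np.int32)
        counts[0, 0, 0] = vec
        return normalize(ConnectionMap("s", counts, 7, grid))

    def test_ratio_formula(self):
        pmap = self._map_from_counts([3, 1, 0, 0, 0, 0, 0])
        assert np.allclose(pmap.probs[0, 0, 0], [0.75, 0.25, 0, 0, 0, 0, 0])

    def test_zero_voxel_excluded_from_support(self):
        pmap = self._map_from_counts([0] * 7)
        assert not pmap.support_mask.any()
        assert (pmap.probs == 0).all()

    def test_unit_sum_on_support(self, clean_probability_map):
        pm = clean_probability_map
        sums = pm.probs.sum(axis=3)
        assert np.allclose(sums[pm.support_mask], 1.0, atol=1e-9)
        assert np.all(sums[~pm.support_mask] == 0.0)
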