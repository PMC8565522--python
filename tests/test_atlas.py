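"""Population atlas averaging, hard segmentation, Dice, split-half."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from callosum.atlas import PopulationAtlas, build_atlas, dice, hard_segment, split_half
from callosum.cohort import make_cohort
from callosum.connectivity import ProbabilityMap
from callosum.grid import Grid

GRID = Grid((3, 3, 3), (2.0, 2.0, 2.0))


def _pmap(channel_vectors, k=7, grid=GRID, sid="s"):
    """Probability map whose first voxels carry the given channel vectors."""
    probs = np.zeros((*grid.shape, k))
    flat = probs.reshape(-1, k)
    for i, vec in enumerate(channel_vectors):
        flat[i] = vec
    support = probs.sum(axis=3) > 0
    return ProbabilityMap(sid, probs, support, k, grid)


class TestBuildAtlas:
    def test_voxelwise_mean(self):
        e1 = [1, 0, 0, 0, 0, 0, 0]
        e2 = [0, 1, 0, 0, 0, 0, 0]
        atlas = build_atlas([_pmap([e1]), _pmap([e2])])
        assert np.allclose(atlas.probs.reshape(-1, 7)[0],
                           [0.5, 0.5, 0, 0, 0, 0, 0])
        assert atlas.n_subjects == 2

    def test_single_subject_identity(self, clean_probability_map):
        atlas = build_atlas([clean_probability_map])
        assert np.array_equal(atlas.probs, clean_probability_map.probs)

    def test_subject_order_invariance(self):
        maps = [_pmap([[1, 0, 0, 0, 0, 0, 0]]), _pmap([[0, 0.4, 0.6, 0, 0, 0, 0]]),
                _pmap([[0.2, 0.8, 0, 0, 0, 0, 0]])]
        a = build_atlas(maps)
        b = build_atlas(maps[::-1])
        assert np.allclose(a.probs, b.probs)

    def test_heterogeneous_inputs_rejected(self):
        other = _pmap([[1, 0, 0, 0, 0, 0, 0, 0, 0]], k=9)
        with pytest.raises(ValueError, match="heterogeneous"):
            build_atlas([_pmap([[1, 0, 0, 0, 0, 0, 0]]), other])
        with pytest.raises(ValueError):
            build_atlas([])

    def test_channel_sums_bounded_by_one(self, phantom, clean_probability_map):
        atlas = build_atlas([clean_probability_map], template_cc_mask=phantom.cc_mask)
        sums = atlas.probs.sum(axis=3)
        assert sums.max() <= 1.0 + 1e-12
        assert atlas.template_voxels == int(phantom.cc_mask.sum())


class TestHardSegment:
    def test_argmax_tie_and_zero_rules(self):
        atlas = build_atlas([_pmap([[0.2, 0.5, 0.3, 0, 0, 0, 0],
                                    [0.5, 0.5, 0, 0, 0, 0, 0],
                                    [0] * 7])])
        labels = hard_segment(atlas).reshape(-1)
        assert labels[0] == 2      # plain argmax
        assert labels[1] == 1      # tie resolves to the lower network index
        assert labels[2] == 0      # all-zero voxel stays unlabeled

    def test_relabeling_permutes_consistently(self):
        rng = np.random.default_rng(5)
        probs = rng.random((3, 3, 3, 7))
        probs /= probs.sum(axis=3, keepdims=True)
        perm = rng.permutation(7)
        a1 = PopulationAtlas(probs, 7, GRID, 1, 27)
        a2 = PopulationAtlas(probs[..., perm], 7, GRID, 1, 27)
        l1, l2 = hard_segment(a1), hard_segment(a2)
        # label in the permuted atlas names the same channel as the original
        assert np.array_equal(perm[l2 - 1], l1 - 1)


class TestDice:
    def test_identical_volumes_give_one(self):
        labels = np.tile(np.arange(8).reshape(2, 2, 2), (2, 2, 2))
        rep = dice(labels, labels.copy())
        assert all(v == 1.0 for v in rep.per_label.values())
        assert rep.weighted_mean == 1.0 and rep.unweighted_mean == 1.0

    def test_disjoint_supports_give_zero(self):
        a = np.zeros((4, 4, 4), int)
        b = np.zeros((4, 4, 4), int)
        a[:2] = 1
        b[2:] = 1
        assert dice(a, b).per_label[1] == 0.0

    def test_half_overlap(self):
        a = np.zeros((4, 4, 4), int)
        b = np.zeros((4, 4, 4), int)
        a[0, 0, :4] = 1
        b[0, 0, 2:4] = 1
        b[0, 1, :2] = 1
        assert dice(a, b).per_label[1] == pytest.approx(0.5)

    def test_absent_label_omitted_and_reported(self):
        a = np.ones((2, 2, 2), int)
        rep = dice(a, a, labels=[1, 5])
        assert rep.omitted_labels == [5]
        assert 5 not in rep.per_label

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 4, size=(5, 5, 5))
        b = rng.integers(0, 4, size=(5, 5, 5))
        ra, rb = dice(a, b), dice(b, a)
        assert ra.per_label == rb.per_label
        assert ra.weighted_mean == rb.weighted_mean
        assert all(0.0 <= v <= 1.0 for v in ra.per_label.values())


class TestSplitHalf:
    def test_identical_maps_give_unit_dice(self, phantom, clean_probability_map):
        cohort = make_cohort(12, seed=0)
        maps = [clean_probability_map] * 12
        res = split_half(cohort, maps, seed=1, template_cc_mask=phantom.cc_mask)
        assert all(v == 1.0 for v in res.report.per_label.values())
        assert abs(len(res.half_ids[0]) - len(res.half_ids[1])) <= 1

    def test_same_seed_reproduces_split(self, phantom, clean_probability_map):
        cohort = make_cohort(20, seed=2)
        maps = [clean_probability_map] * 20
        r1 = split_half(cohort, maps, seed=9, template_cc_mask=phantom.cc_mask)
        r2 = split_half(cohort, maps, seed=9, template_cc_mask=phantom.cc_mask)
        assert r1.half_ids == r2.half_ids

    def test_halves_are_age_and_sex_matched(self, phantom, clean_probability_map):
        cohort = make_cohort(200, "table1", seed=3)
        maps = [clean_probability_map] * 200
        res = split_half(cohort, maps, seed=4, template_cc_mask=phantom.cc_mask)
        by_id = cohort.set_index("id")
        strata = [by_id.loc[ids].groupby(["age_group", "sex"]).size()
                  for ids in res.half_ids]
        diff = (strata[0] - strata[1]).abs().fillna(1)
        assert (diff <= 1).all()

    def test_too_few_subjects_rejected(self, clean_probability_map):
        cohort = make_cohort(3, seed=0)
        with pytest.raises(ValueError, match="four"):
            split_half(cohort, [clean_probability_map] * 3)
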