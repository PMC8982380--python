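"""Segmentation and measurement contracts: QC flags, the two integration
methods, background-region selection, linearity."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acvu import quantify, synth


def _column_nucleus(nz=7):
    """A synthetic 1-voxel-wide nucleus spanning nz slices, for toy stacks."""
    voxels = np.zeros((nz, 5, 5), bool)
    voxels[:, 2, 2] = True
    return voxels


def _toy_stack(gfp_by_slice, mch_by_slice, inside=False):
    nz = len(gfp_by_slice)
    gfp = np.zeros((nz, 5, 5))
    mch = np.zeros((nz, 5, 5))
    gfp[:, 2, 2] = gfp_by_slice
    mch[:, 2, 2] = mch_by_slice
    mask = np.zeros((nz, 5, 5), bool)
    if inside:
        mask[:, :, :3] = True
    return synth.ImageStack(gfp=gfp, mcherry=mch, larva_mask=mask)


def _nucleus_from(voxels, mch):
    zc, yc, xc = [c.mean() for c in np.nonzero(voxels)]
    per_slice = [
        (int(z), float(mch[z][voxels[z]].sum()))
        for z in np.nonzero(voxels.any(axis=(1, 2)))[0]
    ]
    return quantify.SegmentedNucleus(
        label=1, voxels=voxels, centroid=(xc, yc, zc), per_slice_mcherry=per_slice
    )


class TestSegmentation:
    def test_four_separated_nuclei_recovered_within_one_voxel(self, four_nuclei):
        stack, _ = synth.make_animal_image(four_nuclei, seed=3)
        segs, flags = quantify.segment_nuclei(stack, expected_n=4)
        assert flags == []
        assert len(segs) == 4
        matching = quantify.match_segments_to_truth(segs, four_nuclei, max_dist=1.0)
        assert len(matching) == 4  # every truth matched within 1 voxel

    def test_touching_nuclei_flagged_merged_against_truth(self):
        a = synth.NucleusTruth(
            cell_id="alpha1", sister_id="beta1", center=(20.0, 24.0, 8.0), radius=2.5,
            true_gfp_total=5000.0, true_mcherry_total=30000.0,
        )
        b = synth.NucleusTruth(
            cell_id="alpha2", sister_id="beta2", center=(21.8, 24.0, 8.0), radius=2.5,
            true_gfp_total=5000.0, true_mcherry_total=30000.0,
        )
        stack, _ = synth.make_animal_image([a, b], seed=4)
        segs, _ = quantify.segment_nuclei(stack, expected_n=2)
        flags = quantify.qc_from_truth(segs, [a, b])
        assert quantify.FLAG_MERGED in flags or quantify.FLAG_FRAGMENTED in flags

    def test_empty_mcherry_gives_dim_flag(self):
        stack = synth.ImageStack(
            gfp=np.zeros((6, 16, 16)),
            mcherry=np.zeros((6, 16, 16)),
            larva_mask=np.ones((6, 16, 16), bool),
        )
        segs, flags = quantify.segment_nuclei(stack)
        assert segs == []
        assert flags == [quantify.FLAG_DIM]


class TestMethodA:
    def test_simple_subtraction_arithmetic(self):
        # nucleus column sums 1000 AU of GFP; background region holds 100 AU
        gfp = np.zeros((4, 5, 5))
        gfp[:, 2, 1] = 250.0  # nucleus column (inside larva)
        gfp[:, 2, 4] = 25.0  # background column
        mch = np.zeros((4, 5, 5))
        mch[:, 2, 1] = 10.0
        mask = np.zeros((4, 5, 5), bool)
        mask[:, :, :3] = True
        stack = synth.ImageStack(gfp=gfp, mcherry=mch, larva_mask=mask)
        voxels = np.zeros((4, 5, 5), bool)
        voxels[:, 2, 1] = True
        nucleus = _nucleus_from(voxels, mch)
        bg = np.zeros((5, 5), bool)
        bg[2, 4] = True
        m = quantify.measure_sumproj_bgcorr(stack, nucleus, bg)
        assert m.gfp_value == pytest.approx(900.0)

    def test_uniform_background_shift_cancels(self, four_nuclei):
        stack, _ = synth.make_animal_image(four_nuclei, background_level=0.0, noise=synth.NOISE_OFF)
        segs, flags = quantify.segment_nuclei(stack)
        assert not flags
        shifted = synth.ImageStack(
            gfp=stack.gfp + 7.5,
            mcherry=stack.mcherry,
            larva_mask=stack.larva_mask,
        )
        for seg in segs:
            bg = quantify.select_background_region(stack, seg.boundary_2d)
            v0 = quantify.measure_sumproj_bgcorr(stack, seg, bg).gfp_value
            v1 = quantify.measure_sumproj_bgcorr(shifted, seg, bg).gfp_value
            assert v1 == pytest.approx(v0, rel=1e-6)

    def test_truth_support_recovers_total_within_1pct(self):
        nuc = synth.NucleusTruth(
            cell_id="alpha1", sister_id="beta1", center=(24.0, 24.0, 8.0), radius=2.5,
            true_gfp_total=10000.0, true_mcherry_total=30000.0,
        )
        stack, _ = synth.make_animal_image([nuc], background_level=0.0, noise=synth.NOISE_OFF)
        support = stack.mcherry > 0
        nucleus = _nucleus_from(support, stack.mcherry)
        bg = quantify.select_background_region(stack, nucleus.boundary_2d)
        m = quantify.measure_sumproj_bgcorr(stack, nucleus, bg)
        assert m.gfp_value == pytest.approx(10000.0, rel=0.01)

    def test_bg_region_inside_larva_rejected(self):
        stack = _toy_stack([1] * 4, [1] * 4, inside=True)
        voxels = _column_nucleus(4)
        nucleus = _nucleus_from(voxels, stack.mcherry)
        bad = np.zeros((5, 5), bool)
        bad[2, 2] = True  # inside the larva
        with pytest.raises(ValueError, match="larva"):
            quantify.measure_sumproj_bgcorr(stack, nucleus, bad)

    def test_negative_value_retained_and_flagged(self):
        stack = _toy_stack([0, 0, 0], [5, 5, 5], inside=True)
        stack.gfp[:, 2, 4] = 10.0  # bright background column outside larva
        nucleus = _nucleus_from(_column_nucleus(3), stack.mcherry)
        bg = np.zeros((5, 5), bool)
        bg[2, 4] = True
        m = quantify.measure_sumproj_bgcorr(stack, nucleus, bg)
        assert m.gfp_value == pytest.approx(-30.0)
        assert quantify.FLAG_NEGATIVE in m.flags


class TestMethodB:
    def test_worked_example_selects_central_slices(self):
        stack = _toy_stack([0, 2, 4, 6, 4, 2, 0], [1, 5, 9, 10, 9, 5, 1])
        nucleus = _nucleus_from(_column_nucleus(7), stack.mcherry)
        m = quantify.measure_top5(stack, nucleus)
        assert m.z_used == (1, 2, 3, 4, 5)
        assert m.gfp_value == pytest.approx(18.0)

    def test_exactly_five_slices_uses_all(self):
        stack = _toy_stack([1, 2, 3, 4, 5], [9, 9, 9, 9, 9])
        nucleus = _nucleus_from(_column_nucleus(5), stack.mcherry)
        m = quantify.measure_top5(stack, nucleus)
        assert m.gfp_value == pytest.approx(15.0)
        assert quantify.FLAG_SHORT_SPAN not in m.flags

    def test_uniform_mcherry_ties_select_lowest_z(self):
        stack = _toy_stack([1, 2, 3, 4, 5, 6, 7], [4, 4, 4, 4, 4, 4, 4])
        nucleus = _nucleus_from(_column_nucleus(7), stack.mcherry)
        m = quantify.measure_top5(stack, nucleus)
        assert m.z_used == (0, 1, 2, 3, 4)
        assert m.gfp_value == pytest.approx(1 + 2 + 3 + 4 + 5)

    def test_short_span_uses_all_slices_and_flags(self):
        stack = _toy_stack([3, 3, 3], [1, 2, 3])
        nucleus = _nucleus_from(_column_nucleus(3), stack.mcherry)
        m = quantify.measure_top5(stack, nucleus)
        assert m.gfp_value == pytest.approx(9.0)
        assert quantify.FLAG_SHORT_SPAN in m.flags
        assert m.n_slices == 3

    @given(mch=st.lists(st.integers(0, 100), min_size=1, max_size=8))
    @settings(max_examples=200, deadline=None)
    def test_selection_attains_bruteforce_optimum(self, mch):
        """Top-5-by-slice selection maximises total mCherry over 5-subsets."""
        per_slice = list(enumerate(mch))
        selected = quantify.top5_slices(per_slice)
        k = min(5, len(mch))
        assert len(selected) == k
        best = max(
            sum(mch[i] for i in comb)
            for comb in itertools.combinations(range(len(mch)), k)
        )
        assert sum(mch[i] for i in selected) == best


class TestBackgroundRegion:
    def test_region_placed_outside_mask(self):
        mask = np.zeros((4, 20, 20), bool)
        mask[:, :, :10] = True  # left half inside larva
        stack = synth.ImageStack(
            gfp=np.zeros((4, 20, 20)), mcherry=np.zeros((4, 20, 20)), larva_mask=mask
        )
        fp = np.zeros((20, 20), bool)
        fp[:3, :3] = True
        region = quantify.select_background_region(stack, fp)
        assert region.sum() == 9
        assert not np.any(region & mask.any(axis=0))

    def test_full_frame_mask_raises(self):
        mask = np.ones((2, 8, 8), bool)
        stack = synth.ImageStack(
            gfp=np.zeros((2, 8, 8)), mcherry=np.zeros((2, 8, 8)), larva_mask=mask
        )
        fp = np.zeros((8, 8), bool)
        fp[0, 0] = True
        with pytest.raises(ValueError, match="no outside-larva region"):
            quantify.select_background_region(stack, fp)

    def test_area_preserved_for_irregular_footprint(self):
        mask = np.zeros((2, 12, 12), bool)
        mask[:, :, :4] = True
        stack = synth.ImageStack(
            gfp=np.zeros((2, 12, 12)), mcherry=np.zeros((2, 12, 12)), larva_mask=mask
        )
        fp = np.zeros((12, 12), bool)
        fp[0, 0], fp[1, 1], fp[2, 0] = True, True, True
        region = quantify.select_background_region(stack, fp)
        assert region.sum() == fp.sum()


class TestLinearity:
    @pytest.mark.parametrize("method", [quantify.METHOD_A, quantify.METHOD_B])
    def test_scaling_gfp_scales_measurements(self, four_nuclei, method):
        stack, _ = synth.make_animal_image(four_nuclei, background_level=0.0, noise=synth.NOISE_OFF)
        segs, _ = quantify.segment_nuclei(stack)
        scaled = synth.ImageStack(
            gfp=stack.gfp * 2.5, mcherry=stack.mcherry, larva_mask=stack.larva_mask
        )
        for seg in segs:
            if method == quantify.METHOD_A:
                bg = quantify.select_background_region(stack, seg.boundary_2d)
                v0 = quantify.measure_sumproj_bgcorr(stack, seg, bg).gfp_value
                v1 = quantify.measure_sumproj_bgcorr(scaled, seg, bg).gfp_value
            else:
                v0 = quantify.measure_top5(stack, seg).gfp_value
                v1 = quantify.measure_top5(scaled, seg).gfp_value
            assert v1 == pytest.approx(2.5 * v0, rel=1e-9)
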