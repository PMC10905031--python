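"""The watershed baseline pipeline stages on phantoms and built fixtures."""

import numpy as np
import pytest
from scipy import ndimage

from gland3d import (CandidateRegion, PhantomSpec, SegmentationParams,
                     SemanticMask, TwoChannelVolume, compose_mask,
                     filter_lumen_candidates, generate_case, plan_blocks,
                     segment_biopsy, segment_epithelium,
                     segment_lumen_candidates)
from gland3d.types import EPITHELIUM, LUMEN, STROMA

SPACING = (1.8, 1.8, 1.8)
STRUCT6 = ndimage.generate_binary_structure(3, 1)


@pytest.fixture(scope="module")
def bimodal_case(small_spec):
    """Phantom whose eosin channel is strictly bimodal (epithelium rendered at
    stroma brightness), isolating the lumen detector from the three-class
    histogram ambiguity of the full intensity model."""
    import dataclasses

    table = {"stroma": (80.0, 180.0), "epithelium": (200.0, 180.0),
             "lumen": (10.0, 10.0)}
    from gland3d import generate_case as _generate
    return _generate(dataclasses.replace(small_spec, intensity_table=table))


def _dense(candidates, shape):
    out = np.zeros(shape, dtype=bool)
    for reg in candidates:
        out[tuple(reg.voxels.T)] = True
    return out


class TestLumenCandidates:
    def test_every_true_lumen_found_with_high_dice(self, bimodal_case):
        cands = segment_lumen_candidates(bimodal_case.volume)
        truth_lumen = bimodal_case.truth.labels == LUMEN
        comp, n = ndimage.label(truth_lumen, structure=STRUCT6)
        assert n >= 1
        assert len(cands) >= n
        for i in range(1, n + 1):
            ref = comp == i
            best = 0.0
            hits = 0
            for reg in cands:
                pred = np.zeros(ref.shape, bool)
                pred[tuple(reg.voxels.T)] = True
                inter = np.count_nonzero(pred & ref)
                if inter:
                    hits += 1
                    best = max(best, 2 * inter / (pred.sum() + ref.sum()))
            assert hits == 1  # exactly one candidate overlaps each true lumen
            assert best > 0.9

    def test_candidates_are_disjoint(self, small_case):
        cands = segment_lumen_candidates(small_case.volume)
        total = sum(len(r.voxels) for r in cands)
        assert np.count_nonzero(_dense(cands, small_case.truth.shape)) == total

    def test_no_surviving_dark_structures_gives_empty_list(self):
        eosin = np.full((10, 10, 10), 200.0)
        eosin[5, 5, 5] = 150.0  # a single dark voxel, far below the volume floor
        nuclear = np.full((10, 10, 10), 80.0)
        vol = TwoChannelVolume(np.stack([nuclear, eosin]), SPACING)
        assert segment_lumen_candidates(vol, SegmentationParams(smoothing_sigma_um=0)) == []

    def test_speck_below_volume_floor_removed(self):
        eosin = np.full((16, 16, 16), 200.0)
        eosin[4:12, 4:12, 4:12] = 10.0       # big dark cube: kept
        eosin[14, 14, 14] = 10.0             # 1-voxel speck (5.8 um^3): dropped
        vol = TwoChannelVolume(np.stack([np.full_like(eosin, 80.0), eosin]), SPACING)
        cands = segment_lumen_candidates(vol, SegmentationParams(smoothing_sigma_um=0))
        assert len(cands) == 1
        assert len(cands[0].voxels) == 8 ** 3

    def test_constant_eosin_rejected(self):
        vol = TwoChannelVolume(np.full((2, 6, 6, 6), 50.0), SPACING)
        with pytest.raises(ValueError, match="constant"):
            segment_lumen_candidates(vol)


class TestEpithelium:
    def test_phantom_shell_recovered(self, small_case):
        epi = segment_epithelium(small_case.volume)
        ref = small_case.truth.labels == EPITHELIUM
        inter = np.count_nonzero(epi & ref)
        dice = 2 * inter / (epi.sum() + ref.sum())
        assert dice > 0.8

    def test_isolated_bright_shell_returned_exactly(self):
        nuclear = np.zeros((12, 12, 12))
        shell = np.zeros_like(nuclear, dtype=bool)
        shell[3:9, 3:9, 3:9] = True
        shell[4:8, 4:8, 4:8] = False
        nuclear[shell] = 200.0
        vol = TwoChannelVolume(np.stack([nuclear, np.full_like(nuclear, 100.0)]),
                               SPACING)
        epi = segment_epithelium(vol, SegmentationParams(
            smoothing_sigma_um=0, min_epithelium_volume_um3=500))
        assert np.array_equal(epi, shell)

    def test_constant_nuclear_rejected(self):
        vol = TwoChannelVolume(np.full((2, 6, 6, 6), 50.0), SPACING)
        with pytest.raises(ValueError, match="constant"):
            segment_epithelium(vol)


def _bar_candidate(shape=(3, 3, 8)):
    voxels = np.array([[1, 1, x] for x in range(1, 7)])  # 1x1x6 bar, all boundary
    return CandidateRegion(region_id=1, voxels=voxels,
                           volume_um3=len(voxels) * 1.8 ** 3)


class TestLumenFilter:
    def test_fully_enclosed_candidate_kept(self):
        reg = _bar_candidate()
        epi = np.ones((3, 3, 8), dtype=bool)
        epi[tuple(reg.voxels.T)] = False      # epithelium everywhere around
        kept = filter_lumen_candidates([reg], epi)
        assert len(kept) == 1
        assert kept[0].adjacency_fraction == 1.0

    def test_fully_exposed_candidate_eliminated(self):
        reg = _bar_candidate()
        kept = filter_lumen_candidates([reg], np.zeros((3, 3, 8), bool))
        assert kept == []

    def test_exactly_half_adjacent_boundary_is_kept(self):
        # 6 boundary voxels; epithelium placed over exactly three of them
        reg = _bar_candidate()
        epi = np.zeros((3, 3, 8), bool)
        epi[0, 1, 1:4] = True                 # face-neighbors of bar voxels x=1..3
        kept = filter_lumen_candidates([reg], epi)
        assert len(kept) == 1
        assert kept[0].adjacency_fraction == pytest.approx(0.5)
        assert len(kept[0].boundary_voxels) == 6

    def test_monotone_in_epithelium(self, rng):
        # growing the epithelium set never eliminates a previously kept candidate
        for _ in range(20):
            blob = rng.random((6, 6, 6)) < 0.25
            blob[3, 3, 3] = True
            lab, n = ndimage.label(blob, structure=STRUCT6)
            regs = [CandidateRegion(i, np.argwhere(lab == i), 0.0)
                    for i in range(1, n + 1)]
            epi_small = rng.random((6, 6, 6)) < 0.3
            epi_big = epi_small | (rng.random((6, 6, 6)) < 0.3)
            kept_small = {r.region_id for r in filter_lumen_candidates(regs, epi_small)}
            kept_big = {r.region_id for r in filter_lumen_candidates(regs, epi_big)}
            assert kept_small <= kept_big

    def test_geometry_mismatch_rejected(self):
        reg = _bar_candidate()
        with pytest.raises(ValueError, match="geometry|exceeds"):
            filter_lumen_candidates([reg], np.zeros((2, 2, 2), bool))


class TestComposeMask:
    def test_empty_inputs_give_all_stroma(self):
        m = compose_mask((4, 4, 4), SPACING, [], np.zeros((4, 4, 4), bool))
        assert (m.labels == STROMA).all()

    def test_lumen_precedence_over_epithelium(self):
        epi = np.zeros((4, 4, 4), bool)
        epi[1, 1, 1] = True
        reg = CandidateRegion(1, np.array([[1, 1, 1]]), 1.8 ** 3)
        m = compose_mask((4, 4, 4), SPACING, [reg], epi)
        assert m.labels[1, 1, 1] == LUMEN

    def test_no_background_inside_volume(self, small_case):
        pred = segment_biopsy(small_case.volume)
        assert set(np.unique(pred.labels)) <= {STROMA, EPITHELIUM, LUMEN}

    def test_histograms_close_to_truth_on_noise_free_phantom(self, bimodal_case):
        pred = segment_biopsy(bimodal_case.volume)
        want = bimodal_case.truth.class_counts()
        got = pred.class_counts()
        for cls in ("stroma", "epithelium", "lumen"):
            assert got[cls] == pytest.approx(want[cls], rel=0.10)


class TestSegmentBiopsy:
    def test_deterministic(self, small_case):
        a = segment_biopsy(small_case.volume)
        b = segment_biopsy(small_case.volume)
        assert np.array_equal(a.labels, b.labels)

    def test_blocked_agrees_outside_seam_bands(self, small_case):
        whole = segment_biopsy(small_case.volume)
        overlap = 24  # > gland shell diameter (~19 voxels)
        layout = plan_blocks(small_case.volume.shape, (40, 96, 60), (0, 0, overlap))
        assert layout.n_blocks == 2
        blocked = segment_biopsy(small_case.volume, layout=layout)
        diff = np.argwhere(blocked.labels != whole.labels)
        if len(diff):
            seam_x = layout.blocks[1][2][0]  # start of the second block
            assert np.abs(diff[:, 2] - seam_x).max() <= overlap

    def test_zero_overlap_emits_seam_warning(self, small_case):
        layout = plan_blocks(small_case.volume.shape, (40, 96, 48), (0, 0, 0))
        with pytest.warns(UserWarning, match="seam"):
            blocked = segment_biopsy(small_case.volume, layout=layout)
        assert set(np.unique(blocked.labels)) <= {STROMA, EPITHELIUM, LUMEN}

    def test_finer_input_auto_downsampled_to_working_resolution(self):
        spec = PhantomSpec(volume_shape=(64, 96, 96), spacing=(0.9, 0.9, 0.9),
                           n_glands=1, lumen_radius_um=8.0,
                           epithelium_thickness_um=5.4, n_decoys=1,
                           decoy_radius_um=7.0, branching_prob=0.0, seed=11)
        case = generate_case(spec)
        pred = segment_biopsy(case.volume)
        assert np.allclose(pred.spacing, (1.8, 1.8, 1.8))
        assert pred.shape == (32, 48, 48)
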