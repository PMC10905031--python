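"""Dice, 3D Hausdorff, gland-level evaluation and pairwise statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist
from scipy.stats import t as t_dist

from gland3d import (MetricReport, SemanticMask, VoxelSet, dice_coefficient,
                     evaluate_case, gland_mask, hausdorff_3d, pairwise_ttests,
                     summarize)
from gland3d.metrics import EmptySetError, boundary_voxels

SPACING = (1.8, 1.8, 1.8)


# ---------------------------------------------------------------------------
# independent oracles

def dice_oracle(A, B):
    a = {tuple(r) for r in A.coords}
    b = {tuple(r) for r in B.coords}
    return 2 * len(a & b) / (len(a) + len(b))


def boundary_oracle(coords):
    members = {tuple(r) for r in coords}
    offsets = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]
    out = [c for c in members
           if any((c[0] + dz, c[1] + dy, c[2] + dx) not in members
                  for dz, dy, dx in offsets)]
    return np.array(sorted(out), dtype=np.int64).reshape(-1, 3)


def hausdorff_oracle(A, B, mode):
    ca, cb = A.coords, B.coords
    if mode == "boundary":
        ca, cb = boundary_oracle(ca), boundary_oracle(cb)
    pa = ca * np.asarray(A.spacing)
    pb = cb * np.asarray(B.spacing)
    d = cdist(pa, pb)  # all-pairs distances: the literal sup-inf definition
    return max(d.min(axis=1).max(), d.min(axis=0).max())


def _random_voxel_set(rng, max_side=12):
    side = int(rng.integers(2, max_side + 1))
    n = int(rng.integers(1, side ** 3 // 2 + 2))
    coords = rng.integers(0, side, (n, 3))
    return VoxelSet(coords, SPACING)


# ---------------------------------------------------------------------------
# Dice

class TestDice:
    def test_identity_is_one(self, rng):
        A = VoxelSet(rng.integers(0, 6, (17, 3)), SPACING)
        assert dice_coefficient(A, A) == 1.0

    def test_disjoint_is_zero(self):
        A = VoxelSet([[0, 0, 0], [0, 0, 1]], SPACING)
        B = VoxelSet([[5, 5, 5]], SPACING)
        assert dice_coefficient(A, B) == 0.0

    def test_hand_counted_overlap(self):
        A = VoxelSet([[0, 0, 0], [0, 0, 1], [0, 0, 2], [0, 0, 3]], SPACING)
        B = VoxelSet([[0, 0, 1], [0, 0, 2], [0, 0, 3], [0, 1, 0], [0, 1, 1], [0, 1, 2]],
                     SPACING)
        assert dice_coefficient(A, B) == pytest.approx(2 * 3 / (4 + 6))  # 0.6

    def test_both_empty_signals(self):
        E = VoxelSet(np.empty((0, 3)), SPACING)
        with pytest.raises(EmptySetError):
            dice_coefficient(E, E)

    def test_matches_set_oracle_and_symmetry(self, rng):
        for _ in range(50):
            A, B = _random_voxel_set(rng), _random_voxel_set(rng)
            d = dice_coefficient(A, B)
            assert d == pytest.approx(dice_oracle(A, B), abs=1e-12)
            assert d == pytest.approx(dice_coefficient(B, A), abs=1e-12)
            assert 0.0 <= d <= 1.0


# ---------------------------------------------------------------------------
# Hausdorff

class TestHausdorff:
    def test_identity_is_zero(self, rng):
        A = _random_voxel_set(rng)
        assert hausdorff_3d(A, A) == 0.0
        assert hausdorff_3d(A, A, mode="full") == 0.0

    def test_single_pair_closed_form(self):
        A = VoxelSet([[0, 0, 0]], SPACING)
        B = VoxelSet([[0, 0, 3]], SPACING)
        assert hausdorff_3d(A, B) == pytest.approx(5.4)  # 3 voxels x 1.8 um

    @pytest.mark.parametrize("mode", ["boundary", "full"])
    def test_matches_brute_force_oracle(self, rng, mode):
        for _ in range(60):
            A, B = _random_voxel_set(rng), _random_voxel_set(rng)
            got = hausdorff_3d(A, B, mode=mode)
            assert got == pytest.approx(hausdorff_oracle(A, B, mode), abs=1e-9)
            assert got == pytest.approx(hausdorff_3d(B, A, mode=mode), abs=1e-12)

    def test_scales_linearly_with_spacing(self, rng):
        A = _random_voxel_set(rng)
        B = _random_voxel_set(rng)
        A2 = VoxelSet(A.coords, tuple(2 * s for s in SPACING))
        B2 = VoxelSet(B.coords, tuple(2 * s for s in SPACING))
        assert hausdorff_3d(A2, B2) == pytest.approx(2 * hausdorff_3d(A, B))

    def test_adding_shared_point_never_increases_directed_term(self, rng):
        # a point of B added to A contributes distance 0 in the A->B direction
        A, B = _random_voxel_set(rng), _random_voxel_set(rng)
        shared = B.coords[:1]
        A_plus = VoxelSet(np.vstack([A.coords, shared]), SPACING)
        pa, pb = A.points_um, B.points_um
        d_ab = cdist(pa, pb).min(axis=1).max()
        d_ab_plus = cdist(A_plus.points_um, pb).min(axis=1).max()
        assert d_ab_plus <= d_ab + 1e-12

    def test_empty_set_signals(self, rng):
        with pytest.raises(EmptySetError):
            hausdorff_3d(VoxelSet(np.empty((0, 3)), SPACING), _random_voxel_set(rng))

    def test_boundary_extraction_matches_oracle(self, rng):
        for _ in range(20):
            A = _random_voxel_set(rng, max_side=8)
            got = boundary_voxels(A.coords)
            want = boundary_oracle(A.coords)
            assert np.array_equal(np.unique(got, axis=0), want)


# ---------------------------------------------------------------------------
# gland-level protocol

class TestEvaluateCase:
    def _cube_mask(self, lo, hi, code, shape=(24, 24, 24)):
        labels = np.ones(shape, dtype=np.uint8)
        labels[lo:hi, lo:hi, lo:hi] = code
        return SemanticMask(labels, SPACING)

    def test_gland_mask_union_and_invariance(self):
        labels = np.ones((6, 6, 6), dtype=np.uint8)
        labels[0, 0, :4] = 2
        labels[1, 1, :3] = 3
        m = SemanticMask(labels, SPACING)
        assert len(gland_mask(m)) == 7
        swapped = labels.copy()
        swapped[labels == 2] = 3
        swapped[labels == 3] = 2
        assert np.array_equal(
            gland_mask(SemanticMask(swapped, SPACING)).coords, gland_mask(m).coords)
        assert len(gland_mask(SemanticMask(np.ones((4, 4, 4), np.uint8), SPACING))) == 0

    def test_identical_masks_score_perfectly(self):
        m = self._cube_mask(2, 22, 2)
        rows = evaluate_case(m, m, level="gland")
        assert rows.dice.item() == 1.0
        assert rows.hausdorff_um.item() == 0.0

    def test_eroded_cube_closed_form(self):
        # reference gland: 20^3 cube; prediction: the same cube eroded by one
        # voxel shell (18^3).  Dice is the volume ratio; the Hausdorff maximum
        # is attained at a cube corner: sqrt(3) voxel pitches.
        ref = self._cube_mask(2, 22, 2)
        pred = self._cube_mask(3, 21, 2)
        rows = evaluate_case(pred, ref, level="gland")
        assert rows.dice.item() == pytest.approx(2 * 18 ** 3 / (20 ** 3 + 18 ** 3))
        expected_hd = hausdorff_oracle(gland_mask(pred), gland_mask(ref), "boundary")
        assert expected_hd == pytest.approx(math.sqrt(3) * 1.8)
        assert rows.hausdorff_um.item() == pytest.approx(expected_hd)

    def test_per_class_levels(self):
        ref = self._cube_mask(2, 22, 3)
        rows = evaluate_case(ref, ref, level="per_class")
        assert set(rows.comparison) == {"stroma", "lumen"}
        assert (rows.dice == 1.0).all()

    def test_geometry_mismatch_and_empty_reference(self):
        a = self._cube_mask(2, 8, 2, shape=(12, 12, 12))
        b = self._cube_mask(2, 8, 2, shape=(14, 14, 14))
        with pytest.raises(ValueError, match="shape"):
            evaluate_case(a, b)
        stroma_only = SemanticMask(np.ones((12, 12, 12), np.uint8), SPACING)
        with pytest.raises(EmptySetError, match="reference"):
            evaluate_case(a, stroma_only)


# ---------------------------------------------------------------------------
# statistics

def pooled_t_oracle(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = (((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * t_dist.sf(abs(t), na + nb - 2)
    return t, p


def _tidy(groups):
    rows = []
    for method, vals in groups.items():
        for i, v in enumerate(vals):
            rows.append({"case": i, "method": method, "dice": v, "hausdorff_um": v})
    return pd.DataFrame(rows)


class TestPairwiseTTests:
    def test_identical_groups_no_difference(self):
        out = pairwise_ttests(_tidy({"a": [1, 2, 3], "b": [1, 2, 3]}), "a")
        assert (out.t == 0).all()
        assert np.allclose(out.p, 1.0)

    def test_shifted_fixture_closed_form(self):
        out = pairwise_ttests(_tidy({"ref": [1, 2, 3], "other": [2, 3, 4]}), "ref")
        row = out[out.metric == "dice"].iloc[0]
        assert row.t == pytest.approx(-1.2247448, abs=1e-6)
        assert row.p == pytest.approx(0.2878641, abs=1e-6)
        assert row.n == 3

    def test_matches_pooled_variance_oracle(self, rng):
        for _ in range(25):
            a = rng.normal(0.8, 0.1, size=int(rng.integers(3, 12)))
            b = rng.normal(0.75, 0.15, size=int(rng.integers(3, 12)))
            out = pairwise_ttests(_tidy({"m1": a, "m2": b}), "m1")
            t, p = pooled_t_oracle(a, b)
            row = out[out.metric == "dice"].iloc[0]
            assert row.t == pytest.approx(t, abs=1e-10)
            assert row.p == pytest.approx(p, abs=1e-10)

    def test_contract_violations(self):
        with pytest.raises(ValueError, match="unknown reference"):
            pairwise_ttests(_tidy({"a": [1, 2]}), "zzz")
        with pytest.raises(ValueError, match=">= 2"):
            pairwise_ttests(_tidy({"a": [1.0], "b": [1, 2]}), "a")


class TestSummarize:
    def test_single_case_aggregates_collapse(self, tmp_path):
        rep = MetricReport(per_case=_tidy({"m": [0.9]}))
        agg = summarize(rep, tmp_path)
        row = agg[agg.metric == "dice"].iloc[0]
        assert row["mean"] == row["min"] == row["max"] == 0.9
        assert (tmp_path / "per_case.csv").exists()
        assert (tmp_path / "metrics_boxplot.png").exists()

    def test_known_mean(self):
        vals = [0.7, 0.8, 0.9, 1.0]
        agg = summarize(MetricReport(per_case=_tidy({"m": vals})))
        assert agg[agg.metric == "dice"]["mean"].item() == pytest.approx(np.mean(vals))

    def test_empty_report_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize(MetricReport(per_case=pd.DataFrame(
                columns=["case", "method", "dice", "hausdorff_um"])))
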