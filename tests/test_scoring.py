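"""Agatston engine: threshold adaptation, slice scoring, volume totals."""

import numpy as np
import pytest

from cacscore.scoring import (
    AgatstonResult,
    ScoringConfig,
    adapted_threshold,
    cac_positive,
    density_weight,
    mean_roi_hu,
    score_slice,
    total_score,
)
from cacscore.volume import VoxelGrid

# ---------------------------------------------------------------------------
# Brute-force flood-fill oracle, independent of scipy.ndimage
# ---------------------------------------------------------------------------


def oracle_score_slice(slice_hu, pixel_area, threshold=130.0, min_area=1.0, connectivity=8):
    """Enumerate thresholded pixels and group them by explicit flood fill."""
    h, w = slice_hu.shape
    seen = np.zeros((h, w), bool)
    if connectivity == 8:
        steps = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    scores = []
    for i in range(h):
        for j in range(w):
            if seen[i, j] or slice_hu[i, j] < threshold:
                continue
            stack, comp = [(i, j)], []
            seen[i, j] = True
            while stack:
                ci, cj = stack.pop()
                comp.append((ci, cj))
                for di, dj in steps:
                    ni, nj = ci + di, cj + dj
                    if 0 <= ni < h and 0 <= nj < w and not seen[ni, nj] \
                            and slice_hu[ni, nj] >= threshold:
                        seen[ni, nj] = True
                        stack.append((ni, nj))
            area = len(comp) * pixel_area
            if area < min_area:
                continue
            peak = max(slice_hu[c] for c in comp)
            weight = 1 if peak < 200 else 2 if peak < 300 else 3 if peak < 400 else 4
            scores.append(area * weight)
    return sorted(scores)


# ---------------------------------------------------------------------------
# Threshold adaptation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "hu_target, hu_120, expected",
    [(269.0, 269.0, 130.0), (249.0, 269.0, 130.0 * 249.0 / 269.0), (538.0, 269.0, 260.0)],
)
def test_adapted_threshold_formula(hu_target, hu_120, expected):
    assert adapted_threshold(hu_target, hu_120) == expected


def test_adapted_threshold_rejects_non_positive_inputs():
    with pytest.raises(ValueError):
        adapted_threshold(0.0, 269.0)
    with pytest.raises(ValueError):
        adapted_threshold(249.0, -1.0)


# ---------------------------------------------------------------------------
# ROI means
# ---------------------------------------------------------------------------


def test_mean_roi_hu_uniform_and_split():
    uniform = VoxelGrid(np.full((3, 20, 20), 269.0), (3.0, 1.0, 1.0))
    assert mean_roi_hu(uniform, (9.5, 9.5), 8.0) == pytest.approx(269.0)
    split = np.full((1, 20, 20), 200.0)
    split[:, :, 10:] = 300.0  # half the pixels by count within a centred ROI
    grid = VoxelGrid(split, (3.0, 1.0, 1.0))
    assert mean_roi_hu(grid, (9.5, 9.5), 8.0) == pytest.approx(250.0)


def test_mean_roi_empty_roi_errors():
    grid = VoxelGrid(np.zeros((1, 5, 5)), (3.0, 1.0, 1.0))
    with pytest.raises(ValueError):
        mean_roi_hu(grid, (100.0, 100.0), 1.0)


def test_mean_roi_matches_analytic_insert_hu(noise_free_phantoms):
    spec, p120, _ = noise_free_phantoms
    measured = mean_roi_hu(p120, (spec.insert_center_xy[1], spec.insert_center_xy[0]), 20.0)
    assert measured == pytest.approx(spec.insert_hu, abs=2.0)


# ---------------------------------------------------------------------------
# Slice scoring
# ---------------------------------------------------------------------------


def test_air_slice_scores_nothing():
    assert score_slice(np.full((16, 16), -1000.0), 1.0) == []


def test_single_component_weight_and_score():
    s = np.zeros((8, 8))
    s[2:4, 2:4] = 450.0  # 4 pixels of 1 mm^2
    lesions = score_slice(s, 1.0)
    assert len(lesions) == 1
    les = lesions[0]
    assert (les.pixel_count, les.weight, les.score) == (4, 4, 16.0)


@pytest.mark.parametrize(
    "peak, weight",
    [(199.0, 1), (200.0, 2), (299.0, 2), (300.0, 3), (399.0, 3), (400.0, 4)],
)
def test_density_weight_bin_boundaries(peak, weight):
    assert density_weight(peak) == weight


def test_minimum_area_filter_drops_small_components():
    s = np.zeros((8, 8))
    s[1, 1] = 500.0  # isolated pixel of 0.25 mm^2
    assert score_slice(s, 0.25) == []
    s[1, 2] = s[2, 1] = s[2, 2] = 500.0
    assert len(score_slice(s, 0.25)) == 1


def test_diagonal_pixels_merge_under_8_and_split_under_4_connectivity():
    s = np.zeros((6, 6))
    s[2, 2] = 250.0
    s[3, 3] = 450.0
    eight = score_slice(s, 1.0, ScoringConfig(connectivity=8))
    four = score_slice(s, 1.0, ScoringConfig(connectivity=4))
    assert len(eight) == 1 and eight[0].weight == 4 and eight[0].score == 8.0
    assert len(four) == 2 and sorted(l.score for l in four) == [2.0, 4.0]


@pytest.mark.parametrize("connectivity", [4, 8])
def test_score_slice_matches_flood_fill_oracle(rng, connectivity):
    """200 randomized slices agree exactly with the brute-force oracle."""
    config = ScoringConfig(connectivity=connectivity)
    for _ in range(200):
        s = rng.uniform(-100, 600, (32, 32))
        s[rng.random((32, 32)) < 0.7] = 35.0  # sparse calcifications
        pixel_area = float(rng.choice([0.25, 0.5, 1.0]))
        got = sorted(l.score for l in score_slice(s, pixel_area, config))
        want = oracle_score_slice(s, pixel_area, connectivity=connectivity)
        assert got == want


# ---------------------------------------------------------------------------
# Volume totals
# ---------------------------------------------------------------------------


def test_empty_volume_scores_zero():
    vol = VoxelGrid(np.zeros((4, 8, 8)), (3.0, 1.0, 1.0))
    result = total_score(vol)
    assert result.total == 0.0
    assert all(v == 0.0 for v in result.per_vessel.values())
    assert not cac_positive(result)


def test_lesion_spanning_two_slices_scores_per_slice():
    vol = np.zeros((2, 8, 8))
    vol[0, 2:5, 2] = 250.0  # 3 mm^2, peak 250 -> weight 2
    vol[1, 2:5, 2] = 250.0
    result = total_score(VoxelGrid(vol, (3.0, 1.0, 1.0)))
    assert result.total == 12.0


def test_overlapping_reconstruction_scored_on_nonoverlapping_partition():
    # 3 mm slabs every 1.5 mm: only slices 0, 2, 4 belong to the partition
    vol = np.zeros((5, 8, 8))
    vol[:, 2:5, 2] = 250.0
    grid = VoxelGrid(vol, (1.5, 1.0, 1.0), slice_thickness=3.0)
    assert total_score(grid).total == 3 * 6.0


def test_vessel_attribution_by_majority_label():
    vol = np.zeros((1, 8, 8))
    vol[0, 2:4, 2:4] = 450.0
    mask = np.zeros((1, 8, 8), int)
    mask[0, 2:4, 2:3] = 2  # LAD on half the lesion
    mask[0, 2:4, 3:4] = 2
    result = total_score(VoxelGrid(vol, (3.0, 1.0, 1.0)), mask=mask)
    assert result.per_vessel["LAD"] == result.total == 16.0
    assert result.lm_lad == 16.0
    # unlabeled lesions count toward the total only
    result2 = total_score(VoxelGrid(vol, (3.0, 1.0, 1.0)), mask=np.zeros((1, 8, 8), int))
    assert result2.total == 16.0 and result2.unassigned == 16.0


def test_mask_grid_mismatch_errors():
    vol = VoxelGrid(np.zeros((2, 8, 8)), (3.0, 1.0, 1.0))
    with pytest.raises(ValueError, match="mask"):
        total_score(vol, mask=np.zeros((2, 8, 9), int))


def test_totals_monotone_in_threshold_and_lesion_addition(rng):
    base = rng.uniform(-100, 600, (3, 24, 24))
    vol = VoxelGrid(np.clip(base, -1000, 3000), (3.0, 1.0, 1.0))
    t1 = total_score(vol, ScoringConfig(threshold_hu=130.0)).total
    t2 = total_score(vol, ScoringConfig(threshold_hu=200.0)).total
    assert t2 <= t1
    plus = vol.values.copy()
    plus[1, 2:5, 2:5] = 800.0  # add a lesion
    t3 = total_score(VoxelGrid(plus, (3.0, 1.0, 1.0))).total
    assert t3 >= total_score(vol).total


def test_volume_total_matches_per_voxel_oracle(rng):
    """Whole-volume totals equal the flood-fill oracle summed over slices."""
    for _ in range(20):
        vals = rng.uniform(-100, 600, (4, 16, 16))
        vals[rng.random((4, 16, 16)) < 0.6] = 35.0
        vol = VoxelGrid(vals, (3.0, 0.5, 0.5))
        got = total_score(vol).total
        want = sum(sum(oracle_score_slice(vals[k], 0.25)) for k in range(4))
        assert got == pytest.approx(want, abs=1e-9)


@pytest.mark.parametrize("total, positive", [(0.0, False), (0.9, False), (1.0, True), (579.4, True)])
def test_cac_positive_cutoff(total, positive):
    result = AgatstonResult(total, {v: 0.0 for v in ("LM", "LAD", "LCx", "RCA")}, total)
    assert cac_positive(result) is positive
    assert cac_positive(total) is positive
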