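"""Phantom rendering, acquisition degradation and cohort generation."""

from dataclasses import replace

import numpy as np
import pytest

from cacscore.scoring import ScoringConfig, mean_roi_hu, total_score
from cacscore.synthetic import (
    GATED_PROTOCOL,
    HU_CAHA200_120KVP,
    HU_CAHA200_130KVP,
    LDCT_PROTOCOL,
    AcquisitionProtocol,
    CohortSpec,
    LesionSpec,
    PhantomSpec,
    category_counts,
    generate_cohort,
    hu_from_density,
    rasterize_phantom,
    simulate_acquisition,
)
from cacscore.volume import VoxelGrid

NF_GATED = replace(GATED_PROTOCOL, noise_sd=0.0)
NF_LDCT = replace(LDCT_PROTOCOL, noise_sd=0.0)


# ---------------------------------------------------------------------------
# Phantom
# ---------------------------------------------------------------------------


def test_insert_mean_hu_matches_calibration_values(noise_free_phantoms):
    """The 200 mg/cm^3 rod renders at 269 HU (120 kVp) and 249 HU (130 kVp)."""
    spec, p120, p130 = noise_free_phantoms
    roi = (spec.insert_center_xy[1], spec.insert_center_xy[0])
    assert mean_roi_hu(p120, roi, 20.0) == pytest.approx(HU_CAHA200_120KVP, abs=1.0)
    assert mean_roi_hu(p130, roi, 20.0) == pytest.approx(HU_CAHA200_130KVP, abs=1.0)


def test_soft_tissue_is_kvp_invariant(noise_free_phantoms):
    spec, p120, p130 = noise_free_phantoms
    roi = (60.0, 0.0)  # soft tissue between lungs and body edge (y, x)
    assert abs(mean_roi_hu(p120, roi, 15.0) - mean_roi_hu(p130, roi, 15.0)) < 1.0


def test_calcium_roi_scales_by_protocol_ratio(noise_free_phantoms):
    spec, p120, p130 = noise_free_phantoms
    roi = (spec.insert_center_xy[1], spec.insert_center_xy[0])
    ratio = mean_roi_hu(p130, roi, 20.0) / mean_roi_hu(p120, roi, 20.0)
    assert ratio == pytest.approx(NF_LDCT.calcium_hu_ratio, rel=0.02)


def test_calcium_free_phantom_only_exceeds_threshold_at_spine():
    spec = PhantomSpec(insert_density=1e-9)  # effectively no rod
    grid = rasterize_phantom(spec, NF_LDCT, supersample=2)
    hot = grid.values >= 130.0
    y = grid.axis_coords(1)
    x = grid.axis_coords(2)
    yy, xx = np.meshgrid(y, x, indexing="ij")
    sy, sx = spec.spine_center[1], spec.spine_center[0]
    ay, ax = spec.spine_semi_axes[1], spec.spine_semi_axes[0]
    spine = ((yy - sy) / (ay + 2)) ** 2 + ((xx - sx) / (ax + 2)) ** 2 <= 1.0
    assert hot.any(), "spine should exceed the threshold"
    assert not (hot & ~spine[None]).any()


def test_phantom_rendering_is_deterministic():
    a = rasterize_phantom(PhantomSpec(), GATED_PROTOCOL, seed=3, supersample=2)
    b = rasterize_phantom(PhantomSpec(), GATED_PROTOCOL, seed=3, supersample=2)
    assert np.array_equal(a.values, b.values)


def test_doubling_supersampling_shifts_insert_roi_under_1hu():
    spec = PhantomSpec(z_extent=6.0)
    roi = (spec.insert_center_xy[1], spec.insert_center_xy[0])
    m4 = mean_roi_hu(rasterize_phantom(spec, NF_LDCT, supersample=4), roi, 22.0)
    m8 = mean_roi_hu(rasterize_phantom(spec, NF_LDCT, supersample=8), roi, 22.0)
    assert abs(m8 - m4) < 1.0


def test_insert_must_lie_inside_body():
    with pytest.raises(ValueError):
        PhantomSpec(insert_center_xy=(160.0, 0.0))


def test_non_physical_hu_rejected():
    with pytest.raises(ValueError):
        rasterize_phantom(PhantomSpec(spine_hu=5000.0), NF_GATED, supersample=1)


# ---------------------------------------------------------------------------
# Acquisition simulation
# ---------------------------------------------------------------------------


def _truth_with_lesion(peak_hu=700.0, diameter=6.0):
    nz, ny, nx = 24, 64, 64
    spacing = (0.5, 0.5, 0.5)
    values = np.full((nz, ny, nx), 35.0)
    calcium = np.zeros_like(values)
    zz, yy, xx = np.meshgrid(
        (np.arange(nz) + 0.5) * 0.5, (np.arange(ny) + 0.5) * 0.5,
        (np.arange(nx) + 0.5) * 0.5, indexing="ij")
    m = (zz - 6.0) ** 2 + (yy - 16.0) ** 2 + (xx - 16.0) ** 2 <= (diameter / 2) ** 2
    values[m] = peak_hu
    calcium[m] = peak_hu
    return VoxelGrid(values, spacing, (0.25, 0.25, 0.25), calcium=calcium)


def test_identity_degradation_equals_slab_average():
    truth = _truth_with_lesion()
    proto = AcquisitionProtocol("id", 120, slice_thickness=3.0, increment=3.0,
                                pixel_mm=1.0, noise_sd=0.0, motion_sd=0.0)
    out = simulate_acquisition(truth, proto, seed=0)
    manual = truth.values.reshape(4, 6, 32, 2, 32, 2).mean(axis=(1, 3, 5))
    # identical up to float summation order
    assert np.allclose(out.values, manual, atol=1e-10, rtol=0)


def test_slab_averaging_conserves_hu_integral():
    truth = _truth_with_lesion()
    proto = AcquisitionProtocol("id", 120, slice_thickness=3.0, increment=3.0,
                                pixel_mm=1.0, noise_sd=0.0, motion_sd=0.0)
    out = simulate_acquisition(truth, proto, seed=0)
    int_in = truth.values.sum() * np.prod(truth.spacing)
    int_out = out.values.sum() * out.slice_thickness * out.spacing[1] * out.spacing[2]
    assert int_out == pytest.approx(int_in, rel=1e-12)


def test_motion_blur_never_raises_the_peak():
    """Gaussian blur cannot raise a global maximum; peak HU is non-increasing."""
    truth = _truth_with_lesion()
    peaks = []
    for sd in [0.0, 0.5, 1.0, 1.5, 2.0, 3.0]:
        proto = AcquisitionProtocol("m", 120, slice_thickness=3.0, increment=3.0,
                                    pixel_mm=1.0, noise_sd=0.0, motion_sd=sd)
        peaks.append(simulate_acquisition(truth, proto, seed=0).values.max())
    assert all(a >= b - 1e-9 for a, b in zip(peaks, peaks[1:]))


def test_130kvp_rescales_only_the_calcium_component():
    truth = _truth_with_lesion(peak_hu=500.0)
    proto = AcquisitionProtocol("ca", 130, slice_thickness=3.0, increment=3.0,
                                pixel_mm=1.0, noise_sd=0.0, motion_sd=0.0,
                                calcium_hu_ratio=0.9)
    out = simulate_acquisition(truth, proto, seed=0)
    ref = simulate_acquisition(truth, replace(proto, kvp=120, calcium_hu_ratio=1.0), seed=0)
    assert out.values.max() == pytest.approx(ref.values.max() * 0.9, rel=1e-9)
    assert out.values[0, 0, 0] == pytest.approx(ref.values[0, 0, 0])  # soft corner


def test_unsupported_gapped_geometry_rejected():
    truth = _truth_with_lesion()
    bad = AcquisitionProtocol("gap", 120, slice_thickness=1.0, increment=2.5, pixel_mm=1.0)
    with pytest.raises(ValueError, match="increment"):
        simulate_acquisition(truth, bad, seed=0)


def test_acquisition_noise_is_seed_reproducible():
    truth = _truth_with_lesion()
    out1 = simulate_acquisition(truth, LDCT_PROTOCOL, seed=11)
    out2 = simulate_acquisition(truth, LDCT_PROTOCOL, seed=11)
    out3 = simulate_acquisition(truth, LDCT_PROTOCOL, seed=12)
    assert np.array_equal(out1.values, out2.values)
    assert not np.array_equal(out1.values, out3.values)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------


def test_reference_proportions_reproduce_reference_counts():
    counts = category_counts(CohortSpec().category_proportions, 213)
    assert counts.tolist() == [12, 9, 27, 34, 69, 62]


def test_empty_cohort(tmp_path):
    from cacscore.synthetic import write_cohort

    records = generate_cohort(CohortSpec(n_subjects=0, seed=0))
    assert records == []
    write_cohort(records, tmp_path / "cohort")
    assert not (tmp_path / "cohort").exists()


def test_cohort_is_seed_deterministic():
    spec = CohortSpec(n_subjects=6, category_proportions=(1 / 6,) * 6, seed=5)
    a = generate_cohort(spec)
    b = generate_cohort(spec)
    assert [r.true_total for r in a] == [r.true_total for r in b]
    assert all(np.array_equal(x.gated.values, y.gated.values) for x, y in zip(a, b))
    assert all(np.array_equal(x.ldct.values, y.ldct.values) for x, y in zip(a, b))


def test_gated_scan_score_lands_in_assigned_category():
    from cacscore.risk import categorize

    spec = CohortSpec(n_subjects=6, category_proportions=(1 / 6,) * 6, seed=2)
    for rec in generate_cohort(spec):
        total = total_score(rec.gated, ScoringConfig(), rec.gated_mask).total
        assert categorize(total) == rec.category


def test_cohort_manifest_round_trip(tmp_path):
    import pandas as pd

    from cacscore.synthetic import write_cohort
    from cacscore.volume import load_volume

    spec = CohortSpec(n_subjects=2, category_proportions=(0, 0, 0.5, 0.5, 0, 0), seed=9)
    records = generate_cohort(spec)
    manifest = write_cohort(records, tmp_path / "cohort")
    df = pd.read_csv(manifest)
    assert len(df) == 2
    vol = load_volume(manifest.parent / df.iloc[0]["gated_path"])
    assert np.allclose(vol.values, records[0].gated.values, atol=1e-4)
    assert vol.overlapping()  # gated reconstruction: 3 mm slabs every 1.5 mm


def test_lesion_spec_validation():
    with pytest.raises(ValueError):
        LesionSpec((0, 0, 0), diameter=-1.0, density=200.0)
    with pytest.raises(ValueError):
        LesionSpec((0, 0, 0), diameter=3.0, density=200.0, vessel="AORTA")


def test_hu_density_line_passes_through_anchors():
    assert hu_from_density(0.0) == pytest.approx(35.0)
    assert hu_from_density(200.0) == pytest.approx(269.0)
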