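import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varivent import (
    InvalidParameterError,
    UndefinedResultError,
    compute_suv,
    gas_tissue_fraction,
    normalize_uptake,
    regional_summary,
    segment_aeration,
    split_ventral_dorsal,
)
from varivent.imaging import ZONES


def block_ct(counts=(5000, 3000, 2000), values=(-800.0, -300.0, 0.0)):
    """Flat CT with exactly the requested voxels per zone inside the mask."""
    n = sum(counts)
    ct = np.full(n, -1000.0)
    start = 0
    for c, v in zip(counts, values):
        ct[start : start + c] = v
        start += c
    return ct.reshape(10, 10, n // 100), np.ones((10, 10, n // 100), dtype=bool)


class TestSegmentation:
    def test_uniform_single_zone(self):
        ct = np.full((5, 5, 5), -800.0)
        mask = np.ones_like(ct, dtype=bool)
        amap = segment_aeration(ct, mask)
        assert amap.zone_counts() == {"well": 125, "poor": 0, "non": 0}

    def test_constructed_counts(self):
        ct, mask = block_ct()
        amap = segment_aeration(ct, mask)
        assert amap.zone_counts() == {"well": 5000, "poor": 3000, "non": 2000}

    @pytest.mark.parametrize(
        "hu,zone", [(-500.0, "poor"), (-100.0, "non"), (-1000.0, "well"), (100.0, "non")]
    )
    def test_boundary_conventions(self, hu, zone):
        ct = np.full((2, 2, 2), hu)
        amap = segment_aeration(ct, np.ones_like(ct, dtype=bool))
        assert amap.zone_counts()[zone] == 8

    def test_artefact_clipping_counted(self):
        ct = np.full((3, 3, 3), -800.0)
        ct[0, 0, 0] = -1200.0  # cone-beam artefact below the scale
        ct[0, 0, 1] = 400.0
        amap = segment_aeration(ct, np.ones_like(ct, dtype=bool))
        assert amap.n_clipped == 2
        assert amap.zone_counts()["well"] == 26
        assert amap.zone_counts()["non"] == 1

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        ct = rng.uniform(-1100, 200, size=(8, 8, 8))
        mask = rng.random((8, 8, 8)) > 0.3
        amap = segment_aeration(ct, mask)
        assert sum(amap.zone_counts().values()) == int(mask.sum())
        assert np.all((amap.labels > 0) == mask)

    def test_empty_mask(self):
        with pytest.raises(InvalidParameterError):
            segment_aeration(np.zeros((3, 3, 3)), np.zeros((3, 3, 3), dtype=bool))


class TestGasTissueFraction:
    @pytest.mark.parametrize(
        "hu,f_gas,f_tissue",
        [(-1000.0, 1.0, 0.0), (0.0, 0.0, 1.0), (-500.0, 0.5, 0.5), (-250.0, 0.25, 0.75)],
    )
    def test_calibration_points(self, hu, f_gas, f_tissue):
        fg, ft = gas_tissue_fraction(hu)
        assert fg == pytest.approx(f_gas)
        assert ft == pytest.approx(f_tissue)

    @given(st.floats(min_value=-2000.0, max_value=500.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_fractions_sum_to_one_and_clamp(self, hu):
        fg, ft = gas_tissue_fraction(hu)
        assert float(fg + ft) == 1.0
        assert 0.0 <= fg <= 1.0


class TestSUV:
    def test_uniform_activity_gives_unit_suv(self):
        activity = np.full((4, 4, 4), 37000.0 / 670.0)
        assert np.allclose(compute_suv(activity, 37000.0, 670.0), 1.0)

    def test_dose_scale_invariance(self):
        activity = np.random.default_rng(1).random((3, 3, 3))
        assert np.allclose(
            compute_suv(activity, 2 * 37000.0, 670.0),
            compute_suv(activity, 37000.0, 670.0) / 2.0,
        )

    def test_worked_value(self):
        assert compute_suv(np.array(2.0), 37000.0, 670.0) == pytest.approx(
            2.0 / (37000.0 / 670.0)
        )

    def test_invalid(self):
        with pytest.raises(InvalidParameterError):
            compute_suv(np.ones(3), 0.0, 670.0)


class TestNormalizeUptake:
    def test_pure_tissue_identity(self):
        suv = np.random.default_rng(2).random((4, 4, 4))
        ct = np.zeros((4, 4, 4))  # f_tissue = 1
        mask = np.ones((4, 4, 4), dtype=bool)
        out, excluded = normalize_uptake(suv, ct, mask)
        assert np.allclose(out, suv)
        assert excluded.sum() == 0

    def test_midpoint_doubles(self):
        shape = (3, 3, 3)
        out, _ = normalize_uptake(
            np.ones(shape), np.full(shape, -500.0), np.ones(shape, dtype=bool)
        )
        assert np.allclose(out, 2.0)

    def test_low_tissue_voxels_excluded(self):
        ct = np.full((3, 3, 3), -500.0)
        ct[0, 0, 0] = -995.0  # f_tissue 0.005 < 0.05 floor
        out, excluded = normalize_uptake(
            np.ones_like(ct), ct, np.ones_like(ct, dtype=bool), 0.05
        )
        assert excluded[0, 0, 0]
        assert np.isnan(out[0, 0, 0])
        assert excluded.sum() == 1

    def test_all_excluded_is_error(self):
        ct = np.full((3, 3, 3), -990.0)
        with pytest.raises(UndefinedResultError):
            normalize_uptake(np.ones_like(ct), ct, np.ones_like(ct, dtype=bool), 0.05)

    def test_commutes_with_activity_scaling(self):
        rng = np.random.default_rng(3)
        suv = rng.random((4, 4, 4))
        ct = rng.uniform(-900, 0, (4, 4, 4))
        mask = np.ones((4, 4, 4), dtype=bool)
        a, _ = normalize_uptake(3.0 * suv, ct, mask)
        b, _ = normalize_uptake(suv, ct, mask)
        assert np.allclose(a, 3.0 * b, equal_nan=True)


class TestVentralDorsalSplit:
    def test_symmetric_halves(self):
        mask = np.ones((6, 6, 6), dtype=bool)
        ventral, dorsal = split_ventral_dorsal(mask, gravity_axis=2)
        assert ventral.sum() == dorsal.sum() == 108

    def test_centroid_follows_mask(self):
        # asymmetric mask: voxels concentrated dorsally; centroid split stays
        # balanced to within one slice while a fixed midline would not
        mask = np.zeros((4, 4, 10), dtype=bool)
        mask[:, :, 4:] = True
        ventral, dorsal = split_ventral_dorsal(mask, gravity_axis=2)
        assert abs(int(ventral.sum()) - int(dorsal.sum())) <= 16  # one slice
        midline_dorsal = mask[:, :, 5:].sum()
        assert midline_dorsal > mask[:, :, :5].sum()  # midline is unbalanced

    def test_degenerate_mask(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[:, :, 2] = True
        with pytest.raises(InvalidParameterError):
            split_ventral_dorsal(mask, gravity_axis=2)


class TestRegionalSummary:
    def test_phantom_round_trip(self, small_phantom):
        vols = small_phantom
        amap = segment_aeration(vols.ct, vols.mask)
        suv = compute_suv(vols.pet, 37000.0, 670.0)
        norm, _ = normalize_uptake(suv, vols.ct, vols.mask)
        summary = regional_summary(vols, amap, norm, norm)
        pet = summary[summary["modality"] == "pet"].set_index("region")
        for zone, target in zip(ZONES, (2.0, 1.0, 0.5)):
            assert pet.loc[zone, "mean"] == pytest.approx(target, rel=0.02)

    def test_global_mean_conservation(self, small_phantom):
        vols = small_phantom
        amap = segment_aeration(vols.ct, vols.mask)
        rng = np.random.default_rng(4)
        f = rng.random(vols.ct.shape)
        summary = regional_summary(vols, amap, f, f)
        pet = summary[summary["modality"] == "pet"].set_index("region")
        total = pet.loc["total"]
        for partition in (list(ZONES), ["ventral", "dorsal"]):
            parts = pet.loc[partition]
            recon = float((parts["mean"] * parts["count"]).sum() / parts["count"].sum())
            assert recon == pytest.approx(float(total["mean"]), abs=1e-9)
            assert int(parts["count"].sum()) == int(total["count"])

    def test_uniform_field_equal_means(self, small_phantom):
        vols = small_phantom
        amap = segment_aeration(vols.ct, vols.mask)
        f = np.full(vols.ct.shape, 7.0)
        summary = regional_summary(vols, amap, f, f)
        assert np.allclose(summary["mean"], 7.0)

    def test_empty_region_reported_nan(self, small_phantom):
        vols = small_phantom
        amap = segment_aeration(vols.ct, vols.mask)
        amap.labels[amap.labels == 3] = 2  # erase the non-aerated zone
        f = np.ones(vols.ct.shape)
        summary = regional_summary(vols, amap, f, f)
        non = summary[(summary["region"] == "non") & (summary["modality"] == "pet")]
        assert np.isnan(non["mean"].iloc[0])
        assert non["count"].iloc[0] == 0

    def test_volume_is_count_times_voxel_volume(self, small_phantom):
        vols = small_phantom
        amap = segment_aeration(vols.ct, vols.mask)
        f = np.ones(vols.ct.shape)
        summary = regional_summary(vols, amap, f, f)
        assert np.allclose(
            summary["volume_ml"], summary["count"] * vols.voxel_volume_ml
        )
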