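import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from optoquant import (
    ChannelVolume,
    EmbryoTruth,
    RegionMask,
    SampleMeta,
    auto_threshold,
    generate_volume,
    intersect_masks,
    make_region_mask,
    max_projection,
    normalize_effector,
    qc_check,
    quantify_sample,
    region_medians,
    roi_overlap,
)
from optoquant.quantify import QCConfig, embryo_extent

from conftest import random_volume


def brute_force_median(values):
    s = sorted(values)
    n = len(s)
    if n == 0:
        return float("nan")
    return s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2.0


class TestRegionMask:
    def test_threshold_below_minimum_gives_full_mask(self):
        rng = np.random.default_rng(0)
        vol = random_volume(rng)
        vol.voxels[0] += 1  # ensure min > 0
        mask = make_region_mask(vol, "DAPI", 0.0)
        assert mask.voxels.all()

    def test_threshold_at_maximum_gives_empty_mask(self):
        rng = np.random.default_rng(1)
        vol = random_volume(rng)
        mask = make_region_mask(vol, "DAPI", float(vol.channel("DAPI").max()))
        assert not mask.voxels.any()

    def test_mask_equals_voxelwise_comparison_oracle(self):
        rng = np.random.default_rng(2)
        vol = random_volume(rng, shape=(4, 4, 4))
        thr = 500.0
        mask = make_region_mask(vol, "GFP", thr)
        data = vol.channel("GFP")
        for z in range(4):
            for y in range(4):
                for x in range(4):
                    assert mask.voxels[z, y, x] == (data[z, y, x] > thr)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        vol = random_volume(rng)
        low = make_region_mask(vol, "DAPI", 100.0)
        high = make_region_mask(vol, "DAPI", 600.0)
        assert not (high.voxels & ~low.voxels).any()

    def test_unknown_channel_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(KeyError):
            make_region_mask(random_volume(rng), "KAEDE", 10.0)


class TestAutoThreshold:
    def test_bimodal_threshold_lies_between_modes(self):
        vox = np.full((1, 4, 8, 8), 10, dtype=np.uint16)
        vox[0, :, :, 4:] = 200
        vol = ChannelVolume(vox, ("DAPI",))
        thr = auto_threshold(vol, "DAPI")
        assert 10 < thr < 200

    def test_manual_returns_value_unchanged(self):
        rng = np.random.default_rng(5)
        vol = random_volume(rng)
        assert auto_threshold(vol, "DAPI", method="manual", manual_value=37.0) == 37.0

    def test_constant_image_rejected(self):
        vol = ChannelVolume(np.full((1, 2, 2, 2), 7, dtype=np.uint16), ("DAPI",))
        with pytest.raises(ValueError, match="constant"):
            auto_threshold(vol, "DAPI")

    def test_matches_exhaustive_between_class_variance_search(self):
        # tiny histogram: exhaustive split-point search oracle
        values = np.array([1, 1, 2, 40, 41, 42], dtype=np.uint16)
        vol = ChannelVolume(values.reshape(1, 1, 2, 3), ("DAPI",))
        thr = auto_threshold(vol, "DAPI")

        def between_class_variance(cut):
            lo, hi = values[values <= cut], values[values > cut]
            if len(lo) == 0 or len(hi) == 0:
                return -1.0
            w0, w1 = len(lo) / len(values), len(hi) / len(values)
            return w0 * w1 * (lo.mean() - hi.mean()) ** 2

        best_cut = max(np.unique(values), key=between_class_variance)
        # both split the sample identically
        assert np.array_equal(values > thr, values > best_cut)


class TestIntersect:
    def test_idempotent(self):
        rng = np.random.default_rng(6)
        m = RegionMask(rng.random((3, 3, 3)) > 0.5, "DAPI")
        assert np.array_equal(intersect_masks(m, m).voxels, m.voxels)

    def test_disjoint_masks_empty(self):
        a = np.zeros((2, 2, 2), dtype=bool)
        b = np.zeros((2, 2, 2), dtype=bool)
        a[0], b[1] = True, True
        out = intersect_masks(RegionMask(a, "DAPI"), RegionMask(b, "GFP"))
        assert not out.voxels.any()
        assert out.region_name == "DAPI_GFP"

    def test_matches_elementwise_and_oracle(self):
        rng = np.random.default_rng(7)
        a = rng.random((4, 4, 4)) > 0.4
        b = rng.random((4, 4, 4)) > 0.6
        out = intersect_masks(RegionMask(a, "DAPI"), RegionMask(b, "GFP"))
        for idx in np.ndindex(4, 4, 4):
            assert out.voxels[idx] == (a[idx] and b[idx])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            intersect_masks(
                RegionMask(np.zeros((2, 2, 2), bool), "DAPI"),
                RegionMask(np.zeros((3, 2, 2), bool), "GFP"),
            )


class TestNormalize:
    def test_unit_divisor_is_identity(self):
        vox = np.stack([
            np.zeros((2, 2, 2)), np.ones((2, 2, 2)),
            np.arange(8, dtype=float).reshape(2, 2, 2),
        ]).astype(np.uint16)
        vol = ChannelVolume(vox, ("DAPI", "GFP", "EFFECTOR"))
        out = normalize_effector(vol)
        assert np.array_equal(out, vol.channel("EFFECTOR").astype(float))

    def test_forced_arithmetic(self):
        vox = np.zeros((3, 1, 1, 2), dtype=np.uint16)
        vox[1, 0, 0] = [2, 3]   # GFP
        vox[2, 0, 0] = [4, 9]   # EFFECTOR
        vol = ChannelVolume(vox, ("DAPI", "GFP", "EFFECTOR"))
        out = normalize_effector(vol)
        assert out[0, 0, 0] == 2.0 and out[0, 0, 1] == 3.0

    def test_zero_divisor_marked_undefined(self):
        vox = np.zeros((3, 1, 1, 2), dtype=np.uint16)
        vox[1, 0, 0] = [0, 2]
        vox[2, 0, 0] = [5, 8]
        vol = ChannelVolume(vox, ("DAPI", "GFP", "EFFECTOR"))
        out = normalize_effector(vol)
        assert np.isnan(out[0, 0, 0]) and out[0, 0, 1] == 4.0

    def test_all_zero_reporter_warns(self):
        vox = np.zeros((3, 1, 2, 2), dtype=np.uint16)
        vox[2] = 5
        vol = ChannelVolume(vox, ("DAPI", "GFP", "EFFECTOR"))
        with pytest.warns(UserWarning, match="all zero"):
            out = normalize_effector(vol)
        assert np.isnan(out).all()


class TestRegionMedians:
    def _masks(self, shape, rng=None):
        if rng is None:
            full = np.ones(shape, dtype=bool)
            return {k: RegionMask(full, n) for k, n in
                    (("DAPI", "DAPI"), ("GFP", "GFP"), ("DAPI_GFP", "DAPI_GFP"))}
        return {
            "DAPI": RegionMask(rng.random(shape) > 0.3, "DAPI"),
            "GFP": RegionMask(rng.random(shape) > 0.3, "GFP"),
            "DAPI_GFP": RegionMask(rng.random(shape) > 0.5, "DAPI_GFP"),
        }

    def test_constant_effector_unit_gfp_all_medians_equal(self):
        c = 7.0
        vox = np.stack([np.ones((2, 3, 3)), np.ones((2, 3, 3)),
                        np.full((2, 3, 3), c)]).astype(np.uint16)
        vol = ChannelVolume(vox, ("DAPI", "GFP", "EFFECTOR"))
        rec = region_medians(vol, normalize_effector(vol), self._masks((2, 3, 3)))
        for name in ("raw_dapi", "norm_dapi", "raw_gfp", "norm_gfp",
                     "raw_dapi_gfp", "norm_dapi_gfp"):
            assert getattr(rec, name) == c

    def test_median_definition_odd_count(self):
        vals = np.array([1, 2, 3, 9, 10], dtype=np.uint16)
        vox = np.zeros((3, 1, 1, 5), dtype=np.uint16)
        vox[1] = 1
        vox[2, 0, 0] = vals
        vol = ChannelVolume(vox, ("DAPI", "GFP", "EFFECTOR"))
        rec = region_medians(vol, normalize_effector(vol), self._masks((1, 1, 5)))
        assert rec.raw_dapi == 3.0

    def test_empty_mask_yields_nan_and_qc_reason(self):
        vox = np.ones((3, 2, 2, 2), dtype=np.uint16)
        vol = ChannelVolume(vox, ("DAPI", "GFP", "EFFECTOR"))
        masks = self._masks((2, 2, 2))
        masks["DAPI_GFP"] = RegionMask(np.zeros((2, 2, 2), bool), "DAPI_GFP")
        rec = region_medians(vol, normalize_effector(vol), masks)
        assert np.isnan(rec.raw_dapi_gfp) and np.isnan(rec.norm_dapi_gfp)
        assert "empty_region:raw_dapi_gfp" in rec.qc.reasons
        assert not rec.qc.passed

    def test_matches_sort_based_oracle_on_random_volumes(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            vol = random_volume(rng, shape=(5, 5, 5))
            masks = self._masks((5, 5, 5), rng)
            norm = normalize_effector(vol)
            rec = region_medians(vol, norm, masks)
            eff = vol.channel("EFFECTOR").astype(float)
            for key, prefix in (("DAPI", "dapi"), ("GFP", "gfp"),
                                ("DAPI_GFP", "dapi_gfp")):
                m = masks[key].voxels
                expect_raw = brute_force_median(eff[m].tolist())
                sel = norm[m]
                expect_norm = brute_force_median(sel[np.isfinite(sel)].tolist())
                assert getattr(rec, f"raw_{prefix}") == pytest.approx(expect_raw)
                assert getattr(rec, f"norm_{prefix}") == pytest.approx(expect_norm)

    def test_median_invariant_to_slice_permutation(self):
        rng = np.random.default_rng(9)
        vol = random_volume(rng, shape=(6, 4, 4))
        masks = self._masks((6, 4, 4), rng)
        rec1 = region_medians(vol, normalize_effector(vol), masks)
        perm = rng.permutation(6)
        vol2 = ChannelVolume(vol.voxels[:, perm], vol.channel_names)
        masks2 = {k: RegionMask(m.voxels[perm], m.region_name) for k, m in masks.items()}
        rec2 = region_medians(vol2, normalize_effector(vol2), masks2)
        assert rec1.raw_gfp == rec2.raw_gfp
        assert rec1.norm_dapi == rec2.norm_dapi

    @given(k=st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=20, deadline=None)
    def test_joint_channel_scaling_leaves_normalized_medians_unchanged(self, k):
        rng = np.random.default_rng(10)
        eff = rng.integers(1, 100, (4, 4, 4)).astype(float)
        gfp = rng.integers(1, 100, (4, 4, 4)).astype(float)
        mask = rng.random((4, 4, 4)) > 0.4
        base = brute_force_median((eff[mask] / gfp[mask]).tolist())
        scaled = brute_force_median(((k * eff[mask]) / (k * gfp[mask])).tolist())
        assert scaled == pytest.approx(base, rel=1e-9)


class TestMaxProjection:
    def test_single_slice_is_identity(self):
        rng = np.random.default_rng(11)
        vol = random_volume(rng, shape=(1, 4, 4))
        assert np.array_equal(max_projection(vol, "GFP"), vol.channel("GFP")[0])

    def test_disjoint_bright_pixels_union(self):
        vox = np.zeros((1, 2, 2, 2), dtype=np.uint16)
        vox[0, 0, 0, 0] = 10
        vox[0, 1, 1, 1] = 20
        vol = ChannelVolume(vox, ("DAPI",))
        proj = max_projection(vol, "DAPI")
        assert proj[0, 0] == 10 and proj[1, 1] == 20

    def test_matches_per_pixel_max_oracle(self):
        rng = np.random.default_rng(12)
        vol = random_volume(rng, shape=(3, 4, 4))
        proj = max_projection(vol, "EFFECTOR")
        data = vol.channel("EFFECTOR")
        for y in range(4):
            for x in range(4):
                assert proj[y, x] == max(data[z, y, x] for z in range(3))

    def test_nuclear_projection_masks_before_projecting(self):
        vox = np.zeros((1, 2, 2, 2), dtype=np.uint16)
        vox[0, 0] = 50
        vox[0, 1] = 90
        vol = ChannelVolume(vox, ("EFFECTOR",))
        mask = np.zeros((2, 2, 2), bool)
        mask[0] = True  # only the dimmer slice is nuclear
        proj = max_projection(vol, "EFFECTOR", mask=RegionMask(mask, "DAPI"))
        assert np.all(proj == 50)


class TestQC:
    def _coverage_volume(self, coverage):
        """Embryo block with a GFP-positive slab covering the given
        fraction of embryo voxels."""
        shape = (4, 10, 10)
        dapi = np.full(shape, 2000.0)
        dapi[:, :2, :2] = 30000.0  # some nuclei
        gfp = np.zeros(shape)
        n = int(round(coverage * np.prod(shape)))
        gfp.flat[:n] = 5000.0
        eff = np.full(shape, 500.0)
        vox = np.clip(np.stack([dapi, gfp, eff]), 0, 65535).astype(np.uint16)
        vol = ChannelVolume(vox, ("DAPI", "GFP", "EFFECTOR"))
        masks = {
            "DAPI": RegionMask(dapi > 10000, "DAPI"),
            "GFP": RegionMask(gfp > 1000, "GFP"),
        }
        masks["DAPI_GFP"] = intersect_masks(masks["DAPI"], masks["GFP"])
        extent = np.ones(shape, dtype=bool)
        return vol, masks, extent

    def test_low_coverage_excluded_at_three_percent(self):
        vol, masks, extent = self._coverage_volume(0.03)
        qc, cov = qc_check(vol, masks, extent=extent)
        assert cov == pytest.approx(0.03, abs=0.005)
        assert "low_gfp_coverage" in qc.reasons and not qc.passed

    def test_seven_percent_coverage_retained(self):
        vol, masks, extent = self._coverage_volume(0.07)
        qc, cov = qc_check(vol, masks, extent=extent)
        assert "low_gfp_coverage" not in qc.reasons

    def test_fully_saturated_channel_flags_streaking(self):
        vol, masks, extent = self._coverage_volume(0.5)
        vol.voxels[2] = vol.max_intensity
        qc, _ = qc_check(vol, masks, extent=extent)
        assert "saturation_streaking" in qc.reasons

    def test_clean_noiseless_fixture_passes(self):
        truth = EmbryoTruth(seed=21, shape=(16, 48, 48), n_nuclei=40, noise_sd=0.0)
        vol, _ = generate_volume(truth, 0.5)
        rec = quantify_sample(vol)
        assert rec.qc.passed, rec.qc.reasons

    def test_dapi_damage_hole_flagged(self):
        truth = EmbryoTruth(seed=22, shape=(16, 48, 48), n_nuclei=40, noise_sd=0.0)
        vol, masks = generate_volume(truth, 0.5)
        # carve a large enclosed dark cavity into the DAPI channel
        dapi = vol.voxels[0].astype(float)
        emb = masks["embryo"]
        hole = np.zeros_like(emb)
        hole[1:15, 4:44, 4:44] = True
        hole &= emb
        assert hole.sum() > emb.sum() / 3
        dapi[hole] = 0.0
        vol.voxels[0] = dapi.astype(np.uint16)
        rec = quantify_sample(vol)
        assert "dapi_damage" in rec.qc.reasons

    def test_manual_flags_pass_through(self):
        vol, masks, extent = self._coverage_volume(0.5)
        meta = SampleMeta("s", "FGF", "455nm", 0.0, "R1",
                          manual_flags=frozenset({"second_embryo"}))
        qc, _ = qc_check(vol, masks, extent=extent, meta=meta)
        assert "manual_flag" in qc.reasons


class TestRoiOverlap:
    def _mask(self, arr):
        return RegionMask(np.asarray(arr, bool), "GFP")

    def test_identical_masks_full_overlap(self):
        rng = np.random.default_rng(13)
        a = rng.random((3, 3, 3)) > 0.5
        out = roi_overlap(self._mask(a), self._mask(a))
        assert out["inside"] == 1.0 and out["dice"] == 1.0

    def test_disjoint_zero_overlap(self):
        a = np.zeros((2, 2, 2), bool)
        b = np.zeros((2, 2, 2), bool)
        a[0], b[1] = True, True
        out = roi_overlap(self._mask(a), self._mask(b))
        assert out["inside"] == 0.0

    def test_forced_arithmetic(self):
        a = np.zeros((1, 1, 10), bool)
        r = np.zeros((1, 1, 10), bool)
        a[0, 0, :4] = True        # |A| = 4
        r[0, 0, 2:8] = True       # |R| = 6, |A∩R| = 2
        out = roi_overlap(self._mask(a), self._mask(r))
        assert out["inside"] == 0.5
        assert out["dice"] == pytest.approx(0.4)

    def test_empty_activation_reports_zero_with_note(self):
        a = np.zeros((2, 2, 2), bool)
        r = np.ones((2, 2, 2), bool)
        out = roi_overlap(self._mask(a), self._mask(r))
        assert out["inside"] == 0.0 and out["empty_activation"] == 1.0


def test_embryo_extent_is_largest_connected_component():
    shape = (3, 8, 8)
    dapi = np.zeros(shape)
    dapi[:, :5, :5] = 3000.0   # big blob
    dapi[:, 6:, 6:] = 3000.0   # small blob
    dapi[0, 0, 0] = 30000.0    # make Otsu well defined
    vox = np.stack([dapi, np.zeros(shape), np.zeros(shape)]).astype(np.uint16)
    vol = ChannelVolume(vox, ("DAPI", "GFP", "EFFECTOR"))
    extent = embryo_extent(vol)
    assert extent[1, 2, 2] and not extent[1, 7, 7]
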