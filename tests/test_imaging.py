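"""Image quantification ops, including the segmentation-splitting oracle."""

import warnings

import numpy as np
import pytest
from scipy import ndimage

import lysoratio as lr
from lysoratio.imaging import (
    PH_DEP,
    PH_INDEP,
    RATIO_LUT_V1,
    make_mask,
    records_to_frame,
)


def two_channel_stack(dep, ref, pixel_size=0.2):
    dep = np.asarray(dep, float)
    ref = np.asarray(ref, float)
    if dep.ndim == 2:
        dep, ref = dep[None], ref[None]
    return lr.ImageStack({PH_DEP: dep, PH_INDEP: ref}, pixel_size=pixel_size,
                         z_spacing=1.5)


def gaussian_spot(shape, center, sigma, amplitude):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return amplitude * np.exp(
        -((yy - center[0]) ** 2 + (xx - center[1]) ** 2) / (2 * sigma**2)
    )


class TestBackgroundCorrect:
    def test_constant_plane_goes_to_zero(self):
        stack = two_channel_stack(np.full((8, 8), 100.0), np.full((8, 8), 100.0))
        out = lr.background_correct(stack)
        assert (out.channel(PH_DEP) == 0).all()
        assert out.meta["background_subtracted"][PH_DEP] == [100.0]

    def test_sparse_puncta_unchanged(self):
        img = np.zeros((20, 20))
        img[5, 5] = 1000.0
        out = lr.background_correct(two_channel_stack(img, img))
        np.testing.assert_array_equal(out.channel(PH_DEP)[0], img)

    def test_idempotent_once_percentile_reaches_zero(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(50, 60, (16, 16))
        img.ravel()[:26] = 50.0  # >5% of pixels at the floor
        once = lr.background_correct(two_channel_stack(img, img))
        twice = lr.background_correct(once)
        sub = twice.meta["background_subtracted"][PH_DEP][0]
        assert sub == 0.0
        np.testing.assert_array_equal(once.channel(PH_DEP), twice.channel(PH_DEP))

    def test_gradient_background_object_intensity_recovered(self):
        """Per-object integrated intensity within 2% of truth after the
        percentile correction, despite a linear background gradient."""
        cfg = lr.default_config(
            seed=21, n_organelles=5, shape=(3, 128, 128)
        ).without_noise()
        stack, truth = lr.simulate_stack(cfg)
        clean_cfg = lr.default_config(
            seed=21, n_organelles=5, shape=(3, 128, 128),
            background=0.0, background_gradient=0.0,
        ).without_noise()
        clean = lr.render_stack(clean_cfg, truth)
        corr = lr.background_correct(stack)
        thr = float(make_mask(corr.channel(PH_INDEP).reshape(1, -1),
                              "otsu").threshold)
        for p in range(3):
            seg = lr.segment_objects(
                corr.channel(PH_INDEP)[p], thr,
                filters=lr.ObjectFilters(units="pixel"), plane_index=p,
            )
            lr.object_ratios(seg.records, corr)
            ref_true = clean.channel(PH_INDEP)
            for rec in seg.records:
                truth_int = float(ref_true[p, rec.rows, rec.cols].sum())
                assert rec.intensity_ph_indep == pytest.approx(truth_int, rel=0.02)


class TestSumProject:
    def test_single_plane_is_identity(self):
        img = np.arange(16.0).reshape(4, 4)
        stack = two_channel_stack(img, img)
        stack.meta["background_corrected"] = True
        out = lr.sum_project(stack)
        np.testing.assert_array_equal(out.channel(PH_DEP)[0], img)

    def test_two_identical_planes_double(self):
        img = np.arange(16.0).reshape(4, 4)
        stack = lr.ImageStack(
            {PH_DEP: np.stack([img, img]), PH_INDEP: np.stack([img, img])},
            pixel_size=0.2, meta={"background_corrected": True},
        )
        np.testing.assert_array_equal(
            lr.sum_project(stack).channel(PH_DEP)[0], 2 * img
        )

    def test_total_intensity_conserved(self):
        rng = np.random.default_rng(1)
        arr = rng.uniform(0, 1000, (5, 12, 12))
        stack = lr.ImageStack({PH_DEP: arr, PH_INDEP: arr}, pixel_size=0.2,
                              meta={"background_corrected": True})
        out = lr.sum_project(stack)
        assert out.channel(PH_DEP).sum() == pytest.approx(arr.sum(), rel=1e-12)

    def test_warns_without_background_correction(self):
        stack = two_channel_stack(np.ones((4, 4)), np.ones((4, 4)))
        with pytest.warns(UserWarning, match="background"):
            lr.sum_project(stack)


class TestMakeMask:
    def test_fixed_zero_threshold_is_full_mask(self):
        res = make_mask(np.ones((5, 5)), ("fixed", 0.0))
        assert res.mask.all()

    def test_otsu_matches_bruteforce_sweep_on_two_level_image(self):
        img = np.full((20, 20), 10.0)
        img[4:8, 4:8] = 1000.0
        res = make_mask(img, "otsu")
        # brute force: best threshold separates the two populations
        best = None
        for t in np.unique(img):
            inter = ((img >= t).sum() * (img < t).sum())
            lo, hi = img[img < t], img[img >= t]
            if lo.size and hi.size:
                wvar = lo.size * lo.var() + hi.size * hi.var()
                if best is None or wvar < best[0]:
                    best = (wvar, t)
        expected = img >= best[1]
        np.testing.assert_array_equal(res.mask, expected)
        assert res.mask.sum() == 16

    def test_threshold_above_max_gives_empty_flagged_mask(self):
        with pytest.warns(UserWarning, match="empty"):
            res = make_mask(np.ones((5, 5)), ("fixed", 10.0))
        assert res.empty


class TestFieldRatio:
    def test_proportional_channels_give_the_factor(self):
        ref = np.full((10, 10), 200.0)
        stack = two_channel_stack(0.5 * ref, ref)
        res = lr.field_ratio(stack, make_mask(ref, ("fixed", 0.0)))
        assert res.ratio == pytest.approx(0.5, rel=1e-12)

    def test_single_ph_noiseless_field_matches_generative_ratio(self, aphid):
        cfg = lr.default_config(
            seed=3, n_organelles=10, organelle_ph=(5.0, 0.0),
            background=0.0, background_gradient=0.0, shape=(3, 128, 128),
        ).without_noise()
        stack, truth = lr.simulate_stack(cfg)
        proj = lr.sum_project(lr.background_correct(stack))
        res = lr.field_ratio(proj, make_mask(proj.channel(PH_INDEP), "otsu"))
        assert res.ratio == pytest.approx(float(aphid.value(5.0)), rel=1e-9)

    def test_empty_mask_flagged_undefined(self):
        ref = np.ones((5, 5))
        stack = two_channel_stack(ref, ref)
        with pytest.warns(UserWarning):
            mask = make_mask(ref, ("fixed", 10.0))
        res = lr.field_ratio(stack, mask)
        assert not res.defined
        assert res.ph_flag == "empty_mask"

    def test_ratio_invariant_to_common_channel_scaling(self):
        rng = np.random.default_rng(5)
        ref = rng.uniform(10, 1000, (24, 24))
        dep = 0.7 * ref
        for k in (0.5, 3.0, 100.0):
            m1 = make_mask(ref, "otsu")
            m2 = make_mask(k * ref, "otsu")
            np.testing.assert_array_equal(m1.mask, m2.mask)
            r1 = lr.field_ratio(two_channel_stack(dep, ref), m1).ratio
            r2 = lr.field_ratio(two_channel_stack(k * dep, k * ref), m2).ratio
            assert r2 == pytest.approx(r1, rel=1e-12)


# ---------------------------------------------------------------------------
# segmentation oracle: exhaustive threshold-connectivity saddle search


def oracle_object_count(img, threshold, saddle_fraction=0.5):
    """Brute force on a tiny image: find local maxima, find each pair's
    saddle by enumerating thresholds, group maxima whose saddle is too
    shallow, count groups."""
    mask = img >= threshold
    maxima = []
    h, w = img.shape
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            neigh = [
                img[rr, cc]
                for rr in range(max(0, r - 1), min(h, r + 2))
                for cc in range(max(0, c - 1), min(w, c + 2))
                if (rr, cc) != (r, c)
            ]
            if all(img[r, c] >= v for v in neigh):
                maxima.append((r, c))
    # deduplicate plateau maxima that are adjacent to each other
    keep = []
    for m in maxima:
        if not any(abs(m[0] - k[0]) <= 1 and abs(m[1] - k[1]) <= 1 for k in keep):
            keep.append(m)
    maxima = keep
    labels_full, _ = ndimage.label(mask, structure=np.ones((3, 3)))
    comp_of = {m: labels_full[m] for m in maxima}

    def saddle(a, b):
        best = -np.inf
        for t in np.unique(img[mask]):
            sub = mask & (img >= t)
            lab, _ = ndimage.label(sub, structure=np.ones((3, 3)))
            if lab[a] and lab[b] and lab[a] == lab[b]:
                best = max(best, t)
        return best

    # union maxima whose valley is too shallow to separate them
    parent = {m: m for m in maxima}

    def find(m):
        while parent[m] != m:
            m = parent[m]
        return m

    for i, a in enumerate(maxima):
        for b in maxima[i + 1:]:
            if comp_of[a] != comp_of[b]:
                continue
            s = saddle(a, b)
            lo = min(img[a], img[b])
            if not (s <= saddle_fraction * lo):  # too shallow: same object
                parent[find(b)] = find(a)
    return len({find(m) for m in maxima})


def double_gaussian(a1, a2, sep, sigma, size=32):
    c = size // 2
    img = gaussian_spot((size, size), (c, c - sep / 2), sigma, a1)
    img += gaussian_spot((size, size), (c, c + sep / 2), sigma, a2)
    return img


class TestSegmentObjects:
    def test_well_separated_gaussians_give_two_records(self):
        img = np.zeros((32, 32))
        img += gaussian_spot((32, 32), (8, 8), 2.0, 100.0)
        img += gaussian_spot((32, 32), (24, 24), 2.0, 100.0)
        seg = lr.segment_objects(img, 5.0, filters=lr.ObjectFilters(units="pixel"))
        assert len(seg.records) == 2

    def test_area_filter_discards_with_reason(self):
        img = np.zeros((32, 32))
        img[10, 10] = 100.0  # single pixel: area 1 < 10
        seg = lr.segment_objects(img, 5.0, filters=lr.ObjectFilters(units="pixel"))
        assert len(seg.records) == 0
        assert list(seg.discards["reason"]) == ["area"]

    def test_calibrated_units_require_pixel_size(self):
        img = np.zeros((8, 8))
        with pytest.raises(ValueError, match="pixel size"):
            lr.segment_objects(img, 1.0, filters=lr.ObjectFilters())

    @pytest.mark.parametrize("sep,expected", [(10, 2), (6, 1)])
    def test_saddle_rule_on_deep_and_shallow_valleys(self, sep, expected):
        # sep 10, sigma 2: saddle ~9% of the lower peak -> separate;
        # sep 6: saddle ~68% of the lower peak -> one object
        img = double_gaussian(100.0, 90.0, sep=sep, sigma=2.0)
        seg = lr.segment_objects(
            img, 3.0, filters=lr.ObjectFilters(area=(1, 1e9), units="pixel")
        )
        assert len(seg.records) == expected

    @pytest.mark.parametrize("sigma", [1.5, 2.5])
    @pytest.mark.parametrize("sep", [4, 6, 9, 12])
    @pytest.mark.parametrize("a2", [30.0, 55.0, 80.0, 100.0])
    def test_matches_bruteforce_oracle_on_double_gaussians(self, a2, sep, sigma):
        img = np.round(double_gaussian(100.0, a2, sep, sigma), 1)
        thr = 3.0
        seg = lr.segment_objects(
            img, thr, filters=lr.ObjectFilters(area=(0, 1e9), units="pixel")
        )
        assert len(seg.records) == oracle_object_count(img, thr)

    def test_pixel_partition_covers_mask_exactly(self):
        img = double_gaussian(100.0, 40.0, 8, 2.0)
        thr = 3.0
        seg = lr.segment_objects(
            img, thr, filters=lr.ObjectFilters(area=(0, 1e9), units="pixel")
        )
        npix = sum(r.n_pixels for r in seg.records)
        assert npix == int((img >= thr).sum())


class TestObjectRatios:
    def test_proportional_channels_give_factor(self):
        ref = gaussian_spot((32, 32), (16, 16), 2.5, 500.0)
        stack = two_channel_stack(1.7 * ref, ref)
        seg = lr.segment_objects(ref, 10.0, filters=lr.ObjectFilters(units="pixel"))
        lr.object_ratios(seg.records, stack)
        assert seg.records[0].ratio == pytest.approx(1.7, rel=1e-12)

    def test_simulated_organelle_ph_recovered(self, aphid, anchored_curve):
        cfg = lr.default_config(seed=9, n_organelles=15, shape=(5, 128, 128),
                                organelle_ph=(5.4, 0.0))
        stack, truth = lr.simulate_stack(cfg)
        corr = lr.background_correct(stack)
        thr = float(make_mask(corr.channel(PH_INDEP).reshape(1, -1),
                              "otsu").threshold)
        phs = []
        for p in range(5):
            seg = lr.segment_objects(corr.channel(PH_INDEP)[p], thr,
                                     filters=lr.ObjectFilters(units="pixel"),
                                     plane_index=p)
            lr.object_ratios(seg.records, corr, anchored_curve)
            phs += [r.ph for r in seg.records if np.isfinite(r.ph)]
        assert len(phs) >= 3
        assert np.median(phs) == pytest.approx(5.4, abs=0.05)

    def test_ratio_past_asymptote_flagged(self, anchored_curve):
        ref = gaussian_spot((16, 16), (8, 8), 2.0, 500.0)
        dep = ref * (anchored_curve.top * 2.0)  # ratio far above the curve
        stack = two_channel_stack(dep, ref)
        seg = lr.segment_objects(ref, 10.0, filters=lr.ObjectFilters(units="pixel"))
        lr.object_ratios(seg.records, stack, anchored_curve)
        assert seg.records[0].flags.get("non_interpolatable") == "above"
        frame = records_to_frame(seg.records)
        assert "non_interpolatable" in frame.loc[0, "flags"]


class TestRatioImage:
    def _uniform_field(self, ratio):
        ref = np.zeros((20, 20))
        ref[5:15, 5:15] = 1000.0
        return two_channel_stack(ratio * ref, ref)

    def test_min_ratio_maps_to_first_lut_entry(self):
        rgb = lr.ratio_image(self._uniform_field(0.2), 0.2, 1.0,
                             threshold_method=("fixed", 500.0))
        inside = rgb[7, 7]
        np.testing.assert_array_equal(inside, RATIO_LUT_V1[0])  # blue
        np.testing.assert_array_equal(rgb[0, 0], [0, 0, 0])  # outside mask

    def test_midway_ratio_maps_to_middle_entry(self):
        rgb = lr.ratio_image(self._uniform_field(0.6), 0.2, 1.0,
                             threshold_method=("fixed", 500.0))
        np.testing.assert_array_equal(rgb[7, 7], RATIO_LUT_V1[128])

    def test_acidic_and_mild_organelles_ordered_in_lut(self, aphid):
        ref = np.zeros((40, 40))
        ref[8:14, 8:14] = 1000.0
        ref[26:32, 26:32] = 1000.0
        dep = np.zeros_like(ref)
        dep[8:14, 8:14] = 1000.0 * aphid.value(4.6)  # acidic: high ratio
        dep[26:32, 26:32] = 1000.0 * aphid.value(6.0)  # mild: low ratio
        rgb = lr.ratio_image(
            two_channel_stack(dep, ref),
            float(aphid.value(6.0)), float(aphid.value(4.6)),
            threshold_method=("fixed", 500.0),
        )
        acidic = rgb[11, 11].astype(int)
        mild = rgb[29, 29].astype(int)
        # red (acidic) vs blue (least acidic) ends of the LUT
        assert acidic[0] > acidic[2] and mild[2] > mild[0]


class TestPhotobleachCurve:
    def test_constant_series_loses_nothing(self):
        series = lr.photobleach_curve(np.full(50, 123.0))
        assert (series.f_over_f0 == 1.0).all()
        assert series.fraction_lost == 0.0

    def test_first_cycle_normalized_to_exactly_one(self):
        series = lr.photobleach_curve([200.0, 150.0, 120.0])
        assert series.f_over_f0[0] == 1.0

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            lr.photobleach_curve([100.0])


class TestCountNuclei:
    def _nuclei_image(self, centers, diameter_um, pixel_size=1.0,
                      amplitude=150.0, background=50.0, size=256):
        img = np.full((size, size), background)
        rad = diameter_um / 2 / pixel_size
        yy, xx = np.mgrid[:size, :size]
        for cy, cx in centers:
            img[(yy - cy) ** 2 + (xx - cx) ** 2 <= rad**2] += amplitude
        return img

    def test_empty_image_counts_zero(self):
        img = np.full((64, 64), 50.0)
        assert lr.count_nuclei(img, pixel_size=1.0) == 0

    def test_seven_nuclei_counted(self):
        centers = [(30, 30), (30, 100), (30, 200), (100, 60), (128, 160),
                   (200, 40), (210, 210)]
        img = self._nuclei_image(centers, diameter_um=10.0)
        assert lr.count_nuclei(img, pixel_size=1.0, local_threshold=100.0) == 7

    def test_undersized_nucleus_excluded(self):
        img = self._nuclei_image([(100, 100)], diameter_um=2.0)
        assert lr.count_nuclei(img, pixel_size=1.0, min_width=5.0) == 0

    def test_requires_calibration(self):
        with pytest.raises(ValueError):
            lr.count_nuclei(np.zeros((8, 8)), pixel_size=None)
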