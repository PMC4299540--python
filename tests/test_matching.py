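"""Template extraction, NCC matching, Otsu binarization and localization."""

import numpy as np
import pytest
from scipy import ndimage

from tumorloc import (
    BSEParams,
    DegradationSpec,
    GTVStructure,
    PhantomSpec,
    Volume,
    binarize_gtv,
    bse_filter,
    centroid,
    degrade_to_cbct,
    extract_template,
    localize,
    make_phantom_ct,
    match_template,
    otsu_threshold,
)
from tumorloc.matching import TumorTemplate
from tumorloc.phantom import TumorSpec
from tumorloc.pipeline import coarse_register

from conftest import sphere_mask


def _cube_gtv(ct_shape, lo, hi):
    mask = np.zeros(ct_shape, bool)
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return GTVStructure(mask=mask, spacing=(1.0,) * 3, origin=(0.0,) * 3)


class TestExtractTemplate:
    def test_bbox_shape(self, smooth_volume):
        ct = smooth_volume((64, 64, 64))
        g = _cube_gtv((64, 64, 64), (30, 30, 30), (44, 44, 44))
        tpl = extract_template(ct, g, mode="none")
        assert tpl.image.shape == (14, 14, 14)
        assert tpl.gtv_mask.shape == (14, 14, 14)

    def test_raw_mode_is_crop_identity(self, smooth_volume):
        ct = smooth_volume((32, 32, 32))
        g = _cube_gtv((32, 32, 32), (10, 12, 14), (18, 20, 22))
        tpl = extract_template(ct, g, mode="none")
        np.testing.assert_array_equal(tpl.image, ct.data[10:18, 12:20, 14:22])

    def test_bse_padding_matches_whole_image_filtering(self, smooth_volume):
        ct = smooth_volume((48, 48, 48))
        mask = sphere_mask((48, 48, 48), (24, 24, 24), 6.0)
        g = GTVStructure(mask=mask, spacing=(1.0,) * 3, origin=(0.0,) * 3)
        p = BSEParams(sigma_mm=2.0)
        tpl = extract_template(ct, g, mode="bse", p=p)
        whole = bse_filter(ct, p).data[g.bbox_slices()]
        np.testing.assert_allclose(tpl.image, whole, atol=1e-10)

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            TumorTemplate(image=np.zeros((4, 4, 4)), gtv_mask=np.ones((5, 4, 4), bool),
                          mode="none", bbox=((0, 0, 0), (4, 4, 4)),
                          spacing=(1.0,) * 3)


class TestMatchTemplate:
    def _tpl(self, image):
        return TumorTemplate(image=image, gtv_mask=np.ones(image.shape, bool),
                             mode="none", bbox=((0, 0, 0), image.shape),
                             spacing=(1.0,) * 3)

    def test_planted_copy_recovered(self, rng):
        region = ndimage.gaussian_filter(rng.normal(size=(20, 20, 20)), 1.0)
        tpl = self._tpl(region[4:10, 2:8, 9:15].copy())
        offset, score = match_template(region, tpl)
        assert offset == (4, 2, 9)
        assert score == pytest.approx(1.0, abs=1e-7)

    def test_affine_rescaled_copy_recovered(self, rng):
        region = ndimage.gaussian_filter(rng.normal(size=(18, 18, 18)), 1.0)
        tpl = self._tpl(3.0 * region[5:11, 5:11, 5:11] + 40.0)
        offset, score = match_template(region, tpl)
        assert offset == (5, 5, 5)
        assert score == pytest.approx(1.0, abs=1e-7)

    def test_argmax_matches_brute_force(self, rng):
        from test_registration import brute_force_score_map

        region = rng.normal(size=(12, 11, 10))
        tpl = self._tpl(rng.normal(size=(4, 5, 3)))
        offset, score = match_template(region, tpl)
        oracle = brute_force_score_map(region, tpl.image)
        assert score == pytest.approx(oracle.max(), abs=1e-9)
        assert oracle[offset] == pytest.approx(oracle.max(), abs=1e-12)

    def test_oversized_template_rejected(self, rng):
        region = rng.normal(size=(6, 6, 6))
        with pytest.raises(ValueError):
            match_template(region, self._tpl(rng.normal(size=(8, 6, 6))))


class TestOtsu:
    def test_bimodal_lung_tumor_values(self):
        vals = np.array([-900.0] * 100 + [-630.0] * 100)
        thr = otsu_threshold(vals)
        assert -900.0 < thr <= -630.0
        assert np.array_equal(vals >= thr, vals == -630.0)

    def test_matches_exhaustive_bin_cut_oracle(self, rng):
        vals = rng.normal(0, 50, 500) + 200 * (rng.random(500) > 0.6)
        counts, edges = np.histogram(vals, bins=256, range=(vals.min(), vals.max()))
        centers = 0.5 * (edges[:-1] + edges[1:])
        best, best_i = -1.0, 0
        for i in range(255):  # cut after bin i
            w0 = counts[:i + 1].sum()
            w1 = counts[i + 1:].sum()
            if w0 == 0 or w1 == 0:
                continue
            m0 = (counts[:i + 1] * centers[:i + 1]).sum() / w0
            m1 = (counts[i + 1:] * centers[i + 1:]).sum() / w1
            sb = w0 * w1 * (m0 - m1) ** 2
            if sb > best:
                best, best_i = sb, i
        assert otsu_threshold(vals) == pytest.approx(edges[best_i + 1])

    def test_agrees_with_skimage_on_separated_classes(self, rng):
        from skimage.filters import threshold_otsu

        vals = np.concatenate([rng.normal(-900, 10, 300), rng.normal(-630, 10, 200)])
        thr = otsu_threshold(vals)
        thr_sk = threshold_otsu(vals, nbins=256)
        # conventions differ (upper bin edge vs bin center) by at most one bin
        assert abs(thr - thr_sk) <= (vals.max() - vals.min()) / 256
        # and both cleanly separate the two populations (ties across the
        # empty histogram gap resolve to the lowest cut)
        assert -880 < thr < -660
        assert np.array_equal(vals >= thr, vals > -750)

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.full(10, 5.0))

    def test_foreground_count_monotone_in_threshold(self, rng):
        vals = rng.normal(size=400)
        counts = [(vals >= t).sum() for t in np.linspace(vals.min(), vals.max(), 50)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestBinarize:
    def test_two_class_separation(self):
        cbct = Volume(data=np.full((10, 10, 10), -900.0))
        mask = np.zeros((10, 10, 10), bool)
        mask[2:8, 2:8, 2:8] = True
        cbct.data[3:7, 3:7, 3:7] = -630.0
        fg, warns = binarize_gtv(cbct, mask)
        assert not warns
        np.testing.assert_array_equal(fg, cbct.data == -630.0)

    def test_constant_set_falls_back_with_warning(self):
        cbct = Volume(data=np.full((8, 8, 8), -900.0))
        mask = np.zeros((8, 8, 8), bool)
        mask[2:6, 2:6, 2:6] = True
        with pytest.warns(UserWarning, match="constant"):
            fg, warns = binarize_gtv(cbct, mask)
        np.testing.assert_array_equal(fg, mask)
        assert warns

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            binarize_gtv(Volume(data=np.zeros((4, 4, 4))), np.zeros((4, 4, 4), bool))


class TestCentroid:
    def test_single_voxel(self):
        mask = np.zeros((32, 32, 32), bool)
        mask[10, 20, 30] = True
        assert centroid(mask, (1.0,) * 3, (0.0,) * 3) == (10.0, 20.0, 30.0)

    def test_symmetric_sphere(self):
        mask = sphere_mask((100, 100, 100), (50, 50, 50), 8.0)
        c = centroid(mask, (1.0,) * 3, (0.0,) * 3)
        assert np.linalg.norm(np.asarray(c) - 50.0) < 0.1

    def test_matches_brute_force_mean(self, rng):
        idx = rng.integers(0, 30, size=(20, 3))
        spacing, origin = (1.5, 1.0, 2.0), (-4.0, 3.0, 7.0)
        c = centroid(idx, spacing, origin)
        expect = [origin[a] + spacing[a] * idx[:, a].mean() for a in range(3)]
        np.testing.assert_allclose(c, expect, atol=1e-12)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            centroid(np.zeros((4, 4, 4), bool), (1.0,) * 3, (0.0,) * 3)


@pytest.fixture(scope="module")
def noiseless_setup():
    """Small phantom CT and a noiseless integer-shifted 'CBCT' copy."""
    spec = PhantomSpec(shape=(120, 120, 120))
    center = spec.station_center("bifurcation", side=+1)
    spec = PhantomSpec(shape=(120, 120, 120),
                       tumors=(TumorSpec("t", center, 10.0),))
    ct, gtvs, truth = make_phantom_ct(spec)
    shift = (4.0, -3.0, 6.0)
    d = DegradationSpec(blur_fwhm_mm=0.0, noise_sd=0.0, contrast_scale=1.0,
                        shift_mm=shift, fov_mm=90.0)
    cbct, rec = degrade_to_cbct(ct, d)
    tr = coarse_register(ct, cbct)
    return ct, cbct, gtvs[0], tr, np.asarray(truth["t"]), np.asarray(shift)


class TestLocalize:
    def test_noiseless_translated_copy_recovered(self, noiseless_setup):
        ct, cbct, g, tr, center, shift = noiseless_setup
        res = localize(ct, cbct, g, tr, mode="none")
        err = np.asarray(res.centroid_mm) - (center + shift)
        assert np.linalg.norm(err) <= 1.0

    def test_modes_agree_on_noiseless_phantom(self, noiseless_setup):
        ct, cbct, g, tr, center, shift = noiseless_setup
        c_none = np.asarray(localize(ct, cbct, g, tr, mode="none").centroid_mm)
        c_bse = np.asarray(localize(ct, cbct, g, tr, mode="bse").centroid_mm)
        assert np.linalg.norm(c_none - c_bse) <= np.sqrt(3.0)

    def test_deterministic_rerun(self, noiseless_setup):
        ct, cbct, g, tr, _, _ = noiseless_setup
        r1 = localize(ct, cbct, g, tr, mode="bse")
        r2 = localize(ct, cbct, g, tr, mode="bse")
        assert r1.centroid_mm == r2.centroid_mm
        assert r1.matched_offset == r2.matched_offset
        np.testing.assert_array_equal(r1.binarized_mask, r2.binarized_mask)

    def test_translation_equivariance(self):
        """Shifting the CBCT content by an integer vector shifts the
        estimated centroid by the same vector (noiseless case)."""
        spec = PhantomSpec(shape=(120, 120, 120))
        center = spec.station_center("bifurcation", side=-1)
        spec = PhantomSpec(shape=(120, 120, 120),
                           tumors=(TumorSpec("t", center, 10.0),))
        ct, gtvs, _ = make_phantom_ct(spec)
        cents = []
        for shift in [(2.0, 1.0, -3.0), (5.0, 3.0, -7.0)]:
            d = DegradationSpec(blur_fwhm_mm=0.0, noise_sd=0.0, contrast_scale=1.0,
                                shift_mm=shift, fov_mm=90.0)
            cbct, _ = degrade_to_cbct(ct, d)
            tr = coarse_register(ct, cbct)
            cents.append(np.asarray(localize(ct, cbct, gtvs[0], tr,
                                             mode="none").centroid_mm))
        delta = cents[1] - cents[0]
        assert np.all(np.abs(delta - np.array([3.0, 2.0, -4.0])) <= 1.0)

    def test_binarized_subset_of_placed(self, noiseless_setup):
        ct, cbct, g, tr, _, _ = noiseless_setup
        res = localize(ct, cbct, g, tr, mode="bse")
        assert np.all(res.placed_mask[res.binarized_mask])
        lo = np.asarray(res.region.box_min)
        hi = np.asarray(res.region.box_max)
        c_idx = cbct.world_to_index(res.centroid_mm)
        assert np.all(c_idx >= lo) and np.all(c_idx <= hi)
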