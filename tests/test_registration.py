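"""NCC, exhaustive translation registration, GTV mapping and search region."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from tumorloc import (
    DegenerateInputError,
    GTVStructure,
    Volume,
    build_search_region,
    map_gtv_to_cbct,
    ncc,
    register_translation,
)
from tumorloc.registration import TranslationResult, score_map


def brute_force_ncc(t, f):
    """Two-pass mean/SD oracle for the correlation coefficient."""
    t = np.asarray(t, float).ravel()
    f = np.asarray(f, float).ravel()
    tm, fm = t.mean(), f.mean()
    st_ = np.sqrt(((t - tm) ** 2).mean())
    sf = np.sqrt(((f - fm) ** 2).mean())
    return ((t - tm) * (f - fm)).mean() / (st_ * sf)


def brute_force_score_map(image, template):
    out_shape = tuple(i - t + 1 for i, t in zip(image.shape, template.shape))
    out = np.empty(out_shape)
    for x in range(out_shape[0]):
        for y in range(out_shape[1]):
            for z in range(out_shape[2]):
                win = image[x:x + template.shape[0], y:y + template.shape[1],
                            z:z + template.shape[2]]
                out[x, y, z] = brute_force_ncc(template, win)
    return out


class TestNCC:
    def test_identical_grids_score_one(self, rng):
        g = rng.normal(size=(5, 5, 5))
        assert ncc(g, g) == pytest.approx(1.0, abs=1e-12)

    def test_negation_about_mean_scores_minus_one(self, rng):
        g = rng.normal(size=(5, 5, 5))
        assert ncc(g, 2 * g.mean() - g) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_brute_force_formula(self, rng):
        t = rng.normal(size=(6, 6, 6))
        f = rng.normal(size=(6, 6, 6))
        assert ncc(t, f) == pytest.approx(brute_force_ncc(t, f), abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateInputError):
            ncc(np.ones((4, 4, 4)), np.random.default_rng(0).normal(size=(4, 4, 4)))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            ncc(np.zeros((4, 4, 4)), np.zeros((5, 4, 4)))

    @given(a=st.floats(0.1, 50.0), b=st.floats(-100.0, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_positive_affine_maps(self, a, b):
        rng = np.random.default_rng(7)
        t = rng.normal(size=(5, 5, 5))
        f = rng.normal(size=(5, 5, 5))
        assert ncc(a * t + b, f) == pytest.approx(ncc(t, f), abs=1e-10)


class TestRegisterTranslation:
    def _volumes_with_crop(self, rng, offset, ct_shape=(14, 14, 14), size=(6, 6, 6)):
        data = ndimage.gaussian_filter(rng.normal(size=ct_shape), 1.0)
        ct = Volume(data=data, spacing=(5.0,) * 3)
        sl = tuple(slice(o, o + s) for o, s in zip(offset, size))
        cbct = Volume(data=data[sl].copy(), spacing=(5.0,) * 3,
                      origin=tuple(5.0 * o for o in offset))
        return ct, cbct

    def test_recovers_planted_offset_exactly(self, rng):
        ct, cbct = self._volumes_with_crop(rng, (7, 3, 5))
        tr = register_translation(ct, cbct)
        assert tr.offset == (7, 3, 5)
        assert tr.score == pytest.approx(1.0, abs=1e-7)
        # origins encode the true placement, so the world translation is zero
        assert np.allclose(tr.translation_mm, (0.0, 0.0, 0.0))

    def test_recovers_offset_under_noise(self, rng):
        ct, cbct = self._volumes_with_crop(rng, (4, 6, 2))
        noisy = Volume(data=cbct.data + rng.normal(0, cbct.data.std() / 10,
                                                   cbct.data.shape),
                       spacing=cbct.spacing, origin=cbct.origin)
        assert register_translation(ct, noisy).offset == (4, 6, 2)

    @given(ox=st.integers(0, 6), oy=st.integers(0, 6), oz=st.integers(0, 6))
    @settings(max_examples=20, deadline=None)
    def test_exhaustive_recovery_over_random_offsets(self, ox, oy, oz):
        rng = np.random.default_rng(ox * 49 + oy * 7 + oz)
        ct, cbct = self._volumes_with_crop(rng, (ox, oy, oz), (13, 13, 13), (7, 7, 7))
        tr = register_translation(ct, cbct)
        assert tr.offset == (ox, oy, oz)
        assert tr.score == pytest.approx(1.0, abs=1e-7)

    def test_score_map_equals_brute_force(self, rng):
        image = rng.normal(size=(10, 9, 8))
        template = rng.normal(size=(4, 4, 4))
        np.testing.assert_allclose(score_map(image, template),
                                   brute_force_score_map(image, template),
                                   atol=1e-9)

    def test_constant_ct_raises_degenerate(self):
        ct = Volume(data=np.zeros((10, 10, 10)), spacing=(5.0,) * 3)
        cbct = Volume(data=np.random.default_rng(0).normal(size=(4, 4, 4)),
                      spacing=(5.0,) * 3)
        with pytest.raises(DegenerateInputError):
            register_translation(ct, cbct)

    def test_cbct_larger_than_ct_rejected(self, rng):
        ct = Volume(data=rng.normal(size=(6, 6, 6)), spacing=(5.0,) * 3)
        cbct = Volume(data=rng.normal(size=(8, 6, 6)), spacing=(5.0,) * 3)
        with pytest.raises(ValueError, match="nonnegative"):
            register_translation(ct, cbct)

    def test_tie_break_smallest_zyx(self):
        # two identical template copies; the (z, y, x)-smallest offset wins
        image = np.zeros((8, 4, 4))
        patt = np.array([[[0.0, 1.0], [2.0, 3.0]], [[4.0, 5.0], [6.0, 7.0]]])
        image[0:2, 0:2, 0:2] = patt
        image[5:7, 0:2, 0:2] = patt
        ct = Volume(data=image, spacing=(5.0,) * 3)
        cbct = Volume(data=patt.copy(), spacing=(5.0,) * 3)
        assert register_translation(ct, cbct).offset == (0, 0, 0)


class TestMapGTV:
    def _gtv(self, shape=(20, 20, 20), box=(8, 12)):
        mask = np.zeros(shape, bool)
        mask[box[0]:box[1], box[0]:box[1], box[0]:box[1]] = True
        return GTVStructure(mask=mask, spacing=(1.0,) * 3, origin=(0.0,) * 3)

    def _tr(self, translation):
        return TranslationResult(offset=(0, 0, 0), offset_mm=(0.0, 0.0, 0.0),
                                 translation_mm=translation, score=1.0,
                                 spacing_mm=5.0)

    def test_zero_offset_identity(self):
        g = self._gtv()
        cbct = Volume(data=np.zeros((20, 20, 20)))
        out = map_gtv_to_cbct(g, self._tr((0.0, 0.0, 0.0)), cbct)
        np.testing.assert_array_equal(out.mask, g.mask)
        assert out.v_gtv == g.v_gtv and out.d == g.d

    def test_pure_translation_shifts_indices(self):
        g = self._gtv()
        cbct = Volume(data=np.zeros((20, 20, 20)))
        out = map_gtv_to_cbct(g, self._tr((5.0, 0.0, 0.0)), cbct)
        np.testing.assert_array_equal(out.mask[13:17, 8:12, 8:12],
                                      g.mask[8:12, 8:12, 8:12])
        assert out.mask.sum() == g.mask.sum()

    def test_centroid_moves_by_translation(self, rng):
        mask = np.zeros((24, 24, 24), bool)
        idx = rng.integers(4, 16, size=(30, 3))
        mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        g = GTVStructure(mask=mask, spacing=(1.0,) * 3, origin=(0.0,) * 3)
        t = (3.0, -2.0, 4.0)
        out = map_gtv_to_cbct(g, self._tr(t), Volume(data=np.zeros((24, 24, 24))))
        delta = out.centroid_mm() - g.centroid_mm()
        assert np.all(np.abs(delta - np.asarray(t)) <= 0.5)

    def test_fully_outside_raises(self):
        g = self._gtv()
        cbct = Volume(data=np.zeros((20, 20, 20)))
        with pytest.raises(ValueError, match="outside"):
            map_gtv_to_cbct(g, self._tr((100.0, 0.0, 0.0)), cbct)

    def test_partial_clip_warns(self):
        g = self._gtv()
        cbct = Volume(data=np.zeros((20, 20, 20)))
        with pytest.warns(UserWarning, match="clipped"):
            out = map_gtv_to_cbct(g, self._tr((10.0, 0.0, 0.0)), cbct)
        assert out.mask.sum() < g.mask.sum()


class TestSearchRegion:
    def _gtv_box(self, shape, lo, hi):
        mask = np.zeros(shape, bool)
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
        return GTVStructure(mask=mask, spacing=(1.0,) * 3, origin=(0.0,) * 3)

    def test_plus_minus_20_arithmetic(self):
        g = self._gtv_box((128, 128, 128), (30, 30, 30), (40, 40, 40))
        cbct = Volume(data=np.zeros((128, 128, 128)))
        r = build_search_region(g, cbct, dilation_px=20)
        assert r.box_min == (10, 10, 10) and r.box_max == (60, 60, 60)

    def test_border_clip(self):
        g = self._gtv_box((64, 64, 64), (0, 5, 30), (8, 15, 40))
        cbct = Volume(data=np.zeros((64, 64, 64)))
        r = build_search_region(g, cbct, dilation_px=20)
        assert r.box_min == (0, 0, 10) and r.box_max == (28, 35, 60)

    def test_equals_iterated_26_neighbor_dilation(self):
        g = self._gtv_box((60, 60, 60), (25, 25, 25), (30, 31, 32))
        cbct = Volume(data=np.zeros((60, 60, 60)))
        r = build_search_region(g, cbct, dilation_px=20)
        box_mask = np.zeros((60, 60, 60), bool)
        box_mask[r.slices()] = True
        oracle = ndimage.binary_dilation(g.mask, structure=np.ones((3, 3, 3)),
                                         iterations=20)
        np.testing.assert_array_equal(box_mask, oracle)

    def test_monotone_in_dilation(self):
        g = self._gtv_box((64, 64, 64), (20, 20, 20), (30, 30, 30))
        cbct = Volume(data=np.zeros((64, 64, 64)))
        small = build_search_region(g, cbct, dilation_px=5)
        big = build_search_region(g, cbct, dilation_px=15)
        assert all(b <= s for b, s in zip(big.box_min, small.box_min))
        assert all(b >= s for b, s in zip(big.box_max, small.box_max))
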