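import numpy as np
import pytest
from scipy.stats import norm

from egps.scoring import (
    PixelEGPS,
    QuantileReference,
    apply_reference,
    fit_quantile_reference,
    pixel_egps,
    rank_to_normal,
    render_painting,
    slide_egps,
)


class TestRankToNormal:
    def test_median_maps_to_zero(self):
        out = rank_to_normal([0.2, 0.5, 0.9])
        assert out[1] == pytest.approx(0.0, abs=1e-12)

    def test_all_ties_map_to_zero(self):
        np.testing.assert_allclose(rank_to_normal([3.0] * 4), 0.0, atol=1e-12)

    def test_quantile_table_values(self):
        out = rank_to_normal([0.1, 0.4, 0.6, 0.95])
        expected = norm.ppf([0.2, 0.4, 0.6, 0.8])
        np.testing.assert_allclose(out, expected, atol=1e-6)
        np.testing.assert_allclose(
            out, [-0.8416212, -0.2533471, 0.2533471, 0.8416212], atol=1e-6
        )

    def test_strictly_increasing_in_value(self, rng):
        v = rng.normal(size=50)
        out = rank_to_normal(v)
        order = np.argsort(v)
        assert (np.diff(out[order]) > 0).all()


class TestQuantileReference:
    def test_single_slide_reference_equals_pooled_values(self, rng):
        pm = rng.random((2, 8, 8))
        tm = np.ones((8, 8), dtype=np.uint8)
        pm_big = np.repeat(np.repeat(pm, 4, axis=1), 4, axis=2)  # >=100 px/channel
        ref = fit_quantile_reference([pm_big], [np.ones((32, 32), np.uint8)])
        np.testing.assert_allclose(ref.channels[0], np.sort(pm_big[0].ravel()))

    def test_too_few_pixels_rejected(self, rng):
        with pytest.raises(ValueError, match="pooled tissue pixels"):
            fit_quantile_reference([rng.random((1, 5, 5))], [np.ones((5, 5), np.uint8)])

    def test_subsample_deterministic(self, rng):
        pm = rng.random((1, 40, 40))
        tm = np.ones((40, 40), np.uint8)
        r1 = fit_quantile_reference([pm], [tm], max_size=200, seed=4)
        r2 = fit_quantile_reference([pm], [tm], max_size=200, seed=4)
        np.testing.assert_array_equal(r1.channels[0], r2.channels[0])

    def test_self_reference_standardizes(self, rng):
        pm = rng.random((1, 128, 128))
        tm = np.ones((128, 128), np.uint8)
        ref = fit_quantile_reference([pm], [tm])
        scores = apply_reference(pm[0].ravel(), ref.channels[0])
        assert abs(scores.mean()) < 0.02
        assert abs(scores.std() - 1.0) < 0.05


class TestApplyReference:
    def test_below_reference_clipped_to_finite_floor(self):
        ref = np.linspace(0.2, 0.9, 9)
        out = apply_reference(np.array([0.0]), ref)
        assert out[0] == pytest.approx(norm.ppf(1.0 / 10.0), abs=1e-12)

    def test_reference_median_maps_to_zero(self):
        ref = np.linspace(0.0, 1.0, 9)
        assert apply_reference(np.array([0.5]), ref)[0] == pytest.approx(0.0, abs=1e-12)

    def test_self_application_reproduces_rank_to_normal(self, rng):
        vals = rng.random(500)
        vals[::7] = vals[0]  # inject ties
        np.testing.assert_allclose(
            apply_reference(vals, np.sort(vals)), rank_to_normal(vals), atol=1e-9
        )

    def test_monotone_in_value(self, rng):
        ref = np.sort(rng.random(100))
        v = np.sort(rng.random(50))
        out = apply_reference(v, ref)
        assert (np.diff(out) >= 0).all()


def _random_cohort(rng, n_slides=4, k=3, size=24):
    pms = [rng.random((k, size, size)) for _ in range(n_slides)]
    tms = [(rng.random((size, size)) < 0.8).astype(np.uint8) for _ in range(n_slides)]
    return pms, tms


class TestPixelAndSlideScores:
    def test_identical_channels_equal_single_channel_score(self, rng):
        pms, tms = _random_cohort(rng, k=1)
        pm3 = [np.repeat(p, 3, axis=0) for p in pms]
        ref1 = fit_quantile_reference(pms, tms)
        ref3 = fit_quantile_reference(pm3, tms)
        a = pixel_egps(pms[0], ref1, tms[0])
        b = pixel_egps(pm3[0], ref3, tms[0])
        np.testing.assert_allclose(a.scores[a.tissue_mask > 0], b.scores[b.tissue_mask > 0], atol=1e-12)

    def test_pixel_scores_match_brute_force_loop(self, rng):
        pms, tms = _random_cohort(rng, size=16)
        ref = fit_quantile_reference(pms, tms)
        got = pixel_egps(pms[0], ref, tms[0])
        for i in range(16):
            for j in range(16):
                if tms[0][i, j]:
                    manual = np.mean(
                        [
                            apply_reference(np.array([pms[0][c, i, j]]), ref.channels[c])[0]
                            for c in range(3)
                        ]
                    )
                    assert got.scores[i, j] == pytest.approx(manual, abs=1e-10)
                else:
                    assert np.isnan(got.scores[i, j])

    def test_channel_mismatch_rejected(self, rng):
        pms, tms = _random_cohort(rng)
        ref = fit_quantile_reference(pms, tms)
        with pytest.raises(ValueError, match="channels"):
            pixel_egps(pms[0][:2], ref, tms[0])

    def test_slide_mean_over_tissue_only(self, rng):
        scores = rng.normal(size=(5, 5))
        mask = (rng.random((5, 5)) < 0.6).astype(np.uint8)
        mask[0, 0] = 1
        p = PixelEGPS(scores=np.where(mask, scores, np.nan), tissue_mask=mask)
        manual = np.mean([scores[i, j] for i in range(5) for j in range(5) if mask[i, j]])
        assert slide_egps(p) == pytest.approx(manual, abs=1e-12)

    def test_slide_trivial_values(self):
        mask = np.ones((2, 1), np.uint8)
        assert slide_egps(PixelEGPS(np.full((2, 1), 0.7), mask)) == pytest.approx(0.7)
        assert slide_egps(PixelEGPS(np.array([[-1.0], [1.0]]), mask)) == pytest.approx(0.0)

    def test_empty_tissue_rejected(self):
        p = PixelEGPS(np.full((3, 3), np.nan), np.zeros((3, 3), np.uint8))
        with pytest.raises(ValueError, match="tissue"):
            slide_egps(p)

    def test_slide_score_invariant_to_tiling(self, rng):
        """Scoring a slide whole or as tiles gives the same mean."""
        pms, tms = _random_cohort(rng, n_slides=1, size=32)
        ref = fit_quantile_reference(pms, tms)
        whole = slide_egps(pixel_egps(pms[0], ref, tms[0]))
        parts = [
            pixel_egps(pms[0][:, i : i + 16, j : j + 16], ref, tms[0][i : i + 16, j : j + 16])
            for i in (0, 16)
            for j in (0, 16)
            if tms[0][i : i + 16, j : j + 16].any()
        ]
        assert slide_egps(parts) == pytest.approx(whole, abs=1e-12)


class TestMonotoneInvariance:
    def test_increasing_transform_leaves_scores_unchanged(self, rng):
        """eGPS depends only on ranks: applying a strictly increasing map
        to the probabilities (data and reference alike) changes nothing."""
        transforms = [lambda v: v**3, lambda v: 1 / (1 + np.exp(-5 * v)), lambda v: 7 * v - 2]
        for trial in range(50):
            pms, tms = _random_cohort(rng, n_slides=2, size=12)
            ref = fit_quantile_reference(pms, tms)
            base = pixel_egps(pms[0], ref, tms[0])
            g = transforms[trial % len(transforms)]
            pms_t = [g(p) for p in pms]
            ref_t = fit_quantile_reference(pms_t, tms)
            trans = pixel_egps(pms_t[0], ref_t, tms[0])
            sel = base.tissue_mask > 0
            np.testing.assert_allclose(base.scores[sel], trans.scores[sel], atol=1e-9)


class TestPerSlideReferenceDegeneracy:
    def test_per_slide_referencing_collapses_slide_scores(self, rng):
        """Ranking each slide against itself forces every slide mean to ~0,
        which is why the reference must be fitted at cohort level."""
        for _ in range(5):
            k, size = 3, 64
            pm = rng.random((k, size, size))
            tm = (rng.random((size, size)) < 0.9).astype(np.uint8)
            own_ref = fit_quantile_reference([pm], [tm])
            score = slide_egps(pixel_egps(pm, own_ref, tm))
            assert abs(score) < 0.05


class TestPainting:
    def test_all_low_scores_render_uniform_dark_blue(self):
        mask = np.ones((4, 4), np.uint8)
        p = PixelEGPS(np.full((4, 4), -3.0), mask)
        img = render_painting(p, breakpoints=(-1.0, 0.0, 1.0))
        assert (img == np.array([0, 0, 139])).all()

    def test_background_rendered_white(self, rng):
        mask = np.zeros((4, 4), np.uint8)
        mask[0, 0] = 1
        scores = np.full((4, 4), np.nan)
        scores[0, 0] = 0.5
        img = render_painting(PixelEGPS(scores, mask), breakpoints=(-1, 0, 1))
        assert (img[1:] == 255).all()

    def test_monotone_ramp_orders_palette_bands(self):
        scores = np.linspace(-2, 2, 16).reshape(1, 16)
        mask = np.ones((1, 16), np.uint8)
        img = render_painting(PixelEGPS(scores, mask), breakpoints=(-1.0, 0.0, 1.0))
        palette = [(0, 0, 139), (65, 105, 225), (255, 215, 0), (255, 140, 0)]
        bands = [palette.index(tuple(px)) for px in img[0]]
        assert bands == sorted(bands)
        assert set(bands) == {0, 1, 2, 3}
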