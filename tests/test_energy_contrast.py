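import itertools

import numpy as np
import pytest

from mammoprep import (
    ClippedCurve,
    EnergyCurve,
    GrayImage,
    band_distributions,
    build_transfer_function,
    clip_energy_curve,
    compute_energy_curve,
    enhance_contrast,
    partition_bands,
)
from mammoprep.energy_contrast import BandPartition

from conftest import naive_energy_curve


class TestEnergyCurve:
    def test_checkerboard_worked_example(self):
        img = GrayImage(np.array([[0, 1], [1, 0]]), levels=2)
        curve = compute_energy_curve(img, d=1, f=1)
        np.testing.assert_array_equal(curve.values, [16.0, 0.0])

    def test_constant_image_zero_curve(self):
        img = GrayImage(np.full((8, 8), 3, dtype=int), levels=16)
        curve = compute_energy_curve(img)
        assert (curve.values == 0).all()

    def test_top_level_always_zero(self, random_images):
        for img in random_images:
            assert compute_energy_curve(img).values[-1] == 0.0

    @pytest.mark.parametrize("d,f", [(1, 1.0), (2, 1.0), (2, 2.0)])
    def test_matches_naive_oracle(self, rng, d, f):
        pix = rng.integers(0, 8, size=(6, 7))
        img = GrayImage(pix, levels=8)
        curve = compute_energy_curve(img, d=d, f=f)
        expected = naive_energy_curve(pix, 8, d=d, f=f)
        np.testing.assert_allclose(curve.values, expected, atol=1e-9)

    def test_zero_iff_constant_threshold_field(self):
        # exhaustive over all 2x2 binary images
        for bits in itertools.product([0, 1], repeat=4):
            pix = np.array(bits).reshape(2, 2)
            curve = compute_energy_curve(GrayImage(pix, levels=2))
            b0 = pix > 0
            constant = b0.all() or (~b0).all()
            assert (curve.values[0] == 0.0) == constant

    def test_isotropic_under_transpose_and_rotation(self, rng):
        pix = rng.integers(0, 32, size=(9, 9))
        base = compute_energy_curve(GrayImage(pix, 32)).values
        for variant in (pix.T, np.rot90(pix)):
            v = compute_energy_curve(GrayImage(variant.copy(), 32)).values
            np.testing.assert_allclose(v, base, atol=1e-9)

    def test_rejects_bad_params(self, rng):
        img = GrayImage(rng.integers(0, 4, size=(3, 3)), 4)
        with pytest.raises(ValueError):
            compute_energy_curve(img, d=0)
        with pytest.raises(ValueError):
            compute_energy_curve(img, f=5.0)


class TestClip:
    def test_worked_example(self):
        curve = EnergyCurve(np.array([10.0, 30.0, 2.0]))
        clipped = clip_energy_curve(curve)
        assert clipped.clip_threshold == pytest.approx(24.0)  # mean 14 + median 10
        np.testing.assert_allclose(clipped.values, [10.0, 24.0, 2.0])

    def test_below_threshold_unchanged(self):
        curve = EnergyCurve(np.array([1.0, 2.0, 3.0, 0.0]))
        clipped = clip_energy_curve(curve)
        np.testing.assert_allclose(clipped.values, curve.values)

    def test_all_zero_degenerate(self):
        clipped = clip_energy_curve(EnergyCurve(np.zeros(8)))
        assert clipped.degenerate and clipped.clip_threshold == 0.0

    def test_max_bounded_by_threshold(self, rng):
        vals = rng.uniform(0, 100, size=64)
        clipped = clip_energy_curve(EnergyCurve(vals))
        assert clipped.values.max() <= clipped.clip_threshold + 1e-12


class TestPartition:
    def _img(self, lo, hi, R=256):
        return GrayImage(np.array([[lo, hi], [lo, hi]]), levels=R)

    def test_single_spike_zero_spread(self):
        vals = np.zeros(256)
        vals[90] = 50.0
        clipped = ClippedCurve(vals, clip_threshold=50.0)
        bands = partition_bands(clipped, self._img(40, 200))
        assert bands.std_w == pytest.approx(0.0)
        assert bands.lo_low == 40 and bands.lo_high == 200
        assert not bands.fallback

    def test_symmetric_two_spike_triggers_fallback(self):
        vals = np.zeros(256)
        vals[64] = vals[192] = 10.0
        clipped = ClippedCurve(vals, clip_threshold=10.0)
        bands = partition_bands(clipped, self._img(64, 192))
        # m=128, StD=64 -> lo_low = lo_high = 128 -> tercile fallback
        assert bands.fallback
        assert bands.lo_low == 64 and bands.lo_high == 192

    def test_bands_cover_range_disjointly(self, rng):
        for _ in range(20):
            vals = rng.uniform(0, 5, size=64)
            img = GrayImage(rng.integers(0, 64, size=(6, 6)), levels=64)
            bands = partition_bands(ClippedCurve(vals, 5.0), img)
            (a0, b0), (a1, b1), (a2, b2) = bands.band_ranges()
            assert a0 == 0 and b2 == 63
            assert a1 == b0 + 1 and a2 == b1 + 1

    def test_degenerate_curve_fixed_thirds(self):
        bands = partition_bands(ClippedCurve(np.zeros(256), 0.0, degenerate=True),
                                self._img(0, 255))
        assert bands.fallback
        assert 0 < bands.lo_low < bands.lo_high < 255


class TestDistributionsAndTransfer:
    def test_pdfs_sum_to_one(self, rng):
        vals = rng.uniform(0.1, 5, size=32)
        img = GrayImage(rng.integers(0, 32, size=(8, 8)), levels=32)
        clipped = ClippedCurve(vals, vals.max())
        bands = partition_bands(clipped, img)
        pdfs, cdfs, flags = band_distributions(clipped, bands)
        for pdf, cdf, flagged in zip(pdfs, cdfs, flags):
            if len(pdf):
                assert pdf.sum() == pytest.approx(1.0, abs=1e-9)
                assert cdf[-1] == pytest.approx(1.0, abs=1e-9)

    def test_uniform_energy_linear_cdf(self):
        bands = BandPartition(lo_low=9, lo_high=20, R=32)
        vals = np.ones(32)
        pdfs, cdfs, _ = band_distributions(ClippedCurve(vals, 1.0), bands)
        w = 10  # band [0, 9]
        np.testing.assert_allclose(cdfs[0], np.arange(1, w + 1) / w, atol=1e-12)

    def test_zero_mass_band_uniform_and_flagged(self):
        vals = np.zeros(16)
        vals[12:] = 1.0
        bands = BandPartition(lo_low=5, lo_high=10, R=16)
        pdfs, _, flags = band_distributions(ClippedCurve(vals, 1.0), bands)
        assert flags[0] and flags[1] and not flags[2]
        np.testing.assert_allclose(pdfs[0], np.full(6, 1 / 6))

    def test_saturated_cdf_maps_to_band_top(self):
        bands = BandPartition(lo_low=4, lo_high=9, R=16)
        cdfs = [np.ones(5), np.ones(5), np.ones(6)]
        trf = build_transfer_function(bands, cdfs)
        assert (trf.mapping[:5] == 4).all()
        assert (trf.mapping[5:10] == 9).all()
        assert (trf.mapping[10:] == 15).all()

    def test_uniform_band_linear_map(self):
        # uniform energy in band [0, 9]: TrF(l) = round(9*(l+1)/10)
        bands = BandPartition(lo_low=9, lo_high=20, R=32)
        vals = np.ones(32)
        _, cdfs, _ = band_distributions(ClippedCurve(vals, 1.0), bands)
        trf = build_transfer_function(bands, cdfs)
        expected = np.floor(9 * (np.arange(10) + 1) / 10 + 0.5).astype(int)
        np.testing.assert_array_equal(trf.mapping[:10], expected)

    def test_monotone_and_bounded(self, rng):
        for _ in range(25):
            R = 64
            vals = rng.uniform(0, 3, size=R)
            img = GrayImage(rng.integers(0, R, size=(6, 6)), levels=R)
            clipped = ClippedCurve(vals, vals.max() if vals.max() > 0 else 1.0)
            bands = partition_bands(clipped, img)
            _, cdfs, _ = band_distributions(clipped, bands)
            trf = build_transfer_function(bands, cdfs)
            assert trf.mapping.min() >= 0 and trf.mapping.max() <= R - 1
            for a, b in bands.band_ranges():
                if a < b:
                    assert (np.diff(trf.mapping[a:b + 1]) >= 0).all()


class TestEnhanceEndToEnd:
    def test_constant_image_unchanged(self):
        img = GrayImage(np.full((10, 10), 123, dtype=int))
        report = {}
        out = enhance_contrast(img, report=report)
        assert report["degenerate_curve"]
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_output_within_levels(self, random_images):
        for img in random_images:
            out = enhance_contrast(img)
            assert out.pixels.min() >= 0
            assert out.pixels.max() <= img.levels - 1

    def test_low_contrast_range_widens(self):
        rng = np.random.default_rng(5)
        base = rng.integers(100, 157, size=(64, 64))
        smooth = np.clip(base, 100, 156)
        img = GrayImage(smooth, levels=256)
        out = enhance_contrast(img)
        in_range = img.pixels.max() - img.pixels.min()
        out_range = out.pixels.max() - out.pixels.min()
        assert out_range > in_range

    def test_rank_preserved_within_bands(self, rng):
        img = GrayImage(rng.integers(0, 64, size=(12, 12)), levels=64)
        report = {}
        out = enhance_contrast(img, report=report)
        lo_low, lo_high = report["lo_low"], report["lo_high"]

        def band_of(l):
            return 0 if l <= lo_low else (1 if l <= lo_high else 2)

        flat_in = img.pixels.ravel()
        flat_out = out.pixels.ravel()
        for p in range(len(flat_in)):
            for q in range(p + 1, len(flat_in)):
                if band_of(flat_in[p]) == band_of(flat_in[q]) and flat_in[p] <= flat_in[q]:
                    assert flat_out[p] <= flat_out[q]

    def test_deterministic(self, rng):
        pix = rng.integers(0, 256, size=(32, 32))
        a = enhance_contrast(GrayImage(pix))
        b = enhance_contrast(GrayImage(pix.copy()))
        np.testing.assert_array_equal(a.pixels, b.pixels)
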