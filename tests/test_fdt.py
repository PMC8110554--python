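"""Punctum detection and intensity-distribution statistics."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from synei import fdt, synthetic as sy
from conftest import match_centroids


def make_stack(data):
    return fdt.ImageStack(data=data.astype(np.uint8))


class TestNormalizeBackground:
    def test_constant_stack_maps_to_target(self):
        stack = make_stack(np.full((2, 4, 16, 16), 100))
        out = fdt.normalize_background(stack, target_fraction=0.30)
        assert np.all(np.isin(out.data, [76]))  # 0.30 * 255 = 76.5, rounded

    def test_all_zero_stack_unchanged(self):
        stack = make_stack(np.zeros((2, 4, 16, 16)))
        out = fdt.normalize_background(stack)
        assert np.array_equal(out.data, stack.data)

    def test_gradient_background_flattened(self):
        # linear background ramp 40 -> 120 along x plus two bright puncta;
        # away from the puncta and the filter's boundary roll-off the
        # normalized background sits at ~76 (= 0.30 * 255) everywhere
        nz, ny, nx = 8, 96, 160
        ramp = np.linspace(40, 120, nx)[None, None, :]
        data = np.broadcast_to(ramp, (nz, ny, nx)).copy()
        data[4, 30, 60] += 80
        data[4, 60, 100] += 80
        stack = fdt.ImageStack(data=np.stack([data, data]).astype(np.uint8))
        out = fdt.normalize_background(stack, sigma=1.0)  # sigma 10 px in xy
        bg = out.data[0].astype(float)
        mask = np.ones_like(bg, dtype=bool)
        mask[:, :, :35] = mask[:, :, -35:] = False      # ramp edges
        mask[:, :35, :] = mask[:, -35:, :] = False      # y edges
        mask[:, 0:60, 30:90] = False                    # punctum roll-off
        mask[:, 30:90, 70:130] = False
        assert mask.sum() > 0
        assert np.all(np.abs(bg[mask] - 76.0) <= 2.0)

    def test_invalid_target_fraction(self):
        stack = make_stack(np.full((2, 4, 8, 8), 50))
        with pytest.raises(ValueError):
            fdt.normalize_background(stack, target_fraction=1.5)


class TestDetectPuncta:
    def test_empty_scene_yields_no_puncta(self):
        spec = sy.FdtSceneSpec(n_puncta=0, n_blobs=0, noise_sd=0.0)
        stack, _ = sy.gen_fdt_stack(spec, 0)
        norm = fdt.normalize_background(stack)
        assert len(fdt.detect_puncta(norm)) == 0

    def test_planted_puncta_all_recovered(self, detected_separated):
        # 50 well-separated puncta per channel at SNR >= 5: every one is
        # found, none invented, centroids within one voxel diagonal
        pset, truth = detected_separated
        for ch in ("PSD95", "GPHN"):
            det = np.array([p.centroid for p in pset.for_channel(ch).puncta])
            tru = truth.objects.query("channel == @ch")[
                ["z_um", "y_um", "x_um"]].to_numpy()
            assert len(det) == len(tru) == 50
            assert match_centroids(det, tru, tol_um=0.25) == 50

    def test_detection_recall_and_precision(self, detected_separated):
        pset, truth = detected_separated
        det = np.array([p.centroid for p in pset.for_channel("PSD95").puncta])
        tru = truth.objects.query("channel == 'PSD95'")[
            ["z_um", "y_um", "x_um"]].to_numpy()
        matched = match_centroids(det, tru, tol_um=0.25)
        assert matched / len(tru) >= 0.95      # recall
        assert matched / len(det) >= 0.95      # precision

    def test_lipofuscin_blob_excluded(self):
        spec = sy.FdtSceneSpec(n_puncta=0, n_blobs=2, noise_sd=3.0)
        stack, _ = sy.gen_fdt_stack(spec, 1)
        norm = fdt.normalize_background(stack)
        assert len(fdt.detect_puncta(norm)) == 0

    def test_punctum_measures_within_criteria(self, detected_separated):
        pset, _ = detected_separated
        cfg = fdt.DetectionConfig()
        for p in pset.puncta:
            assert cfg.min_volume <= p.volume <= cfg.max_volume
            assert p.eccentricity <= cfg.max_eccentricity
            assert 0 <= p.mean_intensity <= 255

    def test_merging_idempotent_over_duplicate_threshold(self):
        # series {t} union {t} yields exactly the series-{t} result
        spec = sy.FdtSceneSpec(shape=(12, 96, 96), n_puncta=20, n_blobs=0)
        stack, _ = sy.gen_fdt_stack(spec, 3)
        norm = fdt.normalize_background(stack)
        single = fdt.DetectionConfig(threshold_series=(100,))
        dup = fdt.DetectionConfig(threshold_series=(100, 100))
        a = fdt.detect_puncta(norm, single)
        b = fdt.detect_puncta(norm, dup)
        assert len(a) == len(b)
        assert {p.centroid for p in a.puncta} == {p.centroid for p in b.puncta}
        assert ([p.mean_intensity for p in a.puncta]
                == [p.mean_intensity for p in b.puncta])

    def test_offset_invariance_of_count(self):
        bright = sy.IntensityModel(mode=165.0, spread=8.0)
        spec = sy.FdtSceneSpec(shape=(14, 160, 160), n_puncta=40, n_blobs=0,
                               min_separation_factor=1.4, noise_sd=5.0,
                               exc_intensity=bright, inh_intensity=bright)
        stack, _ = sy.gen_fdt_stack(spec, 5)
        base = fdt.detect_puncta(fdt.normalize_background(stack))
        shifted = dataclasses.replace(
            stack, data=np.clip(stack.data.astype(int) + 25, 0, 255
                                ).astype(np.uint8))
        moved = fdt.detect_puncta(fdt.normalize_background(shifted))
        assert len(moved) == len(base)

    def test_degenerate_threshold_series_fails(self):
        with pytest.raises(ValueError):
            fdt.DetectionConfig(threshold_start=100, threshold_stop=50)


class TestIntensityDistribution:
    def test_hand_tallied_histogram(self):
        vals = np.array([30, 30, 80, 95, 95, 95, 120, 150, 60, 60], dtype=float)
        dist = fdt.intensity_frequency_distribution(vals, bin_width=20)
        expected = np.array([20, 0, 20, 40, 0, 10, 10, 0], dtype=float)
        np.testing.assert_allclose(dist.proportions, expected)
        assert dist.n_total == 10

    def test_single_value_single_bin(self):
        dist = fdt.intensity_frequency_distribution(np.full(7, 100.0))
        assert dist.proportions.max() == 100.0
        assert (dist.proportions > 0).sum() == 1

    def test_empty_set_fails(self):
        with pytest.raises(ValueError):
            fdt.intensity_frequency_distribution(np.array([]))

    def test_bin_width_must_divide_scale(self):
        with pytest.raises(ValueError):
            fdt.intensity_frequency_distribution(np.array([50.0]), bin_width=7)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(hst.lists(hst.floats(min_value=20, max_value=179.9), min_size=1,
                     max_size=200))
    def test_proportions_always_sum_to_100(self, values):
        dist = fdt.intensity_frequency_distribution(np.array(values))
        assert abs(dist.proportions.sum() - 100.0) < 1e-9
        low, mid, high = fdt.band_proportions(dist)
        assert abs(low + mid + high - 100.0) < 1e-9


class TestBandsAndPeaks:
    def test_uniform_band_split_is_analytic(self):
        # one punctum per 5-wide bin over [20, 180): low = 55/160 of mass
        centers = np.arange(22.5, 180, 5.0)
        dist = fdt.intensity_frequency_distribution(centers)
        low, mid, high = fdt.band_proportions(dist)
        assert low == pytest.approx(34.375)
        assert mid == pytest.approx(9.375)
        assert high == pytest.approx(56.25)
        assert fdt.high_low_ratio(dist) == pytest.approx(56.25 / 34.375)

    def test_all_mass_at_100_is_all_high(self):
        dist = fdt.intensity_frequency_distribution(np.full(10, 100.0))
        assert fdt.band_proportions(dist) == (0.0, 0.0, 100.0)

    def test_misaligned_bins_fail(self):
        vals = np.array([50.0, 120.0])
        dist = fdt.intensity_frequency_distribution(vals, bin_width=10)
        # edges 20,30,...: 75 is not an edge
        with pytest.raises(ValueError):
            fdt.band_proportions(dist)

    def test_all_low_ratio_is_zero(self):
        dist = fdt.intensity_frequency_distribution(np.full(5, 50.0))
        assert fdt.high_low_ratio(dist) == 0.0

    def test_empty_low_band_flagged_infinite(self):
        dist = fdt.intensity_frequency_distribution(np.full(5, 120.0))
        assert np.isinf(fdt.high_low_ratio(dist))

    def test_peak_tie_broken_toward_lower_bin(self):
        vals = np.array([30.0, 30.0, 150.0, 150.0, 100.0])
        dist = fdt.intensity_frequency_distribution(vals, bin_width=20)
        height, center = fdt.distribution_peak(dist)
        assert height == pytest.approx(40.0)
        assert center == 30.0  # the lower of the two modal bins

    def test_peak_matches_bruteforce_max(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(20, 180, size=500)
        dist = fdt.intensity_frequency_distribution(vals)
        height, _ = fdt.distribution_peak(dist)
        assert height == max(dist.proportions)

    def test_ei_ratio_of_channel_with_itself_is_one(self):
        assert fdt.anatomical_ei_ratio(37.2, 37.2) == 1.0

    def test_ei_ratio_examples(self):
        assert fdt.anatomical_ei_ratio(40.0, 20.0) == 2.0
        with pytest.raises(ValueError):
            fdt.anatomical_ei_ratio(0.0, 20.0)
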