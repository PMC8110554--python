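"""ISH cell counting, Yen thresholding, and Mahalanobis outlier screening."""

import numpy as np
import pandas as pd
import pytest

from synei import ish, synthetic as sy


def yen_criterion_values(image: np.ndarray) -> dict[int, float]:
    """Exhaustive Yen entropic-correlation criterion over all cut points.

    Independent loop-based computation on the trimmed integer histogram:
    TC(s) = -log( sum p_i^2 in [0,s] * sum p_i^2 in (s,255] )
            + 2 log( P(s) (1 - P(s)) ).
    Returns {gray value: criterion} for every valid cut.
    """
    vmin, vmax = int(image.min()), int(image.max())
    counts = np.bincount((image.astype(int) - vmin).ravel(),
                         minlength=vmax - vmin + 1).astype(float)
    p = counts / counts.sum()
    out: dict[int, float] = {}
    for s in range(len(p) - 1):
        p1 = p[:s + 1].sum()
        s1 = (p[:s + 1] ** 2).sum()
        s2 = (p[s + 1:] ** 2).sum()
        if s1 <= 0 or s2 <= 0 or p1 <= 0 or p1 >= 1:
            continue
        out[s + vmin] = -np.log(s1 * s2) + 2 * np.log(p1 * (1 - p1))
    return out


def yen_criterion_bruteforce(image: np.ndarray):
    """Gray value of the exhaustive argmax of the Yen criterion."""
    crit = yen_criterion_values(image)
    return max(crit, key=crit.get)


def yen_attains_bruteforce_max(image: np.ndarray, t: float) -> bool:
    """True when cut ``t`` attains the exhaustive criterion maximum
    (floating-point ties between adjacent cuts count as agreement)."""
    crit = yen_criterion_values(image)
    best = max(crit.values())
    return crit[int(t)] >= best - 1e-9 * max(1.0, abs(best))


class TestPreprocess:
    def test_constant_image_unchanged(self):
        img = ish.IshImage(data=np.full((40, 40), 120.0))
        out = ish.preprocess(img)
        np.testing.assert_allclose(out.data, 120.0)

    def test_single_pixel_speckle_suppressed(self):
        # closed form: a unit impulse blurred at sigma=3 peaks at
        # 1/(2*pi*9) ~ A/56, far below A/10
        img = np.zeros((41, 41))
        img[20, 20] = 100.0
        out = ish.preprocess(ish.IshImage(data=img), sigma_px=3.0)
        assert out.data.max() < 100.0 / 10.0
        assert out.data.max() == pytest.approx(100.0 / (2 * np.pi * 9),
                                               rel=0.05)

    def test_gaussian_semigroup(self):
        rng = np.random.default_rng(0)
        img = ish.IshImage(data=rng.uniform(0, 255, size=(64, 64)))
        twice = ish.preprocess(ish.preprocess(img, 3.0), 3.0)
        once = ish.preprocess(img, np.sqrt(18.0))
        assert np.abs(twice.data - once.data).max() < 1.0


class TestYenThreshold:
    def test_two_level_image_separable(self):
        img = np.full((30, 30), 200.0)
        img[5:12, 5:12] = 40.0
        t = ish.yen_threshold(img)
        assert 40.0 < t < 200.0

    def test_constant_image_fails(self):
        with pytest.raises(ValueError):
            ish.yen_threshold(np.full((20, 20), 7.0))

    def test_matches_bruteforce_on_random_images(self):
        # property over 100 random 8-bit histogram shapes
        rng = np.random.default_rng(42)
        for _ in range(100):
            lo, hi = sorted(rng.integers(0, 256, size=2).tolist())
            if hi - lo < 2:
                hi = lo + 2
            shape = rng.choice(["uniform", "bimodal"])
            if shape == "uniform":
                img = rng.integers(lo, hi + 1, size=(24, 24))
            else:
                a = rng.normal(lo + 10, 8, size=300)
                b = rng.normal(hi - 10, 8, size=276)
                img = np.clip(np.concatenate([a, b]), 0, 255
                              ).astype(np.uint8).reshape(24, 24)
            if np.ptp(img) == 0:
                continue
            img = img.astype(np.uint8)
            assert yen_attains_bruteforce_max(img, ish.yen_threshold(img))

    def test_bimodal_threshold_separates_modes(self):
        rng = np.random.default_rng(1)
        a = rng.normal(60, 6, size=600)
        b = rng.normal(190, 6, size=424)
        img = np.clip(np.concatenate([a, b]), 0, 255).astype(np.uint8)
        t = ish.yen_threshold(img.reshape(32, 32))
        assert 60 < t < 190
        assert (a < t).mean() > 0.85 and (b > t).mean() > 0.99


class TestCountCells:
    def test_density_arithmetic(self):
        binary = np.zeros((100, 100), dtype=bool)
        binary[10:14, 10:14] = True  # one 16-px object
        res = ish.count_cells(binary, min_size_px=10, pixel_size=10.0)
        # field = 1000x1000 um = 1e6 um^2 -> 0.01 per 10^4 um^2
        assert res.n_cells == 1
        assert res.density == pytest.approx(0.01)

    def test_strictly_larger_than_min_size(self):
        binary = np.zeros((60, 60), dtype=bool)
        binary[5:8, 5:8] = True          # 9 px: excluded at min_size 10
        binary[20:25, 20:22] = True      # 10 px: still excluded (strict >)
        binary[40:44, 40:43] = True      # 12 px: counted
        res = ish.count_cells(binary, min_size_px=10)
        assert res.n_cells == 1

    def test_planted_scene_count_recovered(self):
        spec = sy.IshSceneSpec(shape=(700, 700), n_cells=90, n_speckles=40)
        img, truth = sy.gen_ish_image(spec, 4)
        res = ish.count_field(img)
        assert res.n_cells == truth.summary["n_cells"]

    def test_speckles_not_counted(self):
        # sub-threshold speckles must not inflate the count of a labeled field
        base = sy.IshSceneSpec(shape=(500, 500), n_cells=30, n_speckles=0)
        speckled = sy.IshSceneSpec(shape=(500, 500), n_cells=30, n_speckles=60)
        img_a, _ = sy.gen_ish_image(base, 2)
        img_b, _ = sy.gen_ish_image(speckled, 2)
        assert ish.count_field(img_b).n_cells == \
            ish.count_field(img_a).n_cells == 30

    def test_inversion_invariance(self):
        # inverting intensities and flipping the threshold side leaves the
        # count unchanged
        spec = sy.IshSceneSpec(shape=(500, 500), n_cells=40)
        img, _ = sy.gen_ish_image(spec, 7)
        blurred = ish.preprocess(img)
        t = ish.yen_threshold(blurred)
        n_dark = ish.count_cells(blurred.data < t).n_cells
        inv = ish.IshImage(data=255.0 - img.data, pixel_size=img.pixel_size)
        blurred_inv = ish.preprocess(inv)
        t_inv = ish.yen_threshold(blurred_inv)
        n_bright = ish.count_cells(blurred_inv.data > t_inv).n_cells
        assert n_dark == n_bright

    def test_density_scales_with_area_at_fixed_planted_density(self):
        d = []
        for shape, n in (((400, 400), 32), ((800, 800), 128)):
            spec = sy.IshSceneSpec(shape=shape, n_cells=n)
            img, _ = sy.gen_ish_image(spec, 9)
            d.append(ish.count_field(img).density)
        assert d[0] == pytest.approx(d[1], rel=0.05)


class TestCellularEiRatio:
    def test_equal_densities_unity(self):
        assert ish.cellular_ei_ratio(3.2, 3.2) == 1.0

    def test_gat1_halved_doubles_ratio(self):
        assert ish.cellular_ei_ratio(4.0, 2.0) == 2.0

    def test_zero_gat1_fails(self):
        with pytest.raises(ValueError):
            ish.cellular_ei_ratio(4.0, 0.0)


class TestMahalanobisOutliers:
    @staticmethod
    def hand_table():
        return pd.DataFrame({
            "vglut1": [3.0, 3.2, 2.9, 3.1, 3.3, 2.8, 3.0, 3.4],
            "gat1": [1.5, 1.6, 1.4, 1.5, 1.7, 1.3, 1.45, 1.65],
        })

    def test_distances_match_explicit_inverse(self):
        df = self.hand_table()
        out = ish.flag_outliers_mahalanobis(df)
        x = df.to_numpy()
        mu = x.mean(axis=0)
        cov = np.cov(x.T, ddof=1)
        inv = np.linalg.inv(cov)
        expected = np.array([np.sqrt((r - mu) @ inv @ (r - mu)) for r in x])
        np.testing.assert_allclose(out["mahalanobis"].to_numpy(), expected)

    def test_subject_at_mean_distance_zero(self):
        df = self.hand_table()
        mu = df.mean()
        df2 = pd.concat([df, mu.to_frame().T], ignore_index=True)
        out = ish.flag_outliers_mahalanobis(df2)
        assert out["mahalanobis"].iloc[-1] == pytest.approx(0.0, abs=1e-10)
        assert not out["outlier"].iloc[-1]

    def test_extreme_subject_flagged(self):
        df = self.hand_table()
        df.loc[len(df)] = [3.0, 0.01]  # GAT1 collapse: artifactual ratio
        out = ish.flag_outliers_mahalanobis(df, ucl=2.56)
        assert bool(out["outlier"].iloc[-1])
        assert out["outlier"].sum() == 1

    def test_too_few_subjects_fail(self):
        with pytest.raises(ValueError):
            ish.flag_outliers_mahalanobis(self.hand_table().iloc[:2])

    def test_singular_covariance_fails(self):
        df = pd.DataFrame({"vglut1": [1.0, 2.0, 3.0],
                           "gat1": [2.0, 4.0, 6.0]})
        with pytest.raises(ValueError, match="singular"):
            ish.flag_outliers_mahalanobis(df)
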