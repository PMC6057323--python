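import numpy as np
import pytest

from nucleograde.regions import DegenerateRegionError, region_from_mask
from nucleograde.texture import (
    GLCM_NAMES, RLM_NAMES, TEXTURE_NAMES, WAVELET_NAMES, glcm, glcm_features,
    histogram_features, lbp_codes, lbp_features, rlm_features, run_length_matrix,
    tamura_features, tamura_sbest, texture_vector, wavelet_features,
)
from conftest import constant_region, full_region, make_random_region
import oracles


class TestHistogram:
    def test_three_values(self):
        reg = full_region(np.array([[1, 2, 3]]))
        f = histogram_features(reg)
        assert f["mean_value"] == pytest.approx(2.0)
        assert f["standard_deviation"] == pytest.approx(np.sqrt(2 / 3))
        assert f["skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_bimodal_mean(self):
        reg = full_region(np.array([[0, 0], [0, 255]]))
        assert histogram_features(reg)["mean_value"] == pytest.approx(63.75)

    def test_constant_degenerate(self):
        f = histogram_features(constant_region(42))
        assert f["mean_value"] == 42
        assert f["standard_deviation"] == 0
        assert np.isnan(f["skewness"]) and np.isnan(f["kurtosis"])

    def test_gaussian_kurtosis_non_excess(self, rng):
        vals = np.clip(rng.normal(128, 20, (64, 64)), 0, 255).astype(np.uint8)
        f = histogram_features(full_region(vals))
        assert f["kurtosis"] == pytest.approx(3.0, abs=0.3)


class TestGLCM:
    def test_constant_single_cell(self):
        P = glcm(constant_region(100))
        level = 100 // 16
        assert P[level, level] == pytest.approx(1.0)
        f = glcm_features(P)
        assert f["angular_second_moment"] == pytest.approx(1.0)
        assert f["entropy"] == pytest.approx(0.0, abs=1e-12)
        assert f["contrast"] == pytest.approx(0.0)
        assert f["inverse_difference_moment"] == pytest.approx(1.0)
        assert f["correlation"] == 0.0  # zero marginal SD convention
        assert f["information_measure_of_correlation_1"] == 0.0

    def test_two_by_two_pair_enumeration(self):
        # levels after quantization: {0, 15}; horizontal pairs cross-level,
        # vertical pairs same-level
        reg = full_region(np.array([[0, 255], [0, 255]]))
        P0 = glcm(reg, directions=(0,))
        assert P0[0, 15] == pytest.approx(0.5)
        assert P0[15, 0] == pytest.approx(0.5)
        assert P0[0, 0] == 0 and P0[15, 15] == 0
        P90 = glcm(reg, directions=(90,))
        assert P90[0, 0] == pytest.approx(0.5)
        assert P90[15, 15] == pytest.approx(0.5)

    def test_masked_pixel_drops_incident_pairs(self, rng):
        pixels = rng.integers(0, 256, (3, 3)).astype(np.uint8)
        full = np.ones((3, 3), bool)
        holed = full.copy()
        holed[1, 1] = False
        reg_full = region_from_mask(full, pixels)
        pix_holed = np.where(holed, pixels, 0).astype(np.uint8)
        reg_holed = region_from_mask(holed, pix_holed)
        # raw (unnormalized) counts via the oracle
        def count(reg_mask, px):
            h, w = reg_mask.shape
            c = 0
            for ang, (dr, dc) in oracles.DIRS.items():
                for r in range(h):
                    for cc_ in range(w):
                        r2, c2 = r + dr, cc_ + dc
                        if 0 <= r2 < h and 0 <= c2 < w and reg_mask[r, cc_] and reg_mask[r2, c2]:
                            c += 2
            return c
        # the centre pixel of a 3x3 patch has 8 neighbours = 8 ordered pairs
        # per symmetric counting in 4 directions -> 16 fewer entries
        assert count(full, pixels) - count(holed, pix_holed) == 16

    def test_checkerboard_contrast(self):
        # two-level checkerboard, 0 deg only: all pairs differ by 15 levels
        pix = np.zeros((8, 8), np.uint8)
        pix[(np.indices((8, 8)).sum(axis=0) % 2) == 1] = 255
        f = glcm_features(glcm(full_region(pix), directions=(0,)))
        assert f["contrast"] == pytest.approx(225.0)

    def test_matrix_properties(self, random_region_factory):
        reg = random_region_factory()
        P = glcm(reg)
        assert P.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(P, P.T)
        f = glcm_features(P)
        assert f["entropy"] >= 0
        assert 0 <= f["angular_second_moment"] <= 1
        assert f["inverse_difference_moment"] <= 1

    def test_against_oracle(self, rng):
        for _ in range(5):
            reg = make_random_region(rng)
            P = glcm(reg)
            P_oracle = oracles.glcm_oracle(reg.pixels, reg.mask)
            assert np.allclose(P, P_oracle, atol=1e-12)
            got = [glcm_features(P)[n] for n in GLCM_NAMES]
            assert np.allclose(got, oracles.glcm_features_oracle(P), atol=1e-9)

    def test_no_pair_degenerate(self):
        mask = np.zeros((3, 3), bool)
        mask[0, 0] = True
        reg = region_from_mask(mask, np.full((3, 3), 9, np.uint8))
        with pytest.raises(DegenerateRegionError):
            glcm(reg)


class TestRunLength:
    def test_constant_4x4_horizontal(self):
        reg = constant_region(100, size=4)
        f = rlm_features(reg, directions=(0,))
        assert f["short_run_emphasis"] == pytest.approx(1 / 16)
        assert f["long_run_emphasis"] == pytest.approx(16)
        assert f["gray_level_nonuniformity"] == pytest.approx(4)
        assert f["run_length_nonuniformity"] == pytest.approx(4)
        assert f["run_percentage"] == pytest.approx(0.25)

    def test_all_distinct_levels_fragment_fully(self):
        pix = (np.arange(16).reshape(4, 4) * 16).astype(np.uint8)
        f = rlm_features(full_region(pix), directions=(0,))
        assert f["short_run_emphasis"] == pytest.approx(1.0)
        assert f["long_run_emphasis"] == pytest.approx(1.0)
        assert f["run_percentage"] == pytest.approx(1.0)

    def test_run_pixel_conservation(self, random_region_factory):
        reg = random_region_factory()
        for ang in (0, 45, 90, 135):
            Q = run_length_matrix(reg, ang)
            j = np.arange(1, Q.shape[1] + 1)
            assert (Q * j).sum() == reg.mask.sum()

    def test_against_oracle(self, rng):
        for _ in range(5):
            reg = make_random_region(rng)
            got = [rlm_features(reg)[n] for n in RLM_NAMES]
            assert np.allclose(got, oracles.rlm_features_oracle(reg.pixels, reg.mask), atol=1e-9)

    def test_bounds(self, random_region_factory):
        f = rlm_features(random_region_factory())
        assert 0 < f["run_percentage"] <= 1
        assert f["short_run_emphasis"] <= 1 <= f["long_run_emphasis"]


class TestWavelet:
    def test_constant_crop_all_zero(self):
        f = wavelet_features(constant_region(90, size=16))
        assert all(abs(v) < 1e-9 for v in f.values())

    def test_range_identity(self, random_region_factory):
        f = wavelet_features(random_region_factory())
        for d in ("h", "d", "v"):
            assert f[f"dwt2{d}_range_of_values"] == pytest.approx(
                f[f"dwt2{d}_max_value"] - f[f"dwt2{d}_min_value"])

    def test_horizontal_band_loads_horizontal_detail(self):
        pix = np.zeros((32, 32), np.uint8)
        pix[:16] = 200
        pix[16:] = 50
        f = wavelet_features(full_region(pix))
        assert f["dwt2h_mean_absolute_deviation"] > f["dwt2v_mean_absolute_deviation"]

    def test_small_crop_undefined(self):
        f = wavelet_features(constant_region(10, size=6))
        assert all(np.isnan(v) for v in f.values())

    def test_against_oracle(self, rng):
        for _ in range(3):
            reg = make_random_region(rng)
            cH, cV, cD = oracles.dwt2_level2_details_oracle(reg.pixels.astype(float))
            f = wavelet_features(reg)
            for prefix, W in (("dwt2h", cH), ("dwt2d", cD), ("dwt2v", cV)):
                w = W.ravel()
                assert f[f"{prefix}_mean_value"] == pytest.approx(w.mean(), abs=1e-6)
                assert f[f"{prefix}_standard_deviation"] == pytest.approx(w.std(ddof=1), abs=1e-6)
                assert f[f"{prefix}_median_absolute_deviation"] == pytest.approx(
                    np.median(np.abs(w - np.median(w))), abs=1e-6)


class TestTamura:
    def test_constant_tie_break(self):
        f = tamura_features(constant_region(120))
        assert f["tamura_coarseness_1"] == pytest.approx(1.0)
        assert f["tamura_contrast"] == 0.0
        assert f["tamura_roughness"] == pytest.approx(1.0)

    def test_histogram_sums_to_100(self, random_region_factory):
        f = tamura_features(random_region_factory())
        total = f["tamura_coarseness_2"] + f["tamura_coarseness_3"] + f["tamura_coarseness_4"]
        assert total == pytest.approx(100.0)

    def test_coarseness_increases_with_texel_size(self):
        def block_pattern(period):
            idx = np.indices((64, 64)).sum(axis=0) // period % 2
            return (idx * 150 + 50).astype(np.uint8)
        c = []
        for period in (2, 16):
            f = tamura_features(full_region(block_pattern(period)))
            c.append(f["tamura_coarseness_1"])
        assert c[0] < c[1]

    def test_against_oracle(self, rng):
        reg = make_random_region(rng, size=12)
        got = tamura_sbest(reg)
        want = oracles.tamura_sbest_oracle(reg.pixels, reg.mask)
        assert np.allclose(got, want, atol=1e-6)


class TestLBP:
    def test_constant_codes_255(self):
        f = lbp_features(constant_region(80))
        assert f["local_binary_pattern_mean_value"] == 255.0
        assert f["local_binary_pattern_standard_deviation"] == 0.0

    def test_bright_centre_code_zero(self):
        pix = np.full((5, 5), 50, np.uint8)
        pix[2, 2] = 250
        codes = lbp_codes(full_region(pix))
        assert codes.min() == 0  # the bright centre sees only darker neighbours

    def test_against_oracle(self, rng):
        for _ in range(5):
            reg = make_random_region(rng, size=10)
            got = np.sort(lbp_codes(reg))
            want = np.sort(oracles.lbp_codes_oracle(reg.pixels, reg.mask))
            assert np.array_equal(got, want)

    def test_too_small_degenerate(self):
        mask = np.ones((2, 2), bool)
        reg = region_from_mask(mask, np.full((2, 2), 1, np.uint8))
        with pytest.raises(DegenerateRegionError):
            lbp_features(reg)


class TestTextureVector:
    def test_determinism_and_length(self, random_region_factory):
        reg = random_region_factory()
        a, b = texture_vector(reg), texture_vector(reg)
        assert list(a) == list(TEXTURE_NAMES)
        assert a == b

    def test_constant_region_flags(self):
        v = texture_vector(constant_region(60))
        assert v["standard_deviation"] == 0
        assert np.isnan(v["skewness"])
        assert v["angular_second_moment"] == 1.0
        assert all(abs(v[n]) < 1e-9 for n in WAVELET_NAMES)

    def test_rotation_180_invariance(self, rng):
        reg = make_random_region(rng)
        rot_mask = np.rot90(reg.mask, 2)
        rot_pix = np.rot90(reg.pixels, 2)
        rot = region_from_mask(rot_mask, rot_pix)
        a, b = texture_vector(reg), texture_vector(rot)
        for name in GLCM_NAMES + RLM_NAMES:
            assert a[name] == pytest.approx(b[name], abs=1e-9)

    def test_translation_invariance(self, rng):
        reg = make_random_region(rng)
        frame_mask = np.zeros((40, 40), bool)
        frame_pix = np.zeros((40, 40), np.uint8)
        frame_mask[7:23, 11:27] = reg.mask
        frame_pix[7:23, 11:27] = reg.pixels
        moved = region_from_mask(frame_mask, frame_pix)
        a, b = texture_vector(reg), texture_vector(moved)
        for name in TEXTURE_NAMES:
            if np.isnan(a[name]):
                assert np.isnan(b[name])
            else:
                assert a[name] == pytest.approx(b[name], abs=1e-9)
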