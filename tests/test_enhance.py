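"""Log transform, illumination estimation/correction, denoising."""

from dataclasses import replace
from decimal import Decimal, getcontext

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tilecount.config import PipelineConfig
from tilecount.enhance import (
    correct_illumination,
    denoise,
    estimate_illumination,
    load_illumination,
    log_transform,
    save_illumination,
    seam_contrast,
)
from tilecount.errors import ConfigurationError, ContractError
from tilecount.io import TiledWellImage
from tilecount.synth import SyntheticPlateSpec, render_well, vignette_field
from tilecount.wells import apply_mask, detect_well, disc_mask, erode_mask
from tests.conftest import SMALL_GEOMETRY


def _img(arr, **kw):
    return TiledWellImage(pixels=np.asarray(arr, dtype=float), **kw)


def _decimal_log_map(x: float, k: float, digits: int = 50) -> float:
    """Arbitrary-precision oracle for log(1 + k*x) / log(1 + k)."""
    getcontext().prec = digits
    num = (Decimal(1) + Decimal(str(k)) * Decimal(str(x))).ln()
    den = (Decimal(1) + Decimal(str(k))).ln()
    return float(num / den)


class TestLogTransform:
    def test_fixed_points_zero_and_one(self):
        for k in (1.0, 255.0, 4000.0):
            out = log_transform(_img([[0.0, 1.0], [0.0, 1.0]]), k).pixels
            assert out[0, 0] == 0.0
            assert out[0, 1] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("x,k", [(0.5, 255.0), (0.1, 255.0), (0.73, 100.0)])
    def test_matches_arbitrary_precision_oracle(self, x, k):
        out = log_transform(_img([[x, x], [x, x]]), k).pixels[0, 0]
        assert out == pytest.approx(_decimal_log_map(x, k), abs=1e-9)

    def test_known_value_half_input(self):
        # log(1 + 255*0.5)/log(256) = log(128.5)/log(256)
        out = log_transform(_img([[0.5, 0.5], [0.5, 0.5]]), 255.0).pixels[0, 0]
        assert out == pytest.approx(0.8757031, abs=1e-6)

    @given(
        st.floats(0.0, 1.0, allow_nan=False),
        st.floats(0.0, 1.0, allow_nan=False),
        st.floats(0.5, 4000.0, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_strictly_increasing(self, a, b, k):
        lo, hi = sorted((a, b))
        out = log_transform(_img([[lo, hi], [0.0, 0.0]]), k).pixels
        if hi > lo:
            assert out[0, 1] > out[0, 0]
        assert 0.0 <= out[0, 0] <= out[0, 1] <= 1.0 + 1e-12

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ConfigurationError):
            log_transform(_img([[0.1, 0.2], [0.3, 0.4]]), 0.0)


class TestEstimateIllumination:
    def test_constant_full_mask_images_give_unit_gain(self, small_cfg):
        imgs = [_img(np.full((60, 80), 0.4)) for _ in range(10)]
        masks = [np.ones((60, 80), bool)] * 10
        field = estimate_illumination(imgs, small_cfg, masks=masks)
        assert np.allclose(field.gain, 1.0)
        assert field.n_images_used == 10

    def test_single_image_degenerate_median(self, small_cfg):
        img = _img(np.full((60, 80), 0.3))
        field = estimate_illumination([img], small_cfg,
                                      masks=[np.ones((60, 80), bool)])
        assert field.gain.max() == pytest.approx(1.0)

    def test_empty_list_rejected(self, small_cfg):
        with pytest.raises(ContractError):
            estimate_illumination([], small_cfg)

    def test_heterogeneous_shapes_rejected(self, small_cfg):
        with pytest.raises(ContractError):
            estimate_illumination(
                [_img(np.zeros((10, 12)) + 0.1), _img(np.zeros((10, 14)) + 0.1)],
                small_cfg,
            )

    def test_recovers_vignette_shape(self, small_cfg):
        """Estimated gain correlates with the true per-tile falloff."""
        true_g = vignette_field((360, 440), 3, 4, 0.35)
        mask = disc_mask((360, 440), (180.0, 220.0), 150.0)
        rng = np.random.default_rng(0)
        imgs, masks = [], []
        for i in range(10):
            px = np.clip(0.3 * true_g + rng.normal(0, 0.005, (360, 440)), 0, 1)
            px[~mask] = 0.0
            imgs.append(_img(px))
            masks.append(mask)
        field = estimate_illumination(imgs, small_cfg, masks=masks)
        r = np.corrcoef(field.gain[mask], true_g[mask])[0, 1]
        assert r > 0.95

    def test_permutation_invariant(self, small_cfg):
        rng = np.random.default_rng(1)
        mask = np.ones((60, 80), bool)
        imgs = [_img(np.clip(rng.uniform(0.2, 0.6, (60, 80)), 0, 1))
                for _ in range(9)]
        f1 = estimate_illumination(imgs, small_cfg, masks=[mask] * 9)
        f2 = estimate_illumination(imgs[::-1], small_cfg, masks=[mask] * 9)
        assert np.allclose(f1.gain, f2.gain)

    def test_gain_is_smooth(self, small_cfg):
        imgs, masks = [], []
        mask = disc_mask((360, 440), (180.0, 220.0), 150.0)
        g = vignette_field((360, 440), 3, 4, 0.35)
        for _ in range(8):
            px = 0.3 * g.copy()
            px[~mask] = 0.0
            imgs.append(_img(px))
            masks.append(mask)
        field = estimate_illumination(imgs, small_cfg, masks=masks)
        assert np.abs(np.diff(field.gain, axis=0)).max() < 0.02
        assert np.abs(np.diff(field.gain, axis=1)).max() < 0.02


class TestCorrectIllumination:
    def test_unit_gain_is_identity(self, small_cfg):
        img = _img(np.random.default_rng(0).uniform(0, 1, (40, 50)))
        field = estimate_illumination(
            [_img(np.full((40, 50), 0.5))], small_cfg,
            masks=[np.ones((40, 50), bool)],
        )
        assert np.allclose(correct_illumination(img, field).pixels, img.pixels)

    def test_flattens_vignetted_background(self, small_cfg):
        """Correction cuts the in-mask coefficient of variation at least 5x."""
        spec = SyntheticPlateSpec(
            **{**SMALL_GEOMETRY, "rng_seed": 3, "n_nuclei": 0, "n_debris": 0,
               "vignette_strength": 0.4, "noise_sigma": 0.0}
        )
        img, _ = render_well(spec)
        mask = erode_mask(detect_well(img, small_cfg), 5)
        masked = apply_mask(img, mask)
        field = estimate_illumination([masked], small_cfg, masks=[mask.mask])
        corrected = correct_illumination(masked, field)
        cv_before = img.pixels[mask.mask].std() / img.pixels[mask.mask].mean()
        cv_after = (
            corrected.pixels[mask.mask].std() / corrected.pixels[mask.mask].mean()
        )
        assert cv_after < cv_before / 5

    def test_seam_statistic_reduced_below_tenth(self, small_cfg):
        spec = SyntheticPlateSpec(
            **{**SMALL_GEOMETRY, "rng_seed": 4, "n_nuclei": 0, "n_debris": 0,
               "vignette_strength": 0.4, "noise_sigma": 0.0}
        )
        img, _ = render_well(spec)
        mask = erode_mask(detect_well(img, small_cfg), 5)
        masked = apply_mask(img, mask)
        field = estimate_illumination([masked], small_cfg, masks=[mask.mask])
        corrected = correct_illumination(masked, field)
        before = seam_contrast(masked.pixels, 3, 4, mask=mask.mask)
        after = seam_contrast(corrected.pixels, 3, 4, mask=mask.mask)
        assert after < 0.1 * before

    def test_shape_mismatch_rejected(self, small_cfg):
        field = estimate_illumination(
            [_img(np.full((40, 50), 0.5))], small_cfg,
            masks=[np.ones((40, 50), bool)],
        )
        with pytest.raises(ContractError):
            correct_illumination(_img(np.zeros((30, 50))), field)


class TestDenoise:
    def test_sigma_zero_is_identity(self):
        img = _img(np.random.default_rng(0).uniform(0, 1, (30, 30)))
        assert denoise(img, 0.0) is img

    def test_constant_image_preserved(self):
        img = _img(np.full((30, 30), 0.37))
        assert np.allclose(denoise(img, 2.0).pixels, 0.37, atol=1e-6)

    def test_point_source_mass_conserved(self):
        px = np.zeros((41, 41))
        px[20, 20] = 1.0
        out = denoise(_img(px), 1.0).pixels
        assert out[20, 20] < 0.2
        assert out.sum() == pytest.approx(1.0, abs=1e-3)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ConfigurationError):
            denoise(_img(np.zeros((4, 4))), -1.0)


class TestPersistence:
    def test_save_load_round_trip(self, small_cfg, tmp_path):
        g = vignette_field((60, 80), 3, 4, 0.3)
        imgs = [_img(0.4 * g)]
        field = estimate_illumination(imgs, small_cfg,
                                      masks=[np.ones((60, 80), bool)])
        save_illumination(field, tmp_path / "illum.png")
        loaded = load_illumination(tmp_path / "illum.png",
                                   floor_eps=small_cfg.illum_floor_eps)
        assert loaded.n_images_used == 1
        assert np.abs(loaded.gain - field.gain).max() < 1e-3
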