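import numpy as np
import pytest
from skimage.color import rgb2hsv

from oracles import bfs_flood_fill_label
from spikeseg.synthetic import (
    ConfigError,
    GammaLevel,
    SceneConfig,
    apply_gamma,
    generate_plant_views,
    generate_scene,
    small_scene_config,
)


class TestGenerateScene:
    def test_empty_scene_has_blank_mask(self):
        sample = generate_scene(small_scene_config(n_spikes=0), seed=3)
        assert sample.true_count == 0
        assert sample.mask.sum() == 0

    def test_deterministic_for_fixed_seed(self):
        cfg = small_scene_config()
        a = generate_scene(cfg, seed=5)
        b = generate_scene(cfg, seed=5)
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_mask_dims_match_image(self):
        sample = generate_scene(small_scene_config(), seed=0)
        assert sample.mask.shape == sample.image.shape[:2]

    def test_five_spikes_make_five_components(self):
        cfg = small_scene_config(n_spikes=5, spike_axis_range=(9, 12))
        sample = generate_scene(cfg, seed=2)
        _, n = bfs_flood_fill_label(sample.mask, connectivity=8)
        assert n == 5

    @pytest.mark.parametrize("seed", range(100))
    def test_component_count_equals_true_count_without_overlap(self, seed):
        from scipy import ndimage

        sample = generate_scene(small_scene_config(), seed=seed)
        _, n = ndimage.label(sample.mask, structure=np.ones((3, 3)))
        assert n == sample.true_count

    def test_touching_spikes_merge_when_overlap_forced(self):
        cfg = small_scene_config(n_spikes=2, overlap_probability=1.0)
        sample = generate_scene(cfg, seed=4)
        _, n = bfs_flood_fill_label(sample.mask, connectivity=8)
        assert sample.true_count == 2
        assert n == 1

    def test_spike_and_foliage_hues_are_separable(self):
        sample = generate_scene(small_scene_config(), seed=7)
        hue = rgb2hsv(sample.image)[..., 0]
        spike_hue = hue[sample.mask == 1].mean()
        plant_hue = hue[sample.plant_mask == 1].mean()
        assert abs(spike_hue - plant_hue) > 0.1

    def test_scene_too_small_for_spikes_is_rejected(self):
        with pytest.raises(ConfigError, match="too small"):
            SceneConfig(image_height=60, image_width=60, n_spikes=2,
                        spike_axis_range=(25, 30))

    def test_invalid_overlap_probability_rejected(self):
        with pytest.raises(ConfigError):
            small_scene_config(overlap_probability=1.5)


class TestPlantViews:
    def test_max_view_count_equals_plant_total(self):
        cfg = small_scene_config()
        for seed in range(10):
            views = generate_plant_views(cfg, seed)
            counts = [v.true_count for v in views]
            assert max(counts) == cfg.n_spikes
            assert all(v.plant_total == cfg.n_spikes for v in views)

    def test_views_share_plant_id_and_cover_all_angles(self):
        views = generate_plant_views(small_scene_config(), 1, plant_id="p7")
        assert {v.view_angle for v in views} == {0, 120, 240}
        assert {v.plant_id for v in views} == {"p7"}

    def test_single_spike_visible_everywhere(self):
        views = generate_plant_views(small_scene_config(n_spikes=1,
                                                        view_visibility=1.0), 2)
        assert [v.true_count for v in views] == [1, 1, 1]

    def test_deterministic_triple(self):
        cfg = small_scene_config()
        a = generate_plant_views(cfg, 9)
        b = generate_plant_views(cfg, 9)
        for va, vb in zip(a, b):
            np.testing.assert_array_equal(va.image, vb.image)
            np.testing.assert_array_equal(va.mask, vb.mask)

    def test_zero_spike_plant_rejected(self):
        with pytest.raises(ValueError, match="n_spikes"):
            generate_plant_views(small_scene_config(n_spikes=0), 0)


class TestApplyGamma:
    def test_gamma_one_is_identity(self, rng):
        img = rng.integers(0, 256, (20, 20, 3), dtype=np.uint8)
        np.testing.assert_array_equal(apply_gamma(img, 1.0), img)

    def test_half_gamma_squares_normalized_intensity(self):
        assert apply_gamma(np.array([[128]], dtype=np.uint8), 0.5)[0, 0] == 64

    @pytest.mark.parametrize("gamma", [0.1, 0.5, 1.0, 2.5])
    def test_endpoints_are_fixed_points(self, gamma):
        ends = np.array([[0, 255]], dtype=np.uint8)
        np.testing.assert_array_equal(apply_gamma(ends, gamma), ends)

    @pytest.mark.parametrize("gamma", [0.1, 0.3, 0.7, 1.5, 2.5])
    def test_monotone_on_full_ramp(self, gamma):
        ramp = np.arange(256, dtype=np.uint8)[None]
        out = apply_gamma(ramp, GammaLevel(gamma))
        assert (np.diff(out[0].astype(int)) >= 0).all()

    def test_darker_brighter_ordering(self):
        mid = np.array([[100]], dtype=np.uint8)
        assert apply_gamma(mid, 0.1)[0, 0] < 100 < apply_gamma(mid, 2.5)[0, 0]

    @pytest.mark.parametrize("gamma", [0.1, 0.3, 0.5, 1.5, 2.0, 2.5])
    def test_round_trip_within_quantization(self, gamma, rng):
        # single quantization: the map itself is exactly invertible
        img = rng.integers(0, 256, (32, 32, 3), dtype=np.uint8)
        back = apply_gamma(apply_gamma(img, gamma, quantize=False),
                           1.0 / gamma)
        assert np.abs(back.astype(int) - img.astype(int)).max() <= 2

    @pytest.mark.parametrize("gamma", [1.5, 2.0, 2.5])
    def test_quantized_round_trip_for_brightening(self, gamma, rng):
        # brightening expands dark levels, so even the doubly-quantized
        # round trip stays within quantization error (darkening does not:
        # gamma << 1 collapses dark codes irreversibly)
        img = rng.integers(0, 256, (32, 32, 3), dtype=np.uint8)
        back = apply_gamma(apply_gamma(img, gamma), 1.0 / gamma)
        assert np.abs(back.astype(int) - img.astype(int)).max() <= 2

    def test_nonpositive_gamma_rejected(self):
        with pytest.raises(ValueError):
            apply_gamma(np.zeros((2, 2), dtype=np.uint8), 0.0)
        with pytest.raises(ValueError):
            GammaLevel(-1.0)
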