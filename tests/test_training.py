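import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikeseg.architecture import build_network, gmrnet_spec, lpnet_spec
from spikeseg.synthetic import generate_scene, small_scene_config
from spikeseg.training import (
    SplitSpec,
    TrainConfig,
    bce_loss,
    build_refinement_dataset,
    finetune_end_to_end,
    multistage_train,
    split_dataset,
    train_network,
)


class TestSplitDataset:
    def test_reference_cohort_splits_170_30(self):
        train, val = split_dataset([f"p{i}" for i in range(200)], SplitSpec(seed=0))
        assert len(train) == 170
        assert len(val) == 30

    def test_floor_rule_on_ten_plants(self):
        train, val = split_dataset(list(range(10)), SplitSpec(seed=1))
        assert (len(train), len(val)) == (8, 2)

    def test_deterministic_per_seed(self):
        ids = list(range(57))
        assert split_dataset(ids, SplitSpec(seed=4)) == \
            split_dataset(ids, SplitSpec(seed=4))

    @given(n=st.integers(2, 300), seed=st.integers(0, 2 ** 16))
    @settings(max_examples=60, deadline=None)
    def test_disjoint_and_exhaustive(self, n, seed):
        ids = list(range(n))
        train, val = split_dataset(ids, SplitSpec(seed=seed))
        assert len(train) == math.floor(0.85 * n)
        assert sorted(train + val) == ids

    def test_single_plant_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            split_dataset(["only"], SplitSpec())


class TestBceLoss:
    def test_perfect_prediction_is_near_zero(self):
        t = np.array([0.0, 1.0, 1.0, 0.0])
        assert bce_loss(t, t) < 1e-5

    def test_uninformative_half_gives_ln2(self, rng):
        t = (rng.random((8, 8)) > 0.5).astype(float)
        assert bce_loss(np.full((8, 8), 0.5), t) == pytest.approx(math.log(2))

    def test_single_pixel_closed_form(self):
        assert bce_loss(np.array([0.25]), np.array([1.0])) == \
            pytest.approx(-math.log(0.25))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            bce_loss(np.zeros((2, 2)), np.zeros((2, 3)))

    @given(seed=st.integers(0, 2 ** 16))
    @settings(max_examples=30, deadline=None)
    def test_non_negative(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random((4, 4))
        t = (rng.random((4, 4)) > 0.5).astype(float)
        assert bce_loss(p, t) >= 0.0


def _tiny_patch_data(rng, n=12, size=32):
    x = rng.random((n, 3, size, size))
    y = (rng.random((n, 1, size, size)) > 0.8).astype(float)
    return x, y


class TestTrainNetwork:
    def test_zero_epochs_leaves_model_unchanged(self, rng):
        model = build_network(lpnet_spec((2, 3, 4), 32), seed=0)
        before = [p.value.copy() for p in model.params()]
        x, y = _tiny_patch_data(rng)
        history = train_network(model, x, y, TrainConfig(epochs=0))
        assert history.losses == []
        for p, b in zip(model.params(), before):
            np.testing.assert_array_equal(p.value, b)

    def test_loss_decreases_on_learnable_data(self, rng):
        # targets are a thresholded channel of the input: learnable signal
        x = rng.random((16, 3, 32, 32))
        y = (x[:, :1] > 0.7).astype(float)
        model = build_network(lpnet_spec((2, 3, 4), 32), seed=1)
        cfg = TrainConfig(learning_rate=2e-3, epochs=8, batch_size=8, seed=0)
        history = train_network(model, x, y, cfg)
        assert len(history) == 8
        assert history.losses[-1] < history.losses[0]

    def test_history_is_reproducible(self, rng):
        x, y = _tiny_patch_data(rng)
        cfg = TrainConfig(learning_rate=1e-3, epochs=3, batch_size=8, seed=5)
        runs = []
        for _ in range(2):
            model = build_network(gmrnet_spec((2, 3, 4), 32, 3), seed=2)
            runs.append(train_network(model, x, y, cfg).losses)
        assert runs[0] == runs[1]

    def test_empty_dataset_rejected(self):
        model = build_network(lpnet_spec((2, 3, 4), 32), seed=0)
        with pytest.raises(ValueError, match="empty"):
            train_network(model, np.zeros((0, 3, 32, 32)),
                          np.zeros((0, 1, 32, 32)), TrainConfig(epochs=1))

    def test_non_finite_loss_aborts_with_diagnostic(self, rng):
        model = build_network(lpnet_spec((2, 3, 4), 32), seed=0)
        x, y = _tiny_patch_data(rng, n=4)
        y[0, 0, 0, 0] = np.nan  # poisoned target makes the loss non-finite
        with pytest.raises(RuntimeError, match="non-finite"):
            train_network(model, x, y, TrainConfig(epochs=1, batch_size=4))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            TrainConfig(batch_size=0)
        with pytest.raises(ValueError):
            TrainConfig(optimizer="sgd")


def _mini_scenes(n=4, seed0=100):
    cfg = small_scene_config(image_height=96, image_width=96, n_spikes=2,
                             spike_axis_range=(8, 11), n_leaves=2)
    return [generate_scene(cfg, seed=seed0 + i) for i in range(n)]


class TestMultistage:
    def test_patch_accounting_matches_reference_cohort(self):
        # 510 full-size images at 180 tiles each feed stage 1; the same 510
        # merged maps feed stage 2.
        from spikeseg.patchwork import plan_grid

        tiles = plan_grid(1656, 1356, 256, 100).n_tiles
        assert tiles == 180
        assert 510 * tiles == 91800
        assert 91800 // tiles == 510

    def test_scaled_run_returns_trained_pair_and_histories(self):
        scenes = _mini_scenes()
        lp_cfg = TrainConfig(learning_rate=2e-3, epochs=2, batch_size=8, seed=0)
        gm_cfg = TrainConfig(learning_rate=2e-3, epochs=3, batch_size=8, seed=1)
        lpnet, gmrnet, h1, h2 = multistage_train(
            scenes, lp_cfg, gm_cfg, patch_size=32, step=32,
            base_widths=(2, 3, 4))
        assert len(h1) == 2 and len(h2) == 3
        assert lpnet.with_bottleneck and not gmrnet.with_bottleneck

    def test_refinement_inputs_come_from_stage_one_not_ground_truth(self):
        scenes = _mini_scenes(n=2)
        lpnet = build_network(lpnet_spec((2, 3, 4), 32), seed=0)  # untrained
        x2, y2 = build_refinement_dataset(scenes, lpnet, 32, 32)
        assert x2.shape == y2.shape == (2, 1, 32, 32)
        assert x2.min() >= 0.0 and x2.max() <= 1.0
        assert set(np.unique(y2)) <= {0.0, 1.0}
        # an untrained network's merged maps cannot equal the resized truth
        assert np.abs(x2 - y2).max() > 0.1

    def test_stage_one_halves_initial_loss_on_small_preset(self, small_run):
        losses = small_run.lpnet_history.losses
        assert losses[-1] <= 0.5 * losses[0]

    def test_joint_finetune_runs_and_stays_finite(self):
        scenes = _mini_scenes(n=3)
        lp_cfg = TrainConfig(learning_rate=2e-3, epochs=2, batch_size=8, seed=0)
        gm_cfg = TrainConfig(learning_rate=2e-3, epochs=2, batch_size=8, seed=1)
        lpnet, gmrnet, _, _ = multistage_train(
            scenes, lp_cfg, gm_cfg, patch_size=32, step=32,
            base_widths=(2, 3, 4))
        before = [p.value.copy() for p in lpnet.params()]
        cfg = TrainConfig(learning_rate=1e-4, epochs=2, batch_size=1, seed=2)
        history = finetune_end_to_end(lpnet, gmrnet, scenes, cfg, 32, 32)
        assert len(history) == 2
        assert all(np.isfinite(history.losses))
        assert any(not np.array_equal(p.value, b)
                   for p, b in zip(lpnet.params(), before))
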