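"""Network construction, parameter accounting, and the two training stages."""

import numpy as np
import pytest

import annoloop as al
from annoloop import nn
from annoloop.errors import ConfigError, DataError, GateError, ShapeError, StageError
from annoloop.model import ModelConfig, REFERENCE_WIDTHS, _mask_to_labels
from annoloop.patchio import Patch

from conftest import scene_patches


def closed_form_count(widths, in_ch=3, out_ch=2, norm="batch", upsample="transposed"):
    """Independent per-layer arithmetic oracle for the parameter count."""

    def conv(a, b, k):
        return a * b * k * k + b

    bn = (lambda c: 2 * c) if norm == "batch" else (lambda c: 0)
    total = 0
    prev = in_ch
    for c in widths:
        total += conv(prev, c, 3) + bn(c) + conv(c, c, 3) + bn(c)
        prev = c
    for i in range(len(widths) - 2, -1, -1):
        hi, lo = widths[i + 1], widths[i]
        total += conv(hi, lo, 2) if upsample == "transposed" else conv(hi, lo, 1)
        total += conv(2 * lo, lo, 3) + bn(lo) + conv(lo, lo, 3) + bn(lo)
    total += conv(widths[0], out_ch, 1)
    return total


class TestParameterCount:
    def test_reference_config_is_113306(self):
        model = al.build_model(ModelConfig())
        assert al.count_parameters(model) == 113306
        assert model.config.channel_ladder == REFERENCE_WIDTHS

    def test_toy_depth1_hand_sum(self):
        """depth 1, width 2, no norm: conv(3->2)=56, conv(2->2)=38, head=6."""
        cfg = ModelConfig(depth=1, base_width=2, widths=None, norm_mode="none",
                          patch_size=32)
        assert al.count_parameters(al.build_model(cfg)) == 56 + 38 + 6 == 100

    @pytest.mark.parametrize("depth", [1, 2, 3])
    @pytest.mark.parametrize("width", [2, 4, 8])
    @pytest.mark.parametrize("norm", ["none", "batch"])
    @pytest.mark.parametrize("upsample", ["transposed", "interpolate"])
    def test_count_matches_closed_form_grid(self, depth, width, norm, upsample):
        cfg = ModelConfig(depth=depth, base_width=width, widths=None, norm_mode=norm,
                          upsample_mode=upsample, patch_size=32)
        model = al.build_model(cfg)
        expected = closed_form_count(cfg.channel_ladder, norm=norm,
                                     upsample="transposed" if upsample == "transposed" else "interp")
        assert al.count_parameters(model) == expected

    def test_count_invariant_under_reinitialization(self):
        cfg = ModelConfig(depth=2, base_width=4, widths=None, patch_size=32)
        counts = {al.count_parameters(al.build_model(cfg, seed=s)) for s in range(3)}
        assert len(counts) == 1


class TestModelConfig:
    def test_bottleneck_too_small(self):
        with pytest.raises(ConfigError):
            ModelConfig(depth=5, widths=None, base_width=4, patch_size=8)

    def test_widths_length_mismatch(self):
        with pytest.raises(ConfigError):
            ModelConfig(depth=3, widths=(4, 8))

    def test_unknown_modes(self):
        with pytest.raises(ConfigError):
            ModelConfig(upsample_mode="bicubic")
        with pytest.raises(ConfigError):
            ModelConfig(norm_mode="layer")

    def test_json_roundtrip(self):
        cfg = ModelConfig()
        assert ModelConfig.from_json(cfg.to_json()) == cfg


class TestPretraining:
    def test_empty_patch_set(self, tiny_cfg):
        with pytest.raises(DataError):
            al.pretrain_autoencoder(al.build_model(tiny_cfg), [], epochs=1, seed=0)

    def test_zero_epochs_is_noop(self, tiny_cfg, nuclei_scene):
        model = al.build_model(tiny_cfg, seed=1)
        w_before = {k: p.value.copy() for k, p in model.net.params().items()}
        out = al.pretrain_autoencoder(model, scene_patches(nuclei_scene)[:4], epochs=0, seed=0)
        assert out is model and out.stage == "untrained"
        assert all(np.array_equal(w_before[k], p.value)
                   for k, p in model.net.params().items())

    def test_heldout_reconstruction_error_decreases(self, tiny_cfg, nuclei_scene):
        patches = scene_patches(nuclei_scene)
        train, held = patches[:12], patches[12:]
        model = al.build_model(tiny_cfg, seed=3)
        before = al.reconstruction_error(model, held)
        model = al.pretrain_autoencoder(model, train, epochs=5, seed=3)
        after = al.reconstruction_error(model, held)
        assert model.stage == "pretrained"
        assert after < before

    def test_seeded_determinism(self, tiny_cfg, nuclei_scene):
        patches = scene_patches(nuclei_scene)[:6]

        def run():
            m = al.build_model(tiny_cfg, seed=1)
            m = al.pretrain_autoencoder(m, patches, epochs=3, seed=7)
            return m.history[-1]["loss"], al.reconstruction_error(m, patches)

        assert run() == run()


class TestFinetuning:
    def test_gate_rejects_too_few_annotated(self, tiny_cfg, nuclei_scene):
        patches = scene_patches(nuclei_scene)[:2]
        with pytest.raises(GateError, match="3"):
            al.finetune(al.build_model(tiny_cfg), patches, epochs=1)

    def test_all_unknown_masks_count_as_unannotated(self, tiny_cfg, nuclei_scene):
        patches = scene_patches(nuclei_scene)[:5]
        blank = [Patch(pixels=p.pixels, tile_id=p.tile_id, row=p.row, col=p.col)
                 for p in patches]  # fresh all-unknown masks
        with pytest.raises(GateError):
            al.finetune(al.build_model(tiny_cfg), blank, epochs=1)

    def test_unknown_pixels_carry_zero_gradient(self, tiny_cfg):
        """A batch whose masks are entirely unknown produces exactly zero
        gradient on every parameter."""
        model = al.build_model(tiny_cfg, seed=0)
        rng = np.random.default_rng(0)
        x = rng.random((2, 3, 64, 64))
        labels = _mask_to_labels(np.full((2, 64, 64), 0, dtype=np.uint8))  # all unknown
        logits = model.net.forward(x, train=True)
        loss, dlogits = nn.cross_entropy_ignore(logits, labels)
        assert loss == 0.0
        model.net.backward(dlogits)
        assert all(np.all(p.grad == 0) for p in model.net.params().values())

    def test_finetuning_improves_f_score(self, tiny_cfg, nuclei_scene):
        patches = scene_patches(nuclei_scene)
        train, held = patches[:12], patches[12:]
        model = al.build_model(tiny_cfg, seed=3)

        def mean_f(m):
            return float(np.mean([
                al.pixel_f_score(al.binarize(al.predict(m, p), 0.5), p.mask.positive())
                for p in held
            ]))

        f_before = mean_f(model)
        model = al.finetune(model, train, epochs=10, seed=3)
        f_mid = mean_f(model)
        model = al.finetune(model, train, epochs=10, seed=5)
        f_after = mean_f(model)
        assert model.stage == "finetuned"
        assert f_mid > f_before
        # trend continues (plateaus allowed): later checkpoint not worse
        assert f_after >= f_mid - 0.02
        assert f_after > f_before

    def test_wall_time_monotone(self, tiny_cfg, nuclei_scene):
        patches = scene_patches(nuclei_scene)[:4]
        model = al.build_model(tiny_cfg, seed=0)
        assert model.train_wall_time == 0.0
        model = al.finetune(model, patches, epochs=1, seed=0)
        t1 = model.train_wall_time
        assert t1 > 0
        model = al.finetune(model, patches, epochs=1, seed=1)
        assert model.train_wall_time > t1


class TestPredict:
    def test_shape_range_and_determinism(self, trained_tiny_model, nuclei_scene):
        patch = scene_patches(nuclei_scene)[0]
        a = al.predict(trained_tiny_model, patch)
        b = al.predict(trained_tiny_model, patch)
        assert a.shape == patch.pixels.shape[:2]
        assert a.prob_positive.min() >= 0 and a.prob_positive.max() <= 1
        assert np.array_equal(a.prob_positive, b.prob_positive)

    def test_incompatible_patch_size(self, trained_tiny_model):
        bad = np.zeros((50, 50, 3), dtype=np.uint8)  # 50 not divisible by 4
        with pytest.raises(ShapeError):
            al.predict(trained_tiny_model, bad)


class TestBinarize:
    def test_extremes_and_tie(self):
        pm = al.PredictionMap(np.array([[0.2, 0.5], [0.7, 0.9]]))
        assert al.binarize(pm, 0.0).all()
        assert not al.binarize(pm, 0.95).any()
        assert al.binarize(pm, 0.5)[0, 1]  # tie maps to positive

    def test_threshold_out_of_range(self):
        pm = al.PredictionMap(np.zeros((2, 2)))
        with pytest.raises(ValueError):
            al.binarize(pm, 1.5)


class TestCheckpoint:
    def test_roundtrip_preserves_predictions(self, trained_tiny_model, nuclei_scene, tmp_path):
        patch = scene_patches(nuclei_scene)[0]
        path = tmp_path / "model.npz"
        al.save_checkpoint(trained_tiny_model, path)
        loaded = al.load_checkpoint(path)
        assert loaded.stage == trained_tiny_model.stage
        assert np.array_equal(al.predict(loaded, patch).prob_positive,
                              al.predict(trained_tiny_model, patch).prob_positive)


def test_stage_transition_guard(trained_tiny_model, nuclei_scene):
    with pytest.raises(StageError):
        al.pretrain_autoencoder(trained_tiny_model, scene_patches(nuclei_scene)[:2],
                                epochs=1, seed=0)
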