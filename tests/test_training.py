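"""Backbone presets, fusion, the S+1-step procedure, and the LR schedule."""

import numpy as np
import pytest

from robustfood import nn
from robustfood.tensor import Tensor
from robustfood.training import (FeatureFusion, FusionConfig,
                                 TeacherModel, TrainConfig, backbone_preset,
                                 build_backbone, cosine_lr, fuse_features,
                                 wmf_train_step)


def tiny_teacher(num_classes=3, image_size=32, seed=0, betas=(0.4375, 0.5625)):
    return TeacherModel(backbone_preset("tiny"), num_classes=num_classes,
                        image_size=(image_size, image_size),
                        feature_channels=8, restore_channels=4,
                        fusion=FusionConfig(betas=betas, projection_channels=8),
                        seed=seed)


class TestBackbone:
    def test_resnet50_like_stage_shapes(self):
        # stride bookkeeping oracle from the preset table
        spec = backbone_preset("resnet50-like")
        shapes = spec.stage_shapes((448, 448))
        assert shapes[-3:] == [(512, 56, 56), (1024, 28, 28), (2048, 14, 14)]
        assert spec.taps == (2, 3, 4)

    def test_tiny_monotone_downsampling(self):
        bb = build_backbone("tiny", seed=0)
        feats = bb(Tensor(np.random.default_rng(0).uniform(size=(1, 3, 64, 64))))
        sizes = [f.data.shape[-1] for f in feats]
        assert len(feats) == 3
        assert all(a > b for a, b in zip(sizes, sizes[1:]))

    def test_same_seed_identical_parameters(self):
        b1, b2 = build_backbone("tiny", seed=5), build_backbone("tiny", seed=5)
        for (n1, p1), (n2, p2) in zip(b1.named_parameters(),
                                      b2.named_parameters()):
            assert n1 == n2
            np.testing.assert_array_equal(p1.data, p2.data)

    def test_unknown_preset_raises(self):
        with pytest.raises(ValueError, match="unknown backbone"):
            build_backbone("resnet-9000")


class TestFusion:
    def _setup(self, rng, betas):
        fusion = FeatureFusion(FusionConfig(betas=betas, projection_channels=4),
                               [4, 4, 4], rng)
        feats = [Tensor(rng.normal(size=(1, 4, 4, 4))) for _ in range(3)]
        return fusion, feats

    def test_one_hot_weights_select_deepest(self, rng):
        fusion, feats = self._setup(rng, (0.0, 0.0, 1.0))
        out = fuse_features(feats, fusion)
        expect = fusion._projs[2](feats[2]).data
        np.testing.assert_allclose(out.data, expect, atol=1e-12)

    def test_unit_sum_weights_preserve_identical_features(self, rng):
        # betas (0.2, 0.35, 0.45) sum to 1: identical projected features pass
        # through unchanged
        fusion, feats = self._setup(rng, (0.2, 0.35, 0.45))
        f = feats[0]
        for proj in fusion._projs[1:]:
            proj.weight.data = fusion._projs[0].weight.data.copy()
            proj.bias.data = fusion._projs[0].bias.data.copy()
        out = fuse_features([f, f, f], fusion)
        np.testing.assert_allclose(out.data, fusion._projs[0](f).data, atol=1e-9)

    def test_homogeneity_in_betas(self, rng):
        fusion1, feats = self._setup(rng, (0.2, 0.35, 0.45))
        fusion2 = FeatureFusion(FusionConfig(betas=(0.4, 0.7, 0.9),
                                             projection_channels=4),
                                [4, 4, 4], np.random.default_rng(1234))
        for p1, p2 in zip(fusion1._projs, fusion2._projs):
            p2.weight.data = p1.weight.data.copy()
            p2.bias.data = p1.bias.data.copy()
        # doubling all betas doubles x* only for the linear (bias-free) part,
        # so zero the biases first
        for p1, p2 in zip(fusion1._projs, fusion2._projs):
            p1.bias.data[:] = 0
            p2.bias.data[:] = 0
        np.testing.assert_allclose(fuse_features(feats, fusion2).data,
                                   2.0 * fuse_features(feats, fusion1).data,
                                   atol=1e-10)

    def test_resamples_heterogeneous_grids(self, rng):
        fusion = FeatureFusion(FusionConfig(betas=(0.5, 0.5),
                                            projection_channels=4),
                               [2, 3], rng)
        feats = [Tensor(rng.normal(size=(1, 2, 8, 8))),
                 Tensor(rng.normal(size=(1, 3, 4, 4)))]
        assert fuse_features(feats, fusion).data.shape == (1, 4, 4, 4)

    def test_accumulation_order_invariance(self, rng):
        fusion, feats = self._setup(rng, (0.2, 0.35, 0.45))
        out1 = fuse_features(feats, fusion).data
        projected = [b * p(f).data for b, p, f in
                     zip((0.2, 0.35, 0.45), fusion._projs, feats)]
        out2 = projected[2] + projected[0] + projected[1]
        np.testing.assert_allclose(out1, out2, atol=1e-6)

    def test_length_mismatch_raises(self, rng):
        fusion, feats = self._setup(rng, (0.5, 0.5, 0.0))
        with pytest.raises(ValueError, match="stage features"):
            fusion(feats[:2])


class TestCosineLR:
    TC = TrainConfig(lr0=0.002, epochs=200)

    def test_initial_value(self):
        assert cosine_lr(0, self.TC) == pytest.approx(0.002)

    def test_endpoint_zero(self):
        assert cosine_lr(200, self.TC) == pytest.approx(0.0)

    def test_midpoint_half(self):
        assert cosine_lr(100, self.TC) == pytest.approx(0.001)

    def test_nonincreasing(self):
        lrs = [cosine_lr(t, self.TC) for t in range(201)]
        assert np.all(np.diff(lrs) <= 1e-15)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            cosine_lr(201, self.TC)


def make_batch(rng, n=6, size=32, n_classes=3):
    clean = rng.uniform(size=(n, 3, size, size))
    noisy = np.clip(clean + rng.normal(0, 0.1, clean.shape), 0, 1)
    labels = rng.integers(0, n_classes, size=n)
    return noisy, clean, labels


class TestWMFStep:
    def test_returns_s_plus_one_finite_losses_in_order(self, rng):
        model = tiny_teacher()
        tc = TrainConfig(lr0=0.01, epochs=1, batch_size=6)
        opt = nn.SGD(model.parameters(), lr=0.01)
        losses = wmf_train_step(make_batch(rng), model, tc, opt)
        assert len(losses) == model.num_stages + 1 == 3
        assert all(np.isfinite(l) for l in losses)
        assert model.last_backward_order == ["narm_1", "narm_2", "fusion"]

    def test_beta_zero_reduces_to_pure_classification(self, rng):
        model = tiny_teacher()
        tc = TrainConfig(lr0=0.01, epochs=1, alpha=1.0, beta=0.0)
        opt = nn.SGD(model.parameters(), lr=0.01)
        noisy, clean, labels = make_batch(rng)
        losses = wmf_train_step((noisy, clean, labels), model, tc, opt)
        # with (alpha, beta) = (1, 0) each stage loss is exactly L_rec
        from robustfood.tensor import softmax_cross_entropy
        model2 = tiny_teacher()  # same seed -> same initial parameters
        tapped = model2.stage_features(noisy)
        for i, (narm, x) in enumerate(zip(model2.narms, tapped)):
            l_rec = softmax_cross_entropy(narm.aru_forward(x), labels).item()
            assert losses[i] == pytest.approx(l_rec, rel=1e-9)

    def test_all_heads_receive_gradient(self, rng):
        model = tiny_teacher(seed=3)
        tc = TrainConfig(lr0=0.01, epochs=1)
        opt = nn.SGD(model.parameters(), lr=0.01)

        grads = {}
        orig_step = opt.step

        def capture_then_step():
            for name, p in model.named_parameters():
                grads[name] = None if p.grad is None else np.abs(p.grad).sum()
            orig_step()

        opt.step = capture_then_step
        wmf_train_step(make_batch(rng), model, tc, opt)
        for name, g in grads.items():
            assert g is not None and g > 0, f"no gradient reached {name}"

    def test_single_stage_matches_isolated_narm(self, rng):
        # S = 1, beta_1 = 1: the stage loss equals a standalone NARM's loss
        # at identical parameters
        from robustfood.narm import narm_loss
        spec = backbone_preset("tiny", taps=(2,))
        model = TeacherModel(spec, num_classes=3, image_size=(32, 32),
                             feature_channels=8, restore_channels=4,
                             fusion=FusionConfig(betas=(1.0,),
                                                 projection_channels=8),
                             seed=0)
        tc = TrainConfig(lr0=0.01, epochs=1)
        opt = nn.SGD(model.parameters(), lr=0.01)
        noisy, clean, labels = make_batch(rng)
        losses = wmf_train_step((noisy, clean, labels), model, tc, opt)

        model2 = TeacherModel(spec, num_classes=3, image_size=(32, 32),
                              feature_channels=8, restore_channels=4,
                              fusion=FusionConfig(betas=(1.0,),
                                                  projection_channels=8),
                              seed=0)
        x = model2.stage_features(noisy)[0]
        logits, trip = model2.narms[0](x, noisy, clean)
        bundle = narm_loss(logits, labels, trip.I_restored, clean,
                           alpha=tc.alpha, beta=tc.beta)
        assert losses[0] == pytest.approx(bundle.L_NARM.item(), rel=1e-9)

    def test_nonfinite_loss_aborts_with_stage_index(self, rng):
        model = tiny_teacher()
        model.narms[0].scm.out.bias.data[:] = np.inf
        tc = TrainConfig(lr0=0.01, epochs=1)
        opt = nn.SGD(model.parameters(), lr=0.01)
        with pytest.raises(RuntimeError, match="stage 1"):
            wmf_train_step(make_batch(rng), model, tc, opt)


class TestTrainTeacher:
    def test_logging_contract_and_determinism(self, rng):
        from robustfood.training import train_teacher
        x = rng.uniform(size=(12, 3, 32, 32))
        y = rng.integers(0, 3, size=12)
        dataset = {"train_images": x, "train_labels": y}
        tc = TrainConfig(lr0=0.01, epochs=2, batch_size=6, seed=9)
        logs = []
        for _ in range(2):
            model = tiny_teacher(seed=9)
            res = train_teacher(dataset, model, tc, noise_sigma=0.05)
            assert len(res["log"]) == 2
            for rec in res["log"]:
                assert {"epoch", "lr", "L_NARM_1", "L_NARM_2", "L_cls",
                        "top1", "p1", "p2"} <= set(rec)
            logs.append([rec["L_cls"] for rec in res["log"]])
        assert logs[0] == logs[1]

    def test_empty_dataset_raises(self):
        from robustfood.training import train_teacher
        with pytest.raises(ValueError, match="empty"):
            train_teacher({"train_images": np.zeros((0, 3, 32, 32)),
                           "train_labels": np.zeros(0, int)},
                          tiny_teacher(), TrainConfig(lr0=0.01, epochs=1))

    def test_resume_continues_trajectory_identically(self, rng):
        from robustfood.training import train_teacher
        x = rng.uniform(size=(12, 3, 32, 32))
        y = rng.integers(0, 3, size=12)
        dataset = {"train_images": x, "train_labels": y}

        uninterrupted = tiny_teacher(seed=4)
        res_full = train_teacher(dataset, uninterrupted,
                                 TrainConfig(lr0=0.01, epochs=4, batch_size=6,
                                             seed=4, horizon=4),
                                 noise_sigma=0.05)

        resumed = tiny_teacher(seed=4)
        res_a = train_teacher(dataset, resumed,
                              TrainConfig(lr0=0.01, epochs=2, batch_size=6,
                                          seed=4, horizon=4),
                              noise_sigma=0.05)
        res_b = train_teacher(dataset, resumed,
                              TrainConfig(lr0=0.01, epochs=4, batch_size=6,
                                          seed=4, horizon=4),
                              noise_sigma=0.05, resume=res_a["resume_state"])
        full_traj = [r["L_cls"] for r in res_full["log"]]
        split_traj = [r["L_cls"] for r in res_a["log"] + res_b["log"]]
        assert full_traj == split_traj
        for (_, p1), (_, p2) in zip(uninterrupted.named_parameters(),
                                    resumed.named_parameters()):
            np.testing.assert_array_equal(p1.data, p2.data)
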