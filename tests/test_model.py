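"""Counterstream network contracts: embeddings, weight sharing, guidance
limits, losses, IoU, baselines, training sanity."""

import numpy as np
import pytest

from counterstream import cg_tasks
from counterstream.instructions import GuidedOutput, TDInstruction
from counterstream.model import (
    CounterstreamClassifier,
    CounterstreamNet,
    TaskConfig,
    compute_losses,
    iou,
)


@pytest.fixture(scope="module")
def config():
    return TaskConfig(
        image_shape=(1, 12, 48),
        tasks=["left-of", "right-of"],
        answer_spaces={"char": 6},
        task_to_space={"left-of": "char", "right-of": "char"},
        occurrence_classes=6,
        arg_vocab=6,
        relations=["facing"],
    )


@pytest.fixture(scope="module")
def image(config):
    rng = np.random.default_rng(0)
    return rng.random(config.image_shape[1:])


class TestInstructionEmbedding:
    def test_one_hot_lookup(self, config):
        net = CounterstreamNet(config, seed=0)
        e = net.embed_instruction(TDInstruction("right-of", "class", 2))
        np.testing.assert_array_equal(e.e_task, net.E_task.data[1])
        np.testing.assert_array_equal(e.e_arg, net.E_arg.data[2])

    def test_compound_is_sum_of_single_embeddings(self, config):
        net = CounterstreamNet(config, seed=0)
        ej = net.embed_instruction(TDInstruction("left-of", "class", 0)).e_task
        ek = net.embed_instruction(TDInstruction("right-of", "class", 0)).e_task
        ejk = net.embed_instruction(TDInstruction(("left-of", "right-of"), "class", 0)).e_task
        np.testing.assert_allclose(ejk, ej + ek, rtol=1e-6)

    def test_all_zero_task_rejected(self):
        with pytest.raises(ValueError):
            TDInstruction((), "class", 0)

    def test_wrong_mask_shape_rejected(self, config, image):
        net = CounterstreamNet(config, seed=0)
        with pytest.raises(ValueError, match="mask shape"):
            net.forward(image, TDInstruction("left-of", "mask", np.zeros((3, 3))))


class TestGuidedForward:
    def test_output_shapes(self, config, image):
        net = CounterstreamNet(config, seed=0)
        out = net.forward(image, TDInstruction("left-of", "class", 1))
        assert isinstance(out, GuidedOutput)
        assert out.occurrence_logits.shape == (6,)
        assert out.segmentation_logits.shape == (12, 48)
        assert out.task_logits["left-of"].shape == (6,)

    def test_zero_laterals_bu2_equals_bu1(self, config, image):
        net = CounterstreamNet(config, td_laterals=False, seed=0)
        enc = net._encode_single(image, TDInstruction("left-of", "class", 1))
        out = net.forward_batch(enc[0], enc[1], enc[2], enc[3], enc[4], enc[5])
        np.testing.assert_allclose(out["bu1_top"].data, out["bu2_top"].data, rtol=1e-6)

    def test_zero_laterals_instruction_independent(self, config, image):
        net = CounterstreamNet(config, td_laterals=False, seed=0)
        outs = [net.forward(image, TDInstruction(t, "class", a)).task_logits
                for t, a in (("left-of", 0), ("right-of", 3))]
        np.testing.assert_allclose(outs[0]["left-of"], outs[1]["right-of"], rtol=1e-6)

    def test_resolution_mismatch_rejected(self, config):
        net = CounterstreamNet(config, seed=0)
        with pytest.raises(ValueError, match="image shape"):
            net.forward(np.zeros((5, 5)), TDInstruction("left-of", "class", 0))


class TestWeightSharing:
    def test_bu1_bu2_parameters_same_objects_through_training(self, tiny_chargrid_split, tiny_chargrid_config):
        X, y, masks, occ = cg_tasks.encode_chargrid(tiny_chargrid_split, tiny_chargrid_split.train[:40])
        clf = CounterstreamClassifier(task_config=tiny_chargrid_config, max_epochs=1, random_state=0)
        clf.fit(X, y, masks=masks, occurrence=occ)
        ids_before = [id(t) for t in clf.net_.bu_params]
        # another step
        clf2_params = clf.net_.bu_params
        assert ids_before == [id(t) for t in clf2_params]

    def test_gradients_flow_through_both_passes(self, config, image):
        from counterstream.autodiff import softmax_cross_entropy

        net = CounterstreamNet(config, seed=0)
        enc = net._encode_single(image, TDInstruction("left-of", "class", 1))
        out = net.forward_batch(enc[0], enc[1], enc[2], enc[3], enc[4], enc[5])
        loss = softmax_cross_entropy(out["spaces"]["char"], [2])
        loss.backward()
        # shared conv weights got gradient from BU2 (task loss backpropagates
        # through the gated pass and the TD pass into BU1)
        assert net.w1.grad is not None and np.abs(net.w1.grad).sum() > 0


class TestLosses:
    def test_perfect_prediction_zero_task_loss(self):
        out = GuidedOutput(np.zeros(3), np.zeros((4, 4)), {"char": np.array([100.0, 0.0, 0.0])})
        lb = compute_losses(out, {"occurrence": np.zeros(3), "mask": np.zeros((4, 4)),
                                  "answer": ("char", 0)})
        assert lb.task < 1e-6

    @pytest.mark.parametrize("n_classes", [2, 6, 10])
    def test_uniform_prediction_log_c(self, n_classes):
        out = GuidedOutput(np.zeros(3), np.zeros((4, 4)), {"char": np.zeros(n_classes)})
        lb = compute_losses(out, {"occurrence": np.zeros(3), "mask": np.zeros((4, 4)),
                                  "answer": ("char", 1)})
        assert lb.task == pytest.approx(np.log(n_classes), rel=1e-5)

    def test_two_pixel_mask_bce_matches_manual(self):
        logits = np.array([[2.0, -1.0]])
        target = np.array([[1.0, 0.0]])
        out = GuidedOutput(np.zeros(1), logits, {})
        lb = compute_losses(out, {"occurrence": np.zeros(1), "mask": target}, weights=(1, 1, 0))
        manual = -(np.log(1 / (1 + np.exp(-2.0))) + np.log(1 - 1 / (1 + np.exp(1.0)))) / 2
        assert lb.segmentation == pytest.approx(manual, rel=1e-5)

    def test_missing_target_for_enabled_loss(self):
        out = GuidedOutput(np.zeros(1), np.zeros((2, 2)), {})
        with pytest.raises(ValueError, match="occurrence"):
            compute_losses(out, {"mask": np.zeros((2, 2)), "answer": ("char", 0)})


class TestIoU:
    def test_identical_nonempty(self):
        m = np.zeros((4, 4)); m[1:3, 1:3] = 1
        assert iou(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((4, 4)); a[0, 0] = 1
        b = np.zeros((4, 4)); b[3, 3] = 1
        assert iou(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((4, 4)); a[0, 0] = 1
        b = np.zeros((4, 4)); b[0, 0] = 1; b[0, 1] = 1
        assert iou(a, b) == 0.5

    def test_both_empty_defined_as_one(self):
        assert iou(np.zeros((3, 3)), np.zeros((3, 3))) == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            iou(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_symmetry_and_range_property(self, rng):
        for _ in range(50):
            a = rng.random((6, 6)) > 0.5
            b = rng.random((6, 6)) > 0.5
            v = iou(a, b)
            assert 0.0 <= v <= 1.0
            assert v == iou(b, a)
            assert (v == 1.0) == np.array_equal(a, b)


class TestBaselines:
    def test_unguided_backbone_matches_guided_parameter_count(self, config):
        g = CounterstreamNet(config, mode="guided", seed=0)
        u = CounterstreamNet(config, mode="unguided", seed=0)
        assert g.backbone_parameter_count() == u.backbone_parameter_count()

    def test_unguided_arg_changes_only_readout(self, config, image):
        net = CounterstreamNet(config, mode="unguided", seed=0)
        tops = []
        for arg in (0, 3):
            enc = net._encode_single(image, TDInstruction("left-of", "class", arg))
            out = net.forward_batch(enc[0], enc[1], enc[2], enc[3], enc[4], enc[5])
            tops.append(out["bu2_top"].data)
        np.testing.assert_allclose(tops[0], tops[1], rtol=1e-6)

    def test_untrained_unguided_chance_level(self, tiny_chargrid_split, tiny_chargrid_config):
        X, y, _, _ = cg_tasks.encode_chargrid(tiny_chargrid_split, tiny_chargrid_split.train)
        clf = CounterstreamClassifier(task_config=tiny_chargrid_config, mode="unguided",
                                      max_epochs=0, random_state=0)
        clf.fit(X[:10], y[:10])
        rng = np.random.default_rng(1)
        rand_y = rng.integers(0, 6, size=len(X))
        acc = (clf.predict(X) == rand_y).mean()
        assert abs(acc - 1 / 6) < 0.08

    def test_bu_channel_adds_one_input_channel(self, config):
        net = CounterstreamNet(config, mode="bu_channel", seed=0)
        assert net.w1.shape[1] == config.image_shape[0] + 1

    def test_bu_channel_zero_plane_unconditioned(self, config, image):
        net = CounterstreamNet(config, mode="bu_channel", seed=0)
        net.W_plane.data[:] = 0.0
        outs = [net.forward(image, TDInstruction(t, "class", a)).task_logits["left-of" if t == "left-of" else t]
                for t, a in (("left-of", 0), ("right-of", 5))]
        np.testing.assert_allclose(outs[0], outs[1], rtol=1e-6)


class TestTraining:
    def test_zero_epochs_parameters_unchanged(self, tiny_chargrid_split, tiny_chargrid_config):
        X, y, masks, occ = cg_tasks.encode_chargrid(tiny_chargrid_split, tiny_chargrid_split.train[:20])
        clf = CounterstreamClassifier(task_config=tiny_chargrid_config, max_epochs=0, random_state=7)
        clf.fit(X, y, masks=masks, occurrence=occ)
        fresh = CounterstreamNet(tiny_chargrid_config, seed=7)
        for k, v in clf.net_.state_dict().items():
            np.testing.assert_array_equal(v, fresh.state_dict()[k])

    def test_same_seed_identical_trajectory(self, tiny_chargrid_split, tiny_chargrid_config):
        X, y, masks, occ = cg_tasks.encode_chargrid(tiny_chargrid_split, tiny_chargrid_split.train[:60])
        hists = []
        for _ in range(2):
            clf = CounterstreamClassifier(task_config=tiny_chargrid_config, max_epochs=3,
                                          random_state=5, batch_size=16)
            clf.fit(X, y, masks=masks, occurrence=occ)
            hists.append(clf.history_["loss"].to_numpy())
        np.testing.assert_array_equal(hists[0], hists[1])

    def test_tiny_two_class_chargrid_trains_above_90(self):
        split = cg_tasks.make_chargrid_dataset(n_images=250, n_classes=2, chars_per_image=2,
                                               examples_per_image=2, seed=2, n_test_nc=10, n_test_cg=10)
        tc = cg_tasks.chargrid_task_config(split)
        X, y, masks, occ = cg_tasks.encode_chargrid(split, split.train)
        assert len(y) == 500
        clf = CounterstreamClassifier(task_config=tc, max_epochs=8, random_state=0,
                                      lr=2e-3, batch_size=10, seg_pos_weight=8.0)
        clf.fit(X, y, masks=masks, occurrence=occ)
        assert clf.score(X, y) > 0.9

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_divergence_aborts_with_diagnostic(self, tiny_chargrid_split, tiny_chargrid_config):
        X, y, masks, occ = cg_tasks.encode_chargrid(tiny_chargrid_split, tiny_chargrid_split.train[:30])
        clf = CounterstreamClassifier(task_config=tiny_chargrid_config, max_epochs=30,
                                      lr=1e6, optimizer="sgd", random_state=0)
        with pytest.raises(RuntimeError, match="diverged"):
            clf.fit(X, y, masks=masks, occurrence=occ)
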