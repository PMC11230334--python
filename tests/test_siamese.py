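"""Fusion algebra, weight sharing, prediction rules and checkpoints."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trialmatch import (
    ConfigurationError,
    EmbeddedPair,
    InputError,
    SiameseMatcher,
    SingleEncoderMatcher,
    TrainConfig,
    early_fusion_input,
    forward_pair,
    fuse,
    load_checkpoint,
    predict_contrastive,
    predict_label,
    save_checkpoint,
    train,
)
from trialmatch.encoders import EncoderConfig
from trialmatch.siamese import batch_pairs


class TestFuse:
    def test_add_zero_identity(self, rng):
        v = rng.standard_normal(5)
        assert fuse(v, np.zeros(5), "add") == pytest.approx(v)

    def test_multiply_arithmetic(self):
        assert fuse([2.0, 3.0], [4.0, 5.0], "multiply") == pytest.approx([8.0, 15.0])

    def test_mean_of_equal_is_identity(self, rng):
        v = rng.standard_normal(5)
        assert fuse(v, v, "mean") == pytest.approx(v)

    def test_concat_doubles_width(self, rng):
        out = fuse(rng.standard_normal(5), rng.standard_normal(5), "concat")
        assert out.shape == (10,)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000), method=st.sampled_from(["add", "multiply", "mean"]))
    def test_elementwise_methods_are_symmetric(self, seed, method):
        rng = np.random.default_rng(seed)
        a, b = rng.standard_normal(6), rng.standard_normal(6)
        assert fuse(a, b, method) == pytest.approx(fuse(b, a, method))

    def test_concat_is_order_sensitive(self, rng):
        a, b = rng.standard_normal(3), rng.standard_normal(3)
        assert not np.allclose(fuse(a, b, "concat"), fuse(b, a, "concat"))

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            fuse(np.zeros(3), np.zeros(4), "add")

    def test_unknown_method_rejected(self):
        with pytest.raises(ConfigurationError):
            fuse(np.zeros(3), np.zeros(3), "average")


class TestWeightSharing:
    def test_single_parameter_storage(self, mlp_config):
        model = SiameseMatcher(mlp_config)
        encoder_params = set(map(id, model.encoder.parameters()))
        all_params = list(map(id, model.parameters()))
        # encoder parameters appear exactly once in the model's parameter list
        assert len(all_params) == len(set(all_params))
        assert encoder_params <= set(all_params)

    def test_both_branches_encode_identically(self, mlp_config, coarse_pairs):
        model = SiameseMatcher(mlp_config).eval()
        x = np.stack([p.ehr_rep for p in coarse_pairs[:4]])
        re, rc = model.encode_branches(x, None, x, None)
        assert np.array_equal(re.data, rc.data)

    def test_sharing_survives_training(self, mlp_config, coarse_pairs):
        model = SiameseMatcher(mlp_config, loss_kind="wbce")
        train(model, coarse_pairs, TrainConfig(epochs=3, seed=0))
        x = np.stack([p.ehr_rep for p in coarse_pairs[:4]])
        re, rc = model.encode_branches(x, None, x, None)
        assert np.array_equal(re.data, rc.data)

    def test_gradient_reaches_encoder_from_one_branch(self, mlp_config, coarse_pairs):
        """Even with one branch fed zeros, a step must move the shared
        encoder (gradient flows from the other branch)."""
        model = SiameseMatcher(mlp_config, loss_kind="bce")
        pos = [p for p in coarse_pairs if p.label == 1][:5]
        neg = [p for p in coarse_pairs if p.label == 0][:5]
        zeroed = [
            EmbeddedPair(p.pair_id, "coarse", p.ehr_rep, np.zeros_like(p.criteria_rep) + 1e-12, p.label)
            for p in pos + neg
        ]
        before = {k: v.copy() for k, v in model.encoder.state_dict().items()}
        train(model, zeroed, TrainConfig(epochs=1, seed=0))
        moved = any(
            not np.array_equal(before[k], v)
            for k, v in model.encoder.state_dict().items()
        )
        assert moved


class TestForward:
    def test_probability_strictly_inside_unit_interval(self, mlp_config, coarse_pairs):
        model = SiameseMatcher(mlp_config).eval()
        for p in coarse_pairs[:8]:
            prob = forward_pair(model, p)
            assert 0.0 < prob < 1.0

    def test_zeroed_head_gives_half(self, mlp_config, coarse_pairs):
        model = SiameseMatcher(mlp_config).eval()
        model.head.weight.data[:] = 0.0
        model.head.bias.data[:] = 0.0
        assert forward_pair(model, coarse_pairs[0]) == pytest.approx(0.5)

    def test_granularity_mismatch_rejected(self, mlp_config, fine_pairs):
        model = SiameseMatcher(mlp_config)
        with pytest.raises(ConfigurationError):
            forward_pair(model, fine_pairs[0])


class TestEarlyFusion:
    def test_coarse_concatenation(self, coarse_pairs):
        v = early_fusion_input(coarse_pairs[0])
        assert v.shape == (32,)
        assert np.array_equal(v[:16], coarse_pairs[0].ehr_rep)

    def test_fine_concatenates_token_axis(self, fine_pairs):
        p = fine_pairs[0]
        m = early_fusion_input(p)
        assert m.shape == (p.ehr_rep.shape[0] + p.criteria_rep.shape[0], 16)

    def test_single_encoder_contrastive_rejected(self):
        with pytest.raises(ConfigurationError):
            SingleEncoderMatcher(EncoderConfig("mlp", input_dim=32), loss_kind="contrastive")


class TestPrediction:
    @pytest.mark.parametrize("p,thr,want", [(0.7, 0.5, 1), (0.5, 0.5, 1), (0.2, 0.5, 0)])
    def test_threshold_rule_with_tie_to_positive(self, p, thr, want):
        assert predict_label(p, thr) == want

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ConfigurationError):
            predict_label(0.5, 1.5)

    def test_contrastive_prediction_monotone_in_similarity(self, coarse_pairs):
        cfg = EncoderConfig("mlp", input_dim=16, projection_dim=8, seed=0)
        model = SiameseMatcher(cfg, loss_kind="contrastive").eval()
        sims = [forward_pair(model, p) for p in coarse_pairs[:10]]
        for p, s in zip(coarse_pairs[:10], sims):
            assert predict_contrastive(model, p, sim_threshold=s - 1e-9) == 1
            assert predict_contrastive(model, p, sim_threshold=s + 1e-9) == 0

    def test_contrastive_prediction_requires_contrastive_model(self, mlp_config, coarse_pairs):
        model = SiameseMatcher(mlp_config, loss_kind="bce")
        with pytest.raises(ConfigurationError):
            predict_contrastive(model, coarse_pairs[0])


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, mlp_config, coarse_pairs, tmp_path):
        model = SiameseMatcher(mlp_config, loss_kind="wbce")
        train(model, coarse_pairs, TrainConfig(epochs=3, seed=1))
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        back = load_checkpoint(path)
        xe, me, xc, mc, _ = batch_pairs(coarse_pairs)
        a = model.eval().forward_batch(xe, me, xc, mc).data
        b = back.forward_batch(xe, me, xc, mc).data
        assert np.array_equal(a, b)
        assert back.trained_epochs == model.trained_epochs
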