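"""Fold construction, metrics, training harness and model comparison."""

import numpy as np
import pytest

from trialmatch import (
    ConfigurationError,
    CVReport,
    FoldResult,
    InputError,
    SiameseMatcher,
    SyntheticSpec,
    TrainConfig,
    compare_models,
    cross_validate,
    f1,
    generate_coarse,
    stratified_kfold,
    train,
)
from trialmatch.encoders import EncoderConfig
from trialmatch.evaluation import _fold_metrics


class TestStratifiedKFold:
    def test_trial_cohort_shape(self):
        """180 samples at 50/130 split 5 ways -> folds of 36 with 10 positives."""
        labels = np.array([1] * 50 + [0] * 130)
        folds = stratified_kfold(labels, 5, seed=0)
        for _, test_idx in folds:
            assert len(test_idx) == 36
            assert labels[test_idx].sum() == 10

    def test_folds_partition_the_indices(self):
        labels = np.array([1] * 12 + [0] * 28)
        folds = stratified_kfold(labels, 4, seed=1)
        all_test = np.concatenate([t for _, t in folds])
        assert sorted(all_test) == list(range(40))
        for (_, a), (_, b) in zip(folds, folds[1:]):
            assert not set(a) & set(b)

    def test_same_seed_same_folds(self):
        labels = np.array([1] * 10 + [0] * 20)
        a = stratified_kfold(labels, 5, seed=42)
        b = stratified_kfold(labels, 5, seed=42)
        for (ta, sa), (tb, sb) in zip(a, b):
            assert np.array_equal(ta, tb) and np.array_equal(sa, sb)

    def test_k_above_minority_count_rejected(self):
        with pytest.raises(InputError):
            stratified_kfold(np.array([1, 1, 0, 0, 0, 0]), 3, seed=0)


class TestF1:
    def test_perfect(self):
        assert f1(10, 0, 0) == 1.0

    def test_balanced_errors(self):
        assert f1(1, 1, 1) == 0.5

    def test_degenerate_fold_is_zero_by_convention(self):
        assert f1(0, 0, 0) == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(InputError):
            f1(-1, 0, 0)

    def test_macro_f1_is_mean_of_class_f1(self):
        r = _fold_metrics(0, np.array([1, 1, 0, 0]), np.array([1, 0, 0, 1]))
        assert r.f1_overall == pytest.approx((r.f1_pos + r.f1_neg) / 2)


def _mlp_factory(seed):
    return SiameseMatcher(EncoderConfig("mlp", input_dim=16, projection_dim=8, seed=seed),
                          loss_kind="wbce")


class TestTrain:
    def test_loss_decreases_on_separable_data(self, coarse_pairs):
        model = _mlp_factory(0)
        hist, _ = train(model, coarse_pairs, TrainConfig(epochs=20, seed=0))
        assert hist[-1] < hist[0]
        assert len(hist) == 20

    def test_zero_epochs_rejected(self):
        with pytest.raises(ConfigurationError):
            TrainConfig(epochs=0)

    def test_single_class_training_rejected(self, coarse_pairs):
        only_neg = [p for p in coarse_pairs if p.label == 0]
        with pytest.raises(InputError):
            train(_mlp_factory(0), only_neg, TrainConfig(epochs=1))

    def test_identical_seeds_identical_parameters(self, coarse_pairs):
        cfg = TrainConfig(epochs=5, seed=9)
        a = _mlp_factory(9)
        train(a, coarse_pairs, cfg)
        b = _mlp_factory(9)
        train(b, coarse_pairs, cfg)
        for k, v in a.state_dict().items():
            assert np.array_equal(v, b.state_dict()[k]), k


class _OracleModel:
    """Reads the label planted in the first EHR feature; never learns."""

    loss_kind = "bce"
    fusion = "concat"
    margin = 1.0
    trained_epochs = 0

    class _Enc:
        class config:
            family = "oracle"
        accepts_sequences = False

    encoder = _Enc()

    def parameters(self):
        return []

    def state_dict(self):
        return {}

    def train(self):
        return self

    def eval(self):
        return self

    def compatible_with(self, pair):
        return pair.granularity == "coarse"

    def forward_batch(self, xe, me, xc, mc):
        from trialmatch.autodiff import Tensor

        p = np.clip(np.asarray(xe)[:, 0], 0.01, 0.99)
        return Tensor(p)


def _planted_pairs(n=40, n_pos=12, seed=0):
    from trialmatch import EmbeddedPair

    rng = np.random.default_rng(seed)
    labels = np.array([1] * n_pos + [0] * (n - n_pos))
    rng.shuffle(labels)
    pairs = []
    for i, y in enumerate(labels):
        e = rng.standard_normal(8)
        e[0] = y  # the oracle feature
        pairs.append(EmbeddedPair(f"p{i}", "coarse", e, rng.standard_normal(8), int(y)))
    return pairs


class TestCrossValidate:
    def test_oracle_model_scores_perfectly(self):
        report = cross_validate(lambda s: _OracleModel(), _planted_pairs(),
                                TrainConfig(epochs=1, k_folds=4, seed=0))
        assert report.mean_f1 == 1.0

    def test_constant_negative_predictor_has_zero_f1_pos(self):
        class _Never(_OracleModel):
            def forward_batch(self, xe, me, xc, mc):
                from trialmatch.autodiff import Tensor
                return Tensor(np.full(len(np.asarray(xe)), 0.01))

        report = cross_validate(lambda s: _Never(), _planted_pairs(),
                                TrainConfig(epochs=1, k_folds=4, seed=0))
        assert report.mean_f1_pos == 0.0
        for fold in report.folds:
            assert fold.f1_pos == 0.0

    def test_mean_is_mean_of_folds(self, coarse_pairs):
        report = cross_validate(_mlp_factory, coarse_pairs,
                                TrainConfig(epochs=3, k_folds=3, seed=2))
        assert report.mean_f1 == pytest.approx(
            np.mean([f.f1_overall for f in report.folds])
        )

    def test_report_json_round_trip(self, coarse_pairs, tmp_path):
        report = cross_validate(_mlp_factory, coarse_pairs,
                                TrainConfig(epochs=2, k_folds=3, seed=2))
        path = tmp_path / "report.json"
        report.to_json(path)
        back = CVReport.from_json(path)
        assert back.mean_f1 == report.mean_f1
        assert [f.tp for f in back.folds] == [f.tp for f in report.folds]


def _report_from_scores(scores, seed=0):
    folds = [FoldResult(i, 1, 0, 1, 0, s, s, s) for i, s in enumerate(scores)]
    return CVReport(folds=folds, mean_f1=float(np.mean(scores)),
                    mean_f1_pos=float(np.mean(scores)),
                    mean_f1_neg=float(np.mean(scores)), seed=seed, config={})


class TestCompareModels:
    def test_self_comparison_is_null(self):
        r = _report_from_scores([0.8, 0.9, 0.85])
        with pytest.warns(UserWarning):
            result = compare_models(r, r)
        assert result.mean_relative_gain == 0.0
        assert result.p_value == 1.0

    def test_constant_difference_warns_zero_variance(self):
        a = _report_from_scores([0.9, 0.8, 0.7])
        b = _report_from_scores([0.8, 0.7, 0.6])
        with pytest.warns(UserWarning):
            result = compare_models(a, b)
        assert result.fold_deltas == pytest.approx([0.1, 0.1, 0.1])

    def test_hand_computed_relative_gain(self):
        a = _report_from_scores([0.9, 0.8, 0.85, 0.9, 0.95])
        b = _report_from_scores([0.6, 0.6, 0.7, 0.65, 0.6])
        result = compare_models(a, b)
        want = (np.mean([0.9, 0.8, 0.85, 0.9, 0.95]) - 0.63) / 0.63
        assert result.mean_relative_gain == pytest.approx(want)
        assert 0.0 < result.p_value < 0.05

    def test_mismatched_seeds_rejected(self):
        a = _report_from_scores([0.9, 0.8], seed=0)
        b = _report_from_scores([0.8, 0.7], seed=1)
        with pytest.raises(InputError):
            compare_models(a, b)

    def test_mismatched_fold_counts_rejected(self):
        with pytest.raises(InputError):
            compare_models(_report_from_scores([0.9, 0.8]), _report_from_scores([0.8]))


def test_null_data_stays_at_chance_few_seeds():
    """At separation 0 the labels are independent of the features, so CV
    macro-F1 must hover at chance (label-leakage guard)."""
    scores = []
    for seed in range(3):
        pairs = generate_coarse(SyntheticSpec(n_pairs=40, pos_fraction=0.3,
                                              embed_dim=16, separation=0.0, seed=seed))
        rep = cross_validate(
            lambda s: SiameseMatcher(EncoderConfig("mlp", input_dim=16, projection_dim=8, seed=s),
                                     loss_kind="wbce"),
            pairs, TrainConfig(epochs=10, k_folds=4, seed=seed))
        scores.append(rep.mean_f1)
    assert np.mean(scores) < 0.65
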