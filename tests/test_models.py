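"""Encoders and the three classifier stages."""

import numpy as np
import pytest

from treehole.models import (
    ConfigError,
    ModelConfig,
    encode,
    fused_vector,
    load_model,
    make_encoder,
    predict,
    predict_proba,
    save_model,
    train_model1,
    train_model2,
    train_model3,
)
from treehole.psych_features import PsychFeatureVector

CFG = ModelConfig(seed=5, epochs=3)


def tiny_labeled(n=60, seed=0):
    """Linearly separable toy set: a marker token decides the class."""
    rng = np.random.default_rng(seed)
    fillers = ["calm", "walk", "tea", "book", "rain", "sofa"]
    out = []
    for i in range(n):
        words = list(rng.choice(fillers, size=5))
        if i % 2 == 0:
            words.insert(2, "dangertoken")
            out.append((" ".join(words), "high"))
        else:
            out.append((" ".join(words), "low"))
    return out


def feats(value):
    return PsychFeatureVector.from_array([value] * 10)


class TestEncode:
    def test_default_vector_length_is_768(self):
        assert encode("hello", ModelConfig()).shape == (768,)

    def test_empty_string_is_zero_vector(self):
        assert not encode("", ModelConfig()).any()

    def test_deterministic_given_text_and_seed(self):
        a = encode("some comment", ModelConfig(seed=3))
        b = encode("some comment", ModelConfig(seed=3))
        np.testing.assert_array_equal(a, b)

    def test_seed_changes_embedding(self):
        a = encode("some comment", ModelConfig(seed=3))
        b = encode("some comment", ModelConfig(seed=4))
        assert not np.array_equal(a, b)

    def test_unit_norm(self):
        assert np.linalg.norm(encode("some comment", ModelConfig())) == pytest.approx(1.0)

    def test_truncation_at_max_chars(self):
        cfg = ModelConfig(max_chars=8)
        assert np.array_equal(encode("abcdefgh tail", cfg), encode("abcdefgh", cfg))


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"encoder": "bogus"},
            {"dropout": 1.0},
            {"threshold": 0.0},
            {"reduce_dim": 768},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            ModelConfig(**kwargs)

    def test_learning_rate_resolves_per_backend(self):
        assert ModelConfig().lr == 0.01
        assert ModelConfig(learning_rate=3e-4).lr == 3e-4


class TestModel1:
    def test_single_class_input_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            train_model1([("a b c", "low"), ("d e f", "low")], CFG)

    def test_learns_separable_toy_set(self):
        data = tiny_labeled(80)
        model = train_model1(data, CFG)
        preds = [predict(model, t)[1] for t, _ in data]
        acc = np.mean([p == lab for p, (_, lab) in zip(preds, data)])
        assert acc >= 0.95

    def test_seeded_runs_are_bitwise_identical(self):
        data = tiny_labeled(40)
        m1 = train_model1(data, CFG)
        m2 = train_model1(data, CFG)
        p1 = predict_proba(m1, [t for t, _ in data])
        p2 = predict_proba(m2, [t for t, _ in data])
        np.testing.assert_array_equal(p1, p2)

    def test_probability_in_unit_interval_and_tie_goes_high(self):
        model = train_model1(tiny_labeled(40), CFG)
        prob, label = predict(model, "calm walk tea")
        assert 0.0 <= prob <= 1.0
        model.networks["head"].layers[-1].params["W"][:] = 0.0
        model.networks["head"].layers[-1].params["b"][:] = 0.0
        prob, label = predict(model, "calm walk tea")
        assert (prob, label) == (0.5, "high")

    def test_raising_positive_weight_raises_probability(self):
        model = train_model1(tiny_labeled(40), CFG)
        text = "calm walk dangertoken tea"
        x = model.encoder.encode(text) - model.center
        j = int(np.argmax(np.abs(x)))
        before, _ = predict(model, text)
        model.networks["head"].layers[-1].params["W"][j, 0] += np.sign(x[j]) * 2.0
        after, _ = predict(model, text)
        assert after > before


class TestModel2:
    def test_requires_model1_base(self):
        base = train_model1(tiny_labeled(40), CFG)
        m2 = train_model2(base, tiny_labeled(40), CFG)
        with pytest.raises(ValueError, match="model1 base"):
            train_model2(m2, tiny_labeled(40), CFG)

    def test_zero_epochs_still_predicts_valid_probabilities(self):
        base = train_model1(tiny_labeled(40), CFG)
        m2 = train_model2(base, tiny_labeled(40), ModelConfig(seed=5, epochs=0))
        probs = predict_proba(m2, ["calm walk tea", "dangertoken tea"])
        assert np.all((probs >= 0) & (probs <= 1))

    def test_encoder_state_unchanged_by_training(self):
        base = train_model1(tiny_labeled(40), CFG)
        fingerprint = base.encoder_state_hash()
        m2 = train_model2(base, tiny_labeled(40), CFG)
        assert m2.encoder is base.encoder
        assert m2.encoder_state_hash() == fingerprint

    def test_head_architecture(self):
        base = train_model1(tiny_labeled(40), CFG)
        m2 = train_model2(base, tiny_labeled(40), ModelConfig(seed=5, epochs=0))
        shapes = [
            layer.params["W"].shape
            for layer in m2.networks["head"].layers
            if "W" in layer.params
        ]
        assert shapes == [(768, 768), (768, 768), (768, 1)]


class TestModel3:
    def _labeled_with_features(self, n=60):
        rng = np.random.default_rng(2)
        out = []
        for i, (text, lab) in enumerate(tiny_labeled(n)):
            shift = 1.0 if lab == "high" else -1.0
            out.append((text, feats(shift + rng.normal(0, 0.2)), lab))
        return out

    def test_fused_vector_has_length_74_by_default(self):
        base = train_model1(tiny_labeled(40), CFG)
        m3 = train_model3(base, self._labeled_with_features(40), CFG)
        assert m3.meta["fusion_dim"] == 74
        assert fused_vector(m3, "calm walk tea", feats(0.0)).shape == (74,)

    def test_reduce_dim_controls_fusion_size(self):
        cfg = ModelConfig(seed=5, epochs=1, reduce_dim=32)
        base = train_model1(tiny_labeled(40), cfg)
        m3 = train_model3(base, self._labeled_with_features(40), cfg)
        assert m3.meta["fusion_dim"] == 42

    def test_wrong_feature_length_rejected(self):
        base = train_model1(tiny_labeled(40), CFG)
        bad = [(t, None, lab) for t, lab in tiny_labeled(10)]
        with pytest.raises(Exception):
            train_model3(base, bad, CFG)

    def test_feature_requirement_enforced_at_predict(self):
        base = train_model1(tiny_labeled(40), CFG)
        m3 = train_model3(base, self._labeled_with_features(40), CFG)
        with pytest.raises(ValueError, match="requires"):
            predict(m3, "calm walk tea")
        with pytest.raises(ValueError, match="does not accept"):
            predict(base, "calm walk tea", feats(0.0))

    def test_calibration_on_balanced_set(self):
        base = train_model1(tiny_labeled(80), CFG)
        data = self._labeled_with_features(80)
        m3 = train_model3(base, data, CFG)
        probs = predict_proba(m3, [t for t, _, _ in data], [f for _, f, _ in data])
        assert 0.2 <= probs.mean() <= 0.8


class TestPersistence:
    @pytest.mark.parametrize("stage", ["model1", "model2", "model3"])
    def test_save_load_round_trip(self, stage, tmp_path):
        base = train_model1(tiny_labeled(40), CFG)
        if stage == "model1":
            model, f = base, None
        elif stage == "model2":
            model, f = train_model2(base, tiny_labeled(40), CFG), None
        else:
            rng = np.random.default_rng(3)
            data = [(t, feats(rng.normal()), lab) for t, lab in tiny_labeled(40)]
            model, f = train_model3(base, data, CFG), [feats(0.3), feats(-0.4)]
        path = tmp_path / "m.npz"
        save_model(model, path)
        loaded = load_model(path)
        texts = ["calm walk tea ride", "dangertoken walk tea"]
        np.testing.assert_allclose(
            predict_proba(model, texts, f), predict_proba(loaded, texts, f)
        )


def test_transformer_backend_requires_extras():
    with pytest.raises((ConfigError, NotImplementedError)):
        make_encoder(ModelConfig(encoder="transformer"))
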