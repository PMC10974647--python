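"""Fusion architectures: dimensions, purity, attention behavior, composition."""

import numpy as np
import pandas as pd
import pytest

from admetfuse.autodiff import Tensor
from admetfuse.data import default_schema, fit_normalization, apply_normalization, label_matrix, records_to_frame
from admetfuse.encoder import EncoderConfig, TransformerEncoder
from admetfuse.models import (
    ARCHITECTURES,
    ModelConfig,
    PredictionMatrix,
    build_model,
    self_attention,
)
from admetfuse.simulate import GeneratorConfig, generate_dataset
from admetfuse.tokenizer import train_bpe


@pytest.fixture(scope="module")
def fitted_models(tiny_encoder_config):
    """All six architectures fitted briefly on one small synthetic set."""
    schema = default_schema()
    records, _ = generate_dataset(GeneratorConfig(n_molecules=80, seed=13))
    stats = fit_normalization(records, schema)
    normed = apply_normalization(records, stats, schema)
    X = records_to_frame(normed, schema).drop(columns=list(schema.final_label_names))
    y = label_matrix(records, schema)
    vocab = train_bpe([r.smiles for r in records], vocab_size=80)
    models = {}
    for arch in ARCHITECTURES:
        kwargs = dict(learning_rate=1e-3, max_epochs=2, batch_size=32, random_state=0)
        if arch not in ("dnn", "dnn_a"):
            kwargs.update(vocab=vocab, encoder_config=tiny_encoder_config)
        models[arch] = build_model(arch, **kwargs).fit(X, y)
    return models, X, y


class TestModelConfig:
    def test_fused_and_concat_widths(self):
        config = ModelConfig()
        assert config.fused_width == 30
        assert config.concat_width == 798
        assert ModelConfig(encoder_hidden=64).concat_width == 94


class TestAllArchitectures:
    def test_output_shape_and_range(self, fitted_models):
        models, X, y = fitted_models
        for arch, model in models.items():
            probs = model.predict_proba(X)
            assert probs.shape == (len(X), 21), arch
            assert ((probs > 0) & (probs < 1)).all(), arch

    def test_deterministic_under_fixed_weights(self, fitted_models):
        models, X, _ = fitted_models
        for arch, model in models.items():
            assert (model.predict_proba(X) == model.predict_proba(X)).all(), arch

    def test_predict_binarizes_at_half(self, fitted_models):
        models, X, _ = fitted_models
        model = models["dnn"]
        probs = model.predict_proba(X)
        assert (model.predict(X) == (probs >= 0.5)).all()

    def test_prediction_matrix_round_trip(self, fitted_models, tmp_path):
        models, X, _ = fitted_models
        pm = models["dnn"].predict_matrix(X, ids=[str(i) for i in range(len(X))])
        path = tmp_path / "pred.csv"
        pm.to_csv(path)
        back = PredictionMatrix.from_csv(path, model_tag="dnn")
        assert back.label_names == pm.label_names
        np.testing.assert_allclose(back.values, pm.values, atol=1e-12)

    def test_parameter_counts_match_closed_form(self, fitted_models, tiny_encoder_config):
        models, _, _ = fitted_models
        H = tiny_encoder_config.hidden_size
        # dnn: bool embedding 2x10, ints 5->10, floats 7->10, head 30->21
        dnn_expected = 2 * 10 + (5 * 10 + 10) + (7 * 10 + 10) + (30 * 21 + 21)
        assert models["dnn"].model_.n_parameters() == dnn_expected
        assert models["dnn_a"].model_.n_parameters() == dnn_expected  # attention adds no weights
        enc_params = models["encoder"].model_.encoder.n_parameters()
        assert models["encoder"].model_.n_parameters() == enc_params + (H * 21 + 21)
        trunk = 2 * 10 + (5 * 10 + 10) + (7 * 10 + 10)
        assert models["concat"].model_.n_parameters() == enc_params + trunk + ((30 + H) * 21 + 21)
        # pipe: encoder + stage1 H->13 + trunk + head 30->21
        assert models["pipe"].model_.n_parameters() == enc_params + (H * 13 + 13) + trunk + (30 * 21 + 21)

    def test_missing_feature_block_is_hard_error(self, fitted_models):
        models, X, _ = fitted_models
        with pytest.raises(ValueError, match="feature block"):
            models["dnn"].predict_proba(X["smiles"].tolist())

    def test_unknown_architecture_rejected(self):
        with pytest.raises(ValueError, match="unknown architecture"):
            build_model("gnn")


class TestDNN:
    def test_fused_width_is_thirty(self, fitted_models):
        models, X, _ = fitted_models
        trunk = models["dnn"].model_.trunk
        batch = models["dnn"]._prepare(X)
        fused = trunk(batch["bool"], batch["ints"], batch["floats"])
        assert fused.shape == (len(X), 30)

    def test_zeroed_output_head_gives_half_probabilities(self, fitted_models):
        models, X, _ = fitted_models
        model = models["dnn"]
        state = model.model_.state_dict()
        try:
            zeroed = {k: (np.zeros_like(v) if k.startswith("head.") else v) for k, v in state.items()}
            model.model_.load_state_dict(zeroed)
            assert (model.predict_proba(X) == 0.5).all()
        finally:
            model.model_.load_state_dict(state)


class TestConcat:
    def test_fused_width_94_with_h64(self, fitted_models, tiny_encoder_config):
        models, _, _ = fitted_models
        head_in = models["concat"].model_.head.layers[0].weight.shape[0]
        assert head_in == 30 + tiny_encoder_config.hidden_size == 94

    def test_default_encoder_gives_798(self):
        assert ModelConfig(encoder_hidden=768).concat_width == 798

    def test_zeroed_encoder_branch_reduces_to_dnn_function(self, fitted_models):
        """With the encoder half of the head zeroed, concat depends on features only."""
        models, X, _ = fitted_models
        model = models["concat"]
        state = model.model_.state_dict()
        try:
            z = {k: v.copy() for k, v in state.items()}
            z["head.layer0.weight"][30:, :] = 0.0
            model.model_.load_state_dict(z)
            X2 = X.copy()
            X2["smiles"] = X["smiles"].iloc[::-1].to_numpy()  # permute structures
            np.testing.assert_allclose(model.predict_proba(X), model.predict_proba(X2), atol=1e-6)
        finally:
            model.model_.load_state_dict(state)


class TestPipe:
    def test_stage_shapes(self, fitted_models):
        models, X, _ = fitted_models
        model = models["pipe"]
        phys = model.predict_physchem(X)
        assert phys.shape == (len(X), 13)
        assert model.predict_proba(X).shape == (len(X), 21)

    def test_oracle_injection_reduces_pipe_to_dnn(self, fitted_models):
        """Feeding the true feature block into stage 2 makes pipe a DNN on it."""
        models, X, _ = fitted_models
        model = models["pipe"]
        batch = model._prepare(X)
        override = {
            "bool": Tensor(np.asarray(batch["bool"], dtype=np.float32)),
            "ints": Tensor(batch["ints"]),
            "floats": Tensor(batch["floats"]),
        }
        model.model_.eval()
        _, logits = model.model_(batch, physchem_override=override)
        # the same trunk+head applied directly to the true features
        fused = model.model_.trunk(override["bool"], batch["ints"], batch["floats"])
        direct = model.model_.head(fused)
        np.testing.assert_allclose(logits.data, direct.data, atol=1e-6)

    def test_gradient_flows_through_both_stages(self, tiny_encoder_config, fitted_models):
        """Finite-difference check on a 2-molecule batch: the end-to-end loss
        moves when an encoder weight moves, so stage 1 is trained through."""
        models, X, y = fitted_models
        model = models["pipe"]
        batch = model._take(model._prepare(X), np.arange(2))
        model.model_.eval()  # keep the loss deterministic for finite differences
        from admetfuse import nn

        def loss_value():
            phys, logits = model.model_(batch)
            return float(nn.bce_with_logits(logits, y[:2]).data)

        param = model.model_.encoder.tok_emb.weight
        phys, logits = model.model_(batch)
        loss = nn.bce_with_logits(logits, y[:2].astype(np.float32))
        model.model_.zero_grad()
        loss.backward()
        # probe the largest-gradient entry
        flat = np.abs(param.grad).argmax()
        idx = np.unravel_index(flat, param.data.shape)
        assert param.grad[idx] != 0.0
        eps = 1e-2
        orig = param.data[idx]
        param.data[idx] = orig + eps
        up = loss_value()
        param.data[idx] = orig - eps
        down = loss_value()
        param.data[idx] = orig
        numeric = (up - down) / (2 * eps)
        assert np.sign(numeric) == np.sign(param.grad[idx])
        assert abs(numeric - param.grad[idx]) < max(0.2 * abs(param.grad[idx]), 5e-3)


class TestSelfAttention:
    def test_identical_groups_attend_uniformly(self):
        x = np.tile(np.arange(10, dtype=np.float32), (4, 3, 1))
        _, weights = self_attention(x)
        np.testing.assert_allclose(weights, 1.0 / 3.0, atol=1e-6)

    def test_weights_sum_to_one_per_query(self):
        rng = np.random.default_rng(0)
        _, weights = self_attention(rng.normal(size=(5, 3, 10)).astype(np.float32))
        np.testing.assert_allclose(weights.sum(axis=-1), 1.0, atol=1e-6)

    def test_dominant_group_captures_all_attention(self):
        """Hand-computed softmax limit: scaling one group vector x100 makes its
        score dominate every query row, so its weight approaches 1."""
        rng = np.random.default_rng(1)
        x = np.abs(rng.normal(size=(1, 3, 10))).astype(np.float32) + 0.5
        x[0, 2] *= 100.0
        _, weights = self_attention(x)
        assert (weights[0, :, 2] > 0.99).all()

    def test_output_is_tanh_bounded(self):
        rng = np.random.default_rng(2)
        out, _ = self_attention(rng.normal(size=(4, 3, 10)).astype(np.float32) * 10)
        assert (np.abs(out.data) <= 1.0).all()

    def test_attention_variants_expose_weights(self, fitted_models):
        models, X, _ = fitted_models
        model = models["dnn_a"]
        model.predict_proba(X)
        w = model.model_.trunk.attention_weights_
        assert w is not None and w.shape[1:] == (3, 3)
        np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-5)
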