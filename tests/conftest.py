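"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import json

import numpy as np
import pytest

from admetfuse.data import default_schema
from admetfuse.encoder import EncoderConfig
from admetfuse.simulate import GeneratorConfig, generate_dataset, generate_smiles
from admetfuse.tokenizer import train_bpe


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def tiny_encoder_config():
    """Desk-scale encoder used throughout the tests (H=64)."""
    return EncoderConfig(n_layers=2, n_heads=4, hidden_size=64, ffn_size=128, max_len=32, vocab_size=256, dropout=0.1)


@pytest.fixture(scope="session")
def smiles_corpus():
    smiles, _ = generate_smiles(GeneratorConfig(n_molecules=1000, seed=101))
    return smiles


@pytest.fixture(scope="session")
def small_vocab(smiles_corpus):
    return train_bpe(smiles_corpus, vocab_size=150)


@pytest.fixture(scope="session")
def mixed_dataset():
    """200 molecules, mixed label modes, with ground truth."""
    return generate_dataset(GeneratorConfig(n_molecules=200, seed=7, label_mode="mixed"))


def make_json_record(path, record_id="D0001", smiles="CCO", drop=(), extra_props=None, extra_admet=None):
    """Write one schema-complete JSON molecule file, optionally with gaps/extras."""
    schema = default_schema()
    props = {}
    for name in schema.bool_features:
        props[name] = True
    for i, name in enumerate(schema.int_features):
        props[name] = i + 1
    for i, name in enumerate(schema.float_features):
        props[name] = 0.5 * (i + 1)
    for name in drop:
        props.pop(name, None)
    props.update(extra_props or {})
    admet = {name: (i % 2) for i, name in enumerate(schema.raw_label_names)}
    admet.update(extra_admet or {})
    payload = {"id": record_id, "smiles": smiles, "properties": props, "admet": admet}
    path.write_text(json.dumps(payload))
    return path


@pytest.fixture
def json_record_factory(tmp_path):
    def factory(name="mol.json", **kwargs):
        return make_json_record(tmp_path / name, **kwargs)

    return factory
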