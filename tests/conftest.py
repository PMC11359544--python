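import numpy as np
import pytest

import photogen as pg
from photogen.language_model import TrainSchedule, finetune_clm


@pytest.fixture(scope="session")
def fixture_corpus():
    """Deterministic synthetic corpus (SMILES, energy) with both
    criterion-positive and criterion-negative molecules."""
    spec = pg.FixtureSpec(n_molecules=150, positive_fraction=0.4, seed=3)
    return pg.generate_corpus(spec)


@pytest.fixture(scope="session")
def fixture_smiles(fixture_corpus):
    return [s for s, _ in fixture_corpus]


@pytest.fixture(scope="session")
def tokenizer(fixture_smiles):
    return pg.train_bpe(fixture_smiles, max_merges=60)


@pytest.fixture(scope="session")
def tiny_config(tokenizer):
    return pg.GptConfig(vocab_size=tokenizer.vocab_size, d_model=64,
                        n_heads=4, n_blocks=2, max_positions=64)


@pytest.fixture(scope="session")
def trained_model(tiny_config, tokenizer, fixture_smiles):
    """A small decoder fine-tuned on the fixture corpus (shared across
    tests; treat as read-only and clone before mutating)."""
    model = pg.GptLM(tiny_config, seed=0, adapter_config=pg.AdapterConfig(rank=8))
    ids, _ = tokenizer.encode_batch(fixture_smiles)
    finetune_clm(model, ids,
                 TrainSchedule(epochs=50, batch_size=32, seed=0, max_seq_len=64),
                 tokenizer.pad_id)
    return model


@pytest.fixture(scope="session")
def verdicts(fixture_smiles):
    out = {}
    for s in fixture_smiles:
        g = pg.parse_smiles(s)
        out[g.canonical_smiles] = pg.evaluate_criteria(g)
    return out


@pytest.fixture(scope="session")
def reference_table():
    from photogen.screening import load_reference_table

    return load_reference_table()
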