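import math

import numpy as np
import pytest

import photogen as pg
from photogen.language_model import (AdamW, GptLM, TrainSchedule, cosine_lr,
                                     count_parameters, finetune_clm,
                                     parameter_count_closed_form)


def _small_cfg(vocab=20):
    return pg.GptConfig(vocab_size=vocab, d_model=16, n_heads=2, n_blocks=2,
                        max_positions=24)


class TestParameterCount:
    def test_replica_configuration_is_13_4_million(self):
        cfg = pg.GptConfig(vocab_size=1072, d_model=512, n_heads=8,
                           n_blocks=4, max_positions=512, tie_embeddings=True)
        assert parameter_count_closed_form(cfg) == 13_421_568
        assert round(13_421_568 / 1e6, 1) == 13.4

    @pytest.mark.parametrize("vocab,d,heads,blocks,pos", [
        (20, 16, 2, 2, 24), (33, 32, 4, 1, 16), (1072, 512, 8, 4, 512),
    ])
    def test_closed_form_matches_tensor_enumeration(self, vocab, d, heads, blocks, pos):
        cfg = pg.GptConfig(vocab_size=vocab, d_model=d, n_heads=heads,
                           n_blocks=blocks, max_positions=pos)
        model = GptLM(cfg, seed=0)
        assert count_parameters(model) == parameter_count_closed_form(cfg)

    def test_tied_vocab_increment_adds_d_model(self):
        a = parameter_count_closed_form(pg.GptConfig(vocab_size=100, d_model=16,
                                                     n_heads=2, n_blocks=1, max_positions=8))
        b = parameter_count_closed_form(pg.GptConfig(vocab_size=101, d_model=16,
                                                     n_heads=2, n_blocks=1, max_positions=8))
        assert b - a == 16

    def test_adapter_parameter_count_split(self):
        cfg = _small_cfg()
        model = GptLM(cfg, seed=0, adapter_config=pg.AdapterConfig(rank=4))
        base, adapter = count_parameters(model, split=True)
        # rank 4 on query+value of 2 blocks: 2 proj * 2 blocks * (d*r + r*d)
        assert adapter == 2 * 2 * (16 * 4 + 4 * 16)
        assert adapter < base

    def test_indivisible_heads_rejected(self):
        with pytest.raises(ValueError):
            pg.GptConfig(vocab_size=10, d_model=10, n_heads=3)


class TestForward:
    def test_seeded_initialization_is_deterministic(self):
        a = GptLM(_small_cfg(), seed=7)
        b = GptLM(_small_cfg(), seed=7)
        assert all(np.array_equal(a.params[k], b.params[k]) for k in a.params)

    def test_next_token_distribution_normalized(self):
        model = GptLM(_small_cfg(), seed=0)
        ids = np.array([[1, 2, 3, 4]])
        logits, _ = model.forward(ids)
        p = np.exp(logits - logits.max(-1, keepdims=True))
        p /= p.sum(-1, keepdims=True)
        assert np.allclose(p.sum(-1), 1.0)

    def test_causality(self):
        """Perturbing token t+1 never changes logits at positions <= t."""
        model = GptLM(_small_cfg(), seed=0)
        rng = np.random.default_rng(0)
        ids = rng.integers(0, 20, size=(1, 10))
        logits, _ = model.forward(ids)
        for t in (3, 7):
            mutated = ids.copy()
            mutated[0, t + 1] = (mutated[0, t + 1] + 1) % 20
            logits2, _ = model.forward(mutated)
            assert np.allclose(logits[0, : t + 1], logits2[0, : t + 1])
            assert not np.allclose(logits[0, t + 1 :], logits2[0, t + 1 :])

    def test_loss_matches_independent_nll(self):
        """Batch loss equals mean token NLL computed from scipy softmax."""
        from scipy.special import log_softmax

        model = GptLM(_small_cfg(), seed=1)
        rng = np.random.default_rng(1)
        ids = rng.integers(1, 20, size=(3, 8))
        logits, _ = model.forward(ids)
        loss, _ = model.clm_loss_and_dlogits(ids, pad_id=0, logits=logits)
        lp = log_softmax(logits[:, :-1], axis=-1)
        ref = -np.take_along_axis(lp, ids[:, 1:][..., None], axis=-1).mean()
        assert loss == pytest.approx(float(ref), abs=1e-5)

    def test_too_long_sequence_rejected(self):
        model = GptLM(_small_cfg(), seed=0)
        with pytest.raises(ValueError):
            model.forward(np.zeros((1, 30), dtype=int))


class TestGradients:
    def test_backward_matches_finite_differences(self):
        model = GptLM(_small_cfg(vocab=12), seed=2,
                      adapter_config=pg.AdapterConfig(rank=2))
        for k in model.adapter:  # make B nonzero so its path is exercised
            if k.endswith(".B"):
                model.adapter[k] += 0.05
        rng = np.random.default_rng(0)
        ids = rng.integers(1, 12, size=(2, 6))

        def loss():
            logits, cache = model.forward(ids)
            l, dl = model.clm_loss_and_dlogits(ids, 0, logits)
            return l, cache, dl

        l0, cache, dl = loss()
        g, ga = model.backward(cache, dl)
        eps = 1e-6
        for store, grads in ((model.params, g), (model.adapter, ga)):
            for key in store:
                arr = store[key]
                idx = tuple(rng.integers(0, s) for s in arr.shape)
                orig = arr[idx]
                arr[idx] = orig + eps
                lp, _, _ = loss()
                arr[idx] = orig - eps
                lm, _, _ = loss()
                arr[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[key][idx] == pytest.approx(num, abs=1e-6, rel=1e-4), key


class TestTraining:
    def test_cosine_schedule_endpoints(self):
        assert cosine_lr(0, 100, 5e-4, 5e-8) == pytest.approx(5e-4, rel=1e-12)
        assert cosine_lr(99, 100, 5e-4, 5e-8) == pytest.approx(5e-8, rel=1e-12)
        lrs = [cosine_lr(t, 100, 5e-4, 5e-8) for t in range(100)]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))

    def test_overfit_reduces_loss(self, tokenizer):
        corpus = ["CCO", "c1ccncc1", "CCN", "CC(C)O", "CCS"]
        ids, _ = tokenizer.encode_batch(corpus)
        cfg = pg.GptConfig(vocab_size=tokenizer.vocab_size, d_model=32,
                           n_heads=2, n_blocks=2, max_positions=32)
        model = GptLM(cfg, seed=0)
        trace = finetune_clm(model, ids,
                             TrainSchedule(epochs=30, batch_size=5, seed=0,
                                           max_seq_len=32),
                             tokenizer.pad_id)
        assert trace[-1] < trace[0]

    def test_adapter_only_freezes_base(self, tokenizer):
        corpus = ["CCO", "CCN", "CCC"]
        ids, _ = tokenizer.encode_batch(corpus)
        cfg = pg.GptConfig(vocab_size=tokenizer.vocab_size, d_model=16,
                           n_heads=2, n_blocks=1, max_positions=16)
        model = GptLM(cfg, seed=0, adapter_config=pg.AdapterConfig(rank=2))
        before = model.base_fingerprint()
        adapter_before = {k: v.copy() for k, v in model.adapter.items()}
        finetune_clm(model, ids,
                     TrainSchedule(epochs=5, batch_size=3, seed=0, max_seq_len=16),
                     tokenizer.pad_id, trainable="adapter_only")
        assert model.base_fingerprint() == before
        assert any(not np.array_equal(model.adapter[k], adapter_before[k])
                   for k in model.adapter)

    def test_memorization_of_tiny_corpus(self, tokenizer):
        corpus = ["CCO", "CCN", "CCC", "CCS", "CCCO"]
        ids, _ = tokenizer.encode_batch(corpus)
        cfg = pg.GptConfig(vocab_size=tokenizer.vocab_size, d_model=48,
                           n_heads=4, n_blocks=2, max_positions=16)
        model = GptLM(cfg, seed=0)
        finetune_clm(model, ids,
                     TrainSchedule(epochs=200, batch_size=5, lr_initial=2e-3,
                                   seed=0, max_seq_len=16),
                     tokenizer.pad_id)
        rep = pg.sample_smiles(model, tokenizer, n=100, seed=4, max_len=12)
        in_corpus = sum(1 for s in rep.smiles if s in corpus)
        assert in_corpus >= 80


class TestSampling:
    def test_same_seed_identical_samples(self, trained_model, tokenizer):
        a = pg.sample_smiles(trained_model, tokenizer, n=30, seed=9, max_len=24)
        b = pg.sample_smiles(trained_model, tokenizer, n=30, seed=9, max_len=24)
        assert a.smiles == b.smiles

    def test_n_zero_is_empty(self, trained_model, tokenizer):
        rep = pg.sample_smiles(trained_model, tokenizer, n=0, seed=1)
        assert rep.n == rep.n_valid == 0 and rep.smiles == []

    def test_report_counts_consistent(self, trained_model, tokenizer):
        rep = pg.sample_smiles(trained_model, tokenizer, n=60, seed=2, max_len=24)
        assert rep.n == 60 == len(rep.smiles)
        assert 0 <= rep.n_unique_valid <= rep.n_valid <= rep.n

    def test_incremental_step_matches_full_forward(self, trained_model):
        ids = np.array([[1, 5, 9, 3, 7]])
        logits, _ = trained_model.forward(ids)
        kv = None
        for pos in range(ids.shape[1]):
            lg, kv = trained_model._step(ids[:, pos], pos, kv, True)
            assert np.allclose(lg, logits[:, pos, :], atol=1e-9)

    def test_nonpositive_temperature_rejected(self, trained_model, tokenizer):
        with pytest.raises(ValueError):
            trained_model.sample_ids(1, tokenizer.bos_id, tokenizer.eos_id,
                                     seed=0, temperature=0.0)


def test_checkpoint_round_trip(tmp_path, trained_model):
    path = tmp_path / "model.npz"
    trained_model.save(path)
    loaded = GptLM.load(path)
    assert loaded.base_fingerprint() == trained_model.base_fingerprint()
    assert all(np.array_equal(loaded.adapter[k], trained_model.adapter[k])
               for k in trained_model.adapter)
    ids = np.array([[1, 2, 3]])
    a, _ = trained_model.forward(ids)
    b, _ = loaded.forward(ids)
    assert np.array_equal(a, b)
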