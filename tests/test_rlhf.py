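import math

import numpy as np
import pytest

import photogen as pg
from photogen.chem_graph import CriterionVerdict
from photogen.rlhf import (BinaryExample, PreferencePair, RlhfConfig,
                           build_feedback, cpo_loss, dpo_loss,
                           evaluate_generation, kto_loss, read_jsonl,
                           rlhf_finetune, write_jsonl)

LN2 = math.log(2.0)


def _verdict(n: int) -> CriterionVerdict:
    flags = [i < n for i in range(3)]
    return CriterionVerdict(*flags)


class TestBuildFeedback:
    def test_binary_dataset_size_is_positives_plus_negatives(self):
        verdicts = {f"P{i}": _verdict(2) for i in range(121)}
        verdicts.update({f"N{i}": _verdict(0) for i in range(251)})
        pairs, binary = build_feedback(verdicts, seed=0)
        assert len(binary) == 372
        assert sum(b.label for b in binary) == 121
        # cycling positives over negatives: every negative used exactly once
        assert len(pairs) == 251
        assert len({p.rejected for p in pairs}) == 251

    def test_single_criterion_molecules_excluded(self):
        verdicts = {"pos": _verdict(3), "neg": _verdict(0), "ambig": _verdict(1)}
        pairs, binary = build_feedback(verdicts, seed=0)
        names = {b.completion for b in binary}
        assert "ambig" not in names
        assert all(p.chosen != "ambig" and p.rejected != "ambig" for p in pairs)

    def test_pair_invariants(self, verdicts):
        pairs, _ = build_feedback(verdicts, seed=1)
        for p in pairs[:20]:
            assert verdicts[p.chosen].weakened_pass
            assert verdicts[p.rejected].n_satisfied == 0

    def test_empty_class_warns_but_builds_binary(self):
        verdicts = {"a": _verdict(2), "b": _verdict(3)}
        with pytest.warns(UserWarning):
            pairs, binary = build_feedback(verdicts)
        assert pairs == [] and len(binary) == 2

    def test_deterministic_under_seed(self, verdicts):
        a, _ = build_feedback(verdicts, seed=5)
        b, _ = build_feedback(verdicts, seed=5)
        assert a == b


class TestDpoLoss:
    def test_zero_margin_is_ln2(self):
        loss, margin, _, _ = dpo_loss([2.0], [1.0], [2.0], [1.0], beta=0.1)
        assert loss == pytest.approx(LN2, abs=1e-12)
        assert margin[0] == 0.0

    def test_limits(self):
        lo, *_ = dpo_loss([100.0], [-100.0], [0.0], [0.0], beta=1.0)
        hi, *_ = dpo_loss([-50.0], [50.0], [0.0], [0.0], beta=1.0)
        assert lo == pytest.approx(0.0, abs=1e-20)
        assert hi > 50

    def test_finite_case_against_arithmetic_oracle(self):
        # policy-ref gaps (+1, -1): margin 0.1*(1-(-1)) = 0.2
        loss, margin, _, _ = dpo_loss([1.0], [-1.0], [0.0], [0.0], beta=0.1)
        expected = -math.log(1.0 / (1.0 + math.exp(-0.2)))
        assert loss == pytest.approx(expected, abs=1e-6)
        assert margin[0] == pytest.approx(0.2)

    def test_gradient_direction(self):
        # raising chosen log-prob strictly decreases the loss
        l1, *_ = dpo_loss([1.0], [0.0], [0.0], [0.0], beta=0.1)
        l2, *_ = dpo_loss([1.5], [0.0], [0.0], [0.0], beta=0.1)
        assert l2 < l1

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            dpo_loss([1.0, 2.0], [1.0], [0.0, 0.0], [0.0])

    def test_gradients_match_finite_differences(self):
        pc, pr = np.array([1.3, -0.4]), np.array([0.2, 0.9])
        rc, rr = np.array([0.1, 0.1]), np.array([-0.2, 0.3])
        loss, _, d_c, d_r = dpo_loss(pc, pr, rc, rr, beta=0.7)
        eps = 1e-7
        for i in range(2):
            up = pc.copy(); up[i] += eps
            dn = pc.copy(); dn[i] -= eps
            num = (dpo_loss(up, pr, rc, rr, 0.7)[0] - dpo_loss(dn, pr, rc, rr, 0.7)[0]) / (2 * eps)
            assert d_c[i] == pytest.approx(num, abs=1e-6)


class TestCpoLoss:
    def test_zero_margin_pure_sigmoid_is_ln2(self):
        loss, *_ = cpo_loss([1.0], [1.0], beta=0.1, nll_weight=0.0)
        assert loss == pytest.approx(LN2, abs=1e-12)

    def test_nll_term_is_additive(self):
        base, *_ = cpo_loss([-6.0], [-8.0], beta=0.1, nll_weight=0.0)
        full, *_ = cpo_loss([-6.0], [-8.0], chosen_lengths=[3.0], beta=0.1,
                            nll_weight=1.0)
        assert full == pytest.approx(base + 6.0 / 3.0, abs=1e-12)

    def test_finite_case_against_arithmetic_oracle(self):
        # gap 2.0 at beta 0.1 plus an nll contribution of 1.5
        loss, *_ = cpo_loss([-4.5], [-6.5], chosen_lengths=[3.0], beta=0.1,
                            nll_weight=1.0)
        expected = -math.log(1 / (1 + math.exp(-0.2))) + 1.5
        assert loss == pytest.approx(expected, abs=1e-6)

    def test_lengths_required_with_nll(self):
        with pytest.raises(ValueError):
            cpo_loss([1.0], [0.0], beta=0.1, nll_weight=1.0)


class TestKtoLoss:
    def test_at_reference_point_value_half(self):
        loss, v, _, z0 = kto_loss([1.0], [1.0], [True], beta=0.1, z0=0.0)
        assert v[0] == pytest.approx(0.5)
        assert loss == pytest.approx(0.5)

    def test_desirable_saturation(self):
        loss, v, _, _ = kto_loss([100.0], [0.0], [True], beta=1.0, z0=0.0)
        assert loss == pytest.approx(0.0, abs=1e-12)

    def test_mixed_batch_against_arithmetic_oracle(self):
        def sig(x):
            return 1 / (1 + math.exp(-x))

        r = [2.0, -1.0, 0.5, -3.0]
        labels = [True, True, False, False]
        beta = 0.1
        vals = [sig(beta * 2.0), sig(beta * -1.0),
                sig(beta * -0.5), sig(beta * 3.0)]
        expected = np.mean([1 - v for v in vals])
        loss, _, _, _ = kto_loss(r, [0.0] * 4, labels, beta=beta, z0=0.0)
        assert loss == pytest.approx(expected, abs=1e-6)

    def test_reference_point_clamped_nonnegative(self):
        _, _, _, z0 = kto_loss([-5.0, -3.0], [0.0, 0.0], [True, False], beta=0.1)
        assert z0 == 0.0
        _, _, _, z0 = kto_loss([5.0, 3.0], [0.0, 0.0], [True, False], beta=0.1)
        assert z0 == pytest.approx(4.0)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            kto_loss([], [], [], beta=0.1)

    def test_weights_scale_values(self):
        _, v1, _, _ = kto_loss([1.0], [0.0], [True], beta=0.1, z0=0.0,
                               desirable_weight=2.0)
        _, v2, _, _ = kto_loss([1.0], [0.0], [True], beta=0.1, z0=0.0,
                               desirable_weight=1.0)
        assert v1[0] == pytest.approx(2 * v2[0])


class TestFinetune:
    def test_algorithm_dataset_mismatch_rejected(self, trained_model, tokenizer):
        model = trained_model.clone()
        pairs = [PreferencePair("", "CCO", "CCN")]
        binary = [BinaryExample("", "CCO", True)]
        with pytest.raises(ValueError):
            rlhf_finetune(model, tokenizer, binary, RlhfConfig(algorithm="dpo"))
        with pytest.raises(ValueError):
            rlhf_finetune(model, tokenizer, pairs, RlhfConfig(algorithm="kto"))

    def test_base_weights_frozen_and_margin_increases(self, trained_model,
                                                      tokenizer, verdicts):
        model = trained_model.clone()
        pairs, _ = build_feedback(verdicts, seed=0)
        before = model.base_fingerprint()
        res = rlhf_finetune(model, tokenizer, pairs[:10],
                            RlhfConfig(algorithm="dpo", n_steps=50, lr=2e-3,
                                       batch_size=10, seed=0))
        assert model.base_fingerprint() == before
        early = np.mean(res.margin_trace[:5])
        late = np.mean(res.margin_trace[-5:])
        assert late > early > -1e-9

    def test_kto_training_reduces_loss(self, trained_model, tokenizer, verdicts):
        model = trained_model.clone()
        _, binary = build_feedback(verdicts, seed=0)
        res = rlhf_finetune(model, tokenizer, binary,
                            RlhfConfig(algorithm="kto", n_steps=40, lr=2e-3,
                                       batch_size=32, seed=0))
        assert np.mean(res.loss_trace[-5:]) < np.mean(res.loss_trace[:5])

    def test_cpo_runs_without_reference(self, trained_model, tokenizer, verdicts):
        model = trained_model.clone()
        pairs, _ = build_feedback(verdicts, seed=0)
        res = rlhf_finetune(model, tokenizer, pairs[:8],
                            RlhfConfig(algorithm="cpo", n_steps=10, lr=1e-3,
                                       batch_size=8, seed=0))
        assert len(res.loss_trace) == 10
        assert all(np.isfinite(res.loss_trace))


class TestEvaluateGeneration:
    def test_ratio_percent(self):
        samples = (["c1ccncc1"] * 16) + (["CCO"] * 60) + (["C1CC"] * 24)
        n_valid, n_pass, ratio = evaluate_generation(samples)
        assert (n_valid, n_pass) == (76, 16)
        assert ratio == pytest.approx(100 * 16 / 76, abs=1e-9)
        assert ratio == pytest.approx(21.05, abs=0.01)

    def test_zero_pass(self):
        n_valid, n_pass, ratio = evaluate_generation(["CCO", "CCN"])
        assert (n_pass, ratio) == (0, 0.0)

    def test_no_valid_molecules_undefined(self):
        n_valid, n_pass, ratio = evaluate_generation(["xx", ""])
        assert n_valid == 0 and ratio is None


def test_jsonl_round_trip(tmp_path):
    pairs = [PreferencePair("", "CCO", "CCN")]
    binary = [BinaryExample("", "c1ccncc1", True), BinaryExample("", "CCC", False)]
    write_jsonl(tmp_path / "p.jsonl", pairs)
    write_jsonl(tmp_path / "b.jsonl", binary)
    assert read_jsonl(tmp_path / "p.jsonl") == pairs
    assert read_jsonl(tmp_path / "b.jsonl") == binary
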