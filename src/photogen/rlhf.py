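"""Preference alignment of the SMILES generator from rule-based feedback.

The three structural judgments (ring / ring unsaturation / ring heteroatom)
stand in for human feedback: molecules satisfying the weakened criterion
(>= 2 of 3) are desirable, molecules satisfying none are undesirable, and
molecules satisfying exactly one are ambiguous and excluded.  From these
verdicts two dataset shapes are built:

* a **preference dataset** of {prompt, chosen, rejected} records for DPO and
  CPO — prompts are BOS-only because generation is unconditional;
* a **binary-signal dataset** of {prompt, completion, label} records for
  KTO, whose size is always |positives| + |negatives|.

Objectives (beta = 0.1, sigmoid loss, desirable/undesirable weights 1.0 by
default):

* DPO:  L = -log sigma(beta * [(log pi(c) - log ref(c)) - (log pi(r) - log ref(r))])
* CPO:  L = -log sigma(beta * [log pi(c) - log pi(r)]) + w_nll * NLL(c)/|c|
* KTO:  v = w_D * sigma(beta (r - z0)) for desirable, w_U * sigma(beta (z0 - r))
        for undesirable, with r = log pi - log ref and z0 a detached,
        non-negative batch reference point; L = mean(w - v).

Sequence log-probabilities are sums over completion tokens (not length
normalized); only the CPO likelihood term is per-token.  Fine-tuning updates
the low-rank adapter only — the frozen pre-fine-tune snapshot acts as the
reference model for DPO and KTO.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .chem_graph import CriterionVerdict
from .language_model import GptLM, TrainSchedule, AdamW, cosine_lr

__all__ = [
    "PreferencePair",
    "BinaryExample",
    "RlhfConfig",
    "build_feedback",
    "dpo_loss",
    "cpo_loss",
    "kto_loss",
    "rlhf_finetune",
    "evaluate_generation",
    "write_jsonl",
    "read_jsonl",
]


@dataclass(frozen=True)
class PreferencePair:
    prompt: str
    chosen: str
    rejected: str


@dataclass(frozen=True)
class BinaryExample:
    prompt: str
    completion: str
    label: bool


@dataclass
class RlhfConfig:
    algorithm: str = "dpo"  # dpo | cpo | kto
    beta: float = 0.1
    desirable_weight: float = 1.0
    undesirable_weight: float = 1.0
    loss_type: str = "sigmoid"
    nll_weight: float = 1.0  # CPO only; 0 gives the pure sigmoid form
    lr: float = 1e-3
    n_steps: int = 100
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.algorithm not in ("dpo", "cpo", "kto"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.desirable_weight <= 0 or self.undesirable_weight <= 0:
            raise ValueError("weights must be positive")


# ---------------------------------------------------------------------------
# dataset construction
# ---------------------------------------------------------------------------

def build_feedback(verdicts: dict, seed: int = 0, prompt: str = ""):
    """Partition scored molecules into feedback datasets.

    ``verdicts`` maps SMILES -> :class:`CriterionVerdict`.  Weakened-pass
    molecules become positives, zero-criteria molecules negatives; molecules
    satisfying exactly one judgment belong to neither.  Preference pairs are
    formed by seeded cycling of (shuffled) positives over the negatives, so
    every negative is used exactly once.
    """
    positives = sorted(s for s, v in verdicts.items() if v.weakened_pass)
    negatives = sorted(s for s, v in verdicts.items() if v.n_satisfied == 0)

    binary = [BinaryExample(prompt, s, True) for s in positives] + [
        BinaryExample(prompt, s, False) for s in negatives
    ]
    if not positives or not negatives:
        import warnings

        warnings.warn("one feedback class is empty; preference pairs unavailable")
        return [], binary

    rng = np.random.default_rng(seed)
    pos = list(positives)
    rng.shuffle(pos)
    pairs = [
        PreferencePair(prompt, pos[i % len(pos)], neg)
        for i, neg in enumerate(negatives)
    ]
    return pairs, binary


def write_jsonl(path, records) -> None:
    with open(path, "w") as fh:
        for r in records:
            if isinstance(r, PreferencePair):
                fh.write(json.dumps({"prompt": r.prompt, "chosen": r.chosen,
                                     "rejected": r.rejected}) + "\n")
            elif isinstance(r, BinaryExample):
                fh.write(json.dumps({"prompt": r.prompt, "completion": r.completion,
                                     "label": r.label}) + "\n")
            else:
                fh.write(json.dumps(r) + "\n")


def read_jsonl(path) -> list:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        d = json.loads(line)
        if "chosen" in d:
            out.append(PreferencePair(d["prompt"], d["chosen"], d["rejected"]))
        elif "completion" in d:
            out.append(BinaryExample(d["prompt"], d["completion"], bool(d["label"])))
        else:
            out.append(d)
    return out


# ---------------------------------------------------------------------------
# losses (operate on per-sequence summed log-probabilities)
# ---------------------------------------------------------------------------

def _log_sigmoid(x):
    # numerically stable -softplus(-x)
    return np.where(x >= 0, -np.log1p(np.exp(-np.abs(x))),
                    x - np.log1p(np.exp(-np.abs(x))))


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def dpo_loss(policy_chosen, policy_rejected, ref_chosen, ref_rejected, beta: float = 0.1):
    """Direct preference optimization, sigmoid form.

    Returns (mean loss, margins, d loss/d policy_chosen, d loss/d policy_rejected)
    where the margin is beta * [(pi_c - ref_c) - (pi_r - ref_r)].
    """
    pc, pr = np.atleast_1d(np.asarray(policy_chosen, float)), np.atleast_1d(
        np.asarray(policy_rejected, float))
    rc, rr = np.atleast_1d(np.asarray(ref_chosen, float)), np.atleast_1d(
        np.asarray(ref_rejected, float))
    if not (pc.shape == pr.shape == rc.shape == rr.shape):
        raise ValueError("mismatched batch shapes")
    margin = beta * ((pc - rc) - (pr - rr))
    loss = -_log_sigmoid(margin)
    # d/dm of -log sigma(m) = sigma(m) - 1
    dm = (_sigmoid(margin) - 1.0) / len(pc)
    return float(loss.mean()), margin, beta * dm, -beta * dm


def cpo_loss(policy_chosen, policy_rejected, chosen_lengths=None, beta: float = 0.1,
             nll_weight: float = 1.0):
    """Contrastive preference optimization: reference-free sigmoid preference
    term plus a per-token NLL anchor on the chosen completion."""
    pc = np.atleast_1d(np.asarray(policy_chosen, float))
    pr = np.atleast_1d(np.asarray(policy_rejected, float))
    if pc.shape != pr.shape:
        raise ValueError("mismatched batch shapes")
    margin = beta * (pc - pr)
    pref = -_log_sigmoid(margin)
    dm = (_sigmoid(margin) - 1.0) / len(pc)
    d_pc = beta * dm
    d_pr = -beta * dm
    if nll_weight > 0:
        if chosen_lengths is None:
            raise ValueError("chosen_lengths required when nll_weight > 0")
        L = np.atleast_1d(np.asarray(chosen_lengths, float))
        nll = -pc / L
        loss = float(pref.mean() + nll_weight * nll.mean())
        d_pc = d_pc - nll_weight / (L * len(pc))
    else:
        loss = float(pref.mean())
    return loss, margin, d_pc, d_pr


def kto_loss(policy_logps, ref_logps, labels, beta: float = 0.1,
             desirable_weight: float = 1.0, undesirable_weight: float = 1.0,
             z0: float | None = None):
    """Kahneman–Tversky optimization on binary-labeled completions.

    r_i = policy_logp_i - ref_logp_i; z0 defaults to the detached,
    non-negative batch mean of r.  Per-example value
    v_i = w_D * sigma(beta (r_i - z0)) if desirable else
    w_U * sigma(beta (z0 - r_i)); loss = mean(w_i - v_i).
    Returns (loss, per-example values, d loss/d policy_logps, z0).
    """
    p = np.atleast_1d(np.asarray(policy_logps, float))
    r0 = np.atleast_1d(np.asarray(ref_logps, float))
    lab = np.atleast_1d(np.asarray(labels, bool))
    if not (p.shape == r0.shape == lab.shape):
        raise ValueError("mismatched batch shapes")
    if p.size == 0:
        raise ValueError("empty batch")
    r = p - r0
    if z0 is None:
        z0 = max(0.0, float(r.mean()))  # detached reference point
    w = np.where(lab, desirable_weight, undesirable_weight)
    sign = np.where(lab, 1.0, -1.0)
    v = w * _sigmoid(beta * sign * (r - z0))
    loss = float((w - v).mean())
    # d(w - v)/dr = -w * sigma' * beta * sign
    s = _sigmoid(beta * sign * (r - z0))
    dv = w * s * (1 - s) * beta * sign
    d_p = -dv / p.size
    return loss, v, d_p, z0


# ---------------------------------------------------------------------------
# fine-tuning
# ---------------------------------------------------------------------------

def _encode_padded(tokenizer, smiles: Sequence[str], dtype=np.int64):
    ids, _ = tokenizer.encode_batch(list(smiles))
    return ids


@dataclass
class RlhfResult:
    loss_trace: list
    margin_trace: list = field(default_factory=list)
    z0_trace: list = field(default_factory=list)


def rlhf_finetune(model: GptLM, tokenizer, dataset, config: RlhfConfig) -> RlhfResult:
    """Align the generator on a feedback dataset; adapter weights only.

    ``dataset`` is a list of :class:`PreferencePair` (DPO/CPO) or
    :class:`BinaryExample` (KTO).  For DPO and KTO the reference model is a
    frozen snapshot of the model taken before the first update.
    """
    if not model.adapter:
        raise ValueError("rlhf_finetune requires a model with an adapter")
    if not dataset:
        raise ValueError("empty dataset")
    is_pref = isinstance(dataset[0], PreferencePair)
    if config.algorithm in ("dpo", "cpo") and not is_pref:
        raise ValueError(f"{config.algorithm} requires preference pairs")
    if config.algorithm == "kto" and is_pref:
        raise ValueError("kto requires binary examples")

    pad = tokenizer.pad_id
    reference = model.clone() if config.algorithm in ("dpo", "kto") else None
    rng = np.random.default_rng(config.seed)
    sched = TrainSchedule(lr_initial=config.lr, lr_final=config.lr * 1e-4,
                          seed=config.seed)
    opt = AdamW({k: v.shape for k, v in model.adapter.items()}, sched)
    result = RlhfResult(loss_trace=[])

    n = len(dataset)
    for step in range(config.n_steps):
        take = rng.choice(n, size=min(config.batch_size, n), replace=False)
        batch = [dataset[int(i)] for i in take]
        lr = cosine_lr(step, config.n_steps, config.lr, config.lr * 1e-4)

        if is_pref:
            chosen = _encode_padded(tokenizer, [b.chosen for b in batch])
            rejected = _encode_padded(tokenizer, [b.rejected for b in batch])
            lp_c, cache_c, aux_c = model.sequence_logps(chosen, pad)
            lp_r, cache_r, aux_r = model.sequence_logps(rejected, pad)
            if config.algorithm == "dpo":
                ref_c, _, _ = reference.sequence_logps(chosen, pad)
                ref_r, _, _ = reference.sequence_logps(rejected, pad)
                loss, margin, d_c, d_r = dpo_loss(lp_c, lp_r, ref_c, ref_r, config.beta)
            else:
                lengths = aux_c["mask"].sum(-1)
                loss, margin, d_c, d_r = cpo_loss(
                    lp_c, lp_r, lengths, config.beta, config.nll_weight)
            _, ga_c = model.logp_grads(cache_c, aux_c, d_c)
            _, ga_r = model.logp_grads(cache_r, aux_r, d_r)
            ga = {k: ga_c[k] + ga_r[k] for k in ga_c}
            result.margin_trace.append(float(np.mean(margin)))
        else:
            comp = _encode_padded(tokenizer, [b.completion for b in batch])
            labels = np.array([b.label for b in batch])
            lp, cache, aux = model.sequence_logps(comp, pad)
            ref_lp, _, _ = reference.sequence_logps(comp, pad)
            loss, _, d_p, z0 = kto_loss(
                lp, ref_lp, labels, config.beta,
                config.desirable_weight, config.undesirable_weight)
            _, ga = model.logp_grads(cache, aux, d_p)
            result.z0_trace.append(z0)

        opt.step(model.adapter, ga, lr)
        result.loss_trace.append(loss)
    return result


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_generation(samples: Sequence[str]):
    """Count valid molecules and weakened-criterion passes among samples.

    Returns (n_valid, n_weakened_pass, ratio_percent); the ratio is the pass
    count over the *valid* count, as a percentage, or None when nothing
    parses.
    """
    from .chem_graph import parse_smiles, evaluate_criteria, MoleculeGraph

    n_valid = n_pass = 0
    for s in samples:
        if not s or not s.strip():
            continue
        g = parse_smiles(s)
        if not isinstance(g, MoleculeGraph):
            continue
        n_valid += 1
        if evaluate_criteria(g).weakened_pass:
            n_pass += 1
    ratio = 100.0 * n_pass / n_valid if n_valid else None
    return n_valid, n_pass, ratio
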