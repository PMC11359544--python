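"""GPT-2-style causal language model over SMILES tokens, in NumPy.

The decoder replicates the GPT-2 block layout: learned token and position
embeddings, pre-norm residual blocks with multi-head causal self-attention
and a GELU MLP (inner dimension 4 x d_model), a final layer norm, and an
output head tied to the token embedding.  The reference configuration
(vocabulary 1072, d_model 512, 8 heads, 4 blocks, 512 positions, tied
embeddings) has exactly 13,421,568 trainable parameters, i.e. 13.4 M.

Forward and backward passes are written out explicitly so the same machinery
serves ordinary causal-LM training (AdamW + cosine annealing) and the
preference-optimization objectives, which need gradients of per-sequence
log-probabilities.  A low-rank (LoRA-style) adapter on the attention query
and value projections supports parameter-efficient fine-tuning with the base
weights frozen.

Everything is seeded and deterministic: same seed, same weights, same
samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GptConfig",
    "AdapterConfig",
    "TrainSchedule",
    "GptLM",
    "count_parameters",
    "parameter_count_closed_form",
    "cosine_lr",
    "AdamW",
    "finetune_clm",
    "sample_smiles",
    "SampleReport",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class GptConfig:
    vocab_size: int
    d_model: int = 512
    n_heads: int = 8
    n_blocks: int = 4
    max_positions: int = 512
    mlp_multiplier: int = 4
    tie_embeddings: bool = True

    def __post_init__(self):
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")

    @property
    def head_dim(self) -> int:
        return self.d_model // self.n_heads


@dataclass
class AdapterConfig:
    """Low-rank adapter on attention projections; scaling = alpha / rank."""

    rank: int = 8
    alpha: float = 16.0
    target_projections: tuple = ("query", "value")

    def __post_init__(self):
        if self.rank < 1:
            raise ValueError("adapter rank must be >= 1")
        bad = set(self.target_projections) - {"query", "key", "value", "output"}
        if bad:
            raise ValueError(f"unknown target projections: {sorted(bad)}")

    @property
    def scaling(self) -> float:
        return self.alpha / self.rank


@dataclass
class TrainSchedule:
    """AdamW + cosine-annealed learning rate, decaying lr_initial -> lr_final."""

    epochs: int = 6
    lr_initial: float = 5e-4
    lr_final: float = 5e-8
    batch_size: int = 128
    max_seq_len: int = 512
    seed: int = 0
    weight_decay: float = 0.01
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8


def cosine_lr(step: int, total_steps: int, lr_initial: float, lr_final: float) -> float:
    """Cosine annealing; lr(0) = lr_initial, lr(total_steps - 1) = lr_final."""
    if total_steps <= 1:
        return lr_initial
    t = step / (total_steps - 1)
    return lr_final + 0.5 * (lr_initial - lr_final) * (1.0 + math.cos(math.pi * t))


# ---------------------------------------------------------------------------
# primitive layers (forward + backward)
# ---------------------------------------------------------------------------

_LN_EPS = 1e-5


def _layernorm_fwd(x, g, b):
    mu = x.mean(-1, keepdims=True)
    var = x.var(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * inv
    return g * xhat + b, (xhat, inv, g)


def _layernorm_bwd(dy, cache):
    xhat, inv, g = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    m1 = dxhat.mean(-1, keepdims=True)
    m2 = (dxhat * xhat).mean(-1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    return dx, dg, db


_GELU_C = math.sqrt(2.0 / math.pi)


def _gelu_fwd(x):
    u = _GELU_C * (x + 0.044715 * x ** 3)
    t = np.tanh(u)
    return 0.5 * x * (1.0 + t), (x, t)


def _gelu_bwd(dy, cache):
    x, t = cache
    du = _GELU_C * (1.0 + 3 * 0.044715 * x ** 2)
    return dy * (0.5 * (1.0 + t) + 0.5 * x * (1.0 - t ** 2) * du)


def _softmax(z, axis=-1):
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# parameter initialisation and counting
# ---------------------------------------------------------------------------

def _init_params(cfg: GptConfig, seed: int, dtype=np.float64) -> dict:
    rng = np.random.default_rng(seed)
    d, V, P = cfg.d_model, cfg.vocab_size, cfg.max_positions
    inner = cfg.mlp_multiplier * d
    std = 0.02

    def w(*shape):
        return (std * rng.standard_normal(shape)).astype(dtype)

    params = {"wte": w(V, d), "wpe": w(P, d)}
    for i in range(cfg.n_blocks):
        p = f"h{i}."
        params[p + "ln1.g"] = np.ones(d, dtype)
        params[p + "ln1.b"] = np.zeros(d, dtype)
        params[p + "attn.w_qkv"] = w(d, 3 * d)
        params[p + "attn.b_qkv"] = np.zeros(3 * d, dtype)
        params[p + "attn.w_out"] = w(d, d) / math.sqrt(2 * cfg.n_blocks)
        params[p + "attn.b_out"] = np.zeros(d, dtype)
        params[p + "ln2.g"] = np.ones(d, dtype)
        params[p + "ln2.b"] = np.zeros(d, dtype)
        params[p + "mlp.w_in"] = w(d, inner)
        params[p + "mlp.b_in"] = np.zeros(inner, dtype)
        params[p + "mlp.w_out"] = w(inner, d) / math.sqrt(2 * cfg.n_blocks)
        params[p + "mlp.b_out"] = np.zeros(d, dtype)
    params["lnf.g"] = np.ones(d, dtype)
    params["lnf.b"] = np.zeros(d, dtype)
    if not cfg.tie_embeddings:
        params["head.w"] = w(d, V)
    return params


def _init_adapter(cfg: GptConfig, acfg: AdapterConfig, seed: int, dtype=np.float64) -> dict:
    # A is random, B starts at zero so the adapter is initially the identity.
    rng = np.random.default_rng(seed)
    d, r = cfg.d_model, acfg.rank
    adapter = {}
    for i in range(cfg.n_blocks):
        for proj in acfg.target_projections:
            adapter[f"h{i}.lora.{proj}.A"] = (0.02 * rng.standard_normal((d, r))).astype(dtype)
            adapter[f"h{i}.lora.{proj}.B"] = np.zeros((r, d), dtype)
    return adapter


def parameter_count_closed_form(cfg: GptConfig) -> int:
    """Closed-form trainable-scalar count of the decoder."""
    d, V, P, inner = cfg.d_model, cfg.vocab_size, cfg.max_positions, cfg.mlp_multiplier * cfg.d_model
    per_block = (
        (d * 3 * d + 3 * d)      # qkv projection
        + (d * d + d)            # attention output projection
        + (d * inner + inner)    # mlp in
        + (inner * d + d)        # mlp out
        + 4 * d                  # two layer norms
    )
    total = V * d + P * d + cfg.n_blocks * per_block + 2 * d
    if not cfg.tie_embeddings:
        total += d * V
    return total


def count_parameters(state: "GptLM", split: bool = False):
    """Exact trainable-scalar count by enumerating tensors."""
    base = sum(v.size for v in state.params.values())
    adapter = sum(v.size for v in state.adapter.values()) if state.adapter else 0
    if split:
        return base, adapter
    return base + adapter


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

_PROJ_SLICE = {"query": 0, "key": 1, "value": 2}


class GptLM:
    """Decoder-only causal LM with an optional low-rank adapter.

    Parameters live in flat dicts of numpy arrays (``params`` for the base,
    ``adapter`` for the LoRA tensors), which makes freezing, hashing and
    cloning a reference model trivial.
    """

    def __init__(self, config: GptConfig, seed: int = 0, adapter_config: AdapterConfig | None = None,
                 dtype=np.float64):
        self.config = config
        self.dtype = dtype
        self.params = _init_params(config, seed, dtype)
        self.adapter_config = adapter_config
        self.adapter = (
            _init_adapter(config, adapter_config, seed + 1, dtype) if adapter_config else {}
        )

    # -- plumbing ----------------------------------------------------------

    def add_adapter(self, adapter_config: AdapterConfig, seed: int = 0) -> None:
        self.adapter_config = adapter_config
        self.adapter = _init_adapter(self.config, adapter_config, seed, self.dtype)

    def clone(self) -> "GptLM":
        dup = GptLM.__new__(GptLM)
        dup.config = self.config
        dup.dtype = self.dtype
        dup.adapter_config = self.adapter_config
        dup.params = {k: v.copy() for k, v in self.params.items()}
        dup.adapter = {k: v.copy() for k, v in self.adapter.items()}
        return dup

    def base_fingerprint(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for k in sorted(self.params):
            h.update(k.encode())
            h.update(np.ascontiguousarray(self.params[k]).tobytes())
        return h.hexdigest()

    def save(self, path) -> None:
        meta = {
            "config": asdict(self.config),
            "adapter_config": asdict(self.adapter_config) if self.adapter_config else None,
        }
        arrays = {f"base::{k}": v for k, v in self.params.items()}
        arrays.update({f"adapter::{k}": v for k, v in self.adapter.items()})
        np.savez(path, __meta__=np.frombuffer(repr(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "GptLM":
        import ast

        with np.load(path) as z:
            meta = ast.literal_eval(bytes(z["__meta__"]).decode())
            model = cls.__new__(cls)
            model.config = GptConfig(**meta["config"])
            ac = meta["adapter_config"]
            if ac is not None:
                ac["target_projections"] = tuple(ac["target_projections"])
            model.adapter_config = AdapterConfig(**ac) if ac else None
            model.params = {}
            model.adapter = {}
            for key in z.files:
                if key == "__meta__":
                    continue
                scope, name = key.split("::", 1)
                (model.params if scope == "base" else model.adapter)[name] = z[key]
        model.dtype = next(iter(model.params.values())).dtype.type
        return model

    # -- forward -----------------------------------------------------------

    def forward(self, ids: np.ndarray, use_adapter: bool = True):
        """Return logits (B, T, V) and a cache for the backward pass."""
        cfg = self.config
        ids = np.asarray(ids)
        if ids.ndim == 1:
            ids = ids[None, :]
        B, T = ids.shape
        if T > cfg.max_positions:
            raise ValueError(f"sequence length {T} exceeds max_positions {cfg.max_positions}")
        P = self.params
        A = self.adapter if (use_adapter and self.adapter) else {}
        acfg = self.adapter_config
        scale = acfg.scaling if (A and acfg) else 0.0

        x = P["wte"][ids] + P["wpe"][:T][None, :, :]
        mask = np.triu(np.full((T, T), -np.inf, dtype=x.dtype), k=1)
        cache = {"ids": ids, "T": T, "B": B, "use_adapter": bool(A), "blocks": []}
        h, hd = cfg.n_heads, cfg.head_dim

        for i in range(cfg.n_blocks):
            p = f"h{i}."
            c = {}
            a, c["ln1"] = _layernorm_fwd(x, P[p + "ln1.g"], P[p + "ln1.b"])
            a2 = a.reshape(B * T, -1)
            qkv = a2 @ P[p + "attn.w_qkv"] + P[p + "attn.b_qkv"]
            qkv = qkv.reshape(B, T, 3, cfg.d_model)
            c["a2"] = a2
            c["lora"] = {}
            for proj, sl in _PROJ_SLICE.items():
                key = f"h{i}.lora.{proj}.A"
                if key in A:
                    mid = a2 @ A[key]                       # (B*T, r)
                    qkv[:, :, sl, :] += scale * (mid @ A[key.replace(".A", ".B")]).reshape(B, T, -1)
                    c["lora"][proj] = mid
            q = qkv[:, :, 0].reshape(B, T, h, hd).transpose(0, 2, 1, 3)
            k = qkv[:, :, 1].reshape(B, T, h, hd).transpose(0, 2, 1, 3)
            v = qkv[:, :, 2].reshape(B, T, h, hd).transpose(0, 2, 1, 3)
            att = q @ k.transpose(0, 1, 3, 2) / math.sqrt(hd) + mask
            prob = _softmax(att)
            o = (prob @ v).transpose(0, 2, 1, 3).reshape(B * T, cfg.d_model)
            c.update(q=q, k=k, v=v, prob=prob, o=o)
            attn_out = o @ P[p + "attn.w_out"] + P[p + "attn.b_out"]
            x = x + attn_out.reshape(B, T, -1)

            m, c["ln2"] = _layernorm_fwd(x, P[p + "ln2.g"], P[p + "ln2.b"])
            m2 = m.reshape(B * T, -1)
            h1 = m2 @ P[p + "mlp.w_in"] + P[p + "mlp.b_in"]
            hg, c["gelu"] = _gelu_fwd(h1)
            x = x + (hg @ P[p + "mlp.w_out"] + P[p + "mlp.b_out"]).reshape(B, T, -1)
            c["m2"] = m2
            c["hg"] = hg
            cache["blocks"].append(c)

        xf, cache["lnf"] = _layernorm_fwd(x, P["lnf.g"], P["lnf.b"])
        cache["xf"] = xf
        w_head = P["wte"].T if cfg.tie_embeddings else P["head.w"]
        logits = xf.reshape(B * T, -1) @ w_head
        return logits.reshape(B, T, -1), cache

    # -- backward ----------------------------------------------------------

    def backward(self, cache: dict, dlogits: np.ndarray):
        """Backprop from d(loss)/d(logits); returns (base grads, adapter grads)."""
        cfg = self.config
        P = self.params
        A = self.adapter if cache["use_adapter"] else {}
        acfg = self.adapter_config
        scale = acfg.scaling if (A and acfg) else 0.0
        B, T = cache["B"], cache["T"]
        h, hd = cfg.n_heads, cfg.head_dim
        ids = cache["ids"]

        g = {k: np.zeros_like(v) for k, v in P.items()}
        ga = {k: np.zeros_like(v) for k, v in A.items()}

        dl2 = dlogits.reshape(B * T, -1)
        xf2 = cache["xf"].reshape(B * T, -1)
        if cfg.tie_embeddings:
            g["wte"] += dl2.T @ xf2  # (V, d) from head
            dxf2 = dl2 @ P["wte"]
        else:
            g["head.w"] += xf2.T @ dl2
            dxf2 = dl2 @ P["head.w"].T
        dx, dg_, db_ = _layernorm_bwd(dxf2.reshape(B, T, -1), cache["lnf"])
        g["lnf.g"] += dg_
        g["lnf.b"] += db_

        for i in reversed(range(cfg.n_blocks)):
            p = f"h{i}."
            c = cache["blocks"][i]
            # MLP branch
            dh2 = dx.reshape(B * T, -1)
            g[p + "mlp.w_out"] += c["hg"].T @ dh2
            g[p + "mlp.b_out"] += dh2.sum(0)
            dhg = dh2 @ P[p + "mlp.w_out"].T
            dh1 = _gelu_bwd(dhg, c["gelu"])
            g[p + "mlp.w_in"] += c["m2"].T @ dh1
            g[p + "mlp.b_in"] += dh1.sum(0)
            dm2 = dh1 @ P[p + "mlp.w_in"].T
            dm, dg_, db_ = _layernorm_bwd(dm2.reshape(B, T, -1), c["ln2"])
            g[p + "ln2.g"] += dg_
            g[p + "ln2.b"] += db_
            dx = dx + dm

            # attention branch
            do2 = dx.reshape(B * T, -1)
            g[p + "attn.w_out"] += c["o"].T @ do2
            g[p + "attn.b_out"] += do2.sum(0)
            do = (do2 @ P[p + "attn.w_out"].T).reshape(B, T, h, hd).transpose(0, 2, 1, 3)
            dprob = do @ c["v"].transpose(0, 1, 3, 2)
            dv = c["prob"].transpose(0, 1, 3, 2) @ do
            datt = c["prob"] * (dprob - (dprob * c["prob"]).sum(-1, keepdims=True))
            datt /= math.sqrt(hd)
            dq = datt @ c["k"]
            dk = datt.transpose(0, 1, 3, 2) @ c["q"]
            dqkv = np.empty((B, T, 3, cfg.d_model), dtype=dx.dtype)
            dqkv[:, :, 0] = dq.transpose(0, 2, 1, 3).reshape(B, T, -1)
            dqkv[:, :, 1] = dk.transpose(0, 2, 1, 3).reshape(B, T, -1)
            dqkv[:, :, 2] = dv.transpose(0, 2, 1, 3).reshape(B, T, -1)
            da2 = np.zeros_like(c["a2"])
            for proj, sl in _PROJ_SLICE.items():
                keyA = f"h{i}.lora.{proj}.A"
                if keyA in A:
                    keyB = keyA.replace(".A", ".B")
                    dproj = dqkv[:, :, sl].reshape(B * T, -1) * 1.0
                    ga[keyB] += scale * c["lora"][proj].T @ dproj
                    dmid = scale * dproj @ A[keyB].T
                    ga[keyA] += c["a2"].T @ dmid
                    da2 += dmid @ A[keyA].T
            dqkv2 = dqkv.reshape(B * T, 3 * cfg.d_model)
            g[p + "attn.w_qkv"] += c["a2"].T @ dqkv2
            g[p + "attn.b_qkv"] += dqkv2.sum(0)
            da2 += dqkv2 @ P[p + "attn.w_qkv"].T
            da, dg_, db_ = _layernorm_bwd(da2.reshape(B, T, -1), c["ln1"])
            g[p + "ln1.g"] += dg_
            g[p + "ln1.b"] += db_
            dx = dx + da

        # embeddings
        np.add.at(g["wte"], ids.reshape(-1), dx.reshape(B * T, -1))
        g["wpe"][:T] += dx.sum(0)
        return g, ga

    # -- losses ------------------------------------------------------------

    def clm_loss_and_dlogits(self, ids: np.ndarray, pad_id: int, logits: np.ndarray):
        """Mean next-token cross-entropy over non-pad targets, and d/dlogits."""
        targets = ids[:, 1:]
        lg = logits[:, :-1]
        B, Tm1, V = lg.shape
        mask = (targets != pad_id)
        p = _softmax(lg)
        idx = np.clip(targets, 0, V - 1)
        tok_nll = -np.log(
            np.take_along_axis(p, idx[..., None], axis=-1)[..., 0] + 1e-300
        )
        n_tok = max(int(mask.sum()), 1)
        loss = float((tok_nll * mask).sum() / n_tok)
        dlg = p.copy()
        np.put_along_axis(
            dlg, idx[..., None],
            np.take_along_axis(dlg, idx[..., None], axis=-1) - 1.0, axis=-1,
        )
        dlg *= (mask[..., None] / n_tok)
        dlogits = np.zeros_like(logits)
        dlogits[:, :-1] = dlg
        return loss, dlogits

    def sequence_logps(self, ids: np.ndarray, pad_id: int, prompt_len: int = 1,
                       use_adapter: bool = True):
        """Sum of token log-probs over completion tokens for each row.

        ``prompt_len`` tokens at the start (the BOS-only prompt by default)
        are conditioned on, not scored.  Returns (logps, cache, aux) where
        aux holds what the gradient route needs.
        """
        logits, cache = self.forward(ids, use_adapter=use_adapter)
        targets = ids[:, 1:]
        lg = logits[:, :-1]
        logp = lg - (np.log(np.exp(lg - lg.max(-1, keepdims=True)).sum(-1, keepdims=True))
                     + lg.max(-1, keepdims=True))
        tok_lp = np.take_along_axis(logp, targets[..., None], axis=-1)[..., 0]
        mask = (targets != pad_id)
        if prompt_len > 1:
            mask = mask.copy()
            mask[:, : prompt_len - 1] = False
        seq_lp = (tok_lp * mask).sum(-1)
        aux = {"targets": targets, "mask": mask, "p": np.exp(logp)}
        return seq_lp, cache, aux

    def logp_grads(self, cache: dict, aux: dict, seq_weights: np.ndarray):
        """Grads of sum_i w_i * logp_i with respect to all parameters."""
        targets, mask, p = aux["targets"], aux["mask"], aux["p"]
        B, Tm1, V = p.shape
        onehot_minus_p = -p.copy()
        np.put_along_axis(
            onehot_minus_p, targets[..., None],
            np.take_along_axis(onehot_minus_p, targets[..., None], axis=-1) + 1.0, axis=-1,
        )
        d = onehot_minus_p * mask[..., None] * seq_weights[:, None, None]
        dlogits = np.zeros((B, Tm1 + 1, V), dtype=p.dtype)
        dlogits[:, :-1] = d
        return self.backward(cache, dlogits)

    # -- sampling ----------------------------------------------------------

    def sample_ids(self, n: int, bos_id: int, eos_id: int, seed: int,
                   temperature: float = 1.0, max_len: int = 64,
                   use_adapter: bool = True, batch_size: int = 64) -> list:
        """Autoregressive ancestral sampling; returns a list of id lists
        (without BOS/EOS)."""
        if temperature <= 0:
            raise ValueError("temperature must be positive")
        max_len = min(max_len, self.config.max_positions)
        rng = np.random.default_rng(seed)
        out: list[list[int]] = []
        remaining = n
        while remaining > 0:
            b = min(batch_size, remaining)
            ids = np.full((b, 1), bos_id, dtype=np.int64)
            done = np.zeros(b, dtype=bool)
            kv = None
            tok = ids[:, 0]
            for pos in range(max_len - 1):
                logits, kv = self._step(tok, pos, kv, use_adapter)
                probs = _softmax(logits / temperature)
                u = rng.random((b, 1))
                nxt = (probs.cumsum(-1) > u).argmax(-1)
                nxt = np.where(done, eos_id, nxt)
                ids = np.concatenate([ids, nxt[:, None]], axis=1)
                done |= nxt == eos_id
                tok = nxt
                if done.all():
                    break
            for row in ids:
                seq = row[1:].tolist()
                if eos_id in seq:
                    seq = seq[: seq.index(eos_id)]
                out.append(seq)
            remaining -= b
        return out

    def _step(self, tok: np.ndarray, pos: int, kv, use_adapter: bool):
        """One incremental decode step with a per-block key/value cache.

        ``tok`` is the (B,) token at position ``pos``; returns the logits for
        the next position and the updated cache.  Matches :meth:`forward`
        exactly (same layers, same adapter path) but attends with a single
        query, so sampling is linear rather than quadratic in length.
        """
        cfg = self.config
        P = self.params
        A = self.adapter if (use_adapter and self.adapter) else {}
        scale = self.adapter_config.scaling if (A and self.adapter_config) else 0.0
        B = tok.shape[0]
        h, hd = cfg.n_heads, cfg.head_dim
        if kv is None:
            kv = [
                {"k": np.zeros((B, h, 0, hd), dtype=self.params["wte"].dtype),
                 "v": np.zeros((B, h, 0, hd), dtype=self.params["wte"].dtype)}
                for _ in range(cfg.n_blocks)
            ]
        x = P["wte"][tok] + P["wpe"][pos]
        for i in range(cfg.n_blocks):
            p = f"h{i}."
            a, _ = _layernorm_fwd(x, P[p + "ln1.g"], P[p + "ln1.b"])
            qkv = (a @ P[p + "attn.w_qkv"] + P[p + "attn.b_qkv"]).reshape(B, 3, cfg.d_model)
            for proj, sl in _PROJ_SLICE.items():
                key = f"h{i}.lora.{proj}.A"
                if key in A:
                    qkv[:, sl, :] += scale * ((a @ A[key]) @ A[key.replace(".A", ".B")])
            q = qkv[:, 0].reshape(B, h, 1, hd)
            k_new = qkv[:, 1].reshape(B, h, 1, hd)
            v_new = qkv[:, 2].reshape(B, h, 1, hd)
            k = np.concatenate([kv[i]["k"], k_new], axis=2)
            v = np.concatenate([kv[i]["v"], v_new], axis=2)
            kv[i]["k"], kv[i]["v"] = k, v
            att = (q @ k.transpose(0, 1, 3, 2))[:, :, 0, :] / math.sqrt(hd)
            prob = _softmax(att)
            o = (prob[:, :, None, :] @ v)[:, :, 0, :].reshape(B, cfg.d_model)
            x = x + o @ P[p + "attn.w_out"] + P[p + "attn.b_out"]
            m, _ = _layernorm_fwd(x, P[p + "ln2.g"], P[p + "ln2.b"])
            h1 = m @ P[p + "mlp.w_in"] + P[p + "mlp.b_in"]
            hg, _ = _gelu_fwd(h1)
            x = x + hg @ P[p + "mlp.w_out"] + P[p + "mlp.b_out"]
        xf, _ = _layernorm_fwd(x, P["lnf.g"], P["lnf.b"])
        w_head = P["wte"].T if cfg.tie_embeddings else P["head.w"]
        return xf @ w_head, kv


# ---------------------------------------------------------------------------
# optimisation
# ---------------------------------------------------------------------------

class AdamW:
    """AdamW with decoupled weight decay (applied to matrices only)."""

    def __init__(self, shapes: dict, schedule: TrainSchedule):
        self.s = schedule
        self.m = {k: np.zeros(v) for k, v in shapes.items()}
        self.v = {k: np.zeros(v) for k, v in shapes.items()}
        self.t = 0

    def step(self, params: dict, grads: dict, lr: float) -> None:
        s = self.s
        self.t += 1
        bc1 = 1.0 - s.beta1 ** self.t
        bc2 = 1.0 - s.beta2 ** self.t
        for k, gr in grads.items():
            m = self.m[k] = s.beta1 * self.m[k] + (1 - s.beta1) * gr
            v = self.v[k] = s.beta2 * self.v[k] + (1 - s.beta2) * gr * gr
            upd = (m / bc1) / (np.sqrt(v / bc2) + s.eps)
            if params[k].ndim >= 2:
                upd = upd + s.weight_decay * params[k]
            params[k] -= lr * upd


def _batch_iter(ids: np.ndarray, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(len(ids))
    for start in range(0, len(ids), batch_size):
        yield ids[order[start : start + batch_size]]


def finetune_clm(model: GptLM, token_ids: np.ndarray, schedule: TrainSchedule,
                 pad_id: int, trainable: str = "all") -> list:
    """Causal-LM training; returns the per-epoch mean cross-entropy trace.

    ``trainable`` is ``"all"`` or ``"adapter_only"``; with ``adapter_only``
    the base weights are bit-identical before and after.
    """
    if trainable not in ("all", "adapter_only"):
        raise ValueError("trainable must be 'all' or 'adapter_only'")
    if trainable == "adapter_only" and not model.adapter:
        raise ValueError("adapter_only requested but the model has no adapter")
    ids = np.asarray(token_ids)
    n_truncated = 0
    if ids.shape[1] > schedule.max_seq_len:
        n_truncated = int((ids[:, schedule.max_seq_len:] != pad_id).any(1).sum())
        import warnings

        if n_truncated:
            warnings.warn(f"truncated {n_truncated} over-length sequences")
        ids = ids[:, : schedule.max_seq_len]

    rng = np.random.default_rng(schedule.seed)
    n_batches = math.ceil(len(ids) / schedule.batch_size)
    total_steps = schedule.epochs * n_batches
    if trainable == "all":
        opt_b = AdamW({k: v.shape for k, v in model.params.items()}, schedule)
    opt_a = AdamW({k: v.shape for k, v in model.adapter.items()}, schedule) if model.adapter else None

    trace, step = [], 0
    for _ in range(schedule.epochs):
        losses = []
        for batch in _batch_iter(ids, schedule.batch_size, rng):
            logits, cache = model.forward(batch)
            loss, dlogits = model.clm_loss_and_dlogits(batch, pad_id, logits)
            g, ga = model.backward(cache, dlogits)
            lr = cosine_lr(step, total_steps, schedule.lr_initial, schedule.lr_final)
            if trainable == "all":
                opt_b.step(model.params, g, lr)
            if opt_a is not None:
                opt_a.step(model.adapter, ga, lr)
            losses.append(loss)
            step += 1
        trace.append(float(np.mean(losses)))
    return trace


# ---------------------------------------------------------------------------
# sampling to SMILES
# ---------------------------------------------------------------------------

@dataclass
class SampleReport:
    n: int
    n_valid: int
    n_unique_valid: int
    smiles: list = field(repr=False)
    valid_smiles: list = field(repr=False)

    @property
    def valid_fraction(self) -> float:
        return self.n_valid / self.n if self.n else float("nan")


def sample_smiles(model: GptLM, tokenizer, n: int, seed: int,
                  temperature: float = 1.0, max_len: int = 64,
                  use_adapter: bool = True) -> SampleReport:
    """Sample ``n`` SMILES and validate them with the molecular-graph parser."""
    from . import chem_graph

    if n == 0:
        return SampleReport(0, 0, 0, [], [])
    id_lists = model.sample_ids(
        n, tokenizer.bos_id, tokenizer.eos_id, seed=seed,
        temperature=temperature, max_len=max_len, use_adapter=use_adapter,
    )
    smiles = [tokenizer.decode(ids) for ids in id_lists]
    valid = []
    for s in smiles:
        if not s:
            continue
        g = chem_graph.parse_smiles(s)
        if not isinstance(g, chem_graph.InvalidSmiles):
            valid.append(g.canonical_smiles)
    return SampleReport(
        n=n, n_valid=len(valid), n_unique_valid=len(set(valid)),
        smiles=smiles, valid_smiles=valid,
    )
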