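"""Character-level byte-pair-encoding tokenizer for SMILES.

The vocabulary starts from a fixed 72-symbol seed alphabet (SMILES atomic
symbol characters, ring-closure digits and structural punctuation) and is
grown with up to ``max_merges`` most-frequent adjacent-pair merges learned
from a corpus.  Multi-character element symbols such as ``Cl`` or ``Br``
start life as two characters and are acquired as merges — that is what
*character-level* BPE means, as opposed to byte-level or atom-regex
pre-tokenization.

Determinism: merge selection breaks frequency ties lexicographically on the
(left, right) token pair, so two trainings on the same corpus produce
identical merge tables.

The trained vocabulary serializes to the conventional two text artifacts:
a vocab file (one token per line; id = line number) and a merges file
(rank-ordered ``left right`` pairs).
"""

from __future__ import annotations

import collections
from pathlib import Path
from typing import Iterable, Sequence

__all__ = ["SEED_ALPHABET", "SPECIAL_TOKENS", "SmilesBpeTokenizer", "train_bpe"]

# 72 single characters: element-symbol characters (upper + lower case used by
# organic-subset and bracket atoms), digits for ring closures and isotopes,
# and SMILES structural punctuation.
SEED_ALPHABET = (
    list("ABCDEFGHIKLMNOPRSTUVWXYZ")  # 24 upper-case element letters
    + list("abcdefghiklmnoprstuvy")   # 21 lower-case (aromatic/element) letters
    + list("0123456789")              # 10 ring-closure / isotope digits
    + list("()[]=#/\\@+-.:%*$~")      # 17 structural symbols
)
assert len(SEED_ALPHABET) == 72, len(SEED_ALPHABET)

BOS, EOS, PAD, UNK = "<bos>", "<eos>", "<pad>", "<unk>"
SPECIAL_TOKENS = (PAD, BOS, EOS, UNK)


def _pair_counts(words: dict) -> collections.Counter:
    counts = collections.Counter()
    for symbols, freq in words.items():
        for a, b in zip(symbols, symbols[1:]):
            counts[(a, b)] += freq
    return counts


def _merge_word(symbols: tuple, pair: tuple, merged: str) -> tuple:
    out, i = [], 0
    while i < len(symbols):
        if i + 1 < len(symbols) and (symbols[i], symbols[i + 1]) == pair:
            out.append(merged)
            i += 2
        else:
            out.append(symbols[i])
            i += 1
    return tuple(out)


class SmilesBpeTokenizer:
    """BPE tokenizer with a fit/encode/decode surface.

    Parameters
    ----------
    max_merges:
        Upper bound on the number of learned merges (vocabulary grows to at
        most ``72 + max_merges + 4`` special tokens).
    """

    def __init__(self, max_merges: int = 1000):
        if max_merges < 0:
            raise ValueError("max_merges must be >= 0")
        self.max_merges = max_merges
        self.merges: list[tuple[str, str]] = []
        self.vocab: list[str] = []
        self.token_to_id: dict[str, int] = {}
        self._fitted = False

    # -- construction ------------------------------------------------------

    def fit(self, corpus: Sequence[str]) -> "SmilesBpeTokenizer":
        """Learn merges from a corpus of SMILES strings (one molecule each)."""
        corpus = [s.strip() for s in corpus if s and s.strip()]
        if not corpus:
            raise ValueError("empty training corpus")
        # seed alphabet first (stable ids), then characters observed outside it
        alphabet = list(SEED_ALPHABET)
        extra = sorted({c for s in corpus for c in s} - set(alphabet))
        alphabet += extra

        words = collections.Counter(tuple(s) for s in corpus)
        merges: list[tuple[str, str]] = []
        while len(merges) < self.max_merges:
            counts = _pair_counts(words)
            if not counts:
                break
            best_freq = max(counts.values())
            if best_freq < 2:  # nothing worth merging
                break
            pair = min(p for p, c in counts.items() if c == best_freq)
            merged = pair[0] + pair[1]
            merges.append(pair)
            words = collections.Counter(
                {_merge_word(w, pair, merged): f for w, f in words.items()}
            )

        self.merges = merges
        self.vocab = list(SPECIAL_TOKENS) + alphabet + [a + b for a, b in merges]
        self.token_to_id = {t: i for i, t in enumerate(self.vocab)}
        self._merge_rank = {pair: r for r, pair in enumerate(merges)}
        self._fitted = True
        return self

    # -- encoding ----------------------------------------------------------

    @property
    def vocab_size(self) -> int:
        return len(self.vocab)

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD]

    @property
    def bos_id(self) -> int:
        return self.token_to_id[BOS]

    @property
    def eos_id(self) -> int:
        return self.token_to_id[EOS]

    @property
    def unk_id(self) -> int:
        return self.token_to_id[UNK]

    def _check_fitted(self):
        if not self._fitted:
            raise RuntimeError("tokenizer is not fitted; call fit() or load()")

    def tokenize(self, text: str) -> list[str]:
        """Split into characters, then apply merges in rank order."""
        self._check_fitted()
        symbols = list(text)
        while len(symbols) > 1:
            ranked = [
                (self._merge_rank[(a, b)], i)
                for i, (a, b) in enumerate(zip(symbols, symbols[1:]))
                if (a, b) in self._merge_rank
            ]
            if not ranked:
                break
            rank, _ = min(ranked)
            pair = self.merges[rank]
            symbols = list(_merge_word(tuple(symbols), pair, pair[0] + pair[1]))
        return symbols

    def encode(self, text: str, add_specials: bool = True) -> list[int]:
        """Encode to ids: ``[BOS] + payload + [EOS]``; unknown chars -> UNK."""
        self._check_fitted()
        ids = [self.token_to_id.get(tok, self.unk_id) for tok in self.tokenize(text)]
        if add_specials:
            return [self.bos_id] + ids + [self.eos_id]
        return ids

    def decode(self, ids: Iterable[int]) -> str:
        """Concatenate token strings; BOS/EOS/PAD contribute nothing."""
        self._check_fitted()
        specials = {self.bos_id, self.eos_id, self.pad_id}
        out = []
        for i in ids:
            i = int(i)
            if i in specials:
                continue
            if not 0 <= i < len(self.vocab):
                raise KeyError(f"unknown token id {i}")
            out.append(self.vocab[i])
        return "".join(out)

    def encode_batch(self, texts: Sequence[str], max_len: int | None = None):
        """Encode many strings into a padded id matrix + mask (numpy)."""
        import numpy as np

        seqs = [self.encode(t) for t in texts]
        if max_len is not None:
            seqs = [s[:max_len] for s in seqs]
        width = max(len(s) for s in seqs)
        ids = np.full((len(seqs), width), self.pad_id, dtype=np.int64)
        for r, s in enumerate(seqs):
            ids[r, : len(s)] = s
        return ids, ids != self.pad_id

    # -- serialization -----------------------------------------------------

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        (d / "vocab.txt").write_text("\n".join(self.vocab) + "\n")
        (d / "merges.txt").write_text(
            "\n".join(f"{a} {b}" for a, b in self.merges) + "\n"
        )

    @classmethod
    def load(cls, directory) -> "SmilesBpeTokenizer":
        d = Path(directory)
        vocab = (d / "vocab.txt").read_text().splitlines()
        merges = [
            tuple(line.split(" ", 1))
            for line in (d / "merges.txt").read_text().splitlines()
            if line
        ]
        tok = cls(max_merges=len(merges))
        tok.vocab = vocab
        tok.merges = merges
        tok.token_to_id = {t: i for i, t in enumerate(vocab)}
        tok._merge_rank = {pair: r for r, pair in enumerate(merges)}
        tok._fitted = True
        return tok


def train_bpe(corpus: Sequence[str], max_merges: int = 1000) -> SmilesBpeTokenizer:
    """Functional wrapper: train a tokenizer on a SMILES corpus."""
    return SmilesBpeTokenizer(max_merges=max_merges).fit(corpus)
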