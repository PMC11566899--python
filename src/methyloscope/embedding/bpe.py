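"""Byte-pair-encoding subword tokenizer for nucleotide sequences.

Vocabulary learning starts from the single bases present in the corpus and
repeatedly merges the most frequent adjacent token pair into a new token
until the requested vocabulary size is reached or no pair occurs at least
twice.  Ties are broken toward the lexicographically smallest (left, right)
pair for cross-platform determinism.  Tokenization applies the recorded
merges in order (lowest merge rank first), which makes segmentation lossless:
concatenating the tokens always reproduces the input.
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from methyloscope.errors import ConfigError, ValidationError


@dataclass
class TokenizerModel:
    vocab: list[str]
    merges: list[tuple[str, str]]

    @property
    def vocab_size(self) -> int:
        return len(self.vocab)

    def token_to_id(self) -> dict[str, int]:
        return {tok: i for i, tok in enumerate(self.vocab)}

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"vocab": self.vocab, "merges": [list(m) for m in self.merges]},
                fh,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "TokenizerModel":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            vocab=list(data["vocab"]),
            merges=[tuple(m) for m in data["merges"]],
        )

    def tokenize(self, sequence: str, label: str = "<sequence>") -> list[str]:
        """Segment one sequence by applying merges in recorded rank order."""
        alphabet = {t for t in self.vocab if len(t) == 1}
        bad = set(sequence) - alphabet
        if bad:
            raise ValidationError(
                f"sequence {label}: characters {sorted(bad)} outside tokenizer alphabet"
            )
        ranks = {pair: r for r, pair in enumerate(self.merges)}
        tokens = list(sequence)
        while len(tokens) > 1:
            best_rank = None
            for pair in zip(tokens, tokens[1:]):
                r = ranks.get(pair)
                if r is not None and (best_rank is None or r < best_rank):
                    best_rank = r
            if best_rank is None:
                break
            left, right = self.merges[best_rank]
            tokens = _merge_occurrences(tokens, left, right)
        return tokens

    def encode(self, sequence: str, label: str = "<sequence>") -> list[int]:
        t2i = self.token_to_id()
        return [t2i[t] for t in self.tokenize(sequence, label)]


@dataclass(frozen=True)
class TokenizedCgi:
    cgi_id: str
    tokens: list[int]

    @property
    def n_tokens(self) -> int:
        return len(self.tokens)


def _merge_occurrences(tokens: list[str], left: str, right: str) -> list[str]:
    """Left-to-right merge of every (left, right) adjacency (non-overlapping)."""
    out: list[str] = []
    i = 0
    while i < len(tokens):
        if i + 1 < len(tokens) and tokens[i] == left and tokens[i + 1] == right:
            out.append(left + right)
            i += 2
        else:
            out.append(tokens[i])
            i += 1
    return out


def _pair_counts(tokens: list[str]) -> Counter:
    return Counter(zip(tokens, tokens[1:]))


def train_bpe(
    sequences: Sequence[str],
    vocab_size: int = 8192,
    min_pair_count: int = 2,
    seed: int | None = None,
) -> TokenizerModel:
    """Learn a merge table over the corpus (deterministic; ``seed`` unused).

    Stops when ``vocab_size`` entries exist or the most frequent adjacent
    pair occurs fewer than ``min_pair_count`` times.
    """
    sequences = [s for s in sequences if s]
    if not sequences:
        raise ConfigError("empty corpus")
    alphabet = sorted(set().union(*map(set, sequences)))
    if vocab_size < len(alphabet):
        raise ConfigError(
            f"vocab_size {vocab_size} smaller than alphabet size {len(alphabet)}"
        )
    vocab: list[str] = list(alphabet)
    merges: list[tuple[str, str]] = []
    corpus: list[list[str]] = [list(s) for s in sequences]
    counts: Counter = Counter()
    where: dict[tuple[str, str], set[int]] = defaultdict(set)
    for si, toks in enumerate(corpus):
        for pair, c in _pair_counts(toks).items():
            counts[pair] += c
            where[pair].add(si)

    while len(vocab) < vocab_size and counts:
        best_count = max(counts.values())
        if best_count < min_pair_count:
            break
        best = min(pair for pair, c in counts.items() if c == best_count)
        left, right = best
        vocab.append(left + right)
        merges.append(best)
        for si in sorted(where[best]):
            old = corpus[si]
            new = _merge_occurrences(old, left, right)
            for pair, c in _pair_counts(old).items():
                counts[pair] -= c
                if counts[pair] <= 0:
                    del counts[pair]
                where[pair].discard(si)
            for pair, c in _pair_counts(new).items():
                counts[pair] += c
                where[pair].add(si)
            corpus[si] = new
    return TokenizerModel(vocab=vocab, merges=merges)


def tokenize_and_filter(
    sequences: Mapping[str, str],
    tokenizer: TokenizerModel,
    max_tokens: int = 512,
) -> tuple[list[TokenizedCgi], list[str]]:
    """Tokenize each sequence; drop those yielding more than ``max_tokens``.

    Sequences tokenizing to exactly ``max_tokens`` are retained (the cutoff
    is strict 'more than').  Returns (kept, dropped ids).
    """
    kept: list[TokenizedCgi] = []
    dropped: list[str] = []
    t2i = tokenizer.token_to_id()
    for cgi_id in sequences:
        toks = tokenizer.tokenize(sequences[cgi_id], label=cgi_id)
        if len(toks) > max_tokens:
            dropped.append(cgi_id)
        else:
            kept.append(TokenizedCgi(cgi_id=cgi_id, tokens=[t2i[t] for t in toks]))
    return kept, dropped
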