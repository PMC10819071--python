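"""Frequent-consecutive-subsequence vocabulary mining and SMILES segmentation.

The miner is frequency-thresholded iterative adjacent-pair merging (BPE
over chemically atomic units): multi-character SMILES atoms — ``Cl``,
``Br``, bracket atoms and ``%nn`` ring closures — are pre-grouped so a
mined token never splits an element symbol. Decoding is greedy
left-to-right longest match, which is lossless by construction because
every single character seen in the corpus stays in the vocabulary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

#: chemically atomic units that must never be split by a token boundary
_UNIT_RE = re.compile(r"\[[^\]]*\]|Cl|Br|%\d\d|.")


class VocabularyError(ValueError):
    pass


class TokenizationError(ValueError):
    pass


def split_units(smiles: str) -> list[str]:
    """Split a SMILES string into atomic units (never-split substrings)."""
    return _UNIT_RE.findall(smiles)


@dataclass
class FCSVocabulary:
    """Ordered token → corpus frequency map over vocabulary C."""

    tokens: dict[str, int]
    min_freq: int
    max_token_len: int
    _max_len: int = field(init=False, repr=False)

    def __post_init__(self):
        self._max_len = max((len(t) for t in self.tokens), default=0)

    def __contains__(self, token: str) -> bool:
        return token in self.tokens

    def __len__(self) -> int:
        return len(self.tokens)

    def index(self) -> dict[str, int]:
        """Stable token → integer id map (insertion order)."""
        return {tok: i for i, tok in enumerate(self.tokens)}

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"#min_freq={self.min_freq}\tmax_token_len={self.max_token_len}\n")
            for tok, freq in self.tokens.items():
                fh.write(f"{tok}\t{freq}\n")

    @classmethod
    def load(cls, path: str | Path) -> "FCSVocabulary":
        tokens: dict[str, int] = {}
        min_freq, max_token_len = 1, 1
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    meta = dict(kv.split("=") for kv in line[1:].split("\t"))
                    min_freq = int(meta.get("min_freq", 1))
                    max_token_len = int(meta.get("max_token_len", 1))
                    continue
                tok, freq = line.rsplit("\t", 1)
                tokens[tok] = int(freq)
        return cls(tokens=tokens, min_freq=min_freq, max_token_len=max_token_len)


@dataclass
class TokenSequence:
    """Lossless segmentation D = d_1…d_q of a SMILES string."""

    tokens: list[str]
    source: str

    def __post_init__(self):
        if "".join(self.tokens) != self.source:
            raise TokenizationError(
                f"segmentation is not lossless: {self.tokens!r} != {self.source!r}"
            )

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)


def _count_pairs(sequences: list[list[str]]) -> dict[tuple[str, str], int]:
    counts: dict[tuple[str, str], int] = {}
    for seq in sequences:
        for a, b in zip(seq, seq[1:]):
            counts[(a, b)] = counts.get((a, b), 0) + 1
    return counts


def _merge_pair(seq: list[str], pair: tuple[str, str], merged: str) -> list[str]:
    out: list[str] = []
    i = 0
    while i < len(seq):
        if i + 1 < len(seq) and seq[i] == pair[0] and seq[i + 1] == pair[1]:
            out.append(merged)
            i += 2
        else:
            out.append(seq[i])
            i += 1
    return out


def mine_vocabulary(
    corpus: Sequence[str],
    min_freq: int = 5,
    max_token_len: int = 8,
    max_vocab: int = 1024,
) -> FCSVocabulary:
    """Mine a subsequence vocabulary from a SMILES corpus.

    Starts from single characters (always kept, so any string over the
    corpus alphabet remains segmentable) plus atomic units, then repeatedly
    merges the most frequent adjacent token pair whose joint frequency is
    at least ``min_freq`` and merged length at most ``max_token_len``,
    until ``max_vocab`` entries exist or no pair qualifies. Ties break
    lexicographically on the merged string, making mining deterministic.
    """
    corpus = [s for s in corpus if s]
    if not corpus:
        raise VocabularyError("cannot mine a vocabulary from an empty corpus")

    tokens: dict[str, int] = {}
    for smiles in corpus:  # single-character base alphabet
        for ch in smiles:
            tokens[ch] = tokens.get(ch, 0) + 1

    sequences = [split_units(s) for s in corpus]
    unit_counts: dict[str, int] = {}
    for seq in sequences:
        for u in seq:
            unit_counts[u] = unit_counts.get(u, 0) + 1
    for unit in sorted(unit_counts):  # multi-char atoms are base tokens, not mined merges
        if unit not in tokens:
            tokens[unit] = unit_counts[unit]

    while len(tokens) < max_vocab:
        counts = _count_pairs(sequences)
        candidates = [
            (pair, n)
            for pair, n in counts.items()
            if n >= min_freq and len(pair[0]) + len(pair[1]) <= max_token_len
        ]
        if not candidates:
            break
        # highest frequency first, then lexicographically smallest merged string
        pair, n = min(candidates, key=lambda kv: (-kv[1], kv[0][0] + kv[0][1]))
        merged = pair[0] + pair[1]
        sequences = [_merge_pair(seq, pair, merged) for seq in sequences]
        if merged not in tokens:
            tokens[merged] = n
        else:
            tokens[merged] = max(tokens[merged], n)

    return FCSVocabulary(tokens=tokens, min_freq=min_freq, max_token_len=max_token_len)


def tokenize(smiles: str, vocab: FCSVocabulary) -> TokenSequence:
    """Segment a SMILES string by greedy left-to-right longest match.

    Matches are aligned to atomic-unit boundaries; if a whole unit is
    absent from the vocabulary (e.g. an unseen bracket atom) it falls back
    to its single characters, and a character missing from the vocabulary
    raises :class:`TokenizationError`.
    """
    units = split_units(smiles)
    out: list[str] = []
    i = 0
    max_len = max(vocab._max_len, 1)
    while i < len(units):
        best: str | None = None
        best_j = i
        candidate = ""
        for j in range(i, len(units)):
            candidate += units[j]
            if len(candidate) > max_len:
                break
            if candidate in vocab:
                best, best_j = candidate, j
        if best is not None:
            out.append(best)
            i = best_j + 1
        else:
            for ch in units[i]:  # per-character fallback inside an unknown unit
                if ch not in vocab:
                    raise TokenizationError(
                        f"character {ch!r} of {smiles!r} is not in the vocabulary"
                    )
                out.append(ch)
            i += 1
    return TokenSequence(tokens=out, source=smiles)
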