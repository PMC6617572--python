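"""Character-level tokenization and fixed-length one-hot encoding.

SMILES strings and amino-acid sequences enter the end-to-end channels as
low-level representations: each character becomes a one-hot row of an
``L x V`` binary matrix, where ``L`` is a fixed length (sequences longer
than ``L`` are truncated from the end, shorter ones are zero-padded at the
end) and ``V`` is the size of a character vocabulary extracted from the
dataset itself.

SMILES is case-sensitive (aromatic ``c`` vs. aliphatic ``C``); amino-acid
sequences are upper-cased before tokenization by the callers in
:mod:`mcpinn.dataset`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "TokenVocabulary",
    "EncodedSequence",
    "build_vocabulary",
    "encode",
    "encode_indices",
    "decode",
    "read_fasta",
    "read_compound_table",
]


class UnknownTokenError(KeyError):
    """A character of the input sequence is not in the vocabulary."""

    def __init__(self, char: str, position: int):
        self.char = char
        self.position = position
        super().__init__(f"unknown token {char!r} at position {position}")


@dataclass(frozen=True)
class TokenVocabulary:
    """Bijective character -> index map over one sequence alphabet.

    Indices are contiguous ``0..V-1`` and stable under serialization
    round-trip; ordering is lexicographic by character code so that the
    same corpus always yields the same vocabulary.
    """

    tokens: tuple[str, ...]
    index_of: dict[str, int] = field(repr=False)

    def __post_init__(self):
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("duplicate characters in vocabulary")

    @property
    def size(self) -> int:
        return len(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, char: str) -> bool:
        return char in self.index_of

    @classmethod
    def from_tokens(cls, tokens: Sequence[str]) -> "TokenVocabulary":
        tokens = tuple(tokens)
        return cls(tokens=tokens, index_of={c: i for i, c in enumerate(tokens)})

    def save(self, path: str | Path) -> None:
        """One character per line; the line number is the index."""
        Path(path).write_text("".join(c + "\n" for c in self.tokens))

    @classmethod
    def load(cls, path: str | Path) -> "TokenVocabulary":
        lines = Path(path).read_text().splitlines()
        return cls.from_tokens([ln for ln in lines])


@dataclass
class EncodedSequence:
    """Fixed-length one-hot encoding of a character sequence.

    ``matrix`` is ``L x V`` binary; rows past ``min(source_length, L)``
    are all-zero (padding has no dedicated token).
    """

    matrix: np.ndarray
    source_length: int

    @property
    def fixed_length(self) -> int:
        return self.matrix.shape[0]

    @property
    def encoded_length(self) -> int:
        return min(self.source_length, self.matrix.shape[0])


def build_vocabulary(sequences: Iterable[str]) -> TokenVocabulary:
    """Extract the distinct characters of a corpus, sorted lexicographically.

    Deterministic, idempotent and order-insensitive in the input list.
    Raises ``ValueError`` on an empty corpus.
    """
    chars: set[str] = set()
    n = 0
    for seq in sequences:
        n += 1
        chars.update(seq)
    if n == 0 or not chars:
        raise ValueError("empty corpus")
    return TokenVocabulary.from_tokens(sorted(chars))


def encode(sequence: str, vocab: TokenVocabulary, fixed_length: int) -> EncodedSequence:
    """One-hot encode with post truncation / zero-padding at the end."""
    if fixed_length < 1:
        raise ValueError("fixed_length must be >= 1")
    kept = sequence[:fixed_length]
    matrix = np.zeros((fixed_length, vocab.size), dtype=np.uint8)
    for i, ch in enumerate(kept):
        try:
            matrix[i, vocab.index_of[ch]] = 1
        except KeyError:
            raise UnknownTokenError(ch, i) from None
    return EncodedSequence(matrix=matrix, source_length=len(sequence))


def encode_indices(sequence: str, vocab: TokenVocabulary, fixed_length: int) -> np.ndarray:
    """Integer-index form of :func:`encode`: pad positions get index ``V``.

    The extra index ``V`` maps to the all-zero one-hot row; embedding layers
    reserve a frozen zero row for it so both forms are equivalent inputs.
    """
    kept = sequence[:fixed_length]
    out = np.full(fixed_length, vocab.size, dtype=np.int64)
    for i, ch in enumerate(kept):
        try:
            out[i] = vocab.index_of[ch]
        except KeyError:
            raise UnknownTokenError(ch, i) from None
    return out


def decode(encoded: EncodedSequence, vocab: TokenVocabulary) -> str:
    """Invert :func:`encode` over the non-padding rows."""
    out = []
    for row in encoded.matrix:
        nz = np.flatnonzero(row)
        if nz.size == 0:
            break
        out.append(vocab.tokens[int(nz[0])])
    return "".join(out)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Protein id -> upper-cased amino-acid sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_compound_table(path: str | Path, sep: str = "\t") -> dict[str, str]:
    """Compound id -> SMILES from a delimited table with a header row."""
    import pandas as pd

    df = pd.read_csv(path, sep=sep, dtype=str)
    cols = {c.lower(): c for c in df.columns}
    try:
        cid, smi = cols["compound_id"], cols["smiles"]
    except KeyError:
        raise ValueError("compound table needs compound_id and SMILES columns")
    return dict(zip(df[cid], df[smi]))
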