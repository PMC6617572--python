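"""Word-level (high-level) representations of compounds and proteins.

Molecules and proteins are treated as sentences: the words are Morgan
substructure identifiers for compounds and overlapping-shift amino-acid
N-grams for proteins.  Words are embedded with a skip-gram model and a
sentence is reduced to a single d-vector by one of three aggregation
operators,

    S_sum   = sum_i w_i
    S_mean  = (1/N) sum_i w_i
    S_tfidf = sum_i t_{w_i} w_i

where ``w_i`` is the embedding of the i-th word, ``N`` the sentence length
and ``t_w`` the word's TF-IDF weight.  The TF-IDF variant uses the smoothed
idf ``ln((1 + n_docs) / (1 + df)) + 1`` with raw in-sentence term counts and
no vector normalization (a plain weighted sum); iterating occurrences with
per-occurrence weight ``idf(w)`` folds the term frequency in exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SentenceOfWords",
    "EmbeddingTable",
    "TfIdfModel",
    "protein_to_words",
    "compound_to_words",
    "aggregate_sentence",
    "fit_tfidf",
    "train_word_embeddings",
]


@dataclass
class SentenceOfWords:
    """Ordered list of word identifiers for one molecule or protein."""

    words: list[str]

    @property
    def n(self) -> int:
        return len(self.words)

    def __iter__(self):
        return iter(self.words)

    def __len__(self):
        return len(self.words)


@dataclass
class EmbeddingTable:
    """word -> d-vector map with an out-of-vocabulary policy.

    ``oov_policy='zero'`` returns the all-zero d-vector for missing words
    (the behaviour used when an entity has no sequence at all);
    ``'error'`` raises ``KeyError`` for strict pipelines.
    """

    dimension: int
    vectors: dict[str, np.ndarray] = field(repr=False)
    oov_policy: str = "zero"

    def __post_init__(self):
        if self.oov_policy not in ("zero", "error"):
            raise ValueError("oov_policy must be 'zero' or 'error'")

    def __contains__(self, word: str) -> bool:
        return word in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)

    def lookup(self, word: str) -> np.ndarray:
        vec = self.vectors.get(word)
        if vec is None:
            if self.oov_policy == "zero":
                return np.zeros(self.dimension)
            raise KeyError(f"word {word!r} not in embedding table")
        return vec

    def save(self, path: str | Path) -> None:
        """word2vec text format: header ``n_words d``, then word + d floats."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.vectors)} {self.dimension}\n")
            for word, vec in self.vectors.items():
                fh.write(word + " " + " ".join(repr(float(x)) for x in vec) + "\n")

    @classmethod
    def load(cls, path: str | Path, oov_policy: str = "zero") -> "EmbeddingTable":
        with open(path) as fh:
            header = fh.readline().split()
            n, d = int(header[0]), int(header[1])
            vectors: dict[str, np.ndarray] = {}
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                vectors[parts[0]] = np.array([float(x) for x in parts[1 : d + 1]])
        if len(vectors) != n:
            raise ValueError(f"header claims {n} words, file has {len(vectors)}")
        return cls(dimension=d, vectors=vectors, oov_policy=oov_policy)


def protein_to_words(aa_sequence: str, n: int = 3) -> SentenceOfWords:
    """Split an amino-acid sequence into shifted non-overlapping N-grams.

    For shifts ``0..n-1`` the sequence is cut into consecutive length-n
    words, dropping the trailing remainder; the sentence is the
    concatenation of the n shifted word lists, so every length-n window
    of the sequence appears exactly once.
    """
    if n < 1:
        raise ValueError("word size must be >= 1")
    if len(aa_sequence) < n:
        raise ValueError("sequence shorter than word size")
    words: list[str] = []
    for shift in range(n):
        for start in range(shift, len(aa_sequence) - n + 1, n):
            words.append(aa_sequence[start : start + n])
    return SentenceOfWords(words)


def compound_to_words(smiles: str, radii: Iterable[int] = (0, 1)) -> SentenceOfWords:
    """Morgan substructure identifiers of a molecule, as words.

    One word per heavy atom and per radius (default radii {0, 1}), atoms in
    canonical order and radius-0 before radius-1 within an atom.  Words are
    the (unhashed) Morgan environment invariants rendered as decimal strings.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    radii = sorted(set(int(r) for r in radii))
    if not radii or radii[0] < 0:
        raise ValueError("radii must be non-negative integers")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=max(radii))
    ao = rdFingerprintGenerator.AdditionalOutput()
    ao.AllocateBitInfoMap()
    gen.GetSparseCountFingerprint(mol, additionalOutput=ao)
    per_atom: dict[tuple[int, int], int] = {}
    for bit_id, envs in ao.GetBitInfoMap().items():
        for atom_idx, radius in envs:
            per_atom[(atom_idx, radius)] = bit_id
    words = [
        str(per_atom[(a, r)])
        for a in range(mol.GetNumAtoms())
        for r in radii
        if (a, r) in per_atom
    ]
    return SentenceOfWords(words)


@dataclass
class TfIdfModel:
    """Smoothed inverse-document-frequency weights fitted on a corpus."""

    n_documents: int
    document_frequency: dict[str, int] = field(repr=False)

    def idf(self, word: str) -> float:
        df = self.document_frequency.get(word, 0)
        return math.log((1 + self.n_documents) / (1 + df)) + 1.0

    def weight(self, word: str, sentence: SentenceOfWords) -> float:
        """t_w = raw in-sentence term count x idf."""
        return sentence.words.count(word) * self.idf(word)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# n_documents\t{self.n_documents}\n")
            fh.write("word\tdocument_frequency\tidf\n")
            for word, df in sorted(self.document_frequency.items()):
                fh.write(f"{word}\t{df}\t{self.idf(word)!r}\n")

    @classmethod
    def load(cls, path: str | Path) -> "TfIdfModel":
        with open(path) as fh:
            n_docs = int(fh.readline().split("\t")[1])
            fh.readline()
            df = {}
            for line in fh:
                word, count, _ = line.rstrip("\n").split("\t")
                df[word] = int(count)
        return cls(n_documents=n_docs, document_frequency=df)


def fit_tfidf(documents: Sequence[SentenceOfWords]) -> TfIdfModel:
    """Fit document frequencies; idf(w) = ln((1+n)/(1+df(w))) + 1."""
    documents = [d for d in documents]
    if not documents or all(len(d) == 0 for d in documents):
        raise ValueError("empty corpus")
    df: dict[str, int] = {}
    for doc in documents:
        for word in set(doc.words):
            df[word] = df.get(word, 0) + 1
    return TfIdfModel(n_documents=len(documents), document_frequency=df)


def aggregate_sentence(
    sentence: SentenceOfWords,
    table: EmbeddingTable,
    scheme: str = "sum",
    tfidf: TfIdfModel | None = None,
    normalize: bool = False,
) -> np.ndarray:
    """Reduce a sentence to one d-vector by sum, mean or TF-IDF weighted sum.

    ``normalize=True`` divides the TF-IDF sum by the total weight, turning
    the weighted sum into a weighted average; the default follows the plain
    weighted-sum formula.
    """
    if scheme not in ("sum", "mean", "tfidf"):
        raise ValueError(f"unknown aggregation scheme {scheme!r}")
    if len(sentence) == 0:
        raise ValueError("cannot aggregate an empty sentence")
    if scheme == "tfidf" and tfidf is None:
        raise ValueError("tfidf scheme requires a fitted TfIdfModel")

    out = np.zeros(table.dimension)
    total_weight = 0.0
    for word in sentence:
        w = tfidf.idf(word) if scheme == "tfidf" else 1.0
        out += w * table.lookup(word)
        total_weight += w
    if scheme == "mean":
        out /= len(sentence)
    elif scheme == "tfidf" and normalize and total_weight > 0:
        out /= total_weight
    return out


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def train_word_embeddings(
    corpus: Sequence[SentenceOfWords],
    d: int = 300,
    window: int = 35,
    min_count: int = 2,
    seed: int = 0,
    epochs: int = 5,
    negative: int = 5,
    learning_rate: float = 0.025,
) -> EmbeddingTable:
    """Skip-gram embeddings with negative sampling, trained in-process.

    Words below ``min_count`` corpus frequency are dropped from the table
    (their lookup then follows the table's out-of-vocabulary policy).
    Deterministic for a fixed seed: the word order, the dynamic-window
    draws and the negative samples all derive from one seeded generator.
    """
    if d <= 0:
        raise ValueError("embedding dimension must be positive")
    if window <= 0:
        raise ValueError("window size must be positive")
    corpus = [s for s in corpus]
    if not corpus:
        raise ValueError("empty corpus")

    counts: dict[str, int] = {}
    for sent in corpus:
        for w in sent:
            counts[w] = counts.get(w, 0) + 1
    vocab = sorted((w for w, c in counts.items() if c >= min_count),
                   key=lambda w: (-counts[w], w))
    if not vocab:
        return EmbeddingTable(dimension=d, vectors={})
    index = {w: i for i, w in enumerate(vocab)}
    V = len(vocab)

    rng = np.random.default_rng(seed)
    w_in = (rng.random((V, d)) - 0.5) / d
    w_out = np.zeros((V, d))

    # unigram^0.75 negative-sampling distribution
    freq = np.array([counts[w] for w in vocab], dtype=float) ** 0.75
    neg_p = freq / freq.sum()

    sent_idx = [np.array([index[w] for w in s if w in index], dtype=np.int64)
                for s in corpus]
    sent_idx = [s for s in sent_idx if s.size >= 2]

    # pair updates are applied in small chunks (not one sentence-sized batch)
    # with a linearly decaying step, keeping the accumulated per-word step
    # bounded — one big batched update at full rate can diverge
    chunk = 512
    min_rate = learning_rate / 50.0
    for epoch in range(epochs):
        frac = epoch / max(1, epochs)
        rate = learning_rate * (1.0 - frac) + min_rate * frac
        for ids in sent_idx:
            n = ids.size
            b = rng.integers(1, window + 1, size=n)
            centers, contexts = [], []
            for i in range(n):
                lo, hi = max(0, i - b[i]), min(n, i + b[i] + 1)
                for j in range(lo, hi):
                    if j != i:
                        centers.append(ids[i])
                        contexts.append(ids[j])
            if not centers:
                continue
            c_all = np.asarray(centers)
            o_all = np.asarray(contexts)
            for start in range(0, c_all.size, chunk):
                c = c_all[start : start + chunk]
                o = o_all[start : start + chunk]
                negs = rng.choice(V, size=(c.size, negative), p=neg_p)

                vc = w_in[c]                                  # (P, d)
                uo = w_out[o]                                 # (P, d)
                un = w_out[negs]                              # (P, K, d)
                g_pos = _sigmoid(np.einsum("pd,pd->p", vc, uo)) - 1.0
                g_neg = _sigmoid(np.einsum("pd,pkd->pk", vc, un))

                grad_vc = g_pos[:, None] * uo + np.einsum("pk,pkd->pd", g_neg, un)
                # clip elementwise steps: repeated hits on a frequent word
                # within one chunk must not compound into a blow-up
                np.add.at(w_in, c, np.clip(-rate * grad_vc, -0.05, 0.05))
                np.add.at(w_out, o, np.clip(-rate * g_pos[:, None] * vc, -0.05, 0.05))
                np.add.at(
                    w_out,
                    negs.ravel(),
                    np.clip((-rate * g_neg[..., None] * vc[:, None, :]).reshape(-1, d),
                            -0.05, 0.05),
                )

    return EmbeddingTable(dimension=d, vectors={w: w_in[index[w]].copy() for w in vocab})
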