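"""CPI dataset container and per-channel featurization.

A :class:`CPIDataset` holds the compound and protein entities, the labelled
pairs, named train/validation/test splits, and one *feature view* per
channel — a per-pair array ready to feed the matching PINN channel:

======================  ===============================================
view name               contents per pair
======================  ===============================================
``ecfp``                1024-bit ECFP4 fingerprint of the compound
``mol2vec``             aggregated Morgan-substructure sentence vector
``protvec``             aggregated amino-acid N-gram sentence vector
``smiles``              fixed-length token indices of the SMILES string
``aa``                  fixed-length token indices of the AA sequence
======================  ===============================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import encoding
from .embedding import (
    EmbeddingTable,
    TfIdfModel,
    aggregate_sentence,
    compound_to_words,
    fit_tfidf,
    protein_to_words,
    train_word_embeddings,
)

__all__ = ["CPIDataset", "ecfp_fingerprints", "build_views"]

COMPOUND_CHANNELS = ("smiles", "ecfp", "mol2vec")
PROTEIN_CHANNELS = ("aa", "protvec")


def ecfp_fingerprints(smiles_list: list[str], n_bits: int = 1024) -> np.ndarray:
    """ECFP4 (Morgan radius 2) binary fingerprints, one row per molecule."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
    out = np.zeros((len(smiles_list), n_bits), dtype=np.float64)
    for i, smi in enumerate(smiles_list):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smi!r}")
        out[i] = gen.GetFingerprintAsNumPy(mol)
    return out


@dataclass
class CPIDataset:
    """Compound/protein entities, pair labels, feature views and splits."""

    compounds: dict[str, str]                    # id -> SMILES
    proteins: dict[str, str]                     # id -> AA sequence
    pairs: pd.DataFrame                          # compound_id, protein_id, label
    views: dict[str, np.ndarray] = field(default_factory=dict)
    splits: dict[str, np.ndarray] = field(default_factory=dict)
    vocabularies: dict[str, encoding.TokenVocabulary] = field(default_factory=dict)

    def __post_init__(self):
        required = {"compound_id", "protein_id", "label"}
        if not required.issubset(self.pairs.columns):
            raise ValueError(f"pair table needs columns {sorted(required)}")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def labels(self) -> np.ndarray:
        return self.pairs["label"].to_numpy(dtype=np.int64)

    def split_labels(self, split: str) -> np.ndarray:
        return self.labels[self.splits[split]]

    def inputs(self, channels: list[str], split: str | None = None,
               rows: np.ndarray | None = None) -> list[np.ndarray]:
        """Per-channel input arrays in the given channel order."""
        if rows is None:
            rows = self.splits[split] if split is not None else np.arange(self.n_pairs)
        out = []
        for name in channels:
            if name not in self.views:
                raise KeyError(f"view {name!r} not built; have {sorted(self.views)}")
            out.append(self.views[name][rows])
        return out

    def make_splits(self, seed: int, fractions: tuple[float, float, float] = (0.7, 0.15, 0.15)) -> None:
        """Random stratified train/valid/test split over pairs."""
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        rng = np.random.default_rng(seed)
        y = self.labels
        train, valid, test = [], [], []
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            n1 = int(round(fractions[0] * idx.size))
            n2 = n1 + int(round(fractions[1] * idx.size))
            train.append(idx[:n1]); valid.append(idx[n1:n2]); test.append(idx[n2:])
        self.splits = {
            "train": np.sort(np.concatenate(train)),
            "valid": np.sort(np.concatenate(valid)),
            "test": np.sort(np.concatenate(test)),
        }


def build_views(
    dataset: CPIDataset,
    channels: list[str],
    smiles_fixed_length: int = 100,
    protein_fixed_length: int = 700,
    embedding_dim: int = 300,
    embedding_window: int = 35,
    embedding_min_count: int = 2,
    embedding_epochs: int = 5,
    ngram: int = 3,
    morgan_radii: tuple[int, ...] = (0, 1),
    aggregation: str = "mean",
    protein_aggregation: str | None = None,
    compound_table: EmbeddingTable | None = None,
    protein_table: EmbeddingTable | None = None,
    seed: int = 0,
) -> CPIDataset:
    """Compute the requested feature views in place and return the dataset.

    Word-embedding tables are trained on the dataset's own sentences unless
    pretrained tables are passed in; the TF-IDF corpus is likewise the
    dataset itself.  ``protein_aggregation`` defaults to ``aggregation``.
    """
    protein_aggregation = protein_aggregation or aggregation
    cids = list(dataset.compounds)
    pids = list(dataset.proteins)
    c_index = {c: i for i, c in enumerate(cids)}
    p_index = {p: i for i, p in enumerate(pids)}
    c_rows = dataset.pairs["compound_id"].map(c_index).to_numpy()
    p_rows = dataset.pairs["protein_id"].map(p_index).to_numpy()

    for name in channels:
        if name in dataset.views:
            continue
        if name == "ecfp":
            per_entity = ecfp_fingerprints([dataset.compounds[c] for c in cids])
            dataset.views[name] = per_entity[c_rows]
        elif name == "smiles":
            vocab = dataset.vocabularies.get("smiles") or encoding.build_vocabulary(
                dataset.compounds.values())
            dataset.vocabularies["smiles"] = vocab
            per_entity = np.stack([
                encoding.encode_indices(dataset.compounds[c], vocab, smiles_fixed_length)
                for c in cids])
            dataset.views[name] = per_entity[c_rows]
        elif name == "aa":
            vocab = dataset.vocabularies.get("aa") or encoding.build_vocabulary(
                s.upper() for s in dataset.proteins.values())
            dataset.vocabularies["aa"] = vocab
            per_entity = np.stack([
                encoding.encode_indices(dataset.proteins[p].upper(), vocab, protein_fixed_length)
                for p in pids])
            dataset.views[name] = per_entity[p_rows]
        elif name == "mol2vec":
            sentences = [compound_to_words(dataset.compounds[c], morgan_radii) for c in cids]
            table = compound_table or train_word_embeddings(
                sentences, d=embedding_dim, window=embedding_window,
                min_count=embedding_min_count, seed=seed, epochs=embedding_epochs)
            tfidf = fit_tfidf(sentences) if aggregation == "tfidf" else None
            per_entity = np.stack([
                aggregate_sentence(s, table, aggregation, tfidf) for s in sentences])
            dataset.views[name] = per_entity[c_rows]
        elif name == "protvec":
            sentences = [protein_to_words(dataset.proteins[p].upper(), ngram) for p in pids]
            table = protein_table or train_word_embeddings(
                sentences, d=embedding_dim, window=embedding_window,
                min_count=embedding_min_count, seed=seed + 1, epochs=embedding_epochs)
            tfidf = fit_tfidf(sentences) if protein_aggregation == "tfidf" else None
            per_entity = np.stack([
                aggregate_sentence(s, table, protein_aggregation, tfidf) for s in sentences])
            dataset.views[name] = per_entity[p_rows]
        else:
            raise KeyError(f"unknown channel {name!r}")
    return dataset
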