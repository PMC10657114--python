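"""Sequence tokenisation and per-corpus CBOW embedding tables.

A nucleotide sequence is split left-to-right into non-overlapping
3-nucleotide words; a trailing remainder of 1 or 2 nucleotides is kept as
its own word.  One CBOW model is fitted per corpus (miRNA and target-site
sentences are never mixed), always on training-split records only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence, TYPE_CHECKING

import numpy as np

from .word2vec import CbowParams, fit_cbow

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic_data import DuplexRecord

__all__ = [
    "Origin",
    "ALPHABET",
    "normalize_sequence",
    "tokenize_sequence",
    "Corpus",
    "EmbeddingTable",
    "build_corpora",
    "train_cbow",
    "embed_tokens",
]

ALPHABET = frozenset("ACGTU")


class Origin(str, Enum):
    MIRNA = "MIRNA"
    MRNA = "MRNA"


class InvalidSequenceError(ValueError):
    """Raised for empty sequences or characters outside {A, C, G, T, U}."""


def normalize_sequence(sequence: str) -> str:
    """Uppercase and validate a nucleotide sequence.

    T and U are both accepted and deliberately NOT unified: miRNA and mRNA
    vocabularies live in separate embedding tables and never mix.
    """
    if not isinstance(sequence, str):
        raise InvalidSequenceError(f"sequence must be a string, got {type(sequence).__name__}")
    seq = sequence.upper()
    if len(seq) == 0:
        raise InvalidSequenceError("sequence is empty")
    for pos, char in enumerate(seq):
        if char not in ALPHABET:
            raise InvalidSequenceError(
                f"invalid character {char!r} at position {pos} (alphabet is A/C/G/T/U)")
    return seq


def tokenize_sequence(sequence: str) -> list[str]:
    """Split a sequence into consecutive triplet words.

    The trailing remainder of length 1 or 2, if any, is kept as a word, so
    the concatenation of the words always reproduces the input.

    >>> tokenize_sequence("ACGUACGUA")
    ['ACG', 'UAC', 'GUA']
    >>> tokenize_sequence("ACGT")
    ['ACG', 'T']
    """
    seq = normalize_sequence(sequence)
    return [seq[i:i + 3] for i in range(0, len(seq), 3)]


@dataclass
class Corpus:
    """Tokenised sentences originating from one sequence kind."""

    sentences: list[list[str]]
    origin: Origin


@dataclass
class EmbeddingTable:
    """word -> dense vector lookup fitted on one corpus."""

    origin: Origin
    dimension: int
    vectors: dict[str, np.ndarray]
    training_fingerprint: dict = field(default_factory=dict)

    def __contains__(self, word: str) -> bool:
        return word in self.vectors

    def lookup(self, word: str) -> np.ndarray:
        """Vector for `word`; out-of-vocabulary words map to zeros."""
        vec = self.vectors.get(word)
        if vec is None:
            return np.zeros(self.dimension)
        return vec

    # -- plain-text serialisation (word + floats per line, JSON sidecar) ----

    def save(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            for word in sorted(self.vectors):
                values = " ".join(f"{v:.17g}" for v in self.vectors[word])
                fh.write(f"{word} {values}\n")
        meta = {
            "origin": self.origin.value,
            "dimension": self.dimension,
            "fingerprint": self.training_fingerprint,
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingTable":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
        vectors: dict[str, np.ndarray] = {}
        for line in path.read_text().splitlines():
            parts = line.split()
            vectors[parts[0]] = np.array([float(x) for x in parts[1:]])
        table = cls(origin=Origin(meta["origin"]), dimension=int(meta["dimension"]),
                    vectors=vectors, training_fingerprint=meta["fingerprint"])
        for word, vec in table.vectors.items():
            if vec.shape != (table.dimension,):
                raise ValueError(f"vector for {word!r} has wrong dimension")
        return table


def build_corpora(records: Sequence["DuplexRecord"],
                  split: Sequence[str] | None = None,
                  train_tag: str = "train") -> tuple[Corpus, Corpus]:
    """Tokenise the training-split records into (miRNA corpus, mRNA corpus).

    Parameters
    ----------
    records
        Duplex records with `mirna_seq` and `site_seq` attributes.
    split
        Optional per-record split tags; records whose tag equals
        `train_tag` form the corpora.  When omitted, every record is
        treated as a training record.

    Only training data ever reaches the embedding fit — this is the leakage
    guard: the fitted vocabulary can only contain words derivable from the
    selected records.
    """
    if split is not None:
        if len(split) != len(records):
            raise ValueError("split tags and records differ in length")
        selected = [r for r, tag in zip(records, split) if tag == train_tag]
    else:
        selected = list(records)
    if not selected:
        raise ValueError("training split is empty; cannot build corpora")

    mirna = Corpus([tokenize_sequence(r.mirna_seq) for r in selected], Origin.MIRNA)
    mrna = Corpus([tokenize_sequence(r.site_seq) for r in selected], Origin.MRNA)
    return mirna, mrna


def train_cbow(corpus: Corpus, dimension: int = 16, window: int = 5,
               epochs: int = 100, negative: int = 5, min_count: int = 1,
               seed: int = 0) -> EmbeddingTable:
    """Fit a CBOW model on one corpus and return its embedding table.

    Identical (corpus, hyperparameters, seed) inputs produce element-wise
    identical tables.
    """
    if not corpus.sentences:
        raise ValueError("cannot train embeddings on an empty corpus")
    params = CbowParams(dimension=dimension, window=window, epochs=epochs,
                        negative=negative, min_count=min_count, seed=seed)
    result = fit_cbow(corpus.sentences, params)
    vectors = {w: result.vectors[i].copy() for i, w in enumerate(result.vocabulary)}
    return EmbeddingTable(origin=corpus.origin, dimension=dimension,
                          vectors=vectors, training_fingerprint=params.as_dict())


def embed_tokens(sentence: Sequence[str], table: EmbeddingTable,
                 oov_policy: str = "ZERO") -> np.ndarray:
    """Stack per-word vectors into a (len(sentence), dimension) matrix."""
    if oov_policy != "ZERO":
        raise ValueError(f"unknown OOV policy {oov_policy!r}")
    if len(sentence) == 0:
        raise ValueError("cannot embed an empty sentence")
    return np.stack([table.lookup(word) for word in sentence])
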