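"""CBOW word2vec trainer (negative sampling), vectorised with NumPy.

Trains on "sentences" of short nucleotide words.  Mini-batch SGD with a
linearly decaying learning rate is used instead of classic per-example SGD;
for the tiny vocabularies of triplet corpora (<= 4^3 + remainders) this is
equivalent in quality and fully deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CbowParams", "CbowResult", "fit_cbow"]

_NOISE_EXPONENT = 0.75
_INITIAL_LR = 0.025
_FINAL_LR = 1e-4
_BATCH_SIZE = 512


@dataclass(frozen=True)
class CbowParams:
    """Hyperparameters of one CBOW fit."""

    dimension: int = 16
    window: int = 5
    epochs: int = 100
    negative: int = 5
    min_count: int = 1
    seed: int = 0

    def as_dict(self) -> dict:
        return {
            "dimension": self.dimension,
            "window": self.window,
            "epochs": self.epochs,
            "negative": self.negative,
            "min_count": self.min_count,
            "seed": self.seed,
        }


@dataclass
class CbowResult:
    vocabulary: list[str]
    vectors: np.ndarray  # (len(vocabulary), dimension), input embeddings
    params: CbowParams = field(repr=False)


def _build_vocab(sentences: list[list[str]], min_count: int) -> tuple[list[str], dict[str, int], np.ndarray]:
    counts: dict[str, int] = {}
    for sentence in sentences:
        for word in sentence:
            counts[word] = counts.get(word, 0) + 1
    kept = sorted((w for w, c in counts.items() if c >= min_count),
                  key=lambda w: (-counts[w], w))
    if not kept:
        raise ValueError("CBOW vocabulary is empty after min_count filtering")
    index = {w: i for i, w in enumerate(kept)}
    freq = np.array([counts[w] for w in kept], dtype=np.float64)
    return kept, index, freq


def _training_pairs(sentences: list[list[str]], index: dict[str, int],
                    window: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(centers, padded context matrix, context counts); pad value is -1."""
    centers: list[int] = []
    contexts: list[list[int]] = []
    for sentence in sentences:
        ids = [index[w] for w in sentence if w in index]
        for pos, centre in enumerate(ids):
            ctx = ids[max(0, pos - window):pos] + ids[pos + 1:pos + 1 + window]
            if ctx:
                centers.append(centre)
                contexts.append(ctx)
    if not centers:
        # degenerate corpus (all single-word sentences): nothing to train on
        return (np.empty(0, dtype=np.intp),
                np.empty((0, 1), dtype=np.intp),
                np.empty(0, dtype=np.float64))
    width = max(len(c) for c in contexts)
    ctx_matrix = np.full((len(contexts), width), -1, dtype=np.intp)
    for i, ctx in enumerate(contexts):
        ctx_matrix[i, :len(ctx)] = ctx
    n_ctx = np.array([len(c) for c in contexts], dtype=np.float64)
    return np.asarray(centers, dtype=np.intp), ctx_matrix, n_ctx


def fit_cbow(sentences: list[list[str]], params: CbowParams) -> CbowResult:
    """Fit CBOW embeddings on tokenised sentences.

    Raises
    ------
    ValueError
        If the corpus is empty or the dimension is < 1.
    """
    if params.dimension < 1:
        raise ValueError(f"embedding dimension must be >= 1, got {params.dimension}")
    if not sentences:
        raise ValueError("cannot fit CBOW on an empty corpus")

    vocab, index, freq = _build_vocab(sentences, params.min_count)
    rng = np.random.default_rng(params.seed)

    dim = params.dimension
    w_in = (rng.random((len(vocab), dim)) - 0.5) / dim
    w_out = np.zeros((len(vocab), dim))

    centers, ctx_matrix, n_ctx = _training_pairs(sentences, index, params.window)
    n_pairs = centers.shape[0]
    if n_pairs == 0:
        return CbowResult(vocab, w_in, params)

    noise = freq ** _NOISE_EXPONENT
    noise /= noise.sum()
    ctx_mask = (ctx_matrix >= 0).astype(np.float64)[:, :, None]
    ctx_safe = np.where(ctx_matrix >= 0, ctx_matrix, 0)

    total_steps = params.epochs * n_pairs
    step = 0
    for _ in range(params.epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, _BATCH_SIZE):
            sel = order[start:start + _BATCH_SIZE]
            lr = _INITIAL_LR + (_FINAL_LR - _INITIAL_LR) * (step / total_steps)
            step += len(sel)

            ctx_ids = ctx_safe[sel]                      # (B, L)
            mask = ctx_mask[sel]                         # (B, L, 1)
            counts = n_ctx[sel][:, None]                 # (B, 1)
            h = (w_in[ctx_ids] * mask).sum(axis=1) / counts   # (B, dim)

            negatives = rng.choice(len(vocab), size=(len(sel), params.negative),
                                   p=noise)
            targets = np.concatenate([centers[sel][:, None], negatives], axis=1)
            labels = np.zeros(targets.shape)
            labels[:, 0] = 1.0

            w_t = w_out[targets]                         # (B, K+1, dim)
            logits = np.clip(np.einsum("bd,bkd->bk", h, w_t), -30.0, 30.0)
            scores = 1.0 / (1.0 + np.exp(-logits))
            g = (labels - scores) * lr                   # (B, K+1)

            grad_h = np.einsum("bk,bkd->bd", g, w_t)
            np.add.at(w_out, targets, g[:, :, None] * h[:, None, :])
            grad_ctx = (grad_h / counts)[:, None, :] * mask
            np.add.at(w_in, ctx_ids, grad_ctx)

    return CbowResult(vocab, w_in, params)
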