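"""Overlapping k-mer tokenization and dense embedding of DNA sequences.

A length-L sequence scanned with window m and step s yields
floor((L-m)/s) + 1 tokens (198 for the default L=200, m=3, s=1); each token
is mapped to a k-dimensional vector from a pretrained table (dna2vec-style,
k=100) or from a reproducible random fallback table.  The per-sequence
result is the (T, k) matrix of stacked token vectors — the matrix form of
concatenating the token vectors e_1 ... e_T.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .io_formats import EmbeddingTable, LabeledSequence

__all__ = [
    "TokenizerSpec",
    "EmbeddedSample",
    "tokenize",
    "token_count",
    "embed",
    "make_fallback_table",
    "kmer_vocabulary",
    "encode_indices",
    "table_to_matrix",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class TokenizerSpec:
    """Sliding-window tokenizer: window size m, step s."""

    window: int = 3
    step: int = 1

    def __post_init__(self):
        if self.window < 1:
            raise ValueError(f"window must be >= 1, got {self.window}")
        if self.step < 1:
            raise ValueError(f"step must be >= 1, got {self.step}")


@dataclass
class EmbeddedSample:
    """A (T, k) matrix of token vectors plus the sequence label."""

    matrix: np.ndarray
    label: int


def token_count(length: int, spec: TokenizerSpec) -> int:
    """Number of windows: floor((L - m) / s) + 1."""
    if length < spec.window:
        raise ValueError(
            f"sequence length {length} shorter than window {spec.window}")
    return (length - spec.window) // spec.step + 1


def tokenize(seq: LabeledSequence | str, spec: TokenizerSpec = TokenizerSpec()) -> list[str]:
    """Overlapping windows seq[i : i+m] for i = 0, s, 2s, ..."""
    bases = seq.bases if isinstance(seq, LabeledSequence) else seq.upper()
    n = token_count(len(bases), spec)
    m, s = spec.window, spec.step
    return [bases[i * s: i * s + m] for i in range(n)]


def embed(tokens: list[str], table: EmbeddingTable) -> np.ndarray:
    """Stack table lookups into a (T, k) matrix.

    Tokens absent from the table (including any containing N) resolve by
    the table's unk policy; in this pure-lookup form both policies yield a
    zero row — the 'learned' policy only becomes a distinct trainable
    vector inside the network's embedding layer.
    """
    out = np.zeros((len(tokens), table.dimension), dtype=np.float64)
    for t, tok in enumerate(tokens):
        vec = table.lookup(tok)
        if vec is not None:
            out[t] = vec
    return out


def make_fallback_table(m: int, k: int, seed: int,
                        unk_policy: str = "zero") -> EmbeddingTable:
    """A complete random table over all 4**m k-mers, N(0, 1/k) entries.

    Used when no pretrained embedding file is supplied and as the
    initialization of the trainable-embedding ablation.
    """
    if m > 8:
        raise ValueError(f"window {m} too large to enumerate 4**{m} k-mers")
    rng = np.random.default_rng(seed)
    vocab = kmer_vocabulary(m)
    mat = rng.standard_normal((len(vocab), k)) / np.sqrt(k)
    return EmbeddingTable(dimension=k,
                          vectors={tok: mat[i] for i, tok in enumerate(vocab)},
                          unk_policy=unk_policy)


def kmer_vocabulary(m: int) -> list[str]:
    """All 4**m k-mers over {A,C,G,T} in lexicographic order."""
    return ["".join(p) for p in product(_BASES, repeat=m)]


def encode_indices(seqs: list[LabeledSequence] | list[str],
                   spec: TokenizerSpec,
                   vocab: list[str] | None = None) -> np.ndarray:
    """Encode sequences as (N, T) arrays of token indices.

    Index ``4**m`` (one past the vocabulary) is the shared unknown slot for
    tokens containing N or otherwise absent from the vocabulary.  All
    sequences must tokenize to the same length.
    """
    if vocab is None:
        vocab = kmer_vocabulary(spec.window)
    index = {tok: i for i, tok in enumerate(vocab)}
    unk = len(vocab)
    rows = []
    expected_t: int | None = None
    for s in seqs:
        toks = tokenize(s, spec)
        if expected_t is None:
            expected_t = len(toks)
        elif len(toks) != expected_t:
            raise ValueError(
                f"inconsistent token counts: {len(toks)} vs {expected_t}")
        rows.append([index.get(t, unk) for t in toks])
    return np.asarray(rows, dtype=np.int64)


def table_to_matrix(table: EmbeddingTable, vocab: list[str],
                    dtype=np.float32) -> np.ndarray:
    """(V+1, k) matrix in vocabulary order; the final row is the unknown slot.

    The unknown row starts at zero under both policies; under the 'learned'
    policy it is trained along with the rest when the layer is trainable.
    """
    mat = np.zeros((len(vocab) + 1, table.dimension), dtype=dtype)
    for i, tok in enumerate(vocab):
        vec = table.lookup(tok)
        if vec is not None:
            mat[i] = vec
    return mat
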