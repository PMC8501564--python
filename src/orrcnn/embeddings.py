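"""Per-residue numeric embeddings and padded sequence embedding.

Three embedding families are supported:

* one-hot over the 20-letter alphabet (dim 20);
* the 7-class property indicator (dim 7) grouping residues by dipole and
  side-chain volume (the conjoint-triad classes), a proxy for the
  electrostatic and hydrophobic character that dominates interaction
  interfaces;
* skip-gram with negative sampling trained on a sequence corpus, treating
  each protein as one sentence and each residue as a token.

Sequences are embedded as ``max_len x dim`` matrices, zero-padded at the
tail; unknown residues (X, B, Z, U) also map to the zero vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import ALPHABET, ProteinRecord

# Conjoint-triad grouping of the 20 amino acids by dipole and side-chain
# volume; class order fixes the indicator dimensions.
EH_CLASSES: tuple[str, ...] = ("AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C")


@dataclass(frozen=True)
class EmbeddingTable:
    """A map from amino-acid symbol to a fixed-dimension vector."""

    kind: str  # one of {"onehot", "eh", "skipgram"}
    dim: int
    vectors: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        missing = [a for a in ALPHABET if a not in self.vectors]
        if missing:
            raise ValueError(f"embedding table missing symbols {missing}")
        for a, v in self.vectors.items():
            if v.shape != (self.dim,):
                raise ValueError(f"vector for {a!r} has shape {v.shape}, want ({self.dim},)")

    def matrix(self) -> np.ndarray:
        """Vectors stacked in alphabet order, shape (20, dim)."""
        return np.stack([self.vectors[a] for a in ALPHABET])

    def save(self, path) -> None:
        """Two-column text format: symbol then whitespace-separated floats."""
        with open(path, "w") as fh:
            fh.write(f"# kind={self.kind} dim={self.dim}\n")
            for a in ALPHABET:
                vals = " ".join(f"{x:.9g}" for x in self.vectors[a])
                fh.write(f"{a} {vals}\n")

    @classmethod
    def load(cls, path) -> "EmbeddingTable":
        kind, dim, vectors = "unknown", None, {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    for tok in line[1:].split():
                        k, _, v = tok.partition("=")
                        if k == "kind":
                            kind = v
                        elif k == "dim":
                            dim = int(v)
                    continue
                sym, *vals = line.split()
                vectors[sym] = np.array([float(x) for x in vals])
        if not vectors:
            raise ValueError(f"{path}: no embedding vectors found")
        dim = dim if dim is not None else len(next(iter(vectors.values())))
        return cls(kind=kind, dim=dim, vectors=vectors)


@dataclass(frozen=True)
class SkipGramConfig:
    """Hyperparameters for skip-gram with negative sampling.

    ``context_half_len`` (C) gives a window of 2C+1 residues; ``negatives``
    (m) is the number of uniformly drawn negative symbols per positive.
    """

    embed_dim: int = 20
    context_half_len: int = 3
    negatives: int = 5
    epochs: int = 5
    learning_rate: float = 0.025
    seed: int = 0


@dataclass(frozen=True)
class EmbeddedSequence:
    """A zero-padded ``max_len x dim`` embedding matrix with its true length."""

    matrix: np.ndarray
    true_length: int

    def __post_init__(self) -> None:
        if not np.all(self.matrix[self.true_length :] == 0.0):
            raise ValueError("padding rows beyond true_length must be zero")


def onehot_table() -> EmbeddingTable:
    """20 distinct standard basis vectors, alphabet order."""
    eye = np.eye(len(ALPHABET))
    return EmbeddingTable(
        kind="onehot", dim=20, vectors={a: eye[i] for i, a in enumerate(ALPHABET)}
    )


def eh_table() -> EmbeddingTable:
    """7-dimensional indicator of the residue's conjoint-triad class."""
    vectors: dict[str, np.ndarray] = {}
    for ci, members in enumerate(EH_CLASSES):
        v = np.zeros(len(EH_CLASSES))
        v[ci] = 1.0
        for a in members:
            vectors[a] = v.copy()
    return EmbeddingTable(kind="eh", dim=7, vectors=vectors)


def eh_class_index() -> dict[str, int]:
    """Residue -> conjoint-triad class index (0..6)."""
    return {a: ci for ci, members in enumerate(EH_CLASSES) for a in members}


def train_skipgram(
    corpus: list[ProteinRecord], config: SkipGramConfig = SkipGramConfig()
) -> EmbeddingTable:
    """Train residue embeddings by skip-gram with negative sampling.

    Each sequence is one sentence; for every centre position t the targets are
    the positions t-C..t+C (skipping t itself, truncated at sequence ends).
    Per positive pair, ``negatives`` symbols are drawn uniformly from the
    alphabet and pushed apart via the logistic negative-sampling objective.
    Plain SGD with a linearly decaying learning rate; deterministic given the
    config seed.
    """
    if not corpus:
        raise ValueError("skip-gram corpus is empty")
    rng = np.random.default_rng(config.seed)
    V, D = len(ALPHABET), config.embed_dim
    index = {a: i for i, a in enumerate(ALPHABET)}
    # centre (input) and context (output) vectors
    W_in = (rng.random((V, D)) - 0.5) / D
    W_out = np.zeros((V, D))

    encoded = [
        np.array([index[a] for a in rec.residues if a in index], dtype=np.intp)
        for rec in corpus
    ]
    encoded = [s for s in encoded if len(s) >= 2]
    if not encoded:
        raise ValueError("corpus contains no trainable sequences")

    C, m = config.context_half_len, config.negatives
    total_steps = config.epochs * sum(len(s) for s in encoded)
    step = 0
    for _epoch in range(config.epochs):
        order = rng.permutation(len(encoded))
        for si in order:
            seq = encoded[si]
            L = len(seq)
            for t in range(L):
                lr = config.learning_rate * max(
                    1.0 - step / max(total_steps, 1), 1e-4
                )
                step += 1
                centre = seq[t]
                lo, hi = max(0, t - C), min(L, t + C + 1)
                for j in range(lo, hi):
                    if j == t:
                        continue
                    targets = np.empty(m + 1, dtype=np.intp)
                    targets[0] = seq[j]
                    targets[1:] = rng.integers(0, V, size=m)
                    labels = np.zeros(m + 1)
                    labels[0] = 1.0
                    vin = W_in[centre]
                    out = W_out[targets]  # (m+1, D)
                    scores = 1.0 / (1.0 + np.exp(-out @ vin))
                    g = (scores - labels)[:, None] * lr  # (m+1, 1)
                    grad_in = (g * out).sum(axis=0)
                    # accumulate into output rows (targets may repeat)
                    np.add.at(W_out, targets, -g * vin)
                    W_in[centre] -= grad_in

    return EmbeddingTable(
        kind="skipgram",
        dim=D,
        vectors={a: W_in[i].copy() for a, i in index.items()},
    )


def embed_sequence(
    record: ProteinRecord, table: EmbeddingTable, max_len: int
) -> EmbeddedSequence:
    """Embed a sequence as a ``max_len x dim`` matrix, zero-padded at the tail.

    Unknown residues map to zero rows. Raises if the record exceeds
    ``max_len`` (callers length-filter first).
    """
    if len(record) > max_len:
        raise ValueError(
            f"record {record.id!r} has length {len(record)} > max_len {max_len}"
        )
    out = np.zeros((max_len, table.dim))
    for t, a in enumerate(record.residues):
        vec = table.vectors.get(a)
        if vec is not None:
            out[t] = vec
    return EmbeddedSequence(matrix=out, true_length=len(record))
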