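"""Optimisation of the pair encoder with its ordinal or regression head.

The K-1 sub-classifiers are trained jointly on one shared encoder: every
mini-batch is encoded once, and the summed cross-entropy of all K-1
relabelings ("is y > k?") is minimised by AMSGrad. The regression ablation
replaces the heads with a scalar MLP trained on squared error against the
raw confidence score.

AMSGrad keeps the usual Adam moment estimates but divides by the running
*maximum* of the bias-corrected second moment, which restores the
convergence guarantee Adam lacks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .data_io import ProteinRecord, ScoredPair
from .embeddings import EmbeddingTable, embed_sequence
from .encoder import encode_sequence
from .ordinal_head import OrdinalModel, RegressionHead, cross_entropy_loss

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 768
    epochs: int = 30
    seed: int = 0
    eps: float = 1e-8

    def __post_init__(self) -> None:
        if not 0.0 < self.beta1 < self.beta2 < 1.0:
            raise ValueError("need 0 < beta1 < beta2 < 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def amsgrad_step(params, grads, state: dict, config: TrainingConfig) -> None:
    """One AMSGrad update, in place.

    ``state`` maps ``m``, ``v``, ``vhat`` (lists of arrays, zero-initialised)
    and the step counter ``t``. Moments are bias-corrected; the second-moment
    divisor is the running maximum of the corrected estimate.
    """
    if not state:
        state["m"] = [np.zeros_like(p) for p in params]
        state["v"] = [np.zeros_like(p) for p in params]
        state["vhat"] = [np.zeros_like(p) for p in params]
        state["t"] = 0
    state["t"] += 1
    t = state["t"]
    b1, b2 = config.beta1, config.beta2
    for i, (p, g) in enumerate(zip(params, grads)):
        state["m"][i] = b1 * state["m"][i] + (1 - b1) * g
        state["v"][i] = b2 * state["v"][i] + (1 - b2) * g * g
        m_hat = state["m"][i] / (1 - b1**t)
        v_hat = state["v"][i] / (1 - b2**t)
        state["vhat"][i] = np.maximum(state["vhat"][i], v_hat)
        p -= config.learning_rate * m_hat / (np.sqrt(state["vhat"][i]) + config.eps)


class AMSGrad:
    """Stateful wrapper around :func:`amsgrad_step` for Tensor parameters."""

    def __init__(self, params: Sequence[Tensor], config: TrainingConfig):
        self.params = list(params)
        self.config = config
        self.state: dict = {}

    def step(self) -> None:
        grads = [
            p.grad if p.grad is not None else np.zeros_like(p.data)
            for p in self.params
        ]
        datas = [p.data for p in self.params]
        amsgrad_step(datas, grads, self.state, self.config)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


@dataclass
class PairDataset:
    """Pre-embedded sequences plus integer-indexed pairs, ready for batching."""

    embeddings: np.ndarray  # (n_records, max_len, dim)
    i1: np.ndarray
    i2: np.ndarray
    scores: np.ndarray
    labels: np.ndarray  # 0 where unset

    @classmethod
    def build(
        cls,
        records: Sequence[ProteinRecord],
        pairs: Sequence[ScoredPair],
        table: EmbeddingTable,
        max_len: int,
    ) -> "PairDataset":
        index = {r.id: i for i, r in enumerate(records)}
        emb = np.stack([embed_sequence(r, table, max_len).matrix for r in records])
        i1, i2, scores, labels = [], [], [], []
        for p in pairs:
            if p.id1 not in index or p.id2 not in index:
                raise KeyError(f"pair ({p.id1}, {p.id2}) references unknown sequence id")
            i1.append(index[p.id1])
            i2.append(index[p.id2])
            scores.append(p.score)
            labels.append(p.label if p.label is not None else 0)
        return cls(
            embeddings=emb,
            i1=np.array(i1, dtype=np.intp),
            i2=np.array(i2, dtype=np.intp),
            scores=np.array(scores, dtype=float),
            labels=np.array(labels, dtype=np.intp),
        )

    def __len__(self) -> int:
        return len(self.i1)

    def encode_batch(self, model_encoder, config, sel: np.ndarray) -> Tensor:
        """Pair encodings x = E(S1) * E(S2) for the selected pairs, one
        encoder pass over the stacked 2B sequences (shared parameters)."""
        B = len(sel)
        batch = self.embeddings[np.concatenate([self.i1[sel], self.i2[sel]])]
        enc = encode_sequence(Tensor(batch), model_encoder, config)
        e1 = ad.index(enc, np.arange(B))
        e2 = ad.index(enc, np.arange(B, 2 * B))
        return ad.mul(e1, e2)


def encode_pairs(
    encoder, dataset: PairDataset, sel: np.ndarray | None = None, chunk: int = 256
) -> np.ndarray:
    """Inference-mode pair encodings (no autodiff graph), chunked to bound
    memory. Returns an (n, hidden_dim) array."""
    sel = np.arange(len(dataset)) if sel is None else np.asarray(sel)
    out = []
    with ad.no_grad():
        for start in range(0, len(sel), chunk):
            xbar = dataset.encode_batch(encoder, encoder.config, sel[start : start + chunk])
            out.append(xbar.data)
    return np.concatenate(out) if out else np.empty((0, encoder.config.hidden_dim))


def train_ordinal(
    model: OrdinalModel, dataset: PairDataset, config: TrainingConfig
) -> tuple[OrdinalModel, list[float]]:
    """Jointly minimise the summed K-1 sub-classifier cross-entropies.

    Returns the trained model and the per-epoch mean loss trace; aborts with
    a diagnostic if the loss goes non-finite. Deterministic given the config
    seed (single-threaded).
    """
    if np.any(dataset.labels < 1):
        raise ValueError("all training pairs must carry ordinal labels")
    rng = np.random.default_rng(config.seed)
    opt = AMSGrad(model.parameters(), config)
    K = model.partition.K
    trace: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(dataset))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(dataset), config.batch_size):
            sel = order[start : start + config.batch_size]
            xbar = dataset.encode_batch(model.encoder, model.encoder.config, sel)
            y = dataset.labels[sel]
            losses = [
                cross_entropy_loss(xbar, np.where(y > k, 1, -1), model.heads[k - 1])
                for k in range(1, K)
            ]
            total = losses[0]
            for l in losses[1:]:
                total = ad.add(total, l)
            loss_val = float(total.data)
            if not np.isfinite(loss_val):
                raise FloatingPointError(
                    f"non-finite loss {loss_val} at epoch {epoch + 1}; training aborted"
                )
            opt.zero_grad()
            total.backward()
            opt.step()
            epoch_loss += loss_val
            n_batches += 1
        trace.append(epoch_loss / max(n_batches, 1))
        logger.info("epoch %d/%d mean loss %.5f", epoch + 1, config.epochs, trace[-1])
    return model, trace


def train_regression(
    encoder, head: RegressionHead, dataset: PairDataset, config: TrainingConfig
) -> tuple[RegressionHead, list[float]]:
    """Squared-error training of the scalar ablation head (shared encoder)."""
    rng = np.random.default_rng(config.seed)
    opt = AMSGrad(encoder.parameters() + head.parameters(), config)
    trace: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(dataset))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(dataset), config.batch_size):
            sel = order[start : start + config.batch_size]
            xbar = dataset.encode_batch(encoder, encoder.config, sel)
            pred = head.forward(xbar)
            loss = ad.squared_error(pred, dataset.scores[sel])
            loss_val = float(loss.data)
            if not np.isfinite(loss_val):
                raise FloatingPointError(
                    f"non-finite loss {loss_val} at epoch {epoch + 1}; training aborted"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss_val
            n_batches += 1
        trace.append(epoch_loss / max(n_batches, 1))
        logger.info("epoch %d/%d mean loss %.5f", epoch + 1, config.epochs, trace[-1])
    return head, trace
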