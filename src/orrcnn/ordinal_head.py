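"""Ordinal regression over confidence-score sub-intervals.

The confidence-score range (cs_min, cs_max) is split uniformly into K
sub-intervals; a pair whose score falls in the k-th sub-interval gets the
ordinal label k. K-1 binary sub-classifiers answer "is the label greater
than k?"; their positive-decision count plus one is the predicted rank,
which decodes back to a score (sub-interval mid-point by default, or either
endpoint) and is thresholded into the PPI call. A scalar-output regression
head over the same pair encoding provides the ablation model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .data_io import ScoredPair
from .encoder import EncoderState, RCNNConfig


@dataclass(frozen=True)
class IntervalPartition:
    """Uniform K-way partition of (cs_min, cs_max).

    Sub-interval k (1-based) is [cs_min + (k-1) w, cs_min + k w) with
    w = (cs_max - cs_min)/K, except the first which is open at cs_min.
    """

    cs_min: float = 0.0
    cs_max: float = 1.0
    K: int = 20

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError(f"K must be >= 2, got {self.K}")
        if not self.cs_min < self.cs_max:
            raise ValueError("cs_min must be < cs_max")

    @property
    def width(self) -> float:
        return (self.cs_max - self.cs_min) / self.K


def label_of_score(score: float, p: IntervalPartition) -> int:
    """1-based index of the sub-interval containing ``score``.

    Boundaries belong to the interval on their right (the first sub-interval
    is open at cs_min). Scores outside the open range raise.
    """
    if not p.cs_min < score < p.cs_max:
        raise ValueError(f"score {score} outside open range ({p.cs_min}, {p.cs_max})")
    k = int(math.floor((score - p.cs_min) / p.width)) + 1
    return min(k, p.K)  # guard float roundoff at the top edge


def assign_labels(pairs: Iterable[ScoredPair], p: IntervalPartition) -> list[ScoredPair]:
    return [pair.with_label(label_of_score(pair.score, p)) for pair in pairs]


def relabel_for_k(pairs: Sequence[ScoredPair], k: int, K: int) -> tuple[list, list]:
    """Split labeled pairs into (positives: y > k, negatives: y <= k)."""
    if not 1 <= k <= K - 1:
        raise ValueError(f"k must be in 1..{K - 1}, got {k}")
    positives, negatives = [], []
    for pair in pairs:
        if pair.label is None:
            raise ValueError(f"pair ({pair.id1}, {pair.id2}) is unlabeled")
        (positives if pair.label > k else negatives).append(pair)
    return positives, negatives


@dataclass
class MLPParams:
    """One-hidden-layer perceptron with Leaky ReLU."""

    W1: Tensor
    b1: Tensor
    W2: Tensor
    b2: Tensor
    leaky_slope: float = 0.01

    @classmethod
    def init(cls, rng, in_dim: int, hidden: int, out_dim: int, leaky_slope: float = 0.01):
        def u(shape, fan_in):
            bound = 1.0 / np.sqrt(fan_in)
            return Tensor(rng.uniform(-bound, bound, shape), requires_grad=True)

        return cls(
            W1=u((in_dim, hidden), in_dim),
            b1=u(hidden, in_dim),
            W2=u((hidden, out_dim), hidden),
            b2=u(out_dim, hidden),
            leaky_slope=leaky_slope,
        )

    def forward(self, x):
        t = ad.as_tensor(x)
        h = ad.leaky_relu(ad.add(ad.matmul(t, self.W1), self.b1), self.leaky_slope)
        out = ad.add(ad.matmul(h, self.W2), self.b2)
        return out if isinstance(x, Tensor) else out.data

    def parameters(self) -> list[Tensor]:
        return [self.W1, self.b1, self.W2, self.b2]


@dataclass
class SubClassifier:
    """The k-th binary sub-classifier: MLP with a 2-unit output (s_pos, s_neg)."""

    index: int
    mlp: MLPParams

    def logits(self, x):
        return self.mlp.forward(x)

    def parameters(self) -> list[Tensor]:
        return self.mlp.parameters()


def subclassifier_forward(x, c: SubClassifier) -> tuple[np.ndarray, np.ndarray]:
    """Softmax-normalised (s1, s2): confidence of the positive/negative class."""
    logits = np.atleast_2d(c.logits(np.asarray(x, dtype=float)))
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=1, keepdims=True)
    if np.asarray(x).ndim == 1:
        return float(s[0, 0]), float(s[0, 1])
    return s[:, 0], s[:, 1]


def decide_fk(s1, s2):
    """+1 iff s1 > s2, else -1 (ties fall to -1)."""
    return np.where(np.asarray(s1) > np.asarray(s2), 1, -1)[()]


def aggregate_rank(decisions) -> int | np.ndarray:
    """Rank = 1 + number of positive sub-classifier decisions.

    The sum form tolerates mutually inconsistent decisions (for instance f_3
    negative but f_7 positive); no monotonisation is applied.
    """
    d = np.asarray(decisions)
    if not np.isin(d, (-1, 1)).all():
        raise ValueError("decisions must be +1/-1")
    rank = 1 + (d > 0).sum(axis=-1)
    return int(rank) if np.isscalar(rank) or rank.ndim == 0 else rank


def score_from_rank(rank, p: IntervalPartition, mode: str = "mid"):
    """Decode a rank to a confidence score.

    ``mid`` takes the sub-interval mid-point; ``left``/``right`` take the
    lower/upper endpoint (for the (0,1), K=20 partition these are
    0.05*(rank-1) and 0.05*rank).
    """
    r = np.asarray(rank)
    if np.any(r < 1) or np.any(r > p.K):
        raise ValueError(f"rank outside 1..{p.K}")
    left = p.cs_min + p.width * (r - 1)
    if mode == "mid":
        out = left + p.width / 2.0
    elif mode == "left":
        out = left
    elif mode == "right":
        out = left + p.width
    else:
        raise ValueError(f"unknown score mode {mode!r}")
    return float(out) if out.ndim == 0 else out


def call_ppi(score, theta: float):
    """True iff score > theta (strict)."""
    out = np.asarray(score) > theta
    return bool(out) if out.ndim == 0 else out


def cross_entropy_loss(x, labels, c: SubClassifier) -> Tensor | float:
    """Mean two-class cross-entropy of the sub-classifier on +-1 labels."""
    y = np.asarray(labels)
    class_index = np.where(y > 0, 0, 1)  # column 0 is the positive class
    logits = c.logits(x if isinstance(x, Tensor) else Tensor(np.atleast_2d(x)))
    loss = ad.softmax_cross_entropy(logits, np.atleast_1d(class_index))
    return loss if isinstance(x, Tensor) else float(loss.data)


@dataclass
class RegressionHead:
    """Scalar-output MLP ablation head; the raw output is squashed through a
    sigmoid onto (cs_min, cs_max) so predictions stay strictly inside the
    score range."""

    mlp: MLPParams
    partition: IntervalPartition

    @classmethod
    def init(cls, rng, in_dim: int, hidden: int, partition: IntervalPartition):
        return cls(mlp=MLPParams.init(rng, in_dim, hidden, 1), partition=partition)

    def forward(self, x):
        raw = self.mlp.forward(x if isinstance(x, Tensor) else Tensor(np.atleast_2d(x)))
        span = self.partition.cs_max - self.partition.cs_min
        squashed = ad.add(
            ad.mul(ad.sigmoid(raw), Tensor(span)), Tensor(self.partition.cs_min)
        )
        out = ad.reshape(squashed, squashed.data.shape[:-1])
        if isinstance(x, Tensor):
            return out
        vals = out.data
        return float(vals[0]) if np.asarray(x).ndim == 1 else vals

    def parameters(self) -> list[Tensor]:
        return self.mlp.parameters()


def regression_head_forward(x, head: RegressionHead):
    return head.forward(x)


@dataclass(frozen=True)
class RankPrediction:
    """Decisions of the K-1 sub-classifiers plus the decoded outcome."""

    id1: str
    id2: str
    decisions: tuple
    rank: int
    score: float
    call: bool | None = None


@dataclass
class OrdinalModel:
    """Shared encoder + K-1 sub-classifiers + the score partition."""

    encoder: EncoderState
    heads: list[SubClassifier]
    partition: IntervalPartition

    @classmethod
    def init(
        cls,
        config: RCNNConfig,
        partition: IntervalPartition,
        hidden: int = 32,
        seed: int = 0,
    ) -> "OrdinalModel":
        encoder = EncoderState.init(config, seed=seed)
        rng = np.random.default_rng(seed + 1)
        heads = [
            SubClassifier(index=k, mlp=MLPParams.init(rng, config.hidden_dim, hidden, 2))
            for k in range(1, partition.K)
        ]
        return cls(encoder=encoder, heads=heads, partition=partition)

    def parameters(self) -> list[Tensor]:
        out = self.encoder.parameters()
        for h in self.heads:
            out += h.parameters()
        return out

    def decisions_from_encoding(self, x: np.ndarray) -> np.ndarray:
        """(B, K-1) matrix of +-1 decisions from pair encodings (B, d')."""
        x = np.atleast_2d(x)
        cols = []
        for head in self.heads:
            s1, s2 = subclassifier_forward(x, head)
            cols.append(decide_fk(s1, s2))
        return np.stack(cols, axis=1)

    def predict_encoded(
        self, x: np.ndarray, score_mode: str = "mid", theta: float | None = None
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
        """(ranks, scores, calls) from pair encodings."""
        decisions = self.decisions_from_encoding(x)
        ranks = 1 + (decisions > 0).sum(axis=1)
        scores = score_from_rank(ranks, self.partition, score_mode)
        calls = call_ppi(scores, theta) if theta is not None else None
        return ranks, np.atleast_1d(scores), calls

    # -- checkpointing -------------------------------------------------------

    def save(self, path) -> None:
        arrays = self.encoder.to_arrays()
        for h in self.heads:
            arrays[f"head{h.index}.W1"] = h.mlp.W1.data
            arrays[f"head{h.index}.b1"] = h.mlp.b1.data
            arrays[f"head{h.index}.W2"] = h.mlp.W2.data
            arrays[f"head{h.index}.b2"] = h.mlp.b2.data
        cfg = self.encoder.config_dict()
        cfg.update(
            {
                "cs_min": self.partition.cs_min,
                "cs_max": self.partition.cs_max,
                "K": self.partition.K,
                "head_hidden": self.heads[0].mlp.W1.data.shape[1],
                "leaky_slope": self.heads[0].mlp.leaky_slope,
            }
        )
        np.savez(path, __config__=json.dumps(cfg), **arrays)

    @classmethod
    def load(cls, path) -> "OrdinalModel":
        with np.load(path, allow_pickle=False) as npz:
            cfg = json.loads(str(npz["__config__"]))
            if cfg.get("format_version") != EncoderState.FORMAT_VERSION:
                raise ValueError("checkpoint format version mismatch")
            config = RCNNConfig(
                num_units=cfg["num_units"],
                kernel_width=cfg["kernel_width"],
                hidden_dim=cfg["hidden_dim"],
                pool_width=cfg["pool_width"],
                merge=cfg["merge"],
                in_dim=cfg["in_dim"],
            )
            partition = IntervalPartition(cfg["cs_min"], cfg["cs_max"], cfg["K"])
            arrays = {k: npz[k] for k in npz.files if k != "__config__"}
        model = cls.init(config, partition, hidden=cfg["head_hidden"], seed=0)
        model.encoder = EncoderState.from_arrays(config, arrays)
        for h in model.heads:
            h.mlp.W1.data = np.array(arrays[f"head{h.index}.W1"])
            h.mlp.b1.data = np.array(arrays[f"head{h.index}.b1"])
            h.mlp.W2.data = np.array(arrays[f"head{h.index}.W2"])
            h.mlp.b2.data = np.array(arrays[f"head{h.index}.b2"])
        return model
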