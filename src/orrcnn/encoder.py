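"""The recurrent-convolutional sequence encoder and the shared pair encoder.

One RCNN unit is: 1-D convolution (affine, width ``d``, no implicit padding)
-> per-dimension max over disjoint length-``n`` blocks -> bidirectional GRU
whose forward/backward states are merged with the layer input either by
concatenation ``[fwd, bwd, v]`` or by a residual shortcut
``[fwd + v, bwd + v]``. ``num_units`` such units are stacked, a final
convolution follows the last unit, and global average pooling yields the
sequence embedding E(S) of dimension ``hidden_dim``.

A protein pair is encoded by running both sequences through the *same*
parameter bundle and fusing the two embeddings by element-wise
multiplication, which makes the pair encoding exactly symmetric under
argument swap.

All operations accept either plain ndarrays or autodiff Tensors; shapes are
``(length, dim)`` or batched ``(batch, length, dim)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .embeddings import EmbeddedSequence


@dataclass
class RCNNConfig:
    """Architecture hyperparameters.

    Defaults follow the full-scale recipe: kernel width 3, 3-max-pooling,
    hidden dimension 50 (so the concatenate-merged BiGRU emits 150 dims) and
    5 stacked units.
    """

    num_units: int = 5
    kernel_width: int = 3
    hidden_dim: int = 50
    pool_width: int = 3
    merge: str = "concatenate"  # or "residual"
    in_dim: int = 20

    def __post_init__(self) -> None:
        if self.merge not in ("concatenate", "residual"):
            raise ValueError(f"unknown merge mode {self.merge!r}")

    @property
    def unit_out_dim(self) -> int:
        """Feature dimension leaving one unit: 3d' (concatenate) or 2d'."""
        return (3 if self.merge == "concatenate" else 2) * self.hidden_dim


@dataclass
class ConvParams:
    """Width-``d`` 1-D convolution: kernel (d * in_dim, out_dim) plus bias."""

    kernel: Tensor
    bias: Tensor
    kernel_width: int
    in_dim: int
    out_dim: int

    @classmethod
    def init(cls, rng, kernel_width: int, in_dim: int, out_dim: int) -> "ConvParams":
        bound = 1.0 / np.sqrt(kernel_width * in_dim)
        k = Tensor(
            rng.uniform(-bound, bound, size=(kernel_width * in_dim, out_dim)),
            requires_grad=True,
        )
        b = Tensor(rng.uniform(-bound, bound, size=out_dim), requires_grad=True)
        return cls(k, b, kernel_width, in_dim, out_dim)


@dataclass
class GRUParams:
    """Gate parameters: update (z), candidate (s) and reset (r) blocks."""

    M_z: Tensor
    M_s: Tensor
    M_r: Tensor
    N_z: Tensor
    N_s: Tensor
    N_r: Tensor
    b_z: Tensor
    b_s: Tensor
    b_r: Tensor
    hidden_dim: int

    @classmethod
    def init(cls, rng, in_dim: int, hidden_dim: int) -> "GRUParams":
        def w(n_in, n_out):
            bound = 1.0 / np.sqrt(n_in)
            return Tensor(rng.uniform(-bound, bound, (n_in, n_out)), requires_grad=True)

        def b():
            bound = 1.0 / np.sqrt(hidden_dim)
            return Tensor(rng.uniform(-bound, bound, hidden_dim), requires_grad=True)

        return cls(
            M_z=w(in_dim, hidden_dim),
            M_s=w(in_dim, hidden_dim),
            M_r=w(in_dim, hidden_dim),
            N_z=w(hidden_dim, hidden_dim),
            N_s=w(hidden_dim, hidden_dim),
            N_r=w(hidden_dim, hidden_dim),
            b_z=b(),
            b_s=b(),
            b_r=b(),
            hidden_dim=hidden_dim,
        )


@dataclass
class RCNNUnitParams:
    conv: ConvParams
    gru_fwd: GRUParams
    gru_bwd: GRUParams


@dataclass
class EncoderState:
    """The full parameter bundle, shared by both arms of the pair encoder."""

    config: RCNNConfig
    units: list[RCNNUnitParams]
    final_conv: ConvParams

    @classmethod
    def init(cls, config: RCNNConfig, seed: int = 0) -> "EncoderState":
        rng = np.random.default_rng(seed)
        if config.merge == "residual" and config.in_dim != config.hidden_dim:
            raise ValueError(
                "residual merge needs in_dim == hidden_dim for the first unit "
                f"(got {config.in_dim} vs {config.hidden_dim}); concatenate has "
                "no such constraint"
            )
        units = []
        in_dim = config.in_dim
        for _ in range(config.num_units):
            conv = ConvParams.init(rng, config.kernel_width, in_dim, config.hidden_dim)
            fwd = GRUParams.init(rng, config.hidden_dim, config.hidden_dim)
            bwd = GRUParams.init(rng, config.hidden_dim, config.hidden_dim)
            units.append(RCNNUnitParams(conv, fwd, bwd))
            in_dim = config.unit_out_dim
        final_conv = ConvParams.init(rng, config.kernel_width, in_dim, config.hidden_dim)
        return cls(config=config, units=units, final_conv=final_conv)

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for u in self.units:
            out += [u.conv.kernel, u.conv.bias]
            for g in (u.gru_fwd, u.gru_bwd):
                out += [g.M_z, g.M_s, g.M_r, g.N_z, g.N_s, g.N_r, g.b_z, g.b_s, g.b_r]
        out += [self.final_conv.kernel, self.final_conv.bias]
        return out

    # -- checkpointing -------------------------------------------------------

    FORMAT_VERSION = 1

    def to_arrays(self, prefix: str = "enc") -> dict[str, np.ndarray]:
        arrays: dict[str, np.ndarray] = {}
        for i, u in enumerate(self.units):
            arrays[f"{prefix}.u{i}.conv.kernel"] = u.conv.kernel.data
            arrays[f"{prefix}.u{i}.conv.bias"] = u.conv.bias.data
            for name, g in (("fwd", u.gru_fwd), ("bwd", u.gru_bwd)):
                for f in ("M_z", "M_s", "M_r", "N_z", "N_s", "N_r", "b_z", "b_s", "b_r"):
                    arrays[f"{prefix}.u{i}.{name}.{f}"] = getattr(g, f).data
        arrays[f"{prefix}.final.kernel"] = self.final_conv.kernel.data
        arrays[f"{prefix}.final.bias"] = self.final_conv.bias.data
        return arrays

    def config_dict(self) -> dict:
        c = self.config
        return {
            "format_version": self.FORMAT_VERSION,
            "num_units": c.num_units,
            "kernel_width": c.kernel_width,
            "hidden_dim": c.hidden_dim,
            "pool_width": c.pool_width,
            "merge": c.merge,
            "in_dim": c.in_dim,
        }

    def save(self, path) -> None:
        np.savez(path, __config__=json.dumps(self.config_dict()), **self.to_arrays())

    @classmethod
    def from_arrays(cls, config: RCNNConfig, arrays, prefix: str = "enc") -> "EncoderState":
        state = cls.init(config, seed=0)
        for i, u in enumerate(state.units):
            u.conv.kernel.data = np.array(arrays[f"{prefix}.u{i}.conv.kernel"])
            u.conv.bias.data = np.array(arrays[f"{prefix}.u{i}.conv.bias"])
            for name, g in (("fwd", u.gru_fwd), ("bwd", u.gru_bwd)):
                for f in ("M_z", "M_s", "M_r", "N_z", "N_s", "N_r", "b_z", "b_s", "b_r"):
                    getattr(g, f).data = np.array(arrays[f"{prefix}.u{i}.{name}.{f}"])
        state.final_conv.kernel.data = np.array(arrays[f"{prefix}.final.kernel"])
        state.final_conv.bias.data = np.array(arrays[f"{prefix}.final.bias"])
        return state

    @classmethod
    def load(cls, path) -> "EncoderState":
        with np.load(path, allow_pickle=False) as npz:
            cfg = json.loads(str(npz["__config__"]))
            if cfg.get("format_version") != cls.FORMAT_VERSION:
                raise ValueError(
                    f"checkpoint format version {cfg.get('format_version')} != "
                    f"{cls.FORMAT_VERSION}"
                )
            config = RCNNConfig(
                num_units=cfg["num_units"],
                kernel_width=cfg["kernel_width"],
                hidden_dim=cfg["hidden_dim"],
                pool_width=cfg["pool_width"],
                merge=cfg["merge"],
                in_dim=cfg["in_dim"],
            )
            arrays = {k: npz[k] for k in npz.files if k != "__config__"}
        return cls.from_arrays(config, arrays)


# ---------------------------------------------------------------------------
# layers


def _wrap(x):
    """(maybe-batched ndarray | Tensor) -> (Tensor with batch axis, had_batch, was_tensor)."""
    was_tensor = isinstance(x, Tensor)
    t = x if was_tensor else Tensor(x)
    if t.data.ndim == 2:
        return ad.reshape(t, (1,) + t.data.shape), False, was_tensor
    if t.data.ndim == 3:
        return t, True, was_tensor
    raise ValueError(f"expected (length, dim) or (batch, length, dim), got {t.data.shape}")


def _unwrap(out: Tensor, batched: bool, was_tensor: bool):
    if not batched:
        out = ad.reshape(out, out.data.shape[1:])
    return out if was_tensor else out.data


def conv_layer(x, params: ConvParams):
    """Affine width-``d`` convolution: output position t is
    ``M @ v_{t:t+d-1} + b``; output length is l - d + 1. No nonlinearity.
    """
    t, batched, was_tensor = _wrap(x)
    B, L, D = t.data.shape
    d = params.kernel_width
    if L < d:
        raise ValueError(f"input length {L} shorter than kernel width {d}")
    if D != params.in_dim:
        raise ValueError(f"input dim {D} != conv in_dim {params.in_dim}")
    # unfold windows: (B, L-d+1, d*D)
    windows = ad.concat(
        [ad.index_axis1(t, np.arange(s, L - d + 1 + s)) for s in range(d)], axis=-1
    )
    out = ad.add(ad.matmul(windows, params.kernel), params.bias)
    return _unwrap(out, batched, was_tensor)


def n_max_pool(x, n: int):
    """Per-dimension max over consecutive disjoint blocks of ``n`` positions;
    a partial final block is pooled over its available entries. Output length
    is ceil(l / n).
    """
    t, batched, was_tensor = _wrap(x)
    out = ad.max_pool_blocks(t, n, axis=1)
    return _unwrap(out, batched, was_tensor)


def gru_sequence(x, params: GRUParams, h0=None):
    """Run a GRU over the sequence, returning all hidden states.

    Gates: z_t = sigma(M_z v_t + N_z h_{t-1} + b_z),
    r_t = sigma(M_r v_t + N_r h_{t-1} + b_r),
    candidate h~_t = tanh(M_s v_t + r_t * (N_s h_{t-1}) + b_s),
    state h_t = z_t * h~_t + (1 - z_t) * h_{t-1}. h0 defaults to zero.
    """
    t, batched, was_tensor = _wrap(x)
    B, L, D = t.data.shape
    H = params.hidden_dim
    h = Tensor(np.zeros((B, H))) if h0 is None else ad.as_tensor(h0)
    if h.data.ndim == 1:
        h = ad.reshape(h, (1, H))
        h = ad.add(h, Tensor(np.zeros((B, H))))  # broadcast to batch
    # input projections are hoisted out of the recurrence; the recurrence
    # itself is one fused graph node with hand-derived BPTT
    xz = ad.add(ad.matmul(t, params.M_z), params.b_z)
    xr = ad.add(ad.matmul(t, params.M_r), params.b_r)
    xs = ad.add(ad.matmul(t, params.M_s), params.b_s)
    out = ad.gru_recurrence(xz, xr, xs, params.N_z, params.N_r, params.N_s, h.data)
    return _unwrap(out, batched, was_tensor)


def bigru_merge(x, fwd: GRUParams, bwd: GRUParams, merge: str = "concatenate"):
    """Bidirectional GRU with merge.

    ``concatenate`` emits [fwd_t, bwd_t, v_t] (dim 2*hidden + in_dim);
    ``residual`` emits [fwd_t + v_t, bwd_t + v_t] and requires
    hidden_dim == in_dim.
    """
    t, batched, was_tensor = _wrap(x)
    D = t.data.shape[2]
    if merge == "residual" and fwd.hidden_dim != D:
        raise ValueError(
            f"residual merge needs hidden_dim == input dim ({fwd.hidden_dim} != {D})"
        )
    f = gru_sequence(t, fwd)
    b_rev = gru_sequence(ad.flip(t, axis=1), bwd)
    b = ad.flip(b_rev, axis=1)
    if merge == "concatenate":
        out = ad.concat([f, b, t], axis=-1)
    elif merge == "residual":
        out = ad.concat([ad.add(f, t), ad.add(b, t)], axis=-1)
    else:
        raise ValueError(f"unknown merge mode {merge!r}")
    return _unwrap(out, batched, was_tensor)


def rcnn_unit(x, unit: RCNNUnitParams, config: RCNNConfig):
    """conv -> n-max-pool -> BiGRU-with-merge, in that order."""
    h = conv_layer(x, unit.conv)
    h = n_max_pool(h, config.pool_width)
    return bigru_merge(h, unit.gru_fwd, unit.gru_bwd, config.merge)


def global_avg_pool(x):
    """Arithmetic mean over positions, per feature dimension."""
    t, batched, was_tensor = _wrap(x)
    if t.data.shape[1] == 0:
        raise ValueError("global average pooling over an empty sequence")
    out = ad.mean(t, axis=1)
    if not batched:
        out = ad.reshape(out, out.data.shape[1:])
    return out if was_tensor else out.data


def unit_output_length(length: int, config: RCNNConfig) -> int:
    conv_len = length - config.kernel_width + 1
    if conv_len < 1:
        raise ValueError(f"length {length} too short for kernel width {config.kernel_width}")
    return -(-conv_len // config.pool_width)  # ceil division


def encoded_length(max_len: int, config: RCNNConfig) -> int:
    """Positions remaining before global average pooling; raises (naming the
    stage) if the stack exhausts the sequence."""
    length = max_len
    for i in range(config.num_units):
        try:
            length = unit_output_length(length, config)
        except ValueError as e:
            raise ValueError(f"unit {i + 1}: {e}") from None
    final = length - config.kernel_width + 1
    if final < 1:
        raise ValueError(f"final conv: length {length} too short")
    return final


def encode_sequence(emb, state: EncoderState, config: RCNNConfig | None = None):
    """E(S): stacked RCNN units, a final convolution, then global average
    pooling; output dimension is ``hidden_dim``.

    ``emb`` may be an :class:`~orrcnn.embeddings.EmbeddedSequence`, an
    ndarray (length, dim) or (batch, length, dim), or a Tensor.
    """
    config = config or state.config
    if isinstance(emb, EmbeddedSequence):
        emb = emb.matrix
    x = emb
    length = (x.data if isinstance(x, Tensor) else x).shape[-2]
    encoded_length(length, config)  # fail fast with a stage-naming error
    for unit in state.units:
        x = rcnn_unit(x, unit, config)
    x = conv_layer(x, state.final_conv)
    return global_avg_pool(x)


def encode_pair(emb1, emb2, state: EncoderState, config: RCNNConfig | None = None):
    """E(S1) * E(S2): both arms use the identical parameter bundle, so the
    element-wise product is exactly symmetric under argument swap."""
    e1 = encode_sequence(emb1, state, config)
    e2 = encode_sequence(emb2, state, config)
    if isinstance(e1, Tensor) or isinstance(e2, Tensor):
        return ad.mul(e1, e2)
    return e1 * e2
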