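"""Shared attention primitives for the gated image-text network.

Token sequences are ordered ``[image tokens | text tokens | global
tokens]`` with explicit index boundaries; image tokens form a row-major
square grid.  The primitives here are deliberately positional-encoding
free: spatial structure enters only through the window partitioning of
image tokens.

All operations accept numpy arrays or autodiff :class:`~.autodiff.Tensor`
objects with shape ``(..., N, C)`` and are differentiable end-to-end.
Softmax logits are scaled by ``1/sqrt(C/heads)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .errors import DimensionError


@dataclass
class TokenSequence:
    """Concatenated ``[image | text | global]`` tokens with boundaries."""

    tokens: Tensor | np.ndarray   # (..., N, C)
    boundaries: tuple[int, int, int]  # (n_img, n_txt, n_glob)
    grid_side: int

    def __post_init__(self):
        n_img, n_txt, n_glob = self.boundaries
        if n_img != self.grid_side ** 2:
            raise DimensionError(
                f"n_img={n_img} does not match grid {self.grid_side}^2")
        n = ad.as_tensor(self.tokens).shape[-2]
        if n_img + n_txt + n_glob != n:
            raise DimensionError(
                f"boundaries {self.boundaries} do not sum to sequence length {n}")

    @property
    def n_img(self):
        return self.boundaries[0]

    @property
    def n_txt(self):
        return self.boundaries[1]

    @property
    def n_glob(self):
        return self.boundaries[2]

    def slices(self):
        n_img, n_txt, _ = self.boundaries
        return (slice(0, n_img), slice(n_img, n_img + n_txt),
                slice(n_img + n_txt, None))


@dataclass
class AttentionParams:
    """Projections of one multi-head attention operation (width C)."""

    wq: Tensor
    wk: Tensor
    wv: Tensor
    wo: Tensor
    bq: Tensor
    bk: Tensor
    bv: Tensor
    bo: Tensor
    heads: int

    @property
    def width(self) -> int:
        return self.wq.shape[0]

    def tensors(self) -> dict[str, Tensor]:
        return {"wq": self.wq, "wk": self.wk, "wv": self.wv, "wo": self.wo,
                "bq": self.bq, "bk": self.bk, "bv": self.bv, "bo": self.bo}


@dataclass
class QKVParams:
    """A shared query/key/value projection without an output projection."""

    wq: Tensor
    wk: Tensor
    wv: Tensor
    bq: Tensor
    bk: Tensor
    bv: Tensor
    heads: int

    @property
    def width(self) -> int:
        return self.wq.shape[0]

    def tensors(self) -> dict[str, Tensor]:
        return {"wq": self.wq, "wk": self.wk, "wv": self.wv,
                "bq": self.bq, "bk": self.bk, "bv": self.bv}


def init_qkv(width: int, heads: int, rng: np.random.Generator,
             init_scale: float = 0.02) -> QKVParams:
    if width % heads:
        raise DimensionError(f"width {width} not divisible by heads {heads}")
    def w():
        return ad.parameter(rng.normal(0.0, init_scale, size=(width, width)))
    def b():
        return ad.parameter(np.zeros(width))
    return QKVParams(wq=w(), wk=w(), wv=w(), bq=b(), bk=b(), bv=b(), heads=heads)


def init_attention(width: int, heads: int, rng: np.random.Generator,
                   init_scale: float = 0.02) -> AttentionParams:
    if width % heads:
        raise DimensionError(f"width {width} not divisible by heads {heads}")
    def w():
        return ad.parameter(rng.normal(0.0, init_scale, size=(width, width)))
    def b():
        return ad.parameter(np.zeros(width))
    return AttentionParams(wq=w(), wk=w(), wv=w(), wo=w(),
                           bq=b(), bk=b(), bv=b(), bo=b(), heads=heads)


# ----------------------------------------------------------------- internals

def _split_heads(x: Tensor, heads: int) -> Tensor:
    """(B, N, C) -> (B, heads, N, C/heads)."""
    b, n, c = x.shape
    x = ad.reshape(x, (b, n, heads, c // heads))
    return ad.transpose(x, (0, 2, 1, 3))


def _merge_heads(x: Tensor) -> Tensor:
    b, h, n, d = x.shape
    return ad.reshape(ad.transpose(x, (0, 2, 1, 3)), (b, n, h * d))


def _ensure_batched(x) -> tuple[Tensor, bool]:
    t = ad.as_tensor(x)
    if t.ndim == 2:
        return ad.reshape(t, (1,) + t.shape), True
    if t.ndim == 3:
        return t, False
    raise DimensionError(f"expected (N, C) or (B, N, C) tokens, got {t.shape}")


def _scaled_attention(q: Tensor, k: Tensor, v: Tensor, d: int):
    scores = ad.matmul(q, ad.transpose(k, (0, 1, 3, 2))) * (1.0 / np.sqrt(d))
    weights = ad.softmax(scores, axis=-1)
    return ad.matmul(weights, v), weights


def _mha(q_from: Tensor, kv_from: Tensor, p: AttentionParams,
         return_weights: bool = False):
    d = p.width // p.heads
    q = _split_heads(ad.linear(q_from, p.wq, p.bq), p.heads)
    k = _split_heads(ad.linear(kv_from, p.wk, p.bk), p.heads)
    v = _split_heads(ad.linear(kv_from, p.wv, p.bv), p.heads)
    out, weights = _scaled_attention(q, k, v, d)
    out = ad.linear(_merge_heads(out), p.wo, p.bo)
    return (out, weights) if return_weights else out


# ---------------------------------------------------------------- operations

def partition_qkv(seq: TokenSequence, p: "AttentionParams | QKVParams"):
    """Shared Q/K/V projection over the full sequence, sliced by modality.

    Returns ``((qi, ki, vi), (qt, kt, vt), (qg, kg, vg))``, each slice of
    shape ``(B, n_modality, C)``.  Concatenating the three slices of any
    projection reconstructs the full projected sequence.
    """
    tokens, squeezed = _ensure_batched(seq.tokens)
    q = ad.linear(tokens, p.wq, p.bq)
    k = ad.linear(tokens, p.wk, p.bk)
    v = ad.linear(tokens, p.wv, p.bv)
    out = []
    for sl in seq.slices():
        out.append(tuple(t[:, sl, :] for t in (q, k, v)))
    if squeezed:
        out = [tuple(ad.reshape(t, t.shape[1:]) for t in triple) for triple in out]
    return tuple(out)


def global_self_attention(tokens, p: AttentionParams, return_weights=False):
    """Standard scaled dot-product multi-head self-attention."""
    x, squeezed = _ensure_batched(tokens)
    out = _mha(x, x, p, return_weights=return_weights)
    if return_weights:
        out, w = out
    if squeezed:
        out = ad.reshape(out, out.shape[1:])
    return (out, w) if return_weights else out


def cross_attention(queries_from, keys_values_from, p: AttentionParams,
                    return_weights=False):
    """Attention with queries from A and keys/values from B (|A| rows out)."""
    a, squeezed = _ensure_batched(queries_from)
    b, _ = _ensure_batched(keys_values_from)
    if a.shape[-1] != b.shape[-1]:
        raise DimensionError(
            f"query width {a.shape[-1]} != key/value width {b.shape[-1]}")
    out = _mha(a, b, p, return_weights=return_weights)
    if return_weights:
        out, w = out
    if squeezed:
        out = ad.reshape(out, out.shape[1:])
    return (out, w) if return_weights else out


def window_self_attention(tokens, grid_side: int, window: int,
                          p: AttentionParams, return_weights=False):
    """Self-attention within non-overlapping ``window x window`` tiles.

    ``tokens`` are the row-major image tokens of a ``grid_side**2`` grid.
    With ``window == grid_side`` this coincides with global self-attention.
    """
    x, squeezed = _ensure_batched(tokens)
    b, n, c = x.shape
    if n != grid_side ** 2:
        raise DimensionError(f"{n} tokens do not form a {grid_side}x{grid_side} grid")
    if grid_side % window:
        raise DimensionError(f"grid {grid_side} not divisible by window {window}")
    g, w_ = grid_side, window
    nw = g // w_
    # (B, g, g, C) -> (B*nw*nw, w*w, C) tiles
    t = ad.reshape(x, (b, nw, w_, nw, w_, c))
    t = ad.transpose(t, (0, 1, 3, 2, 4, 5))
    t = ad.reshape(t, (b * nw * nw, w_ * w_, c))
    out = _mha(t, t, p, return_weights=return_weights)
    if return_weights:
        out, wts = out
    out = ad.reshape(out, (b, nw, nw, w_, w_, c))
    out = ad.transpose(out, (0, 1, 3, 2, 4, 5))
    out = ad.reshape(out, (b, n, c))
    if squeezed:
        out = ad.reshape(out, (n, c))
    return (out, wts) if return_weights else out


@dataclass
class GateParams:
    """Two-layer gate head: concat-pool -> ReLU -> scalar sigmoid."""

    w1: Tensor  # (2C, C)
    b1: Tensor
    w2: Tensor  # (C, 1)
    b2: Tensor

    def tensors(self) -> dict[str, Tensor]:
        return {"w1": self.w1, "b1": self.b1, "w2": self.w2, "b2": self.b2}


def init_gate(width: int, rng: np.random.Generator,
              init_scale: float = 0.02) -> GateParams:
    return GateParams(
        w1=ad.parameter(rng.normal(0.0, init_scale, size=(2 * width, width))),
        b1=ad.parameter(np.zeros(width)),
        w2=ad.parameter(rng.normal(0.0, init_scale, size=(width, 1))),
        b2=ad.parameter(np.zeros(1)))


def compute_gate(image_tokens, text_tokens, gate: GateParams) -> Tensor:
    """Per-sample scalar fusion gate in (0, 1).

    Mean-pools each modality, concatenates, applies two linear layers with
    a ReLU between, and bounds the scalar with a sigmoid (a ReLU alone
    cannot produce a coefficient confined to (0, 1)).  Returns shape
    ``(B, 1, 1)`` (or ``(1, 1)`` for unbatched input) for broadcasting.
    """
    img, squeezed = _ensure_batched(image_tokens)
    txt, _ = _ensure_batched(text_tokens)
    if img.shape[-2] == 0 or txt.shape[-2] == 0:
        raise ValueError("compute_gate requires non-empty modalities")
    pooled = ad.concat([ad.mean(img, axis=-2), ad.mean(txt, axis=-2)], axis=-1)
    h = ad.relu(ad.linear(pooled, gate.w1, gate.b1))
    g = ad.sigmoid(ad.linear(h, gate.w2, gate.b2))  # (B, 1)
    g = ad.reshape(g, (g.shape[0], 1, 1))
    if squeezed:
        g = ad.reshape(g, (1, 1))
    return g
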