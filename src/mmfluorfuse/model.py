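"""The gated image-text interaction network (Mm-VitnNet-style assembly).

Architecture: a convolutional stem (3x3 stride-2 conv + 2x2 max pool,
224 -> 56) tokenizes the image; the reduced parameter vector is embedded
as one token per principal component; two sets of learnable global tokens
(one per modality) ride along the sequence.  Four stages follow: the first
three interleave a cross-modal gated-fusion block (ITSAI) with a
global-token aggregation block (ITLeSAMM); the fourth stage is
ITLeSAMM-only.  Between stages, image tokens are merged 2x2 (grid halves:
56 -> 28 -> 14 -> 7) while text and global tokens are re-projected to the
next width.

Design choices the source architecture leaves open are made here and
documented in the methods note: no positional encodings (spatial structure
enters via window partitioning only), pre-norm feed-forward residuals,
dedicated projections for each attention operation, and a classifier head
over mean-pooled image tokens concatenated with both global-token means.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass, field

import numpy as np

from . import autodiff as ad
from .attention import (AttentionParams, GateParams, QKVParams, TokenSequence,
                        compute_gate, cross_attention, init_attention,
                        init_gate, init_qkv, window_self_attention)
from .autodiff import Tensor
from .errors import ConfigError, DimensionError

VARIANTS = ("b", "ai", "aip", "bip")


@dataclass
class ModelConfig:
    stage_depths: tuple = (1, 3, 3, 1)
    stage_widths: tuple = (64, 128, 256, 512)
    heads: tuple = (2, 4, 8, 16)
    window: int = 7
    variant: str = "ai"
    pca_k: int = 6
    n_text_global: int = 1
    n_img_global: int = 1
    text_global_dim: int = 256
    mlp_ratio: float = 4.0
    n_classes: int = 5
    img_size: int = 224

    def __post_init__(self):
        self.stage_depths = tuple(int(d) for d in self.stage_depths)
        self.stage_widths = tuple(int(w) for w in self.stage_widths)
        self.heads = tuple(int(h) for h in self.heads)
        if self.variant not in VARIANTS:
            raise ConfigError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if len(self.stage_depths) != 4 or len(self.stage_widths) != 4 or len(self.heads) != 4:
            raise ConfigError("stage_depths, stage_widths and heads must have 4 entries")
        if any(d < 1 for d in self.stage_depths):
            raise ConfigError("stage depths must be positive")
        for w, h in zip(self.stage_widths, self.heads):
            if w % h:
                raise ConfigError(f"stage width {w} not divisible by heads {h}")
        if self.img_size % 4:
            raise ConfigError("img_size must be divisible by 4 (stem downsamples 4x)")
        g = self.img_size // 4
        for s in range(4):
            if g % self.window:
                raise ConfigError(
                    f"stage-{s + 1} grid {g} not divisible by window {self.window}")
            if s < 3 and g % 2:
                raise ConfigError(f"stage-{s + 1} grid {g} is odd; cannot merge 2x2")
            g //= 2
        if self.n_text_global < 1 or self.n_img_global < 1:
            raise ConfigError("need at least one global token per modality")

    @property
    def stem_grid(self) -> int:
        return self.img_size // 4

    def grid_at(self, stage: int) -> int:
        return self.stem_grid // (2 ** stage)


# ------------------------------------------------------------------ modules

class Module:
    """Parameter-container base: recursive named-tensor collection."""

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Tensor):
                if val.requires_grad:
                    out[key] = val
            elif isinstance(val, Module):
                out.update(val.named_parameters(f"{key}."))
            elif isinstance(val, (AttentionParams, QKVParams, GateParams)):
                for tn, t in val.tensors().items():
                    out[f"{key}.{tn}"] = t
            elif isinstance(val, (list, tuple)):
                out.update(_collect_seq(val, key))
        return out


def _collect_seq(seq, prefix: str) -> dict[str, Tensor]:
    out: dict[str, Tensor] = {}
    for i, item in enumerate(seq):
        key = f"{prefix}.{i}"
        if isinstance(item, Module):
            out.update(item.named_parameters(f"{key}."))
        elif isinstance(item, (list, tuple)):
            out.update(_collect_seq(item, key))
    return out


class Linear(Module):
    def __init__(self, c_in: int, c_out: int, rng, init_scale: float = 0.02):
        self.w = ad.parameter(rng.normal(0.0, init_scale, size=(c_in, c_out)))
        self.b = ad.parameter(np.zeros(c_out))

    def __call__(self, x):
        return ad.linear(x, self.w, self.b)


class LayerNorm(Module):
    def __init__(self, c: int):
        self.g = ad.parameter(np.ones(c))
        self.b = ad.parameter(np.zeros(c))

    def __call__(self, x):
        return ad.layer_norm(x, self.g, self.b)


class FeedForward(Module):
    """Pre-norm residual MLP: x + W2 relu(W1 LN(x))."""

    def __init__(self, c: int, ratio: float, rng):
        hidden = int(round(c * ratio))
        self.ln = LayerNorm(c)
        self.fc1 = Linear(c, hidden, rng)
        self.fc2 = Linear(hidden, c, rng)

    def __call__(self, x):
        return x + self.fc2(ad.relu(self.fc1(self.ln(x))))


class ITSAIBlock(Module):
    """Intra-modal enhancement, gated image<-text retrieval, global interact.

    Variants: ``ai`` (unidirectional, image gate), ``b`` (bidirectional with
    a learned softmax-normalized scalar pair, no gates), ``aip`` (``ai``
    plus a text gate modulating a pooled-image broadcast), ``bip``
    (bidirectional with both gates).
    """

    def __init__(self, c: int, heads: int, window: int, variant: str, rng,
                 mlp_ratio: float = 4.0):
        self.variant = variant
        self.window = window
        self.shared = init_qkv(c, heads, rng)  # Q/K/V over the full sequence
        self.wo_img = Linear(c, c, rng)   # output proj of the windowed branch
        self.wo_txt = Linear(c, c, rng)   # output proj of the text branch
        self.cross_it = init_attention(c, heads, rng)  # image queries text
        if variant in ("b", "bip"):
            self.cross_ti = init_attention(c, heads, rng)  # text queries image
        if variant == "b":
            self.pair = ad.parameter(np.zeros(2))
        if variant in ("ai", "aip", "bip"):
            self.gate = init_gate(c, rng)
        if variant in ("aip", "bip"):
            self.gate_txt = init_gate(c, rng)
        if variant == "aip":
            self.pool_proj = Linear(c, c, rng)
        self.glob_interact = init_attention(c, heads, rng)
        self.ffn = FeedForward(c, mlp_ratio, rng)

    def __call__(self, seq: TokenSequence, disable_fusion: bool = False) -> TokenSequence:
        from .attention import partition_qkv, _scaled_attention, _split_heads, _merge_heads
        tokens = ad.as_tensor(seq.tokens)
        sl_img, sl_txt, sl_glob = seq.slices()
        img_in, txt_in = tokens[:, sl_img, :], tokens[:, sl_txt, :]
        glob = tokens[:, sl_glob, :]
        c = tokens.shape[-1]
        heads = self.shared.heads
        d = c // heads

        (qi, ki, vi), (qt, kt, vt), _ = partition_qkv(seq, self.shared)

        # windowed local self-attention on the image tokens
        g_side, w_ = seq.grid_side, self.window
        nw = g_side // w_
        b = tokens.shape[0]

        def tile(x):
            x = ad.reshape(x, (b, nw, w_, nw, w_, c))
            x = ad.transpose(x, (0, 1, 3, 2, 4, 5))
            return ad.reshape(x, (b * nw * nw, w_ * w_, c))

        ti, tk, tv = tile(qi), tile(ki), tile(vi)
        out, _w = _scaled_attention(_split_heads(ti, heads), _split_heads(tk, heads),
                                    _split_heads(tv, heads), d)
        out = _merge_heads(out)
        out = ad.reshape(out, (b, nw, nw, w_, w_, c))
        out = ad.transpose(out, (0, 1, 3, 2, 4, 5))
        img_sa = self.wo_img(ad.reshape(out, (b, g_side * g_side, c)))
        img1 = img_in + img_sa

        # global self-attention on the text tokens
        out, _w = _scaled_attention(_split_heads(qt, heads), _split_heads(kt, heads),
                                    _split_heads(vt, heads), d)
        txt1 = txt_in + self.wo_txt(_merge_heads(out))

        # directed cross-modal retrieval with gated fusion
        img2, txt2 = img1, txt1
        if not disable_fusion:
            x_img = cross_attention(img1, txt1, self.cross_it)
            if self.variant == "ai":
                g = compute_gate(img1, txt1, self.gate)
                img2 = img1 + g * x_img
            elif self.variant == "b":
                w_pair = ad.softmax(self.pair, axis=-1)
                x_txt = cross_attention(txt1, img1, self.cross_ti)
                img2 = img1 + w_pair[0:1] * x_img
                txt2 = txt1 + w_pair[1:2] * x_txt
            elif self.variant == "aip":
                g = compute_gate(img1, txt1, self.gate)
                g_t = compute_gate(img1, txt1, self.gate_txt)
                img2 = img1 + g * x_img
                pooled = self.pool_proj(ad.mean(img1, axis=-2, keepdims=True))
                txt2 = txt1 + g_t * pooled
            elif self.variant == "bip":
                g = compute_gate(img1, txt1, self.gate)
                g_t = compute_gate(img1, txt1, self.gate_txt)
                x_txt = cross_attention(txt1, img1, self.cross_ti)
                img2 = img1 + g * x_img
                txt2 = txt1 + g_t * x_txt

        # all image/text tokens attend to the global memory tokens
        u = ad.concat([img2, txt2], axis=-2)
        u = u + cross_attention(u, glob, self.glob_interact)

        out_tokens = self.ffn(ad.concat([u, glob], axis=-2))
        return TokenSequence(out_tokens, seq.boundaries, seq.grid_side)


class ITLeSAMMBlock(Module):
    """Global-token aggregation and broadcast.

    Each modality's global tokens query that modality (aggregation), then
    image and text tokens query the refreshed global tokens (broadcast).
    Residual connections keep identity paths; a pre-norm feed-forward
    closes the block.
    """

    def __init__(self, c: int, heads: int, n_img_global: int, n_text_global: int,
                 rng, mlp_ratio: float = 4.0):
        self.n_img_global = n_img_global
        self.n_text_global = n_text_global
        self.agg_img = init_attention(c, heads, rng)
        self.agg_txt = init_attention(c, heads, rng)
        self.bc_img = init_attention(c, heads, rng)
        self.bc_txt = init_attention(c, heads, rng)
        self.ffn = FeedForward(c, mlp_ratio, rng)

    def __call__(self, seq: TokenSequence) -> TokenSequence:
        if seq.n_glob != self.n_img_global + self.n_text_global:
            raise ConfigError(
                f"sequence has {seq.n_glob} global tokens, block expects "
                f"{self.n_img_global + self.n_text_global}")
        tokens = ad.as_tensor(seq.tokens)
        sl_img, sl_txt, sl_glob = seq.slices()
        img, txt = tokens[:, sl_img, :], tokens[:, sl_txt, :]
        glob = tokens[:, sl_glob, :]
        g_img = glob[:, :self.n_img_global, :]
        g_txt = glob[:, self.n_img_global:, :]

        g_img = g_img + cross_attention(g_img, img, self.agg_img)
        g_txt = g_txt + cross_attention(g_txt, txt, self.agg_txt)
        gg = ad.concat([g_img, g_txt], axis=-2)

        img = img + cross_attention(img, gg, self.bc_img)
        txt = txt + cross_attention(txt, gg, self.bc_txt)

        out_tokens = self.ffn(ad.concat([img, txt, gg], axis=-2))
        return TokenSequence(out_tokens, seq.boundaries, seq.grid_side)


class StageTransition(Module):
    """2x2 image-token merge to the next width; text/global re-projection."""

    def __init__(self, c_in: int, c_out: int, rng):
        self.merge = Linear(4 * c_in, c_out, rng)
        self.proj_txt = Linear(c_in, c_out, rng)
        self.proj_glob = Linear(c_in, c_out, rng)

    def __call__(self, seq: TokenSequence) -> TokenSequence:
        g = seq.grid_side
        if g % 2:
            raise DimensionError(f"cannot merge an odd grid side {g}")
        tokens = ad.as_tensor(seq.tokens)
        sl_img, sl_txt, sl_glob = seq.slices()
        img, txt = tokens[:, sl_img, :], tokens[:, sl_txt, :]
        glob = tokens[:, sl_glob, :]
        b, _, c = img.shape
        h = g // 2
        x = ad.reshape(img, (b, h, 2, h, 2, c))
        x = ad.transpose(x, (0, 1, 3, 2, 4, 5))       # (B, h, h, 2, 2, C)
        x = ad.reshape(x, (b, h * h, 4 * c))           # [tl, tr, bl, br]
        img = self.merge(x)
        txt = self.proj_txt(txt)
        glob = self.proj_glob(glob)
        out = ad.concat([img, txt, glob], axis=-2)
        return TokenSequence(out, (h * h, seq.n_txt, seq.n_glob), h)


class MmVitnNet(Module):
    """End-to-end network: stem, text embedding, 4 stages, classifier."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c1 = config.stage_widths[0]
        self.stem_w = ad.parameter(rng.normal(0.0, 0.05, size=(c1, 3, 3, 3)))
        self.stem_b = ad.parameter(np.zeros(c1))
        # per-position affine embedding of the k reduced text features
        self.embed_scale = ad.parameter(rng.normal(0.0, 0.5, size=(config.pca_k, c1)))
        self.embed_bias = ad.parameter(np.zeros((config.pca_k, c1)))
        # learnable global memories; the text memory lives in a fixed
        # 256-dim space and is projected into the first stage width
        self.img_global = ad.parameter(
            rng.normal(0.0, 0.02, size=(config.n_img_global, c1)))
        self.txt_global = ad.parameter(
            rng.normal(0.0, 0.02, size=(config.n_text_global, config.text_global_dim)))
        self.txt_global_proj = Linear(config.text_global_dim, c1, rng)

        self.stages: list[list[Module]] = []
        self.transitions: list[StageTransition] = []
        for s in range(4):
            c, h = config.stage_widths[s], config.heads[s]
            blocks: list[Module] = []
            for _ in range(config.stage_depths[s]):
                if s < 3:
                    blocks.append(ITSAIBlock(c, h, config.window, config.variant,
                                             rng, config.mlp_ratio))
                blocks.append(ITLeSAMMBlock(c, h, config.n_img_global,
                                            config.n_text_global, rng,
                                            config.mlp_ratio))
            self.stages.append(blocks)
            if s < 3:
                self.transitions.append(
                    StageTransition(c, config.stage_widths[s + 1], rng))
        c4 = config.stage_widths[3]
        self.head_ln = LayerNorm(4 * c4)
        self.head = Linear(4 * c4, config.n_classes, rng)

    # -- sub-forwards ------------------------------------------------

    def stem_forward(self, images: np.ndarray) -> Tensor:
        """(B, H, W, 3) in [0,1] -> (B, grid^2, C1) row-major tokens."""
        images = np.asarray(images, dtype=float)
        if images.ndim == 3:
            images = images[None]
        s = self.config.img_size
        if images.shape[1:] != (s, s, 3):
            raise DimensionError(
                f"stem expects {s}x{s}x3 input, got {images.shape[1:]}")
        x = (images - 0.5) / 0.5  # standardize to [-1, 1]
        x = ad.Tensor(np.transpose(x, (0, 3, 1, 2)))
        x = ad.conv2d(x, self.stem_w, self.stem_b, stride=2, pad=1)
        x = ad.maxpool2x2(x)
        b, c, g, _ = x.shape
        return ad.reshape(ad.transpose(x, (0, 2, 3, 1)), (b, g * g, c))

    def embed_text(self, features: np.ndarray) -> Tensor:
        """(B, k) reduced features -> (B, k, C1) tokens, one per component."""
        features = np.asarray(features, dtype=float)
        if features.ndim == 1:
            features = features[None]
        if features.shape[1] != self.config.pca_k:
            raise DimensionError(
                f"expected {self.config.pca_k} text features, got {features.shape[1]}")
        f = ad.Tensor(features[:, :, None])  # (B, k, 1)
        return ad.add(ad.mul(f, self.embed_scale), self.embed_bias)

    def assemble(self, images, text) -> TokenSequence:
        img_tok = self.stem_forward(images)
        txt_tok = self.embed_text(text)
        b = img_tok.shape[0]
        zeros = ad.Tensor(np.zeros((b, 1, 1)))
        g_img = ad.add(self.img_global, zeros)  # broadcast over batch
        g_txt = ad.add(self.txt_global_proj(self.txt_global), zeros)
        glob = ad.concat([g_img, g_txt], axis=-2)
        tokens = ad.concat([img_tok, txt_tok, glob], axis=-2)
        n_glob = self.config.n_img_global + self.config.n_text_global
        return TokenSequence(tokens, (img_tok.shape[1], self.config.pca_k, n_glob),
                             self.config.stem_grid)

    def forward(self, images, text, disable_fusion: bool = False) -> Tensor:
        """Class logits ``(B, n_classes)`` for a batch of image/text pairs."""
        seq = self.assemble(images, text)
        for s in range(4):
            for block in self.stages[s]:
                if isinstance(block, ITSAIBlock):
                    seq = block(seq, disable_fusion=disable_fusion)
                else:
                    seq = block(seq)
            if s < 3:
                seq = self.transitions[s](seq)
        tokens = ad.as_tensor(seq.tokens)
        sl_img, sl_txt, sl_glob = seq.slices()
        img_mean = ad.mean(tokens[:, sl_img, :], axis=-2)
        txt_mean = ad.mean(tokens[:, sl_txt, :], axis=-2)
        glob = tokens[:, sl_glob, :]
        gi = ad.mean(glob[:, :self.config.n_img_global, :], axis=-2)
        gt = ad.mean(glob[:, self.config.n_img_global:, :], axis=-2)
        pooled = ad.concat([img_mean, txt_mean, gi, gt], axis=-1)
        return self.head(self.head_ln(pooled))

    __call__ = forward


# --------------------------------------------------------------- accounting

def count_parameters(config: ModelConfig) -> int:
    """Exact trainable scalar count for a configuration."""
    model = MmVitnNet(config, seed=0)
    return int(sum(t.data.size for t in model.named_parameters().values()))


def _attn_flops(n_q: int, n_kv: int, c: int) -> int:
    proj = n_q * c * c + 2 * n_kv * c * c + n_q * c * c
    scores = n_q * n_kv * c  # summed over heads
    return proj + 2 * scores


def count_flops(config: ModelConfig, input_side: int | None = None) -> int:
    """Multiply-add count of conv/linear/attention ops for one forward."""
    side = config.img_size if input_side is None else input_side
    g = side // 4
    k = config.pca_k
    ng = config.n_img_global + config.n_text_global
    total = 0
    # stem conv at stride 2 and the text/global embeddings
    total += config.stage_widths[0] * 3 * 9 * (side // 2) ** 2
    total += k * config.stage_widths[0]
    total += config.n_text_global * config.text_global_dim * config.stage_widths[0]
    for s in range(4):
        c = config.stage_widths[s]
        n_img = g ** 2
        n_all = n_img + k + ng
        hidden = int(round(c * config.mlp_ratio))
        for _ in range(config.stage_depths[s]):
            if s < 3:
                # shared QKV + windowed image SA + text SA + output projs
                total += 3 * n_all * c * c
                total += 2 * n_img * (config.window ** 2) * c  # window scores+AV
                total += n_img * c * c
                total += 2 * k * k * c + k * c * c
                total += _attn_flops(n_img, k, c)              # image queries text
                if config.variant in ("b", "bip"):
                    total += _attn_flops(k, n_img, c)
                if config.variant in ("ai", "aip", "bip"):
                    total += 2 * c * c + c                      # gate MLP
                if config.variant in ("aip", "bip"):
                    total += 2 * c * c + c
                if config.variant == "aip":
                    total += c * c
                total += _attn_flops(n_img + k, ng, c)          # global interact
                total += 2 * n_all * c * hidden                 # FFN
            # ITLeSAMM
            total += _attn_flops(ng, n_img, c) + _attn_flops(ng, k, c)
            total += _attn_flops(n_img, ng, c) + _attn_flops(k, ng, c)
            total += 2 * n_all * c * hidden
        if s < 3:
            c_next = config.stage_widths[s + 1]
            total += (g // 2) ** 2 * 4 * c * c_next
            total += (k + ng) * c * c_next
            g //= 2
    total += 4 * config.stage_widths[3] * config.n_classes
    return int(total)


def model_summary(config: ModelConfig) -> dict:
    """JSON-serializable parameter/FLOP summary."""
    return {
        "config": asdict(config),
        "parameters": count_parameters(config),
        "flops_224": count_flops(config),
        "grids": [config.grid_at(s) for s in range(4)],
    }


# --------------------------------------------------------------- checkpoint

def save_checkpoint(model: MmVitnNet, path, extra: dict | None = None) -> None:
    """Single-file archive: config JSON + named float64 parameter arrays."""
    params = model.named_parameters()
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        meta = {"config": asdict(model.config), "extra": extra or {}}
        zf.writestr("config.json", json.dumps(meta))
        for name, t in params.items():
            buf = io.BytesIO()
            np.save(buf, t.data)
            zf.writestr(f"params/{name}.npy", buf.getvalue())


def load_checkpoint(path) -> MmVitnNet:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("config.json"))
        config = ModelConfig(**meta["config"])
        model = MmVitnNet(config, seed=0)
        params = model.named_parameters()
        for name, t in params.items():
            data = np.load(io.BytesIO(zf.read(f"params/{name}.npy")))
            if data.shape != t.data.shape:
                raise ConfigError(f"checkpoint shape mismatch for {name}")
            t.data = data
    return model
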