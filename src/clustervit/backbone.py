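"""Hierarchical multi-[cls]-token vision transformer with clustering attention.

The encoder replaces the single classification token of a ViT with a set of
learnable [cls] tokens whose count shrinks stage by stage. Each stage is a
standard pre-norm multi-head self-attention (MSA) block stack followed by a
*semantic clustering block*: a cross-attention that soft-assigns input tokens
to the stage's [cls] tokens,

    Attn[i, j] = softmax_j( (W_p x_i) . (W_c c_j) + gamma_j )          (assignment)
    c'_j = c_j + W . ( sum_i Attn[i, j] W_v x_i / sum_i Attn[i, j] )   (update)

i.e. each [cls] token is moved toward the attention-weighted *mean* of its
assigned inputs (note the column-sum normalizer) with a residual connection.
Stage 0 clusters patch tokens; later stages cluster the previous stage's
output [cls] tokens together with a fresh, smaller learnable set. The final
embedding is the average of the last stage's [cls] tokens.

Per-token attention maps are recovered by composing the row-stochastic
assignment matrices down the hierarchy (a product of row-stochastic matrices
is row-stochastic) and bilinearly upsampling from the patch grid to pixels.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import yaml
from scipy import ndimage

from .autodiff import Tensor, concat, gelu, log_softmax, matmul, softmax

__all__ = [
    "BackboneConfig",
    "TokenSet",
    "ClusterAttention",
    "ClusterBlockWeights",
    "AttentionMapStack",
    "init_params",
    "patch_embed",
    "multi_head_attention",
    "msa_block",
    "clustering_attention",
    "update_cls_tokens",
    "forward_features",
    "forward",
    "extract_attention_maps",
    "count_params",
    "save_params",
    "load_params",
]


class ConfigError(ValueError):
    """An architectural hyperparameter violates an invariant."""


class NumericError(FloatingPointError):
    """Non-finite values encountered during a forward pass."""


# ----------------------------------------------------------------- config
@dataclass(frozen=True)
class BackboneConfig:
    """Architectural hyperparameters of the encoder.

    Parameters
    ----------
    image_size, patch_size : int
        Tile side and patch side in pixels; ``image_size`` must be divisible
        by ``patch_size``. The patch grid has ``(image_size/patch_size)**2``
        cells, row-major, 0-based.
    embed_dim, n_heads : int
        Token width d and MSA head count; d must be divisible by heads.
    stage_cls_counts : list of int
        Number of learnable [cls] tokens per stage, strictly decreasing —
        the hierarchy coarsens as features become more abstract.
    msa_blocks_per_stage : list of int
        Depth of the self-attention stack preceding each clustering block.
    mlp_ratio : float
        Hidden width of the MSA blocks' MLP relative to d.
    scaled_cluster_logits : bool
        If True, divide the clustering similarity by sqrt(d) before the
        softmax (off by default: the assignment rule is an unscaled dot
        product).
    """

    image_size: int = 224
    patch_size: int = 16
    embed_dim: int = 384
    n_heads: int = 6
    stage_cls_counts: tuple = (16, 8, 4)
    msa_blocks_per_stage: tuple = (6, 4, 2)
    use_positional_encoding: bool = True
    mlp_ratio: float = 4.0
    scaled_cluster_logits: bool = False

    def __post_init__(self):
        object.__setattr__(self, "stage_cls_counts", tuple(self.stage_cls_counts))
        object.__setattr__(
            self, "msa_blocks_per_stage", tuple(self.msa_blocks_per_stage)
        )
        if self.image_size % self.patch_size != 0:
            raise ConfigError(
                f"image_size {self.image_size} not divisible by patch_size "
                f"{self.patch_size}"
            )
        if self.embed_dim % self.n_heads != 0:
            raise ConfigError(
                f"embed_dim {self.embed_dim} not divisible by n_heads {self.n_heads}"
            )
        if len(self.msa_blocks_per_stage) != len(self.stage_cls_counts):
            raise ConfigError("msa_blocks_per_stage and stage_cls_counts lengths differ")
        if not self.stage_cls_counts:
            raise ConfigError("at least one stage required")
        counts = self.stage_cls_counts
        if any(counts[i + 1] >= counts[i] for i in range(len(counts) - 1)):
            raise ConfigError(
                f"stage_cls_counts must be strictly decreasing, got {counts}"
            )
        if any(c < 1 for c in counts) or any(m < 1 for m in self.msa_blocks_per_stage):
            raise ConfigError("stage sizes must be positive")

    @property
    def grid(self) -> int:
        return self.image_size // self.patch_size

    @property
    def n_patches(self) -> int:
        return self.grid**2

    @property
    def n_stages(self) -> int:
        return len(self.stage_cls_counts)

    # presets ------------------------------------------------------------
    @classmethod
    def small(cls) -> "BackboneConfig":
        """ViT-small-compatible footing: d=384, 6 heads, 12 MSA blocks."""
        return cls()

    @classmethod
    def tiny(cls) -> "BackboneConfig":
        """CPU-scale preset for desk experiments: 64 px tiles, d=64."""
        return cls(
            image_size=64,
            patch_size=8,
            embed_dim=64,
            n_heads=4,
            stage_cls_counts=(8, 4, 2),
            msa_blocks_per_stage=(2, 2, 1),
            mlp_ratio=2.0,
        )

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in dataclasses.asdict(self).items()
                },
                fh,
            )

    @classmethod
    def from_yaml(cls, path) -> "BackboneConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)


# ------------------------------------------------------------------ types
@dataclass
class TokenSet:
    """An ordered set of d-dimensional tokens with a role and stage tag."""

    vectors: Tensor
    role: str  # "patch" | "cls"
    stage: int

    def __post_init__(self):
        if not isinstance(self.vectors, Tensor):
            self.vectors = Tensor(np.asarray(self.vectors, dtype=np.float64))
        if self.role not in ("patch", "cls"):
            raise ValueError(f"role must be 'patch' or 'cls', got {self.role!r}")
        if not np.all(np.isfinite(self.vectors.data)):
            raise NumericError(f"non-finite token values at stage {self.stage}")

    @property
    def count(self) -> int:
        return self.vectors.shape[-2]


@dataclass
class ClusterAttention:
    """Row-stochastic soft assignment of inputs to [cls] tokens."""

    weights: np.ndarray  # (..., N_inputs, N_c)
    stage: int

    def __post_init__(self):
        w = np.asarray(self.weights.data if isinstance(self.weights, Tensor) else self.weights)
        rows = w.sum(axis=-1)
        if not np.allclose(rows, 1.0, atol=1e-6):
            raise NumericError(
                f"assignment rows do not sum to 1 at stage {self.stage}"
            )


@dataclass
class ClusterBlockWeights:
    """Learnable projections of one semantic clustering block (per stage)."""

    patch_projection: Tensor  # W_p, d x d
    cls_projection: Tensor  # W_c, d x d
    value_projection: Tensor  # W_v, d x d
    output_projection: Tensor  # W, d x d
    token_bias: Tensor  # gamma, (N_c,)

    def __post_init__(self):
        for name in ("patch_projection", "cls_projection", "value_projection",
                     "output_projection", "token_bias"):
            v = getattr(self, name)
            if not isinstance(v, Tensor):
                setattr(self, name, Tensor(np.asarray(v, dtype=np.float64)))


@dataclass
class AttentionMapStack:
    """Per-[cls]-token attention maps at tile resolution; pixelwise simplex."""

    maps: np.ndarray  # (N_c, H, W)
    stage: int

    def __post_init__(self):
        self.maps = np.asarray(self.maps)
        if self.maps.min() < -1e-6 or self.maps.max() > 1 + 1e-6:
            raise NumericError("attention map values outside [0, 1]")


# ---------------------------------------------------------------- init
def _trunc_normal(rng: np.random.Generator, shape, std=0.02):
    x = rng.normal(0.0, std, size=shape)
    return np.clip(x, -2 * std, 2 * std)


def _xavier(rng: np.random.Generator, shape):
    """Xavier/Glorot uniform — unit-gain init for projection matrices.

    The clustering hierarchy re-roots the residual stream at the [cls]
    tokens every stage, so the input signal survives only through the
    projections; a 0.02-std init would attenuate it to nothing by the final
    stage, while unit gain preserves it."""
    limit = math.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


def init_params(
    cfg: BackboneConfig, rng: np.random.Generator, dtype=np.float32
) -> dict[str, Tensor]:
    """Initialize all encoder parameters.

    [cls] tokens and linear weights: truncated normal, std 0.02 (standard
    transformer init); biases, gamma and layer-norm offsets: zero; layer-norm
    gains: one.
    """
    d = cfg.embed_dim
    p: dict[str, np.ndarray] = {}
    patch_dim = cfg.patch_size * cfg.patch_size * 3
    p["patch_embed.w"] = _xavier(rng, (patch_dim, d))
    p["patch_embed.b"] = np.zeros(d)
    if cfg.use_positional_encoding:
        p["pos_embed"] = _trunc_normal(rng, (cfg.n_patches, d))
    for s, (n_cls, depth) in enumerate(
        zip(cfg.stage_cls_counts, cfg.msa_blocks_per_stage)
    ):
        p[f"stage{s}.cls"] = _trunc_normal(rng, (n_cls, d))
        for b in range(depth):
            pre = f"stage{s}.msa{b}"
            p[f"{pre}.ln1.g"] = np.ones(d)
            p[f"{pre}.ln1.b"] = np.zeros(d)
            for w in ("wq", "wk", "wv", "wo"):
                p[f"{pre}.{w}"] = _xavier(rng, (d, d))
                p[f"{pre}.{w}_b"] = np.zeros(d)
            p[f"{pre}.ln2.g"] = np.ones(d)
            p[f"{pre}.ln2.b"] = np.zeros(d)
            hidden = int(d * cfg.mlp_ratio)
            p[f"{pre}.mlp.w1"] = _xavier(rng, (d, hidden))
            p[f"{pre}.mlp.b1"] = np.zeros(hidden)
            p[f"{pre}.mlp.w2"] = _xavier(rng, (hidden, d))
            p[f"{pre}.mlp.b2"] = np.zeros(d)
        pre = f"stage{s}.cluster"
        p[f"{pre}.wp"] = _xavier(rng, (d, d))
        p[f"{pre}.wc"] = _xavier(rng, (d, d))
        p[f"{pre}.wv"] = _xavier(rng, (d, d))
        p[f"{pre}.w"] = _xavier(rng, (d, d))
        p[f"{pre}.gamma"] = np.zeros(n_cls)
    return {k: Tensor(v.astype(dtype), requires_grad=True) for k, v in p.items()}


def cluster_weights(params: dict, stage: int) -> ClusterBlockWeights:
    pre = f"stage{stage}.cluster"
    return ClusterBlockWeights(
        patch_projection=params[f"{pre}.wp"],
        cls_projection=params[f"{pre}.wc"],
        value_projection=params[f"{pre}.wv"],
        output_projection=params[f"{pre}.w"],
        token_bias=params[f"{pre}.gamma"],
    )


def count_params(params: dict) -> int:
    return int(sum(t.data.size for t in params.values()))


def save_params(params: dict, path):
    np.savez(path, **{k: v.data for k, v in params.items()})


def load_params(path, requires_grad: bool = True) -> dict[str, Tensor]:
    with np.load(path) as npz:
        return {k: Tensor(npz[k].copy(), requires_grad=requires_grad) for k in npz.files}


# ------------------------------------------------------------- operations
def _as_image_batch(tile) -> np.ndarray:
    x = np.asarray(tile, dtype=np.float64)
    if x.ndim == 3:
        x = x[None]
    if x.ndim != 4 or x.shape[-1] != 3:
        raise ValueError(f"expected RGB image(s) (H, W, 3), got shape {x.shape}")
    if x.max() > 1.5:  # 8-bit input
        x = x / 255.0
    return x


def _pos_interp_matrix(src_grid: int, dst_grid: int) -> np.ndarray:
    """Linear map taking a flattened src_grid^2 table to a dst_grid^2 one.

    Bilinear, align-corners off (pixel-center convention), so views smaller
    than the configured image reuse the positional table consistently.
    """
    if src_grid == dst_grid:
        return np.eye(src_grid * src_grid)
    r = np.zeros((dst_grid, src_grid))
    scale = src_grid / dst_grid
    for t in range(dst_grid):
        s = (t + 0.5) * scale - 0.5
        s = min(max(s, 0.0), src_grid - 1.0)
        lo = int(math.floor(s))
        hi = min(lo + 1, src_grid - 1)
        w = s - lo
        r[t, lo] += 1.0 - w
        r[t, hi] += w
    return np.kron(r, r)


def patch_embed(tile, cfg: BackboneConfig, params: dict) -> TokenSet:
    """Embed an RGB tile into a row-major grid of patch tokens (stage 0).

    Accepts a single (H, W, 3) tile or a (B, H, W, 3) batch; pixel values in
    [0, 1] (8-bit inputs are rescaled). Positional encodings are added iff
    configured; tiles smaller than ``cfg.image_size`` (multi-crop local
    views) get a bilinearly resampled positional table.
    """
    x = _as_image_batch(tile)
    h, w = x.shape[1], x.shape[2]
    if h != w:
        raise ValueError(f"tiles must be square, got {h}x{w}")
    if h % cfg.patch_size != 0:
        raise ConfigError(f"tile side {h} not divisible by patch {cfg.patch_size}")
    if h > cfg.image_size:
        raise ValueError(f"tile side {h} exceeds configured image_size")
    g = h // cfg.patch_size
    ps = cfg.patch_size
    b = x.shape[0]
    # (B, g, ps, g, ps, 3) -> (B, g*g, ps*ps*3), row-major patch order
    patches = (
        x.reshape(b, g, ps, g, ps, 3)
        .transpose(0, 1, 3, 2, 4, 5)
        .reshape(b, g * g, ps * ps * 3)
    )
    dtype = params["patch_embed.w"].data.dtype
    tokens = matmul(Tensor(patches.astype(dtype)), params["patch_embed.w"])
    tokens = tokens + params["patch_embed.b"]
    if cfg.use_positional_encoding:
        pos = params["pos_embed"]
        if g != cfg.grid:
            interp = Tensor(_pos_interp_matrix(cfg.grid, g).astype(dtype))
            pos = matmul(interp, pos)
        tokens = tokens + pos
    out = tokens if np.asarray(tile).ndim == 4 else tokens.reshape(tokens.shape[1:])
    return TokenSet(vectors=out, role="patch", stage=0)


def layer_norm(x: Tensor, g: Tensor, b: Tensor, eps: float = 1e-6) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc / (var + eps).sqrt() * g + b


def multi_head_attention(
    x: Tensor, wq: Tensor, wk: Tensor, wv: Tensor, wo: Tensor, n_heads: int,
    bq=None, bk=None, bv=None, bo=None,
) -> Tensor:
    """Scaled dot-product multi-head self-attention on (..., N, d) tokens."""
    if not isinstance(x, Tensor):
        x = Tensor(x)
    d = x.shape[-1]
    if wq.shape != (d, d):
        raise ConfigError(f"attention weights {wq.shape} mismatch token dim {d}")
    dh = d // n_heads
    n = x.shape[-2]
    lead = x.shape[:-2]

    def heads(t: Tensor) -> Tensor:
        return t.reshape(lead + (n, n_heads, dh)).transpose(
            tuple(range(len(lead))) + (len(lead) + 1, len(lead), len(lead) + 2)
        )

    q = matmul(x, wq)
    k = matmul(x, wk)
    v = matmul(x, wv)
    if bq is not None:
        q, k, v = q + bq, k + bk, v + bv
    q, k, v = heads(q), heads(k), heads(v)
    logits = matmul(q, k.swap_last2()) * (1.0 / math.sqrt(dh))
    attn = softmax(logits, axis=-1)
    ctx = matmul(attn, v)  # (..., heads, N, dh)
    ctx = ctx.transpose(
        tuple(range(len(lead))) + (len(lead) + 1, len(lead), len(lead) + 2)
    ).reshape(lead + (n, d))
    out = matmul(ctx, wo)
    return out + bo if bo is not None else out


def msa_block(tokens, params: dict, prefix: str, n_heads: int) -> Tensor:
    """Pre-norm transformer block: MSA and MLP branches, each residual."""
    x = tokens if isinstance(tokens, Tensor) else Tensor(np.asarray(tokens))
    attn = multi_head_attention(
        layer_norm(x, params[f"{prefix}.ln1.g"], params[f"{prefix}.ln1.b"]),
        params[f"{prefix}.wq"], params[f"{prefix}.wk"],
        params[f"{prefix}.wv"], params[f"{prefix}.wo"], n_heads,
        params[f"{prefix}.wq_b"], params[f"{prefix}.wk_b"],
        params[f"{prefix}.wv_b"], params[f"{prefix}.wo_b"],
    )
    x = x + attn
    h = layer_norm(x, params[f"{prefix}.ln2.g"], params[f"{prefix}.ln2.b"])
    h = gelu(matmul(h, params[f"{prefix}.mlp.w1"]) + params[f"{prefix}.mlp.b1"])
    h = matmul(h, params[f"{prefix}.mlp.w2"]) + params[f"{prefix}.mlp.b2"]
    return x + h


def clustering_attention(
    inputs: TokenSet,
    cls: TokenSet,
    w: ClusterBlockWeights,
    scaled: bool = False,
    as_tensor: bool = False,
):
    """Soft-assign input tokens to [cls] tokens (the clustering softmax).

    ``Attn[i, j] = exp((W_p x_i).(W_c c_j) + gamma_j) / sum_u exp(...)``,
    computed with a shifted softmax for numerical stability. Rows index
    inputs (patches at stage 0, previous-stage [cls] tokens above), columns
    index the current stage's [cls] tokens.
    """
    logits, stage = _cluster_logits(inputs, cls, w, scaled)
    attn = softmax(logits, axis=-1)
    if as_tensor:
        return attn
    return ClusterAttention(weights=attn.data, stage=stage)


def _cluster_logits(inputs, cls, w: ClusterBlockWeights, scaled: bool):
    x = inputs.vectors if isinstance(inputs, TokenSet) else Tensor._wrap(inputs)
    c = cls.vectors if isinstance(cls, TokenSet) else Tensor._wrap(cls)
    stage = cls.stage if isinstance(cls, TokenSet) else 0
    px = matmul(x, w.patch_projection)  # (..., N_in, d)
    pc = matmul(c, w.cls_projection)  # (..., N_c, d)
    logits = matmul(px, pc.swap_last2()) + w.token_bias
    if scaled:
        logits = logits * (1.0 / math.sqrt(x.shape[-1]))
    if not np.all(np.isfinite(logits.data)):
        bad = np.argwhere(~np.isfinite(logits.data))[0]
        raise NumericError(
            f"non-finite clustering logits at stage {stage}, index {tuple(bad)}"
        )
    return logits, stage


def update_cls_tokens(
    inputs: TokenSet,
    cls: TokenSet,
    attn,
    w: ClusterBlockWeights,
    _eps: float = 0.0,
) -> TokenSet:
    """Move each [cls] token toward the attention-weighted mean of its inputs.

    ``c'_j = c_j + W ( sum_i Attn[i,j] W_v x_i / sum_i Attn[i,j] )`` — the
    weighted mean (column-normalized), then a residual add. Exact softmax
    rows guarantee positive column sums, but underflow is guarded.
    """
    x = inputs.vectors if isinstance(inputs, TokenSet) else Tensor._wrap(inputs)
    c = cls.vectors if isinstance(cls, TokenSet) else Tensor._wrap(cls)
    stage = cls.stage if isinstance(cls, TokenSet) else 0
    a = attn.weights if isinstance(attn, ClusterAttention) else attn
    if not isinstance(a, Tensor):
        a = Tensor(np.asarray(a))
    col_sums = a.data.sum(axis=-2)
    if np.any(col_sums <= _eps):
        raise NumericError(
            f"clustering column weight underflow at stage {stage} "
            f"(min column sum {col_sums.min():.3e})"
        )
    vx = matmul(x, w.value_projection)  # (..., N_in, d)
    num = matmul(a.swap_last2(), vx)  # (..., N_c, d)
    den = a.sum(axis=-2).reshape(a.shape[:-2] + (a.shape[-1], 1))
    mean = num / den
    out = c + matmul(mean, w.output_projection)
    return TokenSet(vectors=out, role="cls", stage=stage)


def _update_cls_stable(logits: Tensor, x: Tensor, c: Tensor,
                       w: ClusterBlockWeights) -> Tensor:
    """The token update computed from logits in log space.

    The column-normalized weights ``Attn[i,j] / sum_i Attn[i,j]`` equal a
    softmax over inputs of the row-log-softmax of the logits, which never
    underflows even when a [cls] token is avoided by every input (where the
    explicit ratio would hit 0/0). Algebraically identical to
    ``update_cls_tokens`` on exact softmax rows.
    """
    col_w = softmax(log_softmax(logits, axis=-1), axis=-2)  # cols sum to 1
    vx = matmul(x, w.value_projection)
    mean = matmul(col_w.swap_last2(), vx)
    return c + matmul(mean, w.output_projection)


def forward_features(
    images, cfg: BackboneConfig, params: dict, return_attn: bool = False
):
    """Run the full hierarchy on a (B, H, W, 3) batch.

    Returns the (B, d) pooled embedding Tensor, and when ``return_attn`` the
    list of per-stage assignment Tensors (stage 0: patches x N_c0; stage
    k>0: N_c(k-1) x N_ck).
    """
    x = _as_image_batch(images)
    b = x.shape[0]
    tokens = patch_embed(x, cfg, params).vectors  # (B, N_p, d)
    attns = []
    current = tokens
    for s in range(cfg.n_stages):
        n_cls = cfg.stage_cls_counts[s]
        cls = params[f"stage{s}.cls"].reshape((1, n_cls, cfg.embed_dim)).broadcast_to(
            (b, n_cls, cfg.embed_dim)
        )
        m = concat([current, cls], axis=1)
        for blk in range(cfg.msa_blocks_per_stage[s]):
            m = msa_block(m, params, f"stage{s}.msa{blk}", cfg.n_heads)
        n_in = current.shape[1]
        split_inputs = m[:, :n_in, :]
        split_cls = m[:, n_in:, :]
        cw = cluster_weights(params, s)
        logits, _ = _cluster_logits(
            split_inputs, split_cls, cw, cfg.scaled_cluster_logits
        )
        attns.append(softmax(logits, axis=-1))
        current = _update_cls_stable(logits, split_inputs, split_cls, cw)
    pooled = current.mean(axis=1)  # average over final [cls] tokens
    if return_attn:
        return pooled, attns
    return pooled


def forward(tile, cfg: BackboneConfig, params: dict) -> np.ndarray:
    """Embed one RGB tile; returns the (embed_dim,) pooled representation."""
    emb = forward_features(_as_image_batch(tile), cfg, params)
    out = emb.data[0]
    if not np.all(np.isfinite(out)):
        raise NumericError("non-finite embedding")
    return out


def extract_attention_maps(
    tile, cfg: BackboneConfig, params: dict, stage: int
) -> AttentionMapStack:
    """Per-[cls]-token attention maps at tile resolution for ``stage``.

    Assignment matrices are chained down to patch space (rows are always
    patches), reshaped to the patch grid and bilinearly upsampled. At every
    pixel the maps across tokens sum to ~1.
    """
    if not 0 <= stage < cfg.n_stages:
        raise IndexError(f"stage {stage} out of range [0, {cfg.n_stages})")
    x = _as_image_batch(tile)
    if x.shape[0] != 1:
        raise ValueError("one tile at a time")
    _, attns = forward_features(x, cfg, params, return_attn=True)
    composed = attns[0].data[0]  # (N_p, N_c0)
    for s in range(1, stage + 1):
        composed = composed @ attns[s].data[0]
    g = x.shape[1] // cfg.patch_size
    n_c = composed.shape[1]
    grid_maps = composed.T.reshape(n_c, g, g)
    zoom = x.shape[1] / g
    maps = np.stack(
        [ndimage.zoom(m, zoom, order=1, grid_mode=True, mode="nearest")
         for m in grid_maps]
    )
    maps = np.clip(maps, 0.0, 1.0)
    return AttentionMapStack(maps=maps, stage=stage)


# ------------------------------------------------------------ feature export
def extract_features(
    tiles, cfg: BackboneConfig, params: dict, batch_size: int = 32
) -> np.ndarray:
    """Embed a sequence of tiles; returns an (n, embed_dim) float array."""
    out = []
    for i in range(0, len(tiles), batch_size):
        batch = np.stack([np.asarray(t) for t in tiles[i : i + batch_size]])
        out.append(forward_features(batch, cfg, params).data)
    return np.concatenate(out, axis=0)


def save_features(path, features: np.ndarray, ids) -> None:
    """Write features keyed by tile id; CSV (``.csv``) or HDF5 otherwise."""
    path = str(path)
    if path.endswith(".csv"):
        import pandas as pd

        df = pd.DataFrame(features, index=list(ids))
        df.index.name = "id"
        df.to_csv(path)
    else:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("features", data=features)
            fh.create_dataset(
                "ids", data=np.array([str(i) for i in ids], dtype="S")
            )


def load_features(path):
    path = str(path)
    if path.endswith(".csv"):
        import pandas as pd

        df = pd.read_csv(path, index_col="id")
        return df.to_numpy(), [str(i) for i in df.index]
    import h5py

    with h5py.File(path, "r") as fh:
        return fh["features"][:], [s.decode() for s in fh["ids"][:]]
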