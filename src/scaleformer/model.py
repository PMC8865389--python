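"""Scale-aware transformer classifier for multi-slice biopsy images.

The forward pass has three stages, mirroring how a pathologist combines
detail and context across zoom levels:

1. **Patch embeddings** — a frozen CNN embeds each of the ``m`` patches of a
   slice crop independently at each input scale; a shared linear projection
   maps the native feature width to the working width ``e``.
2. **Contextualized patch embeddings** — per scale, sinusoidal positional
   encodings (1-D, row-major patch index) are added and a transformer
   encoder mixes the patches; the rows are mean-pooled to one vector per
   scale.
3. **Contextualized scale embeddings** — the pooled per-scale vectors are
   stacked, learnable scale positions are added, a second transformer mixes
   the scales, and the flattened result goes through a linear classifier to
   ``C`` category scores.

Each transformer unit is pre-norm: ``x + Attn(LN(x))`` then
``x + FFN(LN(x))``, with a final layer norm after the stack. Attention logits
are scaled by 1/sqrt(e/heads) by default; ``attention_scaling=False`` gives
the literal unscaled dot-product variant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat
from .backbone import RandomConvBackbone
from .slide_prep import DEFAULT_M_PER_SCALE, DEFAULT_SCALE_FACTORS, PatchGrid


@dataclass
class TransformerConfig:
    """Size hyperparameters of one transformer encoder stack."""

    layers: int = 2
    heads: int = 4
    ffn_width: int = 512
    e: int = 128

    def __post_init__(self) -> None:
        if self.e % self.heads:
            raise ValueError("embedding width must be divisible by heads")


@dataclass
class ModelConfig:
    embed_dim: int = 128
    layers: int = 2
    heads: int = 4
    ffn_width: int = 512
    n_classes: int = 4
    scales: tuple[str, ...] = tuple(DEFAULT_SCALE_FACTORS)
    m_per_scale: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_M_PER_SCALE))
    native_dim: int = 192
    attention_scaling: bool = True
    share_patch_transformer: bool = False

    @property
    def n_scales(self) -> int:
        return len(self.scales)

    def transformer(self) -> TransformerConfig:
        return TransformerConfig(self.layers, self.heads, self.ffn_width, self.embed_dim)


def sinusoidal_positions(n: int, e: int) -> np.ndarray:
    """Classic fixed sin/cos positional encoding for 1-D indices 0..n-1."""
    pos = np.arange(n)[:, None]
    dim = np.arange(e // 2)[None, :]
    angles = pos / (10000.0 ** (2 * dim / e))
    out = np.zeros((n, e))
    out[:, 0::2] = np.sin(angles)
    out[:, 1::2] = np.cos(angles)
    return out


# ---------------------------------------------------------------------------
# parameter initialization
# ---------------------------------------------------------------------------


def _init_transformer(params: dict, prefix: str, cfg: TransformerConfig, rng) -> None:
    e, f = cfg.e, cfg.ffn_width
    for layer in range(cfg.layers):
        p = f"{prefix}l{layer}."
        params[p + "ln1.g"] = np.ones(e)
        params[p + "ln1.b"] = np.zeros(e)
        for name in ("Wq", "Wk", "Wv", "Wo"):
            params[p + "attn." + name] = rng.normal(0.0, 0.02, (e, e))
        for name in ("bq", "bk", "bv", "bo"):
            params[p + "attn." + name] = np.zeros(e)
        params[p + "ln2.g"] = np.ones(e)
        params[p + "ln2.b"] = np.zeros(e)
        params[p + "ffn.W1"] = rng.normal(0.0, 0.02, (e, f))
        params[p + "ffn.b1"] = np.zeros(f)
        params[p + "ffn.W2"] = rng.normal(0.0, 0.02, (f, e))
        params[p + "ffn.b2"] = np.zeros(e)
    params[prefix + "ln_f.g"] = np.ones(e)
    params[prefix + "ln_f.b"] = np.zeros(e)


def init_parameters(cfg: ModelConfig, seed: int = 0) -> dict[str, np.ndarray]:
    """Fresh trainable parameters (the frozen backbone is not among them)."""
    rng = np.random.default_rng(seed)
    params: dict[str, np.ndarray] = {}
    params["proj.W"] = rng.normal(0.0, 0.02, (cfg.native_dim, cfg.embed_dim))
    params["proj.b"] = np.zeros(cfg.embed_dim)
    tcfg = cfg.transformer()
    if cfg.share_patch_transformer:
        _init_transformer(params, "patch_tx.shared.", tcfg, rng)
    else:
        for tag in cfg.scales:
            _init_transformer(params, f"patch_tx.{tag}.", tcfg, rng)
    _init_transformer(params, "scale_tx.", tcfg, rng)
    params["pse"] = rng.normal(0.0, 0.02, (cfg.n_scales, cfg.embed_dim))
    params["cls.W"] = rng.normal(0.0, 0.02, (cfg.n_scales * cfg.embed_dim, cfg.n_classes))
    params["cls.b"] = np.zeros(cfg.n_classes)
    return params


def lift_parameters(params: dict[str, np.ndarray], trainable: bool = True) -> dict[str, Tensor]:
    return {k: Tensor(v, requires_grad=trainable) for k, v in params.items()}


# ---------------------------------------------------------------------------
# forward building blocks (operate on Tensors)
# ---------------------------------------------------------------------------


def _layer_norm(x: Tensor, g: Tensor, b: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc * (var + eps) ** -0.5 * g + b


def _mha(x: Tensor, p: dict[str, Tensor], prefix: str, heads: int, scaling: bool) -> Tensor:
    n, e = x.shape
    dh = e // heads

    def split(t: Tensor) -> Tensor:  # (n,e) -> (heads, n, dh)
        return t.reshape(n, heads, dh).swapaxes(0, 1)

    q = split(x @ p[prefix + "attn.Wq"] + p[prefix + "attn.bq"])
    k = split(x @ p[prefix + "attn.Wk"] + p[prefix + "attn.bk"])
    v = split(x @ p[prefix + "attn.Wv"] + p[prefix + "attn.bv"])
    logits = q @ k.swapaxes(-1, -2)
    if scaling:
        logits = logits * (1.0 / np.sqrt(dh))
    attn = logits.softmax(axis=-1)
    out = (attn @ v).swapaxes(0, 1).reshape(n, e)
    return out @ p[prefix + "attn.Wo"] + p[prefix + "attn.bo"]


def _encoder(x: Tensor, p: dict[str, Tensor], prefix: str, cfg: TransformerConfig,
             scaling: bool = True) -> Tensor:
    for layer in range(cfg.layers):
        lp = f"{prefix}l{layer}."
        x = x + _mha(_layer_norm(x, p[lp + "ln1.g"], p[lp + "ln1.b"]), p, lp,
                     cfg.heads, scaling)
        h = _layer_norm(x, p[lp + "ln2.g"], p[lp + "ln2.b"])
        h = (h @ p[lp + "ffn.W1"] + p[lp + "ffn.b1"]).relu()
        x = x + h @ p[lp + "ffn.W2"] + p[lp + "ffn.b2"]
    return _layer_norm(x, p[prefix + "ln_f.g"], p[prefix + "ln_f.b"])


# ---------------------------------------------------------------------------
# public numpy-level operations
# ---------------------------------------------------------------------------


def self_attention(
    x: np.ndarray,
    params: dict[str, np.ndarray],
    heads: int = 1,
    scaling: bool = True,
    prefix: str = "",
) -> np.ndarray:
    """Multi-head self-attention on an (n, e) matrix; returns (n, e)."""
    p = lift_parameters(params, trainable=False)
    return _mha(Tensor(x), p, prefix, heads, scaling).data


def transformer_encode(
    x: np.ndarray,
    params: dict[str, np.ndarray],
    cfg: TransformerConfig,
    prefix: str = "",
    scaling: bool = True,
) -> np.ndarray:
    """Run an (n, e) matrix through the L-unit pre-norm encoder stack."""
    p = lift_parameters(params, trainable=False)
    return _encoder(Tensor(x), p, prefix, cfg, scaling).data


class ScaleAwareModel:
    """The full trainable classifier head over frozen patch features."""

    def __init__(self, cfg: ModelConfig | None = None, seed: int = 0,
                 params: dict[str, np.ndarray] | None = None):
        self.cfg = cfg or ModelConfig()
        self.params = params if params is not None else init_parameters(self.cfg, seed)

    # -- stage 1 ----------------------------------------------------------

    def embed_patches(self, grid: PatchGrid, backbone: RandomConvBackbone) -> np.ndarray:
        """Per-patch CNN features projected to the working width (m, e)."""
        native = backbone(grid.patches)
        return native @ self.params["proj.W"] + self.params["proj.b"]

    # -- stages 2 and 3 ---------------------------------------------------

    def _patch_prefix(self, tag: str) -> str:
        return "patch_tx.shared." if self.cfg.share_patch_transformer else f"patch_tx.{tag}."

    def contextualize_patches(
        self,
        pe: np.ndarray,
        scale_tag: str | None = None,
        use_positions: bool = True,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Transformer-contextualize (m, e) patch embeddings; also pooled mean."""
        tag = scale_tag or self.cfg.scales[0]
        p = lift_parameters(self.params, trainable=False)
        x = Tensor(pe)
        if use_positions:
            x = x + Tensor(sinusoidal_positions(pe.shape[0], self.cfg.embed_dim))
        cpe = _encoder(x, p, self._patch_prefix(tag), self.cfg.transformer(),
                       self.cfg.attention_scaling)
        return cpe.data, cpe.data.mean(axis=0)

    def fuse_scales(self, pooled: list[np.ndarray]) -> np.ndarray:
        """Cross-scale transformer + linear classifier on pooled vectors."""
        p = lift_parameters(self.params, trainable=False)
        return self._fuse(
            [Tensor(v) for v in pooled], p
        ).data

    def _fuse(self, pooled: list[Tensor], p: dict[str, Tensor]) -> Tensor:
        s = len(pooled)
        if s == 0:
            raise ValueError("need at least one scale")
        se = concat([v.reshape(1, -1) for v in pooled], axis=0)
        se = se + p["pse"][:s]
        cse = _encoder(se, p, "scale_tx.", self.cfg.transformer(), self.cfg.attention_scaling)
        flat = cse.reshape(1, s * self.cfg.embed_dim)
        w = p["cls.W"]
        if s != self.cfg.n_scales:  # degenerate scale counts use a weight prefix
            w = w[: s * self.cfg.embed_dim]
        return (flat @ w + p["cls.b"]).reshape(self.cfg.n_classes)

    def forward(
        self,
        native_embeddings: dict[str, np.ndarray],
        params_t: dict[str, Tensor] | None = None,
    ) -> Tensor:
        """Class scores for one slice given frozen (m, native) features per scale.

        When ``params_t`` (lifted trainable tensors) is given, the returned
        scalar graph supports backpropagation; otherwise the call is pure
        inference.
        """
        p = params_t if params_t is not None else lift_parameters(self.params, False)
        pooled = []
        for tag in self.cfg.scales:
            native = Tensor(native_embeddings[tag])
            pe = native @ p["proj.W"] + p["proj.b"]
            pe = pe + Tensor(sinusoidal_positions(pe.shape[0], self.cfg.embed_dim))
            cpe = _encoder(pe, p, self._patch_prefix(tag), self.cfg.transformer(),
                           self.cfg.attention_scaling)
            pooled.append(cpe.mean(axis=0))
        return self._fuse(pooled, p)

    def predict(self, native_embeddings: dict[str, np.ndarray]) -> np.ndarray:
        """Softmax class probabilities for one slice (inference only)."""
        scores = self.forward(native_embeddings).data
        e = np.exp(scores - scores.max())
        return e / e.sum()

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        meta = asdict(self.cfg)
        meta["scales"] = list(self.cfg.scales)
        np.savez(path, __config__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "ScaleAwareModel":
        with np.load(Path(path) if str(path).endswith(".npz") else f"{path}") as archive:
            meta = json.loads(bytes(archive["__config__"].tobytes()).decode())
            params = {k: archive[k] for k in archive.files if k != "__config__"}
        meta["scales"] = tuple(meta["scales"])
        return cls(cfg=ModelConfig(**meta), params=params)
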