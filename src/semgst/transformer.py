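"""A vision-transformer-style classifier for matrix signals, in pure NumPy.

The model follows the standard ViT recipe applied to electrode-grid images:

1. split the H x W x C matrix signal into N = HW/P^2 non-overlapping P x P
   patches, each flattened row-major;
2. linearly embed each patch with a learned matrix E (P^2 C -> D);
3. prepend a learnable CLS token and add learned position embeddings,
   z0 = [x_class; x_p^1 E; ...; x_p^N E] + E_pos;
4. run L pre-norm transformer encoder layers,
   z'_l = MSA(LN(z_{l-1})) + z_{l-1},  z_l = MLP(LN(z'_l)) + z'_l;
5. layer-norm the final CLS token and classify it with an MLP head
   (default hidden sizes 2048 and 1024, GELU) followed by softmax.

Forward and backward passes are written explicitly (no autograd); gradients
are exact and are verified against central finite differences in the test
suite.  Dropout is applied after the attention output projection and after
the MLP block, only in training mode, driven by an explicit Generator so
training is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .matrix import MatrixSignal

__all__ = [
    "STConfig", "SignalTransformer", "split_patches", "merge_patches",
    "embed", "attention_rollout",
]

_SQRT2 = np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)
_LN_EPS = 1e-6


# ---------------------------------------------------------------------------
# patching

def split_patches(image: np.ndarray | MatrixSignal, patch_size: int) -> np.ndarray:
    """Split an H x W x C image into (N, P*P*C) flattened patches.

    Patches are taken row-major over the patch grid and each patch is
    flattened row-major, so the operation is lossless.
    """
    if isinstance(image, MatrixSignal):
        image = image.pixels
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        image = image[:, :, None]
    h, w, c = image.shape
    p = patch_size
    if h % p or w % p:
        raise ValueError(f"image {h}x{w} not divisible by patch size {p}")
    gh, gw = h // p, w // p
    patches = image.reshape(gh, p, gw, p, c).transpose(0, 2, 1, 3, 4)
    return patches.reshape(gh * gw, p * p * c)


def merge_patches(patches: np.ndarray, h: int, w: int, c: int,
                  patch_size: int) -> np.ndarray:
    """Inverse of :func:`split_patches`."""
    p = patch_size
    gh, gw = h // p, w // p
    img = patches.reshape(gh, gw, p, p, c).transpose(0, 2, 1, 3, 4)
    return img.reshape(h, w, c)


def embed(patches: np.ndarray, E: np.ndarray, x_class: np.ndarray,
          E_pos: np.ndarray) -> np.ndarray:
    """Token sequence z0 = [x_class; patch_i E] + E_pos, shape (N+1, D)."""
    patches = np.asarray(patches, dtype=np.float64)
    if patches.shape[1] != E.shape[0]:
        raise ValueError("patch dimension does not match embedding matrix")
    n = patches.shape[0]
    if E_pos.shape[0] != n + 1:
        raise ValueError("E_pos must have N+1 rows")
    tokens = np.empty((n + 1, E.shape[1]))
    tokens[0] = x_class
    tokens[1:] = patches @ E
    return tokens + E_pos


# ---------------------------------------------------------------------------
# primitives (forward + backward)

def _layernorm_fwd(x, g, b):
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc ** 2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = xc * inv
    return g * xhat + b, (xhat, inv, g)


def _layernorm_bwd(dy, cache):
    xhat, inv, g = cache
    axes = tuple(range(dy.ndim - 1))
    dg = (dy * xhat).sum(axis=axes)
    db = dy.sum(axis=axes)
    dxhat = dy * g
    m1 = dxhat.mean(axis=-1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    return dx, dg, db


def _gelu_fwd(x):
    phi = 0.5 * (1.0 + erf(x / _SQRT2))
    return x * phi, (x, phi)


def _gelu_bwd(dy, cache):
    x, phi = cache
    pdf = _INV_SQRT2PI * np.exp(-0.5 * x ** 2)
    return dy * (phi + x * pdf)


def _softmax(x):
    e = np.exp(x - x.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# configuration and model

@dataclass
class STConfig:
    """Architecture and regularization hyperparameters.

    Defaults mirror the training configuration used for the full-scale
    gesture models: 72 x 72 inputs, patch size 6 (so 144 patches / 145
    tokens), 8 encoder layers with 8 attention heads, and an MLP head with
    hidden sizes 2048 and 1024.  The embedding width is a free parameter.
    """

    image_size: int = 72
    patch_size: int = 6
    in_channels: int = 1
    embed_dim: int = 64
    n_layers: int = 8
    n_heads: int = 8
    mlp_ratio: float = 4.0
    mlp_head_dims: tuple[int, ...] = (2048, 1024)
    n_classes: int = 8
    dropout: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size % self.patch_size:
            raise ValueError("image_size must be divisible by patch_size")
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")

    @property
    def n_patches(self) -> int:
        return (self.image_size // self.patch_size) ** 2

    @property
    def patch_dim(self) -> int:
        return self.patch_size ** 2 * self.in_channels

    @property
    def mlp_dim(self) -> int:
        return int(self.mlp_ratio * self.embed_dim)


def _trunc_normal(rng, shape, sd=0.02):
    return np.clip(rng.standard_normal(shape) * sd, -2 * sd, 2 * sd)


def _xavier_uniform(rng, shape):
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


class SignalTransformer:
    """ViT-style classifier over matrix signals; see the module docstring."""

    def __init__(self, config: STConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d, n = config.embed_dim, config.n_patches
        dm = config.mlp_dim
        p: dict[str, np.ndarray] = {
            "embed.E": _trunc_normal(rng, (config.patch_dim, d)),
            "cls": _trunc_normal(rng, (d,)),
            "pos": _trunc_normal(rng, (n + 1, d)),
        }
        for l in range(config.n_layers):
            pre = f"enc{l}."
            p[pre + "ln1.g"] = np.ones(d)
            p[pre + "ln1.b"] = np.zeros(d)
            # embeddings get truncated-normal init; linear maps Xavier-uniform
            for name in ("Wq", "Wk", "Wv", "Wo"):
                p[pre + name] = _xavier_uniform(rng, (d, d))
                p[pre + "b" + name[1].lower()] = np.zeros(d)
            p[pre + "ln2.g"] = np.ones(d)
            p[pre + "ln2.b"] = np.zeros(d)
            p[pre + "W1"] = _xavier_uniform(rng, (d, dm))
            p[pre + "b1"] = np.zeros(dm)
            p[pre + "W2"] = _xavier_uniform(rng, (dm, d))
            p[pre + "b2"] = np.zeros(d)
        p["head.ln.g"] = np.ones(d)
        p["head.ln.b"] = np.zeros(d)
        dims = (d, *config.mlp_head_dims)
        for i in range(len(dims) - 1):
            p[f"head.W{i}"] = _xavier_uniform(rng, (dims[i], dims[i + 1]))
            p[f"head.b{i}"] = np.zeros(dims[i + 1])
        # zero-init the logit layer: predictions start uniform and the first
        # gradient steps are not fighting random-init logit noise
        p["head.out.W"] = np.zeros((dims[-1], config.n_classes))
        p["head.out.b"] = np.zeros(config.n_classes)
        self.params = p

    # -- forward ----------------------------------------------------------

    def n_parameters(self) -> int:
        return sum(v.size for v in self.params.values())

    def _msa_fwd(self, h, l):
        cfg, p = self.config, self.params
        pre = f"enc{l}."
        B, T, D = h.shape
        nh, dh = cfg.n_heads, D // cfg.n_heads

        def heads(x):
            return x.reshape(B, T, nh, dh).transpose(0, 2, 1, 3)

        q = heads(h @ p[pre + "Wq"] + p[pre + "bq"])
        k = heads(h @ p[pre + "Wk"] + p[pre + "bk"])
        v = heads(h @ p[pre + "Wv"] + p[pre + "bv"])
        scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(dh)
        attn = _softmax(scores)
        ctx = attn @ v  # (B, nh, T, dh)
        ctx_m = ctx.transpose(0, 2, 1, 3).reshape(B, T, D)
        out = ctx_m @ p[pre + "Wo"] + p[pre + "bo"]
        cache = (h, q, k, v, attn, ctx_m)
        return out, attn, cache

    def _msa_bwd(self, dout, l, cache, grads):
        cfg, p = self.config, self.params
        pre = f"enc{l}."
        h, q, k, v, attn, ctx_m = cache
        B, T, D = h.shape
        nh, dh = cfg.n_heads, D // cfg.n_heads

        grads[pre + "Wo"] += ctx_m.reshape(-1, D).T @ dout.reshape(-1, D)
        grads[pre + "bo"] += dout.sum(axis=(0, 1))
        dctx_m = dout @ p[pre + "Wo"].T
        dctx = dctx_m.reshape(B, T, nh, dh).transpose(0, 2, 1, 3)

        dattn = dctx @ v.transpose(0, 1, 3, 2)
        dv = attn.transpose(0, 1, 3, 2) @ dctx
        dscores = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
        dscores /= np.sqrt(dh)
        dq = dscores @ k
        dk = dscores.transpose(0, 1, 3, 2) @ q

        def unheads(x):
            return x.transpose(0, 2, 1, 3).reshape(B, T, D)

        dh_total = np.zeros_like(h)
        for name, dx in (("Wq", unheads(dq)), ("Wk", unheads(dk)), ("Wv", unheads(dv))):
            grads[pre + name] += h.reshape(-1, D).T @ dx.reshape(-1, D)
            grads[pre + "b" + name[1].lower()] += dx.sum(axis=(0, 1))
            dh_total += dx @ p[pre + name].T
        return dh_total

    def forward(self, patches: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None):
        """Compute logits for a batch of patch sequences (B, N, P^2 C).

        Returns (logits, cache); the cache holds every intermediate needed
        by :meth:`backward`, including the per-layer attention matrices.
        """
        cfg, p = self.config, self.params
        patches = np.asarray(patches, dtype=np.float64)
        if patches.ndim == 2:
            patches = patches[None]
        B, N, PD = patches.shape
        if N != cfg.n_patches or PD != cfg.patch_dim:
            raise ValueError(
                f"expected (B, {cfg.n_patches}, {cfg.patch_dim}) patches, got {patches.shape}")
        if train and cfg.dropout > 0 and rng is None:
            raise ValueError("training-mode forward with dropout needs an rng")

        tok = patches @ p["embed.E"]
        z = np.concatenate([np.broadcast_to(p["cls"], (B, 1, cfg.embed_dim)), tok],
                           axis=1) + p["pos"]

        layer_caches = []
        attns = []
        for l in range(cfg.n_layers):
            pre = f"enc{l}."
            h, ln1_c = _layernorm_fwd(z, p[pre + "ln1.g"], p[pre + "ln1.b"])
            msa, attn, msa_c = self._msa_fwd(h, l)
            mask1 = None
            if train and cfg.dropout > 0:
                mask1 = (rng.random(msa.shape) >= cfg.dropout) / (1 - cfg.dropout)
                msa = msa * mask1
            z1 = z + msa
            h2, ln2_c = _layernorm_fwd(z1, p[pre + "ln2.g"], p[pre + "ln2.b"])
            a1 = h2 @ p[pre + "W1"] + p[pre + "b1"]
            g1, gelu_c = _gelu_fwd(a1)
            m = g1 @ p[pre + "W2"] + p[pre + "b2"]
            mask2 = None
            if train and cfg.dropout > 0:
                mask2 = (rng.random(m.shape) >= cfg.dropout) / (1 - cfg.dropout)
                m = m * mask2
            z = z1 + m
            layer_caches.append((ln1_c, msa_c, mask1, z1, ln2_c, h2, gelu_c, g1, mask2))
            attns.append(attn)

        logits, head_cache = self._head_fwd(z[:, 0])
        cache = {"patches": patches, "zL": z, "layers": layer_caches,
                 "attns": attns, "head": head_cache, "B": B}
        return logits, cache

    def _head_fwd(self, cls_token):
        p = self.params
        y0, ln_c = _layernorm_fwd(cls_token, p["head.ln.g"], p["head.ln.b"])
        h = y0
        acts = []
        for i in range(len(self.config.mlp_head_dims)):
            a = h @ p[f"head.W{i}"] + p[f"head.b{i}"]
            g, gc = _gelu_fwd(a)
            acts.append((h, gc))
            h = g
        logits = h @ p["head.out.W"] + p["head.out.b"]
        return logits, (ln_c, acts, h)

    def _head_bwd(self, dlogits, head_cache, grads):
        p = self.params
        ln_c, acts, h_last = head_cache
        grads["head.out.W"] += h_last.T @ dlogits
        grads["head.out.b"] += dlogits.sum(axis=0)
        dh = dlogits @ p["head.out.W"].T
        for i in reversed(range(len(self.config.mlp_head_dims))):
            h_in, gc = acts[i]
            da = _gelu_bwd(dh, gc)
            grads[f"head.W{i}"] += h_in.T @ da
            grads[f"head.b{i}"] += da.sum(axis=0)
            dh = da @ p[f"head.W{i}"].T
        dy0, dg, db = _layernorm_bwd(dh, ln_c)
        grads["head.ln.g"] += dg
        grads["head.ln.b"] += db
        return dy0

    def backward(self, cache, dlogits) -> dict[str, np.ndarray]:
        """Exact gradients of the loss w.r.t. every parameter."""
        cfg, p = self.config, self.params
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}

        dcls = self._head_bwd(dlogits, cache["head"], grads)
        dz = np.zeros_like(cache["zL"])
        dz[:, 0] = dcls

        for l in reversed(range(cfg.n_layers)):
            pre = f"enc{l}."
            ln1_c, msa_c, mask1, z1, ln2_c, h2, gelu_c, g1, mask2 = cache["layers"][l]
            dm = dz if mask2 is None else dz * mask2
            D = cfg.embed_dim
            grads[pre + "W2"] += g1.reshape(-1, g1.shape[-1]).T @ dm.reshape(-1, D)
            grads[pre + "b2"] += dm.sum(axis=(0, 1))
            dg1 = dm @ p[pre + "W2"].T
            da1 = _gelu_bwd(dg1, gelu_c)
            grads[pre + "W1"] += h2.reshape(-1, D).T @ da1.reshape(-1, da1.shape[-1])
            grads[pre + "b1"] += da1.sum(axis=(0, 1))
            dh2 = da1 @ p[pre + "W1"].T
            dz1_ln, dg, db = _layernorm_bwd(dh2, ln2_c)
            grads[pre + "ln2.g"] += dg
            grads[pre + "ln2.b"] += db
            dz1 = dz + dz1_ln

            dmsa = dz1 if mask1 is None else dz1 * mask1
            dh = self._msa_bwd(dmsa, l, msa_c, grads)
            dz_ln, dg, db = _layernorm_bwd(dh, ln1_c)
            grads[pre + "ln1.g"] += dg
            grads[pre + "ln1.b"] += db
            dz = dz1 + dz_ln

        grads["pos"] += dz.sum(axis=0)
        grads["cls"] += dz[:, 0].sum(axis=0)
        dtok = dz[:, 1:]
        patches = cache["patches"]
        grads["embed.E"] += patches.reshape(-1, cfg.patch_dim).T @ \
            dtok.reshape(-1, cfg.embed_dim)
        return grads

    # -- losses and inference --------------------------------------------

    def loss_and_grads(self, patches, labels, train=True,
                       rng: np.random.Generator | None = None):
        """Mean cross-entropy over the batch and its parameter gradients."""
        logits, cache = self.forward(patches, train=train, rng=rng)
        labels = np.asarray(labels)
        B = logits.shape[0]
        shifted = logits - logits.max(axis=1, keepdims=True)
        logz = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
        logp = shifted - logz
        loss = -logp[np.arange(B), labels].mean()
        dlogits = (np.exp(logp) - np.eye(logits.shape[1])[labels]) / B
        grads = self.backward(cache, dlogits)
        return loss, grads

    def predict_proba(self, patches) -> np.ndarray:
        logits, _ = self.forward(patches, train=False)
        return _softmax(logits)

    def predict(self, patches) -> np.ndarray:
        logits, _ = self.forward(patches, train=False)
        return logits.argmax(axis=1)

    def classify(self, zL: np.ndarray) -> np.ndarray:
        """Head applied to a final-layer token sequence: LN -> MLP -> softmax.

        Only token 0 (the CLS position) enters the head.
        """
        zL = np.asarray(zL, dtype=np.float64)
        if zL.ndim == 2:
            zL = zL[None]
        logits, _ = self._head_fwd(zL[:, 0])
        return _softmax(logits)

    def attention_maps(self, patches) -> list[np.ndarray]:
        """Per-layer attention matrices, each (B, heads, N+1, N+1)."""
        _, cache = self.forward(patches, train=False)
        return cache["attns"]


def attention_rollout(attns: list[np.ndarray]) -> np.ndarray:
    """CLS-to-patch attention mass propagated through all layers.

    Each layer's head-averaged attention is mixed with the identity (residual
    path) and re-normalized; the layer matrices are multiplied and the CLS
    row over patch tokens is returned, renormalized to sum to 1 per item.
    """
    rollout = None
    for attn in attns:
        a = attn.mean(axis=1)  # (B, T, T)
        a = a + np.eye(a.shape[-1])[None]
        a = a / a.sum(axis=-1, keepdims=True)
        rollout = a if rollout is None else a @ rollout
    mass = rollout[:, 0, 1:]
    return mass / mass.sum(axis=-1, keepdims=True)
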