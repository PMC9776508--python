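"""Stacked graph autoencoder for low-dimensional similarity embeddings.

A stack of L graph-convolutional encoder/decoder pairs:

    Enc(A, Y) = tanh( A . ReLU( A Y W0 ) W1 )
    Dec(A, Z) = sigmoid( A . ReLU( A Z W2 ) W3 )

where A is the Laplacian-normalized similarity matrix.  Layer l encodes the
previous layer's embedding Z^(l-1) into Z^l and decodes it back to X^l; the
training objective is the *sum* of the per-layer squared-Frobenius
reconstruction losses ||Z^(l-1) - X^l||^2, so all layers are optimized
jointly (collaboratively) rather than greedily layer by layer.  Gradients
flow through the whole chain: a parameter in layer 1 affects every deeper
layer's loss through Z^1.

The implementation is plain numpy with hand-derived backpropagation and a
full-batch Adam optimizer; graphs here are dense and small (<= ~500 nodes),
so there is no need for sparse formats or minibatching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._optim import Adam

__all__ = [
    "SgaeConfig",
    "GaeLayerParams",
    "EmbeddingSet",
    "resolve_dims",
    "init_stack",
    "encode_layer",
    "decode_layer",
    "sgae_forward",
    "train_sgae",
]

SUPPORTED_FINAL_DIMS = (16, 32, 64, 128, 256)


@dataclass
class SgaeConfig:
    """Hyperparameters of the stacked graph autoencoder.

    ``dims`` lists the per-layer output widths (len = number of stacked
    autoencoders, default 3, ending at the final embedding dimension,
    default 64).  Leave ``dims=None`` to derive a geometrically decreasing
    chain from the input width down to ``final_dim``.
    """

    dims: list[int] | None = None
    n_layers: int = 3
    final_dim: int = 64
    hidden_factor: int = 2  # encoder ReLU width = hidden_factor * layer output width
    epochs: int = 300
    lr: float = 1e-3
    weight_decay: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError("need at least one layer")
        if self.final_dim not in SUPPORTED_FINAL_DIMS:
            raise ValueError(f"final_dim must be one of {SUPPORTED_FINAL_DIMS}")
        if self.dims is not None:
            if self.dims != sorted(self.dims, reverse=True) or len(set(self.dims)) != len(self.dims):
                raise ValueError("dims must be strictly decreasing")
            self.n_layers = len(self.dims)
            self.final_dim = self.dims[-1]


def resolve_dims(input_dim: int, cfg: SgaeConfig) -> list[int]:
    """Layer output widths for a given input width.

    Wide inputs use the fixed 256 -> 128 -> 64 contraction; narrower inputs
    get a geometric interpolation from input width to the final dimension so
    the chain stays strictly decreasing at any scale.
    """
    if cfg.dims is not None:
        return list(cfg.dims)
    L, f = cfg.n_layers, cfg.final_dim
    halving = [f * 2 ** (L - 1 - i) for i in range(L)]  # e.g. 256 -> 128 -> 64
    if halving[0] < input_dim:
        return halving
    # geometric chain input_dim -> f in L steps
    dims = [int(round(input_dim ** (1 - t) * f**t)) for t in (i / L for i in range(1, L + 1))]
    for i in range(1, L):  # enforce strict decrease on tiny inputs
        dims[i] = min(dims[i], dims[i - 1] - 1)
    dims[-1] = f
    if dims != sorted(dims, reverse=True) or len(set(dims)) != len(dims):
        raise ValueError(f"cannot build a strictly decreasing chain {input_dim} -> {f} in {L} layers")
    return dims


@dataclass
class GaeLayerParams:
    """Encoder (W0, W1) and decoder (W2, W3) weights of one layer."""

    W0: np.ndarray  # in -> hidden
    W1: np.ndarray  # hidden -> out
    W2: np.ndarray  # out -> hidden
    W3: np.ndarray  # hidden -> in

    def as_list(self) -> list[np.ndarray]:
        return [self.W0, self.W1, self.W2, self.W3]


@dataclass
class EmbeddingSet:
    """Per-layer embeddings Z^0..Z^L and reconstructions X^1..X^L."""

    Z: list[np.ndarray]
    X: list[np.ndarray]
    axis: str = "miRNA"
    layer_losses: list[float] = field(default_factory=list)

    @property
    def final(self) -> np.ndarray:
        return self.Z[-1]

    @property
    def total_loss(self) -> float:
        return float(sum(self.layer_losses))


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_stack(input_dim: int, cfg: SgaeConfig, rng: np.random.Generator) -> list[GaeLayerParams]:
    dims = resolve_dims(input_dim, cfg)
    stack = []
    d_in = input_dim
    for d_out in dims:
        h = cfg.hidden_factor * d_out
        stack.append(
            GaeLayerParams(
                W0=_glorot(rng, d_in, h),
                W1=_glorot(rng, h, d_out),
                W2=_glorot(rng, d_out, h),
                W3=_glorot(rng, h, d_in),
            )
        )
        d_in = d_out
    return stack


def encode_layer(a_hat: np.ndarray, y: np.ndarray, params: GaeLayerParams) -> np.ndarray:
    """tanh( A . ReLU( A Y W0 ) W1 ); output entries in (-1, 1)."""
    if not (np.isfinite(a_hat).all() and np.isfinite(y).all()):
        raise FloatingPointError("non-finite encoder input")
    h = np.maximum(a_hat @ y @ params.W0, 0.0)
    return np.tanh(a_hat @ h @ params.W1)


def decode_layer(a_hat: np.ndarray, z: np.ndarray, params: GaeLayerParams) -> np.ndarray:
    """sigmoid( A . ReLU( A Z W2 ) W3 ); output entries in (0, 1)."""
    h = np.maximum(a_hat @ z @ params.W2, 0.0)
    logits = a_hat @ h @ params.W3
    return 1.0 / (1.0 + np.exp(-logits))


def sgae_forward(
    a_hat: np.ndarray, f2: np.ndarray, stack: list[GaeLayerParams], axis: str = "miRNA"
) -> EmbeddingSet:
    """Run the full stack; Z^0 is the similarity feature block F^2."""
    zs = [np.asarray(f2, dtype=float)]
    xs: list[np.ndarray] = []
    losses: list[float] = []
    for params in stack:
        z = encode_layer(a_hat, zs[-1], params)
        x = decode_layer(a_hat, z, params)
        losses.append(float(((zs[-1] - x) ** 2).sum()))
        zs.append(z)
        xs.append(x)
    return EmbeddingSet(Z=zs, X=xs, axis=axis, layer_losses=losses)


def _forward_cached(a_hat, f2, stack):
    """Forward pass keeping every intermediate needed for backprop."""
    zs = [np.asarray(f2, dtype=float)]
    caches = []
    for p in stack:
        ay = a_hat @ zs[-1]
        h1_pre = ay @ p.W0
        h1 = np.maximum(h1_pre, 0.0)
        ah1 = a_hat @ h1
        z = np.tanh(ah1 @ p.W1)
        az = a_hat @ z
        g1_pre = az @ p.W2
        g1 = np.maximum(g1_pre, 0.0)
        ag1 = a_hat @ g1
        x = 1.0 / (1.0 + np.exp(-(ag1 @ p.W3)))
        caches.append((ay, h1_pre, h1, ah1, z, az, g1_pre, g1, ag1, x))
        zs.append(z)
    return zs, caches


def _backward(a_hat, zs, caches, stack):
    """Gradients of sum_l ||Z^(l-1) - X^l||^2 w.r.t. every weight matrix.

    The loss couples layers two ways: X^l reconstructs Z^(l-1), and Z^l is
    the next layer's input; both paths are accumulated into gZ below.
    """
    L = len(stack)
    at = a_hat.T
    grads = [[None] * 4 for _ in range(L)]
    gz = [np.zeros_like(z) for z in zs]  # d total loss / d Z^l

    # decoder paths and direct loss terms
    for l in range(L):
        ay, h1_pre, h1, ah1, z, az, g1_pre, g1, ag1, x = caches[l]
        diff = zs[l] - x
        gz[l] += 2.0 * diff  # target side of layer l+1's loss
        dx = -2.0 * diff
        dlogits = dx * x * (1.0 - x)
        grads[l][3] = ag1.T @ dlogits  # W3
        dg1 = (at @ dlogits) @ stack[l].W3.T
        dg1_pre = dg1 * (g1_pre > 0)
        grads[l][2] = az.T @ dg1_pre  # W2
        gz[l + 1] += (at @ dg1_pre) @ stack[l].W2.T

    # encoder paths, deepest first so gZ[l] is complete before use
    for l in range(L - 1, -1, -1):
        ay, h1_pre, h1, ah1, z, *_ = caches[l]
        dz = gz[l + 1]
        dpre = dz * (1.0 - z * z)
        grads[l][1] = ah1.T @ dpre  # W1
        dh1 = (at @ dpre) @ stack[l].W1.T
        dh1_pre = dh1 * (h1_pre > 0)
        grads[l][0] = ay.T @ dh1_pre  # W0
        gz[l] += (at @ dh1_pre) @ stack[l].W0.T

    flat = []
    for g in grads:
        flat.extend(g)
    return flat


def train_sgae(
    a_hat: np.ndarray,
    f2: np.ndarray,
    cfg: SgaeConfig,
    axis: str = "miRNA",
) -> tuple[EmbeddingSet, list[float], list[GaeLayerParams]]:
    """Jointly train the stack with Adam; returns embeddings, loss trace, params.

    Deterministic for a fixed seed: same inputs and config reproduce the
    trace and embeddings bit for bit.
    """
    rng = np.random.default_rng(cfg.seed)
    stack = init_stack(f2.shape[1], cfg, rng)
    params_flat = [w for p in stack for w in p.as_list()]
    opt = Adam(params_flat, lr=cfg.lr, weight_decay=cfg.weight_decay)
    trace: list[float] = []
    for epoch in range(cfg.epochs):
        zs, caches = _forward_cached(a_hat, f2, stack)
        loss = float(sum(((zs[l] - caches[l][-1]) ** 2).sum() for l in range(len(stack))))
        if not np.isfinite(loss):
            raise FloatingPointError(f"training diverged (non-finite loss) at epoch {epoch}")
        trace.append(loss)
        grads = _backward(a_hat, zs, caches, stack)
        opt.step(grads)
    emb = sgae_forward(a_hat, f2, stack, axis=axis)
    return emb, trace, stack
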