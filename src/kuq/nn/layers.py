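"""Network building blocks: dense layers, ReLU MLPs, encoder-only transformers,
spectral weight normalization and the Adam optimizer."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = [
    "Dense",
    "Mlp",
    "TransformerEncoder",
    "Adam",
    "spectral_normalize",
    "power_iteration_sigma_max",
]


# ---------------------------------------------------------------------------
# spectral normalization
# ---------------------------------------------------------------------------

def power_iteration_sigma_max(
    w: np.ndarray, iterations: int = 20, u0: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Estimate the largest singular value of a 2-D matrix by power iteration.

    Returns (sigma_max_estimate, final_left_vector); the vector can be fed back
    in as a warm start for subsequent calls on a slowly changing matrix.
    """
    w = np.asarray(w, dtype=float)
    if w.ndim != 2:
        raise ValueError("power iteration expects a 2-D weight matrix")
    norm = np.linalg.norm(w)
    if norm == 0.0:
        return 0.0, np.zeros(w.shape[0])
    rng = np.random.default_rng(0)
    u = u0 if u0 is not None and u0.shape == (w.shape[0],) and np.linalg.norm(u0) > 0 \
        else rng.standard_normal(w.shape[0])
    u = u / np.linalg.norm(u)
    for _ in range(max(1, iterations)):
        v = w.T @ u
        vn = np.linalg.norm(v)
        if vn == 0.0:
            return 0.0, u
        v /= vn
        u = w @ v
        un = np.linalg.norm(u)
        if un == 0.0:
            return 0.0, np.zeros_like(u)
        u /= un
    sigma = float(u @ (w @ v))
    return abs(sigma), u


def spectral_normalize(
    w: np.ndarray, bound: float, power_iterations: int = 20
) -> np.ndarray:
    """Rescale `w` so its top singular value does not exceed `bound`.

    Returns ``w * min(1, bound / sigma_max(w))`` with sigma_max estimated by
    power iteration; a matrix already inside the bound (or all-zero) is
    returned unchanged.
    """
    if bound <= 0:
        raise ValueError("spectral bound must be positive")
    if power_iterations < 1:
        raise ValueError("power_iterations must be >= 1")
    w = np.asarray(w, dtype=float)
    sigma, _ = power_iteration_sigma_max(w, power_iterations)
    if sigma <= bound:
        return w.copy()
    return w * (bound / sigma)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Dense:
    """Affine layer y = x W + b with optional spectral-norm constraint.

    When `spectral_bound` is set, :meth:`project` rescales the weight in place
    so its top singular value stays below the bound; call it after every
    optimizer step (projected gradient style).
    """

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 spectral_bound: float | None = None):
        scale = np.sqrt(2.0 / n_in)  # He initialization for ReLU stacks
        self.w = Tensor(rng.standard_normal((n_in, n_out)) * scale, requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)
        self.spectral_bound = spectral_bound
        self._u: np.ndarray | None = None
        if spectral_bound is not None:
            self.project(iterations=50)

    @property
    def params(self) -> list[Tensor]:
        return [self.w, self.b]

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b

    def project(self, iterations: int = 3) -> None:
        if self.spectral_bound is None:
            return
        sigma, self._u = power_iteration_sigma_max(self.w.data, iterations, self._u)
        if sigma > self.spectral_bound:
            self.w.data *= self.spectral_bound / sigma


class Mlp:
    """ReLU multilayer perceptron returning the last hidden representation.

    `depth` counts hidden layers; a separate scalar head (owned by the caller)
    maps the hidden state to a logit, so the same backbone serves both the
    plain ensemble member and the GP-headed variant.
    """

    def __init__(self, n_in: int, width: int, depth: int, seed: int,
                 spectral_bound: float | None = None):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        rng = np.random.default_rng(seed)
        self.layers = [
            Dense(n_in if i == 0 else width, width, rng, spectral_bound)
            for i in range(depth)
        ]
        self.width = width
        self.depth = depth

    @property
    def params(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.params]

    def hidden(self, x) -> Tensor:
        h = x if isinstance(x, Tensor) else Tensor(x)
        for layer in self.layers:
            h = layer(h).relu()
        return h

    def project(self) -> None:
        for layer in self.layers:
            layer.project()


class _EncoderBlock:
    """Pre-norm transformer encoder block: x + MHA(LN x); x + FFN(LN x)."""

    def __init__(self, d_model: int, heads: int, d_ff: int,
                 rng: np.random.Generator, spectral_bound: float | None):
        if d_model % heads != 0:
            raise ValueError("d_model must be divisible by the number of heads")
        self.h = heads
        self.dk = d_model // heads
        self.d_model = d_model
        # attention projections stay unconstrained (no established bi-Lipschitz
        # attention); only the feed-forward sublayers are spectrally normalized
        self.wq = Dense(d_model, d_model, rng)
        self.wk = Dense(d_model, d_model, rng)
        self.wv = Dense(d_model, d_model, rng)
        self.wo = Dense(d_model, d_model, rng)
        self.ff1 = Dense(d_model, d_ff, rng, spectral_bound)
        self.ff2 = Dense(d_ff, d_model, rng, spectral_bound)

    @property
    def params(self) -> list[Tensor]:
        return [p for l in (self.wq, self.wk, self.wv, self.wo, self.ff1, self.ff2)
                for p in l.params]

    def project(self) -> None:
        self.ff1.project()
        self.ff2.project()

    def __call__(self, x: Tensor, attn_bias: np.ndarray) -> Tensor:
        B, T, D = x.shape
        xn = x.layer_norm()

        def split(t: Tensor) -> Tensor:  # (B,T,D) -> (B,H,T,dk)
            return t.reshape(B, T, self.h, self.dk).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(xn)), split(self.wk(xn)), split(self.wv(xn))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.dk))
        attn = (scores + attn_bias).softmax()  # bias masks padded key positions
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, D)
        x = x + self.wo(ctx)
        yn = x.layer_norm()
        return x + self.ff2(self.ff1(yn).relu())


class TransformerEncoder:
    """Encoder-only transformer over embedded token sequences.

    Consumes a padded batch (B, T, d_in) with a boolean validity mask (B, T);
    produces a mean-over-valid-tokens summary vector of width `d_model`.
    """

    def __init__(self, d_in: int, d_model: int, depth: int, heads: int,
                 seed: int, d_ff: int | None = None,
                 spectral_bound: float | None = None):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        rng = np.random.default_rng(seed)
        d_ff = d_ff or 2 * d_model
        self.input_proj = Dense(d_in, d_model, rng, spectral_bound)
        self.blocks = [
            _EncoderBlock(d_model, heads, d_ff, rng, spectral_bound)
            for _ in range(depth)
        ]
        self.width = d_model
        self.depth = depth

    @property
    def params(self) -> list[Tensor]:
        ps = list(self.input_proj.params)
        for blk in self.blocks:
            ps.extend(blk.params)
        return ps

    def project(self) -> None:
        self.input_proj.project()
        for blk in self.blocks:
            blk.project()

    def hidden(self, x: np.ndarray, mask: np.ndarray) -> Tensor:
        """Mean-pooled representation; `mask` marks real (non-padding) tokens."""
        x = np.asarray(x, dtype=float)
        mask = np.asarray(mask, dtype=float)
        B, T, _ = x.shape
        attn_bias = np.where(mask[:, None, None, :] > 0, 0.0, -1e9)  # (B,1,1,T)
        h = self.input_proj(Tensor(x))
        for blk in self.blocks:
            h = blk(h, attn_bias)
        h = h.layer_norm()
        m = mask[:, :, None]
        counts = mask.sum(axis=1, keepdims=True)  # every episode has >= 1 token
        return (h * m).sum(axis=1) * (1.0 / counts)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
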