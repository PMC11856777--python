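"""Knowledge-uncertainty estimators: deep ensembles (ENN) and spectral-normalized
neural Gaussian processes (SNGP).

Both estimators solve the same binary-classification task; they differ in how
they quantify *knowledge* (epistemic) uncertainty:

* **ENN** — K independently initialized and trained networks; the population
  standard deviation of the member logits, sigma(L), is the KU signal.
* **SNGP** — a single network whose hidden layers are spectrally normalized
  (approximately distance preserving) and whose output layer is a Gaussian
  process approximated with random Fourier features (RFF) and a Laplace
  posterior covariance; the predictive standard deviation sigma(x) grows with
  the distance of the query from the training data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .nn.autodiff import Tensor
from .nn.layers import Dense, Mlp, TransformerEncoder, power_iteration_sigma_max, spectral_normalize
from .nn.train import TrainConfig, train_model

__all__ = [
    "BackboneSpec",
    "EnsemblePrediction",
    "SngpPrediction",
    "MlpClassifier",
    "TransformerClassifier",
    "ResidualMlp",
    "SngpClassifier",
    "build_toy_ensemble",
    "build_toy_sngp_pool",
    "build_ehr_ensemble",
    "build_ehr_sngp_pool",
    "enn_predict",
    "rff_features",
    "laplace_precision_update",
    "sngp_predict",
    "pool_sngp",
    "spectral_normalize",
    "train_model",
    "TrainConfig",
]

MEAN_FIELD_LAMBDA = np.pi / 8.0  # logit shrinkage for the mean-field probit link


# ---------------------------------------------------------------------------
# specs and prediction containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BackboneSpec:
    """Architecture descriptor with the study's admissible ranges.

    MLPs: 1-3 hidden layers, 100-150 units. Transformers: 2-4 encoder blocks,
    64-512 units, and never simultaneously 4 blocks and 512 units.
    """

    kind: str  # "mlp" | "transformer"
    depth: int
    width: int
    heads: int | None = None

    def __post_init__(self):
        if self.kind == "mlp":
            if not (1 <= self.depth <= 3):
                raise ValueError("mlp depth must be in 1..3")
            if not (100 <= self.width <= 150):
                raise ValueError("mlp width must be in 100..150")
        elif self.kind == "transformer":
            if not (2 <= self.depth <= 4):
                raise ValueError("transformer depth must be in 2..4")
            if not (64 <= self.width <= 512):
                raise ValueError("transformer width must be in 64..512")
            if self.depth == 4 and self.width == 512:
                raise ValueError("wide-and-deep transformer (4 x 512) excluded")
        else:
            raise ValueError(f"unknown backbone kind {self.kind!r}")


@dataclass
class EnsemblePrediction:
    member_logits: np.ndarray  # (K, n)
    mean_prob: np.ndarray  # (n,)
    ku: np.ndarray  # (n,) population std of member logits


@dataclass
class SngpPrediction:
    mu: np.ndarray  # (n,) posterior logit mean
    sigma: np.ndarray  # (n,) posterior predictive std
    prob: np.ndarray  # (n,) mean-field adjusted class-1 probability


# ---------------------------------------------------------------------------
# plain classifiers (ensemble members)
# ---------------------------------------------------------------------------

class MlpClassifier:
    """ReLU MLP with a scalar logit head; one ENN member."""

    def __init__(self, n_in: int, spec: BackboneSpec, seed: int):
        self.spec = spec
        self.backbone = Mlp(n_in, spec.width, spec.depth, seed)
        rng = np.random.default_rng(seed + 7919)
        self.head = Dense(spec.width, 1, rng)
        self.seed = seed

    @property
    def params(self) -> list[Tensor]:
        return self.backbone.params + self.head.params

    def forward_logits(self, x) -> Tensor:
        h = self.backbone.hidden(np.asarray(x, dtype=float))
        return self.head(h).reshape(-1)

    def predict_logits(self, x) -> np.ndarray:
        return self.forward_logits(x).data


class TransformerClassifier:
    """Encoder-only transformer with mean-token pooling and a logit head."""

    def __init__(self, d_in: int, spec: BackboneSpec, seed: int):
        self.spec = spec
        self.backbone = TransformerEncoder(
            d_in, spec.width, spec.depth, spec.heads or 4, seed
        )
        rng = np.random.default_rng(seed + 7919)
        self.head = Dense(spec.width, 1, rng)
        self.seed = seed

    @property
    def params(self) -> list[Tensor]:
        return self.backbone.params + self.head.params

    def forward_logits(self, x, mask) -> Tensor:
        return self.head(self.backbone.hidden(x, mask)).reshape(-1)

    def predict_logits(self, x, mask) -> np.ndarray:
        return self.forward_logits(x, mask).data


# ---------------------------------------------------------------------------
# SNGP
# ---------------------------------------------------------------------------

class ResidualMlp:
    """Bi-Lipschitz MLP backbone: spectral-normalized input projection followed
    by residual blocks h + ReLU(h W + b) with ||W||_2 <= bound < 1.

    The residual form guarantees a positive lower Lipschitz constant, so hidden
    distances neither explode nor collapse — the property the GP head relies on
    to stay distance aware.
    """

    def __init__(self, n_in: int, width: int, depth: int, seed: int,
                 spectral_bound: float = 0.95):
        rng = np.random.default_rng(seed)
        self.input_proj = Dense(n_in, width, rng, spectral_bound=None)
        self.blocks = [Dense(width, width, rng, spectral_bound) for _ in range(depth)]
        self.width = width
        self.depth = depth
        self.spectral_bound = spectral_bound

    @property
    def params(self) -> list[Tensor]:
        ps = list(self.input_proj.params)
        for b in self.blocks:
            ps.extend(b.params)
        return ps

    def project(self) -> None:
        for b in self.blocks:
            b.project()

    def hidden(self, x) -> Tensor:
        h = self.input_proj(Tensor(np.asarray(x, dtype=float)))
        for blk in self.blocks:
            h = h + blk(h).relu()
        return h


def rff_features(h: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Random Fourier features Phi = sqrt(2/D) * cos(W h + b).

    Inner products of these features approximate the RBF kernel
    exp(-||h - h'||^2 / (2 l^2)) when W has i.i.d. N(0, 1/l^2) entries and b is
    uniform on [0, 2 pi).
    """
    h = np.atleast_2d(np.asarray(h, dtype=float))
    if h.shape[1] != w.shape[1]:
        raise ValueError(
            f"hidden width {h.shape[1]} does not match RFF projection {w.shape[1]}"
        )
    d = w.shape[0]
    return np.sqrt(2.0 / d) * np.cos(h @ w.T + b)


def laplace_precision_update(p_mat: np.ndarray, phi_batch: np.ndarray,
                             prob_batch: np.ndarray) -> np.ndarray:
    """One Laplace-approximation accumulation step:
    P' = P + sum_i p_i (1 - p_i) Phi_i Phi_i^T.
    """
    phi_batch = np.atleast_2d(np.asarray(phi_batch, dtype=float))
    prob_batch = np.atleast_1d(np.asarray(prob_batch, dtype=float))
    if phi_batch.shape[0] == 0:
        return p_mat.copy()
    if not (np.all(np.isfinite(phi_batch)) and np.all(np.isfinite(prob_batch))):
        raise FloatingPointError("non-finite inputs to precision update")
    w = prob_batch * (1.0 - prob_batch)
    return p_mat + (phi_batch * w[:, None]).T @ phi_batch


class SngpClassifier:
    """Spectral-normalized network with an RFF-Laplace Gaussian-process head.

    The backbone maps inputs to a hidden representation on which the RBF
    kernel (via its random-feature expansion) acts directly; the kernel length
    scale is therefore expressed in hidden-space units. Setting
    ``hidden_norm="sphere"`` instead projects the hidden vector onto the unit
    sphere (parameter-free layer norm scaled by 1/sqrt(width)) first, which
    discards the radial component. Training fits the backbone and the output
    weights beta by cross-entropy; `finalize` then accumulates the Laplace
    precision P = I + sum p(1-p) Phi Phi^T over the training split with frozen
    weights, after which `predict` returns N(mu, sigma) per query.
    """

    def __init__(self, backbone, rff_dim: int = 1024, length_scale: float = 1.0,
                 seed: int = 0, mean_field_lambda: float = MEAN_FIELD_LAMBDA,
                 hidden_norm: str = "none"):
        self.backbone = backbone
        self.rff_dim = rff_dim
        self.length_scale = length_scale
        self.mean_field_lambda = mean_field_lambda
        self.hidden_norm = hidden_norm
        rng = np.random.default_rng(seed + 104729)
        self.rff_w = rng.standard_normal((rff_dim, backbone.width)) / length_scale
        self.rff_b = rng.uniform(0.0, 2.0 * np.pi, size=rff_dim)
        self.beta = Tensor(np.zeros(rff_dim), requires_grad=True)
        self.bias = Tensor(np.zeros(1), requires_grad=True)
        self.precision = np.eye(rff_dim)
        self._cho = None
        self.seed = seed

    # -- training-time graph ------------------------------------------------
    @property
    def params(self) -> list[Tensor]:
        return self.backbone.params + [self.beta, self.bias]

    def project(self) -> None:
        self.backbone.project()

    def _normalized_hidden(self, *inputs) -> Tensor:
        h = self.backbone.hidden(*inputs)
        if self.hidden_norm == "sphere":
            h = h.layer_norm() * (1.0 / np.sqrt(self.backbone.width))
        return h

    def forward_logits(self, *inputs) -> Tensor:
        h = self._normalized_hidden(*inputs)
        d = self.rff_dim
        phi = ((h @ self.rff_w.T) + self.rff_b).cos() * np.sqrt(2.0 / d)
        return (phi @ self.beta) + self.bias.reshape(())

    # -- inference ----------------------------------------------------------
    def features(self, *inputs) -> np.ndarray:
        return rff_features(self._normalized_hidden(*inputs).data,
                            self.rff_w, self.rff_b)

    def finalize(self, train_inputs: tuple, batch_size: int = 512) -> None:
        """Accumulate the Laplace precision over the training split."""
        n = len(np.asarray(train_inputs[0]))
        p_mat = np.eye(self.rff_dim)
        for start in range(0, n, batch_size):
            sl = slice(start, start + batch_size)
            batch = tuple(np.asarray(a)[sl] for a in train_inputs)
            phi = self.features(*batch)
            logits = phi @ self.beta.data + self.bias.data[0]
            probs = 1.0 / (1.0 + np.exp(-logits))
            p_mat = laplace_precision_update(p_mat, phi, probs)
        self.precision = p_mat
        self._cho = cho_factor(p_mat)

    def predict(self, *inputs) -> SngpPrediction:
        if self._cho is None:
            self._cho = cho_factor(self.precision)
        phi = self.features(*inputs)
        mu = phi @ self.beta.data + self.bias.data[0]
        solved = cho_solve(self._cho, phi.T)
        var = np.einsum("nd,dn->n", phi, solved)
        sigma = np.sqrt(np.maximum(var, 0.0))
        prob = 1.0 / (1.0 + np.exp(-mu / np.sqrt(1.0 + self.mean_field_lambda * var)))
        return SngpPrediction(mu=mu, sigma=sigma, prob=prob)

    def predict_logits(self, *inputs) -> np.ndarray:
        return self.forward_logits(*inputs).data


def sngp_predict(model: SngpClassifier, *inputs) -> SngpPrediction:
    """Posterior mean/std of a trained, finalized SNGP at the query inputs."""
    return model.predict(*inputs)


def pool_sngp(models: list[SngpClassifier], *inputs,
              var_mode: str = "sigma") -> SngpPrediction:
    """Pool SNGP models: mean of member mu, mean of member sigma.

    `var_mode="sigma2"` averages variances instead and reports its square root.
    """
    if not models:
        raise ValueError("empty SNGP pool")
    preds = [m.predict(*inputs) for m in models]
    mu = np.mean([p.mu for p in preds], axis=0)
    if var_mode == "sigma":
        sigma = np.mean([p.sigma for p in preds], axis=0)
    elif var_mode == "sigma2":
        sigma = np.sqrt(np.mean([p.sigma ** 2 for p in preds], axis=0))
    else:
        raise ValueError("var_mode must be 'sigma' or 'sigma2'")
    prob = np.mean([p.prob for p in preds], axis=0)
    return SngpPrediction(mu=mu, sigma=sigma, prob=prob)


def enn_predict(members: list, *inputs) -> EnsemblePrediction:
    """Pool an ensemble: mean sigmoid probability and sigma(L), the population
    standard deviation of the member logits, as the KU measure."""
    if not members:
        raise ValueError("empty ensemble")
    logits = np.stack([m.predict_logits(*inputs) for m in members])
    probs = 1.0 / (1.0 + np.exp(-logits))
    return EnsemblePrediction(
        member_logits=logits,
        mean_prob=probs.mean(axis=0),
        ku=logits.std(axis=0),  # population (1/K) std
    )


# ---------------------------------------------------------------------------
# model zoo builders
# ---------------------------------------------------------------------------

TOY_ENN_WIDTHS = (100, 106, 112, 118, 125, 131, 137, 143, 150)
TOY_SNGP_WIDTHS = (100, 125, 150)


def build_toy_ensemble(seed: int, n_in: int = 2) -> list[MlpClassifier]:
    """The 27-member toy ensemble: depths 1-3 crossed with nine widths in
    100-150, each member with its own initialization seed."""
    members = []
    i = 0
    for depth in (1, 2, 3):
        for width in TOY_ENN_WIDTHS:
            spec = BackboneSpec("mlp", depth, width)
            members.append(MlpClassifier(n_in, spec, seed=seed + i))
            i += 1
    return members


def build_toy_sngp_pool(seed: int, n_in: int = 2, rff_dim: int = 512,
                        length_scale: float = 5.0,
                        spectral_bound: float = 0.95) -> list[SngpClassifier]:
    """Nine SNGP models of comparable depths and widths to the toy ensemble."""
    models = []
    i = 0
    for depth in (1, 2, 3):
        for width in TOY_SNGP_WIDTHS:
            backbone = ResidualMlp(n_in, width, depth, seed=seed + 500 + i,
                                   spectral_bound=spectral_bound)
            models.append(SngpClassifier(backbone, rff_dim=rff_dim,
                                         length_scale=length_scale,
                                         seed=seed + 500 + i))
            i += 1
    return models


EHR_ENN_SPECS = [(2, 64), (2, 128), (2, 256), (3, 64), (3, 128), (3, 256),
                 (4, 64), (4, 128)]
EHR_SNGP_SPECS = [(2, 64), (2, 128), (3, 64), (3, 128)]
# reduced-size variants keep the member counts and depth spread but pin the
# width to the smallest admissible value; used for fast smoke-scale cohorts
EHR_ENN_SPECS_SMOKE = [(2, 64), (2, 64), (2, 64), (3, 64), (3, 64), (3, 64),
                       (4, 64), (4, 64)]
EHR_SNGP_SPECS_SMOKE = [(2, 64), (2, 64), (3, 64), (3, 64)]


def build_ehr_ensemble(d_in: int, seed: int, heads: int = 4,
                       smoke: bool = False) -> list[TransformerClassifier]:
    """Eight transformer ENN members spanning depths 2-4 and several widths."""
    specs = EHR_ENN_SPECS_SMOKE if smoke else EHR_ENN_SPECS
    return [
        TransformerClassifier(d_in, BackboneSpec("transformer", d, w, heads=heads),
                              seed=seed + i)
        for i, (d, w) in enumerate(specs)
    ]


class _SpectralTransformerBackbone(TransformerEncoder):
    """Transformer backbone with spectral-normalized feed-forward sublayers;
    attention stays standard (no established bi-Lipschitz attention)."""

    def __init__(self, d_in: int, spec: BackboneSpec, seed: int,
                 spectral_bound: float = 0.95):
        super().__init__(d_in, spec.width, spec.depth, spec.heads or 4,
                         seed=seed, spectral_bound=spectral_bound)


def build_ehr_sngp_pool(d_in: int, seed: int, heads: int = 4, rff_dim: int = 1024,
                        length_scale: float = 1.0, smoke: bool = False,
                        spectral_bound: float = 0.95) -> list[SngpClassifier]:
    """Four SNGP transformers with spectral-normalized feed-forward layers."""
    specs = EHR_SNGP_SPECS_SMOKE if smoke else EHR_SNGP_SPECS
    models = []
    for i, (d, w) in enumerate(specs):
        bspec = BackboneSpec("transformer", d, w, heads=heads)
        backbone = _SpectralTransformerBackbone(d_in, bspec, seed=seed + 900 + i,
                                                spectral_bound=spectral_bound)
        models.append(SngpClassifier(backbone, rff_dim=rff_dim,
                                     length_scale=length_scale,
                                     seed=seed + 900 + i))
    return models
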