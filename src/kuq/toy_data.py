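"""Two-dimensional toy datasets and their synthetic out-of-distribution sets.

Two labeled datasets are used to probe uncertainty estimators: the classic
two moons, and a "stripes" dataset of vertical bands with differing densities,
class mixtures and gap widths. OoD companions are built by rejection sampling:
uniform proposals over a bounding box are kept only if their nearest-neighbor
distance to the source dataset is at least a dataset-dependent length scale
(about half the minimum width of the moons, ~0.2, respectively stripes, ~0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial import cKDTree
from sklearn.datasets import make_moons

__all__ = [
    "LabeledPoints",
    "StripeSpec",
    "OoDPointSet",
    "DEFAULT_STRIPES",
    "make_two_moons",
    "make_stripes",
    "make_ood_points",
    "nn_distance",
    "save_points",
    "load_points",
]


@dataclass
class LabeledPoints:
    coords: np.ndarray  # (n, 2)
    labels: np.ndarray  # (n,) in {0, 1}

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be an (n, 2) matrix")
        if len(self.labels) != len(self.coords):
            raise ValueError("labels length must equal number of points")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0/1")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class StripeSpec:
    """Vertical-stripe layout: disjoint sorted x1 intervals, a relative density
    weight and a class-1 probability per stripe, and a common x2 extent."""

    intervals: tuple[tuple[float, float], ...]
    weights: tuple[float, ...]
    class1_probs: tuple[float, ...]
    x2_extent: tuple[float, float] = (0.0, 6.0)

    def __post_init__(self):
        if len(self.intervals) == 0:
            raise ValueError("stripe list must be nonempty")
        if not (len(self.intervals) == len(self.weights) == len(self.class1_probs)):
            raise ValueError("intervals, weights and class1_probs must align")
        prev_hi = -np.inf
        for lo, hi in self.intervals:
            if hi <= lo:
                raise ValueError("each interval needs lo < hi")
            if lo < prev_hi:
                raise ValueError("intervals must be disjoint and sorted")
            prev_hi = hi
        if any(w <= 0 for w in self.weights):
            raise ValueError("density weights must be positive")
        if any(not 0.0 <= p <= 1.0 for p in self.class1_probs):
            raise ValueError("class-1 probabilities must lie in [0, 1]")


# Default layout: four stripes of varying width, density and class mixture
# separated by gaps of varying size — qualitative structure of the study's
# stripes dataset (widths 0.8/1.2/1.0/1.0, gaps 0.8/1.2/1.0 over x1 in [0, 8]).
DEFAULT_STRIPES = StripeSpec(
    intervals=((0.0, 0.8), (1.6, 2.8), (4.0, 5.0), (6.0, 7.0)),
    weights=(3.0, 1.0, 2.0, 1.0),
    class1_probs=(0.97, 0.65, 0.03, 0.9),
    x2_extent=(0.0, 6.0),
)


@dataclass
class OoDPointSet:
    coords: np.ndarray  # (m, 2)
    nn_dist: np.ndarray  # (m,) distance to nearest source point
    length_scale: float

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.nn_dist = np.asarray(self.nn_dist, dtype=float)
        if np.any(self.nn_dist < self.length_scale - 1e-12):
            raise ValueError("OoD point closer than the length scale to source")

    def __len__(self) -> int:
        return len(self.nn_dist)


def make_two_moons(n: int, noise: float = 0.1, seed: int = 0) -> LabeledPoints:
    """Balanced two-moons sample (two interleaving half circles plus isotropic
    Gaussian noise); deterministic for a fixed seed."""
    if n < 2:
        raise ValueError("need at least 2 points")
    coords, labels = make_moons(n_samples=n, noise=noise, random_state=seed)
    return LabeledPoints(coords, labels)


def make_stripes(spec: StripeSpec, n: int, seed: int = 0) -> LabeledPoints:
    """Sample n points from a stripe layout: stripe chosen with probability
    proportional to its density weight, x1 uniform within the stripe, x2
    uniform over the common extent, label Bernoulli with the stripe's
    class-1 rate."""
    if n < 1:
        raise ValueError("need at least 1 point")
    rng = np.random.default_rng(seed)
    w = np.asarray(spec.weights, dtype=float)
    probs = w / w.sum()
    which = rng.choice(len(w), size=n, p=probs)
    los = np.array([iv[0] for iv in spec.intervals])
    his = np.array([iv[1] for iv in spec.intervals])
    x1 = rng.uniform(los[which], his[which])
    x2 = rng.uniform(spec.x2_extent[0], spec.x2_extent[1], size=n)
    p1 = np.asarray(spec.class1_probs)[which]
    labels = (rng.uniform(size=n) < p1).astype(int)
    return LabeledPoints(np.column_stack([x1, x2]), labels)


def nn_distance(query, source: LabeledPoints) -> float:
    """Exact Euclidean distance from a single query to its nearest source point."""
    if len(source) == 0:
        raise ValueError("source dataset is empty")
    q = np.asarray(query, dtype=float)
    return float(np.sqrt(((source.coords - q) ** 2).sum(axis=1)).min())


class GenerationExhausted(RuntimeError):
    pass


def make_ood_points(source: LabeledPoints, length_scale: float, m: int,
                    bbox: tuple[float, float, float, float] | None = None,
                    seed: int = 0, proposal_budget_factor: int = 1000) -> OoDPointSet:
    """Rejection-sample m OoD points at least `length_scale` from the source.

    Proposals are uniform over `bbox` (x1lo, x1hi, x2lo, x2hi); by default the
    source bounding box padded by 3x the length scale. A point is accepted iff
    its nearest-neighbor distance to the source is >= length_scale; that
    distance is recorded per accepted point. Raises :class:`GenerationExhausted`
    if `proposal_budget_factor * m` proposals do not yield m acceptances.
    """
    if m < 1:
        raise ValueError("m must be positive")
    if length_scale < 0:
        raise ValueError("length scale must be nonnegative")
    if bbox is None:
        lo = source.coords.min(axis=0) - 3.0 * max(length_scale, 1e-6)
        hi = source.coords.max(axis=0) + 3.0 * max(length_scale, 1e-6)
        bbox = (lo[0], hi[0], lo[1], hi[1])
    rng = np.random.default_rng(seed)
    tree = cKDTree(source.coords)
    budget = proposal_budget_factor * m
    used = 0
    accepted: list[np.ndarray] = []
    dists: list[np.ndarray] = []
    n_have = 0
    while n_have < m and used < budget:
        chunk = min(max(4 * (m - n_have), 256), budget - used)
        props = np.column_stack([
            rng.uniform(bbox[0], bbox[1], size=chunk),
            rng.uniform(bbox[2], bbox[3], size=chunk),
        ])
        used += chunk
        d, _ = tree.query(props)
        keep = d >= length_scale
        accepted.append(props[keep])
        dists.append(d[keep])
        n_have += int(keep.sum())
    if n_have < m:
        raise GenerationExhausted(
            f"accepted only {n_have}/{m} points after {budget} proposals "
            f"(budget factor {proposal_budget_factor})"
        )
    coords = np.concatenate(accepted)[:m]
    nn = np.concatenate(dists)[:m]
    return OoDPointSet(coords=coords, nn_dist=nn, length_scale=length_scale)


# ---------------------------------------------------------------------------
# serialization: comma-separated table + YAML sidecar with generation metadata
# ---------------------------------------------------------------------------

def save_points(points: LabeledPoints, path: str | Path,
                metadata: dict | None = None) -> None:
    path = Path(path)
    header = "x1,x2,label"
    rows = np.column_stack([points.coords, points.labels.astype(float)])
    np.savetxt(path, rows, delimiter=",", header=header, comments="",
               fmt=("%.17g", "%.17g", "%d"))
    if metadata is not None:
        path.with_suffix(path.suffix + ".meta.yaml").write_text(
            yaml.safe_dump(metadata, sort_keys=True))


def load_points(path: str | Path) -> LabeledPoints:
    rows = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return LabeledPoints(rows[:, :2], rows[:, 2].astype(int))
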