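"""Threshold-based OoD detection and predictive-performance reporting.

Knowledge-uncertainty (KU) values are transformed to a log scale (log(10 sigma)
for the toy experiments, log(10 sigma + 1) for the EHR experiments — both
strictly monotone, chosen only for readable density plots), a threshold is set
at a percentile of the in-distribution test KU (90th for toy, 70th for EHR),
and the *undetected fraction* is the percentage of OoD samples whose KU falls
at or below that threshold. Predictive quality is summarized as AUROC/AUPRC of
the pooled prediction with min/max ranges across members.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from sklearn.metrics import average_precision_score, roc_auc_score

from .uq_models import enn_predict, pool_sngp

__all__ = [
    "KuReport",
    "OodBatch",
    "EnnEstimator",
    "SngpEstimator",
    "ku_transform",
    "percentile_threshold",
    "undetected_fraction",
    "auroc_auprc_with_range",
    "run_ood_experiment",
]


def ku_transform(sigma, variant: str):
    """log(10 sigma) for `variant="toy"` (requires sigma > 0), or
    log(10 sigma + 1) for `variant="ehr"`; both strictly increasing."""
    sigma = np.asarray(sigma, dtype=float)
    if variant == "toy":
        if np.any(sigma <= 0):
            raise ValueError("toy transform log(10 sigma) requires sigma > 0")
        out = np.log(10.0 * sigma)
    elif variant == "ehr":
        if np.any(sigma < 0):
            raise ValueError("sigma must be nonnegative")
        out = np.log(10.0 * sigma + 1.0)
    else:
        raise ValueError("variant must be 'toy' or 'ehr'")
    return float(out) if out.ndim == 0 else out


def percentile_threshold(test_ku, q: float) -> float:
    """Lower nearest-rank percentile: the value such that, for distinct
    inputs, exactly ceil((1 - q/100) n) samples lie strictly above it."""
    test_ku = np.asarray(test_ku, dtype=float)
    if test_ku.size == 0:
        raise ValueError("empty KU sequence")
    if not 0.0 < q < 100.0:
        raise ValueError("percentile must be in (0, 100)")
    srt = np.sort(test_ku)
    n = srt.size
    n_above = int(math.ceil((1.0 - q / 100.0) * n))
    rank = max(n - n_above, 1)
    return float(srt[rank - 1])


def undetected_fraction(ood_ku, threshold: float) -> float:
    """Percentage of OoD samples with KU at or below the threshold."""
    ood_ku = np.asarray(ood_ku, dtype=float)
    if ood_ku.size == 0:
        raise ValueError("empty OoD KU sequence")
    return float(100.0 * np.mean(ood_ku <= threshold))


def auroc_auprc_with_range(member_scores, labels, range_method: str = "members",
                           n_boot: int = 200, seed: int = 0) -> dict:
    """AUROC/AUPRC of the pooled (mean) score, with a (min, max) range.

    `member_scores` is a (K, n) array of per-member class-1 scores; AUROC uses
    the rank statistic, AUPRC the precision-recall step integration. The range
    spans the per-member metrics (`range_method="members"`, the default) or
    the min/max over `n_boot` bootstrap resamples of the pooled score
    (`range_method="bootstrap"`).
    """
    member_scores = np.atleast_2d(np.asarray(member_scores, dtype=float))
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("labels must contain both classes")
    pooled = member_scores.mean(axis=0)
    if range_method == "members":
        per_auroc = [float(roc_auc_score(labels, s)) for s in member_scores]
        per_auprc = [float(average_precision_score(labels, s))
                     for s in member_scores]
    elif range_method == "bootstrap":
        rng = np.random.default_rng(seed)
        n = len(labels)
        per_auroc, per_auprc = [], []
        while len(per_auroc) < n_boot:
            idx = rng.integers(n, size=n)
            if np.unique(labels[idx]).size < 2:
                continue
            per_auroc.append(float(roc_auc_score(labels[idx], pooled[idx])))
            per_auprc.append(float(average_precision_score(labels[idx],
                                                           pooled[idx])))
    else:
        raise ValueError("range_method must be 'members' or 'bootstrap'")
    return {
        "auroc": float(roc_auc_score(labels, pooled)),
        "auroc_range": (min(per_auroc), max(per_auroc)),
        "auprc": float(average_precision_score(labels, pooled)),
        "auprc_range": (min(per_auprc), max(per_auprc)),
    }


# ---------------------------------------------------------------------------
# estimator adapters
# ---------------------------------------------------------------------------

class EnnEstimator:
    """Ensemble adapter: KU = sigma(L), the population std of member logits."""

    name = "enn"

    def __init__(self, members: list):
        if not members:
            raise ValueError("empty ensemble")
        self.members = members

    def ku(self, inputs: tuple) -> np.ndarray:
        return enn_predict(self.members, *inputs).ku

    def prob(self, inputs: tuple) -> np.ndarray:
        return enn_predict(self.members, *inputs).mean_prob

    def member_probs(self, inputs: tuple) -> np.ndarray:
        logits = np.stack([m.predict_logits(*inputs) for m in self.members])
        return 1.0 / (1.0 + np.exp(-logits))


class SngpEstimator:
    """SNGP-pool adapter: KU = pooled predictive standard deviation sigma."""

    name = "sngp"

    def __init__(self, models: list, var_mode: str = "sigma"):
        if not models:
            raise ValueError("empty SNGP pool")
        self.models = models
        self.var_mode = var_mode

    def ku(self, inputs: tuple) -> np.ndarray:
        return pool_sngp(self.models, *inputs, var_mode=self.var_mode).sigma

    def prob(self, inputs: tuple) -> np.ndarray:
        return pool_sngp(self.models, *inputs, var_mode=self.var_mode).prob

    def member_probs(self, inputs: tuple) -> np.ndarray:
        return np.stack([m.predict(*inputs).prob for m in self.models])


@dataclass
class OodBatch:
    """A set of OoD inputs plus the per-sample distance annotation
    (d_proxy for corrupted episodes, NN distance for toy points)."""

    name: str
    inputs: tuple
    distance: np.ndarray | None = None


@dataclass
class KuReport:
    experiment_id: str
    estimator: str
    variant: str  # "toy" | "ehr"
    percentile: float
    threshold: float  # on the transformed KU scale
    test_ku: list[float]  # transformed
    ood_ku: dict[str, list[float]]  # transformed, per OoD batch
    undetected_pct: dict[str, float]
    undetected_pct_by_bin: dict[str, dict[str, float]]
    auroc: float
    auroc_range: tuple[float, float]
    auprc: float
    auprc_range: tuple[float, float]
    metadata: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        d = asdict(self)
        d["auroc_range"] = list(d["auroc_range"])
        d["auprc_range"] = list(d["auprc_range"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "KuReport":
        d = yaml.safe_load(Path(path).read_text())
        d["auroc_range"] = tuple(d["auroc_range"])
        d["auprc_range"] = tuple(d["auprc_range"])
        return cls(**d)


def _bin_label(lo: float, hi: float) -> str:
    return f"({lo:.1f},{hi:.1f}]"


def run_ood_experiment(estimator, id_test: tuple, ood_sets: list[OodBatch],
                       variant: str, q: float = 90.0,
                       experiment_id: str = "", metadata: dict | None = None,
                       range_method: str = "members") -> KuReport:
    """Full threshold experiment for one estimator.

    `id_test` is `(inputs, labels)`; the detection threshold is set from the
    ID test KU only. Undetected fractions are reported per OoD batch and, when
    the batch carries distances, per distance bin of width 0.1.
    """
    inputs, labels = id_test
    test_ku_raw = estimator.ku(inputs)
    test_ku = ku_transform(test_ku_raw, variant)
    threshold = percentile_threshold(test_ku, q)
    perf = auroc_auprc_with_range(estimator.member_probs(inputs), labels,
                                  range_method=range_method)
    metadata = dict(metadata or {})
    metadata.setdefault("range_method", range_method)

    ood_ku: dict[str, list[float]] = {}
    undetected: dict[str, float] = {}
    by_bin: dict[str, dict[str, float]] = {}
    for batch in ood_sets:
        ku = ku_transform(estimator.ku(batch.inputs), variant)
        ood_ku[batch.name] = [float(v) for v in ku]
        undetected[batch.name] = undetected_fraction(ku, threshold)
        if batch.distance is not None:
            d = np.asarray(batch.distance, dtype=float)
            bins: dict[str, float] = {}
            for k in range(10):
                lo, hi = k / 10.0, (k + 1) / 10.0
                sel = (d > lo) & (d <= hi) if k > 0 else (d >= 0) & (d <= hi)
                if sel.any():
                    bins[_bin_label(lo, hi)] = undetected_fraction(ku[sel], threshold)
            by_bin[batch.name] = bins

    return KuReport(
        experiment_id=experiment_id,
        estimator=estimator.name,
        variant=variant,
        percentile=float(q),
        threshold=threshold,
        test_ku=[float(v) for v in test_ku],
        ood_ku=ood_ku,
        undetected_pct=undetected,
        undetected_pct_by_bin=by_bin,
        auroc=perf["auroc"],
        auroc_range=perf["auroc_range"],
        auprc=perf["auprc"],
        auprc_range=perf["auprc_range"],
        metadata=metadata,
    )
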