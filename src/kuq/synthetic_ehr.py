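"""Synthetic ICU-style patient cohorts with known generative structure, plus
the two corruption operators used to manufacture out-of-distribution patients.

The generator emulates the shape of a 48-hour in-hospital-mortality episode:
17 concepts (12 continuous "value" channels, 5 boolean event channels),
hourly timestamps, variable per-patient token counts and imbalanced mortality.
A latent severity score s ~ N(0, 1) drives everything: each value concept's
mean shifts linearly with s, each boolean concept's hourly occurrence odds
shift log-linearly with s, and the mortality label is Bernoulli with
logit(alpha + beta s), alpha calibrated so the marginal rate hits the
configured prevalence.

Corruptions:

* **RTR** (random token replacement) flags a fraction of token positions whose
  model inputs are replaced by standard-normal vectors at embedding time.
* **PTS** (patient token swapping) replaces whole tokens — concept, value and
  timestamp — with tokens drawn from other patients.

Both report ``d_proxy = n_changed / n_total``, the fraction of corrupted
tokens, as a proxy for distance from the known-data manifold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .token_encoding import BOOLEAN, VALUE, Vocabulary

__all__ = [
    "MedicalToken",
    "PatientEpisode",
    "CorruptionRecord",
    "CohortConfig",
    "default_vocabulary",
    "generate_cohort",
    "random_token_replacement",
    "patient_token_swapping",
    "proxy_distance",
    "write_cohort",
    "read_cohort",
    "write_episode_table",
    "read_benchmark_episode",
]


@dataclass(frozen=True)
class MedicalToken:
    """Atomic EHR unit: boolean token (t, c) or value token (t, c, v)."""

    t: float  # hours since episode start
    c: str  # concept identifier
    v: float | None = None  # present iff value token

    def __post_init__(self):
        if self.t < 0:
            raise ValueError("timestamp must be nonnegative")


@dataclass
class PatientEpisode:
    tokens: list[MedicalToken]
    label: int  # in-hospital mortality
    episode_id: str
    latent_severity: float | None = None  # synthetic cohorts only; hidden from models
    rtr_flags: frozenset[int] = frozenset()
    rtr_seed: int = 0

    def __post_init__(self):
        if len(self.tokens) < 1:
            raise ValueError("episode needs at least one token")
        if self.label not in (0, 1):
            raise ValueError("label must be 0/1")

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class CorruptionRecord:
    mode: str  # "RTR" | "PTS"
    n_changed: int
    n_total: int
    changed_positions: tuple[int, ...]

    @property
    def d_proxy(self) -> float:
        return proxy_distance(self.n_changed, self.n_total)


def proxy_distance(n_changed: int, n_total: int) -> float:
    """d_proxy = n_changed / n_total, the fraction of corrupted tokens."""
    if n_total < 1:
        raise ValueError("n_total must be positive")
    if not 0 <= n_changed <= n_total:
        raise ValueError("need 0 <= n_changed <= n_total")
    return n_changed / n_total


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

_VALUE_CONCEPTS = [
    # (name, baseline mean, within-patient sd) — placeholder vitals/labs
    ("heart_rate", 85.0, 12.0),
    ("sbp", 120.0, 15.0),
    ("dbp", 70.0, 10.0),
    ("resp_rate", 18.0, 4.0),
    ("spo2", 96.0, 2.5),
    ("temperature", 37.0, 0.6),
    ("glucose", 130.0, 30.0),
    ("lactate", 1.8, 0.8),
    ("creatinine", 1.1, 0.4),
    ("wbc", 9.0, 3.0),
    ("ph", 7.38, 0.05),
    ("urine_output", 60.0, 25.0),
]
_BOOL_CONCEPTS = [
    # (name, baseline per-hour occurrence probability)
    ("gcs_verbal_confused", 0.10),
    ("gcs_motor_abnormal", 0.08),
    ("gcs_eye_closed", 0.08),
    ("vasopressor_given", 0.06),
    ("ventilated", 0.10),
]


def default_vocabulary() -> Vocabulary:
    """17 concepts (12 value + 5 boolean), mirroring the benchmark's feature
    count; names are placeholders."""
    names = [c for c, _, _ in _VALUE_CONCEPTS] + [c for c, _ in _BOOL_CONCEPTS]
    kinds = [VALUE] * len(_VALUE_CONCEPTS) + [BOOLEAN] * len(_BOOL_CONCEPTS)
    return Vocabulary(tuple(names), tuple(kinds))


@dataclass
class CohortConfig:
    n_patients: int = 2000
    window_hours: int = 48
    base_mortality: float = 0.13
    severity_mortality_coef: float = 2.0  # beta: log-odds of death per unit severity
    value_effect: float = 0.5  # severity effect on value means, in units of each sd
    bool_effect: float = 0.5  # severity effect on boolean occurrence log-odds
    tokens_per_hour: float = 1.5  # expected tokens per patient-hour
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.base_mortality < 1.0:
            raise ValueError("base mortality must be in (0, 1)")
        if self.tokens_per_hour <= 0 or self.window_hours <= 0:
            raise ValueError("rates and window must be positive")


def _calibrate_alpha(base_rate: float, beta: float) -> float:
    """Solve E_s[sigmoid(alpha + beta s)] = base_rate for s ~ N(0, 1)."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(61)
    weights = weights / weights.sum()

    def marginal(alpha: float) -> float:
        return float(weights @ (1.0 / (1.0 + np.exp(-(alpha + beta * nodes)))))

    return brentq(lambda a: marginal(a) - base_rate, -30.0, 30.0)


def generate_cohort(config: CohortConfig,
                    vocab: Vocabulary | None = None) -> list[PatientEpisode]:
    """Draw a synthetic cohort; deterministic for a fixed config seed."""
    vocab = vocab or default_vocabulary()
    if vocab.size == 0:
        raise ValueError("vocabulary must be nonempty")
    rng = np.random.default_rng(config.seed)
    alpha = _calibrate_alpha(config.base_mortality, config.severity_mortality_coef)
    n_value = len(_VALUE_CONCEPTS)
    # presence probability per value concept per hour, from the total token rate
    # after subtracting the expected boolean-token load at severity 0
    bool_base = sum(p for _, p in _BOOL_CONCEPTS)
    p_value_obs = max(min((config.tokens_per_hour - bool_base) / n_value, 1.0), 0.01)

    episodes: list[PatientEpisode] = []
    order = {c: i for i, c in enumerate(vocab.concepts)}
    for pid in range(config.n_patients):
        s = rng.standard_normal()
        tokens: list[MedicalToken] = []
        for hour in range(config.window_hours):
            t = float(hour)
            for name, mu, sd in _VALUE_CONCEPTS:
                if rng.uniform() < p_value_obs:
                    v = mu + config.value_effect * sd * s + sd * rng.standard_normal()
                    tokens.append(MedicalToken(t, name, float(v)))
            for name, p0 in _BOOL_CONCEPTS:
                logit0 = math.log(p0 / (1.0 - p0))
                p = 1.0 / (1.0 + math.exp(-(logit0 + config.bool_effect * s)))
                if rng.uniform() < p:
                    tokens.append(MedicalToken(t, name))
        if not tokens:  # degenerate patient: keep the episode non-empty
            name, mu, sd = _VALUE_CONCEPTS[0]
            tokens.append(MedicalToken(0.0, name, mu))
        tokens.sort(key=lambda tok: (tok.t, order[tok.c]))
        p_death = 1.0 / (1.0 + math.exp(-(alpha + config.severity_mortality_coef * s)))
        label = int(rng.uniform() < p_death)
        episodes.append(PatientEpisode(tokens=tokens, label=label,
                                       episode_id=f"ep{pid:05d}",
                                       latent_severity=float(s)))
    return episodes


# ---------------------------------------------------------------------------
# corruption operators
# ---------------------------------------------------------------------------

def _choose_positions(n_total: int, fraction: float,
                      rng: np.random.Generator) -> np.ndarray:
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    n_changed = int(math.floor(fraction * n_total))
    return np.sort(rng.choice(n_total, size=n_changed, replace=False))


def random_token_replacement(
    episode: PatientEpisode, fraction: float, embed_dim: int | None = None,
    seed: int = 0,
) -> tuple[PatientEpisode, CorruptionRecord]:
    """Flag floor(fraction * n) token positions for replacement by N(0, 1)
    input vectors of the model's embedding width; the actual replacement
    happens at embedding time (see :func:`kuq.token_encoding.embed_episode`).
    Token count is preserved. `embed_dim` is informational: replacements take
    the embedding width in effect when the episode is embedded.
    """
    rng = np.random.default_rng(seed)
    pos = _choose_positions(len(episode), fraction, rng)
    record = CorruptionRecord("RTR", len(pos), len(episode), tuple(int(i) for i in pos))
    corrupted = replace(episode, rtr_flags=frozenset(int(i) for i in pos),
                        rtr_seed=seed)
    return corrupted, record


def patient_token_swapping(
    episode: PatientEpisode, fraction: float, donor_pool: list[PatientEpisode],
    seed: int = 0, vocab: Vocabulary | None = None,
) -> tuple[PatientEpisode, CorruptionRecord]:
    """Replace floor(fraction * n) tokens with whole tokens drawn uniformly
    from the pooled donor episodes; timestamps travel with the swapped-in
    token, and the stream is re-sorted by time afterwards."""
    donors = [d for d in donor_pool if d.episode_id != episode.episode_id]
    if not donors:
        raise ValueError("donor pool must be nonempty and exclude the episode")
    rng = np.random.default_rng(seed)
    pos = _choose_positions(len(episode), fraction, rng)
    donor_tokens = [tok for d in donors for tok in d.tokens]
    tokens = list(episode.tokens)
    for i in pos:
        tokens[i] = donor_tokens[rng.integers(len(donor_tokens))]
    if vocab is not None:
        order = {c: j for j, c in enumerate(vocab.concepts)}
        tokens.sort(key=lambda tok: (tok.t, order.get(tok.c, len(order))))
    else:
        tokens.sort(key=lambda tok: (tok.t, tok.c))
    record = CorruptionRecord("PTS", len(pos), len(episode), tuple(int(i) for i in pos))
    corrupted = replace(episode, tokens=tokens)
    return corrupted, record


# ---------------------------------------------------------------------------
# serialization: one tabular text file per episode + a cohort manifest
# ---------------------------------------------------------------------------

def write_episode_table(episode: PatientEpisode, path: str | Path) -> None:
    rows = [
        {"t_hours": tok.t, "concept": tok.c,
         "value": "" if tok.v is None else repr(tok.v),
         "kind": BOOLEAN if tok.v is None else VALUE}
        for tok in episode.tokens
    ]
    pd.DataFrame(rows, columns=["t_hours", "concept", "value", "kind"]).to_csv(
        path, index=False)


def _read_episode_table(path: Path, episode_id: str, label: int) -> PatientEpisode:
    df = pd.read_csv(path, keep_default_na=False)
    tokens = [
        MedicalToken(float(r.t_hours), str(r.concept),
                     None if r.kind == BOOLEAN or r.value == "" else float(r.value))
        for r in df.itertuples()
    ]
    return PatientEpisode(tokens=tokens, label=label, episode_id=episode_id)


def write_cohort(episodes: list[PatientEpisode], outdir: str | Path,
                 config: CohortConfig | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for ep in episodes:
        fname = f"{ep.episode_id}.csv"
        write_episode_table(ep, outdir / fname)
        manifest.append({"episode_id": ep.episode_id, "label": ep.label,
                         "file": fname})
    pd.DataFrame(manifest).to_csv(outdir / "manifest.csv", index=False)
    if config is not None:
        (outdir / "config.yaml").write_text(
            yaml.safe_dump({k: getattr(config, k) for k in
                            ("n_patients", "window_hours", "base_mortality",
                             "severity_mortality_coef", "value_effect",
                             "bool_effect", "tokens_per_hour", "seed")}))


def read_cohort(indir: str | Path) -> list[PatientEpisode]:
    indir = Path(indir)
    manifest = pd.read_csv(indir / "manifest.csv")
    return [
        _read_episode_table(indir / r.file, r.episode_id, int(r.label))
        for r in manifest.itertuples()
    ]


class EpisodeFormatError(ValueError):
    pass


def read_benchmark_episode(path: str | Path, categorical_channels: set[str] = frozenset(),
                           label: int = 0, episode_id: str | None = None) -> PatientEpisode:
    """Adapter for per-episode benchmark tables: one row per hour, one column
    per channel. Non-missing cells become value tokens (continuous channels)
    or boolean tokens named ``channel=level`` (categorical channels); the row
    index in hours becomes the timestamp."""
    path = Path(path)
    df = pd.read_csv(path, keep_default_na=False)
    if df.shape[1] < 1:
        raise EpisodeFormatError(f"{path.name}: no channel columns in header")
    tokens: list[MedicalToken] = []
    for row_i, row in enumerate(df.itertuples(index=False)):
        for col, cell in zip(df.columns, row):
            if cell == "" or (isinstance(cell, float) and np.isnan(cell)):
                continue
            if col in categorical_channels:
                tokens.append(MedicalToken(float(row_i), f"{col}={cell}"))
            else:
                try:
                    v = float(cell)
                except (TypeError, ValueError):
                    raise EpisodeFormatError(
                        f"{path.name}: non-numeric value {cell!r} in row {row_i}, "
                        f"column {col!r}") from None
                tokens.append(MedicalToken(float(row_i), col, v))
    if not tokens:
        raise EpisodeFormatError(f"{path.name}: table contains no observations")
    return PatientEpisode(tokens=tokens, label=label,
                          episode_id=episode_id or path.stem)
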