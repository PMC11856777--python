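"""Token-to-vector encoding for EHR-style token streams.

A patient episode is a time-ordered stream of medical tokens: boolean tokens
``(t, c)`` marking that concept ``c`` occurred at time ``t`` (e.g. a coma-scale
level), and value tokens ``(t, c, v)`` carrying a measurement (e.g. heart rate
88 bpm). Concepts are encoded one-hot; value tokens use the "1-value" variant
(the one-hot vector scaled by the value, z-scored per concept); the timestamp
in hours enters through the sinusoidal ("circular") embedding familiar from
sequence transformers. The concept block and time block are concatenated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Vocabulary",
    "ValueScaler",
    "encode_concept",
    "encode_value_token",
    "time_embedding",
    "embed_episode",
    "embed_cohort",
]

BOOLEAN = "boolean"
VALUE = "value"


class VocabularyError(KeyError):
    pass


@dataclass(frozen=True)
class Vocabulary:
    """Ordered concept list with a kind flag (boolean or value) per concept."""

    concepts: tuple[str, ...]
    kinds: tuple[str, ...]

    def __post_init__(self):
        if len(self.concepts) != len(set(self.concepts)):
            raise ValueError("concepts must be unique")
        if len(self.kinds) != len(self.concepts):
            raise ValueError("one kind flag per concept required")
        if any(k not in (BOOLEAN, VALUE) for k in self.kinds):
            raise ValueError(f"kinds must be '{BOOLEAN}' or '{VALUE}'")

    @property
    def size(self) -> int:
        return len(self.concepts)

    def index(self, concept: str) -> int:
        try:
            return self.concepts.index(concept)
        except ValueError:
            raise VocabularyError(f"unknown concept {concept!r}") from None

    def kind(self, concept: str) -> str:
        return self.kinds[self.index(concept)]

    def value_concepts(self) -> list[str]:
        return [c for c, k in zip(self.concepts, self.kinds) if k == VALUE]

    # two-column (concept, kind) table
    def save(self, path: str | Path) -> None:
        pd.DataFrame({"concept": self.concepts, "kind": self.kinds}).to_csv(
            path, index=False)

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        df = pd.read_csv(path)
        return cls(tuple(df["concept"]), tuple(df["kind"]))


def encode_concept(concept: str, vocab: Vocabulary) -> np.ndarray:
    """Standard one-hot encoding of a concept over the vocabulary."""
    vec = np.zeros(vocab.size)
    vec[vocab.index(concept)] = 1.0
    return vec


def encode_value_token(concept: str, value: float, vocab: Vocabulary) -> np.ndarray:
    """"1-value" encoding: the concept's one-hot vector scaled by the value."""
    if vocab.kind(concept) != VALUE:
        raise TypeError(f"concept {concept!r} is boolean and carries no value")
    return encode_concept(concept, vocab) * float(value)


def time_embedding(t: float, width: int = 16, base: float = 10000.0) -> np.ndarray:
    """Sinusoidal embedding of a scalar time (hours since episode start).

    Pair i occupies components (2i, 2i+1) and carries
    (sin(t / base^(2i/width)), cos(t / base^(2i/width))).
    """
    if width <= 0 or width % 2 != 0:
        raise ValueError("time-embedding width must be a positive even integer")
    i = np.arange(width // 2)
    freq = base ** (-2.0 * i / width)
    ang = float(t) * freq
    out = np.empty(width)
    out[0::2] = np.sin(ang)
    out[1::2] = np.cos(ang)
    return out


class ValueScaler:
    """Per-concept z-scoring of continuous values, fitted on training episodes
    so raw magnitudes (e.g. a heart rate of 88) do not dominate the unit-scale
    one-hot entries."""

    def __init__(self, means: dict[str, float], stds: dict[str, float]):
        self.means = dict(means)
        self.stds = {c: (s if s > 0 else 1.0) for c, s in stds.items()}

    @classmethod
    def fit(cls, episodes, vocab: Vocabulary) -> "ValueScaler":
        values: dict[str, list[float]] = {c: [] for c in vocab.value_concepts()}
        for ep in episodes:
            for tok in ep.tokens:
                if tok.v is not None and tok.c in values:
                    values[tok.c].append(tok.v)
        means = {c: (float(np.mean(v)) if v else 0.0) for c, v in values.items()}
        stds = {c: (float(np.std(v)) if len(v) > 1 else 1.0)
                for c, v in values.items()}
        return cls(means, stds)

    def transform(self, concept: str, value: float) -> float:
        if concept not in self.means:
            return float(value)
        return (float(value) - self.means[concept]) / self.stds[concept]


def embed_episode(episode, vocab: Vocabulary, time_width: int = 16,
                  base: float = 10000.0, scaler: ValueScaler | None = None) -> np.ndarray:
    """Embed an episode as an (n_tokens, V + time_width) matrix.

    Each row concatenates the concept/value encoding with the time embedding.
    Positions flagged by random-token-replacement corruption are overwritten
    with i.i.d. standard-normal vectors drawn from the episode's corruption
    seed, matching the idea of feeding N(0, 1) input instead of real tokens.
    """
    n = len(episode.tokens)
    d = vocab.size + time_width
    out = np.empty((n, d))
    for i, tok in enumerate(episode.tokens):
        if tok.v is None:
            cvec = encode_concept(tok.c, vocab)
        else:
            v = scaler.transform(tok.c, tok.v) if scaler is not None else tok.v
            cvec = encode_value_token(tok.c, v, vocab)
        out[i, :vocab.size] = cvec
        out[i, vocab.size:] = time_embedding(tok.t, time_width, base)
    flags = getattr(episode, "rtr_flags", None)
    if flags:
        rng = np.random.default_rng(getattr(episode, "rtr_seed", 0))
        idx = np.sort(np.asarray(list(flags), dtype=int))
        out[idx] = rng.standard_normal((len(idx), d))
    return out


def embed_cohort(episodes, vocab: Vocabulary, time_width: int = 16,
                 base: float = 10000.0, scaler: ValueScaler | None = None,
                 max_tokens: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Embed and zero-pad a cohort to a common length.

    Returns (X, mask) with X of shape (B, T, V + time_width) and a 0/1 validity
    mask of shape (B, T); T is the longest episode (optionally capped, keeping
    the earliest tokens)."""
    mats = [embed_episode(ep, vocab, time_width, base, scaler) for ep in episodes]
    if max_tokens is not None:
        mats = [m[:max_tokens] for m in mats]
    T = max(m.shape[0] for m in mats)
    d = mats[0].shape[1]
    X = np.zeros((len(mats), T, d))
    mask = np.zeros((len(mats), T))
    for i, m in enumerate(mats):
        X[i, :m.shape[0]] = m
        mask[i, :m.shape[0]] = 1.0
    return X, mask
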