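"""Sentence-level coherence: next-sentence probabilities and prompt-anchored
embedding-distance trajectories.

A prompt turn is embedded as the mean of its word vectors; each response
sentence is embedded the same way, and the trajectory records the distance
between the two as a function of the sentence's position after the prompt.
Ordinary least squares over pooled trajectory points gives the intercept and
slope (with 95% confidence intervals) summarizing topic drift.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
from scipy import stats as sps

from .transcript_io import (
    DialogueExchange,
    Sentence,
    Speaker,
    Token,
    TokenKind,
    Transcript,
    Turn,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingBackend",
    "CoherenceProfile",
    "TrajectoryPoint",
    "TrajectoryFit",
    "sentence_pairs",
    "mean_nsp",
    "prompt_embedding",
    "sentence_embedding",
    "trajectory_points",
    "fit_trajectory",
    "participant_trajectory_points",
]

#: token kinds carrying embeddable lexical content
_EMBEDDABLE = frozenset(
    {TokenKind.WORD, TokenKind.FILLER_UM, TokenKind.FILLER_UH, TokenKind.INCOMPLETE}
)


class EmbeddingBackend(Protocol):
    """Word-embedding + next-sentence-probability provider.

    Must be deterministic for fixed inputs; vectors share one dimension and
    probabilities lie in [0, 1].
    """

    def embed_words(self, words: Sequence[str]) -> np.ndarray:
        """(len(words), dim) array, one row per word."""
        ...

    def next_sentence_probability(self, first: Sequence[str], second: Sequence[str]) -> float:
        ...


@dataclass
class CoherenceProfile:
    participant_id: str
    pair_probabilities: list[tuple[int, float]]
    mean_nsp: float | None
    min_words: int = 0
    length_weighting: bool = False


@dataclass(frozen=True)
class TrajectoryPoint:
    exchange: int
    position: int
    distance: float


@dataclass
class TrajectoryFit:
    intercept: float
    slope: float
    ci95_intercept: tuple[float, float]
    ci95_slope: tuple[float, float]
    n_points: int


def _words(sentence: Sentence) -> list[str]:
    return [t.norm for t in sentence.tokens if t.kind in _EMBEDDABLE]


def sentence_pairs(transcript: Transcript) -> list[tuple[Sentence, Sentence]]:
    """Ordered (previous sentence, participant sentence) pairs.

    Every participant sentence with an immediately preceding sentence — by
    either speaker — yields one pair; a transcript-initial participant
    sentence yields none.
    """
    sentences = list(transcript.all_sentences())
    return [
        (prev, cur)
        for prev, cur in zip(sentences, sentences[1:])
        if cur.speaker is Speaker.PARTICIPANT
    ]


def mean_nsp(
    pairs: Sequence[tuple[Sentence, Sentence]],
    backend: EmbeddingBackend,
    min_words: int = 0,
    length_weighting: bool = False,
    participant_id: str = "",
) -> CoherenceProfile:
    """Aggregate next-sentence probabilities over a participant's pairs.

    ``min_words`` drops pairs whose *second* sentence is shorter; with
    ``length_weighting`` each retained probability is weighted by the second
    sentence's length normalized to the retained mean length. If every pair
    is filtered out, ``mean_nsp`` is None (missing, flagged for imputation).
    """
    retained: list[tuple[int, float, int]] = []
    for idx, (first, second) in enumerate(pairs):
        n_words = second.word_count
        if n_words < min_words:
            continue
        p = float(backend.next_sentence_probability(_words(first), _words(second)))
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"backend probability {p} outside [0, 1]")
        retained.append((idx, p, n_words))

    if not retained:
        logger.warning("participant %s: no sentence pairs retained", participant_id)
        return CoherenceProfile(participant_id, [], None, min_words, length_weighting)

    probs = np.array([p for _, p, _ in retained])
    if length_weighting:
        lengths = np.array([n for _, _, n in retained], dtype=float)
        weights = lengths / lengths.mean()
        mean = float(np.sum(weights * probs) / np.sum(weights))
    else:
        mean = float(probs.mean())
    return CoherenceProfile(
        participant_id,
        [(idx, p) for idx, p, _ in retained],
        mean,
        min_words,
        length_weighting,
    )


def sentence_embedding(sentence: Sentence, backend: EmbeddingBackend) -> np.ndarray | None:
    """Mean-pooled word-vector embedding; None if nothing is embeddable."""
    words = _words(sentence)
    if not words:
        return None
    return np.asarray(backend.embed_words(words), dtype=float).mean(axis=0)


def prompt_embedding(turn: Turn, backend: EmbeddingBackend) -> np.ndarray:
    """Mean embedding over every word of every sentence in the turn."""
    words = [w for s in turn.sentences for w in _words(s)]
    if not words:
        raise ValueError("turn has no embeddable tokens")
    return np.asarray(backend.embed_words(words), dtype=float).mean(axis=0)


def _distance(u: np.ndarray, v: np.ndarray, metric: str) -> float:
    if metric == "cosine":
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu == 0 or nv == 0:
            raise ValueError("cosine distance undefined for zero vector")
        return float(1.0 - np.dot(u, v) / (nu * nv))
    if metric == "euclidean":
        return float(np.linalg.norm(u - v))
    if metric == "mean_abs":
        return float(np.mean(np.abs(u - v)))
    raise ValueError(f"unknown metric {metric!r}")


def trajectory_points(
    exchange: DialogueExchange,
    backend: EmbeddingBackend,
    metric: str = "cosine",
) -> list[TrajectoryPoint]:
    """One (position, distance) point per embeddable response sentence.

    Positions count 1..k from the prompt; sentences with no embeddable
    content (e.g., redactions only) are skipped with a log message.
    """
    e_prompt = prompt_embedding(exchange.prompt, backend)
    points = []
    for j, sentence in enumerate(exchange.responses, start=1):
        e_s = sentence_embedding(sentence, backend)
        if e_s is None:
            logger.info("exchange %d: unembeddable sentence at position %d skipped", exchange.index, j)
            continue
        points.append(
            TrajectoryPoint(
                exchange=exchange.index,
                position=j,
                distance=_distance(e_prompt, e_s, metric),
            )
        )
    return points


def participant_trajectory_points(
    exchanges: Sequence[DialogueExchange],
    backend: EmbeddingBackend,
    metric: str = "cosine",
) -> list[TrajectoryPoint]:
    points: list[TrajectoryPoint] = []
    for ex in exchanges:
        if ex.responses:
            points.extend(trajectory_points(ex, backend, metric))
    return points


def fit_trajectory(points: Sequence[TrajectoryPoint]) -> TrajectoryFit:
    """OLS of distance on position with t-based 95% confidence intervals."""
    if len(points) < 3:
        raise ValueError("need at least 3 trajectory points")
    x = np.array([p.position for p in points], dtype=float)
    y = np.array([p.distance for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("all positions identical; slope undefined")

    n = len(x)
    xbar, ybar = x.mean(), y.mean()
    sxx = np.sum((x - xbar) ** 2)
    slope = float(np.sum((x - xbar) * (y - ybar)) / sxx)
    intercept = float(ybar - slope * xbar)

    resid = y - (intercept + slope * x)
    dof = n - 2
    s2 = float(np.sum(resid**2) / dof) if dof > 0 else 0.0
    se_slope = math.sqrt(s2 / sxx)
    se_intercept = math.sqrt(s2 * (1.0 / n + xbar**2 / sxx))
    tcrit = float(sps.t.ppf(0.975, dof)) if dof > 0 else float("nan")

    return TrajectoryFit(
        intercept=intercept,
        slope=slope,
        ci95_intercept=(intercept - tcrit * se_intercept, intercept + tcrit * se_intercept),
        ci95_slope=(slope - tcrit * se_slope, slope + tcrit * se_slope),
        n_points=n,
    )
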