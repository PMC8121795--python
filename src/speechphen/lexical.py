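"""Group word-usage comparison via Dirichlet-prior weighted log-odds.

For each word *w* with counts ``y_a``, ``y_b`` in groups of ``n_a``, ``n_b``
tokens and an informative prior ``alpha_w = alpha0 * p_w`` (``p_w`` the
word's relative frequency in the pooled corpus), the statistic is::

    delta_w = log[(y_a + a_w) / (n_a + alpha0 - y_a - a_w)]
            - log[(y_b + a_w) / (n_b + alpha0 - y_b - a_w)]
    var_w   = 1 / (y_a + a_w) + 1 / (y_b + a_w)
    z_w     = delta_w / sqrt(var_w)

Pronoun classes and incomplete words are additionally pooled into
pseudo-words (``<PRON_1SG>``, ..., ``<INCOMPLETE>``) so class-level trends
are scored alongside individual surface forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .transcript_io import PronounClass, Token, TokenKind, Transcript

__all__ = [
    "PSEUDO_WORDS",
    "GroupCounts",
    "WordScore",
    "LexicalProfile",
    "accumulate_counts",
    "weighted_log_odds",
    "lexical_profile",
    "write_word_scores",
]

PRONOUN_PSEUDO = {
    PronounClass.FIRST_SG: "<PRON_1SG>",
    PronounClass.FIRST_PL: "<PRON_1PL>",
    PronounClass.SECOND: "<PRON_2>",
    PronounClass.THIRD: "<PRON_3>",
}
INCOMPLETE_PSEUDO = "<INCOMPLETE>"
PSEUDO_WORDS = frozenset(PRONOUN_PSEUDO.values()) | {INCOMPLETE_PSEUDO}


@dataclass
class GroupCounts:
    """Per-word token counts for two groups over a shared vocabulary."""

    vocabulary: list[str]
    counts_a: np.ndarray
    counts_b: np.ndarray
    n_a: int
    n_b: int

    def __post_init__(self) -> None:
        self.counts_a = np.asarray(self.counts_a, dtype=np.int64)
        self.counts_b = np.asarray(self.counts_b, dtype=np.int64)
        if len(self.vocabulary) != len(self.counts_a) or len(self.vocabulary) != len(
            self.counts_b
        ):
            raise ValueError("vocabulary and count vectors must align")
        if (self.counts_a < 0).any() or (self.counts_b < 0).any():
            raise ValueError("counts must be nonnegative")

    def swapped(self) -> "GroupCounts":
        return GroupCounts(
            self.vocabulary, self.counts_b.copy(), self.counts_a.copy(), self.n_b, self.n_a
        )


@dataclass(frozen=True)
class WordScore:
    word: str
    count_a: int
    count_b: int
    delta: float
    variance: float
    z: float
    prior_alpha: float


@dataclass
class LexicalProfile:
    """Per-participant disfluency and pronoun rates (per 100 counted words)."""

    participant_id: str
    token_total: int
    incomplete_count: int
    incomplete_rate: float
    laughter_rate: float
    um_rate: float
    uh_rate: float
    first_sg_rate: float
    first_pl_rate: float
    second_rate: float
    third_rate: float
    uh_um_ratio: float | None


def _token_words(tokens) -> list[str]:
    """Countable word surfaces (case-folded) plus pseudo-word expansions."""
    out = []
    for tok in tokens:
        if tok.kind is TokenKind.INCOMPLETE:
            out.append(INCOMPLETE_PSEUDO)
        elif tok.counted:
            out.append(tok.norm)
            if tok.pronoun_class is not PronounClass.NONE:
                out.append(PRONOUN_PSEUDO[tok.pronoun_class])
    return out


def accumulate_counts(
    transcripts: Sequence[Transcript],
    group_labels: Sequence[str],
    group_a: str = "SSD",
    group_b: str = "HC",
) -> GroupCounts:
    """Accumulate participant-token counts for two groups.

    Only participant speech is counted. Individual incomplete fragments are
    pooled into ``<INCOMPLETE>``; pronoun surfaces are counted individually
    *and* pooled into their class pseudo-word. ``n_a``/``n_b`` are counted
    spoken tokens (pseudo-word pooling does not inflate the totals).
    """
    if len(transcripts) != len(group_labels):
        raise ValueError("transcripts and group_labels must align")
    counts: dict[str, list[int]] = {}
    totals = {group_a: 0, group_b: 0}
    seen = {group_a: 0, group_b: 0}
    for tr, label in zip(transcripts, group_labels):
        if label not in totals:
            raise ValueError(f"unexpected group label {label!r}")
        seen[label] += 1
        col = 0 if label == group_a else 1
        toks = list(tr.participant_tokens())
        totals[label] += sum(1 for t in toks if t.counted)
        for w in _token_words(toks):
            if w not in counts:
                counts[w] = [0, 0]
            counts[w][col] += 1
    for label, n in seen.items():
        if n == 0:
            raise ValueError(f"no transcripts in group {label!r}")
    vocab = sorted(counts)
    return GroupCounts(
        vocabulary=vocab,
        counts_a=np.array([counts[w][0] for w in vocab]),
        counts_b=np.array([counts[w][1] for w in vocab]),
        n_a=totals[group_a],
        n_b=totals[group_b],
    )


def weighted_log_odds(
    gc: GroupCounts, alpha0: float = 100.0, min_count: int = 0
) -> list[WordScore]:
    """Score every vocabulary word; result sorted by z descending.

    ``alpha0`` is the prior concentration; per-word pseudo-counts are
    proportional to pooled relative frequency. ``min_count`` drops words
    with fewer pooled occurrences before scoring (reporting filter).
    """
    if alpha0 <= 0:
        raise ValueError("alpha0 must be positive")
    pooled_all = gc.counts_a + gc.counts_b
    pooled_total = pooled_all.sum()
    if pooled_total == 0:
        raise ValueError("empty counts")
    # words never observed in the pooled corpus have alpha_w = 0 and cannot
    # be scored; min_count additionally filters unstable rare words
    keep = np.flatnonzero(pooled_all >= max(min_count, 1))
    y_a = gc.counts_a[keep].astype(float)
    y_b = gc.counts_b[keep].astype(float)
    alpha_w = alpha0 * pooled_all[keep] / pooled_total

    delta = np.log(y_a + alpha_w) - np.log(gc.n_a + alpha0 - y_a - alpha_w)
    delta -= np.log(y_b + alpha_w) - np.log(gc.n_b + alpha0 - y_b - alpha_w)
    variance = 1.0 / (y_a + alpha_w) + 1.0 / (y_b + alpha_w)
    z = delta / np.sqrt(variance)

    scores = [
        WordScore(
            word=gc.vocabulary[i],
            count_a=int(gc.counts_a[i]),
            count_b=int(gc.counts_b[i]),
            delta=float(delta[j]),
            variance=float(variance[j]),
            z=float(z[j]),
            prior_alpha=float(alpha_w[j]),
        )
        for j, i in enumerate(keep)
    ]
    scores.sort(key=lambda s: s.z, reverse=True)
    return scores


def lexical_profile(transcript: Transcript) -> LexicalProfile:
    """Disfluency/pronoun rates per 100 counted participant tokens."""
    toks = list(transcript.participant_tokens())
    total = sum(1 for t in toks if t.counted)
    if total == 0:
        raise ValueError(
            f"transcript {transcript.participant_id!r} has no participant tokens"
        )

    def kind_count(kind: TokenKind) -> int:
        return sum(1 for t in toks if t.kind is kind)

    def cls_count(cls: PronounClass) -> int:
        return sum(1 for t in toks if t.pronoun_class is cls)

    n_um = kind_count(TokenKind.FILLER_UM)
    n_uh = kind_count(TokenKind.FILLER_UH)
    n_inc = kind_count(TokenKind.INCOMPLETE)
    rate = lambda c: 100.0 * c / total  # noqa: E731
    return LexicalProfile(
        participant_id=transcript.participant_id,
        token_total=total,
        incomplete_count=n_inc,
        incomplete_rate=rate(n_inc),
        laughter_rate=rate(kind_count(TokenKind.LAUGHTER)),
        um_rate=rate(n_um),
        uh_rate=rate(n_uh),
        first_sg_rate=rate(cls_count(PronounClass.FIRST_SG)),
        first_pl_rate=rate(cls_count(PronounClass.FIRST_PL)),
        second_rate=rate(cls_count(PronounClass.SECOND)),
        third_rate=rate(cls_count(PronounClass.THIRD)),
        uh_um_ratio=(n_uh / (n_uh + n_um)) if (n_uh + n_um) > 0 else None,
    )


def write_word_scores(scores: Sequence[WordScore], path: str | Path) -> None:
    """Write the ranked word-score table as CSV."""
    pd.DataFrame(
        {
            "word": [s.word for s in scores],
            "count_a": [s.count_a for s in scores],
            "count_b": [s.count_b for s in scores],
            "delta": [s.delta for s in scores],
            "z": [s.z for s in scores],
        }
    ).to_csv(path, index=False)
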