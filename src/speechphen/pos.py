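"""Part-of-speech tagging backends and per-100-word rate profiles.

Ten coarse categories are profiled: adverb, determiner, adjective, pronoun,
preposition, particle, conjunction, noun, interjection, verb. Anything else
(incomplete fragments, redactions, numerals, out-of-lexicon items) is
labelled ``OTHER`` — excluded from the ten numerators but kept in the
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence

import pandas as pd

from .resources import word_lexicon
from .transcript_io import Token, TokenKind, Transcript

__all__ = [
    "POS_CATEGORIES",
    "OTHER",
    "POSProfile",
    "TaggerBackend",
    "LexiconTagger",
    "SpacyTagger",
    "tag_transcript",
    "pos_rates",
    "pos_profile",
    "write_pos_profiles",
]

POS_CATEGORIES = (
    "adverb",
    "determiner",
    "adjective",
    "pronoun",
    "preposition",
    "particle",
    "conjunction",
    "noun",
    "interjection",
    "verb",
)
OTHER = "OTHER"
_VALID_LABELS = frozenset(POS_CATEGORIES) | {OTHER}


@dataclass
class POSProfile:
    participant_id: str
    token_total: int
    rates: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(POS_CATEGORIES) - set(self.rates)
        if missing:
            raise ValueError(f"POSProfile missing categories: {sorted(missing)}")


class TaggerBackend(Protocol):
    """Deterministic per-token coarse POS tagger."""

    def tag(self, tokens: Sequence[Token]) -> list[str]:
        """One label from the closed set per token, aligned with input."""
        ...


def _marker_label(token: Token) -> str | None:
    """Labels forced by token kind, independent of the backend."""
    if token.kind in (TokenKind.FILLER_UM, TokenKind.FILLER_UH):
        return "interjection"
    if token.kind in (TokenKind.INCOMPLETE, TokenKind.REDACTION, TokenKind.LAUGHTER):
        return OTHER
    return None


class LexiconTagger:
    """Closed-lexicon rule tagger over the shipped generator vocabulary.

    Exact and deterministic by construction; out-of-lexicon words tag as
    ``OTHER``. This is the hermetic test/default backend.
    """

    def __init__(self, lexicon: dict[str, dict[str, str]] | None = None):
        lex = lexicon if lexicon is not None else word_lexicon()
        self._pos = {w: entry["pos"] for w, entry in lex.items()}

    def tag(self, tokens: Sequence[Token]) -> list[str]:
        labels = []
        for tok in tokens:
            forced = _marker_label(tok)
            if forced is not None:
                labels.append(forced)
            else:
                labels.append(self._pos.get(tok.norm, OTHER))
        return labels


#: spaCy universal POS -> coarse category (production backend mapping).
UPOS_TO_COARSE = {
    "ADV": "adverb",
    "DET": "determiner",
    "ADJ": "adjective",
    "PRON": "pronoun",
    "ADP": "preposition",
    "PART": "particle",
    "CCONJ": "conjunction",
    "SCONJ": "conjunction",
    "NOUN": "noun",
    "PROPN": "noun",
    "INTJ": "interjection",
    "VERB": "verb",
    "AUX": "verb",
}


class SpacyTagger:
    """Optional pretrained-model backend (requires ``spacy`` + a model).

    Auxiliaries fold into verb, proper nouns into noun, both conjunction
    types into conjunction; numerals/symbols/unknowns become ``OTHER``.
    """

    def __init__(self, model: str = "en_core_web_sm"):
        try:
            import spacy  # noqa: PLC0415
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "SpacyTagger requires the optional 'spacy' package and a "
                f"downloaded model ({model!r}); use LexiconTagger for a "
                "hermetic backend"
            ) from exc
        self._nlp = spacy.load(model, disable=["parser", "ner", "lemmatizer"])

    def tag(self, tokens: Sequence[Token]) -> list[str]:  # pragma: no cover
        labels = []
        words = [t.text for t in tokens]
        doc = self._nlp(spacy_doc_from(words, self._nlp.vocab))
        upos = {i: t.pos_ for i, t in enumerate(doc)}
        for i, tok in enumerate(tokens):
            forced = _marker_label(tok)
            labels.append(forced if forced is not None else UPOS_TO_COARSE.get(upos.get(i, ""), OTHER))
        return labels


def spacy_doc_from(words, vocab):  # pragma: no cover - optional dependency
    from spacy.tokens import Doc

    return Doc(vocab, words=words)


def tag_transcript(
    transcript: Transcript, backend: TaggerBackend
) -> list[tuple[Token, str]]:
    """Tag every participant token; interviewer speech is not tagged."""
    tagged = []
    for si, sentence in enumerate(transcript.participant_sentences()):
        try:
            labels = backend.tag(sentence.tokens)
        except Exception as exc:
            raise RuntimeError(
                f"tagger backend failed on participant sentence {si} "
                f"({sentence.text[:40]!r}...)"
            ) from exc
        if len(labels) != len(sentence.tokens):
            raise RuntimeError(
                f"tagger backend returned {len(labels)} labels for "
                f"{len(sentence.tokens)} tokens in sentence {si}"
            )
        bad = set(labels) - _VALID_LABELS
        if bad:
            raise RuntimeError(f"tagger backend emitted unknown labels {sorted(bad)}")
        tagged.extend(zip(sentence.tokens, labels))
    return tagged


def pos_rates(labels: Sequence[str], token_total: int, participant_id: str = "") -> POSProfile:
    """Counts per 100 words for the ten categories.

    ``token_total`` is the counted-token denominator defined by the lexical
    module (spoken tokens; laughter/redactions excluded).
    """
    if token_total <= 0:
        raise ValueError("token_total must be positive")
    counts = {cat: 0 for cat in POS_CATEGORIES}
    for lab in labels:
        if lab in counts:
            counts[lab] += 1
    rates = {cat: 100.0 * c / token_total for cat, c in counts.items()}
    return POSProfile(participant_id=participant_id, token_total=token_total, rates=rates)


def pos_profile(transcript: Transcript, backend: TaggerBackend) -> POSProfile:
    """Tag and profile one transcript's participant speech."""
    tagged = tag_transcript(transcript, backend)
    labels = [lab for tok, lab in tagged if tok.counted]
    total = sum(1 for tok, _ in tagged if tok.counted)
    return pos_rates(labels, total, participant_id=transcript.participant_id)


def write_pos_profiles(profiles: Sequence[POSProfile], path: str | Path) -> None:
    rows = [
        {"participant_id": p.participant_id, **{c: p.rates[c] for c in POS_CATEGORIES}}
        for p in profiles
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
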