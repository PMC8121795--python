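"""Transcript data model, parsing, tokenization, and dialogue segmentation.

The package-native transcript format is a JSON document::

    {
      "participant_id": "P01",
      "group": "SSD",                  # "SSD" | "HC" | "unknown"
      "cohort": "1",                   # optional
      "metadata": {"age": 35, "sex": "F", "race": "...", "education_years": 14},
      "turns": [
        {"speaker": "I", "text": "How are you?"},
        {"speaker": "P", "text": "I am fine. Um, really fine."}
      ]
    }

Transcriber annotations understood by the tokenizer: ``um``/``uh`` filled
pauses, trailing-hyphen incomplete words (``sto-``), ``[laughter]`` marks,
and ``[name]``/``[date]`` redactions.
"""

from __future__ import annotations

import json
import logging
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

from .resources import pronoun_lexicon

logger = logging.getLogger(__name__)

__all__ = [
    "TokenKind",
    "PronounClass",
    "Speaker",
    "Token",
    "Sentence",
    "Turn",
    "Transcript",
    "DialogueExchange",
    "TranscriptParseError",
    "tokenize",
    "split_sentences",
    "parse_transcript",
    "serialize_transcript",
    "load_transcript",
    "save_transcript",
    "extract_exchanges",
    "read_transcriber_xml",
]


class TranscriptParseError(ValueError):
    """Raised when an input document violates the transcript schema."""


class TokenKind(str, Enum):
    WORD = "word"
    FILLER_UM = "filler_um"
    FILLER_UH = "filler_uh"
    INCOMPLETE = "incomplete"
    LAUGHTER = "laughter"
    REDACTION = "redaction"


class PronounClass(str, Enum):
    FIRST_SG = "first_sg"
    FIRST_PL = "first_pl"
    SECOND = "second"
    THIRD = "third"
    NONE = "none"


class Speaker(str, Enum):
    INTERVIEWER = "I"
    PARTICIPANT = "P"


#: token kinds that enter rate denominators (spoken material; laughter and
#: redaction placeholders are excluded, fillers and incomplete words count).
COUNTED_KINDS = frozenset(
    {TokenKind.WORD, TokenKind.FILLER_UM, TokenKind.FILLER_UH, TokenKind.INCOMPLETE}
)


@dataclass(frozen=True)
class Token:
    """One whitespace-delimited transcript item.

    ``text`` preserves surface form; matching is case-insensitive via
    :attr:`norm`.
    """

    text: str
    kind: TokenKind
    pronoun_class: PronounClass = PronounClass.NONE

    @property
    def norm(self) -> str:
        return self.text.casefold()

    @property
    def counted(self) -> bool:
        return self.kind in COUNTED_KINDS


@dataclass
class Sentence:
    tokens: list[Token]
    speaker: Speaker
    index_in_turn: int = 0

    @property
    def word_count(self) -> int:
        """Number of counted (spoken) tokens."""
        return sum(1 for t in self.tokens if t.counted)

    @property
    def text(self) -> str:
        return " ".join(t.text for t in self.tokens)


@dataclass
class Turn:
    speaker: Speaker
    sentences: list[Sentence]
    raw_text: str = ""

    def tokens(self) -> Iterator[Token]:
        for s in self.sentences:
            yield from s.tokens


@dataclass
class Transcript:
    participant_id: str
    group: str = "unknown"
    cohort: str | None = None
    turns: list[Turn] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def participant_tokens(self) -> Iterator[Token]:
        for turn in self.turns:
            if turn.speaker is Speaker.PARTICIPANT:
                yield from turn.tokens()

    def participant_sentences(self) -> Iterator[Sentence]:
        for turn in self.turns:
            if turn.speaker is Speaker.PARTICIPANT:
                yield from turn.sentences

    def all_sentences(self) -> Iterator[Sentence]:
        for turn in self.turns:
            yield from turn.sentences

    @property
    def participant_word_count(self) -> int:
        """Counted participant tokens (rate denominator)."""
        return sum(1 for t in self.participant_tokens() if t.counted)


@dataclass
class DialogueExchange:
    """An interviewer prompt plus the participant sentences that answer it."""

    prompt: Turn
    responses: list[Sentence]
    index: int = 0


# ---------------------------------------------------------------------------
# tokenization
# ---------------------------------------------------------------------------

_BRACKET_MARKERS = {
    "[laughter]": TokenKind.LAUGHTER,
    "[name]": TokenKind.REDACTION,
    "[date]": TokenKind.REDACTION,
}
_FILLERS = {"um": TokenKind.FILLER_UM, "uh": TokenKind.FILLER_UH}
# edge punctuation stripped before classification; trailing "-" is meaningful
# and square brackets are handled first (marker tokens keep them)
_MARKER_STRIP = ".,?!;:\"'()“”‘’…"
_STRIP_CHARS = _MARKER_STRIP + "[]"
_INCOMPLETE_RE = re.compile(r"[^\W\d_]-$", re.UNICODE)


def _classify(item: str) -> Token | None:
    bracketed = item.casefold().strip(_MARKER_STRIP)
    if bracketed in _BRACKET_MARKERS:
        return Token(bracketed, _BRACKET_MARKERS[bracketed])
    # generic punctuation strip, keeping a trailing hyphen intact
    surface = item.strip(_STRIP_CHARS)
    if not surface or not re.search(r"\w", surface):
        return None
    folded = surface.casefold()
    if _INCOMPLETE_RE.search(surface):
        return Token(surface, TokenKind.INCOMPLETE)
    if folded in _FILLERS:
        return Token(surface, _FILLERS[folded])
    for cls, forms in pronoun_lexicon().items():
        if folded in forms:
            return Token(surface, TokenKind.WORD, PronounClass(cls))
    return Token(surface, TokenKind.WORD)


def tokenize(utterance: str) -> list[Token]:
    """Tokenize one utterance into annotated :class:`Token` objects.

    Whitespace-delimited; edge punctuation is stripped, the trailing hyphen
    of incomplete words is preserved, and marker tokens (``[laughter]``,
    ``[name]``, ``[date]``) are recognized case-insensitively. An empty or
    whitespace-only utterance yields an empty list.
    """
    tokens = []
    for item in utterance.split():
        tok = _classify(item)
        if tok is not None:
            tokens.append(tok)
    return tokens


_SENT_BOUNDARY = re.compile(r"([.?!…]+[\"'”’)\]]*)(\s+|$)")


def split_sentences(turn_text: str) -> list[str]:
    """Split a turn's raw text at transcriber terminal punctuation.

    Only ``.``, ``?``, ``!`` (and runs thereof) end a sentence. Incomplete
    words, fillers, and repeated words never cause a split; a trailing
    fragment with no terminal punctuation becomes a final sentence.
    """
    text = turn_text.strip()
    if not text:
        return []
    sentences = []
    pos = 0
    for m in _SENT_BOUNDARY.finditer(text):
        chunk = text[pos : m.end(1)].strip()
        if chunk:
            sentences.append(chunk)
        pos = m.end()
    tail = text[pos:].strip()
    if tail:
        sentences.append(tail)
    return sentences


# ---------------------------------------------------------------------------
# parsing / serialization
# ---------------------------------------------------------------------------

_SPEAKER_ALIASES = {
    "i": Speaker.INTERVIEWER,
    "interviewer": Speaker.INTERVIEWER,
    "p": Speaker.PARTICIPANT,
    "participant": Speaker.PARTICIPANT,
    "subject": Speaker.PARTICIPANT,
}

_GROUPS = {"SSD", "HC", "unknown"}


def _build_turn(speaker: Speaker, raw_text: str) -> Turn:
    sentences = []
    for i, sent_text in enumerate(split_sentences(raw_text)):
        toks = tokenize(sent_text)
        if toks:
            sentences.append(Sentence(tokens=toks, speaker=speaker, index_in_turn=len(sentences)))
    return Turn(speaker=speaker, sentences=sentences, raw_text=raw_text)


def parse_transcript(source: dict) -> Transcript:
    """Parse a schema-conforming JSON document into a :class:`Transcript`.

    Adjacent turns by the same speaker are merged; raw turn text is kept on
    each :class:`Turn` for provenance and round-tripping.
    """
    if not isinstance(source, dict):
        raise TranscriptParseError("transcript document must be a JSON object")
    raw_turns = source.get("turns")
    if not raw_turns:
        raise TranscriptParseError("transcript document has no turns")
    group = source.get("group", "unknown")
    if group not in _GROUPS:
        raise TranscriptParseError(f"unknown group label {group!r}")

    merged: list[tuple[Speaker, list[str]]] = []
    for idx, raw in enumerate(raw_turns):
        try:
            speaker_field = raw["speaker"]
            text = raw["text"]
        except (TypeError, KeyError) as exc:
            raise TranscriptParseError(f"turn {idx}: missing {exc} field") from exc
        speaker = _SPEAKER_ALIASES.get(str(speaker_field).casefold())
        if speaker is None:
            raise TranscriptParseError(
                f"turn {idx}: unrecognized speaker {speaker_field!r}"
            )
        if merged and merged[-1][0] is speaker:
            merged[-1][1].append(text)
        else:
            merged.append((speaker, [text]))

    turns = [_build_turn(spk, " ".join(parts)) for spk, parts in merged]
    turns = [t for t in turns if t.sentences]
    return Transcript(
        participant_id=str(source.get("participant_id", "")),
        group=group,
        cohort=source.get("cohort"),
        turns=turns,
        metadata=dict(source.get("metadata", {})),
    )


def serialize_transcript(transcript: Transcript) -> dict:
    """Inverse of :func:`parse_transcript` (raw turn text is authoritative)."""
    doc = {
        "participant_id": transcript.participant_id,
        "group": transcript.group,
        "cohort": transcript.cohort,
        "metadata": dict(transcript.metadata),
        "turns": [
            {"speaker": turn.speaker.value, "text": turn.raw_text}
            for turn in transcript.turns
        ],
    }
    return doc


def load_transcript(path: str | Path) -> Transcript:
    with open(path) as f:
        return parse_transcript(json.load(f))


def save_transcript(transcript: Transcript, path: str | Path) -> None:
    with open(path, "w") as f:
        json.dump(serialize_transcript(transcript), f, indent=1)
        f.write("\n")


# ---------------------------------------------------------------------------
# dialogue exchanges
# ---------------------------------------------------------------------------


def extract_exchanges(transcript: Transcript) -> list[DialogueExchange]:
    """Segment a transcript into prompt-anchored dialogue exchanges.

    Each interviewer turn that is followed by participant speech yields one
    exchange holding exactly the participant sentences spoken before the
    next interviewer turn. Participant speech preceding the first prompt is
    excluded (and logged); a trailing prompt with no response yields none.
    """
    exchanges: list[DialogueExchange] = []
    if not any(t.speaker is Speaker.INTERVIEWER for t in transcript.turns):
        logger.warning(
            "transcript %s has no interviewer turns; no exchanges",
            transcript.participant_id,
        )
        return exchanges

    current_prompt: Turn | None = None
    for turn in transcript.turns:
        if turn.speaker is Speaker.INTERVIEWER:
            current_prompt = turn
        else:
            if current_prompt is None:
                logger.info(
                    "transcript %s: participant speech before first prompt "
                    "excluded from exchanges",
                    transcript.participant_id,
                )
                continue
            exchanges.append(
                DialogueExchange(
                    prompt=current_prompt,
                    responses=list(turn.sentences),
                    index=len(exchanges),
                )
            )
            current_prompt = None
    return exchanges


# ---------------------------------------------------------------------------
# optional Transcriber-style XML reader
# ---------------------------------------------------------------------------


def read_transcriber_xml(source: str | Path, participant_speakers: set[str] | None = None) -> Transcript:
    """Read a Transcriber-style XML transcript.

    Expects ``<Speakers><Speaker id=... name=.../></Speakers>`` and
    speaker-segmented ``<Turn speaker=...>`` elements whose text content is
    the utterance. Speakers whose name contains "interview" map to the
    interviewer; everything else (or ids in ``participant_speakers``) maps
    to the participant. Unrecognized markup inside turns is skipped with a
    warning.
    """
    if isinstance(source, Path):
        text = source.read_text()
    elif not source.lstrip().startswith("<") and Path(source).exists():
        text = Path(source).read_text()
    else:
        text = source
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise TranscriptParseError(f"invalid XML: {exc}") from exc

    roles: dict[str, str] = {}
    for spk in root.iter("Speaker"):
        sid = spk.get("id", "")
        name = (spk.get("name") or "").casefold()
        if participant_speakers is not None:
            roles[sid] = "P" if sid in participant_speakers else "I"
        else:
            roles[sid] = "I" if "interview" in name else "P"

    turns = []
    for idx, turn_el in enumerate(root.iter("Turn")):
        sid = turn_el.get("speaker", "")
        role = roles.get(sid)
        if role is None:
            logger.warning("Turn %d: unknown speaker id %r; skipped", idx, sid)
            continue
        pieces = [turn_el.text or ""]
        for child in turn_el:
            if child.tag not in {"Sync", "Comment", "Who", "Event"}:
                logger.warning("Turn %d: unrecognized markup <%s>; skipped", idx, child.tag)
            pieces.append(child.tail or "")
        raw = " ".join(p.strip() for p in pieces if p.strip())
        if raw:
            turns.append({"speaker": role, "text": raw})

    if not turns:
        raise TranscriptParseError("XML document contains no usable turns")
    episode = root.find(".//Episode")
    pid = (episode.get("program") if episode is not None else None) or root.get("audio_filename", "")
    return parse_transcript({"participant_id": pid or "xml", "group": "unknown", "turns": turns})
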