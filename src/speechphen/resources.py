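"""Loaders for the data files shipped with the package."""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources


@lru_cache(maxsize=None)
def pronoun_lexicon() -> dict[str, frozenset[str]]:
    """Pronoun class -> lowercased surface forms."""
    raw = json.loads(
        resources.files("speechphen.data").joinpath("pronouns.json").read_text()
    )
    return {cls: frozenset(words) for cls, words in raw.items()}


@lru_cache(maxsize=None)
def word_lexicon() -> dict[str, dict[str, str]]:
    """Closed generator lexicon: word -> {"pos": ..., "topic": ...}."""
    return json.loads(
        resources.files("speechphen.data").joinpath("lexicon.json").read_text()
    )
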