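"""Loaders for the shipped editable word-list assets."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources


@lru_cache(maxsize=None)
def load_wordlist(name: str) -> frozenset[str]:
    """Load ``assets/<name>.txt`` as a lowercase token set.

    Blank lines and '#' comment lines are ignored. The shipped lists
    (stopwords_en, technical_terms, therapeutic_markers, casual_markers,
    backchannels) are defaults meant to be copied and edited per dataset.
    """
    text = resources.files("convoscreen").joinpath(f"assets/{name}.txt").read_text("utf-8")
    words = set()
    for line in text.splitlines():
        line = line.strip().lower()
        if line and not line.startswith("#"):
            words.add(line)
    return frozenset(words)
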