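"""Duplicate-candidate detection and per-transcript language identification.

Duplicates are screened cheaply by filename similarity — the assumption is
that the same recording saved twice gets a near-identical name (copy
suffixes, date stamps) — rather than by comparing full text contents. Pairs
above the threshold are *candidates for manual review*, never automatic
deletions.

Language identification ships with a small self-contained detector scoring
character trigrams plus stopword hits against per-language profiles; any
external detector can be plugged in through the same ``text -> (code,
confidence)`` contract.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from difflib import SequenceMatcher
from pathlib import PurePath
from typing import Mapping, Protocol

from .transcripts import Transcript, tokenize

__all__ = [
    "SimilarityPair",
    "LanguageCall",
    "filename_similarity",
    "find_duplicate_candidates",
    "detect_language",
    "TrigramStopwordDetector",
]


@dataclass(frozen=True)
class SimilarityPair:
    """A candidate duplicate pair, canonically ordered (id_a < id_b)."""

    id_a: str
    id_b: str
    ratio: float

    def __post_init__(self):
        if not 0.0 <= self.ratio <= 1.0:
            raise ValueError(f"ratio out of [0,1]: {self.ratio}")
        if self.id_a >= self.id_b:
            raise ValueError("pair must be canonically ordered id_a < id_b")


@dataclass(frozen=True)
class LanguageCall:
    transcript_id: str
    language: str  # ISO-639-1 code, or "und" when undetermined
    confidence: float


def _basename(name: str) -> str:
    """Strip directory components and the (final) extension."""
    p = PurePath(name)
    return p.stem if p.suffix else p.name


def filename_similarity(a: str, b: str) -> float:
    """Matching-blocks similarity ratio between two filenames, in [0, 1].

    Computes 2·M / (len(a) + len(b)) where M is the total length of the
    matching blocks found by recursively locating the longest common
    substring and matching to its left and right (``difflib``'s classic
    ratio, junk heuristics disabled). Identical names score 1.0; names
    sharing no characters score 0.0. Extensions and directories are stripped
    before comparison, so ``session_12.csv`` vs ``session_12 (copy).csv``
    compares the stems.
    """
    a, b = _basename(a), _basename(b)
    if not a or not b:
        raise ValueError("filenames must be non-empty after stripping extension")
    return SequenceMatcher(None, a, b, autojunk=False).ratio()


def find_duplicate_candidates(
    manifest: Mapping[str, str], threshold: float = 0.75
) -> list[SimilarityPair]:
    """All manifest pairs whose filename similarity strictly exceeds ``threshold``.

    Returns pairs sorted by descending ratio (ties by id pair) for manual
    review. With fewer than two entries there is nothing to compare.
    """
    if len(manifest) < 2:
        raise ValueError("need at least 2 manifest entries")
    pairs = []
    for id_a, id_b in itertools.combinations(sorted(manifest), 2):
        ratio = filename_similarity(manifest[id_a], manifest[id_b])
        if ratio > threshold:
            pairs.append(SimilarityPair(id_a=id_a, id_b=id_b, ratio=ratio))
    pairs.sort(key=lambda p: (-p.ratio, p.id_a, p.id_b))
    return pairs


# --- language identification -------------------------------------------------

# Compact per-language profiles: high-frequency function words plus common
# character trigrams. These separate the shipped set of Western-European
# languages well enough for screening; anything else should come through a
# plugged-in detector.
_PROFILES: dict[str, tuple[frozenset[str], frozenset[str]]] = {
    "en": (
        frozenset(
            "the of and to in is you that it he was for on are as with his they at be this have from or had by word but not what all were when your can there use each which she how their if will other about out many then them these so some would make like him into time has look more write go see no way could people than first been call who its now find long down day get come made may part".split()
        ),
        frozenset(["the", "ing", "and", "ion", "ent", "her", "for", "tha", "nth", "hat", "his", "ere", "you"]),
    ),
    "es": (
        frozenset(
            "el la de que y a en un ser se no haber por con su para como estar tener le lo todo pero más hacer o poder decir este ir otro ese si me ya ver porque dar cuando muy sin vez mucho saber qué sobre mi alguno mismo yo también hasta año dos querer entre así primero desde".split()
        ),
        frozenset(["que", "ent", "de ", "la ", "el ", "ión", "ado", "est", "ara", "os ", "nte"]),
    ),
    "fr": (
        frozenset(
            "le de un être et à il avoir ne je son que se qui ce dans en du elle au pour pas vous par sur faire plus dire me on mon lui nous comme mais pouvoir avec tout y aller voir bien où sans tu ou leur homme si deux mari moi vouloir te femme venir".split()
        ),
        frozenset(["les", "ent", "de ", "ion", "que", "ous", "ait", "eur", "ans", "our"]),
    ),
    "de": (
        frozenset(
            "der die und in den von zu das mit sich des auf für ist im dem nicht ein eine als auch es an werden aus er hat dass sie nach wird bei einer um am sind noch wie einem über einen so zum war haben nur oder aber vor zur bis mehr durch man sein wurde".split()
        ),
        frozenset(["der", "ein", "ich", "und", "sch", "die", "che", "den", "gen", "ung"]),
    ),
}


class LanguageDetector(Protocol):
    """Contract for pluggable detectors: text → (ISO code, confidence)."""

    def __call__(self, text: str) -> tuple[str, float]: ...


def _trigrams(text: str) -> list[str]:
    s = " ".join(text.lower().split())
    return [s[i : i + 3] for i in range(len(s) - 2)]


class TrigramStopwordDetector:
    """Built-in offline detector over a small shipped language set.

    Scores each language as a blend of the stopword hit rate of the word
    tokens and the profile hit rate of character trigrams, returning the
    argmax with the normalized margin over the runner-up as confidence.
    """

    def __init__(self, stopword_weight: float = 0.7, trigram_weight: float = 0.3):
        self.stopword_weight = stopword_weight
        self.trigram_weight = trigram_weight

    def __call__(self, text: str) -> tuple[str, float]:
        tokens = tokenize(text)
        grams = _trigrams(text)
        if not tokens:
            return "und", 0.0
        scores: dict[str, float] = {}
        for lang, (stopwords, trigram_set) in _PROFILES.items():
            sw = sum(t in stopwords for t in tokens) / len(tokens)
            tg = (sum(g in trigram_set for g in grams) / len(grams)) if grams else 0.0
            scores[lang] = self.stopword_weight * sw + self.trigram_weight * tg
        ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        (top_lang, top), (_, second) = ranked[0], ranked[1]
        if top <= 0.0:
            return "und", 0.0
        confidence = (top - second) / top
        return top_lang, confidence


def detect_language(
    t: Transcript,
    detector: LanguageDetector | None = None,
    confidence_floor: float = 0.05,
) -> LanguageCall:
    """Identify the language of a transcript's concatenated text.

    Falls back to ``und`` (undetermined) when the text is empty or the
    detector's confidence is below ``confidence_floor``.
    """
    detector = detector if detector is not None else TrigramStopwordDetector()
    text = t.full_text()
    if not text.strip():
        return LanguageCall(transcript_id=t.id, language="und", confidence=0.0)
    code, confidence = detector(text)
    if code == "und" or confidence < confidence_floor:
        return LanguageCall(transcript_id=t.id, language="und", confidence=confidence)
    return LanguageCall(transcript_id=t.id, language=code, confidence=confidence)
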