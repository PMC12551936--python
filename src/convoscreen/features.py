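"""Per-transcript statistical features and rule-based outlier flagging.

Two speaking-rate statistics are computed for every transcript:

* the **global** rate, total words divided by whole-conversation length —
  silences between segments count against it;
* the **net** rate, the unweighted mean over segments of each segment's
  words-per-second — silences excluded. A duration-weighted variant
  (total words / total spoken seconds) is also available.

The ratio of whole-conversation time to net spoken time (≥ 1 for
non-overlapping segments) rises when the recording dwarfs the speech —
timestamp errors or near-empty recordings. Typical conversational American
English runs about 1.85–4.86 words per second; rates above ~3.5–4 WPS are
characteristic of answering-machine messages and other accidental
recordings, and very short (<15 min) or very long (>1.2 h) durations mark
case-management calls and concatenated/overrun recordings respectively.
Flags are advisory inputs to a disposition policy, never deletions.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from .assets import load_wordlist
from .transcripts import Dataset, Transcript, conversation_length, tokenize

logger = logging.getLogger(__name__)

FLAG_NAMES = (
    "high_rate",
    "short_duration",
    "long_duration",
    "extreme_ratio",
    "too_short_text",
)


class UndefinedRateError(ValueError):
    """Speaking rates are undefined for zero-duration transcripts."""


@dataclass(frozen=True)
class OutlierRules:
    """Thresholds for advisory outlier flags.

    Defaults: >3.5 words/s flags a high speaking rate; <900 s (15 min) is
    short; >4320 s (1.2 h) is long; session-time/spoken-time ratio >5 is
    extreme; under 50 words is too little text to characterize.
    """

    high_rate_wps: float = 3.5
    short_duration_s: float = 900.0
    long_duration_s: float = 4320.0
    extreme_ratio: float = 5.0
    min_words: int = 50

    def __post_init__(self):
        for name in ("high_rate_wps", "short_duration_s", "long_duration_s", "extreme_ratio", "min_words"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class FeatureVector:
    transcript_id: str
    duration_s: float
    n_segments: int
    n_words: int
    rate_global_wps: float
    rate_net_wps: float
    rate_net_weighted_wps: float
    rate_ratio: float
    n_zero_duration_segments: int = 0
    flags: frozenset[str] = frozenset()


def speaking_rates(t: Transcript) -> tuple[float, float, float]:
    """(global WPS, net WPS, session-time / spoken-time ratio).

    Global: total words over whole-conversation length. Net: unweighted mean
    of segment-level rates, skipping zero-duration segments (a
    single-timestamp dialect can yield zero deltas). Ratio: conversation
    length over summed segment seconds.
    """
    duration = conversation_length(t)
    if duration <= 0:
        raise UndefinedRateError(f"transcript {t.id} has zero total duration")
    seg_words = [len(tokenize(s.text)) for s in t.segments]
    seg_secs = t.segment_durations()
    total_words = sum(seg_words)
    spoken = sum(sec for sec in seg_secs if sec > 0)
    rate_global = total_words / duration
    seg_rates = [w / sec for w, sec in zip(seg_words, seg_secs) if sec > 0]
    rate_net = sum(seg_rates) / len(seg_rates) if seg_rates else 0.0
    rate_ratio = duration / spoken if spoken > 0 else float("inf")
    return rate_global, rate_net, rate_ratio


def compute_features(t: Transcript) -> FeatureVector:
    """Assemble the full per-transcript feature vector (flags unset)."""
    duration = conversation_length(t)
    seg_words = [len(tokenize(s.text)) for s in t.segments]
    seg_secs = t.segment_durations()
    rate_global, rate_net, rate_ratio = speaking_rates(t)
    spoken = sum(sec for sec in seg_secs if sec > 0)
    n_zero = sum(1 for sec in seg_secs if sec <= 0)
    if n_zero:
        logger.debug("transcript %s: %d zero-duration segments skipped in net rate", t.id, n_zero)
    total_words = sum(seg_words)
    weighted = total_words / spoken if spoken > 0 else 0.0
    return FeatureVector(
        transcript_id=t.id,
        duration_s=duration,
        n_segments=len(t.segments),
        n_words=total_words,
        rate_global_wps=rate_global,
        rate_net_wps=rate_net,
        rate_net_weighted_wps=weighted,
        rate_ratio=rate_ratio,
        n_zero_duration_segments=n_zero,
    )


def flag_outliers(fv: FeatureVector, rules: OutlierRules = OutlierRules()) -> frozenset[str]:
    """Deterministic advisory flags for one feature vector.

    ``high_rate`` fires when either rate statistic exceeds the threshold
    (answering machines are fast under both definitions; a timestamp error
    can inflate just one).
    """
    flags = set()
    if fv.rate_net_wps > rules.high_rate_wps or fv.rate_global_wps > rules.high_rate_wps:
        flags.add("high_rate")
    if fv.duration_s < rules.short_duration_s:
        flags.add("short_duration")
    if fv.duration_s > rules.long_duration_s:
        flags.add("long_duration")
    if fv.rate_ratio > rules.extreme_ratio:
        flags.add("extreme_ratio")
    if fv.n_words < rules.min_words:
        flags.add("too_short_text")
    return frozenset(flags)


def extract_features(
    d: Dataset | Iterable[Transcript], rules: OutlierRules = OutlierRules()
) -> list[FeatureVector]:
    """Feature vectors with flags for every transcript in a dataset."""
    out = []
    for t in d:
        fv = compute_features(t)
        fv.flags = flag_outliers(fv, rules)
        out.append(fv)
    return out


# --- frequent-noun extraction ------------------------------------------------

Tagger = Callable[[Sequence[str]], list[str]]
"""Contract for POS filtering: token list → the sublist that are nouns."""

_warned_no_tagger = False


def passthrough_tagger(tokens: Sequence[str]) -> list[str]:
    """Fallback tagger: passes all tokens, logging that POS filtering is off."""
    global _warned_no_tagger
    if not _warned_no_tagger:
        logger.warning("no POS tagger configured; noun filtering skipped (all tokens pass)")
        _warned_no_tagger = True
    return list(tokens)


def frequent_nouns(
    d: Dataset | Iterable[Transcript],
    partition: str,
    role_map: Mapping[str, str],
    stoplist: frozenset[str] | None = None,
    technical_terms: frozenset[str] | None = None,
    tagger: Tagger = passthrough_tagger,
    top_k: int = 20,
) -> list[tuple[str, int]]:
    """Most common nouns for one speaker role across a dataset.

    Tokens are first filtered against the stoplist and technical-term list
    (shipped editable defaults), then noun-filtered by the ``tagger``
    contract, and counted over all transcripts in the partition. Returns the
    ``top_k`` (word, count) pairs, descending count, ties alphabetical.
    """
    if partition not in set(role_map.values()):
        raise ValueError(
            f"partition {partition!r} not produced by role_map (roles: {sorted(set(role_map.values()))})"
        )
    stoplist = stoplist if stoplist is not None else load_wordlist("stopwords_en")
    technical_terms = (
        technical_terms if technical_terms is not None else load_wordlist("technical_terms")
    )
    drop = stoplist | technical_terms
    counts: Counter[str] = Counter()
    for t in d:
        for seg in t.segments:
            role = role_map.get(seg.speaker_label)
            if role != partition:
                continue
            kept = [tok for tok in tokenize(seg.text) if tok not in drop]
            counts.update(tagger(kept))
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top_k]
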