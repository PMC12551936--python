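"""Segment-level perplexity under a pluggable language model, with
transcript aggregation and (MWPS, MS) filtering.

Perplexity of a token sequence is ``exp(-1/N · Σ log P(w_i | w_<i))`` —
the inverse geometric mean of the per-token conditional probabilities, so
it is ≥ 1 for any proper model and 1 exactly when every token has
probability 1. High segment perplexity marks text the model finds unlikely:
transcription noise, backchannels rendered as content, or genuinely unusual
language.

Per transcript, segment perplexities are aggregated (mean, SD, max, 75th
percentile) over *qualifying* segments only — those with at least ``mwps``
words (minimum words per segment). A transcript with fewer than ``ms``
(minimal number of segments) qualifying segments yields an *invalid*
profile with null aggregates; downstream analyses drop invalid profiles
rather than guessing.

Any model exposing ``score(tokens) -> per-token natural-log probabilities``
can be plugged in; the shipped default is an additive-smoothed n-gram model
trainable on any token corpus, so the whole pipeline runs offline.
Absolute perplexity scales differ between models; every downstream
statistic here is rank- or threshold-based.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np

from .transcripts import EmptyInputError, Transcript, tokenize

logger = logging.getLogger(__name__)

BOS = "<s>"
UNK = "<unk>"


class LanguageModel(Protocol):
    """Contract: per-token conditional natural-log probabilities.

    ``score(tokens)`` returns one value per token, each ≤ 0 (``-inf`` for a
    zero-probability token), deterministic for fixed model state.
    """

    def score(self, tokens: Sequence[str]) -> list[float]: ...


def segment_perplexity(tokens: Sequence[str], lm: LanguageModel) -> float:
    """Perplexity of one token sequence under ``lm``.

    Any zero-probability token makes the segment's perplexity ``+inf``
    (logged); extreme perplexity is treated as signal, not failure.
    """
    if not tokens:
        raise EmptyInputError("cannot compute perplexity of an empty segment")
    logprobs = lm.score(tokens)
    if len(logprobs) != len(tokens):
        raise ValueError(
            f"model returned {len(logprobs)} log-probabilities for {len(tokens)} tokens"
        )
    if any(lp == -math.inf for lp in logprobs):
        logger.debug("zero-probability token; segment perplexity is +inf")
        return math.inf
    return math.exp(-sum(logprobs) / len(tokens))


@dataclass
class NGramLM:
    """Additive-smoothed n-gram language model.

    Conditional probability of token t after context c is
    ``(count(c,t) + alpha) / (count(c) + alpha·|V|)`` where the vocabulary V
    is the training vocabulary plus an ``<unk>`` bucket that absorbs unseen
    tokens; the distribution over V therefore sums to 1 for every context,
    seen or not. Sequences are padded with ``order − 1`` boundary symbols
    for conditioning only.
    """

    order: int
    alpha: float
    vocabulary: frozenset[str]
    context_counts: dict[tuple[str, ...], Counter]
    context_totals: dict[tuple[str, ...], int]

    def prob(self, token: str, context: tuple[str, ...]) -> float:
        if token not in self.vocabulary:
            token = UNK
        counts = self.context_counts.get(context)
        total = self.context_totals.get(context, 0)
        c = counts[token] if counts is not None else 0
        v = len(self.vocabulary)
        return (c + self.alpha) / (total + self.alpha * v)

    def score(self, tokens: Sequence[str]) -> list[float]:
        padded = [BOS] * (self.order - 1) + [
            t if t in self.vocabulary else UNK for t in tokens
        ]
        out = []
        for i in range(self.order - 1, len(padded)):
            context = tuple(padded[i - self.order + 1 : i])
            out.append(math.log(self.prob(padded[i], context)))
        return out


def train_ngram_lm(
    corpus: Sequence[Sequence[str]], order: int = 2, alpha: float = 0.1
) -> NGramLM:
    """Fit an additive-smoothed n-gram model on a corpus of token lists."""
    if not corpus:
        raise ValueError("empty training corpus")
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    vocab = {tok for sent in corpus for tok in sent}
    vocab.add(UNK)
    context_counts: dict[tuple[str, ...], Counter] = defaultdict(Counter)
    context_totals: dict[tuple[str, ...], int] = defaultdict(int)
    pad = [BOS] * (order - 1)
    for sent in corpus:
        if not sent:
            continue
        padded = pad + list(sent)
        for i in range(order - 1, len(padded)):
            context = tuple(padded[i - order + 1 : i])
            context_counts[context][padded[i]] += 1
            context_totals[context] += 1
    return NGramLM(
        order=order,
        alpha=alpha,
        vocabulary=frozenset(vocab),
        context_counts=dict(context_counts),
        context_totals=dict(context_totals),
    )


def transcript_corpus(transcripts: Sequence[Transcript]) -> list[list[str]]:
    """Tokenized segments of a transcript collection (LM training input)."""
    return [tokenize(seg.text) for t in transcripts for seg in t.segments if seg.text]


@dataclass
class PerplexityProfile:
    """Per-segment perplexities plus filtered transcript aggregates.

    ``segment_ppl`` holds (segment index, token count, perplexity) for
    *every* segment, so aggregates can be recomputed under any
    (mwps, ms) without re-scoring. When the profile is invalid
    (``qualifying_segments < ms`` or no qualifying segments) the aggregate
    fields are None. Segments with infinite perplexity are excluded from
    mean/SD but still count toward max and the 75th percentile.
    """

    transcript_id: str
    segment_ppl: list[tuple[int, int, float]]
    mwps: int
    ms: int
    qualifying_segments: int
    mean_ppl: float | None = None
    sd_ppl: float | None = None
    max_ppl: float | None = None
    p75_ppl: float | None = None

    @property
    def valid(self) -> bool:
        return self.mean_ppl is not None


def _aggregate(
    transcript_id: str,
    segment_ppl: list[tuple[int, int, float]],
    mwps: int,
    ms: int,
) -> PerplexityProfile:
    qualifying = [(i, n, p) for i, n, p in segment_ppl if n >= mwps]
    profile = PerplexityProfile(
        transcript_id=transcript_id,
        segment_ppl=segment_ppl,
        mwps=mwps,
        ms=ms,
        qualifying_segments=len(qualifying),
    )
    if len(qualifying) < ms or not qualifying:
        return profile
    ppls = np.array([p for _, _, p in qualifying], dtype=float)
    finite = ppls[np.isfinite(ppls)]
    if finite.size == 0:
        return profile
    profile.mean_ppl = float(finite.mean())
    profile.sd_ppl = float(finite.std(ddof=0))
    profile.max_ppl = float(ppls.max())
    profile.p75_ppl = _percentile_linear(ppls, 75.0)
    return profile


def _percentile_linear(values: np.ndarray, q: float) -> float:
    """Linear interpolation between closest order statistics, inf-safe.

    Matches numpy's default 'linear' method for finite data; when the upper
    neighbor is infinite with positive weight the result is +inf rather
    than the NaN numpy's lerp can produce.
    """
    v = np.sort(np.asarray(values, dtype=float))
    pos = (v.size - 1) * q / 100.0
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    w = pos - lo
    if w == 0.0 or v[lo] == v[hi]:
        return float(v[lo])
    if np.isinf(v[hi]):
        return float(v[hi])
    return float(v[lo] * (1 - w) + v[hi] * w)


def transcript_profile(
    t: Transcript, lm: LanguageModel, mwps: int = 0, ms: int = 0
) -> PerplexityProfile:
    """Score every segment of a transcript and aggregate under (mwps, ms)."""
    segment_ppl: list[tuple[int, int, float]] = []
    for i, seg in enumerate(t.segments):
        tokens = tokenize(seg.text)
        if not tokens:
            continue
        segment_ppl.append((i, len(tokens), segment_perplexity(tokens, lm)))
    return _aggregate(t.id, segment_ppl, mwps, ms)


def reaggregate(profile: PerplexityProfile, mwps: int, ms: int) -> PerplexityProfile:
    """Recompute a profile's aggregates under new (mwps, ms) filters
    without re-scoring segments."""
    return _aggregate(profile.transcript_id, profile.segment_ppl, mwps, ms)
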