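# Methods

This note documents the models and procedures implemented in
`convoscreen`, the assumptions behind them, the parameters that matter,
and the design choices made where the design was genuinely open.

## Data model and timestamp dialects

A transcript is an ordered list of segments — speaker label, timing, raw
text — plus optional metadata. Platform exports vary in what the
timestamp column means, so the CSV reader supports two dialects: a
start/end pair per segment, and a single timestamp interpreted as the
segment's **end** time. Under the single-timestamp dialect, per-segment
spoken time is the delta from the previous segment's end (first segment:
from 0). This preserves both the whole-conversation and net-spoken-time
computations without inventing data, at a known cost: single-timestamp
deltas include the silence before each segment, so the session-time /
spoken-time ratio is identically 1 under that dialect and only
informative with start/end pairs. Which convention a given platform uses
must be declared in the reader config; neither is assumed.

Rows out of end-timestamp order are sorted with a logged warning rather
than rejected — noisy exports are the norm, and the toolkit's stance
throughout is *flag, never silently delete*.

Tokenization is lowercase, punctuation-stripped, whitespace-split, with
intra-word hyphens and apostrophes preserved so that backchannels
("uh-huh") and contractions count as single words. This matches the
plain-language meaning of "word count"; no subword model is involved.

## Duplicate screening and language identification

Duplicate candidates are found by filename similarity, not content
comparison: the matching-blocks ratio `2M/(|a|+|b|)` where `M` is the
total length of blocks found by recursively taking the longest common
substring (junk heuristics disabled). The alternative reading of
"longest matching segment over total characters" — a single block over
the total — would cap identical names at 0.5 and could never clear a 75%
threshold, so the recursive-blocks ratio is the only self-consistent
interpretation; it is also what Python's `difflib.SequenceMatcher.ratio`
computes. The threshold (default 0.75, strict `>`) yields *candidates
for manual review*. A limitation worth knowing: sequentially numbered
exports (`session_0000`, `session_0001`, …) are mutual candidates by
construction — the method presumes natural, varied filenames. The
synthetic generator therefore offers scrambled filenames for screening
demonstrations.

Language identification is a pluggable `text → (ISO code, confidence)`
contract. The built-in detector scores a small shipped profile set
(en/es/fr/de) as `0.7 · stopword hit rate + 0.3 · trigram hit rate` and
returns the argmax with the normalized margin over the runner-up as
confidence; below the confidence floor (default 0.05) or on empty text
it returns `und`. It is a screening tool for majority-English corpora,
not a general-purpose detector — heavyweight detectors plug in through
the same contract.

## Speaking rates and outlier rules

Two rates are computed because they answer different questions. The
global rate (total words / conversation length) is depressed by silences
and catches recordings where little was actually said; the net rate — the
*unweighted mean* of segment-level words-per-second — estimates how fast
people spoke. A duration-weighted variant (total words / total spoken
seconds) is also reported, since the unweighted mean is sensitive to
very short segments. Zero-duration segments (possible under the
single-timestamp dialect) are skipped in the net rate and counted.

The ratio of conversation length to summed spoken seconds is ≥ 1 for
non-overlapping segments; high values mean the recording dwarfs the
speech — timestamp errors or near-empty recordings.

Default outlier thresholds: high rate > 3.5 words/s (conversational
American English runs roughly 1.85–4.86 WPS; answering machines
typically exceed 4), short < 900 s (15 min, the case-management
signature), long > 4320 s (1.2 h, concatenated or overrun recordings),
ratio > 5, under 50 words. The high-rate flag fires when *either* rate
statistic exceeds the threshold: genuine fast speech moves both, while a
timestamp error can inflate only one, and both cases deserve review.
Flags are advisory; dispositions are a separate, explicit policy.

Frequent-noun extraction filters tokens against editable stoplist and
technical-term assets, then applies a pluggable part-of-speech tagger
contract (`token list → noun sublist`). The shipped fallback passes all
tokens and logs that POS filtering was skipped; a spaCy-backed tagger
can be plugged in where available. Ties in the ranking break
alphabetically for reproducibility.

## Perplexity

Segment perplexity is `exp(−(1/N) Σ log P(wᵢ | w₁..wᵢ₋₁))` in natural
log — the inverse geometric mean of token probabilities, ≥ 1 for any
proper model. The language model is a behavioral contract
(`score(tokens) → per-token log-probabilities`); the shipped default is
an additive-smoothed n-gram model whose vocabulary includes an `<unk>`
bucket absorbing unseen tokens, so conditional distributions sum to 1
for every context (checked to 1e-9 in tests). Absolute perplexity scales
are model-specific; every downstream statistic is rank- or
threshold-based, so conclusions transfer across models even though
values do not.

Numerical choices: a zero-probability token makes its segment's
perplexity `+inf` rather than raising — extreme perplexity is treated as
signal (transcribed noise), not failure. Infinite segments are excluded
from a transcript's mean/SD but retained for max and the 75th
percentile. The 75th percentile interpolates linearly between closest
order statistics (numpy's default convention, stated here for
bit-reproducibility), returning `+inf` when the upper neighbor is
infinite with positive weight.

Transcript aggregates are computed over segments with at least MWPS
words (default grid 0/5/10); transcripts with fewer than MS qualifying
segments (default grid 0/5/10; 10/20 remain selectable) yield an
*invalid* profile with null aggregates rather than a guess. Profiles
retain full per-segment detail, so the (MWPS, MS) grid re-aggregates
without re-scoring.

## Statistics engine

**Permutation test.** The statistic is `mean(x) − mean(y)`; the null
relabels the pooled sample at fixed group sizes. When `C(n, nx)` is at
most the requested permutation count, all distinct relabelings are
enumerated and the p-value is the exact tail proportion (the identity
relabeling included, so p can never be 0). Otherwise random relabelings
with the add-one estimator `(1 + extreme)/(n_perm + 1)`. Two-sided by
default; both one-sided alternatives are exposed because published
analyses of this kind do not always state sidedness, and the choice is
the analyst's.

**Gaussian mixture.** Hand-written 1-D EM: means initialized at
quantile-spaced points with a small seeded jitter, weights equal,
variances at the sample variance; variances floored at `1e-6 · var(x)`
to keep the likelihood bounded; the log-likelihood is asserted
non-decreasing at every iteration. AIC `= 2p − 2ℓ` and BIC
`= p ln n − 2ℓ` with `p = 3k − 1` free parameters (k−1 weights, k means,
k variances) — stated because criterion tables rarely say which
convention they used. scikit-learn's `GaussianMixture` is the
independent cross-check in the tests, never the implementation.

**Agreement.** Cohen κ `= (p_o − p_e)/(1 − p_e)` from the r×r
contingency table over observed labels; percent agreement is the trace
over the total. κ > 0.61 is conventionally read as substantial.

**ROC / PR.** Curves via scikit-learn; ROC AUC is the trapezoidal area,
PR AUC is average precision (step interpolation over recall — linear
interpolation in PR space is optimistic, hence avoided). The operating
threshold maximizes TPR − FPR (Youden's J); among ties the *lowest*
threshold is chosen, which favors recall on the positive class. In the
p75 filter evaluation the positive class is the non-sessions (high
perplexity), so this tie-break errs toward catching more non-sessions.

## Zero-shot classification

The prompt embeds the full transcript plus five criteria that
characterize a treatment session — dynamics (one side shares, the other
listens and responds), personal content, therapeutic elements (active
listening, reframing, coping strategies), professional language, and
context clues (confidentiality, session time limits, scheduling) — and
instructs the model to answer inside fixed XML-style tags with a 1–5
certainty, reasoning, a content summary, and a non-therapeutic-dynamics
flag. Element texts, tag names, and the generation parameters (output
cap 350, temperature 0.3) are all template fields overridable from
config. The backend is a synchronous `prompt → completion` callable with
retry; no provider appears in code paths.

The parser extracts tagged spans, normalizes the label, and infers the
session type from keywords ("couple", "famil-", "group") in the
classification and summary spans; a typed non-individual session against
a rater who was scoped to individual sessions only is re-scoped to
agreement by `reconcile` — mirroring how human validation instructions
and model instructions can legitimately differ in scope.

The shipped mock backend classifies by the *density* of
therapeutic-marker tokens versus casual/backchannel tokens (editable
lexicons), with a minimum marker rate (default 2%) so an isolated
therapy word in a logistics call cannot flip the label. It exists to
exercise the prompt/parse/reconcile plumbing deterministically and to
provide a reliable labeler for synthetic data; it says nothing about any
real model's accuracy.

## Synthetic data: what it emulates, what it does not

The generator produces five classes whose *structure* matches what
ambient recording sweeps up: two-speaker ~45–60 min sessions
(duration N(3150, 450) s truncated at 1 s, net rate N(2.5, 0.35) WPS,
therapeutic vocabulary), short case-management calls (N(480, 180) s,
scheduling vocabulary), single-speaker answering machines (N(45, 15) s
at N(4.8, 0.25) WPS — above the 4 WPS signature), backchannel noise (2–7
segments, ≥ 90% filler tokens), and informal chatter (N(1200, 400) s,
casual vocabulary). Segment durations are words/rate exactly; remaining
silence is spread over inter-segment gaps so each transcript's final
timestamp lands on its drawn duration, making realized class means
unbiased. Error injection (speaker swaps, duplicated segments, dropped
words, filler bursts) is per-event Bernoulli with exact records of what
was injected. Everything is deterministic given (specs, injection,
seed).

Text is drawn from word pools, not generated language. That is enough
for n-gram perplexity contrasts, lexicon-based classification, and rate
statistics — and it is why the synthetic classes separate *cleanly*:
the p75 grid reaches AUC 1.0 and the mock classifier near-perfect
accuracy on defaults. Real transcripts share vocabulary across classes,
carry ASR errors, and overlap in every feature, which is precisely why
the real-data problem is hard (reported discriminative performance there
is moderate, AUC ≈ 0.6–0.7). Passing tests on synthetic data therefore
validate the *machinery* — formulas, filters, thresholds, plumbing — not
expected field performance.

## Screening pipeline

Stages run in order: duplicate candidates → language → features and
flags → perplexity profiles (an n-gram model trained on the dataset
itself by default) → classification → disposition. Dispositions are
three-valued with *review* as the default: a transcript is excluded only
when an explicit policy rule fires (shipped default: the
answering-machine pattern, high rate ∧ short duration), and kept only
when flag-free, classified as a session, and not a duplicate candidate.
Every exclusion is logged as a structured JSON line with the rule that
fired; a stage failure routes the transcript to review rather than
aborting the run. Re-running the pipeline on its own kept subset changes
no dispositions.

## Problem sizes and defaults in tests

The shipped test and acceptance runs use datasets of 25–64 transcripts
(20–30 sessions plus 8–10 of each non-session class), a bigram LM with
α = 0.1 trained on 20 disjoint session fixtures, 999 permutations
(499–999 in calibration loops, 200–500 replicates), and n = 600 for
mixture recovery. These sizes give stable statistics for every property
checked while keeping the whole suite fast enough to run habitually.

## Known limitations

- The built-in language detector covers four Western-European languages;
  everything else returns its best guess or `und`.
- Filename-based duplicate screening fails on systematically numbered
  exports (all-pairs candidates) and on duplicates saved under unrelated
  names (no candidates); it deliberately never inspects content.
- The single-timestamp dialect cannot distinguish silence from speech
  within a segment delta, so net rate under that dialect is a lower
  bound on true articulation rate.
- The p75 threshold classifier's precision/recall trade-off depends on
  class imbalance; with few non-sessions, precision estimates are noisy.
- Metadata-based exclusions (e.g., filtering whole organizations) are
  expressible only through a user-supplied blocklist; no list ships.
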