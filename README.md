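# convoscreen

Quality screening for large datasets of conversational transcripts.

Ambient recording plus automatic speech recognition produces transcript
collections that mix genuine conversations with accidental recordings:
answering-machine messages, brief logistical phone calls, background noise
transcribed as backchannels ("mhm, uh-huh…"), hallway chatter. In
behavioral-health research the problem is acute — downstream analyses of
therapeutic dynamics are only meaningful on transcripts that actually
capture a treatment session. `convoscreen` is a toolkit for characterizing
such datasets, flagging suspicious transcripts, and separating *sessions*
from *non-sessions*, built for researchers working with secondary
transcript data (CSV exports of speaker-labeled, timestamped segments)
without access to the original audio.

## What it computes

- **Dataset hygiene** — duplicate-candidate detection by filename
  similarity (matching-blocks ratio `2M/(|a|+|b|) > 0.75` flags pairs for
  manual review) and per-transcript language identification through a
  pluggable detector contract (a trigram + stopword detector ships
  built in).
- **Per-transcript features** — conversation length (last segment's end
  timestamp); two speaking rates, the *global* rate `total words / total
  time` and the *net* rate (mean of segment-level words-per-second,
  silences excluded); and the session-time / spoken-time ratio. Advisory
  outlier flags fire on rule thresholds: rate > 3.5 words/s, duration
  < 15 min or > 1.2 h, ratio > 5, under 50 words.
- **Perplexity profiling** — segment perplexity
  `exp(−(1/N) Σᵢ log P(wᵢ | w₁..wᵢ₋₁))` under any language model exposing
  per-token log-probabilities (an additive-smoothed n-gram model ships for
  offline use), aggregated per transcript (mean, SD, max, 75th percentile)
  over segments with ≥ MWPS words, requiring ≥ MS qualifying segments.
- **Classification** — a zero-shot prompt builder / tagged-response parser
  over any text-generation backend (five session criteria, 1–5 certainty,
  summary, XML-style tags; a deterministic mock backend ships for
  tests), plus a p75-perplexity threshold classifier evaluated over the
  (MWPS, MS) grid with non-sessions as the positive high-perplexity class
  and the operating threshold maximizing TPR − FPR.
- **Statistics** — permutation tests for mean differences (exact
  enumeration when feasible), 1-D Gaussian-mixture fits of duration
  distributions with AIC/BIC model selection, Cohen κ and percent
  agreement, ROC/PR analysis.
- **Synthetic data** — a seeded generator of five transcript classes
  (session, case management, answering machine, backchannel noise,
  informal) with injectable diarization/duplication/word-drop errors, so
  every stage is testable offline.

## Worked example

```python
import convoscreen as cs

dataset, labels = cs.generate_dataset(
    {"session": 12, "case_management": 4, "answering_machine": 4,
     "noise": 4, "informal": 4},
    seed=42, scramble_names=True,
)
report = cs.screen(dataset, cs.ScreeningConfig(seed=42))
print(report.summary["dispositions"])
print(report.summary["flags"])
```

prints

```
{'keep': 12, 'review': 12, 'exclude': 4}
{'extreme_ratio': 1, 'high_rate': 4, 'short_duration': 13, 'too_short_text': 4}
```

All 4 answering-machine fixtures are excluded by the
high-rate-and-short-duration rule, the 12 clean sessions are kept, and
everything ambiguous (short case-management calls, noise, informal
chatter) is routed to human review — exclusion only ever happens through
an explicit, logged policy rule. The `examples/` directory has one
narrative script per capability (screening, perplexity contrast, duration
mixtures, agreement statistics); each prints the numbers it computes and
what they mean. A thin CLI mirrors the library:
`convoscreen simulate|dedup|lang|features|perplexity|classify|screen|stats …`.

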