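"""End-to-end screening orchestration.

``screen`` runs the stages in order — duplicate candidates → language →
features and outlier flags → perplexity profiles → classification — and
assigns each transcript a three-valued disposition (*keep* / *review* /
*exclude*) through an ordered, explicit rule policy. Review is the default:
anything not positively cleared or positively excluded goes to a human,
encoding the human-in-the-loop stance of the screening design. Exclusions
happen only through configured rules and every one is logged with the rule
that fired.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .classify import Backend, ClassificationResult, MockBackend, PromptTemplate, classify
from .dedup_lang import LanguageCall, detect_language, find_duplicate_candidates
from .features import FeatureVector, OutlierRules, compute_features, flag_outliers
from .perplexity import PerplexityProfile, train_ngram_lm, transcript_corpus, transcript_profile
from .transcripts import Dataset

logger = logging.getLogger(__name__)

DISPOSITIONS = ("keep", "review", "exclude")


@dataclass(frozen=True)
class DispositionRule:
    """One ordered policy rule: fire when all conditions hold.

    ``requires_flags`` must be a subset of the transcript's outlier flags;
    ``requires_label``/``forbid_flags``/``require_no_duplicate`` constrain
    the classification label, flag absence, and duplicate status. The first
    matching rule decides.
    """

    name: str
    disposition: str
    requires_flags: frozenset[str] = frozenset()
    forbid_flags: frozenset[str] = frozenset()
    requires_label: str | None = None
    require_no_duplicate: bool = False

    def __post_init__(self):
        if self.disposition not in DISPOSITIONS:
            raise ValueError(f"unknown disposition {self.disposition!r}")

    def matches(self, flags: frozenset[str], label: str | None, duplicate_of: str | None) -> bool:
        if not self.requires_flags <= flags:
            return False
        if self.forbid_flags & flags:
            return False
        if self.requires_label is not None and label != self.requires_label:
            return False
        if self.require_no_duplicate and duplicate_of is not None:
            return False
        return True


DEFAULT_POLICY: tuple[DispositionRule, ...] = (
    DispositionRule(
        name="answering_machine_pattern",
        disposition="exclude",
        requires_flags=frozenset({"high_rate", "short_duration"}),
    ),
    DispositionRule(
        name="clean_session",
        disposition="keep",
        forbid_flags=frozenset(
            {"high_rate", "short_duration", "long_duration", "extreme_ratio", "too_short_text"}
        ),
        requires_label="session",
        require_no_duplicate=True,
    ),
)


@dataclass
class ScreeningConfig:
    """Everything a screening run needs, seeds included."""

    rules: OutlierRules = field(default_factory=OutlierRules)
    dedup_threshold: float = 0.75
    lm_order: int = 2
    lm_alpha: float = 0.1
    mwps: int = 5
    ms: int = 10
    seed: int = 0
    policy: tuple[DispositionRule, ...] = DEFAULT_POLICY
    default_disposition: str = "review"
    template: PromptTemplate = field(default_factory=PromptTemplate)

    def __post_init__(self):
        if self.default_disposition not in DISPOSITIONS:
            raise ValueError(f"unknown disposition {self.default_disposition!r}")


@dataclass
class ScreeningRow:
    transcript_id: str
    language: str
    duplicate_of: str | None
    features: FeatureVector | None
    flags: frozenset[str]
    profile: PerplexityProfile | None
    classification: ClassificationResult | None
    final_disposition: str
    failed_stages: list[str] = field(default_factory=list)


@dataclass
class ScreeningReport:
    rows: list[ScreeningRow]
    summary: dict


def _log_event(**payload) -> None:
    logger.info(json.dumps(payload, sort_keys=True, default=str))


def screen(d: Dataset, cfg: ScreeningConfig = ScreeningConfig(), backend: Backend | None = None) -> ScreeningReport:
    """Run the full screening pipeline over a dataset.

    A hard error in any stage marks that transcript's row failed for that
    stage and sends it to review; the run itself never aborts on a
    single transcript. Idempotent for fixed inputs, config, and seeds.
    """
    backend = backend if backend is not None else MockBackend()
    _log_event(event="start", stage="screen", n_transcripts=len(d))

    duplicate_of: dict[str, str] = {}
    if len(d.manifest) >= 2:
        for pair in find_duplicate_candidates(d.manifest, cfg.dedup_threshold):
            # the lexicographically later id is marked as the candidate copy
            duplicate_of.setdefault(pair.id_b, pair.id_a)
    _log_event(event="stage_done", stage="dedup", n_candidates=len(duplicate_of))

    corpus = transcript_corpus(list(d))
    lm = train_ngram_lm(corpus, order=cfg.lm_order, alpha=cfg.lm_alpha) if corpus else None
    _log_event(event="stage_done", stage="lm_training", corpus_segments=len(corpus))

    rows: list[ScreeningRow] = []
    for t in d:
        failed: list[str] = []
        try:
            language = detect_language(t).language
        except Exception as exc:
            logger.exception("language detection failed for %s", t.id)
            language, failed = "und", failed + ["language"]
        features = None
        flags: frozenset[str] = frozenset()
        try:
            features = compute_features(t)
            flags = flag_outliers(features, cfg.rules)
            features.flags = flags
        except Exception:
            logger.exception("feature extraction failed for %s", t.id)
            failed.append("features")
        profile = None
        if lm is not None:
            try:
                profile = transcript_profile(t, lm, mwps=cfg.mwps, ms=cfg.ms)
            except Exception:
                logger.exception("perplexity profiling failed for %s", t.id)
                failed.append("perplexity")
        classification = None
        try:
            classification = classify(t, backend, cfg.template)
        except Exception:
            logger.exception("classification failed for %s", t.id)
            failed.append("classification")

        if failed:
            disposition, rule_name = cfg.default_disposition, "stage_failure"
        else:
            disposition, rule_name = _apply_policy(cfg, flags, classification, duplicate_of.get(t.id))
        if disposition == "exclude":
            _log_event(event="exclude", transcript_id=t.id, rule=rule_name,
                       flags=sorted(flags))
        rows.append(
            ScreeningRow(
                transcript_id=t.id,
                language=language,
                duplicate_of=duplicate_of.get(t.id),
                features=features,
                flags=flags,
                profile=profile,
                classification=classification,
                final_disposition=disposition,
                failed_stages=failed,
            )
        )
    report = ScreeningReport(rows=rows, summary={})
    report.summary = summarize(report)
    _log_event(event="done", stage="screen", **report.summary["dispositions"])
    return report


def _apply_policy(
    cfg: ScreeningConfig,
    flags: frozenset[str],
    classification: ClassificationResult | None,
    duplicate_of: str | None,
) -> tuple[str, str]:
    label = classification.label if classification is not None else None
    for rule in cfg.policy:
        if rule.matches(flags, label, duplicate_of):
            return rule.disposition, rule.name
    return cfg.default_disposition, "default"


def summarize(report: ScreeningReport) -> dict:
    """Counts and proportions per disposition, flag, and classification label."""
    rows = report.rows
    n = len(rows)
    dispositions = {disp: sum(r.final_disposition == disp for r in rows) for disp in DISPOSITIONS}
    flag_counts: dict[str, int] = {}
    for r in rows:
        for f in r.flags:
            flag_counts[f] = flag_counts.get(f, 0) + 1
    labels: dict[str, int] = {}
    for r in rows:
        if r.classification is not None:
            labels[r.classification.label] = labels.get(r.classification.label, 0) + 1
    summary = {
        "n_transcripts": n,
        "dispositions": dispositions,
        "disposition_proportions": {k: (v / n if n else 0.0) for k, v in dispositions.items()},
        "flags": dict(sorted(flag_counts.items())),
        "classification_labels": dict(sorted(labels.items())),
    }
    return summary


def classification_shares(label_counts: Mapping[str, int]) -> dict[str, float]:
    """Percent shares (0-100) from a label→count mapping."""
    total = sum(label_counts.values())
    if total == 0:
        raise ValueError("no classified transcripts")
    return {label: 100.0 * count / total for label, count in label_counts.items()}


def certainty_distribution(certainties: Sequence[int]) -> dict[int, float]:
    """Percent of rated transcripts at each certainty level (1-5)."""
    if not certainties:
        raise ValueError("no certainty ratings")
    n = len(certainties)
    return {level: 100.0 * sum(c == level for c in certainties) / n for level in range(1, 6)}
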