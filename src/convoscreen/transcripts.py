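"""Transcript data model, CSV I/O, tokenization, and annotation utilities.

A transcript is an ordered list of speaker-labeled, timestamped speech
segments exported from an ambient transcription platform as a small CSV
(speaker label, timestamp(s), content — one segment per row). Two timestamp
layouts are supported: a single per-segment timestamp (interpreted as the
segment's end time) and an explicit start/end pair. With a single timestamp,
per-segment spoken time is derived as the delta from the previous segment's
timestamp (the first segment measures from 0), which preserves both the
"net spoken time" and "whole conversation" computations downstream.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

ERROR_FLAGS = frozenset(
    {
        "non_session_content",
        "too_short",
        "unreadable",
        "diarization_error",
        "missing_or_duplicated",
    }
)

_TOKEN_RE = re.compile(r"\w+(?:['’\-]\w+)*", re.UNICODE)


class TranscriptFormatError(ValueError):
    """A CSV file does not conform to the declared dialect."""


class TranscriptRowError(ValueError):
    """A specific CSV row could not be parsed; carries the row index."""

    def __init__(self, message: str, row_index: int):
        super().__init__(f"row {row_index}: {message}")
        self.row_index = row_index


class EmptyInputError(ValueError):
    """An operation received an empty transcript/record list."""


@dataclass(frozen=True)
class Segment:
    """One speech turn: a speaker label, timing, and raw content text."""

    speaker_label: str
    end_s: float
    text: str
    start_s: float | None = None

    def __post_init__(self):
        if self.end_s < 0:
            raise ValueError(f"end_s must be >= 0, got {self.end_s}")
        if self.start_s is not None and self.start_s > self.end_s:
            raise ValueError(
                f"start_s ({self.start_s}) must not exceed end_s ({self.end_s})"
            )


@dataclass
class Transcript:
    """An ordered, speaker-labeled transcript plus optional metadata.

    ``metadata`` may carry therapist_id, client_id, organization, date and
    delivery_method; all are optional and never required by any computation.
    """

    id: str
    segments: list[Segment]
    metadata: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.segments)

    def full_text(self, sep: str = " ") -> str:
        return sep.join(s.text for s in self.segments)

    def segment_durations(self) -> list[float]:
        """Per-segment spoken seconds under the transcript's dialect.

        Segments carrying an explicit start use ``end - start``; segments
        with only an end timestamp use the delta from the previous segment's
        end (first segment: delta from 0).
        """
        durations: list[float] = []
        prev_end = 0.0
        for seg in self.segments:
            if seg.start_s is not None:
                durations.append(seg.end_s - seg.start_s)
            else:
                durations.append(seg.end_s - prev_end)
            prev_end = seg.end_s
        return durations


@dataclass
class Dataset:
    """A collection of transcripts plus a manifest of source filenames."""

    transcripts: list[Transcript]
    manifest: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        ids = [t.id for t in self.transcripts]
        if len(ids) != len(set(ids)):
            dupes = [i for i, c in Counter(ids).items() if c > 1]
            raise ValueError(f"duplicate transcript ids in dataset: {dupes}")

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts)

    def get(self, transcript_id: str) -> Transcript:
        for t in self.transcripts:
            if t.id == transcript_id:
                return t
        raise KeyError(transcript_id)


@dataclass(frozen=True)
class AnnotationRecord:
    """One rater's judgement of one transcript."""

    transcript_id: str
    rater_id: str
    label: str  # session | non_session | undecided
    session_type: str = "unknown"  # individual | couple | family | group | unknown
    error_flags: frozenset[str] = frozenset()
    needs_context: bool = False

    def __post_init__(self):
        if self.label not in {"session", "non_session", "undecided"}:
            raise ValueError(f"unknown label {self.label!r}")
        if self.session_type not in {"individual", "couple", "family", "group", "unknown"}:
            raise ValueError(f"unknown session_type {self.session_type!r}")
        unknown = set(self.error_flags) - ERROR_FLAGS
        if unknown:
            raise ValueError(f"unknown error flags: {sorted(unknown)}")
        if self.label == "undecided" and not self.needs_context:
            raise ValueError("label 'undecided' requires needs_context=True")


@dataclass(frozen=True)
class CsvDialect:
    """Column mapping and timestamp layout for transcript CSV files.

    ``layout`` is ``"single"`` (one timestamp column, mapped to the segment
    end) or ``"pair"`` (explicit start and end columns).
    """

    layout: str = "single"
    speaker_col: str = "speaker"
    timestamp_col: str = "timestamp"
    start_col: str = "start"
    end_col: str = "end"
    content_col: str = "content"
    allow_empty_text: bool = False

    def __post_init__(self):
        if self.layout not in {"single", "pair"}:
            raise ValueError(f"layout must be 'single' or 'pair', got {self.layout!r}")

    def required_columns(self) -> tuple[str, ...]:
        if self.layout == "single":
            return (self.speaker_col, self.timestamp_col, self.content_col)
        return (self.speaker_col, self.start_col, self.end_col, self.content_col)


def tokenize(text: str) -> list[str]:
    """Lowercased whitespace/punctuation tokenization.

    Punctuation is stripped except intra-word hyphens and apostrophes, so
    backchannels like ``uh-huh`` and contractions like ``don't`` stay single
    tokens. Empty text yields an empty list.
    """
    return _TOKEN_RE.findall(text.lower())


def _parse_float(value: str, row_index: int, col: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise TranscriptRowError(f"unparseable timestamp {value!r} in column {col!r}", row_index)


def read_transcript_csv(
    path: str | Path,
    dialect: CsvDialect = CsvDialect(),
    transcript_id: str | None = None,
) -> Transcript:
    """Read one per-transcript CSV into a :class:`Transcript`.

    Rows out of end-timestamp order are sorted (stably) with a logged
    warning rather than rejected; noisy exports are tolerated, not edited.
    """
    path = Path(path)
    tid = transcript_id if transcript_id is not None else path.stem
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in dialect.required_columns() if c not in header]
        if missing:
            raise TranscriptFormatError(
                f"{path}: missing required column(s) {missing}; header was {header}"
            )
        segments: list[Segment] = []
        for i, row in enumerate(reader):
            text = (row[dialect.content_col] or "").strip()
            if not text and not dialect.allow_empty_text:
                raise TranscriptRowError("empty content text", i)
            if dialect.layout == "single":
                end = _parse_float(row[dialect.timestamp_col], i, dialect.timestamp_col)
                start = None
            else:
                start = _parse_float(row[dialect.start_col], i, dialect.start_col)
                end = _parse_float(row[dialect.end_col], i, dialect.end_col)
            try:
                segments.append(
                    Segment(speaker_label=row[dialect.speaker_col], end_s=end,
                            text=text, start_s=start)
                )
            except ValueError as exc:
                raise TranscriptRowError(str(exc), i) from exc
    ends = [s.end_s for s in segments]
    if any(b < a for a, b in zip(ends, ends[1:])):
        logger.warning("%s: segments out of end-timestamp order; sorting", path)
        segments.sort(key=lambda s: s.end_s)
    return Transcript(id=tid, segments=segments)


def write_transcript_csv(
    t: Transcript, path: str | Path, dialect: CsvDialect = CsvDialect()
) -> None:
    """Write a transcript back to CSV under the given dialect.

    Timestamps are written with ``repr`` so a read/write round trip
    reproduces them bit-exactly.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        if dialect.layout == "single":
            writer.writerow([dialect.speaker_col, dialect.timestamp_col, dialect.content_col])
            for seg in t.segments:
                writer.writerow([seg.speaker_label, repr(seg.end_s), seg.text])
        else:
            writer.writerow(
                [dialect.speaker_col, dialect.start_col, dialect.end_col, dialect.content_col]
            )
            for seg in t.segments:
                if seg.start_s is None:
                    raise ValueError(
                        f"transcript {t.id}: segment lacks start_s, cannot write 'pair' layout"
                    )
                writer.writerow(
                    [seg.speaker_label, repr(seg.start_s), repr(seg.end_s), seg.text]
                )


def load_dataset(
    source: str | Path | Mapping[str, str | Path],
    dialect: CsvDialect = CsvDialect(),
    glob: str = "*.csv",
) -> Dataset:
    """Load a dataset from a directory of CSVs or an id→path manifest.

    A directory is globbed (sorted for determinism) and each file becomes a
    transcript keyed by its stem; a mapping is read as an explicit manifest.
    """
    entries: list[tuple[str, Path]] = []
    if isinstance(source, (str, Path)):
        root = Path(source)
        if not root.is_dir():
            raise FileNotFoundError(f"{root} is not a directory")
        entries = [(p.stem, p) for p in sorted(root.glob(glob))]
    else:
        entries = [(tid, Path(p)) for tid, p in source.items()]
    transcripts = [read_transcript_csv(p, dialect, transcript_id=tid) for tid, p in entries]
    manifest = {tid: p.name for tid, p in entries}
    return Dataset(transcripts=transcripts, manifest=manifest)


def conversation_length(t: Transcript) -> float:
    """Whole-conversation length: the latest segment end timestamp.

    Time before the first utterance counts toward the length; time after the
    last segment (device left running without further speech) does not.
    """
    if not t.segments:
        raise EmptyInputError(f"transcript {t.id} has no segments")
    return max(s.end_s for s in t.segments)


def sample_review_sheet(
    d: Dataset, n_transcripts: int, segments_per: int, seed: int
) -> dict[str, list[int]]:
    """Draw a reproducible manual-review sample.

    Picks ``n_transcripts`` transcripts without replacement and, within each,
    ``segments_per`` segment indices (all of them when a transcript is
    shorter). Returns transcript id → sorted segment indices.
    """
    if n_transcripts > len(d):
        raise ValueError(
            f"n_transcripts={n_transcripts} exceeds dataset size {len(d)}"
        )
    rng = np.random.default_rng(seed)
    order = sorted(t.id for t in d)
    chosen = rng.choice(len(order), size=n_transcripts, replace=False)
    sheet: dict[str, list[int]] = {}
    for idx in sorted(chosen):
        tid = order[idx]
        n_seg = len(d.get(tid))
        if n_seg <= segments_per:
            picks = list(range(n_seg))
        else:
            picks = sorted(rng.choice(n_seg, size=segments_per, replace=False).tolist())
        sheet[tid] = picks
    return sheet


def error_prevalence(records: Sequence[AnnotationRecord]) -> dict[str, float]:
    """Per-flag error prevalence over distinct transcripts.

    Each transcript counts at most once per flag: when several raters cover
    the same transcript, the flag is attributed by majority, with ties
    counted as flagged (conservative toward review). The special key
    ``any_error`` is the proportion of transcripts carrying at least one
    majority flag.
    """
    if not records:
        raise EmptyInputError("no annotation records")
    by_transcript: dict[str, list[AnnotationRecord]] = defaultdict(list)
    for rec in records:
        by_transcript[rec.transcript_id].append(rec)
    n = len(by_transcript)
    flag_counts: Counter[str] = Counter()
    any_count = 0
    for recs in by_transcript.values():
        n_raters = len(recs)
        flagged_here = False
        for flag in ERROR_FLAGS:
            votes = sum(flag in r.error_flags for r in recs)
            if votes * 2 >= n_raters and votes > 0:  # majority; tie -> flagged
                flag_counts[flag] += 1
                flagged_here = True
        if flagged_here:
            any_count += 1
    out = {flag: flag_counts.get(flag, 0) / n for flag in sorted(ERROR_FLAGS)}
    out["any_error"] = any_count / n
    return out


def write_review_sheet_csv(sheet: Mapping[str, list[int]], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["transcript_id", "segment_index"])
        for tid, indices in sheet.items():
            for idx in indices:
                writer.writerow([tid, idx])


def write_prevalence_report(
    prevalence: Mapping[str, float], csv_path: str | Path, json_path: str | Path | None = None
) -> None:
    with Path(csv_path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["flag", "proportion"])
        for flag, prop in prevalence.items():
            writer.writerow([flag, prop])
    if json_path is not None:
        Path(json_path).write_text(json.dumps(dict(prevalence), indent=2))
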