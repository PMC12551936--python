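"""Seeded synthetic transcript generator with class-conditional structure
and error injection.

Five transcript classes emulate what turns up in ambiently recorded
behavioral-health datasets:

* ``session`` — 45–60 min two-speaker dialogues drawing on a therapeutic
  vocabulary (the only class mapped to the *session* label);
* ``case_management`` — short (<15 min) logistical phone calls;
* ``answering_machine`` — very short single-speaker recordings with a
  speaking rate above 4 words/s;
* ``noise`` — a handful of segments of repeated backchannel fillers
  ("mhm", "uh-huh"), the signature of transcribed noise;
* ``informal`` — casual conversations with everyday vocabulary.

Text is drawn from editable word pools rather than generated language:
deterministic, dependency-free, and sufficient to give an n-gram model the
session/non-session perplexity contrast (session vocabulary is predictable
under a session-trained model; backchannel noise and off-domain chatter are
not). Injectable errors mirror the observed error taxonomy: speaker-label
swaps, duplicated segments, dropped words, and filler bursts.

Everything is deterministic given (specs, injection, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .assets import load_wordlist
from .transcripts import CsvDialect, Dataset, Segment, Transcript, write_transcript_csv

KINDS = ("session", "case_management", "answering_machine", "noise", "informal")

# Everyday / function words shared across speech-like classes so that
# language detection and n-gram training see natural token statistics.
_COMMON = (
    "i you we the a to and it that was is in of for on with my your have had "
    "do did not but so then there what how about going really think know want "
    "been this week today time day"
).split()

_EVERYDAY = (
    "relationship house job school sleep car work talk life friend mom dad "
    "sister kid family money morning night dinner doctor week month"
).split()

_SCHEDULING = (
    "appointment schedule reschedule paperwork form insurance billing copay "
    "referral intake availability tuesday thursday confirm cancel office "
    "transportation housing benefits caseworker"
).split()

_MACHINE = (
    "you have reached the voicemail of please leave a message after the tone "
    "our office hours are monday through friday press one to for assistance "
    "thank calling"
).split()


def _lexicon(kind: str) -> list[str]:
    therapeutic = sorted(load_wordlist("therapeutic_markers"))
    casual = sorted(load_wordlist("casual_markers"))
    backchannels = sorted(load_wordlist("backchannels"))
    if kind == "session":
        return _COMMON * 3 + _EVERYDAY * 2 + therapeutic * 2
    if kind == "case_management":
        return _COMMON * 2 + _SCHEDULING * 3 + _EVERYDAY
    if kind == "answering_machine":
        return _MACHINE * 3 + _SCHEDULING
    if kind == "noise":
        return backchannels
    if kind == "informal":
        return _COMMON * 2 + casual * 3 + _EVERYDAY
    raise ValueError(f"unknown kind {kind!r}")


@dataclass(frozen=True)
class ClassSpec:
    """Generative parameters for one transcript class.

    Durations are seconds, rates words/second, segment lengths words; all
    draws are truncated normals (durations floored at 1 s).
    """

    kind: str
    duration_dist: tuple[float, float]
    rate_dist: tuple[float, float]
    n_speakers: int
    segment_len_dist: tuple[float, float]
    backchannel_fraction: float = 0.0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.duration_dist[0] <= 0 or self.rate_dist[0] <= 0 or self.segment_len_dist[0] <= 0:
            raise ValueError("all distribution means must be positive")
        if self.n_speakers < 1:
            raise ValueError("need at least one speaker")
        if self.kind == "answering_machine":
            if not (self.rate_dist[0] > 4.0 and self.duration_dist[0] < 120.0):
                raise ValueError(
                    "answering_machine requires rate mean > 4 WPS and duration mean < 120 s"
                )
        if self.kind == "case_management" and not self.duration_dist[0] < 900.0:
            raise ValueError("case_management requires duration mean < 900 s")
        if self.kind == "noise" and self.backchannel_fraction < 0.8:
            raise ValueError("noise requires backchannel_fraction >= 0.8")


DEFAULT_SPECS: dict[str, ClassSpec] = {
    "session": ClassSpec(
        kind="session",
        duration_dist=(3150.0, 450.0),  # ~45-60 min
        rate_dist=(2.5, 0.35),
        n_speakers=2,
        segment_len_dist=(12.0, 6.0),
    ),
    "case_management": ClassSpec(
        kind="case_management",
        duration_dist=(480.0, 180.0),  # well under 15 min
        rate_dist=(2.6, 0.35),
        n_speakers=2,
        segment_len_dist=(10.0, 5.0),
    ),
    "answering_machine": ClassSpec(
        kind="answering_machine",
        duration_dist=(45.0, 15.0),
        rate_dist=(4.8, 0.25),
        n_speakers=1,
        segment_len_dist=(14.0, 4.0),
    ),
    "noise": ClassSpec(
        kind="noise",
        duration_dist=(120.0, 60.0),
        rate_dist=(1.2, 0.3),
        n_speakers=1,
        segment_len_dist=(5.0, 2.0),
        backchannel_fraction=0.9,
    ),
    "informal": ClassSpec(
        kind="informal",
        duration_dist=(1200.0, 400.0),
        rate_dist=(2.8, 0.4),
        n_speakers=2,
        segment_len_dist=(11.0, 5.0),
    ),
}

LABEL_OF_KIND = {k: ("session" if k == "session" else "non_session") for k in KINDS}


@dataclass(frozen=True)
class ErrorInjection:
    """Per-event probabilities for injected transcript errors."""

    p_speaker_swap: float = 0.0
    p_duplicate_segment: float = 0.0
    p_word_drop: float = 0.0
    p_filler_burst: float = 0.0

    def __post_init__(self):
        for name in ("p_speaker_swap", "p_duplicate_segment", "p_word_drop", "p_filler_burst"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {p}")


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, floor: float) -> float:
    return max(float(rng.normal(mean, sd)), floor)


def generate_transcript(
    spec: ClassSpec,
    inject: ErrorInjection = ErrorInjection(),
    seed: int = 0,
    transcript_id: str = "synthetic",
) -> tuple[Transcript, str, dict]:
    """Generate one transcript; returns (transcript, label, injected-error record).

    Speakers alternate; each segment's duration is its word count divided by
    a drawn per-segment rate, timestamps accumulate with small silent gaps,
    and generation stops once the drawn total duration is reached. Injected
    errors are applied after generation and recorded exactly.
    """
    rng = np.random.default_rng(seed)
    pool = np.array(_lexicon(spec.kind))
    backchannels = np.array(sorted(load_wordlist("backchannels")))
    duration = _truncnorm(rng, *spec.duration_dist, floor=1.0)
    lead_silence = float(rng.uniform(0.5, 3.0))
    target = max(duration - lead_silence, 1.0)

    # Draw (words, seconds) per segment until spoken time plus a nominal
    # silence budget (~1.2 s per gap) fills the target; noise transcripts
    # instead have a small fixed number of segments spread over the target.
    drawn: list[tuple[list[str], float]] = []
    n_noise_segments = int(rng.integers(2, 8)) if spec.kind == "noise" else None
    spoken = 0.0
    while True:
        if n_noise_segments is not None:
            if len(drawn) >= n_noise_segments:
                break
        elif drawn and spoken + 1.2 * len(drawn) >= target:
            break
        n_words = max(1, int(round(rng.normal(*spec.segment_len_dist))))
        rate = max(0.3, float(rng.normal(*spec.rate_dist)))
        if spec.kind == "noise":
            filler = str(rng.choice(backchannels))
            words = [
                filler if rng.random() < spec.backchannel_fraction else str(rng.choice(pool))
                for _ in range(n_words)
            ]
        else:
            words = [str(w) for w in rng.choice(pool, size=n_words)]
        seg_seconds = round(n_words / rate, 3)
        drawn.append((words, seg_seconds))
        spoken += seg_seconds

    # Distribute the remaining silence over the inter-segment gaps so the
    # final end timestamp lands on the drawn duration.
    n = len(drawn)
    leftover = max(target - spoken, 0.0)
    gaps = rng.dirichlet(np.ones(n - 1)) * leftover if n > 1 else np.array([])
    segments: list[Segment] = []
    clock = lead_silence
    for i, (words, seg_seconds) in enumerate(drawn):
        start = round(clock, 3)
        end = round(start + seg_seconds, 3)
        segments.append(
            Segment(
                speaker_label=f"speaker_{i % spec.n_speakers}",
                start_s=start,
                end_s=end,
                text=" ".join(words),
            )
        )
        clock = end + (float(gaps[i]) if i < n - 1 else 0.0)

    errors = {"speaker_swap": [], "duplicate_segment": [], "word_drop": [], "filler_burst": []}
    out: list[Segment] = []
    for idx, seg in enumerate(segments):
        if inject.p_speaker_swap and rng.random() < inject.p_speaker_swap:
            swapped = f"speaker_{(int(seg.speaker_label.rsplit('_', 1)[1]) + 1) % max(spec.n_speakers, 2)}"
            seg = replace(seg, speaker_label=swapped)
            errors["speaker_swap"].append(idx)
        if inject.p_word_drop:
            words = seg.text.split()
            kept = [w for w in words if rng.random() >= inject.p_word_drop]
            if len(kept) < len(words):
                errors["word_drop"].append({"segment": idx, "dropped": len(words) - len(kept)})
                seg = replace(seg, text=" ".join(kept) if kept else words[0])
        if inject.p_filler_burst and rng.random() < inject.p_filler_burst:
            filler = str(rng.choice(backchannels))
            seg = replace(seg, text=" ".join([filler] * max(len(seg.text.split()), 3)))
            errors["filler_burst"].append(idx)
        out.append(seg)
        if inject.p_duplicate_segment and rng.random() < inject.p_duplicate_segment:
            out.append(seg)
            errors["duplicate_segment"].append(idx)
    transcript = Transcript(id=transcript_id, segments=out)
    return transcript, LABEL_OF_KIND[spec.kind], errors


DEFAULT_CLASS_COUNTS = {
    "session": 40,
    "case_management": 10,
    "answering_machine": 10,
    "noise": 10,
    "informal": 10,
}


def generate_dataset(
    class_counts: Mapping[str, int] | None = None,
    inject: ErrorInjection = ErrorInjection(),
    seed: int = 0,
    specs: Mapping[str, ClassSpec] | None = None,
    scramble_names: bool = False,
) -> tuple[Dataset, list[dict]]:
    """Generate a labeled synthetic dataset.

    Returns the dataset plus a label table: one record per transcript with
    its id, kind, session/non-session label, source filename, and injected
    error record. Filenames are class-tagged by default or random hex when
    ``scramble_names`` is set. Same inputs → identical output, byte for
    byte when written out.
    """
    class_counts = dict(class_counts) if class_counts is not None else dict(DEFAULT_CLASS_COUNTS)
    if sum(class_counts.values()) < 1:
        raise ValueError("need at least one transcript")
    specs = dict(specs) if specs is not None else DEFAULT_SPECS
    root_seq = np.random.SeedSequence(seed)
    name_rng = np.random.default_rng(root_seq.spawn(1)[0])
    transcripts: list[Transcript] = []
    manifest: dict[str, str] = {}
    labels: list[dict] = []
    idx = 0
    for kind in KINDS:  # fixed order for determinism
        count = class_counts.get(kind, 0)
        for j in range(count):
            child = root_seq.spawn(1)[0]
            tid = f"{kind}_{j:04d}"
            t, label, errors = generate_transcript(
                specs[kind], inject, seed=int(child.generate_state(1)[0] % (2**31)), transcript_id=tid
            )
            if scramble_names:
                fname = f"{name_rng.integers(0, 2**32):08x}.csv"
            else:
                fname = f"{tid}.csv"
            transcripts.append(t)
            manifest[tid] = fname
            labels.append(
                {"transcript_id": tid, "kind": kind, "label": label,
                 "filename": fname, "errors": errors}
            )
            idx += 1
    return Dataset(transcripts=transcripts, manifest=manifest), labels


def write_dataset(
    dataset: Dataset, labels: list[dict], out_dir: str | Path,
    dialect: CsvDialect = CsvDialect(layout="pair"),
) -> None:
    """Write per-transcript CSVs plus labels.csv and errors.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for t in dataset:
        write_transcript_csv(t, out / dataset.manifest[t.id], dialect)
    with (out / "labels.csv").open("w", encoding="utf-8") as fh:
        fh.write("transcript_id,kind,label,filename\n")
        for rec in labels:
            fh.write(f"{rec['transcript_id']},{rec['kind']},{rec['label']},{rec['filename']}\n")
    (out / "errors.json").write_text(
        json.dumps({rec["transcript_id"]: rec["errors"] for rec in labels}, indent=2)
    )
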