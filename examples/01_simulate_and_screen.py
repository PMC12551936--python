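"""Generate a small labeled synthetic dataset and run the full screening
pipeline: duplicate candidates, language, outlier flags, perplexity
profiles, mock classification, and final dispositions."""

import logging

import convoscreen as cs

logging.basicConfig(level=logging.ERROR)

dataset, labels = cs.generate_dataset(
    {"session": 12, "case_management": 4, "answering_machine": 4, "noise": 4, "informal": 4},
    seed=42,
    scramble_names=True,  # sequential fixture names would all look like duplicates
)
report = cs.screen(dataset, cs.ScreeningConfig(seed=42))

print(f"screened {report.summary['n_transcripts']} transcripts")
print("dispositions:", report.summary["dispositions"])
print("outlier flags:", report.summary["flags"])
print("classified as:", report.summary["classification_labels"])

# "exclude" rows fired the answering-machine rule (high rate + short duration);
# "keep" rows are flag-free transcripts the classifier called sessions;
# everything else goes to human review.
kind_of = {r["transcript_id"]: r["kind"] for r in labels}
for row in report.rows:
    if row.final_disposition == "exclude":
        print(f"  excluded {row.transcript_id} (true kind: {kind_of[row.transcript_id]}), "
              f"flags={sorted(row.flags)}")
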