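"""Inter-rater agreement statistics and rater-vs-model reconciliation.

Reproduces the arithmetic of a validation exercise: two raters agreeing on
44 of 51 transcripts, and a model-vs-raters contingency table with the
couple/family re-scoping rule."""

import convoscreen as cs
from convoscreen.classify import ClassificationResult

# two raters, 44 agreements out of 51
rater_1 = ["session"] * 44 + ["session"] * 7
rater_2 = ["session"] * 44 + ["non_session"] * 7
rep = cs.agreement(rater_1, rater_2)
print(f"raters: percent agreement {100 * rep.percent_agreement:.1f}%")

# model vs raters: yes/yes 26, yes/no 7, no/yes 2, no/no 9
model = ["yes"] * 33 + ["no"] * 11
raters = ["yes"] * 26 + ["no"] * 7 + ["yes"] * 2 + ["no"] * 9
rep2 = cs.agreement(model, raters)
print(f"model vs raters: kappa {rep2.kappa:.3f}, "
      f"agreement {100 * rep2.percent_agreement:.1f}%")
print("contingency table (rows=model, cols=raters):")
print(rep2.table)
# kappa ~0.53 is moderate chance-corrected agreement on the raw labels.

# re-scoping: raters marked only individual sessions as sessions, so a model
# "session" explicitly typed as couple counts as agreement with rater "no"
call = ClassificationResult(
    transcript_id="t", label="session", session_type="couple", certainty=5,
    explanation="", summary="a couple session about communication",
    nontherapeutic_dynamics=False,
)
print("couple session vs rater non-session, individual-only scope:",
      cs.reconcile(call, "non_session", "individual_only"))
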