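"""Zero-shot prompt building/parsing, the mock backend, reconciliation,
and the p75-perplexity threshold classifier grid."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from convoscreen import (
    MockBackend,
    PromptTemplate,
    Segment,
    Transcript,
    build_prompt,
    classify,
    evaluate_p75_classifier,
    generate_dataset,
    parse_response,
    reconcile,
    transcript_profile,
)
from convoscreen.classify import (
    DEFAULT_GRID,
    BackendError,
    ClassificationResult,
    PromptTemplateError,
    ResponseParseError,
)
from convoscreen.transcripts import EmptyInputError


@pytest.fixture
def session_like():
    return Transcript(
        id="s1",
        segments=[
            Segment("therapist", end_s=5.0, text=(
                "Everything we discuss here stays confidential so let us review "
                "your treatment goals and the coping strategies homework"
            )),
            Segment("client", end_s=15.0, text=(
                "My anxiety has been better this week and the breathing exercises "
                "helped with the stress and the feelings of depression at work"
            )),
            Segment("therapist", end_s=25.0, text=(
                "That is real progress let us try reframing those thoughts and "
                "talk about triggers and support before our session ends"
            )),
        ],
    )


class TestBuildPrompt:
    def test_contains_elements_and_tags(self, session_like):
        template = PromptTemplate()
        prompt = build_prompt(session_like, template)
        for element_text in template.elements.values():
            assert element_text in prompt
        for tag in template.output_tags.values():
            assert f"<{tag}>" in prompt
        assert "confidential" in prompt  # transcript embedded

    def test_missing_element_is_construction_error(self):
        bad = dict(PromptTemplate().elements)
        bad["dynamics"] = ""
        with pytest.raises(PromptTemplateError):
            PromptTemplate(elements=bad)

    def test_duplicate_tag_names_rejected(self):
        tags = dict(PromptTemplate().output_tags)
        tags["certainty"] = tags["classification"]
        with pytest.raises(PromptTemplateError):
            PromptTemplate(output_tags=tags)

    def test_prompts_differ_only_in_transcript_block(self, session_like):
        other = Transcript(id="s2", segments=[Segment("A", end_s=2.0, text="short call")])
        p1 = build_prompt(session_like)
        p2 = build_prompt(other)
        head1 = p1[: p1.index("<transcript>")]
        head2 = p2[: p2.index("<transcript>")]
        assert head1 == head2
        assert p1 != p2

    def test_empty_transcript_rejected(self):
        with pytest.raises(EmptyInputError):
            build_prompt(Transcript(id="e", segments=[]))


def _completion(cls="session", cert="5", summary="a talk about feelings", dyn="no"):
    return (
        f"<classification>{cls}</classification>"
        f"<certainty>{cert}</certainty>"
        f"<explanation>reasoning here</explanation>"
        f"<summary>{summary}</summary>"
        f"<nontherapeutic_dynamics>{dyn}</nontherapeutic_dynamics>"
    )


class TestParseResponse:
    def test_well_formed(self):
        r = parse_response(_completion(), transcript_id="t")
        assert (r.label, r.certainty, r.session_type) == ("session", 5, "individual")

    def test_non_session_variants(self):
        for raw in ("non-session", "Non_session", "NON-SESSION"):
            assert parse_response(_completion(cls=raw)).label == "non_session"

    def test_missing_classification_tag_errors(self):
        with pytest.raises(ResponseParseError):
            parse_response("<certainty>5</certainty>")

    def test_certainty_out_of_range_keeps_raw(self):
        with pytest.raises(ResponseParseError) as exc:
            parse_response(_completion(cert="7"))
        assert "7" in str(exc.value)
        assert exc.value.raw  # raw payload retained

    def test_couple_keyword_sets_session_type(self):
        r = parse_response(_completion(summary="clearly a couple session about marriage"))
        assert r.session_type == "couple"

    def test_family_keyword_in_classification_span(self):
        r = parse_response(_completion(cls="session (family therapy)"))
        assert r.session_type == "family"

    def test_non_session_type_unknown(self):
        r = parse_response(_completion(cls="non-session", summary="an answering machine"))
        assert r.session_type == "unknown"

    @settings(max_examples=150, deadline=None)
    @given(
        cls=st.sampled_from(["session", "non-session", "Session", "non_session"]),
        cert=st.integers(min_value=1, max_value=5),
        summary=st.text(
            alphabet=st.characters(blacklist_characters="<>", blacklist_categories=("Cs",)),
            max_size=80,
        ),
        dyn=st.sampled_from(["yes", "no", "Yes", "No"]),
    )
    def test_round_trip_over_valid_completions_never_errors(self, cls, cert, summary, dyn):
        r = parse_response(_completion(cls=cls, cert=str(cert), summary=summary, dyn=dyn))
        assert r.certainty == cert
        assert r.label in {"session", "non_session"}


class TestClassify:
    def test_mock_calls_session_fixture_session(self, session_like):
        r = classify(session_like, MockBackend())
        assert r.label == "session"
        assert 1 <= r.certainty <= 5

    def test_mock_calls_answering_machine_non_session(self):
        t = Transcript(
            id="am",
            segments=[Segment("A", end_s=10.0, text=(
                "you have reached the voicemail please leave a message after the tone"
            ))],
        )
        assert classify(t, MockBackend()).label == "non_session"

    def test_backend_retried_then_surfaced(self, session_like):
        calls = {"n": 0}

        def flaky(prompt):
            calls["n"] += 1
            raise ConnectionError("down")

        with pytest.raises(BackendError):
            classify(session_like, flaky, retries=2)
        assert calls["n"] == 3

    def test_backend_recovers_on_retry(self, session_like):
        calls = {"n": 0}
        good = MockBackend()

        def flaky(prompt):
            calls["n"] += 1
            if calls["n"] == 1:
                raise ConnectionError("down")
            return good(prompt)

        assert classify(session_like, flaky, retries=1).label == "session"


class TestReconcile:
    def _model(self, label="session", session_type="individual"):
        return ClassificationResult(
            transcript_id="t", label=label, session_type=session_type,
            certainty=5, explanation="", summary="", nontherapeutic_dynamics=False,
        )

    def test_direct_match(self):
        assert reconcile(self._model(), "session") is True

    def test_couple_rescoped_to_agreement(self):
        model = self._model(session_type="couple")
        assert reconcile(model, "non_session", "individual_only") is True

    def test_couple_not_rescoped_under_any_session_scope(self):
        model = self._model(session_type="couple")
        assert reconcile(model, "non_session", "any_session") is False

    def test_model_non_session_never_agrees_with_rater_session(self):
        for stype in ("unknown", "couple", "family"):
            model = self._model(label="non_session", session_type=stype)
            assert reconcile(model, "session") is False

    def test_unknown_scope_rejected(self):
        with pytest.raises(ValueError):
            reconcile(self._model(), "session", "whatever")


class TestP75Classifier:
    def _profiles(self, session_lm, counts, seed):
        dataset, labels = generate_dataset(counts, seed=seed)
        label_of = {r["transcript_id"]: r["label"] for r in labels}
        return [
            (transcript_profile(t, session_lm), label_of[t.id]) for t in dataset
        ]

    def test_grid_cardinality(self, session_lm):
        profiles = self._profiles(
            session_lm, {"session": 10, "informal": 5, "case_management": 5}, seed=404
        )
        report = evaluate_p75_classifier(profiles, DEFAULT_GRID)
        assert len(report.rows) + len(report.skipped) == 9

    def test_separable_classes_give_unit_auc(self, session_lm):
        profiles = self._profiles(session_lm, {"session": 10, "noise": 6}, seed=405)
        report = evaluate_p75_classifier(profiles, [(0, 0)])
        assert report.rows[0].roc_auc == pytest.approx(1.0)

    def test_counts_non_increasing_in_both_filters(self, session_lm):
        profiles = self._profiles(
            session_lm,
            {"session": 15, "informal": 5, "case_management": 5, "noise": 5},
            seed=406,
        )
        report = evaluate_p75_classifier(profiles, DEFAULT_GRID)
        cells = {(c.mwps, c.ms): c for c in report.rows}
        for (m, s), cell in cells.items():
            for m2, s2 in cells:
                if m2 >= m and s2 >= s:
                    other = cells[(m2, s2)]
                    assert other.n_sessions <= cell.n_sessions
                    assert other.n_non_sessions <= cell.n_non_sessions

    def test_empty_grid_rejected(self, session_lm):
        with pytest.raises(ValueError):
            evaluate_p75_classifier([], [])

    def test_end_to_end_mock_accuracy(self, mixed_dataset):
        dataset, labels = mixed_dataset
        backend = MockBackend()
        correct = sum(
            classify(dataset.get(r["transcript_id"]), backend).label == r["label"]
            for r in labels
        )
        assert correct / len(labels) >= 0.9
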