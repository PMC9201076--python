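import datetime

import pytest
from hypothesis import given, settings, strategies as st

from tnmstage import (
    NoteType,
    assemble_patients,
    detect_narrative_mentions,
    dichotomize,
    extract_patient_stage,
    parse_compact_tnm,
    render_compact,
    resolve_patient_stage,
)
from tnmstage.rules import (
    CLINICAL,
    PATHOLOGICAL,
    UNSPECIFIED,
    ContextFlags,
    StageMention,
    apply_context,
    extract_sentence_mentions,
)


class TestCompactPatterns:
    def test_full_pathological_pattern(self):
        ms = parse_compact_tnm("pT1N2M0")
        assert [(m.axis, m.numeral, m.prefix) for m in ms] == [
            ("T", 1, PATHOLOGICAL),
            ("N", 2, PATHOLOGICAL),
            ("M", 0, PATHOLOGICAL),
        ]

    def test_clinical_pattern_with_subtype(self):
        ms = parse_compact_tnm("cT2aN0M0")
        assert [(m.axis, m.numeral, m.subtype, m.prefix) for m in ms] == [
            ("T", 2, "a", CLINICAL),
            ("N", 0, None, CLINICAL),
            ("M", 0, None, CLINICAL),
        ]

    def test_no_pattern_no_mentions(self):
        assert parse_compact_tnm("no staging discussed") == []

    def test_whitespace_separated_components(self):
        ms = parse_compact_tnm("Stage pT3a N1 documented")
        assert [(m.axis, m.numeral) for m in ms] == [("T", 3), ("N", 1)]

    def test_yp_prefix_is_pathological(self):
        ms = parse_compact_tnm("ypT2N0")
        assert all(m.prefix == PATHOLOGICAL for m in ms)

    def test_out_of_range_component_dropped(self):
        ms = parse_compact_tnm("pT7N1")
        assert [(m.axis, m.numeral) for m in ms] == [("N", 1)]

    def test_bare_single_component_left_to_narrative_detector(self):
        assert parse_compact_tnm("t3a") == []

    @given(
        prefix=st.sampled_from(["c", "p"]),
        t=st.one_of(st.none(), st.tuples(st.integers(0, 4), st.sampled_from([None, "a", "b", "c"]))),
        n=st.one_of(st.none(), st.integers(0, 3)),
        m=st.one_of(st.none(), st.integers(0, 1)),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_round_trip_well_formed_patterns(self, prefix, t, n, m):
        parts = ""
        if t is not None:
            parts += f"T{t[0]}{t[1] or ''}"
        if n is not None:
            parts += f"N{n}"
        if m is not None:
            parts += f"M{m}"
        if not parts:
            return
        pattern = prefix + parts
        mentions = parse_compact_tnm(pattern)
        assert render_compact(mentions) == pattern


class TestNarrativeMentions:
    def test_bare_token_is_ambiguous(self, lexicon):
        ms = extract_sentence_mentions("he has t3a prostate cancer", lexicon)
        assert [(m.axis, m.numeral, m.subtype, m.prefix, m.ambiguous) for m in ms] == [
            ("T", 3, "a", UNSPECIFIED, True)
        ]

    def test_mapped_term_yields_stage_value(self, lexicon):
        ms = detect_narrative_mentions("lymph node involvement identified", lexicon.targets)
        assert [(m.axis, m.numeral, m.prefix) for m in ms] == [("N", 1, UNSPECIFIED)]

    def test_plain_sentence_yields_nothing(self, lexicon):
        assert detect_narrative_mentions("Patient doing well.", lexicon.targets) == []

    def test_overall_stage_recorded_but_not_tnm(self, lexicon):
        ms = extract_sentence_mentions("stage 1 prostate cancer", lexicon)
        overall = [m for m in ms if m.axis == "overall"]
        assert len(overall) == 1 and overall[0].ambiguous
        assert not [m for m in ms if m.axis in "TNM" and m.numeral == 1]


class TestConText:
    def test_forward_negation(self, lexicon):
        (m,) = extract_sentence_mentions("no evidence of nodal metastasis", lexicon)
        assert m.context.negated

    def test_hypothetical_if(self, lexicon):
        (m,) = extract_sentence_mentions("will discuss if metastasis develops", lexicon)
        assert m.context.hypothetical and not m.context.negated

    def test_no_trigger_no_flags(self, lexicon):
        (m,) = extract_sentence_mentions("nodal metastasis is present", lexicon)
        assert m.context == ContextFlags()

    def test_termination_closes_scope(self, lexicon):
        ms = extract_sentence_mentions(
            "no evidence of nodal metastasis but distant metastasis is present", lexicon
        )
        flags = {m.axis: m.context.negated for m in ms}
        assert flags == {"N": True, "M": False}

    def test_backward_trigger(self, lexicon):
        (m,) = extract_sentence_mentions("extracapsular extension was ruled out", lexicon)
        assert m.context.negated

    def test_pseudo_trigger_blocks_negation(self):
        mention = StageMention(axis="M", numeral=1, span=(15, 25))
        from tnmstage.lexicon import ModifierTrigger

        triggers = [
            ModifierTrigger("no", "negation", "forward"),
            ModifierTrigger("no increase", "pseudo", "forward"),
        ]
        (out,) = apply_context("no increase in metastasis", [mention], triggers)
        assert not out.context.negated

    def test_historical_flag_set(self, lexicon):
        (m,) = extract_sentence_mentions("history of t2a disease", lexicon)
        assert m.context.historical

    def test_other_experiencer(self, lexicon):
        (m,) = extract_sentence_mentions("father had metastatic prostate cancer", lexicon)
        assert m.context.experiencer_other


class TestDichotomize:
    @pytest.mark.parametrize(
        "kind,axis,numeral,expected",
        [
            (CLINICAL, "T", 1, "T1-2"),
            (CLINICAL, "T", 2, "T1-2"),
            (CLINICAL, "T", 3, "T3-4"),
            (PATHOLOGICAL, "T", 4, "T3-4"),
            (PATHOLOGICAL, "T", 2, "T2"),
            (CLINICAL, "N", 0, "N0"),
            (CLINICAL, "N", 2, "N1"),
            (CLINICAL, "M", 1, "M1"),
        ],
    )
    def test_mapping(self, kind, axis, numeral, expected):
        assert dichotomize(kind, axis, numeral) == expected

    def test_pathological_m_unsupported(self):
        with pytest.raises(ValueError):
            dichotomize(PATHOLOGICAL, "M", 1)

    def test_illegal_numeral_rejected(self):
        with pytest.raises(ValueError):
            dichotomize(CLINICAL, "M", 3)


def _mention(axis, numeral, prefix=CLINICAL, negated=False, hypothetical=False,
             note_type=NoteType.PROGRESS, date="2015-01-01", note_id="n1", span=(0, 4)):
    return StageMention(
        axis=axis,
        numeral=numeral,
        prefix=prefix,
        context=ContextFlags(negated=negated, hypothetical=hypothetical),
        note_type=note_type,
        date=datetime.date.fromisoformat(date) if date else None,
        note_id=note_id,
        span=span,
    )


class TestResolvePatientStage:
    def test_negated_m1_asserts_m0(self):
        fields = resolve_patient_stage([_mention("M", 1, negated=True)], CLINICAL)
        assert fields["cM"].category == "M0" and fields["cM"].from_negation

    def test_negation_never_asserts_complement_for_t(self):
        fields = resolve_patient_stage([_mention("T", 3, negated=True)], CLINICAL)
        assert "cT" not in fields

    def test_modal_numeral_wins(self):
        mentions = [
            _mention("T", 2, note_id="a"),
            _mention("T", 2, note_id="b"),
            _mention("T", 3, note_id="c"),
        ]
        fields = resolve_patient_stage(mentions, CLINICAL)
        assert fields["cT"].category == "T1-2" and fields["cT"].numeral == 2

    def test_tie_breaks_by_recency(self):
        mentions = [
            _mention("T", 2, date="2014-01-01"),
            _mention("T", 3, date="2015-06-01"),
        ]
        assert resolve_patient_stage(mentions, CLINICAL)["cT"].numeral == 3

    def test_no_mentions_all_missing(self):
        assert resolve_patient_stage([], CLINICAL) == {}

    def test_unspecified_prefix_routes_by_note_type(self):
        path_mention = _mention("T", 3, prefix=UNSPECIFIED, note_type=NoteType.PATHOLOGY)
        assert resolve_patient_stage([path_mention], PATHOLOGICAL)["pT"].category == "T3-4"
        assert resolve_patient_stage([path_mention], CLINICAL) == {}

    def test_historical_mentions_are_retained(self):
        m = _mention("T", 2)
        m.context.historical = True
        assert resolve_patient_stage([m], CLINICAL)["cT"].category == "T1-2"

    def test_monotonic_under_added_negation(self):
        positive = [_mention("N", 1, date="2015-01-01")]
        with_neg = positive + [_mention("N", 1, negated=True, date="2016-01-01", note_id="n9")]
        assert (
            resolve_patient_stage(positive, CLINICAL)["cN"].category
            == resolve_patient_stage(with_neg, CLINICAL)["cN"].category
            == "N1"
        )

    @given(st.permutations(list(range(6))), st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_permutation_invariant(self, order, data):
        base = []
        for i in range(6):
            base.append(
                _mention(
                    data.draw(st.sampled_from(["T", "N", "M"])),
                    data.draw(st.integers(0, 1)),
                    negated=data.draw(st.booleans()),
                    date=f"2015-0{data.draw(st.integers(1, 9))}-01",
                    note_id=f"n{i}",
                    span=(i, i + 4),
                )
            )
        ref = resolve_patient_stage(base, CLINICAL)
        shuffled = [base[i] for i in order]
        got = resolve_patient_stage(shuffled, CLINICAL)
        assert {k: v.category for k, v in ref.items()} == {k: v.category for k, v in got.items()}


class TestPatientLevelExtraction:
    def test_prefixed_mentions_route_to_their_own_stage_kind(self, note_factory):
        notes = [
            note_factory(note_id="n1", note_type="progress", date="2015-01-01",
                         text="Staging: cT2aN0M0."),
            note_factory(note_id="n2", note_type="pathology", date="2015-03-01",
                         text="Final stage pT3aN1."),
        ]
        (record,) = assemble_patients(notes)
        from tnmstage import default_lexicon

        stage = extract_patient_stage(record, default_lexicon())
        assert stage.category("cT") == "T1-2"
        assert stage.category("cN") == "N0"
        assert stage.category("cM") == "M0"
        assert stage.category("pT") == "T3-4"
        assert stage.category("pN") == "N1"

    def test_radiology_only_patient_has_no_stage(self, note_factory):
        notes = [note_factory(note_id="n1", note_type="radiology", text="Staging: cT3bN1M1.")]
        (record,) = assemble_patients(notes)
        from tnmstage import default_lexicon

        stage = extract_patient_stage(record, default_lexicon())
        assert stage.fields == {}
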