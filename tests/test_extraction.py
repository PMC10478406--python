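"""Extraction of AUC values: cues, roles, guards, normalization."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from auccaliper.extraction import (
    CandidateRejected,
    decimal_places,
    extract_values,
    find_cue_mentions,
    normalize_value,
)


def extract(record_factory, text, **kwargs):
    return extract_values(record_factory(text, **kwargs))


class TestCueMentions:
    def test_single_acronym(self):
        mentions = find_cue_mentions("The AUC was 0.82.")
        assert len(mentions) == 1
        assert mentions[0].canonical_cue == "auc"
        assert (mentions[0].char_start, mentions[0].char_end) == (4, 7)

    def test_phrase_and_parenthetical_acronym_both_found(self):
        mentions = find_cue_mentions(
            "area under the receiver operating characteristic curve (AUROC)"
        )
        assert [m.canonical_cue for m in mentions] == ["roc_area_phrase", "auroc"]

    def test_long_phrase_not_double_counted(self):
        mentions = find_cue_mentions("Area under the curve analysis was performed.")
        assert len(mentions) == 1

    def test_acronyms_case_sensitive(self):
        assert find_cue_mentions("The auc was 0.8.") == []

    @pytest.mark.parametrize("cue,canonical", [
        ("c-statistic", "c_statistic"),
        ("c-index", "c_index"),
        ("concordance index", "concordance"),
    ])
    def test_survival_cues(self, cue, canonical):
        mentions = find_cue_mentions(f"The {cue} was 0.71.")
        assert mentions[0].canonical_cue == canonical

    def test_pharmacokinetic_subscript_flagged(self):
        mentions = find_cue_mentions("glucose AUC0-24 was 412 ng·h/mL")
        assert len(mentions) == 1
        assert mentions[0].pk_suffix


class TestRoleClassification:
    def test_ci_triplet_point_lower_upper(self, record_factory):
        m = extract(record_factory, "The AUC was 0.704 (95% CI 0.603 to 0.806).")
        assert [(x.value, x.role) for x in m] == [
            (0.704, "point"), (0.603, "ci_lower"), (0.806, "ci_upper"),
        ]

    @pytest.mark.parametrize("text", [
        "The AUC was 0.704 (95% CI 0.603-0.806).",
        "The AUC was 0.704 (95% CI 0.603–0.806).",  # en dash
        "The AUC was 0.704 (0.603, 0.806).",
        "The AUC was 0.704 [0.603 to 0.806].",
    ])
    def test_interval_pattern_variants(self, record_factory, text):
        m = extract(record_factory, text)
        assert [x.role for x in m] == ["point", "ci_lower", "ci_upper"]

    def test_reversed_interval_flagged_not_swapped(self, record_factory):
        m = extract(record_factory, "The AUC was 0.70 (95% CI 0.80 to 0.60).")
        lower = next(x for x in m if x.role == "ci_lower")
        assert lower.value == 0.80  # as printed
        assert "ci_reversed" in lower.anomaly_flags

    def test_upper_limit_dropped_flags_partner(self, record_factory):
        m = extract(record_factory, "The AUC was 0.97 (95% CI 0.93 to 1.00).")
        assert [x.role for x in m] == ["point", "ci_lower"]
        lower = m[1]
        assert "out_of_range_partner" in lower.anomaly_flags

    def test_standalone_number_is_point(self, record_factory):
        (m,) = extract(record_factory, "The AUROC was 0.88.")
        assert m.role == "point"


class TestGuards:
    def test_scale_definition_sentence_yields_nothing(self, record_factory):
        assert extract(record_factory, "The AUC ranges between 0.5 and 1.") == []

    def test_qualitative_threshold_sentence_yields_nothing(self, record_factory):
        assert extract(
            record_factory,
            "AUC values between 0.7 and 0.8 were considered acceptable.",
        ) == []

    def test_value_of_exactly_one_excluded(self, record_factory):
        assert extract(record_factory, "The model achieved an AUC of 1.") == []
        assert extract(record_factory, "The model achieved an AUC of 1.0.") == []

    def test_sensitivity_specificity_numbers_not_claimed(self, record_factory):
        m = extract(
            record_factory, "The sensitivity was 0.91, specificity 0.66, AUC 0.83."
        )
        assert [(x.value, x.role) for x in m] == [(0.83, "point")]

    def test_pharmacokinetic_unit_rejected(self, record_factory):
        assert extract(record_factory, "The glucose AUC0-24 was 412 ng·h/mL.") == []
        assert extract(record_factory, "Dose-normalized AUC0-12 of 0.84 mg·h/L.") == []

    def test_number_without_nearby_cue_ignored(self, record_factory):
        assert extract(record_factory, "We recruited 120 patients over 0.5 years.") == []

    def test_rejections_logged_with_reason(self, record_factory):
        rejections = []
        extract_values(
            record_factory("The sensitivity was 0.91 and the AUC was 1.0."),
            rejections=rejections,
        )
        reasons = {r.reason for r in rejections}
        assert {"competing_cue", "out_of_range"} <= reasons

    def test_confidence_level_not_extracted_as_value(self, record_factory):
        m = extract(record_factory, "The AUC was 0.70 (95% CI 0.60 to 0.80).")
        assert all(x.value != 0.95 for x in m)


class TestNormalization:
    @pytest.mark.parametrize("token,expected", [
        ("85%", (0.85, True)),
        ("0.5", (0.5, False)),
        ("0.704", (0.704, False)),
    ])
    def test_accepted_tokens(self, token, expected):
        assert normalize_value(token) == expected

    @pytest.mark.parametrize("token", ["1.0", "1", "-0.2", "412", "101%"])
    def test_rejected_tokens(self, token):
        with pytest.raises(CandidateRejected):
            normalize_value(token)

    def test_bare_number_above_one_needs_percent_context(self):
        assert normalize_value("85", percent_context=True) == (0.85, True)
        with pytest.raises(CandidateRejected):
            normalize_value("85", percent_context=False)

    def test_percent_value_extracted_in_sentence(self, record_factory):
        (m,) = extract(record_factory, "The AUC was 85%.")
        assert (m.value, m.was_percent) == (0.85, True)


class TestDecimalPlaces:
    @pytest.mark.parametrize("token,expected", [
        ("0.8", 1),
        ("0.704", 3),
        ("80%", 2),
        ("73.1%", 3),
        ("1", 0),
    ])
    def test_printed_precision(self, token, expected):
        assert decimal_places(token) == expected

    def test_one_decimal_value_still_extracted(self, record_factory):
        (m,) = extract(record_factory, "The AUC was 0.8.")
        assert (m.value, m.decimal_places) == (0.8, 1)


class TestInvariantsAndDeterminism:
    def test_extraction_deterministic(self, record_factory):
        rec = record_factory(
            "The AUC was 0.704 (95% CI 0.603 to 0.806); sensitivity was 0.91."
        )
        assert extract_values(rec) == extract_values(rec)

    @settings(deadline=None, derandomize=True, max_examples=120)
    @given(
        st.floats(min_value=-5, max_value=150, allow_nan=False).map(lambda v: f"{v:.3f}"),
        st.booleans(),
    )
    def test_every_retained_value_in_unit_interval(self, token, pct):
        token = token + "%" if pct else token
        try:
            value, _ = normalize_value(token, percent_context=True)
        except CandidateRejected:
            return
        assert 0 <= value < 1

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.floats(min_value=0.01, max_value=0.99).map(lambda v: round(v, 3)))
    def test_fuzzed_auc_sentences_extracted(self, value):
        from conftest import make_record

        (m,) = extract_values(make_record(f"The AUC was {value:.3f}."))
        assert m.value == pytest.approx(value)
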