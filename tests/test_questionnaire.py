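"""Questionnaire scoring, severity bands and ratio memberships."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cloudhealth import (
    Instrument,
    MembershipReference,
    QuestionnaireResponse,
    Severity,
    cohort_summary,
    index_from_total,
    membership_index,
    membership_level,
    score_response,
)
from cloudhealth.questionnaire import (
    frame_to_responses,
    reference_from_worst_stratum,
    responses_to_frame,
)


def make_response(instrument: Instrument, total: int, rid="r1", **demo):
    """Items realising a given total (greedy 3s then the remainder)."""
    items = []
    remaining = total
    for _ in range(instrument.n_items):
        take = min(3, remaining)
        items.append(take)
        remaining -= take
    assert remaining == 0
    return QuestionnaireResponse(rid, instrument, tuple(items), demo)


class TestScoring:
    @pytest.mark.parametrize(
        "instrument, total, flagged, severity",
        [
            (Instrument.DEPRESSION9, 27, True, Severity.EXTREME_SEVERE),
            (Instrument.DEPRESSION9, 20, True, Severity.EXTREME_SEVERE),
            (Instrument.DEPRESSION9, 19, True, Severity.SEVERE),
            (Instrument.DEPRESSION9, 15, True, Severity.SEVERE),
            (Instrument.DEPRESSION9, 10, True, Severity.MODERATE),
            (Instrument.DEPRESSION9, 6, True, Severity.MILD),
            (Instrument.DEPRESSION9, 5, False, Severity.MILD),  # band/flag quirk
            (Instrument.DEPRESSION9, 4, False, Severity.NONE),
            (Instrument.DEPRESSION9, 0, False, Severity.NONE),
            (Instrument.ANXIETY7, 21, True, Severity.SEVERE),
            (Instrument.ANXIETY7, 15, True, Severity.SEVERE),
            (Instrument.ANXIETY7, 14, True, Severity.MODERATE),
            (Instrument.ANXIETY7, 10, True, Severity.MODERATE),
            (Instrument.ANXIETY7, 5, False, Severity.MILD),
            (Instrument.ANXIETY7, 0, False, Severity.NONE),
        ],
    )
    def test_totals_flags_and_bands(self, instrument, total, flagged, severity):
        a = score_response(make_response(instrument, total))
        assert a.total == total
        assert a.flagged is flagged
        assert a.severity is severity

    def test_extreme_severe_unreachable_for_anxiety(self):
        worst = score_response(make_response(Instrument.ANXIETY7, 21))
        assert worst.severity is Severity.SEVERE

    def test_severity_non_decreasing_in_total(self):
        order = list(Severity)
        ranks = [
            order.index(score_response(make_response(Instrument.DEPRESSION9, t)).severity)
            for t in range(28)
        ]
        assert ranks == sorted(ranks)

    @given(st.lists(st.integers(0, 3), min_size=9, max_size=9))
    def test_permutation_invariance(self, items):
        base = QuestionnaireResponse("p", Instrument.DEPRESSION9, tuple(items))
        shuffled = QuestionnaireResponse(
            "p", Instrument.DEPRESSION9, tuple(sorted(items, reverse=True))
        )
        assert score_response(base) == score_response(shuffled)

    def test_bad_item_value_names_position(self):
        with pytest.raises(ValueError, match="item4"):
            QuestionnaireResponse(
                "bad", Instrument.DEPRESSION9, (0, 1, 2, 4, 0, 0, 0, 0, 0)
            )

    def test_wrong_item_count(self):
        with pytest.raises(ValueError, match="7 items"):
            QuestionnaireResponse("bad", Instrument.ANXIETY7, (1, 2, 3))


class TestMembership:
    REF = MembershipReference(25.6)

    @pytest.mark.parametrize(
        "x, expected",
        [(30.0, 1.0), (25.6, 1.0), (18.0, 0.703125), (0.0, 0.0)],
    )
    def test_index_membership(self, x, expected):
        assert membership_index(x, self.REF) == pytest.approx(expected, abs=1e-12)

    def test_level_membership_matches_ratio(self):
        ref = MembershipReference(0.8)
        assert membership_level(0.43 * 0.8, ref) == pytest.approx(0.43)
        assert membership_level(1.2 * 0.8, ref) == 1.0

    def test_negative_value_rejected(self):
        with pytest.raises(ValueError):
            membership_index(-1.0, self.REF)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            MembershipReference(0.0)

    @given(st.floats(0, 100, allow_nan=False))
    def test_bounded_and_monotone(self, x):
        u = membership_index(x, self.REF)
        assert 0.0 <= u <= 1.0
        assert membership_index(x + 1.0, self.REF) >= u

    def test_vectorised(self):
        out = membership_index(np.array([0.0, 12.8, 25.6, 40.0]), self.REF)
        np.testing.assert_allclose(out, [0.0, 0.5, 1.0, 1.0])

    def test_affine_index_map_defaults_to_identity(self):
        assert index_from_total(17) == 17.0
        assert index_from_total(17, a=1.2, c=2.0) == pytest.approx(22.4)


class TestCohortSummary:
    def test_single_respondent(self):
        resp = make_response(Instrument.DEPRESSION9, 12, gender="female")
        table = cohort_summary([resp], by=["gender"])
        assert len(table) == 1
        row = table.iloc[0]
        assert row["n"] == 1
        assert row["mean_total"] == 12
        assert row["flagged_fraction"] == 1.0
        assert row["n_moderate"] == 1

    def test_identical_strata_give_identical_rows(self):
        cohort = [
            make_response(Instrument.DEPRESSION9, 8, rid=f"a{i}", gender="female")
            for i in range(3)
        ] + [
            make_response(Instrument.DEPRESSION9, 8, rid=f"b{i}", gender="male")
            for i in range(3)
        ]
        table = cohort_summary(cohort, by=["gender"]).drop(columns=["stratum"])
        female = table.iloc[0].drop("demographic")
        male = table.iloc[1].drop("demographic")
        assert (female == male).all()

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            cohort_summary([])

    def test_worst_stratum_reference(self):
        cohort = [
            make_response(Instrument.DEPRESSION9, 6, rid="a", occupation="cadre"),
            make_response(Instrument.DEPRESSION9, 20, rid="b", occupation="police"),
        ]
        ref = reference_from_worst_stratum(cohort, by="occupation")
        assert ref.reference_value == 20.0
        ref2 = reference_from_worst_stratum(cohort, indices={"a": 10.0, "b": 30.0})
        assert ref2.reference_value == 30.0


class TestResponseIO:
    def test_frame_round_trip_mixed_instruments(self):
        cohort = [
            make_response(Instrument.DEPRESSION9, 14, rid="d1", gender="female"),
            make_response(Instrument.ANXIETY7, 7, rid="a1", gender="male"),
        ]
        frame = responses_to_frame(cohort)
        assert frame.loc[1, "item8"] is not None  # column present, value NA
        back = frame_to_responses(frame)
        assert back == cohort

    def test_missing_item_rejected(self):
        frame = responses_to_frame(
            [make_response(Instrument.DEPRESSION9, 9, rid="d1")]
        )
        frame.loc[0, "item5"] = None
        with pytest.raises(ValueError, match="item5"):
            frame_to_responses(frame)
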