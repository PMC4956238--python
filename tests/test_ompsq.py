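"""ÖMPSQ scoring: transformation rules, checkbox handling, mean substitution,
risk banding and the scoring invariants."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bpscreen.errors import InvalidRecordError, RangeError
from bpscreen.ompsq import (
    MISSING,
    OmpsqResponse,
    default_instrument,
    resolve_checkbox,
    risk_band,
    score_ompsq,
    substitute_missing,
    transform_item,
    validate_record,
)
from conftest import make_response, maximal_response, minimal_response

INST = default_instrument()


class TestInstrumentTable:
    def test_counts_of_special_items(self):
        assert len(INST.items) == 21
        assert sum(s.inverted for s in INST.items) == 8
        assert [s.item_id for s in INST.items if s.inverted] == [12, 16, 17, 21, 22, 23, 24, 25]
        assert [s.item_id for s in INST.items if s.doubled] == [5]
        assert INST.checkbox_ids == (8, 16, 17)
        assert sum(s.scale_min == 1 for s in INST.items) == 3

    def test_total_bounds_derived_from_table(self):
        assert INST.total_bounds() == (4.0, 212.0)


class TestTransform:
    @pytest.mark.parametrize(
        "item_id,raw,expected",
        [
            (12, 0, 10.0),   # inversion endpoint
            (12, 7, 3.0),
            (12, 10, 0.0),
            (5, 1, 2.0),     # pain-sites doubling
            (5, 6, 12.0),
            (9, 4, 4.0),     # plain item is identity
        ],
    )
    def test_examples(self, item_id, raw, expected):
        assert transform_item(INST.spec(item_id), raw) == expected

    def test_out_of_range_names_item(self):
        with pytest.raises(RangeError) as exc:
            transform_item(INST.spec(5), 7)
        assert exc.value.item_id == 5

    @given(st.integers(0, 10))
    def test_inversion_is_involution(self, raw):
        spec = INST.spec(12)
        assert transform_item(spec, transform_item(spec, raw)) == raw


class TestCheckbox:
    def test_value_overrides_ticked_box(self):
        assert resolve_checkbox(6, True) == 6

    def test_ticked_without_value_is_missing(self):
        assert resolve_checkbox(MISSING, True) is MISSING

    def test_blank_without_tick_is_missing(self):
        assert resolve_checkbox(MISSING, False) is MISSING


class TestSubstitution:
    def test_complete_map_is_identity(self):
        m = {i: float(i) for i in range(21)}
        completed, n = substitute_missing(m)
        assert completed == m and n == 0

    def test_single_missing_gets_mean_of_constants(self):
        m = {i: 5.0 for i in range(20)}
        m[20] = MISSING
        completed, n = substitute_missing(m)
        assert completed[20] == 5.0 and n == 1

    def test_three_missing_total_is_21_times_mean(self):
        present = [2.0, 4.0, 6.0, 8.0, 10.0, 1.0, 3.0, 5.0, 7.0,
                   9.0, 0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 5.0, 5.0]
        mean = sum(present) / 18.0
        m = {i: v for i, v in enumerate(present)}
        m.update({18: MISSING, 19: MISSING, 20: MISSING})
        completed, n = substitute_missing(m)
        assert n == 3
        assert sum(completed.values()) == pytest.approx(21 * mean, abs=1e-12)

    def test_four_missing_rejected(self):
        m = {i: 5.0 for i in range(17)}
        m.update({i: MISSING for i in range(17, 21)})
        with pytest.raises(InvalidRecordError):
            substitute_missing(m)

    @given(
        st.lists(st.floats(0, 10), min_size=18, max_size=21),
        st.integers(0, 3),
    )
    def test_substitution_preserves_mean_exactly(self, values, n_missing):
        n_missing = min(n_missing, 21 - len(values))
        m = {i: v for i, v in enumerate(values)}
        m.update({100 + i: MISSING for i in range(n_missing)})
        completed, _ = substitute_missing(m)
        before = sum(values) / len(values)
        after = sum(completed.values()) / len(completed)
        assert after == pytest.approx(before, abs=1e-9)


class TestScoring:
    def test_minimal_and_maximal_totals(self):
        lo = score_ompsq(minimal_response())
        hi = score_ompsq(maximal_response())
        assert lo.total == 4.0 and lo.risk_band == "low"
        assert hi.total == 212.0 and hi.risk_band == "high"

    def test_hand_scored_fixture_with_two_checkbox_substitutions(self):
        # items 8 and 17 ticked "not working" and left empty; item 16 ticked
        # but answered (value overrides); the remaining 19 transformed values
        # sum to 87, so the total is 87 * 21 / 19 (hand computation).
        resp = OmpsqResponse(
            "FIX",
            raw_values={
                5: 3, 6: 2, 7: 4, 8: MISSING, 9: 5, 10: 6, 11: 7, 12: 2,
                13: 1, 14: 0, 15: 9, 16: 4, 17: MISSING, 18: 3, 19: 8,
                20: 2, 21: 5, 22: 9, 23: 0, 24: 10, 25: 6,
            },
            checkbox_ticked={8: True, 16: True, 17: True},
        )
        score = score_ompsq(resp)
        assert score.n_substituted == 2
        assert score.total == pytest.approx(87 * 21 / 19, abs=1e-12)
        assert score.risk_band == "medium"
        assert score.per_item_transformed[16] == 6.0  # 10 - 4, override kept

    def test_total_equals_sum_of_transformed(self):
        s = score_ompsq(make_response())
        assert s.total == pytest.approx(sum(s.per_item_transformed.values()), abs=1e-12)

    def test_permutation_invariance_of_column_order(self):
        resp = make_response()
        shuffled = OmpsqResponse(
            resp.participant_id,
            dict(reversed(list(resp.raw_values.items()))),
            resp.checkbox_ticked,
        )
        assert score_ompsq(resp).total == score_ompsq(shuffled).total

    def test_invalid_record_raises_structured_error(self):
        resp = make_response({8: MISSING, 9: MISSING, 10: MISSING, 11: MISSING})
        with pytest.raises(InvalidRecordError) as exc:
            score_ompsq(resp)
        assert "missing" in str(exc.value)


class TestValidation:
    def test_complete_record_valid(self):
        assert validate_record(make_response()).valid

    def test_three_missing_valid_with_substitutions(self):
        resp = make_response({9: MISSING, 10: MISSING, 11: MISSING})
        v = validate_record(resp)
        assert v.valid and v.n_missing == 3
        assert score_ompsq(resp).n_substituted == 3

    def test_four_missing_invalid(self):
        v = validate_record(make_response({9: MISSING, 10: MISSING, 11: MISSING, 13: MISSING}))
        assert not v.valid and "missing" in v.reason

    def test_out_of_range_invalid(self):
        assert not validate_record(make_response({9: 11})).valid


class TestRiskBands:
    @pytest.mark.parametrize(
        "total,band",
        [(90.9, "low"), (91.0, "medium"), (106.0, "medium"), (106.1, "high"), (4.0, "low"), (212.0, "high")],
    )
    def test_band_boundaries(self, total, band):
        assert risk_band(total) == band


@st.composite
def valid_raw_maps(draw):
    raw = {}
    for spec in INST.items:
        raw[spec.item_id] = draw(st.integers(spec.scale_min, spec.scale_max))
    return raw


class TestProperties:
    @settings(max_examples=60, deadline=None)
    @given(valid_raw_maps())
    def test_total_bounded(self, raw):
        total = score_ompsq(OmpsqResponse("H", raw)).total
        assert 4.0 <= total <= 212.0

    @settings(max_examples=60, deadline=None)
    @given(valid_raw_maps(), st.sampled_from([s.item_id for s in INST.items]))
    def test_risk_monotonicity(self, raw, item_id):
        """Raising a plain item (or lowering an inverted one) never lowers the total."""
        spec = INST.spec(item_id)
        base = score_ompsq(OmpsqResponse("H", raw)).total
        bumped = dict(raw)
        if spec.inverted:
            bumped[item_id] = max(spec.scale_min, raw[item_id] - 1)
        else:
            bumped[item_id] = min(spec.scale_max, raw[item_id] + 1)
        assert score_ompsq(OmpsqResponse("H", bumped)).total >= base - 1e-12
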