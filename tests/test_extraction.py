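"""Calendar parsing, episode extraction, classification, and the window."""

import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

import termcal as tc
from termcal.extraction import (
    MalformedRecordError, classify_union, classify_use, extract_episodes,
    impute_age_and_filter, parse_calendar,
)

from conftest import make_record

CAL = "0000BPPPPPPPP33333000000"  # v008=1200 -> B at 1196, P 1188-1195


class TestParseCalendar:
    def test_canonical_orientation_hand_trace(self):
        series = parse_calendar(make_record(CAL, v008=1200, v017=1177))
        assert series.cal1_at(1200) == "0"
        assert series.cal1_at(1196) == "B"
        for m in range(1188, 1196):
            assert series.cal1_at(m) == "P"
        for m in range(1183, 1188):
            assert series.cal1_at(m) == "3"
        assert series.cal1_at(1177) == "0"
        assert series.cal1_at(1176) is None

    def test_all_pad_string_gives_empty_series(self):
        series = parse_calendar(make_record(" " * 24, v008=1200, v017=1177))
        assert series.is_empty()
        assert all(series.cal1_at(m) is None for m in range(1177, 1201))

    def test_reversed_orientation_is_symmetric(self):
        canonical = parse_calendar(make_record(CAL, v008=1200, v017=1177))
        mirrored = parse_calendar(
            make_record(CAL[::-1], v008=1200, v017=1177),
            dataclasses.replace(tc.CANONICAL, left_is_interview=False),
        )
        assert all(canonical.cal1_at(m) == mirrored.cal1_at(m)
                   for m in range(1177, 1201))

    def test_length_mismatch_is_malformed(self):
        with pytest.raises(MalformedRecordError):
            parse_calendar(make_record(CAL[:10], v008=1200, v017=1177))

    def test_trailing_pad_beyond_span_is_accepted(self):
        series = parse_calendar(
            make_record(CAL + "    ", v008=1200, v017=1177))
        assert len(series) == 24

    def test_anchor_violation_is_malformed(self):
        with pytest.raises(MalformedRecordError):
            parse_calendar(make_record(CAL, v008=1200, v017=1177, v011=1300))


class TestExtractEpisodes:
    def extract(self, cal1, **kw):
        rec = make_record(cal1, **kw)
        return extract_episodes(parse_calendar(rec), rec), rec

    def test_full_term_birth_hand_trace(self):
        eps, _ = self.extract(CAL, v008=1200, v017=1177)
        assert len(eps) == 1
        ep = eps[0]
        assert (ep.start_cmc, ep.outcome_cmc, ep.outcome,
                ep.gestation_months) == (1188, 1196, "B", 9)

    def test_three_month_termination(self):
        eps, _ = self.extract("000TPP000000000000000000")
        assert len(eps) == 1
        assert eps[0].outcome == "PT"
        assert eps[0].gestation_months == 3

    def test_all_zero_calendar_is_empty(self):
        eps, _ = self.extract("0" * 24)
        assert eps == []

    def test_trailing_pregnancy_run_is_ignored(self):
        eps, _ = self.extract("PPPP0000B" + "PPPPPPPP" + "0000000")
        assert len(eps) == 1
        assert eps[0].outcome == "B"

    def test_consecutive_outcomes_are_separate_pregnancies(self):
        eps, _ = self.extract("0000BTPP0000000000000000")
        assert [(e.outcome, e.gestation_months) for e in eps] == [
            ("PT", 3), ("B", 1)]

    def test_overlong_run_capped_at_nine_months(self):
        eps, _ = self.extract("0000B" + "P" * 11 + "00000000")
        assert len(eps) == 1
        assert eps[0].gestation_months == 9
        assert eps[0].start_cmc == eps[0].outcome_cmc - 8

    def test_run_touching_calendar_start_is_undatable(self):
        eps, _ = self.extract("0000000000000000000BPPPP")
        assert eps == []

    def test_pt_type_read_from_parallel_string(self):
        rec = make_record("000TPP00T000000000000000",
                          reports_pt_type=True,
                          pt_types="000I0000S000000000000000")
        eps = extract_episodes(parse_calendar(rec), rec)
        assert [e.pt_type for e in eps] == ["ST", "IA"]


class TestClassifyUse:
    def test_fallback_method_month_before_start(self):
        rec = make_record(CAL)
        series = parse_calendar(rec)
        eps = extract_episodes(series, rec)
        assert classify_use(eps[0], series) is True  # '3' at 1187

    def test_fallback_no_method_month_before_start(self):
        rec = make_record("0000BPPPPPPPP00000000000")
        series = parse_calendar(rec)
        eps = extract_episodes(series, rec)
        assert classify_use(eps[0], series) is False

    def test_cal2_code_wins_over_bare_cal1(self):
        # '1' in cal2 at the final use month although cal1 shows '0' before
        rec = make_record("0000BPPPPPPPP00000000000",
                          cal2="            1           ")
        series = parse_calendar(rec)
        eps = extract_episodes(series, rec)
        assert series.cal2_at(1188) == "1"
        assert classify_use(eps[0], series) is True

    def test_code_from_preceding_pregnancy_outcome_month_not_inherited(self):
        # a one-month termination at 1189 carries the while-using code in
        # its own (outcome) month; the next conception at 1190 must not
        # pick it up
        rec = make_record("00BPPPPPPPPT333000000000",
                          cal2="           1            ")
        series = parse_calendar(rec)
        eps = extract_episodes(series, rec)
        by_start = {e.start_cmc: e for e in eps}
        assert classify_use(by_start[1189], series) is True
        assert classify_use(by_start[1190], series) is False

    def test_cal2_present_but_silent_means_not_using(self):
        rec = make_record(CAL, cal2=" " * 24)
        series = parse_calendar(rec)
        eps = extract_episodes(series, rec)
        # without cal2 the '3' fallback would say using; cal2 overrides
        assert classify_use(eps[0], series) is False


class TestClassifyUnion:
    def test_cal3_in_union_at_start_month(self):
        rec = make_record(CAL, cal3="NNNNNNNNNNNNXXXXXXXXXXXX")
        series = parse_calendar(rec)
        eps = extract_episodes(series, rec)
        assert series.cal3_at(1188) == "X"
        assert classify_union(eps[0], series, rec) is True

    def test_imputed_from_first_union_date(self):
        rec = make_record(CAL, first_union=1188 - 6)
        series = parse_calendar(rec)
        eps = extract_episodes(series, rec)
        assert classify_union(eps[0], series, rec) is True

    def test_never_in_union(self):
        rec = make_record(CAL)
        series = parse_calendar(rec)
        eps = extract_episodes(series, rec)
        assert classify_union(eps[0], series, rec) is False


class TestWindowAndAge:
    def one_episode(self, start, outcome="B", v008=1200, v011=900):
        gest = 9 if outcome == "B" else 3
        return tc.PregnancyEpisode(
            caseid="w", start_cmc=start, outcome_cmc=start + gest - 1,
            outcome=outcome, gestation_months=gest)

    def test_window_boundaries_inclusive(self):
        rec = make_record("0" * 60, v008=1200)
        for start, kept in ((1191, True), (1192, False),
                            (1155, True), (1154, False)):
            out = impute_age_and_filter([self.one_episode(start)], rec)
            assert bool(out) is kept, start

    def test_pt_age_anchor_is_start_plus_nine(self):
        rec = make_record("0" * 60, v008=1200, v011=900)
        ep = self.one_episode(1188, outcome="PT")
        out = impute_age_and_filter([ep], rec)
        assert out[0].imputed_age_at_birth_years == 24  # (1197-900)//12
        assert out[0].age_group == "20-24"

    def test_under_15_excluded(self):
        # B anchored at outcome: age (outcome - v011)//12 = 14
        rec = make_record("0" * 60, v008=1200, v011=1196 - 179)
        out = impute_age_and_filter([self.one_episode(1188)], rec)
        assert out == []

    def test_birth_outcomes_span_three_years_before_interview(self):
        rec = make_record("0" * 60, v008=1200, v011=900)
        outs = []
        for start in range(1155, 1192):
            kept = impute_age_and_filter([self.one_episode(start)], rec)
            outs.extend(e.outcome_cmc for e in kept)
        assert min(outs) == 1163 and max(outs) == 1199


@settings(max_examples=60, deadline=None)
@given(st.lists(st.sampled_from("00PPBT33"), min_size=20, max_size=60),
       st.integers(min_value=1100, max_value=1400))
def test_extraction_invariants_on_random_calendars(chars, v008):
    """Episodes from arbitrary calendars respect ordering, gestation and
    determinism invariants."""
    cal1 = "".join(chars)
    rec = make_record(cal1, v008=v008, v011=v008 - 400)
    series = parse_calendar(rec)
    eps1 = extract_episodes(series, rec)
    eps2 = extract_episodes(series, rec)
    assert eps1 == eps2
    for ep in eps1:
        assert ep.start_cmc <= ep.outcome_cmc
        assert 1 <= ep.gestation_months <= 9
        assert ep.gestation_months == ep.outcome_cmc - ep.start_cmc + 1
        assert series.cal1_at(ep.outcome_cmc) in "BT"
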