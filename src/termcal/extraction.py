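"""Pregnancy-episode extraction from reproductive calendar strings.

A respondent's record carries up to three aligned monthly calendars:

* ``cal1`` — pregnancies ('P'), outcomes (birth 'B' / termination 'T') and
  contraceptive method codes;
* ``cal2`` — reason for discontinuing a method, in particular the
  "became pregnant while using" code;
* ``cal3`` — union status month by month.

This module parses those strings into a CMC-indexed month series, closes one
pregnancy episode per outcome month, classifies each episode by contraceptive
use and union status at the time of pregnancy, imputes age at birth, and
applies the selection window (by default pregnancies starting 45 to 9 months
before the interview, so that full-term births cover the three years before
the interview — the standard fertility-estimation window).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dialect import CANONICAL, CalendarDialect, age_group_of

logger = logging.getLogger(__name__)

#: Default selection window: pregnancy starts 45..9 months before interview.
DEFAULT_WINDOW = (45, 9)


class MalformedRecordError(ValueError):
    """Calendar string inconsistent with the record's date anchors."""


@dataclass
class WomanRecord:
    """One survey respondent with her calendar strings and date anchors."""

    caseid: str
    weight: float
    interview_cmc: int        # v008
    birth_cmc: int            # v011
    calendar_start_cmc: int   # v017
    first_union_cmc: int | None = None
    cal1: str | None = None
    cal2: str | None = None
    cal3: str | None = None
    reports_pt_type: bool = False
    pt_type_by_outcome: str | None = None
    survey: str | None = None

    def validate(self) -> None:
        if not (self.birth_cmc < self.calendar_start_cmc <= self.interview_cmc):
            raise MalformedRecordError(
                f"{self.caseid}: anchors must satisfy v011 < v017 <= v008"
            )
        if not self.weight > 0:
            raise MalformedRecordError(f"{self.caseid}: weight must be positive")


@dataclass
class MonthSeries:
    """Calendar codes indexed by CMC over the used span [v017, v008].

    Strings are normalized so that index ``i`` corresponds to CMC
    ``interview_cmc - i`` regardless of the dialect's orientation.  Pad
    positions read as ``None``.
    """

    interview_cmc: int
    start_cmc: int
    s1: str
    s2: str | None = None
    s3: str | None = None
    s_pt_type: str | None = None
    pad_char: str = " "

    def __len__(self) -> int:
        return self.interview_cmc - self.start_cmc + 1

    def _at(self, s: str | None, cmc: int) -> str | None:
        if s is None:
            return None
        if not self.start_cmc <= cmc <= self.interview_cmc:
            return None
        c = s[self.interview_cmc - cmc]
        return None if c == self.pad_char else c

    def cal1_at(self, cmc: int) -> str | None:
        return self._at(self.s1, cmc)

    def cal2_at(self, cmc: int) -> str | None:
        return self._at(self.s2, cmc)

    def cal3_at(self, cmc: int) -> str | None:
        return self._at(self.s3, cmc)

    def pt_type_at(self, cmc: int) -> str | None:
        return self._at(self.s_pt_type, cmc)

    @property
    def has_cal2(self) -> bool:
        return self.s2 is not None

    @property
    def has_cal3(self) -> bool:
        return self.s3 is not None

    def is_empty(self) -> bool:
        return all(c == self.pad_char for c in self.s1)


@dataclass
class PregnancyEpisode:
    """One extracted pregnancy with its classification fields."""

    caseid: str
    start_cmc: int
    outcome_cmc: int
    outcome: str                     # "B" or "PT"
    gestation_months: int
    pt_type: str | None = None       # "IA" / "ST" / None (unknown or birth)
    use_at_pregnancy: bool | None = None
    union_at_pregnancy: bool | None = None
    imputed_age_at_birth_years: int | None = None
    age_group: str | None = None
    weight: float = 1.0
    survey: str | None = None


def _normalize(s: str, used: int, dialect: CalendarDialect, name: str,
               caseid: str) -> str:
    """Return the string oriented interview-first and cut to the used span."""
    if not dialect.left_is_interview:
        s = s[::-1]
    if len(s) < used:
        raise MalformedRecordError(
            f"{caseid}: {name} length {len(s)} shorter than span {used}"
        )
    extra = s[used:]
    if extra and extra.strip(dialect.pad_char):
        raise MalformedRecordError(
            f"{caseid}: {name} has non-pad codes beyond the calendar span"
        )
    return s[:used]


def parse_calendar(record: WomanRecord,
                   dialect: CalendarDialect = CANONICAL) -> MonthSeries:
    """Map calendar positions to CMCs under the dialect's orientation."""
    record.validate()
    if record.cal1 is None:
        raise MalformedRecordError(f"{record.caseid}: cal1 is required")
    used = record.interview_cmc - record.calendar_start_cmc + 1

    def norm(s: str | None, name: str) -> str | None:
        if s is None or s == "":
            return None
        return _normalize(s, used, dialect, name, record.caseid)

    return MonthSeries(
        interview_cmc=record.interview_cmc,
        start_cmc=record.calendar_start_cmc,
        s1=norm(record.cal1, "cal1"),
        s2=norm(record.cal2, "cal2"),
        s3=norm(record.cal3, "cal3"),
        s_pt_type=norm(record.pt_type_by_outcome, "pt_type_by_outcome"),
        pad_char=dialect.pad_char,
    )


def extract_episodes(series: MonthSeries, record: WomanRecord,
                     dialect: CalendarDialect = CANONICAL,
                     ) -> list[PregnancyEpisode]:
    """Close one episode per outcome month in ``cal1``.

    The episode start is the first month of the contiguous 'P' run
    immediately preceding the outcome (or the outcome month itself when there
    is none).  A trailing 'P' run with no outcome is an ongoing pregnancy and
    yields no episode.  Runs touching the calendar start cannot be dated
    (possible left truncation) and are excluded.  A 'P' run longer than eight
    months before its outcome is capped at a nine-month gestation with the
    start adjusted.
    """
    episodes: list[PregnancyEpisode] = []
    for m in range(series.start_cmc, series.interview_cmc + 1):
        c = series.cal1_at(m)
        if c is None or not dialect.is_outcome(c):
            continue
        start = m
        while (start - 1 >= series.start_cmc
               and series.cal1_at(start - 1) == dialect.pregnancy_code):
            start -= 1
        if start == series.start_cmc and start != m:
            # run touches the calendar start: possibly left-truncated
            logger.warning("%s: undatable episode at calendar start dropped",
                           record.caseid)
            continue
        gestation = m - start + 1
        if gestation > 9:
            logger.warning("%s: pregnancy run of %d months capped at 9",
                           record.caseid, gestation)
            start = m - 8
            gestation = 9
        outcome = "B" if c == dialect.birth_code else "PT"
        pt_type = None
        if outcome == "PT" and record.reports_pt_type:
            label = series.pt_type_at(m)
            if label == dialect.ia_code:
                pt_type = "IA"
            elif label == dialect.st_code:
                pt_type = "ST"
        episodes.append(PregnancyEpisode(
            caseid=record.caseid, start_cmc=start, outcome_cmc=m,
            outcome=outcome, gestation_months=gestation, pt_type=pt_type,
            weight=record.weight, survey=record.survey,
        ))
    return episodes


def classify_use(episode: PregnancyEpisode, series: MonthSeries,
                 dialect: CalendarDialect = CANONICAL) -> bool:
    """Contraceptive use at the time of pregnancy.

    When cal2 is available it identifies use at pregnancy perfectly: the
    "became pregnant while using" code is looked for at the pregnancy start
    month and the month before (the last month of use under either placement
    convention).  The month before only counts when it is not itself a
    pregnancy or outcome month — a code there belongs to the preceding
    pregnancy, not this one.  Without cal2, a pregnancy is assumed to have
    occurred while using when any method code occupies the month preceding
    the start.  Any method counts — use of any method signals a desire to
    avoid pregnancy.
    """
    if series.has_cal2:
        code = dialect.pregnant_while_using_code
        if series.cal2_at(episode.start_cmc) == code:
            return True
        prev = episode.start_cmc - 1
        c1 = series.cal1_at(prev)
        return (series.cal2_at(prev) == code
                and not (c1 is not None and (dialect.is_outcome(c1)
                                             or c1 == dialect.pregnancy_code)))
    if episode.start_cmc - 1 < series.start_cmc:
        logger.warning("%s: no pre-pregnancy month in calendar; "
                       "classified not using", episode.caseid)
        return False
    c = series.cal1_at(episode.start_cmc - 1)
    return c is not None and dialect.is_method(c)


def classify_union(episode: PregnancyEpisode, series: MonthSeries,
                   record: WomanRecord,
                   dialect: CalendarDialect = CANONICAL) -> bool:
    """Union status at the time of pregnancy.

    cal3, when present, is read at the start month; otherwise union status is
    imputed from the date of first union (in union from that month onward).
    Married women and those in consensual unions both count as in-union.
    """
    if series.has_cal3:
        return series.cal3_at(episode.start_cmc) == dialect.in_union_code
    if record.first_union_cmc is None:
        return False
    return episode.start_cmc >= record.first_union_cmc


def imputed_age_at_birth(episode: PregnancyEpisode, birth_cmc: int) -> int:
    """Completed years at the (actual or projected) birth month.

    The anchor is the outcome month for births and the start month plus nine
    months for terminated pregnancies, so that age groups are comparable
    across outcomes.
    """
    anchor = (episode.outcome_cmc if episode.outcome == "B"
              else episode.start_cmc + 9)
    return math.floor((anchor - birth_cmc) / 12)


def impute_age_and_filter(episodes: list[PregnancyEpisode],
                          record: WomanRecord,
                          window: tuple[int, int] = DEFAULT_WINDOW,
                          ) -> list[PregnancyEpisode]:
    """Apply the selection window and the under-15 exclusion.

    Keeps episodes whose start lies in the closed interval
    ``[v008 - window[0], v008 - window[1]]`` and whose imputed age at birth
    is at least 15, and assigns the five-year age group (40-49 pooled).
    """
    lo = record.interview_cmc - window[0]
    hi = record.interview_cmc - window[1]
    kept = []
    for ep in episodes:
        if not lo <= ep.start_cmc <= hi:
            continue
        age = imputed_age_at_birth(ep, record.birth_cmc)
        group = age_group_of(age)
        if group is None:
            continue
        ep.imputed_age_at_birth_years = age
        ep.age_group = group
        kept.append(ep)
    return kept


def episodes_for_record(record: WomanRecord,
                        dialect: CalendarDialect = CANONICAL,
                        window: tuple[int, int] = DEFAULT_WINDOW,
                        ) -> list[PregnancyEpisode]:
    """Full per-record chain: parse, extract, classify, window-filter."""
    series = parse_calendar(record, dialect)
    episodes = extract_episodes(series, record, dialect)
    for ep in episodes:
        ep.use_at_pregnancy = classify_use(ep, series, dialect)
        ep.union_at_pregnancy = classify_union(ep, series, record, dialect)
    return impute_age_and_filter(episodes, record, window)


EPISODE_COLUMNS = [
    "survey", "caseid", "weight", "start_cmc", "outcome_cmc", "outcome",
    "pt_type", "gestation_months", "use_at_pregnancy", "union_at_pregnancy",
    "imputed_age", "age_group",
]


def record_from_row(row: pd.Series) -> WomanRecord:
    """Build a :class:`WomanRecord` from one interchange-CSV row."""
    fu = row.get("first_union_cmc")
    if fu is None or (isinstance(fu, float) and np.isnan(fu)) or fu is pd.NA:
        fu = None
    else:
        fu = int(fu)

    def s(name: str) -> str | None:
        v = row.get(name)
        if v is None or v is pd.NA or (isinstance(v, float) and np.isnan(v)):
            return None
        v = str(v)
        return v if v else None

    return WomanRecord(
        caseid=str(row["caseid"]), weight=float(row["weight"]),
        interview_cmc=int(row["v008"]), birth_cmc=int(row["v011"]),
        calendar_start_cmc=int(row["v017"]), first_union_cmc=fu,
        cal1=s("cal1"), cal2=s("cal2"), cal3=s("cal3"),
        reports_pt_type=bool(int(row.get("reports_pt_type", 0))),
        pt_type_by_outcome=s("pt_type_by_outcome"),
        survey=s("survey"),
    )


def extract_survey(women: pd.DataFrame,
                   dialect: CalendarDialect = CANONICAL,
                   window: tuple[int, int] = DEFAULT_WINDOW,
                   ) -> tuple[pd.DataFrame, dict]:
    """Extract classified, window-filtered episodes for a whole dataset.

    Returns the episodes table (one row per pregnancy) and a stats dict with
    counts of processed, malformed (skipped), and extracted records — the
    exclusion accounting a survey analyst expects to see reported.
    """
    rows = []
    stats = {"n_women": len(women), "n_malformed": 0, "n_episodes": 0}
    for _, r in women.iterrows():
        try:
            record = record_from_row(r)
            eps = episodes_for_record(record, dialect, window)
        except MalformedRecordError as exc:
            logger.warning("skipping malformed record: %s", exc)
            stats["n_malformed"] += 1
            continue
        for ep in eps:
            rows.append((ep.survey, ep.caseid, ep.weight, ep.start_cmc,
                         ep.outcome_cmc, ep.outcome, ep.pt_type,
                         ep.gestation_months, ep.use_at_pregnancy,
                         ep.union_at_pregnancy,
                         ep.imputed_age_at_birth_years, ep.age_group))
    out = pd.DataFrame(rows, columns=EPISODE_COLUMNS)
    stats["n_episodes"] = len(out)
    return out, stats
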