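"""Calendar dialect: code maps, string orientation, CMC and age-group helpers.

DHS reproductive calendars are fixed-width strings with one character per
month.  Code sets and orientation vary across survey phases, so every parsing
routine takes a :class:`CalendarDialect` describing the convention in use.
The canonical dialect here places the interview month in the leftmost used
position, with time running right-to-left (oldest month rightmost) and
pre-calendar positions padded.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Standard five-year age groups with 40-49 pooled (few pregnancies past 40).
AGE_GROUPS = ("15-19", "20-24", "25-29", "30-34", "35-39", "40-49")

#: Coarse age bands used for women not in union when building survey profiles.
REGROUPED_AGE_BANDS = ("15-24", "25-49")

#: Width in years of each age band, used when cumulating age-specific rates.
AGE_BAND_WIDTHS = {
    "15-19": 5, "20-24": 5, "25-29": 5, "30-34": 5, "35-39": 5, "40-49": 10,
}


def cmc(year: int, month: int) -> int:
    """Century-month code: months since January 1900 (Jan 1900 = 1)."""
    return (year - 1900) * 12 + month


def cmc_to_year_month(code: int) -> tuple[int, int]:
    return 1900 + (code - 1) // 12, (code - 1) % 12 + 1


def age_group_of(age_years: int) -> str | None:
    """Map a completed age in years to its group; ``None`` below 15."""
    if age_years < 15:
        return None
    if age_years >= 40:
        return "40-49"
    lo = 15 + 5 * ((age_years - 15) // 5)
    return f"{lo}-{lo + 4}"


def regrouped_band_of(age_years: int) -> str | None:
    if age_years < 15:
        return None
    return "15-24" if age_years < 25 else "25-49"


@dataclass(frozen=True)
class CalendarDialect:
    """Code maps and orientation for one survey's calendar strings.

    ``left_is_interview`` selects the canonical orientation (interview month
    leftmost, oldest month rightmost); when false, the string is read
    mirrored, i.e. the interview month sits at the rightmost used position.
    """

    birth_code: str = "B"
    termination_code: str = "T"
    pregnancy_code: str = "P"
    no_method_code: str = "0"
    pad_char: str = " "
    pregnant_while_using_code: str = "1"  # cal2
    in_union_code: str = "X"              # cal3
    not_in_union_code: str = "N"
    ia_code: str = "I"                    # pt_type_by_outcome
    st_code: str = "S"
    left_is_interview: bool = True

    def is_outcome(self, c: str) -> bool:
        return c in (self.birth_code, self.termination_code)

    def is_method(self, c: str) -> bool:
        """True for any contraceptive-method code.

        Anything alphanumeric that is not the no-method code or a pregnancy
        state counts as a method; DHS phases use varying digit/letter sets.
        """
        return (
            c.isalnum()
            and c not in (self.no_method_code, self.birth_code,
                          self.termination_code, self.pregnancy_code)
        )


CANONICAL = CalendarDialect()
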