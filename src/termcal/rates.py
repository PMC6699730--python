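"""Termination and pregnancy rates derived from conditional probabilities.

A termination probability ``T`` describes what happens once a pregnancy
exists; rates describe how likely a woman is to experience a termination in
a year.  Because the pregnancy selection window matches the standard
three-year fertility-estimation window and age is the imputed age at birth,
``T`` composes exactly with reported fertility rates:

    ASTR_a = T_a / (1 - T_a) * ASFR_a        (terminations per woman-year)
    GTR    = T / (1 - T) * GFR
    TTR    = sum_a width_a * ASTR_a          (expected lifetime terminations)
    TPR    = TFR + TTR                       (expected lifetime pregnancies)

The odds factor ``T/(1-T)`` converts births per woman-year into
terminations per woman-year, since ``PT_a/N_a = (PT_a/B_a) * (B_a/N_a)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .dialect import AGE_BAND_WIDTHS, AGE_GROUPS


class UndefinedRateError(ValueError):
    """T = 1 leaves no births to anchor the rate conversion."""


#: Literal five-year aggregation weights (alternative convention where the
#: pooled 40-49 band still counts five years).
LITERAL_FIVE_WIDTHS = {a: 5 for a in AGE_GROUPS}


@dataclass
class FertilityInputs:
    """Per-subpopulation fertility table.

    ``asfr`` maps age group to births per woman-year; ``gfr`` is carried
    with an explicit unit flag (births per 1000 women per year, the usual
    reporting unit, or per woman-year) to avoid silent thousand-fold
    errors.  Optional exposure (woman-years) and birth counts allow
    consistency checks against ``asfr = births / exposure``.
    """

    subpop: str
    asfr: dict
    gfr: float
    tfr: float
    gfr_per_1000: bool = True
    exposure: dict | None = None
    births: dict | None = None

    def validate(self, rtol: float = 1e-6) -> None:
        if any(v < 0 for v in self.asfr.values()) or self.gfr < 0 or self.tfr < 0:
            raise ValueError("fertility inputs must be nonnegative")
        if self.exposure is not None and self.births is not None:
            for a, n in self.exposure.items():
                if n > 0:
                    implied = self.births.get(a, 0.0) / n
                    if abs(implied - self.asfr[a]) > rtol * max(1.0, implied):
                        raise ValueError(
                            f"asfr[{a}] inconsistent with births/exposure")


@dataclass
class RateResults:
    subpop: str
    astr: dict
    gtr: float
    ttr: float
    tpr: float
    band_widths: dict = field(default_factory=lambda: dict(AGE_BAND_WIDTHS))
    gtr_per_1000: bool = True


def astr_from_T(T_a: float, asfr_a: float) -> float:
    """Age-specific termination rate from ``T`` and the matching ASFR."""
    if not 0 <= T_a <= 1:
        raise ValueError("T must lie in [0, 1]")
    if T_a == 1:
        raise UndefinedRateError(
            "T = 1: no births in the stratum, rate conversion undefined")
    return T_a / (1.0 - T_a) * asfr_a


def gtr_from_T(T: float, gfr: float) -> float:
    """General termination rate from the all-pregnancy ``T`` and the GFR."""
    return astr_from_T(T, gfr)


def ttr(astr: dict, band_widths: dict | None = None) -> float:
    """Total termination rate: ASTRs cumulated over the reproductive span.

    Default band widths are 5 years for each five-year group and 10 for the
    pooled 40-49 band, preserving the synthetic-cohort interpretation (and
    the ``TPR = TFR + TTR`` identity when the TFR uses standard bands); pass
    :data:`LITERAL_FIVE_WIDTHS` for the uniform-five convention.
    """
    widths = dict(AGE_BAND_WIDTHS) if band_widths is None else band_widths
    missing = set(widths) - set(astr)
    if missing:
        raise ValueError(f"missing ASTR for age bands: {sorted(missing)}")
    return float(sum(widths[a] * astr[a] for a in widths))


def tpr(tfr: float, ttr_value: float) -> float:
    """Total pregnancy rate: expected lifetime pregnancies = TFR + TTR."""
    return tfr + ttr_value


def rates_from_estimates(age_estimates: pd.DataFrame, overall_T: float,
                         fertility: FertilityInputs,
                         band_widths: dict | None = None) -> RateResults:
    """Derive the full rate set from age-specific and overall ``T``.

    ``age_estimates`` must carry one row per age group with columns
    ``age_group`` and ``T`` for the relevant subpopulation.
    """
    fertility.validate()
    t_by_age = dict(zip(age_estimates["age_group"], age_estimates["T"]))
    widths = dict(AGE_BAND_WIDTHS) if band_widths is None else band_widths
    astr = {a: astr_from_T(t_by_age[a], fertility.asfr[a]) for a in widths
            if a in t_by_age and a in fertility.asfr}
    if set(astr) != set(widths):
        raise ValueError(
            f"missing T or ASFR for age bands: {sorted(set(widths) - set(astr))}")
    ttr_value = ttr(astr, widths)
    return RateResults(
        subpop=fertility.subpop, astr=astr,
        gtr=gtr_from_T(overall_T, fertility.gfr),
        ttr=ttr_value, tpr=tpr(fertility.tfr, ttr_value),
        band_widths=widths, gtr_per_1000=fertility.gfr_per_1000,
    )


def fertility_from_truth(truth, subpop: str | None = None,
                         weighted: bool = True) -> FertilityInputs:
    """Fertility inputs computed from a simulated survey's ground truth.

    Births are in-window planted episodes by imputed age group; exposure is
    realized woman-months over the 36 months before the interview converted
    to woman-years.  Using the same episodes and weights on both sides makes
    the rate identities exact rather than approximate.
    """
    eps = truth.episodes
    eps = eps[eps["in_window"]]
    wcol = eps["weight"] if weighted else 1.0
    exposure_m = (truth.exposure_months if weighted
                  else truth.exposure_months_unweighted)
    births, asfr, exposure = {}, {}, {}
    for a in AGE_GROUPS:
        sel = (eps["age_group"] == a) & (eps["outcome"] == "B")
        b = float((eps.loc[sel, "weight"] if weighted else sel).sum())
        n_years = exposure_m[a] / 12.0
        births[a] = b
        exposure[a] = n_years
        asfr[a] = b / n_years if n_years > 0 else 0.0
    tfr_value = sum(AGE_BAND_WIDTHS[a] * asfr[a] for a in AGE_GROUPS)
    total_b = sum(births.values())
    total_years = sum(exposure.values())
    return FertilityInputs(
        subpop=subpop or truth.survey_id, asfr=asfr,
        gfr=total_b / total_years if total_years else 0.0,
        tfr=tfr_value, gfr_per_1000=False,
        exposure=exposure, births=births,
    )
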