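"""Synthetic DHS-style calendar surveys with known ground truth.

Restricted microdata cannot ship with the package, so every downstream stage
is exercised against simulated surveys.  The generator runs a month-by-month
history per woman from the calendar start to the interview: union entry,
contraceptive adoption and discontinuation, conception, gestation and
outcome.  Each conceived pregnancy ends in a termination with a per-stratum
probability (``true_T``) and, when the survey reports the type of
termination, is labelled induced with probability ``true_IA_share``.  The
emitted cal1/cal2/cal3 strings encode the same history in the configured
calendar dialect, and a :class:`TruthBundle` retains every planted episode
with its classification so recovery can be checked cell by cell.

Defaults encode the stratum-level conditions observed in large pooled DHS
analyses: termination probabilities around 9-20% rising with age, roughly
twice as high after contraceptive failure, slightly higher out of union, and
an induced share of terminations that grows logistically with the stratum's
termination probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dialect import AGE_GROUPS, CANONICAL, CalendarDialect
from .clustering import FEATURE_COLUMNS
from .dialect import age_group_of

__all__ = [
    "SimulationConfig", "TruthBundle", "simulate_survey", "simulate_many",
    "write_interchange", "read_interchange", "write_truth", "read_truth",
    "default_true_T", "default_ia_share", "default_conception_hazard",
    "scaled_true_T",
    "planted_profiles", "profile_archetypes",
]


class ConfigurationError(ValueError):
    """A simulation parameter violates its invariants."""


#: Conditional termination probability for in-union non-users by age group;
#: minimum at 20-24 and maximum in the pooled 40-49 band, the age profile
#: typical of pooled DHS estimates.
_BASE_T = {"15-19": 0.110, "20-24": 0.093, "25-29": 0.100,
           "30-34": 0.120, "35-39": 0.150, "40-49": 0.204}
_USE_T_MULT = 2.1        # users vs non-users (~21% vs ~10% overall)
_NOT_IN_UNION_T_MULT = 1.15

#: Monthly conception hazard for in-union non-users by age group.
_BASE_HAZARD = {"15-19": 0.020, "20-24": 0.022, "25-29": 0.019,
                "30-34": 0.014, "35-39": 0.009, "40-49": 0.003}
_USE_HAZARD_MULT = 0.2   # contraceptive failure ≈ 5%/yr at peak ages
_NOT_IN_UNION_HAZARD_MULT = 0.15

#: Gestation distribution for terminated pregnancies (months 1..9): most
#: losses occur in the first trimester.
_PT_GESTATION_PROBS = (0.05, 0.15, 0.25, 0.20, 0.12, 0.08, 0.06, 0.05, 0.04)

#: Default split coefficients used to plant the induced share of
#: terminations: share = expit(b0 + b1 * T).
_IA_SHARE_COEFS = (-1.632, 6.733)


def default_true_T() -> dict:
    """Per-stratum termination probabilities: (age_group, union, use) -> T."""
    out = {}
    for a in AGE_GROUPS:
        for union in (False, True):
            for use in (False, True):
                t = _BASE_T[a]
                if use:
                    t *= _USE_T_MULT
                if not union:
                    t *= _NOT_IN_UNION_T_MULT
                out[(a, union, use)] = min(t, 0.95)
    return out


def scaled_true_T(scale: float) -> dict:
    """Default stratum probabilities scaled by a survey-level factor.

    Multi-survey studies use factors roughly between 0.4 and 2.2 to emulate
    the observed spread of survey-level termination probabilities, from
    low-reporting settings (overall T near 5%) to very high ones (near
    30%), around the default mid-level profile.  Values are capped at 0.95.
    """
    return {k: min(v * scale, 0.95) for k, v in default_true_T().items()}


def default_ia_share(true_T: dict | float | None = None) -> dict:
    """Induced share of terminations per stratum, logistic in the stratum T."""
    tt = default_true_T() if true_T is None else true_T
    b0, b1 = _IA_SHARE_COEFS
    out = {}
    for a in AGE_GROUPS:
        for union in (False, True):
            for use in (False, True):
                t = _lookup(tt, a, union, use)
                out[(a, union, use)] = float(1.0 / (1.0 + np.exp(-(b0 + b1 * t))))
    return out


def default_conception_hazard() -> dict:
    out = {}
    for a in AGE_GROUPS:
        for union in (False, True):
            for use in (False, True):
                h = _BASE_HAZARD[a]
                if use:
                    h *= _USE_HAZARD_MULT
                if not union:
                    h *= _NOT_IN_UNION_HAZARD_MULT
                out[(a, union, use)] = h
    return out


def _lookup(spec, age_group: str, union: bool, use: bool) -> float:
    """Resolve a stratum-level parameter given flexibly-keyed input.

    Accepts a scalar, a dict keyed by ``(age_group, union, use)``,
    ``(age_group, use)``, ``(union, use)``, ``use`` or ``age_group``.
    """
    if np.isscalar(spec):
        return float(spec)
    for key in ((age_group, union, use), (age_group, use), (union, use),
                use, age_group):
        if key in spec:
            return float(spec[key])
    raise ConfigurationError(
        f"no value for stratum ({age_group}, union={union}, use={use})"
    )


def _stratum_array(spec) -> np.ndarray:
    """Resolve a stratum map to a (6, 2, 2) array [age, union, use]."""
    arr = np.empty((len(AGE_GROUPS), 2, 2))
    for i, a in enumerate(AGE_GROUPS):
        for j, union in enumerate((False, True)):
            for k, use in enumerate((False, True)):
                arr[i, j, k] = _lookup(spec, a, union, use)
    return arr


@dataclass
class SimulationConfig:
    """All knobs of one simulated survey.

    Stratum-valued parameters (``monthly_conception_hazard``, ``true_T``,
    ``true_IA_share``) may be scalars, use-keyed dicts, or full
    ``(age_group, union, use)`` maps.
    """

    n_women: int = 5000
    interview_cmc: int = 1440          # December 2019
    calendar_length: int = 80
    age_distribution: dict = field(default_factory=lambda: {
        "15-19": 0.20, "20-24": 0.18, "25-29": 0.17,
        "30-34": 0.16, "35-39": 0.15, "40-49": 0.14})
    monthly_conception_hazard: object = field(
        default_factory=default_conception_hazard)
    method_adoption_rate: float = 0.03
    method_discontinuation_rate: float = 0.015
    union_entry_rate: float = 0.007
    true_T: object = field(default_factory=default_true_T)
    true_IA_share: object = field(default_factory=default_ia_share)
    pt_gestation_probs: tuple = _PT_GESTATION_PROBS
    weight_sigma: float = 0.25
    report_type_of_PT: bool = False
    method_codes: tuple = ("1", "2", "3")
    survey_id: str = "SYN1"
    seed: int = 0
    dialect: CalendarDialect = CANONICAL

    def validate(self) -> None:
        if self.n_women < 1:
            raise ConfigurationError("n_women must be positive")
        if self.calendar_length < 46:
            raise ConfigurationError(
                "calendar_length must be >= 46 so the 45..9-month "
                "estimation window fits")
        probs = np.array(list(self.age_distribution.values()), dtype=float)
        if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
            raise ConfigurationError("age_distribution must be a simplex")
        for name, spec in (("monthly_conception_hazard",
                            self.monthly_conception_hazard),
                           ("true_T", self.true_T),
                           ("true_IA_share", self.true_IA_share)):
            arr = _stratum_array(spec)
            if (arr < 0).any() or (arr > 1).any():
                raise ConfigurationError(f"{name} values must lie in [0, 1]")
        for name, v in (("method_adoption_rate", self.method_adoption_rate),
                        ("method_discontinuation_rate",
                         self.method_discontinuation_rate),
                        ("union_entry_rate", self.union_entry_rate)):
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        g = np.array(self.pt_gestation_probs, dtype=float)
        if len(g) != 9 or (g < 0).any() or not np.isclose(g.sum(), 1.0):
            raise ConfigurationError(
                "pt_gestation_probs must be 9 probabilities summing to 1")


@dataclass
class TruthBundle:
    """Ground truth of one simulated survey.

    ``episodes`` lists every completed planted pregnancy with the same
    classification fields the extraction stage produces, plus ``in_window``
    (start inside the selection window and imputed age >= 15).  ``exposure``
    holds realized woman-months by current age group over the 36 months
    before the interview, weighted and unweighted, for rate oracles.
    """

    survey_id: str
    episodes: pd.DataFrame
    true_T: dict
    true_IA_share: dict
    exposure_months: dict
    exposure_months_unweighted: dict
    n_ongoing: int


def simulate_survey(config: SimulationConfig
                    ) -> tuple[pd.DataFrame, TruthBundle]:
    """Run the monthly simulation and emit interchange records plus truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    d = config.dialect
    n = config.n_women
    v008 = config.interview_cmc
    L = config.calendar_length
    v017 = v008 - L + 1

    hazard = _stratum_array(config.monthly_conception_hazard)
    true_T = _stratum_array(config.true_T)
    ia_share = _stratum_array(config.true_IA_share)

    # ages 15-49 at interview, drawn by group then uniformly within it
    group_names = list(config.age_distribution)
    probs = np.array([config.age_distribution[g] for g in group_names])
    gidx_iv = rng.choice(len(group_names), size=n, p=probs)
    lo = np.array([int(g.split("-")[0]) for g in group_names])
    hi = np.array([int(g.split("-")[1]) for g in group_names])
    span = hi - lo + 1
    age_years_iv = lo[gidx_iv] + (rng.random(n) * span[gidx_iv]).astype(int)
    age_months_iv = age_years_iv * 12 + rng.integers(0, 12, size=n)
    birth_cmc = v008 - age_months_iv

    # first union: constant monthly hazard from the 15th birthday
    if config.union_entry_rate > 0:
        wait = rng.geometric(config.union_entry_rate, size=n)
    else:
        wait = np.full(n, np.iinfo(np.int64).max // 2)
    first_union = birth_cmc + 180 + wait - 1

    weight = rng.lognormal(0.0, config.weight_sigma, size=n)
    weight = weight / weight.mean()

    cal1 = np.full((n, L), d.pad_char, dtype="<U1")
    cal2 = np.full((n, L), d.pad_char, dtype="<U1")
    cal3 = np.full((n, L), d.pad_char, dtype="<U1")
    ptt = np.full((n, L), d.pad_char, dtype="<U1")

    using = np.zeros(n, dtype=bool)
    method = np.array(rng.choice(config.method_codes, size=n), dtype="<U1")
    preg_left = np.zeros(n, dtype=np.int64)
    outcome_char = np.full(n, "", dtype="<U1")
    outcome_label = np.full(n, "", dtype="<U1")

    ep_case, ep_start, ep_out_cmc, ep_outcome = [], [], [], []
    ep_use, ep_union, ep_pt_type, ep_widx = [], [], [], []
    n_ongoing = 0

    gest_vals = np.arange(1, 10)
    exp_w = np.zeros(len(AGE_GROUPS))
    exp_u = np.zeros(len(AGE_GROUPS))

    for m in range(v017, v008 + 1):
        j = m - v017
        age_months = m - birth_cmc
        age_years = age_months // 12
        adult = (age_years >= 15) & (age_years <= 49)
        gidx = np.clip((age_years - 15) // 5, 0, 5)
        in_union = first_union <= m
        cal3[:, j] = np.where(in_union, d.in_union_code, d.not_in_union_code)

        # exposure over the 36 months before the interview, by current age
        if v008 - 36 <= m <= v008 - 1:
            np.add.at(exp_w, gidx[adult], weight[adult])
            np.add.at(exp_u, gidx[adult], 1.0)

        pregnant = preg_left > 0
        ongoing = pregnant & (preg_left > 1)
        delivering = pregnant & (preg_left == 1)
        cal1[ongoing, j] = d.pregnancy_code
        cal1[delivering, j] = outcome_char[delivering]
        lab = delivering & (outcome_label != "")
        ptt[lab, j] = outcome_label[lab]
        preg_left[pregnant] -= 1

        idle = ~pregnant
        h = hazard[gidx, in_union.astype(int), using.astype(int)]
        h[~adult] = 0.0
        conceive = idle & (rng.random(n) < h)
        if j == 0:
            # the first calendar month only sets up state; a conception here
            # could not be dated from the emitted string
            conceive[:] = False

        if conceive.any():
            idxc = np.flatnonzero(conceive)
            gi = gidx[idxc]
            un = in_union[idxc].astype(int)
            us = using[idxc].astype(int)
            is_pt = rng.random(idxc.size) < true_T[gi, un, us]
            gest = np.full(idxc.size, 9, dtype=np.int64)
            n_pt = int(is_pt.sum())
            if n_pt:
                gest[is_pt] = rng.choice(
                    gest_vals, size=n_pt, p=config.pt_gestation_probs)
            out_cmc = m + gest - 1
            completed = out_cmc <= v008
            n_ongoing += int((~completed).sum())

            labels = np.full(idxc.size, "", dtype="<U1")
            if config.report_type_of_PT and n_pt:
                is_ia = rng.random(idxc.size) < ia_share[gi, un, us]
                labels[is_pt & is_ia] = d.ia_code
                labels[is_pt & ~is_ia] = d.st_code

            ep_widx.extend(idxc[completed].tolist())
            ep_case.extend(idxc[completed].tolist())
            ep_start.extend([m] * int(completed.sum()))
            ep_out_cmc.extend(out_cmc[completed].tolist())
            ep_outcome.extend(np.where(is_pt, "PT", "B")[completed].tolist())
            ep_use.extend(using[idxc][completed].tolist())
            ep_union.extend(in_union[idxc][completed].tolist())
            ep_pt_type.extend(labels[completed].tolist())

            oc = np.where(is_pt, d.termination_code, d.birth_code)
            one_month = gest == 1
            cal1[idxc[one_month], j] = oc[one_month]
            cal1[idxc[~one_month], j] = d.pregnancy_code
            if config.report_type_of_PT:
                lbl1 = one_month & (labels != "")
                ptt[idxc[lbl1], j] = labels[lbl1]
            outcome_char[idxc] = oc
            outcome_label[idxc] = labels
            preg_left[idxc] = gest - 1
            # cal2: became pregnant while using, in the conception month
            used = idxc[using[idxc]]
            cal2[used, j] = d.pregnant_while_using_code
            using[idxc] = False

        # months with neither pregnancy nor conception show the method state
        plain = idle & ~conceive
        cal1[plain & using, j] = method[plain & using]
        cal1[plain & ~using, j] = d.no_method_code

        # end-of-month transitions (this month is the last month of use for
        # a voluntary discontinuation, hence the cal2 reason code here)
        stop = plain & using & (rng.random(n) < config.method_discontinuation_rate)
        cal2[stop, j] = "9"
        using[stop] = False
        can_adopt = adult & ~using & (preg_left == 0) & ~conceive
        adopt = can_adopt & (rng.random(n) < config.method_adoption_rate)
        if adopt.any():
            using[adopt] = True
            method[adopt] = rng.choice(config.method_codes,
                                       size=int(adopt.sum()))

    caseids = np.array([f"{config.survey_id}-{i:06d}" for i in range(n)])

    def strings(arr: np.ndarray) -> list[str]:
        return ["".join(row) for row in arr[:, ::-1]]

    never = first_union > v008
    women = pd.DataFrame({
        "survey": config.survey_id,
        "caseid": caseids,
        "weight": weight,
        "v008": v008, "v011": birth_cmc, "v017": v017,
        "first_union_cmc": pd.array(
            np.where(never, 0, first_union), dtype="Int64"),
        "cal1": strings(cal1), "cal2": strings(cal2), "cal3": strings(cal3),
        "reports_pt_type": int(config.report_type_of_PT),
        "pt_type_by_outcome": (strings(ptt) if config.report_type_of_PT
                               else ""),
    })
    women.loc[never, "first_union_cmc"] = pd.NA

    truth_eps = pd.DataFrame({
        "survey": config.survey_id,
        "caseid": caseids[np.array(ep_widx, dtype=int)]
        if ep_widx else np.array([], dtype=str),
        "weight": weight[np.array(ep_widx, dtype=int)]
        if ep_widx else np.array([]),
        "start_cmc": np.array(ep_start, dtype=np.int64),
        "outcome_cmc": np.array(ep_out_cmc, dtype=np.int64),
        "outcome": np.array(ep_outcome, dtype=object),
        "pt_type": [{"": None, d.ia_code: "IA", d.st_code: "ST"}[t]
                    for t in ep_pt_type],
        "use_at_pregnancy": np.array(ep_use, dtype=bool),
        "union_at_pregnancy": np.array(ep_union, dtype=bool),
    })
    if len(truth_eps):
        birth_of = birth_cmc[np.array(ep_widx, dtype=int)]
        anchor = np.where(truth_eps["outcome"] == "B",
                          truth_eps["outcome_cmc"],
                          truth_eps["start_cmc"] + 9)
        age = np.floor((anchor - birth_of) / 12).astype(int)
        truth_eps["imputed_age"] = age
        truth_eps["age_group"] = [age_group_of(a) for a in age]
        truth_eps["gestation_months"] = (truth_eps["outcome_cmc"]
                                         - truth_eps["start_cmc"] + 1)
        truth_eps["in_window"] = (
            (truth_eps["start_cmc"] >= v008 - 45)
            & (truth_eps["start_cmc"] <= v008 - 9)
            & (age >= 15))
    else:
        for c in ("imputed_age", "age_group", "gestation_months",
                  "in_window"):
            truth_eps[c] = []

    truth = TruthBundle(
        survey_id=config.survey_id,
        episodes=truth_eps,
        true_T={(a, bool(un), bool(us)): float(true_T[i, un, us])
                for i, a in enumerate(AGE_GROUPS)
                for un in (0, 1) for us in (0, 1)},
        true_IA_share={(a, bool(un), bool(us)): float(ia_share[i, un, us])
                       for i, a in enumerate(AGE_GROUPS)
                       for un in (0, 1) for us in (0, 1)},
        exposure_months={a: float(exp_w[i])
                         for i, a in enumerate(AGE_GROUPS)},
        exposure_months_unweighted={a: float(exp_u[i])
                                    for i, a in enumerate(AGE_GROUPS)},
        n_ongoing=n_ongoing,
    )
    return women, truth


def simulate_many(configs: list[SimulationConfig]
                  ) -> tuple[pd.DataFrame, list[TruthBundle]]:
    """Simulate several surveys and stack their interchange tables."""
    frames, truths = [], []
    for cfg in configs:
        w, t = simulate_survey(cfg)
        frames.append(w)
        truths.append(t)
    return pd.concat(frames, ignore_index=True), truths


# ---------------------------------------------------------------------------
# interchange CSV

_STR_COLS = ["cal1", "cal2", "cal3", "pt_type_by_outcome"]


def write_interchange(dataset: pd.DataFrame, path) -> None:
    """Write the flat interchange CSV (lossless round trip, pads preserved)."""
    if len(dataset) == 0:
        raise ValueError("refusing to write an empty dataset")
    dataset.to_csv(path, index=False)


def read_interchange(path) -> pd.DataFrame:
    """Read an interchange CSV, keeping calendar pads and empty strings."""
    df = pd.read_csv(
        path, dtype={c: str for c in _STR_COLS + ["caseid", "survey"]},
        keep_default_na=False, na_values=[],
    )
    for c in _STR_COLS:
        if c in df:
            df[c] = df[c].fillna("")
    df["first_union_cmc"] = pd.array(
        [pd.NA if v == "" else int(float(v))
         for v in df["first_union_cmc"].astype(str)], dtype="Int64")
    return df


def write_truth(truth: TruthBundle, path) -> None:
    truth.episodes.to_csv(path, index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"caseid": str, "survey": str})


# ---------------------------------------------------------------------------
# planted survey profiles for clustering studies

def profile_archetypes() -> pd.DataFrame:
    """Four archetypal 16-feature survey profiles, in increasing overall T.

    Archetype 1: uniformly low T, flat in age.  2: moderate T with a mild
    age gradient.  3: high T for women in union with a strong use
    differential but low T out of union.  4: very high T everywhere with a
    steep age gradient.
    """
    ages6 = np.array([1.0, 0.85, 0.9, 1.05, 1.25, 1.6])
    steep = np.array([0.7, 0.8, 1.0, 1.3, 1.7, 2.2])
    flat = np.ones(6)
    rows = []
    for level, use_mult, niu_mult, shape in (
            (0.045, 1.3, 1.1, flat),
            (0.10, 1.8, 1.1, ages6),
            (0.24, 2.4, 0.35, ages6),
            (0.38, 1.9, 0.9, steep)):
        row = []
        for use_m in (use_mult, 1.0):          # using first, then not using
            row.extend(np.clip(level * use_m * shape, 0.005, 0.95))
            niu = level * use_m * niu_mult
            row.extend(np.clip([niu * 0.9, niu * 1.1], 0.005, 0.95))
        rows.append(row)
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS,
                        index=[1, 2, 3, 4])


def planted_profiles(n_surveys: int = 40, noise_sd: float = 0.045,
                     missing_frac: float = 0.12, seed: int = 0,
                     archetypes: pd.DataFrame | None = None,
                     ) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw survey profiles around planted archetypes and mask cells.

    ``noise_sd`` approximates the sampling noise of a termination
    probability estimated from roughly 50-150 unweighted pregnancies per
    cell (binomial sd 0.03-0.06 for T between 0.1 and 0.4); cells are
    masked completely at random at the requested fraction.  Returns the
    feature matrix (NaN = missing) and the planted archetype labels.
    """
    rng = np.random.default_rng(seed)
    arch = profile_archetypes() if archetypes is None else archetypes
    k = len(arch)
    labels = np.repeat(np.arange(k), int(np.ceil(n_surveys / k)))[:n_surveys]
    rng.shuffle(labels)
    X = arch.to_numpy()[labels] + rng.normal(0, noise_sd,
                                             (n_surveys, len(arch.columns)))
    X = np.clip(X, 0.0, 1.0)
    mask = rng.random(X.shape) < missing_frac
    # keep at least one observed cell per survey
    full_rows = mask.all(axis=1)
    mask[full_rows, 0] = False
    X[mask] = np.nan
    idx = [f"S{i:03d}" for i in range(n_surveys)]
    return pd.DataFrame(X, columns=list(arch.columns), index=idx), \
        arch.index.to_numpy()[labels]
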