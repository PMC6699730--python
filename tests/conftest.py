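import pandas as pd
import pytest

import termcal as tc


@pytest.fixture(scope="session")
def recovery_survey():
    """A seeded 20,000-woman survey with use-keyed planted termination
    probabilities (0.08 non-users / 0.20 users) and reported PT types."""
    cfg = tc.SimulationConfig(
        n_women=20_000, seed=20,
        true_T={False: 0.08, True: 0.20},
        report_type_of_PT=True,
    )
    women, truth = tc.simulate_survey(cfg)
    episodes, stats = tc.extract_survey(women)
    return cfg, women, truth, episodes, stats


@pytest.fixture(scope="session")
def default_survey():
    """A mid-sized survey under the default (study-condition) parameters."""
    cfg = tc.SimulationConfig(n_women=6000, seed=7, report_type_of_PT=True)
    women, truth = tc.simulate_survey(cfg)
    episodes, _ = tc.extract_survey(women)
    return cfg, women, truth, episodes


def make_record(cal1, v008=1200, v017=None, v011=900, weight=1.0,
                cal2=None, cal3=None, first_union=None, caseid="w1",
                reports_pt_type=False, pt_types=None):
    """Hand-built record; v017 inferred from the string length by default."""
    if v017 is None:
        v017 = v008 - len(cal1) + 1
    return tc.WomanRecord(
        caseid=caseid, weight=weight, interview_cmc=v008, birth_cmc=v011,
        calendar_start_cmc=v017, first_union_cmc=first_union,
        cal1=cal1, cal2=cal2, cal3=cal3,
        reports_pt_type=reports_pt_type, pt_type_by_outcome=pt_types,
    )
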