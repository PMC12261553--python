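import pandas as pd
import pytest
from hypothesis import settings

from palliseq import ClaimsDataset, PathwaySequence, synthetic_reference_cohort

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def make_seq(pid, events, gaps=None):
    if gaps is None:
        gaps = (0,) * len(events)
    return PathwaySequence(pid, tuple(events), tuple(gaps))


@pytest.fixture(scope="session")
def reference_cohort():
    """Synthetic cohort with planted published marginal counts."""
    return synthetic_reference_cohort()


@pytest.fixture
def toy_claims():
    """Three individuals: ALS-only, ALS+cancer, non-ALS."""
    diagnoses = pd.DataFrame(
        [
            ("a", "G12.2", "outpatient", 200),
            ("a", "I50.1", "outpatient", 100),
            ("b", "G12.2", "inpatient", 150),
            ("b", "C34.1", "outpatient", 90),
            ("c", "I21", "inpatient", 10),
        ],
        columns=["individual_id", "icd10_code", "setting", "day_before_death"],
    )
    services = pd.DataFrame(
        [
            ("a", "PPC", 126),
            ("a", "HOSPITAL", 25),
            ("b", "SPHC", 40),
        ],
        columns=["individual_id", "service", "day_before_death"],
    )
    persons = pd.DataFrame(
        [
            ("a", "female", 71, "other"),
            ("b", "male", 68, "hospital"),
            ("c", "female", 80, "hospital"),
        ],
        columns=["individual_id", "sex", "age_at_death", "place_of_death"],
    )
    return ClaimsDataset(diagnoses=diagnoses, services=services, persons=persons)
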