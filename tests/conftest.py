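import string
from datetime import date

import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from rtdet.cleaning import clean_table
from rtdet.io_model import (
    AppointmentRecord,
    FractionRecord,
    Intent,
    ReferralRecord,
    Task,
)
from rtdet.synthetic import generate_exact_fixture, study_contamination_specs

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


# --- hypothesis strategies for records -------------------------------------

_ident = st.text(alphabet=string.ascii_uppercase + string.digits, min_size=1, max_size=8)
_dates = st.dates(min_value=date(2014, 1, 1), max_value=date(2017, 12, 31))
_diagnosis = st.builds(
    lambda letter, num, sub: f"{letter}{num:02d}" + (f".{sub}" if sub is not None else ""),
    st.sampled_from(string.ascii_uppercase),
    st.integers(0, 99),
    st.one_of(st.none(), st.integers(0, 9)),
)

referral_records = st.builds(
    ReferralRecord,
    patient_id=_ident,
    diagnosis=_diagnosis,
    intent=st.sampled_from(list(Intent)),
    referral_date=_dates,
)
appointment_records = st.builds(
    AppointmentRecord,
    appointment_id=_ident,
    patient_id=_ident,
    task=st.sampled_from(list(Task)),
    appointment_date=_dates,
)
fraction_records = st.builds(
    FractionRecord, patient_id=_ident, fraction_date=_dates
)


# --- shared fixtures --------------------------------------------------------


@pytest.fixture(scope="session")
def study_specs():
    return study_contamination_specs()


@pytest.fixture(scope="session")
def study_fixture_tables(study_specs):
    """Exact-marginal raw tables for every table of the default suite."""
    return {name: generate_exact_fixture(spec, seed=7) for name, spec in study_specs.items()}


@pytest.fixture(scope="session")
def cleaned_study_referrals(study_fixture_tables):
    records, stats = clean_table(study_fixture_tables["referrals"])
    return records, stats


def make_referral(pid, diagnosis="C50", intent=Intent.CURATIVE, day=1):
    return ReferralRecord(
        patient_id=str(pid),
        diagnosis=diagnosis,
        intent=intent,
        referral_date=date(2015, 1, day),
    )
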