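"""Shared fixtures: hand-built mini EHR tables and a small synthetic cohort."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hfreadmit.config import CohortSpec, SyntheticConfig
from hfreadmit.synthetic_ehr import EHRTables, generate_ehr

T0 = pd.Timestamp("2010-01-01")


def ts(days: float) -> pd.Timestamp:
    """Timestamp ``days`` after the fixture calendar origin."""
    return T0 + pd.Timedelta(seconds=round(days * 86400))


def make_tables(patients, admissions, labevents=(), diagnoses=(), procedures=(),
                cptevents=(), lab_items=(("BUN", 50001),)) -> EHRTables:
    """Build EHRTables from compact tuples.

    patients:   (pid, gender, dob_days, ethnicity, expire_flag)
    admissions: (pid, hadm, admit_days, disch_days, type, insurance)
    labevents:  (hadm, analyte, chart_days, value)
    diagnoses:  (hadm, seq, icd9)
    procedures: (hadm, seq, icd9)
    cptevents:  (hadm, chart_days, cpt)
    """
    item_id = dict(lab_items)
    return EHRTables(
        patients=pd.DataFrame(
            [(p, g, ts(d), e, x) for p, g, d, e, x in patients],
            columns=["SUBJECT_ID", "GENDER", "DOB", "ETHNICITY", "EXPIRE_FLAG"],
        ),
        admissions=pd.DataFrame(
            [(p, h, ts(a), ts(d), t, i) for p, h, a, d, t, i in admissions],
            columns=["SUBJECT_ID", "HADM_ID", "ADMITTIME", "DISCHTIME",
                     "ADMISSION_TYPE", "INSURANCE"],
        ),
        labevents=pd.DataFrame(
            [(h, item_id[a], ts(c), v) for h, a, c, v in labevents],
            columns=["HADM_ID", "ITEMID", "CHARTTIME", "VALUENUM"],
        ),
        d_labitems=pd.DataFrame(
            [(i, a) for a, i in lab_items], columns=["ITEMID", "LABEL"]
        ),
        diagnoses_icd=pd.DataFrame(
            list(diagnoses), columns=["HADM_ID", "SEQ_NUM", "ICD9_CODE"]
        ),
        procedures_icd=pd.DataFrame(
            list(procedures), columns=["HADM_ID", "SEQ_NUM", "ICD9_CODE"]
        ),
        cptevents=pd.DataFrame(
            [(h, ts(c), cpt) for h, c, cpt in cptevents],
            columns=["HADM_ID", "CHARTTIME", "CPT_CD"],
        ),
    )


@pytest.fixture(scope="session")
def spec() -> CohortSpec:
    return CohortSpec()


@pytest.fixture(scope="session")
def small_synth():
    """300-patient synthetic EHR with moderate signal, plus latent frame."""
    tables, latent = generate_ehr(
        SyntheticConfig(n_patients=300, seed=5, signal_strength=1.0), return_latent=True
    )
    return tables, latent


@pytest.fixture(scope="session")
def small_cohort(small_synth, spec):
    from hfreadmit.cohort import select_cohort

    tables, _ = small_synth
    return select_cohort(tables, spec)


@pytest.fixture(scope="session")
def small_log(small_synth, small_cohort):
    """Artificial-event model and event log for the small synthetic cohort."""
    from hfreadmit.eventlog import build_event_log, fit_artificial_events

    tables, _ = small_synth
    art = fit_artificial_events(tables, small_cohort, k=30, seed=0)
    traces = build_event_log(tables, small_cohort, art)
    return art, traces


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
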