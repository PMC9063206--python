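"""Heart-failure cohort selection, 30-day unplanned readmission labels and
train/validation/test splitting.

Inclusion rules: the index admission is the most recent admission carrying an
HF ICD-9 diagnosis that still has at least one subsequent admission; members
need >=1 prior admission (the process-mining features require a history),
>=1 future admission of any type (guarantees the patient is alive and in the
system), and must not be flagged deceased.  Patients whose HF codes appear
only in admissions without the required prior history are excluded.

The label is TRUE iff the next admission after the index discharge is of an
unplanned type (emergency/urgent) and begins within the 30-day window
(boundary inclusive).  Label assignment reads nothing from the index
admission except its discharge time and nothing beyond the next admission's
admit record, so no feature leakage is possible through the label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CohortSpec
from .synthetic_ehr import EHRTables

logger = logging.getLogger(__name__)

__all__ = ["CohortMember", "select_cohort", "assign_label", "split_cohort"]


@dataclass
class CohortMember:
    """One selected patient with index admission and readmission label."""

    patient_id: int
    index_admission_id: int
    prior_admission_ids: tuple
    label: bool
    discharge_time: pd.Timestamp


def assign_label(
    index_discharge_time: pd.Timestamp,
    next_admit_time: pd.Timestamp,
    next_admission_type: str,
    spec: CohortSpec,
) -> bool:
    """TRUE iff the next admission is unplanned and starts within the window."""
    gap_days = (next_admit_time - index_discharge_time).total_seconds() / 86400.0
    return (next_admission_type in spec.unplanned_types) and gap_days <= spec.window_days


def select_cohort(tables: EHRTables, spec: CohortSpec) -> list[CohortMember]:
    """Apply the inclusion/exclusion rules and label every selected member.

    Returns members sorted by patient id (stable).  An empty table set yields
    an empty cohort with a warning.
    """
    spec.validate()
    adm = tables.admissions
    if len(adm) == 0:
        logger.warning("empty ADMISSIONS table: cohort is empty")
        return []

    deceased = set(
        tables.patients.loc[tables.patients["EXPIRE_FLAG"] == 1, "SUBJECT_ID"]
    )
    diag = tables.diagnoses_icd
    hf_admissions = set(
        diag.loc[[spec.is_hf_code(c) for c in diag["ICD9_CODE"]], "HADM_ID"]
    )

    members: list[CohortMember] = []
    for pid, grp in adm.sort_values(["SUBJECT_ID", "ADMITTIME"]).groupby(
        "SUBJECT_ID", sort=True
    ):
        if pid in deceased:
            continue
        hadm = grp["HADM_ID"].tolist()
        # most recent HF admission that still has a subsequent admission
        index_pos = None
        for j in range(len(hadm) - 2, -1, -1):
            if hadm[j] in hf_admissions:
                index_pos = j
                break
        if index_pos is None or index_pos == 0:
            continue  # no qualifying HF admission, or no prior history
        nxt = grp.iloc[index_pos + 1]
        members.append(
            CohortMember(
                patient_id=int(pid),
                index_admission_id=int(hadm[index_pos]),
                prior_admission_ids=tuple(int(h) for h in hadm[:index_pos]),
                label=assign_label(
                    grp.iloc[index_pos]["DISCHTIME"],
                    nxt["ADMITTIME"],
                    nxt["ADMISSION_TYPE"],
                    spec,
                ),
                discharge_time=grp.iloc[index_pos]["DISCHTIME"],
            )
        )
    return members


def split_cohort(
    members: list[CohortMember],
    ratios: tuple[float, float, float] = (0.731, 0.129, 0.140),
    seed: int = 0,
) -> tuple[list[CohortMember], list[CohortMember], list[CohortMember]]:
    """Random disjoint train/validation/test partition with exact sizes.

    Subset sizes are the largest-remainder rounding of ``len(members) *
    ratios`` so they always sum to the cohort size; the permutation is
    deterministic given the seed.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    n = len(members)
    if n < 3:
        raise ValueError("need at least 3 members to split")
    exact = np.asarray(ratios, dtype=float) * n
    sizes = np.floor(exact).astype(int)
    remainder = exact - sizes
    for k in np.argsort(-remainder)[: n - sizes.sum()]:
        sizes[k] += 1
    perm = np.random.default_rng(seed).permutation(n)
    bounds = np.cumsum(sizes)[:2]
    idx_train, idx_val, idx_test = np.split(perm, bounds)
    pick = lambda idx: [members[i] for i in sorted(idx)]
    return pick(idx_train), pick(idx_val), pick(idx_test)


def cohort_to_frame(members: list[CohortMember]) -> pd.DataFrame:
    """Cohort as a flat table (CSV-friendly export)."""
    return pd.DataFrame(
        [
            {
                "patient_id": m.patient_id,
                "index_admission_id": m.index_admission_id,
                "label": m.label,
                "discharge_time": m.discharge_time,
            }
            for m in members
        ]
    )
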