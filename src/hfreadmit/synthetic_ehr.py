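"""Synthetic MIMIC-III-shaped EHR tables with a latent readmission mechanism.

The generator emulates the relational schema consumed by the downstream
pipeline (PATIENTS, ADMISSIONS, LABEVENTS, D_LABITEMS, DIAGNOSES_ICD,
PROCEDURES_ICD, CPTEVENTS) for an elderly heart-failure ICU population.

Each patient draws a standard-normal latent severity ``z``.  For patients
eligible for the readmission cohort (>=1 prior admission, an HF ICD-9 code in
the index admission, >=1 future admission) the probability that the admission
following the index discharge is an unplanned (emergency/urgent) admission
within 30 days is exactly ``logistic(logit(base_rate) + signal_strength * z)``.
The same ``z`` shifts the four HF lab analyte means and the Elixhauser group
prevalences so that the outcome signal is recoverable from the generated
features; with ``signal_strength = 0`` the readmission indicator is
Bernoulli(base_rate) independent of every feature.

Timestamps are generated on a synthetic calendar at 1-second resolution;
inter-admission gaps are drawn from a mixture producing both <=30-day and
>30-day gaps so the label boundary is exercised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ConfigurationError, SyntheticConfig
from .severity import ELIXHAUSER_GROUPS, _ELIX

__all__ = ["EHRTables", "FormatError", "generate_ehr", "write_tables", "read_tables"]

DAY_S = 86400.0

TABLE_FILES = {
    "patients": "PATIENTS.csv",
    "admissions": "ADMISSIONS.csv",
    "labevents": "LABEVENTS.csv",
    "d_labitems": "D_LABITEMS.csv",
    "diagnoses_icd": "DIAGNOSES_ICD.csv",
    "procedures_icd": "PROCEDURES_ICD.csv",
    "cptevents": "CPTEVENTS.csv",
}

_ETHNICITIES = ["WHITE", "AFRICAN AMERICAN", "HISPANIC", "OTHERS NON-HISPANIC", "ASIAN"]
_ETH_P = [0.758, 0.120, 0.031, 0.070, 0.021]
_INSURANCES = ["Medicare", "Medicaid", "Private", "Government", "Self-pay"]
_INS_P = [0.55, 0.08, 0.30, 0.04, 0.03]

# ICD-9 code choices per Elixhauser group (the Quan mapping prefixes double
# as emitted codes; prefix matching makes them valid group members).  Codes
# that would trigger HF cohort inclusion (428.xx family and the hypertensive
# heart/renal HF codes) are excluded so that the explicitly injected HF code
# is the only inclusion trigger and the label mechanism stays calibrated.
from .config import HF_ICD9_EXACT as _HF_EXACT

_GROUP_CODES: dict[str, list[str]] = {
    g: [
        c
        for c in _ELIX.loc[_ELIX["group"] == g, "icd9_prefix"]
        if c not in _HF_EXACT and not c.startswith("428")
    ]
    for g in ELIXHAUSER_GROUPS
}


class FormatError(ValueError):
    """A table file is missing, unparsable or violates a schema invariant."""


@dataclass
class EHRTables:
    """The seven relational EHR tables keyed by SUBJECT_ID / HADM_ID."""

    patients: pd.DataFrame
    admissions: pd.DataFrame
    labevents: pd.DataFrame
    d_labitems: pd.DataFrame
    diagnoses_icd: pd.DataFrame
    procedures_icd: pd.DataFrame
    cptevents: pd.DataFrame

    def validate(self) -> None:
        adm = self.admissions
        bad = adm["DISCHTIME"] <= adm["ADMITTIME"]
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"ADMISSIONS row {row}: DISCHTIME <= ADMITTIME "
                f"(HADM_ID={adm.iloc[row]['HADM_ID']})"
            )
        # admissions of one patient must not overlap
        srt = adm.sort_values(["SUBJECT_ID", "ADMITTIME"])
        same = srt["SUBJECT_ID"].to_numpy()[1:] == srt["SUBJECT_ID"].to_numpy()[:-1]
        overlap = same & (
            srt["ADMITTIME"].to_numpy()[1:] < srt["DISCHTIME"].to_numpy()[:-1]
        )
        if overlap.any():
            i = int(np.flatnonzero(overlap)[0]) + 1
            raise FormatError(
                f"overlapping admissions for SUBJECT_ID={srt.iloc[i]['SUBJECT_ID']}"
            )
        # foreign keys
        known_pat = set(self.patients["SUBJECT_ID"])
        if not set(adm["SUBJECT_ID"]).issubset(known_pat):
            raise FormatError("ADMISSIONS.csv: dangling SUBJECT_ID foreign key")
        known_adm = set(adm["HADM_ID"])
        for name in ("labevents", "diagnoses_icd", "procedures_icd", "cptevents"):
            tab = getattr(self, name)
            if not set(tab["HADM_ID"]).issubset(known_adm):
                raise FormatError(f"{TABLE_FILES[name]}: dangling HADM_ID foreign key")
        if not set(self.labevents["ITEMID"]).issubset(set(self.d_labitems["ITEMID"])):
            raise FormatError("LABEVENTS.csv: dangling ITEMID foreign key")
        # every labevent charttime inside its admission interval
        if len(self.labevents):
            merged = self.labevents.merge(
                adm[["HADM_ID", "ADMITTIME", "DISCHTIME"]], on="HADM_ID", how="left"
            )
            out = (merged["CHARTTIME"] < merged["ADMITTIME"]) | (
                merged["CHARTTIME"] > merged["DISCHTIME"]
            )
            if out.any():
                row = int(np.flatnonzero(out.to_numpy())[0])
                raise FormatError(f"LABEVENTS row {row}: CHARTTIME outside admission")

    def equals(self, other: "EHRTables") -> bool:
        for name in TABLE_FILES:
            a = getattr(self, name).reset_index(drop=True)
            b = getattr(other, name).reset_index(drop=True)
            if not a.equals(b):
                return False
        return True


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def generate_ehr(config: SyntheticConfig, return_latent: bool = False):
    """Generate the seven EHR tables under the configured latent mechanism.

    Deterministic for a fixed config (single RNG stream, sequential
    generation); two calls with the same config produce identical tables.
    With ``return_latent=True`` also returns the per-patient latent frame
    (severity draw, eligibility, death flag and drawn label) for simulation
    studies that need the ground-truth mechanism.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    t0 = pd.Timestamp(config.calendar_start)

    analytes = list(config.lab_panel)
    itemids = {a: 50001 + i for i, a in enumerate(analytes)}
    groups = [g for g in ELIXHAUSER_GROUPS]
    prevs = np.array(
        [config.comorbidity_prevalences.get(g, 0.0) for g in groups], dtype=float
    )
    chf_idx = groups.index("CongestiveHeartFailure")
    n_proc_vocab = int(config.code_vocab_sizes.get("procedure", 120))
    n_cpt_vocab = int(config.code_vocab_sizes.get("cpt", 150))
    proc_vocab = [f"{100 + i:04d}" for i in range(n_proc_vocab)]
    cpt_vocab = [f"9{1000 + i:04d}" for i in range(n_cpt_vocab)]

    pat_rows, adm_rows, lab_rows, diag_rows, proc_rows, cpt_rows = [], [], [], [], [], []
    latent_rows = []
    hadm_id = 100000

    base_logit = _logit(config.readmit_base_rate)
    prior_extra = max(0.0, config.mean_admissions_per_patient - 3.0)

    for i in range(config.n_patients):
        pid = 10000 + i
        z = rng.standard_normal()
        death_flag = int(rng.random() < config.death_rate)
        eligible = rng.random() < config.eligible_fraction

        if eligible:
            n_prior = 1 + rng.poisson(prior_extra)
            n_adm = n_prior + 2
            index_pos = n_adm - 2
            label = rng.random() < _sigmoid(base_logit + config.signal_strength * z)
            hf_first_only = False
        else:
            n_adm = 1 + rng.poisson(1.0)
            index_pos = None
            label = None
            hf_first_only = n_adm >= 2 and rng.random() < 0.3

        # demographics
        age = float(np.clip(rng.normal(70.0, 14.0), 30.0, 95.0))
        gender = "F" if rng.random() < 0.476 else "M"
        ethnicity = _ETHNICITIES[rng.choice(len(_ETHNICITIES), p=_ETH_P)]

        # admission skeleton: default types first, then times with gaps;
        # the gap/type following the index admission encodes the drawn label
        types = [
            str(rng.choice(["EMERGENCY", "ELECTIVE", "URGENT"], p=[0.5, 0.3, 0.2]))
            for _ in range(n_adm)
        ]
        if index_pos is not None:
            types[index_pos] = str(
                rng.choice(["EMERGENCY", "URGENT", "ELECTIVE"], p=[0.75, 0.15, 0.10])
            )
        elif rng.random() < 0.02:
            types[0] = "NEWBORN"

        start_s = rng.uniform(0.0, 1095.0) * DAY_S
        admit_s, disch_s = [], []
        cur = start_s
        for j in range(n_adm):
            los = rng.uniform(2.0, 14.0) * DAY_S
            admit_s.append(cur)
            disch_s.append(cur + los)
            if j == n_adm - 1:
                break
            if index_pos is not None and j == index_pos:
                if label:
                    gap = rng.uniform(1.0, 30.0)
                    types[j + 1] = str(rng.choice(["EMERGENCY", "URGENT"], p=[0.8, 0.2]))
                elif rng.random() < 0.3:
                    gap = rng.uniform(0.5, 30.0)
                    types[j + 1] = "ELECTIVE"
                else:
                    gap = rng.uniform(31.0, 365.0)
            else:
                gap = rng.uniform(2.0, 30.0) if rng.random() < 0.3 else rng.uniform(31.0, 400.0)
            cur = disch_s[-1] + gap * DAY_S

        dob = t0 + pd.Timedelta(seconds=int(admit_s[0] - age * 365.25 * DAY_S))
        pat_rows.append((pid, gender, dob, ethnicity, death_flag))
        latent_rows.append((pid, z, eligible, bool(death_flag), label))

        for j in range(n_adm):
            hadm_id += 1
            adm_t = t0 + pd.Timedelta(seconds=int(admit_s[j]))
            dis_t = t0 + pd.Timedelta(seconds=int(disch_s[j]))
            insurance = _INSURANCES[rng.choice(len(_INSURANCES), p=_INS_P)]
            adm_rows.append((pid, hadm_id, adm_t, dis_t, types[j], insurance))

            # labs
            for a in analytes:
                mean, sd = config.lab_panel[a]
                n_meas = 1 + rng.poisson(max(0.0, config.mean_lab_measurements - 1.0))
                span = disch_s[j] - admit_s[j] - 7200.0
                offs = np.sort(rng.uniform(3600.0, 3600.0 + max(span, 1.0), n_meas))
                # 4-decimal rounding keeps CSV round trips byte-exact
                vals = rng.normal(mean + config.lab_shift * z * sd, sd, n_meas).round(4)
                for off, v in zip(offs, vals):
                    ct = t0 + pd.Timedelta(seconds=int(admit_s[j] + off))
                    lab_rows.append((hadm_id, itemids[a], ct, float(v)))

            # comorbidity diagnoses; zero-prevalence groups stay absent
            p = np.where(
                prevs > 0.0, np.clip(prevs + config.comorbidity_shift * z, 0.0, 1.0), 0.0
            )
            present = rng.random(len(groups)) < p
            if not eligible:
                present[chf_idx] = False  # keep non-eligible patients HF-free
            seq = 1
            if eligible and j == index_pos:
                diag_rows.append((hadm_id, seq, "4280"))
                seq += 1
            if hf_first_only and j == 0:
                diag_rows.append((hadm_id, seq, "4280"))
                seq += 1
            for gi in np.flatnonzero(present):
                codes = _GROUP_CODES[groups[gi]]
                diag_rows.append((hadm_id, seq, codes[rng.integers(len(codes))]))
                seq += 1

            # procedures and CPT events
            n_proc = rng.poisson(2.0)
            for s in range(n_proc):
                proc_rows.append((hadm_id, s + 1, proc_vocab[rng.integers(n_proc_vocab)]))
            n_cpt = rng.poisson(3.0)
            if n_cpt:
                offs = np.sort(rng.uniform(1800.0, max(disch_s[j] - admit_s[j] - 1800.0, 1801.0), n_cpt))
                for off in offs:
                    ct = t0 + pd.Timedelta(seconds=int(admit_s[j] + off))
                    cpt_rows.append((hadm_id, ct, cpt_vocab[rng.integers(n_cpt_vocab)]))

    tables = EHRTables(
        patients=pd.DataFrame(
            pat_rows, columns=["SUBJECT_ID", "GENDER", "DOB", "ETHNICITY", "EXPIRE_FLAG"]
        ),
        admissions=pd.DataFrame(
            adm_rows,
            columns=["SUBJECT_ID", "HADM_ID", "ADMITTIME", "DISCHTIME", "ADMISSION_TYPE", "INSURANCE"],
        ),
        labevents=pd.DataFrame(lab_rows, columns=["HADM_ID", "ITEMID", "CHARTTIME", "VALUENUM"]),
        d_labitems=pd.DataFrame(
            [(itemids[a], a) for a in analytes], columns=["ITEMID", "LABEL"]
        ),
        diagnoses_icd=pd.DataFrame(diag_rows, columns=["HADM_ID", "SEQ_NUM", "ICD9_CODE"]),
        procedures_icd=pd.DataFrame(proc_rows, columns=["HADM_ID", "SEQ_NUM", "ICD9_CODE"]),
        cptevents=pd.DataFrame(cpt_rows, columns=["HADM_ID", "CHARTTIME", "CPT_CD"]),
    )
    tables.validate()
    if return_latent:
        latent = pd.DataFrame(
            latent_rows,
            columns=["SUBJECT_ID", "latent_severity", "eligible", "death", "drawn_label"],
        )
        return tables, latent
    return tables


def write_tables(tables: EHRTables, directory: str | Path) -> list[Path]:
    """Write the seven tables as MIMIC-III-named CSVs with ISO-8601 timestamps."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for attr, fname in TABLE_FILES.items():
        df = getattr(tables, attr).copy()
        for col in df.columns:
            if pd.api.types.is_datetime64_any_dtype(df[col]):
                df[col] = df[col].dt.strftime("%Y-%m-%dT%H:%M:%S")
        path = directory / fname
        df.to_csv(path, index=False)
        written.append(path)
    return written


_DTYPES = {
    "SUBJECT_ID": "int64", "HADM_ID": "int64", "ITEMID": "int64",
    "SEQ_NUM": "int64", "EXPIRE_FLAG": "int64", "VALUENUM": "float64",
    "ICD9_CODE": "str", "CPT_CD": "str", "GENDER": "str", "ETHNICITY": "str",
    "ADMISSION_TYPE": "str", "INSURANCE": "str", "LABEL": "str",
}
_TIME_COLS = {"DOB", "ADMITTIME", "DISCHTIME", "CHARTTIME"}


def read_tables(directory: str | Path) -> EHRTables:
    """Read tables written by :func:`write_tables`; validates all invariants."""
    directory = Path(directory)
    frames = {}
    for attr, fname in TABLE_FILES.items():
        path = directory / fname
        if not path.exists():
            raise FormatError(f"missing table file: {fname}")
        df = pd.read_csv(path, dtype={c: t for c, t in _DTYPES.items()})
        for col in df.columns:
            if col in _TIME_COLS:
                try:
                    df[col] = pd.to_datetime(df[col], format="%Y-%m-%dT%H:%M:%S")
                except (ValueError, TypeError) as exc:
                    raise FormatError(f"{fname}: unparsable timestamp in {col}: {exc}")
        frames[attr] = df
    tables = EHRTables(**frames)
    tables.validate()
    return tables
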