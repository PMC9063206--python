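"""Charlson and Elixhauser comorbidity scoring from ICD-9-CM diagnosis codes.

Both indices are computed with the Quan et al. ICD-9-CM coding algorithms,
shipped as CSV mapping tables under ``hfreadmit/data``.  Codes are matched by
prefix on the decimal-stripped representation (e.g. ``428.0`` -> ``4280``
matches the Elixhauser congestive-heart-failure prefix ``428``).

The Elixhauser score defaults to the unweighted count of distinct comorbidity
groups present; the van Walraven weighted sum is available behind a flag.
The Charlson score is the sum of the canonical category weights
(1, 2, 3 or 6), each category counted at most once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SeverityScores",
    "ELIXHAUSER_GROUPS",
    "normalize_icd9",
    "elixhauser_groups",
    "elixhauser_score",
    "charlson_score",
    "scores_at_discharge",
]


def _load_table(name: str) -> pd.DataFrame:
    with resources.files("hfreadmit.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, dtype=str)


_ELIX = _load_table("elixhauser_icd9.csv")
_CHARLSON = _load_table("charlson_icd9.csv")

#: Canonical Elixhauser group order (used for deterministic event ordering).
ELIXHAUSER_GROUPS: tuple[str, ...] = tuple(dict.fromkeys(_ELIX["group"]))

_ELIX_PREFIXES: list[tuple[str, str]] = list(
    zip(_ELIX["icd9_prefix"], _ELIX["group"])
)
_VW_WEIGHT: dict[str, int] = {
    g: int(w) for g, w in zip(_ELIX["group"], _ELIX["vw_weight"])
}
_CHARLSON_PREFIXES: list[tuple[str, str, int]] = [
    (p, c, int(w))
    for p, c, w in zip(
        _CHARLSON["icd9_prefix"], _CHARLSON["category"], _CHARLSON["weight"]
    )
]


@dataclass(frozen=True)
class SeverityScores:
    """Severity summary for one patient at the index discharge."""

    charlson: int
    elixhauser: int
    groups_present: frozenset[str] = field(default_factory=frozenset)

    def as_vector(self) -> list[float]:
        return [float(self.charlson), float(self.elixhauser)]


def normalize_icd9(code: str) -> str:
    """Strip the decimal point and surrounding whitespace from an ICD-9 code."""
    return str(code).strip().replace(".", "").upper()


def elixhauser_groups(icd9_codes) -> set[str]:
    """Map ICD-9 diagnosis codes to the set of Elixhauser comorbidity groups.

    Prefix matching against the Quan mapping; duplicated codes are idempotent
    and unrecognized codes are ignored (logged at DEBUG level).
    """
    groups: set[str] = set()
    for code in icd9_codes:
        norm = normalize_icd9(code)
        hit = False
        for prefix, group in _ELIX_PREFIXES:
            if norm.startswith(prefix):
                groups.add(group)
                hit = True
        if not hit:
            logger.debug("ICD-9 code %r matched no Elixhauser group", code)
    return groups


def elixhauser_score(icd9_codes, weighted: bool = False) -> int:
    """Elixhauser score: group count by default, van Walraven sum if weighted."""
    groups = elixhauser_groups(icd9_codes)
    if weighted:
        return sum(_VW_WEIGHT[g] for g in groups)
    return len(groups)


def charlson_score(icd9_codes) -> int:
    """Charlson comorbidity index (Quan ICD-9 mapping, original weights)."""
    weights: dict[str, int] = {}
    for code in icd9_codes:
        norm = normalize_icd9(code)
        for prefix, category, weight in _CHARLSON_PREFIXES:
            if norm.startswith(prefix):
                weights[category] = weight
    return sum(weights.values())


def codes_by_admission(tables) -> dict:
    """Precomputed HADM_ID -> diagnosis code list index (reusable across members)."""
    return {
        h: g["ICD9_CODE"].tolist() for h, g in tables.diagnoses_icd.groupby("HADM_ID")
    }


def scores_at_discharge(member, tables, weighted_elixhauser: bool = False,
                        code_index: dict | None = None) -> SeverityScores:
    """Severity scores from all diagnoses up to and including the index admission.

    Pools the diagnosis codes of the member's prior admissions and index
    admission; admissions after the index discharge never contribute, so the
    scores are leakage-free with respect to the readmission outcome.
    ``code_index`` (from :func:`codes_by_admission`) avoids re-scanning the
    diagnosis table when scoring many members.
    """
    adm_ids = set(member.prior_admission_ids) | {member.index_admission_id}
    if code_index is not None:
        codes = [c for h in adm_ids for c in code_index.get(h, [])]
    else:
        diag = tables.diagnoses_icd
        codes = diag.loc[diag["HADM_ID"].isin(adm_ids), "ICD9_CODE"].tolist()
    groups = elixhauser_groups(codes)
    if weighted_elixhauser:
        elix = sum(_VW_WEIGHT[g] for g in groups)
    else:
        elix = len(groups)
    return SeverityScores(
        charlson=charlson_score(codes),
        elixhauser=elix,
        groups_present=frozenset(groups),
    )
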