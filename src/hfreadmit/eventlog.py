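"""Conversion of EHR histories into ordered, timestamped event logs.

Every admission of a cohort member (all prior admissions plus the index
admission) contributes, in order:

* an admission-type event at the admission time;
* an insurance event 1 ms later;
* per lab analyte, a Mean event at the first measurement time and a Std
  event 1 ms after it (single measurement) or at the last measurement time
  (repeated measurements);
* one event per Elixhauser comorbidity group scored for the admission,
  placed just before discharge with successive +1 ms offsets
  (the i-th of m groups at discharge - (m - i) ms, canonical group order);
* one artificial event abstracting the admission's ICD-9 procedure / CPT
  code sequence (k-means cluster label, k = 30 by default) at the first
  code observation time + 1 ms, clipped to discharge - 0.5 ms if later;
* a discharge event at the discharge time.

The timed-state-sample marker sits at the index admission's discharge event;
nothing after it ever contributes to features.  Within a trace all
timestamps are strictly increasing; exact ties (possible only in
adversarially constructed tables) are resolved deterministically by +0.5 ms
bumps, and an unresolvable tie at the discharge anchor raises.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .severity import ELIXHAUSER_GROUPS, elixhauser_groups
from .synthetic_ehr import EHRTables

logger = logging.getLogger(__name__)

__all__ = [
    "Event",
    "Trace",
    "ArtificialEventModel",
    "EVENT_CATEGORIES",
    "fit_artificial_events",
    "build_event_log",
    "write_xes",
    "read_xes",
]

MS = pd.Timedelta(milliseconds=1)
HALF_MS = pd.Timedelta(microseconds=500)

EVENT_CATEGORIES = ("admission", "insurance", "lab", "comorbidity", "artificial", "discharge")

_SORT_PRIORITY = {"admission": 0, "insurance": 1, "lab": 2, "artificial": 3,
                  "comorbidity": 4, "discharge": 5}


@dataclass(frozen=True)
class Event:
    name: str
    timestamp: pd.Timestamp
    category: str


@dataclass
class Trace:
    """One patient's ordered event sequence with label and TSS marker."""

    case_id: int
    events: list
    label: bool
    tss_marker_index: int

    def validate(self) -> None:
        ts = [e.timestamp for e in self.events]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError(f"trace {self.case_id}: timestamps not strictly increasing")
        if self.events[self.tss_marker_index].category != "discharge":
            raise ValueError(f"trace {self.case_id}: TSS marker is not a discharge event")


class InvariantError(RuntimeError):
    """An event-log construction invariant was violated."""


def _hash_vectorize(codes: list[str], dim: int) -> np.ndarray:
    """Hashed bag of code 1-grams + 2-grams (crc32, stable across runs)."""
    v = np.zeros(dim, dtype=float)
    grams = list(codes) + [f"{a}|{b}" for a, b in zip(codes, codes[1:])]
    for g in grams:
        v[zlib.crc32(g.encode()) % dim] += 1.0
    return v


@dataclass
class ArtificialEventModel:
    """Clustering of per-admission code sequences into artificial event names.

    The vectorization (hashed n-gram counts) and the clustering algorithm
    (k-means, seeded, 10 restarts) are a replaceable abstraction strategy;
    any model exposing ``predict_name`` can stand in.
    """

    k: int = 30
    dim: int = 256
    seed: int = 0
    kmeans: KMeans | None = field(default=None, repr=False)

    @property
    def fitted(self) -> bool:
        return self.kmeans is not None

    def fit(self, code_sequences: list[list[str]]) -> "ArtificialEventModel":
        nonempty = [c for c in code_sequences if c]
        if not nonempty:
            raise ValueError("no non-empty code sequences to fit on")
        k = self.k
        if len(nonempty) < k:
            logger.warning("only %d admissions with codes; reducing k from %d", len(nonempty), k)
            k = len(nonempty)
        X = np.stack([_hash_vectorize(c, self.dim) for c in nonempty])
        self.kmeans = KMeans(n_clusters=k, n_init=10, random_state=self.seed).fit(X)
        self.k = k
        return self

    def predict_name(self, codes: list[str]) -> str | None:
        if not codes:
            return None
        if not self.fitted:
            raise RuntimeError("artificial event model not fitted")
        j = int(self.kmeans.predict(_hash_vectorize(codes, self.dim)[None, :])[0])
        return f"ART_{j}"


def _admission_code_sequence(hadm_id, proc_by_adm, cpt_by_adm) -> tuple[list[str], pd.Timestamp | None]:
    """Ordered ICD-9 procedure + CPT codes and the first observation time."""
    codes: list[str] = []
    first_time = None
    if hadm_id in proc_by_adm.groups:
        proc = proc_by_adm.get_group(hadm_id).sort_values("SEQ_NUM")
        codes.extend(str(c) for c in proc["ICD9_CODE"])
    if hadm_id in cpt_by_adm.groups:
        cpt = cpt_by_adm.get_group(hadm_id).sort_values("CHARTTIME")
        codes.extend(str(c) for c in cpt["CPT_CD"])
        first_time = cpt["CHARTTIME"].iloc[0]
    return codes, first_time


def fit_artificial_events(
    tables: EHRTables, train_members, k: int = 30, seed: int = 0
) -> ArtificialEventModel:
    """Fit the artificial-event clustering on the training cohort only."""
    if not train_members:
        raise ValueError("training cohort is empty")
    if k < 2:
        raise ValueError("k must be >= 2")
    proc_by_adm = tables.procedures_icd.groupby("HADM_ID")
    cpt_by_adm = tables.cptevents.groupby("HADM_ID")
    seqs = []
    for m in train_members:
        for hadm in list(m.prior_admission_ids) + [m.index_admission_id]:
            codes, _ = _admission_code_sequence(hadm, proc_by_adm, cpt_by_adm)
            seqs.append(codes)
    return ArtificialEventModel(k=k, seed=seed).fit(seqs)


def _admission_events(
    adm_row, labs, diag_codes, art_name, first_code_time, drop: frozenset
) -> list[Event]:
    admit, disch = adm_row["ADMITTIME"], adm_row["DISCHTIME"]
    floating: list[Event] = []
    if "admission" not in drop:
        floating.append(Event(f"ADMISSION_{adm_row['ADMISSION_TYPE']}", admit, "admission"))
    if "insurance" not in drop:
        floating.append(Event(f"INSURANCE_{adm_row['INSURANCE']}", admit + MS, "insurance"))

    if "lab" not in drop:
        for analyte, times in labs:
            t_first, t_last, n = times
            mean_ts = t_first
            std_ts = t_first + MS if n == 1 else t_last
            if std_ts <= mean_ts:  # repeated measurements at an identical time
                std_ts = mean_ts + MS
            floating.append(Event(f"{analyte}_Mean", mean_ts, "lab"))
            floating.append(Event(f"{analyte}_Std", std_ts, "lab"))

    if art_name is not None and "artificial" not in drop:
        ts = (first_code_time if first_code_time is not None else admit) + MS
        latest = disch - HALF_MS
        floating.append(Event(art_name, min(ts, latest), "artificial"))

    anchored: list[Event] = []
    if "comorbidity" not in drop:
        groups = sorted(elixhauser_groups(diag_codes), key=ELIXHAUSER_GROUPS.index)
        m = len(groups)
        for i, g in enumerate(groups):
            anchored.append(Event(f"COMORB_{g}", disch - (m - i) * MS, "comorbidity"))
    anchored.append(Event("DISCHARGE", disch, "discharge"))

    events = sorted(
        floating + anchored, key=lambda e: (e.timestamp, _SORT_PRIORITY[e.category], e.name)
    )
    # deterministic resolution of exact ties: later event bumped by +0.5 ms
    out: list[Event] = []
    for e in events:
        if out and e.timestamp <= out[-1].timestamp:
            e = Event(e.name, out[-1].timestamp + HALF_MS, e.category)
        out.append(e)
    if out[-1].category != "discharge" or (len(out) > 1 and out[-2].timestamp >= disch):
        raise InvariantError(
            f"admission {adm_row['HADM_ID']}: could not order events before discharge"
        )
    return out


def build_event_log(
    tables: EHRTables,
    members,
    art_model: ArtificialEventModel,
    lab_panel: list[str] | None = None,
    drop_event_types: frozenset = frozenset(),
) -> list[Trace]:
    """Convert each member's prior + index admissions into one trace.

    Pure function of its inputs: repeated calls yield identical traces.
    ``drop_event_types`` supports the variable-ablation study; dropping
    discharge events is refused because they carry the TSS marker.
    """
    drop = frozenset(drop_event_types)
    if "discharge" in drop:
        raise ValueError("discharge events cannot be dropped (they carry the TSS marker)")
    unknown = drop - set(EVENT_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown event categories: {sorted(unknown)}")

    adm_by_id = {int(r["HADM_ID"]): r for r in tables.admissions.to_dict("records")}
    item_label = dict(zip(tables.d_labitems["ITEMID"], tables.d_labitems["LABEL"]))
    panel = lab_panel or list(tables.d_labitems["LABEL"])
    lab_by_adm = dict(tuple(tables.labevents.groupby("HADM_ID")))
    diag_by_adm = dict(tuple(tables.diagnoses_icd.groupby("HADM_ID")))
    proc_by_adm = tables.procedures_icd.groupby("HADM_ID")
    cpt_by_adm = tables.cptevents.groupby("HADM_ID")

    traces: list[Trace] = []
    for m in members:
        events: list[Event] = []
        for hadm in list(m.prior_admission_ids) + [m.index_admission_id]:
            adm_row = adm_by_id[hadm]
            labs = []
            if hadm in lab_by_adm:
                le = lab_by_adm[hadm]
                for analyte in panel:
                    sel = le.loc[[item_label[i] == analyte for i in le["ITEMID"]], "CHARTTIME"]
                    if len(sel):
                        sel = sel.sort_values()
                        labs.append((analyte, (sel.iloc[0], sel.iloc[-1], len(sel))))
            diag_codes = (
                diag_by_adm[hadm]["ICD9_CODE"].tolist() if hadm in diag_by_adm else []
            )
            codes, first_time = _admission_code_sequence(hadm, proc_by_adm, cpt_by_adm)
            art_name = art_model.predict_name(codes) if art_model is not None else None
            events.extend(
                _admission_events(adm_row, labs, diag_codes, art_name, first_time, drop)
            )
        trace = Trace(
            case_id=m.patient_id,
            events=events,
            label=bool(m.label),
            tss_marker_index=len(events) - 1,
        )
        trace.validate()
        traces.append(trace)
    return traces


# ---------------------------------------------------------------------------
# XES serialization

_XES_NS = "http://www.xes-standard.org/"


def write_xes(traces: list[Trace], path) -> None:
    """Write traces as XES 2.0; refuses logs violating the ordering invariant."""
    from lxml import etree

    for t in traces:
        t.validate()
    root = etree.Element("log", attrib={"xes.version": "2.0"})
    for t in traces:
        tr = etree.SubElement(root, "trace")
        etree.SubElement(tr, "string", key="concept:name", value=str(t.case_id))
        etree.SubElement(tr, "boolean", key="label", value=str(t.label).lower())
        etree.SubElement(tr, "int", key="tss_marker", value=str(t.tss_marker_index))
        for e in t.events:
            ev = etree.SubElement(tr, "event")
            etree.SubElement(ev, "string", key="concept:name", value=e.name)
            etree.SubElement(ev, "date", key="time:timestamp", value=e.timestamp.isoformat())
            etree.SubElement(ev, "string", key="category", value=e.category)
    etree.ElementTree(root).write(str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8")


def read_xes(path) -> list[Trace]:
    """Read an XES file written by :func:`write_xes` (round-trip exact)."""
    from lxml import etree

    try:
        root = etree.parse(str(path)).getroot()
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed XES file {path}: {exc}") from exc
    traces = []
    for tr in root.findall("trace"):
        attrs = {c.get("key"): c.get("value") for c in tr if c.tag != "event"}
        events = []
        for ev in tr.findall("event"):
            kv = {c.get("key"): c.get("value") for c in ev}
            events.append(
                Event(kv["concept:name"], pd.Timestamp(kv["time:timestamp"]), kv.get("category", ""))
            )
        traces.append(
            Trace(
                case_id=int(attrs["concept:name"]),
                events=events,
                label=attrs["label"] == "true",
                tss_marker_index=int(attrs["tss_marker"]),
            )
        )
    return traces
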