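"""Mapping of NN input columns to the six variable families used for the
grouped Shapley attribution: severity scores, admission events,
demographics, artificial events, comorbidity events and lab measurement
events.

Timed-state-sample columns derive from directly-follows places
``p__a__b``; each is assigned to the family of its *source* event ``a``
(the event whose occurrence deposits the token, hence the one whose
recency the decay value encodes).  Admission-type, insurance and
discharge events form one "admission events" family; START/source/sink
bookkeeping places join it too.
"""

from __future__ import annotations

import numpy as np

__all__ = ["event_family", "feature_groups", "nn_predict_on_matrix"]

FAMILIES = ("severity", "admission_events", "demographics",
            "artificial_events", "comorbidity_events", "lab_events")


def event_family(name: str) -> str:
    if name.startswith("COMORB_"):
        return "comorbidity_events"
    if name.startswith("ART_"):
        return "artificial_events"
    if name.endswith("_Mean") or name.endswith("_Std"):
        return "lab_events"
    # ADMISSION_*, INSURANCE_*, DISCHARGE, START/END/OTHER bookkeeping
    return "admission_events"


def _place_family(place: str) -> str:
    if place.startswith("p__"):
        source = place[3:].split("__")[0]
        return event_family(source)
    return "admission_events"  # source / sink


def feature_groups(bundle) -> dict:
    """Column-index partition of ``bundle.nn_matrix()`` into the six families."""
    groups: dict[str, list[int]] = {f: [] for f in FAMILIES}
    col = 0
    for name in bundle.tss_names:
        place = name.split("__", 1)[1]
        groups[_place_family(place)].append(col)
        col += 1
    for _ in bundle.demographics_names:
        groups["demographics"].append(col)
        col += 1
    for _ in bundle.severity_names:
        groups["severity"].append(col)
        col += 1
    return {f: idx for f, idx in groups.items() if idx}


def nn_predict_on_matrix(trained, bundle):
    """Positive-class probability on a flat ``[tss | demo | sev]`` matrix."""
    w_tss = bundle.tss.shape[1]
    w_demo = bundle.demographics.shape[1]

    def predict(X: np.ndarray) -> np.ndarray:
        parts = [X[:, :w_tss], X[:, w_tss : w_tss + w_demo], X[:, w_tss + w_demo :]]
        return trained.network.predict_proba(parts)[:, 1]

    return predict
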