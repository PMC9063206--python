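"""Event-log conversion rules: one fixture per timestamp rule, plus the
ordering/coverage/purity invariants and XES round trips."""

import numpy as np
import pandas as pd
import pytest

from hfreadmit.cohort import select_cohort
from hfreadmit.eventlog import (
    MS,
    ArtificialEventModel,
    Event,
    Trace,
    build_event_log,
    fit_artificial_events,
    read_xes,
    write_xes,
)

from conftest import make_tables, ts

PAT = [(1, "F", -25000, "WHITE", 0)]
LAB_ITEMS = (("BUN", 50001), ("SerumCreatinine", 50002),
             ("Sodium", 50003), ("NTproBNP", 50004))


def build_fixture(labevents=(), diagnoses=(), procedures=(), cptevents=()):
    """Patient with one prior admission (10) and the HF index admission (11)."""
    tables = make_tables(
        PAT,
        [(1, 10, 0, 5, "EMERGENCY", "Medicare"),
         (1, 11, 50, 60, "URGENT", "Private"),
         (1, 12, 100, 105, "ELECTIVE", "Medicare")],
        labevents=labevents,
        diagnoses=list(diagnoses) + [(11, 99, "4280")],
        procedures=procedures,
        cptevents=cptevents,
        lab_items=LAB_ITEMS,
    )
    members = select_cohort(tables, __import__("hfreadmit.config", fromlist=["CohortSpec"]).CohortSpec())
    assert len(members) == 1
    return tables, members


def get_trace(tables, members, **kw):
    traces = build_event_log(tables, members, art_model=None,
                             lab_panel=[a for a, _ in LAB_ITEMS], **kw)
    return traces[0]


def by_name(trace, name):
    return [e for e in trace.events if e.name == name]


def test_admission_and_insurance_events():
    tables, members = build_fixture()
    trace = get_trace(tables, members)
    adm = by_name(trace, "ADMISSION_URGENT")[0]
    ins = by_name(trace, "INSURANCE_Private")[0]
    assert adm.timestamp == ts(50)
    assert ins.timestamp == ts(50) + MS


def test_single_lab_measurement_mean_then_std_1ms_later():
    tables, members = build_fixture(labevents=[(11, "BUN", 52.0, 30.0)])
    trace = get_trace(tables, members)
    mean = by_name(trace, "BUN_Mean")[0]
    std = by_name(trace, "BUN_Std")[0]
    assert mean.timestamp == ts(52.0)
    assert std.timestamp == ts(52.0) + MS


def test_repeated_lab_measurements_std_at_last_time():
    tables, members = build_fixture(
        labevents=[(11, "BUN", 51.0, 30.0), (11, "BUN", 53.0, 35.0), (11, "BUN", 55.0, 40.0)]
    )
    trace = get_trace(tables, members)
    assert by_name(trace, "BUN_Mean")[0].timestamp == ts(51.0)
    assert by_name(trace, "BUN_Std")[0].timestamp == ts(55.0)


def test_comorbidity_events_offsets_before_discharge():
    # three Elixhauser groups on the index admission -> D-3, D-2, D-1 ms
    tables, members = build_fixture(
        diagnoses=[(11, 1, "2500"), (11, 2, "401"), (11, 3, "311")]
    )
    trace = get_trace(tables, members)
    comorb = [e for e in trace.events if e.category == "comorbidity"
              and e.timestamp > ts(50)]
    D = ts(60)
    # CHF group is present too via the injected 4280 -> four groups
    assert len(comorb) == 4
    assert [e.timestamp for e in comorb] == [D - 4 * MS, D - 3 * MS, D - 2 * MS, D - 1 * MS]
    assert all(e.timestamp < D for e in comorb)
    discharge = trace.events[trace.tss_marker_index]
    assert discharge.name == "DISCHARGE" and discharge.timestamp == D


def test_comorbidity_events_any_count_strictly_ordered():
    # all 31 groups cannot occur here, but a large subset stays ordered
    codes = ["2500", "401", "311", "042", "196", "286", "2780", "4950", "585", "571"]
    tables, members = build_fixture(diagnoses=[(11, i, c) for i, c in enumerate(codes, 1)])
    trace = get_trace(tables, members)
    stamps = [e.timestamp for e in trace.events]
    assert all(b > a for a, b in zip(stamps, stamps[1:]))


def test_artificial_event_placed_after_first_code_observation():
    model = ArtificialEventModel(k=2, seed=0).fit([["A", "B"], ["C"], ["A", "B"]])
    tables, members = build_fixture(
        procedures=[(11, 1, "3961")], cptevents=[(11, 54.0, "91000")]
    )
    traces = build_event_log(tables, members, art_model=model,
                             lab_panel=[a for a, _ in LAB_ITEMS])
    art = [e for e in traces[0].events if e.category == "artificial"]
    assert len(art) == 1  # only the index admission has codes
    assert art[0].timestamp == ts(54.0) + MS


def test_artificial_event_clipped_before_discharge():
    model = ArtificialEventModel(k=2, seed=0).fit([["A"], ["B"], ["C"]])
    tables, members = build_fixture(cptevents=[(11, 60.0, "91000")])  # at discharge
    traces = build_event_log(tables, members, art_model=model,
                             lab_panel=[a for a, _ in LAB_ITEMS])
    art = [e for e in traces[0].events if e.category == "artificial"][0]
    D = ts(60)
    assert art.timestamp < D
    assert D - art.timestamp <= MS


def test_every_admission_covered_and_marker_at_index_discharge(small_synth, small_cohort, small_log):
    tables, _ = small_synth
    _, traces = small_log
    for trace, member in zip(traces[:40], small_cohort[:40]):
        n_adm = len(member.prior_admission_ids) + 1
        cats = [e.category for e in trace.events]
        assert cats.count("admission") == n_adm
        assert cats.count("insurance") == n_adm
        assert cats.count("discharge") == n_adm
        assert trace.tss_marker_index == len(trace.events) - 1
        stamps = [e.timestamp for e in trace.events]
        assert all(b > a for a, b in zip(stamps, stamps[1:]))


def test_conversion_is_pure(small_synth, small_cohort, small_log):
    tables, _ = small_synth
    art, traces = small_log
    again = build_event_log(tables, small_cohort, art)
    assert all(a.events == b.events for a, b in zip(traces, again))


def test_identical_code_sequences_share_artificial_name():
    model = ArtificialEventModel(k=3, seed=1).fit([["A", "B"], ["C", "D"], ["E"], ["A", "B"]])
    assert model.predict_name(["A", "B"]) == model.predict_name(["A", "B"])
    assert model.predict_name([]) is None


def test_artificial_vocabulary_bounded_by_k(small_synth, small_log):
    _, traces = small_log
    names = {e.name for t in traces for e in t.events if e.category == "artificial"}
    assert 1 <= len(names) <= 30


def test_k_reduced_when_fewer_admissions(caplog):
    model = ArtificialEventModel(k=30, seed=0).fit([["A"], ["B", "C"]])
    assert model.k == 2


def test_fit_requires_train_cohort(small_synth):
    tables, _ = small_synth
    with pytest.raises(ValueError):
        fit_artificial_events(tables, [], k=30)


def test_xes_roundtrip(small_log, tmp_path):
    _, traces = small_log
    path = tmp_path / "log.xes"
    write_xes(traces[:25], path)
    back = read_xes(path)
    for a, b in zip(traces[:25], back):
        assert a.case_id == b.case_id and a.label == b.label
        assert a.tss_marker_index == b.tss_marker_index
        assert a.events == b.events


def test_xes_writer_refuses_decreasing_timestamps(tmp_path):
    bad = Trace(
        1,
        [Event("A", ts(1), "admission"), Event("DISCHARGE", ts(0.5), "discharge")],
        False,
        1,
    )
    with pytest.raises(ValueError, match="strictly increasing"):
        write_xes([bad], tmp_path / "bad.xes")


def test_malformed_xes_raises(tmp_path):
    p = tmp_path / "broken.xes"
    p.write_text("<log><trace></log>")
    with pytest.raises(ValueError, match="malformed"):
        read_xes(p)


def test_dropping_discharge_events_refused(small_synth, small_cohort):
    tables, _ = small_synth
    with pytest.raises(ValueError, match="discharge"):
        build_event_log(tables, small_cohort, None, drop_event_types=frozenset({"discharge"}))
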