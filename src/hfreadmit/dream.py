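"""Decay replay: timed state samples from token replay with per-place decay.

Each trace is replayed on the discovered Petri net.  A virtual START
transition fires at the first event's timestamp (consuming the initial
source token), then every event up to and including the TSS marker fires
the transition carrying its name (unknown names route to OTHER).  Firing
consumes one token from one input place — the one with the most recent
token arrival among the marked inputs; if none is marked, a missing token
is inserted there and counted — and produces one token into every output
place, resetting that place's decay clock and incrementing its cumulative
arrival counter.

The decay function of place ``p`` is ``f_p(t) = max(0, beta - alpha_p *
(t - t_last_p))`` with ``beta = 1`` by default, evaluated in days (the
millisecond ordering offsets of the event log therefore contribute
negligible decay).  ``alpha_p = beta / D_p`` where ``D_p`` is the largest
observed within-trace token inter-arrival time at ``p`` over the training
replay; places never re-activated fall back to the maximum trace duration.

The timed state sample captured at the marker concatenates the decay
values, cumulative token counts and current marking over the net's
canonical place order.  Post-marker events never influence the sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .discovery import OTHER, START, PetriNet
from .eventlog import Trace

__all__ = ["TimedStateSample", "replay_arrivals", "estimate_decay_rates",
           "replay_to_tss", "tss_matrix"]

DAY_S = 86400.0


@dataclass
class TimedStateSample:
    """Per-place decay values, token counters and marking at the TSS marker."""

    decay_values: np.ndarray
    token_counts: np.ndarray
    marking: np.ndarray
    taken_at: pd.Timestamp
    missing_token_insertions: int

    def vector(self, include_counts: bool = True, include_marking: bool = True) -> np.ndarray:
        parts = [self.decay_values]
        if include_counts:
            parts.append(self.token_counts.astype(float))
        if include_marking:
            parts.append(self.marking.astype(float))
        return np.concatenate(parts)


def _replay(net: PetriNet, trace: Trace, upto_marker: bool = True):
    """Token replay; returns (arrivals, t_last, marking, counts, missing, t_capture)."""
    if trace.tss_marker_index is None:
        raise ValueError(f"trace {trace.case_id} has no TSS marker")
    place_idx = {p: i for i, p in enumerate(net.places)}
    transitions = set(net.transitions)
    marking = {p: 0 for p in net.places}
    t_last: dict = {p: None for p in net.places}
    counts = {p: 0 for p in net.places}
    arrivals: dict = {p: [] for p in net.places}
    missing = 0

    events = trace.events[: trace.tss_marker_index + 1] if upto_marker else trace.events
    if not events:
        raise ValueError(f"trace {trace.case_id} is empty")
    epoch = events[0].timestamp

    def day(ts) -> float:
        return (ts - epoch).total_seconds() / DAY_S

    def arrive(p, tau):
        marking[p] += 1
        counts[p] += 1
        t_last[p] = tau
        arrivals[p].append(tau)

    # initial token enters the initially marked (source) place at trace start
    for p, k in net.initial_marking.items():
        for _ in range(k):
            arrive(p, 0.0)

    def fire(t_name, tau):
        nonlocal missing
        inputs = net.in_places(t_name)
        if inputs:
            marked = [p for p in inputs if marking[p] > 0]
            if marked:
                chosen = max(marked, key=lambda p: (t_last[p], -place_idx[p]))
            else:
                chosen = inputs[0]
                marking[chosen] += 1  # missing-token insertion (not an arrival)
                missing += 1
            marking[chosen] -= 1
        for p in net.out_places(t_name):
            arrive(p, tau)

    if START in transitions:
        fire(START, 0.0)
    for e in events:
        name = e.name if e.name in transitions else OTHER
        if name not in transitions:
            raise ValueError(f"event {e.name!r} not in net vocabulary and no OTHER transition")
        fire(name, day(e.timestamp))
    return arrivals, t_last, marking, counts, missing, events[-1].timestamp, day(events[-1].timestamp)


def estimate_decay_rates(net: PetriNet, train_traces, beta: float = 1.0) -> dict:
    """Per-place decay rates ``alpha_p = beta / D_p`` from the training replay."""
    max_gap = {p: 0.0 for p in net.places}
    max_duration = 0.0
    for trace in train_traces:
        arrivals, *_ = _replay(net, trace)
        dur = (trace.events[trace.tss_marker_index].timestamp - trace.events[0].timestamp)
        max_duration = max(max_duration, dur.total_seconds() / DAY_S)
        for p, times in arrivals.items():
            if len(times) >= 2:
                gaps = np.diff(np.asarray(times))
                max_gap[p] = max(max_gap[p], float(gaps.max()))
    if max_duration <= 0.0:
        raise ValueError("zero-duration log: cannot estimate decay rates")
    alphas = {}
    for p in net.places:
        d = max_gap[p] if max_gap[p] > 0.0 else max_duration
        alphas[p] = beta / d
    return alphas


def replay_to_tss(net: PetriNet, trace: Trace, alphas: dict, beta: float = 1.0) -> TimedStateSample:
    """Replay one trace up to its marker and capture the timed state sample."""
    _, t_last, marking, counts, missing, taken_at, tau = _replay(net, trace, upto_marker=True)
    decay = np.zeros(len(net.places))
    cnt = np.zeros(len(net.places), dtype=int)
    mark = np.zeros(len(net.places), dtype=int)
    for i, p in enumerate(net.places):
        if t_last[p] is not None:
            decay[i] = max(0.0, beta - alphas[p] * (tau - t_last[p]))
        cnt[i] = counts[p]
        mark[i] = marking[p]
    return TimedStateSample(decay, cnt, mark, taken_at, missing)


def tss_matrix(
    traces,
    net: PetriNet,
    alphas: dict,
    beta: float = 1.0,
    include_counts: bool = True,
    include_marking: bool = True,
    normalize: bool = False,
    norm_params: tuple | None = None,
):
    """Stack timed state samples into a feature matrix.

    Columns are ``[decay || token_counts || marking]`` blocks over the net's
    canonical place order.  With ``normalize=True`` a per-column min-max
    transform is applied; its parameters are fit on the given matrix unless
    ``norm_params`` (from the training matrix) is supplied — test values may
    then fall outside [0, 1] but are never NaN.

    Returns ``(X, column_names, norm_params)``.
    """
    rows = [
        replay_to_tss(net, t, alphas, beta).vector(include_counts, include_marking)
        for t in traces
    ]
    X = np.vstack(rows) if rows else np.zeros((0, 0))
    names = [f"decay__{p}" for p in net.places]
    if include_counts:
        names += [f"count__{p}" for p in net.places]
    if include_marking:
        names += [f"marking__{p}" for p in net.places]
    if X.shape[1] != len(names):
        raise ValueError("inconsistent TSS dimensionality")
    if normalize:
        if norm_params is None:
            lo, hi = X.min(axis=0), X.max(axis=0)
        else:
            lo, hi = norm_params
        span = np.where(hi > lo, hi - lo, 1.0)
        X = (X - lo) / span
        norm_params = (lo, hi)
    return X, names, norm_params
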