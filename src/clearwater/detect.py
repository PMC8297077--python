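"""Clear-water-phase event detection and event summaries.

A CWP episode is a run of at least two consecutive week-to-week transitions
in which secchi depth strictly increases, chlorophyll-a strictly decreases,
and total zooplankton strictly increases; the candidate run is confirmed as
an event only if turbidity shows a net decrease from onset to end (the
"final determination" step). Runs are maximal and events are disjoint;
transitions across a missing week never qualify. Only the signs of
week-to-week differences matter, so detection is invariant to affine
rescaling of any single variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import SiteSeries, SeriesError


@dataclass
class CWPEvent:
    """One detected clear-water episode.

    onset_week/end_week index rows of the series; duration_weeks counts the
    qualifying transitions (a "2-week" event spans 3 observations). Deltas
    are end-week minus onset-week values.
    """

    site: str
    onset_week: int
    end_week: int
    duration_weeks: int
    delta_secchi: float
    delta_turbidity: float
    delta_chl_a: float
    delta_total_zoo: float
    delta_cladocera: float


@dataclass
class EventSummary:
    site: str
    n_events: int
    counts_by_duration: dict[int, int]
    mean_delta: dict[str, float | None]
    range_delta: dict[str, tuple[float, float] | None]


DELTA_VARS = {
    "delta_secchi": "secchi_depth",
    "delta_turbidity": "turbidity",
    "delta_chl_a": "chl_a",
    "delta_total_zoo": "total_zoo",
    "delta_cladocera": "cladocera",
}


def qualifying_transitions(series: SiteSeries) -> np.ndarray:
    """Boolean array over the n-1 week-to-week transitions.

    Transition t -> t+1 qualifies iff secchi strictly rises, chl-a strictly
    falls and total zooplankton strictly rises; strict inequalities, so ties
    break a run. Transitions across a gap (missing week) or involving
    missing values never qualify.
    """
    if len(series) < 2:
        raise SeriesError("need at least 2 weekly records")
    sd = series.column("secchi_depth")
    chl = series.column("chl_a")
    zoo = series.column("total_zoo")
    ok = (np.diff(sd) > 0) & (np.diff(chl) < 0) & (np.diff(zoo) > 0)
    ok &= ~series.gap_breaks()
    for x in (sd, chl, zoo):
        ok &= ~(np.isnan(x[:-1]) | np.isnan(x[1:]))
    return ok


def detect_events(
    series: SiteSeries,
    min_duration: int = 2,
    strict_turbidity: bool = False,
) -> list[CWPEvent]:
    """Detect CWP events as maximal qualifying runs confirmed by turbidity.

    ``strict_turbidity=True`` additionally demands a turbidity decrease at
    every transition of the run instead of only net over the event.
    """
    q = qualifying_transitions(series)
    turb = series.column("turbidity")
    events: list[CWPEvent] = []
    i, n = 0, len(q)
    while i < n:
        if not q[i]:
            i += 1
            continue
        j = i
        while j < n and q[j]:
            j += 1
        run_len = j - i           # transitions i .. j-1, weeks i .. j
        if run_len >= min_duration:
            onset, end = i, j
            net_ok = turb[end] < turb[onset]
            if strict_turbidity:
                net_ok = bool(np.all(np.diff(turb[onset : end + 1]) < 0))
            if net_ok:
                deltas = {
                    name: float(series.column(col)[end] - series.column(col)[onset])
                    for name, col in DELTA_VARS.items()
                }
                events.append(
                    CWPEvent(
                        site=series.site,
                        onset_week=onset,
                        end_week=end,
                        duration_weeks=run_len,
                        **deltas,
                    )
                )
        i = j
    return events


def summarize_events(events: list[CWPEvent], series: SiteSeries) -> EventSummary:
    """Counts by duration and mean/min-max of each per-event delta."""
    counts: dict[int, int] = {}
    for ev in events:
        counts[ev.duration_weeks] = counts.get(ev.duration_weeks, 0) + 1
    mean_delta: dict[str, float | None] = {}
    range_delta: dict[str, tuple[float, float] | None] = {}
    for name in DELTA_VARS:
        vals = [getattr(ev, name) for ev in events]
        if vals:
            mean_delta[name] = float(np.mean(vals))
            range_delta[name] = (float(np.min(vals)), float(np.max(vals)))
        else:
            mean_delta[name] = None
            range_delta[name] = None
    return EventSummary(
        site=series.site,
        n_events=len(events),
        counts_by_duration=dict(sorted(counts.items())),
        mean_delta=mean_delta,
        range_delta=range_delta,
    )


def match_events(
    detected: list[CWPEvent],
    planted: list[tuple[int, int]],
    onset_tolerance: int = 1,
) -> tuple[float, float]:
    """(precision, recall) of detected vs planted (onset, end) events,
    matching greedily on onset within ``onset_tolerance`` weeks."""
    unmatched = list(planted)
    tp = 0
    for ev in detected:
        for k, (a, _b) in enumerate(unmatched):
            if abs(ev.onset_week - a) <= onset_tolerance:
                tp += 1
                unmatched.pop(k)
                break
    precision = tp / len(detected) if detected else (1.0 if not planted else 0.0)
    recall = tp / len(planted) if planted else 1.0
    return precision, recall
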