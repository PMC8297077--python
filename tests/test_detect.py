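import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from clearwater.detect import detect_events, match_events, qualifying_transitions, summarize_events
from clearwater.series import SeriesError, SiteSeries
from conftest import make_series


def test_all_monotone_case():
    s = make_series(
        secchi_depth=[1.0, 1.5, 2.0],
        chl_a=[10, 8, 6],
        rotifera=[50, 80, 120],
    )
    assert qualifying_transitions(s).tolist() == [True, True]


def test_reversed_directions():
    s = make_series(secchi_depth=[2.0, 1.5], chl_a=[6, 8], rotifera=[120, 80])
    assert qualifying_transitions(s).tolist() == [False]


def test_strict_inequality_all_sign_patterns():
    """Enumerate every up/flat-or-down combination of the three variables:
    only the strict (+, -, +) pattern qualifies, ties never do."""
    for d_sd, d_chl, d_zoo in itertools.product([-1, 0, 1], repeat=3):
        s = make_series(
            secchi_depth=[2.0, 2.0 + 0.5 * d_sd],
            chl_a=[10.0, 10.0 + d_chl],
            rotifera=[50.0, 50.0 + 10 * d_zoo],
        )
        expected = d_sd > 0 and d_chl < 0 and d_zoo > 0
        assert qualifying_transitions(s).tolist() == [expected], (d_sd, d_chl, d_zoo)


def test_too_short_series_rejected():
    s = make_series(secchi_depth=[1.0])
    with pytest.raises(SeriesError):
        qualifying_transitions(s)


def test_hand_enumerated_event():
    s = make_series(
        secchi_depth=[1.0, 1.5, 2.0, 1.8],
        chl_a=[10, 8, 6, 7],
        rotifera=[50, 80, 120, 90],
        turbidity=[3.0, 2.5, 2.0, 2.2],
    )
    events = detect_events(s)
    assert len(events) == 1
    ev = events[0]
    assert (ev.onset_week, ev.end_week, ev.duration_weeks) == (0, 2, 2)
    assert ev.delta_secchi == pytest.approx(1.0)
    assert ev.delta_turbidity == pytest.approx(-1.0)
    assert ev.delta_chl_a == pytest.approx(-4.0)


def test_turbidity_net_increase_vetoes():
    s = make_series(
        secchi_depth=[1.0, 1.5, 2.0],
        chl_a=[10, 8, 6],
        rotifera=[50, 80, 120],
        turbidity=[2.0, 1.5, 2.5],
    )
    assert detect_events(s) == []


def test_strict_turbidity_variant():
    # net decrease but one up-tick inside the run
    s = make_series(
        secchi_depth=[1.0, 1.5, 2.0, 2.5],
        chl_a=[10, 8, 6, 5],
        rotifera=[50, 80, 120, 150],
        turbidity=[3.0, 2.0, 2.2, 1.5],
    )
    assert len(detect_events(s)) == 1
    assert detect_events(s, strict_turbidity=True) == []


def test_maximal_run_single_event():
    """Three consecutive qualifying transitions are one 3-week event, not
    two overlapping 2-week events."""
    s = make_series(
        secchi_depth=[1.0, 1.4, 1.8, 2.2],
        chl_a=[10, 9, 8, 7],
        rotifera=[50, 60, 70, 80],
        turbidity=[3.0, 2.8, 2.6, 2.4],
    )
    events = detect_events(s)
    assert len(events) == 1
    assert events[0].duration_weeks == 3


def test_events_disjoint_and_no_gap_spanning():
    dates = pd.date_range("2015-03-02", periods=6, freq="7D").tolist()
    dates[3:] = [d + pd.Timedelta(days=21) for d in dates[3:]]  # gap after week 2
    df = pd.DataFrame(
        {
            "date": dates,
            "secchi_depth": [1.0, 1.5, 2.0, 2.5, 3.0, 3.5],
            "chl_a": [10, 8, 6, 5, 4, 3],
            "turbidity": [3.0, 2.5, 2.0, 1.8, 1.5, 1.2],
            "rotifera": [50, 80, 120, 150, 180, 210],
            "cladocera": [20.0] * 6,
            "copepoda": [30.0] * 6,
        }
    )
    s = SiteSeries("g", df)
    events = detect_events(s)
    # the qualifying run is broken at the 4-week gap: weeks 0-2 and 3-5
    assert [(e.onset_week, e.end_week) for e in events] == [(0, 2), (3, 5)]
    spans = [set(range(e.onset_week, e.end_week + 1)) for e in events]
    assert not (spans[0] & spans[1])


@settings(max_examples=40, derandomize=True)
@given(
    a=st.floats(0.01, 100.0),
    b=st.floats(-50.0, 50.0),
    var=st.sampled_from(["secchi_depth", "chl_a", "total_zoo_proxy", "turbidity"]),
)
def test_affine_invariance(a, b, var):
    """Rescaling any single variable by x -> a*x + b (a > 0) leaves the
    detected events unchanged: only difference signs matter."""
    base = dict(
        secchi_depth=np.array([1.0, 1.5, 2.0, 1.8, 1.9, 2.4, 3.0]),
        chl_a=np.array([10, 8, 6, 7, 9, 7.5, 6.0]),
        rotifera=np.array([50, 80, 120, 90, 85, 95, 130.0]),
        turbidity=np.array([3.0, 2.5, 2.0, 2.2, 2.4, 2.1, 1.7]),
    )
    ref = [
        (e.onset_week, e.end_week) for e in detect_events(make_series(**base))
    ]
    mod = dict(base)
    key = "rotifera" if var == "total_zoo_proxy" else var
    mod[key] = a * base[key] + b
    if (mod[key] < 0).any():
        mod[key] -= mod[key].min()  # keep series valid; shift preserves diffs
    got = [(e.onset_week, e.end_week) for e in detect_events(make_series(**mod))]
    assert got == ref


def test_summaries_two_point_mean():
    s = make_series(
        secchi_depth=[1.0, 1.3, 1.6, 1.5, 2.0, 2.4, 2.8],
        chl_a=[10, 9, 8, 9, 8, 7, 6],
        rotifera=[50, 60, 70, 65, 70, 80, 90],
        turbidity=[3.0, 2.8, 2.6, 2.7, 2.5, 2.3, 2.1],
    )
    events = detect_events(s)
    assert len(events) == 2
    summ = summarize_events(events, s)
    assert summ.n_events == 2
    d = [e.delta_secchi for e in events]
    assert summ.mean_delta["delta_secchi"] == pytest.approx(np.mean(d))
    lo, hi = summ.range_delta["delta_secchi"]
    assert lo <= summ.mean_delta["delta_secchi"] <= hi


def test_summary_empty_events():
    s = make_series(secchi_depth=[1.0, 1.0, 1.0])
    summ = summarize_events([], s)
    assert summ.n_events == 0
    assert summ.counts_by_duration == {}
    assert summ.mean_delta["delta_secchi"] is None
    assert summ.range_delta["delta_chl_a"] is None


def test_match_events_tolerance():
    s = make_series(
        secchi_depth=[1.0, 1.5, 2.0, 1.8],
        chl_a=[10, 8, 6, 7],
        rotifera=[50, 80, 120, 90],
        turbidity=[3.0, 2.5, 2.0, 2.2],
    )
    events = detect_events(s)
    assert match_events(events, [(1, 3)]) == (1.0, 1.0)   # off by one week
    assert match_events(events, [(2, 4)]) == (0.0, 0.0)   # off by two
    assert match_events([], []) == (1.0, 1.0)
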