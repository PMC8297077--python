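"""Pearson correlation screening and the before/after paired design.

Correlations use pairwise deletion of missing weeks; the paired t-test
compares the value at each event's onset week ("before") with its end week
("after"), one pair per event. Statistics are computed by their closed
forms (so the degenerate-case conventions below are explicit); p-values
come from the t distribution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .detect import CWPEvent
from .series import SiteSeries

log = logging.getLogger(__name__)


class StatsError(ValueError):
    pass


@dataclass
class CorrelationEntry:
    var_x: str
    var_y: str
    r: float | None
    n: int
    p_two_sided: float | None
    undefined: bool = False   # zero variance or too few complete pairs


@dataclass
class PairedComparison:
    variable: str
    site: str
    pairs: list[tuple[float, float]]
    mean_before: float
    sd_before: float
    mean_after: float
    sd_after: float
    t: float
    df: int
    p_two_sided: float
    degenerate: bool = False  # sd(d) == 0 with nonzero mean difference


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Product-moment r and two-sided p via the t transform (n-2 df) on
    complete pairs. Raises StatsError on <3 pairs or zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise StatsError("need >= 3 complete pairs")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = float(dx @ dx)
    sy = float(dy @ dy)
    if sx == 0.0 or sy == 0.0:
        raise StatsError("zero variance")
    r = float(dx @ dy) / math.sqrt(sx * sy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1 - r * r))
        p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return r, p, n


def pearson_matrix(
    data: SiteSeries | pd.DataFrame,
    variables: list[str],
) -> list[CorrelationEntry]:
    """All unordered variable pairs (plus unit diagonal), pairwise deletion.

    Zero-variance or under-sampled pairs are returned flagged undefined
    rather than propagating NaN.
    """
    df = data.data if isinstance(data, SiteSeries) else data
    out: list[CorrelationEntry] = []
    for i, vx in enumerate(variables):
        for vy in variables[i:]:
            if vx == vy:
                n = int((~df[vx].isna()).sum())
                out.append(CorrelationEntry(vx, vy, 1.0, n, 0.0))
                continue
            try:
                r, p, n = pearson(df[vx].to_numpy(float), df[vy].to_numpy(float))
                out.append(CorrelationEntry(vx, vy, r, n, p))
            except StatsError:
                ok = ~(df[vx].isna() | df[vy].isna())
                out.append(CorrelationEntry(vx, vy, None, int(ok.sum()), None, True))
    return out


def extract_pairs(
    events: list[CWPEvent],
    series: SiteSeries,
    variable: str,
) -> list[tuple[float, float]]:
    """One (before, after) pair per event: onset-week vs end-week value.

    Events touching a missing value are skipped with a logged warning.
    """
    vals = series.column(variable)
    pairs: list[tuple[float, float]] = []
    for ev in events:
        b, a = vals[ev.onset_week], vals[ev.end_week]
        if np.isnan(b) or np.isnan(a):
            log.warning(
                "site %s: skipping event at week %d, missing %s",
                series.site, ev.onset_week, variable,
            )
            continue
        pairs.append((float(b), float(a)))
    return pairs


def extract_window_pairs(
    events: list[CWPEvent],
    series: SiteSeries,
    variable: str,
    window: int,
) -> list[tuple[float, float]]:
    """Alternative pairing: means of the k weeks before onset and after end."""
    vals = series.column(variable)
    pairs = []
    for ev in events:
        pre = vals[max(0, ev.onset_week - window) : ev.onset_week]
        post = vals[ev.end_week + 1 : ev.end_week + 1 + window]
        if len(pre) == 0 or len(post) == 0 or np.isnan(pre).all() or np.isnan(post).all():
            log.warning("site %s: skipping event at week %d (window empty)",
                        series.site, ev.onset_week)
            continue
        pairs.append((float(np.nanmean(pre)), float(np.nanmean(post))))
    return pairs


def paired_t_test(
    pairs: list[tuple[float, float]],
    variable: str = "",
    site: str = "",
) -> PairedComparison:
    """Paired t on differences d = after - before; two-sided p, df = n-1.

    Conventions: sd(d)=0 with mean(d)=0 gives t=0, p=1 (no change);
    sd(d)=0 with mean(d)!=0 is flagged degenerate with t=+-inf, p=0.
    """
    n = len(pairs)
    if n < 2:
        raise StatsError("paired t-test needs at least 2 pairs")
    before = np.array([p[0] for p in pairs], dtype=float)
    after = np.array([p[1] for p in pairs], dtype=float)
    d = after - before
    md = float(d.mean())
    sd_d = float(d.std(ddof=1))
    degenerate = False
    if sd_d == 0.0:
        if md == 0.0:
            t, p = 0.0, 1.0
        else:
            t, p = math.copysign(math.inf, md), 0.0
            degenerate = True
    else:
        t = md / (sd_d / math.sqrt(n))
        p = 2.0 * float(sps.t.sf(abs(t), n - 1))
    return PairedComparison(
        variable=variable,
        site=site,
        pairs=list(pairs),
        mean_before=float(before.mean()),
        sd_before=float(before.std(ddof=1)),
        mean_after=float(after.mean()),
        sd_after=float(after.std(ddof=1)),
        t=t,
        df=n - 1,
        p_two_sided=p,
        degenerate=degenerate,
    )


def before_after_table(
    events_by_site: dict[str, list[CWPEvent]],
    series_by_site: dict[str, SiteSeries],
    variables: list[str],
    window: int = 0,
) -> pd.DataFrame:
    """Per-site before/after comparison table for the given variables.

    ``window=0`` pairs onset vs end week; ``window=k`` pairs k-week
    pre/post means. Sites with fewer than 2 usable events are skipped.
    """
    rows = []
    for site, series in series_by_site.items():
        events = events_by_site.get(site, [])
        for var in variables:
            if window > 0:
                pairs = extract_window_pairs(events, series, var, window)
            else:
                pairs = extract_pairs(events, series, var)
            if len(pairs) < 2:
                continue
            c = paired_t_test(pairs, variable=var, site=site)
            rows.append(
                {
                    "variable": var,
                    "site": site,
                    "n_events": len(pairs),
                    "mean_before": c.mean_before,
                    "sd_before": c.sd_before,
                    "mean_after": c.mean_after,
                    "sd_after": c.sd_after,
                    "t": c.t,
                    "df": c.df,
                    "p": c.p_two_sided,
                    "significant_05": c.p_two_sided < 0.05,
                }
            )
    return pd.DataFrame(rows)
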