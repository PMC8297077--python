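"""Delimited-text interchange: weekly series, daily hydrology, ground truth,
and network exports (GraphML / DOT)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import columns as C
from .bayes import BayesNet
from .series import SiteSeries
from .synthetic import GroundTruth


class ParseError(ValueError):
    pass


def read_weekly_csv(path: str | Path) -> dict[str, SiteSeries]:
    """Read a weekly CSV (one row per site-week, ISO-8601 dates) into
    per-site series. Headers may use canonical names or the standard
    abbreviations (SD, TUR, PRECI, ...). Missing cells stay missing.

    Raises ParseError naming the offending column or row for unknown
    headers, unparseable dates, or negative concentrations.
    """
    path = Path(path)
    df = pd.read_csv(path)
    rename = {}
    for col in df.columns:
        try:
            rename[col] = C.canonical_name(col)
        except KeyError:
            raise ParseError(f"{path.name}: unknown column {col!r}") from None
    df = df.rename(columns=rename)
    if C.DATE not in df.columns:
        raise ParseError(f"{path.name}: no date column")
    try:
        df[C.DATE] = pd.to_datetime(df[C.DATE], format="ISO8601")
    except (ValueError, TypeError):
        parsed = pd.to_datetime(df[C.DATE], errors="coerce")
        bad = int(parsed.isna().idxmax())
        raise ParseError(f"{path.name}: unparseable date at row {bad + 2}") from None
    for col in C.NON_NEGATIVE:
        if col in df.columns:
            vals = df[col].to_numpy(dtype=float)
            neg = np.flatnonzero(vals < 0)
            if neg.size:
                raise ParseError(
                    f"{path.name}: negative {col} at row {int(neg[0]) + 2}"
                )
    if C.SITE not in df.columns:
        df[C.SITE] = "site_1"
    out = {}
    for site, sub in df.groupby(C.SITE, sort=False):
        out[str(site)] = SiteSeries(str(site), sub.drop(columns=[C.SITE]))
    return out


def write_weekly_csv(series: dict[str, SiteSeries] | SiteSeries, path: str | Path) -> None:
    """Write per-site weekly series as one CSV with a site column."""
    if isinstance(series, SiteSeries):
        series = {series.site: series}
    frames = []
    for site, s in series.items():
        df = s.data.copy()
        df.insert(0, C.SITE, site)
        frames.append(df)
    allf = pd.concat(frames, ignore_index=True)
    allf[C.DATE] = allf[C.DATE].dt.strftime("%Y-%m-%d")
    allf.to_csv(path, index=False)


def write_daily_csv(daily: dict[str, pd.DataFrame], path: str | Path) -> None:
    frames = []
    for site, df in daily.items():
        d = df.copy()
        d.insert(0, C.SITE, site)
        frames.append(d)
    allf = pd.concat(frames, ignore_index=True)
    allf["date"] = pd.to_datetime(allf["date"]).dt.strftime("%Y-%m-%d")
    allf.to_csv(path, index=False)


def read_daily_csv(path: str | Path) -> dict[str, pd.DataFrame]:
    df = pd.read_csv(path, parse_dates=["date"])
    if C.SITE not in df.columns:
        return {"site_1": df}
    return {str(s): sub.drop(columns=[C.SITE]).reset_index(drop=True)
            for s, sub in df.groupby(C.SITE, sort=False)}


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    payload = {
        "events": [list(e) for e in gt.events],
        "true_dag": [list(e) for e in gt.true_dag],
        "generator_params": gt.generator_params,
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        events=[(s, int(a), int(b)) for s, a, b in payload["events"]],
        true_dag=[(u, v) for u, v in payload["true_dag"]],
        generator_params=payload["generator_params"],
    )


def network_to_graphml(net: BayesNet, path: str | Path) -> None:
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(sorted(net.nodes))
    g.add_edges_from(sorted(net.edges))
    nx.write_graphml(g, path)


def network_to_dot(net: BayesNet, path: str | Path) -> None:
    lines = ["digraph bayesnet {"]
    for v in sorted(net.nodes):
        lines.append(f'  "{v}";')
    for u, v in sorted(net.edges):
        lines.append(f'  "{u}" -> "{v}";')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


def cpts_to_json(net: BayesNet, path: str | Path) -> None:
    payload = {
        "ess": net.ess,
        "nodes": net.nodes,
        "card": net.card,
        "parents": {v: list(ps) for v, ps in net.parents.items()},
        "cpts": {v: net.cpts[v].tolist() for v in net.nodes} if net.cpts else {},
    }
    Path(path).write_text(json.dumps(payload, indent=2))
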