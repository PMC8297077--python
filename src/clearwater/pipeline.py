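"""End-to-end orchestration: simulate or ingest, summarize hydrology,
detect clear-water phases, run the before/after and correlation statistics,
and learn per-site plus pooled tier-constrained networks.

The report bundle is deterministic for a fixed config: re-running with the
same config and seed reproduces every output byte for byte (the manifest
records the config hash and seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import columns as C
from . import io as cw_io
from .bayes import (
    fit_cpts,
    k_fold_validate,
    learn_structure,
    sensitivity_analysis,
    strength_of_influence,
)
from .detect import CWPEvent, detect_events, summarize_events
from .discretize import DiscretizationError, discretize_frame
from .hydromet import seasonal_summary
from .series import SiteSeries
from .stats import before_after_table, pearson_matrix
from .synthetic import SimParams, SiteArchetype, default_sites, emulate_dataset

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Run configuration. Exactly one of ``simulate`` / ``inputs`` is set."""

    output_dir: str
    seed: int | None = None
    simulate: dict | None = None          # SimParams field overrides
    inputs: dict | None = None            # {"weekly": path, "daily": path}
    detection: dict = field(default_factory=dict)   # strict_turbidity, pairing_window
    network: dict = field(default_factory=dict)     # ess, restarts, max_parents, k, metric
    winter_gaps: bool = False

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yml", ".yaml"):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        if "output_dir" not in raw:
            raise ConfigError("missing required field 'output_dir'")
        return cls(**raw)

    def validate(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ConfigError("exactly one of 'simulate' or 'inputs' must be set")
        if self.simulate is not None and self.seed is None:
            raise ConfigError("'seed' is mandatory when simulating")

    def sim_params(self) -> SimParams:
        over = dict(self.simulate or {})
        if "sites" in over:
            over["sites"] = [SiteArchetype(**s) for s in over["sites"]]
        params = SimParams(seed=self.seed or 0, **over)
        params.validate()
        return params

    def canonical_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)


TABLE2_VARIABLES = ["secchi_depth", "turbidity", "total_zoo", "chl_a", "tn", "tp", "hrt"]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle into config.output_dir.

    Returns the manifest dict. On a stage failure the partial outputs
    written by this run are removed and PipelineError names the stage.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def out(name: str) -> Path:
        p = outdir / name
        written.append(p)
        return p

    stage = "setup"
    try:
        stage = "input"
        ground_truth = None
        if config.simulate is not None:
            params = config.sim_params()
            weekly, daily, ground_truth = emulate_dataset(
                params, winter_gaps=config.winter_gaps
            )
            cw_io.write_weekly_csv(weekly, out("weekly.csv"))
            cw_io.write_daily_csv(daily, out("daily.csv"))
            cw_io.write_ground_truth(ground_truth, out("ground_truth.json"))
        else:
            weekly = cw_io.read_weekly_csv(config.inputs["weekly"])
            daily = (
                cw_io.read_daily_csv(config.inputs["daily"])
                if config.inputs.get("daily")
                else {}
            )

        stage = "hydromet"
        if daily:
            hydro = pd.concat(
                [s.assign(site=k) for k, s in daily.items()], ignore_index=True
            )
            summaries = []
            for site, sub in hydro.groupby("site", sort=False):
                summ = seasonal_summary(sub.drop(columns=["site"]))
                summ.insert(0, "site", site)
                summaries.append(summ)
            pd.concat(summaries, ignore_index=True).to_csv(
                out("hydro_summary.csv"), index=False
            )

        stage = "detect"
        det = config.detection
        events_by_site = {
            site: detect_events(
                s,
                strict_turbidity=bool(det.get("strict_turbidity", False)),
            )
            for site, s in weekly.items()
        }
        rows = []
        for site, events in events_by_site.items():
            for ev in events:
                rows.append(dataclasses.asdict(ev))
        event_cols = [f.name for f in dataclasses.fields(CWPEvent)]
        pd.DataFrame(rows, columns=event_cols).to_csv(out("events.csv"), index=False)
        summaries = {
            site: dataclasses.asdict(summarize_events(events_by_site[site], s))
            for site, s in weekly.items()
        }
        out("event_summary.json").write_text(
            json.dumps(summaries, indent=2, sort_keys=True, default=str)
        )

        stage = "stats"
        table2 = before_after_table(
            events_by_site,
            weekly,
            TABLE2_VARIABLES,
            window=int(det.get("pairing_window", 0)),
        )
        table2.to_csv(out("before_after.csv"), index=False)
        corr_rows = []
        pooled = pd.concat([s.data for s in weekly.values()], ignore_index=True)
        scopes = {"all": pooled, **{k: s.data for k, s in weekly.items()}}
        corr_vars = [v for v in C.MODELED_VARIABLES if v in pooled.columns]
        for scope, df in scopes.items():
            for e in pearson_matrix(df, corr_vars):
                corr_rows.append(
                    {
                        "scope": scope,
                        "var_x": e.var_x,
                        "var_y": e.var_y,
                        "r": e.r,
                        "n": e.n,
                        "p": e.p_two_sided,
                        "undefined": e.undefined,
                    }
                )
        pd.DataFrame(corr_rows).to_csv(out("correlations.csv"), index=False)

        stage = "network"
        netcfg = config.network
        ess = float(netcfg.get("ess", 50.0))
        restarts = int(netcfg.get("restarts", 5))
        max_parents = int(netcfg.get("max_parents", 8))
        metric = netcfg.get("metric", "euclidean")
        kfold = int(netcfg.get("k", 0))
        tiers = dict(C.DEFAULT_TIERS)
        net_seed = config.seed or 0
        network_report = {}
        for scope, df in scopes.items():
            try:
                disc, _maps = discretize_frame(df, corr_vars)
            except DiscretizationError as err:
                log.warning("scope %s: skipping network (%s)", scope, err)
                continue
            net = learn_structure(
                disc,
                tiers=tiers,
                max_parents=max_parents,
                ess=ess,
                restarts=restarts,
                seed=net_seed,
            )
            net = fit_cpts(net, disc)
            cw_io.network_to_graphml(net, out(f"network_{scope}.graphml"))
            cw_io.network_to_dot(net, out(f"network_{scope}.dot"))
            cw_io.cpts_to_json(net, out(f"network_{scope}_cpts.json"))
            sens = {
                target: sensitivity_analysis(net, target).ranking
                for target in ("secchi_depth", "turbidity")
            }
            strengths = [
                dataclasses.asdict(s)
                for s in strength_of_influence(net, disc, metric=metric)
            ]
            entry = {
                "edges": sorted(net.edges),
                "sensitivity": sens,
                "strength_of_influence": strengths,
            }
            if kfold >= 2:
                accs, mean_acc = k_fold_validate(
                    disc,
                    "secchi_depth",
                    tiers=tiers,
                    k=kfold,
                    seed=net_seed,
                    ess=ess,
                    restarts=max(1, restarts // 2),
                    max_parents=max_parents,
                )
                entry["kfold"] = {"k": kfold, "fold_accuracy": accs, "mean": mean_acc}
            network_report[scope] = entry
        out("networks.json").write_text(
            json.dumps(network_report, indent=2, sort_keys=True)
        )

        stage = "manifest"
        manifest = {
            "config_sha256": hashlib.sha256(
                config.canonical_json().encode()
            ).hexdigest(),
            "seed": config.seed,
            "version": __version__,
            "sites": sorted(weekly),
            "n_weeks": {site: len(s) for site, s in sorted(weekly.items())},
            "n_events": {site: len(ev) for site, ev in sorted(events_by_site.items())},
            "outputs": sorted(p.name for p in written) + ["manifest.json"],
        }
        out("manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest
    except Exception as err:
        for p in written:
            p.unlink(missing_ok=True)
        if isinstance(err, PipelineError):
            raise
        raise PipelineError(stage, err) from err
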