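"""Seeded synthetic limnology: daily hydrology, weekly plankton, ground truth.

Generates the study conditions the analysis assumes — a monsoon-forced
reservoir system (about 63% of annual precipitation in June–August, HRT of
order 10–20 d, sluice-gate level control) sampled weekly at four archetype
sites, with spring Cladocera emergence and stochastic grazing pulses that
plant clear-water-phase (CWP) episodes. Every planted episode and the true
generating dependency graph are returned as :class:`GroundTruth`, so event
detection and network structure learning can be scored against a known
answer.

Design notes
------------
The weekly plankton skeleton is a difference-equation system chosen so the
qualitative relationships of temperate reservoir limnology hold with the
correct sign (Cladocera–temperature positive, turbidity–secchi negative,
TP–turbidity positive, precipitation shortens HRT). Phytoplankton growth is
temperature-driven with Monod nutrient limitation on a deterministic
seasonal TP climatology; because of that, on noise-free runs the detection
variables move monotonically with water temperature between pulses, and the
planted pulses are the only episodes satisfying the CWP rule. Grazing
pulses deplete phytoplankton and suspended seston (filter feeding) while
zooplankton spike, which is exactly the CWP signature.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .series import SiteSeries


class ParameterError(ValueError):
    """Raised for invalid simulation parameters."""


# ---------------------------------------------------------------------------
# parameter types

@dataclass(frozen=True)
class SiteArchetype:
    """One monitoring site's physical character.

    label : one of lake_deep, lake_shallow, river, stream_shallow
    mean_depth : m, site average depth (upper bound for secchi depth)
    hrt_scale : multiplier on the reservoir volume seen by this site
    cladocera_favorability : 0..1, how strongly the site supports Cladocera
    """

    label: str
    mean_depth: float
    hrt_scale: float = 1.0
    cladocera_favorability: float = 0.8

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ParameterError(f"{self.label}: mean_depth must be > 0")
        if self.hrt_scale <= 0:
            raise ParameterError(f"{self.label}: hrt_scale must be > 0")


def default_sites() -> list[SiteArchetype]:
    """Four archetypes: deep dam-front lake, shallower lake-like reach,
    river confluence, small shallow stream mouth."""
    return [
        SiteArchetype("lake_deep", mean_depth=21.0, hrt_scale=1.0,
                      cladocera_favorability=0.9),
        SiteArchetype("lake_shallow", mean_depth=9.0, hrt_scale=0.9,
                      cladocera_favorability=0.8),
        SiteArchetype("river", mean_depth=8.0, hrt_scale=0.7,
                      cladocera_favorability=0.5),
        SiteArchetype("stream_shallow", mean_depth=2.5, hrt_scale=1.1,
                      cladocera_favorability=0.85),
    ]


@dataclass
class SimParams:
    """Simulation parameters. Identical parameters (including seed) give
    bit-identical output.

    years : whole simulated calendar years (52 sampled weeks each)
    summer_precip_fraction : expected June–August share of annual rain
    temp_range : (min, max) water temperature °C of the seasonal sinusoid
    reservoir_volume : m^3, level-control target storage per unit hrt_scale
    baseflow : m^3 s^-1, dry-weather inflow
    precip_scale : multiplier on rainfall amounts (0 = no rain)
    noise_sd : relative measurement noise (lognormal sigma); 0 = noise-free
    grazing_pulse_rate : expected CWP-triggering grazing pulses per year
    pulses_per_site : exact pulse count per site, overriding the rate
    """

    years: int = 2
    sites: list[SiteArchetype] = field(default_factory=default_sites)
    summer_precip_fraction: float = 0.63
    temp_range: tuple[float, float] = (2.0, 28.0)
    reservoir_volume: float = 2.44e8
    baseflow: float = 150.0
    precip_scale: float = 1.0
    noise_sd: float = 0.05
    grazing_pulse_rate: float = 4.5
    pulses_per_site: int | None = None
    seed: int = 0
    start_year: int = 2015

    def validate(self) -> None:
        if self.years < 1:
            raise ParameterError("years must be >= 1")
        if not 0.0 < self.summer_precip_fraction < 1.0:
            raise ParameterError("summer_precip_fraction must be in (0, 1)")
        if self.reservoir_volume <= 0:
            raise ParameterError("reservoir_volume must be > 0")
        if self.baseflow <= 0:
            raise ParameterError("baseflow must be > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.precip_scale < 0:
            raise ParameterError("precip_scale must be >= 0")
        if self.grazing_pulse_rate < 0:
            raise ParameterError("grazing_pulse_rate must be >= 0")
        if not self.sites:
            raise ParameterError("at least one site is required")


@dataclass
class GroundTruth:
    """Planted events, the generating DAG, and a parameter echo."""

    events: list[tuple[str, int, int]]          # (site, onset_week, end_week)
    true_dag: list[tuple[str, str]]             # directed edges
    generator_params: dict

    def events_for(self, site: str) -> list[tuple[int, int]]:
        return [(a, b) for s, a, b in self.events if s == site]


#: causal edges actually wired into the generator, tier-consistent
TRUE_DAG: list[tuple[str, str]] = [
    ("precipitation", "hrt"),
    ("precipitation", "nh4_n"),
    ("precipitation", "po4_p"),
    ("precipitation", "dtn"),
    ("precipitation", "dtp"),
    ("precipitation", "ss"),
    ("precipitation", "turbidity"),
    ("dtn", "tn"),
    ("dtp", "tp"),
    ("water_temp", "cyanobacteria"),
    ("water_temp", "diatoms"),
    ("water_temp", "green_algae"),
    ("water_temp", "other_algae"),
    ("water_temp", "rotifera"),
    ("water_temp", "cladocera"),
    ("water_temp", "copepoda"),
    ("cladocera", "total_phyto"),
    ("cladocera", "ss"),
    ("cyanobacteria", "total_phyto"),
    ("diatoms", "total_phyto"),
    ("green_algae", "total_phyto"),
    ("other_algae", "total_phyto"),
    ("rotifera", "total_zoo"),
    ("cladocera", "total_zoo"),
    ("copepoda", "total_zoo"),
    ("rotifera", "rotifera_ra"),
    ("cladocera", "cladocera_ra"),
    ("copepoda", "copepoda_ra"),
    ("total_phyto", "chl_a"),
    ("total_phyto", "turbidity"),
    ("ss", "turbidity"),
    ("chl_a", "secchi_depth"),
    ("turbidity", "secchi_depth"),
]

# one block of generator coefficients (kept together deliberately)
COEFF = dict(
    wet_prob=0.30,            # non-summer wet-day probability
    wet_prob_summer=0.45,     # summer wet-day probability
    gamma_shape=0.7,          # daily rainfall gamma shape
    annual_precip_mm=950.0,   # target expected annual total
    runoff_coeff=16.0,        # m^3 s^-1 per mm of routed rain
    runoff_decay_d=3.0,       # runoff recession e-folding, days
    level_relax_d=2.0,        # storage relaxation toward target, days
    base_level_m=25.2,        # reference water level
    tp_base=0.018,            # mg L^-1
    tp_precip=0.012,          # TP gain per mm of weekly antecedent rain
    tn_base=1.8,              # mg L^-1
    tn_precip=0.004,
    phyto_eq=3000.0,          # cells mL^-1 at 15 °C before limitation
    phyto_temp=0.09,          # per-°C log growth of the equilibrium
    phyto_relax=0.25,         # weekly memory weight (0 = instant tracking)
    monod_k=0.010,            # mg L^-1 half-saturation on climatological TP
    graze_factor=0.40,        # weekly phytoplankton survival during a pulse
    chl_per_cell=0.004,       # mg m^-3 per cells mL^-1
    ss_base=4.0,              # mg L^-1
    ss_precip=0.010,          # relative gain per mm of weekly rain
    ss_precip_cap=150.0,      # mm cap on the storm response
    ss_clarify=0.55,          # weekly SS survival during a pulse
    turb_base=0.6,            # NTU
    turb_ss=0.25,             # NTU per mg L^-1 SS
    turb_phyto=4.0e-4,        # NTU per cells mL^-1
    turb_spate=0.08,          # NTU per unit relative inflow spate (capped 3)
    secchi_c0=6.0,            # clarity scale
    rot_base=60.0,            # Ind L^-1 at 15 °C
    rot_temp=0.08,
    cop_base=25.0,
    cop_temp=0.05,
    clad_base=40.0,           # Ind L^-1 asymptote, scaled by favorability
    clad_t50=12.0,            # °C, spring emergence midpoint
    clad_slope=3.0,           # °C, emergence steepness
    pulse_boost=(40.0, 90.0, 150.0),  # additive Cladocera Ind L^-1 per pulse week
    pulse_p3=0.12,            # probability a pulse lasts 3 transitions
    pulse_min_gap=5,          # weeks between pulse onsets
)


def _rng(seed: int, *labels: str) -> np.random.Generator:
    return np.random.default_rng(
        [seed] + [zlib.crc32(s.encode()) for s in labels]
    )


def _water_temp(doy: np.ndarray, tmin: float, tmax: float) -> np.ndarray:
    # minimum in mid-January, maximum in mid-July
    return tmin + (tmax - tmin) * 0.5 * (1 - np.cos(2 * np.pi * (doy - 15) / 365.25))


# ---------------------------------------------------------------------------
# daily forcing

def generate_daily_forcing(params: SimParams, site: SiteArchetype) -> pd.DataFrame:
    """Daily hydrology and water temperature for one site.

    Returns a DataFrame with columns date, precipitation (mm d^-1), inflow,
    outflow (m^3 s^-1), storage (m^3), water_level (m), water_temp (°C).

    Rainfall is a zero-inflated gamma whose summer (Jun–Aug) scale is set so
    the *expected* summer share equals ``params.summer_precip_fraction``.
    Inflow is baseflow plus an exponentially recessed runoff response;
    outflow relaxes storage toward the level-control target, emulating
    sluice-gate operation (water level stays within a narrow band).
    """
    params.validate()
    c = COEFF
    rng = _rng(params.seed, "forcing", site.label)

    start = np.datetime64(f"{params.start_year}-01-01")
    ndays = int(np.round(params.years * 365.25))
    dates = start + np.arange(ndays)
    months = pd.DatetimeIndex(dates).month.to_numpy()
    doy = pd.DatetimeIndex(dates).dayofyear.to_numpy()
    summer = (months >= 6) & (months <= 8)

    f = params.summer_precip_fraction
    p0, ps, k = c["wet_prob"], c["wet_prob_summer"], c["gamma_shape"]
    # expected non-summer total fixes the base scale; the summer scale
    # multiplier s makes the expected summer share equal f
    ktheta = c["annual_precip_mm"] * (1 - f) / (273.0 * p0)
    theta = ktheta / k
    s_mult = f * 273.0 * p0 / ((1 - f) * 92.0 * ps)

    wet = rng.random(ndays) < np.where(summer, ps, p0)
    amounts = rng.gamma(k, theta, ndays) * np.where(summer, s_mult, 1.0)
    precip = params.precip_scale * np.where(wet, amounts, 0.0)

    temp = _water_temp(doy, *params.temp_range)
    if params.noise_sd > 0:
        temp = temp + rng.normal(0.0, params.noise_sd * 4.0, ndays)

    decay = np.exp(-1.0 / c["runoff_decay_d"])
    runoff = np.empty(ndays)
    state = 0.0
    for i in range(ndays):
        state = state * decay + precip[i]
        runoff[i] = state
    inflow = params.baseflow + c["runoff_coeff"] * runoff * (1 - decay)

    target = params.reservoir_volume * site.hrt_scale
    relax = c["level_relax_d"] * 86400.0
    storage = np.empty(ndays)
    outflow = np.empty(ndays)
    stor = target
    for i in range(ndays):
        out = max(1e-6, inflow[i] + (stor - target) / relax)
        stor = stor + (inflow[i] - out) * 86400.0
        storage[i] = stor
        outflow[i] = out
    level = c["base_level_m"] + 5.0 * (storage / target - 1.0)

    return pd.DataFrame(
        {
            "date": dates,
            "precipitation": precip,
            "inflow": inflow,
            "outflow": outflow,
            "storage": storage,
            "water_level": level,
            "water_temp": temp,
        }
    )


# ---------------------------------------------------------------------------
# weekly plankton dynamics

def _plant_pulses(
    n_weeks: int,
    temp_weekly: np.ndarray,
    params: SimParams,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Choose pulse (onset_week, n_transitions) pairs, seasonally weighted
    toward the Cladocera window, non-overlapping with a minimum gap."""
    c = COEFF
    if params.pulses_per_site is not None:
        n_pulses = params.pulses_per_site
    else:
        n_pulses = rng.poisson(params.grazing_pulse_rate * params.years)
    lo, hi = 2, n_weeks - 5
    if n_pulses == 0 or hi <= lo:
        return []
    cand = np.arange(lo, hi)
    t = temp_weekly[cand]
    w = 1.0 / (1 + np.exp(-(t - 10.0) / 3.0)) * (1 - 1.0 / (1 + np.exp(-(t - 24.0) / 2.0)))
    w = w + 0.02
    pulses: list[tuple[int, int]] = []
    taken = np.zeros(n_weeks, dtype=bool)
    order = rng.choice(len(cand), size=len(cand), replace=False, p=w / w.sum())
    for idx in order:
        if len(pulses) == n_pulses:
            break
        w0 = int(cand[idx])
        length = 3 if rng.random() < c["pulse_p3"] else 2
        a, b = max(0, w0 - c["pulse_min_gap"]), min(n_weeks, w0 + length + c["pulse_min_gap"])
        if taken[a:b].any() or w0 + length >= n_weeks:
            continue
        taken[a:b] = True
        pulses.append((w0, length))
    return sorted(pulses)


def simulate_plankton(
    forcing: pd.DataFrame,
    site: SiteArchetype,
    params: SimParams,
    pulses: list[tuple[int, int]] | None = None,
) -> tuple[SiteSeries, list[tuple[int, int]]]:
    """Weekly plankton, nutrient and optical series from daily forcing.

    Returns the SiteSeries plus the planted pulses as (onset_week,
    end_week) pairs in weekly indices. ``pulses`` may be supplied to
    reproduce a specific planting; otherwise they are drawn from the
    seasonally weighted pulse process.
    """
    params.validate()
    c = COEFF
    if len(forcing) < 8 * 7:
        raise ParameterError("forcing must span at least 8 weeks")
    rng = _rng(params.seed, "plankton", site.label)

    # sampling day: every 7 days, starting on day 3 (midweek)
    samp = np.arange(3, len(forcing), 7)
    n = len(samp)
    dates = forcing["date"].to_numpy()[samp]
    temp = forcing["water_temp"].to_numpy()[samp]
    precip_d = forcing["precipitation"].to_numpy()
    p7 = np.array([precip_d[max(0, i - 6): i + 1].sum() for i in samp])
    storage = forcing["storage"].to_numpy()[samp]
    outflow = forcing["outflow"].to_numpy()[samp]
    inflow = forcing["inflow"].to_numpy()[samp]
    hrt = storage / (outflow * 86400.0)

    if pulses is None:
        pulses = _plant_pulses(n, temp, params, rng)
    in_pulse = np.zeros(n, dtype=int)  # pulse week index (1-based), 0 = none
    for w0, length in pulses:
        for j in range(1, length + 1):
            in_pulse[w0 + j] = j

    tmin, tmax = params.temp_range

    # nutrients: precipitation-driven dissolved pools, bulk pools derived
    dtp = c["tp_base"] * 0.6 * (1 + c["tp_precip"] * p7)
    tp = dtp / 0.6
    po4 = 0.4 * dtp
    dtn = c["tn_base"] * 0.85 * (1 + c["tn_precip"] * p7)
    tn = dtn / 0.85
    nh4 = 0.04 * (1 + c["tn_precip"] * 2 * p7)
    no3 = 0.6 * dtn

    # deterministic TP climatology drives Monod limitation, so baseline
    # phytoplankton is monotone in temperature (see module docstring)
    tp_clim = 0.012 + 0.02 * (temp - tmin) / (tmax - tmin)
    limit = tp_clim / (tp_clim + c["monod_k"])
    phyto_eq = c["phyto_eq"] * np.exp(c["phyto_temp"] * (temp - 15.0)) * limit

    rho = c["phyto_relax"]
    phyto = np.empty(n)
    phyto[0] = phyto_eq[0]
    for t in range(1, n):
        if in_pulse[t]:
            phyto[t] = phyto[t - 1] * c["graze_factor"]
        else:
            phyto[t] = phyto[t - 1] ** rho * phyto_eq[t] ** (1 - rho)

    # community split, smooth functions of temperature
    cy_w = np.exp(0.20 * (temp - 20.0))
    ba_w = np.exp(-0.10 * (temp - 10.0))
    ch_w = np.exp(0.05 * (temp - 15.0))
    etc_w = np.full(n, 0.25)
    tot_w = cy_w + ba_w + ch_w + etc_w
    cyano = phyto * cy_w / tot_w
    diatoms = phyto * ba_w / tot_w
    green = phyto * ch_w / tot_w
    other = phyto * etc_w / tot_w

    chl = c["chl_per_cell"] * phyto

    # zooplankton: temperature-monotone baselines, additive pulse boost
    rot = c["rot_base"] * np.exp(c["rot_temp"] * (temp - 15.0))
    cop = c["cop_base"] * np.exp(c["cop_temp"] * (temp - 15.0))
    fav = site.cladocera_favorability
    clad = fav * c["clad_base"] / (1 + np.exp(-(temp - c["clad_t50"]) / c["clad_slope"]))
    boost = np.array(c["pulse_boost"])
    clad = clad + np.where(in_pulse > 0, fav * boost[np.clip(in_pulse, 1, 3) - 1], 0.0)

    # seston and optics; pulses clarify (filter feeding removes seston)
    clarify = np.where(in_pulse > 0, c["ss_clarify"] ** in_pulse, 1.0)
    ss = c["ss_base"] * (1 + c["ss_precip"] * np.minimum(p7, c["ss_precip_cap"])) * clarify
    spate = np.minimum(np.maximum(inflow / params.baseflow - 1.0, 0.0), 3.0)
    turb = c["turb_base"] + c["turb_ss"] * ss + c["turb_phyto"] * phyto + c["turb_spate"] * spate

    if params.noise_sd > 0:
        def jitter(x, scale=1.0):
            return x * np.exp(rng.normal(0.0, params.noise_sd * scale, n))
        tp, dtp, po4 = jitter(tp), jitter(dtp), jitter(po4)
        tn, dtn, nh4, no3 = jitter(tn), jitter(dtn), jitter(nh4), jitter(no3)
        cyano, diatoms, green, other = (jitter(x) for x in (cyano, diatoms, green, other))
        chl = jitter(chl)
        rot, clad, cop = jitter(rot), jitter(clad), jitter(cop)
        ss = jitter(ss)
        turb = jitter(turb)

    clarity = turb + 0.15 * chl
    raw = c["secchi_c0"] / clarity ** 0.8
    secchi = site.mean_depth * np.tanh(raw / site.mean_depth)

    df = pd.DataFrame(
        {
            "date": dates,
            "water_temp": temp,
            "turbidity": turb,
            "secchi_depth": secchi,
            "ss": ss,
            "tn": tn,
            "tp": tp,
            "dtn": dtn,
            "dtp": dtp,
            "nh4_n": nh4,
            "no3_n": no3,
            "po4_p": po4,
            "chl_a": chl,
            "cyanobacteria": cyano,
            "diatoms": diatoms,
            "green_algae": green,
            "other_algae": other,
            "rotifera": rot,
            "cladocera": clad,
            "copepoda": cop,
            "precipitation": p7,
            "hrt": hrt,
        }
    )
    events = [(w0, w0 + length) for w0, length in pulses]
    return SiteSeries(site.label, df), events


# ---------------------------------------------------------------------------
# full dataset

def mask_winter(series: SiteSeries) -> SiteSeries:
    """Drop freeze-period weeks (Dec 15 – Feb 20), leaving explicit gaps."""
    d = series.data
    md = d["date"].dt.month * 100 + d["date"].dt.day
    frozen = (md >= 1215) | (md <= 220)
    return SiteSeries(series.site, d.loc[~frozen].reset_index(drop=True))


def emulate_dataset(
    params: SimParams | None = None,
    winter_gaps: bool = False,
) -> tuple[dict[str, SiteSeries], dict[str, pd.DataFrame], GroundTruth]:
    """Generate the full multi-site dataset plus ground truth.

    Returns (weekly series per site, daily forcing per site, GroundTruth).
    With the default two-year parameters each site has 104 weekly records,
    the size of the study design this emulates. ``winter_gaps=True`` masks
    freeze-period weeks as explicit gaps.
    """
    params = params or SimParams()
    params.validate()
    weekly: dict[str, SiteSeries] = {}
    daily: dict[str, pd.DataFrame] = {}
    events: list[tuple[str, int, int]] = []
    for site in params.sites:
        forcing = generate_daily_forcing(params, site)
        ser, ev = simulate_plankton(forcing, site, params)
        if winter_gaps:
            ser = mask_winter(ser)
        weekly[site.label] = ser
        daily[site.label] = forcing
        events.extend((site.label, a, b) for a, b in ev)
    gt = GroundTruth(
        events=events,
        true_dag=list(TRUE_DAG),
        generator_params=asdict(params),
    )
    return weekly, daily, gt
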