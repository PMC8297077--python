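"""Column dictionary for weekly limnological series.

Canonical column names, the field-standard abbreviations accepted as CSV
header aliases, and the temporal-tier assignment used to constrain Bayesian
network edges (variables in a later tier never point at an earlier tier).
"""

from __future__ import annotations

DATE = "date"
SITE = "site"

#: measured weekly columns, in canonical order
MEASURED = [
    "water_temp",      # °C
    "turbidity",       # NTU
    "secchi_depth",    # m
    "ss",              # suspended solids, mg L^-1
    "tn",              # total nitrogen, mg L^-1
    "tp",              # total phosphorus, mg L^-1
    "dtn",             # dissolved total nitrogen, mg L^-1
    "dtp",             # dissolved total phosphorus, mg L^-1
    "nh4_n",           # ammonium nitrogen, mg L^-1
    "no3_n",           # nitrate nitrogen, mg L^-1
    "po4_p",           # orthophosphate-P, mg L^-1
    "chl_a",           # chlorophyll-a, mg m^-3
    "cyanobacteria",   # cells mL^-1
    "diatoms",         # cells mL^-1
    "green_algae",     # cells mL^-1
    "other_algae",     # cells mL^-1
    "rotifera",        # Ind L^-1
    "cladocera",       # Ind L^-1
    "copepoda",        # Ind L^-1
    "precipitation",   # 7-day antecedent total, mm
    "hrt",             # hydraulic retention time on the sampling day, d
]

#: derived columns appended by SiteSeries
DERIVED = [
    "total_phyto",     # cells mL^-1
    "total_zoo",       # Ind L^-1
    "rotifera_ra",     # % of total zooplankton
    "cladocera_ra",
    "copepoda_ra",
]

#: columns that must be non-negative when present
NON_NEGATIVE = [c for c in MEASURED if c != "water_temp"] + DERIVED

#: standard abbreviations accepted as header aliases (case-insensitive,
#: '-'/'_'/'.' interchangeable)
ALIASES = {
    "PRECI": "precipitation",
    "TEMP": "water_temp",
    "HRT": "hrt",
    "NH4-N": "nh4_n",
    "NO3-N": "no3_n",
    "PO4-P": "po4_p",
    "DTN": "dtn",
    "DTP": "dtp",
    "CY": "cyanobacteria",
    "BA": "diatoms",
    "CH": "green_algae",
    "ETC-DEN": "other_algae",
    "ETC": "other_algae",
    "RO-IND": "rotifera",
    "CL-IND": "cladocera",
    "CO-IND": "copepoda",
    "T-PHYTO-DEN": "total_phyto",
    "T-PHYTO": "total_phyto",
    "T-ZOO-IND": "total_zoo",
    "T-ZOO": "total_zoo",
    "RO-RA": "rotifera_ra",
    "CL-RA": "cladocera_ra",
    "CO-RA": "copepoda_ra",
    "TN": "tn",
    "TP": "tp",
    "CHL-A": "chl_a",
    "SS": "ss",
    "SD": "secchi_depth",
    "TUR": "turbidity",
    "DATE": "date",
    "SITE": "site",
}

#: temporal tiers: 1 = meteorology, 2 = hydrology & dissolved nutrients,
#: 3 = plankton group densities/counts, 4 = community totals and relative
#: abundance, 5 = bulk nutrients & chl-a, 6 = optical response variables
DEFAULT_TIERS = {
    "precipitation": 1,
    "water_temp": 1,
    "hrt": 2,
    "nh4_n": 2,
    "po4_p": 2,
    "dtn": 2,
    "dtp": 2,
    "cyanobacteria": 3,
    "diatoms": 3,
    "green_algae": 3,
    "other_algae": 3,
    "rotifera": 3,
    "cladocera": 3,
    "copepoda": 3,
    "total_phyto": 4,
    "total_zoo": 4,
    "rotifera_ra": 4,
    "cladocera_ra": 4,
    "copepoda_ra": 4,
    "tn": 5,
    "tp": 5,
    "chl_a": 5,
    "ss": 6,
    "secchi_depth": 6,
    "turbidity": 6,
}

#: variables entering the network stage, canonical order
MODELED_VARIABLES = list(DEFAULT_TIERS)


def canonical_name(header: str) -> str:
    """Map a CSV header (canonical name or alias) to its canonical name.

    Raises KeyError for unknown headers.
    """
    h = header.strip()
    if h in MEASURED or h in DERIVED or h in (DATE, SITE):
        return h
    key = h.upper().replace("_", "-").replace(".", "-").rstrip("-")
    if key in ALIASES:
        return ALIASES[key]
    key2 = h.lower().replace("-", "_").replace(".", "_")
    if key2 in MEASURED or key2 in DERIVED or key2 in (DATE, SITE):
        return key2
    raise KeyError(header)
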