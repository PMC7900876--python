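"""Published reference inputs for the US-fisheries climate analysis.

These small tables are the printed inputs the analysis is anchored to:
the CIRA 2.0 / EPPA6 decadal GDP projection, the 2007-2016 NMFS baseline
revenue statistics for the 16 modeled fisheries, the regional revenue
coverage of the habitat-projection screening, the screened present-value
changes for the 20 highest-value fisheries, the ensemble harvest
projections for 2050/2090, and the per-group consumer-welfare NPVs.
They serve as calibration targets for the synthetic generator and as
inputs to the bookkeeping checks in the acceptance script.

All dollar figures are real 2018 US$; quantities are million lb (MM lb).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "GDP_DECADAL",
    "EXPENDITURE_DECADAL",
    "GDP_BASE_AVERAGE",
    "EXPENDITURE_BASE_AVERAGE",
    "EXPENDITURE_ANCHOR_2020",
    "INCOME_ELASTICITY",
    "SPECIES_GROUPS",
    "SPECIES_REGION",
    "modeled_species_table",
    "screening_top20",
    "harvest_projections",
    "revenue_coverage",
    "welfare_npv_by_group",
]

# CIRA 2.0 GDP forecast (EPPA6), billions of 2018 US$, decadal.
GDP_DECADAL: dict[int, float] = {
    2020: 19_090.0,
    2030: 23_859.0,
    2040: 29_253.0,
    2050: 35_051.0,
    2060: 41_589.0,
    2070: 48_864.0,
    2080: 56_849.0,
    2090: 65_477.0,
    2100: 74_688.0,
}

#: 2007-2016 average GDP (billions 2018 US$).
GDP_BASE_AVERAGE: float = 16_674.0

#: Forecast expenditures on the 16 modeled species (millions 2018 US$).
EXPENDITURE_DECADAL: dict[int, float] = {
    2020: 3088.0,
    2030: 3165.0,
    2040: 3237.0,
    2050: 3302.0,
    2060: 3364.0,
    2070: 3424.0,
    2080: 3482.0,
    2090: 3536.0,
    2100: 3588.0,
}

#: 2007-2016 average expenditures on the modeled species (millions 2018 US$).
EXPENDITURE_BASE_AVERAGE: float = 3080.0

#: Forecast anchor: predicted expenditures in 2020 (millions 2018 US$).
EXPENDITURE_ANCHOR_2020: float = 3088.0

#: Income elasticity of demand for seafood.
INCOME_ELASTICITY: float = 0.11

# The four fishery groups and their member species (the two-stage budget
# hierarchy). High/low-value fish split at a $0.75/lb mean ex-vessel price.
SPECIES_GROUPS: dict[str, list[str]] = {
    "Lobster/crab": [
        "American lobster",
        "Blue crab",
        "Dungeness crab",
        "Florida stone crab (claws)",
    ],
    "Shrimp/mollusk": [
        "Sea scallop",
        "White shrimp",
        "Brown shrimp",
        "California market squid",
    ],
    "High-value fish": [
        "Pacific halibut",
        "Sablefish",
        "Chinook salmon",
        "Summer flounder",
    ],
    "Low-value fish": [
        "Walleye pollock",
        "Pacific cod",
        "Yellowfin sole",
        "Chum salmon",
    ],
}

# Primary landing region used by the synthetic generator (one per species;
# the real data spreads several species over multiple regions).
SPECIES_REGION: dict[str, str] = {
    "American lobster": "East Coast",
    "Blue crab": "Gulf Coast",
    "Dungeness crab": "West Coast",
    "Florida stone crab (claws)": "Gulf Coast",
    "Sea scallop": "East Coast",
    "White shrimp": "Gulf Coast",
    "Brown shrimp": "Gulf Coast",
    "California market squid": "West Coast",
    "Pacific halibut": "Alaska",
    "Sablefish": "Alaska",
    "Chinook salmon": "West Coast",
    "Summer flounder": "East Coast",
    "Walleye pollock": "Alaska",
    "Pacific cod": "Alaska",
    "Yellowfin sole": "Alaska",
    "Chum salmon": "Alaska",
}

# species: (mean revenue, sd revenue, baseline rank, group,
#           baseline harvest MM lb/yr)
_MODELED = [
    ("American lobster", 502.5, 111.5, 1, "Lobster/crab", 126.7),
    ("Sea scallop", 501.4, 72.8, 2, "Shrimp/mollusk", 49.3),
    ("Walleye pollock", 390.4, 49.9, 3, "Low-value fish", 2760.6),
    ("White shrimp", 246.3, 30.1, 4, "Shrimp/mollusk", 109.1),
    ("Brown shrimp", 216.2, 51.6, 5, "Shrimp/mollusk", 107.4),
    ("Pacific cod", 212.1, 56.9, 6, "Low-value fish", 620.2),
    ("Blue crab", 209.4, 19.6, 7, "Lobster/crab", 168.3),
    ("Dungeness crab", 186.1, 48.0, 8, "Lobster/crab", 58.9),
    ("Pacific halibut", 182.9, 60.3, 9, "High-value fish", 43.2),
    ("Sablefish", 140.0, 27.3, 10, "High-value fish", 39.6),
    ("Chum salmon", 73.3, 20.1, 12, "Low-value fish", 118.7),
    ("California market squid", 58.0, 22.0, 13, "Shrimp/mollusk", 179.4),
    ("Chinook salmon", 51.8, 15.1, 14, "High-value fish", 14.5),
    ("Yellowfin sole", 49.2, 10.5, 15, "Low-value fish", 290.6),
    ("Summer flounder", 31.3, 3.6, 18, "High-value fish", 11.2),
    ("Florida stone crab (claws)", 28.7, 5.0, 20, "Lobster/crab", 4.6),
]


def modeled_species_table() -> pd.DataFrame:
    """Baseline statistics for the 16 species in the welfare analysis.

    Columns: species, mean_revenue, sd_revenue, rank, group,
    mean_pounds (annual averages, 2007-2016; MM$ and MM lb).
    """
    df = pd.DataFrame(
        _MODELED,
        columns=["species", "mean_revenue", "sd_revenue", "rank", "group",
                 "mean_pounds"],
    )
    df["region"] = df["species"].map(SPECIES_REGION)
    return df


# Screening results for the 20 highest-value fisheries with habitat
# projections: mean/sd of annual ex-vessel revenue (MM 2018 US$) and the
# change in present value of revenues 2021-2100 vs baseline (MM 2018 US$)
# under each RCP.
_TOP20 = [
    # fishery, mean, sd, dPV RCP4.5, dPV RCP8.5
    ("American lobster", 502.5, 111.5, 54.1, -219.9),
    ("Sea scallop", 501.4, 72.8, 410.4, -114.3),
    ("Walleye pollock", 390.4, 49.9, 79.9, 189.9),
    ("White shrimp", 246.3, 30.1, 670.2, 1269.8),
    ("Brown shrimp", 216.2, 51.6, -133.3, -176.5),
    ("Pacific cod", 212.1, 56.9, 13.0, 26.8),
    ("Blue crab", 209.4, 19.6, 407.8, 649.2),
    ("Dungeness crab", 186.1, 48.0, -800.4, -1160.5),
    ("Pacific halibut", 182.9, 60.3, 52.0, 28.9),
    ("Sablefish", 140.0, 27.3, 227.6, 403.6),
    ("Snow crab", 113.0, 38.4, -1048.4, -1549.8),
    ("Chum salmon", 73.3, 20.1, -210.9, -425.6),
    ("California market squid", 58.0, 22.0, 132.3, 205.7),
    ("Chinook salmon", 51.8, 15.1, -36.3, 24.3),
    ("Yellowfin sole", 49.2, 10.5, -180.4, -349.0),
    ("Pacific hake", 46.6, 17.9, -51.6, -78.5),
    ("Ocean shrimp", 34.2, 20.6, -185.0, -258.2),
    ("Summer flounder", 31.3, 3.6, 80.7, 82.4),
    ("Longfin squid", 29.7, 9.2, 79.3, 76.0),
    ("Florida stone crab (claws)", 28.7, 5.0, -164.9, -204.3),
]


def screening_top20() -> pd.DataFrame:
    """Screened PV changes for the 20 highest-value covered fisheries."""
    return pd.DataFrame(
        _TOP20,
        columns=["fishery", "mean_revenue", "sd_revenue",
                 "dpv_rcp45", "dpv_rcp85"],
    )


# Ensemble harvest projections for the 16 modeled species: baseline annual
# average (MM lb) and projected landings in 2050 and 2090 under each RCP.
_HARVEST = [
    # species, baseline, 2050 rcp45, 2090 rcp45, 2050 rcp85, 2090 rcp85
    ("Blue crab", 168.3, 180.1, 194.5, 179.1, 250.5),
    ("Dungeness crab", 58.9, 49.2, 41.0, 45.6, 23.0),
    ("American lobster", 126.7, 128.3, 121.1, 129.2, 101.5),
    ("Florida stone crab (claws)", 4.6, 3.5, 3.0, 3.3, 2.1),
    ("Sea scallop", 49.3, 51.5, 49.2, 51.2, 39.5),
    ("Brown shrimp", 107.4, 104.8, 102.7, 103.4, 101.9),
    ("White shrimp", 109.1, 120.8, 127.7, 127.8, 161.8),
    ("California market squid", 179.4, 193.9, 215.0, 201.6, 241.4),
    ("Pacific halibut", 43.2, 43.1, 44.8, 44.1, 39.4),
    ("Sablefish", 39.6, 42.1, 44.6, 45.1, 42.8),
    ("Chinook salmon", 14.5, 13.9, 14.3, 14.8, 15.4),
    ("Summer flounder", 11.2, 12.4, 13.0, 12.3, 14.5),
    ("Walleye pollock", 2760.6, 2765.1, 2840.3, 2840.4, 2733.3),
    ("Pacific cod", 620.2, 616.4, 631.2, 633.9, 582.8),
    ("Yellowfin sole", 290.6, 257.7, 200.4, 213.3, 92.5),
    ("Chum salmon", 118.7, 106.8, 84.5, 95.1, 41.9),
]


def harvest_projections() -> pd.DataFrame:
    """Baseline and projected landings (MM lb) for the modeled species."""
    df = pd.DataFrame(
        _HARVEST,
        columns=["species", "baseline", "landings_2050_rcp45",
                 "landings_2090_rcp45", "landings_2050_rcp85",
                 "landings_2090_rcp85"],
    )
    return df


# Revenue coverage of the screening dataset by region (billions 2018 US$).
_COVERAGE = [
    ("East Coast", 1.906, 1.519),
    ("Gulf Coast", 0.885, 0.567),
    ("West Coast", 0.693, 0.443),
    ("Alaska", 1.848, 1.247),
]


def revenue_coverage() -> pd.DataFrame:
    """All-fisheries vs habitat-covered annual revenue by region (B$)."""
    return pd.DataFrame(
        _COVERAGE, columns=["region", "all_fisheries", "covered"]
    )


# Present values of consumer welfare impacts by fishery group (MM 2018 US$,
# r = 3%, 2021-2100).
_WELFARE_NPV = [
    ("Lobster/crab", -2126.0, -2848.2),
    ("Shrimp/mollusk", 265.7, 1469.7),
    ("High-value fish", -585.1, 441.2),
    ("Low-value fish", 355.8, -3292.0),
]


def welfare_npv_by_group() -> pd.DataFrame:
    """Per-group consumer-welfare NPVs under RCP 4.5 and 8.5 (MM$)."""
    return pd.DataFrame(
        _WELFARE_NPV, columns=["group", "npv_rcp45", "npv_rcp85"]
    )


def ensemble_percent_changes() -> pd.DataFrame:
    """Ensemble-mean harvest percent changes implied by the projections.

    Derived from :func:`harvest_projections`: fractional change of the 2050
    and 2090 landings vs the baseline annual average, per RCP.
    """
    df = harvest_projections().set_index("species")
    out = pd.DataFrame(index=df.index)
    for rcp in ("rcp45", "rcp85"):
        for yr in (2050, 2090):
            out[f"pct_{yr}_{rcp}"] = (
                df[f"landings_{yr}_{rcp}"] / df["baseline"] - 1.0
            )
    return out.reset_index()


def annual_gdp_path() -> pd.DataFrame:
    """Annual GDP 2020-2100, linear interpolation of the decadal values."""
    years = np.arange(2020, 2101)
    dec_years = np.array(sorted(GDP_DECADAL))
    dec_vals = np.array([GDP_DECADAL[y] for y in dec_years])
    return pd.DataFrame(
        {"year": years, "gdp_billion_2018usd": np.interp(years, dec_years, dec_vals)}
    )
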