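"""Economic screening of climate-driven landings changes.

Reproduces the first-order assessment pipeline: CPI deflation of ex-vessel
revenues, collapsing the monthly panel to baseline (2007-2016) annual
statistics, matching landings records to habitat projections (with
synonym curation, multi-species exclusions and a $100,000 de minimis
filter), converting per-bin habitat totals to annualized multipliers,
projecting landings proportionally, discounting at a 3% real rate, and
propagating uncertainty by Monte Carlo over interannual landings
variation and the five-GCM spread.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "deflate",
    "baseline_stats",
    "match_records",
    "habitat_change",
    "annualize",
    "project_landings",
    "annuity_factor",
    "present_value",
    "aggregate_regions",
    "monte_carlo_ci",
    "BIN_MIDPOINTS",
]

#: Midpoint years anchoring the twenty-year habitat bins.
BIN_MIDPOINTS = {"B0": 2013.5, "T1": 2030.5, "T2": 2050.5, "T3": 2070.5,
                 "T4": 2090.5}

ATLANTIC = ("East Coast", "Gulf Coast")
PACIFIC = ("West Coast", "Alaska")


def deflate(panel: pd.DataFrame, cpi: dict[int, float],
            base_year: int = 2018,
            revenue_col: str = "revenue_mm_2018usd") -> pd.DataFrame:
    """Convert nominal revenues to base-year dollars with a CPI series.

    revenue_real = revenue_nominal * cpi(base_year) / cpi(year).
    Quantities are untouched. Raises KeyError naming any missing CPI year.
    """
    years = set(panel["year"].unique()) | {base_year}
    missing = sorted(y for y in years if y not in cpi)
    if missing:
        raise KeyError(f"CPI index missing for year(s): {missing}")
    out = panel.copy()
    factor = out["year"].map(lambda y: cpi[base_year] / cpi[y])
    out[revenue_col] = out[revenue_col] * factor
    out.attrs["real_dollars"] = True
    out.attrs["base_year"] = base_year
    return out


def baseline_stats(panel: pd.DataFrame) -> pd.DataFrame:
    """Collapse the monthly panel to per-(species, region) baseline stats.

    Sums to annual totals, then takes the mean and sample SD (n-1
    denominator) over years.  The per-year values are retained (as list
    columns) for bootstrap resampling.  With a single year the SD is NaN.
    """
    annual = (
        panel.groupby(["species", "region", "year"], sort=True)
        [["pounds_mm", "revenue_mm_2018usd"]].sum().reset_index()
    )
    def collapse(g: pd.DataFrame) -> pd.Series:
        return pd.Series({
            "mean_pounds": g["pounds_mm"].mean(),
            "sd_pounds": g["pounds_mm"].std(ddof=1),
            "mean_revenue": g["revenue_mm_2018usd"].mean(),
            "sd_revenue": g["revenue_mm_2018usd"].std(ddof=1),
            "annual_pounds": g["pounds_mm"].to_list(),
            "annual_revenue": g["revenue_mm_2018usd"].to_list(),
            "n_years": len(g),
        })
    out = (
        annual.groupby(["species", "region"], sort=True)
        .apply(collapse, include_groups=False).reset_index()
    )
    return out


def match_records(landings: pd.DataFrame, habitat: pd.DataFrame,
                  synonyms: dict[str, str] | None = None,
                  multi_species_flags: set[str] | frozenset[str] = frozenset(),
                  de_minimis: float = 0.1) -> pd.DataFrame:
    """Classify each (species, region) landings record for the screening.

    Classes (each record gets exactly one, in this order):

    * ``matched-automated`` -- species name present in the habitat table
      for the region;
    * ``matched-manual`` -- matched through the synonym map;
    * ``excluded-multi-species`` -- flagged multi-species aggregate;
    * ``excluded-de-minimis`` -- otherwise unmatched with mean revenue
      below ``de_minimis`` (strict; MM$, 0.1 = $100,000);
    * ``excluded-no-projection`` -- everything else.

    Returns the landings table with a ``disposition`` column plus
    ``revenue_share`` (fraction of total mean revenue).  A species in
    both the synonym map and the multi-species set raises ValueError.
    """
    synonyms = synonyms or {}
    overlap = set(synonyms) & set(multi_species_flags)
    if overlap:
        raise ValueError(f"ambiguous curation: {sorted(overlap)} in both the "
                         "synonym map and the multi-species set")
    hab_keys = set(zip(habitat["species"], habitat["region"]))
    out = landings.copy()
    disposition = []
    for _, rec in out.iterrows():
        sp, rg = rec["species"], rec["region"]
        if (sp, rg) in hab_keys:
            disposition.append("matched-automated")
        elif sp in synonyms and (synonyms[sp], rg) in hab_keys:
            disposition.append("matched-manual")
        elif sp in multi_species_flags:
            disposition.append("excluded-multi-species")
        elif rec["mean_revenue"] < de_minimis:
            disposition.append("excluded-de-minimis")
        else:
            disposition.append("excluded-no-projection")
    out["disposition"] = disposition
    total = out["mean_revenue"].sum()
    out["revenue_share"] = out["mean_revenue"] / total if total > 0 else 0.0
    return out


def habitat_change(habitat: pd.DataFrame) -> pd.DataFrame:
    """Fractional habitat change vs the baseline bin, per GCM and ensemble.

    For each (species, region, rcp, gcm): dh(bin) = (H(bin) - H(B0)) / H(B0).
    The ensemble value is the arithmetic mean over GCMs of the per-GCM
    fractional changes (mean of ratios).  A zero baseline raises -- the
    percent change is undefined (such degenerate records are excluded
    upstream, as snow crab was).

    Returns a long frame (species, region, rcp, gcm, bin, dh) where
    ``gcm == "ensemble"`` rows hold the cross-GCM mean.
    """
    required = set(BIN_MIDPOINTS)
    rows = []
    for (sp, rg, rcp, gcm), g in habitat.groupby(
            ["species", "region", "rcp", "gcm"], sort=True):
        bins = dict(zip(g["bin"], g["habitat_total"]))
        if set(bins) != required:
            raise ValueError(
                f"incomplete bin set for ({sp}, {rg}, {rcp}, {gcm}): "
                f"have {sorted(bins)}"
            )
        h0 = bins["B0"]
        if h0 == 0:
            raise ValueError(
                f"zero baseline habitat for ({sp}, {rg}, {rcp}, {gcm}); "
                "percent change undefined -- exclude this record upstream"
            )
        for b in BIN_MIDPOINTS:
            rows.append((sp, rg, rcp, gcm, b, (bins[b] - h0) / h0))
    df = pd.DataFrame(rows, columns=["species", "region", "rcp", "gcm", "bin", "dh"])
    ens = (
        df.groupby(["species", "region", "rcp", "bin"], sort=True)["dh"]
        .mean().reset_index()
    )
    ens["gcm"] = "ensemble"
    return pd.concat([df, ens[df.columns]], ignore_index=True)


def annualize(dh_by_bin: dict[str, float], years=(2021, 2100)) -> pd.Series:
    """Annual landings multipliers m_t = 1 + dh(t) from per-bin changes.

    Bin values are anchored at the bin midpoint years, linearly
    interpolated between anchors, and held flat beyond the last anchor
    (2090.5).  ``dh_by_bin`` must include B0 (which is 0 by construction).
    """
    anchors = sorted((BIN_MIDPOINTS[b], dh) for b, dh in dh_by_bin.items())
    xs = np.array([a[0] for a in anchors])
    ys = np.array([a[1] for a in anchors])
    t = np.arange(years[0], years[1] + 1)
    dh = np.interp(t, xs, ys)  # np.interp clamps flat outside the anchors
    return pd.Series(1.0 + dh, index=t, name="multiplier")


def project_landings(baseline_mean: float, multipliers: pd.Series) -> pd.Series:
    """Annual projected landings (or revenue): baseline mean x multiplier.

    Ex-vessel prices are held constant, so the same proportional path
    applies to both weight and value.
    """
    return baseline_mean * multipliers


def annuity_factor(r: float = 0.03, years=(2021, 2100),
                   base_year: int = 2020) -> float:
    """Present value of one unit per year over ``years`` discounted to
    end-``base_year``: sum_k (1+r)^-(t-base_year)."""
    t = np.arange(years[0], years[1] + 1)
    return float(np.sum((1.0 + r) ** -(t - base_year)))


def present_value(series: pd.Series, r: float = 0.03,
                  base_year: int = 2020) -> float:
    """PV = sum_t value_t (1+r)^-(t-base_year) over the series' years.

    Years at or before ``base_year`` are not discounted into the sum.
    """
    t = series.index.to_numpy()
    keep = t > base_year
    return float(np.sum(series.to_numpy()[keep]
                        * (1.0 + r) ** -(t[keep] - base_year)))


def aggregate_regions(per_species: pd.DataFrame, r: float = 0.03,
                      years=(2021, 2100), base_year: int = 2020) -> pd.DataFrame:
    """Regional screening table from per-species PV changes.

    ``per_species`` needs columns (species, region, mean_revenue, dpv)
    with revenue and dpv in the same units.  Returns rows for each
    region, Atlantic/Pacific subtotals and the total, with
    ``pct_change = dpv / (mean_revenue x annuity_factor)``.
    """
    af = annuity_factor(r, years, base_year)
    by_region = (
        per_species.groupby("region", sort=True)[["mean_revenue", "dpv"]]
        .sum().reset_index()
    )
    rows = [tuple(x) for x in by_region.itertuples(index=False)]
    def subtotal(name, members):
        sub = by_region[by_region["region"].isin(members)]
        return (name, sub["mean_revenue"].sum(), sub["dpv"].sum())
    rows.append(subtotal("Subtotal: Atlantic", ATLANTIC))
    rows.append(subtotal("Subtotal: Pacific", PACIFIC))
    rows.append(("Total", by_region["mean_revenue"].sum(), by_region["dpv"].sum()))
    out = pd.DataFrame(rows, columns=["region", "mean_revenue", "dpv"])
    out["pct_change"] = out["dpv"] / (out["mean_revenue"] * af)
    return out


def monte_carlo_ci(annual_values: np.ndarray, gcm_multipliers: np.ndarray,
                   n_draws: int = 10_000,
                   seed: int | np.random.SeedSequence = 0,
                   ci: float = 0.95) -> tuple[float, float, float]:
    """Monte Carlo percent-change CI for one species at one target year.

    Each draw bootstraps the baseline annual values (sampling years with
    replacement) for a draw-specific baseline mean, picks one GCM's
    annualized multiplier uniformly, and records
    (mean_draw * m - mean_full) / mean_full.  Returns the point estimate
    (full mean x ensemble-mean multiplier) and the percentile bounds.
    """
    annual_values = np.asarray(annual_values, dtype=float)
    gcm_multipliers = np.asarray(gcm_multipliers, dtype=float)
    if annual_values.size < 2:
        raise ValueError("need at least two baseline years to resample")
    rng = np.random.default_rng(seed)
    n = annual_values.size
    mean_full = annual_values.mean()
    idx = rng.integers(0, n, size=(n_draws, n))
    means = annual_values[idx].mean(axis=1)
    ms = gcm_multipliers[rng.integers(0, gcm_multipliers.size, size=n_draws)]
    draws = (means * ms - mean_full) / mean_full
    point = float(gcm_multipliers.mean() - 1.0)
    a = (1.0 - ci) / 2.0
    lo, hi = np.quantile(draws, [a, 1.0 - a])
    return point, float(lo), float(hi)
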