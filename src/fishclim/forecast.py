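"""Expenditure forecasting and the two-stage budget-allocation simulation.

Total real expenditures on the modeled species grow with GDP through an
income elasticity of 0.11: E_t = E_anchor (GDP_t / GDP_anchor)^eta,
anchored at 2020.  The fitted first-stage demand system then allocates
each year's total across the four fishery groups (shares evaluated at the
projected group quantity indices), the second-stage systems allocate each
group's budget across its member species, and implied ex-vessel prices
fall out as expenditure over harvest.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .demand import InverseAIDS

__all__ = [
    "forecast_expenditures",
    "allocate_stage1",
    "allocate_stage2",
    "implied_prices",
    "group_quantity_index",
]


def forecast_expenditures(gdp: pd.DataFrame, eta: float = 0.11,
                          anchor: tuple[int, float] = (2020, 3088.0),
                          base: float = 3080.0) -> pd.DataFrame:
    """Annual expenditure path E_t = E_anchor (GDP_t/GDP_anchor)^eta.

    ``gdp`` has columns (year, gdp_billion_2018usd) at annual resolution
    and must cover the anchor year. Returns (year, gdp, expenditure_mm)
    with ``attrs['growth_vs_base']`` = E_final/base - 1.
    """
    anchor_year, e_anchor = anchor
    g = gdp.set_index("year")["gdp_billion_2018usd"]
    if anchor_year not in g.index:
        raise ValueError(f"GDP path does not cover anchor year {anchor_year}")
    e = e_anchor * (g / g.loc[anchor_year]) ** eta
    out = pd.DataFrame(
        {"year": g.index, "gdp_billion_2018usd": g.to_numpy(),
         "expenditure_mm": e.to_numpy()}
    )
    out.attrs["growth_vs_base"] = float(e.iloc[-1] / base - 1.0)
    return out


def group_quantity_index(lnq_species: pd.DataFrame,
                         base_shares: np.ndarray) -> pd.Series:
    """Stone log-quantity index for a group from member-species paths.

    ``lnq_species`` is (year x species) log quantities; ``base_shares``
    are the frozen base-period within-group expenditure shares, which
    avoids simultaneity between the forecast shares and the index.
    """
    return pd.Series(lnq_species.to_numpy() @ np.asarray(base_shares),
                     index=lnq_species.index)


def _allocate(model: InverseAIDS, lnq: pd.DataFrame,
              budget: pd.Series, level: str) -> pd.DataFrame:
    shares = model.predict(lnq.to_numpy())
    if np.any(shares <= 0):
        bad_t, bad_i = np.argwhere(shares <= 0)[0]
        raise ValueError(
            f"predicted {level} share non-positive for "
            f"{lnq.columns[bad_i]!r} in year {lnq.index[bad_t]}: "
            "out-of-sample extrapolation failure"
        )
    budget = budget.loc[lnq.index]
    out = pd.DataFrame(shares * budget.to_numpy()[:, None],
                       index=lnq.index, columns=lnq.columns)
    return out


def allocate_stage1(model: InverseAIDS, group_lnq: pd.DataFrame,
                    expenditures: pd.Series) -> pd.DataFrame:
    """Allocate total expenditures across fishery groups, per year.

    ``group_lnq`` is (year x group) log quantity indices;
    ``expenditures`` is the total budget per year.  Group expenditure =
    predicted share x E_t; by adding-up the shares sum to one, so the
    allocation conserves the budget.  A non-positive predicted share
    raises, naming the year and group.
    """
    return _allocate(model, group_lnq, expenditures, "group")


def allocate_stage2(model: InverseAIDS, species_lnq: pd.DataFrame,
                    group_expenditure: pd.Series) -> pd.DataFrame:
    """Allocate one group's budget across its member species, per year."""
    return _allocate(model, species_lnq, group_expenditure, "species")


def implied_prices(species_expenditure: pd.DataFrame,
                   quantities: pd.DataFrame) -> pd.DataFrame:
    """Implied ex-vessel prices: expenditure / harvest, per species-year.

    Expenditures in MM$ and quantities in MM lb give prices in $/lb.
    Raises on zero quantities (price undefined).
    """
    q = quantities.loc[species_expenditure.index, species_expenditure.columns]
    if (q <= 0).to_numpy().any():
        raise ValueError("non-positive harvest: implied price undefined")
    return species_expenditure / q
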