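"""Distance-function consumer-welfare measurement.

The IAIDS corresponds to the translog distance function

    ln D(q, u) = a(q) - u * b(q),
    a(q) = alpha0 + sum_i alpha_i ln q_i
           + 1/2 sum_i sum_j gamma_ij ln q_i ln q_j,
    b(q) = beta0 * prod_i q_i^{b_i},   b_i = -beta_i,

where ``beta_i`` are the share-equation scale coefficients (the exponent
sign flip makes d ln D / d ln q_i reproduce the estimated share equations
at D = 1).  The restriction set delivers linear homogeneity in q:
D(lambda q, u) = lambda D(q, u).

Utility is benchmarked at the baseline harvest bundle, u0 = a(q0)/b(q0),
the unique level with D(q0, u0) = 1.  Annual welfare monetizes the
distance gap with that year's forecast expenditures,

    W_t = E_t (1 - 1/D(q_t, u0))        (compensating-style, default)
    W_t = E_t (D(q_t, u0) - 1)          (equivalent-style variant),

which is exact for proportional bundle changes, zero at the baseline, and
signed with the utility change.  Group welfare uses each group's
second-stage distance function and its forecast stage-1 expenditure;
the total is the sum over groups, and NPVs discount at a 3% real rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import IaidsParams
from .screening import present_value

__all__ = [
    "DistanceSpec",
    "distance",
    "benchmark_utility",
    "annual_welfare",
    "welfare_series",
    "welfare_npv",
]


@dataclass
class DistanceSpec:
    """Translog distance function implied by one estimated IAIDS."""

    params: IaidsParams

    def a(self, q: np.ndarray) -> float:
        lnq = np.log(np.asarray(q, dtype=float))
        p = self.params
        return float(p.alpha0 + p.alpha @ lnq + 0.5 * lnq @ p.gamma @ lnq)

    def b(self, q: np.ndarray) -> float:
        lnq = np.log(np.asarray(q, dtype=float))
        p = self.params
        # share-equation beta enters the distance function with a sign flip
        return float(p.beta0 * np.exp(-(p.beta @ lnq)))


def distance(spec: DistanceSpec, q: np.ndarray, u: float) -> float:
    """D(q, u) = exp(a(q) - u b(q)); linearly homogeneous in q."""
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("quantities must be strictly positive")
    return float(np.exp(spec.a(q) - u * spec.b(q)))


def benchmark_utility(spec: DistanceSpec, q_base: np.ndarray) -> float:
    """u0 = a(q0)/b(q0): the unique utility with D(q0, u0) = 1."""
    q_base = np.asarray(q_base, dtype=float)
    if np.any(q_base <= 0):
        raise ValueError("baseline quantities must be strictly positive")
    return spec.a(q_base) / spec.b(q_base)


def annual_welfare(spec: DistanceSpec, q_t: np.ndarray, u0: float,
                   E_t: float, variant: str = "compensating") -> float:
    """Monetized welfare impact of the bundle q_t relative to benchmark u0.

    Positive when the year's bundle yields more utility than the
    benchmark.  ``variant`` selects the monetization:
    ``"compensating"`` -> E_t (1 - 1/D); ``"equivalent"`` -> E_t (D - 1).
    """
    if E_t <= 0:
        raise ValueError("expenditures must be positive")
    D = distance(spec, q_t, u0)
    if variant == "compensating":
        return float(E_t * (1.0 - 1.0 / D))
    if variant == "equivalent":
        return float(E_t * (D - 1.0))
    raise ValueError(f"unknown monetization variant {variant!r}")


def welfare_series(stage2_params: dict[str, IaidsParams],
                   quantities: dict[str, pd.DataFrame],
                   baselines: dict[str, np.ndarray],
                   group_expenditures: pd.DataFrame,
                   variant: str = "compensating") -> pd.DataFrame:
    """Annual welfare impacts per fishery group and in total.

    Parameters
    ----------
    stage2_params : group -> fitted IAIDS parameters (member-species order).
    quantities : group -> (year x species) harvest paths, MM lb.
    baselines : group -> baseline harvest bundle (benchmark utility point).
    group_expenditures : (year x group) forecast stage-1 expenditures, MM$.
    variant : monetization variant passed to :func:`annual_welfare`.

    Returns a (year x group) DataFrame with a ``total`` column.
    """
    groups = list(stage2_params)
    years = group_expenditures.index
    out = pd.DataFrame(index=years, columns=groups, dtype=float)
    for g in groups:
        spec = DistanceSpec(stage2_params[g])
        u0 = benchmark_utility(spec, baselines[g])
        q = quantities[g]
        for t in years:
            out.loc[t, g] = annual_welfare(
                spec, q.loc[t].to_numpy(), u0,
                float(group_expenditures.loc[t, g]), variant,
            )
    out["total"] = out[groups].sum(axis=1)
    return out


def welfare_npv(series: pd.DataFrame, r: float = 0.03,
                base_year: int = 2020) -> pd.Series:
    """NPV per column of an annual welfare table, discounted to base year.

    Years at or before the base year carry no weight (the 2020 row of the
    annual table is reported but not discounted into the NPV).
    """
    return series.apply(lambda col: present_value(col, r, base_year))
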