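"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates the three external inputs of the analysis:

* a monthly landings panel (16 species in 4 fishery groups, 120 months)
  drawn from a *known* two-stage IAIDS process, so estimation can be
  validated by parameter recovery;
* a per-species habitat-projection table (2 RCPs x 5 GCMs x 5 twenty-year
  bins) whose bin trends default to the ensemble harvest changes of the
  published screening analysis;
* the decadal GDP path (packaged printed values, annually interpolated).

Quantities are million lb per month; expenditures million 2018 US$.
The defaults mirror the published study's baseline conditions (baseline
revenues, group structure, habitat trajectories); they are fixed study
conditions, not tuning knobs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import reference as ref
from .demand import solve_share_fixed_point, stone_index
from .params import IaidsParams

__all__ = [
    "SyntheticConfig",
    "default_stage1_params",
    "default_stage2_params",
    "default_habitat_trend",
    "gen_demand_history",
    "gen_habitat_table",
    "packaged_gdp_path",
    "write_synthetic_inputs",
]

GCMS = ["CanESM2", "CCSM4", "GISS-E2-R", "HadGEM2-ES", "MIROC5"]
RCPS = ["RCP4.5", "RCP8.5"]
#: Twenty-year averaging bins: label -> (first year, last year).
BINS = {
    "B0": (2007, 2020),
    "T1": (2021, 2040),
    "T2": (2041, 2060),
    "T3": (2061, 2080),
    "T4": (2081, 2100),
}


def _share_proportional_gamma(w: np.ndarray, k: float) -> np.ndarray:
    """Symmetric gamma with zero row/column sums: k * (w w' - diag(w)).

    Negative diagonal and positive off-diagonals of magnitude set by the
    shares, which yields own flexibilities around -(1 + k(1 - w_i)) and
    hence negative own elasticities of plausible seafood magnitude.
    """
    w = np.asarray(w, dtype=float)
    return k * (np.outer(w, w) - np.diag(w))


def _make_params(shares: np.ndarray, k: float, beta_scale: float,
                 labels: list[str], lnq0: np.ndarray) -> IaidsParams:
    """Build a true parameter set hitting ``shares`` at the point ``lnq0``.

    gamma and beta are set from the target shares; the intercepts are then
    recentred so the Stone fixed point at the baseline log quantities
    reproduces the target shares:

        alpha = w - Gamma lnq0 - beta (w' lnq0).

    Adding-up survives the recentring because the gamma columns and beta
    sum to zero.
    """
    w = np.asarray(shares, dtype=float)
    n = len(w)
    beta = beta_scale * (w - 1.0 / n)
    gamma = _share_proportional_gamma(w, k)
    alpha = w - gamma @ lnq0 - beta * float(w @ lnq0)
    p = IaidsParams(alpha=alpha, beta=beta, gamma=gamma, labels=labels)
    p.validate()
    return p


def _baseline_lnq() -> pd.Series:
    """Log of baseline mean monthly harvests (MM lb/month) per species."""
    df = ref.modeled_species_table().set_index("species")
    return np.log(df["mean_pounds"] / 12.0)


def default_stage1_params() -> IaidsParams:
    """True group-level system: baseline group revenue shares at the
    baseline group quantity indices."""
    df = ref.modeled_species_table()
    rev = df.groupby("group", sort=False)["mean_revenue"].sum()
    groups = list(ref.SPECIES_GROUPS)
    shares = (rev[groups] / rev.sum()).to_numpy()
    lnq_sp = _baseline_lnq()
    df = df.set_index("species")
    lnq0 = np.empty(len(groups))
    for gi, g in enumerate(groups):
        sp = ref.SPECIES_GROUPS[g]
        w_in = df.loc[sp, "mean_revenue"].to_numpy()
        w_in = w_in / w_in.sum()
        lnq0[gi] = float(w_in @ lnq_sp[sp].to_numpy())
    return _make_params(shares, k=0.55, beta_scale=0.04, labels=groups,
                        lnq0=lnq0)


def default_stage2_params() -> dict[str, IaidsParams]:
    """True within-group systems: baseline within-group shares at the
    baseline member-species log quantities."""
    df = ref.modeled_species_table().set_index("species")
    lnq_sp = _baseline_lnq()
    out = {}
    for g_idx, (group, species) in enumerate(ref.SPECIES_GROUPS.items()):
        rev = df.loc[species, "mean_revenue"].to_numpy()
        shares = rev / rev.sum()
        # vary the substitution strength a little across groups
        k = (0.5, 0.65, 0.45, 0.6)[g_idx]
        out[group] = _make_params(shares, k=k, beta_scale=0.03,
                                  labels=species,
                                  lnq0=lnq_sp[species].to_numpy())
    return out


def default_habitat_trend() -> dict[str, dict[str, dict[str, float]]]:
    """Per-species fractional habitat change per future bin and RCP.

    Anchored to the published ensemble harvest changes: bin T2 carries the
    2050 change, T4 the 2090 change, T1 = T2/2 and T3 = (T2 + T4)/2.
    """
    pct = ref.ensemble_percent_changes().set_index("species")
    trend: dict[str, dict[str, dict[str, float]]] = {}
    for species in pct.index:
        trend[species] = {}
        for rcp, tag in (("RCP4.5", "rcp45"), ("RCP8.5", "rcp85")):
            t2 = float(pct.loc[species, f"pct_2050_{tag}"])
            t4 = float(pct.loc[species, f"pct_2090_{tag}"])
            trend[species][rcp] = {
                "T1": t2 / 2.0, "T2": t2, "T3": (t2 + t4) / 2.0, "T4": t4,
            }
    return trend


@dataclass
class SyntheticConfig:
    """Configuration of the synthetic input generator.

    Defaults emulate the 2007-2016 monthly panel of the 16 modeled
    fisheries: 120 months, 4 groups x 4 species, baseline expenditure of
    3,080 MM$/yr spread over 12 months, small share noise, and habitat
    trends matching the published ensemble projections.
    """

    seed: int = 0
    n_months: int = 120
    start_year: int = 2007
    species_groups: dict[str, list[str]] = field(
        default_factory=lambda: {g: list(s) for g, s in ref.SPECIES_GROUPS.items()}
    )
    true_params_stage1: IaidsParams = field(default_factory=default_stage1_params)
    true_params_stage2: dict[str, IaidsParams] = field(
        default_factory=default_stage2_params
    )
    share_noise_sd: float = 0.01
    habitat_trend: dict[str, dict[str, dict[str, float]]] = field(
        default_factory=default_habitat_trend
    )
    gcm_spread_sd: float = 0.08
    total_expenditure_level: float = ref.EXPENDITURE_BASE_AVERAGE / 12.0
    seasonal_amplitude: float = 0.3
    ar1_rho: float = 0.5
    ar1_sd: float = 0.15

    def __post_init__(self) -> None:
        if self.share_noise_sd < 0 or self.gcm_spread_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.n_months < 1:
            raise ValueError("n_months must be positive")
        groups = list(self.species_groups)
        if list(self.true_params_stage1.labels or groups) != groups:
            raise ValueError("stage-1 labels must match the group labels")
        self.true_params_stage1.validate()
        for g in groups:
            if g not in self.true_params_stage2:
                raise ValueError(f"missing stage-2 parameters for group {g!r}")
            p = self.true_params_stage2[g]
            if p.n != len(self.species_groups[g]):
                raise ValueError(f"stage-2 system size mismatch for group {g!r}")
            p.validate()

    @property
    def species(self) -> list[str]:
        return [s for ss in self.species_groups.values() for s in ss]


def _noisy_shares(w: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Additive Gaussian noise on the first n-1 shares; last is the residual."""
    if sd == 0:
        return w
    out = w.copy()
    out[:-1] = out[:-1] + rng.normal(0.0, sd, size=w.size - 1)
    out[-1] = 1.0 - out[:-1].sum()
    return out


def gen_demand_history(cfg: SyntheticConfig) -> pd.DataFrame:
    """Monthly landings panel drawn from the true two-stage IAIDS process.

    For each month, species log quantities follow a seasonal sinusoid plus
    AR(1) Gaussian noise around species-specific means set by the baseline
    harvests.  Expenditure shares are the exact Stone-index fixed point of
    the true share equations (stage 2 within each group, then stage 1
    across groups) plus renormalized additive noise; revenue is share x
    stage expenditure and price falls out as revenue/quantity.

    Returns a long DataFrame with columns (species, region, group, year,
    month, pounds_mm, revenue_mm_2018usd).  Deterministic given the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    groups = list(cfg.species_groups)
    base = ref.modeled_species_table().set_index("species")
    T = cfg.n_months

    # per-species monthly log-quantity process
    lnq: dict[str, np.ndarray] = {}
    for s in cfg.species:
        if s in base.index:
            mu = np.log(base.loc[s, "mean_pounds"] / 12.0)
        else:  # non-default species label: unit-scale baseline
            mu = 0.0
        phase = rng.uniform(0, 2 * np.pi)
        season = cfg.seasonal_amplitude * np.sin(
            2 * np.pi * np.arange(T) / 12.0 + phase
        )
        eps = np.empty(T)
        innov_sd = cfg.ar1_sd * np.sqrt(1 - cfg.ar1_rho**2)
        eps[0] = rng.normal(0.0, cfg.ar1_sd)
        for t in range(1, T):
            eps[t] = cfg.ar1_rho * eps[t - 1] + rng.normal(0.0, innov_sd)
        lnq[s] = mu + season + eps  # log of a positive number: q > 0 always

    records = []
    for t in range(T):
        year = cfg.start_year + t // 12
        month = t % 12 + 1
        E_total = cfg.total_expenditure_level

        # stage 2: within-group shares at the Stone fixed point
        w2: dict[str, np.ndarray] = {}
        ln_group = np.empty(len(groups))
        for gi, g in enumerate(groups):
            lnq_g = np.array([lnq[s][t] for s in cfg.species_groups[g]])
            w_exact, _ = solve_share_fixed_point(cfg.true_params_stage2[g], lnq_g)
            w2[g] = _noisy_shares(w_exact, cfg.share_noise_sd, rng)
            # group quantity index: Stone over member species
            ln_group[gi] = stone_index(w2[g], lnq_g)

        # stage 1: group shares at the Stone fixed point
        w1_exact, _ = solve_share_fixed_point(cfg.true_params_stage1, ln_group)
        w1 = _noisy_shares(w1_exact, cfg.share_noise_sd, rng)

        for gi, g in enumerate(groups):
            E_group = w1[gi] * E_total
            for si, s in enumerate(cfg.species_groups[g]):
                q = float(np.exp(lnq[s][t]))
                rev = float(w2[g][si] * E_group)
                records.append(
                    (s, ref.SPECIES_REGION.get(s, "East Coast"), g,
                     year, month, q, rev)
                )

    return pd.DataFrame(
        records,
        columns=["species", "region", "group", "year", "month",
                 "pounds_mm", "revenue_mm_2018usd"],
    )


def gen_habitat_table(cfg: SyntheticConfig) -> pd.DataFrame:
    """Habitat-projection table: (species, region, rcp, gcm, bin) totals.

    Each future-bin value is baseline_level x (1 + trend(bin)) x
    exp(GCM noise), with log-normal noise independent across GCMs and
    bins; the baseline bin is shared (noise-free) across GCMs.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    rows = []
    for s in cfg.species:
        region = ref.SPECIES_REGION.get(s, "East Coast")
        base_level = 100.0
        trend_s = cfg.habitat_trend.get(s, {})
        for rcp in RCPS:
            trend = trend_s.get(rcp, {})
            for gcm in GCMS:
                rows.append((s, region, rcp, gcm, "B0", base_level))
                for b in ("T1", "T2", "T3", "T4"):
                    noise = (
                        np.exp(rng.normal(0.0, cfg.gcm_spread_sd))
                        if cfg.gcm_spread_sd > 0 else 1.0
                    )
                    val = base_level * (1.0 + trend.get(b, 0.0)) * noise
                    rows.append((s, region, rcp, gcm, b, val))
    return pd.DataFrame(
        rows, columns=["species", "region", "rcp", "gcm", "bin", "habitat_total"]
    )


def packaged_gdp_path() -> pd.DataFrame:
    """Annual GDP path 2020-2100 (billions 2018 US$).

    The packaged decadal projection, linearly interpolated to annual
    resolution; the 2007-2016 average is available as
    ``reference.GDP_BASE_AVERAGE``.
    """
    return ref.annual_gdp_path()


def write_synthetic_inputs(cfg: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the three input CSVs plus a JSON sidecar echoing the config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "landings": outdir / "landings_panel.csv",
        "habitat": outdir / "habitat_projections.csv",
        "gdp": outdir / "gdp_path.csv",
        "sidecar": outdir / "synthetic_config.json",
    }
    gen_demand_history(cfg).to_csv(paths["landings"], index=False)
    gen_habitat_table(cfg).to_csv(paths["habitat"], index=False)
    packaged_gdp_path().to_csv(paths["gdp"], index=False)
    sidecar = {
        "seed": cfg.seed,
        "n_months": cfg.n_months,
        "start_year": cfg.start_year,
        "share_noise_sd": cfg.share_noise_sd,
        "gcm_spread_sd": cfg.gcm_spread_sd,
        "total_expenditure_level": cfg.total_expenditure_level,
        "species_groups": cfg.species_groups,
        "true_params_stage1": {
            "alpha": cfg.true_params_stage1.alpha.tolist(),
            "beta": cfg.true_params_stage1.beta.tolist(),
            "gamma": cfg.true_params_stage1.gamma.tolist(),
        },
        "true_params_stage2": {
            g: {"alpha": p.alpha.tolist(), "beta": p.beta.tolist(),
                "gamma": p.gamma.tolist()}
            for g, p in cfg.true_params_stage2.items()
        },
        "habitat_trend": cfg.habitat_trend,
    }
    paths["sidecar"].write_text(json.dumps(sidecar, indent=2))
    return paths
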