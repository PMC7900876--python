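"""End-to-end orchestration: screening and welfare runs with file output.

Ties the stages together on synthetic inputs: generate the landings panel
and habitat table, run the screening analysis (regional and top-fishery
present-value tables, Monte Carlo CIs), estimate the two-stage demand
system, forecast expenditures and prices, and compute the welfare series
and NPVs.  Every run writes CSV tables plus a JSON manifest (config echo,
package version, seed) from which the outputs are reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import __version__
from . import reference as ref
from .demand import InverseAIDS, flexibilities
from .forecast import (allocate_stage1, allocate_stage2, forecast_expenditures,
                       group_quantity_index, implied_prices)
from .screening import (aggregate_regions, annualize, annuity_factor,
                        baseline_stats, habitat_change, monte_carlo_ci,
                        present_value, project_landings)
from .synthetic import (GCMS, RCPS, SyntheticConfig, gen_demand_history,
                        gen_habitat_table, packaged_gdp_path)
from .welfare import welfare_npv, welfare_series

__all__ = ["RunConfig", "run_screening", "run_welfare", "panel_to_stage_obs"]

log = logging.getLogger("fishclim")


class RunConfig(BaseModel):
    """Configuration of one reproducible pipeline run."""

    seed: int = 0
    n_months: int = 120
    share_noise_sd: float = 0.01
    gcm_spread_sd: float = 0.08
    rcp: str = "both"
    discount_rate: float = Field(default=0.03, gt=-1.0)
    income_elasticity: float = 0.11
    n_draws: int = Field(default=10_000, ge=1)
    base_year: int = 2020
    monetization: str = "compensating"
    habitat_trend_scale: float = 1.0
    outdir: str = "fishclim_output"

    @field_validator("rcp")
    @classmethod
    def _check_rcp(cls, v: str) -> str:
        if v not in {"RCP4.5", "RCP8.5", "both"}:
            raise ValueError("rcp must be 'RCP4.5', 'RCP8.5' or 'both'")
        return v

    @property
    def rcps(self) -> list[str]:
        return list(RCPS) if self.rcp == "both" else [self.rcp]

    def synthetic_config(self) -> SyntheticConfig:
        scfg = SyntheticConfig(
            seed=self.seed, n_months=self.n_months,
            share_noise_sd=self.share_noise_sd,
            gcm_spread_sd=self.gcm_spread_sd,
        )
        if self.habitat_trend_scale != 1.0:
            scfg.habitat_trend = {
                s: {rcp: {b: v * self.habitat_trend_scale
                          for b, v in bins.items()}
                    for rcp, bins in per_rcp.items()}
                for s, per_rcp in scfg.habitat_trend.items()
            }
        return scfg


def _write_manifest(cfg: RunConfig, outdir: Path, stage: str,
                    extra: dict | None = None) -> None:
    manifest = {
        "stage": stage,
        "package": "fishclim",
        "version": __version__,
        "config": cfg.model_dump(),
    }
    if extra:
        manifest.update(extra)
    (outdir / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2))


def _species_trajectories(habitat: pd.DataFrame, rcp: str,
                          years=(2021, 2100)) -> tuple[pd.DataFrame, dict]:
    """Ensemble and per-GCM annual multipliers per (species, region)."""
    dh = habitat_change(habitat)
    dh = dh[dh["rcp"] == rcp]
    ens_mult = {}
    gcm_mult = {}
    for (sp, rg), g in dh.groupby(["species", "region"], sort=True):
        by_gcm = {}
        for gcm, gg in g.groupby("gcm"):
            by_gcm[gcm] = annualize(dict(zip(gg["bin"], gg["dh"])), years)
        ens_mult[(sp, rg)] = by_gcm.pop("ensemble")
        gcm_mult[(sp, rg)] = by_gcm
    return ens_mult, gcm_mult


def run_screening(cfg: RunConfig) -> dict[str, Path]:
    """Synthetic screening run: PV tables and Monte Carlo CIs, written as CSV."""
    t0 = time.time()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scfg = cfg.synthetic_config()
    panel = gen_demand_history(scfg)
    habitat = gen_habitat_table(scfg)
    stats = baseline_stats(panel)
    af = annuity_factor(cfg.discount_rate, base_year=cfg.base_year)
    ss = np.random.SeedSequence([scfg.seed, 2])  # screening MC substream

    paths: dict[str, Path] = {}
    for rcp in cfg.rcps:
        tag = rcp.replace("RCP", "rcp").replace(".", "")
        ens_mult, gcm_mult = _species_trajectories(habitat, rcp)
        rows = []
        ci_rows = []
        child_seeds = ss.spawn(len(stats))
        for (idx, rec), child in zip(stats.iterrows(), child_seeds):
            key = (rec["species"], rec["region"])
            if key not in ens_mult:
                continue
            m = ens_mult[key]
            proj_rev = project_landings(rec["mean_revenue"], m)
            dpv = present_value(proj_rev, cfg.discount_rate, cfg.base_year) \
                - rec["mean_revenue"] * af
            rows.append((rec["species"], rec["region"], rec["mean_revenue"],
                         rec["sd_revenue"], dpv,
                         dpv / (rec["mean_revenue"] * af)))
            per_gcm = gcm_mult[key]
            for target_year in (2050, 2090):
                mults = np.array([per_gcm[g].loc[target_year] for g in GCMS])
                point, lo, hi = monte_carlo_ci(
                    np.asarray(rec["annual_pounds"]), mults,
                    n_draws=cfg.n_draws, seed=child,
                )
                ci_rows.append((rec["species"], rec["region"], target_year,
                                rec["mean_pounds"],
                                rec["mean_pounds"] * m.loc[target_year],
                                point, lo, hi))
        species_pv = pd.DataFrame(
            rows, columns=["species", "region", "mean_revenue", "sd_revenue",
                           "dpv", "pct_change"],
        ).sort_values("mean_revenue", ascending=False)
        regional = aggregate_regions(
            species_pv[["species", "region", "mean_revenue", "dpv"]],
            cfg.discount_rate, base_year=cfg.base_year,
        )
        projections = pd.DataFrame(
            ci_rows, columns=["species", "region", "year", "baseline_pounds",
                              "projected_pounds", "pct_change", "ci_lo", "ci_hi"],
        )
        for name, df in (("screening_species", species_pv),
                         ("screening_regional", regional),
                         ("harvest_projections", projections)):
            p = outdir / f"{name}_{tag}.csv"
            df.to_csv(p, index=False)
            paths[f"{name}_{tag}"] = p

    _write_manifest(cfg, outdir, "screening",
                    {"annuity_factor": af, "n_species": int(len(stats))})
    log.info("screening run finished in %.1fs", time.time() - t0)
    return paths


def panel_to_stage_obs(panel: pd.DataFrame, species_groups: dict[str, list[str]]):
    """Monthly panel -> estimation observations for both stages.

    Returns ``(stage1, stage2)`` where stage1 is a dict with (T, G) arrays
    ``lnq`` (Stone group quantity indices, observed within-group shares)
    and ``w`` (group expenditure shares), and stage2 maps each group to
    its (T, n_g) ``lnq``/``w`` arrays.
    """
    groups = list(species_groups)
    q = panel.pivot_table(index=["year", "month"], columns="species",
                          values="pounds_mm", sort=True)
    rev = panel.pivot_table(index=["year", "month"], columns="species",
                            values="revenue_mm_2018usd", sort=True)
    lnq = np.log(q)
    stage2 = {}
    ln_group = {}
    w_group_rev = {}
    for g in groups:
        sp = species_groups[g]
        r = rev[sp].to_numpy()
        w = r / r.sum(axis=1, keepdims=True)
        stage2[g] = {"lnq": lnq[sp].to_numpy(), "w": w, "labels": sp}
        ln_group[g] = (w * lnq[sp].to_numpy()).sum(axis=1)
        w_group_rev[g] = r.sum(axis=1)
    total = np.column_stack([w_group_rev[g] for g in groups]).sum(axis=1)
    stage1 = {
        "lnq": np.column_stack([ln_group[g] for g in groups]),
        "w": np.column_stack([w_group_rev[g] / total for g in groups]),
        "labels": groups,
    }
    return stage1, stage2


def _elasticity_frame(model: InverseAIDS, labels: list[str],
                      group: str | None = None) -> pd.DataFrame:
    tab = flexibilities(model.params_, model.mean_shares_)
    n = len(labels)
    df = pd.DataFrame({
        "name": labels,
        "own_flexibility": np.diag(tab.flexibility),
        "own_elasticity": np.diag(tab.elasticity),
        "elasticity_lo": tab.own_elas_lo if tab.own_elas_lo is not None else [np.nan] * n,
        "elasticity_hi": tab.own_elas_hi if tab.own_elas_hi is not None else [np.nan] * n,
    })
    # flag which reading of the table is reported, see module docs
    df["reported_column"] = "own_elasticity (inverse flexibility matrix)"
    if group is not None:
        df.insert(0, "group", group)
    return df


def run_welfare(cfg: RunConfig) -> dict[str, Path]:
    """Estimation + forecast + welfare run on synthetic inputs."""
    t0 = time.time()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scfg = cfg.synthetic_config()
    panel = gen_demand_history(scfg)
    habitat = gen_habitat_table(scfg)
    groups = list(scfg.species_groups)

    # --- estimation -------------------------------------------------------
    stage1, stage2 = panel_to_stage_obs(panel, scfg.species_groups)
    m1 = InverseAIDS().fit(stage1["lnq"], stage1["w"], labels=stage1["labels"])
    m2 = {g: InverseAIDS().fit(d["lnq"], d["w"], labels=d["labels"])
          for g, d in stage2.items()}
    log.info("estimation done (%.1fs): stage-1 iters=%d", time.time() - t0,
             m1.n_iter_)

    paths: dict[str, Path] = {}
    e1 = _elasticity_frame(m1, groups)
    p = outdir / "elasticities_stage1.csv"
    e1.to_csv(p, index=False); paths["elasticities_stage1"] = p
    e2 = pd.concat([_elasticity_frame(m2[g], stage2[g]["labels"], g)
                    for g in groups], ignore_index=True)
    p = outdir / "elasticities_stage2.csv"
    e2.to_csv(p, index=False); paths["elasticities_stage2"] = p

    # --- expenditure forecast --------------------------------------------
    e_base = float(panel.groupby("year")["revenue_mm_2018usd"].sum().mean())
    gdp = packaged_gdp_path()
    expend = forecast_expenditures(gdp, cfg.income_elasticity,
                                   anchor=(2020, e_base), base=e_base)
    p = outdir / "expenditure_forecast.csv"
    expend.to_csv(p, index=False); paths["expenditure_forecast"] = p
    e_path = expend.set_index("year")["expenditure_mm"]

    # baseline bundles: geometric-mean monthly quantities (the estimation
    # anchor point, so baseline shares reproduce the sample means exactly)
    q = panel.pivot_table(index=["year", "month"], columns="species",
                          values="pounds_mm", sort=True)
    lnq_base = np.log(q).mean(axis=0)
    rev_mean = panel.groupby("species")["revenue_mm_2018usd"].mean()
    w2_base = {g: (rev_mean[scfg.species_groups[g]]
                   / rev_mean[scfg.species_groups[g]].sum()).to_numpy()
               for g in groups}

    price_rows = []
    welfare_tables = {}
    npv_tables = {}
    for rcp in cfg.rcps:
        tag = rcp.replace("RCP", "rcp").replace(".", "")
        ens_mult, _ = _species_trajectories(habitat, rcp,
                                            years=(cfg.base_year, 2100))
        years = np.arange(cfg.base_year, 2101)
        # per-species monthly-scale quantity paths
        lnq_paths = {}
        for s in scfg.species:
            key = (s, ref.SPECIES_REGION.get(s, "East Coast"))
            m = ens_mult[key].loc[years]
            lnq_paths[s] = lnq_base[s] + np.log(m.to_numpy())
        lnq_sp = {g: pd.DataFrame({s: lnq_paths[s]
                                   for s in scfg.species_groups[g]}, index=years)
                  for g in groups}
        group_lnq = pd.DataFrame(
            {g: group_quantity_index(lnq_sp[g], w2_base[g]) for g in groups})
        group_E = allocate_stage1(m1, group_lnq, e_path)
        species_E = pd.concat(
            [allocate_stage2(m2[g], lnq_sp[g], group_E[g]) for g in groups],
            axis=1)
        q_annual = pd.DataFrame(
            {s: 12.0 * np.exp(lnq_paths[s]) for s in scfg.species}, index=years)
        prices = implied_prices(species_E, q_annual)
        base_price = rev_mean / q.mean(axis=0)  # monthly MM$ over monthly MM lb
        for g in groups:
            for s in scfg.species_groups[g]:
                price_rows.append(
                    (rcp, g, s, base_price[s],
                     prices.loc[2100, s] / prices.loc[cfg.base_year, s] - 1.0))

        quantities = {g: np.exp(lnq_sp[g]) for g in groups}
        baselines = {g: np.exp(lnq_base[scfg.species_groups[g]].to_numpy())
                     for g in groups}
        wf = welfare_series({g: m2[g].params_ for g in groups}, quantities,
                            baselines, group_E, cfg.monetization)
        welfare_tables[rcp] = wf
        npv_tables[rcp] = welfare_npv(wf, cfg.discount_rate, cfg.base_year)
        p = outdir / f"welfare_annual_{tag}.csv"
        wf.rename_axis("year").to_csv(p); paths[f"welfare_annual_{tag}"] = p

    price_df = pd.DataFrame(
        price_rows, columns=["rcp", "group", "species", "baseline_price",
                             "pct_change_2100"])
    p = outdir / "price_forecast.csv"
    price_df.to_csv(p, index=False); paths["price_forecast"] = p

    npv_df = pd.DataFrame(npv_tables).rename_axis("group")
    p = outdir / "welfare_npv.csv"
    npv_df.to_csv(p); paths["welfare_npv"] = p

    try:  # optional annual-impacts figure
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(7, 4))
        for rcp, wf in welfare_tables.items():
            ax.plot(wf.index, wf["total"], label=rcp)
        ax.set_xlabel("Year")
        ax.set_ylabel("Annual consumer welfare impact (MM 2018 US$)")
        ax.axhline(0.0, color="0.6", lw=0.8)
        ax.legend()
        fig.tight_layout()
        figpath = outdir / "welfare_annual.png"
        fig.savefig(figpath, dpi=120)
        plt.close(fig)
        paths["figure"] = figpath
    except Exception as exc:  # pragma: no cover - plotting is best-effort
        log.warning("figure not written: %s", exc)

    _write_manifest(cfg, outdir, "welfare", {
        "expenditure_growth_vs_base": expend.attrs["growth_vs_base"],
        "stage1_iterations": m1.n_iter_,
    })
    log.info("welfare run finished in %.1fs", time.time() - t0)
    return paths
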