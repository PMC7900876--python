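import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fishclim.screening import (aggregate_regions, annualize, annuity_factor,
                                baseline_stats, deflate, habitat_change,
                                match_records, monte_carlo_ci, present_value,
                                project_landings)


def _panel(records):
    return pd.DataFrame(
        records,
        columns=["species", "region", "year", "month", "pounds_mm",
                 "revenue_mm_2018usd"],
    )


class TestDeflate:
    def test_constant_cpi_leaves_revenue_unchanged(self):
        panel = _panel([("a", "East Coast", 2010, 1, 1.0, 100.0)])
        cpi = {2010: 200.0, 2018: 200.0}
        out = deflate(panel, cpi)
        assert out["revenue_mm_2018usd"].iloc[0] == 100.0

    def test_direct_ratio(self):
        panel = _panel([("a", "East Coast", 2010, 1, 1.0, 100.0)])
        out = deflate(panel, {2010: 200.0, 2018: 250.0})
        assert out["revenue_mm_2018usd"].iloc[0] == pytest.approx(125.0)
        # quantities untouched
        assert out["pounds_mm"].iloc[0] == 1.0

    def test_round_trip(self, noisy_panel):
        cpi = {y: 180.0 + 2.5 * (y - 2007) for y in range(2007, 2019)}
        inv = {y: cpi[2018] ** 2 / cpi[y] for y in cpi}
        back = deflate(deflate(noisy_panel, cpi), inv)
        np.testing.assert_allclose(back["revenue_mm_2018usd"],
                                   noisy_panel["revenue_mm_2018usd"],
                                   rtol=1e-12)

    def test_missing_year_named_in_error(self):
        panel = _panel([("a", "East Coast", 2011, 1, 1.0, 1.0)])
        with pytest.raises(KeyError, match="2011"):
            deflate(panel, {2018: 250.0})


class TestBaselineStats:
    def test_identical_annual_totals_have_zero_sd(self):
        recs = [("a", "East Coast", y, m, 1.0, 2.0)
                for y in (2007, 2008) for m in (1, 2)]
        stats = baseline_stats(_panel(recs))
        assert stats["sd_revenue"].iloc[0] == 0.0
        assert stats["mean_revenue"].iloc[0] == pytest.approx(4.0)

    def test_two_point_formula(self):
        recs = [("a", "East Coast", 2007, 1, 1.0, 100.0),
                ("a", "East Coast", 2008, 1, 1.0, 120.0)]
        stats = baseline_stats(_panel(recs))
        assert stats["mean_revenue"].iloc[0] == pytest.approx(110.0)
        assert stats["sd_revenue"].iloc[0] == pytest.approx(np.sqrt(200.0))

    def test_single_year_sd_missing(self):
        stats = baseline_stats(_panel([("a", "East Coast", 2007, 1, 1.0, 1.0)]))
        assert np.isnan(stats["sd_revenue"].iloc[0])

    def test_matches_brute_force_on_synthetic_panel(self, noisy_panel):
        stats = baseline_stats(
            noisy_panel[["species", "region", "year", "month", "pounds_mm",
                         "revenue_mm_2018usd"]])
        sp = "Blue crab"
        sub = noisy_panel[noisy_panel["species"] == sp]
        expected = sub["revenue_mm_2018usd"].sum() / sub["year"].nunique()
        got = stats.loc[stats["species"] == sp, "mean_revenue"].iloc[0]
        assert got == pytest.approx(expected)


class TestMatchRecords:
    @pytest.fixture
    def landings(self):
        return pd.DataFrame({
            "species": ["cod", "scup", "skates", "minnow", "eel"],
            "region": ["East Coast"] * 5,
            "mean_revenue": [10.0, 5.0, 3.0, 0.05, 2.0],
        })

    @pytest.fixture
    def habitat(self):
        return pd.DataFrame({
            "species": ["cod", "porgy"],
            "region": ["East Coast", "East Coast"],
        })

    def test_hand_classified_fixture(self, landings, habitat):
        out = match_records(landings, habitat, synonyms={"scup": "porgy"},
                            multi_species_flags={"skates"})
        got = out.set_index("species")["disposition"]
        assert got["cod"] == "matched-automated"
        assert got["scup"] == "matched-manual"
        assert got["skates"] == "excluded-multi-species"
        assert got["minnow"] == "excluded-de-minimis"
        assert got["eel"] == "excluded-no-projection"
        # partition: one class per record, revenue shares sum to 1
        assert out["disposition"].notna().all()
        assert out["revenue_share"].sum() == pytest.approx(1.0)

    def test_empty_habitat_table_matches_nothing(self, landings):
        out = match_records(landings, pd.DataFrame({"species": [],
                                                    "region": []}))
        assert not out["disposition"].str.startswith("matched").any()

    def test_de_minimis_boundary_is_strict(self, habitat):
        rec = pd.DataFrame({"species": ["eel"], "region": ["East Coast"],
                            "mean_revenue": [0.1]})
        out = match_records(rec, habitat)
        assert out["disposition"].iloc[0] == "excluded-no-projection"

    def test_ambiguous_curation_raises(self, landings, habitat):
        with pytest.raises(ValueError, match="ambiguous"):
            match_records(landings, habitat, synonyms={"skates": "porgy"},
                          multi_species_flags={"skates"})


def _habitat_rows(values_by_gcm):
    rows = []
    for gcm, bins in values_by_gcm.items():
        for b, v in bins.items():
            rows.append(("s", "East Coast", "RCP4.5", gcm, b, v))
    return pd.DataFrame(rows, columns=["species", "region", "rcp", "gcm",
                                       "bin", "habitat_total"])


class TestHabitatChange:
    def test_flat_habitat_gives_zero_change(self):
        tab = _habitat_rows({"g1": {b: 50.0 for b in
                                    ("B0", "T1", "T2", "T3", "T4")}})
        dh = habitat_change(tab)
        np.testing.assert_allclose(dh["dh"], 0.0)

    def test_single_gcm_ratio(self):
        bins = {"B0": 100.0, "T1": 100.0, "T2": 100.0, "T3": 100.0,
                "T4": 150.0}
        dh = habitat_change(_habitat_rows({"g1": bins}))
        t4 = dh[(dh["bin"] == "T4") & (dh["gcm"] == "g1")]["dh"].iloc[0]
        assert t4 == pytest.approx(0.5)

    def test_ensemble_is_arithmetic_mean_of_gcm_changes(self):
        gcms = {}
        for i, d in enumerate([0.1, 0.2, 0.3, 0.4, 0.5]):
            gcms[f"g{i}"] = {"B0": 100.0, "T1": 100.0, "T2": 100.0,
                             "T3": 100.0, "T4": 100.0 * (1 + d)}
        dh = habitat_change(_habitat_rows(gcms))
        ens = dh[(dh["bin"] == "T4") & (dh["gcm"] == "ensemble")]["dh"].iloc[0]
        assert ens == pytest.approx(0.3)
        per_gcm = dh[(dh["bin"] == "T4") & (dh["gcm"] != "ensemble")]["dh"]
        assert per_gcm.min() <= ens <= per_gcm.max()

    def test_zero_baseline_raises(self):
        bins = {"B0": 0.0, "T1": 1.0, "T2": 1.0, "T3": 1.0, "T4": 1.0}
        with pytest.raises(ValueError, match="zero baseline"):
            habitat_change(_habitat_rows({"g1": bins}))

    def test_incomplete_bins_raise(self):
        tab = _habitat_rows({"g1": {"B0": 1.0, "T1": 1.0}})
        with pytest.raises(ValueError, match="incomplete"):
            habitat_change(tab)


class TestAnnualize:
    def test_zero_change_gives_unit_multipliers(self):
        m = annualize({"B0": 0.0, "T1": 0.0, "T2": 0.0, "T3": 0.0, "T4": 0.0})
        np.testing.assert_allclose(m, 1.0)
        assert list(m.index) == list(range(2021, 2101))

    def test_hand_interpolation_between_bins(self):
        m = annualize({"B0": 0.0, "T1": 0.10, "T2": 0.20, "T3": 0.20,
                       "T4": 0.20})
        # 2040 sits (2040 - 2030.5)/20 of the way from T1 to T2
        assert m.loc[2040] == pytest.approx(
            1 + 0.10 + 0.10 * (2040 - 2030.5) / 20)

    def test_flat_tail_beyond_last_anchor(self):
        m = annualize({"B0": 0.0, "T1": 0.1, "T2": 0.2, "T3": 0.3, "T4": 0.4})
        assert m.loc[2095] == m.loc[2091] == pytest.approx(1.4)


class TestProjectAndDiscount:
    def test_unit_multipliers_give_flat_series(self):
        m = annualize({"B0": 0.0, "T1": 0.0, "T2": 0.0, "T3": 0.0, "T4": 0.0})
        s = project_landings(168.3, m)
        np.testing.assert_allclose(s, 168.3)

    def test_blue_crab_2090_projection(self):
        assert 168.3 * 1.156 == pytest.approx(194.6, abs=0.05)

    def test_zero_multiplier_zero_landings(self):
        m = pd.Series(0.0, index=range(2021, 2101))
        assert project_landings(100.0, m).sum() == 0.0

    def test_annuity_factor_closed_form(self):
        af = annuity_factor(0.03)
        assert af == pytest.approx((1 - 1.03 ** -80) / 0.03)
        assert af == pytest.approx(30.2008, abs=5e-5)

    def test_pv_of_constant_series_is_annuity(self):
        s = pd.Series(1.0, index=range(2021, 2101))
        assert present_value(s) == pytest.approx(annuity_factor())
        assert present_value(0.0 * s) == 0.0

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(a=st.floats(-5, 5), b=st.floats(-5, 5))
    def test_pv_linearity(self, a, b):
        years = range(2021, 2101)
        rng = np.random.default_rng(0)
        x = pd.Series(rng.normal(size=80), index=years)
        y = pd.Series(rng.normal(size=80), index=years)
        lhs = present_value(a * x + b * y)
        rhs = a * present_value(x) + b * present_value(y)
        assert lhs == pytest.approx(rhs, abs=1e-9 * (1 + abs(a) + abs(b)))


class TestAggregateRegions:
    def test_one_species_per_region(self):
        df = pd.DataFrame({
            "species": ["a", "b", "c", "d"],
            "region": ["East Coast", "Gulf Coast", "West Coast", "Alaska"],
            "mean_revenue": [1.0, 2.0, 3.0, 4.0],
            "dpv": [10.0, -20.0, 30.0, -40.0],
        })
        out = aggregate_regions(df).set_index("region")
        assert out.loc["East Coast", "dpv"] == 10.0
        assert out.loc["Subtotal: Atlantic", "dpv"] == pytest.approx(-10.0)
        assert out.loc["Subtotal: Pacific", "dpv"] == pytest.approx(-10.0)
        assert out.loc["Total", "dpv"] == pytest.approx(-20.0)

    def test_all_negative_species_give_negative_totals(self):
        df = pd.DataFrame({
            "species": ["a", "b"],
            "region": ["East Coast", "Alaska"],
            "mean_revenue": [1.0, 1.0],
            "dpv": [-1.0, -2.0],
        })
        out = aggregate_regions(df).set_index("region")
        assert (out["dpv"] < 0).all()

    def test_percentage_formula_reproduces_total(self):
        df = pd.DataFrame({
            "species": ["a"], "region": ["East Coast"],
            "mean_revenue": [3.775], "dpv": [-1.037],
        })
        out = aggregate_regions(df).set_index("region")
        assert out.loc["Total", "pct_change"] == pytest.approx(-0.009, abs=5e-4)


class TestMonteCarloCI:
    def test_degenerate_inputs_collapse_to_point(self):
        vals = np.full(10, 50.0)
        mults = np.full(5, 1.2)
        point, lo, hi = monte_carlo_ci(vals, mults, n_draws=500, seed=0)
        assert point == pytest.approx(0.2)
        assert lo == pytest.approx(0.2)
        assert hi == pytest.approx(0.2)

    def test_normal_theory_width(self):
        """Bootstrap CI width matches the normal-theory oracle for iid data."""
        rng = np.random.default_rng(5)
        mu, sigma, n = 100.0, 8.0, 10
        vals = rng.normal(mu, sigma, size=n)
        mults = np.full(5, 1.1)
        _, lo, hi = monte_carlo_ci(vals, mults, n_draws=200_000, seed=1)
        # bootstrap sd of the mean uses the population-style (1/n) variance
        s_boot = np.std(vals, ddof=0) / np.sqrt(n)
        expected = 2 * 1.96 * 1.1 * s_boot / np.mean(vals)
        assert (hi - lo) == pytest.approx(expected, rel=0.05)

    def test_seeded_reproducibility(self):
        vals = np.arange(10.0) + 50.0
        mults = np.array([0.9, 1.0, 1.1, 1.2, 1.3])
        a = monte_carlo_ci(vals, mults, n_draws=2000, seed=9)
        b = monte_carlo_ci(vals, mults, n_draws=2000, seed=9)
        c = monte_carlo_ci(vals, mults, n_draws=2000, seed=10)
        assert a == b
        assert a != c

    def test_requires_two_years(self):
        with pytest.raises(ValueError):
            monte_carlo_ci(np.array([1.0]), np.ones(5))
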