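import numpy as np
import pandas as pd
import pytest

from impact_atlas.trade import (
    FLOW_COLS,
    PROD_COLS,
    OriginMatrix,
    TradeTensor,
    average_flows,
    combine_sugar_items,
    major_suppliers,
    read_faostat_csv,
    supplier_table,
    trace_origins,
)

from oracles import (
    linear_solve_attribution,
    path_enumeration_attribution,
    random_acyclic_network,
)


def tensor_from(flows, production):
    """flows: (item, exporter, importer, tonnes); production: (item, country, tonnes)."""
    fl = pd.DataFrame(
        [(-1, *f) for f in flows], columns=FLOW_COLS
    )
    pr = pd.DataFrame([(-1, *p) for p in production], columns=PROD_COLS)
    return TradeTensor(fl, pr)


class TestTradeTensor:
    def test_rejects_negative_tonnage(self):
        with pytest.raises(ValueError):
            tensor_from([("w", "A", "B", -1.0)], [])

    def test_rejects_domestic_flow_records(self):
        with pytest.raises(ValueError):
            tensor_from([("w", "A", "A", 1.0)], [])


class TestAverageFlows:
    def test_window_mean(self):
        fl = pd.DataFrame(
            [(2003, "w", "A", "B", 10.0), (2004, "w", "A", "B", 20.0)], columns=FLOW_COLS
        )
        t = TradeTensor(fl, pd.DataFrame(columns=PROD_COLS))
        out = average_flows(t, (2003, 2004))
        assert out.flows["tonnes"].iloc[0] == 15.0

    def test_missing_years_count_as_zero(self):
        fl = pd.DataFrame([(2003, "w", "A", "B", 22.0)], columns=FLOW_COLS)
        t = TradeTensor(fl, pd.DataFrame(columns=PROD_COLS))
        out = average_flows(t, (2003, 2013))
        assert out.flows["tonnes"].iloc[0] == pytest.approx(2.0)

    def test_single_year_window_is_identity(self):
        fl = pd.DataFrame([(2005, "w", "A", "B", 7.0)], columns=FLOW_COLS)
        pr = pd.DataFrame([(2005, "w", "A", 100.0)], columns=PROD_COLS)
        out = average_flows(TradeTensor(fl, pr), (2005, 2005))
        assert out.flows["tonnes"].iloc[0] == 7.0
        assert out.production["tonnes"].iloc[0] == 100.0

    def test_empty_window_rejected(self):
        t = tensor_from([], [])
        with pytest.raises(ValueError):
            average_flows(t, (2010, 2009))


class TestCombineSugarItems:
    def test_cane_and_beet_sum_on_shared_dyad(self):
        t = tensor_from(
            [("sugarcane", "A", "B", 5.0), ("sugarbeet", "A", "B", 3.0)],
            [("sugarcane", "A", 50.0), ("sugarbeet", "A", 30.0)],
        )
        out = combine_sugar_items(t)
        assert out.flows["item"].unique().tolist() == ["sugar"]
        assert out.flows["tonnes"].iloc[0] == 8.0
        assert out.production["tonnes"].iloc[0] == 80.0

    def test_only_cane_present(self):
        t = tensor_from([("sugarcane", "A", "B", 5.0)], [])
        out = combine_sugar_items(t)
        assert out.flows["item"].iloc[0] == "sugar"
        assert out.flows["tonnes"].iloc[0] == 5.0

    def test_non_sugar_items_untouched(self):
        t = tensor_from([("wheat", "A", "B", 5.0)], [("wheat", "A", 9.0)])
        out = combine_sugar_items(t)
        assert out.flows["item"].iloc[0] == "wheat"


class TestTraceOrigins:
    def test_no_reexport_network(self):
        t = tensor_from([("w", "A", "B", 30.0)], [("w", "A", 100.0), ("w", "B", 0.0)])
        om = trace_origins(t, "w")
        f = om.as_frame()
        assert f.loc["B", "A"] == pytest.approx(30.0, abs=1e-9)
        assert f.loc["A", "A"] == pytest.approx(70.0, abs=1e-9)
        assert f.loc["B", "B"] == pytest.approx(0.0, abs=1e-9)

    def test_single_reexport_chain_splits_proportionally(self):
        # A produces 100, sends 50 to B; B produces 50, sends 60 on to C
        t = tensor_from(
            [("w", "A", "B", 50.0), ("w", "B", "C", 60.0)],
            [("w", "A", 100.0), ("w", "B", 50.0), ("w", "C", 0.0)],
        )
        om = trace_origins(t, "w")
        f = om.as_frame()
        # B's supply of 100 is half A half B; C gets 60 of it, B keeps 40
        assert f.loc["C", "A"] == pytest.approx(30.0, abs=1e-8)
        assert f.loc["C", "B"] == pytest.approx(30.0, abs=1e-8)
        assert f.loc["B", "A"] == pytest.approx(20.0, abs=1e-8)
        assert f.loc["B", "B"] == pytest.approx(20.0, abs=1e-8)
        assert f.loc["A", "A"] == pytest.approx(50.0, abs=1e-8)

    def test_two_country_cycle_matches_geometric_series(self):
        t = tensor_from(
            [("w", "A", "B", 10.0), ("w", "B", "A", 10.0)],
            [("w", "A", 100.0), ("w", "B", 100.0)],
        )
        om = trace_origins(t, "w")
        f = om.as_frame()
        # supply of each country: 110; per round trip a tonne of A-origin
        # returns with weight r = (10/110)^2, so A's own-origin supply mass
        # is 100 / (1 - r); consumption keeps fraction 100/110 of supply
        r = (10.0 / 110.0) ** 2
        own_supply = 100.0 / (1.0 - r)
        cross_supply = own_supply * 10.0 / 110.0
        assert f.loc["A", "A"] == pytest.approx(own_supply * 100.0 / 110.0, abs=1e-9)
        assert f.loc["A", "B"] == pytest.approx(cross_supply * 100.0 / 110.0, abs=1e-9)
        assert f.loc["B", "B"] == pytest.approx(f.loc["A", "A"], abs=1e-9)

    def test_matches_path_enumeration_on_random_acyclic_networks(self):
        failures = []
        for seed in range(120):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(2, 6))
            T, P = random_acyclic_network(rng, n)
            names = [f"N{i}" for i in range(n)]
            flows = [
                ("w", names[i], names[j], T[i, j])
                for i in range(n)
                for j in range(n)
                if T[i, j] > 0
            ]
            production = [("w", names[i], P[i]) for i in range(n)]
            om = trace_origins(tensor_from(flows, production), "w")
            got = om.as_frame().loc[names, names].values
            expected = path_enumeration_attribution(T, P)
            err = np.abs(got - expected).max()
            if err > 1e-9:
                failures.append((seed, err))
        assert not failures

    def test_matches_direct_linear_solve(self):
        rng = np.random.default_rng(7)
        T, P = random_acyclic_network(rng, 5)
        # add a feedback edge to make it cyclic but still sub-stochastic
        T[4, 0] = 5.0
        names = [f"N{i}" for i in range(5)]
        flows = [
            ("w", names[i], names[j], T[i, j])
            for i in range(5)
            for j in range(5)
            if T[i, j] > 0
        ]
        production = [("w", names[i], P[i]) for i in range(5)]
        om = trace_origins(tensor_from(flows, production), "w")
        expected = linear_solve_attribution(T, P)
        assert np.abs(om.as_frame().loc[names, names].values - expected).max() < 1e-7

    def test_conservation_and_row_sums(self):
        rng = np.random.default_rng(99)
        T, P = random_acyclic_network(rng, 5)
        names = [f"N{i}" for i in range(5)]
        flows = [
            ("w", names[i], names[j], T[i, j])
            for i in range(5)
            for j in range(5)
            if T[i, j] > 0
        ]
        production = [("w", names[i], P[i]) for i in range(5)]
        om = trace_origins(tensor_from(flows, production), "w")
        assert om.attributed.sum() == pytest.approx(P.sum(), rel=1e-6)
        supply = P + T.sum(axis=0)
        apparent = supply - T.sum(axis=1)
        assert np.allclose(om.attributed.sum(axis=1), apparent, rtol=1e-6)
        # no origin over-attribution
        assert np.all(om.attributed.sum(axis=0) <= om.production * (1 + 1e-9))

    def test_idempotent_on_origin_pure_network(self):
        t = tensor_from(
            [("w", "A", "B", 30.0), ("w", "A", "C", 20.0)],
            [("w", "A", 100.0), ("w", "B", 10.0), ("w", "C", 0.0)],
        )
        om = trace_origins(t, "w")
        f = om.as_frame()
        assert f.loc["B", "A"] == pytest.approx(30.0, abs=1e-9)
        assert f.loc["B", "B"] == pytest.approx(10.0, abs=1e-9)
        assert f.loc["C", "A"] == pytest.approx(20.0, abs=1e-9)
        assert f.loc["A", "A"] == pytest.approx(50.0, abs=1e-9)

    def test_excess_exports_clipped_with_warning(self):
        # B exports more than it could possibly supply
        t = tensor_from(
            [("w", "A", "B", 10.0), ("w", "B", "C", 50.0)],
            [("w", "A", 100.0), ("w", "B", 20.0), ("w", "C", 0.0)],
        )
        with pytest.warns(UserWarning, match="exceed supply"):
            om = trace_origins(t, "w")
        assert om.warnings
        # after clipping, B exports exactly its supply of 30
        f = om.as_frame()
        assert f.loc["C"].sum() == pytest.approx(30.0, abs=1e-8)
        assert om.attributed.sum() == pytest.approx(120.0, rel=1e-6)


class TestSupplierTable:
    def _om(self):
        t = tensor_from(
            [("w", "A", "UK", 36.0), ("w", "B", "UK", 35.0), ("w", "C", "UK", 10.0),
             ("w", "D", "UK", 7.0), ("w", "E", "UK", 12.0)],
            [("w", "A", 400.0), ("w", "B", 100.0), ("w", "C", 200.0),
             ("w", "D", 140.0), ("w", "E", 300.0), ("w", "UK", 0.0)],
        )
        return trace_origins(t, "w")

    def test_shares_and_five_percent_filter(self):
        table = supplier_table(self._om(), "UK")
        majors = major_suppliers(table, 0.05)
        assert majors["country"].tolist() == ["A", "B", "E", "C", "D"]
        shares = dict(zip(table["country"], table["consumption_share"]))
        assert shares["A"] == pytest.approx(0.36)
        assert shares["D"] == pytest.approx(0.07)
        filtered = major_suppliers(table, 0.10)
        assert filtered["country"].tolist() == ["A", "B", "E", "C"]

    def test_production_share(self):
        table = supplier_table(self._om(), "UK")
        row = table[table["country"] == "B"].iloc[0]
        assert row["production_share"] == pytest.approx(0.35)

    def test_domestic_production_appears_as_origin(self):
        t = tensor_from(
            [("w", "A", "UK", 10.0)], [("w", "A", 50.0), ("w", "UK", 90.0)]
        )
        table = supplier_table(trace_origins(t, "w"), "UK")
        assert "UK" in table["country"].tolist()
        uk = table[table["country"] == "UK"].iloc[0]
        assert uk["consumption_share"] == pytest.approx(0.9)

    def test_single_origin_world(self):
        t = tensor_from([], [("w", "A", 100.0)])
        table = supplier_table(trace_origins(t, "w"), "A")
        assert len(table) == 1
        assert table["consumption_share"].iloc[0] == pytest.approx(1.0)

    def test_unknown_consumer_is_key_error(self):
        with pytest.raises(KeyError):
            supplier_table(self._om(), "Atlantis")

    def test_threshold_boundary_is_inclusive(self):
        table = pd.DataFrame(
            {
                "country": ["A", "B"],
                "attributed_tonnes": [4.99, 5.0],
                "consumption_share": [0.0499, 0.05],
                "production_share": [0.1, 0.1],
            }
        )
        out = major_suppliers(table, 0.05)
        assert out["country"].tolist() == ["B"]

    def test_all_below_threshold_yields_empty_table(self):
        table = supplier_table(self._om(), "UK")
        assert major_suppliers(table, 0.99).empty

    def test_consumption_shares_sum_to_one(self):
        table = supplier_table(self._om(), "UK")
        assert table["consumption_share"].sum() == pytest.approx(1.0, abs=1e-9)


class TestFaostatReader:
    def test_reads_flows_and_production(self, tmp_path):
        csv = tmp_path / "tm.csv"
        csv.write_text(
            "Reporter,Partner,Item,Element,Year,Unit,Value\n"
            "France,United Kingdom,wheat,Export Quantity,2003,tonnes,1000\n"
            "France,,wheat,Production,2003,tonnes,50000\n"
        )
        t = read_faostat_csv(csv)
        assert t.flows.iloc[0]["exporter"] == "France"
        assert t.flows.iloc[0]["importer"] == "United Kingdom"
        assert t.flows.iloc[0]["tonnes"] == 1000.0
        assert t.production.iloc[0]["tonnes"] == 50000.0

    def test_rejects_missing_columns(self, tmp_path):
        csv = tmp_path / "bad.csv"
        csv.write_text("Reporter,Partner\nA,B\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_faostat_csv(csv)

    def test_rejects_non_tonne_units(self, tmp_path):
        csv = tmp_path / "units.csv"
        csv.write_text(
            "Reporter,Partner,Item,Element,Year,Unit,Value\n"
            "A,B,wheat,Export Quantity,2003,1000 US$,5\n"
        )
        with pytest.raises(ValueError, match="tonnes"):
            read_faostat_csv(csv)
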