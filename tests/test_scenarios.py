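"""Policy construction, integrated solve, exchanges and the comparative report."""

import numpy as np
import pytest

from basinopt import (
    Basin,
    CropActivity,
    District,
    Network,
    PolicyScenario,
    RiverReach,
    ValidationError,
    apply_drought,
    build_policy_constraints,
    check_min_flows,
    compute_exchanges,
    exchanged_volumes,
    percent_change,
    solve,
    welfare_report,
)
from basinopt.agriculture import HA_TO_MEUR


class TestApplyDrought:
    def test_forty_percent_reduction(self):
        inflows = {"a": 10000.0, "b": 4600.0}
        reduced = apply_drought(inflows, 0.4)
        assert sum(reduced.values()) == pytest.approx(8760.0)

    def test_zero_reduction_identity(self):
        inflows = {"a": 1.0, "b": 2.0}
        assert apply_drought(inflows, 0.0) == inflows

    def test_moderate_drought(self):
        assert sum(apply_drought({"a": 14600.0}, 0.3).values()) == pytest.approx(10220.0)

    def test_reduction_range_validated(self):
        with pytest.raises(ValidationError):
            apply_drought({"a": 1.0}, 1.0)


class TestPolicyConstraints:
    def test_proportional_rationing_caps(self, toy_calibrated):
        pc = build_policy_constraints(PolicyScenario("ic", 0.4), toy_calibrated)
        base = toy_calibrated.baseline_allocations()
        assert pc.pooled_cap is None and not pc.include_env
        for did, cap in pc.per_district_caps.items():
            assert cap == pytest.approx(0.6 * base[did])

    def test_market_pooling_removes_individual_caps(self, toy_calibrated):
        pc = build_policy_constraints(PolicyScenario("wm", 0.4), toy_calibrated)
        assert pc.per_district_caps is None
        assert pc.pooled_cap == pytest.approx(
            0.6 * sum(toy_calibrated.baseline_allocations().values())
        )

    def test_environmental_objective_composition(self, toy_calibrated):
        for policy, include in (("ic", False), ("eic", True), ("wm", False), ("ewm", True)):
            pc = build_policy_constraints(PolicyScenario(policy, 0.4), toy_calibrated)
            assert pc.include_env is include

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValidationError, match="unknown policy"):
            PolicyScenario("central_planning", 0.1)


class TestSolveBaseline:
    def test_calibration_fixed_point(self, toy_calibrated, toy_solutions):
        """Reduction 0 under proportional rationing reproduces the PMP baseline."""
        base = toy_solutions["baseline"]
        for did, d in toy_calibrated.districts.items():
            assert base.water_use[did] == pytest.approx(d.observed_water_use(), rel=1e-5)
            for a in d.activities:
                assert base.acreage[did][a.key] == pytest.approx(
                    a.observed_acreage, rel=1e-4, abs=1e-5
                )

    def test_feasibility_always_checked(self, toy_calibrated, toy_solutions):
        for label, s in toy_solutions.items():
            net = toy_calibrated.network.scaled_inflows(1.0 - s.scenario.drought_reduction)
            assert check_min_flows(s.flows, net, drought=s.scenario.drought) == []
            assert all(v >= 0 for v in s.flows.wout.values())

    def test_urban_priority_constant_across_policies(self, toy_solutions):
        """Urban withdrawals and surplus are identical in every scenario."""
        ref = toy_solutions["baseline"]
        for s in toy_solutions.values():
            assert s.urban_use == ref.urban_use
            assert s.ledger.urban == pytest.approx(ref.ledger.urban, rel=1e-12)

    def test_determinism(self, toy_calibrated):
        s1 = solve(PolicyScenario("wm", 0.4), toy_calibrated)
        s2 = solve(PolicyScenario("wm", 0.4), toy_calibrated)
        assert s1.objective == s2.objective
        assert s1.acreage == s2.acreage


class TestPolicyOrderings:
    def test_environmental_variants_dominate_social(self, toy_solutions):
        assert (
            toy_solutions["eic"].ledger.social
            >= toy_solutions["ic"].ledger.social - 1e-6
        )
        assert (
            toy_solutions["ewm"].ledger.social
            >= toy_solutions["wm"].ledger.social - 1e-6
        )

    def test_market_dominates_rationing_privately(self, toy_solutions):
        assert (
            toy_solutions["wm"].ledger.private
            >= toy_solutions["ic"].ledger.private - 1e-6
        )

    def test_social_benefits_decline_with_drought(self, toy_calibrated):
        socials = [
            solve(PolicyScenario("ic", red), toy_calibrated).ledger.social
            for red in (0.0, 0.2, 0.4)
        ]
        assert socials[0] >= socials[1] - 1e-6 >= socials[2] - 2e-6


class TestGridSearchOracle:
    @pytest.mark.parametrize("policy", ["ic", "eic", "wm", "ewm"])
    @pytest.mark.parametrize("reduction", [0.0, 0.4])
    def test_solver_matches_exhaustive_search(self, tiny_calibrated, policy, reduction):
        from conftest import tiny_grid_best

        scenario = PolicyScenario(policy, reduction)
        sol = solve(scenario, tiny_calibrated)
        best = tiny_grid_best(tiny_calibrated, scenario)
        assert sol.objective == pytest.approx(best, rel=1e-3, abs=1e-3)


class TestExchanges:
    def test_rationing_has_no_exchanges(self, toy_solutions):
        assert toy_solutions["ic"].exchanges == []
        assert compute_exchanges(toy_solutions["ic"]).empty

    def test_sales_balance_purchases(self, toy_solutions):
        for label in ("eic", "wm", "ewm"):
            s = toy_solutions[label]
            sold = {
                d: s.allocations[d] - s.water_use[d]
                for d in s.allocations
                if s.allocations[d] - s.water_use[d] > 1e-6
            }
            table = compute_exchanges(s)
            if table.empty:
                continue
            per_seller = table.groupby("seller")["volume"].sum()
            for d, v in sold.items():
                assert per_seller.get(d, 0.0) == pytest.approx(v, rel=1e-5)

    def test_transfers_do_not_change_social_welfare(self, toy_solutions):
        for s in toy_solutions.values():
            assert s.ledger.social == pytest.approx(
                s.ledger.irrigation + s.ledger.urban + s.ledger.environmental
            )
            assert s.ledger.public_expenditure == pytest.approx(
                s.ledger.irrigation_env_income
            )

    def test_environmental_purchase_pricing(self, toy_solutions):
        """Purchases are priced at the sellers' marginal profit of water."""
        s = toy_solutions["eic"]
        env_ex = [e for e in s.exchanges if e.buyer == "environment"]
        assert env_ex, "expected environmental purchases under eic drought"
        for e in env_ex:
            assert e.price >= 0.0
            assert e.payment == pytest.approx(e.volume * e.price)


class TestWelfareReport:
    def test_ledger_identities(self, toy_solutions):
        rep = welfare_report(toy_solutions)
        for col in rep.columns:
            assert rep.loc["water_use_total", col] == pytest.approx(
                rep.loc["water_use_irrigation", col] + rep.loc["water_use_urban", col]
            )
            assert rep.loc["social_benefits", col] == pytest.approx(
                rep.loc["private_benefits", col]
                + rep.loc["environmental_benefits", col]
            )
            assert rep.loc["area_total", col] == pytest.approx(
                rep.loc["area_field", col]
                + rep.loc["area_fruit", col]
                + rep.loc["area_vegetable", col]
            )

    def test_column_order(self, toy_solutions):
        rep = welfare_report(toy_solutions)
        assert list(rep.columns) == ["baseline", "ic", "eic", "wm", "ewm"]

    def test_non_environmental_policies_buy_nothing(self, toy_solutions):
        rep = welfare_report(toy_solutions)
        for col in ("baseline", "ic", "wm"):
            assert rep.loc["exchanges_to_environment", col] == 0.0
            assert rep.loc["public_expenditure", col] == 0.0


class TestDegenerateBasin:
    def test_zero_inflow_yields_all_zero_solution(self):
        reaches = {
            "a": RiverReach(id="a", downstream_id="b", length_km=10.0, local_inflow=0.0, beta=-1.0),
            "b": RiverReach(id="b", downstream_id=None, length_km=10.0, local_inflow=0.0, beta=-1.0),
        }
        d = District(
            id="d",
            activities=[
                CropActivity(
                    crop_id="c", tech="flood", district_id="d", price=100.0, cost=50.0,
                    water_req=1.0, labor_req=1.0, observed_acreage=5.0, avg_yield=5.0,
                )
            ],
            land_by_tech={"flood": 10.0, "sprinkler": 0.0, "drip": 0.0},
            water_endowment=10.0,
            labor_endowment=10.0,
            withdraw_reach="a",
            return_reach="b",
        )
        basin = Basin(network=Network(reaches=reaches), districts={"d": d}, cities={})
        sol = solve(PolicyScenario("ic", 0.0), basin.calibrate())
        assert sol.water_use["d"] == pytest.approx(0.0, abs=1e-6)
        assert sol.ledger.social == pytest.approx(0.0, abs=1e-6)


class TestPercentChange:
    def test_signed_change(self):
        assert percent_change(761, 956) == pytest.approx(-20.397, abs=1e-3)

    def test_zero_base_rejected(self):
        with pytest.raises(ValidationError):
            percent_change(1.0, 0.0)
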