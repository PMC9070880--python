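"""Mass balance, flow continuity, minimum flows and closure calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from basinopt import (
    CycleError,
    InfeasibleFlowError,
    Network,
    RiverReach,
    ValidationError,
    calibrate_closure,
    check_min_flows,
    mass_balance_outflow,
    propagate_flows,
)


def reach(rid, down, inflow=0.0, loss=0.0, r_ir=0.2, closure=0.0, minflow=0.0, **kw):
    return RiverReach(
        id=rid,
        downstream_id=down,
        length_km=kw.pop("length_km", 10.0),
        local_inflow=inflow,
        loss=loss,
        return_coef_irrigation=r_ir,
        closure_term=closure,
        min_env_flow=minflow,
        beta=kw.pop("beta", -1.0),
        **kw,
    )


def chain(*reaches):
    return Network(reaches={r.id: r for r in reaches})


class TestMassBalance:
    @pytest.mark.parametrize(
        "inflow, loss, div_ir, div_urb, closure, expected",
        [
            (100.0, 5.0, 60.0, 10.0, 0.0, 25.0),
            (50.0, 0.0, 0.0, 0.0, 0.0, 50.0),
            (100.0, 5.0, 60.0, 10.0, 3.0, 28.0),
        ],
    )
    def test_outflow_arithmetic(self, inflow, loss, div_ir, div_urb, closure, expected):
        r = reach("r", None, loss=loss, closure=closure)
        out = mass_balance_outflow(r, inflow, div_ir, div_urb)
        assert out == pytest.approx(expected)

    def test_deficit_raises_identifying_reach(self):
        r = reach("r7", None, loss=5.0)
        with pytest.raises(InfeasibleFlowError) as exc:
            mass_balance_outflow(r, 20.0, div_ir=30.0)
        assert exc.value.reach_id == "r7"
        assert exc.value.deficit == pytest.approx(15.0)

    @settings(max_examples=100, derandomize=True)
    @given(
        inflow=st.floats(0, 1e5),
        loss=st.floats(0, 100),
        div=st.floats(0, 1e4),
    )
    def test_outflow_nonnegative_when_feasible(self, inflow, loss, div):
        r = reach("r", None, loss=loss)
        if inflow >= loss + div:
            assert mass_balance_outflow(r, inflow, div) >= 0.0


class TestPropagation:
    def test_two_reach_chain_with_returns(self):
        net = chain(
            reach("r1", "r2", inflow=100.0, r_ir=0.25),
            reach("r2", None, inflow=10.0),
        )
        state = propagate_flows(net, div_ir={"r1": 40.0})
        assert state.wout["r1"] == pytest.approx(60.0)
        # Win_2 = Wout_1 + r^IR * Div_1 + RO_2 = 60 + 10 + 10
        assert state.win["r2"] == pytest.approx(80.0)

    def test_no_diversions_conserves_inflows_minus_losses(self):
        net = chain(
            reach("a", "c", inflow=120.0, loss=10.0),
            reach("b", "c", inflow=80.0, loss=0.0),
            reach("c", None, inflow=30.0, loss=5.0),
        )
        state = propagate_flows(net)
        assert state.wout["c"] == pytest.approx(120 + 80 + 30 - 15)

    def test_zero_return_coefficients_degenerate(self):
        net = chain(
            reach("r1", "r2", inflow=100.0, r_ir=0.0),
            reach("r2", None, inflow=10.0),
        )
        state = propagate_flows(net, div_ir={"r1": 40.0})
        assert state.win["r2"] == pytest.approx(state.wout["r1"] + 10.0)

    def test_conservation_identity(self):
        """Mouth outflow equals inflows - losses - consumptive use to 1e-9 rel."""
        net = chain(
            reach("a", "b", inflow=500.0, loss=12.0, r_ir=0.3),
            reach("b", "c", inflow=200.0, loss=8.0, r_ir=0.1),
            reach("c", None, inflow=100.0, loss=4.0),
        )
        div = {"a": 120.0, "b": 55.0}
        state = propagate_flows(net, div_ir=div)
        consumptive = 120.0 * 0.7 + 55.0 * 0.9
        expected = 800.0 - 24.0 - consumptive
        assert state.wout["c"] == pytest.approx(expected, rel=1e-9)

    def test_idempotence_on_own_diversions(self):
        net = chain(
            reach("a", "b", inflow=500.0, loss=12.0),
            reach("b", None, inflow=100.0),
        )
        s1 = propagate_flows(net, div_ir={"a": 100.0})
        s2 = propagate_flows(net, div_ir=s1.div_ir, div_urb=s1.div_urb)
        assert s1.win == s2.win and s1.wout == s2.wout

    def test_unattached_diversion_rejected(self):
        net = chain(reach("a", None, inflow=10.0))
        with pytest.raises(ValidationError, match="unknown reach"):
            propagate_flows(net, div_ir={"zz": 1.0})

    def test_cycle_detection(self):
        with pytest.raises(ValidationError):
            # two mouths is also invalid, so build an actual cycle
            Network(
                reaches={
                    "a": reach("a", "b", inflow=1.0),
                    "b": reach("b", "a", inflow=1.0),
                }
            )


class TestMinFlows:
    def test_mouth_above_minimum_is_clean(self):
        net = chain(reach("m", None, inflow=8895.0, minflow=3000.0))
        state = propagate_flows(net)
        assert check_min_flows(state, net) == []

    def test_boundary_violation_at_mouth(self):
        net = chain(reach("m", None, inflow=2999.0, minflow=3000.0))
        state = propagate_flows(net)
        violations = check_min_flows(state, net)
        assert len(violations) == 1
        assert violations[0].reach_id == "m"
        assert violations[0].deficit == pytest.approx(1.0)

    def test_multiple_control_points_reported_individually(self):
        net = chain(
            reach("mendavia", "zaragoza", inflow=250.0, minflow=300.0),
            reach("zaragoza", "tortosa", inflow=100.0, minflow=640.0),
            reach("tortosa", None, inflow=100.0, minflow=3000.0),
        )
        state = propagate_flows(net)
        violations = check_min_flows(state, net)
        assert [v.reach_id for v in violations] == ["mendavia", "zaragoza", "tortosa"]

    def test_drought_minimum_selected(self):
        r = reach("z", None, inflow=700.0, minflow=945.0)
        r.min_env_flow_drought = 640.0
        net = chain(r)
        state = propagate_flows(net)
        assert check_min_flows(state, net, drought=True) == []
        assert len(check_min_flows(state, net, drought=False)) == 1


class TestClosureCalibration:
    def net(self):
        return chain(
            reach("a", "b", inflow=500.0, loss=10.0, r_ir=0.2),
            reach("b", "c", inflow=200.0, loss=5.0),
            reach("c", None, inflow=50.0),
        )

    def test_already_calibrated_gives_zero_closures(self):
        net = self.net()
        state = propagate_flows(net, div_ir={"a": 100.0})
        cal, report = calibrate_closure(net, dict(state.wout), div_ir={"a": 100.0})
        assert all(abs(c) < 1e-9 for c in report.closures.values())

    def test_single_gauge_offset_absorbed_at_that_reach(self):
        net = self.net()
        state = propagate_flows(net, div_ir={"a": 100.0})
        observed = {"b": state.wout["b"] + 10.0}
        cal, report = calibrate_closure(net, observed, div_ir={"a": 100.0})
        assert report.closures["b"] == pytest.approx(10.0)
        assert report.consistent

    def test_two_gauges_on_chain_reproduced_exactly(self):
        net = self.net()
        state = propagate_flows(net, div_ir={"a": 100.0})
        observed = {"a": state.wout["a"] + 7.0, "c": state.wout["c"] - 3.0}
        cal, report = calibrate_closure(net, observed, div_ir={"a": 100.0})
        # least-squares split: +7 upstream, -10 at the mouth gauge
        assert report.closures["a"] == pytest.approx(7.0)
        assert report.closures["c"] == pytest.approx(-10.0)
        recheck = propagate_flows(cal, div_ir={"a": 100.0})
        for g, v in observed.items():
            assert recheck.wout[g] == pytest.approx(v, abs=1e-9)

    def test_unknown_gauge_rejected(self):
        with pytest.raises(ValidationError, match="unknown reach"):
            calibrate_closure(self.net(), {"nope": 1.0})


class TestReachValidation:
    def test_nonnegative_beta_rejected(self):
        with pytest.raises(ValidationError, match="beta"):
            RiverReach(id="x", downstream_id=None, length_km=1.0, local_inflow=0.0, beta=0.5)

    def test_return_coefficient_range(self):
        with pytest.raises(ValidationError):
            reach("x", None, r_ir=1.5)

    def test_single_mouth_required(self):
        with pytest.raises(ValidationError, match="mouth"):
            Network(
                reaches={
                    "a": reach("a", None, inflow=1.0),
                    "b": reach("b", None, inflow=1.0),
                }
            )
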