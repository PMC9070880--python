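"""Shared fixtures: the frozen toy basin, a tiny two-reach basin, solved scenarios."""

import numpy as np
import pytest

from basinopt import (
    Basin,
    City,
    CropActivity,
    District,
    Network,
    PolicyScenario,
    RiverReach,
    solve,
    toy_ebro,
)


@pytest.fixture(scope="session")
def toy_basin():
    return toy_ebro()


@pytest.fixture(scope="session")
def toy_calibrated(toy_basin):
    return toy_basin.calibrate()


@pytest.fixture(scope="session")
def toy_solutions(toy_calibrated):
    """Baseline plus the four policies under a 40% drought, solved once."""
    sols = {"baseline": solve(PolicyScenario("ic", 0.0), toy_calibrated)}
    for pol in ("ic", "eic", "wm", "ewm"):
        sols[pol] = solve(PolicyScenario(pol, 0.4), toy_calibrated)
    return sols


def make_tiny_basin() -> Basin:
    """Two reaches, two one-crop districts, one city: small enough for grid search."""
    reaches = {
        "A": RiverReach(
            id="A",
            downstream_id="B",
            length_km=100.0,
            local_inflow=100.0,
            loss=2.0,
            return_coef_irrigation=0.25,
            return_coef_urban=0.5,
            beta=-1.0,
            wua_flow_scale=0.02,
            valuation_tier="medium",
        ),
        "B": RiverReach(
            id="B",
            downstream_id=None,
            length_km=150.0,
            local_inflow=20.0,
            loss=1.0,
            return_coef_irrigation=0.25,
            return_coef_urban=0.5,
            min_env_flow=10.0,
            beta=-0.5,
            wua_flow_scale=0.03,
            valuation_tier="high",
        ),
    }
    d1 = District(
        id="d1",
        activities=[
            CropActivity(
                crop_id="corn",
                tech="flood",
                district_id="d1",
                price=200.0,
                cost=800.0,
                water_req=1.5,
                labor_req=5.0,
                observed_acreage=20.0,
                avg_yield=10.0,
                group="field",
            )
        ],
        land_by_tech={"flood": 24.0, "sprinkler": 0.0, "drip": 0.0},
        water_endowment=33.0,
        labor_endowment=110.0,
        withdraw_reach="A",
        return_reach="B",
    )
    d2 = District(
        id="d2",
        activities=[
            CropActivity(
                crop_id="fruit",
                tech="drip",
                district_id="d2",
                price=400.0,
                cost=6000.0,
                water_req=1.0,
                labor_req=25.0,
                observed_acreage=15.0,
                avg_yield=20.0,
                group="fruit",
            )
        ],
        land_by_tech={"flood": 0.0, "sprinkler": 0.0, "drip": 18.0},
        water_endowment=16.5,
        labor_endowment=420.0,
        withdraw_reach="B",
        return_reach="B",
    )
    city = City(
        id="u1",
        demand_intercept=3.0,
        demand_slope=0.3,
        supply_intercept=0.6,
        supply_slope=0.1,
        withdraw_reach="A",
        return_reach="B",
    )
    return Basin(
        network=Network(reaches=reaches),
        districts={"d1": d1, "d2": d2},
        cities={"u1": city},
        name="tiny",
    )


def tiny_grid_best(basin: Basin, scenario) -> float:
    """Exhaustive-search welfare optimum of the tiny basin at 0.01 resolution.

    Independent oracle: re-derives the flow balances of the two-reach network
    by hand and scans both districts' acreages on a grid.
    """
    d1 = basin.districts["d1"].activities[0]
    d2 = basin.districts["d2"].activities[0]
    lin1 = (d1.price * d1.yield_intercept - d1.cost) * 1e-3
    q1 = d1.price * d1.yield_slope * 1e-3
    lin2 = (d2.price * d2.yield_intercept - d2.cost) * 1e-3
    q2 = d2.price * d2.yield_slope * 1e-3

    factor = 1.0 - scenario.drought_reduction
    qcity = (3.0 - 0.6) / 0.4  # interior urban optimum of the tiny city
    x1 = np.arange(0.0, 24.0005, 0.01)
    x2 = np.arange(0.0, 18.0005, 0.01)
    g1, g2 = np.meshgrid(x1, x2, indexing="ij")
    u1, u2 = 1.5 * g1, 1.0 * g2

    win_a = 100.0 * factor
    wout_a = win_a - 2.0 - u1 - qcity
    # d2 withdraws at B and returns to B, so its return feeds its own reach
    win_b = wout_a + 0.25 * u1 + 0.5 * qcity + 20.0 * factor + 0.25 * u2
    wout_b = win_b - 1.0 - u2

    feas = (wout_a >= -1e-9) & (wout_b >= 10.0 - 1e-9)
    feas &= (u1 + qcity <= win_a + 1e-9) & (u2 <= win_b + 1e-9)
    feas &= g1 <= 24.0 + 1e-9
    feas &= g2 <= 18.0 + 1e-9
    feas &= (u1 <= 33.0) & (u2 <= 16.5)
    caps1, caps2 = 30.0 * factor, 15.0 * factor
    if scenario.pooled:
        feas &= u1 + u2 <= caps1 + caps2 + 1e-9
    else:
        feas &= (u1 <= caps1 + 1e-9) & (u2 <= caps2 + 1e-9)

    obj = lin1 * g1 + q1 * g1**2 + lin2 * g2 + q2 * g2**2
    if scenario.include_env:
        env = 0.18 * 100.0 * (1 - np.exp(-0.02 * np.clip(wout_a, 0, None)))
        env += 0.45 * 150.0 * (1 - np.exp(-0.015 * np.clip(wout_b, 0, None)))
        obj = obj + env
    obj = np.where(feas, obj, -np.inf)
    return float(obj.max())


@pytest.fixture()
def tiny_basin():
    return make_tiny_basin()


@pytest.fixture()
def tiny_calibrated(tiny_basin):
    return tiny_basin.calibrate()
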