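"""Integrated welfare optimization under four drought allocation policies.

The basin authority's problem is

    max  sum_k B_k^IR + sum_u B_u^URB + sum_s B_s^eco

subject to reach mass balance and continuity, minimum environmental flows,
district land/water/labor endowments, urban priority, and the institutional
constraints of the active policy:

* institutional_cooperation (ic): each district's withdrawal is capped at its
  baseline allocation scaled by (1 - drought reduction); only private benefits
  enter the objective (the authority rations, agents optimize privately).
* environmental_institutional_cooperation (eic): same per-district caps, but
  environmental benefits enter the objective; the authority buys unused
  allocation from districts for the river.
* water_markets (wm): the per-district caps are pooled into a single basin cap
  (entitlements trade freely among districts); private benefits only.
* environmental_water_markets (ewm): pooled cap and environmental benefits in
  the objective; the authority buys water on the market for the river.

Urban withdrawals are a fixed priority pre-allocation in every policy. With
quadratic irrigation profit, quadratic urban surplus and saturating-exponential
environmental benefits over affine flows, the objective is concave and every
constraint linear, so the solver (SLSQP with analytic gradients) finds the
global optimum. Exchange volumes are priced at the marginal value of water
(the relevant constraint dual, obtained by a finite-difference re-solve);
payments are pure transfers and do not enter social welfare.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize

from .agriculture import CROP_GROUPS, district_optimize
from .basin import Basin
from .environment import env_benefit
from .errors import SolverError, ValidationError
from .network import FlowState, LinearFlowSystem, check_min_flows
from .urban import urban_optimize, urban_surplus

POLICIES = (
    "institutional_cooperation",
    "environmental_institutional_cooperation",
    "water_markets",
    "environmental_water_markets",
)

POLICY_ALIASES = {
    "ic": "institutional_cooperation",
    "eic": "environmental_institutional_cooperation",
    "wm": "water_markets",
    "ewm": "environmental_water_markets",
}

#: canonical column order of comparative reports
REPORT_ORDER = ("baseline", "ic", "eic", "wm", "ewm")

_ENV_POLICIES = {
    "environmental_institutional_cooperation",
    "environmental_water_markets",
}
_MARKET_POLICIES = {"water_markets", "environmental_water_markets"}


def canonical_policy(policy: str) -> str:
    policy = POLICY_ALIASES.get(policy, policy)
    if policy not in POLICIES:
        raise ValidationError(f"unknown policy {policy!r}")
    return policy


@dataclass(frozen=True)
class PolicyScenario:
    """One allocation regime combined with a drought inflow reduction."""

    policy: str
    drought_reduction: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "policy", canonical_policy(self.policy))
        if not 0.0 <= self.drought_reduction < 1.0:
            raise ValidationError("drought_reduction must lie in [0, 1)")

    @property
    def include_env(self) -> bool:
        return self.policy in _ENV_POLICIES

    @property
    def pooled(self) -> bool:
        return self.policy in _MARKET_POLICIES

    @property
    def drought(self) -> bool:
        return self.drought_reduction > 0


def apply_drought(inflows: Mapping[str, float], reduction: float) -> dict[str, float]:
    """Scale every local inflow by (1 - reduction)."""
    if not 0.0 <= reduction < 1.0:
        raise ValidationError("reduction must lie in [0, 1)")
    return {rid: v * (1.0 - reduction) for rid, v in inflows.items()}


@dataclass
class PolicyConstraints:
    """Institutional constraint set and objective composition of a policy."""

    per_district_caps: dict[str, float] | None  # Mm^3, ic/eic
    pooled_cap: float | None  # Mm^3, wm/ewm
    include_env: bool
    allocations: dict[str, float]  # reduced allocation per district


def build_policy_constraints(scenario: PolicyScenario, basin: Basin) -> PolicyConstraints:
    """Reduced allocations and their institutional arrangement for the policy."""
    factor = 1.0 - scenario.drought_reduction
    allocations = {
        did: alloc * factor for did, alloc in basin.baseline_allocations().items()
    }
    if scenario.pooled:
        return PolicyConstraints(
            per_district_caps=None,
            pooled_cap=sum(allocations.values()),
            include_env=scenario.include_env,
            allocations=allocations,
        )
    return PolicyConstraints(
        per_district_caps=dict(allocations),
        pooled_cap=None,
        include_env=scenario.include_env,
        allocations=allocations,
    )


@dataclass
class Ledger:
    """Benefit accounting (M EUR). Payments among agents are transfers and are
    reported separately; social welfare is production + urban + environmental."""

    irrigation: float
    urban: float
    environmental: float
    irrigation_trade_income: float = 0.0
    irrigation_env_income: float = 0.0
    public_expenditure: float = 0.0

    @property
    def private(self) -> float:
        return self.irrigation + self.urban

    @property
    def social(self) -> float:
        return self.irrigation + self.urban + self.environmental


def ledger_from_components(irrigation: float, urban: float, environmental: float) -> Ledger:
    return Ledger(irrigation=irrigation, urban=urban, environmental=environmental)


def percent_change(new: float, base: float) -> float:
    """Relative change in percent, 100 * (new - base) / base."""
    if base == 0:
        raise ValidationError("base must be nonzero for a percent change")
    return 100.0 * (new - base) / base


@dataclass(frozen=True)
class Exchange:
    seller: str
    buyer: str  # district id or "environment"
    volume: float  # Mm^3
    price: float  # EUR/m^3 (= M EUR per Mm^3)

    @property
    def payment(self) -> float:
        return self.volume * self.price


@dataclass
class Solution:
    """Optimized allocation, flows and the benefit ledger of one scenario."""

    scenario: PolicyScenario
    acreage: dict[str, dict[tuple[str, str], float]]
    water_use: dict[str, float]
    urban_use: dict[str, float]
    allocations: dict[str, float]
    flows: FlowState
    ledger: Ledger
    mouth_id: str = ""
    exchanges: list[Exchange] = field(default_factory=list)
    market_price: float | None = None
    objective: float = 0.0
    status: str = "optimal"

    @property
    def mouth_flow(self) -> float:
        return self.flows.wout[self.mouth_id]

    def irrigated_area(self, group: str | None = None) -> float:
        total = 0.0
        for did, plan in self.acreage.items():
            for (crop, tech), x in plan.items():
                if group is None or self._groups[did][(crop, tech)] == group:
                    total += x
        return total


class _Problem:
    """Assembled NLP for one (scenario, basin) pair."""

    def __init__(self, scenario: PolicyScenario, basin: Basin):
        if not basin.calibrated:
            raise ValidationError("basin must be PMP-calibrated before solving")
        self.scenario = scenario
        self.basin = basin
        self.network = basin.network.scaled_inflows(1.0 - scenario.drought_reduction)
        self.districts = [basin.districts[d] for d in sorted(basin.districts)]
        self.cities = [basin.cities[c] for c in sorted(basin.cities)]
        self.constraints = build_policy_constraints(scenario, basin)

        # decision vector: acreages, concatenated per district
        self.slices: dict[str, slice] = {}
        start = 0
        for d in self.districts:
            self.slices[d.id] = slice(start, start + len(d.activities))
            start += len(d.activities)
        self.n = start

        # quadratic private profit terms
        self.lin = np.zeros(self.n)
        self.quad = np.zeros(self.n)
        from .agriculture import _profit_terms

        for d in self.districts:
            sl = self.slices[d.id]
            self.lin[sl], self.quad[sl] = _profit_terms(d)

        # water-use map: div_district = T x
        units = self.basin.attachments()
        self.unit_ids = [a.unit_id for a in units]
        self.t_mat = np.zeros((len(units), self.n))
        for i, a in enumerate(units):
            if a.unit_type == "district":
                d = basin.districts[a.unit_id]
                sl = self.slices[d.id]
                self.t_mat[i, sl] = [act.water_req for act in d.activities]

        # fixed urban pre-allocation (priority): surplus-optimal quantities
        self.urban_q = {c.id: urban_optimize(c)[0] for c in self.cities}
        self.flow_system = LinearFlowSystem(self.network, units)
        self._scale_urban_to_feasible()

        q_vec = np.zeros(len(units))
        for i, a in enumerate(units):
            if a.unit_type == "city":
                q_vec[i] = self.urban_q[a.unit_id]
        self.q_vec = q_vec

        wa, wb = self.flow_system.wout_matrix()
        ia, ib = self.flow_system.win_matrix()
        # fold fixed city diversions into constants; keep district dependence on x
        self.wout_const = wa + wb @ q_vec
        self.wout_mat = wb @ self.t_mat
        self.win_const = ia + ib @ q_vec
        self.win_mat = ib @ self.t_mat
        self.reach_order = self.flow_system.order

        # environmental benefit coefficients over outflows
        self.env_scale = np.array(
            [
                self.network.reaches[rid].beta
                * self.network.reaches[rid].wua_flow_scale
                * basin.dry_season_fraction
                for rid in self.reach_order
            ]
        )
        self.env_value = np.array(
            [
                basin.tier_values[self.network.reaches[rid].valuation_tier]
                * self.network.reaches[rid].length_km
                for rid in self.reach_order
            ]
        )
        self._assemble_constraints()

    # -- feasibility of the fixed urban block -----------------------------

    def _scale_urban_to_feasible(self):
        """Shrink urban withdrawals proportionally if inflows cannot carry them.

        Only triggers in degenerate basins (e.g. zero inflow); in ordinary
        instances the optimum urban quantity is feasible and kept exactly.
        """
        if not self.cities:
            return

        def feasible(s: float) -> bool:
            div = {c.id: self.urban_q[c.id] * s for c in self.cities}
            try:
                state = self.flow_system.evaluate(div)
            except Exception:
                return False
            for a in self.flow_system.units:
                if a.unit_type == "city":
                    if div[a.unit_id] > state.win[a.withdraw_reach] + 1e-9:
                        return False
            return True

        if feasible(1.0):
            return
        lo, hi = 0.0, 1.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if feasible(mid):
                lo = mid
            else:
                hi = mid
        for c in self.cities:
            self.urban_q[c.id] *= lo

    # -- constraint assembly ----------------------------------------------

    def _assemble_constraints(self):
        rows, rhs = [], []
        # district resources
        for d in self.districts:
            a_ub, b_ub, _ = d.constraint_matrix()
            for r, b in zip(a_ub, b_ub):
                row = np.zeros(self.n)
                row[self.slices[d.id]] = r
                rows.append(row)
                rhs.append(b)
        # policy caps on withdrawals
        water_rows = {}
        for i, a in enumerate(self.flow_system.units):
            if a.unit_type == "district":
                water_rows[a.unit_id] = self.t_mat[i]
        if self.constraints.per_district_caps is not None:
            for did, cap in self.constraints.per_district_caps.items():
                rows.append(water_rows[did])
                rhs.append(cap)
        self.pooled_row_index = None
        if self.constraints.pooled_cap is not None:
            rows.append(sum(water_rows.values()))
            rhs.append(self.constraints.pooled_cap)
            self.pooled_row_index = len(rows) - 1
        # reach-local availability (extraction <= net inflow at the reach)
        for j, rid in enumerate(self.reach_order):
            idx = self.flow_system.withdrawals_at(rid)
            if not idx:
                continue
            div_row = np.zeros(self.n)
            div_const = 0.0
            for i in idx:
                div_row += self.t_mat[i]
                div_const += self.q_vec[i]
            rows.append(div_row - self.win_mat[j])
            rhs.append(self.win_const[j] - div_const)
        # minimum environmental flows at control points, and nonnegative outflow
        drought = self.scenario.drought
        for j, rid in enumerate(self.reach_order):
            minflow = self.network.reaches[rid].min_flow(drought)
            rows.append(-self.wout_mat[j])
            rhs.append(self.wout_const[j] - minflow)
        self.a_ub = np.vstack(rows)
        self.b_ub = np.array(rhs)

    # -- objective ---------------------------------------------------------

    def private(self, x: np.ndarray) -> float:
        return float(self.lin @ x + self.quad @ (x * x))

    def env(self, x: np.ndarray) -> float:
        wout = np.clip(self.wout_const + self.wout_mat @ x, 0.0, None)
        return float(self.env_value @ (1.0 - np.exp(self.env_scale * wout)))

    def objective(self, x: np.ndarray) -> float:
        val = self.private(x)
        if self.constraints.include_env:
            val += self.env(x)
        return val

    def _neg_obj_grad(self, x: np.ndarray):
        g = self.lin + 2.0 * self.quad * x
        val = self.lin @ x + self.quad @ (x * x)
        if self.constraints.include_env:
            wout = self.wout_const + self.wout_mat @ x
            wpos = np.clip(wout, 0.0, None)
            e = np.exp(self.env_scale * wpos)
            val += self.env_value @ (1.0 - e)
            # d env / d x_j = sum_s v_s (-theta_s e^{theta_s w_s}) dw_s/dx_j,
            # zero where the outflow is clipped at 0
            active = (wout > 0).astype(float)
            g = g - (self.env_value * self.env_scale * e * active) @ self.wout_mat
        return -float(val), -g

    def solve_x(self, x0: np.ndarray | None = None) -> tuple[np.ndarray, str]:
        if self.n == 0:
            return np.zeros(0), "optimal"
        if x0 is None:
            factor = 1.0 - self.scenario.drought_reduction
            x0 = np.concatenate(
                [
                    np.array([a.observed_acreage for a in d.activities]) * factor
                    for d in self.districts
                ]
            )
        cons = [
            {
                "type": "ineq",
                "fun": lambda x: self.b_ub - self.a_ub @ x,
                "jac": lambda x: -self.a_ub,
            }
        ]
        res = optimize.minimize(
            lambda x: self._neg_obj_grad(x)[0],
            x0,
            jac=lambda x: self._neg_obj_grad(x)[1],
            method="SLSQP",
            bounds=[(0.0, None)] * self.n,
            constraints=cons,
            options={"maxiter": 1000, "ftol": 1e-10},
        )
        if not res.success:
            res = optimize.minimize(
                lambda x: self._neg_obj_grad(x)[0],
                np.zeros(self.n),
                jac=lambda x: self._neg_obj_grad(x)[1],
                method="SLSQP",
                bounds=[(0.0, None)] * self.n,
                constraints=cons,
                options={"maxiter": 2000, "ftol": 1e-10},
            )
        if not res.success:
            raise SolverError(
                f"policy solve failed ({self.scenario.policy}): {res.message}",
                {"status": res.status},
            )
        return np.clip(res.x, 0.0, None), "optimal"


def solve(scenario: PolicyScenario, basin: Basin) -> Solution:
    """Welfare-maximal solution of the scenario on a calibrated basin.

    Deterministic: fixed start at the drought-scaled baseline acreage.
    The returned solution always satisfies minimum flows and urban priority
    (checked explicitly); infeasibility raises :class:`SolverError`.
    """
    prob = _Problem(scenario, basin)
    x, status = prob.solve_x()
    return _build_solution(prob, x, status)


def _build_solution(prob: _Problem, x: np.ndarray, status: str) -> Solution:
    basin, scenario = prob.basin, prob.scenario
    acreage = {}
    water_use = {}
    irrigation = 0.0
    for d in prob.districts:
        sl = prob.slices[d.id]
        xd = x[sl]
        acreage[d.id] = {a.key: float(v) for a, v in zip(d.activities, xd)}
        water_use[d.id] = float(np.array([a.water_req for a in d.activities]) @ xd)
        irrigation += float(prob.lin[sl] @ xd + prob.quad[sl] @ (xd * xd))

    urban = sum(
        urban_surplus(c, prob.urban_q[c.id], prob.urban_q[c.id]) for c in prob.cities
    )

    diversions = {d.id: water_use[d.id] for d in prob.districts}
    diversions.update(prob.urban_q)
    flows = prob.flow_system.evaluate(diversions)

    environmental = sum(
        env_benefit(
            prob.network.reaches[rid],
            flows.wout[rid],
            basin.tier_values,
            basin.dry_season_fraction,
        )
        for rid in prob.reach_order
    )

    violations = check_min_flows(flows, prob.network, drought=scenario.drought)
    if violations:
        raise SolverError(
            "solution violates minimum flows",
            {"violations": [(v.reach_id, v.deficit) for v in violations]},
        )

    ledger = Ledger(irrigation=irrigation, urban=urban, environmental=environmental)
    sol = Solution(
        scenario=scenario,
        acreage=acreage,
        water_use=water_use,
        urban_use=dict(prob.urban_q),
        allocations=dict(prob.constraints.allocations),
        flows=flows,
        ledger=ledger,
        mouth_id=prob.network.mouth.id,
        objective=prob.objective(x),
        status=status,
    )
    sol._groups = {
        d.id: {a.key: a.group for a in d.activities} for d in prob.districts
    }
    sol.exchanges, sol.market_price = _price_exchanges(prob, sol, x)
    _apply_transfer_accounting(sol)
    return sol


def _pooled_price(prob: _Problem, x: np.ndarray) -> float:
    """Dual of the pooled water cap by a forward-difference re-solve."""
    cap = prob.constraints.pooled_cap
    if cap is None:
        return 0.0
    if not prob.constraints.include_env:
        # without environmental purchases the cap can be genuinely slack
        total_use = float(sum(prob.t_mat @ x))
        if total_use < cap - 1e-6:
            return 0.0
    delta = max(1.0, 1e-3 * cap)
    base_obj = prob.objective(x)
    prob2 = _Problem(prob.scenario, prob.basin)
    prob2.b_ub = prob2.b_ub.copy()
    prob2.b_ub[prob2.pooled_row_index] += delta
    x2, _ = prob2.solve_x(x0=x)
    return max((prob2.objective(x2) - base_obj) / delta, 0.0)


def _price_exchanges(
    prob: _Problem, sol: Solution, x: np.ndarray
) -> tuple[list[Exchange], float | None]:
    scenario = prob.scenario
    caps = prob.constraints.allocations
    use = sol.water_use
    exchanges: list[Exchange] = []

    if scenario.policy == "institutional_cooperation":
        return [], None

    if scenario.policy == "environmental_institutional_cooperation":
        # authority buys each district's unused allocation at its marginal
        # profit of water
        for did in sorted(caps):
            v = caps[did] - use[did]
            if v > 1e-6:
                dual = district_optimize(
                    prob.basin.districts[did], water_available=use[did]
                ).water_dual
                exchanges.append(Exchange(seller=did, buyer="environment", volume=v, price=dual))
        return exchanges, None

    # market policies: inter-district trades priced at the pooled cap's dual;
    # environmental purchases at the seller's marginal profit of water (when
    # the authority buys, the cap itself is slack and its dual is zero)
    price = _pooled_price(prob, x)
    sellers = {d: caps[d] - use[d] for d in caps if caps[d] - use[d] > 1e-6}
    buyers = {d: use[d] - caps[d] for d in caps if use[d] - caps[d] > 1e-6}
    env_purchase = prob.constraints.pooled_cap - sum(use.values())
    env_purchase = env_purchase if env_purchase > 1e-6 else 0.0

    total_sales = sum(sellers.values())
    if total_sales > 0:
        # pro-rata split of each seller's volume between buyers and the river
        seller_duals = {
            sid: district_optimize(
                prob.basin.districts[sid], water_available=use[sid]
            ).water_dual
            for sid in sellers
        }
        for sid in sorted(sellers):
            share = sellers[sid] / total_sales
            trade_price = price if price > 0 else seller_duals[sid]
            for bid in sorted(buyers):
                v = buyers[bid] * share
                if v > 1e-9:
                    exchanges.append(
                        Exchange(seller=sid, buyer=bid, volume=v, price=trade_price)
                    )
            if scenario.policy == "environmental_water_markets" and env_purchase > 0:
                v = env_purchase * share
                if v > 1e-9:
                    exchanges.append(
                        Exchange(
                            seller=sid,
                            buyer="environment",
                            volume=v,
                            price=seller_duals[sid],
                        )
                    )
    return exchanges, price if price > 0 else None


def _apply_transfer_accounting(sol: Solution) -> None:
    trade = sum(e.payment for e in sol.exchanges if e.buyer != "environment")
    env_pay = sum(e.payment for e in sol.exchanges if e.buyer == "environment")
    sol.ledger.irrigation_trade_income = trade
    sol.ledger.irrigation_env_income = env_pay
    sol.ledger.public_expenditure = env_pay


def compute_exchanges(solution: Solution) -> pd.DataFrame:
    """Exchange table of a solved scenario (empty under pure rationing)."""
    rows = [
        {
            "seller": e.seller,
            "buyer": e.buyer,
            "volume": e.volume,
            "price": e.price,
            "payment": e.payment,
        }
        for e in solution.exchanges
    ]
    return pd.DataFrame(rows, columns=["seller", "buyer", "volume", "price", "payment"])


def exchanged_volumes(solution: Solution) -> dict[str, float]:
    """Traded volumes: between irrigators, and from irrigators to the river."""
    irr = sum(e.volume for e in solution.exchanges if e.buyer != "environment")
    env = sum(e.volume for e in solution.exchanges if e.buyer == "environment")
    return {"between_irrigators": irr, "to_environment": env, "total": irr + env}


def welfare_report(solutions: Mapping[str, Solution]) -> pd.DataFrame:
    """Comparative policy table: water accounts, areas and the benefit ledger.

    Columns follow the canonical order baseline, ic, eic, wm, ewm for known
    labels; rows mirror the usual policy-comparison layout.
    """
    if not solutions:
        raise ValidationError("need at least one solution to report")
    labels = [l for l in REPORT_ORDER if l in solutions]
    labels += [l for l in solutions if l not in labels]
    rows: dict[str, dict[str, float]] = {}
    for label in labels:
        s = solutions[label]
        ex = exchanged_volumes(s)
        irr_use = sum(s.water_use.values())
        urb_use = sum(s.urban_use.values())
        mouth = s.mouth_flow
        col = {
            "water_use_total": irr_use + urb_use,
            "water_use_irrigation": irr_use,
            "water_use_urban": urb_use,
            "water_exchanges_total": ex["total"],
            "exchanges_between_irrigators": ex["between_irrigators"],
            "exchanges_to_environment": ex["to_environment"],
            "flow_at_mouth": mouth,
            "area_total": s.irrigated_area(),
            "area_field": s.irrigated_area("field"),
            "area_fruit": s.irrigated_area("fruit"),
            "area_vegetable": s.irrigated_area("vegetable"),
            "private_benefits": s.ledger.private,
            "irrigation_benefits": s.ledger.irrigation,
            "irrigation_trade_income": s.ledger.irrigation_trade_income,
            "irrigation_env_income": s.ledger.irrigation_env_income,
            "urban_benefits": s.ledger.urban,
            "environmental_benefits": s.ledger.environmental,
            "social_benefits": s.ledger.social,
            "public_expenditure": s.ledger.public_expenditure,
        }
        for k, v in col.items():
            rows.setdefault(k, {})[label] = v
    return pd.DataFrame(rows).T[labels]
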