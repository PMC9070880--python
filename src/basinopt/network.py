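"""River-network hydrology: reaches, mass balance, flow continuity, minimum flows.

The basin is a directed tree of river reaches rooted at the mouth. Each reach
receives local (tributary + runoff) inflow, loses a fixed volume to seepage and
evaporation, and may host irrigation/urban diversions. Outflow follows the
annual mass balance

    Wout_d = Win_d - Wloss_d - Div_d^IR - Div_d^URB (+ closure_d)

and continuity passes outflow plus return flows to the downstream reach

    Win_down = sum_upstream Wout_u + r^IR Div^IR + r^URB Div^URB + RO_down.

All volumes are Mm^3 per year. Closure terms are signed constants that absorb
non-observed flows (groundwater exchange, unmeasured returns) so that the
propagated flows reproduce gauged observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import CycleError, InfeasibleFlowError, ValidationError

VALUATION_TIERS = ("low", "medium", "high")

#: numerical slack for feasibility checks, Mm^3
_FEAS_TOL = 1e-9


@dataclass
class RiverReach:
    """One river segment (network arc) with its hydrology and ecology parameters.

    ``beta`` is the (negative) habitat-response coefficient of the reach's
    weighted-usable-area curve; ``wua_flow_scale`` converts annual reach flow in
    Mm^3 to the flow units beta was estimated in.
    """

    id: str
    downstream_id: str | None
    length_km: float
    local_inflow: float
    loss: float = 0.0
    return_coef_irrigation: float = 0.2
    return_coef_urban: float = 0.5
    min_env_flow: float = 0.0
    min_env_flow_drought: float | None = None
    closure_term: float = 0.0
    beta: float = -1.0
    valuation_tier: str = "medium"
    wua_flow_scale: float = 1.0

    def __post_init__(self):
        problems = []
        if self.length_km <= 0:
            problems.append(f"reach {self.id}: length_km must be > 0")
        if self.local_inflow < 0:
            problems.append(f"reach {self.id}: local_inflow must be >= 0")
        if self.loss < 0:
            problems.append(f"reach {self.id}: loss must be >= 0")
        for name in ("return_coef_irrigation", "return_coef_urban"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                problems.append(f"reach {self.id}: {name}={r} outside [0, 1]")
        if self.beta >= 0:
            problems.append(f"reach {self.id}: beta must be strictly negative")
        if self.valuation_tier not in VALUATION_TIERS:
            problems.append(
                f"reach {self.id}: unknown valuation_tier {self.valuation_tier!r}"
            )
        if self.wua_flow_scale <= 0:
            problems.append(f"reach {self.id}: wua_flow_scale must be > 0")
        if problems:
            raise ValidationError(problems)

    def min_flow(self, drought: bool = False) -> float:
        """Minimum environmental flow under normal or drought regulation."""
        if drought and self.min_env_flow_drought is not None:
            return self.min_env_flow_drought
        return self.min_env_flow


@dataclass(frozen=True)
class Attachment:
    """Links a demand unit (district or city) to its withdrawal and return reaches."""

    unit_id: str
    unit_type: str  # "district" | "city"
    withdraw_reach: str
    return_reach: str


@dataclass
class Network:
    """Directed tree of reaches rooted at the mouth, plus demand attachments."""

    reaches: dict[str, RiverReach]
    attachments: list[Attachment] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        problems = []
        mouths = [r.id for r in self.reaches.values() if r.downstream_id is None]
        if len(mouths) != 1:
            problems.append(
                f"network must have exactly one mouth reach, found {mouths!r}"
            )
        for r in self.reaches.values():
            if r.downstream_id is not None and r.downstream_id not in self.reaches:
                problems.append(
                    f"reach {r.id}: downstream_id {r.downstream_id!r} does not exist"
                )
        for a in self.attachments:
            if a.unit_type not in ("district", "city"):
                problems.append(f"attachment {a.unit_id}: bad unit_type {a.unit_type!r}")
            for which in ("withdraw_reach", "return_reach"):
                rid = getattr(a, which)
                if rid not in self.reaches:
                    problems.append(
                        f"attachment {a.unit_id}: {which} {rid!r} does not exist"
                    )
        if problems:
            raise ValidationError(problems)
        g = self._graph()
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            raise CycleError(
                "cycle in downstream links: "
                + " -> ".join(str(u) for u, _ in cyc)
            )

    def _graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.reaches)
        for r in self.reaches.values():
            if r.downstream_id is not None:
                g.add_edge(r.id, r.downstream_id)
        return g

    @property
    def mouth(self) -> RiverReach:
        return next(r for r in self.reaches.values() if r.downstream_id is None)

    def topological_order(self) -> list[str]:
        """Reach ids ordered upstream -> downstream (computed, never file order)."""
        g = self._graph()
        # lexicographic tie-break keeps ordering deterministic
        return list(nx.lexicographical_topological_sort(g))

    def upstream_map(self) -> dict[str, list[str]]:
        up: dict[str, list[str]] = {rid: [] for rid in self.reaches}
        for r in self.reaches.values():
            if r.downstream_id is not None:
                up[r.downstream_id].append(r.id)
        for v in up.values():
            v.sort()
        return up

    def control_points(self) -> list[str]:
        """Reaches carrying a minimum-flow requirement."""
        return [
            r.id
            for r in self.reaches.values()
            if r.min_env_flow > 0
            or (r.min_env_flow_drought is not None and r.min_env_flow_drought > 0)
        ]

    def with_closure(self, closures: Mapping[str, float]) -> "Network":
        reaches = {
            rid: replace(r, closure_term=closures.get(rid, r.closure_term))
            for rid, r in self.reaches.items()
        }
        return Network(reaches=reaches, attachments=list(self.attachments))

    def scaled_inflows(self, factor: float) -> "Network":
        """Network with every local inflow multiplied by ``factor`` (drought scaling)."""
        reaches = {
            rid: replace(r, local_inflow=r.local_inflow * factor)
            for rid, r in self.reaches.items()
        }
        return Network(reaches=reaches, attachments=list(self.attachments))


@dataclass
class FlowState:
    """Complete per-reach flow description: inflow, outflow, diversions (Mm^3/yr)."""

    win: dict[str, float]
    wout: dict[str, float]
    div_ir: dict[str, float]
    div_urb: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "reach_id": rid,
                "win": self.win[rid],
                "wout": self.wout[rid],
                "div_ir": self.div_ir.get(rid, 0.0),
                "div_urb": self.div_urb.get(rid, 0.0),
            }
            for rid in sorted(self.win)
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class MinFlowViolation:
    reach_id: str
    flow: float
    required: float

    @property
    def deficit(self) -> float:
        return self.required - self.flow


def mass_balance_outflow(
    reach: RiverReach,
    inflow: float,
    div_ir: float = 0.0,
    div_urb: float = 0.0,
    use_closure: bool = True,
) -> float:
    """Annual mass balance of a single reach.

    Raises :class:`InfeasibleFlowError` when losses plus diversions exceed the
    inflow (before the closure adjustment), identifying the reach.
    """
    if min(inflow, div_ir, div_urb) < 0:
        raise ValidationError(f"reach {reach.id}: flows and diversions must be >= 0")
    balance = inflow - reach.loss - div_ir - div_urb
    if balance < -_FEAS_TOL:
        raise InfeasibleFlowError(reach.id, -balance)
    out = balance + (reach.closure_term if use_closure else 0.0)
    if out < -_FEAS_TOL:
        raise InfeasibleFlowError(reach.id, -out)
    return max(out, 0.0)


def propagate_flows(
    network: Network,
    div_ir: Mapping[str, float] | None = None,
    div_urb: Mapping[str, float] | None = None,
    use_closure: bool = True,
) -> FlowState:
    """Propagate flows through the network in topological order.

    ``div_ir``/``div_urb`` map reach ids to diversion volumes; return flows
    re-enter the immediately downstream reach with the withdrawing reach's
    return coefficients (flow-continuity rule).
    """
    div_ir = dict(div_ir or {})
    div_urb = dict(div_urb or {})
    for d in (div_ir, div_urb):
        unknown = set(d) - set(network.reaches)
        if unknown:
            raise ValidationError(
                [f"diversion attached to unknown reach {rid!r}" for rid in sorted(unknown)]
            )
    up = network.upstream_map()
    win: dict[str, float] = {}
    wout: dict[str, float] = {}
    for rid in network.topological_order():
        reach = network.reaches[rid]
        inflow = reach.local_inflow
        for uid in up[rid]:
            u = network.reaches[uid]
            inflow += (
                wout[uid]
                + u.return_coef_irrigation * div_ir.get(uid, 0.0)
                + u.return_coef_urban * div_urb.get(uid, 0.0)
            )
        win[rid] = inflow
        wout[rid] = mass_balance_outflow(
            reach, inflow, div_ir.get(rid, 0.0), div_urb.get(rid, 0.0), use_closure
        )
    return FlowState(win=win, wout=wout, div_ir=div_ir, div_urb=div_urb)


def check_min_flows(
    state: FlowState, network: Network, drought: bool = False
) -> list[MinFlowViolation]:
    """Report every control point whose outflow falls short of its minimum.

    Returns an empty list for feasible states.
    """
    violations = []
    for rid in network.topological_order():
        required = network.reaches[rid].min_flow(drought)
        if required > 0 and state.wout[rid] < required - _FEAS_TOL:
            violations.append(
                MinFlowViolation(reach_id=rid, flow=state.wout[rid], required=required)
            )
    return violations


@dataclass
class ClosureReport:
    closures: dict[str, float]
    residuals: dict[str, float]
    consistent: bool


def calibrate_closure(
    network: Network,
    observed_flows: Mapping[str, float],
    div_ir: Mapping[str, float] | None = None,
    div_urb: Mapping[str, float] | None = None,
) -> tuple[Network, ClosureReport]:
    """Fit per-reach closure terms so propagated flows match gauged outflows.

    Closure unknowns live at the gauged reaches; a closure at reach ``d``
    raises the outflow of every reach at or downstream of ``d`` by the same
    amount, so in topological order the gauge system is lower-triangular with a
    unit diagonal and admits an exact solution (minimal in squared magnitude
    among exact solutions). Residuals at the gauges are reported.
    """
    unknown = set(observed_flows) - set(network.reaches)
    if unknown:
        raise ValidationError(
            [f"observed flow at unknown reach {rid!r}" for rid in sorted(unknown)]
        )
    base = Network(
        reaches={rid: replace(r, closure_term=0.0) for rid, r in network.reaches.items()},
        attachments=list(network.attachments),
    )
    nominal = propagate_flows(base, div_ir, div_urb, use_closure=True)

    order = base.topological_order()
    gauges = [rid for rid in order if rid in observed_flows]
    resid = np.array([observed_flows[g] - nominal.wout[g] for g in gauges])

    # downstream reachability: M[i, j] = 1 iff gauge i is at/downstream of gauge j
    g = base._graph()
    reach_sets = {rid: nx.descendants(g, rid) | {rid} for rid in gauges}
    m = np.zeros((len(gauges), len(gauges)))
    for i, gi in enumerate(gauges):
        for j, gj in enumerate(gauges):
            if gi in reach_sets[gj]:
                m[i, j] = 1.0
    c, _, _, _ = np.linalg.lstsq(m, resid, rcond=None)
    closures = {gid: float(ci) for gid, ci in zip(gauges, c)}

    calibrated = network.with_closure(closures)
    check = propagate_flows(calibrated, div_ir, div_urb, use_closure=True)
    residuals = {gid: check.wout[gid] - observed_flows[gid] for gid in gauges}
    consistent = all(abs(v) < 1e-6 for v in residuals.values())
    return calibrated, ClosureReport(closures=closures, residuals=residuals, consistent=consistent)


class LinearFlowSystem:
    """Affine representation of reach flows as a function of unit diversions.

    For a fixed network, ``win`` and ``wout`` of every reach are affine in the
    vector of diversions taken by the demand units (districts, cities). The
    withdrawal is subtracted at the unit's withdraw reach; the return fraction
    re-enters at the unit's return reach. Used by the policy optimizer, where
    district diversions are linear in crop acreage.
    """

    def __init__(self, network: Network, units: Sequence[Attachment]):
        self.network = network
        self.units = list(units)
        self.unit_index = {a.unit_id: i for i, a in enumerate(self.units)}
        n = len(self.units)
        order = network.topological_order()
        self.order = order
        up = network.upstream_map()

        withdraw_at: dict[str, list[int]] = {rid: [] for rid in order}
        return_at: dict[str, list[tuple[int, float]]] = {rid: [] for rid in order}
        for i, a in enumerate(self.units):
            withdraw_at[a.withdraw_reach].append(i)
            wreach = network.reaches[a.withdraw_reach]
            r = (
                wreach.return_coef_irrigation
                if a.unit_type == "district"
                else wreach.return_coef_urban
            )
            return_at[a.return_reach].append((i, r))

        self.win_const: dict[str, float] = {}
        self.win_coef: dict[str, np.ndarray] = {}
        self.wout_const: dict[str, float] = {}
        self.wout_coef: dict[str, np.ndarray] = {}
        for rid in order:
            reach = network.reaches[rid]
            const = reach.local_inflow
            coef = np.zeros(n)
            for uid in up[rid]:
                const += self.wout_const[uid]
                coef = coef + self.wout_coef[uid]
            for i, r in return_at[rid]:
                coef[i] += r
            self.win_const[rid] = const
            self.win_coef[rid] = coef
            ocoef = coef.copy()
            for i in withdraw_at[rid]:
                ocoef[i] -= 1.0
            self.wout_const[rid] = const - reach.loss + reach.closure_term
            self.wout_coef[rid] = ocoef
        self._withdraw_at = withdraw_at

    def evaluate(self, diversions: Mapping[str, float]) -> FlowState:
        """FlowState for the given per-unit diversion volumes."""
        d = np.zeros(len(self.units))
        for uid, v in diversions.items():
            d[self.unit_index[uid]] = v
        win = {rid: float(self.win_const[rid] + self.win_coef[rid] @ d) for rid in self.order}
        wout = {rid: float(self.wout_const[rid] + self.wout_coef[rid] @ d) for rid in self.order}
        div_ir: dict[str, float] = {rid: 0.0 for rid in self.order}
        div_urb: dict[str, float] = {rid: 0.0 for rid in self.order}
        for a in self.units:
            v = diversions.get(a.unit_id, 0.0)
            if a.unit_type == "district":
                div_ir[a.withdraw_reach] += v
            else:
                div_urb[a.withdraw_reach] += v
        for rid in self.order:
            if wout[rid] < -_FEAS_TOL:
                raise InfeasibleFlowError(rid, -wout[rid])
            wout[rid] = max(wout[rid], 0.0)
        return FlowState(win=win, wout=wout, div_ir=div_ir, div_urb=div_urb)

    def wout_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(constants, coefficients) of outflows, rows ordered by topological order."""
        a = np.array([self.wout_const[rid] for rid in self.order])
        b = np.vstack([self.wout_coef[rid] for rid in self.order])
        return a, b

    def win_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        a = np.array([self.win_const[rid] for rid in self.order])
        b = np.vstack([self.win_coef[rid] for rid in self.order])
        return a, b

    def withdrawals_at(self, rid: str) -> list[int]:
        return list(self._withdraw_at[rid])
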