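"""Irrigation-district economics with Ricardian yields and PMP calibration.

Each district chooses crop x technology acreages X (1,000 ha) to maximize

    B = sum_a C'_a(X_a) X_a,      C'_a(X) = P_a (b0_a + b1_a X) - CP_a

subject to land-by-technology, water and labor endowments. Yields decline
linearly with acreage (Ricardian rent: the best land enters production first),
so profit is concave quadratic and the optimum is unique whenever b1 < 0.

Positive Mathematical Programming (PMP) picks (b0, b1) per activity so that
(i) the yield at the observed acreage equals the observed average yield and
(ii) the first-order conditions of profit maximization hold at the observed
acreage given the duals of the resource constraints, making the observed
baseline the model's exact optimum.

Units: acreage 1,000 ha; prices EUR/t; costs EUR/ha; water Mm^3 per 1,000 ha;
labor 1,000 person-days per 1,000 ha; profits M EUR.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from .errors import SolverError, UnboundedError, ValidationError

TECHNOLOGIES = ("flood", "sprinkler", "drip")
CROP_GROUPS = ("field", "fruit", "vegetable")

#: EUR/ha times 1,000 ha -> M EUR
HA_TO_MEUR = 1e-3

#: calibration bound slack of the stage-1 PMP linear program
PMP_EPSILON = 1e-6


@dataclass
class CropActivity:
    """One crop x irrigation-technology activity inside a district."""

    crop_id: str
    tech: str
    district_id: str
    price: float  # EUR/t
    cost: float  # EUR/ha, direct + indirect incl. water costs
    water_req: float  # Mm^3 per 1,000 ha
    labor_req: float  # 1,000 person-days per 1,000 ha
    observed_acreage: float = 0.0  # 1,000 ha
    avg_yield: float | None = None  # t/ha at observed acreage
    group: str = "field"
    yield_intercept: float | None = None  # b0, t/ha
    yield_slope: float | None = None  # b1 <= 0, t/ha per 1,000 ha

    def __post_init__(self):
        problems = []
        if self.tech not in TECHNOLOGIES:
            problems.append(f"activity {self.key}: unknown tech {self.tech!r}")
        if self.group not in CROP_GROUPS:
            problems.append(f"activity {self.key}: unknown group {self.group!r}")
        for name in ("price", "cost", "water_req", "labor_req"):
            if getattr(self, name) < 0:
                problems.append(f"activity {self.key}: {name} must be >= 0")
        if self.observed_acreage < 0:
            problems.append(f"activity {self.key}: observed_acreage must be >= 0")
        if self.yield_slope is not None and self.yield_slope > 0:
            problems.append(f"activity {self.key}: yield_slope must be <= 0")
        if problems:
            raise ValidationError(problems)

    @property
    def key(self) -> tuple[str, str]:
        return (self.crop_id, self.tech)

    @property
    def calibrated(self) -> bool:
        return self.yield_intercept is not None and self.yield_slope is not None


def net_income_per_ha(activity: CropActivity, acreage: float) -> float:
    """C'(X) = P (b0 + b1 X) - CP at the given acreage (EUR/ha)."""
    if acreage < 0:
        raise ValidationError(f"activity {activity.key}: acreage must be >= 0")
    if not activity.calibrated:
        raise ValidationError(f"activity {activity.key}: yield coefficients not set")
    y = activity.yield_intercept + activity.yield_slope * acreage
    return activity.price * y - activity.cost


@dataclass
class District:
    """Irrigation district: activities plus land/water/labor endowments."""

    id: str
    activities: list[CropActivity]
    land_by_tech: dict[str, float]  # 1,000 ha per technology
    water_endowment: float  # Mm^3
    labor_endowment: float  # 1,000 person-days
    withdraw_reach: str = ""
    return_reach: str = ""

    def __post_init__(self):
        problems = []
        if self.water_endowment < 0 or self.labor_endowment < 0:
            problems.append(f"district {self.id}: endowments must be >= 0")
        if any(v < 0 for v in self.land_by_tech.values()):
            problems.append(f"district {self.id}: land endowments must be >= 0")
        if problems:
            raise ValidationError(problems)

    @property
    def calibrated(self) -> bool:
        return all(a.calibrated for a in self.activities)

    def observed_acreage(self) -> dict[tuple[str, str], float]:
        return {a.key: a.observed_acreage for a in self.activities}

    def observed_water_use(self) -> float:
        return sum(a.water_req * a.observed_acreage for a in self.activities)

    def observed_labor_use(self) -> float:
        return sum(a.labor_req * a.observed_acreage for a in self.activities)

    def constraint_matrix(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Land/water/labor rows (A x <= b) over the district's activities."""
        acts = self.activities
        rows, b, labels = [], [], []
        for tech in TECHNOLOGIES:
            if tech in self.land_by_tech:
                rows.append([1.0 if a.tech == tech else 0.0 for a in acts])
                b.append(self.land_by_tech[tech])
                labels.append(f"land:{tech}")
        rows.append([a.water_req for a in acts])
        b.append(self.water_endowment)
        labels.append("water")
        rows.append([a.labor_req for a in acts])
        b.append(self.labor_endowment)
        labels.append("labor")
        return np.array(rows), np.array(b), labels


@dataclass
class DistrictSolution:
    acreage: dict[tuple[str, str], float]  # 1,000 ha
    profit: float  # M EUR
    water_use: float  # Mm^3
    water_dual: float  # M EUR per Mm^3 (= EUR/m^3)
    status: str = "optimal"


def _profit_terms(district: District) -> tuple[np.ndarray, np.ndarray]:
    """(linear, quadratic) coefficients of profit in M EUR: p(x) = l.x + q.x^2."""
    lin = np.array(
        [
            (a.price * a.yield_intercept - a.cost) * HA_TO_MEUR
            for a in district.activities
        ]
    )
    quad = np.array(
        [a.price * a.yield_slope * HA_TO_MEUR for a in district.activities]
    )
    return lin, quad


def district_profit(district: District, acreage: np.ndarray) -> float:
    """Profit (M EUR) of a calibrated district at the given acreage vector."""
    lin, quad = _profit_terms(district)
    x = np.asarray(acreage, dtype=float)
    return float(lin @ x + quad @ (x * x))


def _solve_qp(
    lin: np.ndarray,
    quad: np.ndarray,
    a_ub: np.ndarray,
    b_ub: np.ndarray,
    x0: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Maximize lin.x + quad.x^2 s.t. A x <= b, x >= 0 (quad <= 0: concave)."""
    n = len(lin)
    if n == 0:
        return np.zeros(0), 0.0
    if np.any((quad >= -1e-15) & (lin > 0) & (np.abs(a_ub).sum(axis=0) == 0)):
        raise UnboundedError("linear activity with positive margin and no binding constraint")

    def neg_obj(x):
        return -(lin @ x + quad @ (x * x))

    def neg_grad(x):
        return -(lin + 2.0 * quad * x)

    cons = [
        {
            "type": "ineq",
            "fun": lambda x: b_ub - a_ub @ x,
            "jac": lambda x: -a_ub,
        }
    ]
    if x0 is None:
        x0 = np.zeros(n)
    res = optimize.minimize(
        neg_obj,
        x0,
        jac=neg_grad,
        method="SLSQP",
        bounds=[(0.0, None)] * n,
        constraints=cons,
        options={"maxiter": 500, "ftol": 1e-12},
    )
    if not res.success:
        # retry from an interior-ish start before giving up
        res = optimize.minimize(
            neg_obj,
            np.full(n, 1e-3),
            jac=neg_grad,
            method="SLSQP",
            bounds=[(0.0, None)] * n,
            constraints=cons,
            options={"maxiter": 1000, "ftol": 1e-12},
        )
    if not res.success:
        raise SolverError(f"district optimization failed: {res.message}")
    x = np.clip(res.x, 0.0, None)
    return x, float(lin @ x + quad @ (x * x))


def district_optimize(
    district: District,
    water_available: float | None = None,
    compute_dual: bool = True,
) -> DistrictSolution:
    """Profit-maximizing acreage plan under land/water/labor constraints.

    ``water_available`` caps the district's water below its endowment (the link
    to the hydrologic component). Returns the optimal plan, profit (M EUR), and
    the marginal value of water (the water constraint's dual, EUR/m^3),
    obtained by a forward-difference re-solve.
    """
    if not district.calibrated:
        raise ValidationError(f"district {district.id}: calibrate before optimizing")
    if water_available is not None and water_available < 0:
        raise ValidationError("water_available must be >= 0")
    lin, quad = _profit_terms(district)
    a_ub, b_ub, labels = district.constraint_matrix()
    w_row = labels.index("water")
    if water_available is not None:
        b_ub = b_ub.copy()
        b_ub[w_row] = min(b_ub[w_row], water_available)

    x, profit = _solve_qp(lin, quad, a_ub, b_ub)
    water_use = float(a_ub[w_row] @ x)

    dual = 0.0
    if compute_dual:
        w = b_ub[w_row]
        delta = max(1e-3, 1e-4 * max(w, 1.0))
        b2 = b_ub.copy()
        b2[w_row] = w + delta
        _, profit2 = _solve_qp(lin, quad, a_ub, b2, x0=x)
        dual = max((profit2 - profit) / delta, 0.0)

    acreage = {a.key: float(xi) for a, xi in zip(district.activities, x)}
    return DistrictSolution(
        acreage=acreage,
        profit=profit,
        water_use=water_use,
        water_dual=dual,
    )


def pmp_calibrate(district: District) -> District:
    """Calibrate yield coefficients so the observed baseline is the optimum.

    Two-stage procedure: a stage-1 linear program with calibration bounds
    X <= Xbar (1 + eps) supplies the duals of the resource constraints; then,
    per observed activity,

        b1 = -mu / (P Xbar),   b0 = ybar - b1 Xbar,

    where mu = linear margin - opportunity cost from the resource duals is the
    calibration-bound dual. Activities with zero observed acreage keep a flat
    yield (b1 = 0) at their average yield. Activities whose opportunity cost
    equals their margin (binding resource, mu = 0) also stay linear and are
    held by the binding constraint.
    """
    acts = district.activities
    problems = [
        f"activity {a.key}: avg_yield required for calibration"
        for a in acts
        if a.avg_yield is None
    ]
    if problems:
        raise ValidationError(problems)

    margin = np.array([a.price * a.avg_yield - a.cost for a in acts])  # EUR/ha
    xbar = np.array([a.observed_acreage for a in acts])
    observed = xbar > 0
    for a, m, obs in zip(acts, margin, observed):
        if obs and m <= 0:
            raise ValidationError(
                f"activity {a.key}: non-positive margin {m:.4g} EUR/ha cannot "
                "rationalize positive observed acreage"
            )

    a_ub, b_ub, labels = district.constraint_matrix()
    bounds = [
        (0.0, x * (1.0 + PMP_EPSILON)) if obs else (0.0, 0.0)
        for x, obs in zip(xbar, observed)
    ]
    res = optimize.linprog(
        -margin, A_ub=a_ub, b_ub=b_ub, bounds=bounds, method="highs"
    )
    if not res.success:
        raise SolverError(f"PMP stage-1 LP failed for district {district.id}: {res.message}")
    lam = np.clip(-res.ineqlin.marginals, 0.0, None)  # resource duals, EUR/ha terms
    opp_cost = lam @ a_ub  # per-activity opportunity cost of resources

    new_acts = []
    for a, m, oc, x in zip(acts, margin, opp_cost, xbar):
        if x > 0:
            mu = max(m - oc, 0.0)
            b1 = -mu / (a.price * x)
            b0 = a.avg_yield - b1 * x
        else:
            b1 = 0.0
            b0 = a.avg_yield
        new_acts.append(replace(a, yield_intercept=b0, yield_slope=b1))
    return replace(district, activities=new_acts)
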