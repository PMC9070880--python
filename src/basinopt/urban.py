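"""Urban water-use surplus with linear inverse demand and supply.

City surplus is the sum of consumer and producer surplus,

    B = a_d Q_d - 1/2 b_d Q_d^2 - a_s Q_s - 1/2 b_s Q_s^2,   Q_s >= Q_d >= 0,

with intercepts in EUR/m^3 (equivalently M EUR per Mm^3) and quantities in
Mm^3/yr. Since surplus strictly decreases in excess supply, supply equals
demand at the optimum and Q* = (a_d - a_s) / (b_d + b_s) unless a water cap
binds. Urban supply has priority in every allocation policy.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConstraintViolationError, ValidationError


@dataclass
class City:
    id: str
    demand_intercept: float  # a_d, EUR/m^3
    demand_slope: float  # b_d > 0, EUR/m^3 per Mm^3
    supply_intercept: float  # a_s
    supply_slope: float  # b_s >= 0
    withdraw_reach: str = ""
    return_reach: str = ""
    priority: bool = True

    def __post_init__(self):
        problems = []
        if self.demand_slope <= 0:
            problems.append(f"city {self.id}: demand_slope must be > 0")
        if self.supply_slope < 0:
            problems.append(f"city {self.id}: supply_slope must be >= 0")
        if self.demand_intercept <= self.supply_intercept:
            problems.append(
                f"city {self.id}: demand intercept must exceed supply intercept "
                "(positive gains from trade)"
            )
        if problems:
            raise ValidationError(problems)


def urban_surplus(city: City, q_demand: float, q_supply: float) -> float:
    """Consumer plus producer surplus (M EUR) at the given quantities."""
    if q_demand < 0 or q_supply < 0:
        raise ValidationError(f"city {city.id}: quantities must be >= 0")
    if q_demand > q_supply + 1e-12:
        raise ConstraintViolationError(
            f"city {city.id}: demand {q_demand:.6g} exceeds supply {q_supply:.6g}"
        )
    return (
        city.demand_intercept * q_demand
        - 0.5 * city.demand_slope * q_demand**2
        - city.supply_intercept * q_supply
        - 0.5 * city.supply_slope * q_supply**2
    )


def urban_optimize(city: City, water_cap: float | None = None) -> tuple[float, float]:
    """Surplus-maximizing quantity (Q_d = Q_s = Q*) and the surplus attained.

    ``water_cap`` limits the withdrawal (binding reach constraint); surplus is
    concave in Q so the capped optimum is the clipped interior optimum.
    """
    q = (city.demand_intercept - city.supply_intercept) / (
        city.demand_slope + city.supply_slope
    )
    q = max(q, 0.0)
    if water_cap is not None:
        if water_cap < 0:
            raise ValidationError("water_cap must be >= 0")
        q = min(q, water_cap)
    return q, urban_surplus(city, q, q)
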