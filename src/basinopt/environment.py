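"""Ecological response to flow and monetized environmental benefits.

Reach habitat follows a saturating weighted-usable-area (WUA) curve

    WUA(X) = 1 - exp(beta X),   beta < 0,

an index in [0, 1) that is zero at zero flow, strictly increasing and concave,
approaching one as flow rises. Ecosystem health status is identified with WUA,
and the reach's environmental benefit is

    B_eco = VE * l * health,

with VE the tier value of ecosystem services (M EUR/km) and l the reach length
(km). beta is estimated per reach by nonlinear least squares on (flow, WUA)
observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import InvalidParameterError, SolverError, ValidationError
from .network import RiverReach

#: default ecosystem-service values by tier, M EUR per km of reach
TIER_VALUES = {"low": 0.072, "medium": 0.180, "high": 0.450}


@dataclass(frozen=True)
class WUAObservation:
    reach_id: str
    flow: float
    wua: float

    def __post_init__(self):
        if self.flow < 0:
            raise ValidationError(f"reach {self.reach_id}: flow must be >= 0")
        if not 0.0 <= self.wua <= 1.0:
            raise ValidationError(f"reach {self.reach_id}: wua must lie in [0, 1]")


def wua(beta: float, flow):
    """Weighted usable area 1 - exp(beta * flow); beta must be negative."""
    if beta >= 0:
        raise InvalidParameterError(f"beta must be negative, got {beta}")
    flow = np.asarray(flow, dtype=float)
    if np.any(flow < 0):
        raise ValidationError("flow must be >= 0")
    out = 1.0 - np.exp(beta * flow)
    return float(out) if out.ndim == 0 else out


def ecosystem_health(reach: RiverReach, flow, dry_season_fraction: float = 1.0):
    """Health status of the reach ecosystem at the given annual flow (Mm^3).

    Identical to the WUA index evaluated at the reach's flow-unit scale;
    ``dry_season_fraction`` optionally maps annual flow to the effective flow
    of the low-water months that drive habitat stress (default 1.0).
    """
    if not 0.0 < dry_season_fraction <= 1.0:
        raise ValidationError("dry_season_fraction must lie in (0, 1]")
    return wua(reach.beta, np.asarray(flow, dtype=float) * reach.wua_flow_scale * dry_season_fraction)


def env_benefit(
    reach: RiverReach,
    flow,
    tier_values: dict[str, float] | None = None,
    dry_season_fraction: float = 1.0,
):
    """Environmental benefit of the reach (M EUR): VE * length * health."""
    values = TIER_VALUES if tier_values is None else tier_values
    if reach.valuation_tier not in values:
        raise ValidationError(
            f"reach {reach.id}: no value for tier {reach.valuation_tier!r}"
        )
    ve = values[reach.valuation_tier]
    if ve <= 0:
        raise ValidationError(f"tier {reach.valuation_tier!r}: value_per_km must be > 0")
    return ve * reach.length_km * ecosystem_health(reach, flow, dry_season_fraction)


@dataclass(frozen=True)
class BetaFit:
    beta: float
    se: float
    t: float
    n: int

    def as_row(self) -> dict:
        return {"n": self.n, "beta": self.beta, "se": self.se, "t": self.t}


def fit_beta(flows, wuas) -> BetaFit:
    """Nonlinear least-squares fit of WUA = 1 - exp(beta * flow).

    Returns the estimate, its asymptotic standard error and t = beta_hat / se.
    Requires at least three observations with distinct flows; the estimate is
    constrained negative.
    """
    x = np.asarray(flows, dtype=float)
    y = np.asarray(wuas, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("flows and wuas must be 1-D arrays of equal length")
    if len(np.unique(x)) < 3:
        raise ValidationError("need >= 3 observations with distinct flows")
    if np.any(x < 0):
        raise ValidationError("flows must be >= 0")

    # data-driven start: invert the curve at interior points
    mask = (y > 0) & (y < 1) & (x > 0)
    if mask.any():
        b0 = float(np.median(np.log(1.0 - y[mask]) / x[mask]))
        b0 = min(b0, -1e-8)
    else:
        b0 = -1.0 / max(x.max(), 1.0)

    try:
        popt, pcov = optimize.curve_fit(
            lambda xx, b: 1.0 - np.exp(b * xx),
            x,
            y,
            p0=[b0],
            bounds=(-np.inf, -1e-12),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise SolverError(f"beta fit did not converge: {exc}")
    beta = float(popt[0])
    se = float(np.sqrt(pcov[0, 0]))
    if not np.isfinite(se):
        raise SolverError("beta fit produced a non-finite standard error", {"beta": beta})
    # a noise-free fit has zero residual variance; report an infinite t
    t = beta / se if se > 0 else -np.inf
    return BetaFit(beta=beta, se=se, t=t, n=len(x))


def value_per_km(value_per_ha: float, water_area_ha: float, river_length_km: float) -> float:
    """Convert an ecosystem-service value in EUR/ha of wetted riverbed to M EUR/km.

    value_per_km = value_per_ha * water_area_ha / river_length_km / 1e6.
    """
    if value_per_ha <= 0 or water_area_ha <= 0:
        raise ValidationError("value_per_ha and water_area_ha must be > 0")
    if river_length_km <= 0:
        raise ValidationError("river_length_km must be > 0")
    return value_per_ha * water_area_ha / river_length_km / 1e6


def extraction_damage(cost_per_m3: float, volume_mm3: float) -> float:
    """Environmental damage of withdrawals (M EUR) at a unit damage cost.

    ``cost_per_m3`` is a polluter-pays damage value in EUR/m^3 and
    ``volume_mm3`` a withdrawal or residual-flow volume in Mm^3; used to
    cross-check the habitat-based benefit estimates against damage-cost
    valuations from the literature.
    """
    if cost_per_m3 < 0 or volume_mm3 < 0:
        raise ValidationError("damage cost and volume must be >= 0")
    return cost_per_m3 * volume_mm3
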