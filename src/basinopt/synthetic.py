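"""Synthetic basin instances with the structural properties the model assumes.

The generator builds directed-tree river networks with tributary inflows,
PMP-calibratable irrigation districts whose observed baselines respect their
endowments, cities with quadratic surplus, habitat-response coefficients drawn
over the empirically observed range, and three-tier ecosystem valuation. It
also ships ``toy_ebro``, a fixed 14-reach Ebro-like fixture with the published
habitat coefficients and control-point minimum flows; its district and city
economics are synthetic stand-ins (the real calibration dataset is not
public).

Seeds are explicit everywhere; there is no hidden global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .agriculture import CropActivity, District
from .basin import Basin
from .environment import TIER_VALUES, WUAObservation
from .errors import ValidationError
from .network import Network, RiverReach
from .urban import City

#: habitat coefficients of the 14 studied reaches (reach id -> beta)
EBRO_BETAS = {
    "202": -9.65,
    "264": -2.07,
    "274": -1.42,
    "406": -16.39,
    "418": -1.89,
    "421": -0.12,
    "426": -0.52,
    "428": -0.30,
    "433": -0.10,
    "441": -8.14,
    "446": -1.96,
    "455": -9.61,
    "463": -0.23,
    "662": -0.26,
}


@dataclass
class GeneratorConfig:
    """Knobs of the random-basin generator; defaults mirror the study basin."""

    n_reaches: int = 8
    n_districts: int = 4
    n_cities: int = 2
    seed: int = 0
    inflow_total: float = 14600.0  # Mm^3/yr
    beta_range: tuple[float, float] = (-16.39, -0.10)
    tier_probabilities: tuple[float, float, float] = (0.35, 0.4, 0.25)
    noise_sd: float = 0.05
    drought_levels: tuple[float, ...] = (0.3, 0.4)

    def __post_init__(self):
        problems = []
        if min(self.n_reaches, self.n_districts, self.n_cities) < 1:
            problems.append("counts must be >= 1")
        if not (self.beta_range[0] < 0 and self.beta_range[1] < 0):
            problems.append("beta_range must be strictly negative")
        if abs(sum(self.tier_probabilities) - 1.0) > 1e-9:
            problems.append("tier_probabilities must sum to 1")
        if self.inflow_total <= 0:
            problems.append("inflow_total must be > 0")
        if any(not 0.0 <= d < 1.0 for d in self.drought_levels):
            problems.append("drought levels must lie in [0, 1)")
        if problems:
            raise ValidationError(problems)


_CROP_POOL = [
    # crop, group, price EUR/t, cost EUR/ha, yield t/ha, water Mm^3/1000ha, labor
    ("corn", "field", 180.0, 1500.0, 11.0, 8.5, 6.0),
    ("barley", "field", 170.0, 650.0, 4.8, 4.0, 3.5),
    ("wheat", "field", 190.0, 700.0, 5.5, 4.5, 3.5),
    ("alfalfa", "field", 150.0, 1400.0, 13.5, 9.5, 5.0),
    ("fruit", "fruit", 450.0, 7200.0, 22.0, 6.0, 28.0),
    ("vegetable", "vegetable", 320.0, 6000.0, 28.0, 5.0, 35.0),
]

#: admissible technologies by crop group (field crops: flood/sprinkler;
#: fruit trees and vegetables: drip/flood)
_GROUP_TECHS = {
    "field": ("flood", "sprinkler"),
    "fruit": ("drip", "flood"),
    "vegetable": ("drip", "flood"),
}

#: technology effects relative to flood: water multiplier, cost adder EUR/ha
_TECH_EFFECTS = {"flood": (1.0, 0.0), "sprinkler": (0.75, 160.0), "drip": (0.6, 260.0)}


def _make_district(
    rng: np.random.Generator, did: str, withdraw: str, ret: str, size: float
) -> District:
    """A district with 3-4 activities whose observed baseline is interior.

    ``size`` scales total observed acreage (1,000 ha). Endowments are slack
    (5-20% above observed use) so PMP calibrates every activity interior.
    """
    n_crops = int(rng.integers(3, 5))
    picks = rng.choice(len(_CROP_POOL), size=n_crops, replace=False)
    acts = []
    shares = rng.dirichlet(np.ones(n_crops) * 2.0)
    for p, share in zip(picks, shares):
        crop, group, price, cost, yld, water, labor = _CROP_POOL[p]
        tech = _GROUP_TECHS[group][int(rng.integers(0, 2))]
        wmult, cadd = _TECH_EFFECTS[tech]
        acreage = float(size * share)
        yld_obs = yld * float(rng.uniform(0.9, 1.1))
        cost_eff = cost + cadd
        # guarantee a positive observed margin
        margin = price * yld_obs - cost_eff
        if margin <= 50.0:
            yld_obs = (cost_eff + float(rng.uniform(200.0, 600.0))) / price
        acts.append(
            CropActivity(
                crop_id=crop,
                tech=tech,
                district_id=did,
                price=price,
                cost=cost_eff,
                water_req=water * wmult,
                labor_req=labor,
                observed_acreage=acreage,
                avg_yield=yld_obs,
                group=group,
            )
        )
    land = {t: 0.0 for t in ("flood", "sprinkler", "drip")}
    for a in acts:
        land[a.tech] += a.observed_acreage
    slack = lambda: float(rng.uniform(1.05, 1.2))
    district = District(
        id=did,
        activities=acts,
        land_by_tech={t: v * slack() for t, v in land.items()},
        water_endowment=sum(a.water_req * a.observed_acreage for a in acts) * slack(),
        labor_endowment=sum(a.labor_req * a.observed_acreage for a in acts) * slack(),
        withdraw_reach=withdraw,
        return_reach=ret,
    )
    return district


def generate_basin(config: GeneratorConfig) -> Basin:
    """Random feasible basin instance; deterministic for a given seed.

    The network is a mainstem chain with tributary reaches; districts and
    cities withdraw from tributaries or upper-mainstem reaches and return to
    the next reach downstream. Observed withdrawals are sized against reach
    inflows so the baseline and every configured drought level are feasible
    (checked at generation time).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_reaches
    n_main = max(2, n // 2)
    main_ids = [f"M{i:02d}" for i in range(n_main)]
    trib_ids = [f"T{i:02d}" for i in range(n - n_main)]

    # inflow split: tributaries and the headwater carry most of the water
    weights = np.concatenate(
        [
            rng.uniform(0.5, 1.5, size=1),  # headwater
            rng.uniform(0.05, 0.2, size=n_main - 1),
            rng.uniform(0.5, 1.5, size=len(trib_ids)),
        ]
    )
    inflows = config.inflow_total * weights / weights.sum()

    lo, hi = config.beta_range
    log_lo, log_hi = np.log(-hi), np.log(-lo)  # sample magnitude log-uniformly
    tiers = rng.choice(
        ["low", "medium", "high"], size=n, p=list(config.tier_probabilities)
    )

    reaches: dict[str, RiverReach] = {}
    all_ids = main_ids + trib_ids
    trib_to = {
        tid: main_ids[int(rng.integers(0, n_main - 1))] for tid in trib_ids
    }
    for j, rid in enumerate(all_ids):
        if rid in main_ids:
            i = main_ids.index(rid)
            down = main_ids[i + 1] if i + 1 < n_main else None
        else:
            down = trib_to[rid]
        reaches[rid] = RiverReach(
            id=rid,
            downstream_id=down,
            length_km=float(rng.uniform(60.0, 500.0)),
            local_inflow=float(inflows[j]),
            loss=float(inflows[j] * rng.uniform(0.0, 0.05)),
            return_coef_irrigation=float(rng.uniform(0.15, 0.3)),
            return_coef_urban=float(rng.uniform(0.4, 0.6)),
            beta=float(-np.exp(rng.uniform(log_lo, log_hi))),
            valuation_tier=str(tiers[j]),
        )
    network = Network(reaches=reaches)

    # place districts on the wettest reaches, withdrawals sized to local inflow
    order = network.topological_order()
    candidates = sorted(all_ids, key=lambda r: -reaches[r].local_inflow)
    districts: dict[str, District] = {}
    worst = 1.0 - max(config.drought_levels, default=0.0)
    for i in range(config.n_districts):
        rid = candidates[i % len(candidates)]
        down = reaches[rid].downstream_id or rid
        # share of drought-year local inflow this district may claim
        budget = reaches[rid].local_inflow * worst * float(rng.uniform(0.25, 0.45))
        did = f"D{i:02d}"
        d = _make_district(rng, did, rid, down, size=1.0)
        use = d.observed_water_use()
        scale = budget / use
        for a in d.activities:
            a.observed_acreage *= scale
        d.land_by_tech = {t: v * scale for t, v in d.land_by_tech.items()}
        d.water_endowment *= scale
        d.labor_endowment *= scale
        districts[did] = d

    cities: dict[str, City] = {}
    for i in range(config.n_cities):
        rid = candidates[(config.n_districts + i) % len(candidates)]
        down = reaches[rid].downstream_id or rid
        a_d = float(rng.uniform(2.5, 3.5))
        a_s = float(rng.uniform(0.4, 0.8))
        q_target = reaches[rid].local_inflow * worst * float(rng.uniform(0.02, 0.08))
        q_target = max(q_target, 1.0)
        b_total = (a_d - a_s) / q_target
        cities[f"U{i:02d}"] = City(
            id=f"U{i:02d}",
            demand_intercept=a_d,
            demand_slope=0.75 * b_total,
            supply_intercept=a_s,
            supply_slope=0.25 * b_total,
            withdraw_reach=rid,
            return_reach=down,
        )

    basin = Basin(
        network=network, districts=districts, cities=cities, name=f"synthetic-{config.seed}"
    )

    # habitat flow scale: baseline health in (0.55, 0.9) at observed flows
    flows = _observed_flows(basin)
    for rid in order:
        r = reaches[rid]
        target = float(rng.uniform(0.55, 0.9))
        w = max(flows.wout[rid], 1e-6)
        r.wua_flow_scale = float(np.log(1.0 - target) / (r.beta * w))

    # minimum flows: mouth control point, satisfiable at the worst drought
    mouth = network.mouth.id
    worst_flow = _observed_flows(basin, factor=worst).wout[mouth]
    network.reaches[mouth].min_env_flow = round(0.5 * worst_flow, 3)

    _check_feasible(basin, config)
    return basin


def _observed_flows(basin: Basin, factor: float = 1.0):
    from .network import LinearFlowSystem

    net = basin.network.scaled_inflows(factor) if factor != 1.0 else basin.network
    system = LinearFlowSystem(net, basin.attachments())
    div = {d.id: d.observed_water_use() * factor for d in basin.districts.values()}
    for c in basin.cities.values():
        from .urban import urban_optimize

        div[c.id] = urban_optimize(c)[0]
    return system.evaluate(div)


def _check_feasible(basin: Basin, config: GeneratorConfig) -> None:
    """Construct-time check: baseline and drought scalings stay feasible."""
    for level in (0.0, *config.drought_levels):
        factor = 1.0 - level
        state = _observed_flows(basin, factor=factor)
        mouth = basin.network.mouth.id
        required = basin.network.reaches[mouth].min_flow(drought=level > 0)
        if state.wout[mouth] < required - 1e-6:
            raise ValidationError(
                f"generated basin infeasible at drought {level}: mouth flow "
                f"{state.wout[mouth]:.3f} < minimum {required:.3f}"
            )
        # reach-local availability at the observed withdrawals
        for a in basin.attachments():
            div = (
                basin.districts[a.unit_id].observed_water_use() * factor
                if a.unit_type == "district"
                else state.div_urb[a.withdraw_reach]
            )
            if div > state.win[a.withdraw_reach] + 1e-6:
                raise ValidationError(
                    f"generated basin infeasible at drought {level}: unit "
                    f"{a.unit_id} withdraws {div:.3f} > inflow "
                    f"{state.win[a.withdraw_reach]:.3f} at reach {a.withdraw_reach}"
                )


def generate_wua_observations(
    beta: float, n: int, noise_sd: float, seed: int
) -> list[WUAObservation]:
    """(flow, WUA) observations from the saturating habitat curve plus noise.

    Flows are spread so the noiseless curve traverses (0.05, 0.95); noisy WUA
    values are clamped to [0, 1].
    """
    if beta >= 0:
        raise ValidationError("beta must be negative")
    if n < 3:
        raise ValidationError("need n >= 3 observations")
    rng = np.random.default_rng(seed)
    x_lo = np.log(1.0 - 0.05) / beta
    x_hi = np.log(1.0 - 0.95) / beta
    flows = np.linspace(x_lo, x_hi, n)
    wua_true = 1.0 - np.exp(beta * flows)
    noisy = np.clip(wua_true + rng.normal(0.0, noise_sd, size=n), 0.0, 1.0)
    return [
        WUAObservation(reach_id="synthetic", flow=float(f), wua=float(w))
        for f, w in zip(flows, noisy)
    ]


def toy_ebro() -> Basin:
    """Fixed 14-reach Ebro-like fixture, loaded from packaged data files.

    Uses the published habitat coefficients and control-point minimum flows
    (300 Mm^3 upper mainstem; 945 normal / 640 drought mid mainstem; 3,000 at
    the mouth), total inflow 14,600 Mm^3 and an urban withdrawal of 402 Mm^3.
    District and city economics are synthetic stand-ins.
    """
    from . import io as bio

    data = resources.files("basinopt") / "data"
    with resources.as_file(data) as root:
        return bio.read_basin(
            root / "toy_ebro_network.csv",
            root / "toy_ebro_districts.csv",
            root / "toy_ebro_endowments.csv",
            root / "toy_ebro_cities.csv",
            name="toy_ebro",
        )
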