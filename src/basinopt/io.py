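"""Readers/writers for basin schemas, results and run configuration.

All files are plain CSV/JSON, UTF-8, decimal point, no thousands separators.
Writers are deterministic: stable row ordering and fixed float formatting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .agriculture import TECHNOLOGIES, CropActivity, District
from .basin import Basin
from .environment import TIER_VALUES, WUAObservation
from .errors import ValidationError
from .network import Network, RiverReach
from .scenarios import Solution, compute_exchanges, welfare_report
from .urban import City

_FLOAT_FMT = "%.10g"

NETWORK_COLUMNS = [
    "reach_id",
    "downstream_id",
    "length_km",
    "local_inflow",
    "loss",
    "r_ir",
    "r_urb",
    "min_env_flow",
    "min_env_flow_drought",
    "closure_term",
    "beta",
    "wua_flow_scale",
    "valuation_tier",
]

DISTRICT_COLUMNS = [
    "district_id",
    "crop_id",
    "group",
    "tech",
    "price",
    "cost",
    "water_req",
    "labor_req",
    "observed_acreage",
    "avg_yield",
]

ENDOWMENT_COLUMNS = [
    "district_id",
    "tland_flood",
    "tland_sprinkler",
    "tland_drip",
    "twater",
    "tlabor",
    "withdraw_reach",
    "return_reach",
]

CITY_COLUMNS = ["city_id", "a_d", "b_d", "a_s", "b_s", "withdraw_reach", "return_reach"]


def _require_columns(df: pd.DataFrame, cols, path) -> list[str]:
    return [f"{path}: missing column {c!r}" for c in cols if c not in df.columns]


def read_network(path) -> Network:
    df = pd.read_csv(path, dtype={"reach_id": str, "downstream_id": str})
    problems = _require_columns(df, [c for c in NETWORK_COLUMNS if c != "min_env_flow_drought"], path)
    if problems:
        raise ValidationError(problems)
    reaches = {}
    for i, row in df.iterrows():
        down = row["downstream_id"]
        down = None if (pd.isna(down) or str(down) == "") else str(down)
        drought_min = row.get("min_env_flow_drought", np.nan)
        try:
            reaches[str(row["reach_id"])] = RiverReach(
                id=str(row["reach_id"]),
                downstream_id=down,
                length_km=float(row["length_km"]),
                local_inflow=float(row["local_inflow"]),
                loss=float(row["loss"]),
                return_coef_irrigation=float(row["r_ir"]),
                return_coef_urban=float(row["r_urb"]),
                min_env_flow=float(row["min_env_flow"]),
                min_env_flow_drought=None if pd.isna(drought_min) else float(drought_min),
                closure_term=float(row.get("closure_term", 0.0)),
                beta=float(row["beta"]),
                wua_flow_scale=float(row.get("wua_flow_scale", 1.0)),
                valuation_tier=str(row["valuation_tier"]),
            )
        except ValidationError as exc:
            problems.extend(f"{path} line {i + 2}: {p}" for p in exc.problems)
    if problems:
        raise ValidationError(problems)
    return Network(reaches=reaches)


def read_districts(districts_path, endowments_path) -> dict[str, District]:
    ddf = pd.read_csv(districts_path, dtype={"district_id": str, "crop_id": str})
    edf = pd.read_csv(
        endowments_path,
        dtype={"district_id": str, "withdraw_reach": str, "return_reach": str},
    )
    problems = _require_columns(ddf, DISTRICT_COLUMNS, districts_path)
    problems += _require_columns(edf, ENDOWMENT_COLUMNS, endowments_path)
    if problems:
        raise ValidationError(problems)
    districts: dict[str, District] = {}
    for _, erow in edf.iterrows():
        did = str(erow["district_id"])
        sub = ddf[ddf["district_id"].astype(str) == did]
        if sub.empty:
            problems.append(f"{endowments_path}: district {did} has no activities")
            continue
        acts = [
            CropActivity(
                crop_id=str(r["crop_id"]),
                tech=str(r["tech"]),
                district_id=did,
                price=float(r["price"]),
                cost=float(r["cost"]),
                water_req=float(r["water_req"]),
                labor_req=float(r["labor_req"]),
                observed_acreage=float(r["observed_acreage"]),
                avg_yield=float(r["avg_yield"]),
                group=str(r["group"]),
            )
            for _, r in sub.iterrows()
        ]
        districts[did] = District(
            id=did,
            activities=acts,
            land_by_tech={
                tech: float(erow[f"tland_{tech}"]) for tech in TECHNOLOGIES
            },
            water_endowment=float(erow["twater"]),
            labor_endowment=float(erow["tlabor"]),
            withdraw_reach=str(erow["withdraw_reach"]),
            return_reach=str(erow["return_reach"]),
        )
    orphans = set(ddf["district_id"].astype(str)) - set(districts)
    problems += [f"{districts_path}: district {d} has no endowment row" for d in sorted(orphans)]
    if problems:
        raise ValidationError(problems)
    return districts


def read_cities(path) -> dict[str, City]:
    df = pd.read_csv(
        path, dtype={"city_id": str, "withdraw_reach": str, "return_reach": str}
    )
    problems = _require_columns(df, CITY_COLUMNS, path)
    if problems:
        raise ValidationError(problems)
    return {
        str(r["city_id"]): City(
            id=str(r["city_id"]),
            demand_intercept=float(r["a_d"]),
            demand_slope=float(r["b_d"]),
            supply_intercept=float(r["a_s"]),
            supply_slope=float(r["b_s"]),
            withdraw_reach=str(r["withdraw_reach"]),
            return_reach=str(r["return_reach"]),
        )
        for _, r in df.iterrows()
    }


def read_basin(
    network_path,
    districts_path,
    endowments_path,
    cities_path,
    tier_values: Mapping[str, float] | None = None,
    dry_season_fraction: float = 1.0,
    name: str = "basin",
) -> Basin:
    """Load and cross-validate a full basin instance from its CSV files."""
    network = read_network(network_path)
    districts = read_districts(districts_path, endowments_path)
    cities = read_cities(cities_path)
    return Basin(
        network=network,
        districts=districts,
        cities=cities,
        tier_values=dict(tier_values or TIER_VALUES),
        dry_season_fraction=dry_season_fraction,
        name=name,
    )


# -- writers ---------------------------------------------------------------


def network_frame(network: Network) -> pd.DataFrame:
    rows = []
    for rid in sorted(network.reaches):
        r = network.reaches[rid]
        rows.append(
            {
                "reach_id": r.id,
                "downstream_id": "" if r.downstream_id is None else r.downstream_id,
                "length_km": r.length_km,
                "local_inflow": r.local_inflow,
                "loss": r.loss,
                "r_ir": r.return_coef_irrigation,
                "r_urb": r.return_coef_urban,
                "min_env_flow": r.min_env_flow,
                "min_env_flow_drought": (
                    "" if r.min_env_flow_drought is None else r.min_env_flow_drought
                ),
                "closure_term": r.closure_term,
                "beta": r.beta,
                "wua_flow_scale": r.wua_flow_scale,
                "valuation_tier": r.valuation_tier,
            }
        )
    return pd.DataFrame(rows, columns=NETWORK_COLUMNS)


def basin_frames(basin: Basin) -> dict[str, pd.DataFrame]:
    drows, erows, crows = [], [], []
    for did in sorted(basin.districts):
        d = basin.districts[did]
        for a in d.activities:
            drows.append(
                {
                    "district_id": did,
                    "crop_id": a.crop_id,
                    "group": a.group,
                    "tech": a.tech,
                    "price": a.price,
                    "cost": a.cost,
                    "water_req": a.water_req,
                    "labor_req": a.labor_req,
                    "observed_acreage": a.observed_acreage,
                    "avg_yield": a.avg_yield,
                }
            )
        erows.append(
            {
                "district_id": did,
                **{f"tland_{t}": d.land_by_tech.get(t, 0.0) for t in TECHNOLOGIES},
                "twater": d.water_endowment,
                "tlabor": d.labor_endowment,
                "withdraw_reach": d.withdraw_reach,
                "return_reach": d.return_reach,
            }
        )
    for cid in sorted(basin.cities):
        c = basin.cities[cid]
        crows.append(
            {
                "city_id": cid,
                "a_d": c.demand_intercept,
                "b_d": c.demand_slope,
                "a_s": c.supply_intercept,
                "b_s": c.supply_slope,
                "withdraw_reach": c.withdraw_reach,
                "return_reach": c.return_reach,
            }
        )
    return {
        "network": network_frame(basin.network),
        "districts": pd.DataFrame(drows, columns=DISTRICT_COLUMNS),
        "endowments": pd.DataFrame(erows, columns=ENDOWMENT_COLUMNS),
        "cities": pd.DataFrame(crows, columns=CITY_COLUMNS),
    }


def write_basin(basin: Basin, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in basin_frames(basin).items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False, float_format=_FLOAT_FMT)
        paths[name] = p
    return paths


def read_wua_observations(path) -> list[WUAObservation]:
    df = pd.read_csv(path, dtype={"reach_id": str})
    problems = _require_columns(df, ["reach_id", "flow", "wua"], path)
    if problems:
        raise ValidationError(problems)
    return [
        WUAObservation(reach_id=str(r["reach_id"]), flow=float(r["flow"]), wua=float(r["wua"]))
        for _, r in df.iterrows()
    ]


def write_flow_state(state, path) -> None:
    state.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


@dataclass
class RunConfig:
    """Configuration of one model run, loadable from JSON."""

    network: str
    districts: str
    endowments: str
    cities: str
    policy: str = "institutional_cooperation"
    drought_reduction: float = 0.0
    seed: int = 1
    outdir: str = "results"
    tier_values: dict[str, float] = field(default_factory=lambda: dict(TIER_VALUES))
    dry_season_fraction: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.drought_reduction < 1.0:
            raise ValidationError("drought_reduction must lie in [0, 1)")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        missing = [k for k in ("network", "districts", "endowments", "cities") if k not in known]
        if missing:
            raise ValidationError([f"{path}: missing config key {k!r}" for k in missing])
        return cls(**known)

    def load_basin(self) -> Basin:
        return read_basin(
            self.network,
            self.districts,
            self.endowments,
            self.cities,
            tier_values=self.tier_values,
            dry_season_fraction=self.dry_season_fraction,
        )


def write_results(
    solutions: Mapping[str, Solution],
    outdir,
    metadata: Mapping | None = None,
) -> dict[str, Path]:
    """Comparative table, per-reach flows, exchange ledger and a run manifest.

    The comparative table rounds volumes and money to whole units (Mm^3, M EUR)
    as in standard policy-comparison layouts; the flow and exchange files keep
    full precision.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    report = welfare_report(solutions).round(0)
    paths["comparative"] = outdir / "comparative.csv"
    report.to_csv(paths["comparative"], float_format="%.0f")

    flow_frames = []
    for label, s in solutions.items():
        f = s.flows.to_frame()
        f.insert(0, "scenario", label)
        flow_frames.append(f)
    paths["flows"] = outdir / "flows.csv"
    pd.concat(flow_frames).to_csv(paths["flows"], index=False, float_format=_FLOAT_FMT)

    ex_frames = []
    for label, s in solutions.items():
        e = compute_exchanges(s)
        if not e.empty:
            e.insert(0, "scenario", label)
            ex_frames.append(e)
    paths["exchanges"] = outdir / "exchanges.csv"
    if ex_frames:
        pd.concat(ex_frames).to_csv(paths["exchanges"], index=False, float_format=_FLOAT_FMT)
    else:
        pd.DataFrame(
            columns=["scenario", "seller", "buyer", "volume", "price", "payment"]
        ).to_csv(paths["exchanges"], index=False)

    manifest = {
        "scenarios": {
            label: {
                "policy": s.scenario.policy,
                "drought_reduction": s.scenario.drought_reduction,
                "status": s.status,
                "objective": s.objective,
                "market_price": s.market_price,
            }
            for label, s in solutions.items()
        },
    }
    if metadata:
        manifest["run"] = dict(metadata)
    paths["manifest"] = outdir / "manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return paths
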