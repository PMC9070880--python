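"""Basin container tying network, districts, cities and valuation together."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .agriculture import District, pmp_calibrate
from .environment import TIER_VALUES
from .errors import ValidationError
from .network import Attachment, Network
from .urban import City


@dataclass
class Basin:
    """A complete basin instance: hydrology, irrigation economy, cities, valuation."""

    network: Network
    districts: dict[str, District]
    cities: dict[str, City]
    tier_values: dict[str, float] = field(default_factory=lambda: dict(TIER_VALUES))
    dry_season_fraction: float = 1.0
    name: str = "basin"

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        problems = []
        reaches = self.network.reaches
        for d in self.districts.values():
            for which in ("withdraw_reach", "return_reach"):
                rid = getattr(d, which)
                if rid not in reaches:
                    problems.append(f"district {d.id}: {which} {rid!r} does not exist")
        for c in self.cities.values():
            for which in ("withdraw_reach", "return_reach"):
                rid = getattr(c, which)
                if rid not in reaches:
                    problems.append(f"city {c.id}: {which} {rid!r} does not exist")
        missing = set(TIER_VALUES) - set(self.tier_values)
        if missing:
            problems.append(f"tier values missing for {sorted(missing)}")
        if problems:
            raise ValidationError(problems)

    def attachments(self) -> list[Attachment]:
        """Demand-unit attachments in deterministic order (districts, then cities)."""
        atts = [
            Attachment(d.id, "district", d.withdraw_reach, d.return_reach)
            for d in sorted(self.districts.values(), key=lambda d: d.id)
        ]
        atts += [
            Attachment(c.id, "city", c.withdraw_reach, c.return_reach)
            for c in sorted(self.cities.values(), key=lambda c: c.id)
        ]
        return atts

    def calibrate(self) -> "Basin":
        """PMP-calibrate every district; returns a new Basin."""
        districts = {did: pmp_calibrate(d) for did, d in self.districts.items()}
        return replace(self, districts=districts)

    @property
    def calibrated(self) -> bool:
        return all(d.calibrated for d in self.districts.values())

    def baseline_allocations(self) -> dict[str, float]:
        """Observed baseline water use per district (Mm^3) - the water rights."""
        return {
            did: d.observed_water_use() for did, d in sorted(self.districts.items())
        }
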