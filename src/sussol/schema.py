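"""Property schema: canonical column names, units, plausibility bounds, weights.

The default schema ships as a YAML file inside the package (``data/
property_schema.yaml``) and lists the 22 physical properties a solvent record
may carry, in canonical column order.  Users can load their own schema file
with :func:`load_schema` to add or drop property columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml

__all__ = [
    "PropertySpec",
    "Schema",
    "load_schema",
    "default_schema",
    "PROPERTY_NAMES",
    "HAZARD_COLUMNS",
    "NAME_COLUMN",
    "CAS_COLUMN",
    "TAGS_COLUMN",
]

NAME_COLUMN = "Name"
CAS_COLUMN = "CAS"
TAGS_COLUMN = "Tags"

#: Hazard-metadata columns recognised in the CSV besides the numeric schema.
#: ``H3xx``/``H4xx`` hold semicolon-separated GHS statement codes or the
#: literal ``UNKNOWN``; the three flag columns hold 0/1 booleans.
HAZARD_COLUMNS = (
    "H3xx",
    "H4xx",
    "REACH_status",
    "High_resistivity",
    "Peroxide_former",
    "High_energy_decomposition",
)


@dataclass(frozen=True)
class PropertySpec:
    """One numeric property column: unit, plausibility bounds, default weight.

    Bounds describe physical plausibility (used for clipping synthetic data),
    not validation limits for user-supplied values.
    """

    name: str
    unit: str
    low: float
    high: float
    weight: float = 1.0


class Schema:
    """Ordered collection of :class:`PropertySpec` entries."""

    def __init__(self, specs: list[PropertySpec]):
        self.specs = list(specs)
        self._by_name = {s.name: s for s in self.specs}
        if len(self._by_name) != len(self.specs):
            raise ValueError("duplicate property names in schema")

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> PropertySpec:
        return self._by_name[name]

    def __len__(self) -> int:
        return len(self.specs)

    def __iter__(self):
        return iter(self.specs)

    def default_weights(self) -> dict[str, float]:
        return {s.name: s.weight for s in self.specs}


def _schema_from_mapping(doc: dict) -> Schema:
    specs = []
    for entry in doc["properties"]:
        lo, hi = entry.get("bounds", (float("-inf"), float("inf")))
        specs.append(
            PropertySpec(
                name=entry["name"],
                unit=str(entry.get("unit", "")),
                low=float(lo),
                high=float(hi),
                weight=float(entry.get("weight", 1.0)),
            )
        )
    return Schema(specs)


def load_schema(path) -> Schema:
    """Load a property schema from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        return _schema_from_mapping(yaml.safe_load(fh))


def default_schema() -> Schema:
    """The packaged 22-property schema."""
    text = (
        resources.files("sussol").joinpath("data/property_schema.yaml").read_text("utf-8")
    )
    return _schema_from_mapping(yaml.safe_load(text))


#: Canonical property names of the default schema, in column order.
PROPERTY_NAMES: tuple[str, ...] = tuple(default_schema().names)
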