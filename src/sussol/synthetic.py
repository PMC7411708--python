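"""Synthetic solvent tables with known structure.

Real solvent datasets with full 22-property coverage are proprietary, so
every higher-level module here is exercised against generated tables whose
ground truth is known:

* :func:`make_blob_table` draws Gaussian clusters around archetype solvent
  profiles (alkane-like, alcohol-like, ketone-like by default), mirroring the
  "several obvious chemical families" structure used to validate clusterers,
  and returns the true labels separately.
* :func:`make_homologous_series` emulates a homologous series (increasing
  alkyl chain): strictly increasing boiling point, non-increasing water
  solubility, increasing molecular weight, with an optional outsized jump
  between consecutive members.
* :func:`inject_missing` masks a seeded fraction of one column, emulating the
  incomplete property coverage of new solvents.

All generated values are clipped to the per-property plausibility bounds
declared in the schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .chem21 import HazardProfile
from .errors import SchemaError
from .schema import Schema, default_schema
from .table import MISSING, HazardInfo, SolventRecord, SolventTable

__all__ = [
    "BlobSpec",
    "SeriesSpec",
    "make_blob_table",
    "make_homologous_series",
    "inject_missing",
    "ARCHETYPE_CENTERS",
    "example_hazard_profiles",
]

# Archetype property centers: typical mid-chain alkane, short-chain alcohol
# and small ketone profiles (units per the schema).
ARCHETYPE_CENTERS: dict[str, dict[str, float]] = {
    "alkane": {
        "Boiling_point": 98.0, "Melting_point": -91.0, "Vapor_pressure": 46.0,
        "Flash_point": -4.0, "Autoignition_temperature": 204.0,
        "Hansen_delta_D": 15.3, "Hansen_delta_P": 0.0, "Hansen_delta_H": 0.0,
        "Solubility_in_water": 0.003, "Density": 0.684, "Viscosity": 0.39,
        "Relative_vapor_density": 3.5, "Log_P_octanol_water": 4.66,
        "Refractive_index": 1.387, "Surface_tension": 20.1, "Molar_volume": 147.0,
        "Relative_evaporation_rate": 290.0, "Antoine_A": 6.9, "Antoine_B": 1270.0,
        "Antoine_C": 216.0, "Molecular_weight": 100.2, "Log_S": -4.5,
    },
    "alcohol": {
        "Boiling_point": 97.0, "Melting_point": -126.0, "Vapor_pressure": 21.0,
        "Flash_point": 23.0, "Autoignition_temperature": 371.0,
        "Hansen_delta_D": 16.0, "Hansen_delta_P": 6.8, "Hansen_delta_H": 17.4,
        "Solubility_in_water": 1000.0, "Density": 0.803, "Viscosity": 1.95,
        "Relative_vapor_density": 2.1, "Log_P_octanol_water": 0.25,
        "Refractive_index": 1.384, "Surface_tension": 23.7, "Molar_volume": 75.0,
        "Relative_evaporation_rate": 94.0, "Antoine_A": 7.8, "Antoine_B": 1500.0,
        "Antoine_C": 205.0, "Molecular_weight": 60.1, "Log_S": 1.0,
    },
    "ketone": {
        "Boiling_point": 80.0, "Melting_point": -86.0, "Vapor_pressure": 78.0,
        "Flash_point": -9.0, "Autoignition_temperature": 404.0,
        "Hansen_delta_D": 16.0, "Hansen_delta_P": 9.0, "Hansen_delta_H": 5.1,
        "Solubility_in_water": 275.0, "Density": 0.805, "Viscosity": 0.40,
        "Relative_vapor_density": 2.5, "Log_P_octanol_water": 0.29,
        "Refractive_index": 1.379, "Surface_tension": 24.6, "Molar_volume": 90.0,
        "Relative_evaporation_rate": 380.0, "Antoine_A": 7.1, "Antoine_B": 1250.0,
        "Antoine_C": 221.0, "Molecular_weight": 72.1, "Log_S": 0.4,
    },
}

# Hazard metadata for the archetype families (typical GHS statements).
_ARCHETYPE_HAZARDS: dict[str, HazardInfo] = {
    "alkane": HazardInfo(h3xx=frozenset({"H304", "H336"}), h4xx=frozenset({"H411"})),
    "alcohol": HazardInfo(h3xx=frozenset({"H319"}), h4xx=frozenset()),
    "ketone": HazardInfo(h3xx=frozenset({"H319", "H336"}), h4xx=frozenset()),
}


@dataclass
class BlobSpec:
    """Gaussian cluster specification in property space.

    ``centers`` maps cluster name -> property center; ``None`` uses the
    first ``k`` archetypes (random plausible centers beyond three).
    ``spread`` scales the per-property base standard deviation, which is 2%
    of each property's plausibility range.
    """

    k: int = 3
    n_per: int = 20
    centers: Optional[dict[str, dict[str, float]]] = None
    spread: float = 1.0
    seed: int = 0
    with_hazards: bool = False
    schema: Schema = field(default_factory=default_schema)

    def __post_init__(self):
        if self.k < 1 or self.n_per < 1:
            raise ValueError("k and n_per must be >= 1")
        if not self.spread > 0:
            raise ValueError(f"spread must be > 0, got {self.spread}")


def _resolve_centers(spec: BlobSpec, rng: np.random.Generator) -> dict[str, dict[str, float]]:
    if spec.centers is not None:
        if len(spec.centers) != spec.k:
            raise ValueError("number of centers must equal k")
        return spec.centers
    names = list(ARCHETYPE_CENTERS)
    centers = {}
    for c in range(spec.k):
        if c < len(names):
            centers[names[c]] = ARCHETYPE_CENTERS[names[c]]
        else:
            # random plausible center inside the middle 80% of the bounds
            centers[f"family{c}"] = {
                s.name: float(rng.uniform(s.low + 0.1 * (s.high - s.low),
                                          s.high - 0.1 * (s.high - s.low)))
                for s in spec.schema
            }
    return centers


def make_blob_table(spec: BlobSpec) -> tuple[SolventTable, np.ndarray]:
    """Draw ``k * n_per`` solvents from per-cluster Gaussians.

    Values are clipped to the schema's plausibility bounds and the melting
    point is kept below the boiling point.  Returns the table and the true
    integer cluster labels (in record order).
    """
    rng = np.random.default_rng(spec.seed)
    centers = _resolve_centers(spec, rng)
    base_sd = {s.name: 0.02 * (s.high - s.low) for s in spec.schema}
    records, labels = [], []
    for label, (family, center) in enumerate(centers.items()):
        hazard = _ARCHETYPE_HAZARDS.get(family) if spec.with_hazards else None
        for i in range(spec.n_per):
            props = {}
            for s in spec.schema:
                mu = center.get(s.name)
                if mu is None:
                    continue
                v = rng.normal(mu, spec.spread * base_sd[s.name])
                props[s.name] = float(np.clip(v, s.low, s.high))
            if "Boiling_point" in props and "Melting_point" in props:
                props["Melting_point"] = min(
                    props["Melting_point"], props["Boiling_point"] - 5.0
                )
            records.append(
                SolventRecord(
                    name=f"{family}_{i:02d}",
                    properties=props,
                    hazard=hazard,
                    tags=frozenset({family}),
                )
            )
            labels.append(label)
    return SolventTable(records, schema=spec.schema), np.asarray(labels)


@dataclass
class SeriesSpec:
    """Homologous-series specification (increasing alkyl chain length)."""

    length: int = 6
    base: Optional[dict[str, float]] = None
    bp_step: float = 20.0            # degC per CH2, strictly positive
    ws_factor: float = 0.35          # water solubility multiplier per step, in (0, 1]
    mw_step: float = 14.0            # g/mol per CH2
    jump_at: Optional[int] = None    # index of the step getting an outsized jump
    jump_scale: float = 3.0
    seed: int = 0
    noise: float = 0.0               # sd of jitter on the non-trend properties
    schema: Schema = field(default_factory=default_schema)

    def __post_init__(self):
        if self.length < 2:
            raise ValueError("a series needs at least 2 members")
        if not self.bp_step > 0:
            raise ValueError("boiling point must strictly increase along the series")
        if not 0 < self.ws_factor <= 1:
            raise ValueError("water solubility must be non-increasing (factor in (0, 1])")


def make_homologous_series(spec: SeriesSpec) -> SolventTable:
    """Generate a homologous series with monotone trend properties."""
    rng = np.random.default_rng(spec.seed)
    base = dict(spec.base or ARCHETYPE_CENTERS["alcohol"])
    records = []
    bp = base.get("Boiling_point", 80.0)
    ws = base.get("Solubility_in_water", 1000.0)
    mw = base.get("Molecular_weight", 60.0)
    for m in range(spec.length):
        props = {}
        for s in spec.schema:
            if s.name in ("Boiling_point", "Solubility_in_water", "Molecular_weight"):
                continue
            mu = base.get(s.name)
            if mu is None:
                continue
            v = mu + (rng.normal(0, spec.noise) if spec.noise > 0 else 0.0)
            props[s.name] = float(np.clip(v, s.low, s.high))
        props["Boiling_point"] = float(bp)
        props["Solubility_in_water"] = float(ws)
        props["Molecular_weight"] = float(mw)
        if "Melting_point" in props:
            props["Melting_point"] = min(props["Melting_point"], props["Boiling_point"] - 5.0)
        records.append(SolventRecord(name=f"series_{m:02d}", properties=props))
        scale = spec.jump_scale if spec.jump_at is not None and m == spec.jump_at else 1.0
        bp += scale * spec.bp_step
        ws *= spec.ws_factor / scale
        mw += scale * spec.mw_step
    return SolventTable(records, schema=spec.schema)


def inject_missing(
    table: SolventTable, column: str, fraction: float, seed: int = 0
) -> SolventTable:
    """Mask ``round(fraction * n)`` seeded entries of one column as MISSING."""
    if column not in table.schema:
        raise SchemaError(f"unknown column {column!r}")
    if not 0 <= fraction <= 1:
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    n_mask = round(fraction * len(table))
    rng = np.random.default_rng(seed)
    masked = set(rng.choice(len(table), size=n_mask, replace=False)) if n_mask else set()
    records = []
    for i, rec in enumerate(table):
        props = dict(rec.properties)
        if i in masked:
            props[column] = MISSING
        records.append(
            SolventRecord(
                name=rec.name, cas=rec.cas, properties=props,
                hazard=rec.hazard, tags=rec.tags, extra=dict(rec.extra),
            )
        )
    return SolventTable(records, schema=table.schema)


def example_hazard_profiles() -> dict[str, HazardProfile]:
    """Edge-case hazard profiles exercising every scoring branch."""
    return {
        "benign": HazardProfile(boiling_point=100.0, flash_point=80.0,
                                autoignition_temperature=400.0),
        "peroxide_former": HazardProfile(boiling_point=100.0, flash_point=80.0,
                                         autoignition_temperature=400.0,
                                         peroxide_former=True),
        "high_energy_decomposition": HazardProfile(boiling_point=100.0, flash_point=80.0,
                                                   high_energy_decomposition=True),
        "unknown_toxicity": HazardProfile(boiling_point=100.0, flash_point=80.0,
                                          h3xx=None),
        "unknown_environment": HazardProfile(boiling_point=100.0, flash_point=80.0,
                                             h4xx=None),
        "ozone_hazard": HazardProfile(boiling_point=100.0, flash_point=80.0,
                                      h4xx=frozenset({"H420"})),
        "volatile_ether": HazardProfile(boiling_point=35.0, flash_point=-45.0,
                                        autoignition_temperature=160.0,
                                        peroxide_former=True,
                                        h3xx=frozenset({"H302", "H336"}),
                                        h4xx=frozenset()),
        "reprotoxic_amide": HazardProfile(boiling_point=202.0, flash_point=91.0,
                                          h3xx=frozenset({"H360D", "H319"}),
                                          h4xx=frozenset(), reach_status="restricted"),
        "missing_flash_point": HazardProfile(boiling_point=100.0, flash_point=None),
    }
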