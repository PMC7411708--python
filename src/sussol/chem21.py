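"""CHEM21-style safety / health / environment (SH&E) scoring.

Each solvent receives three integer scores on a 1-10 scale (10 = highest
hazard), a green / yellow / red colour per score, and an overall
``Recommended`` / ``Problematic`` / ``Hazardous`` ranking:

* **Safety** comes from a flash-point (and volatility) band table, with one
  penalty point each for a low autoignition temperature, high electrical
  resistivity, or peroxide formation; a high energy of decomposition forces
  the score to 10.
* **Health** is the worst mapped H3xx statement, plus a penalty point for
  low-boiling (< 85 degC) solvents; incomplete toxicological data scores 5.
* **Environment** starts from a boiling-point band (70-139 degC is the ideal
  range), is raised by H4xx statements and REACH status, scores 5 on
  incomplete data, and is forced to 10 by the ozone-hazard statement H420.

All thresholds and maps live in an editable YAML rules file
(``data/chem21_rules.yaml``); the shipped defaults are a reconstruction of
the CHEM21 rubric and can be overridden wholesale or per solvent (manual
overall-ranking overrides mirror the published guides' footnotes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional

import yaml

__all__ = [
    "HazardProfile",
    "SHEScore",
    "Chem21Scorer",
    "safety_score",
    "health_score",
    "environment_score",
    "classify",
    "color_of",
    "REACH_STATUSES",
]

logger = logging.getLogger(__name__)

REACH_STATUSES = ("full", "intermediate-only", "unregistered", "restricted")

GREEN, YELLOW, RED = "green", "yellow", "red"
RECOMMENDED, PROBLEMATIC, HAZARDOUS = "Recommended", "Problematic", "Hazardous"


def color_of(score: int) -> str:
    """Colour band for an integer 1-10 score: green 1-3, yellow 4-6, red 7-10."""
    if not 1 <= int(score) <= 10 or int(score) != score:
        raise ValueError(f"score must be an integer in [1, 10], got {score!r}")
    if score <= 3:
        return GREEN
    if score <= 6:
        return YELLOW
    return RED


@dataclass(frozen=True)
class HazardProfile:
    """Hazard metadata for one solvent.

    ``h3xx`` / ``h4xx`` are frozensets of GHS statement codes; ``None`` means
    the data is UNKNOWN (incomplete), which is distinct from an empty set
    (no statements).
    """

    boiling_point: float
    flash_point: Optional[float] = None
    autoignition_temperature: Optional[float] = None
    high_resistivity: bool = False
    peroxide_former: bool = False
    high_energy_decomposition: bool = False
    h3xx: Optional[frozenset[str]] = frozenset()
    h4xx: Optional[frozenset[str]] = frozenset()
    reach_status: str = "full"

    def __post_init__(self):
        if self.boiling_point is None:
            raise ValueError("boiling_point is required for SH&E scoring")
        if self.reach_status not in REACH_STATUSES:
            raise ValueError(
                f"reach_status must be one of {REACH_STATUSES}, got {self.reach_status!r}"
            )


@dataclass(frozen=True)
class SHEScore:
    """Scored SH&E triple with colour bands and overall ranking."""

    safety: int
    health: int
    environment: int
    colors: Mapping[str, str] = field(default_factory=dict)
    overall: str = PROBLEMATIC

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.safety, self.health, self.environment)


def _clamp(score: float) -> int:
    return int(min(10, max(1, round(score))))


def _load_rules(rules) -> dict:
    if rules is None:
        text = (
            resources.files("sussol").joinpath("data/chem21_rules.yaml").read_text("utf-8")
        )
        return yaml.safe_load(text)
    if isinstance(rules, Mapping):
        return dict(rules)
    with open(rules, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


class Chem21Scorer:
    """SH&E scorer driven by a rules mapping (default: packaged YAML).

    Parameters
    ----------
    rules : None, mapping, or path
        ``None`` loads the packaged defaults; a path loads a user YAML file;
        a mapping is used as-is.
    overrides : mapping, optional
        Per-solvent manual overall-ranking overrides,
        e.g. ``{"Pyridine": "Hazardous"}``.
    """

    def __init__(self, rules=None, overrides: Optional[Mapping[str, str]] = None):
        self.rules = _load_rules(rules)
        self.overrides = dict(overrides or {})

    # -- individual criteria -------------------------------------------------

    def safety_score(self, profile: HazardProfile) -> int:
        cfg = self.rules["safety"]
        if profile.high_energy_decomposition:
            return _clamp(cfg.get("high_energy_decomposition_score", 10))
        fp = profile.flash_point
        bp = profile.boiling_point
        base = None
        if fp is None:
            logger.warning(
                "missing flash point: scoring in the most conservative band"
            )
            base = cfg["missing_flash_point_score"]
        else:
            for band in cfg["bands"]:
                if "fp_min" in band and not fp >= band["fp_min"]:
                    continue
                if "fp_below" in band and not fp < band["fp_below"]:
                    continue
                if "bp_below" in band and not bp < band["bp_below"]:
                    continue
                base = band["score"]
                break
        score = base
        penalty = cfg.get("penalty", 1)
        ait = profile.autoignition_temperature
        if ait is not None and ait < cfg["low_autoignition_threshold"]:
            score += penalty
        if profile.high_resistivity:
            score += penalty
        if profile.peroxide_former:
            score += penalty
        return _clamp(score)

    def health_score(self, profile: HazardProfile) -> int:
        cfg = self.rules["health"]
        if profile.h3xx is None:
            base = cfg["unknown_score"]
        else:
            mapped = [self._map_code(code, cfg["h3_scores"]) for code in profile.h3xx]
            mapped = [m for m in mapped if m is not None]
            base = max(mapped) if mapped else cfg.get("no_statement_score", 1)
        if profile.boiling_point < cfg["low_bp_threshold"]:
            base += cfg.get("low_bp_penalty", 1)
        return _clamp(base)

    def environment_score(self, profile: HazardProfile) -> int:
        cfg = self.rules["environment"]
        bp = profile.boiling_point
        base = None
        for band in cfg["bp_bands"]:
            lo = band.get("min", float("-inf"))
            hi = band.get("max", float("inf"))
            if lo <= bp <= hi:
                base = band["score"]
                break
        if profile.h4xx is None:
            h4 = cfg["unknown_score"]
        else:
            codes = {c.upper() for c in profile.h4xx}
            if "H420" in codes:
                return _clamp(cfg.get("h420_score", 10))
            mapped = [self._map_code(c, cfg["h4_scores"]) for c in codes]
            mapped = [m for m in mapped if m is not None]
            h4 = max(mapped) if mapped else 0
        score = max(base, h4)
        score += cfg["reach_adjustment"].get(profile.reach_status, 0)
        return _clamp(score)

    @staticmethod
    def _map_code(code: str, table: Mapping[str, int]) -> Optional[int]:
        # Match H360FD on its H360 stem; unknown codes are ignored.
        code = code.strip().upper()
        if code in table:
            return table[code]
        stem = code[:4]
        return table.get(stem)

    # -- combination ---------------------------------------------------------

    def classify(
        self,
        safety: int,
        health: int,
        environment: int,
        override: Optional[str] = None,
    ) -> SHEScore:
        """Colour bands and overall ranking for a scored triple."""
        colors = {
            "safety": color_of(safety),
            "health": color_of(health),
            "environment": color_of(environment),
        }
        if override is not None:
            overall = override
        else:
            rk = self.rules["ranking"]
            hz = rk["hazardous"]
            h_ge, e_ge = hz.get("health_and_environment_ge", (11, 11))
            if (
                safety >= hz["safety_ge"]
                or health >= hz["health_ge"]
                or environment >= hz["environment_ge"]
                or (health >= h_ge and environment >= e_ge)
            ):
                overall = HAZARDOUS
            elif max(safety, health, environment) <= rk["recommended_all_le"]:
                overall = RECOMMENDED
            else:
                overall = PROBLEMATIC
        return SHEScore(int(safety), int(health), int(environment), colors, overall)

    def score_profile(self, profile: HazardProfile, name: Optional[str] = None) -> SHEScore:
        s = self.safety_score(profile)
        h = self.health_score(profile)
        e = self.environment_score(profile)
        return self.classify(s, h, e, override=self.overrides.get(name))

    def score_record(self, record) -> SHEScore:
        """Score a :class:`~sussol.table.SolventRecord` with hazard metadata."""
        profile = record.hazard_profile()
        return self.score_profile(profile, name=record.name)

    def score_table(self, table):
        """Score every record of a table; returns a tidy DataFrame."""
        import pandas as pd

        rows = []
        for rec in table:
            try:
                she = self.score_record(rec)
            except ValueError:
                rows.append(
                    {"Name": rec.name, "S": None, "H": None, "E": None, "overall": None}
                )
                continue
            rows.append(
                {
                    "Name": rec.name,
                    "S": she.safety,
                    "H": she.health,
                    "E": she.environment,
                    "S_color": she.colors["safety"],
                    "H_color": she.colors["health"],
                    "E_color": she.colors["environment"],
                    "overall": she.overall,
                }
            )
        return pd.DataFrame(rows)


# -- module-level convenience wrappers --------------------------------------

def safety_score(profile: HazardProfile, rules=None) -> int:
    return Chem21Scorer(rules).safety_score(profile)


def health_score(profile: HazardProfile, rules=None) -> int:
    return Chem21Scorer(rules).health_score(profile)


def environment_score(profile: HazardProfile, rules=None) -> int:
    return Chem21Scorer(rules).environment_score(profile)


def classify(safety: int, health: int, environment: int, rules=None, override=None) -> SHEScore:
    return Chem21Scorer(rules).classify(safety, health, environment, override=override)
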