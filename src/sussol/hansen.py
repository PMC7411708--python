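"""Hansen solubility parameters: distance and radius-based subsetting.

The Hansen distance between solvents a and b uses the conventional factor-4
weighting on the dispersion component:

    Ra**2 = 4*(dD_a - dD_b)**2 + (dP_a - dP_b)**2 + (dH_a - dH_b)**2

Two nonpolar compounds within roughly 4 MPa^0.5 of each other are expected to
be miscible (Seymour rule of thumb), which motivates the default subsetting
radius.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .errors import MissingDataError

__all__ = ["HansenParameters", "hansen_distance", "hansen_subset"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HansenParameters:
    """Dispersion / polar / hydrogen-bonding cohesion parameters (MPa^0.5)."""

    deltaD: float
    deltaP: float
    deltaH: float

    def __post_init__(self):
        for label, v in (("deltaD", self.deltaD), ("deltaP", self.deltaP), ("deltaH", self.deltaH)):
            if v is None or math.isnan(v):
                raise MissingDataError(f"Hansen {label} is missing")
            if v < 0:
                raise ValueError(f"Hansen {label} must be >= 0, got {v}")


def hansen_distance(a: HansenParameters, b: HansenParameters) -> float:
    """Hansen distance Ra between two complete parameter triples (MPa^0.5)."""
    return math.sqrt(
        4.0 * (a.deltaD - b.deltaD) ** 2
        + (a.deltaP - b.deltaP) ** 2
        + (a.deltaH - b.deltaH) ** 2
    )


def hansen_subset(table, reference: str, radius: float):
    """Records strictly within ``radius`` of the reference solvent.

    The reference itself is always retained.  Records lacking a complete
    Hansen triple are excluded with a logged warning.
    """
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    ref = table.get(reference)
    ref_hsp = ref.hansen()  # raises MissingDataError when incomplete
    kept = []
    for rec in table:
        if rec is ref:
            kept.append(rec)
            continue
        try:
            hsp = rec.hansen()
        except MissingDataError:
            logger.warning(
                "excluding %r from Hansen subset: incomplete Hansen parameters",
                rec.name,
            )
            continue
        if hansen_distance(ref_hsp, hsp) < radius:
            kept.append(rec)
    return table.subset([rec.name for rec in kept])
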