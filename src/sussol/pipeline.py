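"""End-to-end substitution workflow.

Glues the pieces together the way an analyst uses them: optional Hansen
subsetting around the query, missing-property column selection, weighted
min-max scaling, the SOM ensemble, stability accumulation, the significance
band, and the ranked candidate list.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .chem21 import Chem21Scorer
from .hansen import hansen_subset
from .som import run_ensemble
from .stability import (
    CandidateList,
    NeighborhoodCounts,
    SignificanceBand,
    StabilityTable,
    accumulate,
    candidates_for,
    significance_band,
)
from .table import SolventTable, feature_matrix, select_feature_columns

__all__ = ["SubstitutionResult", "find_substitutes"]


@dataclass
class SubstitutionResult:
    """Everything the substitution pipeline produced for one query."""

    query: str
    candidates: CandidateList
    counts: NeighborhoodCounts
    stab: StabilityTable
    band: SignificanceBand
    columns: list[str]
    table: SolventTable


def find_substitutes(
    table: SolventTable,
    query: str,
    width: int = 5,
    height: int = 5,
    runs: int = 250,
    seed: int = 0,
    r: int = 0,
    alpha: float = 0.05,
    weights: Optional[Mapping[str, float]] = None,
    scaling: str = "minmax",
    hansen_radius: Optional[float] = None,
    exclude_tags: Sequence[str] = (),
    sort: str = "hansen",
    scorer: Optional[Chem21Scorer] = None,
    presentations: Optional[int] = None,
) -> SubstitutionResult:
    """Run the full substitution analysis for one query solvent.

    When ``hansen_radius`` is given, the table is first restricted to
    solvents strictly within that Hansen distance of the query.  Properties
    missing for the query (or for any remaining solvent) are dropped before
    clustering.  ``exclude_tags`` removes tagged solvents (e.g. ``protic``)
    from the candidate list only, never from the clustering.
    """
    work = table
    if hansen_radius is not None:
        work = hansen_subset(work, query, hansen_radius)
    columns = select_feature_columns(work, query=query)
    features = feature_matrix(work, columns=columns, weights=weights, scaling=scaling)
    assignments = run_ensemble(
        features,
        runs=runs,
        base_seed=seed,
        width=width,
        height=height,
        presentations=presentations,
    )
    counts, stab = accumulate(assignments, r=r)
    band = significance_band(B=runs, U=width * height, r=r, alpha=alpha)
    if scorer is None:
        scorer = Chem21Scorer()
    candidates = candidates_for(
        query,
        counts,
        band,
        table=work,
        sort=sort,
        scorer=scorer,
        exclude_tags=exclude_tags,
    )
    return SubstitutionResult(
        query=query,
        candidates=candidates,
        counts=counts,
        stab=stab,
        band=band,
        columns=columns,
        table=work,
    )
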