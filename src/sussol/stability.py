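"""Cluster-stability statistics over an ensemble of SOM runs.

For each pair of solvents (i, j) and each run b, the neighbourhood indicator

    NEIGH_ij^b(r) = 1  if the two solvents' neurons are within grid radius r
                    0  otherwise

uses the Chebyshev metric on the grid, so a radius-r neighbourhood covers
``nu = (2r + 1)**2`` neurons (r = 0 means "same neuron").  The stability
statistic is the ensemble average

    STAB_ij(r) = sum_b NEIGH_ij^b(r) / B

Under the null hypothesis of an unorganized map, a pair lands together with
probability ``p = nu / U`` per run (U = number of neurons), so the neighbour
count over B runs is Binomial(B, p).  When ``B*p > 10`` and ``B*(1-p) > 10``
the normal approximation applies and the two-sided band

    B*p +/- z_(1-alpha/2) * sqrt(B*p*(1-p))

separates significant neighbours (count above the upper limit) from
significant non-neighbours (count below the lower limit).  At r = 0 the
validity condition reduces to "at least 10 runs per neuron".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import MissingDataError
from .hansen import hansen_distance
from .som import ClusterAssignment

__all__ = [
    "NeighborhoodCounts",
    "StabilityTable",
    "SignificanceBand",
    "CandidateList",
    "neigh",
    "accumulate",
    "significance_band",
    "candidates_for",
    "candidate_rsd",
    "modal_assignment",
]


def modal_assignment(assignments: Sequence[ClusterAssignment]) -> ClusterAssignment:
    """The most frequent partition in an ensemble, up to neuron relabelling.

    Each run's neuron vector is canonicalized (clusters renumbered in order
    of first appearance) so that runs producing the same grouping with
    different neuron labels count as the same partition; the earliest run
    realizing the most common partition is returned.
    """
    if len(assignments) == 0:
        raise ValueError("at least one assignment is required")
    names = sorted(assignments[0].names)

    def canonical(a: ClusterAssignment) -> tuple[int, ...]:
        relabel: dict[int, int] = {}
        out = []
        for name in names:
            u = a.neuron_of(name)
            out.append(relabel.setdefault(u, len(relabel)))
        return tuple(out)

    keys = [canonical(a) for a in assignments]
    tally: dict[tuple[int, ...], int] = {}
    for k in keys:
        tally[k] = tally.get(k, 0) + 1
    best = max(tally.items(), key=lambda kv: kv[1])[0]
    return assignments[keys.index(best)]


def neigh(assignment: ClusterAssignment, i: str, j: str, r: int = 0) -> int:
    """Binary neighbourhood indicator for one run (Chebyshev grid metric)."""
    if r < 0 or int(r) != r:
        raise ValueError(f"radius must be a non-negative integer, got {r}")
    ri, ci = assignment.position_of(i)
    rj, cj = assignment.position_of(j)
    return int(max(abs(ri - rj), abs(ci - cj)) <= r)


@dataclass
class NeighborhoodCounts:
    """Symmetric pairwise neighbour counts summed over B runs."""

    names: list[str]
    counts: np.ndarray
    B: int
    n_units: int
    r: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        n = len(self.names)
        if self.counts.shape != (n, n):
            raise ValueError("counts must be n x n")
        if not np.array_equal(self.counts, self.counts.T):
            raise ValueError("counts must be symmetric")
        if (self.counts < 0).any() or (self.counts > self.B).any():
            raise ValueError("counts must lie in [0, B]")
        self._index = {name: k for k, name in enumerate(self.names)}

    def count(self, i: str, j: str) -> int:
        return int(self.counts[self._index[i], self._index[j]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.names, columns=self.names)


@dataclass
class StabilityTable:
    """STAB matrix: neighbour counts divided by the number of runs."""

    names: list[str]
    stab: np.ndarray
    B: int
    r: int

    def __post_init__(self):
        self.stab = np.asarray(self.stab, dtype=float)
        self._index = {name: k for k, name in enumerate(self.names)}

    def value(self, i: str, j: str) -> float:
        return float(self.stab[self._index[i], self._index[j]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stab, index=self.names, columns=self.names)


def accumulate(
    assignments: Sequence[ClusterAssignment], r: int = 0
) -> tuple[NeighborhoodCounts, StabilityTable]:
    """Pairwise neighbour counts and STAB values over an ensemble."""
    if len(assignments) == 0:
        raise ValueError("at least one assignment is required")
    first = assignments[0]
    names = list(first.names)
    name_set = set(names)
    for a in assignments[1:]:
        if set(a.names) != name_set:
            raise ValueError("all runs must cover the same solvent set")
        if (a.width, a.height) != (first.width, first.height):
            raise ValueError("all runs must share the same grid size")
    B = len(assignments)
    n = len(names)
    counts = np.zeros((n, n), dtype=int)
    for a in assignments:
        neurons = np.array([a.neuron_of(name) for name in names])
        rows, cols = np.divmod(neurons, a.width)
        cheb = np.maximum(
            np.abs(rows[:, None] - rows[None, :]),
            np.abs(cols[:, None] - cols[None, :]),
        )
        counts += cheb <= r
    cnt = NeighborhoodCounts(
        names=names, counts=counts, B=B, n_units=first.n_units, r=r
    )
    stab = StabilityTable(names=names, stab=counts / B, B=B, r=r)
    return cnt, stab


@dataclass(frozen=True)
class SignificanceBand:
    """Two-sided normal-approximation band for the binomial neighbour count."""

    B: int
    U: int
    r: int
    alpha: float
    nu: int
    expected: float
    lower: float
    upper: float
    valid: bool

    def display(self, decimals: int = 1) -> tuple[float, float]:
        """Band limits rounded for display (the test itself uses unrounded values)."""
        return (round(self.lower, decimals), round(self.upper, decimals))


def significance_band(
    B: int, U: int, r: int = 0, alpha: float = 0.05
) -> SignificanceBand:
    """Null band for the neighbour count of a solvent pair over B runs.

    ``nu = (2r + 1)**2`` (clamped to U) neurons fall inside the radius-r
    neighbourhood, so the null co-clustering probability is ``nu / U``.  The
    ``valid`` flag records whether the Gaussian-approximation conditions
    ``B*p > 10`` and ``B*(1-p) > 10`` hold; an invalid approximation is
    flagged, never fatal.
    """
    if B < 1 or U < 1:
        raise ValueError("B and U must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if r < 0 or int(r) != r:
        raise ValueError(f"radius must be a non-negative integer, got {r}")
    nu = min((2 * int(r) + 1) ** 2, U)
    p = nu / U
    z = stats.norm.ppf(1 - alpha / 2)
    half_width = z * math.sqrt(B * p * (1 - p))
    expected = B * p
    return SignificanceBand(
        B=B,
        U=U,
        r=int(r),
        alpha=alpha,
        nu=nu,
        expected=expected,
        lower=expected - half_width,
        upper=expected + half_width,
        valid=(B * p > 10) and (B * (1 - p) > 10),
    )


@dataclass
class CandidateList:
    """Ranked substitution candidates for a query solvent."""

    query: str
    frame: pd.DataFrame
    sort: str

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def names(self) -> list[str]:
        return list(self.frame["candidate"])


def candidates_for(
    query: str,
    counts: NeighborhoodCounts,
    band: SignificanceBand,
    table=None,
    sort: str = "hansen",
    scorer=None,
    exclude_tags: Sequence[str] = (),
    top_k: Optional[int] = None,
) -> CandidateList:
    """Statistically significant substitution candidates for a query solvent.

    A candidate is any other solvent whose neighbour count with the query
    exceeds the (unrounded) upper band limit.  When a solvent table is
    supplied, candidates are annotated with the Hansen distance to the query
    and, when a scorer is supplied, with SH&E scores.  ``sort="hansen"``
    ranks by Hansen distance ascending; ``sort="she"`` by (health,
    environment, safety) ascending.
    """
    if query not in counts._index:
        raise KeyError(f"query solvent {query!r} not present in the ensemble")
    if sort not in ("hansen", "she", "count"):
        raise ValueError(f"unknown sort key {sort!r}")
    exclude_tags = set(exclude_tags)

    query_hsp = None
    if table is not None:
        try:
            query_hsp = table.get(query).hansen()
        except MissingDataError:
            query_hsp = None

    rows = []
    for name in counts.names:
        if name == query:
            continue
        c = counts.count(query, name)
        if not c > band.upper:
            continue
        row = {"candidate": name, "count": c, "stab": c / counts.B}
        if table is not None:
            rec = table.get(name)
            if exclude_tags & rec.tags:
                continue
            dist = math.nan
            if query_hsp is not None:
                try:
                    dist = hansen_distance(query_hsp, rec.hansen())
                except MissingDataError:
                    pass
            row["hansen_distance"] = dist
            if scorer is not None:
                try:
                    she = scorer.score_record(rec)
                    row.update(
                        S=she.safety, H=she.health, E=she.environment, overall=she.overall
                    )
                except ValueError:
                    row.update(S=None, H=None, E=None, overall=None)
        rows.append(row)

    frame = pd.DataFrame(rows)
    if len(frame):
        if sort == "hansen" and "hansen_distance" in frame:
            frame = frame.sort_values("hansen_distance", na_position="last")
        elif sort == "she" and "H" in frame:
            frame = frame.sort_values(["H", "E", "S"])
        else:
            frame = frame.sort_values("count", ascending=False)
        frame = frame.reset_index(drop=True)
        if top_k is not None:
            frame = frame.head(top_k)
    return CandidateList(query=query, frame=frame, sort=sort)


def candidate_rsd(
    candidates: CandidateList,
    table,
    property: str,
    top_k: Optional[int] = None,
) -> float:
    """Relative standard deviation (%) of a property over the candidate list.

    Sample (n-1) standard deviation over the candidates' property values,
    divided by the absolute mean, times 100.  A single value has RSD 0 by
    convention; a zero mean is undefined and reported as NaN.
    """
    names = candidates.names if top_k is None else candidates.names[:top_k]
    values = [table.get(n).get(property) for n in names]
    values = [v for v in values if not math.isnan(v)]
    if not values:
        raise MissingDataError(
            f"property {property!r} is missing for every candidate"
        )
    if len(values) == 1:
        return 0.0
    mean = float(np.mean(values))
    if mean == 0:
        return math.nan
    return 100.0 * float(np.std(values, ddof=1)) / abs(mean)
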