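"""Packaged worked example: the d-limonene substitution case study.

A published substitution analysis clustered the 57 solvents lying within a
Hansen distance of 4 MPa^0.5 of d-limonene on a 5x5 map (25 neurons) and
repeated the run 250 times.  This module transcribes the printed record of
that analysis:

* which solvents shared d-limonene's cluster in each of the first 10 runs;
* the neighbour counts of the 20 reported candidates after 10 and 250 runs
  with their STAB values.

The transcription drives regression tests and the reproduction script: the
first 10 runs can be replayed as :class:`~sussol.som.ClusterAssignment`
objects and pushed through the stability pipeline, and the 250-run counts can
be screened against the significance band (with B = 250 and U = 25 the
two-sided 95% band is 10 +/- 6.07, i.e. (3.9, 16.1) at one decimal, so every
count above 16 flags a significant neighbour).
"""

from __future__ import annotations

from .som import ClusterAssignment

__all__ = [
    "QUERY",
    "GRID_WIDTH",
    "GRID_HEIGHT",
    "N_UNITS",
    "ENSEMBLE_RUNS",
    "LIMONENE_RUN_MEMBERS",
    "LIMONENE_COUNTS_10",
    "LIMONENE_COUNTS_250",
    "LIMONENE_STAB",
    "limonene_run_assignments",
]

QUERY = "d-Limonene"
GRID_WIDTH = 5
GRID_HEIGHT = 5
N_UNITS = GRID_WIDTH * GRID_HEIGHT  # 25 possible clusters
ENSEMBLE_RUNS = 250

#: Runs (1-10) in which each solvent shared d-limonene's cluster.
LIMONENE_RUN_MEMBERS: dict[str, frozenset[int]] = {
    "cis-Decalin": frozenset({1, 3, 6, 7, 8, 9}),
    "alpha-Pinene": frozenset({1, 3, 5, 6, 9}),
    "Dihexyl ether": frozenset({1, 3, 5, 7, 8}),
    "Butylcyclohexane": frozenset({2, 3, 6, 7}),
    "Undecane": frozenset({1, 4, 7}),
    "1-Decene": frozenset({2, 4, 5}),
    "Tridecane": frozenset({1, 7, 8}),
    "Propylcyclohexane": frozenset({2, 3}),
    "Tributylamine": frozenset({2, 3}),
    "1-Tetradecene": frozenset({1, 7}),
    "Pentadecane": frozenset({1, 7}),
    "Hexadecane": frozenset({1, 7}),
    "Tetradecane": frozenset({1, 7}),
    "Orange terpene": frozenset({1}),
    "o-Diethylbenzene": frozenset({9}),
    "1,2,4-Trimethylbenzene": frozenset({3}),
    "Dodecane": frozenset({1}),
    "Decane": frozenset({4}),
    "Varsol 60": frozenset({4}),
    "p-Diethylbenzene": frozenset({10}),
    "1,3-Dimethylcyclohexane": frozenset({10}),
}

#: Candidate-list neighbour counts after the first 10 runs.
LIMONENE_COUNTS_10: dict[str, int] = {
    "alpha-Pinene": 5,
    "Butylcyclohexane": 4,
    "cis-Decalin": 6,
    "Propylcyclohexane": 2,
    "Orange terpene": 1,
    "Tributylamine": 2,
    "Dihexyl ether": 5,
    "o-Diethylbenzene": 1,
    "Isopropylbenzene": 0,
    "1-Decene": 3,
    "Undecane": 3,
    "Ethylbenzene": 0,
    "1-Tetradecene": 2,
    "Pentadecane": 2,
    "Tridecane": 3,
    "Shellsol A100": 0,
    "Hexadecane": 2,
    "1,2,4-Trimethylbenzene": 1,
    "Dodecane": 1,
    "Tetradecane": 2,
}

#: Candidate-list neighbour counts after all 250 runs.
LIMONENE_COUNTS_250: dict[str, int] = {
    "alpha-Pinene": 90,
    "Butylcyclohexane": 78,
    "cis-Decalin": 74,
    "Propylcyclohexane": 67,
    "Orange terpene": 53,
    "Tributylamine": 51,
    "Dihexyl ether": 49,
    "o-Diethylbenzene": 48,
    "Isopropylbenzene": 47,
    "1-Decene": 39,
    "Undecane": 39,
    "Ethylbenzene": 34,
    "1-Tetradecene": 28,
    "Pentadecane": 24,
    "Tridecane": 23,
    "Shellsol A100": 22,
    "Hexadecane": 21,
    "1,2,4-Trimethylbenzene": 21,
    "Dodecane": 20,
    "Tetradecane": 20,
}

#: Published STAB values (counts / 250, printed at two decimals).
LIMONENE_STAB: dict[str, float] = {
    "alpha-Pinene": 0.36,
    "Butylcyclohexane": 0.31,
    "cis-Decalin": 0.30,
    "Propylcyclohexane": 0.27,
    "Orange terpene": 0.21,
    "Tributylamine": 0.20,
    "Dihexyl ether": 0.20,
    "o-Diethylbenzene": 0.19,
    "Isopropylbenzene": 0.19,
    "1-Decene": 0.16,
    "Undecane": 0.16,
    "Ethylbenzene": 0.14,
    "1-Tetradecene": 0.11,
    "Pentadecane": 0.10,
    "Tridecane": 0.09,
    "Shellsol A100": 0.09,
    "Hexadecane": 0.08,
    "1,2,4-Trimethylbenzene": 0.08,
    "Dodecane": 0.08,
    "Tetradecane": 0.08,
}


def limonene_run_assignments() -> list[ClusterAssignment]:
    """The first 10 runs as cluster assignments.

    Only the membership of d-limonene's own cluster is recorded in the
    source, so the query sits on neuron 0 together with that run's members
    and every other solvent is parked on the opposite grid corner.
    """
    names = [QUERY] + sorted(LIMONENE_RUN_MEMBERS)
    far_corner = N_UNITS - 1
    assignments = []
    for run in range(1, 11):
        neurons = [0] + [
            0 if run in LIMONENE_RUN_MEMBERS[name] else far_corner
            for name in names[1:]
        ]
        assignments.append(
            ClusterAssignment(
                names=names,
                neurons=neurons,
                width=GRID_WIDTH,
                height=GRID_HEIGHT,
                run_id=run - 1,
            )
        )
    return assignments
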