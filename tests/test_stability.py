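"""Stability statistics: NEIGH, STAB, significance band, candidates, RSD."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sussol.errors import MissingDataError
from sussol.examples import (
    ENSEMBLE_RUNS,
    LIMONENE_COUNTS_250,
    LIMONENE_STAB,
    N_UNITS,
    QUERY,
    limonene_run_assignments,
)
from sussol.som import ClusterAssignment
from sussol.stability import (
    accumulate,
    candidate_rsd,
    candidates_for,
    neigh,
    significance_band,
)
from sussol.table import SolventRecord, SolventTable


def _assignment(neurons, width=3, height=3, run_id=0):
    names = [f"s{i}" for i in range(len(neurons))]
    return ClusterAssignment(names=names, neurons=neurons, width=width,
                             height=height, run_id=run_id)


class TestNeigh:
    def test_same_neuron_radius_zero(self):
        a = _assignment([4, 4])
        assert neigh(a, "s0", "s1", r=0) == 1

    def test_adjacent_neurons_radius_zero(self):
        a = _assignment([4, 5])  # horizontally adjacent on a 3x3 grid
        assert neigh(a, "s0", "s1", r=0) == 0

    def test_diagonal_neighbors_at_radius_one(self):
        a = _assignment([0, 4])  # (0,0) and (1,1): diagonal
        assert neigh(a, "s0", "s1", r=1) == 1

    def test_radius_at_grid_diameter_always_one(self):
        a = _assignment([0, 8])  # opposite corners of the 3x3 grid
        assert neigh(a, "s0", "s1", r=2) == 1

    def test_unknown_solvent_rejected(self):
        with pytest.raises(KeyError):
            neigh(_assignment([0, 0]), "s0", "ghost", r=0)


class TestAccumulate:
    def test_pair_together_90_of_250_runs(self):
        runs = [
            _assignment([0, 0] if b < 90 else [0, 1], run_id=b) for b in range(250)
        ]
        counts, stab = accumulate(runs, r=0)
        assert counts.count("s0", "s1") == 90
        assert stab.value("s0", "s1") == pytest.approx(0.36)

    def test_never_and_always_together(self):
        never = [_assignment([0, 1], run_id=b) for b in range(5)]
        always = [_assignment([2, 2], run_id=b) for b in range(5)]
        assert accumulate(never)[1].value("s0", "s1") == 0.0
        assert accumulate(always)[1].value("s0", "s1") == 1.0

    def test_stab_matrix_invariants(self, blob_ensemble):
        _, _, _, assignments = blob_ensemble
        counts, stab = accumulate(assignments, r=0)
        assert np.array_equal(stab.stab, stab.stab.T)
        assert (stab.stab >= 0).all() and (stab.stab <= 1).all()
        np.testing.assert_allclose(np.diag(stab.stab), 1.0)
        np.testing.assert_allclose(np.diag(counts.counts), counts.B)

    def test_inconsistent_solvent_sets_rejected(self):
        a = _assignment([0, 0])
        b = ClusterAssignment(names=["x", "y"], neurons=[0, 0], width=3, height=3)
        with pytest.raises(ValueError, match="same solvent set"):
            accumulate([a, b])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        data=st.integers(min_value=4, max_value=6).flatmap(
            lambda n: st.lists(
                st.lists(st.integers(min_value=0, max_value=8), min_size=n, max_size=n),
                min_size=1,
                max_size=5,
            )
        ),
        r=st.integers(min_value=0, max_value=2),
    )
    def test_counts_match_brute_force_enumeration(self, data, r):
        """Vectorized accumulation equals explicit pairwise NEIGH sums."""
        runs = [_assignment(neurons, run_id=b) for b, neurons in enumerate(data)]
        counts, stab = accumulate(runs, r=r)
        n = len(data[0])
        for i, j in itertools.combinations(range(n), 2):
            brute = sum(neigh(a, f"s{i}", f"s{j}", r=r) for a in runs)
            assert counts.count(f"s{i}", f"s{j}") == brute
            assert stab.value(f"s{i}", f"s{j}") == pytest.approx(brute / len(runs))


class TestSignificanceBand:
    def test_published_band_250_runs_25_neurons(self):
        band = significance_band(B=250, U=25, r=0, alpha=0.05)
        assert band.display() == (3.9, 16.1)
        assert band.expected == pytest.approx(10.0)

    def test_band_1000_runs_100_neurons(self):
        band = significance_band(B=1000, U=100, r=0, alpha=0.05)
        assert band.display() == (3.8, 16.2)

    def test_nu_is_one_at_radius_zero(self):
        assert significance_band(B=100, U=25, r=0).nu == 1

    def test_nu_grows_as_square_and_clamps_to_grid(self):
        assert significance_band(B=1000, U=100, r=1).nu == 9
        assert significance_band(B=1000, U=4, r=3).nu == 4  # (2r+1)^2 clamped

    def test_validity_requires_ten_runs_per_neuron(self):
        assert not significance_band(B=50, U=25, r=0).valid
        assert not significance_band(B=250, U=25, r=0).valid  # Bp = 10, not > 10
        assert significance_band(B=500, U=25, r=0).valid

    def test_band_symmetric_about_expectation(self):
        band = significance_band(B=777, U=31, r=0, alpha=0.01)
        assert band.lower + band.upper == pytest.approx(2 * band.expected)

    def test_band_widens_with_more_runs_at_fixed_p(self):
        widths = [
            significance_band(B=B, U=25, r=0).upper - significance_band(B=B, U=25, r=0).lower
            for B in (100, 400, 1600)
        ]
        assert widths[0] < widths[1] < widths[2]

    def test_degenerate_band_at_full_coverage(self):
        band = significance_band(B=100, U=9, r=4)
        assert band.nu == 9
        assert band.lower == band.upper == band.expected == 100


class TestCandidates:
    def test_published_counts_all_significant(self):
        """Every count in the 250-run candidate table exceeds the band."""
        band = significance_band(B=ENSEMBLE_RUNS, U=N_UNITS, r=0, alpha=0.05)
        names = [QUERY] + list(LIMONENE_COUNTS_250)
        n = len(names)
        counts = np.zeros((n, n), dtype=int)
        for k, c in enumerate(LIMONENE_COUNTS_250.values(), start=1):
            counts[0, k] = counts[k, 0] = c
        np.fill_diagonal(counts, ENSEMBLE_RUNS)
        from sussol.stability import NeighborhoodCounts

        nc = NeighborhoodCounts(names=names, counts=counts, B=ENSEMBLE_RUNS,
                                n_units=N_UNITS, r=0)
        result = candidates_for(QUERY, nc, band, sort="count")
        assert len(result) == 20
        assert set(result.names) == set(LIMONENE_COUNTS_250)
        for _, row in result.frame.iterrows():
            assert row["stab"] == pytest.approx(
                LIMONENE_STAB[row["candidate"]], abs=0.005
            )

    def test_all_zero_counts_yield_empty_list(self):
        runs = [_assignment([0, 1, 2], run_id=b) for b in range(10)]
        counts, _ = accumulate(runs)
        band = significance_band(B=10, U=9, r=0)
        assert len(candidates_for("s0", counts, band)) == 0

    def test_query_never_in_its_own_list(self):
        runs = [_assignment([0, 0, 0], run_id=b) for b in range(10)]
        counts, _ = accumulate(runs)
        band = significance_band(B=10, U=9, r=0)
        result = candidates_for("s0", counts, band)
        assert "s0" not in result.names

    def test_absent_query_rejected(self):
        runs = [_assignment([0, 0], run_id=0)]
        counts, _ = accumulate(runs)
        band = significance_band(B=1, U=9, r=0)
        with pytest.raises(KeyError):
            candidates_for("ghost", counts, band)


class TestCandidateRSD:
    def _setup(self, values):
        runs = [_assignment([0] * (len(values) + 1), run_id=b) for b in range(10)]
        counts, _ = accumulate(runs)
        band = significance_band(B=10, U=9, r=0)
        result = candidates_for("s0", counts, band)
        recs = [SolventRecord("s0", properties={"Density": 1.0})]
        recs += [
            SolventRecord(f"s{i + 1}", properties={"Density": v})
            for i, v in enumerate(values)
        ]
        return result, SolventTable(recs)

    def test_identical_values_have_zero_rsd(self):
        result, table = self._setup([2.0, 2.0, 2.0])
        assert candidate_rsd(result, table, "Density") == 0.0

    def test_two_values_sample_sd(self):
        result, table = self._setup([1.0, 3.0])
        # sd = sqrt(2), mean = 2 -> 70.7%
        assert candidate_rsd(result, table, "Density") == pytest.approx(70.7, abs=0.05)

    def test_single_candidate_is_zero_by_convention(self):
        result, table = self._setup([5.0])
        assert candidate_rsd(result, table, "Density") == 0.0

    def test_zero_mean_is_undefined(self):
        result, table = self._setup([-1.0, 1.0])
        assert math.isnan(candidate_rsd(result, table, "Density"))

    def test_property_missing_everywhere_is_an_error(self):
        result, table = self._setup([1.0, 2.0])
        with pytest.raises(MissingDataError):
            candidate_rsd(result, table, "Viscosity")


def test_blob_pairs_separate_across_the_band(blob_ensemble):
    """Within-family counts sit above, cross-family counts below the band."""
    _, labels, _, assignments = blob_ensemble
    counts, _ = accumulate(assignments, r=0)
    band = significance_band(B=len(assignments), U=3, r=0, alpha=0.05)
    n = len(labels)
    for i, j in itertools.combinations(range(n), 2):
        c = counts.counts[i, j]
        if labels[i] == labels[j]:
            assert c > band.upper
        else:
            assert c < band.lower


def test_worked_example_replay():
    """The transcribed 10-run record accumulates to its printed counts."""
    counts, _ = accumulate(limonene_run_assignments(), r=0)
    assert counts.count(QUERY, "cis-Decalin") == 6
    assert counts.count(QUERY, "alpha-Pinene") == 5
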