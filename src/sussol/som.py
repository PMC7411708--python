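"""Kohonen Self-Organizing Map clustering of the solvent feature space.

The map is a rectangular, non-toroidal grid of ``width x height`` neurons,
each holding a prototype vector in feature space.  Online training repeats:
draw a random input, find its best-matching unit (BMU, nearest prototype by
Euclidean distance), and pull every prototype in the BMU's grid neighbourhood
towards the input by ``y <- y + gamma * (x - y)``, while the learning rate
``gamma`` and the neighbourhood radius decay linearly over the presentation
budget.  After training, each solvent is assigned to its BMU; solvents that
share a neuron form a cluster.

Because the trained map depends on the random initialization and presentation
order, cluster membership varies between runs; :func:`run_ensemble` trains B
independent maps (seeds ``base_seed + b``) so that the stability statistics in
:mod:`sussol.stability` can separate meaningful from accidental co-clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_random_state

from .table import FeatureMatrix

__all__ = ["KohonenSOM", "ClusterAssignment", "train_som", "assign", "run_ensemble"]


@dataclass
class ClusterAssignment:
    """Solvent -> neuron partition from one trained map."""

    names: list[str]
    neurons: np.ndarray
    width: int
    height: int
    run_id: int = 0
    seed: Optional[int] = None
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.neurons = np.asarray(self.neurons, dtype=int)
        if len(self.names) != len(self.neurons):
            raise ValueError("one neuron index per solvent is required")
        n_units = self.width * self.height
        if len(self.neurons) and not (
            (self.neurons >= 0).all() and (self.neurons < n_units).all()
        ):
            raise ValueError(f"neuron indices must lie in [0, {n_units})")
        self._index = {name: i for i, name in enumerate(self.names)}

    @property
    def n_units(self) -> int:
        return self.width * self.height

    def neuron_of(self, name: str) -> int:
        try:
            return int(self.neurons[self._index[name]])
        except KeyError:
            raise KeyError(f"solvent {name!r} not in this assignment") from None

    def position_of(self, name: str) -> tuple[int, int]:
        """(row, col) grid coordinates of the solvent's neuron."""
        u = self.neuron_of(name)
        return divmod(u, self.width)

    @property
    def mapping(self) -> dict[str, int]:
        return {name: int(u) for name, u in zip(self.names, self.neurons)}


class KohonenSOM(ClusterMixin, BaseEstimator):
    """Self-organizing map with online training and a bubble neighbourhood.

    Parameters
    ----------
    width, height : int
        Grid dimensions; ``width * height`` is the number of possible
        clusters.
    learning_rate : float
        Initial learning rate ``gamma`` in (0, 1].  The degenerate value 0
        is accepted for testing and leaves the map at its initialization.
    presentations : int or None
        Total number of input presentations; ``None`` uses ``500 * n``.
    neighborhood : {"bubble", "gaussian"}
        ``bubble`` updates every prototype within the (Chebyshev) radius by
        the full ``gamma``; ``gaussian`` weights updates by grid distance.
    initial_radius : float or None
        Starting neighbourhood radius in grid units; ``None`` uses
        ``max(width, height) / 2``.  Both the radius and the learning rate
        decay linearly to their floors over the presentation budget.
    final_learning_rate : float
        Learning-rate floor (capped at ``learning_rate`` so a zero initial
        rate stays zero).
    initial_weights : ndarray of shape (width * height, n_features), optional
        Explicit starting prototypes (warm start / reproducible tests);
        ``None`` draws them uniformly inside the per-column data range.
    random_state : int, RandomState or None
        Seeds initialization and presentation order; training is
        deterministic given a seed.

    Attributes
    ----------
    weights_ : ndarray of shape (width * height, n_features)
        Trained prototype vectors, one per neuron.
    grid_positions_ : ndarray of shape (width * height, 2)
        (row, col) coordinates of each neuron.
    labels_ : ndarray of shape (n_samples,)
        BMU index of each training sample.
    """

    def __init__(
        self,
        width: int = 5,
        height: int = 5,
        learning_rate: float = 0.5,
        presentations: Optional[int] = None,
        neighborhood: str = "bubble",
        initial_radius: Optional[float] = None,
        final_learning_rate: float = 0.01,
        initial_weights=None,
        random_state=None,
    ):
        self.width = width
        self.height = height
        self.learning_rate = learning_rate
        self.presentations = presentations
        self.neighborhood = neighborhood
        self.initial_radius = initial_radius
        self.final_learning_rate = final_learning_rate
        self.initial_weights = initial_weights
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X, dtype=float, ensure_min_samples=1)
        if self.width < 1 or self.height < 1:
            raise ValueError("grid dimensions must be positive")
        if not 0 <= self.learning_rate <= 1:
            raise ValueError("learning_rate must lie in [0, 1]")
        if self.neighborhood not in ("bubble", "gaussian"):
            raise ValueError(f"unknown neighborhood {self.neighborhood!r}")
        rng = check_random_state(self.random_state)
        n, d = X.shape
        n_units = self.width * self.height
        T = self.presentations if self.presentations is not None else 500 * n
        gamma0 = float(self.learning_rate)
        gamma_floor = min(float(self.final_learning_rate), gamma0)
        r0 = (
            float(self.initial_radius)
            if self.initial_radius is not None
            else max(self.width, self.height) / 2.0
        )

        if self.initial_weights is not None:
            W = np.array(self.initial_weights, dtype=float)
            if W.shape != (n_units, d):
                raise ValueError(
                    f"initial_weights must have shape ({n_units}, {d}), got {W.shape}"
                )
        else:
            # Prototypes start uniformly inside the per-column data range, so
            # they stay inside the data's bounding box throughout training.
            lo, hi = X.min(axis=0), X.max(axis=0)
            W = rng.uniform(size=(n_units, d)) * (hi - lo) + lo
        rows, cols = np.divmod(np.arange(n_units), self.width)

        for t in range(T):
            x = X[rng.randint(n)]
            diff = W - x
            bmu = int(np.argmin(np.einsum("ij,ij->i", diff, diff)))
            frac = t / T
            gamma = gamma0 + (gamma_floor - gamma0) * frac
            radius = r0 * (1.0 - frac)
            cheb = np.maximum(np.abs(rows - rows[bmu]), np.abs(cols - cols[bmu]))
            if self.neighborhood == "bubble":
                mask = cheb <= radius
                W[mask] += gamma * (x - W[mask])
            else:
                h = np.exp(-(cheb.astype(float) ** 2) / (2.0 * max(radius, 1e-9) ** 2))
                W += (gamma * h)[:, None] * (x - W)

        self.n_features_in_ = d
        self.weights_ = W
        self.grid_positions_ = np.column_stack([rows, cols])
        self.labels_ = self.predict(X)
        return self

    def predict(self, X) -> np.ndarray:
        """Best-matching unit per sample; ties break to the lowest index."""
        check_is_fitted(self, "weights_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.weights_.shape[1]:
            raise ValueError(
                f"feature dimensionality {X.shape[1]} does not match the "
                f"trained grid ({self.weights_.shape[1]})"
            )
        return np.argmin(cdist(X, self.weights_), axis=1)

    def assignment(
        self, features: FeatureMatrix, run_id: int = 0, seed: Optional[int] = None
    ) -> ClusterAssignment:
        """Named solvent -> neuron partition for a feature matrix."""
        return ClusterAssignment(
            names=list(features.rows),
            neurons=self.predict(features.values),
            width=self.width,
            height=self.height,
            run_id=run_id,
            seed=seed,
        )


# -- functional wrappers -----------------------------------------------------

def train_som(features: FeatureMatrix, **params) -> KohonenSOM:
    """Train a single map on a feature matrix (thin wrapper over the class)."""
    return KohonenSOM(**params).fit(features.values)


def assign(som: KohonenSOM, features: FeatureMatrix, run_id: int = 0) -> ClusterAssignment:
    return som.assignment(features, run_id=run_id)


def run_ensemble(
    features: FeatureMatrix,
    runs: int,
    base_seed: int = 0,
    **som_params,
) -> list[ClusterAssignment]:
    """Train ``runs`` independent maps with seeds ``base_seed + b``.

    Emits a warning when ``runs`` is below 10x the number of neurons, the
    validity condition of the Gaussian approximation used by the stability
    significance test (at radius 0).
    """
    if runs < 1:
        raise ValueError("at least one run is required")
    width = som_params.get("width", 5)
    height = som_params.get("height", 5)
    n_units = width * height
    if runs < 10 * n_units:
        warnings.warn(
            f"runs ({runs}) < 10 x neurons ({n_units}): the Gaussian "
            "approximation behind the significance band may be invalid",
            UserWarning,
            stacklevel=2,
        )
    assignments = []
    for b in range(runs):
        seed = base_seed + b
        som = KohonenSOM(random_state=seed, **som_params).fit(features.values)
        assignments.append(features_assignment(som, features, run_id=b, seed=seed))
    return assignments


def features_assignment(
    som: KohonenSOM, features: FeatureMatrix, run_id: int, seed: Optional[int]
) -> ClusterAssignment:
    return som.assignment(features, run_id=run_id, seed=seed)
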