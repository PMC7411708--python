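"""Metric multidimensional scaling of the solvent space.

The solvent table is reduced to 2D by minimizing the metric stress

    sigma(X) = sum_{i<j} (d_ij - dhat_ij(X))**2

where ``d_ij`` are the Euclidean distances between solvents in the scaled,
weighted feature space and ``dhat_ij`` the distances on the 2D map.  The
normalized stress reported to the user divides by ``sum_{i<j} d_ij**2`` so it
lies in [0, 1]; ``1 - sigma_n`` is the fitted proportion (a coefficient of
determination).  Minimization uses SMACOF-style iterative majorization
(Guttman transform) from a classical-scaling start, which makes the per-
iteration stress sequence monotone non-increasing.

The map axes are abstract; :func:`axis_correlations` reports Pearson
correlations between each dimension and the raw physical properties so users
can attach approximate meanings (volatility, polarity, ...) to them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_random_state

from .errors import MissingDataError
from .table import FeatureMatrix

__all__ = [
    "DistanceMatrix",
    "MetricMDS",
    "distance_matrix",
    "mds_embed",
    "normalized_stress",
    "axis_correlations",
]


@dataclass
class DistanceMatrix:
    """Square symmetric Euclidean distance matrix with a solvent-name index."""

    names: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.names)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix must be n x n")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if (self.values < 0).any():
            raise ValueError("distances must be non-negative")
        if not np.allclose(np.diag(self.values), 0):
            raise ValueError("distance matrix must have a zero diagonal")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.names, columns=self.names)

    def to_csv(self, path) -> None:
        """Log the pairwise distances to file for external processing."""
        self.to_frame().to_csv(path, float_format="%.12g")


def distance_matrix(features: FeatureMatrix) -> DistanceMatrix:
    """Pairwise Euclidean distances over the scaled, weighted feature columns."""
    if np.isnan(features.values).any():
        raise MissingDataError("feature matrix contains MISSING entries")
    return DistanceMatrix(
        names=list(features.rows),
        values=squareform(pdist(features.values, metric="euclidean")),
    )


def normalized_stress(coordinates: np.ndarray, distances: DistanceMatrix) -> tuple[float, float]:
    """Normalized stress sigma_n and fit = 1 - sigma_n.

    ``sigma_n = sum_{i<j} (d_ij - dhat_ij)**2 / sum_{i<j} d_ij**2``.  An
    all-zero distance matrix has sigma_n = 0 by definition.
    """
    coordinates = np.asarray(coordinates, dtype=float)
    d = squareform(distances.values, checks=False)
    dhat = pdist(coordinates)
    denom = float(np.sum(d**2))
    if denom == 0:
        return 0.0, 1.0
    sigma_n = float(np.sum((d - dhat) ** 2) / denom)
    return sigma_n, 1.0 - sigma_n


def _classical_scaling(D: np.ndarray, n_components: int) -> tuple[np.ndarray, np.ndarray]:
    """Torgerson classical scaling; returns coordinates and all eigenvalues."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    top = eigval[:n_components]
    X = eigvec[:, :n_components] * np.sqrt(np.maximum(top, 0.0))
    return X, eigval


class MetricMDS(BaseEstimator):
    """Metric MDS by SMACOF majorization with classical-scaling start.

    Parameters
    ----------
    n_components : int
        Output dimensionality (2 for the solvent map).
    max_iter : int
        Majorization iteration cap.
    tol : float
        Stop when the relative decrease of raw stress per iteration falls
        below this value.
    init : {"classical", "random"}
        Starting configuration.  Classical (Torgerson) scaling is
        deterministic; random draws from the seeded generator.
    random_state : int or None
        Only used for ``init="random"``.

    Attributes
    ----------
    embedding_ : ndarray (n, n_components)
    stress_sequence_ : list of raw stress values, monotone non-increasing
    normalized_stress_ : sigma_n in [0, 1]
    fit_ : 1 - sigma_n
    variance_share_ : share of positive classical-scaling eigenvalue mass
        captured by the first ``n_components`` components (diagnostic)
    """

    def __init__(
        self,
        n_components: int = 2,
        max_iter: int = 300,
        tol: float = 1e-10,
        init: str = "classical",
        random_state=None,
    ):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.init = init
        self.random_state = random_state

    def fit(self, distances, names: Optional[Sequence[str]] = None):
        if not isinstance(distances, DistanceMatrix):
            arr = np.asarray(distances, dtype=float)
            distances = DistanceMatrix(
                names=list(names) if names is not None else [str(i) for i in range(len(arr))],
                values=arr,
            )
        D = distances.values
        n = D.shape[0]
        self.names_ = list(distances.names)
        if n == 1:
            self.embedding_ = np.zeros((1, self.n_components))
            self.stress_sequence_ = [0.0]
            self.n_iter_ = 0
            self.variance_share_ = 1.0
            self.normalized_stress_, self.fit_ = 0.0, 1.0
            return self

        X0, eigval = _classical_scaling(D, self.n_components)
        pos = np.maximum(eigval, 0.0)
        total = pos.sum()
        self.variance_share_ = float(pos[: self.n_components].sum() / total) if total > 0 else 1.0
        if self.init == "random":
            rng = check_random_state(self.random_state)
            X = rng.uniform(-1, 1, size=(n, self.n_components)) * max(D.max(), 1.0)
        elif self.init == "classical":
            X = X0
        else:
            raise ValueError(f"unknown init {self.init!r}")

        def raw_stress(coords):
            return float(np.sum((squareform(D, checks=False) - pdist(coords)) ** 2))

        stress = raw_stress(X)
        seq = [stress]
        for it in range(self.max_iter):
            dhat = squareform(pdist(X), checks=False)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(dhat > 0, D / np.where(dhat > 0, dhat, 1.0), 0.0)
            Bmat = -ratio
            np.fill_diagonal(Bmat, 0.0)
            np.fill_diagonal(Bmat, -Bmat.sum(axis=1))
            X = Bmat @ X / n  # Guttman transform
            new_stress = raw_stress(X)
            seq.append(new_stress)
            if stress > 0 and (stress - new_stress) / stress < self.tol:
                stress = new_stress
                break
            stress = new_stress
        self.embedding_ = X - X.mean(axis=0)
        self.stress_sequence_ = seq
        self.n_iter_ = len(seq) - 1
        self.normalized_stress_, self.fit_ = normalized_stress(self.embedding_, distances)
        return self

    def fit_transform(self, distances, names: Optional[Sequence[str]] = None) -> np.ndarray:
        return self.fit(distances, names=names).embedding_

    def coordinates_frame(self) -> pd.DataFrame:
        cols = [f"D{k + 1}" for k in range(self.n_components)]
        return pd.DataFrame(self.embedding_, index=self.names_, columns=cols)


def mds_embed(
    distances: DistanceMatrix,
    seed: Optional[int] = None,
    max_iter: int = 300,
    tol: float = 1e-10,
    init: str = "classical",
) -> MetricMDS:
    """Fit a 2D metric MDS embedding (thin wrapper over :class:`MetricMDS`)."""
    return MetricMDS(
        n_components=2, max_iter=max_iter, tol=tol, init=init, random_state=seed
    ).fit(distances)


def axis_correlations(
    model: MetricMDS, table, properties: Sequence[str]
) -> pd.DataFrame:
    """Pearson correlation between each map dimension and each raw property.

    Pairwise-complete: solvents missing the property are dropped for that
    property.  Correlations needing fewer than 3 points or a zero-variance
    input are reported as NaN.
    """
    rows = []
    name_pos = {n: i for i, n in enumerate(model.names_)}
    for prop in properties:
        vals, idx = [], []
        for name in model.names_:
            v = table.get(name).get(prop)
            if not math.isnan(v):
                vals.append(v)
                idx.append(name_pos[name])
        for k in range(model.embedding_.shape[1]):
            r = math.nan
            if len(vals) >= 3:
                coords = model.embedding_[idx, k]
                if np.std(vals) > 0 and np.std(coords) > 0:
                    r = float(pearsonr(coords, vals)[0])
            rows.append({"property": prop, "dimension": f"D{k + 1}", "r": r, "n": len(vals)})
    return pd.DataFrame(rows)
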