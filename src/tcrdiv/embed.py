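"""Classical (Torgerson) multidimensional scaling of a distance matrix.

Double-centre ``B = -1/2 J D^2 J``, eigendecompose, and scale the top
eigenvectors by the square roots of their (non-negative) eigenvalues.  For an
exactly Euclidean distance matrix the embedding reproduces the input distances
up to numerical tolerance; coordinates are defined only up to rotation and
reflection.  Negative eigenvalues (which arise when down-sampling noise makes
the matrix slightly non-Euclidean) are clipped, with a warning, following the
usual classical-scaling convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .diversity import DistanceMatrix

__all__ = ["Embedding", "ClassicalMDS", "classical_mds", "plot_embedding", "GROUP_COLORS"]

#: group colour scheme used throughout the figures
GROUP_COLORS = {"MEsa": "red", "MEmm": "gold", "MS": "green", "HC": "blue"}


@dataclass
class Embedding:
    sample_ids: list[str]
    coordinates: np.ndarray  # (n_samples, k), columns ordered by eigenvalue
    eigenvalues: np.ndarray  # full spectrum of the doubly-centred matrix

    def to_frame(self) -> pd.DataFrame:
        cols = [f"dim{i + 1}" for i in range(self.coordinates.shape[1])]
        df = pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)
        df.index.name = "sample_id"
        return df


class ClassicalMDS(TransformerMixin, BaseEstimator):
    """Torgerson scaling as a (fit_transform-style) sklearn transformer.

    Parameters
    ----------
    n_components : int
        Number of embedding dimensions requested.  Dimensions whose
        eigenvalue is not positive are suppressed, so the output may have
        fewer columns.

    Attributes
    ----------
    eigenvalues_ : full spectrum, descending.
    embedding_ : coordinates from ``fit``.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def fit_transform(self, X, y=None):
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        D = np.asarray(X, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(D, D.T, atol=1e-8):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diagonal(D) < -1e-12) or np.any(np.abs(np.diagonal(D)) > 1e-8):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(D < 0):
            raise ValueError("distances must be non-negative")
        n = D.shape[0]
        J = np.eye(n) - np.full((n, n), 1.0 / n)
        B = -0.5 * J @ (D**2) @ J
        evals, evecs = np.linalg.eigh((B + B.T) / 2)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        k = min(self.n_components, n)
        pos = evals[:k] > 1e-12
        if np.any(evals < -1e-8 * max(1.0, float(abs(evals[0])))):
            warnings.warn(
                "distance matrix is not exactly Euclidean; negative eigenvalues clipped",
                stacklevel=2,
            )
        coords = evecs[:, :k][:, pos] * np.sqrt(evals[:k][pos])
        self.eigenvalues_ = evals
        self.embedding_ = coords
        self.n_features_in_ = n
        return coords


def classical_mds(D, k: int = 2) -> Embedding:
    """Embed a :class:`~tcrdiv.diversity.DistanceMatrix` (or square array)."""
    if isinstance(D, DistanceMatrix):
        ids, values = D.sample_ids, D.values
    else:
        values = np.asarray(D, dtype=float)
        ids = [f"s{i}" for i in range(values.shape[0])]
    mds = ClassicalMDS(n_components=k)
    coords = mds.fit_transform(values)
    return Embedding(sample_ids=list(ids), coordinates=coords, eigenvalues=mds.eigenvalues_)


def plot_embedding(embedding: Embedding, metadata, path, axes: tuple = (1, 2)):
    """Scatter an embedding coloured by group and write a figure file.

    ``metadata`` maps sample id to group (mapping or DataFrame with
    ``sample_id``/``group`` columns).  ``axes`` picks embedding dimensions
    (1-based); three axes give a 3-D scatter.  Samples with no group are drawn
    as "unknown" with a warning.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if embedding.coordinates.size == 0:
        raise ValueError("cannot plot an empty embedding")
    if isinstance(metadata, pd.DataFrame):
        group_of = dict(zip(metadata["sample_id"].astype(str), metadata["group"]))
    else:
        group_of = dict(metadata)
    if max(axes) > embedding.coordinates.shape[1]:
        raise ValueError("requested axis exceeds embedding dimensionality")

    groups = []
    for s in embedding.sample_ids:
        g = group_of.get(s)
        if g is None:
            warnings.warn(f"sample {s} has no group; plotted as 'unknown'", stacklevel=2)
            g = "unknown"
        groups.append(g)

    fig = plt.figure(figsize=(6, 5))
    three_d = len(axes) == 3
    ax = fig.add_subplot(111, projection="3d" if three_d else None)
    cols = [a - 1 for a in axes]
    for g in dict.fromkeys(groups):
        sel = [i for i, gg in enumerate(groups) if gg == g]
        pts = embedding.coordinates[np.ix_(sel, cols)]
        ax.scatter(*pts.T, label=g, color=GROUP_COLORS.get(g, "grey"), s=25)
    ax.set_xlabel(f"dimension {axes[0]}")
    ax.set_ylabel(f"dimension {axes[1]}")
    if three_d:
        ax.set_zlabel(f"dimension {axes[2]}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
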