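"""viSNE-style 2D projection of the physical phenotype space.

Phenotype vectors are standardized and projected onto two axes with
t-distributed stochastic neighbor embedding (all pairwise Euclidean
distances in the 21-dimensional space), giving a biaxial scatter plot
that preserves local neighborhood structure.  Recoloring the projection
by one parameter per category (size, deformability, morphology,
kinetics) visualises how the phenotype changes across populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.manifold import TSNE

from .classify import PhenotypeStandardizer
from .errors import DataError
from .registry import FEATURE_NAMES, parameter_info

DEFAULT_PERPLEXITY = 30
DEFAULT_ITERATIONS = 1000


@dataclass
class Embedding2D:
    """2D stochastic-neighbor coordinates for a set of cells."""

    coords: np.ndarray                  # (n, 2), arbitrary units
    cell_ids: np.ndarray
    params_used: dict

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise DataError("coords must be (n, 2)")
        if not np.all(np.isfinite(self.coords)):
            raise DataError("embedding produced non-finite coordinates")
        if len(self.cell_ids) != len(self.coords):
            raise DataError("one coordinate pair per cell required")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": self.cell_ids,
                             "tsne_1": self.coords[:, 0],
                             "tsne_2": self.coords[:, 1]})


class PhenotypeEmbedding(BaseEstimator):
    """t-SNE of standardized phenotype vectors, sklearn-style.

    Deterministic given random_state (single-threaded exact/Barnes-Hut
    run).  Fitted attributes: embedding_, scaler_.
    """

    def __init__(self, perplexity=DEFAULT_PERPLEXITY,
                 n_iter=DEFAULT_ITERATIONS, learning_rate="auto",
                 random_state=0):
        self.perplexity = perplexity
        self.n_iter = n_iter
        self.learning_rate = learning_rate
        self.random_state = random_state

    def fit_transform(self, X, y=None) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            cols = [c for c in FEATURE_NAMES if c in X.columns] or \
                list(X.columns)
            X = X[cols].to_numpy(float)
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if n < 3 * self.perplexity:
            raise DataError(
                f"{n} rows is too few for perplexity {self.perplexity}; "
                f"use perplexity <= {max(n // 3, 1)}")
        self.scaler_ = PhenotypeStandardizer().fit(X)
        tsne = TSNE(n_components=2, perplexity=self.perplexity,
                    max_iter=self.n_iter, learning_rate=self.learning_rate,
                    init="pca", metric="euclidean",
                    random_state=int(self.random_state) & 0x7FFFFFFF)
        self.embedding_ = tsne.fit_transform(self.scaler_.transform(X))
        return self.embedding_

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self


def embed(table: pd.DataFrame, perplexity: int = DEFAULT_PERPLEXITY,
          seed: int = 0, n_iter: int = DEFAULT_ITERATIONS) -> Embedding2D:
    """Embed a feature table (registry columns, optional cell_id) in 2D."""
    est = PhenotypeEmbedding(perplexity=perplexity, n_iter=n_iter,
                             random_state=seed)
    coords = est.fit_transform(table)
    if "cell_id" in getattr(table, "columns", []):
        ids = table["cell_id"].to_numpy()
    else:
        ids = np.arange(len(coords))
    return Embedding2D(coords=coords, cell_ids=ids,
                       params_used={"perplexity": perplexity,
                                    "iterations": n_iter, "seed": seed})


def recolor(embedding: Embedding2D, table: pd.DataFrame, parameter: str,
            out_path=None, cmap: str = "viridis", point_size: float = 8.0):
    """Scatter the 2D projection colored by one registry parameter.

    Pure presentation: returns the matplotlib figure (saved to out_path
    when given) and never mutates the data.  A constant column yields a
    single-color plot, not an error.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    info = parameter_info(parameter)   # raises for unknown names
    if parameter not in table.columns:
        raise DataError(f"table has no column {parameter!r}")
    values = table[parameter].to_numpy(float)
    if len(values) != len(embedding.coords):
        raise DataError("table and embedding row counts differ")
    fig, ax = plt.subplots(figsize=(5, 4.2))
    sc = ax.scatter(embedding.coords[:, 0], embedding.coords[:, 1],
                    c=values, s=point_size, cmap=cmap, linewidths=0)
    cb = fig.colorbar(sc, ax=ax)
    cb.set_label(f"{parameter} [{info.unit}]")
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    ax.set_title(f"{info.category}: {parameter}")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
    return fig
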