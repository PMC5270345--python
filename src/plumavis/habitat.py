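"""Vegetation-cover habitat axis from per-taxon environmental means.

The habitat table holds per-taxon means of three environmental variables
(evapotranspiration, net primary productivity, potential vegetation in the
source study), plus mean latitude, annual rainfall and temperature.  A
principal component analysis on the covariance matrix (centered, not
scaled) of the three environmental variables yields the vegetation axis;
PC1 is oriented so that higher scores mean denser vegetation (positive
loading on the potential-vegetation variable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ENV_COLS = ("env1", "env2", "env3")


@dataclass
class VegetationPC:
    scores: pd.Series            # PC1 score per taxon
    loadings: pd.DataFrame       # env variable x component
    explained: np.ndarray        # proportion of variance per component
    mean: np.ndarray             # column means used for centering

    @property
    def pc1_explained(self) -> float:
        return float(self.explained[0])


def pca_covariance(
    habitat: pd.DataFrame,
    env_cols=ENV_COLS,
    orient_on: str = "env3",
    standardize: bool = False,
) -> VegetationPC:
    """Covariance-matrix PCA of the environmental columns.

    ``standardize=True`` switches to the correlation matrix for real data
    on wildly different scales; the default follows the covariance
    convention and expects comparable scales.
    """
    env_cols = list(env_cols)
    X = habitat[env_cols].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing environmental values in habitat table")
    if X.shape[0] < 3:
        raise ValueError("PCA requires at least 3 taxa")
    if not habitat.index.is_unique:
        raise ValueError("taxon_ids must be unique")
    mean = X.mean(axis=0)
    Xc = X - mean
    if standardize:
        sd = Xc.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("constant environmental column cannot be standardized")
        Xc = Xc / sd
    cov = np.cov(Xc, rowvar=False, ddof=1)
    total_var = np.trace(cov)
    if total_var <= 0:
        raise ValueError("environmental columns are constant; covariance has rank 0")
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    anchor = env_cols.index(orient_on)
    for j in range(evecs.shape[1]):
        pivot = evecs[anchor, j]
        if pivot == 0:
            pivot = evecs[np.argmax(np.abs(evecs[:, j])), j]
        if pivot < 0:
            evecs[:, j] = -evecs[:, j]
    scores = Xc @ evecs
    return VegetationPC(
        scores=pd.Series(scores[:, 0], index=habitat.index, name="vegetation_pc"),
        loadings=pd.DataFrame(
            evecs, index=env_cols,
            columns=[f"PC{i + 1}" for i in range(evecs.shape[1])],
        ),
        explained=evals / evals.sum(),
        mean=mean,
    )


def correlate(x, y) -> dict:
    """Pearson correlation between two per-taxon vectors: r, r^2, p, n."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D vectors")
    if x.size < 3:
        raise ValueError("correlation requires at least 3 taxa")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "r2": float(r**2), "p": float(p), "n": int(x.size)}


def read_habitat(path) -> pd.DataFrame:
    """Read a habitat table (delimited; taxon_id column becomes the index)."""
    df = pd.read_csv(path, sep=None, engine="python")
    return df.set_index("taxon_id")
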