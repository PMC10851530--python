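"""Principal component analysis of frequency matrices.

Breeds are observations, alleles (or pocket amino-acid motifs) are
variables.  The default decomposes the covariance matrix of the raw
frequencies; a correlation variant standardises columns first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import FrequencyMatrix


@dataclass
class PcaResult:
    """Scores per breed, loadings per variable, percent variance per PC."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    percent_variance: pd.Series

    @property
    def n_components(self) -> int:
        return len(self.percent_variance)


def pca_frequencies(
    fm: FrequencyMatrix | pd.DataFrame, matrix_type: str = "covariance"
) -> PcaResult:
    """Eigen-decomposition PCA of a breed-by-variable frequency matrix.

    Columns are centered (and scaled to unit variance for
    matrix_type='correlation'); components are ordered by decreasing
    eigenvalue and the percent variance is each eigenvalue's share of the
    total.  Sign convention: on every component the loading of largest
    magnitude is positive.  Constant input yields an empty result with a
    warning.
    """
    df = fm.df if isinstance(fm, FrequencyMatrix) else fm
    if len(df) < 2:
        raise ValueError("PCA requires >= 2 rows")
    x = df.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    if matrix_type == "correlation":
        sd = x.std(axis=0, ddof=1)
        keep = sd > 0
        x = x[:, keep] / sd[keep]
        cols = df.columns[keep]
    elif matrix_type == "covariance":
        cols = df.columns
    else:
        raise ValueError("matrix_type must be 'covariance' or 'correlation'")
    if not np.any(x):
        warnings.warn("matrix is constant: no variance to decompose")
        empty = pd.DataFrame(index=df.index)
        return PcaResult(empty, pd.DataFrame(index=cols),
                         pd.Series(dtype=float))
    # SVD of the centered matrix: eigenvalues of the covariance are s^2/(n-1)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    n = x.shape[0]
    eig = s ** 2 / (n - 1)
    keep = eig > 1e-12 * eig[0]
    eig, u, s, vt = eig[keep], u[:, keep], s[keep], vt[keep]
    loadings = vt.T
    # largest-magnitude loading positive on each component
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            u[:, j] *= -1
    scores = u * s
    names = [f"PC{i + 1}" for i in range(len(eig))]
    return PcaResult(
        scores=pd.DataFrame(scores, index=df.index, columns=names),
        loadings=pd.DataFrame(loadings, index=cols, columns=names),
        percent_variance=pd.Series(
            100.0 * eig / eig.sum(), index=names, name="percent_variance"
        ),
    )
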