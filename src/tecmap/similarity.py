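"""Tissue-tissue global expression similarity and hierarchical trees.

Pairwise Spearman correlation between tissue columns, transformed into the
distance 1 - rho and clustered agglomeratively (Ward's criterion or UPGMA
average linkage).  Ward is applied to the 1 - rho dissimilarity directly
via the classical Lance-Williams update, accepting that 1 - rho is not a
Euclidean metric — fidelity to the procedure over metric purity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .datatypes import ExpressionMatrix

LINKAGES = ("ward", "average")


def spearman_matrix(matrix: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    """Column-by-column Spearman correlation (average ranks on ties).

    Constant columns have undefined rank correlation; their entries are
    recorded as NaN with a warning.
    """
    data = matrix.data if isinstance(matrix, ExpressionMatrix) else matrix
    if data.shape[1] < 2 or data.shape[0] < 2:
        raise ValueError("need at least 2 columns and 2 genes")
    constant = data.columns[data.nunique(axis=0) <= 1]
    if len(constant):
        warnings.warn(f"constant column(s), correlations undefined: {list(constant)}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = spearmanr(data.to_numpy()).statistic
    if np.ndim(rho) == 0:  # scipy returns a scalar for exactly two columns
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    out = pd.DataFrame(rho, index=data.columns, columns=data.columns)
    np.fill_diagonal(out.values, 1.0)
    out.loc[constant, :] = np.nan
    out.loc[:, constant] = np.nan
    for c in constant:
        out.loc[c, c] = 1.0
    return out


@dataclass
class TissueTree:
    """Dendrogram over tissues: scipy linkage matrix + leaf ids."""

    linkage_matrix: np.ndarray
    ids: list[str]
    method: str

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def to_skbio(self) -> skbio.TreeNode:
        return skbio.TreeNode.from_linkage_matrix(self.linkage_matrix, self.ids)

    def to_newick(self, path) -> None:
        self.to_skbio().write(str(path), format="newick")


def tissue_tree(corr: pd.DataFrame, method: str = "ward") -> TissueTree:
    """Agglomerate tissues on the distance 1 - rho.

    Branch heights are the merge distances; missing correlations abort
    with the offending pairs listed.
    """
    if method not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    if not np.allclose(corr.values, corr.values.T, atol=1e-12, equal_nan=True):
        raise ValueError("correlation matrix is not symmetric")
    dist = 1.0 - corr.values
    np.fill_diagonal(dist, 0.0)
    if np.isnan(dist).any():
        pairs = [
            (corr.index[i], corr.columns[j])
            for i, j in zip(*np.where(np.isnan(dist)))
            if i < j
        ]
        raise ValueError(f"missing correlations for pairs: {pairs}")
    # guard against tiny negative values from float round-off
    dist = np.clip(dist, 0.0, None)
    condensed = squareform(dist, checks=False)
    z = linkage(condensed, method=method)
    return TissueTree(z, [str(c) for c in corr.columns], method)
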