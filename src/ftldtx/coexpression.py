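"""Regional co-expression network of a selected gene set.

Genes are nodes; two genes are connected when the Pearson correlation of
their regional expression profiles exceeds a threshold (default 0.3,
signed).  Nodal degree summarizes how connected each gene's regional
expression is to the rest of the selected set.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd


@dataclasses.dataclass
class CoexpressionGraph:
    r: pd.DataFrame           # gene × gene Pearson r
    theta: float
    adjacency: pd.DataFrame   # boolean, symmetric, zero diagonal
    degree: pd.Series

    def to_networkx(self) -> nx.Graph:
        g = nx.from_pandas_adjacency(self.adjacency.astype(int))
        for a, b in g.edges:
            g.edges[a, b]["r"] = float(self.r.loc[a, b])
        return g


def coexpression_matrix(expr: pd.DataFrame, genes: Sequence[str]) -> pd.DataFrame:
    """Gene × gene Pearson r over regions for the selected genes.

    Constant genes (undefined correlation) are dropped with a warning.
    """
    missing = [g for g in genes if g not in expr.columns]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing}")
    if len(expr) < 3:
        raise ValueError("need >= 3 regions")
    sub = expr[list(genes)]
    sd = sub.std(ddof=0)
    const = list(sd.index[sd == 0])
    if const:
        warnings.warn(f"dropping constant gene(s): {const}")
        sub = sub.drop(columns=const)
    r = sub.corr(method="pearson")
    np.fill_diagonal(r.to_numpy(), 1.0)
    return r


def binarize_and_degree(r: pd.DataFrame, theta: float = 0.3,
                        *, use_absolute: bool = False) -> CoexpressionGraph:
    """Threshold the correlation matrix and count surviving edges per gene.

    Edge iff r > theta strictly (|r| > theta with `use_absolute`), diagonal
    excluded; negative correlations never form edges in the default signed
    mode.
    """
    arr = r.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T, equal_nan=True):
        raise ValueError("correlation matrix must be square and symmetric")
    vals = np.abs(arr) if use_absolute else arr
    adj = vals > theta
    np.fill_diagonal(adj, False)
    adjacency = pd.DataFrame(adj, index=r.index, columns=r.columns)
    degree = adjacency.sum(axis=1).astype(int)
    degree.name = "degree"
    return CoexpressionGraph(r=r, theta=theta, adjacency=adjacency, degree=degree)
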