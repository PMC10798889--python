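"""Louvain robustness check for the NMF protein clusters.

Builds a weighted protein coexpression network (Pearson correlations over AD
samples, negative edges truncated to zero, zero diagonal), partitions it
with the Louvain algorithm at a configurable resolution and quantifies the
overlap with another protein partition via optimal one-to-one cluster
matching.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .exceptions import ContractError
from .io import SampleMetadata
from .normalize import NormalizedMatrix


@dataclasses.dataclass
class CoexpressionNetwork:
    proteins: tuple[str, ...]
    adjacency: np.ndarray  # symmetric, non-negative, zero diagonal
    correlation_type: str = "pearson"
    warnings: list[str] = dataclasses.field(default_factory=list)


def build_coexpression_network(
    norm: NormalizedMatrix | pd.DataFrame,
    proteins: Sequence[str],
    meta: SampleMetadata | None = None,
    ad_only: bool = True,
    absolute: bool = False,
) -> CoexpressionNetwork:
    """Pairwise Pearson coexpression over AD samples with truncated negatives.

    Negative correlations are set to zero by default (``absolute=True``
    keeps magnitudes instead); constant proteins get zero weights with a
    warning.
    """
    values = norm.values if isinstance(norm, NormalizedMatrix) else norm
    proteins = list(proteins)
    if len(proteins) < 3:
        raise ContractError("need at least 3 proteins")
    if ad_only:
        if meta is None:
            raise ContractError("metadata required to restrict to AD samples")
        groups = meta.groups()
        cols = [s for s in values.columns if groups.get(s) == "AD"]
    else:
        cols = list(values.columns)
    if len(cols) < 3:
        raise ContractError("need at least 3 samples")
    sub = values.loc[proteins, cols].dropna(axis=0, how="any")
    notes = []
    arr = sub.to_numpy()
    sd = arr.std(axis=1)
    constant = sd == 0
    if constant.any():
        for prot in sub.index[constant]:
            notes.append(f"constant protein {prot}: correlations set to 0")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(arr)
    corr[np.isnan(corr)] = 0.0
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    adj = np.abs(corr) if absolute else np.clip(corr, 0.0, None)
    np.fill_diagonal(adj, 0.0)
    return CoexpressionNetwork(
        proteins=tuple(sub.index), adjacency=adj, warnings=notes
    )


def louvain_communities(
    net: CoexpressionNetwork, resolution: float = 1.15, seed: int = 0
) -> tuple[pd.Series, float]:
    """Louvain partition of the weighted network and its modularity Q.

    Q uses the standard resolution-scaled quality function
    ``sum_c [e_c/m - gamma * (d_c / 2m)^2]`` on edge weights.
    """
    G = nx.Graph()
    G.add_nodes_from(net.proteins)
    rows, cols = np.nonzero(np.triu(net.adjacency, k=1))
    if len(rows) == 0:
        raise ContractError("network has no edges")
    for i, j in zip(rows, cols):
        G.add_edge(net.proteins[i], net.proteins[j], weight=float(net.adjacency[i, j]))
    communities = nx.community.louvain_communities(
        G, weight="weight", resolution=resolution, seed=seed
    )
    Q = nx.community.modularity(
        G, communities, weight="weight", resolution=resolution
    )
    labels = {}
    for idx, members in enumerate(communities, start=1):
        for node in members:
            labels[node] = idx
    series = pd.Series({p: labels[p] for p in net.proteins}, name="community")
    return series, float(Q)


def cluster_overlap(labels_a, labels_b) -> float:
    """Percent agreement under the best one-to-one matching of clusters.

    Builds the contingency table of the two partitions over the shared
    protein universe and solves the maximum-weight assignment exactly.
    """
    a = pd.Series(labels_a)
    b = pd.Series(labels_b)
    if not a.index.equals(b.index):
        common = a.index.intersection(b.index)
        if len(common) == 0 or len(common) != len(a) or len(common) != len(b):
            raise ContractError("partitions must cover the same protein universe")
        a, b = a.loc[common], b.loc[common]
    table = pd.crosstab(a, b).to_numpy()
    rows, cols = linear_sum_assignment(-table)
    matched = table[rows, cols].sum()
    return float(matched) / len(a) * 100.0
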