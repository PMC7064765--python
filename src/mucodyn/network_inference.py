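"""Rank-correlation co-occurrence network inference and graph summaries.

Pipeline: pairwise Spearman correlation of taxon abundance profiles across
samples, edge retention by |rho| and p-value thresholds, then eigenvector /
betweenness centrality, unweighted diameter and connected-component counts
on the retained graph.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AbundanceTable",
    "CorrelationResult",
    "InteractionMatrix",
    "NetworkSummary",
    "spearman_matrix",
    "threshold_network",
    "eigen_centrality",
    "betweenness_centrality",
    "diameter",
    "component_count",
    "summarize_network",
    "to_graph",
    "write_graphml",
    "write_edge_list",
]

RHO_THRESHOLD = 0.7
P_THRESHOLD = 0.001


@dataclass
class AbundanceTable:
    """Sample-by-taxon matrix of relative abundances in percent."""

    sample_ids: list[str]
    taxon_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n_s, n_t = len(self.sample_ids), len(self.taxon_ids)
        if self.values.shape != (n_s, n_t):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{n_s} samples x {n_t} taxa"
            )
        if len(set(self.sample_ids)) != n_s:
            raise ValueError("duplicate sample IDs")
        if len(set(self.taxon_ids)) != n_t:
            raise ValueError("duplicate taxon IDs")
        if np.any(self.values < 0):
            r, c = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative abundance at sample {self.sample_ids[r]!r}, "
                f"taxon {self.taxon_ids[c]!r}"
            )
        row_sums = self.values.sum(axis=1)
        if np.any(row_sums > 100.0 + 1e-6):
            bad = self.sample_ids[int(np.argmax(row_sums))]
            raise ValueError(f"sample {bad!r} sums to more than 100%")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.taxon_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AbundanceTable":
        return cls(
            sample_ids=[str(s) for s in df.index],
            taxon_ids=[str(t) for t in df.columns],
            values=df.to_numpy(dtype=float),
        )

    def subset_taxa(self, taxa: list[str]) -> "AbundanceTable":
        idx = [self.taxon_ids.index(t) for t in taxa]
        return AbundanceTable(
            sample_ids=list(self.sample_ids),
            taxon_ids=list(taxa),
            values=self.values[:, idx],
        )


@dataclass
class CorrelationResult:
    """Symmetric Spearman rho and p-value matrices over taxa.

    Pairs involving a taxon with constant abundance across samples have
    undefined correlation; those entries are NaN and never become edges.
    """

    taxon_ids: list[str]
    rho: np.ndarray
    pvalues: np.ndarray


@dataclass
class InteractionMatrix:
    """Thresholded correlation coefficients used as ODE coupling weights.

    Entries are either 0 (filtered) or a retained signed rho; symmetric
    with a zero diagonal.
    """

    taxon_ids: list[str]
    eta: np.ndarray

    def __post_init__(self) -> None:
        self.eta = np.asarray(self.eta, dtype=float)
        n = len(self.taxon_ids)
        if self.eta.shape != (n, n):
            raise ValueError(f"eta shape {self.eta.shape}, expected {(n, n)}")
        if not np.allclose(self.eta, self.eta.T):
            raise ValueError("eta must be symmetric")

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.eta, k=1)))


@dataclass
class NetworkSummary:
    """Per-node centralities and whole-graph statistics of a retained network."""

    taxon_ids: list[str]
    eigen: dict[str, float]
    betweenness: dict[str, float]
    diameter: int | None
    n_nodes: int
    n_edges: int
    n_components: int
    n_isolated: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "taxon": self.taxon_ids,
                "eigen_centrality": [self.eigen[t] for t in self.taxon_ids],
                "betweenness": [self.betweenness[t] for t in self.taxon_ids],
            }
        )


def spearman_matrix(table: AbundanceTable) -> CorrelationResult:
    """Pairwise Spearman correlations between taxa across samples.

    Ranks use average ranks for ties; p-values come from the
    t-approximation on ``n - 2`` degrees of freedom. Requires at least
    3 samples and 2 taxa. Taxa constant across samples yield NaN entries.
    """
    if table.n_samples < 3:
        raise ValueError(f"need >= 3 samples, got {table.n_samples}")
    if table.n_taxa < 2:
        raise ValueError(f"need >= 2 taxa, got {table.n_taxa}")
    n = table.n_taxa
    rho = np.eye(n)
    pval = np.zeros((n, n))
    constant = np.array([np.unique(col).size == 1 for col in table.values.T])
    for i in range(n):
        for j in range(i + 1, n):
            if constant[i] or constant[j]:
                r = p = np.nan
            else:
                r, p = stats.spearmanr(table.values[:, i], table.values[:, j])
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    rho[constant, constant] = np.nan
    pval[constant, constant] = np.nan
    return CorrelationResult(taxon_ids=list(table.taxon_ids), rho=rho, pvalues=pval)


def threshold_network(
    corr: CorrelationResult,
    rho_min: float = RHO_THRESHOLD,
    p_max: float = P_THRESHOLD,
) -> InteractionMatrix:
    """Retain edges with ``|rho| >= rho_min`` and ``p <= p_max``.

    All other entries (including NaNs from constant taxa) are set to 0;
    the diagonal is forced to 0. Negative correlations that pass the
    absolute threshold are retained with their sign.
    """
    rho = np.array(corr.rho, dtype=float)
    p = np.array(corr.pvalues, dtype=float)
    with np.errstate(invalid="ignore"):
        keep = (np.abs(rho) >= rho_min) & (p <= p_max)
    keep &= np.isfinite(rho) & np.isfinite(p)
    eta = np.where(keep, rho, 0.0)
    np.fill_diagonal(eta, 0.0)
    eta = (eta + eta.T) / 2.0  # guard symmetry against float asymmetries
    return InteractionMatrix(taxon_ids=list(corr.taxon_ids), eta=eta)


def to_graph(matrix: InteractionMatrix, include_isolated: bool = True) -> nx.Graph:
    """Undirected weighted graph over the interaction matrix.

    Edge attribute ``weight`` is the signed rho; ``abs_weight`` its
    magnitude (used for eigenvector centrality).
    """
    g = nx.Graph()
    if include_isolated:
        g.add_nodes_from(matrix.taxon_ids)
    n = len(matrix.taxon_ids)
    for i in range(n):
        for j in range(i + 1, n):
            w = matrix.eta[i, j]
            if w != 0:
                g.add_edge(
                    matrix.taxon_ids[i],
                    matrix.taxon_ids[j],
                    weight=float(w),
                    abs_weight=abs(float(w)),
                )
    return g


def eigen_centrality(matrix: InteractionMatrix) -> dict[str, float]:
    """Eigenvector centrality on the absolute-weight adjacency.

    Scores are normalized so the maximum is 1; taxa with no retained
    edges score 0. Raises on a graph with no edges at all.
    """
    if matrix.n_edges == 0:
        raise ValueError("cannot compute eigen centrality on an empty graph")
    adj = np.abs(matrix.eta)
    eigvals, eigvecs = np.linalg.eigh(adj)
    v = np.abs(eigvecs[:, -1])  # Perron vector of the dominant component
    v = np.where(v < 1e-12, 0.0, v)
    v = v / v.max()
    return {t: float(v[i]) for i, t in enumerate(matrix.taxon_ids)}


def betweenness_centrality(
    matrix: InteractionMatrix, normalized: bool = False
) -> dict[str, float]:
    """Unweighted shortest-path betweenness (unnormalized counts by default)."""
    g = to_graph(matrix)
    raw = nx.betweenness_centrality(g, normalized=normalized, weight=None)
    return {t: float(raw[t]) for t in matrix.taxon_ids}


def diameter(matrix: InteractionMatrix) -> int:
    """Unweighted diameter (hops) of the retained network.

    Isolated taxa are excluded; a disconnected edge set raises with the
    component memberships named.
    """
    g = to_graph(matrix, include_isolated=False)
    if g.number_of_nodes() == 0:
        raise ValueError("network has no edges; diameter undefined")
    if not nx.is_connected(g):
        comps = [sorted(c) for c in nx.connected_components(g)]
        raise ValueError(f"network is disconnected; components: {comps}")
    return int(nx.diameter(g))


def component_count(matrix: InteractionMatrix) -> tuple[int, int]:
    """Number of connected components among taxa with >= 1 retained edge,
    and the number of isolated taxa, returned separately."""
    g = to_graph(matrix, include_isolated=False)
    n_comp = nx.number_connected_components(g) if g.number_of_nodes() else 0
    n_isolated = len(matrix.taxon_ids) - g.number_of_nodes()
    return n_comp, n_isolated


def summarize_network(matrix: InteractionMatrix) -> NetworkSummary:
    """Centralities, diameter and component structure in one pass."""
    g = to_graph(matrix, include_isolated=False)
    n_comp, n_iso = component_count(matrix)
    diam = None
    if g.number_of_nodes() >= 2 and nx.is_connected(g):
        diam = int(nx.diameter(g))
    if g.number_of_edges() > 0:
        eigen = eigen_centrality(matrix)
    else:
        eigen = {t: 0.0 for t in matrix.taxon_ids}
    betw = betweenness_centrality(matrix)
    return NetworkSummary(
        taxon_ids=list(matrix.taxon_ids),
        eigen=eigen,
        betweenness=betw,
        diameter=diam,
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        n_components=n_comp,
        n_isolated=n_iso,
    )


def write_graphml(matrix: InteractionMatrix, path: str) -> None:
    nx.write_graphml(to_graph(matrix), path)


def write_edge_list(
    matrix: InteractionMatrix, path: str, corr: CorrelationResult | None = None
) -> None:
    """Weighted edge list CSV ``taxon_a,taxon_b,rho,p``."""
    rows = []
    n = len(matrix.taxon_ids)
    for i, j in itertools.combinations(range(n), 2):
        w = matrix.eta[i, j]
        if w != 0:
            p = corr.pvalues[i, j] if corr is not None else np.nan
            rows.append(
                {
                    "taxon_a": matrix.taxon_ids[i],
                    "taxon_b": matrix.taxon_ids[j],
                    "rho": w,
                    "p": p,
                }
            )
    pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "rho", "p"]).to_csv(
        path, index=False
    )
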