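"""Spearman co-occurrence matrices and thresholded correlation networks.

A co-occurrence network connects two taxa when their abundances across samples
are strongly and significantly rank-correlated: an edge requires |rho| > r_min
(default 0.6, strict) and p < alpha (default 0.05, strict, uncorrected).
Negative correlations qualify as edges too and carry a sign attribute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    """Pairwise Spearman rho and p-values over a set of taxa.

    ``rho`` is symmetric with unit diagonal; ``p`` is symmetric (diagonal 0);
    both are square over ``taxon_ids``; ``n_samples`` records the number of
    observations behind each coefficient.
    """

    taxon_ids: list
    rho: np.ndarray
    p: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        k = len(self.taxon_ids)
        if self.rho.shape != (k, k) or self.p.shape != (k, k):
            raise ValueError("rho and p must be square over taxon_ids")
        if not np.allclose(self.rho, self.rho.T, equal_nan=True):
            raise ValueError("rho must be symmetric")
        if np.nanmax(np.abs(self.rho)) > 1 + 1e-12:
            raise ValueError("|rho| must not exceed 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.taxon_ids, columns=self.taxon_ids)


def spearman_matrix(table) -> CorrelationMatrix:
    """All-pairs Spearman correlation of taxa across samples.

    rho is the Pearson correlation of midrank-transformed columns; the
    two-sided p-value uses the t approximation ``t = rho*sqrt((n-2)/(1-rho^2))``
    with n-2 degrees of freedom.  Constant columns have no defined rank
    correlation and are recorded as rho = 0, p = 1 (never an edge), with a
    logged warning.  Requires at least 4 samples for the approximation to mean
    anything at all.
    """
    values = np.asarray(table.data.to_numpy(), dtype=float)
    n, k = values.shape
    if n < 4:
        raise ValueError(f"need at least 4 samples for Spearman p-values, got {n}")
    taxon_ids = list(table.data.columns)
    if k < 2:
        return CorrelationMatrix(taxon_ids, np.ones((k, k)), np.zeros((k, k)), n)

    constant = np.ptp(values, axis=0) == 0
    if constant.any():
        names = [t for t, c in zip(taxon_ids, constant) if c]
        logger.warning(
            "%d constant taxa have undefined correlations (recorded as rho=0, p=1): %s",
            len(names), ", ".join(map(str, names[:5])) + ("..." if len(names) > 5 else ""),
        )

    ranks = np.apply_along_axis(stats.rankdata, 0, values)  # midranks
    centered = ranks - ranks.mean(axis=0)
    norms = np.sqrt((centered ** 2).sum(axis=0))
    safe = np.where(norms == 0.0, 1.0, norms)
    rho = (centered / safe).T @ (centered / safe)
    rho = np.clip(rho, -1.0, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(t)] = 0.0  # |rho| == 1: t -> inf, two-sided p -> 0

    # Constant columns have no defined rank correlation: rho=0, p=1.
    rho[constant, :] = 0.0
    rho[:, constant] = 0.0
    p[constant, :] = 1.0
    p[:, constant] = 1.0
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    return CorrelationMatrix(taxon_ids, rho, p, n)


def build_network(
    corr: CorrelationMatrix,
    r_min: float = 0.6,
    alpha: float = 0.05,
    drop_isolated: bool = True,
    taxonomy=None,
    mean_abund: pd.Series | None = None,
) -> nx.Graph:
    """Threshold a correlation matrix into an undirected co-occurrence graph.

    An edge is present iff ``|rho| > r_min`` and ``p < alpha`` (both strict: a
    pair at exactly rho = 0.6 is excluded).  Node attributes ``genus`` and
    ``mean_rel_abund`` are attached when a taxonomy map / abundance series is
    supplied.  With ``drop_isolated`` (the default) taxa with no qualifying
    edge do not appear as vertices.
    """
    if not 0.0 <= r_min <= 1.0:
        raise ValueError(f"r_min must be in [0, 1], got {r_min}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")

    graph = nx.Graph(r_min=r_min, alpha=alpha, n_samples=corr.n_samples)
    graph.add_nodes_from(corr.taxon_ids)

    iu, ju = np.triu_indices(len(corr.taxon_ids), k=1)
    keep = (np.abs(corr.rho[iu, ju]) > r_min) & (corr.p[iu, ju] < alpha)
    for i, j in zip(iu[keep], ju[keep]):
        rho = float(corr.rho[i, j])
        graph.add_edge(
            corr.taxon_ids[i],
            corr.taxon_ids[j],
            rho=rho,
            p=float(corr.p[i, j]),
            sign="positive" if rho > 0 else "negative",
        )

    if taxonomy is not None:
        genus = taxonomy.genus
        for node in graph.nodes:
            graph.nodes[node]["genus"] = str(genus.get(node, ""))
    if mean_abund is not None:
        for node in graph.nodes:
            if node in mean_abund.index:
                graph.nodes[node]["mean_rel_abund"] = float(mean_abund.loc[node])

    if drop_isolated:
        graph.remove_nodes_from(list(nx.isolates(graph)))
    return graph


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def write_edgelist_tsv(graph: nx.Graph, path) -> None:
    """Plain edge list: source, target, rho, p, sign."""
    rows = [
        {"source": u, "target": v, "rho": d["rho"], "p": d["p"], "sign": d["sign"]}
        for u, v, d in sorted(graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["source", "target", "rho", "p", "sign"]).to_csv(
        path, sep="\t", index=False
    )
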