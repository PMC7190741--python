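"""Degree-centrality classification of network nodes.

Nodes are partitioned into three classes by raw degree (edge count,
sign-agnostic): *key* nodes occupy the top fraction of degree centrality
(default 20%), *peripheral* nodes the bottom fraction (default 20%), and
*moderate* nodes the remainder.  Ties at a class boundary are absorbed into
the extreme class by default, which is why the extreme classes can be much
larger than their nominal quota — real amplicon networks carry massive
degree-1 ties at the bottom.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

KEY, MODERATE, PERIPHERAL = "key", "moderate", "peripheral"
_TIE_RULES = ("absorb", "truncate")


@dataclass
class NodeClassification:
    """Per-node degree and class label.

    ``table`` is indexed by node with columns ``degree`` (int) and ``class``
    (one of key/moderate/peripheral), sorted by descending degree then node
    ID.  The boundary degrees actually used are recorded alongside the
    nominal fractions.
    """

    table: pd.DataFrame
    top_frac: float
    bottom_frac: float
    ties: str
    key_degree_min: int
    peripheral_degree_max: int

    @property
    def classes(self) -> pd.Series:
        return self.table["class"]

    def nodes_in(self, label: str) -> list:
        return list(self.table.index[self.table["class"] == label])

    def counts(self) -> dict:
        c = self.classes.value_counts()
        return {label: int(c.get(label, 0)) for label in (KEY, MODERATE, PERIPHERAL)}

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="node")


def classify_nodes(
    net,
    top_frac: float = 0.2,
    bottom_frac: float = 0.2,
    ties: str = "absorb",
) -> NodeClassification:
    """Partition network nodes into key / moderate / peripheral by degree.

    The key class is the smallest degree-downward-closed set containing at
    least ``ceil(top_frac * N)`` nodes; with ``ties="absorb"`` every node tying
    the boundary degree is pulled into the extreme class, with
    ``ties="truncate"`` exactly the quota is kept (ties broken by node ID).
    The peripheral class is defined symmetrically from the bottom.  A node
    eligible for both classes is assigned key (with a warning).
    """
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("cannot classify an empty network")
    if not (0 < top_frac <= 1) or not (0 < bottom_frac <= 1):
        raise ValueError("top_frac and bottom_frac must be in (0, 1]")
    if top_frac + bottom_frac > 1:
        raise ValueError(
            f"top_frac + bottom_frac must not exceed 1, got {top_frac + bottom_frac}"
        )
    if ties not in _TIE_RULES:
        raise ValueError(f"ties must be one of {_TIE_RULES}, got {ties!r}")

    degrees = dict(net.degree())
    desc = sorted(degrees, key=lambda v: (-degrees[v], str(v)))
    asc = sorted(degrees, key=lambda v: (degrees[v], str(v)))

    k_top = math.ceil(top_frac * n)
    k_bot = math.ceil(bottom_frac * n)
    top_boundary = degrees[desc[k_top - 1]]
    bot_boundary = degrees[asc[k_bot - 1]]

    if ties == "absorb":
        key = {v for v in desc if degrees[v] >= top_boundary}
        peripheral = {v for v in asc if degrees[v] <= bot_boundary}
    else:
        key = set(desc[:k_top])
        peripheral = set(asc[:k_bot])

    collision = key & peripheral
    if collision:
        logger.warning(
            "%d node(s) eligible for both key and peripheral; assigned key: %s",
            len(collision), sorted(map(str, collision))[:5],
        )
        peripheral -= key

    labels = {
        v: KEY if v in key else PERIPHERAL if v in peripheral else MODERATE
        for v in desc
    }
    table = pd.DataFrame(
        {"degree": [degrees[v] for v in desc], "class": [labels[v] for v in desc]},
        index=pd.Index(desc, name="node"),
    )
    peripheral_max = max((degrees[v] for v in peripheral), default=bot_boundary)
    return NodeClassification(
        table=table,
        top_frac=top_frac,
        bottom_frac=bottom_frac,
        ties=ties,
        key_degree_min=min(degrees[v] for v in key),
        peripheral_degree_max=int(peripheral_max),
    )


def annotate_nodes(cls: NodeClassification, tax, mean_abund: pd.Series) -> pd.DataFrame:
    """Join genus and mean relative abundance (%) onto the classification.

    ``mean_abund`` is a per-taxon mean *fraction* (as from
    :func:`matnet.abundance.mean_relative_abundance`); the report converts it
    to percent.  Every node must be covered by both inputs.
    """
    if cls.table.empty:
        return pd.DataFrame(
            columns=["genus", "degree", "class", "mean_rel_abund_pct"],
            index=pd.Index([], name="node"),
        )
    tax.covers(cls.table.index)
    missing = [v for v in cls.table.index if v not in mean_abund.index]
    if missing:
        raise KeyError(f"no abundance entry for node {missing[0]!r}")
    out = cls.table.copy()
    out.insert(0, "genus", tax.genus.reindex(out.index))
    out["mean_rel_abund_pct"] = mean_abund.reindex(out.index) * 100.0
    return out


def update_graph_classes(net, cls: NodeClassification) -> None:
    """Write ``degree`` and ``class`` node attributes back onto the graph."""
    for node in net.nodes:
        net.nodes[node]["degree"] = int(cls.table.loc[node, "degree"])
        net.nodes[node]["class"] = str(cls.table.loc[node, "class"])
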