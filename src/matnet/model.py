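"""Model/Results interface over the network-directed analysis pipeline.

`CooccurrenceNetworkModel` holds the data (abundance table + taxonomy) and the
fixed preprocessing choices; `fit()` runs the estimation chain — relative
abundance on the full community, genus filtering, all-pairs Spearman
correlation with t-approximation p-values, strict thresholding into a graph,
and degree-centrality classification — and returns a
`CooccurrenceNetworkResults` carrying the correlation matrix, the graph, the
node classification, an annotated node table, and a text `summary()`.
Candidate selection against a culture collection hangs off the results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import abundance as ab
from . import classify as cl
from . import network as nw
from . import targets as tg


class CooccurrenceNetworkModel:
    """Co-occurrence network analysis of an abundance table.

    Parameters
    ----------
    table
        Counts- or relative-mode :class:`~matnet.abundance.AbundanceTable`.
        Counts are converted to community-wide relative abundances before any
        filtering.
    taxonomy
        :class:`~matnet.abundance.TaxonomyMap` covering every taxon.
    genus_filter
        Drop taxa without genus-level annotation before correlation (the
        default, matching the convention that network vertices must be
        nameable, hence culturable-in-principle, taxa).
    """

    def __init__(self, table: ab.AbundanceTable, taxonomy: ab.TaxonomyMap,
                 genus_filter: bool = True):
        taxonomy.covers(table.taxon_ids)
        self.table = table
        self.taxonomy = taxonomy
        self.genus_filter = genus_filter

    @classmethod
    def from_tsv(cls, table_path, taxonomy_path, orient: str = "samples",
                 mode: str = "counts", **kwargs) -> "CooccurrenceNetworkModel":
        table = ab.AbundanceTable.from_tsv(table_path, mode=mode, orient=orient)
        tax = ab.TaxonomyMap.from_tsv(taxonomy_path)
        return cls(table, tax, **kwargs)

    def fit(self, r_min: float = 0.6, alpha: float = 0.05,
            top_frac: float = 0.2, bottom_frac: float = 0.2,
            ties: str = "absorb", drop_isolated: bool = True,
            sample_subset=None) -> "CooccurrenceNetworkResults":
        """Estimate the thresholded network and classify its nodes.

        ``sample_subset`` restricts the fit to a subset of samples (e.g. one
        sampling region) without touching the stored table.
        """
        table = self.table
        if sample_subset is not None:
            table = ab.AbundanceTable(table.data.loc[list(sample_subset)],
                                      mode=table.mode, closed=table.closed)
        rel = ab.to_relative(table) if table.mode == "counts" else table
        mean_abund = ab.mean_relative_abundance(rel)
        if self.genus_filter:
            rel = ab.filter_genus_annotated(rel, self.taxonomy)
        corr = nw.spearman_matrix(rel)
        graph = nw.build_network(corr, r_min=r_min, alpha=alpha,
                                 drop_isolated=drop_isolated,
                                 taxonomy=self.taxonomy, mean_abund=mean_abund)
        classification = cl.classify_nodes(graph, top_frac=top_frac,
                                           bottom_frac=bottom_frac, ties=ties)
        cl.update_graph_classes(graph, classification)
        nodes = cl.annotate_nodes(classification, self.taxonomy, mean_abund)
        return CooccurrenceNetworkResults(
            model=self, correlations=corr, graph=graph,
            classification=classification, nodes=nodes, mean_abund=mean_abund)


@dataclass
class CooccurrenceNetworkResults:
    """Fitted co-occurrence network: estimates, graph, and node classes."""

    model: CooccurrenceNetworkModel
    correlations: nw.CorrelationMatrix
    graph: object
    classification: cl.NodeClassification
    #: Annotated node table: genus, degree, class, mean relative abundance (%).
    nodes: pd.DataFrame
    mean_abund: pd.Series = field(repr=False)

    def select_candidates(self, collection: tg.CultureCollection,
                          target_temp: float = 55.0,
                          require_aerobic: bool = True) -> tg.CandidateReport:
        """Rank culturable key-node genera as growth-promoter candidates."""
        return tg.select_candidates(self.classification, self.model.taxonomy,
                                    collection, target_temp=target_temp,
                                    require_aerobic=require_aerobic,
                                    mean_abund=self.mean_abund)

    def to_graphml(self, path) -> None:
        nw.write_graphml(self.graph, path)

    def to_edgelist_tsv(self, path) -> None:
        nw.write_edgelist_tsv(self.graph, path)

    def summary(self) -> str:
        counts = self.classification.counts()
        g = self.graph
        key = self.nodes[self.nodes["class"] == cl.KEY]
        lines = [
            "Co-occurrence network analysis",
            "=" * 46,
            f"Samples:            {self.correlations.n_samples}",
            f"Taxa correlated:    {len(self.correlations.taxon_ids)}",
            f"Edge rule:          |rho| > {g.graph['r_min']} and p < {g.graph['alpha']}",
            f"Network:            {g.number_of_nodes()} nodes, {g.number_of_edges()} edges",
            (f"Classes:            {counts['key']} key / {counts['moderate']} moderate"
             f" / {counts['peripheral']} peripheral"),
            (f"Class quotas:       top {self.classification.top_frac:.0%} / "
             f"bottom {self.classification.bottom_frac:.0%}, "
             f"ties={self.classification.ties}"),
            (f"Boundary degrees:   key >= {self.classification.key_degree_min}, "
             f"peripheral <= {self.classification.peripheral_degree_max}"),
            "",
            "Top key nodes (by degree):",
        ]
        for node, row in key.head(8).iterrows():
            lines.append(
                f"  {node:<12} {row['genus']:<18} degree {int(row['degree']):>3}"
                f"  abund {row['mean_rel_abund_pct']:.3f}%")
        return "\n".join(lines)
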