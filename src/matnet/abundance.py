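"""OTU abundance tables and taxonomy annotations.

The pipeline starts from a samples x taxa table of amplicon read counts (or
relative abundances) plus a QIIME-style taxonomy map.  Relative abundances are
computed on the *full* community before any genus-level filtering, so that a
taxon's reported fraction refers to the whole community rather than to the
filtered subset.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Seven-rank lineage used in QIIME-style taxonomy strings.
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")

#: Reserved genus token for taxa with no genus-level annotation.
UNCLASSIFIED = "unclassified"

_MODES = ("counts", "relative")
_REL_TOL = 1e-9


@dataclass
class AbundanceTable:
    """Samples x taxa abundance matrix.

    Parameters
    ----------
    data
        DataFrame with sample identifiers as the index and taxon identifiers
        as columns; values are non-negative read counts or fractions.
    mode
        ``"counts"`` for raw reads, ``"relative"`` for per-sample fractions
        (each row then sums to 1 within 1e-9).
    """

    data: pd.DataFrame
    mode: str = "counts"
    #: False once taxa have been filtered out without renormalizing, in which
    #: case relative rows sum to <= 1 rather than exactly 1.
    closed: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample identifiers: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate taxon identifiers: {dups}")
        values = self.data.to_numpy()
        if values.size and values.min() < 0:
            raise ValueError("abundance values must be non-negative")
        if self.mode == "relative" and self.data.shape[1] and self.closed:
            sums = values.sum(axis=1)
            bad = np.abs(sums - 1.0) > _REL_TOL
            if bad.any():
                name = self.data.index[np.argmax(bad)]
                raise ValueError(
                    f"relative-mode rows must sum to 1: sample {name!r} sums to "
                    f"{sums[np.argmax(bad)]:.12g}"
                )

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    @classmethod
    def from_tsv(cls, path, mode: str = "counts", orient: str = "samples") -> "AbundanceTable":
        """Read a tab-separated table.

        ``orient="samples"`` expects samples as rows (first column sample ID,
        header row of taxon IDs); ``orient="taxa"`` accepts the classic OTU
        table layout with taxa as rows and transposes it.
        """
        df = pd.read_csv(path, sep="\t", index_col=0)
        if orient == "taxa":
            df = df.T
        elif orient != "samples":
            raise ValueError(f"orient must be 'samples' or 'taxa', got {orient!r}")
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        df.index.name = None
        df.columns.name = None
        return cls(df, mode=mode)

    def to_tsv(self, path, orient: str = "samples") -> None:
        df = self.data if orient == "samples" else self.data.T
        df.to_csv(path, sep="\t", index_label="sample_id" if orient == "samples" else "taxon_id")


@dataclass
class TaxonomyMap:
    """Per-taxon rank annotations (domain ... species).

    ``ranks`` is a DataFrame indexed by taxon ID with the seven columns of
    :data:`RANKS`; an empty string or the reserved :data:`UNCLASSIFIED` token
    marks a missing annotation at that rank.
    """

    ranks: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [r for r in RANKS if r not in self.ranks.columns]
        if missing:
            raise ValueError(f"taxonomy table lacks rank columns {missing}")
        if self.ranks.index.has_duplicates:
            raise ValueError("duplicate taxon identifiers in taxonomy")

    @classmethod
    def from_lineages(cls, lineages: dict) -> "TaxonomyMap":
        """Build from ``taxon_id -> 'd__X;p__Y;...;s__Z'`` strings."""
        rows = {}
        for taxon, lineage in lineages.items():
            fields = [f.strip() for f in str(lineage).split(";")]
            row = {}
            for rank, prefix, value in zip(RANKS, RANK_PREFIXES, fields + [""] * 7):
                row[rank] = value[len(prefix):] if value.startswith(prefix) else value
            rows[taxon] = row
        df = pd.DataFrame.from_dict(rows, orient="index", dtype=object)
        df = df.reindex(columns=list(RANKS)).fillna("")
        return cls(df)

    @classmethod
    def from_tsv(cls, path) -> "TaxonomyMap":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str).fillna("")
        if "lineage" in df.columns:
            return cls.from_lineages(df["lineage"].to_dict())
        return cls(df)

    def to_tsv(self, path) -> None:
        out = pd.DataFrame({"lineage": [self.lineage(t) for t in self.ranks.index]},
                           index=self.ranks.index)
        out.to_csv(path, sep="\t", index_label="taxon_id")

    def lineage(self, taxon) -> str:
        row = self.ranks.loc[taxon]
        return ";".join(p + ("" if row[r] == UNCLASSIFIED else str(row[r]))
                        for r, p in zip(RANKS, RANK_PREFIXES))

    @property
    def genus(self) -> pd.Series:
        return self.ranks["genus"].astype(str)

    @property
    def genus_annotated(self) -> pd.Series:
        g = self.genus
        return (g != "") & (g != UNCLASSIFIED)

    def covers(self, taxa) -> None:
        """Raise ``KeyError`` naming the first taxon without an entry."""
        known = set(self.ranks.index)
        for taxon in taxa:
            if taxon not in known:
                raise KeyError(f"no taxonomy entry for taxon {taxon!r}")


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Convert counts to per-sample relative abundances.

    Each row is divided by its total; zero counts stay zero.  All-zero samples
    are an error (they signal upstream corruption rather than a real sample).
    """
    if table.mode != "counts":
        raise ValueError("to_relative expects a counts-mode table")
    totals = table.data.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero total reads")
    rel = table.data.div(totals, axis=0)
    return AbundanceTable(rel, mode="relative")


def filter_genus_annotated(table: AbundanceTable, tax: TaxonomyMap) -> AbundanceTable:
    """Keep only genus-annotated taxa.

    Rows are *not* renormalized: in relative mode the retained taxa keep their
    community-wide fractions (row sums become <= 1).
    """
    tax.covers(table.taxon_ids)
    annotated = tax.genus_annotated
    keep = [t for t in table.taxon_ids if bool(annotated.loc[t])]
    if not keep:
        logger.warning("no genus-annotated taxa retained; returning empty table")
    filtered = table.data[keep]
    closed = len(keep) == table.n_taxa and table.closed
    return AbundanceTable(filtered, mode=table.mode, closed=closed)


def mean_relative_abundance(table: AbundanceTable, percent: bool = False) -> pd.Series:
    """Arithmetic mean fraction of each taxon across samples.

    Set ``percent=True`` to report percentages instead of fractions.
    """
    if table.mode != "relative":
        raise ValueError("mean_relative_abundance expects a relative-mode table")
    means = table.data.mean(axis=0)
    return means * 100.0 if percent else means


def read_summary(table: AbundanceTable) -> tuple:
    """Total read count and floor of the per-sample average."""
    if table.mode != "counts":
        raise ValueError("read_summary expects a counts-mode table")
    total = int(table.data.to_numpy().sum())
    return total, total // max(table.n_samples, 1)
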