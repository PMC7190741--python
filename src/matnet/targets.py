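"""Selection of growth-promoter candidates from key-node genera.

Key nodes point at taxa that may organize the community; to act on them in
the lab, a candidate genus must additionally be present and available in the
culture collection, grow aerobically (isolation plates are incubated in air),
and tolerate the target isolation temperature.  Oxygen requirement and
growth-temperature range are *declared collection metadata*, not predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .classify import KEY, NodeClassification

logger = logging.getLogger(__name__)

OXYGEN_CLASSES = ("aerobic", "anaerobic", "facultative")

#: Exclusion reasons, in the order the filters are applied; each excluded
#: genus is recorded under the first filter it fails.
REASONS = ("not_in_collection", "unavailable", "oxygen", "temperature")


@dataclass
class CultureCollection:
    """Genus-level culture-collection metadata.

    ``table`` is indexed by genus with columns ``available`` (bool),
    ``oxygen`` (aerobic/anaerobic/facultative), ``temp_min`` and ``temp_max``
    (degrees C).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("genus names in a culture collection must be unique")
        bad = set(self.table["oxygen"]) - set(OXYGEN_CLASSES)
        if bad:
            raise ValueError(f"unknown oxygen class(es): {sorted(bad)}")

    @classmethod
    def from_records(cls, records: list[dict]) -> "CultureCollection":
        df = pd.DataFrame.from_records(records).set_index("genus")
        return cls(df)

    @classmethod
    def from_tsv(cls, path) -> "CultureCollection":
        df = pd.read_csv(path, sep="\t", index_col="genus")
        df["available"] = df["available"].astype(bool)
        return cls(df)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="genus")


@dataclass
class CandidateReport:
    """Ranked growth-promoter candidates plus per-genus exclusion reasons.

    ``candidates`` has one row per selected genus (n_key_otus, max_degree,
    mean_rel_abund_pct, oxygen, temp range), ranked by max key-node degree
    descending, then supporting OTU count, then genus name.  ``exclusions``
    records exactly one first-failing filter per rejected key-node genus.
    """

    candidates: pd.DataFrame
    exclusions: pd.DataFrame
    target_temp: float
    require_aerobic: bool

    def to_tsv(self, path) -> None:
        self.candidates.to_csv(path, sep="\t", index_label="genus")


def select_candidates(
    cls: NodeClassification,
    tax,
    coll: CultureCollection,
    target_temp: float = 55.0,
    require_aerobic: bool = True,
    mean_abund: pd.Series | None = None,
) -> CandidateReport:
    """Turn key-node genera into culturable growth-promoter candidates.

    A genus qualifies when it has at least one key-node OTU, is present and
    available in the collection, is aerobic or facultative when
    ``require_aerobic`` is set, and its growth range contains ``target_temp``.
    An empty candidate list is a valid result; every near-miss is logged with
    the single filter that removed it.
    """
    key_nodes = cls.nodes_in(KEY)
    rows = []
    if key_nodes:
        tax.covers(key_nodes)
        genus = tax.genus
        per_genus = {}
        for node in key_nodes:
            g = str(genus.loc[node])
            per_genus.setdefault(g, []).append(node)
        for g in sorted(per_genus):
            nodes = per_genus[g]
            degrees = [int(cls.table.loc[v, "degree"]) for v in nodes]
            abund = (
                float(sum(mean_abund.loc[v] for v in nodes)) * 100.0
                if mean_abund is not None
                else float("nan")
            )
            rows.append(
                {"genus": g, "n_key_otus": len(nodes), "max_degree": max(degrees),
                 "mean_rel_abund_pct": abund}
            )

    candidates, exclusions = [], []
    for row in rows:
        g = row["genus"]
        if g not in coll.table.index:
            exclusions.append({"genus": g, "reason": "not_in_collection"})
            continue
        meta = coll.table.loc[g]
        if not bool(meta["available"]):
            exclusions.append({"genus": g, "reason": "unavailable"})
            continue
        if require_aerobic and meta["oxygen"] == "anaerobic":
            exclusions.append({"genus": g, "reason": "oxygen"})
            continue
        if not (float(meta["temp_min"]) <= target_temp <= float(meta["temp_max"])):
            exclusions.append({"genus": g, "reason": "temperature"})
            continue
        row = dict(row, oxygen=meta["oxygen"],
                   temp_min=float(meta["temp_min"]), temp_max=float(meta["temp_max"]))
        candidates.append(row)

    for exc in exclusions:
        logger.info("key-node genus %s excluded: %s", exc["genus"], exc["reason"])

    cand_df = pd.DataFrame(
        candidates,
        columns=["genus", "n_key_otus", "max_degree", "mean_rel_abund_pct",
                 "oxygen", "temp_min", "temp_max"],
    )
    if len(cand_df):
        cand_df = cand_df.sort_values(
            by=["max_degree", "n_key_otus", "genus"], ascending=[False, False, True]
        )
    cand_df = cand_df.set_index("genus")
    exc_df = pd.DataFrame(exclusions, columns=["genus", "reason"]).set_index("genus")
    return CandidateReport(cand_df, exc_df, target_temp, require_aerobic)
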