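"""Taxonomic-novelty classification of cultured isolates and campaign tallies.

Each isolate carries the 16S rRNA identity of its best hit against validly
described species.  Identity bands map to novelty tiers:

* >= 98.7%          known species
* 95.3 - <98.7%     candidate novel species
* 90.0 - <95.3%     candidate novel genus
* < 90.0%           candidate novel higher taxon

Thresholds are lower-inclusive for the higher tier (98.7 is a known species)
and configurable, since the species cutoff is debated between 98.5 and 98.7.
Isolates below the 95.3% genus cutoff are flagged for cloning of the
near-complete gene before phylogenetic placement.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

KNOWN_SPECIES = "known_species"
NOVEL_SPECIES = "novel_species"
NOVEL_GENUS = "novel_genus"
NOVEL_HIGHER_TAXON = "novel_higher_taxon"
TIERS = (KNOWN_SPECIES, NOVEL_SPECIES, NOVEL_GENUS, NOVEL_HIGHER_TAXON)

SPECIES_THRESHOLD = 98.7
GENUS_THRESHOLD = 95.3
HIGHER_TAXON_THRESHOLD = 90.0
CLONING_THRESHOLD = 95.3


def _check_identity(identity: float) -> float:
    identity = float(identity)
    if not 0.0 <= identity <= 100.0:
        raise ValueError(f"16S identity must be in [0, 100] percent, got {identity}")
    return identity


def classify_novelty(
    identity: float,
    species_threshold: float = SPECIES_THRESHOLD,
    genus_threshold: float = GENUS_THRESHOLD,
    higher_taxon_threshold: float = HIGHER_TAXON_THRESHOLD,
) -> str:
    """Map a best-hit 16S identity (percent) to its novelty tier."""
    identity = _check_identity(identity)
    if identity >= species_threshold:
        return KNOWN_SPECIES
    if identity >= genus_threshold:
        return NOVEL_SPECIES
    if identity >= higher_taxon_threshold:
        return NOVEL_GENUS
    return NOVEL_HIGHER_TAXON


def flag_for_cloning(identity: float, threshold: float = CLONING_THRESHOLD) -> bool:
    """True iff the isolate's identity falls below the cloning cutoff (95.3%)."""
    return _check_identity(identity) < threshold


@dataclass
class IsolateRecord:
    """One cultured strain: isolation medium, phylum, best-hit 16S identity."""

    isolate_id: str
    medium: str
    phylum: str
    identity: float
    novelty: str = field(default="")

    def __post_init__(self) -> None:
        self.identity = _check_identity(self.identity)
        if not self.medium:
            raise ValueError(f"isolate {self.isolate_id}: medium must be non-empty")
        if not self.phylum:
            raise ValueError(f"isolate {self.isolate_id}: phylum must be non-empty")
        if not self.novelty:
            self.novelty = classify_novelty(self.identity)


@dataclass
class CampaignSummary:
    """Isolation-campaign tallies: per-phylum, per-medium, novelty, cloning."""

    total: int
    by_phylum: dict
    by_medium: dict
    scm_count: int
    scm_percentage: int
    novelty_counts: dict
    cloning_count: int

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [("total", "", self.total)]
            + [("phylum", k, v) for k, v in sorted(self.by_phylum.items())]
            + [("medium", k, v) for k, v in sorted(self.by_medium.items())]
            + [("scm", "count", self.scm_count), ("scm", "percent", self.scm_percentage)]
            + [("novelty", k, self.novelty_counts.get(k, 0)) for k in TIERS]
            + [("cloning", "flagged", self.cloning_count)]
        )
        return pd.DataFrame(rows, columns=["group", "item", "count"])


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def tally_isolates(
    records: list[IsolateRecord],
    scm_media: frozenset = frozenset({"SCM"}),
    known_media: frozenset | None = None,
) -> CampaignSummary:
    """Summarize an isolation campaign.

    ``scm_media`` names the media counted as spent-culture-medium plates; the
    SCM percentage is rounded to the nearest integer (half up).  When
    ``known_media`` is given, records on media outside it are tallied under
    "other" with a warning.
    """
    if not records:
        raise ValueError("cannot tally an empty isolate list")
    by_phylum: Counter = Counter()
    by_medium: Counter = Counter()
    novelty: Counter = Counter()
    scm = 0
    cloning = 0
    for rec in records:
        medium = rec.medium
        if known_media is not None and medium not in known_media:
            logger.warning("isolate %s has unknown medium %r; counted under 'other'",
                           rec.isolate_id, medium)
            medium = "other"
        by_phylum[rec.phylum] += 1
        by_medium[medium] += 1
        novelty[rec.novelty or classify_novelty(rec.identity)] += 1
        if rec.medium in scm_media:
            scm += 1
        if flag_for_cloning(rec.identity):
            cloning += 1
    total = len(records)
    return CampaignSummary(
        total=total,
        by_phylum=dict(by_phylum),
        by_medium=dict(by_medium),
        scm_count=scm,
        scm_percentage=_round_half_up(100.0 * scm / total),
        novelty_counts=dict(novelty),
        cloning_count=cloning,
    )


def read_isolates_tsv(path) -> list[IsolateRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        IsolateRecord(str(r.isolate_id), str(r.medium), str(r.phylum),
                      float(r.identity_pct))
        for r in df.itertuples(index=False)
    ]


def write_isolates_tsv(records: list[IsolateRecord], path) -> None:
    pd.DataFrame(
        [
            {"isolate_id": r.isolate_id, "medium": r.medium, "phylum": r.phylum,
             "identity_pct": r.identity, "novelty": r.novelty}
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)
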