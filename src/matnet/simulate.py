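"""Synthetic hot-spring mat community, isolate, assay, and metabolome generators.

These generators produce every pipeline input with the statistical structure
the analysis assumes, together with the planted ground truth needed for
recovery testing:

* ``generate_community`` — a compositional amplicon table over ~26 samples in
  which a handful of *rare* hub taxa and their partners are driven by shared
  per-hub latent variables (so they form strongly rank-correlated groups),
  while a few *abundant* taxa fluctuate independently of every latent and
  therefore acquire no strong correlations.  This reproduces, by
  construction, the contrast between rare high-centrality key taxa and
  abundant peripheral phototrophs.
* ``generate_isolates`` — an isolation-campaign record set whose default
  totals mirror the study campaign (319 isolates over eight phyla, 239 of
  them on spent-culture medium).
* ``generate_assay`` / ``generate_metabolome`` — OD590 replicate tables with
  planted mean shifts, and metabolite time courses with planted accumulating
  compounds (one pinned at a 78.9-fold rise) among null compounds.

Identical (spec, seed) pairs reproduce bit-identical outputs; each generator
draws from its own deterministic substream of the single integer seed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abundance import RANK_PREFIXES, AbundanceTable, TaxonomyMap
from .growthstats import MetaboliteProfile
from .isolates import IsolateRecord

#: Per-generator substream tags mixed into the seed sequence.
_STREAMS = {"community": 1, "isolates": 2, "assay": 3, "metabolome": 4}

#: Genera used to label planted hubs (first five) and abundant peripherals
#: (first three); extra planted taxa get generic names.
HUB_GENERA = ("Tepidimonas", "Geobacillus", "Meiothermus", "Sphingomonas",
              "Anaerosolibacter")
PERIPHERAL_GENERA = ("Chloroflexus", "Thermus", "Roseiflexus")

#: Phyla used to flavor synthetic taxonomy strings (the eight recovered in
#: the isolation campaign).
PHYLA = ("Acidobacteria", "Actinobacteria", "Aquificae", "Bacteroidetes",
         "Chloroflexi", "Deinococcus-Thermus", "Firmicutes", "Proteobacteria")


class SpecError(ValueError):
    """A generator spec violates one of its invariants."""


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


# ---------------------------------------------------------------------------
# Community

@dataclass
class CommunitySpec:
    """Design of the synthetic mat community.

    ``hub_mean_rel_abund`` is a per-run ceiling on each hub's mean relative
    abundance; the generator targets half the ceiling so that sampling noise
    never pushes a run over it.  ``latent_loading`` is the population
    correlation within a hub group and must exceed the 0.6 edge threshold
    used downstream.  ``noise_sd`` scales only the idiosyncratic
    (latent-independent) part of each taxon's variation: at ``noise_sd=0``
    hub groups become deterministic monotone functions of their latent.
    """

    n_samples: int = 26
    n_taxa: int = 200
    n_hubs: int = 5
    partners_per_hub: int = 20
    hub_mean_rel_abund: float = 0.008
    n_abundant_peripherals: int = 3
    peripheral_mean_rel_abund: float = 0.10
    #: Mean relative abundance of hub partners.  Kept small so that the total
    #: latent-driven mass stays a minor fraction of the community; otherwise
    #: compositional closure would couple every taxon to the hub latents.
    partner_mean_rel_abund: float = 0.003
    latent_loading: float = 0.85
    unclassified_fraction: float = 0.3
    noise_sd: float = 1.1
    #: Overall per-taxon log-scale spread (lognormal sigma) for hub-group and
    #: background taxa; abundant peripherals use peripheral_log_sd (dominant
    #: mat phototrophs are comparatively stable across samples).
    log_sd: float = 0.5
    peripheral_log_sd: float = 0.25
    #: Fixed per-sample sequencing depth (the study's mean reads per sample).
    depth: int = 83_610
    output_mode: str = "counts"

    def validate(self) -> None:
        planted = self.n_hubs * (self.partners_per_hub + 1) + self.n_abundant_peripherals
        if self.n_samples < 4:
            raise SpecError("n_samples must be at least 4")
        if planted > self.n_taxa:
            raise SpecError(
                "invariant violated: n_hubs * (partners_per_hub + 1) + "
                f"n_abundant_peripherals = {planted} exceeds n_taxa = {self.n_taxa}"
            )
        if not 0.0 < self.hub_mean_rel_abund <= 0.01:
            raise SpecError("hub_mean_rel_abund must be in (0, 0.01]")
        if not 0.05 <= self.peripheral_mean_rel_abund <= 0.20:
            raise SpecError("peripheral_mean_rel_abund must be in [0.05, 0.20]")
        if self.partner_mean_rel_abund <= 0:
            raise SpecError("partner_mean_rel_abund must be positive")
        if not (0.6 < self.latent_loading <= 1.0):
            raise SpecError(
                "invariant violated: latent_loading must exceed the downstream "
                f"edge threshold 0.6 (and be <= 1), got {self.latent_loading}"
            )
        if not 0.0 <= self.unclassified_fraction < 1.0:
            raise SpecError("unclassified_fraction must be in [0, 1)")
        n_unclassified = round(self.unclassified_fraction * self.n_taxa)
        if n_unclassified > self.n_taxa - planted:
            raise SpecError(
                "unclassified_fraction too large: planted taxa must stay "
                "genus-annotated"
            )
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be non-negative")
        if self.log_sd <= 0 or self.peripheral_log_sd <= 0:
            raise SpecError("log_sd and peripheral_log_sd must be positive")
        if self.n_abundant_peripherals * self.peripheral_mean_rel_abund >= 0.9:
            raise SpecError("abundant peripherals would exhaust the community")
        if self.depth < 1:
            raise SpecError("depth must be positive")
        if self.output_mode not in ("counts", "relative"):
            raise SpecError("output_mode must be 'counts' or 'relative'")


@dataclass
class PlantedStructure:
    """Ground truth of a generated community."""

    hub_taxa: set
    partner_map: dict
    abundant_peripheral_taxa: set
    seed: int

    def __post_init__(self) -> None:
        partners = set().union(*self.partner_map.values()) if self.partner_map else set()
        sets = [self.hub_taxa, partners, self.abundant_peripheral_taxa]
        if sum(len(s) for s in sets) != len(set().union(*sets)):
            raise SpecError("hub, partner, and peripheral sets must be disjoint")

    @property
    def partner_taxa(self) -> set:
        return set().union(*self.partner_map.values()) if self.partner_map else set()

    def to_tsv(self, path) -> None:
        rows = [{"taxon_id": t, "role": "hub", "hub": t} for t in sorted(self.hub_taxa)]
        for hub in sorted(self.partner_map):
            rows += [{"taxon_id": t, "role": "partner", "hub": hub}
                     for t in sorted(self.partner_map[hub])]
        rows += [{"taxon_id": t, "role": "abundant_peripheral", "hub": ""}
                 for t in sorted(self.abundant_peripheral_taxa)]
        pd.DataFrame(rows, columns=["taxon_id", "role", "hub"]).to_csv(
            path, sep="\t", index=False)


def _lineage(phylum: str, genus: str) -> str:
    parts = ("Bacteria", phylum, f"{phylum}ia", f"{phylum}ales", f"{phylum}aceae",
             genus, "")
    return ";".join(p + v for p, v in zip(RANK_PREFIXES, parts))


def generate_community(spec: CommunitySpec, seed: int):
    """Generate (AbundanceTable, TaxonomyMap, PlantedStructure).

    Per-taxon baseline intensities are log-normal; each hub group shares a
    latent Gaussian per sample with loading sqrt(latent_loading), so every
    within-group pair has population correlation latent_loading (its Spearman
    counterpart is within a few hundredths for loadings above 0.6).  The
    exponential link keeps the coupling monotone, multinomial resampling to a
    fixed per-sample depth converts intensities to counts, and closure makes
    the table compositional.
    """
    spec.validate()
    rng = _rng(seed, "community")

    n, k = spec.n_samples, spec.n_taxa
    group_size = spec.partners_per_hub + 1
    n_planted = spec.n_hubs * group_size
    taxa = [f"OTU_{i + 1:04d}" for i in range(k)]
    samples = [f"S{i + 1:02d}" for i in range(n)]

    hub_idx = [g * group_size for g in range(spec.n_hubs)]
    partner_idx = {g: list(range(g * group_size + 1, (g + 1) * group_size))
                   for g in range(spec.n_hubs)}
    peripheral_idx = list(range(n_planted, n_planted + spec.n_abundant_peripherals))
    background_idx = list(range(n_planted + spec.n_abundant_peripherals, k))

    # Target mean relative abundances: hubs at half their ceiling, partners at
    # the same rare scale (key-node groups are rare taxa), abundant
    # peripherals at their stated level, and the independent background
    # sharing the remaining mass with a log-normal spread.  Keeping partner
    # and background weights free of heavy tails matters: a single dominant
    # latent-driven taxon would move every sample's denominator and smear
    # spurious closure-induced correlations across the whole table.
    weights = np.empty(k)
    hub_target = 0.5 * spec.hub_mean_rel_abund
    weights[hub_idx] = hub_target
    all_partner_idx = [i for g in range(spec.n_hubs) for i in partner_idx[g]]
    weights[all_partner_idx] = spec.partner_mean_rel_abund * np.exp(
        rng.normal(0.0, 0.5, size=len(all_partner_idx)))
    weights[peripheral_idx] = spec.peripheral_mean_rel_abund
    raw = np.exp(rng.normal(0.0, 0.7, size=len(background_idx)))
    remaining = (1.0 - weights[hub_idx].sum() - weights[all_partner_idx].sum()
                 - weights[peripheral_idx].sum())
    if remaining <= 0:
        raise SpecError("planted abundances exhaust the community")
    weights[background_idx] = remaining * raw / raw.sum()

    sigma = np.full(k, spec.log_sd)
    sigma[peripheral_idx] = spec.peripheral_log_sd
    # Variance of the standardized deviate z per taxon (latent + idiosyncratic
    # for group members, idiosyncratic only for independents), then the
    # E[exp(sigma*z)] correction so expected intensity tracks the target weight.
    zvar = np.full(k, spec.noise_sd**2)
    all_member_idx = hub_idx + all_partner_idx
    zvar[hub_idx] = 1.0
    zvar[all_partner_idx] = (spec.latent_loading**2
                             + (1.0 - spec.latent_loading**2) * spec.noise_sd**2)
    mu = np.log(weights) - 0.5 * sigma**2 * zvar

    # The hub *is* its latent (a deterministic monotone driver); partners load
    # on it at latent_loading with idiosyncratic noise, so each hub-partner
    # pair has population correlation latent_loading while partner-partner
    # pairs sit at its square.  Hubs therefore carry the highest degree in
    # their group once the network is thresholded.
    # Quantile-matched latents: each hub's latent is a random permutation of
    # fixed standard-normal scores, so every group experiences the same
    # latent spread in every run.  Rank structure (all that Spearman sees) is
    # untouched; what this removes is the seed-to-seed lottery in which an
    # unusually wide latent draw saturates a whole group's correlations or an
    # unusually narrow one erases them.
    from scipy.stats import norm

    scores = norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    scores = (scores - scores.mean()) / scores.std()
    latent = np.column_stack([rng.permutation(scores) for _ in range(spec.n_hubs)])
    eps = rng.normal(size=(n, k))
    a = spec.latent_loading
    b = math.sqrt(1.0 - spec.latent_loading**2) * spec.noise_sd
    z = np.empty((n, k))
    for g in range(spec.n_hubs):
        z[:, hub_idx[g]] = latent[:, g]
        z[:, partner_idx[g]] = a * latent[:, [g]] + b * eps[:, partner_idx[g]]
    independent = peripheral_idx + background_idx
    z[:, independent] = spec.noise_sd * eps[:, independent]

    log_intensity = mu[None, :] + sigma[None, :] * z
    intensity = np.exp(log_intensity)
    rel = intensity / intensity.sum(axis=1, keepdims=True)

    if spec.output_mode == "counts":
        counts = np.vstack([rng.multinomial(spec.depth, rel[i]) for i in range(n)])
        table = AbundanceTable(
            pd.DataFrame(counts, index=samples, columns=taxa), mode="counts")
    else:
        table = AbundanceTable(
            pd.DataFrame(rel, index=samples, columns=taxa), mode="relative")

    # Taxonomy: planted taxa always genus-annotated; the unclassified quota is
    # drawn from the background.
    n_unclassified = round(spec.unclassified_fraction * k)
    unclassified = set(
        rng.choice(background_idx, size=n_unclassified, replace=False).tolist()
    ) if n_unclassified else set()

    genus = {}
    for g, i in enumerate(hub_idx):
        genus[i] = HUB_GENERA[g] if g < len(HUB_GENERA) else f"KeyGenus{g + 1}"
    for g, i in enumerate(peripheral_idx):
        genus[i] = (PERIPHERAL_GENERA[g] if g < len(PERIPHERAL_GENERA)
                    else f"AbundantGenus{g + 1}")
    lineages = {}
    for i, taxon in enumerate(taxa):
        phylum = PHYLA[i % len(PHYLA)]
        if i in unclassified:
            lineages[taxon] = _lineage(phylum, "")
        else:
            lineages[taxon] = _lineage(phylum, genus.get(i, f"Genus{i + 1:04d}"))
    tax = TaxonomyMap.from_lineages(lineages)

    planted = PlantedStructure(
        hub_taxa={taxa[i] for i in hub_idx},
        partner_map={taxa[hub_idx[g]]: {taxa[i] for i in partner_idx[g]}
                     for g in range(spec.n_hubs)},
        abundant_peripheral_taxa={taxa[i] for i in peripheral_idx},
        seed=int(seed),
    )
    return table, tax, planted


# ---------------------------------------------------------------------------
# Isolates

#: The study campaign's printed per-phylum totals (319 isolates overall).
CAMPAIGN_PHYLUM_COUNTS = {
    "Acidobacteria": 4, "Actinobacteria": 5, "Aquificae": 3, "Bacteroidetes": 6,
    "Chloroflexi": 69, "Deinococcus-Thermus": 142, "Firmicutes": 13,
    "Proteobacteria": 77,
}
#: 239 of 319 isolates came off spent-culture-medium plates; the remainder
#: split across the four standard thermophile media.
CAMPAIGN_MEDIUM_COUNTS = {"SCM": 239, "R2A": 30, "T5": 20, "CC": 15, "Thermus162": 15}


@dataclass
class IsolateSpec:
    """Design of a synthetic isolation campaign.

    Exact per-phylum and per-medium totals are planted (defaults mirror the
    study campaign); identities are drawn per novelty tier with the stated
    weights, or pinned exactly via ``planted_identities``.
    """

    phylum_counts: dict = field(default_factory=lambda: dict(CAMPAIGN_PHYLUM_COUNTS))
    medium_counts: dict = field(default_factory=lambda: dict(CAMPAIGN_MEDIUM_COUNTS))
    tier_weights: tuple = (0.60, 0.25, 0.10, 0.05)  # known, species, genus, higher
    planted_identities: tuple | None = None

    @property
    def n_isolates(self) -> int:
        return sum(self.phylum_counts.values())

    def validate(self) -> None:
        if any(v < 0 for v in self.phylum_counts.values()):
            raise SpecError("phylum counts must be non-negative")
        if sum(self.medium_counts.values()) != self.n_isolates:
            raise SpecError(
                "medium counts must sum to the phylum-count total "
                f"({sum(self.medium_counts.values())} != {self.n_isolates})"
            )
        if len(self.tier_weights) != 4 or any(w < 0 for w in self.tier_weights):
            raise SpecError("tier_weights must be 4 non-negative numbers")
        if self.planted_identities is not None:
            if len(self.planted_identities) != self.n_isolates:
                raise SpecError("planted_identities length must match n_isolates")
            if any(not 0 <= x <= 100 for x in self.planted_identities):
                raise SpecError("planted identities must be in [0, 100]")


#: Identity bands sampled per tier (low edge, high edge).
_TIER_BANDS = ((98.7, 100.0), (95.3, 98.7), (90.0, 95.3), (80.0, 90.0))


def generate_isolates(spec: IsolateSpec, seed: int) -> list[IsolateRecord]:
    """Generate isolate records with planted phylum/medium totals."""
    spec.validate()
    rng = _rng(seed, "isolates")
    n = spec.n_isolates
    if n == 0:
        return []

    phyla = [p for p, c in sorted(spec.phylum_counts.items()) for _ in range(c)]
    media = [m for m, c in sorted(spec.medium_counts.items()) for _ in range(c)]
    rng.shuffle(media)

    if spec.planted_identities is not None:
        identities = np.asarray(spec.planted_identities, dtype=float)
    else:
        weights = np.asarray(spec.tier_weights, dtype=float)
        tiers = rng.choice(4, size=n, p=weights / weights.sum())
        lo = np.array([_TIER_BANDS[t][0] for t in tiers])
        hi = np.array([_TIER_BANDS[t][1] for t in tiers])
        identities = np.round(lo + (hi - lo) * rng.random(n), 2)
        identities = np.minimum(identities, 100.0)

    return [
        IsolateRecord(f"SYSU_G{i + 1:05d}", media[i], phyla[i], float(identities[i]))
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# Growth assay

@dataclass
class AssaySpec:
    """Design of a growth-promotion assay (OD590, replicated).

    Defaults emulate a supernatant-harvest-time experiment: supernatants
    harvested at 8, 12 and 24 h of the promoter culture carry real planted
    gains over the control, the 0 h and 4 h harvests do not.
    """

    strain: str = "Chloroflexus_190R"
    control_condition: str = "control"
    control_mean_od: float = 0.20
    condition_shifts: dict = field(default_factory=lambda: {
        "supernatant_0h": 0.0, "supernatant_4h": 0.005, "supernatant_8h": 0.04,
        "supernatant_12h": 0.09, "supernatant_24h": 0.11,
    })
    n_replicates: int = 3
    noise_sd: float = 0.005

    def validate(self) -> None:
        if self.n_replicates < 2:
            raise SpecError("n_replicates must be at least 2")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be non-negative")
        if self.control_mean_od < 0:
            raise SpecError("control_mean_od must be non-negative")


def generate_assay(spec: AssaySpec, seed: int) -> pd.DataFrame:
    """Long OD590 table: strain, condition, replicate, od590."""
    spec.validate()
    rng = _rng(seed, "assay")
    rows = []
    conditions = [(spec.control_condition, 0.0)] + sorted(spec.condition_shifts.items())
    for condition, shift in conditions:
        ods = spec.control_mean_od + shift + rng.normal(0.0, spec.noise_sd,
                                                        size=spec.n_replicates)
        for r, od in enumerate(ods, start=1):
            rows.append({"strain": spec.strain, "condition": condition,
                         "replicate": r, "od590": max(float(od), 0.0)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Metabolome

@dataclass
class MetabolomeSpec:
    """Design of a synthetic extracellular metabolome time course.

    ``n_accumulating`` compounds carry a planted monotone accumulation from
    baseline to ``fold`` at the final timepoint (log-fold applied along
    ``ramp``); the remainder are null.  One accumulating compound is pinned
    to ``named_fold`` (deoxycytidine at 78.9-fold, the strongest accumulation
    the campaign observed); the rest draw log-uniform folds from
    ``fold_range`` with a ``weak_fraction`` drawn from ``weak_fold_range`` so
    that effect sizes span clearly detectable to borderline.
    """

    n_compounds: int = 412
    n_accumulating: int = 83
    timepoints: tuple = (0.0, 4.0, 8.0, 12.0, 24.0)
    n_replicates: int = 3
    #: Fraction of planted log-fold reached at each timepoint (accumulation
    #: concentrated late in growth, as in the study's stationary phase).
    ramp: tuple = (0.0, 0.05, 0.15, 0.40, 1.0)
    fold_range: tuple = (2.0, 50.0)
    weak_fraction: float = 0.5
    weak_fold_range: tuple = (1.15, 2.0)
    named_fold: tuple = ("deoxycytidine", 78.9)
    baseline_log10_mean: float = 6.0
    baseline_log10_sd: float = 0.8
    #: Multiplicative replicate noise, natural-log scale.
    noise_sd: float = 0.15

    def validate(self) -> None:
        if self.n_replicates < 2:
            raise SpecError("n_replicates must be at least 2")
        if list(self.timepoints) != sorted(set(self.timepoints)):
            raise SpecError("timepoints must be strictly increasing")
        if len(self.timepoints) < 2:
            raise SpecError("need at least 2 timepoints")
        if len(self.ramp) != len(self.timepoints):
            raise SpecError("ramp must have one entry per timepoint")
        if not 0 <= self.n_accumulating <= self.n_compounds:
            raise SpecError("n_accumulating must be in [0, n_compounds]")
        for pair in (self.fold_range, self.weak_fold_range):
            if pair[0] <= 0 or pair[1] < pair[0]:
                raise SpecError("fold ranges must be positive and ordered")
        if not 0 <= self.weak_fraction <= 1:
            raise SpecError("weak_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be non-negative")


def generate_metabolome(spec: MetabolomeSpec, seed: int):
    """Generate (MetaboliteProfile, truth) where truth maps compound -> planted fold.

    Mean intensity of an accumulating compound at timepoint t is
    ``baseline * fold**ramp(t)``; replicates are multiplied by lognormal noise
    ``exp(noise_sd * eps)``.  Null compounds have flat means (fold 1).
    """
    spec.validate()
    rng = _rng(seed, "metabolome")
    n_c, n_t, n_r = spec.n_compounds, len(spec.timepoints), spec.n_replicates

    compounds = [f"M{i + 1:04d}" for i in range(n_c)]
    folds = np.ones(n_c)
    if spec.n_accumulating:
        compounds[0] = spec.named_fold[0]
        folds[0] = spec.named_fold[1]
        extra = spec.n_accumulating - 1
        if extra:
            n_weak = round(spec.weak_fraction * extra)
            strong = np.exp(rng.uniform(*np.log(spec.fold_range), size=extra - n_weak))
            weak = np.exp(rng.uniform(*np.log(spec.weak_fold_range), size=n_weak))
            folds[1:spec.n_accumulating] = np.concatenate([strong, weak])

    baseline = 10.0 ** rng.normal(spec.baseline_log10_mean, spec.baseline_log10_sd,
                                  size=n_c)
    ramp = np.asarray(spec.ramp)
    means = baseline[:, None] * folds[:, None] ** ramp[None, :]
    noise = np.exp(spec.noise_sd * rng.normal(size=(n_c, n_t, n_r)))
    intensities = means[:, :, None] * noise

    rows = []
    for c in range(n_c):
        for t, tp in enumerate(spec.timepoints):
            for r in range(n_r):
                rows.append({"compound": compounds[c], "timepoint_h": float(tp),
                             "replicate": r + 1,
                             "intensity": float(intensities[c, t, r])})
    profile = MetaboliteProfile(pd.DataFrame(rows))
    truth = pd.Series(folds, index=compounds, name="planted_fold")
    return profile, truth


# ---------------------------------------------------------------------------
# Spec I/O for the command line

def spec_from_mapping(kind: str, mapping: dict):
    """Build a generator spec from a flat key/value mapping."""
    classes = {"community": CommunitySpec, "isolates": IsolateSpec,
               "assay": AssaySpec, "metabolome": MetabolomeSpec}
    if kind not in classes:
        raise SpecError(f"unknown spec kind {kind!r}")
    cls = classes[kind]
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise SpecError(f"unknown {kind} spec key(s): {sorted(unknown)}")
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name in mapping:
            value = mapping[f.name]
            coerced[f.name] = tuple(value) if isinstance(value, list) else value
    return cls(**coerced)
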