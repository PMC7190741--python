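import numpy as np
import pandas as pd
import pytest

import matnet as mn
from matnet.simulate import SpecError, spec_from_mapping


class TestCommunitySpecValidation:
    def test_planted_taxa_must_fit(self):
        spec = mn.CommunitySpec(n_taxa=50)
        with pytest.raises(SpecError, match="n_taxa"):
            spec.validate()

    def test_loading_must_beat_edge_threshold(self):
        with pytest.raises(SpecError, match="0.6"):
            mn.CommunitySpec(latent_loading=0.5).validate()

    def test_unclassified_quota_cannot_hit_planted_taxa(self):
        with pytest.raises(SpecError, match="unclassified"):
            mn.CommunitySpec(unclassified_fraction=0.8).validate()

    def test_hub_ceiling_range(self):
        with pytest.raises(SpecError, match="hub_mean_rel_abund"):
            mn.CommunitySpec(hub_mean_rel_abund=0.05).validate()


class TestGenerateCommunity:
    def test_shapes_and_disjoint_planted_sets(self, default_community):
        spec, table, tax, planted = default_community
        assert table.data.shape == (26, 200)
        assert (table.data.to_numpy() >= 0).all()
        assert len(planted.hub_taxa) == 5
        groups = [planted.partner_map[h] for h in planted.hub_taxa]
        assert all(len(g) == 20 for g in groups)
        everything = (planted.hub_taxa | planted.abundant_peripheral_taxa
                      | planted.partner_taxa)
        assert len(everything) == 5 * 21 + 3

    def test_identical_spec_and_seed_reproduce_bitwise(self):
        spec = mn.CommunitySpec(n_taxa=60, n_hubs=2, partners_per_hub=10,
                                n_abundant_peripherals=2)
        t1, tax1, p1 = mn.generate_community(spec, 9)
        t2, tax2, p2 = mn.generate_community(spec, 9)
        pd.testing.assert_frame_equal(t1.data, t2.data)
        pd.testing.assert_frame_equal(tax1.ranks, tax2.ranks)
        assert p1 == p2
        t3, _, _ = mn.generate_community(spec, 10)
        assert not t3.data.equals(t1.data)

    def test_fixed_depth_per_sample(self, default_community):
        spec, table, _, _ = default_community
        assert (table.data.sum(axis=1) == spec.depth).all()

    def test_relative_output_closes_to_one(self):
        spec = mn.CommunitySpec(output_mode="relative")
        table, _, _ = mn.generate_community(spec, 3)
        assert table.mode == "relative"
        np.testing.assert_allclose(table.data.sum(axis=1), 1.0, atol=1e-9)

    def test_noiseless_unit_loading_gives_exact_rank_correlation(self):
        spec = mn.CommunitySpec(latent_loading=1.0, noise_sd=0.0,
                                output_mode="relative")
        table, _, planted = mn.generate_community(spec, 5)
        corr = mn.spearman_matrix(table).to_frame()
        for hub, partners in planted.partner_map.items():
            for partner in partners:
                assert abs(corr.loc[hub, partner]) == pytest.approx(1.0,
                                                                    abs=1e-12)

    def test_hub_partner_rank_correlation_near_loading(self):
        """Mean sample Spearman |rho| over hub-partner pairs within 0.1 of
        the planted loading, averaged over seeds."""
        spec = mn.CommunitySpec()
        rhos = []
        for seed in range(20):
            table, _, planted = mn.generate_community(spec, seed)
            corr = mn.spearman_matrix(mn.to_relative(table)).to_frame()
            for hub, partners in planted.partner_map.items():
                rhos.extend(abs(corr.loc[hub, p]) for p in partners)
        assert abs(np.mean(rhos) - spec.latent_loading) < 0.1

    def test_abundance_contrast(self, default_community):
        spec, table, _, planted = default_community
        means = mn.mean_relative_abundance(mn.to_relative(table))
        for hub in planted.hub_taxa:
            assert means[hub] <= spec.hub_mean_rel_abund
            assert means[hub] < 0.01
        for taxon in planted.abundant_peripheral_taxa:
            assert means[taxon] > 0.05

    def test_unclassified_fraction_and_planted_annotation(self, default_community):
        spec, table, tax, planted = default_community
        annotated = tax.genus_annotated
        assert (~annotated).sum() == round(0.3 * 200)
        planted_taxa = (planted.hub_taxa | planted.partner_taxa
                        | planted.abundant_peripheral_taxa)
        assert annotated[list(planted_taxa)].all()

    def test_hub_and_peripheral_genus_labels(self, default_community):
        _, _, tax, planted = default_community
        hub_genera = set(tax.genus[list(planted.hub_taxa)])
        assert hub_genera == {"Tepidimonas", "Geobacillus", "Meiothermus",
                              "Sphingomonas", "Anaerosolibacter"}
        periph = set(tax.genus[list(planted.abundant_peripheral_taxa)])
        assert periph == {"Chloroflexus", "Thermus", "Roseiflexus"}


class TestGenerateIsolates:
    def test_planted_identity_counts_per_tier(self):
        identities = (99.0,) * 4 + (97.0,) * 3 + (92.0,) * 2 + (85.0,)
        spec = mn.IsolateSpec(phylum_counts={"Chloroflexi": 10},
                              medium_counts={"SCM": 10},
                              planted_identities=identities)
        records = mn.generate_isolates(spec, 1)
        tiers = pd.Series([r.novelty for r in records]).value_counts()
        assert tiers.to_dict() == {"known_species": 4, "novel_species": 3,
                                   "novel_genus": 2, "novel_higher_taxon": 1}

    def test_repeat_seed_identical_records(self):
        spec = mn.IsolateSpec()
        assert mn.generate_isolates(spec, 5) == mn.generate_isolates(spec, 5)

    def test_zero_records_allowed(self):
        spec = mn.IsolateSpec(phylum_counts={}, medium_counts={})
        assert mn.generate_isolates(spec, 1) == []

    def test_defaults_span_media_phyla_and_tiers(self):
        records = mn.generate_isolates(mn.IsolateSpec(), 2)
        assert len({r.medium for r in records}) >= 2
        assert len({r.phylum for r in records}) >= 2
        assert {r.novelty for r in records} == {
            "known_species", "novel_species", "novel_genus",
            "novel_higher_taxon"}

    def test_mismatched_media_totals_rejected(self):
        spec = mn.IsolateSpec(medium_counts={"SCM": 1})
        with pytest.raises(SpecError, match="sum"):
            spec.validate()


class TestAssayAndMetabolome:
    def test_assay_reproducible_and_well_formed(self):
        spec = mn.AssaySpec()
        a1 = mn.generate_assay(spec, 3)
        a2 = mn.generate_assay(spec, 3)
        pd.testing.assert_frame_equal(a1, a2)
        assert set(a1.columns) == {"strain", "condition", "replicate", "od590"}
        assert (a1["od590"] >= 0).all()
        assert a1.groupby("condition").size().eq(3).all()

    def test_null_shift_rejects_at_nominal_rate(self):
        """Zero planted OD shift -> downstream Welch test at ~alpha."""
        spec = mn.AssaySpec(condition_shifts={"sham": 0.0})
        rejections = 0
        for seed in range(400):
            table = mn.generate_assay(spec, seed)
            treat = table.loc[table["condition"] == "sham", "od590"]
            ctrl = table.loc[table["condition"] == "control", "od590"]
            rejections += mn.growth_test(treat, ctrl).pvalue < 0.05
        assert 0.02 < rejections / 400 < 0.08

    def test_metabolome_noise_free_fold_exact(self):
        spec = mn.MetabolomeSpec(n_compounds=6, n_accumulating=2,
                                 noise_sd=0.0,
                                 fold_range=(2.0, 2.0), weak_fraction=0.0,
                                 named_fold=("planted", 2.0))
        profile, truth = mn.generate_metabolome(spec, 8)
        folds = mn.fold_changes(profile, 0.0, 24.0)
        for compound, planted_fold in truth.items():
            assert folds.loc[compound, "fold"] == pytest.approx(planted_fold,
                                                                abs=1e-9)

    def test_metabolome_reproducible(self):
        spec = mn.MetabolomeSpec(n_compounds=10, n_accumulating=3)
        p1, t1 = mn.generate_metabolome(spec, 6)
        p2, t2 = mn.generate_metabolome(spec, 6)
        pd.testing.assert_frame_equal(p1.data, p2.data)
        pd.testing.assert_series_equal(t1, t2)

    def test_timepoint_validation(self):
        with pytest.raises(SpecError, match="increasing"):
            mn.MetabolomeSpec(timepoints=(0.0, 8.0, 4.0),
                              ramp=(0.0, 0.5, 1.0)).validate()


class TestSpecFromMapping:
    def test_builds_spec_with_overrides(self):
        spec = spec_from_mapping("community", {"n_taxa": 80, "n_hubs": 2,
                                               "partners_per_hub": 10})
        assert isinstance(spec, mn.CommunitySpec)
        assert (spec.n_taxa, spec.n_hubs) == (80, 2)

    def test_unknown_keys_rejected(self):
        with pytest.raises(SpecError, match="unknown"):
            spec_from_mapping("assay", {"bogus": 1})
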