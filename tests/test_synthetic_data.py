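import numpy as np
import pytest

from phyloloc import age_dating as ad
from phyloloc import synthetic_data as sd
from phyloloc.ppi_compartments import expected_wc_fraction
from phyloloc.vocab import BRANCH_LABELS, COMPARTMENTS


def _params(**kw):
    defaults = dict(n_genes=300, n_edges=500, n_paralog_pairs=30,
                    sequence_length=50, seed=42)
    defaults.update(kw)
    return sd.SimulationParams(**defaults)


class TestGeneHistory:
    def test_no_loss_oldest_present_everywhere(self):
        weights = {b: 0.0 for b in BRANCH_LABELS}
        weights["br-2"] = 1.0
        presence, _, truth = sd.gen_gene_history(
            _params(branch_birth_weights=weights, outgroup_loss_prob=0.0)
        )
        assert presence.all().all()
        assert set(truth.true_branch.values()) == {"br-2"}

    def test_species_specific_absent_everywhere(self):
        weights = {b: 0.0 for b in BRANCH_LABELS}
        weights["br6"] = 1.0
        presence, _, _ = sd.gen_gene_history(
            _params(branch_birth_weights=weights, outgroup_loss_prob=0.0)
        )
        assert not presence.any().any()

    def test_total_loss_erases_all_presence(self):
        presence, _, _ = sd.gen_gene_history(_params(outgroup_loss_prob=1.0))
        assert not presence.any().any()

    def test_zero_genes_gives_empty_matrix(self):
        presence, secondary, truth = sd.gen_gene_history(_params(n_genes=0))
        assert presence.empty and secondary.empty and not truth.true_branch

    def test_full_branch_recovery_without_loss(self):
        presence, _, truth = sd.gen_gene_history(_params(n_genes=500))
        ages = ad.assign_ages(presence, ad.default_clade_map())
        assert all(ages[g] == b for g, b in truth.true_branch.items())

    def test_recovery_degrades_monotonically_in_loss(self):
        rates = []
        for loss in (0.0, 0.2, 0.5):
            presence, _, truth = sd.gen_gene_history(
                _params(n_genes=800, outgroup_loss_prob=loss, seed=9)
            )
            ages = ad.assign_ages(presence, ad.default_clade_map())
            rates.append(
                np.mean([ages[g] == b for g, b in truth.true_branch.items()])
            )
        assert rates[0] == 1.0
        assert rates[0] >= rates[1] >= rates[2]
        assert rates[2] < rates[0]

    def test_loss_correction_restores_older_branch_recovery(self):
        """With loss confined to the br-1-level clade, the secondary deep
        outgroup lets the correction restore br-1 assignments."""
        presence, secondary, truth = sd.gen_gene_history(
            _params(n_genes=2000, outgroup_loss_prob={"sleb": 0.15}, seed=5)
        )
        ages = ad.assign_ages(presence, ad.default_clade_map()).to_dict()
        br1_genes = [g for g, b in truth.true_branch.items() if b == "br-1"]
        before = np.mean([ages[g] == "br-1" for g in br1_genes])
        corrected, moved = ad.apply_loss_correction(
            ages, secondary.to_dict(), "br0", "br-1"
        )
        after = np.mean([corrected[g] == "br-1" for g in br1_genes])
        assert moved > 0
        assert after >= before
        assert after == 1.0


class TestLocalizations:
    def test_single_label_without_multi_rate(self):
        params = _params(multi_label_rate=0.0)
        _, _, truth = sd.gen_gene_history(params)
        table = sd.gen_localizations(truth, params)
        assert ((table > 0.5).sum(axis=1) == 1).all()

    def test_point_mass_preference_forces_compartment(self):
        pref = sd.uniform_compartment_preference()
        point = np.zeros(len(COMPARTMENTS))
        point[COMPARTMENTS.index("Extracellular")] = 1.0
        pref["young"] = point
        params = _params(compartment_preference=pref, multi_label_rate=0.0)
        _, _, truth = sd.gen_gene_history(params)
        sd.gen_localizations(truth, params)
        young = [g for g, b in truth.true_branch.items()
                 if b not in ("br-2", "br-1", "br0")]
        assert young
        assert all(truth.compartments[g] == frozenset({"Extracellular"}) for g in young)

    def test_same_seed_identical_tables(self):
        params = _params()
        _, _, t1 = sd.gen_gene_history(params)
        _, _, t2 = sd.gen_gene_history(params)
        assert sd.gen_localizations(t1, params).equals(sd.gen_localizations(t2, params))


class TestPpi:
    def test_neutral_preference_matches_random_pairing(self):
        """At preference 1 the realized within-compartment edge fraction sits
        at the closed-form random-pairing expectation (binomial tolerance)."""
        params = _params(n_genes=400, n_edges=10_000,
                         within_edge_preference=1.0, seed=3)
        _, _, truth = sd.gen_gene_history(params)
        sd.gen_localizations(truth, params)
        links = sd.gen_ppi(truth, params)
        sets = truth.compartments
        wc = np.mean([bool(sets[a] & sets[b])
                      for a, b in links[["protein_a", "protein_b"]].itertuples(index=False)])
        expected = expected_wc_fraction(sets)
        se = np.sqrt(expected * (1 - expected) / len(links))
        assert abs(wc - expected) < 4 * se

    def test_infinite_preference_all_within(self):
        params = _params(n_genes=200, n_edges=300,
                         within_edge_preference=float("inf"), multi_label_rate=0.0)
        _, _, truth = sd.gen_gene_history(params)
        sd.gen_localizations(truth, params)
        links = sd.gen_ppi(truth, params)
        sets = truth.compartments
        assert all(sets[a] & sets[b]
                   for a, b in links[["protein_a", "protein_b"]].itertuples(index=False))

    def test_zero_edges_empty_table(self):
        params = _params(n_edges=0)
        _, _, truth = sd.gen_gene_history(params)
        sd.gen_localizations(truth, params)
        assert sd.gen_ppi(truth, params).empty

    def test_infeasible_edge_count_rejected(self):
        params = _params(n_genes=4, n_edges=100)
        _, _, truth = sd.gen_gene_history(params)
        sd.gen_localizations(truth, params)
        with pytest.raises(ValueError):
            sd.gen_ppi(truth, params)

    def test_wc_fraction_monotone_in_preference(self):
        fractions = []
        for pref in (1.0, 3.0, 10.0):
            params = _params(n_genes=300, n_edges=4000,
                             within_edge_preference=pref, seed=8)
            _, _, truth = sd.gen_gene_history(params)
            sd.gen_localizations(truth, params)
            links = sd.gen_ppi(truth, params)
            sets = truth.compartments
            fractions.append(np.mean([
                bool(sets[a] & sets[b])
                for a, b in links[["protein_a", "protein_b"]].itertuples(index=False)
            ]))
        assert fractions[0] <= fractions[1] <= fractions[2]
        assert fractions[2] > fractions[0]


class TestPathways:
    def test_two_equiprobable_pathways_half_cofunctional(self):
        params = _params(n_genes=2000, n_pathways=2, cofunction_boost=1.0, seed=6)
        _, _, truth = sd.gen_gene_history(params)
        mapping = sd.gen_pathways(truth, params)
        genes = sorted(mapping)
        rng = np.random.default_rng(0)
        ii = rng.integers(0, len(genes), 4000)
        jj = rng.integers(0, len(genes), 4000)
        keep = ii != jj
        co = np.mean([
            bool(mapping[genes[i]] & mapping[genes[j]])
            for i, j in zip(ii[keep], jj[keep])
        ])
        assert co == pytest.approx(0.5, abs=0.05)

    def test_single_pathway_everyone_cofunctional(self):
        params = _params(n_pathways=1)
        _, _, truth = sd.gen_gene_history(params)
        mapping = sd.gen_pathways(truth, params)
        universe = set().union(*mapping.values())
        assert len(universe) == 1

    def test_zero_pathways_rejected(self):
        with pytest.raises(ValueError):
            _params(n_pathways=0).validate()

    def test_same_seed_identical_mapping(self):
        params = _params()
        _, _, truth = sd.gen_gene_history(params)
        assert sd.gen_pathways(truth, params) == sd.gen_pathways(truth, params)


class TestParalogsAndSequences:
    def test_zero_substitution_pure_k_mix_gives_identical_sequences(self):
        params = _params(
            pattern_fractions={"K": 1.0, "KE": 0.0, "S": 0.0, "E": 0.0, "SE": 0.0},
            paralog_substitution_rate_k=0.0,
        )
        _, _, truth = sd.gen_gene_history(params)
        loc = sd.gen_localizations(truth, params)
        pairs, seqs = sd.gen_paralogs_and_sequences(truth, params, loc)
        assert len(pairs) > 0
        for parent, offspring in pairs.itertuples(index=False):
            assert seqs[parent] == seqs[offspring]
            assert truth.compartments[parent] == truth.compartments[offspring]

    def test_designated_e_pairs_are_disjoint(self):
        params = _params(
            pattern_fractions={"K": 0.0, "KE": 0.0, "S": 0.0, "E": 1.0, "SE": 0.0}
        )
        _, _, truth = sd.gen_gene_history(params)
        loc = sd.gen_localizations(truth, params)
        pairs, _ = sd.gen_paralogs_and_sequences(truth, params, loc)
        assert len(pairs) > 0
        for parent, offspring in pairs.itertuples(index=False):
            assert not (truth.compartments[parent] & truth.compartments[offspring])

    def test_parent_strictly_older(self):
        params = _params()
        _, _, truth = sd.gen_gene_history(params)
        loc = sd.gen_localizations(truth, params)
        pairs, _ = sd.gen_paralogs_and_sequences(truth, params, loc)
        for parent, offspring in pairs.itertuples(index=False):
            assert (BRANCH_LABELS.index(truth.true_branch[parent])
                    < BRANCH_LABELS.index(truth.true_branch[offspring]))

    def test_same_seed_identical_fasta(self):
        params = _params()
        _, _, t1 = sd.gen_gene_history(params)
        loc1 = sd.gen_localizations(t1, params)
        _, s1 = sd.gen_paralogs_and_sequences(t1, params, loc1)
        _, _, t2 = sd.gen_gene_history(params)
        loc2 = sd.gen_localizations(t2, params)
        _, s2 = sd.gen_paralogs_and_sequences(t2, params, loc2)
        assert s1 == s2


class TestDatasetContracts:
    def test_full_simulation_bit_reproducible(self, small_dataset):
        again = sd.simulate(small_dataset.params)
        assert again.presence.equals(small_dataset.presence)
        assert again.localization.equals(small_dataset.localization)
        assert again.links.equals(small_dataset.links)
        assert again.sequences == small_dataset.sequences
        assert again.pathways == small_dataset.pathways
        assert again.paralog_pairs.equals(small_dataset.paralog_pairs)

    def test_localization_table_consistent_with_truth(self, small_dataset):
        from phyloloc.localization import called_sets_from_table

        called = called_sets_from_table(small_dataset.localization)
        assert called == small_dataset.truth.compartments

    def test_written_files_round_trip(self, small_dataset, tmp_path):
        from phyloloc import tables_io

        paths = small_dataset.write_all(tmp_path)
        presence = tables_io.read_presence_matrix(paths["presence"])
        assert presence.equals(small_dataset.presence)
        loc = tables_io.read_localization_table(paths["localization"])
        assert np.allclose(loc.values, small_dataset.localization.values)
        seqs = tables_io.read_fasta(paths["fasta"])
        assert seqs == small_dataset.sequences
        pathways = tables_io.read_pathways(paths["pathways"])
        assert pathways == small_dataset.pathways
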