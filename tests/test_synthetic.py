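"""Generator contracts: determinism, planted structure, manifest fidelity."""

from __future__ import annotations

import itertools
import json

import numpy as np
import pytest

from marinepde import conservation, synthetic
from marinepde.synthetic import (
    PlantSpec,
    SyntheticError,
    generate_proteome,
    generate_reference_set,
    make_study_bundle,
    simulate_conserved_trait,
    simulate_tree,
)


class TestTreeSimulation:
    def test_leaf_count_and_unique_labels(self):
        tree = simulate_tree(16, seed=1)
        labels = conservation.leaf_labels(tree)
        assert len(labels) == 16 and len(set(labels)) == 16

    @pytest.mark.parametrize("model", ["yule", "coalescent"])
    def test_deterministic_per_seed(self, model):
        t1 = simulate_tree(12, model=model, seed=9)
        t2 = simulate_tree(12, model=model, seed=9)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")
        t3 = simulate_tree(12, model=model, seed=10)
        assert t1.as_string(schema="newick") != t3.as_string(schema="newick")

    def test_too_few_leaves_rejected(self):
        with pytest.raises(SyntheticError):
            simulate_tree(1, seed=0)

    def test_yule_depth_matches_closed_form_expectation(self):
        # E[root-to-tip depth] = sum_{k=2..n} 1/(k * birth_rate)
        n, rate, reps = 40, 1.0, 200
        expected = sum(1.0 / (k * rate) for k in range(2, n + 1))
        depths = []
        for seed in range(reps):
            tree = simulate_tree(n, seed=seed, birth_rate=rate)
            tree.calc_node_ages(ultrametricity_precision=1e-6)
            depths.append(tree.seed_node.age)
        depths = np.asarray(depths)
        se = depths.std(ddof=1) / np.sqrt(reps)
        assert abs(depths.mean() - expected) < 3 * se

    def test_branch_lengths_positive(self):
        tree = simulate_tree(20, seed=3)
        for edge in tree.preorder_edge_iter():
            if edge.head_node is not tree.seed_node:
                assert edge.length is not None and edge.length > 0


class TestTraitSimulation:
    def test_random_mode_exact_count(self):
        tree = simulate_tree(20, seed=4)
        trait = simulate_conserved_trait(tree, "random",
                                         {"n_positive": 7}, seed=1)
        assert sum(trait.values()) == 7

    def test_clade_planted_recovered_by_consentrait(self):
        tree = simulate_tree(24, seed=5)
        trait = simulate_conserved_trait(
            tree, "clade-planted", {"clade_sizes": [2]}, seed=1)
        report = conservation.consentrait(tree, trait)
        assert report.n_genotypes == 1
        assert report.clades[0].clade_size == 2
        assert not report.clades[0].is_singleton

    def test_oversized_clade_request_rejected(self):
        tree = simulate_tree(8, seed=6)
        with pytest.raises(SyntheticError, match="exceeds"):
            simulate_conserved_trait(tree, "clade-planted",
                                     {"clade_sizes": [100]}, seed=0)

    def test_markov_clustered_deeper_than_random_sign_test(self):
        from scipy.stats import binomtest

        tree = simulate_tree(32, seed=13)
        wins = losses = 0
        for seed in range(100):
            markov = simulate_conserved_trait(
                tree, "two-state-markov",
                {"gain": 0.05, "loss": 0.4, "root_state": 1}, seed=seed)
            k = sum(markov.values())
            if k == 0 or k == len(markov):
                continue
            random_trait = simulate_conserved_trait(
                tree, "random", {"n_positive": k}, seed=seed + 10_000)
            tau_m = conservation.consentrait(tree, markov).tau_d
            tau_r = conservation.consentrait(tree, random_trait).tau_d
            if tau_m > tau_r:
                wins += 1
            elif tau_m < tau_r:
                losses += 1
        assert binomtest(wins, wins + losses,
                         alternative="greater").pvalue < 0.01

    def test_growing_planted_clades_deepen_tau(self):
        tree = simulate_tree(48, seed=17)
        taus = []
        for size in (3, 8, 16):
            vals = []
            for seed in range(15):
                trait = simulate_conserved_trait(
                    tree, "clade-planted", {"clade_sizes": [size]},
                    seed=seed)
                vals.append(conservation.consentrait(tree, trait).tau_d)
            taus.append(np.mean(vals))
        assert taus[0] < taus[1] < taus[2]


class TestReferenceGeneration:
    def test_counts_and_domain_rows(self):
        refset, domains, manifest = generate_reference_set(n_per_type=5,
                                                           seed=1)
        assert len(refset) == 50
        assert len(domains) == 50
        assert manifest["n_references"] == 50

    def test_domain_spans_inside_sequences(self):
        refset, _, _ = generate_reference_set(n_per_type=3, seed=2)
        for ref in refset:
            for d in ref.domains:
                assert 1 <= d.start <= d.end <= len(ref.sequence)

    def test_cross_type_domain_blocks_dissimilar(self):
        _, _, manifest = generate_reference_set(n_per_type=1, seed=3)
        blocks = manifest["domain_blocks"]
        idents = []
        for fa, fb in itertools.combinations(sorted(blocks), 2):
            a, b = blocks[fa], blocks[fb]
            matches = sum(x == y for x, y in zip(a, b))
            idents.append(matches / len(a))
        assert np.mean(idents) < 0.25


@pytest.fixture(scope="module")
def refset():
    return generate_reference_set(n_per_type=2, seed=4)[0]


class TestProteomeGeneration:
    def test_identity_targeting_within_two_points(self, refset):
        specs = [PlantSpec(refset.ids[0], t) for t in (35.0, 60.0, 90.0)]
        proteome, truth, _ = generate_proteome(refset, specs, n_decoys=0,
                                               seed=1, genome_id="g")
        ref = refset[refset.ids[0]]
        for spec, record in zip(specs, truth):
            planted = proteome[record.protein_id]
            assert len(planted) == len(ref.sequence)
            hamming = sum(a == b for a, b in zip(planted, ref.sequence))
            identity = 100.0 * hamming / len(ref.sequence)
            assert abs(identity - spec.target_identity) <= 2.0
            assert record.achieved_identity == round(identity, 2)

    def test_intact_plants_preserve_domain_residues(self, refset):
        rid = refset.ids[0]
        ref = refset[rid]
        proteome, truth, qdoms = generate_proteome(
            refset, [PlantSpec(rid, 60.0)], n_decoys=0, seed=2,
            genome_id="g")
        d = ref.domains[0]
        planted = proteome[truth[0].protein_id]
        assert planted[d.start - 1:d.end] == ref.sequence[d.start - 1:d.end]
        assert truth[0].protein_id in qdoms

    def test_scrambled_plants_have_no_domain_row(self, refset):
        rid = refset.ids[0]
        _, truth, qdoms = generate_proteome(
            refset, [PlantSpec(rid, 90.0, domain_intact=False)],
            n_decoys=0, seed=2, genome_id="g")
        assert truth[0].protein_id not in qdoms

    def test_decoys_preserve_composition(self, refset):
        proteome, _, _ = generate_proteome(refset, [], n_decoys=4, seed=3,
                                           genome_id="g")
        compositions = {tuple(sorted(r.sequence)) for r in refset}
        for seq in proteome.values():
            assert tuple(sorted(seq)) in compositions

    def test_unreachable_identity_refused(self, refset):
        with pytest.raises(SyntheticError, match="20%"):
            generate_proteome(refset, [PlantSpec(refset.ids[0], 15.0)],
                              seed=0)


class TestStudyBundle:
    def test_byte_identical_regeneration(self):
        b1 = make_study_bundle(seed=5)
        b2 = make_study_bundle(seed=5)
        assert b1.tree_newick == b2.tree_newick
        assert json.dumps(b1.manifest, sort_keys=True) == \
            json.dumps(b2.manifest, sort_keys=True)
        assert b1.proteomes == b2.proteomes
        assert b1.taxonomy.equals(b2.taxonomy)

    def test_genera_are_tree_contiguous_clades(self, bundle):
        # every genus must correspond to exactly one clade of the tree
        by_genus = bundle.taxonomy.groupby("genus").groups
        tip_sets = {
            frozenset(lf.taxon.label for lf in node.leaf_iter())
            for node in bundle.tree.preorder_node_iter()
        }
        for genus, members in by_genus.items():
            assert frozenset(members) in tip_sets

    def test_trait_table_matches_genus_configs(self, bundle):
        for genus_cfg in bundle.config.genera:
            ids = [g for g in bundle.genome_ids
                   if g.startswith(genus_cfg.name + "_")]
            for enzyme, blocks in genus_cfg.traits.items():
                expected = set()
                for start, count in blocks:
                    expected.update(ids[start:start + count])
                positive = {
                    g for g in ids if bundle.trait_truth.loc[g, enzyme]
                }
                assert positive == expected

    def test_inconsistent_config_rejected(self):
        bad = synthetic.GenusConfig(name="G", n_genomes=10)
        with pytest.raises(SyntheticError):
            synthetic.GenusConfig(name="G", n_genomes=10,
                                  traits={"chitinase": ((5, 8),)})
        assert bad.traits == {}

    def test_qc_expectations_recorded(self, bundle):
        ids = {r.assembly_id for r in bundle.assembly_records}
        for aid in bundle.manifest["qc_expected_fail"]:
            assert aid in ids
        assert "soil_00" in ids

    def test_write_produces_readable_files(self, bundle, tmp_path):
        from marinepde import qc, refdb, traits

        bundle.write(tmp_path)
        refset = refdb.attach_domains(
            refdb.load_reference_set(tmp_path / "references.faa",
                                     tmp_path / "reference_metadata.tsv"),
            refdb.read_domain_table(tmp_path / "reference_domains.tsv"),
        )
        assert refset.ids == bundle.refset.ids
        records = qc.read_assembly_metadata(tmp_path / "assembly_metadata.tsv")
        assert len(records) == len(bundle.assembly_records)
        tax = traits.read_taxonomy(tmp_path / "taxonomy.tsv")
        assert set(tax.index) == set(bundle.taxonomy.index)
        tree = conservation.read_tree(tmp_path / "tree.nwk")
        assert sorted(conservation.leaf_labels(tree)) == \
            sorted(bundle.genome_ids)
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["seed"] == bundle.seed
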