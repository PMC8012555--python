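#!/usr/bin/env python
"""Stage 6 — enzyme co-occurrence networks and threshold robustness.

Computes Pearson/phi correlations and Jaccard distances between enzyme
presence/absence vectors over all genomes and within each genus with >= 25
genomes; keeps edges with |r| > 0.4 and p < 0.05.  Then re-annotates at
identity 25% and 50%, rebuilds the genus networks, and reports how many
edges from the main (30%) run are supported by the alternative thresholds.
"""

from pathlib import Path

from Bio import SeqIO

from marinepde import annotate, correlate, qc, refdb, traits

ROOT = Path(__file__).resolve().parent.parent / "results"


def _edges_at_identity(min_identity, genomes, refset, qdoms, taxonomy):
    thresholds = annotate.AnnotationThresholds(min_identity=min_identity)
    annotations = []
    for gid in genomes:
        proteome = {
            rec.id: str(rec.seq)
            for rec in SeqIO.parse(
                ROOT / "bundle" / "proteomes" / f"{gid}.faa", "fasta")
        }
        annotations.extend(
            annotate.annotate_genome(proteome, refset, qdoms, thresholds,
                                     genome_id=gid))
    matrix = traits.build_trait_matrix(annotations, genomes,
                                       refdb.ENZYME_TYPES)
    return correlate.genus_networks(matrix, taxonomy)


def main() -> None:
    bundle_dir = ROOT / "bundle"
    matrix = traits.read_trait_matrix(ROOT / "trait_counts.tsv")
    taxonomy = traits.read_taxonomy(bundle_dir / "taxonomy.tsv")

    edges = correlate.genus_networks(matrix, taxonomy)
    correlate.write_edges(edges, ROOT / "correlation_edges.tsv")
    correlate.write_network(edges, ROOT / "correlation_network.gml")
    print("correlated enzyme pairs (|r| > 0.4, p < 0.05):")
    print(correlate.edges_to_frame(edges).to_string(index=False))

    refset = refdb.attach_domains(
        refdb.load_reference_set(bundle_dir / "references.faa",
                                 bundle_dir / "reference_metadata.tsv"),
        refdb.read_domain_table(bundle_dir / "reference_domains.tsv"),
    )
    qdoms = refdb.domains_by_id(
        refdb.read_domain_table(bundle_dir / "query_domains.tsv"))
    genomes = [r.assembly_id
               for r in qc.read_assembly_metadata(ROOT / "qc_passed.tsv")]

    comparison = correlate.compare_edge_sets({
        "identity30": edges,
        "identity25": _edges_at_identity(25.0, genomes, refset, qdoms,
                                         taxonomy),
        "identity50": _edges_at_identity(50.0, genomes, refset, qdoms,
                                         taxonomy),
    })
    print(f"\nedge sets: {comparison['set_sizes']}")
    print(f"main-set edges supported by >= 1 alternative threshold: "
          f"{comparison['main_supported']} "
          f"({100 * comparison['main_supported_fraction']:.0f}%)")


if __name__ == "__main__":
    main()
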