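#!/usr/bin/env python
"""Stage 4 — trait matrix and taxonomic distribution.

Aggregates accepted annotations into the genome x enzyme matrix, counts
distinct positive taxa per enzyme at every rank, reports per-genus positive
ratios for well-sampled genera, and computes fold expansion of each
enzyme's genus-level range relative to the reference set's source genera.
"""

from pathlib import Path

import pandas as pd

from marinepde import annotate, qc, refdb, traits

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    bundle_dir = ROOT / "bundle"
    annotations = annotate.read_annotations(ROOT / "annotations.tsv")
    genomes = [r.assembly_id
               for r in qc.read_assembly_metadata(ROOT / "qc_passed.tsv")]
    taxonomy = traits.read_taxonomy(bundle_dir / "taxonomy.tsv")

    matrix = traits.build_trait_matrix(annotations, genomes,
                                       refdb.ENZYME_TYPES)
    traits.write_trait_matrix(matrix, ROOT / "trait_counts.tsv",
                              ROOT / "trait_binary.tsv")

    counts = traits.distribution_counts(matrix, taxonomy)
    counts.to_csv(ROOT / "taxa_counts.tsv", sep="\t")
    present = counts[counts["genus"] > 0]
    print("distinct positive taxa per enzyme (phylum -> genus):")
    print(present.to_string())

    ratio_tables = []
    for enzyme in matrix.enzyme_types:
        table = traits.taxon_positive_ratio(matrix, taxonomy, "genus",
                                            enzyme, min_genomes=25)
        table.insert(0, "enzyme_type", enzyme)
        ratio_tables.append(table[table["n_positive"] > 0])
    ratios = pd.concat(ratio_tables, ignore_index=True)
    ratios.to_csv(ROOT / "genus_ratios.tsv", sep="\t", index=False)
    print("\npositive ratios in genera with >= 25 genomes:")
    print(ratios.to_string(index=False))

    refset = refdb.load_reference_set(bundle_dir / "references.faa",
                                      bundle_dir / "reference_metadata.tsv")
    ref_genera = traits.reference_taxa_counts(refset, rank_index=4)
    annotated_genera = counts["genus"].to_dict()
    folds = traits.fold_expansion(
        {e: c for e, c in annotated_genera.items() if c > 0}, ref_genera)
    pd.Series(folds, name="fold").rename_axis("enzyme_type").to_csv(
        ROOT / "fold_expansion.tsv", sep="\t")
    print("\ngenus-range fold expansion vs the reference set:", folds)


if __name__ == "__main__":
    main()
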