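#!/usr/bin/env python
"""Stage 5 — phylogenetic conservation (consenTRAIT).

For every enzyme with at least one positive tree tip, detects the maximal
clades in which >90% of tips carry the enzyme, reports genotype counts,
singleton fractions, mean clade sizes and the mean trait depth tau_D, and
converts each depth to the 16S-identity scale.
"""

from pathlib import Path

from marinepde import conservation, traits

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    tree = conservation.read_tree(ROOT / "bundle" / "tree.nwk")
    matrix = traits.read_trait_matrix(ROOT / "trait_counts.tsv")
    table, reports = conservation.conservation_table(tree, matrix)
    table.to_csv(ROOT / "conservation.tsv", sep="\t", index=False)
    print("consenTRAIT conservation summary:")
    print(table.to_string(index=False))
    deepest = table.loc[table["tau_d"].idxmax()]
    print(f"\nmost conserved (deepest) trait: {deepest['enzyme_type']} "
          f"(tau_D = {deepest['tau_d']:.4f})")
    print(f"wrote {ROOT/'conservation.tsv'}")


if __name__ == "__main__":
    main()
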