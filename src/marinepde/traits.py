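"""Genome x enzyme trait matrices and taxonomic aggregation.

A genome "has" an enzyme when at least one of its proteins was accepted by
the annotation pipeline for that enzyme type.  The binary presence/absence
view drives the conservation and correlation analyses; the parallel
gene-count matrix is kept for heatmap-style exports.

Aggregations: per-taxon positive ratios at any rank (e.g. what fraction of a
genus encodes chitinases), counts of distinct positive taxa per enzyme and
rank, and fold expansion of annotated taxon ranges relative to the reference
set's known ranges.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotate import PDEAnnotation
from .refdb import ReferenceSet

RANKS = ("phylum", "class", "order", "family", "genus")
UNKNOWN = "unknown"


class TraitError(ValueError):
    pass


@dataclass
class TraitMatrix:
    """Gene counts and derived binary presence/absence, genomes x enzymes."""

    counts: pd.DataFrame  # int counts, index=genome_ids, columns=enzyme_types

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise TraitError("negative gene counts")

    @property
    def values(self) -> pd.DataFrame:
        """Binary view: 1 iff the genome carries >= 1 accepted gene."""
        return (self.counts >= 1).astype(int)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def enzyme_types(self) -> list[str]:
        return list(self.counts.columns)

    def positives(self, enzyme: str) -> list[str]:
        v = self.values[enzyme]
        return list(v.index[v == 1])


def build_trait_matrix(
    annotations: Iterable[PDEAnnotation],
    genome_ids: Sequence[str],
    enzyme_types: Sequence[str],
) -> TraitMatrix:
    """Aggregate accepted annotations into a counts matrix.

    Every genome in ``genome_ids`` gets a row even when it has no accepted
    annotation (all-zero rows are informative: they are the trait-negative
    genomes).  An annotation for a genome or enzyme type outside the given
    universes is an error.
    """
    counts = pd.DataFrame(
        0, index=list(genome_ids), columns=list(enzyme_types), dtype=int
    )
    for ann in annotations:
        if ann.genome_id not in counts.index:
            raise TraitError(f"annotation references unknown genome "
                             f"{ann.genome_id!r}")
        if ann.enzyme_type not in counts.columns:
            raise TraitError(f"annotation references unknown enzyme type "
                             f"{ann.enzyme_type!r}")
        counts.loc[ann.genome_id, ann.enzyme_type] += 1
    return TraitMatrix(counts)


def _check_taxonomy(matrix: TraitMatrix, taxonomy: pd.DataFrame) -> pd.DataFrame:
    missing = set(matrix.genome_ids) - set(taxonomy.index)
    if missing:
        raise TraitError(
            f"taxonomy missing for genomes {sorted(missing)[:5]} "
            f"({len(missing)} total)"
        )
    return taxonomy.reindex(matrix.genome_ids).fillna(UNKNOWN)


def taxon_positive_ratio(
    matrix: TraitMatrix,
    taxonomy: pd.DataFrame,
    level: str,
    enzyme: str,
    min_genomes: int | None = None,
) -> pd.DataFrame:
    """Percent of trait-positive genomes per taxon at one rank.

    Taxa labelled ``unknown`` at the rank are excluded.  ``min_genomes``
    suppresses small taxa (e.g. 25 for genus-level reporting).  Returns a
    DataFrame (taxon, n_genomes, n_positive, ratio) sorted by descending
    ratio then taxon name.
    """
    if level not in RANKS:
        raise TraitError(f"unknown rank {level!r}; expected one of {RANKS}")
    if enzyme not in matrix.enzyme_types:
        raise TraitError(f"unknown enzyme {enzyme!r}")
    tax = _check_taxonomy(matrix, taxonomy)
    df = pd.DataFrame({
        "taxon": tax[level],
        "positive": matrix.values[enzyme].to_numpy(),
    })
    df = df[df["taxon"] != UNKNOWN]
    grouped = df.groupby("taxon", sort=True)["positive"].agg(["count", "sum"])
    grouped.columns = ["n_genomes", "n_positive"]
    if min_genomes is not None:
        grouped = grouped[grouped["n_genomes"] >= min_genomes]
    grouped["ratio"] = 100.0 * grouped["n_positive"] / grouped["n_genomes"]
    out = grouped.reset_index().sort_values(
        ["ratio", "taxon"], ascending=[False, True]
    ).reset_index(drop=True)
    return out


def distribution_counts(matrix: TraitMatrix,
                        taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Distinct positive taxa per enzyme at every rank.

    A taxon is positive when >= 1 member genome carries the enzyme; genomes
    with an unknown label at a rank do not contribute a taxon at that rank.
    Returns a DataFrame indexed by enzyme with one column per rank.
    """
    tax = _check_taxonomy(matrix, taxonomy)
    out = pd.DataFrame(0, index=matrix.enzyme_types, columns=list(RANKS),
                       dtype=int)
    values = matrix.values
    for enzyme in matrix.enzyme_types:
        positive_genomes = values.index[values[enzyme] == 1]
        for rank in RANKS:
            labels = set(tax.loc[positive_genomes, rank]) - {UNKNOWN}
            out.loc[enzyme, rank] = len(labels)
    out.index.name = "enzyme_type"
    return out


def reference_taxa_counts(refset: ReferenceSet, rank_index: int) -> dict[str, int]:
    """Distinct source taxa per enzyme type in the reference set, using the
    lineage element at ``rank_index`` (0 = highest rank recorded)."""
    taxa: dict[str, set[str]] = {}
    for ref in refset:
        if len(ref.lineage) <= rank_index:
            continue
        label = ref.lineage[rank_index]
        if label and label != UNKNOWN:
            taxa.setdefault(ref.enzyme_type, set()).add(label)
    return {etype: len(s) for etype, s in taxa.items()}


def fold_expansion(
    annotated_taxa_counts: Mapping[str, int],
    reference_taxa_counts: Mapping[str, int],
) -> dict[str, float | str]:
    """Per-enzyme fold change of taxon range: annotated / reference.

    Reported to two decimals; an enzyme absent from the reference range
    (reference count 0) has no defined fold and reports ``"new"``.
    """
    out: dict[str, float | str] = {}
    for enzyme, annotated in annotated_taxa_counts.items():
        reference = reference_taxa_counts.get(enzyme, 0)
        if reference == 0:
            out[enzyme] = "new"
        else:
            out[enzyme] = round(annotated / reference, 2)
    return out


# ---------------------------------------------------------------------------
# I/O


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Read a taxonomy TSV (genome_id + rank columns); missing ranks become
    ``unknown``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "genome_id" not in df.columns:
        raise TraitError(f"{path}: missing genome_id column")
    df = df.set_index("genome_id")
    for rank in RANKS:
        if rank not in df.columns:
            df[rank] = UNKNOWN
    return df[list(RANKS)].fillna(UNKNOWN)


def write_taxonomy(taxonomy: pd.DataFrame, path: str | Path) -> None:
    taxonomy.rename_axis("genome_id").reset_index().to_csv(
        path, sep="\t", index=False
    )


def write_trait_matrix(matrix: TraitMatrix, counts_path: str | Path,
                       binary_path: str | Path | None = None) -> None:
    matrix.counts.rename_axis("genome_id").to_csv(counts_path, sep="\t")
    if binary_path is not None:
        matrix.values.rename_axis("genome_id").to_csv(binary_path, sep="\t")


def read_trait_matrix(counts_path: str | Path) -> TraitMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="genome_id")
    return TraitMatrix(counts.astype(int))
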