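"""consenTRAIT: phylogenetic conservation of binary traits.

Given a rooted tree with branch lengths and a binary trait over its tips,
the algorithm walks the tree from the root and accepts an internal node as a
trait-conserved clade root when strictly more than 90% of its tips carry the
trait (threshold configurable); accepted clades are maximal — the walk does
not descend below an accepted node.  Trait-positive tips not covered by any
accepted clade are counted as singleton clades of size one.

The depth of a clade is the mean branch-length distance from its
trait-positive member tips to the clade root; a singleton's depth is, by
convention, half its terminal branch length (configurable, since different
conventions exist and published tables rarely say which was used).  The mean
trait depth tau_D is the unweighted mean of clade depths, singletons
included.

On a 16S rRNA gene tree, depths translate to sequence identities:
identity% = (1 - 2 * tau_D) * 100, so tau_D = 0.02 corresponds to clades of
~96% 16S identity.  Depths from trees with different total lengths (e.g. a
core-gene tree) are not directly comparable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import pandas as pd

from .traits import TraitMatrix

logger = logging.getLogger(__name__)

SINGLETON_MODES = ("half-branch", "full-branch", "half-nearest-positive")


class TreeError(ValueError):
    pass


@dataclass(frozen=True)
class TraitClade:
    """One detected trait-conserved clade (or singleton)."""

    members: tuple[str, ...]      # trait-positive tip labels in the clade
    clade_size: int               # number of positive members
    n_tips: int                   # all tips under the clade root
    depth: float                  # mean member-to-clade-root distance
    is_singleton: bool


@dataclass(frozen=True)
class ConsenTraitReport:
    """Per-trait conservation summary (one table row per enzyme)."""

    enzyme_type: str
    clades: tuple[TraitClade, ...]
    n_genotypes: int         # detected clades, singletons included
    pct_singletons: float    # percent of clades that are singletons
    mean_clade_size: float   # positive tips in clades / n_genotypes
    tau_d: float             # unweighted mean of clade depths

    @property
    def identity_pct(self) -> float:
        return tau_to_identity(self.tau_d)


# ---------------------------------------------------------------------------
# tree utilities


def read_tree(path: str | Path) -> dendropy.Tree:
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = True
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root a tree at its midpoint (helper for unrooted inputs)."""
    tree = tree.clone(depth=1)
    tree.reroot_at_midpoint(update_bipartitions=False)
    tree.is_rooted = True
    return tree


def _require_rooted(tree: dendropy.Tree) -> None:
    seed = tree.seed_node
    if tree.is_rooted or len(seed.child_nodes()) == 2:
        return
    raise TreeError(
        "tree appears unrooted (basal polytomy without a root flag); "
        "root it first, e.g. with marinepde.conservation.midpoint_root"
    )


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise TreeError("duplicate leaf labels")
    return labels


def _edge_len(node: dendropy.Node) -> float:
    length = node.edge.length
    if length is None:
        return 0.0
    if length < 0:
        raise TreeError(f"negative branch length {length}")
    return float(length)


# ---------------------------------------------------------------------------
# clade detection


def find_trait_clades(
    tree: dendropy.Tree,
    trait: Mapping[str, int],
    fraction_threshold: float = 0.9,
    strict: bool = True,
    singleton_mode: str = "half-branch",
) -> list[TraitClade]:
    """Detect maximal trait-conserved clades plus singleton positives.

    ``strict=True`` accepts a node only when its positive-tip fraction is
    strictly greater than the threshold ("more than 90%"); ``strict=False``
    gives the >= variant.  Multifurcating nodes are scored as-is.
    """
    if not 0 < fraction_threshold <= 1:
        raise TreeError("fraction_threshold must be in (0, 1]")
    if singleton_mode not in SINGLETON_MODES:
        raise TreeError(f"singleton_mode must be one of {SINGLETON_MODES}")
    _require_rooted(tree)
    labels = set(leaf_labels(tree))
    missing = labels - set(trait)
    if missing:
        raise TreeError(f"trait vector missing tips {sorted(missing)[:5]}")

    # bottom-up tally of tips / positive tips per node
    stats: dict[int, tuple[int, int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            stats[id(node)] = (1, 1 if trait[node.taxon.label] else 0)
        else:
            n = p = 0
            for child in node.child_nodes():
                cn, cp = stats[id(child)]
                n += cn
                p += cp
            stats[id(node)] = (n, p)

    def qualifies(node: dendropy.Node) -> bool:
        n, p = stats[id(node)]
        if n < 2:
            return False
        frac = p / n
        return frac > fraction_threshold if strict else frac >= fraction_threshold

    clades: list[TraitClade] = []
    covered: set[str] = set()
    stack = [tree.seed_node]
    while stack:  # pre-order; do not descend below an accepted clade root
        node = stack.pop()
        if qualifies(node):
            members = tuple(
                sorted(
                    lf.taxon.label
                    for lf in node.leaf_iter()
                    if trait[lf.taxon.label]
                )
            )
            depth = _clade_depth_of_members(node, set(members))
            n_tips = stats[id(node)][0]
            clades.append(
                TraitClade(members=members, clade_size=len(members),
                           n_tips=n_tips, depth=depth, is_singleton=False)
            )
            covered.update(members)
        else:
            stack.extend(reversed(node.child_nodes()))

    needs_pdm = singleton_mode == "half-nearest-positive"
    pdm = tree.phylogenetic_distance_matrix() if needs_pdm else None
    positives = [lb for lb in sorted(labels) if trait[lb]]
    for leaf in sorted(tree.leaf_node_iter(), key=lambda lf: lf.taxon.label):
        label = leaf.taxon.label
        if not trait[label] or label in covered:
            continue
        depth = _singleton_depth(leaf, singleton_mode, pdm, positives)
        clades.append(
            TraitClade(members=(label,), clade_size=1, n_tips=1,
                       depth=depth, is_singleton=True)
        )
    clades.sort(key=lambda c: c.members)
    return clades


def _clade_depth_of_members(clade_root: dendropy.Node,
                            members: set[str]) -> float:
    total = 0.0
    count = 0
    # depth-first accumulation of member-tip distances to the clade root
    stack = [(child, _edge_len(child)) for child in clade_root.child_nodes()]
    if not stack and clade_root.is_leaf():
        return 0.0
    while stack:
        node, dist = stack.pop()
        if node.is_leaf():
            if node.taxon.label in members:
                total += dist
                count += 1
        else:
            for child in node.child_nodes():
                stack.append((child, dist + _edge_len(child)))
    return total / count if count else 0.0


def _singleton_depth(
    leaf: dendropy.Node,
    mode: str,
    pdm,
    positives: Sequence[str],
) -> float:
    terminal = _edge_len(leaf)
    if mode == "half-branch":
        return terminal / 2
    if mode == "full-branch":
        return terminal
    # half-nearest-positive: half the patristic distance to the nearest
    # other trait-positive tip (falls back to the terminal branch when the
    # tip is the only positive).
    label = leaf.taxon.label
    taxon_by_label = {t.label: t for t in pdm.taxon_iter()}
    best = None
    for other in positives:
        if other == label:
            continue
        d = pdm.patristic_distance(taxon_by_label[label],
                                   taxon_by_label[other])
        best = d if best is None else min(best, d)
    if best is None:
        return terminal / 2
    return best / 2


def clade_depth(tree: dendropy.Tree, clade_root: dendropy.Node,
                trait: Mapping[str, int] | None = None,
                singleton_mode: str = "half-branch") -> float:
    """Mean distance from a clade's (trait-positive) tips to its root.

    With no trait given, all tips count as members.  A leaf node follows the
    singleton convention (default: half its terminal branch length).
    """
    if clade_root.is_leaf():
        return _singleton_depth(clade_root, singleton_mode, None, ())
    members = {
        lf.taxon.label
        for lf in clade_root.leaf_iter()
        if trait is None or trait[lf.taxon.label]
    }
    return _clade_depth_of_members(clade_root, members)


def consentrait(
    tree: dendropy.Tree,
    trait: Mapping[str, int],
    fraction_threshold: float = 0.9,
    strict: bool = True,
    singleton_mode: str = "half-branch",
    enzyme_type: str = "",
) -> ConsenTraitReport:
    """Full conservation analysis of one binary trait.

    Returns clade list, genotype count, singleton percentage, mean clade
    size and the mean trait depth tau_D (all detected clades weighted
    equally).  A trait with zero positive tips yields an empty report.
    """
    clades = tuple(
        find_trait_clades(tree, trait, fraction_threshold, strict,
                          singleton_mode)
    )
    n = len(clades)
    if n == 0:
        return ConsenTraitReport(enzyme_type=enzyme_type, clades=(),
                                 n_genotypes=0, pct_singletons=0.0,
                                 mean_clade_size=0.0, tau_d=0.0)
    n_singletons = sum(1 for c in clades if c.is_singleton)
    total_members = sum(c.clade_size for c in clades)
    return ConsenTraitReport(
        enzyme_type=enzyme_type,
        clades=clades,
        n_genotypes=n,
        pct_singletons=100.0 * n_singletons / n,
        mean_clade_size=total_members / n,
        tau_d=sum(c.depth for c in clades) / n,
    )


# ---------------------------------------------------------------------------
# depth <-> 16S identity conversion


def tau_to_identity(tau: float) -> float:
    """16S identity (%) corresponding to a mean trait depth on a 16S tree:
    (1 - 2*tau) * 100, reported to one decimal.  Depths above 0.5 have no
    meaningful identity (result is negative) and trigger a warning."""
    if tau < 0:
        raise TreeError("tau must be >= 0")
    identity = (1.0 - 2.0 * tau) * 100.0
    if identity < 0:
        warnings.warn(
            f"tau_D={tau} exceeds 0.5; converted identity {identity:.1f}% "
            "is negative and not interpretable",
            stacklevel=2,
        )
    return round(identity, 1)


def identity_to_tau(identity_pct: float) -> float:
    """Inverse of :func:`tau_to_identity` (exact, unrounded)."""
    return (1.0 - identity_pct / 100.0) / 2.0


# ---------------------------------------------------------------------------
# per-enzyme table


def conservation_table(
    tree: dendropy.Tree,
    matrix: TraitMatrix,
    fraction_threshold: float = 0.9,
    strict: bool = True,
    singleton_mode: str = "half-branch",
) -> tuple[pd.DataFrame, dict[str, ConsenTraitReport]]:
    """Conservation summary for every enzyme with >= 1 positive tree tip.

    Matrix genomes absent from the tree are dropped (with a log message),
    mirroring marker-gene subsets that cover only part of a genome panel;
    an empty intersection is an error.  Returns the summary table plus the
    full per-enzyme reports.
    """
    tips = set(leaf_labels(tree))
    genomes = [g for g in matrix.genome_ids if g in tips]
    dropped = len(matrix.genome_ids) - len(genomes)
    if not genomes:
        raise TreeError("no trait-matrix genome appears as a tree tip")
    if dropped:
        logger.info("conservation_table: %d of %d genomes not on the tree; "
                    "analysed %d", dropped, len(matrix.genome_ids),
                    len(genomes))
    binary = matrix.values.loc[genomes]
    reports: dict[str, ConsenTraitReport] = {}
    rows = []
    for enzyme in matrix.enzyme_types:
        positives_on_tree = int(binary[enzyme].sum())
        if positives_on_tree == 0:
            logger.info("conservation_table: %s has no positive tip; omitted",
                        enzyme)
            continue
        trait = {tip: 0 for tip in tips}
        trait.update(binary[enzyme].to_dict())
        report = consentrait(tree, trait, fraction_threshold, strict,
                             singleton_mode, enzyme_type=enzyme)
        reports[enzyme] = report
        rows.append({
            "enzyme_type": enzyme,
            "n_genotypes": report.n_genotypes,
            "pct_singletons": round(report.pct_singletons, 2),
            "mean_clade_size": round(report.mean_clade_size, 2),
            "tau_d": round(report.tau_d, 7),
            "identity_pct": report.identity_pct,
        })
    table = pd.DataFrame(
        rows, columns=["enzyme_type", "n_genotypes", "pct_singletons",
                       "mean_clade_size", "tau_d", "identity_pct"],
    )
    return table, reports
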