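"""Pairwise enzyme co-occurrence: Pearson/phi correlations and Jaccard.

Each enzyme is a binary presence/absence vector over genomes.  For every
unordered enzyme pair the Pearson product-moment correlation is computed
(on binary vectors this is exactly the phi coefficient of the 2x2
contingency table) with a two-sided p-value from the t-transform with n-2
degrees of freedom, together with the Jaccard distance
1 - |a AND b| / |a OR b| (double absences ignored).

Networks are built per genus — only genera with enough genomes (default
>= 25) are informative — plus one pass over all genomes.  An edge is kept
when |r| strictly exceeds the r threshold (default 0.4) and p < 0.05.
Raw p-values are reported by default; Benjamini-Hochberg adjustment is
available but off, and a seeded permutation p-value is available for small
panels.  Constant vectors (enzyme present in every genome of a genus, or in
none) have no defined correlation and are excluded pairwise.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .traits import TraitMatrix, _check_taxonomy

logger = logging.getLogger(__name__)

ALL_SCOPE = "all"


class CorrelationError(ValueError):
    pass


@dataclass(frozen=True)
class CorrelationEdge:
    """One tested enzyme pair within a scope (a genus or all genomes)."""

    enzyme_a: str
    enzyme_b: str
    scope: str
    n: int
    r: float
    p: float
    jaccard: float

    def __post_init__(self) -> None:
        if self.enzyme_a >= self.enzyme_b:
            raise CorrelationError("enzyme pair must be in canonical order "
                                   "(enzyme_a < enzyme_b)")
        if not -1.0000001 <= self.r <= 1.0000001:
            raise CorrelationError(f"r={self.r} outside [-1, 1]")

    @property
    def sign(self) -> str:
        return "positive" if self.r > 0 else "negative"

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.scope, self.enzyme_a, self.enzyme_b, self.sign)


def pearson_binary(vec_a: Sequence[int], vec_b: Sequence[int]
                   ) -> tuple[float, float]:
    """Pearson r and two-sided p for two equal-length binary vectors.

    Returns ``(nan, nan)`` when either vector is constant (r undefined);
    callers exclude such pairs from networks.  Requires n >= 3 (the
    t-transform needs n - 2 > 0 degrees of freedom).
    """
    a = np.asarray(vec_a, dtype=float)
    b = np.asarray(vec_b, dtype=float)
    if a.shape != b.shape:
        raise CorrelationError("vectors differ in length")
    if a.size < 3:
        raise CorrelationError("need at least 3 observations")
    if np.all(a == a[0]) or np.all(b == b[0]):
        return (math.nan, math.nan)
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def pearson_binary_permutation(
    vec_a: Sequence[int], vec_b: Sequence[int],
    n_permutations: int = 9999, seed: int = 0,
) -> tuple[float, float]:
    """Permutation two-sided p-value for the same statistic (seeded)."""
    a = np.asarray(vec_a, dtype=float)
    b = np.asarray(vec_b, dtype=float)
    r_obs, _ = pearson_binary(vec_a, vec_b)
    if math.isnan(r_obs):
        return (math.nan, math.nan)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        r_perm = np.corrcoef(a, rng.permutation(b))[0, 1]
        if abs(r_perm) >= abs(r_obs) - 1e-12:
            hits += 1
    return r_obs, (hits + 1) / (n_permutations + 1)


def phi_coefficient(n11: int, n10: int, n01: int, n00: int) -> float:
    """Phi from a 2x2 contingency table (independent of pearson_binary;
    used as its cross-check)."""
    num = n11 * n00 - n10 * n01
    den = math.sqrt(
        (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
    )
    if den == 0:
        return math.nan
    return num / den


def jaccard_distance(vec_a: Sequence[int], vec_b: Sequence[int]) -> float:
    """1 - intersection/union over presences; nan when both vectors are
    all-zero (undefined)."""
    a = np.asarray(vec_a, dtype=bool)
    b = np.asarray(vec_b, dtype=bool)
    if a.shape != b.shape:
        raise CorrelationError("vectors differ in length")
    union = int(np.sum(a | b))
    if union == 0:
        return math.nan
    return 1.0 - int(np.sum(a & b)) / union


def _scope_edges(
    binary: pd.DataFrame,
    scope: str,
    r_threshold: float,
    p_threshold: float,
    bh_correct: bool,
) -> list[CorrelationEdge]:
    n = len(binary)
    tested: list[tuple[str, str, float, float, float]] = []
    for ea, eb in itertools.combinations(sorted(binary.columns), 2):
        a = binary[ea].to_numpy()
        b = binary[eb].to_numpy()
        r, p = pearson_binary(a, b)
        if math.isnan(r):
            logger.debug("scope %s: pair (%s, %s) skipped (constant trait)",
                         scope, ea, eb)
            continue
        tested.append((ea, eb, r, p, jaccard_distance(a, b)))
    if bh_correct and tested:
        ps = [t[3] for t in tested]
        adj = _benjamini_hochberg(ps)
        tested = [(ea, eb, r, q, j)
                  for (ea, eb, r, _, j), q in zip(tested, adj)]
    edges = []
    for ea, eb, r, p, j in tested:
        if abs(r) > r_threshold and p < p_threshold:
            edges.append(CorrelationEdge(enzyme_a=ea, enzyme_b=eb,
                                         scope=scope, n=n, r=r, p=p,
                                         jaccard=j))
    return edges


def _benjamini_hochberg(pvalues: Sequence[float]) -> list[float]:
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    prev = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        q = min(prev, pvalues[idx] * m / rank)
        adjusted[idx] = q
        prev = q
    return adjusted


def genus_networks(
    matrix: TraitMatrix,
    taxonomy: pd.DataFrame,
    min_genomes: int = 25,
    r_threshold: float = 0.4,
    p_threshold: float = 0.05,
    include_all_scope: bool = True,
    bh_correct: bool = False,
) -> list[CorrelationEdge]:
    """Significant enzyme-pair edges per genus (and over all genomes).

    Only genera with >= ``min_genomes`` genomes are tested.  An edge needs
    |r| strictly above ``r_threshold`` and p below ``p_threshold``.  Output
    order is deterministic (scope, then pair) and invariant to genome or
    enzyme ordering in the inputs.
    """
    tax = _check_taxonomy(matrix, taxonomy)
    binary = matrix.values
    edges: list[CorrelationEdge] = []
    if include_all_scope:
        edges.extend(_scope_edges(binary, ALL_SCOPE, r_threshold,
                                  p_threshold, bh_correct))
    genera = tax["genus"]
    for genus in sorted(set(genera) - {"unknown"}):
        members = genera.index[genera == genus]
        if len(members) < min_genomes:
            logger.debug("genus %s skipped: %d genomes < %d", genus,
                         len(members), min_genomes)
            continue
        edges.extend(_scope_edges(binary.loc[members], genus, r_threshold,
                                  p_threshold, bh_correct))
    return edges


def compare_edge_sets(
    edge_sets: Mapping[str, Iterable[CorrelationEdge]],
) -> dict[str, object]:
    """Membership comparison of >= 2 named edge sets (Venn-style).

    Edges are identified by (scope, pair, sign).  Returns per-region counts
    keyed by the sorted tuple of set names sharing the region, per-set
    totals, and the fraction of the *first* (main) set's edges supported by
    at least one other set.
    """
    names = list(edge_sets)
    if len(names) < 2:
        raise CorrelationError("need at least two edge sets to compare")
    keyed = {
        name: {e.key for e in edges} for name, edges in edge_sets.items()
    }
    universe = set().union(*keyed.values())
    regions: dict[tuple[str, ...], int] = {}
    for key in universe:
        membership = tuple(n for n in names if key in keyed[n])
        regions[membership] = regions.get(membership, 0) + 1
    main = names[0]
    main_keys = keyed[main]
    others = set().union(*(keyed[n] for n in names[1:]))
    supported = len(main_keys & others)
    return {
        "set_sizes": {n: len(keyed[n]) for n in names},
        "regions": regions,
        "main_set": main,
        "main_supported": supported,
        "main_supported_fraction": supported / len(main_keys)
        if main_keys else math.nan,
    }


# ---------------------------------------------------------------------------
# export


def edges_to_frame(edges: Iterable[CorrelationEdge]) -> pd.DataFrame:
    rows = [
        {
            "scope": e.scope,
            "enzyme_a": e.enzyme_a,
            "enzyme_b": e.enzyme_b,
            "n": e.n,
            "r": round(e.r, 4),
            "p": e.p,
            "jaccard": round(e.jaccard, 4),
            "sign": e.sign,
        }
        for e in edges
    ]
    return pd.DataFrame(
        rows, columns=["scope", "enzyme_a", "enzyme_b", "n", "r", "p",
                       "jaccard", "sign"],
    )


def write_edges(edges: Iterable[CorrelationEdge], path: str | Path) -> None:
    edges_to_frame(edges).to_csv(path, sep="\t", index=False)


def to_networkx(edges: Iterable[CorrelationEdge]) -> nx.MultiGraph:
    """Collapse edges into a multigraph: one edge per (pair, scope) with r,
    p, jaccard and sign attributes (parallel edges = different genera)."""
    graph = nx.MultiGraph()
    for e in edges:
        graph.add_edge(e.enzyme_a, e.enzyme_b, key=e.scope, scope=e.scope,
                       n=e.n, r=e.r, p=e.p, jaccard=e.jaccard, sign=e.sign)
    return graph


def write_network(edges: Iterable[CorrelationEdge], path: str | Path) -> None:
    """Write the collapsed network as GML (plain-text graph format)."""
    nx.write_gml(to_networkx(edges), str(path))
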