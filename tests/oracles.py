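"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive results by the most transparent method
available (full dynamic-programming tables, exhaustive per-node scoring,
trying every candidate value) and share no logic with the package paths
they validate.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Smith-Waterman optimal local score, full Gotoh DP over three tables.

    Affine gaps cost ``gap_open + k * gap_extend`` for length k, matching
    the convention of the package aligner it checks.
    """
    n1, n2 = len(a), len(b)
    NEG = float("-inf")
    open_cost = gap_open + gap_extend
    H = [[0.0] * (n2 + 1) for _ in range(n1 + 1)]
    E = [[NEG] * (n2 + 1) for _ in range(n1 + 1)]  # gap in b
    F = [[NEG] * (n2 + 1) for _ in range(n1 + 1)]  # gap in a
    best = 0.0
    for i in range(1, n1 + 1):
        ca = a[i - 1]
        for j in range(1, n2 + 1):
            E[i][j] = max(H[i - 1][j] - open_cost, E[i - 1][j] - gap_extend)
            F[i][j] = max(H[i][j - 1] - open_cost, F[i][j - 1] - gap_extend)
            diag = H[i - 1][j - 1] + _BLOSUM62[ca, b[j - 1]]
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def n50_bruteforce(lengths: list[int]) -> int:
    """Largest contig length L whose >=L contigs cover >= half the total,
    found by trying every distinct length."""
    total = sum(lengths)
    for candidate in sorted(set(lengths), reverse=True):
        if sum(x for x in lengths if x >= candidate) >= total / 2:
            return candidate
    raise AssertionError("unreachable")


def consentrait_bruteforce(tree, trait, threshold=0.9, strict=True,
                           singleton_half=True):
    """Exhaustive consenTRAIT: score every node independently, keep accepted
    nodes with no accepted ancestor, then collect uncovered positives as
    singletons.  Returns (clade member-sets, per-clade depths, tau_D).
    """
    nodes = list(tree.preorder_node_iter())
    accepted = {}
    for node in nodes:
        tips = [lf.taxon.label for lf in node.leaf_iter()]
        if len(tips) < 2:
            accepted[id(node)] = False
            continue
        frac = sum(trait[t] for t in tips) / len(tips)
        accepted[id(node)] = (frac > threshold) if strict else (frac >= threshold)

    def has_accepted_ancestor(node):
        anc = node.parent_node
        while anc is not None:
            if accepted[id(anc)]:
                return True
            anc = anc.parent_node
        return False

    def leaf_to_ancestor(leaf, ancestor):
        dist = 0.0
        node = leaf
        while node is not ancestor:
            dist += node.edge.length or 0.0
            node = node.parent_node
        return dist

    clades, depths = [], []
    covered = set()
    for node in nodes:
        if accepted[id(node)] and not has_accepted_ancestor(node):
            members = frozenset(
                lf.taxon.label for lf in node.leaf_iter()
                if trait[lf.taxon.label]
            )
            positive_leaves = [lf for lf in node.leaf_iter()
                               if trait[lf.taxon.label]]
            depth = sum(leaf_to_ancestor(lf, node) for lf in positive_leaves)
            depth /= len(positive_leaves)
            clades.append(members)
            depths.append(depth)
            covered |= members
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        if trait[label] and label not in covered:
            clades.append(frozenset({label}))
            term = leaf.edge.length or 0.0
            depths.append(term / 2 if singleton_half else term)
    tau = sum(depths) / len(depths) if depths else 0.0
    return clades, depths, tau
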