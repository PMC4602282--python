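"""Independent reference implementations used only to check the package.

These deliberately share no code with phyloprofiler: a plain three-state
Gotoh dynamic program for affine-gap local alignment, a fully exhaustive
local-alignment path enumerator for tiny sequences, and an exhaustive
minimal-loss search for single-gain (Dollo) reconstructions.
"""

from __future__ import annotations

import itertools


def gotoh_local_score(a: str, b: str, score, gap_open: int, gap_extend: int) -> int:
    """Affine-gap Smith-Waterman score; gap of length k costs open + k*extend."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    best = 0
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    first = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            Ix[i][j] = max(M[i - 1][j] - first, Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(M[i][j - 1] - first, Iy[i][j - 1] - gap_extend)
            diag = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            M[i][j] = max(0.0, diag + score(a[i - 1], b[j - 1]))
            best = max(best, M[i][j])
    return int(best)


def enumerate_local_score(a: str, b: str, score, gap_open: int, gap_extend: int) -> int:
    """Brute force: try every pair of substrings and every alignment path.

    Exponential; only usable for sequences of a handful of residues.
    """

    def paths(x: str, y: str):
        # all global alignment column sequences of x vs y
        def rec(i, j, cols):
            if i == len(x) and j == len(y):
                yield tuple(cols)
                return
            if i < len(x) and j < len(y):
                yield from rec(i + 1, j + 1, cols + [(x[i], y[j])])
            if i < len(x):
                yield from rec(i + 1, j, cols + [(x[i], None)])
            if j < len(y):
                yield from rec(i, j + 1, cols + [(None, y[j])])

        yield from rec(0, 0, [])

    def path_score(cols) -> float:
        total = 0.0
        gap_len = 0
        for ca, cb in cols:
            if ca is None or cb is None:
                gap_len += 1
            else:
                if gap_len:
                    total -= gap_open + gap_len * gap_extend
                    gap_len = 0
                total += score(ca, cb)
        if gap_len:
            total -= gap_open + gap_len * gap_extend
        return total

    best = 0.0
    for i1, i2 in itertools.combinations(range(len(a) + 1), 2):
        for j1, j2 in itertools.combinations(range(len(b) + 1), 2):
            for cols in paths(a[i1:i2], b[j1:j2]):
                best = max(best, path_score(cols))
    return int(best)


def dollo_min_losses(tree, present_leaves: set[str]) -> int:
    """Exhaustive minimum loss count for a single-gain scenario.

    ``tree`` is a dendropy tree with labelled nodes; the gain is placed at
    the MRCA of the present leaves and every subset of descendant edges is
    tried in increasing size until one implies exactly the observed leaf
    states.  Independent of the package's subtree-merging construction.
    """
    if not present_leaves:
        return 0
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    taxa = [tree.taxon_namespace.get_taxon(x) for x in sorted(present_leaves)]
    origin = tree.mrca(taxa=taxa) if len(taxa) > 1 else tree.find_node_with_taxon_label(taxa[0].label)

    below = [nd for nd in origin.preorder_iter() if nd is not origin]

    def implied_states(loss_nodes) -> dict[str, bool]:
        states = {}

        def walk(node, state):
            if node in loss_nodes:
                state = False
            if node.is_leaf():
                states[node.taxon.label] = state
            for ch in node.child_nodes():
                walk(ch, state)

        walk(origin, True)
        return states

    target = {lf: (lf in present_leaves) for lf in leaves if lf in _leaf_set(origin)}
    for k in range(len(below) + 1):
        for combo in itertools.combinations(below, k):
            if implied_states(set(combo)) == target:
                return k
    raise AssertionError("unreachable: full loss set always matches")


def _leaf_set(node) -> set[str]:
    return {lf.taxon.label for lf in node.leaf_iter()}
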