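"""Distance-based gene trees and duplication placement.

A paralog family (e.g. the two tagged copies arising from the
vertebrate-specific Emc8 duplication) is dated by building a
neighbor-joining tree from alignment-score distances, rooting it with an
explicit outgroup and asking whether the clade of ``b``-tagged copies is
confined to the tested lineage with the lineage's ``a`` copies as its
sister — the classic test for a lineage-specific duplication.

The distance is ``d(a, b) = -ln( S(a,b) / min(S(a,a), S(b,b)) )`` with
``S`` the raw local-alignment score: 0 for identical sequences, growing
roughly linearly in divergence time at moderate distances, and capped
when sequences share no positive-scoring alignment.  Neighbor joining is
the canonical Saitou-Nei/Studier-Keppler algorithm with lexicographic
tie-breaking (deterministic) and negative branch lengths clamped to zero
with the excess moved to the sister branch.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .scoring import ScoringScheme, default_scheme
from .seqsearch import self_score
from .trees import ensure_node_labels, node_label

logger = logging.getLogger(__name__)

LINEAGE_SPECIFIC = "lineage-specific"
PRE_DATES = "pre-dates lineage"
UNRESOLVED = "unresolved"


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with a fixed taxon order."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if not np.isfinite(v).all() or (v < 0).any():
            raise ValueError("distances must be finite and non-negative")
        self.values = v

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])


@dataclass(frozen=True)
class DuplicationCall:
    verdict: str  # lineage-specific | pre-dates lineage | unresolved
    duplication_node: str | None
    lineage: str
    notes: str = ""


def score_distance(
    sequences: Mapping[str, str],
    scheme: ScoringScheme | None = None,
    cap: float = 10.0,
) -> DistanceMatrix:
    """Alignment-score distances between all pairs of sequences."""
    if len(sequences) < 3:
        raise ValueError("need at least 3 sequences for a distance matrix")
    scheme = scheme or default_scheme()
    ids = list(sequences)
    aligner = scheme.aligner()
    selfs = {i: self_score(sequences[i], scheme) for i in ids}
    n = len(ids)
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        raw = aligner.score(sequences[ids[i]], sequences[ids[j]])
        denom = min(selfs[ids[i]], selfs[ids[j]])
        if raw <= 0 or denom <= 0:
            logger.warning("no positive alignment for %s vs %s; capped", ids[i], ids[j])
            d = cap
        else:
            d = min(cap, max(0.0, -math.log(raw / denom)))
        mat[i, j] = mat[j, i] = d
    return DistanceMatrix(ids, mat)


def nj_build(matrix: DistanceMatrix) -> dendropy.Tree:
    """Neighbor joining with deterministic tie-breaking.

    Returns an unrooted dendropy tree (trifurcation at the seed node).
    """
    ids = list(matrix.ids)
    if len(ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = {a: {b: matrix.get(a, b) for b in ids} for a in ids}
    namespace = dendropy.TaxonNamespace()
    nodes: dict[str, dendropy.Node] = {}
    for taxon_id in ids:
        node = dendropy.Node()
        node.taxon = dendropy.Taxon(label=taxon_id)
        namespace.add_taxon(node.taxon)
        nodes[taxon_id] = node

    active = list(ids)
    counter = itertools.count(1)
    while len(active) > 3:
        r = len(active)
        totals = {a: sum(d[a][b] for b in active if b != a) for a in active}
        best_pair, best_q = None, None
        for a, b in itertools.combinations(sorted(active), 2):
            q = (r - 2) * d[a][b] - totals[a] - totals[b]
            if best_q is None or q < best_q - 1e-12:
                best_q, best_pair = q, (a, b)
        a, b = best_pair
        # branch lengths to the new internal node
        la = 0.5 * d[a][b] + (totals[a] - totals[b]) / (2 * (r - 2))
        lb = d[a][b] - la
        # clamp negatives, moving the excess to the sister branch
        if la < 0:
            lb, la = lb + la, 0.0
        if lb < 0:
            la, lb = la + lb, 0.0
        new_id = f"_nj{next(counter)}"
        parent = dendropy.Node()
        parent.label = new_id
        parent.add_child(nodes[a])
        parent.add_child(nodes[b])
        nodes[a].edge.length = la
        nodes[b].edge.length = lb
        nodes[new_id] = parent
        d[new_id] = {}
        for c in active:
            if c in (a, b):
                continue
            dc = 0.5 * (d[a][c] + d[b][c] - d[a][b])
            d[new_id][c] = d[c][new_id] = max(0.0, dc)
        d[new_id][new_id] = 0.0
        active = sorted(set(active) - {a, b}) + [new_id]

    # join the final three nodes in a trifurcation
    x, y, z = sorted(active)
    lx = 0.5 * (d[x][y] + d[x][z] - d[y][z])
    ly = 0.5 * (d[x][y] + d[y][z] - d[x][z])
    lz = 0.5 * (d[x][z] + d[y][z] - d[x][y])
    root = dendropy.Node()
    for taxon_id, length in ((x, lx), (y, ly), (z, lz)):
        root.add_child(nodes[taxon_id])
        nodes[taxon_id].edge.length = max(0.0, length)
    tree = dendropy.Tree(taxon_namespace=namespace)
    tree.seed_node = root
    tree.is_rooted = False
    ensure_node_labels(tree)
    return tree


def root_with_outgroup(tree: dendropy.Tree, outgroup: Sequence[str]) -> dendropy.Tree:
    """Root a gene tree on the edge above the outgroup (or its MRCA)."""
    if not outgroup:
        raise ValueError("outgroup must name at least one leaf")
    rooted = tree.clone(depth=1)
    rooted.is_rooted = True
    taxa = [rooted.taxon_namespace.get_taxon(o) for o in outgroup]
    if any(t is None for t in taxa):
        missing = [o for o, t in zip(outgroup, taxa) if t is None]
        raise ValueError(f"outgroup leaves not in tree: {missing}")
    if len(taxa) == 1:
        node = rooted.find_node_with_taxon(lambda t: t is taxa[0])
    else:
        node = rooted.mrca(taxa=taxa)
    if node is rooted.seed_node:
        raise ValueError("outgroup is not monophyletically placeable")
    length = node.edge.length or 0.0
    rooted.reroot_at_edge(node.edge, length1=length / 2, length2=length / 2)
    rooted.update_bipartitions(suppress_unifurcations=True)
    ensure_node_labels(rooted)
    return rooted


def duplication_clade_test(
    tree: dendropy.Tree,
    species_of: Mapping[str, str],  # leaf id -> species
    tag_of: Mapping[str, str],  # leaf id -> "a" | "b" | ""
    lineage_of: Mapping[str, str],  # species -> lineage
    lineage: str,
    outgroup: Sequence[str],
) -> DuplicationCall:
    """Decide whether the tagged duplication is specific to one lineage.

    Roots by the outgroup, finds the smallest clade holding every
    ``b``-tagged leaf and checks that (i) its species all belong to the
    tested lineage and (ii) the lineage's ``a``-tagged leaves form its
    sister group.  One stray leaf inside the duplication clade downgrades
    the verdict to unresolved rather than flipping it.
    """
    b_leaves = sorted(l for l, t in tag_of.items() if t == "b")
    if not b_leaves:
        return DuplicationCall(
            UNRESOLVED, None, lineage, "no b-tagged paralogs in the tree"
        )
    try:
        rooted = root_with_outgroup(tree, outgroup)
    except ValueError as exc:
        return DuplicationCall(UNRESOLVED, None, lineage, f"rooting failed: {exc}")

    taxa = [rooted.taxon_namespace.get_taxon(l) for l in b_leaves]
    if len(taxa) == 1:
        dup_node = rooted.find_node_with_taxon(lambda t: t is taxa[0])
    else:
        dup_node = rooted.mrca(taxa=taxa)
    clade_leaves = [lf.taxon.label for lf in dup_node.leaf_iter()]
    dup_label = node_label(dup_node)

    off_lineage = [
        l for l in clade_leaves if lineage_of.get(species_of.get(l, ""), "") != lineage
    ]
    wrong_tag = [
        l for l in clade_leaves
        if l not in off_lineage and tag_of.get(l, "") != "b"
    ]
    violations = off_lineage + wrong_tag
    if len(violations) == 1:
        # tolerance: a single stray leaf downgrades rather than flips
        return DuplicationCall(
            UNRESOLVED, dup_label, lineage,
            f"one stray leaf in duplication clade: {violations}",
        )
    if off_lineage:
        return DuplicationCall(
            PRE_DATES, dup_label, lineage,
            f"duplication clade extends beyond {lineage}: {sorted(off_lineage)[:5]}",
        )
    if wrong_tag:
        return DuplicationCall(
            UNRESOLVED, dup_label, lineage,
            f"untagged or a-tagged leaves inside duplication clade: {sorted(wrong_tag)[:5]}",
        )

    # sister group: the a-tagged copies of the same lineage
    parent = dup_node.parent_node
    if parent is None:
        return DuplicationCall(UNRESOLVED, dup_label, lineage, "clade at root")
    sister_leaves = [
        lf.taxon.label
        for sib in parent.child_nodes()
        if sib is not dup_node
        for lf in sib.leaf_iter()
    ]
    sister_lineage_a = [
        l for l in sister_leaves
        if tag_of.get(l, "") == "a"
        and lineage_of.get(species_of.get(l, ""), "") == lineage
    ]
    off_lineage_sister = [
        l for l in sister_leaves
        if lineage_of.get(species_of.get(l, ""), "") != lineage
    ]
    if sister_lineage_a and not off_lineage_sister:
        return DuplicationCall(LINEAGE_SPECIFIC, dup_label, lineage)
    if sister_lineage_a and off_lineage_sister:
        return DuplicationCall(
            UNRESOLVED, dup_label, lineage,
            f"sister group mixes lineages: {sorted(off_lineage_sister)[:5]}",
        )
    return DuplicationCall(
        UNRESOLVED, dup_label, lineage,
        "sister group holds no a-tagged leaves of the tested lineage",
    )
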