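"""Rooted species-tree utilities on top of dendropy.

Branches are identified throughout the package by the label of their
child node, so every node (internal ones included) gets a stable label:
unlabelled internal nodes are named ``N1, N2, ...`` in preorder.
"""

from __future__ import annotations

from pathlib import Path

import dendropy


def load_tree(source: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree from a path or a Newick string."""
    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    tree = dendropy.Tree.get(
        data=text, schema="newick", suppress_internal_node_taxa=False
    )
    tree.is_rooted = True
    ensure_node_labels(tree)
    validate_tree(tree)
    return tree


def ensure_node_labels(tree: dendropy.Tree) -> None:
    """Assign preorder labels N1.. to unlabelled internal nodes."""
    counter = 1
    for node in tree.preorder_node_iter():
        if node_label(node) is None:
            while True:
                candidate = f"N{counter}"
                counter += 1
                if not any(node_label(nd) == candidate for nd in tree):
                    break
            if node.taxon is None:
                node.label = candidate
            else:
                node.taxon.label = candidate


def node_label(node: dendropy.Node) -> str | None:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    return node.label or None


def validate_tree(tree: dendropy.Tree) -> None:
    """Check rootedness, unique leaf names and sane branch lengths."""
    leaves = [node_label(lf) for lf in tree.leaf_node_iter()]
    if len(set(leaves)) != len(leaves):
        dupes = sorted({x for x in leaves if leaves.count(x) > 1})
        raise ValueError(f"duplicate leaf names: {dupes}")
    for node in tree.preorder_node_iter():
        el = node.edge.length
        if el is not None and (el < 0 or el != el or el in (float("inf"),)):
            raise ValueError(f"invalid branch length {el} above {node_label(node)}")


def leaf_names(tree: dendropy.Tree) -> list[str]:
    return [node_label(lf) for lf in tree.leaf_node_iter()]


def find_node(tree: dendropy.Tree, label: str) -> dendropy.Node:
    for node in tree.preorder_node_iter():
        if node_label(node) == label:
            return node
    raise KeyError(f"no node labelled {label!r} in tree")


def mrca(tree: dendropy.Tree, labels: list[str]) -> dendropy.Node:
    """Most recent common ancestor of the named leaves."""
    if not labels:
        raise ValueError("mrca of empty leaf set")
    if len(labels) == 1:
        return find_node(tree, labels[0])
    nodes = [find_node(tree, x) for x in labels]
    paths = []
    for nd in nodes:
        path = []
        while nd is not None:
            path.append(nd)
            nd = nd.parent_node
        paths.append(set(path))
    common = set.intersection(*paths)
    # the common ancestor with no child also in the common set is the MRCA
    for nd in common:
        if not any(ch in common for ch in nd.child_nodes()):
            return nd
    raise AssertionError("unreachable")


def _depths(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    depths = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        el = node.edge.length or 0.0
        depths[node] = el + (depths[parent] if parent is not None else 0.0)
    return depths


def patristic_distances(tree: dendropy.Tree, focal: str) -> dict[str, float]:
    """Path-length distance from a focal leaf to every other leaf.

    Missing branch lengths count as 0.
    """
    depths = _depths(tree)
    focal_node = find_node(tree, focal)
    ancestors: dict[dendropy.Node, float] = {}
    nd = focal_node
    while nd is not None:
        ancestors[nd] = depths[focal_node] - depths[nd]
        nd = nd.parent_node
    out: dict[str, float] = {}
    for leaf in tree.leaf_node_iter():
        label = node_label(leaf)
        if label == focal:
            continue
        nd = leaf
        while nd not in ancestors:
            nd = nd.parent_node
        out[label] = ancestors[nd] + depths[leaf] - depths[nd]
    return out


def to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()
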