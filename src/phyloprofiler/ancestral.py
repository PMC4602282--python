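"""Dollo-parsimony gain/loss reconstruction on a rooted species tree.

Under Dollo parsimony a family is gained exactly once — at the most
recent common ancestor (MRCA) of the leaves that carry it — and can only
be lost afterwards.  The minimal loss set under that single-gain
constraint is exactly one loss on the root edge of every maximal
all-absent subtree below the origin, which is what the reconstruction
returns; minimality therefore holds by construction.  Families observed
nowhere yield an empty reconstruction (no evidence of a gain), never a
root gain plus immediate losses.

Weak orthology calls count as presence by default (a divergent but
validated ortholog still documents retention); ambiguous calls are
conservatively treated as absence.  Both choices are flag-controlled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy

from .profiles import PhyleticProfile
from .trees import find_node, leaf_names, mrca, node_label


@dataclass
class DolloReconstruction:
    """Single-gain reconstruction of one family."""

    family: str
    origin: str | None  # node label of the gain; None if never observed
    losses: set[str] = field(default_factory=set)  # child-node labels
    states: dict[str, bool] = field(default_factory=dict)  # node label -> present


def _implied_states(
    tree: dendropy.Tree, origin: dendropy.Node | None, losses: set[str]
) -> dict[str, bool]:
    states: dict[str, bool] = {node_label(nd): False for nd in tree.preorder_node_iter()}
    if origin is None:
        return states

    def walk(node: dendropy.Node, state: bool) -> None:
        label = node_label(node)
        if label in losses:
            state = False
        states[label] = state
        for child in node.child_nodes():
            walk(child, state)

    walk(origin, True)
    return states


def dollo_reconstruct(
    profile: PhyleticProfile,
    tree: dendropy.Tree,
    weak_counts_as_present: bool = True,
    ambiguous_counts_as_present: bool = False,
) -> list[DolloReconstruction]:
    """One reconstruction per family in the profile.

    The profile's species must be exactly the tree's leaves.
    """
    tree_leaves = set(leaf_names(tree))
    prof_species = set(profile.species)
    if tree_leaves != prof_species:
        raise ValueError(
            "profile species and tree leaves differ: "
            f"only_profile={sorted(prof_species - tree_leaves)} "
            f"only_tree={sorted(tree_leaves - prof_species)}"
        )
    out = []
    for family in profile.families:
        present = [
            sp
            for sp in profile.species
            if profile.status(sp, family) == "present"
            or (weak_counts_as_present and profile.status(sp, family) == "weak")
            or (ambiguous_counts_as_present and profile.status(sp, family) == "ambiguous")
        ]
        if not present:
            out.append(DolloReconstruction(family, None, set(),
                                           _implied_states(tree, None, set())))
            continue
        origin = mrca(tree, present)
        present_set = set(present)
        losses: set[str] = set()

        def collect(node: dendropy.Node) -> None:
            subtree_leaves = {node_label(lf) for lf in node.leaf_iter()}
            if subtree_leaves.isdisjoint(present_set):
                losses.add(node_label(node))  # maximal absent subtree: one loss
                return
            for child in node.child_nodes():
                collect(child)

        for child in origin.child_nodes():
            collect(child)
        states = _implied_states(tree, origin, losses)
        out.append(DolloReconstruction(family, node_label(origin), losses, states))
    return out


def ancestral_state(
    reconstructions: Sequence[DolloReconstruction], tree: dendropy.Tree, node: str
) -> set[str]:
    """Families implied present at the named node."""
    find_node(tree, node)  # raises KeyError for unknown nodes
    return {rec.family for rec in reconstructions if rec.states.get(node, False)}


def annotate_events(
    reconstructions: Sequence[DolloReconstruction], tree: dendropy.Tree
) -> tuple[list[tuple[str, str, str]], str]:
    """Event table (family, gain|loss, branch) plus an annotated Newick.

    Branch annotations are Newick comment blocks of the form
    ``[&events=gain:Emc1|loss:Emc5]`` attached to the child node.
    """
    events: list[tuple[str, str, str]] = []
    for rec in reconstructions:
        if rec.origin is not None:
            events.append((rec.family, "gain", rec.origin))
        for branch in sorted(rec.losses):
            events.append((rec.family, "loss", branch))
    events.sort()

    per_branch: dict[str, list[str]] = {}
    for family, kind, branch in events:
        per_branch.setdefault(branch, []).append(f"{kind}:{family}")

    annotated = tree.clone(depth=1)
    for node in annotated.preorder_node_iter():
        label = node_label(node)
        if label in per_branch:
            node.annotations.add_new("events", "|".join(per_branch[label]))
    newick = annotated.as_string(
        schema="newick", suppress_rooting=True, suppress_annotations=False
    ).strip()
    return events, newick


def parse_annotated_newick(newick: str) -> list[tuple[str, str, str]]:
    """Recover the event table from an annotated Newick string."""
    tree = dendropy.Tree.get(
        data=newick, schema="newick", suppress_internal_node_taxa=False,
        extract_comment_metadata=True,
    )
    events = []
    for node in tree.preorder_node_iter():
        value = node.annotations.get_value("events")
        if not value:
            continue
        for item in value.split("|"):
            kind, family = item.split(":", 1)
            events.append((family, kind, node_label(node)))
    events.sort()
    return events


def write_events_tsv(events: Sequence[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("family\tevent\tbranch\n")
        for family, kind, branch in events:
            fh.write(f"{family}\t{kind}\t{branch}\n")
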