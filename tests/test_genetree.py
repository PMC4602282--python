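"""Distance matrices, neighbor joining and duplication placement."""

import random

import dendropy
import numpy as np
import pytest

from phyloprofiler.genetree import (
    LINEAGE_SPECIFIC,
    PRE_DATES,
    UNRESOLVED,
    DistanceMatrix,
    duplication_clade_test,
    nj_build,
    score_distance,
)
from phyloprofiler.simulate import FamilySpec, evolve_family, random_root_sequence
from phyloprofiler.trees import load_tree, node_label, patristic_distances


def rf_unrooted(nwk1: str, nwk2: str) -> int:
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=nwk1, schema="newick", taxon_namespace=tns,
                           rooting="force-unrooted")
    t2 = dendropy.Tree.get(data=nwk2, schema="newick", taxon_namespace=tns,
                           rooting="force-unrooted")
    return dendropy.calculate.treecompare.symmetric_difference(t1, t2)


def additive_matrix(tree, labels):
    n = len(labels)
    mat = np.zeros((n, n))
    for i, a in enumerate(labels):
        dists = patristic_distances(tree, a)
        for j, b in enumerate(labels):
            if a != b:
                mat[i, j] = dists[b]
    mat = (mat + mat.T) / 2  # patristic sums can differ in the last ulp
    return DistanceMatrix(labels, mat)


def random_tree_newick(rng: random.Random, n: int):
    labels = [f"T{i}" for i in range(n)]
    nodes = [f"{l}:{rng.uniform(0.2, 2):.4f}" for l in labels]
    while len(nodes) > 2:
        i, j = sorted(rng.sample(range(len(nodes)), 2), reverse=True)
        a, b = nodes.pop(i), nodes.pop(j)
        nodes.append(f"({a},{b}):{rng.uniform(0.2, 2):.4f}")
    return f"({nodes[0]},{nodes[1]});", labels


def test_identical_sequences_have_zero_distance():
    seq = random_root_sequence(120, np.random.default_rng(0))
    other = random_root_sequence(150, np.random.default_rng(1))
    dm = score_distance({"a": seq, "b": seq, "c": other})
    assert dm.get("a", "b") == 0.0
    assert dm.get("a", "c") > 0.5


def test_unrelated_pair_hits_the_cap():
    dm = score_distance({"a": "WWWWWWWW", "b": "AAAAAAAA", "c": "AAAAAAAA"}, cap=10.0)
    assert dm.get("a", "b") == 10.0


def test_distances_grow_with_substitution_rate():
    tree = load_tree("(A:0.3,(B:0.3,C:0.3)bc:0.2)R;")
    root = random_root_sequence(250, np.random.default_rng(4))
    means = []
    for rate in (0.25, 0.5, 0.8, 1.2, 1.8):
        vals = []
        for seed in range(1, 11):
            leafs, _ = evolve_family(
                tree, FamilySpec("F", root, 0.0, rate, 0.01, None, seed)
            )
            seqs = {sp: copies[0][0] for sp, copies in leafs.items()}
            dm = score_distance(seqs)
            vals.append(dm.get("A", "B"))
        means.append(np.mean(vals))
    assert all(a < b for a, b in zip(means, means[1:]))


def test_three_taxon_closed_form():
    mat = DistanceMatrix(
        ["a", "b", "c"],
        np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]]),
    )
    tree = nj_build(mat)
    lengths = {
        node_label(lf): lf.edge.length for lf in tree.leaf_node_iter()
    }
    assert lengths["a"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
    assert lengths["b"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
    assert lengths["c"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))


def test_nj_recovers_additive_topologies():
    rng = random.Random(11)
    for _ in range(40):
        nwk, labels = random_tree_newick(rng, rng.randint(5, 8))
        tree = load_tree(nwk)
        nj = nj_build(additive_matrix(tree, labels))
        assert rf_unrooted(tree.as_string(schema="newick"),
                           nj.as_string(schema="newick")) == 0


def test_nj_matches_independent_implementation():
    """Cross-check topologies against scikit-bio's neighbor joining."""
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj as skbio_nj

    rng = random.Random(23)
    for _ in range(10):
        nwk, labels = random_tree_newick(rng, rng.randint(5, 7))
        tree = load_tree(nwk)
        dm = additive_matrix(tree, labels)
        ours = nj_build(dm)
        theirs = skbio_nj(SkbioDM(dm.values, ids=labels))
        assert rf_unrooted(ours.as_string(schema="newick"), str(theirs)) == 0


def test_taxon_order_invariance():
    rng = random.Random(3)
    nwk, labels = random_tree_newick(rng, 7)
    tree = load_tree(nwk)
    dm = additive_matrix(tree, labels)
    shuffled = labels[::-1]
    idx = [labels.index(s) for s in shuffled]
    dm2 = DistanceMatrix(shuffled, dm.values[np.ix_(idx, idx)])
    assert rf_unrooted(
        nj_build(dm).as_string(schema="newick"),
        nj_build(dm2).as_string(schema="newick"),
    ) == 0


def test_asymmetric_matrix_rejected():
    with pytest.raises(ValueError, match="symmetric"):
        DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))


# --- duplication placement --------------------------------------------------


def duplication_scenario(seed: int, branch: str):
    tree = load_tree(
        "(((S1:0.1,S2:0.1)A1:0.1,(S3:0.1,S4:0.1)A2:0.1)CladeA:0.15,"
        "((S5:0.1,S6:0.1)B1:0.1,(S7:0.1,S8:0.1)B2:0.1)CladeB:0.15)R;"
    )
    rng = np.random.default_rng([seed, 17, 0])
    root = random_root_sequence(300, rng)
    leafs, _ = evolve_family(
        tree, FamilySpec("Emc8", root, 0.0, 1.0, 0.01, branch, seed=seed)
    )
    seqs, species_of, tag_of = {}, {}, {}
    for leaf, copies in leafs.items():
        for seq, tag in copies:
            sid = f"{leaf}|Emc8" + (f"_{tag}" if tag else "")
            seqs[sid] = seq
            species_of[sid] = leaf
            tag_of[sid] = tag
    lineage_of = {
        sp: ("B1" if sp in ("S5", "S6") else "other")
        for sp in (f"S{i}" for i in range(1, 9))
    }
    outgroup = [sid for sid in seqs if species_of[sid] == "S1"]
    gene_tree = nj_build(score_distance(seqs))
    return duplication_clade_test(
        gene_tree, species_of, tag_of, lineage_of, "B1", outgroup
    )


def test_stem_duplication_called_lineage_specific():
    call = duplication_scenario(2, "B1")
    assert call.verdict == LINEAGE_SPECIFIC


def test_deep_duplication_pre_dates_lineage():
    call = duplication_scenario(2, "CladeB")
    assert call.verdict == PRE_DATES


def test_single_copy_family_is_unresolved():
    seq = random_root_sequence(150, np.random.default_rng(5))
    seqs = {"a|F": seq, "b|F": seq[10:], "c|F": seq[:140]}
    gene_tree = nj_build(score_distance(seqs))
    call = duplication_clade_test(
        gene_tree,
        {k: k[0] for k in seqs},
        {k: "" for k in seqs},
        {"a": "X", "b": "X", "c": "Y"},
        "X",
        ["c|F"],
    )
    assert call.verdict == UNRESOLVED
    assert "no b-tagged" in call.notes
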