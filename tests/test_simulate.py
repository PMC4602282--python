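"""Properties of the proteome evolution simulator."""

import numpy as np
import pytest

from phyloprofiler.seqsearch import local_align, read_fasta, self_score
from phyloprofiler.simulate import (
    FamilySpec,
    evolve_family,
    generate_proteomes,
    random_root_sequence,
)
from phyloprofiler.trees import find_node, load_tree, node_label

from .conftest import make_specs

ROOT_SEQ = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKALPDAQFEVVHSLAKWKR"


def test_zero_rate_identity(demo_tree):
    spec = FamilySpec("F", ROOT_SEQ, 0.0, 1e-12, 0.0, None, seed=1)
    leafs, log = evolve_family(demo_tree, spec)
    assert all(copies == [(ROOT_SEQ, "")] for copies in leafs.values())
    assert log.loss_branches == set()


def test_forced_loss_removes_family_everywhere(demo_tree):
    spec = FamilySpec("F", ROOT_SEQ, 1 - 1e-12, 1.0, 0.01, None, seed=1)
    leafs, log = evolve_family(demo_tree, spec)
    assert all(copies == [] for copies in leafs.values())
    # both root children lose the family; nothing below is ever tested
    assert log.loss_branches == {"CladeA", "CladeB"}


def test_loss_probability_validated():
    with pytest.raises(ValueError):
        FamilySpec("F", ROOT_SEQ, 1.0)
    with pytest.raises(ValueError):
        FamilySpec("F", "")


def test_loss_frequency_matches_configured_rate(demo_tree):
    """Per-branch loss frequency ~ Bernoulli(p) within 3 binomial SE."""
    p = 0.1
    trials = {}  # branch -> [attempts, losses]
    for seed in range(1, 101):
        spec = FamilySpec("F", ROOT_SEQ, p, 1.0, 0.01, None, seed=seed)
        _, log = evolve_family(demo_tree, spec)
        lost_subtrees = {
            node_label(lf)
            for b in log.loss_branches
            for lf in find_node(demo_tree, b).leaf_iter()
        }
        for node in demo_tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            label = node_label(node)
            # the branch is only at risk if the family survived to its parent
            parent = node.parent_node
            alive = parent.parent_node is None or not any(
                node_label(anc) in log.loss_branches
                for anc in _ancestors_inclusive(parent)
            )
            if alive:
                attempts, losses = trials.get(label, (0, 0))
                trials[label] = (attempts + 1, losses + (label in log.loss_branches))
        del lost_subtrees
    total_attempts = sum(a for a, _ in trials.values())
    total_losses = sum(l for _, l in trials.values())
    freq = total_losses / total_attempts
    se = (p * (1 - p) / total_attempts) ** 0.5
    assert abs(freq - p) <= 3 * se


def _ancestors_inclusive(node):
    while node is not None:
        yield node
        node = node.parent_node


def test_dollo_consistency_of_event_logs(demo_tree):
    """No leaf below a recorded loss branch ever carries the family."""
    for seed in range(1, 21):
        spec = FamilySpec("F", ROOT_SEQ, 0.15, 1.0, 0.01, None, seed=seed)
        leafs, log = evolve_family(demo_tree, spec)
        for branch in log.loss_branches:
            for lf in find_node(demo_tree, branch).leaf_iter():
                assert leafs[node_label(lf)] == []
        for leaf, copies in leafs.items():
            below_loss = any(
                node_label(anc) in log.loss_branches
                for anc in _ancestors_inclusive(find_node(demo_tree, leaf))
            )
            assert below_loss == (copies == [])


def test_divergence_monotone_in_rate(demo_tree):
    """Mean leaf-vs-root similarity is non-increasing in the rate multiplier."""
    means = []
    for rate in (0.3, 1.0, 2.5):
        sims = []
        for seed in range(1, 21):
            spec = FamilySpec("F", ROOT_SEQ, 0.0, rate, 0.01, None, seed=seed)
            leafs, _ = evolve_family(demo_tree, spec)
            for copies in leafs.values():
                seq = copies[0][0]
                sims.append(local_align(seq, ROOT_SEQ).raw_score / self_score(seq))
        means.append(sum(sims) / len(sims))
    assert means[0] > means[1] > means[2]


def test_duplication_tags_both_copies(demo_tree):
    spec = FamilySpec("F", ROOT_SEQ, 0.0, 1.0, 0.01, "B1", seed=3)
    leafs, log = evolve_family(demo_tree, spec)
    assert log.duplication_branch == "B1"
    for sp in ("S5", "S6"):
        assert sorted(tag for _, tag in leafs[sp]) == ["a", "b"]
    for sp in ("S1", "S2", "S3", "S4", "S7", "S8"):
        assert [tag for _, tag in leafs[sp]] == [""]


def test_proteome_counts_match_event_logs(demo_tree, tmp_path):
    specs = make_specs(7, loss=0.1, duplication=("Emc8", "B1"))
    pset = generate_proteomes(demo_tree, specs, 50, 7, tmp_path / "out")
    for sp, path in pset.fasta_paths.items():
        records = read_fasta(path)
        expected = 50 + sum(len(log.leaf_copies[sp]) for log in pset.event_logs)
        assert len(records) == expected
    all_ids = [sid for p in pset.fasta_paths.values() for sid in read_fasta(p)]
    assert len(all_ids) == len(set(all_ids))  # globally unique ids


def test_generation_is_deterministic(demo_tree, tmp_path):
    specs = make_specs(5)
    generate_proteomes(demo_tree, specs, 5, 5, tmp_path / "a")
    generate_proteomes(demo_tree, specs, 5, 5, tmp_path / "b")
    for sp in ("S1", "S8"):
        assert (tmp_path / "a" / f"{sp}.fasta").read_bytes() == (
            tmp_path / "b" / f"{sp}.fasta"
        ).read_bytes()
    assert (tmp_path / "a" / "events.tsv").read_bytes() == (
        tmp_path / "b" / "events.tsv"
    ).read_bytes()


def test_refuses_overwrite_without_force(demo_tree, tmp_path):
    specs = make_specs(5, n_families=1)
    generate_proteomes(demo_tree, specs, 0, 5, tmp_path / "x")
    with pytest.raises(FileExistsError):
        generate_proteomes(demo_tree, specs, 0, 5, tmp_path / "x")
    generate_proteomes(demo_tree, specs, 0, 5, tmp_path / "x", force=True)


def test_single_family_no_decoys_counts():
    tree = load_tree("((A:0.1,B:0.1)ab:0.1,(C:0.1,D:0.1)cd:0.1)R;")
    import tempfile, pathlib

    with tempfile.TemporaryDirectory() as tmp:
        spec = FamilySpec("F", ROOT_SEQ, 0.0, 1.0, 0.01, None, seed=2)
        pset = generate_proteomes(tree, [spec], 0, 2, pathlib.Path(tmp) / "o")
        assert len(pset.fasta_paths) == 4
        for path in pset.fasta_paths.values():
            assert len(read_fasta(path)) == 1


def test_root_sequence_sampler_uses_canonical_alphabet():
    seq = random_root_sequence(500, np.random.default_rng(0))
    from phyloprofiler.scoring import AMINO_ACIDS

    assert set(seq) <= set(AMINO_ACIDS) and len(seq) == 500
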