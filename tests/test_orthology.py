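"""Reciprocal-best-hit classification, paralog merging and propagation."""

import numpy as np
import pytest

from phyloprofiler.orthology import (
    ABSENT,
    AMBIGUOUS,
    PRESENT,
    WEAK,
    OrthologyCall,
    ParalogGroup,
    ReferenceSequence,
    ReferenceSet,
    Thresholds,
    classify_species,
    merge_paralog_columns,
    propagate_search,
    reciprocal_check,
)
from phyloprofiler.seqsearch import read_fasta
from phyloprofiler.simulate import (
    FamilySpec,
    evolve_family,
    generate_proteomes,
    random_root_sequence,
    reference_set_from_logs,
)
from phyloprofiler.trees import load_tree

from .conftest import make_specs

REF_SEQ = (
    "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKALPDAQFEVVHSLAKWKR"
    "QQLARHGFIRNLDAVQGSAAKVAEDLGLNEYVSFEQNMAFITGLSDLHDPKTARVLEFSAGVMDVEFADYLT"
)


def simple_refset(extra: dict[str, str] | None = None) -> ReferenceSet:
    proteome = {"R|Emc1": REF_SEQ, "R|decoy": random_root_sequence(200, np.random.default_rng(8))}
    proteome.update(extra or {})
    return ReferenceSet(
        {"Emc1": [ReferenceSequence("Emc1", "R", "R|Emc1", REF_SEQ)]},
        {"R": proteome},
    )


def test_reciprocal_self_recovery_is_present():
    refs = simple_refset()
    status, evidence = reciprocal_check(REF_SEQ, "cand", "Emc1", refs)
    assert status == PRESENT
    assert evidence["reciprocal_hit_id"] == "R|Emc1"
    assert evidence["reciprocal_norm"] == pytest.approx(1.0)
    assert evidence["margin"] is not None and evidence["margin"] > 0.5


def test_missing_reference_sequence_is_configuration_error():
    with pytest.raises(ValueError):
        ReferenceSet(
            {"Emc1": [ReferenceSequence("Emc1", "R", "R|missing", REF_SEQ)]},
            {"R": {"R|other": REF_SEQ}},
        )


def test_divergent_ortholog_lands_in_weak_band():
    """A fast-evolving true ortholog passes reciprocity but scores weakly."""
    tree = load_tree("(Ref:0.625,Div:0.625)R;")
    root = random_root_sequence(300, np.random.default_rng(3))
    leafs, _ = evolve_family(tree, FamilySpec("Emc1", root, 0.0, 1.0, 0.01, None, seed=1))
    ref_seq, div_seq = leafs["Ref"][0][0], leafs["Div"][0][0]
    refs = ReferenceSet(
        {"Emc1": [ReferenceSequence("Emc1", "Ref", "Ref|Emc1", ref_seq)]},
        {"Ref": {"Ref|Emc1": ref_seq,
                 "Ref|decoy": random_root_sequence(250, np.random.default_rng(9))}},
    )
    status, evidence = reciprocal_check(div_seq, "Div|Emc1", "Emc1", refs)
    assert status == WEAK
    assert 0.15 <= evidence["reciprocal_norm"] < 0.25


def test_near_paralog_in_reference_proteome_gives_ambiguous():
    """A planted close paralog erodes the reciprocal margin below threshold."""
    rng = np.random.default_rng(12)
    # near-paralog: a handful of substitutions on the reference sequence
    positions = rng.choice(len(REF_SEQ), size=6, replace=False)
    paralog = list(REF_SEQ)
    for pos in positions:
        paralog[pos] = "A" if REF_SEQ[pos] != "A" else "G"
    refs = simple_refset({"R|near_paralog": "".join(paralog)})
    status, evidence = reciprocal_check(REF_SEQ, "cand", "Emc1", refs)
    assert status == AMBIGUOUS
    assert evidence["margin"] is not None and evidence["margin"] < 0.10
    # hand cross-check: margin = (rank1 - rank2) / rank1 from the raw scores
    from phyloprofiler.seqsearch import local_align

    s1 = local_align(REF_SEQ, REF_SEQ).raw_score
    s2 = local_align(REF_SEQ, "".join(paralog)).raw_score
    assert evidence["margin"] == pytest.approx((s1 - s2) / s1)


def test_classification_matches_simulated_truth(small_dataset, small_calls):
    pset, _ = small_dataset
    truth = {
        (leaf, log.family_id): bool(log.leaf_copies[leaf])
        for log in pset.event_logs
        for leaf in log.leaf_copies
    }
    for call in small_calls:
        assert (call.status in (PRESENT, WEAK)) == truth[(call.species, call.family)], call


def test_partial_retention_scenario(demo_tree, tmp_path):
    """A species retaining only a subset is called present for exactly that subset."""
    specs = make_specs(31, loss=0.0)
    retained = {"Emc1", "Emc2", "Emc3", "Emc4", "Emc7", "Emc10"}
    # delete the other families on S3's terminal branch
    specs = [
        FamilySpec(s.family_id, s.root_sequence,
                   0.0, s.rate_multiplier, s.indel_rate, None, s.seed)
        for s in specs
    ]
    pset = generate_proteomes(demo_tree, specs, 20, 31, tmp_path / "p")
    proteomes = {sp: read_fasta(p) for sp, p in pset.fasta_paths.items()}
    # drop the non-retained families from S3's proteome outright
    proteomes["S3"] = {
        sid: seq for sid, seq in proteomes["S3"].items()
        if "decoy" in sid or sid.split("|")[1] in retained
    }
    refs = reference_set_from_logs(proteomes, pset.event_logs, ["S1"])
    calls = classify_species("S3", proteomes["S3"], refs)
    called_present = {c.family for c in calls if c.status in (PRESENT, WEAK)}
    assert called_present == retained


def test_decoy_only_proteome_all_absent(small_dataset):
    pset, proteomes = small_dataset
    decoys = {sid: seq for sid, seq in proteomes["S2"].items() if "decoy" in sid}
    refs = reference_set_from_logs(proteomes, pset.event_logs, ["S1", "S5"])
    calls = classify_species("S2", decoys, refs)
    assert all(c.status == ABSENT for c in calls)


def test_empty_proteome_yields_absent_calls(small_dataset):
    pset, proteomes = small_dataset
    refs = reference_set_from_logs(proteomes, pset.event_logs, ["S1", "S5"])
    calls = classify_species("SX", {}, refs)
    assert len(calls) == len(refs.families)
    assert all(c.status == ABSENT for c in calls)


def rescue_setup(tmp_path, loss_on_target: bool):
    """Two-rate scenario: reference far from the target, sister close."""
    tree = load_tree("(R:0.75,(Sis:0.05,T:0.85)ST:0.05)root;")
    root = random_root_sequence(300, np.random.default_rng(3))
    spec = FamilySpec("Emc1", root, 0.0, 1.0, 0.01, None, seed=1)
    pset = generate_proteomes(tree, [spec], 20, 1, tmp_path / "resc")
    proteomes = {sp: read_fasta(p) for sp, p in pset.fasta_paths.items()}
    if loss_on_target:  # emulate a true deletion on T's branch
        proteomes["T"] = {
            sid: seq for sid, seq in proteomes["T"].items() if "decoy" in sid
        }
    refs = reference_set_from_logs(proteomes, pset.event_logs, ["R"])
    calls = []
    for sp in sorted(proteomes):
        calls.extend(classify_species(sp, proteomes[sp], refs))
    return tree, proteomes, calls


def test_propagation_rescues_fast_evolving_ortholog(tmp_path):
    tree, proteomes, calls = rescue_setup(tmp_path, loss_on_target=False)
    before = {(c.species, c.family): c.status for c in calls}
    assert before[("T", "Emc1")] == ABSENT  # direct reference search misses it
    assert before[("Sis", "Emc1")] == PRESENT
    after = propagate_search(calls, proteomes, tree)
    upgraded = {(c.species, c.family): c for c in after}[("T", "Emc1")]
    assert upgraded.status in (PRESENT, WEAK)
    assert upgraded.provenance == "propagated from Sis"


def test_propagation_leaves_true_loss_absent(tmp_path):
    tree, proteomes, calls = rescue_setup(tmp_path, loss_on_target=True)
    after = propagate_search(calls, proteomes, tree)
    assert {(c.species, c.family): c.status for c in after}[("T", "Emc1")] == ABSENT


def test_propagation_fixpoint_and_never_demotes(small_dataset, small_calls, demo_tree):
    _, proteomes = small_dataset
    after = propagate_search(small_calls, proteomes, demo_tree)
    before_status = {(c.species, c.family): c.status for c in small_calls}
    rank = {PRESENT: 3, WEAK: 2, AMBIGUOUS: 1, ABSENT: 0}
    for call in after:
        assert rank[call.status] >= rank[before_status[(call.species, call.family)]]
    # a profile with no absents is a fixpoint
    again = propagate_search(after, proteomes, demo_tree)
    assert [(c.species, c.family, c.status) for c in again] == [
        (c.species, c.family, c.status) for c in after
    ]


def test_classification_is_deterministic(small_dataset):
    pset, proteomes = small_dataset
    refs = reference_set_from_logs(proteomes, pset.event_logs, ["S1", "S5"])
    a = classify_species("S4", proteomes["S4"], refs)
    b = classify_species("S4", proteomes["S4"], refs)
    assert a == b


# --- paralog group handling -------------------------------------------------


def paralog_refset():
    """Emc8 and Emc9 references are ancient near-paralogs of each other."""
    rng = np.random.default_rng(21)
    emc8 = random_root_sequence(250, rng)
    tree = load_tree("(A:0.35,B:0.35)R;")
    leafs, _ = evolve_family(tree, FamilySpec("x", emc8, 0.0, 1.0, 0.01, None, seed=4))
    emc8_ref, emc9_ref = leafs["A"][0][0], leafs["B"][0][0]
    proteome = {
        "R|Emc8": emc8_ref,
        "R|Emc9": emc9_ref,
        "R|decoy": random_root_sequence(220, rng),
    }
    refs = ReferenceSet(
        {
            "Emc8": [ReferenceSequence("Emc8", "R", "R|Emc8", emc8_ref)],
            "Emc9": [ReferenceSequence("Emc9", "R", "R|Emc9", emc9_ref)],
        },
        {"R": proteome},
    )
    return refs, emc8_ref, emc9_ref


def test_group_exemption_allows_co_member_rank_one():
    refs, emc8_ref, emc9_ref = paralog_refset()
    group = ParalogGroup.of("Emc8", "Emc9")
    # candidate is an exact Emc9: for an Emc8 forward candidate the reciprocal
    # rank-1 is the Emc9 reference -- absent without the exemption
    status_no_group, _ = reciprocal_check(emc9_ref, "cand", "Emc8", refs)
    status_group, _ = reciprocal_check(
        emc9_ref, "cand", "Emc8", refs, groups=[group]
    )
    assert status_no_group == ABSENT
    assert status_group == PRESENT


def test_two_candidates_get_paralog_tags():
    calls = [
        OrthologyCall("V", "Emc8", PRESENT, candidate_id="V|copy1", forward_norm=0.8),
        OrthologyCall("V", "Emc9", PRESENT, candidate_id="V|copy2", forward_norm=0.7),
    ]
    merged = merge_paralog_columns(calls, [ParalogGroup.of("Emc8", "Emc9")])
    tags = {c.family: c.paralog_tag for c in merged if c.status == PRESENT}
    assert tags == {"Emc8": "a", "Emc9": "b"}


def test_single_group_homolog_kept_untagged():
    calls = [
        OrthologyCall("U", "Emc8", PRESENT, candidate_id="U|only", forward_norm=0.8),
        OrthologyCall("U", "Emc9", PRESENT, candidate_id="U|only", forward_norm=0.75),
    ]
    merged = merge_paralog_columns(calls, [ParalogGroup.of("Emc8", "Emc9")])
    by_family = {c.family: c for c in merged}
    assert by_family["Emc8"].status == PRESENT
    assert by_family["Emc8"].paralog_tag == ""
    assert by_family["Emc9"].status == ABSENT
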