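"""Synthetic proteome evolution along a rooted species tree.

Protein families descend from a root sequence down the species tree.
On each branch of length t the family may be lost outright (Bernoulli,
Dollo-consistent: once lost it never returns in that subtree), every
site substitutes with probability 1 - exp(-t * rate), replacements drawn
from a BLOSUM62-derived exchange kernel conditioned on the current
residue, and indels occur as point events (Poisson in t * length) with
geometric lengths of mean 3.  One branch per family may carry a
duplication: the sequence is copied there and both copies evolve
independently afterwards, tagged ``a`` and ``b`` (the analogue of the
vertebrate-specific Emc8 -> Emc8a/Emc8b duplication).  Decoy proteins
are i.i.d. draws from the BLOSUM62 background composition, so they share
no homology with anything.

Reproducibility: every random stream is derived as
``default_rng([seed, stream_index, branch_index, copy_index])`` from the
family seed (itself derived from the master seed and the family index),
so any family can be regenerated independently of the others.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .scoring import AMINO_ACIDS, background_probabilities, exchange_distribution
from .seqsearch import write_fasta
from .trees import node_label, to_newick

_DECOY_STREAM = 1_000_003  # stream index offset keeps decoy rng disjoint from family streams


@dataclass(frozen=True)
class FamilySpec:
    """Evolutionary scenario for one protein family."""

    family_id: str
    root_sequence: str
    loss_probability: float = 0.0
    rate_multiplier: float = 1.0
    indel_rate: float = 0.01  # events per site per unit branch length
    duplication_branch: str | None = None  # child-node label
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.root_sequence:
            raise ValueError(f"{self.family_id}: empty root sequence")
        bad = set(self.root_sequence) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(
                f"{self.family_id}: root sequence must use the 20 canonical "
                f"amino acids, found {sorted(bad)}"
            )
        if not 0.0 <= self.loss_probability < 1.0:
            raise ValueError(f"{self.family_id}: loss probability must be in [0, 1)")
        if self.rate_multiplier <= 0:
            raise ValueError(f"{self.family_id}: rate multiplier must be positive")
        if self.indel_rate < 0:
            raise ValueError(f"{self.family_id}: indel rate must be non-negative")


@dataclass
class FamilyEventLog:
    """Ground truth for one simulated family."""

    family_id: str
    loss_branches: set[str] = field(default_factory=set)
    duplication_branch: str | None = None
    #: leaf -> list of (sequence id, family id, paralog tag "" | "a" | "b")
    leaf_copies: dict[str, list[tuple[str, str, str]]] = field(default_factory=dict)

    def presence(self) -> dict[str, bool]:
        return {leaf: bool(copies) for leaf, copies in self.leaf_copies.items()}


@dataclass
class SyntheticProteomeSet:
    """A full set of per-species FASTA files plus ground truth."""

    fasta_paths: dict[str, Path]
    decoy_counts: dict[str, int]
    event_logs: list[FamilyEventLog]
    master_seed: int


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([seed, *key])


def _substitute(seq: np.ndarray, t: float, rate: float, rng: np.random.Generator,
                kernel: np.ndarray) -> np.ndarray:
    if t <= 0 or rate <= 0 or len(seq) == 0:
        return seq
    p = 1.0 - np.exp(-t * rate)
    hits = rng.random(len(seq)) < p
    if not hits.any():
        return seq
    out = seq.copy()
    for i in np.flatnonzero(hits):
        out[i] = rng.choice(20, p=kernel[out[i]])
    return out


def _indels(seq: np.ndarray, t: float, rate: float, rng: np.random.Generator,
            background: np.ndarray) -> np.ndarray:
    if t <= 0 or rate <= 0 or len(seq) == 0:
        return seq
    n_events = rng.poisson(rate * t * len(seq))
    for _ in range(n_events):
        length = rng.geometric(1.0 / 3.0)  # mean 3
        if rng.random() < 0.5 and len(seq) > length + 10:  # deletion, keep a core
            start = rng.integers(0, len(seq) - length + 1)
            seq = np.concatenate([seq[:start], seq[start + length:]])
        else:  # insertion
            start = rng.integers(0, len(seq) + 1)
            insert = rng.choice(20, size=length, p=background)
            seq = np.concatenate([seq[:start], insert, seq[start:]])
    return seq


def _encode(seq: str) -> np.ndarray:
    index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    return np.array([index[c] for c in seq], dtype=np.int64)


def _decode(arr: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[i] for i in arr)


def evolve_family(
    tree: dendropy.Tree, spec: FamilySpec,
    protected_leaves: frozenset[str] | set[str] = frozenset(),
) -> tuple[dict[str, list[tuple[str, str]]], FamilyEventLog]:
    """Evolve one family down the tree.

    Returns ``leaf -> [(sequence, paralog tag), ...]`` plus the event log
    recording planted losses and the duplication.  Fully deterministic in
    ``spec.seed``.  Branches on the root-to-leaf path of any protected
    leaf never lose the family (used to keep reference species carrying
    every family, mirroring how reference proteomes are chosen in
    practice); loss rates elsewhere are unaffected.
    """
    kernel = exchange_distribution()
    background = background_probabilities()
    log = FamilyEventLog(family_id=spec.family_id)
    leaf_seqs: dict[str, list[tuple[str, str]]] = {}
    branch_index = {node_label(nd): i for i, nd in enumerate(tree.preorder_node_iter())}
    protected_branches: set[str] = set()
    for leaf in tree.leaf_node_iter():
        if node_label(leaf) in protected_leaves:
            nd = leaf
            while nd is not None:
                protected_branches.add(node_label(nd))
                nd = nd.parent_node

    def descend(node: dendropy.Node, copies: list[tuple[np.ndarray, str]]) -> None:
        label = node_label(node)
        bidx = branch_index[label]
        if node.parent_node is not None and copies:
            loss_rng = _rng(spec.seed, 0, bidx)
            if label not in protected_branches and loss_rng.random() < spec.loss_probability:
                log.loss_branches.add(label)
                copies = []
            else:
                t = node.edge.length or 0.0
                if label == spec.duplication_branch and len(copies) == 1:
                    # duplication at the branch midpoint: evolve the single
                    # copy over t/2, duplicate, then evolve both halves
                    # independently -- this leaves a positive-length edge
                    # between the speciation and the duplication node.
                    log.duplication_branch = label
                    seq, _ = copies[0]
                    rng = _rng(spec.seed, 1, bidx, 0)
                    seq = _substitute(seq, t / 2, spec.rate_multiplier, rng, kernel)
                    seq = _indels(seq, t / 2, spec.indel_rate, rng, background)
                    copies = [(seq.copy(), "a"), (seq.copy(), "b")]
                    evolved = []
                    for cidx, (seq, tag) in enumerate(copies):
                        rng = _rng(spec.seed, 2, bidx, cidx)
                        seq = _substitute(seq, t / 2, spec.rate_multiplier, rng, kernel)
                        seq = _indels(seq, t / 2, spec.indel_rate, rng, background)
                        evolved.append((seq, tag))
                    copies = evolved
                else:
                    evolved = []
                    for cidx, (seq, tag) in enumerate(copies):
                        rng = _rng(spec.seed, 1, bidx, cidx)
                        seq = _substitute(seq, t, spec.rate_multiplier, rng, kernel)
                        seq = _indels(seq, t, spec.indel_rate, rng, background)
                        evolved.append((seq, tag))
                    copies = evolved
        if node.is_leaf():
            leaf_seqs[label] = [(_decode(seq), tag) for seq, tag in copies]
            log.leaf_copies[label] = []  # sequence ids are filled by the caller
        else:
            for child in node.child_nodes():
                descend(child, copies)

    descend(tree.seed_node, [(_encode(spec.root_sequence), "")])
    return leaf_seqs, log


def random_root_sequence(length: int, rng: np.random.Generator) -> str:
    """A root sequence drawn from the background composition."""
    return _decode(rng.choice(20, size=length, p=background_probabilities()))


def make_decoys(
    count: int, rng: np.random.Generator, min_len: int = 80, max_len: int = 500
) -> list[str]:
    """Unrelated background-composition proteins of random length."""
    background = background_probabilities()
    lengths = rng.integers(min_len, max_len + 1, size=count)
    return [_decode(rng.choice(20, size=int(n), p=background)) for n in lengths]


def derive_family_seed(master_seed: int, family_index: int) -> int:
    """Stable per-family sub-seed, kept below 2**31."""
    ss = np.random.SeedSequence([master_seed, family_index])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_proteomes(
    tree: dendropy.Tree,
    specs: Iterable[FamilySpec],
    decoys_per_species: int,
    master_seed: int,
    out_dir: str | Path,
    force: bool = False,
    protected_leaves: frozenset[str] | set[str] = frozenset(),
) -> SyntheticProteomeSet:
    """Write one FASTA per leaf species plus truth logs.

    Every species receives its surviving family copies (ids
    ``species|family`` with ``_a``/``_b`` suffixes past a duplication)
    and ``decoys_per_species`` unrelated proteins.  Refuses to overwrite
    an existing output directory unless ``force`` is given.  Output is
    byte-reproducible from (tree, specs, master seed).
    """
    specs = list(specs)
    ids = [s.family_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("family ids must be unique")
    out_dir = Path(out_dir)
    if out_dir.exists():
        if not force:
            raise FileExistsError(f"output directory exists: {out_dir} (use force)")
        shutil.rmtree(out_dir)
    out_dir.mkdir(parents=True)

    # reseed specs deterministically from the master seed when unset (0)
    effective = [
        spec if spec.seed else FamilySpec(
            spec.family_id, spec.root_sequence, spec.loss_probability,
            spec.rate_multiplier, spec.indel_rate, spec.duplication_branch,
            derive_family_seed(master_seed, i),
        )
        for i, spec in enumerate(specs)
    ]

    per_leaf: dict[str, dict[str, str]] = {
        node_label(lf): {} for lf in tree.leaf_node_iter()
    }
    logs: list[FamilyEventLog] = []
    for spec in effective:
        leaf_seqs, log = evolve_family(tree, spec, protected_leaves)
        for leaf, copies in leaf_seqs.items():
            for seq, tag in copies:
                sid = f"{leaf}|{spec.family_id}" + (f"_{tag}" if tag else "")
                per_leaf[leaf][sid] = seq
                log.leaf_copies[leaf].append((sid, spec.family_id, tag))
        logs.append(log)

    fasta_paths: dict[str, Path] = {}
    decoy_counts: dict[str, int] = {}
    for sidx, leaf in enumerate(sorted(per_leaf)):
        decoy_rng = _rng(master_seed, _DECOY_STREAM, sidx)
        for d, seq in enumerate(make_decoys(decoys_per_species, decoy_rng)):
            per_leaf[leaf][f"{leaf}|decoy{d:04d}"] = seq
        path = out_dir / f"{leaf}.fasta"
        write_fasta(per_leaf[leaf], path)
        fasta_paths[leaf] = path
        decoy_counts[leaf] = decoys_per_species

    write_event_logs(logs, out_dir / "events.tsv")
    (out_dir / "tree.nwk").write_text(to_newick(tree) + "\n")
    return SyntheticProteomeSet(fasta_paths, decoy_counts, logs, master_seed)


def write_event_logs(logs: Iterable[FamilyEventLog], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("family\tbranch\tevent\tleaf\tsequence_id\n")
        for log in logs:
            for branch in sorted(log.loss_branches):
                fh.write(f"{log.family_id}\t{branch}\tloss\t\t\n")
            if log.duplication_branch:
                fh.write(f"{log.family_id}\t{log.duplication_branch}\tduplication\t\t\n")
            for leaf in sorted(log.leaf_copies):
                for sid, fam, tag in log.leaf_copies[leaf]:
                    fh.write(f"{fam}\t\tcopy\t{leaf}\t{sid}\n")


def reference_set_from_logs(
    proteomes: Mapping[str, Mapping[str, str]],
    logs: Iterable[FamilyEventLog],
    reference_species: Sequence[str],
):
    """Build an orthology ReferenceSet from simulated truth.

    The designated reference species play the role of the experimentally
    anchored proteomes; their surviving family copies become the
    reference queries.  Fails if a family has no copy in any reference
    species.
    """
    from .orthology import ReferenceSequence, ReferenceSet

    references: dict[str, list[ReferenceSequence]] = {}
    for log in logs:
        refs = []
        for species in reference_species:
            for sid, fam, tag in log.leaf_copies.get(species, []):
                refs.append(
                    ReferenceSequence(fam, species, sid, proteomes[species][sid])
                )
        if not refs:
            raise ValueError(
                f"family {log.family_id} absent from all reference species"
            )
        references[log.family_id] = refs
    return ReferenceSet(
        references, {sp: proteomes[sp] for sp in reference_species}
    )
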