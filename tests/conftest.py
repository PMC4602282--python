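"""Shared fixtures: a small simulated proteome set reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from phyloprofiler.orthology import classify_species
from phyloprofiler.pipeline import DEMO_TREE
from phyloprofiler.seqsearch import read_fasta
from phyloprofiler.simulate import (
    FamilySpec,
    generate_proteomes,
    random_root_sequence,
    reference_set_from_logs,
)
from phyloprofiler.trees import load_tree

FAMILY_IDS = ["Emc1", "Emc2", "Emc3", "Emc4", "Emc5", "Emc6", "Emc7", "Emc8", "Emc10"]


def make_specs(
    seed: int,
    loss: float = 0.05,
    rate: float = 1.0,
    duplication: tuple[str, str] | None = None,
    n_families: int = 9,
) -> list[FamilySpec]:
    """Deterministic family scenarios for the demo topology."""
    rng = np.random.default_rng([seed, 17])
    specs = []
    for i, fam in enumerate(FAMILY_IDS[:n_families]):
        root = random_root_sequence(int(rng.integers(150, 400)), rng)
        dup = duplication[1] if duplication and duplication[0] == fam else None
        specs.append(FamilySpec(fam, root, loss, rate, 0.01, dup, seed=seed + i + 1))
    return specs


@pytest.fixture(scope="session")
def demo_tree():
    return load_tree(DEMO_TREE)


@pytest.fixture(scope="session")
def small_dataset(demo_tree, tmp_path_factory):
    """8 species, 9 families, 20 decoys, planted losses (seed 101)."""
    out = tmp_path_factory.mktemp("proteomes")
    pset = generate_proteomes(demo_tree, make_specs(101), 20, 101, out / "set", force=True)
    proteomes = {sp: read_fasta(p) for sp, p in pset.fasta_paths.items()}
    return pset, proteomes


@pytest.fixture(scope="session")
def small_calls(small_dataset):
    pset, proteomes = small_dataset
    refs = reference_set_from_logs(proteomes, pset.event_logs, ["S1", "S5"])
    calls = []
    for sp in sorted(proteomes):
        calls.extend(classify_species(sp, proteomes[sp], refs))
    return calls
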