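"""Evolve synthetic proteomes for 8 species and inspect the ground truth.

Nine subunit families descend from random root sequences along a rooted
species tree, with substitutions, indels and a 10% per-branch chance of
losing each family (reference species S1/S5 are protected so they can
later serve as search anchors).  Each species also receives 30 unrelated
decoy proteins.
"""

from pathlib import Path
import tempfile

import numpy as np

from phyloprofiler import FamilySpec, generate_proteomes, load_tree, random_root_sequence
from phyloprofiler.pipeline import DEMO_TREE

tree = load_tree(DEMO_TREE)
rng = np.random.default_rng(42)
specs = [
    FamilySpec(f"Emc{i}", random_root_sequence(250, rng),
               loss_probability=0.1, rate_multiplier=1.0, seed=42 + i)
    for i in (1, 2, 3, 4, 5, 6, 7, 8, 10)
]

with tempfile.TemporaryDirectory() as tmp:
    pset = generate_proteomes(
        tree, specs, decoys_per_species=30, master_seed=42,
        out_dir=Path(tmp) / "proteomes", protected_leaves={"S1", "S5"},
    )
    for sp, path in sorted(pset.fasta_paths.items()):
        n = path.read_text().count(">")
        print(f"{sp}: {n} sequences")
    print("\nplanted events:")
    for log in pset.event_logs:
        if log.loss_branches:
            print(f"  {log.family_id}: lost on {sorted(log.loss_branches)}")

# Each proteome holds 30 decoys plus one copy of every family that
# survived on the path to that leaf; the loss lines are the ground truth
# that the orthology and Dollo stages are later measured against.
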