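"""Reconstruct gains and losses of the EMC on the eukaryote tree.

Dollo parsimony places each family's single gain at the MRCA of the
species that carry it and explains every absence below that point with
the minimal set of loss branches.
"""

from phyloprofiler import (
    ancestral_state,
    annotate_events,
    curated_profile,
    curated_species_tree,
    dollo_reconstruct,
)

profile = curated_profile()
tree = curated_species_tree()
recs = dollo_reconstruct(profile, tree)

leca = ancestral_state(recs, tree, "LECA")
print("families at the eukaryote root (LECA):",
      ", ".join(sorted(leca, key=lambda f: int(f[3:]))))

events, annotated = annotate_events(recs, tree)
losses = [e for e in events if e[1] == "loss"]
print(f"\n{len(losses)} loss events, for example:")
for family, _, branch in losses[:8]:
    print(f"  {family} lost on the branch to {branch}")

# Nine of the ten subunits trace back to the eukaryote root; Emc9 alone
# originates within vertebrates because it is the product of a
# vertebrate-specific duplication of Emc8.
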