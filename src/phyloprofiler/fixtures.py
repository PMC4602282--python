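"""Curated EMC phyletic profile over representative eukaryotes.

This fixture hand-codes the published presence/absence statements for
the ER membrane protein complex (EMC) across a reduced species panel:
six species that lost the complex entirely (two microsporidians, a
metamonad, a stramenopile, an alveolate and a red alga), the documented
partial retainers (Entamoeba histolytica, Cryptosporidium parvum,
Piromyces sp.), Trichomonas vaginalis with its single weakly supported
Emc2, Saccharomyces cerevisiae with Emc1-7 and Emc10 (Sop4 and YDR056C
being Emc7 and Emc10), Homo sapiens with all ten subunits (Emc8/Emc9
being the products of a vertebrate-specific duplication of Emc8), and
one complete-complement representative for each remaining supergroup.
Only species-level statements are encoded; no per-genus rescues.

The companion species tree (``data/emc_species_tree.nwk``) is a
consensus eukaryote supergroup topology rooted at LECA; the placement of
Excavata as sister to Diaphoretickes is a documented choice, not a
result.
"""

from __future__ import annotations

import importlib.resources

import dendropy
import pandas as pd

from .orthology import ABSENT, PRESENT, WEAK
from .profiles import PhyleticProfile
from .trees import load_tree

FAMILIES = [f"Emc{i}" for i in range(1, 11)]

#: species -> (lineage, retained families); "weak:" prefixes a weak call.
_CURATED: dict[str, tuple[str, list[str]]] = {
    "Homo sapiens": ("Opisthokonta", FAMILIES),
    "Saccharomyces cerevisiae": (
        "Opisthokonta", ["Emc1", "Emc2", "Emc3", "Emc4", "Emc5", "Emc6", "Emc7", "Emc10"],
    ),
    "Piromyces sp.": (
        "Opisthokonta", ["Emc1", "Emc2", "Emc3", "Emc4", "Emc6", "Emc7", "Emc10"],
    ),
    "Nosema ceranae": ("Opisthokonta", []),
    "Encephalitozoon cuniculi": ("Opisthokonta", []),
    "Dictyostelium discoideum": (
        "Amoebozoa", ["Emc1", "Emc2", "Emc3", "Emc4", "Emc5", "Emc6", "Emc7", "Emc8", "Emc10"],
    ),
    "Entamoeba histolytica": (
        "Amoebozoa", ["Emc1", "Emc2", "Emc3", "Emc4", "Emc7", "Emc10"],
    ),
    "Naegleria gruberi": (
        "Excavata", ["Emc1", "Emc2", "Emc3", "Emc4", "Emc5", "Emc6", "Emc7", "Emc8", "Emc10"],
    ),
    "Giardia intestinalis": ("Excavata", []),
    "Trichomonas vaginalis": ("Excavata", ["weak:Emc2"]),
    "Blastocystis hominis": ("SAR", []),
    "Phytophthora sojae": (
        "SAR", ["Emc1", "Emc2", "Emc3", "Emc4", "Emc5", "Emc6", "Emc7", "Emc8", "Emc10"],
    ),
    "Theileria parva": ("SAR", []),
    "Cryptosporidium parvum": ("SAR", ["Emc1", "Emc2", "Emc3", "Emc4", "Emc8"]),
    "Arabidopsis thaliana": (
        "Archaeplastida", ["Emc1", "Emc2", "Emc3", "Emc4", "Emc5", "Emc6", "Emc7", "Emc8", "Emc10"],
    ),
    "Cyanidioschyzon merolae": ("Archaeplastida", []),
    "Emiliania huxleyi": (
        "Haptophyta", ["Emc1", "Emc2", "Emc3", "Emc4", "Emc5", "Emc6", "Emc7", "Emc8", "Emc10"],
    ),
}

#: The six species documented as having lost the complex entirely.
COMPLETE_LOSS_SPECIES = [
    "Nosema ceranae",
    "Encephalitozoon cuniculi",
    "Giardia intestinalis",
    "Blastocystis hominis",
    "Theileria parva",
    "Cyanidioschyzon merolae",
]


def curated_profile() -> PhyleticProfile:
    """The curated EMC presence/absence matrix as a PhyleticProfile."""
    species = list(_CURATED)
    rows = {}
    for sp, (_lineage, retained) in _CURATED.items():
        statuses = {}
        for fam in FAMILIES:
            if fam in retained:
                statuses[fam] = PRESENT
            elif f"weak:{fam}" in retained:
                statuses[fam] = WEAK
            else:
                statuses[fam] = ABSENT
        rows[sp] = statuses
    matrix = pd.DataFrame.from_dict(rows, orient="index")[FAMILIES].loc[species]
    lineages = {sp: lineage for sp, (lineage, _) in _CURATED.items()}
    tags = {
        ("Homo sapiens", "Emc8"): "a",  # the vertebrate Emc8a/Emc8b pair
        ("Homo sapiens", "Emc9"): "b",
    }
    return PhyleticProfile(species, FAMILIES, matrix, lineages, tags)


def curated_species_tree() -> dendropy.Tree:
    """The rooted supergroup tree shipped with the package (root = LECA)."""
    ref = importlib.resources.files("phyloprofiler.data") / "emc_species_tree.nwk"
    return load_tree(str(ref))
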