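"""Phyletic profiles: the species x subunit presence/absence matrix.

A :class:`PhyleticProfile` holds one orthology status per (species,
family) cell plus lineage labels for grouping rows, and round-trips to a
plain TSV.  Summaries report complete-loss species, partial retention
and per-family retention counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .orthology import ABSENT, AMBIGUOUS, PRESENT, WEAK, OrthologyCall

_STATUSES = (PRESENT, WEAK, AMBIGUOUS, ABSENT)


@dataclass
class PhyleticProfile:
    """Ordered species x family status matrix with lineage grouping."""

    species: list[str]
    families: list[str]
    statuses: pd.DataFrame  # index species, columns families, values status strings
    lineages: dict[str, str] = field(default_factory=dict)  # species -> lineage
    paralog_tags: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.statuses.index) != self.species or list(
            self.statuses.columns
        ) != self.families:
            raise ValueError("status matrix must match species/family orderings")
        bad = set(self.statuses.values.ravel()) - set(_STATUSES)
        if bad:
            raise ValueError(f"invalid statuses in matrix: {sorted(bad)}")

    def status(self, species: str, family: str) -> str:
        return self.statuses.at[species, family]

    def is_present(self, species: str, family: str, weak_counts: bool = True) -> bool:
        st = self.status(species, family)
        return st == PRESENT or (weak_counts and st == WEAK)

    def present_species(self, family: str, weak_counts: bool = True) -> list[str]:
        return [s for s in self.species if self.is_present(s, family, weak_counts)]

    def calls_count(self) -> dict[str, int]:
        flat = self.statuses.values.ravel()
        return {st: int((flat == st).sum()) for st in _STATUSES}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("species\tlineage\t" + "\t".join(self.families) + "\n")
            for sp in self.species:
                row = "\t".join(self.statuses.loc[sp])
                fh.write(f"{sp}\t{self.lineages.get(sp, '')}\t{row}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PhyleticProfile":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        families = list(df.columns[2:])
        species = list(df["species"])
        statuses = df[families]
        statuses.index = species
        lineages = dict(zip(df["species"], df["lineage"]))
        return cls(species, families, statuses, lineages)


def assemble_profile(
    calls: Sequence[OrthologyCall],
    species_order: Sequence[str],
    family_order: Sequence[str],
    lineages: Mapping[str, str] | None = None,
) -> PhyleticProfile:
    """Arrange calls into a matrix; every (species, family) exactly once."""
    table: dict[tuple[str, str], OrthologyCall] = {}
    dupes = []
    for call in calls:
        key = (call.species, call.family)
        if key in table:
            dupes.append(key)
        table[key] = call
    missing = [
        (sp, fam)
        for sp in species_order
        for fam in family_order
        if (sp, fam) not in table
    ]
    if dupes or missing:
        raise ValueError(
            f"calls must cover every (species, family) exactly once; "
            f"duplicates={sorted(dupes)} missing={sorted(missing)}"
        )
    data = {
        fam: [table[(sp, fam)].status for sp in species_order] for fam in family_order
    }
    statuses = pd.DataFrame(data, index=list(species_order))[list(family_order)]
    tags = {
        (c.species, c.family): c.paralog_tag
        for c in calls
        if c.paralog_tag
    }
    return PhyleticProfile(
        list(species_order), list(family_order), statuses,
        dict(lineages or {}), tags,
    )


@dataclass(frozen=True)
class LossSummary:
    """Loss patterns across the profile."""

    complete_loss_species: list[str]
    partial_retention: dict[str, list[str]]  # species -> retained families
    family_retention_counts: dict[str, int]


def summarize_losses(
    profile: PhyleticProfile, weak_counts: bool = True
) -> LossSummary:
    """Complete-loss species, partial retainers and per-family counts.

    ``weak_counts`` mirrors the reconstruction default: a weak ortholog
    still documents retention.
    """
    complete, partial = [], {}
    for sp in profile.species:
        retained = [
            fam for fam in profile.families if profile.is_present(sp, fam, weak_counts)
        ]
        if not retained:
            complete.append(sp)
        elif len(retained) < len(profile.families):
            partial[sp] = retained
    counts = {
        fam: len(profile.present_species(fam, weak_counts))
        for fam in profile.families
    }
    return LossSummary(complete, partial, counts)
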