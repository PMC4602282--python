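"""Coulson plot rendering: one segmented pie per species.

Each pie has as many equal sectors as there are subunit families.
Sector encoding: present = solid family colour, weak = hatched (a
pattern fill of the family colour), ambiguous = outlined in the family
colour with white fill, absent = empty.  Species are grouped by lineage
and the output is plain SVG 1.1 text, byte-deterministic for a given
profile and style.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

from .orthology import AMBIGUOUS, PRESENT, WEAK
from .profiles import PhyleticProfile

#: Deterministic palette keyed by family index (repeats past 12).
PALETTE = [
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd", "#8c564b",
    "#e377c2", "#7f7f7f", "#bcbd22", "#17becf", "#aec7e8", "#ffbb78",
]

MAX_SPECIES = 200
MAX_FAMILIES = 24


@dataclass(frozen=True)
class CoulsonStyle:
    pie_radius: float = 26.0
    cell: float = 70.0  # grid pitch
    columns: int = 8
    label_size: float = 8.0
    group_gap: float = 26.0


def _fmt(x: float) -> str:
    return f"{x:.3f}"


def _sector_path(cx: float, cy: float, r: float, start: float, end: float) -> str:
    """SVG path for a pie sector between two angles (radians, clockwise)."""
    x1, y1 = cx + r * math.sin(start), cy - r * math.cos(start)
    x2, y2 = cx + r * math.sin(end), cy - r * math.cos(end)
    large = 1 if (end - start) > math.pi else 0
    return (
        f"M {_fmt(cx)} {_fmt(cy)} L {_fmt(x1)} {_fmt(y1)} "
        f"A {_fmt(r)} {_fmt(r)} 0 {large} 1 {_fmt(x2)} {_fmt(y2)} Z"
    )


def family_color(index: int) -> str:
    return PALETTE[index % len(PALETTE)]


def render_coulson(
    profile: PhyleticProfile, style: CoulsonStyle = CoulsonStyle()
) -> str:
    """Render the profile as an SVG document string."""
    if len(profile.species) > MAX_SPECIES or len(profile.families) > MAX_FAMILIES:
        raise ValueError(
            f"layout bound exceeded: at most {MAX_SPECIES} species and "
            f"{MAX_FAMILIES} families per plot"
        )
    n_fam = len(profile.families)
    # group species by lineage, preserving profile order within and across groups
    groups: list[tuple[str, list[str]]] = []
    for sp in profile.species:
        lineage = profile.lineages.get(sp, "")
        if groups and groups[-1][0] == lineage:
            groups[-1][1].append(sp)
        else:
            groups.append((lineage, [sp]))

    defs = []
    for i in range(n_fam):
        color = family_color(i)
        defs.append(
            f'<pattern id="hatch{i}" width="4" height="4" '
            'patternUnits="userSpaceOnUse" patternTransform="rotate(45)">'
            f'<rect width="4" height="4" fill="#ffffff"/>'
            f'<line x1="0" y1="0" x2="0" y2="4" stroke="{color}" stroke-width="2"/>'
            "</pattern>"
        )

    body = []
    y = style.cell * 0.75
    for lineage, members in groups:
        if lineage:
            body.append(
                f'<text x="10" y="{_fmt(y - style.cell * 0.55)}" '
                f'font-size="{style.label_size + 2}" font-weight="bold" '
                f'font-family="sans-serif">{lineage}</text>'
            )
        for i, sp in enumerate(members):
            col, row = i % style.columns, i // style.columns
            cx = 40 + col * style.cell + style.cell / 2
            cy = y + row * style.cell
            for j, fam in enumerate(profile.families):
                start = 2 * math.pi * j / n_fam
                end = 2 * math.pi * (j + 1) / n_fam
                status = profile.status(sp, fam)
                color = family_color(j)
                if status == PRESENT:
                    fill, stroke = color, "#333333"
                elif status == WEAK:
                    fill, stroke = f"url(#hatch{j})", "#333333"
                elif status == AMBIGUOUS:
                    fill, stroke = "#ffffff", color
                else:
                    fill, stroke = "none", "#bbbbbb"
                body.append(
                    f'<path class="sector {status}" d="'
                    + _sector_path(cx, cy, style.pie_radius, start, end)
                    + f'" fill="{fill}" stroke="{stroke}" stroke-width="0.8"/>'
                )
            body.append(
                f'<text x="{_fmt(cx)}" y="{_fmt(cy + style.pie_radius + 11)}" '
                f'font-size="{style.label_size}" text-anchor="middle" '
                f'font-family="sans-serif" font-style="italic">{sp}</text>'
            )
        rows = (len(members) - 1) // style.columns + 1
        y += rows * style.cell + style.group_gap

    # legend: one swatch per family
    legend_y = y
    for j, fam in enumerate(profile.families):
        lx = 40 + (j % 6) * 90
        ly = legend_y + (j // 6) * 18
        body.append(
            f'<rect x="{_fmt(lx)}" y="{_fmt(ly)}" width="12" height="12" '
            f'fill="{family_color(j)}" stroke="#333333" stroke-width="0.5"/>'
        )
        body.append(
            f'<text x="{_fmt(lx + 16)}" y="{_fmt(ly + 10)}" '
            f'font-size="{style.label_size}" font-family="sans-serif">{fam}</text>'
        )
    height = legend_y + ((n_fam - 1) // 6 + 1) * 18 + 20
    width = 60 + style.columns * style.cell
    header = (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(width)}" height="{_fmt(height)}">\n<defs>'
        + "".join(defs)
        + "</defs>\n"
    )
    return header + "\n".join(body) + "\n</svg>\n"


def write_coulson(
    profile: PhyleticProfile, path: str | Path, style: CoulsonStyle = CoulsonStyle()
) -> None:
    Path(path).write_text(render_coulson(profile, style))
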