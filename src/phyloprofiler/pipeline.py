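"""End-to-end pipeline: simulate -> search -> classify -> propagate ->
profile -> ancestral reconstruction -> duplication dating.

A single YAML config drives every stage; each stage writes its artifact
under the output directory and the run ends with a manifest recording
the config echo, per-stage timings, call counters and SHA-256 checksums
of every non-timing output.  Re-running the same config reproduces
identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import ancestral as anc
from . import orthology as orth
from .coulson import write_coulson
from .fixtures import curated_profile, curated_species_tree
from .genetree import duplication_clade_test, nj_build, score_distance
from .profiles import PhyleticProfile, assemble_profile, summarize_losses
from .seqsearch import read_fasta
from .simulate import (
    FamilySpec,
    derive_family_seed,
    generate_proteomes,
    random_root_sequence,
    reference_set_from_logs,
)
from .trees import find_node, leaf_names, load_tree, node_label, to_newick

logger = logging.getLogger(__name__)

#: 8-species demo topology: two major clades, reference species S1 and S5,
#: the (S5,S6) stem ``B1`` available as a duplication branch.
DEMO_TREE = (
    "(((S1:0.1,S2:0.1)A1:0.1,(S3:0.1,S4:0.1)A2:0.1)CladeA:0.15,"
    "((S5:0.1,S6:0.1)B1:0.1,(S7:0.1,S8:0.1)B2:0.1)CladeB:0.15)R;"
)

DEFAULT_FAMILIES = ["Emc1", "Emc2", "Emc3", "Emc4", "Emc5", "Emc6", "Emc7", "Emc8", "Emc10"]


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run."""

    out_dir: Path
    seed: int = 0
    mode: str = "simulate"  # simulate | fixture
    tree: str | None = None  # newick path/string; demo topology when None
    families: list[str] = field(default_factory=lambda: list(DEFAULT_FAMILIES))
    loss_probability: float = 0.05
    rate_multiplier: float = 1.0
    indel_rate: float = 0.01
    root_length_range: tuple[int, int] = (150, 400)
    duplication: dict[str, str] | None = None  # {"family": ..., "branch": ...}
    decoys: int = 30
    reference_species: list[str] = field(default_factory=lambda: ["S1", "S5"])
    thresholds: orth.Thresholds = orth.Thresholds()
    paralog_groups: list[list[str]] = field(default_factory=list)
    genetree: dict[str, Any] | None = None  # {"lineage": label} for the dup family
    force: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thresholds = orth.Thresholds(**raw.pop("thresholds", {}))
        out_dir = Path(raw.pop("out_dir"))
        rlr = raw.pop("root_length_range", (150, 400))
        return cls(
            out_dir=out_dir, thresholds=thresholds,
            root_length_range=tuple(rlr), **raw,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _natural_family_order(families: list[str]) -> list[str]:
    def key(f: str):
        m = re.search(r"(\d+)$", f)
        return (f[: m.start()] if m else f, int(m.group(1)) if m else 0)

    return sorted(families, key=key)


def _lineage_map(tree) -> dict[str, str]:
    """Label every leaf with the root child (major clade) it belongs to."""
    mapping = {}
    for top in tree.seed_node.child_nodes():
        label = node_label(top)
        for leaf in top.leaf_iter():
            mapping[node_label(leaf)] = label
    return mapping


def build_family_specs(config: PipelineConfig, tree) -> list[FamilySpec]:
    """Deterministic per-family scenarios from the config seed."""
    specs = []
    lo, hi = config.root_length_range
    for i, family in enumerate(_natural_family_order(config.families)):
        fseed = derive_family_seed(config.seed, i)
        rng = np.random.default_rng([config.seed, 17, i])
        root = random_root_sequence(int(rng.integers(lo, hi + 1)), rng)
        dup = config.duplication or {}
        specs.append(
            FamilySpec(
                family, root,
                loss_probability=config.loss_probability,
                rate_multiplier=config.rate_multiplier,
                indel_rate=config.indel_rate,
                duplication_branch=(
                    dup.get("branch") if dup.get("family") == family else None
                ),
                seed=fseed,
            )
        )
    return specs


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every configured stage and return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in vars(config).items()
            if k != "thresholds"
        },
        "thresholds": vars(config.thresholds).copy(),
        "seed": config.seed,
        "stages": {},
        "counters": {},
        "checksums": {},
    }

    def stage(name):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                manifest["stages"][name] = round(time.perf_counter() - self_inner.t0, 3)
                if exc is not None:
                    logger.error("stage %s failed: %s", name, exc)
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
                logger.info("stage %s: done", name)

        return _Timer()

    if config.mode == "fixture":
        with stage("profile"):
            profile = curated_profile()
            tree = curated_species_tree()
            profile.to_tsv(out / "profile.tsv")
            write_coulson(profile, out / "coulson.svg")
        _run_ancestral(profile, tree, out, manifest)
        _finish_manifest(out, manifest)
        return manifest
    if config.mode != "simulate":
        raise ValueError(f"unknown pipeline mode: {config.mode!r}")

    tree = load_tree(config.tree) if config.tree else load_tree(DEMO_TREE)
    with stage("simulate"):
        specs = build_family_specs(config, tree)
        pset = generate_proteomes(
            tree, specs, config.decoys, config.seed,
            out / "proteomes", force=True,
            protected_leaves=set(config.reference_species),
        )
        proteomes = {sp: read_fasta(p) for sp, p in pset.fasta_paths.items()}
        manifest["counters"]["species"] = len(proteomes)
        manifest["counters"]["sequences"] = sum(len(p) for p in proteomes.values())

    with stage("classify"):
        refs = reference_set_from_logs(
            proteomes, pset.event_logs, config.reference_species
        )
        groups = [orth.ParalogGroup.of(*g) for g in config.paralog_groups]
        calls: list[orth.OrthologyCall] = []
        for sp in sorted(proteomes):
            calls.extend(
                orth.classify_species(
                    sp, proteomes[sp], refs, thresholds=config.thresholds,
                    groups=groups,
                )
            )
        if groups:
            calls = orth.merge_paralog_columns(calls, groups)

    with stage("propagate"):
        calls = orth.propagate_search(
            calls, proteomes, tree, thresholds=config.thresholds, groups=groups
        )
        orth.write_calls_tsv(calls, out / "calls.tsv")
        status_counts: dict[str, int] = {}
        for c in calls:
            status_counts[c.status] = status_counts.get(c.status, 0) + 1
        manifest["counters"]["calls"] = status_counts

    with stage("profile"):
        species_order = leaf_names(tree)
        family_order = _natural_family_order({c.family for c in calls})
        profile = assemble_profile(
            calls, species_order, family_order, _lineage_map(tree)
        )
        profile.to_tsv(out / "profile.tsv")
        write_coulson(profile, out / "coulson.svg")
        summary = summarize_losses(profile)
        manifest["counters"]["complete_loss_species"] = len(
            summary.complete_loss_species
        )

    _run_ancestral(profile, tree, out, manifest)

    if config.duplication:
        with stage("genetree"):
            manifest["counters"]["duplication"] = _run_genetree(
                config, tree, pset, proteomes, out
            )

    _finish_manifest(out, manifest)
    return manifest


def _run_ancestral(profile: PhyleticProfile, tree, out: Path, manifest: dict) -> None:
    t0 = time.perf_counter()
    recs = anc.dollo_reconstruct(profile, tree)
    events, annotated = anc.annotate_events(recs, tree)
    anc.write_events_tsv(events, out / "events.tsv")
    (out / "annotated.nwk").write_text(annotated + "\n")
    manifest["counters"]["gains"] = sum(1 for _, k, _b in events if k == "gain")
    manifest["counters"]["losses"] = sum(1 for _, k, _b in events if k == "loss")
    manifest["stages"]["ancestral"] = round(time.perf_counter() - t0, 3)


def _run_genetree(config, tree, pset, proteomes, out: Path) -> dict:
    dup_family = config.duplication["family"]
    log = next(l for l in pset.event_logs if l.family_id == dup_family)
    sequences, species_of, tag_of = {}, {}, {}
    for leaf, copies in log.leaf_copies.items():
        for sid, _fam, tag in copies:
            sequences[sid] = proteomes[leaf][sid]
            species_of[sid] = leaf
            tag_of[sid] = tag
    if len(sequences) < 3:
        raise ValueError(f"too few copies of {dup_family} for a gene tree")
    gt_conf = config.genetree or {}
    lineage_map = _lineage_map(tree)
    dup_branch = config.duplication.get("branch")
    lineage = gt_conf.get("lineage")
    if lineage is None and dup_branch:
        # default lineage under test: the leaves below the planted branch
        lineage = dup_branch
        for leaf in find_node(tree, dup_branch).leaf_iter():
            lineage_map[node_label(leaf)] = dup_branch
    outgroup_species = gt_conf.get("outgroup_species")
    if not outgroup_species:
        # any out-of-lineage species still carrying an untagged copy,
        # preferring the reference species; deterministic order
        candidates = [
            sp for sp in list(config.reference_species) + sorted(log.leaf_copies)
            if lineage_map.get(sp) != lineage
            and any(t == "" for _s, _f, t in log.leaf_copies.get(sp, []))
        ]
        if not candidates:
            raise ValueError(
                f"no out-of-lineage species retains {dup_family}: cannot root"
            )
        outgroup_species = candidates[:1]
    outgroup = [
        sid for sp in outgroup_species for sid, _f, _t in log.leaf_copies.get(sp, [])
    ]
    matrix = score_distance(sequences)
    gene_tree = nj_build(matrix)
    (out / f"genetree_{dup_family}.nwk").write_text(to_newick(gene_tree) + "\n")
    call = duplication_clade_test(
        gene_tree, species_of, tag_of, lineage_map, lineage, outgroup
    )
    (out / "duplication.tsv").write_text(
        "family\tverdict\tduplication_node\tlineage\tnotes\n"
        f"{dup_family}\t{call.verdict}\t{call.duplication_node or ''}"
        f"\t{call.lineage}\t{call.notes}\n"
    )
    return {"family": dup_family, "verdict": call.verdict}


def _finish_manifest(out: Path, manifest: dict) -> None:
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["checksums"][str(path.relative_to(out))] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
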