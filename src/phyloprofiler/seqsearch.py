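"""Local protein similarity search against a proteome.

This is the search engine behind the reciprocal-best-hit orthology
logic: exact affine-gap Smith-Waterman local alignment of a query
against every sequence of a proteome, ranked by raw score.  Acceptance
is based on the *query-self-normalized* score (raw score divided by the
query's self-alignment score) rather than on E-value statistics: the
downstream orthology criterion is rank-based, so a deterministic
normalized score is sufficient and keeps the whole chain reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from .scoring import ScoringScheme, default_scheme, sanitize


@dataclass(frozen=True)
class ScoredAlignment:
    """Result of one local pairwise alignment.

    Spans are 1-based inclusive; a raw score of 0 means no positive-scoring
    local alignment exists and the spans are empty (None).
    """

    query_id: str
    target_id: str
    raw_score: int
    normalized_score: float
    query_span: tuple[int, int] | None
    target_span: tuple[int, int] | None


@dataclass(frozen=True)
class HitList:
    """Ordered search result: descending raw score, ties by target id."""

    query_id: str
    hits: tuple[ScoredAlignment, ...]
    min_normalized_score: float

    def __len__(self) -> int:
        return len(self.hits)

    def best(self) -> ScoredAlignment | None:
        return self.hits[0] if self.hits else None


def self_score(sequence: str, scheme: ScoringScheme | None = None) -> int:
    """Smith-Waterman score of a sequence against itself."""
    scheme = scheme or default_scheme()
    seq = sanitize(sequence)
    if not seq:
        return 0
    return int(round(scheme.aligner().score(seq, seq)))


def local_align(
    a: str,
    b: str,
    scheme: ScoringScheme | None = None,
    query_id: str = "query",
    target_id: str = "target",
    query_self_score: int | None = None,
) -> ScoredAlignment:
    """Optimal affine-gap local alignment of ``a`` (query) versus ``b``.

    Returns the raw integer score, the query-self-normalized score and the
    aligned spans from the traceback.  Empty sequences or all-negative
    pairs yield score 0 with empty spans.
    """
    scheme = scheme or default_scheme()
    a, b = sanitize(a), sanitize(b)
    if query_self_score is None:
        query_self_score = self_score(a, scheme)
    if not a or not b:
        return ScoredAlignment(query_id, target_id, 0, 0.0, None, None)
    aligner = scheme.aligner()
    raw = int(round(aligner.score(a, b)))
    if raw <= 0:
        return ScoredAlignment(query_id, target_id, 0, 0.0, None, None)
    aln = next(iter(aligner.align(a, b)))
    qblocks, tblocks = aln.aligned
    qspan = (int(qblocks[0][0]) + 1, int(qblocks[-1][1]))
    tspan = (int(tblocks[0][0]) + 1, int(tblocks[-1][1]))
    norm = raw / query_self_score if query_self_score > 0 else 0.0
    return ScoredAlignment(query_id, target_id, raw, norm, qspan, tspan)


def search(
    query: str,
    proteome: Mapping[str, str],
    scheme: ScoringScheme | None = None,
    min_normalized_score: float = 0.0,
    query_id: str = "query",
    with_spans: bool = True,
) -> HitList:
    """Align ``query`` to every proteome sequence and rank the hits.

    Scores every target (score-only pass), keeps hits whose normalized
    score reaches ``min_normalized_score``, then computes tracebacks for
    the retained hits only.  Ordering is by descending raw score with
    ties broken lexicographically by target id, which makes hit lists
    deterministic.
    """
    if not proteome:
        raise ValueError("proteome is empty")
    scheme = scheme or default_scheme()
    q = sanitize(query)
    qself = self_score(q, scheme)
    if not q or qself <= 0:
        return HitList(query_id, (), min_normalized_score)
    aligner = scheme.aligner()
    kept: list[tuple[str, int]] = []
    for tid in proteome:
        t = sanitize(proteome[tid])
        if not t:
            continue
        raw = int(round(aligner.score(q, t)))
        if raw > 0 and raw / qself >= min_normalized_score:
            kept.append((tid, raw))
    kept.sort(key=lambda item: (-item[1], item[0]))
    hits = []
    for tid, raw in kept:
        if with_spans:
            hits.append(
                local_align(q, sanitize(proteome[tid]), scheme, query_id, tid, qself)
            )
        else:
            hits.append(ScoredAlignment(query_id, tid, raw, raw / qself, None, None))
    return HitList(query_id, tuple(hits), min_normalized_score)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a protein FASTA into an ordered id -> sequence mapping.

    Fails with the offending record identifier on duplicate ids or
    malformed sequences.
    """
    proteome: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in proteome:
            raise ValueError(f"duplicate FASTA record id: {record.id!r} in {path}")
        try:
            proteome[record.id] = sanitize(str(record.seq))
        except ValueError as exc:
            raise ValueError(f"malformed FASTA record {record.id!r}: {exc}") from exc
    return proteome


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    """Write sequences as multi-FASTA wrapped at ``width`` columns."""
    with open(path, "w") as handle:
        for sid, seq in sequences.items():
            handle.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def write_hits_tsv(hitlists: Iterable[HitList], path: str | Path) -> None:
    """Tabular hit output: one row per hit, sorted as in the HitLists."""
    with open(path, "w") as handle:
        handle.write(
            "query\ttarget\traw_score\tnormalized_score\tqstart\tqend\ttstart\ttend\n"
        )
        for hl in hitlists:
            for h in hl.hits:
                qs, qe = h.query_span or ("", "")
                ts, te = h.target_span or ("", "")
                handle.write(
                    f"{h.query_id}\t{h.target_id}\t{h.raw_score}"
                    f"\t{h.normalized_score:.6f}\t{qs}\t{qe}\t{ts}\t{te}\n"
                )
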