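# Methods

This note documents the models, parameters and design choices behind
phyloprofiler, in the spirit of a package vignette: what each stage
assumes, what the defaults mean, and what the synthetic benchmark does
and does not demonstrate.

## Local alignment and scoring

All similarity search is exact affine-gap Smith–Waterman local
alignment under BLOSUM62.  Gap costs follow the NCBI convention — a gap
of length *k* costs `gap_open + k * gap_extend`, default 11 + *k* —
realized through Biopython's `PairwiseAligner` (C implementation) with
`open_gap_score = -(gap_open + gap_extend)` and
`extend_gap_score = -gap_extend`.  Non-canonical residues (X, B, Z, U,
O, J, `*`) are collapsed to a neutral symbol scoring −1 against
everything, because predicted proteomes routinely contain them.

No E-value statistics are computed.  The downstream orthology criterion
is rank-based ("does the candidate retrieve its own family first?"),
so hits are ranked by raw score (ties broken lexicographically by
target id) and accepted on the *query-self-normalized* score
`S(q,t)/S(q,q) ∈ [0, 1]`.  This keeps the entire chain deterministic
and independent of database size.  The test suite checks the scores
against an independent pure-Python Gotoh dynamic program on hundreds of
random pairs, and that oracle in turn against a fully exhaustive
alignment-path enumerator at tiny lengths.

## Orthology classification

Thresholds (all exposed in `Thresholds` and the pipeline config):

| parameter | default | meaning |
|---|---|---|
| `forward` | 0.15 | minimum normalized score for a forward candidate |
| `strong`  | 0.25 | reciprocal normalized score separating present from weak |
| `margin`  | 0.10 | minimum relative gap between the reciprocal rank-1 (family) hit and the best non-family hit |

The margin test operationalizes the requirement that a candidate "not
retrieve closely related non-family sequences": rank-1 must beat the
best non-family sequence by at least 10% of its own score, otherwise
the call is `ambiguous`.  A candidate whose reciprocal rank-1 is the
right family but whose normalized score falls below `strong` is `weak`
(the divergent-but-validated case).  When both degradations apply, the
weak label wins, as the low score is the more informative caveat.  The
defaults were calibrated on the simulator so that orthologs separated
by patristic distance ≲ 0.95 (in expected substitutions per site) read
out `present`, the band around 1.25 reads out `weak`, and unrelated
background-composition sequences score ≈ 0.03, far below the floor.

Paralog groups (default `{Emc8, Emc9}`) are treated as one reciprocal
family: a reciprocal rank-1 on a co-member confirms the candidate, and
a species with two distinct accepted candidates keeps both, tagged
`a`/`b` in sorted family order.  With a single accepted candidate the
group reports one untagged call on its first member.

Propagated fallback: for every (species, family) still absent after
direct classification, the validated (`present`) orthologs of the
nearest species by patristic distance are tried as queries, in
increasing-distance order with lexicographic tie-breaks, stopping at
the first `present`/`weak` outcome.  The reciprocal test for a
propagated candidate runs against the *donor* species' proteome and
must retrieve the donor's validated ortholog (or group co-member) at
rank 1 — the natural reciprocal-best-hit generalization, given that the
distant reference proteome by construction cannot retrieve a sequence
its own queries already missed.  Propagation never demotes a call and
iterates to a fixpoint, bounded at three rounds.

## Dollo reconstruction

A family is gained once, at the MRCA of the leaves carrying it, and
only lost afterwards.  The minimal loss set under that constraint is
one loss on the root edge of each maximal all-absent subtree below the
origin; the implementation returns exactly that set, so minimality is
structural rather than searched.  The test suite still verifies it
against a brute-force enumeration over loss subsets on hundreds of
random trees.  Families observed nowhere produce "no gain" rather than
a root gain plus immediate losses: Dollo forbids regain, and a
never-observed character carries no evidence of ever existing.  Weak
calls count as presence by default (a validated divergent ortholog
still documents retention); ambiguous calls count as absence —
conservative, and both are flag-controlled.

## Gene trees and duplication dating

Distances are `d(a,b) = −ln(S(a,b)/min(S(a,a),S(b,b)))`, clamped at 0
and capped (default 10) when no positive-scoring alignment exists.
This is a crude but monotone proxy for divergence time, adequate for a
clade-membership question; the verdict logic is method-agnostic.
Neighbor joining is the canonical Saitou–Nei formulation with
Studier–Keppler updates, deterministic lexicographic tie-breaking, and
negative branch lengths clamped to zero with the excess moved to the
sister branch.  Consistency (exact recovery on additive matrices) is
tested against random trees and cross-checked against scikit-bio's
independent implementation.

The duplication test roots the gene tree with an explicit outgroup
(no midpoint-rooting default), finds the smallest clade containing all
b-tagged copies and reports `lineage-specific` only when that clade's
species all belong to the tested lineage and the lineage's a-tagged
copies form its sister group.  One stray leaf downgrades the verdict to
`unresolved` rather than flipping it — misassignment should fail safe,
never assert the opposite history.

## The synthetic proteome simulator

The simulator emulates the study conditions of a desk-scale
comparative survey: N species related by a known rooted tree, ~9
orthologous subunit families, per-branch losses, one lineage-specific
duplication, and unrelated decoy proteins.

* **Substitutions.** Per site, probability `1 − exp(−t·rate)` on a
  branch of length *t*; replacements drawn from a BLOSUM62-derived
  conditional exchange kernel, `P(b|a) ∝ π_b · 2^(S(a,b)/2)`, so the
  generating process matches the search stage's scoring model
  qualitatively.
* **Indels.** Point events, Poisson with rate 0.01 events/site/unit
  branch length, geometric lengths of mean 3, insertions drawn from the
  background composition; deletions keep a minimal core so sequences
  never collapse.
* **Losses.** Bernoulli per branch with the configured probability;
  once lost, a family never returns in that subtree (the event log is
  Dollo-consistent by construction).  Branches leading to designated
  reference species can be protected from loss, mirroring the fact that
  reference proteomes are chosen because they carry the complex.
* **Duplication.** At the midpoint of the designated branch: the single
  copy evolves over t/2, duplicates, and both copies evolve
  independently thereafter (tags a/b).  The midpoint placement leaves a
  positive-length edge between the preceding speciation and the
  duplication node, so the event is in principle recoverable from the
  gene tree.
* **Decoys.** I.i.d. draws from the BLOSUM62 background composition,
  length uniform in 80–500; no homology among decoys by construction.
* **Seeding.** Every stream is `default_rng([seed, stream, branch,
  copy])` from a per-family seed derived from the master seed and the
  family index, so outputs are byte-reproducible and any family can be
  regenerated in isolation.

Default study conditions: the 8-leaf demo topology with root-to-leaf
paths of ~0.35 expected substitutions per site and rate multiplier 1.0,
giving ≈ 39% mean pairwise divergence between leaf orthologs of
150–400-residue families — a realistic inter-supergroup figure, chosen
once as a calibration (divergence levels among real inter-supergroup
orthologs vary widely and no single published value exists).

What passing the synthetic benchmark shows: the chain makes no
reciprocity or bookkeeping errors, recovers planted presence/absence
perfectly at these divergences, and places a planted duplication
correctly in ≥ 90% of runs.  What it does not show: robustness to
compositional bias, repeats and low-complexity regions, domain-level
chimerism, alternative isoforms, or annotation noise — none of which
the generator models.  Real-proteome performance therefore depends on
threshold re-calibration against curated references.

## The curated panel

`fixtures.curated_profile()` hand-codes only species-level,
text-documented presence/absence statements for the EMC across 17
representative eukaryotes (six complete losses; the partial retainers
Entamoeba histolytica, Cryptosporidium parvum and Piromyces sp.; the
weak Trichomonas vaginalis Emc2; yeast's Emc1–7 + Emc10; the human
Emc8a/Emc8b pair; one complete-complement representative per remaining
supergroup).  Cells not documented at species level are excluded rather
than guessed.  The companion species tree is a consensus supergroup
topology rooted at LECA; the placement of Excavata (sister to
Diaphoretickes here) is a documented choice that does not affect the
root-state conclusions, since every family's carriers span the root
under either placement.  In this panel Emc9 appears only in the human
row, so its Dollo origin is that leaf — consistent with reading the
vertebrate Emc8/Emc9 pair as a lineage-internal duplication rather than
two ancient families.

## Problem sizes and numerical notes

The shipped tests and the acceptance script run the simulator at 8
species × 9 families with 10–50 decoys per species and 10–20 replicate
seeds per question, sizes chosen so the full suite completes on a
single CPU in minutes while still exercising every code path; all
statistics scale with these knobs.  Score normalization uses the exact
self-alignment score (not the diagonal sum, which can differ when
neutral residues are present).  SVG output uses fixed 3-decimal
formatting, and manifests hash every non-timing artifact, so identical
configs reproduce byte-identical outputs.
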