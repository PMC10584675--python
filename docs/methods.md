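# Methods

This note documents the models, algorithms and numerical choices behind
foldcluster, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the design was genuinely open.

## Scoring model

Residue columns are scored as a weighted sum of a 3Di substitution matrix
and BLOSUM62: `s(i,j) = w_3di·M3di + w_aa·B62` with defaults
`w_3di = 2.1`, `w_aa = 1.4` and affine gap penalties open 10 / extend 1.
All four are configurable on `ScoringParams`; the sequence pre-clustering
stage uses AA-only scoring (`w_3di = 0`, `w_aa = 1`).

The default 3Di matrix is the log-odds matrix of a uniform-resampling
mutation model over the 20 3Di states: one match value (+6) and one
mismatch value (−4), in half-bit units on the same scale as published 3Di
matrices. Under the package's own synthetic mutation model this two-value
form *is* the correct log-odds matrix (substitutions are uniform over
states). Users working with real 3Di data should load an externally
published 3Di matrix with `read_substitution_matrix`, which accepts the
usual whitespace-separated matrix dialect.

Unknown letters map to a neutral symbol (`X`) that scores 0 against
everything. Alignment traceback is made deterministic by a fixed tie-break:
diagonal move, then gap-in-target, then gap-in-query; the highest-scoring
cell with the smallest (i, j) ends the alignment.

Sequence identity is matches over alignment columns including gap columns
(the "fident" convention); coverage is the aligned span over the full
length, required of *both* sequences ("bidirectional coverage") wherever a
coverage threshold applies.

## E-value model

Raw Gotoh scores are used directly in a Karlin–Altschul-style Gumbel model
`E = K·m·n·N·exp(−λ·s)` with m, n the pair's sequence lengths and N the
database size. λ and K are calibrated per run by aligning shuffled decoy
pairs (AA and 3Di shuffled with the same permutation, preserving the
pairing of the two strings) and fitting a Gumbel by maximum likelihood from
a method-of-moments start. No bit-score rescaling and no composition
correction are applied — a deliberate simplification; the calibration test
verifies that the fraction of decoy pairs with E ≤ 0.1 is within 3× of the
nominal rate. Calibration requires ≥ 100 decoy pairs (default 200) and is
deterministic given the seed.

## Linear-time candidate generation

Per sequence, all overlapping 3Di 10-mers are hashed with a seeded 64-bit
keyed hash (BLAKE2b) and the m = 300 smallest hash values are kept.
Smallest-hash selection makes the *choice* of k-mers consistent across
sequences (a minimizer-style sketch), which the grouping step requires:
hashes seen in ≥ 2 sequences form groups, each group's longest sequence
(ties: smallest id) becomes the centre, and every other member yields one
candidate pair carrying the shared k-mer diagonal. Duplicate (member,
centre) pairs keep the diagonal of the lowest-hash shared k-mer; groups are
capped at 1000 members to bound work on low-complexity k-mers.

Candidates are rescored with a 1-D local alignment (Kadane with floor 0)
along the stored diagonal; pairs at or above a configurable admission floor
(default 0 — all candidates verified, appropriate at desk scale) proceed to
full gapped verification. No reduced alphabet is used for k-mer matching:
3Di is already a compressed representation.

## Cascade and set-cover clustering

Accepted alignments form an undirected acceptance graph clustered greedily
by set cover: repeatedly pick the node covering the most uncovered nodes
(itself plus uncovered neighbours; ties → more total neighbours, then
smallest id) as a representative. After the Linclust round, up to three
cascade rounds mutually compare the current representatives only — by
all-vs-all gapped alignment when ≤ 2000 representatives remain, and by the
k-mer prefilter (with the admission floor halved each round, approximating
progressive sensitivity) above that. Clusters whose representatives are
accepted together merge transitively, so later-stage clusters are always
unions of earlier-stage clusters and the cluster count is non-increasing
through the cascade.

The full pipeline is: AA pre-cluster → pLDDT representative selection
(missing pLDDT counts as 0; ties → longest, then smallest id) → structural
clustering of representatives → member expansion through the pre-clusters →
fragment removal (fragment members deleted; clusters whose representative
was a fragment re-select by pLDDT; emptied clusters dropped).

## Structural metrics

*Alignment LDDT* is Cα-only and superposition-free: over all pairs of
aligned columns whose query-side Cα distance is < 15 Å (sequence separation
≥ 1), the fraction with |d_q − d_t| under each of {0.5, 1, 2, 4} Å,
averaged over the four thresholds — the standard LDDT constants. Fewer than
2 aligned columns, or no pair inside the inclusion radius, is an error.

*TM-score* uses `d0 = 1.24·(L_norm − 15)^{1/3} − 1.8` floored at 0.5 Å,
normalized by query length by default (flag-switchable). The maximization
starts from a superposition on all aligned columns and refines on the
columns with superposed distance < d0·c for c in {8,…,3}, iterating each
cut to a fixed subset (≤ 20 iterations) and keeping the best score seen.
Scaling the cuts by d0 keeps the refinement radius proportionate to the
protein size; a test checks the result against a multi-start reference
maximization on a half-displaced decoy.

Superposition is Kabsch/SVD with reflection correction; nearly collinear
point sets warn but remain defined.

## Consistency metrics and the dark sieve

Pfam consistency scores all *ordered* pairs of annotated members: the
fraction of the reference member's Pfam domains whose clan occurs among the
other member's clans, averaged over pairs. The directional phrasing is made
well-defined by averaging over both directions; clanless families fall back
to their own accession (otherwise they could never be consistent), and
duplicate accessions within one protein count once. EC consistency is the
same score on EC codes truncated to level 1–4, ignoring codes undefined at
the level; ECOD consistency is the fraction of unordered annotated pairs
sharing the group id at a level (A/X/H/T/F). Clusters with fewer than two
annotated members are undefined (null), never zero.

The dark sieve is strictly sequential: representative PDB hit at E ≤ 0.1 →
`known_structure`; else representative Pfam profile hit at E ≤ 10⁻³ →
`pfam_annotated`; else any member Pfam/TIGRFAM annotation →
`member_annotated`; else `dark`. The searches themselves are external; the
package consumes hit tables.

## Taxonomy

Strict LCA after removing the "unclassified sequences" (12908) and "other
sequences" (28384) subtrees from the member list; members with unknown or
missing taxids are skipped, not treated as root. Rank summaries roll each
cluster's LCA up its ancestor path, so a taxon's count is the number of
clusters whose LCA lies at or below it; species-rank LCAs are flagged as
species-specific.

## Domain-family prediction

Hits are filtered at E ≤ 10⁻³ (self-hits dropped). Per protein, the
(target-start, target-end) points of incoming hits are clustered by
complete-linkage hierarchical clustering on Euclidean distance, cutting at
height 250 residues; complete linkage bounds intra-cluster spread, matching
the intent of a height cut in residue units. Region boundaries are
outward-rounded medians of member endpoints (robust to outliers). Target-side
coordinates are used because they describe where hits *land on* the protein.

Regions are linked when a hit overlaps both endpoints by ≥ 50% of each
region's length, keeping the best E-value per edge; the graph is trimmed
(edges E ≤ 10⁻⁵, regions ≤ 350 residues, components ≥ 5 nodes) and
clustered by walktrap (6 steps) on weights −log10(E) floored at 10⁻³⁰⁰,
with a fixed vertex ordering for determinism. Families need ≥ 5 members. A
family's annotation is its most frequent accession among member regions
covering > 75% of the Pfam domain's extent; accessions named `DUF…` mark
domains of unknown function. Inter-family links use the *pre-trim* graph at
E < 10⁻³, so similarities too weak to merge families are still reported;
the threshold is flag-exposed since the reported cutoff could also be read
as a separate probability. Oversized communities are reported via a
configurable size flag rather than removed.

## Synthetic data: what it emulates, and what it does not

Families descend from a random ancestor (uniform letter frequencies, with a
config hook for realistic 3Di frequencies). Each member site mutates with
the substitution rate; with probability `coupling` (default 0.8) the AA and
3Di letters share one mutation event, otherwise they mutate independently —
so structure co-varies with sequence, qualitatively matching the premise
that structural similarity persists below the sequence-identity floor.
Indels (off by default) apply to both strings in lockstep.

Cα traces are built NeRF-style: 3.8 Å steps with bond angle and dihedral
keyed to the 3Di letter through a fixed pseudo-random map, so unrelated
ancestors produce rapidly diverging compact paths. Family members share the
ancestor path plus a chain-smoothed Gaussian displacement field (moving
average window 5; `noise_sigma` is the white-field amplitude, so the
marginal per-residue displacement is ~σ/√5). By construction same-family
LDDT stays > 0.7 at σ = 1 Å while unrelated pairs stay < 0.3 — the regime
the purity metrics need to discriminate.

The benchmark conditions are 20 families × 10 members at L = 200 and
substitution rate 0.15 (mean pairwise identity ≈ 0.74). Multi-domain
fixtures concatenate 200-residue family segments (a typical domain scale,
and wide enough that adjacent domains on one protein stay separated
relative to the 250-residue boundary-clustering cut) with 5–20 residue
linkers; hit tables derive from the planted intervals with Gaussian
boundary jitter (σ = 5) and log-normal E-value scatter. Annotation noise is
a two-label flip (planted vs decoy clan per family), chosen so the expected
pairwise consistency of a two-member cluster is exactly
(1−p)² + p² — 0.5 at p = 0.5 — giving the calibration tests a closed form.

Not emulated: realistic protein geometry (no secondary-structure elements,
no excluded volume), realistic amino-acid or 3Di composition, domain-order
evolution, horizontal transfer in the toy taxonomies, or the error modes of
real structure predictors. Passing tests therefore demonstrate algorithmic
correctness and threshold compliance under the stated generative model, not
performance on real structure databases.

## Problem sizes and determinism

All shipped benchmarks run at desk scale: 200-record clustering benchmarks,
40-protein domain fixtures, 30-leaf taxonomies, 200–300 decoy calibration
pairs. These sizes were chosen so every planted signal is recoverable and
the full suite runs in seconds while still exercising each code path; the
counts appear in the tests and the acceptance script. Every stochastic
component takes an explicit seed (sub-seeded per family/record with
`numpy.random.default_rng`), and re-running any pipeline with the same seed
reproduces byte-identical outputs.

## Known limitations

- The Gumbel calibration assumes the decoy score distribution is already in
  the extreme-value regime; very short or very biased sequences would need
  length-dependent edge corrections that are not implemented.
- The cascade's progressive-sensitivity schedule (halving the admission
  floor each round) is a parameterized stand-in; per-round schedules are
  exposed rather than tuned.
- Set-cover clustering recomputes cover gains per iteration (O(n²) per
  round) — correct and simple, but not the external-memory implementation
  needed beyond desk scale, which is out of scope.
- Fragment status is consumed as an input flag; no fragment detection is
  attempted.
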