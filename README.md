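# foldcluster

Linear-time structural clustering of proteins represented in the 3Di
structural alphabet, with downstream cluster-quality, taxonomy and
domain-family analyses.

## The problem

Predicted protein structure databases now hold hundreds of millions of
models. Grouping them by *structural* similarity — which reaches far below
the ~50% sequence-identity floor of sequence clustering — requires avoiding
all-vs-all comparison. foldcluster implements a clustering stack for
structures encoded as strings over the 20-letter 3Di alphabet (each letter
describes one residue's local tertiary geometry), so structures can be
compared with fast string alignment:

1. **Sequence pre-clustering** — a Linclust-style linear-time round over the
   amino-acid strings (identity ≥ 50%, bidirectional coverage ≥ 90%); the
   highest-confidence member (mean pLDDT) represents each cluster.
2. **Structural clustering** of the representatives with combined 3Di+AA
   scoring (E < 0.01, bidirectional coverage ≥ 90%, no identity threshold),
   plus cascaded rounds over surviving representatives for remote pairs.
3. **Fragment removal** and final representative selection.

The Linclust candidate stage selects, per sequence, the *m* = 300 k-mers
(*k* = 10) with the smallest seeded hash values, groups sequences sharing a
k-mer, and pairs every group member with the group's longest sequence. Pairs
are rescored on the shared diagonal (1-D local alignment), verified with an
affine-gap Gotoh local alignment under

    s(i, j) = w_3di · M3di[q_i, t_j] + w_aa · B62[q_i, t_j],

and accepted pairs are clustered greedily by set cover. E-values follow a
Gumbel null model `E = K·m·n·N·exp(−λ·s)` calibrated on shuffled decoy
pairs.

Downstream analyses: per-cluster alignment LDDT (superposition-free,
inclusion radius 15 Å, thresholds {0.5, 1, 2, 4} Å) and TM-score
(`d0 = 1.24·(L−15)^{1/3} − 1.8`, iterative superposition); Pfam-clan, EC-level
and ECOD-level pairwise consistency; a dark-cluster sieve (no PDB hit for
the representative at E ≤ 0.1, no Pfam profile hit at E ≤ 10⁻³, no member
Pfam/TIGRFAM annotation); per-cluster lowest common ancestor on an NCBI-style
taxonomy (ignoring the "unclassified/other sequences" subtrees 12908 and
28384); and domain-family prediction from local structural hits (boundary
clustering at tree height 250, graph trimming at E ≤ 10⁻⁵ / ≤ 350 residues /
≥ 5 nodes, walktrap communities with 6 steps).

A synthetic-data module generates every input — mutated AA/3Di families,
idealized Cα traces, multi-domain architectures, toy taxonomies and
annotation tables — with known ground truth, so the whole stack is testable
without external databases.

## Worked example

Simulate five families of six members each and cluster them:

```bash
foldcluster simulate families --seed 42 --out-dir demo \
    --n-families 5 --n-members 6 --length 150
foldcluster pipeline --aa demo/aa.fasta --tdi demo/tdi.fasta \
    --meta demo/meta.tsv --out-dir demo/out --seed 42
```

which prints

```json
{
  "n_records": 30,
  "n_sequence_clusters": 5,
  "n_structural_clusters": 5,
  "n_final_clusters": 5,
  "n_final_nonsingleton": 5,
  "seed": 42,
  "parameters": {
    "seq_min_id": 0.5, "seq_cov": 0.9, "struct_evalue": 0.01,
    "struct_cov": 0.9, "cascade_rounds": 3, "k": 10, "m": 300
  },
  "gumbel": {"lambda": 0.1000218742164489, "K": 0.009355714734471462}
}
```

The 30 records collapse into exactly the 5 planted families at every stage
(sequence pre-clustering already separates families at this mutation rate;
the structural stage confirms no cross-family merges survive the E < 0.01 /
90% coverage thresholds). `lambda`/`K` are the Gumbel null parameters
calibrated on shuffled decoys for this run; `demo/out/` holds per-stage
cluster TSVs and a JSON manifest sufficient to reproduce the run
bit-for-bit.

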