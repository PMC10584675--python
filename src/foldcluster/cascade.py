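"""End-to-end clustering pipeline.

Two-step strategy: (1) cluster by amino-acid sequence at 50% identity and
90% bidirectional coverage, keeping the highest-confidence (mean pLDDT)
member of each cluster as representative; (2) cluster the representatives
structurally (combined 3Di+AA scoring, E < 0.01, 90% bidirectional
coverage, no identity threshold), with additional cascaded rounds over the
surviving representatives to pick up remote pairs; finally expand members
back through the sequence clusters and drop fragment records.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .alignment import (Alignment, GumbelParams, ScoringParams,
                        calibrate_evalue, evalue, gapped_align)
from .linclust import linclust_round
from .records import Clustering, StructureSet

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "set_cover_cluster",
    "sequence_precluster",
    "select_representatives",
    "structural_cluster",
    "remove_fragments",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    """Thresholds of the two-step clustering pipeline."""

    seq_min_id: float = 0.5
    seq_cov: float = 0.9
    struct_evalue: float = 0.01
    struct_cov: float = 0.9
    cascade_rounds: int = 3
    k: int = 10
    m: int = 300
    seed: int = 0
    rescore_floor: float = 0.0
    all_vs_all_limit: int = 2000
    calibration_pairs: int = 200
    aa_params: ScoringParams = field(default_factory=ScoringParams.aa_only)
    struct_params: ScoringParams = field(default_factory=ScoringParams)

    def __post_init__(self) -> None:
        for cov in (self.seq_cov, self.struct_cov):
            if not (0 < cov <= 1):
                raise ValueError("coverage thresholds must be in (0, 1]")
        if self.cascade_rounds < 0:
            raise ValueError("cascade_rounds must be >= 0")


def set_cover_cluster(ids: Iterable[str],
                      edges: Iterable[tuple[str, str]]) -> Clustering:
    """Greedy set-cover clustering of an acceptance graph.

    Repeatedly pick the node covering the most uncovered nodes (itself plus
    its uncovered neighbours) as a representative and assign those nodes to
    it.  Ties go to the node with more total neighbours, then the smallest
    id.  Isolated nodes end up as singletons.
    """
    ids = list(ids)
    adj: dict[str, set[str]] = {i: set() for i in ids}
    for a, b in edges:
        if a == b:
            continue
        adj[a].add(b)
        adj[b].add(a)
    uncovered = set(ids)
    clusters: dict[str, list[str]] = {}
    while uncovered:
        best = None
        best_key = None
        for node in uncovered:
            gain = 1 + sum(1 for nb in adj[node] if nb in uncovered)
            key = (-gain, -len(adj[node]), node)
            if best_key is None or key < best_key:
                best_key = key
                best = node
        assert best is not None
        members = [best] + sorted(nb for nb in adj[best] if nb in uncovered)
        clusters[best] = members
        uncovered.difference_update(members)
    return Clustering(clusters)


def sequence_precluster(sset: StructureSet, config: PipelineConfig
                        ) -> Clustering:
    """AA-only Linclust round at ``seq_min_id`` identity / ``seq_cov``."""
    clustering, _ = linclust_round(
        sset,
        config.aa_params,
        alphabet="aa",
        k=config.k,
        m=config.m,
        seed=config.seed,
        gumbel=None,
        max_evalue=None,
        min_cov=config.seq_cov,
        min_seq_id=config.seq_min_id,
        rescore_floor=config.rescore_floor,
    )
    clustering.provenance.update({r: "sequence" for r in clustering.clusters})
    return clustering


def select_representatives(clustering: Clustering, sset: StructureSet
                           ) -> Clustering:
    """Re-key every cluster to its highest mean-pLDDT member.

    Missing pLDDT counts as 0; ties go to the longest member, then the
    smallest id.
    """
    clusters: dict[str, list[str]] = {}
    for rep, members in clustering.clusters.items():
        def key(rid: str):
            rec = sset[rid]
            p = rec.mean_plddt
            return (-(p if p is not None else 0.0), -len(rec), rid)
        new_rep = min(members, key=key)
        clusters[new_rep] = members
    return Clustering(clusters, provenance=clustering.provenance)


def _all_vs_all_accept(reps: StructureSet, params: ScoringParams,
                       gumbel: GumbelParams, db_size: int,
                       max_evalue: float, min_cov: float
                       ) -> list[Alignment]:
    accepted = []
    for q, t in itertools.combinations(list(reps), 2):
        aln = gapped_align(q, t, params)
        if aln.score <= 0:
            continue
        aln.evalue = evalue(aln.score, len(q), len(t), gumbel, db_size)
        if aln.evalue > max_evalue:
            continue
        if aln.qcov < min_cov or aln.tcov < min_cov:
            continue
        accepted.append(aln)
    return accepted


def _merge_through_reps(base: Clustering, rep_clustering: Clustering,
                        stage: str) -> Clustering:
    """Merge base clusters whose representatives were co-clustered."""
    clusters: dict[str, list[str]] = {}
    provenance: dict[str, str] = {}
    for new_rep, rep_members in rep_clustering.clusters.items():
        merged: list[str] = []
        for r in rep_members:
            merged.extend(base.clusters[r])
        # keep the new representative first for readability
        merged.remove(new_rep)
        clusters[new_rep] = [new_rep] + merged
        provenance[new_rep] = (base.provenance.get(new_rep, "")
                               if len(rep_members) == 1 else stage)
    return Clustering(clusters, provenance=provenance)


def structural_cluster(reps: StructureSet, config: PipelineConfig,
                       gumbel: Optional[GumbelParams] = None) -> Clustering:
    """Structural clustering of representatives with cascaded rounds.

    Round 0 is a full Linclust round under combined 3Di+AA scoring with
    E <= ``struct_evalue`` and bidirectional coverage >= ``struct_cov`` (no
    identity threshold).  Each cascade round then mutually compares only
    the current representatives — all-vs-all gapped alignment below
    ``all_vs_all_limit`` representatives, a k-mer prefilter (with the
    rescore admission floor relaxed each round) above it — and merges
    clusters whose representatives were accepted together.
    """
    db_size = max(len(reps), 1)
    if gumbel is None:
        gumbel = calibrate_evalue(reps, config.calibration_pairs, config.seed,
                                  config.struct_params)
    clustering, _ = linclust_round(
        reps,
        config.struct_params,
        alphabet="tdi",
        k=config.k,
        m=config.m,
        seed=config.seed,
        gumbel=gumbel,
        db_size=db_size,
        max_evalue=config.struct_evalue,
        min_cov=config.struct_cov,
        rescore_floor=config.rescore_floor,
    )
    clustering.provenance.update({r: "structural" for r in clustering.clusters})

    for round_idx in range(config.cascade_rounds):
        current = reps.subset(clustering.representatives)
        if len(current) <= 1:
            break
        if len(current) <= config.all_vs_all_limit:
            accepted = _all_vs_all_accept(
                current, config.struct_params, gumbel, db_size,
                config.struct_evalue, config.struct_cov)
            rep_clustering = set_cover_cluster(
                current.ids, [(a.query_id, a.target_id) for a in accepted])
        else:
            # progressive sensitivity: relax the admission floor each round
            floor = config.rescore_floor / (2.0 ** (round_idx + 1))
            rep_clustering, _ = linclust_round(
                current,
                config.struct_params,
                alphabet="tdi",
                k=config.k,
                m=config.m,
                seed=config.seed + round_idx + 1,
                gumbel=gumbel,
                db_size=db_size,
                max_evalue=config.struct_evalue,
                min_cov=config.struct_cov,
                rescore_floor=floor,
            )
        if len(rep_clustering) == len(clustering):
            continue  # fixed point: nothing merged this round
        clustering = _merge_through_reps(clustering, rep_clustering,
                                         f"cascade{round_idx}")
    return clustering


def remove_fragments(clustering: Clustering, sset: StructureSet) -> Clustering:
    """Drop fragment members; re-pick representatives where needed."""
    clusters: dict[str, list[str]] = {}
    provenance: dict[str, str] = {}
    for rep, members in clustering.clusters.items():
        kept = [m for m in members if not sset[m].is_fragment]
        if not kept:
            continue
        new_rep = rep if rep in kept else None
        if new_rep is None:
            tmp = select_representatives(Clustering({kept[0]: kept}), sset)
            new_rep = tmp.representatives[0]
        ordered = [new_rep] + [m for m in kept if m != new_rep]
        clusters[new_rep] = ordered
        provenance[new_rep] = clustering.provenance.get(rep, "")
    return Clustering(clusters, provenance=provenance)


@dataclass
class PipelineResult:
    """Per-stage clusterings plus a run log of counts and parameters."""

    sequence_clusters: Clustering
    structural_clusters: Clustering      # over sequence representatives
    expanded_clusters: Clustering        # structural clusters, all members
    final_clusters: Clustering           # after fragment removal
    gumbel: GumbelParams
    log: dict

    @property
    def n_nonsingleton(self) -> int:
        return self.final_clusters.n_nonsingleton


def run_pipeline(sset: StructureSet, config: PipelineConfig) -> PipelineResult:
    """Run the full two-step pipeline on a structure set."""
    seq_clusters = sequence_precluster(sset, config)
    seq_clusters = select_representatives(seq_clusters, sset)
    reps = sset.subset(seq_clusters.representatives)
    if len(reps) >= 2:
        gumbel = calibrate_evalue(reps, config.calibration_pairs, config.seed,
                                  config.struct_params)
    else:
        # degenerate input: no pairs exist, any finite null model will do
        gumbel = GumbelParams(lambda_=0.3, K=0.1)
    struct_clusters = structural_cluster(reps, config, gumbel=gumbel)
    expanded = _merge_through_reps(seq_clusters, struct_clusters, "structural")
    final = remove_fragments(expanded, sset)
    log = {
        "n_records": len(sset),
        "n_sequence_clusters": len(seq_clusters),
        "n_structural_clusters": len(struct_clusters),
        "n_final_clusters": len(final),
        "n_final_nonsingleton": final.n_nonsingleton,
        "seed": config.seed,
        "parameters": {
            "seq_min_id": config.seq_min_id,
            "seq_cov": config.seq_cov,
            "struct_evalue": config.struct_evalue,
            "struct_cov": config.struct_cov,
            "cascade_rounds": config.cascade_rounds,
            "k": config.k,
            "m": config.m,
        },
        "gumbel": None,
    }
    result = PipelineResult(
        sequence_clusters=seq_clusters,
        structural_clusters=struct_clusters,
        expanded_clusters=expanded,
        final_clusters=final,
        gumbel=gumbel,
        log=log,
    )
    log["gumbel"] = {"lambda": gumbel.lambda_, "K": gumbel.K}
    return result
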