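"""Linear-time candidate generation over 3Di (or AA) strings.

The strategy avoids all-vs-all comparison: each sequence contributes at most
``m`` k-mers (those with the smallest seeded hash values), sequences sharing
a k-mer hash are grouped, and every group member is paired with the group's
longest sequence (the centre).  Candidate pairs are then rescored on the
shared diagonal and finally verified by gapped alignment, so total work is
linear in the number of sequences times a constant.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Optional

from .alignment import (Alignment, GumbelParams, ScoringParams, evalue,
                        gapped_align, ungapped_diagonal_score)
from .records import Clustering, StructureRecord, StructureSet

__all__ = [
    "KmerSelection",
    "CandidatePair",
    "select_kmers",
    "group_by_kmer",
    "assign_centres",
    "linclust_round",
]


@dataclass
class KmerSelection:
    record_id: str
    kmers: list[tuple[int, int]]  # (hash, position), sorted by hash


@dataclass(frozen=True)
class CandidatePair:
    member_id: str
    centre_id: str
    diagonal: int  # member k-mer position - centre k-mer position


def _hash_kmer(kmer: str, seed: int) -> int:
    h = hashlib.blake2b(kmer.encode(),
                        digest_size=8,
                        key=seed.to_bytes(8, "little"))
    return int.from_bytes(h.digest(), "little")


def select_kmers(record: StructureRecord, k: int = 10, m: int = 300,
                 seed: int = 0, alphabet: str = "tdi") -> KmerSelection:
    """Select the ``m`` smallest-hash k-mers of a record's 3Di (or AA) string.

    Hashing is a seeded 64-bit string hash, so identical substrings hash
    identically across records — the property the grouping step relies on.
    Smallest-hash selection makes the *choice* of k-mers consistent across
    sequences too (a minimizer-style sketch).  Sequences shorter than ``k``
    yield an empty selection.
    """
    seq = record.tdi_seq if alphabet == "tdi" else record.aa_seq
    if len(seq) < k:
        return KmerSelection(record.id, [])
    entries = [(_hash_kmer(seq[i:i + k], seed), i)
               for i in range(len(seq) - k + 1)]
    entries.sort()
    return KmerSelection(record.id, entries[:m])


def group_by_kmer(selections: list[KmerSelection],
                  lengths: Optional[dict[str, int]] = None
                  ) -> dict[int, list[tuple[str, int]]]:
    """Group selected k-mers by hash; keep hashes seen in >= 2 records.

    Each group is sorted by (record length descending, id ascending) so that
    the centre — the longest sequence — is first.
    """
    groups: dict[int, list[tuple[str, int]]] = {}
    for sel in selections:
        for h, pos in sel.kmers:
            groups.setdefault(h, []).append((sel.record_id, pos))
    out: dict[int, list[tuple[str, int]]] = {}
    for h, entries in groups.items():
        ids = {rid for rid, _ in entries}
        if len(ids) < 2:
            continue
        if lengths is not None:
            entries.sort(key=lambda e: (-lengths[e[0]], e[0], e[1]))
        else:
            entries.sort()
        out[h] = entries
    return out


def assign_centres(groups: dict[int, list[tuple[str, int]]],
                   lengths: dict[str, int],
                   group_cap: int = 1000) -> list[CandidatePair]:
    """Pair every group member with the group's longest sequence.

    The centre of a group is its longest record (ties broken by smallest
    id).  Each other member yields one :class:`CandidatePair` carrying the
    shared diagonal (member k-mer position minus centre k-mer position).
    Duplicate (member, centre) pairs across groups are collapsed, keeping
    the diagonal from the lowest-hash shared k-mer.  Oversized groups
    (low-complexity k-mers) are truncated at ``group_cap`` members.
    """
    best: dict[tuple[str, str], tuple[int, int]] = {}  # pair -> (hash, diag)
    for h in sorted(groups):
        entries = groups[h]
        # one position per record: first occurrence in sort order
        per_record: dict[str, int] = {}
        for rid, pos in entries:
            if rid not in per_record:
                per_record[rid] = pos
        ids = sorted(per_record, key=lambda r: (-lengths[r], r))[:group_cap]
        if len(ids) < 2:
            continue
        centre = ids[0]
        cpos = per_record[centre]
        for rid in ids[1:]:
            key = (rid, centre)
            cand = (h, per_record[rid] - cpos)
            if key not in best or cand[0] < best[key][0]:
                best[key] = cand
    return [CandidatePair(member_id=m, centre_id=c, diagonal=d)
            for (m, c), (_, d) in sorted(best.items())]


def linclust_round(
    sset: StructureSet,
    params: ScoringParams,
    *,
    alphabet: str = "tdi",
    k: int = 10,
    m: int = 300,
    seed: int = 0,
    gumbel: Optional[GumbelParams] = None,
    db_size: int = 1,
    max_evalue: Optional[float] = 0.01,
    min_cov: float = 0.9,
    min_seq_id: Optional[float] = None,
    rescore_floor: float = 0.0,
    group_cap: int = 1000,
) -> tuple[Clustering, list[Alignment]]:
    """One Linclust round: sketch, group, rescore, verify, set-cover cluster.

    Candidate (member, centre) pairs are rescored with the ungapped diagonal
    score; pairs at or above ``rescore_floor`` are verified with a gapped
    alignment and accepted when they meet every enabled threshold (E-value,
    bidirectional coverage, sequence identity).  Accepted alignments form an
    undirected acceptance graph which is clustered greedily by set cover.
    """
    from .cascade import set_cover_cluster

    ids = sset.ids
    if not ids:
        return Clustering({}), []
    lengths = {r.id: len(r) for r in sset}
    selections = [select_kmers(r, k=k, m=m, seed=seed, alphabet=alphabet)
                  for r in sset]
    groups = group_by_kmer(selections, lengths)
    pairs = assign_centres(groups, lengths, group_cap=group_cap)

    accepted: list[Alignment] = []
    for pair in pairs:
        member = sset[pair.member_id]
        centre = sset[pair.centre_id]
        score, _, _ = ungapped_diagonal_score(member, centre, pair.diagonal,
                                              params)
        if score < rescore_floor:
            continue
        aln = gapped_align(member, centre, params)
        if aln.score <= 0:
            continue
        if gumbel is not None:
            aln.evalue = evalue(aln.score, len(member), len(centre), gumbel,
                                db_size)
            if max_evalue is not None and aln.evalue > max_evalue:
                continue
        if aln.qcov < min_cov or aln.tcov < min_cov:
            continue
        if min_seq_id is not None and aln.seq_identity < min_seq_id:
            continue
        accepted.append(aln)

    edges = [(a.query_id, a.target_id) for a in accepted]
    clustering = set_cover_cluster(ids, edges)
    return clustering, accepted
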