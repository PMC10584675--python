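"""Canonical in-memory containers: protein records, hits and clusterings.

A protein is represented by two parallel strings — its amino-acid sequence
and its 3Di string, a 20-letter structural alphabet in which each letter
encodes the local tertiary geometry of one residue.  Both strings have the
same length, and optional per-residue data (C-alpha coordinates, pLDDT
confidence) must match that length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np

#: Shared 20-letter alphabet used for both amino acids and 3Di states.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Neutral symbol: unknown residue/state, scores 0 against everything.
NEUTRAL = "X"


@dataclass
class StructureRecord:
    """One protein: paired AA/3Di strings plus optional structural metadata."""

    id: str
    aa_seq: str
    tdi_seq: str
    coords: Optional[np.ndarray] = None  # N x 3 C-alpha positions, Angstrom
    plddt: Optional[np.ndarray] = None   # per-residue confidence in [0, 100]
    is_fragment: bool = False
    taxid: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if len(self.aa_seq) != len(self.tdi_seq):
            raise ValueError(
                f"record {self.id!r}: AA length {len(self.aa_seq)} != "
                f"3Di length {len(self.tdi_seq)}"
            )
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (len(self.aa_seq), 3):
                raise ValueError(
                    f"record {self.id!r}: coords shape {self.coords.shape} "
                    f"does not match sequence length {len(self.aa_seq)}"
                )
        if self.plddt is not None:
            self.plddt = np.asarray(self.plddt, dtype=float)
            if self.plddt.shape != (len(self.aa_seq),):
                raise ValueError(
                    f"record {self.id!r}: plddt length does not match sequence"
                )

    def __len__(self) -> int:
        return len(self.aa_seq)

    @property
    def mean_plddt(self) -> Optional[float]:
        if self.plddt is None:
            return None
        return float(np.mean(self.plddt))


class StructureSet:
    """Ordered collection of :class:`StructureRecord` keyed by id.

    Iteration order is insertion order; duplicate ids are rejected so that a
    set can serve as the universe of a clustering partition.
    """

    def __init__(self, records: Iterable[StructureRecord] = ()) -> None:
        self._records: dict[str, StructureRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: StructureRecord) -> None:
        if rec.id in self._records:
            raise ValueError(f"duplicate record id {rec.id!r}")
        self._records[rec.id] = rec

    def __getitem__(self, rid: str) -> StructureRecord:
        return self._records[rid]

    def __contains__(self, rid: str) -> bool:
        return rid in self._records

    def __iter__(self) -> Iterator[StructureRecord]:
        return iter(self._records.values())

    def __len__(self) -> int:
        return len(self._records)

    @property
    def ids(self) -> list[str]:
        return list(self._records)

    def subset(self, ids: Iterable[str]) -> "StructureSet":
        return StructureSet(self._records[i] for i in ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StructureSet):
            return NotImplemented
        if self.ids != other.ids:
            return False
        for a, b in zip(self, other):
            if (a.id, a.aa_seq, a.tdi_seq, a.is_fragment, a.taxid) != (
                b.id, b.aa_seq, b.tdi_seq, b.is_fragment, b.taxid
            ):
                return False
            for x, y in ((a.coords, b.coords), (a.plddt, b.plddt)):
                if (x is None) != (y is None):
                    return False
                if x is not None and not np.allclose(x, y):
                    return False
        return True


@dataclass
class HitRecord:
    """A local pairwise hit with 0-based half-open residue intervals."""

    query_id: str
    target_id: str
    qstart: int
    qend: int
    tstart: int
    tend: int
    score: float
    evalue: float

    def __post_init__(self) -> None:
        if not (0 <= self.qstart < self.qend):
            raise ValueError(
                f"hit {self.query_id}->{self.target_id}: invalid query interval "
                f"[{self.qstart}, {self.qend})"
            )
        if not (0 <= self.tstart < self.tend):
            raise ValueError(
                f"hit {self.query_id}->{self.target_id}: invalid target interval "
                f"[{self.tstart}, {self.tend})"
            )
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


class Clustering:
    """A partition of record ids into clusters, each with a representative.

    The representative is always a member of its own cluster.  ``provenance``
    optionally records which pipeline stage produced each cluster.
    """

    def __init__(
        self,
        clusters: dict[str, list[str]],
        provenance: Optional[dict[str, str]] = None,
    ) -> None:
        self.clusters: dict[str, list[str]] = {}
        seen: dict[str, str] = {}
        for rep, members in clusters.items():
            members = list(members)
            if rep not in members:
                raise ValueError(f"representative {rep!r} not in its own cluster")
            for m in members:
                if m in seen:
                    raise ValueError(
                        f"member {m!r} appears under both {seen[m]!r} and {rep!r}"
                    )
                seen[m] = rep
            self.clusters[rep] = members
        self._rep_of = seen
        self.provenance = dict(provenance or {})

    @classmethod
    def singletons(cls, ids: Iterable[str]) -> "Clustering":
        return cls({i: [i] for i in ids})

    def rep_of(self, member: str) -> str:
        return self._rep_of[member]

    @property
    def members(self) -> list[str]:
        return list(self._rep_of)

    @property
    def representatives(self) -> list[str]:
        return list(self.clusters)

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def n_nonsingleton(self) -> int:
        return sum(1 for m in self.clusters.values() if len(m) > 1)

    def is_partition_of(self, ids: Iterable[str]) -> bool:
        return set(self._rep_of) == set(ids)

    def co_clustered(self, a: str, b: str) -> bool:
        return self._rep_of[a] == self._rep_of[b]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Clustering):
            return NotImplemented
        mine = {r: sorted(m) for r, m in self.clusters.items()}
        theirs = {r: sorted(m) for r, m in other.clusters.items()}
        return mine == theirs

    def __repr__(self) -> str:
        return (
            f"Clustering(n_clusters={len(self)}, "
            f"n_members={len(self._rep_of)})"
        )
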