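"""Cluster quality and novelty assessment.

Three families of per-cluster scores are computed:

* structural purity — mean alignment LDDT and TM-score of the
  representative aligned against every member;
* annotation consistency — pairwise Pfam-clan, EC-level and ECOD-level
  agreement among annotated members;
* the dark-cluster sieve — clusters without any hit to known structures,
  without Pfam profile hits for the representative, and without member
  Pfam/TIGRFAM annotations are classified as dark.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .alignment import ScoringParams, alignment_lddt, gapped_align, tm_score
from .records import Clustering, HitRecord, StructureSet

__all__ = [
    "PfamRegion",
    "AnnotationTable",
    "ClusterQuality",
    "structural_purity",
    "pfam_consistency",
    "ec_consistency",
    "ecod_consistency",
    "classify_dark",
    "cluster_quality_table",
]

ECOD_LEVELS = ("A", "X", "H", "T", "F")

_EC_RE = re.compile(r"^(\d+|-)\.(\d+|-)\.(\d+|-)\.(n?\d+|-)$")


@dataclass
class PfamRegion:
    accession: str
    clan: Optional[str]
    start: int  # 0-based half-open on the protein
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("Pfam region start must be < end")

    @property
    def effective_clan(self) -> str:
        """Clan, falling back to the accession for clanless families."""
        return self.clan if self.clan else self.accession


@dataclass
class AnnotationTable:
    """Per-protein annotations: Pfam regions, EC codes, TIGRFAMs, ECOD."""

    pfam: dict[str, list[PfamRegion]] = field(default_factory=dict)
    ec: dict[str, list[str]] = field(default_factory=dict)
    tigrfam: dict[str, list[str]] = field(default_factory=dict)
    ecod: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, codes in self.ec.items():
            for code in codes:
                if not _EC_RE.match(code):
                    raise ValueError(f"invalid EC code {code!r} for {pid!r}")

    @classmethod
    def from_tsvs(cls, pfam_path=None, ec_path=None, tigrfam_path=None,
                  ecod_path=None) -> "AnnotationTable":
        """Load annotations from TSV files.

        pfam: id, accession, clan, start, end (1-based inclusive on disk);
        ec: id, ec; tigrfam: id, accession; ecod: id, a, x, h, t, f.
        """
        pfam: dict[str, list[PfamRegion]] = {}
        if pfam_path is not None:
            df = pd.read_csv(pfam_path, sep="\t", dtype=str)
            for row in df.itertuples(index=False):
                clan = None if pd.isna(row.clan) or row.clan == "" else row.clan
                pfam.setdefault(row.id, []).append(
                    PfamRegion(row.accession, clan,
                               int(row.start) - 1, int(row.end)))
        ec: dict[str, list[str]] = {}
        if ec_path is not None:
            df = pd.read_csv(ec_path, sep="\t", dtype=str)
            for row in df.itertuples(index=False):
                ec.setdefault(row.id, []).append(row.ec)
        tigr: dict[str, list[str]] = {}
        if tigrfam_path is not None:
            df = pd.read_csv(tigrfam_path, sep="\t", dtype=str)
            for row in df.itertuples(index=False):
                tigr.setdefault(row.id, []).append(row.accession)
        ecod: dict[str, dict[str, str]] = {}
        if ecod_path is not None:
            df = pd.read_csv(ecod_path, sep="\t", dtype=str)
            for row in df.itertuples(index=False):
                ecod[row.id] = {"A": row.a, "X": row.x, "H": row.h,
                                "T": row.t, "F": row.f}
        return cls(pfam=pfam, ec=ec, tigrfam=tigr, ecod=ecod)


def structural_purity(members: list[str], representative: str,
                      sset: StructureSet, params: ScoringParams
                      ) -> tuple[Optional[float], Optional[float]]:
    """Mean alignment LDDT and TM-score of representative vs members.

    The representative is aligned to each other member with no E-value
    cutoff (forced reporting); members without coordinates are skipped with
    a warning.  Singleton clusters yield ``(None, None)``.
    """
    rep = sset[representative]
    if rep.coords is None:
        raise ValueError(f"representative {representative!r} has no coords")
    lddts, tms = [], []
    for mid in members:
        if mid == representative:
            continue
        member = sset[mid]
        if member.coords is None:
            warnings.warn(f"member {mid!r} has no coordinates; skipped")
            continue
        aln = gapped_align(rep, member, params)
        if len(aln.columns) < 3:
            warnings.warn(f"alignment {representative!r} vs {mid!r} too short")
            continue
        lddts.append(alignment_lddt(aln, rep.coords, member.coords))
        tms.append(tm_score(aln, rep.coords, member.coords,
                            normalize="query"))
    if not lddts:
        return None, None
    return float(np.mean(lddts)), float(np.mean(tms))


def _pairwise_coverage_score(labels: dict[str, tuple[set[str], set[str]]]
                             ) -> Optional[float]:
    """Mean over ordered pairs of |ref labels covered by other| / |ref labels|.

    ``labels[pid] = (own_labels, match_labels)``: the reference side scores
    its ``own_labels`` against the other protein's ``match_labels``.
    """
    ids = [p for p, (own, _) in labels.items() if own]
    if len(ids) < 2:
        return None
    scores = []
    for ref in ids:
        own, _ = labels[ref]
        for other in ids:
            if other == ref:
                continue
            _, match = labels[other]
            covered = sum(1 for lab in own if lab in match)
            scores.append(covered / len(own))
    return float(np.mean(scores))


def pfam_consistency(members: list[str], annotations: AnnotationTable
                     ) -> Optional[float]:
    """Pairwise Pfam-clan consistency of a cluster.

    For every ordered pair (reference, other) of annotated members, the
    score is the fraction of the reference's Pfam domains whose clan occurs
    among the other's clans; duplicate accessions within one protein count
    once.  The cluster score is the mean over all ordered pairs; clusters
    with fewer than two annotated members are undefined (None).
    """
    labels: dict[str, tuple[set[str], set[str]]] = {}
    for mid in members:
        regions = annotations.pfam.get(mid, [])
        clans = {r.effective_clan for r in regions}
        labels[mid] = (clans, clans)
    return _pairwise_coverage_score(labels)


def _truncate_ec(code: str, level: int) -> Optional[str]:
    fields = code.split(".")[:level]
    if "-" in fields:
        return None
    return ".".join(fields)


def ec_consistency(members: list[str], annotations: AnnotationTable,
                   level: int) -> Optional[float]:
    """Pairwise EC consistency at one of the four EC levels.

    ECs are truncated to ``level`` fields; codes undefined at or before the
    level (a ``-`` field) are ignored.  Scoring is the same ordered-pair
    coverage as :func:`pfam_consistency`, with each protein's ECs compared
    as a set.
    """
    if level not in (1, 2, 3, 4):
        raise ValueError("EC level must be in 1..4")
    labels: dict[str, tuple[set[str], set[str]]] = {}
    for mid in members:
        codes = {t for c in annotations.ec.get(mid, [])
                 if (t := _truncate_ec(c, level)) is not None}
        labels[mid] = (codes, codes)
    return _pairwise_coverage_score(labels)


def ecod_consistency(members: list[str], annotations: AnnotationTable,
                     level: str) -> Optional[float]:
    """Fraction of annotated member pairs sharing the ECOD group at a level."""
    if level not in ECOD_LEVELS:
        raise ValueError(f"ECOD level must be one of {ECOD_LEVELS}")
    groups = [annotations.ecod[mid][level] for mid in members
              if mid in annotations.ecod]
    if len(groups) < 2:
        return None
    same = total = 0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            total += 1
            same += groups[i] == groups[j]
    return same / total


DARK_CATEGORIES = ("known_structure", "pfam_annotated", "member_annotated",
                   "dark")


def classify_dark(clustering: Clustering,
                  pdb_hits: list[HitRecord],
                  pfam_profile_hits: list[HitRecord],
                  annotations: AnnotationTable,
                  pdb_evalue: float = 0.1,
                  pfam_evalue: float = 0.001) -> dict[str, str]:
    """Sequential sieve classifying each cluster's novelty.

    1. representative has a PDB hit with E <= 0.1 -> ``known_structure``;
    2. else representative has a Pfam profile hit with E <= 0.001 ->
       ``pfam_annotated``;
    3. else any member carries a Pfam or TIGRFAM annotation ->
       ``member_annotated``;
    4. else ``dark``.
    """
    pdb_by_query: dict[str, float] = {}
    for h in pdb_hits:
        pdb_by_query[h.query_id] = min(
            pdb_by_query.get(h.query_id, np.inf), h.evalue)
    pfam_by_query: dict[str, float] = {}
    for h in pfam_profile_hits:
        pfam_by_query[h.query_id] = min(
            pfam_by_query.get(h.query_id, np.inf), h.evalue)
    out: dict[str, str] = {}
    for rep, members in clustering.clusters.items():
        if pdb_by_query.get(rep, np.inf) <= pdb_evalue:
            out[rep] = "known_structure"
        elif pfam_by_query.get(rep, np.inf) <= pfam_evalue:
            out[rep] = "pfam_annotated"
        elif any(annotations.pfam.get(m) or annotations.tigrfam.get(m)
                 for m in members):
            out[rep] = "member_annotated"
        else:
            out[rep] = "dark"
    return out


@dataclass
class ClusterQuality:
    cluster_id: str
    mean_lddt: Optional[float]
    mean_tm: Optional[float]
    pfam: Optional[float]
    ec: dict[int, Optional[float]]
    ecod: dict[str, Optional[float]]


def cluster_quality_table(clustering: Clustering, sset: StructureSet,
                          annotations: AnnotationTable,
                          params: Optional[ScoringParams] = None,
                          with_structure: bool = True) -> pd.DataFrame:
    """Per-cluster quality summary as a DataFrame."""
    params = params or ScoringParams()
    rows = []
    for rep, members in clustering.clusters.items():
        if with_structure and sset[rep].coords is not None:
            lddt, tm = structural_purity(members, rep, sset, params)
        else:
            lddt, tm = None, None
        row = {
            "cluster": rep,
            "size": len(members),
            "mean_lddt": lddt,
            "mean_tm": tm,
            "pfam_consistency": pfam_consistency(members, annotations),
        }
        for level in (1, 2, 3, 4):
            row[f"ec{level}"] = ec_consistency(members, annotations, level)
        for level in ECOD_LEVELS:
            row[f"ecod_{level}"] = ecod_consistency(members, annotations,
                                                    level)
        rows.append(row)
    return pd.DataFrame(rows)
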