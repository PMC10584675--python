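"""File I/O: paired FASTA, C-alpha coordinates, cluster / hit / metadata TSVs.

Conventions
-----------
* Internally every residue interval is 0-based half-open.
* On disk (hit tables, alignment tables) intervals are 1-based inclusive,
  following the convention of the common structure-search tools.
* Cluster files are two-column TSV ``representative<TAB>member`` with the
  representative listed as its own member.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional

import gemmi
import numpy as np
import pandas as pd
from Bio import SeqIO

from .records import Clustering, HitRecord, StructureRecord, StructureSet

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_paired_fasta",
    "write_paired_fasta",
    "read_calpha",
    "read_cluster_tsv",
    "write_cluster_tsv",
    "read_hit_table",
    "write_hit_table",
    "write_alignment_tsv",
    "read_metadata",
    "write_metadata",
]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in seqs.items():
            fh.write(f">{rid}\n{seq}\n")


def read_paired_fasta(aa_path, tdi_path, metadata_path=None) -> StructureSet:
    """Read paired AA / 3Di FASTA files (and optional metadata TSV).

    Both files must contain exactly the same set of ids, and for each id the
    AA and 3Di strings must have equal length.  The metadata TSV may carry
    columns ``id``, ``plddt`` (mean, expanded to a flat per-residue vector),
    ``fragment`` (0/1) and ``taxid``.
    """
    aa = read_fasta(aa_path)
    tdi = read_fasta(tdi_path)
    if set(aa) != set(tdi):
        missing = sorted(set(aa) ^ set(tdi))
        raise ValueError(
            f"AA and 3Di FASTA id sets differ; first offending id: {missing[0]!r}"
        )
    meta = read_metadata(metadata_path) if metadata_path is not None else {}
    records = []
    for rid in aa:
        if len(aa[rid]) != len(tdi[rid]):
            raise ValueError(
                f"record {rid!r}: AA length {len(aa[rid])} != 3Di length "
                f"{len(tdi[rid])}"
            )
        m = meta.get(rid, {})
        plddt = None
        if m.get("plddt") is not None:
            plddt = np.full(len(aa[rid]), float(m["plddt"]))
        records.append(
            StructureRecord(
                id=rid,
                aa_seq=aa[rid],
                tdi_seq=tdi[rid],
                plddt=plddt,
                is_fragment=bool(m.get("fragment", False)),
                taxid=m.get("taxid"),
            )
        )
    return StructureSet(records)


def write_paired_fasta(sset: StructureSet, aa_path, tdi_path,
                       metadata_path=None) -> None:
    write_fasta({r.id: r.aa_seq for r in sset}, aa_path)
    write_fasta({r.id: r.tdi_seq for r in sset}, tdi_path)
    if metadata_path is not None:
        write_metadata(sset, metadata_path)


def read_metadata(path) -> dict[str, dict]:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    out: dict[str, dict] = {}
    for row in df.itertuples(index=False):
        d: dict = {}
        if hasattr(row, "plddt") and not pd.isna(row.plddt):
            d["plddt"] = float(row.plddt)
        if hasattr(row, "fragment") and not pd.isna(row.fragment):
            d["fragment"] = bool(int(row.fragment))
        if hasattr(row, "taxid") and not pd.isna(row.taxid):
            d["taxid"] = int(row.taxid)
        out[row.id] = d
    return out


def write_metadata(sset: StructureSet, path) -> None:
    rows = []
    for r in sset:
        rows.append(
            {
                "id": r.id,
                "plddt": "" if r.mean_plddt is None else r.mean_plddt,
                "fragment": int(r.is_fragment),
                "taxid": "" if r.taxid is None else r.taxid,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_calpha(path, format: Optional[str] = None) -> dict[str, np.ndarray]:
    """Extract C-alpha traces from a PDB or mmCIF file.

    Returns one ``"<file-stem>_<chain>"`` entry per chain, with one row per
    residue that has a C-alpha atom, in residue order.  Residues lacking a
    C-alpha are skipped with a warning.
    """
    path = Path(path)
    if format is None:
        format = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    if format == "pdb":
        structure = gemmi.read_pdb(str(path))
    elif format == "mmcif":
        structure = gemmi.read_structure(str(path))
    else:
        raise ValueError(f"unknown structure format {format!r}")
    out: dict[str, np.ndarray] = {}
    stem = path.stem
    model = structure[0]
    for chain in model:
        rows = []
        for residue in chain:
            ca = residue.find_atom("CA", "*")
            if ca is None:
                warnings.warn(
                    f"{path.name} chain {chain.name}: residue "
                    f"{residue.seqid.num} lacks a C-alpha atom; skipped"
                )
                continue
            rows.append([ca.pos.x, ca.pos.y, ca.pos.z])
        coords = np.asarray(rows, dtype=float).reshape(len(rows), 3)
        if len(rows) == 0:
            warnings.warn(f"{path.name} chain {chain.name}: no C-alpha atoms")
        out[f"{stem}_{chain.name}"] = coords
    return out


def write_cluster_tsv(clustering: Clustering, path) -> None:
    with open(path, "w") as fh:
        for rep, members in clustering.clusters.items():
            for m in members:
                fh.write(f"{rep}\t{m}\n")


def read_cluster_tsv(path) -> Clustering:
    clusters: dict[str, list[str]] = {}
    seen: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            rep, member = line.split("\t")
            if member in seen and seen[member] != rep:
                raise ValueError(
                    f"member {member!r} listed under two representatives "
                    f"({seen[member]!r} and {rep!r}): not a partition"
                )
            seen[member] = rep
            clusters.setdefault(rep, []).append(member)
    return Clustering(clusters)


_HIT_COLUMNS = ["query", "target", "qstart", "qend", "tstart", "tend",
                "score", "evalue"]


def read_hit_table(path) -> list[HitRecord]:
    """Read a hit TSV (1-based inclusive coordinates on disk)."""
    df = pd.read_csv(path, sep="\t", dtype={"query": str, "target": str})
    hits = []
    for row in df.itertuples(index=False):
        qstart, qend = int(row.qstart) - 1, int(row.qend)
        tstart, tend = int(row.tstart) - 1, int(row.tend)
        if qend <= qstart or tend <= tstart:
            raise ValueError(
                f"hit {row.query}->{row.target}: empty interval after "
                "coordinate conversion"
            )
        hits.append(
            HitRecord(row.query, row.target, qstart, qend, tstart, tend,
                      float(row.score), float(row.evalue))
        )
    return hits


ALN_COLUMNS = ["query", "target", "qstart", "qend", "tstart", "tend",
               "score", "evalue", "qcov", "tcov", "fident", "lddt",
               "alntmscore"]


def write_alignment_tsv(alignments, path) -> None:
    """Write alignments with the common search-tool output vocabulary.

    Coordinates are 1-based inclusive; unset E-value/LDDT/TM fields are
    left empty.
    """
    rows = []
    for a in alignments:
        qs, qe = (a.columns[0][0], a.columns[-1][0] + 1) if a.columns \
            else (0, 0)
        ts, te = (a.columns[0][1], a.columns[-1][1] + 1) if a.columns \
            else (0, 0)
        rows.append({
            "query": a.query_id, "target": a.target_id,
            "qstart": qs + 1, "qend": qe, "tstart": ts + 1, "tend": te,
            "score": a.score,
            "evalue": "" if a.evalue is None else a.evalue,
            "qcov": a.qcov, "tcov": a.tcov, "fident": a.seq_identity,
            "lddt": "" if a.lddt is None else a.lddt,
            "alntmscore": "" if a.alntmscore is None else a.alntmscore,
        })
    pd.DataFrame(rows, columns=ALN_COLUMNS).to_csv(path, sep="\t",
                                                   index=False)


def write_hit_table(hits: list[HitRecord], path) -> None:
    rows = [
        {
            "query": h.query_id,
            "target": h.target_id,
            "qstart": h.qstart + 1,
            "qend": h.qend,
            "tstart": h.tstart + 1,
            "tend": h.tend,
            "score": h.score,
            "evalue": h.evalue,
        }
        for h in hits
    ]
    pd.DataFrame(rows, columns=_HIT_COLUMNS).to_csv(path, sep="\t", index=False)
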