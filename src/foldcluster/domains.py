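"""Domain-region and domain-family prediction from local structural hits.

Pipeline: local hits are filtered at E <= 1e-3; for each protein the
(start, end) points of hits landing on it are clustered hierarchically
(complete linkage, tree cut at height 250 residues) to define putative
domain regions; regions are linked into a graph when a hit overlaps both
endpoints by at least 50%; the graph is trimmed (edge E <= 1e-5, region
length <= 350, component size >= 5) and clustered into domain families by
walktrap random-walk communities (6 steps, min size 5).  Families are
annotated with their most frequent well-overlapping Pfam accession, and
remaining inter-family similarities (E < 1e-3 in the untrimmed graph) are
reported as family-pair links.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import igraph
import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .annotate import PfamRegion
from .records import HitRecord

__all__ = [
    "DomainRegion",
    "DomainGraph",
    "DomainFamily",
    "filter_hits",
    "boundary_cluster",
    "build_domain_graph",
    "detect_families",
    "annotate_families",
    "connect_families",
    "predict_domains",
]


@dataclass(frozen=True)
class DomainRegion:
    """A predicted domain interval [start, end) on one protein."""

    protein_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError("domain region must span at least one residue")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start))


@dataclass
class DomainGraph:
    """Region graph: nodes are regions, edges carry the best hit E-value."""

    graph: nx.Graph          # trimmed graph used for community detection
    full_graph: nx.Graph     # pre-trim graph (kept for inter-family links)


@dataclass
class DomainFamily:
    family_id: int
    members: list[DomainRegion]
    majority_pfam: Optional[str] = None
    majority_frequency: Optional[float] = None
    annotation_class: str = "unannotated"  # pfam | duf | unannotated


def filter_hits(hits: list[HitRecord],
                max_evalue: float = 1e-3) -> list[HitRecord]:
    """Keep hits with E <= max_evalue; drop self-hits."""
    return [h for h in hits
            if h.evalue <= max_evalue and h.query_id != h.target_id]


def boundary_cluster(hits_onto_protein: list[HitRecord],
                     height: float = 250.0) -> list[DomainRegion]:
    """Cluster hit (tstart, tend) endpoints into domain regions.

    Each hit landing on the protein contributes one 2-D point; points are
    clustered by complete-linkage hierarchical clustering on Euclidean
    distance, cutting the tree at ``height`` (residue units).  Each point
    cluster becomes a region with outward-rounded median boundaries.
    """
    if not hits_onto_protein:
        return []
    protein_id = hits_onto_protein[0].target_id
    points = np.array([[h.tstart, h.tend] for h in hits_onto_protein],
                      dtype=float)
    if len(points) == 1:
        labels = np.array([1])
    else:
        Z = linkage(points, method="complete", metric="euclidean")
        labels = fcluster(Z, t=height, criterion="distance")
    regions = []
    for lab in sorted(set(labels)):
        pts = points[labels == lab]
        start = int(math.floor(np.median(pts[:, 0])))
        end = int(math.ceil(np.median(pts[:, 1])))
        regions.append(DomainRegion(protein_id, start, max(end, start + 1)))
    regions.sort(key=lambda r: (r.start, r.end))
    return regions


def _regions_overlapping(regions: list[DomainRegion], start: int, end: int,
                         min_frac: float = 0.5) -> list[DomainRegion]:
    return [r for r in regions
            if r.overlap(start, end) >= min_frac * r.length]


def build_domain_graph(regions: list[DomainRegion], hits: list[HitRecord],
                       trim_evalue: float = 1e-5, max_len: int = 350,
                       min_component: int = 5) -> DomainGraph:
    """Link regions supported by a hit covering both; then trim the graph.

    An edge joins region r on protein P and region s on protein Q when some
    hit P->Q overlaps r on its query side and s on its target side by at
    least 50% of each region's length; parallel edges keep the lowest
    E-value.  Trimming removes edges with E > ``trim_evalue``, regions
    longer than ``max_len`` residues, and connected components with fewer
    than ``min_component`` nodes.
    """
    by_protein: dict[str, list[DomainRegion]] = {}
    for r in regions:
        by_protein.setdefault(r.protein_id, []).append(r)
    full = nx.Graph()
    full.add_nodes_from(regions)
    for h in hits:
        q_regions = _regions_overlapping(by_protein.get(h.query_id, []),
                                         h.qstart, h.qend)
        t_regions = _regions_overlapping(by_protein.get(h.target_id, []),
                                         h.tstart, h.tend)
        for r in q_regions:
            for s in t_regions:
                if r == s:
                    continue
                if full.has_edge(r, s):
                    if h.evalue < full[r][s]["evalue"]:
                        full[r][s]["evalue"] = h.evalue
                else:
                    full.add_edge(r, s, evalue=h.evalue)
    trimmed = nx.Graph()
    trimmed.add_nodes_from(n for n in full.nodes if n.length <= max_len)
    for r, s, data in full.edges(data=True):
        if data["evalue"] > trim_evalue:
            continue
        if r.length > max_len or s.length > max_len:
            continue
        trimmed.add_edge(r, s, evalue=data["evalue"])
    for comp in list(nx.connected_components(trimmed)):
        if len(comp) < min_component:
            trimmed.remove_nodes_from(comp)
    return DomainGraph(graph=trimmed, full_graph=full)


def _edge_weight(e: float) -> float:
    return -math.log10(max(e, 1e-300))


def detect_families(domain_graph: DomainGraph, steps: int = 6,
                    min_size: int = 5,
                    max_family_size: Optional[int] = None
                    ) -> list[DomainFamily]:
    """Walktrap community detection on the trimmed region graph.

    Edge weights are -log10(E) (E floored at 1e-300).  Communities smaller
    than ``min_size`` are dropped.  ``max_family_size`` does not remove
    anything; oversized families are only flagged by the caller's report.
    Vertex ordering is fixed (sorted regions) for determinism.
    """
    g = domain_graph.graph
    nodes = sorted(g.nodes, key=lambda r: (r.protein_id, r.start, r.end))
    if not nodes:
        return []
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in g.edges]
    weights = [_edge_weight(g[u][v]["evalue"]) for u, v in g.edges]
    ig = igraph.Graph(n=len(nodes), edges=edges)
    dendro = ig.community_walktrap(weights=weights, steps=steps)
    communities = dendro.as_clustering()
    families = []
    fid = 0
    for community in sorted(map(sorted, communities), key=lambda c: c[0]):
        members = [nodes[i] for i in community]
        if len(members) < min_size:
            continue
        families.append(DomainFamily(family_id=fid, members=members))
        fid += 1
    return families


def annotate_families(families: list[DomainFamily],
                      pfam_regions: dict[str, list[PfamRegion]],
                      min_overlap: float = 0.75) -> list[DomainFamily]:
    """Assign each family its most frequent well-covered Pfam accession.

    A member region carries Pfam F when more than ``min_overlap`` of F's
    extent overlaps the region.  The family's annotation is the accession
    carried by the largest number of members, with its frequency among all
    members; accessions whose name starts with ``DUF`` mark the family as a
    domain of unknown function.
    """
    for fam in families:
        counter: Counter[str] = Counter()
        for region in fam.members:
            carried = set()
            for pf in pfam_regions.get(region.protein_id, []):
                pf_len = pf.end - pf.start
                if region.overlap(pf.start, pf.end) > min_overlap * pf_len:
                    carried.add(pf.accession)
            counter.update(carried)
        if counter:
            # deterministic: highest count, then lexicographic accession
            acc, count = min(counter.items(), key=lambda kv: (-kv[1], kv[0]))
            fam.majority_pfam = acc
            fam.majority_frequency = count / len(fam.members)
            fam.annotation_class = "duf" if acc.startswith("DUF") else "pfam"
        else:
            fam.majority_pfam = None
            fam.majority_frequency = None
            fam.annotation_class = "unannotated"
    return families


def connect_families(families: list[DomainFamily],
                     domain_graph: DomainGraph,
                     threshold: float = 1e-3
                     ) -> list[tuple[int, int, float]]:
    """Link family pairs sharing an inter-region hit with E < threshold.

    Links are looked up in the pre-trim graph, so similarities too weak to
    merge two families (E between the trim cutoff and ``threshold``) are
    still reported.  Returns ``(family_a, family_b, best_evalue)`` tuples.
    """
    family_of: dict[DomainRegion, int] = {}
    for fam in families:
        for region in fam.members:
            family_of[region] = fam.family_id
    best: dict[tuple[int, int], float] = {}
    for r, s, data in domain_graph.full_graph.edges(data=True):
        fr, fs = family_of.get(r), family_of.get(s)
        if fr is None or fs is None or fr == fs:
            continue
        if data["evalue"] >= threshold:
            continue
        key = (min(fr, fs), max(fr, fs))
        if key not in best or data["evalue"] < best[key]:
            best[key] = data["evalue"]
    return [(a, b, e) for (a, b), e in sorted(best.items())]


def predict_domains(hits: list[HitRecord],
                    pfam_regions: Optional[dict[str, list[PfamRegion]]] = None,
                    *, max_evalue: float = 1e-3, height: float = 250.0,
                    trim_evalue: float = 1e-5, max_len: int = 350,
                    min_component: int = 5, steps: int = 6,
                    min_family: int = 5, min_overlap: float = 0.75
                    ) -> tuple[list[DomainRegion], list[DomainFamily],
                               list[tuple[int, int, float]]]:
    """Full domain-prediction pipeline from a hit table."""
    kept = filter_hits(hits, max_evalue=max_evalue)
    by_target: dict[str, list[HitRecord]] = {}
    for h in kept:
        by_target.setdefault(h.target_id, []).append(h)
    regions: list[DomainRegion] = []
    for pid in sorted(by_target):
        regions.extend(boundary_cluster(by_target[pid], height=height))
    graph = build_domain_graph(regions, kept, trim_evalue=trim_evalue,
                               max_len=max_len, min_component=min_component)
    families = detect_families(graph, steps=steps, min_size=min_family)
    families = annotate_families(families, pfam_regions or {},
                                 min_overlap=min_overlap)
    links = connect_families(families, graph, threshold=max_evalue)
    return regions, families, links
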