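"""NCBI-style taxonomy handling: taxdump parsing, LCA, rank summaries.

The lowest common ancestor of a cluster is computed after removing two
designated "unclassified sequences" (taxid 12908) and "other sequences"
(taxid 28384) subtrees, which otherwise drag almost any LCA to the root.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .records import Clustering

__all__ = ["Taxonomy", "LcaResult", "read_taxdump", "write_taxdump", "lca",
           "cluster_lca_summary", "DEFAULT_IGNORED_TAXA"]

#: "unclassified sequences" and "other sequences" pseudo-taxa.
DEFAULT_IGNORED_TAXA = frozenset({12908, 28384})


@dataclass
class TaxNode:
    taxid: int
    parent: int
    rank: str
    name: str


class Taxonomy:
    """Rooted tree of taxid nodes with ranks and scientific names."""

    def __init__(self, nodes: dict[int, TaxNode], root: int) -> None:
        self.nodes = nodes
        self.root = root
        self._validate()

    def _validate(self) -> None:
        if self.nodes[self.root].parent != self.root:
            raise ValueError("root's parent must be itself")
        for taxid, node in self.nodes.items():
            if node.parent not in self.nodes:
                raise ValueError(f"orphan taxid {taxid}: parent "
                                 f"{node.parent} unknown")
            # walk to root, detecting cycles
            seen = set()
            cur = taxid
            while cur != self.root:
                if cur in seen:
                    raise ValueError(f"cycle in taxonomy at taxid {cur}")
                seen.add(cur)
                cur = self.nodes[cur].parent

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def path_to_root(self, taxid: int) -> list[int]:
        """Ancestor path from the node itself up to (and including) root."""
        path = [taxid]
        while path[-1] != self.root:
            path.append(self.nodes[path[-1]].parent)
        return path

    def is_ancestor(self, ancestor: int, descendant: int) -> bool:
        return ancestor in self.path_to_root(descendant)

    def rank(self, taxid: int) -> str:
        return self.nodes[taxid].rank

    def name(self, taxid: int) -> str:
        return self.nodes[taxid].name


def read_taxdump(nodes_path, names_path) -> Taxonomy:
    """Parse nodes.dmp / names.dmp (pipe-delimited dialect)."""
    nodes: dict[int, TaxNode] = {}
    root: Optional[int] = None
    with open(nodes_path) as fh:
        for line in fh:
            fields = [f.strip() for f in line.rstrip("\t|\n").split("\t|\t")]
            taxid, parent, rank = int(fields[0]), int(fields[1]), fields[2]
            nodes[taxid] = TaxNode(taxid, parent, rank, "")
            if taxid == parent:
                root = taxid
    if root is None:
        raise ValueError("taxdump has no root (node with parent == itself)")
    with open(names_path) as fh:
        for line in fh:
            fields = [f.strip() for f in line.rstrip("\t|\n").split("\t|\t")]
            taxid, name, name_class = int(fields[0]), fields[1], fields[3]
            if name_class == "scientific name" and taxid in nodes:
                nodes[taxid].name = name
    return Taxonomy(nodes, root)


def write_taxdump(taxonomy: Taxonomy, nodes_path, names_path) -> None:
    """Write the standard pipe-delimited dialect (test fixtures, round trips)."""
    with open(nodes_path, "w") as fh:
        for node in taxonomy.nodes.values():
            fh.write(f"{node.taxid}\t|\t{node.parent}\t|\t{node.rank}\t|\n")
    with open(names_path, "w") as fh:
        for node in taxonomy.nodes.values():
            fh.write(f"{node.taxid}\t|\t{node.name}\t|\t\t|\t"
                     f"scientific name\t|\n")


def lca(taxonomy: Taxonomy, taxids: Iterable[int],
        ignore: frozenset[int] = DEFAULT_IGNORED_TAXA) -> Optional[int]:
    """Lowest common ancestor of a set of taxids.

    Ignored taxa and all of their descendants are removed from the input
    first; unknown taxids are skipped with a warning.  Returns None when
    nothing remains.
    """
    kept_paths = []
    for t in taxids:
        if t not in taxonomy:
            warnings.warn(f"unknown taxid {t}; skipped")
            continue
        path = taxonomy.path_to_root(t)
        if any(a in ignore for a in path):
            continue
        kept_paths.append(path)
    if not kept_paths:
        return None
    common = set(kept_paths[0])
    for path in kept_paths[1:]:
        common &= set(path)
    # the deepest common ancestor is the first common node on any path
    for node in kept_paths[0]:
        if node in common:
            return node
    raise AssertionError("paths share no node, tree is not rooted")


@dataclass
class LcaResult:
    cluster_id: str
    taxid: Optional[int]
    rank: Optional[str]
    name: Optional[str]


def cluster_lca(clustering: Clustering, member_taxids: dict[str, int],
                taxonomy: Taxonomy,
                ignore: frozenset[int] = DEFAULT_IGNORED_TAXA
                ) -> list[LcaResult]:
    """Strict LCA per cluster; members without a taxid are skipped."""
    out = []
    for rep, members in clustering.clusters.items():
        taxids = [member_taxids[m] for m in members if m in member_taxids]
        t = lca(taxonomy, taxids, ignore=ignore)
        out.append(LcaResult(
            cluster_id=rep,
            taxid=t,
            rank=None if t is None else taxonomy.rank(t),
            name=None if t is None else taxonomy.name(t),
        ))
    return out


def cluster_lca_summary(clustering: Clustering,
                        member_taxids: dict[str, int],
                        taxonomy: Taxonomy,
                        ignore: frozenset[int] = DEFAULT_IGNORED_TAXA
                        ) -> pd.DataFrame:
    """Cluster counts per LCA taxon, rolled up along ancestor ranks.

    For every cluster the count of each ancestor of its LCA (including the
    LCA itself) is incremented, so each row reports how many clusters have
    their LCA at or below that taxon.  ``species_specific`` flags rows whose
    taxon rank is species.  ``fraction`` is relative to the number of
    clusters with a defined LCA.
    """
    results = cluster_lca(clustering, member_taxids, taxonomy, ignore=ignore)
    counts: dict[int, int] = {}
    exact: dict[int, int] = {}
    n_defined = 0
    for res in results:
        if res.taxid is None:
            continue
        n_defined += 1
        exact[res.taxid] = exact.get(res.taxid, 0) + 1
        for anc in taxonomy.path_to_root(res.taxid):
            counts[anc] = counts.get(anc, 0) + 1
    rows = []
    for taxid, n in sorted(counts.items()):
        rows.append({
            "rank": taxonomy.rank(taxid),
            "taxid": taxid,
            "name": taxonomy.name(taxid),
            "n_clusters": n,
            "n_exact": exact.get(taxid, 0),
            "fraction": n / n_defined if n_defined else 0.0,
            "species_specific": taxonomy.rank(taxid) == "species",
        })
    return pd.DataFrame(rows)
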