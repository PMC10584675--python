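import numpy as np
import pytest

from foldcluster.annotate import PfamRegion
from foldcluster.domains import (DomainGraph, DomainRegion, annotate_families,
                                 boundary_cluster, build_domain_graph,
                                 connect_families, detect_families,
                                 filter_hits, predict_domains)
from foldcluster.records import HitRecord
from foldcluster.synthetic import simulate_domain_hits, simulate_multidomain


def hit(q, t, qs, qe, ts, te, e=1e-10):
    return HitRecord(q, t, qs, qe, ts, te, score=50.0, evalue=e)


class TestFilterHits:
    def test_threshold(self):
        kept = filter_hits([hit("a", "b", 0, 10, 0, 10, e=1e-2),
                            hit("a", "b", 0, 10, 0, 10, e=1e-4)])
        assert len(kept) == 1 and kept[0].evalue == 1e-4

    def test_self_hits_removed(self):
        assert filter_hits([hit("a", "a", 0, 10, 0, 10, e=1e-9)]) == []

    def test_matches_predicate_oracle(self):
        rng = np.random.default_rng(0)
        hits = [hit(f"q{i}", f"t{i % 3}", 0, 10, 0, 10,
                    e=float(10.0 ** rng.uniform(-8, 0))) for i in range(100)]
        kept = filter_hits(hits)
        expected = [h for h in hits
                    if h.evalue <= 1e-3 and h.query_id != h.target_id]
        assert kept == expected

    def test_region_count_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        hits = []
        for i in range(60):
            s = int(rng.integers(0, 200))
            hits.append(hit(f"q{i}", "P", 0, 50, s, s + 80,
                            e=float(10.0 ** rng.uniform(-8, 0))))
        counts = []
        for emax in (1e-6, 1e-4, 1e-2):
            kept = [h for h in filter_hits(hits, max_evalue=emax)]
            counts.append(len(boundary_cluster(kept)) if kept else 0)
        assert counts == sorted(counts)


class TestBoundaryCluster:
    def test_identical_hits_one_region(self):
        hits = [hit("q", "P", 0, 10, 10, 110) for _ in range(5)]
        regions = boundary_cluster(hits)
        assert regions == [DomainRegion("P", 10, 110)]

    def test_well_separated_hits_two_regions(self):
        hits = ([hit("q", "P", 0, 10, 0, 100) for _ in range(5)]
                + [hit("q", "P", 0, 10, 300, 400) for _ in range(5)])
        regions = boundary_cluster(hits)
        assert len(regions) == 2
        assert regions[0].start == 0 and regions[0].end == 100
        assert regions[1].start == 300 and regions[1].end == 400

    def test_jittered_hits_recover_planted_boundaries(self):
        rng = np.random.default_rng(2)
        planted = [(0, 100), (150, 260), (320, 400)]
        hits = []
        for start, end in planted:
            for _ in range(17):
                s = int(round(start + rng.normal(0, 10)))
                e = int(round(end + rng.normal(0, 10)))
                hits.append(hit("q", "P", 0, 10, max(0, s), max(s + 2, e)))
        regions = boundary_cluster(hits)
        assert len(regions) == 3
        for region, (ps, pe) in zip(regions, planted):
            assert abs(region.start - ps) <= 15
            assert abs(region.end - pe) <= 15


class TestDomainGraph:
    def star_regions(self, n, length=100):
        return [DomainRegion(f"P{i}", 0, length) for i in range(n)]

    def link_all(self, regions, e=1e-8):
        hits = []
        for i in range(len(regions)):
            for j in range(len(regions)):
                if i != j:
                    hits.append(hit(regions[i].protein_id,
                                    regions[j].protein_id,
                                    0, 100, 0, 100, e=e))
        return hits

    def test_small_component_removed(self):
        regions = self.star_regions(4)
        graph = build_domain_graph(regions, self.link_all(regions))
        assert graph.graph.number_of_nodes() == 0
        assert graph.full_graph.number_of_edges() > 0

    def test_long_region_removed(self):
        regions = self.star_regions(5) + [DomainRegion("PX", 0, 400)]
        hits = self.link_all(regions[:5]) + [
            hit("P0", "PX", 0, 100, 0, 400)]
        graph = build_domain_graph(regions, hits)
        assert DomainRegion("PX", 0, 400) not in graph.graph
        assert graph.graph.number_of_nodes() == 5

    def test_weak_edges_trimmed_but_kept_in_full_graph(self):
        regions = self.star_regions(6)
        strong = self.link_all(regions[:5], e=1e-8)
        weak = [hit("P0", "P5", 0, 100, 0, 100, e=1e-4)]
        graph = build_domain_graph(regions, strong + weak)
        r5 = DomainRegion("P5", 0, 100)
        assert r5 not in graph.graph or graph.graph.degree(r5) == 0
        assert graph.full_graph.has_edge(DomainRegion("P0", 0, 100), r5)

    def test_overlap_rule_and_duplicate_resolution(self):
        regions = [DomainRegion("A", 0, 100), DomainRegion("A", 200, 300),
                   DomainRegion("B", 0, 100)]
        # hit covers only the first region of A on the query side
        hits = [hit("A", "B", 0, 100, 0, 100, e=1e-7),
                hit("A", "B", 10, 90, 5, 95, e=1e-9)]
        graph = build_domain_graph(regions, hits, min_component=1)
        edge = graph.full_graph[regions[0]][regions[2]]
        assert edge["evalue"] == 1e-9  # duplicate kept the best E-value
        assert not graph.full_graph.has_edge(regions[1], regions[2])

    def test_planted_two_family_adjacency(self):
        fam_a = [DomainRegion(f"P{i}", 0, 100) for i in range(5)]
        fam_b = [DomainRegion(f"P{i}", 150, 250) for i in range(5)]
        hits = []
        for i in range(5):
            for j in range(5):
                if i == j:
                    continue
                hits.append(hit(f"P{i}", f"P{j}", 0, 100, 0, 100))
                hits.append(hit(f"P{i}", f"P{j}", 150, 250, 150, 250))
        graph = build_domain_graph(fam_a + fam_b, hits)
        for u, v in graph.graph.edges:
            # edges never cross the two planted families
            assert (u.start == v.start)


class TestDetectFamilies:
    def make_cliques(self, sizes, bridge_evalue=None):
        import networkx as nx
        g = nx.Graph()
        cliques = []
        offset = 0
        for size in sizes:
            nodes = [DomainRegion(f"P{offset + i}", 0, 100)
                     for i in range(size)]
            for i in range(size):
                for j in range(i + 1, size):
                    g.add_edge(nodes[i], nodes[j], evalue=1e-10)
            cliques.append(nodes)
            offset += size
        if bridge_evalue is not None:
            g.add_edge(cliques[0][0], cliques[1][0], evalue=bridge_evalue)
        return DomainGraph(graph=g, full_graph=g.copy()), cliques

    def test_two_cliques_weakly_bridged_split(self):
        graph, cliques = self.make_cliques([6, 6], bridge_evalue=1e-6)
        families = detect_families(graph)
        assert len(families) == 2
        got = {frozenset(r.protein_id for r in f.members)
               for f in families}
        expected = {frozenset(r.protein_id for r in c) for c in cliques}
        assert got == expected

    def test_small_community_dropped(self):
        graph, _ = self.make_cliques([4])
        assert detect_families(graph) == []

    def test_disconnected_components_never_merged(self):
        graph, cliques = self.make_cliques([6, 7])
        families = detect_families(graph)
        assert len(families) == 2
        for fam in families:
            proteins = {r.protein_id for r in fam.members}
            assert proteins <= {r.protein_id for r in cliques[0]} or \
                proteins <= {r.protein_id for r in cliques[1]}

    def test_empty_graph(self):
        import networkx as nx
        graph = DomainGraph(nx.Graph(), nx.Graph())
        assert detect_families(graph) == []


class TestAnnotateFamilies:
    def family_of(self, n=4, start=0, end=100):
        from foldcluster.domains import DomainFamily
        return DomainFamily(0, [DomainRegion(f"P{i}", start, end)
                                for i in range(n)])

    def test_fully_covered_unanimous(self):
        fam = self.family_of()
        pfam = {f"P{i}": [PfamRegion("PF00069", "CL0016", 0, 100)]
                for i in range(4)}
        annotate_families([fam], pfam)
        assert fam.majority_pfam == "PF00069"
        assert fam.majority_frequency == 1.0
        assert fam.annotation_class == "pfam"

    def test_insufficient_overlap_not_assigned(self):
        fam = self.family_of()
        # Pfam domain of length 200, only half inside the region
        pfam = {f"P{i}": [PfamRegion("PF1", "CL1", 0, 200)]
                for i in range(4)}
        annotate_families([fam], pfam)
        assert fam.majority_pfam is None
        assert fam.annotation_class == "unannotated"

    def test_duf_class(self):
        fam = self.family_of()
        pfam = {f"P{i}": [PfamRegion("DUF998", None, 0, 100)]
                for i in range(4)}
        annotate_families([fam], pfam)
        assert fam.annotation_class == "duf"

    def test_mixed_fixture_matches_counting_oracle(self):
        fam = self.family_of(n=6)
        pfam = {}
        for i in range(6):
            acc = "PF1" if i < 4 else "PF2"
            pfam[f"P{i}"] = [PfamRegion(acc, None, 0, 100)]
        annotate_families([fam], pfam)
        assert fam.majority_pfam == "PF1"
        assert fam.majority_frequency == pytest.approx(4 / 6)


class TestConnectFamilies:
    def test_remote_link_above_trim_below_threshold(self):
        import networkx as nx
        from foldcluster.domains import DomainFamily
        a = [DomainRegion(f"A{i}", 0, 100) for i in range(5)]
        b = [DomainRegion(f"B{i}", 0, 100) for i in range(5)]
        full = nx.Graph()
        full.add_edge(a[0], b[0], evalue=1e-4)
        graph = DomainGraph(nx.Graph(), full)
        fams = [DomainFamily(0, a), DomainFamily(1, b)]
        assert connect_families(fams, graph) == [(0, 1, 1e-4)]

    def test_no_inter_family_hits_no_links(self):
        import networkx as nx
        from foldcluster.domains import DomainFamily
        fams = [DomainFamily(0, [DomainRegion("A", 0, 10)]),
                DomainFamily(1, [DomainRegion("B", 0, 10)])]
        graph = DomainGraph(nx.Graph(), nx.Graph())
        assert connect_families(fams, graph) == []


@pytest.fixture(scope="module")
def planted():
    from foldcluster.synthetic import (default_domain_pool,
                                       random_architectures)
    pool = default_domain_pool(n_families=5, seed=7)
    archs = random_architectures(pool, n_proteins=40, seed=7)
    sset, truth = simulate_multidomain(pool, archs, seed=7)
    hits = simulate_domain_hits(
        truth, seed=7, remote_pairs=[("D0", "D1", 1e-4)])
    return truth, hits


class TestEndToEnd:
    def test_planted_family_recovery(self, planted):
        truth, hits = planted
        regions, families, links = predict_domains(hits)
        assert len(families) == 5
        # purity: map each region to the planted domain it overlaps most
        correct = total = 0
        for fam in families:
            planted_ids = []
            for region in fam.members:
                best = max(truth.domains[region.protein_id],
                           key=lambda d: region.overlap(d[1], d[2]))
                planted_ids.append(best[0])
            majority = max(set(planted_ids), key=planted_ids.count)
            correct += planted_ids.count(majority)
            total += len(planted_ids)
        assert correct / total >= 0.9

    def test_boundary_error_within_tolerance(self, planted):
        truth, hits = planted
        regions, _, _ = predict_domains(hits)
        errors = []
        for region in regions:
            best = max(truth.domains[region.protein_id],
                       key=lambda d: region.overlap(d[1], d[2]))
            errors.append(abs(region.start - best[1]))
            errors.append(abs(region.end - best[2]))
        assert np.mean(errors) <= 15

    def test_remote_link_recovered(self, planted):
        truth, hits = planted
        regions, families, links = predict_domains(hits)
        # identify which detected family corresponds to D0 and D1
        def planted_family(fam):
            ids = []
            for region in fam.members:
                best = max(truth.domains[region.protein_id],
                           key=lambda d: region.overlap(d[1], d[2]))
                ids.append(best[0])
            return max(set(ids), key=ids.count)
        fam_map = {planted_family(f): f.family_id for f in families}
        linked = {(min(a, b), max(a, b)) for a, b, _ in links}
        expected = (min(fam_map["D0"], fam_map["D1"]),
                    max(fam_map["D0"], fam_map["D1"]))
        assert expected in linked
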