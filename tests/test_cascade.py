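import numpy as np
import pytest

from foldcluster.cascade import (PipelineConfig, remove_fragments,
                                 run_pipeline, select_representatives,
                                 sequence_precluster, set_cover_cluster,
                                 structural_cluster)
from foldcluster.io import write_cluster_tsv
from foldcluster.records import Clustering, StructureRecord, StructureSet
from foldcluster.synthetic import (FamilySpec, demo_families,
                                   simulate_families)

from oracles import greedy_set_cover


def small_config(**kw) -> PipelineConfig:
    return PipelineConfig(calibration_pairs=120, **kw)


class TestSetCover:
    def test_star_graph_hub_representative(self):
        ids = ["hub"] + [f"leaf{i}" for i in range(5)]
        edges = [("hub", leaf) for leaf in ids[1:]]
        clustering = set_cover_cluster(ids, edges)
        assert len(clustering) == 1
        assert clustering.representatives == ["hub"]

    def test_edgeless_graph_singletons(self):
        ids = [f"n{i}" for i in range(7)]
        clustering = set_cover_cluster(ids, [])
        assert len(clustering) == 7
        assert all(len(m) == 1 for m in clustering.clusters.values())

    @pytest.mark.parametrize("seed", range(100))
    def test_random_graphs_match_greedy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 31))
        ids = [f"v{i:02d}" for i in range(n)]
        p = rng.uniform(0.05, 0.4)
        edges = [(ids[i], ids[j])
                 for i in range(n) for j in range(i + 1, n)
                 if rng.random() < p]
        got = set_cover_cluster(ids, edges)
        expected = greedy_set_cover(ids, edges)
        assert {r: sorted(m) for r, m in got.clusters.items()} == \
            {r: sorted(m) for r, m in expected.items()}


class TestSequencePrecluster:
    def test_duplicates_one_cluster(self, aa_params):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 80))
        sset = StructureSet([
            StructureRecord("a", seq, seq),
            StructureRecord("b", seq, seq),
        ])
        clustering = sequence_precluster(sset, small_config())
        assert len(clustering) == 1

    def test_low_identity_never_coclustered(self):
        # two unrelated random sequences: identity ~5%, far below 50%
        rng = np.random.default_rng(1)
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        a = "".join(rng.choice(letters, 100))
        b = "".join(rng.choice(letters, 100))
        sset = StructureSet([StructureRecord("a", a, a),
                             StructureRecord("b", b, b)])
        clustering = sequence_precluster(sset, small_config())
        assert len(clustering) == 2

    def test_family_coclustered_and_audited(self, aa_params):
        from foldcluster.alignment import gapped_align

        sset, _ = simulate_families(
            [FamilySpec("FA", length=150, n_members=6, sub_rate=0.1)], seed=2)
        config = small_config()
        clustering = sequence_precluster(sset, config)
        assert len(clustering) == 1
        rep = clustering.representatives[0]
        for m in clustering.members:
            if m == rep:
                continue
            aln = gapped_align(sset[m], sset[rep], aa_params)
            assert aln.seq_identity >= config.seq_min_id
            assert aln.qcov >= config.seq_cov and aln.tcov >= config.seq_cov


class TestSelectRepresentatives:
    def make_set(self, plddts):
        recs = []
        for i, p in enumerate(plddts):
            rec = StructureRecord(f"r{i}", "ACDEFGHIKL", "ACDEFGHIKL",
                                  plddt=None if p is None else
                                  np.full(10, float(p)))
            recs.append(rec)
        return StructureSet(recs)

    def test_highest_plddt_wins(self):
        sset = self.make_set([90, 70])
        clustering = Clustering({"r1": ["r1", "r0"]})
        out = select_representatives(clustering, sset)
        assert out.representatives == ["r0"]

    def test_missing_plddt_tie_breaks_by_length_then_id(self):
        recs = [
            StructureRecord("b", "ACDEF", "ACDEF"),
            StructureRecord("a", "ACDEF", "ACDEF"),
            StructureRecord("long", "ACDEFGHIKL", "ACDEFGHIKL"),
        ]
        sset = StructureSet(recs)
        clustering = Clustering({"b": ["b", "a", "long"]})
        out = select_representatives(clustering, sset)
        assert out.representatives == ["long"]
        # equal lengths: smallest id
        clustering2 = Clustering({"b": ["b", "a"]})
        assert select_representatives(clustering2, sset).representatives == \
            ["a"]

    def test_matches_max_scan_oracle(self):
        rng = np.random.default_rng(3)
        plddts = rng.uniform(40, 95, size=30).round(2)
        sset = self.make_set(list(plddts))
        clustering = Clustering({"r0": [f"r{i}" for i in range(30)]})
        out = select_representatives(clustering, sset)
        best = max(range(30), key=lambda i: (plddts[i], -i))
        assert out.representatives == [f"r{best}"]


class TestRemoveFragments:
    def base_set(self, frag_ids, n=5):
        recs = []
        for i in range(n):
            recs.append(StructureRecord(
                f"r{i}", "ACDEFGHIKL", "ACDEFGHIKL",
                plddt=np.full(10, 50.0 + i),
                is_fragment=f"r{i}" in frag_ids))
        return StructureSet(recs)

    def test_fragment_representative_reassigned(self):
        sset = self.base_set({"r0"})
        clustering = Clustering({"r0": ["r0", "r1", "r2"]})
        out = remove_fragments(clustering, sset)
        assert "r0" not in out.members
        assert out.representatives == ["r2"]  # highest pLDDT survivor

    def test_all_fragment_cluster_dropped(self):
        sset = self.base_set({"r0", "r1"})
        clustering = Clustering({"r0": ["r0", "r1"], "r2": ["r2"]})
        out = remove_fragments(clustering, sset)
        assert set(out.members) == {"r2"}

    def test_random_flags_match_filter_oracle(self):
        rng = np.random.default_rng(4)
        n = 40
        frag = {f"r{i}" for i in range(n) if rng.random() < 0.3}
        sset = self.base_set(frag, n=n)
        groups = {}
        for i in range(n):
            groups.setdefault(int(rng.integers(0, 8)), []).append(f"r{i}")
        clustering = Clustering({ms[0]: ms for ms in groups.values()})
        out = remove_fragments(clustering, sset)
        expected_members = {m for m in clustering.members if m not in frag}
        assert set(out.members) == expected_members
        # cluster co-membership preserved for survivors
        for rep, members in clustering.clusters.items():
            kept = [m for m in members if m not in frag]
            for a in kept[1:]:
                assert out.co_clustered(kept[0], a)


@pytest.fixture(scope="module")
def bench():
    sset, truth = demo_families(n_families=8, n_members=6, length=150,
                                seed=11)
    config = small_config(seed=11)
    return sset, truth, run_pipeline(sset, config)


class TestPipeline:
    def test_single_record_singleton_at_every_stage(self):
        sset = StructureSet([StructureRecord(
            "only", "ACDEFGHIKL" * 4, "ACDEFGHIKL" * 4)])
        res = run_pipeline(sset, small_config())
        for stage in (res.sequence_clusters, res.structural_clusters,
                      res.expanded_clusters, res.final_clusters):
            assert len(stage) == 1

    def test_partition_preserved_at_every_stage(self, bench):
        sset, _, res = bench
        assert res.sequence_clusters.is_partition_of(sset.ids)
        assert res.expanded_clusters.is_partition_of(sset.ids)
        assert res.final_clusters.is_partition_of(
            [r.id for r in sset if not r.is_fragment])

    def test_structural_stage_merges_sequence_clusters(self, bench):
        _, _, res = bench
        # hierarchy consistency: every structural cluster is a union of
        # sequence clusters
        seq_rep = {m: rep for rep, ms in
                   res.sequence_clusters.clusters.items() for m in ms}
        for rep, members in res.expanded_clusters.clusters.items():
            seq_cluster_ids = {seq_rep[m] for m in members}
            n = sum(len(res.sequence_clusters.clusters[s])
                    for s in seq_cluster_ids)
            assert n == len(members)

    def test_family_recovery(self, bench):
        from foldcluster.synthetic import pairwise_family_metrics
        _, truth, res = bench
        precision, recall = pairwise_family_metrics(res.final_clusters,
                                                    truth.member_family)
        assert precision >= 0.95 and recall >= 0.95

    def test_rerun_byte_identical(self, tmp_path):
        sset, _ = demo_families(n_families=4, n_members=4, length=100,
                                seed=12)
        outs = []
        for run in range(2):
            res = run_pipeline(sset, small_config(seed=5))
            path = tmp_path / f"run{run}.tsv"
            write_cluster_tsv(res.final_clusters, path)
            outs.append(path.read_bytes())
        assert outs[0] == outs[1]

    def test_cluster_count_non_increasing_through_cascade(self):
        sset, _ = demo_families(n_families=6, n_members=5, length=120,
                                seed=13)
        config = small_config(seed=13)
        seq = select_representatives(sequence_precluster(sset, config), sset)
        reps = sset.subset(seq.representatives)
        if len(reps) < 2:
            pytest.skip("degenerate preclustering")
        no_cascade = structural_cluster(
            reps, small_config(seed=13, cascade_rounds=0))
        with_cascade = structural_cluster(
            reps, small_config(seed=13, cascade_rounds=3))
        assert len(with_cascade) <= len(no_cascade)

    def test_fragments_removed_from_final(self):
        sset, _ = demo_families(n_families=3, n_members=4, length=100,
                                seed=14)
        # mark one member per family as fragment
        for rid in list(sset.ids)[::4]:
            sset[rid].is_fragment = True
        res = run_pipeline(sset, small_config(seed=14))
        assert all(not sset[m].is_fragment
                   for m in res.final_clusters.members)
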