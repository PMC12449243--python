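"""Directional UMI clustering and per-cell deduplication."""

import itertools
import random

import pytest

from conftest import make_sam
from nanosc.correction import hamming_distance
from nanosc.dedup import (
    DedupParams,
    cluster_umis_directional,
    dedup_bam,
    group_alignments,
    select_representative,
)

CONTIGS = [("chr1", 100000), ("chr2", 100000)]
CB = "ACGTACGTACGTACGT"


def tagged(name, contig, pos, umi, cb=CB, flag=0, mapq=60, cigar="50M"):
    tags = {"CR": cb, "CB": cb, "UR": umi, "CY": "I" * 16, "UY": "I" * len(umi)}
    return (name, flag, contig, pos, mapq, cigar, "A" * 50, tags)


def brute_force_directional(counts, umi_hamming=1):
    """Independent oracle: directed reachability among unclaimed nodes,
    seeds in count-descending (lexicographic) order."""
    import networkx as nx

    graph = nx.DiGraph()
    graph.add_nodes_from(counts)
    for a, b in itertools.permutations(counts, 2):
        if hamming_distance(a, b) <= umi_hamming and counts[a] >= 2 * counts[b] - 1:
            graph.add_edge(a, b)
    claimed = set()
    clusters = []
    for seed in sorted(counts, key=lambda u: (-counts[u], u)):
        if seed in claimed:
            continue
        sub = graph.subgraph([n for n in counts if n not in claimed])
        members = {seed} | nx.descendants(sub, seed)
        claimed |= members
        clusters.append(frozenset(members))
    return set(clusters)


class TestDirectionalClustering:
    @pytest.mark.parametrize(
        "counts,n_clusters,representative",
        [
            ({"AAAA": 10, "AAAT": 1}, 1, "AAAA"),  # 10 >= 2*1-1
            ({"AAAA": 4, "AAAT": 3}, 2, "AAAA"),  # 4 < 2*3-1
            ({"AAAA": 1, "TTTT": 1}, 2, "AAAA"),  # distance 4 > 1
        ],
    )
    def test_hand_cases(self, counts, n_clusters, representative):
        clusters = cluster_umis_directional(counts)
        assert len(clusters) == n_clusters
        assert clusters[0].representative_umi == representative

    def test_chain_collapses_transitively(self):
        # A -> B -> C even though A and C are Hamming distance 2 apart
        counts = {"AAAA": 16, "AAAT": 8, "AATT": 4}
        clusters = cluster_umis_directional(counts)
        assert len(clusters) == 1 and clusters[0].n_reads == 28

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError):
            cluster_umis_directional({"AAA": 1, "AAAA": 1})

    def test_matches_brute_force_oracle(self):
        rng = random.Random(2024)
        kmers = ["".join(p) for p in itertools.product("ACGT", repeat=3)]
        for _ in range(1500):
            n = rng.randint(1, 4)
            counts = {u: rng.randint(1, 10) for u in rng.sample(kmers, n)}
            ours = {frozenset(u for u, _ in c.member_umis) for c in cluster_umis_directional(counts)}
            assert ours == brute_force_directional(counts)


class TestGrouping:
    def test_same_key_groups_together(self, tmp_path):
        sam = make_sam(
            tmp_path / "in.sam",
            [tagged("r0", "chr1", 100, "AAAACCCCGGGG"), tagged("r1", "chr1", 100, "AAAACCCCGGGG")],
            CONTIGS,
        )
        groups = list(group_alignments(sam, "genome"))
        assert len(groups) == 1 and len(groups[0][1]) == 2

    def test_different_cb_split_groups(self, tmp_path):
        sam = make_sam(
            tmp_path / "in.sam",
            [
                tagged("r0", "chr1", 100, "AAAACCCCGGGG"),
                tagged("r1", "chr1", 100, "AAAACCCCGGGG", cb="T" * 16),
            ],
            CONTIGS,
        )
        assert len(list(group_alignments(sam, "genome"))) == 2

    def test_softclip_adjusted_5prime(self, tmp_path):
        # 10S shifts the clip-adjusted start back to 90 == the unclipped read
        sam = make_sam(
            tmp_path / "in.sam",
            [
                tagged("r0", "chr1", 90, "AAAACCCCGGGG", cigar="50M"),
                tagged("r1", "chr1", 100, "AAAACCCCGGGG", cigar="10S40M"),
            ],
            CONTIGS,
        )
        assert len(list(group_alignments(sam, "genome"))) == 1

    def test_transcriptome_mode_keys_on_reference(self, tmp_path):
        tx_contigs = [("t1", 1000), ("t2", 1000)]
        sam = make_sam(
            tmp_path / "in.sam",
            [tagged("r0", "t1", 0, "AAAACCCCGGGG"), tagged("r1", "t2", 500, "AAAACCCCGGGG")],
            tx_contigs,
        )
        assert len(list(group_alignments(sam, "transcriptome"))) == 2

    def test_missing_ur_is_an_error(self, tmp_path):
        rec = ("r0", 0, "chr1", 10, 60, "50M", "A" * 50, {"CB": CB})
        sam = make_sam(tmp_path / "in.sam", [rec], CONTIGS)
        with pytest.raises(ValueError, match="r0"):
            list(group_alignments(sam, "genome"))


class TestSelectRepresentative:
    def _alignments(self, tmp_path, specs):
        sam = make_sam(tmp_path / "sel.sam", specs, CONTIGS)
        ((_, alignments),) = group_alignments(sam, "transcriptome")
        return alignments

    def test_highest_mapq_wins(self, tmp_path):
        alns = self._alignments(
            tmp_path,
            [tagged("lo", "chr1", 0, "A" * 12, mapq=30), tagged("hi", "chr1", 0, "A" * 12, mapq=60)],
        )
        assert select_representative(alns).query_name == "hi"

    def test_longest_span_breaks_mapq_tie(self, tmp_path):
        alns = self._alignments(
            tmp_path,
            [
                tagged("short", "chr1", 0, "A" * 12, cigar="30M20S"),
                tagged("long", "chr1", 0, "A" * 12, cigar="50M"),
            ],
        )
        assert select_representative(alns).query_name == "long"

    def test_read_id_breaks_full_tie(self, tmp_path):
        alns = self._alignments(
            tmp_path, [tagged("zzz", "chr1", 0, "A" * 12), tagged("aaa", "chr1", 0, "A" * 12)]
        )
        assert select_representative(alns).query_name == "aaa"


class TestDedupBam:
    def test_triplicate_collapses_to_one(self, tmp_path):
        sam = make_sam(
            tmp_path / "in.sam",
            [tagged(f"r{i}", "chr1", 100, "AAAACCCCGGGG") for i in range(3)],
            CONTIGS,
        )
        stats = dedup_bam(sam, tmp_path / "out.sam", DedupParams(mode="genome"))
        assert stats == {"n_in": 3, "n_out": 1, "n_molecules": 1}

    def test_unique_method_keeps_distinct_umis(self, tmp_path):
        sam = make_sam(
            tmp_path / "in.sam",
            [tagged("r0", "chr1", 100, "AAAA" * 3), tagged("r1", "chr1", 100, "AAAT" + "A" * 8)],
            CONTIGS,
        )
        stats = dedup_bam(sam, tmp_path / "out.sam", DedupParams(method="unique", mode="genome"))
        assert stats["n_out"] == 2

    def test_untagged_input_errors(self, tmp_path):
        sam = make_sam(
            tmp_path / "in.sam", [("r0", 0, "chr1", 10, 60, "50M", "A" * 50, {})], CONTIGS
        )
        with pytest.raises(ValueError, match="tag"):
            dedup_bam(sam, tmp_path / "out.sam")

    def test_simulation_truth_molecule_count(self, sim_clean, run_clean):
        _, sim, _ = sim_clean
        _, result = run_clean
        assert result.dedup_stats["n_out"] == sim.truth_matrix.total_mass()

    def test_deterministic_output(self, sim_clean, run_clean, tmp_path):
        _, result = run_clean
        tagged_sam = result.out_dir / "tagged.sam"
        dedup_bam(tagged_sam, tmp_path / "a.sam", DedupParams(mode="genome"))
        dedup_bam(tagged_sam, tmp_path / "b.sam", DedupParams(mode="genome"))
        assert (tmp_path / "a.sam").read_bytes() == (tmp_path / "b.sam").read_bytes()

    def test_split_invariance(self, run_clean, tmp_path):
        from nanosc.tagging import split_by_chromosome

        _, result = run_clean
        tagged_sam = result.out_dir / "tagged.sam"
        whole = dedup_bam(tagged_sam, tmp_path / "whole.sam", DedupParams(mode="genome"))
        parts = split_by_chromosome(tagged_sam, tmp_path / "parts")
        total = 0
        for contig, path in parts.items():
            stats = dedup_bam(path, tmp_path / f"{contig}.dedup.sam", DedupParams(mode="genome"))
            total += stats["n_out"]
        assert total == whole["n_out"]
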