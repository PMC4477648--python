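import numpy as np
import pytest

from slqscan.annotation import (
    NON_TEMPLATE,
    TEMPLATE,
    GeneModel,
    GeneModelError,
    annotate_hit,
    annotate_hits,
    cluster_hits,
    counts_per_gene,
    intersect_track,
    read_bed12,
    read_refgene,
    tss_profile,
    write_refgene,
)
from slqscan.reports import SimpleHit


def hit(start, end, strand="+", hid=None, chrom="chr1", tracts=()):
    return SimpleHit(
        seq_name=chrom, strand=strand, span=(start, end),
        class_label="SLQS", id=hid or f"h{start}", tracts=tracts,
    )


@pytest.fixture
def plus_gene():
    return GeneModel(
        tx_id="NM_1", gene_symbol="GENE1", seq_name="chr1", strand="+",
        tx_start=1000, tx_end=5000, cds_start=1500, cds_end=4500,
        exons=((1000, 2000), (3000, 5000)),
    )


@pytest.fixture
def minus_gene():
    return GeneModel(
        tx_id="NM_2", gene_symbol="GENE2", seq_name="chr1", strand="-",
        tx_start=10_000, tx_end=14_000, cds_start=10_500, cds_end=13_500,
        exons=((10_000, 11_000), (12_000, 14_000)),
    )


class TestClusterHits:
    def test_shared_tract_joins(self):
        a = hit(0, 30, tracts=((0, 3), (10, 13), (20, 23), (27, 30)))
        b = hit(0, 40, hid="b", tracts=((0, 3), (10, 13), (20, 23), (37, 40)))
        assert len(cluster_hits([a, b])) == 1

    def test_disjoint_hits_separate(self):
        a = hit(0, 30, tracts=((0, 3), (10, 13), (20, 23), (27, 30)))
        b = hit(100, 130, hid="b", tracts=((100, 103), (110, 113), (120, 123), (127, 130)))
        assert len(cluster_hits([a, b])) == 2

    def test_transitive_chain_one_cluster(self):
        a = hit(0, 30, hid="a", tracts=((0, 3), (10, 13), (20, 23), (27, 30)))
        b = hit(10, 40, hid="b", tracts=((10, 13), (20, 23), (27, 30), (37, 40)))
        c = hit(37, 70, hid="c", tracts=((37, 40), (50, 53), (60, 63), (67, 70)))
        clusters = cluster_hits([a, b, c])  # a-b share, b-c share, a-c disjoint
        assert len(clusters) == 1
        assert set(clusters[0].member_ids) == {"a", "b", "c"}

    def test_membership_partition(self):
        hits = [
            hit(i * 100, i * 100 + 30, hid=f"x{i}",
                tracts=tuple((i * 100 + k, i * 100 + k + 3) for k in (0, 9, 18, 27)))
            for i in range(5)
        ]
        clusters = cluster_hits(hits)
        assert sum(len(c.member_ids) for c in clusters) == len(hits)


class TestAnnotateHit:
    def test_promoter_distance_minus_29(self, plus_gene):
        (ann,) = annotate_hit(hit(942, 971), [plus_gene])
        assert ann.segments == frozenset({"promoter"})
        assert ann.distance_from_tss == -29

    def test_exon1_upstream_of_cds_is_5utr(self, plus_gene):
        (ann,) = annotate_hit(hit(1100, 1130), [plus_gene])
        assert {"genic", "exon", "5UTR"} <= ann.segments
        assert "intron" not in ann.segments

    def test_intron_hit(self, plus_gene):
        (ann,) = annotate_hit(hit(2400, 2430), [plus_gene])
        assert {"genic", "intron"} <= ann.segments
        assert "exon" not in ann.segments

    def test_cds_subset_of_exon(self, plus_gene):
        (ann,) = annotate_hit(hit(1600, 1630), [plus_gene])
        assert {"genic", "exon", "CDS"} <= ann.segments

    def test_strand_class(self, plus_gene, minus_gene):
        (ann,) = annotate_hit(hit(1600, 1630, strand="+"), [plus_gene])
        assert ann.strand_class == NON_TEMPLATE
        (ann,) = annotate_hit(hit(12_500, 12_530, strand="+"), [minus_gene])
        assert ann.strand_class == TEMPLATE

    def test_minus_gene_promoter_upstream_right(self, minus_gene):
        (ann,) = annotate_hit(hit(14_029, 14_058), [minus_gene])
        assert ann.segments == frozenset({"promoter"})
        assert ann.distance_from_tss == -29

    def test_malformed_gene_names_transcript(self):
        with pytest.raises(GeneModelError, match="NM_BAD"):
            GeneModel(
                tx_id="NM_BAD", gene_symbol="X", seq_name="chr1", strand="+",
                tx_start=100, tx_end=50, cds_start=0, cds_end=0, exons=(),
            )


class TestTssProfile:
    def test_single_position_spike(self, plus_gene):
        positions, profiles, empty = tss_profile([hit(900, 901)], [plus_gene])
        assert not empty
        arr = profiles[NON_TEMPLATE]
        assert arr[np.where(positions == -100)[0][0]] == pytest.approx(1.0)
        assert arr.sum() == pytest.approx(1.0)

    def test_normalization(self, plus_gene, minus_gene):
        hits = [hit(900, 950), hit(1200, 1260), hit(13_900, 13_950, strand="-")]
        _, profiles, empty = tss_profile(hits, [plus_gene, minus_gene])
        assert not empty
        for arr in profiles.values():
            if arr.sum():
                assert arr.sum() == pytest.approx(1.0)

    def test_translation_invariance(self, plus_gene):
        hits = [hit(900, 950), hit(1100, 1180)]
        shift = 10_000
        shifted_gene = GeneModel(
            tx_id="NM_1", gene_symbol="GENE1", seq_name="chr1", strand="+",
            tx_start=plus_gene.tx_start + shift, tx_end=plus_gene.tx_end + shift,
            cds_start=plus_gene.cds_start + shift, cds_end=plus_gene.cds_end + shift,
            exons=tuple((s + shift, e + shift) for s, e in plus_gene.exons),
        )
        shifted_hits = [hit(h.span[0] + shift, h.span[1] + shift) for h in hits]
        _, p1, _ = tss_profile(hits, [plus_gene])
        _, p2, _ = tss_profile(shifted_hits, [shifted_gene])
        for cls in p1:
            assert np.allclose(p1[cls], p2[cls])

    def test_no_hits_flagged_empty(self, plus_gene):
        _, profiles, empty = tss_profile([hit(50_000, 50_030)], [plus_gene])
        assert empty
        assert all(arr.sum() == 0 for arr in profiles.values())


class TestIntersectTrack:
    def test_one_nt_overlap_flags(self):
        assert intersect_track([hit(10, 20)], [("chr1", 19, 30)]) == [True]

    def test_half_open_adjacency_does_not_flag(self):
        assert intersect_track([hit(10, 20)], [("chr1", 20, 30)]) == [False]

    def test_containment_flags_and_unsorted_ok(self):
        track = [("chr1", 500, 600), ("chr1", 5, 50)]
        assert intersect_track([hit(10, 20)], track) == [True]


class TestCountsPerGene:
    def test_histogram(self, plus_gene, minus_gene):
        gene3 = GeneModel(
            tx_id="NM_3", gene_symbol="GENE3", seq_name="chr1", strand="+",
            tx_start=20_000, tx_end=22_000, cds_start=20_100, cds_end=21_900,
            exons=((20_000, 22_000),),
        )
        hits = [
            hit(1500, 1530, hid="a"),
            hit(12_100, 12_130, hid="b"),
            hit(20_100, 20_130, hid="c"),
            hit(21_000, 21_030, hid="d"),
        ]
        anns = annotate_hits(hits, [plus_gene, minus_gene, gene3])
        assert counts_per_gene(anns) == {1: 2, 2: 1}

    def test_multi_transcript_dedup(self, plus_gene):
        iso = GeneModel(
            tx_id="NM_1b", gene_symbol="GENE1", seq_name="chr1", strand="+",
            tx_start=900, tx_end=5000, cds_start=1500, cds_end=4500,
            exons=((900, 2000), (3000, 5000)),
        )
        anns = annotate_hits([hit(1500, 1530, hid="a")], [plus_gene, iso])
        assert len(anns) == 2  # one per transcript
        assert counts_per_gene(anns) == {1: 1}


class TestGeneModelIO:
    def test_refgene_round_trip(self, tmp_path, plus_gene, minus_gene):
        p = tmp_path / "genes.txt"
        write_refgene([plus_gene, minus_gene], p)
        back = read_refgene(p)
        assert [(g.tx_id, g.strand, g.exons) for g in back] == [
            (g.tx_id, g.strand, g.exons) for g in (plus_gene, minus_gene)
        ]

    def test_bed12(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text(
            "chr1\t1000\t5000\tNM_9\t0\t+\t1500\t4500\t0\t2\t1000,2000,\t0,2000,\n"
        )
        (g,) = read_bed12(p)
        assert g.exons == ((1000, 2000), (3000, 5000))
        assert (g.cds_start, g.cds_end) == (1500, 4500)
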