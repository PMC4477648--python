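"""Gene-model annotation, clustering, TSS profiles and track intersection.

Segment vocabulary: a hit is *genic* if it overlaps the transcript interval
by >= 1 nt, *promoter* if it overlaps the 2-kb window upstream of the TSS in
gene orientation, and exon / intron / CDS / 5'-UTR / 3'-UTR by interval
algebra on the transcript's exon and CDS structure.  A hit is *non-template*
when its G-tracts lie on the gene's sense strand (hit strand equals gene
strand), template otherwise.  Distances from the TSS use the hit boundary
nearest the TSS, signed negative upstream in gene orientation.

Gene models come from UCSC refGene flat files (with or without the leading
bin column) or BED12.  Track intersection is the ">= 1-nt overlap"
rule on half-open intervals.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np
from intervaltree import IntervalTree

__all__ = [
    "GeneModel",
    "GeneModelError",
    "HitAnnotation",
    "Cluster",
    "read_refgene",
    "write_refgene",
    "read_bed12",
    "read_bed",
    "cluster_hits",
    "annotate_hit",
    "annotate_hits",
    "tss_profile",
    "intersect_track",
    "counts_per_gene",
    "NON_TEMPLATE",
    "TEMPLATE",
]

NON_TEMPLATE = "non-template"
TEMPLATE = "template"

SEGMENTS = ("genic", "promoter", "exon", "CDS", "intron", "5UTR", "3UTR")


class GeneModelError(ValueError):
    pass


@dataclass(frozen=True)
class GeneModel:
    """One transcript: strand, TSS, CDS and exon structure (0-based half-open)."""

    tx_id: str
    gene_symbol: str
    seq_name: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        try:
            self.validate()
        except AssertionError as exc:
            raise GeneModelError(f"malformed gene model {self.tx_id}: {exc}") from None

    def validate(self) -> None:
        assert self.strand in "+-", "strand must be + or -"
        assert self.tx_start < self.tx_end, "empty transcript interval"
        prev_end = self.tx_start - 1
        for s, e in self.exons:
            assert s < e, "empty exon"
            assert s >= self.tx_start and e <= self.tx_end, "exon outside transcript"
            assert s > prev_end or s == self.tx_start, "exons unsorted or overlapping"
            assert s >= prev_end, "exons overlap"
            prev_end = e
        if self.cds_start < self.cds_end:  # coding
            assert self.cds_start >= self.tx_start and self.cds_end <= self.tx_end, \
                "CDS outside transcript"

    @property
    def coding(self) -> bool:
        return self.cds_start < self.cds_end

    @property
    def tss(self) -> int:
        """TSS boundary coordinate: tx_start for + genes, tx_end for - genes."""
        return self.tx_start if self.strand == "+" else self.tx_end

    def promoter_interval(self, promoter_len: int = 2000) -> tuple[int, int]:
        if self.strand == "+":
            return (self.tx_start - promoter_len, self.tx_start)
        return (self.tx_end, self.tx_end + promoter_len)


@dataclass(frozen=True)
class HitAnnotation:
    hit_id: str
    tx_id: str
    gene_symbol: str
    segments: frozenset[str]
    strand_class: str
    distance_from_tss: int | None  # None when the hit is outside the +-2 kb context
    regulatory: bool = False


@dataclass(frozen=True)
class Cluster:
    cluster_id: int
    member_ids: tuple[str, ...]
    span: tuple[int, int]
    strand: str


# ---------------------------------------------------------------- gene models

def _parse_block_list(text: str) -> tuple[int, ...]:
    return tuple(int(x) for x in text.rstrip(",").split(",") if x)


def read_refgene(path) -> list[GeneModel]:
    """Parse a UCSC refGene flat file (tab-separated, optional leading bin)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            # with bin: bin name chrom strand ... ; without: name chrom strand ...
            if f[2] in ("+", "-"):
                off = 0
            elif len(f) > 3 and f[3] in ("+", "-"):
                off = 1
            else:
                raise GeneModelError(f"{path}: cannot locate strand column in refGene line")
            name, chrom, strand = f[off], f[off + 1], f[off + 2]
            tx_start, tx_end, cds_start, cds_end = (int(x) for x in f[off + 3: off + 7])
            starts = _parse_block_list(f[off + 8])
            ends = _parse_block_list(f[off + 9])
            symbol = f[off + 11] if len(f) > off + 11 else name
            genes.append(
                GeneModel(
                    tx_id=name, gene_symbol=symbol, seq_name=chrom, strand=strand,
                    tx_start=tx_start, tx_end=tx_end,
                    cds_start=cds_start, cds_end=cds_end,
                    exons=tuple(zip(starts, ends)),
                )
            )
    return genes


def write_refgene(genes, path) -> None:
    """Write gene models in refGene flat format (with bin column)."""
    with open(path, "w") as fh:
        for g in genes:
            starts = ",".join(str(s) for s, _ in g.exons) + ","
            ends = ",".join(str(e) for _, e in g.exons) + ","
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        0, g.tx_id, g.seq_name, g.strand, g.tx_start, g.tx_end,
                        g.cds_start, g.cds_end, len(g.exons), starts, ends,
                        0, g.gene_symbol, "unk", "unk",
                        ",".join("-1" for _ in g.exons) + ",",
                    )
                )
                + "\n"
            )


def read_bed12(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            sizes = _parse_block_list(f[10])
            offsets = _parse_block_list(f[11])
            exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
            genes.append(
                GeneModel(
                    tx_id=name, gene_symbol=name, seq_name=chrom, strand=strand,
                    tx_start=start, tx_end=end,
                    cds_start=thick_start, cds_end=thick_end, exons=exons,
                )
            )
    return genes


def read_bed(path) -> list[tuple[str, int, int]]:
    """Plain BED3+ interval reader (chrom, start, end)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


# ----------------------------------------------------------------- clustering

def _hit_id(hit, index: int) -> str:
    return hit.id or f"{hit.seq_name}:{hit.span[0]}-{hit.span[1]}({hit.strand})#{index}"


def cluster_hits(hits, by_class: bool = True) -> list[Cluster]:
    """Connected components of same-strand hits sharing >= 1 identical tract.

    An edge joins two hits with a tract at identical coordinates on the same
    strand of the same sequence; components are the transitive closure.  By
    default clustering is additionally per class label.
    """
    hits = list(hits)
    n = len(hits)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    tract_owner: dict[tuple, int] = {}
    for i, h in enumerate(hits):
        group = (h.seq_name, h.strand, h.class_label if by_class else None)
        for t in h.tracts:
            key = (group, t)
            if key in tract_owner:
                union(i, tract_owner[key])
            else:
                tract_owner[key] = i

    members: dict[int, list[int]] = defaultdict(list)
    for i in range(n):
        members[find(i)].append(i)
    clusters = []
    for cid, (_, idxs) in enumerate(sorted(members.items())):
        spans = [hits[i].span for i in idxs]
        clusters.append(
            Cluster(
                cluster_id=cid,
                member_ids=tuple(_hit_id(hits[i], i) for i in idxs),
                span=(min(s for s, _ in spans), max(e for _, e in spans)),
                strand=hits[idxs[0]].strand,
            )
        )
    return clusters


# ----------------------------------------------------------------- annotation

def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _tss_distance(hit_span, gene: GeneModel) -> int:
    """Signed distance (negative upstream, in gene orientation) of the hit
    boundary nearest the TSS; 0 if the hit covers the TSS."""
    s, e = hit_span
    if gene.strand == "+":
        u1, u2 = s - gene.tx_start, e - gene.tx_start
    else:
        u1, u2 = gene.tx_end - e, gene.tx_end - s
    if u2 <= 0:
        return u2
    if u1 > 0:
        return u1
    return 0


def _segments_for(hit_span, gene: GeneModel, promoter_len: int) -> frozenset[str]:
    segs = set()
    if _overlap(hit_span, (gene.tx_start, gene.tx_end)):
        segs.add("genic")
    if _overlap(hit_span, gene.promoter_interval(promoter_len)):
        segs.add("promoter")
    if "genic" in segs:
        in_exon = any(_overlap(hit_span, ex) for ex in gene.exons)
        if in_exon:
            segs.add("exon")
        # introns: genic gaps between exons
        prev = None
        for s, e in gene.exons:
            if prev is not None and _overlap(hit_span, (prev, s)):
                segs.add("intron")
            prev = e
        if gene.coding and in_exon:
            cds = (gene.cds_start, gene.cds_end)
            for ex_s, ex_e in gene.exons:
                seg_s, seg_e = max(ex_s, cds[0]), min(ex_e, cds[1])
                if seg_s < seg_e and _overlap(hit_span, (seg_s, seg_e)):
                    segs.add("CDS")
                # exonic sequence outside the CDS is UTR; 5' vs 3' by orientation
                for utr in ((ex_s, min(ex_e, cds[0])), (max(ex_s, cds[1]), ex_e)):
                    if utr[0] < utr[1] and _overlap(hit_span, utr):
                        upstream_of_cds = utr[1] <= cds[0]
                        five = upstream_of_cds if gene.strand == "+" else not upstream_of_cds
                        segs.add("5UTR" if five else "3UTR")
    return frozenset(segs)


def annotate_hit(hit, genes, promoter_len: int = 2000, hit_id: str | None = None) -> list[HitAnnotation]:
    """One annotation per transcript the hit touches (genic or promoter)."""
    out = []
    hid = hit_id if hit_id is not None else _hit_id(hit, 0)
    for gene in genes:
        if gene.seq_name != hit.seq_name:
            continue
        segs = _segments_for(hit.span, gene, promoter_len)
        if not segs:
            continue
        out.append(
            HitAnnotation(
                hit_id=hid,
                tx_id=gene.tx_id,
                gene_symbol=gene.gene_symbol,
                segments=segs,
                strand_class=NON_TEMPLATE if hit.strand == gene.strand else TEMPLATE,
                distance_from_tss=_tss_distance(hit.span, gene),
            )
        )
    return out


def annotate_hits(hits, genes, promoter_len: int = 2000) -> list[HitAnnotation]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    gene_list = list(genes)
    for gi, g in enumerate(gene_list):
        lo = min(g.tx_start, g.promoter_interval(promoter_len)[0])
        hi = max(g.tx_end, g.promoter_interval(promoter_len)[1])
        trees[g.seq_name].addi(lo, hi, gi)
    out = []
    for i, hit in enumerate(hits):
        tree = trees.get(hit.seq_name)
        if tree is None:
            continue
        touched = sorted(iv.data for iv in tree.overlap(hit.span[0], hit.span[1]))
        out.extend(
            annotate_hit(hit, [gene_list[gi] for gi in touched], promoter_len,
                         hit_id=_hit_id(hit, i))
        )
    return out


# ---------------------------------------------------------------- TSS profile

def tss_profile(hits, genes, window: int = 2000):
    """Positional frequency of hit coverage around the TSS per strand class.

    For every transcript, positions -window..+window relative to the TSS (in
    gene orientation) covered by a hit are counted, separately for
    non-template and template hits; each profile is normalized to sum to 1.
    Returns (positions, {strand_class: profile}, empty_flag).
    """
    size = 2 * window + 1
    positions = np.arange(-window, window + 1)
    raw = {NON_TEMPLATE: np.zeros(size), TEMPLATE: np.zeros(size)}
    gene_list = list(genes)
    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for g in gene_list:
        by_chrom[g.seq_name].append(g)
    for hit in hits:
        s, e = hit.span
        for g in by_chrom.get(hit.seq_name, ()):
            if g.strand == "+":
                rel_lo, rel_hi = s - g.tx_start, e - g.tx_start
            else:
                rel_lo, rel_hi = g.tx_end - e, g.tx_end - s
            lo = max(rel_lo, -window)
            hi = min(rel_hi, window + 1)
            if lo >= hi:
                continue
            cls = NON_TEMPLATE if hit.strand == g.strand else TEMPLATE
            raw[cls][lo + window: hi + window] += 1
    profiles = {}
    empty = True
    for cls, arr in raw.items():
        total = arr.sum()
        if total > 0:
            empty = False
            profiles[cls] = arr / total
        else:
            profiles[cls] = arr
    return positions, profiles, empty


# ----------------------------------------------------------- track intersect

def intersect_track(hits, track) -> list[bool]:
    """Flag each hit that overlaps >= 1 track interval by >= 1 nt.

    `track` is an iterable of (chrom, start, end); sorting is not required.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for chrom, s, e in track:
        if s < e:
            trees[chrom].addi(s, e)
    flags = []
    for hit in hits:
        tree = trees.get(hit.seq_name)
        flags.append(bool(tree and tree.overlap(hit.span[0], hit.span[1])))
    return flags


# ------------------------------------------------------------ per-gene counts

def counts_per_gene(annotations, segments: frozenset[str] | set[str] = frozenset({"genic", "promoter"})):
    """Histogram {m: number of genes with m distinct hits} for the segment filter.

    A gene symbol overlapped by the same hit through several transcripts
    counts that hit once.
    """
    per_gene: dict[str, set[str]] = defaultdict(set)
    segments = frozenset(segments)
    for ann in annotations:
        if ann.segments & segments:
            per_gene[ann.gene_symbol].add(ann.hit_id)
    return dict(Counter(len(v) for v in per_gene.values()))
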