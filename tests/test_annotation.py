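"""Annotation parsing, exon-bin flattening, promoters and BED round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicemeth.annotation import (
    AnnotationError,
    GeneModel,
    GenomicInterval,
    flatten_gene,
    promoter_of,
    read_bed,
    read_gtf,
    write_bed,
    write_gtf,
)
from conftest import random_gene_model

GTF_ONE_GENE = """\
chr1\tsrc\tgene\t100\t400\t.\t+\t.\tgene_id "G1"; gene_name "ALPHA";
chr1\tsrc\ttranscript\t100\t400\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
chr1\tsrc\texon\t100\t200\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
chr1\tsrc\texon\t300\t400\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
"""

GFF3_ONE_GENE = """\
chr1\tsrc\tgene\t100\t400\t.\t+\t.\tID=G1;Name=ALPHA
chr1\tsrc\tmRNA\t100\t400\t.\t+\t.\tID=T1;Parent=G1
chr1\tsrc\texon\t100\t200\t.\t+\t.\tID=E1;Parent=T1
chr1\tsrc\texon\t300\t400\t.\t+\t.\tID=E2;Parent=T1
"""


def exon_membership(gene: GeneModel) -> set[int]:
    """Per-base oracle: every position covered by any transcript exon."""
    bases = set()
    for exons in gene.transcripts.values():
        for e in exons:
            bases.update(range(e.start, e.end + 1))
    return bases


def test_read_gtf_one_gene(tmp_path):
    p = tmp_path / "a.gtf"
    p.write_text(GTF_ONE_GENE)
    genes = read_gtf(str(p))
    assert list(genes) == ["G1"]
    g = genes["G1"]
    assert g.gene_name == "ALPHA"
    assert list(g.transcripts) == ["T1"]
    assert [(e.start, e.end) for e in g.transcripts["T1"]] == [(100, 200), (300, 400)]


def test_gff3_dialect_equivalent(tmp_path):
    p1 = tmp_path / "a.gtf"
    p1.write_text(GTF_ONE_GENE)
    p2 = tmp_path / "a.gff3"
    p2.write_text(GFF3_ONE_GENE)
    g1 = read_gtf(str(p1))["G1"]
    g2 = read_gtf(str(p2))["G1"]
    assert [(e.start, e.end) for e in g1.transcripts["T1"]] == [
        (e.start, e.end) for e in g2.transcripts["T1"]
    ]
    assert (g1.chrom, g1.strand) == (g2.chrom, g2.strand)


def test_two_transcripts_share_exon(tmp_path):
    extra = (
        'chr1\tsrc\texon\t100\t200\t.\t+\t.\tgene_id "G1"; transcript_id "T2";\n'
    )
    p = tmp_path / "b.gtf"
    p.write_text(GTF_ONE_GENE + extra)
    genes = read_gtf(str(p))
    assert len(genes) == 1
    assert set(genes["G1"].transcripts) == {"T1", "T2"}


def test_malformed_attribute_column_names_line(tmp_path):
    p = tmp_path / "bad.gtf"
    p.write_text("chr1\tsrc\texon\t1\t10\t.\t+\t.\tnot an attribute column\n")
    with pytest.raises(AnnotationError, match="line 1"):
        read_gtf(str(p))


def test_mixed_strand_transcript_rejected(tmp_path):
    lines = GTF_ONE_GENE + (
        'chr1\tsrc\texon\t500\t600\t.\t-\t.\tgene_id "G1"; transcript_id "T1";\n'
    )
    p = tmp_path / "mix.gtf"
    p.write_text(lines)
    with pytest.raises(AnnotationError, match="strand"):
        read_gtf(str(p))


def test_write_gtf_round_trip(tmp_path, small_dataset):
    genes = small_dataset["genes"]
    p = tmp_path / "out.gtf"
    write_gtf(genes, str(p))
    back = read_gtf(str(p))
    assert set(back) == set(genes)
    gid = sorted(genes)[0]
    assert {
        t: [(e.start, e.end) for e in ex] for t, ex in back[gid].transcripts.items()
    } == {
        t: [(e.start, e.end) for e in ex] for t, ex in genes[gid].transcripts.items()
    }


# ---------------------------------------------------------------------------
# flattening


def _mk(gene_id, strand, tx):
    transcripts = {
        tid: [GenomicInterval("chr1", s, e, strand) for s, e in exons]
        for tid, exons in tx.items()
    }
    return GeneModel(gene_id, "chr1", strand, transcripts)


def test_flatten_boundary_cutting():
    # overlapping transcripts are cut at every exon boundary
    g = _mk("G1", "+", {"t1": [(100, 200)], "t2": [(100, 150), (180, 200)]})
    fl = flatten_gene(g)
    assert [(iv.start, iv.end) for _, iv in fl.bins] == [
        (100, 150), (151, 179), (180, 200),
    ]
    assert [bid for bid, _ in fl.bins] == ["E001", "E002", "E003"]
    assert fl.introns == []  # bins are adjacent, no gaps


def test_flatten_minus_strand_ids_count_5prime_to_3prime():
    g = _mk("G1", "-", {"t1": [(100, 150), (300, 350)]})
    fl = flatten_gene(g)
    assert [(bid, iv.start, iv.end) for bid, iv in fl.bins] == [
        ("E001", 300, 350), ("E002", 100, 150),
    ]
    assert len(fl.introns) == 1
    intron = fl.introns[0]
    assert (intron.intron_id, intron.interval.start, intron.interval.end) == (
        "I001", 151, 299,
    )
    assert (intron.upstream_bin, intron.downstream_bin) == ("E001", "E002")


def test_flatten_single_exon_gene():
    g = _mk("G1", "+", {"t1": [(5000, 5100)]})
    fl = flatten_gene(g)
    assert len(fl.bins) == 1 and fl.introns == []
    assert (fl.promoter.start, fl.promoter.end) == (2000, 4999)
    assert len(fl.promoter) == 3000


def test_flatten_matches_per_base_oracle():
    rng = np.random.default_rng(123)
    for _ in range(60):
        g = random_gene_model(rng)
        fl = flatten_gene(g)
        bin_bases = set()
        for _bid, iv in fl.bins:
            seg = set(range(iv.start, iv.end + 1))
            assert not (bin_bases & seg), "bins overlap"
            bin_bases |= seg
        assert bin_bases == exon_membership(g)
        # ids unique, intervals monotone in transcription direction
        ids = [bid for bid, _ in fl.bins]
        assert len(set(ids)) == len(ids)
        starts = [iv.start for _, iv in fl.bins]
        assert starts == sorted(starts, reverse=(g.strand == "-"))


@settings(derandomize=True, deadline=None, max_examples=60)
@given(
    strand=st.sampled_from("+-"),
    skeleton=st.lists(
        st.tuples(st.integers(1, 50), st.integers(1, 60)),  # (gap, length)
        min_size=1, max_size=6,
    ),
    drops=st.lists(st.booleans(), min_size=0, max_size=12),
)
def test_flatten_partition_property(strand, skeleton, drops):
    # bins always partition the exonic union, whatever the transcript mix
    pos = 100
    exons = []
    for gap, length in skeleton:
        pos += gap
        exons.append((pos, pos + length - 1))
        pos += length
    tx = {"t1": exons}
    kept = [e for e, d in zip(exons, drops + [False] * len(exons)) if not d]
    if kept:
        tx["t2"] = kept
    g = _mk("G1", strand, tx)
    fl = flatten_gene(g)
    bases = set()
    for _bid, iv in fl.bins:
        seg = set(range(iv.start, iv.end + 1))
        assert not (bases & seg)
        bases |= seg
    assert bases == exon_membership(g)
    # introns exactly fill the gaps between bins
    intron_bases = set()
    for intr in fl.introns:
        intron_bases |= set(range(intr.interval.start, intr.interval.end + 1))
    span = set(range(min(bases), max(bases) + 1))
    assert intron_bases == span - bases


# ---------------------------------------------------------------------------
# promoters


@pytest.mark.parametrize(
    "strand,tss_exon,expected",
    [
        ("+", (5000, 5100), (2000, 4999)),
        ("-", (4900, 5000), (5001, 8000)),
        ("+", (100, 200), (1, 99)),  # clipped at chromosome start
    ],
)
def test_promoter_window(strand, tss_exon, expected):
    g = _mk("G1", strand, {"t1": [tss_exon]})
    prom = promoter_of(g)
    assert (prom.start, prom.end) == expected


def test_promoter_length_property():
    rng = np.random.default_rng(99)
    for _ in range(40):
        g = random_gene_model(rng)
        prom = promoter_of(g)
        if prom is None:
            continue
        assert len(prom) <= 3000
        if g.strand == "-" or g.tss > 3000:
            assert len(prom) == 3000


def test_promoter_uses_five_prime_most_tss():
    g = _mk("G1", "+", {"t1": [(5000, 5100)], "t2": [(4500, 4600)]})
    assert promoter_of(g).end == 4499


# ---------------------------------------------------------------------------
# BED


def test_bed_round_trip(tmp_path):
    feats = [
        ("f1", GenomicInterval("chr1", 100, 150, "+")),
        ("f2", GenomicInterval("chr2", 1, 10, "-")),
    ]
    p = tmp_path / "x.bed"
    write_bed(feats, str(p))
    lines = p.read_text().splitlines()
    assert lines[0].split("\t")[1:3] == ["99", "150"]
    assert read_bed(str(p)) == feats


def test_flattened_gff3_carries_feature_ids(tmp_path):
    from splicemeth.annotation import write_flattened_gff3

    g = _mk("G1", "+", {"t1": [(100, 150), (300, 350)]})
    fl = flatten_gene(g)
    p = tmp_path / "flat.gff3"
    write_flattened_gff3({"G1": fl}, str(p))
    lines = [l for l in p.read_text().splitlines() if not l.startswith("#")]
    types = [l.split("\t")[2] for l in lines]
    assert types.count("exonic_part") == 2
    assert types.count("intron") == 1
    assert types.count("promoter") == 1
    assert any("feature_id=E001" in l for l in lines)


def test_bed_empty(tmp_path):
    p = tmp_path / "e.bed"
    write_bed([], str(p))
    assert p.read_text() == ""
    assert read_bed(str(p)) == []
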