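"""Gene annotation handling: GTF/GFF3 parsing, exon-bin flattening, promoters.

Coordinates are 1-based inclusive throughout (GTF convention); only BED
output converts to 0-based half-open. Genes are flattened independently of
one another: the union of a gene's transcript exons is cut at every distinct
exon boundary across its transcripts, producing disjoint counting bins
labelled ``E001``, ``E002``, ... counted 5'->3' on the gene's strand.
Maximal gaps between consecutive bins are introns ``I001``, ... (also
5'->3'), and the promoter is the window (default 3 kb) immediately upstream
of the gene's 5'-most transcription start site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gffutils

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "Intron",
    "FlattenedGene",
    "AnnotationError",
    "read_gtf",
    "flatten_gene",
    "promoter_of",
    "write_bed",
    "read_bed",
    "write_gtf",
    "write_flattened_gff3",
]

PROMOTER_WINDOW = 3000


class AnnotationError(ValueError):
    """Raised for malformed annotation input or invalid gene structure."""


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise AnnotationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class GeneModel:
    """A gene with its transcripts, each an ordered list of exon intervals."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: dict[str, list[GenomicInterval]]
    gene_name: str | None = None

    def validate(self) -> None:
        if not self.transcripts:
            raise AnnotationError(f"gene {self.gene_id} has no transcripts")
        for tid, exons in self.transcripts.items():
            if not exons:
                raise AnnotationError(f"transcript {tid} has no exons")
            for e in exons:
                if e.chrom != self.chrom or e.strand != self.strand:
                    raise AnnotationError(
                        f"transcript {tid} mixes chrom/strand within gene "
                        f"{self.gene_id}"
                    )
            for a, b in zip(exons, exons[1:]):
                if b.start <= a.end:
                    raise AnnotationError(
                        f"transcript {tid} has unsorted or overlapping exons"
                    )

    @property
    def span(self) -> GenomicInterval:
        starts = [e.start for exs in self.transcripts.values() for e in exs]
        ends = [e.end for exs in self.transcripts.values() for e in exs]
        return GenomicInterval(self.chrom, min(starts), max(ends), self.strand)

    @property
    def tss(self) -> int:
        """5'-most transcription start site across transcripts."""
        if self.strand == "+":
            return min(exs[0].start for exs in self.transcripts.values())
        return max(exs[-1].end for exs in self.transcripts.values())


@dataclass(frozen=True)
class Intron:
    intron_id: str
    interval: GenomicInterval
    # flanking bin ids in 5'->3' order (upstream, downstream)
    upstream_bin: str
    downstream_bin: str


@dataclass
class FlattenedGene:
    gene_id: str
    chrom: str
    strand: str
    bins: list[tuple[str, GenomicInterval]]  # 5'->3' order
    introns: list[Intron] = field(default_factory=list)  # 5'->3' order
    promoter: GenomicInterval | None = None
    gene_name: str | None = None

    def bin_interval(self, bin_id: str) -> GenomicInterval:
        for bid, iv in self.bins:
            if bid == bin_id:
                return iv
        raise KeyError(bin_id)


def _interval_union(intervals: list[GenomicInterval]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for iv in sorted(intervals, key=lambda i: (i.start, i.end)):
        if merged and iv.start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], iv.end))
        else:
            merged.append((iv.start, iv.end))
    return merged


def flatten_gene(g: GeneModel, promoter_window: int = PROMOTER_WINDOW) -> FlattenedGene:
    """Cut the union of a gene's exons at every exon boundary into disjoint bins.

    Bin ids ``E001...`` increase in transcription direction (reversed genomic
    order on the minus strand); introns are the maximal gaps between
    genomically consecutive bins and carry their flanking bin ids.
    """
    g.validate()
    all_exons = [e for exs in g.transcripts.values() for e in exs]
    union = _interval_union(all_exons)
    # boundary cut points: each exon start opens a segment, each exon end closes one
    starts = {e.start for e in all_exons}
    ends = {e.end for e in all_exons}
    bins_genomic: list[GenomicInterval] = []
    for lo, hi in union:
        cuts = sorted(
            {lo}
            | {s for s in starts if lo < s <= hi}
            | {e + 1 for e in ends if lo <= e < hi}
        )
        for a, b in zip(cuts, cuts[1:] + [hi + 1]):
            bins_genomic.append(GenomicInterval(g.chrom, a, b - 1, g.strand))

    ordered = bins_genomic if g.strand == "+" else bins_genomic[::-1]
    bins = [(f"E{i + 1:03d}", iv) for i, iv in enumerate(ordered)]

    introns: list[Intron] = []
    n_introns = 0
    for (up_id, up_iv), (dn_id, dn_iv) in zip(bins, bins[1:]):
        if g.strand == "+":
            gap_lo, gap_hi = up_iv.end + 1, dn_iv.start - 1
        else:
            gap_lo, gap_hi = dn_iv.end + 1, up_iv.start - 1
        if gap_lo <= gap_hi:
            n_introns += 1
            introns.append(
                Intron(
                    f"I{n_introns:03d}",
                    GenomicInterval(g.chrom, gap_lo, gap_hi, g.strand),
                    up_id,
                    dn_id,
                )
            )

    return FlattenedGene(
        gene_id=g.gene_id,
        chrom=g.chrom,
        strand=g.strand,
        bins=bins,
        introns=introns,
        promoter=promoter_of(g, promoter_window),
        gene_name=g.gene_name,
    )


def promoter_of(g: GeneModel, window: int = PROMOTER_WINDOW) -> GenomicInterval | None:
    """Window immediately upstream of the gene's 5'-most TSS, clipped at 1.

    Returns None when a plus-strand TSS sits at position 1 (no upstream base).
    """
    tss = g.tss
    if g.strand == "+":
        lo, hi = max(1, tss - window), tss - 1
        if hi < lo:
            return None
        return GenomicInterval(g.chrom, lo, hi, "+")
    return GenomicInterval(g.chrom, tss + 1, tss + window, "-")


# ---------------------------------------------------------------------------
# GTF / GFF3 reading

_TRANSCRIPT_TYPES = {"transcript", "mRNA"}


def _prescan(path: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            attrs = fields[8]
            if "=" not in attrs and '"' not in attrs and attrs.strip() != ".":
                raise AnnotationError(
                    f"{path}: line {lineno}: malformed attribute column: {attrs!r}"
                )


def _first(attrs, *keys) -> str | None:
    for k in keys:
        if k in attrs:
            v = attrs[k]
            return v[0] if isinstance(v, list) else v
    return None


def read_gtf(path: str) -> dict[str, GeneModel]:
    """Parse a GTF or GFF3 file into GeneModels keyed by gene_id.

    Both dialects are accepted; exons are grouped by transcript and sorted.
    Records on unplaced contigs are retained. Raises :class:`AnnotationError`
    with a line number for malformed attribute columns and for transcripts
    whose exons mix strands.
    """
    _prescan(path)
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    # transcript -> gene map and gene names from parent features (GFF3)
    tx2gene: dict[str, str] = {}
    gene_names: dict[str, str] = {}
    for ftype in _TRANSCRIPT_TYPES:
        for f in db.features_of_type(ftype):
            tid = _first(f.attributes, "transcript_id", "ID") or f.id
            gid = _first(f.attributes, "gene_id", "Parent")
            if gid:
                tx2gene[tid] = gid
    for f in db.features_of_type("gene"):
        gid = _first(f.attributes, "gene_id", "ID") or f.id
        name = _first(f.attributes, "gene_name", "Name")
        if name:
            gene_names[gid] = name

    genes: dict[str, GeneModel] = {}
    for ex in db.features_of_type("exon"):
        tid = _first(ex.attributes, "transcript_id", "Parent")
        if tid is None:
            raise AnnotationError(f"exon without transcript_id/Parent at {ex.seqid}:{ex.start}")
        gid = _first(ex.attributes, "gene_id") or tx2gene.get(tid)
        if gid is None:
            raise AnnotationError(f"cannot resolve gene for transcript {tid}")
        name = _first(ex.attributes, "gene_name") or gene_names.get(gid)
        iv = GenomicInterval(ex.seqid, ex.start, ex.end, ex.strand)
        if gid not in genes:
            genes[gid] = GeneModel(gid, ex.seqid, ex.strand, {}, gene_name=name)
        gm = genes[gid]
        if gm.gene_name is None and name:
            gm.gene_name = name
        if iv.strand != gm.strand:
            raise AnnotationError(
                f"transcript {tid} of gene {gid} has exons on mixed strands"
            )
        gm.transcripts.setdefault(tid, []).append(iv)

    for gm in genes.values():
        for tid in gm.transcripts:
            gm.transcripts[tid].sort(key=lambda e: e.start)
        gm.validate()
    return genes


def write_gtf(genes: dict[str, GeneModel] | list[GeneModel], path: str) -> None:
    """Write GeneModels as GTF (gene/transcript/exon features)."""
    if isinstance(genes, dict):
        genes = list(genes.values())
    with open(path, "w") as fh:
        for g in genes:
            sp = g.span
            name = f' gene_name "{g.gene_name}";' if g.gene_name else ""
            fh.write(
                f"{g.chrom}\tsplicemeth\tgene\t{sp.start}\t{sp.end}\t.\t"
                f'{g.strand}\t.\tgene_id "{g.gene_id}";{name}\n'
            )
            for tid, exons in g.transcripts.items():
                fh.write(
                    f"{g.chrom}\tsplicemeth\ttranscript\t{exons[0].start}\t"
                    f'{exons[-1].end}\t.\t{g.strand}\t.\tgene_id "{g.gene_id}"; '
                    f'transcript_id "{tid}";{name}\n'
                )
                for e in exons:
                    fh.write(
                        f"{g.chrom}\tsplicemeth\texon\t{e.start}\t{e.end}\t.\t"
                        f'{g.strand}\t.\tgene_id "{g.gene_id}"; '
                        f'transcript_id "{tid}";{name}\n'
                    )


def write_flattened_gff3(flat_genes, path: str) -> None:
    """Write flattened genes as GFF3: exon bins, introns and promoters with
    their ids in the attribute column."""
    items = flat_genes.values() if isinstance(flat_genes, dict) else flat_genes
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for fl in items:
            rows = [("exonic_part", bid, iv) for bid, iv in fl.bins]
            rows += [("intron", i.intron_id, i.interval) for i in fl.introns]
            if fl.promoter is not None:
                rows.append(("promoter", "P001", fl.promoter))
            for ftype, fid, iv in sorted(rows, key=lambda r: r[2].start):
                fh.write(
                    f"{fl.chrom}\tsplicemeth\t{ftype}\t{iv.start}\t{iv.end}\t.\t"
                    f"{fl.strand}\t.\tID={fl.gene_id}:{fid};gene_id={fl.gene_id};"
                    f"feature_id={fid}\n"
                )


# ---------------------------------------------------------------------------
# BED6

def write_bed(features: list[tuple[str, GenomicInterval]], path: str) -> None:
    """Write (name, interval) pairs as BED6 (0-based half-open)."""
    with open(path, "w") as fh:
        for name, iv in features:
            fh.write(
                f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{name}\t0\t{iv.strand}\n"
            )


def read_bed(path: str) -> list[tuple[str, GenomicInterval]]:
    out: list[tuple[str, GenomicInterval]] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, name, _score, strand = line.rstrip("\n").split("\t")[:6]
            out.append((name, GenomicInterval(chrom, int(start) + 1, int(end), strand)))
    return out
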