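"""Coordinate types, gene models and file I/O shared by every pipeline stage.

Internal coordinates are 0-based half-open throughout; GFF3/GTF (1-based
inclusive) and VCF positions (1-based) are converted at the boundary, so no
other module ever sees file-convention coordinates.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from gffutils.feature import feature_from_line
from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")


class ParseError(ValueError):
    """A malformed record in an input file; message names the line number."""


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A half-open genomic interval [start, end) on ``chrom``.

    ``strand`` is '+', '-' or '.' (unstranded). Zero-length intervals are
    rejected; the empty sentinel is ``None`` where an operation can produce
    nothing (see :func:`flank`).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


def overlap_length(a: GenomeInterval, b: GenomeInterval) -> int:
    """Number of bases shared by two intervals (0 if different chroms)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def flank(
    region: GenomeInterval,
    size: int,
    side: str,
    chrom_length: int | None = None,
) -> GenomeInterval | None:
    """Strand-aware flanking interval of ``region``.

    ``side`` is '5prime' or '3prime'; for a + strand (or unstranded) region the
    5' flank lies upstream of ``start``. The result is clipped at 0 and at
    ``chrom_length`` when given; a flank falling entirely off-chromosome
    returns ``None``.
    """
    if size <= 0:
        raise ValueError("flank size must be positive")
    if side not in ("5prime", "3prime"):
        raise ValueError("side must be '5prime' or '3prime'")
    # '.' treated as '+' (flagged upstream by callers that care)
    plus = region.strand != "-"
    upstream = side == "5prime"
    if plus == upstream:  # left of start
        lo, hi = region.start - size, region.start
    else:  # right of end
        lo, hi = region.end, region.end + size
    lo = max(lo, 0)
    if chrom_length is not None:
        hi = min(hi, chrom_length)
    if lo >= hi:
        return None
    return GenomeInterval(region.chrom, lo, hi, region.strand)


@dataclass
class TranscriptModel:
    """A transcript: ordered exons (and optional CDS pieces) on one strand.

    Exons are sorted, non-overlapping intervals on a single chrom/strand;
    ``cds_intervals`` must lie within the exon union. Introns are the gaps
    between consecutive exons.
    """

    transcript_id: str
    gene_id: str
    exons: list[GenomeInterval]
    cds_intervals: list[GenomeInterval] = field(default_factory=list)
    biotype: str = "other"  # protein_coding | lncRNA_candidate | other

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        self.cds_intervals = sorted(self.cds_intervals, key=lambda e: e.start)
        chroms = {e.chrom for e in self.exons}
        if len(chroms) != 1:
            raise ValueError(f"transcript {self.transcript_id} spans chroms {chroms}")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"transcript {self.transcript_id} has overlapping exons"
                )
        for c in self.cds_intervals:
            if not any(e.contains(c) for e in self.exons):
                raise ValueError(
                    f"CDS interval outside exons in {self.transcript_id}"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomeInterval:
        return GenomeInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def introns(self) -> list[GenomeInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomeInterval(self.chrom, a.end, b.start, self.strand))
        return out

    @property
    def junctions(self) -> list[tuple[int, int]]:
        """Intron (start, end) pairs — the splice-junction chain."""
        return [(i.start, i.end) for i in self.introns]

    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass
class GeneModel:
    gene_id: str
    extent: GenomeInterval
    transcript_ids: list[str]
    biotype: str = "other"


class AnnotationSet:
    """A collection of transcripts with derived genes and an interval index."""

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self.transcripts: dict[str, TranscriptModel] = {}
        for t in transcripts:
            if t.transcript_id in self.transcripts:
                raise ValueError(f"duplicate transcript_id {t.transcript_id}")
            self.transcripts[t.transcript_id] = t
        self.genes: dict[str, GeneModel] = {}
        by_gene: dict[str, list[TranscriptModel]] = {}
        for t in self.transcripts.values():
            by_gene.setdefault(t.gene_id, []).append(t)
        for gid, ts in by_gene.items():
            chrom = ts[0].chrom
            extent = GenomeInterval(
                chrom,
                min(t.start for t in ts),
                max(t.end for t in ts),
                ts[0].strand,
            )
            biotype = (
                "protein_coding"
                if any(t.biotype == "protein_coding" for t in ts)
                else ts[0].biotype
            )
            self.genes[gid] = GeneModel(gid, extent, [t.transcript_id for t in ts], biotype)
        self._index: dict[str, IntervalTree] = {}
        for t in self.transcripts.values():
            self._index.setdefault(t.chrom, IntervalTree()).addi(
                t.start, t.end, t.transcript_id
            )

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())

    def chroms(self) -> set[str]:
        return set(self._index)

    def query(self, chrom: str, start: int, end: int) -> list[TranscriptModel]:
        """Transcripts whose span overlaps [start, end)."""
        tree = self._index.get(chrom)
        if tree is None:
            return []
        return [self.transcripts[iv.data] for iv in sorted(tree.overlap(start, end))]


# ---------------------------------------------------------------------------
# GFF3 / GTF reading & writing
# ---------------------------------------------------------------------------

_TX_FEATURES = {"mrna", "transcript", "lnc_rna", "ncrna"}


def _first(attrs, *keys) -> str | None:
    for k in keys:
        if k in attrs and attrs[k]:
            return attrs[k][0]
    return None


def parse_gff(source, chrom_lengths: Mapping[str, int] | None = None) -> AnnotationSet:
    """Parse a GFF3 or GTF stream/path/string into an :class:`AnnotationSet`.

    The dialect is auto-detected per line from the attribute syntax. Exon and
    CDS features are grouped under their transcript; unknown feature types are
    ignored. Raises :class:`ParseError` naming the line number on a malformed
    line, and ``ValueError`` when a feature exceeds a declared chrom length.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        s = str(source)
        text = open(s).read() if ("\n" not in s and len(s) < 4096) else s

    exons: dict[str, list[GenomeInterval]] = {}
    cds: dict[str, list[GenomeInterval]] = {}
    tx_gene: dict[str, str] = {}
    tx_biotype: dict[str, str] = {}
    gene_biotype: dict[str, str] = {}

    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if len(line.split("\t")) < 8:
            raise ParseError(f"line {lineno}: expected ≥8 tab-separated fields")
        try:
            feat = feature_from_line(line)
        except Exception as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
        ftype = feat.featuretype.lower()
        start, end = feat.start - 1, feat.end  # 1-based inclusive -> half-open
        if start < 0 or start >= end:
            raise ParseError(f"line {lineno}: invalid coordinates {feat.start}..{feat.end}")
        if chrom_lengths is not None:
            if feat.seqid not in chrom_lengths:
                raise ValueError(f"line {lineno}: unknown chrom {feat.seqid}")
            if end > chrom_lengths[feat.seqid]:
                raise ValueError(
                    f"line {lineno}: feature end {end} exceeds {feat.seqid} "
                    f"length {chrom_lengths[feat.seqid]}"
                )
        strand = feat.strand if feat.strand in ("+", "-") else "."
        attrs = feat.attributes
        bt = _first(attrs, "biotype", "gene_biotype", "transcript_biotype")
        if ftype == "gene":
            gid = _first(attrs, "ID", "gene_id")
            if gid and bt:
                gene_biotype[gid] = bt
            continue
        if ftype in _TX_FEATURES:
            tid = _first(attrs, "ID", "transcript_id")
            gid = _first(attrs, "Parent", "gene_id") or tid
            if tid is None:
                raise ParseError(f"line {lineno}: transcript feature without ID")
            tx_gene[tid] = gid
            if bt:
                tx_biotype[tid] = bt
            continue
        if ftype in ("exon", "cds"):
            tid = _first(attrs, "Parent", "transcript_id")
            if tid is None:
                raise ParseError(f"line {lineno}: {feat.featuretype} without parent transcript")
            iv = GenomeInterval(feat.seqid, start, end, strand)
            (exons if ftype == "exon" else cds).setdefault(tid, []).append(iv)
        # all other feature types ignored

    transcripts = []
    for tid, ex in exons.items():
        gid = tx_gene.get(tid, tid)
        bt = tx_biotype.get(tid) or gene_biotype.get(gid) or (
            "protein_coding" if tid in cds else "other"
        )
        if bt not in ("protein_coding", "lncRNA_candidate", "other"):
            bt = "protein_coding" if bt == "protein_coding" else (
                "lncRNA_candidate" if "lnc" in bt.lower() else "other"
            )
        transcripts.append(
            TranscriptModel(tid, gid, ex, cds.get(tid, []), biotype=bt)
        )
    return AnnotationSet(transcripts)


def write_gff3(ann: AnnotationSet, handle=None) -> str:
    """Serialise an AnnotationSet as GFF3 (gene/mRNA/exon/CDS rows)."""
    out = io.StringIO()
    out.write("##gff-version 3\n")
    for gid in sorted(ann.genes):
        g = ann.genes[gid]
        e = g.extent
        out.write(
            f"{e.chrom}\t.\tgene\t{e.start + 1}\t{e.end}\t.\t{e.strand}\t.\t"
            f"ID={gid};biotype={g.biotype}\n"
        )
        for tid in sorted(g.transcript_ids):
            t = ann.transcripts[tid]
            out.write(
                f"{t.chrom}\t.\tmRNA\t{t.start + 1}\t{t.end}\t.\t{t.strand}\t.\t"
                f"ID={tid};Parent={gid};biotype={t.biotype}\n"
            )
            for i, ex in enumerate(t.exons, 1):
                out.write(
                    f"{ex.chrom}\t.\texon\t{ex.start + 1}\t{ex.end}\t.\t{ex.strand}\t.\t"
                    f"ID={tid}.exon{i};Parent={tid}\n"
                )
            for i, c in enumerate(t.cds_intervals, 1):
                out.write(
                    f"{c.chrom}\t.\tCDS\t{c.start + 1}\t{c.end}\t.\t{c.strand}\t0\t"
                    f"ID={tid}.cds{i};Parent={tid}\n"
                )
    text = out.getvalue()
    if handle is not None:
        handle.write(text)
    return text


def write_bed6(intervals: Iterable[tuple[GenomeInterval, str, float]], handle=None) -> str:
    """BED6 text for (interval, name, score) triples."""
    out = io.StringIO()
    for iv, name, score in intervals:
        strand = iv.strand if iv.strand in ("+", "-") else "."
        out.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{strand}\n")
    text = out.getvalue()
    if handle is not None:
        handle.write(text)
    return text


class GenomeSequence:
    """Per-chromosome nucleotide strings (A/C/G/T/N)."""

    def __init__(self, seqs: Mapping[str, str]):
        self.seqs = {c: str(s).upper() for c, s in seqs.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.seqs

    def length(self, chrom: str) -> int:
        return len(self.seqs[chrom])

    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.seqs.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self.seqs:
            raise KeyError(f"unknown chrom {chrom}")
        if start < 0 or end > len(self.seqs[chrom]):
            raise ValueError(f"[{start},{end}) outside {chrom}")
        return self.seqs[chrom][start:end]

    @classmethod
    def from_fasta(cls, source) -> "GenomeSequence":
        if hasattr(source, "read"):
            handle = source
        else:
            handle = open(source)
        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(handle, "fasta")})

    def to_fasta(self, handle=None, width: int = 70) -> str:
        out = io.StringIO()
        for chrom in sorted(self.seqs):
            out.write(f">{chrom}\n")
            s = self.seqs[chrom]
            for i in range(0, len(s), width):
                out.write(s[i : i + width] + "\n")
        text = out.getvalue()
        if handle is not None:
            handle.write(text)
        return text
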