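"""SNP filtering, fixed/segregating split, per-kb rates, and consequence
annotation.

Discovery filters follow the conventions of RNA-seq variant calling against a
reference assembly: call quality ≥ 10, read depth ≥ 3× for fixed differences
(homozygous alternate) and ≥ 4× for segregating (heterozygous) sites, with
splice-proximal calls removed because alignment around splice junctions is
unreliable. ASE site selection is stricter: quality > 10, depth ≥ 4 and at
least 2 reads per allele.

Consequence categories are assigned by precedence: splice site, then
codon-level CDS calls (synonymous / non-synonymous / stop gained / stop
lost), UTRs, intronic, within-non-coding-gene, 1 kb up/downstream flanks,
intergenic.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

from Bio.Seq import Seq

from .ase import AlleleCountSite
from .genomic import AnnotationSet, GenomeInterval, GenomeSequence, TranscriptModel

EFFECT_CATEGORIES = (
    "splice_site",
    "synonymous_coding",
    "non_synonymous_coding",
    "stop_gained",
    "stop_lost",
    "utr5",
    "utr3",
    "intronic",
    "within_non_coding_gene",
    "upstream5",
    "downstream3",
    "intergenic",
)

_NUC = set("ACGT")


@dataclass(frozen=True)
class VariantCall:
    chrom: str
    pos: int  # 0-based
    ref_allele: str
    alt_allele: str
    quality: float
    depth: int
    genotype: str  # "hom_alt" | "het"
    allele_counts: tuple[int, int] = (0, 0)  # (ref reads, alt reads)

    def __post_init__(self) -> None:
        if self.ref_allele not in _NUC or self.alt_allele not in _NUC:
            raise ValueError(f"alleles must be single nucleotides, got "
                             f"{self.ref_allele}>{self.alt_allele}")
        if self.genotype not in ("hom_alt", "het"):
            raise ValueError(f"genotype must be hom_alt or het, got {self.genotype}")
        if sum(self.allele_counts) > self.depth:
            raise ValueError("allele counts exceed depth")

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.pos}"


def filter_variants(
    calls,
    min_quality: float = 10,
    min_depth_fixed: int = 3,
    min_depth_segregating: int = 4,
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Quality/depth filter and split into (fixed, segregating).

    Fixed = homozygous alternate (difference from the assembly); segregating
    = heterozygous. Depth floors differ by class.
    """
    fixed, seg = [], []
    for c in calls:
        if c.quality < min_quality:
            continue
        if c.genotype == "hom_alt" and c.depth >= min_depth_fixed:
            fixed.append(c)
        elif c.genotype == "het" and c.depth >= min_depth_segregating:
            seg.append(c)
    return fixed, seg


def _splice_boundaries(ann: AnnotationSet) -> dict[str, set[int]]:
    """Intronic positions of exon-intron boundaries (first/last intron base)."""
    out: dict[str, set[int]] = {}
    for t in ann:
        s = out.setdefault(t.chrom, set())
        for intron in t.introns:
            s.add(intron.start)      # donor-side first intronic base
            s.add(intron.end - 1)    # acceptor-side last intronic base
    return out


def remove_splice_proximal(calls, ann: AnnotationSet, window_bp: int = 2):
    """Drop calls within ``window_bp`` of any exon-intron boundary."""
    if window_bp < 1:
        raise ValueError("window_bp must be ≥ 1")
    edges: dict[str, list[int]] = {}
    for t in ann:
        lst = edges.setdefault(t.chrom, [])
        for intron in t.introns:
            lst.extend((intron.start, intron.end))
    kept = []
    for c in calls:
        near = any(
            abs(c.pos - e) < window_bp or abs(c.pos - (e - 1)) < window_bp
            for e in edges.get(c.chrom, ())
        )
        if not near:
            kept.append(c)
    return kept


def _codon_context(
    call: VariantCall, t: TranscriptModel, genome: GenomeSequence
) -> tuple[str, str] | None:
    """(ref_codon, alt_codon) in coding orientation, or None if not in CDS."""
    cds = t.cds_intervals
    if not cds:
        return None
    # genomic CDS positions in transcription order
    positions: list[int] = []
    for iv in cds:
        positions.extend(range(iv.start, iv.end))
    if len(positions) % 3 != 0:
        raise ValueError(f"CDS length not divisible by 3 in {t.transcript_id}")
    if t.strand == "-":
        positions = positions[::-1]
    try:
        idx = positions.index(call.pos)
    except ValueError:
        return None
    codon_i = idx // 3
    codon_pos = positions[codon_i * 3 : codon_i * 3 + 3]

    def base(p: int, allele: str | None = None) -> str:
        nt = allele if allele is not None else genome.fetch(call.chrom, p, p + 1)
        if t.strand == "-":
            nt = str(Seq(nt).complement())
        return nt

    ref_codon = "".join(
        base(p, call.ref_allele if p == call.pos else None) for p in codon_pos
    )
    alt_codon = "".join(
        base(p, call.alt_allele if p == call.pos else None) for p in codon_pos
    )
    return ref_codon, alt_codon


def classify_effect(
    call: VariantCall,
    ann: AnnotationSet,
    genome: GenomeSequence,
    flank_bp: int = 1000,
    splice_window: int = 2,
) -> str:
    """Single consequence category for a variant (see module docstring)."""
    pos = call.pos
    hits = ann.query(call.chrom, pos, pos + 1)

    # splice site: within splice_window of an exon-intron boundary, intron side
    for t in hits:
        for intron in t.introns:
            if intron.start <= pos < intron.start + splice_window or \
               intron.end - splice_window <= pos < intron.end:
                return "splice_site"

    coding_hit = utr5 = utr3 = intronic = noncoding = False
    effect = None
    for t in hits:
        in_exon = any(e.start <= pos < e.end for e in t.exons)
        in_cds = any(c.start <= pos < c.end for c in t.cds_intervals)
        if in_cds:
            ctx = _codon_context(call, t, genome)
            if ctx is not None:
                ref_c, alt_c = ctx
                ref_aa = str(Seq(ref_c).translate())
                alt_aa = str(Seq(alt_c).translate())
                coding_hit = True
                if ref_aa == alt_aa:
                    eff = "synonymous_coding"
                elif ref_aa == "*" and alt_aa != "*":
                    eff = "stop_lost"
                elif ref_aa != "*" and alt_aa == "*":
                    eff = "stop_gained"
                else:
                    eff = "non_synonymous_coding"
                # most severe coding call across transcripts wins
                order = ("stop_gained", "stop_lost", "non_synonymous_coding",
                         "synonymous_coding")
                if effect is None or order.index(eff) < order.index(effect):
                    effect = eff
        elif in_exon:
            if t.cds_intervals:
                cds_start = t.cds_intervals[0].start
                cds_end = t.cds_intervals[-1].end
                before = pos < cds_start
                if (t.strand != "-" and before) or (t.strand == "-" and not before and pos >= cds_end):
                    utr5 = True
                else:
                    utr3 = True
            else:
                noncoding = True
        elif any(i.start <= pos < i.end for i in t.introns):
            if t.biotype == "protein_coding":
                intronic = True
            else:
                noncoding = True

    if coding_hit:
        return effect
    if utr5:
        return "utr5"
    if utr3:
        return "utr3"
    if intronic:
        return "intronic"
    if noncoding:
        return "within_non_coding_gene"

    # flanks, strand-aware, nearest gene wins
    best = None
    for g in ann.genes.values():
        e = g.extent
        if e.chrom != call.chrom:
            continue
        if e.start - flank_bp <= pos < e.start:
            d = e.start - pos
            side = "upstream5" if e.strand != "-" else "downstream3"
        elif e.end <= pos < e.end + flank_bp:
            d = pos - e.end + 1
            side = "downstream3" if e.strand != "-" else "upstream5"
        else:
            continue
        if best is None or d < best[0]:
            best = (d, side)
    if best is not None:
        return best[1]
    return "intergenic"


def effect_table(calls, ann, genome, **kw):
    """Category -> count mapping over a collection of calls."""
    import pandas as pd

    counts = dict.fromkeys(EFFECT_CATEGORIES, 0)
    for c in calls:
        counts[classify_effect(c, ann, genome, **kw)] += 1
    return pd.Series(counts, name="count")


def snp_rate(n_snps: int, bp_covered: int) -> float:
    """SNPs per kilobase of covered sequence."""
    if bp_covered <= 0:
        raise ValueError("bp_covered must be positive")
    return 1000.0 * n_snps / bp_covered


def select_ase_sites(calls) -> list[VariantCall]:
    """Heterozygous sites usable for ASE testing.

    Quality strictly > 10, depth ≥ 4, and at least 2 reads supporting each
    allele.
    """
    return [
        c for c in calls
        if c.genotype == "het"
        and c.quality > 10
        and c.depth >= 4
        and min(c.allele_counts) >= 2
    ]


def to_allele_count_sites(calls) -> list[AlleleCountSite]:
    """ASE input sites; n counts only the two focal alleles, n_a is the ALT
    count (use ``randomize_alleles`` for the arbitrary-allele orientation)."""
    return [
        AlleleCountSite(c.site_id, sum(c.allele_counts), c.allele_counts[1])
        for c in calls
    ]


def randomize_alleles(sites, rng) -> list[AlleleCountSite]:
    """Flip n_a to the other allele with probability 1/2 (seeded)."""
    return [
        AlleleCountSite(s.site_id, s.n, s.n - s.n_a if rng.random() < 0.5 else s.n_a)
        for s in sites
    ]


# ---------------------------------------------------------------------------
# Minimal VCF subset I/O (CHROM POS REF ALT QUAL; INFO DP= ; FORMAT GT:AD)
# ---------------------------------------------------------------------------

VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele read depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample
"""


def write_vcf(calls, handle=None) -> str:
    out = io.StringIO()
    out.write(VCF_HEADER)
    for c in sorted(calls, key=lambda c: (c.chrom, c.pos)):
        gt = "1/1" if c.genotype == "hom_alt" else "0/1"
        ad = f"{c.allele_counts[0]},{c.allele_counts[1]}"
        out.write(
            f"{c.chrom}\t{c.pos + 1}\t.\t{c.ref_allele}\t{c.alt_allele}\t"
            f"{c.quality:g}\t.\tDP={c.depth}\tGT:AD\t{gt}:{ad}\n"
        )
    text = out.getvalue()
    if handle is not None:
        handle.write(text)
    return text


def read_vcf(source) -> list[VariantCall]:
    """Read the VCF subset written by :func:`write_vcf` (plain text).

    Multi-allelic records keep only the first (major) alternate allele.
    """
    import warnings

    text = source.read() if hasattr(source, "read") else open(source).read()
    calls = []
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 8:
            raise ValueError(f"VCF line {lineno}: expected ≥8 fields")
        chrom, pos, _, ref, alt, qual = f[0], int(f[1]) - 1, f[2], f[3], f[4], f[5]
        alts = alt.split(",")
        if len(alts) > 1:
            warnings.warn(f"VCF line {lineno}: multi-allelic site, keeping {alts[0]}")
        alt = alts[0]
        if len(ref) != 1 or len(alt) != 1:
            continue  # indels out of scope
        depth = 0
        for kv in f[7].split(";"):
            if kv.startswith("DP="):
                depth = int(kv[3:])
        genotype, ad = "hom_alt", (0, 0)
        if len(f) >= 10:
            fmt = f[8].split(":")
            vals = f[9].split(":")
            d = dict(zip(fmt, vals))
            if "GT" in d:
                gt = d["GT"].replace("|", "/")
                genotype = "het" if set(gt.split("/")) == {"0", "1"} else "hom_alt"
            if "AD" in d:
                parts = [int(x) for x in d["AD"].split(",")[:2]]
                ad = (parts[0], parts[1] if len(parts) > 1 else 0)
        calls.append(
            VariantCall(chrom, pos, ref, alt, float(qual), depth, genotype, ad)
        )
    return calls
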