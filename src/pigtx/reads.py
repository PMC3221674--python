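"""Classify aligned fragments against an annotation, and assembled
transcripts against a reference.

Fragments are binned into exon / intron / flank / intergenic with a
configurable minimum-overlap rule (default 1 nt) and a 1 kb flank on each
gene. Assembled transcripts receive a single-character class code describing
their relation to the reference transcript set ('=' exact intron chain, 'c'
contained, 'j' novel isoform sharing a junction, 'e' pre-mRNA, 'i' intronic,
'o' other exonic overlap, 'p' polymerase run-on, 'u' intergenic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .genomic import AnnotationSet, GenomeInterval, TranscriptModel, flank, overlap_length

READ_CATEGORIES = ("exon", "intron", "flank", "intergenic")
CLASS_CODES = ("=", "c", "e", "i", "j", "o", "p", "u")


@dataclass
class FragmentAlignment:
    """One aligned fragment; split alignments carry multiple blocks."""

    read_id: str
    blocks: list[GenomeInterval]
    mate_of: str | None = None

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError(f"fragment {self.read_id} has no blocks")
        self.blocks = sorted(self.blocks, key=lambda b: b.start)
        if len({b.chrom for b in self.blocks}) != 1:
            raise ValueError(f"fragment {self.read_id} blocks on multiple chroms")
        for a, b in zip(self.blocks, self.blocks[1:]):
            if b.start < a.end:
                raise ValueError(f"fragment {self.read_id} has overlapping blocks")

    @property
    def chrom(self) -> str:
        return self.blocks[0].chrom


class _FeatureIndex:
    """Per-class interval trees (exon, intron, flank) over an annotation."""

    def __init__(self, ann: AnnotationSet, flank_size: int):
        self.trees: dict[str, dict[str, IntervalTree]] = {
            "exon": {}, "intron": {}, "flank": {}
        }
        for t in ann:
            for e in t.exons:
                self._add("exon", e)
            for i in t.introns:
                self._add("intron", i)
        for g in ann.genes.values():
            for side in ("5prime", "3prime"):
                f = flank(g.extent, flank_size, side)
                if f is not None:
                    self._add("flank", f)

    def _add(self, cls: str, iv: GenomeInterval) -> None:
        self.trees[cls].setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)

    def overlap_bp(self, cls: str, frag: FragmentAlignment) -> int:
        """Total fragment bp covered by features of ``cls`` (union, per block)."""
        tree = self.trees[cls].get(frag.chrom)
        if tree is None:
            return 0
        total = 0
        for b in frag.blocks:
            hits = tree.overlap(b.start, b.end)
            if not hits:
                continue
            # merge hit intervals clipped to the block, then sum
            clipped = sorted(
                (max(h.begin, b.start), min(h.end, b.end)) for h in hits
            )
            cur_s, cur_e = clipped[0]
            for s, e in clipped[1:]:
                if s > cur_e:
                    total += cur_e - cur_s
                    cur_s, cur_e = s, e
                else:
                    cur_e = max(cur_e, e)
            total += cur_e - cur_s
        return total


def build_feature_index(ann: AnnotationSet, flank_size: int = 1000) -> _FeatureIndex:
    return _FeatureIndex(ann, flank_size)


def classify_fragment(
    frag: FragmentAlignment,
    ann: AnnotationSet | _FeatureIndex,
    min_overlap: int = 1,
    flank_size: int = 1000,
) -> str:
    """Assign one category to a fragment.

    Precedence exon > intron > flank > intergenic; a class wins when its
    features cover at least ``min_overlap`` fragment bp in total. Raising
    ``min_overlap`` can only demote a fragment to a lower-precedence class.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be ≥ 1")
    index = ann if isinstance(ann, _FeatureIndex) else _FeatureIndex(ann, flank_size)
    known = set()
    for cls_trees in index.trees.values():
        known |= set(cls_trees)
    if frag.chrom not in known:
        warnings.warn(f"fragment {frag.read_id} on unannotated chrom {frag.chrom}")
        return "intergenic"
    for cls in ("exon", "intron", "flank"):
        if index.overlap_bp(cls, frag) >= min_overlap:
            return cls
    return "intergenic"


def tally_reads(
    frags, ann: AnnotationSet, min_overlap: int = 1, flank_size: int = 1000,
    sample: str = "sample",
) -> pd.DataFrame:
    """Per-category fragment counts (one column per sample, Table-style)."""
    index = _FeatureIndex(ann, flank_size)
    counts = dict.fromkeys(READ_CATEGORIES, 0)
    for f in frags:
        counts[classify_fragment(f, index, min_overlap, flank_size)] += 1
    return pd.DataFrame({sample: counts}).reindex(list(READ_CATEGORIES))


# ---------------------------------------------------------------------------
# Transcript class codes
# ---------------------------------------------------------------------------

def _exonic_overlap(query: TranscriptModel, ref: TranscriptModel) -> int:
    return sum(
        overlap_length(qe, re) for qe in query.exons for re in ref.exons
    )


def _intron_compatible(query: TranscriptModel, ref: TranscriptModel) -> bool:
    """Query's junction chain is a contiguous sub-chain of the ref's, and no
    query exon crosses a ref junction it does not use."""
    qj, rj = query.junctions, ref.junctions
    if qj:
        try:
            i = rj.index(qj[0])
        except ValueError:
            return False
        if rj[i : i + len(qj)] != qj:
            return False
    # query exons must not extend across unused ref introns
    for qe in query.exons:
        for rs, re_ in rj:
            if (rs, re_) in qj:
                continue
            if qe.start < re_ and rs < qe.end and not (qe.start >= re_ or qe.end <= rs):
                # exon overlaps an unused ref intron boundary region
                if qe.start < rs < qe.end or qe.start < re_ < qe.end:
                    return False
    return True


def classify_transcript(
    query: TranscriptModel,
    ref: AnnotationSet,
    run_on_window: int = 2000,
    pre_mrna_min_intron_overlap: int = 10,
    mono_exon_equal_frac: float = 0.95,
) -> str:
    """Single class code for a query transcript against the reference.

    Precedence: '=' > 'c' > 'j' > 'e' > 'i' > 'o' > 'p' > 'u'.
    """
    if not query.exons:
        raise ValueError("query transcript has no exons")
    overlapping = [
        t for t in ref.query(query.chrom, query.start, query.end)
        if _exonic_overlap_span(query, t)
    ]

    qj = query.junctions
    # '=': identical intron chain (multi-exon) or near-reciprocal span (mono)
    for t in overlapping:
        if qj and qj == t.junctions:
            return "="
        if not qj and not t.junctions:
            ov = overlap_length(query.span, t.span)
            if ov >= mono_exon_equal_frac * len(query.span) and \
               ov >= mono_exon_equal_frac * len(t.span):
                return "="
    # 'c': contained within a ref transcript, intron-compatible
    for t in overlapping:
        if t.span.contains(query.span) and _exonic_overlap(query, t) > 0 \
                and _intron_compatible(query, t):
            return "c"
    # 'j': shares at least one junction but the chain differs
    for t in overlapping:
        if qj and set(qj) & set(t.junctions) and qj != t.junctions:
            return "j"
    # 'e': mono-exon query overlapping a ref exon AND retaining ref intron
    if not qj:
        for t in overlapping:
            if _exonic_overlap(query, t) > 0:
                intron_bp = sum(
                    overlap_length(query.span, i) for i in t.introns
                )
                if intron_bp >= pre_mrna_min_intron_overlap:
                    return "e"
    # 'i': entirely within a ref intron
    for t in ref.query(query.chrom, query.start, query.end):
        for intron in t.introns:
            if intron.contains(query.span):
                return "i"
    # 'o': any other exonic overlap
    for t in overlapping:
        if _exonic_overlap(query, t) > 0:
            return "o"
    # within a ref span but touching only intron ends etc. → treat as 'o'
    if overlapping:
        return "o"
    # 'p': run-on — within window downstream of a ref transcript end, no overlap
    for t in ref.query(query.chrom, max(0, query.start - run_on_window),
                       query.end + run_on_window):
        if overlap_length(query.span, t.span) > 0:
            continue
        gap = (t.start - query.end) if t.strand == "-" else (query.start - t.end)
        if 0 <= gap <= run_on_window:
            return "p"
    return "u"


def _exonic_overlap_span(query: TranscriptModel, t: TranscriptModel) -> bool:
    return overlap_length(query.span, t.span) > 0


def classify_transcripts(
    queries, ref: AnnotationSet, **kw
) -> pd.DataFrame:
    rows = [
        {"transcript_id": q.transcript_id, "class_code": classify_transcript(q, ref, **kw)}
        for q in queries
    ]
    return pd.DataFrame(rows, columns=["transcript_id", "class_code"])


def class_code_summary(codes: pd.DataFrame, sample: str = "sample") -> pd.DataFrame:
    """Counts and percentages per class code (Table-style, one sample row)."""
    counts = codes["class_code"].value_counts().reindex(list(CLASS_CODES), fill_value=0)
    total = int(counts.sum())
    out = pd.DataFrame(
        {c: [int(counts[c])] for c in CLASS_CODES}, index=[sample]
    )
    out["Total"] = total
    return out


# ---------------------------------------------------------------------------
# Fragment I/O (BED12 blocks or 6-column TSV)
# ---------------------------------------------------------------------------

def read_fragments(source) -> list[FragmentAlignment]:
    """Read fragments from BED12 (block-aware) or BED6-like text."""
    text = source.read() if hasattr(source, "read") else open(source).read()
    frags = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track")):
            continue
        f = line.split("\t")
        if len(f) < 4:
            raise ValueError(f"line {lineno}: expected ≥4 BED fields")
        chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
        strand = f[5] if len(f) > 5 and f[5] in "+-" else "."
        if len(f) >= 12:  # BED12 blocks
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            blocks = [
                GenomeInterval(chrom, start + s, start + s + sz, strand)
                for s, sz in zip(starts, sizes)
            ]
        else:
            blocks = [GenomeInterval(chrom, start, end, strand)]
        frags.append(FragmentAlignment(name, blocks))
    return frags
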