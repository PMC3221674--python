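"""Long non-coding RNA candidate cascade and conservation categorisation.

Stage 1 keeps assembled transcripts that do not overlap, and lie at least
1 kb away from, any protein-coding annotation. Stage 2 removes transcripts
with complete predicted coding potential, a protein or domain hit at
e < 1e-5, or any structured-RNA family hit. Stage 3 removes transcripts
whose human homologue is fully contained in protein-coding exons. Surviving
candidates are categorised from homology hits retained at > 70% query
coverage: repeat-containing, conserved including human, Artiodactyla-only
(cow but not human), or no homolog.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genomic import AnnotationSet, TranscriptModel, overlap_length

CATEGORIES = (
    "repeat_containing",
    "conserved_incl_human",
    "artiodactyl_only",
    "no_homolog",
    "removed",
)
HUMAN_SUBCLASSES = ("unannotated", "protein_coding_overlap", "known_lncRNA",
                    "pseudogene")
OVERLAP_CLASSES = ("protein_coding_exon_full", "protein_coding_partial",
                   "lncRNA", "pseudogene", "unannotated", "none")


@dataclass
class EvidenceRecord:
    """External-evidence summary for one transcript (tool outputs as data)."""

    coding_call: str = "none"  # none | partial | complete
    protein_hits: list[tuple[str, float]] = field(default_factory=list)
    domain_hits: list[tuple[str, float]] = field(default_factory=list)
    rna_family_hits: list[str] = field(default_factory=list)
    repeat_flag: bool = False

    def __post_init__(self) -> None:
        if self.coding_call not in ("none", "partial", "complete"):
            raise ValueError(f"bad coding_call {self.coding_call!r}")
        for _, e in self.protein_hits + self.domain_hits:
            if e <= 0:
                raise ValueError("e-values must be positive")


@dataclass(frozen=True)
class HomologyHit:
    transcript_id: str
    genome: str
    coverage: float  # aligned fraction of the pig query, [0, 1]
    similarity: float
    overlap_class: str = "none"

    def __post_init__(self) -> None:
        if not (0.0 <= self.coverage <= 1.0):
            raise ValueError("coverage must be in [0, 1]")
        if self.overlap_class not in OVERLAP_CLASSES:
            raise ValueError(f"bad overlap_class {self.overlap_class!r}")


@dataclass
class LncRNACandidate:
    transcript: TranscriptModel
    filter_state: dict = field(default_factory=dict)
    category: str | None = None

    @property
    def transcript_id(self) -> str:
        return self.transcript.transcript_id


def _distance(t: TranscriptModel, extent) -> int:
    if t.chrom != extent.chrom:
        return 10**12
    if overlap_length(t.span, extent) > 0:
        return 0
    return extent.start - t.end if t.end <= extent.start else t.start - extent.end


def candidate_transcripts(
    assembled: AnnotationSet,
    reference: AnnotationSet,
    min_distance: int = 1000,
) -> list[LncRNACandidate]:
    """Assembled transcripts with no overlap and ≥ ``min_distance`` bp to
    every protein-coding gene extent (distance exactly min_distance passes)."""
    coding = [
        g.extent for g in reference.genes.values() if g.biotype == "protein_coding"
    ]
    out = []
    for t in assembled:
        d = min((_distance(t, e) for e in coding), default=10**12)
        ok = d >= min_distance
        out.append(
            LncRNACandidate(
                t,
                filter_state={"distance": "pass" if ok else "fail"},
                category=None if ok else "removed",
            )
        )
    return [c for c in out if c.category != "removed"], [
        c for c in out if c.category == "removed"
    ]


def apply_evidence_filters(
    candidates: list[LncRNACandidate],
    evidence: dict[str, EvidenceRecord],
    e_threshold: float = 1e-5,
) -> tuple[list[LncRNACandidate], list[LncRNACandidate]]:
    """Coding-potential / protein / domain / RNA-family filters.

    A transcript is removed when its predicted coding potential is complete,
    when any protein or domain hit has e-value strictly below
    ``e_threshold``, or when it hits any structured-RNA family. A missing
    evidence record counts as no evidence.
    """
    survivors, removed = [], []
    for c in candidates:
        ev = evidence.get(c.transcript_id, EvidenceRecord())
        checks = {
            "coding_complete": ev.coding_call == "complete",
            "protein_hit": any(e < e_threshold for _, e in ev.protein_hits),
            "domain_hit": any(e < e_threshold for _, e in ev.domain_hits),
            "rna_family": bool(ev.rna_family_hits),
        }
        for name, failed in checks.items():
            c.filter_state[name] = "fail" if failed else "pass"
        if any(checks.values()):
            c.category = "removed"
            removed.append(c)
        else:
            survivors.append(c)
    return survivors, removed


def human_overlap_filter(
    candidates: list[LncRNACandidate],
    human_hits: dict[str, HomologyHit],
) -> tuple[list[LncRNACandidate], list[LncRNACandidate]]:
    """Remove candidates whose human homologue is fully inside protein-coding
    exons; partial overlaps are retained and flagged."""
    survivors, removed = [], []
    for c in candidates:
        hit = human_hits.get(c.transcript_id)
        cls = hit.overlap_class if hit is not None else "none"
        c.filter_state["human_overlap"] = cls
        if cls == "protein_coding_exon_full":
            c.category = "removed"
            removed.append(c)
        else:
            survivors.append(c)
    return survivors, removed


def best_hits(hits) -> dict[tuple[str, str], HomologyHit]:
    """Best hit per (transcript, genome): highest similarity, ties broken by
    coverage then lexicographic genome order."""
    best: dict[tuple[str, str], HomologyHit] = {}
    for h in hits:
        key = (h.transcript_id, h.genome)
        cur = best.get(key)
        if cur is None or (h.similarity, h.coverage) > (cur.similarity, cur.coverage):
            best[key] = h
    return best


def categorize_conservation(
    candidates: list[LncRNACandidate],
    hits,
    repeat_flags: dict[str, bool] | None = None,
    min_coverage: float = 0.70,
    human_genome: str = "human",
    cow_genome: str = "cow",
) -> tuple[pd.Series, pd.DataFrame]:
    """Assign each surviving candidate a conservation category and build the
    genome × transcript similarity matrix.

    Hits with query coverage ≤ ``min_coverage`` are discarded (strictly more
    than 70% required). Categories: repeat_containing beats everything; then
    conserved_incl_human if a human hit survives; then artiodactyl_only on a
    surviving cow hit; else no_homolog.
    """
    repeat_flags = repeat_flags or {}
    bh = best_hits(h for h in hits if h.coverage > min_coverage)
    genomes = sorted({g for _, g in bh})
    tids = [c.transcript_id for c in candidates]
    matrix = pd.DataFrame(float("nan"), index=tids, columns=genomes)
    cats = {}
    for c in candidates:
        tid = c.transcript_id
        mine = {g: h for (t, g), h in bh.items() if t == tid}
        for g, h in mine.items():
            matrix.loc[tid, g] = h.similarity
        if repeat_flags.get(tid, False):
            cat = "repeat_containing"
        elif human_genome in mine:
            cat = "conserved_incl_human"
        elif cow_genome in mine:
            cat = "artiodactyl_only"
        else:
            cat = "no_homolog"
        c.category = cat
        cats[tid] = cat
    return pd.Series(cats, name="category"), matrix


def subcategorize_human(
    candidates: list[LncRNACandidate],
    human_hits: dict[str, HomologyHit],
) -> pd.Series:
    """Partition human-conserved candidates by what their human locus
    overlaps: nothing, a protein-coding gene, a known lncRNA or a
    pseudogene."""
    mapping = {
        "unannotated": "unannotated",
        "none": "unannotated",
        "protein_coding_partial": "protein_coding_overlap",
        "protein_coding_exon_full": "protein_coding_overlap",
        "lncRNA": "known_lncRNA",
        "pseudogene": "pseudogene",
    }
    counts = dict.fromkeys(HUMAN_SUBCLASSES, 0)
    for c in candidates:
        if c.category != "conserved_incl_human":
            raise ValueError(f"{c.transcript_id} is not in the human-conserved class")
        hit = human_hits.get(c.transcript_id)
        cls = hit.overlap_class if hit is not None else "none"
        counts[mapping[cls]] += 1
    return pd.Series(counts, name="n_transcripts")


def run_cascade(
    assembled: AnnotationSet,
    reference: AnnotationSet,
    evidence: dict[str, EvidenceRecord],
    homology_hits,
    min_distance: int = 1000,
    e_threshold: float = 1e-5,
    min_coverage: float = 0.70,
) -> dict:
    """Full cascade; returns survivors, per-stage removals, categories and
    the conservation matrix."""
    stage1, removed_distance = candidate_transcripts(assembled, reference, min_distance)
    stage2, removed_evidence = apply_evidence_filters(stage1, evidence, e_threshold)
    human = {
        h.transcript_id: h
        for h in best_hits(
            h for h in homology_hits
            if h.genome == "human" and h.coverage > min_coverage
        ).values()
    }
    stage3, removed_human = human_overlap_filter(stage2, human)
    repeat_flags = {
        c.transcript_id: evidence.get(c.transcript_id, EvidenceRecord()).repeat_flag
        for c in stage3
    }
    categories, matrix = categorize_conservation(
        stage3, homology_hits, repeat_flags, min_coverage
    )
    human_class = [c for c in stage3 if c.category == "conserved_incl_human"]
    sub = subcategorize_human(human_class, human) if human_class else pd.Series(
        dict.fromkeys(HUMAN_SUBCLASSES, 0), name="n_transcripts"
    )
    return {
        "survivors": stage3,
        "removed": {
            "distance": removed_distance,
            "evidence": removed_evidence,
            "human_overlap": removed_human,
        },
        "categories": categories,
        "matrix": matrix,
        "human_subclasses": sub,
    }


# ---------------------------------------------------------------------------
# Evidence / homology tables as TSV
# ---------------------------------------------------------------------------

def read_evidence_tables(
    coding_calls, protein_hits, domain_hits, rfam_hits, repeat_flags
) -> dict[str, EvidenceRecord]:
    """Assemble EvidenceRecords from five TSV tables (paths or handles)."""

    def load(src, names):
        text = src.read() if hasattr(src, "read") else open(src).read()
        rows = [
            line.split("\t") for line in text.splitlines()
            if line.strip() and not line.startswith("#")
        ]
        return pd.DataFrame(rows[1:] if rows and rows[0] == names else rows,
                            columns=names)

    records: dict[str, EvidenceRecord] = {}

    def rec(tid: str) -> EvidenceRecord:
        return records.setdefault(tid, EvidenceRecord())

    for _, r in load(coding_calls, ["transcript_id", "coding_call"]).iterrows():
        rec(r.transcript_id).coding_call = r.coding_call
    for _, r in load(protein_hits, ["transcript_id", "subject", "e_value"]).iterrows():
        rec(r.transcript_id).protein_hits.append((r.subject, float(r.e_value)))
    for _, r in load(domain_hits, ["transcript_id", "profile", "e_value"]).iterrows():
        rec(r.transcript_id).domain_hits.append((r.profile, float(r.e_value)))
    for _, r in load(rfam_hits, ["transcript_id", "family"]).iterrows():
        rec(r.transcript_id).rna_family_hits.append(r.family)
    for _, r in load(repeat_flags, ["transcript_id", "repeat_flag"]).iterrows():
        rec(r.transcript_id).repeat_flag = r.repeat_flag in ("1", "True", "true")
    return records


def read_homology_hits(source) -> list[HomologyHit]:
    text = source.read() if hasattr(source, "read") else open(source).read()
    hits = []
    for line in text.splitlines():
        if not line.strip() or line.startswith(("#", "transcript_id\t")):
            continue
        tid, genome, cov, sim, cls = line.split("\t")[:5]
        hits.append(HomologyHit(tid, genome, float(cov), float(sim), cls))
    return hits
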