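"""Seeded generators for every input the pipeline consumes, with planted
ground truth.

The fixtures emulate the statistical structure the pipeline assumes: a toy
genome with protein-coding and non-coding genes (UTR/CDS/intron structure,
valid open reading frames), planted variants whose consequence category is
known by construction, beta-binomially overdispersed allele counts with
planted ASE sites, Poisson two-library count matrices with planted fold
changes, assembled transcripts with planted class codes, and evidence tables
driving the lncRNA cascade to planted categories.

One global seed expands to fixed per-generator substreams
(``numpy.random.SeedSequence`` spawn keys), so adding a generator never
perturbs the others. All generators are deterministic under seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .ase import AlleleCountSite
from .genomic import AnnotationSet, GenomeInterval, GenomeSequence, TranscriptModel
from .lncrna import EvidenceRecord, HomologyHit
from .reads import FragmentAlignment
from .variants import VariantCall

_STREAMS = {
    "genome": 0,
    "variants": 1,
    "ase": 2,
    "de": 3,
    "lncrna": 4,
    "fragments": 5,
    "classes": 6,
}

_STOPS = ("TAA", "TAG", "TGA")
_COMP = str.maketrans("ACGT", "TGCA")


def rng_for(seed: int, stream: str) -> np.random.Generator:
    """Independent generator for one named substream of the global seed."""
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(entropy=seed,
                                               spawn_key=(_STREAMS[stream],)))
    )


class ConfigError(ValueError):
    """Infeasible fixture configuration (quotas that cannot be placed)."""


@dataclass
class FixtureConfig:
    """Study-condition defaults for all fixture generators.

    Coverage means 55 and 121 echo the two samples' mean ASE coverages; the
    null-overdispersion hyperparameters default to the fitted Large White
    prior Be(4.99, 3.84). Genome sizes are kept tiny so the full suite runs
    in well under a minute.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length_bp: int = 100_000
    n_genes: int = 24
    n_noncoding_genes: int = 4
    exons_per_gene: tuple[int, int] = (1, 4)
    min_intergenic_gap: int = 2600
    # ASE
    n_ase_sites: int = 1000
    ase_fraction: float = 0.04
    ase_true_p: float = 0.9
    alpha0: float = 4.99
    beta0: float = 3.84
    coverage_mean: float = 55.0
    coverage_dispersion: float = 5.0
    null_mode: str = "prior"  # "prior" (p ~ Be(alpha0, beta0)) or "fixed" (p = 0.5)
    # DE
    n_expr_genes: int = 2000
    n_de_genes: int = 100
    de_log2fc: float = 3.0
    mean_count: int = 200
    # variants
    variant_quota: dict = field(default_factory=lambda: {
        "synonymous_coding": 5, "non_synonymous_coding": 5, "stop_gained": 2,
        "stop_lost": 2, "utr5": 3, "utr3": 3, "intronic": 5,
        "splice_site": 3, "upstream5": 3, "downstream3": 3,
        "within_non_coding_gene": 3, "intergenic": 4,
    })
    # lncRNA
    lncrna_quota: dict = field(default_factory=lambda: {
        "removed_distance": 2, "removed_coding": 2, "removed_protein": 2,
        "removed_domain": 1, "removed_rfam": 1, "removed_human_full": 2,
        "repeat_containing": 3, "conserved_incl_human": 4,
        "artiodactyl_only": 3, "no_homolog": 3,
    })
    human_subclass_quota: dict = field(default_factory=lambda: {
        "unannotated": 1, "protein_coding_overlap": 1, "known_lncRNA": 1,
        "pseudogene": 1,
    })


# ---------------------------------------------------------------------------
# Genome & annotation
# ---------------------------------------------------------------------------

def _random_seq(rng, n: int) -> list[str]:
    return list(rng.choice(list("ACGT"), size=n))


def _random_cds(rng, n_codons: int) -> str:
    """ATG + (n_codons − 2) random non-stop codons + a stop codon."""
    bases = "ACGT"
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(list(bases), size=3))
        if c not in _STOPS:
            codons.append(c)
    codons.append(_STOPS[rng.integers(len(_STOPS))])
    return "".join(codons)


def make_genome_and_annotation(
    config: FixtureConfig,
) -> tuple[GenomeSequence, AnnotationSet, dict]:
    """Toy genome with planted gene structures.

    Genes are placed with at least ``min_intergenic_gap`` bp between extents
    (clean flank-only and intergenic zones for fragment classification).
    CDSs have a valid start, internal-stop-free body and terminal stop codon
    on the coding strand; the terminal stop is part of the CDS intervals.
    Returns (genome, annotation, truth) where truth records per-gene layout.
    """
    rng = rng_for(config.seed, "genome")
    seqs = {
        f"chr{i + 1}": _random_seq(rng, config.chrom_length_bp)
        for i in range(config.n_chroms)
    }
    if config.n_noncoding_genes > config.n_genes:
        raise ConfigError("n_noncoding_genes exceeds n_genes")

    transcripts: list[TranscriptModel] = []
    truth: dict = {"genes": {}}
    chrom_names = sorted(seqs)
    noncoding_ids = set(range(0, config.n_noncoding_genes))
    placed = 0
    cursor = {c: 1500 for c in chrom_names}
    attempts = 0
    while placed < config.n_genes:
        attempts += 1
        if attempts > 10 * config.n_genes:
            raise ConfigError("cannot place requested genes on this genome size")
        chrom = chrom_names[placed % len(chrom_names)]
        strand = "+" if rng.random() < 0.5 else "-"
        noncoding = placed in noncoding_ids
        n_exons = int(rng.integers(config.exons_per_gene[0],
                                   config.exons_per_gene[1] + 1))
        u5 = int(rng.integers(60, 150))
        u3 = int(rng.integers(90, 200))
        n_codons = int(rng.integers(80, 160))
        cds_len = 0 if noncoding else 3 * n_codons
        mrna_len = u5 + cds_len + u3
        # split mRNA into exon pieces of at least 60 bp
        cuts = sorted(rng.choice(
            np.arange(60, mrna_len - 60), size=n_exons - 1, replace=False
        )) if n_exons > 1 else []
        bounds = [0, *map(int, cuts), mrna_len]
        piece_lens = [b - a for a, b in zip(bounds, bounds[1:])]
        if min(piece_lens) < 20:
            continue
        introns = [int(rng.integers(200, 800)) for _ in range(n_exons - 1)]
        start = cursor[chrom]
        exon_ivs = []
        pos = start
        for i, plen in enumerate(piece_lens):
            exon_ivs.append(GenomeInterval(chrom, pos, pos + plen, strand))
            pos += plen
            if i < len(introns):
                pos += introns[i]
        gene_end = pos
        if gene_end + config.min_intergenic_gap > len(seqs[chrom]) - 1500:
            # chrom full; try the next one via the round-robin
            cursor[chrom] = len(seqs[chrom])
            full = all(
                cursor[c] + 6000 > len(seqs[c]) for c in chrom_names
            )
            if full:
                raise ConfigError("genome too small for requested gene count")
            chrom_names.append(chrom_names.pop(0))  # try the next chrom
            continue
        cursor[chrom] = gene_end + config.min_intergenic_gap + int(rng.integers(0, 500))

        gid = f"G{placed + 1:03d}"
        tid = f"{gid}.t1"
        # transcript-order genomic positions
        pos_tx = []
        for iv in exon_ivs:
            pos_tx.extend(range(iv.start, iv.end))
        if strand == "-":
            pos_tx = pos_tx[::-1]
        cds_ivs: list[GenomeInterval] = []
        if not noncoding:
            cds_seq = _random_cds(rng, n_codons)
            cds_positions = pos_tx[u5 : u5 + cds_len]
            for p, base in zip(cds_positions, cds_seq):
                seqs[chrom][p] = base if strand == "+" else base.translate(_COMP)
            gpos = sorted(cds_positions)
            run_start = gpos[0]
            prev = gpos[0]
            for p in gpos[1:]:
                if p != prev + 1:
                    cds_ivs.append(GenomeInterval(chrom, run_start, prev + 1, strand))
                    run_start = p
                prev = p
            cds_ivs.append(GenomeInterval(chrom, run_start, prev + 1, strand))
        biotype = "other" if noncoding else "protein_coding"
        t = TranscriptModel(tid, gid, exon_ivs, cds_ivs, biotype=biotype)
        transcripts.append(t)
        truth["genes"][gid] = {
            "transcript_id": tid, "chrom": chrom, "strand": strand,
            "noncoding": noncoding, "u5": u5, "u3": u3, "cds_len": cds_len,
            "pos_tx": pos_tx,
        }
        placed += 1

    genome = GenomeSequence({c: "".join(s) for c, s in seqs.items()})
    ann = AnnotationSet(transcripts)
    return genome, ann, truth


# ---------------------------------------------------------------------------
# Variant planting
# ---------------------------------------------------------------------------

def _splice_zone(t: TranscriptModel, window: int = 2) -> set[int]:
    zone = set()
    for intron in t.introns:
        zone |= set(range(intron.start - window, intron.start + window))
        zone |= set(range(intron.end - window, intron.end + window))
    return zone


def _tx_base(genome: GenomeSequence, chrom: str, pos: int, strand: str) -> str:
    b = genome.fetch(chrom, pos, pos + 1)
    return b if strand == "+" else b.translate(_COMP)


def plant_variants(
    genome: GenomeSequence,
    ann: AnnotationSet,
    truth_genes: dict,
    config: FixtureConfig,
    flank_bp: int = 1000,
) -> tuple[list[VariantCall], dict]:
    """Variants constructed so an independent re-annotation recovers the
    planted consequence category; quality/depth fields exercise the filter
    boundaries. Returns (calls, truth) with truth[site_id] = category."""
    rng = rng_for(config.seed, "variants")
    coding = [t for t in ann if t.biotype == "protein_coding"]
    noncoding = [t for t in ann if t.biotype != "protein_coding"]
    calls: list[VariantCall] = []
    truth: dict[str, str] = {}
    used: set[tuple[str, int]] = set()

    def emit(chrom: str, pos: int, ref: str, alt: str, category: str) -> None:
        if (chrom, pos) in used:
            raise ConfigError(f"site {chrom}:{pos} planted twice")
        used.add((chrom, pos))
        het = rng.random() < 0.5
        depth = int(rng.integers(6, 40))
        alt_reads = int(rng.integers(2, depth - 1)) if het else depth
        quality = float(rng.integers(15, 60))
        calls.append(VariantCall(
            chrom, pos, ref, alt, quality, depth,
            "het" if het else "hom_alt",
            (depth - alt_reads, alt_reads),
        ))
        truth[f"{chrom}:{pos}"] = category

    def pick_transcript(pool):
        return pool[int(rng.integers(len(pool)))]

    def mutate_codon(category: str) -> None:
        for _ in range(200):
            t = pick_transcript(coding)
            g = truth_genes["genes"][t.gene_id]
            pos_tx, u5, cds_len = g["pos_tx"], g["u5"], g["cds_len"]
            zone = _splice_zone(t)
            n_codons = cds_len // 3
            if category == "stop_lost":
                ci = n_codons - 1
            elif category == "stop_gained":
                ci = int(rng.integers(1, n_codons - 1))
            else:
                ci = int(rng.integers(1, n_codons - 1))
            cpos = pos_tx[u5 + 3 * ci : u5 + 3 * ci + 3]
            if any(p in zone for p in cpos):
                continue
            codon = "".join(
                _tx_base(genome, t.chrom, p, t.strand) for p in cpos
            )
            aa = str(Seq(codon).translate())
            options = []
            for j in range(3):
                for b in "ACGT":
                    if b == codon[j]:
                        continue
                    alt_codon = codon[:j] + b + codon[j + 1 :]
                    alt_aa = str(Seq(alt_codon).translate())
                    ok = (
                        (category == "synonymous_coding" and alt_aa == aa and aa != "*")
                        or (category == "non_synonymous_coding"
                            and alt_aa not in (aa, "*") and aa != "*")
                        or (category == "stop_gained" and aa != "*" and alt_aa == "*")
                        or (category == "stop_lost" and aa == "*" and alt_aa != "*")
                    )
                    if ok:
                        options.append((j, b))
            if not options:
                continue
            j, b = options[int(rng.integers(len(options)))]
            gpos = cpos[j]
            ref = genome.fetch(t.chrom, gpos, gpos + 1)
            alt = b if t.strand == "+" else b.translate(_COMP)
            if (t.chrom, gpos) in used or ref == alt:
                continue
            emit(t.chrom, gpos, ref, alt, category)
            return
        raise ConfigError(f"could not plant a {category} variant")

    def random_alt(ref: str) -> str:
        choices = [b for b in "ACGT" if b != ref]
        return choices[int(rng.integers(3))]

    def positional(category: str) -> None:
        for _ in range(500):
            if category in ("utr5", "utr3", "intronic", "splice_site",
                            "upstream5", "downstream3"):
                t = pick_transcript(coding)
            elif category == "within_non_coding_gene":
                t = pick_transcript(noncoding)
            else:
                t = pick_transcript(list(ann))
            g = truth_genes["genes"][t.gene_id]
            zone = _splice_zone(t)
            pos = None
            if category in ("utr5", "utr3"):
                u5, u3, pos_tx = g["u5"], g["u3"], g["pos_tx"]
                cand = pos_tx[:u5] if category == "utr5" else pos_tx[-u3:]
                cand = [p for p in cand if p not in zone]
                if cand:
                    pos = cand[int(rng.integers(len(cand)))]
            elif category == "intronic":
                introns = t.introns
                if introns:
                    iv = introns[int(rng.integers(len(introns)))]
                    if iv.end - 3 > iv.start + 3:
                        pos = int(rng.integers(iv.start + 3, iv.end - 3))
            elif category == "splice_site":
                introns = t.introns
                if introns:
                    iv = introns[int(rng.integers(len(introns)))]
                    pos = int(rng.choice(
                        [iv.start, iv.start + 1, iv.end - 2, iv.end - 1]
                    ))
            elif category in ("upstream5", "downstream3"):
                e = ann.genes[t.gene_id].extent
                d = int(rng.integers(10, min(flank_bp, 1200)))
                left = (category == "upstream5") == (e.strand != "-")
                pos = e.start - d if left else e.end - 1 + d
                if pos < 0 or pos >= genome.length(t.chrom):
                    pos = None
                elif ann.query(t.chrom, pos, pos + 1):
                    pos = None
                else:
                    # another gene must not be nearer on a conflicting side
                    others = [
                        og for og in ann.genes.values()
                        if og.extent.chrom == t.chrom and og.gene_id != t.gene_id
                    ]
                    if any(
                        min(abs(pos - og.extent.start), abs(pos - og.extent.end)) <= d
                        for og in others
                    ):
                        pos = None
            elif category == "within_non_coding_gene":
                ex = t.exons[int(rng.integers(len(t.exons)))]
                pos = int(rng.integers(ex.start, ex.end))
                if pos in zone:
                    pos = None
            elif category == "intergenic":
                ig_chrom = f"chr{int(rng.integers(config.n_chroms)) + 1}"
                pos = int(rng.integers(0, genome.length(ig_chrom)))
                near = any(
                    g2.extent.chrom == ig_chrom
                    and g2.extent.start - flank_bp - 2 <= pos < g2.extent.end + flank_bp + 2
                    for g2 in ann.genes.values()
                )
                if near:
                    pos = None
                else:
                    t = None
            if pos is None:
                continue
            site_chrom = t.chrom if t is not None else ig_chrom
            if (site_chrom, pos) in used:
                continue
            ref = genome.fetch(site_chrom, pos, pos + 1)
            if ref == "N":
                continue
            emit(site_chrom, pos, ref, random_alt(ref), category)
            return
        raise ConfigError(f"could not plant a {category} variant")

    for category, quota in config.variant_quota.items():
        for _ in range(quota):
            if category in ("synonymous_coding", "non_synonymous_coding",
                            "stop_gained", "stop_lost"):
                mutate_codon(category)
            else:
                positional(category)
    return calls, truth


# ---------------------------------------------------------------------------
# Allele counts (ASE)
# ---------------------------------------------------------------------------

def _nb_coverage(rng, n: int, mean: float, dispersion: float, floor: int = 4):
    p = dispersion / (dispersion + mean)
    cov = rng.negative_binomial(dispersion, p, size=n)
    return np.maximum(cov, floor)


def simulate_allele_counts(
    config: FixtureConfig,
) -> tuple[list[AlleleCountSite], dict]:
    """Overdispersed allele counts with planted ASE sites.

    Null sites draw p ~ Be(alpha0, beta0) (``null_mode='prior'``) or use
    p = 0.5 exactly (``'fixed'``); planted ASE sites use ``ase_true_p`` on a
    random allele. Counts are n_a ~ Binomial(n, p) with n from a negative
    binomial coverage distribution. Truth maps site_id -> (p, is_ase).
    """
    rng = rng_for(config.seed, "ase")
    n = config.n_ase_sites
    n_ase = int(round(config.ase_fraction * n))
    cov = _nb_coverage(rng, n, config.coverage_mean, config.coverage_dispersion)
    is_ase = np.zeros(n, dtype=bool)
    is_ase[rng.choice(n, size=n_ase, replace=False)] = True
    if config.null_mode == "prior":
        p = rng.beta(config.alpha0, config.beta0, size=n)
    elif config.null_mode == "fixed":
        p = np.full(n, 0.5)
    else:
        raise ConfigError(f"unknown null_mode {config.null_mode!r}")
    p[is_ase] = np.where(
        rng.random(is_ase.sum()) < 0.5, config.ase_true_p, 1 - config.ase_true_p
    )
    n_a = rng.binomial(cov, p)
    sites, truth = [], {}
    for i in range(n):
        sid = f"site{i + 1:05d}"
        sites.append(AlleleCountSite(sid, int(cov[i]), int(n_a[i])))
        truth[sid] = {"p": float(p[i]), "is_ase": bool(is_ase[i])}
    return sites, truth


# ---------------------------------------------------------------------------
# Two-library counts (DE)
# ---------------------------------------------------------------------------

def simulate_counts_de(config: FixtureConfig):
    """Two-sample Poisson count table with planted fold changes.

    Null genes share the same expected rate in both libraries; DE genes have
    rate ratio 2**log2fc (half up, half down). Returns (DataFrame, truth)
    with truth[gene_id] = {"log2fc", "is_de"}.
    """
    import pandas as pd

    rng = rng_for(config.seed, "de")
    n = config.n_expr_genes
    base = rng.lognormal(mean=np.log(config.mean_count), sigma=1.0, size=n)
    lfc = np.zeros(n)
    de_idx = rng.choice(n, size=config.n_de_genes, replace=False)
    signs = np.where(rng.random(config.n_de_genes) < 0.5, 1.0, -1.0)
    lfc[de_idx] = signs * config.de_log2fc
    rate_a = base * np.power(2.0, lfc / 2.0)
    rate_b = base * np.power(2.0, -lfc / 2.0)
    count_a = rng.poisson(rate_a)
    count_b = rng.poisson(rate_b)
    lengths = rng.integers(500, 5000, size=n)
    gene_ids = [f"EG{i + 1:05d}" for i in range(n)]
    df = pd.DataFrame({
        "gene_id": gene_ids,
        "count_a": count_a,
        "count_b": count_b,
        "exonic_length": lengths,
    })
    truth = {
        g: {"log2fc": float(lfc[i]), "is_de": bool(lfc[i] != 0)}
        for i, g in enumerate(gene_ids)
    }
    return df, truth


def simulate_zscores(truth_de: dict, config: FixtureConfig,
                     detect_fraction: float = 0.6):
    """Microarray-style breed z-scores consistent with a fraction of the
    planted DE genes; null genes draw z ~ N(0, 1)."""
    rng = rng_for(config.seed, "de")
    _ = rng.random(10 * config.n_expr_genes)  # decouple from count draws
    z = {}
    for g, rec in truth_de.items():
        if rec["is_de"] and rng.random() < detect_fraction:
            z[g] = float(np.sign(rec["log2fc"]) * rng.uniform(2.5, 8.0))
        else:
            z[g] = float(rng.normal(0.0, 1.0))
    return z


# ---------------------------------------------------------------------------
# Fragments with planted read categories
# ---------------------------------------------------------------------------

def simulate_fragments(
    ann: AnnotationSet,
    genome: GenomeSequence,
    quota: dict[str, int],
    seed: int,
    frag_len: int = 50,
    flank_size: int = 1000,
) -> tuple[list[FragmentAlignment], dict]:
    """Fragments planted wholly inside exons, introns, flank-only zones or
    deep intergenic space. Truth maps read_id -> category."""
    rng = rng_for(seed, "fragments")
    frags, truth = [], {}
    exons = [e for t in ann for e in t.exons if len(e) >= frag_len]
    introns = [i for t in ann for i in t.introns if len(i) >= frag_len + 8]
    from .genomic import flank as _flank

    def gene_zones():
        zones = []
        for g in ann.genes.values():
            for side in ("5prime", "3prime"):
                f = _flank(g.extent, flank_size, side)
                if f is not None and len(f) >= frag_len:
                    # exclude zones that touch another gene or its features
                    if not any(
                        og.extent.chrom == f.chrom
                        and og.extent.start < f.end and f.start < og.extent.end
                        for og in ann.genes.values()
                    ):
                        zones.append(f)
        return zones

    flanks = gene_zones()
    counter = 0

    def add(iv: GenomeInterval, category: str) -> None:
        nonlocal counter
        counter += 1
        rid = f"frag{counter:05d}"
        frags.append(FragmentAlignment(rid, [iv]))
        truth[rid] = category

    for _ in range(quota.get("exon", 0)):
        e = exons[int(rng.integers(len(exons)))]
        s = int(rng.integers(e.start, e.end - frag_len + 1))
        add(GenomeInterval(e.chrom, s, s + frag_len), "exon")
    for _ in range(quota.get("intron", 0)):
        if not introns:
            raise ConfigError("no introns wide enough for intronic fragments")
        i = introns[int(rng.integers(len(introns)))]
        s = int(rng.integers(i.start + 4, i.end - frag_len - 4))
        add(GenomeInterval(i.chrom, s, s + frag_len), "intron")
    for _ in range(quota.get("flank", 0)):
        if not flanks:
            raise ConfigError("no clean flank zones available")
        f = flanks[int(rng.integers(len(flanks)))]
        s = int(rng.integers(f.start, f.end - frag_len + 1))
        add(GenomeInterval(f.chrom, s, s + frag_len), "flank")
    placed = 0
    attempts = 0
    while placed < quota.get("intergenic", 0):
        attempts += 1
        if attempts > 100 * quota.get("intergenic", 1):
            raise ConfigError("cannot place intergenic fragments")
        chrom = sorted(genome.seqs)[int(rng.integers(len(genome.seqs)))]
        s = int(rng.integers(0, genome.length(chrom) - frag_len))
        iv = GenomeInterval(chrom, s, s + frag_len)
        near = any(
            g.extent.chrom == chrom
            and g.extent.start - flank_size < iv.end
            and iv.start < g.extent.end + flank_size
            for g in ann.genes.values()
        )
        if near:
            continue
        add(iv, "intergenic")
        placed += 1
    return frags, truth


# ---------------------------------------------------------------------------
# Transcript class-code fixtures
# ---------------------------------------------------------------------------

def plant_transcript_classes(seed: int, per_code: int = 2):
    """A reference annotation plus query transcripts with planted class
    codes covering all eight codes. Returns (ref, queries, truth)."""
    rng = rng_for(seed, "classes")
    refs = []
    queries = []
    truth = {}
    chrom = "chrT"
    base = 5000
    spacing = 30_000
    qi = 0

    def q(exons, code):
        nonlocal qi
        qi += 1
        tid = f"Q{qi:03d}"
        queries.append(TranscriptModel(tid, tid, exons))
        truth[tid] = code

    for rep in range(per_code):
        off = base + rep * 8 * spacing
        for k, code in enumerate("=cjeiopu"):
            o = off + k * spacing
            jitter = int(rng.integers(0, 50))
            # reference: three exons of 400 bp, introns of 600 bp
            e = [
                GenomeInterval(chrom, o, o + 400, "+"),
                GenomeInterval(chrom, o + 1000, o + 1400, "+"),
                GenomeInterval(chrom, o + 2000, o + 2400, "+"),
            ]
            rid = f"R{rep}{k}"
            refs.append(TranscriptModel(rid, rid, e, biotype="protein_coding"))
            if code == "=":
                q([GenomeInterval(chrom, o + 50 + jitter, o + 400, "+"),
                   GenomeInterval(chrom, o + 1000, o + 1400, "+"),
                   GenomeInterval(chrom, o + 2000, o + 2300, "+")], "=")
            elif code == "c":
                q([GenomeInterval(chrom, o + 100, o + 300 + jitter, "+")], "c")
            elif code == "j":
                q([GenomeInterval(chrom, o + 200, o + 400, "+"),
                   GenomeInterval(chrom, o + 1000, o + 1100 + jitter, "+"),
                   GenomeInterval(chrom, o + 1200 + jitter, o + 1400, "+")], "j")
            elif code == "e":
                q([GenomeInterval(chrom, o + 300, o + 450 + jitter, "+")], "e")
            elif code == "i":
                q([GenomeInterval(chrom, o + 500, o + 800 + jitter, "+")], "i")
            elif code == "o":
                q([GenomeInterval(chrom, o - 200, o + 200 + jitter, "+")], "o")
            elif code == "p":
                q([GenomeInterval(chrom, o + 3400 + jitter, o + 3800 + jitter, "+")],
                  "p")
            elif code == "u":
                q([GenomeInterval(chrom, o + 9000 + jitter, o + 9400 + jitter, "+")],
                  "u")
    return AnnotationSet(refs), queries, truth


# ---------------------------------------------------------------------------
# lncRNA cascade fixture
# ---------------------------------------------------------------------------

def make_lncrna_fixture(config: FixtureConfig):
    """Reference coding genes, assembled transcripts and evidence/homology
    tables constructed so the cascade yields exactly the planted outcomes.

    Truth maps transcript_id -> planted outcome (a removal reason or a final
    conservation category).
    """
    rng = rng_for(config.seed, "lncrna")
    chrom = "chrL"
    refs = []
    spacing = 12_000
    n_ref = 6
    for i in range(n_ref):
        o = 5000 + i * spacing
        e = [GenomeInterval(chrom, o, o + 500, "+"),
             GenomeInterval(chrom, o + 1100, o + 1600, "+")]
        cds = [GenomeInterval(chrom, o + 99, o + 500, "+"),
               GenomeInterval(chrom, o + 1100, o + 1199, "+")]
        refs.append(TranscriptModel(f"PC{i + 1}", f"PCG{i + 1}", e, cds,
                                    biotype="protein_coding"))
    reference = AnnotationSet(refs)

    assembled = []
    evidence: dict[str, EvidenceRecord] = {}
    hits: list[HomologyHit] = []
    truth: dict[str, str] = {}
    counter = 0
    far_cursor = [5000 + n_ref * spacing + 5000]

    def new_transcript(far: bool = True) -> TranscriptModel:
        nonlocal counter
        counter += 1
        tid = f"A{counter:03d}"
        length = int(rng.integers(300, 800))
        if far:
            s = far_cursor[0]
            far_cursor[0] += length + 3000
        else:
            # 200-900 bp away from a reference gene: fails the 1 kb rule
            ref = refs[int(rng.integers(len(refs)))]
            s = ref.end + int(rng.integers(200, 900 - length)) if length < 700 \
                else ref.end + 200
        return TranscriptModel(tid, tid, [GenomeInterval(chrom, s, s + length, "+")],
                               biotype="lncRNA_candidate")

    def sim() -> float:
        return float(rng.uniform(0.5, 1.0))

    quota = config.lncrna_quota
    for reason, n in quota.items():
        for _ in range(n):
            if reason == "removed_distance":
                t = new_transcript(far=False)
                evidence[t.transcript_id] = EvidenceRecord()
            else:
                t = new_transcript(far=True)
            tid = t.transcript_id
            if reason == "removed_distance":
                pass  # evidence already blank; the distance rule removes it
            elif reason == "removed_coding":
                evidence[tid] = EvidenceRecord(coding_call="complete")
            elif reason == "removed_protein":
                evidence[tid] = EvidenceRecord(
                    protein_hits=[("sp|XXXX", float(10 ** -rng.uniform(6, 12)))]
                )
            elif reason == "removed_domain":
                evidence[tid] = EvidenceRecord(
                    domain_hits=[("PF00001", float(10 ** -rng.uniform(6, 12)))]
                )
            elif reason == "removed_rfam":
                evidence[tid] = EvidenceRecord(rna_family_hits=["RF00001"])
            elif reason == "removed_human_full":
                evidence[tid] = EvidenceRecord()
                hits.append(HomologyHit(tid, "human", float(rng.uniform(0.75, 0.95)),
                                        sim(), "protein_coding_exon_full"))
            elif reason == "repeat_containing":
                evidence[tid] = EvidenceRecord(repeat_flag=True)
                if rng.random() < 0.5:
                    hits.append(HomologyHit(tid, "cow", float(rng.uniform(0.75, 0.95)),
                                            sim(), "unannotated"))
            elif reason == "conserved_incl_human":
                evidence[tid] = EvidenceRecord()
            elif reason == "artiodactyl_only":
                evidence[tid] = EvidenceRecord()
                hits.append(HomologyHit(tid, "cow", float(rng.uniform(0.75, 0.95)),
                                        sim(), "unannotated"))
                # a human hit below the coverage bar must be discarded
                hits.append(HomologyHit(tid, "human", float(rng.uniform(0.3, 0.65)),
                                        sim(), "unannotated"))
            elif reason == "no_homolog":
                evidence[tid] = EvidenceRecord()
                if rng.random() < 0.5:
                    hits.append(HomologyHit(tid, "mouse", float(rng.uniform(0.2, 0.6)),
                                            sim(), "unannotated"))
            else:
                raise ConfigError(f"unknown lncRNA quota key {reason!r}")
            assembled.append(t)
            truth[tid] = reason

    # distribute human subclasses among the conserved_incl_human transcripts
    conserved = [tid for tid, r in truth.items() if r == "conserved_incl_human"]
    sub_quota = dict(config.human_subclass_quota)
    if sum(sub_quota.values()) != len(conserved):
        raise ConfigError("human_subclass_quota must sum to conserved_incl_human quota")
    cls_map = {"unannotated": "unannotated",
               "protein_coding_overlap": "protein_coding_partial",
               "known_lncRNA": "lncRNA", "pseudogene": "pseudogene"}
    sub_truth = {}
    i = 0
    for sub, n in sub_quota.items():
        for _ in range(n):
            tid = conserved[i]
            i += 1
            hits.append(HomologyHit(tid, "human", float(rng.uniform(0.75, 0.95)),
                                    sim(), cls_map[sub]))
            sub_truth[tid] = sub
    return {
        "reference": reference,
        "assembled": AnnotationSet(assembled),
        "evidence": evidence,
        "hits": hits,
        "truth": truth,
        "human_subclass_truth": sub_truth,
    }
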