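import io

import pytest

from pigtx.genomic import AnnotationSet, GenomeInterval, GenomeSequence, TranscriptModel
from pigtx.variants import (
    VariantCall,
    classify_effect,
    filter_variants,
    read_vcf,
    remove_splice_proximal,
    select_ase_sites,
    snp_rate,
    write_vcf,
)

# independent codon table for oracle checks (not the Biopython path the
# implementation uses)
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
_COMP = str.maketrans("ACGT", "TGCA")


def call(genotype="het", quality=20.0, depth=10, counts=(5, 5), pos=0,
         chrom="chr1", ref="A", alt="G"):
    return VariantCall(chrom, pos, ref, alt, quality, depth, genotype, counts)


class TestFilterVariants:
    @pytest.mark.parametrize(
        "genotype,quality,depth,kept_as",
        [
            ("het", 9, 10, None),          # quality floor 10
            ("hom_alt", 20, 3, "fixed"),   # depth 3x suffices for fixed
            ("hom_alt", 20, 2, None),
            ("het", 20, 3, None),          # segregating needs 4x
            ("het", 20, 4, "segregating"),
            ("het", 10, 10, "segregating"),  # quality 10 passes (>= 10)
        ],
    )
    def test_boundaries(self, genotype, quality, depth, kept_as):
        counts = (depth // 2, depth - depth // 2) if genotype == "het" else (0, depth)
        fixed, seg = filter_variants([call(genotype, quality, depth, counts)])
        got = "fixed" if fixed else ("segregating" if seg else None)
        assert got == kept_as

    def test_monotone_in_thresholds(self, planted_variants):
        calls, _ = planted_variants
        base = sum(map(len, filter_variants(calls)))
        stricter = sum(map(len, filter_variants(calls, min_quality=30)))
        deeper = sum(map(len, filter_variants(calls, min_depth_fixed=10,
                                              min_depth_segregating=10)))
        assert stricter <= base and deeper <= base


class TestSelectAseSites:
    @pytest.mark.parametrize(
        "genotype,quality,depth,counts,selected",
        [
            ("het", 11, 6, (4, 2), True),
            ("het", 30, 6, (5, 1), False),   # allele count floor 2
            ("het", 10, 10, (5, 5), False),  # strict > 10
            ("het", 10.5, 4, (2, 2), True),
            ("het", 30, 3, (2, 1), False),   # depth floor 4
            ("hom_alt", 30, 10, (0, 10), False),
        ],
    )
    def test_boundaries(self, genotype, quality, depth, counts, selected):
        got = select_ase_sites([call(genotype, quality, depth, counts)])
        assert bool(got) == selected


class TestSpliceProximal:
    @pytest.fixture(scope="class")
    def ann(self):
        t = TranscriptModel(
            "t", "g",
            [GenomeInterval("chr1", 100, 200), GenomeInterval("chr1", 300, 400)],
        )
        return AnnotationSet([t])

    def test_intronic_donor_site_removed(self, ann):
        assert remove_splice_proximal([call(pos=200)], ann, window_bp=2) == []
        assert remove_splice_proximal([call(pos=201)], ann, window_bp=2) == []

    def test_mid_exon_retained(self, ann):
        kept = remove_splice_proximal([call(pos=150)], ann, window_bp=2)
        assert len(kept) == 1

    def test_window_zero_rejected(self, ann):
        with pytest.raises(ValueError):
            remove_splice_proximal([], ann, window_bp=0)


class TestClassifyEffect:
    def test_planted_consequences_recovered(self, genome_annotation,
                                            planted_variants):
        genome, ann, _ = genome_annotation
        calls, truth = planted_variants
        for c in calls:
            assert classify_effect(c, ann, genome) == truth[c.site_id]

    def test_codon_calls_match_independent_table(self, genome_annotation,
                                                 planted_variants):
        """Re-derive coding consequences by translating both haplotypes with
        a hand-coded codon table and the planted gene layout."""
        genome, ann, truth_layout = genome_annotation
        calls, truth = planted_variants
        checked = 0
        for c in calls:
            if truth[c.site_id] not in (
                "synonymous_coding", "non_synonymous_coding",
                "stop_gained", "stop_lost",
            ):
                continue
            t = next(
                t for t in ann.query(c.chrom, c.pos, c.pos + 1)
                if any(iv.start <= c.pos < iv.end for iv in t.cds_intervals)
            )
            g = truth_layout["genes"][t.gene_id]
            cds_pos = g["pos_tx"][g["u5"] : g["u5"] + g["cds_len"]]

            def tx_seq(allele):
                out = []
                for p in cds_pos:
                    b = allele if p == c.pos else genome.fetch(c.chrom, p, p + 1)
                    out.append(b if t.strand == "+" else b.translate(_COMP))
                return "".join(out)

            ref_aa = [CODON_TABLE[tx_seq(c.ref_allele)[i : i + 3]]
                      for i in range(0, len(cds_pos), 3)]
            alt_aa = [CODON_TABLE[tx_seq(c.alt_allele)[i : i + 3]]
                      for i in range(0, len(cds_pos), 3)]
            diff = [(r, a) for r, a in zip(ref_aa, alt_aa) if r != a]
            if not diff:
                expected = "synonymous_coding"
            elif diff[0][0] == "*":
                expected = "stop_lost"
            elif diff[0][1] == "*":
                expected = "stop_gained"
            else:
                expected = "non_synonymous_coding"
            assert classify_effect(c, ann, genome) == expected == truth[c.site_id]
            checked += 1
        assert checked >= 10

    def test_partition_sums(self, genome_annotation, planted_variants):
        from pigtx.variants import effect_table

        genome, ann, _ = genome_annotation
        calls, _ = planted_variants
        fixed, seg = filter_variants(calls)
        table = effect_table(fixed + seg, ann, genome)
        assert int(table.sum()) == len(fixed) + len(seg)

    def test_upstream_by_construction(self):
        t = TranscriptModel("t", "g", [GenomeInterval("chr1", 5000, 6000, "+")])
        ann = AnnotationSet([t])
        genome = GenomeSequence({"chr1": "A" * 10_000})
        c = call(pos=4500, ref="A", alt="C")
        assert classify_effect(c, ann, genome, flank_bp=1000) == "upstream5"
        c2 = call(pos=3500, ref="A", alt="C")
        assert classify_effect(c2, ann, genome, flank_bp=1000) == "intergenic"


class TestSnpRate:
    @pytest.mark.parametrize(
        "n,bp,expected", [(50, 100_000, 0.5), (0, 1000, 0.0), (170, 10**6, 0.17)]
    )
    def test_values(self, n, bp, expected):
        assert snp_rate(n, bp) == pytest.approx(expected)

    def test_zero_coverage_rejected(self):
        with pytest.raises(ValueError):
            snp_rate(10, 0)


class TestVcfRoundTrip:
    def test_round_trip(self, planted_variants):
        calls, _ = planted_variants
        text = write_vcf(calls)
        back = read_vcf(io.StringIO(text))
        key = lambda c: (c.chrom, c.pos)
        for a, b in zip(sorted(calls, key=key), sorted(back, key=key)):
            assert a == b

    def test_multiallelic_warns_and_keeps_major(self):
        text = ("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
                "chr1\t10\t.\tA\tG,T\t30\t.\tDP=12\n")
        with pytest.warns(UserWarning, match="multi-allelic"):
            calls = read_vcf(io.StringIO(text))
        assert calls[0].alt_allele == "G"
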