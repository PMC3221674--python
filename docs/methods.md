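# Methods

## Allele-specific expression model

Each selected heterozygous site contributes counts `(n, n_a)`, with `n_a`
the reads carrying one focal allele (ALT by default; a seeded
`randomize_alleles` mode picks the allele arbitrarily, which leaves the
decision unchanged under a symmetric prior). The model is beta-binomial:
`n_a | p ~ Binomial(n, p)` with `p ~ Beta(α, β)`, giving the conjugate
posterior `Beta(α + n_a, β + n − n_a)`.

**Empirical-Bayes fit.** (α, β) are estimated by the method of moments on
the observed fractions `n_a/n`: with sample mean `m` and variance `v`,
`c = m(1−m)/v − 1`, `α = mc`, `β = (1−m)c`. The fit requires at least 10
sites and `0 < v < m(1−m)`; outside that range no Beta distribution has the
requested moments and the fit refuses rather than clamping. Fitting to raw
fractions (not via the beta-binomial likelihood) deliberately mirrors the
study pipeline this package reimplements; a marginal-likelihood fit would
attribute part of the observed variance to binomial noise and return a
tighter prior. Consequently, on counts rather than pure Beta draws the
moment fit is biased toward larger spread — the parameter-recovery tests
therefore exercise the pure-Beta path only.

**Decision rule.** A site is called ASE when the 95% highest density region
of the posterior excludes 0.5 (closed-interval convention: 0.5 exactly on
an endpoint is *not* significant). For a unimodal Beta the HDR is the
shortest interval at the target mass, found by minimising the
interval-width objective `w(q) = F⁻¹(q + 0.95) − F⁻¹(q)` over
`q ∈ [0, 0.05]`: a 512-point scan brackets the global minimum and bounded
scalar minimisation (tolerance 1e-12 in `q`) refines it, so the returned
interval has exactly the target mass by construction and endpoints agree
with a 10⁵-point grid search to ~1e-7. Symmetric posteriors short-circuit
to the equal-tailed interval, which for `α = β` is provably shortest and
fixes the non-unique flat case `Beta(1, 1)` to the centred (0.025, 0.975).
For `α ≤ 1` or `β ≤ 1` the width objective is monotone and the scan finds
the one-sided interval.

Properties guaranteed by the construction and verified in the test suite:
for fixed `n` the significant set in `n_a` is a lower tail plus an upper
tail; at a fixed intermediate fraction (0.65) significance switches on at a
single coverage threshold (n* = 50 under a symmetric Beta(6.29, 6.29)
prior); extreme fractions (≥ 0.95) are significant from n = 20; a balanced
site never is; and the decision is invariant to allele relabelling under a
symmetric prior. The fixed-fraction sweeps hold the fraction exact by
passing continuous pseudo-counts `n_a = f·n` — the conjugate algebra is
well-defined for real-valued counts, and integer rounding would jitter the
realized fraction across the sweep. No multiple-testing correction is
applied by default, matching the single-site decision rule; BH adjustment
is available in `expression.go_fisher` where enrichment p-values are
produced in bulk.

## Variant pipeline

Discovery filtering retains calls with quality ≥ 10 and depth ≥ 3× for
homozygous-alternate ("fixed" against the assembly) or ≥ 4× for
heterozygous ("segregating") sites. ASE site selection is stricter —
quality strictly > 10, depth ≥ 4, both allele counts ≥ 2 — reflecting the
two different rules the pipeline applies at the two stages. Splice-proximal
calls (within 2 bp of an exon–intron boundary by default) can be removed
because alignment around junctions is unreliable; removal and
classification windows are independent parameters, and the default order
annotates before removal, so a "splice site" consequence class still
exists.

Consequence classification uses precedence splice_site > coding (codon
translation of ref vs alt on the coding strand: synonymous /
non-synonymous / stop gained / stop lost, most severe across transcripts) >
5'/3' UTR > intronic > within-non-coding-gene > 1 kb strand-aware flanks
(nearest gene wins) > intergenic. CDS lengths must be divisible by 3;
violations raise rather than truncate. Multi-allelic records keep the first
alternate allele with a warning.

## Read and transcript classification

Fragments are classified exon > intron > flank > intergenic; a class wins
when its features cover at least `min_overlap` fragment bases (default
1 nt, summed across alignment blocks with per-class interval union so a
fragment spanning two exons counts both). Raising `min_overlap` can only
demote a fragment — the direction of the drop seen when the overlap
requirement is raised from 1 nt to a full read length.

Assembled transcripts receive a single class code against the reference by
precedence `=` (identical intron chain; mono-exon queries need ≥ 95%
reciprocal span overlap) > `c` (contained and intron-compatible) > `j`
(shares ≥ 1 junction, chain differs) > `e` (mono-exon over a ref exon with
≥ 10 bp ref-intron overlap: unspliced pre-mRNA signature) > `i` (inside a
ref intron) > `o` (other exonic overlap) > `p` (within 2 kb downstream of a
ref end with no overlap: polymerase run-on) > `u` (intergenic). The run-on
window and pre-mRNA intron-overlap minimum are configurable since no
canonical values exist.

## lncRNA cascade

Four stages, each only removing candidates: (1) distance — no overlap with
and ≥ 1000 bp ("at least 1 kb", inclusive) from any protein-coding gene
extent; (2) evidence — removed on complete predicted coding potential, any
protein or domain hit with e-value strictly below 10⁻⁵, or any
structured-RNA family hit (any-hit rule: family membership is a class
statement, not a similarity score); (3) human overlap — removed only when
the human homologue is fully inside protein-coding exons, partial overlaps
are kept and flagged; (4) conservation — hits retained at coverage strictly
above 0.70 of the pig query, best hit per (transcript, genome) by
similarity; categories: repeat-containing ≻ conserved-including-human ≻
Artiodactyla-only (cow without human) ≻ no-homolog, plus a human-locus
subclassification (unannotated / protein-coding overlap / known lncRNA /
pseudogene). External aligners and databases are never executed; their
tabular outputs are the interface, which makes the cascade deterministic
and directly testable.

## Differential expression

The two-library, no-replicate test is a two-sided exact binomial test of a
gene's count in library A among its pooled counts against the proportion
implied by the library sizes. This is a deliberate, documented stand-in
for the published MA-plot random-sampling statistic used in the original
two-sample design — same null (counts split by library size), exact rather
than sampled. A gene is "expressed" at ≥ 40 pooled counts; DE requires
P < 0.001 and linear fold change > 2 (|log2 FC| > 1; infinite fold changes
from a zero denominator pass the fold-change arm). Cross-platform
confirmation intersects the DE set with microarray breed z-scores at
|z| > 1.65 (strict). FPKM bins are half-open decades `[lo, hi)` — the
descriptive prose this follows had overlapping ranges ("10–1000" and
"10–100"), which non-overlapping half-open bins resolve. GO enrichment is a
per-term two-sided Fisher exact test of DE membership against the
background, raw p-values by default (BH optional) to match the raw
P < 10⁻³ reporting convention.

## Synthetic data

All generators draw from per-generator substreams of one global seed
(`SeedSequence` spawn keys), so outputs are byte-identical under a seed and
adding a generator never perturbs existing ones. Defaults are the study
conditions where stated: coverage negative-binomial with means 55 / 121
(the two samples' mean ASE coverages, dispersion 5 for overdispersion
realism), null overdispersion Be(4.99, 3.84) (the fitted Large White
prior), ASE sites planted at rate 0.9 on a random allele, DE genes planted
at |log2 FC| = 3 among Poisson nulls. Genome fixtures default to 2 × 100 kb
chromosomes with 24 genes so the whole suite runs in about a minute; gene
spacing (≥ 2.6 kb) guarantees clean flank-only and intergenic zones.
Planted CDSs have valid start/stop codons and stop-free interiors on
either strand; planted variants are constructed so that independent
re-annotation recovers the category, and planted stop-gain/loss sites are
verified codon-level in the tests against a hand-coded codon table
independent of the implementation's translator.

What the fixtures do **not** emulate: read-level sequences and alignment
artifacts (fragments arrive as intervals), mapping bias between alleles,
haplotype/linkage structure, transcript-assembly fragmentation, and real
annotation incompleteness. Passing the planted-truth tests therefore
demonstrates that the *rules and statistics* are implemented correctly, not
that the pipeline is robust to alignment pathologies — the two null modes
of the allele-count generator (`fixed`: p = 0.5; `prior`: p drawn from the
overdispersed prior) bracket the realistic range of null behaviour.

## Numerical choices and limitations

- HDR: ICDF-width minimisation with coarse-scan bracketing; achieved mass
  exact by construction; flat/symmetric tie-breaks centred.
- Moment fit refuses infeasible moments instead of clamping; degenerate
  (zero-variance) samples are an error.
- Fold changes use ±inf / NaN sentinels; correlations drop non-finite
  pairs and return NaN below 3 pairs or at zero variance.
- Unstranded features are treated as + strand for flank logic.
- Exact binomial DE p-values are conservative for discrete counts (null
  fraction below a threshold is at most the threshold), which the
  calibration test exploits.
- The classifiers assume a non-overlapping gene layout in fixtures; real
  annotations with nested or overlapping genes exercise the documented
  precedence rules but were not the design target.
- Reported study-scale counts (significant-site totals per sample,
  lncRNA category totals, DE-gene counts) depend on the original
  sequencing data and database versions and are out of scope; the package
  reproduces the schemes and verifies them on planted fixtures.
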