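# pigtx

Analysis toolkit for two-breed pig testis RNA-seq: allele-specific
expression (ASE) inference with an empirical-Bayes beta-binomial model, SNP
filtering and consequence annotation, read/transcript classification against
a genome annotation, a long-non-coding-RNA filter cascade with mammalian
conservation categories, and two-library differential-expression calling
intersected with microarray breed scores. Every stage can be exercised on
built-in seeded synthetic data with planted ground truth, so the whole
pipeline is testable without any external downloads.

## Who this is for

Researchers analysing low-replicate livestock RNA-seq — in the motivating
design, one Large White and one Iberian pig gonad transcriptome — who need
the bespoke statistical steps of such a study as reusable, tested library
code rather than one-off scripts.

## The core model

At a heterozygous SNP covered by `n` reads of which `n_a` support one
allele, the allele transcription rate `p` is modelled as

    n_a | p ~ Binomial(n, p),        p ~ Beta(α, β)

so the posterior is the conjugate `Beta(α + n_a, β + n − n_a)`. The
hyperparameters (α, β) are fitted empirically by matching the Beta mean and
variance to the observed allele fractions `n_a/n` across all selected sites
(method of moments). A site shows ASE when the **95% highest density
region** (HDR) — the shortest interval containing 95% posterior mass,
found by minimising `icdf(q + 0.95) − icdf(q)` over `q` — excludes
`p = 0.5`. Low-coverage sites are dominated by the prior and are only called
at extreme allele fractions; as coverage grows, progressively milder
imbalance becomes detectable.

Around this core the package implements the pipeline's deterministic rules
exactly as printed in the study design: SNP quality ≥ 10 with depth ≥ 3×
(fixed) / 4× (segregating); ASE site selection at quality > 10, depth ≥ 4,
both alleles ≥ 2 reads; lncRNA candidates ≥ 1 kb from coding annotation,
removed on complete coding potential or protein/domain hits at e < 10⁻⁵ or
any structured-RNA family hit, with conservation requiring > 70% query
coverage; DE at P < 0.001 and fold change > 2, intersected with microarray
breed z-scores at |z| > 1.65.

## Worked example

```python
from pigtx import fit_hyperparameters, test_ase
from pigtx.ase import summarize_ase, test_sites
from pigtx.simulate import FixtureConfig, simulate_allele_counts

cfg = FixtureConfig(seed=1, n_ase_sites=2000, ase_fraction=0.04,
                    coverage_mean=55, null_mode="fixed")
sites, truth = simulate_allele_counts(cfg)

prior = fit_hyperparameters([s.n_a / s.n for s in sites])
print(f"fitted prior: alpha={prior.alpha:.2f} beta={prior.beta:.2f}")

for sid in ("site00004", "site00002"):
    s = next(x for x in sites if x.site_id == sid)
    r = test_ase(s, prior)
    print(f"{s.site_id}: n={s.n} n_a={s.n_a} p_mean={r.p_mean:.3f} "
          f"HDR=({r.hdr[0]:.3f}, {r.hdr[1]:.3f}) ASE={r.significant}")

summary = summarize_ase(test_sites(sites, prior))
print(f"significant: {summary['n_significant']}/{summary['n_sites']} "
      f"({summary['pct_significant']:.1f}%), mean coverage "
      f"{summary['mean_coverage_significant']:.0f}x")
```

prints

```
fitted prior: alpha=9.93 beta=10.13
site00004: n=38 n_a=26 p_mean=0.619 HDR=(0.494, 0.741) ASE=False
site00002: n=21 n_a=0 p_mean=0.242 HDR=(0.118, 0.372) ASE=True
significant: 124/2000 (6.2%), mean coverage 58x
```

2,000 simulated heterozygous sites at mean coverage 55× contain 4% planted
ASE sites (true allele rate 0.9); the rest are balanced. The fitted prior is
pulled toward symmetry by the balanced majority. Site 4 (26/38 reads, 68%)
is *not* called — its HDR still touches 0.5 at this coverage — while the
fully skewed site 2 is. The 6.2% significant fraction is the 4% planted
signal plus the null sites flagged at the 95% level.

The same API covers the other stages: `pigtx.variants` (filtering,
splice-proximal removal, codon-level consequence calls), `pigtx.reads`
(fragment categories and transcript class codes `= c e i j o p u`),
`pigtx.lncrna` (the filter cascade and conservation matrix),
`pigtx.expression` (FPKM, exact-binomial DE test, platform intersection,
Fisher GO enrichment), and `pigtx.simulate` (all fixtures). A `pigtx`
command-line entry point wraps each stage (`pigtx --help`).

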