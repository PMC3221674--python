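"""Empirical-Bayes beta-binomial test for allele-specific expression (ASE).

At a heterozygous site with ``n`` reads of which ``n_a`` support one
(arbitrarily chosen) allele, the allele transcription rate ``p`` has the
conjugate posterior Be(α + n_a, β + n − n_a) under a Be(α, β) prior and a
binomial read-count likelihood. The prior hyperparameters are fitted
empirically by matching the Beta mean and variance to the observed allele
fractions n_a/n across all selected sites. A site shows ASE when the 95%
highest density region (HDR) of the posterior — the shortest interval holding
95% posterior mass — excludes p = 0.5.

The HDR is found by minimising ``icdf(q + mass) − icdf(q)`` over
q ∈ [0, 1 − mass] (the interval-width parameterisation of the highest-density
interval): a coarse scan brackets the global minimum, then bounded scalar
minimisation refines it. For symmetric posteriors the HDR equals the
equal-tailed interval; for the flat Beta(1,1), whose HDR is non-unique, the
centred interval is returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass(frozen=True)
class BetaParams:
    """Shape parameters of a Beta distribution; both must be positive."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha) and np.isfinite(self.beta)):
            raise ValueError("Beta parameters must be finite")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("Beta parameters must be positive")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def variance(self) -> float:
        s = self.alpha + self.beta
        return self.alpha * self.beta / (s * s * (s + 1.0))


@dataclass(frozen=True)
class AlleleCountSite:
    """Read counts at one heterozygous site: n total, n_a for one allele."""

    site_id: str
    n: float
    n_a: float

    def __post_init__(self) -> None:
        if not (0 <= self.n_a <= self.n):
            raise ValueError(f"{self.site_id}: need 0 ≤ n_a ≤ n")


@dataclass(frozen=True)
class ASEResult:
    site_id: str
    posterior: BetaParams
    p_mean: float
    hdr: tuple[float, float]
    significant: bool
    n: float = float("nan")


def beta_from_moments(mean: float, variance: float) -> BetaParams:
    """Beta(α, β) with the given mean and variance (method of moments)."""
    if not (0.0 < mean < 1.0):
        raise ValueError("mean must lie in (0, 1)")
    if variance <= 0.0:
        raise ValueError("variance must be positive (degenerate sample)")
    if variance >= mean * (1.0 - mean):
        raise ValueError(
            "variance too large for a Beta distribution "
            f"(v={variance:.4g} ≥ m(1−m)={mean * (1 - mean):.4g})"
        )
    c = mean * (1.0 - mean) / variance - 1.0
    return BetaParams(mean * c, (1.0 - mean) * c)


def fit_hyperparameters(fractions) -> BetaParams:
    """Empirical-Bayes prior: match Beta mean/variance to observed n_a/n.

    Requires at least 10 sites and a sample variance inside the Beta-feasible
    range 0 < v < m(1 − m).
    """
    x = np.asarray(list(fractions), dtype=float)
    if x.size < 10:
        raise ValueError(f"need ≥ 10 fractions to fit a prior, got {x.size}")
    if np.any((x < 0) | (x > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    return beta_from_moments(float(x.mean()), float(x.var(ddof=1)))


def posterior_update(prior: BetaParams, site: AlleleCountSite) -> BetaParams:
    """Conjugate update: Be(α + n_a, β + n − n_a)."""
    return BetaParams(prior.alpha + site.n_a, prior.beta + site.n - site.n_a)


def hdr_beta(params: BetaParams, mass: float = 0.95, *, _scan: int = 512) -> tuple[float, float]:
    """Shortest interval with ``mass`` probability under Beta(α, β).

    Returned as (lo, hi) with cdf(hi) − cdf(lo) = mass to numerical
    precision. Non-unique cases (flat density) return the centred interval.
    """
    if not (0.0 < mass < 1.0):
        raise ValueError("mass must be in (0, 1)")
    a, b = params.alpha, params.beta
    dist = stats.beta(a, b)
    if a == b:
        # symmetric: the equal-tailed interval is shortest (centred tie-break
        # for the flat a = b = 1 case)
        q = (1.0 - mass) / 2.0
        return float(dist.ppf(q)), float(dist.ppf(q + mass))

    def width(q: float) -> float:
        return dist.ppf(q + mass) - dist.ppf(q)

    qmax = 1.0 - mass
    grid = np.linspace(0.0, qmax, _scan)
    widths = dist.ppf(grid + mass) - dist.ppf(grid)
    k = int(np.argmin(widths))
    lo_b = grid[max(k - 1, 0)]
    hi_b = grid[min(k + 1, _scan - 1)]
    if hi_b > lo_b:
        res = optimize.minimize_scalar(
            width, bounds=(lo_b, hi_b), method="bounded",
            options={"xatol": 1e-12},
        )
        q = float(res.x) if res.fun <= widths[k] else float(grid[k])
    else:
        q = float(grid[k])
    return float(dist.ppf(q)), float(dist.ppf(q + mass))


def test_ase(
    site: AlleleCountSite, prior: BetaParams, mass: float = 0.95
) -> ASEResult:
    """Posterior, its HDR, and the ASE call for one site.

    ASE is declared when 0.5 falls outside the closed HDR interval.
    """
    post = posterior_update(prior, site)
    p_mean = post.mean
    lo, hi = hdr_beta(post, mass)
    significant = not (lo <= 0.5 <= hi)
    return ASEResult(site.site_id, post, p_mean, (lo, hi), significant, n=site.n)


def test_sites(
    sites, prior: BetaParams, mass: float = 0.95
) -> list[ASEResult]:
    return [test_ase(s, prior, mass) for s in sites]


def summarize_ase(results) -> dict:
    """Counts, percentage and mean coverage of significant sites."""
    results = list(results)
    total = len(results)
    sig = [r for r in results if r.significant]
    mean_cov = float(np.mean([r.n for r in sig])) if sig else float("nan")
    return {
        "n_sites": total,
        "n_significant": len(sig),
        "pct_significant": 100.0 * len(sig) / total if total else 0.0,
        "mean_coverage_significant": mean_cov,
    }


def ase_table(results) -> pd.DataFrame:
    """Plot-ready per-site table (coverage vs posterior mean vs call)."""
    return pd.DataFrame(
        {
            "site_id": [r.site_id for r in results],
            "n": [r.n for r in results],
            "alpha_post": [r.posterior.alpha for r in results],
            "beta_post": [r.posterior.beta for r in results],
            "p_mean": [r.p_mean for r in results],
            "hdr_lo": [r.hdr[0] for r in results],
            "hdr_hi": [r.hdr[1] for r in results],
            "significant": [r.significant for r in results],
        }
    )


def compare_samples(results_a, results_b) -> dict:
    """Sites significant in both samples, split by allele-direction agreement.

    A shared site is discordant when the posterior means fall on opposite
    sides of 0.5 in the two samples (different allele over-expressed).
    """
    sig_a = {r.site_id: r for r in results_a if r.significant}
    sig_b = {r.site_id: r for r in results_b if r.significant}
    shared = sorted(set(sig_a) & set(sig_b))
    discordant = [
        s for s in shared
        if (sig_a[s].p_mean - 0.5) * (sig_b[s].p_mean - 0.5) < 0
    ]
    return {
        "shared": shared,
        "n_shared": len(shared),
        "n_discordant": len(discordant),
        "discordant": discordant,
    }


class BetaBinomialASE:
    """Fit-then-test convenience wrapper around the module functions.

    ``fit`` estimates the empirical-Bayes prior from observed allele
    fractions; ``test_site``/``test_sites`` apply the HDR decision rule with
    that prior.
    """

    def __init__(self, mass: float = 0.95, prior: BetaParams | None = None):
        self.mass = mass
        self.prior = prior

    def fit(self, sites) -> "BetaBinomialASE":
        fracs = [s.n_a / s.n for s in sites if s.n > 0]
        self.prior = fit_hyperparameters(fracs)
        return self

    def test_site(self, site: AlleleCountSite) -> ASEResult:
        if self.prior is None:
            raise ValueError("fit() first or pass an explicit prior")
        return test_ase(site, self.prior, self.mass)

    def test_sites(self, sites) -> list[ASEResult]:
        return [self.test_site(s) for s in sites]
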