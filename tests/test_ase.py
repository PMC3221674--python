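import numpy as np
import pytest
from scipy import integrate, stats

from pigtx.ase import (
    AlleleCountSite,
    BetaBinomialASE,
    BetaParams,
    beta_from_moments,
    compare_samples,
    fit_hyperparameters,
    hdr_beta,
    posterior_update,
    summarize_ase,
    test_ase as evaluate_site,
    test_sites as evaluate_sites,
)

# hyperparameters as fitted in the two study samples
LW_PRIOR = BetaParams(4.99, 3.84)
IB_PRIOR = BetaParams(6.38, 6.20)


def grid_hdr(a, b, mass=0.95, m=100_000):
    """Independent shortest-interval oracle on an ICDF grid."""
    d = stats.beta(a, b)
    q = np.linspace(0.0, 1.0 - mass, m)
    lo, hi = d.ppf(q), d.ppf(q + mass)
    k = int(np.argmin(hi - lo))
    return float(lo[k]), float(hi[k])


class TestMoments:
    def test_uniform_closed_form(self):
        p = beta_from_moments(0.5, 1 / 12)
        assert (p.alpha, p.beta) == pytest.approx((1.0, 1.0))

    def test_beta_2_3(self):
        p = beta_from_moments(0.4, 0.04)
        assert (p.alpha, p.beta) == pytest.approx((2.0, 3.0))

    def test_overdispersed_rejected(self):
        with pytest.raises(ValueError, match="variance too large"):
            beta_from_moments(0.5, 0.3)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            beta_from_moments(0.5, 0.0)

    @pytest.mark.parametrize("prior", [LW_PRIOR, IB_PRIOR])
    def test_recovery_from_seeded_draws(self, prior):
        rng = np.random.default_rng(123)
        draws = rng.beta(prior.alpha, prior.beta, size=100_000)
        fit = fit_hyperparameters(draws)
        assert fit.alpha == pytest.approx(prior.alpha, rel=0.03)
        assert fit.beta == pytest.approx(prior.beta, rel=0.03)

    def test_needs_ten_sites(self):
        with pytest.raises(ValueError, match="≥ 10"):
            fit_hyperparameters([0.4, 0.5, 0.6])


class TestPosteriorUpdate:
    @pytest.mark.parametrize(
        "prior,n,na,expected",
        [
            (BetaParams(1, 1), 10, 5, (6, 6)),
            (LW_PRIOR, 55, 40, (44.99, 18.84)),
            (LW_PRIOR, 0, 0, (4.99, 3.84)),  # no data leaves the prior
        ],
    )
    def test_conjugate_arithmetic(self, prior, n, na, expected):
        post = posterior_update(prior, AlleleCountSite("s", n, na))
        assert (post.alpha, post.beta) == pytest.approx(expected)

    def test_conjugacy_against_numerical_normalisation(self):
        """Posterior density equals the normalised Binomial x Beta product."""
        rng = np.random.default_rng(99)
        grid = np.linspace(1e-6, 1 - 1e-6, 10_001)
        for _ in range(20):
            a, b = rng.uniform(0.5, 20, 2)
            n = int(rng.integers(1, 200))
            na = int(rng.integers(0, n + 1))
            post = posterior_update(BetaParams(a, b), AlleleCountSite("s", n, na))
            unnorm = lambda p: stats.binom.pmf(na, n, p) * stats.beta.pdf(p, a, b)
            mode = (post.alpha - 1) / (post.alpha + post.beta - 2) \
                if min(post.alpha, post.beta) > 1 else na / max(n, 1)
            z, _ = integrate.quad(unnorm, 0.0, 1.0, limit=500,
                                  epsabs=0, epsrel=1e-12, points=[mode])
            dens = unnorm(grid) / z
            err = np.max(np.abs(dens - stats.beta.pdf(grid, post.alpha, post.beta)))
            assert err < 1e-6 * max(1.0, dens.max())


class TestHdrBeta:
    def test_symmetric_equals_equal_tailed(self):
        lo, hi = hdr_beta(BetaParams(6, 6))
        d = stats.beta(6, 6)
        assert lo == pytest.approx(d.ppf(0.025), abs=1e-9)
        assert hi == pytest.approx(d.ppf(0.975), abs=1e-9)
        assert lo == pytest.approx(1 - hi, abs=1e-9)

    def test_uniform_centred_tie_break(self):
        lo, hi = hdr_beta(BetaParams(1, 1))
        assert (lo, hi) == pytest.approx((0.025, 0.975))
        assert hi - lo == pytest.approx(0.95)

    def test_skewed_matches_grid_oracle_and_beats_equal_tailed(self):
        lo, hi = hdr_beta(BetaParams(2, 8))
        glo, ghi = grid_hdr(2, 8)
        assert lo == pytest.approx(glo, abs=1e-3)
        assert hi == pytest.approx(ghi, abs=1e-3)
        d = stats.beta(2, 8)
        et = d.ppf(0.975) - d.ppf(0.025)
        assert hi - lo < et

    def test_mass_exact_and_width_minimal(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            a, b = rng.uniform(0.5, 200, 2)
            lo, hi = hdr_beta(BetaParams(a, b))
            d = stats.beta(a, b)
            assert d.cdf(hi) - d.cdf(lo) == pytest.approx(0.95, abs=1e-6)
            assert hi - lo <= d.ppf(0.975) - d.ppf(0.025) + 1e-9

    def test_endpoint_densities_equal_when_interior(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            a, b = rng.uniform(1.5, 50, 2)
            lo, hi = hdr_beta(BetaParams(a, b))
            d = stats.beta(a, b)
            assert d.pdf(lo) == pytest.approx(d.pdf(hi), abs=1e-4 * d.pdf(d.mean()))

    def test_bad_mass_rejected(self):
        with pytest.raises(ValueError):
            hdr_beta(BetaParams(2, 2), mass=1.0)


class TestTestAse:
    def test_balanced_site_not_significant(self):
        r = evaluate_site(AlleleCountSite("s", 10, 5), BetaParams(1, 1))
        assert not r.significant

    def test_extreme_site_significant(self):
        r = evaluate_site(AlleleCountSite("s", 100, 90), LW_PRIOR)
        assert r.significant
        assert r.p_mean == pytest.approx(94.99 / 108.83, abs=1e-4)

    def test_low_coverage_moderate_fraction_not_significant(self):
        r = evaluate_site(AlleleCountSite("s", 8, 5), IB_PRIOR)
        assert not r.significant

    def test_two_threshold_decision_structure(self):
        """For fixed n, the significant set in n_a is a union of a lower and
        an upper tail (single pair of thresholds)."""
        n = 60
        flags = [
            evaluate_site(AlleleCountSite("s", n, na), LW_PRIOR).significant
            for na in range(n + 1)
        ]
        # pattern must be True..True False..False True..True (either tail may
        # be empty): at most two sign changes
        changes = sum(flags[i] != flags[i + 1] for i in range(n))
        assert changes <= 2
        assert not flags[n // 2]

    def test_no_reference_allele_bias_under_symmetric_prior(self):
        prior = BetaParams(6.29, 6.29)
        for n, na in [(30, 4), (55, 40), (100, 90), (12, 6)]:
            a = evaluate_site(AlleleCountSite("s", n, na), prior)
            b = evaluate_site(AlleleCountSite("s", n, n - na), prior)
            assert a.significant == b.significant
            assert a.hdr[0] == pytest.approx(1 - b.hdr[1], abs=1e-6)

    def test_coverage_threshold_behaviour(self):
        """Intermediate fractions become significant once coverage crosses a
        single threshold; extreme fractions are significant from n = 20 on;
        a balanced site never is."""
        prior = BetaParams(6.29, 6.29)
        ns = range(4, 501)
        flags_065 = [
            evaluate_site(AlleleCountSite("s", n, 0.65 * n), prior).significant
            for n in ns
        ]
        changes = sum(flags_065[i] != flags_065[i + 1]
                      for i in range(len(flags_065) - 1))
        assert changes == 1 and not flags_065[0] and flags_065[-1]
        assert all(
            evaluate_site(AlleleCountSite("s", n, 0.95 * n), prior).significant
            for n in range(20, 501, 7)
        )
        assert not any(
            evaluate_site(AlleleCountSite("s", n, 0.5 * n), prior).significant
            for n in range(4, 501, 11)
        )


class TestSummaries:
    def test_empty_summary(self):
        s = summarize_ase([])
        assert s["n_significant"] == 0 and s["pct_significant"] == 0.0

    def test_percentage_arithmetic(self):
        sites = [AlleleCountSite(f"s{i}", 100, 95) for i in range(3)]
        sites += [AlleleCountSite(f"t{i}", 100, 50) for i in range(7)]
        res = evaluate_sites(sites, BetaParams(1, 1))
        s = summarize_ase(res)
        assert s["n_significant"] == 3
        assert s["pct_significant"] == pytest.approx(30.0)
        assert s["mean_coverage_significant"] == pytest.approx(100.0)

    def test_compare_samples_concordance(self):
        prior = BetaParams(1, 1)
        mk = lambda sid, n, na: evaluate_site(AlleleCountSite(sid, n, na), prior)
        a = [mk("x", 100, 90), mk("y", 100, 10), mk("z", 100, 50)]
        b = [mk("x", 100, 85), mk("y", 100, 88), mk("w", 100, 95)]
        out = compare_samples(a, b)
        assert out["n_shared"] == 2
        assert out["n_discordant"] == 1 and out["discordant"] == ["y"]

    def test_disjoint_sets_empty(self):
        prior = BetaParams(1, 1)
        a = [evaluate_site(AlleleCountSite("x", 100, 90), prior)]
        b = [evaluate_site(AlleleCountSite("y", 100, 90), prior)]
        assert compare_samples(a, b)["n_shared"] == 0


class TestBetaBinomialASE:
    def test_fit_then_test(self):
        rng = np.random.default_rng(17)
        p = rng.beta(4.99, 3.84, size=500)
        n = rng.integers(20, 100, size=500)
        sites = [
            AlleleCountSite(f"s{i}", int(n[i]), int(rng.binomial(n[i], p[i])))
            for i in range(500)
        ]
        model = BetaBinomialASE().fit(sites)
        assert 0 < model.prior.alpha < 50
        res = model.test_sites(sites[:10])
        assert len(res) == 10

    def test_requires_fit(self):
        with pytest.raises(ValueError):
            BetaBinomialASE().test_site(AlleleCountSite("s", 10, 5))
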