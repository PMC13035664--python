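"""Distributional tests for the covariance/correlation priors.

Closed-form marginals are exact theory (IW and SIW correlations are
uniform at their default shapes; the LKJ marginal is a scaled Beta), so
Kolmogorov-Smirnov tests at alpha = .01 against the exact CDFs are valid
at large draw counts.
"""

import numpy as np
import pytest
from scipy import stats

from hiercorr.priors import (
    IWSpec,
    LKJSpec,
    SIWSpec,
    corr_from_cov,
    corr_from_partial,
    cov_from_corr,
    default_iw,
    invwishart_bartlett,
    lkj_marginal_beta_param,
    partial_from_corr,
    prior_panels,
    sample_iw,
    sample_lkj_corr,
    sample_lkj_rejection,
    sample_scale,
    sample_siw,
    sample_siw_scipy,
    scale_logpdf,
    spec_from_yaml,
    spec_to_yaml,
)

ALPHA = 0.01


def _offdiag(draws):
    sd, rho = corr_from_cov(draws)
    return sd, rho


class TestCorrFromCov:
    def test_diagonal_gives_identity(self):
        sd, rho = corr_from_cov(np.diag([4.0, 9.0, 16.0]))
        np.testing.assert_allclose(sd, [2, 3, 4])
        np.testing.assert_array_equal(rho, np.eye(3))

    def test_simple_arithmetic(self):
        sd, rho = corr_from_cov(np.array([[4.0, 2.0], [2.0, 4.0]]))
        np.testing.assert_allclose(sd, [2, 2])
        assert rho[0, 1] == pytest.approx(0.5)

    def test_round_trip_random_pd(self, rng):
        for _ in range(25):
            A = rng.standard_normal((4, 4))
            Sigma = A @ A.T + 0.5 * np.eye(4)
            sd, rho = corr_from_cov(Sigma)
            np.testing.assert_allclose(cov_from_corr(sd, rho), Sigma,
                                       atol=1e-12)

    def test_nonpositive_diagonal_errors(self):
        with pytest.raises(ValueError, match="diagonal"):
            corr_from_cov(np.array([[0.0, 0.0], [0.0, 1.0]]))


class TestInverseWishart:
    @pytest.mark.parametrize("J", [2, 3, 5, 8])
    def test_default_marginal_correlation_uniform(self, J):
        """IW(v=J+1, I): each pairwise correlation is Uniform(-1, 1)."""
        draws = sample_iw(default_iw(J), 100_000, seed=J)
        _, rho = corr_from_cov(draws)
        r = rho[:, 0, 1]
        p = stats.kstest(r, stats.uniform(loc=-1, scale=2).cdf).pvalue
        assert p > ALPHA

    def test_mean_formula(self):
        """E[Sigma] = S/(v - J - 1); v chosen so entry variances are finite."""
        J = 3
        S = np.array([[2.0, 0.5, 0.0], [0.5, 1.0, 0.3], [0.0, 0.3, 1.5]])
        v = J + 5.0
        draws = sample_iw(IWSpec(v=v, S=S), 200_000, seed=5)
        np.testing.assert_allclose(draws.mean(axis=0), S / (v - J - 1),
                                   rtol=0.03, atol=5e-3)

    def test_univariate_reduces_to_inverse_gamma(self):
        v, s2 = 5.0, 2.0
        draws = sample_iw(IWSpec(v=v, S=np.array([[s2]])), 50_000, seed=3)
        x = draws[:, 0, 0]
        p = stats.kstest(x, stats.invgamma(a=v / 2, scale=s2 / 2).cdf).pvalue
        assert p > ALPHA

    def test_bartlett_draw_matches_scipy(self, rng):
        """Hand-rolled Bartlett inverse-Wishart vs scipy, non-diagonal scale."""
        S = np.array([[2.0, 0.8], [0.8, 1.5]])
        df = 6.0
        mine = np.array([invwishart_bartlett(rng, df, S) for _ in range(20_000)])
        ref = stats.invwishart.rvs(df=df, scale=S, size=20_000,
                                   random_state=np.random.default_rng(8))
        for i, j in [(0, 0), (0, 1), (1, 1)]:
            assert stats.ks_2samp(mine[:, i, j], ref[:, i, j]).pvalue > ALPHA

    def test_singular_scale_errors(self):
        with pytest.raises(ValueError, match="positive definite"):
            IWSpec(v=4, S=np.array([[1.0, 1.0], [1.0, 1.0]]))

    def test_df_bound(self):
        with pytest.raises(ValueError, match="v > J - 1"):
            IWSpec(v=1.0, S=np.eye(3))


class TestScaledInverseWishart:
    @pytest.mark.parametrize("J", [2, 5])
    def test_marginal_correlation_uniform(self, J):
        """SIW(v=2): correlations uniform on (-1, 1) for any J."""
        draws = sample_siw(SIWSpec(s=np.full(J, 0.1)), 100_000, seed=J)
        _, rho = corr_from_cov(draws)
        p = stats.kstest(rho[:, 0, 1],
                         stats.uniform(loc=-1, scale=2).cdf).pvalue
        assert p > ALPHA

    def test_sd_marginal_tracks_half_t2(self):
        """The SIW(v=2) SD marginal should follow half-t(2, s_j)."""
        s = np.array([0.1, 0.3])
        draws = sample_siw(SIWSpec(s=s), 50_000, seed=2)
        sd, _ = corr_from_cov(draws)
        for j in range(2):
            cdf = lambda x, sj=s[j]: 2 * stats.t.cdf(x / sj, df=2) - 1
            p = stats.kstest(sd[:, j], cdf).pvalue
            assert p > ALPHA, f"SD marginal for s={s[j]} deviates from half-t(2)"

    def test_mixture_routes_agree(self):
        """Bartlett-based and scipy-based mixture draws agree in law.

        Both samples carry Monte-Carlo noise, so the two-sample comparison
        uses a stricter alpha than the exact-CDF tests.
        """
        spec = SIWSpec(s=np.array([0.1, 0.2]))
        a = sample_siw(spec, 30_000, seed=4)
        b = sample_siw_scipy(spec, 30_000, seed=5)
        sd_a, rho_a = corr_from_cov(a)
        sd_b, rho_b = corr_from_cov(b)
        assert stats.ks_2samp(rho_a[:, 0, 1], rho_b[:, 0, 1]).pvalue > 1e-3
        assert stats.ks_2samp(sd_a[:, 0], sd_b[:, 0]).pvalue > 1e-3
        # energy distance between the joint summaries is near zero
        ed = stats.energy_distance(sd_a[:, 1], sd_b[:, 1])
        scale = np.std(np.concatenate([sd_a[:, 1], sd_b[:, 1]]))
        assert ed < 0.05 * scale


class TestLKJ:
    def test_bivariate_eta1_uniform(self):
        rho = sample_lkj_corr(1.0, 2, 100_000, seed=1)
        p = stats.kstest(rho[:, 0, 1],
                         stats.uniform(loc=-1, scale=2).cdf).pvalue
        assert p > ALPHA

    @pytest.mark.parametrize("J", [2, 4, 8])
    @pytest.mark.parametrize("eta", [0.25, 0.5, 1.0, 2.0, 4.0])
    def test_marginal_matches_beta_closed_form(self, J, eta):
        """(rho_12 + 1)/2 ~ Beta(a, a), a = eta + (J - 2)/2."""
        rho = sample_lkj_corr(eta, J, 20_000, seed=int(10 * eta) + J)
        a = lkj_marginal_beta_param(eta, J)
        p = stats.kstest((rho[:, 0, 1] + 1) / 2, stats.beta(a, a).cdf).pvalue
        assert p > ALPHA / 5  # 15-cell grid: guard the familywise rate

    def test_matches_rejection_oracle_at_J3(self):
        vine = sample_lkj_corr(1.0, 3, 6000, seed=0)
        brute = sample_lkj_rejection(1.0, 3, 6000, seed=1)
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            assert stats.ks_2samp(vine[:, i, j], brute[:, i, j]).pvalue > 1e-3

    def test_extreme_mass_shrinks_with_J(self):
        tail = []
        for J in (2, 4, 8):
            rho = sample_lkj_corr(1.0, J, 30_000, seed=J)
            tail.append(np.mean(np.abs(rho[:, 0, 1]) > 0.8))
        assert tail[0] > tail[1] > tail[2]

    def test_all_draws_valid_correlation_matrices(self):
        rho = sample_lkj_corr(0.5, 5, 2000, seed=3)
        np.testing.assert_allclose(rho, np.swapaxes(rho, 1, 2), atol=1e-12)
        np.testing.assert_allclose(rho[:, range(5), range(5)], 1.0,
                                   atol=1e-12)
        assert np.linalg.eigvalsh(rho).min() > -1e-10

    def test_partial_correlation_round_trip(self, rng):
        for J in (3, 5):
            R = sample_lkj_corr(1.0, J, 1, seed=rng.integers(2**31))[0]
            P = partial_from_corr(R)
            np.testing.assert_allclose(corr_from_partial(P), R, atol=1e-12)


class TestScaleFamilies:
    def test_all_positive(self):
        for fam in ("half_t_2", "half_normal", "half_cauchy", "exponential",
                    "gamma", "lognormal", "uniform"):
            x = sample_scale(fam, 0.1, 5000, seed=1)
            assert (x > 0).all()

    def test_half_t_median(self):
        x = sample_scale("half_t_2", 0.1, 200_000, seed=2)
        expected = 0.1 * stats.t.ppf(0.75, df=2)
        assert np.median(x) == pytest.approx(expected, rel=0.02)

    def test_exponential_mean(self):
        x = sample_scale("exponential", 0.1, 200_000, seed=3)
        assert x.mean() == pytest.approx(0.1, rel=0.02)

    def test_unknown_family_lists_supported(self):
        with pytest.raises(ValueError, match="half_t_2"):
            sample_scale("triangular", 0.1, 10, seed=0)

    @pytest.mark.parametrize("fam,dist", [
        ("half_normal", stats.halfnorm(scale=0.1)),
        ("half_cauchy", stats.halfcauchy(scale=0.1)),
        ("exponential", stats.expon(scale=0.1)),
        ("gamma", stats.gamma(a=2.0, scale=0.05)),
        ("lognormal", stats.lognorm(s=0.5, scale=0.1)),
        ("uniform", stats.uniform(loc=0, scale=0.2)),
    ])
    def test_logpdf_matches_scipy(self, fam, dist):
        x = np.array([0.01, 0.05, 0.1, 0.19, 0.5, 2.0])
        mine = scale_logpdf(fam, 0.1, x)
        ref = dist.logpdf(x)
        np.testing.assert_allclose(mine, ref, atol=1e-10)

    def test_half_t_logpdf_matches_t_density(self):
        x = np.array([0.02, 0.1, 0.4, 1.0])
        mine = scale_logpdf("half_t_2", 0.1, x)
        ref = np.log(2.0) + stats.t.logpdf(x, df=2, scale=0.1)
        np.testing.assert_allclose(mine, ref, atol=1e-10)


class TestPriorPanels:
    def test_histograms_normalized(self):
        draws = sample_iw(default_iw(3), 20_000, seed=0)
        panels = prior_panels(draws)
        edges = panels["rho_bin_edges"]
        w = np.diff(edges)
        for key in ("marginal_rho12", "rho12_given_low_sd1",
                    "rho12_given_high_sd1"):
            assert np.sum(panels[key] * w) == pytest.approx(1.0, abs=1e-9)

    def test_iw_scale_correlation_dependence(self):
        """Small SDs concentrate correlations near 0; large SDs near +-1."""
        draws = sample_iw(default_iw(3), 60_000, seed=1)
        panels = prior_panels(draws)
        edges = panels["rho_bin_edges"]
        centers = (edges[:-1] + edges[1:]) / 2
        w = np.diff(edges)
        small = np.abs(centers) < 0.2
        mass_low = np.sum((panels["rho12_given_low_sd1"] * w)[small])
        mass_high = np.sum((panels["rho12_given_high_sd1"] * w)[small])
        assert mass_low > 2 * mass_high

    def test_lkj_conditionals_homogeneous(self):
        """Scale and correlation independent: conditionals match marginal."""
        rho = sample_lkj_corr(1.0, 3, 60_000, seed=2)
        sd = sample_scale("half_t_2", 0.1, 60_000 * 3, seed=3).reshape(-1, 3)
        panels = prior_panels((sd, rho), n_bins=21)
        n_low = 12_000  # bottom/top 20% windows
        w = np.diff(panels["rho_bin_edges"])
        counts_m = panels["marginal_rho12"] * w
        for key in ("rho12_given_low_sd1", "rho12_given_high_sd1"):
            # chi-square homogeneity on binned counts vs marginal shape
            obs = panels[key] * w * n_low
            exp = counts_m / counts_m.sum() * obs.sum()
            keep = exp > 5
            chi2 = np.sum((obs[keep] - exp[keep]) ** 2 / exp[keep])
            pval = stats.chi2.sf(chi2, keep.sum() - 1)
            assert pval > ALPHA

    def test_too_few_draws_errors(self):
        draws = sample_iw(default_iw(2), 100, seed=0)
        with pytest.raises(ValueError, match="10\\^4"):
            prior_panels(draws)


class TestSpecSerialization:
    def test_yaml_round_trip(self):
        for spec in (default_iw(3, 0.1), SIWSpec(s=np.array([0.1, 0.2])),
                     LKJSpec(eta=2.0, s=np.array([0.1]),
                             scale_family="gamma")):
            back = spec_from_yaml(spec_to_yaml(spec))
            assert type(back) is type(spec)
            assert back.to_dict() == spec.to_dict()
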