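import numpy as np
import pytest
from scipy import stats

from magblup.gblup import (
    GBLUP,
    McmcSettings,
    PriorSpec,
    compute_prior_scale,
    derive_genetic_parameters,
    design_matrix,
    summarize_posterior,
)
from magblup.grm import compute_grm
from magblup.simulate import SimulationConfig, simulate_genotypes


def _family_grm(seed, n=200, n_snps=1000):
    cfg = SimulationConfig(
        n_animals=n, n_sires_extra=20, n_snps=n_snps, n_mg=2, seed=seed
    )
    geno = simulate_genotypes(cfg)
    p = geno.mean(axis=0) / 2.0
    geno = geno.loc[:, (p > 0) & (p < 1)]
    return compute_grm(geno).to_numpy()[:n, :n]


class TestPriorScale:
    @pytest.mark.parametrize(
        "var_y,df0,t,r2,expected",
        [
            (1.0, 5, 1, 0.5, 3.5),
            (1.0, 5, 1, 0.0, 0.0),
            (0.148, 5, 1, 0.5, 0.518),
        ],
    )
    def test_scalar_formula(self, var_y, df0, t, r2, expected):
        assert compute_prior_scale(var_y, df0, t, r2) == pytest.approx(expected)

    def test_matrix_formula(self):
        v = np.array([[1.0, 0.2], [0.2, 0.8]])
        out = compute_prior_scale(v, 3, 2, 0.5)
        assert out == pytest.approx(v * 3.0)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            compute_prior_scale(0.0, 5, 1)
        with pytest.raises(ValueError):
            compute_prior_scale(np.array([[1.0, 2.0], [2.0, 1.0]]), 5, 2)

    def test_df0_defaults_by_trait_count(self):
        assert PriorSpec().resolved_df0_genomic(1) == 5.0
        assert PriorSpec().resolved_df0_genomic(2) == 3.0
        assert PriorSpec(df0_genomic=10).resolved_df0_genomic(2) == 10.0


class TestSummarizePosterior:
    def test_constant_chain(self):
        s = summarize_posterior(np.full(100, 0.4))
        assert s.median == pytest.approx(0.4)
        assert s.hpd95_high - s.hpd95_low == pytest.approx(0.0)
        assert s.p0 == 1.0
        assert np.isnan(s.geweke_z)  # flagged, not an error

    def test_normal_chain_matches_quantiles(self):
        x = np.random.default_rng(0).standard_normal(100_000)
        s = summarize_posterior(x)
        assert s.hpd95_low == pytest.approx(-1.96, abs=0.05)
        assert s.hpd95_high == pytest.approx(1.96, abs=0.05)
        assert s.p0 == pytest.approx(0.5, abs=0.02)
        assert abs(s.geweke_z) < 4

    def test_strictly_positive_chain_has_p0_one(self):
        x = np.random.default_rng(1).uniform(0.1, 2.0, 500)
        assert summarize_posterior(x).p0 == 1.0

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            summarize_posterior(np.arange(5.0))


class TestDeriveGeneticParameters:
    def test_zero_residual_gives_unit_heritability(self):
        G = np.ones((50, 1, 1))
        R = np.zeros((50, 1, 1))
        out = derive_genetic_parameters(G, R)
        assert out["h2"][0]["chain"] == pytest.approx(np.ones(50))

    def test_unit_variance_correlation_passthrough(self):
        G = np.tile(np.array([[1.0, 0.4], [0.4, 1.0]]), (40, 1, 1))
        R = np.tile(np.eye(2), (40, 1, 1))
        out = derive_genetic_parameters(G, R)
        assert out["rg"][(0, 1)]["chain"] == pytest.approx(np.full(40, 0.4))

    def test_matches_bruteforce_recomputation(self, rng):
        S = 60
        G = np.empty((S, 2, 2))
        R = np.empty((S, 2, 2))
        for s in range(S):
            a = rng.uniform(0.2, 1.0, 2)
            c = rng.uniform(-0.5, 0.5) * np.sqrt(a.prod())
            G[s] = [[a[0], c], [c, a[1]]]
            R[s] = np.diag(rng.uniform(0.2, 1.0, 2))
        out = derive_genetic_parameters(G, R)
        rg_brute = G[:, 0, 1] / np.sqrt(G[:, 0, 0] * G[:, 1, 1])
        assert out["rg"][(0, 1)]["chain"] == pytest.approx(rg_brute)
        h2_brute = G[:, 0, 0] / (G[:, 0, 0] + R[:, 0, 0])
        assert out["h2"][0]["chain"] == pytest.approx(h2_brute)

    def test_zero_total_variance_samples_excluded(self):
        G = np.zeros((20, 1, 1))
        R = np.zeros((20, 1, 1))
        G[:10] = 1.0
        R[:10] = 1.0
        out = derive_genetic_parameters(G, R)
        assert out["n_excluded"] == 10
        assert out["h2"][0]["chain"].size == 10


class TestGibbsSampler:
    def test_variance_full_conditional_matches_scaled_inv_chi2(self):
        # u of length 2, GRM = I, df0 = 5, S0 = 1:
        # sigma2 | u ~ scaled-inv-chi2(7, (u'u + 5) / 7)
        rng = np.random.default_rng(0)
        u = np.array([0.7, -1.2])
        SS = np.array([[float(u @ u)]])
        draws = np.array(
            [
                GBLUP._draw_variance(rng, SS, 5.0, np.eye(1), 2)[0, 0]
                for _ in range(10_000)
            ]
        )
        cdf = lambda x: stats.chi2.sf((u @ u + 5.0) / x, 7)
        assert stats.kstest(draws, cdf).pvalue > 0.01

    def test_noiseless_limit_recovers_u(self):
        rng = np.random.default_rng(2)
        n = 80
        u = rng.standard_normal(n)
        y = u.copy()
        m = GBLUP(
            n_iter=600, burn_in=100, thin=1, seed=0,
            fixed_G=np.array([[1.0]]), fixed_R=np.array([[1e-6]]),
        ).fit(y, np.eye(n), np.zeros((n, 1)) + 1.0)
        assert np.corrcoef(m.u_mean_[:, 0], u)[0, 1] > 0.99

    def test_seeded_runs_are_identical(self):
        rng = np.random.default_rng(3)
        K = _family_grm(3, n=60, n_snps=300)
        y = rng.standard_normal(60)
        a = GBLUP(n_iter=400, burn_in=100, thin=2, seed=9).fit(y, K)
        b = GBLUP(n_iter=400, burn_in=100, thin=2, seed=9).fit(y, K)
        assert np.array_equal(a.G_chain_, b.G_chain_)
        assert np.array_equal(a.u_mean_, b.u_mean_)

    def test_trait_order_exchange_is_consistent(self):
        rng = np.random.default_rng(4)
        n = 150
        K = _family_grm(4, n=n, n_snps=800)
        L = np.linalg.cholesky(K + 1e-8 * np.eye(n))
        S = 0.4 * np.array([[1.0, 0.5], [0.5, 1.0]])
        U = L @ rng.standard_normal((n, 2)) @ np.linalg.cholesky(S).T
        Y = U + rng.standard_normal((n, 2)) * np.sqrt(0.6)
        m12 = GBLUP(n_iter=3000, burn_in=1000, thin=4, seed=5).fit(Y, K)
        m21 = GBLUP(n_iter=3000, burn_in=1000, thin=4, seed=5).fit(Y[:, ::-1], K)
        rg12 = m12.genetic_parameters()["rg"][(0, 1)]["summary"].median
        rg21 = m21.genetic_parameters()["rg"][(0, 1)]["summary"].median
        assert rg12 == pytest.approx(rg21, abs=0.08)
        h2_a = m12.genetic_parameters()["h2"][0]["summary"].median
        h2_b = m21.genetic_parameters()["h2"][1]["summary"].median
        assert h2_a == pytest.approx(h2_b, abs=0.08)

    def test_univariate_h2_recovery_hpd_covers_truth(self):
        rng = np.random.default_rng(6)
        n = 400
        K = _family_grm(6, n=n, n_snps=2000)
        d, V = np.linalg.eigh(K)
        L = V @ np.diag(np.sqrt(np.maximum(d, 0)))
        u = L @ rng.standard_normal(n) * np.sqrt(0.3)
        y = 2.0 + u + rng.normal(0, np.sqrt(0.7), n)
        # realized heritability of this draw (family/breed structure makes
        # the realized genetic variance deviate from its nominal value)
        h2_real = u.var(ddof=1) / (u.var(ddof=1) + 0.7)
        m = GBLUP(n_iter=3000, burn_in=1000, thin=5, seed=1).fit(y, K)
        s = m.genetic_parameters()["h2"][0]["summary"]
        assert s.hpd95_low <= h2_real <= s.hpd95_high

    def test_missing_phenotypes_are_augmented_not_dropped(self):
        rng = np.random.default_rng(7)
        n = 100
        K = _family_grm(7, n=n, n_snps=500)
        y = rng.standard_normal(n)
        y[:15] = np.nan  # genotyped, never phenotyped
        m = GBLUP(n_iter=500, burn_in=100, thin=2, seed=0).fit(y, K)
        assert m.u_mean_.shape == (n, 1)
        assert np.isfinite(m.u_mean_).all()

    def test_fixed_covariances_skip_variance_updates(self):
        rng = np.random.default_rng(8)
        n = 40
        y = rng.standard_normal(n)
        G0 = np.array([[0.4]])
        R0 = np.array([[0.6]])
        m = GBLUP(
            n_iter=300, burn_in=50, thin=1, seed=0, fixed_G=G0, fixed_R=R0
        ).fit(y, np.eye(n))
        assert np.all(m.G_chain_ == 0.4)
        assert np.all(m.R_chain_ == 0.6)

    def test_invalid_inputs_rejected(self):
        y = np.zeros(10)
        with pytest.raises(ValueError, match="symmetric"):
            GBLUP(n_iter=20, burn_in=5).fit(y, np.triu(np.ones((10, 10))))
        with pytest.raises(ValueError, match="positive definite"):
            GBLUP(
                n_iter=20, burn_in=5,
                fixed_G=np.array([[-1.0]]), fixed_R=np.array([[1.0]]),
            ).fit(np.random.default_rng(0).standard_normal(10), np.eye(10))
        with pytest.raises(ValueError, match="together"):
            GBLUP(n_iter=20, burn_in=5, fixed_G=np.array([[1.0]])).fit(
                y, np.eye(10)
            )

    def test_mcmc_settings_validated(self):
        with pytest.raises(ValueError, match="burn_in"):
            McmcSettings(n_iter=100, burn_in=200)
        with pytest.raises(ValueError, match="thin"):
            McmcSettings(thin=0)


def test_design_matrix_is_full_rank_one_hot():
    X = design_matrix(np.array(["b", "a", "b", "c"]))
    assert X.shape == (4, 3)
    assert np.linalg.matrix_rank(X) == 3
    assert (X.sum(axis=1) == 1).all()
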