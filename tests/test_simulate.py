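import numpy as np
import pandas as pd
import pytest

from magblup.growth import adg_table
from magblup.simulate import (
    SimulationConfig,
    simulate_dataset,
    simulate_genotypes,
    simulate_mg_counts,
    simulate_true_effects,
)


def _cfg(**kw):
    base = dict(n_animals=30, n_sires_extra=4, n_snps=50, n_mg=10, seed=1)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize("maf_range", [(0.0, 0.5), (0.1, 0.6), (-0.1, 0.4)])
    def test_invalid_maf_range_rejected(self, maf_range):
        with pytest.raises(ValueError, match="maf_range"):
            _cfg(maf_range=maf_range)

    def test_invalid_h2_rejected(self):
        with pytest.raises(ValueError, match="herit"):
            _cfg(h2_adg=(1.2, 0.3, 0.3, 0.3))

    def test_non_psd_genetic_corr_rejected(self):
        bad = np.eye(14)
        bad[0, 1] = bad[1, 0] = 0.99
        bad[0, 2] = bad[2, 0] = 0.99
        bad[1, 2] = bad[2, 1] = -0.99
        cfg = _cfg(genetic_corr=bad)
        grm = pd.DataFrame(np.eye(34))
        with pytest.raises(ValueError, match="positive semidefinite"):
            simulate_true_effects(cfg, grm)


class TestGenotypes:
    def test_seeded_determinism(self):
        cfg = _cfg()
        pd.testing.assert_frame_equal(
            simulate_genotypes(cfg), simulate_genotypes(cfg)
        )

    def test_shape_and_code_set(self):
        g = simulate_genotypes(_cfg(n_animals=5, n_snps=3, n_sires_extra=0))
        assert g.shape == (5, 3)
        assert g.isin([0.0, 1.0, 2.0]).all().all()

    def test_mean_dosage_follows_binomial_law(self):
        # maf fixed at 0.5: per-SNP mean dosage within 3 binomial SEs of 1
        cfg = _cfg(
            n_animals=10_000, n_sires_extra=0, n_snps=30,
            maf_range=(0.5, 0.5), family_structure=False,
            n_breeds=1, fst=0.0,
        )
        g = simulate_genotypes(cfg)
        se = np.sqrt(2 * 0.5 * 0.5 / 10_000)
        assert np.abs(g.mean(axis=0) - 1.0).max() < 3 * se

    def test_half_sib_families_raise_relatedness(self):
        from magblup.grm import compute_grm

        cfg = _cfg(n_animals=200, n_sires_extra=5, n_snps=500,
                   n_breeds=1, fst=0.0)
        g = simulate_genotypes(cfg)
        grm = compute_grm(g).to_numpy()[:200, :200]
        off = grm[np.triu_indices(200, 1)]
        # half sibs (~1/5 of pairs) share ~0.25: the upper tail is heavy
        assert np.quantile(off, 0.92) > 0.12

    def test_missingness_rate_configurable(self):
        g = simulate_genotypes(_cfg(missing_geno_rate=0.1, n_snps=200))
        frac = g.isna().to_numpy().mean()
        assert 0.05 < frac < 0.15


class TestTrueEffects:
    def test_independent_traits_have_near_zero_cross_correlation(self):
        cfg = _cfg(n_animals=500, n_sires_extra=0, n_mg=2,
                   genetic_corr=np.eye(6), use_grm_for_effects=False)
        grm = pd.DataFrame(np.eye(500))
        true = simulate_true_effects(cfg, grm)
        corr = np.corrcoef(true.true_u.to_numpy().T)
        off = corr[np.triu_indices(6, 1)]
        assert np.abs(off).max() < 0.15

    def test_two_trait_correlation_recovered(self):
        # rg_true = 0.4, GRM = I, 2000 animals: empirical corr within 0.05
        corr = np.eye(6)
        corr[0, 1] = corr[1, 0] = 0.4
        cfg = _cfg(n_animals=2000, n_sires_extra=0, n_mg=2, genetic_corr=corr)
        grm = pd.DataFrame(np.eye(2000))
        true = simulate_true_effects(cfg, grm)
        r = np.corrcoef(true.true_u.iloc[:, 0], true.true_u.iloc[:, 1])[0, 1]
        assert r == pytest.approx(0.4, abs=0.05)

    def test_zero_heritability_trait_is_exactly_zero(self):
        cfg = _cfg(h2_adg=(0.0, 0.3, 0.3, 0.3))
        grm = pd.DataFrame(np.eye(34))
        true = simulate_true_effects(cfg, grm)
        assert true.true_sigma_u2["ADG_1"] == 0.0
        assert (true.true_u["ADG_1"] == 0.0).all()


class TestWeightSeries:
    def _noiseless(self, **kw):
        return _cfg(
            h2_adg=(0.0, 0.0, 0.0, 0.0),
            adg_phen_sd=0.0,
            fixed_sd_adg=0.0,
            weight_noise_sd=0.0,
            **kw,
        )

    def test_noiseless_series_round_trips_to_configured_means(self):
        cfg = self._noiseless(adg_means=(1.57, 1.50, 1.48, 1.41))
        data = simulate_dataset(cfg)
        adg = adg_table(data.weights)
        for j, expected in enumerate((1.57, 1.50, 1.48, 1.41)):
            assert adg.iloc[:, j].to_numpy() == pytest.approx(expected, abs=1e-9)

    def test_weekly_schedule(self):
        data = simulate_dataset(_cfg())
        for _, grp in data.weights.groupby("animal"):
            days = np.sort(grp["day"].to_numpy())
            assert len(days) == 17
            assert (np.diff(days) == 7).all()


class TestMgCounts:
    def test_counts_close_to_depth_exactly(self):
        data = simulate_dataset(_cfg())
        depths = data.counts.sum(axis=1)
        lo, hi = _cfg().depth_range
        assert ((depths >= lo) & (depths <= hi)).all()

    def test_seeded_count_tables_identical(self):
        cfg = _cfg()
        a = simulate_dataset(cfg).counts
        b = simulate_dataset(cfg).counts
        pd.testing.assert_frame_equal(a, b)

    def test_huge_depth_concentrates_on_softmax(self):
        cfg = _cfg(n_animals=3, depth_range=(10**9, 10**9))
        data = simulate_dataset(cfg)
        latent = data.truth.latent_log_abundance.to_numpy()
        z = latent - latent.max(axis=1, keepdims=True)
        probs = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        obs = data.counts.to_numpy() / 1e9
        assert np.abs(obs - probs).max() < 1e-3

    def test_zero_fraction_increases_at_low_depth(self):
        cfg_hi = _cfg(n_animals=100, n_mg=200, depth_range=(10**6, 10**6))
        cfg_lo = _cfg(n_animals=100, n_mg=200, depth_range=(10**3, 10**3))
        hi = simulate_dataset(cfg_hi).counts
        lo = simulate_dataset(cfg_lo).counts
        assert (lo == 0).to_numpy().mean() > (hi == 0).to_numpy().mean()

    def test_depth_below_mg_count_warns(self):
        cfg = _cfg(n_mg=50, depth_range=(10, 20))
        data = simulate_dataset(_cfg())
        with pytest.warns(UserWarning, match="zero inflation"):
            simulate_mg_counts(data.truth, cfg)


def test_bundle_roundtrip_to_disk(tmp_path, tiny_dataset):
    _, data = tiny_dataset
    data.to_dir(tmp_path)
    for name in (
        "genotypes.tsv",
        "weights.tsv",
        "ko_counts.tsv",
        "fixed_effects.tsv",
        "truth.json",
    ):
        assert (tmp_path / name).exists()
    counts = pd.read_csv(tmp_path / "ko_counts.tsv", sep="\t", index_col=0)
    pd.testing.assert_frame_equal(
        counts, data.counts, check_names=False
    )
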