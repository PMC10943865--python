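import math

import numpy as np
import pandas as pd
import pytest
from skbio.stats.composition import alr as skbio_alr
from skbio.stats.composition import clr as skbio_clr

from magblup.compositions import (
    AlrTransform,
    CoreFilter,
    GbmZeroImputer,
    alr_inverse,
    clr_matrix,
    procrustes_correlation,
    select_alr_reference,
)


def _counts(mat, **kw):
    mat = np.asarray(mat)
    return pd.DataFrame(
        mat,
        index=[f"s{i}" for i in range(mat.shape[0])],
        columns=[f"K{j:05d}" for j in range(1, mat.shape[1] + 1)],
    )


class TestCoreFilter:
    def test_ubiquitous_mg_kept_rare_mg_dropped(self):
        # MG present in 6/10 samples is below the 70% cut-off
        mat = np.ones((10, 2), dtype=int)
        mat[6:, 1] = 0
        cf = CoreFilter(0.70).fit(_counts(mat))
        assert list(cf.kept_columns_) == ["K00001"]

    def test_cutoff_is_ceiling_of_fraction(self):
        # 359 samples at 70% -> at least 252 samples
        assert math.ceil(0.70 * 359) == 252
        mat = np.zeros((359, 2), dtype=int)
        mat[:252, 0] = 5  # exactly at cut-off: kept
        mat[:251, 1] = 5  # one short: dropped
        cf = CoreFilter(0.70).fit(_counts(mat))
        assert cf.presence_cutoff_ == 252
        assert list(cf.kept_columns_) == ["K00001"]

    def test_retained_count_fraction(self):
        mat = np.array([[90, 10], [90, 0]])
        cf = CoreFilter(0.9).fit(_counts(mat))
        assert cf.retained_count_fraction_ == pytest.approx(180 / 190)

    def test_empty_result_is_an_error(self):
        with pytest.raises(ValueError, match="every MG"):
            CoreFilter(1.0).fit(_counts([[1, 0], [0, 1]]))


class TestGbmZeroImputer:
    def test_identity_on_zero_free_samples(self):
        mat = _counts([[10, 30, 60], [20, 20, 60]])
        comp = GbmZeroImputer().fit(mat).transform(mat)
        assert comp.to_numpy() == pytest.approx(
            mat.to_numpy() / mat.to_numpy().sum(1, keepdims=True)
        )

    def test_nonzero_ratios_preserved(self):
        mat = _counts([[0, 5, 20], [4, 8, 12]])
        comp = GbmZeroImputer().fit(mat).transform(mat)
        assert comp.iloc[0, 2] / comp.iloc[0, 1] == pytest.approx(4.0)
        assert (comp.sum(axis=1) - 1.0).abs().max() < 1e-12

    def test_replacement_matches_formula_oracle(self):
        # straight-line oracle: replaced = t_j * s / (depth + s)
        mat = _counts([[0, 5, 5], [2, 4, 4], [3, 3, 4]])
        imp = GbmZeroImputer(strength=2.0).fit(mat)
        comp = imp.transform(mat)
        x = mat.to_numpy(dtype=float)
        prop = x / x.sum(1, keepdims=True)
        logp = np.where(prop > 0, np.log(np.where(prop > 0, prop, 1.0)), np.nan)
        gm = np.exp(np.nanmean(logp, axis=0))
        t = gm / gm.sum()
        expected = t[0] * 2.0 / (10.0 + 2.0)
        assert comp.iloc[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_all_zero_sample_rejected(self):
        mat = _counts([[0, 0, 0], [1, 2, 3]])
        with pytest.raises(ValueError, match="all-zero"):
            GbmZeroImputer().fit(mat)

    def test_default_strength_is_sqrt_mean_depth(self):
        mat = _counts([[50, 50], [100, 100]])
        imp = GbmZeroImputer().fit(mat)
        assert imp.strength_ == pytest.approx(np.sqrt(150.0))


class TestProcrustesCorrelation:
    def test_identity_and_rotation_invariance(self, rng):
        a = rng.standard_normal((15, 4))
        assert procrustes_correlation(a, a) == pytest.approx(1.0)
        q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        assert procrustes_correlation(a, a @ q) == pytest.approx(1.0)

    def test_matches_bruteforce_svd(self, rng):
        comp = rng.dirichlet(np.ones(3), size=4)
        a = clr_matrix(comp)
        b = np.log(comp[:, :2]) - np.log(comp[:, [2]])
        ac = a - a.mean(0)
        bc = b - b.mean(0)
        sv = np.linalg.svd(ac.T @ bc, compute_uv=False)
        expected = sv.sum() / np.sqrt((ac**2).sum() * (bc**2).sum())
        assert procrustes_correlation(a, b) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            procrustes_correlation(np.ones((5, 2)), np.ones((5, 2)))


class TestAlrAndReference:
    def test_alr_hand_computed(self):
        comp = _counts([[1 / 7, 2 / 7, 4 / 7]])
        out = AlrTransform("K00003").fit(comp).transform(comp)
        assert out.to_numpy()[0] == pytest.approx(
            [np.log(0.25), np.log(0.5)], abs=1e-10
        )

    def test_reference_column_gives_zero_and_matches_skbio(self, composition_10x5):
        out = AlrTransform("K00005").fit(composition_10x5).transform(composition_10x5)
        expected = skbio_alr(composition_10x5.to_numpy(), ref_idx=4)
        assert out.to_numpy() == pytest.approx(expected, abs=1e-12)

    def test_scale_invariance_per_sample(self, composition_10x5):
        tf = AlrTransform("K00002").fit(composition_10x5)
        scaled = composition_10x5 * np.linspace(1, 9, 10)[:, None]
        assert tf.transform(scaled).to_numpy() == pytest.approx(
            tf.transform(composition_10x5).to_numpy(), abs=1e-12
        )

    def test_unknown_reference_rejected(self, composition_10x5):
        with pytest.raises(ValueError, match="not in table"):
            AlrTransform("K99999").fit(composition_10x5)

    def test_round_trip_through_alr_inverse(self, composition_10x5):
        alr = AlrTransform("K00004").fit(composition_10x5).transform(composition_10x5)
        back = alr_inverse(alr, "K00004")[composition_10x5.columns]
        assert back.to_numpy() == pytest.approx(
            composition_10x5.to_numpy(), abs=1e-12
        )

    def test_clr_matches_skbio(self, composition_10x5):
        ours = clr_matrix(composition_10x5.to_numpy())
        assert ours == pytest.approx(
            skbio_clr(composition_10x5.to_numpy()), abs=1e-12
        )

    def test_constant_part_has_zero_variance_and_wins(self, rng):
        base = rng.dirichlet(np.ones(4), size=30)
        comp = np.column_stack([base * 0.9, np.full(30, 0.1)])
        comp /= comp.sum(1, keepdims=True)
        table = _counts(comp)
        ref, diag = select_alr_reference(table)
        assert ref == "K00005"
        assert diag.loc["K00005", "logratio_variance"] == pytest.approx(0.0, abs=1e-20)

    def test_selection_matches_exhaustive_scoring(self, rng):
        comp = rng.dirichlet(np.full(20, 1.5), size=50)
        # engineer a low-variance part
        comp[:, 7] = 0.05 * (1 + 0.01 * rng.standard_normal(50))
        comp /= comp.sum(1, keepdims=True)
        table = _counts(comp)
        ref, diag = select_alr_reference(table, top_quantile=0.10)
        # independent exhaustive scoring
        lx = np.log(comp)
        clr = lx - lx.mean(1, keepdims=True)
        scores = {}
        for j, mg in enumerate(table.columns):
            alr = np.delete(lx, j, 1) - lx[:, [j]]
            scores[mg] = (
                procrustes_correlation(clr, alr),
                lx[:, j].var(ddof=1),
            )
        cut = np.quantile([s[0] for s in scores.values()], 0.90)
        top = {m: s for m, s in scores.items() if s[0] >= cut}
        expected = min(top, key=lambda m: top[m][1])
        assert ref == expected


def test_filter_impute_alr_pipeline_is_deterministic(tiny_dataset):
    _, data = tiny_dataset
    counts = data.counts

    def run():
        core = CoreFilter(0.70).fit(counts)
        kept = core.transform(counts)
        comp = GbmZeroImputer().fit(kept).transform(kept)
        ref, _ = select_alr_reference(comp)
        return AlrTransform(ref).fit(comp).transform(comp)

    a, b = run(), run()
    pd.testing.assert_frame_equal(a, b)
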