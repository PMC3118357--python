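"""Weibull fitting, KS statistic/p-value, and the screening pipeline."""

import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate, stats

import wdcm
from wdcm import (
    ExpressionMatrix,
    FitConfig,
    empirical_cdf,
    fit_weibull_mle,
    fit_weibull_minimize_ks,
    kolmogorov_pvalue,
    ks_statistic,
    screen_genes,
    weibull_cdf,
    weibull_pdf,
)


class TestEmpiricalCdf:
    @pytest.mark.parametrize(
        "x,expected",
        [(2.5, 2 / 3), (0.0, 0.0), (1.0, 1 / 3), (3.0, 1.0), (100.0, 1.0)],
    )
    def test_small_sample_values(self, x, expected):
        assert empirical_cdf([1, 2, 3], x) == pytest.approx(expected)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            empirical_cdf([], 1.0)

    @given(seed=st.integers(0, 10_000), n=st.integers(1, 40))
    def test_matches_brute_force_indicator_mean(self, seed, n):
        rng = np.random.default_rng(seed)
        sample = rng.normal(size=n)
        xs = rng.normal(size=10)
        for x in xs:
            assert empirical_cdf(sample, x) == pytest.approx(
                np.mean(sample <= x), abs=0
            )

    @given(seed=st.integers(0, 10_000))
    def test_monotone_nondecreasing(self, seed):
        rng = np.random.default_rng(seed)
        sample = rng.normal(size=20)
        grid = np.sort(rng.normal(size=50) * 2)
        vals = empirical_cdf(sample, grid)
        assert (np.diff(vals) >= 0).all()


class TestWeibullDensity:
    def test_exponential_special_case_at_zero(self):
        assert weibull_pdf(0.0, 1.0, 1.0) == pytest.approx(1.0)

    def test_cdf_at_scale_is_one_minus_inv_e(self):
        for a, b in [(1, 1), (2, 1.5), (0.3, 7)]:
            assert weibull_cdf(a, a, b) == pytest.approx(1 - np.exp(-1))

    def test_pdf_integrates_to_one(self):
        total, _ = integrate.quad(lambda x: weibull_pdf(x, 2.0, 1.5), 0, 100.0)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_matches_scipy_weibull_min(self):
        x = np.linspace(0.01, 10, 200)
        a, b = 2.0, 1.5
        np.testing.assert_allclose(
            weibull_pdf(x, a, b), stats.weibull_min.pdf(x, b, scale=a), rtol=1e-12
        )
        np.testing.assert_allclose(
            weibull_cdf(x, a, b), stats.weibull_min.cdf(x, b, scale=a), rtol=1e-12
        )

    @pytest.mark.parametrize("a,b", [(0, 1), (1, 0), (-1, 2), (2, -3)])
    def test_nonpositive_parameters_rejected(self, a, b):
        with pytest.raises(ValueError, match="positive"):
            weibull_pdf(1.0, a, b)
        with pytest.raises(ValueError, match="positive"):
            weibull_cdf(1.0, a, b)

    def test_negative_x_rejected_for_pdf(self):
        with pytest.raises(ValueError, match=">= 0"):
            weibull_pdf(-1.0, 1.0, 1.0)


def _loglik(x, a, b):
    with np.errstate(divide="ignore"):
        return np.sum(np.log(weibull_pdf(x, a, b)))


class TestMleFit:
    def test_beats_grid_search_on_small_sample(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        a_hat, b_hat = fit_weibull_mle(x)
        grid = np.linspace(0.1, 10, 200)
        best = max(_loglik(x, a, b) for a in grid for b in grid)
        assert _loglik(x, a_hat, b_hat) >= best - 1e-9

    def test_agrees_with_scipy_fixed_location_fit(self, rng):
        x = 2.0 * rng.weibull(1.5, 500)
        a_hat, b_hat = fit_weibull_mle(x)
        b_ref, _, a_ref = stats.weibull_min.fit(x, floc=0)
        assert a_hat == pytest.approx(a_ref, rel=1e-4)
        assert b_hat == pytest.approx(b_ref, rel=1e-4)

    def test_degenerate_spike_flagged_not_crashed(self):
        x = np.full(20, 3.0)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            a, b = fit_weibull_mle(x)
        assert a == pytest.approx(3.0)
        assert b >= 1e3

    def test_near_constant_sample_capped(self):
        x = 3.0 + np.linspace(-1e-9, 1e-9, 10)
        with pytest.warns(RuntimeWarning):
            a, b = fit_weibull_mle(x)
        assert a == pytest.approx(3.0, rel=1e-6)
        assert b >= 1e3

    def test_nonpositive_values_instruct_positivity(self):
        with pytest.raises(ValueError, match="positivity"):
            fit_weibull_mle([-1.0, 2.0, 3.0])

    def test_minimize_ks_never_worse_than_mle(self, rng):
        x = np.sort(2.0 * rng.weibull(1.5, 80))
        a0, b0 = fit_weibull_mle(x)
        a1, b1 = fit_weibull_minimize_ks(x)
        d_mle = ks_statistic(x, lambda v: weibull_cdf(v, a0, b0))
        d_ks = ks_statistic(x, lambda v: weibull_cdf(v, a1, b1))
        assert d_ks <= d_mle + 1e-12


class TestKsStatistic:
    def test_single_observation_at_median(self):
        # F(x) = 0.5 at the observation: gaps are |1 - 0.5| and |0.5 - 0|
        assert ks_statistic([0.0], lambda x: np.full_like(x, 0.5)) == pytest.approx(0.5)

    @pytest.mark.parametrize("n", [1, 5, 20])
    def test_mid_quantile_placement_gives_half_over_n(self, n):
        # Points at F^{-1}((i-1/2)/n) straddle the ECDF steps symmetrically.
        u = (np.arange(1, n + 1) - 0.5) / n
        x = stats.norm.ppf(u)
        assert ks_statistic(x, stats.norm.cdf) == pytest.approx(1 / (2 * n))

    def test_matches_scipy_kstest(self, rng):
        x = rng.lognormal(size=60)
        ours = ks_statistic(x, lambda v: weibull_cdf(v, 2.0, 1.5))
        ref = stats.kstest(x, lambda v: weibull_cdf(v, 2.0, 1.5)).statistic
        assert ours == pytest.approx(ref, abs=1e-15)

    @given(seed=st.integers(0, 10_000))
    def test_probability_integral_transform_invariance(self, seed):
        # A strictly monotone re-parameterization applied jointly to the
        # sample and the CDF argument leaves D unchanged.
        rng = np.random.default_rng(seed)
        x = rng.weibull(1.5, 30) * 2
        d1 = ks_statistic(x, lambda v: weibull_cdf(v, 2.0, 1.5))
        y = np.log(x)  # strictly increasing transform
        d2 = ks_statistic(y, lambda v: weibull_cdf(np.exp(v), 2.0, 1.5))
        assert d1 == pytest.approx(d2, abs=1e-14)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            ks_statistic([], stats.norm.cdf)


class TestKolmogorovPvalue:
    def test_perfect_fit_gives_one(self):
        assert kolmogorov_pvalue(0.0, 50) == 1.0

    def test_large_lambda_tail_decays(self):
        # sqrt(n) * D = 5
        assert kolmogorov_pvalue(0.5, 100) < 1e-10

    def test_matches_scipy_kstwobign(self):
        for lam in [0.5, 0.8, 1.0, 1.358, 2.0]:
            ours = kolmogorov_pvalue(lam / 10, 100)  # sqrt(100)*lam/10 = lam
            ref = stats.kstwobign.sf(lam)
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            kolmogorov_pvalue(1.5, 10)
        with pytest.raises(ValueError):
            kolmogorov_pvalue(0.1, 0)


class TestScreenGenes:
    def test_gene_below_min_n_skipped(self):
        vals = np.ones((2, 10))
        vals[0] = np.linspace(1, 2, 10)
        vals[1, 3:] = np.nan  # 3 observed values
        vals[1, :3] = [1.0, 2.0, 3.0]
        mat = ExpressionMatrix(["ok", "sparse"], [f"s{i}" for i in range(10)], vals)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = screen_genes(mat, FitConfig(min_n=8))
        assert "sparse" in res.skipped
        assert "sparse" not in res.params.gene_ids

    def test_global_shift_applied_once_and_recorded(self, rng):
        vals = rng.normal(0.0, 1.0, size=(5, 30))  # negatives guaranteed
        mat = ExpressionMatrix(
            [f"g{i}" for i in range(5)], [f"s{j}" for j in range(30)], vals
        )
        res = screen_genes(mat, FitConfig(positivity_mode="global_shift"))
        offsets = {f.offset for f in res.fits}
        assert len(offsets) == 1
        off = offsets.pop()
        assert off > -vals.min()

    def test_drop_nonpositive_mode_skips_offenders(self, rng):
        vals = np.abs(rng.normal(5, 1, size=(3, 20))) + 0.1
        vals[1, 0] = -2.0
        mat = ExpressionMatrix(["a", "neg", "c"], [f"s{j}" for j in range(20)], vals)
        res = screen_genes(mat, FitConfig(positivity_mode="drop_nonpositive_genes"))
        assert "neg" in res.skipped
        assert {f.gene_id for f in res.fits} == {"a", "c"}

    def test_zero_accepted_is_empty_result_not_crash(self, rng):
        # Strongly bimodal genes at large n: every gene rejected.
        m, n = 5, 300
        vals = np.where(
            rng.random((m, n)) < 0.5,
            rng.normal(1.0, 0.02, (m, n)),
            rng.normal(10.0, 0.02, (m, n)),
        )
        mat = ExpressionMatrix(
            [f"g{i}" for i in range(m)], [f"s{j}" for j in range(n)], vals
        )
        res = screen_genes(mat)
        assert res.n_accepted == 0
        assert len(res.params) == 0

    def test_rejection_rate_conservative_under_fitted_null(self):
        # Testing against the *fitted* CDF makes KS conservative: the
        # realized alpha sits below the nominal 0.05.
        rng = np.random.default_rng(7)
        reps, n = 500, 100
        rejected = 0
        for _ in range(reps):
            x = 2.0 * rng.weibull(1.5, n)
            a, b = fit_weibull_mle(x)
            D = ks_statistic(x, lambda v: weibull_cdf(v, a, b))
            if kolmogorov_pvalue(D, n) <= 0.05:
                rejected += 1
        assert rejected / reps <= 0.05

    def test_masked_screen_overlaps_complete_screen(self, four_blob_sim):
        mat = four_blob_sim.matrix
        complete = set(screen_genes(mat).accepted_genes)
        masked = wdcm.mask_matrix(mat, 0.05, seed=42)
        part = set(screen_genes(masked).accepted_genes)
        overlap = len(complete & part) / max(len(complete | part), 1)
        assert overlap >= 0.90

    def test_accept_flag_matches_alpha_rule(self, four_blob_screen):
        for f in four_blob_screen.fits:
            assert f.accepted == (f.p_value > 0.05)
            assert 0 <= f.D <= 1
            assert f.a > 0 and f.b > 0


class TestMleSamplingBehaviour:
    def test_estimates_tighten_with_sample_size(self):
        # RMSE of both parameters shrinks as n grows (law of large numbers
        # for the MLE); a compact version of the full acceptance check.
        rng = np.random.default_rng(3)
        a0, b0 = 2.0, 1.5
        rmse = []
        for n in (50, 1000):
            errs = np.array(
                [fit_weibull_mle(a0 * rng.weibull(b0, n)) for _ in range(60)]
            ) - (a0, b0)
            rmse.append(np.sqrt((errs**2).mean(axis=0)))
        assert (rmse[1] < rmse[0]).all()
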