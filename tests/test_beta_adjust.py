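import numpy as np
import pandas as pd
import pytest

from purebeta.beta_adjust import (
    adjust_cpg,
    adjust_matrix,
    derive_cpg_seed,
    population_state_matrix,
    single_population_adjust,
)


def _ols_detrend(beta, purity):
    """Closed-form single-population dual detrending (independent oracle)."""
    x = 1.0 - purity
    slope, intercept = np.polyfit(x, beta, 1)
    tumor = intercept + (beta - (intercept + slope * x))
    slope_n, intercept_n = np.polyfit(purity, beta, 1)
    normal = intercept_n + (beta - (intercept_n + slope_n * purity))
    return np.clip(tumor, 0, 1), np.clip(normal, 0, 1)


class TestDeriveCpgSeed:
    def test_deterministic(self):
        assert derive_cpg_seed(42, 0) == derive_cpg_seed(42, 0)

    def test_distinct_across_indices_and_seeds(self):
        seeds = {derive_cpg_seed(42, i) for i in range(1000)}
        assert len(seeds) == 1000
        assert derive_cpg_seed(42, 0) != derive_cpg_seed(43, 0)

    def test_independent_of_cpg_id(self):
        assert derive_cpg_seed(42, 5, "cg0001") == derive_cpg_seed(42, 5, "cgXXXX")

    def test_negative_seed_rejected(self):
        with pytest.raises(ValueError):
            derive_cpg_seed(-1, 0)


class TestAdjustCpg:
    def test_noiseless_single_population_line(self):
        rng = np.random.default_rng(0)
        purity = rng.uniform(0.2, 0.95, 100)
        beta = 0.2 + 0.5 * (1.0 - purity)  # tumor 0.2, normal 0.7
        adj = adjust_cpg(beta, purity, seed=1)
        assert np.allclose(adj.tumor_beta, 0.2, atol=1e-2)
        assert np.allclose(adj.normal_beta, 0.7, atol=1e-2)

    def test_brca1_like_two_population_geometry(self, brca1_like):
        beta, purity, hyper, normal_state = brca1_like
        adj = adjust_cpg(beta, purity, seed=20)
        assert adj.k_selected == 2
        # purified tumor betas are bimodal near {0, 1}
        hi = adj.tumor_beta > 0.5
        assert np.mean(np.abs(adj.tumor_beta[hi] - 1.0) < 0.15) > 0.9
        assert np.mean(np.abs(adj.tumor_beta[~hi]) < 0.15) > 0.9
        # population split matches hypermethylation truth
        acc = max(
            np.mean((adj.labels == 1) == hyper), np.mean((adj.labels == 2) == hyper)
        )
        assert acc >= 0.95
        # inferred normal background near the generating value
        assert abs(np.mean(adj.normal_beta) - normal_state) <= 0.05

    def test_outputs_clamped(self):
        rng = np.random.default_rng(3)
        purity = rng.uniform(0.2, 1.0, 60)
        beta = rng.uniform(0, 1, 60)
        adj = adjust_cpg(beta, purity, seed=0)
        for arr in (adj.tumor_beta, adj.normal_beta):
            assert np.nanmin(arr) >= 0.0 and np.nanmax(arr) <= 1.0

    def test_preclamp_population_identity(self, brca1_like):
        """Within each population: normal - tumor (pre-clamp) equals the
        tumor-fit slope, and the dual fits share residuals exactly."""
        beta, purity, _, _ = brca1_like
        adj = adjust_cpg(beta, purity, seed=20)
        for pop in range(1, adj.k_selected + 1):
            m = adj.labels == pop
            a_t, b_t = adj.tumor_fits[pop - 1]
            a_n, b_n = adj.normal_fits[pop - 1]
            diff = adj.normal_raw[m] - adj.tumor_raw[m]
            assert np.allclose(diff, b_t, atol=1e-10)
            # the two parametrizations describe one line
            assert a_n == pytest.approx(a_t + b_t, abs=1e-10)
            assert b_n == pytest.approx(-b_t, abs=1e-10)
            res_t = adj.tumor_raw[m] - a_t
            res_n = adj.normal_raw[m] - a_n
            assert np.allclose(res_t, res_n, atol=1e-10)

    def test_missing_betas_excluded_and_propagated(self):
        rng = np.random.default_rng(8)
        purity = rng.uniform(0.3, 0.9, 50)
        beta = 0.1 + 0.6 * (1 - purity) + rng.normal(0, 0.02, 50)
        beta = np.clip(beta, 0, 1)
        beta[[3, 17]] = np.nan
        adj = adjust_cpg(beta, purity, seed=5)
        assert np.isnan(adj.tumor_beta[[3, 17]]).all()
        assert (adj.labels[[3, 17]] == 0).all()
        assert np.isfinite(np.delete(adj.tumor_beta, [3, 17])).all()

    @pytest.mark.parametrize(
        "beta,purity,err",
        [
            (np.full(5, 0.5), np.full(5, 0.5), "at least"),
            (np.full(20, 0.5), np.full(20, 0.0), r"\(0, 1\]"),
            (np.full(20, 1.5), np.full(20, 0.5), r"\[0, 1\]"),
        ],
    )
    def test_precondition_errors(self, beta, purity, err):
        with pytest.raises(ValueError, match=err):
            adjust_cpg(beta, purity, seed=0)

    def test_purity_one_allowed(self):
        rng = np.random.default_rng(4)
        purity = np.concatenate([[1.0, 1.0], rng.uniform(0.3, 0.9, 48)])
        beta = np.clip(0.3 + 0.4 * (1 - purity) + rng.normal(0, 0.02, 50), 0, 1)
        adj = adjust_cpg(beta, purity, seed=2)
        assert np.isfinite(adj.tumor_beta).all()


class TestSinglePopulationAdjust:
    def test_equals_closed_form_ols(self):
        rng = np.random.default_rng(12)
        purity = rng.uniform(0.2, 0.95, 80)
        beta = np.clip(0.3 + 0.4 * (1 - purity) + rng.normal(0, 0.05, 80), 0, 1)
        tumor, normal = single_population_adjust(beta, purity)
        t0, n0 = _ols_detrend(beta, purity)
        assert np.allclose(tumor, t0, atol=1e-10)
        assert np.allclose(normal, n0, atol=1e-10)

    def test_equals_adjust_cpg_when_k1_selected(self):
        rng = np.random.default_rng(13)
        purity = rng.uniform(0.2, 0.95, 100)
        beta = np.clip(0.2 + 0.5 * (1 - purity) + rng.normal(0, 0.04, 100), 0, 1)
        adj = adjust_cpg(beta, purity, seed=6)
        assert adj.k_selected == 1
        tumor, normal = single_population_adjust(beta, purity)
        assert np.allclose(adj.tumor_beta, tumor, atol=1e-12)
        assert np.allclose(adj.normal_beta, normal, atol=1e-12)

    def test_confounds_bimodality_relative_to_mixture(self, brca1_like):
        beta, purity, hyper, _ = brca1_like
        adj = adjust_cpg(beta, purity, seed=20)
        tumor_single, _ = single_population_adjust(beta, purity)

        def separation(values):
            return abs(np.mean(values[hyper]) - np.mean(values[~hyper]))

        assert separation(tumor_single) < separation(adj.tumor_beta)

    def test_constant_beta_passes_through(self):
        rng = np.random.default_rng(14)
        purity = rng.uniform(0.2, 0.95, 30)
        beta = np.full(30, 0.42)
        tumor, normal = single_population_adjust(beta, purity)
        assert np.allclose(tumor, beta, atol=1e-12)
        assert np.allclose(normal, beta, atol=1e-12)

    def test_swapping_covariate_roles_swaps_outputs(self):
        """Regressing on purity instead of 1 - purity exchanges the tumor
        and normal outputs exactly."""
        rng = np.random.default_rng(15)
        purity = rng.uniform(0.2, 0.8, 60)
        beta = np.clip(0.3 + 0.3 * (1 - purity) + rng.normal(0, 0.03, 60), 0, 1)
        tumor, normal = single_population_adjust(beta, purity)
        tumor_sw, normal_sw = single_population_adjust(beta, 1.0 - purity)
        assert np.allclose(tumor_sw, normal, atol=1e-10)
        assert np.allclose(normal_sw, tumor, atol=1e-10)


class TestAdjustMatrix:
    def test_constant_rows_pass_through(self):
        rng = np.random.default_rng(21)
        samples = [f"S{i}" for i in range(30)]
        purity = pd.Series(rng.uniform(0.3, 0.9, 30), index=samples)
        betas = pd.DataFrame(
            np.tile([[0.2], [0.8]], (1, 30)), index=["cgA", "cgB"], columns=samples
        )
        tumor, normal, pops, summary = adjust_matrix(betas, purity, global_seed=1)
        assert np.allclose(tumor.values, betas.values, atol=1e-6)
        assert np.allclose(normal.values, betas.values, atol=1e-6)
        assert not summary["failed"].any()

    def test_worker_count_does_not_change_output(self, small_cohort):
        betas = small_cohort.observed.iloc[:12]
        t1, n1, p1, s1 = adjust_matrix(betas, small_cohort.purity, global_seed=5,
                                       n_workers=1)
        t2, n2, p2, s2 = adjust_matrix(betas, small_cohort.purity, global_seed=5,
                                       n_workers=2)
        assert np.array_equal(t1.values, t2.values)
        assert np.array_equal(n1.values, n2.values)
        assert np.array_equal(p1.values, p2.values)
        assert s1.equals(s2)

    def test_recovers_simulated_states(self, small_cohort):
        tumor, normal, pops, summary = adjust_matrix(
            small_cohort.observed, small_cohort.purity, global_seed=2
        )
        rec_tumor = population_state_matrix(pops, summary, "tumor").to_numpy()
        true_tumor = small_cohort.true_tumor_matrix()
        assert np.nanmean(np.abs(rec_tumor - true_tumor)) <= 0.05
        rec_normal = population_state_matrix(pops, summary, "normal").to_numpy()
        true_normal = small_cohort.true_normal_states[:, None]
        assert np.nanmean(np.abs(rec_normal - true_normal)) <= 0.05

    def test_recovery_error_shrinks_with_generator_noise(self):
        from purebeta import simulate_cohort

        errors = []
        for noise in (0.01, 0.05, 0.10):
            cohort = simulate_cohort(
                n_samples=100, n_cpgs=25, k_probs={1: 0.5, 2: 0.5},
                noise_sd=noise, normal_levels=(0.0, 0.3, 0.7), seed=31,
            )
            _, _, pops, summary = adjust_matrix(
                cohort.observed, cohort.purity, global_seed=3
            )
            rec = population_state_matrix(pops, summary, "tumor").to_numpy()
            errors.append(np.nanmean(np.abs(rec - cohort.true_tumor_matrix())))
        assert errors[0] < errors[1] < errors[2]

    def test_missing_purity_sample_is_fatal(self, small_cohort):
        purity = small_cohort.purity.iloc[:-1]
        dropped = small_cohort.purity.index[-1]
        with pytest.raises(ValueError, match=str(dropped)):
            adjust_matrix(small_cohort.observed, purity, global_seed=0)

    def test_failed_rows_flagged_not_fatal(self, small_cohort):
        betas = small_cohort.observed.iloc[:3].copy()
        betas.iloc[0, 5:] = np.nan  # too few observed values to fit
        tumor, normal, pops, summary = adjust_matrix(
            betas, small_cohort.purity, global_seed=4
        )
        assert summary["failed"].tolist() == [True, False, False]
        # failed row passes through unadjusted
        assert np.array_equal(
            tumor.iloc[0].values, betas.iloc[0].values, equal_nan=True
        )
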