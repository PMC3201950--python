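import numpy as np
import pytest
from scipy import stats

from epifst import (
    DiseaseModel,
    covariance_asymptotics_check,
    pair_counts,
    penetrance_table,
    simulate_case_control,
    simulate_null_dataset,
)
from epifst.simulate import (
    SimulationConfig,
    exact_multinomial_mean_cov,
    hwe_probs,
    rng_for,
    sample_pair_counts_cc,
    sample_pair_counts_null,
)


class TestNullGenerator:
    def test_deterministic_given_seed(self):
        a = simulate_null_dataset(50, seed=42)
        b = simulate_null_dataset(50, seed=42)
        assert a == b
        c = simulate_null_dataset(50, seed=43)
        assert not np.array_equal(a.genotypes, c.genotypes)

    def test_half_subjects_are_cases(self):
        ds = simulate_null_dataset(101, seed=0)
        assert ds.n_cases == 50 and ds.n_controls == 51  # controls get extra

    def test_hwe_proportions_at_half(self):
        ds = simulate_null_dataset(10000, maf_low=0.5, maf_high=0.5, seed=7)
        freqs = np.bincount(ds.genotypes[:, 0].astype(int), minlength=3) / 10000
        np.testing.assert_allclose(freqs, [0.25, 0.5, 0.25], atol=0.02)

    def test_maf_bounds_validated(self):
        with pytest.raises(ValueError):
            simulate_null_dataset(10, maf_low=0.0, maf_high=0.4)

    def test_fast_path_matches_dataset_path_in_distribution(self):
        """Multinomial cell sampling and per-subject simulation agree."""
        reps, n = 300, 400
        tallies = np.zeros((2, 9))
        for rep in range(reps):
            ds = simulate_null_dataset(n, 0.3, 0.3, seed=rep)
            pc = pair_counts(ds, 0, 1)
            tallies[0] += pc.pooled_table().ravel()
            tallies[1] += sample_pair_counts_null(
                n, 0.3, 0.3, np.random.default_rng(10_000 + rep)
            ).sum(axis=2).ravel()
        # same expected cell counts; compare via two-sample chi-square
        chi2, p, _, _ = stats.chi2_contingency(tallies)
        assert p > 0.01


class TestPenetranceModel:
    def test_null_model_flat_at_prevalence(self):
        dm = penetrance_table("dominant", 0.3, 0.8, ln_rr=0.0, prevalence=0.01)
        np.testing.assert_allclose(dm.penetrance, 0.01, atol=1e-12)

    def test_recessive_touches_only_double_homozygote(self):
        dm = penetrance_table("recessive", 0.2, 0.4, ln_rr=0.8)
        pen = dm.penetrance
        off = pen.copy()
        off[2, 2] = pen[0, 0]
        np.testing.assert_allclose(off, pen[0, 0], atol=1e-15)
        assert pen[2, 2] > pen[0, 0]

    def test_baseline_solved_by_enumeration(self):
        dm = penetrance_table("dominant", 0.3, 0.8, ln_rr=1.3, prevalence=0.01)
        total = 0.0
        for g1 in range(3):
            for g2 in range(3):
                x1 = 1.0 if g1 >= 1 else 0.0
                x2 = 1.0 if g2 >= 1 else 0.0
                p_g = hwe_probs(0.3)[g1] * hwe_probs(0.8)[g2]
                total += p_g * np.exp(1.3 * x1 * x2)
        assert dm.f0 == pytest.approx(0.01 / total, rel=1e-12)

    def test_hwe_weighted_mean_equals_prevalence(self):
        for model in ("dominant", "additive", "recessive"):
            dm = penetrance_table(model, 0.2, 0.4, ln_rr=0.65, prevalence=0.01)
            mean_pen = float((dm.genotype_probs_hwe() * dm.penetrance).sum())
            assert mean_pen == pytest.approx(0.01, abs=1e-10)

    def test_infeasible_model_rejected(self):
        # recessive with rare risk cell: baseline ~ prevalence, so a huge RR
        # pushes the (2,2) penetrance past certainty
        with pytest.raises(ValueError, match="infeasible"):
            penetrance_table("recessive", 0.05, 0.05, ln_rr=5.0, prevalence=0.3)

    def test_additive_coding_half_steps(self):
        dm = penetrance_table("additive", 0.3, 0.8, ln_rr=1.0)
        # x1 x2 = (d1/2)(d2/2): cell (1,1) carries a quarter of the effect
        assert dm.penetrance[1, 1] == pytest.approx(dm.f0 * np.exp(0.25))
        assert dm.penetrance[2, 2] == pytest.approx(dm.f0 * np.exp(1.0))

    def test_conditional_probs_bayes_consistent(self):
        dm = penetrance_table("dominant", 0.3, 0.8, ln_rr=0.8, prevalence=0.01)
        p_case, p_ctrl = dm.conditional_probs()
        assert p_case.sum() == pytest.approx(1.0)
        assert p_ctrl.sum() == pytest.approx(1.0)
        # P(g) recovered by mixing the conditionals with the prevalence
        hwe = dm.genotype_probs_hwe()
        mix = 0.01 * p_case + 0.99 * p_ctrl
        np.testing.assert_allclose(mix, hwe, atol=1e-12)


class TestCaseControlGenerator:
    def test_null_effect_reduces_to_hwe_in_both_groups(self):
        dm = penetrance_table("additive", 0.3, 0.4, ln_rr=0.0)
        ds = simulate_case_control(dm, 25000, 25000, seed=3)
        expected = hwe_probs(0.3)
        for grp in (0, 1):
            g1 = ds.genotypes[ds.status == grp, 0].astype(int)
            obs = np.bincount(g1, minlength=3)
            chi2 = (((obs - 25000 * expected) ** 2) / (25000 * expected)).sum()
            assert stats.chi2.sf(chi2, 2) > 0.001

    def test_recessive_enrichment_matches_analytic_conditional(self):
        dm = penetrance_table("recessive", 0.4, 0.4, ln_rr=2.0)
        p_case, _ = dm.conditional_probs()
        ds = simulate_case_control(dm, 20000, 100, seed=11)
        cases = ds.genotypes[ds.status == 1]
        cells = (cases[:, 0] * 3 + cases[:, 1]).astype(int)
        obs = np.bincount(cells, minlength=9) / 20000
        np.testing.assert_allclose(obs, p_case.ravel(), atol=0.01)
        # only the double-homozygote cell is enriched over HWE
        hwe = dm.genotype_probs_hwe().ravel()
        ratio = obs / hwe
        assert np.argmax(ratio) == 8

    def test_null_snp_panel_width(self):
        dm = penetrance_table("dominant", 0.3, 0.8, ln_rr=0.5)
        ds = simulate_case_control(dm, 50, 50, seed=1, n_null_snps=11)
        assert ds.n_snps == 13
        assert ds.snp_ids[:2] == ["g1", "g2"]

    def test_fast_count_path_matches_dataset_path(self):
        dm = penetrance_table("dominant", 0.3, 0.8, ln_rr=0.8)
        reps = 300
        tallies = np.zeros((2, 9))
        for rep in range(reps):
            ds = simulate_case_control(dm, 200, 200, seed=rep)
            tallies[0] += pair_counts(ds, 0, 1).counts[:, :, 1].ravel()
            tallies[1] += sample_pair_counts_cc(
                dm, 200, 200, np.random.default_rng(50_000 + rep)
            )[:, :, 1].ravel()
        chi2, p, _, _ = stats.chi2_contingency(tallies[:, tallies.sum(0) > 0])
        assert p > 0.01


class TestSeedScheme:
    def test_streams_are_order_insensitive(self):
        a = rng_for(5, 0, 7).integers(0, 1 << 30, 4)
        _ = rng_for(5, 0, 3).integers(0, 1 << 30, 4)
        b = rng_for(5, 0, 7).integers(0, 1 << 30, 4)
        np.testing.assert_array_equal(a, b)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(alpha=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(n_cases=0)


class TestCovarianceAsymptotics:
    def test_differences_shrink_with_n(self):
        df = covariance_asymptotics_check(
            n_grid=[100, 10000], reps=3000, seed=2
        )
        assert df.loc[1, "max_abs_diff"] < df.loc[0, "max_abs_diff"]

    def test_equilibrium_off_diagonal_near_zero(self):
        df = covariance_asymptotics_check(
            n_grid=[2000], reps=4000, seed=3,
            h=np.array([0.25, 0.25, 0.25, 0.25]),
        )
        assert abs(df.loc[0, "emp_cov_AB"]) < 5e-5

    def test_against_exact_multinomial_formula(self):
        h = np.array([0.4, 0.2, 0.3, 0.1])
        n = 2000
        exact = exact_multinomial_mean_cov(h, n)
        df = covariance_asymptotics_check(n_grid=[n], reps=6000, seed=4, h=h)
        emp = np.array([
            [df.loc[0, "emp_var_A"], df.loc[0, "emp_cov_AB"]],
            [df.loc[0, "emp_cov_AB"], df.loc[0, "emp_var_B"]],
        ])
        # MC error of a covariance entry over 6000 reps is ~ entry * sqrt(2/reps)
        np.testing.assert_allclose(emp, exact, atol=4 * exact.max() * np.sqrt(2 / 6000))
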