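import numpy as np
import pytest

from iamfam import (
    IamAceParams,
    InvalidParameterError,
    SimulationConfig,
    Zygosity,
    breed_offspring,
    expected_cov_iam_ace,
    expected_cov_iam_cots,
    mate_by_sorting_factor,
    simulate_equilibrium_population,
    simulate_extended_families,
)
from iamfam.covariance import _ACE_CLASSES, _COTS_CLASSES
from iamfam.simulate import run_burn_in

from conftest import class_means, cov_se, random_cots


class TestMating:
    def test_zero_target_is_random_pairing(self):
        rng = np.random.default_rng(0)
        s = rng.normal(0, 1.2, 60_000)
        s2 = rng.normal(0, 1.2, 60_000)
        ia, ib = mate_by_sorting_factor(s, s2, 0.0, rng)
        r = np.corrcoef(s[ia], s2[ib])[0, 1]
        assert abs(r) < 3 / np.sqrt(60_000)

    def test_calibrated_noise_hits_published_partner_correlation(self):
        """Target 0.68 (the sorting-factor partner correlation) is realised
        within Monte-Carlo error, and matching leaves the marginals alone."""
        rng = np.random.default_rng(1)
        n = 100_000
        s_m = rng.normal(0, 1.1, n)
        s_f = rng.normal(0, 1.1, n)
        ia, ib = mate_by_sorting_factor(s_m, s_f, 0.68, rng)
        r = np.corrcoef(s_m[ia], s_f[ib])[0, 1]
        se = (1 - 0.68**2) / np.sqrt(n)
        assert r == pytest.approx(0.68, abs=3 * se)
        # copath property: matching only permutes, variances unchanged
        np.testing.assert_array_equal(np.sort(s_m[ia]), np.sort(s_m))
        assert np.var(s_m[ia]) == pytest.approx(np.var(s_m), rel=1e-12)
        assert np.var(s_f[ib]) == pytest.approx(np.var(s_f), rel=1e-12)

    def test_extreme_target_approaches_perfect_rank_matching(self):
        rng = np.random.default_rng(2)
        s_m = rng.normal(0, 1, 20_000)
        s_f = rng.normal(0, 1, 20_000)
        ia, ib = mate_by_sorting_factor(s_m, s_f, 0.999, rng)
        perfect = np.corrcoef(np.sort(s_m), np.sort(s_f))[0, 1]
        assert np.corrcoef(s_m[ia], s_f[ib])[0, 1] > 0.995 * perfect

    def test_negative_assortment_supported(self):
        rng = np.random.default_rng(3)
        s_m = rng.normal(0, 1, 50_000)
        s_f = rng.normal(0, 1, 50_000)
        ia, ib = mate_by_sorting_factor(s_m, s_f, -0.4, rng)
        assert np.corrcoef(s_m[ia], s_f[ib])[0, 1] == pytest.approx(-0.4, abs=0.02)

    def test_infeasible_target_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(InvalidParameterError):
            mate_by_sorting_factor(np.zeros(10), np.zeros(10), 1.0, rng)
        with pytest.raises(ValueError):
            mate_by_sorting_factor(np.zeros(10), np.zeros(9), 0.3, rng)


class TestEquilibrium:
    def test_random_mating_keeps_sibling_correlation_at_half(self):
        params = IamAceParams(
            a=0.7, c=0.3, t=0.2, e=0.6, c_s=0.4, t_s=0.2, e_s=0.3, mu=0.0
        )
        rng = np.random.default_rng(5)
        wide, diag = simulate_extended_families(params, Zygosity.FS, 40_000, rng)
        assert diag["realized_sib_corr_a"] == pytest.approx(0.5, abs=0.02)
        assert diag["realized_var_a"] == pytest.approx(1.0, abs=0.02)

    def test_assortment_inflates_sibling_genetic_correlation_to_formula(
        self, ace_params
    ):
        rng = np.random.default_rng(6)
        _, _, diag = run_burn_in(ace_params, 150_000, 15, 1e-6, rng)
        traj = diag["var_a_trajectory"]
        assert traj[0] < traj[-1] <= 1.05  # variance rises then plateaus
        assert diag["realized_var_a"] == pytest.approx(1.0, abs=0.02)
        r_a = diag["realized_couple_corr_a"]
        assert (1 + r_a) / 2 == pytest.approx(ace_params.f_fs, abs=0.01)

    def test_equilibrium_formula_matches_forward_simulation(self, ace_params):
        rng = np.random.default_rng(7)
        wide, diag = simulate_extended_families(ace_params, Zygosity.FS, 100_000, rng)
        se = (1 - ace_params.f_fs**2) / np.sqrt(100_000)
        assert diag["realized_sib_corr_a"] == pytest.approx(
            ace_params.f_fs, abs=3 * se + 0.003
        )


class TestBreeding:
    def test_random_mating_parent_child_correlation_is_half_heritability(self):
        # classical expectation: r_po = a * a1 * 1/2 ... here a1 = a, no
        # environmental transmission, no assortment
        from iamfam import IamCotsParams, resolve_omega

        parent = IamAceParams(
            a=0.7, c=0.3, t=0.0, e=0.6481, c_s=0.3, t_s=0.0, e_s=0.3, mu=0.0
        )
        cots = resolve_omega(
            IamCotsParams(parent=parent, p=0.0, c1_prime=0.0, a1=0.7, a2=0.3,
                          c2=0.2, e2=0.6)
        )
        rng = np.random.default_rng(8)
        wide, _ = simulate_extended_families(cots, Zygosity.FS, 60_000, rng)
        r = np.corrcoef(wide[:, 0], wide[:, 4])[0, 1]
        expected = 0.5 * parent.a * cots.a1 / np.sqrt(
            parent.var_p
            * (cots.a1**2 + cots.a2**2 + cots.c2**2 + cots.e2**2)
        )
        assert r == pytest.approx(expected, abs=0.012)

    def test_children_of_mz_parents_genetically_closer_cousins(self, cots_params):
        rng = np.random.default_rng(9)
        out = {}
        for zyg in (Zygosity.MZ, Zygosity.FS):
            wide, _ = simulate_extended_families(cots_params, zyg, 60_000, rng)
            out[zyg] = np.corrcoef(wide[:, 4], wide[:, 6])[0, 1]
        assert out[Zygosity.MZ] > out[Zygosity.FS]

    def test_breed_offspring_contract(self, cots_params):
        rng = np.random.default_rng(10)
        n = 5000
        couples = {
            k: rng.normal(0, 1, n)
            for k in ("a_m", "a_f", "c_m", "c_f", "p_m", "p_f", "u_m", "u_f")
        }
        kids = breed_offspring(couples, cots_params, rng)
        assert kids["p_1"].shape == (n,)
        # siblings share F and C2 -> positively correlated
        assert np.corrcoef(kids["p_1"], kids["p_2"])[0, 1] > 0.1


class TestOracleAgreement:
    """Analytic matrices vs the mechanistic simulator (reduced n here; the
    full-scale sweep lives in the acceptance suite)."""

    def test_iam_ace_entries_within_monte_carlo_error(self, ace_params):
        rng = np.random.default_rng(11)
        n = 40_000
        for zyg in Zygosity:
            wide, _ = simulate_extended_families(ace_params, zyg, n, rng)
            emp = np.cov(wide.T)
            exp = expected_cov_iam_ace(ace_params, zyg).matrix
            se = cov_se(emp, n)
            emp_cls = class_means(emp, _ACE_CLASSES)
            for name, cells in _ACE_CLASSES.items():
                i, j = cells[0]
                assert abs(emp_cls[name] - exp[i, j]) < 3 * se[i, j], (zyg, name)

    def test_iam_cots_entries_within_monte_carlo_error(self, cots_params):
        rng = np.random.default_rng(12)
        n = 40_000
        for zyg in Zygosity:
            wide, _ = simulate_extended_families(cots_params, zyg, n, rng)
            emp = np.cov(wide.T)
            exp = expected_cov_iam_cots(cots_params, zyg, resolve=False).matrix
            se = cov_se(emp, n)
            emp_cls = class_means(emp, _COTS_CLASSES)
            for name, cells in _COTS_CLASSES.items():
                i, j = cells[0]
                assert abs(emp_cls[name] - exp[i, j]) < 3 * se[i, j], (zyg, name)

    def test_stratification_realised_by_simulator(self, ace_params):
        strat = IamAceParams(**{**ace_params.__dict__, "strat_var": 0.1})
        rng = np.random.default_rng(13)
        wide, _ = simulate_extended_families(strat, Zygosity.FS, 50_000, rng)
        emp = np.cov(wide.T)
        exp = expected_cov_iam_ace(strat, Zygosity.FS).matrix
        se = cov_se(emp, 50_000)
        assert np.all(np.abs(emp - exp) < 3.5 * se)


class TestPopulationAssembly:
    def test_family_table_layout_and_determinism(self, cots_params):
        cfg = SimulationConfig(
            params=cots_params,
            n_families={Zygosity.MZ: 300, Zygosity.DZ: 300, Zygosity.FS: 1200},
            seed=42,
        )
        table1, diag = simulate_equilibrium_population(cfg)
        table2, _ = simulate_equilibrium_population(cfg)
        assert table1.equals(table2)  # bit-reproducible given the seed
        assert len(table1) == 8 * 1800
        counts = table1.groupby("zygosity")["family_id"].nunique()
        assert counts["MZ"] == 300 and counts["FS"] == 1200
        roles = table1[table1.family_id == table1.family_id.iloc[0]]["role"]
        assert len(set(roles)) == 8
        # twins are same-sex, their partners opposite-sex
        fam = table1[table1.family_id == table1.family_id.iloc[0]].set_index("role")
        assert fam.loc["twin1", "sex"] == fam.loc["twin2", "sex"]
        assert fam.loc["twin1", "sex"] != fam.loc["partner1", "sex"]

    def test_missingness_masks(self, ace_params):
        cfg = SimulationConfig(
            params=ace_params,
            n_families={Zygosity.MZ: 500, Zygosity.FS: 1500},
            seed=7,
            missing_second_nuclear=0.3,
            missing_rate=0.05,
        )
        table, _ = simulate_equilibrium_population(cfg)
        miss = table.groupby("role")["phenotype"].apply(lambda s: s.isna().mean())
        assert miss["partner2"] > 0.25
        assert 0.01 < miss["twin1"] < 0.12

    def test_default_mix_reproduces_study_sample_shape(self, ace_params):
        cfg = SimulationConfig(params=ace_params)
        assert cfg.n_families == {
            Zygosity.MZ: 2447, Zygosity.DZ: 3360, Zygosity.FS: 206263,
        }

    def test_invalid_config_rejected(self, ace_params):
        with pytest.raises(ValueError):
            SimulationConfig(params=ace_params, n_families={Zygosity.FS: 0})
        with pytest.raises(ValueError):
            SimulationConfig(
                params=ace_params, n_families={Zygosity.FS: 10}, burnin=0
            )
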