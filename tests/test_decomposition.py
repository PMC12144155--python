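import numpy as np
import pytest

from iamfam import (
    IamAceParams,
    IamCotsParams,
    Variant,
    Zygosity,
    decompose_parent_offspring,
    direct_assortment_expected_genotypic_corr,
    expected_cov_iam_cots,
    implied_genotypic_partner_corr,
    offspring_variance_partition,
    resolve_omega,
    standardize_components,
)

from conftest import random_ace, random_cots


class TestVarianceShares:
    def test_share_vectors_sum_to_one(self):
        rng = np.random.default_rng(1)
        for _ in range(6):
            rep = standardize_components(random_cots(rng))
            assert sum(rep.focal_shares.values()) == pytest.approx(1, abs=1e-10)
            assert sum(rep.sorting_shares.values()) == pytest.approx(1, abs=1e-10)
            assert sum(rep.offspring_shares.values()) == pytest.approx(1, abs=1e-10)

    def test_direct_assortment_equates_focal_and_sorting_shares(self):
        params = IamAceParams(
            a=0.6, c=0.4, t=0.3, e=0.55, c_s=0.4, t_s=0.3, e_s=0.55, mu=0.3
        )
        rep = standardize_components(params)
        for key in rep.focal_shares:
            assert rep.focal_shares[key] == pytest.approx(rep.sorting_shares[key])

    def test_no_assortment_shares_are_squared_standardised_paths(self):
        params = IamAceParams(
            a=0.6, c=0.4, t=0.3, e=0.55, c_s=0.5, t_s=0.2, e_s=0.3, mu=0.0
        )
        rep = standardize_components(params)
        assert rep.focal_shares["V_A"] == pytest.approx(0.36 / params.var_p)
        assert rep.partner_corr_p == 0.0

    def test_stratification_share_reported(self, ace_params):
        strat = IamAceParams(**{**ace_params.__dict__, "strat_var": 0.1})
        rep = standardize_components(strat)
        assert rep.focal_shares["V_strat"] == pytest.approx(0.1 / (strat.var_p + 0.1))
        assert sum(rep.focal_shares.values()) == pytest.approx(1, abs=1e-10)


class TestImpliedGenotypicCorr:
    def test_published_sorting_factor_arithmetic(self, ace_params):
        """Sorting-factor heritability 0.38 x partner correlation 0.68 -> 0.26."""
        rep = standardize_components(ace_params)
        implied = rep.sorting_shares["V_A"] * rep.partner_corr_s
        assert round(implied, 2) == 0.26
        # the model-level quantity agrees with the share arithmetic when
        # omega = 0
        assert implied_genotypic_partner_corr(ace_params) == pytest.approx(implied)

    def test_no_assortment_gives_zero(self, ace_params):
        none = IamAceParams(**{**ace_params.__dict__, "mu": 0.0})
        assert implied_genotypic_partner_corr(none) == 0.0

    def test_direct_assortment_benchmark_arithmetic(self):
        """h^2 x r: 0.44 x 0.46 -> 0.20."""
        assert round(direct_assortment_expected_genotypic_corr(0.44, 0.46), 2) == 0.20
        assert direct_assortment_expected_genotypic_corr(0.0, 0.5) == 0.0
        assert direct_assortment_expected_genotypic_corr(1.0, 0.5) == 0.5
        with pytest.raises(ValueError):
            direct_assortment_expected_genotypic_corr(1.4, 0.5)

    def test_direct_variant_identity_with_benchmark(self):
        params = IamAceParams(
            a=0.6, c=0.4, t=0.3, e=0.55, c_s=0.4, t_s=0.3, e_s=0.55, mu=0.3
        )
        rep = standardize_components(params)
        assert implied_genotypic_partner_corr(params) == pytest.approx(
            direct_assortment_expected_genotypic_corr(
                rep.focal_shares["V_A"], rep.partner_corr_p
            )
        )

    def test_monotone_in_genetic_loading_on_sorting_factor(self):
        prev = -1.0
        for a in (0.3, 0.45, 0.6):
            params = IamAceParams(
                a=a, c=0.4, t=0.2, e=0.55, c_s=0.5, t_s=0.2, e_s=0.2, mu=0.3
            )
            cur = implied_genotypic_partner_corr(params)
            assert cur > prev
            prev = cur

    def test_gene_environment_covariance_raises_it(self, cots_params):
        with_omega = implied_genotypic_partner_corr(cots_params)
        without = implied_genotypic_partner_corr(cots_params.with_omega(0.0))
        assert with_omega > without


class TestParentOffspringDecomposition:
    def test_components_sum_to_matrix_entry_after_standardisation(self, cots_params):
        po = decompose_parent_offspring(cots_params)
        parts = sum(
            po[k]["total"]
            for k in ("direct_phenotypic", "passive_genetic", "passive_env")
        )
        assert parts == pytest.approx(po["total"], rel=1e-12)
        cov = expected_cov_iam_cots(cots_params, Zygosity.FS, resolve=False)
        from iamfam.covariance import offspring_moments

        denom = np.sqrt(cots_params.parent.var_p * offspring_moments(cots_params)["var_child"])
        assert po["total"] == pytest.approx(
            cov.entry("twin1", "child1a") / denom, rel=1e-10
        )

    def test_no_assortment_means_no_coparent_mediation(self):
        parent = IamAceParams(
            a=0.6, c=0.3, t=0.2, e=0.6, c_s=0.5, t_s=0.2, e_s=0.2, mu=0.0
        )
        cots = resolve_omega(
            IamCotsParams(parent=parent, p=0.08, c1_prime=0.12, a1=0.5,
                          a2=0.4, c2=0.15, e2=0.6)
        )
        po = decompose_parent_offspring(cots)
        for k in ("direct_phenotypic", "passive_genetic", "passive_env"):
            assert po[k]["via_coparent"] == 0.0
        assert po["coparent_share"] == 0.0

    def test_published_scale_parameters_reproduce_printed_split(self, cots_params):
        po = decompose_parent_offspring(cots_params)
        assert round(po["total"], 2) == 0.34
        assert round(po["passive_genetic"]["total"], 2) == 0.21
        assert round(po["passive_env"]["total"], 2) == 0.08
        assert round(po["direct_phenotypic"]["total"], 2) == 0.05
        assert round(100 * po["passive_genetic"]["share_of_total"]) == 62
        assert round(100 * po["coparent_share"]) == 39

    def test_requires_two_generation_parameters(self, ace_params):
        with pytest.raises(TypeError):
            decompose_parent_offspring(ace_params)


class TestOffspringVariancePartition:
    def test_parts_sum_to_sibling_shared_share(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            cots = random_cots(rng)
            part = offspring_variance_partition(cots)
            total = (
                part["passive_transmission"] + part["direct_transmission"]
                + part["covariance"] + part["parent_independent"]
            )
            assert total == pytest.approx(part["total_V_C"], rel=1e-12)
            rep = standardize_components(cots)
            assert part["total_V_C"] == pytest.approx(
                rep.offspring_shares["V_C"], rel=1e-12
            )

    def test_no_transmission_leaves_only_parent_independent_variance(self):
        parent = IamAceParams(
            a=0.6, c=0.3, t=0.2, e=0.6, c_s=0.5, t_s=0.2, e_s=0.2, mu=0.3
        )
        cots = resolve_omega(
            IamCotsParams(parent=parent, p=0.0, c1_prime=0.0, a1=0.5, a2=0.4,
                          c2=0.15, e2=0.6)
        )
        part = offspring_variance_partition(cots)
        assert part["passive_transmission"] == 0.0
        assert part["direct_transmission"] == 0.0
        assert part["covariance"] == 0.0
        assert part["parent_independent"] > 0.0


class TestDeltaMethodCis:
    def test_share_cis_bracket_estimates_and_match_bootstrap_scale(
        self, small_ace_dataset
    ):
        from iamfam import FamilyData, delta_method_cis, fit_model

        data = FamilyData.from_wide(small_ace_dataset)
        fit = fit_model(data, Variant.DIRECT, seed=0, n_restarts=1)
        cis = delta_method_cis(fit)
        for name, ci in cis.items():
            assert ci["lo"] <= ci["estimate"] <= ci["hi"], name
        assert 0 < cis["focal.V_A"]["se"] < 0.2

    def test_delta_method_width_matches_parametric_bootstrap(self):
        """Delta-method interval width for the heritability share agrees
        with a 200-replicate parametric bootstrap within 10%."""
        from iamfam import (
            FamilyData, IamAceParams, delta_method_cis, expected_cov_iam_ace,
            fit_model,
        )

        truth = IamAceParams(
            a=0.65, c=0.35, t=0.25, e=0.6, c_s=0.35, t_s=0.25, e_s=0.6, mu=0.4
        )
        rng = np.random.default_rng(77)
        n = 4000
        sigmas = {z: expected_cov_iam_ace(truth, z).matrix for z in Zygosity}

        def draw():
            return {
                z: rng.multivariate_normal(np.zeros(4), s, n)
                for z, s in sigmas.items()
            }

        fit = fit_model(
            FamilyData.from_wide(draw()), Variant.DIRECT, seed=0, n_restarts=1
        )
        delta_se = delta_method_cis(fit)["focal.V_A"]["se"]
        boot = []
        for _ in range(200):
            bfit = fit_model(
                FamilyData.from_wide(draw()), Variant.DIRECT, seed=0,
                n_restarts=0, compute_se=False,
            )
            rep = standardize_components(bfit.params)
            boot.append(rep.focal_shares["V_A"])
        boot_se = np.std(boot, ddof=1)
        assert delta_se == pytest.approx(boot_se, rel=0.10)


def test_report_serialisation_and_text():
    from iamfam import published_ea_cots
    import json

    rep = standardize_components(published_ea_cots())
    payload = json.loads(rep.to_json())
    assert payload["model"] == "iam_cots"
    txt = rep.as_text()
    assert "parent-offspring correlation" in txt
    assert "sorting factor" in txt
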