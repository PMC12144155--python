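"""Standardised variance components and parent-offspring correlation splits.

Converts fitted (or generating) parameters into the quantities the models
exist to report:

* standardised variance components of the focal phenotype and of the
  sorting factor, including the gene-environment share V_rAC = 2*a*c*omega;
* the implied genotypic correlation between partners,
  ``mu * (a_s + omega*c_s)**2``, which under a no-omega fit reduces to
  sorting-factor heritability x sorting-factor partner correlation;
* the parent-offspring correlation decomposed into direct phenotypic,
  passive genetic and passive environmental transmission, each split into
  the part running through the parent alone and the part mediated by the
  co-parent (the assortment inflation);
* the partition of the offspring sibling-shared variance into parts
  associated with parental phenotype/environment and a parent-independent
  remainder.

Raw values are kept at full precision; ``as_text`` rounds for display
(2 d.p. for correlations, whole percent for shares).

V_rAC is always reported as its own component and never folded into the
genetic or environmental side; with omega != 0 any such attribution would
be a convention, not an estimate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from statsmodels.tools import numdiff

from .covariance import offspring_moments, parent_child_pathways
from .estimation import FitResult, _layout
from .params import IamAceParams, IamCotsParams

__all__ = [
    "DecompositionReport",
    "standardize_components",
    "implied_genotypic_partner_corr",
    "direct_assortment_expected_genotypic_corr",
    "decompose_parent_offspring",
    "offspring_variance_partition",
    "delta_method_cis",
]


def _ace_of(params) -> IamAceParams:
    return params.parent if isinstance(params, IamCotsParams) else params


def _params_of(obj) -> IamAceParams | IamCotsParams:
    return obj.params if isinstance(obj, FitResult) else obj


@dataclass
class DecompositionReport:
    """Standardised components of one fitted model."""

    model: str
    focal_shares: dict
    sorting_shares: dict
    partner_corr_p: float
    partner_corr_s: float
    implied_genotypic_partner_corr: float
    parent_offspring: dict | None = None
    offspring_shares: dict | None = None
    offspring_vc_partition: dict | None = None
    genetic_corr_generations: float | None = None
    notes: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def conv(x):
            if isinstance(x, dict):
                return {k: conv(v) for k, v in x.items()}
            if isinstance(x, (np.floating, np.integer)):
                return float(x)
            return x

        return json.dumps(
            {k: conv(v) for k, v in self.__dict__.items()}, indent=2
        )

    def as_text(self) -> str:
        lines = [f"model: {self.model}"]
        lines.append("focal phenotype variance shares (%):")
        for k, v in self.focal_shares.items():
            lines.append(f"  {k:8s} {100 * v:5.0f}")
        lines.append("sorting factor variance shares (%):")
        for k, v in self.sorting_shares.items():
            lines.append(f"  {k:8s} {100 * v:5.0f}")
        lines.append(f"partner correlation (phenotype): {self.partner_corr_p:.2f}")
        lines.append(f"partner correlation (sorting factor): {self.partner_corr_s:.2f}")
        lines.append(
            f"implied genotypic partner correlation: "
            f"{self.implied_genotypic_partner_corr:.2f}"
        )
        if self.parent_offspring is not None:
            po = self.parent_offspring
            lines.append(f"parent-offspring correlation: {po['total']:.2f}")
            for name in ("direct_phenotypic", "passive_genetic", "passive_env"):
                lines.append(
                    f"  {name:18s} {po[name]['total']:.3f} "
                    f"({100 * po[name]['share_of_total']:.0f}%, "
                    f"co-parent part {po[name]['via_coparent']:.3f})"
                )
            lines.append(
                f"  via co-parent overall: {100 * po['coparent_share']:.0f}%"
            )
        if self.offspring_shares is not None:
            lines.append("offspring variance shares (%):")
            for k, v in self.offspring_shares.items():
                lines.append(f"  {k:8s} {100 * v:5.1f}")
        if self.offspring_vc_partition is not None:
            lines.append("offspring sibling-shared variance partition (% of Var(P)):")
            for k, v in self.offspring_vc_partition.items():
                lines.append(f"  {k:18s} {100 * v:5.1f}")
        return "\n".join(lines)


def _variance_shares(ace: IamAceParams) -> tuple[dict, dict]:
    var_p = ace.var_p + ace.strat_var
    focal = {
        "V_A": ace.a**2 / var_p,
        "V_C": ace.c**2 / var_p,
        "V_T": ace.t**2 / var_p,
        "V_E": ace.e**2 / var_p,
    }
    if ace.omega != 0.0:
        focal["V_rAC"] = 2.0 * ace.a * ace.c * ace.omega / var_p
    if ace.strat_var > 0.0:
        focal["V_strat"] = ace.strat_var / var_p
    var_s = ace.var_s
    sorting = {
        "V_A": ace.a_s**2 / var_s,
        "V_C": ace.c_s**2 / var_s,
        "V_T": ace.t_s**2 / var_s,
        "V_E": ace.e_s**2 / var_s,
    }
    if ace.omega != 0.0:
        sorting["V_rAC"] = 2.0 * ace.a_s * ace.c_s * ace.omega / var_s
    return focal, sorting


def implied_genotypic_partner_corr(fit_or_params) -> float:
    """Correlation between partners' additive-genetic values.

    ``mu * Cov(A, S)**2`` with ``Cov(A, S) = a_s + omega * c_s`` and
    Var(A) = 1.  Without gene-environment correlation this equals the
    sorting-factor heritability times the sorting-factor partner
    correlation (e.g. 0.38 x 0.68 = 0.26); with omega the gene-environment
    cross path raises it.
    """
    ace = _ace_of(_params_of(fit_or_params))
    cov_as = ace.a_s + ace.omega * ace.c_s
    return float(ace.mu * cov_as**2)


def direct_assortment_expected_genotypic_corr(h2: float, r_partner: float) -> float:
    """Expected genotypic partner correlation under direct assortment, h^2 * r.

    The benchmark the indirect-assortment estimate is compared against
    (e.g. 0.44 x 0.46 = 0.20 for educational attainment).
    """
    if not 0.0 <= h2 <= 1.0:
        raise ValueError("h2 must lie in [0, 1]")
    if abs(r_partner) > 1.0:
        raise ValueError("r_partner must lie in [-1, 1]")
    return h2 * r_partner


def decompose_parent_offspring(fit_or_params) -> dict:
    """Split the model-implied parent-offspring correlation by pathway.

    Returns a dict with, per pathway, the standardised component, its own /
    co-parent-mediated parts and its share of the total; the components sum
    to the standardised (parent, child) entry of the expected covariance
    matrix.
    """
    params = _params_of(fit_or_params)
    if not isinstance(params, IamCotsParams):
        raise TypeError("parent-offspring decomposition needs iAM-COTS parameters")
    par = params.parent
    paths = parent_child_pathways(params)
    mom = offspring_moments(params)
    denom = np.sqrt((par.var_p + par.strat_var) * mom["var_child"])
    out: dict = {}
    total = paths["total"] / denom
    coparent_sum = 0.0
    for name, own_key, cop_key in (
        ("direct_phenotypic", "direct_phenotypic_own", "direct_phenotypic_coparent"),
        ("passive_genetic", "passive_genetic_own", "passive_genetic_coparent"),
        ("passive_env", "passive_env_own", "passive_env_coparent"),
    ):
        own = paths[own_key] / denom
        cop = paths[cop_key] / denom
        out[name] = {
            "total": own + cop,
            "own": own,
            "via_coparent": cop,
            "share_of_total": (own + cop) / total if total else 0.0,
        }
        coparent_sum += cop
    if par.strat_var > 0.0:
        out["stratification"] = {
            "total": paths["stratification"] / denom,
            "own": paths["stratification"] / denom,
            "via_coparent": 0.0,
            "share_of_total": paths["stratification"] / denom / total if total else 0.0,
        }
    out["total"] = total
    out["coparent_share"] = coparent_sum / total if total else 0.0
    return out


def offspring_variance_partition(fit_or_params) -> dict:
    """Partition of the offspring sibling-shared variance (share of Var(P)).

    The offspring shared environment is F + c2*C2 with
    F = p*(P_m + P_f) + c1'*(C_m + C_f); its variance splits into a passive
    part (c1'), a direct part (p), their covariance, and the
    parent-independent remainder c2^2.  Parts sum to the offspring V_C
    share.
    """
    params = _params_of(fit_or_params)
    if not isinstance(params, IamCotsParams):
        raise TypeError("offspring variance partition needs iAM-COTS parameters")
    par = params.parent
    sc_var = offspring_moments(params)
    var_child = sc_var["var_child"]
    from .covariance import _couple_scalars  # scalar couple covariances

    sc = _couple_scalars(par)
    p, c1p = params.p, params.c1_prime
    direct = p * p * 2.0 * (par.var_p + sc["cov_pp_x"])
    passive = c1p * c1p * 2.0 * (1.0 + sc["cov_cc_x"])
    covar = 2.0 * p * c1p * 2.0 * (sc["cov_pc_own"] + sc["cov_pc_x"])
    indep = params.c2**2
    total = direct + passive + covar + indep
    return {
        "passive_transmission": passive / var_child,
        "direct_transmission": direct / var_child,
        "covariance": covar / var_child,
        "parent_independent": indep / var_child,
        "total_V_C": total / var_child,
    }


def standardize_components(fit_or_params) -> DecompositionReport:
    """Full standardised report for a fitted model (variance part always;
    intergenerational parts when the parameters are iAM-COTS)."""
    params = _params_of(fit_or_params)
    ace = _ace_of(params)
    focal, sorting = _variance_shares(ace)
    report = DecompositionReport(
        model="iam_cots" if isinstance(params, IamCotsParams) else "iam_ace",
        focal_shares=focal,
        sorting_shares=sorting,
        partner_corr_p=float(ace.partner_corr_p()),
        partner_corr_s=float(ace.partner_corr_s()),
        implied_genotypic_partner_corr=implied_genotypic_partner_corr(params),
        notes={
            "V_rAC": "variance from the A-C covariance; reported separately, "
            "never attributed to the genetic or environmental side"
        },
    )
    if isinstance(params, IamCotsParams):
        mom = offspring_moments(params)
        var_child = mom["var_child"]
        off = {
            "V_A": mom["var_g"] / var_child,
            "V_rAC": 2.0 * mom["cov_g_esh"] / var_child,
            "V_C": mom["var_esh"] / var_child,
            "V_E": params.e2**2 / var_child,
        }
        if ace.strat_var > 0.0:
            off["V_strat"] = ace.strat_var / var_child
        report.offspring_shares = off
        report.parent_offspring = decompose_parent_offspring(params)
        report.offspring_vc_partition = offspring_variance_partition(params)
        var_g = mom["var_g"]
        report.genetic_corr_generations = (
            float(params.a1 / np.sqrt(var_g)) if var_g > 0 else 0.0
        )
    return report


# ---------------------------------------------------------------------------
# delta-method confidence intervals for standardised quantities


def _report_scalars(report: DecompositionReport) -> dict:
    flat = {}
    for k, v in report.focal_shares.items():
        flat[f"focal.{k}"] = v
    for k, v in report.sorting_shares.items():
        flat[f"sorting.{k}"] = v
    flat["partner_corr_p"] = report.partner_corr_p
    flat["partner_corr_s"] = report.partner_corr_s
    flat["implied_genotypic_partner_corr"] = report.implied_genotypic_partner_corr
    if report.parent_offspring is not None:
        po = report.parent_offspring
        flat["po.total"] = po["total"]
        for name in ("direct_phenotypic", "passive_genetic", "passive_env"):
            flat[f"po.{name}"] = po[name]["total"]
        flat["po.coparent_share"] = po["coparent_share"]
    return flat


def delta_method_cis(fit: FitResult, level: float = 0.95) -> dict:
    """Wald intervals for every standardised quantity via the delta method.

    Uses the numerical Jacobian of the report vector with respect to the
    free parameters and the inverse-Hessian covariance stored on the fit.
    """
    from scipy import stats as sps
    from .covariance import resolve_omega

    if fit.vcov is None:
        raise ValueError("fit carries no parameter covariance (compute_se=False?)")
    layout = _layout(fit.model, fit.variant)
    theta0 = np.array([fit.estimates[n] for n in layout.names])

    def vec(theta):
        params, _ = layout.build(theta)
        if fit.model == "iam_cots":
            params = resolve_omega(params)
        return np.array(list(_report_scalars(standardize_components(params)).values()))

    names = list(_report_scalars(standardize_components(fit.params)).keys())
    jac = numdiff.approx_fprime(theta0, vec, centered=True)
    var = np.einsum("ij,jk,ik->i", jac, fit.vcov, jac)
    se = np.sqrt(np.clip(var, 0.0, None))
    z = sps.norm.ppf(0.5 + level / 2.0)
    point = vec(theta0)
    return {
        nm: {"estimate": float(pt), "se": float(s), "lo": float(pt - z * s),
             "hi": float(pt + z * s)}
        for nm, pt, s in zip(names, point, se)
    }
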