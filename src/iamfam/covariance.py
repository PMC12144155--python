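"""Model-implied covariance matrices for extended families via copath tracing.

Every family member's phenotype is a linear combination of jointly Gaussian
latent factors, so each cell of the family covariance matrix is a quadratic
form in small latent covariance blocks.  The blocks encode the three path
tracing rules that matter here:

* within a person the four factors (A, C, T, E) are independent apart from
  the A-C covariance ``omega``;
* between siblings, A correlates ``f`` (1 for MZ), C is the same factor,
  T correlates ``r_t`` and E is unshared;
* across a partnership the only connection is the copath ``mu`` between the
  two sorting factors: a chain X -> S_m --mu-- S_p -> Y contributes
  ``Cov(X, S) * mu * Cov(S, Y)``.  A chain may traverse at most one copath
  per partnership, which is what lets assortment induce covariance without
  touching any variance.

Matrices are filled per dyad *class* (twin, partner, in-law, ...), so
equivalent dyads are bitwise identical by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .params import (
    IamAceParams,
    IamCotsParams,
    InvalidParameterError,
    Variant,
    VariantConstraints,
    Zygosity,
    equilibrium_sibling_genetic_corr,
)

__all__ = [
    "ROLES_ACE",
    "ROLES_COTS",
    "ExpectedCovariance",
    "closed_form_partner_cov",
    "expected_cov_iam_ace",
    "expected_cov_iam_cots",
    "omega_fixed_point",
    "parent_child_pathways",
    "offspring_moments",
    "equilibrium_sibling_genetic_corr",
]

ROLES_ACE = ("twin1", "partner1", "twin2", "partner2")
ROLES_COTS = ROLES_ACE + ("child1a", "child1b", "child2a", "child2b")

# dyad classes -> representative + all (i, j) cells they occupy (upper triangle)
_ACE_CLASSES = {
    "var": [(0, 0), (1, 1), (2, 2), (3, 3)],
    "twin": [(0, 2)],
    "partner": [(0, 1), (2, 3)],
    "in_law": [(0, 3), (1, 2)],
    "co_in_law": [(1, 3)],
}
_COTS_CLASSES = {
    **_ACE_CLASSES,
    "var_child": [(4, 4), (5, 5), (6, 6), (7, 7)],
    "parent_offspring": [(0, 4), (0, 5), (1, 4), (1, 5), (2, 6), (2, 7), (3, 6), (3, 7)],
    "avuncular": [(0, 6), (0, 7), (2, 4), (2, 5)],
    "avuncular_in_law": [(1, 6), (1, 7), (3, 4), (3, 5)],
    "sibling": [(4, 5), (6, 7)],
    "cousin": [(4, 6), (4, 7), (5, 6), (5, 7)],
}


@dataclass(frozen=True)
class ExpectedCovariance:
    """Model-implied covariance matrix over family roles for one zygosity."""

    zygosity: Zygosity
    roles: tuple
    matrix: np.ndarray

    def entry(self, role_i: str, role_j: str) -> float:
        return float(self.matrix[self.roles.index(role_i), self.roles.index(role_j)])

    def to_json(self) -> str:
        return json.dumps(
            {
                "zygosity": self.zygosity.value,
                "roles": list(self.roles),
                "matrix": self.matrix.tolist(),
            }
        )

    def _check_psd(self) -> "ExpectedCovariance":
        eigvals = np.linalg.eigvalsh(self.matrix)
        if eigvals.min() < -1e-8 * max(1.0, eigvals.max()):
            raise InvalidParameterError(
                f"implied covariance matrix not positive semi-definite "
                f"(min eigenvalue {eigvals.min():.3e})"
            )
        return self


def _sigma_within(omega: float) -> np.ndarray:
    s = np.eye(4)
    s[0, 1] = s[1, 0] = omega
    return s


def _sigma_sib(f: float, r_t: float, omega: float) -> np.ndarray:
    s = np.diag([f, 1.0, r_t, 0.0])
    s[0, 1] = s[1, 0] = omega
    return s


def _parent_latent_cov(params: IamAceParams, zyg: Zygosity) -> np.ndarray:
    """16x16 covariance of (A, C, T, E) for (twin1, partner1, twin2, partner2)."""
    w_s = np.array([params.a_s, params.c_s, params.t_s, params.e_s])
    sig_w = _sigma_within(params.omega)
    sig_sib = _sigma_sib(zyg.f(params.f_fs), zyg.r_t, params.omega)
    mu = params.mu
    v = sig_w @ w_s          # Cov(own latents, own S)
    u = sig_sib @ w_s        # Cov(own latents, sibling's S)
    s_ss = float(w_s @ sig_sib @ w_s)  # Cov(S_twin1, S_twin2)

    blocks = {}
    for i in range(4):
        blocks[(i, i)] = sig_w
    blocks[(0, 2)] = sig_sib                     # twin1 - twin2
    blocks[(0, 1)] = mu * np.outer(v, v)         # twin1 - partner1 (copath)
    blocks[(2, 3)] = mu * np.outer(v, v)         # twin2 - partner2
    blocks[(0, 3)] = mu * np.outer(u, v)         # twin1 - partner2 (in-law)
    blocks[(1, 2)] = mu * np.outer(v, u)         # partner1 - twin2
    blocks[(1, 3)] = mu * mu * s_ss * np.outer(v, v)  # partner1 - partner2

    out = np.zeros((16, 16))
    for i in range(4):
        for j in range(4):
            if (i, j) in blocks:
                b = blocks[(i, j)]
            elif (j, i) in blocks:
                b = blocks[(j, i)].T
            else:
                continue
            out[4 * i : 4 * i + 4, 4 * j : 4 * j + 4] = b
    return out


def _fill_by_class(raw: np.ndarray, classes: dict) -> np.ndarray:
    """Copy each class's representative entry into all equivalent cells."""
    n = raw.shape[0]
    out = np.zeros((n, n))
    for cells in classes.values():
        rep = raw[cells[0]]
        for i, j in cells:
            out[i, j] = rep
            out[j, i] = rep
    return out


def closed_form_partner_cov(
    params: IamAceParams, variant: VariantConstraints | None = None
) -> float:
    """Closed-form phenotypic partner covariance, ``mu * Cov(P, S)**2``.

    Under the direct-assortment variant Cov(P, S) = Var(P), recovering the
    textbook ``mu * (a^2 + c^2 + t^2 + e^2)**2``.  A stratification factor
    adds its variance on top, as it does for every cross-person entry.
    """
    if variant is not None:
        params = variant.apply_ace(params)
    return params.mu * params.cov_ps**2 + params.strat_var


def expected_cov_iam_ace(
    params: IamAceParams,
    zyg: Zygosity,
    variant: VariantConstraints | None = None,
) -> ExpectedCovariance:
    """4x4 expected covariance of (twin1, partner1, twin2, partner2)."""
    if variant is not None:
        params = variant.apply_ace(params)
    w_p = np.array([params.a, params.c, params.t, params.e])
    w_s = np.array([params.a_s, params.c_s, params.t_s, params.e_s])
    sig_w = _sigma_within(params.omega)
    sig_sib = _sigma_sib(zyg.f(params.f_fs), zyg.r_t, params.omega)
    mu = params.mu
    v_p = float(w_p @ sig_w @ w_s)   # Cov(P, own S)
    u_p = float(w_p @ sig_sib @ w_s)  # Cov(P, sibling's S)
    s_ss = float(w_s @ sig_sib @ w_s)

    strat = params.strat_var
    entries = {
        "var": float(w_p @ sig_w @ w_p) + strat,
        "twin": float(w_p @ sig_sib @ w_p) + strat,
        "partner": mu * v_p * v_p + strat,
        "in_law": mu * u_p * v_p + strat,
        "co_in_law": mu * mu * s_ss * v_p * v_p + strat,
    }
    raw = np.zeros((4, 4))
    for name, cells in _ACE_CLASSES.items():
        for i, j in cells:
            raw[i, j] = raw[j, i] = entries[name]
    return ExpectedCovariance(zyg, ROLES_ACE, raw)._check_psd()


def _couple_scalars(params: IamAceParams) -> dict:
    """Scalar covariances between the two members of a partnership."""
    om, mu = params.omega, params.mu
    v_a = params.a_s + om * params.c_s          # Cov(A, S)
    v_c = params.c_s + om * params.a_s          # Cov(C, S)
    v_p = params.cov_ps                         # Cov(P, S)
    return {
        "cov_pa_own": params.a + params.c * om,     # Cov(P, own A)
        "cov_pc_own": params.c + params.a * om,     # Cov(P, own C)
        "cov_pa_x": mu * v_p * v_a,                 # Cov(P_m, A_f)
        "cov_pc_x": mu * v_p * v_c,                 # Cov(P_m, C_f)
        "cov_pp_x": mu * v_p * v_p,                 # Cov(P_m, P_f)
        "cov_aa_x": mu * v_a * v_a,                 # Cov(A_m, A_f)
        "cov_ac_x": mu * v_a * v_c,                 # Cov(A_m, C_f)
        "cov_cc_x": mu * v_c * v_c,                 # Cov(C_m, C_f)
        "v_a": v_a,
        "v_c": v_c,
        "v_p": v_p,
    }


def offspring_moments(params: IamCotsParams) -> dict:
    """Second moments of the offspring phenotype components.

    Returns variances of the genetic composite G = a1*A1' + a2*A2 and the
    shared-environment composite Esh = F + c2*C2 (where
    F = p*(P_m + P_f) + c1'*(C_m + C_f)), their covariance, the implied
    offspring gene-environment correlation, and the offspring phenotypic
    variance.
    """
    par = params.parent
    sc = _couple_scalars(par)
    a1, p, c1p = params.a1, params.p, params.c1_prime
    var_p = par.var_p
    # Cov(A1', F): A1' is the mid-parent value plus independent segregation.
    cov_a1p_f = p * (sc["cov_pa_own"] + sc["cov_pa_x"]) + c1p * (
        par.omega + sc["cov_ac_x"]
    )
    var_f = 2.0 * (
        p * p * (var_p + sc["cov_pp_x"])
        + c1p * c1p * (1.0 + sc["cov_cc_x"])
        + 2.0 * p * c1p * (sc["cov_pc_own"] + sc["cov_pc_x"])
    )
    var_g = a1 * a1 + params.a2 * params.a2
    var_esh = var_f + params.c2 * params.c2
    cov_g_esh = a1 * cov_a1p_f
    if var_g > 0 and var_esh > 0:
        omega_off = cov_g_esh / np.sqrt(var_g * var_esh)
    else:
        omega_off = 0.0
    var_child = var_g + var_esh + 2.0 * cov_g_esh + params.e2**2
    return {
        "var_g": var_g,
        "var_f": var_f,
        "var_esh": var_esh,
        "cov_g_esh": cov_g_esh,
        "cov_a1p_f": cov_a1p_f,
        "omega_offspring": float(omega_off),
        "var_child": var_child + par.strat_var,
        "var_child_nostrat": var_child,
    }


def omega_fixed_point(
    params: IamCotsParams, tol: float = 1e-10, max_iter: int = 100
) -> float:
    """Solve the gene-environment-correlation constraint of the iAM-COTS model.

    The parent-generation correlation between A1 and C1 is not free: it is
    constrained to equal the offspring gene-environment correlation
    Corr(a1*A1' + a2*A2, F + c2*C2), which itself depends on omega through
    the parental covariances.  The fixed point is found by direct iteration
    from omega = 0.
    """
    omega = params.omega
    for _ in range(max_iter):
        cur = params.with_omega(omega)
        new = offspring_moments(cur)["omega_offspring"]
        new = float(np.clip(new, -0.99, 0.99))
        if abs(new - omega) < tol:
            return new
        omega = new
    raise InvalidParameterError(
        f"omega fixed point did not converge within {max_iter} iterations"
    )


def resolve_omega(params: IamCotsParams, tol: float = 1e-10) -> IamCotsParams:
    """Return params with omega set to its fixed-point value."""
    return params.with_omega(omega_fixed_point(params, tol=tol))


def parent_child_pathways(params: IamCotsParams) -> dict:
    """Parent-offspring covariance split into its three transmission pathways.

    Each pathway (passive genetic via a1, direct phenotypic via p, passive
    environmental via c1') is further split into the part running through
    the parent alone and the part mediated by the co-parent (the terms that
    traverse the copath; they vanish when mu = 0).  The pieces sum to the
    parent-offspring covariance cell of :func:`expected_cov_iam_cots`.
    """
    par = params.parent
    sc = _couple_scalars(par)
    a1, p, c1p = params.a1, params.p, params.c1_prime
    out = {
        "passive_genetic_own": 0.5 * a1 * sc["cov_pa_own"],
        "passive_genetic_coparent": 0.5 * a1 * sc["cov_pa_x"],
        "direct_phenotypic_own": p * par.var_p,
        "direct_phenotypic_coparent": p * sc["cov_pp_x"],
        "passive_env_own": c1p * sc["cov_pc_own"],
        "passive_env_coparent": c1p * sc["cov_pc_x"],
        "stratification": par.strat_var,
    }
    out["total"] = sum(out.values())
    return out


def expected_cov_iam_cots(
    params: IamCotsParams,
    zyg: Zygosity,
    variant: VariantConstraints | None = None,
    resolve: bool = True,
) -> ExpectedCovariance:
    """8x8 expected covariance over two parent couples and their children.

    Basis construction: the 16 parent latents (A, C, T, E per adult) are
    augmented with the offspring-unique factors (A2 per child, C2 per
    couple, E2 per child) and the segregation deviations of A1' (variance
    ``k`` per child); every phenotype is a linear form in this basis.
    """
    if variant is not None:
        params = variant.apply_cots(params)
    if resolve:
        params = resolve_omega(params)
    par = params.parent
    k = par.k
    q = zyg.q

    sigma = np.zeros((30, 30))
    sigma[:16, :16] = _parent_latent_cov(par, zyg)
    a2_block = np.array(
        [
            [1.0, 0.5, q, q],
            [0.5, 1.0, q, q],
            [q, q, 1.0, 0.5],
            [q, q, 0.5, 1.0],
        ]
    )
    sigma[16:20, 16:20] = a2_block
    sigma[20:22, 20:22] = np.eye(2)
    sigma[22:26, 22:26] = np.eye(4)
    sigma[26:30, 26:30] = k * np.eye(4)

    w_p = np.array([par.a, par.c, par.t, par.e])
    a1, p, c1p = params.a1, params.p, params.c1_prime
    # weight of a child on each of its two parents' latent vectors
    w_on_parent = 0.5 * a1 * np.eye(4)[0] + p * w_p + c1p * np.eye(4)[1]

    W = np.zeros((8, 30))
    for i in range(4):  # adults
        W[i, 4 * i : 4 * i + 4] = w_p
    child_specs = [  # (row, parent persons, A2 idx, C2 idx, E2 idx, seg idx)
        (4, (0, 1), 16, 20, 22, 26),
        (5, (0, 1), 17, 20, 23, 27),
        (6, (2, 3), 18, 21, 24, 28),
        (7, (2, 3), 19, 21, 25, 29),
    ]
    for row, parents, i_a2, i_c2, i_e2, i_seg in child_specs:
        for person in parents:
            W[row, 4 * person : 4 * person + 4] = w_on_parent
        W[row, i_a2] = params.a2
        W[row, i_c2] = params.c2
        W[row, i_e2] = params.e2
        W[row, i_seg] = a1

    raw = W @ sigma @ W.T + par.strat_var
    mat = _fill_by_class(raw, _COTS_CLASSES)
    return ExpectedCovariance(zyg, ROLES_COTS, mat)._check_psd()
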