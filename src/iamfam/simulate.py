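"""Forward-time simulation of extended families under indirect assortative mating.

The generative process mirrors the structural model mechanically rather than
by sampling from its implied covariance matrix, so it can serve as an
independent Monte-Carlo oracle:

* genetics follow the infinitesimal model -- a child's transmitted additive
  value is the mid-parent value plus segregation noise of variance ``k``;
* each generation, couples form by rank-matching on the latent sorting
  factor S after adding calibrated Gaussian noise, which realises the
  copath: covariance is induced between partners while every marginal
  variance is untouched;
* the population is iterated to intergenerational equilibrium before
  families are observed, so the sibling genetic correlation f and the
  genetic variance emerge from the mechanism instead of being imposed.

Observed extended families consist of a twin/sibling pair, their partners
and (for the two-generation model) two children per couple.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .covariance import ROLES_ACE, ROLES_COTS
from .params import IamAceParams, IamCotsParams, InvalidParameterError, Zygosity

__all__ = [
    "SimulationConfig",
    "mate_by_sorting_factor",
    "breed_offspring",
    "simulate_extended_families",
    "simulate_equilibrium_population",
]


@dataclass
class SimulationConfig:
    """Settings for one synthetic-population run.

    ``n_families`` gives the number of extended families per zygosity group.
    The study-shaped default mix is heavily dominated by full-sibling
    families.  ``burnin`` generations of assortment + breeding precede any
    observation; the burn-in stops early once the genetic variance changes
    by less than ``conv_tol`` between generations.
    """

    params: IamAceParams | IamCotsParams
    n_families: Mapping[Zygosity, int] = field(
        default_factory=lambda: {Zygosity.MZ: 2447, Zygosity.DZ: 3360, Zygosity.FS: 206263}
    )
    burnin: int = 15
    conv_tol: float = 1e-4
    seed: int | None = None
    missing_second_nuclear: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.burnin < 1:
            raise ValueError("burnin must be >= 1")
        if any(n <= 0 for n in self.n_families.values()):
            raise ValueError("n_families must be positive")


def _ace_of(params: IamAceParams | IamCotsParams) -> IamAceParams:
    return params.parent if isinstance(params, IamCotsParams) else params


def mate_by_sorting_factor(
    pool_m: np.ndarray,
    pool_f: np.ndarray,
    target_corr: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Pair two pools by rank-matching on the sorting factor.

    Gaussian noise of variance ``Var(S) * (1 - r) / r`` is added to each
    pool's S before ranking; pairing equal ranks then yields
    ``Corr(S_m, S_f) = r`` for bivariate-normal S while leaving both
    marginals exactly unchanged (matching only permutes individuals).
    Returns index arrays (idx_m, idx_f) such that couple ``i`` is
    ``(pool_m[idx_m[i]], pool_f[idx_f[i]])``.
    """
    n = len(pool_m)
    if len(pool_f) != n:
        raise ValueError("pools must have equal size")
    r = float(target_corr)
    if abs(r) >= 1.0:
        raise InvalidParameterError(f"infeasible matching target {r}")
    if r == 0.0:
        return rng.permutation(n), rng.permutation(n)
    var_s = float(np.var(np.concatenate([pool_m, pool_f])))
    noise_var = var_s * (1.0 - abs(r)) / abs(r)
    x_m = pool_m + rng.normal(0.0, np.sqrt(noise_var), n)
    x_f = np.sign(r) * pool_f + rng.normal(0.0, np.sqrt(noise_var), n)
    return np.argsort(x_m, kind="stable"), np.argsort(x_f, kind="stable")


def _child_c(ace: IamAceParams, mp, rng):
    """Sibling-shared C with the equilibrium A-C covariance omega built in."""
    f = ace.f_fs
    om = ace.omega
    resid_var = 1.0 - om * om / f
    if resid_var < 0:
        raise InvalidParameterError("omega^2 exceeds f; C variance negative")
    return (om / f) * mp + rng.normal(0.0, np.sqrt(resid_var), mp.shape)


def _sorting_factor(ace: IamAceParams, a, c, t, e):
    return ace.a_s * a + ace.c_s * c + ace.t_s * t + ace.e_s * e


def run_burn_in(
    ace: IamAceParams,
    n_couples: int,
    burnin: int,
    conv_tol: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Iterate assortment + breeding until the genetic variance stabilises.

    Returns the final couples' additive-genetic values (A_m, A_f) and a
    diagnostics dict with the variance / correlation trajectories.
    """
    n_couples += n_couples % 2
    a_m = rng.normal(0.0, 1.0, n_couples)
    a_f = rng.normal(0.0, 1.0, n_couples)
    var_a_traj, r_s_traj, var_s_traj = [], [], []
    prev_var = 1.0
    generations = 0
    for _ in range(burnin):
        mp = 0.5 * (a_m + a_f)
        mp2 = np.repeat(mp, 2)
        a_kids = mp2 + rng.normal(0.0, np.sqrt(ace.k), 2 * n_couples)
        c_kids = _child_c(ace, mp2, rng)
        t_kids = rng.normal(0.0, 1.0, 2 * n_couples)
        e_kids = rng.normal(0.0, 1.0, 2 * n_couples)
        s = _sorting_factor(ace, a_kids, c_kids, t_kids, e_kids)
        # children of even-indexed couples marry children of odd-indexed ones
        fam = np.repeat(np.arange(n_couples), 2)
        half_a = np.flatnonzero(fam % 2 == 0)
        half_b = np.flatnonzero(fam % 2 == 1)
        target = ace.mu * float(np.var(s))
        idx_a, idx_b = mate_by_sorting_factor(s[half_a], s[half_b], target, rng)
        a_m = a_kids[half_a][idx_a]
        a_f = a_kids[half_b][idx_b]
        generations += 1
        var_a = float(np.var(a_kids))
        var_a_traj.append(var_a)
        var_s_traj.append(float(np.var(s)))
        r_s_traj.append(float(np.corrcoef(a_m, a_f)[0, 1]))
        if abs(var_a - prev_var) < conv_tol and generations >= 3:
            break
        prev_var = var_a
    # rank matching leaves couples ordered by sorting-factor rank; restore
    # exchangeability so downstream slices are random subsets
    perm = rng.permutation(len(a_m))
    a_m, a_f = a_m[perm], a_f[perm]
    diagnostics = {
        "generations": generations,
        "var_a_trajectory": var_a_traj,
        "var_s_trajectory": var_s_traj,
        "couple_corr_a_trajectory": r_s_traj,
        "realized_couple_corr_a": float(np.corrcoef(a_m, a_f)[0, 1]),
        "realized_var_a": var_a_traj[-1],
    }
    return a_m, a_f, diagnostics


def breed_offspring(
    couples: dict, params: IamCotsParams, rng: np.random.Generator
) -> dict:
    """Two children per couple under the iAM-COTS transmission rules.

    ``couples`` maps 'a_m', 'a_f', 'c_m', 'c_f', 'p_m', 'p_f', 'u_m', 'u_f'
    to arrays (U carries offspring-unique genetic variance through the
    parents without affecting their phenotypes).  Returns per-child latents
    and phenotypes (keys suffixed _1 / _2).
    """
    ace = params.parent
    n = len(couples["a_m"])
    k = ace.k
    mp = 0.5 * (couples["a_m"] + couples["a_f"])
    mp_u = 0.5 * (couples["u_m"] + couples["u_f"])
    shared_env = params.p * (couples["p_m"] + couples["p_f"]) + params.c1_prime * (
        couples["c_m"] + couples["c_f"]
    )
    c2 = rng.normal(0.0, 1.0, n)
    out = {"f_env": shared_env}
    for j in (1, 2):
        a1p = mp + rng.normal(0.0, np.sqrt(k), n)
        a2 = mp_u + rng.normal(0.0, np.sqrt(0.5), n)
        e2 = rng.normal(0.0, 1.0, n)
        pheno = (
            params.a1 * a1p
            + params.a2 * a2
            + shared_env
            + params.c2 * c2
            + params.e2 * e2
        )
        out[f"a1p_{j}"] = a1p
        out[f"a2_{j}"] = a2
        out[f"p_{j}"] = pheno
    return out


def simulate_extended_families(
    params: IamAceParams | IamCotsParams,
    zyg: Zygosity,
    n_families: int,
    rng: np.random.Generator,
    burnin: int = 15,
    conv_tol: float = 1e-4,
    couples: tuple[np.ndarray, np.ndarray] | None = None,
    return_latents: bool = False,
) -> tuple[np.ndarray, dict]:
    """Simulate one zygosity group; returns a wide phenotype matrix.

    Columns follow ``ROLES_ACE`` (4) for iAM-ACE parameters or
    ``ROLES_COTS`` (8) for iAM-COTS parameters.  ``couples`` allows reuse of
    an equilibrium population across zygosity groups (at least
    ``3 * n_families`` couples are consumed: one third produce the sibling
    pairs, two thirds produce the partner pool).
    """
    ace = _ace_of(params)
    is_cots = isinstance(params, IamCotsParams)
    diagnostics: dict = {}
    n = n_families
    f = ace.f_fs
    if ace.omega == 0.0:
        # iterate the population forward so the equilibrium genetic variance
        # and sibling correlation emerge from the mechanism
        if couples is None:
            a_m, a_f, diagnostics = run_burn_in(ace, 3 * n, burnin, conv_tol, rng)
        else:
            a_m, a_f = couples
        if len(a_m) < 3 * n:
            raise ValueError("equilibrium population too small for requested families")
        mp = 0.5 * (a_m[:n] + a_f[:n])
        mp_p = 0.5 * (a_m[n : 3 * n] + a_f[n : 3 * n])
        a_pool = mp_p + rng.normal(0.0, np.sqrt(ace.k), 2 * n)
        c_pool = _child_c(ace, mp_p, rng)
    else:
        # with a gene-environment covariance the parent generation is drawn
        # at its nominal equilibrium (Var(A)=1, sib corr f, Cov(A,C)=omega);
        # matching and breeding below remain fully mechanistic
        mp = rng.normal(0.0, np.sqrt(f), n)
        a_pool = rng.normal(0.0, 1.0, 2 * n)
        c_pool = ace.omega * a_pool + rng.normal(
            0.0, np.sqrt(1.0 - ace.omega**2), 2 * n
        )
    # --- sibling pairs share the mid-parent genetic value mp ---
    if zyg is Zygosity.MZ:
        seg = rng.normal(0.0, np.sqrt(ace.k), n)
        a_sib = np.stack([mp + seg, mp + seg], axis=1)
        u_sib = np.stack([rng.normal(0.0, 1.0, n)] * 2, axis=1)
    else:
        a_sib = mp[:, None] + rng.normal(0.0, np.sqrt(ace.k), (n, 2))
        u_sh = rng.normal(0.0, np.sqrt(0.5), n)
        u_sib = u_sh[:, None] + rng.normal(0.0, np.sqrt(0.5), (n, 2))
    c_sib = np.repeat(_child_c(ace, mp, rng)[:, None], 2, axis=1)
    if zyg.r_t == 1.0:
        t_sib = np.repeat(rng.normal(0.0, 1.0, n)[:, None], 2, axis=1)
    else:
        t_sib = rng.normal(0.0, 1.0, (n, 2))
    e_sib = rng.normal(0.0, 1.0, (n, 2))

    # --- remaining latents of the partner pool ---
    t_pool = rng.normal(0.0, 1.0, 2 * n)
    e_pool = rng.normal(0.0, 1.0, 2 * n)
    u_pool = rng.normal(0.0, 1.0, 2 * n)

    s_sib = _sorting_factor(ace, a_sib, c_sib, t_sib, e_sib)
    s_pool = _sorting_factor(ace, a_pool, c_pool, t_pool, e_pool)
    pooled_var = float(np.var(np.concatenate([s_sib.ravel(), s_pool])))
    target = ace.mu * pooled_var
    idx_s, idx_p = mate_by_sorting_factor(s_sib.ravel(), s_pool, target, rng)
    partner_of = np.empty(2 * n, dtype=int)
    partner_of[idx_s] = idx_p

    def pheno(a, c, t, e):
        return ace.a * a + ace.c * c + ace.t * t + ace.e * e

    p_sib = pheno(a_sib, c_sib, t_sib, e_sib)
    p_pool = pheno(a_pool, c_pool, t_pool, e_pool)

    part_idx = partner_of.reshape(n, 2)  # partner of twin1 / twin2 per family
    wide = np.empty((n, 8 if is_cots else 4))
    wide[:, 0] = p_sib[:, 0]
    wide[:, 1] = p_pool[part_idx[:, 0]]
    wide[:, 2] = p_sib[:, 1]
    wide[:, 3] = p_pool[part_idx[:, 1]]

    latents = {
        "a_sib": a_sib,
        "a_partner": np.stack([a_pool[part_idx[:, 0]], a_pool[part_idx[:, 1]]], axis=1),
        "c_sib": c_sib,
        "s_sib": s_sib,
        "s_partner": np.stack([s_pool[part_idx[:, 0]], s_pool[part_idx[:, 1]]], axis=1),
    }

    if is_cots:
        for couple_no in (0, 1):
            pi = part_idx[:, couple_no]
            couple_latents = {
                "a_m": a_sib[:, couple_no],
                "a_f": a_pool[pi],
                "c_m": c_sib[:, couple_no],
                "c_f": c_pool[pi],
                "p_m": p_sib[:, couple_no],
                "p_f": p_pool[pi],
                "u_m": u_sib[:, couple_no],
                "u_f": u_pool[pi],
            }
            kids = breed_offspring(couple_latents, params, rng)
            wide[:, 4 + 2 * couple_no] = kids["p_1"]
            wide[:, 5 + 2 * couple_no] = kids["p_2"]
            latents[f"kids_{couple_no}"] = kids

    if ace.strat_var > 0:
        wide += rng.normal(0.0, np.sqrt(ace.strat_var), n)[:, None]

    diagnostics["realized_sib_corr_a"] = float(np.corrcoef(a_sib[:, 0], a_sib[:, 1])[0, 1])
    diagnostics["realized_partner_corr_s"] = float(
        np.corrcoef(s_sib.ravel(), s_pool[partner_of])[0, 1]
    )
    if return_latents:
        diagnostics["latents"] = latents
    return wide, diagnostics


def simulate_equilibrium_population(config: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate all zygosity groups and assemble a long-format family table.

    One burn-in is shared by the groups; each group consumes a disjoint set
    of equilibrium couples.  Returns the family table (one row per
    individual) and a diagnostics dict.
    """
    rng = np.random.default_rng(config.seed)
    ace = _ace_of(config.params)
    is_cots = isinstance(config.params, IamCotsParams)
    roles = ROLES_COTS if is_cots else ROLES_ACE
    total = 3 * sum(config.n_families.values())
    if ace.omega == 0.0:
        a_m, a_f, diagnostics = run_burn_in(
            ace, total, config.burnin, config.conv_tol, rng
        )
    else:
        a_m = a_f = None
        diagnostics = {}

    frames = []
    offset = 0
    fam_offset = 0
    for zyg in (Zygosity.MZ, Zygosity.DZ, Zygosity.FS):
        n = config.n_families.get(zyg, 0)
        if n == 0:
            continue
        sl = slice(offset, offset + 3 * n)
        couples = (a_m[sl], a_f[sl]) if a_m is not None else None
        wide, diag_z = simulate_extended_families(
            config.params, zyg, n, rng, couples=couples
        )
        offset += 3 * n
        diagnostics[f"group_{zyg.value}"] = diag_z
        if config.missing_second_nuclear > 0:
            drop = rng.random(n) < config.missing_second_nuclear
            cols = [3] + ([6, 7] if is_cots else [])
            wide[np.ix_(drop, cols)] = np.nan
        if config.missing_rate > 0:
            wide[rng.random(wide.shape) < config.missing_rate] = np.nan

        n_roles = len(roles)
        sex_twin = rng.integers(0, 2, n)
        sex = np.empty((n, n_roles), dtype=object)
        sex[:, 0] = sex[:, 2] = np.where(sex_twin == 1, "F", "M")
        sex[:, 1] = sex[:, 3] = np.where(sex_twin == 1, "M", "F")
        if is_cots:
            sex[:, 4:] = np.where(rng.integers(0, 2, (n, 4)) == 1, "F", "M")
        frames.append(
            pd.DataFrame(
                {
                    "family_id": np.repeat(np.arange(fam_offset, fam_offset + n), n_roles),
                    "zygosity": zyg.value,
                    "role": np.tile(roles, n),
                    "sex": sex.ravel(),
                    "generation": np.tile(
                        ["parent"] * 4 + ["offspring"] * (n_roles - 4), n
                    ),
                    "phenotype": wide.ravel(),
                }
            )
        )
        fam_offset += n
    table = pd.concat(frames, ignore_index=True)
    return table, diagnostics
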