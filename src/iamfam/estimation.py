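"""Full-information maximum likelihood estimation of the family models.

Families are grouped by zygosity and missingness pattern; within a group
every family shares the same expected sub-covariance, so the likelihood is
evaluated from per-group sufficient statistics (count, mean, scatter) and
its cost does not grow with the number of families.  Optimisation is
bounded quasi-Newton (L-BFGS-B) with moment-based starting values and
seeded jittered restarts; inadmissible parameter regions (non-PSD implied
covariance, |mu|*Var(S) too close to 1) are handled with a large smooth
penalty.  Standard errors come from the numerical Hessian of -2LL at the
optimum; the omega constraint of the two-generation model is resolved by
fixed-point substitution inside every likelihood evaluation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.tools import numdiff

from .covariance import (
    ROLES_ACE,
    ROLES_COTS,
    ExpectedCovariance,
    expected_cov_iam_ace,
    expected_cov_iam_cots,
    resolve_omega,
)
from .params import (
    IamAceParams,
    IamCotsParams,
    InvalidParameterError,
    Variant,
    VariantConstraints,
    Zygosity,
)
from . import io as fio

__all__ = [
    "FamilyData",
    "FitResult",
    "EstimationError",
    "family_loglik",
    "fit_model",
    "fit_nested_pair",
    "lrt",
    "wald_ci",
]

_PENALTY = 1e12
_LOG2PI = np.log(2.0 * np.pi)


class EstimationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# data container


class FamilyData:
    """Pattern-grouped sufficient statistics of a family phenotype table."""

    def __init__(self, wide: dict, roles: tuple):
        self.roles = tuple(roles)
        self.n_roles = len(roles)
        self.groups = []  # (zyg, obs_idx, n, mean, scatter/n)
        self.n_families = 0
        self.pattern_counts: dict = {}
        for zyg, mat in wide.items():
            obs = ~np.isnan(mat)
            keep = obs.any(axis=1)
            mat, obs = mat[keep], obs[keep]
            self.n_families += mat.shape[0]
            patterns, inverse = np.unique(obs, axis=0, return_inverse=True)
            for pi, pat in enumerate(patterns):
                rows = mat[inverse == pi][:, pat]
                n = rows.shape[0]
                xbar = rows.mean(axis=0)
                centred = rows - xbar
                s = centred.T @ centred / n
                idx = np.flatnonzero(pat)
                self.groups.append((zyg, idx, n, xbar, s))
                key = zyg.value + ":" + "".join("1" if o else "0" for o in pat)
                self.pattern_counts[key] = int(n)
        if not self.groups:
            raise EstimationError("no observed data")
        self.zygosities = sorted({g[0] for g in self.groups}, key=lambda z: z.value)

    @classmethod
    def from_table(cls, df: pd.DataFrame, roles: tuple | None = None) -> "FamilyData":
        fio.validate_family_table(df)
        if roles is None:
            roles = (
                ROLES_COTS
                if df.loc[df["phenotype"].notna(), "role"].isin(ROLES_COTS[4:]).any()
                else ROLES_ACE
            )
        return cls(fio.to_wide(df, roles), roles)

    @classmethod
    def from_wide(cls, wide: dict, roles: tuple | None = None) -> "FamilyData":
        if roles is None:
            k = next(iter(wide.values())).shape[1]
            roles = ROLES_COTS if k == 8 else ROLES_ACE
        return cls(wide, roles)

    def observed_moments(self, zyg: Zygosity):
        """Complete-case mean/covariance for starting values (may be None)."""
        for g_zyg, idx, n, xbar, s in self.groups:
            if g_zyg is zyg and len(idx) == self.n_roles and n > self.n_roles:
                return xbar, s
        return None


# ---------------------------------------------------------------------------
# likelihood


def family_loglik(
    family_obs: np.ndarray, expcov: ExpectedCovariance, means: np.ndarray
) -> float:
    """Log-likelihood contribution of one family (NaN entries = unobserved)."""
    y = np.asarray(family_obs, dtype=float)
    obs = ~np.isnan(y)
    if not obs.any():
        raise ValueError("family has no observed members")
    sub = expcov.matrix[np.ix_(obs, obs)]
    diff = y[obs] - np.asarray(means, dtype=float)[obs]
    try:
        chol = np.linalg.cholesky(sub)
    except np.linalg.LinAlgError as exc:
        raise InvalidParameterError("singular observed sub-matrix") from exc
    z = np.linalg.solve(chol, diff)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    return float(-0.5 * (obs.sum() * _LOG2PI + logdet + z @ z))


def _neg2ll(data: FamilyData, covs: dict, means: np.ndarray) -> float:
    total = 0.0
    for zyg, idx, n, xbar, s in data.groups:
        sigma = covs[zyg][np.ix_(idx, idx)]
        try:
            chol = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return _PENALTY
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        sinv_s = np.linalg.solve(chol.T, np.linalg.solve(chol, s))
        diff = xbar - means[idx]
        z = np.linalg.solve(chol, diff)
        total += n * (len(idx) * _LOG2PI + logdet + np.trace(sinv_s) + z @ z)
    return float(total)


# ---------------------------------------------------------------------------
# free-parameter layout per model/variant


@dataclass(frozen=True)
class _Layout:
    model: str  # "iam_ace" | "iam_cots"
    variant: Variant
    names: tuple
    bounds: tuple

    def build(self, theta: np.ndarray):
        """Map a free-parameter vector to (params, means array)."""
        d = dict(zip(self.names, theta))
        ace = IamAceParams(
            a=d["a"],
            c=d["c"],
            t=d["t"],
            e=d["e"],
            c_s=d.get("c_s", d["c"]),
            t_s=d.get("t_s", d["t"]),
            e_s=d.get("e_s", d["e"]),
            mu=d["mu"],
            strat_var=d.get("strat_var", 0.0),
        )
        if self.model == "iam_ace":
            means = np.full(4, d["mean_parent"])
            return ace, means
        cots = IamCotsParams(
            parent=ace,
            p=d.get("p", 0.0),
            c1_prime=d.get("c1_prime", 0.0),
            a1=d.get("a1", 0.0),
            a2=d["a2"],
            c2=d["c2"],
            e2=d["e2"],
        )
        means = np.concatenate(
            [np.full(4, d["mean_parent"]), np.full(4, d["mean_offspring"])]
        )
        return cots, means


_PATH_B = (0.0, 5.0)
_TILDE_B = (-5.0, 5.0)
_MU_B = (-3.0, 3.0)
_MEAN_B = (-10.0, 10.0)


def _layout(model: str, variant: Variant) -> _Layout:
    names: list = ["a", "c", "t", "e"]
    bounds: list = [_PATH_B] * 4
    if variant in (Variant.FULL_INDIRECT, Variant.STRATIFICATION) or model == "iam_cots":
        if variant not in (Variant.DIRECT, Variant.DIRECT_WITH_ERROR):
            names += ["c_s", "t_s", "e_s"]
            bounds += [_TILDE_B] * 3
    if variant is Variant.DIRECT_WITH_ERROR:
        names += ["e_s"]
        bounds += [_TILDE_B]
    names += ["mu"]
    bounds += [_MU_B]
    if variant is Variant.STRATIFICATION:
        names += ["strat_var"]
        bounds += [(0.0, 5.0)]
    if model == "iam_cots":
        if variant is not Variant.NO_DIRECT_TRANSMISSION:
            names += ["p"]
            bounds += [(-2.0, 2.0)]
        if variant is not Variant.NO_PASSIVE_ENV:
            names += ["c1_prime"]
            bounds += [(-5.0, 5.0)]
        if variant is not Variant.NO_PASSIVE_GENETIC:
            names += ["a1"]
            bounds += [_PATH_B]
        names += ["a2", "c2", "e2"]
        bounds += [_PATH_B] * 3
        names += ["mean_parent", "mean_offspring"]
        bounds += [_MEAN_B] * 2
    else:
        names += ["mean_parent"]
        bounds += [_MEAN_B]
    return _Layout(model, Variant(variant), tuple(names), tuple(bounds))


def _start_values(layout: _Layout, data: FamilyData) -> np.ndarray:
    """Moment-based starting values (classical twin heuristics)."""
    var_p, r_partner, mean_par, mean_off = 1.0, 0.4, 0.0, 0.0
    mom = None
    for zyg in data.zygosities:
        mom = data.observed_moments(zyg) or mom
    if mom is not None:
        xbar, s = mom
        var_p = float(np.mean(np.diag(s)[:4]))
        r_partner = float(
            np.clip(s[0, 1] / np.sqrt(s[0, 0] * s[1, 1]), -0.9, 0.9)
        )
        mean_par = float(np.mean(xbar[:4]))
        if len(xbar) == 8:
            mean_off = float(np.mean(xbar[4:]))
    sd = np.sqrt(max(var_p, 1e-3))
    base = {
        "a": 0.6 * sd,
        "c": 0.35 * sd,
        "t": 0.25 * sd,
        "e": 0.6 * sd,
        "c_s": 0.5 * sd,
        "t_s": 0.2 * sd,
        "e_s": 0.2 * sd,
        "strat_var": 0.05,
        "p": 0.08,
        "c1_prime": 0.1,
        "a1": 0.55 * sd,
        "a2": 0.4 * sd,
        "c2": 0.2 * sd,
        "e2": 0.6 * sd,
        "mean_parent": mean_par,
        "mean_offspring": mean_off,
    }
    # start mu so the implied partner correlation matches the observed one
    trial = dict(base)
    var_s0 = sum(trial[k] ** 2 for k in ("a", "c_s", "t_s", "e_s"))
    if layout.variant in (Variant.DIRECT, Variant.DIRECT_WITH_ERROR):
        var_s0 = sum(trial[k] ** 2 for k in ("a", "c", "t", "e"))
    base["mu"] = float(np.clip(r_partner / max(var_s0, 1e-3), -0.9, 0.9))
    return np.array([base[name] for name in layout.names])


@dataclass
class FitResult:
    """Converged (or best-found) FIML solution for one model variant."""

    model: str
    variant: Variant
    estimates: dict
    se: dict
    minus2ll: float
    n_params: int
    converged: bool
    grad_norm: float
    n_families: int
    pattern_counts: dict
    omega: float = 0.0
    vcov: np.ndarray | None = None
    roles: tuple = ROLES_ACE

    @property
    def params(self) -> IamAceParams | IamCotsParams:
        layout = _layout(self.model, self.variant)
        theta = np.array([self.estimates[n] for n in layout.names])
        params, _ = layout.build(theta)
        if self.model == "iam_cots":
            params = params.with_omega(self.omega)
        return params

    @property
    def means(self) -> np.ndarray:
        layout = _layout(self.model, self.variant)
        theta = np.array([self.estimates[n] for n in layout.names])
        return layout.build(theta)[1]

    def expected_cov(self, zyg: Zygosity) -> ExpectedCovariance:
        if self.model == "iam_ace":
            return expected_cov_iam_ace(self.params, zyg)
        return expected_cov_iam_cots(self.params, zyg, resolve=False)

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": self.model,
                "variant": self.variant.value,
                "estimates": self.estimates,
                "se": self.se,
                "minus2ll": self.minus2ll,
                "n_params": self.n_params,
                "converged": self.converged,
                "grad_norm": self.grad_norm,
                "n_families": self.n_families,
                "pattern_counts": self.pattern_counts,
                "omega": self.omega,
            },
            indent=2,
        )


def _objective(layout: _Layout, data: FamilyData):
    resolve_cache: dict = {}

    def fun(theta: np.ndarray) -> float:
        try:
            params, means = layout.build(theta)
            if layout.model == "iam_cots":
                params = resolve_omega(params)
            covs = {}
            for zyg in data.zygosities:
                if layout.model == "iam_ace":
                    covs[zyg] = expected_cov_iam_ace(params, zyg).matrix
                else:
                    covs[zyg] = expected_cov_iam_cots(
                        params, zyg, resolve=False
                    ).matrix
        except (InvalidParameterError, ValueError):
            return _PENALTY
        return _neg2ll(data, covs, means)

    return fun


def fit_model(
    data: FamilyData | pd.DataFrame,
    variant: Variant | VariantConstraints = Variant.FULL_INDIRECT,
    model: str | None = None,
    n_restarts: int = 5,
    seed: int = 0,
    start: np.ndarray | None = None,
    compute_se: bool = True,
    maxiter: int = 1000,
) -> FitResult:
    """Fit a model variant to family data by FIML.

    ``model`` is "iam_ace" or "iam_cots" (inferred from the data layout when
    None).  The optimiser runs from a moment-based start plus ``n_restarts``
    jittered restarts (deterministic given ``seed``); the best -2LL wins.
    """
    if isinstance(data, pd.DataFrame):
        data = FamilyData.from_table(data)
    if isinstance(variant, VariantConstraints):
        variant = variant.variant
    variant = Variant(variant)
    if model is None:
        model = "iam_cots" if data.n_roles == 8 else "iam_ace"
    if len(data.zygosities) < 2:
        raise EstimationError(
            "identification requires at least two zygosity groups"
        )
    layout = _layout(model, variant)
    fun = _objective(layout, data)
    rng = np.random.default_rng(seed)
    base_start = _start_values(layout, data)
    starts = [base_start] if start is None else [np.asarray(start, float), base_start]
    for _ in range(n_restarts):
        jitter = rng.normal(0.0, 0.08, base_start.shape)
        starts.append(base_start + jitter)
    lo = np.array([b[0] for b in layout.bounds])
    hi = np.array([b[1] for b in layout.bounds])

    best = None
    for s0 in starts:
        s0 = np.clip(s0, lo + 1e-6, hi - 1e-6)
        res = optimize.minimize(
            fun,
            s0,
            method="L-BFGS-B",
            bounds=layout.bounds,
            options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or best.fun >= _PENALTY:
        raise EstimationError("all optimisation attempts failed")

    theta = best.x
    params, _ = layout.build(theta)
    omega = 0.0
    if model == "iam_cots":
        omega = resolve_omega(params).omega

    se = {n: float("nan") for n in layout.names}
    vcov = None
    if compute_se:
        try:
            hess = numdiff.approx_hess1(theta, fun)
            vcov = 2.0 * np.linalg.inv(hess)
            diag = np.diag(vcov)
            se = {
                n: (float(np.sqrt(d)) if d > 0 else float("nan"))
                for n, d in zip(layout.names, diag)
            }
        except np.linalg.LinAlgError:
            pass

    grad = optimize.approx_fprime(theta, fun, 1e-6)
    return FitResult(
        model=model,
        variant=variant,
        estimates={n: float(v) for n, v in zip(layout.names, theta)},
        se=se,
        minus2ll=float(best.fun),
        n_params=len(layout.names),
        converged=bool(best.success),
        grad_norm=float(np.linalg.norm(grad)),
        n_families=data.n_families,
        pattern_counts=data.pattern_counts,
        omega=float(omega),
        vcov=vcov,
        roles=tuple(data.roles),
    )


def fit_nested_pair(
    data: FamilyData | pd.DataFrame,
    full_variant: Variant,
    nested_variant: Variant,
    model: str | None = None,
    seed: int = 0,
    n_restarts: int = 5,
    compute_se: bool = True,
) -> tuple[FitResult, FitResult]:
    """Fit a full and a nested variant, starting the nested fit from the
    projection of the full solution (guards against negative LRT)."""
    if isinstance(data, pd.DataFrame):
        data = FamilyData.from_table(data)
    full = fit_model(
        data, full_variant, model=model, seed=seed, n_restarts=n_restarts,
        compute_se=compute_se,
    )
    nested_layout = _layout(full.model, Variant(nested_variant))
    proj = np.array(
        [full.estimates.get(n, 0.05) for n in nested_layout.names]
    )
    nested = fit_model(
        data, nested_variant, model=full.model, seed=seed,
        n_restarts=n_restarts, start=proj, compute_se=compute_se,
    )
    return full, nested


def lrt(full: FitResult, nested: FitResult) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested against a full model fit.

    Returns (delta_minus2ll, delta_df, p).  Small negative deltas from
    optimiser tolerance are clamped to zero.
    """
    delta = nested.minus2ll - full.minus2ll
    ddf = full.n_params - nested.n_params
    if ddf < 0:
        raise ValueError("nested model has more parameters than full model")
    if delta < -1e-4 * max(1.0, abs(full.minus2ll)):
        raise EstimationError(
            f"nested fit beat the full fit (delta={delta:.4g}); refit the "
            "nested model from the full solution (see fit_nested_pair)"
        )
    delta = max(delta, 0.0)
    p = 1.0 if ddf == 0 else float(stats.chi2.sf(delta, ddf))
    return float(delta), int(ddf), p


def wald_ci(estimate: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Wald interval: estimate +/- z_{alpha/2} * SE."""
    if se < 0:
        raise ValueError("se must be non-negative")
    if not 0.0 <= level < 1.0:
        raise ValueError("level must be in [0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (estimate - z * se, estimate + z * se)
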