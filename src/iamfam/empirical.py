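"""Descriptive per-zygosity correlation matrices, independent of any
structural model.

Dependencies between overlapping dyads (one individual appears in several
pairs) are handled as in the source design: a semi-constrained covariance
matrix is estimated for the whole family vector by full-information maximum
likelihood, with equivalent relations (e.g. twin1-partner2 and
twin2-partner1) constrained equal and means/variances equal within a
generation, then standardised to correlations.  Confidence intervals use
Fisher's r-to-z transformation with the number of complete dyads as the
effective n (an approximation under FIML; validated by coverage
simulation in the test suite).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .covariance import _ACE_CLASSES, _COTS_CLASSES, ROLES_ACE, ROLES_COTS
from .estimation import EstimationError, FamilyData, _neg2ll
from .params import Zygosity

__all__ = [
    "constrained_covariance_fit",
    "correlation_table",
    "corr_with_fisher_ci",
    "DYAD_CLASSES",
]

# dyad classes of the semi-constrained matrix, in display order
DYAD_CLASSES = [
    "twin",
    "partner",
    "in_law",
    "co_in_law",
    "parent_offspring",
    "avuncular",
    "avuncular_in_law",
    "sibling",
    "cousin",
]


def _class_map(n_roles: int) -> dict:
    return _COTS_CLASSES if n_roles == 8 else _ACE_CLASSES


def _build_sigma(theta: np.ndarray, n_roles: int) -> tuple[np.ndarray, np.ndarray]:
    classes = _class_map(n_roles)
    if n_roles == 4:
        mean_p, var_p = theta[0], theta[1]
        covs = dict(zip(["twin", "partner", "in_law", "co_in_law"], theta[2:]))
        means = np.full(4, mean_p)
        variances = {"var": var_p}
    else:
        mean_p, mean_o, var_p, var_o = theta[:4]
        covs = dict(zip(DYAD_CLASSES, theta[4:]))
        means = np.concatenate([np.full(4, mean_p), np.full(4, mean_o)])
        variances = {"var": var_p, "var_child": var_o}
    sigma = np.zeros((n_roles, n_roles))
    for name, cells in classes.items():
        val = variances[name] if name in variances else covs[name]
        for i, j in cells:
            sigma[i, j] = sigma[j, i] = val
    return sigma, means


def _start_from_moments(data: FamilyData, zyg: Zygosity, n_roles: int) -> np.ndarray:
    # pairwise-complete moments as starting values
    classes = _class_map(n_roles)
    sums = np.zeros(n_roles)
    counts = np.zeros(n_roles)
    cross: dict = {}
    for g_zyg, idx, n, xbar, s in data.groups:
        if g_zyg is not zyg:
            continue
        sums[idx] += n * xbar
        counts[idx] += n
        for a, i in enumerate(idx):
            for b, j in enumerate(idx):
                key = (i, j)
                c_n, c_s = cross.get(key, (0.0, 0.0))
                cross[key] = (c_n + n, c_s + n * s[a, b])
    means = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)

    def pooled(cells):
        tot_n = tot_s = 0.0
        for i, j in cells:
            if (i, j) in cross:
                c_n, c_s = cross[(i, j)]
                tot_n += c_n
                tot_s += c_s
        return tot_s / tot_n if tot_n else 0.1

    if n_roles == 4:
        theta = [means[:4].mean(), pooled(classes["var"])]
        theta += [pooled(classes[c]) for c in ["twin", "partner", "in_law", "co_in_law"]]
    else:
        theta = [
            means[:4].mean(),
            means[4:].mean(),
            pooled(classes["var"]),
            pooled(classes["var_child"]),
        ]
        theta += [pooled(classes[c]) for c in DYAD_CLASSES]
    return np.array(theta)


def constrained_covariance_fit(
    data: FamilyData | pd.DataFrame, zyg: Zygosity
) -> tuple[np.ndarray, np.ndarray, float]:
    """ML estimate of the semi-constrained covariance for one zygosity group.

    Returns (sigma, means, minus2ll).  Equality constraints: equivalent
    dyads share one covariance; means and variances are equal within each
    generation.  Families with partially observed members contribute
    through their observed subset.
    """
    if isinstance(data, pd.DataFrame):
        data = FamilyData.from_table(data)
    groups = [g for g in data.groups if g[0] is zyg]
    if not groups:
        raise EstimationError(f"no data for zygosity {zyg.value}")
    observed_roles = sorted({int(i) for g in groups for i in g[1]})
    if len(observed_roles) < 2:
        raise EstimationError("need at least two observed roles")
    sub = FamilyData.__new__(FamilyData)
    sub.roles = data.roles
    sub.n_roles = data.n_roles
    sub.groups = groups
    sub.n_families = sum(g[2] for g in groups)
    sub.pattern_counts = {}
    sub.zygosities = [zyg]

    n_roles = data.n_roles

    def fun(theta):
        sigma, means = _build_sigma(theta, n_roles)
        return _neg2ll(sub, {zyg: sigma}, means)

    theta0 = _start_from_moments(data, zyg, n_roles)
    res = optimize.minimize(fun, theta0, method="BFGS",
                            options={"gtol": 1e-8, "maxiter": 2000})
    best = res
    if not res.success or res.fun >= 1e11:
        res2 = optimize.minimize(
            fun, theta0, method="Nelder-Mead",
            options={"maxiter": 20000, "xatol": 1e-8, "fatol": 1e-10},
        )
        if res2.fun < best.fun:
            best = res2
    sigma, means = _build_sigma(best.x, n_roles)
    return sigma, means, float(best.fun)


def corr_with_fisher_ci(
    r: float, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Fisher r-to-z confidence interval for a correlation from n pairs."""
    if abs(r) > 1.0:
        raise ValueError("correlation outside [-1, 1]")
    if abs(r) == 1.0:
        return (r, r)  # degenerate interval
    if n <= 3:
        raise ValueError("Fisher interval needs n > 3")
    z = np.arctanh(r)
    half = stats.norm.ppf(0.5 + level / 2.0) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def _complete_dyads(data: FamilyData, zyg: Zygosity, cells) -> int:
    total = 0
    for g_zyg, idx, n, _, _ in data.groups:
        if g_zyg is not zyg:
            continue
        present = set(int(i) for i in idx)
        for i, j in cells:
            if i in present and j in present:
                total += n
    return total


def correlation_table(
    data: FamilyData | pd.DataFrame, level: float = 0.95
) -> pd.DataFrame:
    """Constrained correlation estimates for every dyad class and zygosity.

    Returns a DataFrame with columns zygosity, dyad, r, ci_low, ci_high, n
    (n = number of complete dyads pooled over equivalent cells).
    """
    if isinstance(data, pd.DataFrame):
        data = FamilyData.from_table(data)
    classes = _class_map(data.n_roles)
    rows = []
    for zyg in data.zygosities:
        sigma, _, _ = constrained_covariance_fit(data, zyg)
        sd = np.sqrt(np.diag(sigma))
        corr = sigma / np.outer(sd, sd)
        for name, cells in classes.items():
            if name in ("var", "var_child"):
                continue
            i, j = cells[0]
            r = float(corr[i, j])
            n = _complete_dyads(data, zyg, cells)
            if n > 3 and abs(r) < 1:
                lo, hi = corr_with_fisher_ci(r, n, level)
            else:
                lo = hi = float("nan")
            rows.append(
                {"zygosity": zyg.value, "dyad": name, "r": r,
                 "ci_low": lo, "ci_high": hi, "n": n}
            )
    return pd.DataFrame(rows)
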