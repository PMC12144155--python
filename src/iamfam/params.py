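"""Parameterisations of the iAM-ACE and iAM-COTS models.

The focal phenotype P of an adult is decomposed into additive-genetic (A),
sibling-shared environmental (C), twin-shared environmental (T) and
non-shared environmental (E) factors with paths ``a, c, t, e``.  Partners do
not assort on P itself but on a latent *sorting factor* S, influenced by the
same four factors with (possibly different) paths ``a_s, c_s, t_s, e_s``.
Assortment strength is the copath coefficient ``mu``; a copath induces
covariance between the connected variables without altering any variance.
For identification ``a_s`` is fixed equal to ``a`` (the sorting factor is
then rescaled to unit variance for reporting).

All latent factors have unit variance in the adult (parent) generation; the
consequences of assortment at intergenerational equilibrium are carried by
the sibling genetic correlation ``f`` and the segregation-variance factor
``k = 1 - f_FS``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

__all__ = [
    "Zygosity",
    "IamAceParams",
    "IamCotsParams",
    "Variant",
    "VariantConstraints",
    "InvalidParameterError",
]


class InvalidParameterError(ValueError):
    """Raised when parameters leave the admissible region of the model."""


class Zygosity(str, enum.Enum):
    """Relation of the adult sibling pair: MZ / DZ twins or full siblings."""

    MZ = "MZ"
    DZ = "DZ"
    FS = "FS"

    @property
    def r_t(self) -> float:
        """Correlation of twin-shared environment (1 for twins, 0 for FS)."""
        return 0.0 if self is Zygosity.FS else 1.0

    @property
    def q(self) -> float:
        """Cousin correlation of the offspring-unique genetic factor A2."""
        return 0.25 if self is Zygosity.MZ else 0.125

    def f(self, f_fs: float) -> float:
        """Additive-genetic correlation of the sibling pair.

        MZ twins share their genome (f=1); DZ twins and full siblings share
        the equilibrium sibling genetic correlation ``f_fs``.
        """
        return 1.0 if self is Zygosity.MZ else f_fs


def equilibrium_sibling_genetic_corr(
    mu: float, a_s: float, c_s: float = 0.0, omega: float = 0.0
) -> float:
    """Sibling genetic correlation f_FS at intergenerational equilibrium.

    Under assortment the partners' additive-genetic values correlate
    ``mu * Cov(A, S)**2`` with ``Cov(A, S) = a_s + omega * c_s`` (the
    gene-environment covariance ``omega`` opens a second path from A to S).
    Siblings share the mid-parent genetic value, so

        f_FS = (1 + mu * (a_s + omega * c_s)**2) / 2

    which reduces to the random-mating value 1/2 when ``mu = 0`` and to the
    familiar ``(1 + mu * a_s**2) / 2`` when ``omega = 0``.
    """
    cov_as = a_s + omega * c_s
    r_g = mu * cov_as * cov_as
    if abs(r_g) >= 1.0:
        raise InvalidParameterError(
            f"implied partner genotypic correlation {r_g:.3f} outside (-1, 1)"
        )
    return (1.0 + r_g) / 2.0


@dataclass(frozen=True)
class IamAceParams:
    """Paths of the single-generation iAM-ACE model.

    ``a, c, t, e`` act on the focal phenotype; ``c_s, t_s, e_s`` act on the
    sorting factor (the genetic path on S is fixed at ``a_s = a``); ``mu`` is
    the copath.  ``omega`` is the A-C covariance (zero in the pure iAM-ACE
    model; used by the iAM-COTS parent generation).  ``strat_var`` is the
    variance of a latent stratification factor loading equally on every
    family member (social-stratification variant only).
    """

    a: float
    c: float
    t: float
    e: float
    c_s: float
    t_s: float
    e_s: float
    mu: float
    omega: float = 0.0
    strat_var: float = 0.0

    def __post_init__(self) -> None:
        for name in ("a", "c", "t", "e"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"path {name} must be non-negative")
        if self.strat_var < 0:
            raise InvalidParameterError("strat_var must be non-negative")
        if not all(
            math.isfinite(getattr(self, n))
            for n in ("a", "c", "t", "e", "c_s", "t_s", "e_s", "mu", "omega")
        ):
            raise InvalidParameterError("parameters must be finite")
        if abs(self.mu) * self.var_s > 0.9999:
            raise InvalidParameterError(
                "mu * Var(S) must lie in (-1, 1) for a proper matching process"
            )

    @property
    def a_s(self) -> float:
        """Genetic path on the sorting factor, fixed to ``a`` for identification."""
        return self.a

    @property
    def var_p(self) -> float:
        """Variance of the focal phenotype (excluding stratification)."""
        return (
            self.a**2 + self.c**2 + self.t**2 + self.e**2
            + 2.0 * self.a * self.c * self.omega
        )

    @property
    def var_s(self) -> float:
        """Variance of the sorting factor."""
        return (
            self.a_s**2 + self.c_s**2 + self.t_s**2 + self.e_s**2
            + 2.0 * self.a_s * self.c_s * self.omega
        )

    @property
    def cov_ps(self) -> float:
        """Covariance between an individual's phenotype and sorting factor."""
        return (
            self.a * self.a_s + self.c * self.c_s + self.t * self.t_s
            + self.e * self.e_s
            + self.omega * (self.a * self.c_s + self.a_s * self.c)
        )

    @property
    def f_fs(self) -> float:
        """Equilibrium sibling genetic correlation for DZ twins / full sibs."""
        return equilibrium_sibling_genetic_corr(self.mu, self.a_s, self.c_s, self.omega)

    @property
    def k(self) -> float:
        """Segregation (recombination) variance factor, ``1 - f_FS``."""
        return 1.0 - self.f_fs

    def partner_corr_s(self) -> float:
        """Model-implied partner correlation on the sorting factor, mu*Var(S)."""
        return self.mu * self.var_s

    def partner_corr_p(self) -> float:
        """Model-implied phenotypic partner correlation."""
        total = self.var_p + self.strat_var
        return (self.mu * self.cov_ps**2 + self.strat_var) / total


@dataclass(frozen=True)
class IamCotsParams:
    """Paths of the two-generation iAM-COTS model.

    The parent generation follows :class:`IamAceParams` (with a free A-C
    covariance ``omega``).  The offspring phenotype receives

    * ``a1`` times the transmitted genetic factor A1' (mid-parent value
      plus segregation noise of variance ``k``); fixing ``a1 = 0`` removes
      passive genetic transmission,
    * ``a2`` times the offspring-unique genetic factor A2 (sibling
      correlation 0.5, cousin correlation q),
    * ``p`` times each parent's phenotype (direct phenotypic transmission),
    * ``c1_prime`` times each parent's sibling-shared factor C1 (passive
      environmental transmission),
    * ``c2`` / ``e2`` times offspring-unique shared / non-shared factors.

    ``parent.omega`` is not free: it must satisfy the fixed-point constraint
    that it equals the offspring gene-environment correlation (see
    :func:`iamfam.covariance.omega_fixed_point`).
    """

    parent: IamAceParams
    p: float
    c1_prime: float
    a1: float
    a2: float
    c2: float
    e2: float

    def __post_init__(self) -> None:
        for name in ("a1", "a2", "c2", "e2"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"path {name} must be non-negative")

    @property
    def omega(self) -> float:
        return self.parent.omega

    def with_omega(self, omega: float) -> "IamCotsParams":
        return replace(self, parent=replace(self.parent, omega=omega))


class Variant(str, enum.Enum):
    """Nested model variants testing different partner-similarity mechanisms."""

    FULL_INDIRECT = "full_indirect"
    DIRECT = "direct"
    DIRECT_WITH_ERROR = "direct_with_error"
    STRATIFICATION = "stratification"
    NO_DIRECT_TRANSMISSION = "no_direct_transmission"
    NO_PASSIVE_GENETIC = "no_passive_genetic"
    NO_PASSIVE_ENV = "no_passive_env"


@dataclass(frozen=True)
class VariantConstraints:
    """A model variant plus any auxiliary fixed values it needs."""

    variant: Variant = Variant.FULL_INDIRECT
    stratification_var: float = 0.0

    def apply_ace(self, params: IamAceParams) -> IamAceParams:
        """Return params with the variant's equality constraints imposed."""
        v = self.variant
        if v is Variant.DIRECT:
            return replace(params, c_s=params.c, t_s=params.t, e_s=params.e)
        if v is Variant.DIRECT_WITH_ERROR:
            return replace(params, c_s=params.c, t_s=params.t)
        if v is Variant.STRATIFICATION and self.stratification_var:
            return replace(params, strat_var=self.stratification_var)
        return params

    def apply_cots(self, params: IamCotsParams) -> IamCotsParams:
        v = self.variant
        if v in (Variant.DIRECT, Variant.DIRECT_WITH_ERROR):
            return replace(params, parent=self.apply_ace(params.parent))
        if v is Variant.NO_DIRECT_TRANSMISSION:
            return replace(params, p=0.0)
        if v is Variant.NO_PASSIVE_GENETIC:
            return replace(params, a1=0.0)
        if v is Variant.NO_PASSIVE_ENV:
            return replace(params, c1_prime=0.0)
        return params
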