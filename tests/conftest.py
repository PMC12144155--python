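import numpy as np
import pytest

from iamfam import (
    IamAceParams,
    IamCotsParams,
    Zygosity,
    published_ea_ace,
    published_ea_cots,
    resolve_omega,
)


@pytest.fixture(scope="session")
def ace_params() -> IamAceParams:
    return published_ea_ace()


@pytest.fixture(scope="session")
def cots_params() -> IamCotsParams:
    return published_ea_cots()


def random_ace(rng: np.random.Generator, omega: float = 0.0) -> IamAceParams:
    """Draw a valid random parameter set (used by property/oracle tests)."""
    while True:
        a, c, t, e = rng.uniform(0.15, 0.75, 4)
        c_s, t_s, e_s = rng.uniform(-0.7, 0.9, 3)
        mu = rng.uniform(0.1, 0.55)
        try:
            params = IamAceParams(
                a=a, c=c, t=t, e=e, c_s=c_s, t_s=t_s, e_s=e_s, mu=mu,
                omega=omega,
            )
        except Exception:
            continue
        if abs(params.partner_corr_s()) < 0.85 and params.f_fs > abs(omega) ** 2:
            return params


def random_cots(rng: np.random.Generator) -> IamCotsParams:
    while True:
        ace = random_ace(rng)
        cots = IamCotsParams(
            parent=ace,
            p=rng.uniform(0.0, 0.15),
            c1_prime=rng.uniform(0.0, 0.25),
            a1=rng.uniform(0.2, 0.6),
            a2=rng.uniform(0.2, 0.6),
            c2=rng.uniform(0.05, 0.3),
            e2=rng.uniform(0.4, 0.8),
        )
        try:
            return resolve_omega(cots)
        except Exception:
            continue


def class_means(matrix: np.ndarray, classes: dict) -> dict:
    """Average the empirical matrix over each equivalence class."""
    return {
        name: float(np.mean([matrix[i, j] for i, j in cells]))
        for name, cells in classes.items()
    }


def cov_se(emp: np.ndarray, n: int) -> np.ndarray:
    """Large-sample SE of each entry of an empirical covariance matrix."""
    d = np.diag(emp)
    return np.sqrt((np.outer(d, d) + emp**2) / n)


@pytest.fixture(scope="session")
def small_ace_dataset(ace_params):
    """Balanced three-group sample used by several estimation tests."""
    from iamfam.simulate import simulate_extended_families

    rng = np.random.default_rng(2024)
    wide = {
        zyg: simulate_extended_families(ace_params, zyg, 6000, rng)[0]
        for zyg in Zygosity
    }
    return wide
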