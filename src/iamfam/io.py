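"""Reading, validating and transforming long-format family phenotype tables.

The canonical format is one row per individual:

    family_id, zygosity, role, sex, generation, phenotype

with ``zygosity`` in {MZ, DZ, FS}, ``role`` one of the eight extended-family
role labels, and ``phenotype`` numeric (empty = missing).  Missingness is
per individual, which is what full-information likelihood needs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .covariance import ROLES_ACE, ROLES_COTS
from .params import Zygosity

__all__ = [
    "FamilyTableError",
    "read_family_table",
    "write_family_table",
    "validate_family_table",
    "zstandardize",
    "to_wide",
]

_COLUMNS = ["family_id", "zygosity", "role", "sex", "generation", "phenotype"]
_ZYG_VALUES = {z.value for z in Zygosity}


class FamilyTableError(ValueError):
    """Schema violation in a family table; message names offending rows."""


def validate_family_table(df: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [c for c in _COLUMNS if c not in df.columns]
    if missing_cols:
        raise FamilyTableError(f"missing columns: {missing_cols}")
    bad = ~df["zygosity"].isin(_ZYG_VALUES)
    if bad.any():
        rows = df.index[bad].tolist()[:5]
        raise FamilyTableError(f"unknown zygosity at rows {rows}")
    bad = ~df["role"].isin(ROLES_COTS)
    if bad.any():
        rows = df.index[bad].tolist()[:5]
        raise FamilyTableError(f"unknown role at rows {rows}")
    dup = df.duplicated(subset=["family_id", "role"], keep=False)
    if dup.any():
        rows = df.index[dup].tolist()[:5]
        raise FamilyTableError(f"duplicate (family_id, role) at rows {rows}")
    n_zyg = df.groupby("family_id")["zygosity"].nunique()
    mixed = n_zyg[n_zyg > 1]
    if len(mixed):
        raise FamilyTableError(
            f"zygosity not constant within families {mixed.index.tolist()[:5]}"
        )
    pheno = df["phenotype"]
    bad = pheno.notna() & ~np.isfinite(pheno.astype(float))
    if bad.any():
        rows = df.index[bad].tolist()[:5]
        raise FamilyTableError(f"non-finite phenotype at rows {rows}")
    return df


def read_family_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a family table CSV."""
    df = pd.read_csv(path, dtype={"zygosity": str, "role": str, "sex": str,
                                  "generation": str})
    df["phenotype"] = pd.to_numeric(df["phenotype"], errors="coerce")
    return validate_family_table(df)


def write_family_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def zstandardize(
    df: pd.DataFrame, by: tuple = ("sex", "generation")
) -> pd.DataFrame:
    """Z-standardise the phenotype within strata (default sex x generation).

    Missing values are left untouched; a stratum with fewer than two
    non-missing values or zero spread is an error.
    """
    out = df.copy()
    for key, idx in out.groupby(list(by)).groups.items():
        vals = out.loc[idx, "phenotype"]
        obs = vals.dropna()
        if len(obs) < 2:
            raise FamilyTableError(f"stratum {key} has fewer than 2 observed values")
        sd = obs.std(ddof=0)
        if sd == 0 or not np.isfinite(sd):
            raise FamilyTableError(f"stratum {key} has zero phenotype variance")
        out.loc[idx, "phenotype"] = (vals - obs.mean()) / sd
    return out


def to_wide(df: pd.DataFrame, roles: tuple | None = None) -> dict:
    """Pivot a long table to per-zygosity wide matrices (NaN = missing).

    Returns ``{Zygosity: (n_families, n_roles) ndarray}``.  If ``roles`` is
    None the 8-role layout is used when any offspring role is present,
    otherwise the 4-role adult layout.
    """
    if roles is None:
        has_kids = df["role"].isin(ROLES_COTS[4:]).any()
        roles = ROLES_COTS if has_kids else ROLES_ACE
    wide = df.pivot(index="family_id", columns="role", values="phenotype")
    for r in roles:
        if r not in wide.columns:
            wide[r] = np.nan
    zyg_of = df.groupby("family_id")["zygosity"].first()
    out = {}
    for zyg in Zygosity:
        fams = zyg_of.index[zyg_of == zyg.value]
        if len(fams) == 0:
            continue
        out[zyg] = wide.loc[fams, list(roles)].to_numpy(dtype=float)
    return out
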