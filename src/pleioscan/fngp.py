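"""Femoral-neck geometric parameters (FNGPs) and appendicular lean mass.

DXA reports areal bone mineral density (BMD, g/cm^2) and projected bone
area (cm^2) over the femoral-neck scan region.  From those two numbers a
circular-annulus model of the neck cross-section yields five geometry
indices widely used in hip-fracture research:

* ``W``   periosteal (outer) diameter, cm: scan area / scan width H
* ``CSA`` mineralised cross-sectional area, cm^2: BMD * W / rho_m, where
  rho_m is the effective mineral density of fully mineralised bone
* ``CT``  cortical thickness, cm: outer minus inner radius of the annulus
  that holds a fraction ``f_cort`` of CSA in its cortical shell
* ``BR``  buckling ratio (dimensionless): outer radius / CT; larger means
  a thinner shell relative to its span, i.e. more prone to local buckling
* ``Z``   section modulus, cm^3: bending strength index, the annulus
  cross-sectional moment of inertia divided by the outer radius

Appendicular lean mass (ALM, kg) is the sum of arm and leg lean soft
tissue.  Records whose annulus is geometrically impossible (cortical area
exceeding the full disc) are flagged invalid rather than silently NaN'd,
and are meant to be excluded from downstream association with a logged
count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

TRAIT_COLUMNS = ["W", "CSA", "CT", "Z", "BR", "ALM"]


@dataclass(frozen=True)
class FNGPParams:
    """Annulus-model parameters.

    ``scan_width_h`` is the length of the DXA scan region along the neck
    axis (cm); ``rho_m`` the effective mineral density of compact bone
    (g/cm^3); ``f_cort`` the fraction of the mineralised area located in
    the cortical shell.  The defaults reproduce adult reference means for
    cortical thickness and buckling ratio to within a few percent.
    """

    scan_width_h: float = 1.5
    rho_m: float = 1.053
    f_cort: float = 0.6

    def __post_init__(self) -> None:
        if self.scan_width_h <= 0 or self.rho_m <= 0:
            raise ValueError("scan_width_h and rho_m must be positive")
        if not 0.0 < self.f_cort <= 1.0:
            raise ValueError("f_cort must be in (0, 1]")


@dataclass(frozen=True)
class FNGPSet:
    """Derived geometry for one record; ``valid`` is False when the annulus
    model has no solution (with ``reason`` saying why)."""

    W: float
    CSA: float
    CT: float
    Z: float
    BR: float
    ALM: float
    valid: bool = True
    reason: str = ""


def annulus_geometry(W: float, CSA: float, f_cort: float) -> tuple[float, float, float]:
    """Solve the annulus for (CT, BR, Z) given outer diameter and CSA.

    Raises ``ValueError`` when the required cortical area does not fit in
    the outer disc or the shell has zero thickness.
    """
    r_o = W / 2.0
    inner_sq = r_o * r_o - f_cort * CSA / math.pi
    if inner_sq < 0:
        raise ValueError("annulus impossible: cortical area exceeds outer disc")
    r_i = math.sqrt(inner_sq)
    ct = r_o - r_i
    if ct <= 0:
        raise ValueError("degenerate annulus: zero cortical thickness")
    br = r_o / ct
    csmi = math.pi / 4.0 * (r_o**4 - r_i**4)
    z = csmi / r_o
    return ct, br, z


def compute_alm(arm_lean: float, leg_lean: float) -> float:
    """Appendicular lean mass: arm + leg lean soft-tissue mass (kg)."""
    if arm_lean < 0 or leg_lean < 0:
        raise ValueError("lean masses must be nonnegative")
    return arm_lean + leg_lean


def compute_fngp(
    fn_bmd: float,
    fn_area: float,
    arm_lean: float,
    leg_lean: float,
    params: FNGPParams | None = None,
) -> FNGPSet:
    """Derive the five geometry indices plus ALM for one DXA record."""
    params = params or FNGPParams()
    if fn_bmd <= 0 or fn_area <= 0:
        raise ValueError("fn_bmd and fn_area must be positive")
    alm = compute_alm(arm_lean, leg_lean)
    w = fn_area / params.scan_width_h
    csa = fn_bmd * w / params.rho_m
    try:
        ct, br, z = annulus_geometry(w, csa, params.f_cort)
    except ValueError as err:
        return FNGPSet(w, csa, float("nan"), float("nan"), float("nan"), alm,
                       valid=False, reason=str(err))
    return FNGPSet(w, csa, ct, z, br, alm)


def compute_fngp_table(
    dxa: pd.DataFrame, params: FNGPParams | None = None
) -> pd.DataFrame:
    """Vectorised :func:`compute_fngp` over a raw DXA table.

    ``dxa`` needs columns ``sample_id, age, sex, fn_bmd, fn_area,
    arm_lean, leg_lean``.  Returns those identifiers plus
    ``W, CSA, CT, Z, BR, ALM`` and a boolean ``valid`` column; invalid
    annulus records keep NaN geometry and ``valid=False``.
    """
    params = params or FNGPParams()
    required = ["sample_id", "age", "sex", "fn_bmd", "fn_area", "arm_lean", "leg_lean"]
    missing = [c for c in required if c not in dxa.columns]
    if missing:
        raise ValueError(f"DXA table lacks columns: {missing}")
    if (dxa["fn_bmd"] <= 0).any() or (dxa["fn_area"] <= 0).any():
        raise ValueError("fn_bmd and fn_area must be positive")
    if (dxa["arm_lean"] < 0).any() or (dxa["leg_lean"] < 0).any():
        raise ValueError("lean masses must be nonnegative")

    w = dxa["fn_area"].to_numpy() / params.scan_width_h
    csa = dxa["fn_bmd"].to_numpy() * w / params.rho_m
    r_o = w / 2.0
    inner_sq = r_o**2 - params.f_cort * csa / math.pi
    valid = inner_sq > 0
    r_i = np.sqrt(np.where(valid, inner_sq, np.nan))
    ct = r_o - r_i
    valid &= ct > 0
    ct = np.where(valid, ct, np.nan)
    br = r_o / ct
    z = math.pi / 4.0 * (r_o**4 - r_i**4) / r_o

    out = dxa[["sample_id", "age", "sex"]].copy()
    out["W"] = w
    out["CSA"] = csa
    out["CT"] = ct
    out["Z"] = np.where(valid, z, np.nan)
    out["BR"] = np.where(valid, br, np.nan)
    out["ALM"] = dxa["arm_lean"].to_numpy() + dxa["leg_lean"].to_numpy()
    out["valid"] = valid
    return out


def describe_traits(
    table: pd.DataFrame, trait_cols: list[str] | None = None
) -> pd.DataFrame:
    """Per-sex mean +/- SD summary of trait columns (sample SD, n-1).

    Mirrors the usual cohort-characteristics table: rows are traits,
    columns a MultiIndex (sex label, statistic).  A sex stratum with a
    single sample reports its SD as missing.
    """
    if table.empty:
        raise ValueError("trait table is empty")
    trait_cols = trait_cols or [c for c in TRAIT_COLUMNS if c in table.columns]
    if not trait_cols:
        raise ValueError("no trait columns found to summarise")
    label = table["sex"].map({0.0: "female", 1.0: "male", 0: "female", 1: "male"})
    grouped = table.assign(_sex=label).groupby("_sex")[trait_cols]
    mean = grouped.mean().T
    sd = grouped.std(ddof=1).T  # NaN for single-sample strata
    out = pd.concat({"mean": mean, "sd": sd}, axis=1)
    return out.swaplevel(axis=1).sort_index(axis=1)
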