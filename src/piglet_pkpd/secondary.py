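"""Secondary PK parameters derived from primary compartmental estimates.

All quantities follow the standard compartmental identities: Tmax/Cmax from
the closed-form concentration curve, half-lives as ln(2)/k, clearance as
Cl/F = Ke * Vd/F, AUC as dose / (Cl/F), and the tissue penetration factor as
the ISF-to-plasma AUC ratio.  The plasma-scale IC50 of the ISF-driven model
is the ISF IC50 divided by the penetration fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar

from .models import DegenerateParametersError, IsfLink, OneCptPK, TwoCptPK

__all__ = [
    "SecondaryPK",
    "tmax_cmax",
    "tmax_cmax_two_cpt",
    "half_life",
    "mrt",
    "auc_clearance",
    "isf_auc",
    "penetration_and_plasma_ic50",
    "secondary_table",
]

MG_PER_KG_TO_UG_PER_KG = 1000.0


@dataclass(frozen=True)
class SecondaryPK:
    """Derived exposure metrics for one PK model (units as published)."""

    tmax: float  # h
    cmax: float  # ug/ml
    ka_half_life: float  # h
    ke_half_life: float  # h
    mrt: float  # h
    auc: float  # h.ug/ml
    clearance: float  # Cl/F, ml/h/kg
    penetration_percent: Optional[float] = None
    plasma_ic50: Optional[float] = None


def half_life(k: float) -> float:
    """t1/2 = ln(2) / k for a first-order rate constant (1/h)."""
    if k <= 0:
        raise ValueError("rate constant must be > 0")
    return float(np.log(2.0) / k)


def mrt(pk: OneCptPK | TwoCptPK, *, include_absorption: bool = False) -> float:
    """Mean residence time.

    The disposition convention 1/Ke is the default (it reproduces the
    published tables); ``include_absorption`` adds the textbook 1/Ka mean
    absorption time.
    """
    out = 1.0 / pk.ke
    if include_absorption:
        out += 1.0 / pk.ka
    return float(out)


def auc_clearance(pk: OneCptPK | TwoCptPK) -> tuple[float, float]:
    """(AUC to infinity in h.ug/ml, apparent clearance Cl/F in ml/h/kg).

    Cl/F = Ke * Vd/F and AUC = dose / (Cl/F); the identity AUC * Cl/F = dose
    holds exactly.  Over a 0-48 h window with half-lives of a few hours the
    truncation difference is far below reporting precision.
    """
    clearance = pk.ke * pk.v
    auc = pk.dose * MG_PER_KG_TO_UG_PER_KG / clearance
    return float(auc), float(clearance)


def tmax_cmax(pk: OneCptPK) -> tuple[float, float]:
    """Closed-form peak of the one-compartment curve.

    Tmax = ln(Ka/Ke) / (Ka - Ke); Cmax is the curve value there.
    """
    if abs(pk.ka - pk.ke) <= 1e-12 * max(pk.ka, pk.ke):  # pragma: no cover
        raise DegenerateParametersError("ka = ke has no closed-form Tmax")
    tmax = float(np.log(pk.ka / pk.ke) / (pk.ka - pk.ke))
    cmax = float(pk.conc(tmax))
    return tmax, cmax


def tmax_cmax_two_cpt(pk: TwoCptPK, *, horizon: float = 48.0) -> tuple[float, float]:
    """Peak of the tri-exponential curve by bounded numeric maximization."""
    curve = pk.expsum()
    res = minimize_scalar(
        lambda t: -curve(t), bounds=(0.0, horizon), method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x), float(-res.fun)


def isf_auc(pk: OneCptPK, link: IsfLink) -> float:
    """AUC to infinity of the ISF concentration curve (h.ug/ml)."""
    return link.drive(pk.expsum()).auc_inf()


def penetration_and_plasma_ic50(
    auc_isf: float, auc_plasma: float, isf_ic50: float
) -> tuple[float, float]:
    """Tissue penetration and the plasma-scale IC50.

    penetration% = 100 * AUC_ISF / AUC_plasma; the plasma IC50 is the ISF
    IC50 divided by the penetration fraction (round-trip identity:
    plasma_IC50 * penetration/100 = ISF IC50).
    """
    if auc_plasma <= 0 or auc_isf <= 0 or isf_ic50 <= 0:
        raise ValueError("AUCs and IC50 must be > 0")
    penetration = 100.0 * auc_isf / auc_plasma
    return float(penetration), float(isf_ic50 / (penetration / 100.0))


def secondary_table(
    pk: OneCptPK | TwoCptPK,
    *,
    link: Optional[IsfLink] = None,
    isf_ic50: Optional[float] = None,
) -> SecondaryPK:
    """Assemble the full secondary-parameter block for one PK model."""
    if isinstance(pk, OneCptPK):
        tmax, cmax = tmax_cmax(pk)
    else:
        tmax, cmax = tmax_cmax_two_cpt(pk)
    auc, clearance = auc_clearance(pk)
    penetration = plasma_ic50 = None
    if link is not None:
        auc_i = isf_auc(pk, link)
        penetration = 100.0 * auc_i / auc
        if isf_ic50 is not None:
            penetration, plasma_ic50 = penetration_and_plasma_ic50(auc_i, auc, isf_ic50)
    return SecondaryPK(
        tmax=tmax,
        cmax=cmax,
        ka_half_life=half_life(pk.ka),
        ke_half_life=half_life(pk.ke),
        mrt=mrt(pk),
        auc=auc,
        clearance=clearance,
        penetration_percent=penetration,
        plasma_ic50=plasma_ic50,
    )
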