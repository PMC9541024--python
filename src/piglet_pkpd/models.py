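"""Structural PK/PD models for NSAID biomarker suppression in piglets.

Three drug-biomarker systems are supported, each a first-order-absorption
compartmental PK model coupled one-way into an inhibitory indirect-response
(turnover) model:

``ketoprofen_pge2``
    One-compartment S-(+)-ketoprofen disposition; an interstitial-fluid (ISF)
    compartment filled at rate ``Ke0in`` and drained at ``Ke0out``; the ISF
    concentration drives a sigmoidal (Hill) inhibition of PGE2 production.

``ketoprofen_cortisol``
    Same plasma PK; a classical effect compartment equilibrating at ``Ke0``
    (unit partition coefficient) drives sigmoidal inhibition of cortisol
    production.

``flunixin_cortisol``
    Two-compartment flunixin disposition in micro-constant parameterisation;
    the plasma concentration itself drives an Imax (gamma = 1) inhibition of
    cortisol production.

The biomarker state ``E`` is expressed in percent-of-control units: production
at zero-order rate ``Kin`` (%/h) balanced by first-order loss ``Kout`` (1/h),
so the untreated steady state is ``Kin/Kout`` (near 100).

Units convention: doses are given in mg/kg and carried internally in ug/kg,
volumes in ml/kg, concentrations in ug/ml, times in hours.  This makes the
published typical-value tables directly pluggable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Union

import numpy as np

__all__ = [
    "DegenerateParametersError",
    "ExpSum",
    "OneCptPK",
    "TwoCptPK",
    "IsfLink",
    "EffectLink",
    "IndirectResponse",
    "StructuralModel",
    "MODEL_TOPOLOGY",
    "plasma_conc_one_cpt",
    "plasma_conc_two_cpt",
    "inhibition",
    "rhs",
]

#: relative tolerance under which two exponential rates are considered
#: coincident (degenerate closed form)
RATE_DEGENERACY_RTOL = 1e-9

MG_PER_KG_TO_UG_PER_KG = 1000.0


class DegenerateParametersError(ValueError):
    """Raised when rate constants coincide and a closed form degenerates."""


# ---------------------------------------------------------------------------
# Exponential-sum algebra
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpSum:
    """A function ``f(t) = sum_i coef_i * exp(-rate_i * t)``.

    Plasma and link-compartment concentration profiles after a single
    extravascular dose are all of this form, which keeps the PK layer in
    closed form (no ODE solves) and makes AUC computations exact.
    """

    coefs: tuple[float, ...]
    rates: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.coefs) != len(self.rates):
            raise ValueError("coefs and rates must have equal length")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for c, r in zip(self.coefs, self.rates):
            out = out + c * np.exp(-r * t)
        return out

    def auc_inf(self) -> float:
        """Exact integral over [0, inf); requires all rates > 0."""
        if any(r <= 0 for r in self.rates):
            raise ValueError("AUC to infinity requires strictly positive rates")
        return float(sum(c / r for c, r in zip(self.coefs, self.rates)))

    def auc(self, t0: float, t1: float) -> float:
        """Exact integral over [t0, t1]."""
        total = 0.0
        for c, r in zip(self.coefs, self.rates):
            total += c * (np.exp(-r * t0) - np.exp(-r * t1)) / r
        return float(total)

    def filtered(self, k_in: float, k_out: float) -> "ExpSum":
        """Response of ``dy/dt = k_in * f(t) - k_out * y`` with ``y(0) = 0``.

        The result is again an exponential sum.  When ``k_out`` collides with
        one of the driver rates the partial-fraction form degenerates; the
        collision is resolved by nudging ``k_out`` by one part in 1e9, which
        perturbs the curve by a comparable relative amount -- far below any
        tolerance used in this package.
        """
        ko = float(k_out)
        scale = max(abs(ko), max((abs(r) for r in self.rates), default=1.0), 1.0)
        for r in self.rates:
            if abs(ko - r) < 1e-9 * scale:
                ko = r + 1e-9 * scale
        coefs = []
        rates = []
        tail = 0.0
        for c, r in zip(self.coefs, self.rates):
            a = k_in * c / (ko - r)
            coefs.append(a)
            rates.append(r)
            tail -= a
        coefs.append(tail)
        rates.append(ko)
        return ExpSum(tuple(coefs), tuple(rates))


# ---------------------------------------------------------------------------
# PK blocks
# ---------------------------------------------------------------------------


def _require_positive(obj, names) -> None:
    for name in names:
        if not getattr(obj, name) > 0:
            raise ValueError(f"{type(obj).__name__}.{name} must be > 0")


@dataclass(frozen=True)
class OneCptPK:
    """First-order absorption into a single disposition compartment.

    Parameters
    ----------
    ka : absorption rate constant (1/h)
    ke : elimination rate constant (1/h)
    v : apparent volume of distribution per fraction absorbed, Vd/F (ml/kg)
    dose : intramuscular dose (mg/kg)
    """

    ka: float
    ke: float
    v: float
    dose: float

    def __post_init__(self) -> None:
        _require_positive(self, ("ka", "ke", "v"))
        if self.dose < 0:
            raise ValueError("dose must be >= 0")
        if abs(self.ka - self.ke) <= RATE_DEGENERACY_RTOL * max(self.ka, self.ke):
            raise DegenerateParametersError(
                f"ka ({self.ka}) and ke ({self.ke}) coincide; the Bateman "
                "closed form is degenerate"
            )

    def expsum(self) -> ExpSum:
        dose_ug = self.dose * MG_PER_KG_TO_UG_PER_KG
        a = dose_ug * self.ka / (self.v * (self.ka - self.ke))
        return ExpSum((a, -a), (self.ke, self.ka))

    def conc(self, t):
        """Plasma concentration (ug/ml) at time ``t`` (h)."""
        return self.expsum()(t)


@dataclass(frozen=True)
class TwoCptPK:
    """First-order absorption, two-compartment micro-constant disposition.

    ``k12``/``k21`` are the central-peripheral distribution rate constants;
    the derived macro rates ``alpha > beta`` satisfy ``alpha*beta = ke*k21``
    and ``alpha + beta = ke + k12 + k21`` and are always real and distinct
    for positive micro-constants.
    """

    ka: float
    ke: float
    k12: float
    k21: float
    v: float
    dose: float

    def __post_init__(self) -> None:
        _require_positive(self, ("ka", "ke", "k12", "k21", "v"))
        if self.dose < 0:
            raise ValueError("dose must be >= 0")
        alpha, beta = self.macro_rates()
        scale = max(alpha, self.ka)
        if min(abs(self.ka - alpha), abs(self.ka - beta)) <= RATE_DEGENERACY_RTOL * scale:
            raise DegenerateParametersError(
                "absorption rate coincides with a disposition macro-rate"
            )

    def macro_rates(self) -> tuple[float, float]:
        s = self.ke + self.k12 + self.k21
        p = self.ke * self.k21
        disc = s * s - 4.0 * p
        root = np.sqrt(max(disc, 0.0))
        alpha = 0.5 * (s + root)
        beta = p / alpha  # numerically stable for the smaller root
        return float(alpha), float(beta)

    def expsum(self) -> ExpSum:
        alpha, beta = self.macro_rates()
        ka, k21 = self.ka, self.k21
        dose_ug = self.dose * MG_PER_KG_TO_UG_PER_KG
        front = ka * dose_ug / self.v
        ca = front * (k21 - alpha) / ((ka - alpha) * (beta - alpha))
        cb = front * (k21 - beta) / ((ka - beta) * (alpha - beta))
        cka = front * (k21 - ka) / ((alpha - ka) * (beta - ka))
        return ExpSum((ca, cb, cka), (alpha, beta, ka))

    def conc(self, t):
        return self.expsum()(t)


def plasma_conc_one_cpt(t, pk: OneCptPK):
    """Bateman closed form for the one-compartment model (ug/ml)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    return pk.conc(t)


def plasma_conc_two_cpt(t, pk: TwoCptPK):
    """Tri-exponential closed form for the two-compartment model (ug/ml)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    return pk.conc(t)


# ---------------------------------------------------------------------------
# Link compartments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IsfLink:
    """Interstitial-fluid compartment: dCe/dt = ke0in*C - ke0out*Ce."""

    ke0in: float
    ke0out: float

    def __post_init__(self) -> None:
        _require_positive(self, ("ke0in", "ke0out"))

    def drive(self, plasma: ExpSum) -> ExpSum:
        return plasma.filtered(self.ke0in, self.ke0out)


@dataclass(frozen=True)
class EffectLink:
    """First-order effect compartment: dCe/dt = ke0*(C - Ce).

    Unit partition: at steady state Ce equals the plasma concentration, so
    the IC50 driven by Ce is on the plasma concentration scale.
    """

    ke0: float

    def __post_init__(self) -> None:
        _require_positive(self, ("ke0",))

    def drive(self, plasma: ExpSum) -> ExpSum:
        return plasma.filtered(self.ke0, self.ke0)


# ---------------------------------------------------------------------------
# Indirect (turnover) response
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IndirectResponse:
    """Inhibitory indirect-response model of biomarker turnover.

    ``dE/dt = kin * (1 - I(Ce)) - kout * E`` with
    ``I(Ce) = imax * Ce**gamma / (Ce**gamma + ic50**gamma)``.

    ``imax`` is stored as a fraction in (0, 1] (published tables print it in
    percent); ``gamma`` is the Hill exponent and equals 1 for the plasma-driven
    flunixin model.
    """

    kin: float
    kout: float
    imax: float
    ic50: float
    gamma: float = 1.0

    def __post_init__(self) -> None:
        _require_positive(self, ("kin", "kout", "ic50", "gamma"))
        if not 0.0 < self.imax <= 1.0:
            raise ValueError("imax must be a fraction in (0, 1]")

    @property
    def baseline(self) -> float:
        """Untreated steady state E0 = kin/kout (percent-of-control units)."""
        return self.kin / self.kout

    def inhibition(self, ce):
        return inhibition(ce, self)


def inhibition(ce, idr: IndirectResponse):
    """Fraction of production suppressed at driver concentration ``ce``.

    Bounded by ``imax``, strictly increasing in ``ce``, half-maximal at
    ``ce = ic50`` for any Hill exponent.
    """
    ce = np.asarray(ce, dtype=float)
    if np.any(ce < 0):
        raise ValueError("driver concentration must be >= 0")
    # (ce/ic50)**gamma formulation avoids overflow for large ce and keeps
    # the ce = 0 branch exact for gamma < 1
    ratio = np.power(ce / idr.ic50, idr.gamma)
    with np.errstate(invalid="ignore"):
        frac = np.where(np.isinf(ratio), 1.0, ratio / (1.0 + ratio))
    return idr.imax * frac


# ---------------------------------------------------------------------------
# Structural model
# ---------------------------------------------------------------------------

#: topology registry: model name -> (PK class, link class or None, drive, gamma fixed to 1)
MODEL_TOPOLOGY = {
    "ketoprofen_pge2": (OneCptPK, IsfLink, "isf", False),
    "ketoprofen_cortisol": (OneCptPK, EffectLink, "effect", False),
    "flunixin_cortisol": (TwoCptPK, type(None), "plasma", True),
}

#: mapping from flat parameter names to (block, field) used by ``replace_params``
_PARAM_FIELDS = {
    "Ka": ("pk", "ka"),
    "Ke": ("pk", "ke"),
    "K12": ("pk", "k12"),
    "K21": ("pk", "k21"),
    "V": ("pk", "v"),
    "dose": ("pk", "dose"),
    "Ke0in": ("link", "ke0in"),
    "Ke0out": ("link", "ke0out"),
    "Ke0": ("link", "ke0"),
    "Kin": ("idr", "kin"),
    "Kout": ("idr", "kout"),
    "Imax": ("idr", "imax"),
    "IC50": ("idr", "ic50"),
    "gamma": ("idr", "gamma"),
}


@dataclass(frozen=True)
class StructuralModel:
    """One drug-biomarker system: PK block + optional link + turnover model.

    The state vector used by :func:`rhs` is ordered
    ``(depot, central, [peripheral], [link Ce], E)`` with the depot in ug/kg
    and the concentration states in ug/ml.
    """

    name: str
    pk: Union[OneCptPK, TwoCptPK]
    idr: IndirectResponse
    link: Optional[Union[IsfLink, EffectLink]] = None
    drive: str = ""

    def __post_init__(self) -> None:
        if self.name not in MODEL_TOPOLOGY:
            raise ValueError(
                f"unknown model {self.name!r}; expected one of {sorted(MODEL_TOPOLOGY)}"
            )
        pk_cls, link_cls, drive, gamma_fixed = MODEL_TOPOLOGY[self.name]
        if not isinstance(self.pk, pk_cls):
            raise TypeError(f"{self.name} requires a {pk_cls.__name__} PK block")
        if not isinstance(self.link, link_cls):
            raise TypeError(
                f"{self.name} requires link {link_cls.__name__}, got "
                f"{type(self.link).__name__}"
            )
        if self.drive == "":
            object.__setattr__(self, "drive", drive)
        elif self.drive != drive:
            raise ValueError(f"{self.name} must be driven by {drive!r}")
        if gamma_fixed and self.idr.gamma != 1.0:
            raise ValueError(f"{self.name} fixes the Hill exponent to 1")

    # -- parameter access ---------------------------------------------------

    def param_dict(self) -> dict[str, float]:
        """Flat name -> value mapping over all structural parameters."""
        out: dict[str, float] = {}
        for name, (block, attr) in _PARAM_FIELDS.items():
            obj = getattr(self, block)
            if obj is not None and hasattr(obj, attr):
                out[name] = getattr(obj, attr)
        return out

    def replace_params(self, **updates: float) -> "StructuralModel":
        """Return a copy with the given flat parameters replaced."""
        by_block: dict[str, dict[str, float]] = {}
        for name, value in updates.items():
            if name not in _PARAM_FIELDS:
                raise KeyError(f"unknown parameter {name!r}")
            block, attr = _PARAM_FIELDS[name]
            obj = getattr(self, block)
            if obj is None or not hasattr(obj, attr):
                raise KeyError(f"model {self.name!r} has no parameter {name!r}")
            by_block.setdefault(block, {})[attr] = float(value)
        new = {}
        for block, kw in by_block.items():
            new[block] = replace(getattr(self, block), **kw)
        return replace(self, **new)

    def with_dose(self, dose_mg_kg: float) -> "StructuralModel":
        return replace(self, pk=replace(self.pk, dose=float(dose_mg_kg)))

    # -- closed-form concentration curves -----------------------------------

    def plasma_expsum(self) -> ExpSum:
        return self.pk.expsum()

    def driver_expsum(self) -> ExpSum:
        """Closed form of the concentration that enters the inhibition term."""
        plasma = self.pk.expsum()
        if self.link is None:
            return plasma
        return self.link.drive(plasma)

    # -- ODE form (verification path) ---------------------------------------

    @property
    def n_states(self) -> int:
        n = 2  # depot + central
        if isinstance(self.pk, TwoCptPK):
            n += 1
        if self.link is not None:
            n += 1
        return n + 1  # E

    def initial_state(self) -> np.ndarray:
        """Dose in the depot at t = 0; biomarker at its untreated steady state."""
        y0 = np.zeros(self.n_states)
        y0[0] = self.pk.dose * MG_PER_KG_TO_UG_PER_KG
        y0[-1] = self.idr.baseline
        return y0

    def rhs(self, t: float, state: np.ndarray) -> np.ndarray:
        return rhs(self, state, t)


def rhs(model: StructuralModel, state: np.ndarray, t: float) -> np.ndarray:
    """Coupled right-hand side of the full ODE system.

    PK states never depend on the biomarker ``E`` (one-way coupling).  Used
    as the independent verification path for the closed-form fast path.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (model.n_states,):
        raise ValueError(
            f"state must have shape ({model.n_states},) for model "
            f"{model.name!r}, got {state.shape}"
        )
    pk = model.pk
    dy = np.empty_like(state)
    depot, central = state[0], state[1]
    dy[0] = -pk.ka * depot
    i = 2
    if isinstance(pk, TwoCptPK):
        periph = state[i]
        dy[1] = pk.ka * depot / pk.v - (pk.ke + pk.k12) * central + pk.k21 * periph
        dy[i] = pk.k12 * central - pk.k21 * periph
        i += 1
    else:
        dy[1] = pk.ka * depot / pk.v - pk.ke * central
    if model.link is not None:
        ce = state[i]
        if isinstance(model.link, IsfLink):
            dy[i] = model.link.ke0in * central - model.link.ke0out * ce
        else:
            dy[i] = model.link.ke0 * (central - ce)
        driver = ce
        i += 1
    else:
        driver = central
    e = state[i]
    dy[i] = model.idr.kin * (1.0 - inhibition(max(driver, 0.0), model.idr)) - model.idr.kout * e
    return dy
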