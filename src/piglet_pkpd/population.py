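"""Statistical layer: inter-individual variability and residual error.

Individual parameters follow the exponential (lognormal) model
``P_i = theta * exp(eta_i)`` with ``eta_i ~ Normal(0, omega^2)`` drawn
independently per parameter (diagonal omega matrix).  Residual error is
either multiplicative, ``obs = pred * (1 + eps)``, or Poisson-type,
``obs = pred + sqrt(pred) * eps``, with ``eps ~ Normal(0, sigma^2)``.

All randomness flows from a single root seed: the root generator spawns one
independent substream per subject and per observation stream, so draws are
reproducible regardless of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .models import StructuralModel

__all__ = [
    "ErrorSpec",
    "PopulationModel",
    "IndividualParams",
    "sample_individuals",
    "apply_residual",
    "iiv_percent",
    "omega2_from_percent",
]


@dataclass(frozen=True)
class ErrorSpec:
    """Residual error model for one observation stream.

    kind : ``"multiplicative"`` (constant CV) or ``"poisson"`` (variance
    proportional to the prediction).
    """

    kind: str
    sigma: float

    def __post_init__(self) -> None:
        if self.kind not in ("multiplicative", "poisson"):
            raise ValueError(f"unknown residual model {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def variance(self, pred):
        pred = np.asarray(pred, dtype=float)
        if self.kind == "multiplicative":
            return self.sigma**2 * pred**2
        return self.sigma**2 * pred


@dataclass(frozen=True)
class IndividualParams:
    """One realized parameter set for one subject."""

    subject: int
    model: StructuralModel
    eta: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class PopulationModel:
    """Typical values plus diagonal IIV variances and residual-error specs.

    ``omega2`` maps flat parameter names (``"Ke"``, ``"IC50"``, ...) to the
    variance of the corresponding eta; parameters absent from the mapping
    carry no inter-individual variability.  ``error`` maps observation-stream
    names (``"plasma"``, ``"isf"``, ``"pd"``) to :class:`ErrorSpec`.
    """

    structural: StructuralModel
    omega2: Mapping[str, float] = field(default_factory=dict)
    error: Mapping[str, ErrorSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = set(self.structural.param_dict())
        for name, w2 in self.omega2.items():
            if name not in known:
                raise KeyError(f"omega2 references unknown parameter {name!r}")
            if w2 < 0:
                raise ValueError(f"omega2[{name!r}] must be >= 0")

    @property
    def iiv_names(self) -> tuple[str, ...]:
        """Parameters with nonzero IIV, in stable sorted order."""
        return tuple(sorted(n for n, w2 in self.omega2.items() if w2 > 0))

    def with_dose(self, dose_mg_kg: float) -> "PopulationModel":
        return PopulationModel(
            structural=self.structural.with_dose(dose_mg_kg),
            omega2=dict(self.omega2),
            error=dict(self.error),
        )

    def realize(self, subject: int, eta: Mapping[str, float]) -> IndividualParams:
        theta = self.structural.param_dict()
        updates = {name: theta[name] * float(np.exp(val)) for name, val in eta.items()}
        # the lognormal tail can push the inhibition ceiling above 1; cap it
        # at the physical bound rather than reject the draw
        if "Imax" in updates and updates["Imax"] > 1.0:
            updates["Imax"] = 1.0
        return IndividualParams(
            subject=subject, model=self.structural.replace_params(**updates), eta=dict(eta)
        )


def sample_individuals(
    pop: PopulationModel, n: int, seed: int | np.random.Generator
) -> list[IndividualParams]:
    """Draw ``n`` individual parameter sets from the population model.

    Each subject consumes its own spawned substream; with all omega^2 zero
    every individual equals the typical values exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = pop.iiv_names
    sds = np.sqrt([pop.omega2[name] for name in names])
    out = []
    for subject, sub in enumerate(rng.spawn(n), start=1):
        eta = dict(zip(names, sds * sub.standard_normal(len(names))))
        out.append(pop.realize(subject, eta))
    return out


def apply_residual(pred, spec: ErrorSpec, seed: int | np.random.Generator, *, truncate_at_zero: bool = False):
    """Add residual noise to a predicted series.

    Multiplicative: ``obs = pred * (1 + eps)``; Poisson-type:
    ``obs = pred + sqrt(pred) * eps``.  Negative observations are retained
    unless ``truncate_at_zero`` is set (the error models themselves permit
    them at small predictions).
    """
    pred = np.asarray(pred, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps = rng.standard_normal(pred.shape) * spec.sigma
    if spec.kind == "multiplicative":
        obs = pred * (1.0 + eps)
    else:
        if np.any(pred < 0):
            raise ValueError("Poisson-type residual requires nonnegative predictions")
        obs = pred + np.sqrt(pred) * eps
    if truncate_at_zero:
        obs = np.maximum(obs, 0.0)
    return obs


def iiv_percent(omega2: float) -> float:
    """Report an eta variance as a lognormal CV percentage.

    ``IIV% = 100 * sqrt(exp(omega^2) - 1)``, the standard pharmacometrics
    reporting convention.
    """
    if omega2 < 0:
        raise ValueError("omega2 must be >= 0")
    return 100.0 * float(np.sqrt(np.expm1(omega2)))


def omega2_from_percent(percent: float) -> float:
    """Inverse of :func:`iiv_percent`."""
    if percent < 0:
        raise ValueError("percent must be >= 0")
    return float(np.log1p((percent / 100.0) ** 2))
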