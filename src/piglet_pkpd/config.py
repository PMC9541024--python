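"""Declarative model/study configuration (TOML).

A config file describes one drug-biomarker system: the ``[pk]``, ``[link]``
and ``[idr]`` blocks hold typical values with the flat parameter names used
throughout the package, ``[iiv_percent]`` lists lognormal CV percentages for
the parameters that carry inter-individual variability, ``[residual]`` the
per-stream error models, and ``[design]`` the sampling schedule and assay
limits of quantification.  Bundled configs reproduce the published
typical-value tables for the three supported systems.
"""

from __future__ import annotations

import tomllib
from importlib import resources
from pathlib import Path
from typing import Any

from .datasets import StudyDesign
from .models import (
    EffectLink,
    IndirectResponse,
    IsfLink,
    OneCptPK,
    StructuralModel,
    TwoCptPK,
)
from .population import ErrorSpec, PopulationModel, omega2_from_percent

__all__ = [
    "BUNDLED_MODELS",
    "load_config",
    "structural_from_config",
    "population_from_config",
    "design_from_config",
    "load_population",
]

BUNDLED_MODELS = ("ketoprofen_pge2", "ketoprofen_cortisol", "flunixin_cortisol")


class ConfigError(ValueError):
    """Malformed or inconsistent configuration."""


def load_config(source: str | Path) -> dict[str, Any]:
    """Read a TOML config from a path or a bundled model name."""
    if isinstance(source, str) and source in BUNDLED_MODELS:
        text = resources.files("piglet_pkpd.configs").joinpath(f"{source}.toml").read_bytes()
        return tomllib.loads(text.decode())
    path = Path(source)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def _require(cfg: dict, section: str) -> dict:
    if section not in cfg:
        raise ConfigError(f"config is missing the [{section}] section")
    return cfg[section]


def structural_from_config(cfg: dict[str, Any], *, dose: float | None = None) -> StructuralModel:
    model_cfg = _require(cfg, "model")
    name = model_cfg.get("name")
    if dose is None:
        dose = float(model_cfg.get("label_dose", 0.0))
    pk_cfg = _require(cfg, "pk")
    try:
        if "K12" in pk_cfg:
            pk = TwoCptPK(
                ka=pk_cfg["Ka"], ke=pk_cfg["Ke"], k12=pk_cfg["K12"],
                k21=pk_cfg["K21"], v=pk_cfg["V"], dose=dose,
            )
        else:
            pk = OneCptPK(ka=pk_cfg["Ka"], ke=pk_cfg["Ke"], v=pk_cfg["V"], dose=dose)
    except KeyError as exc:
        raise ConfigError(f"[pk] is missing parameter {exc}") from None

    link = None
    if "link" in cfg:
        link_cfg = cfg["link"]
        if "Ke0in" in link_cfg:
            link = IsfLink(ke0in=link_cfg["Ke0in"], ke0out=link_cfg["Ke0out"])
        elif "Ke0" in link_cfg:
            link = EffectLink(ke0=link_cfg["Ke0"])
        else:
            raise ConfigError("[link] must define Ke0in/Ke0out or Ke0")

    idr_cfg = _require(cfg, "idr")
    try:
        idr = IndirectResponse(
            kin=idr_cfg["Kin"], kout=idr_cfg["Kout"], imax=idr_cfg["Imax"],
            ic50=idr_cfg["IC50"], gamma=idr_cfg.get("gamma", 1.0),
        )
    except KeyError as exc:
        raise ConfigError(f"[idr] is missing parameter {exc}") from None
    return StructuralModel(name=name, pk=pk, idr=idr, link=link)


def population_from_config(
    cfg: dict[str, Any], *, dose: float | None = None, iiv: bool = True
) -> PopulationModel:
    structural = structural_from_config(cfg, dose=dose)
    omega2 = {}
    if iiv:
        for name, pct in cfg.get("iiv_percent", {}).items():
            omega2[name] = omega2_from_percent(float(pct))
    error = {}
    for stream, spec in cfg.get("residual", {}).items():
        error[stream] = ErrorSpec(kind=spec["type"], sigma=float(spec["sigma"]))
    return PopulationModel(structural=structural, omega2=omega2, error=error)


def design_from_config(cfg: dict[str, Any]) -> StudyDesign:
    design_cfg = _require(cfg, "design")
    model_cfg = _require(cfg, "model")
    return StudyDesign(
        n_per_group=int(design_cfg.get("n_per_group", 8)),
        dose=float(model_cfg.get("label_dose", 0.0)),
        castration_time=float(design_cfg.get("castration_time", 2.0)),
        schedule={k: tuple(v) for k, v in design_cfg.get("schedule", {}).items()},
        loq={k: float(v) for k, v in design_cfg.get("loq", {}).items()},
    )


def load_population(
    source: str | Path, *, dose: float | None = None, iiv: bool = True
) -> PopulationModel:
    """One-call loader: bundled name or path -> PopulationModel."""
    return population_from_config(load_config(source), dose=dose, iiv=iiv)
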