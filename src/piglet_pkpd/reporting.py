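"""Report tables, the end-to-end pipeline, and run manifests.

Parameter tables follow the column layout conventional for population PK/PD
reports: ``Parameter | Estimate (CI) | Units | CV% | IIV% | Bootstrap median
estimate (CI)``, with en-dash placeholders for non-applicable cells.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import design_from_config, load_config, population_from_config
from .datasets import generate_study, write_dataset
from .dose_response import build_curve
from .estimate import BootstrapResult, FitResult, fit_sequential
from .models import IsfLink
from .secondary import secondary_table

__all__ = ["RunConfig", "render_param_table", "run_pipeline"]

#: default units for reported parameters
PARAM_UNITS = {
    "Ka": "1/h", "Ke": "1/h", "K12": "1/h", "K21": "1/h", "V": "ml/kg",
    "Ke0in": "1/h", "Ke0out": "1/h", "Ke0": "1/h",
    "Kin": "%/h", "Kout": "1/h", "Imax": "", "IC50": "ug/ml", "gamma": "",
}

NA = "-"


def _fmt(value: float) -> str:
    """Two decimals for ordinary magnitudes, two significant digits below 0.1."""
    if value == 0:
        return "0.00"
    if abs(value) >= 0.095:
        return f"{value:.2f}"
    from math import floor, log10

    digits = 1 - floor(log10(abs(value)))
    return f"{value:.{digits}f}"


def _fmt_ci(value: float, ci: Optional[tuple[float, float]]) -> str:
    if ci is None:
        return _fmt(value)
    return f"{_fmt(value)} ({_fmt(ci[0])}–{_fmt(ci[1])})"


def render_param_table(
    fit_result: FitResult,
    boot: Optional[BootstrapResult] = None,
    *,
    units: Optional[Mapping[str, str]] = None,
    order: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Render a fit (and optional bootstrap) as a report table.

    Units come from the supplied mapping (falling back to the package
    defaults), never inferred from values.  Use ``to_string(index=False)``
    or ``to_csv`` on the result for text/CSV renderings.
    """
    units = {**PARAM_UNITS, **(units or {})}
    names = list(order) if order else sorted(fit_result.theta)
    rows = []
    for name in names:
        est = fit_result.theta[name]
        iiv = fit_result.iiv_percent.get(name)
        cv = fit_result.cv_percent.get(name)
        brow = NA
        if boot is not None and name in boot.median:
            brow = _fmt_ci(boot.median[name], boot.ci.get(name))
        rows.append(
            {
                "Parameter": name,
                "Estimate (CI)": _fmt_ci(est, fit_result.ci.get(name)),
                "Units": units.get(name, ""),
                "CV%": _fmt(cv) if cv is not None else NA,
                "IIV%": _fmt(iiv) if iiv is not None else NA,
                "Bootstrap median estimate (CI)": brow,
            }
        )
    for stream, sigma in sorted(fit_result.sigma.items()):
        key = f"sigma_{stream}"
        cv = fit_result.cv_percent.get(key)
        rows.append(
            {
                "Parameter": f"sigma ({stream})",
                "Estimate (CI)": _fmt_ci(sigma, fit_result.ci.get(key)),
                "Units": "",
                "CV%": _fmt(cv) if cv is not None else NA,
                "IIV%": NA,
                "Bootstrap median estimate (CI)": (
                    _fmt_ci(boot.median[key], boot.ci.get(key))
                    if boot is not None and key in boot.median
                    else NA
                ),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run (see :func:`run_pipeline`)."""

    model: str  # bundled model name or path to a TOML config
    seed: int = 0
    outdir: str | Path = "piglet-pkpd-run"
    iiv: bool = True
    residual: bool = True
    n_mc: int = 1000
    doses: Optional[tuple[float, ...]] = None
    skip_fit: bool = False
    skip_dose_response: bool = False
    fit_kwargs: Mapping[str, object] = field(default_factory=dict)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _fit_to_dict(res: FitResult) -> dict:
    return _jsonable(
        {
            "theta": res.theta,
            "omega2": res.omega2,
            "iiv_percent": res.iiv_percent,
            "sigma": res.sigma,
            "ci": res.ci,
            "cv_percent": res.cv_percent,
            "ofv": res.ofv,
            "aic": res.aic,
            "bic": res.bic,
            "n_obs": res.n_obs,
            "n_params": res.n_params,
            "converged": res.converged,
            "status": res.status,
            "n_blq_excluded": res.n_blq_excluded,
            "ebes": res.ebes,
        }
    )


def run_pipeline(config: RunConfig) -> dict:
    """Generate a synthetic study, fit it, and run the dose-response analysis.

    Stages: generate dataset -> sequential PK/PD fit -> secondary parameters
    -> dose-response curve (both Monte-Carlo and typical-value modes).  Each
    stage's outputs are written under ``config.outdir`` together with a
    manifest (config hash, seed, package version, stage wall times) that
    fully determines every output byte.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = load_config(config.model)
    pop = population_from_config(cfg, iiv=config.iiv)
    design = design_from_config(cfg)
    label_dose = float(cfg["model"].get("label_dose", 0.0))
    manifest: dict = {
        "model": config.model,
        "seed": config.seed,
        "version": __version__,
        "config_sha256": hashlib.sha256(
            json.dumps(_jsonable(cfg), sort_keys=True).encode()
        ).hexdigest(),
        "stages": {},
    }
    results: dict = {"manifest": manifest}

    t0 = time.perf_counter()
    if config.residual:
        dataset = generate_study(design, pop, seed=config.seed)
    else:
        noiseless = population_from_config(cfg, iiv=config.iiv)
        noiseless = type(noiseless)(
            structural=noiseless.structural,
            omega2=noiseless.omega2,
            error={k: type(v)(v.kind, 0.0) for k, v in noiseless.error.items()},
        )
        dataset = generate_study(design, noiseless, seed=config.seed)
    write_dataset(dataset, outdir / "dataset.csv")
    manifest["stages"]["generate"] = {
        "seconds": round(time.perf_counter() - t0, 3),
        "n_obs": int((dataset.frame["EVID"] == 0).sum()),
        "n_blq": dataset.n_blq(),
    }
    results["dataset"] = dataset

    if not config.skip_fit:
        t0 = time.perf_counter()
        fit_pk, fit_pd = fit_sequential(dataset, dataset, pop, **dict(config.fit_kwargs))
        for tag, res in (("pk", fit_pk), ("pd", fit_pd)):
            with open(outdir / f"fit_{tag}.json", "w") as fh:
                json.dump(_fit_to_dict(res), fh, indent=1)
            render_param_table(res).to_csv(outdir / f"params_{tag}.csv", index=False)
        manifest["stages"]["fit"] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "ofv_pk": fit_pk.ofv,
            "ofv_pd": fit_pd.ofv,
            "n_blq_excluded": fit_pk.n_blq_excluded,
        }
        results["fit_pk"], results["fit_pd"] = fit_pk, fit_pd

        structural = fit_pk.pop.structural
        sec = secondary_table(
            structural.pk,
            link=structural.link if isinstance(structural.link, IsfLink) else None,
            isf_ic50=(
                fit_pd.theta.get("IC50") if isinstance(structural.link, IsfLink) else None
            ),
        )
        with open(outdir / "secondary.json", "w") as fh:
            json.dump(_jsonable(vars(sec)), fh, indent=1)
        results["secondary"] = sec

    if not config.skip_dose_response:
        t0 = time.perf_counter()
        curves = {}
        for mode, iiv in (("mc", True), ("typical", False)):
            curve = build_curve(
                pop,
                doses=config.doses,
                n_mc=config.n_mc,
                seed=config.seed,
                iiv=iiv and config.iiv,
            )
            curve.to_frame().to_csv(outdir / f"dose_response_{mode}.csv", index=False)
            curves[mode] = curve
        summary = {
            mode: {
                "ed50": c.ed50,
                "ed50_method": c.ed50_method,
                "pct_at_label_dose": c.pct_at(label_dose) if label_dose else None,
                "n_mc": c.n_mc,
            }
            for mode, c in curves.items()
        }
        with open(outdir / "ed50.json", "w") as fh:
            json.dump(_jsonable(summary), fh, indent=1)
        manifest["stages"]["dose_response"] = {
            "seconds": round(time.perf_counter() - t0, 3),
            **summary,
        }
        results["curves"] = curves

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(_jsonable(manifest), fh, indent=1)
    return results
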