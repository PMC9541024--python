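"""Nonlinear mixed-effects estimation (FOCE/Laplace), bootstrap, and VPC.

The marginal likelihood of each subject's data is approximated by the
first-order conditional (FOCE) method: for the current population parameters
the subject-level random effects ``eta`` are optimised (inner problem), and
the integral over ``eta`` is approximated by a Gaussian expansion around the
conditional mode.  The expansion Hessian is either the Gauss-Newton/expected
form built from first-order sensitivities (``approx="foce"``, the default,
corresponding to FOCE with interaction since the residual variance depends
on the individual prediction) or the full finite-difference Hessian of the
conditional objective (``approx="laplace"``).

The outer problem maximises the summed approximate marginal likelihood over
``(log theta, log omega^2, log sigma)`` with a derivative-free direction-set
(Powell) search; confidence intervals are Wald intervals on the log scale
from the finite-difference Hessian of the objective, back-transformed (hence
strictly positive bounds).

Workflow mirrors standard practice for these models: the PK (and, for the
ISF system, link) parameters are estimated first from the drug-concentration
streams; the PD stage then conditions on the per-subject empirical Bayes PK
parameters, estimating only turnover/link-to-effect parameters.  Below-LOQ
observations are excluded from the likelihood (M1) with the count logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import optimize

from .datasets import StudyDataset
from .population import ErrorSpec, PopulationModel, apply_residual, iiv_percent
from .simulate import STREAM_IDS, _build_grid, _linear_turnover

__all__ = [
    "FitResult",
    "BootstrapResult",
    "VpcResult",
    "NonConvergenceError",
    "fit",
    "fit_sequential",
    "information_criteria",
    "bootstrap",
    "vpc",
]

#: biomarker-integration grid step (h) used inside estimation; coarser than
#: the simulation default because residual noise dominates at this scale
FIT_GRID_STEP = 0.1

_LOG2PI = float(np.log(2.0 * np.pi))
_BIG = 1e10


class NonConvergenceError(RuntimeError):
    """Raised when an operation requires a converged fit and none is available."""


@dataclass(frozen=True)
class FitResult:
    """Population estimates with uncertainty and per-subject random effects."""

    theta: dict[str, float]
    omega2: dict[str, float]
    sigma: dict[str, float]
    ci: dict[str, Optional[tuple[float, float]]]
    cv_percent: dict[str, Optional[float]]
    ofv: float  # -2 log (approximate) marginal likelihood
    aic: float
    bic: float
    n_obs: int
    n_params: int
    ebes: dict[int, dict[str, float]]  # subject -> eta-hat
    converged: bool
    status: str
    n_blq_excluded: int
    streams: tuple[str, ...]
    pop: PopulationModel  # population model at the estimates
    subject_params: dict[int, dict[str, float]] = field(default_factory=dict)
    history: tuple[float, ...] = ()  # objective at accepted outer iterations
    multistart_ofvs: tuple[float, ...] = ()

    @property
    def iiv_percent(self) -> dict[str, float]:
        return {k: iiv_percent(v) for k, v in self.omega2.items()}


@dataclass(frozen=True)
class BootstrapResult:
    """Subject-resampling bootstrap summary."""

    median: dict[str, float]
    ci: dict[str, tuple[float, float]]
    n_rep: int
    n_failed: int
    estimates: tuple[dict[str, float], ...] = ()


@dataclass(frozen=True)
class VpcResult:
    """Visual-predictive-check bands and observed percentiles per time bin."""

    stream: str
    times: np.ndarray
    observed: np.ndarray  # (3, n_bins): 5th/50th/95th percentile of the data
    predicted_median: np.ndarray  # (3, n_bins): median over replicates
    predicted_low: np.ndarray  # (3, n_bins): 2.5th percentile over replicates
    predicted_high: np.ndarray  # (3, n_bins): 97.5th percentile over replicates


# ---------------------------------------------------------------------------
# data extraction
# ---------------------------------------------------------------------------


def _subject_tables(dataset: StudyDataset, streams: Sequence[str]):
    """Per-subject observation arrays (BLQ excluded) and doses."""
    subjects = []
    n_blq = 0
    for subject in dataset.subjects:
        dose = dataset.dose_of(subject)
        obs = {}
        for stream in streams:
            rows = dataset.observations(stream)
            rows = rows[rows["ID"] == subject]
            blq_rows = dataset.observations(stream, include_blq=True)
            n_blq += int(blq_rows[blq_rows["ID"] == subject]["BLQ"].sum())
            if len(rows):
                obs[stream] = (
                    rows["TIME"].to_numpy(dtype=float),
                    rows["DV"].to_numpy(dtype=float),
                )
        if obs:
            subjects.append((subject, dose, obs))
    return subjects, n_blq


# ---------------------------------------------------------------------------
# prediction (fast path on plain parameter dicts -- called millions of times
# inside the optimizer, so it bypasses the dataclass layer; equivalence with
# the model-object path is asserted in the test suite)
# ---------------------------------------------------------------------------


def _expsum_one(ka, ke, v, dose_ug):
    if ka <= 0 or ke <= 0 or v <= 0 or abs(ka - ke) <= 1e-9 * max(ka, ke):
        raise ValueError("invalid one-compartment parameters")
    a = dose_ug * ka / (v * (ka - ke))
    return np.array([a, -a]), np.array([ke, ka])


def _expsum_two(ka, ke, k12, k21, v, dose_ug):
    if min(ka, ke, k12, k21, v) <= 0:
        raise ValueError("invalid two-compartment parameters")
    s = ke + k12 + k21
    p = ke * k21
    alpha = 0.5 * (s + np.sqrt(max(s * s - 4.0 * p, 0.0)))
    beta = p / alpha
    if min(abs(ka - alpha), abs(ka - beta)) <= 1e-9 * max(ka, alpha):
        raise ValueError("absorption rate coincides with a macro-rate")
    front = ka * dose_ug / v
    with np.errstate(divide="ignore", invalid="ignore"):
        coefs = np.array(
            [
                front * (k21 - alpha) / ((ka - alpha) * (beta - alpha)),
                front * (k21 - beta) / ((ka - beta) * (alpha - beta)),
                front * (k21 - ka) / ((alpha - ka) * (beta - ka)),
            ]
        )
    if not np.all(np.isfinite(coefs)):
        raise ValueError("degenerate two-compartment exponents")
    return coefs, np.array([alpha, beta, ka])


def _filter_expsum(coefs, rates, k_in, k_out):
    ko = k_out
    scale = max(abs(ko), float(np.max(np.abs(rates))), 1.0)
    for r in rates:
        if abs(ko - r) < 1e-9 * scale:
            ko = r + 1e-9 * scale
    new = k_in * coefs / (ko - rates)
    return np.concatenate([new, [-new.sum()]]), np.concatenate([rates, [ko]])


def _eval_expsum(coefs, rates, t):
    return np.exp(-np.multiply.outer(rates, t)).T @ coefs


def _fast_predict(
    pk_kind: str,
    link_kind: Optional[str],
    params: Mapping[str, float],
    times_by_stream: Mapping[str, np.ndarray],
    grid_step: float = FIT_GRID_STEP,
    pd_grid: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> dict[str, np.ndarray]:
    """Stream predictions from a flat parameter dict (incl. ``dose`` mg/kg)."""
    dose_ug = params["dose"] * 1000.0
    if pk_kind == "one":
        coefs, rates = _expsum_one(params["Ka"], params["Ke"], params["V"], dose_ug)
    else:
        coefs, rates = _expsum_two(
            params["Ka"], params["Ke"], params["K12"], params["K21"], params["V"], dose_ug
        )
    out = {}
    if "plasma" in times_by_stream:
        out["plasma"] = _eval_expsum(coefs, rates, times_by_stream["plasma"])
    need_driver = "isf" in times_by_stream or "pd" in times_by_stream
    if need_driver:
        if link_kind == "isf":
            if params["Ke0in"] <= 0 or params["Ke0out"] <= 0:
                raise ValueError("invalid link parameters")
            dcoefs, drates = _filter_expsum(coefs, rates, params["Ke0in"], params["Ke0out"])
        elif link_kind == "effect":
            if params["Ke0"] <= 0:
                raise ValueError("invalid link parameters")
            dcoefs, drates = _filter_expsum(coefs, rates, params["Ke0"], params["Ke0"])
        else:
            dcoefs, drates = coefs, rates
    if "isf" in times_by_stream:
        out["isf"] = _eval_expsum(dcoefs, drates, times_by_stream["isf"])
    if "pd" in times_by_stream:
        kin, kout = params["Kin"], params["Kout"]
        imax, ic50, gamma = params["Imax"], params["IC50"], params.get("gamma", 1.0)
        if min(kin, kout, ic50, gamma) <= 0 or not 0 < imax <= 1:
            raise ValueError("invalid turnover parameters")
        if pd_grid is None:
            t_obs = times_by_stream["pd"]
            horizon = float(t_obs.max()) if len(t_obs) else 0.0
            grid = _build_grid(max(horizon, grid_step), grid_step, t_obs)
            idx = np.searchsorted(grid, t_obs)
        else:
            grid, idx = pd_grid
        driver = np.maximum(_eval_expsum(dcoefs, drates, grid), 0.0)
        ratio = np.power(driver / ic50, gamma)
        source = kin * (1.0 - imax * ratio / (1.0 + ratio))
        e = _linear_turnover(grid, source, kout, kin / kout)
        out["pd"] = e[idx]
    return out


# ---------------------------------------------------------------------------
# FOCE machinery
# ---------------------------------------------------------------------------


class _FoceProblem:
    """Bundles data, parameterisation, and the approximate -2 log likelihood."""

    def __init__(
        self,
        pop0: PopulationModel,
        subjects,
        streams: Sequence[str],
        free_theta: Sequence[str],
        fixed: frozenset,
        subject_frozen: Optional[Mapping[int, Mapping[str, float]]] = None,
        approx: str = "foce",
        grid_step: float = FIT_GRID_STEP,
    ) -> None:
        if approx not in ("foce", "laplace"):
            raise ValueError("approx must be 'foce' or 'laplace'")
        self.pop0 = pop0
        self.subjects = subjects
        self.streams = tuple(streams)
        self.approx = approx
        self.grid_step = grid_step
        self.subject_frozen = dict(subject_frozen or {})
        all_params = pop0.structural.param_dict()
        self.theta_names = [n for n in free_theta if n not in fixed]
        for name in self.theta_names:
            if name not in all_params:
                raise KeyError(f"unknown parameter {name!r}")
        self.omega_names = [
            n for n in sorted(pop0.omega2) if pop0.omega2[n] > 0 and n in set(free_theta)
        ]
        self.sigma_streams = [
            s for s in self.streams if s in pop0.error and f"sigma_{s}" not in fixed
        ]
        self.fixed_sigma = {
            s: pop0.error[s].sigma for s in self.streams if s in pop0.error
        }
        self.theta0 = {n: all_params[n] for n in self.theta_names}
        self.base_params = dict(all_params)
        self.pk_kind = "two" if "K12" in all_params else "one"
        self.link_kind = (
            "isf" if "Ke0in" in all_params else "effect" if "Ke0" in all_params else None
        )
        self._warm: dict[int, np.ndarray] = {}
        self._pd_grid: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for subject, _, obs in subjects:
            if "pd" in obs:
                t_obs = obs["pd"][0]
                grid = _build_grid(max(float(t_obs.max()), grid_step), grid_step, t_obs)
                self._pd_grid[subject] = (grid, np.searchsorted(grid, t_obs))
        self.n_obs = sum(len(y) for _, _, obs in subjects for (_, y) in obs.values())

    # -- packing ------------------------------------------------------------

    def x0(self) -> np.ndarray:
        parts = [np.log([self.theta0[n] for n in self.theta_names])] if self.theta_names else []
        if self.omega_names:
            parts.append(np.log([self.pop0.omega2[n] for n in self.omega_names]))
        if self.sigma_streams:
            parts.append(np.log([self.pop0.error[s].sigma for s in self.sigma_streams]))
        return np.concatenate(parts) if parts else np.array([])

    def unpack(self, x: np.ndarray):
        nt, no = len(self.theta_names), len(self.omega_names)
        theta = dict(zip(self.theta_names, np.exp(x[:nt])))
        omega2 = dict(zip(self.omega_names, np.exp(x[nt : nt + no])))
        sigma = dict(self.fixed_sigma)
        sigma.update(zip(self.sigma_streams, np.exp(x[nt + no :])))
        return theta, omega2, sigma

    @property
    def n_params(self) -> int:
        return len(self.theta_names) + len(self.omega_names) + len(self.sigma_streams)

    # -- likelihood ---------------------------------------------------------

    def _merged_params(
        self, dose: float, theta: Mapping[str, float], subject: int, eta: np.ndarray
    ) -> dict[str, float]:
        params = dict(self.base_params)
        params.update(theta)
        params.update(self.subject_frozen.get(subject, {}))
        params["dose"] = dose
        for name, e in zip(self.omega_names, eta):
            params[name] = params[name] * float(np.exp(np.clip(e, -50.0, 50.0)))
        if params.get("Imax", 0.5) > 1.0:
            params["Imax"] = 1.0
        return params

    def _predict(self, params, times_by_stream, subject=None):
        return _fast_predict(
            self.pk_kind,
            self.link_kind,
            params,
            times_by_stream,
            self.grid_step,
            self._pd_grid.get(subject),
        )

    def _residual_terms(self, params, obs, sigma, subject=None):
        """Sum over streams of log(2 pi v) + (y - f)^2 / v."""
        times = {s: t for s, (t, _) in obs.items()}
        preds = self._predict(params, times, subject)
        total = 0.0
        for stream, (t, y) in obs.items():
            f = preds[stream]
            spec = self.pop0.error[stream]
            v = ErrorSpec(spec.kind, sigma[stream]).variance(np.maximum(f, 1e-12))
            v = np.maximum(v, 1e-300)
            total += float(np.sum(np.log(2.0 * np.pi * v) + (y - f) ** 2 / v))
        return total, preds

    def _conditional_m(self, subject, dose, obs, theta, omega2_vec, sigma, eta):
        """-2 log [p(y|eta) p(eta)] up to the constant d*log(2pi)."""
        try:
            params = self._merged_params(dose, theta, subject, eta)
            resid, _ = self._residual_terms(params, obs, sigma, subject)
        except (ValueError, OverflowError, FloatingPointError):
            return _BIG
        if not np.isfinite(resid):
            return _BIG
        pen = float(np.sum(eta**2 / omega2_vec) + np.sum(np.log(omega2_vec)))
        return resid + pen

    def _subject_nll(self, subject, dose, obs, theta, omega2, sigma):
        d = len(self.omega_names)
        if d == 0:
            m = self._conditional_m(subject, dose, obs, theta, np.array([]), sigma, np.array([]))
            return m, np.array([])
        w2 = np.array([omega2[n] for n in self.omega_names])
        eta0 = self._warm.get(subject, np.zeros(d))

        def m_of(eta):
            return self._conditional_m(subject, dose, obs, theta, w2, sigma, eta)

        eta_hat = _newton_inner(m_of, eta0, self._grad_hess_factory(subject, dose, obs, theta, w2, sigma))
        if not np.isfinite(m_of(eta_hat)):
            eta_hat = np.zeros(d)
        self._warm[subject] = eta_hat
        m_val = m_of(eta_hat)
        if m_val >= _BIG:
            return _BIG, eta_hat
        # curvature term of the Gaussian integral approximation
        hess = self._expansion_hessian(subject, dose, obs, theta, w2, sigma, eta_hat, m_of)
        sign, logdet = np.linalg.slogdet(hess)
        if sign <= 0:
            return _BIG, eta_hat
        return m_val + logdet, eta_hat

    def _grad_hess_factory(self, subject, dose, obs, theta, w2, sigma):
        """Gauss-Newton gradient/Hessian of the conditional objective."""

        def grad_hess(eta):
            d = len(eta)
            times = {s: t for s, (t, _) in obs.items()}
            try:
                f0 = self._predict(self._merged_params(dose, theta, subject, eta), times, subject)
            except ValueError:
                return None, None
            # forward differences of predictions wrt eta
            h = 1e-5
            fps = []
            for k in range(d):
                ek = eta.copy()
                ek[k] += h
                try:
                    fps.append(
                        self._predict(
                            self._merged_params(dose, theta, subject, ek), times, subject
                        )
                    )
                except ValueError:
                    return None, None
            grad = 2.0 * eta / w2
            hess = np.diag(2.0 / w2)
            for stream, (t, y) in obs.items():
                f = np.maximum(f0[stream], 1e-12)
                spec = self.pop0.error[stream]
                s2 = sigma[stream] ** 2
                v = np.maximum(ErrorSpec(spec.kind, sigma[stream]).variance(f), 1e-300)
                r = y - f0[stream]
                df = np.stack([(fps[k][stream] - f0[stream]) / h for k in range(d)])
                if spec.kind == "multiplicative":
                    dv = 2.0 * s2 * f * df
                else:
                    dv = s2 * df
                grad += np.sum(dv / v - r**2 * dv / v**2 - 2.0 * r * df / v, axis=1)
                hess += 2.0 * (df / v) @ df.T + (dv / v**2) @ dv.T
            return grad, hess

        return grad_hess

    def _expansion_hessian(self, subject, dose, obs, theta, w2, sigma, eta_hat, m_of):
        d = len(eta_hat)
        if self.approx == "foce":
            _, hess = self._grad_hess_factory(subject, dose, obs, theta, w2, sigma)(eta_hat)
            if hess is None:
                return np.eye(d)
            return 0.5 * hess  # M = Hessian of m/2
        # laplace: full numeric Hessian of m/2
        h = 1e-4
        hess = np.empty((d, d))
        m0 = m_of(eta_hat)
        for i in range(d):
            for j in range(i, d):
                ei = np.zeros(d)
                ej = np.zeros(d)
                ei[i] = h
                ej[j] = h
                mpp = m_of(eta_hat + ei + ej)
                mpm = m_of(eta_hat + ei - ej)
                mmp = m_of(eta_hat - ei + ej)
                mmm = m_of(eta_hat - ei - ej)
                hess[i, j] = hess[j, i] = (mpp - mpm - mmp + mmm) / (8.0 * h * h)
        return hess

    def objective(self, x: np.ndarray) -> float:
        theta, omega2, sigma = self.unpack(x)
        # soft box keeping the search within +-5 log units of the start
        pen = 0.0
        x0 = self.x0()
        excess = np.abs(x - x0) - 5.0
        pen += 1e4 * float(np.sum(np.maximum(excess, 0.0) ** 2))
        total = pen
        for subject, dose, obs in self.subjects:
            nll, _ = self._subject_nll(subject, dose, obs, theta, omega2, sigma)
            total += nll
            if total >= _BIG:
                return total
        return total

    def ebes(self, x: np.ndarray) -> dict[int, dict[str, float]]:
        theta, omega2, sigma = self.unpack(x)
        out = {}
        for subject, dose, obs in self.subjects:
            _, eta_hat = self._subject_nll(subject, dose, obs, theta, omega2, sigma)
            out[subject] = dict(zip(self.omega_names, eta_hat))
        return out


def _newton_inner(m_of, eta0, grad_hess, max_iter=8, tol=1e-5):
    """Damped Newton minimisation of the conditional objective."""
    eta = eta0.copy()
    m_cur = m_of(eta)
    if m_cur >= _BIG:
        eta = np.zeros_like(eta)
        m_cur = m_of(eta)
        if m_cur >= _BIG:
            return eta
    for _ in range(max_iter):
        grad, hess = grad_hess(eta)
        if grad is None or not np.all(np.isfinite(grad)):
            break
        try:
            step = np.linalg.solve(hess + 1e-10 * np.eye(len(eta)), grad)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)):
            break
        if float(np.max(np.abs(step))) < tol:
            break
        scale = 1.0
        for _ in range(8):
            cand = eta - scale * step
            m_new = m_of(cand)
            if m_new < m_cur:
                break
            scale *= 0.5
        else:
            break
        eta, m_cur = cand, m_new
        if float(np.max(np.abs(scale * step))) < tol:
            break
    return eta


# ---------------------------------------------------------------------------
# public fitting API
# ---------------------------------------------------------------------------


def fit(
    dataset: StudyDataset,
    pop0: PopulationModel,
    *,
    streams: Optional[Sequence[str]] = None,
    free_theta: Optional[Sequence[str]] = None,
    fixed: frozenset | set = frozenset(),
    subject_frozen: Optional[Mapping[int, Mapping[str, float]]] = None,
    approx: str = "foce",
    n_starts: int = 1,
    compute_se: bool = True,
    maxfev: int = 2000,
    xtol: float = 1e-4,
    seed: int = 0,
    grid_step: float = FIT_GRID_STEP,
) -> FitResult:
    """Estimate population parameters from a study dataset.

    ``streams`` selects the observation streams entering the likelihood
    (default: all streams present in both data and error spec).  ``free_theta``
    lists the structural parameters to estimate (default: all parameters of
    the structural model except the dose); names in ``fixed`` (parameters or
    ``"sigma_<stream>"``) are frozen at their ``pop0`` values.
    ``subject_frozen`` supplies per-subject parameter values conditioned on
    (used by the sequential PD stage).  ``n_starts > 1`` repeats the fit from
    jittered initial values and keeps the best objective.
    """
    fixed = frozenset(fixed)
    present = [s for s in STREAM_IDS if not dataset.observations(s, include_blq=True).empty]
    if streams is None:
        streams = [s for s in present if s in pop0.error]
    subjects, n_blq = _subject_tables(dataset, streams)
    if not subjects:
        raise ValueError("dataset contains no usable observations for the fitted streams")
    if max(len(y) for _, _, obs in subjects for (_, y) in obs.values()) < 2:
        raise ValueError("at least one subject needs >= 2 observations of a fitted stream")
    if free_theta is None:
        free_theta = [n for n in pop0.structural.param_dict() if n != "dose"]

    problem = _FoceProblem(
        pop0, subjects, streams, free_theta, fixed, subject_frozen, approx, grid_step
    )
    rng = np.random.default_rng(seed)
    history: list[float] = []

    best = None
    multistart_ofvs = []
    for start in range(max(1, n_starts)):
        x0 = problem.x0()
        if start > 0:
            x0 = x0 + 0.2 * rng.standard_normal(x0.shape)
        problem._warm.clear()
        if x0.size == 0:
            res_x, res_fun, success, message = x0, problem.objective(x0), True, "nothing to estimate"
        else:
            res = optimize.minimize(
                problem.objective,
                x0,
                method="Powell",
                callback=lambda xk: history.append(problem.objective(xk)),
                options={"maxfev": maxfev, "xtol": xtol, "ftol": 1e-7},
            )
            res_x, res_fun, success, message = res.x, float(res.fun), bool(res.success), res.message
        multistart_ofvs.append(res_fun)
        if best is None or res_fun < best[1]:
            best = (np.atleast_1d(res_x), res_fun, success, message)

    x_hat, ofv, converged, status = best
    if ofv >= _BIG:
        converged = False
        status = "objective did not evaluate to a finite value"
    theta, omega2, sigma = problem.unpack(x_hat)

    ci: dict[str, Optional[tuple[float, float]]] = {}
    cv: dict[str, Optional[float]] = {}
    if compute_se and converged and x_hat.size:
        ses = _wald_se(problem, x_hat)
        names = (
            problem.theta_names
            + [f"omega2_{n}" for n in problem.omega_names]
            + [f"sigma_{s}" for s in problem.sigma_streams]
        )
        values = np.concatenate(
            [
                [theta[n] for n in problem.theta_names],
                [omega2[n] for n in problem.omega_names],
                [sigma[s] for s in problem.sigma_streams],
            ]
        )
        for name, value, se in zip(names, values, ses):
            if se is None or not np.isfinite(se):
                ci[name] = None
                cv[name] = None
            else:
                ci[name] = (value * np.exp(-1.96 * se), value * np.exp(1.96 * se))
                cv[name] = 100.0 * se  # delta method: SE(theta)/theta = SE(log theta)

    ebes = problem.ebes(x_hat)
    all_params = pop0.structural.param_dict()
    subject_params = {}
    for subject, dose, _ in subjects:
        params = {n: theta.get(n, all_params[n]) for n in free_theta}
        if subject_frozen and subject in subject_frozen:
            params.update(subject_frozen[subject])
        for n, e in ebes[subject].items():
            params[n] = params[n] * float(np.exp(e))
        subject_params[subject] = params

    structural_hat = pop0.structural.replace_params(
        **{n: min(v, 1.0) if n == "Imax" else v for n, v in theta.items()}
    )
    omega2_hat = dict(pop0.omega2)
    omega2_hat.update(omega2)
    error_hat = {
        s: ErrorSpec(pop0.error[s].kind, sigma.get(s, pop0.error[s].sigma))
        for s in pop0.error
    }
    pop_hat = PopulationModel(structural=structural_hat, omega2=omega2_hat, error=error_hat)

    p = problem.n_params
    aic = ofv + 2.0 * p
    bic = ofv + p * np.log(max(problem.n_obs, 1))
    return FitResult(
        theta=theta,
        omega2=omega2,
        sigma=sigma,
        ci=ci,
        cv_percent=cv,
        ofv=ofv,
        aic=float(aic),
        bic=float(bic),
        n_obs=problem.n_obs,
        n_params=p,
        ebes=ebes,
        converged=converged,
        status=str(status),
        n_blq_excluded=n_blq,
        streams=tuple(streams),
        pop=pop_hat,
        subject_params=subject_params,
        history=tuple(history),
        multistart_ofvs=tuple(multistart_ofvs),
    )


def _wald_se(problem: _FoceProblem, x_hat: np.ndarray):
    """SEs of the log-scale parameters from the FD Hessian of the objective."""
    k = len(x_hat)
    h = 1e-3
    hess = np.empty((k, k))
    f = problem.objective
    f0 = f(x_hat)
    fp = np.empty(k)
    fm = np.empty(k)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h
        fp[i] = f(x_hat + ei)
        fm[i] = f(x_hat - ei)
    for i in range(k):
        for j in range(i, k):
            if i == j:
                hess[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / h**2
            else:
                ei = np.zeros(k)
                ej = np.zeros(k)
                ei[i] = h
                ej[j] = h
                hess[i, j] = hess[j, i] = (
                    f(x_hat + ei + ej) - fp[i] - fp[j] + 2.0 * f0 - fm[i] - fm[j] + f(x_hat - ei - ej)
                ) / (2.0 * h**2)
    # objective is -2 log L, so cov = 2 * H^{-1}
    try:
        cov = 2.0 * np.linalg.inv(hess)
        diag = np.diag(cov)
        return [float(np.sqrt(d)) if d > 0 else None for d in diag]
    except np.linalg.LinAlgError:
        return [None] * k


PK_PARAMS = {"Ka", "Ke", "K12", "K21", "V", "Ke0in", "Ke0out"}
PD_PARAMS = {"Kin", "Kout", "Imax", "IC50", "gamma", "Ke0"}


def fit_sequential(
    pk_dataset: StudyDataset,
    pd_dataset: StudyDataset,
    pop0: PopulationModel,
    *,
    conditioning: str = "ebe",
    fixed: frozenset | set = frozenset(),
    **fit_kwargs,
) -> tuple[FitResult, FitResult]:
    """Two-stage estimation: drug-concentration streams first, then PD.

    Stage 1 fits the PK (and ISF link) parameters to the plasma (and ISF)
    drug concentrations.  Stage 2 fits the turnover parameters (plus the
    effect-compartment rate when the model has one) to the biomarker stream,
    conditioning each subject on their stage-1 empirical Bayes parameter set
    (``conditioning="ebe"``) or on the population estimates
    (``conditioning="population"``).
    """
    if conditioning not in ("ebe", "population"):
        raise ValueError("conditioning must be 'ebe' or 'population'")
    if pk_dataset.observations("plasma", include_blq=True).empty:
        raise ValueError(
            "stage-1 dataset has no plasma drug concentrations; "
            "PK must be fitted before PD"
        )
    if pd_dataset.observations("pd", include_blq=True).empty:
        raise ValueError("stage-2 dataset has no biomarker observations")
    if not set(pk_dataset.subjects) & set(pd_dataset.subjects):
        raise ValueError("PK and PD datasets share no subject IDs")

    model_params = set(pop0.structural.param_dict())
    has_isf_link = "Ke0in" in model_params
    pk_free = sorted((PK_PARAMS if has_isf_link else PK_PARAMS - {"Ke0in", "Ke0out"}) & model_params)
    pk_streams = ["plasma"] + (["isf"] if has_isf_link else [])
    pk_streams = [s for s in pk_streams if not pk_dataset.observations(s, include_blq=True).empty]
    fit_pk = fit(
        pk_dataset, pop0, streams=pk_streams, free_theta=pk_free, fixed=fixed, **fit_kwargs
    )

    pd_free = sorted(PD_PARAMS & model_params)
    if "gamma" in pd_free and pop0.structural.idr.gamma == 1.0 and pop0.structural.name == "flunixin_cortisol":
        pd_free.remove("gamma")  # Hill exponent fixed to 1 in this model
    all_params = pop0.structural.param_dict()
    subject_frozen = {}
    for subject in pd_dataset.subjects:
        if conditioning == "ebe" and subject in fit_pk.subject_params:
            subject_frozen[subject] = {
                n: v for n, v in fit_pk.subject_params[subject].items() if n in PK_PARAMS
            }
        else:
            subject_frozen[subject] = {
                n: fit_pk.theta.get(n, all_params[n]) for n in pk_free
            }
    fit_pd = fit(
        pd_dataset,
        pop0,
        streams=["pd"],
        free_theta=pd_free,
        fixed=fixed,
        subject_frozen=subject_frozen,
        **fit_kwargs,
    )
    return fit_pk, fit_pd


def information_criteria(fit_result: FitResult) -> tuple[float, float]:
    """(AIC, BIC) = (OFV + 2p, OFV + p ln N_obs) for a converged fit."""
    if not fit_result.converged:
        raise NonConvergenceError("information criteria require a converged fit")
    p = fit_result.n_params
    return fit_result.ofv + 2.0 * p, fit_result.ofv + p * np.log(max(fit_result.n_obs, 1))


def bootstrap(
    dataset: StudyDataset,
    pop0: PopulationModel,
    n_rep: int = 100,
    seed: int = 0,
    **fit_kwargs,
) -> BootstrapResult:
    """Subject-resampling bootstrap of the population fit.

    Subjects are resampled with replacement ``n_rep`` times; each replicate
    is refitted and the per-parameter median and 2.5-97.5 percentile interval
    over successful replicates is reported.  More than 50% replicate failures
    invalidates the bootstrap.
    """
    subjects = dataset.subjects
    if len(subjects) < 2:
        raise ValueError("bootstrap requires >= 2 subjects")
    rng = np.random.default_rng(seed)
    fit_kwargs.setdefault("compute_se", False)
    estimates = []
    n_failed = 0
    for _ in range(n_rep):
        chosen = rng.choice(subjects, size=len(subjects), replace=True)
        frames = []
        for new_id, subject in enumerate(chosen, start=1):
            sub = dataset.frame[dataset.frame["ID"] == subject].copy()
            sub["ID"] = new_id
            frames.append(sub)
        import pandas as pd

        resampled = StudyDataset(frame=pd.concat(frames, ignore_index=True))
        try:
            res = fit(resampled, pop0, **fit_kwargs)
            if not res.converged:
                raise RuntimeError(res.status)
            est = dict(res.theta)
            est.update({f"omega2_{k}": v for k, v in res.omega2.items()})
            est.update({f"sigma_{k}": v for k, v in res.sigma.items()})
            estimates.append(est)
        except Exception:
            n_failed += 1
    if n_failed > n_rep / 2:
        raise RuntimeError(
            f"bootstrap unreliable: {n_failed}/{n_rep} replicates failed to converge"
        )
    keys = estimates[0].keys()
    median = {}
    ci = {}
    for key in keys:
        vals = np.array([e[key] for e in estimates])
        median[key] = float(np.median(vals))
        ci[key] = (float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5)))
    return BootstrapResult(
        median=median, ci=ci, n_rep=n_rep, n_failed=n_failed, estimates=tuple(estimates)
    )


def vpc(
    fit_result: FitResult,
    dataset: StudyDataset,
    n_sim: int = 200,
    seed: int = 0,
    *,
    stream: Optional[str] = None,
) -> VpcResult:
    """Visual predictive check for one observation stream.

    Simulates ``n_sim`` replicate studies from the fitted population model at
    the observed design (same subjects' doses and sampling times, IIV and
    residual error on), computes the 5th/50th/95th percentile of each
    replicate per time bin, and summarises each percentile by its median and
    2.5-97.5 band over replicates, alongside the observed percentiles.
    """
    if not fit_result.converged:
        raise NonConvergenceError("VPC requires a converged fit")
    if stream is None:
        stream = fit_result.streams[0]
    obs = dataset.observations(stream)
    if obs.empty:
        raise ValueError(f"dataset has no {stream!r} observations")
    times = np.array(sorted(obs["TIME"].unique()))
    observed = np.stack(
        [
            np.array([np.percentile(obs[obs["TIME"] == t]["DV"], q) for t in times])
            for q in (5, 50, 95)
        ]
    )
    pop = fit_result.pop
    designs = [(subject, dataset.dose_of(subject)) for subject in dataset.subjects]
    rng = np.random.default_rng(seed)
    spec = pop.error[stream]
    qs = (5, 50, 95)
    sim_percentiles = np.empty((n_sim, 3, len(times)))
    from .population import sample_individuals
    from .simulate import simulate_individual

    for r in range(n_sim):
        values = []
        individuals = sample_individuals(pop, len(designs), rng)
        for (subject, dose), ind in zip(designs, individuals):
            model = ind.model.with_dose(dose)
            traj = simulate_individual(model, times=times, grid_step=FIT_GRID_STEP)
            values.append(apply_residual(traj.stream(stream), spec, rng))
        mat = np.stack(values)
        for qi, q in enumerate(qs):
            sim_percentiles[r, qi] = np.percentile(mat, q, axis=0)
    return VpcResult(
        stream=stream,
        times=times,
        observed=observed,
        predicted_median=np.median(sim_percentiles, axis=0),
        predicted_low=np.percentile(sim_percentiles, 2.5, axis=0),
        predicted_high=np.percentile(sim_percentiles, 97.5, axis=0),
    )
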