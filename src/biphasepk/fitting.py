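"""Identification of disposition (and oral absorption) parameters from plasma data.

Given an observed plasma concentration-time table and the dosing event that
produced it, :func:`fit_disposition` estimates CL, Vc and (for 2-3 compartment
candidates) the inter-compartment clearances and peripheral volumes by
minimizing the sum of squared log-concentration residuals

    SSE(theta) = sum_i (log C_obs(t_i) - log C_sim(t_i; theta))^2

with seeded multistart bounded least squares in log-parameter space.  Plasma
curves span orders of magnitude, so log residuals weight the terminal phase
on a par with the peak.  Observations below the LLOQ are excluded outright.

Hepatic extraction is not identifiable from oral data alone (only the product
``Fa * (1 - E_h)`` enters the curve), so ``eh`` is a fixed input here and must
come from i.v. data or literature.  :func:`select_model` fits every candidate
compartment count and picks the lowest small-sample-corrected AIC, breaking
near-ties (delta < 2) toward fewer compartments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .pbpk import (DoseEvent, ParameterizationError, PBPKParameters,
                   PlasmaProfile, disposition_concentrations)

__all__ = ["FitSpec", "FitResult", "FitError", "fit_disposition", "select_model"]

#: physiologic midpoints used to centre parameter bounds and starts
MIDPOINTS = {"cl": 5.0, "vc": 50.0, "q": 5.0, "v": 50.0, "k_ge": math.log(2) / 0.25}
#: default bounds are midpoint / BOUND_FACTOR .. midpoint * BOUND_FACTOR
BOUND_FACTOR = 1e3
#: SSE floor per observation (log-scale residual^2) used in AICc, so that
#: numerically-zero losses compare as ties rather than by floating noise
SSE_FLOOR_PER_OBS = 1e-12


class FitError(RuntimeError):
    """Raised when a fit is infeasible or no start converges."""


@dataclass(frozen=True)
class FitSpec:
    """Configuration of the identification run."""

    candidate_n_compartments: Sequence[int] = (1, 2)
    fit_k_ge: bool = False
    lloq: float = 0.0
    multistart: int = 8
    seed: int = 0
    bounds: Optional[Mapping[str, tuple]] = None

    def __post_init__(self) -> None:
        if len(self.candidate_n_compartments) == 0:
            raise FitError("at least one candidate compartment count required")
        if any(n not in (1, 2, 3) for n in self.candidate_n_compartments):
            raise FitError("candidates must be within {1, 2, 3}")
        if self.multistart < 1:
            raise FitError("multistart must be >= 1")
        if self.lloq < 0:
            raise FitError("lloq must be >= 0")


@dataclass(frozen=True)
class FitResult:
    """Best-run estimates with loss, AICc and asymptotic precision."""

    params: PBPKParameters
    n_compartments: int
    loss: float               # sum of squared log residuals
    aicc: float
    n_obs: int
    n_params: int
    estimates: Mapping[str, float]
    cv: Mapping[str, float]   # asymptotic CV (sd of log estimate)
    n_starts_converged: int
    message: str = ""


def _param_names(n_compartments: int, fit_k_ge: bool) -> list[str]:
    names = ["cl", "vc"]
    for i in range(1, n_compartments):
        names += [f"q{i}", f"v{i}"]
    if fit_k_ge:
        names.append("k_ge")
    return names


def _build_params(theta: np.ndarray, names: Sequence[str],
                  template: PBPKParameters) -> PBPKParameters:
    vals = dict(zip(names, np.exp(theta)))
    q, v = [], []
    for i in range(1, 4):
        if f"q{i}" in vals:
            q.append(vals[f"q{i}"])
            v.append(vals[f"v{i}"])
    gi = template.gi
    if "k_ge" in vals:
        gi = type(gi)(k_ge=vals["k_ge"], coupling=gi.coupling,
                      n_segments=gi.n_segments, t_si=gi.t_si,
                      radius_cm=gi.radius_cm, colon_absorption=gi.colon_absorption)
    return PBPKParameters(cl=vals["cl"], vc=vals["vc"], q=tuple(q), v=tuple(v),
                          eh=template.eh, fu=template.fu,
                          prodrug=template.prodrug, gi=gi)


def _midpoint(name: str) -> float:
    return MIDPOINTS[name.rstrip("123") if name[-1].isdigit() else name]


def fit_disposition(observed: PlasmaProfile, dosing: DoseEvent, spec: FitSpec,
                    n_compartments: Optional[int] = None,
                    eh: float = 0.0) -> FitResult:
    """Fit one disposition structure to an observed plasma profile.

    ``n_compartments`` defaults to the single entry of
    ``spec.candidate_n_compartments`` (use :func:`select_model` to compare
    several).  ``eh`` is held fixed.  Raises :class:`FitError` when the data
    cannot support the parameter count or no multistart run converges.
    """
    if n_compartments is None:
        if len(spec.candidate_n_compartments) != 1:
            raise FitError("several candidates: use select_model, or pass "
                           "n_compartments explicitly")
        n_compartments = spec.candidate_n_compartments[0]
    if dosing.route == "oral_cr":
        raise FitError("disposition fitting expects i.v. or oral-solution data")
    fit_k_ge = spec.fit_k_ge and dosing.route == "oral_solution"
    names = _param_names(n_compartments, fit_k_ge)
    k = len(names)

    mask = (observed.concentrations >= max(spec.lloq, 0.0)) & \
           (observed.concentrations > 0.0)
    t_obs = observed.times[mask]
    c_obs = observed.concentrations[mask]
    n = int(t_obs.size)
    if n < k + 2:
        raise FitError(f"{n} usable observations cannot identify {k} parameters "
                       f"(need at least {k + 2})")
    log_c_obs = np.log(c_obs)

    template = PBPKParameters(cl=1.0, vc=1.0, eh=eh,
                              q=(1.0,) * (n_compartments - 1),
                              v=(1.0,) * (n_compartments - 1))

    def residuals(theta: np.ndarray) -> np.ndarray:
        try:
            p = _build_params(theta, names, template)
            c_sim = disposition_concentrations(p, dosing, t_obs)
        except (ParameterizationError, np.linalg.LinAlgError):
            return np.full(n, 1e3)
        return np.log(np.clip(c_sim, 1e-30, None)) - log_c_obs

    user_bounds = spec.bounds or {}
    lo = np.empty(k)
    hi = np.empty(k)
    for j, name in enumerate(names):
        mid = _midpoint(name)
        b = user_bounds.get(name, (mid / BOUND_FACTOR, mid * BOUND_FACTOR))
        lo[j], hi[j] = math.log(b[0]), math.log(b[1])

    rng = np.random.default_rng(spec.seed)
    starts = [np.array([math.log(_midpoint(nm)) for nm in names])]
    for _ in range(spec.multistart - 1):
        starts.append(np.array([
            math.log(_midpoint(nm)) + rng.uniform(-1.5, 1.5) * math.log(10)
            for nm in names]))
    starts = [np.clip(s, lo, hi) for s in starts]

    best = None
    n_conv = 0
    for x0 in starts:
        try:
            sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if not sol.success and not np.isfinite(sol.cost):
            continue
        n_conv += 1
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitError("no multistart run converged")

    sse = float(2.0 * best.cost)
    sse_floored = max(sse, n * SSE_FLOOR_PER_OBS)
    if n - k - 1 > 0:
        aicc = n * math.log(sse_floored / n) + 2 * k \
            + 2 * k * (k + 1) / (n - k - 1)
    else:
        aicc = math.inf

    # asymptotic CVs of the log-parameters from the Gauss-Newton Hessian
    cv = {}
    try:
        J = best.jac
        dof = max(n - k, 1)
        cov = np.linalg.pinv(J.T @ J) * sse / dof
        sd = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        cv = {nm: float(s) for nm, s in zip(names, sd)}
    except np.linalg.LinAlgError:
        cv = {nm: math.nan for nm in names}

    params = _build_params(best.x, names, template)
    estimates = dict(zip(names, np.exp(best.x)))
    return FitResult(params=params, n_compartments=n_compartments, loss=sse,
                     aicc=aicc, n_obs=n, n_params=k,
                     estimates={nm: float(v) for nm, v in estimates.items()},
                     cv=cv, n_starts_converged=n_conv,
                     message=str(best.message))


def select_model(observed: PlasmaProfile, dosing: DoseEvent,
                 spec: FitSpec, eh: float = 0.0) -> FitResult:
    """Fit every candidate compartment count, return the lowest-AICc fit.

    Candidates whose AICc lies within 2 of the minimum are treated as ties
    and resolved toward fewer compartments (parsimony).
    """
    candidates = sorted(set(spec.candidate_n_compartments))
    results: list[FitResult] = []
    errors: list[str] = []
    for nc in candidates:
        try:
            results.append(fit_disposition(observed, dosing, spec,
                                           n_compartments=nc, eh=eh))
        except FitError as exc:
            errors.append(f"{nc}-compartment: {exc}")
    if not results:
        raise FitError("all candidates failed: " + "; ".join(errors))
    best_aicc = min(r.aicc for r in results)
    for r in results:  # ascending compartment order
        if r.aicc - best_aicc < 2.0:
            return r
    return min(results, key=lambda r: r.aicc)
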