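"""Structural parent-metabolite pharmacokinetic model.

Aripiprazole (ARI) disposition is described by a depot compartment with
first-order absorption feeding a one-compartment parent model, whose
elimination flux forms dehydroaripiprazole (DARI) in a tandem one-compartment
metabolite model::

    dA_dose/dt = -ka * A_dose * F
    dA_p/dt    =  ka * A_dose * F - (CL/Vd) * A_p
    dA_m/dt    =  Fm * kn * (CL/Vd) * A_p - (CLm/Vdm) * A_m

Amounts are in mg, volumes in L, times in h and concentrations in ng/ml
(= ug/L), so the amount-to-concentration step carries a single factor of
1000 ng/ml per mg/L.  ``F`` and ``Fm`` are fixed scale conventions (both 1):
all clearances and volumes are apparent (bioavailability-scaled) quantities.
``kn`` is the DARI/ARI molecular-mass ratio (0.995), converting the parent
mass flux into metabolite mass.

The primary evaluator is the closed-form superposition of single-dose
tri-exponential solutions; it falls back to numerical ODE integration when
two rate constants coincide within ``DEGENERACY_RTOL * ka`` (the closed form
then suffers catastrophic cancellation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.integrate import quad, solve_ivp
from scipy.optimize import minimize_scalar

__all__ = [
    "StructuralParams",
    "Regimen",
    "SteadyStateMetrics",
    "CovariateEffect",
    "CovariateModel",
    "individual_params",
    "concentration_profile",
    "ode_states",
    "steady_state_concentration",
    "steady_state_metrics",
    "ss_trough_arrays",
]

#: conversion from mg/L to ng/ml (1e6 ng/mg over 1e3 ml/L)
MG_L_TO_NG_ML = 1000.0

#: DARI/ARI molecular-mass ratio
DEFAULT_KN = 0.995

#: relative rate-constant separation below which the closed form is abandoned
DEGENERACY_RTOL = 1e-8

PARAM_NAMES = ("vd_f", "cl_f", "vdm_fm", "clm_fm")

PHENOTYPES = ("UM", "NM", "IM", "PM")


@dataclass(frozen=True)
class StructuralParams:
    """Per-individual apparent PK constants.

    ka : absorption rate constant (1/h)
    vd_f, cl_f : apparent parent volume (L) and clearance (L/h)
    vdm_fm, clm_fm : apparent metabolite volume (L) and clearance (L/h)
    kn : DARI/ARI molecular-mass ratio
    f, fm : bioavailability / conversion-fraction scale conventions, fixed 1
    """

    ka: float
    vd_f: float
    cl_f: float
    vdm_fm: float
    clm_fm: float
    kn: float = DEFAULT_KN
    f: float = 1.0
    fm: float = 1.0

    def __post_init__(self) -> None:
        for name in ("ka", "vd_f", "cl_f", "vdm_fm", "clm_fm", "kn"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def ke(self) -> float:
        """Parent elimination rate constant CL/Vd (1/h)."""
        return self.cl_f / self.vd_f

    @property
    def kem(self) -> float:
        """Metabolite elimination rate constant CLm/Vdm (1/h)."""
        return self.clm_fm / self.vdm_fm

    @property
    def degenerate(self) -> bool:
        """True when two rate constants coincide within tolerance."""
        tol = DEGENERACY_RTOL * self.ka
        return (
            abs(self.ka - self.ke) < tol
            or abs(self.ke - self.kem) < tol
            or abs(self.ka - self.kem) < tol
        )


@dataclass(frozen=True)
class Regimen:
    """Repeated oral dosing: `n_doses` administrations of `dose` mg every `tau` h."""

    dose: float
    tau: float = 24.0
    n_doses: int = 1
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError("dose must be non-negative")
        if not self.tau > 0:
            raise ValueError("tau must be positive")
        if self.n_doses < 1:
            raise ValueError("n_doses must be at least 1")

    @property
    def dose_times(self) -> np.ndarray:
        return self.start_time + self.tau * np.arange(self.n_doses)


@dataclass(frozen=True)
class SteadyStateMetrics:
    """Steady-state exposure metrics per analyte and their DARI/ARI ratios.

    AUCs in ng*h/ml, concentrations in ng/ml.  For a zero dose all metrics
    are 0 and the metabolic ratios are NaN (undefined, flagged rather than
    raised).
    """

    auc24_ari: float
    auc24_dari: float
    cmin_ari: float
    cmin_dari: float
    cmax_ari: float
    cmax_dari: float
    mr_auc: float
    mr_cmin: float
    mr_cmax: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.mr_auc)


# ---------------------------------------------------------------------------
# covariate model
# ---------------------------------------------------------------------------

class UnknownLevelError(KeyError):
    """A categorical covariate level without a configured coefficient."""


@dataclass(frozen=True)
class CovariateEffect:
    """One multiplicative covariate effect on a structural parameter.

    Forms
    -----
    power      : (cov / ref) ** coef                      (continuous)
    linear     : 1 + coef * (cov - ref), floored at 1e-6  (continuous)
    exp_cat    : exp(coef[level]); reference level has no entry (coef 0)
    maturation : cov**hill / (cov**hill + ref**hill) with coef = hill,
                 ref = value at half-maturation (continuous, e.g. age)
    """

    parameter: str
    covariate: str
    form: str
    coef: float | Mapping[str, float]
    ref: float = 0.0
    fixed: bool = False

    def __post_init__(self) -> None:
        if self.parameter not in PARAM_NAMES:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if self.form not in ("power", "linear", "exp_cat", "maturation"):
            raise ValueError(f"unknown covariate form {self.form!r}")

    def leaf_names(self) -> list[str]:
        base = f"{self.covariate}_{self.parameter}"
        if isinstance(self.coef, Mapping):
            return [f"{base}_{k}" for k in self.coef]
        return [base]

    def evaluate(self, value):
        if self.form == "power":
            return (np.asarray(value, dtype=float) / self.ref) ** float(self.coef)
        if self.form == "linear":
            out = 1.0 + float(self.coef) * (np.asarray(value, dtype=float) - self.ref)
            return np.maximum(out, 1e-6)
        if self.form == "maturation":
            v = np.asarray(value, dtype=float)
            h = float(self.coef)
            return v**h / (v**h + float(self.ref) ** h)
        # exp_cat
        levels = np.atleast_1d(np.asarray(value, dtype=object))
        coefs = np.empty(levels.shape, dtype=float)
        for i, lev in enumerate(levels.ravel()):
            lev = str(lev)
            if lev in self.coef:
                coefs.ravel()[i] = self.coef[lev]
            elif lev == self.ref:
                coefs.ravel()[i] = 0.0
            else:
                raise UnknownLevelError(
                    f"no coefficient configured for {self.covariate}={lev!r} "
                    f"on {self.parameter}"
                )
        out = np.exp(coefs)
        return out if out.size > 1 else float(out.ravel()[0])


@dataclass(frozen=True)
class CovariateModel:
    """Typical structural values plus multiplicative covariate effects.

    ``theta`` maps each structural parameter to its typical value at the
    reference covariates (weight ``ref`` inside each effect, 70 kg in the
    shipped model); ``effects`` multiply the typical values.
    """

    theta: Mapping[str, float]
    effects: tuple[CovariateEffect, ...] = ()
    ka: float = 1.06
    kn: float = DEFAULT_KN

    def __post_init__(self) -> None:
        for p in PARAM_NAMES:
            if p not in self.theta:
                raise ValueError(f"theta missing entry for {p!r}")
            if not self.theta[p] > 0:
                raise ValueError(f"theta[{p!r}] must be positive")

    def typical_values(self, covariates: Mapping[str, object]) -> dict[str, np.ndarray]:
        """Typical (eta = 0) parameter values for covariate value(s)."""
        out = {p: np.asarray(self.theta[p], dtype=float) for p in PARAM_NAMES}
        for eff in self.effects:
            if eff.covariate not in covariates:
                raise KeyError(f"covariate {eff.covariate!r} not supplied")
            out[eff.parameter] = out[eff.parameter] * eff.evaluate(
                covariates[eff.covariate]
            )
        return out

    def with_effect(self, effect: CovariateEffect) -> "CovariateModel":
        return replace(self, effects=self.effects + (effect,))

    def without_effect(self, index: int) -> "CovariateModel":
        effs = list(self.effects)
        del effs[index]
        return replace(self, effects=tuple(effs))


def individual_params(
    cov_model: CovariateModel,
    weight: float,
    phenotype: str,
    etas: Mapping[str, float] | None = None,
    **extra_covariates,
) -> StructuralParams:
    """Individual structural parameters from covariates and random effects.

    ``etas`` maps parameter names (e.g. ``"cl_f"``) to log-scale random
    effects entering as ``exp(eta)``; missing entries default to 0.  An
    unknown phenotype raises; a PM phenotype raises unless the covariate
    model carries an explicit PM coefficient.
    """
    if weight <= 0:
        raise ValueError("weight must be positive")
    if phenotype not in PHENOTYPES:
        raise ValueError(f"unknown CYP2D6 phenotype {phenotype!r}")
    etas = dict(etas or {})
    cov = {"WT": weight, "PHEN": phenotype, **extra_covariates}
    tv = cov_model.typical_values(cov)
    vals = {p: float(tv[p]) * math.exp(etas.get(p, 0.0)) for p in PARAM_NAMES}
    return StructuralParams(ka=cov_model.ka, kn=cov_model.kn, **vals)


# ---------------------------------------------------------------------------
# closed-form evaluator
# ---------------------------------------------------------------------------

def _accum(k, w, m, tau):
    """Sum of exp(-k*(w + j*tau)) for j = 0..m-1, numerically stable.

    ``w`` is the time since the most recent dose, ``m`` the number of doses
    administered so far (``np.inf`` gives the steady-state accumulation).
    """
    k = np.asarray(k, dtype=float)
    m = np.asarray(m, dtype=float)
    finite = np.isfinite(m)
    num = np.where(finite, -np.expm1(-k * tau * np.where(finite, m, 1.0)), 1.0)
    den = -np.expm1(-k * tau)
    return np.exp(-k * w) * num / den


def _conc_terms(dose, ka, ke, kem, vd, vdm, kn, f, fm, w, m, tau):
    """Parent and metabolite concentrations (ng/ml) by superposition.

    All arguments broadcast; ``m`` may be ``np.inf`` for steady state.
    """
    s_ke = _accum(ke, w, m, tau)
    s_ka = _accum(ka, w, m, tau)
    s_kem = _accum(kem, w, m, tau)
    a = dose * f * ka / (ka - ke)
    ap = a * (s_ke - s_ka)
    am = fm * kn * ke * a * ((s_ke - s_kem) / (kem - ke) - (s_ka - s_kem) / (kem - ka))
    return ap / vd * MG_L_TO_NG_ML, am / vdm * MG_L_TO_NG_ML


def _closed_form_profile(params: StructuralParams, regimen: Regimen, times: np.ndarray):
    t = np.asarray(times, dtype=float)
    rel = t - regimen.start_time
    dosed = rel >= 0
    # number of doses administered by each time point, time since last dose
    m = np.where(dosed, np.minimum(np.floor(rel / regimen.tau) + 1, regimen.n_doses), 1.0)
    w = np.where(dosed, rel - (m - 1) * regimen.tau, 0.0)
    cp, cm = _conc_terms(
        regimen.dose, params.ka, params.ke, params.kem, params.vd_f,
        params.vdm_fm, params.kn, params.f, params.fm, w, m, regimen.tau,
    )
    zero = ~dosed | (regimen.dose == 0)
    return np.where(zero, 0.0, cp), np.where(zero, 0.0, cm)


# ---------------------------------------------------------------------------
# ODE evaluator (oracle and degenerate-rate fallback)
# ---------------------------------------------------------------------------

def _ode_rhs(params: StructuralParams):
    ka, ke, kem = params.ka, params.ke, params.kem
    f, fm, kn = params.f, params.fm, params.kn

    def rhs(t, y):
        depot, ap, am, _ = y
        return [
            -ka * depot * f,
            ka * depot * f - ke * ap,
            fm * kn * ke * ap - kem * am,
            kem * am,  # cumulative metabolite elimination (mass-balance state)
        ]

    return rhs


def ode_states(
    params: StructuralParams,
    regimen: Regimen,
    times,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> np.ndarray:
    """Amount states [depot, parent, metabolite, eliminated] at `times` (ODE).

    Doses enter the depot compartment instantaneously at each dose time;
    integration proceeds piecewise between dose events.  Time points that
    coincide with a dose time are evaluated just after that dose (the depot
    jump is included; parent and metabolite are continuous either way).
    """
    t = np.atleast_1d(np.asarray(times, dtype=float))
    out = np.zeros((t.size, 4))
    rhs = _ode_rhs(params)
    dts = regimen.dose_times
    horizon = float(t.max(initial=dts[0]))
    eps = 1e-9
    y = np.zeros(4)
    for j in range(regimen.n_doses):
        a = float(dts[j])
        if a > horizon + eps:
            break
        b = float(dts[j + 1]) if j + 1 < regimen.n_doses else np.inf
        y[0] += regimen.dose
        out[np.abs(t - a) <= eps] = y
        inside = np.where((t > a + eps) & (t < b - eps))[0]
        pts = np.unique(t[inside])
        t_now = a
        if pts.size:
            sol = solve_ivp(rhs, (t_now, pts[-1]), y, t_eval=pts,
                            rtol=rtol, atol=atol, method="LSODA")
            for col, tp in enumerate(pts):
                out[inside[np.abs(t[inside] - tp) <= eps]] = sol.y[:, col]
            y = sol.y[:, -1].copy()
            t_now = float(pts[-1])
        if np.isfinite(b) and b <= horizon + regimen.tau and b > t_now:
            sol = solve_ivp(rhs, (t_now, b), y, rtol=rtol, atol=atol, method="LSODA")
            y = sol.y[:, -1].copy()
    return out


def _ode_profile(params: StructuralParams, regimen: Regimen, times, **kw):
    states = ode_states(params, regimen, times, **kw)
    cp = states[:, 1] / params.vd_f * MG_L_TO_NG_ML
    cm = states[:, 2] / params.vdm_fm * MG_L_TO_NG_ML
    return cp, cm


def concentration_profile(
    params: StructuralParams,
    regimen: Regimen,
    times,
    method: str = "auto",
):
    """ARI and DARI concentrations (ng/ml) at ``times`` under ``regimen``.

    ``method`` is "auto" (closed form, ODE fallback on rate-constant
    coincidence), "closed" or "ode".
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    if regimen.dose == 0:
        z = np.zeros_like(times)
        return z, z.copy()
    if method == "ode" or (method == "auto" and params.degenerate):
        return _ode_profile(params, regimen, times)
    if method not in ("auto", "closed"):
        raise ValueError(f"unknown method {method!r}")
    return _closed_form_profile(params, regimen, times)


# ---------------------------------------------------------------------------
# steady state
# ---------------------------------------------------------------------------

def steady_state_concentration(params: StructuralParams, dose: float, tau: float, w):
    """ARI and DARI concentrations at time-within-interval ``w`` at steady state.

    Analytic geometric accumulation of the exponential terms (infinite-dose
    superposition); ``w`` may be an array in [0, tau].
    """
    w = np.asarray(w, dtype=float)
    return _conc_terms(
        dose, params.ka, params.ke, params.kem, params.vd_f, params.vdm_fm,
        params.kn, params.f, params.fm, w, np.inf, tau,
    )


def ss_trough_arrays(cl_f, vd_f, clm_fm, vdm_fm, dose, tau=24.0, ka=1.06, kn=DEFAULT_KN, w=None):
    """Vectorised steady-state concentrations for parameter arrays.

    Returns (ARI, DARI) ng/ml at time ``w`` within the interval (default the
    pre-dose trough ``w = tau``).  Rate-constant coincidences are nudged by
    a relative 1e-8 instead of switching to the ODE path; the perturbation is
    below the evaluator's own tolerance.
    """
    cl_f = np.asarray(cl_f, dtype=float)
    vd_f = np.asarray(vd_f, dtype=float)
    ke = cl_f / vd_f
    kem = np.asarray(clm_fm, dtype=float) / np.asarray(vdm_fm, dtype=float)
    eps = DEGENERACY_RTOL * ka
    ke = np.where(np.abs(ka - ke) < eps, ke * (1 + 2 * DEGENERACY_RTOL) + eps, ke)
    kem = np.where(np.abs(kem - ke) < eps, kem * (1 + 2 * DEGENERACY_RTOL) + eps, kem)
    kem = np.where(np.abs(kem - ka) < eps, kem * (1 + 2 * DEGENERACY_RTOL) + eps, kem)
    if w is None:
        w = tau
    return _conc_terms(dose, ka, ke, kem, vd_f, vdm_fm, kn, 1.0, 1.0, w, np.inf, tau)


def steady_state_metrics(params: StructuralParams, regimen: Regimen) -> SteadyStateMetrics:
    """Steady-state AUC24, Cmin, Cmax per analyte plus DARI/ARI ratios.

    AUC by adaptive quadrature of the analytic steady-state profile over one
    interval (it reproduces the identities AUC_ARI = dose/CL and
    AUC_DARI = kn * dose / CLm); Cmax by bounded scalar maximisation; Cmin is
    the pre-dose trough at the interval end.  A zero dose yields all-zero
    metrics with NaN ratios.
    """
    tau = regimen.tau
    if regimen.dose == 0:
        nan = float("nan")
        return SteadyStateMetrics(0, 0, 0, 0, 0, 0, nan, nan, nan)

    def cp(w):
        return steady_state_concentration(params, regimen.dose, tau, w)[0]

    def cm(w):
        return steady_state_concentration(params, regimen.dose, tau, w)[1]

    auc_ari = quad(cp, 0, tau, epsabs=1e-10, epsrel=1e-10, limit=200)[0]
    auc_dari = quad(cm, 0, tau, epsabs=1e-10, epsrel=1e-10, limit=200)[0]
    res_p = minimize_scalar(lambda w: -cp(w), bounds=(0.0, tau), method="bounded",
                            options={"xatol": 1e-6})
    res_m = minimize_scalar(lambda w: -cm(w), bounds=(0.0, tau), method="bounded",
                            options={"xatol": 1e-6})
    cmax_ari = float(-res_p.fun)
    cmax_dari = float(-res_m.fun)
    cmin_ari = float(cp(tau))
    cmin_dari = float(cm(tau))
    return SteadyStateMetrics(
        auc24_ari=float(auc_ari),
        auc24_dari=float(auc_dari),
        cmin_ari=cmin_ari,
        cmin_dari=cmin_dari,
        cmax_ari=cmax_ari,
        cmax_dari=cmax_dari,
        mr_auc=float(auc_dari / auc_ari),
        mr_cmin=float(cmin_dari / cmin_ari),
        mr_cmax=float(cmax_dari / cmax_ari),
    )
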