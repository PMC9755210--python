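"""Stochastic population layer: variability specs, virtual cohorts and the
synthetic study generator.

Inter-individual variability is log-normal (``P_i = theta * exp(eta_i)``,
``eta_i ~ N(0, omega^2)``, independent across parameters — diagonal Omega);
residual error is proportional (``Y = IPRED * (1 + eps)``,
``eps ~ N(0, sigma^2)``) with ``eps`` truncated at -0.999 so observed
concentrations stay positive (the truncation probability at the shipped
sigma of ~0.35 is about 2e-3 of a standard deviation tail — negligible, and
counted when it happens).

The synthetic study generator emulates a sparse pediatric therapeutic-drug-
monitoring design: ~84 subjects on once-daily oral dosing, 1-5 serum samples
per subject drawn at random times at least 14 days after the start of
treatment (when the long parent half-life has reached steady state), both
analytes measured at each draw, and an optional 12-week tic-severity
(YGTSS) efficacy record whose response probability follows a logistic link
on the subject's true steady-state parent trough concentration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .data import StudyDataset
from .structural import CovariateModel, ss_trough_arrays

__all__ = [
    "OmegaSpec",
    "SigmaSpec",
    "PopulationModel",
    "CohortSpec",
    "EfficacyLink",
    "sample_etas",
    "apply_residual_error",
    "generate_virtual_cohort",
    "generate_synthetic_study",
]

logger = logging.getLogger(__name__)

#: truncation floor for the proportional residual deviate
RESIDUAL_FLOOR = -0.999


@dataclass(frozen=True)
class OmegaSpec:
    """Diagonal inter-individual log-scale variances omega^2 per parameter.

    Parameters without an entry (or with variance 0) carry no random effect.
    """

    omega2: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, v in self.omega2.items():
            if v < 0:
                raise ValueError(f"omega^2 for {name!r} must be non-negative")

    @property
    def names(self) -> tuple[str, ...]:
        """Parameters with a strictly positive random-effect variance."""
        return tuple(n for n, v in self.omega2.items() if v > 0)

    @property
    def variances(self) -> np.ndarray:
        return np.array([self.omega2[n] for n in self.names], dtype=float)


@dataclass(frozen=True)
class SigmaSpec:
    """Proportional residual SD (as a fraction) per analyte."""

    cv_ari: float
    cv_dari: float

    def __post_init__(self) -> None:
        for name in ("cv_ari", "cv_dari"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValueError(f"{name} must lie in [0, 1)")

    def cv(self, analyte: str) -> float:
        if analyte.upper() == "ARI":
            return self.cv_ari
        if analyte.upper() == "DARI":
            return self.cv_dari
        raise ValueError(f"unknown analyte {analyte!r}")


@dataclass(frozen=True)
class PopulationModel:
    """Full population model: typical values + covariates, Omega and sigma.

    ``fixed`` names leaves excluded from estimation (in addition to effects
    whose own ``fixed`` flag is set); the absorption rate constant is a fixed
    structural constant and is never estimated.
    """

    cov_model: CovariateModel
    omega: OmegaSpec
    sigma: SigmaSpec
    fixed: frozenset[str] = frozenset()

    def replace(self, **kw) -> "PopulationModel":
        return replace(self, **kw)


@dataclass(frozen=True)
class EfficacyLink:
    """Logistic response model on the log steady-state ARI trough.

    P(responder) = expit(slope * (log C_trough - log midpoint)); the response
    probability crosses 0.5 at ``midpoint_ng_ml``.
    """

    midpoint_ng_ml: float = 101.6
    slope: float = 4.0


@dataclass(frozen=True)
class CohortSpec:
    """Design of a virtual pediatric cohort on once-daily oral dosing.

    Weights and ages are truncated log-normals parameterised by median and
    log-scale spread; the dose policy assigns ``dose_per_kg`` mg/kg rounded
    to the ``dose_step`` grid and clipped to [dose_min, dose_max].  Sampling
    draws 1-5 occasions per subject on a uniform random day within
    ``sample_day_range`` with a uniform within-interval offset.
    """

    n_subjects: int = 84
    weight_median: float = 36.0
    weight_log_sd: float = 0.40
    weight_bounds: tuple[float, float] = (17.90, 100.00)
    age_median: float = 9.17
    age_log_sd: float = 0.28
    age_bounds: tuple[float, float] = (4.83, 17.33)
    p_male: float = 64 / 84
    phenotype_probs: Mapping[str, float] = field(
        default_factory=lambda: {"UM": 15 / 84, "NM": 34 / 84, "IM": 35 / 84, "PM": 0.0}
    )
    dose_per_kg: float = 0.15
    dose_step: float = 2.5
    dose_min: float = 2.5
    dose_max: float = 20.0
    tau: float = 24.0
    samples_probs: tuple[float, ...] = (0.60, 0.20, 0.10, 0.06, 0.04)
    sample_day_range: tuple[int, int] = (14, 30)
    treatment_days: int = 31
    lloq_ari: float = 10.0
    lloq_dari: float = 15.0
    efficacy_fraction: float = 56 / 84

    def __post_init__(self) -> None:
        total = float(sum(self.phenotype_probs.values()))
        if abs(total - 1.0) > 1e-6:
            raise ValueError("phenotype probabilities must sum to 1")
        if not any(p > 0 for p in self.phenotype_probs.values()):
            raise ValueError("phenotype support is empty")
        lo, hi = self.weight_bounds
        if not (0 < lo <= hi):
            raise ValueError("invalid weight bounds")
        if abs(sum(self.samples_probs) - 1.0) > 1e-6:
            raise ValueError("samples-per-subject probabilities must sum to 1")
        if self.sample_day_range[0] * 24 < 14 * 24:
            raise ValueError("sampling must start at or after 14 days of dosing")

    def dose_for_weight(self, weight):
        """Once-daily dose (mg) under the per-weight policy."""
        raw = self.dose_per_kg * np.asarray(weight, dtype=float)
        return np.clip(np.round(raw / self.dose_step) * self.dose_step,
                       self.dose_min, self.dose_max)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_etas(omega: OmegaSpec, n: int, seed=None) -> pd.DataFrame:
    """Independent N(0, omega^2) log-scale random effects for ``n`` subjects.

    Columns follow ``omega.names``; reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = _as_rng(seed)
    names = omega.names
    draws = rng.standard_normal((n, len(names))) * np.sqrt(omega.variances)
    return pd.DataFrame(draws, columns=[f"eta_{n_}" for n_ in names])


def apply_residual_error(conc, sigma: SigmaSpec, analyte: str, seed=None):
    """Observed concentration conc * (1 + eps) with proportional error.

    ``eps ~ N(0, cv^2)`` truncated below at -0.999; truncations are counted
    through the module logger.  Zero concentrations stay exactly zero.
    """
    rng = _as_rng(seed)
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    eps = rng.normal(0.0, sigma.cv(analyte), size=conc.shape)
    n_trunc = int(np.sum(eps < RESIDUAL_FLOOR))
    if n_trunc:
        logger.info("truncated %d residual deviates at %.3f", n_trunc, RESIDUAL_FLOOR)
    eps = np.maximum(eps, RESIDUAL_FLOOR)
    return conc * (1.0 + eps)


def _truncated_lognormal(rng, median, log_sd, bounds, size):
    lo, hi = bounds
    if lo == hi:
        return np.full(size, float(lo))
    out = np.empty(size, dtype=float)
    filled = 0
    while filled < size:
        draw = median * np.exp(rng.standard_normal(size) * log_sd)
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(ok.size, size - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return out


def generate_virtual_cohort(
    spec: CohortSpec,
    omega: OmegaSpec | None = None,
    seed=None,
) -> pd.DataFrame:
    """Virtual cohort of (weight, age, sex, phenotype[, etas]) rows.

    Weights and ages come from truncated log-normals, phenotypes from the
    spec's multinomial; when ``omega`` is given, per-subject random effects
    are appended as ``eta_*`` columns via :func:`sample_etas`.
    """
    rng = _as_rng(seed)
    n = spec.n_subjects
    weight = _truncated_lognormal(rng, spec.weight_median, spec.weight_log_sd,
                                  spec.weight_bounds, n)
    age = _truncated_lognormal(rng, spec.age_median, spec.age_log_sd,
                               spec.age_bounds, n)
    sex = np.where(rng.random(n) < spec.p_male, "M", "F")
    phens = list(spec.phenotype_probs)
    probs = np.array([spec.phenotype_probs[p] for p in phens], dtype=float)
    phenotype = rng.choice(phens, size=n, p=probs / probs.sum())
    cohort = pd.DataFrame(
        {"weight": weight, "age": age, "sex": sex, "phenotype": phenotype}
    )
    if omega is not None:
        etas = sample_etas(omega, n, rng)
        cohort = pd.concat([cohort, etas], axis=1)
    return cohort


#: diplotype composition of each phenotype in the reference cohort census,
#: used to attach plausible genotypes to simulated phenotypes
PHENOTYPE_GENOTYPES: Mapping[str, Mapping[str, int]] = {
    "UM": {"*1/*1": 1, "*1/*2": 6, "*39/*39": 8},
    "NM": {"*1/*10": 27, "*1/*41": 3, "*1/*14": 1, "*10/*34": 1,
           "*10/*35": 1, "*1/*33": 1},
    "IM": {"*10/*10": 30, "*10/*14": 3, "*10/*41": 2},
    "PM": {"*4/*4": 1},  # synthetic stand-in; the reference cohort had no PMs
}


def _sample_diplotypes(rng, phenotypes):
    out = []
    for ph in phenotypes:
        table = PHENOTYPE_GENOTYPES[str(ph)]
        names = list(table)
        p = np.array([table[g] for g in names], dtype=float)
        out.append(rng.choice(names, p=p / p.sum()))
    return np.array(out, dtype=object)


def generate_synthetic_study(
    spec: CohortSpec,
    truth: PopulationModel,
    efficacy_link: EfficacyLink | None = EfficacyLink(),
    seed=None,
) -> StudyDataset:
    """Full synthetic study dataset under a known generating model.

    Once-daily dosing for ``spec.treatment_days`` days, sparse dual-analyte
    sampling at >= 14 days, concentrations from the structural model with
    log-normal IIV and proportional residual error, observations below the
    assay quantitation limits dropped (and counted through the logger), and
    an efficacy record generated from the logistic link on each subject's
    *true* steady-state trough for a fraction of subjects.
    """
    ss = np.random.SeedSequence(seed)
    rng_cohort, rng_sampling, rng_resid, rng_eff = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    cohort = generate_virtual_cohort(spec, truth.omega, rng_cohort)
    n = spec.n_subjects
    doses = spec.dose_for_weight(cohort["weight"].to_numpy())
    diplo = _sample_diplotypes(rng_cohort, cohort["phenotype"])

    eta_names = truth.omega.names
    tv = truth.cov_model.typical_values(
        {"WT": cohort["weight"].to_numpy(),
         "AGE": cohort["age"].to_numpy(),
         "SEX": cohort["sex"].to_numpy(),
         "PHEN": cohort["phenotype"].to_numpy()}
    )
    # typical values are scalar when no covariate effect touches a parameter
    indiv = {p: np.broadcast_to(np.asarray(tv[p], dtype=float), (n,)).copy()
             for p in tv}
    for name in eta_names:
        indiv[name] = indiv[name] * np.exp(cohort[f"eta_{name}"].to_numpy())

    n_samples = rng_sampling.choice(
        np.arange(1, len(spec.samples_probs) + 1), size=n, p=spec.samples_probs
    )
    ka, kn = truth.cov_model.ka, truth.cov_model.kn
    tau = spec.tau
    day_lo, day_hi = spec.sample_day_range

    ids = np.arange(1, n + 1)
    event_rows = []
    n_lloq = 0
    for i in range(n):
        sid = ids[i]
        for d in range(spec.treatment_days):
            event_rows.append((sid, d * tau, 1, doses[i], np.nan, 0))
        days = rng_sampling.integers(day_lo, day_hi + 1, size=n_samples[i])
        offsets = rng_sampling.uniform(0.0, tau, size=n_samples[i])
        times = np.sort(days * tau + offsets)
        m = np.minimum(np.floor(times / tau) + 1, spec.treatment_days)
        w = times - (m - 1) * tau
        from .structural import _conc_terms  # closed-form multi-dose evaluator

        cp, cm = _conc_terms(
            doses[i], ka, indiv["cl_f"][i] / indiv["vd_f"][i],
            indiv["clm_fm"][i] / indiv["vdm_fm"][i], indiv["vd_f"][i],
            indiv["vdm_fm"][i], kn, 1.0, 1.0, w, m, tau,
        )
        obs_ari = apply_residual_error(cp, truth.sigma, "ARI", rng_resid)
        obs_dari = apply_residual_error(cm, truth.sigma, "DARI", rng_resid)
        for t, oa, od in zip(times, obs_ari, obs_dari):
            if oa >= spec.lloq_ari:
                event_rows.append((sid, t, 0, np.nan, oa, 1))
            else:
                n_lloq += 1
            if od >= spec.lloq_dari:
                event_rows.append((sid, t, 0, np.nan, od, 2))
            else:
                n_lloq += 1
    if n_lloq:
        logger.info("dropped %d observations below the quantitation limits", n_lloq)

    events = pd.DataFrame(
        event_rows, columns=["id", "time", "evid", "amt", "dv", "dvid"]
    ).sort_values(["id", "time", "evid"], kind="stable").reset_index(drop=True)

    subjects = pd.DataFrame(
        {
            "id": ids,
            "WT": cohort["weight"].to_numpy(),
            "AGE": cohort["age"].to_numpy(),
            "SEX": cohort["sex"].to_numpy(),
            "PHEN": cohort["phenotype"].to_numpy(),
            "DIPLO": diplo,
        }
    )

    if efficacy_link is not None:
        trough_ari, trough_dari = ss_trough_arrays(
            indiv["cl_f"], indiv["vd_f"], indiv["clm_fm"], indiv["vdm_fm"],
            doses, tau=tau, ka=ka, kn=kn,
        )
        logit = efficacy_link.slope * (
            np.log(trough_ari) - np.log(efficacy_link.midpoint_ng_ml)
        )
        p_resp = 1.0 / (1.0 + np.exp(-logit))
        responder = rng_eff.random(n) < p_resp
        has_eff = rng_eff.random(n) < spec.efficacy_fraction
        baseline = rng_eff.integers(25, 51, size=n).astype(float)
        rate = np.where(
            responder,
            rng_eff.uniform(0.52, 0.85, size=n),
            rng_eff.uniform(0.05, 0.48, size=n),
        )
        week12 = np.round(baseline * (1.0 - rate))
        # keep the strict >50% responder rule intact after rounding
        crossed = ((baseline - week12) / baseline > 0.5) != responder
        week12 = np.where(crossed & responder, week12 - 1, week12)
        week12 = np.where(crossed & ~responder, week12 + 1, week12)
        week12 = np.clip(week12, 0, None)
        subjects["YGTSS_BL"] = np.where(has_eff, baseline, np.nan)
        subjects["YGTSS_W12"] = np.where(has_eff, week12, np.nan)

    dataset = StudyDataset(subjects=subjects, events=events)
    dataset.validate()
    return dataset
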