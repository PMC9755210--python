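"""Stepwise covariate model building on the FOCE-ELS objective.

Forward selection adds, one candidate per round, the covariate effect with
the largest drop in objective function value, provided the drop strictly
exceeds 3.84 (chi-square, p < 0.05, df = 1).  Backward elimination then
removes any retained effect whose deletion raises the objective by strictly
less than 6.64 (p < 0.01, df = 1), one at a time starting from the weakest,
until every survivor is significant at the stricter level.

Continuous covariates enter as powers of (cov / median); categorical ones as
``exp(theta_cov)`` per non-reference level.  The registry of candidate
developmental models for body weight (fixed-exponent allometry, estimated
power, linear, age power, weight-power-times-age-maturation) is exposed for
model comparison by information criteria.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .data import StudyDataset
from .model import PopPKModel, PopPKResults
from .population import PopulationModel
from .structural import CovariateEffect

__all__ = [
    "Candidate",
    "StepRecord",
    "CovariateSearchResult",
    "stepwise_search",
    "default_candidates",
    "developmental_weight_models",
    "compare_developmental_models",
]

logger = logging.getLogger(__name__)

FORWARD_THRESHOLD = 3.84
BACKWARD_THRESHOLD = 6.64


@dataclass(frozen=True)
class Candidate:
    """A named covariate-effect candidate for the stepwise search."""

    name: str
    effect: CovariateEffect

    @property
    def n_coefs(self) -> int:
        coef = self.effect.coef
        return len(coef) if isinstance(coef, dict) else 1


@dataclass(frozen=True)
class StepRecord:
    phase: str          # 'forward' | 'backward'
    candidate: str
    delta_ofv: float
    action: str         # 'included' | 'rejected' | 'removed' | 'retained' | 'skipped'
    ofv: float


@dataclass
class CovariateSearchResult:
    """Outcome of the forward/backward covariate search."""

    retained: tuple[Candidate, ...]
    final: PopulationModel
    final_fit: PopPKResults
    steps: list[StepRecord] = field(default_factory=list)

    @property
    def retained_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.retained)

    def step_table(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.steps])


def default_candidates(dataset: StudyDataset) -> list[Candidate]:
    """Candidate registry: weight/age powers and sex on CL and Vd, genotype
    on CL.  Continuous references are the cohort medians; user-extensible by
    appending further :class:`Candidate` objects."""
    subs = dataset.subjects
    wt_med = float(subs["WT"].median())
    cands = [
        Candidate("WT_on_CL", CovariateEffect("cl_f", "WT", "power", 0.0, ref=wt_med)),
        Candidate("WT_on_Vd", CovariateEffect("vd_f", "WT", "power", 0.0, ref=wt_med)),
        Candidate("GENO_on_CL", CovariateEffect("cl_f", "PHEN", "exp_cat",
                                                {"IM": 0.0, "UM": 0.0}, ref="NM")),
    ]
    if "AGE" in subs:
        age_med = float(subs["AGE"].median())
        cands.append(Candidate("AGE_on_CL",
                               CovariateEffect("cl_f", "AGE", "power", 0.0, ref=age_med)))
    if "SEX" in subs:
        cands.append(Candidate("SEX_on_CL",
                               CovariateEffect("cl_f", "SEX", "exp_cat",
                                               {"F": 0.0}, ref="M")))
    return cands


def _default_fitter(dataset: StudyDataset, pop: PopulationModel, **fit_kwargs):
    return PopPKModel(dataset, pop).fit(compute_rse=False, **fit_kwargs)


def stepwise_search(
    dataset: StudyDataset,
    base: PopulationModel,
    candidates: Sequence[Candidate] | None = None,
    forward_threshold: float = FORWARD_THRESHOLD,
    backward_threshold: float = BACKWARD_THRESHOLD,
    fitter: Callable | None = None,
    **fit_kwargs,
) -> CovariateSearchResult:
    """Greedy forward inclusion / backward elimination of covariate effects.

    ``fitter(dataset, pop)`` must return an object with ``.ofv`` and
    ``.params``; the default fits with :class:`PopPKModel` (RSEs off).
    Candidates whose fit fails are skipped and logged.
    """
    if candidates is None:
        candidates = default_candidates(dataset)
    fitter = fitter or (lambda ds, pop: _default_fitter(ds, pop, **fit_kwargs))
    steps: list[StepRecord] = []

    current_fit = fitter(dataset, base)
    current = current_fit.params
    remaining = list(candidates)
    included: list[Candidate] = []

    while remaining:
        trials = []
        for cand in remaining:
            pop_c = current.replace(cov_model=current.cov_model.with_effect(cand.effect))
            try:
                fit_c = fitter(dataset, pop_c)
            except Exception as exc:
                logger.warning("candidate %s skipped (fit failed: %s)", cand.name, exc)
                steps.append(StepRecord("forward", cand.name, np.nan, "skipped", np.nan))
                continue
            delta = current_fit.ofv - fit_c.ofv
            trials.append((cand, fit_c, delta))
        if not trials:
            break
        # largest delta wins; ties by fewer added coefficients, then input order
        order = sorted(
            range(len(trials)),
            key=lambda i: (-round(trials[i][2], 9), trials[i][0].n_coefs, i),
        )
        best_cand, best_fit, best_delta = trials[order[0]]
        for i, (cand, _, delta) in enumerate(trials):
            if cand is not best_cand:
                steps.append(StepRecord("forward", cand.name, delta, "rejected",
                                        trials[i][1].ofv))
        if best_delta > forward_threshold:
            steps.append(StepRecord("forward", best_cand.name, best_delta,
                                    "included", best_fit.ofv))
            included.append(best_cand)
            remaining = [c for c in remaining if c is not best_cand]
            current_fit = best_fit
            current = best_fit.params
        else:
            steps.append(StepRecord("forward", best_cand.name, best_delta,
                                    "rejected", best_fit.ofv))
            break

    # backward elimination: effects were appended in inclusion order at the
    # end of the base model's effect tuple
    n_base_effects = len(base.cov_model.effects)
    while included:
        increases = []
        for pos, cand in enumerate(included):
            idx = n_base_effects + pos
            pop_r = current.replace(cov_model=current.cov_model.without_effect(idx))
            try:
                fit_r = fitter(dataset, pop_r)
            except Exception as exc:
                logger.warning("backward refit without %s failed: %s", cand.name, exc)
                continue
            increases.append((pos, cand, fit_r, fit_r.ofv - current_fit.ofv))
        if not increases:
            break
        pos, cand, fit_r, inc = min(increases, key=lambda t: t[3])
        if inc < backward_threshold:
            steps.append(StepRecord("backward", cand.name, inc, "removed", fit_r.ofv))
            included.pop(pos)
            current_fit = fit_r
            current = fit_r.params
        else:
            for pos2, cand2, _, inc2 in increases:
                steps.append(StepRecord("backward", cand2.name, inc2, "retained",
                                        current_fit.ofv))
            break

    return CovariateSearchResult(
        retained=tuple(included),
        final=current,
        final_fit=current_fit,
        steps=steps,
    )


def developmental_weight_models(
    wt_ref: float = 70.0, age_ref: float = 9.17
) -> dict[str, tuple[CovariateEffect, ...]]:
    """The candidate developmental models for the weight effect on clearance.

    Each entry is a tuple of effects to add to the covariate-free base model;
    all five keep a unit weight exponent on the parent volume.
    """
    vd_wt = CovariateEffect("vd_f", "WT", "power", 1.0, ref=wt_ref, fixed=True)
    return {
        "fixed_allometric": (vd_wt, CovariateEffect("cl_f", "WT", "power", 0.75,
                                                    ref=wt_ref, fixed=True)),
        "estimated_power": (vd_wt, CovariateEffect("cl_f", "WT", "power", 0.75,
                                                   ref=wt_ref)),
        "linear_weight": (vd_wt, CovariateEffect("cl_f", "WT", "linear", 0.01,
                                                 ref=wt_ref)),
        "age_power": (vd_wt, CovariateEffect("cl_f", "AGE", "power", 0.5,
                                             ref=age_ref)),
        "maturation": (
            vd_wt,
            CovariateEffect("cl_f", "WT", "power", 0.75, ref=wt_ref, fixed=True),
            CovariateEffect("cl_f", "AGE", "maturation", 2.0, ref=1.0),
        ),
    }


def compare_developmental_models(
    dataset: StudyDataset,
    base: PopulationModel,
    models: dict[str, tuple[CovariateEffect, ...]] | None = None,
    fitter: Callable | None = None,
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit each developmental model and rank by OFV / AIC / BIC."""
    models = models or developmental_weight_models()
    fitter = fitter or (lambda ds, pop: _default_fitter(ds, pop, **fit_kwargs))
    rows = []
    for name, effects in models.items():
        pop = base
        for eff in effects:
            pop = pop.replace(cov_model=pop.cov_model.with_effect(eff))
        try:
            fit = fitter(dataset, pop)
        except Exception as exc:
            logger.warning("developmental model %s failed: %s", name, exc)
            continue
        rows.append({"model": name, "ofv": fit.ofv, "aic": fit.aic,
                     "bic": fit.bic, "n_params": fit.n_params})
    return pd.DataFrame(rows).sort_values("bic").reset_index(drop=True)
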