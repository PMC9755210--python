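"""Run configuration: YAML round-tripping of the model, cohort and scenario
settings, with the reference parameter set embedded as the default.

Every pipeline run resolves its configuration against the defaults, writes
the resolved copy next to its outputs and stamps artifacts with the SHA-256
hash of the canonical YAML, so two runs with equal hashes and seeds are
byte-identical.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict
from typing import Mapping

import yaml

from .population import CohortSpec, EfficacyLink, OmegaSpec, PopulationModel, SigmaSpec
from .simulate import PtaCriterion, default_pta_criteria
from .structural import CovariateEffect, CovariateModel

__all__ = [
    "default_config",
    "load_config",
    "resolve_config",
    "config_hash",
    "model_from_config",
    "cohort_from_config",
    "criteria_from_config",
    "efficacy_link_from_config",
    "dump_config",
]


def _effect_to_dict(eff: CovariateEffect) -> dict:
    d = {"parameter": eff.parameter, "covariate": eff.covariate,
         "form": eff.form, "ref": eff.ref, "fixed": eff.fixed}
    d["coef"] = dict(eff.coef) if isinstance(eff.coef, Mapping) else float(eff.coef)
    return d


def model_to_config(pop: PopulationModel) -> dict:
    return {
        "theta": {k: float(v) for k, v in pop.cov_model.theta.items()},
        "effects": [_effect_to_dict(e) for e in pop.cov_model.effects],
        "ka": float(pop.cov_model.ka),
        "kn": float(pop.cov_model.kn),
        "omega2": {k: float(v) for k, v in pop.omega.omega2.items()},
        "sigma": {"cv_ari": float(pop.sigma.cv_ari),
                  "cv_dari": float(pop.sigma.cv_dari)},
        "fixed": sorted(pop.fixed),
    }


def model_from_config(cfg: Mapping) -> PopulationModel:
    block = cfg["model"] if "model" in cfg else cfg
    effects = tuple(
        CovariateEffect(
            parameter=e["parameter"], covariate=e["covariate"], form=e["form"],
            coef=e["coef"], ref=e.get("ref", 0.0), fixed=bool(e.get("fixed", False)),
        )
        for e in block.get("effects", [])
    )
    cov = CovariateModel(theta=dict(block["theta"]), effects=effects,
                         ka=float(block.get("ka", 1.06)),
                         kn=float(block.get("kn", 0.995)))
    return PopulationModel(
        cov_model=cov,
        omega=OmegaSpec(dict(block.get("omega2", {}))),
        sigma=SigmaSpec(**block.get("sigma", {"cv_ari": 0.3545, "cv_dari": 0.3537})),
        fixed=frozenset(block.get("fixed", ())),
    )


def cohort_from_config(cfg: Mapping) -> CohortSpec:
    block = dict(cfg.get("cohort", {}))
    for key in ("weight_bounds", "age_bounds", "sample_day_range", "samples_probs"):
        if key in block:
            block[key] = tuple(block[key])
    return CohortSpec(**block)


def criteria_from_config(cfg: Mapping) -> tuple[PtaCriterion, ...]:
    block = cfg.get("pta", {}).get("criteria")
    if not block:
        return default_pta_criteria()
    return tuple(PtaCriterion(**c) for c in block)


def efficacy_link_from_config(cfg: Mapping) -> EfficacyLink:
    return EfficacyLink(**cfg.get("efficacy_link", {}))


def default_config() -> dict:
    """Full default configuration with the reference model embedded."""
    from .reference import RECOMMENDED_DOSES, REFERENCE_WEIGHTS, reference_model

    return {
        "model": model_to_config(reference_model()),
        "cohort": asdict(CohortSpec()),
        "efficacy_link": asdict(EfficacyLink()),
        "pta": {
            "criteria": [
                {"analyte": c.analyte, "threshold": c.threshold,
                 "kind": c.kind, "prob": c.prob}
                for c in default_pta_criteria()
            ],
            "n_sim": 1000,
        },
        "scenarios": {
            "weights": list(REFERENCE_WEIGHTS),
            "phenotypes": ["IM", "NM", "UM"],
            "dose_grid": [2.5 * i for i in range(1, 9)],
            "reference_doses": {ph: {float(w): d for w, d in row.items()}
                                for ph, row in RECOMMENDED_DOSES.items()},
        },
        "estimation": {"maxiter": 200, "ftol": 1.0e-9, "compute_rse": True},
    }


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for key, val in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(val, Mapping):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path=None) -> dict:
    """Defaults deep-merged with an optional user YAML file."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _deep_merge(cfg, user)
    return cfg


resolve_config = load_config


def dump_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True, default_flow_style=False)


def config_hash(cfg: Mapping) -> str:
    """SHA-256 of the canonical (key-sorted) YAML serialisation."""
    text = yaml.safe_dump(_plain(cfg), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()


def _plain(obj):
    if isinstance(obj, Mapping):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, float):
        return float(obj)
    return obj
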