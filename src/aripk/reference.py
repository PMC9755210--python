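"""Reference pediatric model and cohort constants shipped with the package.

The reference parameter set is the final combined parent-metabolite model
estimated in a prospective cohort of 84 Chinese children with tic disorders
on once-daily oral aripiprazole (sparse therapeutic-drug-monitoring design,
143 serum concentrations).  Apparent clearances and volumes scale
allometrically with body weight around a 70 kg reference; CYP2D6 phenotype
enters the parent clearance as an additive log-scale shift (NM reference,
IM -0.23, UM +0.21 — a 20.55% decrease and a 23.37% increase respectively).

Note on the variability scale: the inter-individual variances below are the
log-scale omega^2 values 0.7999 (Vd/F), 0.1207 (CL/F) and 0.1531 (CLm/Fm),
i.e. roughly 35% CV for the clearances — the same percent scale on which the
proportional residual SDs (35.45% / 35.37%) are quoted.
"""

from __future__ import annotations

from types import MappingProxyType

from .population import OmegaSpec, PopulationModel, SigmaSpec
from .structural import CovariateEffect, CovariateModel

__all__ = [
    "reference_model",
    "base_model",
    "OBSERVED_GENOTYPE_COUNTS",
    "RECOMMENDED_DOSES",
    "REFERENCE_WEIGHTS",
]

#: CYP2D6 diplotype counts observed in the reference cohort (n = 84)
OBSERVED_GENOTYPE_COUNTS = MappingProxyType({
    "*1/*1": 1,
    "*1/*2": 6,
    "*39/*39": 8,
    "*1/*10": 27,
    "*1/*41": 3,
    "*1/*14": 1,
    "*10/*34": 1,
    "*10/*35": 1,
    "*1/*33": 1,
    "*10/*10": 30,
    "*10/*14": 3,
    "*10/*41": 2,
})

#: weight grid (kg) used for the recommended-regimen table
REFERENCE_WEIGHTS = (20.0, 40.0, 60.0, 80.0, 100.0)

#: recommended once-daily doses (mg) per phenotype and weight under the
#: reference model and the trough-concentration targets
RECOMMENDED_DOSES = MappingProxyType({
    "NM": MappingProxyType({20.0: 7.5, 40.0: 10.0, 60.0: 12.5, 80.0: 15.0, 100.0: 17.5}),
    "IM": MappingProxyType({20.0: 5.0, 40.0: 7.5, 60.0: 10.0, 80.0: 12.5, 100.0: 12.5}),
    "UM": MappingProxyType({20.0: 10.0, 40.0: 12.5, 60.0: 17.5, 80.0: 20.0, 100.0: 20.0}),
})


def reference_model() -> PopulationModel:
    """The final covariate model with the shipped reference estimates.

    Fixed (never estimated): ka = 1.06 1/h, the unit allometric exponents on
    the volumes, the 0.75 exponent on metabolite clearance, and the NM
    reference genotype coefficient.  Estimated leaves: the four structural
    typical values, the weight exponent on parent clearance, the IM/UM
    genotype shifts, three omega^2 entries and two proportional sigmas.
    """
    cov = CovariateModel(
        theta={"vd_f": 219.91, "cl_f": 3.06, "vdm_fm": 423.78, "clm_fm": 8.86},
        effects=(
            CovariateEffect("vd_f", "WT", "power", 1.0, ref=70.0, fixed=True),
            CovariateEffect("cl_f", "WT", "power", 0.64, ref=70.0),
            CovariateEffect("vdm_fm", "WT", "power", 1.0, ref=70.0, fixed=True),
            CovariateEffect("clm_fm", "WT", "power", 0.75, ref=70.0, fixed=True),
            CovariateEffect("cl_f", "PHEN", "exp_cat", {"IM": -0.23, "UM": 0.21},
                            ref="NM"),
        ),
        ka=1.06,
        kn=0.995,
    )
    omega = OmegaSpec({"vd_f": 0.7999, "cl_f": 0.1207, "clm_fm": 0.1531})
    sigma = SigmaSpec(cv_ari=0.3545, cv_dari=0.3537)
    return PopulationModel(cov_model=cov, omega=omega, sigma=sigma)


def base_model() -> PopulationModel:
    """Covariate-free base model (typical values only, same variability).

    The starting point for covariate search: no weight or genotype effects.
    """
    cov = CovariateModel(
        theta={"vd_f": 219.91, "cl_f": 3.06, "vdm_fm": 423.78, "clm_fm": 8.86},
        effects=(),
        ka=1.06,
        kn=0.995,
    )
    omega = OmegaSpec({"vd_f": 0.7999, "cl_f": 0.1207, "clm_fm": 0.1531})
    sigma = SigmaSpec(cv_ari=0.3545, cv_dari=0.3537)
    return PopulationModel(cov_model=cov, omega=omega, sigma=sigma)
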