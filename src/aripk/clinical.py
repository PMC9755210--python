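"""Pharmacogenetic classification, efficacy scoring and exposure-response ROC.

CYP2D6 diplotypes are mapped to metaboliser phenotypes from the function
class of the two alleles:

* UM (ultra-rapid): two normal-function alleles (e.g. ``*1/*1``, ``*1/*2``);
* NM (normal): exactly one normal-function allele (e.g. ``*1/*10``);
* IM (intermediate): one decreased- plus one no-function allele, or two
  decreased-function alleles (e.g. ``*10/*10``, ``*3/*10``);
* PM (poor): two no-function alleles (e.g. ``*3/*3``).

This rule intentionally counts functional alleles rather than using CPIC
activity scores; the normal/decreased/no-function assignment of each allele
is configurable through :class:`AlleleFunctionTable`.  ``*14`` is classed
no-function by default (its subtypes differ in the literature; either
decreased or none yields the same IM assignment under the rule above) and
``*34``/``*35`` are classed normal-function.

Efficacy on the Yale Global Tic Severity Scale (YGTSS) is summarised as the
percentage reduction of the total score after 12 weeks of treatment; a
patient is a responder when the reduction strictly exceeds 50%.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

__all__ = [
    "AlleleFunctionTable",
    "DEFAULT_ALLELE_FUNCTIONS",
    "classify_cyp2d6",
    "phenotype_census",
    "EfficacyRecord",
    "ygtss_reduction",
    "RocReport",
    "roc_analysis",
    "mr_phenotype_discrimination",
    "bsa_mosteller",
    "egfr_schwartz",
]

_FUNCTION_CLASSES = ("normal", "decreased", "none")

#: default allele function classes covering the alleles observed in the
#: reference pediatric cohort
DEFAULT_ALLELE_FUNCTIONS: Mapping[str, str] = {
    "*1": "normal",
    "*2": "normal",
    "*34": "normal",
    "*35": "normal",
    "*39": "normal",
    # *33 is normal-function in CPIC, but the reference cohort's census lists
    # *1/*33 among the NM (single-functional-allele) diplotypes, so the
    # shipped table classes it decreased-function; override via
    # AlleleFunctionTable if desired
    "*33": "decreased",
    "*10": "decreased",
    "*41": "decreased",
    "*3": "none",
    "*4": "none",
    "*5": "none",
    "*6": "none",
    "*14": "none",
}


@dataclass(frozen=True)
class AlleleFunctionTable:
    """Map from CYP2D6 star-allele name to function class."""

    functions: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_ALLELE_FUNCTIONS)
    )

    def __post_init__(self) -> None:
        for allele, cls in self.functions.items():
            if cls not in _FUNCTION_CLASSES:
                raise ValueError(
                    f"function class for {allele} must be one of {_FUNCTION_CLASSES}"
                )

    def function_of(self, allele: str) -> str:
        try:
            return self.functions[allele]
        except KeyError:
            raise KeyError(f"unknown CYP2D6 allele {allele!r}") from None


def _parse_diplotype(diplotype) -> tuple[str, str]:
    if isinstance(diplotype, (tuple, list)):
        a, b = diplotype
        return str(a), str(b)
    s = str(diplotype)
    alleles = re.findall(r"\*\w+", s)
    if len(alleles) != 2:
        raise ValueError(f"cannot parse diplotype {diplotype!r}")
    return alleles[0], alleles[1]


def classify_cyp2d6(diplotype, table: AlleleFunctionTable | None = None) -> str:
    """CYP2D6 metaboliser phenotype (UM/NM/IM/PM) of a two-allele diplotype.

    ``diplotype`` may be a string (``"*1/*10"`` or ``"*1*10"``) or a pair of
    allele names.  Symmetric in allele order; unknown alleles raise KeyError.
    """
    table = table or AlleleFunctionTable()
    a1, a2 = _parse_diplotype(diplotype)
    funcs = sorted((table.function_of(a1), table.function_of(a2)))
    n_normal = funcs.count("normal")
    if n_normal == 2:
        return "UM"
    if n_normal == 1:
        return "NM"
    if funcs == ["decreased", "decreased"] or funcs == ["decreased", "none"]:
        return "IM"
    return "PM"


def phenotype_census(
    genotype_counts: Mapping[str, int],
    table: AlleleFunctionTable | None = None,
) -> pd.DataFrame:
    """Aggregate diplotype counts into phenotype counts and percentages.

    Returns a frame indexed by phenotype (UM, NM, IM, PM) with columns
    ``n`` and ``percent``; percentages are of the total subject count and
    sum to 100 up to rounding of the individual entries.
    """
    counts = {"UM": 0, "NM": 0, "IM": 0, "PM": 0}
    for genotype, n in genotype_counts.items():
        if n < 0:
            raise ValueError(f"negative count for {genotype!r}")
        counts[classify_cyp2d6(genotype, table)] += int(n)
    total = sum(counts.values())
    pct = {k: (100.0 * v / total if total else 0.0) for k, v in counts.items()}
    return pd.DataFrame(
        {"n": pd.Series(counts), "percent": pd.Series(pct)},
        index=["UM", "NM", "IM", "PM"],
    )


# ---------------------------------------------------------------------------
# efficacy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EfficacyRecord:
    """YGTSS totals before and after 12 weeks with the derived response.

    ``reduction_rate`` is (baseline - week12) / baseline * 100; the patient
    is a responder when the rate strictly exceeds 50% (an exactly-50%
    reduction is a non-responder).
    """

    ygtss_baseline: float
    ygtss_week12: float
    reduction_rate: float
    responder: bool


def ygtss_reduction(baseline: float, week12: float) -> EfficacyRecord:
    """YGTSS percentage reduction and responder status after treatment."""
    if baseline <= 0:
        raise ValueError("baseline YGTSS total must be positive")
    if week12 < 0:
        raise ValueError("week-12 YGTSS total must be non-negative")
    rate = (baseline - week12) / baseline * 100.0
    return EfficacyRecord(
        ygtss_baseline=float(baseline),
        ygtss_week12=float(week12),
        reduction_rate=float(rate),
        responder=bool(rate > 50.0),
    )


# ---------------------------------------------------------------------------
# ROC analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RocReport:
    """Empirical ROC summary in the layout of a diagnostic cutoff table."""

    auc: float
    auc_se: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    direction: str  # ">=" calls values at or above the cutoff positive
    n_positive: int
    n_negative: int


def _hanley_mcneil_se(auc: float, n1: int, n0: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)
    ) / (n1 * n0)
    return math.sqrt(max(var, 0.0))


def roc_analysis(values, labels, direction: str = ">=") -> RocReport:
    """Empirical ROC of an exposure metric against a binary response.

    AUC by the trapezoid rule (equal to the Mann-Whitney pair-ordering
    probability with ties counted half), SE by Hanley-McNeil, and the cutoff
    maximising Youden's J; ties in J are broken toward the cutoff with the
    higher sensitivity.  ``direction`` ``">="`` treats large values as
    predictive of response, ``"<="`` small values.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if values.shape != labels.shape or values.ndim != 1:
        raise ValueError("values and labels must be equal-length 1-D arrays")
    n1 = int(labels.sum())
    n0 = int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both responder and non-responder classes required")
    if direction not in (">=", "<="):
        raise ValueError("direction must be '>=' or '<='")
    x = values if direction == ">=" else -values
    fpr, tpr, thr = roc_curve(labels.astype(int), x)
    auc = float(np.trapezoid(tpr, fpr))
    # thresholds descend; among J ties prefer the largest sensitivity,
    # i.e. the lowest threshold
    j = tpr - fpr
    best = np.flatnonzero(j >= j.max() - 1e-12)[-1]
    cutoff = float(thr[best])
    if not np.isfinite(cutoff):  # the sklearn sentinel above the max value
        cutoff = float(x.max())
    if direction == "<=":
        cutoff = -cutoff
    se = _hanley_mcneil_se(auc, n1, n0)
    return RocReport(
        auc=auc,
        auc_se=se,
        ci_low=float(max(0.0, auc - 1.959963984540054 * se)),
        ci_high=float(min(1.0, auc + 1.959963984540054 * se)),
        cutoff=cutoff,
        sensitivity=float(tpr[best]),
        specificity=float(1.0 - fpr[best]),
        direction=direction,
        n_positive=n1,
        n_negative=n0,
    )


def mr_phenotype_discrimination(
    mr_table: pd.DataFrame,
    target: str,
    metrics: Sequence[str] = ("mr_auc", "mr_cmin", "mr_cmax"),
) -> dict[str, RocReport]:
    """One-vs-rest ROC of steady-state metabolic ratios against a phenotype.

    UM discrimination reports ``>=`` cutoffs (UMs have high DARI/ARI ratios),
    IM discrimination ``<=`` cutoffs.  ``mr_table`` needs a ``phenotype``
    column plus the requested MR columns.
    """
    if target not in ("UM", "IM"):
        raise ValueError("target must be 'UM' or 'IM'")
    labels = (mr_table["phenotype"] == target).to_numpy()
    if not labels.any():
        raise ValueError(f"no {target} subjects present")
    direction = ">=" if target == "UM" else "<="
    return {
        m: roc_analysis(mr_table[m].to_numpy(), labels, direction=direction)
        for m in metrics
    }


# ---------------------------------------------------------------------------
# covariate utilities
# ---------------------------------------------------------------------------

def bsa_mosteller(height_cm: float, weight_kg: float) -> float:
    """Body surface area (m^2) by the Mosteller formula sqrt(ht*wt/3600)."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    return math.sqrt(height_cm * weight_kg / 3600.0)


def egfr_schwartz(height_cm: float, scr_umol_l: float) -> float:
    """Estimated GFR (ml/min/1.73 m^2) by the modified (bedside) Schwartz
    formula 0.413 * height / Scr, with serum creatinine supplied in umol/L
    (converted internally to mg/dl by 88.4)."""
    if height_cm <= 0 or scr_umol_l <= 0:
        raise ValueError("height and serum creatinine must be positive")
    return 0.413 * height_cm / (scr_umol_l / 88.4)
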