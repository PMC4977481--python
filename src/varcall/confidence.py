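"""Variant confidence score (VCOS) and three-way variant classification.

A called non-reference genotype is scored by the mean negative log
probability, over the reads whose base is one of its alleles, of that
base arising by substitution of the reference: transitions of the
reference carry probability ``S_ti = delta*theta/(1+delta)``,
transversions ``S_tv = 0.5*theta/(1+delta)`` and the reference base
itself ``1 - theta``.  The score is compared against two analytic
thresholds: a column of perfect variant evidence for a transition
lands exactly on the high-confidence threshold, so scores at or above
it are "high", scores at or above the low-confidence threshold are
"low", and anything below is a false positive.

Natural logarithms are used throughout; any other base rescales score
and thresholds identically, leaving the classification unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .genotypes import GenotypeCategory, category, genotype_alleles, is_transition
from .params import ModelParams
from .pileup_io import SiteColumn

# relative tolerance for the >= comparisons: perfect-evidence columns
# land on a threshold exactly in real arithmetic but may sit one ulp
# below it after summation
_REL_TOL = 1e-9


@dataclass
class ConfidenceResult:
    vcos: float
    hc_threshold: float
    lc_threshold: float
    label: str  # "high" | "low" | "false_positive"


def substitution_prob(x: str, ref_base: str, params: ModelParams) -> float:
    """Prior probability of observing allele ``x`` given reference base."""
    if x == ref_base:
        return 1.0 - params.theta
    if is_transition(ref_base, x):
        return params.s_ti
    return params.s_tv


def vcos(
    column: SiteColumn, genotype: str, ref_base: str | None = None,
    params: ModelParams | None = None,
) -> float:
    """Mean negative log substitution probability over reads supporting
    the genotype.  Zero (classified false positive downstream) when no
    read matches either allele."""
    if params is None:
        params = ModelParams()
    if ref_base is None:
        ref_base = column.ref_base
    if category(genotype, ref_base) is GenotypeCategory.HOM_REF:
        raise ValueError("VCOS is defined only for non-reference genotypes")
    alleles = set(genotype_alleles(genotype))
    total = 0.0
    n = 0
    for obs in column.observations:
        if obs.base in alleles:
            total += -math.log(substitution_prob(obs.base, ref_base, params))
            n += 1
    if n == 0:
        return 0.0
    return total / n


def thresholds(
    genotype: str, ref_base: str, params: ModelParams
) -> tuple[float, float]:
    """High- and low-confidence thresholds for the genotype's case.

    Case 1: heterozygous-reference genotypes.  Case 2: genotypes with
    no reference allele (homozygous variant and heterozygous variant).
    """
    cat = category(genotype, ref_base)
    if cat is GenotypeCategory.HOM_REF:
        raise ValueError("thresholds are defined only for non-reference genotypes")
    s_ti, s_tv, theta = params.s_ti, params.s_tv, params.theta
    if cat is GenotypeCategory.HET_REF:
        hc = -0.5 * math.log((1.0 - theta) * s_ti)
        lc = -params.phi * math.log(1.0 - theta) - 0.5 * (1.0 - params.phi) * math.log(
            s_ti * s_tv
        )
    else:
        hc = -math.log(s_ti)
        lc = -0.5 * params.psi * math.log(s_ti * s_tv) - (1.0 - params.psi) * math.log(
            1.0 - theta
        )
    return hc, lc


def _at_least(score: float, threshold: float) -> bool:
    return score >= threshold or math.isclose(
        score, threshold, rel_tol=_REL_TOL, abs_tol=1e-12
    )


def classify(
    column: SiteColumn,
    genotype: str,
    ref_base: str | None = None,
    params: ModelParams | None = None,
) -> ConfidenceResult:
    """Score a called genotype and label it high / low / false_positive."""
    if params is None:
        params = ModelParams()
    if ref_base is None:
        ref_base = column.ref_base
    score = vcos(column, genotype, ref_base, params)
    hc, lc = thresholds(genotype, ref_base, params)
    if _at_least(score, hc):
        label = "high"
    elif _at_least(score, lc):
        label = "low"
    else:
        label = "false_positive"
    return ConfidenceResult(vcos=score, hc_threshold=hc, lc_threshold=lc, label=label)
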