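"""Model parameters and the base-substitution probability table.

``ModelParams`` collects every tunable quantity of the calling models:

theta
    Expected heterozygous point-mutation rate between two haploid
    chromosomes of the same individual (~1e-3 in humans).
delta
    Transition/transversion (Ti/Tv) ratio; ~2.0 for whole-genome human
    data.
alpha
    Proportion of reads expected from the first haploid chromosome;
    0.5 under unbiased sequencing of both haplotypes.
phi, psi
    Mixing weights of the low-confidence score thresholds for
    heterozygous-reference and reference-free genotypes respectively.
    They are constrained at construction so the high-confidence
    threshold never falls below the low-confidence one.
purity
    Expected fraction of tumor-cell reads in the tumor sample; ``None``
    requests the fallback estimator.
somatic_rate
    Dependency rate of the tumor-genotype-given-normal-genotype prior:
    the prior probability mass allotted to the tumor genotype differing
    from the germline genotype.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


def _hc_lc(theta: float, delta: float, phi: float, psi: float):
    """Closed-form confidence thresholds for both genotype cases."""
    s_ti = delta * theta / (1.0 + delta)
    s_tv = 0.5 * theta / (1.0 + delta)
    hc1 = -0.5 * math.log((1.0 - theta) * s_ti)
    lc1 = -phi * math.log(1.0 - theta) - 0.5 * (1.0 - phi) * math.log(s_ti * s_tv)
    hc2 = -math.log(s_ti)
    lc2 = -0.5 * psi * math.log(s_ti * s_tv) - (1.0 - psi) * math.log(1.0 - theta)
    return (hc1, lc1), (hc2, lc2)


@dataclass
class ModelParams:
    theta: float = 1e-3
    delta: float = 2.0
    alpha: float = 0.5
    prior_mode: str = "theta"  # flat | theta | titv
    # phi defaults to the midpoint of its admissible range at the default
    # theta/delta (admissibility: the Case-1 high-confidence threshold must
    # not fall below the low-confidence one, which requires phi >~ 0.54)
    phi: float = 0.75
    psi: float = 0.5
    purity: float | None = None
    somatic_rate: float = 1e-4
    window: int = 1000
    use_window_alpha: bool = False
    # indel candidate identification
    mu: float = 1e-3          # point-mutation rate of Fisher test 1
    mu_indel: float = 1e-3    # indel rate of Fisher test 2
    a1: float = 0.01          # significance level, test 1
    a2: float = 0.01          # significance level, test 2
    hom_frac: float = 0.75    # indel zygosity threshold
    pswm_likelihood_mode: str = "literal"  # literal | mean
    # somatic post-processing relaxed constraint
    min_var_reads: int = 2
    relax_factor: float = 1.0
    # minimum retained reads for a genotype call
    min_depth: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if self.theta <= 0 or self.theta >= 1:
            raise ValueError("theta must lie in (0, 1)")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.purity is not None and not (0.0 <= self.purity <= 1.0):
            raise ValueError("purity must lie in [0, 1]")
        if self.prior_mode not in ("flat", "theta", "titv"):
            raise ValueError(f"unknown prior mode {self.prior_mode!r}")
        if not (0.0 <= self.phi <= 1.0 and 0.0 <= self.psi <= 1.0):
            raise ValueError("phi and psi must lie in [0, 1]")
        (hc1, lc1), (hc2, lc2) = _hc_lc(self.theta, self.delta, self.phi, self.psi)
        if hc1 < lc1 - 1e-12 or hc2 < lc2 - 1e-12:
            raise ValueError(
                "phi/psi leave a low-confidence threshold above the "
                "high-confidence one for these theta/delta"
            )

    @property
    def s_ti(self) -> float:
        """Prior substitution probability of a transition of the reference."""
        return self.delta * self.theta / (1.0 + self.delta)

    @property
    def s_tv(self) -> float:
        """Prior substitution probability of one specific transversion."""
        return 0.5 * self.theta / (1.0 + self.delta)


@dataclass
class SubstitutionTable:
    """P(true chromosomal base | observed base was miscalled/misaligned).

    Row = observed base, column = candidate true base; the diagonal is
    unused and each row sums to 1 over the three other bases.  The
    default is non-informative (1/3 everywhere off-diagonal); a
    platform-specific error profile can be loaded from any 4x4
    row-normalisable matrix.
    """

    table: np.ndarray = field(
        default_factory=lambda: (np.ones((4, 4)) - np.eye(4)) / 3.0
    )

    def __post_init__(self) -> None:
        t = np.asarray(self.table, dtype=float)
        if t.shape != (4, 4):
            raise ValueError("substitution table must be 4x4")
        off = t * (1.0 - np.eye(4))
        rows = off.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError("each row must sum to 1 over off-diagonal cells")
        self.table = off

    @classmethod
    def flat(cls) -> "SubstitutionTable":
        return cls()

    @classmethod
    def from_rates(cls, rates) -> "SubstitutionTable":
        """Build from relative miscall rates; rows are renormalised."""
        t = np.asarray(rates, dtype=float) * (1.0 - np.eye(4))
        sums = t.sum(axis=1, keepdims=True)
        if np.any(sums <= 0):
            raise ValueError("every observed base needs positive rates")
        return cls(t / sums)

    def __getitem__(self, key) -> float:
        obs, true = key
        from .genotypes import BASE_INDEX

        i = BASE_INDEX[obs] if isinstance(obs, str) else obs
        j = BASE_INDEX[true] if isinstance(true, str) else true
        return float(self.table[i, j])


DEFAULT_PHI_TABLE = SubstitutionTable()
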