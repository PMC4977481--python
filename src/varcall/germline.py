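"""Bayesian diploid genotype inference from per-site allele counts.

The allele counts at a site are modelled as multinomial draws
conditioned on the diploid genotype.  Each read contributes a mixture
over the two haploid chromosomes: with probability ``alpha`` it was
sequenced from the first haplotype and with ``1 - alpha`` from the
second.  A read drawn from haplotype base ``g`` shows base ``x`` with
probability ``omega`` if ``x == g`` and ``(1 - omega) * Phi[x, g]``
otherwise, where ``omega`` combines the base and mapping qualities and
``Phi`` is the substitution table.  Genotype priors come from the
heterozygous mutation rate (optionally reweighted by the Ti/Tv ratio),
and the posterior is the prior-weighted, normalised likelihood over the
ten genotypes.

All likelihoods are kept in log space: at depths beyond a few hundred
reads the per-site product underflows double precision otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import (
    BASE_INDEX,
    GENOTYPES,
    GENOTYPE_ALLELES,
    K,
    GenotypeCategory,
    category,
    is_transition,
)
from .params import DEFAULT_PHI_TABLE, ModelParams, SubstitutionTable
from .pileup_io import AlleleObservation, SiteColumn


@dataclass
class GenotypePosterior:
    """Posterior over the ten diploid genotypes at one site."""

    log_likelihoods: np.ndarray  # shape (10,), log P(X_i | G_k) up to a constant
    posteriors: np.ndarray  # shape (10,), sums to 1
    best: str
    runner_up: str

    @property
    def best_posterior(self) -> float:
        from .genotypes import GENOTYPE_INDEX

        return float(self.posteriors[GENOTYPE_INDEX[self.best]])


def allele_weight(base_quality: float, mapping_quality: float) -> float:
    """Read-accuracy weight: 1 minus the harmonic mean of the two
    Phred-scaled error probabilities.  Negative qualities are clamped
    to zero."""
    bq = max(base_quality, 0.0)
    mq = max(mapping_quality, 0.0)
    eb = 10.0 ** (-0.1 * bq)
    em = 10.0 ** (-0.1 * mq)
    return 1.0 - 2.0 * eb * em / (eb + em)


def allele_prob_haploid(
    obs: AlleleObservation,
    haploid_base: str,
    phi_table: SubstitutionTable = DEFAULT_PHI_TABLE,
    omega: float | None = None,
) -> float:
    """P(observed base | true haploid base)."""
    if omega is None:
        omega = allele_weight(obs.base_quality, obs.mapping_quality)
    if obs.base == haploid_base:
        return omega
    return (1.0 - omega) * phi_table[obs.base, haploid_base]


def allele_prob_genotype(
    obs: AlleleObservation,
    genotype: str,
    alpha: float = 0.5,
    phi_table: SubstitutionTable = DEFAULT_PHI_TABLE,
    max_form: bool = False,
) -> float:
    """P(observed base | diploid genotype) as a haplotype mixture.

    ``max_form=True`` uses the strand-agnostic variant that takes the
    larger of the two haplotype orderings; at ``alpha = 0.5`` both
    forms coincide.
    """
    p1 = allele_prob_haploid(obs, genotype[0], phi_table)
    p2 = allele_prob_haploid(obs, genotype[1], phi_table)
    mixed = alpha * p1 + (1.0 - alpha) * p2
    if max_form:
        return max(mixed, (1.0 - alpha) * p1 + alpha * p2)
    return mixed


def strand_alpha(columns: list[SiteColumn], center: int, window: int = 1000) -> float:
    """Sliding-window haplotype-sampling proportion.

    Mean over the window (centred on index ``center``) of the per-site
    fraction of forward-strand observations; sites without retained
    observations are skipped.  Used with the max-form mixture when the
    window mode is enabled.
    """
    half = window // 2
    lo = max(0, center - half)
    hi = min(len(columns), center + half + 1)
    fracs = []
    for col in columns[lo:hi]:
        if col.observations:
            fwd = sum(1 for o in col.observations if o.strand == "+")
            fracs.append(fwd / len(col.observations))
    if not fracs:
        return 0.5
    return float(sum(fracs) / len(fracs))


# cache of per-(bq, mq) 4x10 log-probability matrices:
# entry [x, k] = log P(observed base x | genotype k)
_LOGP_CACHE: dict[tuple, np.ndarray] = {}


def _log_prob_matrix(
    bq: int, mq: int, alpha: float, phi_table: SubstitutionTable
) -> np.ndarray:
    key = (bq, mq, alpha, id(phi_table))
    mat = _LOGP_CACHE.get(key)
    if mat is None:
        omega = allele_weight(bq, mq)
        # P(x | haploid base g): 4x4
        hap = omega * np.eye(4) + (1.0 - omega) * phi_table.table
        a1 = [p[0] for p in GENOTYPE_ALLELES]
        a2 = [p[1] for p in GENOTYPE_ALLELES]
        geno = alpha * hap[:, a1] + (1.0 - alpha) * hap[:, a2]
        with np.errstate(divide="ignore"):
            mat = np.log(geno)
        if len(_LOGP_CACHE) > 4096:
            _LOGP_CACHE.clear()
        _LOGP_CACHE[key] = mat
    return mat


def site_log_likelihoods(
    column: SiteColumn,
    params: ModelParams,
    phi_table: SubstitutionTable = DEFAULT_PHI_TABLE,
    alpha: float | None = None,
) -> np.ndarray | None:
    """log P(X_i | G_k) for all ten genotypes (up to a shared constant).

    Returns ``None`` for a column with no retained observations.
    Observations sharing (base quality, mapping quality) are grouped so
    the per-genotype log probability is computed once per group.
    """
    if not column.observations:
        return None
    if alpha is None:
        alpha = params.alpha
    counts: dict[tuple[int, int], np.ndarray] = {}
    for obs in column.observations:
        key = (obs.base_quality, obs.mapping_quality)
        vec = counts.get(key)
        if vec is None:
            vec = np.zeros(4)
            counts[key] = vec
        vec[BASE_INDEX[obs.base]] += 1
    total = np.zeros(K)
    for (bq, mq), vec in counts.items():
        total += vec @ _log_prob_matrix(bq, mq, alpha, phi_table)
    return total


def site_log_likelihood(
    column: SiteColumn,
    genotype: str,
    params: ModelParams,
    phi_table: SubstitutionTable = DEFAULT_PHI_TABLE,
) -> float | None:
    """log P(X_i | G_k) for a single genotype; None on an empty column."""
    vec = site_log_likelihoods(column, params, phi_table)
    if vec is None:
        return None
    from .genotypes import GENOTYPE_INDEX

    return float(vec[GENOTYPE_INDEX[genotype]])


def genotype_priors(
    ref_base: str, params: ModelParams, mode: str | None = None
) -> np.ndarray:
    """Prior probability of each genotype given the reference base.

    ``theta`` mode: heterozygous-reference genotypes get theta,
    heterozygous-variant theta^2, homozygous-variant theta/2, and the
    homozygous-reference genotype absorbs the remaining mass.  ``flat``
    mode is uniform.  ``titv`` mode reweights the non-reference mass of
    the theta prior by transition/transversion plausibility of each
    changed allele, preserving the total non-reference mass.
    """
    if mode is None:
        mode = params.prior_mode
    if mode == "flat":
        return np.full(K, 1.0 / K)
    theta = params.theta
    priors = np.empty(K)
    for k, g in enumerate(GENOTYPES):
        cat = category(g, ref_base)
        if cat is GenotypeCategory.HET_REF:
            priors[k] = theta
        elif cat is GenotypeCategory.HET_VAR:
            priors[k] = theta * theta
        elif cat is GenotypeCategory.HOM_VAR:
            priors[k] = theta / 2.0
        else:
            priors[k] = 0.0
    hom_ref_idx = next(
        k
        for k, g in enumerate(GENOTYPES)
        if category(g, ref_base) is GenotypeCategory.HOM_REF
    )
    priors[hom_ref_idx] = 1.0 - priors.sum()
    if mode == "theta":
        return priors
    # titv: scale each non-reference genotype by the Ti/Tv weight of its
    # changed alleles, then restore the non-reference mass
    delta = params.delta
    w_ti = delta / (1.0 + delta)
    w_tv = 0.5 / (1.0 + delta)
    weights = np.ones(K)
    for k, g in enumerate(GENOTYPES):
        for allele in g:
            if allele != ref_base:
                weights[k] *= w_ti if is_transition(ref_base, allele) else w_tv
    nonref_mass = priors.sum() - priors[hom_ref_idx]
    scaled = priors * weights
    scaled[hom_ref_idx] = 0.0
    scaled *= nonref_mass / scaled.sum()
    scaled[hom_ref_idx] = priors[hom_ref_idx]
    return scaled


_PRIOR_CACHE: dict[tuple, np.ndarray] = {}


def log_genotype_priors(ref_base: str, params: ModelParams) -> np.ndarray:
    """Log priors, precomputed per reference base and parameter set."""
    key = (ref_base, params.prior_mode, params.theta, params.delta)
    lp = _PRIOR_CACHE.get(key)
    if lp is None:
        lp = np.log(genotype_priors(ref_base, params))
        _PRIOR_CACHE[key] = lp
    return lp


def _normalise_log(logpost: np.ndarray) -> np.ndarray:
    m = logpost.max()
    p = np.exp(logpost - m)
    return p / p.sum()


def infer_genotype(
    column: SiteColumn,
    ref_base: str | None = None,
    params: ModelParams | None = None,
    phi_table: SubstitutionTable = DEFAULT_PHI_TABLE,
    alpha: float | None = None,
) -> GenotypePosterior | None:
    """Posterior over genotypes and the maximum-a-posteriori call.

    Returns ``None`` (no call) when the column has fewer retained
    observations than ``params.min_depth``.  Exact posterior ties are
    broken by the canonical genotype ordering.
    """
    if params is None:
        params = ModelParams()
    if ref_base is None:
        ref_base = column.ref_base
    if len(column.observations) < max(params.min_depth, 1):
        return None
    loglik = site_log_likelihoods(column, params, phi_table, alpha=alpha)
    logpost = loglik + log_genotype_priors(ref_base, params)
    post = _normalise_log(logpost)
    order = np.argsort(-post, kind="stable")
    return GenotypePosterior(
        log_likelihoods=loglik,
        posteriors=post,
        best=GENOTYPES[order[0]],
        runner_up=GENOTYPES[order[1]],
    )
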