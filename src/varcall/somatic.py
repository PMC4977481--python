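"""Somatic variant calling from matched tumor-normal column pairs.

The caller is a hybrid of two analyses.  Subtraction analysis first
genotypes each sample independently: a site whose normal genotype is
homozygous reference while the tumor carries a high-confidence variant
is reported Somatic immediately.  Every other site goes to the joint
analysis, which models the pair of allele-count vectors under a joint
posterior over all 100 genotype pairs: the two per-sample likelihoods
multiply a dependency prior P(tumor genotype | normal genotype) that
concentrates mass on identical genotypes (the samples come from one
individual and share germline polymorphisms) and spreads the remaining
``somatic_rate`` mass over genotype changes weighted by
transition/transversion plausibility.

The joint maximum-a-posteriori pair then passes a four-step
post-processing: (i) a joint genotype disagreeing with its subtraction
counterpart survives only with a high-confidence score, otherwise it
is demoted to homozygous reference; (ii) a joint genotype confirming
the subtraction call is accepted under a relaxed, depth-conditioned
minimum count of variant-supporting reads (scaled by tumor purity for
the tumor sample); (iii) a site where both genotypes fall is dropped;
(iv) the surviving pair is typed Wild / Somatic / LOH / Germline /
Unknown from the genotype-category pair and written to VCF.

Somatic indels use an asymmetry rule: a site that is an indel
candidate in exactly one of the two samples is reported (tumor-only as
Somatic, normal-only as an LOH-type loss), with the consensus sequence
from the multiple ungapped alignment of that sample's indel
observations.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Iterator

import numpy as np

from .confidence import ConfidenceResult, classify
from .genotypes import (
    GENOTYPES,
    K,
    GenotypeCategory,
    alt_alleles,
    category,
    genotype_alleles,
    is_transition,
)
from .germline import (
    infer_genotype,
    log_genotype_priors,
    site_log_likelihoods,
)
from .indels import detect_candidate, mua_search
from .params import DEFAULT_PHI_TABLE, ModelParams, SubstitutionTable
from .pileup_io import SiteColumn, VariantRecord

logger = logging.getLogger(__name__)

SOMATIC_TYPES = ("Wild", "Somatic", "LOH", "Germline", "Unknown")


@dataclass
class JointPrior:
    """P(normal genotype) and the dependency matrix P(tumor | normal)."""

    log_marginal: np.ndarray  # (K,)
    log_dependency: np.ndarray  # (K, K): row = normal, column = tumor
    somatic_rate: float

    @property
    def log_joint(self) -> np.ndarray:
        return self.log_marginal[:, None] + self.log_dependency


@dataclass
class JointGenotypeCall:
    chrom: str
    pos: int
    ref_base: str
    g_normal: str
    g_tumor: str
    somatic_type: str
    provenance: str  # "subtraction" | "joint"
    conf_normal: ConfidenceResult | None
    conf_tumor: ConfidenceResult | None
    depth_normal: int
    depth_tumor: int


def _allele_change_weight(old: str, new: str, params: ModelParams) -> float:
    """Ti/Tv plausibility of replacing one allele by another."""
    if is_transition(old, new):
        return params.delta / (1.0 + params.delta)
    return 0.5 / (1.0 + params.delta)


def _pair_change_weight(gn: str, gt: str, params: ModelParams) -> tuple[int, float]:
    """Number of allele changes between two genotypes and the weight of
    the most plausible pairing of removed to added alleles."""
    a = list(genotype_alleles(gn))
    b = list(genotype_alleles(gt))
    # cancel shared alleles (multiset intersection)
    removed = a.copy()
    added = b.copy()
    for x in a:
        if x in added:
            added.remove(x)
            removed.remove(x)
    n_changes = len(added)
    if n_changes == 0:
        return 0, 1.0
    best = 0.0
    for perm in permutations(added):
        w = 1.0
        for old, new in zip(removed, perm):
            w *= _allele_change_weight(old, new, params)
        best = max(best, w)
    return n_changes, best


_JOINT_PRIOR_CACHE: dict[tuple, JointPrior] = {}


def joint_prior(ref_base: str, params: ModelParams) -> JointPrior:
    """Joint genotype prior for one reference base.

    Each row of the dependency matrix puts mass proportional to
    ``1 - s`` on the unchanged genotype, ``s * w`` on single-allele
    changes and ``s^2 * w`` on double changes (``w`` the Ti/Tv weight
    of the changed alleles), then is normalised.  As ``s -> 0`` the
    matrix tends to the identity and the joint caller reduces to
    "tumor genotype equals normal genotype".
    """
    key = (ref_base, params.somatic_rate, params.delta, params.theta, params.prior_mode)
    cached = _JOINT_PRIOR_CACHE.get(key)
    if cached is not None:
        return cached
    s = params.somatic_rate
    dep = np.empty((K, K))
    for i, gn in enumerate(GENOTYPES):
        for j, gt in enumerate(GENOTYPES):
            n_changes, w = _pair_change_weight(gn, gt, params)
            if n_changes == 0:
                dep[i, j] = 1.0 - s
            else:
                dep[i, j] = (s**n_changes) * w
        dep[i] /= dep[i].sum()
    prior = JointPrior(
        log_marginal=log_genotype_priors(ref_base, params),
        log_dependency=np.log(dep),
        somatic_rate=s,
    )
    _JOINT_PRIOR_CACHE[key] = prior
    return prior


def joint_posterior(
    normal_col: SiteColumn,
    tumor_col: SiteColumn,
    ref_base: str | None = None,
    params: ModelParams | None = None,
    phi_table: SubstitutionTable = DEFAULT_PHI_TABLE,
) -> np.ndarray | None:
    """Normalised posterior over the 100 genotype pairs, or ``None``
    when either column is empty.  Row index = normal genotype, column
    index = tumor genotype, both in canonical order."""
    if params is None:
        params = ModelParams()
    if ref_base is None:
        ref_base = normal_col.ref_base
    ll_n = site_log_likelihoods(normal_col, params, phi_table)
    ll_t = site_log_likelihoods(tumor_col, params, phi_table)
    if ll_n is None or ll_t is None:
        return None
    prior = joint_prior(ref_base, params)
    logpost = ll_n[:, None] + ll_t[None, :] + prior.log_joint
    m = logpost.max()
    p = np.exp(logpost - m)
    return p / p.sum()


def joint_argmax(post: np.ndarray) -> tuple[str, str]:
    """Maximum cell of a K x K posterior, ties broken by canonical
    genotype order (normal major, tumor minor)."""
    flat = int(np.argmax(post))
    return GENOTYPES[flat // K], GENOTYPES[flat % K]


def classify_somatic(g_normal: str, g_tumor: str, ref_base: str) -> str:
    """Genotype-pair typing.

    With A the reference base and B any non-reference allele, the
    normal/tumor category pair maps as: AA row -> Wild / Somatic /
    Somatic; AB row -> LOH / Germline / LOH; BB row -> Unknown /
    Unknown / Germline.  A heterozygous-variant normal genotype uses
    the AB row when it shares an allele with the tumor genotype and
    the BB row otherwise; heterozygous-variant tumor genotypes use the
    BB column (no reference allele).
    """
    cat_n = category(g_normal, ref_base)
    cat_t = category(g_tumor, ref_base)
    if cat_t is GenotypeCategory.HOM_REF:
        col = 0  # AA
    elif cat_t is GenotypeCategory.HET_REF:
        col = 1  # AB
    else:
        col = 2  # BB
    if cat_n is GenotypeCategory.HOM_REF:
        row = 0
    elif cat_n is GenotypeCategory.HET_REF:
        row = 1
    elif cat_n is GenotypeCategory.HOM_VAR:
        row = 2
    else:  # het_var: AB row when an allele is shared with the tumor genotype
        shared = set(genotype_alleles(g_normal)) & set(genotype_alleles(g_tumor))
        row = 1 if shared else 2
    table = (
        ("Wild", "Somatic", "Somatic"),
        ("LOH", "Germline", "LOH"),
        ("Unknown", "Unknown", "Germline"),
    )
    return table[row][col]


def _hom_ref(ref_base: str) -> str:
    return ref_base + ref_base


def _variant_support(column: SiteColumn, genotype: str, ref_base: str) -> int:
    alts = set(alt_alleles(genotype, ref_base))
    return sum(1 for o in column.observations if o.base in alts)


def relaxed_threshold(depth: int, params: ModelParams, is_tumor: bool) -> int:
    """Depth-conditioned minimum variant-read count of post-processing
    step (ii): half the expected heterozygous variant reads, scaled by
    tumor purity for the tumor sample, with an absolute floor."""
    purity = params.purity if (is_tumor and params.purity is not None) else 1.0
    f = 0.5 * 0.5 * purity * params.relax_factor
    return max(params.min_var_reads, math.ceil(f * depth))


def _postprocess_genotype(
    joint_g: str,
    sub_g: str,
    column: SiteColumn,
    ref_base: str,
    params: ModelParams,
    is_tumor: bool,
) -> tuple[str, ConfidenceResult | None]:
    """Steps (i)/(ii) for one sample; returns the surviving genotype
    (possibly demoted to homozygous reference) and its confidence."""
    if category(joint_g, ref_base) is GenotypeCategory.HOM_REF:
        return _hom_ref(ref_base), None
    conf = classify(column, joint_g, ref_base, params)
    if joint_g != sub_g:
        # step (i): disagreement with subtraction requires high confidence
        if conf.label == "high":
            return joint_g, conf
        return _hom_ref(ref_base), None
    # step (ii): agreement, relaxed depth-conditioned read-count constraint
    support = _variant_support(column, joint_g, ref_base)
    if support >= relaxed_threshold(column.depth, params, is_tumor):
        return joint_g, conf
    return _hom_ref(ref_base), None


def subtraction_call(
    normal_col: SiteColumn,
    tumor_col: SiteColumn,
    ref_base: str | None = None,
    params: ModelParams | None = None,
    phi_table: SubstitutionTable = DEFAULT_PHI_TABLE,
) -> JointGenotypeCall | None:
    """Independent per-sample genotyping; returns an immediate Somatic
    call when the normal is homozygous reference and the tumor variant
    is high-confidence, otherwise ``None`` (defer to joint analysis)."""
    if params is None:
        params = ModelParams()
    if ref_base is None:
        ref_base = normal_col.ref_base
    post_n = infer_genotype(normal_col, ref_base, params, phi_table)
    post_t = infer_genotype(tumor_col, ref_base, params, phi_table)
    if post_n is None or post_t is None:
        return None
    gn, gt = post_n.best, post_t.best
    if category(gn, ref_base) is not GenotypeCategory.HOM_REF:
        return None
    if category(gt, ref_base) is GenotypeCategory.HOM_REF:
        return None
    conf_t = classify(tumor_col, gt, ref_base, params)
    if conf_t.label != "high":
        return None
    return JointGenotypeCall(
        chrom=tumor_col.chrom,
        pos=tumor_col.pos,
        ref_base=ref_base,
        g_normal=gn,
        g_tumor=gt,
        somatic_type=classify_somatic(gn, gt, ref_base),
        provenance="subtraction",
        conf_normal=None,
        conf_tumor=conf_t,
        depth_normal=normal_col.depth,
        depth_tumor=tumor_col.depth,
    )


def call_somatic_snv(
    normal_col: SiteColumn,
    tumor_col: SiteColumn,
    params: ModelParams | None = None,
    phi_table: SubstitutionTable = DEFAULT_PHI_TABLE,
) -> JointGenotypeCall | None:
    """Full subtraction -> joint -> post-processing pipeline for one
    site; ``None`` when no non-Wild genotype pair survives."""
    if params is None:
        params = ModelParams()
    ref_base = normal_col.ref_base
    n_empty = not normal_col.observations
    t_empty = not tumor_col.observations
    if n_empty and t_empty:
        return None
    if n_empty or t_empty:
        # one-sided site: germline call on the present sample, Unknown type
        col = tumor_col if n_empty else normal_col
        post = infer_genotype(col, ref_base, params, phi_table)
        if post is None:
            return None
        g = post.best
        if category(g, ref_base) is GenotypeCategory.HOM_REF:
            return None
        conf = classify(col, g, ref_base, params)
        if conf.label == "false_positive":
            return None
        hom = _hom_ref(ref_base)
        return JointGenotypeCall(
            chrom=col.chrom,
            pos=col.pos,
            ref_base=ref_base,
            g_normal=hom if n_empty else g,
            g_tumor=g if n_empty else hom,
            somatic_type="Unknown",
            provenance="subtraction",
            conf_normal=None if n_empty else conf,
            conf_tumor=conf if n_empty else None,
            depth_normal=normal_col.depth,
            depth_tumor=tumor_col.depth,
        )

    # fast path: no non-reference evidence anywhere -> Wild with certainty
    if all(o.base == ref_base for o in normal_col.observations) and all(
        o.base == ref_base for o in tumor_col.observations
    ):
        return None

    sub = subtraction_call(normal_col, tumor_col, ref_base, params, phi_table)
    if sub is not None:
        return sub

    post_n = infer_genotype(normal_col, ref_base, params, phi_table)
    post_t = infer_genotype(tumor_col, ref_base, params, phi_table)
    sub_gn = post_n.best if post_n else _hom_ref(ref_base)
    sub_gt = post_t.best if post_t else _hom_ref(ref_base)

    post = joint_posterior(normal_col, tumor_col, ref_base, params, phi_table)
    if post is None:
        return None
    jn, jt = joint_argmax(post)
    final_gn, conf_n = _postprocess_genotype(
        jn, sub_gn, normal_col, ref_base, params, is_tumor=False
    )
    final_gt, conf_t = _postprocess_genotype(
        jt, sub_gt, tumor_col, ref_base, params, is_tumor=True
    )
    hom = _hom_ref(ref_base)
    if final_gn == hom and final_gt == hom:
        return None  # step (iii): nothing survived
    stype = classify_somatic(final_gn, final_gt, ref_base)
    if stype == "Wild":
        return None
    return JointGenotypeCall(
        chrom=normal_col.chrom,
        pos=normal_col.pos,
        ref_base=ref_base,
        g_normal=final_gn,
        g_tumor=final_gt,
        somatic_type=stype,
        provenance="joint",
        conf_normal=conf_n,
        conf_tumor=conf_t,
        depth_normal=normal_col.depth,
        depth_tumor=tumor_col.depth,
    )


def somatic_indel(
    normal_col: SiteColumn,
    tumor_col: SiteColumn,
    params: ModelParams | None = None,
) -> VariantRecord | None:
    """Asymmetry rule for somatic indels: report only when exactly one
    sample is an indel candidate (tumor-only Somatic, normal-only LOH)."""
    if params is None:
        params = ModelParams()
    cand_n = detect_candidate(normal_col, params)
    cand_t = detect_candidate(tumor_col, params)
    if (cand_n is None) == (cand_t is None):
        return None
    if cand_t is not None:
        cand, col, stype = cand_t, tumor_col, "Somatic"
    else:
        cand, col, stype = cand_n, normal_col, "LOH"
    seqs = cand.insertion_seqs if cand.kind == "insertion" else cand.deletion_seqs
    mua = mua_search(seqs, mode=params.pswm_likelihood_mode)
    anchor = col.ref_base
    if cand.kind == "insertion":
        ref, alt = anchor, anchor + mua.consensus
    else:
        ref, alt = anchor + mua.consensus, anchor
    denom = max(col.depth, len(seqs), 1)
    gt_var = "1/1" if len(seqs) / denom >= params.hom_frac else "0/1"
    if stype == "Somatic":
        genotypes = ("0/0", gt_var)
    else:
        genotypes = (gt_var, "0/0")
    return VariantRecord(
        chrom=col.chrom,
        pos=col.pos,
        ref=ref,
        alts=(alt,),
        genotypes=genotypes,
        depths=(normal_col.depth, tumor_col.depth),
        vcos=(None, None),
        somatic_type=stype,
        filter_status="PASS",
        is_indel=True,
    )


def call_to_record(call: JointGenotypeCall) -> VariantRecord:
    """Render a joint SNV call as a two-sample VCF record."""
    ref = call.ref_base
    alts: list[str] = []
    for g in (call.g_normal, call.g_tumor):
        for a in alt_alleles(g, ref):
            if a not in alts:
                alts.append(a)
    alts.sort()
    allele_idx = {ref: 0, **{a: i + 1 for i, a in enumerate(alts)}}

    def gt_string(g: str) -> str:
        i, j = sorted(allele_idx[a] for a in genotype_alleles(g))
        return f"{i}/{j}"

    labels = [
        c.label for c in (call.conf_normal, call.conf_tumor) if c is not None
    ]
    filt = "LowConfidence" if any(l == "low" for l in labels) else "PASS"
    return VariantRecord(
        chrom=call.chrom,
        pos=call.pos,
        ref=ref,
        alts=tuple(alts),
        genotypes=(gt_string(call.g_normal), gt_string(call.g_tumor)),
        depths=(call.depth_normal, call.depth_tumor),
        vcos=(
            call.conf_normal.vcos if call.conf_normal else None,
            call.conf_tumor.vcos if call.conf_tumor else None,
        ),
        somatic_type=call.somatic_type,
        filter_status=filt,
    )


def pair_columns(
    normal: Iterable[SiteColumn], tumor: Iterable[SiteColumn]
) -> Iterator[tuple[SiteColumn | None, SiteColumn | None]]:
    """Synchronise two sorted column streams by (chromosome, position).

    Chromosome order follows first appearance; sites present in only
    one stream are paired with ``None`` (treated downstream as a
    zero-depth partner).
    """
    rank: dict[str, int] = {}

    def key(col: SiteColumn) -> tuple[int, int]:
        if col.chrom not in rank:
            rank[col.chrom] = len(rank)
        return rank[col.chrom], col.pos

    it_n, it_t = iter(normal), iter(tumor)
    n = next(it_n, None)
    t = next(it_t, None)
    while n is not None or t is not None:
        if n is not None and t is not None:
            kn, kt = key(n), key(t)
            if kn == kt:
                yield n, t
                n, t = next(it_n, None), next(it_t, None)
            elif kn < kt:
                yield n, None
                n = next(it_n, None)
            else:
                yield None, t
                t = next(it_t, None)
        elif n is not None:
            yield n, None
            n = next(it_n, None)
        else:
            yield None, t
            t = next(it_t, None)


def _empty_like(col: SiteColumn) -> SiteColumn:
    return SiteColumn(col.chrom, col.pos, col.ref_base, [], [], 0)


def call_somatic_pairs(
    pairs: Iterable[tuple[SiteColumn | None, SiteColumn | None]],
    params: ModelParams | None = None,
    phi_table: SubstitutionTable = DEFAULT_PHI_TABLE,
) -> Iterator[VariantRecord]:
    """Run the somatic SNV and indel pipelines over a paired stream."""
    if params is None:
        params = ModelParams()
    for ncol, tcol in pairs:
        if ncol is None and tcol is None:
            continue
        if ncol is None:
            ncol = _empty_like(tcol)
        if tcol is None:
            tcol = _empty_like(ncol)
        snv = call_somatic_snv(ncol, tcol, params, phi_table)
        if snv is not None:
            yield call_to_record(snv)
        if ncol.indels or tcol.indels:
            indel = somatic_indel(ncol, tcol, params)
            if indel is not None:
                yield indel


def estimate_or_accept_purity(
    params: ModelParams,
    pairs: Iterable[tuple[SiteColumn | None, SiteColumn | None]] | None = None,
    phi_table: SubstitutionTable = DEFAULT_PHI_TABLE,
) -> float:
    """Pass through a user-supplied purity; otherwise a synthetic
    stand-in estimator: the median, over sites whose normal genotype is
    homozygous reference and whose tumor genotype is a heterozygous
    variant above the false-positive confidence floor, of twice the
    tumor variant-allele fraction, clamped to (0, 1].  Defaults to 1.0
    (with a warning) when no such site exists.

    The high-confidence gate of the subtraction analysis is *not*
    applied here: it only passes sites with variant-allele fraction
    >= 0.5, which would truncate the fraction distribution and bias
    the estimate towards 1 whenever the true purity is below 1.
    """
    if params.purity is not None:
        return params.purity
    if pairs is None:
        logger.warning("no purity given and no data to estimate it; using 1.0")
        return 1.0
    vafs: list[float] = []
    for ncol, tcol in pairs:
        if ncol is None or tcol is None:
            continue
        if not ncol.observations or not tcol.observations:
            continue
        ref_base = ncol.ref_base
        post_n = infer_genotype(ncol, ref_base, params, phi_table)
        post_t = infer_genotype(tcol, ref_base, params, phi_table)
        if post_n is None or post_t is None:
            continue
        if category(post_n.best, ref_base) is not GenotypeCategory.HOM_REF:
            continue
        if category(post_t.best, ref_base) is not GenotypeCategory.HET_REF:
            continue
        conf_t = classify(tcol, post_t.best, ref_base, params)
        if conf_t.label == "false_positive":
            continue
        support = _variant_support(tcol, post_t.best, ref_base)
        if tcol.depth > 0:
            vafs.append(support / tcol.depth)
    if not vafs:
        logger.warning("no confident somatic site found; assuming purity 1.0")
        return 1.0
    est = 2.0 * statistics.median(vafs)
    return min(max(est, 1e-6), 1.0)
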