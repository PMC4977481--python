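"""Indel candidate detection and consensus derivation.

Candidate identification is deliberately lightweight: a site with at
least one insertion/deletion event is screened by two one-sided
Fisher's exact tests.  The first asks whether the substitution signal
at the site is already significant against the expected count under a
point-mutation rate — if so the site is treated as a substitution site
and dropped as an indel candidate.  The second asks whether the indel
event count is significant against the expectation under an indel
rate — only then is the site a candidate.

Because reads covering a true indel often disagree on the exact
inserted/deleted bases (sequencing error, alignment wobble), the
consensus sequence is derived by a multiple ungapped alignment (MUA):
every substring of every observed indel sequence seeds a gapless
overlay against all sequences, each overlay is summarised by a
position-specific weight matrix (PSWM) of log2 frequency/background
ratios, and the overlay whose consensus has the largest likelihood
score wins.  This seed-search strategy follows the starting-point
search used by motif discovery tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import fisher_exact

from .genotypes import ALPHABET, BASE_INDEX
from .params import ModelParams
from .pileup_io import SiteColumn, VariantRecord


@dataclass
class IndelCandidate:
    chrom: str
    pos: int
    ref_base: str
    sequences: tuple[str, ...]  # all indel sequences at the site (both kinds)
    kind: str  # dominant kind: "insertion" | "deletion"
    n_indel: int
    n_ref: int
    n_var: int
    p_substitution: float  # Fisher test 1
    p_indel: float  # Fisher test 2
    insertion_seqs: tuple[str, ...] = ()
    deletion_seqs: tuple[str, ...] = ()

    @property
    def l_min(self) -> int:
        return min(len(s) for s in self.sequences)

    @property
    def l_max(self) -> int:
        return max(len(s) for s in self.sequences)


@dataclass
class Pswm:
    """Position-specific weight matrix of a multiple ungapped alignment.

    ``p`` holds the raw per-column character frequencies (each column
    sums to 1); zero frequencies are floored at ``epsilon`` before the
    log-odds ``W`` is taken so the matrix stays finite.
    """

    weights: np.ndarray  # W, 4 x l
    frequencies: np.ndarray  # p, 4 x l, columns sum to 1
    background: np.ndarray  # q, length 4
    members: tuple[str, ...] = ()


@dataclass
class MuaResult:
    pswm: Pswm
    length: int
    consensus: str
    likelihood: float
    seed: tuple[int, int] = (0, 0)  # (sequence index, offset)


def fisher_greater(n_signal: int, n_ref: int, e_signal: int, e_ref: int) -> float:
    """One-sided Fisher's exact p-value that the observed signal count
    exceeds the expected one."""
    table = [[n_signal, n_ref], [e_signal, e_ref]]
    return float(fisher_exact(table, alternative="greater")[1])


def detect_candidate(
    column: SiteColumn, params: ModelParams | None = None
) -> IndelCandidate | None:
    """Screen a column for indel candidacy with the two Fisher tests."""
    if params is None:
        params = ModelParams()
    if not column.indels:
        return None
    n_ref = sum(1 for o in column.observations if o.base == column.ref_base)
    n_var = len(column.observations) - n_ref
    n_indel = len(column.indels)
    if n_ref + n_var + n_indel == 0:
        return None
    # test 1: is the substitution signal already significant?
    n = n_ref + n_var
    e_var = round(n * params.mu)
    p1 = fisher_greater(n_var, n_ref, e_var, n - e_var)
    if p1 < params.a1:
        return None
    # test 2: is the indel signal significant?
    n2 = n_ref + n_indel
    e_ind = round(n2 * params.mu_indel)
    p2 = fisher_greater(n_indel, n_ref, e_ind, n2 - e_ind)
    if p2 >= params.a2:
        return None
    ins = tuple(i.sequence for i in column.indels if i.kind == "insertion")
    dels = tuple(i.sequence for i in column.indels if i.kind == "deletion")
    kind = "insertion" if len(ins) >= len(dels) else "deletion"
    return IndelCandidate(
        chrom=column.chrom,
        pos=column.pos,
        ref_base=column.ref_base,
        sequences=tuple(i.sequence for i in column.indels),
        kind=kind,
        n_indel=n_indel,
        n_ref=n_ref,
        n_var=n_var,
        p_substitution=p1,
        p_indel=p2,
        insertion_seqs=ins,
        deletion_seqs=dels,
    )


def ungapped_align_score(a: str, b: str) -> int:
    """Gapless overlay score of two equal-length strings: +1 per match,
    -1 per mismatch."""
    if len(a) != len(b):
        raise ValueError("ungapped alignment compares equal-length strings")
    return sum(1 if x == y else -1 for x, y in zip(a, b))


def _best_window(seed: str, sequence: str) -> tuple[int, int] | None:
    """Highest-scoring (leftmost on ties) placement of ``seed`` fully
    inside ``sequence``; None when the sequence is shorter than the seed."""
    l = len(seed)
    if len(sequence) < l:
        return None
    best_score = None
    best_off = 0
    for v in range(len(sequence) - l + 1):
        s = ungapped_align_score(seed, sequence[v : v + l])
        if best_score is None or s > best_score:
            best_score = s
            best_off = v
    return best_off, best_score


def build_pswm(
    members: list[str], n_total: int, background: np.ndarray | None = None
) -> Pswm:
    """PSWM of an ungapped alignment.

    ``n_total`` is the size of the full sequence set the alignment was
    drawn from; the zero-frequency floor is ``1 / (2 * n_total)``.
    """
    if not members:
        raise ValueError("empty alignment")
    l = len(members[0])
    if any(len(m) != l for m in members):
        raise ValueError("alignment members must share one length")
    if background is None:
        background = np.full(4, 0.25)
    counts = np.zeros((4, l))
    for m in members:
        for j, c in enumerate(m):
            counts[BASE_INDEX[c], j] += 1
    freqs = counts / len(members)
    eps = 1.0 / (2.0 * max(n_total, 1))
    floored = np.where(counts > 0, freqs, eps)
    weights = np.log2(floored / background[:, None])
    return Pswm(
        weights=weights,
        frequencies=freqs,
        background=background,
        members=tuple(members),
    )


def consensus_of(pswm: Pswm) -> str:
    """Per-column argmax of the weight matrix; ties resolve to the
    alphabetically first base (argmax returns the first maximum and the
    rows are in A,C,G,T order)."""
    idx = np.argmax(pswm.weights, axis=0)
    return "".join(ALPHABET[i] for i in idx)


def pswm_likelihood(pswm: Pswm, consensus: str, mode: str = "literal") -> float:
    """Likelihood score of a consensus under its PSWM.

    ``literal`` mode takes ``log2`` of the summed per-column log-odds,
    divided by the length; since log-odds may be negative the score is
    -inf when the sum is non-positive, ranking such alignments last.
    ``mean`` mode returns the mean per-column log-odds instead.
    """
    l = len(consensus)
    inner = float(
        sum(pswm.weights[BASE_INDEX[c], j] for j, c in enumerate(consensus))
    )
    if mode == "mean":
        return inner / l
    if inner <= 0.0:
        return -math.inf
    return math.log2(inner) / l


def mua_search(
    sequences: list[str] | tuple[str, ...],
    background: np.ndarray | None = None,
    mode: str = "literal",
) -> MuaResult:
    """Exhaustive seed search for the best multiple ungapped alignment.

    Every substring of every sequence, at every length between the
    shortest and longest sequence, seeds a gapless overlay: per
    sequence (long enough to contain the seed) the best-scoring,
    leftmost window joins the alignment.  The alignment maximising the
    consensus likelihood wins; ties favour more columns, then the
    earlier seed (sequence index, offset).
    """
    if not sequences:
        raise ValueError("empty sequence set")
    seqs = list(sequences)
    n_total = len(seqs)
    l_min = min(len(s) for s in seqs)
    l_max = max(len(s) for s in seqs)
    best: MuaResult | None = None
    for l in range(l_min, l_max + 1):
        seen: dict[str, tuple[int, int]] = {}
        for i, s in enumerate(seqs):
            for j in range(len(s) - l + 1):
                sub = s[j : j + l]
                if sub not in seen:
                    seen[sub] = (i, j)
        for sub, (i, j) in sorted(seen.items(), key=lambda kv: kv[1]):
            members = []
            for u, s_u in enumerate(seqs):
                win = _best_window(sub, s_u)
                if win is not None:
                    members.append(s_u[win[0] : win[0] + l])
            pswm = build_pswm(members, n_total, background)
            cons = consensus_of(pswm)
            lik = pswm_likelihood(pswm, cons, mode=mode)
            cand = MuaResult(
                pswm=pswm, length=l, consensus=cons, likelihood=lik, seed=(i, j)
            )
            if best is None or _mua_better(cand, best):
                best = cand
    assert best is not None
    return best


def _mua_better(a: MuaResult, b: MuaResult) -> bool:
    """Tie cascade: likelihood, then more columns, then earlier seed."""
    if a.likelihood != b.likelihood:
        return a.likelihood > b.likelihood
    if a.length != b.length:
        return a.length > b.length
    return a.seed < b.seed


def call_indel(
    column: SiteColumn, params: ModelParams | None = None
) -> VariantRecord | None:
    """Candidate screen plus MUA consensus, emitted as an anchored
    VCF-style record.

    Insertions and deletions at a mixed site are pooled separately and
    the better-supported kind is called (insertions win exact ties).
    Zygosity is heuristic: indel-supporting read fraction at or above
    ``hom_frac`` is reported homozygous, otherwise heterozygous.
    """
    if params is None:
        params = ModelParams()
    cand = detect_candidate(column, params)
    if cand is None:
        return None
    seqs = (
        cand.insertion_seqs if cand.kind == "insertion" else cand.deletion_seqs
    )
    mua = mua_search(seqs, mode=params.pswm_likelihood_mode)
    anchor = column.ref_base
    if cand.kind == "insertion":
        ref, alt = anchor, anchor + mua.consensus
    else:
        ref, alt = anchor + mua.consensus, anchor
    denom = max(column.depth, len(seqs), 1)
    frac = len(seqs) / denom
    gt = "1/1" if frac >= params.hom_frac else "0/1"
    return VariantRecord(
        chrom=column.chrom,
        pos=column.pos,
        ref=ref,
        alts=(alt,),
        genotypes=(gt,),
        depths=(column.depth,),
        vcos=(None,),
        confidence=None,
        filter_status="PASS",
        is_indel=True,
    )
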