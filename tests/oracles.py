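"""Independent brute-force reference implementations used as oracles.

Everything here is deliberately naive — linear-space products, explicit
loops, exact integer arithmetic — and shares no code path with the
package internals it checks.
"""

from __future__ import annotations

import math
from itertools import permutations

ALPHABET = ("A", "C", "G", "T")
GENOTYPES = ("AA", "CC", "GG", "TT", "AC", "AG", "AT", "CG", "CT", "GT")


def naive_weight(bq: float, mq: float) -> float:
    eb = 10 ** (-0.1 * max(bq, 0))
    em = 10 ** (-0.1 * max(mq, 0))
    return 1 - 2 * eb * em / (eb + em)


def naive_read_prob(base: str, genotype: str, bq: float, mq: float, alpha: float = 0.5) -> float:
    """Linear-space haplotype-mixture probability, flat miscall table."""
    w = naive_weight(bq, mq)

    def hap(g: str) -> float:
        return w if base == g else (1 - w) / 3.0

    return alpha * hap(genotype[0]) + (1 - alpha) * hap(genotype[1])


def naive_priors(ref: str, theta: float) -> dict[str, float]:
    priors = {}
    for g in GENOTYPES:
        n_ref = (g[0] == ref) + (g[1] == ref)
        if n_ref == 2:
            priors[g] = None  # fill after
        elif n_ref == 1:
            priors[g] = theta
        elif g[0] == g[1]:
            priors[g] = theta / 2
        else:
            priors[g] = theta * theta
    rest = sum(v for v in priors.values() if v is not None)
    for g in GENOTYPES:
        if priors[g] is None:
            priors[g] = 1 - rest
    return priors


def naive_posterior(
    reads: list[tuple[str, int, int]], ref: str, theta: float = 1e-3, alpha: float = 0.5
) -> dict[str, float]:
    """Direct Bayes over the ten genotypes for (base, bq, mq) reads."""
    priors = naive_priors(ref, theta)
    joint = {}
    for g in GENOTYPES:
        lik = 1.0
        for base, bq, mq in reads:
            lik *= naive_read_prob(base, g, bq, mq, alpha)
        joint[g] = lik * priors[g]
    total = sum(joint.values())
    return {g: v / total for g, v in joint.items()}


def naive_joint_posterior(
    normal_reads: list[tuple[str, int, int]],
    tumor_reads: list[tuple[str, int, int]],
    ref: str,
    theta: float = 1e-3,
    delta: float = 2.0,
    s: float = 1e-4,
    alpha: float = 0.5,
) -> dict[tuple[str, str], float]:
    """Direct Bayes over the 100 genotype pairs with the dependency prior."""
    priors = naive_priors(ref, theta)
    transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

    def change_weight(old: str, new: str) -> float:
        return delta / (1 + delta) if (old, new) in transitions else 0.5 / (1 + delta)

    def dep(gn: str, gt: str) -> float:
        a, b = list(gn), list(gt)
        removed, added = a.copy(), b.copy()
        for x in a:
            if x in added:
                added.remove(x)
                removed.remove(x)
        if not added:
            return 1 - s
        best = 0.0
        for perm in permutations(added):
            w = 1.0
            for old, new in zip(removed, perm):
                w *= change_weight(old, new)
            best = max(best, w)
        return (s ** len(added)) * best

    joint = {}
    for gn in GENOTYPES:
        row_norm = sum(dep(gn, gt) for gt in GENOTYPES)
        for gt in GENOTYPES:
            lik = priors[gn] * dep(gn, gt) / row_norm
            for base, bq, mq in normal_reads:
                lik *= naive_read_prob(base, gn, bq, mq, alpha)
            for base, bq, mq in tumor_reads:
                lik *= naive_read_prob(base, gt, bq, mq, alpha)
            joint[(gn, gt)] = lik
    total = sum(joint.values())
    return {k: v / total for k, v in joint.items()}


def hypergeom_fisher_greater(a: int, b: int, c: int, d: int) -> float:
    """Exact one-sided (greater) Fisher p-value for [[a, b], [c, d]]
    from the hypergeometric tail, in exact integer arithmetic."""
    row1 = a + b
    row2 = c + d
    col1 = a + c
    n = row1 + row2
    denom = math.comb(n, col1)
    p = 0
    for k in range(a, min(row1, col1) + 1):
        if col1 - k > row2:
            continue
        p += math.comb(row1, k) * math.comb(row2, col1 - k)
    from fractions import Fraction

    return float(Fraction(p, denom))


def brute_force_mua(sequences: list[str], eps_n: int | None = None):
    """Exhaustive seed enumeration of the best multiple ungapped
    alignment; returns (consensus, likelihood, length)."""
    n = len(sequences)
    if eps_n is None:
        eps_n = n
    l_min = min(len(s) for s in sequences)
    l_max = max(len(s) for s in sequences)
    best = None  # (lik, length, neg seed order) comparison handled manually
    for l in range(l_min, l_max + 1):
        for i, s in enumerate(sequences):
            for j in range(len(s) - l + 1):
                seed = s[j : j + l]
                members = []
                for u, su in enumerate(sequences):
                    if len(su) < l:
                        continue
                    best_score, best_v = None, 0
                    for v in range(len(su) - l + 1):
                        sc = sum(
                            1 if x == y else -1
                            for x, y in zip(seed, su[v : v + l])
                        )
                        if best_score is None or sc > best_score:
                            best_score, best_v = sc, v
                    members.append(su[best_v : best_v + l])
                counts = [
                    [sum(1 for m in members if m[col] == ch) for col in range(l)]
                    for ch in ALPHABET
                ]
                eps = 1.0 / (2 * eps_n)
                cons = []
                inner = 0.0
                for col in range(l):
                    ws = []
                    for ci, ch in enumerate(ALPHABET):
                        f = counts[ci][col] / len(members)
                        f = f if f > 0 else eps
                        ws.append(math.log2(f / 0.25))
                    wmax = max(ws)
                    ci = ws.index(wmax)
                    cons.append(ALPHABET[ci])
                    inner += wmax
                lik = math.log2(inner) / l if inner > 0 else -math.inf
                cand = (lik, l, (-i, -j))
                if best is None or cand > best:
                    best = cand
                    best_result = ("".join(cons), lik, l)
    return best_result
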