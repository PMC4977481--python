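"""Diploid genotype space over the DNA alphabet.

A diploid genotype is an unordered pair of alleles drawn from
``{A, C, G, T}``, giving ten distinct genotypes.  Relative to the
reference base at a site each genotype falls into one of four
categories: homozygous reference, heterozygous reference (one reference
allele, one alternative), homozygous variant (two copies of the same
alternative allele) and heterozygous variant (two distinct alternative
alleles).
"""

from __future__ import annotations

from enum import Enum

ALPHABET = ("A", "C", "G", "T")
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

# Canonical genotype order: homozygotes first, then heterozygotes in
# lexicographic allele order.  All tie-breaking in the callers resolves
# against this fixed ordering so results are platform-independent.
GENOTYPES = ("AA", "CC", "GG", "TT", "AC", "AG", "AT", "CG", "CT", "GT")
K = len(GENOTYPES)
GENOTYPE_INDEX = {g: i for i, g in enumerate(GENOTYPES)}

# allele index pairs per genotype, aligned with GENOTYPES
GENOTYPE_ALLELES = tuple(
    (BASE_INDEX[g[0]], BASE_INDEX[g[1]]) for g in GENOTYPES
)

_TRANSITION = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class GenotypeCategory(str, Enum):
    HOM_REF = "hom_ref"
    HET_REF = "het_ref"
    HOM_VAR = "hom_var"
    HET_VAR = "het_var"


def genotype_alleles(genotype: str) -> tuple[str, str]:
    """Return the unordered allele pair of a genotype string."""
    if genotype not in GENOTYPE_INDEX:
        raise ValueError(f"unknown genotype {genotype!r}")
    return genotype[0], genotype[1]


def canonical(allele1: str, allele2: str) -> str:
    """Canonical genotype string for an unordered allele pair."""
    a, b = sorted((allele1, allele2))
    g = a + b
    if g not in GENOTYPE_INDEX:
        raise ValueError(f"alleles {allele1!r}/{allele2!r} not in alphabet")
    return g


def category(genotype: str, ref_base: str) -> GenotypeCategory:
    """Category of ``genotype`` relative to the reference base."""
    a1, a2 = genotype_alleles(genotype)
    n_ref = (a1 == ref_base) + (a2 == ref_base)
    if n_ref == 2:
        return GenotypeCategory.HOM_REF
    if n_ref == 1:
        return GenotypeCategory.HET_REF
    if a1 == a2:
        return GenotypeCategory.HOM_VAR
    return GenotypeCategory.HET_VAR


def is_transition(x: str, y: str) -> bool:
    """True when x->y is a transition (A<->G or C<->T)."""
    return (x, y) in _TRANSITION


def alt_alleles(genotype: str, ref_base: str) -> tuple[str, ...]:
    """Distinct non-reference alleles of a genotype, in alphabet order."""
    return tuple(
        sorted({a for a in genotype_alleles(genotype) if a != ref_base})
    )
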