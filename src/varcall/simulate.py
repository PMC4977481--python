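"""Ground-truth-labelled synthetic pileup columns.

The generator emulates the statistical structure the calling models
assume, at the pileup level (no read sequences and no aligner):

* the reference base at each site is uniform over A/C/G/T;
* the germline genotype is drawn from the heterozygous-mutation-rate
  prior used by the caller;
* depth is Poisson with the requested mean coverage;
* each read picks a haplotype (probability ``alpha`` for the first)
  and its base is flipped, uniformly to one of the other three bases,
  with the uniform per-base error probability; the base quality is the
  Phred encoding of that error rate and the mapping quality a fixed
  constant;
* tumor columns mix reads from the tumor genotype (with probability
  ``purity``) and the matched normal genotype;
* somatic mutations are implanted at a fixed fraction of sites, with
  the normal genotype forced homozygous reference and the tumor
  heterozygous for a novel allele; each implanted mutation is an indel
  (insertion or deletion, equiprobable) with probability
  ``indel_fraction`` and indel lengths follow 1 + a geometric number
  of extensions with continuation probability ``indel_ext``.

Because there is no read-level alignment step, benchmarks run on these
columns see none of the alignment noise real pipelines face; recovery
rates measured here are optimistic relative to read-level data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import IO, Iterable, Iterator

import numpy as np

from .genotypes import ALPHABET, BASE_INDEX, GENOTYPES
from .germline import genotype_priors
from .params import ModelParams
from .pileup_io import AlleleObservation, IndelObservation, SiteColumn

DEFAULT_MAPQ = 60


@dataclass(slots=True)
class TruthRecord:
    chrom: str
    pos: int
    normal_genotype: str
    tumor_genotype: str
    somatic: bool = False
    indel_kind: str | None = None  # "insertion" | "deletion" | None
    indel_seq: str | None = None


def _phred(error_rate: float) -> int:
    if error_rate <= 0:
        return 60
    return int(round(-10.0 * math.log10(error_rate)))


def _apply_errors(alleles: np.ndarray, rng: np.random.Generator, error_rate: float) -> np.ndarray:
    """Flip each allele index to one of the other three with the error
    probability."""
    if error_rate <= 0 or alleles.size == 0:
        return alleles
    flip = rng.random(alleles.size) < error_rate
    shift = rng.integers(1, 4, size=alleles.size)
    out = alleles.copy()
    out[flip] = (out[flip] + shift[flip]) % 4
    return out


def _draw_reads(
    genotype: str,
    depth: int,
    rng: np.random.Generator,
    alpha: float,
    error_rate: float,
) -> np.ndarray:
    a1, a2 = BASE_INDEX[genotype[0]], BASE_INDEX[genotype[1]]
    hap = rng.random(depth) < alpha
    alleles = np.where(hap, a1, a2)
    return _apply_errors(alleles, rng, error_rate)


def _column(
    chrom: str,
    pos: int,
    ref: str,
    alleles: np.ndarray,
    strands: np.ndarray,
    bq: int,
    mapq: int,
    indels: list[IndelObservation] | None = None,
) -> SiteColumn:
    obs = [
        AlleleObservation(ALPHABET[a], bq, mapq, "+" if s else "-")
        for a, s in zip(alleles, strands)
    ]
    return SiteColumn(chrom, pos, ref, obs, indels or [], len(obs))


def _noisy_seq(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    idx = np.array([BASE_INDEX[c] for c in seq])
    idx = _apply_errors(idx, rng, error_rate)
    return "".join(ALPHABET[i] for i in idx)


def iter_germline(
    n_sites: int,
    coverage: float = 30.0,
    error_rate: float = 0.01,
    params: ModelParams | None = None,
    seed: int = 0,
    chrom: str = "sim1",
    start: int = 1,
    mapq: int = DEFAULT_MAPQ,
) -> Iterator[tuple[SiteColumn, TruthRecord]]:
    """Stream (column, truth) pairs for a single germline sample."""
    if params is None:
        params = ModelParams()
    rng = np.random.default_rng(seed)
    bq = _phred(error_rate)
    priors = {b: genotype_priors(b, params, mode="theta") for b in ALPHABET}
    refs = rng.integers(0, 4, size=n_sites)
    depths = rng.poisson(coverage, size=n_sites)
    for i in range(n_sites):
        ref = ALPHABET[refs[i]]
        g = GENOTYPES[rng.choice(10, p=priors[ref])]
        depth = int(depths[i])
        alleles = _draw_reads(g, depth, rng, params.alpha, error_rate)
        strands = rng.random(depth) < 0.5
        col = _column(chrom, start + i, ref, alleles, strands, bq, mapq)
        yield col, TruthRecord(chrom, start + i, g, g)


def simulate_germline(
    n_sites: int,
    coverage: float = 30.0,
    error_rate: float = 0.01,
    params: ModelParams | None = None,
    seed: int = 0,
    **kwargs,
) -> tuple[list[SiteColumn], list[TruthRecord]]:
    """Materialised form of :func:`iter_germline`."""
    cols, truths = [], []
    for col, truth in iter_germline(
        n_sites, coverage, error_rate, params, seed, **kwargs
    ):
        cols.append(col)
        truths.append(truth)
    return cols, truths


def iter_tumor_normal(
    n_sites: int,
    coverage: float = 30.0,
    error_rate: float = 0.01,
    purity: float = 0.9,
    somatic_fraction: float = 0.01,
    indel_fraction: float = 0.15,
    indel_ext: float = 0.3,
    params: ModelParams | None = None,
    seed: int = 0,
    chrom: str = "sim1",
    start: int = 1,
    mapq: int = DEFAULT_MAPQ,
) -> Iterator[tuple[SiteColumn, SiteColumn, TruthRecord]]:
    """Stream matched (normal column, tumor column, truth) triples."""
    if params is None:
        params = ModelParams()
    rng = np.random.default_rng(seed)
    bq = _phred(error_rate)
    priors = {b: genotype_priors(b, params, mode="theta") for b in ALPHABET}
    refs = rng.integers(0, 4, size=n_sites)
    depths_n = rng.poisson(coverage, size=n_sites)
    depths_t = rng.poisson(coverage, size=n_sites)
    somatic_flags = rng.random(n_sites) < somatic_fraction
    for i in range(n_sites):
        ref = ALPHABET[refs[i]]
        pos = start + i
        somatic = bool(somatic_flags[i])
        if somatic:
            g_normal = ref + ref
        else:
            g_normal = GENOTYPES[rng.choice(10, p=priors[ref])]

        indel_kind: str | None = None
        indel_seq: str | None = None
        g_tumor = g_normal
        if somatic:
            if rng.random() < indel_fraction:
                indel_kind = "insertion" if rng.random() < 0.5 else "deletion"
                length = int(rng.geometric(1.0 - indel_ext))
                indel_seq = "".join(
                    ALPHABET[j] for j in rng.integers(0, 4, size=length)
                )
            else:
                novel = (BASE_INDEX[ref] + int(rng.integers(1, 4))) % 4
                g_tumor = "".join(sorted((ref, ALPHABET[novel])))

        # normal sample reads
        dn = int(depths_n[i])
        alleles_n = _draw_reads(g_normal, dn, rng, params.alpha, error_rate)
        strands_n = rng.random(dn) < 0.5
        ncol = _column(chrom, pos, ref, alleles_n, strands_n, bq, mapq)

        # tumor sample reads: tumor genotype with probability purity
        dt = int(depths_t[i])
        from_tumor = rng.random(dt) < purity
        indels_t: list[IndelObservation] = []
        if indel_kind is None:
            a1t, a2t = BASE_INDEX[g_tumor[0]], BASE_INDEX[g_tumor[1]]
            a1n, a2n = BASE_INDEX[g_normal[0]], BASE_INDEX[g_normal[1]]
            hap = rng.random(dt) < params.alpha
            alleles_t = np.where(
                from_tumor,
                np.where(hap, a1t, a2t),
                np.where(hap, a1n, a2n),
            )
            alleles_t = _apply_errors(alleles_t, rng, error_rate)
        else:
            # indel haplotype: reference base plus the indel event
            alleles_t = _draw_reads(g_normal, dt, rng, params.alpha, error_rate)
            carries = from_tumor & (rng.random(dt) < params.alpha)
            for _ in range(int(carries.sum())):
                seq = (
                    _noisy_seq(indel_seq, rng, error_rate)
                    if indel_kind == "insertion"
                    else indel_seq  # deletions report reference bases
                )
                indels_t.append(
                    IndelObservation(
                        indel_kind, seq, "+" if rng.random() < 0.5 else "-"
                    )
                )
        strands_t = rng.random(dt) < 0.5
        tcol = _column(
            chrom, pos, ref, alleles_t, strands_t, bq, mapq, indels_t
        )
        yield ncol, tcol, TruthRecord(
            chrom, pos, g_normal, g_tumor, somatic, indel_kind, indel_seq
        )


def simulate_tumor_normal(
    n_sites: int,
    coverage: float = 30.0,
    error_rate: float = 0.01,
    purity: float = 0.9,
    somatic_fraction: float = 0.01,
    indel_fraction: float = 0.15,
    indel_ext: float = 0.3,
    params: ModelParams | None = None,
    seed: int = 0,
    **kwargs,
) -> tuple[list[SiteColumn], list[SiteColumn], list[TruthRecord]]:
    """Materialised form of :func:`iter_tumor_normal`."""
    ncols, tcols, truths = [], [], []
    for ncol, tcol, truth in iter_tumor_normal(
        n_sites,
        coverage,
        error_rate,
        purity,
        somatic_fraction,
        indel_fraction,
        indel_ext,
        params,
        seed,
        **kwargs,
    ):
        ncols.append(ncol)
        tcols.append(tcol)
        truths.append(truth)
    return ncols, tcols, truths


def render_mpileup(columns: Iterable[SiteColumn], out: IO[str] | str) -> None:
    """Write columns as 7-column mpileup text (with mapping qualities)
    that :func:`varcall.pileup_io.read_mpileup` round-trips exactly.

    Indel events are emitted immediately after successive read symbols
    (event k after read k); columns with indels but no reads cannot be
    expressed in the format and drop their events.
    """
    close = False
    if isinstance(out, str):
        out = open(out, "w")
        close = True
    try:
        for col in columns:
            out.write(render_mpileup_line(col))
    finally:
        if close:
            out.close()


def render_mpileup_line(col: SiteColumn) -> str:
    """One mpileup text line (with trailing newline) for a column."""
    n_obs = len(col.observations)
    if n_obs == 0:
        return f"{col.chrom}\t{col.pos}\t{col.ref_base}\t0\t*\t*\n"
    parts: list[str] = []
    quals: list[str] = []
    mapqs: list[str] = []
    for obs in col.observations:
        if obs.base == col.ref_base:
            parts.append("." if obs.strand == "+" else ",")
        else:
            parts.append(obs.base if obs.strand == "+" else obs.base.lower())
        quals.append(chr(min(obs.base_quality, 93) + 33))
        mapqs.append(chr(min(obs.mapping_quality, 93) + 33))
    # indel event k follows read k; any surplus follows the last read
    tokens: list[str] = []
    for k in range(n_obs):
        tokens.append(parts[k])
        if k < n_obs - 1:
            if k < len(col.indels):
                tokens.append(_indel_token(col.indels[k]))
        else:
            for ind in col.indels[k:]:
                tokens.append(_indel_token(ind))
    return (
        f"{col.chrom}\t{col.pos}\t{col.ref_base}\t{col.raw_depth}\t"
        + "".join(tokens)
        + "\t"
        + "".join(quals)
        + "\t"
        + "".join(mapqs)
        + "\n"
    )


def _indel_token(ind: IndelObservation) -> str:
    seq = ind.sequence if ind.strand == "+" else ind.sequence.lower()
    sign = "+" if ind.kind == "insertion" else "-"
    return f"{sign}{len(ind.sequence)}{seq}"


TRUTH_HEADER = (
    "chrom\tpos\tnormal_genotype\ttumor_genotype\tsomatic\tindel_kind\tindel_seq"
)


def write_truth(truths: Iterable[TruthRecord], out: IO[str] | str) -> None:
    close = False
    if isinstance(out, str):
        out = open(out, "w")
        close = True
    try:
        out.write(TRUTH_HEADER + "\n")
        for t in truths:
            out.write(
                f"{t.chrom}\t{t.pos}\t{t.normal_genotype}\t{t.tumor_genotype}\t"
                f"{int(t.somatic)}\t{t.indel_kind or '.'}\t{t.indel_seq or '.'}\n"
            )
    finally:
        if close:
            out.close()
        else:
            out.flush()


def read_truth(path_or_stream: IO[str] | str) -> list[TruthRecord]:
    close = False
    if isinstance(path_or_stream, str):
        stream = open(path_or_stream)
        close = True
    else:
        stream = path_or_stream
    try:
        header = next(stream).rstrip("\n")
        if header != TRUTH_HEADER:
            raise ValueError("unrecognised truth TSV header")
        truths = []
        for line in stream:
            chrom, pos, gn, gt, som, kind, seq = line.rstrip("\n").split("\t")
            truths.append(
                TruthRecord(
                    chrom,
                    int(pos),
                    gn,
                    gt,
                    som == "1",
                    None if kind == "." else kind,
                    None if seq == "." else seq,
                )
            )
        return truths
    finally:
        if close:
            stream.close()
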