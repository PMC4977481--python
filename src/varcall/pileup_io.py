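"""Pileup/mpileup/BAM input and VCF output.

The calling engines operate on one genomic site at a time, represented
as a :class:`SiteColumn`: the reference base plus every aligned base
observation (with base and mapping qualities and strand) and every
insertion/deletion event attached to reads covering the site.  This
module decodes the SAMtools mpileup and MAQ pileup text dialects into
``SiteColumn`` streams, offers an equivalent column stream straight
from an indexed BAM, and renders calls as VCF 4.2.

Coordinates are 1-based inclusive throughout, matching the native
convention of both pileup and VCF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

VALID_BASES = frozenset("ACGT")

# mpileup symbols that consume one character of the quality (and
# mapping-quality) strings
_QUAL_CONSUMING = frozenset(".,ACGTNacgtn*#><")


class PileupParseError(ValueError):
    """Malformed pileup/mpileup line; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


@dataclass(slots=True)
class AlleleObservation:
    """One aligned base at one site."""

    base: str
    base_quality: int
    mapping_quality: int
    strand: str  # "+" forward, "-" reverse

    def __post_init__(self) -> None:
        if self.base not in VALID_BASES:
            raise ValueError(f"base {self.base!r} outside A/C/G/T")
        if self.base_quality < 0 or self.mapping_quality < 0:
            raise ValueError("qualities must be non-negative")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")


@dataclass(slots=True)
class IndelObservation:
    """An insertion or deletion event attached to one read at one site.

    For deletions ``sequence`` holds the deleted reference bases; for
    insertions the inserted bases.
    """

    kind: str  # "insertion" | "deletion"
    sequence: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion"):
            raise ValueError(f"kind {self.kind!r}")
        if not self.sequence or any(c not in VALID_BASES for c in self.sequence):
            raise ValueError(f"indel sequence {self.sequence!r} invalid")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")


@dataclass(slots=True)
class SiteColumn:
    """All observations at one genomic site."""

    chrom: str
    pos: int  # 1-based
    ref_base: str
    observations: list[AlleleObservation] = field(default_factory=list)
    indels: list[IndelObservation] = field(default_factory=list)
    raw_depth: int | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.ref_base not in VALID_BASES:
            raise ValueError(f"ref base {self.ref_base!r} outside A/C/G/T")
        if self.raw_depth is None:
            self.raw_depth = len(self.observations)

    @property
    def depth(self) -> int:
        return len(self.observations)


@dataclass(slots=True)
class VariantRecord:
    """One VCF output row (possibly multi-sample)."""

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    genotypes: tuple[str, ...]  # VCF GT strings per sample
    depths: tuple[int, ...]
    vcos: tuple[float | None, ...] = ()
    confidence: str | None = None  # "high" | "low"
    somatic_type: str | None = None  # Wild|Somatic|LOH|Germline|Unknown
    filter_status: str = "PASS"
    is_indel: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        for alt in self.alts:
            if alt == self.ref:
                raise ValueError("ALT equal to REF")


def _decode_bases(
    bases: str,
    quals: str,
    mapqs: str | None,
    ref_base: str,
    default_mapq: int,
    line_number: int,
) -> tuple[list[AlleleObservation], list[IndelObservation]]:
    """Decode one mpileup read-bases field into observations and indels."""
    observations: list[AlleleObservation] = []
    indels: list[IndelObservation] = []
    qi = 0  # index into quals / mapqs
    i = 0
    n = len(bases)
    pending_start_mapq: int | None = None
    while i < n:
        c = bases[i]
        if c == "^":
            if i + 1 >= n:
                raise PileupParseError(line_number, "dangling '^'")
            # mapping quality of the starting read, Phred+33
            pending_start_mapq = ord(bases[i + 1]) - 33
            i += 2
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise PileupParseError(line_number, f"bad indel length after {c!r}")
            length = int(bases[i + 1 : j])
            seq = bases[j : j + length]
            if len(seq) != length:
                raise PileupParseError(line_number, "truncated indel sequence")
            strand = "-" if seq.islower() else "+"
            kind = "insertion" if c == "+" else "deletion"
            up = seq.upper()
            if all(b in VALID_BASES for b in up):
                indels.append(IndelObservation(kind, up, strand))
            i = j + length
            continue
        if c in _QUAL_CONSUMING:
            if qi >= len(quals):
                raise PileupParseError(
                    line_number, "base string longer than quality string"
                )
            bq = ord(quals[qi]) - 33
            if mapqs is not None:
                mq = ord(mapqs[qi]) - 33
            elif pending_start_mapq is not None:
                mq = pending_start_mapq
            else:
                mq = default_mapq
            qi += 1
            pending_start_mapq = None
            if c in ".,":
                observations.append(
                    AlleleObservation(ref_base, bq, mq, "+" if c == "." else "-")
                )
            elif c in "ACGTacgt":
                observations.append(
                    AlleleObservation(c.upper(), bq, mq, "+" if c.isupper() else "-")
                )
            # '*', '#', '>', '<', 'N', 'n': placeholders — no base observation
            i += 1
            continue
        raise PileupParseError(line_number, f"unexpected symbol {c!r}")
    if qi != len(quals):
        raise PileupParseError(
            line_number, "quality string longer than base string"
        )
    return observations, indels


def read_mpileup(
    stream: IO[str] | Iterable[str],
    min_base_quality: int = 13,
    min_mapping_quality: int = 0,
    default_mapq: int = 60,
    skip_errors: bool = False,
) -> Iterator[SiteColumn]:
    """Parse SAMtools mpileup text into SiteColumns.

    Expects the 6-column single-sample dialect (chrom, pos, ref, depth,
    read bases, base qualities) with an optional 7th mapping-quality
    column (``samtools mpileup -s``).  Observations below either quality
    floor are dropped but still counted in ``raw_depth``.  Columns whose
    reference base is not A/C/G/T are skipped.
    """
    for line_number, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) == 1:
            fields = line.split()
        try:
            if len(fields) not in (6, 7):
                raise PileupParseError(
                    line_number, f"expected 6 or 7 columns, got {len(fields)}"
                )
            chrom, pos_s, ref, depth_s, bases, quals = fields[:6]
            mapqs = fields[6] if len(fields) == 7 else None
            try:
                pos = int(pos_s)
                raw_depth = int(depth_s)
            except ValueError as exc:
                raise PileupParseError(line_number, str(exc)) from None
            ref = ref.upper()
            if ref not in VALID_BASES:
                continue
            obs, indels = _decode_bases(
                bases, quals, mapqs, ref, default_mapq, line_number
            )
            kept = [
                o
                for o in obs
                if o.base_quality >= min_base_quality
                and o.mapping_quality >= min_mapping_quality
            ]
            yield SiteColumn(chrom, pos, ref, kept, indels, raw_depth)
        except PileupParseError:
            if skip_errors:
                continue
            raise


def read_pileup(
    stream: IO[str] | Iterable[str],
    min_base_quality: int = 13,
    min_mapping_quality: int = 0,
    default_mapq: int = 60,
    skip_errors: bool = False,
) -> Iterator[SiteColumn]:
    """Parse 10-column MAQ pileup text into SiteColumns.

    Columns: chrom, pos, ref, consensus, consensus quality, SNP
    quality, max mapping quality, depth, read bases, base qualities.
    The consensus columns are ignored; the read-base dialect is shared
    with mpileup.
    """
    for line_number, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) == 1:
            fields = line.split()
        try:
            if len(fields) < 10:
                raise PileupParseError(
                    line_number, f"expected 10 columns, got {len(fields)}"
                )
            chrom, pos_s, ref = fields[0], fields[1], fields[2]
            depth_s, bases, quals = fields[7], fields[8], fields[9]
            try:
                pos = int(pos_s)
                raw_depth = int(depth_s)
            except ValueError as exc:
                raise PileupParseError(line_number, str(exc)) from None
            ref = ref.upper()
            if ref not in VALID_BASES:
                continue
            obs, indels = _decode_bases(
                bases, quals, None, ref, default_mapq, line_number
            )
            kept = [
                o
                for o in obs
                if o.base_quality >= min_base_quality
                and o.mapping_quality >= min_mapping_quality
            ]
            yield SiteColumn(chrom, pos, ref, kept, indels, raw_depth)
        except PileupParseError:
            if skip_errors:
                continue
            raise


def columns_from_bam(
    bam_path: str,
    fasta_path: str,
    region: str | None = None,
    min_base_quality: int = 13,
    min_mapping_quality: int = 0,
) -> Iterator[SiteColumn]:
    """Stream SiteColumns straight from a coordinate-sorted, indexed BAM.

    Equivalent to piping ``samtools mpileup`` output through
    :func:`read_mpileup` on the same reads.  Overlapping mates are both
    counted (naive pileup semantics) and duplicates are not filtered;
    these are the knobs on which this path may diverge from other
    pileup engines.
    """
    import pysam

    bam = pysam.AlignmentFile(bam_path, "rb")
    fasta = pysam.FastaFile(fasta_path)
    contig = None
    if region is not None:
        contig = region.split(":")[0]
        if contig not in bam.references:
            raise ValueError(f"contig {contig!r} not in BAM header")
        if contig not in fasta.references:
            raise ValueError(f"contig {contig!r} not in FASTA")
    try:
        for col in bam.pileup(
            region=region,
            truncate=region is not None,
            min_base_quality=0,
            min_mapping_quality=0,
            ignore_overlaps=False,
            ignore_orphans=False,
            compute_baq=False,
            max_depth=100000,
        ):
            ref = fasta.fetch(col.reference_name, col.pos, col.pos + 1).upper()
            if ref not in VALID_BASES:
                continue
            observations: list[AlleleObservation] = []
            indels: list[IndelObservation] = []
            raw = 0
            for pr in col.pileups:
                aln = pr.alignment
                strand = "-" if aln.is_reverse else "+"
                if not pr.is_del and not pr.is_refskip:
                    raw += 1
                    base = aln.query_sequence[pr.query_position].upper()
                    if base in VALID_BASES:
                        bq = aln.query_qualities[pr.query_position]
                        mq = aln.mapping_quality
                        if bq >= min_base_quality and mq >= min_mapping_quality:
                            observations.append(
                                AlleleObservation(base, bq, mq, strand)
                            )
                elif pr.is_del:
                    raw += 1
                if pr.indel > 0:
                    qp = pr.query_position
                    seq = aln.query_sequence[qp + 1 : qp + 1 + pr.indel].upper()
                    if seq and all(b in VALID_BASES for b in seq):
                        indels.append(IndelObservation("insertion", seq, strand))
                elif pr.indel < 0:
                    seq = fasta.fetch(
                        col.reference_name, col.pos + 1, col.pos + 1 - pr.indel
                    ).upper()
                    if seq and all(b in VALID_BASES for b in seq):
                        indels.append(IndelObservation("deletion", seq, strand))
            yield SiteColumn(
                col.reference_name, col.pos + 1, ref, observations, indels, raw
            )
    finally:
        bam.close()
        fasta.close()


_VCF_HEADER_LINES = [
    '##INFO=<ID=SS,Number=1,Type=String,Description="Somatic status (Wild/Somatic/LOH/Germline/Unknown)">',
    '##INFO=<ID=TYPE,Number=1,Type=String,Description="Variant type (snv/ins/del)">',
    '##FILTER=<ID=LowConfidence,Description="Variant confidence score between the low- and high-confidence thresholds">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Retained read depth">',
    '##FORMAT=<ID=VCOS,Number=1,Type=Float,Description="Variant confidence score (mean negative log substitution probability over genotype-supporting reads)">',
]


def write_vcf(
    records: Iterable[VariantRecord],
    sample_names: list[str],
    out: IO[str] | str,
) -> None:
    """Write records sorted by (chrom, pos) as VCF 4.2.

    Raises ``ValueError`` on unsorted input (positions must be
    non-decreasing within each chromosome block and chromosomes must
    not repeat).
    """
    close = False
    if isinstance(out, str):
        out = open(out, "w")
        close = True
    try:
        out.write("##fileformat=VCFv4.2\n")
        out.write("##source=varcall\n")
        for line in _VCF_HEADER_LINES:
            out.write(line + "\n")
        records = list(records)
        chrom_order: list[str] = []
        finished: set[str] = set()
        cur: str | None = None
        last_pos = 0
        for r in records:
            if r.chrom != cur:
                if r.chrom in finished:
                    raise ValueError("records not sorted: chromosome block repeats")
                if cur is not None:
                    finished.add(cur)
                cur = r.chrom
                last_pos = 0
                chrom_order.append(r.chrom)
            if r.pos < last_pos:
                raise ValueError("records not sorted by position")
            last_pos = r.pos
        for c in chrom_order:
            out.write(f"##contig=<ID={c}>\n")
        out.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names)
            + "\n"
        )
        for r in records:
            info_parts = []
            if r.somatic_type is not None:
                info_parts.append(f"SS={r.somatic_type}")
            info_parts.append(f"TYPE={'indel' if r.is_indel else 'snv'}")
            info = ";".join(info_parts) if info_parts else "."
            vcos = r.vcos if r.vcos else (None,) * len(sample_names)
            samples = []
            for s in range(len(sample_names)):
                gt = r.genotypes[s] if s < len(r.genotypes) else "./."
                dp = r.depths[s] if s < len(r.depths) else 0
                v = vcos[s] if s < len(vcos) else None
                vs = f"{v:.4f}" if v is not None else "."
                samples.append(f"{gt}:{dp}:{vs}")
            alt = ",".join(r.alts) if r.alts else "."
            out.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{alt}\t.\t"
                f"{r.filter_status}\t{info}\tGT:DP:VCOS\t" + "\t".join(samples) + "\n"
            )
    finally:
        if close:
            out.close()
        else:
            out.flush()
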