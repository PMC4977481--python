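# Methods

This document specifies the statistical model implemented by
`varcall`, the default parameter values and why they were chosen, and
the numerical conventions that make results reproducible.

Notation: Σ = {A, C, G, T}; γ is the reference base at a site; the ten
unordered diploid genotypes over Σ are written in the canonical order
AA, CC, GG, TT, AC, AG, AT, CG, CT, GT; transitions are A↔G and C↔T.

## Germline genotype model

Each site is summarised by its column of allele observations
X = (x₁, …, x_N), each x_j carrying a base, a Phred base quality B_q,
a Phred mapping quality M_q, and a strand. The likelihood of a
genotype G = (g¹, g²) is the product over reads of a haplotype
mixture:

    P(x | G) = α · P(x | g¹) + (1 − α) · P(x | g²)

with α the probability of sampling the first haplotype (default 0.5;
a strand-fraction-based α over a surrounding window is available via
`strand_alpha` but off by default). The haploid term is

    P(x | g) = ω            if x = g
             = (1 − ω) Φ[x, g]  otherwise,

where Φ is a substitution table over Σ (default: flat, 1/3 per
miscall) and ω folds both qualities into one read weight through the
harmonic mean of their error probabilities:

    ω = 1 − 2·e_b·e_m / (e_b + e_m),   e_b = 10^(−B_q/10),  e_m = 10^(−M_q/10).

Equal qualities collapse to ω = 1 − 10^(−q/10); e.g. B_q = M_q = 30
gives ω = 0.999. The genotype prior is built from the heterozygous
point-mutation rate θ (default 10⁻³): heterozygous-reference
genotypes get θ, homozygous-variant θ/2, heterozygous-variant θ², and
the homozygous-reference genotype the remainder (0.995497 at
θ = 10⁻³). Alternative prior modes: `flat` (uniform 1/10) and `titv`
(the θ prior with the non-reference mass reweighted toward
transitions by the δ ratio, total non-reference mass preserved). The
posterior is the normalised product of prior and likelihood; the call
is the maximum-a-posteriori genotype with ties broken by canonical
order.

## Variant confidence score (VCOS)

A called non-reference genotype is graded by the mean negative log
substitution probability over its supporting reads (reads whose base
appears in the genotype):

    VCOS = − (1/|R|) Σ_{x ∈ R} ln P_sub(x | γ)

where P_sub(x | γ) is 1 − θ when x = γ, S_ti = δθ/(1+δ) for a
transition away from γ, and S_tv = 0.5·θ/(1+δ) for a transversion
(at defaults: S_ti ≈ 6.667·10⁻⁴, S_tv ≈ 1.667·10⁻⁴). A genotype with
no supporting read scores 0. Thresholds:

* **Case 1** (heterozygous-reference genotype, e.g. AG with γ = A):
  HC = −½ ln((1 − θ)·S_ti) ≈ 3.6571 at defaults; the low-confidence
  threshold mixes in the relaxation parameters φ and ψ:
  LC = −½ ln(φ(1 − θ) · (ψ(1 − θ) + (1 − ψ)S_ti)).
* **Case 2** (no reference allele in the genotype, e.g. GG or CG):
  HC = −ln S_ti ≈ 7.3132; LC = −ln(ψ(1 − θ) + (1 − ψ)S_ti).

Scores ≥ HC classify `high`, ≥ LC `low`, below LC
`false_positive` (suppressed from output). Boundary comparisons use a
relative tolerance of 10⁻⁹ because clean columns land exactly on HC
up to floating-point rounding.

**φ default.** The model requires HC ≥ LC for both cases. At the
default θ and δ, Case 1 admissibility requires φ ≳ 0.54 — a naive
"midpoint" choice of φ = 0.5 violates the constraint and is rejected
at `ModelParams` construction. The default is φ = 0.75, the midpoint
of the admissible interval at default θ/δ; ψ defaults to 0.5, which
is admissible.

## Indel calling

A site with at least one indel event in its column is screened by two
one-sided Fisher's exact tests (α₁ = α₂ = 0.01, point-mutation rate
μ = indel rate μ_i = 10⁻³):

1. observed [n_var, n_ref] against expected
   [round(N·μ), N − round(N·μ)]; a *significant* substitution signal
   vetoes indel candidacy (the site is treated as a substitution
   site);
2. observed [n_indel, n_ref] against the analogous expectation under
   μ_i; only a significant indel signal makes the site a candidate.

The consensus sequence is then derived by a multiple ungapped
alignment (MUA) over the observed indel sequences S (insertions and
deletions pooled separately; the better-supported kind is called,
insertions winning exact ties): for every length l between the
shortest and longest sequence and every l-substring seed, the seed is
laid gaplessly over each sequence (+1 match / −1 mismatch; best
window, leftmost on ties), the resulting equal-length member set is
summarised by a position-specific weight matrix
W[i, j] = log₂(p[i, j] / q_i) with background q = 1/4, and the
consensus is the per-column argmax of W (ties to the first base in
A, C, G, T order). Zero frequencies are floored at ε = 1/(2·|S|)
*only* — positive frequencies are left untouched, so unanimous
columns keep p = 1 and W = log₂ 4 = 2, and the stored frequency
columns always sum to 1. The alignment likelihood is

    L = (1/l) · log₂( Σ_j W[consensus_j, j] ),

with L = −∞ when the inner sum is non-positive (log-odds may be
negative), ranking such alignments last; a mean-log-odds alternative
((1/l)·Σ_j W) is selectable via `pswm_likelihood_mode="mean"`. The
best MUA maximises L, ties favouring more columns (larger l), then
the earlier seed (sequence index, offset) — a fully deterministic
cascade. Zygosity is heuristic: indel-supporting read fraction
≥ `hom_frac` (default 0.75) reports homozygous. Records use the
left-anchored VCF convention (REF includes the base before a
deletion, ALT the base before an insertion).

## Somatic calling

Matched tumor–normal column pairs are synchronised by (chromosome,
position); a site present in only one stream is processed against a
zero-depth partner and, if its single-sample genotype is a confident
variant, reported with type `Unknown`.

**Subtraction analysis.** Both samples are genotyped independently.
If the normal is homozygous reference and the tumor carries a
high-confidence variant, the site is reported `Somatic` immediately.

**Joint analysis.** Otherwise the posterior over all 100 genotype
pairs is

    P(G^N, G^T | X, Y) ∝ P(X | G^N) · P(Y | G^T) · P(G^N) · P(G^T | G^N),

with both likelihoods from the germline model and a dependency prior
whose rows put mass ∝ 1 − s on G^T = G^N, ∝ s·w on single-allele
changes, and ∝ s²·w on double changes, where s is `somatic_rate`
(default 10⁻⁴) and w the transition/transversion plausibility of the
changed alleles (δ/(1+δ) per transition, 0.5/(1+δ) per transversion;
ambiguous double changes take the most plausible pairing of removed
to added alleles). Rows are normalised; as s → 0 the matrix tends to
the identity. The tumor likelihood is treated as independent of G^N
given G^T; purity does not enter the likelihood, only the
post-processing threshold below.

**Post-processing** of the joint argmax pair, step by step per
sample:

1. a joint genotype that *disagrees* with its subtraction counterpart
   survives only with a high-confidence VCOS, otherwise it is demoted
   to homozygous reference;
2. a joint genotype that *confirms* the subtraction call passes a
   relaxed, depth-conditioned constraint instead: variant-supporting
   reads ≥ max(min_var_reads, ⌈f · depth⌉) with
   f = 0.5 · (expected het VAF = 0.5) · purity_eff · relax_factor,
   i.e. f = 0.25·purity for the tumor sample and 0.25 for the normal
   (purity applies to the tumor only; defaults min_var_reads = 2,
   relax_factor = 1). At 30× and purity 0.9 this demands 7 tumor
   variant reads — half the expected heterozygous somatic support;
3. a site where both genotypes fall to homozygous reference is
   discarded;
4. the surviving pair is typed from the genotype-category pair: with
   A = γ and B any non-reference allele, rows (normal) × columns
   (tumor) map as AA → Wild/Somatic/Somatic, AB → LOH/Germline/LOH,
   BB → Unknown/Unknown/Germline over columns AA/AB/BB. A
   heterozygous-variant normal genotype (two non-reference alleles,
   e.g. CG) uses the AB row when it shares an allele with the tumor
   genotype and the BB row otherwise; heterozygous-variant tumor
   genotypes use the BB column. Subtraction-stage calls re-enter only
   at this typing step. Wild-typed sites produce no record.

**Somatic indels** use an asymmetry rule: exactly one of the two
columns passes the two-test indel screen ⇒ report with the MUA
consensus from that sample — tumor-only as `Somatic`, normal-only as
`LOH` (mirroring the typing table); both or neither ⇒ no record.

**Purity.** A user-supplied purity is passed through unchanged. When
omitted, a clearly-labelled stand-in estimator takes the median, over
sites with a homozygous-reference normal genotype and a heterozygous
tumor variant above the false-positive confidence floor, of twice the
tumor variant-allele fraction, clamped to (0, 1] (default 1.0 with a
warning when no such site exists). The subtraction stage's
high-confidence gate is deliberately *not* used for selection: it
only passes sites with variant fraction ≥ 0.5, which would truncate
the distribution and bias the estimate toward 1 whenever true purity
is below 1.

## Synthetic data

The simulator works at pileup level — no read sequences and no
aligner. Per site: the reference base is uniform over Σ; the germline
genotype is drawn from the θ prior; depth ~ Poisson(coverage); each
read picks a haplotype with probability α and its base is flipped
uniformly to one of the other three with the uniform error
probability; B_q is the Phred encoding of the error rate (20 at 1%)
and M_q a constant 60. Tumor columns draw each read from the tumor
genotype with probability `purity`, else from the normal genotype.
Somatic sites are implanted at `somatic_fraction` of sites with the
normal genotype forced homozygous reference and the tumor
heterozygous for a novel allele; each implanted mutation is an indel
(insertion or deletion, equiprobable) with probability
`indel_fraction`, with length 1 + Geometric(`indel_ext`) and a
uniform random sequence (insertion sequences are re-noised per
carrying read; deletion sequences report reference bases verbatim).
Defaults are the study conditions: coverage 30, error 0.01, purity
0.9, somatic fraction 0.01, indel fraction 0.15, extension 0.3.
Everything derives from one seed; equal seeds give byte-identical
mpileup output.

Because alignment noise is absent, recovery rates measured on this
generator are optimistic relative to read-level pipelines; published
read-level figures therefore serve as conservative lower bounds for
the acceptance run (`scripts/acceptance.py`).

## Numerical and interface conventions

* All likelihood work is in log space; per-(B_q, M_q) 4×10 log
  probability matrices are cached and columns are reduced to grouped
  observation counts, which makes the 200,000-site studies run in
  about a minute each.
* Deterministic tie-breaking everywhere: canonical genotype order for
  posterior argmaxes, Σ order for PSWM consensus columns, the
  (likelihood, length, seed) cascade for MUAs.
* mpileup parsing implements the full read-base dialect (`.`/`,`,
  case-coded substitutions, `^X` read starts carrying the next
  read's mapping quality, `$`, `+n`/`-n` indels, `*` placeholders
  consuming a quality but no observation). Observations below the
  quality floors (defaults B_q ≥ 13, M_q ≥ 0) are dropped but remain
  in the raw depth. Columns with a non-ACGT reference base are
  skipped.
* VCF 4.2 output is plain text with GT/DP/VCOS per sample, INFO keys
  SS (somatic type) and TYPE, and a LowConfidence FILTER; it is
  verified in the test suite with an independent parser (cyvcf2).
* Exit codes: 0 success, 1 data errors, 2 usage errors.

## Resolved design questions

* **φ = 0.75 default** — see above; φ = 0.5 is inadmissible under
  HC ≥ LC.
* **Likelihood guard** — the literal L = (1/l)·log₂(ΣW) form is the
  default, with −∞ for non-positive inner sums; the mean-log-odds
  form is available by configuration.
* **PSWM floor** — applied to zero frequencies only, preserving the
  unanimous-column identities p = 1, W = 2.
* **Dependency prior** — the s-parametrised Ti/Tv-weighted matrix
  described above; its limits (identity as s → 0, row normalisation)
  are tested.
* **Relaxed-constraint fraction** — f = 0.25·purity (half the
  expected heterozygous variant fraction), depth-proportional with an
  absolute floor of 2 reads.
* **Typing of heterozygous-variant genotypes** — shared-allele
  routing as described under post-processing step 4.
* **Subtraction calls and post-processing** — subtraction-stage
  Somatic calls re-enter at the typing step only.
* **Purity estimator selection gate** — false-positive floor rather
  than the high-confidence gate, to avoid truncation bias.
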