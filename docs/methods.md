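# Methods

## Problem setting

Two dissected components of one tumour (labelled `Neg` and `Abr`, for
E-cadherin-negative and aberrant/positive in the motivating lobular
breast cancer setting) are each sequenced against one matched normal.
The pipeline decides whether the components are clonally related by
combining the overlap of their consensus somatic callsets with
mutational-signature profiles, ploidy-adjusted copy-number gene states
and differential promoter methylation. All statistics are per pair; no
cross-patient modelling is attempted.

## Generative model of the simulator

The synthetic-data module is first-class: it defines the conditions
under which every downstream stage is validated.

**Reference.** A uniform-random multi-contig sequence (default 5 contigs,
here run at 0.2–1 Mb each) written as indexed FASTA. Mutation placement
is conditioned on context: for each SNV a 96-channel trinucleotide class
is drawn from the configured signature mixture, and the site is sampled
uniformly from the reference positions carrying that pyrimidine-centred
trinucleotide, so the emitted callset's context spectrum converges to the
mixture by construction. Sites are never reused.

**Clonal structure.** Of `n_mutations_total` mutations per component,
`round(trunk_fraction · n)` are truncal (present in both components,
cancer-cell fraction 1) and the rest private; optional subclones add
private mutations at a configured cellular fraction. Truncal mutations
draw contexts from a `truncal` mixture (defaulting to the Neg mixture),
private mutations from per-component mixtures, so signature-divergent
pairs can be generated. `trunk_fraction = 0` produces the
independent-collision regime.

**Reads.** The expected VAF of a clonal diploid-heterozygous mutation is
`purity · CCF / 2`. Per site, tumour depth is Poisson around
`mean_depth_tumour` (Poisson chosen for realistic dispersion at
negligible cost) and the alt count binomial at that depth; the normal
has Poisson depth and zero alt reads except for a small
`normal_contamination_fraction` given 3–6 normal alt reads (exercising
the normal-alt filter). Defaults: purity 0.7 per component (a typical
macrodissected-tumour value; the purity of the motivating samples is not
published, so it is a free parameter), tumour depth 80×, normal 40×.

**Callers.** Three callers are emulated positionally
(`callerA`/`callerB` call SNVs and indels, `callerC` SNVs only). Each
caller sees the same simulated reads; a call is emitted with probability
`sensitivity`, its reported AF is the observed alt fraction plus
Gaussian noise (`vaf_noise_sd`). False positives are caller-private SNVs
with truth VAF 0 and 1–4 stray tumour alt reads — they can never reach
two-caller consensus and are additionally caught by the alt-read filter.
Indels are 1–5 bp insertions/deletions emitted in left-aligned
parsimonious form.

**Annotations.** Population AF, functional class and gene are attached
per variant so that every filter rule sees both passing and failing
records: a `common_variant_fraction` of mutations get population
AF ∈ [0.02, 0.2], a `synonymous_fraction` of genic SNVs are synonymous,
and a `multiallelic_fraction` of SNVs are written as genuine two-ALT VCF
records. These properties attach to the variant (not the component), so
their removal is symmetric and does not bias the overlap coefficient.

**Copy number.** Segments tile each contig at `segment_length` with
baseline total CN `round(ploidy)` and minor CN `total // 2`; planted
events are carved out exactly over their gene's interval, supporting
loss, LOH and copy-neutral LOH at ploidy 4.

**Methylation.** Each probe has one underlying beta value drawn
bimodally — scaled Beta(2,5) in [0, 0.2] (unmethylated mode) or
0.4 + 0.55·Beta(5,2) (methylated mode) — plus independent per-sample
Gaussian noise (sd 0.02). Keeping the background clear of the 0.3
status threshold reflects the strongly bimodal beta distribution of
real arrays and makes the planted set the exact differential set:
planted discordant probes get one component in [0.5, 0.8] and the other
in [0.05, 0.2] (opposite status and delta ≥ 0.1 by construction, with
> 5 sd of margin against the noise). Small fractions of probes fail
detection p-value, sit on chrY, or carry SNP/cross-reactive flags.

**Determinism.** All draws flow from one `numpy` Generator seeded from
the config (the methylation stage derives its stream from the same seed
so it is invariant to call order); identical config and seed give
byte-identical files.

## Consensus and normalization

Variant identity is `(chrom, pos, ref, alt)` after vt-style
normalization: shared trailing bases are trimmed (left-extending from
the reference when an allele empties) and shared leading bases trimmed
to parsimony. The operation is idempotent and maps left- and
right-aligned indel representations to one key. SNVs need support from
≥ 2 of the 3 SNV callers; indels from both indel-capable callers.
Resolved VAF follows caller precedence (callerA, then callerB, else
alt/depth recomputed). Multiallelic records are retained at parse time
and removed by the first filter rule, preserving the stated rule order.

## Filter chain

Six pure predicates applied in fixed order with first-failure
attribution: multiallelic; population AF > 0.01 (missing AF treated as
0, i.e. kept); VAF < 0.01 (boundary kept); depth < 10 — read strictly as
*require both* tumour and normal ≥ 10, with `depth_rule: either` as the
lenient alternative; tumour alt < 5 or normal alt > 2 (both boundaries
inclusive on the keep side); synonymous (exonic annotation only, so
promoter/intronic/intergenic variants survive this rule). Because each
rule is a pure predicate the surviving set is order-independent; only
the attribution depends on order.

## Pair statistics

The overlap coefficient `|A ∩ B| / min(|A|, |B|)` is computed on
filtered consensus keys, separately per variant class, and defined as 0
when either set is empty (avoiding 0/0). The relatedness call is an
explicit heuristic: SNV overlap ≥ 0.3 → clonally related, < 0.1 →
independent, else indeterminate; both thresholds sit in config because
the underlying evidence is qualitative. Six-class substitution spectra
fold purine-reference SNVs to the pyrimidine strand.

Per-gene recurrence between two groups of samples counts carriers
(excluding intergenic/upstream/downstream variants), drops genes with
absolute carrier-count difference < 3, and tests the rest with a
continuity-corrected chi-squared two-proportion test (numerically
identical to R's `prop.test`; Fisher's exact available by option).
Benjamini–Hochberg q-values are reported alongside raw p as an
extension.

## Signatures

Profiles are raw counts over the 96 channels in COSMIC order
(substitution class major, then 5′ and 3′ base alphabetical); cosine
similarity is scale-invariant so no normalization is applied. The
bundled catalogue is **synthetic**: 12 columns named for the breast-
cancer signatures (SBS1/2/3/5/6/8/13/17/18/20/26/30) built from their
canonical channel enrichments (e.g. SBS1 concentrated at N[C>T]G, SBS2
at T[C>T]N) with seeded jitter — adequate for recovery and ordering
tests, not a substitute for the real catalogue, which loads from any
96 × S TSV; a checksum of the catalogue used is recorded in outputs.
Similarity matrices are clustered with complete linkage on Euclidean
distances over both dimensions. Signature *fitting* (NNLS, de novo
extraction) is out of scope.

## Copy number

A gene overlapping several segments takes the one covering most of its
bases (ties to the lower-coordinate segment; overlap measured in bases
rather than fraction of gene length, switchable). Effective state is the
ratio `total_cn / ploidy` against thresholds 0.75 / 1.25 / 2.0 — no
published formula exists for this adjustment, so the rule was chosen to
(a) reduce exactly to conventional diploid calls at ploidy 2 and (b)
call total CN 4 at ploidy 4 copy-neutral (the anchoring tetraploid
case); thresholds are configurable. LOH is `minor_cn == 0` with
`total_cn > 0`. Purity is carried but unused (segments are assumed
purity-corrected upstream, as ASCAT-style output is).

## Methylation

Status is dichotomised at beta > 0.3 (strict), differential promoter
probes require opposite status and |Δ| ≥ 0.1 on raw betas. Promoter
membership is an input annotation (TSS1500/TSS200/5′UTR by EPIC
convention is the intended use); SNP/cross-reactive exclusions are input
flags because the published lists are external data. The per-gene
"promoter methylated" call (> 50 % of promoter probes methylated) is an
artifact-level summary rule, configurable.

## Subclone detection

A k-component binomial mixture on (alt, depth) fitted by EM
(deterministic k-quantile initialization, log-space responsibilities,
success probabilities clipped to [1e-6, 1−1e-6], convergence at relative
log-likelihood change < 1e-8, ≤ 300 iterations), with k ∈ {1..k_max}
selected by BIC (2k−1 parameters). It refuses fewer than 20 variants or
all-zero alt counts. This is intentionally a simplified clonality
readout: it has no neutral power-law tail component and does not adjust
VAF for local copy number, so it under-models neutrally evolving tails
present in real WGS data.

## What passing tests do and do not show

The simulator reproduces the *structure* of the real data (shared/private
clonal architecture, signature mixtures, caller behaviour, plantable CNA
and methylation events) but not read-level artifacts: no alignment error,
strand bias, FFPE damage, germline leakage beyond the injected
contamination, subclonal copy number, or array batch effects. Recovery
results therefore validate the pipeline's correctness and statistical
behaviour under its stated model, not caller accuracy on real reads.
Problem sizes used by the test suite and acceptance script — 2,000
mutations per component over 20–50 replicate seeds for trunk recovery,
20,000 draws for signature convergence, 10,000 probes with 100 planted
events, 100 mixture-fit replicates — were chosen as the smallest sizes at
which the binomial/multinomial sampling noise is comfortably below the
tolerances being checked.

## Known limitations

- The consensus rule is positional (which callers define the indel pair
  is configuration, not inference).
- The recurrence test needs groups of multiple samples; a single pair
  yields no testable genes by construction.
- The relatedness call is a threshold heuristic on one statistic; it is
  surfaced in config precisely because it is not a fitted model.
- Overlap coefficients are computed on filtered callsets by default
  (switchable); very small filtered sets make the coefficient noisy.
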