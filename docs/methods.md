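# Methods

## Haplotype blocks from phased VCFs

Linked-read pipelines emit per-sample VCFs whose heterozygous genotypes
are phased (`0|1`) and grouped by the FORMAT/PS phase-set tag with a
per-call phase quality PQ.  A call enters a block iff it is heterozygous,
phased, and `PQ ≥ 23` (the threshold above which assignment to a haplotype
is considered reliable); the threshold is applied *before* stitching, and
both it and the ordering are parameters.  Homozygous-alt calls carry no
phasing information and are re-attached to both haplotypes at vector
extraction (`hom_calls`).

**Stitching.**  When one sample's phasing breaks inside the window but a
matched sample (e.g. the tumor of a tumor/normal pair) phases across the
gap, two adjacent blocks are merged using the bridge block's alleles.  The
relative orientation of each target block against the bridge is taken
from majority allele agreement over shared het sites; a merge requires
`≥ 3` informative sites per side and `≥ 0.9` agreement (tolerating one
genotyping error while refusing 50/50 ambiguity).  Stitching only
concatenates and possibly swaps hap1/hap2 of one side; allele values and
the multiset of (site, unordered genotype) are conserved, and this is
asserted as an invariant test.

**Haplotype vectors.**  Vectors are 0/1 over the panel's site list
restricted to the closed window `[focal − 100 kb, focal + 100 kb]`
(inclusive bounds being the simplest defensible reading of "±100 kb").
Window sites absent from a sample's calls are imputed as reference,
consistent with per-sample callers not emitting homozygous-reference
records.  The haplotype carrying the focal alt allele is labeled mutant;
when neither does, both are wild-type.

## Fine-mapping by haplotype contingency

For each site, the 2×2 table (mutant blocks carrying / not carrying,
wild-type blocks carrying / not carrying) is tested with a one-sided
Fisher's exact test, `p = P(X ≥ a)` under the hypergeometric null with
all margins fixed, evaluated through scipy's log-space survival function.
Only enrichment on the mutant haplotypes is tested — the hypothesis is
directional by design — and raw p-values are reported without correction
(a Bonferroni column is included as information only).  Ties are broken by
genomic position.  Correctness is pinned two ways: exhaustive agreement
with exact rational-arithmetic enumeration for every table with `N ≤ 12`,
and null calibration (the fraction of sites with `p ≤ α` stays at or
below `α` — the test is conservative because the support is discrete).

## PCA engine

Column-mean-centered SVD via `numpy.linalg.svd`; no variance scaling by
default, so 0/1 haplotype columns are treated as-is (the conventional
default of R's `prcomp`).  At most `min(10, rank)` components are
returned.  Component signs are fixed by forcing the largest-magnitude
loading of each component positive, making scores reproducible across
runs; the engine is checked against an explicit covariance
eigendecomposition oracle, the reconstruction identity
`scores · loadingsᵀ = centered input`, and row-permutation invariance.
Genotype-PCA site filters: MAF ≥ 0.05 and missing fraction < 0.1 on the
combined cohort; missing dosages are imputed to the site mean
(frequency-preserving).  Ancestry assignment is nearest panel centroid in
the PC2/PC3 subspace (the components that separate the major
populations), ties to the lexicographically smaller label.  Cohort and
panel haplotypes enter the joint PCA unweighted.

## SV junction chemistry

Microhomology is defined by split ambiguity.  With `A` = longest contig
prefix matching the left-flank suffix and `B` = longest contig suffix
matching the right-flank prefix (flanks anchored at their breakpoints),
every split position in `[L − B, A]` explains the contig, so
`mh = A + B − L` (number of equivalent placements minus one; the leftmost
placement is canonical, and reporting is placement-invariant).  If
`A + B < L` the uncovered middle is an untemplated insertion with
`mh = 0`.  The scan ceiling for homology or insertion is 20 bp
(configurable); beyond it, or when a flank fails to match at all, the
contig is "unalignable".  The classifier is validated by exhaustive
enumeration of flank attributions on 1,000 designed events (100%
class-and-length agreement required).

**Breakpoint coordinates.**  A breakpoint is the 1-based position of the
last retained reference base; annotation queries the junction *boundary*
immediately after that base against 0-based half-open BED intervals, so a
breakpoint whose position equals an interval's exclusive end does not
overlap it.  When several repeats overlap, the class with the largest
overlap (ties lexicographic) is reported.  "Transcribed" means genic with
expression ≥ 1 TPM by default; the threshold is a parameter because
RNA-evidence cutoffs are study-specific.

**Fusion transcripts.**  Orientation classes (sense-to-sense,
sense-to-antisense, sense-to-intergenic, antisense-origin) derive from
the strands of genes overlapping the two ends; the donor side is checked
for the canonical 5′-splice GT immediately 3′ of the junction on the
transcribed strand and the acceptor side for AG immediately 5′.
Percent identity of homologous partner genes is global alignment
(match +1, mismatch 0, linear gap −1) via Biopython's PairwiseAligner,
identity = matches / alignment columns.

## Filter cascades

Somatic: panel-of-normals blacklist (site in ≥ 2 normals) → VAF > 10%
(strict) → alt reads ≥ 6 → population AF ≤ 0.1% (removed when above).
Germline candidates: candidate gene ∧ disruptive consequence (splice,
frameshift, nonsense/stop-gain, deletion) ∧ population AF < 0.1%
(strict).  The inequalities' strictness is part of the contract and is
asserted at the boundaries.  Every input call appears exactly once in
retained ∪ removed-with-reason (first failing rule in cascade order), and
tightening any threshold can only shrink the retained set.

Kataegis: maximal runs of ≥ 6 SNVs with adjacent inter-mutation distance
≤ 1 kb — the field-standard definition — after position deduplication; a
rainfall table accompanies the clusters.  Trait enrichment:
`fold = (carriers/n)/freq` with a one-sided binomial tail; the population
trait frequency is an explicit parameter.  Sex inference: chrX:chrY read
ratio with the decision boundary at the geometric mean (≈12.65) of the
~40:1 female and ~4:1 male anchor ratios, flagged indeterminate within a
factor 1.25 of the boundary.  Absent genotype at a risk-allele site is
treated as homozygous reference and flagged.

## Synthetic data: what it emulates and what it does not

`syndata` encodes the study conditions as defaults: a 200-kb window with
the focal allele at its center and ~300 polymorphic sites; three
populations of 92 panel haplotypes each with 137 carriers total
(46+46+45); 14 diploid trait-carrier cohort cases (one mutant, one
wild-type haplotype each, two of them with a deliberately broken and
haplotype-swapped phase block bridged by an unbroken tumor file); 24 SV
events with a designed class mix (blunt 0.50, microhomology 0.29,
insertion 0.21 — the first two fractions follow the observed 12/24 and
7/24, the remainder is assigned to insertions since its composition was
not enumerated); somatic call sets of 40 real calls at fixed depth 80
(the order of the tumor coverage the filter defaults assume) with
binomial alt counts, 12 planted panel-of-normals artifacts, 10
common-variant leaks and 2 kataegis clusters of 8.

Background structure follows the Balding–Nichols model: per-site ancestral
frequency `p0 ~ Uniform(0.05, 0.95)`, population frequency
`~ Beta(p0(1−F)/F, (1−p0)(1−F)/F)`, haplotypes Bernoulli.  `F = 0.01` by
default, the magnitude of pairwise F_ST among African subpopulations —
the relevant setting, since the three carrier groups represent regions
within Africa; the across-population frequency variance `F·p0(1−p0)` is
verified by Monte-Carlo.  Identity-by-descent cores (half-width 50 kb,
within the ±100 kb analysis window) are copied verbatim from one template
haplotype per population, with the focal allele set on carriers only;
verbatim copying reproduces the tight within-group clustering that
motivates the haplotype PCA, and mutation/recombination decay of cores is
deliberately not modelled.  SV designs are resampled whenever a chance
homology extension would make the constructed contig classify differently
from its design, so every truth record is unambiguous by construction.

Consequently, passing tests demonstrate recovery of planted structure
under this model — they do not establish performance on real data with
recombination-eroded cores, genotyping error, allele-frequency spectra
shaped by demography, or read-level artifacts; none of those are
simulated (no coalescent, no FASTQ/BAM, no barcode model).

## Problem sizes and numerical choices

The recovery experiments use 20 seeds for haplotype-PCA clustering (full
panel, k-means k=3 on PC1/PC2, adjusted Rand index ≥ 0.9 against the
population truth, with wild-type haplotypes as the negative control),
100 seeds for fine-mapping rank-1 recovery (panels of 20 haplotypes per
population, 8 carriers each, 14 cohort cases), and 10,000 independent
site-tests for null calibration — sizes chosen so the full suite and the
acceptance script each complete in seconds while keeping Monte-Carlo
error well inside the asserted margins.  Exact-test agreement is checked
exhaustively rather than sampled (all 1,819 tables with `N ≤ 12`).
Floating-point comparisons use relative tolerances of 1e-8–1e-12
depending on the identity asserted; the SVD rank cutoff is
`max(dim) · eps · s₁`.

## Known limitations

- Stitching merges greedily left-to-right; pathological bridge sets that
  support conflicting merges are resolved in position order, not
  globally.
- The junction model assumes the contig orientation matches both flanks
  as given; inversion-type junctions must be pre-oriented by the caller.
- Percent identity between co-optimal alignments is taken from the
  aligner's first reported optimum; ties can differ in identity by a few
  percent.
- The genotype-PCA path supports joint PCA only (no panel-fit/project),
  matching the analysis it reproduces.
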