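# Methods

This note documents the models and procedures famvar implements, the
assumptions behind the synthetic cohort that drives testing, the
numerical and design choices that were genuinely open, and what the
passing test suite does and does not demonstrate about real data.

## Analysis procedures

### Trio de novo SNV calling

The de novo rule operates on dual-caller trio records and uses strict
inequalities exactly as the thresholds are conventionally stated: read
depth DP > 9 in the child and both parents, child genotype quality
GQ > 20, child allele balance AB > 0.25, parental alternate read count
AO = 0, child heterozygous and parents homozygous reference in both call
sets. AB is computed as alt_reads / (ref_reads + alt_reads) from the AD
field — the standard definition and the one the filter's semantics
assume. A trio record with a missing parent can never be called de novo;
its carrier variants are routed to "unknown" origin, which is also where
carrier records land when both parents carry the allele (phase
unresolvable from transmission).

The upstream quality/rarity filter retains coding variants (consequences
PTV / missense / synonymous, with canonical-splice variants folded into
PTV by the annotation) with DP ≥ 10 and GQ ≥ 20 in the carrier child, a
PASS site filter, position outside an excluded-region set (emulating
HLA, mucin and olfactory-receptor clusters), and population MAF ≤ 0.1%
for monoallelic analyses or ≤ 1% for biallelic ones. DP > 9 and DP ≥ 10
are the same predicate on integer depths; both spellings appear in the
code deliberately, matching how each filter is usually quoted.

Severity bins partition retained coding variants: PTVs split at gene
LOEUF 0.6; missense at MPC 2 and 1; synonymous separate. A missense
variant lacking an MPC score is binned low with a logged warning rather
than dropped — it still counts toward totals. pdSNV = {PTV_LOEUF, DmisB,
DmisA}. The "severe" flag requires independent functional support:
LOFTEE high-confidence for PTVs, AlphaMissense likely-pathogenic for
DmisB. The pext brain-expression tiers are constitutive (> 0.9),
intermediate ((0.1, 0.9]) and low; only the upper cut is standard, the
0.1 lower edge was chosen so that published intermediate examples
(0.46, 0.69) fall in the middle band.

### CNV consensus and prioritization

Array consensus per sample: members must have confidence ≥ 10, size
≥ 1 kb and ≥ 3 probes; same-type calls cluster by single-linkage over
the ≥ 50% reciprocal-overlap relation (order-independent after sorting);
a cluster is kept when it contains the designated primary caller and at
least two distinct callers. The consensus interval is the union extent
(min start, max end) of its members — the "keep the largest boundaries"
reading — so the consensus always contains every supporting call.

The stringent rare filter keeps CNVs ≥ 10 kb that overlap at least one
exon and, when array-derived, have ≥ 5 probes; a CNV then passes either
as a recurrent-genomic-disorder (RGD) hit — covering ≥ 40% of a known
locus, measured one-sidedly over the locus — or as a clean rare event:
segmental-duplication and centromere overlap each < 50% of the CNV,
parental cohort frequency ≤ 1% at 50% reciprocal overlap, and > 75% of
the CNV inside the copy-number-stable map. The ≥ 5-probe rule applies
only to array-derived calls; WGS-only calls have no probes to count.

Inheritance: a same-type parental call at ≥ 50% reciprocal overlap
assigns paternal/maternal; no parental overlap at all means potentially
de novo; partial or type-mismatched overlap — and any missing parent —
yields "unknown" (the manual-review bucket of array workflows).
Array/WGS reconciliation pairs same-sample same-type calls at ≥ 50%
reciprocal overlap and keeps the WGS coordinates (read-depth callers
resolve boundaries far better than probe grids).

Prioritization precedence is LARGE (≥ 3 Mb) > RGD > DE_NOVO >
DOSAGE_SENSITIVE, so each CNV is reported once in its highest category.
"CDS-disrupting" is operationalized as: a deletion overlapping ≥ 1
coding exon, or any breakpoint strictly inside the CDS span (this also
captures intragenic duplications); dosage sensitivity requires
pHaplo ≥ 0.55 for disrupting events or pTriplo ≥ 0.68 for duplications
containing a gene's entire CDS. Tandem-vs-inverted duplication structure
(resolved by manual read inspection in array/WGS practice) is replaced
by the boolean full-CDS-containment test plus a fusion-candidate flag
(both breakpoints inside two different genes).

### Recessive and X-linked scans

Phase comes from parental transmission only. Two pdSNV alleles in one
gene form a trans pair when their origins are paternal + maternal, or
when one origin is unknown or de novo and the other is established;
same-parent pairs are assumed cis and never emitted, and
unknown + unknown pairs are not emitted. Deletion + pdSNV compounds
follow the same origin logic. `passes_strict` additionally requires zero
homozygotes in the reference population for every SNV allele and a
biallelic (or dual) gene mode of inheritance — the MOI is an input
column standing in for curated disease-gene panels. X-linked candidates
are hemizygous chrX pdSNVs/pdCNVs in affected males, outside the
pseudo-autosomal region, absent from every unaffected full brother
(half-siblings are not used for exclusion); absence in reference males
is annotated from a per-variant hemizygote count. Transmission balance
uses the exact two-sided binomial test against 1/2; zero informative
transmissions report p = 1.

### PRS and pTDT

QC removes SNPs with effect-allele frequency ≤ 1%, imputation INFO
≤ 0.8, or strand-ambiguous alleles (A/T, C/G). Clumping is greedy by
ascending association p (ties broken by chromosome and position); a
candidate is dropped when an already-retained SNP within 250 kb
(centre-to-centre) has r² > 0.1; the p ≤ 0.01 threshold applies last.
The r² provider is pluggable: a precomputed pair table or a genotype
reference matrix (the pipeline uses the cohort founders). Scores are
Σ dosage × ln(OR); natural-log weighting is the additive log-odds
convention of the standard scoring tools, and a switch restores raw-OR
weighting for comparison since the descriptions of such scores are often
ambiguous between the two. The pTDT deviation is
(child − midparent) / SD(midparent), with the SD taken over the tested
group's trios with the n−1 denominator; the test is a one-sample
two-sided t-test of zero mean. The statistic is invariant to shifting or
rescaling all scores.

### Cohort statistics and enrichment

Pearson chi-square on 2×2 tables is computed **without** Yates
continuity correction: only the uncorrected statistic reproduces both
published carrier-comparison p-values this pipeline is calibrated
against (0.28 and 0.03); with the correction they become 0.36 and 0.05.
Fisher tests are two-sided by the point-probability rule (sum of tables
with probability ≤ observed) and report the sample odds ratio ad/bc,
infinite when bc = 0. Group-mean tests are Welch (unequal variance),
two-sided. Reported p-values round to two decimals, or two significant
figures below 0.01.

Term enrichment is one-tailed hypergeometric over-representation against
an explicit background with Benjamini-Hochberg control across tested
terms (significant at q ≤ 0.01); term hierarchy is carried as parent
links for reporting but each term is tested independently. Edge
enrichment uses a density-based null: the observed within-query edge
count against a hypergeometric draw of C(q,2) pairs from all C(N,2)
pairs with the graph's edges as successes; expected = C(q,2) × density,
fold = observed/expected. Proprietary degree-corrected nulls of external
network services are not reproduced; only the statistic's form is.

## The synthetic cohort

The simulator emulates the study conditions of a ~116-family ASD cohort:
about 22% multiplex families (two, occasionally three, affected
children), affected children male with probability 110/144 (the ~3.2:1
male excess), Poisson(0.5) unaffected siblings per family, and a mean of
1.24 rare coding de novo variants per child. The default de novo
severity mix follows the published bin distribution in probands (≈ 5%
PTV in constrained genes, 7% other PTV, 7% DmisB, 11% DmisA, 43%
low-MPC missense, 26% synonymous, renormalized); the printed bin
percentages and pdSNV totals of the motivating cohort do not reconcile
exactly with one another, so the mix is treated as approximate, not a
calibration target. Inherited background variants (40 per family) sit
het in one parent and transmit with probability 1/2; ~30% are novel
(absent from reference populations) and a tail exceeds the rarity cuts
to exercise the filters. A configurable fraction of planted de novos is
given exactly one failing property (low DP, low GQ, low AB, parental
alternate reads, single-caller support, or a non-PASS site filter).

The genome is six 60-Mb autosomes plus chrX with regularly spaced
10-exon genes, fixed RGD loci, segmental-duplication and centromere
windows, a copy-number-stable map, a difficult-to-call excluded cluster,
and array probes on a 2-kb grid. CNV events are placed on genes drawn
without replacement cohort-wide, so private events stay private and the
1% parental-frequency filter behaves as it does in a real cohort of
~100+ parents; a polymorphic common deletion (≈ 8% of parents) exercises
that filter. Large (≥ 3 Mb) events are planted de novo only, matching a
cohort pre-screened by clinical array. Boundary jitter is Gaussian
(default SD 500 bp for array callers, 50 bp for the WGS caller),
truncated so start < end. The WGS caller covers ~90% of families and
only events ≥ 10 kb.

PRS inputs are simulated GWAS summary rows with LD blocks of 2-3
near-copy SNPs inside the clumping radius (block representatives carry
the low p-values, so clumping must pick them) and trio genotypes
transmitted from parental draws. A planted overtransmission of ``e``
midparent-SD units biases transmission at heterozygous effect-SNP sites
by delta = e·sqrt(Σw²pq)/(4Σ|w|pq) toward the risk allele (w = ln OR,
p = allele frequency, sums over the clump-surviving effect SNPs), which
makes the expected pTDT deviation equal ``e`` by construction.

All randomness flows from one seed through named, order-stable
substreams (genome, pedigree, SNV, CNV, PRS), so identical
configurations give byte-identical outputs and adding draws to one stage
never perturbs another.

**What the simulator does not model:** read-level data and sequence
context, realistic site-frequency spectra and LD beyond block-wise
correlation, mosaicism, genotyping batch effects, population structure,
and correlated caller errors. Passing recovery tests therefore
demonstrate the *logic* of the filters and scans — thresholds, caller
agreement, Mendelian bookkeeping, interval arithmetic, test statistics —
not calling performance on real sequencing data.

## Numerical and reporting choices

- Coordinates are 0-based half-open internally and in BED; VCF positions
  are 1-based. Male chrX genotypes are haploid in VCF ("0"/"1"); an alt
  count of 1 on a haploid call means hemizygous.
- Consensus clustering sorts by (sample, chromosome, type, start) before
  single-linkage, making cluster membership order-independent.
- Fisher two-sidedness uses a 1e-7 relative tolerance for floating-point
  ties between table probabilities (scipy's convention), verified
  against exact rational enumeration for all tables with n ≤ 12.
- Degenerate pTDT groups (fewer than two scored trios, or zero midparent
  variance — e.g. multiple trios sharing the same two parents) are
  reported as skipped rather than tested.
- Reports contain no timestamps; run logs record the package version,
  seed, thresholds and per-stage counts only, so report bundles are
  reproducible byte for byte.

## Problem sizes used in tests

The recovery and calibration checks run on simulated cohorts of 8-60
families: 60 families (≈ 120 parents) for the CNV recovery and de novo
recovery checks, so the 1% parental-frequency rule is exercised on its
natural scale; 100-trio replicates (1000 for the type-I error, 200 for
effect recovery) for the pTDT; 10-12 families for end-to-end determinism
runs. These sizes were chosen as the smallest at which each property is
measured on its natural scale.

## Known limitations

- The excluded-region, RGD, segmental-duplication and copy-number-stable
  sets are synthetic fixtures; swapping in real BED resources is
  supported by the same readers but untested against real annotation
  quirks (overlapping records, alternative contigs).
- X-linked CNV candidates are supported by the scan but the simulator
  plants only X-linked SNVs.
- The enrichment module's network null is density-based; degree-corrected
  nulls would need the external service's degree distribution.
- ACMG/InterVar evidence-code classification, ancestry inference and
  mitochondrial analyses are out of scope.
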