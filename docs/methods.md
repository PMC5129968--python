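# Methods

This note documents the models, parameter choices and numerical decisions
behind each stage of the package, and what the synthetic-data experiments
do and do not establish about real data.

## Study design and data model

The package targets the multiregion exome design: R regional biopsies of
one lesion (R = 3 by default) plus a matched normal. Inputs are
call-level: per-region somatic mutation call sets (VCF 4.2 or MAF-like
TSV), a per-site × region read-evidence table (alt/ref counts),
per-microsatellite repeat-length read histograms for tumor and normal,
and binned tumor/normal read depths with GC fraction. Alignment and
primary variant calling are upstream of this package.

Coordinates: mutation positions are 1-based (VCF convention); all
interval files (depth bins, gene models, chromosome arms) are 0-based
half-open. Conversions are centralized in `variants.to_zero_based` /
`to_one_based`.

## Joint genotyping (evidence rescue)

A mutation called in any region of a case is re-examined in every region:
a region is marked mutant when the caller reported it, or when its reads
meet all of `min_alt_reads >= 2`, `VAF >= 0.02`, `depth >= 10`. The
re-examination rule is deliberately evidence-threshold based, not
probabilistic. Two or more alt reads suppress isolated sequencing errors
(a single mismatching read at 100x with error rate 1e-3 is common; two at
the same site are not) while staying sensitive to clonal mutations at
purity ~0.7, whose expected VAF is ~0.35. Cells with depth below
`min_depth` are non-evaluable: they are excluded from a site's category
denominator (so low coverage cannot turn a clonal mutation into an
apparently shared one) but counted and reported, never silently dropped.
All three thresholds are configuration and echoed into output metadata.

Presence is monotone in the thresholds (relaxing any threshold can only
add marks), and rescue never invents a site: only sites in the union of
caller output are genotyped.

## ITH statistics

With R evaluable regions, a site is public when present in all R, private
when present in exactly one, shared otherwise; R = 3 gives the 3/2/1
scheme. The public fraction is (#public)/(#categorized). Mutation burden
is exonic mutations per Mb of capture target; the target size is
configuration with default 50 Mb (the nominal size of a standard 50 Mb
whole-exome capture; the true territory of a given kit differs by a few
percent, which is why it is exposed). The NS/S ratio counts missense +
nonsense + canonical-splice SNVs over synonymous SNVs; indels are excluded
from both sides because the ratio is an SNV selection statistic, and it is
reported as undefined (not infinity) without synonymous counts.

Functional classes: loss-of-function = nonsense, canonical ±2 splice, or
out-of-frame (frameshift) indel; in-frame indels are not LoF. A missense
call is a hotspot when its (gene, protein change) pair reaches
`hotspot_min_count` (default 5) occurrences in the supplied catalog.

## MSI calling

Per microsatellite, tumor and normal repeat-length histograms are
compared with the two-sample KS statistic over the pooled integer
support, D = max |F_T - F_N| evaluated after each distinct length
(computed in exact integer arithmetic as max |m·C_T - n·C_N| / nm). Loci
with fewer than `min_reads = 20` reads in either sample are untestable
and excluded from the multiple-testing family — KS at trivial depth is
meaningless. P-values:

* **asymptotic** (default): p = 2 Σ_{k≥1} (−1)^{k−1} exp(−2k²λ²) with
  λ = D√(nm/(n+m)), series truncated when terms fall below 1e-12. For
  equal sample sizes this limit is accurate to < 0.003 in the mid range
  at n = m ≥ 100 (measured against the exact conditional law); for
  unequal sizes it is conservative by up to ~0.03, which the optional
  `corrected=True` effective lambda (√ne + 0.12 + 0.11/√ne)·D repairs.
* **permutation**: the exact conditional test given the pooled histogram.
  Label permutations are sampled as multivariate hypergeometric tumor
  counts per length bin (equivalent to shuffling read labels, orders of
  magnitude faster on tied data), with add-one correction and integer
  statistic comparisons so ties with the observed D are handled exactly.

Repeat lengths are heavily tied integers, so the asymptotic test is
conservative under the permutation null; the permutation method is the
reference behavior in tests. Events are loci with Benjamini–Hochberg
FDR q < 0.05 (family = testable loci of one tumor–normal pair; the BH
step-up is delegated to statsmodels and checked against the literal
formula in tests). A genome with ≥ `msih_min_events = 20` events is
MSI-H. The published case counts this default separates (0–5 events for
MSS genomes vs 46 and 128 for MSI-H) leave a wide margin on both sides.

Case-level calling pools tumor reads across the regional biopsies against
the matched normal. Pooling was chosen a priori on power grounds: at the
simulated study conditions (below), pooled 3×100 vs 100 reads gives
sensitivity 0.93 at FDR < 0.05 over 10,000 loci, while a single region's
100 vs 100 gives 0.64. Per-region calling with a majority/any/all case
rule remains available.

## Copy number

Per-bin log2 ratio = log2((tumor/T)/(normal/N)) with T, N the library
totals, median-centered; bins with normal depth < 10 are masked. GC
correction subtracts the median log-ratio of each GC stratum (width
0.02; strata with < 50 bins merged into the nearest rich stratum), then
re-centers. Median-per-stratum correction assumes a copy-neutral majority
within each stratum — an aberration covering half the genome would be
partially absorbed; at realistic aberration fractions (tested at 25%)
step heights are preserved within 0.05.

Segmentation is an in-package CBS variant: per chromosome, find the arc
(i, j] maximizing |mean(arc) − mean(complement)| / √(1/k + 1/(n−k))
(the global sd cancels under permutation and is omitted), accept the
split when a seeded permutation test rejects at `alpha = 0.01` with both
parts ≥ `min_bins = 5`, recurse, then merge adjacent segments with
|Δmean| < `merge_tol = 0.1`. The permutation test is adaptive: it stops
early once the exceedance count already guarantees p ≥ alpha, and
accepts early (p = 1/(1+done)) after 500 clean permutations; draws are
seeded, so segmentation is deterministic given the seed. Spurious
alpha-level splits inside true segments occur at the expected ~1% rate
per test — as in any CBS — and are bounded by the flat-chromosome
false-split checks; planted breakpoints with gaps ≥ 5× the noise sd are
recovered within ±2 bins.

Gain/loss thresholds ±0.3 on the segment mean separate single-copy
events at purity ~0.7 (|log2| ≈ 0.43–0.62) from noise; a called segment
covering ≥ 80% of a chromosome arm is arm-level, otherwise focal. The
chromothripsis-like flag collapses segment means into discrete states
(single-linkage within `state_tol = 0.15`) and fires when a run of
consecutive segments alternates between exactly two states for ≥
`min_switches = 8` segments — a generalization of the single oscillation
pattern that motivated it; both knobs are configuration.

## Evolution

Spatial categories proxy temporal order: public events (trunk) precede
shared (branch) precede private; within a stratum no order is asserted.
Biallelic inactivation in a region requires two distinct LoF mutations,
or one LoF mutation plus a copy loss overlapping the gene (≥ 1 bp against
a supplied gene-model BED). Phase is unobservable in exome data, so two
LoF hits in one region are assumed to strike both alleles; the output
labels this as an assumption. Convergence requires ≥ 2 functional hits
(LoF mutation, hotspot missense, or copy loss) on one gene with disjoint
region sets. Pathway-level convergence is only reported when a
gene→pathway map is supplied.

The region tree is a greedy laminar family: observed region subsets are
accepted in decreasing mutation-count order (ties broken by
lexicographic region-set order, making output deterministic) when they
nest with everything accepted; conflicting subsets are flagged with the
accepted subset they cross, never silently resolved — mosaic cases are
expected to show such conflicts.

## Synthetic data

The generator emulates the study design with known ground truth: three
biopsies, purity 0.7 per region (the emulated study enrolled lesions
with purity > 70%; per-region purity is a free parameter), mean depth
100x (Poisson per site/bin), heterozygous diploid VAF = purity/2, and a
50/20/30 trunk/branch/private architecture by default. Read counts are
binomial with per-read alt probability vaf(1−e) + (1−vaf)e/3. Caller
dropout is discovery-conditioned: applied per (mutation, region), but
each mutation stays called in at least one region where it is present,
because a variant called nowhere is outside any pipeline's candidate
universe; dropout exists to exercise the rescue step.

Microsatellites use a symmetric triangular stutter null over the
reference length ± 2 units; unstable loci draw tumor reads from
(1 − slip_fraction)·null + slip_fraction·(null shifted by slip_shift).
Study conditions for MSI experiments — slip_fraction 0.5, slip_shift −2,
~100 reads per sample per region — represent an MSI-H lesion at purity
0.7 where most tumor cells carry a slipped allele, and were fixed a
priori from the power analysis quoted above. Depth tracks are Poisson
around mean·2^log2true with a differential GC bias 2^(amp·sin(2πgc))
applied to the tumor library only (a shared bias would cancel in the
ratio and leave nothing for GC correction to do).

What the simulations do not model: mapping artifacts and alignment
error, strand or context-specific sequencing error, germline
contamination, subclonal copy number, stutter that varies with repeat
unit and length, and inter-region purity variation (available but not
default). Passing recovery tests therefore demonstrates correctness of
the statistical machinery under the stated generative model, not
end-to-end accuracy on raw patient sequencing.

## Numerical and testing notes

* All randomness flows through seeded `numpy` generators; identical seed
  and configuration give byte-identical outputs (asserted in tests).
* KS statistics and permutation comparisons use integer arithmetic, so
  oracle comparisons are exact, not tolerance-based.
* The acceptance tests compare the asymptotic KS p against the exact
  conditional two-sample distribution (an independent implementation) on
  equal-size tie-free pairs at tolerance 0.02, with a B = 10⁴
  permutation-oracle cross-check on a subsample; a B = 10⁴ estimate has
  Monte-Carlo sd up to 0.005, which is why the noise-free exact law is
  the primary oracle.
* Degenerate inputs are errors, not silent results: all-absent presence
  rows, empty stutter profiles, zero capture size, all-masked depth
  tracks, unsorted bins, single-region trees.

## Known limitations

* The trunk/branch/private chronology is a partial order; it cannot time
  events within a stratum, and with R = 3 the branch stratum is coarse.
* Median-stratum GC correction degrades when aberrations dominate a GC
  stratum (see above).
* The MSS/MSI-H boundary (20 events) is a point threshold; genomes near
  the boundary should be reviewed with the per-locus table.
* CBS breakpoint resolution is bounded by bin size, and segment means
  are biased for segments shorter than `min_bins`.
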