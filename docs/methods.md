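# Methods

## Dosage model

At a SNP site diagnostic of the B subgenome, a cultivar carrying B dose
*d* of local ploidy *P* produces alternate reads as

    alt ~ Binomial(depth, (1 − ε)·d/P + ε·(1 − d/P))

with ε the per-read allele error (sequencing plus mapping), default
0.005. This single expression drives filtration expectations, the
frequency track, window classification and aneuploidy calling. With ε > 0
a fully substituted region (B3:A0) shows frequencies *near* 1 rather than
exactly 1, which matches observed data better than a noise-free model.

Diagnostic variants are not homogeneous: some are carried by every B copy
("shared", expected fraction d/P) while others are specific to a single B
subgenome ("hemi", expected fraction min(1, d)/P). This is why an
unrecombined two-B region shows a bimodal 1/3 + 2/3 frequency pattern and
why exchanged B3:A0 regions retain a residual low-frequency population.
The segmentation likelihood therefore models each candidate dose as a
two-component binomial mixture (default weights 0.75 shared / 0.25 hemi)
plus a small uniform outlier component (weight 0.05, density 1/(depth+1))
that bounds the influence of private mutations accumulated during
vegetative propagation. The hemi component is what gives the disomy test
its power: a disomic B2:A0 chromosome puts the hemi mass at 1/2, which no
trisomic dose grid can explain.

## Filtration

A site is kept only if no A-panel sample with depth ≥ `min_a_depth`
(default 10) shows an alternate fraction above `max_a_alt_fraction`
(default 0.05); sites the panel cannot assess at all are dropped as
unassessable rather than silently kept. The thresholds translate the
binary notion "monomorphic in the A genomes" into read-level evidence;
strictness deliberately errs toward discarding (the retained set must be
trustworthy, not complete). Replicates are pooled by summing depths, so
frequency estimates are weighted by evidence. Multi-allelic records keep
the highest-depth alternate only, because the frequency model is
biallelic.

## Segmentation and aneuploidy

Per-site log-likelihood vectors over the dose grid are summed in a
centred rolling window of 25 sites (an O(n) cumulative-sum
implementation; windows slide per site, so breakpoints resolve at site
granularity). Each site takes the arg-max dose of its window; runs of
equal dose become segments; runs spanning fewer than 10 genes (or 5
sites) are absorbed into whichever neighbour explains them better.
Breakpoints are snapped to the boundary between the flanking genes, so
segment intervals tile each chromosome and every anchored gene receives
exactly one (b_dose, a_dose, ploidy) via its midpoint. Genes on
unanchored scaffolds (`chr00`) are excluded with an audit tag.

Window and minimum-segment scales were chosen to resolve exchanges a few
tens of genes long while suppressing single-site noise; they are explicit
parameters (`SegmentationParams`). A likelihood grid was preferred over
an HMM because it is directly checkable against brute-force enumeration;
an HMM is a possible extension.

Aneuploidy: each chromosome (and each arm, split at a supplied centromere
or the covered midpoint) is segmented under P = 3 and P = 2; disomy is
called when the disomic total log-likelihood wins by ≥ 10 nats. On
simulated data the margin is typically hundreds of nats in either
direction, so the threshold's exact value is uncritical. Disomic
chromosomes are reported as aneuploidy calls and masked from enrichment
margins; they are not listed as homoeologous exchanges.

## Differential expression

Counts are normalised by RLE (median-of-ratios) size factors rescaled to
geometric mean 1. Only factor ratios are identifiable: scaling one
sample by c scales its factor by c relative to every other sample, while
the per-gene geometric-mean reference absorbs c^(1/m).

The test is a conditional exact test on pseudo-counts (counts / size
factor, rounded): with a dispersion φ common to all genes, the group
totals are negative binomial with shapes n_A/φ and n_B/φ, and conditional
on their sum the group-A total has a distribution free of the unknown
mean. The two-sided p-value sums the probabilities of all outcomes less
probable than the observed one plus half the observed point mass (mid-p);
without the mid-p correction the discrete test is measurably conservative
(≈3.5% rejections at nominal 5% on 2,000-gene null simulations), and with
it the type-I error sits at the nominal rate. φ is estimated by method of
moments, (s² − m)/m² pooled across genes with total pseudo-count ≥ 10 and
weighted by within-group degrees of freedom. The suite cross-checks the
whole construction against the Bioconductor edgeR exact test on the same
matrix (Spearman correlation of p-values ≈ 0.998 at n = 3 vs 3); any
externally produced result table with columns (gene_id, logFC, logCPM,
pvalue, qvalue) can be plugged into the downstream stages instead.

Consensus DEGs require q ≤ 0.05 with a concordant fold-change sign in
all three allo-vs-AAA comparisons; sign concordance is a flag
(`require_sign_concordance`) because "detected in all comparisons" does
not by itself pin the direction. The top-k ranking intersection (default
k = 150) breaks ties at the boundary by gene id, making the selection
deterministic and invariant to ordering below rank k.

## Region enrichment

The null is central hypergeometric with fixed margins (N population
genes, K in the region class, n DEGs); both one-sided tails are
accumulated from log-pmf values with log-sum-exp, so deep tails (p ~
1e-100) keep full relative precision — verified against rational-number
enumeration for N ≤ 60. No multiple-testing correction is applied across
region classes by default (raw p-values are reported, as is conventional
for these small families of tests); the population universe is the set of
dosage-assigned genes by default, switchable to the whole annotation.

## PIE

For each focal DEG with paralogs, the family's normalised counts are
summed per sample, rounded, and re-tested with the same NB machinery
(dispersion recomputed on the aggregated matrix, BH across the re-tested
set). `retained` = aggregated q ≤ 0.05 with the focal gene's sign;
`overruled` otherwise; genes in tandem clusters with more than 10 copies
are excluded (short reads cannot apportion expression within such
clusters), and singleton genes are `no_paralogs`. An all-zero aggregated
vector is retained with a flag: family-wide absence is itself the
signal. When no tandem annotation exists, clusters are approximated as
runs of same-family genes within 100 kb on one chromosome. The explicit
re-test replaces what was originally a partly visual judgement, making
the retained/overruled split algorithmic and testable.

## Synthetic data generator

The generator emulates the study design: 11 chromosomes, 100 genes per
chromosome (3 kb genes every 10 kb), Poisson(5) SNP sites per gene, site
classes 70% B-diagnostic (split 75/25 shared/hemi), 20% A-polymorphic and
10% cultivar-private. A-polymorphic sites carry their alternate on 1 or 2
A copies of every cultivar — or on every copy of every cultivar
("reference-private" variants, the pre-filtration frequency-1 bar, which
filtration removes. Per-site depth is negative binomial (mean 30, shape
10) per replicate; three replicates per cultivar. Expression counts are
NB with log-normal baselines (median 100, log-sd 1), per-sample
log-normal library factors (sd 0.1) and gene dispersion 0.05; designed
effect genes shift by ±3 log2 units where a B genome is present.
Compensated effect genes are silenced/reduced with a designated paralog
raised so the family total is conserved; uncompensated genes' paralogs
are flat and low (10% of the focal baseline split among them). Effect
genes are drawn one per paralog family so a compensating partner is never
itself an effect gene.

What the generator does **not** emulate: read-level artefacts (mappability,
allele-specific mapping bias beyond the symmetric ε), linkage between
neighbouring sites, expression differences between homeoalleles, batch
structure, or realistic gene-length/GC effects. Passing recovery tests
therefore demonstrates correctness of the inference under the stated
model, not robustness to alignment artefacts in real data.

## Problem sizes and numerical choices

Recovery suites run 50 seeded single-chromosome cultivars (150 genes,
~750 sites) for HE and aneuploidy, 2,000-gene null matrices for type-I
calibration, and 2 × 100 designed effect genes for PIE; these sizes give
stable pass/fail margins while keeping the whole suite fast. Tie-breaks
are deterministic everywhere (first arg-max dose, lexicographic gene
order at ranking boundaries). Seeds are explicit arguments; derived
seeds are drawn below 2^31. Degenerate inputs (empty windows, zero
pooled depth, all-zero genes, undersized tracks) yield explicit errors,
warnings or "uncallable" records rather than NaNs.

## Known limitations

- Frequencies are computed from read depths, not from triploid genotype
  likelihoods; at low depth the binomial model understates genotype
  uncertainty.
- The common-dispersion exact test ignores gene-specific dispersion
  (tagwise shrinkage would be the natural upgrade).
- Segmentation assumes at most one dosage change between adjacent
  windows; exchanges shorter than the minimum segment span are absorbed.
- Which parental haplotype contributed a segment, phasing, and
  homeoallele-specific expression are out of scope; shared-ancestry
  claims between cultivars can be read from segment overlap but are not
  statistically tested.
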