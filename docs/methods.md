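# Methods

## The problem and the model

An allodiploid hybrid carries one chromosome set from each of two parental
species. In the hybrids this package targets, the parents are ~10.84%
diverged at the nucleotide level but nearly perfectly syntenic, so each
chromosome pair can be treated as a collinear alignment of two haplotypes.
Three post-hybridization processes structure such genomes: loss of
heterozygosity (LOH) that overwrites blocks of one copy with the other,
reciprocal exchanges that swap parental origin between the two copies distal
to a breakpoint, and a slow trickle of residual point mutations that
re-diverges LOH blocks and therefore dates them.

The package resolves these structures from composition alone, without any
outgroup genome, using two weak but genome-wide compositional signals that
distinguish the parents: a small GC offset and a third-position C/T usage
offset in the twelve NNT/NNC two-codon tRNA families.

## dGC and trend curves

For an allelic gene pair with GC fractions GC_1, GC_2, the normalized
ratios dGC_i = GC_i / ((GC_1+GC_2)/2) satisfy dGC_1 + dGC_2 = 2 identically;
alleles that are identical at the nucleotide level are assigned
dGC_1 = dGC_2 = 1 by definition (the normalization carries no information in
that case). The statistic deliberately normalizes within the pair only:
between-gene GC variation (which is much larger than the parental offset)
cancels, leaving a per-gene estimate whose noise is set by the number of
differing sites — for ~1.4 kb CDS at 10.84% divergence the per-gene
standard deviation of dGC−1 is ≈0.007, against a parental separation of
≈±0.003. The 11-gene moving average (step 1, anchored at the central gene's
start codon on a configurable copy, default copy 1) brings the noise below
the signal; region means over ≥20 curve points decide polarity. The copy
with mean smoothed dGC > 1 is labeled Pγ (the GC-richer parent), the other
Pε; regions with both means within `epsilon` (default 0.001) of 1 are
undetermined. Only identical-length allele pairs enter the dGC gene set, so
insertions/deletions cannot bias the GC comparison; the codon-usage gene
set, by contrast, uses all syntenic pairs — the two filters are distinct and
both implemented.

## Exchange detection

On the signed difference s(i) = smoothed dGC_1 − smoothed dGC_2, a
reciprocal exchange appears as a stable sign swap. Maximal constant-sign
runs with ≥ `min_run` points and mean |s| ≥ `min_amplitude` serve as
anchors; a breakpoint is emitted between adjacent anchors of opposite sign,
its interval spanning from the last gene of one anchor to the first gene of
the next. Short sign flips (sampling noise; the smoothed series flips sign
at isolated points with non-trivial probability at this signal-to-noise
ratio) and low-amplitude stretches never become anchors, and a long
near-zero run (a homozygous region, where s ≡ 0) separates anchors without
creating a breakpoint. The defaults min_run = 40 and min_amplitude = 0.0035
were calibrated on the simulator so that a single planted exchange in a
500-gene pair is reported exactly once and exchange-free genomes report
none; both are exposed in `RunConfig`.

## Codon-usage bias and LOH classification

Per region, usage percentages u_T = 100·n_T/(n_T+n_C) are computed on raw
codon counts pooled over genes (not per-gene averages): this reproduces the
published table's printed percentages from its printed counts exactly,
which per-gene averaging would not. Counting is frame-based and
code-agnostic (no translation): terminal stop codons are excluded, CDS with
length not a multiple of 3 are skipped with a warning, codons containing N
are ignored. Report rounding is two decimals, half-up; differences are
computed from unrounded values. A gene-level variant (`gene_level_bias`) is
provided for completeness but the family-level pooled statistic is the
validated summary.

Heterozygous regions that received a polarity are pooled per subgenome into
two centroid profiles; each homozygous region is then assigned to the
nearest centroid in Euclidean distance on the 12-dimensional u_T vector,
with margin |d_ε − d_γ|/(d_ε + d_γ). Calls with margin < 0.05 or fewer than
2000 family codons are undetermined. Centroids never use homozygous
regions, so classification cannot feed back into polarity.

## Alignment

`align_alleles` is a global affine-gap aligner (match +1, mismatch −1, gap
open −2 for the first gap base, extend −1 thereafter) with a fully
specified tie-break (diagonal over gap-in-seq1 over gap-in-seq2, fixed
incoming-state preference in every maximum), implemented as a numba-jitted
Gotoh recursion; the test suite holds it equal — score, identity, and
column string — to an independently written pure-Python reference.
Identity is matches over all alignment columns, excluding columns that
contain an N.

Whole chromosomes are aligned piecewise: accepted gene pairs act as
anchors, and each anchor block and intergenic block is aligned
independently. Equal-length blocks below 30% ungapped divergence take an
ungapped fast path (at these divergences the affine optimum is the ungapped
alignment); other blocks go through an edit-distance path alignment
(edlib). The result is stored as per-base boolean masks (aligned,
mismatch) and a monotone copy-1→copy-2 coordinate projection.

Gene pairing is synteny-first: candidate pairs are restricted to
near-collinear ranks and weighted by a fast identity estimate (ungapped for
equal lengths, edit-distance bound otherwise, with early bail-out below the
eligibility floor); a banded dynamic program then finds the
maximum-total-identity monotone matching in which consecutive accepted
pairs drift in rank by at most `max_rank_offset` (default 3). The identity
floor (default 0.5) is permissive because heterozygous divergence is ~11%
but some alleles diverge much more. The assumption of collinear,
same-orientation synteny (no inversions) is a stated limitation.

## Zygosity segmentation

Windows (default 10 kb, step 1 kb) are labeled hemizygous if the aligned
fraction is below 0.4 **or** divergence exceeds 0.25 (beyond-threshold
divergence is treated as absence of credible homology, which also makes the
three labels exhaustive), homozygous below 0.5% divergence, heterozygous
otherwise. The thresholds sit far from both observed modes (~0.05% within
LOH vs ~11% heterozygous), so classification is insensitive to ±2× changes.
Same-label runs are merged, segments shorter than 5 kb are absorbed into
the longer neighbor, and each het/homo junction is refined from the
window-midpoint estimate to base precision by maximizing the profile
log-likelihood of a two-rate Poisson split of the mismatch process within
±10 kb. With an ~11% rate on one side and ~0 on the other the refinement
localizes junctions to tens of base pairs.

Residual density of a homozygous segment is mismatches per aligned site
×10⁴ (SNP per 10 kb). LOH events are ranked by density descending (densest
= oldest); ties share a rank and are flagged. The generations estimate
g = d/(ploidy_factor·μ) takes the mutation rate and the ploidy factor
(whether divergence accrues on one or both copies) as mandatory explicit
parameters — published estimates of this form are not reproducible without
both, so the package refuses to default them. At μ = 3×10⁻¹⁰ per site per
generation and factor 1, a density of 1 SNP per 18 kb corresponds to
≈185,000 generations.

## Feature scanning

Centromere candidates: 1-kb windows at 0.2-kb step; windows with
GC ≤ (1−0.08)·global GC are flagged; flagged runs ≤600 bp apart are merged;
candidates must span 1.5–5 kb and overlap no gene. The observed ~10.8%
deficit of real islands is a property, not a threshold: the looser 8%
relative cut carries sensitivity while the length and gene-free filters
carry specificity. Multiple survivors on one chromosome are all reported,
flagged non-unique. Candidates on the two copies are matched when their
alignment-projected midpoints agree within 50 kb.

NUMTs: exact 12-mer seeds against the mitochondrial genome (circularized by
appending min_len−1 leading bases; both strands via the reverse
complement), ungapped extension one base at a time until identity over the
trailing 30 bp drops below 0.8, trailing mismatches trimmed; hits ≥50 bp at
≥80% identity are kept, and same-strand hits separated by ≤40 bp are
chained into one hit (extension through a locally noisy patch otherwise
splits one insertion in two). A hit is biallelic when the projected allelic
interval on the partner chromosome (±100 bp for projection jitter) overlaps
a hit there, else hemizygous; biallelic twin hits count as one locus in the
per-subgenome asymmetry summary.

## The synthetic allodiploid generator

The generator is the package's test bed and defines the conditions every
recovery claim is made under. Defaults: 7 chromosome pairs × 500 genes
(~1.4 kb CDS, ~0.6 kb intergenic; ~14 Mb diploid), heterozygous divergence
10.84%, third-position offset 1.57 points, 40% LOH in four blocks at
0.556/0.40/0.28/0.194 SNP per 10 kb (two whole pairs, two terminal blocks,
one resolved to Pε), one reciprocal exchange at the midpoint of a fully
heterozygous pair, 24 NUMTs (14 hemizygous in heterozygous territory, 10
biallelic inside LOH blocks; 4 of Pγ origin, 20 of Pε), and one gene-free
AT-rich island (2.5 kb, 12% relative GC deficit) per chromosome at
homologous positions, with independently drawn sequence in the two parents.

Generation proceeds ancestor-first. Genes are sampled codon-wise from a
pool in which the 12 two-codon families carry 55% of codons (their relative
weights and T/C split taken from the published GC-richer subgenome counts)
and the remaining mass is uniform over other sense codons; intergenic
sequence defaults to the pool's expected coding GC so that composition is
homogeneous outside planted islands. Both parents are then mutated
**symmetrically and independently** from the ancestor (per-parent rate r
solving 2r − (4/3)r² = target divergence). Symmetry matters: mutating one
parent from the other lets substitution pressure toward 50% GC cancel the
planted third-position deficit almost exactly. The third-position offset is
implemented afterwards by directed C→T flips in Pε (per family, calibrated
against measured post-substitution usage so each family's u_T offset equals
the target), touching only the 12 families so the planted signal is exactly
the statistic being measured. Because flips and stop-codon repairs add
mismatches of their own, substitutions are applied in two rounds — an
undershooting first round, then a measured top-up — so realized divergence
matches the target to ~0.1 points. In-frame stop codons created by any edit
are repaired (third base → C), keeping every annotated gene an open frame.

LOH blocks overwrite the non-resolving copy with the resolving parent's
sequence part-by-part and then sprinkle an exact number of residual SNPs
(round(density×length/10⁴), each on one random copy, never creating a
stop), so recovered densities are limited only by boundary precision. The
exchange swaps all parts distal to an intergenic boundary. NUMTs replace
intergenic slices (rather than inserting) so coordinates stay collinear;
the 4:20 asymmetry and the hemizygous/biallelic split mirror the observed
pattern in which all heterozygous-region NUMTs are hemizygous. Indels
(default rate 0) can be enabled to exercise the identical-length dGC
filter; they are applied codon-wise to Pε genes.

What the simulator does **not** emulate: real intergenic composition
(promoters, repeats, telomeres), introns, inversions or translocations
between non-homeologous chromosomes, pseudogene alleles, selection, and
rate heterogeneity along chromosomes. Passing the recovery tests therefore
shows the statistics and segmentation behave correctly under the stated
compositional model, not that thresholds are universal for real genomes —
which is why every threshold is a config parameter.

## Problem sizes and numerics

The default simulation (14 Mb diploid) generates in ~3 s and runs the full
pipeline in ~10 s on one CPU; tests use a 3-pair × 150-gene genome for
mid-scale checks and the default scale for the end-to-end recovery
assertions. All analysis stages are deterministic; the simulator is
deterministic given its mandatory seed (two runs are byte-identical). N
bases are excluded from every GC and divergence denominator. Degenerate
inputs: a gene pair with GC_1+GC_2 = 0 is an error; fewer dGC values than
the window yields an empty curve with a warning; windows with no aligned
columns have undefined divergence and are treated as unalignable; an empty
gene list on one side of a pair makes all opposite genes single-allele
(not an error).

## Known limitations

- Hemizygosity at the window level is driven by divergence/aligned-fraction
  thresholds, not by an explicit structural model of synteny loss.
- The exchange detector assumes at most modest noise-run lengths; exchanges
  closer than `min_run` genes to a chromosome end or to each other are not
  separable.
- The published "mean 1.56 [1.08–1.95]" summary of the usage table is not
  reproducible from the printed family values (their median is 1.57); the
  family-level average (1.57) is the implemented and validated summary, and
  the gene-level variant is provided unvalidated.
- NUMT identity after chaining is a length-weighted average of the
  component segments, not a re-alignment across the chained gap.
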