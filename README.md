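# homeoscan

Resolution of allodiploid hybrid yeast genomes from a phased assembly.

Interspecies yeast hybrids carry two parental chromosome sets (subgenomes)
that are typically ~10% diverged at the nucleotide level yet nearly
perfectly syntenic. After hybridization the genome is reshaped by loss of
heterozygosity (LOH), reciprocal inter-homeolog exchanges, and asymmetric
accumulation of mitochondrial DNA insertions (NUMTs). `homeoscan` takes a
phased assembly — each chromosome copy its own FASTA record, genes in GFF3,
and a two-column pairing manifest — and reconstructs that history:

- **Subgenome assignment by dGC.** For every allelic gene pair with
  identical CDS lengths, the GC fractions of the two copies are compared
  through the normalized ratio

      dGC_1 = GC_1 / ((GC_1 + GC_2)/2),  dGC_2 = GC_2 / ((GC_1 + GC_2)/2)

  so dGC_1 + dGC_2 = 2 and identical alleles give exactly (1, 1). An
  11-gene moving average separates each chromosome pair into a GC-richer
  track (parent "Pγ") and a GC-poorer track ("Pε"); a stable swap of the two
  trend curves marks a reciprocal exchange breakpoint.
- **Codon-usage bias.** Twelve NNT/NNC synonymous codon pairs, each read by
  a single tRNA, give per-region usage percentages
  u_T = 100·n_T/(n_T+n_C). The mean per-family |Δu_T| between subgenomes
  quantifies the systematic third-position C/T offset (~1.57 points), and
  nearest-centroid classification on the 12-dimensional u_T vector assigns
  homozygous (LOH) regions to the parent that resolved them.
- **Zygosity segmentation.** Sliding-window divergence between the two
  copies partitions each pair into heterozygous / homozygous / hemizygous
  segments, with junctions refined to base precision by a two-rate Poisson
  change-point fit. Residual SNP density inside LOH blocks (per 10 kb)
  orders LOH events in time and, given a mutation rate μ, dates their onset
  as g = d / (ploidy_factor · μ).
- **Feature scanning.** Candidate centromeres are unique, gene-free GC-poor
  islands (2–3 kb, ≥8% relative GC deficit); NUMTs are found by exact
  k-mer seeding and ungapped extension against the mitochondrial genome on
  both strands and classified hemizygous/biallelic via the allelic position
  on the partner chromosome.
- **Synthetic allodiploid generator.** A seeded simulator
  (`homeoscan.synthetic_hybrid`) builds genomes with all of these structures
  planted and emits a ground-truth record, so every stage is scored against
  known answers.

## Worked example

The numbered drivers under `analysis/` run the whole study on the bundled
simulator (seed 42, written to `scratch/sim/`, tables to `results/`):

```
$ python analysis/01_simulate_hybrid.py
simulated genome (seed 42): 7 pairs, 14.05 Mb total, 40.0% homozygous
planted: 24 NUMTs, 14 centromere islands, 1 reciprocal exchange(s)

$ python analysis/02_resolve_subgenomes.py
polarity correct for 6/6 heterozygous regions
trend-curve exchanges detected: [('pA', 269220, 637651)]

$ python analysis/03_map_zygosity.py
homozygous fraction: 40.0% (planted 40%)
LOH events, oldest first:
 rank pair_id  snp_per_10kb  generations_estimate
    1      pG         0.556                185220
    2      pF         0.400                133267
    3      pD         0.271                 90440
    4      pE         0.194                 64603

$ python analysis/04_scan_features.py
centromere candidates: 14 (one per chromosome), mean GC deficit 10.7%
NUMT loci: 24; per subgenome {'Pgamma': 4, 'Pepsilon': 20, ...}; epsilon:gamma ratio 5.0

$ python analysis/05_codon_usage_table.py
...
average |delta u_T| = 1.57  (median 1.57, Q1-Q3 1.08-1.96)
```

Reading the output: every heterozygous region is assigned its true parental
origin; the planted 40% LOH fraction is recovered exactly and the four LOH
blocks are ordered by residual density (densest = oldest), the densest
corresponding to ~185,000 generations of re-accumulated polymorphism at
μ = 3×10⁻¹⁰ per site per generation; all 14 planted centromere islands are
called exactly once with a mean relative GC deficit of ~11%; and the 24
planted NUMTs split 4:20 between subgenomes (ratio 5).

The same stages are available as a CLI (`homeoscan simulate|run|codon-table …`)
for running on real phased assemblies.

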