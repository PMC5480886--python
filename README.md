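# bsamap

Bulk-segregant allele-frequency mapping of EMS-induced mutations from pooled
whole-genome sequencing, for forward-genetics screens in selfing crops.

## The problem

A recessive mutation found in an EMS-mutagenized C4 grass (e.g. a sorghum
mutant whose leaf dry matter shows a C3-shifted carbon isotope ratio, δ13C)
can be mapped without a marker panel: cross the mutant to its wild type,
self the BC1F1, pool the DNA of phenotypically extreme BC1F2 segregants, and
sequence the pools. At every locus unlinked to the phenotype the mutant
allele drifts around frequency 0.5; at the causal locus a pool of homozygous
mutants is fixed (AF = 1), a pool of heterozygotes sits at 0.5, and a pool
drawn from the surviving non-mutant classes (1 hom-WT : 2 het) at 1/3. The
causal region is the interval where the mutant pools rise to 1 while the
non-mutant pool stays low.

`bsamap` implements that analysis end to end:

* **Simulator** (`SimConfig`, `make_genome`, `make_gene_models`,
  `mutagenize`, `simulate_cross`, `make_pools`, `sample_pooled_reads`,
  `write_study`) — a multi-chromosome genome with repeat tracts and
  single-transcript gene models; EMS mutagenesis (reference-strand G>A /
  C>T, plus a configurable non-canonical trickle and WT-shared divergence
  variants); a BC1F1 selfing cross with Haldane recombination (Poisson
  crossovers, no interference); the four-pool design (2× hom-mut, 1× het,
  1× non-mutant); Poisson depth / binomial allele-count read sampling; and
  FASTA/GFF3/BED/VCF/TSV/JSON output of the whole study.
* **Variant filter** (`apply_filters`) — the five criteria used in EMS
  pooled mapping: (1) canonical EMS transition, (2) depth in [10, 150],
  (3) AF ≥ 0.3, (4) genotype quality ≥ 30, (5) no WT allele; plus
  region-local repeat masking (`mask_repeats`) and relaxed re-extraction of
  a candidate interval for manual review (`relaxed_reextract`).
* **AF scan** (`expected_pool_af`, `build_af_tracks`, `smooth_track`,
  `detect_candidate_regions`) — sliding-window AF profiles and detection of
  runs where both mutant pools are ≥ 0.9 while the non-mutant pool is
  ≤ 0.45, reported at member-SNP coordinates.
* **Effect annotation** (`classify_context`, `codon_change`) — CDS / UTR /
  core-promoter / intron / intergenic context with CDS-first precedence, and
  codon-level amino-acid-change / stop-gain calls on either strand.
* **Phenotype utilities** — δ13C and Δ13C arithmetic, C3/C4/intermediate
  classification, δ13C-interval pool assignment, Pearson correlation and
  group summaries (`isotope`); A/Ci and light-response curve parameters CE,
  CP, Pmax and QE, RD, Jmax (`gasexchange`); sequencing-run QC arithmetic
  (`qc`).

## Worked example

Run the whole pipeline on a desk-scale synthetic study (10 chromosomes ×
5 Mb, 2,300 EMS SNPs, 400 BC1F2 plants, four 30-plant pools at ~40X):

```python
from bsamap import RunConfig, SimConfig, run_pipeline

res = run_pipeline(RunConfig(sim=SimConfig(seed=1), outdir="demo_run"))
top = res.regions[0]
print(top.chrom, top.start, top.end, top.n_snps, round(top.peak_af, 3))
print({p: round(af, 3) for p, af in top.pool_mean_af.items()})
print(res.effect_summary["nonsynonymous_genes"])
```

prints

```
Chr10 55480 4997107 217 0.998
{'SbPool1': 0.988, 'SbPool2': 0.984, 'SbPool4': 0.308}
['Gene00001', 'Gene00391']
```

One candidate region is detected, on the chromosome carrying the planted
causal SNP (`Chr10:4000001 G>A`, written to `demo_run/truth.json`). The
mutant pools average AF ≈ 0.99 over the region while the non-mutant pool
sits at the expected 1/3; annotation of the region's SNPs against the
gene models reports the causal gene (`Gene00001`, whose planted change is
Ala>Thr) among the genes with nonsynonymous changes. Because the simulated
chromosomes are only 5 Mb (≈ 5 cM), linkage keeps the mutant-pool AF high
across the whole causal chromosome, so the region spans most of it — on a
full-length chromosome the same thresholds cut out a sub-interval around
the causal site.

The same stages are available from a shell:

```bash
bsamap simulate --outdir demo --seed 1
bsamap filter --vcf demo/pools.vcf --wt-vcf demo/wt.vcf --out demo/audit.tsv
bsamap scan --vcf demo/pools.vcf --wt-vcf demo/wt.vcf --out demo/regions.bed
bsamap qc --read-pairs 93467000 --read-length 125 --genome-size 730000000
```

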