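# Methods

## The genetic model

The package analyses (and simulates) a bulk-segregant mapping design for a
recessive-lethal EMS allele in a selfing diploid. The mutant parent is taken
to be homozygous for all of its induced SNPs; crossed to the wild type it
yields a BC1F1 that is heterozygous at every mutant locus, and each BC1F2
individual is formed from two independent BC1F1 gametes. Genotypes at the
causal locus therefore segregate 1 hom-WT : 2 het : 1 hom-mut, and the
expected pooled mutant-allele fraction of a pool with composition
(n_WT, n_het, n_mut) is

    AF = (0·n_WT + 1·n_het + 2·n_mut) / (2·(n_WT + n_het + n_mut)).

This gives the three diagnostic levels the scan relies on: 1 in a
homozygous-mutant pool, 0.5 in a heterozygote pool, 1/3 in a pool drawn from
the surviving classes in their Mendelian 1:2 ratio, and 0.5 genome-wide at
unlinked loci.

Recombination follows the Haldane model: per chromosome and gamete the
crossover count is Poisson(length_Mb × r / 100) with r in cM/Mb (default
1 cM/Mb, a typical plant genome-wide average) and uniform crossover
positions, i.e. no interference. Haldane was chosen because it is standard
and analytically checkable (the recombination fraction at distance d Mb is
(1 − e^(−2rd/100))/2); the linkage-decay property test checks the simulated
mutant-pool AF is non-increasing with distance from the causal site.

Lethality is modelled as a phenotype label, not removal: homozygous mutants
are the "low-δ13C, lethal" class but remain poolable, matching a study
design in which seedlings are sampled before they die. Heterozygotes are the
"normal, slow-growing" class and homozygous wild types the "normal, tall"
class; whether the slow-growing survivors are genotypically pure
heterozygotes is an inference from their pooled AF ≈ 0.5, and the simulator
adopts it.

## The simulator

`SimConfig` defaults describe a desk-scale study: 10 chromosomes × 5 Mb,
2,300 EMS SNPs (the same ~31 SNPs/Mb density as the ~23,000 SNPs a
mutagenized ~730 Mb genome carries; `SimConfig.full_scale()` provides that
scale directly), 5% non-canonical induced changes, 500 variants shared with
the WT parent, four 30-plant pools at a 40X target depth, and a per-base
error rate of 0.002. The desk scale keeps a complete
simulate→filter→scan→annotate run at a few seconds so that multi-seed
recovery experiments are cheap; nothing in the code depends on the scale.

The BC1F2 population defaults to 400 individuals. A census of ~200 plants —
the size of the screen the design mirrors — yields only ~50 homozygous
mutants in expectation under the 1:2:1 model and cannot fill two disjoint
30-plant mutant pools; 400 gives ~100 and makes pooling reliable. (The
mirrored study reported more low-δ13C seedlings than the Mendelian quarter,
115/197; the simulator follows the Mendelian model and treats that
discrepancy as biological noise it does not reproduce.)

δ13C phenotypes are Gaussian per class: wild-type-like classes at
−12.98 ± 0.13 ‰ and homozygous mutants at −13.94 ± 0.40 ‰. The mutant mean
is fixed by mixture algebra — 0.25·(−13.94) + 0.75·(−12.98) = −13.22 ‰, the
overall BC1F2 mean the design targets — and the 0.40 ‰ sd spreads the
population over the observed −15.6…−12.1 ‰ range.

Genomes are uniform random sequence with repeat tracts of 5 kb laid on a
grid to cover 10% of each chromosome (the slot holding the causal position
is excluded so the causal SNP always survives masking). Gene models are
single-transcript: 150 bp UTRs, 1–3 exons of stop-free sense codons starting
with ATG and ending with TAA, introns of 120–300 bp, on either strand; the
coding sequence is embedded into the genome so annotation is exact. One
designated plus-strand gene overlaps the causal position with a GCA (Ala)
codon whose first base is the causal base, so the planted G>A transition is
always nonsynonymous (Ala>Thr). A configurable number of genes (default 37)
is laid out in a 2 Mb window around the causal site, mirroring the gene
content of a mapped locus.

EMS mutagenesis plants reference-strand G>A or C>T transitions at G/C sites
(both strands of the underlying G:C→A:T chemistry collapse to these two
reference-strand spellings); the `noncanonical_fraction` plants any other
substitution, exercising the EMS-type filter. WT-shared variants are
homozygous in both parents, hence at true frequency 1 in every pool — they
are removed only by the WT-allele criterion (or, when their alleles happen
to be non-canonical, by the EMS criterion first, as the reason codes follow
the stated order).

Pooled sequencing is emulated at the site level: depth ~ Poisson(target),
alternate count ~ Binomial(depth, p′) with p′ = p(1−e) + (1−p)e for true
pool fraction p and error rate e. Genotype quality is synthesized as the
phred-scaled likelihood-ratio gap between the best and second-best of three
idealized pooled states (all-reference, balanced, all-alternate), capped at
99 — a documented, monotone-decreasing function of allele-count ambiguity.
No read-level artefacts (mapping bias, indels, duplicates, GC bias,
base-quality structure) are simulated, so passing tests demonstrate the
statistical logic of the pipeline, not robustness to alignment pathology on
real data.

All stages draw from independent generators derived from the single
`seed`, so identical seeds give byte-identical study files.

## Filtering

A variant is kept iff it is a canonical EMS transition, has depth in
[10, 150], AF ≥ 0.3 and GQ ≥ 30, and carries no WT allele. Boundaries are
inclusive, reading "outside 10–150" and "less than 0.3/30" literally as the
exclusions. Depth/AF/GQ are per-pool quantities; by default a variant is
kept if at least one mutant pool passes them, because the non-mutant pool's
expected AF of 1/3 sits at the 0.3 cutoff and an all-pools AND would discard
true signal (a strict mode is available). Removals carry the first failing
criterion in the stated 1→5 order. Repeat masking is applied only inside the
candidate region, as dense repeat-driven variant clusters are a local
artefact; `relaxed_reextract` returns every pre-filter variant of a region
annotated with all criteria it fails, so nothing is silently lost before
manual review.

## Scanning and detection

AF tracks hold one point per kept SNP per pool; sliding windows (default
1 Mb window, 0.2 Mb step, ≥5 SNPs per window else missing) smooth them. A
candidate region is a maximal run of windows with mean AF ≥ 0.9 in *both*
mutant pools (two independent mutant pools act as replication) and ≤ 0.45 in
the non-mutant pool; bounds are reported at the member-SNP extremes, the way
a mapped locus is quoted by its SNP coordinates. The 0.9/0.45 thresholds are
this package's construction — the underlying visual criterion ("AF rises to
1") has no published number — and were set so that binomial read noise at
40X rarely breaches them: a ≥5-SNP window of true-AF-1 sites at depth 40 has
a window-mean standard error well under 0.03, putting 0.9 more than 3 sd
below 1.0, while the non-mutant pool's 1/3 expectation sits comfortably
below 0.45 and the unlinked 0.5 above it. All are configurable.

## Effect annotation

Context classification uses precedence CDS > UTR > core promoter > intron >
intergenic when features of different genes overlap a position. The core
promoter is defined as 1,000 bp upstream of the transcript start on the
coding strand (no standard definition exists; configurable), and the
"gene-boundary overlap" counter includes CDS, UTR and promoter but excludes
introns. Codon calls extract the affected codon in coding orientation
(reverse-complementing minus-strand genes), substitute the alternate base
and translate with the standard genetic code; an alternate stop is a stop
gain, unchanged residue synonymous, any other difference nonsynonymous.
Gene models are single-transcript; organellar codes and splice-site effects
are out of scope. A property test checks every call against translating the
entire CDS before and after the substitution, and a strand-symmetry test
checks calls are invariant under reverse-complementing the whole fixture.

## Phenotype modules

Isotope arithmetic is exact: δ = (R_p/R_std − 1)×1000 and
Δ = (R_air/R_p − 1)×1000, both in ‰. The C4 (−14…−10 ‰) and C3 (−23…−35 ‰)
classification bands are closed at their boundaries. Pool assignment
requires both the δ13C interval and the growth class, because the normal-
slow and normal-tall pools' δ13C intervals overlap; samples falling between
intervals stay unassigned, as only a subset of a screened population enters
pools. Group comparisons use Welch's t-test at α = 0.05.

Gas-exchange parameters: CE is the least-squares slope over A/Ci points
with Ci < 100, QE the slope over exactly the first four light-response
points with PPFD < 100 (ascending), and CP/RD the x-intercept of the fitted
initial line — deterministic and noise-robust, with a raw-curve linear-
interpolation mode as an option; CP/RD are withheld when the fitted slope is
not positive. Pmax/Jmax are the maximum observed A, not a fitted asymptote,
since single reported maxima do not identify a saturating model. The
recovery test generator uses the non-rectangular hyperbola (θ = 0.95) so the
sub-100 region is near-linear.

QC arithmetic rounds percentages half-even to 2 decimals by default and
offers a truncate mode, because published run tables mix the two
conventions across rows; fold coverage is reported at integer precision.

## Numerical and interface choices

Coordinates are 0-based half-open in memory and 1-based in VCF/GFF3 output
(BED stays 0-based). FASTA/VCF reading and writing go through pysam, GFF3
parsing through gffutils, translation through biopython, statistics through
scipy; GFF3/BED/TSV are written as plain text. Zero-depth observations are
missing (AF undefined), windows below the SNP minimum are missing rather
than zero, and detection returns an empty list (not an error) when nothing
qualifies.

## Known limitations

No indels, structural variants, or multi-allelic genotype modelling beyond
splitting records; no read-level simulation or alignment; no significance
envelope for the AF scan (threshold-based detection only); single-transcript
gene models; the simulator's per-class Gaussian δ13C ignores measurement
batch effects and any partial-penetrance biology. On very short simulated
chromosomes the detected region can span most of the causal chromosome,
because a few cM of linkage keeps the mutant-pool AF above threshold
end-to-end; that is a property of the scaled-down genome, not of the
detector.
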