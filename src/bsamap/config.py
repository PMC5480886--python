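"""Simulation configuration for the synthetic BC1F2 mapping study.

The defaults describe a desk-scale version of a pooled-mapping experiment in
an EMS-mutagenized C4 grass: ten chromosomes, a recessive-lethal causal SNP on
the last one, four 30-plant DNA pools sequenced at ~40X, and a carbon-isotope
phenotype that separates homozygous mutants (low delta13C, lethal) from their
normal siblings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

#: per-class phenotype labels for BC1F2 individuals
LOW_D13C_LETHAL = "low_d13C_lethal"
NORMAL_SLOW = "normal_slow"
NORMAL_TALL = "normal_tall"

POOL_NAMES = ("SbPool1", "SbPool2", "SbPool3", "SbPool4")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Attributes
    ----------
    seed : master seed; every stage derives an independent stream from it.
    n_chromosomes, chrom_lengths : genome shape. ``chrom_lengths`` may be a
        single int (applied to every chromosome) or one length per chromosome.
    ems_snp_count : total EMS-induced SNPs across the genome (incl. the causal
        one). The full-scale study carries 22,000-25,000 per genome; the
        desk-scale default keeps the same per-Mb density on a 50 Mb genome.
    noncanonical_fraction : fraction of induced changes that are not reference-
        strand G>A / C>T (these exercise the EMS-type filter).
    wt_divergence_count : variants shared with the wild-type parent relative to
        the reference (homozygous in both parents; exercise the WT filter).
    causal_chrom : 0-based index of the chromosome carrying the causal SNP.
    causal_pos : 0-based position of the causal SNP; ``None`` places it at 80%
        of the causal chromosome (the q-arm).
    recomb_rate : cM/Mb, Haldane model (no interference).
    repeat_fraction : fraction of each chromosome covered by repeat tracts.
    pool_size : individuals per DNA pool.
    target_depth : mean pooled sequencing depth per site.
    error_rate : per-base sequencing error.
    delta13c_* : per-class carbon-isotope distributions (permil vs PDB). The
        mutant-class mean -13.94 is fixed by mixture algebra so that
        0.25*mut + 0.75*(-12.98) reproduces the observed BC1F2 overall mean
        of -13.22; the sd 0.40 spreads the simulated population over the
        observed -15.61..-12.06 range.
    population_size : number of BC1F2 individuals grown.
    """

    seed: int = 0
    n_chromosomes: int = 10
    chrom_lengths: int | Sequence[int] = 5_000_000
    ems_snp_count: int = 2_300
    noncanonical_fraction: float = 0.05
    wt_divergence_count: int = 500
    causal_chrom: int = 9
    causal_pos: int | None = None
    recomb_rate: float = 1.0
    repeat_fraction: float = 0.10
    repeat_tract_bp: int = 5_000
    pool_size: int = 30
    target_depth: float = 40.0
    error_rate: float = 0.002
    delta13c_wt_mean: float = -12.98
    delta13c_wt_sd: float = 0.13
    delta13c_mut_mean: float = -13.94
    delta13c_mut_sd: float = 0.40
    population_size: int = 400
    # gene-model layout
    n_genes_per_chromosome: int = 40
    causal_window_bp: int = 2_000_000
    causal_window_genes: int = 37
    promoter_bp: int = 1_000

    def __post_init__(self) -> None:
        lengths = self.resolved_chrom_lengths()
        if len(lengths) != self.n_chromosomes:
            raise ValueError(
                f"chrom_lengths has {len(lengths)} entries for "
                f"{self.n_chromosomes} chromosomes"
            )
        if any(l <= 0 for l in lengths):
            raise ValueError("zero- or negative-length chromosome")
        for name in ("noncanonical_fraction", "repeat_fraction", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        for name in ("ems_snp_count", "wt_divergence_count", "population_size"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.causal_chrom < self.n_chromosomes:
            raise ValueError("causal_chrom out of range")
        if not 0 <= self.resolved_causal_pos() < lengths[self.causal_chrom]:
            raise ValueError("causal_pos outside the causal chromosome")

    def resolved_chrom_lengths(self) -> tuple[int, ...]:
        if isinstance(self.chrom_lengths, int):
            return (self.chrom_lengths,) * self.n_chromosomes
        return tuple(int(x) for x in self.chrom_lengths)

    def resolved_causal_pos(self) -> int:
        if self.causal_pos is not None:
            return self.causal_pos
        return int(0.8 * self.resolved_chrom_lengths()[self.causal_chrom])

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(f"Chr{i + 1:02d}" for i in range(self.n_chromosomes))

    @property
    def causal_chrom_name(self) -> str:
        return self.chrom_names[self.causal_chrom]

    @classmethod
    def full_scale(cls, seed: int = 0, **kw) -> "SimConfig":
        """Study-scale configuration: 10 x 73 Mb genome, 23,000 EMS SNPs."""
        kw.setdefault("chrom_lengths", 73_000_000)
        kw.setdefault("ems_snp_count", 23_000)
        return cls(seed=seed, **kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["chrom_lengths"] = list(self.resolved_chrom_lengths())
        return d

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


# stage identifiers used to derive independent random streams from the seed
STAGE_GENOME = 1
STAGE_GENES = 2
STAGE_MUTAGENESIS = 3
STAGE_CROSS = 4
STAGE_POOLS = 5
STAGE_READS = 6


def stage_rng(config: SimConfig, stage: int):
    """Independent ``numpy`` Generator for one simulation stage."""
    import numpy as np

    return np.random.default_rng([int(config.seed), int(stage)])
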