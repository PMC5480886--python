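"""EMS mutagenesis of the simulated genome: canonical G>A / C>T transitions,
a configurable trickle of non-canonical changes, parental (WT-shared)
divergence variants, and exactly one causal nonsynonymous SNP."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation import EFFECT_NONSYNONYMOUS, EFFECT_STOP_GAIN, codon_change
from .config import SimConfig, STAGE_MUTAGENESIS, stage_rng
from .genes import GeneModel, causal_gene
from .genome import GenomeRef

_GC = frozenset(b"GC")
#: canonical EMS transitions on the reference strand
_EMS_ALT = {"G": "A", "C": "T"}


@dataclass(frozen=True)
class SimVariant:
    chrom: str
    pos0: int  # 0-based
    ref: str
    alt: str
    ems_canonical: bool
    in_wt: bool = False
    causal: bool = False

    @property
    def pos(self) -> int:
        """1-based position, as in VCF."""
        return self.pos0 + 1


@dataclass
class TruthSet:
    """Ground truth of the simulated study: every induced or parental variant
    with its provenance flags, and the causal gene."""

    variants: list[SimVariant]
    causal_gene_id: str

    def __post_init__(self) -> None:
        if sum(v.causal for v in self.variants) != 1:
            raise ValueError("TruthSet must contain exactly one causal variant")

    @property
    def causal_variant(self) -> SimVariant:
        return next(v for v in self.variants if v.causal)

    @property
    def ems_variants(self) -> list[SimVariant]:
        """Variants induced by mutagenesis (canonical or not), excluding the
        parental divergence set."""
        return [v for v in self.variants if not v.in_wt]

    @property
    def wt_variants(self) -> list[SimVariant]:
        return [v for v in self.variants if v.in_wt]


def _sample_positions(rng, genome: GenomeRef, n: int, taken: set, require_gc: bool):
    """n distinct (chrom, pos0) sites, allocated ~proportionally to length."""
    lengths = np.array([genome.length(c) for c in genome.names], dtype=float)
    alloc = rng.multinomial(n, lengths / lengths.sum())
    out = []
    for chrom, k in zip(genome.names, alloc):
        if k == 0:
            continue
        seq = genome.seqs[chrom]
        eligible = int(np.isin(seq, np.frombuffer(b"GC", np.uint8)).sum()) if require_gc else seq.size
        eligible -= sum(1 for c, _ in taken if c == chrom)
        if k > eligible:
            raise ValueError(
                f"{chrom}: {k} variant sites requested but only {eligible} "
                f"eligible{' G/C' if require_gc else ''} sites remain"
            )
        got = 0
        while got < k:
            cand = rng.integers(0, seq.size, size=max(16, 4 * (k - got)))
            for p in cand:
                p = int(p)
                if (chrom, p) in taken:
                    continue
                if require_gc and seq[p] not in _GC:
                    continue
                taken.add((chrom, p))
                out.append((chrom, p))
                got += 1
                if got == k:
                    break
    return out


def mutagenize(genome: GenomeRef, config: SimConfig, genes: list[GeneModel]) -> TruthSet:
    """Plant the study's variants and return the ground truth.

    ``ems_snp_count`` induced SNPs (including the causal one):
    a ``1 - noncanonical_fraction`` share are G>A or C>T at G/C reference
    bases, the rest any other substitution. ``wt_divergence_count`` additional
    variants are flagged as shared with the WT parent. The causal variant is a
    canonical transition inside the designated gene's CDS and must be
    nonsynonymous (or stop-gain); otherwise a diagnostic error is raised.
    """
    rng = stage_rng(config, STAGE_MUTAGENESIS)
    if config.ems_snp_count < 1:
        raise ValueError("ems_snp_count must be >= 1 (the causal variant)")

    cpos = config.resolved_causal_pos()
    cchrom = config.causal_chrom_name
    cref = genome.base(cchrom, cpos)
    if cref not in _EMS_ALT:
        raise ValueError(
            f"causal site {cchrom}:{cpos + 1} has reference base {cref}; a "
            "canonical EMS transition needs G or C"
        )
    calt = _EMS_ALT[cref]
    cgene = causal_gene(genes, config)
    ann = codon_change(cchrom, cpos, cref, calt, cgene, genome)
    if ann.effect not in (EFFECT_NONSYNONYMOUS, EFFECT_STOP_GAIN):
        raise ValueError(
            f"causal transition {cref}>{calt} at {cchrom}:{cpos + 1} is "
            f"{ann.effect} in {cgene.gene_id} (codon {ann.ref_codon}>{ann.alt_codon}); "
            "no nonsynonymous canonical change available at this codon"
        )
    causal = SimVariant(cchrom, cpos, cref, calt, ems_canonical=True, causal=True)

    taken = {(cchrom, cpos)}
    n_noncanon = int(round(config.noncanonical_fraction * config.ems_snp_count))
    n_canon = config.ems_snp_count - n_noncanon - 1

    variants = [causal]
    for chrom, p in _sample_positions(rng, genome, n_canon, taken, require_gc=True):
        ref = genome.base(chrom, p)
        variants.append(SimVariant(chrom, p, ref, _EMS_ALT[ref], ems_canonical=True))
    for chrom, p in _sample_positions(rng, genome, n_noncanon, taken, require_gc=False):
        ref = genome.base(chrom, p)
        alts = [b for b in "ACGT" if b != ref and _EMS_ALT.get(ref) != b]
        variants.append(
            SimVariant(chrom, p, ref, alts[int(rng.integers(0, len(alts)))], ems_canonical=False)
        )
    for chrom, p in _sample_positions(rng, genome, config.wt_divergence_count, taken, require_gc=False):
        ref = genome.base(chrom, p)
        alts = [b for b in "ACGT" if b != ref]
        alt = alts[int(rng.integers(0, len(alts)))]
        variants.append(
            SimVariant(chrom, p, ref, alt, ems_canonical=alt == _EMS_ALT.get(ref), in_wt=True)
        )
    variants.sort(key=lambda v: (v.chrom, v.pos0))
    return TruthSet(variants=variants, causal_gene_id=cgene.gene_id)
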