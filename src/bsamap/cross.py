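"""Forward simulation of the mapping cross.

The mutant parent (homozygous for all its induced SNPs) is crossed to the
wild type; the fully heterozygous BC1F1 is selfed; each BC1F2 individual is
formed from two independent BC1F1 gametes. Recombination follows the Haldane
model: per chromosome, a Poisson number of crossovers (length_Mb x cM/Mb /
100) at uniform positions, no interference. The causal genotype determines
the phenotype class deterministically — homozygous mutants are the low-δ13C
lethal class — and δ13C is drawn from the class's distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import (
    LOW_D13C_LETHAL, NORMAL_SLOW, NORMAL_TALL, POOL_NAMES,
    SimConfig, STAGE_CROSS, STAGE_POOLS, stage_rng,
)
from .mutagenesis import TruthSet

#: ancestry codes
WT_PARENT = 0
MUTANT_PARENT = 1

GENOTYPE_CLASS = {2: LOW_D13C_LETHAL, 1: NORMAL_SLOW, 0: NORMAL_TALL}


@dataclass(frozen=True)
class Haplotype:
    """One gamete chromosome: starting ancestry plus crossover breakpoints."""

    start: int  # WT_PARENT or MUTANT_PARENT
    breakpoints: np.ndarray  # sorted positions (bp)

    def ancestry(self, pos) -> np.ndarray | int:
        """Ancestry (0=WT, 1=mutant) at one position or an array of them."""
        k = np.searchsorted(self.breakpoints, pos, side="right")
        return self.start ^ (k & 1)


@dataclass
class Individual:
    id: str
    haplotypes: dict[str, tuple[Haplotype, Haplotype]]
    causal_genotype: int  # mutant-allele count, 0/1/2
    phenotype_class: str
    delta13c: float

    def allele_count(self, chrom: str, pos: int) -> int:
        a, b = self.haplotypes[chrom]
        return int(a.ancestry(pos)) + int(b.ancestry(pos))


def _gamete(rng, length: int, recomb_rate: float) -> Haplotype:
    n_co = rng.poisson(length / 1e6 * recomb_rate / 100.0)
    bps = np.sort(rng.uniform(0, length, size=n_co)) if n_co else np.empty(0)
    return Haplotype(start=int(rng.integers(0, 2)), breakpoints=bps)


def simulate_cross(truth: TruthSet, config: SimConfig) -> list[Individual]:
    """Simulate ``population_size`` BC1F2 individuals."""
    rng = stage_rng(config, STAGE_CROSS)
    lengths = dict(zip(config.chrom_names, config.resolved_chrom_lengths()))
    cchrom, cpos = config.causal_chrom_name, config.resolved_causal_pos()
    out = []
    for i in range(config.population_size):
        haps = {
            chrom: (_gamete(rng, L, config.recomb_rate), _gamete(rng, L, config.recomb_rate))
            for chrom, L in lengths.items()
        }
        a, b = haps[cchrom]
        gt = int(a.ancestry(cpos)) + int(b.ancestry(cpos))
        cls = GENOTYPE_CLASS[gt]
        if cls == LOW_D13C_LETHAL:
            d13c = rng.normal(config.delta13c_mut_mean, config.delta13c_mut_sd)
        else:
            d13c = rng.normal(config.delta13c_wt_mean, config.delta13c_wt_sd)
        out.append(
            Individual(
                id=f"BC1F2_{i + 1:04d}", haplotypes=haps, causal_genotype=gt,
                phenotype_class=cls, delta13c=float(d13c),
            )
        )
    return out


@dataclass
class Pool:
    name: str
    members: list[Individual]

    @property
    def size(self) -> int:
        return len(self.members)

    def true_allele_fraction(self, chrom: str, pos: int) -> float:
        """Pooled mutant-allele fraction at a locus, from genotypes."""
        total = sum(m.allele_count(chrom, pos) for m in self.members)
        return total / (2 * len(self.members))


class PoolingError(ValueError):
    pass


def make_pools(individuals: list[Individual], config: SimConfig) -> dict[str, Pool]:
    """The four-pool design of the study.

    SbPool1 and SbPool2: disjoint sets of ``pool_size`` homozygous mutants
    (low-δ13C lethal class). SbPool3: ``pool_size`` heterozygotes (normal,
    slow growing). SbPool4: ``pool_size`` sampled from all remaining
    non-homozygous-mutant individuals (expected 1 hom-WT : 2 het). All pools
    are disjoint.
    """
    rng = stage_rng(config, STAGE_POOLS)
    n = config.pool_size
    by_class = {
        LOW_D13C_LETHAL: [i for i in individuals if i.phenotype_class == LOW_D13C_LETHAL],
        NORMAL_SLOW: [i for i in individuals if i.phenotype_class == NORMAL_SLOW],
        NORMAL_TALL: [i for i in individuals if i.phenotype_class == NORMAL_TALL],
    }
    if len(by_class[LOW_D13C_LETHAL]) < 2 * n:
        raise PoolingError(
            f"need {2 * n} individuals of class {LOW_D13C_LETHAL} for SbPool1/2, "
            f"have {len(by_class[LOW_D13C_LETHAL])}"
        )
    if len(by_class[NORMAL_SLOW]) < n:
        raise PoolingError(
            f"need {n} individuals of class {NORMAL_SLOW} for SbPool3, "
            f"have {len(by_class[NORMAL_SLOW])}"
        )

    def pick(pool, k):
        idx = rng.choice(len(pool), size=k, replace=False)
        chosen = [pool[i] for i in sorted(idx)]
        remaining = [x for j, x in enumerate(pool) if j not in set(int(i) for i in idx)]
        return chosen, remaining

    muts = by_class[LOW_D13C_LETHAL]
    p1, muts = pick(muts, n)
    p2, _ = pick(muts, n)
    p3, slow_rest = pick(by_class[NORMAL_SLOW], n)
    nonmut_rest = slow_rest + by_class[NORMAL_TALL]
    if len(nonmut_rest) < n:
        raise PoolingError(
            f"need {n} non-homozygous-mutant individuals for SbPool4, have {len(nonmut_rest)}"
        )
    nonmut_rest.sort(key=lambda i: i.id)
    p4, _ = pick(nonmut_rest, n)
    return {
        POOL_NAMES[0]: Pool(POOL_NAMES[0], p1),
        POOL_NAMES[1]: Pool(POOL_NAMES[1], p2),
        POOL_NAMES[2]: Pool(POOL_NAMES[2], p3),
        POOL_NAMES[3]: Pool(POOL_NAMES[3], p4),
    }


def true_pool_allele_fractions(truth: TruthSet, pools: dict[str, Pool]) -> "pd.DataFrame":
    """True (pre-sequencing) pooled allele fraction of every truth variant in
    every pool. Variants shared with the WT parent are homozygous in both
    parents, hence fraction 1 everywhere.
    """
    import pandas as pd

    by_chrom: dict[str, list] = {}
    for v in truth.variants:
        by_chrom.setdefault(v.chrom, []).append(v)

    rows = []
    for chrom, vs in by_chrom.items():
        pos = np.array([v.pos0 for v in vs])
        wt_mask = np.array([v.in_wt for v in vs])
        for pname, pool in pools.items():
            counts = np.zeros(len(vs))
            for m in pool.members:
                a, b = m.haplotypes[chrom]
                counts += a.ancestry(pos) + b.ancestry(pos)
            frac = counts / (2 * pool.size)
            frac[wt_mask] = 1.0
            for v, f in zip(vs, frac):
                rows.append({"chrom": chrom, "pos0": v.pos0, "pool": pname, "p_true": float(f)})
    df = pd.DataFrame(rows)
    return df.sort_values(["chrom", "pos0", "pool"]).reset_index(drop=True)
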