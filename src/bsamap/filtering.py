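"""The five-criterion variant filter for pooled EMS mapping, plus repeat
masking and relaxed re-extraction of a candidate region.

A variant is kept iff it (1) is a canonical EMS transition (reference-strand
G>A or C>T), (2) has read depth within [10, 150], (3) alternate-allele
frequency >= 0.3, (4) genotype quality >= 30, and (5) carries no WT allele
(is absent from the wild-type parent's variant set). Depth/AF/GQ are
evaluated per pool; by default a variant passes if at least one mutant pool
satisfies them, since the non-mutant pool's expected AF of 1/3 sits right at
the 0.3 cutoff and a per-all-pools AND would discard true signal. Removals
carry the first failing criterion's reason code in the stated order.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import POOL_NAMES

VALID_BASES = frozenset("ACGT")

REASON_NON_EMS = "non_ems"
REASON_DEPTH = "depth"
REASON_AF = "af"
REASON_GQ = "gq"
REASON_WT = "wt_allele"
REASON_REPEAT = "repeat"

STATUS_KEPT = "kept"
STATUS_REMOVED = "removed"


class InvalidAlleleError(ValueError):
    pass


class DataIntegrityError(ValueError):
    pass


@dataclass(frozen=True)
class PoolObservation:
    """Read support for one variant in one pool."""

    depth: int
    alt: int
    gq: int

    def __post_init__(self) -> None:
        if self.alt < 0 or self.depth < 0:
            raise DataIntegrityError("negative read counts")
        if self.alt > self.depth:
            raise DataIntegrityError(f"alt count {self.alt} exceeds depth {self.depth}")

    @property
    def af(self) -> float | None:
        """Alternate-allele frequency; None (missing) at zero depth."""
        return None if self.depth == 0 else self.alt / self.depth


def compute_af(obs: PoolObservation) -> float | None:
    """Reads supporting the mutant allele over total aligned reads."""
    return obs.af


def is_ems_transition(ref: str, alt: str) -> bool:
    """True iff (ref, alt) is a reference-strand G>A or C>T transition."""
    if ref not in VALID_BASES or alt not in VALID_BASES:
        raise InvalidAlleleError(f"invalid alleles {ref!r}>{alt!r}")
    return (ref, alt) in {("G", "A"), ("C", "T")}


@dataclass
class Variant:
    """One SNP site with per-pool read support and filter provenance."""

    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    pools: dict[str, PoolObservation]
    in_wt: bool = False
    status: str = STATUS_KEPT
    reason: str | None = None

    def __post_init__(self) -> None:
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise InvalidAlleleError(f"invalid alleles {self.ref!r}>{self.alt!r}")
        if self.ref == self.alt:
            raise InvalidAlleleError("ref equals alt")
        if self.pos < 1:
            raise ValueError("position must be >= 1")

    @property
    def ems_canonical(self) -> bool:
        return is_ems_transition(self.ref, self.alt)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class FilterParams:
    min_dp: int = 10
    max_dp: int = 150
    min_af: float = 0.3
    min_gq: int = 30
    #: pools whose evidence can keep a variant for the genome-wide scan
    mutant_pools: tuple[str, ...] = (POOL_NAMES[0], POOL_NAMES[1])
    #: if True, depth/AF/GQ must pass in every pool instead of >=1 mutant pool
    require_all_pools: bool = False

    def __post_init__(self) -> None:
        if self.min_dp > self.max_dp:
            raise ValueError(f"min_dp {self.min_dp} > max_dp {self.max_dp}")


def _obs_pass(obs: PoolObservation, params: FilterParams, upto: str) -> bool:
    """Does one pool observation pass the per-pool criteria up to and
    including ``upto`` ('depth' | 'af' | 'gq')? Boundaries inclusive; a
    missing AF (zero depth) fails the depth criterion already."""
    if not params.min_dp <= obs.depth <= params.max_dp:
        return False
    if upto == REASON_DEPTH:
        return True
    if obs.af is None or obs.af < params.min_af:
        return False
    if upto == REASON_AF:
        return True
    return obs.gq >= params.min_gq


@dataclass
class FilterResult:
    kept: list[Variant]
    removed: list[Variant]

    @property
    def all_variants(self) -> list[Variant]:
        return self.kept + self.removed

    def audit_table(self) -> pd.DataFrame:
        """Per-variant per-pool audit of depth, alt, AF, GQ and outcome."""
        rows = []
        for v in self.all_variants:
            for pool, obs in v.pools.items():
                rows.append(
                    {
                        "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                        "pool": pool, "depth": obs.depth, "alt_count": obs.alt,
                        "af": np.nan if obs.af is None else obs.af, "gq": obs.gq,
                        "status": v.status, "reason": v.reason or "",
                    }
                )
        return pd.DataFrame(rows)


def apply_filters(
    variants: list[Variant],
    wt_variants: set[tuple] | list,
    params: FilterParams = FilterParams(),
) -> FilterResult:
    """Partition variants into kept and removed with reason codes.

    ``wt_variants`` holds (chrom, pos, ref, alt) keys (or (chrom, pos) pairs)
    of the wild-type parent's variant set. Every input variant appears in
    exactly one of the two output lists.
    """
    wt_keys = set()
    wt_sites = set()
    for w in wt_variants:
        t = tuple(w)
        (wt_keys if len(t) == 4 else wt_sites).add(t)

    def in_wt(v: Variant) -> bool:
        return v.in_wt or v.key in wt_keys or (v.chrom, v.pos) in wt_sites

    eval_pools = (
        (lambda v: list(v.pools))
        if params.require_all_pools
        else (lambda v: [p for p in params.mutant_pools if p in v.pools])
    )
    kept, removed = [], []
    for v in variants:
        pools = eval_pools(v)
        reason = None
        if not v.ems_canonical:
            reason = REASON_NON_EMS
        else:
            if params.require_all_pools:
                ok = lambda upto: all(_obs_pass(v.pools[p], params, upto) for p in pools)
            else:
                ok = lambda upto: any(_obs_pass(v.pools[p], params, upto) for p in pools)
            if not pools or not ok(REASON_DEPTH):
                reason = REASON_DEPTH
            elif not ok(REASON_AF):
                reason = REASON_AF
            elif not ok(REASON_GQ):
                reason = REASON_GQ
            elif in_wt(v):
                reason = REASON_WT
        out = replace(v, status=STATUS_KEPT if reason is None else STATUS_REMOVED, reason=reason)
        (kept if reason is None else removed).append(out)
    return FilterResult(kept=kept, removed=removed)


def mask_repeats(
    variants: list[Variant],
    repeat_intervals: dict[str, list[tuple[int, int]]],
    region: tuple[str, int, int] | None = None,
) -> FilterResult:
    """Remove variants inside repeat tracts, applied only within ``region``
    (chrom, start0, end0, half-open) when one is given — the masking is local
    to the candidate interval, everywhere else variants are untouched."""
    kept, removed = [], []
    for v in variants:
        pos0 = v.pos - 1
        in_region = region is None or (
            v.chrom == region[0] and region[1] <= pos0 < region[2]
        )
        hit = False
        if in_region:
            ivals = repeat_intervals.get(v.chrom, [])
            starts = [s for s, _ in ivals]
            i = bisect.bisect_right(starts, pos0) - 1
            hit = i >= 0 and ivals[i][0] <= pos0 < ivals[i][1]
        if hit:
            removed.append(replace(v, status=STATUS_REMOVED, reason=REASON_REPEAT))
        else:
            kept.append(v)
    return FilterResult(kept=kept, removed=removed)


def failing_criteria(
    v: Variant, wt_variants: set, params: FilterParams = FilterParams()
) -> list[str]:
    """All criteria a variant fails (not just the first), for manual review."""
    fails = []
    if not v.ems_canonical:
        fails.append(REASON_NON_EMS)
    pools = (
        list(v.pools) if params.require_all_pools
        else [p for p in params.mutant_pools if p in v.pools]
    )
    agg = all if params.require_all_pools else any
    if not pools or not agg(_obs_pass(v.pools[p], params, REASON_DEPTH) for p in pools):
        fails.append(REASON_DEPTH)
    if not pools or not agg(
        v.pools[p].af is not None and v.pools[p].af >= params.min_af for p in pools
    ):
        fails.append(REASON_AF)
    if not pools or not agg(v.pools[p].gq >= params.min_gq for p in pools):
        fails.append(REASON_GQ)
    wt_keys = {tuple(w) for w in wt_variants}
    if v.in_wt or v.key in wt_keys or (v.chrom, v.pos) in wt_keys:
        fails.append(REASON_WT)
    return fails


def relaxed_reextract(
    variants_prefilter: list[Variant],
    region: tuple[str, int, int],
    wt_variants: set = frozenset(),
    params: FilterParams = FilterParams(),
) -> pd.DataFrame:
    """Re-extract every pre-filter variant of a candidate region with the
    full list of criteria it fails, so nothing is silently lost; the main
    kept set is not altered."""
    chrom, start0, end0 = region
    rows = []
    for v in variants_prefilter:
        if v.chrom != chrom or not start0 <= v.pos - 1 < end0:
            continue
        fails = failing_criteria(v, wt_variants, params)
        rows.append(
            {
                "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                "passes_all": not fails,
                "failed_criteria": ",".join(fails),
                **{f"{k}_fail": k in fails for k in
                   (REASON_NON_EMS, REASON_DEPTH, REASON_AF, REASON_GQ, REASON_WT)},
            }
        )
    cols = [
        "chrom", "pos", "ref", "alt", "passes_all", "failed_criteria",
        "non_ems_fail", "depth_fail", "af_fail", "gq_fail", "wt_allele_fail",
    ]
    return pd.DataFrame(rows, columns=cols)


def observations_to_variants(obs: pd.DataFrame) -> list[Variant]:
    """Build Variant records from the simulator's tidy observation table."""
    variants = []
    for (chrom, pos0), grp in obs.groupby(["chrom", "pos0"], sort=True):
        first = grp.iloc[0]
        pools = {
            r.pool: PoolObservation(depth=int(r.depth), alt=int(r.alt_count), gq=int(r.gq))
            for r in grp.itertuples()
        }
        variants.append(
            Variant(
                chrom=chrom, pos=int(pos0) + 1, ref=first.ref, alt=first.alt_allele,
                pools=pools, in_wt=bool(first.in_wt),
            )
        )
    return variants
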