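"""Genome-wide alternate-allele-frequency scanning and candidate-region
detection for bulk-segregant mapping, plus the Mendelian expected-AF model.

At the causal locus of a recessive-lethal mutation, a pool of homozygous
mutants has allele frequency 1, a heterozygote pool 0.5, and a pool drawn
from the surviving non-mutant classes (1 hom-WT : 2 het) 1/3, while unlinked
loci average 0.5 in any pool. The scan looks for runs of sliding windows
where both mutant pools are near 1 and the non-mutant pool is well below 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import POOL_NAMES
from .filtering import Variant


def expected_pool_af(n_wt: int, n_het: int, n_mut: int) -> float:
    """Expected pooled mutant-allele fraction of a pool with the given
    genotype composition: (0*n_wt + 1*n_het + 2*n_mut) / (2*total).
    Invariant under scaling of the counts."""
    total = n_wt + n_het + n_mut
    if total <= 0:
        raise ValueError("pool composition is empty")
    if min(n_wt, n_het, n_mut) < 0:
        raise ValueError("negative genotype count")
    return (n_het + 2 * n_mut) / (2 * total)


@dataclass
class AFTrack:
    """Per-pool allele-frequency profile along one chromosome."""

    chrom: str
    pool: str
    positions: np.ndarray  # 1-based, strictly increasing
    af: np.ndarray  # in [0, 1], NaN = missing (zero depth)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions)
        self.af = np.asarray(self.af, dtype=float)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        ok = self.af[~np.isnan(self.af)]
        if ok.size and (ok.min() < 0 or ok.max() > 1):
            raise ValueError("AF outside [0, 1]")

    def __len__(self) -> int:
        return int(self.positions.size)


def build_af_tracks(variants: list[Variant], pool: str) -> dict[str, AFTrack]:
    """One AF point per variant for one pool, keyed by chromosome."""
    if variants and not any(pool in v.pools for v in variants):
        raise KeyError(f"unknown pool {pool!r}")
    by_chrom: dict[str, list[Variant]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)
    tracks = {}
    for chrom, vs in by_chrom.items():
        vs.sort(key=lambda v: v.pos)
        pos = np.array([v.pos for v in vs])
        af = np.array(
            [np.nan if v.pools[pool].af is None else v.pools[pool].af for v in vs]
        )
        tracks[chrom] = AFTrack(chrom=chrom, pool=pool, positions=pos, af=af)
    return tracks


def smooth_track(
    track: AFTrack,
    window_bp: int = 1_000_000,
    step_bp: int = 200_000,
    min_snps: int = 5,
    chrom_length: int | None = None,
) -> pd.DataFrame:
    """Sliding-window mean AF.

    Windows start at 0 and advance by ``step_bp``; windows holding fewer than
    ``min_snps`` non-missing points are reported with NaN mean. Returns
    columns start, end (0-based half-open), mean_af, n_snps.
    """
    if not (window_bp >= step_bp > 0):
        raise ValueError("need window_bp >= step_bp > 0")
    span = chrom_length if chrom_length is not None else (
        int(track.positions.max()) if len(track) else 0
    )
    starts = np.arange(0, max(span - window_bp, 0) + step_bp, step_bp, dtype=np.int64)
    if starts.size == 0:
        starts = np.array([0], dtype=np.int64)
    rows = []
    pos0 = track.positions - 1
    valid = ~np.isnan(track.af)
    for s in starts:
        e = s + window_bp
        m = (pos0 >= s) & (pos0 < e) & valid
        n = int(m.sum())
        rows.append(
            {
                "start": int(s), "end": int(e),
                "mean_af": float(track.af[m].mean()) if n >= min_snps else np.nan,
                "n_snps": n,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CandidateRegion:
    """A contiguous interval where the mutant pools reach the detection
    threshold. Bounds are the first/last member SNP positions (1-based,
    inclusive), as a mapped locus is reported by its SNP coordinates."""

    chrom: str
    start: int
    end: int
    snps: list[Variant]
    pool_mean_af: dict[str, float]
    peak_af: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start > end")
        for v in self.snps:
            if not self.start <= v.pos <= self.end:
                raise ValueError("member SNP outside region bounds")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass(frozen=True)
class ScanParams:
    window_bp: int = 1_000_000
    step_bp: int = 200_000
    min_snps: int = 5
    high_threshold: float = 0.9
    low_threshold: float = 0.45
    mutant_pools: tuple[str, ...] = (POOL_NAMES[0], POOL_NAMES[1])
    nonmutant_pool: str = POOL_NAMES[3]


def detect_candidate_regions(
    variants: list[Variant],
    params: ScanParams = ScanParams(),
    chrom_lengths: dict[str, int] | None = None,
) -> list[CandidateRegion]:
    """Maximal runs of consecutive windows where mean AF >= high_threshold in
    every mutant pool AND <= low_threshold in the non-mutant pool (a missing
    non-mutant window does not veto). Regions are ranked by peak mutant-pool
    window mean. An empty result is not an error."""
    pools = list(params.mutant_pools) + [params.nonmutant_pool]
    tracks = {p: build_af_tracks(variants, p) for p in pools}
    by_chrom: dict[str, list[Variant]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)

    regions: list[CandidateRegion] = []
    for chrom, vs in by_chrom.items():
        length = chrom_lengths.get(chrom) if chrom_lengths else None
        win = {
            p: smooth_track(
                tracks[p][chrom], params.window_bp, params.step_bp,
                params.min_snps, length,
            )
            for p in pools
        }
        base = win[pools[0]]
        mut_means = np.stack([win[p]["mean_af"].to_numpy() for p in params.mutant_pools])
        mut_ok = np.all(mut_means >= params.high_threshold, axis=0)  # NaN -> False
        non = win[params.nonmutant_pool]["mean_af"].to_numpy()
        non_ok = np.isnan(non) | (non <= params.low_threshold)
        qual = mut_ok & non_ok
        # maximal runs of qualifying windows
        idx = np.flatnonzero(qual)
        if idx.size == 0:
            continue
        splits = np.flatnonzero(np.diff(idx) > 1)
        runs = np.split(idx, splits + 1)
        vs.sort(key=lambda v: v.pos)
        for run in runs:
            s = int(base["start"].iloc[run[0]])
            e = int(base["end"].iloc[run[-1]])
            members = [v for v in vs if s <= v.pos - 1 < e]
            if not members:
                continue
            mean_window_peak = float(np.nanmax(mut_means[:, run].mean(axis=0)))
            pool_means = {}
            for p in pools:
                afs = [v.pools[p].af for v in members if v.pools[p].af is not None]
                pool_means[p] = float(np.mean(afs)) if afs else float("nan")
            regions.append(
                CandidateRegion(
                    chrom=chrom, start=members[0].pos, end=members[-1].pos,
                    snps=members, pool_mean_af=pool_means, peak_af=mean_window_peak,
                )
            )
    regions.sort(key=lambda r: r.peak_af, reverse=True)
    return regions


def region_snp_report(
    region: CandidateRegion,
    annotations=None,
) -> tuple[pd.DataFrame, dict]:
    """Tabulate a candidate region's SNPs with per-pool AF, filter history
    and (if annotations are supplied) effect class and gene; returns the
    table and a summary with SNP and overlapped-gene counts."""
    ann_by_pos = {}
    if annotations:
        ann_by_pos = {(a.chrom, a.pos): a for a in annotations}
    rows = []
    for v in region.snps:
        row = {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
               "status": v.status, "reason": v.reason or ""}
        for pool, obs in v.pools.items():
            row[f"af_{pool}"] = np.nan if obs.af is None else obs.af
        a = ann_by_pos.get((v.chrom, v.pos))
        if a is not None:
            row.update(
                {"gene_id": a.gene_id or "", "context": a.context,
                 "effect": a.effect, "amino_acid_change": a.aa_change or ""}
            )
        rows.append(row)
    columns = None
    if not rows:
        columns = ["chrom", "pos", "ref", "alt", "status", "reason"]
    df = pd.DataFrame(rows, columns=columns)
    genes = set()
    if annotations:
        for v in region.snps:
            a = ann_by_pos.get((v.chrom, v.pos))
            if a is not None and a.gene_id:
                genes.add(a.gene_id)
    summary = {
        "chrom": region.chrom, "start": region.start, "end": region.end,
        "n_snps": region.n_snps, "n_genes_overlapped": len(genes),
        "genes": sorted(genes), "pool_mean_af": region.pool_mean_af,
    }
    return df, summary


def plot_af_tracks(
    variants: list[Variant],
    pool: str,
    outdir,
    params: ScanParams = ScanParams(),
    chrom_lengths: dict[str, int] | None = None,
) -> list[str]:
    """Per-chromosome AF scatter with the window mean overlaid; one PNG per
    chromosome, returns the written paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tracks = build_af_tracks(variants, pool)
    paths = []
    for chrom, track in sorted(tracks.items()):
        length = chrom_lengths.get(chrom) if chrom_lengths else None
        win = smooth_track(track, params.window_bp, params.step_bp, params.min_snps, length)
        fig, ax = plt.subplots(figsize=(8, 2.5))
        ax.plot(track.positions / 1e6, track.af, ".", ms=2, alpha=0.5, label="SNP AF")
        mid = (win["start"] + win["end"]) / 2 / 1e6
        ax.plot(mid, win["mean_af"], "-", lw=1.5, label="window mean")
        ax.set_ylim(-0.02, 1.02)
        ax.set_xlabel(f"{chrom} position (Mb)")
        ax.set_ylabel(f"AF ({pool})")
        ax.legend(loc="lower right", fontsize=7)
        fig.tight_layout()
        path = outdir / f"af_{pool}_{chrom}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(str(path))
    return paths
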