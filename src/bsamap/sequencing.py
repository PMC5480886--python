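"""Pooled short-read sequencing emulation at the site level.

For every variant site and pool, depth is Poisson around the target coverage
and the alternate-read count is binomial at the pool's true allele fraction
perturbed by the per-base error rate. A phred-like genotype quality is
synthesized as the likelihood-ratio gap between the best and second-best of
the three idealized pooled states (all-reference, balanced, all-alternate) —
a documented, monotone-decreasing function of allele-count ambiguity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import SimConfig, STAGE_READS, stage_rng
from .cross import Pool, true_pool_allele_fractions
from .mutagenesis import TruthSet

GQ_CAP = 99


def genotype_quality(depth, alt, error_rate: float = 0.002) -> np.ndarray:
    """Phred-scaled gap between the best and second-best binomial likelihood
    among alternate-allele fractions {error, 0.5, 1-error}. Capped at 99;
    zero at zero depth."""
    depth = np.atleast_1d(np.asarray(depth, dtype=np.int64))
    alt = np.atleast_1d(np.asarray(alt, dtype=np.int64))
    e = min(max(error_rate, 1e-6), 0.5)
    ps = np.array([e, 0.5, 1.0 - e])
    ll = np.stack([stats.binom.logpmf(alt, depth, p) for p in ps])  # (3, n)
    ll_sorted = np.sort(ll, axis=0)
    gq = 10.0 / np.log(10.0) * (ll_sorted[-1] - ll_sorted[-2])
    gq = np.where(depth == 0, 0.0, np.minimum(np.round(gq), GQ_CAP))
    return gq.astype(np.int64)


def sample_pooled_reads(
    truth: TruthSet, pools: dict[str, Pool], config: SimConfig
) -> pd.DataFrame:
    """Site-level pooled observations for every truth variant and pool.

    Returns a tidy frame with columns chrom, pos0, ref, alt_allele,
    ems_canonical, in_wt, causal, pool, depth, alt_count, gq, sorted by
    (chrom, pos0, pool). Depth 0 rows represent missing observations.
    Deterministic for a fixed seed.
    """
    rng = stage_rng(config, STAGE_READS)
    p_true = true_pool_allele_fractions(truth, pools)
    meta = pd.DataFrame(
        [
            {
                "chrom": v.chrom, "pos0": v.pos0, "ref": v.ref, "alt_allele": v.alt,
                "ems_canonical": v.ems_canonical, "in_wt": v.in_wt, "causal": v.causal,
            }
            for v in truth.variants
        ]
    )
    df = p_true.merge(meta, on=["chrom", "pos0"], how="left")
    df = df.sort_values(["chrom", "pos0", "pool"]).reset_index(drop=True)
    e = config.error_rate
    p_eff = df["p_true"].to_numpy() * (1 - e) + (1 - df["p_true"].to_numpy()) * e
    depth = rng.poisson(config.target_depth, size=len(df))
    alt = rng.binomial(depth, p_eff)
    df["depth"] = depth
    df["alt_count"] = alt
    df["gq"] = genotype_quality(depth, alt, e)
    return df
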