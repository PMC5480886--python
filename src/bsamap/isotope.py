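"""Carbon-isotope phenotype computations.

δ13C of leaf dry matter is reported in per mil against the PDB carbonate
standard, δ = (R_p/R_PDB − 1) × 1000, and photosynthetic discrimination as
Δ = (R_air/R_p − 1) × 1000. C4 grasses sit near −10..−14 ‰, C3 plants near
−23..−35 ‰; a C4 mutant sliding toward C3-like values is the screening
signal. The module also assigns BC1F2 samples to sequencing pools from their
δ13C interval and growth class, and provides the simple summary statistics
reported for greenness and stomatal density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

GROWTH_SMALL = "small"
GROWTH_TALL = "tall"
GROWTH_WILDTYPE = "wildtype"

C3 = "C3"
C4 = "C4"
INTERMEDIATE = "intermediate"

#: closed classification boundaries, permil
C4_RANGE = (-14.0, -10.0)
C3_RANGE = (-35.0, -23.0)


def delta13c(r_p: float, r_standard: float) -> float:
    """δ13C in permil: (R_p/R_standard − 1) × 1000. Strictly increasing in
    R_p."""
    if r_p <= 0 or r_standard <= 0:
        raise ValueError("isotope ratios must be positive")
    return (r_p / r_standard - 1.0) * 1000.0


def discrimination(r_air: float, r_p: float) -> float:
    """Photosynthetic 13C discrimination Δ in permil:
    (R_air/R_p − 1) × 1000. Strictly increasing in R_air."""
    if r_air <= 0 or r_p <= 0:
        raise ValueError("isotope ratios must be positive")
    return (r_air / r_p - 1.0) * 1000.0


def classify_photosynthetic_type(d13c: float) -> str:
    """C4 if −14 ≤ δ ≤ −10, C3 if −35 ≤ δ ≤ −23, else intermediate
    (boundaries closed)."""
    if not np.isfinite(d13c):
        raise ValueError("delta13C must be finite")
    if C4_RANGE[0] <= d13c <= C4_RANGE[1]:
        return C4
    if C3_RANGE[0] <= d13c <= C3_RANGE[1]:
        return C3
    return INTERMEDIATE


@dataclass(frozen=True)
class IsotopeSample:
    sample_id: str
    d13c: float
    growth_class: str  # small | tall | wildtype
    r_p: float | None = None
    greenness: float | None = None
    stomatal_density: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.d13c):
            raise ValueError("delta13C must be finite")
        if self.r_p is not None and self.r_p <= 0:
            raise ValueError("isotope ratio must be positive")


@dataclass(frozen=True)
class PoolRange:
    """A sequencing pool's δ13C interval (closed) and required growth
    class."""

    name: str
    lower: float
    upper: float
    growth_class: str

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError(f"{self.name}: interval lower > upper")

    def matches(self, sample: IsotopeSample) -> bool:
        return (
            self.lower <= sample.d13c <= self.upper
            and sample.growth_class == self.growth_class
        )


#: the study's pooling design: two low-δ13C lethal pools, one normal-slow,
#: one normal-tall; the pool 3/4 δ13C intervals overlap and are told apart by
#: growth class.
STUDY_POOL_RANGES = (
    PoolRange("SbPool1", -14.319, -13.5869, GROWTH_SMALL),
    PoolRange("SbPool2", -13.5762, -13.3126, GROWTH_SMALL),
    PoolRange("SbPool3", -12.7924, -11.1609, GROWTH_SMALL),
    PoolRange("SbPool4", -12.6585, -12.2538, GROWTH_TALL),
)


class AmbiguousPoolError(ValueError):
    pass


def assign_pool(sample: IsotopeSample, ranges=STUDY_POOL_RANGES) -> str | None:
    """Pool whose δ13C interval contains the sample AND whose growth class
    matches; None if no pool matches (samples between intervals stay
    unpooled), error if more than one still matches."""
    hits = [r.name for r in ranges if r.matches(sample)]
    if len(hits) > 1:
        raise AmbiguousPoolError(
            f"{sample.sample_id}: δ13C {sample.d13c} matches pools {hits}"
        )
    return hits[0] if hits else None


def greenness_correlation(d13c, greenness) -> tuple[float, int]:
    """Pearson product-moment correlation between δ13C and greenness (SPAD),
    with the paired-sample count."""
    x = np.asarray(d13c, dtype=float)
    y = np.asarray(greenness, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r = stats.pearsonr(x, y).statistic
    return float(r), int(x.size)


def stomatal_summary(groups: dict[str, "np.ndarray"], alpha: float = 0.05) -> dict:
    """Mean ± sd of stomatal density per group plus pairwise two-sample
    Welch t-tests at the given significance level."""
    means, out = {}, {"groups": {}, "pairwise": {}}
    for name, obs in groups.items():
        arr = np.asarray(obs, dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {name!r}: sd undefined with < 2 observations")
        out["groups"][name] = {
            "n": int(arr.size),
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)),
        }
    names = list(groups)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            res = stats.ttest_ind(
                np.asarray(groups[a], float), np.asarray(groups[b], float), equal_var=False
            )
            out["pairwise"][f"{a}|{b}"] = {
                "p_value": float(res.pvalue),
                "significant": bool(res.pvalue <= alpha),
            }
    return out
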