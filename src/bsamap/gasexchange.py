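"""Gas-exchange curve parameters.

From an A/Ci curve (CO2 assimilation rate A against intercellular CO2
concentration Ci): carboxylation efficiency CE as the least-squares initial
slope over points with Ci < 100, the CO2 compensation point CP as that
line's x-intercept, and Pmax as the maximum observed A. From a light-response
curve (A against PPFD): quantum efficiency QE from the first four points with
PPFD < 100, the light compensation point RD as the x-intercept, and Jmax as
the maximum observed A.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

MODE_ACI = "aci"
MODE_LIGHT = "light"

#: initial-slope cutoffs on the abscissa
ACI_INITIAL_CUTOFF = 100.0
LIGHT_INITIAL_CUTOFF = 100.0
LIGHT_INITIAL_POINTS = 4


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class GasCurve:
    """Observations of one response curve; ``x`` is Ci (µmol CO2 / mol air)
    or PPFD (µmol quanta m⁻² s⁻¹), ``y`` is A (µmol CO2 m⁻² s⁻¹)."""

    mode: str
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.mode not in (MODE_ACI, MODE_LIGHT):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.x.size != self.y.size or self.x.size < 4:
            raise ValueError("need >= 4 (x, A) points")
        if np.any(self.x < 0):
            raise ValueError("abscissa must be non-negative")

    def sorted(self) -> tuple[np.ndarray, np.ndarray]:
        order = np.argsort(self.x, kind="stable")
        return self.x[order], self.y[order]


@dataclass(frozen=True)
class CurveParams:
    """Derived parameters; slope is CE or QE, compensation is CP or RD, and
    a_max is Pmax or Jmax depending on the curve mode. ``compensation`` is
    None when the initial-slope fit is not positive."""

    mode: str
    slope: float
    intercept: float
    compensation: float | None
    a_max: float
    n_initial: int

    @property
    def ce(self) -> float:
        return self.slope

    @property
    def qe(self) -> float:
        return self.slope

    @property
    def cp(self) -> float | None:
        return self.compensation

    @property
    def rd(self) -> float | None:
        return self.compensation

    @property
    def pmax(self) -> float:
        return self.a_max

    @property
    def jmax(self) -> float:
        return self.a_max


def _initial_fit(x, y, mode, intercept_mode: str):
    res = stats.linregress(x, y)
    slope, intercept = float(res.slope), float(res.intercept)
    if slope > 0:
        comp = -intercept / slope
        if intercept_mode == "interpolate":
            comp = _interp_x_intercept(x, y, comp)
    else:
        warnings.warn(
            f"{mode}: non-positive initial slope; compensation point undefined",
            RuntimeWarning,
            stacklevel=3,
        )
        comp = None
    return slope, intercept, comp


def _interp_x_intercept(x, y, fallback):
    """Linear interpolation between the raw points bracketing A = 0."""
    order = np.argsort(x)
    xs, ys = np.asarray(x)[order], np.asarray(y)[order]
    sign = np.sign(ys)
    for i in range(len(xs) - 1):
        if sign[i] <= 0 <= sign[i + 1] and ys[i + 1] != ys[i]:
            return float(xs[i] - ys[i] * (xs[i + 1] - xs[i]) / (ys[i + 1] - ys[i]))
    return fallback


def fit_aci(curve: GasCurve, intercept_mode: str = "line") -> CurveParams:
    """CE, CP and Pmax from an A/Ci curve.

    CE is the ordinary-least-squares slope over points with Ci < 100 (at
    least two required); CP is the x-intercept of that fitted line (or, with
    ``intercept_mode='interpolate'``, of the raw curve bracketing A = 0);
    Pmax is the maximum observed A.
    """
    if curve.mode != MODE_ACI:
        raise ValueError("fit_aci needs an A/Ci curve")
    x, y = curve.sorted()
    m = x < ACI_INITIAL_CUTOFF
    if m.sum() < 2:
        raise InsufficientDataError(
            f"A/Ci initial slope needs >= 2 points with Ci < {ACI_INITIAL_CUTOFF:g}, "
            f"have {int(m.sum())}"
        )
    slope, intercept, comp = _initial_fit(x[m], y[m], "A/Ci", intercept_mode)
    return CurveParams(
        mode=MODE_ACI, slope=slope, intercept=intercept, compensation=comp,
        a_max=float(y.max()), n_initial=int(m.sum()),
    )


def fit_light(curve: GasCurve, intercept_mode: str = "line") -> CurveParams:
    """QE, RD and Jmax from a light-response curve.

    QE is the least-squares slope over exactly the first four points (in
    ascending PPFD) with PPFD < 100; RD is the x-intercept of that line;
    Jmax is the maximum observed A.
    """
    if curve.mode != MODE_LIGHT:
        raise ValueError("fit_light needs a light-response curve")
    x, y = curve.sorted()
    m = np.flatnonzero(x < LIGHT_INITIAL_CUTOFF)
    if m.size < LIGHT_INITIAL_POINTS:
        raise InsufficientDataError(
            f"light-response initial slope needs >= {LIGHT_INITIAL_POINTS} points "
            f"with PPFD < {LIGHT_INITIAL_CUTOFF:g}, have {int(m.size)}"
        )
    sel = m[:LIGHT_INITIAL_POINTS]
    slope, intercept, comp = _initial_fit(x[sel], y[sel], "light response", intercept_mode)
    return CurveParams(
        mode=MODE_LIGHT, slope=slope, intercept=intercept, compensation=comp,
        a_max=float(y.max()), n_initial=LIGHT_INITIAL_POINTS,
    )


def synthesize_curve(
    mode: str,
    initial_slope: float,
    compensation: float,
    a_max: float,
    x_values,
    noise_sd: float = 0.0,
    rng=None,
    theta: float = 0.95,
) -> GasCurve:
    """A saturating response curve for recovery tests: the non-rectangular
    hyperbola θA² − (s·(x−c) + a_max)·A + s·(x−c)·a_max = 0 (the standard
    photosynthesis response model), whose lower root has initial slope s at
    the compensation point c and asymptote a_max, plus optional Gaussian
    noise."""
    x = np.asarray(x_values, dtype=float)
    u = initial_slope * (x - compensation)
    disc = np.maximum((u + a_max) ** 2 - 4.0 * theta * u * a_max, 0.0)
    a = (u + a_max - np.sqrt(disc)) / (2.0 * theta)
    if noise_sd > 0:
        rng = np.random.default_rng(rng)
        a = a + rng.normal(0.0, noise_sd, size=a.size)
    return GasCurve(mode=mode, x=x, y=a)
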