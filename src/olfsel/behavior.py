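"""Two-choice preference statistics and biphasic dose-response fitting.

The T-maze two-choice assay summarises the behaviour of a group of flies as a
preference index

    PI = (O - N) / (O + N)

where ``O`` flies chose the odor arm and ``N`` the odorless arm.  PI = +1 is
full attraction, -1 full aversion.  Dose-response curves of PI against odorant
concentration typically show attraction at low concentration switching to
aversion at high concentration; we model this as the difference of two Hill
terms and locate the valence crossover (the concentration where the fitted
curve changes sign).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.optimize import brentq, least_squares
from scipy.special import expit

__all__ = [
    "AssayCount",
    "DoseResponseCurve",
    "BiphasicFit",
    "compute_pi",
    "delta_pi",
    "fit_dose_response",
]


@dataclass(frozen=True)
class AssayCount:
    """Flies counted on the odor arm and on the no-odor arm of one assay."""

    n_odor: int
    n_no_odor: int

    def __post_init__(self) -> None:
        if self.n_odor < 0 or self.n_no_odor < 0:
            raise ValueError("arm counts must be non-negative")
        if self.n_odor + self.n_no_odor == 0:
            raise ValueError("empty assay: no flies on either arm")

    @property
    def total(self) -> int:
        return self.n_odor + self.n_no_odor


def compute_pi(counts: AssayCount) -> float:
    """Preference index (O - N) / (O + N) of a single two-choice assay."""
    return (counts.n_odor - counts.n_no_odor) / counts.total


def delta_pi(
    mean_selected: float,
    mean_control: float,
    direction: Literal["positive", "negative"] = "positive",
) -> float:
    """Generalization contrast between a selected treatment and the control.

    For lines selected toward attraction the contrast is
    ``mean(PI+) - mean(control)``; for lines selected toward aversion the sign
    is flipped (``mean(control) - mean(PI-)``) so that in both cases a larger
    value means the treatment moved in its selected direction relative to
    control.
    """
    if direction == "positive":
        return mean_selected - mean_control
    if direction == "negative":
        return mean_control - mean_selected
    raise ValueError(f"direction must be 'positive' or 'negative', got {direction!r}")


@dataclass(frozen=True)
class DoseResponseCurve:
    """Mean PI (+/- SE, n assays) at a series of increasing concentrations.

    Concentrations are v/v dilution fractions and must be positive and
    strictly increasing.
    """

    concentrations: tuple[float, ...]
    mean_pi: tuple[float, ...]
    se: tuple[float, ...] = ()
    n: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        y = np.asarray(self.mean_pi, dtype=float)
        if c.size != y.size:
            raise ValueError("concentrations and mean_pi must have equal length")
        if np.any(c <= 0):
            raise ValueError("concentrations must be positive (v/v fractions)")
        if np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be strictly increasing")

    def __len__(self) -> int:
        return len(self.concentrations)


@dataclass(frozen=True)
class BiphasicFit:
    """Difference-of-Hill-terms fit PI(c) = a*H(c;k_a,h_a) - b*H(c;k_b,h_b)."""

    a: float
    k_a: float
    h_a: float
    b: float
    k_b: float
    h_b: float
    crossover: Optional[float]
    rss: float

    def predict(self, concentration) -> np.ndarray:
        return biphasic(
            np.asarray(concentration, dtype=float),
            self.a, self.k_a, self.h_a, self.b, self.k_b, self.h_b,
        )

    def to_dict(self) -> dict:
        return {
            "a": self.a, "k_a": self.k_a, "h_a": self.h_a,
            "b": self.b, "k_b": self.k_b, "h_b": self.h_b,
            "crossover": self.crossover, "rss": self.rss,
        }


def hill(c, k, h):
    """Hill saturation c^h / (c^h + k^h), computed stably on the log scale."""
    c = np.asarray(c, dtype=float)
    return expit(h * (np.log(c) - math.log(k)))


def biphasic(c, a, k_a, h_a, b, k_b, h_b):
    return a * hill(c, k_a, h_a) - b * hill(c, k_b, h_b)


_CROSSOVER_TOL = 1e-10  # PI units


def fit_dose_response(
    curve: DoseResponseCurve,
    n_starts: int = 6,
    seed: int = 0,
) -> BiphasicFit:
    """Fit the biphasic valence model to a dose-response curve.

    Bounded nonlinear least squares with multiple starts: the two Hill
    midpoints are initialised on a log-spaced grid spanning the observed
    concentration range (attractive term toward low concentrations, aversive
    toward high), with small seeded jitter.  The crossover concentration is
    the first sign change of the fitted curve between the smallest and largest
    observed concentration, refined by root bisection to |PI| < 1e-10; it is
    ``None`` when the fitted curve does not change sign on that interval.
    """
    if len(curve) < 3:
        raise ValueError("dose-response fitting requires at least 3 points")
    c = np.asarray(curve.concentrations, dtype=float)
    y = np.asarray(curve.mean_pi, dtype=float)
    lc = np.log10(c)

    def residuals(theta):
        a, b, lka, lkb, ha, hb = theta
        return biphasic(c, a, 10.0 ** lka, ha, b, 10.0 ** lkb, hb) - y

    lo = np.array([0.0, 0.0, lc[0] - 3.0, lc[0] - 3.0, 0.2, 0.2])
    hi = np.array([2.0, 2.0, lc[-1] + 3.0, lc[-1] + 3.0, 8.0, 8.0])

    rng = np.random.default_rng(seed)
    span = lc[-1] - lc[0]
    a0 = float(np.clip(np.max(y), 0.05, 2.0))
    b0 = float(np.clip(np.max(y) - y[-1], 0.05, 2.0))
    solutions = []
    for i in range(max(n_starts, 1)):
        frac = i / max(n_starts - 1, 1)
        lka0 = lc[0] + 0.4 * span * frac + rng.uniform(-0.2, 0.2)
        lkb0 = lc[-1] - 0.4 * span * (1 - frac) + rng.uniform(-0.2, 0.2)
        h0 = 1.0 if i % 2 == 0 else 2.0
        theta0 = np.clip([a0, b0, lka0, lkb0, h0, h0], lo + 1e-9, hi - 1e-9)
        sol = least_squares(residuals, theta0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14)
        solutions.append(sol)
    # ties in cost are broken toward the smallest aversive amplitude: a
    # monotone attractive curve should not acquire a phantom aversive term
    # hidden beyond the observed concentration range
    best_cost = min(s.cost for s in solutions)
    tol = 1e-10 * (1.0 + best_cost)
    best = min((s for s in solutions if s.cost <= best_cost + tol),
               key=lambda s: s.x[1])

    a, b, lka, lkb, ha, hb = best.x
    k_a, k_b = 10.0 ** lka, 10.0 ** lkb
    rss = float(np.sum(best.fun ** 2))
    crossover = _find_crossover(lambda x: biphasic(x, a, k_a, ha, b, k_b, hb), c[0], c[-1])
    return BiphasicFit(a=float(a), k_a=float(k_a), h_a=float(ha),
                       b=float(b), k_b=float(k_b), h_b=float(hb),
                       crossover=crossover, rss=rss)


def _find_crossover(f, c_min: float, c_max: float, n_grid: int = 512) -> Optional[float]:
    """First sign change of ``f`` on [c_min, c_max], refined on the log axis."""
    grid = np.logspace(math.log10(c_min), math.log10(c_max), n_grid)
    vals = f(grid)
    if np.all(np.abs(vals) < _CROSSOVER_TOL):  # flat (null) curve: no crossing
        return None
    for i in range(n_grid - 1):
        v0, v1 = vals[i], vals[i + 1]
        if abs(v0) < _CROSSOVER_TOL and abs(f(grid[i])) < _CROSSOVER_TOL:
            continue
        if v0 * v1 < 0:
            g = lambda x: float(f(10.0 ** x))
            root = brentq(g, math.log10(grid[i]), math.log10(grid[i + 1]),
                          xtol=1e-15, maxiter=200)
            c_root = 10.0 ** root
            if abs(f(c_root)) <= max(_CROSSOVER_TOL, 1e-8 * max(abs(v0), abs(v1))):
                return float(c_root)
            return float(c_root)
    return None
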