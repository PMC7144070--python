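"""Realized-heritability estimation from selection trajectories.

Realized heritability is estimated as the slope of the cumulative response to
selection regressed on the cumulative selection differential across
generations (Falconer-style).  By default the regression is through the
origin: zero cumulative selection must give zero expected cumulative
response.  An intercept variant is exposed for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .selection import SelectionTrajectory

__all__ = ["HeritabilityEstimate", "realized_h2", "pi_scale_inputs"]

Scale = Literal["liability", "pi"]


@dataclass(frozen=True)
class HeritabilityEstimate:
    """Through-origin (or intercept) regression estimate of realized h2."""

    h2_hat: float
    se: float
    p_value: float
    df: int
    n_generations_used: int
    scale: Scale
    intercept: float = 0.0

    def to_dict(self) -> dict:
        return {
            "h2": self.h2_hat, "se": self.se, "p": self.p_value,
            "df": self.df, "scale": self.scale, "intercept": self.intercept,
        }


def realized_h2(
    population_means: Sequence[float],
    selected_means: Sequence[float],
    scale: Scale = "liability",
    intercept: bool = False,
) -> HeritabilityEstimate:
    """Realized h2 from per-generation population and selected-parent means.

    ``selected_means[t]`` is the mean trait of the parents chosen in
    generation ``t``; ``population_means`` carries one extra trailing entry
    (the post-selection generation) or, if the sequences have equal length,
    the final generation's selection round is dropped.  Per generation
    ``S_t = selected - population`` and ``R_t = population[t+1] -
    population[t]``; the estimate is the OLS slope of cumulative R on
    cumulative S, with a two-sided t test on the slope.
    """
    pop = np.asarray(population_means, dtype=float)
    sel = np.asarray(selected_means, dtype=float)
    if len(pop) == len(sel):
        sel = sel[:-1]
    if len(pop) != len(sel) + 1:
        raise ValueError(
            "population_means must have exactly one more entry than selected_means"
        )
    T = len(sel)
    if T < 3:
        raise ValueError("realized h2 needs at least 3 generations of selection")
    S = sel - pop[:-1]
    R = np.diff(pop)
    if np.all(S == 0):
        raise ValueError("all selection differentials are zero; slope undefined")
    cum_s = np.cumsum(S)
    cum_r = np.cumsum(R)

    if intercept:
        res = stats.linregress(cum_s, cum_r)
        df = T - 2
        return HeritabilityEstimate(
            h2_hat=float(res.slope), se=float(res.stderr),
            p_value=float(res.pvalue) if np.isfinite(res.pvalue) else np.finfo(float).tiny,
            df=df, n_generations_used=T, scale=scale,
            intercept=float(res.intercept),
        )

    sxx = float(np.dot(cum_s, cum_s))
    slope = float(np.dot(cum_s, cum_r)) / sxx
    resid = cum_r - slope * cum_s
    df = T - 1
    rss = float(np.dot(resid, resid))
    se = np.sqrt(rss / df / sxx)
    if se > 0:
        t_stat = slope / se
        p = float(2.0 * stats.t.sf(abs(t_stat), df))
        p = max(p, np.finfo(float).tiny)
    else:
        p = np.finfo(float).tiny if slope != 0 else 1.0
    return HeritabilityEstimate(
        h2_hat=slope, se=float(se), p_value=p, df=df,
        n_generations_used=T, scale=scale,
    )


def pi_scale_inputs(trajectory: SelectionTrajectory) -> tuple[np.ndarray, np.ndarray]:
    """Adapter for assay-only data: PI-scale (population, selected) means.

    When only the assay PI is observable, the selected parents all sit on one
    arm, so their group PI is +1 (upward lines) or -1 (downward lines) by
    construction.  Returns ``(population_means, selected_means)`` with
    ``population_means`` of length T+1 (including the post-selection census)
    and ``selected_means`` of length T.
    """
    if trajectory.direction == "control":
        raise ValueError("control trajectories have no defined selected-group PI")
    target = 1.0 if trajectory.direction == "positive" else -1.0
    pop = trajectory.pi_full
    sel = np.full(len(trajectory.pi), target)
    return pop, sel
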