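"""Individual-based simulation of divergent truncation selection on a
binary-choice preference trait, under a liability-threshold model.

Each fly carries a latent "liability" z ~ Normal(mu_t, sigma_p^2); it walks to
the odor arm iff z > 0.  Selection keeps the flies of one arm as parents
(odor arm for upward selection, odorless arm for downward, a random arm for
the unselected controls) and advances the population mean by the breeder's
equation mu_{t+1} = mu_t + h2 * S_t, where S_t is the realized liability-scale
selection differential.  The assay-scale preference index follows as
PI_t = 2 * Phi(mu_t / sigma_p) - 1 in expectation.

``expected_trajectory`` gives the infinite-population (deterministic)
recursion using the truncated-normal mean identities; the Monte-Carlo mean of
``simulate_line`` converges to it as the assay size and the number of
replicate lines grow.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .behavior import AssayCount, compute_pi

__all__ = [
    "Direction",
    "SelectionParams",
    "SelectionTrajectory",
    "ExpectedTrajectory",
    "simulate_line",
    "expected_trajectory",
]

Direction = Literal["positive", "negative", "control"]


@dataclass(frozen=True)
class SelectionParams:
    """Parameters of one artificial-selection line.

    h2 : narrow-sense heritability of the liability, in [0, 1].
    sigma_p : phenotypic SD of the liability (the liability scale unit).
    mu0 : initial mean liability; mu0 = 0 gives an initially indifferent
        population (expected PI = 0).
    n_flies : flies loaded into the T-maze each generation.
    n_generations : selection rounds (the study ran 30).
    direction : 'positive' (keep odor-arm flies), 'negative' (keep the other
        arm) or 'control' (keep one randomly chosen arm, odor absent).
    """

    h2: float
    sigma_p: float = 1.0
    mu0: float = 0.0
    n_flies: int = 30
    n_generations: int = 30
    direction: Direction = "positive"
    n_replicate_lines: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        if self.sigma_p <= 0:
            raise ValueError("sigma_p must be positive")
        if self.n_flies < 2:
            raise ValueError("n_flies must be at least 2")
        if self.n_generations < 1:
            raise ValueError("n_generations must be positive")
        if self.direction not in ("positive", "negative", "control"):
            raise ValueError(f"unknown direction {self.direction!r}")


class SelectionFailure(RuntimeError):
    """All retries of a generation's assay left the selected arm empty."""


@dataclass(frozen=True)
class SelectionTrajectory:
    """Per-generation records of one simulated line.

    Arrays have length ``n_generations``.  ``mu[t]`` / ``pi[t]`` are the mean
    liability and realized assay PI *before* selection in generation t;
    ``final_mu`` / ``final_pi`` record generation T after the last round of
    selection, so that responses telescope: ``r_liab[t] = mu[t+1] - mu[t]``.
    ``n_retries[t]`` counts assay re-draws forced by an empty selected arm.
    """

    direction: Direction
    mu: np.ndarray
    pi: np.ndarray
    s_liab: np.ndarray
    r_liab: np.ndarray
    s_pi: np.ndarray
    r_pi: np.ndarray
    n_selected: np.ndarray
    n_retries: np.ndarray
    final_mu: float
    final_pi: float

    @property
    def mu_full(self) -> np.ndarray:
        """Mean liability at generations 0..T (length n_generations + 1)."""
        return np.append(self.mu, self.final_mu)

    @property
    def pi_full(self) -> np.ndarray:
        """Assay PI at generations 0..T (length n_generations + 1)."""
        return np.append(self.pi, self.final_pi)

    def to_frame(self) -> pd.DataFrame:
        t = np.arange(len(self.mu))
        return pd.DataFrame({
            "generation": t,
            "mu": self.mu,
            "pi": self.pi,
            "s_liab": self.s_liab,
            "r_liab": self.r_liab,
            "s_pi": self.s_pi,
            "r_pi": self.r_pi,
            "n_selected": self.n_selected,
            "n_retries": self.n_retries,
        })


def _select_parents(z: np.ndarray, direction: Direction, rng: np.random.Generator) -> np.ndarray:
    on_odor = z > 0
    if direction == "positive":
        return z[on_odor]
    if direction == "negative":
        return z[~on_odor]
    # control: odor absent; one side is picked at random and its flies kept
    return z[on_odor] if rng.random() < 0.5 else z[~on_odor]


def simulate_line(
    params: SelectionParams,
    rng: Optional[np.random.Generator] = None,
    max_retries: int = 100,
) -> SelectionTrajectory:
    """Simulate one selection line for ``params.n_generations`` generations.

    If the selected arm is empty (every fly chose the other arm) the assay is
    re-drawn, mirroring the protocol of re-testing until enough parents are
    obtained; after ``max_retries`` consecutive failures a
    :class:`SelectionFailure` is raised.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    T = params.n_generations
    mu = np.empty(T)
    pi = np.empty(T)
    s_liab = np.empty(T)
    s_pi = np.empty(T)
    n_selected = np.empty(T, dtype=int)
    n_retries = np.zeros(T, dtype=int)

    mu_t = params.mu0
    for t in range(T):
        for attempt in range(max_retries + 1):
            z = rng.normal(mu_t, params.sigma_p, params.n_flies)
            n_odor = int(np.count_nonzero(z > 0))
            parents = _select_parents(z, params.direction, rng)
            if parents.size > 0:
                break
            n_retries[t] += 1
        else:
            raise SelectionFailure(
                f"generation {t}: selected arm empty in {max_retries} consecutive assays"
            )
        pi_t = compute_pi(AssayCount(n_odor, params.n_flies - n_odor))
        mu[t] = mu_t
        pi[t] = pi_t
        s_liab[t] = parents.mean() - z.mean()
        n_selected[t] = parents.size
        if params.direction == "positive":
            s_pi[t] = 1.0 - pi_t
        elif params.direction == "negative":
            s_pi[t] = -1.0 - pi_t
        else:
            s_pi[t] = 0.0
        mu_t = mu_t + params.h2 * s_liab[t]

    # final census assay (generation T, after the last selection round)
    z = rng.normal(mu_t, params.sigma_p, params.n_flies)
    n_odor = int(np.count_nonzero(z > 0))
    final_pi = compute_pi(AssayCount(n_odor, params.n_flies - n_odor))

    r_liab = np.diff(np.append(mu, mu_t))
    r_pi = np.diff(np.append(pi, final_pi))
    return SelectionTrajectory(
        direction=params.direction,
        mu=mu, pi=pi, s_liab=s_liab, r_liab=r_liab, s_pi=s_pi, r_pi=r_pi,
        n_selected=n_selected, n_retries=n_retries,
        final_mu=float(mu_t), final_pi=float(final_pi),
    )


@dataclass(frozen=True)
class ExpectedTrajectory:
    """Infinite-population expectation of a selected line.

    ``mu`` and ``pi`` have length ``n_generations + 1`` (generations 0..T);
    ``s_liab`` has length ``n_generations``.
    """

    mu: np.ndarray
    pi: np.ndarray
    s_liab: np.ndarray


def expected_trajectory(params: SelectionParams) -> ExpectedTrajectory:
    """Deterministic recursion for the expected selection trajectory.

    Uses the truncated-normal mean identities: selecting the z > 0 tail of
    Normal(mu, sigma^2) gives a selection differential
    sigma * phi(mu/sigma) / Phi(mu/sigma); the z < 0 tail gives
    -sigma * phi(mu/sigma) / (1 - Phi(mu/sigma)).  The expected assay PI is
    2 * Phi(mu/sigma) - 1.
    """
    if params.direction == "control":
        raise ValueError("control lines have no selection expectation beyond mu0")
    T = params.n_generations
    mu = np.empty(T + 1)
    pi = np.empty(T + 1)
    s = np.empty(T)
    mu[0] = params.mu0
    for t in range(T):
        m = mu[t] / params.sigma_p
        pi[t] = 2.0 * norm.cdf(m) - 1.0
        if params.direction == "positive":
            s[t] = params.sigma_p * norm.pdf(m) / norm.cdf(m)
        else:
            s[t] = -params.sigma_p * norm.pdf(m) / norm.sf(m)
        mu[t + 1] = mu[t] + params.h2 * s[t]
    pi[T] = 2.0 * norm.cdf(mu[T] / params.sigma_p) - 1.0
    return ExpectedTrajectory(mu=mu, pi=pi, s_liab=s)
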