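"""Physicochemical odor-space distances and generalization regression.

Odorants are embedded in a descriptor space (any user-supplied odorant x
descriptor matrix of physicochemical properties).  Each descriptor column is
z-scored across the loaded odorant set (sample SD, n-1 denominator) and the
distance between two odorants is the Euclidean distance between their
standardized rows; zero-variance descriptors carry no information and are
dropped with a warning.  Because standardization is relative to the loaded
set, adding or removing odorants changes the metric — distances are always
recomputed from the current matrix, never cached.

Behavioral generalization is quantified by regressing the selected-line PI
contrast (delta-PI, see :mod:`olfsel.behavior`) against the distance between
the selection odorant and each test odorant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DescriptorMatrix",
    "GeneralizationFit",
    "physchem_distance",
    "pairwise_distances",
    "generalization_regression",
]


@dataclass(frozen=True)
class DescriptorMatrix:
    """Odorant x descriptor matrix (rows indexed by unique odorant names)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("odorant names must be unique")
        if self.data.columns.has_duplicates:
            raise ValueError("descriptor names must be unique")
        if self.data.isna().any().any():
            raise ValueError("descriptor matrix contains missing values")

    @classmethod
    def from_csv(cls, path) -> "DescriptorMatrix":
        """Load a CSV whose first column is the odorant name."""
        df = pd.read_csv(path, index_col=0)
        return cls(df.astype(float))

    @property
    def odorants(self) -> list[str]:
        return list(self.data.index)

    @property
    def descriptors(self) -> list[str]:
        return list(self.data.columns)

    def standardized(self) -> pd.DataFrame:
        """Column-wise z-scores over the loaded set; constant columns dropped."""
        if len(self.data) < 2:
            raise ValueError("standardization requires at least 2 odorants")
        sd = self.data.std(axis=0, ddof=1)
        constant = sd[sd == 0].index
        if len(constant) > 0:
            warnings.warn(
                f"dropping {len(constant)} zero-variance descriptor(s): "
                f"{list(constant)[:5]}...",
                UserWarning,
                stacklevel=2,
            )
        kept = self.data.drop(columns=constant)
        return (kept - kept.mean(axis=0)) / sd.drop(constant)


def physchem_distance(matrix: DescriptorMatrix, a: str, b: str) -> float:
    """Euclidean distance between two odorants in standardized descriptor space."""
    z = matrix.standardized()
    for name in (a, b):
        if name not in z.index:
            raise KeyError(f"unknown odorant {name!r}")
    return float(np.linalg.norm(z.loc[a].to_numpy() - z.loc[b].to_numpy()))


def pairwise_distances(
    matrix: DescriptorMatrix,
    pairs: Optional[Iterable[tuple[str, str]]] = None,
    reference: Optional[str] = None,
) -> pd.DataFrame:
    """Distances for explicit pairs, or from one reference odorant to all others."""
    z = matrix.standardized()
    if (pairs is None) == (reference is None):
        raise ValueError("provide exactly one of 'pairs' or 'reference'")
    if reference is not None:
        if reference not in z.index:
            raise KeyError(f"unknown odorant {reference!r}")
        pairs = [(reference, other) for other in z.index if other != reference]
    rows = []
    for a, b in pairs:
        for name in (a, b):
            if name not in z.index:
                raise KeyError(f"unknown odorant {name!r}")
        d = float(np.linalg.norm(z.loc[a].to_numpy() - z.loc[b].to_numpy()))
        rows.append({"odorant_a": a, "odorant_b": b, "distance": d})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GeneralizationFit:
    """OLS fit (with intercept) of delta-PI on physicochemical distance."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int

    def to_dict(self) -> dict:
        return {
            "slope": self.slope, "intercept": self.intercept,
            "r_squared": self.r_squared, "p": self.p_value, "n": self.n,
        }


def generalization_regression(
    distances: Sequence[float],
    delta_pi: Sequence[float],
) -> GeneralizationFit:
    """Regress delta-PI against odor-space distance (two-sided slope test)."""
    x = np.asarray(distances, dtype=float)
    y = np.asarray(delta_pi, dtype=float)
    if x.size != y.size:
        raise ValueError("distances and delta_pi must be aligned")
    if x.size < 3:
        raise ValueError("generalization regression needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("distances have zero variance; slope undefined")
    if np.ptp(y) == 0:
        # flat response: slope 0 explains nothing beyond the mean
        return GeneralizationFit(slope=0.0, intercept=float(y[0]),
                                 r_squared=0.0, p_value=1.0, n=int(x.size))
    res = stats.linregress(x, y)
    return GeneralizationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        p_value=float(res.pvalue),
        n=int(x.size),
    )
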