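"""Synthetic-data generators for every pipeline stage.

These emulate the statistical structure of a divergent-selection study:
replicate selection trajectories under a stated heritability, negative-
binomial RNA-seq count matrices with planted fold changes across the three
treatments (PI+, PI-, control) in the study's design shape (3 replicate
lines x 2 biological reps per treatment per regime), odorant descriptor
matrices with a planted distance-response slope, and random term
annotations with one planted enriched term.  Every generator is a pure
function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .odorspace import DescriptorMatrix, pairwise_distances
from .selection import SelectionParams, SelectionTrajectory, simulate_line

__all__ = [
    "CountSimSpec",
    "gen_selection_experiment",
    "gen_counts",
    "gen_generalization",
    "gen_annotation",
]


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def gen_selection_experiment(
    template: SelectionParams,
    seed: int,
    n_replicate_lines: Optional[int] = None,
) -> pd.DataFrame:
    """Simulate a full experiment: replicate PI+, PI- and control lines.

    Returns a tidy frame with one row per (line, generation) and the
    trajectory columns, plus ``direction`` and ``replicate`` identifiers.
    Each line runs on an independent substream derived from ``seed``.
    """
    n_rep = n_replicate_lines or template.n_replicate_lines
    directions = ("positive", "negative", "control")
    rngs = _spawn_rngs(seed, len(directions) * n_rep)
    frames = []
    i = 0
    for direction in directions:
        for rep in range(1, n_rep + 1):
            params = replace(template, direction=direction)
            traj = simulate_line(params, rng=rngs[i])
            df = traj.to_frame()
            df.insert(0, "replicate", rep)
            df.insert(0, "direction", direction)
            frames.append(df)
            i += 1
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class CountSimSpec:
    """Specification of a synthetic NB count matrix with planted DE genes.

    ``de_assignment`` maps gene index -> (tuple of affected treatment
    groups, sign); if omitted, the first ``n_de`` genes are planted with the
    affected non-control group cycling and signs alternating up/down, so
    that the bulk of genes stays non-DE and symmetric (TMM's assumption).
    Library sizes are drawn uniformly per sample; baseline expression is
    log-normal (log2 mean 5, log2 SD 2 by default), giving a realistic
    dynamic range.
    """

    n_genes: int = 2000
    samples_per_group: int = 6
    groups: tuple = ("PI_plus", "PI_minus", "control")
    lib_size_range: tuple = (800_000, 1_200_000)
    dispersion: float = 0.1
    n_de: int = 0
    log2fc_magnitude: float = 2.0
    de_assignment: Optional[Mapping[int, tuple]] = None
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 2.0
    regime: str = "BUT"
    n_replicate_lines: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_de > self.n_genes:
            raise ValueError("n_de cannot exceed n_genes")
        if min(self.lib_size_range) <= 0:
            raise ValueError("library sizes must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")

    def resolved_assignment(self) -> dict[int, tuple]:
        if self.de_assignment is not None:
            return dict(self.de_assignment)
        non_control = [g for g in self.groups if g != "control"] or list(self.groups)
        out = {}
        for i in range(self.n_de):
            group = non_control[i % len(non_control)]
            sign = 1 if (i // len(non_control)) % 2 == 0 else -1
            out[i] = ((group,), sign)
        return out


def gen_counts(spec: CountSimSpec) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate ``(counts, metadata, truth)`` for one selection regime.

    Counts are NB(mean = relative abundance x library size x 2^lfc,
    dispersion) — Poisson when the dispersion is 0.  Metadata follows the
    study design: each treatment's samples are labelled with a replicate
    line (cycling 1..n_replicate_lines) and a biological rep.  ``truth``
    records, per gene, whether it is DE and its true log2 fold change
    relative to control in each non-control group.
    """
    rng = np.random.default_rng(spec.seed)
    G, S = spec.n_genes, spec.samples_per_group
    genes = [f"g{i:05d}" for i in range(G)]

    rel = 2.0 ** rng.normal(spec.baseline_log2_mean, spec.baseline_log2_sd, G)
    rel /= rel.sum()

    assignment = spec.resolved_assignment()
    lfc = pd.DataFrame(0.0, index=genes, columns=list(spec.groups))
    for idx, (affected, sign) in assignment.items():
        for g in affected:
            lfc.iloc[idx, lfc.columns.get_loc(g)] = sign * spec.log2fc_magnitude

    sample_ids, rows = [], []
    for group in spec.groups:
        for j in range(S):
            line = j % spec.n_replicate_lines + 1
            rep = j // spec.n_replicate_lines + 1
            sid = f"{spec.regime}_{group}_L{line}_R{rep}"
            sample_ids.append(sid)
            rows.append({
                "sample_id": sid, "regime": spec.regime, "treatment": group,
                "replicate_line": line, "bio_rep": rep,
            })
    metadata = pd.DataFrame(rows)

    lib = rng.integers(spec.lib_size_range[0], spec.lib_size_range[1] + 1,
                       size=len(sample_ids))
    counts = np.empty((G, len(sample_ids)), dtype=np.int64)
    col = 0
    for group in spec.groups:
        fold = 2.0 ** lfc[group].to_numpy()
        for j in range(S):
            mu = rel * fold * lib[col]
            if spec.dispersion == 0:
                counts[:, col] = rng.poisson(mu)
            else:
                shape = 1.0 / spec.dispersion
                lam = rng.gamma(shape, mu * spec.dispersion)
                counts[:, col] = rng.poisson(lam)
            col += 1
    counts_df = pd.DataFrame(counts, index=genes, columns=sample_ids)

    truth = pd.DataFrame({"is_de": np.zeros(G, dtype=bool)}, index=genes)
    for g in spec.groups:
        if g != "control":
            truth[f"lfc_{g}_vs_control"] = lfc[g].to_numpy()
    for idx in assignment:
        truth.iloc[idx, truth.columns.get_loc("is_de")] = True
    return counts_df, metadata, truth


def gen_generalization(
    n_odorants: int = 13,
    slope: float = -0.08,
    intercept: float = 0.5,
    noise_sd: float = 0.05,
    n_descriptors: int = 20,
    seed: int = 0,
) -> tuple[DescriptorMatrix, pd.DataFrame, dict]:
    """Descriptor matrix plus delta-PI responses with a planted linear slope.

    The first odorant plays the role of the selection odorant; distances from
    it to the remaining test odorants are computed in standardized descriptor
    space, and delta-PI = slope * distance + intercept + Gaussian noise.
    Returns ``(descriptors, table, truth)`` where ``table`` has columns
    ``odorant``, ``distance``, ``delta_pi``.
    """
    if n_odorants < 3:
        raise ValueError("need at least 3 odorants")
    rng = np.random.default_rng(seed)
    names = ["selection_odorant"] + [f"test_{i:02d}" for i in range(1, n_odorants)]
    values = rng.normal(size=(n_odorants, n_descriptors))
    matrix = DescriptorMatrix(pd.DataFrame(
        values, index=names,
        columns=[f"d{j:03d}" for j in range(n_descriptors)],
    ))
    dist = pairwise_distances(matrix, reference=names[0])
    d = dist["distance"].to_numpy()
    dpi = slope * d + intercept + rng.normal(0.0, noise_sd, size=d.size)
    table = pd.DataFrame({
        "odorant": dist["odorant_b"], "distance": d, "delta_pi": dpi,
    })
    return matrix, table, {"slope": slope, "intercept": intercept, "noise_sd": noise_sd}


def gen_annotation(
    n_terms: int = 50,
    term_size_range: tuple = (10, 80),
    universe_size: int = 5000,
    study_size: int = 100,
    planted_term_size: int = 50,
    planted_enrichment_fold: float = 5.0,
    seed: int = 0,
) -> tuple[dict, set, str]:
    """Random GMT-style annotation with one planted enriched term.

    Returns ``(annotation, study, planted_term_id)``.  Genes of the planted
    term are oversampled into the study set at ``planted_enrichment_fold``
    times the base rate; fold 1 reduces to a null draw.
    """
    rng = np.random.default_rng(seed)
    universe = np.array([f"g{i:05d}" for i in range(universe_size)])
    annotation: dict[str, set] = {}
    planted_id = "T0000_planted"
    planted_genes = rng.choice(universe, size=min(planted_term_size, universe_size),
                               replace=False)
    annotation[planted_id] = set(planted_genes)
    for t in range(1, n_terms):
        size = int(rng.integers(term_size_range[0], term_size_range[1] + 1))
        annotation[f"T{t:04d}"] = set(rng.choice(universe, size=size, replace=False))

    weights = np.ones(universe_size)
    planted_idx = np.isin(universe, planted_genes)
    weights[planted_idx] = planted_enrichment_fold
    weights /= weights.sum()
    study = set(rng.choice(universe, size=study_size, replace=False, p=weights))
    return annotation, study, planted_id
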