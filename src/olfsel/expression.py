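"""Expression-divergence engine: count matrix -> valence-classified DE genes.

The pipeline mirrors a standard bulk RNA-seq differential-expression
workflow for a three-treatment selection design (PI+, PI-, unselected
control), starting from a gene x sample matrix of raw counts:

1. keep genes with CPM >= 1 in at least half the samples;
2. trimmed-mean-of-M-values (TMM) normalization factors;
3. a single common negative-binomial dispersion (method of moments);
4. per-gene conditional NB exact tests for the three pairwise contrasts
   (PI+ vs control, PI+ vs PI-, PI- vs control), pooling replicate lines
   within each treatment;
5. Benjamini-Hochberg FDR at q <= 0.1;
6. Venn classification of the significant sets into positive-valence,
   negative-valence and generalized candidate genes;
7. hypergeometric (one-sided Fisher) term overrepresentation with BH FDR.

Counts are held in plain pandas DataFrames (genes as the index, samples as
columns); sample metadata is a DataFrame with columns ``sample_id``,
``regime``, ``treatment``, ``replicate_line``, ``bio_rep``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

__all__ = [
    "cpm",
    "filter_expressed",
    "tmm_factors",
    "estimate_common_dispersion",
    "nb_exact_test",
    "bh_adjust",
    "run_contrasts",
    "venn_classify",
    "term_enrichment",
    "VennClassification",
    "RegimeDEResult",
    "CONTRAST_NAMES",
]

TREATMENTS = ("PI_plus", "PI_minus", "control")
CONTRAST_NAMES = ("PI_plus_vs_control", "PI_plus_vs_PI_minus", "PI_minus_vs_control")
_CONTRAST_GROUPS = {
    "PI_plus_vs_control": ("PI_plus", "control"),
    "PI_plus_vs_PI_minus": ("PI_plus", "PI_minus"),
    "PI_minus_vs_control": ("PI_minus", "control"),
}


def _validate_counts(counts: pd.DataFrame) -> None:
    if (counts.to_numpy() < 0).any():
        raise ValueError("count matrix contains negative entries")


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million: each entry scaled by its sample's library size."""
    _validate_counts(counts)
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"zero library size for sample(s) {bad}")
    return counts / lib * 1e6


def filter_expressed(
    counts: pd.DataFrame,
    min_cpm: float = 1.0,
    min_fraction: float = 0.5,
) -> pd.DataFrame:
    """Keep genes with CPM >= ``min_cpm`` in at least ``min_fraction`` of samples.

    For an even sample count the default means exactly half the samples
    qualifying is enough.  Gene order is preserved; the operation is
    idempotent (library sizes are taken from the input matrix each call, but
    a gene passing on the full matrix also passes on the filtered one since
    filtering only lowers library sizes and thus raises CPMs).
    """
    c = cpm(counts)
    n_qualifying = (c >= min_cpm).sum(axis=1)
    keep = n_qualifying >= counts.shape[1] * min_fraction
    return counts.loc[keep]


def tmm_factors(
    counts: pd.DataFrame,
    log_ratio_trim: float = 0.3,
    abs_expr_trim: float = 0.05,
    min_genes: int = 5,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors (geometric mean 1).

    The reference sample is the one whose upper-quartile relative abundance
    is closest to the mean upper quartile.  For each sample, gene-wise log2
    expression ratios to the reference (M) and average log2 abundances (A)
    are computed over genes nonzero in both samples, the most extreme
    ``log_ratio_trim`` of M and ``abs_expr_trim`` of A are dropped from each
    tail, and the factor is 2 to the precision-weighted mean of the
    surviving M values (weights: inverse binomial delta-method variances).
    If fewer than ``min_genes`` genes survive trimming the factor falls back
    to 1 with a warning.
    """
    _validate_counts(counts)
    X = counts.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    if n_samples < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = X.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("zero library size")

    f75 = np.quantile(X / lib, 0.75, axis=0)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(n_samples)
    refv = X[:, ref]
    for k in range(n_samples):
        obs = X[:, k]
        both = (obs > 0) & (refv > 0)
        if both.sum() < min_genes:
            warnings.warn(f"sample {counts.columns[k]!r}: too few genes shared "
                          "with the reference; TMM factor set to 1", UserWarning)
            continue
        p_obs = obs[both] / lib[k]
        p_ref = refv[both] / lib[ref]
        M = np.log2(p_obs / p_ref)
        A = 0.5 * np.log2(p_obs * p_ref)
        n = M.size
        lo_m = math.floor(n * log_ratio_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * abs_expr_trim) + 1
        hi_a = n + 1 - lo_a
        r_m = rankdata(M)
        r_a = rankdata(A)
        keep = (r_m >= lo_m) & (r_m <= hi_m) & (r_a >= lo_a) & (r_a <= hi_a)
        if keep.sum() < min_genes:
            warnings.warn(f"sample {counts.columns[k]!r}: fewer than {min_genes} "
                          "genes after trimming; TMM factor set to 1", UserWarning)
            continue
        w = ((lib[k] - obs[both]) / (lib[k] * obs[both])
             + (lib[ref] - refv[both]) / (lib[ref] * refv[both]))
        factors[k] = 2.0 ** (np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep]))

    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def _effective_lib_sizes(counts: pd.DataFrame, factors: Optional[pd.Series]) -> pd.Series:
    lib = counts.sum(axis=0)
    if factors is None:
        return lib.astype(float)
    return lib * factors.reindex(lib.index)


# chi-square median-bias correction for a sample variance on df degrees of
# freedom: median(chi2_df) ~ df * (1 - 2/(9 df))^3
def _median_bias_factor(df: int) -> float:
    return 1.0 / (1.0 - 2.0 / (9.0 * df)) ** 3


def estimate_common_dispersion(
    counts: pd.DataFrame,
    groups: Mapping[str, Sequence[str]] | Sequence[Sequence[str]],
    factors: Optional[pd.Series] = None,
) -> float:
    """Common NB dispersion: median of per-gene method-of-moments estimates.

    Counts are scaled to a common effective library size; within each group
    the gene's mean m and sample variance v give a moment estimate
    (v - m) / m^2 of the dispersion (clipped at 0), and the per-gene
    estimates (df-weighted across groups) are summarised by their median
    across genes.  Sample variances are multiplied by the chi-square
    median-bias factor so the median across genes is approximately centred
    on the true dispersion at small group sizes.
    """
    if isinstance(groups, Mapping):
        group_list = list(groups.values())
    else:
        group_list = [list(g) for g in groups]
    for g in group_list:
        if len(g) < 2:
            raise ValueError("every group needs at least 2 samples to estimate dispersion")
    eff = _effective_lib_sizes(counts, factors)
    all_samples = [s for g in group_list for s in g]
    L = float(np.exp(np.mean(np.log(eff[all_samples]))))

    per_gene_num = np.zeros(counts.shape[0])
    per_gene_den = np.zeros(counts.shape[0])
    defined = np.zeros(counts.shape[0], dtype=bool)
    # the per-gene estimate pools both groups, so the variance correction
    # uses the combined degrees of freedom
    df_total = sum(len(g) - 1 for g in group_list)
    for g in group_list:
        Y = counts[g].to_numpy(dtype=float) * (L / eff[g].to_numpy())
        m = Y.mean(axis=1)
        df = len(g) - 1
        v = Y.var(axis=1, ddof=1) * _median_bias_factor(df_total)
        ok = m > 0
        phi = np.zeros_like(m)
        phi[ok] = np.clip((v[ok] - m[ok]) / m[ok] ** 2, 0.0, None)
        per_gene_num[ok] += df * phi[ok]
        per_gene_den[ok] += df
        defined |= ok
    usable = defined & (per_gene_den > 0)
    if not usable.any():
        return 0.0
    phi_gene = per_gene_num[usable] / per_gene_den[usable]
    return float(np.median(phi_gene))


def _pseudo_counts(
    counts: pd.DataFrame,
    samples: Sequence[str],
    factors: Optional[pd.Series],
) -> tuple[np.ndarray, float]:
    """Counts scaled to the geometric-mean effective library size, rounded."""
    eff = _effective_lib_sizes(counts, factors)[list(samples)]
    L = float(np.exp(np.mean(np.log(eff))))
    scaled = counts[list(samples)].to_numpy(dtype=float) * (L / eff.to_numpy())
    return np.rint(scaled).astype(np.int64), L


def exact_nb_p_value(y_a: int, y_b: int, n_a: int, n_b: int, dispersion: float) -> float:
    """Two-sided conditional exact p for an A/B split of a gene's total count.

    Group sums of ``n`` i.i.d. NB(mean mu, dispersion phi) variables are
    NB(mean n*mu, dispersion phi/n); conditioning on the total, the group-A
    sum has a distribution free of mu (binomial when phi = 0).  The two-sided
    p sums the probabilities of all splits as or less likely than the one
    observed (ties included).
    """
    total = y_a + y_b
    if total == 0:
        return 1.0
    k = np.arange(total + 1)
    if dispersion <= 0:
        logp = stats.binom.logpmf(k, total, n_a / (n_a + n_b))
    else:
        r_a = n_a / dispersion
        r_b = n_b / dispersion
        mu = total / (n_a + n_b)
        p_a = r_a / (r_a + n_a * mu)
        p_b = r_b / (r_b + n_b * mu)
        logp = stats.nbinom.logpmf(k, r_a, p_a) + stats.nbinom.logpmf(k[::-1], r_b, p_b)
        logp -= logsumexp(logp)
    obs = logp[y_a]
    p = float(np.exp(logsumexp(logp[logp <= obs + 1e-10])))
    return min(p, 1.0)


def nb_exact_test(
    counts: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    dispersion: float,
    factors: Optional[pd.Series] = None,
    pseudo_count: float = 0.5,
) -> pd.DataFrame:
    """Per-gene NB exact test between two sample groups.

    Returns a DataFrame indexed by gene with ``log2_fold_change`` (group A
    over group B, from normalized group-mean CPMs with a ``pseudo_count``
    offset) and ``p_value``.  FDR adjustment is applied separately (see
    :func:`bh_adjust`).
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    pseudo, L = _pseudo_counts(counts, group_a + group_b, factors)
    n_a, n_b = len(group_a), len(group_b)
    y_a = pseudo[:, :n_a].sum(axis=1)
    y_b = pseudo[:, n_a:].sum(axis=1)

    p_values = np.array([
        exact_nb_p_value(int(ya), int(yb), n_a, n_b, dispersion)
        for ya, yb in zip(y_a, y_b)
    ])
    mean_a = y_a / n_a + pseudo_count
    mean_b = y_b / n_b + pseudo_count
    log2fc = np.log2((mean_a / L) / (mean_b / L))
    return pd.DataFrame(
        {"log2_fold_change": log2fc, "p_value": p_values},
        index=counts.index,
    )


def bh_adjust(p_values: Sequence[float], alpha: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment; significance at q <= ``alpha``.

    Returns ``(q_values, significant)``; empty input gives empty arrays.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def _finalize_contrast(de: pd.DataFrame, alpha: float) -> pd.DataFrame:
    q, sig = bh_adjust(de["p_value"].to_numpy(), alpha=alpha)
    out = de.copy()
    out["fdr_q"] = q
    out["significant"] = sig
    direction = np.where(
        ~sig, "none",
        np.where(out["log2_fold_change"] > 0, "up_in_first", "up_in_second"),
    )
    out["direction"] = direction
    return out


@dataclass(frozen=True)
class VennClassification:
    """Disjoint regions of the three DE contrasts and the valence labels.

    A = PI+ vs control, B = PI+ vs PI-, C = PI- vs control.  Genes shared by
    A and B respond to upward selection both against the control and against
    the opposite line — positive-valence candidates; B and C similarly mark
    negative-valence candidates; genes in all three contrasts are candidates
    for generalized (valence-independent) change.
    """

    a_only: frozenset
    b_only: frozenset
    c_only: frozenset
    ab: frozenset
    ac: frozenset
    bc: frozenset
    abc: frozenset

    @property
    def positive_valence_candidates(self) -> frozenset:
        return self.ab | self.abc

    @property
    def negative_valence_candidates(self) -> frozenset:
        return self.bc | self.abc

    @property
    def generalized(self) -> frozenset:
        return self.abc

    @property
    def union(self) -> frozenset:
        return (self.a_only | self.b_only | self.c_only
                | self.ab | self.ac | self.bc | self.abc)

    def region_counts(self) -> dict[str, int]:
        return {
            "A_only": len(self.a_only), "B_only": len(self.b_only),
            "C_only": len(self.c_only), "AB": len(self.ab),
            "AC": len(self.ac), "BC": len(self.bc), "ABC": len(self.abc),
        }


def venn_classify(a: Iterable, b: Iterable, c: Iterable) -> VennClassification:
    """Partition three DE gene sets into the seven disjoint Venn regions."""
    A, B, C = set(a), set(b), set(c)
    abc = A & B & C
    return VennClassification(
        a_only=frozenset(A - B - C),
        b_only=frozenset(B - A - C),
        c_only=frozenset(C - A - B),
        ab=frozenset((A & B) - abc),
        ac=frozenset((A & C) - abc),
        bc=frozenset((B & C) - abc),
        abc=frozenset(abc),
    )


@dataclass(frozen=True)
class RegimeDEResult:
    """Full DE analysis of one selection regime."""

    contrasts: dict
    venn: VennClassification
    dispersion: float
    factors: pd.Series
    n_genes_tested: int


def run_contrasts(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    regime: str,
    fdr: float = 0.1,
) -> RegimeDEResult:
    """Run the three pairwise treatment contrasts for one selection regime.

    Replicate lines are pooled within each treatment.  Expression filtering,
    TMM factors and the common dispersion are computed once on the regime's
    full matrix and shared by the three contrasts.
    """
    meta = metadata[metadata["regime"] == regime]
    if meta.empty:
        raise ValueError(f"no samples for regime {regime!r}")
    samples_by_treatment = {}
    for t in TREATMENTS:
        s = list(meta.loc[meta["treatment"] == t, "sample_id"])
        if not s:
            raise ValueError(f"regime {regime!r} is missing treatment {t!r}")
        samples_by_treatment[t] = s
    all_samples = [s for t in TREATMENTS for s in samples_by_treatment[t]]
    missing = [s for s in all_samples if s not in counts.columns]
    if missing:
        raise ValueError(f"metadata samples absent from count matrix: {missing}")

    sub = counts[all_samples]
    filtered = filter_expressed(sub)
    factors = tmm_factors(filtered)
    dispersion = estimate_common_dispersion(filtered, samples_by_treatment, factors)

    results = {}
    for name, (ga, gb) in _CONTRAST_GROUPS.items():
        de = nb_exact_test(
            filtered, samples_by_treatment[ga], samples_by_treatment[gb],
            dispersion, factors=factors,
        )
        results[name] = _finalize_contrast(de, alpha=fdr)

    sig_sets = [
        set(results[name].index[results[name]["significant"]])
        for name in CONTRAST_NAMES
    ]
    venn = venn_classify(*sig_sets)
    return RegimeDEResult(
        contrasts=results, venn=venn, dispersion=dispersion,
        factors=factors, n_genes_tested=filtered.shape[0],
    )


def term_enrichment(
    study: Iterable,
    universe: Iterable,
    annotation: Mapping[str, Iterable],
    alpha: float = 0.1,
) -> pd.DataFrame:
    """Overrepresentation of annotation terms in a study gene set.

    One-sided hypergeometric upper-tail p per term (equivalent to Fisher's
    exact test on the 2x2 in/out-of-study x in/out-of-term table), with BH
    adjustment across terms.  Annotation gene sets are intersected with the
    universe first.
    """
    universe = set(universe)
    study = set(study)
    if not universe:
        raise ValueError("empty universe")
    if not study <= universe:
        raise ValueError("study set must be a subset of the universe")
    M, N = len(universe), len(study)
    rows = []
    for term, genes in annotation.items():
        term_genes = set(genes) & universe
        K = len(term_genes)
        k = len(term_genes & study)
        p = float(stats.hypergeom.sf(k - 1, M, K, N)) if K > 0 else 1.0
        rows.append({
            "term_id": term, "overlap_count": k, "term_size": K,
            "study_size": N, "universe_size": M, "p_value": min(p, 1.0),
        })
    out = pd.DataFrame(rows).set_index("term_id")
    if len(out) > 0:
        q, sig = bh_adjust(out["p_value"].to_numpy(), alpha=alpha)
        out["fdr_q"] = q
        out["significant"] = sig
    return out
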