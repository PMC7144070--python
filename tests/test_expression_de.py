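"""NB dispersion, exact tests, FDR, Venn valence logic and term enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from olfsel.expression import (
    bh_adjust,
    estimate_common_dispersion,
    exact_nb_p_value,
    filter_expressed,
    nb_exact_test,
    run_contrasts,
    term_enrichment,
    venn_classify,
)
from olfsel.synth import CountSimSpec, gen_counts


# --- independent oracles -------------------------------------------------

def oracle_exact_p(y_a, y_b, n_a, n_b, phi):
    """Direct enumeration of the conditional split distribution via lgamma."""
    t = y_a + y_b
    if t == 0:
        return 1.0
    if phi == 0:
        q = n_a / (n_a + n_b)
        probs = [math.comb(t, j) * q ** j * (1 - q) ** (t - j) for j in range(t + 1)]
    else:
        r_a, r_b = n_a / phi, n_b / phi
        mu = t / (n_a + n_b)
        p_a = r_a / (r_a + n_a * mu)
        p_b = r_b / (r_b + n_b * mu)

        def nbpmf(k, r, p):
            return math.exp(
                math.lgamma(k + r) - math.lgamma(r) - math.lgamma(k + 1)
                + r * math.log(p) + k * math.log(1 - p)
            )

        probs = [nbpmf(j, r_a, p_a) * nbpmf(t - j, r_b, p_b) for j in range(t + 1)]
    total = sum(probs)
    probs = [x / total for x in probs]
    obs = probs[y_a]
    return min(sum(x for x in probs if x <= obs * (1 + 1e-9)), 1.0)


def oracle_bh(p, alpha):
    """Brute-force step-up: scan every threshold k*alpha/m."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    k_max = 0
    for k in range(1, m + 1):
        if sorted_p[k - 1] <= k * alpha / m:
            k_max = k
    reject = np.zeros(m, dtype=bool)
    if k_max > 0:
        reject[order[:k_max]] = True
    # q-values: running minimum of m*p_(j)/j from the largest rank down
    q_sorted = np.minimum.accumulate((m * sorted_p / np.arange(1, m + 1))[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, reject


def _equal_lib_counts(per_gene_columns, lib=100_000):
    df = pd.DataFrame(per_gene_columns)
    df.loc["pad"] = lib - df.sum(axis=0)
    assert (df.loc["pad"] >= 0).all()
    return df


# --- exact test ----------------------------------------------------------

class TestNBExactTest:
    def test_perfectly_balanced_gene_is_null(self):
        counts = _equal_lib_counts({
            "a1": {"g": 10}, "a2": {"g": 10}, "a3": {"g": 10},
            "b1": {"g": 10}, "b2": {"g": 10}, "b3": {"g": 10},
        })
        res = nb_exact_test(counts, ["a1", "a2", "a3"], ["b1", "b2", "b3"], 0.0)
        assert res.loc["g", "p_value"] == pytest.approx(1.0)
        assert res.loc["g", "log2_fold_change"] == pytest.approx(0.0)

    @pytest.mark.parametrize("phi", [0.0, 0.1, 0.5])
    @pytest.mark.parametrize("split", [(0, 7), (3, 4), (12, 3), (15, 15), (1, 20)])
    def test_matches_enumeration_oracle(self, phi, split):
        y_a, y_b = split
        counts = _equal_lib_counts({
            "a1": {"g": y_a // 2}, "a2": {"g": y_a - y_a // 2},
            "b1": {"g": y_b // 2}, "b2": {"g": y_b - y_b // 2},
        })
        res = nb_exact_test(counts, ["a1", "a2"], ["b1", "b2"], phi)
        expected = oracle_exact_p(y_a, y_b, 2, 2, phi)
        assert res.loc["g", "p_value"] == pytest.approx(expected, abs=1e-12)

    def test_unbalanced_group_sizes_against_oracle(self):
        counts = _equal_lib_counts({
            "a1": {"g": 9}, "a2": {"g": 8}, "a3": {"g": 7},
            "b1": {"g": 2}, "b2": {"g": 1},
        })
        res = nb_exact_test(counts, ["a1", "a2", "a3"], ["b1", "b2"], 0.2)
        assert res.loc["g", "p_value"] == pytest.approx(
            oracle_exact_p(24, 3, 3, 2, 0.2), abs=1e-12)

    def test_errors(self):
        counts = _equal_lib_counts({"a1": {"g": 1}, "b1": {"g": 1}})
        with pytest.raises(ValueError, match="non-empty"):
            nb_exact_test(counts, [], ["b1"], 0.1)
        with pytest.raises(ValueError, match="disjoint"):
            nb_exact_test(counts, ["a1"], ["a1"], 0.1)
        with pytest.raises(ValueError, match="dispersion"):
            nb_exact_test(counts, ["a1"], ["b1"], -0.5)


# --- dispersion ----------------------------------------------------------

class TestCommonDispersion:
    def test_zero_within_group_variance(self):
        counts = pd.DataFrame({
            "a1": [5, 10, 20], "a2": [5, 10, 20],
            "b1": [7, 9, 30], "b2": [7, 9, 30],
        })
        assert estimate_common_dispersion(counts, [["a1", "a2"], ["b1", "b2"]]) == 0.0

    def test_poisson_floor(self):
        spec = CountSimSpec(n_genes=1000, dispersion=0.0, n_de=0,
                            lib_size_range=(400_000, 600_000), seed=21)
        counts, meta, _ = gen_counts(spec)
        ga = list(meta.loc[meta.treatment == "PI_plus", "sample_id"])
        gb = list(meta.loc[meta.treatment == "control", "sample_id"])
        est = estimate_common_dispersion(counts[ga + gb], [ga, gb])
        assert est <= 0.05

    def test_nb_recovery(self):
        spec = CountSimSpec(n_genes=1500, dispersion=0.1, n_de=0,
                            lib_size_range=(400_000, 600_000), seed=22)
        counts, meta, _ = gen_counts(spec)
        ga = list(meta.loc[meta.treatment == "PI_plus", "sample_id"])
        gb = list(meta.loc[meta.treatment == "control", "sample_id"])
        est = estimate_common_dispersion(counts[ga + gb], [ga, gb])
        assert est == pytest.approx(0.1, abs=0.05)

    def test_singleton_group_rejected(self):
        counts = pd.DataFrame({"a1": [5], "b1": [5], "b2": [6]})
        with pytest.raises(ValueError, match="at least 2"):
            estimate_common_dispersion(counts, [["a1"], ["b1", "b2"]])


# --- BH FDR --------------------------------------------------------------

class TestBHAdjust:
    def test_step_up_example_all_rejected(self):
        q, sig = bh_adjust([0.01, 0.02, 0.03, 0.04], alpha=0.1)
        assert sig.all()

    def test_all_ones_none_rejected(self):
        _, sig = bh_adjust([1.0, 1.0, 1.0], alpha=0.1)
        assert not sig.any()

    def test_single_p(self):
        _, sig = bh_adjust([0.05], alpha=0.1)
        assert sig.all()

    def test_empty_input(self):
        q, sig = bh_adjust([], alpha=0.1)
        assert q.size == 0 and sig.size == 0

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_step_up(self, p):
        q, sig = bh_adjust(p, alpha=0.1)
        q_expect, sig_expect = oracle_bh(p, 0.1)
        np.testing.assert_allclose(q, q_expect, atol=1e-12)
        np.testing.assert_array_equal(sig, sig_expect)


# --- Venn ----------------------------------------------------------------

class TestVennClassify:
    def test_enumerated_example(self):
        v = venn_classify({"g1", "g2"}, {"g2", "g3"}, {"g3"})
        assert v.ab == {"g2"}
        assert v.bc == {"g3"}
        assert v.abc == set()
        assert v.positive_valence_candidates == {"g2"}
        assert v.negative_valence_candidates == {"g3"}

    def test_full_overlap_is_generalized(self):
        v = venn_classify({"g1"}, {"g1"}, {"g1"})
        assert v.abc == {"g1"}
        assert v.generalized == {"g1"}

    def test_disjoint_sets(self):
        v = venn_classify({"a"}, {"b"}, {"c"})
        assert v.ab == v.ac == v.bc == v.abc == frozenset()

    @given(
        a=st.sets(st.integers(0, 15)),
        b=st.sets(st.integers(0, 15)),
        c=st.sets(st.integers(0, 15)),
    )
    @settings(max_examples=100, deadline=None)
    def test_regions_partition_the_union(self, a, b, c):
        v = venn_classify(a, b, c)
        regions = [v.a_only, v.b_only, v.c_only, v.ab, v.ac, v.bc, v.abc]
        assert sum(len(r) for r in regions) == len(v.union)
        assert v.union == a | b | c


# --- enrichment ----------------------------------------------------------

class TestTermEnrichment:
    def test_hypergeometric_closed_form(self):
        """Universe 20, term 5, study 5, overlap 4: p = 76/15504."""
        universe = [f"g{i}" for i in range(20)]
        term = set(universe[:5])
        study = set(universe[:4]) | {universe[10]}
        res = term_enrichment(study, universe, {"t": term})
        assert res.loc["t", "p_value"] == pytest.approx(76 / 15504, abs=1e-12)
        assert res.loc["t", "overlap_count"] == 4

    def test_overlap_at_expectation_not_enriched(self):
        universe = [f"g{i}" for i in range(1000)]
        term = set(universe[:10])
        study = set(universe[9:108])  # overlap 1 ~ expectation 10*99/1000
        res = term_enrichment(study, universe, {"t": term})
        assert res.loc["t", "p_value"] >= 0.5

    def test_study_equal_universe_forces_p_one(self):
        universe = [f"g{i}" for i in range(30)]
        annotation = {"t1": set(universe[:5]), "t2": set(universe[10:20])}
        res = term_enrichment(set(universe), universe, annotation)
        assert (res["p_value"] == 1.0).all()

    def test_errors(self):
        with pytest.raises(ValueError, match="empty universe"):
            term_enrichment(set(), set(), {})
        with pytest.raises(ValueError, match="subset"):
            term_enrichment({"x"}, {"y"}, {})


# --- full pipeline -------------------------------------------------------

class TestRunContrasts:
    def test_planted_positive_genes_land_in_ab(self):
        assign = {i: (("PI_plus",), +1) for i in range(30)}
        spec = CountSimSpec(n_genes=600, dispersion=0.1, n_de=30,
                            log2fc_magnitude=2.5, de_assignment=assign,
                            lib_size_range=(300_000, 400_000), seed=31)
        counts, meta, truth = gen_counts(spec)
        res = run_contrasts(counts, meta, "BUT", fdr=0.1)
        planted = set(truth.index[truth.is_de])
        pvc = res.venn.positive_valence_candidates
        assert len(planted & pvc) / len(planted) >= 0.6
        # contrast C (PI- vs control) should be mostly clean
        sig_c = res.contrasts["PI_minus_vs_control"]["significant"].sum()
        assert sig_c <= 0.02 * res.n_genes_tested

    def test_sample_relabelling_within_treatment_is_invariant(self, null_counts_small):
        counts, meta, _ = null_counts_small
        res1 = run_contrasts(counts, meta, "BUT", fdr=0.1)
        # permute metadata row order and count columns
        rng = np.random.default_rng(0)
        meta_perm = meta.sample(frac=1.0, random_state=1).reset_index(drop=True)
        cols = list(counts.columns)
        rng.shuffle(cols)
        res2 = run_contrasts(counts[cols], meta_perm, "BUT", fdr=0.1)
        for name in res1.contrasts:
            pd.testing.assert_series_equal(
                res1.contrasts[name]["p_value"], res2.contrasts[name]["p_value"])

    def test_missing_treatment_rejected(self, null_counts_small):
        counts, meta, _ = null_counts_small
        broken = meta[meta.treatment != "control"]
        with pytest.raises(ValueError, match="missing treatment"):
            run_contrasts(counts, broken, "BUT")

    def test_unknown_regime_rejected(self, null_counts_small):
        counts, meta, _ = null_counts_small
        with pytest.raises(ValueError, match="no samples"):
            run_contrasts(counts, meta, "XYZ")
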