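"""ANOVA decompositions, Tukey contrasts, matched sign test, permutation null."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats as sps

from compevol.data import CompartmentClass
from compevol.regression import deming_fit, transform_records
from compevol.simulate import default_params, generate_dataset
from compevol.stats import (
    factorial_anova,
    matched_binomial_test,
    oneway_anova,
    pairwise_groups,
    permutation_location_test,
)
from conftest import make_record

M, C = CompartmentClass.MEMBRANE, CompartmentClass.CYTOPLASM


# ---------------------------------------------------------------- one-way


def test_oneway_anova_matches_hand_decomposition():
    # balanced 3x4 layout: group means 2.5/4.5/6.5, grand mean 4.5
    y = [1, 2, 3, 4, 3, 4, 5, 6, 5, 6, 7, 8]
    g = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
    tab = oneway_anova(y, g)
    assert tab.rows[0].ss == pytest.approx(32.0)
    assert tab.residual.ss == pytest.approx(15.0)
    assert tab.rows[0].df == 2 and tab.residual.df == 9
    assert tab.rows[0].f == pytest.approx(9.6)
    assert tab.rows[0].percent == pytest.approx(100 * 32 / 47)
    assert tab.percent_sum() == pytest.approx(100.0, abs=1e-9)


def test_oneway_anova_identical_values_gives_p_one():
    tab = oneway_anova([3.0] * 8, ["a"] * 4 + ["b"] * 4)
    assert tab.rows[0].p == 1.0 and tab.rows[0].f == 0.0


def test_oneway_anova_dominant_group_effect():
    rng = np.random.default_rng(0)
    y = np.concatenate([rng.normal(0, 0.01, 20), rng.normal(10, 0.01, 20)])
    tab = oneway_anova(y, ["a"] * 20 + ["b"] * 20)
    assert tab.rows[0].percent > 99


def test_oneway_anova_rejects_tiny_groups():
    with pytest.raises(ValueError):
        oneway_anova([1.0, 2.0, 3.0], ["a", "a", "b"])


# ---------------------------------------------------------------- pairwise


def test_tukey_two_groups_reduces_to_t_test():
    rng = np.random.default_rng(1)
    a = rng.normal(0, 1, 15)
    b = rng.normal(0.8, 1, 12)
    rows = pairwise_groups(np.concatenate([a, b]), ["a"] * 15 + ["b"] * 12, "tukey")
    t = sps.ttest_ind(a, b, equal_var=True)
    assert rows[0].p_adj == pytest.approx(t.pvalue, rel=1e-6)


def test_tukey_fwer_controlled_under_null():
    rng = np.random.default_rng(2)
    fw_errors = 0
    n_sim = 1000
    for _ in range(n_sim):
        y = rng.normal(0, 1, 60)
        rows = pairwise_groups(y, ["a"] * 20 + ["b"] * 20 + ["c"] * 20, "tukey")
        fw_errors += any(r.p_adj < 0.05 for r in rows)
    assert fw_errors / n_sim <= 0.07


def test_tukey_flags_only_the_shifted_group():
    rng = np.random.default_rng(3)
    y = np.concatenate([rng.normal(0, 1, 40), rng.normal(0, 1, 40), rng.normal(5, 1, 40)])
    rows = pairwise_groups(y, ["a"] * 40 + ["b"] * 40 + ["c"] * 40, "tukey")
    sig = {(r.group_a, r.group_b) for r in rows if r.p_adj < 0.01}
    assert sig == {("a", "c"), ("b", "c")}


def test_permutation_maxt_agrees_with_tukey_direction():
    rng = np.random.default_rng(4)
    y = np.concatenate([rng.normal(0, 1, 30), rng.normal(2, 1, 30), rng.normal(0, 1, 30)])
    g = ["a"] * 30 + ["b"] * 30 + ["c"] * 30
    rows = pairwise_groups(y, g, "permutation-maxT", n_perm=999, seed=5)
    by_pair = {(r.group_a, r.group_b): r.p_adj for r in rows}
    assert by_pair[("a", "b")] < 0.01 and by_pair[("b", "c")] < 0.01
    assert by_pair[("a", "c")] > 0.1


# ---------------------------------------------------------------- factorial


def test_factorial_single_active_factor_takes_all_explained_variance():
    rng = np.random.default_rng(6)
    a = np.repeat([0, 1], 40)
    b = np.tile([0, 1], 40)
    y = 3.0 * a + rng.normal(0, 0.01, 80)
    tab = factorial_anova(y, {"A": a, "B": b})
    rows = {r.term: r for r in tab.rows}
    a_row = rows["A"]
    explained = sum(r.ss for r in tab.rows)
    assert a_row.ss / explained > 0.999
    assert tab.percent_sum() == pytest.approx(100.0, abs=1e-9)


def test_factorial_balanced_design_order_invariant():
    rng = np.random.default_rng(7)
    a = np.repeat([0, 1], 20)
    b = np.tile([0, 1], 20)
    y = 1.0 * a - 0.5 * b + 0.3 * a * b + rng.normal(0, 0.5, 40)
    t1 = factorial_anova(y, {"A": a, "B": b}, order=["A", "B", "A:B"])
    t2 = factorial_anova(y, {"A": a, "B": b}, order=["B", "A", "B:A"])
    ss1 = {r.term: r.ss for r in t1.rows}
    ss2 = {r.term.replace("B:A", "A:B"): r.ss for r in t2.rows}
    assert ss1["A"] == pytest.approx(ss2["A"])
    assert ss1["B"] == pytest.approx(ss2["B"])
    assert t1.residual.ss == pytest.approx(t2.residual.ss)


def test_essentiality_share_shrinks_when_abundance_enters_first():
    """Essentiality links to rate only through abundance in the generator, so
    entering abundance first should absorb most of its share."""
    recs, _ = generate_dataset(default_params("yeast-like", seed=12))
    _, x, y, _ = transform_records(recs)
    ess = [bool(r.essential) for r in recs]
    comps = [r.compartment.value for r in recs]
    ess_first = factorial_anova(y, {"essential": ess, "compartment": comps}, covariate=x,
                                order=["essential", "compartment", "log10_abundance"])
    ab_first = factorial_anova(y, {"essential": ess, "compartment": comps}, covariate=x,
                               order=["log10_abundance", "essential", "compartment"])
    pct = lambda tab: {r.term: r.percent for r in tab.rows}
    assert pct(ab_first)["essential"] < 0.25 * pct(ess_first)["essential"]


def test_factorial_rank_deficient_design_names_aliased_term():
    a = np.repeat([0, 1], 10)
    with pytest.raises(ValueError, match="alias"):
        factorial_anova(np.arange(20.0), {"A": a, "B": a}, order=["A", "B"])


# ------------------------------------------------------ matched binomial


def _paired_records(n, delta_omega=0.1):
    recs = []
    for i in range(n):
        ab = 10.0 ** (1.0 + 0.1 * i)
        recs.append(make_record(f"m{i}", 0.2, ab, M))
        recs.append(make_record(f"c{i}", 0.2 + delta_omega, ab * 1.01, C))
    return recs


def test_matched_binomial_all_successes_closed_form():
    res = matched_binomial_test(_paired_records(10), window=0.05, seed=0)
    assert res.n == 10 and res.successes == 10
    assert res.p == pytest.approx(0.5**10, abs=1e-15)


def test_matched_binomial_half_successes_is_nonsignificant():
    recs = []
    for i in range(12):
        ab = 10.0 ** (1.0 + 0.2 * i)
        sign = 1 if i % 2 else -1
        recs.append(make_record(f"m{i}", 0.2, ab, M))
        recs.append(make_record(f"c{i}", 0.2 + 0.05 * sign, ab, C))
    res = matched_binomial_test(recs, window=0.05, seed=1)
    assert res.successes == res.n // 2
    assert res.p > 0.5


def test_matched_binomial_p_matches_exact_binomial_tail():
    """Exact one-sided tail computed independently with rational arithmetic."""
    for n_pairs, delta in ((6, 0.1), (9, 0.1), (14, 0.1)):
        recs = _paired_records(n_pairs, delta)
        # flip some cytoplasm rates downward to vary the success count
        for j, r in enumerate(recs):
            if r.gene_id.startswith("c") and j % 5 == 0:
                r.omega = 0.05
        res = matched_binomial_test(recs, window=0.05, seed=2)
        exact = sum(Fraction(math.comb(res.n, k), 2**res.n) for k in range(res.successes, res.n + 1))
        assert res.p == pytest.approx(float(exact), abs=1e-12)


def test_matched_binomial_ties_dropped():
    recs = _paired_records(8, delta_omega=0.0)  # every pair tied
    res = matched_binomial_test(recs, window=0.05, seed=3)
    assert res.ties == 8 and res.n == 0 and res.p is None


def test_matched_binomial_respects_window_and_uniqueness():
    """6-gene toy: the pair assignment must be a valid greedy outcome for
    some visiting order, with each cytoplasmic gene used at most once and
    every pair within the window."""
    mem_ab = {"m0": 1.00, "m1": 1.30, "m2": 2.00}
    cyt_ab = {"c0": 1.05, "c1": 1.28, "c2": 3.00}
    recs = [make_record(g, 0.2, 10.0**a, M) for g, a in mem_ab.items()]
    recs += [make_record(g, 0.3, 10.0**a, C) for g, a in cyt_ab.items()]
    window = 0.30
    res = matched_binomial_test(recs, window=window, seed=4)

    def greedy(order):
        used, pairs = set(), set()
        for m in order:
            best = None
            for c, ca in cyt_ab.items():
                if c in used:
                    continue
                d = abs(ca - mem_ab[m])
                if d <= window and (best is None or d < best[0]):
                    best = (d, c)
            if best:
                used.add(best[1])
                pairs.add((m, best[1]))
        return frozenset(pairs)

    valid = {greedy(order) for order in itertools.permutations(mem_ab)}
    got = frozenset((p.membrane_id, p.cytoplasm_id) for p in res.pairs)
    assert got in valid
    assert all(p.abund_diff <= window for p in res.pairs)
    cyt_used = [p.cytoplasm_id for p in res.pairs]
    assert len(cyt_used) == len(set(cyt_used))


def test_matched_binomial_requires_both_classes():
    recs = [make_record("m0", 0.2, 10.0, M)]
    with pytest.raises(ValueError):
        matched_binomial_test(recs, window=0.1)


# ------------------------------------------------------ permutation null


def _two_class_records(rng, n_m=4, n_c=4, slope=-0.3, sd=0.2):
    recs = []
    for i in range(n_m + n_c):
        comp = M if i < n_m else C
        x = rng.normal(2.0, 1.0)
        y = slope * x + rng.normal(0, sd)
        recs.append(make_record(f"p{i}", 10.0**y, 10.0**x, comp))
    return recs


def test_permutation_exact_mode_matches_brute_force():
    rng = np.random.default_rng(31)
    recs = _two_class_records(rng)
    res = permutation_location_test(recs, "residual_mean_diff", method="exact")

    # independent enumeration: pooled fit is label-invariant, so compute the
    # residuals once and enumerate every distinct membrane/cytoplasm split
    _, x, y, _ = transform_records(recs)
    fit = deming_fit(x, y, delta=1.0)
    r = y - (fit.intercept + fit.slope * x)
    obs = r[:4].mean() - r[4:].mean()
    stats_all = []
    for mem_idx in itertools.combinations(range(8), 4):
        mask = np.zeros(8, bool)
        mask[list(mem_idx)] = True
        stats_all.append(r[mask].mean() - r[~mask].mean())
    p_exact = np.mean(np.abs(stats_all) >= abs(obs) - 1e-12)
    assert res.observed == pytest.approx(obs)
    assert res.p == pytest.approx(p_exact)


def test_permutation_sampled_p_approaches_exact_p():
    rng = np.random.default_rng(33)
    recs = _two_class_records(rng, n_m=6, n_c=6)
    exact = permutation_location_test(recs, "residual_mean_diff", method="exact")
    sampled = permutation_location_test(recs, "residual_mean_diff", n_perm=9999, seed=1)
    assert sampled.p == pytest.approx(exact.p, abs=0.03)


def test_permutation_constant_y_gives_p_one():
    recs = [make_record(f"k{i}", 0.5, 10.0 ** (1 + 0.1 * i), M if i < 5 else C) for i in range(10)]
    # constant omega -> y constant -> slope fit degenerate for slope stats;
    # use the residual statistic, which is well-defined (all residuals equal)
    res = permutation_location_test(recs, "residual_mean_diff", n_perm=199, seed=2)
    assert res.observed == pytest.approx(0.0, abs=1e-12)
    assert res.p == 1.0


def test_permutation_detects_planted_intercept_shift():
    rng = np.random.default_rng(35)
    recs = []
    for i in range(120):
        comp = M if i < 60 else C
        x = rng.normal(2.0, 1.0)
        shift = -0.5 if comp is M else 0.0
        y = -0.3 * x + shift + rng.normal(0, 0.2)
        recs.append(make_record(f"s{i}", 10.0**y, 10.0**x, comp))
    res = permutation_location_test(recs, "residual_mean_diff", n_perm=999, seed=3)
    assert res.p < 0.01
    assert res.observed < 0


def test_permutation_p_uses_add_one_estimator():
    rng = np.random.default_rng(37)
    recs = _two_class_records(rng, n_m=20, n_c=20)
    res = permutation_location_test(recs, "deming_slope_diff", n_perm=199, seed=4)
    assert res.p >= 1.0 / 200.0  # never exactly zero
    assert (res.p * 200.0) == pytest.approx(round(res.p * 200.0))
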