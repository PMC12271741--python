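"""Group comparisons on rates and abundance-controlled residuals.

One-way ANOVA with Tukey HSD (or permutation max-T) pairwise contrasts,
sequential (Type I) factorial variance decompositions, the abundance-matched
membrane/cytoplasm sign test, and a size-preserving permutation null for
per-compartment regression parameters.
"""

from __future__ import annotations

import bisect
import itertools
import math
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data import CompartmentClass, GeneRecord
from .regression import RegressionFit, TransformSpec, deming_fit, transform_records

__all__ = [
    "AnovaRow",
    "AnovaTable",
    "MatchedPairSet",
    "PermutationResult",
    "oneway_anova",
    "pairwise_groups",
    "factorial_anova",
    "matched_binomial_test",
    "permutation_location_test",
]


@dataclass
class AnovaRow:
    term: str
    df: float
    ss: float
    percent: float
    f: Optional[float]
    p: Optional[float]


@dataclass
class AnovaTable:
    """Term-wise sequential sums of squares with percent variance explained.

    Percent variance of all terms plus the residual row sums to 100 by
    construction (sequential SS partition the total exactly).
    """

    rows: list
    residual: AnovaRow

    @property
    def total_ss(self) -> float:
        return sum(r.ss for r in self.rows) + self.residual.ss

    def percent_sum(self) -> float:
        return sum(r.percent for r in self.rows) + self.residual.percent

    def to_dataframe(self) -> pd.DataFrame:
        rows = self.rows + [self.residual]
        return pd.DataFrame(
            {
                "term": [r.term for r in rows],
                "df": [r.df for r in rows],
                "ss": [r.ss for r in rows],
                "percent": [r.percent for r in rows],
                "F": [r.f for r in rows],
                "p": [r.p for r in rows],
            }
        )

    def to_dict(self) -> dict:
        return {
            "rows": [vars(r) for r in self.rows],
            "residual": vars(self.residual),
        }


def _percent(ss: float, total: float) -> float:
    return 100.0 * ss / total if total > 0 else 0.0


def oneway_anova(values: Sequence[float], groups: Sequence) -> AnovaTable:
    """One-way between/within decomposition with the F test.

    Degenerate data (zero total variance) is reported as F=0, p=1.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    labels = pd.unique(g)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    parts = [y[g == lab] for lab in labels]
    if any(p.size < 2 for p in parts):
        raise ValueError("every group needs at least 2 values")
    grand = y.mean()
    ssb = float(sum(p.size * (p.mean() - grand) ** 2 for p in parts))
    ssw = float(sum(((p - p.mean()) ** 2).sum() for p in parts))
    sst = ssb + ssw
    dfb, dfw = len(labels) - 1, y.size - len(labels)
    if sst == 0 or ssw == 0 and ssb == 0:
        f_stat, p = 0.0, 1.0
    elif ssw == 0:
        f_stat, p = math.inf, 0.0
    else:
        f_stat = (ssb / dfb) / (ssw / dfw)
        p = float(sps.f.sf(f_stat, dfb, dfw))
    between = AnovaRow("group", dfb, ssb, _percent(ssb, sst), f_stat, p)
    residual = AnovaRow("Residual", dfw, ssw, 100.0 - between.percent if sst > 0 else 100.0, None, None)
    return AnovaTable([between], residual)


@dataclass
class PairwiseRow:
    group_a: object
    group_b: object
    mean_diff: float
    p_adj: float


def pairwise_groups(
    values: Sequence[float],
    groups: Sequence,
    method: str = "tukey",
    n_perm: int = 9999,
    seed: int = 0,
) -> list:
    """All pairwise mean contrasts with family-wise error control.

    "tukey" uses the studentized-range law (Tukey-Kramer for unequal n);
    "permutation-maxT" shuffles labels and adjusts each pair's |t| against
    the permutation distribution of the maximum |t|.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    labels = list(pd.unique(g))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    parts = [y[g == lab] for lab in labels]
    if any(p.size < 2 for p in parts):
        raise ValueError("every group needs at least 2 values")

    if method == "tukey":
        res = sps.tukey_hsd(*parts)
        out = []
        for i, j in itertools.combinations(range(len(labels)), 2):
            out.append(
                PairwiseRow(
                    str(labels[i]), str(labels[j]), float(parts[i].mean() - parts[j].mean()), float(res.pvalue[i, j])
                )
            )
        return out
    if method == "permutation-maxT":
        rng = np.random.default_rng(seed)
        pairs = list(itertools.combinations(range(len(labels)), 2))

        def pair_ts(yv):
            ps = [yv[g == lab] for lab in labels]
            ts = []
            for i, j in pairs:
                a, b = ps[i], ps[j]
                va = a.var(ddof=1) / a.size + b.var(ddof=1) / b.size
                ts.append(abs(a.mean() - b.mean()) / math.sqrt(va) if va > 0 else 0.0)
            return np.array(ts)

        t_obs = pair_ts(y)
        exceed = np.zeros(len(pairs))
        for _ in range(n_perm):
            t_max = pair_ts(rng.permutation(y)).max()
            exceed += t_max >= t_obs
        p_adj = (1.0 + exceed) / (n_perm + 1)
        return [
            PairwiseRow(
                str(labels[i]), str(labels[j]), float(y[g == labels[i]].mean() - y[g == labels[j]].mean()), float(pa)
            )
            for (i, j), pa in zip(pairs, p_adj)
        ]
    raise ValueError(f"unknown method {method!r}")


def _term_columns(
    term: str,
    factors: Mapping[str, np.ndarray],
    covariate: Optional[np.ndarray],
    covariate_name: str,
) -> np.ndarray:
    """Full (over-complete) dummy/product design columns for one term."""
    cols = None
    for t in term.split(":"):
        t = t.strip()
        if t in factors:
            f = factors[t]
            levels = pd.unique(f)
            block = np.column_stack([(f == lev).astype(float) for lev in levels])
        elif covariate is not None and t == covariate_name:
            block = covariate[:, None]
        else:
            raise ValueError(f"unknown term component {t!r}")
        if cols is None:
            cols = block
        else:
            cols = (cols[:, :, None] * block[:, None, :]).reshape(len(block), -1)
    return cols


def factorial_anova(
    y: Sequence[float],
    factors: Mapping[str, Sequence],
    covariate: Optional[Sequence[float]] = None,
    covariate_name: str = "log10_abundance",
    order: Optional[Sequence[str]] = None,
) -> AnovaTable:
    """Sequential (Type I) factorial decomposition of variance in y.

    ``order`` lists the terms in entry order, using factor names, the
    covariate name, and ":" for interactions (e.g. ``["essential",
    "compartment", "essential:compartment"]``). When omitted, the default is
    covariate first (if given), main effects in mapping order, then all
    interactions by increasing order. Terms are entered one at a time and
    each SS is the drop in residual SS — only this sequential partition
    makes "percent of variance" sum to 100 with the residual. A term whose
    columns add no rank beyond the previous ones is aliased and raises an
    error naming it.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    fac = {name: np.asarray(list(vals)) for name, vals in factors.items()}
    cov = np.asarray(covariate, dtype=float) if covariate is not None else None

    names = list(fac)
    if order is None:
        order = []
        if cov is not None:
            order.append(covariate_name)
        order.extend(names)
        all_main = ([covariate_name] if cov is not None else []) + names
        for k in range(2, len(all_main) + 1):
            for combo in itertools.combinations(all_main, k):
                order.append(":".join(combo))

    sst = float(np.sum((y - y.mean()) ** 2))

    def rss_and_rank(X):
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        return float(np.sum((y - X @ beta) ** 2)), rank

    X = np.ones((n, 1))
    rss_prev, rank_prev = rss_and_rank(X)
    entries = []  # (term, df, ss)
    for term in order:
        X = np.column_stack([X, _term_columns(term, fac, cov, covariate_name)])
        rss, rank = rss_and_rank(X)
        df_term = rank - rank_prev
        if df_term == 0:
            raise ValueError(f"rank-deficient design: term {term!r} is aliased")
        entries.append((term, df_term, max(rss_prev - rss, 0.0)))
        rss_prev, rank_prev = rss, rank

    df_resid = n - rank_prev
    if df_resid <= 0:
        raise ValueError("saturated design: no residual degrees of freedom")
    mse = rss_prev / df_resid
    rows = []
    for term, df_term, ss in entries:
        f_stat = (ss / df_term) / mse if mse > 0 else (math.inf if ss > 0 else 0.0)
        p = float(sps.f.sf(f_stat, df_term, df_resid)) if math.isfinite(f_stat) else 0.0
        rows.append(AnovaRow(term, df_term, ss, _percent(ss, sst), f_stat, p))
    residual = AnovaRow(
        "Residual",
        df_resid,
        rss_prev,
        100.0 - sum(r.percent for r in rows) if sst > 0 else 100.0,
        None,
        None,
    )
    return AnovaTable(rows, residual)


@dataclass
class MatchedPair:
    membrane_id: str
    cytoplasm_id: str
    abund_diff: float  # |delta log10 abundance|


@dataclass
class MatchedPairSet:
    window: float
    pairs: list
    n: int  # pairs entering the sign count (omega ties dropped)
    successes: int  # pairs with omega_cytoplasm > omega_membrane
    ties: int
    p: Optional[float]
    seed: int


def matched_binomial_test(
    records: Sequence[GeneRecord],
    window: float,
    direction: Callable[[float, float], bool] = lambda w_mem, w_cyt: w_cyt > w_mem,
    seed: int = 0,
    with_replacement: bool = False,
) -> MatchedPairSet:
    """Sign test on membrane/cytoplasm genes matched on abundance.

    Membrane genes are visited in a seeded random order; each takes the
    as-yet-unused cytoplasmic gene closest in log10 abundance, provided the
    gap is within ``window`` (log10 units), else it stays unmatched. Pairs
    with exactly equal omega are dropped from the sign count. The one-sided
    exact binomial p tests whether ``direction`` (default: cytoplasmic gene
    faster) holds more often than the fair-coin null.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    mem = [r for r in records if r.compartment == CompartmentClass.MEMBRANE and r.abundance and r.omega is not None]
    cyt = [r for r in records if r.compartment == CompartmentClass.CYTOPLASM and r.abundance and r.omega is not None]
    if not mem or not cyt:
        raise ValueError("need at least one membrane and one cytoplasm record with abundance")

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(mem))

    pool = sorted(((math.log10(r.abundance), i) for i, r in enumerate(cyt)))
    keys = [k for k, _ in pool]
    pairs: list[MatchedPair] = []
    successes = ties = 0
    for mi in order:
        m = mem[mi]
        if not pool:
            break
        xm = math.log10(m.abundance)
        j = bisect.bisect_left(keys, xm)
        best = None
        for cand in (j - 1, j):
            if 0 <= cand < len(keys):
                d = abs(keys[cand] - xm)
                if best is None or d < best[0]:
                    best = (d, cand)
        if best is None or best[0] > window:
            continue
        d, cand = best
        ci = pool[cand][1]
        c = cyt[ci]
        pairs.append(MatchedPair(m.gene_id, c.gene_id, float(d)))
        if not with_replacement:
            del pool[cand]
            del keys[cand]
        if c.omega == m.omega:
            ties += 1
        elif direction(m.omega, c.omega):
            successes += 1
    n = len(pairs) - ties
    if n == 0:
        return MatchedPairSet(window, pairs, 0, 0, ties, None, seed)
    p = float(sps.binomtest(successes, n, 0.5, alternative="greater").pvalue)
    return MatchedPairSet(window, pairs, n, successes, ties, p, seed)


@dataclass
class PermutationResult:
    statistic: str
    observed: float
    n_perm: int
    p: float
    seed: int
    method: str = "sample"
    n_redrawn: int = 0


_PERM_STATS = ("deming_slope_diff", "intercept_diff", "residual_mean_diff")


def _class_moments(masks: np.ndarray, x: np.ndarray, y: np.ndarray, n_c: int):
    """Per-permutation central moments of (x, y) within one class.

    ``masks`` is (B, n) boolean: row b selects the class members under
    permutation b. Returns xbar, ybar, sxx, syy, sxy (each length B).
    """
    W = masks.astype(float)
    sx = W @ x
    sy = W @ y
    sxx = W @ (x * x)
    syy = W @ (y * y)
    sxy = W @ (x * y)
    xbar = sx / n_c
    ybar = sy / n_c
    return xbar, ybar, sxx / n_c - xbar**2, syy / n_c - ybar**2, sxy / n_c - xbar * ybar


def _deming_slope_vec(sxx, syy, sxy, delta: float):
    a = syy - delta * sxx
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (a + np.sqrt(a * a + 4.0 * delta * sxy * sxy)) / (2.0 * sxy)
    flat = sxy == 0
    slope = np.where(flat & (delta * sxx >= syy), 0.0, slope)
    slope = np.where(flat & (delta * sxx < syy), np.nan, slope)
    slope = np.where(sxx <= 0, np.nan, slope)
    return slope


def _perm_statistic(
    labels: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    resid: np.ndarray,
    statistic: str,
    delta: float,
    class_a: int,
    class_b: int,
    n_a: int,
    n_b: int,
):
    """Statistic under each row of ``labels`` (B, n); returns length-B array."""
    ma = labels == class_a
    mb = labels == class_b
    if statistic == "residual_mean_diff":
        return (ma.astype(float) @ resid) / n_a - (mb.astype(float) @ resid) / n_b
    xa_bar, ya_bar, sxx_a, syy_a, sxy_a = _class_moments(ma, x, y, n_a)
    xb_bar, yb_bar, sxx_b, syy_b, sxy_b = _class_moments(mb, x, y, n_b)
    sl_a = _deming_slope_vec(sxx_a, syy_a, sxy_a, delta)
    sl_b = _deming_slope_vec(sxx_b, syy_b, sxy_b, delta)
    if statistic == "deming_slope_diff":
        return sl_a - sl_b
    if statistic == "intercept_diff":
        return (ya_bar - sl_a * xa_bar) - (yb_bar - sl_b * xb_bar)
    raise ValueError(f"unknown statistic {statistic!r}; expected one of {_PERM_STATS}")


def permutation_location_test(
    records: Sequence[GeneRecord],
    statistic: str = "deming_slope_diff",
    n_perm: int = 10_000,
    seed: int = 0,
    delta: float = 1.0,
    transform: TransformSpec = TransformSpec(),
    classes: tuple = (CompartmentClass.MEMBRANE, CompartmentClass.CYTOPLASM),
    pooled_fit: Optional[RegressionFit] = None,
    method: str = "sample",
    _chunk: int = 2048,
) -> PermutationResult:
    """Permutation null of location independence for a regression contrast.

    Compartment labels are shuffled over all records (group sizes fixed) and
    the chosen statistic — difference between ``classes[0]`` and
    ``classes[1]`` in per-class Deming slope, intercept, or pooled-fit
    residual mean — is recomputed each time. Two-sided p with the add-one
    estimator: p = (1 + #{|perm| >= |observed|}) / (n_perm + 1).
    ``method="exact"`` enumerates every distinct label assignment instead
    (p = #{|stat| >= |observed|} / N, the identity assignment included).
    Permutations where the statistic is undefined are redrawn and counted.
    """
    if statistic not in _PERM_STATS:
        raise ValueError(f"unknown statistic {statistic!r}; expected one of {_PERM_STATS}")
    usable = [r for r in records if r.abundance and r.omega is not None and r.compartment is not None]
    comps = [r.compartment for r in usable]
    present = [c for c in CompartmentClass if c in comps]
    if len({c for c in comps}) < 2:
        raise ValueError("need at least 2 compartment classes")
    _, x, y, _ = transform_records(usable, transform)
    lab = np.array([present.index(c) for c in comps])
    class_a, class_b = (present.index(classes[0]), present.index(classes[1]))
    n_a = int((lab == class_a).sum())
    n_b = int((lab == class_b).sum())
    if n_a < 3 or n_b < 3:
        raise ValueError("contrast classes need at least 3 usable records each")

    if pooled_fit is None:
        pooled_fit = deming_fit(x, y, delta=delta, transform=transform)
    resid = y - pooled_fit.predict(x)

    obs = float(
        _perm_statistic(lab[None, :], x, y, resid, statistic, delta, class_a, class_b, n_a, n_b)[0]
    )

    if method == "exact":
        counts = [(c, int((lab == c).sum())) for c in sorted(set(lab.tolist()))]
        assignments: list[np.ndarray] = []

        def assign(free: tuple, remaining: list, current: np.ndarray) -> None:
            if not remaining:
                assignments.append(current.copy())
                return
            c, k = remaining[0]
            if len(remaining) == 1:
                current[list(free)] = c
                assignments.append(current.copy())
                current[list(free)] = -1
                return
            for chosen in itertools.combinations(free, k):
                current[list(chosen)] = c
                assign(tuple(i for i in free if i not in chosen), remaining[1:], current)
                current[list(chosen)] = -1

        if math.prod(math.comb(sum(k for _, k in counts[i:]), k) for i, (_, k) in enumerate(counts)) > 200_000:
            raise ValueError("too many distinct label assignments for exact enumeration")
        assign(tuple(range(lab.size)), counts, np.full(lab.size, -1))
        L = np.array(assignments)
        vals = _perm_statistic(L, x, y, resid, statistic, delta, class_a, class_b, n_a, n_b)
        good = np.isfinite(vals)
        vals = vals[good]
        p = float(np.mean(np.abs(vals) >= abs(obs) - 1e-12))
        return PermutationResult(statistic, obs, int(vals.size), p, seed, "exact", int((~good).sum()))

    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    rng = np.random.default_rng(seed)
    exceed = 0
    redrawn = 0
    remaining = n_perm
    while remaining > 0:
        b = min(_chunk, remaining)
        P = np.argsort(rng.random((b, lab.size)), axis=1)
        L = lab[P]
        vals = _perm_statistic(L, x, y, resid, statistic, delta, class_a, class_b, n_a, n_b)
        bad = ~np.isfinite(vals)
        while bad.any():
            redrawn += int(bad.sum())
            P2 = np.argsort(rng.random((int(bad.sum()), lab.size)), axis=1)
            vals[bad] = _perm_statistic(lab[P2], x, y, resid, statistic, delta, class_a, class_b, n_a, n_b)
            bad = ~np.isfinite(vals)
        exceed += int(np.sum(np.abs(vals) >= abs(obs) - 1e-12))
        remaining -= b
    p = (1.0 + exceed) / (n_perm + 1.0)
    return PermutationResult(statistic, obs, n_perm, float(p), seed, "sample", redrawn)
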