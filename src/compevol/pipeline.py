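"""End-to-end orchestration: curate -> transform -> fit -> residuals ->
compartment/essentiality tests -> codon-proxy robustness.

The pipeline is a pure function of (config, seed): identical inputs give a
byte-identical JSON report. The headline outputs are two verdicts — which
compartment class is slowest on the raw rate scale and which is slowest on
the abundance-controlled (residual) scale — plus the tables behind them.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .data import (
    CompartmentClass,
    CurationConfig,
    GeneRecord,
    curate,
    read_gene_table,
    write_gene_table,
    write_rejection_log,
)
from .regression import (
    TransformSpec,
    deming_fit,
    fit_residuals,
    linear_vs_quadratic,
    loess_fit,
    ols_fit,
    slope_equality_test,
    transform_records,
)
from .simulate import default_params, generate_dataset, params_from_dict, write_truth_table
from .stats import (
    factorial_anova,
    matched_binomial_test,
    oneway_anova,
    pairwise_groups,
    permutation_location_test,
)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "compartment_verdicts", "PipelineError"]

_CLASS_ORDER = [c.value for c in CompartmentClass]

#: conventional printed order for the two-way decomposition
TWOWAY_ORDER = ("essential", "compartment", "essential:compartment")
#: printed order for the three-way decomposition with abundance
THREEWAY_ORDER = (
    "essential",
    "compartment",
    "essential:compartment",
    "log10_abundance",
    "log10_abundance:essential",
    "log10_abundance:compartment",
    "log10_abundance:essential:compartment",
)


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything a run needs; exactly one of input_table / profile is set."""

    input_table: Optional[str] = None
    profile: Optional[str] = None
    synthetic_params: Optional[dict] = None  # overrides profile defaults
    seed: int = 0
    transform: TransformSpec = field(default_factory=TransformSpec)
    curation: CurationConfig = field(default_factory=CurationConfig)
    delta: float = 1.0
    loess_span: float = 0.75
    loess_degree: int = 1
    do_loess: bool = True
    binomial_windows: Sequence[float] = (0.1, 0.25, 0.5)
    n_perm: int = 10_000
    perm_statistics: Sequence[str] = ("deming_slope_diff", "residual_mean_diff")
    anova_order: Sequence[str] = TWOWAY_ORDER
    cds_fasta: Optional[str] = None
    outdir: Optional[str] = None
    write_tables: bool = True
    figures: bool = False
    dialect: Optional[dict] = None

    def __post_init__(self) -> None:
        if (self.input_table is None) == (self.profile is None):
            raise ValueError("set exactly one of input_table / profile")
        if self.delta <= 0 or not 0 < self.loess_span <= 1:
            raise ValueError("delta must be positive and loess_span in (0, 1]")


def _class_means(values, comps):
    out = {}
    for c in _CLASS_ORDER:
        sel = [v for v, k in zip(values, comps) if k == c]
        if sel:
            out[c] = float(np.mean(sel))
    return out


def compartment_verdicts(records: Sequence[GeneRecord], transform: TransformSpec, delta: float) -> dict:
    """Raw vs abundance-controlled ranking of compartment classes.

    Fits the pooled Deming regression of log10(omega+eps) on log10 abundance
    and compares class means of the raw transformed rate and of the vertical
    residuals. Returns the two "slowest" verdicts plus the means behind them.
    """
    usable = [r for r in records if r.abundance and r.omega is not None and r.compartment]
    _, x, y, _ = transform_records(usable, transform)
    fit = deming_fit(x, y, delta=delta, transform=transform)
    resid = y - fit.predict(x)
    comps = [r.compartment.value for r in usable]
    raw_means = _class_means(y, comps)
    res_means = _class_means(resid, comps)
    return {
        "raw_class_means": raw_means,
        "residual_class_means": res_means,
        "raw_slowest": min(raw_means, key=raw_means.get),
        "residual_slowest": min(res_means, key=res_means.get),
        "pooled_deming_slope": fit.slope,
        "pooled_deming_intercept": fit.intercept,
    }


@dataclass
class RunReport:
    config: dict
    counts: dict
    fits: dict
    anova: dict
    pairwise: dict
    binomial: list
    permutation: list
    verdicts: dict
    residual_shape: dict
    codon: Optional[dict] = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    if isinstance(obj, CompartmentClass):
        return obj.value
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["transform"] = dataclasses.asdict(config.transform)
    cur = dataclasses.asdict(config.curation)
    cur["ds_columns"] = list(cur["ds_columns"])
    d["curation"] = cur
    for key in ("binomial_windows", "perm_statistics", "anova_order"):
        d[key] = list(d[key])
    return d


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-labelled and re-raised
            raise PipelineError(name, exc) from exc

    return wrap


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis; see module docstring."""
    # --- load or simulate -------------------------------------------------
    truth = None
    if config.input_table is not None:
        records = _stage("load")(read_gene_table, config.input_table, config.dialect)
    else:
        params = default_params(config.profile, seed=config.seed)
        if config.synthetic_params:
            from .simulate import params_to_dict

            base = params_to_dict(params)
            base.update(config.synthetic_params)
            base["seed"] = config.seed
            params = params_from_dict(base)
        records, truth = _stage("simulate")(generate_dataset, params)

    n_input = len(records)

    # --- curation ---------------------------------------------------------
    cur = _stage("curate")(curate, records, config.curation)
    kept = cur.kept
    reasons: dict[str, int] = {}
    for _, reason in cur.rejected:
        reasons[reason] = reasons.get(reason, 0) + 1
    counts = {
        "input": n_input,
        "curated": len(kept),
        "rejected": len(cur.rejected),
        "rejected_by_reason": reasons,
        "ds_fences": cur.fences,
    }

    # --- transforms and fits ----------------------------------------------
    usable = [r for r in kept if r.abundance and r.omega is not None and r.compartment]
    ids, x, y, skipped = transform_records(usable, config.transform)
    counts["usable_for_fit"] = len(ids)
    counts["skipped_at_fit"] = len(skipped) + (len(kept) - len(usable))
    if len(ids) < 3:
        raise PipelineError("fit", ValueError(f"only {len(ids)} usable genes; need at least 3"))

    pooled = _stage("fit")(deming_fit, x, y, config.delta, config.transform)
    pooled_ols = ols_fit(x, y, config.transform)
    resid_recs, _ = fit_residuals(usable, pooled)
    resid = np.array([r.residual for r in resid_recs])
    comps = [r.compartment.value for r in usable]
    ess = [bool(r.essential) for r in usable]

    fits = {
        "pooled_deming": {"slope": pooled.slope, "intercept": pooled.intercept, "delta": config.delta, "n": pooled.n},
        "pooled_ols": {"slope": pooled_ols.slope, "intercept": pooled_ols.intercept, "n": pooled_ols.n},
        "per_class_deming": {},
    }
    groups_for_slopes = []
    for c in _CLASS_ORDER:
        mask = np.array([k == c for k in comps])
        if mask.sum() >= 3 and np.ptp(x[mask]) > 0:
            f = deming_fit(x[mask], y[mask], config.delta, config.transform)
            fits["per_class_deming"][c] = {"slope": f.slope, "intercept": f.intercept, "n": f.n}
            groups_for_slopes.append((x[mask], y[mask]))
    if config.do_loess:
        lo = _stage("loess")(loess_fit, x, y, config.loess_span, config.loess_degree, config.transform)
        lo_resid = lo.residuals
        fits["loess"] = {
            "span": config.loess_span,
            "degree": config.loess_degree,
            "n": lo.n,
            "residual_variance": float(lo_resid.var()),
        }
    else:
        lo_resid = None

    # --- compartment comparisons -------------------------------------------
    anova = {
        "omega_by_compartment": oneway_anova(y, comps).to_dict(),
        "abundance_by_compartment": oneway_anova(x, comps).to_dict(),
        "residual_by_compartment": oneway_anova(resid, comps).to_dict(),
    }
    if lo_resid is not None:
        anova["loess_residual_by_compartment"] = oneway_anova(lo_resid, comps).to_dict()

    pairwise = {
        "omega_by_compartment": [vars(r) for r in pairwise_groups(y, comps, "tukey")],
        "residual_by_compartment": [vars(r) for r in pairwise_groups(resid, comps, "tukey")],
    }

    # essentiality-stratified residual comparisons
    strat = {}
    for level, name in ((True, "essential"), (False, "nonessential")):
        mask = np.array([e == level for e in ess])
        sub_comps = [c for c, m in zip(comps, mask) if m]
        if mask.sum() >= 6 and len(set(sub_comps)) >= 2 and min(sub_comps.count(c) for c in set(sub_comps)) >= 2:
            strat[name] = oneway_anova(resid[mask], sub_comps).to_dict()
    anova["residual_by_compartment_within_essentiality"] = strat

    # factorial decompositions (conventional printed term order)
    if len(set(ess)) == 2:
        anova["twoway_omega"] = factorial_anova(
            y, {"essential": ess, "compartment": comps}, order=list(config.anova_order)
        ).to_dict()
        anova["twoway_residual"] = factorial_anova(
            resid, {"essential": ess, "compartment": comps}, order=list(config.anova_order)
        ).to_dict()
        anova["threeway_omega"] = factorial_anova(
            y,
            {"essential": ess, "compartment": comps},
            covariate=x,
            order=list(THREEWAY_ORDER),
        ).to_dict()

    # residual shape diagnostics: linear vs quadratic, median-split slopes
    lvq = linear_vs_quadratic(x, resid)
    med = float(np.median(x))
    lo_mask = x <= med
    hi_mask = ~lo_mask
    shape = {"linear_vs_quadratic": {"f": lvq.f, "df": list(lvq.df), "p": lvq.p}}
    if lo_mask.sum() >= 3 and hi_mask.sum() >= 3:
        se = slope_equality_test([(x[lo_mask], y[lo_mask]), (x[hi_mask], y[hi_mask])], delta=config.delta)
        shape["median_split_slopes"] = {
            "f": se.f,
            "p": se.p,
            "deming_slopes": se.deming_slopes,
            "ols_slopes": se.ols_slopes,
        }
    if len(groups_for_slopes) >= 2:
        se2 = slope_equality_test(groups_for_slopes, delta=config.delta)
        shape["per_class_slope_equality"] = {"f": se2.f, "p": se2.p, "deming_slopes": se2.deming_slopes}

    # --- matched binomial window sweep -------------------------------------
    binomial = []
    for w in config.binomial_windows:
        try:
            mp = matched_binomial_test(usable, w, seed=config.seed)
        except ValueError:
            continue
        binomial.append(
            {"window": w, "n": mp.n, "successes": mp.successes, "ties": mp.ties, "p": mp.p}
        )

    # --- permutation tests ---------------------------------------------------
    permutation = []
    if config.n_perm >= 99:
        for stat_name in config.perm_statistics:
            pr = _stage("permutation")(
                permutation_location_test,
                usable,
                stat_name,
                config.n_perm,
                config.seed,
                config.delta,
                config.transform,
                pooled_fit=pooled,
            )
            permutation.append(
                {
                    "statistic": pr.statistic,
                    "observed": pr.observed,
                    "n_perm": pr.n_perm,
                    "p": pr.p,
                    "seed": pr.seed,
                    "n_redrawn": pr.n_redrawn,
                }
            )

    # --- verdicts -----------------------------------------------------------
    verdicts = compartment_verdicts(usable, config.transform, config.delta)
    abund_means = {}
    for c in _CLASS_ORDER:
        sel = [r.abundance for r in usable if r.compartment.value == c]
        if sel:
            abund_means[c] = float(np.mean(sel))
    if "Membrane" in abund_means and "Cytoplasm" in abund_means:
        verdicts["membrane_cytoplasm_abundance_ratio"] = abund_means["Membrane"] / abund_means["Cytoplasm"]

    # --- codon-proxy robustness path ----------------------------------------
    codon_section = None
    if config.cds_fasta:
        codon_section = _stage("codon")(_codon_proxy_section, config, usable)

    report = RunReport(
        config=_config_dict(config),
        counts=counts,
        fits=fits,
        anova=anova,
        pairwise=pairwise,
        binomial=binomial,
        permutation=permutation,
        verdicts=verdicts,
        residual_shape=shape,
    )
    report.codon = codon_section

    if config.outdir:
        _write_outputs(config, report, records, truth, cur, resid_recs, comps, ess)
        if config.figures:
            from .figures import write_figures

            write_figures(config.outdir, x, y, resid, comps, pooled.slope, pooled.intercept)
    return report


def _codon_proxy_section(config: RunConfig, usable: Sequence[GeneRecord]) -> dict:
    """Replace abundance with the log-odds codon score in the pooled fit."""
    from .codon import codon_log_odds, log_odds_score, read_cds_fasta

    seqs, skipped = read_cds_fasta(config.cds_fasta)
    abund = {r.gene_id: r.abundance for r in usable if r.abundance}
    table = codon_log_odds(seqs, abund)
    scores = {s.gene_id: sc for s in seqs if (sc := log_odds_score(s, table)) is not None}
    xs, ys, gids = [], [], []
    from .regression import log_omega

    for r in usable:
        if r.gene_id in scores and r.omega is not None:
            gids.append(r.gene_id)
            xs.append(scores[r.gene_id])
            ys.append(log_omega(r.omega, config.transform))
    if len(xs) < 3 or np.ptp(xs) == 0:
        raise ValueError("too few genes with codon scores for the proxy regression")
    fit = deming_fit(xs, ys, config.delta, config.transform)
    comps = {r.gene_id: r.compartment.value for r in usable if r.compartment}
    resid = {g: float(yv - (fit.intercept + fit.slope * xv)) for g, xv, yv in zip(gids, xs, ys)}
    by_class = {}
    for c in _CLASS_ORDER:
        sel = [v for g, v in resid.items() if comps.get(g) == c]
        if sel:
            by_class[c] = float(np.mean(sel))
    return {
        "n_sequences": len(seqs),
        "n_skipped": len(skipped),
        "n_scored": len(xs),
        "proxy_deming_slope": fit.slope,
        "proxy_deming_intercept": fit.intercept,
        "residual_class_means": by_class,
    }


def _write_outputs(config, report, records, truth, cur, resid_recs, comps, ess):
    os.makedirs(config.outdir, exist_ok=True)
    with open(os.path.join(config.outdir, "report.json"), "w", encoding="utf-8") as fh:
        fh.write(report.to_json() + "\n")
    if config.write_tables:
        write_gene_table(records, os.path.join(config.outdir, "gene_table.tsv"))
        write_rejection_log(cur, os.path.join(config.outdir, "rejections.tsv"))
        if truth is not None:
            write_truth_table(truth, os.path.join(config.outdir, "truth.tsv"))
        with open(os.path.join(config.outdir, "residuals.tsv"), "w", encoding="utf-8") as fh:
            fh.write("gene_id\tx\ty\tresidual\tcompartment\tessential\n")
            for rr, c, e in zip(resid_recs, comps, ess):
                fh.write(f"{rr.gene_id}\t{rr.x!r}\t{rr.y!r}\t{rr.residual!r}\t{c}\t{int(e)}\n")
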