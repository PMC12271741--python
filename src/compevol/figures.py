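"""Optional figure output (requires matplotlib).

Two panels mirror the analysis: per-compartment box plots of raw log rates
and of abundance-controlled residuals, and the pooled log-log scatter with
the Deming line. Figures are a convenience; the analysis surface is the
JSON report and TSV tables.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np


def _require_mpl():
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError("figure output needs matplotlib (install compevol[plot])") from exc
    return plt


def compartment_boxes(values: Sequence[float], comps: Sequence[str], title: str, path: str) -> None:
    plt = _require_mpl()
    values = np.asarray(values, dtype=float)
    comps = np.asarray(comps)
    order = [c for c in ("Membrane", "Cytoplasm", "Others") if c in comps]
    data = [values[comps == c] for c in order]
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.boxplot(data, tick_labels=order, showfliers=False)
    ax.set_ylabel(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def regression_panel(x, y, slope: float, intercept: float, path: str) -> None:
    plt = _require_mpl()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.plot(x, y, ".", ms=2, alpha=0.4)
    xs = np.linspace(x.min(), x.max(), 50)
    ax.plot(xs, intercept + slope * xs, "r-", lw=1.5)
    ax.set_xlabel("log10 abundance (ppm)")
    ax.set_ylabel("log10 (omega + eps)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def write_figures(outdir: str, x, y, resid, comps, slope: float, intercept: float) -> None:
    os.makedirs(outdir, exist_ok=True)
    compartment_boxes(y, comps, "log10 (omega + eps)", os.path.join(outdir, "omega_by_compartment.png"))
    compartment_boxes(resid, comps, "abundance-controlled residual", os.path.join(outdir, "residual_by_compartment.png"))
    regression_panel(x, y, slope, intercept, os.path.join(outdir, "pooled_regression.png"))
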