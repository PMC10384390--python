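"""Diagnostic figures: forest, scatter, funnel and leave-one-out plots.

Figures are deterministic views; every figure's underlying numbers are also
written as a plot-data TSV next to the image, so the tables, not the
rasters, are the test surface.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .estimators import MRResult, ratio_estimates, wald_ratio
from .harmonization import HarmonizedSet
from .sensitivity import SensitivityReport

logger = logging.getLogger(__name__)

DEFAULT_FORMAT = "png"
DEFAULT_DPI = 150
DEFAULT_SIZE = (6.0, 5.0)


def _save(fig: plt.Figure, out_dir: Path, stem: str, fmt: str, dpi: int) -> Path:
    path = out_dir / f"{stem}.{fmt}"
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
    return path


def _write_data(df: pd.DataFrame, out_dir: Path, stem: str) -> Path:
    path = out_dir / f"{stem}_data.tsv"
    df.to_csv(path, sep="\t", index=False)
    return path


def forest_plot(h: HarmonizedSet, mr: Sequence[MRResult], out_dir: Path,
                fmt: str, dpi: int, size: tuple[float, float]) -> dict[str, Path]:
    rows = []
    for pair in h.retained:
        res = wald_ratio(pair)
        rows.append({"label": pair.snp_id, "kind": "snp",
                     "estimate": res.estimate, "ci_low": res.ci_low,
                     "ci_high": res.ci_high})
    for res in mr:
        rows.append({"label": res.method, "kind": "summary",
                     "estimate": res.estimate, "ci_low": res.ci_low,
                     "ci_high": res.ci_high})
    df = pd.DataFrame(rows)
    fig, ax = plt.subplots(figsize=size)
    y = np.arange(len(df))[::-1]
    colors = np.where(df["kind"] == "summary", "firebrick", "black")
    for yi, (_, row), c in zip(y, df.iterrows(), colors):
        ax.plot([row["ci_low"], row["ci_high"]], [yi, yi], color=c, lw=1.2)
        ax.plot(row["estimate"], yi, "o", color=c, ms=4)
    ax.axvline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(y)
    ax.set_yticklabels(df["label"])
    ax.set_xlabel("causal estimate (95% CI)")
    ax.set_title("Per-SNP and summary causal estimates")
    return {"figure": _save(fig, out_dir, "forest", fmt, dpi),
            "data": _write_data(df, out_dir, "forest")}


def scatter_plot(h: HarmonizedSet, mr: Sequence[MRResult], out_dir: Path,
                 fmt: str, dpi: int, size: tuple[float, float]) -> dict[str, Path]:
    pairs = h.retained
    bx = np.array([p.beta_exp for p in pairs])
    by = np.array([p.beta_out for p in pairs])
    sx = np.array([p.se_exp for p in pairs])
    sy = np.array([p.se_out for p in pairs])
    df = pd.DataFrame({"snp_id": [p.snp_id for p in pairs], "beta_exp": bx,
                       "beta_out": by, "se_exp": sx, "se_out": sy})
    fig, ax = plt.subplots(figsize=size)
    ax.errorbar(bx, by, xerr=sx, yerr=sy, fmt="o", ms=4, color="black",
                ecolor="silver", elinewidth=0.8, capsize=0)
    xs = np.linspace(min(0.0, bx.min()), bx.max() * 1.05, 50)
    lines = []
    for res in mr:
        intercept = res.extra.get("intercept", 0.0)
        ax.plot(xs, intercept + res.estimate * xs, lw=1.2,
                label=f"{res.method} (slope={res.estimate:.4g})")
        lines.append({"method": res.method, "slope": res.estimate,
                      "intercept": intercept})
    ax.axhline(0.0, color="grey", lw=0.6)
    ax.set_xlabel("SNP effect on exposure")
    ax.set_ylabel("SNP effect on outcome")
    ax.legend(fontsize=7)
    ax.set_title("SNP effects with fitted causal slopes")
    data = pd.concat([df, pd.DataFrame(lines)], axis=1)
    return {"figure": _save(fig, out_dir, "scatter", fmt, dpi),
            "data": _write_data(data, out_dir, "scatter")}


def funnel_plot(h: HarmonizedSet, mr: Sequence[MRResult], out_dir: Path,
                fmt: str, dpi: int, size: tuple[float, float]) -> dict[str, Path]:
    ratios = ratio_estimates(h)
    precision = 1.0 / ratios.se_b
    df = pd.DataFrame({"snp_id": ratios.snp_ids, "ratio": ratios.b,
                       "precision": precision})
    fig, ax = plt.subplots(figsize=size)
    ax.plot(ratios.b, precision, "o", ms=4, color="black")
    for res in mr:
        ax.axvline(res.estimate, lw=1.0, ls="--", label=res.method)
    ax.set_xlabel("per-SNP causal estimate")
    ax.set_ylabel("precision (1/SE)")
    ax.legend(fontsize=7)
    ax.set_title("Funnel of per-SNP estimates")
    return {"figure": _save(fig, out_dir, "funnel", fmt, dpi),
            "data": _write_data(df, out_dir, "funnel")}


def loo_plot(sens: SensitivityReport, out_dir: Path, fmt: str, dpi: int,
             size: tuple[float, float]) -> dict[str, Path]:
    rows = [{"excluded_snp": r.extra.get("excluded_snp", ""),
             "estimate": r.estimate, "ci_low": r.ci_low, "ci_high": r.ci_high}
            for r in sens.loo]
    df = pd.DataFrame(rows)
    fig, ax = plt.subplots(figsize=size)
    if not df.empty:
        y = np.arange(len(df))[::-1]
        full = df.loc[df["excluded_snp"] == "All", "estimate"]
        for yi, (_, row) in zip(y, df.iterrows()):
            c = "firebrick" if row["excluded_snp"] == "All" else "black"
            ax.plot([row["ci_low"], row["ci_high"]], [yi, yi], color=c, lw=1.2)
            ax.plot(row["estimate"], yi, "o", color=c, ms=4)
        if len(full):
            ax.axvline(float(full.iloc[0]), color="firebrick", lw=0.8, ls="--")
        ax.set_yticks(y)
        ax.set_yticklabels(df["excluded_snp"])
    ax.set_xlabel("IVW estimate excluding each SNP (95% CI)")
    ax.set_title("Leave-one-out sensitivity")
    return {"figure": _save(fig, out_dir, "leave_one_out", fmt, dpi),
            "data": _write_data(df, out_dir, "leave_one_out")}


def render_diagnostics(
    mr: Sequence[MRResult],
    sens: Optional[SensitivityReport],
    h: HarmonizedSet,
    out_dir: str | Path,
    format: str = DEFAULT_FORMAT,
    dpi: int = DEFAULT_DPI,
    size: tuple[float, float] = DEFAULT_SIZE,
) -> dict[str, dict[str, Path]]:
    """Render the four diagnostic plots plus their data TSVs.

    Empty inputs are a warning-level no-op (no files written).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if h.n_retained == 0:
        logger.warning("render_diagnostics: no retained instruments, nothing to plot")
        return {}
    artifacts = {
        "forest": forest_plot(h, mr, out_dir, format, dpi, size),
        "scatter": scatter_plot(h, mr, out_dir, format, dpi, size),
        "funnel": funnel_plot(h, mr, out_dir, format, dpi, size),
    }
    if sens is not None and sens.loo:
        artifacts["leave_one_out"] = loo_plot(sens, out_dir, format, dpi, size)
    return artifacts


def miami_plot(miami_df: pd.DataFrame, threshold: float, out_dir: str | Path,
               format: str = DEFAULT_FORMAT, dpi: int = DEFAULT_DPI,
               size: tuple[float, float] = (9.0, 5.0)) -> dict[str, Path]:
    """Mirrored Manhattan-style plot of a phenome-wide scan's signed scores."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=size)
    if not miami_df.empty:
        x = np.arange(len(miami_df))
        for pathway, grp in miami_df.groupby("super_pathway", sort=True):
            ax.plot(x[grp.index], grp["signed_score"], "o", ms=4, label=pathway)
        cut = -np.log10(threshold)
        ax.axhline(cut, color="firebrick", lw=0.8, ls="--")
        ax.axhline(-cut, color="firebrick", lw=0.8, ls="--")
        ax.axhline(0.0, color="grey", lw=0.6)
        ax.legend(fontsize=7)
    ax.set_xlabel("outcomes (grouped by category)")
    ax.set_ylabel("signed -log10 p")
    ax.set_title("Phenome-wide MR scan")
    return {"figure": _save(fig, out_dir, "miami", format, dpi),
            "data": _write_data(miami_df, out_dir, "miami")}
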