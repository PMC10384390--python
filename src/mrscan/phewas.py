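"""Batch phenome-wide two-sample MR over an exposure x outcome grid.

Each pair runs the full selection -> harmonization -> estimation pipeline;
family-wise control is a Bonferroni threshold alpha / (n_exposures *
n_outcomes) with strict inequality. Pairs without usable instruments are
recorded with a skip reason, never dropped silently, and the scan result is
independent of pair execution order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd

from .errors import InsufficientInstrumentsError, ParameterError
from .estimators import METHOD_ALIASES, ivw, wald_ratio
from .harmonization import (DEFAULT_AMBIGUITY_WINDOW, DEFAULT_MODE,
                            harmonize_set)
from .instruments import (DEFAULT_CLUMP_R2, DEFAULT_CLUMP_WINDOW,
                          DEFAULT_P_THRESHOLD, DEFAULT_PROXY_R2,
                          apply_proxies, select_instruments)
from .ld import LDProvider
from .sumstats import SummaryStatsSet

logger = logging.getLogger(__name__)


def bonferroni_threshold(alpha: float, n_exposures: int, n_outcomes: int) -> float:
    """Family-wise p-value threshold alpha / (n_exposures * n_outcomes)."""
    if not 0.0 < alpha < 1.0:
        raise ParameterError(f"alpha must be in (0,1), got {alpha}")
    if n_exposures < 1 or n_outcomes < 1:
        raise ParameterError("exposure/outcome counts must be >= 1")
    return alpha / (n_exposures * n_outcomes)


@dataclass
class ScanConfig:
    """Per-pair pipeline settings for a phenome-wide scan."""

    p_threshold: float = DEFAULT_P_THRESHOLD
    mhc_exclude: bool = True
    ld: Optional[LDProvider] = None
    clump_r2: float = DEFAULT_CLUMP_R2
    clump_window_bp: int = DEFAULT_CLUMP_WINDOW
    proxy_r2_min: float = DEFAULT_PROXY_R2
    harmonize_mode: int = DEFAULT_MODE
    ambiguity_window: float = DEFAULT_AMBIGUITY_WINDOW
    method: str = "ivw_re"  # headline method; Wald fallback at one instrument
    alpha_family: float = 0.05
    seed: int = 0


@dataclass
class ScanRow:
    exposure_id: str
    outcome_id: str
    method: Optional[str] = None
    estimate: Optional[float] = None
    se: Optional[float] = None
    pval: Optional[float] = None
    n_snp: int = 0
    significant: bool = False
    skip_reason: Optional[str] = None


@dataclass
class ScanResult:
    rows: list[ScanRow]
    alpha_family: float
    threshold: float
    n_exposures: int
    n_outcomes: int
    outcome_categories: dict[str, str] = field(default_factory=dict)
    exposure_pathways: dict[str, str] = field(default_factory=dict)

    @property
    def tested(self) -> list[ScanRow]:
        return [r for r in self.rows if r.skip_reason is None]

    @property
    def skipped(self) -> list[ScanRow]:
        return [r for r in self.rows if r.skip_reason is not None]

    @property
    def significant_rows(self) -> list[ScanRow]:
        return [r for r in self.tested if r.significant]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])


def _run_pair(exposure: SummaryStatsSet, outcome: SummaryStatsSet,
              cfg: ScanConfig) -> ScanRow:
    row = ScanRow(exposure_id=exposure.trait_id, outcome_id=outcome.trait_id)
    instruments, selection = select_instruments(
        exposure, outcome=outcome, ld=cfg.ld, p_threshold=cfg.p_threshold,
        mhc_exclude=cfg.mhc_exclude, r2_max=cfg.clump_r2,
        window_bp=cfg.clump_window_bp, proxy_r2_min=cfg.proxy_r2_min)
    if len(instruments) == 0:
        row.skip_reason = "no_instruments"
        return row
    out = outcome
    if selection.proxies:
        out = apply_proxies(outcome, selection.proxies, exposure)
    h = harmonize_set(instruments, out, mode=cfg.harmonize_mode,
                      ambiguity_window=cfg.ambiguity_window)
    if h.n_retained == 0:
        row.skip_reason = "no_harmonized_pairs"
        return row
    try:
        if h.n_retained == 1:
            res = wald_ratio(h.retained[0])
        else:
            method = METHOD_ALIASES.get(cfg.method, cfg.method)
            if method == "ivw_fe":
                res = ivw(h, mode="fixed")
            elif method == "ivw_re":
                res = ivw(h, mode="random")
            else:
                raise ParameterError(
                    f"unsupported scan headline method {cfg.method!r}")
        row.method, row.estimate, row.se = res.method, res.estimate, res.se
        row.pval, row.n_snp = res.pval, res.n_snp
    except InsufficientInstrumentsError as exc:
        row.skip_reason = f"estimation_failed:{exc}"
    return row


def scan(
    exposures: list[SummaryStatsSet],
    outcomes: list[SummaryStatsSet],
    config: Optional[ScanConfig] = None,
    outcome_categories: Optional[Mapping[str, str]] = None,
    exposure_pathways: Optional[Mapping[str, str]] = None,
) -> ScanResult:
    """Run the full pipeline on every exposure/outcome pair of the grid."""
    if not exposures or not outcomes:
        raise ParameterError("scan requires at least one exposure and one outcome")
    cfg = config or ScanConfig()
    threshold = bonferroni_threshold(cfg.alpha_family, len(exposures), len(outcomes))
    rows: list[ScanRow] = []
    for exposure in exposures:
        for outcome in outcomes:
            row = _run_pair(exposure, outcome, cfg)
            if row.skip_reason is None:
                row.significant = row.pval < threshold
            rows.append(row)
    result = ScanResult(
        rows=rows, alpha_family=cfg.alpha_family, threshold=threshold,
        n_exposures=len(exposures), n_outcomes=len(outcomes),
        outcome_categories=dict(outcome_categories or {}),
        exposure_pathways=dict(exposure_pathways or {}),
    )
    logger.info("scan: %d/%d pair(s) tested, %d significant at %.3g",
                len(result.tested), len(rows), len(result.significant_rows),
                threshold)
    return result


def miami_table(sr: ScanResult) -> pd.DataFrame:
    """Plot-ready mirrored-Manhattan table for the scan.

    Per tested pair: signed score = sign(estimate) * (-log10 p), the outcome
    category's order index and the exposure's super-pathway color key.
    Rows are sorted by (category, outcome_id, exposure_id); positive scores
    belong on the top half of the plot.
    """
    records = []
    categories = sr.outcome_categories
    pathways = sr.exposure_pathways
    cat_order = {c: i for i, c in enumerate(sorted(set(categories.values())))}
    for row in sr.tested:
        score = math.copysign(-math.log10(max(row.pval, 1e-300)),
                              row.estimate if row.estimate else 1.0)
        category = categories.get(row.outcome_id, "uncategorized")
        records.append({
            "exposure_id": row.exposure_id,
            "outcome_id": row.outcome_id,
            "estimate": row.estimate,
            "pval": row.pval,
            "signed_score": score,
            "significant": row.significant,
            "category": category,
            "category_index": cat_order.get(category, len(cat_order)),
            "super_pathway": pathways.get(row.exposure_id, "unassigned"),
        })
    df = pd.DataFrame(records)
    if not df.empty:
        df = df.sort_values(["category", "outcome_id", "exposure_id"],
                            kind="stable").reset_index(drop=True)
    return df
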