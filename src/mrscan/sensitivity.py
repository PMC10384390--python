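"""Heterogeneity, pleiotropy, directionality and influence diagnostics.

Cochran's Q uses the ratio-estimate weights (se_out/|beta_exp|)^-2 around
the fixed-effect IVW estimate; the exposure-side standard error's variance
contribution is ignored (first-order, NOME-style), consistent with the IVW
estimator itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .errors import ConfigurationError, InsufficientInstrumentsError
from .estimators import MRResult, egger, ivw, ratio_estimates, wald_ratio, run_mr
from .harmonization import HarmonizedSet

logger = logging.getLogger(__name__)


@dataclass
class SteigerRow:
    snp_id: str
    r2_exp: float
    r2_out: float
    direction_ok: bool
    steiger_pval: float
    removed: bool


@dataclass
class SensitivityReport:
    """Grouped sensitivity diagnostics for one harmonized instrument set."""

    q_stat: Optional[float] = None
    q_df: Optional[int] = None
    q_pval: Optional[float] = None
    egger_intercept: Optional[float] = None
    egger_intercept_se: Optional[float] = None
    egger_intercept_pval: Optional[float] = None
    steiger: list[SteigerRow] = field(default_factory=list)
    loo: list[MRResult] = field(default_factory=list)
    single_snp: list[MRResult] = field(default_factory=list)


def cochran_q(h: HarmonizedSet) -> tuple[float, int, float]:
    """Cochran's Q of the per-SNP ratios around the fixed-effect IVW estimate.

    Returns (Q, df, upper-tail chi-square p) with df = J - 1.
    """
    pairs = h.retained
    if len(pairs) < 2:
        raise InsufficientInstrumentsError(
            f"cochran_q needs >= 2 instruments, have {len(pairs)}")
    ratios = ratio_estimates(h)
    w = ratios.w
    theta = float(np.sum(w * ratios.b) / np.sum(w))  # == IVW fixed-effect estimate
    q = float(np.sum(w * (ratios.b - theta) ** 2))
    df = len(pairs) - 1
    pval = float(stats.chi2.sf(q, df))
    return q, df, pval


def egger_intercept_test(h: HarmonizedSet) -> tuple[float, float, float]:
    """Egger regression intercept, its SE, and the t-test p (J-2 df)."""
    res = egger(h)
    return (res.extra["intercept"], res.extra["intercept_se"],
            res.extra["intercept_pval"])


def _r_from_t(beta: float, se: float, n: int) -> float:
    t2 = (beta / se) ** 2
    return float(np.sqrt(t2 / (t2 + n - 2)))


def steiger_filter(
    h: HarmonizedSet,
    n_exp: Optional[int] = None,
    n_out: Optional[int] = None,
    alpha: float = 0.05,
) -> tuple[HarmonizedSet, list[SteigerRow]]:
    """Directionality filter comparing per-SNP variance explained on each side.

    r is recovered from the t statistic, r = sqrt(t²/(t² + n - 2)); a SNP
    points the right way when r²_exp > r²_out. The Steiger p comes from a
    two-sample z-test on Fisher-transformed |r| with variance
    1/(n_exp-3) + 1/(n_out-3). A SNP is removed only when the direction is
    wrong AND p < alpha (direction alone is noisy at weak instruments).

    Record-level sample sizes are preferred; ``n_exp``/``n_out`` are
    set-level fallbacks.
    """
    rows: list[SteigerRow] = []
    kept_ids: list[str] = []
    for pair in h.retained:
        ne = pair.n_exp if pair.n_exp is not None else n_exp
        no = pair.n_out if pair.n_out is not None else n_out
        if ne is None or no is None:
            raise ConfigurationError(
                f"steiger_filter: sample size unavailable for {pair.snp_id} "
                "(provide record-level n or set-level n_exp/n_out)")
        r_exp = _r_from_t(pair.beta_exp, pair.se_exp, ne)
        r_out = _r_from_t(pair.beta_out, pair.se_out, no)
        direction_ok = r_exp**2 > r_out**2
        z = (np.arctanh(min(abs(r_exp), 1 - 1e-15))
             - np.arctanh(min(abs(r_out), 1 - 1e-15)))
        z /= np.sqrt(1.0 / (ne - 3) + 1.0 / (no - 3))
        pval = float(2.0 * stats.norm.sf(abs(z)))
        removed = (not direction_ok) and pval < alpha
        rows.append(SteigerRow(pair.snp_id, r_exp**2, r_out**2, direction_ok,
                               pval, removed))
        if not removed:
            kept_ids.append(pair.snp_id)
    n_removed = sum(r.removed for r in rows)
    if n_removed:
        logger.info("steiger_filter removed %d/%d instrument(s)", n_removed, len(rows))
    return h.subset(kept_ids), rows


def leave_one_out(h: HarmonizedSet, mode: str = "random") -> list[MRResult]:
    """IVW re-estimates excluding each SNP in turn, plus the all-SNP row.

    The excluded snp_id is reported in ``extra['excluded_snp']`` (the
    all-SNP row uses the sentinel ``'All'``).
    """
    pairs = h.retained
    if len(pairs) < 3:
        raise InsufficientInstrumentsError(
            f"leave_one_out needs >= 3 instruments, have {len(pairs)}")
    results: list[MRResult] = []
    for pair in pairs:
        res = ivw(h.drop(pair.snp_id), mode=mode)
        res.extra["excluded_snp"] = pair.snp_id
        results.append(res)
    full = ivw(h, mode=mode)
    full.extra["excluded_snp"] = "All"
    results.append(full)
    return results


def single_snp(h: HarmonizedSet, summary_methods: tuple[str, ...] = ("ivw_re",),
               n_boot: int = 1000, seed: int = 0) -> list[MRResult]:
    """Per-SNP Wald ratios plus one summary row per requested multi-SNP method."""
    pairs = h.retained
    if not pairs:
        return []
    results = [wald_ratio(p) for p in pairs]
    if summary_methods and len(pairs) >= 1:
        try:
            results.extend(run_mr(h, list(summary_methods), n_boot=n_boot, seed=seed))
        except InsufficientInstrumentsError:
            logger.info("single_snp: summary methods skipped (too few instruments)")
    return results


def sensitivity_report(
    h: HarmonizedSet,
    n_exp: Optional[int] = None,
    n_out: Optional[int] = None,
    steiger_alpha: float = 0.05,
    run_steiger: bool = True,
) -> SensitivityReport:
    """Assemble every diagnostic that the instrument count permits."""
    report = SensitivityReport()
    n = h.n_retained
    if n >= 2:
        report.q_stat, report.q_df, report.q_pval = cochran_q(h)
    if n >= 3:
        (report.egger_intercept, report.egger_intercept_se,
         report.egger_intercept_pval) = egger_intercept_test(h)
        report.loo = leave_one_out(h)
    if run_steiger:
        try:
            _, report.steiger = steiger_filter(h, n_exp=n_exp, n_out=n_out,
                                               alpha=steiger_alpha)
        except ConfigurationError:
            logger.info("sensitivity_report: Steiger skipped (no sample sizes)")
    report.single_snp = single_snp(h)
    return report
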