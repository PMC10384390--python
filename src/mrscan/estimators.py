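"""Causal-effect estimators for two-sample MR on harmonized effect pairs.

Implemented methods: Wald ratio, inverse-variance-weighted (fixed and
multiplicative random effects), Egger regression, weighted/simple median,
and weighted/simple mode. All ratio-based quantities use the first-order
delta approximation se(b_j) = se_out,j / |beta_exp,j|, consistent with the
NOME-style weighting of the IVW estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import stats

from .errors import InsufficientInstrumentsError, ParameterError
from .harmonization import HarmonizedPair, HarmonizedSet

logger = logging.getLogger(__name__)

Z95 = stats.norm.ppf(0.975)

METHOD_WALD = "wald_ratio"
METHOD_IVW_FE = "ivw_fe"
METHOD_IVW_RE = "ivw_re"
METHOD_EGGER = "egger"
METHOD_WEIGHTED_MEDIAN = "weighted_median"
METHOD_SIMPLE_MEDIAN = "simple_median"
METHOD_WEIGHTED_MODE = "weighted_mode"
METHOD_SIMPLE_MODE = "simple_mode"

DEFAULT_N_BOOT = 1000


@dataclass
class MRResult:
    """One method's causal estimate with its uncertainty."""

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    extra: dict = field(default_factory=dict)


@dataclass
class RatioEstimates:
    """Per-SNP Wald ratios b_j with delta-method SEs and inverse-variance weights."""

    snp_ids: list[str]
    b: np.ndarray
    se_b: np.ndarray

    @property
    def w(self) -> np.ndarray:
        return 1.0 / self.se_b**2


def _retained(h: HarmonizedSet, minimum: int, method: str) -> list[HarmonizedPair]:
    pairs = h.retained
    if len(pairs) < minimum:
        raise InsufficientInstrumentsError(
            f"{method} needs >= {minimum} retained instruments, have {len(pairs)}")
    return pairs


def _arrays(pairs: list[HarmonizedPair]) -> tuple[np.ndarray, ...]:
    bx = np.array([p.beta_exp for p in pairs], dtype=float)
    by = np.array([p.beta_out for p in pairs], dtype=float)
    sx = np.array([p.se_exp for p in pairs], dtype=float)
    sy = np.array([p.se_out for p in pairs], dtype=float)
    return bx, by, sx, sy


def ratio_estimates(h: HarmonizedSet) -> RatioEstimates:
    """Per-SNP ratios; requires every retained beta_exp to be nonzero."""
    pairs = _retained(h, 1, "ratio_estimates")
    bx, by, _, sy = _arrays(pairs)
    if np.any(bx == 0):
        raise ParameterError("ratio estimates undefined for beta_exp == 0")
    return RatioEstimates(
        snp_ids=[p.snp_id for p in pairs],
        b=by / bx,
        se_b=sy / np.abs(bx),
    )


def _finish(method: str, estimate: float, se: float, pval: float, n_snp: int,
            extra: Optional[dict] = None) -> MRResult:
    return MRResult(
        method=method,
        estimate=float(estimate),
        se=float(se),
        ci_low=float(estimate - Z95 * se),
        ci_high=float(estimate + Z95 * se),
        pval=float(pval),
        n_snp=n_snp,
        extra=extra or {},
    )


def wald_ratio(pair: HarmonizedPair) -> MRResult:
    """Single-instrument ratio estimate with first-order delta SE."""
    if pair.beta_exp == 0:
        raise ParameterError(f"Wald ratio undefined: beta_exp == 0 for {pair.snp_id}")
    estimate = pair.beta_out / pair.beta_exp
    se = pair.se_out / abs(pair.beta_exp)
    pval = 2.0 * stats.norm.sf(abs(estimate) / se)
    return _finish(METHOD_WALD, estimate, se, pval, 1, {"snp_id": pair.snp_id})


def _ivw_core(bx: np.ndarray, by: np.ndarray, sy: np.ndarray
              ) -> tuple[float, float, float]:
    """Zero-intercept WLS of by on bx with weights 1/sy²: (theta, fixed se, Q)."""
    w = 1.0 / sy**2
    den = float(np.sum(w * bx**2))
    theta = float(np.sum(w * bx * by)) / den
    se_fixed = den**-0.5
    # Cochran's Q in ratio form == weighted RSS of this regression
    q = float(np.sum(w * (by - theta * bx) ** 2))
    return theta, se_fixed, q


def ivw(h: HarmonizedSet, mode: str = "random") -> MRResult:
    """Inverse-variance-weighted estimate.

    ``mode='fixed'`` uses the analytic fixed-effect SE; ``mode='random'``
    (the default) applies multiplicative random-effects scaling
    max(1, sqrt(Q/(J-1))). A single retained instrument reduces exactly to
    the Wald ratio.
    """
    if mode not in ("fixed", "random"):
        raise ParameterError(f"ivw mode must be 'fixed' or 'random', got {mode!r}")
    method = METHOD_IVW_FE if mode == "fixed" else METHOD_IVW_RE
    pairs = _retained(h, 1, method)
    if len(pairs) == 1:
        res = wald_ratio(pairs[0])
        res.method = method
        return res
    bx, by, _, sy = _arrays(pairs)
    theta, se_fixed, q = _ivw_core(bx, by, sy)
    se = se_fixed
    if mode == "random":
        se = se_fixed * max(1.0, np.sqrt(q / (len(pairs) - 1)))
    pval = 2.0 * stats.norm.sf(abs(theta) / se)
    return _finish(method, theta, se, pval, len(pairs), {"q_stat": q})


def egger(h: HarmonizedSet) -> MRResult:
    """Egger regression: weighted fit of by on bx with an intercept.

    Pairs are first oriented so every beta_exp is positive (negating both
    effects where needed), which makes the intercept well defined. SEs carry
    multiplicative residual scaling max(1, residual SE); p-values use the
    t distribution with J-2 degrees of freedom. The intercept block is
    reported in ``extra``.
    """
    pairs = _retained(h, 3, METHOD_EGGER)
    bx, by, _, sy = _arrays(pairs)
    if np.any(bx == 0):
        raise ParameterError("egger orientation undefined for beta_exp == 0")
    flip = np.sign(bx)
    bx, by = bx * flip, by * flip
    w = 1.0 / sy**2
    X = np.column_stack([np.ones_like(bx), bx])
    xtwx = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (w * by))
    resid = by - X @ coef
    dof = len(pairs) - 2
    sigma2 = float(np.sum(w * resid**2)) / dof
    scale = max(1.0, np.sqrt(sigma2))
    cov_unit = np.linalg.inv(xtwx)
    se_int = float(np.sqrt(cov_unit[0, 0])) * scale
    se_slope = float(np.sqrt(cov_unit[1, 1])) * scale
    slope, intercept = float(coef[1]), float(coef[0])
    p_slope = 2.0 * stats.t.sf(abs(slope) / se_slope, dof)
    p_int = 2.0 * stats.t.sf(abs(intercept) / se_int, dof)
    res = _finish(METHOD_EGGER, slope, se_slope, p_slope, len(pairs), {
        "intercept": intercept,
        "intercept_se": se_int,
        "intercept_pval": p_int,
        "residual_scale": scale,
    })
    return res


def _weighted_median_point(b: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(b, kind="stable")
    b_sorted, w_sorted = b[order], w[order]
    p = (np.cumsum(w_sorted) - 0.5 * w_sorted) / np.sum(w_sorted)
    return float(np.interp(0.5, p, b_sorted))


def _parametric_boot(
    pairs: list[HarmonizedPair],
    point_fn: Callable[[np.ndarray, np.ndarray], float],
    n_boot: int,
    seed: int,
) -> float:
    """SE of an estimator of (b, se_b) arrays under parametric resampling."""
    bx, by, sx, sy = _arrays(pairs)
    rng = np.random.default_rng(seed)
    J = len(pairs)
    ests = np.empty(n_boot)
    bx_star = rng.normal(bx, sx, size=(n_boot, J))
    by_star = rng.normal(by, sy, size=(n_boot, J))
    for i in range(n_boot):
        bxs = bx_star[i]
        bxs = np.where(bxs == 0, np.finfo(float).tiny, bxs)
        ests[i] = point_fn(by_star[i] / bxs, sy / np.abs(bxs))
    return float(np.std(ests, ddof=1))


def weighted_median(
    h: HarmonizedSet,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    weighted: bool = True,
) -> MRResult:
    """Weighted (or simple) median of the per-SNP ratio estimates.

    The estimate interpolates the ratio order statistics at standardized
    cumulative weight 0.5; the SE comes from a parametric bootstrap with a
    fixed seed.
    """
    method = METHOD_WEIGHTED_MEDIAN if weighted else METHOD_SIMPLE_MEDIAN
    pairs = _retained(h, 3, method)
    ratios = ratio_estimates(h)

    def point(b: np.ndarray, se_b: np.ndarray) -> float:
        w = 1.0 / se_b**2 if weighted else np.ones_like(b)
        return _weighted_median_point(b, w)

    estimate = point(ratios.b, ratios.se_b)
    se = _parametric_boot(pairs, point, n_boot, seed)
    pval = 2.0 * stats.norm.sf(abs(estimate) / se) if se > 0 else float(estimate == 0)
    return _finish(method, estimate, se, pval, len(pairs))


def simple_median(h: HarmonizedSet, n_boot: int = DEFAULT_N_BOOT, seed: int = 0
                  ) -> MRResult:
    return weighted_median(h, n_boot=n_boot, seed=seed, weighted=False)


def _silverman_bandwidth(b: np.ndarray) -> float:
    n = len(b)
    sd = float(np.std(b, ddof=1))
    iqr = float(np.subtract(*np.percentile(b, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * n ** (-1 / 5)


def _mode_point(b: np.ndarray, w: np.ndarray, bandwidth_factor: float,
                n_grid: int = 512) -> float:
    if np.ptp(b) == 0:
        return float(b[0])
    bw = bandwidth_factor * _silverman_bandwidth(b)
    if bw <= 0:
        return float(np.median(b))
    grid = np.linspace(b.min() - 3 * bw, b.max() + 3 * bw, n_grid)
    # weighted Gaussian KDE evaluated on the grid
    z = (grid[:, None] - b[None, :]) / bw
    density = (np.exp(-0.5 * z**2) * w[None, :]).sum(axis=1)
    return float(grid[int(np.argmax(density))])


def mode_estimator(
    h: HarmonizedSet,
    weighted: bool = True,
    bandwidth_factor: float = 1.0,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> MRResult:
    """Mode of the kernel-smoothed ratio-estimate density.

    Bandwidth is ``bandwidth_factor`` times the Silverman rule on the
    ratios; the argmax is taken on a 512-point grid spanning
    [min-3h, max+3h]. SE via parametric bootstrap with a fixed seed.
    """
    if bandwidth_factor <= 0:
        raise ParameterError("bandwidth_factor must be positive")
    method = METHOD_WEIGHTED_MODE if weighted else METHOD_SIMPLE_MODE
    pairs = _retained(h, 3, method)
    ratios = ratio_estimates(h)

    def point(b: np.ndarray, se_b: np.ndarray) -> float:
        w = 1.0 / se_b**2 if weighted else np.ones_like(b)
        return _mode_point(b, w, bandwidth_factor)

    estimate = point(ratios.b, ratios.se_b)
    se = _parametric_boot(pairs, point, n_boot, seed)
    pval = 2.0 * stats.norm.sf(abs(estimate) / se) if se > 0 else float(estimate == 0)
    return _finish(method, estimate, se, pval, len(pairs))


# ---------------------------------------------------------------------------
# method registry / dispatch

#: method name -> (minimum retained instruments, maximum or None, callable)
METHOD_REGISTRY: dict[str, tuple[int, Optional[int], Callable[..., MRResult]]] = {
    METHOD_WALD: (1, 1, lambda h, **kw: wald_ratio(h.retained[0])),
    METHOD_IVW_FE: (1, None, lambda h, **kw: ivw(h, mode="fixed")),
    METHOD_IVW_RE: (1, None, lambda h, **kw: ivw(h, mode="random")),
    METHOD_EGGER: (3, None, lambda h, **kw: egger(h)),
    METHOD_WEIGHTED_MEDIAN: (3, None, lambda h, **kw: weighted_median(h, **kw)),
    METHOD_SIMPLE_MEDIAN: (3, None, lambda h, **kw: simple_median(h, **kw)),
    METHOD_WEIGHTED_MODE: (
        3, None, lambda h, **kw: mode_estimator(h, weighted=True, **kw)),
    METHOD_SIMPLE_MODE: (
        3, None, lambda h, **kw: mode_estimator(h, weighted=False, **kw)),
}

#: convenience alias: plain "ivw" means the random-effects default
METHOD_ALIASES = {"ivw": METHOD_IVW_RE}


def run_mr(
    h: HarmonizedSet,
    methods: list[str],
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> list[MRResult]:
    """Dispatch the requested methods, skipping any whose instrument count
    requirements are unmet (with a logged reason). Raises when every method
    is skipped or the method list is empty.
    """
    if not methods:
        raise ParameterError("run_mr requires a non-empty method list")
    n = h.n_retained
    results: list[MRResult] = []
    skipped: list[str] = []
    for name in methods:
        canonical = METHOD_ALIASES.get(name, name)
        if canonical not in METHOD_REGISTRY:
            raise ParameterError(f"unknown MR method {name!r}")
        minimum, maximum, fn = METHOD_REGISTRY[canonical]
        if n < minimum or (maximum is not None and n > maximum):
            reason = (f"{canonical}: needs "
                      + (f"exactly {minimum}" if maximum == minimum
                         else f">= {minimum}")
                      + f" instruments, have {n}")
            logger.info("run_mr skipping %s", reason)
            skipped.append(reason)
            continue
        kwargs = {"n_boot": n_boot, "seed": seed} if canonical in (
            METHOD_WEIGHTED_MEDIAN, METHOD_SIMPLE_MEDIAN,
            METHOD_WEIGHTED_MODE, METHOD_SIMPLE_MODE) else {}
        results.append(fn(h, **kwargs))
    if not results:
        raise InsufficientInstrumentsError(
            "all requested methods were skipped: " + "; ".join(skipped))
    return results
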