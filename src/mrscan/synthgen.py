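"""Synthetic paired summary statistics, LD references and triple fixtures.

Everything is simulated directly on the summary-statistic scale under a
linear instrumental-variable model: per SNP j,

    se_exp,j = (2 * EAF_j * (1 - EAF_j) * n_exp)^(-1/2)
    beta_exp,j ~ Normal(gamma_j, se_exp,j^2)
    beta_out,j ~ Normal(theta * gamma_j + alpha_j, se_out,j^2)

with gamma_j the true SNP-exposure effects, alpha_j direct (pleiotropic)
outcome effects and theta the causal effect of interest. Exposure and
outcome samples are non-overlapping by construction. Setting
``reverse_causation=True`` swaps the generative roles of the two sides.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .ld import BlockLDProvider
from .sumstats import AssociationRecord, SummaryStatsSet
from .triples import TripleRecord

#: smallest reportable p-value (record invariant requires pval > 0)
P_FLOOR = 1e-300

# non-palindromic allele pairs cycled across simulated SNPs
_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"))


@dataclass
class SimulationConfig:
    """Ground-truth parameters for one paired exposure/outcome simulation."""

    n_snp: int = 50
    n_exp: int = 50_000
    n_out: int = 50_000
    theta: float = 0.0
    gamma_mean: float = 0.1
    gamma_sd: float = 0.02
    gamma_values: Optional[Sequence[float]] = None
    eaf_low: float = 0.1
    eaf_high: float = 0.9
    mu_alpha: float = 0.0
    sd_alpha: float = 0.0
    correlated_pleiotropy: bool = False
    reverse_causation: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snp < 1:
            raise ParameterError("n_snp must be >= 1")
        if self.n_exp < 10 or self.n_out < 10:
            raise ParameterError("sample sizes must be >= 10")
        if not (0.0 < self.eaf_low < self.eaf_high < 1.0):
            raise ParameterError(
                f"eaf bounds must satisfy 0 < low < high < 1, got "
                f"({self.eaf_low}, {self.eaf_high})")
        if self.gamma_values is not None and len(self.gamma_values) != self.n_snp:
            raise ParameterError("gamma_values length must equal n_snp")


@dataclass
class SimulationTruth:
    theta: float
    gamma: np.ndarray
    alpha: np.ndarray
    eaf: np.ndarray
    snp_ids: list[str]


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.maximum(p, P_FLOOR)


def simulate_sumstats(
    cfg: SimulationConfig,
    trait_prefix: str = "sim",
    snp_offset: int = 0,
) -> tuple[SummaryStatsSet, SummaryStatsSet, SimulationTruth]:
    """Simulate one exposure/outcome pair of summary-statistic sets.

    SNPs are placed 1 Mb apart on chromosome 1 (well outside any clumping
    window interaction) with non-palindromic aligned alleles, so downstream
    harmonization keeps every pair. Deterministic for a fixed config.
    """
    rng = np.random.default_rng(cfg.seed)
    J = cfg.n_snp
    eaf = rng.uniform(cfg.eaf_low, cfg.eaf_high, size=J)
    if cfg.gamma_values is not None:
        gamma = np.asarray(cfg.gamma_values, dtype=float)
    else:
        gamma = rng.normal(cfg.gamma_mean, cfg.gamma_sd, size=J)
    alpha = np.zeros(J)
    if cfg.mu_alpha != 0 or cfg.sd_alpha != 0:
        noise = rng.normal(0.0, 1.0, size=J)
        if cfg.correlated_pleiotropy and cfg.gamma_sd > 0:
            # InSIDE violation: pleiotropic effects track instrument strength
            g_std = (gamma - np.mean(gamma)) / max(np.std(gamma), 1e-12)
            noise = 0.7 * g_std + np.sqrt(1 - 0.7**2) * noise
        alpha = cfg.mu_alpha + cfg.sd_alpha * noise

    se_exp = (2.0 * eaf * (1.0 - eaf) * cfg.n_exp) ** -0.5
    se_out = (2.0 * eaf * (1.0 - eaf) * cfg.n_out) ** -0.5
    true_exp, true_out = gamma, cfg.theta * gamma + alpha
    if cfg.reverse_causation:
        true_exp, true_out = true_out, true_exp
    beta_exp = rng.normal(true_exp, se_exp)
    beta_out = rng.normal(true_out, se_out)
    p_exp = _two_sided_p(beta_exp, se_exp)
    p_out = _two_sided_p(beta_out, se_out)

    snp_ids = [f"rs{snp_offset + j + 1:07d}" for j in range(J)]
    exp_records, out_records = [], []
    for j, snp in enumerate(snp_ids):
        ea, oa = _ALLELE_PAIRS[j % len(_ALLELE_PAIRS)]
        pos = 1_000_000 * (snp_offset + j + 1)
        exp_records.append(AssociationRecord(
            snp_id=snp, chrom="1", pos=pos, effect_allele=ea, other_allele=oa,
            beta=float(beta_exp[j]), se=float(se_exp[j]), pval=float(p_exp[j]),
            eaf=float(eaf[j]), n=cfg.n_exp))
        out_records.append(AssociationRecord(
            snp_id=snp, chrom="1", pos=pos, effect_allele=ea, other_allele=oa,
            beta=float(beta_out[j]), se=float(se_out[j]), pval=float(p_out[j]),
            eaf=float(eaf[j]), n=cfg.n_out))
    exposure = SummaryStatsSet(f"{trait_prefix}_exposure", "exposure", exp_records)
    outcome = SummaryStatsSet(f"{trait_prefix}_outcome", "outcome", out_records)
    truth = SimulationTruth(cfg.theta, gamma, alpha, eaf, snp_ids)
    return exposure, outcome, truth


def simulate_ld(
    blocks: Sequence[tuple[int, float]],
    seed: int = 0,
    chrom: str = "1",
    spacing_bp: int = 10_000,
) -> tuple[BlockLDProvider, pd.DataFrame]:
    """Block-diagonal LD reference plus contiguous SNP placement.

    ``blocks`` is a list of (size, within_r2); every within-block pair shares
    that r², cross-block pairs are 0. Returns the provider and a placement
    table (snp_id, chrom, pos, block).
    """
    block_of: dict[str, int] = {}
    within: dict[int, float] = {}
    rows = []
    counter = 0
    for b, (size, r2) in enumerate(blocks):
        if not 0.0 <= r2 <= 1.0:
            raise ParameterError(f"within_r2 must be in [0,1], got {r2}")
        within[b] = r2
        for _ in range(size):
            counter += 1
            snp = f"rs{counter}"
            block_of[snp] = b
            rows.append({"snp_id": snp, "chrom": chrom,
                         "pos": counter * spacing_bp, "block": b})
    placement = pd.DataFrame(rows)
    return BlockLDProvider(block_of, within), placement


def make_triple_fixture(
    n_overlap: int,
    n_noise: int,
    seed: int = 0,
    exposure_term: str = "Exposure Compound",
    outcome_term: str = "Outcome Disease",
) -> tuple[list[TripleRecord], list[TripleRecord], list[str]]:
    """Triple tables with planted overlap terms and known enrichment ordering.

    Returns (exposure triples, outcome triples, expected overlap ranking).
    Overlap term i gets exposure-side counts of strictly increasing
    enrichment with i, so the expected ranking is simply the planted order.
    """
    if n_overlap < 0 or n_noise < 0:
        raise ParameterError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    exposure_triples: list[TripleRecord] = []
    outcome_triples: list[TripleRecord] = []
    expected_order: list[str] = []
    global_total = 100_000
    for i in range(n_overlap):
        term = f"shared_mediator_{i:02d}"
        expected_order.append(term)
        # enrichment strictly decreasing with i: local_count falls, margins fixed
        local_count = max(1, 40 - 10 * i)
        exposure_triples.append(TripleRecord(
            subject=exposure_term, predicate="INTERACTS_WITH", object=term,
            local_count=local_count, local_total=50,
            global_count=50, global_total=global_total))
        outcome_triples.append(TripleRecord(
            subject=term, predicate="PREDISPOSES", object=outcome_term,
            local_count=5, local_total=50,
            global_count=2000, global_total=global_total))
    for i in range(n_noise):
        exposure_triples.append(TripleRecord(
            subject=exposure_term, predicate="INTERACTS_WITH",
            object=f"exposure_only_{i:02d}",
            local_count=int(rng.integers(1, 10)), local_total=50,
            global_count=int(rng.integers(100, 5000)), global_total=global_total))
        outcome_triples.append(TripleRecord(
            subject=f"outcome_only_{i:02d}", predicate="PREDISPOSES",
            object=outcome_term,
            local_count=int(rng.integers(1, 10)), local_total=50,
            global_count=int(rng.integers(100, 5000)), global_total=global_total))
    return exposure_triples, outcome_triples, expected_order


def simulate_grid(
    n_exposures: int,
    n_outcomes: int,
    theta: float | np.ndarray = 0.0,
    n_snp_per_exposure: int = 10,
    n_exp: int = 50_000,
    n_out: int = 50_000,
    gamma_mean: float = 0.1,
    gamma_sd: float = 0.02,
    seed: int = 0,
) -> tuple[list[SummaryStatsSet], list[SummaryStatsSet], np.ndarray]:
    """Exposure x outcome grid of summary statistics with known causal matrix.

    Each exposure owns a disjoint panel of instruments; every outcome carries
    records for all panels with beta_out,j ~ N(theta[e,o] * gamma_j, se²).
    Returns (exposures, outcomes, theta matrix).
    """
    if n_exposures < 1 or n_outcomes < 1:
        raise ParameterError("grid dimensions must be >= 1")
    theta_m = np.broadcast_to(np.asarray(theta, dtype=float),
                              (n_exposures, n_outcomes)).copy()
    rng = np.random.default_rng(seed)
    J = n_snp_per_exposure

    gammas, eafs, exp_sets = [], [], []
    for e in range(n_exposures):
        offset = e * J
        eaf = rng.uniform(0.1, 0.9, size=J)
        gamma = rng.normal(gamma_mean, gamma_sd, size=J)
        se_exp = (2.0 * eaf * (1.0 - eaf) * n_exp) ** -0.5
        beta = rng.normal(gamma, se_exp)
        pv = _two_sided_p(beta, se_exp)
        records = []
        for j in range(J):
            ea, oa = _ALLELE_PAIRS[j % len(_ALLELE_PAIRS)]
            records.append(AssociationRecord(
                snp_id=f"rs{offset + j + 1:07d}", chrom="1",
                pos=1_000_000 * (offset + j + 1), effect_allele=ea,
                other_allele=oa, beta=float(beta[j]), se=float(se_exp[j]),
                pval=float(pv[j]), eaf=float(eaf[j]), n=n_exp))
        exp_sets.append(SummaryStatsSet(f"exposure_{e}", "exposure", records))
        gammas.append(gamma)
        eafs.append(eaf)

    out_sets = []
    for o in range(n_outcomes):
        records = []
        for e in range(n_exposures):
            offset = e * J
            se_out = (2.0 * eafs[e] * (1.0 - eafs[e]) * n_out) ** -0.5
            beta = rng.normal(theta_m[e, o] * gammas[e], se_out)
            pv = _two_sided_p(beta, se_out)
            for j in range(J):
                ea, oa = _ALLELE_PAIRS[j % len(_ALLELE_PAIRS)]
                records.append(AssociationRecord(
                    snp_id=f"rs{offset + j + 1:07d}", chrom="1",
                    pos=1_000_000 * (offset + j + 1), effect_allele=ea,
                    other_allele=oa, beta=float(beta[j]), se=float(se_out[j]),
                    pval=float(pv[j]), eaf=float(eafs[e][j]), n=n_out))
        out_sets.append(SummaryStatsSet(f"outcome_{o}", "outcome", records))
    return exp_sets, out_sets, theta_m


def config_to_dict(cfg: SimulationConfig) -> dict:
    d = dataclasses.asdict(cfg)
    if d.get("gamma_values") is not None:
        d["gamma_values"] = list(map(float, d["gamma_values"]))
    return d
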