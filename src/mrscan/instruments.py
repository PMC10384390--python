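"""Instrumental-variable selection.

Pipeline: genome-wide significance filter -> MHC exclusion -> greedy LD
clumping -> proxy substitution for instruments absent from the outcome.
All tie-breaking is by lexicographic snp_id so results are deterministic
and invariant to input row order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .errors import ParameterError
from .ld import LDProvider
from .sumstats import AssociationRecord, SummaryStatsSet, normalize_chrom

logger = logging.getLogger(__name__)

# default MHC interval, 1-based inclusive ("26 Mb" == 26,000,000 bp exactly)
MHC_CHROM = "6"
MHC_START = 26_000_000
MHC_END = 34_000_000

DEFAULT_P_THRESHOLD = 5e-8
DEFAULT_CLUMP_R2 = 0.001
DEFAULT_CLUMP_WINDOW = 10_000_000
DEFAULT_PROXY_R2 = 0.8


@dataclass
class InstrumentSelection:
    """Bookkeeping of kept/removed SNPs across the selection pipeline.

    ``removed`` holds (snp_id, reason) with reason one of
    ``above_p_threshold``, ``mhc_region``, ``clumped_by:<snp_id>``,
    ``missing_in_outcome_no_proxy``. ``proxies`` lists
    (original snp_id, proxy snp_id, r²) substitutions.
    """

    kept: list[str] = field(default_factory=list)
    removed: list[tuple[str, str]] = field(default_factory=list)
    proxies: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def removed_ids(self) -> set[str]:
        return {snp for snp, _ in self.removed}

    def merge(self, other: "InstrumentSelection") -> "InstrumentSelection":
        return InstrumentSelection(
            kept=list(other.kept),
            removed=self.removed + other.removed,
            proxies=self.proxies + other.proxies,
        )


def filter_significant(s: SummaryStatsSet, p_threshold: float = DEFAULT_P_THRESHOLD
                       ) -> SummaryStatsSet:
    """Keep records with ``pval < p_threshold`` (strict), preserving order."""
    if not 0.0 < p_threshold <= 1.0:
        raise ParameterError(f"p_threshold must be in (0,1], got {p_threshold}")
    return s.with_records([r for r in s if r.pval < p_threshold])


def exclude_mhc(
    s: SummaryStatsSet,
    chrom: str = MHC_CHROM,
    start_bp: int = MHC_START,
    end_bp: int = MHC_END,
) -> SummaryStatsSet:
    """Drop records inside the closed interval [start_bp, end_bp] on ``chrom``."""
    if not start_bp < end_bp:
        raise ParameterError("start_bp must be < end_bp")
    target = normalize_chrom(chrom)
    return s.with_records(
        [r for r in s if not (r.chrom == target and start_bp <= r.pos <= end_bp)])


def clump(
    s: SummaryStatsSet,
    ld: LDProvider,
    r2_max: float = DEFAULT_CLUMP_R2,
    window_bp: int = DEFAULT_CLUMP_WINDOW,
) -> InstrumentSelection:
    """Greedy LD clumping.

    Records are ranked by (pval, snp_id); the top-ranked SNP is kept and every
    remaining SNP on the same chromosome within ``window_bp`` with
    r² >= ``r2_max`` against it is removed with reason ``clumped_by:<kept>``.
    Pairs the LD panel does not cover count as r²=0 (logged).
    """
    if not 0.0 < r2_max <= 1.0:
        raise ParameterError(f"r2_max must be in (0,1], got {r2_max}")
    if window_bp <= 0:
        raise ParameterError("window_bp must be positive")

    ranked = sorted(s, key=lambda r: (r.pval, r.snp_id))
    selection = InstrumentSelection()
    active: list[AssociationRecord] = ranked
    removed: set[str] = set()
    n_unknown = 0
    for rec in ranked:
        if rec.snp_id in removed:
            continue
        selection.kept.append(rec.snp_id)
        for other in active:
            if other.snp_id == rec.snp_id or other.snp_id in removed:
                continue
            if other.chrom != rec.chrom or abs(other.pos - rec.pos) > window_bp:
                continue
            if not ld.known(rec.snp_id, other.snp_id):
                n_unknown += 1
                continue
            if ld.r2(rec.snp_id, other.snp_id) >= r2_max:
                removed.add(other.snp_id)
                selection.removed.append(
                    (other.snp_id, f"clumped_by:{rec.snp_id}"))
    if n_unknown:
        logger.info("clump: %d pair lookup(s) absent from the LD panel treated as r2=0",
                    n_unknown)
    selection.kept.sort(key=lambda snp: (s[snp].pval, snp))
    return selection


def find_proxy(
    snp: str,
    outcome: SummaryStatsSet,
    ld: LDProvider,
    r2_min: float = DEFAULT_PROXY_R2,
) -> Optional[tuple[str, float]]:
    """Best proxy for ``snp`` among outcome SNPs in LD at r² >= ``r2_min``.

    Candidates without a resolved allele-orientation flag are rejected
    (conservative). Ties on r² break to the lexicographically smaller snp_id.
    Returns ``None`` when no usable candidate exists.
    """
    candidates = [
        c for c in ld.neighbors(snp, r2_min)
        if c.snp_id != snp and c.snp_id in outcome and c.aligned is True
    ]
    if not candidates:
        return None
    best = min(candidates, key=lambda c: (-c.r2, c.snp_id))
    return best.snp_id, best.r2


def apply_proxies(
    outcome: SummaryStatsSet,
    proxies: list[tuple[str, str, float]],
    exposure: SummaryStatsSet,
) -> SummaryStatsSet:
    """Relabel proxy outcome records under the original instrument's snp_id.

    The LD provider's ``aligned=True`` contract guarantees the proxy's effect
    allele tags the original SNP's effect allele, so the substituted record
    carries the exposure record's allele labels with the proxy's statistics.
    """
    by_original = {orig: proxy for orig, proxy, _ in proxies}
    replaced: list[AssociationRecord] = []
    for orig, proxy in by_original.items():
        src = outcome[proxy]
        exp_rec = exposure[orig]
        replaced.append(AssociationRecord(
            snp_id=orig,
            chrom=src.chrom,
            pos=src.pos,
            effect_allele=exp_rec.effect_allele,
            other_allele=exp_rec.other_allele,
            beta=src.beta,
            se=src.se,
            pval=src.pval,
            eaf=src.eaf,
            n=src.n,
        ))
    proxy_ids = set(by_original.values())
    records = [r for r in outcome if r.snp_id not in proxy_ids] + replaced
    return outcome.with_records(records)


def select_instruments(
    exposure: SummaryStatsSet,
    outcome: Optional[SummaryStatsSet] = None,
    ld: Optional[LDProvider] = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    mhc_exclude: bool = True,
    r2_max: float = DEFAULT_CLUMP_R2,
    window_bp: int = DEFAULT_CLUMP_WINDOW,
    proxy_r2_min: float = DEFAULT_PROXY_R2,
) -> tuple[SummaryStatsSet, InstrumentSelection]:
    """Full selection pipeline; returns the instrument subset and its audit.

    When ``outcome`` is given, instruments absent from it get a proxy
    substitution attempt; failures are removed with reason
    ``missing_in_outcome_no_proxy``. When ``ld`` is ``None`` clumping and
    proxy search are skipped (instruments assumed independent).
    """
    selection = InstrumentSelection()
    sig = filter_significant(exposure, p_threshold)
    selection.removed += [(snp, "above_p_threshold")
                          for snp in exposure.snp_ids if snp not in sig]
    if mhc_exclude:
        outside = exclude_mhc(sig)
        selection.removed += [(snp, "mhc_region")
                              for snp in sig.snp_ids if snp not in outside]
        sig = outside
    if ld is not None:
        clumped = clump(sig, ld, r2_max=r2_max, window_bp=window_bp)
        selection.removed += clumped.removed
        kept_ids = clumped.kept
    else:
        kept_ids = list(sig.snp_ids)
    if outcome is not None:
        final: list[str] = []
        for snp in kept_ids:
            if snp in outcome:
                final.append(snp)
                continue
            proxy = find_proxy(snp, outcome, ld, proxy_r2_min) if ld is not None else None
            if proxy is None:
                selection.removed.append((snp, "missing_in_outcome_no_proxy"))
            else:
                selection.proxies.append((snp, proxy[0], proxy[1]))
                final.append(snp)
        kept_ids = final
    selection.kept = kept_ids
    return sig.subset(kept_ids), selection
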