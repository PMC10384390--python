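"""Allele harmonization of exposure/outcome summary statistics.

Three strategies are supported for palindromic (A/T, C/G) variants:

1. assume every allele label is reported on the forward strand;
2. infer strand from effect-allele frequencies, dropping variants whose
   frequency is too close to 0.5 to call (the default, window 0.08);
3. drop all palindromic variants.

Non-palindromic variants are reconciled by allele labels alone: direct
match, effect/other swap (sign flip), strand complement, or complement plus
swap. Anything irreconcilable (indels, mismatched allele sets) is dropped
rather than raised, so batch scans never abort on a single variant.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .sumstats import AssociationRecord, SummaryStatsSet

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PALINDROMIC_PAIRS = ({"A", "T"}, {"C", "G"})

ACTION_ALIGNED = "aligned"
ACTION_SIGN_FLIPPED = "sign_flipped"
ACTION_STRAND_FLIPPED = "strand_flipped"
ACTION_STRAND_SIGN_FLIPPED = "strand_flipped_and_sign_flipped"
ACTION_DROP_PALINDROMIC = "dropped_palindromic"
ACTION_DROP_AMBIGUOUS = "dropped_ambiguous_freq"
ACTION_DROP_INCOMPATIBLE = "dropped_incompatible"

DEFAULT_MODE = 2
DEFAULT_AMBIGUITY_WINDOW = 0.08


def is_palindromic(allele_a: str, allele_b: str) -> bool:
    return {allele_a, allele_b} in PALINDROMIC_PAIRS


@dataclass(frozen=True)
class HarmonizedPair:
    """Per-SNP exposure/outcome effects after allele reconciliation.

    Unless ``action`` starts with ``dropped``, ``beta_out`` (and ``eaf_out``)
    refer to the exposure's effect allele.
    """

    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: Optional[float]
    eaf_out: Optional[float]
    action: str
    n_exp: Optional[int] = None
    n_out: Optional[int] = None

    @property
    def retained(self) -> bool:
        return not self.action.startswith("dropped")


class HarmonizedSet:
    """Ordered collection of :class:`HarmonizedPair` plus the mode used."""

    def __init__(self, pairs: list[HarmonizedPair], mode: int = DEFAULT_MODE,
                 ambiguity_window: float = DEFAULT_AMBIGUITY_WINDOW) -> None:
        self.pairs = list(pairs)
        self.mode = mode
        self.ambiguity_window = ambiguity_window

    @property
    def retained(self) -> list[HarmonizedPair]:
        return [p for p in self.pairs if p.retained]

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    def action_counts(self) -> Counter:
        return Counter(p.action for p in self.pairs)

    def subset(self, snp_ids) -> "HarmonizedSet":
        wanted = set(snp_ids)
        return HarmonizedSet([p for p in self.pairs if p.snp_id in wanted],
                             mode=self.mode, ambiguity_window=self.ambiguity_window)

    def drop(self, snp_id: str) -> "HarmonizedSet":
        return HarmonizedSet([p for p in self.pairs if p.snp_id != snp_id],
                             mode=self.mode, ambiguity_window=self.ambiguity_window)

    def audit_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"snp_id": p.snp_id, "action": p.action, "retained": p.retained}
             for p in self.pairs])

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


def _pair(exp: AssociationRecord, out: AssociationRecord, action: str,
          flip_sign: bool = False) -> HarmonizedPair:
    beta_out = -out.beta if flip_sign else out.beta
    eaf_out = out.eaf
    if flip_sign and eaf_out is not None:
        eaf_out = 1.0 - eaf_out
    return HarmonizedPair(
        snp_id=exp.snp_id,
        beta_exp=exp.beta, se_exp=exp.se,
        beta_out=beta_out, se_out=out.se,
        eaf_exp=exp.eaf, eaf_out=eaf_out,
        action=action,
        n_exp=exp.n, n_out=out.n,
    )


def harmonize_pair(
    exp: AssociationRecord,
    out: AssociationRecord,
    mode: int = DEFAULT_MODE,
    ambiguity_window: float = DEFAULT_AMBIGUITY_WINDOW,
) -> HarmonizedPair:
    """Reconcile one exposure/outcome record pair onto the exposure's effect allele."""
    if exp.snp_id != out.snp_id:
        raise ValueError(
            f"harmonize_pair called on different SNPs: {exp.snp_id} vs {out.snp_id}")
    if mode not in (1, 2, 3):
        raise ValueError(f"mode must be 1, 2 or 3, got {mode}")

    alleles = (exp.effect_allele, exp.other_allele,
               out.effect_allele, out.other_allele)
    if any(a not in COMPLEMENT for a in alleles):
        return _pair(exp, out, ACTION_DROP_INCOMPATIBLE)

    e_ea, e_oa = exp.effect_allele, exp.other_allele
    o_ea, o_oa = out.effect_allele, out.other_allele

    if is_palindromic(e_ea, e_oa):
        if {o_ea, o_oa} != {e_ea, e_oa}:
            return _pair(exp, out, ACTION_DROP_INCOMPATIBLE)
        if mode == 3:
            return _pair(exp, out, ACTION_DROP_PALINDROMIC)
        if mode == 1:
            # trust the labels as same-strand
            if (o_ea, o_oa) == (e_ea, e_oa):
                return _pair(exp, out, ACTION_ALIGNED)
            return _pair(exp, out, ACTION_SIGN_FLIPPED, flip_sign=True)
        # mode 2: orient by which side of 0.5 each frequency falls
        w = ambiguity_window
        if exp.eaf is None or out.eaf is None:
            return _pair(exp, out, ACTION_DROP_AMBIGUOUS)
        # closed ambiguity interval [0.5-w, 0.5+w]; epsilon guards float
        # representation of decimal boundaries (0.5 - 0.08 != 0.42 exactly)
        if (abs(exp.eaf - 0.5) <= w + 1e-12
                or abs(out.eaf - 0.5) <= w + 1e-12):
            return _pair(exp, out, ACTION_DROP_AMBIGUOUS)
        if (exp.eaf < 0.5) == (out.eaf < 0.5):
            return _pair(exp, out, ACTION_ALIGNED)
        return _pair(exp, out, ACTION_SIGN_FLIPPED, flip_sign=True)

    # non-palindromic: label logic, optionally through the strand complement
    if (o_ea, o_oa) == (e_ea, e_oa):
        return _pair(exp, out, ACTION_ALIGNED)
    if (o_ea, o_oa) == (e_oa, e_ea):
        return _pair(exp, out, ACTION_SIGN_FLIPPED, flip_sign=True)
    c_ea, c_oa = COMPLEMENT[o_ea], COMPLEMENT[o_oa]
    if (c_ea, c_oa) == (e_ea, e_oa):
        return _pair(exp, out, ACTION_STRAND_FLIPPED)
    if (c_ea, c_oa) == (e_oa, e_ea):
        return _pair(exp, out, ACTION_STRAND_SIGN_FLIPPED, flip_sign=True)
    return _pair(exp, out, ACTION_DROP_INCOMPATIBLE)


def harmonize_set(
    exp: SummaryStatsSet,
    out: SummaryStatsSet,
    mode: int = DEFAULT_MODE,
    ambiguity_window: float = DEFAULT_AMBIGUITY_WINDOW,
) -> HarmonizedSet:
    """Intersect on snp_id (exposure order) and harmonize each shared pair."""
    shared = [snp for snp in exp.snp_ids if snp in out]
    if not shared:
        logger.warning("harmonize_set: no shared SNPs between %s and %s",
                       exp.trait_id, out.trait_id)
    pairs = [harmonize_pair(exp[snp], out[snp], mode=mode,
                            ambiguity_window=ambiguity_window)
             for snp in shared]
    hs = HarmonizedSet(pairs, mode=mode, ambiguity_window=ambiguity_window)
    counts = hs.action_counts()
    if counts:
        logger.info("harmonize_set %s vs %s: %s", exp.trait_id, out.trait_id,
                    dict(counts))
    return hs
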