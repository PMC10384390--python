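"""Pairwise-LD lookup contract and file-backed implementations.

The reference panel behind clumping and proxy search is abstracted to an
:class:`LDProvider`: ``r2(a, b)`` with unit diagonal and symmetry, and
``neighbors(snp, r2_min)`` returning candidate proxies together with an
allele-orientation flag (``aligned=True`` means the candidate's effect
allele tags the query SNP's effect allele; ``None`` means unknown, in which
case proxy substitution refuses the candidate).
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from pathlib import Path
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .errors import InputError


class ProxyCandidate(NamedTuple):
    snp_id: str
    r2: float
    aligned: Optional[bool]


class LDProvider(ABC):
    """Symmetric pairwise r-squared lookup with unit diagonal."""

    @abstractmethod
    def r2(self, snp_a: str, snp_b: str) -> float:
        """Pairwise r² in [0, 1]; 0 for pairs the panel does not cover."""

    @abstractmethod
    def neighbors(self, snp: str, r2_min: float) -> list[ProxyCandidate]:
        """All panel SNPs b != snp with r2(snp, b) >= r2_min."""

    def known(self, snp_a: str, snp_b: str) -> bool:
        """Whether the panel covers the pair (diagonal is always known)."""
        return True


class MatrixLDProvider(LDProvider):
    """LD from a square labeled r² matrix (rows/columns indexed by snp_id)."""

    def __init__(self, matrix: pd.DataFrame, aligned: bool = True) -> None:
        if list(matrix.index) != list(matrix.columns):
            raise InputError("LD matrix row and column labels differ")
        values = matrix.to_numpy(dtype=float)
        if not np.allclose(values, values.T, atol=1e-8):
            raise InputError("LD matrix is not symmetric")
        if not np.allclose(np.diag(values), 1.0, atol=1e-8):
            raise InputError("LD matrix diagonal is not 1")
        if values.min() < -1e-8 or values.max() > 1 + 1e-8:
            raise InputError("LD matrix values outside [0, 1]")
        self._labels = list(matrix.index.astype(str))
        self._pos = {s: i for i, s in enumerate(self._labels)}
        self._m = np.clip(values, 0.0, 1.0)
        self._aligned = aligned

    def r2(self, snp_a: str, snp_b: str) -> float:
        if snp_a == snp_b:
            return 1.0
        ia, ib = self._pos.get(snp_a), self._pos.get(snp_b)
        if ia is None or ib is None:
            return 0.0
        return float(self._m[ia, ib])

    def known(self, snp_a: str, snp_b: str) -> bool:
        return snp_a == snp_b or (snp_a in self._pos and snp_b in self._pos)

    def neighbors(self, snp: str, r2_min: float) -> list[ProxyCandidate]:
        i = self._pos.get(snp)
        if i is None:
            return []
        flag = True if self._aligned else None
        out = [
            ProxyCandidate(self._labels[j], float(v), flag)
            for j, v in enumerate(self._m[i])
            if j != i and v >= r2_min
        ]
        return sorted(out, key=lambda c: (-c.r2, c.snp_id))


class PairTableLDProvider(LDProvider):
    """LD from a (snp_a, snp_b, r2[, aligned]) long table; unlisted pairs are r²=0."""

    def __init__(self, table: pd.DataFrame) -> None:
        required = {"snp_a", "snp_b", "r2"}
        if not required <= set(table.columns):
            raise InputError(f"LD pair table needs columns {sorted(required)}")
        has_aligned = "aligned" in table.columns
        self._pairs: dict[tuple[str, str], float] = {}
        self._aligned: dict[tuple[str, str], Optional[bool]] = {}
        self._adj: dict[str, set[str]] = {}
        for row in table.itertuples(index=False):
            a, b = str(row.snp_a), str(row.snp_b)
            v = float(row.r2)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"r2 {v} outside [0,1] for pair ({a}, {b})")
            flag: Optional[bool] = bool(row.aligned) if has_aligned else None
            for key in ((a, b), (b, a)):
                self._pairs[key] = v
                self._aligned[key] = flag
            self._adj.setdefault(a, set()).add(b)
            self._adj.setdefault(b, set()).add(a)

    def r2(self, snp_a: str, snp_b: str) -> float:
        if snp_a == snp_b:
            return 1.0
        return self._pairs.get((snp_a, snp_b), 0.0)

    def known(self, snp_a: str, snp_b: str) -> bool:
        return snp_a == snp_b or (snp_a, snp_b) in self._pairs

    def neighbors(self, snp: str, r2_min: float) -> list[ProxyCandidate]:
        out = [
            ProxyCandidate(b, self._pairs[(snp, b)], self._aligned[(snp, b)])
            for b in self._adj.get(snp, ())
            if self._pairs[(snp, b)] >= r2_min
        ]
        return sorted(out, key=lambda c: (-c.r2, c.snp_id))


class BlockLDProvider(LDProvider):
    """Synthetic block-diagonal LD: within-block pairs share one r², cross-block 0."""

    def __init__(self, block_of: dict[str, int], within_r2: dict[int, float]) -> None:
        self._block_of = dict(block_of)
        self._within = dict(within_r2)
        self._members: dict[int, list[str]] = {}
        for snp, blk in self._block_of.items():
            self._members.setdefault(blk, []).append(snp)

    def r2(self, snp_a: str, snp_b: str) -> float:
        if snp_a == snp_b:
            return 1.0
        ba, bb = self._block_of.get(snp_a), self._block_of.get(snp_b)
        if ba is None or bb is None or ba != bb:
            return 0.0
        return self._within[ba]

    def known(self, snp_a: str, snp_b: str) -> bool:
        return snp_a == snp_b or (snp_a in self._block_of and snp_b in self._block_of)

    def neighbors(self, snp: str, r2_min: float) -> list[ProxyCandidate]:
        blk = self._block_of.get(snp)
        if blk is None or self._within[blk] < r2_min:
            return []
        v = self._within[blk]
        out = [ProxyCandidate(b, v, True) for b in self._members[blk] if b != snp]
        return sorted(out, key=lambda c: (-c.r2, c.snp_id))


def load_ld(path: str | Path, sep: Optional[str] = None) -> LDProvider:
    """Load an LD reference from a file.

    A table with columns ``snp_a, snp_b, r2`` (optionally ``aligned``) becomes
    a :class:`PairTableLDProvider`; anything else is interpreted as a square
    labeled matrix (first column = row labels).
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    if {"snp_a", "snp_b", "r2"} <= set(df.columns):
        return PairTableLDProvider(df)
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return MatrixLDProvider(df, aligned=False)
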