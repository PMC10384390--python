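"""Data model and file I/O for GWAS summary statistics.

Coordinates are 1-based inclusive throughout. Allele columns are restricted
to single-nucleotide biallelic variants by default; indels can be passed
through with ``allow_indels=True`` but are untested by the harmonization
rules downstream.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
VALID_CHROMS = frozenset([str(i) for i in range(1, 23)] + ["X", "Y", "MT"])

#: canonical field names every :func:`read_sumstats` column map must resolve
REQUIRED_FIELDS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pval",
)
OPTIONAL_FIELDS = ("eaf", "n")


def normalize_chrom(label: object) -> str:
    """Map 'chr6', '06', 6, 'chrMT' etc. onto the canonical labels 1-22, X, Y, MT."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.upper() in ("M", "MT"):
        return "MT"
    s = s.upper()
    if s.isdigit():
        s = str(int(s))
    return s


@dataclass(frozen=True)
class AssociationRecord:
    """One SNP's summary statistics in one GWAS.

    Parameters
    ----------
    snp_id : str
        rsID (or any unique variant label).
    chrom : str
        Chromosome label, one of 1-22, X, Y, MT (``chr`` prefixes are accepted
        and stripped).
    pos : int
        1-based base-pair position.
    effect_allele, other_allele : str
        Single-nucleotide alleles over {A, C, G, T}; upper-cased.
    eaf : float or None
        Effect-allele frequency in [0, 1]; ``None`` when unavailable.
    beta : float
        Per-allele effect size on the effect allele.
    se : float
        Standard error of ``beta`` (strictly positive).
    pval : float
        Association p-value in (0, 1].
    n : int or None
        Sample size, when known.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: Optional[float] = None
    n: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        object.__setattr__(self, "effect_allele", str(self.effect_allele).upper())
        object.__setattr__(self, "other_allele", str(self.other_allele).upper())

    def violations(self, allow_indels: bool = False) -> list[str]:
        """Return the list of invariant violations (empty when valid)."""
        problems: list[str] = []
        if not self.snp_id:
            problems.append("empty snp_id")
        if self.chrom not in VALID_CHROMS:
            problems.append(f"invalid chromosome {self.chrom!r}")
        if not (isinstance(self.pos, (int, np.integer)) and self.pos > 0):
            problems.append("pos must be a positive integer")
        for name, allele in (("effect_allele", self.effect_allele),
                             ("other_allele", self.other_allele)):
            if allow_indels:
                if not allele or not set(allele) <= VALID_BASES:
                    problems.append(f"{name} {allele!r} not over ACGT")
            elif allele not in VALID_BASES:
                problems.append(f"{name} {allele!r} is not a single nucleotide")
        if self.effect_allele == self.other_allele:
            problems.append("effect_allele equals other_allele")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            problems.append(f"eaf {self.eaf} outside [0,1]")
        if not (math.isfinite(self.beta)):
            problems.append("beta not finite")
        if not (math.isfinite(self.se) and self.se > 0):
            problems.append("se must be a positive finite float")
        if not (math.isfinite(self.pval) and 0.0 < self.pval <= 1.0):
            problems.append(f"pval {self.pval} outside (0,1]")
        if self.n is not None and not self.n > 0:
            problems.append("n must be positive")
        return problems

    def is_valid(self, allow_indels: bool = False) -> bool:
        return not self.violations(allow_indels=allow_indels)


class SummaryStatsSet:
    """An ordered, snp_id-unique collection of :class:`AssociationRecord`.

    ``role`` is fixed at construction to either ``"exposure"`` or
    ``"outcome"``; duplicate snp_ids raise :class:`~mrscan.errors.InputError`.
    """

    def __init__(
        self,
        trait_id: str,
        role: str,
        records: Iterable[AssociationRecord],
        trait_label: Optional[str] = None,
    ) -> None:
        if role not in ("exposure", "outcome"):
            raise ValueError(f"role must be 'exposure' or 'outcome', got {role!r}")
        self.trait_id = trait_id
        self.trait_label = trait_label if trait_label is not None else trait_id
        self.role = role
        self._records: list[AssociationRecord] = list(records)
        self._index: dict[str, AssociationRecord] = {}
        for rec in self._records:
            if rec.snp_id in self._index:
                raise InputError(f"duplicate snp_id {rec.snp_id!r} in {trait_id!r}")
            self._index[rec.snp_id] = rec

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[AssociationRecord]:
        return iter(self._records)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def __getitem__(self, snp_id: str) -> AssociationRecord:
        return self._index[snp_id]

    def get(self, snp_id: str) -> Optional[AssociationRecord]:
        return self._index.get(snp_id)

    @property
    def records(self) -> Sequence[AssociationRecord]:
        return tuple(self._records)

    @property
    def snp_ids(self) -> tuple[str, ...]:
        return tuple(r.snp_id for r in self._records)

    def subset(self, snp_ids: Iterable[str]) -> "SummaryStatsSet":
        """Return a new set restricted to ``snp_ids``, preserving input order."""
        wanted = set(snp_ids)
        return SummaryStatsSet(
            self.trait_id,
            self.role,
            [r for r in self._records if r.snp_id in wanted],
            trait_label=self.trait_label,
        )

    def with_records(self, records: Iterable[AssociationRecord]) -> "SummaryStatsSet":
        return SummaryStatsSet(self.trait_id, self.role, records,
                               trait_label=self.trait_label)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self._records],
                            columns=list(REQUIRED_FIELDS) + list(OPTIONAL_FIELDS))

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return (f"SummaryStatsSet(trait_id={self.trait_id!r}, role={self.role!r}, "
                f"n_records={len(self)})")


def _coerce_optional_float(value: object) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or pd.isna(value):
        return None
    return float(value)


def _coerce_optional_int(value: object) -> Optional[int]:
    v = _coerce_optional_float(value)
    return None if v is None else int(round(v))


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str],
    role: str,
    trait_id: Optional[str] = None,
    trait_label: Optional[str] = None,
    sep: Optional[str] = None,
    allow_indels: bool = False,
) -> SummaryStatsSet:
    """Read a delimited summary-statistics table into a validated set.

    ``column_map`` maps canonical field names (:data:`REQUIRED_FIELDS` plus
    optionally ``eaf`` and ``n``) to the file's header names; published
    summary-statistic dialects differ, so no fixed header is assumed.
    Rows violating record invariants, and rows repeating an earlier snp_id,
    are dropped with a logged count. ``.gz`` files are decompressed
    transparently.
    """
    path = Path(path)
    missing = [f for f in REQUIRED_FIELDS if f not in column_map]
    if missing:
        raise ConfigurationError(f"column_map missing required fields: {missing}")
    try:
        df = pd.read_csv(path, sep=sep, engine="python")
    except (pd.errors.EmptyDataError, csv.Error) as exc:
        # csv.Error: the delimiter sniffer cannot work on an empty file
        raise InputError(f"empty or unreadable summary-statistics file: {path}"
                         ) from exc
    absent = [col for col in column_map.values() if col not in df.columns]
    if absent:
        raise ConfigurationError(
            f"columns {absent} not found in {path} (header: {list(df.columns)})")
    if df.empty:
        raise InputError(f"summary-statistics file has a header but no rows: {path}")

    records: list[AssociationRecord] = []
    seen: set[str] = set()
    n_invalid = 0
    n_dup = 0
    has_eaf = "eaf" in column_map
    has_n = "n" in column_map
    # positional lookup: itertuples mangles non-identifier header names
    col = {f: df.columns.get_loc(column_map[f]) for f in column_map}
    for row in df.itertuples(index=False):
        vals = tuple(row)
        try:
            rec = AssociationRecord(
                snp_id=str(vals[col["snp_id"]]),
                chrom=vals[col["chrom"]],
                pos=int(vals[col["pos"]]),
                effect_allele=str(vals[col["effect_allele"]]),
                other_allele=str(vals[col["other_allele"]]),
                beta=float(vals[col["beta"]]),
                se=float(vals[col["se"]]),
                pval=float(vals[col["pval"]]),
                eaf=_coerce_optional_float(vals[col["eaf"]]) if has_eaf else None,
                n=_coerce_optional_int(vals[col["n"]]) if has_n else None,
            )
        except (TypeError, ValueError):
            n_invalid += 1
            continue
        if not rec.is_valid(allow_indels=allow_indels):
            n_invalid += 1
            continue
        if rec.snp_id in seen:
            n_dup += 1
            logger.warning("duplicate snp_id %s in %s: keeping first occurrence",
                           rec.snp_id, path)
            continue
        seen.add(rec.snp_id)
        records.append(rec)
    if n_invalid:
        logger.info("%s: dropped %d row(s) failing record invariants", path, n_invalid)
    if n_dup:
        logger.info("%s: dropped %d duplicated snp_id row(s)", path, n_dup)
    return SummaryStatsSet(
        trait_id=trait_id or path.stem.removesuffix(".tsv").removesuffix(".csv"),
        role=role,
        records=records,
        trait_label=trait_label,
    )


# ---------------------------------------------------------------------------
# report serialization


def _as_table(results: object) -> pd.DataFrame:
    """Normalize a report object into a flat DataFrame."""
    if isinstance(results, pd.DataFrame):
        return results
    if isinstance(results, SummaryStatsSet):
        return results.to_dataframe()
    if dataclasses.is_dataclass(results) and not isinstance(results, type):
        return pd.DataFrame([dataclasses.asdict(results)])
    if isinstance(results, Mapping):
        return pd.DataFrame([dict(results)])
    if isinstance(results, Iterable):
        rows = []
        for item in results:
            if dataclasses.is_dataclass(item) and not isinstance(item, type):
                rows.append(dataclasses.asdict(item))
            elif isinstance(item, Mapping):
                rows.append(dict(item))
            else:
                raise TypeError(f"cannot serialize row of type {type(item)}")
        return pd.DataFrame(rows)
    raise TypeError(f"cannot serialize report of type {type(results)}")


def write_results(results: object, path: str | Path, format: str = "tsv") -> None:
    """Write a report as TSV or JSON.

    Numeric fields round-trip: reading the file back reproduces every value
    to better than 1e-12 relative tolerance (floats are written with full
    ``repr`` precision). Empty reports produce a header-only file.
    """
    path = Path(path)
    df = _as_table(results)
    if format == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif format == "json":
        payload = df.to_dict(orient="records")
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=str)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'tsv' or 'json')")


def read_results(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    """Read back a report written by :func:`write_results`."""
    path = Path(path)
    if format == "tsv":
        return pd.read_csv(path, sep="\t")
    if format == "json":
        with open(path) as fh:
            return pd.DataFrame(json.load(fh))
    raise ValueError(f"unknown format {format!r}")
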