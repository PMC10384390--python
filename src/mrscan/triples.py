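"""Literature triangulation via semantic triples.

An exposure-side triple's object can coincide with an outcome-side triple's
subject; those overlap terms are candidate mechanistic links between an
exposure and an outcome. Per-triple enrichment uses a one-sided Fisher
exact test of the query-local count against the background count; the
comparable output across sources is the rank, not the p-value itself.
Term matching is case-insensitive exact string equality after whitespace
normalization — deliberately no stemming or ontology mapping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx
import pandas as pd
from scipy import stats

from .errors import InputError

ROLE_EXPOSURE_SUBJECT = "exposure_subject"
ROLE_OVERLAP = "overlap"
ROLE_OUTCOME_OBJECT = "outcome_object"

TRIPLE_COLUMNS = ("subject", "predicate", "object", "local_count",
                  "local_total", "global_count", "global_total")


def normalize_term(term: str) -> str:
    """Whitespace-collapse and lower-case a term for matching."""
    return " ".join(str(term).split()).lower()


@dataclass
class TripleRecord:
    """One subject-predicate-object assertion with enrichment counts."""

    subject: str
    predicate: str
    object: str
    local_count: Optional[int] = None
    local_total: Optional[int] = None
    global_count: Optional[int] = None
    global_total: Optional[int] = None
    pval: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.local_count is not None and self.local_total is not None
                and self.local_count > self.local_total):
            raise InputError(
                f"local_count {self.local_count} > local_total {self.local_total}")
        if (self.global_count is not None and self.global_total is not None
                and self.global_count > self.global_total):
            raise InputError(
                f"global_count {self.global_count} > global_total {self.global_total}")

    @property
    def has_counts(self) -> bool:
        return None not in (self.local_count, self.local_total,
                            self.global_count, self.global_total)


def triple_enrichment(t: TripleRecord) -> Optional[float]:
    """One-sided Fisher exact p for local over-representation of the triple.

    Tests the 2x2 table [[local_count, local_total - local_count],
    [global_count, global_total - global_count]] with alternative 'greater'.
    Returns ``None`` (triple retained, p unset) when counts are missing.
    """
    if not t.has_counts:
        return None
    table = [[t.local_count, t.local_total - t.local_count],
             [t.global_count, t.global_total - t.global_count]]
    return float(stats.fisher_exact(table, alternative="greater").pvalue)


def annotate_enrichment(triples: Iterable[TripleRecord]) -> list[TripleRecord]:
    """Fill ``pval`` in place for every triple with complete counts."""
    out = list(triples)
    for t in out:
        if t.pval is None:
            t.pval = triple_enrichment(t)
    return out


@dataclass
class NetworkNode:
    term: str
    role: str


@dataclass
class NetworkEdge:
    source: str
    predicate: str
    target: str
    side: str  # "exposure" or "outcome"
    pval: Optional[float] = None


@dataclass
class TriangulationNetwork:
    """Edges incident to the overlap terms, with role-annotated nodes."""

    nodes: list[NetworkNode] = field(default_factory=list)
    edges: list[NetworkEdge] = field(default_factory=list)

    @property
    def overlap_terms(self) -> list[str]:
        return sorted(n.term for n in self.nodes if n.role == ROLE_OVERLAP)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for node in self.nodes:
            g.add_node(node.term, role=node.role)
        for e in self.edges:
            g.add_edge(e.source, e.target, predicate=e.predicate, side=e.side,
                       pval=e.pval)
        return g


def overlap_triples(
    exposure_triples: list[TripleRecord],
    outcome_triples: list[TripleRecord],
) -> tuple[set[str], TriangulationNetwork]:
    """Overlap of exposure objects with outcome subjects, plus the network.

    The overlap set is returned in normalized form; the network keeps only
    edges incident to overlap terms together with their exposure subjects
    and outcome objects. Display strings use the first spelling seen.
    """
    exposure_triples = annotate_enrichment(exposure_triples)
    outcome_triples = annotate_enrichment(outcome_triples)
    display: dict[str, str] = {}

    def norm(term: str) -> str:
        key = normalize_term(term)
        display.setdefault(key, " ".join(str(term).split()))
        return key

    exp_objects = {norm(t.object) for t in exposure_triples}
    out_subjects = {norm(t.subject) for t in outcome_triples}
    overlap = exp_objects & out_subjects

    net = TriangulationNetwork()
    roles: dict[str, str] = {}
    for t in exposure_triples:
        if norm(t.object) not in overlap:
            continue
        subj, obj = norm(t.subject), norm(t.object)
        roles[obj] = ROLE_OVERLAP
        roles.setdefault(subj, ROLE_EXPOSURE_SUBJECT)
        net.edges.append(NetworkEdge(display[subj], t.predicate, display[obj],
                                     "exposure", t.pval))
    for t in outcome_triples:
        if norm(t.subject) not in overlap:
            continue
        subj, obj = norm(t.subject), norm(t.object)
        roles[subj] = ROLE_OVERLAP
        roles.setdefault(obj, ROLE_OUTCOME_OBJECT)
        net.edges.append(NetworkEdge(display[subj], t.predicate, display[obj],
                                     "outcome", t.pval))
    net.nodes = [NetworkNode(display[k], role)
                 for k, role in sorted(roles.items())]
    return overlap, net


@dataclass
class OverlapRank:
    term: str
    best_pval: float
    best_exposure_edge: Optional[NetworkEdge]
    best_outcome_edge: Optional[NetworkEdge]


def rank_overlaps(net: TriangulationNetwork) -> list[OverlapRank]:
    """Overlap terms ordered by min(best exposure p, best outcome p), ties by term."""
    inf = float("inf")
    ranks: list[OverlapRank] = []
    for term in net.overlap_terms:
        key = normalize_term(term)
        exp_edges = [e for e in net.edges
                     if e.side == "exposure" and normalize_term(e.target) == key]
        out_edges = [e for e in net.edges
                     if e.side == "outcome" and normalize_term(e.source) == key]
        best_exp = min(exp_edges, default=None,
                       key=lambda e: inf if e.pval is None else e.pval)
        best_out = min(out_edges, default=None,
                       key=lambda e: inf if e.pval is None else e.pval)
        candidates = [e.pval for e in (best_exp, best_out)
                      if e is not None and e.pval is not None]
        ranks.append(OverlapRank(term, min(candidates, default=inf),
                                 best_exp, best_out))
    ranks.sort(key=lambda r: (r.best_pval, normalize_term(r.term)))
    return ranks


# ---------------------------------------------------------------------------
# file I/O


def read_triples(path: str | Path, sep: str = "\t") -> list[TripleRecord]:
    """Read a triple table; counts are optional columns."""
    df = pd.read_csv(path, sep=sep)
    required = {"subject", "predicate", "object"}
    if not required <= set(df.columns):
        raise InputError(f"triple table needs columns {sorted(required)}")

    def opt_int(row, col):
        if col not in df.columns or pd.isna(row[col]):
            return None
        return int(row[col])

    out = []
    for _, row in df.iterrows():
        out.append(TripleRecord(
            subject=str(row["subject"]), predicate=str(row["predicate"]),
            object=str(row["object"]),
            local_count=opt_int(row, "local_count"),
            local_total=opt_int(row, "local_total"),
            global_count=opt_int(row, "global_count"),
            global_total=opt_int(row, "global_total"),
        ))
    return out


def write_triples(triples: list[TripleRecord], path: str | Path) -> None:
    rows = [{c: getattr(t, c) for c in TRIPLE_COLUMNS} for t in triples]
    pd.DataFrame(rows, columns=list(TRIPLE_COLUMNS)).to_csv(path, sep="\t", index=False)


def export_network(net: TriangulationNetwork, out_dir: str | Path,
                   prefix: str = "triangulation") -> dict[str, Path]:
    """Write node/edge TSVs plus a JSON graph document; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nodes_path = out_dir / f"{prefix}_nodes.tsv"
    edges_path = out_dir / f"{prefix}_edges.tsv"
    json_path = out_dir / f"{prefix}_network.json"
    pd.DataFrame([{"term": n.term, "role": n.role} for n in net.nodes]).to_csv(
        nodes_path, sep="\t", index=False)
    pd.DataFrame([{"source": e.source, "predicate": e.predicate,
                   "target": e.target, "side": e.side, "pval": e.pval}
                  for e in net.edges]).to_csv(edges_path, sep="\t", index=False)
    doc = {
        "nodes": [{"id": n.term, "role": n.role} for n in net.nodes],
        "links": [{"source": e.source, "target": e.target,
                   "predicate": e.predicate, "side": e.side, "pval": e.pval}
                  for e in net.edges],
    }
    with open(json_path, "w") as fh:
        json.dump(doc, fh, indent=1)
    return {"nodes": nodes_path, "edges": edges_path, "json": json_path}
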