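"""MID-similarity networks and pathway overlays.

Metabolites in the same pathway tend to inherit closely related labeling
patterns from their shared precursors, so similarity between corrected
MIDs can place unknown features next to annotated ones. This module
scores all node pairs of a MID table (per shared experiment/condition,
combined by mean or min), thresholds the result into an undirected
network, and optionally overlays annotated nodes onto a reference
pathway graph where each pathway metabolite's nearest unknown neighbors
can be ranked.

Two similarity metrics are offered: plain cosine, and a Euclidean score
1 - ||a-b|| / sqrt(2) normalized by the simplex diameter so it also
lands in [0, 1]. MIDs of different lengths are zero-padded before
comparison. No layout is computed; exports target Cytoscape-compatible
consumers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .io_tables import MIDTable, MidRecord, PathwayGraph

METRICS = ("cosine", "euclidean")
COMBINES = ("mean", "min")


@dataclass
class ContextNode:
    """A metabolite (annotated or unknown) with its per-condition MIDs."""

    node_id: str
    display_name: str
    annotated: bool
    records: list[MidRecord] = field(default_factory=list)

    @property
    def scopes(self) -> dict[tuple[str, str], MidRecord]:
        return {(r.experiment, r.condition): r for r in self.records}

    @property
    def mean_enrichment(self) -> float:
        return float(np.mean([r.enrichment for r in self.records]))

    @property
    def sd_enrichment(self) -> float:
        vals = [r.enrichment for r in self.records]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    @property
    def mean_quantification(self) -> float:
        return float(np.mean([r.quantification for r in self.records]))

    @property
    def sd_quantification(self) -> float:
        vals = [r.quantification for r in self.records]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    @property
    def representative_mid(self) -> np.ndarray:
        """Element-wise mean MID across records (zero-padded), renormalized."""
        length = max(r.length for r in self.records)
        mat = np.vstack([np.pad(r.fractions, (0, length - r.length))
                         for r in self.records])
        mean = mat.mean(axis=0)
        return mean / mean.sum()


@dataclass(frozen=True)
class SimilarityEdge:
    """Undirected similarity edge; endpoints stored lexicographically."""

    node_a: str
    node_b: str
    similarity: float
    metric: str
    condition_scope: str = "combined"

    def __post_init__(self) -> None:
        if self.node_a == self.node_b:
            raise ValidationError("self-edges are not allowed")
        if self.node_a > self.node_b:
            object.__setattr__(self, "node_a", self.node_b)
            object.__setattr__(self, "node_b", self.node_a)
        if not 0.0 <= self.similarity <= 1.0 + 1e-12:
            raise ValidationError(f"similarity {self.similarity} outside [0, 1]")


@dataclass
class ContextNetwork:
    """Nodes plus MID-similarity edges, exportable as Cytoscape JSON."""

    nodes: list[ContextNode]
    edges: list[SimilarityEdge]
    provenance: dict = field(default_factory=dict)

    def node(self, node_id: str) -> ContextNode:
        for n in self.nodes:
            if n.node_id == node_id:
                return n
        raise KeyError(f"unknown node '{node_id}'")

    def neighbors(self, node_id: str) -> list[tuple[str, float]]:
        out = []
        for e in self.edges:
            if e.node_a == node_id:
                out.append((e.node_b, e.similarity))
            elif e.node_b == node_id:
                out.append((e.node_a, e.similarity))
        return out

    def degree(self, node_id: str) -> int:
        return len(self.neighbors(node_id))

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"node_a": e.node_a, "node_b": e.node_b,
              "similarity": e.similarity, "metric": e.metric,
              "condition_scope": e.condition_scope} for e in self.edges],
            columns=["node_a", "node_b", "similarity", "metric",
                     "condition_scope"])


def mid_similarity(a, b, metric: str = "cosine") -> float:
    """Similarity in [0, 1] between two MID vectors (zero-padded to match)."""
    if metric not in METRICS:
        raise ConfigurationError(f"unknown metric '{metric}'; use one of {METRICS}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    length = max(len(a), len(b))
    a = np.pad(a, (0, length - len(a)))
    b = np.pad(b, (0, length - len(b)))
    if metric == "cosine":
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0 or nb == 0:
            raise ValidationError("cosine undefined for all-zero MID")
        return float(np.clip(a @ b / (na * nb), 0.0, 1.0))
    return float(np.clip(1.0 - np.linalg.norm(a - b) / np.sqrt(2.0), 0.0, 1.0))


def combined_similarity(node_a: ContextNode, node_b: ContextNode,
                        metric: str = "cosine",
                        combine: str = "mean") -> float | None:
    """Similarity across shared (experiment, condition) scopes; None if none.

    Scopes present in only one node are skipped; per-scope similarities
    are combined by mean (default) or min.
    """
    if combine not in COMBINES:
        raise ConfigurationError(f"unknown combine '{combine}'; use {COMBINES}")
    scopes_a = node_a.scopes
    scopes_b = node_b.scopes
    shared = sorted(set(scopes_a) & set(scopes_b))
    if not shared:
        return None
    sims = [mid_similarity(scopes_a[s].fractions, scopes_b[s].fractions, metric)
            for s in shared]
    return float(np.mean(sims)) if combine == "mean" else float(min(sims))


def build_network(mids: MIDTable, threshold: float = 0.9,
                  metric: str = "cosine", combine: str = "mean") -> ContextNetwork:
    """Score all unordered node pairs; keep edges at or above the threshold.

    Isolated nodes are retained; pairs sharing no (experiment, condition)
    scope produce no edge. Output is independent of node input order.
    """
    by_node = mids.by_node()
    if len(by_node) < 2:
        raise ConfigurationError("need at least 2 nodes to build a network")
    nodes = []
    for node_id in sorted(by_node):
        records = by_node[node_id]
        display = next((r.display_name for r in records if r.display_name), "")
        annotated = any(r.annotated for r in records)
        nodes.append(ContextNode(node_id, display, annotated, records))
    edges = []
    for i, na in enumerate(nodes):
        for nb in nodes[i + 1:]:
            sim = combined_similarity(na, nb, metric=metric, combine=combine)
            if sim is not None and sim >= threshold:
                edges.append(SimilarityEdge(na.node_id, nb.node_id, sim, metric))
    return ContextNetwork(nodes, edges, provenance={
        "threshold": threshold, "metric": metric, "combine": combine})


def filter_network(net: ContextNetwork, min_similarity: float = 0.0,
                   min_degree: int = 0,
                   max_degree: float = float("inf")) -> ContextNetwork:
    """Drop weak edges, then nodes with out-of-range degree (single pass).

    Degrees are evaluated once, after the edge drop; no cascading
    recomputation, so the result is deterministic and order-free.
    """
    edges = [e for e in net.edges if e.similarity >= min_similarity]
    degree: dict[str, int] = {n.node_id: 0 for n in net.nodes}
    for e in edges:
        degree[e.node_a] += 1
        degree[e.node_b] += 1
    keep = {nid for nid, d in degree.items() if min_degree <= d <= max_degree}
    nodes = [n for n in net.nodes if n.node_id in keep]
    edges = [e for e in edges if e.node_a in keep and e.node_b in keep]
    prov = dict(net.provenance)
    prov.update({"min_similarity": min_similarity, "min_degree": min_degree,
                 "max_degree": max_degree})
    return ContextNetwork(nodes, edges, provenance=prov)


@dataclass
class PathwayOverlay:
    """Pathway nodes matched (or not) to context nodes, with a match table."""

    pathway: PathwayGraph
    matches: dict[str, str]          # pathway node id -> context node id
    unmatched: list[str]             # pathway node ids without counterpart
    match_table: pd.DataFrame


def map_to_pathway(net: ContextNetwork, pathway: PathwayGraph,
                   annotations: dict[str, str] | None = None,
                   case_insensitive: bool = False) -> PathwayOverlay:
    """Match pathway nodes to context nodes by exact identifier equality.

    A context node's identifiers are its node_id, its display name and an
    optional identifier from ``annotations`` (node_id -> external id,
    e.g. KEGG). Duplicate matching identifiers among pathway nodes are an
    ambiguity error.
    """
    annotations = annotations or {}

    def norm(s: str) -> str:
        return s.lower() if case_insensitive else s

    keys: dict[str, str] = {}
    for pid in pathway.node_ids:
        key = pathway.match_key(pid)
        if not key:
            continue
        key = norm(key)
        if key in keys:
            raise ValidationError(
                f"duplicate pathway identifier '{key}' on nodes "
                f"'{keys[key]}' and '{pid}'"
            )
        keys[key] = pid
    matches: dict[str, str] = {}
    rows = []
    for node in net.nodes:
        idents = {norm(node.node_id)}
        if node.display_name:
            idents.add(norm(node.display_name))
        if node.node_id in annotations:
            idents.add(norm(annotations[node.node_id]))
        for ident in sorted(idents):
            pid = keys.get(ident)
            if pid is not None and pid not in matches:
                matches[pid] = node.node_id
                rows.append({"pathway_node": pid, "identifier": ident,
                             "context_node": node.node_id,
                             "enrichment": node.mean_enrichment,
                             "quantification": node.mean_quantification})
    unmatched = [pid for pid in pathway.node_ids if pid not in matches]
    table = pd.DataFrame(rows, columns=["pathway_node", "identifier",
                                        "context_node", "enrichment",
                                        "quantification"])
    return PathwayOverlay(pathway, matches, unmatched, table)


def nearest_unknown_neighbors(net: ContextNetwork, node_id: str,
                              k: int = 5) -> list[tuple[str, float]]:
    """Top-k unannotated neighbors by similarity; ties broken by node id."""
    node = net.node(node_id)  # raises KeyError for unknown ids
    assert node is not None
    unknown = [(nid, sim) for nid, sim in net.neighbors(node_id)
               if not net.node(nid).annotated]
    unknown.sort(key=lambda t: (-t[1], t[0]))
    return unknown[:k]


def condition_stats(mids: MIDTable) -> pd.DataFrame:
    """Per-node mean/sd of enrichment and quantification across records."""
    rows = []
    for node_id, records in mids.by_node().items():
        enr = np.array([r.enrichment for r in records])
        quant = np.array([r.quantification for r in records])
        rows.append({
            "node_id": node_id,
            "n_records": len(records),
            "enrichment_mean": float(enr.mean()),
            "enrichment_sd": float(enr.std(ddof=1)) if len(enr) > 1 else 0.0,
            "quantification_mean": float(quant.mean()),
            "quantification_sd": float(quant.std(ddof=1)) if len(quant) > 1 else 0.0,
        })
    return pd.DataFrame(rows, columns=["node_id", "n_records", "enrichment_mean",
                                       "enrichment_sd", "quantification_mean",
                                       "quantification_sd"])
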