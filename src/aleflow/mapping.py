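"""Map consolidated mutations onto features at every annotation scale and
build the weighted convergence DAG (the data structure behind Sankey-style
mutation-flow diagrams).

Mapping rules
-------------
* genomic_feature scale — a mutation maps to every gene/regulatory feature
  whose interval shares a nucleotide with the mutation's half-open interval
  ``[position, position + span)``; if none overlaps, it maps to exactly one
  derived intergenic region (named by its flanking genes).
* gene_and_intergenic scale — genes only; falling back to the containing
  intergenic region when no gene overlaps.
* TU scale — genes map to the TUs listing them; regulatory features to the
  TUs listing them; intergenic hits to TUs by coordinate overlap (possibly
  none, a dead end).
* operon scale — TUs map to their operons.
* regulon/pathway/COG scales — TUs map to the functional annotations of
  every gene they host, which is what lets non-coding hits reach gene-based
  functional annotations.

A mutation reaching one broad feature via two children (e.g. a gene and a
TFBS inside it, same TU) is counted once per scale in the observed
statistics, while the DAG keeps one flow per child edge — preserving the
flow-diagram semantics without double-counting a single mutation event in
significance testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import pandas as pd
from intervaltree import IntervalTree

from . import _intervals as iv
from .annotations import SCALES, AnnotationFramework
from .errors import DagStructureError
from .mutations import ConsolidatedMutation

MutationKey = Tuple[str, str, int, int, str]

#: DAG scales, in flow order (gene_and_intergenic is an enrichment-only
#: re-partition of the genomic_feature scale and carries no DAG nodes).
DAG_SCALES = ("genomic_feature", "TU", "operon", "regulon", "pathway", "COG")

MUTATION_TYPE_SCALE = "mutation_type"


@dataclass(frozen=True)
class MutatedFeatureInstance:
    """One (mutation, feature, scale) incidence."""

    mutation_key: MutationKey
    feature_id: str
    annotation_type: str


class _FeatureIndex:
    """Interval trees over the framework, built once per framework."""

    def __init__(self, fw: AnnotationFramework):
        self.annotated = IntervalTree()
        self.genes = IntervalTree()
        self.intergenic = IntervalTree()
        self.tu_tree = IntervalTree()
        for f in fw.features.values():
            if f.feature_type == "intergenic":
                self.intergenic[f.start : f.end] = f.id
            else:
                self.annotated[f.start : f.end] = f.id
                if f.feature_type == "gene":
                    self.genes[f.start : f.end] = f.id
        for tu in fw.tus.values():
            self.tu_tree[tu.start : tu.end] = tu.id


def _index(fw: AnnotationFramework) -> _FeatureIndex:
    idx = getattr(fw, "_aleflow_index", None)
    if idx is None:
        idx = _FeatureIndex(fw)
        fw.__dict__["_aleflow_index"] = idx
    return idx


def map_mutation(
    mutation: ConsolidatedMutation, framework: AnnotationFramework
) -> List[MutatedFeatureInstance]:
    """Genomic_feature-scale instances for one mutation (see module rules)."""
    idx = _index(framework)
    s, e = mutation.interval
    hits = sorted(h.data for h in idx.annotated[s:e])
    if not hits:
        hits = sorted(h.data for h in idx.intergenic[s:e])[:1]
    return [
        MutatedFeatureInstance(mutation.key, fid, "genomic_feature") for fid in hits
    ]


def map_gene_and_intergenic(
    mutation: ConsolidatedMutation, framework: AnnotationFramework
) -> List[MutatedFeatureInstance]:
    idx = _index(framework)
    s, e = mutation.interval
    hits = sorted(h.data for h in idx.genes[s:e])
    if not hits:
        hits = sorted(h.data for h in idx.intergenic[s:e])[:1]
    return [
        MutatedFeatureInstance(mutation.key, fid, "gene_and_intergenic")
        for fid in hits
    ]


@dataclass
class MutationPaths:
    """Per-mutation features per scale, plus the child→parent flow edges."""

    key: MutationKey
    mutation_type: str
    features: Dict[str, Set[str]] = field(default_factory=dict)
    edges: Set[Tuple[Tuple[str, str], Tuple[str, str]]] = field(default_factory=set)


def trace_mutation(
    mutation: ConsolidatedMutation, fw: AnnotationFramework
) -> MutationPaths:
    """Propagate one mutation across all scales, recording flow edges."""
    idx = _index(fw)
    paths = MutationPaths(key=mutation.key, mutation_type=mutation.mutation_type)
    gf = {i.feature_id for i in map_mutation(mutation, fw)}
    paths.features["genomic_feature"] = gf
    paths.features["gene_and_intergenic"] = {
        i.feature_id for i in map_gene_and_intergenic(mutation, fw)
    }

    s, e = mutation.interval
    tus: Set[str] = set()
    for fid in gf:
        f = fw.features[fid]
        if f.feature_type == "gene":
            fid_tus = {tu.id for tu in fw.gene_tus(fid)}
        elif f.feature_type == "intergenic":
            fid_tus = {h.data for h in idx.tu_tree[s:e]}
        else:
            fid_tus = {tu.id for tu in fw.regulatory_tus(fid)}
        for tid in fid_tus:
            paths.edges.add((("genomic_feature", fid), ("TU", tid)))
        tus |= fid_tus
    paths.features["TU"] = tus

    operons: Set[str] = set()
    funct: Dict[str, Set[str]] = {"regulon": set(), "pathway": set(), "COG": set()}
    for tid in tus:
        for op in fw.tu_operons(tid):
            paths.edges.add((("TU", tid), ("operon", op.id)))
            operons.add(op.id)
        for gid in fw.tus[tid].gene_ids:
            for kind in ("regulon", "pathway", "COG"):
                for fa in fw.gene_functional(gid, kind):
                    # pathway/COG lengths exclude non-member gene positions
                    # inside their TUs; the mapping must honour the same
                    # footprint or the length-proportional null is miscalibrated
                    if kind != "regulon" and not _in_footprint(
                        fw, kind, fa.id, s, e
                    ):
                        continue
                    paths.edges.add((("TU", tid), (kind, fa.id)))
                    funct[kind].add(fa.id)
    paths.features["operon"] = operons
    paths.features.update(funct)
    return paths


def _in_footprint(
    fw: AnnotationFramework, kind: str, fid: str, s: int, e: int
) -> bool:
    cache = fw.__dict__.setdefault("_aleflow_footprints", {})
    ivs = cache.get((kind, fid))
    if ivs is None:
        ivs = fw.feature_positions(kind, fid)
        cache[(kind, fid)] = ivs
    return any(iv.overlaps(s, e, fs, fe) for fs, fe in ivs)


def propagate_to_scales(
    instances: Iterable[MutatedFeatureInstance],
    framework: AnnotationFramework,
    mutations: Sequence[ConsolidatedMutation],
) -> List[MutatedFeatureInstance]:
    """All-scale instances for a mutation set (each pair once per scale).

    ``instances`` are the genomic_feature-scale incidences (as produced by
    :func:`map_mutation`); they are re-derived internally from ``mutations``
    so callers may pass ``[]``.
    """
    out: List[MutatedFeatureInstance] = []
    for m in mutations:
        paths = trace_mutation(m, framework)
        for scale in SCALES:
            for fid in sorted(paths.features.get(scale, ())):
                out.append(MutatedFeatureInstance(m.key, fid, scale))
    return out


def instances_to_frame(instances: Iterable[MutatedFeatureInstance]) -> pd.DataFrame:
    rows = [
        (
            i.mutation_key[0],
            i.mutation_key[1],
            i.mutation_key[2],
            i.mutation_key[3],
            i.mutation_key[4],
            i.annotation_type,
            i.feature_id,
        )
        for i in instances
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "experiment_id",
            "ale_id",
            "position",
            "span",
            "mutation_type",
            "scale",
            "feature_id",
        ],
    )


# ---------------------------------------------------------------------------
# convergence DAG


@dataclass
class ConvergenceDAG:
    """Weighted DAG of mutated features, small scales flowing into broad ones.

    Nodes are ``(scale, feature_id)`` pairs plus ``(mutation_type, <type>)``
    source nodes. Edge weight = number of mutations flowing along the link;
    node weight = sum of incoming edge weights (for source nodes, the count
    of mutations of that type).
    """

    graph: nx.DiGraph
    mutation_paths: List[MutationPaths] = field(default_factory=list)

    def node_weight(self, node: Tuple[str, str]) -> int:
        return self.graph.nodes[node]["weight"]


def build_convergence_dag(
    mutations: Sequence[ConsolidatedMutation], framework: AnnotationFramework
) -> ConvergenceDAG:
    """Build the convergence DAG for one experiment's consolidated mutations."""
    g = nx.DiGraph()
    all_paths = []
    for m in mutations:
        paths = trace_mutation(m, framework)
        all_paths.append(paths)
        src = (MUTATION_TYPE_SCALE, m.mutation_type)
        if src not in g:
            g.add_node(src, scale=MUTATION_TYPE_SCALE, weight=0)
        g.nodes[src]["weight"] += len(paths.features["genomic_feature"])
        edges = set(paths.edges)
        for fid in paths.features["genomic_feature"]:
            edges.add((src, ("genomic_feature", fid)))
        for u, v in edges:
            for node in (u, v):
                if node not in g:
                    g.add_node(node, scale=node[0], weight=0)
            if g.has_edge(u, v):
                g[u][v]["weight"] += 1
            else:
                g.add_edge(u, v, weight=1)
    # node weight = sum of incoming edge weights (sources keep instance counts)
    for node in g.nodes:
        if node[0] != MUTATION_TYPE_SCALE:
            g.nodes[node]["weight"] = sum(
                d["weight"] for _, _, d in g.in_edges(node, data=True)
            )
    if not nx.is_directed_acyclic_graph(g):
        raise DagStructureError("convergence graph contains a cycle")
    return ConvergenceDAG(graph=g, mutation_paths=all_paths)


def _contracted_edges(dag: ConvergenceDAG) -> Dict[Tuple, int]:
    """Flows with TU nodes contracted, recomputed per mutation path."""
    weights: Dict[Tuple, int] = {}
    for paths in dag.mutation_paths:
        into_tu: Dict[str, Set[Tuple[str, str]]] = {}
        out_of_tu: Dict[str, Set[Tuple[str, str]]] = {}
        plain = set()
        for u, v in paths.edges:
            if v[0] == "TU":
                into_tu.setdefault(v[1], set()).add(u)
            elif u[0] == "TU":
                out_of_tu.setdefault(u[1], set()).add(v)
            else:
                plain.add((u, v))
        for tid, children in into_tu.items():
            for child in children:
                for parent in out_of_tu.get(tid, ()):  # dead-end TUs drop out
                    plain.add((child, parent))
        src = (MUTATION_TYPE_SCALE, paths.mutation_type)
        for fid in paths.features["genomic_feature"]:
            plain.add((src, ("genomic_feature", fid)))
        for edge in plain:
            weights[edge] = weights.get(edge, 0) + 1
    return weights


def export_flow_table(
    dag: ConvergenceDAG,
    significant: Optional[Mapping[str, Set[str]]] = None,
    include_tu: bool = False,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Serialize the DAG as (flows, nodes) tables.

    ``significant`` maps scale → significant feature ids; those node labels
    get an asterisk (``*``) prefix, the flow-diagram convention for features
    significantly enriched by mutations. By default TU nodes are contracted
    out (they carry mostly redundant convergence relative to operons); pass
    ``include_tu=True`` for a lossless export.
    """
    significant = significant or {}
    if include_tu:
        edge_weights = {
            (u, v): d["weight"] for u, v, d in dag.graph.edges(data=True)
        }
    else:
        edge_weights = _contracted_edges(dag)

    node_weights: Dict[Tuple[str, str], int] = {}
    for (u, v), w in edge_weights.items():
        node_weights.setdefault(u, 0)
        node_weights[v] = node_weights.get(v, 0) + w
    for node in node_weights:
        if node[0] == MUTATION_TYPE_SCALE and node in dag.graph:
            node_weights[node] = dag.graph.nodes[node]["weight"]

    flows = pd.DataFrame(
        sorted(
            (f"{u[0]}:{u[1]}", f"{v[0]}:{v[1]}", w)
            for (u, v), w in edge_weights.items()
        ),
        columns=["source", "target", "weight"],
    )
    node_rows = []
    for (scale, fid), w in sorted(node_weights.items()):
        sig = fid in significant.get(scale, set())
        label = f"*{fid}" if sig else fid
        node_rows.append((f"{scale}:{fid}", scale, w, int(sig), label))
    nodes = pd.DataFrame(
        node_rows, columns=["id", "scale", "weight", "significant", "label"]
    )
    return flows, nodes


def import_flow_table(flows: pd.DataFrame, nodes: pd.DataFrame) -> ConvergenceDAG:
    """Rebuild a DAG (graph topology and weights) from exported tables."""
    g = nx.DiGraph()
    for row in nodes.itertuples(index=False):
        scale, fid = row.id.split(":", 1)
        g.add_node((scale, fid), scale=scale, weight=int(row.weight))
    for row in flows.itertuples(index=False):
        us, uf = row.source.split(":", 1)
        vs, vf = row.target.split(":", 1)
        g.add_edge((us, uf), (vs, vf), weight=int(row.weight))
    if not nx.is_directed_acyclic_graph(g):
        raise DagStructureError("imported flow table contains a cycle")
    return ConvergenceDAG(graph=g)


def dag_to_json(dag: ConvergenceDAG) -> dict:
    """JSON-serializable view of the full DAG (nodes, edges, weights)."""
    return {
        "nodes": [
            {"scale": n[0], "id": n[1], "weight": d["weight"]}
            for n, d in sorted(dag.graph.nodes(data=True))
        ],
        "edges": [
            {
                "source": {"scale": u[0], "id": u[1]},
                "target": {"scale": v[0], "id": v[1]},
                "weight": d["weight"],
            }
            for u, v, d in sorted(dag.graph.edges(data=True))
        ],
    }
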