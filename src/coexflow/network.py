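"""Pearson/HRR co-expression network construction and HCCA clustering.

The network is built from pairwise Pearson correlations of (by default)
log2(x + 1)-transformed expression.  Edges are filtered by the highest
reciprocal rank (HRR): for transcripts i and j, rank_i(j) is j's position in
i's correlation-sorted neighbor list (best = 1) and
HRR(i, j) = max(rank_i(j), rank_j(i)); only mutually top-ranked pairs get
small HRR.  Two thresholds are conventionally used: a looser one (HRR <= 30)
defining the candidate graph handed to clustering, and a strict one
(HRR <= 3) for reported/visualized edges.

Clustering uses a heuristic cluster chiseling algorithm (HCCA): every node
seeds a candidate set (its vicinity within a fixed number of hops) which is
"chiseled" by repeatedly removing nodes with more edges leaving the set than
staying inside; surviving candidates within size bounds are scored and
accepted greedily without overlap, and the procedure repeats on the residual
graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .abundance import ExpressionMatrix

logger = logging.getLogger(__name__)

NODE_CLASSES = ("DET_up_A", "DET_up_B", "UET_A", "UET_B", "neighbor", "other")


def pearson_matrix(
    matrix, transform: Optional[str] = "log2p1"
) -> Tuple[pd.DataFrame, List[str]]:
    """Pairwise Pearson correlations between transcripts.

    ``transform`` is ``"log2p1"`` (log2(x + 1), the default, which tames
    heavy-tailed FPKM) or ``None`` for the raw scale.  Constant rows have
    undefined correlations; these are recorded as 0 and the affected
    transcript ids returned as flags.  Requires at least 3 samples.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    if values.shape[1] < 3:
        raise ValueError("pearson_matrix requires at least 3 samples")
    x = values.to_numpy(dtype=float)
    if transform == "log2p1":
        x = np.log2(x + 1.0)
    elif transform is not None:
        raise ValueError(f"unknown transform {transform!r}")
    sd = x.std(axis=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    flags = list(values.index[constant])
    if flags:
        logger.warning("%d constant transcripts: correlations set to 0", len(flags))
    return pd.DataFrame(corr, index=values.index, columns=values.index), flags


def hrr_edges(correlations: pd.DataFrame, hrr_max: int = 30) -> pd.DataFrame:
    """Highest-reciprocal-rank edge filter.

    Within each transcript's neighbor list, partners are ranked by
    descending correlation (rank 1 = best), ties broken by position in the
    index (lexicographic transcript order when the index is sorted).  An
    edge (i, j) is kept when max(rank_i(j), rank_j(i)) <= ``hrr_max``.
    Returns a DataFrame with columns i, j, r, hrr; each unordered pair once.
    """
    ids = correlations.index
    n = len(ids)
    m = correlations.to_numpy(dtype=float).copy()
    np.fill_diagonal(m, -np.inf)
    # stable argsort on -r keeps index order among ties
    order = np.argsort(-m, axis=1, kind="stable")
    ranks = np.empty_like(order)
    row_idx = np.arange(n)[:, None]
    ranks[row_idx, order] = np.arange(1, n + 1)[None, :]
    hrr = np.maximum(ranks, ranks.T)
    iu, ju = np.triu_indices(n, k=1)
    keep = hrr[iu, ju] <= hrr_max
    return pd.DataFrame(
        {
            "i": ids[iu[keep]],
            "j": ids[ju[keep]],
            "r": m[iu[keep], ju[keep]],
            "hrr": hrr[iu[keep], ju[keep]].astype(int),
        }
    )


def edges_to_graph(edges: pd.DataFrame) -> nx.Graph:
    g = nx.Graph()
    for i, j, r, h in edges[["i", "j", "r", "hrr"]].itertuples(index=False):
        g.add_edge(i, j, r=float(r), hrr=int(h))
    return g


@dataclass
class ClusterSet:
    """Disjoint HCCA clusters plus the unassigned remainder."""

    clusters: Dict[int, Set[str]]
    unassigned: Set[str]
    summary: pd.DataFrame  # cluster id -> size, internal_edges, density

    def membership(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for cid, members in self.clusters.items():
            for node in members:
                out[node] = cid
        return out

    def check_invariants(self, min_size: int, max_size: int) -> None:
        seen: Set[str] = set()
        for members in self.clusters.values():
            assert min_size <= len(members) <= max_size, "cluster size out of bounds"
            assert not (seen & members), "clusters must be disjoint"
            seen |= members
        assert not (seen & self.unassigned), "unassigned overlaps clusters"


def _chisel(graph: nx.Graph, candidate: Set[str]) -> Set[str]:
    """Remove nodes better connected outside the candidate than inside."""
    cand = set(candidate)
    while cand:
        doomed = []
        for node in cand:
            inside = sum(1 for nb in graph[node] if nb in cand)
            outside = graph.degree(node) - inside
            if inside < outside:
                doomed.append(node)
        if not doomed:
            break
        cand.difference_update(doomed)
    return cand


def hcca(
    network: nx.Graph,
    step_size: int = 3,
    min_size: int = 40,
    max_size: int = 200,
) -> ClusterSet:
    """Heuristic cluster chiseling on an HRR network.

    For every seed node the candidate set is its ``step_size``-hop vicinity,
    chiseled until stable.  Surviving candidates within [min_size, max_size]
    are scored by internal edge density (internal edges / C(size, 2)) and
    accepted greedily without overlap (ties by the smallest member id);
    the procedure repeats on the residual graph until no candidate reaches
    ``min_size``.  Deterministic for a fixed input.
    """
    if min_size < 1 or max_size < min_size:
        raise ValueError("invalid size bounds")
    residual = network.copy()
    clusters: Dict[int, Set[str]] = {}
    rows = []
    cid = 0
    while True:
        candidates: Dict[frozenset, Set[str]] = {}
        for seed in residual.nodes:
            vicinity = set(
                nx.single_source_shortest_path_length(residual, seed, cutoff=step_size)
            )
            cand = _chisel(residual, vicinity)
            if min_size <= len(cand) <= max_size:
                candidates.setdefault(frozenset(cand), set(cand))
        if not candidates:
            break
        scored = []
        for cand in candidates.values():
            internal = residual.subgraph(cand).number_of_edges()
            size = len(cand)
            density = internal / (size * (size - 1) / 2)
            scored.append((-density, min(cand), cand, internal))
        scored.sort(key=lambda t: (t[0], t[1]))
        accepted_any = False
        taken: Set[str] = set()
        for neg_density, _, cand, internal in scored:
            if cand & taken:
                continue
            clusters[cid] = cand
            rows.append(
                {
                    "cluster": cid,
                    "size": len(cand),
                    "internal_edges": internal,
                    "density": -neg_density,
                }
            )
            cid += 1
            taken |= cand
            accepted_any = True
        if not accepted_any:
            break
        residual.remove_nodes_from(taken)
    unassigned = set(residual.nodes)
    summary = pd.DataFrame(rows, columns=["cluster", "size", "internal_edges", "density"])
    result = ClusterSet(clusters=clusters, unassigned=unassigned, summary=summary)
    result.check_invariants(min_size, max_size)
    return result


def det_neighborhood(
    network: nx.Graph,
    det_directions: Dict[str, str],
    uet_sets: Optional[Dict[str, Set[str]]] = None,
    depth: int = 1,
) -> nx.Graph:
    """Subnetwork of DETs and their neighbors within ``depth`` hops.

    ``det_directions`` maps DET transcript id -> over-expressed population
    label ("A"/"B" or population names); ``uet_sets`` maps "A"/"B" to UET id
    sets.  Node classes are assigned with precedence DET > UET > neighbor,
    so at depth 1 only UETs directly connected to a DET appear.  DET ids
    absent from the network are skipped with a warning.
    """
    uet_sets = uet_sets or {}
    labels = sorted(set(det_directions.values()))
    a_labels = {"A", "DET_up_A"} | ({labels[0]} if len(labels) == 2 else set())
    keep: Set[str] = set()
    for det in det_directions:
        if det not in network:
            logger.warning("DET %r not present in the network; skipped", det)
            continue
        keep.add(det)
        keep |= set(
            nx.single_source_shortest_path_length(network, det, cutoff=depth)
        )
    # deterministic node/edge order regardless of set iteration order
    sub = nx.Graph()
    sub.add_nodes_from(sorted(keep))
    for u, v, data in network.edges(data=True):
        if u in keep and v in keep:
            sub.add_edge(u, v, **data)
    uet_a = uet_sets.get("A", set())
    uet_b = uet_sets.get("B", set())
    for node in sub.nodes:
        if node in det_directions:
            label = det_directions[node]
            cls = "DET_up_A" if label in a_labels else "DET_up_B"
        elif node in uet_a:
            cls = "UET_A"
        elif node in uet_b:
            cls = "UET_B"
        else:
            cls = "neighbor"
        sub.nodes[node]["node_class"] = cls
    return sub
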