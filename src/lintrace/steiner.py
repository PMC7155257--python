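"""Maximum-parsimony inference as a Steiner-tree problem.

The observed character strings are embedded in a *potential graph*: a DAG over
cells plus inferred ancestral strings, built by repeatedly joining pairs of
current source nodes through their latest common ancestor (LCA) whenever their
edit distance is at most a threshold d.  The minimum Steiner arborescence of
that graph, rooted at the unedited (or clade-ancestral) string and spanning
the observed cells, is a maximum-parsimony tree over the represented states.
The Steiner problem is solved with an integer linear program in network-flow
form (HiGHS backend); an exact Dreyfus-Wagner dynamic program over terminal
subsets serves as an independent oracle for small instances.

Missing data: a MISSING entry behaves as a wildcard — it matches any state in
LCA computation and contributes nothing to edit distance.  This approximates
exhaustive imputation over all possible indels, which is exponential.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse import lil_matrix

from .core import MISSING, CharacterMatrix, LineageTree

logger = logging.getLogger(__name__)

#: Paper-scale defaults; tests and the benchmark harness pass smaller values.
DEFAULT_TIME_LIMIT = 12_600.0
DEFAULT_MAX_NEIGHBORHOOD = 10_000


# ---------------------------------------------------------------------------
# string primitives
# ---------------------------------------------------------------------------

def lca_string(a, b) -> tuple:
    """Latest common ancestor of two character strings.

    Per character: equal non-missing states keep the state; disagreement
    yields the unmutated state 0; MISSING defers to the other string
    (wildcard); MISSING in both stays MISSING.
    """
    if len(a) != len(b):
        raise ValueError("character strings must have equal length")
    out = []
    for x, y in zip(a, b):
        if x == y:
            out.append(x)
        elif x == MISSING:
            out.append(y)
        elif y == MISSING:
            out.append(x)
        else:
            out.append(0)
    return tuple(out)


def edit_distance(a, b) -> int:
    """Number of characters holding different non-missing states."""
    if len(a) != len(b):
        raise ValueError("character strings must have equal length")
    return sum(1 for x, y in zip(a, b)
               if x != y and x != MISSING and y != MISSING)


def _pairwise_distances(arr: np.ndarray) -> np.ndarray:
    """Dense pairwise edit-distance matrix for rows of ``arr`` (chunked)."""
    k = arr.shape[0]
    obs = arr != MISSING
    out = np.zeros((k, k), dtype=np.int32)
    chunk = max(1, 2_000_000 // max(1, k * arr.shape[1]))
    for start in range(0, k, chunk):
        sl = slice(start, min(k, start + chunk))
        diff = (arr[sl, None, :] != arr[None, :, :]) \
            & obs[sl, None, :] & obs[None, :, :]
        out[sl] = diff.sum(axis=2)
    return out


# ---------------------------------------------------------------------------
# potential graph
# ---------------------------------------------------------------------------

@dataclass
class PotentialGraph:
    """DAG over observed cells and inferred ancestors.

    Nodes are state tuples; edge weights are parent-to-child edit distances.
    ``targets`` are the (deduplicated) observed cell strings and every target
    is reachable from ``root``.
    """

    graph: nx.DiGraph
    root: tuple
    targets: list[tuple]
    threshold: int
    cell_map: dict[tuple, list[str]] = field(default_factory=dict)

    @property
    def num_nodes(self) -> int:
        return self.graph.number_of_nodes()


def _strings_from_matrix(matrix: CharacterMatrix):
    cell_map: dict[tuple, list[str]] = {}
    for cid, row in zip(matrix.cell_ids, matrix.values):
        cell_map.setdefault(tuple(int(v) for v in row), []).append(cid)
    return list(cell_map), cell_map


def _lca_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise LCA of paired state arrays (wildcard MISSING)."""
    out = np.where(A == B, A, 0)
    out = np.where((A == MISSING) & (B != MISSING), B, out)
    out = np.where((B == MISSING) & (A != MISSING), A, out)
    out = np.where((A == MISSING) & (B == MISSING), MISSING, out)
    return out


def build_potential_graph(matrix: CharacterMatrix, d: int,
                          root_state: tuple | None = None,
                          max_nodes: int | None = None,
                          max_rounds: int = 100) -> PotentialGraph | None:
    """Build the potential graph at LCA threshold ``d``.

    Layer by layer: every pair of the current layer's source nodes at edit
    distance strictly below ``d`` is joined through its LCA (edges weighted by
    edit distance); the next layer consists of the new LCAs plus any source
    left unpartnered.  When no pair qualifies, the remaining sources are
    connected to the designated root (all-zero unless ``root_state`` is
    given).  Returns None as soon as the node count exceeds ``max_nodes``.
    """
    strings, cell_map = _strings_from_matrix(matrix)
    root = tuple(root_state) if root_state is not None \
        else tuple([0] * matrix.m)
    g = nx.DiGraph()
    g.add_nodes_from(strings)
    targets = list(strings)

    layer = list(strings)
    for _ in range(max_rounds):
        if len(layer) <= 1 or d <= 0:
            break
        arr = np.array(layer, dtype=np.int64)
        dist = _pairwise_distances(arr)
        ii, jj = np.nonzero(np.triu(dist < d, k=1))
        if ii.size == 0:
            break
        nxt: set = set()
        partnered: set = set()
        chunk = 50_000  # bound LCA scratch memory near the explosion regime
        for start in range(0, ii.size, chunk):
            si = ii[start:start + chunk]
            sj = jj[start:start + chunk]
            ancestors = _lca_rows(arr[si], arr[sj])
            for r in range(si.size):
                a, b = layer[int(si[r])], layer[int(sj[r])]
                anc = tuple(int(x) for x in ancestors[r])
                partnered.add(a)
                partnered.add(b)
                for child in (a, b):
                    if anc != child and not g.has_edge(anc, child):
                        g.add_edge(anc, child,
                                   weight=edit_distance(anc, child))
                nxt.add(anc)
            if max_nodes is not None and g.number_of_nodes() > max_nodes:
                return None
        nxt |= {s for s in layer if s not in partnered
                and g.in_degree(s) == 0}
        if nxt == set(layer):
            break
        layer = sorted(nxt)

    sources = [v for v in g if g.in_degree(v) == 0 and v != root]
    if sources or root not in g:
        g.add_node(root)
        for s in sources:
            g.add_edge(root, s, weight=edit_distance(root, s))
    if max_nodes is not None and g.number_of_nodes() > max_nodes:
        return None
    return PotentialGraph(g, root, targets, d, cell_map)


def optimize_neighborhood(matrix: CharacterMatrix,
                          max_neighborhood_size: int = DEFAULT_MAX_NEIGHBORHOOD,
                          root_state: tuple | None = None
                          ) -> tuple[PotentialGraph, int]:
    """Largest LCA threshold d whose potential graph fits the node cap.

    Increases d from 1, rebuilding the graph each time, and returns the last
    graph within ``max_neighborhood_size`` nodes together with its d.  If even
    d=1 exceeds the cap, the d=0 graph (cells plus root star) is returned with
    a warning.
    """
    best: PotentialGraph | None = None
    best_d = 0
    prev_size: tuple[int, int] | None = None
    for d in range(1, matrix.m + 1):
        pg = build_potential_graph(matrix, d, root_state,
                                   max_nodes=max_neighborhood_size)
        if pg is None:
            break
        best, best_d = pg, d
        size = (pg.graph.number_of_nodes(), pg.graph.number_of_edges())
        if size == prev_size:
            break  # saturated: larger d adds nothing
        prev_size = size
    if best is None:
        warnings.warn("neighborhood cap exceeded even at d=1; "
                      "returning the trivial star graph")
        best = build_potential_graph(matrix, 0, root_state)
        best_d = 0
    logger.info("potential graph: d=%d, %d nodes", best_d, best.num_nodes)
    return best, best_d


# ---------------------------------------------------------------------------
# Steiner ILP (network-flow formulation, HiGHS backend)
# ---------------------------------------------------------------------------

@dataclass
class SteinerSolution:
    tree: LineageTree
    objective: float
    status: str
    gap: float | None
    threshold: int | None = None


def _steiner_milp(g: nx.DiGraph, root, targets,
                  time_limit: float | None, gap_tolerance: float | None):
    """Solve the flow ILP; returns (selected edges, objective, status, gap).

    Variables: integer flow f_uv in {0..|S|} and binary selection b_uv per
    edge.  Constraints: flow conservation at non-target internal nodes, |S|
    units leaving the root, one unit absorbed per target (net: in minus out,
    so flow may route through a target that is ancestral to other cells), and
    b_uv >= f_uv/|S| coupling selection to use.  Objective: sum of
    w(u,v) * b_uv.
    """
    edges = list(g.edges)
    nE = len(edges)
    S = [t for t in targets if t != root]
    nS = len(S)
    if nE == 0 or nS == 0:
        return [], 0.0, "optimal", 0.0
    eidx = {e: i for i, e in enumerate(edges)}
    target_set = set(S)
    # variable vector: [f_0..f_{E-1}, b_0..b_{E-1}]
    c = np.zeros(2 * nE)
    for e, i in eidx.items():
        c[nE + i] = g.edges[e]["weight"]

    rows: list = []
    lb: list[float] = []
    ub: list[float] = []
    A = lil_matrix((0, 2 * nE))

    def add_row(coeffs: dict[int, float], lo: float, hi: float):
        nonlocal A
        A.resize((A.shape[0] + 1, 2 * nE))
        for j, v in coeffs.items():
            A[A.shape[0] - 1, j] = v
        lb.append(lo)
        ub.append(hi)

    for v in g.nodes:
        if v == root or v in target_set:
            continue
        coeffs: dict[int, float] = {}
        for e in g.in_edges(v):
            coeffs[eidx[e]] = coeffs.get(eidx[e], 0) + 1.0
        for e in g.out_edges(v):
            coeffs[eidx[e]] = coeffs.get(eidx[e], 0) - 1.0
        if coeffs:
            add_row(coeffs, 0.0, 0.0)
    root_out = {eidx[e]: 1.0 for e in g.out_edges(root)}
    if not root_out:
        raise ValueError("root has no outgoing edges; targets unreachable")
    add_row(root_out, float(nS), float(nS))
    for s in S:
        coeffs: dict[int, float] = {}
        for e in g.in_edges(s):
            coeffs[eidx[e]] = coeffs.get(eidx[e], 0) + 1.0
        if not coeffs:
            raise ValueError(f"target {s} unreachable from root")
        for e in g.out_edges(s):
            coeffs[eidx[e]] = coeffs.get(eidx[e], 0) - 1.0
        add_row(coeffs, 1.0, 1.0)
    for e, i in eidx.items():
        add_row({i: 1.0, nE + i: -float(nS)}, -np.inf, 0.0)

    integrality = np.ones(2 * nE)
    bounds_lo = np.zeros(2 * nE)
    bounds_hi = np.concatenate([np.full(nE, float(nS)), np.ones(nE)])
    options: dict = {}
    if time_limit is not None:
        options["time_limit"] = float(time_limit)
    if gap_tolerance is not None:
        options["mip_rel_gap"] = float(gap_tolerance)
    res = milp(c, constraints=LinearConstraint(A.tocsr(), lb, ub),
               integrality=integrality,
               bounds=Bounds(bounds_lo, bounds_hi),
               options=options)
    if res.x is None:
        raise RuntimeError(f"Steiner ILP failed: {res.message}")
    status = "optimal" if res.status == 0 else (
        "time_limit" if res.status == 1 else f"status_{res.status}")
    gap = getattr(res, "mip_gap", None)
    # extract by positive flow: selection variables may sit at 1 on unused
    # zero-weight edges without affecting the objective, and such edges need
    # not be root-connected
    chosen = [edges[i] for i in range(nE) if res.x[i] > 0.5]
    return chosen, float(res.fun), status, gap


def _edges_to_tree(pg: PotentialGraph, chosen_edges) -> LineageTree:
    """Convert the selected subgraph into a LineageTree over cell ids.

    Degenerate multi-parent ties keep the incoming edge of smallest weight
    (then lexicographically smallest parent string); branches that reach no
    target are pruned; duplicate cells sharing one string hang as a polytomy.
    """
    sub = nx.DiGraph()
    sub.add_node(pg.root)
    for u, v in chosen_edges:
        sub.add_edge(u, v, weight=pg.graph.edges[u, v]["weight"])
    for v in list(sub.nodes):
        parents = list(sub.predecessors(v))
        if len(parents) > 1:
            keep = min(parents,
                       key=lambda p: (sub.edges[p, v]["weight"], p))
            for p in parents:
                if p != keep:
                    sub.remove_edge(p, v)
    # drop anything not reachable from root, then childless non-targets
    reachable = nx.descendants(sub, pg.root) | {pg.root}
    sub.remove_nodes_from([v for v in list(sub.nodes) if v not in reachable])
    tset = set(pg.targets)
    pruning = True
    while pruning:
        pruning = False
        for v in list(sub.nodes):
            if v != pg.root and sub.out_degree(v) == 0 and v not in tset:
                sub.remove_node(v)
                pruning = True

    g = nx.DiGraph()
    name_of: dict[tuple, str] = {}
    counter = itertools.count()
    for v in nx.topological_sort(sub):
        name = f"s{next(counter)}" if v != pg.root else "root"
        name_of[v] = name
        g.add_node(name, state=v)
        for p in sub.predecessors(v):
            g.add_edge(name_of[p], name,
                       length=sub.edges[p, v]["weight"])
    for v in sub.nodes:
        for cid in pg.cell_map.get(v, []):
            g.add_node(cid, state=v)
            g.add_edge(name_of[v], cid, length=0)
    tree = LineageTree(g, name_of[pg.root])
    tree.annotate_edges_from_states()
    return tree


def solve_steiner(pg: PotentialGraph, time_limit: float | None = None,
                  gap_tolerance: float | None = None) -> SteinerSolution:
    """Minimum Steiner arborescence of the potential graph via the flow ILP.

    Returns the extracted tree (leaves relabeled to cell ids), the ILP
    objective, the solver status and the optimality gap.  A time-limit hit
    returns the incumbent with status ``"time_limit"``.
    """
    chosen, obj, status, gap = _steiner_milp(pg.graph, pg.root, pg.targets,
                                             time_limit, gap_tolerance)
    tree = _edges_to_tree(pg, chosen)
    return SteinerSolution(tree, obj, status, gap, pg.threshold)


# ---------------------------------------------------------------------------
# exact oracle (Dreyfus-Wagner dynamic program)
# ---------------------------------------------------------------------------

def exact_steiner_oracle(graph: nx.DiGraph, root, targets) -> float:
    """Exact minimum Steiner arborescence weight by dynamic programming over
    terminal subsets (independent of the ILP path; test oracle).

    Feasible for roughly <= 10 targets and <= 2000 nodes.
    """
    terms = [t for t in targets if t != root]
    if len(terms) > 12:
        raise ValueError("oracle limited to small terminal sets")
    nodes = list(graph.nodes)
    if len(nodes) > 2000:
        raise ValueError("oracle limited to small graphs")
    dist = dict(nx.all_pairs_dijkstra_path_length(graph, weight="weight"))

    def d(u, v):
        return dist.get(u, {}).get(v, np.inf)

    k = len(terms)
    full = (1 << k) - 1
    # f[mask][v] = min weight arborescence rooted at v covering terms in mask
    f = [dict.fromkeys(nodes, np.inf) for _ in range(full + 1)]
    for i, t in enumerate(terms):
        for v in nodes:
            f[1 << i][v] = d(v, t)
    for mask in range(1, full + 1):
        if mask & (mask - 1) == 0:
            continue
        merged = dict.fromkeys(nodes, np.inf)
        sub = (mask - 1) & mask
        while sub:
            rest = mask ^ sub
            if sub < rest:  # each split once
                for v in nodes:
                    w = f[sub][v] + f[rest][v]
                    if w < merged[v]:
                        merged[v] = w
            sub = (sub - 1) & mask
        for v in nodes:
            best = merged[v]
            for u in nodes:
                w = d(v, u) + merged[u]
                if w < best:
                    best = w
            f[mask][v] = best
    return float(f[full][root])
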