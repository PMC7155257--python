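"""Top-down greedy maximum-parsimony solver.

The solver recursively partitions the cells on the most frequent (character,
state) mutation — or, when indel priors are supplied, on the pair minimizing
p_i(s0, s_j)^(n_ij) — splitting into the carriers and the rest, and recursing
until subsets are singletons.  Cells missing the split character are assigned
to the side whose members share, on average, the larger fraction of their
mutated states.  On data admitting a perfect phylogeny this recovers it
exactly; on real data it is a fast heuristic justified by the negative
correlation between a mutation's observed frequency and its number of
independent origins (see the theory module).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .core import MISSING, CharacterMatrix, LineageTree, PriorSet


class NoSplitError(ValueError):
    """All entries are zero or missing: no mutation is available to split on."""


def select_split(matrix: CharacterMatrix, priors: PriorSet | None = None,
                 locked: set[int] | None = None) -> tuple[int, int]:
    """Choose the (character, state) pair to split on.

    Without priors: argmax over nonzero states of n_ij, the number of
    (non-missing) carriers.  With priors: argmin p_i(s0,s_j)^(n_ij),
    evaluated in log space as argmin n_ij * log p.  Ties break to the lowest
    (character, state) index pair.  ``locked`` characters (already mutated in
    the ancestor) are skipped.
    """
    return _select_split_values(matrix.values, priors, locked or set())


def _select_split_values(vals: np.ndarray, priors: PriorSet | None,
                         locked: set[int]) -> tuple[int, int]:
    best = None
    best_score = None
    for i in range(vals.shape[1]):
        if i in locked:
            continue
        col = vals[:, i]
        states, counts = np.unique(col[col > 0], return_counts=True)
        for s, n in zip(states, counts):
            if priors is None:
                score = -float(n)  # more carriers first
            else:
                score = float(n) * math.log(priors.prob(i, int(s)))
            key = (score, i, int(s))
            if best_score is None or key < (best_score, *best):
                best_score, best = score, (i, int(s))
    if best is None:
        raise NoSplitError("no nonzero non-missing entry to split on")
    return best


def shared_mutation_fraction(a: np.ndarray, b: np.ndarray) -> float:
    """Fraction of characters, among those non-missing in both cells, where
    both carry the same nonzero state.  0 when no character is comparable."""
    both = (a != MISSING) & (b != MISSING)
    denom = int(both.sum())
    if denom == 0:
        return 0.0
    num = int(((a == b) & (a > 0) & both).sum())
    return num / denom


def partition_with_missing(matrix: CharacterMatrix, char: int, state: int
                           ) -> tuple[list[str], list[str]]:
    """Split cells into carriers of (char, state) and the rest.

    Cells missing the split character join the side with the greater mean
    shared-mutation fraction against that side's members; exact ties go to
    the larger subset (then to the carrier side).
    """
    o_idx, c_idx, miss_idx = _partition_indices(matrix.values, char, state)
    ids = matrix.cell_ids
    return [ids[i] for i in o_idx], [ids[i] for i in c_idx]


def _partition_indices(vals: np.ndarray, char: int, state: int):
    col = vals[:, char]
    o = list(np.flatnonzero(col == state))
    comp = list(np.flatnonzero((col != state) & (col != MISSING)))
    missing = list(np.flatnonzero(col == MISSING))
    o0, c0 = list(o), list(comp)  # assignment compares against observed members
    for x in missing:
        row = vals[x]
        mean_o = (np.mean([shared_mutation_fraction(row, vals[y]) for y in o0])
                  if o0 else 0.0)
        mean_c = (np.mean([shared_mutation_fraction(row, vals[y]) for y in c0])
                  if c0 else 0.0)
        if mean_o > mean_c:
            o.append(x)
        elif mean_c > mean_o:
            comp.append(x)
        elif len(o) >= len(comp):
            o.append(x)
        else:
            comp.append(x)
    return o, comp, missing


@dataclass
class GreedyResult:
    """Greedy tree plus, when a cutoff was given, the subproblems left for a
    more exact solver (hybrid mode)."""

    tree: LineageTree
    unsolved: list[tuple[str, list[str], tuple[int, ...]]] = field(
        default_factory=list)


def build_greedy(matrix: CharacterMatrix, priors: PriorSet | None = None,
                 cutoff: int | None = None,
                 root_state: tuple | None = None) -> GreedyResult:
    """Recursive greedy reconstruction.

    Subsets with no available split become a polytomy; mutations carried by
    every (non-missing) cell of a subset are absorbed into the subset's
    ancestral string rather than producing a degenerate split.  With
    ``cutoff``, recursion stops at subsets of at most that many cells, which
    are returned in ``unsolved`` for the hybrid solver.
    """
    if matrix.n < 1:
        raise ValueError("need at least one cell")
    g = nx.DiGraph()
    counter = [0]
    unsolved: list[tuple[str, list[str], tuple[int, ...]]] = []
    vals = matrix.values
    ids = matrix.cell_ids

    def new_node(state) -> str:
        name = f"g{counter[0]}"
        counter[0] += 1
        g.add_node(name, state=tuple(int(s) for s in state))
        return name

    def leaf(idx: int) -> str:
        g.add_node(ids[idx], state=tuple(int(s) for s in vals[idx]))
        return ids[idx]

    def expand(cells: list[int], ancestral: np.ndarray) -> str:
        ancestral = ancestral.copy()
        if len(cells) == 1:
            return leaf(cells[0])
        if cutoff is not None and len(cells) <= cutoff:
            node = new_node(ancestral)
            unsolved.append((node, [ids[i] for i in cells], tuple(
                int(s) for s in ancestral)))
            return node
        sub = vals[cells]
        while True:
            locked = {i for i in range(sub.shape[1]) if ancestral[i] > 0}
            try:
                i, j = _select_split_values(sub, priors, locked)
            except NoSplitError:
                node = new_node(ancestral)
                for c in cells:
                    g.add_edge(node, leaf(c))
                return node
            o_rel, comp_rel, _ = _partition_indices(sub, i, j)
            if not comp_rel:  # mutation shared by all: absorb and retry
                ancestral[i] = j
                continue
            node = new_node(ancestral)
            child_anc = ancestral.copy()
            child_anc[i] = j
            o_cells = [cells[r] for r in o_rel]
            c_cells = [cells[r] for r in comp_rel]
            g.add_edge(node, expand(o_cells, child_anc))
            g.add_edge(node, expand(c_cells, ancestral))
            return node

    base = np.zeros(matrix.m, dtype=np.int64) if root_state is None \
        else np.asarray(root_state, dtype=np.int64)
    top = expand(list(range(matrix.n)), base)
    state_top = g.nodes[top].get("state")
    if tuple(state_top) != tuple(int(s) for s in base):
        root = new_node(base)
        g.add_edge(root, top)
    else:
        root = top
    tree = LineageTree(g, root)
    tree.annotate_edges_from_states()
    return GreedyResult(tree, unsolved)


def greedy_split_precision(true_tree: LineageTree, matrix: CharacterMatrix,
                           priors: PriorSet | None = None) -> float:
    """Precision of the first greedy split against the true phylogeny.

    G is the set of cells carrying the selected (character, state); the true
    tree's independent origins of that mutation partition G's inheritance, and
    the precision is |largest single-origin subset| / |G|.
    """
    i, j = select_split(matrix, priors)
    col = matrix.values[:, i]
    G = {matrix.cell_ids[x] for x in np.flatnonzero(col == j)}
    origin_sets = []
    for u, v in true_tree.graph.edges:
        if (i, j) in true_tree.mutations(u, v):
            below = nx.descendants(true_tree.graph, v) | {v}
            leaves = {x for x in below if true_tree.graph.out_degree(x) == 0}
            origin_sets.append(leaves & G)
    if not origin_sets:
        raise ValueError(f"selected mutation ({i},{j}) absent from true tree")
    return max(len(s) for s in origin_sets) / len(G)
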