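"""Domain types and character-compatibility primitives.

A lineage-tracing experiment is summarized by a *character matrix*: one row per
cell, one column per Cas9 target site ("character"), each entry the integer
state of the indel observed there.  State 0 means the site is uncut; a missing
observation (dropout) is recorded with the :data:`MISSING` sentinel, which is
distinct from every real state.  State labels are per-character namespaces:
state 3 in character 1 is unrelated to state 3 in character 2.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

#: Sentinel for a dropped-out (unobserved) character state.  In files it is
#: written as "-" and "-", "NA" and "?" are all accepted on input.
MISSING: int = -1


# ---------------------------------------------------------------------------
# CharacterMatrix
# ---------------------------------------------------------------------------

class CharacterMatrix:
    """Cells x characters table of integer indel states.

    Parameters
    ----------
    data
        2-D array-like of integers (``MISSING`` = -1 for dropout), or a
        :class:`pandas.DataFrame` whose index holds the cell ids.
    cell_ids, characters
        Row / column labels; defaults are ``c0..`` / ``r0..`` style labels.
    """

    def __init__(self, data, cell_ids: Sequence[str] | None = None,
                 characters: Sequence[str] | None = None):
        if isinstance(data, pd.DataFrame):
            if cell_ids is None:
                cell_ids = [str(i) for i in data.index]
            if characters is None:
                characters = [str(c) for c in data.columns]
            data = data.to_numpy()
        arr = np.asarray(data)
        if arr.ndim != 2:
            raise ValueError("character matrix must be two-dimensional")
        arr = arr.astype(np.int64, copy=True)
        n, m = arr.shape
        if cell_ids is None:
            cell_ids = [f"c{i}" for i in range(n)]
        if characters is None:
            characters = [f"r{j}" for j in range(m)]
        cell_ids = [str(c) for c in cell_ids]
        if len(cell_ids) != n:
            raise ValueError("ragged input: cell_ids length does not match rows")
        if len(set(cell_ids)) != n:
            dupes = sorted({c for c in cell_ids if cell_ids.count(c) > 1})
            raise ValueError(f"duplicate cell_ids: {dupes}")
        if len(characters) != m:
            raise ValueError("characters length does not match columns")
        if (arr < MISSING).any():
            raise ValueError("states must be nonnegative integers or MISSING (-1)")
        self.values: np.ndarray = arr
        self.cell_ids: list[str] = list(cell_ids)
        self.characters: list[str] = [str(c) for c in characters]

    # -- basic views --------------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values.copy(), index=self.cell_ids,
                            columns=self.characters)

    def row(self, cell_id: str) -> np.ndarray:
        return self.values[self.cell_ids.index(cell_id)]

    def subset(self, cell_ids: Sequence[str]) -> "CharacterMatrix":
        idx = [self.cell_ids.index(c) for c in cell_ids]
        return CharacterMatrix(self.values[idx], list(cell_ids), self.characters)

    def __repr__(self) -> str:  # pragma: no cover
        return f"CharacterMatrix({self.n} cells x {self.m} characters)"

    # -- per-character mutated-cell sets ------------------------------------
    def mutated_sets(self, char: int) -> dict[int, set[str]]:
        """Map nonzero state -> set of cell_ids carrying it (MISSING excluded)."""
        if not 0 <= char < self.m:
            raise IndexError(f"character index {char} out of range")
        col = self.values[:, char]
        out: dict[int, set[str]] = {}
        for i, s in enumerate(col):
            if s > 0:
                out.setdefault(int(s), set()).add(self.cell_ids[i])
        return out


def validate_matrix(matrix: CharacterMatrix) -> dict:
    """Validation report: duplicates, negative states, per-character missing.

    Construction already raises on ragged rows / duplicate ids; this reports
    the summary statistics for a well-formed matrix.
    """
    vals = matrix.values
    missing_frac = (vals == MISSING).mean(axis=0)
    return {
        "valid": True,
        "n_cells": matrix.n,
        "n_characters": matrix.m,
        "missing_fraction": {c: float(f) for c, f in
                             zip(matrix.characters, missing_frac)},
        "overall_missing_fraction": float((vals == MISSING).mean()),
    }


def binarize_matrix(matrix: CharacterMatrix) -> CharacterMatrix:
    """One-hot factorization into binary characters.

    Each observed (character, nonzero state) pair becomes one binary column; a
    cell carries 1 exactly at the column of its observed state.  A MISSING
    entry at character i expands to MISSING across all of i's columns.
    Column names are ``"<char>=<state>"``.
    """
    cols = []
    names = []
    vals = matrix.values
    for j in range(matrix.m):
        states = sorted({int(s) for s in vals[:, j] if s > 0})
        for s in states:
            col = (vals[:, j] == s).astype(np.int64)
            col[vals[:, j] == MISSING] = MISSING
            cols.append(col)
            names.append(f"{matrix.characters[j]}={s}")
    if not cols:
        data = np.zeros((matrix.n, 0), dtype=np.int64)
    else:
        data = np.column_stack(cols)
    return CharacterMatrix(data, matrix.cell_ids, names)


def characters_compatible(obs_set_1: Iterable, obs_set_2: Iterable) -> bool:
    """Two binary characters are compatible iff their mutated-cell sets nest
    or are disjoint (O1 <= O2, O2 <= O1, or O1 & O2 empty)."""
    a, b = set(obs_set_1), set(obs_set_2)
    return a <= b or b <= a or not (a & b)


def _pairs_for_characters(matrix: CharacterMatrix, char_i: int, char_j: int):
    """All (state-of-i, state-of-j) mutated-set pairs, MISSING cells excluded."""
    sets_i = matrix.mutated_sets(char_i)
    sets_j = matrix.mutated_sets(char_j)
    return [(oi, oj) for oi in sets_i.values() for oj in sets_j.values()]


def _all_compatible(pairs, removed: set) -> bool:
    for oi, oj in pairs:
        if not characters_compatible(oi - removed, oj - removed):
            return False
    return True


def min_compatibility_distance(matrix: CharacterMatrix, char_i: int,
                               char_j: int, exhaustive_limit: int = 12) -> dict:
    """Minimum number of cells to remove so characters i and j are compatible.

    Every (state-of-i, state-of-j) pair of mutated-cell sets must satisfy the
    nesting/disjointness condition after removal.  Exact by exhaustive search
    over removal subsets when at most ``exhaustive_limit`` cells are involved;
    otherwise a greedy heuristic repeatedly removes the cell participating in
    the most violated pairs.  The report says which method was used.
    """
    pairs = _pairs_for_characters(matrix, char_i, char_j)
    involved = sorted(set().union(*[oi | oj for oi, oj in pairs]) if pairs else set())
    if _all_compatible(pairs, set()):
        return {"distance": 0, "removed": [], "method": "exact"}
    if len(involved) <= exhaustive_limit:
        for k in range(1, len(involved) + 1):
            for combo in itertools.combinations(involved, k):
                if _all_compatible(pairs, set(combo)):
                    return {"distance": k, "removed": list(combo),
                            "method": "exact"}
        return {"distance": len(involved), "removed": involved,
                "method": "exact"}  # pragma: no cover
    removed: set = set()
    while not _all_compatible(pairs, removed):
        counts: dict[str, int] = {}
        for oi, oj in pairs:
            a, b = oi - removed, oj - removed
            if not characters_compatible(a, b):
                for c in a | b:
                    counts[c] = counts.get(c, 0) + 1
        victim = max(sorted(counts), key=lambda c: counts[c])
        removed.add(victim)
    return {"distance": len(removed), "removed": sorted(removed),
            "method": "greedy"}


# ---------------------------------------------------------------------------
# PriorSet
# ---------------------------------------------------------------------------

@dataclass
class PriorSet:
    """Per-character indel priors and mutation rates.

    ``state_priors[i][j]`` is q_ij, the conditional probability that character
    i takes state j given that it mutates; for each character with entries the
    q_ij are positive and sum to 1.  ``mutation_rates[i]`` is p_i, the
    per-generation probability that character i mutates.
    """

    state_priors: list[dict[int, float]]
    mutation_rates: list[float] = field(default_factory=list)

    def __post_init__(self):
        for i, qs in enumerate(self.state_priors):
            if qs:
                if any(q <= 0 for q in qs.values()):
                    raise ValueError(f"character {i}: priors must be positive")
                total = sum(qs.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(
                        f"character {i}: priors sum to {total}, expected 1")
        for i, p in enumerate(self.mutation_rates):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"character {i}: mutation rate {p} not in [0,1]")

    @property
    def m(self) -> int:
        return len(self.state_priors)

    def prob(self, char: int, state: int) -> float:
        return self.state_priors[char][state]

    @classmethod
    def uniform(cls, num_characters: int, states_per_char: Mapping[int, Sequence[int]]
                ) -> "PriorSet":
        priors = []
        for i in range(num_characters):
            states = list(states_per_char.get(i, []))
            priors.append({s: 1.0 / len(states) for s in states} if states else {})
        return cls(priors)


# ---------------------------------------------------------------------------
# LineageTree
# ---------------------------------------------------------------------------

class LineageTree:
    """Rooted tree whose leaves are observed cells.

    Wraps a :class:`networkx.DiGraph`.  Node attribute ``state`` (a tuple of
    length m) optionally annotates each node with its character string; edge
    attribute ``mutations`` is the set of ``(character, state)`` events on the
    edge.  When annotated, the root string is all-zero and along any
    root-to-leaf path each character changes at most once, from 0 to a nonzero
    state (irreversibility).
    """

    def __init__(self, graph: nx.DiGraph, root):
        if root not in graph:
            raise ValueError("root not in graph")
        roots = [v for v in graph if graph.in_degree(v) == 0]
        if roots != [root] and set(roots) != {root}:
            raise ValueError(f"tree must have exactly one root, found {roots}")
        self.graph = graph
        self.root = root
        self._depth: dict | None = None

    # -- structure ----------------------------------------------------------
    def leaves(self) -> list:
        return [v for v in self.graph if self.graph.out_degree(v) == 0]

    def children(self, v) -> list:
        return list(self.graph.successors(v))

    def parent(self, v):
        preds = list(self.graph.predecessors(v))
        return preds[0] if preds else None

    def depths(self) -> dict:
        """Edge-count depth of every node from the root (cached)."""
        if self._depth is None:
            self._depth = nx.single_source_shortest_path_length(self.graph,
                                                                self.root)
        return self._depth

    def lca(self, a, b):
        depth = self.depths()
        while a != b:
            if depth[a] < depth[b]:
                b = self.parent(b)
            elif depth[b] < depth[a]:
                a = self.parent(a)
            else:
                a, b = self.parent(a), self.parent(b)
        return a

    # -- annotations --------------------------------------------------------
    def state(self, v) -> tuple | None:
        return self.graph.nodes[v].get("state")

    def set_state(self, v, state: Sequence[int]) -> None:
        self.graph.nodes[v]["state"] = tuple(int(s) for s in state)

    def mutations(self, u, v) -> set:
        return self.graph.edges[u, v].get("mutations", set())

    def annotate_edges_from_states(self) -> None:
        """Derive per-edge mutation sets as character-wise parent/child
        differences (0 -> s transitions; MISSING never counts)."""
        for u, v in self.graph.edges:
            su, sv = self.state(u), self.state(v)
            muts = set()
            if su is not None and sv is not None:
                for i, (a, b) in enumerate(zip(su, sv)):
                    if a != b and a == 0 and b > 0:
                        muts.add((i, int(b)))
            self.graph.edges[u, v]["mutations"] = muts

    def check_irreversibility(self) -> None:
        """Raise if any root-to-leaf path mutates a character twice or back."""
        for v in self.graph:
            sv = self.state(v)
            if sv is None:
                continue
            p = self.parent(v)
            if p is None:
                if any(s != 0 for s in sv):
                    raise ValueError("annotated root string must be all-zero")
                continue
            sp = self.state(p)
            for i, (a, b) in enumerate(zip(sp, sv)):
                if a > 0 and b != a and b != MISSING:
                    raise ValueError(
                        f"character {i} reverses {a}->{b} on edge {p}->{v}")

    # -- editing ------------------------------------------------------------
    def collapse_singles(self) -> "LineageTree":
        """Remove single-child internal nodes, merging their edges; mutation
        sets union, branch lengths add."""
        g = self.graph.copy()
        changed = True
        while changed:
            changed = False
            for v in list(g.nodes):
                if v == self.root or v not in g:
                    continue
                if g.out_degree(v) == 1 and g.in_degree(v) == 1:
                    p = next(g.predecessors(v))
                    c = next(g.successors(v))
                    muts = (g.edges[p, v].get("mutations", set())
                            | g.edges[v, c].get("mutations", set()))
                    length = (g.edges[p, v].get("length", 0)
                              + g.edges[v, c].get("length", 0))
                    g.remove_node(v)
                    g.add_edge(p, c, mutations=muts, length=length)
                    changed = True
        # the root is kept even if it has one child: depth semantics anchor there
        return LineageTree(g, self.root)

    def copy(self) -> "LineageTree":
        return LineageTree(self.graph.copy(), self.root)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"LineageTree({self.graph.number_of_nodes()} nodes, "
                f"{len(self.leaves())} leaves)")


@dataclass
class TripletReport:
    """Depth-stratified triplet agreement between a true and a
    reconstructed tree."""

    per_depth_correct: dict[int, float]
    per_depth_counts: dict[int, int]
    thresholded: float
    unthresholded: float
    included_depths: list[int]

    def __post_init__(self):
        for d, f in self.per_depth_correct.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction at depth {d} outside [0,1]")
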