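"""Hybrid solver: greedy partitioning down to a cell-count cutoff, then an
exact Steiner ILP on each small subproblem, merged back into the greedy tree.

The greedy stage fixes the early (high-confidence, frequency-supported)
splits; each remaining subset of at most ``cutoff`` cells is solved as an
independent Steiner instance rooted at the subset's accumulated ancestral
string.  Subproblems are independent, so the merged result does not depend on
the order in which they are solved.  If an ILP subproblem fails, or its tree
is less parsimonious than plain greedy on the same subset (possible when the
neighborhood cap truncates the potential graph), the greedy subtree is used
instead and the event is logged.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np

from .core import CharacterMatrix, LineageTree, PriorSet
from .greedy import build_greedy
from .metrics import annotate_ancestral_states, parsimony_score
from .steiner import (DEFAULT_MAX_NEIGHBORHOOD, optimize_neighborhood,
                      solve_steiner)

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 200


def _graft(main: nx.DiGraph, placeholder: str, subtree: LineageTree,
           prefix: str) -> None:
    """Replace ``placeholder`` in ``main`` with ``subtree`` (internal node
    names prefixed to stay unique; leaves keep their cell ids)."""
    rename = {}
    for v in subtree.graph.nodes:
        if subtree.graph.out_degree(v) == 0:
            rename[v] = v  # leaf: cell id, globally unique
        else:
            rename[v] = f"{prefix}{v}"
    for v, data in subtree.graph.nodes(data=True):
        main.add_node(rename[v], **data)
    for u, v, data in subtree.graph.edges(data=True):
        main.add_edge(rename[u], rename[v], **data)
    parents = list(main.predecessors(placeholder))
    sub_root = rename[subtree.root]
    for p in parents:
        data = main.edges[p, placeholder]
        main.add_edge(p, sub_root, **data)
    main.remove_node(placeholder)


def _subtree_parsimony(tree: LineageTree, matrix: CharacterMatrix) -> int:
    annotated = annotate_ancestral_states(tree, matrix)
    return parsimony_score(annotated)


def build_hybrid(matrix: CharacterMatrix, cutoff: int = DEFAULT_CUTOFF,
                 priors: PriorSet | None = None,
                 max_neighborhood_size: int = DEFAULT_MAX_NEIGHBORHOOD,
                 time_limit: float | None = None,
                 gap_tolerance: float | None = None) -> LineageTree:
    """Greedy-then-ILP reconstruction.

    ``cutoff >= n`` reduces to pure ILP; ``cutoff = 1`` reduces to pure
    greedy.  ILP parameters are passed through to each subproblem.
    """
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    result = build_greedy(matrix, priors, cutoff=cutoff)
    main = result.tree.graph
    root = result.tree.root
    for k, (node, cells, ancestral) in enumerate(result.unsolved):
        sub = matrix.subset(cells)
        subtree = None
        try:
            pg, d = optimize_neighborhood(sub, max_neighborhood_size,
                                          root_state=ancestral)
            sol = solve_steiner(pg, time_limit, gap_tolerance)
            subtree = sol.tree
            logger.info("subproblem %d: %d cells, d=%d, objective=%.0f (%s)",
                        k, len(cells), d, sol.objective, sol.status)
        except Exception as exc:  # noqa: BLE001 - per-subproblem isolation
            logger.warning("subproblem %d: ILP failed (%s); greedy fallback",
                           k, exc)
        fallback = build_greedy(sub, priors, root_state=ancestral).tree
        if subtree is None or (_subtree_parsimony(subtree, sub)
                               > _subtree_parsimony(fallback, sub)):
            if subtree is not None:
                logger.warning(
                    "subproblem %d: ILP tree less parsimonious than greedy; "
                    "keeping greedy subtree", k)
            subtree = fallback
        _graft(main, node, subtree, prefix=f"h{k}_")
        if node == root:
            root = f"h{k}_{subtree.root}" \
                if subtree.graph.out_degree(subtree.root) > 0 else subtree.root
    tree = LineageTree(main, root)
    tree.annotate_edges_from_states()
    return tree
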