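"""Forward simulation of CRISPR/Cas9 lineage-tracing experiments.

A recording experiment is modeled as a full binary tree of ``depth`` cell
divisions starting from a single unedited founder.  After each division, every
still-uncut character of each daughter mutates independently with its
per-generation probability; when a mutation occurs the new state is drawn from
the character's state distribution.  Mutated characters never change again
(irreversibility).  At the end, a fraction of the 2^depth terminal cells is
sampled uniformly, and per-character dropout masks entries to MISSING.

The simulated ground-truth tree, the pre- and post-dropout character matrices
and the generating state probabilities together form a
:class:`SimulatedExperiment`, the benchmark fixture for the solvers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.stats import nbinom

from .core import MISSING, CharacterMatrix, LineageTree, PriorSet

STATE_FAMILIES = ("negative-binomial-like", "uniform")

#: Shape of the surrogate skewed state-frequency family (see
#: :func:`draw_state_distribution`): a zero-truncated negative binomial.
_NB_N, _NB_P = 5, 0.5

#: Concentration of the Beta draw used when only a mean dropout rate is given.
_DROPOUT_CONCENTRATION = 10.0


@dataclass
class SimulationParams:
    """Generating parameters of a simulated lineage-tracing experiment.

    ``mutation_rate`` may be a single per-generation probability shared by all
    characters or a per-character sequence; ``dropout_rates`` may be a mean
    (per-character rates are then Beta-drawn around it) or a per-character
    sequence.  ``subsample`` is the fraction of the 2^depth terminal cells
    kept; ``unique_states`` switches on infinite-alleles mode in which every
    mutation event creates a globally novel state, guaranteeing a perfect
    phylogeny.
    """

    num_characters: int = 40
    num_states: int = 40
    state_family: str = "negative-binomial-like"
    theta: float = 0.0
    mutation_rate: float | Sequence[float] = 0.025
    dropout_rates: float | Sequence[float] = 0.17
    depth: int = 11
    subsample: float = 400 / 2048
    unique_states: bool = False
    seed: int | None = None

    def __post_init__(self):
        rates = np.atleast_1d(np.asarray(self.mutation_rate, dtype=float))
        if ((rates < 0) | (rates > 1)).any():
            raise ValueError("mutation rates must lie in [0,1]")
        drops = np.atleast_1d(np.asarray(self.dropout_rates, dtype=float))
        if ((drops < 0) | (drops > 1)).any():
            raise ValueError("dropout rates must lie in [0,1]")
        if not 0.0 <= self.subsample <= 1.0:
            raise ValueError("subsample fraction must lie in [0,1]")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0,1]")
        if self.state_family not in STATE_FAMILIES:
            raise ValueError(f"unknown state family {self.state_family!r}")

    def per_character_rates(self) -> np.ndarray:
        rates = np.atleast_1d(np.asarray(self.mutation_rate, dtype=float))
        if rates.size == 1:
            return np.full(self.num_characters, float(rates[0]))
        if rates.size != self.num_characters:
            raise ValueError("per-character mutation rates have wrong length")
        return rates

    def per_character_dropout(self, rng: np.random.Generator) -> np.ndarray:
        drops = np.atleast_1d(np.asarray(self.dropout_rates, dtype=float))
        if drops.size == self.num_characters:
            return drops.astype(float)
        if drops.size != 1:
            raise ValueError("per-character dropout rates have wrong length")
        mean = float(drops[0])
        if mean in (0.0, 1.0):
            return np.full(self.num_characters, mean)
        a = mean * _DROPOUT_CONCENTRATION
        b = (1 - mean) * _DROPOUT_CONCENTRATION
        return rng.beta(a, b, size=self.num_characters)


@dataclass
class SimulatedExperiment:
    """Ground truth plus observations for one simulated experiment."""

    tree: LineageTree
    ground_truth: CharacterMatrix
    observed: CharacterMatrix
    params: SimulationParams
    state_probs: list[dict[int, float]]
    dropout_rates: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def priors(self) -> PriorSet:
        """The exact generating priors, as used by the prior-aware solvers."""
        rates = self.params.per_character_rates()
        return PriorSet([dict(d) for d in self.state_probs],
                        [float(r) for r in rates])


def draw_state_distribution(S: int, family: str = "negative-binomial-like",
                            theta: float = 0.0, p: float = 0.5,
                            rng: np.random.Generator | int | None = None
                            ) -> np.ndarray:
    """Draw S positive state probabilities summing to ``p``.

    Each raw value is ``theta * Unif(0,1) + (1-theta) * F'`` where F' is the
    skewed surrogate family: the NB(5, 0.5) probability mass over randomly
    permuted state labels, rescaled to mean 1/2 so the two mixture components
    are on the same scale.  Like real indel-formation frequencies this is
    heavy-tailed — a handful of outcomes dominate while most are rare — so
    at theta=0 the normalized distribution has much lower entropy than the
    theta=1 (uniform) draws.  The values are normalized to sum to ``p`` (the
    uncut probability is 1-p); dividing by p gives the conditional state
    distribution.
    """
    if S < 1:
        raise ValueError("need at least one state")
    if family not in STATE_FAMILIES:
        raise ValueError(f"unknown state family {family!r}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) \
        else rng
    u = rng.uniform(size=S)
    pmf = nbinom.pmf(rng.permutation(S), _NB_N, _NB_P)
    pmf = np.maximum(pmf, 1e-12)  # deep-tail states stay positive
    skew = pmf / pmf.mean() * 0.5
    if family == "uniform":
        raw = u
    else:
        raw = theta * u + (1.0 - theta) * skew
    return raw / raw.sum() * p


def simulate_lineage(params: SimulationParams) -> SimulatedExperiment:
    """Run the forward simulation and return tree + matrices.

    Nodes of the returned tree are ``(generation, index)`` tuples except the
    sampled leaves, which are relabeled to cell ids ``c0..``; every node is
    annotated with its character string and edges carry mutation events.
    """
    rng = np.random.default_rng(params.seed)
    C, S, D = params.num_characters, params.num_states, params.depth
    n_sample = int(round(2 ** D * params.subsample))
    if n_sample < 1:
        raise ValueError("subsample * 2^depth must be >= 1")
    rates = params.per_character_rates()

    state_probs: list[dict[int, float]] = []
    cond: list[np.ndarray] = []
    for c in range(C):
        probs = draw_state_distribution(S, params.state_family, params.theta,
                                        rates[c] if rates[c] > 0 else 1.0, rng)
        conditional = probs / probs.sum()
        cond.append(conditional)
        state_probs.append({s + 1: float(q) for s, q in enumerate(conditional)})

    # state evolution, level by level
    levels: list[np.ndarray] = [np.zeros((1, C), dtype=np.int64)]
    next_state = np.ones(C, dtype=np.int64)  # per-character fresh-state counter
    for t in range(1, D + 1):
        parent = levels[-1]
        child = np.repeat(parent, 2, axis=0)  # children 2i, 2i+1 of parent i
        uncut = child == 0
        mutate = uncut & (rng.uniform(size=child.shape) < rates[None, :])
        if params.unique_states:
            for c in range(C):
                k = int(mutate[:, c].sum())
                if k:
                    child[mutate[:, c], c] = np.arange(next_state[c],
                                                       next_state[c] + k)
                    next_state[c] += k
        else:
            for c in range(C):
                idx = np.flatnonzero(mutate[:, c])
                if idx.size:
                    child[idx, c] = rng.choice(S, size=idx.size,
                                               p=cond[c]) + 1
        levels.append(child)

    sampled = np.sort(rng.choice(2 ** D, size=n_sample, replace=False))
    cell_ids = [f"c{i}" for i in range(n_sample)]

    tree = _build_pruned_tree(levels, sampled, cell_ids, D)

    truth = CharacterMatrix(levels[D][sampled], cell_ids,
                            [f"r{c}" for c in range(C)])
    d_c = params.per_character_dropout(rng)
    observed_vals = truth.values.copy()
    mask = rng.uniform(size=observed_vals.shape) < d_c[None, :]
    observed_vals[mask] = MISSING
    observed = CharacterMatrix(observed_vals, cell_ids, truth.characters)
    return SimulatedExperiment(tree, truth, observed, params, state_probs, d_c)


def _build_pruned_tree(levels, sampled, cell_ids, D) -> LineageTree:
    """Tree restricted to ancestors of the sampled leaves (singles kept, so
    node depth equals generation)."""
    g = nx.DiGraph()
    keep: set[tuple[int, int]] = set()
    for idx in sampled:
        node = (D, int(idx))
        while node not in keep:
            keep.add(node)
            if node[0] == 0:
                break
            node = (node[0] - 1, node[1] // 2)
    label = {}
    sampled_set = {int(s) for s in sampled}
    for (t, i) in keep:
        if t == D and i in sampled_set:
            label[(t, i)] = cell_ids[int(np.searchsorted(sampled, i))]
        else:
            label[(t, i)] = (t, i)
    for (t, i) in keep:
        g.add_node(label[(t, i)], state=tuple(int(s) for s in levels[t][i]))
        if t > 0:
            g.add_edge(label[(t - 1, i // 2)], label[(t, i)])
    tree = LineageTree(g, label[(0, 0)])
    tree.annotate_edges_from_states()
    return tree


def inject_parallel_evolution(base: SimulatedExperiment, k: int, d: int,
                              rng: np.random.Generator | int | None = None
                              ) -> SimulatedExperiment:
    """Turn a perfect phylogeny into a near-perfect one with k parallel events.

    ``base`` must be simulated with ``total - k`` characters (unique states, no
    dropout).  k times: pick a node at generation ``d`` in the true tree, pick
    one grandchild through each of two children, and place the *same*
    new-character mutation on both child-to-grandchild edges.  The output has
    k extra characters, each arising exactly twice.
    """
    if d >= base.params.depth - 1:
        raise ValueError("parallel-event depth must be < depth-1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) \
        else rng
    tree = base.tree.copy()
    depths = tree.depths()
    eligible = []
    for v in tree.graph:
        if depths[v] != d:
            continue
        kids = [c for c in tree.children(v) if tree.children(c)]
        if len(kids) >= 2:
            eligible.append(v)
    if len(eligible) == 0:
        raise ValueError(f"no node at depth {d} with two grandchild lineages")

    C0 = base.params.num_characters
    new_cols = {cid: [] for cid in base.ground_truth.cell_ids}
    order = sorted(tree.graph.nodes, key=str)
    for event in range(k):
        v = eligible[int(rng.integers(len(eligible)))]
        kids = [c for c in tree.children(v) if tree.children(c)]
        c1, c2 = [kids[i] for i in rng.choice(len(kids), size=2, replace=False)]
        g1 = tree.children(c1)[int(rng.integers(len(tree.children(c1))))]
        g2 = tree.children(c2)[int(rng.integers(len(tree.children(c2))))]
        carriers = (nx.descendants(tree.graph, g1) | {g1}
                    | nx.descendants(tree.graph, g2) | {g2})
        char = C0 + event
        for node in order:
            st = list(tree.state(node))
            st.append(1 if node in carriers else 0)
            tree.set_state(node, st)
        for cid in new_cols:
            new_cols[cid].append(1 if cid in carriers else 0)
    tree.annotate_edges_from_states()

    cells = base.ground_truth.cell_ids
    extra = np.array([new_cols[c] for c in cells], dtype=np.int64).reshape(
        len(cells), k)
    vals = np.hstack([base.ground_truth.values, extra])
    chars = base.ground_truth.characters + [f"r{C0 + j}" for j in range(k)]
    truth = CharacterMatrix(vals, cells, chars)
    params = replace(base.params, num_characters=C0 + k)
    probs = [dict(p) for p in base.state_probs] + [{1: 1.0}] * k
    return SimulatedExperiment(tree, truth, truth, params, probs,
                               np.zeros(C0 + k))


def preset_base_editor(num_characters: int) -> SimulationParams:
    """Base-editor regime: characters x states held at 400, 1.04% mutation
    rate, 10% dropout, depth 10, 400 sampled cells, NB-shaped states."""
    if 400 % num_characters != 0:
        raise ValueError("number of characters must divide 400")
    return SimulationParams(
        num_characters=num_characters,
        num_states=400 // num_characters,
        state_family="negative-binomial-like",
        theta=0.0,
        mutation_rate=0.0104,
        dropout_rates=0.10,
        depth=10,
        subsample=400 / 2 ** 10,
    )


def preset_phased_recorder(e_j: float, p0: float = 0.025) -> SimulationParams:
    """Phased-recorder regime: 50 characters, 10 states, rates rising in
    blocks of five: m_i = p0 * (1 + e_j * floor(i/5)) with i counted from 1,
    so the max/min rate ratio over 50 characters is 1 + 10 * e_j."""
    rates = [p0 * (1 + e_j * ((i + 1) // 5)) for i in range(50)]
    return SimulationParams(
        num_characters=50,
        num_states=10,
        mutation_rate=rates,
        dropout_rates=0.17,
        depth=11,
        subsample=400 / 2048,
    )
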