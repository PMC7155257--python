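"""Moments of parallel evolution in a binary lineage.

For a full binary tree of height h (one division per generation, mutation
after division), a character mutates each generation with probability p, and
takes a particular state with conditional probability q.  X is the number of
times that particular mutation arises independently in the tree; Y is the
fraction of the 2^h leaves that carry it.  The closed-form first and second
moments of (X, Y) justify the greedy split criterion: for biologically
plausible p (below 1 - 1/sqrt(2) ~ 0.29), Cov(X, Y) diverges to -infinity
with h, i.e., frequent mutations tend to be single-origin.

All moments are evaluated as exact finite geometric sums over depth indices
rather than the fully expanded closed forms, which removes the p = 0.5
removable singularity; E(X) at p = 0.5 agrees with the special case 2pqh.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class TheoryParams:
    """p: per-generation mutation probability; q: conditional probability of
    the particular state; h: tree height in generations."""

    p: float
    q: float
    h: int

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0 or not 0.0 <= self.q <= 1.0:
            raise ValueError("p and q must lie in [0,1]")
        if self.h < 1:
            raise ValueError("h must be >= 1")


def closed_form_moments(params: TheoryParams) -> dict[str, float]:
    """E(X), Var(X) (exact and bound), E(Y), E(XY), Cov(X,Y), Var(Y).

    A mutation on the edge ending at depth t (probability pq(1-p)^(t-1) per
    edge, 2^t edges) contributes 1 to X and 2^(-t) to Y (it fixes 2^(h-t) of
    the 2^h leaves).  Pairs of edges on disjoint branches below a depth-d
    ancestor co-mutate with probability p^2 q^2 (1-p)^(d+l+k) where l, k are
    the extra depths of the two edges.
    """
    p, q, h = params.p, params.q, params.h
    d = np.arange(h, dtype=float)          # ancestor depths 0..h-1
    t = np.arange(1, h + 1, dtype=float)   # edge (child) depths 1..h

    E_X = float(np.sum(2.0 ** t * p * q * (1 - p) ** (t - 1)))
    E_Y = float(q * (1 - (1 - p) ** h))

    # geometric partial sums over the l/k branch depths, per ancestor depth
    def gsum(base: float) -> np.ndarray:
        # sum_{j=0}^{h-d-1} base^j for each d
        return np.array([np.sum(base ** np.arange(h - int(dd)))
                         for dd in d])

    s_2p = gsum(2 * (1 - p))     # weight 2^j (1-p)^j
    s_1p = gsum(1 - p)           # weight (1-p)^j

    pair_XX = float(p * p * q * q * np.sum((2 * (1 - p)) ** d * s_2p ** 2))
    Var_X = 2 * pair_XX + E_X - E_X ** 2
    # bound step: ((2-2p)^(h-d) - 1)^2 <= (2-2p)^(2(h-d)) for p <= 1/2,
    # applied to s_2p = ((2-2p)^(h-d) - 1)/(1-2p); degenerate at p = 1/2,
    # where the exact variance (O(h^3)) stands in for the bound
    if abs(1 - 2 * p) < 1e-9:
        Var_X_bound = Var_X
    else:
        pair_XX_bound = float(p * p * q * q / (1 - 2 * p) ** 2 * np.sum(
            (2 * (1 - p)) ** d * (2 * (1 - p)) ** (2 * (h - d))))
        Var_X_bound = 2 * pair_XX_bound + E_X - E_X ** 2

    pair_XY = float(p * p * q * q * np.sum((1 - p) ** d * s_2p * s_1p))
    E_XY = pair_XY + E_Y
    Cov_XY = E_XY - E_X * E_Y

    # pair_YY is the sum over *ordered* pairs of distinct edges
    pair_YY = float(p * p * q * q / 2.0
                    * np.sum(((1 - p) / 2.0) ** d * s_1p ** 2))
    diag_YY = float(p * q / 2.0 * np.sum(((1 - p) / 2.0) ** d))
    Var_Y = pair_YY + diag_YY - E_Y ** 2

    return {"E_X": E_X, "Var_X": Var_X, "Var_X_bound": Var_X_bound,
            "E_Y": E_Y, "E_XY": E_XY, "Cov_XY": Cov_XY, "Var_Y": Var_Y}


def llse_X_given_Y(y: float, params: TheoryParams) -> float:
    """Least-squares linear estimate of the origin count X from an observed
    leaf frequency y: E(X) + Cov(X,Y)/Var(Y) * (y - E(Y))."""
    m = closed_form_moments(params)
    if m["Var_Y"] <= 0:
        raise ValueError("Var(Y) is degenerate for these parameters")
    return m["E_X"] + m["Cov_XY"] / m["Var_Y"] * (y - m["E_Y"])


def simulate_markov(params: TheoryParams, reps: int, seed=None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo (X, Y) samples from the unmutated-cell-count Markov chain.

    N_t tracks unmutated cells (N_1 = 1); each generation A_t ~ Bin(2 N_t, p)
    cells mutate, of which B_t ~ Bin(A_t, q) take the tracked state; then
    N_{t+1} = 2 N_t - A_t.  X = sum B_t; Y = sum 2^(-t) B_t, each
    generation-t event fixing 2^(h-t) of the 2^h leaves.
    """
    if reps < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    p, q, h = params.p, params.q, params.h
    N = np.ones(reps, dtype=np.int64)
    X = np.zeros(reps, dtype=np.int64)
    Y = np.zeros(reps, dtype=float)
    for gen in range(1, h + 1):
        A = rng.binomial(2 * N, p)
        B = rng.binomial(A, q)
        X += B
        Y += B * 2.0 ** (-gen)
        N = 2 * N - A
    return X, Y


def critical_mutation_rate(q: float = 0.5,
                           heights: tuple[int, ...] = (10, 20, 30, 40),
                           p_grid: np.ndarray | None = None) -> float:
    """Largest p on the grid for which Cov(X,Y) diverges negatively with h.

    Scans p over 0.01..0.49 (step 0.01 by default): in the divergent regime
    the covariance is eventually negative with magnitude growing across the
    given heights, while above the boundary it converges to a positive
    constant.  The two-decimal boundary is the analytic threshold
    1 - 1/sqrt(2) ~ 0.29.
    """
    if p_grid is None:
        p_grid = np.round(np.arange(0.01, 0.50, 0.01), 2)
    best = None
    for p in p_grid:
        covs = [closed_form_moments(TheoryParams(p, q, h))["Cov_XY"]
                for h in heights]
        diverges = covs[-1] < 0 and all(
            abs(b) > abs(a) for a, b in zip(covs[-3:], covs[-2:]))
        if diverges:
            best = float(p)
    if best is None:
        raise RuntimeError("no divergent p found on the grid")
    return best
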