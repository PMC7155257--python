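"""Allele-table utilities: priors, mutation rates, clones, doublets.

An *allele table* is the contract boundary with the upstream read-processing
pipeline: one row per (cell barcode, integration barcode) holding the called
allele (comma-joined per-cut-site indel states) and the number of supporting
UMIs.  From it the package estimates indel-formation priors and per-character
mutation rates, calls independent clones from shared intBC sets, and detects
intra-/inter-clone doublets.

Tables are plain :class:`pandas.DataFrame` objects with columns
``cellBC``, ``intBC``, ``allele``, ``UMI``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, CharacterMatrix

REQUIRED_COLUMNS = ("cellBC", "intBC", "allele", "UMI")

#: Indel states written as "0" (or empty) in an allele are uncut sites.
_UNCUT = "0"


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"allele table lacks columns {missing}")
    if len(table) == 0:
        raise ValueError("allele table is empty")
    if (table["UMI"] < 1).any():
        raise ValueError("UMI counts must be >= 1")


def _allele_sites(allele: str) -> list[str]:
    return [s.strip() for s in str(allele).split(",")]


# ---------------------------------------------------------------------------
# priors and mutation rate
# ---------------------------------------------------------------------------

def estimate_indel_priors(table: pd.DataFrame) -> pd.Series:
    """Empirical prior q_s = f(s) / |I| for every distinct indel state.

    f(s) counts the integration barcodes in which state s was observed in at
    least one cell; |I| is the total number of integration barcodes.
    """
    _check_table(table)
    n_intbc = table["intBC"].nunique()
    seen: dict[str, set] = {}
    for intbc, allele in zip(table["intBC"], table["allele"]):
        for s in _allele_sites(allele):
            if s and s != _UNCUT:
                seen.setdefault(s, set()).add(intbc)
    q = pd.Series({s: len(bcs) / n_intbc for s, bcs in seen.items()},
                  name="prior").sort_index()
    return q


def estimate_mutation_rate(matrix: CharacterMatrix, d: int) -> float:
    """Per-generation mutation rate from the mean mutated fraction per cell.

    With n characters cut independently at rate p over d generations, the
    expected number of mutated characters per cell is K = n(1 - (1-p)^d);
    inverting gives p = 1 - (1 - K/n)^(1/d).  Dropout is independent of the
    underlying state, so K is estimated from the mutated fraction among
    *observed* (non-missing) entries, scaled to n characters; otherwise
    masked mutations would bias the rate downward.
    """
    if d < 1:
        raise ValueError("generation count must be >= 1")
    vals = matrix.values
    observed = int((vals != MISSING).sum())
    if observed == 0:
        raise ValueError("matrix has no observed entries")
    n = matrix.m
    K = n * float((vals > 0).sum()) / observed
    if K == 0:
        return 0.0
    if K >= n:
        warnings.warn("all characters saturated; mutation rate estimate "
                      "is a lower bound of 1")
        return 1.0
    return 1.0 - (1.0 - K / n) ** (1.0 / d)


# ---------------------------------------------------------------------------
# clone calling
# ---------------------------------------------------------------------------

@dataclass
class CloneAssignment:
    """Cell -> clone mapping plus each clone's intBC prevalence rates."""

    assignments: dict[str, str]
    clone_intbcs: dict[str, dict[str, float]] = field(default_factory=dict)
    junk_clone: str = "junk"

    def cells_of(self, clone: str) -> list[str]:
        return [c for c, k in self.assignments.items() if k == clone]

    @property
    def clones(self) -> list[str]:
        return sorted({k for k in self.assignments.values()
                       if k != self.junk_clone})


def call_clones(table: pd.DataFrame, junk_fraction: float = 0.005,
                min_prevalence: float = 0.10) -> CloneAssignment:
    """Iterative clone calling from shared integration-barcode sets.

    Repeatedly the intBC present in the most unassigned cells (ties broken
    lexicographically) seeds a new clone containing every unassigned cell
    carrying it, until at most ``junk_fraction`` of cells remain; those go to
    the junk clone.  Each clone's intBC set then drops barcodes present in
    fewer than ``min_prevalence`` of the clone's cells.
    """
    _check_table(table)
    cell_intbcs = table.groupby("cellBC")["intBC"].agg(set)
    unassigned = set(cell_intbcs.index)
    total = len(unassigned)
    assignments: dict[str, str] = {}
    clone_intbcs: dict[str, dict[str, float]] = {}
    k = 0
    while len(unassigned) > junk_fraction * total:
        counts: dict[str, int] = {}
        for cell in unassigned:
            for bc in cell_intbcs[cell]:
                counts[bc] = counts.get(bc, 0) + 1
        best = max(sorted(counts), key=lambda bc: counts[bc])
        members = {c for c in unassigned if best in cell_intbcs[c]}
        clone = f"clone{k}"
        for c in members:
            assignments[c] = clone
        unassigned -= members
        k += 1
    for c in unassigned:
        assignments[c] = "junk"
    for clone in {v for v in assignments.values() if v != "junk"}:
        cells = [c for c, v in assignments.items() if v == clone]
        prev: dict[str, float] = {}
        for c in cells:
            for bc in cell_intbcs[c]:
                prev[bc] = prev.get(bc, 0) + 1
        prev = {bc: n / len(cells) for bc, n in prev.items()
                if n / len(cells) >= min_prevalence}
        clone_intbcs[clone] = prev
    return CloneAssignment(assignments, clone_intbcs)


# ---------------------------------------------------------------------------
# doublet detection
# ---------------------------------------------------------------------------

def intra_doublet_scores(table: pd.DataFrame) -> pd.Series:
    """Per cell, the fraction of UMIs on alleles conflicting with the
    plurality allele of their intBC (0 for a clean singlet)."""
    _check_table(table)
    scores = {}
    for cell, sub in table.groupby("cellBC"):
        total = int(sub["UMI"].sum())
        if total == 0:
            raise ValueError(f"cell {cell} has zero UMIs")
        conflict = 0
        for _, grp in sub.groupby("intBC"):
            by_allele = grp.groupby("allele")["UMI"].sum()
            conflict += int(by_allele.sum() - by_allele.max())
        scores[cell] = conflict / total
    return pd.Series(scores, name="intra_score")


def inter_doublet_memberships(table: pd.DataFrame, clones: CloneAssignment
                              ) -> pd.DataFrame:
    """Normalized clone-membership statistic m'_{i,k} per cell.

    m_{i,k} weights each clone-k intBC by its prevalence p(j,k) among the
    cells observed to carry it, and m' normalizes so each cell's memberships
    sum to 1.
    """
    _check_table(table)
    cell_intbcs = table.groupby("cellBC")["intBC"].agg(set)
    clone_ids = clones.clones
    rows = {}
    for cell, bcs in cell_intbcs.items():
        m = {}
        for k in clone_ids:
            prev = clones.clone_intbcs.get(k, {})
            denom = sum(prev.values())
            num = sum(pjk for j, pjk in prev.items() if j in bcs)
            m[k] = num / denom if denom > 0 else 0.0
        total = sum(m.values())
        rows[cell] = {k: (v / total if total > 0 else 0.0)
                      for k, v in m.items()}
    return pd.DataFrame.from_dict(rows, orient="index")[clone_ids]


def detect_doublets(table: pd.DataFrame, clones: CloneAssignment | None = None,
                    intra_threshold: float | None = None,
                    inter_threshold: float | None = None) -> pd.DataFrame:
    """Flag suspected doublets.

    A cell is flagged when its conflicting-UMI fraction reaches
    ``intra_threshold`` or when the membership m' of its assigned clone falls
    below ``inter_threshold`` (inter mode requires a clone assignment).
    """
    intra = intra_doublet_scores(table)
    out = pd.DataFrame({"intra_score": intra})
    flagged = pd.Series(False, index=out.index)
    if intra_threshold is not None:
        flagged |= out["intra_score"] >= intra_threshold
    if inter_threshold is not None:
        if clones is None:
            raise ValueError("inter-doublet detection needs a clone assignment")
        m = inter_doublet_memberships(table, clones)
        own = pd.Series(
            {cell: (m.loc[cell, clones.assignments[cell]]
                    if clones.assignments.get(cell) in m.columns else 0.0)
             for cell in out.index})
        out["inter_membership"] = own
        flagged |= own < inter_threshold
    out["doublet"] = flagged
    return out


def simulate_doublets(table: pd.DataFrame, n: int = 200, mode: str = "intra",
                      clones: CloneAssignment | None = None, seed=None
                      ) -> tuple[pd.DataFrame, pd.Series]:
    """Inject n synthetic doublets by pooling the UMIs of two parent cells.

    ``intra`` doublets merge two cells of the same clone; ``inter`` doublets
    merge cells of different clones (a clone assignment is then required).
    Returns the augmented table and a boolean ground-truth label per cell.
    """
    if mode not in ("intra", "inter"):
        raise ValueError("mode must be 'intra' or 'inter'")
    _check_table(table)
    rng = np.random.default_rng(seed)
    cells = sorted(table["cellBC"].unique())
    if mode == "inter":
        if clones is None:
            raise ValueError("inter mode requires a clone assignment")
        by_clone = {k: clones.cells_of(k) for k in clones.clones}
        by_clone = {k: v for k, v in by_clone.items() if v}
        if len(by_clone) < 2:
            raise ValueError("inter doublets need at least two clones")
    pieces = [table]
    new_ids = []
    for i in range(n):
        if mode == "intra":
            if clones is not None:
                pool = clones.cells_of(
                    clones.clones[int(rng.integers(len(clones.clones)))])
                if len(pool) < 2:
                    pool = cells
            else:
                pool = cells
            a, b = rng.choice(len(pool), size=2, replace=False)
            pa, pb = pool[a], pool[b]
        else:
            ka, kb = rng.choice(len(by_clone), size=2, replace=False)
            ka, kb = sorted(by_clone)[ka], sorted(by_clone)[kb]
            pa = by_clone[ka][int(rng.integers(len(by_clone[ka])))]
            pb = by_clone[kb][int(rng.integers(len(by_clone[kb])))]
        did = f"doublet{i}"
        new_ids.append(did)
        merged = table[table["cellBC"].isin([pa, pb])].copy()
        merged["cellBC"] = did
        pieces.append(merged)
    augmented = pd.concat(pieces, ignore_index=True)
    labels = pd.Series(False, index=sorted(set(cells) | set(new_ids)))
    labels.loc[new_ids] = True
    return augmented, labels


def tune_doublet_threshold(datasets: list[tuple[pd.Series, pd.Series]]
                           ) -> tuple[float, float, float, float]:
    """Grid-search the decision rule maximizing the F-measure.

    Each dataset is (scores, labels) with scores oriented so that larger
    means more doublet-like (pass 1 - m' for the inter statistic).  The 21
    thresholds 0, 0.05, ..., 1.0 are scanned; precision/recall are averaged
    across datasets and the F-maximizing threshold is returned as
    (threshold, precision, recall, F).
    """
    if not datasets:
        raise ValueError("need at least one labeled dataset")
    grid = np.round(np.arange(0.0, 1.0001, 0.05), 2)
    best = None
    for thr in grid:
        precs, recs = [], []
        for scores, labels in datasets:
            labels = labels.reindex(scores.index).fillna(False).astype(bool)
            if not labels.any():
                raise ValueError("dataset has no positive labels")
            called = scores >= thr
            tp = int((called & labels).sum())
            fp = int((called & ~labels).sum())
            fn = int((~called & labels).sum())
            precs.append(tp / (tp + fp) if tp + fp else 0.0)
            recs.append(tp / (tp + fn))
        precision = float(np.mean(precs))
        recall = float(np.mean(recs))
        f = (2 * precision * recall / (precision + recall)
             if precision + recall else 0.0)
        if best is None or f > best[3]:
            best = (float(thr), precision, recall, f)
    return best


# ---------------------------------------------------------------------------
# synthetic allele-table generator
# ---------------------------------------------------------------------------

def generate_allele_table(num_clones: int = 4, cells_per_clone: int = 60,
                          intbcs_per_clone: int = 8, sites_per_intbc: int = 3,
                          num_states: int = 30, edit_rate: float = 0.5,
                          clonal_fraction: float = 0.5,
                          detection_dropout: float = 0.05,
                          intbc_leak_rate: float = 0.0, seed=None
                          ) -> tuple[pd.DataFrame, pd.Series, dict[str, str]]:
    """Synthetic allele table with known clone structure and state priors.

    Clones carry disjoint intBC sets (unless ``intbc_leak_rate`` shares some
    across clones).  Per (clone, intBC, site), with probability
    ``clonal_fraction`` the indel is fixed clonally (inherited by every
    cell); otherwise each cell edits independently.  Each site is edited with
    probability ``edit_rate``, drawing states from a geometric-decay
    distribution (so generating probabilities are rankable against estimated
    priors).  Detection dropout removes whole (cell, intBC) rows; UMI counts
    are log-normal-ish integers.

    Returns (table, generating state probabilities, cell -> clone truth).
    """
    rng = np.random.default_rng(seed)
    weights = 0.7 ** np.arange(num_states)
    state_probs = pd.Series(weights / weights.sum(),
                            index=[f"i{s}" for s in range(num_states)])

    rows = []
    truth: dict[str, str] = {}
    bc_counter = 0
    shared_pool: list[str] = []
    for k in range(num_clones):
        clone = f"clone{k}"
        intbcs = []
        for _ in range(intbcs_per_clone):
            if shared_pool and rng.uniform() < intbc_leak_rate:
                intbcs.append(shared_pool[int(rng.integers(len(shared_pool)))])
            else:
                intbcs.append(f"BC{bc_counter:04d}")
                bc_counter += 1
        shared_pool.extend(intbcs)
        clonal_site = {
            (bc, s): (state_probs.index[rng.choice(num_states,
                                                   p=state_probs.values)]
                      if rng.uniform() < edit_rate else _UNCUT)
            for bc in intbcs for s in range(sites_per_intbc)
            if rng.uniform() < clonal_fraction}
        for c in range(cells_per_clone):
            cell = f"{clone}_c{c}"
            truth[cell] = clone
            for bc in intbcs:
                if rng.uniform() < detection_dropout:
                    continue
                sites = []
                for s in range(sites_per_intbc):
                    if (bc, s) in clonal_site:
                        sites.append(clonal_site[(bc, s)])
                    elif rng.uniform() < edit_rate:
                        sites.append(state_probs.index[
                            rng.choice(num_states, p=state_probs.values)])
                    else:
                        sites.append(_UNCUT)
                umi = max(1, int(np.round(rng.lognormal(1.5, 0.6))))
                rows.append((cell, bc, ",".join(sites), umi))
    table = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
    return table, state_probs, truth
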