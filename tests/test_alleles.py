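"""Allele-table utilities: priors, rates, clones, doublets."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from lintrace.alleles import (CloneAssignment, call_clones, detect_doublets,
                              estimate_indel_priors, estimate_mutation_rate,
                              generate_allele_table,
                              inter_doublet_memberships, intra_doublet_scores,
                              simulate_doublets, tune_doublet_threshold)
from lintrace.core import CharacterMatrix, MISSING
from lintrace.sim import SimulationParams, simulate_lineage


def _table(rows):
    return pd.DataFrame(rows, columns=["cellBC", "intBC", "allele", "UMI"])


class TestIndelPriors:
    def test_formula_f_over_total(self):
        table = _table([
            ("c1", "bc1", "i5,0", 3),
            ("c2", "bc2", "i5,0", 2),
            ("c3", "bc3", "0,0", 1),
            ("c4", "bc4", "i9,0", 1),
        ])
        q = estimate_indel_priors(table)
        assert q["i5"] == pytest.approx(2 / 4)
        assert q["i9"] == pytest.approx(1 / 4)

    def test_ubiquitous_indel_has_prior_one(self):
        table = _table([(f"c{i}", f"bc{i}", "i1", 1) for i in range(5)])
        assert estimate_indel_priors(table)["i1"] == 1.0

    def test_rank_correlates_with_generating_probabilities(self):
        table, probs, _ = generate_allele_table(seed=12)
        q = estimate_indel_priors(table)
        common = [s for s in q.index if s in probs.index]
        rho = spearmanr(q[common].values, probs[common].values).statistic
        assert rho > 0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            estimate_indel_priors(_table([]))


class TestMutationRate:
    def test_no_mutations_give_zero(self):
        m = CharacterMatrix(np.zeros((5, 4), dtype=int))
        assert estimate_mutation_rate(m, 10) == 0.0

    def test_inversion_identity(self):
        # plugging the estimate back reproduces the observed fraction
        m = CharacterMatrix([[1, 0, 0, 0]] * 10)
        d = 7
        p = estimate_mutation_rate(m, d)
        assert 1 - (1 - p) ** d == pytest.approx(0.25)

    def test_saturated_matrix_warns(self):
        m = CharacterMatrix(np.ones((3, 3), dtype=int))
        with pytest.warns(UserWarning, match="saturated"):
            assert estimate_mutation_rate(m, 5) == 1.0

    def test_monotone_in_mutated_fraction(self):
        lo = CharacterMatrix([[1] + [0] * 9] * 4)
        hi = CharacterMatrix([[1, 1, 1] + [0] * 7] * 4)
        assert estimate_mutation_rate(hi, 6) > estimate_mutation_rate(lo, 6)

    def test_parameter_recovery_under_dropout(self):
        ests = []
        for seed in range(3):
            exp = simulate_lineage(SimulationParams(seed=200 + seed))
            ests.append(estimate_mutation_rate(exp.observed, 11))
        assert np.mean(ests) == pytest.approx(0.025, rel=0.10)


class TestCloneCalling:
    def test_disjoint_intbc_sets_recovered(self):
        table, _, truth = generate_allele_table(
            num_clones=3, cells_per_clone=30, detection_dropout=0.0, seed=5)
        clones = call_clones(table)
        assert len(clones.clones) == 3
        # every called clone maps to exactly one true clone
        for clone in clones.clones:
            true_labels = {truth[c] for c in clones.cells_of(clone)}
            assert len(true_labels) == 1

    def test_low_prevalence_intbc_filtered(self):
        rows = [(f"c{i}", "bcA", "i1", 1) for i in range(20)]
        rows += [("c0", "bcRare", "i2", 1)]  # 5% of the clone
        clones = call_clones(_table(rows), junk_fraction=0.0)
        assert "bcRare" not in clones.clone_intbcs["clone0"]
        assert "bcA" in clones.clone_intbcs["clone0"]

    def test_every_cell_assigned_exactly_once(self):
        table, _, truth = generate_allele_table(seed=6)
        clones = call_clones(table)
        assert set(clones.assignments) == set(table["cellBC"].unique())


class TestDoublets:
    def test_clean_cell_has_zero_intra_score(self):
        table = _table([("c1", "bc1", "i1", 5), ("c1", "bc2", "i2", 3)])
        assert intra_doublet_scores(table)["c1"] == 0.0

    def test_conflicting_umis_counted(self):
        table = _table([("c1", "bc1", "i1", 6), ("c1", "bc1", "i9", 2)])
        assert intra_doublet_scores(table)["c1"] == pytest.approx(2 / 8)

    def test_full_membership_for_own_clone(self):
        table = _table([("c1", "bc1", "i1", 1), ("c1", "bc2", "i1", 1),
                        ("c2", "bc9", "i3", 1)])
        clones = CloneAssignment(
            {"c1": "cloneA", "c2": "cloneB"},
            {"cloneA": {"bc1": 1.0, "bc2": 1.0}, "cloneB": {"bc9": 1.0}})
        m = inter_doublet_memberships(table, clones)
        assert m.loc["c1", "cloneA"] == 1.0
        assert m.loc["c1", "cloneB"] == 0.0

    def test_memberships_sum_to_one(self):
        table, _, _ = generate_allele_table(seed=7)
        clones = call_clones(table)
        m = inter_doublet_memberships(table, clones)
        sums = m.sum(axis=1)
        nonzero = sums[sums > 0]
        assert np.allclose(nonzero.values, 1.0)

    def test_doublets_score_higher_than_singlets(self):
        table, _, _ = generate_allele_table(num_clones=2, cells_per_clone=40,
                                            seed=8)
        clones = call_clones(table)
        aug, labels = simulate_doublets(table, n=40, mode="intra",
                                        clones=clones, seed=0)
        scores = intra_doublet_scores(aug)
        labels = labels.reindex(scores.index).fillna(False)
        assert scores[labels].mean() > scores[~labels].mean()

    def test_detect_flags_with_thresholds(self):
        table, _, _ = generate_allele_table(num_clones=2, cells_per_clone=30,
                                            seed=9)
        clones = call_clones(table)
        aug, labels = simulate_doublets(table, n=30, mode="intra",
                                        clones=clones, seed=1)
        out = detect_doublets(aug, clones, intra_threshold=0.1)
        flagged = set(out.index[out["doublet"]])
        true_doublets = set(labels.index[labels])
        assert len(flagged & true_doublets) / len(true_doublets) > 0.5


class TestSimulateDoublets:
    def test_zero_doublets_is_identity(self):
        table, _, _ = generate_allele_table(seed=10)
        aug, labels = simulate_doublets(table, n=0, seed=0)
        assert len(aug) == len(table)
        assert not labels.any()

    def test_doublet_umis_are_parent_sums(self):
        table = _table([("c1", "bc1", "i1", 5), ("c2", "bc2", "i2", 7)])
        aug, labels = simulate_doublets(table, n=1, mode="intra", seed=0)
        doublet_umis = aug[aug["cellBC"] == "doublet0"]["UMI"].sum()
        assert doublet_umis == 12

    def test_inter_mode_uses_different_clones(self):
        table, _, truth = generate_allele_table(num_clones=3,
                                                cells_per_clone=20, seed=11)
        clones = call_clones(table)
        with pytest.raises(ValueError):
            simulate_doublets(table, n=5, mode="inter", clones=None, seed=0)
        aug, labels = simulate_doublets(table, n=20, mode="inter",
                                        clones=clones, seed=0)
        assert labels.sum() == 20

    def test_inter_needs_two_clones(self):
        table = _table([("c1", "bc1", "i1", 1), ("c2", "bc1", "i1", 1)])
        clones = CloneAssignment({"c1": "cloneA", "c2": "cloneA"},
                                 {"cloneA": {"bc1": 1.0}})
        with pytest.raises(ValueError, match="two clones"):
            simulate_doublets(table, n=2, mode="inter", clones=clones, seed=0)


class TestThresholdTuning:
    def test_grid_has_21_points_and_perfect_separation(self):
        scores = pd.Series({"s1": 0.0, "s2": 0.1, "d1": 0.9, "d2": 1.0})
        labels = pd.Series({"s1": False, "s2": False, "d1": True, "d2": True})
        thr, prec, rec, f = tune_doublet_threshold([(scores, labels)])
        assert f == 1.0
        assert prec == 1.0 and rec == 1.0
        assert round(thr / 0.05, 6) == round(thr / 0.05)  # on the grid

    def test_returned_threshold_is_grid_maximizer(self):
        rng = np.random.default_rng(2)
        scores = pd.Series(rng.uniform(size=60),
                           index=[f"c{i}" for i in range(60)])
        labels = pd.Series(rng.uniform(size=60) < 0.3, index=scores.index)
        thr, prec, rec, f = tune_doublet_threshold([(scores, labels)])
        # independent exhaustive scan
        best_f = -1.0
        for t in np.round(np.arange(0, 1.0001, 0.05), 2):
            called = scores >= t
            tp = int((called & labels).sum())
            fp = int((called & ~labels).sum())
            fn = int((~called & labels).sum())
            p = tp / (tp + fp) if tp + fp else 0.0
            r = tp / (tp + fn)
            fmeas = 2 * p * r / (p + r) if p + r else 0.0
            best_f = max(best_f, fmeas)
        assert f == pytest.approx(best_f)

    def test_no_positive_labels_rejected(self):
        scores = pd.Series({"a": 0.3})
        labels = pd.Series({"a": False})
        with pytest.raises(ValueError, match="positive"):
            tune_doublet_threshold([(scores, labels)])
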