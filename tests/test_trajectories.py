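"""Driver orderings, transfer fit, repeated transitions, cohort clustering."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from mesoclone.trees import GL, CloneTree
from mesoclone.trajectories import (
    DRIVER_VOCABULARY,
    assign_by_decision_tree,
    cluster_cohort,
    distance_matrix,
    evolutionary_distance,
    extract_orderings,
    jackknife_stability,
    repeated_transitions,
    train_decision_tree,
    transfer_fit,
)

CHAIN = CloneTree(parents={0: GL, 1: 0, 2: 1})


class TestOrderings:
    def test_truncal_then_child(self):
        pairs = extract_orderings(CHAIN, {"BAP1": 0, "NF2": 1})
        assert pairs == frozenset({(GL, "BAP1"), ("BAP1", "NF2")})

    def test_single_truncal_driver(self):
        assert extract_orderings(CHAIN, {"BAP1": 0}) == frozenset({(GL, "BAP1")})

    def test_co_resident_drivers_unordered(self):
        pairs = extract_orderings(CHAIN, {"BAP1": 0, "SETD2": 0})
        assert pairs == frozenset({(GL, "BAP1"), (GL, "SETD2")})

    def test_transitive_ancestry(self):
        pairs = extract_orderings(CHAIN, {"BAP1": 0, "NF2": 1, "-22q": 2})
        assert ("BAP1", "-22q") in pairs and ("NF2", "-22q") in pairs

    def test_unknown_node_raises(self):
        with pytest.raises(ValueError):
            extract_orderings(CHAIN, {"BAP1": 99})


def cand(orderings, bic=0.0):
    return dict(tree=CHAIN, orderings=frozenset(orderings), bic=bic)


class TestTransferFit:
    def test_unique_candidates_simple_count(self):
        candidates = {
            "P1": [cand({(GL, "BAP1")})],
            "P2": [cand({(GL, "BAP1")})],
            "P3": [cand({(GL, "NF2")})],
        }
        model = transfer_fit(candidates)
        assert model.transition_counts[(GL, "BAP1")] == 2
        assert model.transition_counts[(GL, "NF2")] == 1

    def test_ambiguous_patient_follows_cohort_support(self):
        shared = {(GL, "BAP1"), ("BAP1", "NF2")}
        alt = {(GL, "NF2"), ("NF2", "BAP1")}
        candidates = {f"P{i}": [cand(shared)] for i in range(5)}
        # ambiguous patient: both orderings available, contrarian one has
        # better BIC — cohort support must win
        candidates["PX"] = [cand(alt, bic=0.0), cand(shared, bic=1.0)]
        model = transfer_fit(candidates)
        assert model.orderings["PX"] == frozenset(shared)

    def test_permutation_invariant_counts(self):
        candidates = {
            "A": [cand({(GL, "BAP1")})],
            "B": [cand({(GL, "NF2")})],
        }
        renamed = {"Z": candidates["A"], "Y": candidates["B"]}
        assert (transfer_fit(candidates).transition_counts
                == transfer_fit(renamed).transition_counts)

    def test_empty_candidate_set_raises(self):
        with pytest.raises(ValueError):
            transfer_fit({"P1": []})

    def test_support_objective_monotone(self):
        """Total within-cohort support never decreases across refits."""
        rng = np.random.default_rng(4)
        events = ["BAP1", "NF2", "-22q", "SETD2"]
        candidates = {}
        for i in range(12):
            opts = []
            for _ in range(3):
                chosen = rng.choice(events, size=2, replace=False)
                opts.append(cand({(GL, chosen[0]), (chosen[0], chosen[1])},
                                 bic=float(rng.normal())))
            candidates[f"P{i:02d}"] = opts
        model = transfer_fit(candidates, max_iter=10)
        w = model.transition_counts
        # fixed point: no patient can unilaterally improve its cohort support
        for p, opts in candidates.items():
            w_others = w.copy()
            for pair in model.orderings[p]:
                w_others[pair] -= 1
            selected = sum(w_others[pair] for pair in model.orderings[p])
            best_alt = max(
                sum(w_others[pair] for pair in o["orderings"]) for o in opts
            )
            assert selected >= best_alt


class TestRepeated:
    def test_rule_boundary(self):
        w = Counter({(GL, "BAP1"): 5, (GL, "NF2"): 4, (GL, "SETD2"): 3})
        rep = repeated_transitions(w)
        assert (GL, "BAP1") in rep and (GL, "NF2") in rep
        assert (GL, "SETD2") not in rep

    def test_empty(self):
        assert repeated_transitions(Counter()) == set()


class TestDistance:
    def test_identical_and_disjoint(self):
        a = frozenset({(GL, "BAP1")})
        b = frozenset({(GL, "NF2")})
        assert evolutionary_distance(a, a) == 0.0
        assert evolutionary_distance(a, b) == 1.0
        assert evolutionary_distance(frozenset(), frozenset()) == 0.0

    def test_jaccard_arithmetic(self):
        a = frozenset({("x", "a"), ("x", "b")})
        b = frozenset({("x", "a")})
        assert evolutionary_distance(a, b) == pytest.approx(0.5)

    @given(
        st.lists(st.sampled_from([("g", x) for x in "abcdef"]), max_size=6),
        st.lists(st.sampled_from([("g", x) for x in "abcdef"]), max_size=6),
        st.lists(st.sampled_from([("g", x) for x in "abcdef"]), max_size=6),
    )
    @settings(max_examples=200, deadline=None)
    def test_pseudo_metric(self, la, lb, lc):
        a, b, c = frozenset(la), frozenset(lb), frozenset(lc)
        dab = evolutionary_distance(a, b)
        assert dab == evolutionary_distance(b, a)
        assert evolutionary_distance(a, a) == 0.0
        assert dab <= evolutionary_distance(a, c) + evolutionary_distance(c, b) + 1e-12


class TestClusterCohort:
    def make_block_distances(self, sizes):
        n = sum(sizes)
        d = np.ones((n, n))
        start = 0
        for s in sizes:
            d[start:start + s, start:start + s] = 0.0
            start += s
        np.fill_diagonal(d, 0.0)
        names = [f"P{i}" for i in range(n)]
        return pd.DataFrame(d, index=names, columns=names)

    def test_exact_recovery_of_blocks(self):
        dist = self.make_block_distances([5, 5, 5, 5, 5])
        labels = cluster_cohort(dist, k=5)
        truth = np.repeat(range(5), 5)
        got = [labels[f"P{i}"] for i in range(25)]
        assert adjusted_rand_score(truth, got) == 1.0

    def test_k_one(self):
        dist = self.make_block_distances([4, 4])
        assert set(cluster_cohort(dist, k=1).values()) == {1}

    def test_k_exceeds_n(self):
        with pytest.raises(ValueError):
            cluster_cohort(self.make_block_distances([2]), k=5)

    def test_labels_ordered_by_complexity(self):
        dist = self.make_block_distances([3, 3])
        orderings = {f"P{i}": frozenset({("g", str(j)) for j in range(1)})
                     for i in range(3)}
        orderings.update({f"P{i}": frozenset({("g", str(j)) for j in range(4)})
                          for i in range(3, 6)})
        labels = cluster_cohort(dist, k=2, orderings=orderings)
        assert labels["P0"] == 1 and labels["P5"] == 2


class TestJackknife:
    def archetype_candidates(self, n=25):
        archetypes = [
            {(GL, "BAP1"), (GL, "-3p21")},
            {(GL, "-chr4"), (GL, "FBXW7")},
            {(GL, "-chr4"), (GL, "9p21-loss"), ("-chr4", "NF2")},
            {(GL, "BAP1"), (GL, "9p21-loss"), ("BAP1", "-22q")},
            {(GL, "BAP1"), (GL, "-chr4"), (GL, "SETD2"), ("BAP1", "NF2"),
             ("-chr4", "-22q")},
        ]
        return {
            f"P{i:02d}": [cand(archetypes[i % 5])] for i in range(n)
        }

    def test_separable_archetypes_stable(self):
        candidates = self.archetype_candidates()
        res = jackknife_stability(candidates, k=5, leave_fraction=0.1,
                                  reps=30, seed=0)
        assert all(v >= 0.8 for v in res["cluster_stability"].values())

    def test_fixed_seed_reproducible(self):
        candidates = self.archetype_candidates(10)
        a = jackknife_stability(candidates, k=2, reps=5, seed=3)
        b = jackknife_stability(candidates, k=2, reps=5, seed=3)
        assert a["co_clustering"].equals(b["co_clustering"])
        assert a["cluster_stability"] == b["cluster_stability"]

    def test_invalid_leave_fraction(self):
        with pytest.raises(ValueError):
            jackknife_stability(self.archetype_candidates(10), leave_fraction=0.9)


class TestDecisionTree:
    def test_resubstitution_accuracy_on_separable_profiles(self):
        profiles, labels = {}, {}
        patterns = [
            {"BAP1", "-3p21"},
            {"-chr4", "FBXW7"},
            {"-chr4", "9p21-loss", "NF2"},
            {"BAP1", "-3p21", "9p21-loss", "-22q"},
            {"BAP1", "-chr4", "9p21-loss", "NF2", "-22q", "SETD2"},
        ]
        for i in range(25):
            profiles[f"P{i}"] = patterns[i % 5]
            labels[f"P{i}"] = i % 5 + 1
        clf = train_decision_tree(profiles, labels, seed=0)
        correct = sum(
            assign_by_decision_tree(profiles[p], clf) == labels[p]
            for p in profiles
        )
        assert correct / len(profiles) >= 0.9

    def test_unseen_features_ignored(self):
        profiles = {"A": {"BAP1"}, "B": {"NF2"}}
        labels = {"A": 1, "B": 2}
        clf = train_decision_tree(profiles, labels, seed=0)
        assert assign_by_decision_tree({"BAP1", "NOT_A_DRIVER"}, clf) == 1

    def test_identical_profiles_identical_labels(self):
        profiles = {"A": {"BAP1"}, "B": {"NF2"}}
        clf = train_decision_tree(profiles, {"A": 1, "B": 2}, seed=0)
        assert (assign_by_decision_tree({"NF2"}, clf)
                == assign_by_decision_tree({"NF2"}, clf))
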