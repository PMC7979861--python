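"""Tree enumeration vs brute force, BIC selection, topology, SCNA calls."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mesoclone.simulate import ARM_TABLE, assign_region_ccfs, simulate_clone_tree
from mesoclone.trees import (
    GL,
    CloneTree,
    call_scna_events,
    classify_topology,
    detect_double_hits,
    enumerate_feasible_trees,
    score_and_select,
)


def brute_force_feasible(means: np.ndarray, root: int, tol: float):
    """Oracle: filter all k^(k-1) parent vectors by acyclicity + sum rule."""
    k = means.shape[0]
    others = [v for v in range(k) if v != root]
    out = set()
    for choice in itertools.product(range(k), repeat=k - 1):
        parents = {root: -1}
        parents.update(dict(zip(others, choice)))
        # every node must reach the root without revisiting a node
        ok = True
        for v in others:
            seen, u = set(), v
            while u != root:
                if u in seen:
                    ok = False
                    break
                seen.add(u)
                u = parents[u]
            if not ok:
                break
        if not ok:
            continue
        child_sum = np.zeros_like(means)
        for v in others:
            child_sum[parents[v]] += means[v]
        if np.all(child_sum <= means + tol):
            out.add(tuple(parents[v] for v in range(k)))
    return out


class TestEnumeration:
    def test_spec_three_cluster_instance(self):
        cm = pd.DataFrame(
            {"R1": [1.0, 0.6, 0.3], "R2": [1.0, 0.5, 0.4]}, index=["T", "A", "B"]
        )
        ts = enumerate_feasible_trees(cm, tol=0.05)
        parent_sets = {frozenset(t.parents.items()) for t in ts}
        chain = frozenset({"T": GL, "A": "T", "B": "A"}.items())
        star = frozenset({"T": GL, "A": "T", "B": "T"}.items())
        bad_chain = frozenset({"T": GL, "B": "T", "A": "B"}.items())
        assert chain in parent_sets
        assert star in parent_sets
        assert bad_chain not in parent_sets
        assert len(ts) == 2

    def test_single_cluster_trivial_tree(self):
        cm = pd.DataFrame({"R1": [1.0]}, index=["T"])
        ts = enumerate_feasible_trees(cm)
        assert len(ts) == 1 and ts[0].parents == {"T": GL}

    def test_requires_unique_clonal_cluster(self):
        cm = pd.DataFrame({"R1": [0.6, 0.3]}, index=["A", "B"])
        with pytest.raises(ValueError, match="truncal"):
            enumerate_feasible_trees(cm)

    def test_k_max_guard(self):
        k = 10
        cm = pd.DataFrame({"R1": [1.0] + [0.5 / k] * (k - 1)})
        with pytest.raises(ValueError, match="exhaustive"):
            enumerate_feasible_trees(cm, k_max=9)

    @pytest.mark.parametrize("k", [3, 4, 5, 6])
    def test_matches_brute_force_oracle(self, k, rng):
        """Exhaustive enumeration equals parent-vector filtering, 25 random
        instances per cluster count."""
        for _ in range(25):
            parents = simulate_clone_tree(k, rng)
            means = assign_region_ccfs(parents, 3, rng)
            cm = pd.DataFrame(means, index=range(k))
            got = {t.parent_vector(list(range(k))) for t in
                   enumerate_feasible_trees(cm, tol=0.05, truncal=0)}
            expected = brute_force_feasible(means, root=0, tol=0.05)
            assert got == expected


class TestSelection:
    def test_noiseless_planted_tree_has_zero_rss(self, rng):
        parents = np.array([-1, 0, 1, 0])
        means = assign_region_ccfs(parents, 3, rng)
        cm = pd.DataFrame(means, index=range(4))
        ts = enumerate_feasible_trees(cm, tol=1e-9, truncal=0)
        best = score_and_select(ts, cm)
        planted = tuple(parents)
        assert best.rss == pytest.approx(0.0, abs=1e-8)
        assert best.parent_vector(list(range(4))) == planted or best.rss <= min(
            t.rss for t in ts
        )

    def test_selected_rss_not_above_any_feasible(self, rng):
        parents = simulate_clone_tree(4, rng)
        means = assign_region_ccfs(parents, 2, rng)
        noisy = np.clip(means + rng.normal(0, 0.03, means.shape), 0, 1)
        noisy[0] = 1.0
        cm = pd.DataFrame(noisy, index=range(4))
        ts = enumerate_feasible_trees(cm, tol=0.2, truncal=0)
        best = score_and_select(ts, cm)
        assert best.rss <= min(t.rss for t in ts) + 1e-9

    def test_projection_respects_sum_rule(self, rng):
        cm = pd.DataFrame(
            {"R1": [1.0, 0.7, 0.6], "R2": [1.0, 0.8, 0.5]}, index=["T", "A", "B"]
        )
        ts = enumerate_feasible_trees(cm, tol=0.35, truncal="T")
        for t in score_and_select(ts, cm), :
            f = t.fitted_ccf
            for node in t.clusters:
                kids = t.children(node)
                if kids:
                    assert np.all(
                        f.loc[kids].sum(axis=0) <= f.loc[node] + 1e-6
                    )

    def test_tie_breaks_lexicographically(self):
        # both chain and star fit exactly: tie on RSS and edge count
        cm = pd.DataFrame(
            {"R1": [1.0, 0.6, 0.3], "R2": [1.0, 0.5, 0.4]}, index=["T", "A", "B"]
        )
        ts = enumerate_feasible_trees(cm, tol=0.05)
        best = score_and_select(ts, cm)
        assert len({t.rss for t in ts}) == 1  # genuine tie
        order = list(cm.index)  # implementation's canonical order
        vectors = sorted(t.parent_vector(order) for t in ts)
        assert best.parent_vector(order) == vectors[0]

    def test_empty_candidate_list(self):
        with pytest.raises(ValueError):
            score_and_select([], pd.DataFrame({"R1": [1.0]}, index=["T"]))


class TestTopology:
    def test_chain_is_linear(self):
        t = CloneTree(parents={"T": GL, "A": "T", "B": "A"})
        assert classify_topology(t) == "linear"

    def test_truncal_star_is_linear(self):
        t = CloneTree(parents={"T": GL, "A": "T", "B": "T"})
        assert classify_topology(t) == "linear"

    def test_subclonal_branch_is_branched(self):
        t = CloneTree(parents={"T": GL, "A": "T", "B": "A", "C": "A"})
        assert classify_topology(t) == "branched"

    def test_invariant_under_relabelling(self):
        t1 = CloneTree(parents={"T": GL, "A": "T", "B": "A", "C": "A"})
        t2 = CloneTree(parents={"X": GL, "Q": "X", "Z": "Q", "W": "Q"})
        assert classify_topology(t1) == classify_topology(t2)


def seg(region, chrom, start, end, major, minor, lost=""):
    return dict(patient="P1", region=region, chrom=chrom, start=start, end=end,
                major=major, minor=minor, lost_allele=lost)


class TestScnaEvents:
    def test_whole_chromosome_loss_sixty_percent(self):
        length = int(ARM_TABLE.loc[ARM_TABLE["chrom"] == "chr4", "end"].max())
        cut = int(0.62 * length)
        segs = pd.DataFrame([
            seg("R1", "chr4", 0, cut, 1, 0, "A"),
            seg("R1", "chr4", cut, length, 1, 1),
        ])
        classes = {e.event_class for e in call_scna_events(segs, ARM_TABLE)}
        assert "chr_loss" in classes

    def test_fiftynine_percent_not_chromosome_loss(self):
        length = int(ARM_TABLE.loc[ARM_TABLE["chrom"] == "chr4", "end"].max())
        cut = int(0.59 * length)
        segs = pd.DataFrame([
            seg("R1", "chr4", 0, cut, 1, 0, "A"),
            seg("R1", "chr4", cut, length, 1, 1),
        ])
        classes = {e.event_class for e in call_scna_events(segs, ARM_TABLE)}
        assert "chr_loss" not in classes

    def test_cnloh_and_homdel_and_gain(self):
        segs = pd.DataFrame([
            seg("R1", "chr9", 0, 10_000_000, 2, 0, "A"),
            seg("R1", "chr9", 21_000_000, 23_000_000, 0, 0),
            seg("R1", "chr5", 0, 50_000_000, 2, 1),
            seg("R1", "chr5", 50_000_000, 100_000_000, 3, 1),
        ])
        classes = {e.event_class for e in call_scna_events(segs, ARM_TABLE)}
        assert {"cnloh", "homozygous_deletion", "gain", "amplification"} <= classes

    def test_msai_reciprocal_losses(self):
        segs = pd.DataFrame([
            seg("R1", "chr10", 88_000_000, 92_000_000, 1, 0, "A"),
            seg("R2", "chr10", 88_000_000, 92_000_000, 1, 0, "B"),
        ])
        events = call_scna_events(segs, ARM_TABLE)
        msai = [e for e in events if e.event_class == "msai"]
        assert len(msai) == 1 and set(msai[0].regions) == {"R1", "R2"}

    def test_same_allele_not_msai(self):
        segs = pd.DataFrame([
            seg("R1", "chr10", 88_000_000, 92_000_000, 1, 0, "A"),
            seg("R2", "chr10", 88_000_000, 92_000_000, 1, 0, "A"),
        ])
        assert not [e for e in call_scna_events(segs, ARM_TABLE)
                    if e.event_class == "msai"]

    def test_clonality_requires_all_regions(self):
        segs = pd.DataFrame([
            seg("R1", "chr22", 15_000_000, 51_000_000, 1, 0, "A"),
            seg("R2", "chr22", 15_000_000, 51_000_000, 1, 0, "A"),
            seg("R2", "chr3", 0, 1_000_000, 1, 1),
        ])
        loss = [e for e in call_scna_events(segs, ARM_TABLE)
                if e.event_class == "loss" and e.location.startswith("chr22")]
        assert loss[0].clonality == "clonal"

    def test_overlapping_segments_rejected(self):
        segs = pd.DataFrame([
            seg("R1", "chr1", 0, 10, 1, 1),
            seg("R1", "chr1", 5, 20, 1, 0),
        ])
        with pytest.raises(ValueError, match="overlapping"):
            call_scna_events(segs, ARM_TABLE)


class TestDoubleHits:
    GENES = {"BAP1": ("chr3", 52_400_000, 52_440_000)}

    def test_mutation_plus_loss(self):
        muts = pd.DataFrame([
            dict(gene="BAP1", mutation="m1", clonality="clonal", deleterious=True)
        ])
        segs = pd.DataFrame([seg("R1", "chr3", 46_000_000, 54_000_000, 1, 0, "A")])
        out = detect_double_hits(muts, segs, self.GENES)
        assert out["BAP1"]["double_hit"]
        assert out["BAP1"]["mechanism"] == "mutation_plus_loss"
        assert out["BAP1"]["timing"] == "clonal"

    def test_mutation_only_single_hit(self):
        muts = pd.DataFrame([
            dict(gene="BAP1", mutation="m1", clonality="clonal", deleterious=True)
        ])
        segs = pd.DataFrame([seg("R1", "chr3", 46_000_000, 54_000_000, 1, 1)])
        assert not detect_double_hits(muts, segs, self.GENES)["BAP1"]["double_hit"]

    def test_homozygous_deletion_alone(self):
        muts = pd.DataFrame(columns=["gene", "mutation", "clonality", "deleterious"])
        segs = pd.DataFrame([seg("R1", "chr3", 52_000_000, 53_000_000, 0, 0)])
        out = detect_double_hits(muts, segs, self.GENES)
        assert out["BAP1"]["double_hit"]
        assert out["BAP1"]["mechanism"] == "homozygous_deletion"

    def test_two_mutations(self):
        muts = pd.DataFrame([
            dict(gene="BAP1", mutation="m1", clonality="clonal", deleterious=True),
            dict(gene="BAP1", mutation="m2", clonality="subclonal", deleterious=True),
        ])
        segs = pd.DataFrame([seg("R1", "chr3", 46_000_000, 54_000_000, 1, 1)])
        out = detect_double_hits(muts, segs, self.GENES)
        assert out["BAP1"]["mechanism"] == "two_mutations"
        assert out["BAP1"]["timing"] == "subclonal"
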