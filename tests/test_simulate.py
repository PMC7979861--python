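"""Synthetic cohort generator: tree uniformity, sum rule, read model."""

import itertools

import numpy as np
import pytest
from scipy.stats import chisquare

from mesoclone.clonality import expected_vaf, mutation_copy_number
from mesoclone.simulate import (
    SimulationConfig,
    assign_region_ccfs,
    simulate_clone_tree,
    simulate_cohort,
    simulate_reads,
)


def enumerate_rooted_trees(k):
    """Oracle: all rooted labelled trees on k nodes (root 0) by filtering the
    k^(k-1) parent vectors."""
    trees = []
    for choice in itertools.product(range(k), repeat=k - 1):
        parents = np.array([-1] + list(choice))
        ok = True
        for v in range(1, k):
            seen, u = set(), v
            while u != 0 and ok:
                if u in seen or parents[u] == v:
                    ok = False
                seen.add(u)
                u = parents[u]
        if ok:
            trees.append(tuple(parents))
    return trees


class TestCloneTree:
    def test_single_node(self, rng):
        assert list(simulate_clone_tree(1, rng)) == [-1]

    def test_two_nodes_forced_edge(self, rng):
        for _ in range(5):
            assert list(simulate_clone_tree(2, rng)) == [-1, 0]

    def test_invalid_k(self, rng):
        with pytest.raises(ValueError):
            simulate_clone_tree(0, rng)

    def test_uniform_over_labelled_trees_k4(self, rng):
        all_trees = enumerate_rooted_trees(4)
        assert len(all_trees) == 16  # Cayley: 4^(4-2)
        counts = {t: 0 for t in all_trees}
        for _ in range(10_000):
            counts[tuple(simulate_clone_tree(4, rng))] += 1
        stat, p = chisquare(list(counts.values()))
        assert p > 0.01


class TestRegionCcfs:
    def test_chain_respects_parent(self, rng):
        ccf = assign_region_ccfs(np.array([-1, 0]), 2, rng)
        assert np.allclose(ccf[0], 1.0)
        assert np.all(ccf[1] <= ccf[0])

    def test_star_sum_rule(self, rng):
        ccf = assign_region_ccfs(np.array([-1, 0, 0]), 3, rng)
        assert np.all(ccf[1] + ccf[2] <= 1.0 + 1e-12)

    def test_no_sum_rule_violations_1000_draws(self, rng):
        for _ in range(1000):
            k = int(rng.integers(1, 7))
            parents = simulate_clone_tree(k, rng)
            ccf = assign_region_ccfs(parents, int(rng.integers(1, 6)), rng)
            assert np.allclose(ccf[0], 1.0)
            for v in range(k):
                kids = [u for u in range(k) if parents[u] == v]
                if kids:
                    assert np.all(
                        ccf[kids].sum(axis=0) <= ccf[v] + 1e-12
                    )

    def test_spatial_heterogeneity_guaranteed(self, rng):
        for _ in range(50):
            parents = simulate_clone_tree(4, rng)
            ccf = assign_region_ccfs(parents, 4, rng)
            assert np.any(ccf[1:] == 0.0)


class TestReadSimulation:
    def test_empirical_vaf_matches_expectation(self, rng):
        """Binomial draws centre on the copy-number-aware expected VAF."""
        p, cn, m, cc, depth = 0.5, 3, 2, 0.5, 250.0
        ev = expected_vaf(p, m, cc, cn)
        assert ev == pytest.approx(0.2)
        ccf_matrix = np.array([[cc]])
        t_depth, t_alt, _, _ = simulate_reads(
            ccf_matrix, np.zeros(10_000, dtype=int), np.full(10_000, m),
            np.full((10_000, 1), cn), p, depth, rng,
        )
        vafs = t_alt[:, 0] / t_depth[:, 0]
        se = np.sqrt(ev * (1 - ev) / depth) / np.sqrt(10_000)
        assert abs(vafs.mean() - ev) < 3 * se

    def test_impossible_configuration_raises(self, rng):
        with pytest.raises(ValueError):
            simulate_reads(
                np.array([[1.0]]), np.array([0]), np.array([3]),
                np.full((1, 1), 2), 1.0, 100.0, rng,
            )

    def test_round_trip_noiseless(self):
        """Applying the copy-number relation to a noiseless VAF recovers m*CCF."""
        for p, cn, m, cc in [(0.4, 2, 1, 0.7), (0.8, 3, 2, 0.9), (1.0, 2, 1, 1.0)]:
            vaf = expected_vaf(p, m, cc, cn)
            assert mutation_copy_number(vaf, p, cn) == pytest.approx(m * cc)


class TestCohort:
    def test_determinism(self):
        cfg = SimulationConfig(n_patients=3, n_mutations_range=(20, 30), seed=5)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        assert a.variants.equals(b.variants)
        assert a.segments.equals(b.segments)
        assert a.clinical.equals(b.clinical)
        assert a.hla_coverage.equals(b.hla_coverage)

    def test_region_sample_count(self, small_cohort):
        per_patient = small_cohort.variants.groupby("patient")["region"].nunique()
        assert per_patient.between(4, 5).all()

    def test_truncal_ccf_and_sum_rule_in_truth(self, small_cohort):
        for t in small_cohort.truth.patients.values():
            assert np.allclose(t.ccf[0], 1.0)
            for v in range(len(t.parents)):
                kids = [u for u in range(len(t.parents)) if t.parents[u] == v]
                if kids:
                    assert np.all(t.ccf[kids].sum(axis=0) <= t.ccf[v] + 1e-9)

    def test_hazard_ratio_reflected_in_survival(self):
        """A 2x hazard halves median survival (exponential closed form)."""
        from mesoclone.simulate import Archetype

        arch = (
            Archetype("slow", ("BAP1",), ()),
            Archetype("fast", ("NF2",), ()),
        )
        cfg = SimulationConfig(
            n_patients=400, n_mutations_range=(1, 2), n_regions=(1, 1),
            driver_archetypes=arch, hazard_by_archetype=(0.001, 0.002),
            censor_time=1e9, hla_positions=0, seed=7,
        )
        cohort = simulate_cohort(cfg)
        med = cohort.clinical.groupby("archetype")["time"].median()
        assert med["fast"] / med["slow"] == pytest.approx(0.5, rel=0.25)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(depth=0)
        with pytest.raises(ValueError):
            SimulationConfig(purity_range=(0, 0.5))
        with pytest.raises(ValueError):
            SimulationConfig(hazard_by_archetype=(0.1,))
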