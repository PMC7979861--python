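"""Association and survival statistics against independent small-n oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from mesoclone.stats import (
    clinical_indices,
    fisher_2x2,
    km_logrank,
    kruskal,
    mann_whitney,
    shapiro_gate,
    spearman,
)


def mann_whitney_exact_oracle(x, y):
    """Brute force: enumerate all group assignments of the pooled sample."""
    pooled = list(x) + list(y)
    n_x = len(x)
    u_obs = sum(1 for xi in x for yi in y if xi > yi) + \
        0.5 * sum(1 for xi in x for yi in y if xi == yi)
    us = []
    for combo in itertools.combinations(range(len(pooled)), n_x):
        gx = [pooled[i] for i in combo]
        gy = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = sum(1 for xi in gx for yi in gy if xi > yi) + \
            0.5 * sum(1 for xi in gx for yi in gy if xi == yi)
        us.append(u)
    mu = len(x) * len(y) / 2
    extreme = sum(1 for u in us if abs(u - mu) >= abs(u_obs - mu) - 1e-12)
    return extreme / len(us)


class TestMannWhitney:
    def test_separated_groups_exact(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res["U"] == 0.0
        assert res["p"] == pytest.approx(0.1)  # 2/C(6,3)

    def test_identical_samples(self):
        assert mann_whitney([1, 2, 3], [1, 2, 3])["p"] == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            x = list(rng.choice(100, size=5, replace=False))
            y = list(rng.choice(200, size=6, replace=False) + 100)
            res = mann_whitney(x, y)
            assert res["p"] == pytest.approx(mann_whitney_exact_oracle(x, y),
                                             abs=1e-9)

    def test_exact_vs_approximation_agree(self, rng):
        import scipy.stats as ss

        diffs = []
        for _ in range(20):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            exact = mann_whitney(list(x), list(y))["p"]
            approx = ss.mannwhitneyu(x, y, alternative="two-sided",
                                     method="asymptotic").pvalue
            diffs.append(abs(exact - approx))
        assert np.mean(diffs) < 0.01

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1])


def fisher_oracle(a, b, c, d):
    """Sum hypergeometric probabilities <= P(observed), fixed margins."""
    r1, c1, n = a + b, a + c, a + b + c + d

    def prob(a_):
        return (math.comb(c1, a_) * math.comb(n - c1, r1 - a_)
                / math.comb(n, r1))

    p_obs = prob(a)
    return sum(prob(a_) for a_ in range(max(0, r1 - (n - c1)), min(r1, c1) + 1)
               if prob(a_) <= p_obs + 1e-12)


class TestFisher:
    def test_infinite_odds_ratio_case(self):
        res = fisher_2x2(4, 0, 1, 6)
        assert np.isinf(res["odds_ratio"])
        assert res["p"] == pytest.approx(5 / 330)

    def test_balanced_table(self):
        res = fisher_2x2(1, 1, 1, 1)
        assert res["odds_ratio"] == 1.0 and res["p"] == 1.0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(20):
            a, b, c, d = rng.integers(0, 6, size=4)
            if (a + b + c + d) == 0:
                continue
            assert fisher_2x2(a, b, c, d)["p"] == pytest.approx(
                fisher_oracle(a, b, c, d), abs=1e-9
            )

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fisher_2x2(0, 0, 0, 0)


class TestKmLogrank:
    def test_identical_groups_null(self):
        df = pd.DataFrame({
            "time": [3, 5, 8, 10] * 2, "event": [1, 1, 1, 0] * 2,
            "group": ["a"] * 4 + ["b"] * 4,
        })
        res = km_logrank(df)
        assert res["chisq"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)
        assert res["hr"] == pytest.approx(1.0)

    def test_km_curve_properties(self):
        df = pd.DataFrame({
            "time": [1, 2, 3, 4, 5, 6], "event": [1, 0, 1, 1, 0, 1],
            "group": ["a"] * 3 + ["b"] * 3,
        })
        res = km_logrank(df)
        for curve in res["km_curves"].values():
            vals = curve.iloc[:, 0].to_numpy()
            assert vals[0] == 1.0
            assert np.all(np.diff(vals) <= 1e-12)

    def test_hr_recovery_exponential(self, rng):
        hits = 0
        for _ in range(30):
            t1 = rng.exponential(1.0, 200)
            t2 = rng.exponential(0.5, 200)
            df = pd.DataFrame({
                "time": np.concatenate([t1, t2]), "event": 1,
                "group": ["a"] * 200 + ["b"] * 200,
            })
            hits += 1.6 <= km_logrank(df)["hr"] <= 2.5
        assert hits / 30 >= 0.9

    def test_null_rejection_rate(self, rng):
        """Log-rank under identical exponential arms rejects <= ~5%."""
        rejections = 0
        n_sims = 300
        for _ in range(n_sims):
            df = pd.DataFrame({
                "time": rng.exponential(1.0, 60), "event": 1,
                "group": ["a"] * 30 + ["b"] * 30,
            })
            rejections += km_logrank(df)["p"] < 0.05
        assert rejections / n_sims <= 0.08

    def test_requires_two_groups_and_events(self):
        with pytest.raises(ValueError):
            km_logrank(pd.DataFrame({"time": [1, 2], "event": [1, 1],
                                     "group": ["a", "a"]}))
        with pytest.raises(ValueError):
            km_logrank(pd.DataFrame({"time": [1, 2], "event": [0, 0],
                                     "group": ["a", "b"]}))


class TestOtherStats:
    def test_spearman_monotone(self):
        res = spearman([1, 2, 3, 4], [10, 20, 30, 400])
        assert res["rho"] == pytest.approx(1.0)

    def test_spearman_matches_rank_formula(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        rx = pd.Series(x).rank().to_numpy()
        ry = pd.Series(y).rank().to_numpy()
        d2 = np.sum((rx - ry) ** 2)
        rho_formula = 1 - 6 * d2 / (10 * 99)
        assert spearman(x, y)["rho"] == pytest.approx(rho_formula)

    def test_kruskal_identical_groups(self):
        assert kruskal([1, 1], [1, 1], [1, 1])["H"] == 0.0

    def test_shapiro_gate_routes(self, rng):
        assert shapiro_gate(rng.normal(size=200)) == "normal"
        assert shapiro_gate(rng.exponential(size=200)) == "skewed"

    def test_clinical_indices(self):
        ci = clinical_indices(4, 2, 300)
        assert ci.nlr == 2.0 and ci.plr == 150.0
        with pytest.raises(ValueError):
            clinical_indices(4, 0, 300)

    def test_nlr_scale_invariance(self):
        a = clinical_indices(4, 2, 300)
        b = clinical_indices(4000, 2000, 300)
        assert a.nlr == b.nlr

    def test_indices_match_hand_computation(self, rng):
        for _ in range(10):
            n, l, p = rng.uniform(1, 10), rng.uniform(0.5, 4), rng.uniform(100, 500)
            ci = clinical_indices(n, l, p)
            assert ci.nlr == pytest.approx(n / l)
            assert ci.plr == pytest.approx(p / l)
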