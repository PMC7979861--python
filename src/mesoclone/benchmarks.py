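"""Calibration and recovery benchmarks run against simulator ground truth.

Each function builds its own synthetic inputs with a caller-supplied seed,
runs the corresponding pipeline component, and returns the recovery or
calibration metric. These back both the acceptance checks and the
reproducibility script.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import selection, stats, trajectories, trees
from .clonality import cluster_ccfs, estimate_ccf_table, mutation_copy_number
from .filters import VariantCall, consensus_filter_snv, force_call
from .immune import HlaAlleleCoverage, call_hla_loh
from .simulate import SimulationConfig, simulate_clone_tree, simulate_cohort
from .trees import GL, CloneTree, enumerate_feasible_trees, score_and_select

__all__ = [
    "ccf_recovery_rmse",
    "clustering_recovery_ari",
    "tree_oracle_agreement",
    "tree_recovery_rate",
    "filter_fixture",
    "dnds_null_and_power",
    "signature_mixture_l1",
    "trajectory_recovery",
    "hla_loh_calibration",
    "hr_recovery_rate",
]


# ---------------------------------------------------------------------------
# CCF recovery on the bundled cohort
# ---------------------------------------------------------------------------

def ccf_recovery_rmse(seed: int = 0, gibbs_iters: int = 300,
                      gibbs_burnin: int = 50) -> dict:
    """RMSE of estimated vs true CCF on the default 22-patient cohort.

    A mutation's estimated CCF is its CCF cluster's per-region mean (the
    quantity consumed downstream), computed from read counts through the
    copy-number relation and Dirichlet-process clustering. The headline
    figure is restricted to sites at total copy number 2; the raw
    per-mutation (pre-clustering) RMSE is reported alongside.
    """
    cohort = simulate_cohort(SimulationConfig(seed=seed))
    variants = cohort.variants.copy()
    variants["mutation"] = (
        variants["chrom"].astype(str) + ":" + variants["pos"].astype(str)
        + ":" + variants["ref"] + ">" + variants["alt"]
    )
    table = estimate_ccf_table(variants, cohort.segments, cohort.purity)
    err_cluster, err_raw, n_sites = [], [], 0
    for patient, g in table.groupby("patient"):
        truth = cohort.truth.patients[patient]
        wide = g.pivot_table(index="mutation", columns="region",
                             values="ccf", fill_value=0.0)
        depth = (
            variants[variants["patient"] == patient]
            .pivot_table(index="mutation", columns="region",
                         values="tumour_depth", fill_value=100)
            .reindex(index=wide.index, columns=wide.columns).fillna(100)
        )
        labels, clusters = cluster_ccfs(
            wide.to_numpy(), depth.to_numpy(), iters=gibbs_iters,
            burnin=gibbs_burnin, seed=seed + 1,
            mutation_ids=list(wide.index),
        )
        means = {c.cluster_id: c.mean_ccf for c in clusters}
        cn2 = g.set_index(["mutation", "region"])["cn_t"]
        region_pos = {r: i for i, r in enumerate(wide.columns)}
        for mi, m in enumerate(wide.index):
            true_cluster = truth.mutation_cluster[m]
            for r in wide.columns:
                if cn2.get((m, r), 2) != 2:
                    continue
                true_ccf = truth.ccf[true_cluster, region_pos[r]]
                est = means[labels[mi]][f"R{region_pos[r] + 1}"]
                err_cluster.append(est - true_ccf)
                err_raw.append(wide.loc[m, r] - true_ccf)
                n_sites += 1
    return {
        "rmse": float(np.sqrt(np.mean(np.square(err_cluster)))),
        "rmse_per_mutation": float(np.sqrt(np.mean(np.square(err_raw)))),
        "n": n_sites,
    }


# ---------------------------------------------------------------------------
# DP clustering recovery on planted clusters
# ---------------------------------------------------------------------------

def clustering_recovery_ari(seed: int = 0, n_cohorts: int = 3,
                            iters: int = 2000, burnin: int = 200) -> dict:
    """ARI of DP clustering on planted 3-cluster cohorts (dCCF >= 0.3).

    Each cohort: 60 mutations over 3 clusters with per-region CCF profiles
    separated by at least 0.3, two regions, depth 250.
    """
    rng = np.random.default_rng(seed)
    profiles = np.array([[1.0, 1.0], [0.65, 0.6], [0.3, 0.0]])
    aris = []
    for c in range(n_cohorts):
        true = np.repeat([0, 1, 2], 20)
        depth = np.full((60, 2), 250.0)
        vaf = profiles[true] / 2.0
        noisy = 2 * rng.binomial(250, vaf) / 250.0
        labels, _ = cluster_ccfs(noisy, depth, iters=iters, burnin=burnin,
                                 seed=seed + 10 + c)
        aris.append(adjusted_rand_score(true, labels))
    return {"ari_min": float(min(aris)), "ari_mean": float(np.mean(aris)),
            "n": n_cohorts * 60}


# ---------------------------------------------------------------------------
# Tree enumeration vs brute force
# ---------------------------------------------------------------------------

def _brute_force_feasible(means: np.ndarray, root: int, tol: float) -> set:
    k = means.shape[0]
    others = [v for v in range(k) if v != root]
    out = set()
    for choice in itertools.product(range(k), repeat=k - 1):
        parents = {root: -1, **dict(zip(others, choice))}
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


def tree_oracle_agreement(seed: int = 0, n_instances: int = 100) -> dict:
    """Fraction of random instances (k in 3..6) where exhaustive enumeration
    equals independent parent-vector filtering."""
    from .simulate import assign_region_ccfs

    rng = np.random.default_rng(seed)
    agree = 0
    for i in range(n_instances):
        k = 3 + i % 4
        parents = simulate_clone_tree(k, rng)
        means = assign_region_ccfs(parents, 3, rng)
        cm = pd.DataFrame(means, index=range(k))
        got = {t.parent_vector(list(range(k)))
               for t in enumerate_feasible_trees(cm, tol=0.05, truncal=0)}
        agree += got == _brute_force_feasible(means, 0, 0.05)
    return {"agreement": agree / n_instances, "n": n_instances}


# ---------------------------------------------------------------------------
# Planted-tree recovery under read noise
# ---------------------------------------------------------------------------

def _identifiable_instance(rng, n_regions: int = 3):
    """A 3-cluster chain or star whose noiseless CCFs admit only the planted
    tree (level separation >= 0.25)."""
    if rng.random() < 0.5:
        # chain T -> A -> B with A + B > 1 somewhere (excludes the star)
        a = rng.uniform(0.65, 0.75, n_regions)
        b = a - 0.25 - rng.uniform(0, 0.05, n_regions)
        planted = (-1, 0, 1)
        means = np.vstack([np.ones(n_regions), a, b])
    else:
        # star T -> {A, B} with each order A<B and B<A somewhere
        a = rng.uniform(0.5, 0.6, n_regions)
        b = rng.uniform(0.15, 0.25, n_regions)
        a[0], b[0] = b[0], a[0]  # flip one region: neither chain feasible
        planted = (-1, 0, 0)
        means = np.vstack([np.ones(n_regions), a, b])
    return planted, means


def tree_recovery_rate(seed: int = 0, n_sims: int = 50, depth: int = 250,
                       muts_per_cluster: int = 25) -> dict:
    """How often the planted tree is the minimum-BIC selection at 250x."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sims):
        planted, means = _identifiable_instance(rng)
        noisy = np.empty_like(means)
        for c in range(means.shape[0]):
            draws = rng.binomial(depth, means[c] / 2.0,
                                 size=(muts_per_cluster, means.shape[1]))
            noisy[c] = 2 * draws.mean(axis=0) / depth
        cm = pd.DataFrame(noisy, index=range(3))
        feas = enumerate_feasible_trees(cm, tol=0.1, truncal=0)
        best = score_and_select(feas, cm)
        hits += best.parent_vector([0, 1, 2]) == planted
    return {"recovery_rate": hits / n_sims, "n": n_sims}


# ---------------------------------------------------------------------------
# Filter fixture
# ---------------------------------------------------------------------------

def filter_fixture() -> dict:
    """Twelve constructed SNV calls covering every threshold boundary, plus
    the three force-calling outcomes. Expected: 3 pass, 9 fail, 1 rescue."""
    def call(**kw):
        base = dict(chrom="chr1", pos=1, ref="A", alt="T",
                    called_by={"callerA", "callerB"}, somatic_p=0.05,
                    tumour_depth=1000, tumour_alt=30,
                    normal_depth=1000, normal_alt=0)
        base.update(kw)
        return VariantCall(**base)

    fixture = [
        (call(), "pass"),                                        # 3% dual
        (call(tumour_alt=20), "pass"),                           # 2% boundary
        (call(tumour_alt=19), "fail"),                           # below 2%
        (call(called_by={"callerB"}, tumour_alt=60), "pass"),    # 6% single
        (call(called_by={"callerB"}, tumour_alt=50), "fail"),    # =5% single
        (call(called_by={"callerB"}, tumour_alt=40), "fail"),    # 4% single
        (call(somatic_p=0.11), "fail"),                          # somatic p
        (call(normal_alt=5), "fail"),                            # >=5 normal reads
        (call(normal_alt=4, normal_depth=300), "fail"),          # normal VAF >=1%
        (call(blacklist_flag=True), "fail"),                     # blacklist
        (call(population_freqs={"1000G": 0.02}), "fail"),        # population
        (call(tumour_depth=0, tumour_alt=0), "fail"),            # no coverage
    ]
    decisions = [consensus_filter_snv(c) for c, _ in fixture]
    matches = sum(d.status == exp for d, (_, exp) in zip(decisions, fixture))
    n_pass = sum(d.status == "pass" for d in decisions)

    fc = force_call("chr1:1:A>T", {
        "R2": dict(mapping_quality=25, tumour_depth=100, tumour_alt=3),
        "R3": dict(mapping_quality=25, tumour_depth=200, tumour_alt=3),
        "R4": dict(mapping_quality=18, tumour_depth=100, tumour_alt=10),
    })
    rescued = sum(v["force_called"] for v in fc.values())
    return {"n_variants": len(fixture), "matches": matches, "n_pass": n_pass,
            "force_called": rescued}


# ---------------------------------------------------------------------------
# dN/dS calibration
# ---------------------------------------------------------------------------

def dnds_null_and_power(seed: int = 0, n_null: int = 10_000,
                        n_genes: int = 20, n_enriched: int = 3,
                        muts_per_gene: int = 500) -> dict:
    """Genome-wide dN/dS under neutrality and q-values under 2x enrichment."""
    rng = np.random.default_rng(seed)
    stops = {"TAA", "TAG", "TGA"}
    codons = []
    while len(codons) < 2000:
        c = "".join("ACGT"[i] for i in rng.integers(0, 4, 3))
        if c not in stops:
            codons.append(c)
    cds = "".join(codons)
    l_non, l_syn = selection.expected_site_counts(cds)
    n_non, n_syn = selection.sample_mutation_counts(cds, n_null, rng)
    null = selection.dnds(n_non, n_syn, l_non, l_syn)

    rows = []
    for i in range(n_genes):
        mult = 2.0 if i < n_enriched else 1.0
        nn, ns = selection.sample_mutation_counts(cds, muts_per_gene, rng,
                                                  nonsyn_multiplier=mult)
        rows.append(dict(gene=f"G{i}", n_non=nn, n_syn=ns,
                         l_non=l_non, l_syn=l_syn))
    scan = selection.dnds_scan(pd.DataFrame(rows))
    enriched_q = scan.loc[scan["gene"].isin([f"G{i}" for i in range(n_enriched)]),
                          "q_value"]
    return {
        "dnds_null": float(null.dnds),
        "max_enriched_q": float(enriched_q.max()),
        "n": n_null,
    }


# ---------------------------------------------------------------------------
# Signature fitting
# ---------------------------------------------------------------------------

def signature_mixture_l1(seed: int = 0, n_mutations: int = 1000) -> dict:
    """L1 exposure error on an exact 0.7/0.3 two-signature mixture, plus the
    under-50-mutation exclusion check."""
    basis = selection.toy_signature_matrix()
    mix = 0.7 * basis["SCtoT"].to_numpy() + 0.3 * basis["SCtoA"].to_numpy()
    fit = selection.fit_signatures(mix * n_mutations, basis)
    l1 = abs(fit.exposures["SCtoT"] - 0.7) + abs(fit.exposures["SCtoA"] - 0.3)
    small = np.zeros(96)
    small[0] = 49
    excluded = selection.fit_signatures(small, basis).status == "excluded"
    return {"l1_error": float(l1), "exclusion_enforced": bool(excluded),
            "n": n_mutations}


# ---------------------------------------------------------------------------
# Trajectory clustering recovery
# ---------------------------------------------------------------------------

def _truth_candidates(cohort):
    """One candidate per patient from the simulator's planted tree/drivers."""
    candidates, archetypes = {}, {}
    for patient, t in cohort.truth.patients.items():
        parents = {
            v: (GL if t.parents[v] == -1 else int(t.parents[v]))
            for v in range(len(t.parents))
        }
        tree = CloneTree(parents=parents)
        orderings = trajectories.extract_orderings(tree, t.drivers)
        candidates[patient] = [dict(tree=tree, orderings=orderings, bic=0.0)]
        archetypes[patient] = t.archetype
    return candidates, archetypes


def trajectory_recovery(seed: int = 0, n_patients: int = 25,
                        jackknife_reps: int = 50) -> dict:
    """Cluster recovery and jackknife stability on a 5-archetype cohort."""
    cohort = simulate_cohort(SimulationConfig(
        n_patients=n_patients, n_mutations_range=(5, 10), seed=seed,
        hla_positions=0,
    ))
    candidates, archetypes = _truth_candidates(cohort)
    model = trajectories.transfer_fit(candidates)
    dist = trajectories.distance_matrix(model.orderings)
    labels = trajectories.cluster_cohort(dist, k=5, orderings=model.orderings)
    patients = sorted(candidates)
    ari = adjusted_rand_score(
        [archetypes[p] for p in patients], [labels[p] for p in patients]
    )
    jack = trajectories.jackknife_stability(
        candidates, k=5, leave_fraction=0.1, reps=jackknife_reps, seed=seed + 1
    )
    from collections import Counter

    w = Counter({("GL", "X"): 4, ("GL", "Y"): 3, ("GL", "Z"): 5})
    repeated_ok = trajectories.repeated_transitions(w) == {("GL", "X"), ("GL", "Z")}
    return {
        "ari": float(ari),
        "min_stability": float(min(jack["cluster_stability"].values())),
        "repeated_rule_exact": bool(repeated_ok),
        "n": n_patients,
    }


# ---------------------------------------------------------------------------
# HLA-LOH calibration
# ---------------------------------------------------------------------------

def hla_loh_calibration(seed: int = 0, n_power: int = 100,
                        n_null: int = 1000, purity: float = 0.3,
                        depth: float = 100.0, positions: int = 20) -> dict:
    """Detection power under one-allele loss and false-positive rate under a
    balanced null."""
    rng = np.random.default_rng(seed)
    half = depth / 2.0
    detected = 0
    for _ in range(n_power):
        kept = rng.poisson(half, positions)
        lost = rng.poisson(half * (1 - purity), positions)
        if call_hla_loh(HlaAlleleCoverage("P", "HLA-A", kept, lost))["loh"]:
            detected += 1
    fp = 0
    for _ in range(n_null):
        d1 = rng.poisson(half, positions)
        d2 = rng.poisson(half, positions)
        if call_hla_loh(HlaAlleleCoverage("P", "HLA-A", d1, d2))["loh"]:
            fp += 1
    return {"power": detected / n_power, "fpr": fp / n_null,
            "n": n_power + n_null}


# ---------------------------------------------------------------------------
# Hazard-ratio recovery
# ---------------------------------------------------------------------------

def hr_recovery_rate(seed: int = 0, n_reps: int = 100, n_per_arm: int = 200,
                     true_hr: float = 2.0) -> dict:
    """Mantel-Haenszel HR recovery on exponential survival, true HR 2."""
    rng = np.random.default_rng(seed)
    hits, estimates = 0, []
    for _ in range(n_reps):
        t1 = rng.exponential(1.0, n_per_arm)
        t2 = rng.exponential(1.0 / true_hr, n_per_arm)
        df = pd.DataFrame({
            "time": np.concatenate([t1, t2]),
            "event": 1,
            "group": ["a"] * n_per_arm + ["b"] * n_per_arm,
        })
        hr = stats.km_logrank(df)["hr"]
        estimates.append(hr)
        hits += 1.6 <= hr <= 2.5
    return {"in_range_rate": hits / n_reps,
            "median_hr": float(np.median(estimates)), "n": n_reps}
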