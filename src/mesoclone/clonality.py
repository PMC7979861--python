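"""Cancer cell fraction (CCF) estimation and Dirichlet-process clustering.

The mutation copy number ``n_mut`` is the expected number of mutant-allele
copies per tumour cell at a site with variant allele frequency ``VAF``,
tumour purity ``p``, local tumour total copy number ``CN_t`` and normal copy
number ``CN_n`` (2 on autosomes)::

    n_mut = VAF * (1/p) * [ p * CN_t + CN_n * (1 - p) ]

Decomposing ``n_mut = m * CCF`` — multiplicity ``m`` (integer number of
chromosome copies bearing the mutation) times the cancer cell fraction —
gives the per-region CCF once ``m`` is assigned by maximum likelihood over
the admissible integer states ``1..major``.

Mutations are then clustered across regions with a Dirichlet-process mixture
of per-region binomials over pseudo-counts derived from the pre-clustering
CCF (reference configuration: VAF = 0.5 x CCF, major copy number 2, minor 0,
purity 0.5), sampled by collapsed Gibbs.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betaln, gammaln
from scipy.stats import beta as beta_dist
from scipy.stats import binom

__all__ = [
    "CcfEstimate",
    "CcfCluster",
    "mutation_copy_number",
    "assign_multiplicity",
    "ccf",
    "estimate_ccf_table",
    "cluster_ccfs",
    "classify_clonality",
]

#: tolerance above 1.0 within which a CCF is clipped rather than flagged
CCF_TOL = 0.1

#: default clonality threshold on per-region mean CCF
CLONAL_THRESHOLD = 0.9


@dataclass
class CcfEstimate:
    """Per-mutation, per-region CCF estimate."""

    mutation: str
    region: str
    vaf: float
    purity: float
    cn_t: float
    cn_n: float
    n_mut: float
    multiplicity: int
    ccf: float
    ci95: tuple[float, float]
    consistent: bool = True


@dataclass
class CcfCluster:
    """A group of mutations sharing a CCF profile across regions."""

    cluster_id: int
    members: list = field(default_factory=list)
    mean_ccf: dict = field(default_factory=dict)  # region -> mean CCF
    clonality: str = "subclonal"


def mutation_copy_number(vaf: float, p: float, cn_t: float, cn_n: float = 2.0) -> float:
    """Expected mutant-allele copies per tumour cell.

    Parameters
    ----------
    vaf : variant allele frequency in [0, 1].
    p : tumour purity in (0, 1].
    cn_t : local tumour total copy number (>= 0).
    cn_n : local normal copy number (2 on autosomes).
    """
    if not 0 < p <= 1:
        raise ValueError(f"purity must be in (0, 1], got {p}")
    if cn_t < 0:
        raise ValueError(f"tumour copy number must be >= 0, got {cn_t}")
    if not 0 <= vaf <= 1:
        raise ValueError(f"VAF must be in [0, 1], got {vaf}")
    return vaf * (1.0 / p) * (p * cn_t + cn_n * (1.0 - p))


def expected_vaf(p: float, m: int, ccf_value: float, cn_t: float, cn_n: float = 2.0) -> float:
    """VAF implied by purity, multiplicity, CCF and copy number (inverse of n_mut)."""
    denom = p * cn_t + cn_n * (1.0 - p)
    if denom <= 0:
        raise ValueError("non-positive expected total copy mass")
    return p * m * ccf_value / denom


def assign_multiplicity(alt: int, depth: int, p: float, cn_t: float, major: int) -> int:
    """Maximum-likelihood multiplicity among integer states 1..major.

    Likelihood is Binomial(alt; depth, VAF_m) with VAF_m the expected VAF of
    a clonal mutation (CCF = 1) at multiplicity m, capped at 1. Ties break to
    the smaller multiplicity.
    """
    if major < 1:
        raise ValueError("major allele copy number must be >= 1")
    best_m, best_ll = 1, -np.inf
    for m in range(1, major + 1):
        q = min(1.0, expected_vaf(p, m, 1.0, cn_t))
        q = min(max(q, 1e-12), 1 - 1e-12)
        ll = binom.logpmf(alt, depth, q)
        if ll > best_ll + 1e-12:
            best_m, best_ll = m, ll
    return best_m


def ccf(n_mut: float, m: int, tol: float = CCF_TOL, return_flag: bool = False):
    """CCF = n_mut / m, clipped to [0, 1].

    Values in (1, 1+tol] are clipped with a warning; values above 1+tol are
    clipped and flagged inconsistent (returned flag False when
    ``return_flag``).
    """
    if m < 1:
        raise ValueError("multiplicity must be >= 1")
    raw = n_mut / m
    consistent = True
    if raw > 1.0 + tol:
        consistent = False
    elif raw > 1.0:
        warnings.warn(f"CCF {raw:.4f} slightly above 1; clipped", stacklevel=2)
    value = float(np.clip(raw, 0.0, 1.0))
    if return_flag:
        return value, consistent
    return value


def _ccf_ci95(alt: int, depth: int, p: float, cn_t: float, m: int, cn_n: float = 2.0):
    """95% CI on CCF from a Jeffreys beta posterior on the VAF."""
    if depth == 0:
        return (0.0, 1.0)
    lo_v, hi_v = beta_dist.ppf([0.025, 0.975], alt + 0.5, depth - alt + 0.5)
    lo = mutation_copy_number(lo_v, p, cn_t, cn_n) / m
    hi = mutation_copy_number(hi_v, p, cn_t, cn_n) / m
    return (float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1)))


def estimate_ccf_table(
    variants: pd.DataFrame,
    segments: pd.DataFrame,
    purity: dict,
    tol: float = CCF_TOL,
) -> pd.DataFrame:
    """Per-mutation, per-region CCF estimates for one patient or a cohort.

    ``variants`` needs columns: patient, region, chrom, pos (1-based), ref,
    alt, tumour_depth, tumour_alt. ``segments`` needs: patient, region,
    chrom, start, end (0-based half-open), major, minor. ``purity`` maps
    (patient, region) or patient -> purity.

    Mutations falling outside every segment use the diploid default (1, 1).
    """
    rows = []
    seg_by_key = {k: g for k, g in segments.groupby(["patient", "region", "chrom"])}
    for _, v in variants.iterrows():
        key = (v["patient"], v["region"], v["chrom"])
        major, minor = 1, 1
        if key in seg_by_key:
            g = seg_by_key[key]
            pos0 = int(v["pos"]) - 1
            hit = g[(g["start"] <= pos0) & (pos0 < g["end"])]
            if len(hit) > 0:
                major = int(hit.iloc[0]["major"])
                minor = int(hit.iloc[0]["minor"])
        cn_t = major + minor
        p = purity.get((v["patient"], v["region"]), purity.get(v["patient"]))
        if p is None:
            raise KeyError(f"no purity for patient {v['patient']}")
        depth = int(v["tumour_depth"])
        alt_count = int(v["tumour_alt"])
        vaf = alt_count / depth if depth > 0 else 0.0
        if cn_t == 0 or depth == 0:
            # site deleted or uncovered: no usable estimate
            rows.append(
                dict(
                    patient=v["patient"], region=v["region"],
                    mutation=_mutation_key(v), vaf=vaf, purity=p, cn_t=cn_t,
                    multiplicity=1, n_mut=0.0, ccf=0.0,
                    ci_lo=0.0, ci_hi=0.0, consistent=True,
                )
            )
            continue
        n_mut = mutation_copy_number(vaf, p, cn_t)
        m = assign_multiplicity(alt_count, depth, p, cn_t, max(major, 1))
        with warnings.catch_warnings():
            # mild >1 overshoot is routine binomial noise at table scale
            warnings.simplefilter("ignore", UserWarning)
            value, consistent = ccf(n_mut, m, tol=tol, return_flag=True)
        lo, hi = _ccf_ci95(alt_count, depth, p, cn_t, m)
        rows.append(
            dict(
                patient=v["patient"], region=v["region"],
                mutation=_mutation_key(v), vaf=vaf, purity=p, cn_t=cn_t,
                multiplicity=m, n_mut=n_mut, ccf=value,
                ci_lo=lo, ci_hi=hi, consistent=consistent,
            )
        )
    return pd.DataFrame(rows)


def _mutation_key(v) -> str:
    return f"{v['chrom']}:{v['pos']}:{v['ref']}>{v['alt']}"


# ---------------------------------------------------------------------------
# Dirichlet-process clustering
# ---------------------------------------------------------------------------

def _pseudo_counts(ccf_matrix: np.ndarray, depth_matrix: np.ndarray):
    """Binomial pseudo-counts: alt* = round(depth * CCF / 2), ref* = depth - alt*.

    This is the reference transform mapping CCF back onto a VAF of
    0.5 x CCF under major copy number 2, minor 0 and purity 0.5.
    """
    alt = np.rint(depth_matrix * ccf_matrix / 2.0).astype(np.int64)
    ref = depth_matrix.astype(np.int64) - alt
    return alt, ref


def _partition_log_posterior(labels, alt, ref, alpha):
    """Joint log p(partition, data) under the CRP + Beta(1,1) binomial model."""
    lp = 0.0
    for c in np.unique(labels):
        idx = labels == c
        n_c = int(idx.sum())
        lp += gammaln(n_c) + np.log(alpha)
        a = alt[idx].sum(axis=0)
        r = ref[idx].sum(axis=0)
        lp += float(np.sum(betaln(a + 1, r + 1)))
    return lp


def cluster_ccfs(
    ccf_matrix,
    depth_matrix,
    iters: int = 10_000,
    burnin: int = 1_000,
    alpha: float = 1.0,
    seed: int | None = None,
    mutation_ids=None,
) -> tuple[np.ndarray, list[CcfCluster]]:
    """Cluster mutations by their multi-region CCF profiles.

    Collapsed Gibbs sampling of a Dirichlet-process mixture of per-region
    binomials on the pseudo-counts. The returned point partition is the one
    visited most often after burn-in (ties broken by joint posterior). The
    result is invariant to the input row order for a fixed seed: rows are
    processed in a canonical sort order internally.

    Returns ``(labels, clusters)`` with labels aligned to the input rows and
    cluster ids ordered by decreasing mean CCF (0 = highest, typically
    clonal).
    """
    ccf_matrix = np.asarray(ccf_matrix, dtype=float)
    depth_matrix = np.asarray(depth_matrix, dtype=float)
    if ccf_matrix.ndim != 2:
        raise ValueError("ccf_matrix must be 2-D (mutations x regions)")
    n, _ = ccf_matrix.shape
    if n < 2:
        labels = np.zeros(n, dtype=int)
        clusters = _summarise_clusters(labels, ccf_matrix, mutation_ids)
        return labels, clusters

    alt, ref = _pseudo_counts(ccf_matrix, depth_matrix)

    # canonical processing order -> row-order invariance at fixed seed
    order = np.lexsort(np.hstack([alt, ref]).T[::-1])
    inv = np.argsort(order)
    alt_s, ref_s = alt[order], ref[order]

    rng = np.random.default_rng(seed)
    n_reg = alt_s.shape[1]
    labels = np.zeros(n, dtype=int)
    cap = max(8, n + 1)
    A = np.zeros((cap, n_reg))
    R = np.zeros((cap, n_reg))
    counts = np.zeros(cap, dtype=np.int64)
    counts[0] = n
    A[0] = alt_s.sum(axis=0)
    R[0] = ref_s.sum(axis=0)
    k = 1
    # cached per-cluster prior normaliser sum_r betaln(A+1, R+1)
    prior = np.zeros(cap)
    prior[0] = betaln(A[0] + 1, R[0] + 1).sum()

    new_terms = betaln(alt_s + 1, ref_s + 1).sum(axis=1)  # per-mutation
    base = float(betaln(np.ones(n_reg), np.ones(n_reg)).sum())
    log_alpha = np.log(alpha)

    tally: Counter = Counter()

    for it in range(iters):
        for i in range(n):
            c_old = labels[i]
            counts[c_old] -= 1
            A[c_old] -= alt_s[i]
            R[c_old] -= ref_s[i]
            if counts[c_old] == 0:
                # swap-delete the empty cluster with the last one
                k -= 1
                if c_old != k:
                    A[c_old], R[c_old] = A[k].copy(), R[k].copy()
                    counts[c_old] = counts[k]
                    prior[c_old] = prior[k]
                    labels[labels == k] = c_old
                counts[k] = 0
            else:
                prior[c_old] = betaln(A[c_old] + 1, R[c_old] + 1).sum()

            joint = betaln(A[:k] + alt_s[i] + 1, R[:k] + ref_s[i] + 1).sum(axis=1)
            log_w = np.empty(k + 1)
            log_w[:k] = np.log(counts[:k]) + joint - prior[:k]
            log_w[k] = log_alpha + new_terms[i] - base
            log_w -= log_w.max()
            w = np.exp(log_w)
            w /= w.sum()
            c_new = int(np.searchsorted(np.cumsum(w), rng.random()))
            c_new = min(c_new, k)
            if c_new == k:
                A[k] = 0.0
                R[k] = 0.0
                counts[k] = 0
                k += 1
            labels[i] = c_new
            counts[c_new] += 1
            A[c_new] += alt_s[i]
            R[c_new] += ref_s[i]
            prior[c_new] = betaln(A[c_new] + 1, R[c_new] + 1).sum()

        if it >= burnin:
            tally[_canonical(labels)] += 1

    if tally:
        top = tally.most_common()
        best_count = top[0][1]
        cands = [t for t, c in top if c == best_count]
        if len(cands) > 1:
            cands.sort(
                key=lambda t: _partition_log_posterior(np.array(t), alt_s, ref_s, alpha),
                reverse=True,
            )
        labels_s = np.array(cands[0], dtype=int)
    else:
        labels_s = labels

    labels_out = labels_s[inv]
    # order cluster ids by decreasing overall mean CCF
    means = {
        c: ccf_matrix[labels_out == c].mean() for c in np.unique(labels_out)
    }
    remap = {c: i for i, c in enumerate(sorted(means, key=means.get, reverse=True))}
    labels_out = np.array([remap[c] for c in labels_out], dtype=int)
    clusters = _summarise_clusters(labels_out, ccf_matrix, mutation_ids)
    return labels_out, clusters


def _canonical(labels) -> tuple:
    """Renumber labels by first occurrence so identical partitions compare equal."""
    seen: dict[int, int] = {}
    out = []
    for x in labels:
        if x not in seen:
            seen[x] = len(seen)
        out.append(seen[x])
    return tuple(out)


def _summarise_clusters(labels, ccf_matrix, mutation_ids=None) -> list[CcfCluster]:
    if mutation_ids is None:
        mutation_ids = list(range(len(labels)))
    clusters = []
    for c in sorted(set(labels.tolist())):
        idx = labels == c
        means = ccf_matrix[idx].mean(axis=0)
        cl = CcfCluster(
            cluster_id=int(c),
            members=[mutation_ids[i] for i in np.flatnonzero(idx)],
            mean_ccf={f"R{r + 1}": float(means[r]) for r in range(ccf_matrix.shape[1])},
        )
        cl.clonality = classify_clonality(means)
        clusters.append(cl)
    return clusters


def classify_clonality(mean_ccfs, threshold: float = CLONAL_THRESHOLD) -> str:
    """'clonal' iff the cluster's mean CCF is >= threshold in every region."""
    means = np.asarray(list(mean_ccfs.values()) if isinstance(mean_ccfs, dict) else mean_ccfs, dtype=float)
    if means.size == 0:
        raise ValueError("cluster has no per-region means")
    return "clonal" if bool(np.all(means >= threshold)) else "subclonal"
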