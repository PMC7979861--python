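"""Repeated evolutionary trajectories across a multi-region cohort.

Driver events (mutations and copy-number losses in NF2, BAP1, FBXW7, SETD2,
LATS2, PTEN, CDKN2A and their loci) are mapped to clone-tree nodes; each
patient's tree induces a set of ordered driver pairs (germline GL before
truncal drivers, ancestors before descendants). A transfer-learning re-fit
iterates between counting transitions cohort-wide and letting each patient
re-select, among its near-optimal candidate trees, the one whose orderings
are best supported by the rest of the cohort. Transitions seen in more than
three patients are "repeated". Patients are then clustered on the Jaccard
distance between their ordering sets (average-linkage hierarchical
clustering), labelled C1..Ck from simplest to most complex, with jackknife
resampling to assess stability, and a CART decision tree to transfer the
cluster definitions onto an external cohort's binary driver profiles.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.tree import DecisionTreeClassifier

from .trees import GL, CloneTree

__all__ = [
    "DriverEvent",
    "TrajectoryModel",
    "DRIVER_VOCABULARY",
    "extract_orderings",
    "transfer_fit",
    "repeated_transitions",
    "evolutionary_distance",
    "cluster_cohort",
    "jackknife_stability",
    "train_decision_tree",
    "assign_by_decision_tree",
]

#: default driver-event vocabulary: mutations and copy-number events
DRIVER_VOCABULARY: tuple[str, ...] = (
    "NF2", "BAP1", "FBXW7", "SETD2", "LATS2", "PTEN", "CDKN2A",
    "-3p21", "-chr4", "9p21-loss", "-22q", "10q23-loss",
)

REPEAT_MIN_PATIENTS = 3  # "more than three patients" => count > 3


@dataclass
class DriverEvent:
    id: str
    kind: str  # mutation | scna
    cluster: int | None = None
    clonality: str | None = None

    def __post_init__(self):
        if self.id not in DRIVER_VOCABULARY:
            raise ValueError(f"unknown driver event {self.id!r}")


@dataclass
class TrajectoryModel:
    """Cohort-level transition counts and per-patient ordering sets."""

    transition_counts: Counter = field(default_factory=Counter)
    orderings: dict = field(default_factory=dict)  # patient -> frozenset of pairs
    selected_trees: dict = field(default_factory=dict)
    cluster_labels: dict = field(default_factory=dict)
    distance_matrix: pd.DataFrame | None = None


def _ancestors(tree: CloneTree, node) -> set:
    out = set()
    p = tree.parents[node]
    while p != GL:
        out.add(p)
        p = tree.parents[p]
    return out


def extract_orderings(tree: CloneTree, driver_nodes: dict) -> frozenset:
    """Ordered driver pairs induced by a clone tree.

    ``driver_nodes`` maps driver event id -> cluster node. Truncal drivers
    get (GL -> x); x precedes y when x's node is a strict ancestor of y's
    node. Drivers on the same node are left unordered (both still get their
    upstream pairs).
    """
    truncal = tree.truncal
    nodes = set(tree.clusters)
    for d, node in driver_nodes.items():
        if node not in nodes:
            raise ValueError(f"driver {d} mapped to unknown node {node!r}")
    pairs = set()
    anc_cache = {node: _ancestors(tree, node) for node in nodes}
    for d, node in driver_nodes.items():
        if node == truncal:
            pairs.add((GL, d))
        for d2, node2 in driver_nodes.items():
            if d2 == d:
                continue
            if node in anc_cache[node2]:
                pairs.add((d, d2))
    return frozenset(pairs)


def build_transition_counts(orderings: dict) -> Counter:
    """w(x -> y): number of patients whose ordering set contains (x, y)."""
    w: Counter = Counter()
    for pairs in orderings.values():
        for pair in pairs:
            w[pair] += 1
    return w


def transfer_fit(candidates: dict, max_iter: int = 10) -> TrajectoryModel:
    """Jointly re-select each patient's tree to maximise cohort support.

    ``candidates`` maps patient -> list of dicts with keys ``tree``
    (CloneTree), ``orderings`` (frozenset of pairs) and ``bic``; the list
    should already be restricted to trees within a small BIC band of each
    patient's optimum. Iteration alternates between (1) building the
    transition-count matrix w from current selections and (2) each patient
    (in ascending id order) re-selecting the candidate maximising the sum of
    w over its ordered pairs, with BIC as tie-break. Stops at a fixed point
    or ``max_iter``.
    """
    patients = sorted(candidates)
    for p in patients:
        if not candidates[p]:
            raise ValueError(f"patient {p} has an empty candidate set")
    selection = {p: 0 for p in patients}

    def orderings_of(sel):
        return {p: candidates[p][sel[p]]["orderings"] for p in patients}

    # initial selection: best BIC
    for p in patients:
        selection[p] = int(
            np.argmin([c.get("bic", 0.0) for c in candidates[p]])
        )

    for _ in range(max_iter):
        w = build_transition_counts(orderings_of(selection))
        changed = False
        for p in patients:
            # support counted against the rest of the cohort
            w_minus = w.copy()
            for pair in candidates[p][selection[p]]["orderings"]:
                w_minus[pair] -= 1
            best_i, best_key = selection[p], None
            for i, cand in enumerate(candidates[p]):
                support = sum(w_minus[pair] for pair in cand["orderings"])
                key = (-support, cand.get("bic", 0.0), i)
                if best_key is None or key < best_key:
                    best_key, best_i = key, i
            if best_i != selection[p]:
                selection[p] = best_i
                changed = True
                w = build_transition_counts(orderings_of(selection))
        if not changed:
            break

    model = TrajectoryModel()
    model.orderings = orderings_of(selection)
    model.transition_counts = build_transition_counts(model.orderings)
    model.selected_trees = {
        p: candidates[p][selection[p]]["tree"] for p in patients
    }
    return model


def repeated_transitions(w: Counter) -> set:
    """Transitions supported by more than three patients (count >= 4)."""
    return {pair for pair, count in w.items() if count > REPEAT_MIN_PATIENTS}


def evolutionary_distance(t_i: frozenset, t_j: frozenset) -> float:
    """Jaccard distance between two ordering sets (0 when both empty)."""
    union = len(t_i | t_j)
    if union == 0:
        return 0.0
    return 1.0 - len(t_i & t_j) / union


def distance_matrix(orderings: dict) -> pd.DataFrame:
    patients = sorted(orderings)
    n = len(patients)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = evolutionary_distance(
                orderings[patients[i]], orderings[patients[j]]
            )
    return pd.DataFrame(d, index=patients, columns=patients)


def cluster_cohort(dist: pd.DataFrame, k: int = 5, orderings: dict | None = None) -> dict:
    """Average-linkage hierarchical clustering of patients, cut at k.

    Labels are renumbered so cluster 1 has the lowest mean event count
    (simplest trajectories) and cluster k the highest; ``orderings`` supplies
    the event counts (defaults to label order by cluster size).
    """
    n = len(dist)
    if k > n:
        raise ValueError(f"k={k} exceeds {n} patients")
    patients = list(dist.index)
    if k == n:
        raw = np.arange(1, n + 1)
    elif k == 1:
        raw = np.ones(n, dtype=int)
    else:
        z = linkage(squareform(dist.to_numpy(), checks=False), method="average")
        raw = fcluster(z, t=k, criterion="maxclust")
    complexity = {}
    for c in np.unique(raw):
        members = [patients[i] for i in np.flatnonzero(raw == c)]
        if orderings is not None:
            complexity[c] = float(np.mean([len(orderings[p]) for p in members]))
        else:
            complexity[c] = float(len(members))
    order = sorted(np.unique(raw), key=lambda c: (complexity[c], c))
    remap = {c: i + 1 for i, c in enumerate(order)}
    return {patients[i]: int(remap[raw[i]]) for i in range(n)}


def jackknife_stability(
    candidates: dict,
    k: int = 5,
    leave_fraction: float = 0.1,
    reps: int = 100,
    seed: int | None = None,
    max_iter: int = 10,
) -> dict:
    """Leave-out resampling of the transfer fit + clustering.

    Repeatedly drops ``ceil(leave_fraction * n)`` patients, re-runs the
    transfer fit and clustering, and records how often each patient pair
    lands in the same cluster among runs retaining both. Returns the
    co-clustering frequency matrix and, for each original cluster, the
    median within-cluster pairwise frequency.
    """
    if not 0 < leave_fraction <= 0.5:
        raise ValueError("leave_fraction must be in (0, 0.5]")
    rng = np.random.default_rng(seed)
    patients = sorted(candidates)
    n = len(patients)
    idx = {p: i for i, p in enumerate(patients)}

    base_model = transfer_fit(candidates, max_iter=max_iter)
    base_dist = distance_matrix(base_model.orderings)
    base_labels = cluster_cohort(base_dist, k=k, orderings=base_model.orderings)

    together = np.zeros((n, n))
    retained = np.zeros((n, n))
    n_drop = int(np.ceil(leave_fraction * n))
    for _ in range(reps):
        drop = set(rng.choice(n, size=n_drop, replace=False))
        keep = [p for p in patients if idx[p] not in drop]
        sub = {p: candidates[p] for p in keep}
        model = transfer_fit(sub, max_iter=max_iter)
        dist = distance_matrix(model.orderings)
        labels = cluster_cohort(dist, k=min(k, len(keep)), orderings=model.orderings)
        for a in range(len(keep)):
            for b in range(a + 1, len(keep)):
                ia, ib = idx[keep[a]], idx[keep[b]]
                retained[ia, ib] += 1
                retained[ib, ia] += 1
                if labels[keep[a]] == labels[keep[b]]:
                    together[ia, ib] += 1
                    together[ib, ia] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(retained > 0, together / retained, np.nan)
    np.fill_diagonal(freq, 1.0)
    freq_df = pd.DataFrame(freq, index=patients, columns=patients)

    stability = {}
    for c in sorted(set(base_labels.values())):
        members = [p for p in patients if base_labels[p] == c]
        vals = [
            freq_df.loc[a, b]
            for i, a in enumerate(members)
            for b in members[i + 1:]
            if np.isfinite(freq_df.loc[a, b])
        ]
        stability[c] = float(np.median(vals)) if vals else 1.0
    return {
        "co_clustering": freq_df,
        "cluster_stability": stability,
        "base_labels": base_labels,
    }


def _profile_matrix(profiles: dict, vocabulary=DRIVER_VOCABULARY) -> np.ndarray:
    x = np.zeros((len(profiles), len(vocabulary)))
    for i, p in enumerate(sorted(profiles)):
        for j, ev in enumerate(vocabulary):
            x[i, j] = 1.0 if ev in profiles[p] else 0.0
    return x


def train_decision_tree(
    profiles: dict, labels: dict, vocabulary=DRIVER_VOCABULARY,
    max_depth: int = 4, seed: int = 0,
) -> DecisionTreeClassifier:
    """CART on binary driver-event profiles to transfer cluster labels to an
    external cohort."""
    x = _profile_matrix(profiles, vocabulary)
    y = np.array([labels[p] for p in sorted(profiles)])
    clf = DecisionTreeClassifier(max_depth=max_depth, random_state=seed)
    clf.fit(x, y)
    return clf


def assign_by_decision_tree(
    profile, clf: DecisionTreeClassifier, vocabulary=DRIVER_VOCABULARY
) -> int:
    """Deterministic cluster label for one binary driver profile; events not
    in the vocabulary are treated as absent."""
    x = np.zeros((1, len(vocabulary)))
    for j, ev in enumerate(vocabulary):
        if ev in profile:
            x[0, j] = 1.0
    return int(clf.predict(x)[0])
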