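"""Clone-tree enumeration, BIC scoring, topology classes and SCNA events.

Clone trees are rooted at a germline (GL) node whose single child is the
truncal cluster (CCF ~ 1 in every region). A tree over k CCF clusters is
feasible when it satisfies the sum rule (pigeonhole principle) in every
region: the CCFs of a node's children cannot sum to more than the node's
own CCF. Feasible trees are scored by projecting the observed cluster CCFs
onto the tree's sum-rule polytope (least squares) and ranked by BIC; the
minimum-BIC tree is selected.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "CloneTree",
    "ScnaEvent",
    "enumerate_feasible_trees",
    "score_and_select",
    "classify_topology",
    "call_scna_events",
    "detect_double_hits",
]

GL = "GL"

#: maximum cluster count for exhaustive enumeration
K_MAX = 9


@dataclass
class CloneTree:
    """Rooted clone tree over CCF clusters.

    ``parents`` maps each cluster id to its parent (the truncal cluster's
    parent is the germline node ``GL``).
    """

    parents: dict
    fitted_ccf: pd.DataFrame | None = None  # clusters x regions
    rss: float = np.nan
    bic: float = np.nan

    @property
    def clusters(self) -> list:
        return sorted(self.parents)

    @property
    def truncal(self):
        roots = [c for c, p in self.parents.items() if p == GL]
        if len(roots) != 1:
            raise ValueError("tree must have exactly one truncal child of GL")
        return roots[0]

    def children(self, node) -> list:
        return sorted(c for c, p in self.parents.items() if p == node)

    def parent_vector(self, order=None) -> tuple:
        order = order or self.clusters
        index = {c: i for i, c in enumerate(order)}
        return tuple(
            -1 if self.parents[c] == GL else index[self.parents[c]] for c in order
        )

    def to_newick(self) -> str:
        def sub(node):
            kids = self.children(node)
            label = str(node)
            if not kids:
                return label
            return "(" + ",".join(sub(c) for c in kids) + ")" + label

        return "(" + sub(self.truncal) + ")GL;"


@dataclass
class ScnaEvent:
    """A somatic copy-number event call."""

    event_class: str  # arm_loss|chr_loss|cnloh|homozygous_deletion|msai|gain|amplification|loss
    location: str
    regions: list = field(default_factory=list)
    clonality: str = "subclonal"


def _sum_rule_ok(parent_idx, means: np.ndarray, tol: float) -> bool:
    """means: clusters x regions; parent_idx: -1 for truncal."""
    k = means.shape[0]
    child_sum = np.zeros_like(means)
    for v in range(k):
        p = parent_idx[v]
        if p >= 0:
            child_sum[p] += means[v]
    for v in range(k):
        if np.any(child_sum[v] > means[v] + tol):
            return False
    return True


def enumerate_feasible_trees(
    cluster_means: pd.DataFrame,
    tol: float = 0.05,
    clonal_threshold: float = 0.9,
    k_max: int = K_MAX,
    truncal=None,
) -> list[CloneTree]:
    """All sum-rule-feasible rooted trees over the given CCF clusters.

    ``cluster_means`` is a clusters x regions table of mean CCFs. Exactly one
    cluster must be clonal (CCF >= ``clonal_threshold`` in every region); it
    becomes the truncal child of GL. Enumeration walks all parent vectors
    over the k clusters with early sum-rule pruning. Pass ``truncal`` to fix
    the root cluster explicitly (bypasses the clonal-cluster detection, e.g.
    on noisy data where no cluster clears the threshold in every region).
    """
    means = cluster_means.to_numpy(dtype=float)
    ids = list(cluster_means.index)
    k = len(ids)
    if truncal is not None:
        if truncal not in ids:
            raise ValueError(f"truncal cluster {truncal!r} not in table")
        clonal = [ids.index(truncal)]
    else:
        clonal = [i for i in range(k) if np.all(means[i] >= clonal_threshold)]
    if len(clonal) != 1:
        raise ValueError(
            f"expected exactly one truncal (clonal) cluster, found {len(clonal)}"
        )
    if k > k_max:
        raise ValueError(
            f"{k} clusters exceeds exhaustive limit {k_max}; reduce clusters "
            "or raise k_max"
        )
    root = clonal[0]
    others = [i for i in range(k) if i != root]
    trees = []
    for choice in itertools.product(range(k), repeat=len(others)):
        parent_idx = np.full(k, -1, dtype=int)
        for node, par in zip(others, choice):
            if par == node:
                break
            parent_idx[node] = par
        else:
            if not _is_acyclic(parent_idx, root):
                continue
            if not _sum_rule_ok(parent_idx, means, tol):
                continue
            parents = {
                ids[v]: (GL if parent_idx[v] == -1 else ids[parent_idx[v]])
                for v in range(k)
            }
            trees.append(CloneTree(parents=parents))
    return trees


def _is_acyclic(parent_idx, root) -> bool:
    k = len(parent_idx)
    for v in range(k):
        if v == root:
            if parent_idx[v] != -1:
                return False
            continue
        if parent_idx[v] == -1:
            return False
        seen = set()
        u = v
        while u != root:
            if u in seen:
                return False
            seen.add(u)
            u = parent_idx[u]
            if u == -1:
                return False
    return True


def _project_region(obs: np.ndarray, parent_idx, root) -> np.ndarray:
    """Least-squares projection of one region's CCFs onto the sum-rule cone.

    minimise ||f - obs||^2 subject to sum(children f) <= f_parent for every
    node, 0 <= f <= 1, with the truncal entry allowed to move like any
    other (its observed value is ~1).
    """
    k = len(obs)
    cons = []
    for v in range(k):
        kids = [c for c in range(k) if parent_idx[c] == v]
        if kids:
            cons.append(
                {
                    "type": "ineq",
                    "fun": lambda f, v=v, kids=tuple(kids): f[v] - sum(f[c] for c in kids),
                }
            )
    res = minimize(
        lambda f: np.sum((f - obs) ** 2),
        x0=np.clip(obs, 0, 1),
        jac=lambda f: 2 * (f - obs),
        bounds=[(0.0, 1.0)] * k,
        constraints=cons,
        method="SLSQP",
    )
    return res.x


def score_and_select(
    trees: list[CloneTree], cluster_means: pd.DataFrame
) -> CloneTree:
    """Fit each candidate tree and return the minimum-BIC solution.

    Fitted CCFs are the least-squares projection of the observed cluster
    means onto each tree's sum-rule polytope, region by region. BIC =
    n*ln(RSS/n) + q*ln(n) with n = clusters x regions and q = edge count.
    Ties break to fewer edges, then to the lexicographically smaller parent
    vector.
    """
    if not trees:
        raise ValueError("no candidate trees to score")
    means = cluster_means.to_numpy(dtype=float)
    ids = list(cluster_means.index)
    index = {c: i for i, c in enumerate(ids)}
    n = means.size
    for tree in trees:
        parent_idx = [
            -1 if tree.parents[c] == GL else index[tree.parents[c]] for c in ids
        ]
        root = parent_idx.index(-1)
        fitted = np.column_stack(
            [
                _project_region(means[:, r], parent_idx, root)
                for r in range(means.shape[1])
            ]
        )
        tree.fitted_ccf = pd.DataFrame(
            fitted, index=ids, columns=cluster_means.columns
        )
        tree.rss = float(np.sum((fitted - means) ** 2))
        q = len(ids)  # every cluster has one incoming edge (incl. GL->truncal)
        # RSS floor absorbs solver round-off so exact fits tie exactly
        tree.bic = n * np.log(max(tree.rss, 1e-8) / n) + q * np.log(n)
    return min(
        trees,
        key=lambda t: (round(t.bic, 6), len(t.parents), t.parent_vector(ids)),
    )


def classify_topology(tree: CloneTree) -> str:
    """'branched' iff some non-truncal cluster has two or more children.

    Branching at the truncal most-recent-common-ancestor alone still counts
    as linear: linear trees are those without subclonal branching.
    """
    truncal = tree.truncal
    for node in tree.clusters:
        if node == truncal:
            continue
        if len(tree.children(node)) >= 2:
            return "branched"
    return "linear"


# ---------------------------------------------------------------------------
# SCNA event classes
# ---------------------------------------------------------------------------

def _loss_fraction(segs: pd.DataFrame, start: int, end: int) -> float:
    """Fraction of [start, end) covered by segments with total CN < 2."""
    lost = 0
    for _, s in segs.iterrows():
        if s["major"] + s["minor"] < 2:
            lost += max(0, min(end, s["end"]) - max(start, s["start"]))
    return lost / (end - start) if end > start else 0.0


def call_scna_events(
    segments: pd.DataFrame,
    arm_table: pd.DataFrame,
    ploidy: float = 2.0,
    arm_loss_fraction: float = 0.5,
    chr_loss_fraction: float = 0.6,
) -> list[ScnaEvent]:
    """Classify copy-number events for one patient across regions.

    Segment classes per region: loss (total < 2), CN-LOH (major 2, minor 0),
    homozygous deletion (total 0), gain (total > ploidy), amplification
    (total >= 2*ploidy). Aggregates: arm loss when >= ``arm_loss_fraction``
    of the arm is lost; whole-chromosome loss when >= ``chr_loss_fraction``
    of the chromosome is lost; MSAI when the same interval has minor = 0 in
    two or more regions with opposite parental alleles lost (requires a
    ``lost_allele`` phase column). An event is clonal iff present in every
    region.
    """
    regions = sorted(segments["region"].unique())
    n_regions = len(regions)
    for region, g in segments.groupby("region"):
        for chrom, gc in g.groupby("chrom"):
            gc = gc.sort_values("start")
            if np.any(gc["start"].values[1:] < gc["end"].values[:-1]):
                raise ValueError(
                    f"overlapping segments in region {region}, {chrom}"
                )

    events: list[ScnaEvent] = []

    def add(cls, loc, regs):
        events.append(
            ScnaEvent(
                event_class=cls, location=loc, regions=sorted(regs),
                clonality="clonal" if len(set(regs)) == n_regions else "subclonal",
            )
        )

    # segment-level classes, grouped by identical interval across regions
    for (chrom, start, end), g in segments.groupby(["chrom", "start", "end"]):
        loc = f"{chrom}:{start}-{end}"
        total = g["major"] + g["minor"]
        homdel = g.loc[total == 0, "region"]
        if len(homdel):
            add("homozygous_deletion", loc, homdel)
        cnloh = g.loc[(g["major"] == 2) & (g["minor"] == 0), "region"]
        if len(cnloh):
            add("cnloh", loc, cnloh)
        loss = g.loc[(total < 2) & (total > 0), "region"]
        if len(loss):
            add("loss", loc, loss)
        gain = g.loc[total > ploidy, "region"]
        if len(gain):
            add("gain", loc, gain)
        amp = g.loc[total >= 2 * ploidy, "region"]
        if len(amp):
            add("amplification", loc, amp)
        # MSAI: minor = 0 in >= 2 regions but opposite parental allele lost
        if "lost_allele" in g.columns:
            lost = g[(g["minor"] == 0) & (g["major"] > 0) & (g["lost_allele"] != "")]
            alleles = set(lost["lost_allele"])
            if len(lost) >= 2 and len(alleles) >= 2:
                add("msai", loc, lost["region"])

    # arm- and chromosome-level losses
    for region, g in segments.groupby("region"):
        for _, arm in arm_table.iterrows():
            segs = g[g["chrom"] == arm["chrom"]]
            frac = _loss_fraction(segs, arm["start"], arm["end"])
            if frac >= arm_loss_fraction:
                events.append(
                    ScnaEvent(
                        "arm_loss", f"{arm['chrom']}{arm['arm']}",
                        [region], "subclonal",
                    )
                )
        for chrom in arm_table["chrom"].unique():
            length = int(arm_table.loc[arm_table["chrom"] == chrom, "end"].max())
            segs = g[g["chrom"] == chrom]
            if _loss_fraction(segs, 0, length) >= chr_loss_fraction:
                events.append(ScnaEvent("chr_loss", chrom, [region], "subclonal"))

    # merge per-region arm/chr events into cohort-of-regions events
    merged: dict = {}
    out: list[ScnaEvent] = []
    for ev in events:
        if ev.event_class in ("arm_loss", "chr_loss"):
            key = (ev.event_class, ev.location)
            merged.setdefault(key, set()).update(ev.regions)
        else:
            out.append(ev)
    for (cls, loc), regs in merged.items():
        out.append(
            ScnaEvent(
                cls, loc, sorted(regs),
                "clonal" if len(regs) == n_regions else "subclonal",
            )
        )
    return out


def detect_double_hits(
    driver_mutations: pd.DataFrame,
    segments: pd.DataFrame,
    gene_coords: dict,
) -> dict:
    """Bi-allelic inactivation calls per driver gene.

    A double hit is (a) a deleterious mutation plus an overlapping loss of
    the other allele (minor = 0), (b) two distinct deleterious mutations in
    the gene, or (c) a homozygous deletion of the locus. Timing is clonal
    iff every component event is clonal.

    ``driver_mutations`` needs columns gene, clonality and (optionally)
    deleterious (default True). Returns gene -> dict(double_hit, mechanism,
    timing).
    """
    regions = sorted(segments["region"].unique()) if len(segments) else []
    out = {}
    for gene, (chrom, start, end) in gene_coords.items():
        muts = driver_mutations[driver_mutations["gene"] == gene]
        if "deleterious" in muts.columns:
            muts = muts[muts["deleterious"]]
        segs = segments[
            (segments["chrom"] == chrom)
            & (segments["start"] < end)
            & (segments["end"] > start)
        ]
        hom = segs[(segs["major"] + segs["minor"]) == 0]
        loh = segs[(segs["minor"] == 0) & (segs["major"] > 0)]
        hom_regions = set(hom["region"])
        loh_regions = set(loh["region"])
        n_mut = muts["mutation"].nunique() if "mutation" in muts.columns else len(muts)

        double, mechanism = False, None
        if hom_regions:
            double, mechanism = True, "homozygous_deletion"
        elif n_mut >= 2:
            double, mechanism = True, "two_mutations"
        elif n_mut >= 1 and loh_regions:
            double, mechanism = True, "mutation_plus_loss"

        timing = None
        if double:
            comps_clonal = []
            if mechanism == "homozygous_deletion":
                comps_clonal.append(hom_regions == set(regions))
            if mechanism in ("two_mutations", "mutation_plus_loss"):
                comps_clonal.append(
                    len(muts) > 0 and bool((muts["clonality"] == "clonal").all())
                )
            if mechanism == "mutation_plus_loss":
                comps_clonal.append(loh_regions == set(regions))
            timing = "clonal" if all(comps_clonal) else "subclonal"
        out[gene] = {
            "double_hit": double, "mechanism": mechanism, "timing": timing,
            "n_mutations": int(n_mut),
        }
    return out
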