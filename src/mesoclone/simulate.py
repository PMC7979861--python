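"""Synthetic multi-region tumour cohort generator with known ground truth.

Emulates a surgical multi-region exome study of malignant pleural
mesothelioma: 4-5 anatomically distinct regions per tumour, ~250x depth,
purity 0.3-0.9 and of order 100 somatic mutations per patient. Each patient
receives a planted clone tree, per-region cluster CCFs obeying the sum rule
by construction (recursive stick-breaking), allele-specific copy-number
segments, driver mutations/losses placed according to one of five
evolutionary archetypes, exponential survival with archetype-specific
hazards, and allele-specific HLA coverage with or without loss of
heterozygosity.

Read counts invert the mutation-copy-number relation: the expected VAF of a
mutation with multiplicity m and cancer cell fraction CCF in a region of
purity p and tumour copy number CN_t is p*m*CCF / (p*CN_t + 2*(1-p)); site
depth is Poisson around the target depth and alt counts are binomial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clonality import expected_vaf

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "PatientTruth",
    "CohortData",
    "Archetype",
    "DEFAULT_ARCHETYPES",
    "GENOME",
    "ARM_TABLE",
    "DRIVER_GENES",
    "SCNA_EVENTS",
    "simulate_clone_tree",
    "assign_region_ccfs",
    "simulate_reads",
    "simulate_cohort",
]

# ---------------------------------------------------------------------------
# Simplified autosomal genome model (coordinates in bp, approximate hg19 scale)
# ---------------------------------------------------------------------------

GENOME: dict[str, int] = {
    "chr1": 249_000_000,
    "chr2": 243_000_000,
    "chr3": 198_000_000,
    "chr4": 190_000_000,
    "chr5": 182_000_000,
    "chr9": 138_000_000,
    "chr10": 134_000_000,
    "chr13": 114_000_000,
    "chr22": 51_000_000,
}

_CENTROMERE: dict[str, int] = {
    "chr1": 125_000_000,
    "chr2": 93_000_000,
    "chr3": 91_000_000,
    "chr4": 50_000_000,
    "chr5": 48_000_000,
    "chr9": 49_000_000,
    "chr10": 40_000_000,
    "chr13": 17_000_000,
    "chr22": 15_000_000,
}


def _build_arm_table() -> pd.DataFrame:
    rows = []
    for chrom, length in GENOME.items():
        cen = _CENTROMERE[chrom]
        rows.append(dict(chrom=chrom, arm="p", start=0, end=cen))
        rows.append(dict(chrom=chrom, arm="q", start=cen, end=length))
    return pd.DataFrame(rows)


#: chromosome-arm coordinates (0-based half-open)
ARM_TABLE: pd.DataFrame = _build_arm_table()

#: driver gene loci (chrom, start, end) — tumour suppressors recurrently
#: altered in pleural mesothelioma
DRIVER_GENES: dict[str, tuple[str, int, int]] = {
    "BAP1": ("chr3", 52_400_000, 52_440_000),    # 3p21.1
    "SETD2": ("chr3", 47_000_000, 47_150_000),   # 3p21.31
    "FBXW7": ("chr4", 152_300_000, 152_500_000),  # 4q31.3
    "CDKN2A": ("chr9", 21_960_000, 22_000_000),  # 9p21.3
    "PTEN": ("chr10", 89_600_000, 89_730_000),   # 10q23.31
    "LATS2": ("chr13", 21_000_000, 21_100_000),  # 13q12.11
    "NF2": ("chr22", 29_600_000, 29_700_000),    # 22q12.2
}

#: copy-number driver events: id -> (chrom, start, end, major, minor)
SCNA_EVENTS: dict[str, tuple[str, int, int, int, int]] = {
    "-3p21": ("chr3", 46_000_000, 54_000_000, 1, 0),
    # 70% of chromosome 4 (satisfies the >=60% whole-chromosome loss rule)
    "-chr4": ("chr4", 0, 133_000_000, 1, 0),
    # homozygous deletion of the 9p21.3 band (CDKN2A/MTAP)
    "9p21-loss": ("chr9", 21_000_000, 23_000_000, 0, 0),
    "-22q": ("chr22", 15_000_000, 51_000_000, 1, 0),
    "10q23-loss": ("chr10", 88_000_000, 92_000_000, 1, 0),
    "+chr5": ("chr5", 0, 182_000_000, 2, 1),
}


@dataclass(frozen=True)
class Archetype:
    """An evolutionary trajectory archetype: which drivers arise truncally
    versus subclonally."""

    name: str
    truncal: tuple[str, ...]
    subclonal: tuple[str, ...]

    @property
    def events(self) -> tuple[str, ...]:
        return self.truncal + self.subclonal


#: five archetypes ordered from simplest to most complex trajectory;
#: BAP1/-3p21 and -chr4/FBXW7 appear only early (truncal) while NF2/-22q is
#: predominantly late, mirroring the bottleneck structure of mesothelioma
#: evolution
DEFAULT_ARCHETYPES: tuple[Archetype, ...] = (
    Archetype("C1", ("BAP1", "-3p21"), ()),
    Archetype("C2", ("-chr4", "FBXW7"), ()),
    Archetype("C3", ("-chr4", "9p21-loss"), ("NF2",)),
    Archetype("C4", ("BAP1", "-3p21", "9p21-loss"), ("NF2", "-22q")),
    Archetype(
        "C5",
        ("BAP1", "-3p21", "-chr4", "FBXW7", "9p21-loss", "SETD2"),
        ("NF2", "-22q", "LATS2"),
    ),
)

#: exponential survival hazards per day; the most complex archetype carries
#: a ~4x hazard, matching its poor-prognosis role
DEFAULT_HAZARDS: tuple[float, ...] = (0.0008, 0.0008, 0.0010, 0.0012, 0.0032)


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults emulate the real study design: 22 patients, 4-5 regions each,
    mean depth 250x, purity 0.3-0.9, 86-204 mutations per patient.
    """

    n_patients: int = 22
    n_regions: tuple[int, int] = (4, 5)
    n_clusters_range: tuple[int, int] = (2, 5)
    depth: float = 250.0
    purity_range: tuple[float, float] = (0.3, 0.9)
    n_mutations_range: tuple[int, int] = (86, 204)
    error_rate: float = 0.001
    driver_archetypes: tuple[Archetype, ...] = DEFAULT_ARCHETYPES
    hazard_by_archetype: tuple[float, ...] = DEFAULT_HAZARDS
    censor_time: float = 1825.0
    hla_positions: int = 20
    hla_depth: float = 100.0
    hla_loh_prob: float = 0.2
    absent_prob: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not (1 <= self.n_regions[0] <= self.n_regions[1]):
            raise ValueError("invalid n_regions range")
        if not (1 <= self.n_clusters_range[0] <= self.n_clusters_range[1]):
            raise ValueError("invalid n_clusters_range")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        lo, hi = self.purity_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("purity must be in (0, 1]")
        if not (1 <= self.n_mutations_range[0] <= self.n_mutations_range[1]):
            raise ValueError("invalid n_mutations_range")
        if len(self.hazard_by_archetype) != len(self.driver_archetypes):
            raise ValueError("one hazard per archetype required")


@dataclass
class PatientTruth:
    """Ground truth for a single simulated patient."""

    patient: str
    parents: np.ndarray            # parent vector; parents[0] = -1 (truncal root)
    ccf: np.ndarray                # clusters x regions
    regions: list[str]
    mutation_cluster: dict         # mutation key -> cluster index
    multiplicity: dict             # mutation key -> int
    drivers: dict                  # driver event id -> cluster index
    archetype: str
    purity: dict                   # region -> purity
    survival_time: float
    survival_event: int
    hla_loh: bool


@dataclass
class GroundTruth:
    patients: dict[str, PatientTruth] = field(default_factory=dict)


@dataclass
class CohortData:
    """All synthetic inputs for the downstream pipeline stages."""

    variants: pd.DataFrame
    segments: pd.DataFrame
    purity: dict
    clinical: pd.DataFrame
    hla_coverage: pd.DataFrame
    neoantigens: pd.DataFrame
    truth: GroundTruth
    config: SimulationConfig


# ---------------------------------------------------------------------------
# Clone tree and CCFs
# ---------------------------------------------------------------------------

def _is_tree(parents: np.ndarray) -> bool:
    k = len(parents)
    for v in range(1, k):
        seen = set()
        u = v
        while u != 0:
            if u in seen:
                return False
            seen.add(u)
            u = parents[u]
            if u < 0:
                return False
    return True


def simulate_clone_tree(k: int, rng) -> np.ndarray:
    """Draw a rooted labelled clone tree on k clusters, uniformly.

    Node 0 is the truncal root. Sampling is by rejection over the parent
    vectors (each non-root node picks any of the k nodes); conditioning on
    acyclicity yields the uniform distribution over the k^(k-2) rooted
    labelled trees.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if k < 1:
        raise ValueError("cluster count must be >= 1")
    if k == 1:
        return np.array([-1])
    while True:
        parents = np.concatenate([[-1], rng.integers(0, k, size=k - 1)])
        if _is_tree(parents):
            return parents


def _children(parents: np.ndarray) -> dict[int, list[int]]:
    ch: dict[int, list[int]] = {v: [] for v in range(len(parents))}
    for v in range(1, len(parents)):
        ch[int(parents[v])].append(v)
    return ch


def _subtree(parents: np.ndarray, v: int) -> list[int]:
    ch = _children(parents)
    out, stack = [], [v]
    while stack:
        u = stack.pop()
        out.append(u)
        stack.extend(ch[u])
    return out


def assign_region_ccfs(
    parents: np.ndarray, n_regions: int, rng, absent_prob: float = 0.3
) -> np.ndarray:
    """Per-region cluster CCFs obeying the sum rule by construction.

    The truncal root has CCF 1 in every region. Each node's children split a
    Dirichlet stick of the parent's CCF (one extra stick is left unassigned,
    so children sum to <= parent). Spatial heterogeneity: each non-truncal
    subtree is absent (CCF 0) in a region with probability ``absent_prob``;
    with 3 or more clusters at least one cluster is guaranteed absent in at
    least one region.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    k = len(parents)
    ccf = np.zeros((k, n_regions))
    ccf[0, :] = 1.0
    ch = _children(parents)
    for r in range(n_regions):
        # breadth-first top-down allocation
        queue = [0]
        while queue:
            v = queue.pop(0)
            kids = ch[v]
            if not kids:
                continue
            if ccf[v, r] == 0.0:
                continue  # whole subtree absent
            sticks = rng.dirichlet(np.ones(len(kids) + 1))
            for c, s in zip(kids, sticks[:-1]):
                if rng.random() < absent_prob:
                    ccf[c, r] = 0.0
                else:
                    ccf[c, r] = ccf[v, r] * s
            queue.extend(kids)
    if k >= 3 and not np.any(ccf[1:, :] == 0.0):
        # force heterogeneity: zero out the smallest subclone in its weakest region
        v = 1 + int(np.argmin(ccf[1:, :].mean(axis=1)))
        r = int(np.argmin(ccf[v, :]))
        for u in _subtree(parents, v):
            ccf[u, r] = 0.0
    return ccf


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def simulate_reads(
    ccf_matrix: np.ndarray,
    assignments: np.ndarray,
    multiplicities: np.ndarray,
    cn_t: np.ndarray,
    purity,
    depth: float,
    rng,
    error_rate: float = 0.001,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Simulate tumour/normal read counts for each mutation in each region.

    Parameters
    ----------
    ccf_matrix : clusters x regions true CCFs.
    assignments : mutation -> cluster index.
    multiplicities : mutation -> integer multiplicity.
    cn_t : mutations x regions local tumour total copy number.
    purity : scalar or per-region array.
    depth : mean sequencing depth (site depth is Poisson around it).

    Returns (tumour_depth, tumour_alt, normal_depth, normal_alt), each
    mutations x regions.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n_mut = len(assignments)
    n_reg = ccf_matrix.shape[1]
    purity = np.broadcast_to(np.asarray(purity, dtype=float), (n_reg,))
    t_depth = rng.poisson(depth, size=(n_mut, n_reg))
    t_depth = np.maximum(t_depth, 1)
    t_alt = np.zeros_like(t_depth)
    for j in range(n_reg):
        p = purity[j]
        for i in range(n_mut):
            cc = ccf_matrix[assignments[i], j]
            ct = cn_t[i, j]
            if ct == 0:
                ev = 0.0
            else:
                ev = expected_vaf(p, int(multiplicities[i]), cc, ct)
            if ev > 1.0 + 1e-9:
                raise ValueError(
                    f"expected VAF {ev:.3f} > 1 (m={multiplicities[i]}, CN_t={ct})"
                )
            t_alt[i, j] = rng.binomial(t_depth[i, j], min(ev, 1.0))
    n_depth = rng.poisson(depth, size=(n_mut, n_reg))
    n_depth = np.maximum(n_depth, 1)
    n_alt = rng.binomial(n_depth, error_rate)
    return t_depth, t_alt, n_depth, n_alt


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def _segments_for_patient(patient, regions, events_by_region, rng):
    """Diploid baseline plus event overlays, flattened to disjoint segments."""
    rows = []
    for region in regions:
        events = events_by_region.get(region, [])
        for chrom, length in GENOME.items():
            # collect overlays on this chromosome
            here = [
                SCNA_EVENTS[e] + (e,) for e in events if SCNA_EVENTS[e][0] == chrom
            ]
            cuts = sorted({0, length} | {x[1] for x in here} | {x[2] for x in here})
            for a, b in zip(cuts[:-1], cuts[1:]):
                major, minor = 1, 1
                lost = ""
                for (c, s, e_, ma, mi, eid) in here:
                    if s <= a and b <= e_:
                        major, minor = ma, mi
                        lost = events_by_region["_lost_allele"].get(eid, "")
                rows.append(
                    dict(
                        patient=patient, region=region, chrom=chrom,
                        start=a, end=b, major=major, minor=minor,
                        lost_allele=lost if (minor == 0 and major > 0) else "",
                    )
                )
    return rows


def _choose_subclonal_node(parents: np.ndarray) -> int:
    """Deterministic 'late' node: deepest, ties to smallest index."""
    k = len(parents)
    if k == 1:
        return 0
    def depth_of(v):
        d = 0
        while parents[v] != -1:
            v = parents[v]
            d += 1
        return d
    depths = [depth_of(v) for v in range(k)]
    return int(np.argmax(depths))


def simulate_cohort(config: SimulationConfig) -> CohortData:
    """Generate a full multi-region cohort with ground truth.

    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()
    variant_rows, segment_rows, clinical_rows = [], [], []
    hla_rows, neo_rows = [], []
    purity_map: dict = {}

    n_arch = len(config.driver_archetypes)
    for ip in range(config.n_patients):
        patient = f"P{ip + 1:03d}"
        arch_idx = ip % n_arch
        arch = config.driver_archetypes[arch_idx]
        n_regions = int(rng.integers(config.n_regions[0], config.n_regions[1] + 1))
        regions = [f"R{r + 1}" for r in range(n_regions)]
        k = int(
            rng.integers(config.n_clusters_range[0], config.n_clusters_range[1] + 1)
        )
        if arch.subclonal:
            k = max(k, 2)
        parents = simulate_clone_tree(k, rng)
        ccf = assign_region_ccfs(parents, n_regions, rng, config.absent_prob)
        pur = float(rng.uniform(*config.purity_range))
        for region in regions:
            purity_map[(patient, region)] = pur
        purity_map[patient] = pur

        late_node = _choose_subclonal_node(parents)

        # --- copy-number events -------------------------------------------
        events_by_region: dict = {region: [] for region in regions}
        events_by_region["_lost_allele"] = {}
        driver_nodes: dict[str, int] = {}
        for eid in arch.truncal:
            if eid in SCNA_EVENTS:
                for region in regions:
                    events_by_region[region].append(eid)
                events_by_region["_lost_allele"][eid] = "A"
                driver_nodes[eid] = 0
        for eid in arch.subclonal:
            if eid in SCNA_EVENTS:
                present = [
                    regions[j] for j in range(n_regions) if ccf[late_node, j] >= 0.5
                ]
                if not present:
                    present = [regions[int(np.argmax(ccf[late_node]))]]
                for region in present:
                    events_by_region[region].append(eid)
                events_by_region["_lost_allele"][eid] = "A"
                driver_nodes[eid] = late_node
        segment_rows.extend(
            _segments_for_patient(patient, regions, events_by_region, rng)
        )

        # quick per-region CN lookup for this patient
        seg_df = pd.DataFrame(
            [r for r in segment_rows if r["patient"] == patient]
        )

        # --- mutations -----------------------------------------------------
        n_mut = int(
            rng.integers(config.n_mutations_range[0], config.n_mutations_range[1] + 1)
        )
        # truncal cluster carries about half the burden
        weights = np.ones(k)
        weights[0] = max(1.0, k - 1.0)
        weights /= weights.sum()
        assignments = rng.choice(k, size=n_mut, p=weights)

        # driver point mutations (placed on top of the passenger burden)
        driver_mut = []
        for gid in arch.truncal:
            if gid in DRIVER_GENES:
                driver_mut.append((gid, 0))
                driver_nodes[gid] = 0
        for gid in arch.subclonal:
            if gid in DRIVER_GENES:
                driver_mut.append((gid, late_node))
                driver_nodes[gid] = late_node

        chroms = list(GENOME)
        positions, mut_chrom = [], []
        for _ in range(n_mut):
            c = chroms[int(rng.integers(len(chroms)))]
            # avoid the homozygously deleted band (unobservable)
            while True:
                pos = int(rng.integers(1, GENOME[c]))
                if not (c == "chr9" and 21_000_000 <= pos < 23_000_000):
                    break
            mut_chrom.append(c)
            positions.append(pos)
        genes = [""] * n_mut
        effects = list(rng.choice(["nonsynonymous", "synonymous"], size=n_mut, p=[0.8, 0.2]))
        for gid, node in driver_mut:
            c, s, e_ = DRIVER_GENES[gid]
            mut_chrom.append(c)
            positions.append(int(rng.integers(s + 1, e_)))
            genes.append(gid)
            effects.append("nonsynonymous")
            assignments = np.append(assignments, node)
        n_tot = len(positions)

        # local CN per mutation per region from the segment table
        cn_t = np.zeros((n_tot, n_regions), dtype=int)
        major_m = np.zeros((n_tot, n_regions), dtype=int)
        for j, region in enumerate(regions):
            sub = seg_df[seg_df["region"] == region]
            for i in range(n_tot):
                hit = sub[
                    (sub["chrom"] == mut_chrom[i])
                    & (sub["start"] <= positions[i] - 1)
                    & (positions[i] - 1 < sub["end"])
                ]
                if len(hit):
                    cn_t[i, j] = int(hit.iloc[0]["major"] + hit.iloc[0]["minor"])
                    major_m[i, j] = int(hit.iloc[0]["major"])
                else:
                    cn_t[i, j] = 2
                    major_m[i, j] = 1
        min_major = np.maximum(major_m.min(axis=1), 1)
        mults = np.array(
            [1 if mm == 1 else int(rng.integers(1, mm + 1)) for mm in min_major]
        )

        t_depth, t_alt, n_depth, n_alt = simulate_reads(
            ccf, assignments, mults, cn_t, pur, config.depth, rng, config.error_rate
        )

        bases = np.array(["A", "C", "G", "T"])
        refs = bases[rng.integers(0, 4, size=n_tot)]
        alts = np.array(
            [bases[(list(bases).index(rf) + 1 + rng.integers(3)) % 4] for rf in refs]
        )
        flank5 = bases[rng.integers(0, 4, size=n_tot)]
        flank3 = bases[rng.integers(0, 4, size=n_tot)]
        contexts = [f"{flank5[i]}{refs[i]}{flank3[i]}" for i in range(n_tot)]
        mut_keys = [
            f"{mut_chrom[i]}:{positions[i]}:{refs[i]}>{alts[i]}" for i in range(n_tot)
        ]
        for j, region in enumerate(regions):
            for i in range(n_tot):
                variant_rows.append(
                    dict(
                        patient=patient, region=region, chrom=mut_chrom[i],
                        pos=positions[i], ref=refs[i], alt=alts[i],
                        gene=genes[i], effect=effects[i], context=contexts[i],
                        called_by="callerA,callerB", somatic_p=0.01,
                        tumour_depth=int(t_depth[i, j]),
                        tumour_alt=int(t_alt[i, j]),
                        normal_depth=int(n_depth[i, j]),
                        normal_alt=int(n_alt[i, j]),
                        mapping_quality=60, blacklist=False, popfreq_max=0.0,
                    )
                )

        # --- clinical ------------------------------------------------------
        hz = config.hazard_by_archetype[arch_idx]
        t = float(rng.exponential(1.0 / hz))
        event = int(t <= config.censor_time)
        t = min(t, config.censor_time)
        clinical_rows.append(
            dict(
                patient=patient, time=t, event=event, archetype=arch.name,
                neutrophils=float(max(0.5, rng.normal(5.0, 1.2))),
                lymphocytes=float(max(0.3, rng.normal(1.8, 0.4))),
                platelets=float(max(50, rng.normal(300, 60))),
            )
        )

        # --- HLA coverage ----------------------------------------------------
        hla_loh = bool(rng.random() < config.hla_loh_prob)
        half = config.hla_depth / 2.0
        for gene_h in ("HLA-A", "HLA-B", "HLA-C"):
            lost = hla_loh and gene_h == "HLA-A"
            d1 = rng.poisson(half, size=config.hla_positions)
            lam2 = half * (1.0 - pur) if lost else half
            d2 = rng.poisson(lam2, size=config.hla_positions)
            for pos_i in range(config.hla_positions):
                hla_rows.append(
                    dict(
                        patient=patient, gene=gene_h, position=pos_i,
                        allele1_depth=int(d1[pos_i]), allele2_depth=int(d2[pos_i]),
                        purity=pur,
                    )
                )

        # --- neoantigen candidates ------------------------------------------
        nonsyn_idx = [i for i in range(n_tot) if effects[i] == "nonsynonymous"]
        n_neo = min(len(nonsyn_idx), int(rng.integers(5, 28)))
        chosen = rng.choice(nonsyn_idx, size=n_neo, replace=False)
        for i in chosen:
            aff = float(rng.lognormal(np.log(300), 0.9))
            fold = float(rng.lognormal(np.log(2.0), 0.6))
            n_pep = int(rng.integers(1, 4))
            for _ in range(n_pep):
                neo_rows.append(
                    dict(
                        patient=patient, mutation=mut_keys[i],
                        peptide_length=int(rng.integers(8, 12)),
                        affinity_mut=aff, affinity_wt=aff * fold,
                        tumour_depth=int(t_depth[i, 0]),
                        tumour_alt=int(t_alt[i, 0]),
                        normal_depth=int(n_depth[i, 0]),
                        normal_alt=int(n_alt[i, 0]),
                    )
                )

        truth.patients[patient] = PatientTruth(
            patient=patient, parents=parents, ccf=ccf, regions=regions,
            mutation_cluster={mut_keys[i]: int(assignments[i]) for i in range(n_tot)},
            multiplicity={mut_keys[i]: int(mults[i]) for i in range(n_tot)},
            drivers=driver_nodes, archetype=arch.name,
            purity={region: pur for region in regions},
            survival_time=t, survival_event=event, hla_loh=hla_loh,
        )

    return CohortData(
        variants=pd.DataFrame(variant_rows),
        segments=pd.DataFrame(segment_rows),
        purity=purity_map,
        clinical=pd.DataFrame(clinical_rows),
        hla_coverage=pd.DataFrame(hla_rows),
        neoantigens=pd.DataFrame(neo_rows),
        truth=truth,
        config=config,
    )
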