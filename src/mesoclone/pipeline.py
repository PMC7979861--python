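"""End-to-end orchestration of the multi-region evolution pipeline.

Stage order: simulate (optional) -> filter -> ccf -> cluster -> tree ->
scna-events -> trajectories -> dnds/signatures -> neoantigen/hla-loh ->
stats. Each stage writes its outputs under the run directory and the run
manifest records the configuration hash, seed and per-file checksums, so a
rerun with the same configuration is bit-identical.

A single global seed fans out to per-stage seeds by stable hashing, keeping
the stages decoupled.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clonality, immune, io, selection, stats, trajectories, trees
from .filters import VariantCall, consensus_filter_snv
from .simulate import (
    ARM_TABLE,
    DRIVER_GENES,
    SCNA_EVENTS,
    SimulationConfig,
    simulate_cohort,
)
from .trajectories import DRIVER_VOCABULARY

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "stage_seed",
           "fit_patient_tree", "detect_driver_scnas", "load_config"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, with the study's defaults.

    Gibbs defaults here are the desk-scale setting (2,000 iterations, 200
    burn-in); the library function's own defaults are 10,000/1,000.
    """

    outdir: str = "run"
    seed: int = 0
    simulate: bool = True
    simulation: dict = field(default_factory=dict)
    # filtering
    snv_vaf_both: float = 0.02
    snv_vaf_single: float = 0.05
    # clustering
    gibbs_iters: int = 2000
    gibbs_burnin: int = 200
    dp_alpha: float = 1.0
    clonal_threshold: float = 0.9
    # trees
    sum_rule_tol: float = 0.05
    bic_epsilon: float = 2.0
    # trajectories
    n_trajectory_clusters: int = 5
    jackknife_reps: int = 25
    jackknife_leave_fraction: float = 0.1
    # signatures
    min_signature_mutations: int = 50
    log_level: str = "INFO"

    _KNOWN = None  # populated after class creation

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.from_dict(raw)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: list = field(default_factory=list)
    checksums: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"config_hash": self.config_hash, "seed": self.seed,
             "stages": self.stages, "checksums": self.checksums},
            indent=2,
        )


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the global seed (< 2^31)."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def fit_patient_tree(
    cluster_means: pd.DataFrame,
    tol: float = 0.05,
    clonal_threshold: float = 0.9,
    bic_epsilon: float = 2.0,
):
    """Enumerate, score and select one patient's clone tree.

    The truncal cluster is the one maximising its minimum per-region CCF
    (falling back gracefully when noise keeps every cluster below the
    clonal threshold somewhere). The sum-rule tolerance is doubled, up to
    0.4, until at least one feasible tree exists. Returns the selected tree
    and the candidate list (all trees within ``bic_epsilon`` of the
    optimum).
    """
    means = cluster_means.to_numpy(dtype=float)
    truncal = cluster_means.index[int(np.argmax(means.min(axis=1)))]
    feasible: list = []
    t = tol
    while not feasible and t <= 0.4:
        feasible = trees.enumerate_feasible_trees(
            cluster_means, tol=t, clonal_threshold=clonal_threshold,
            truncal=truncal,
        )
        t *= 2
    if not feasible:
        # degenerate fallback: star on the truncal cluster
        parents = {c: truncal for c in cluster_means.index if c != truncal}
        parents[truncal] = trees.GL
        feasible = [trees.CloneTree(parents=parents)]
    best = trees.score_and_select(feasible, cluster_means)
    candidates = [
        tr for tr in feasible if tr.bic <= best.bic + bic_epsilon
    ]
    return best, candidates


def detect_driver_scnas(segments: pd.DataFrame) -> dict:
    """Presence of the vocabulary copy-number driver events, per region.

    Returns event id -> {region: bool}. An interval event is present in a
    region when at least half of the interval is lost (homozygously for the
    9p21 deletion); whole-chromosome loss uses the 60% rule.
    """
    regions = sorted(segments["region"].unique())
    out: dict = {}
    for eid, (chrom, start, end, major, minor) in SCNA_EVENTS.items():
        if eid not in DRIVER_VOCABULARY:
            continue
        presence = {}
        for region in regions:
            segs = segments[
                (segments["region"] == region) & (segments["chrom"] == chrom)
            ]
            lost = 0
            for _, s in segs.iterrows():
                total = s["major"] + s["minor"]
                is_lost = total == 0 if (major + minor) == 0 else total < 2
                if is_lost:
                    lost += max(0, min(end, s["end"]) - max(start, s["start"]))
            frac = lost / (end - start)
            threshold = 0.6 if eid == "-chr4" else 0.5
            presence[region] = frac >= threshold
        if any(presence.values()):
            out[eid] = presence
    return out


def _assign_scna_to_cluster(presence: dict, cluster_means: pd.DataFrame):
    """Match an SCNA's region presence pattern to the closest CCF cluster."""
    regions = list(cluster_means.columns)
    pat = np.array([1.0 if presence.get(r, False) else 0.0 for r in regions])
    best, best_d = None, np.inf
    for c in cluster_means.index:
        cpat = (cluster_means.loc[c].to_numpy() >= 0.05).astype(float)
        d = float(np.abs(cpat - pat).sum())
        if d < best_d:
            best, best_d = c, d
    return best


def _synthetic_cds(rng, n_codons: int = 3000) -> str:
    """Random stop-free CDS used for the cohort-level dN/dS site model."""
    codons = []
    stops = {"TAA", "TAG", "TGA"}
    bases = "ACGT"
    while len(codons) < n_codons:
        c = "".join(bases[i] for i in rng.integers(0, 4, size=3))
        if c not in stops:
            codons.append(c)
    return "".join(codons)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage and return the run manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True).encode()
    ).hexdigest()[:16]
    manifest = RunManifest(config_hash=cfg_hash, seed=config.seed)

    # --- simulate ----------------------------------------------------------
    if not config.simulate:
        raise NotImplementedError(
            "external-input mode: load tables with mesoclone.io and call the "
            "stage functions directly"
        )
    sim_cfg = SimulationConfig(
        **{**config.simulation, "seed": stage_seed(config.seed, "simulate")}
    )
    cohort = simulate_cohort(sim_cfg)
    paths = io.write_cohort(cohort, outdir / "inputs")
    manifest.stages.append("simulate")

    # --- filter ------------------------------------------------------------
    decisions = []
    for idx, row in cohort.variants.iterrows():
        call = VariantCall(
            chrom=row["chrom"], pos=int(row["pos"]), ref=row["ref"],
            alt=row["alt"], region_id=row["region"],
            called_by=row["called_by"], somatic_p=row["somatic_p"],
            tumour_depth=int(row["tumour_depth"]),
            tumour_alt=int(row["tumour_alt"]),
            normal_depth=int(row["normal_depth"]),
            normal_alt=int(row["normal_alt"]),
            mapping_quality=row["mapping_quality"],
            blacklist_flag=bool(row["blacklist"]),
            population_freqs={"db": row["popfreq_max"]},
        )
        d = consensus_filter_snv(call)
        decisions.append(
            dict(index=idx, patient=row["patient"], region=row["region"],
                 variant=d.variant_key, status=d.status,
                 failed_rules=";".join(d.failed_rules))
        )
    decisions = pd.DataFrame(decisions)
    decisions.to_csv(outdir / "filter_decisions.tsv", sep="\t", index=False)
    # a mutation is retained for a patient when it passes in >= 1 region
    passing = decisions[decisions["status"] == "pass"]
    keep_keys = set(zip(passing["patient"], passing["variant"]))
    variants = cohort.variants.copy()
    variants["mutation"] = (
        variants["chrom"].astype(str) + ":" + variants["pos"].astype(str)
        + ":" + variants["ref"] + ">" + variants["alt"]
    )
    variants = variants[
        [(p, m) in keep_keys for p, m in zip(variants["patient"], variants["mutation"])]
    ]
    manifest.stages.append("filter")

    # --- ccf ---------------------------------------------------------------
    ccf_table = clonality.estimate_ccf_table(
        variants, cohort.segments, cohort.purity
    )
    ccf_table.to_csv(outdir / "ccf.tsv", sep="\t", index=False)
    manifest.stages.append("ccf")

    # --- cluster / tree / trajectories per patient --------------------------
    cluster_rows, tree_records, candidates_by_patient = [], {}, {}
    driver_nodes_by_patient: dict = {}
    clonality_by_patient: dict = {}
    seed_cluster = stage_seed(config.seed, "cluster")
    for pi, (patient, g) in enumerate(sorted(ccf_table.groupby("patient"))):
        wide_ccf = g.pivot_table(index="mutation", columns="region",
                                 values="ccf", fill_value=0.0)
        wide_depth = (
            variants[variants["patient"] == patient]
            .pivot_table(index="mutation", columns="region",
                         values="tumour_depth", fill_value=100)
            .reindex(index=wide_ccf.index, columns=wide_ccf.columns)
            .fillna(100)
        )
        labels, clusters = clonality.cluster_ccfs(
            wide_ccf.to_numpy(), wide_depth.to_numpy(),
            iters=config.gibbs_iters, burnin=config.gibbs_burnin,
            alpha=config.dp_alpha, seed=seed_cluster + pi,
            mutation_ids=list(wide_ccf.index),
        )
        mut_cluster = dict(zip(wide_ccf.index, labels))
        clon_map = {}
        for cl in clusters:
            for m in cl.members:
                clon_map[m] = cl.clonality
        clonality_by_patient[patient] = clon_map
        for m, lab in mut_cluster.items():
            cluster_rows.append(dict(patient=patient, mutation=m, cluster=lab))

        cluster_means = pd.DataFrame(
            {f"c{cl.cluster_id}": pd.Series(cl.mean_ccf) for cl in clusters}
        ).T
        cluster_means.columns = [
            wide_ccf.columns[i] for i in range(len(wide_ccf.columns))
        ]
        best, candidates = fit_patient_tree(
            cluster_means, tol=config.sum_rule_tol,
            clonal_threshold=config.clonal_threshold,
            bic_epsilon=config.bic_epsilon,
        )
        io.write_tree_json(best, outdir / f"tree_{patient}.json")
        io.write_newick(best, outdir / f"tree_{patient}.nwk")
        tree_records[patient] = dict(
            tree=best, topology=trees.classify_topology(best),
            cluster_means=cluster_means,
        )

        # drivers: mutations in vocabulary genes + detected SCNA events
        pvars = variants[variants["patient"] == patient]
        driver_nodes = {}
        for _, row in pvars[pvars["gene"].isin(DRIVER_VOCABULARY)].iterrows():
            m = row["mutation"]
            if m in mut_cluster:
                driver_nodes[row["gene"]] = f"c{mut_cluster[m]}"
        psegs = cohort.segments[cohort.segments["patient"] == patient]
        for eid, presence in detect_driver_scnas(psegs).items():
            driver_nodes[eid] = _assign_scna_to_cluster(presence, cluster_means)
        driver_nodes_by_patient[patient] = driver_nodes
        cand_records = []
        for tr in candidates:
            try:
                orderings = trajectories.extract_orderings(tr, driver_nodes)
            except ValueError:
                continue
            cand_records.append(dict(tree=tr, orderings=orderings, bic=tr.bic))
        if not cand_records:
            cand_records = [
                dict(tree=best,
                     orderings=trajectories.extract_orderings(best, driver_nodes)
                     if set(driver_nodes.values()) <= set(best.clusters)
                     else frozenset(),
                     bic=best.bic)
            ]
        candidates_by_patient[patient] = cand_records

    pd.DataFrame(cluster_rows).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    manifest.stages.extend(["cluster", "tree"])

    # --- scna events ---------------------------------------------------------
    scna_rows = []
    for patient, psegs in cohort.segments.groupby("patient"):
        for ev in trees.call_scna_events(psegs, ARM_TABLE):
            scna_rows.append(
                dict(patient=patient, event_class=ev.event_class,
                     location=ev.location, regions=",".join(ev.regions),
                     clonality=ev.clonality)
            )
    scna_df = pd.DataFrame(scna_rows)
    scna_df.to_csv(outdir / "scna_events.tsv", sep="\t", index=False)
    manifest.stages.append("scna-events")

    # --- trajectories --------------------------------------------------------
    model = trajectories.transfer_fit(candidates_by_patient)
    dist = trajectories.distance_matrix(model.orderings)
    labels = trajectories.cluster_cohort(
        dist, k=min(config.n_trajectory_clusters, len(dist)),
        orderings=model.orderings,
    )
    model.cluster_labels = labels
    jack = trajectories.jackknife_stability(
        candidates_by_patient, k=min(config.n_trajectory_clusters, len(dist)),
        leave_fraction=config.jackknife_leave_fraction,
        reps=config.jackknife_reps,
        seed=stage_seed(config.seed, "jackknife"),
    )
    pd.DataFrame(
        [{"transition": f"{a}->{b}", "count": c}
         for (a, b), c in sorted(model.transition_counts.items())]
    ).to_csv(outdir / "transitions.tsv", sep="\t", index=False)
    repeated = trajectories.repeated_transitions(model.transition_counts)
    (outdir / "repeated_transitions.json").write_text(
        json.dumps(sorted([f"{a}->{b}" for a, b in repeated]), indent=1) + "\n"
    )
    pd.Series(labels, name="cluster").rename_axis("patient").to_csv(
        outdir / "trajectory_clusters.tsv", sep="\t"
    )
    manifest.stages.append("trajectories")

    # --- dN/dS and signatures -------------------------------------------------
    rng = np.random.default_rng(stage_seed(config.seed, "dnds"))
    cds = _synthetic_cds(rng)
    l_non, l_syn = selection.expected_site_counts(cds)
    dnds_rows = []
    merged = variants.drop_duplicates(subset=["patient", "mutation"]).merge(
        pd.DataFrame(cluster_rows), on=["patient", "mutation"], how="left"
    )
    merged["clonality"] = [
        clonality_by_patient.get(p, {}).get(m, "subclonal")
        for p, m in zip(merged["patient"], merged["mutation"])
    ]
    for scope in ("clonal", "subclonal", "all"):
        sub = merged if scope == "all" else merged[merged["clonality"] == scope]
        n_non = int((sub["effect"] == "nonsynonymous").sum())
        n_syn = int((sub["effect"] == "synonymous").sum())
        res = selection.dnds(n_non, n_syn, l_non, l_syn, gene="cohort", scope=scope)
        dnds_rows.append(
            dict(scope=scope, n_non=n_non, n_syn=n_syn, dnds=res.dnds,
                 p_value=res.p_value)
        )
    pd.DataFrame(dnds_rows).to_csv(outdir / "dnds.tsv", sep="\t", index=False)

    basis = selection.toy_signature_matrix()
    sig_rows = []
    for patient, g in merged.groupby("patient"):
        counts = selection.context_counts(g)
        fit = selection.fit_signatures(
            counts, basis, sample=patient,
            min_mutations=config.min_signature_mutations,
        )
        sig_rows.append(
            dict(patient=patient, status=fit.status, n=fit.n_mutations,
                 residual=fit.residual, **fit.exposures)
        )
    pd.DataFrame(sig_rows).to_csv(outdir / "signatures.tsv", sep="\t", index=False)
    manifest.stages.extend(["dnds", "signatures"])

    # --- neoantigens / HLA LOH --------------------------------------------------
    neo = immune.filter_neoantigens(cohort.neoantigens)
    burden_rows = []
    for patient, g in neo.groupby("patient"):
        clon = clonality_by_patient.get(patient, {})
        g = g[g["mutation"].isin(clon)]
        burden = immune.neoantigen_burden(g, clon)
        if len(burden):
            burden_rows.append(burden.assign(patient=patient))
        else:
            burden_rows.append(
                pd.DataFrame([dict(patient=patient, clonal=0, subclonal=0)])
            )
    burden_df = pd.concat(burden_rows, ignore_index=True)
    burden_df.to_csv(outdir / "neoantigen_burden.tsv", sep="\t", index=False)

    loh_rows = []
    for (patient, gene), g in cohort.hla_coverage.groupby(["patient", "gene"]):
        cov = immune.HlaAlleleCoverage(
            patient=patient, gene=gene,
            allele1_depth=g["allele1_depth"].to_numpy(),
            allele2_depth=g["allele2_depth"].to_numpy(),
            purity=float(g["purity"].iloc[0]),
        )
        res = immune.call_hla_loh(cov)
        loh_rows.append(dict(patient=patient, gene=gene, **{
            k: v for k, v in res.items() if k != "status"
        }))
    loh_df = pd.DataFrame(loh_rows)
    loh_df.to_csv(outdir / "hla_loh.tsv", sep="\t", index=False)
    manifest.stages.extend(["neoantigen", "hla-loh"])

    # --- cohort statistics -------------------------------------------------------
    clinical = cohort.clinical.copy()
    kmax = max(labels.values())
    clinical["group"] = [
        "C_max" if labels.get(p) == kmax else "other" for p in clinical["patient"]
    ]
    stats_out = {}
    try:
        km = stats.km_logrank(clinical[["time", "event", "group"]])
        stats_out["survival_most_complex_vs_rest"] = {
            "p": km["p"], "hr": km["hr"], "hr_ci95": list(km["hr_ci95"]),
        }
    except ValueError as exc:
        stats_out["survival_most_complex_vs_rest"] = {"error": str(exc)}
    clinical["nlr"] = clinical["neutrophils"] / clinical["lymphocytes"]
    clinical["plr"] = clinical["platelets"] / clinical["lymphocytes"]
    clonal_scna = (
        scna_df[scna_df["clonality"] == "clonal"].groupby("patient").size()
        if len(scna_df) else pd.Series(dtype=int)
    )
    clinical["clonal_scna"] = clinical["patient"].map(clonal_scna).fillna(0)
    hi = clinical["clonal_scna"] > clinical["clonal_scna"].median()
    if hi.any() and (~hi).any():
        stats_out["nlr_vs_clonal_scna"] = stats.mann_whitney(
            clinical.loc[hi, "nlr"], clinical.loc[~hi, "nlr"]
        )
    (outdir / "stats.json").write_text(json.dumps(stats_out, indent=2) + "\n")
    manifest.stages.append("stats")

    for f in sorted(outdir.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest.checksums[str(f.relative_to(outdir))] = io.file_checksum(f)
    (outdir / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest
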