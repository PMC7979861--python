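"""Reading and writing the pipeline's on-disk formats.

Variants travel as a minimal VCF v4.2 dialect (one file per patient, one
sample column per region, FORMAT fields TDEP/TALT/NDEP/NALT, INFO key
CALLER) or an equivalent flat TSV; copy-number segments, clinical tables and
decisions are TSV; trees are JSON plus a Newick export. VCF positions are
1-based at the file boundary; segment coordinates are 0-based half-open.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .simulate import CohortData
from .trees import CloneTree

__all__ = [
    "write_vcf_minimal",
    "read_vcf_minimal",
    "write_segments",
    "read_segments",
    "write_tree_json",
    "read_tree_json",
    "write_newick",
    "write_cohort",
    "read_cohort_tables",
    "file_checksum",
]

VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=CALLER,Number=.,Type=String,Description="Callers supporting the variant">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=EFFECT,Number=1,Type=String,Description="Coding effect">
##FORMAT=<ID=TDEP,Number=1,Type=Integer,Description="Tumour depth">
##FORMAT=<ID=TALT,Number=1,Type=Integer,Description="Tumour alt reads">
##FORMAT=<ID=NDEP,Number=1,Type=Integer,Description="Normal depth">
##FORMAT=<ID=NALT,Number=1,Type=Integer,Description="Normal alt reads">
"""


def write_vcf_minimal(variants: pd.DataFrame, path) -> None:
    """Write one patient's variants as a minimal multi-sample VCF.

    ``variants`` holds rows for a single patient across regions; region ids
    become the sample columns.
    """
    patients = variants["patient"].unique()
    if len(patients) != 1:
        raise ValueError("write one patient per VCF file")
    regions = sorted(variants["region"].unique())
    lines = [VCF_HEADER.rstrip("\n")]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(regions)
    )
    keyed = variants.set_index(["chrom", "pos", "ref", "alt", "region"]).sort_index()
    sites = variants[["chrom", "pos", "ref", "alt", "called_by", "gene", "effect"]]
    sites = sites.drop_duplicates(subset=["chrom", "pos", "ref", "alt"])
    sites = sites.sort_values(["chrom", "pos"])
    for _, s in sites.iterrows():
        info = f"CALLER={s['called_by'].replace(',', '|') or '.'}"
        if s.get("gene"):
            info += f";GENE={s['gene']}"
        if s.get("effect"):
            info += f";EFFECT={s['effect']}"
        cells = []
        for region in regions:
            try:
                row = keyed.loc[(s["chrom"], s["pos"], s["ref"], s["alt"], region)]
            except KeyError:
                cells.append(".:.:.:.")
                continue
            cells.append(
                f"{int(row['tumour_depth'])}:{int(row['tumour_alt'])}:"
                f"{int(row['normal_depth'])}:{int(row['normal_alt'])}"
            )
        lines.append(
            f"{s['chrom']}\t{int(s['pos'])}\t.\t{s['ref']}\t{s['alt']}\t.\tPASS\t"
            f"{info}\tTDEP:TALT:NDEP:NALT\t" + "\t".join(cells)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf_minimal(path, patient: str | None = None) -> pd.DataFrame:
    """Read the minimal VCF dialect back into the flat variant table."""
    path = str(path)
    if patient is None:
        patient = Path(path).stem.split(".")[0]
    rows = []
    try:
        vcf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise ValueError(f"malformed VCF {path}: {exc}") from exc
    with vcf:
        regions = list(vcf.header.samples)
        for i, rec in enumerate(vcf, start=1):
            try:
                caller = rec.info.get("CALLER", ("",))
                caller = ",".join(caller) if isinstance(caller, tuple) else str(caller)
                caller = caller.replace("|", ",")
                for region in regions:
                    smp = rec.samples[region]
                    if smp.get("TDEP") is None:
                        continue
                    rows.append(
                        dict(
                            patient=patient, region=region, chrom=rec.chrom,
                            pos=rec.pos, ref=rec.ref, alt=rec.alts[0],
                            gene=rec.info.get("GENE", ""),
                            effect=rec.info.get("EFFECT", ""),
                            called_by=caller,
                            tumour_depth=int(smp["TDEP"]),
                            tumour_alt=int(smp["TALT"]),
                            normal_depth=int(smp["NDEP"]),
                            normal_alt=int(smp["NALT"]),
                        )
                    )
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(
                    f"malformed VCF record {i} in {path}: {exc}"
                ) from exc
    return pd.DataFrame(rows)


def write_segments(segments: pd.DataFrame, path) -> None:
    segments.to_csv(path, sep="\t", index=False)


def read_segments(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "major", "minor", "region"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"segment table missing columns: {sorted(missing)}")
    if "lost_allele" in df.columns:
        df["lost_allele"] = df["lost_allele"].fillna("")
    return df


def write_tree_json(tree: CloneTree, path) -> None:
    payload = {
        "parents": {str(k): str(v) for k, v in tree.parents.items()},
        "rss": tree.rss,
        "bic": tree.bic,
    }
    if tree.fitted_ccf is not None:
        payload["fitted_ccf"] = {
            str(c): [float(x) for x in tree.fitted_ccf.loc[c]]
            for c in tree.fitted_ccf.index
        }
        payload["regions"] = list(map(str, tree.fitted_ccf.columns))
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_tree_json(path) -> CloneTree:
    payload = json.loads(Path(path).read_text())
    parents = {
        (int(k) if k.isdigit() else k): (int(v) if v.isdigit() else v)
        for k, v in payload["parents"].items()
    }
    tree = CloneTree(parents=parents, rss=payload.get("rss", np.nan),
                     bic=payload.get("bic", np.nan))
    if "fitted_ccf" in payload:
        tree.fitted_ccf = pd.DataFrame(
            {c: payload["fitted_ccf"][str(c)] for c in parents},
            index=payload["regions"],
        ).T
    return tree


def write_newick(tree: CloneTree, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def write_cohort(cohort: CohortData, outdir) -> dict:
    """Write every simulated table (VCF + TSVs + ground-truth JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    cohort.variants.to_csv(outdir / "variants.tsv", sep="\t", index=False)
    paths["variants"] = outdir / "variants.tsv"
    for patient, g in cohort.variants.groupby("patient"):
        p = outdir / f"{patient}.vcf"
        write_vcf_minimal(g, p)
        paths[f"vcf:{patient}"] = p
    write_segments(cohort.segments, outdir / "segments.tsv")
    paths["segments"] = outdir / "segments.tsv"
    pd.Series(
        {f"{k[0]}:{k[1]}" if isinstance(k, tuple) else k: v
         for k, v in cohort.purity.items()}
    ).rename("purity").to_csv(outdir / "purity.tsv", sep="\t")
    paths["purity"] = outdir / "purity.tsv"
    cohort.clinical.to_csv(outdir / "clinical.tsv", sep="\t", index=False)
    paths["clinical"] = outdir / "clinical.tsv"
    cohort.hla_coverage.to_csv(outdir / "hla_coverage.tsv", sep="\t", index=False)
    paths["hla_coverage"] = outdir / "hla_coverage.tsv"
    cohort.neoantigens.to_csv(outdir / "neoantigens.tsv", sep="\t", index=False)
    paths["neoantigens"] = outdir / "neoantigens.tsv"

    truth = {
        patient: {
            "parents": t.parents.tolist(),
            "ccf": t.ccf.tolist(),
            "regions": t.regions,
            "mutation_cluster": t.mutation_cluster,
            "multiplicity": t.multiplicity,
            "drivers": t.drivers,
            "archetype": t.archetype,
            "purity": t.purity,
            "survival_time": t.survival_time,
            "survival_event": t.survival_event,
            "hla_loh": t.hla_loh,
        }
        for patient, t in cohort.truth.patients.items()
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=1) + "\n")
    paths["ground_truth"] = outdir / "ground_truth.json"
    return paths


def read_cohort_tables(indir) -> dict:
    """Load the cohort TSVs written by :func:`write_cohort`."""
    indir = Path(indir)
    purity_raw = pd.read_csv(indir / "purity.tsv", sep="\t", index_col=0)["purity"]
    purity = {}
    for key, val in purity_raw.items():
        if ":" in str(key):
            patient, region = str(key).split(":", 1)
            purity[(patient, region)] = float(val)
        else:
            purity[str(key)] = float(val)
    return {
        "variants": pd.read_csv(indir / "variants.tsv", sep="\t"),
        "segments": read_segments(indir / "segments.tsv"),
        "purity": purity,
        "clinical": pd.read_csv(indir / "clinical.tsv", sep="\t"),
        "hla_coverage": pd.read_csv(indir / "hla_coverage.tsv", sep="\t"),
        "neoantigens": pd.read_csv(indir / "neoantigens.tsv", sep="\t"),
    }


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
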