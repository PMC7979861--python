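"""Neoantigen filtering/burden and HLA loss-of-heterozygosity calling.

Neoantigen candidates (8-11-mer peptides from non-synonymous mutations, with
externally predicted MHC-I binding affinities) are kept when the mutant
affinity is below 500 nM and the sequencing evidence holds (normal coverage
>= 5x, normal VAF <= 2%, tumour coverage >= 10x, tumour VAF >= 10%);
candidates whose wild-type/mutant affinity fold change exceeds 2 are flagged
higher priority. Burden counts each source mutation once, by clonality.

HLA LOH is called per gene from allele-specific coverage at mismatch
positions between the two homologous alleles: the per-position log2 depth
ratio is tested against zero by a paired Wilcoxon signed-rank test, with a
median absolute log-ratio floor as the effect-size guard (the printed
"PVal_unique <= 0.01" rule is internally inconsistent as stated upstream, so
the test here is a documented interpretation: p <= 0.01 plus effect floor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

__all__ = [
    "NeoantigenCandidate",
    "HlaAlleleCoverage",
    "filter_neoantigens",
    "neoantigen_burden",
    "call_hla_loh",
]

AFFINITY_CUTOFF_NM = 500.0
PRIORITY_FOLD_CHANGE = 2.0
LOH_P_CUTOFF = 0.01
LOH_MIN_EFFECT = 0.3
MIN_MISMATCH_POSITIONS = 5


@dataclass
class NeoantigenCandidate:
    mutation: str
    peptide_length: int
    affinity_mut: float
    affinity_wt: float
    tumour_depth: int
    tumour_alt: int
    normal_depth: int
    normal_alt: int

    def __post_init__(self):
        if self.peptide_length not in (8, 9, 10, 11):
            raise ValueError("peptide length must be 8-11")
        if self.affinity_mut <= 0 or self.affinity_wt <= 0:
            raise ValueError("affinities must be positive")


@dataclass
class HlaAlleleCoverage:
    patient: str
    gene: str
    allele1_depth: np.ndarray
    allele2_depth: np.ndarray
    purity: float = np.nan
    ploidy: float = 2.0

    def __post_init__(self):
        self.allele1_depth = np.asarray(self.allele1_depth, dtype=float)
        self.allele2_depth = np.asarray(self.allele2_depth, dtype=float)
        if self.allele1_depth.shape != self.allele2_depth.shape:
            raise ValueError("allele depth vectors must have equal length")
        if np.any(self.allele1_depth < 0) or np.any(self.allele2_depth < 0):
            raise ValueError("depths must be non-negative")


def filter_neoantigens(candidates: pd.DataFrame) -> pd.DataFrame:
    """Apply affinity and sequencing-evidence rules; flag priority.

    Expects columns: mutation, peptide_length, affinity_mut, affinity_wt,
    tumour_depth, tumour_alt, normal_depth, normal_alt. Returns the input
    with boolean columns ``kept`` and ``priority``.
    """
    df = candidates.copy()
    t_vaf = np.where(df["tumour_depth"] > 0, df["tumour_alt"] / df["tumour_depth"], 0.0)
    n_vaf = np.where(df["normal_depth"] > 0, df["normal_alt"] / df["normal_depth"], 0.0)
    df["kept"] = (
        (df["affinity_mut"] < AFFINITY_CUTOFF_NM)
        & (df["normal_depth"] >= 5)
        & (n_vaf <= 0.02)
        & (df["tumour_depth"] >= 10)
        & (t_vaf >= 0.10)
    )
    df["priority"] = df["kept"] & (
        df["affinity_wt"] / df["affinity_mut"] > PRIORITY_FOLD_CHANGE
    )
    return df


def neoantigen_burden(kept: pd.DataFrame, clonality: dict) -> pd.DataFrame:
    """Per-patient clonal/subclonal neoantigen counts.

    A neoantigen is counted once per unique source mutation (multiple
    peptide lengths from one mutation count once). ``clonality`` maps
    mutation key -> "clonal" | "subclonal"; an unlabelled mutation raises.
    """
    rows = []
    if len(kept) == 0:
        return pd.DataFrame(columns=["patient", "clonal", "subclonal"])
    for patient, g in kept[kept["kept"]].groupby("patient"):
        muts = g["mutation"].unique()
        counts = {"clonal": 0, "subclonal": 0}
        for m in muts:
            if m not in clonality:
                raise KeyError(f"mutation {m} has no clonality label")
            counts[clonality[m]] += 1
        rows.append(dict(patient=patient, **counts))
    return pd.DataFrame(rows)


def call_hla_loh(
    cov: HlaAlleleCoverage,
    p_cutoff: float = LOH_P_CUTOFF,
    min_effect: float = LOH_MIN_EFFECT,
) -> dict:
    """HLA LOH call from allele-specific coverage at mismatch positions.

    Per-position log2 ratios (allele1+0.5)/(allele2+0.5) are tested against
    zero with a two-sided paired Wilcoxon signed-rank test; LOH is called
    when p <= ``p_cutoff`` and the median |log ratio| >= ``min_effect``.
    The lost allele is the lower-coverage one. Fewer than 5 mismatch
    positions -> indeterminate.
    """
    n = len(cov.allele1_depth)
    if n < MIN_MISMATCH_POSITIONS:
        return {"status": "indeterminate", "loh": False,
                "logR_diff": np.nan, "p": np.nan, "lost_allele": None}
    log_r = np.log2((cov.allele1_depth + 0.5) / (cov.allele2_depth + 0.5))
    if np.allclose(log_r, 0.0):
        p = 1.0
    else:
        p = float(wilcoxon(log_r, alternative="two-sided",
                           zero_method="wilcox").pvalue)
    med = float(np.median(log_r))
    loh = bool(p <= p_cutoff and abs(med) >= min_effect)
    lost = None
    if loh:
        lost = "allele2" if med > 0 else "allele1"
    return {"status": "determined", "loh": loh, "logR_diff": med,
            "p": p, "lost_allele": lost}
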