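"""Somatic SNV/indel consensus filtering, force-calling and driver flagging.

Implements the bespoke evidence rules of a two-caller (MuTect2-like +
VarScan2-like) somatic pipeline:

* SNVs pass when called by both callers (somatic p <= 0.1) with VAF >= 2% in
  both, or by the second caller alone with VAF > 5%; the matched normal must
  show VAF < 1% and fewer than 5 alt reads; blacklisted (simple-repeat /
  segmental-duplication) sites and variants above 1% population frequency in
  any database are removed.
* Indels require VAF >= 5% with somatic p <= 0.05, tumour depth > 50,
  tumour alt reads > 10 and normal alt reads < 2, plus the same blacklist
  and population rules.
* Force-calling rescues a site in regions where it was not called, when the
  site passed in at least one region of the same patient and the negative
  region shows mapping quality > 20 and VAF > 2%.

Boundary semantics: "no <2%" is read as >= 2%, "greater than 5%" as strictly
> 5%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

__all__ = [
    "VariantCall",
    "FilterDecision",
    "consensus_filter_snv",
    "filter_indel",
    "force_call",
    "purity_sanity_check",
    "deleteriousness_consensus",
    "flag_drivers",
]

logger = logging.getLogger(__name__)

CALLER_A = "callerA"  # MuTect2-like
CALLER_B = "callerB"  # VarScan2-like


@dataclass
class VariantCall:
    """One somatic variant observed in one tumour region."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    region_id: str = "R1"
    called_by: frozenset = frozenset({CALLER_A, CALLER_B})
    somatic_p: float | None = None
    tumour_depth: int = 0
    tumour_alt: int = 0
    normal_depth: int = 0
    normal_alt: int = 0
    mapping_quality: float = 60.0
    population_freqs: dict = field(default_factory=dict)
    blacklist_flag: bool = False
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        if isinstance(self.called_by, (set, list, tuple, str)):
            if isinstance(self.called_by, str):
                self.called_by = frozenset(
                    x for x in self.called_by.split(",") if x
                )
            else:
                self.called_by = frozenset(self.called_by)
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if not (0 <= self.tumour_alt <= self.tumour_depth):
            raise ValueError("tumour alt count out of range")
        if not (0 <= self.normal_alt <= self.normal_depth):
            raise ValueError("normal alt count out of range")

    @property
    def vaf(self) -> float:
        return self.tumour_alt / self.tumour_depth if self.tumour_depth else 0.0

    @property
    def normal_vaf(self) -> float:
        return self.normal_alt / self.normal_depth if self.normal_depth else 0.0

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass
class FilterDecision:
    variant_key: str
    status: str  # pass | fail | force_called
    failed_rules: list = field(default_factory=list)

    def __post_init__(self):
        if self.status == "pass" and self.failed_rules:
            raise ValueError("passing decision cannot carry failed rules")


def _common_rules(call: VariantCall, failed: list) -> None:
    if call.blacklist_flag:
        failed.append("blacklist")
    if any(f > 0.01 for f in call.population_freqs.values()):
        failed.append("population-frequency")


def consensus_filter_snv(call: VariantCall) -> FilterDecision:
    """Dual-caller consensus filter for somatic SNVs."""
    failed: list[str] = []
    if call.tumour_depth == 0:
        return FilterDecision(call.key, "fail", ["no-coverage"])

    both = {CALLER_A, CALLER_B} <= call.called_by
    b_only = call.called_by == {CALLER_B}
    somatic_p = 1.0 if call.somatic_p is None else call.somatic_p
    evidence_ok = (both and somatic_p <= 0.1 and call.vaf >= 0.02) or (
        b_only and call.vaf > 0.05
    )
    if not evidence_ok:
        failed.append("caller-evidence")
    if not call.normal_vaf < 0.01:
        failed.append("normal-vaf")
    if not call.normal_alt < 5:
        failed.append("normal-alt-reads")
    _common_rules(call, failed)
    return FilterDecision(call.key, "pass" if not failed else "fail", failed)


def filter_indel(call: VariantCall) -> FilterDecision:
    """Indel filter: stricter evidence thresholds than the SNV rule."""
    failed: list[str] = []
    if call.tumour_depth == 0:
        return FilterDecision(call.key, "fail", ["no-coverage"])
    somatic_p = 1.0 if call.somatic_p is None else call.somatic_p
    if not call.vaf >= 0.05:
        failed.append("vaf")
    if not somatic_p <= 0.05:
        failed.append("somatic-p")
    if not call.tumour_depth > 50:
        failed.append("tumour-depth")
    if not call.tumour_alt > 10:
        failed.append("tumour-alt-reads")
    if not call.normal_alt < 2:
        failed.append("normal-alt-reads")
    _common_rules(call, failed)
    return FilterDecision(call.key, "pass" if not failed else "fail", failed)


def force_call(site_key: str, region_readcounts: dict) -> dict:
    """Rescue a filtered-out site in negative regions of the same patient.

    ``region_readcounts`` maps region id -> dict with keys mapping_quality,
    tumour_depth, tumour_alt (or None when no readcount data exists).
    Returns region -> status in {"positive", "negative"}; rescued regions
    are additionally flagged ``force_called``. Force-calling only ever adds
    presence.
    """
    out = {}
    for region, rc in region_readcounts.items():
        if rc is None:
            logger.warning(
                "no readcount data for %s in region %s; stays negative",
                site_key, region,
            )
            out[region] = {"status": "negative", "force_called": False}
            continue
        depth = rc.get("tumour_depth", 0)
        vaf = rc.get("tumour_alt", 0) / depth if depth else 0.0
        positive = rc.get("mapping_quality", 0) > 20 and vaf > 0.02
        out[region] = {
            "status": "positive" if positive else "negative",
            "force_called": bool(positive),
        }
    return out


def purity_sanity_check(vafs, purity: float):
    """Check that the VAF-distribution peak is consistent with purity/2.

    Under clonal heterozygous diploid mutations the VAF mode should sit at
    one half of the tumour purity. Samples whose kernel-density VAF mode
    falls below 0.1 are excluded as low purity.

    Returns dict with status in {"pass", "exclude", "indeterminate"}, the
    KDE mode, and |mode - purity/2|.
    """
    vafs = np.asarray(list(vafs), dtype=float)
    if vafs.size < 20:
        return {"status": "indeterminate", "mode": np.nan, "deviation": np.nan}
    kde = gaussian_kde(vafs)
    grid = np.linspace(0.0, 1.0, 512)
    mode = float(grid[np.argmax(kde(grid))])
    status = "exclude" if mode < 0.1 else "pass"
    return {"status": status, "mode": mode, "deviation": abs(mode - purity / 2.0)}


_DELETERIOUS = {"D"}
_LOWCONF = {"low-D", "low_confidence_D"}


def deleteriousness_consensus(annotations: dict) -> str:
    """Four-predictor consensus (CScape, MutationTaster, SIFT, PolyPhen).

    Deleterious iff CScape and MutationTaster both call deleterious, or
    CScape is low-confidence deleterious while the other three predictors
    all call deleterious. Missing predictions count as tolerated.
    """
    cscape = annotations.get("CScape", "T")
    mt = annotations.get("MutationTaster", "T")
    sift = annotations.get("SIFT", "T")
    pp = annotations.get("PolyPhen", "T")
    if cscape in _DELETERIOUS and mt in _DELETERIOUS:
        return "deleterious"
    if cscape in _LOWCONF and all(x in _DELETERIOUS for x in (mt, sift, pp)):
        return "deleterious"
    return "tolerated"


def flag_drivers(gene_qvalues: dict, curated_list, mutated_genes=None) -> set:
    """Candidate driver genes: q < 0.05 by either supplied method, plus any
    curated gene carrying a non-silent variant.

    ``gene_qvalues`` maps gene -> iterable of q-values (one per method).
    ``mutated_genes`` is the set of genes with non-silent variants in the
    cohort (defaults to all genes in ``gene_qvalues``).
    """
    flagged = set()
    for gene, qs in gene_qvalues.items():
        qs = [qs] if np.isscalar(qs) else list(qs)
        if any(not 0 <= q <= 1 for q in qs):
            raise ValueError(f"q-values must be in [0,1] for {gene}")
        if any(q < 0.05 for q in qs):
            flagged.add(gene)
    if mutated_genes is None:
        mutated_genes = set(gene_qvalues)
    flagged |= set(curated_list) & set(mutated_genes)
    return flagged
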