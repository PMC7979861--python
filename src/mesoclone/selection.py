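"""Positive-selection scan (dN/dS) and mutational-signature exposure fitting.

dN/dS here is a counting estimator: observed non-synonymous and synonymous
mutation counts are normalised by the expected numbers of non-synonymous and
synonymous sites in the coding sequence under a substitution-rate model
(uniform by default, optionally trinucleotide-context weighted)::

    dN/dS = (n_non / L_non) / (n_syn / L_syn)

A ratio above 1 indicates positive selection. Significance per gene is a
conditional binomial test of the non-synonymous count against the neutral
site proportion, corrected across genes by Benjamini-Hochberg.

Signature fitting decomposes a sample's 96-channel trinucleotide mutation
spectrum onto a fixed signature matrix by non-negative least squares;
samples with fewer than 50 mutations are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from scipy.optimize import nnls
from scipy.stats import binomtest, false_discovery_control

__all__ = [
    "SelectionResult",
    "SignatureFit",
    "expected_site_counts",
    "dnds",
    "dnds_scan",
    "classify_context",
    "context_counts",
    "fit_signatures",
    "sample_mutation_counts",
    "toy_signature_matrix",
    "MIN_MUTATIONS_FOR_SIGNATURES",
]

MIN_MUTATIONS_FOR_SIGNATURES = 50

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"


@dataclass
class SelectionResult:
    gene: str
    scope: str  # clonal | subclonal | all
    n_non: int
    n_syn: int
    l_non: float
    l_syn: float
    dnds: float
    ci95: tuple[float, float]
    p_value: float
    q_value: float = np.nan
    flagged_infinite: bool = False


@dataclass
class SignatureFit:
    sample: str
    exposures: dict = field(default_factory=dict)
    residual: float = np.nan
    n_mutations: int = 0
    status: str = "fitted"  # fitted | excluded


def expected_site_counts(cds: str, rate_model: dict | None = None) -> tuple[float, float]:
    """Expected non-synonymous and synonymous site counts of a CDS.

    Every possible single-base substitution at every position is weighted by
    the rate model and classified through the standard codon table. Under
    the uniform default each of a site's three alternative bases carries
    weight 1/3, so every site contributes total mass 1 and
    L_non + L_syn = len(cds). A ``rate_model`` maps trinucleotide-context
    mutation keys (``"ACA>T"``-style) to relative rates.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    n_codons = len(cds) // 3
    for i in range(n_codons - 1):
        if _CODON_TABLE.get(cds[3 * i: 3 * i + 3]) == "*":
            raise ValueError(f"internal stop codon at codon {i}")
    l_non = l_syn = 0.0
    for pos in range(len(cds)):
        ref = cds[pos]
        if ref not in _BASES:
            raise ValueError(f"ambiguous base {ref!r} at {pos}")
        ci = pos // 3
        codon = cds[3 * ci: 3 * ci + 3]
        aa = _CODON_TABLE[codon]
        off = pos % 3
        for alt in _BASES:
            if alt == ref:
                continue
            if rate_model is None:
                rate = 1.0 / 3.0
            else:
                left = cds[pos - 1] if pos > 0 else "N"
                right = cds[pos + 1] if pos < len(cds) - 1 else "N"
                rate = rate_model.get(f"{left}{ref}{right}>{alt}", 1.0)
            new_codon = codon[:off] + alt + codon[off + 1:]
            if _CODON_TABLE[new_codon] == aa:
                l_syn += rate
            else:
                l_non += rate
    return l_non, l_syn


def dnds(
    n_non: int,
    n_syn: int,
    l_non: float,
    l_syn: float,
    gene: str = "",
    scope: str = "all",
) -> SelectionResult:
    """Site-normalised dN/dS with a conditional binomial test.

    Conditional on the total mutation count, the non-synonymous count is
    Binomial(n_non + n_syn, L_non / (L_non + L_syn)) under neutrality; the
    reported CI on dN/dS transforms the exact CI on that proportion.
    """
    if l_syn <= 0:
        raise ValueError("expected synonymous site count must be positive")
    null_p = l_non / (l_non + l_syn)
    total = n_non + n_syn
    infinite = n_syn == 0
    ratio = np.inf if infinite else (n_non / l_non) / (n_syn / l_syn)
    if total == 0:
        return SelectionResult(gene, scope, 0, 0, l_non, l_syn, np.nan,
                               (np.nan, np.nan), 1.0)
    test = binomtest(n_non, total, null_p, alternative="two-sided")
    ci = test.proportion_ci(confidence_level=0.95, method="exact")
    site_ratio = l_non / l_syn

    def prop_to_dnds(pi):
        if pi >= 1.0:
            return np.inf
        return (pi / (1 - pi)) / site_ratio

    return SelectionResult(
        gene=gene, scope=scope, n_non=n_non, n_syn=n_syn,
        l_non=l_non, l_syn=l_syn, dnds=float(ratio),
        ci95=(prop_to_dnds(ci.low), prop_to_dnds(ci.high)),
        p_value=float(test.pvalue), flagged_infinite=infinite,
    )


def dnds_scan(gene_counts: pd.DataFrame, scope: str = "all") -> pd.DataFrame:
    """Per-gene dN/dS with Benjamini-Hochberg q-values.

    ``gene_counts`` needs columns gene, n_non, n_syn, l_non, l_syn.
    """
    results = [
        dnds(int(r["n_non"]), int(r["n_syn"]), float(r["l_non"]),
             float(r["l_syn"]), gene=r["gene"], scope=scope)
        for _, r in gene_counts.iterrows()
    ]
    pvals = np.array([r.p_value for r in results])
    qvals = false_discovery_control(pvals, method="bh") if len(pvals) else pvals
    rows = []
    for r, q in zip(results, qvals):
        r.q_value = float(q)
        rows.append(
            dict(gene=r.gene, scope=r.scope, n_non=r.n_non, n_syn=r.n_syn,
                 l_non=r.l_non, l_syn=r.l_syn, dnds=r.dnds,
                 ci_lo=r.ci95[0], ci_hi=r.ci95[1],
                 p_value=r.p_value, q_value=r.q_value,
                 flagged_infinite=r.flagged_infinite)
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# 96-channel trinucleotide contexts
# ---------------------------------------------------------------------------

_SUBS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


def channel_names() -> list[str]:
    """The 96 channel labels in canonical COSMIC order."""
    names = []
    for sub in _SUBS:
        ref = sub[0]
        for five in _BASES:
            for three in _BASES:
                names.append(f"{five}[{sub}]{three}")
    return names


def classify_context(ref: str, alt: str, context: str) -> int:
    """96-channel index of a substitution in its trinucleotide context.

    ``context`` is the 3-mer centred on the mutated base on the reference
    strand. Purine references are complemented onto the pyrimidine strand
    (reversing the context), following the COSMIC single-base-substitution
    convention. Channels are ordered C>A, C>G, C>T, T>A, T>C, T>G, each with
    16 contexts (5' base fast within 3' base... 5' outer, 3' inner).
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(context) != 3 or context[1] != ref:
        raise ValueError("context must be a 3-mer centred on the reference base")
    if any(b not in _BASES for b in context + alt) or ref == alt:
        raise ValueError(f"ambiguous or invalid substitution {context}>{alt}")
    if ref in "AG":  # purine: flip to the pyrimidine strand
        context = context.translate(_COMPLEMENT)[::-1]
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
    sub_idx = _SUBS.index(f"{ref}>{alt}")
    five = _BASES.index(context[0])
    three = _BASES.index(context[2])
    return sub_idx * 16 + five * 4 + three


def context_counts(mutations: pd.DataFrame) -> np.ndarray:
    """96-vector of counts from a table with columns ref, alt, context.

    Rows with ambiguous bases are skipped.
    """
    counts = np.zeros(96, dtype=int)
    for _, row in mutations.iterrows():
        try:
            counts[classify_context(row["ref"], row["alt"], row["context"])] += 1
        except ValueError:
            continue
    return counts


def sample_mutation_counts(
    cds: str, n: int, rng, nonsyn_multiplier: float = 1.0
) -> tuple[int, int]:
    """Draw ``n`` substitutions on a CDS and count (n_non, n_syn).

    Each possible (site, alternative base) substitution is equally likely
    under neutrality; non-synonymous substitutions get their probability
    multiplied by ``nonsyn_multiplier`` to emulate positive selection.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    cds = cds.upper()
    is_non = []
    for pos in range(len(cds)):
        ref = cds[pos]
        ci, off = pos // 3, pos % 3
        codon = cds[3 * ci: 3 * ci + 3]
        aa = _CODON_TABLE[codon]
        for alt in _BASES:
            if alt == ref:
                continue
            new_codon = codon[:off] + alt + codon[off + 1:]
            is_non.append(_CODON_TABLE[new_codon] != aa)
    is_non = np.asarray(is_non)
    w = np.where(is_non, nonsyn_multiplier, 1.0)
    w = w / w.sum()
    draws = rng.choice(len(is_non), size=n, p=w)
    n_non = int(is_non[draws].sum())
    return n_non, n - n_non


def toy_signature_matrix() -> pd.DataFrame:
    """A small 5-signature basis for tests and demo runs.

    Columns: SFlat (uniform background), SCtoT (ageing-like C>T), SCtoA
    (oxidative/smoking-like C>A), STtoC (T>C dominated) and STpC (C>T/C>G
    restricted to the TpC context). Each column sums to 1. Real analyses
    should pass a reference signature matrix instead.
    """
    names = channel_names()
    cols = {}
    cols["SFlat"] = np.full(96, 1 / 96)
    for label, subs in (
        ("SCtoT", ("C>T",)),
        ("SCtoA", ("C>A",)),
        ("STtoC", ("T>C",)),
    ):
        v = np.array([1.0 if any(s in n for s in subs) else 0.0 for n in names])
        cols[label] = v / v.sum()
    v = np.array(
        [1.0 if n.startswith("T[C>") and "C>A" not in n else 0.0 for n in names]
    )
    cols["STpC"] = v / v.sum()
    return pd.DataFrame(cols, index=names)


def fit_signatures(
    counts96,
    signature_matrix: pd.DataFrame,
    sample: str = "",
    min_mutations: int = MIN_MUTATIONS_FOR_SIGNATURES,
) -> SignatureFit:
    """Non-negative least-squares exposure fit of a 96-channel spectrum.

    ``signature_matrix`` is 96 rows x signatures, each column a probability
    vector. The spectrum is normalised to proportions before fitting and
    exposures renormalised to sum <= 1. Samples with fewer than
    ``min_mutations`` mutations are excluded.
    """
    counts96 = np.asarray(counts96, dtype=float)
    if counts96.shape != (96,):
        raise ValueError("expected a 96-channel count vector")
    n = int(counts96.sum())
    if n < min_mutations:
        return SignatureFit(sample=sample, n_mutations=n, status="excluded")
    s = signature_matrix.to_numpy(dtype=float)
    if not np.allclose(s.sum(axis=0), 1.0, atol=1e-6):
        raise ValueError("signature columns must each sum to 1")
    target = counts96 / n
    coef, resid = nnls(s, target)
    total = coef.sum()
    if total > 1.0:
        coef = coef / total
    return SignatureFit(
        sample=sample,
        exposures={
            name: float(c) for name, c in zip(signature_matrix.columns, coef)
        },
        residual=float(resid),
        n_mutations=n,
    )
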