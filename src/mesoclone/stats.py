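"""Association and survival statistics for cohort-level comparisons.

Thin, explicitly two-sided wrappers over the standard nonparametric tests
(Mann-Whitney U, Fisher's exact, Spearman, Kruskal-Wallis, Shapiro-Wilk
normality gate) plus Kaplan-Meier/log-rank survival with a Mantel-Haenszel
hazard ratio, and the systemic-inflammation indices (neutrophil:lymphocyte
and platelet:lymphocyte ratios).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats as ss
from scipy.stats.contingency import odds_ratio as _conditional_or

__all__ = [
    "SurvivalRecord",
    "ClinicalIndices",
    "mann_whitney",
    "fisher_2x2",
    "km_logrank",
    "spearman",
    "kruskal",
    "shapiro_gate",
    "clinical_indices",
]


@dataclass
class SurvivalRecord:
    patient: str
    time: float
    event: int
    group: str

    def __post_init__(self):
        if self.time <= 0:
            raise ValueError("survival time must be positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


@dataclass
class ClinicalIndices:
    neutrophils: float
    lymphocytes: float
    platelets: float
    nlr: float
    plr: float


def mann_whitney(x, y) -> dict:
    """Two-sided Mann-Whitney U.

    Exact enumeration when n_x + n_y <= 12 with no ties, else the normal
    approximation with tie correction.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (x.size + y.size <= 12 and no_ties) else "asymptotic"
    res = ss.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return {"U": float(res.statistic), "p": float(res.pvalue), "method": method}


def fisher_2x2(a: int, b: int, c: int, d: int) -> dict:
    """Two-sided Fisher's exact test on [[a, b], [c, d]].

    Odds ratio is the sample OR ad/bc (infinite when bc = 0); the CI is the
    conditional exact (non-central hypergeometric) interval.
    """
    table = np.array([[a, b], [c, d]])
    if np.any(table < 0):
        raise ValueError("cell counts must be non-negative")
    if table.sum() == 0:
        raise ValueError("all-zero table")
    orr, p = ss.fisher_exact(table, alternative="two-sided")
    if b * c == 0:
        orr = np.inf if a * d > 0 else np.nan
    ci = _conditional_or(table, kind="conditional").confidence_interval(0.95)
    return {
        "odds_ratio": float(orr), "p": float(p),
        "ci95": (float(ci.low), float(ci.high)),
    }


def _logrank_oev(time, event, group_indicator):
    """O - E and hypergeometric variance for group 1 across event times."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    g = np.asarray(group_indicator, dtype=int)
    o_minus_e, var, observed1 = 0.0, 0.0, 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (g == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (g == 1)).sum()
        if n < 2:
            continue
        e1 = d * n1 / n
        v = d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        o_minus_e += d1 - e1
        var += v
        observed1 += d1
    return o_minus_e, var


def km_logrank(records: pd.DataFrame, hr_method: str = "cox") -> dict:
    """Kaplan-Meier curves, Mantel-Cox log-rank test and hazard ratio.

    ``records`` needs columns time, event, group with exactly two groups; the
    HR is for the second group in sorted order. The default estimator is a
    Cox proportional-hazards fit (better calibrated away from the null);
    ``hr_method="mantel-haenszel"`` uses the score-based exp((O - E)/V) with
    a log-normal CI instead, and is also the automatic fallback when the Cox
    fit fails to converge on degenerate data. The log-rank test itself is
    always Mantel-Cox.
    """
    groups = sorted(records["group"].unique())
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    for grp in groups:
        if (records["group"] == grp).sum() == 0:
            raise ValueError(f"group {grp} is empty")
    if records["event"].sum() == 0:
        raise ValueError("at least one event required")

    curves = {}
    for grp in groups:
        sub = records[records["group"] == grp]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(grp))
        curves[grp] = kmf.survival_function_

    indicator = (records["group"] == groups[1]).astype(int)
    o_minus_e, var = _logrank_oev(records["time"], records["event"], indicator)
    if var <= 0:
        chisq, p = 0.0, 1.0
    else:
        chisq = o_minus_e**2 / var
        p = float(ss.chi2.sf(chisq, df=1))

    if hr_method not in ("cox", "mantel-haenszel"):
        raise ValueError(f"unknown hr_method {hr_method!r}")
    hr = lo = hi = np.nan
    if hr_method == "cox":
        try:
            cph = CoxPHFitter()
            df = records[["time", "event"]].copy()
            df["g"] = indicator.values
            cph.fit(df, duration_col="time", event_col="event")
            hr = float(np.exp(cph.params_["g"]))
            lo, hi = np.exp(cph.confidence_intervals_.loc["g"]).to_numpy()
        except Exception:
            hr_method = "mantel-haenszel"  # degenerate data: fall back
    if hr_method == "mantel-haenszel" or not np.isfinite(hr):
        if var <= 0:
            hr, lo, hi = 1.0, np.nan, np.nan
        else:
            log_hr = o_minus_e / var
            se = 1.0 / np.sqrt(var)
            hr = float(np.exp(log_hr))
            lo, hi = float(np.exp(log_hr - 1.96 * se)), float(np.exp(log_hr + 1.96 * se))
    return {
        "chisq": float(chisq), "p": float(p), "hr": hr,
        "hr_ci95": (float(lo), float(hi)), "km_curves": curves,
    }


def spearman(x, y) -> dict:
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    rho, p = ss.spearmanr(x, y)
    return {"rho": float(rho), "p": float(p)}


def kruskal(*groups) -> dict:
    if any(len(g) < 1 for g in groups) or len(groups) < 2:
        raise ValueError("need at least two non-empty groups")
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    if np.unique(pooled).size == 1:  # all values identical: H = 0 by definition
        return {"H": 0.0, "p": 1.0}
    h, p = ss.kruskal(*groups)
    return {"H": float(h), "p": float(p)}


def shapiro_gate(x, alpha: float = 0.05) -> str:
    """Route a variable as 'normal' or 'skewed' by Shapiro-Wilk.

    Mean comparisons (Welch's t) are appropriate when both variables gate
    'normal'; otherwise medians are compared nonparametrically.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    _, p = ss.shapiro(x)
    return "normal" if p > alpha else "skewed"


def clinical_indices(neutrophils: float, lymphocytes: float, platelets: float) -> ClinicalIndices:
    """Neutrophil:lymphocyte and platelet:lymphocyte ratios."""
    if lymphocytes <= 0:
        raise ValueError("lymphocyte count must be positive")
    return ClinicalIndices(
        neutrophils=neutrophils, lymphocytes=lymphocytes, platelets=platelets,
        nlr=neutrophils / lymphocytes, plr=platelets / lymphocytes,
    )
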