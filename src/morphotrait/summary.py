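"""Demographic and trait comparison statistics between the two samples.

One-way ANOVA recomputable from group summaries (n, mean, sample SD) with
eta-squared effect size, Pearson chi-square on contingency counts with
phi / Cramer's V, and the Shapiro-Wilk normality check -- the layer that
reproduces a demographics table comparing exploration and validation
samples from printed summary numbers alone.

Conventions: group SDs use the n-1 denominator; chi-square carries no
continuity correction; for an r x c table the effect size is
sqrt(chi2 / (N * min(r-1, c-1))), which reduces to phi for 2 x 2 (and for
2 x 3 tables equals Cramer's V).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateDataError

__all__ = [
    "GroupSummary",
    "anova_from_summary",
    "chi_square",
    "normality_w",
    "effect_size_eta",
    "cohort_comparison",
]


@dataclass(frozen=True)
class GroupSummary:
    """Moments of one group: size, mean and sample (n-1) standard deviation."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group size n={self.n} must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def anova_from_summary(groups: list[GroupSummary] | list[tuple]
                       ) -> tuple[float, float, float]:
    """One-way ANOVA (F, p, eta-squared) from per-group (n, mean, sd).

    SSb = sum n_i (mean_i - grand_mean)^2, SSw = sum (n_i - 1) sd_i^2,
    F = (SSb / (k-1)) / (SSw / (N-k)), eta^2 = SSb / (SSb + SSw).
    """
    gs = [g if isinstance(g, GroupSummary) else GroupSummary(*g) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    n = np.array([g.n for g in gs], dtype=float)
    m = np.array([g.mean for g in gs], dtype=float)
    sd = np.array([g.sd for g in gs], dtype=float)
    big_n = n.sum()
    k = len(gs)
    grand = (n * m).sum() / big_n
    ssb = (n * (m - grand) ** 2).sum()
    ssw = ((n - 1) * sd ** 2).sum()
    if ssw == 0:
        raise DegenerateDataError("zero within-group variance")
    f = (ssb / (k - 1)) / (ssw / (big_n - k))
    p = float(stats.f.sf(f, k - 1, big_n - k))
    eta2 = ssb / (ssb + ssw)
    return float(f), p, float(eta2)


def chi_square(table: np.ndarray | list) -> tuple[float, float, float]:
    """Pearson chi-square (no continuity correction) with phi / Cramer's V.

    Returns (chi2, p, effect size) where the effect size is
    sqrt(chi2 / (N * min(r-1, c-1))).
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or (counts < 0).any():
        raise ValueError("table must be a non-negative r x c count matrix")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise DegenerateDataError("zero margin: expected counts undefined")
    chi2, p, _, _ = stats.chi2_contingency(counts, correction=False)
    n = counts.sum()
    r, c = counts.shape
    effect = float(np.sqrt(chi2 / (n * min(r - 1, c - 1))))
    return float(chi2), float(p), effect


def normality_w(x: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value (3 <= n <= 5000)."""
    x = np.asarray(x, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {len(x)}")
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant sample: W undefined")
    w, p = stats.shapiro(x)
    return float(w), float(p)


def effect_size_eta(f: float, df1: int, df2: int) -> float:
    """eta^2 = F df1 / (F df1 + df2), the ANOVA effect size from F."""
    if f < 0:
        raise ValueError("F must be non-negative")
    return float(f * df1 / (f * df1 + df2))


def _group_summary(values: np.ndarray) -> GroupSummary:
    return GroupSummary(n=len(values), mean=float(np.mean(values)),
                        sd=float(np.std(values, ddof=1)))


def cohort_comparison(subjects: pd.DataFrame) -> dict:
    """Demographics-table-shaped comparison of the two samples.

    For each continuous variable (age, AQ total): per-sample n/mean/sd, F,
    p and eta^2; for each categorical variable (sex, education, handedness):
    counts, chi2, p and phi/Cramer's V; plus per-sample Shapiro-Wilk W for
    the AQ totals.
    """
    expl = subjects[subjects["sample"] == "exploration"]
    valid = subjects[subjects["sample"] == "validation"]
    report: dict = {"n_exploration": len(expl), "n_validation": len(valid)}

    for var in ("age", "aq_total"):
        g1 = _group_summary(expl[var].to_numpy(dtype=float))
        g2 = _group_summary(valid[var].to_numpy(dtype=float))
        f, p, eta2 = anova_from_summary([g1, g2])
        report[var] = {
            "exploration": {"n": g1.n, "mean": g1.mean, "sd": g1.sd},
            "validation": {"n": g2.n, "mean": g2.mean, "sd": g2.sd},
            "F": f, "p": p, "eta_squared": eta2,
        }

    levels = {"sex": ["M", "F"], "handedness": ["L", "R"],
              "education": ["low", "middle", "high"]}
    for var, cats in levels.items():
        counts = np.array([
            [int((grp[var] == c).sum()) for grp in (expl, valid)]
            for c in cats]).T  # samples x categories
        chi2, p, eff = chi_square(counts)
        report[var] = {
            "levels": cats,
            "counts_exploration": counts[0].tolist(),
            "counts_validation": counts[1].tolist(),
            "chi2": chi2, "p": p, "phi": eff,
        }

    report["aq_normality"] = {
        label: dict(zip(("W", "p"),
                        normality_w(grp["aq_total"].to_numpy(dtype=float))))
        for label, grp in (("exploration", expl), ("validation", valid))
    }
    return report
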