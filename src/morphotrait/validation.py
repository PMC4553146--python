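"""Validation-stage partial-correlation tests of exploration-derived ROIs.

The replication criterion: each candidate ROI's mean signal is partially
correlated with the AQ total in the independent validation sample
(controlling age, sex, handedness, education, ICV), at a Bonferroni-
adjusted level family_alpha / K for K ROIs.  By default a hit must also
match the exploration-stage sign of association to count as replication;
the overall verdict is "replicated" iff at least one ROI replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateDataError, SampleLeakageError
from .screening import residualize

__all__ = [
    "ValidationResult",
    "partial_correlation",
    "bonferroni_alpha",
    "validate_rois",
]


@dataclass(frozen=True)
class ValidationResult:
    roi_id: str
    partial_r: float
    p_value: float
    alpha_adjusted: float
    replicated: bool
    n_validation: int

    def to_dict(self) -> dict:
        return {
            "roi_id": self.roi_id,
            "r": self.partial_r,
            "p_value": self.p_value,
            "alpha_adjusted": self.alpha_adjusted,
            "replicated": self.replicated,
            "n_validation": self.n_validation,
        }


def partial_correlation(x: np.ndarray, y: np.ndarray,
                        covariates: pd.DataFrame | np.ndarray | None = None,
                        ) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given covariates.

    Both vectors are residualized on the covariate design (plus intercept)
    and correlated.  The two-sided p-value comes from
    t = r * sqrt(df / (1 - r^2)) with df = n - 2 - c, where c is the number
    of covariate columns (intercept excluded).  With no covariates this is
    the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if covariates is None:
        c = 0
    elif isinstance(covariates, pd.DataFrame):
        c = covariates.shape[1]
    else:
        arr = np.asarray(covariates)
        c = 1 if arr.ndim == 1 else arr.shape[1]
    df = n - 2 - c
    if df < 1:
        raise ValueError(f"need n > covariates + 2 (n={n}, c={c})")
    rx = residualize(x, covariates)
    ry = residualize(y, covariates)
    sx, sy = np.sqrt((rx ** 2).sum()), np.sqrt((ry ** 2).sum())
    # residuals at round-off scale mean the design explains the vector exactly
    tol_x = np.linalg.norm(x - x.mean()) * 1e-10
    tol_y = np.linalg.norm(y - y.mean()) * 1e-10
    if sx <= tol_x or sy <= tol_y or sx == 0 or sy == 0:
        raise DegenerateDataError(
            "zero-variance residual: partial correlation undefined")
    r = float((rx @ ry) / (sx * sy))
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r ** 2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p


def bonferroni_alpha(family_alpha: float, m: int) -> float:
    """Per-test significance level family_alpha / m."""
    if not 0.0 < family_alpha < 1.0:
        raise ValueError(f"family_alpha={family_alpha} not in (0, 1)")
    if m < 1:
        raise ValueError(f"number of tests m={m} must be >= 1")
    return family_alpha / m


def validate_rois(
    roi_means: np.ndarray,
    aq: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None,
    exploration_signs: list[str],
    family_alpha: float = 0.05,
    sign_strict: bool = True,
    roi_ids: list[str] | None = None,
    sample_labels: np.ndarray | None = None,
) -> tuple[list[ValidationResult], dict]:
    """Bonferroni-controlled replication test of each ROI in the validation sample.

    ``roi_means`` is subjects x ROIs (validation subjects only; passing
    ``sample_labels`` enforces this).  ``exploration_signs`` carries the
    sign ('positive'/'negative') each ROI showed at screening; with
    ``sign_strict`` a significant hit of opposite sign does not count as
    replication.  Returns per-ROI results and an overall verdict dict with
    the maximum |r| observed.
    """
    roi_means = np.asarray(roi_means, dtype=float)
    if roi_means.ndim == 1:
        roi_means = roi_means[:, None]
    k = roi_means.shape[1]
    if k == 0:
        raise ValueError("ROI set is empty")
    if len(exploration_signs) != k:
        raise ValueError("one exploration sign required per ROI")
    if sample_labels is not None:
        leaked = np.asarray(sample_labels) == "exploration"
        if leaked.any():
            raise SampleLeakageError(
                f"{int(leaked.sum())} exploration subject(s) present in the "
                "validation stage")
    if roi_ids is None:
        roi_ids = [f"roi-{j + 1:02d}" for j in range(k)]

    alpha_adj = bonferroni_alpha(family_alpha, k)
    n = roi_means.shape[0]
    results = []
    for j in range(k):
        r, p = partial_correlation(roi_means[:, j], aq, covariates)
        sign_ok = (not sign_strict) or (
            (r > 0) == (exploration_signs[j] == "positive"))
        results.append(ValidationResult(
            roi_id=roi_ids[j], partial_r=r, p_value=p,
            alpha_adjusted=alpha_adj,
            replicated=bool(p < alpha_adj and sign_ok),
            n_validation=n))
    any_rep = any(res.replicated for res in results)
    verdict = {
        "replicated": any_rep,
        "conclusion": ("replicated association" if any_rep
                       else "no validated association"),
        "n_rois": k,
        "alpha_adjusted": alpha_adj,
        "max_abs_r": max(abs(res.partial_r) for res in results),
    }
    return results, verdict
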