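"""Exploration-stage mass-univariate screening and cluster extraction.

The screening model regresses each in-mask voxel on the AQ total plus the
nuisance design, keeps voxels whose (permutation or parametric) p-value
falls below a lenient uncorrected threshold, and extracts sign-separated
connected components above a minimum extent (100 voxels for gray-matter
maps, 50 for FA skeletons) as candidate ROIs for independent validation.

Permutation inference follows the Freedman-Lane scheme: residuals from the
nuisance-only model are permuted, added back to the nuisance fit, and the
full model is refit -- the standard approach of permutation GLM tools for
neuroimaging, with close-to-exact type-I control when nuisance effects are
present.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import linalg, ndimage, stats

from .cohort import VoxelImageSet
from .covariates import as_design_array
from .exceptions import DesignMatrixError, DimensionError

logger = logging.getLogger(__name__)

__all__ = [
    "GLMResult",
    "ClusterROI",
    "residualize",
    "glm_tmap",
    "permutation_pvalues",
    "parametric_pvalues",
    "extract_clusters",
    "roi_means",
]


@dataclass(frozen=True)
class GLMResult:
    """Voxelwise slope/t maps for the AQ term, defined within ``mask``."""

    beta_map: np.ndarray
    t_map: np.ndarray
    mask: np.ndarray
    df: int
    p_map: np.ndarray | None = None
    n_permutations: int = 0

    def __post_init__(self) -> None:
        if self.p_map is not None:
            p = self.p_map[self.mask]
            if ((p < 0) | (p > 1)).any():
                raise ValueError("p-values outside [0, 1]")


@dataclass(frozen=True)
class ClusterROI:
    """A sign-labeled connected suprathreshold voxel set."""

    roi_id: str
    sign: str                      # positive | negative
    voxel_list: np.ndarray         # (k, 3) 0-based indices
    size_voxels: int
    size_mm3: float
    peak_voxel: tuple[int, int, int]

    def to_dict(self) -> dict:
        return {
            "roi_id": self.roi_id,
            "sign": self.sign,
            "size_voxels": int(self.size_voxels),
            "size_mm3": float(self.size_mm3),
            "peak_voxel": [int(c) for c in self.peak_voxel],
            "voxels": [[int(c) for c in v] for v in self.voxel_list],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClusterROI":
        return cls(roi_id=d["roi_id"], sign=d["sign"],
                   voxel_list=np.asarray(d["voxels"], dtype=int),
                   size_voxels=int(d["size_voxels"]),
                   size_mm3=float(d["size_mm3"]),
                   peak_voxel=tuple(int(c) for c in d["peak_voxel"]))


def _check_full_rank(design: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # pivoted QR exposes which trailing columns are linear combinations
        _, r, piv = linalg.qr(design, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(design.shape) * np.finfo(float).eps
        bad = [names[piv[i]] for i in range(design.shape[1]) if diag[i] <= tol]
        raise DesignMatrixError(
            f"design is rank deficient (rank {rank} < {design.shape[1]}); "
            f"collinear column(s): {', '.join(bad) or 'unidentified'}")


def residualize(values: np.ndarray,
                covariates: pd.DataFrame | np.ndarray | None,
                add_intercept: bool = True) -> np.ndarray:
    """Least-squares residuals of ``values`` on the covariate design.

    ``values`` may be a vector or a subjects x variables matrix; an
    intercept is appended unless ``add_intercept=False``.  The result is
    orthogonal to every design column.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    design, names = as_design_array(covariates, n, add_intercept=add_intercept)
    if design.shape[1] == 0:
        return values.copy()
    _check_full_rank(design, names)
    coef, *_ = np.linalg.lstsq(design, values, rcond=None)
    return values - design @ coef


def _design_for_glm(aq: np.ndarray,
                    covariates: pd.DataFrame | np.ndarray | None
                    ) -> tuple[np.ndarray, list[str]]:
    aq = np.asarray(aq, dtype=float)
    nuis, names = as_design_array(covariates, len(aq), add_intercept=True)
    design = np.column_stack([aq, nuis])
    _check_full_rank(design, ["aq", *names])
    return design, ["aq", *names]


def _tmap_from_design(y: np.ndarray, design: np.ndarray,
                      pinv: np.ndarray | None = None,
                      ) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorized OLS t-statistics for the first design column.

    ``y`` is (n_subjects, n_voxels).  Returns (beta, t, df); voxels whose
    residual variance vanishes (constant under the model) get t = 0.
    """
    n, p = design.shape
    df = n - p
    if df < 1:
        raise DimensionError(f"need at least {p + 1} subjects, got {n}")
    if pinv is None:
        pinv = np.linalg.pinv(design)
    coef = pinv @ y                          # (p, V)
    resid = y - design @ coef
    sigma2 = (resid ** 2).sum(axis=0) / df
    # voxels constant under the model leave round-off residuals only
    degenerate = sigma2 <= (y ** 2).mean(axis=0) * (n * np.finfo(float).eps) ** 2
    c00 = np.linalg.inv(design.T @ design)[0, 0]
    se = np.sqrt(sigma2 * c00)
    beta = coef[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(~degenerate & (se > 0),
                     beta / np.where(se > 0, se, 1.0), 0.0)
    n_degenerate = int(degenerate.sum())
    if n_degenerate:
        logger.warning("%d voxel(s) constant under the model; t set to 0",
                       n_degenerate)
    return beta, t, df


def glm_tmap(images: VoxelImageSet, aq: np.ndarray,
             covariates: pd.DataFrame | np.ndarray | None) -> GLMResult:
    """Voxelwise t-map for the AQ slope, adjusting for the nuisance design."""
    design, _ = _design_for_glm(aq, covariates)
    y = images.data[:, images.mask]
    beta, t, df = _tmap_from_design(y, design)
    beta_map = np.zeros(images.mask.shape)
    t_map = np.zeros(images.mask.shape)
    beta_map[images.mask] = beta
    t_map[images.mask] = t
    return GLMResult(beta_map=beta_map, t_map=t_map, mask=images.mask, df=df)


def parametric_pvalues(glm: GLMResult) -> GLMResult:
    """Two-sided Student-t p-values from the observed t-map."""
    p_map = np.ones(glm.mask.shape)
    p_map[glm.mask] = 2.0 * stats.t.sf(np.abs(glm.t_map[glm.mask]), glm.df)
    return replace(glm, p_map=p_map, n_permutations=0)


def permutation_pvalues(glm: GLMResult, images: VoxelImageSet,
                        aq: np.ndarray,
                        covariates: pd.DataFrame | np.ndarray | None,
                        n_perm: int = 1000, seed: int = 0) -> GLMResult:
    """Freedman-Lane permutation p-values for the voxelwise AQ t-map.

    p(v) = (1 + #{perm : |t_perm(v)| >= |t_obs(v)|}) / (1 + n_perm); the
    +1/+1 smoothing keeps p-values strictly positive.  Deterministic under
    ``seed``.
    """
    if n_perm < 100:
        raise ValueError(f"n_perm={n_perm} < 100 gives unstable tail estimates")
    design, _ = _design_for_glm(aq, covariates)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    y = images.data[:, images.mask]
    n = y.shape[0]

    nuis = design[:, 1:]                     # nuisance-only model (with intercept)
    coef, *_ = np.linalg.lstsq(nuis, y, rcond=None)
    fitted = nuis @ coef
    resid = y - fitted

    t_obs = np.abs(glm.t_map[images.mask])
    exceed = np.zeros(y.shape[1])
    pinv = np.linalg.pinv(design)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        y_star = fitted + resid[perm]
        _, t_star, _ = _tmap_from_design(y_star, design, pinv=pinv)
        exceed += np.abs(t_star) >= t_obs
    p = (1.0 + exceed) / (1.0 + n_perm)
    p_map = np.ones(images.mask.shape)
    p_map[images.mask] = p
    return replace(glm, p_map=p_map, n_permutations=n_perm)


_STRUCTURES = {
    26: np.ones((3, 3, 3), dtype=bool),
    6: ndimage.generate_binary_structure(3, 1),
}


def extract_clusters(glm: GLMResult, p_threshold: float = 0.05,
                     k_min: int = 100, voxel_size_mm: float = 2.0,
                     connectivity: int = 26) -> list[ClusterROI]:
    """Sign-separated connected components of suprathreshold voxels.

    Voxels with p below ``p_threshold`` are partitioned by the sign of the
    AQ slope; components (26-connectivity by default) of at least ``k_min``
    voxels become ROIs, sorted by size descending.  Positive and negative
    clusters are never merged, even when adjacent.  An empty list is a
    valid outcome.
    """
    if glm.p_map is None:
        raise ValueError("p_map absent: run permutation_pvalues or "
                         "parametric_pvalues first")
    try:
        structure = _STRUCTURES[connectivity]
    except KeyError:
        raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")
    supra = (glm.p_map < p_threshold) & glm.mask
    voxel_volume = float(voxel_size_mm) ** 3

    rois: list[ClusterROI] = []
    for sign, sign_mask in [("positive", glm.beta_map > 0),
                            ("negative", glm.beta_map < 0)]:
        labeled, n_comp = ndimage.label(supra & sign_mask, structure=structure)
        for comp in range(1, n_comp + 1):
            vox = np.argwhere(labeled == comp)
            if len(vox) < k_min:
                continue
            tvals = np.abs(glm.t_map[tuple(vox.T)])
            peak_candidates = vox[tvals == tvals.max()]
            peak = peak_candidates[np.lexsort(peak_candidates.T[::-1])][0]
            rois.append(ClusterROI(
                roi_id="",  # assigned after global sort
                sign=sign,
                voxel_list=vox,
                size_voxels=len(vox),
                size_mm3=len(vox) * voxel_volume,
                peak_voxel=tuple(int(c) for c in peak)))
    rois.sort(key=lambda r: (-r.size_voxels, r.sign, r.peak_voxel))
    return [replace(r, roi_id=f"roi-{i + 1:02d}") for i, r in enumerate(rois)]


def roi_means(images: VoxelImageSet, rois: list[ClusterROI]) -> np.ndarray:
    """Per-subject mean image value over each ROI: (n_subjects, n_rois)."""
    out = np.empty((images.n_subjects, len(rois)))
    for j, roi in enumerate(rois):
        ix = tuple(roi.voxel_list.T)
        if not images.mask[ix].all():
            raise DimensionError(f"ROI {roi.roi_id} has voxels outside the mask")
        out[:, j] = images.data[:, ix[0], ix[1], ix[2]].mean(axis=1)
    return out
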