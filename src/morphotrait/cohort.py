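"""Synthetic cohort, regional morphometry and voxel-map generation.

The generator emulates the two stratified samples of a population study of
autistic traits in young adults: an exploration sample of 204 and a
validation sample of 304 subjects, aged 20-26, roughly 51 % male, with a
12/43/45 % low/middle/high education split, about 10 % left-handed, and
AQ-28 trait totals distributed approximately normally with per-sample means
near 55.6 and 57.05 (SDs 8.96 and 8.70).  Regional morphometry values are
produced by a linear covariate model plus shared latent factors (which
induce the dense positive structural covariance that coupling analyses
rest on), and voxel maps are spatially smoothed Gaussian noise fields.
Trait effects -- regional slopes, voxel clusters, coupling modulations --
can be injected on top of this null construction for power and recovery
studies; the default :class:`EffectSpec` is null.

All generation is deterministic given a seed: each generator derives an
independent stream from ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .atlas import labels_for_measure
from .exceptions import ConfigurationError, DimensionError

__all__ = [
    "CohortConfig",
    "EffectSpec",
    "VoxelClusterEffect",
    "RegionalMatrix",
    "RegionalModelParams",
    "GridParams",
    "VoxelImageSet",
    "generate_subjects",
    "generate_regional_measures",
    "generate_voxel_maps",
    "inject_coupling_modulation",
    "sphere_voxels",
]


# --------------------------------------------------------------------------
# configuration / effect specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of the two stratified samples.

    ``aq_mean``/``aq_sd`` are per-sample pairs (exploration, validation).
    AQ totals are drawn from a normal truncated to ``aq_range``; the default
    interval [28, 112] is the attainable range of 28 items scored 1-4.
    ICV defaults (1.5e6 +/- 1.5e5 mm^3) are typical adult values.
    """

    n_exploration: int = 204
    n_validation: int = 304
    age_range: tuple[float, float] = (20.0, 26.0)
    male_prop: float = 0.51
    education_props: tuple[float, float, float] = (0.12, 0.43, 0.45)
    left_hand_prop: float = 0.10
    aq_mean: tuple[float, float] = (55.63, 57.05)
    aq_sd: tuple[float, float] = (8.96, 8.70)
    aq_range: tuple[float, float] = (28.0, 112.0)
    icv_mean: float = 1.5e6
    icv_sd: float = 1.5e5
    seed: int = 0

    def validate(self) -> None:
        if self.n_exploration <= 0 or self.n_validation <= 0:
            raise ConfigurationError("sample sizes must be positive")
        for name, frac in [("male_prop", self.male_prop),
                           ("left_hand_prop", self.left_hand_prop)]:
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(f"{name}={frac} not in [0, 1]")
        props = np.asarray(self.education_props, dtype=float)
        if props.shape != (3,) or (props < 0).any() or (props > 1).any():
            raise ConfigurationError("education_props must be 3 fractions in [0, 1]")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"education_props sum to {props.sum():.12g}, expected 1")
        if not self.age_range[0] < self.age_range[1]:
            raise ConfigurationError("age_range must be an increasing interval")
        if any(sd <= 0 for sd in self.aq_sd) or self.icv_sd <= 0:
            raise ConfigurationError("scale parameters must be positive")


@dataclass(frozen=True)
class VoxelClusterEffect:
    """A spherical voxel region whose signal scales with centered AQ."""

    center: tuple[int, int, int]
    radius: float          # voxels
    slope: float           # image units per AQ point


@dataclass(frozen=True)
class EffectSpec:
    """Trait effects injected into the synthetic data; null by default.

    ``null=True`` asserts that every effect collection is empty, mirroring
    the no-association scenario the pipeline's error control is judged on.
    """

    regional_slopes: dict[str, float] = field(default_factory=dict)
    voxel_clusters: tuple[VoxelClusterEffect, ...] = ()
    coupling_modulations: tuple[tuple[str, str, float], ...] = ()
    null: bool = True

    def __post_init__(self) -> None:
        has_effects = bool(self.regional_slopes or self.voxel_clusters
                           or self.coupling_modulations)
        if self.null and has_effects:
            raise ConfigurationError("null EffectSpec carries non-empty effects")
        if not self.null and not has_effects:
            raise ConfigurationError("non-null EffectSpec carries no effects")


# --------------------------------------------------------------------------
# subject tables
# --------------------------------------------------------------------------

def generate_subjects(config: CohortConfig) -> pd.DataFrame:
    """Draw the two stratified samples as one subject table.

    Stratification is implemented by drawing sex, education and handedness
    for each sample independently from identical category probabilities, so
    realized proportions agree between samples up to binomial noise.  Ages
    are uniform on ``age_range``; AQ totals are truncated-normal with the
    per-sample moments; ICV is normal truncated at zero.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    frames = []
    sizes = {"exploration": config.n_exploration,
             "validation": config.n_validation}
    for which, (label, n) in enumerate(sizes.items()):
        age = rng.uniform(*config.age_range, size=n)
        sex = np.where(rng.random(n) < config.male_prop, "M", "F")
        hand = np.where(rng.random(n) < config.left_hand_prop, "L", "R")
        edu = rng.choice(["low", "middle", "high"], size=n,
                         p=np.asarray(config.education_props, dtype=float)
                         / np.sum(config.education_props))
        mu, sd = config.aq_mean[which], config.aq_sd[which]
        lo, hi = config.aq_range
        a, b = (lo - mu) / sd, (hi - mu) / sd
        aq = stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=n, random_state=rng)
        icv = np.abs(rng.normal(config.icv_mean, config.icv_sd, size=n))
        frames.append(pd.DataFrame({
            "subject_id": [f"{label[:3]}-{i:04d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "handedness": hand,
            "education": edu,
            "icv": icv,
            "aq_total": aq,
            "sample": label,
        }))
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# regional morphometry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionalMatrix:
    """Subjects x regions morphometry values for one measure."""

    values: np.ndarray            # (n_subjects, n_regions)
    region_labels: tuple[str, ...]
    measure: str                  # thickness_mm | volume_mm3
    subject_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.shape != (len(self.subject_ids), len(self.region_labels)):
            raise DimensionError(
                f"values shape {v.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.region_labels)} labels")
        if not np.isfinite(v).all():
            raise DimensionError("regional values contain non-finite entries")

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.region_labels))
        df.insert(0, "subject_id", list(self.subject_ids))
        return df

    def column(self, label: str) -> np.ndarray:
        try:
            j = self.region_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown region label {label!r}") from None
        return self.values[:, j]


@dataclass(frozen=True)
class RegionalModelParams:
    """Linear model generating regional values from covariates and factors.

    value(s, r) = intercept_r + b_age*age + b_sex*[sex=M] + b_icv*icv
                  + sum_k loadings[r, k] * f[s, k] + slope_r * aq + noise.

    Latent factors ``f`` are iid standard normal per subject and shared
    across regions, so two regions with loadings ``l_r, l_s`` and noise SD
    ``sigma`` have raw correlation l_r.l_s / sqrt((|l_r|^2 + sigma^2)
    (|l_s|^2 + sigma^2)) -- a dense positive coupling structure.  Defaults
    are in measure units (mm for thickness): a 2.5 mm grand-mean cortex
    thinning slightly with age, a small sex offset, negligible direct ICV
    dependence, four factors and 0.12 mm residual noise give within-sample
    coupling values in the 0.3-0.5 band typical of structural covariance.
    """

    intercept: float | np.ndarray = 2.5
    beta_age: float = -0.005
    beta_sex: float = 0.02
    beta_icv: float = 2e-8
    n_factors: int = 4
    loadings: np.ndarray | None = None   # (n_regions, n_factors); drawn if None
    loading_range: tuple[float, float] = (0.03, 0.09)
    noise_sd: float = 0.12

    @classmethod
    def for_measure(cls, measure: str) -> "RegionalModelParams":
        if measure == "thickness_mm":
            return cls()
        if measure == "volume_mm3":
            # region-scale gray matter volumes ~ a few thousand mm^3
            return cls(intercept=4500.0, beta_age=-15.0, beta_sex=120.0,
                       beta_icv=1.5e-3, loading_range=(80.0, 220.0),
                       noise_sd=320.0)
        raise ValueError(f"unknown measure {measure!r}")


def generate_regional_measures(
    subjects: pd.DataFrame,
    effects: EffectSpec,
    model_params: RegionalModelParams | None = None,
    measure: str = "thickness_mm",
    region_labels: list[str] | None = None,
    seed: int = 0,
) -> RegionalMatrix:
    """Generate a subjects x regions matrix under the latent-factor model."""
    if region_labels is None:
        region_labels = labels_for_measure(measure)
    params = model_params or RegionalModelParams.for_measure(measure)
    n, r = len(subjects), len(region_labels)
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    if params.loadings is not None:
        loadings = np.asarray(params.loadings, dtype=float)
        if loadings.shape != (r, params.n_factors):
            raise DimensionError(
                f"loadings shape {loadings.shape} != ({r}, {params.n_factors})")
    else:
        loadings = rng.uniform(*params.loading_range, size=(r, params.n_factors))

    unknown = set(effects.regional_slopes) - set(region_labels)
    if unknown:
        raise DimensionError(f"regional_slopes reference unknown label(s): "
                             f"{sorted(unknown)}")

    age = subjects["age"].to_numpy(dtype=float)
    sex_m = (subjects["sex"] == "M").to_numpy(dtype=float)
    icv = subjects["icv"].to_numpy(dtype=float)
    aq = subjects["aq_total"].to_numpy(dtype=float)

    intercept = np.broadcast_to(np.asarray(params.intercept, dtype=float), (r,))
    covar_part = (params.beta_age * age + params.beta_sex * sex_m
                  + params.beta_icv * icv)
    factors = rng.standard_normal((n, params.n_factors))
    noise = params.noise_sd * rng.standard_normal((n, r))

    slopes = np.array([effects.regional_slopes.get(lab, 0.0)
                       for lab in region_labels])
    values = (intercept[None, :] + covar_part[:, None]
              + factors @ loadings.T + aq[:, None] * slopes[None, :] + noise)
    for lab_i, lab_j, strength in effects.coupling_modulations:
        _apply_coupling_modulation(values, list(region_labels), aq,
                                   [(lab_i, lab_j)], strength)
    return RegionalMatrix(values=values,
                          region_labels=tuple(region_labels),
                          measure=measure,
                          subject_ids=tuple(subjects["subject_id"]))


def _apply_coupling_modulation(values: np.ndarray, labels: list[str],
                               aq: np.ndarray,
                               pairs: list[tuple[str, str]],
                               strength: float) -> np.ndarray:
    """Add a shared trait loading to both members of each pair (in place)."""
    aq_z = (aq - aq.mean()) / aq.std(ddof=0)
    for lab_i, lab_j in pairs:
        for lab in (lab_i, lab_j):
            if lab not in labels:
                raise DimensionError(f"unknown region label {lab!r}")
        i, j = labels.index(lab_i), labels.index(lab_j)
        for col in (i, j):
            sd = values[:, col].std(ddof=0)
            values[:, col] = values[:, col] + strength * sd * aq_z
    return values


def inject_coupling_modulation(
    regional: RegionalMatrix,
    subjects: pd.DataFrame,
    pairs: list[tuple[str, str]],
    strength: float,
) -> RegionalMatrix:
    """Make a region pair's coupling depend on the trait score.

    Both members of each (i, j) pair gain a shared component
    ``strength * sd_region * aq_z(s)``: the pair's correlation then carries
    trait-driven variance that conditioning on AQ removes, which is
    precisely the alternative the |dZ| > z_crit nested-covariate criterion
    can detect.  (A pure trait-by-region interaction, by contrast, is
    invisible to linear partialling and leaves dZ at its null level.)
    ``strength`` is in units of region SD per AQ standard deviation;
    strength 0 returns the input unchanged.
    """
    values = np.array(regional.values, dtype=float, copy=True)
    aq = subjects["aq_total"].to_numpy(dtype=float)
    _apply_coupling_modulation(values, list(regional.region_labels), aq,
                               pairs, strength)
    return replace(regional, values=values)


# --------------------------------------------------------------------------
# voxel maps
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GridParams:
    """Voxel-grid geometry and noise model for synthetic images.

    The default 32^3 grid at 2 mm isotropic makes cluster sizes reportable
    both in voxels and mm^3 (x8).  ``smooth_sigma_mm`` mirrors the 4 mm
    Gaussian kernel applied to modulated gray-matter images; noise fields
    are renormalized after smoothing so the per-voxel SD stays ``noise_sd``.
    """

    shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: float = 2.0
    smooth_sigma_mm: float = 4.0
    noise_sd: float = 1.0
    baseline: float = 0.0

    def validate(self) -> None:
        if any(s < 8 for s in self.shape):
            raise ConfigurationError("grid dimensions must be >= 8 per axis")
        if self.voxel_size_mm <= 0:
            raise ConfigurationError("voxel size must be positive")
        if self.smooth_sigma_mm < 0:
            raise ConfigurationError("smoothing sigma must be >= 0")


@dataclass(frozen=True)
class VoxelImageSet:
    """Per-subject 3-D scalar maps with a shared binary mask."""

    data: np.ndarray        # (n_subjects, X, Y, Z)
    mask: np.ndarray        # bool (X, Y, Z)
    voxel_size_mm: float
    modality: str = "gm_density"
    subject_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.data.ndim != 4 or self.data.shape[1:] != self.mask.shape:
            raise DimensionError(
                f"data shape {self.data.shape} incompatible with mask "
                f"{self.mask.shape}")
        if not self.mask.any():
            raise DimensionError("mask is empty")
        if not np.isfinite(self.data[:, self.mask]).all():
            raise DimensionError("non-finite values inside mask")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.voxel_size_mm) ** 3


def sphere_voxels(center: tuple[int, int, int], radius: float,
                  shape: tuple[int, int, int]) -> np.ndarray:
    """0-based lattice coordinates within Euclidean ``radius`` of ``center``."""
    grids = np.indices(shape)
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return np.argwhere(d2 <= radius ** 2)


def _interior_mask(shape: tuple[int, int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    mask[1:-1, 1:-1, 1:-1] = True
    return mask


def generate_voxel_maps(
    subjects: pd.DataFrame,
    effects: EffectSpec,
    grid_params: GridParams | None = None,
    modality: str = "gm_density",
    seed: int = 0,
) -> VoxelImageSet:
    """Smooth Gaussian noise fields per subject plus injected cluster effects.

    Each :class:`VoxelClusterEffect` adds ``slope * (aq_s - mean aq)`` inside
    a sphere around its center.  The mask covers the grid interior (one-voxel
    rim excluded); a sphere reaching outside the mask is an error.
    """
    gp = grid_params or GridParams()
    gp.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = len(subjects)
    mask = _interior_mask(gp.shape)

    sigma_vox = gp.smooth_sigma_mm / gp.voxel_size_mm
    data = rng.standard_normal((n,) + gp.shape)
    if sigma_vox > 0:
        # normalize by the kernel's l2 norm so smoothed white noise keeps unit SD
        impulse = np.zeros(gp.shape)
        impulse[tuple(s // 2 for s in gp.shape)] = 1.0
        kernel_l2 = np.sqrt((ndimage.gaussian_filter(impulse, sigma_vox) ** 2).sum())
        data = ndimage.gaussian_filter(data, (0.0,) + (sigma_vox,) * 3)
        data /= kernel_l2
    data = gp.baseline + gp.noise_sd * data

    aq = subjects["aq_total"].to_numpy(dtype=float)
    aq_c = aq - aq.mean()
    for eff in effects.voxel_clusters:
        vox = sphere_voxels(eff.center, eff.radius, gp.shape)
        inside = mask[tuple(vox.T)]
        if not inside.all():
            raise DimensionError(
                f"cluster sphere at {eff.center} (r={eff.radius}) leaves the mask")
        ix = tuple(vox.T)
        data[:, ix[0], ix[1], ix[2]] += np.outer(aq_c, np.ones(len(vox))) * eff.slope

    return VoxelImageSet(data=data, mask=mask, voxel_size_mm=gp.voxel_size_mm,
                         modality=modality,
                         subject_ids=tuple(subjects["subject_id"]))
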