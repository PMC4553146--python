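"""Standard-format I/O: subject CSV, regional CSV, NIfTI image sets, configs.

All tables round-trip through CSV, images through one NIfTI per subject
plus a mask NIfTI (affine = diag(voxel size)), configurations through
YAML/JSON.  Schema violations raise :class:`SchemaError` naming the
offending column or field.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .atlas import labels_for_measure
from .cohort import (CohortConfig, EffectSpec, RegionalMatrix,
                     VoxelClusterEffect, VoxelImageSet)
from .covariates import SUBJECT_COLUMNS, check_subject_table
from .exceptions import SchemaError

__all__ = [
    "write_subjects", "read_subjects",
    "write_regional", "read_regional",
    "write_images", "read_images",
    "write_json", "read_json",
    "load_cohort_config", "load_effect_spec", "read_yaml", "write_yaml",
]


# ---------------------------------------------------------------- tables

def write_subjects(subjects: pd.DataFrame, path: str | Path) -> None:
    check_subject_table(subjects)
    subjects.loc[:, SUBJECT_COLUMNS].to_csv(path, index=False)


def read_subjects(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    check_subject_table(df)
    return df


def write_regional(regional: RegionalMatrix, path: str | Path) -> None:
    regional.to_dataframe().to_csv(path, index=False)


def read_regional(path: str | Path, measure: str | None = None
                  ) -> RegionalMatrix:
    """Read a subjects x regions CSV; measure inferred from label count."""
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise SchemaError("regional matrix CSV missing column: subject_id")
    labels = [c for c in df.columns if c != "subject_id"]
    if measure is None:
        measure = {68: "thickness_mm", 84: "volume_mm3"}.get(len(labels))
        if measure is None:
            raise SchemaError(
                f"cannot infer measure from {len(labels)} region columns; "
                "pass measure explicitly")
    return RegionalMatrix(values=df[labels].to_numpy(dtype=float),
                          region_labels=tuple(labels), measure=measure,
                          subject_ids=tuple(df["subject_id"].astype(str)))


# ---------------------------------------------------------------- images

def _affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
    return aff


def write_images(images: VoxelImageSet, out_dir: str | Path) -> None:
    """One NIfTI per subject plus mask.nii.gz and a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = _affine(images.voxel_size_mm)
    for sid, vol in zip(images.subject_ids, images.data):
        nib.save(nib.Nifti1Image(vol.astype(np.float32), aff),
                 out_dir / f"{sid}.nii.gz")
    nib.save(nib.Nifti1Image(images.mask.astype(np.uint8), aff),
             out_dir / "mask.nii.gz")
    manifest = {"subject_ids": list(images.subject_ids),
                "voxel_size_mm": images.voxel_size_mm,
                "modality": images.modality}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_images(in_dir: str | Path) -> VoxelImageSet:
    in_dir = Path(in_dir)
    manifest_path = in_dir / "manifest.json"
    if not manifest_path.exists():
        raise SchemaError(f"image directory {in_dir} missing manifest.json")
    manifest = json.loads(manifest_path.read_text())
    for fieldname in ("subject_ids", "voxel_size_mm", "modality"):
        if fieldname not in manifest:
            raise SchemaError(f"image manifest missing field: {fieldname}")
    mask_img = nib.load(in_dir / "mask.nii.gz")
    mask = np.asarray(mask_img.dataobj).astype(bool)
    voxel_size = float(mask_img.header.get_zooms()[0])
    data = np.stack([
        np.asarray(nib.load(in_dir / f"{sid}.nii.gz").dataobj, dtype=float)
        for sid in manifest["subject_ids"]])
    return VoxelImageSet(data=data, mask=mask, voxel_size_mm=voxel_size,
                         modality=manifest["modality"],
                         subject_ids=tuple(manifest["subject_ids"]))


# ---------------------------------------------------------------- json / yaml

class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def load_cohort_config(spec: dict | str | Path) -> CohortConfig:
    """Build a CohortConfig from a dict or a YAML/JSON file."""
    if not isinstance(spec, dict):
        spec = read_yaml(spec)
    known = set(CohortConfig.__dataclass_fields__)
    unknown = set(spec) - known
    if unknown:
        raise SchemaError(f"unknown cohort config field(s): {sorted(unknown)}")
    for tup_field in ("age_range", "education_props", "aq_mean", "aq_sd",
                      "aq_range"):
        if tup_field in spec and isinstance(spec[tup_field], list):
            spec[tup_field] = tuple(spec[tup_field])
    cfg = CohortConfig(**spec)
    cfg.validate()
    return cfg


def load_effect_spec(spec: dict | str | Path | None) -> EffectSpec:
    """Build an EffectSpec from a dict or a YAML/JSON file; None -> null."""
    if spec is None:
        return EffectSpec()
    if not isinstance(spec, dict):
        spec = read_yaml(spec)
    clusters = tuple(
        VoxelClusterEffect(center=tuple(c["center"]), radius=float(c["radius"]),
                           slope=float(c["slope"]))
        for c in spec.get("voxel_clusters", []))
    modulations = tuple(
        (str(m[0]), str(m[1]), float(m[2]))
        for m in spec.get("coupling_modulations", []))
    slopes = {str(k): float(v)
              for k, v in (spec.get("regional_slopes") or {}).items()}
    null = bool(spec.get("null",
                         not (slopes or clusters or modulations)))
    return EffectSpec(regional_slopes=slopes, voxel_clusters=clusters,
                      coupling_modulations=modulations, null=null)


def cohort_config_to_dict(config: CohortConfig) -> dict:
    d = asdict(config)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def regional_from_labels(values: np.ndarray, measure: str,
                         subject_ids: list[str]) -> RegionalMatrix:
    return RegionalMatrix(values=values,
                          region_labels=tuple(labels_for_measure(measure)),
                          measure=measure, subject_ids=tuple(subject_ids))
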