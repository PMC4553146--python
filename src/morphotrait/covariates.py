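"""Nuisance covariate design built from a subject table.

Every association analysis in the pipeline adjusts for the same five
nuisance factors: age, sex, handedness, level of education and intracranial
volume.  Education is a three-level factor entered as two dummy indicators
(middle and high, versus a low reference level).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import SchemaError

#: columns a subject table must carry
SUBJECT_COLUMNS = [
    "subject_id",
    "age",
    "sex",
    "handedness",
    "education",
    "icv",
    "aq_total",
    "sample",
]

NUISANCE_COLUMNS = ["age", "sex_m", "hand_l", "edu_middle", "edu_high", "icv"]


def check_subject_table(subjects: pd.DataFrame) -> None:
    """Validate the subject-table schema, raising :class:`SchemaError`."""
    missing = [c for c in SUBJECT_COLUMNS if c not in subjects.columns]
    if missing:
        raise SchemaError(f"subject table missing column(s): {', '.join(missing)}")
    if subjects["subject_id"].duplicated().any():
        raise SchemaError("subject_id values are not unique")
    bad_sample = set(subjects["sample"]) - {"exploration", "validation"}
    if bad_sample:
        raise SchemaError(f"unknown sample label(s): {sorted(bad_sample)}")


def nuisance_design(subjects: pd.DataFrame) -> pd.DataFrame:
    """Nuisance covariate matrix (no intercept column).

    Returns a DataFrame with columns ``age, sex_m, hand_l, edu_middle,
    edu_high, icv`` aligned to the rows of ``subjects``.
    """
    check_subject_table(subjects)
    out = pd.DataFrame(index=subjects.index)
    out["age"] = subjects["age"].astype(float)
    out["sex_m"] = (subjects["sex"] == "M").astype(float)
    out["hand_l"] = (subjects["handedness"] == "L").astype(float)
    out["edu_middle"] = (subjects["education"] == "middle").astype(float)
    out["edu_high"] = (subjects["education"] == "high").astype(float)
    out["icv"] = subjects["icv"].astype(float)
    return out


def as_design_array(
    covariates: pd.DataFrame | np.ndarray | None,
    n: int,
    add_intercept: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Coerce covariates into a float design array with column names.

    ``None`` yields an intercept-only design.  Column names are taken from
    the DataFrame when available, else synthesized as ``x0, x1, ...``.
    """
    if covariates is None:
        arr = np.empty((n, 0))
        names: list[str] = []
    elif isinstance(covariates, pd.DataFrame):
        arr = covariates.to_numpy(dtype=float)
        names = [str(c) for c in covariates.columns]
    else:
        arr = np.asarray(covariates, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        names = [f"x{i}" for i in range(arr.shape[1])]
    if arr.shape[0] != n:
        raise ValueError(f"covariates have {arr.shape[0]} rows, expected {n}")
    if add_intercept:
        arr = np.column_stack([np.ones(n), arr])
        names = ["intercept", *names]
    return arr, names
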