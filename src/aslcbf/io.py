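"""Volume and table I/O: NIfTI maps, CSV cohort tables, manifests, configs.

Volumes travel as one NIfTI file per map with the voxel geometry in the
affine; cohort tables as CSV with the fixed column set of
:data:`aslcbf.cohort.COHORT_COLUMNS`.  A phantom/stack bundle is a directory
of NIfTI files plus a plain-text ``manifest.txt`` of ``key: value`` lines.
Uncompressed ``.nii`` is the default so repeated writes are byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .cohort import COHORT_COLUMNS

__all__ = [
    "write_volume",
    "read_volume",
    "write_cohort",
    "read_cohort",
    "write_manifest",
    "read_manifest",
    "load_yaml_config",
]

REQUIRED_COHORT_COLUMNS = ("subject_id", "visit_time_years", "mmse")


def write_volume(path, data: np.ndarray, voxel_size_mm) -> Path:
    """Write a 3-D map to NIfTI with a diagonal affine from the voxel size."""
    path = Path(path)
    affine = np.diag([*voxel_size_mm, 1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    img.header.set_zooms(tuple(voxel_size_mm))
    nib.save(img, path)
    return path


def read_volume(path) -> tuple[np.ndarray, tuple[float, ...]]:
    """Read a NIfTI map; returns the array and per-axis voxel size in mm."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    try:
        img = nib.load(path)
        data = np.asarray(img.dataobj, dtype=np.float64)
    except Exception as exc:  # corrupt/truncated file
        raise ValueError(f"cannot parse volume file {path}: {exc}") from exc
    zooms = tuple(float(z) for z in img.header.get_zooms()[:data.ndim])
    return data, zooms


def write_cohort(path, cohort: pd.DataFrame) -> Path:
    """Write a cohort visit table as CSV in the canonical column order."""
    path = Path(path)
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing required column(s): {missing}")
    cols = [c for c in COHORT_COLUMNS if c in cohort.columns] + [
        c for c in cohort.columns if c not in COHORT_COLUMNS
    ]
    cohort[cols].to_csv(path, index=False, lineterminator="\n")
    return path


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV; errors name the offending column."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cohort file not found: {path}")
    table = pd.read_csv(path, float_precision="round_trip")
    for col in REQUIRED_COHORT_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"cohort file {path} lacks required column {col!r}")
    for col in ("visit_time_years", "mmse"):
        try:
            table[col] = pd.to_numeric(table[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(
                f"cohort file {path}: column {col!r} is not numeric"
            ) from exc
    if (table["visit_time_years"] < 0).any():
        raise ValueError(f"cohort file {path}: negative visit_time_years")
    return table


def write_manifest(path, entries: dict) -> Path:
    path = Path(path)
    lines = [f"{k}: {v}" for k, v in entries.items()]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_manifest(path) -> dict[str, str]:
    path = Path(path)
    out: dict[str, str] = {}
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        if ":" not in line:
            raise ValueError(f"manifest {path}: malformed line {line!r}")
        k, v = line.split(":", 1)
        out[k.strip()] = v.strip()
    return out


def load_yaml_config(path) -> dict:
    """Load a structured YAML config file into a plain dict."""
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return cfg
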