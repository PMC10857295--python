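"""File formats: NIfTI spatial maps, TSV tables, CSV matrices.

Two NIfTI dialects are supported for spatial maps: one 3D file per
component (``<subject>_<component>.nii``) or one 4D file per subject with
components stacked along the fourth axis. Tabular outputs are TSV with
explicit headers; square matrices (FNC, thresholded graphs) are CSV with
component-id headers.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

FORMAT_VERSION = "1"


# -- NIfTI spatial maps -------------------------------------------------------

def write_subject_maps_3d(out_dir, subject_id: str,
                          maps: Mapping[str, np.ndarray]) -> List[Path]:
    """One 3D NIfTI per component: ``<subject>_<component>.nii``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for cid, vol in maps.items():
        p = out_dir / f"{subject_id}_{cid}.nii"
        nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float32), np.eye(4)), p)
        paths.append(p)
    return paths


def write_subject_maps_4d(out_dir, subject_id: str,
                          maps: Mapping[str, np.ndarray]) -> Path:
    """One 4D NIfTI per subject, components along the fourth axis."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stack = np.stack([np.asarray(v, dtype=np.float32) for v in maps.values()],
                     axis=-1)
    p = out_dir / f"{subject_id}.nii"
    nib.save(nib.Nifti1Image(stack, np.eye(4)), p)
    return p


def read_subject_maps(maps_dir, subject_id: str,
                      component_ids: Sequence[str]) -> Dict[str, np.ndarray]:
    """Read a subject's maps in either dialect (4D file wins if present)."""
    maps_dir = Path(maps_dir)
    p4 = maps_dir / f"{subject_id}.nii"
    if p4.exists():
        data = np.asarray(nib.load(p4).dataobj, dtype=float)
        if data.ndim != 4 or data.shape[-1] != len(component_ids):
            raise ValueError(f"{p4}: expected 4D with {len(component_ids)} volumes")
        return {cid: data[..., j] for j, cid in enumerate(component_ids)}
    out = {}
    for cid in component_ids:
        p = maps_dir / f"{subject_id}_{cid}.nii"
        if not p.exists():
            raise FileNotFoundError(f"no map for subject {subject_id!r}, "
                                    f"component {cid!r}: {p}")
        out[cid] = np.asarray(nib.load(p).dataobj, dtype=float)
    return out


def read_mask(path) -> np.ndarray:
    return np.asarray(nib.load(path).dataobj) > 0


# -- tabular ------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path, index: bool = True) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    return path


def read_timecourses(path) -> pd.DataFrame:
    """T x C TSV with component ids as header."""
    return pd.read_csv(path, sep="\t")


def read_sizes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_groups(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("subject_id")["group"]


def read_partition(path) -> Dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["component_id"], df["domain"]))


def write_partition(assignment: Mapping[str, str], path) -> Path:
    df = pd.DataFrame({"component_id": list(assignment),
                       "domain": list(assignment.values())})
    return write_tsv(df, path, index=False)


def write_matrix_csv(mat: np.ndarray, component_ids: Sequence[str], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(mat, index=component_ids, columns=component_ids).to_csv(path)
    return path


def read_matrix_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
    return path


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
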