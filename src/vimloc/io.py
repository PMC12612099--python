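"""NIfTI / TSV / JSON readers and writers.

Volumes are NIfTI-1/2 (gzipped or plain) read through nibabel.  All of a
subject's volumes must agree on shape and affine (to 1e-5); a mismatch is a
hard error naming both files.  Probability outputs are stored as 32-bit
float volumes, labels as 8-bit unsigned.  Feature tables are TSV with
``i j k`` voxel-index columns followed by one column per feature, rows in
mask storage order.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import ConnectivityFeatureSet, CRFParams, LabelField, VoxelGrid

__all__ = [
    "read_volume",
    "grid_from_mask",
    "flat_field_from_volume",
    "write_flat_field",
    "write_feature_table",
    "read_feature_table",
    "write_params",
    "read_params",
    "write_cohort",
    "read_cohort",
]


def read_volume(path: str | Path):
    """Load a NIfTI volume; returns ``(data, affine, voxel_size_mm)``."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return data, img.affine, tuple(float(z) for z in img.header.get_zooms()[:3])


def _check_affine(path, affine, ref_path, ref_affine, atol=1e-5):
    if not np.allclose(affine, ref_affine, atol=atol):
        raise ValueError(
            f"affine mismatch between {path} and {ref_path}; "
            "all of a subject's volumes must share one native grid"
        )


def grid_from_mask(path: str | Path) -> VoxelGrid:
    """Build the thalamic :class:`VoxelGrid` from a binary mask volume."""
    data, affine, zooms = read_volume(path)
    idx = np.argwhere(data > 0)
    if idx.size == 0:
        raise ValueError(f"{path}: mask is empty")
    return VoxelGrid(data.shape, zooms, affine, idx)


def flat_field_from_volume(path: str | Path, grid: VoxelGrid, ref_path: str = "mask") -> np.ndarray:
    """Extract the mask voxels of a volume that must match the grid."""
    data, affine, _ = read_volume(path)
    if data.shape != grid.shape:
        raise ValueError(
            f"shape mismatch between {path} ({data.shape}) and {ref_path} ({grid.shape})"
        )
    _check_affine(path, affine, ref_path, grid.affine)
    return grid.flat_from_dense(data)


def write_flat_field(
    path: str | Path, grid: VoxelGrid, values: np.ndarray, dtype=np.float32
) -> None:
    """Scatter a flat mask field into a dense volume and save as NIfTI."""
    dense = grid.dense_from_flat(np.asarray(values, dtype=float)).astype(dtype)
    nib.save(nib.Nifti1Image(dense, grid.affine), str(path))


def write_feature_table(features: ConnectivityFeatureSet, path: str | Path) -> None:
    """TSV with header ``i j k <feature names...>``, full float precision."""
    df = pd.concat(
        [
            pd.DataFrame(features.grid.mask_indices, columns=["i", "j", "k"]),
            pd.DataFrame(features.X, columns=features.feature_names),
        ],
        axis=1,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_feature_table(path: str | Path, grid: VoxelGrid) -> ConnectivityFeatureSet:
    """Read a feature TSV back onto a grid (row order must match the mask)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(set(header)) != len(header):
        # checked on the raw line: pandas silently renames duplicates
        raise ValueError(f"{path}: duplicate feature names in header")
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    names = [c for c in df.columns if c not in ("i", "j", "k")]
    idx = df[["i", "j", "k"]].to_numpy()
    if not np.array_equal(idx, grid.mask_indices):
        raise ValueError(f"{path}: voxel index columns do not match the mask order")
    return ConnectivityFeatureSet(grid, names, df[names].to_numpy())


def write_params(params: CRFParams, path: str | Path, extra: dict | None = None) -> None:
    """Serialise fitted CRF parameters to a documented JSON container."""
    payload = {
        "format": "vimloc-crf-params",
        "version": 1,
        "W": params.W.tolist(),
        "rho": params.rho,
        "gamma": params.gamma,
        "powers": list(params.powers),
        "lambda1": params.lambda1,
        "lambda2": params.lambda2,
        "feature_names": list(params.feature_names),
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2))


def read_params(path: str | Path) -> CRFParams:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "vimloc-crf-params":
        raise ValueError(f"{path}: not a vimloc parameter file")
    return CRFParams(
        W=np.asarray(payload["W"]),
        rho=payload["rho"],
        gamma=payload["gamma"],
        powers=tuple(payload["powers"]),
        lambda1=payload.get("lambda1", 0.0),
        lambda2=payload.get("lambda2", 0.0),
        feature_names=payload.get("feature_names", []),
    )


def _safe_name(feature: str) -> str:
    return feature.replace("*", "_x_")


def write_cohort(subjects, out_dir: str | Path, spec=None) -> Path:
    """Write a cohort as per-subject NIfTI volumes plus a JSON manifest.

    Layout: ``<out>/<subject>/mask.nii.gz``, ``truth.nii.gz`` and one volume
    per feature under ``hq/`` and ``lq/``.  The manifest records subject
    ids, feature name -> file mappings, and an echo of the generating spec.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"format": "vimloc-cohort", "version": 1, "subjects": []}
    if spec is not None:
        echo = asdict(spec)
        echo["feature_recipe"] = [asdict(f) for f in spec.feature_recipe]
        echo["degradation"] = asdict(spec.degradation)
        manifest["spec"] = json.loads(json.dumps(echo, default=list))
    for s in subjects:
        sdir = out / s.subject_id
        (sdir / "hq").mkdir(parents=True, exist_ok=True)
        (sdir / "lq").mkdir(parents=True, exist_ok=True)
        grid = s.grid
        write_flat_field(sdir / "mask.nii.gz", grid, np.ones(grid.n_voxels), np.uint8)
        write_flat_field(sdir / "truth.nii.gz", grid, s.truth.y, np.uint8)
        entry = {
            "id": s.subject_id,
            "mask": str(sdir / "mask.nii.gz"),
            "truth": str(sdir / "truth.nii.gz"),
            "hq_features": {},
            "lq_features": {},
        }
        for quality, feats in (("hq", s.hq_features), ("lq", s.lq_features)):
            for name in feats.feature_names:
                p = sdir / quality / f"{_safe_name(name)}.nii.gz"
                write_flat_field(p, grid, feats.column(name))
                entry[f"{quality}_features"][name] = str(p)
        manifest["subjects"].append(entry)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out / "manifest.json"


def read_cohort(manifest_path: str | Path):
    """Read a cohort written by :func:`write_cohort`.

    Returns a list of :class:`~vimloc.simulate.SyntheticSubject`.  Grid
    consistency (shape and affine) is enforced across each subject's files.
    """
    from .simulate import SyntheticSubject

    manifest = json.loads(Path(manifest_path).read_text())
    if manifest.get("format") != "vimloc-cohort":
        raise ValueError(f"{manifest_path}: not a vimloc cohort manifest")
    ids = [e["id"] for e in manifest["subjects"]]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids in manifest")
    subjects = []
    for entry in manifest["subjects"]:
        grid = grid_from_mask(entry["mask"])
        truth = LabelField(
            grid, flat_field_from_volume(entry["truth"], grid, entry["mask"]).astype(np.int8)
        )
        sets = {}
        for quality in ("hq", "lq"):
            names, cols = [], []
            for name, p in entry[f"{quality}_features"].items():
                names.append(name)
                cols.append(flat_field_from_volume(p, grid, entry["mask"]))
            sets[quality] = ConnectivityFeatureSet(grid, names, np.column_stack(cols))
        subjects.append(
            SyntheticSubject(
                subject_id=entry["id"],
                grid=grid,
                truth=truth,
                hq_features=sets["hq"],
                lq_features=sets["lq"],
            )
        )
    return subjects
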