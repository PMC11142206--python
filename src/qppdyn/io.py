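"""Reading and writing of standard-format artifacts.

Volumes go to NIfTI-1 (via nibabel, TR recorded in the time-axis zoom);
region timecourses, metric tables and ANOVA tables go to TSV; configs,
manifests and ground truth go to JSON. TSV floats are written with a
fixed format so identical runs produce byte-identical files.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import ParcellatedScan, VoxelScan
from .synthetic import GroundTruth

FLOAT_FMT = "%.12g"


def write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT,
              lineterminator="\n")


def read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_parcellated_tsv(scan: ParcellatedScan, path: Path) -> None:
    """Region × time TSV (first column = region name) plus a JSON sidecar
    with scan metadata."""
    path = Path(path)
    df = pd.DataFrame(scan.values, index=scan.region_names)
    df.insert(0, "region_name", scan.region_names)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT,
              lineterminator="\n")
    meta = {
        "scan_id": scan.scan_id,
        "virus": scan.virus,
        "stimulation": scan.stimulation,
        "tr_seconds": scan.tr_seconds,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1) + "\n")


def read_parcellated_tsv(path: Path) -> ParcellatedScan:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(path.with_suffix(".json").read_text())
    names = df["region_name"].tolist()
    values = df.drop(columns=["region_name"]).to_numpy(dtype=float)
    return ParcellatedScan(
        values=values, region_names=names,
        tr_seconds=float(meta["tr_seconds"]),
        scan_id=meta.get("scan_id") or "",
        virus=meta.get("virus"), stimulation=meta.get("stimulation"),
    )


def write_cohort(scans: list[ParcellatedScan], out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    index = []
    for scan in scans:
        fname = f"{scan.scan_id or 'scan'}.tsv"
        write_parcellated_tsv(scan, out_dir / fname)
        index.append(fname)
    (out_dir / "cohort.json").write_text(json.dumps({"scans": index}, indent=1) + "\n")


def read_cohort(in_dir: Path) -> list[ParcellatedScan]:
    in_dir = Path(in_dir)
    index = json.loads((in_dir / "cohort.json").read_text())
    return [read_parcellated_tsv(in_dir / f) for f in index["scans"]]


def write_voxel_nifti(vol: VoxelScan, path: Path) -> None:
    """4D BOLD volume as NIfTI-1 with TR in the header; mask and labels as
    sibling integer volumes."""
    path = Path(path)
    affine = np.diag([vol.voxel_mm] * 3 + [1.0])
    img = nib.Nifti1Image(vol.data.astype(np.float32), affine)
    img.header.set_zooms((vol.voxel_mm,) * 3 + (vol.tr_seconds,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, path)
    base = path.name
    for suffix in (".nii.gz", ".nii"):
        if base.endswith(suffix):
            base = base[: -len(suffix)]
            break
    nib.save(nib.Nifti1Image(vol.brain_mask.astype(np.uint8), affine),
             path.parent / f"{base}_mask.nii.gz")
    nib.save(nib.Nifti1Image(vol.labels.astype(np.int16), affine),
             path.parent / f"{base}_labels.nii.gz")


def read_voxel_nifti(path: Path, voxel_mm: float = 0.5) -> VoxelScan:
    path = Path(path)
    img = nib.load(path)
    tr = float(img.header.get_zooms()[3])
    base = path.name
    for suffix in (".nii.gz", ".nii"):
        if base.endswith(suffix):
            base = base[: -len(suffix)]
            break
    mask = np.asarray(
        nib.load(path.parent / f"{base}_mask.nii.gz").dataobj
    ).astype(bool)
    labels = np.asarray(nib.load(path.parent / f"{base}_labels.nii.gz").dataobj)
    return VoxelScan(
        data=np.asarray(img.dataobj, dtype=float), brain_mask=mask,
        labels=labels, tr_seconds=tr, voxel_mm=voxel_mm,
    )


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_ground_truth(truth: GroundTruth, path: Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(truth), indent=1) + "\n")


def write_json(obj, path: Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=1, sort_keys=True) + "\n")
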