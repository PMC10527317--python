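"""On-disk formats: indicator CSVs, volume files (NIfTI / npz), manifest.

Layout written by :func:`write_dataset`::

    <outdir>/table.csv        one row per sample, indicator columns + label
    <outdir>/repeated.csv     long format (sample_id, feature, time, value)
    <outdir>/volumes/sXXXX.npz or .nii.gz
    <outdir>/manifest.json    sample ids -> volume files, spacing, checksums
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .datatypes import CTVolume, FeatureTable, PairedDataset

__all__ = ["write_dataset", "read_dataset", "write_table", "read_table"]


def write_table(table: FeatureTable, path: Path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_table(path: Path, repeated_path: Path | None = None) -> FeatureTable:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError(f"{path}: missing 'label' column")
    labels = df.pop("label").to_numpy()
    repeated = None
    if repeated_path is not None and Path(repeated_path).exists():
        repeated = pd.read_csv(repeated_path)
    return FeatureTable(df.to_numpy(float), list(df.columns), labels, repeated)


def _write_volume(vol: CTVolume, path: Path) -> None:
    if path.suffix == ".npz":
        np.savez_compressed(path, voxels=vol.voxels,
                            spacing=np.asarray(vol.spacing))
    else:
        affine = np.diag([*vol.spacing, 1.0])
        nib.save(nib.Nifti1Image(vol.voxels.astype(np.float32), affine), path)


def _read_volume(path: Path, sample_id: str) -> CTVolume:
    if path.suffix == ".npz":
        with np.load(path) as z:
            return CTVolume(z["voxels"], tuple(z["spacing"]), sample_id)
    img = nib.load(str(path))
    spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
    return CTVolume(np.asarray(img.dataobj, dtype=np.float32), spacing,
                    sample_id)


def write_dataset(ds: PairedDataset, outdir: str | Path,
                  volume_format: str = "npz") -> Path:
    if volume_format not in ("npz", "nii.gz"):
        raise ValueError(f"unknown volume format {volume_format!r}")
    outdir = Path(outdir)
    (outdir / "volumes").mkdir(parents=True, exist_ok=True)
    write_table(ds.table, outdir / "table.csv")
    if ds.table.repeated is not None:
        ds.table.repeated.to_csv(outdir / "repeated.csv", index=False)
    ext = ".npz" if volume_format == "npz" else ".nii.gz"
    entries = []
    for i, vol in enumerate(ds.volumes):
        sid = vol.sample_id or f"s{i:04d}"
        fname = f"volumes/{sid}{ext}"
        _write_volume(vol, outdir / fname)
        entries.append({"sample_id": sid, "row": i, "volume": fname,
                        "label": int(ds.labels[i]),
                        "spacing": list(map(float, vol.spacing))})
    manifest = {"n_samples": len(ds), "table": "table.csv",
                "repeated": "repeated.csv" if ds.table.repeated is not None else None,
                "samples": entries}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir


def read_dataset(outdir: str | Path) -> PairedDataset:
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json under {outdir}")
    manifest = json.loads(manifest_path.read_text())
    rep = outdir / manifest["repeated"] if manifest.get("repeated") else None
    table = read_table(outdir / manifest["table"], rep)
    volumes = []
    for entry in manifest["samples"]:
        vpath = outdir / entry["volume"]
        if not vpath.exists():
            raise FileNotFoundError(
                f"manifest names missing volume for sample "
                f"{entry['sample_id']!r}: {vpath}"
            )
        volumes.append(_read_volume(vpath, entry["sample_id"]))
    labels = np.array([e["label"] for e in manifest["samples"]])
    if not np.array_equal(labels, table.labels):
        raise ValueError("manifest labels disagree with table.csv labels")
    return PairedDataset(table=table, volumes=volumes, labels=labels)
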