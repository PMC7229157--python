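"""Readers and writers for the pipeline's on-disk formats.

Volumes travel as NIfTI (one file per wavelength, voxel size in the header)
or multi-page TIFF; per-frame laser energies and cohort tables as CSV;
contour stacks and ellipsoids as JSON.  The NIfTI affine maps array indices
(slice, row, col) to world (z, y, x) mm, matching the in-memory convention.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .exceptions import DataError
from .roi3d import ContourStack, Ellipsoid, SliceContours, VoxelMask
from .unmixing import DualWavelengthVolume, SO2Volume

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_tiff_stack",
    "load_tiff_stack",
    "save_so2_volume",
    "save_contours_json",
    "load_contours_json",
    "load_contours_csv",
    "save_ellipsoid_json",
    "load_ellipsoid_json",
    "save_energies_csv",
    "load_energies_csv",
    "save_dual_volume",
    "load_dual_volume",
]


def _affine(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def save_nifti(array: np.ndarray, voxel_size, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(array, dtype=np.float32), _affine(voxel_size)), str(path))


def load_nifti(path) -> tuple:
    """Returns (array, voxel_size)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    voxel_size = tuple(float(v) for v in img.header.get_zooms()[:3])
    return data, voxel_size


def save_tiff_stack(array: np.ndarray, path) -> None:
    tifffile.imwrite(str(path), np.asarray(array, dtype=np.float32), photometric="minisblack")


def load_tiff_stack(path) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)), dtype=float)


def save_so2_volume(so2: SO2Volume, path, sidecar: bool = True) -> None:
    """SO2 as NIfTI float with NaN marking invalid voxels, plus a JSON
    sidecar recording the unmixing policies applied."""
    save_nifti(so2.so2, so2.voxel_size, path)
    if sidecar:
        side = Path(str(path)).with_suffix("").with_suffix(".json")
        side.write_text(json.dumps({"invalid_marker": "NaN", **_jsonable(so2.meta)}, indent=2))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def save_contours_json(stack: ContourStack, path) -> None:
    doc = {
        "units": "mm",
        "vertex_order": "xy",
        "slices": [
            {"position_mm": s.position, "polygons": [p.tolist() for p in s.polygons]}
            for s in stack.slices
        ],
    }
    Path(str(path)).write_text(json.dumps(doc))


def load_contours_json(path) -> ContourStack:
    doc = json.loads(Path(str(path)).read_text())
    return ContourStack(
        slices=[
            SliceContours(
                position=float(s["position_mm"]),
                polygons=[np.asarray(p, dtype=float) for p in s["polygons"]],
            )
            for s in doc["slices"]
        ]
    )


def load_contours_csv(path) -> ContourStack:
    """Simple dialect: columns ``slice`` (position mm), ``x``, ``y``; one
    polygon per slice, vertices in file order."""
    df = pd.read_csv(path)
    for col in ("slice", "x", "y"):
        if col not in df.columns:
            raise DataError(f"contour CSV needs a {col!r} column")
    slices = []
    for pos, grp in df.groupby("slice", sort=True):
        slices.append(
            SliceContours(position=float(pos), polygons=[grp[["x", "y"]].to_numpy(dtype=float)])
        )
    return ContourStack(slices=slices)


def save_ellipsoid_json(e: Ellipsoid, path) -> None:
    Path(str(path)).write_text(json.dumps(e.to_dict(), indent=2))


def load_ellipsoid_json(path) -> Ellipsoid:
    return Ellipsoid.from_dict(json.loads(Path(str(path)).read_text()))


def save_energies_csv(frame_energies: dict, path) -> None:
    df = pd.DataFrame(
        {f"energy_{int(w)}nm": np.asarray(e, dtype=float) for w, e in sorted(frame_energies.items())}
    )
    df.insert(0, "frame", np.arange(len(df)))
    df.to_csv(path, index=False)


def load_energies_csv(path) -> dict:
    df = pd.read_csv(path)
    out = {}
    for col in df.columns:
        if col.startswith("energy_") and col.endswith("nm"):
            out[float(col[len("energy_"):-2])] = df[col].to_numpy(dtype=float)
    if not out:
        raise DataError("no energy_<wavelength>nm columns found")
    return out


def save_dual_volume(volume: DualWavelengthVolume, directory, fmt: str = "nifti") -> None:
    """One volume file per wavelength plus the frame-energy CSV."""
    d = Path(str(directory))
    d.mkdir(parents=True, exist_ok=True)
    for w in volume.wavelengths:
        if fmt == "nifti":
            save_nifti(volume.stacks[w], volume.voxel_size, d / f"pa_{int(w)}nm.nii.gz")
        elif fmt == "tiff":
            save_tiff_stack(volume.stacks[w], d / f"pa_{int(w)}nm.tif")
        else:
            raise DataError(f"unknown volume format {fmt!r}")
    save_energies_csv(volume.frame_energies, d / "frame_energies.csv")
    (d / "volume_meta.json").write_text(
        json.dumps(_jsonable({"voxel_size_mm": volume.voxel_size, **volume.meta}), indent=2)
    )


def load_dual_volume(directory) -> DualWavelengthVolume:
    d = Path(str(directory))
    meta = json.loads((d / "volume_meta.json").read_text())
    voxel_size = tuple(meta.pop("voxel_size_mm"))
    energies = load_energies_csv(d / "frame_energies.csv")
    stacks = {}
    for w in energies:
        nii = d / f"pa_{int(w)}nm.nii.gz"
        tif = d / f"pa_{int(w)}nm.tif"
        if nii.exists():
            stacks[w], _ = load_nifti(nii)
        elif tif.exists():
            stacks[w] = load_tiff_stack(tif)
        else:
            raise DataError(f"no volume file for {w} nm in {d}")
    return DualWavelengthVolume(
        stacks=stacks, frame_energies=energies, voxel_size=voxel_size, meta=meta
    )


def save_mask_nifti(mask: VoxelMask, path) -> None:
    nib.save(
        nib.Nifti1Image(mask.data.astype(np.uint8), _affine(mask.voxel_size)), str(path)
    )
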