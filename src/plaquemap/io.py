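"""Readers and writers for the pipeline's file formats.

TIFF via tifffile (multichannel 2D planes and 3D stacks with voxel-size
sidecar metadata), label volumes via NIfTI (nibabel), tables via CSV
(pandas), gene sets via GMT. Writers avoid embedding timestamps or UUIDs
so repeated runs with the same inputs are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
import yaml

from plaquemap.images import Plane2D, Volume3D


# -- TIFF ------------------------------------------------------------------


def write_section_tiff(path: str | Path, channels: Mapping[str, Plane2D]) -> None:
    """Write a multichannel 2D section as a (C, Y, X) TIFF plus sidecar YAML."""
    path = Path(path)
    names = list(channels)
    stack = np.stack([np.asarray(channels[n].data, dtype=np.float32) for n in names])
    tifffile.imwrite(path, stack, photometric="minisblack")
    meta = {"channels": names, "pixel_size_um": channels[names[0]].pixel_size}
    path.with_suffix(".yaml").write_text(yaml.safe_dump(meta, sort_keys=True))


def read_section_tiff(path: str | Path) -> dict[str, Plane2D]:
    path = Path(path)
    meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
    stack = tifffile.imread(path)
    ps = float(meta["pixel_size_um"])
    return {n: Plane2D(stack[i], pixel_size=ps) for i, n in enumerate(meta["channels"])}


def write_volume_tiff(path: str | Path, vol: Volume3D) -> None:
    """Write a 3D stack as a (Z, Y, X) TIFF plus voxel-size sidecar YAML."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(vol.data, dtype=np.float32))
    meta = {"voxel_size_um_zyx": list(vol.voxel_size), "channel": vol.channel}
    path.with_suffix(".yaml").write_text(yaml.safe_dump(meta, sort_keys=True))


def read_volume_tiff(path: str | Path) -> Volume3D:
    path = Path(path)
    meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
    data = tifffile.imread(path)
    return Volume3D(data, tuple(meta["voxel_size_um_zyx"]), channel=meta.get("channel"))


def write_mask_tiff(path: str | Path, mask: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(mask, dtype=np.uint8))


def read_mask_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)) > 0


# -- label volumes (NIfTI) -------------------------------------------------


def write_label_volume(path: str | Path, labels: np.ndarray, voxel_um: float) -> None:
    """Integer label volume as NIfTI with the voxel size in the affine (mm)."""
    affine = np.diag([voxel_um * 1e-3] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(labels, dtype=np.int32), affine)
    nib.save(img, str(path))


def read_label_volume(path: str | Path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    voxel_um = float(img.affine[0, 0]) * 1e3
    return np.asarray(img.dataobj, dtype=np.int32), voxel_um


# -- section manifests -----------------------------------------------------


def write_section_manifest(
    path: str | Path, sections: Sequence[tuple[np.ndarray, float]], directory: str | Path
) -> pd.DataFrame:
    """Write per-section masks plus a (filename, z_um) manifest CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (mask, z) in enumerate(sections):
        fname = f"section_{i:04d}.tif"
        write_mask_tiff(directory / fname, mask)
        rows.append({"filename": fname, "z_um": z})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(path, index=False)
    return manifest


def read_section_manifest(path: str | Path, directory: str | Path) -> list[tuple[np.ndarray, float]]:
    manifest = pd.read_csv(path)
    directory = Path(directory)
    return [
        (read_mask_tiff(directory / row.filename), float(row.z_um))
        for row in manifest.itertuples()
    ]


# -- gene sets (GMT) -------------------------------------------------------


def write_gmt(path: str | Path, gene_sets: Mapping[str, Sequence[str]]) -> None:
    lines = [
        "\t".join([name, "na", *genes]) for name, genes in gene_sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


# -- run manifests ---------------------------------------------------------


def write_run_manifest(path: str | Path, params: Mapping) -> None:
    """Record every resolved parameter of a run as sorted JSON."""
    Path(path).write_text(json.dumps(params, indent=2, sort_keys=True, default=str) + "\n")
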