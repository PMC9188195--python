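"""Whole-brain plaque counting and density over an atlas ontology.

Serial block-face imaging yields, per coronal section, a full-resolution
binary segmentation mask of plaque signal (default 0.35 um/pixel) at a
fixed sectioning interval (default 100 um). The pipeline:

1. bins each section's positive pixels into an isotropic summary grid
   (default 10 um voxels), recording the number of signal-positive pixels
   per grid voxel;
2. groups adjacent (face-connected by default) positive grid voxels into
   plaque objects — because the sectioning interval exceeds the grid voxel,
   objects never span sections, so the z-resolution for separating plaques
   equals the sectioning interval;
3. assigns each object to the atlas structure under its centroid voxel and
   summarizes signal, counts, structure volume and plaques per mm^3;
4. rolls summaries up the structure ontology tree.

Densities are reported both raw (objects per full structure volume) and
with a z-sampling correction factor ``section_interval / grid_voxel``
that compensates for plaques lying between sampled planes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

UNASSIGNED = -1  # structure bucket for objects whose centroid has atlas label 0


@dataclass
class GridParams:
    """Voxel-grid parameters. All lengths in micrometres."""

    grid_voxel: float = 10.0
    lateral_pixel: float = 0.35
    section_interval: float = 100.0
    connectivity: Literal["face6", "full26"] = "face6"
    sampling_correction: bool = False

    def __post_init__(self) -> None:
        if self.grid_voxel <= 0:
            raise ValueError("grid_voxel must be > 0")
        if self.section_interval < self.grid_voxel:
            raise ValueError("section_interval must be >= grid_voxel")
        if self.lateral_pixel >= self.grid_voxel:
            raise ValueError("lateral_pixel must be < grid_voxel")
        if self.connectivity not in ("face6", "full26"):
            raise ValueError("connectivity must be 'face6' or 'full26'")


@dataclass
class SignalGrid:
    """Isotropic grid of signal-positive pixel counts.

    ``counts`` is indexed (z, y, x); ``z_sections`` maps each occupied
    z-plane index to the section z position (um) it came from.
    """

    counts: np.ndarray
    grid_voxel: float
    z_sections: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("counts must be a 3D array")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")


@dataclass
class StructureSummary:
    """Per-structure plaque statistics."""

    structure_id: int
    signal_voxels: int
    summed_signal: int
    structure_volume_mm3: float
    plaque_count: int
    plaques_per_mm3: float
    plaques_per_mm3_corrected: float
    rolled_up: bool = False


def voxelize_sections(
    sections: list[tuple[np.ndarray, float]],
    params: GridParams,
    grid_shape: tuple[int, int, int] | None = None,
) -> SignalGrid:
    """Bin per-section binary masks into the isotropic summary grid.

    ``sections`` is a list of (mask, z_position_um) pairs sharing one
    lateral pixel size (``params.lateral_pixel``); section z positions must
    be multiples of the sectioning interval. Pixel (i, j) at height z maps
    to grid voxel (floor(z/g), floor(i*p/g), floor(j*p/g)) and each voxel
    stores the number of positive pixels mapped into it, so the total
    positive-pixel count is conserved.
    """
    if not sections:
        raise ValueError("need at least one section")
    g, p = params.grid_voxel, params.lateral_pixel
    shapes = {np.asarray(m).shape for m, _ in sections}
    if len(shapes) != 1:
        raise ValueError("all section masks must share one shape")
    (ny, nx) = shapes.pop()
    z_max = max(z for _, z in sections)
    if grid_shape is None:
        grid_shape = (
            int(np.floor(z_max / g)) + 1,
            int(np.ceil(ny * p / g)),
            int(np.ceil(nx * p / g)),
        )
    counts = np.zeros(grid_shape, dtype=np.int64)
    z_sections: dict[int, float] = {}
    for mask, z_um in sections:
        if abs(z_um / params.section_interval - round(z_um / params.section_interval)) > 1e-9:
            raise ValueError(
                f"section z={z_um} um is not a multiple of the interval "
                f"{params.section_interval} um"
            )
        zi = int(np.floor(z_um / g))
        z_sections[zi] = z_um
        ii, jj = np.nonzero(np.asarray(mask, dtype=bool))
        gy = np.floor(ii * p / g).astype(np.int64)
        gx = np.floor(jj * p / g).astype(np.int64)
        np.add.at(counts[zi], (gy, gx), 1)
    return SignalGrid(counts, grid_voxel=g, z_sections=z_sections)


def _structure_element(connectivity: str) -> np.ndarray:
    return ndimage.generate_binary_structure(3, 1 if connectivity == "face6" else 3)


def label_plaques(grid: SignalGrid, params: GridParams) -> tuple[np.ndarray, int]:
    """Group positive grid voxels into plaque objects.

    Connected components of ``counts > 0`` under the configured
    connectivity (face adjacency by default). Returns (label volume,
    object count).
    """
    labels, n = ndimage.label(grid.counts > 0, structure=_structure_element(params.connectivity))
    logger.info("labeled %d plaque objects (%s connectivity)", n, params.connectivity)
    return labels, int(n)


def _object_centroids(labels: np.ndarray, n: int) -> np.ndarray:
    """Centroid voxel (rounded mean coordinate) of each object, shape (n, 3)."""
    centroids = ndimage.center_of_mass(labels > 0, labels, index=range(1, n + 1))
    out = np.rint(np.asarray(centroids)).astype(np.int64)
    return np.clip(out, 0, np.array(labels.shape) - 1)


def structure_summary(
    grid: SignalGrid,
    labels: np.ndarray,
    n_objects: int,
    atlas: np.ndarray,
    params: GridParams,
) -> pd.DataFrame:
    """Per-structure signal, object counts and densities.

    ``atlas`` is an integer label volume aligned voxel-for-voxel with the
    grid. Each plaque object is assigned to the structure of its centroid
    voxel; objects whose centroid carries atlas label 0 are collected under
    the ``UNASSIGNED`` (-1) bucket and logged. Structure volume is the
    atlas voxel count times the grid voxel volume; ``plaques_per_mm3`` is
    the raw object-count density and ``plaques_per_mm3_corrected``
    multiplies it by the z-sampling factor ``section_interval/grid_voxel``.
    """
    atlas = np.asarray(atlas)
    if atlas.shape != grid.counts.shape:
        raise ValueError("atlas must be grid-aligned (same shape as the signal grid)")
    voxel_mm3 = (grid.grid_voxel * 1e-3) ** 3
    correction = params.section_interval / params.grid_voxel

    structure_ids = np.unique(atlas)
    structure_ids = structure_ids[structure_ids > 0]
    plaque_counts: dict[int, int] = {int(s): 0 for s in structure_ids}
    if n_objects:
        centroids = _object_centroids(labels, n_objects)
        obj_struct = atlas[tuple(centroids.T)]
        n_unassigned = int((obj_struct == 0).sum())
        if n_unassigned:
            logger.warning("%d plaque objects have unlabeled centroids", n_unassigned)
            plaque_counts[UNASSIGNED] = n_unassigned
        for s in obj_struct[obj_struct > 0]:
            plaque_counts[int(s)] += 1

    rows = []
    positive = grid.counts > 0
    for s, count in sorted(plaque_counts.items()):
        if s == UNASSIGNED:
            in_struct = np.zeros_like(positive)
            vol_mm3 = np.nan
        else:
            in_struct = atlas == s
            vol_mm3 = float(in_struct.sum()) * voxel_mm3
        density = count / vol_mm3 if vol_mm3 and np.isfinite(vol_mm3) and vol_mm3 > 0 else np.nan
        rows.append(
            {
                "structure_id": s,
                "signal_voxels": int((positive & in_struct).sum()),
                "summed_signal": int(grid.counts[in_struct].sum()),
                "structure_volume_mm3": vol_mm3,
                "plaque_count": count,
                "plaques_per_mm3": density,
                "plaques_per_mm3_corrected": density * correction if np.isfinite(density) else np.nan,
                "rolled_up": False,
            }
        )
    return pd.DataFrame(rows)


def rollup_ontology(summaries: pd.DataFrame, ontology: pd.DataFrame) -> pd.DataFrame:
    """Propagate leaf summaries up the structure ontology tree.

    ``ontology`` needs columns ``id`` and ``parent_id`` (parent of the root
    is missing/0/-1 or self). Each parent's signal, volume and plaque count
    become the sums over all its descendants (plus its own leaf values, if
    any); densities are recomputed from the summed counts and volumes.
    """
    onto = ontology.set_index("id")
    children: dict[int, list[int]] = {}
    for sid, row in onto.iterrows():
        pid = row["parent_id"]
        if pd.isna(pid) or int(pid) in (0, -1, int(sid)):
            continue
        children.setdefault(int(pid), []).append(int(sid))

    leaf = summaries.set_index("structure_id")

    def totals(sid: int) -> tuple[int, int, float, int]:
        sig_v, sig, vol, cnt = 0, 0, 0.0, 0
        if sid in leaf.index:
            r = leaf.loc[sid]
            sig_v += int(r["signal_voxels"])
            sig += int(r["summed_signal"])
            if np.isfinite(r["structure_volume_mm3"]):
                vol += float(r["structure_volume_mm3"])
            cnt += int(r["plaque_count"])
        for ch in children.get(sid, []):
            c = totals(ch)
            sig_v, sig, vol, cnt = sig_v + c[0], sig + c[1], vol + c[2], cnt + c[3]
        return sig_v, sig, vol, cnt

    correction = np.nan
    if len(summaries) and summaries["plaques_per_mm3"].gt(0).any():
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = summaries["plaques_per_mm3_corrected"] / summaries["plaques_per_mm3"]
        correction = float(ratio.dropna().iloc[0]) if ratio.notna().any() else np.nan

    rows = []
    for sid in onto.index:
        sig_v, sig, vol, cnt = totals(int(sid))
        density = cnt / vol if vol > 0 else np.nan
        rows.append(
            {
                "structure_id": int(sid),
                "signal_voxels": sig_v,
                "summed_signal": sig,
                "structure_volume_mm3": vol if vol > 0 else np.nan,
                "plaque_count": cnt,
                "plaques_per_mm3": density,
                "plaques_per_mm3_corrected": density * correction
                if np.isfinite(density) and np.isfinite(correction)
                else np.nan,
                "rolled_up": bool(children.get(int(sid))),
            }
        )
    return pd.DataFrame(rows)


def apply_hemisphere(
    grid: SignalGrid, atlas: np.ndarray, side: Literal["left", "right", "both"], axis: int = 2
) -> tuple[SignalGrid, np.ndarray]:
    """Restrict grid and atlas to one hemisphere along ``axis``.

    The midplane splits the volume in half; ``"left"`` keeps the lower-index
    half. Reported plaque quantification conventionally uses a single
    hemisphere per brain.
    """
    if side == "both":
        return grid, atlas
    mid = grid.counts.shape[axis] // 2
    sel = [slice(None)] * 3
    sel[axis] = slice(0, mid) if side == "left" else slice(mid, None)
    counts = np.zeros_like(grid.counts)
    counts[tuple(sel)] = grid.counts[tuple(sel)]
    atlas_out = np.zeros_like(atlas)
    atlas_out[tuple(sel)] = atlas[tuple(sel)]
    return SignalGrid(counts, grid.grid_voxel, dict(grid.z_sections)), atlas_out


def run_pipeline(
    sections: list[tuple[np.ndarray, float]],
    atlas: np.ndarray,
    ontology: pd.DataFrame,
    params: GridParams,
) -> tuple[SignalGrid, pd.DataFrame, pd.DataFrame]:
    """Voxelize, label, summarize per structure, and roll up the ontology.

    Returns (grid, leaf summaries, rolled-up summaries).
    """
    grid = voxelize_sections(sections, params, grid_shape=atlas.shape)
    labels, n = label_plaques(grid, params)
    leaves = structure_summary(grid, labels, n, atlas, params)
    rolled = rollup_ontology(leaves, ontology)
    return grid, leaves, rolled
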