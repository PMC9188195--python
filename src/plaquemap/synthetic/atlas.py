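"""Toy whole-brain stacks: full-resolution section masks over a labeled
atlas with a small structure ontology."""

from __future__ import annotations

import numpy as np
import pandas as pd

from plaquemap.synthetic.truth import AtlasTruth


def make_atlas_sections(
    truth: AtlasTruth, seed: int = 0
) -> tuple[list[tuple[np.ndarray, float]], np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Rasterize planted plaques into per-section binary masks.

    Returns (sections, label_volume, ontology, truth_table) where
    ``sections`` is a list of (full-resolution mask, z position um) pairs —
    one per sampled plane covered by the atlas — and ``truth_table``
    records each plaque's structure assignment (the atlas label of the
    grid voxel under its center) and positive-pixel count.
    """
    g = truth.grid_voxel
    n_z = truth.label_volume.shape[0]
    n_sections = int(np.floor((n_z * g - 1e-9) / truth.section_interval)) + 1
    shape = truth.section_shape_px
    masks = {i: np.zeros(shape, dtype=bool) for i in range(n_sections)}

    yy = (np.arange(shape[0]) + 0.5) * truth.lateral_pixel_size
    xx = (np.arange(shape[1]) + 0.5) * truth.lateral_pixel_size
    rows = []
    for pid, p in enumerate(truth.plaques):
        si = int(round(p["z_um"] / truth.section_interval))
        if si not in masks:
            raise ValueError(f"plaque {pid} lies on an unsampled plane z={p['z_um']}")
        cy = (p["y_px"] + 0.5) * truth.lateral_pixel_size
        cx = (p["x_px"] + 0.5) * truth.lateral_pixel_size
        r_um = p["radius_px"] * truth.lateral_pixel_size
        disk = (yy[:, None] - cy) ** 2 + (xx[None, :] - cx) ** 2 <= r_um**2
        masks[si] |= disk
        gz = int(np.floor(p["z_um"] / g))
        gy = int(np.floor(cy / g))
        gx = int(np.floor(cx / g))
        label = int(truth.label_volume[gz, gy, gx])
        rows.append(
            {
                "plaque_id": pid,
                "z_um": p["z_um"],
                "structure_id": label,
                "positive_px": int(disk.sum()),
            }
        )
    sections = [(masks[i], i * truth.section_interval) for i in range(n_sections)]
    return sections, truth.label_volume, truth.ontology, pd.DataFrame(rows)


def random_atlas_truth(
    seed: int,
    grid_shape: tuple[int, int, int] = (20, 18, 18),
    grid_voxel: float = 10.0,
    lateral_pixel_size: float = 0.35,
    section_interval: float = 100.0,
    plaques_per_structure: dict[int, int] | None = None,
    plaque_radius_px: float = 6.0,
) -> AtlasTruth:
    """A two-structure toy brain with plaques planted per structure.

    The atlas splits the in-brain grid volume into two lateral halves:
    structure 2 (left) and 3 (right), both children of root structure 1.
    ``plaques_per_structure`` maps structure id to planted plaque count
    (default {2: 3, 3: 0}). Plaques land on sampled section planes, at
    grid-voxel-aligned positions separated by at least two grid voxels so
    each rasterizes to its own connected object.
    """
    rng = np.random.default_rng(seed)
    if plaques_per_structure is None:
        plaques_per_structure = {2: 3, 3: 0}

    nz, ny, nx = grid_shape
    label = np.zeros(grid_shape, dtype=np.int32)
    # 1-voxel empty margin, two lateral halves
    label[1 : nz - 1, 1 : ny - 1, 1 : nx // 2] = 2
    label[1 : nz - 1, 1 : ny - 1, nx // 2 : nx - 1] = 3
    ontology = pd.DataFrame(
        {
            "id": [1, 2, 3],
            "parent_id": [0, 1, 1],
            "acronym": ["ROOT", "L", "R"],
            "name": ["root", "left half", "right half"],
        }
    )

    px_per_grid = grid_voxel / lateral_pixel_size
    section_shape = (int(np.ceil(ny * px_per_grid)), int(np.ceil(nx * px_per_grid)))
    margin_px = int(np.ceil(plaque_radius_px)) + 2
    sections_z = [
        z * section_interval
        for z in range(int(np.floor((nz * grid_voxel - 1e-9) / section_interval)) + 1)
    ]

    plaques: list[dict] = []
    taken: list[tuple[float, float, float]] = []
    min_sep_px = 2 * px_per_grid + 2 * plaque_radius_px
    for sid, count in plaques_per_structure.items():
        placed, attempts = 0, 0
        while placed < count and attempts < 10000:
            attempts += 1
            z_um = float(rng.choice(sections_z))
            y_px = float(rng.uniform(margin_px, section_shape[0] - margin_px))
            x_px = float(rng.uniform(margin_px, section_shape[1] - margin_px))
            gz = int(np.floor(z_um / grid_voxel))
            # every grid voxel the disk footprint touches must carry the
            # target label, so the object's centroid assignment is unambiguous
            lo_gy = int(np.floor((y_px - plaque_radius_px) * lateral_pixel_size / grid_voxel))
            hi_gy = int(np.floor((y_px + plaque_radius_px) * lateral_pixel_size / grid_voxel))
            lo_gx = int(np.floor((x_px - plaque_radius_px) * lateral_pixel_size / grid_voxel))
            hi_gx = int(np.floor((x_px + plaque_radius_px) * lateral_pixel_size / grid_voxel))
            footprint = label[gz, lo_gy : hi_gy + 1, lo_gx : hi_gx + 1]
            if footprint.size == 0 or not (footprint == sid).all():
                continue
            if any(
                z_um == tz and np.hypot(y_px - ty, x_px - tx) < min_sep_px
                for tz, ty, tx in taken
            ):
                continue
            plaques.append({"z_um": z_um, "y_px": y_px, "x_px": x_px, "radius_px": plaque_radius_px})
            taken.append((z_um, y_px, x_px))
            placed += 1
        if placed < count:
            raise ValueError(f"could not place {count} plaques in structure {sid}")

    return AtlasTruth(
        label_volume=label,
        ontology=ontology,
        plaques=plaques,
        section_interval=section_interval,
        lateral_pixel_size=lateral_pixel_size,
        grid_voxel=grid_voxel,
        section_shape_px=section_shape,
    )
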