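"""Ground-truth descriptions of the synthetic phantoms.

Coordinates follow array order: (y, x) for planes and (z, y, x) for
volumes, in micrometres. Validation happens at construction; generators
can assume a valid truth object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SectionTruth:
    """Geometry and imaging parameters of one synthetic 2D section.

    Plaques and microglia are disks given by center (y, x) in um and
    radius in um; all must lie inside the image bounds. ``roi_polygon``
    (optional) is a list of (y, x) um vertices outlining the analyzed
    region; when absent the whole image is the ROI.
    """

    image_shape_px: tuple[int, int]
    pixel_size: float
    plaque_centers: list[tuple[float, float]] = field(default_factory=list)
    plaque_radii: list[float] = field(default_factory=list)
    microglia_centers: list[tuple[float, float]] = field(default_factory=list)
    microglia_radii: list[float] = field(default_factory=list)
    background_level: float = 0.0
    noise_sd: float = 0.0
    foreground_level: float = 1.0
    roi_polygon: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if len(self.plaque_centers) != len(self.plaque_radii):
            raise ValueError("plaque centers and radii must pair up")
        if len(self.microglia_centers) != len(self.microglia_radii):
            raise ValueError("microglia centers and radii must pair up")
        if any(r <= 0 for r in list(self.plaque_radii) + list(self.microglia_radii)):
            raise ValueError("all radii must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        ny, nx = self.image_shape_px
        h, w = ny * self.pixel_size, nx * self.pixel_size
        for (cy, cx), r in zip(
            list(self.plaque_centers) + list(self.microglia_centers),
            list(self.plaque_radii) + list(self.microglia_radii),
        ):
            if not (r <= cy <= h - r and r <= cx <= w - r):
                raise ValueError(
                    f"object at ({cy}, {cx}) um with radius {r} um exceeds the "
                    f"{h} x {w} um image bounds"
                )


@dataclass
class VolumeTruth:
    """Geometry of one synthetic 3D confocal volume.

    Somata are spheres (center (z, y, x) um, diameter um); processes are
    capsules (segment endpoints plus radius); plaques are spheres.
    ``methoxy_fraction_per_cell`` gives, per soma, the approximate volume
    fraction of the soma occupied by methoxy-X04 signal (0 = negative
    cell).
    """

    volume_shape_vox: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    soma_centers: list[tuple[float, float, float]] = field(default_factory=list)
    soma_diameters: list[float] = field(default_factory=list)
    process_segments: list[tuple[tuple[float, float, float], tuple[float, float, float], float]] = field(
        default_factory=list
    )
    plaque_blobs: list[tuple[tuple[float, float, float], float]] = field(default_factory=list)
    methoxy_fraction_per_cell: list[float] = field(default_factory=list)
    noise_sd: float = 0.0
    foreground_level: float = 1.0

    def __post_init__(self) -> None:
        if len(self.soma_centers) != len(self.soma_diameters):
            raise ValueError("soma centers and diameters must pair up")
        if self.methoxy_fraction_per_cell and len(self.methoxy_fraction_per_cell) != len(
            self.soma_centers
        ):
            raise ValueError("methoxy fractions must pair with somata")
        if any(d <= 0 for d in self.soma_diameters):
            raise ValueError("soma diameters must be > 0")
        if any(not 0 <= f <= 1 for f in self.methoxy_fraction_per_cell):
            raise ValueError("methoxy fractions must lie in [0, 1]")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        extent = [n * s for n, s in zip(self.volume_shape_vox, self.voxel_size)]
        for c, d in zip(self.soma_centers, self.soma_diameters):
            r = d / 2
            if not all(r <= c[i] <= extent[i] - r for i in range(3)):
                raise ValueError(f"soma at {c} um (diameter {d}) exceeds volume bounds")
        for c, r in self.plaque_blobs:
            if not all(r <= c[i] <= extent[i] - r for i in range(3)):
                raise ValueError(f"plaque at {c} um (radius {r}) exceeds volume bounds")


@dataclass
class AtlasTruth:
    """A toy brain: grid-resolution atlas labels plus planted plaques.

    ``label_volume`` assigns a structure id to each grid voxel (0 =
    outside); ``ontology`` is a table with columns id, parent_id, name
    whose parent links form a rooted tree. ``plaques`` are full-resolution
    disks (z um on a sampled section plane, center y/x px, radius px).
    """

    label_volume: np.ndarray
    ontology: pd.DataFrame
    plaques: list[dict]
    section_interval: float = 100.0
    lateral_pixel_size: float = 0.35
    grid_voxel: float = 10.0
    section_shape_px: tuple[int, int] = (512, 512)

    def __post_init__(self) -> None:
        self.label_volume = np.asarray(self.label_volume)
        ids = set(int(i) for i in self.ontology["id"])
        labels = set(int(v) for v in np.unique(self.label_volume)) - {0}
        if not labels <= ids:
            raise ValueError(f"atlas labels missing from ontology: {sorted(labels - ids)}")
        n_roots = 0
        for _, row in self.ontology.iterrows():
            pid = row["parent_id"]
            if pd.isna(pid) or int(pid) in (0, -1):
                n_roots += 1
            elif int(pid) not in ids:
                raise ValueError(f"parent {pid} of structure {row['id']} not in ontology")
        if n_roots != 1:
            raise ValueError(f"ontology must have exactly one root, found {n_roots}")
        for p in self.plaques:
            ratio = p["z_um"] / self.section_interval
            if abs(ratio - round(ratio)) > 1e-9:
                raise ValueError(
                    f"plaque at z={p['z_um']} um is off the {self.section_interval} um "
                    "section planes"
                )


@dataclass
class OmicsTruth:
    """Planted structure of a synthetic analyte/expression experiment.

    Two genotype groups of ``n_per_group`` subjects each, with per-feature
    condition effects (``true_log2fc``), batch and sex offsets, and a
    per-feature detection rate applied as missing-completely-at-random.
    """

    true_log2fc: np.ndarray
    batch_effects: np.ndarray
    sex_effects: np.ndarray
    detection_rate: np.ndarray
    n_per_group: int
    noise_sd: float = 0.25
    baseline: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.true_log2fc = np.asarray(self.true_log2fc, dtype=float)
        n = self.true_log2fc.size
        for name in ("batch_effects", "sex_effects", "detection_rate"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.size != n:
                raise ValueError(f"{name} must have one value per feature")
            setattr(self, name, arr)
        if ((self.detection_rate < 0) | (self.detection_rate > 1)).any():
            raise ValueError("detection_rate must lie in [0, 1]")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_features(self) -> int:
        return self.true_log2fc.size

    @property
    def affected_features(self) -> np.ndarray:
        return np.flatnonzero(self.true_log2fc != 0)
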