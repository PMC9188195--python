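"""Synthetic 2D sections: plaque and microglia disks with noise."""

from __future__ import annotations

import numpy as np
from skimage.draw import polygon2mask

from plaquemap.images import Plane2D
from plaquemap.synthetic.truth import SectionTruth

# markers treated as microglial by default; anything else gets plaques
MICROGLIA_MARKERS = {"iba1", "cd68"}


def _disk_mask(
    shape: tuple[int, int],
    centers: list[tuple[float, float]],
    radii: list[float],
    pixel_size: float,
) -> np.ndarray:
    """Rasterize closed disks: pixel on iff its center lies inside a disk."""
    mask = np.zeros(shape, dtype=bool)
    yy = (np.arange(shape[0]) + 0.5) * pixel_size
    xx = (np.arange(shape[1]) + 0.5) * pixel_size
    for (cy, cx), r in zip(centers, radii):
        d2 = (yy[:, None] - cy) ** 2 + (xx[None, :] - cx) ** 2
        mask |= d2 <= r * r
    return mask


def make_section(
    truth: SectionTruth, channels: list[str], seed: int
) -> tuple[dict[str, Plane2D], dict[str, np.ndarray], np.ndarray]:
    """Render a multichannel section plus its ground-truth masks.

    Channels whose lower-cased name is a microglial marker (Iba1, CD68)
    receive the microglia disks; every other channel receives the plaque
    disks. Each channel is foreground plus a linear background ramp scaled
    by ``truth.background_level`` plus Gaussian noise (sd
    ``truth.noise_sd``), clipped at zero. Returns (channel planes,
    ground-truth masks per channel, ROI mask).
    """
    rng = np.random.default_rng(seed)
    shape = truth.image_shape_px
    ps = truth.pixel_size

    plaque_mask = _disk_mask(shape, truth.plaque_centers, truth.plaque_radii, ps)
    micro_mask = _disk_mask(shape, truth.microglia_centers, truth.microglia_radii, ps)

    ramp = np.add.outer(np.linspace(0, 1, shape[0]), np.linspace(0, 1, shape[1])) / 2.0
    background = truth.background_level * ramp

    if truth.roi_polygon is not None:
        poly_px = np.asarray(truth.roi_polygon) / ps
        roi = polygon2mask(shape, poly_px)
    else:
        roi = np.ones(shape, dtype=bool)

    planes: dict[str, Plane2D] = {}
    masks: dict[str, np.ndarray] = {}
    for name in channels:
        gt = micro_mask if name.lower() in MICROGLIA_MARKERS else plaque_mask
        img = truth.foreground_level * gt.astype(float) + background
        if truth.noise_sd > 0:
            img = img + rng.normal(0.0, truth.noise_sd, size=shape)
        img = np.clip(img, 0, None)
        planes[name] = Plane2D(img, pixel_size=ps, roi=roi)
        masks[name] = gt
    return planes, masks, roi


def random_section_truth(
    seed: int,
    image_shape_px: tuple[int, int] = (256, 256),
    pixel_size: float = 1.0,
    n_plaques: int = 5,
    n_microglia: int = 12,
    plaque_radius_um: tuple[float, float] = (5.0, 15.0),
    microglia_radius_um: tuple[float, float] = (3.0, 6.0),
    fraction_near_plaques: float = 0.5,
    near_distance_um: float = 20.0,
    background_level: float = 0.0,
    noise_sd: float = 0.0,
    foreground_level: float = 1000.0,
) -> SectionTruth:
    """Draw a random, valid section layout.

    A configurable fraction of microglia is placed within
    ``near_distance_um`` of a plaque center (plaque-associated microglia);
    the rest are uniform over the section.
    """
    rng = np.random.default_rng(seed)
    ny, nx = image_shape_px
    h, w = ny * pixel_size, nx * pixel_size
    margin = max(plaque_radius_um[1], microglia_radius_um[1]) + 1.0

    def uniform_point() -> tuple[float, float]:
        return (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))

    plaque_centers = [uniform_point() for _ in range(n_plaques)]
    plaque_radii = list(rng.uniform(*plaque_radius_um, size=n_plaques))

    micro_centers: list[tuple[float, float]] = []
    for i in range(n_microglia):
        if plaque_centers and i < fraction_near_plaques * n_microglia:
            py, px = plaque_centers[rng.integers(len(plaque_centers))]
            ang = rng.uniform(0, 2 * np.pi)
            dist = rng.uniform(0, near_distance_um)
            cy = float(np.clip(py + dist * np.sin(ang), margin, h - margin))
            cx = float(np.clip(px + dist * np.cos(ang), margin, w - margin))
            micro_centers.append((cy, cx))
        else:
            micro_centers.append(uniform_point())
    micro_radii = list(rng.uniform(*microglia_radius_um, size=n_microglia))

    return SectionTruth(
        image_shape_px=image_shape_px,
        pixel_size=pixel_size,
        plaque_centers=plaque_centers,
        plaque_radii=plaque_radii,
        microglia_centers=micro_centers,
        microglia_radii=micro_radii,
        background_level=background_level,
        noise_sd=noise_sd,
        foreground_level=foreground_level,
    )
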