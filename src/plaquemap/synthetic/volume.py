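"""Synthetic 3D confocal volumes: sphere somata, capsule processes,
plaque blobs and per-cell methoxy-X04 content."""

from __future__ import annotations

import numpy as np

from plaquemap.images import Volume3D
from plaquemap.synthetic.truth import VolumeTruth


def _voxel_centers(shape, voxel_size):
    axes = [(np.arange(n) + 0.5) * s for n, s in zip(shape, voxel_size)]
    return axes


def _sphere_mask(shape, voxel_size, center, radius) -> np.ndarray:
    zz, yy, xx = _voxel_centers(shape, voxel_size)
    d2 = (
        (zz[:, None, None] - center[0]) ** 2
        + (yy[None, :, None] - center[1]) ** 2
        + (xx[None, None, :] - center[2]) ** 2
    )
    return d2 <= radius * radius


def _capsule_mask(shape, voxel_size, a, b, radius) -> np.ndarray:
    """Voxels within ``radius`` of segment a-b (centers-inside rule)."""
    zz, yy, xx = _voxel_centers(shape, voxel_size)
    pz, py, px = np.meshgrid(zz, yy, xx, indexing="ij")
    a = np.asarray(a, dtype=float)
    ab = np.asarray(b, dtype=float) - a
    ab2 = float(ab @ ab)
    dz, dy, dx = pz - a[0], py - a[1], px - a[2]
    if ab2 == 0:
        d2 = dz**2 + dy**2 + dx**2
    else:
        t = np.clip((dz * ab[0] + dy * ab[1] + dx * ab[2]) / ab2, 0.0, 1.0)
        d2 = (dz - t * ab[0]) ** 2 + (dy - t * ab[1]) ** 2 + (dx - t * ab[2]) ** 2
    return d2 <= radius * radius


def make_volume(
    truth: VolumeTruth, seed: int
) -> tuple[dict[str, Volume3D], dict[str, np.ndarray]]:
    """Render Iba1 / methoxy-X04 / Abeta channels plus ground-truth masks.

    The Iba1 channel contains soma spheres and process capsules; the
    methoxy channel contains, for each soma with a positive methoxy
    fraction, a concentric sphere occupying approximately that volume
    fraction of the soma (exact voxel overlap recorded in the returned
    masks); the Abeta channel contains the plaque blobs. Gaussian noise of
    sd ``truth.noise_sd`` is added and clipped at zero.
    """
    rng = np.random.default_rng(seed)
    shape, vs = truth.volume_shape_vox, truth.voxel_size

    iba1 = np.zeros(shape, dtype=bool)
    for c, d in zip(truth.soma_centers, truth.soma_diameters):
        iba1 |= _sphere_mask(shape, vs, c, d / 2.0)
    for a, b, r in truth.process_segments:
        iba1 |= _capsule_mask(shape, vs, a, b, r)

    methoxy = np.zeros(shape, dtype=bool)
    fractions = truth.methoxy_fraction_per_cell or [0.0] * len(truth.soma_centers)
    for c, d, f in zip(truth.soma_centers, truth.soma_diameters, fractions):
        if f > 0:
            methoxy |= _sphere_mask(shape, vs, c, (d / 2.0) * f ** (1.0 / 3.0))

    abeta = np.zeros(shape, dtype=bool)
    for c, r in truth.plaque_blobs:
        abeta |= _sphere_mask(shape, vs, c, r)

    masks = {"iba1": iba1, "methoxy": methoxy, "abeta": abeta}
    channels: dict[str, Volume3D] = {}
    for name, gt in masks.items():
        img = truth.foreground_level * gt.astype(float)
        if truth.noise_sd > 0:
            img = img + rng.normal(0.0, truth.noise_sd, size=shape)
        channels[name] = Volume3D(np.clip(img, 0, None), vs, channel=name)
    return channels, masks


def random_volume_truth(
    seed: int,
    volume_shape_vox: tuple[int, int, int] = (60, 80, 80),
    voxel_size: tuple[float, float, float] = (0.5, 0.5, 0.5),
    n_somata: int = 4,
    soma_diameter_um: tuple[float, float] = (8.0, 10.0),
    min_spacing_um: float = 14.0,
    methoxy_positive_fraction: float = 0.5,
    methoxy_content: float = 0.3,
    n_plaques: int = 1,
    plaque_radius_um: float = 4.0,
    noise_sd: float = 0.0,
) -> VolumeTruth:
    """Draw a random, valid volume layout with well-separated somata.

    A ``methoxy_positive_fraction`` of somata receive methoxy-X04 content
    (``methoxy_content`` volume fraction each); plaques are placed near
    the methoxy-positive somata so proximity calls have signal.
    """
    rng = np.random.default_rng(seed)
    extent = [n * s for n, s in zip(volume_shape_vox, voxel_size)]
    margin = soma_diameter_um[1] / 2.0 + 1.0

    centers: list[tuple[float, float, float]] = []
    attempts = 0
    while len(centers) < n_somata and attempts < 5000:
        attempts += 1
        c = tuple(rng.uniform(margin, e - margin) for e in extent)
        if all(np.linalg.norm(np.subtract(c, o)) >= min_spacing_um for o in centers):
            centers.append(c)
    if len(centers) < n_somata:
        raise ValueError("could not place the requested somata with the given spacing")
    diameters = list(rng.uniform(*soma_diameter_um, size=len(centers)))
    n_pos = int(round(methoxy_positive_fraction * len(centers)))
    fractions = [methoxy_content if i < n_pos else 0.0 for i in range(len(centers))]

    plaques = []
    for i in range(n_plaques):
        anchor = centers[i % max(n_pos, 1)] if n_pos else tuple(e / 2 for e in extent)
        offset = rng.uniform(-3.0, 3.0, size=3)
        c = tuple(
            float(np.clip(a + o, plaque_radius_um, e - plaque_radius_um))
            for a, o, e in zip(anchor, offset, extent)
        )
        plaques.append((c, plaque_radius_um))

    return VolumeTruth(
        volume_shape_vox=volume_shape_vox,
        voxel_size=voxel_size,
        soma_centers=centers,
        soma_diameters=diameters,
        plaque_blobs=plaques,
        methoxy_fraction_per_cell=fractions,
        noise_sd=noise_sd,
    )
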