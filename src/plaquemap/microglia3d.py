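"""3D confocal microglia pipeline.

Reconstructs individual microglia from confocal z-stacks and classifies
them by phagocytosed fibrillar amyloid (methoxy-X04 content) and proximity
to plaques:

1. local-mean resampling to an isotropic voxel grid (default 0.5 um);
2. background subtraction via an isotropic Gaussian estimate (default
   10 um kernel);
3. strict manual thresholding for the methoxy-X04 and Abeta surfaces;
4. bipartite thresholding of the Iba1 channel — voxels below the low
   threshold are background, above the high threshold are microglia, and
   intermediate voxels are resolved with the random-walker diffusive
   segmentation (diffusion/sharpness parameter beta, default 10);
5. soma seeding: local thickness (2x Euclidean distance to background) is
   computed over the microglial surface; regions at least ``min_soma_diameter``
   thick yield candidate peaks, thinned by greedy non-maximum suppression
   with exclusion radius ``min_soma_spacing``;
6. every surface voxel is assigned to its geodesically nearest peak
   (watershed of the surface on the distance-to-peak landscape);
7. per-cell methoxy-X04 overlap and distance to the nearest plaque voxel.
"""

from __future__ import annotations

import heapq
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from skimage import segmentation

from plaquemap.images import Volume3D

logger = logging.getLogger(__name__)


@dataclass
class Soma3DParams:
    """Parameters of the 3D soma pipeline. All lengths in micrometres."""

    iso_voxel: float = 0.5
    bg_kernel_um: float = 10.0
    methoxy_threshold: float = 0.5
    abeta_threshold: float = 0.5
    iba1_low_threshold: float = 0.2
    iba1_high_threshold: float = 0.6
    rw_diffusion: float = 10.0
    min_soma_diameter_um: float = 7.0
    min_soma_spacing_um: float = 10.0
    proximity_um: float = 10.0
    methoxy_min_voxels: int = 1

    def __post_init__(self) -> None:
        if self.iso_voxel <= 0:
            raise ValueError("iso_voxel must be > 0")
        if not self.iba1_low_threshold < self.iba1_high_threshold:
            raise ValueError("iba1_low_threshold must be < iba1_high_threshold")
        if self.min_soma_spacing_um <= 0:
            raise ValueError("min_soma_spacing_um must be > 0")
        if self.methoxy_min_voxels < 1:
            raise ValueError("methoxy_min_voxels must be >= 1")


@dataclass
class SomaRecord:
    """One reconstructed microglial cell."""

    soma_id: int
    peak_position_um: tuple[float, float, float]  # (z, y, x)
    cell_voxels: int
    cell_volume_um3: float
    methoxy_overlap_voxels: int
    methoxy_positive: bool
    distance_to_nearest_plaque_um: float
    proximal_to_plaque: bool


def _axis_pool_matrix(n_in: int, s_in: float, s_out: float) -> np.ndarray:
    """Box-average matrix mapping ``n_in`` cells of width ``s_in`` onto
    output cells of width ``s_out`` (area-weighted overlap; exact block mean
    for integer pooling factors)."""
    n_out = int(round(n_in * s_in / s_out))
    if n_out < 1:
        raise ValueError("resampling target has no voxels along an axis")
    mat = np.zeros((n_out, n_in))
    for k in range(n_out):
        lo, hi = k * s_out, (k + 1) * s_out
        i0, i1 = int(np.floor(lo / s_in)), int(np.ceil(hi / s_in))
        for i in range(i0, min(i1, n_in)):
            overlap = min(hi, (i + 1) * s_in) - max(lo, i * s_in)
            if overlap > 0:
                mat[k, i] = overlap
        total = mat[k].sum()
        if total > 0:
            mat[k] /= total
    return mat


def resample_isotropic(vol: Volume3D, iso_voxel: float = 0.5) -> Volume3D:
    """Local-mean resampling to an isotropic grid.

    Each output voxel is the (area-weighted) mean of the input voxels it
    covers; for integer pooling factors this is an exact block mean and
    the volume mean is conserved.
    """
    if iso_voxel <= 0:
        raise ValueError("iso_voxel must be > 0")
    if vol.is_isotropic and np.isclose(vol.voxel_size[0], iso_voxel):
        return Volume3D(vol.data.copy(), (iso_voxel,) * 3, channel=vol.channel)
    data = np.asarray(vol.data, dtype=float)
    for axis in range(3):
        mat = _axis_pool_matrix(data.shape[axis], vol.voxel_size[axis], iso_voxel)
        data = np.moveaxis(np.tensordot(mat, np.moveaxis(data, axis, 0), axes=1), 0, axis)
    return Volume3D(data, (iso_voxel,) * 3, channel=vol.channel)


def subtract_background(vol: Volume3D, kernel_um: float = 10.0) -> Volume3D:
    """Subtract a Gaussian background estimate; clip at zero.

    The kernel size is given in micrometres and converted to voxels; the
    input must be isotropic (resample first).
    """
    if not vol.is_isotropic:
        raise ValueError("background subtraction requires an isotropic volume; resample first")
    sigma = kernel_um / vol.voxel_size[0]
    data = np.asarray(vol.data, dtype=float)
    background = ndimage.gaussian_filter(data, sigma=sigma, mode="nearest")
    return Volume3D(np.clip(data - background, 0, None), vol.voxel_size, channel=vol.channel)


def surface_threshold(vol: Volume3D, threshold: float) -> np.ndarray:
    """Binary surface: voxels strictly greater than ``threshold``."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return np.asarray(vol.data) > threshold


def segment_microglia(
    vol: Volume3D, low: float, high: float, rw_diffusion: float = 10.0, mode: str = "cg_j"
) -> np.ndarray:
    """Bipartite threshold plus random-walker labeling of the Iba1 channel.

    Voxels with intensity < ``low`` seed the background class; voxels with
    intensity > ``high`` seed the microglia class; intermediate voxels are
    assigned by the random-walker algorithm (anisotropic-diffusion analogy;
    ``rw_diffusion`` is the edge-weight sharpness parameter beta). Returns a
    binary microglia mask that always contains every voxel > ``high`` and no
    voxel < ``low``.
    """
    if not low < high:
        raise ValueError("low threshold must be < high threshold")
    data = np.asarray(vol.data, dtype=float)
    fg_seed = data > high
    bg_seed = data < low
    if not fg_seed.any():
        warnings.warn("no voxel above the high threshold; returning empty mask", stacklevel=2)
        return np.zeros_like(data, dtype=bool)
    if not bg_seed.any():
        warnings.warn("no voxel below the low threshold; returning full mask", stacklevel=2)
        return np.ones_like(data, dtype=bool)
    undecided = ~(fg_seed | bg_seed)
    if not undecided.any():
        return fg_seed
    labels = np.zeros(data.shape, dtype=np.int32)
    labels[fg_seed] = 1
    labels[bg_seed] = 2
    rw = segmentation.random_walker(data, labels, beta=rw_diffusion, mode=mode)
    mask = rw == 1
    # seed classes are authoritative regardless of solver round-off
    mask |= fg_seed
    mask &= ~bg_seed
    return mask


def local_thickness(mask: np.ndarray, voxel_um: float) -> np.ndarray:
    """Local thickness map: 2x the Euclidean distance to background, in um."""
    return 2.0 * voxel_um * ndimage.distance_transform_edt(np.asarray(mask, dtype=bool))


def detect_somata(
    mask: np.ndarray,
    voxel_um: float,
    min_diameter_um: float = 7.0,
    min_spacing_um: float = 10.0,
) -> list[tuple[int, int, int]]:
    """Find soma peaks by thickness with greedy non-maximum suppression.

    Candidate voxels are those whose local thickness is at least
    ``min_diameter_um``. Candidates are visited in order of decreasing
    thickness (ties broken by lexicographic voxel order) and accepted iff
    they lie at least ``min_spacing_um`` from every previously accepted
    peak. Returns peak voxel coordinates (z, y, x).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    thickness = local_thickness(mask, voxel_um)
    cand = np.argwhere(thickness >= min_diameter_um)
    if cand.size == 0:
        return []
    t = thickness[tuple(cand.T)]
    # sort by descending thickness, then lexicographic (z, y, x)
    order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0], -t))
    cand = cand[order]
    accepted: list[np.ndarray] = []
    spacing_vox = min_spacing_um / voxel_um
    for c in cand:
        if all(np.linalg.norm(c - a) >= spacing_vox for a in accepted):
            accepted.append(c)
    return [tuple(int(v) for v in a) for a in accepted]


def _mask_graph(mask: np.ndarray, voxel_um: float) -> tuple[coo_matrix, np.ndarray]:
    """Sparse 26-connectivity graph over mask voxels with Euclidean edge
    weights in um. Returns (graph, flat-index -> node-id map)."""
    idx = -np.ones(mask.size, dtype=np.int64)
    flat = np.flatnonzero(mask.ravel())
    idx[flat] = np.arange(flat.size)
    coords = np.array(np.unravel_index(flat, mask.shape)).T
    rows, cols, weights = [], [], []
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) > (0, 0, 0)
    ]
    for off in offsets:
        nb = coords + off
        ok = np.all((nb >= 0) & (nb < mask.shape), axis=1)
        nb_flat = np.ravel_multi_index(nb[ok].T, mask.shape)
        nb_id = idx[nb_flat]
        valid = nb_id >= 0
        src = np.arange(flat.size)[ok][valid]
        dst = nb_id[valid]
        w = voxel_um * np.linalg.norm(off)
        rows.append(src)
        cols.append(dst)
        weights.append(np.full(src.size, w))
    graph = coo_matrix(
        (np.concatenate(weights), (np.concatenate(rows), np.concatenate(cols))),
        shape=(flat.size, flat.size),
    )
    return graph + graph.T, idx


def assign_cells(
    mask: np.ndarray, peaks: list[tuple[int, int, int]], voxel_um: float = 1.0
) -> np.ndarray:
    """Partition the microglial surface among soma peaks.

    Each mask voxel receives the 1-based label of its nearest peak, where
    distance is geodesic within the mask (26-connected lattice, Euclidean
    edge lengths) — the watershed of the surface on the distance-to-peak
    landscape. Ties go to the lowest peak id. Voxels unreachable from every
    peak (and all voxels, when no peak is given) stay 0 with a warning.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=np.int32)
    if not mask.any():
        return labels
    if not peaks:
        warnings.warn("no peaks supplied; all mask voxels left unassigned", stacklevel=2)
        return labels
    graph, idx = _mask_graph(mask, voxel_um)
    peak_ids = []
    for p in peaks:
        node = idx[np.ravel_multi_index(p, mask.shape)]
        if node < 0:
            raise ValueError(f"peak {p} lies outside the mask")
        peak_ids.append(node)
    dist = dijkstra(graph, indices=peak_ids, directed=False)
    dmin = dist.min(axis=0)
    # ties (within float tolerance of path-length sums) -> lowest peak id
    nearest = np.argmax(dist <= dmin + 1e-9, axis=0)
    reachable = np.isfinite(dmin)
    flat = np.flatnonzero(mask.ravel())
    out = np.zeros(flat.size, dtype=np.int32)
    out[reachable] = nearest[reachable] + 1
    if not reachable.all():
        warnings.warn(
            f"{int((~reachable).sum())} mask voxels unreachable from any peak; left unassigned",
            stacklevel=2,
        )
    labels.ravel()[flat] = out
    return labels


def geodesic_nearest_peak_bruteforce(
    mask: np.ndarray, peaks: list[tuple[int, int, int]], voxel_um: float = 1.0
) -> np.ndarray:
    """Reference nearest-peak assignment by per-peak heap Dijkstra.

    Pure-Python oracle for :func:`assign_cells`; practical only for small
    volumes.
    """
    mask = np.asarray(mask, dtype=bool)
    shape = mask.shape
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    best = np.full(shape, np.inf)
    labels = np.zeros(shape, dtype=np.int32)
    for pid, start in enumerate(peaks, start=1):
        dist = {tuple(start): 0.0}
        heap = [(0.0, tuple(start))]
        while heap:
            d, node = heapq.heappop(heap)
            if d > dist.get(node, np.inf):
                continue
            for off in offsets:
                nb = (node[0] + off[0], node[1] + off[1], node[2] + off[2])
                if not all(0 <= nb[i] < shape[i] for i in range(3)):
                    continue
                if not mask[nb]:
                    continue
                nd = d + voxel_um * float(np.linalg.norm(off))
                if nd < dist.get(nb, np.inf) - 1e-12:
                    dist[nb] = nd
                    heapq.heappush(heap, (nd, nb))
        for node, d in dist.items():
            if d < best[node] - 1e-9:  # strict improvement; ties keep lower id
                best[node] = d
                labels[node] = pid
    return labels


def classify_cells(
    cells: np.ndarray,
    methoxy: np.ndarray,
    plaques: np.ndarray,
    params: Soma3DParams,
    peaks: list[tuple[int, int, int]] | None = None,
) -> tuple[list[SomaRecord], dict[str, float]]:
    """Per-cell methoxy-X04 content and plaque proximity.

    A cell is methoxy-X04(+) iff it overlaps the methoxy surface in at
    least ``params.methoxy_min_voxels`` voxels (the in-tissue analogue of
    the FACS methoxy gate). Distance to the nearest plaque is measured
    from the cell surface in micrometres; a cell is proximal iff that
    distance is <= ``params.proximity_um``. Returns per-cell records and
    summary fractions (fraction methoxy(+); fraction of methoxy(+) cells
    that are plaque-proximal).
    """
    cells = np.asarray(cells)
    methoxy = np.asarray(methoxy, dtype=bool)
    plaques = np.asarray(plaques, dtype=bool)
    if cells.shape != methoxy.shape or cells.shape != plaques.shape:
        raise ValueError("cells, methoxy and plaque volumes must share one shape")
    voxel_um = params.iso_voxel
    if plaques.any():
        plaque_dist = voxel_um * ndimage.distance_transform_edt(~plaques)
    else:
        plaque_dist = np.full(cells.shape, np.inf)

    records: list[SomaRecord] = []
    ids = np.unique(cells)
    ids = ids[ids > 0]
    for soma_id in ids:
        cell = cells == soma_id
        n_vox = int(cell.sum())
        overlap = int((cell & methoxy).sum())
        dist = float(plaque_dist[cell].min())
        peak = peaks[soma_id - 1] if peaks is not None else tuple(
            int(round(v)) for v in np.argwhere(cell).mean(axis=0)
        )
        records.append(
            SomaRecord(
                soma_id=int(soma_id),
                peak_position_um=tuple(v * voxel_um for v in peak),
                cell_voxels=n_vox,
                cell_volume_um3=n_vox * voxel_um**3,
                methoxy_overlap_voxels=overlap,
                methoxy_positive=overlap >= params.methoxy_min_voxels,
                distance_to_nearest_plaque_um=dist,
                proximal_to_plaque=dist <= params.proximity_um,
            )
        )
    n = len(records)
    n_pos = sum(r.methoxy_positive for r in records)
    n_pos_prox = sum(r.methoxy_positive and r.proximal_to_plaque for r in records)
    summary = {
        "n_cells": float(n),
        "fraction_methoxy_positive": n_pos / n if n else 0.0,
        "fraction_methoxy_positive_proximal": n_pos_prox / n_pos if n_pos else 0.0,
        "proximity_um": params.proximity_um,
    }
    return records, summary


def records_to_frame(records: list[SomaRecord]) -> pd.DataFrame:
    """SomaRecord list as a tidy table."""
    return pd.DataFrame(
        {
            "soma_id": r.soma_id,
            "peak_z_um": r.peak_position_um[0],
            "peak_y_um": r.peak_position_um[1],
            "peak_x_um": r.peak_position_um[2],
            "cell_voxels": r.cell_voxels,
            "cell_volume_um3": r.cell_volume_um3,
            "methoxy_overlap_voxels": r.methoxy_overlap_voxels,
            "methoxy_positive": r.methoxy_positive,
            "distance_to_nearest_plaque_um": r.distance_to_nearest_plaque_um,
            "proximal_to_plaque": r.proximal_to_plaque,
        }
        for r in records
    )


def run_pipeline(
    iba1: Volume3D, methoxy: Volume3D, abeta: Volume3D, params: Soma3DParams
) -> tuple[np.ndarray, list[SomaRecord], dict[str, float]]:
    """End-to-end 3D pipeline on raw channel volumes.

    Resamples each channel isotropically, subtracts background, thresholds
    the methoxy-X04 and Abeta surfaces, segments microglia from Iba1,
    seeds and assigns cells, and classifies them. Returns the cell label
    volume, per-cell records and the summary.
    """
    chans = {}
    for name, vol in (("iba1", iba1), ("methoxy", methoxy), ("abeta", abeta)):
        v = resample_isotropic(vol, params.iso_voxel)
        chans[name] = subtract_background(v, params.bg_kernel_um)
    methoxy_mask = surface_threshold(chans["methoxy"], params.methoxy_threshold)
    plaque_mask = surface_threshold(chans["abeta"], params.abeta_threshold)
    micro_mask = segment_microglia(
        chans["iba1"], params.iba1_low_threshold, params.iba1_high_threshold, params.rw_diffusion
    )
    peaks = detect_somata(
        micro_mask, params.iso_voxel, params.min_soma_diameter_um, params.min_soma_spacing_um
    )
    cells = assign_cells(micro_mask, peaks, params.iso_voxel)
    records, summary = classify_cells(cells, methoxy_mask, plaque_mask, params, peaks=peaks)
    return cells, records, summary
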