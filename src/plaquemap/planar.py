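"""2D section quantification for plaque and microglia immunofluorescence.

Reimplements, as composable functions, the slide-scanner macro used to
quantify Abeta, Iba1, CD68 and AT8 signal in cortical and hippocampal ROIs:
median smoothing and local background subtraction per channel, strict
thresholding into binary masks, exclusion of sub-threshold-size objects as
staining artifacts, Euclidean dilation of plaques into a surrounding region,
and per-ROI percent-positivity and overlap statistics, averaged over
sections per mouse.

Conventions pinned here (and tested):

* a pixel is positive iff its value is strictly greater than the threshold;
* objects with fewer than ``min_object_px`` pixels are removed (an object of
  exactly ``min_object_px`` pixels survives);
* dilation by radius r marks a pixel iff its center lies within Euclidean
  distance r of a positive pixel center; radius 0 is the identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, morphology, restoration

from plaquemap.images import Plane2D

logger = logging.getLogger(__name__)

Connectivity2D = Literal[4, 8]


@dataclass
class PlanarParams:
    """Parameters of the 2D quantification pipeline.

    Attributes
    ----------
    median_radius
        Radius of the median smoothing disk, in pixels. 0 disables smoothing.
    background_method
        ``"rolling_ball"`` (default) or ``"gaussian_highpass"``. The source
        macro's "local background subtraction" operator is not further
        specified; both common choices are exposed.
    background_radius_um
        Spatial scale of the background estimate, in micrometres
        (ball radius, or Gaussian sigma).
    threshold
        Per-channel intensity threshold, or ``"otsu"`` to derive one per
        channel. Positivity is strict (value > threshold).
    min_object_px
        Connected components smaller than this many pixels are removed.
        Default 10: objects of 10+ pixels survive, 9-pixel objects do not.
    dilation_radius_um
        Radius of the ring dilated around each plaque, in micrometres.
    connectivity
        2D object connectivity, 8 (default, diagonal-adjacent pixels touch)
        or 4.
    """

    median_radius: int = 1
    background_method: Literal["rolling_ball", "gaussian_highpass"] = "rolling_ball"
    background_radius_um: float = 50.0
    threshold: float | Literal["otsu"] | Mapping[str, float] = "otsu"
    min_object_px: int = 10
    dilation_radius_um: float = 10.0
    connectivity: Connectivity2D = 8

    def __post_init__(self) -> None:
        if self.min_object_px < 1:
            raise ValueError("min_object_px must be >= 1")
        if self.dilation_radius_um < 0:
            raise ValueError("dilation_radius_um must be >= 0")
        if self.background_radius_um <= 0:
            raise ValueError("background_radius_um must be > 0")
        if self.median_radius < 0:
            raise ValueError("median_radius must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    def resolve_threshold(self, channel: str, img: np.ndarray) -> float:
        """Resolve the binarization threshold for one channel.

        Otsu-derived thresholds are logged so each run records the value it
        actually used.
        """
        thr = self.threshold
        if isinstance(thr, Mapping):
            thr = thr[channel]
        if thr == "otsu":
            thr = float(filters.threshold_otsu(np.asarray(img)))
            logger.info("channel %s: otsu threshold resolved to %g", channel, thr)
        return float(thr)


@dataclass
class QuantRecord2D:
    """Per-section quantification record.

    Percentages are in [0, 100]. ``overlap_flags`` records markers whose
    overlap denominators were empty (no signal / no plaques), for which the
    overlap is reported as 0.
    """

    roi_area_px: int
    roi_area_mm2: float
    positive_area_px: dict[str, int]
    percent_positive: dict[str, float]
    plaque_count: int
    plaque_areas_px: list[int]
    plaque_areas_um2: list[float]
    overlap_marker_in_plaque_region: dict[str, float]
    overlap_plaque_in_marker: dict[str, float]
    masked_mean_intensity: dict[str, float] = field(default_factory=dict)
    dilation_radius_um: float = 0.0
    overlap_flags: list[str] = field(default_factory=list)


def preprocess_channel(img: Plane2D, params: PlanarParams) -> Plane2D:
    """Median-smooth a channel and subtract its local background.

    The median filter uses a disk footprint of ``params.median_radius``
    pixels. The background is estimated at ``params.background_radius_um``
    (converted to pixels via the image's pixel size) with either a rolling
    ball or a Gaussian low-pass, subtracted, and the result clipped at 0.
    """
    data = np.asarray(img.data, dtype=float)
    if params.median_radius > 0:
        footprint = morphology.disk(params.median_radius)
        data = ndimage.median_filter(data, footprint=footprint, mode="nearest")
    radius_px = params.background_radius_um / img.pixel_size
    if params.background_method == "rolling_ball":
        background = restoration.rolling_ball(data, radius=radius_px)
    elif params.background_method == "gaussian_highpass":
        background = ndimage.gaussian_filter(data, sigma=radius_px, mode="nearest")
    else:  # pragma: no cover - guarded by dataclass validation
        raise ValueError(f"unknown background_method {params.background_method!r}")
    out = np.clip(data - background, 0, None)
    return Plane2D(out, pixel_size=img.pixel_size, roi=img.roi)


def binarize(img: Plane2D | np.ndarray, threshold: float | str) -> np.ndarray:
    """Binary mask of pixels strictly greater than ``threshold``.

    ``threshold="otsu"`` derives the threshold from the image histogram.
    """
    data = img.data if isinstance(img, Plane2D) else np.asarray(img)
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold rule {threshold!r}")
        threshold = float(filters.threshold_otsu(data))
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return data > threshold


def filter_small_objects(
    mask: np.ndarray, min_px: int, connectivity: Connectivity2D = 8
) -> np.ndarray:
    """Remove connected components with fewer than ``min_px`` pixels.

    A component of exactly ``min_px`` pixels is kept. Idempotent.
    """
    if min_px < 1:
        raise ValueError("min_px must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    labels, n = label_objects(mask, connectivity)
    if n == 0:
        return mask.copy()
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_px
    keep[0] = False
    return keep[labels]


def dilate_objects(mask: np.ndarray, radius_um: float, pixel_size: float) -> np.ndarray:
    """Euclidean dilation of a binary mask by a physical radius.

    A pixel is positive in the output iff its center lies within
    ``radius_um`` of some positive pixel center of the input. ``radius_um=0``
    returns the mask unchanged.
    """
    if radius_um < 0:
        raise ValueError("radius_um must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if radius_um == 0 or not mask.any():
        return mask.copy()
    radius_px = radius_um / pixel_size
    dist = ndimage.distance_transform_edt(~mask)
    return dist <= radius_px


def label_objects(mask: np.ndarray, connectivity: Connectivity2D = 8):
    """Label connected components; returns (labels, count)."""
    structure = ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)
    return ndimage.label(np.asarray(mask, dtype=bool), structure=structure)


def quantify_roi(
    channel_masks: Mapping[str, np.ndarray],
    plaque_mask: np.ndarray,
    roi: np.ndarray,
    params: PlanarParams,
    pixel_size: float,
    channel_images: Mapping[str, np.ndarray] | None = None,
) -> QuantRecord2D:
    """Compute per-ROI marker statistics for one section.

    All statistics are restricted to ``roi``. Percent positivity normalizes
    each marker's positive pixel area to the ROI area. Plaques are counted
    and measured after small-object filtering; the overlap of each marker
    with the dilated plaque region (plaques plus a surrounding ring of
    ``params.dilation_radius_um``) and the reverse overlap of plaques with
    each marker are reported as percentages. Overlaps with an empty
    denominator are reported as 0 and flagged in ``overlap_flags``.

    ``channel_images`` optionally supplies the preprocessed intensity images
    so a masked mean intensity can be reported per marker (used for e.g.
    astrocyte marker intensity within a cell mask).
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("ROI is empty")
    plaque_mask = np.asarray(plaque_mask, dtype=bool)
    if plaque_mask.shape != roi.shape:
        raise ValueError("plaque mask shape must match ROI shape")
    for name, m in channel_masks.items():
        if np.asarray(m).shape != roi.shape:
            raise ValueError(f"channel {name!r} mask shape must match ROI shape")

    roi_area = int(roi.sum())
    roi_area_mm2 = roi_area * (pixel_size * 1e-3) ** 2

    plaque_in_roi = plaque_mask & roi
    labels, _ = label_objects(plaque_in_roi, params.connectivity)
    counts = np.bincount(labels.ravel())[1:]  # drop background
    plaque_areas_px = sorted(int(c) for c in counts)
    plaque_count = len(plaque_areas_px)
    plaque_region = dilate_objects(plaque_in_roi, params.dilation_radius_um, pixel_size) & roi

    positive_area: dict[str, int] = {}
    percent_positive: dict[str, float] = {}
    overlap_in_region: dict[str, float] = {}
    overlap_plaque: dict[str, float] = {}
    masked_mean: dict[str, float] = {}
    flags: list[str] = []
    plaque_area_total = int(plaque_in_roi.sum())
    for name, m in channel_masks.items():
        m = np.asarray(m, dtype=bool) & roi
        area = int(m.sum())
        positive_area[name] = area
        percent_positive[name] = 100.0 * area / roi_area
        if area > 0:
            overlap_in_region[name] = 100.0 * int((m & plaque_region).sum()) / area
        else:
            overlap_in_region[name] = 0.0
            flags.append(f"{name}: no marker signal in ROI")
        if plaque_area_total > 0:
            overlap_plaque[name] = 100.0 * int((plaque_in_roi & m).sum()) / plaque_area_total
        else:
            overlap_plaque[name] = 0.0
            flags.append(f"{name}: no plaques in ROI")
        if channel_images is not None and name in channel_images:
            img = np.asarray(channel_images[name], dtype=float)
            masked_mean[name] = float(img[m].mean()) if area > 0 else 0.0
    if flags:
        logger.info("empty overlap denominators: %s", "; ".join(flags))

    um2 = pixel_size**2
    return QuantRecord2D(
        roi_area_px=roi_area,
        roi_area_mm2=roi_area_mm2,
        positive_area_px=positive_area,
        percent_positive=percent_positive,
        plaque_count=plaque_count,
        plaque_areas_px=plaque_areas_px,
        plaque_areas_um2=[a * um2 for a in plaque_areas_px],
        overlap_marker_in_plaque_region=overlap_in_region,
        overlap_plaque_in_marker=overlap_plaque,
        masked_mean_intensity=masked_mean,
        dilation_radius_um=params.dilation_radius_um,
        overlap_flags=flags,
    )


def quantify_section(
    channels: Mapping[str, Plane2D],
    plaque_channel: str,
    roi: np.ndarray,
    params: PlanarParams,
) -> QuantRecord2D:
    """Full single-section pipeline: preprocess, binarize, filter, quantify.

    ``channels`` maps marker names to raw single-channel planes sharing one
    pixel size; ``plaque_channel`` names the amyloid channel used for plaque
    objects and dilation rings.
    """
    if plaque_channel not in channels:
        raise KeyError(f"plaque channel {plaque_channel!r} not among channels")
    pixel_sizes = {c.pixel_size for c in channels.values()}
    if len(pixel_sizes) != 1:
        raise ValueError("all channels must share one pixel size")
    pixel_size = pixel_sizes.pop()

    masks: dict[str, np.ndarray] = {}
    images: dict[str, np.ndarray] = {}
    for name, plane in channels.items():
        pre = preprocess_channel(plane, params)
        thr = params.resolve_threshold(name, pre.data)
        mask = binarize(pre, thr)
        masks[name] = filter_small_objects(mask, params.min_object_px, params.connectivity)
        images[name] = pre.data
    return quantify_roi(
        masks, masks[plaque_channel], roi, params, pixel_size, channel_images=images
    )


def records_to_frame(records: list[QuantRecord2D]) -> pd.DataFrame:
    """Flatten per-section records into a table (one row per section)."""
    rows = []
    for i, r in enumerate(records):
        row: dict[str, float] = {
            "section": i,
            "roi_area_px": r.roi_area_px,
            "roi_area_mm2": r.roi_area_mm2,
            "plaque_count": r.plaque_count,
            "plaque_area_total_px": sum(r.plaque_areas_px),
            "plaque_area_total_um2": sum(r.plaque_areas_um2),
        }
        for name, v in r.percent_positive.items():
            row[f"percent_positive_{name}"] = v
        for name, v in r.overlap_marker_in_plaque_region.items():
            row[f"overlap_{name}_in_plaque_region"] = v
        for name, v in r.overlap_plaque_in_marker.items():
            row[f"overlap_plaque_in_{name}"] = v
        for name, v in r.masked_mean_intensity.items():
            row[f"mean_intensity_{name}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_mouse(records: list[QuantRecord2D]) -> tuple[pd.Series, pd.DataFrame]:
    """Average per-section metrics into a per-mouse summary.

    Each percentage and count metric is the unweighted arithmetic mean over
    sections (sections per mouse are typically 7-12). Returns the summary
    series and the per-section table it was computed from.
    """
    if not records:
        raise ValueError("need at least one section record")
    table = records_to_frame(records)
    summary = table.drop(columns="section").mean()
    return summary, table
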