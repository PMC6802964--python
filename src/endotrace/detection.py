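"""Endocytic-site detection by temporal standard-deviation projection.

Candidate sites are pixels whose intensity fluctuates strongly over the
movie: a per-pixel standard-deviation z-projection turns transient
accumulation/disassembly events into bright spots, which are picked as
robust-thresholded local maxima. Each detection defines a 5x5-pixel
measurement core (0.5 um at 0.1 um/pixel) and a surrounding 1.5-um
diameter background region that excludes the core.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import peak_local_max

from endotrace.containers import Movie

CORE_HALF_WIDTH = 2  # 5x5-pixel measurement core
BACKGROUND_DIAMETER_UM = 1.5


@dataclass
class EventROI:
    """Measurement geometry around one candidate endocytic site.

    ``center`` is (row, col) in 0-based pixel indices, centre-of-pixel
    convention. Quality flags: ``overlap-contaminated`` when another
    detection falls inside this ROI's background region, ``edge-clipped``
    when the background region extends beyond the frame.
    """

    center: tuple[int, int]
    core_half_width: int = CORE_HALF_WIDTH
    background_diameter_um: float = BACKGROUND_DIAMETER_UM
    flags: set = field(default_factory=set)

    @property
    def overlap_contaminated(self) -> bool:
        return "overlap-contaminated" in self.flags

    @property
    def edge_clipped(self) -> bool:
        return "edge-clipped" in self.flags


def std_projection(movie: Movie) -> np.ndarray:
    """Per-pixel temporal standard deviation of the whole movie.

    Uses the sample standard deviation (ddof=1). Invariant to frame
    order; a constant movie projects to zero everywhere.
    """
    if movie.n_frames < 2:
        raise ValueError("std_projection requires at least 2 frames")
    return movie.frames.std(axis=0, ddof=1)


def _mad(values: np.ndarray) -> float:
    med = np.median(values)
    return float(np.median(np.abs(values - med)))


def detect_event_sites(
    projection: np.ndarray,
    pixel_size: float,
    threshold_mads: float = 6.0,
    min_separation_um: float = 1.0,
) -> list[EventROI]:
    """Detect candidate endocytic sites in a standard-deviation projection.

    Local maxima above ``median + threshold_mads * MAD`` of the
    projection are retained, non-maximum-suppressed at
    ``min_separation_um``, and wrapped in :class:`EventROI` objects.
    ROIs whose background region contains another detection are flagged
    ``overlap-contaminated``; ROIs whose background circle leaves the
    frame are flagged ``edge-clipped``. An empty list is a valid result.
    """
    projection = np.asarray(projection, dtype=float)
    if not np.all(np.isfinite(projection)):
        raise ValueError("projection contains non-finite values")
    threshold = np.median(projection) + threshold_mads * _mad(projection)
    min_dist_px = max(1, int(round(min_separation_um / pixel_size)))
    peaks = peak_local_max(
        projection, min_distance=min_dist_px, threshold_abs=threshold, exclude_border=False
    )
    rois = [EventROI(center=(int(r), int(c))) for r, c in peaks]

    # Two sites closer than the background diameter have overlapping
    # background regions (and each other's light in them): both are
    # contaminated.
    bg_radius_px = BACKGROUND_DIAMETER_UM / 2.0 / pixel_size
    for i, a in enumerate(rois):
        for j, b in enumerate(rois):
            if i == j:
                continue
            d = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
            if d <= 2.0 * bg_radius_px:
                a.flags.add("overlap-contaminated")
        r, c = a.center
        ny, nx = projection.shape
        if (
            r - bg_radius_px < -0.5
            or c - bg_radius_px < -0.5
            or r + bg_radius_px > ny - 0.5
            or c + bg_radius_px > nx - 0.5
        ):
            a.flags.add("edge-clipped")
    return rois


def roi_masks(roi: EventROI, shape: tuple[int, int], pixel_size: float) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (core, background) pixel masks for an ROI.

    The core is the (2h+1) x (2h+1) square around the centre; the
    background region is the circle of ``background_diameter_um`` around
    the centre minus the core pixels. Both are clipped to the frame.
    """
    ny, nx = shape
    r0, c0 = roi.center
    core = np.zeros(shape, dtype=bool)
    h = roi.core_half_width
    core[max(0, r0 - h) : min(ny, r0 + h + 1), max(0, c0 - h) : min(nx, c0 + h + 1)] = True
    rr, cc = np.ogrid[:ny, :nx]
    radius_px = roi.background_diameter_um / 2.0 / pixel_size
    circle = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius_px**2
    background = circle & ~core
    return core, background


def extract_roi_trace(movie: Movie, roi: EventROI) -> tuple[np.ndarray, np.ndarray]:
    """Raw core and background traces of one ROI.

    Returns per-frame ``(core_sum, background_mean)``: the summed
    intensity over the 5x5 core and the mean intensity per pixel over the
    background region. If the core is clipped by the frame edge the ROI
    is flagged and the sum runs over the available pixels; an ROI with an
    empty background region is uncorrectable and rejected.
    """
    r0, c0 = roi.center
    ny, nx = movie.shape
    if not (0 <= r0 < ny and 0 <= c0 < nx):
        raise ValueError("ROI centre outside frame bounds")
    h = roi.core_half_width
    if r0 - h < 0 or c0 - h < 0 or r0 + h >= ny or c0 + h >= nx:
        roi.flags.add("edge-clipped")
    core, background = roi_masks(roi, (ny, nx), movie.pixel_size)
    if not background.any():
        raise ValueError("ROI background region is fully clipped; trace is uncorrectable")
    core_trace = movie.frames[:, core].sum(axis=1)
    background_trace = movie.frames[:, background].mean(axis=1)
    return core_trace, background_trace
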