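"""Gray-standard detection and pixel-to-physical scale calibration.

Photographs carry a circular achromatic reflectance standard of known
physical diameter.  Candidate circles come from a Circle Hough Transform on
an edge map; candidates are then screened for achromaticity (a color-checker
chart in frame also produces strong circular edges, but its patches are
chromatic) and ranked by accumulator score.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage import feature as skfeature
from skimage import transform as sktransform

from . import roi_io


class StandardNotFoundError(RuntimeError):
    """No acceptable gray-circle candidate; carries per-candidate diagnostics."""

    def __init__(self, message: str, candidates: list[dict] | None = None):
        super().__init__(message)
        self.candidates = candidates or []


@dataclass(frozen=True)
class CircleDetection:
    center: tuple[float, float]  # (x, y) px
    radius: float
    achromaticity: float  # mean absolute inter-channel difference inside the disk
    uniformity: float  # intensity SD inside the disk (lower = more uniform)
    accumulator: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass(frozen=True)
class ScaleCalibration:
    px_per_mm: float
    source: CircleDetection

    def __post_init__(self) -> None:
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be positive")


def _disk_stats(image: np.ndarray, cx: float, cy: float, r: float) -> tuple[float, float]:
    """(achromaticity, uniformity) over the disk interior, rim excluded."""
    h, w = image.shape[:2]
    rr = max(r - 2.0, 1.0)
    y0, y1 = max(int(cy - rr), 0), min(int(cy + rr + 2), h)
    x0, x1 = max(int(cx - rr), 0), min(int(cx + rr + 2), w)
    if y0 >= y1 or x0 >= x1:
        return 1.0, 1.0
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (xx + 0.5 - cx) ** 2 + (yy + 0.5 - cy) ** 2 <= rr**2
    if not inside.any():
        return 1.0, 1.0
    px = image[y0:y1, x0:x1][inside]  # (n, 3)
    achro = float(
        np.mean(
            (np.abs(px[:, 0] - px[:, 1]) + np.abs(px[:, 0] - px[:, 2]) + np.abs(px[:, 1] - px[:, 2]))
            / 3.0
        )
    )
    uniform = float(px.mean(axis=1).std())
    return achro, uniform


def detect_gray_standard(
    image: np.ndarray,
    radius_range_px: tuple[int, int],
    achromaticity_max: float = 0.08,
    uniformity_max: float = 0.08,
    n_candidates: int = 30,
    canny_sigma: float = 2.0,
) -> CircleDetection:
    """Find the circular gray standard in an RGB image.

    Circle Hough Transform candidates are screened lexicographically: first
    achromaticity and uniformity below threshold, then the highest Hough
    accumulator score wins.
    """
    rmin, rmax = int(radius_range_px[0]), int(radius_range_px[1])
    if rmin <= 0 or rmax < rmin:
        raise ValueError("radius_range_px must be positive and ordered")
    image = np.asarray(image, dtype=float)
    # per-channel edges: an achromatic disk on a colored mat may contrast
    # strongly in one channel while vanishing in the luminance mean
    edges = np.zeros(image.shape[:2], dtype=bool)
    for c in range(image.shape[-1]):
        edges |= skfeature.canny(image[..., c], sigma=canny_sigma)
    radii = np.arange(rmin, rmax + 1)
    hough = sktransform.hough_circle(edges, radii)
    accums, cxs, cys, rads = sktransform.hough_circle_peaks(
        hough, radii, total_num_peaks=n_candidates
    )
    diagnostics: list[dict] = []
    best: CircleDetection | None = None
    for acc, cx, cy, r in zip(accums, cxs, cys, rads):
        achro, uniform = _disk_stats(image, float(cx), float(cy), float(r))
        diagnostics.append(
            {"center": (float(cx), float(cy)), "radius": float(r),
             "accumulator": float(acc), "achromaticity": achro, "uniformity": uniform}
        )
        if achro > achromaticity_max or uniform > uniformity_max:
            continue
        det = CircleDetection(
            center=(float(cx), float(cy)), radius=float(r),
            achromaticity=achro, uniformity=uniform, accumulator=float(acc),
        )
        if best is None or det.accumulator > best.accumulator:
            best = det
    if best is None:
        raise StandardNotFoundError(
            f"no achromatic uniform circle found in radius range [{rmin}, {rmax}]",
            candidates=diagnostics,
        )
    return best


def calibrate_scale(det: CircleDetection, standard_diameter_mm: float) -> ScaleCalibration:
    """Pixel-per-millimetre scale from the detected standard.

    px_per_mm = 2 * radius_px / diameter_mm.  The physical diameter is a
    required configuration value (it depends on the standard in use).
    """
    if standard_diameter_mm <= 0:
        raise ValueError("standard_diameter_mm must be positive")
    return ScaleCalibration(
        px_per_mm=2.0 * det.radius / standard_diameter_mm, source=det
    )


def standard_polygon(det: CircleDetection, n_vertices: int = 64) -> roi_io.PolygonROI:
    """Regular-polygon approximation of the detected standard disk."""
    th = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    cx, cy = det.center
    return roi_io.PolygonROI(
        vertices=tuple(
            (float(cx + det.radius * np.cos(t)), float(cy + det.radius * np.sin(t)))
            for t in th
        ),
        region_class="gray_standard",
    )


def export_combined_rois(
    specimen_mask: np.ndarray,
    det: CircleDetection,
    image_id: str,
    path: str | Path,
) -> roi_io.LabelFile:
    """Write specimen polygons plus the standard into one label JSON file."""
    h, w = specimen_mask.shape
    rois = roi_io.mask_to_polygons(specimen_mask, region_class="specimen")
    rois.append(standard_polygon(det))
    label = roi_io.LabelFile(image_id=image_id, height=h, width=w, rois=rois)
    roi_io.write_labels(label, path)
    return label
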