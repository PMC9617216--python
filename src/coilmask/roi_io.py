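"""Landmark/ROI formats and polygon <-> raster mask conversion.

Coordinate convention used throughout the package: x = column, y = row,
origin at the top-left corner, 0-based, with the center of pixel ``(r, c)``
at ``(x, y) = (c + 0.5, r + 0.5)``.  TPS files written by landmarking tools
that use a bottom-left origin can be flipped at read time.

Masks are boolean rasters with 1 = specimen, 0 = background.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

LABEL_SCHEMA_VERSION = 1


class TPSParseError(ValueError):
    """Raised for structurally invalid TPS records."""


class LabelSchemaError(ValueError):
    """Raised when a label JSON file does not match the documented schema."""


@dataclass(frozen=True)
class PolygonROI:
    """A closed polygon outline naming a region class.

    ``vertices`` are continuous (x, y) image coordinates in pixels; the
    polygon is implicitly closed (last vertex connects back to the first).
    """

    vertices: tuple[tuple[float, float], ...]
    region_class: str = "specimen"

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError("a polygon needs at least 3 vertices")
        arr = np.asarray(self.vertices, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("polygon coordinates must be finite")
        object.__setattr__(
            self, "vertices", tuple((float(x), float(y)) for x, y in self.vertices)
        )


@dataclass
class LandmarkChain:
    """One LM record from a TPS file: an ordered open chain of landmarks."""

    points: list[tuple[float, float]]
    image: str | None = None
    record_id: str | None = None


@dataclass
class LabelFile:
    """Polygon ROIs for one photograph, serializable to JSON."""

    image_id: str
    height: int
    width: int
    rois: list[PolygonROI] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("image_size must be positive")


def read_tps(
    stream: IO[str] | str,
    origin: str = "top-left",
    image_height: float | None = None,
) -> list[LandmarkChain]:
    """Parse a TPS landmark file into chains of (x, y) coordinates.

    Each record starts with ``LM=n`` followed by n whitespace-separated
    coordinate lines; ``IMAGE=`` and ``ID=`` lines attach metadata to the
    preceding record.  With ``origin="bottom-left"`` the y coordinate is
    flipped to the package's top-left convention, which requires
    ``image_height``.  An ``LM=0`` record is tolerated (empty chain) but
    flagged with a warning.
    """
    if origin not in ("top-left", "bottom-left"):
        raise ValueError(f"unknown tps_origin {origin!r}")
    if origin == "bottom-left" and image_height is None:
        raise ValueError("bottom-left origin requires image_height")
    text = stream if isinstance(stream, str) else stream.read()

    chains: list[LandmarkChain] = []
    lines = [ln.strip() for ln in text.splitlines()]
    i = 0
    record_no = 0
    while i < len(lines):
        line = lines[i]
        if not line:
            i += 1
            continue
        upper = line.upper()
        if upper.startswith("LM="):
            record_no += 1
            try:
                n = int(line.split("=", 1)[1])
            except ValueError as exc:
                raise TPSParseError(f"record {record_no}: bad LM count {line!r}") from exc
            pts: list[tuple[float, float]] = []
            i += 1
            while len(pts) < n and i < len(lines):
                ln = lines[i]
                if not ln:
                    i += 1
                    continue
                if "=" in ln and not ln[0].isdigit() and not ln[0] in "+-.":
                    break  # hit a keyword line before enough coordinates
                parts = ln.split()
                if len(parts) < 2:
                    raise TPSParseError(
                        f"record {record_no}: bad coordinate line {ln!r}"
                    )
                pts.append((float(parts[0]), float(parts[1])))
                i += 1
            if len(pts) < n:
                raise TPSParseError(
                    f"record {record_no}: LM={n} but only {len(pts)} coordinate lines"
                )
            if n == 0:
                warnings.warn(f"TPS record {record_no} has LM=0 (empty chain)")
            chains.append(LandmarkChain(points=pts))
        elif upper.startswith("IMAGE="):
            if chains:
                chains[-1].image = line.split("=", 1)[1].strip()
            i += 1
        elif upper.startswith("ID="):
            if chains:
                chains[-1].record_id = line.split("=", 1)[1].strip()
            i += 1
        else:
            i += 1  # SCALE= and other keywords ignored
    if origin == "bottom-left":
        for ch in chains:
            ch.points = [(x, float(image_height) - y) for x, y in ch.points]
    return chains


def write_tps(chains: Sequence[LandmarkChain]) -> str:
    """Serialize chains back to TPS text (coordinates to 6 significant digits)."""
    out: list[str] = []
    for ch in chains:
        out.append(f"LM={len(ch.points)}")
        for x, y in ch.points:
            out.append(f"{x:.6g} {y:.6g}")
        if ch.image is not None:
            out.append(f"IMAGE={ch.image}")
        if ch.record_id is not None:
            out.append(f"ID={ch.record_id}")
    return "\n".join(out) + "\n"


def _segments_intersect(p1, p2, p3, p4) -> bool:
    def orient(a, b, c):
        v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        return 0 if abs(v) < 1e-12 else (1 if v > 0 else -1)

    o1, o2 = orient(p1, p2, p3), orient(p1, p2, p4)
    o3, o4 = orient(p3, p4, p1), orient(p3, p4, p2)
    return o1 != o2 and o3 != o4


def polygon_self_intersects(vertices: Sequence[tuple[float, float]]) -> bool:
    """Check whether any two non-adjacent edges of the closed polygon cross."""
    n = len(vertices)
    edges = [(vertices[i], vertices[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if j == i or (j + 1) % n == i or (i + 1) % n == j:
                continue
            if _segments_intersect(*edges[i], *edges[j]):
                return True
    return False


def chains_to_polygon(
    chains: Sequence[LandmarkChain | Sequence[tuple[float, float]]],
    reverse_second: bool = True,
    region_class: str = "specimen",
) -> PolygonROI:
    """Join 1 or 2 landmark chains into one closed polygon.

    Two chains landmarked down each side of a body travel in the same
    direction, so the second chain is appended reversed by default — the
    outline then runs down one side and back up the other.  A resulting
    self-intersecting polygon triggers a warning, not an error.
    """
    pts_lists = [
        list(c.points) if isinstance(c, LandmarkChain) else [tuple(p) for p in c]
        for c in chains
    ]
    if len(pts_lists) == 0 or len(pts_lists) > 2:
        raise ValueError(f"expected 1 or 2 chains, got {len(pts_lists)} (ambiguous)")
    vertices = list(pts_lists[0])
    if len(pts_lists) == 2:
        second = pts_lists[1][::-1] if reverse_second else pts_lists[1]
        vertices.extend(second)
    poly = PolygonROI(vertices=tuple(vertices), region_class=region_class)
    if polygon_self_intersects(poly.vertices):
        warnings.warn("joined polygon is self-intersecting")
    return poly


def _clamp_vertices(vertices: np.ndarray, image_size: tuple[int, int]) -> np.ndarray:
    h, w = image_size
    out = vertices.copy()
    out[:, 0] = np.clip(out[:, 0], 0.0, float(w))
    out[:, 1] = np.clip(out[:, 1], 0.0, float(h))
    return out


def rasterize(roi: PolygonROI, image_size: tuple[int, int]) -> np.ndarray:
    """Rasterize a polygon to a boolean mask by the even-odd pixel-center rule.

    Pixel ``(r, c)`` is foreground iff its center ``(c+0.5, r+0.5)`` lies
    inside the polygon under the even-odd (crossing-number) rule.  Vertices
    outside the image are clamped to the image boundary first.  A degenerate
    zero-area polygon yields an empty mask with a warning.
    """
    h, w = int(image_size[0]), int(image_size[1])
    if h <= 0 or w <= 0:
        raise ValueError("image_size must be positive")
    verts = _clamp_vertices(np.asarray(roi.vertices, dtype=float), (h, w))

    # shoelace area to detect degeneracy
    x, y = verts[:, 0], verts[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    if area == 0.0:
        warnings.warn("zero-area polygon rasterizes to an empty mask")
        return np.zeros((h, w), dtype=bool)

    cx = np.arange(w, dtype=float) + 0.5
    cy = np.arange(h, dtype=float) + 0.5
    px, py = np.meshgrid(cx, cy)  # (h, w)
    inside = np.zeros((h, w), dtype=bool)
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        crosses = (y1 > py) != (y2 > py)
        if not crosses.any():
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (px < xint)
    return inside


def mask_to_polygons(
    mask: np.ndarray, simplify_tolerance: float = 0.05, region_class: str = "specimen"
) -> list[PolygonROI]:
    """Trace one boundary polygon per 8-connected foreground component.

    Rasterizing the returned polygons reproduces the input mask up to
    boundary pixels (interior pixels are exact).  Holes inside a component
    are filled: each component is represented by its single outer contour.
    An empty mask yields an empty list.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    polys: list[PolygonROI] = []
    for lab in range(1, n + 1):
        comp = labels == lab
        padded = np.pad(comp.astype(float), 1)
        contours = measure.find_contours(padded, 0.5, fully_connected="high")
        if not contours:
            continue
        contour = max(contours, key=len)  # outer boundary is the longest
        if simplify_tolerance > 0:
            contour = measure.approximate_polygon(contour, simplify_tolerance)
        # find_contours indexes the padded array; pixel (r, c) center is (c+0.5, r+0.5)
        ys = contour[:, 0] - 1.0 + 0.5
        xs = contour[:, 1] - 1.0 + 0.5
        if len(xs) >= 2 and xs[0] == xs[-1] and ys[0] == ys[-1]:
            xs, ys = xs[:-1], ys[:-1]
        if len(xs) < 3:
            continue
        polys.append(
            PolygonROI(
                vertices=tuple(zip(map(float, xs), map(float, ys))),
                region_class=region_class,
            )
        )
    return polys


def write_labels(labels: LabelFile, path: str | Path) -> None:
    """Write a LabelFile as schema-version-1 JSON (lossless round trip)."""
    doc = {
        "schema_version": LABEL_SCHEMA_VERSION,
        "image_id": labels.image_id,
        "height": int(labels.height),
        "width": int(labels.width),
        "rois": [
            {"class": r.region_class, "vertices": [[x, y] for x, y in r.vertices]}
            for r in labels.rois
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_labels(path: str | Path) -> LabelFile:
    """Read a schema-version-1 label JSON file."""
    doc = json.loads(Path(path).read_text())
    if not isinstance(doc, dict) or "schema_version" not in doc:
        raise LabelSchemaError(f"{path}: not a label file (no schema_version)")
    if doc["schema_version"] != LABEL_SCHEMA_VERSION:
        raise LabelSchemaError(
            f"{path}: unknown schema version {doc['schema_version']!r}"
        )
    for key in ("image_id", "height", "width", "rois"):
        if key not in doc:
            raise LabelSchemaError(f"{path}: missing required key {key!r}")
    rois = [
        PolygonROI(
            vertices=tuple((float(x), float(y)) for x, y in r["vertices"]),
            region_class=r["class"],
        )
        for r in doc["rois"]
    ]
    return LabelFile(
        image_id=doc["image_id"], height=doc["height"], width=doc["width"], rois=rois
    )


def labels_to_mask(labels: LabelFile, region_class: str | None = "specimen") -> np.ndarray:
    """Union-rasterize all ROIs of a class (or all classes if None) to one mask."""
    mask = np.zeros((labels.height, labels.width), dtype=bool)
    for roi in labels.rois:
        if region_class is None or roi.region_class == region_class:
            mask |= rasterize(roi, (labels.height, labels.width))
    return mask
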