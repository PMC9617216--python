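"""Ground-truthed synthetic photographs of coiled specimens.

Emulates field photography of limbless, elongate organisms coiled on a
uniform PVC mat: an Archimedean-spiral body swept by a tapering thickness
profile, banded/blotched/plain coloration drawn relative to the body
centerline, a circular achromatic gray standard for size calibration, a
multiplicative lighting gradient, and sensor noise.  Every scene carries its
exact specimen mask and the standard-circle truth, so every pipeline stage is
testable without external photographs.

What this generator does NOT emulate: scale texture, specular highlights,
cast shadows, and out-of-plane anatomy; see the methods note for what that
implies about tests passing here versus on real photographs.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage import color as skcolor

from . import roi_io
from ._util import derive_seed, write_image_png, write_mask_png


class SceneSpecError(ValueError):
    """Raised when a SceneSpec violates its invariants."""


@dataclass
class CoilSpec:
    turns: float = 1.8
    direction: str = "ccw"  # cw | ccw
    center: tuple[float, float] = (128.0, 128.0)  # (x, y) px
    spacing: float = 34.0  # radial gap between successive coils, px


@dataclass
class BodySpec:
    thickness_head: float = 14.0  # body diameter at the head, px
    taper: float = 0.35  # tail thickness as a fraction of head thickness
    base_color: tuple[float, float, float] = (0.45, 0.3, 0.12)
    pattern: str = "bands"  # bands | blotches | plain
    pattern_period: float = 24.0  # along-body period, px
    pattern_color: tuple[float, float, float] = (0.1, 0.07, 0.05)


@dataclass
class BackgroundSpec:
    color: tuple[float, float, float] = (0.07, 0.18, 0.55)  # blue-ish mat
    texture_sd: float = 0.01


@dataclass
class StandardSpec:
    center: tuple[float, float] = (220.0, 30.0)  # (x, y) px
    radius: float = 16.0
    gray: float = 0.4  # 40% reflectance standard


@dataclass
class LightingSpec:
    gradient_amplitude: float = 0.08  # peak-to-center multiplicative swing
    direction_deg: float = 30.0


@dataclass
class SceneSpec:
    image_size: tuple[int, int] = (256, 256)  # (height, width)
    coil: CoilSpec = field(default_factory=CoilSpec)
    body: BodySpec = field(default_factory=BodySpec)
    background: BackgroundSpec = field(default_factory=BackgroundSpec)
    standard: StandardSpec = field(default_factory=StandardSpec)
    lighting: LightingSpec = field(default_factory=LightingSpec)
    noise_sd: float = 0.008
    seed: int = 0


def _spiral_centerline(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """Arc-length-uniform samples of the spiral centerline and their arc positions.

    r(theta) = a + b*theta with b = spacing / (2*pi); direction flips the sign
    of the y component.  Returns (points (n,2) as (x,y), arclength (n,)).
    """
    c = spec.coil
    if c.turns < 0.5:
        raise SceneSpecError("coil.turns must be >= 0.5")
    if c.direction not in ("cw", "ccw"):
        raise SceneSpecError(f"coil.direction must be cw|ccw, got {c.direction!r}")
    b = c.spacing / (2.0 * np.pi)
    a = max(spec.body.thickness_head, 2.0)  # inner radius clears the center
    theta_max = 2.0 * np.pi * c.turns
    # dense parameter sampling, then resample uniformly by arc length
    theta = np.linspace(0.0, theta_max, max(int(theta_max * (a + b * theta_max)), 64))
    r = a + b * theta
    sgn = 1.0 if c.direction == "ccw" else -1.0
    pts = np.stack([c.center[0] + r * np.cos(theta), c.center[1] + sgn * r * np.sin(theta)], 1)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    s_uniform = np.arange(0.0, total, 0.5)  # 0.5 px spacing along the body
    x = np.interp(s_uniform, s, pts[:, 0])
    y = np.interp(s_uniform, s, pts[:, 1])
    return np.stack([x, y], 1), s_uniform


def _sweep_body(
    spec: SceneSpec, points: np.ndarray, arclen: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Paint the swept body region.

    Returns (mask, arc position of the nearest centerline sample per pixel,
    squared distance to it).  The mask is the union of disks of the local
    thickness radius centered on the arc-length-uniform centerline samples;
    a z-buffer over squared distance makes per-pixel arc position well
    defined, so patterns can be drawn perpendicular to the centerline.
    """
    h, w = spec.image_size
    total = arclen[-1] if len(arclen) else 0.0
    thick = spec.body.thickness_head * (
        1.0 - (1.0 - spec.body.taper) * (arclen / max(total, 1e-9))
    )
    radius = thick / 2.0
    best_d2 = np.full((h, w), np.inf)
    arc_pos = np.zeros((h, w))
    mask = np.zeros((h, w), dtype=bool)
    cx = np.arange(w) + 0.5
    cy = np.arange(h) + 0.5
    for (px, py), s_i, rad in zip(points, arclen, radius):
        if rad <= 0:
            continue
        x0 = max(int(px - rad - 1), 0)
        x1 = min(int(px + rad + 2), w)
        y0 = max(int(py - rad - 1), 0)
        y1 = min(int(py + rad + 2), h)
        if x0 >= x1 or y0 >= y1:
            continue
        dx = cx[x0:x1] - px
        dy = cy[y0:y1] - py
        d2 = dy[:, None] ** 2 + dx[None, :] ** 2
        local_best = best_d2[y0:y1, x0:x1]
        closer = d2 < local_best
        local_best[closer] = d2[closer]
        arc_pos[y0:y1, x0:x1][closer] = s_i
        mask[y0:y1, x0:x1] |= d2 <= rad**2
    return mask, arc_pos, best_d2


def _validate(spec: SceneSpec, points: np.ndarray, radius_max: float) -> None:
    h, w = spec.image_size
    if h <= 0 or w <= 0:
        raise SceneSpecError("image_size must be positive")
    for name, col in (
        ("body.base_color", spec.body.base_color),
        ("body.pattern_color", spec.body.pattern_color),
        ("background.color", spec.background.color),
    ):
        if not all(0.0 <= v <= 1.0 for v in col):
            raise SceneSpecError(f"{name} values must be in [0, 1]")
    if not 0.0 <= spec.standard.gray <= 1.0:
        raise SceneSpecError("standard.gray must be in [0, 1]")
    if spec.standard.radius <= 0:
        raise SceneSpecError("standard.radius must be positive")
    lo = points.min(0) - radius_max
    hi = points.max(0) + radius_max
    if lo[0] < 0 or lo[1] < 0 or hi[0] > w or hi[1] > h:
        raise SceneSpecError("body does not fit in frame")
    sx, sy = spec.standard.center
    r = spec.standard.radius
    if sx - r < 0 or sy - r < 0 or sx + r > w or sy + r > h:
        raise SceneSpecError("standard does not fit in frame")
    d = np.hypot(points[:, 0] - sx, points[:, 1] - sy).min() if len(points) else np.inf
    if d < r + radius_max + 2.0:
        raise SceneSpecError("standard overlaps body")


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray, dict]:
    """Render one scene: float RGB image in [0,1], exact specimen mask, metadata.

    Deterministic per spec (including its seed).  Zero body thickness yields
    an empty mask with a warning.
    """
    h, w = spec.image_size
    rng = np.random.default_rng(spec.seed)
    points, arclen = _spiral_centerline(spec)
    radius_max = spec.body.thickness_head / 2.0
    _validate(spec, points, radius_max)

    if spec.body.thickness_head <= 0:
        warnings.warn("zero body thickness: empty specimen mask")
        mask = np.zeros((h, w), dtype=bool)
        arc_pos = np.zeros((h, w))
    else:
        mask, arc_pos, _ = _sweep_body(spec, points, arclen)

    img = np.empty((h, w, 3))
    img[:] = spec.background.color
    if spec.background.texture_sd > 0:
        img += rng.normal(0.0, spec.background.texture_sd, size=(h, w, 1))

    base = np.asarray(spec.body.base_color)
    pat = np.asarray(spec.body.pattern_color)
    if mask.any():
        body_rgb = np.broadcast_to(base, (h, w, 3)).copy()
        if spec.body.pattern == "bands":
            phase = np.floor(arc_pos / max(spec.body.pattern_period, 1e-9)) % 2 == 1
            body_rgb[phase] = pat
        elif spec.body.pattern == "blotches":
            # pseudo-random blotches keyed to quantized arc position
            cells = np.floor(arc_pos / max(spec.body.pattern_period, 1e-9)).astype(int)
            cell_rng = np.random.default_rng(derive_seed(spec.seed, "blotch"))
            n_cells = cells.max() + 1 if mask.any() else 1
            on = cell_rng.random(max(n_cells, 1)) < 0.5
            body_rgb[on[np.clip(cells, 0, n_cells - 1)]] = pat
        elif spec.body.pattern != "plain":
            raise SceneSpecError(f"unknown pattern {spec.body.pattern!r}")
        img[mask] = body_rgb[mask]

    # gray standard disk with ~1 px anti-aliased rim
    sx, sy = spec.standard.center
    r = spec.standard.radius
    yy, xx = np.mgrid[0:h, 0:w]
    d = np.hypot(xx + 0.5 - sx, yy + 0.5 - sy)
    cover = np.clip(r + 0.5 - d, 0.0, 1.0)
    img = img * (1 - cover[..., None]) + cover[..., None] * spec.standard.gray

    # multiplicative lighting gradient across the frame
    amp = spec.lighting.gradient_amplitude
    if amp > 0:
        ang = np.deg2rad(spec.lighting.direction_deg)
        u = (xx + 0.5) * np.cos(ang) + (yy + 0.5) * np.sin(ang)
        u = (u - u.min()) / max(u.max() - u.min(), 1e-9) - 0.5
        img *= (1.0 + 2.0 * amp * u)[..., None]

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    meta = {
        "spec": asdict(spec),
        "standard_truth": {"center": [sx, sy], "radius": r, "gray": spec.standard.gray},
        "mask_area_px": int(mask.sum()),
    }
    return img, mask, meta


def random_scene_spec(
    rng: np.random.Generator, image_size: tuple[int, int] = (256, 256)
) -> SceneSpec:
    """Draw one SceneSpec from the default variability ranges.

    The ranges emulate the stated variability of field photographs of coiled
    organisms: coil count, direction, thickness, banding/blotching, warm body
    hues on a blue or black mat, lighting gradients.
    """
    h, w = image_size
    scale = min(h, w) / 256.0
    turns = float(rng.uniform(1.2, 2.4))
    thickness = float(rng.uniform(10.0, 18.0)) * scale
    spacing = thickness + float(rng.uniform(6.0, 14.0)) * scale
    # keep the body inside the frame: outer radius = a + b*theta_max + thickness/2
    b = spacing / (2 * np.pi)
    a = max(thickness, 2.0)
    outer = a + b * 2 * np.pi * turns + thickness / 2.0
    max_outer = min(h, w) / 2.0 - 6.0 * scale
    if outer > max_outer:
        turns = float((max_outer - thickness / 2.0 - a) / (b * 2 * np.pi))
        turns = max(turns, 0.5)
        outer = a + b * 2 * np.pi * turns + thickness / 2.0
    center = (w / 2.0 + float(rng.uniform(-4, 4)), h / 2.0 + float(rng.uniform(-4, 4)))

    hue = float(rng.choice([rng.uniform(0.0, 0.16), rng.uniform(0.2, 0.38)]))
    sat = float(rng.uniform(0.45, 0.9))
    val = float(rng.uniform(0.35, 0.8))
    base = tuple(float(v) for v in skcolor.hsv2rgb(np.array([[[hue, sat, val]]]))[0, 0])
    dark = rng.random() < 0.6
    pv = val * 0.25 if dark else min(val * 1.8, 0.95)
    pat_col = tuple(
        float(v) for v in skcolor.hsv2rgb(np.array([[[hue, sat * 0.8, pv]]]))[0, 0]
    )
    pattern = str(rng.choice(["bands", "bands", "blotches", "plain"]))

    if rng.random() < 0.7:
        bg = (
            float(rng.uniform(0.02, 0.12)),
            float(rng.uniform(0.1, 0.3)),
            float(rng.uniform(0.4, 0.7)),
        )
    else:
        g = float(rng.uniform(0.02, 0.1))
        bg = (g, g, g * 1.1)

    std_r = float(rng.uniform(12.0, 20.0)) * scale
    # place the standard in the corner farthest outside the coil's extent
    margin = std_r + 3.0
    corners = [
        (margin, margin),
        (w - margin, margin),
        (margin, h - margin),
        (w - margin, h - margin),
    ]
    dists = [np.hypot(cx - center[0], cy - center[1]) for cx, cy in corners]
    std_center = corners[int(np.argmax(dists))]

    return SceneSpec(
        image_size=image_size,
        coil=CoilSpec(
            turns=turns,
            direction=str(rng.choice(["cw", "ccw"])),
            center=center,
            spacing=spacing,
        ),
        body=BodySpec(
            thickness_head=thickness,
            taper=float(rng.uniform(0.3, 0.5)),
            base_color=base,
            pattern=pattern,
            pattern_period=float(rng.uniform(14.0, 32.0)) * scale,
            pattern_color=pat_col,
        ),
        background=BackgroundSpec(color=bg, texture_sd=0.01),
        standard=StandardSpec(center=std_center, radius=std_r, gray=float(rng.uniform(0.35, 0.5))),
        lighting=LightingSpec(
            gradient_amplitude=float(rng.uniform(0.0, 0.12)),
            direction_deg=float(rng.uniform(0.0, 360.0)),
        ),
        noise_sd=0.008,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_dataset(
    n: int,
    out_dir: str | Path,
    seed: int = 0,
    image_size: tuple[int, int] = (256, 256),
) -> list[dict]:
    """Generate n labeled scenes on disk: PNG images, mask PNGs, label JSON, manifest CSV.

    The manifest records each scene's full spec (as JSON), so regenerating
    from the manifest reproduces identical files.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    (out / "labels").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        spec = random_scene_spec(rng, image_size=image_size)
        scene_id = f"scene_{i:04d}"
        rows.append(_write_scene(out, scene_id, spec))
    with open(out / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["scene_id", "spec_json"])
        writer.writeheader()
        writer.writerows(rows)
    return rows


def _write_scene(out: Path, scene_id: str, spec: SceneSpec) -> dict:
    img, mask, meta = generate_scene(spec)
    write_image_png(img, out / "images" / f"{scene_id}.png")
    write_mask_png(mask, out / "masks" / f"{scene_id}.png")
    polys = roi_io.mask_to_polygons(mask)
    sx, sy = spec.standard.center
    std_poly = _circle_polygon(sx, sy, spec.standard.radius)
    label = roi_io.LabelFile(
        image_id=scene_id,
        height=spec.image_size[0],
        width=spec.image_size[1],
        rois=polys + [std_poly],
    )
    roi_io.write_labels(label, out / "labels" / f"{scene_id}.json")
    return {"scene_id": scene_id, "spec_json": json.dumps(asdict(spec))}


def _circle_polygon(cx: float, cy: float, r: float, n: int = 64) -> roi_io.PolygonROI:
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return roi_io.PolygonROI(
        vertices=tuple((float(cx + r * np.cos(t)), float(cy + r * np.sin(t))) for t in th),
        region_class="gray_standard",
    )


def spec_from_manifest_row(row: dict) -> SceneSpec:
    doc = json.loads(row["spec_json"])
    return SceneSpec(
        image_size=tuple(doc["image_size"]),
        coil=CoilSpec(**{**doc["coil"], "center": tuple(doc["coil"]["center"])}),
        body=BodySpec(
            **{
                **doc["body"],
                "base_color": tuple(doc["body"]["base_color"]),
                "pattern_color": tuple(doc["body"]["pattern_color"]),
            }
        ),
        background=BackgroundSpec(
            color=tuple(doc["background"]["color"]),
            texture_sd=doc["background"]["texture_sd"],
        ),
        standard=StandardSpec(
            center=tuple(doc["standard"]["center"]),
            radius=doc["standard"]["radius"],
            gray=doc["standard"]["gray"],
        ),
        lighting=LightingSpec(**doc["lighting"]),
        noise_sd=doc["noise_sd"],
        seed=doc["seed"],
    )


def regenerate_from_manifest(manifest_csv: str | Path, out_dir: str | Path) -> None:
    """Re-render every scene recorded in a manifest (byte-identical outputs)."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    (out / "labels").mkdir(parents=True, exist_ok=True)
    with open(manifest_csv, newline="") as fh:
        for row in csv.DictReader(fh):
            _write_scene(out, row["scene_id"], spec_from_manifest_row(row))


def apply_hue_brightness(image: np.ndarray, hue_shift: float, brightness: float) -> np.ndarray:
    """Deterministic core of augmentation: rotate hue (in turns) and scale brightness."""
    img = np.asarray(image, dtype=float)
    hsv = skcolor.rgb2hsv(img)
    hsv[..., 0] = np.mod(hsv[..., 0] + hue_shift, 1.0)
    out = skcolor.hsv2rgb(hsv) * brightness
    return np.clip(out, 0.0, 1.0)


def augment(
    image: np.ndarray,
    hue_jitter: float = 0.05,
    brightness_jitter: float = 0.1,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Randomly shift hue and scale brightness within the stated bounds.

    Introduces useful variation into a training set whose diversity cannot be
    expanded with more photographs; the specimen mask is unchanged.  Zero
    jitter is the identity.
    """
    if hue_jitter == 0.0 and brightness_jitter == 0.0:
        return np.asarray(image, dtype=float).copy()
    rng = rng or np.random.default_rng()
    hs = float(rng.uniform(-hue_jitter, hue_jitter))
    br = float(rng.uniform(1.0 - brightness_jitter, 1.0 + brightness_jitter))
    return apply_hue_brightness(image, hs, br)
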