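"""Z-buffered software rasterization of sphere impostors.

The projection is orthographic: the camera rotation is applied to
mean-centered coordinates and the x/y plane maps to the screen with a
uniform scale chosen so the visible set (including sphere radii) fits with
a 10% margin.  Shading is a fixed headlight (ambient 0.35, diffuse 0.65,
light along +z), making output bytes fully deterministic.

Rasterization math, normative for the brute-force test oracle:

* ``pts = (coords - centroid) @ R.T`` with ``centroid`` the mean of the
  visible coordinates and ``R`` the view rotation;
* screen center ``(W/2, H/2)``; atom center pixel
  ``px = W/2 + (x - cx) * scale``, ``py = H/2 - (y - cy) * scale`` where
  ``(cx, cy)`` centers the radius-padded x/y bounding box and
  ``scale = (min(W, H) / 2) / (half_extent * 1.1)``;
* a pixel (column i, row j) samples at ``(i + 0.5, j + 0.5)``; it is
  covered when ``d2 <= (r * scale)**2`` and the sphere surface sits at
  ``z * scale + sqrt((r * scale)**2 - d2)``; the largest surface z wins;
* intensity ``0.35 + 0.65 * nz`` with ``nz = sqrt(pr2 - d2) / pr``;
  channel value ``clip(rint(color * intensity), 0, 255)``.

Rendering happens at ``supersample`` times the largest requested size and
is box-downsampled; smaller resolutions are always derived from the
largest render, never re-rendered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image, ImageDraw

from .errors import RenderError
from .orientation import view_rotation
from .scenes import SceneSpec

AMBIENT = 0.35
DIFFUSE = 0.65
MARGIN = 1.1  # 10% framing margin

DEFAULT_SIZES = ((1600, 1600), (800, 800), (200, 200), (100, 100))

AXIS_COLORS = ((200, 40, 40), (40, 160, 40), (40, 60, 220))  # PCA axes 1..3


@dataclass
class RenderSettings:
    sizes: tuple = DEFAULT_SIZES
    supersample: int = 2
    background: tuple = (255, 255, 255)
    draw_axes: bool = True

    def __post_init__(self) -> None:
        if not self.sizes:
            raise ValueError("sizes must be non-empty")
        if any(w <= 0 or h <= 0 for w, h in self.sizes):
            raise ValueError("all sizes must be positive")
        w0, h0 = self.sizes[0]
        if any(w > w0 or h > h0 for w, h in self.sizes[1:]):
            raise ValueError("largest size must come first")
        if self.supersample < 1:
            raise ValueError("supersample must be >= 1")


@dataclass
class ImageBuffer:
    width: int
    height: int
    pixels: np.ndarray = field(repr=False)  # (height, width, 3) uint8, row-major

    def __post_init__(self) -> None:
        self.pixels = np.ascontiguousarray(self.pixels, dtype=np.uint8)
        if self.pixels.shape != (self.height, self.width, 3):
            raise ValueError(
                f"pixel array shape {self.pixels.shape} does not match "
                f"{self.height}x{self.width}x3"
            )

    def to_pil(self) -> Image.Image:
        return Image.fromarray(self.pixels, mode="RGB")

    def save_png(self, path) -> None:
        self.to_pil().save(path, format="PNG")


def project_scene(scene: SceneSpec, view: str, width: int, height: int):
    """Project the visible atoms to screen space.

    Returns ``(px, py, pz, pr, colors)`` arrays — pixel-space centers,
    depths, radii, and uint8 colors — or ``None`` when nothing is visible.
    """
    visible = list(scene.visible_atoms)
    if not visible:
        return None
    coords = scene.flat.coords[visible]
    radii = np.array([scene.atom_radii[i] for i in visible], dtype=float)
    colors = np.array([scene.atom_colors[i] for i in visible], dtype=float)
    rot = view_rotation(scene.camera_front, view)
    pts = (coords - coords.mean(axis=0)) @ rot.T
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    cx = ((x - radii).min() + (x + radii).max()) / 2.0
    cy = ((y - radii).min() + (y + radii).max()) / 2.0
    half_extent = max(
        (x + radii).max() - cx, cx - (x - radii).min(),
        (y + radii).max() - cy, cy - (y - radii).min(),
    )
    if half_extent <= 0:
        scale = 1.0
    else:
        scale = (min(width, height) / 2.0) / (half_extent * MARGIN)
    px = width / 2.0 + (x - cx) * scale
    py = height / 2.0 - (y - cy) * scale
    pz = z * scale
    pr = radii * scale
    return px, py, pz, pr, colors


def rasterize(scene: SceneSpec, view: str, settings: RenderSettings) -> ImageBuffer:
    """Render one view of a scene at the largest configured size."""
    width, height = settings.sizes[0]
    ss = settings.supersample
    buf = _rasterize_at(scene, view, width * ss, height * ss, settings.background)
    if ss > 1:
        buf = downscale(buf, (width, height))
    return buf


def _rasterize_at(scene, view, width, height, background) -> ImageBuffer:
    img = np.empty((height, width, 3), dtype=np.uint8)
    img[:, :] = np.asarray(background, dtype=np.uint8)
    projected = project_scene(scene, view, width, height)
    if projected is None:
        return ImageBuffer(width=width, height=height, pixels=img)
    px, py, pz, pr, colors = projected
    zbuf = np.full((height, width), -np.inf)
    for k in range(len(px)):
        if pr[k] <= 0:
            continue
        x0 = max(int(np.floor(px[k] - pr[k])), 0)
        x1 = min(int(np.ceil(px[k] + pr[k])) + 1, width)
        y0 = max(int(np.floor(py[k] - pr[k])), 0)
        y1 = min(int(np.ceil(py[k] + pr[k])) + 1, height)
        if x0 >= x1 or y0 >= y1:
            continue
        sx = np.arange(x0, x1) + 0.5
        sy = np.arange(y0, y1) + 0.5
        dx2 = (sx[None, :] - px[k]) ** 2
        dy2 = (sy[:, None] - py[k]) ** 2
        d2 = dx2 + dy2
        pr2 = pr[k] ** 2
        inside = d2 <= pr2
        if not inside.any():
            continue
        bump = np.sqrt(np.where(inside, pr2 - d2, 0.0))
        zs = pz[k] + bump
        patch_z = zbuf[y0:y1, x0:x1]
        update = inside & (zs > patch_z)
        if not update.any():
            continue
        nz = bump / pr[k]
        intensity = AMBIENT + DIFFUSE * nz
        shaded = np.clip(np.rint(colors[k][None, None, :] * intensity[:, :, None]), 0, 255)
        patch_img = img[y0:y1, x0:x1]
        patch_img[update] = shaded[update].astype(np.uint8)
        patch_z[update] = zs[update]
    return ImageBuffer(width=width, height=height, pixels=img)


def downscale(image: ImageBuffer, target) -> ImageBuffer:
    """Integer-ratio box-filter downsampling.

    Each output channel is the rounded average of the source block
    (``(sum + n // 2) // n``, i.e. round-half-up).  Upscaling or
    non-integer ratios raise :class:`RenderError`.
    """
    tw, th = target
    if tw > image.width or th > image.height:
        raise RenderError(
            f"cannot upscale {image.width}x{image.height} to {tw}x{th}"
        )
    if image.width % tw or image.height % th:
        raise RenderError(
            f"downscale ratio {image.width}x{image.height} -> {tw}x{th} is not integer"
        )
    fx, fy = image.width // tw, image.height // th
    if fx == 1 and fy == 1:
        return ImageBuffer(width=tw, height=th, pixels=image.pixels.copy())
    block = image.pixels.reshape(th, fy, tw, fx, 3).astype(np.uint64)
    total = block.sum(axis=(1, 3))
    n = fx * fy
    out = ((total + n // 2) // n).astype(np.uint8)
    return ImageBuffer(width=tw, height=th, pixels=out)


def draw_axes_overlay(image: ImageBuffer, front: np.ndarray, view: str) -> ImageBuffer:
    """Arrows in the bottom-left corner showing the screen-projected PCA axes.

    Returns a new buffer; the overlay stays within the bottom-left
    quadrant.  Axes pointing along the depth direction (negligible screen
    component) are skipped.
    """
    rot = view_rotation(front, view)
    # In the front view R maps PCA axis i onto screen axis e_i; the extra
    # side/top rotation is rot @ front^-1, so axis i projects to that
    # rotation applied to e_i.
    extra = rot @ np.asarray(front, dtype=float).T
    pil = image.to_pil().copy()
    draw = ImageDraw.Draw(pil)
    ox = max(int(image.width * 0.06), 4)
    oy = image.height - max(int(image.height * 0.06), 4)
    length = max(int(min(image.width, image.height) * 0.09), 8)
    line_w = max(image.width // 400, 1)
    for i in range(3):
        direction = extra[:, i]
        dx, dy = float(direction[0]), float(direction[1])
        norm = np.hypot(dx, dy)
        if norm < 0.05:
            continue
        ex = ox + dx * length
        ey = oy - dy * length
        # Clamp into the bottom-left quadrant.
        ex = min(max(ex, 0), image.width / 2 - 1)
        ey = min(max(ey, image.height / 2), image.height - 1)
        draw.line([(ox, oy), (ex, ey)], fill=AXIS_COLORS[i], width=line_w)
        _arrow_head(draw, ox, oy, ex, ey, AXIS_COLORS[i], line_w)
    return ImageBuffer(width=image.width, height=image.height, pixels=np.asarray(pil))


def _arrow_head(draw, ox, oy, ex, ey, color, line_w) -> None:
    vx, vy = ex - ox, ey - oy
    norm = float(np.hypot(vx, vy))
    if norm < 1e-9:
        return
    ux, uy = vx / norm, vy / norm
    size = max(3 * line_w, 3)
    left = (ex - size * ux + size * 0.5 * uy, ey - size * uy - size * 0.5 * ux)
    right = (ex - size * ux - size * 0.5 * uy, ey - size * uy + size * 0.5 * ux)
    draw.polygon([(ex, ey), left, right], fill=color)
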