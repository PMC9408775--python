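"""Synthetic TEM-like patches of single mitochondria, and the raster
measurement operators (area, normalized matrix electron density) that read
them back.

Conventions: 8-bit grayscale, y-down raster with the origin at the top-left
pixel center; no anti-aliasing, so mask areas are exact pixel counts.
Electron density is inverted gray (density = 255 - gray): electron-dense
material appears dark in TEM, and matrix dilution brightens the matrix.

The rendered organelle is an axis-aligned ellipse with a double membrane
(two concentric dark rings separated by a light inter-membrane space),
parallel dark crest bars across the matrix, and parameterized damage:
focal bright disks (dilution spots) or whole-matrix brightening
(widespread dilution), truncated crest bars (broken crests), and membrane
rings opened over a fraction of the perimeter (ruptured membranes).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .cohort import Dilution

__all__ = [
    "CYTOSOL", "MATRIX", "CREST", "MEMBRANE", "CLASS_NAMES",
    "RenderSpec", "Patch", "render_mitochondrion",
    "measure_area", "shoelace_area", "measure_ed_norm",
]

# mask label codes
CYTOSOL, MATRIX, CREST, MEMBRANE = 0, 1, 2, 3
CLASS_NAMES = {CYTOSOL: "cytosol", MATRIX: "matrix", CREST: "crest", MEMBRANE: "membrane"}

# geometry constants (nm), resolved at the default 2 nm/px working scale
MEMBRANE_THICKNESS_NM = 7.0
INTERMEMBRANE_GAP_NM = 8.0
CREST_WIDTH_NM = 6.0
CREST_SPACING_NM = 40.0


class RenderError(ValueError):
    pass


class MeasurementError(ValueError):
    pass


@dataclass
class RenderSpec:
    """Parameters of one rendered mitochondrion."""

    area: float = 0.35            # um^2, target organelle section area
    aspect: float = 1.6           # d_max / d_min
    dilution: str = Dilution.NONE
    n_spots: int = 4
    crest_break_fraction: float = 0.0
    membrane_gap_fraction: float = 0.0
    cytosol_gray: int = 150
    matrix_gray: int = 80
    crest_gray: int = 40
    membrane_gray: int = 40
    dilution_gray: int = 140
    noise_sigma: float = 4.0      # gray units
    scale: float = 2.0            # nm per pixel
    seed: int = 0

    def validate(self) -> "RenderSpec":
        for name in ("cytosol_gray", "matrix_gray", "crest_gray", "membrane_gray", "dilution_gray"):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise RenderError(f"{name}={v} outside [0, 255]")
        if self.matrix_gray >= self.dilution_gray:
            raise RenderError("dilution must brighten: matrix_gray < dilution_gray required")
        for name in ("crest_break_fraction", "membrane_gap_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise RenderError(f"{name}={v} outside [0, 1]")
        if not self.area > 0:
            raise RenderError("area must be > 0")
        if not self.aspect >= 1.0:
            raise RenderError("aspect must be >= 1")
        if not self.scale > 0:
            raise RenderError("scale must be > 0")
        if self.n_spots < 0 or self.noise_sigma < 0:
            raise RenderError("n_spots and noise_sigma must be >= 0")
        return self

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "RenderSpec":
        return cls(**json.loads(Path(path).read_text())).validate()


@dataclass
class Patch:
    image: np.ndarray   # uint8, (H, W)
    masks: np.ndarray   # uint8 label raster, same shape
    scale: float        # nm per pixel
    legend: dict = None

    def __post_init__(self):
        if self.image.shape != self.masks.shape:
            raise RenderError("image and masks must share dimensions")
        if not self.scale > 0:
            raise RenderError("scale must be > 0")
        if self.legend is None:
            self.legend = dict(CLASS_NAMES)

    def save(self, stem) -> dict:
        """Write image and mask PNGs plus a JSON legend next to ``stem``."""
        from PIL import Image

        stem = Path(stem)
        paths = {
            "image": stem.with_suffix(".png"),
            "masks": stem.parent / f"{stem.name}_masks.png",
            "legend": stem.parent / f"{stem.name}_legend.json",
        }
        Image.fromarray(self.image, mode="L").save(paths["image"])
        Image.fromarray(self.masks, mode="L").save(paths["masks"])
        paths["legend"].write_text(json.dumps(
            {"scale_nm_per_px": self.scale, "classes": {str(k): v for k, v in self.legend.items()}},
            indent=1))
        return {k: str(v) for k, v in paths.items()}


def _ellipse_mask(yy, xx, cy, cx, a_px, b_px):
    """Pixel-center membership in an axis-aligned ellipse (a = x semi-axis)."""
    if a_px <= 0 or b_px <= 0:
        return np.zeros_like(yy, dtype=bool)
    return ((xx - cx) / a_px) ** 2 + ((yy - cy) / b_px) ** 2 <= 1.0


def render_mitochondrion(spec: RenderSpec, max_canvas_px: int = 4096) -> Patch:
    """Render one mitochondrion per ``spec``; deterministic per seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nm_per_um = 1000.0

    # ellipse semi-axes in px from area and aspect: area = pi a b
    d_min_um = np.sqrt(4.0 * spec.area / (np.pi * spec.aspect))
    d_max_um = spec.aspect * d_min_um
    a_px = d_max_um / 2.0 * nm_per_um / spec.scale
    b_px = d_min_um / 2.0 * nm_per_um / spec.scale
    margin = max(16, int(0.15 * a_px))
    w = int(np.ceil(2 * a_px)) + 2 * margin
    h = int(np.ceil(2 * b_px)) + 2 * margin
    if max(w, h) > max_canvas_px:
        raise RenderError(
            f"target area {spec.area} um^2 at {spec.scale} nm/px needs a "
            f"{w}x{h} canvas (limit {max_canvas_px})")

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0

    t_px = max(2.0, MEMBRANE_THICKNESS_NM / spec.scale)
    g_px = max(1.0, INTERMEMBRANE_GAP_NM / spec.scale)

    outer = _ellipse_mask(yy, xx, cy, cx, a_px, b_px)
    inner_of_outer = _ellipse_mask(yy, xx, cy, cx, a_px - t_px, b_px - t_px)
    outer_of_inner = _ellipse_mask(yy, xx, cy, cx, a_px - t_px - g_px, b_px - t_px - g_px)
    inner_of_inner = _ellipse_mask(
        yy, xx, cy, cx, a_px - 2 * t_px - g_px, b_px - 2 * t_px - g_px)

    ring_outer = outer & ~inner_of_outer
    gap_zone = inner_of_outer & ~outer_of_inner
    ring_inner = outer_of_inner & ~inner_of_inner
    matrix = inner_of_inner

    image = np.full((h, w), spec.cytosol_gray, dtype=float)
    masks = np.full((h, w), CYTOSOL, dtype=np.uint8)

    # envelope: rings dark, inter-membrane space light; all three bands are
    # membrane class so the organelle mask is the full ellipse
    masks[ring_outer | gap_zone | ring_inner] = MEMBRANE
    image[ring_outer | ring_inner] = spec.membrane_gray
    image[gap_zone] = spec.cytosol_gray
    masks[matrix] = MATRIX
    image[matrix] = spec.matrix_gray

    # membrane rupture: open both rings over an arc of the perimeter; the
    # opened pixels revert to matrix (envelope locally dissolved) so the
    # organelle area is unchanged
    if spec.membrane_gap_fraction > 0:
        theta = np.arctan2((yy - cy) / max(b_px, 1e-9), (xx - cx) / max(a_px, 1e-9))
        theta0 = rng.uniform(-np.pi, np.pi)
        half = np.pi * spec.membrane_gap_fraction
        delta = np.angle(np.exp(1j * (theta - theta0)))
        in_arc = np.abs(delta) <= half
        ruptured = (ring_outer | gap_zone | ring_inner) & in_arc
        image[ruptured] = spec.matrix_gray
        masks[ruptured] = MATRIX

    # crests: vertical dark bars across the matrix, truncated when broken
    spacing = max(2, int(round(CREST_SPACING_NM / spec.scale)))
    width = max(1, int(round(CREST_WIDTH_NM / spec.scale)))
    crest_cols = np.arange(int(cx) % spacing, w, spacing)
    for col0 in crest_cols:
        bar = matrix & (xx >= col0) & (xx < col0 + width)
        rows = np.flatnonzero(bar.any(axis=1))
        if rows.size == 0:
            continue
        if spec.crest_break_fraction > 0:
            drop = int(round(spec.crest_break_fraction * rows.size))
            if drop >= rows.size:
                continue  # fully broken: no crest pixels survive
            if drop > 0:
                start = rng.integers(0, rows.size - drop + 1)
                keep = np.ones(rows.size, dtype=bool)
                keep[start:start + drop] = False
                bar = bar & np.isin(yy, rows[keep])
        image[bar] = spec.crest_gray
        masks[bar] = CREST

    # matrix dilution: focal bright disks or whole-matrix brightening
    matrix_now = masks == MATRIX
    if spec.dilution == Dilution.WIDESPREAD:
        image[matrix_now] = spec.dilution_gray
    elif spec.dilution == Dilution.SPOTS and spec.n_spots > 0:
        r_spot = max(2.0, 0.15 * b_px)
        ys, xs = np.nonzero(matrix_now)
        if ys.size == 0:
            raise RenderError("matrix too small for dilution spots at this scale")
        for _ in range(spec.n_spots):
            j = rng.integers(0, ys.size)
            disk = ((xx - xs[j]) ** 2 + (yy - ys[j]) ** 2) <= r_spot**2
            image[disk & matrix_now] = spec.dilution_gray
    elif spec.dilution not in Dilution.ORDER:
        raise RenderError(f"unknown dilution {spec.dilution!r}")

    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, image.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    return Patch(image=image, masks=masks, scale=spec.scale)


# ---------------------------------------------------------------------------
# measurement


def measure_area(masks: np.ndarray, scale: float, polygon=None):
    """Organelle area in um^2: pixel count of matrix+crest+membrane x scale^2.

    With ``polygon`` (an (n, 2) array of (x, y) vertices in px), also returns
    the shoelace polygon area in um^2, for parity with freehand tracing:
    ``(mask_area, polygon_area)``.
    """
    organelle = np.isin(masks, (MATRIX, CREST, MEMBRANE))
    count = int(organelle.sum())
    if count == 0:
        raise MeasurementError("empty organelle mask")
    px_um = scale / 1000.0
    mask_area = count * px_um**2
    if polygon is None:
        return mask_area
    return mask_area, shoelace_area(polygon) * px_um**2


def shoelace_area(vertices) -> float:
    """Polygon area by the shoelace formula, in squared vertex units."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[0] < 3 or v.shape[1] != 2:
        raise MeasurementError("polygon needs at least 3 (x, y) vertices")
    x, y = v[:, 0], v[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def measure_ed_norm(image: np.ndarray, masks: np.ndarray) -> float:
    """Matrix electron density normalized to the cytosol.

    Electron density of a region is inverted mean gray (255 - mean); the
    return value is ED(matrix) / ED(cytosol), so a matrix darker than the
    cytosol gives a ratio above 1 and dilution lowers it.
    """
    matrix = masks == MATRIX
    cytosol = masks == CYTOSOL
    if not matrix.any():
        raise MeasurementError("empty matrix region")
    if not cytosol.any():
        raise MeasurementError("empty cytosol region")
    ed_matrix = 255.0 - float(image[matrix].mean())
    ed_cytosol = 255.0 - float(image[cytosol].mean())
    if ed_cytosol == 0:
        raise MeasurementError("cytosol is saturated white: density ratio undefined")
    return ed_matrix / ed_cytosol
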