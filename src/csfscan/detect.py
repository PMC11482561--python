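"""Circle detection in chip-field fluorescence images.

The detection stage finds circular cells in a 2-D intensity raster with a
gradient-direction circle Hough transform, filters the detections by physical
size, and measures background-corrected per-channel fluorescence for each
detected cell.  It stands in for the counting instrument's image-analysis
front end.

Coordinates are 0-based with ``x`` the column and ``y`` the row; pixel centers
sit at integer coordinates.  No sub-pixel refinement is attempted — detected
centers and radii are accurate to about one pixel on well-contrasted cells.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "FieldImage",
    "DetectorConfig",
    "CellDetection",
    "detect_circles",
    "filter_by_size",
    "measure_intensities",
    "load_field",
    "load_field_channels",
]


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass
class FieldImage:
    """One imaged chip section: three co-registered intensity rasters.

    ``bf`` (bright field), ``gf`` (green fluorescence, nucleic-acid stain /
    WBC channel) and ``cf`` (cyan/far-red fluorescence, glycophorin-A stain /
    RBC channel) must share a shape.  ``volume_nl`` is the imaged sample
    volume in nanolitres; when omitted it is derived from the geometry as
    ``width * height * pixel_size_um**2 * depth_um * 1e-6``.
    """

    bf: np.ndarray
    gf: np.ndarray
    cf: np.ndarray
    pixel_size_um: float
    depth_um: float
    volume_nl: float | None = None
    field_id: str = ""

    def __post_init__(self) -> None:
        self.bf = np.asarray(self.bf, dtype=float)
        self.gf = np.asarray(self.gf, dtype=float)
        self.cf = np.asarray(self.cf, dtype=float)
        if not (self.bf.shape == self.gf.shape == self.cf.shape):
            raise ValueError("bf, gf and cf rasters must share a shape")
        if self.bf.ndim != 2 or self.bf.size == 0:
            raise ValueError("rasters must be non-empty 2-D arrays")
        if not (math.isfinite(self.pixel_size_um) and self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be positive and finite")
        if not (math.isfinite(self.depth_um) and self.depth_um > 0):
            raise ValueError("depth_um must be positive and finite")
        geom = self.geometric_volume_nl()
        if self.volume_nl is None:
            self.volume_nl = geom
        elif abs(self.volume_nl - geom) > 1e-6 * max(geom, 1e-300):
            raise ValueError(
                f"volume_nl={self.volume_nl} inconsistent with geometry "
                f"({geom} nL)"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.bf.shape

    def geometric_volume_nl(self) -> float:
        h, w = self.bf.shape
        return w * h * self.pixel_size_um**2 * self.depth_um * 1e-6


@dataclass(frozen=True)
class DetectorConfig:
    """Circle-Hough detector parameters.

    ``edge_threshold`` is in gradient units (intensity per pixel);
    ``accumulator_threshold`` is the minimum fraction of a circle's
    circumference that must vote for a candidate (1.0 would be a complete,
    perfectly sharp circle); ``nms_min_distance_px`` is the minimum spacing
    between reported centers.
    """

    radius_min_px: int = 2
    radius_max_px: int = 8
    edge_threshold: float = 50.0
    accumulator_threshold: float = 1.5
    nms_min_distance_px: float = 5.0

    def __post_init__(self) -> None:
        if not (0 < self.radius_min_px <= self.radius_max_px):
            raise ValueError("require 0 < radius_min_px <= radius_max_px")
        if self.edge_threshold < 0 or self.accumulator_threshold < 0:
            raise ValueError("thresholds must be >= 0")
        if self.nms_min_distance_px < 0:
            raise ValueError("nms_min_distance_px must be >= 0")


@dataclass
class CellDetection:
    """A detected circle with optional per-channel intensity measurements.

    ``gf_intensity``/``cf_intensity`` are background-corrected mean disc
    intensities (mean over the disc minus the median of a surrounding
    annulus); they may be negative for background-level discs.
    """

    center_x_px: float
    center_y_px: float
    radius_px: float
    score: float = 0.0
    gf_intensity: float | None = None
    cf_intensity: float | None = None
    field_id: str = ""
    flags: tuple[str, ...] = field(default_factory=tuple)

    def radius_um(self, pixel_size_um: float) -> float:
        return self.radius_px * pixel_size_um


# --------------------------------------------------------------------------
# Circle Hough transform
# --------------------------------------------------------------------------

def _gradients(image: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sobel gradients scaled to intensity-per-pixel units."""
    img = np.asarray(image, dtype=float)
    gx = ndimage.sobel(img, axis=1, mode="reflect") / 8.0
    gy = ndimage.sobel(img, axis=0, mode="reflect") / 8.0
    return gx, gy, np.hypot(gx, gy)


def detect_circles(
    image: np.ndarray, config: DetectorConfig = DetectorConfig()
) -> list[CellDetection]:
    """Detect circles in a single 2-D raster.

    Edge pixels (gradient magnitude above ``edge_threshold``) cast votes along
    the positive and negative gradient direction at every candidate radius;
    the (x, y, r) accumulator is aggregated over a 3x3 center neighbourhood,
    normalised by circumference, thresholded and reduced by greedy
    non-maximum suppression.  Entirely deterministic: candidates are ranked
    by (score, then smaller y, then smaller x).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a non-empty 2-D raster")
    h, w = img.shape
    if 2 * config.radius_max_px >= min(h, w):
        raise ValueError(
            f"radius_max_px={config.radius_max_px} too large for a "
            f"{h}x{w} image (need 2*radius_max < min side)"
        )

    gx, gy, mag = _gradients(img)
    ys, xs = np.nonzero(mag > config.edge_threshold)
    if ys.size == 0:
        return []
    m = mag[ys, xs]
    ux = gx[ys, xs] / m
    uy = gy[ys, xs] / m

    radii = np.arange(config.radius_min_px, config.radius_max_px + 1)
    acc = np.zeros((radii.size, h, w), dtype=np.float64)
    for ir, r in enumerate(radii):
        for sign in (1.0, -1.0):
            cx = np.rint(xs + sign * r * ux).astype(np.intp)
            cy = np.rint(ys + sign * r * uy).astype(np.intp)
            ok = (cx >= 0) & (cx < w) & (cy >= 0) & (cy < h)
            np.add.at(acc[ir], (cy[ok], cx[ok]), 1.0)

    # aggregate votes over a 3x3 center neighbourhood (rounding scatter)
    acc = ndimage.uniform_filter(acc, size=(1, 3, 3), mode="constant") * 9.0
    acc /= (2.0 * np.pi * radii)[:, None, None]

    best_ir = np.argmax(acc, axis=0)
    best = np.take_along_axis(acc, best_ir[None], axis=0)[0]
    cand_y, cand_x = np.nonzero(best > config.accumulator_threshold)
    if cand_y.size == 0:
        return []
    scores = best[cand_y, cand_x]
    order = np.lexsort((cand_x, cand_y, -scores))

    kept: list[CellDetection] = []
    kept_xy: list[tuple[float, float]] = []
    min_d2 = config.nms_min_distance_px**2
    for i in order:
        x, y = float(cand_x[i]), float(cand_y[i])
        if any((x - kx) ** 2 + (y - ky) ** 2 < min_d2 for kx, ky in kept_xy):
            continue
        kept.append(
            CellDetection(
                center_x_px=x,
                center_y_px=y,
                radius_px=float(radii[best_ir[cand_y[i], cand_x[i]]]),
                score=float(scores[i]),
            )
        )
        kept_xy.append((x, y))
    return kept


def filter_by_size(
    detections: list[CellDetection],
    radius_range_um: tuple[float, float],
    pixel_size_um: float,
) -> list[CellDetection]:
    """Keep detections whose radius in µm lies in the closed interval."""
    lo, hi = radius_range_um
    if not lo <= hi:
        raise ValueError(f"empty radius interval [{lo}, {hi}]")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    return [d for d in detections if lo <= d.radius_px * pixel_size_um <= hi]


# --------------------------------------------------------------------------
# Intensity measurement
# --------------------------------------------------------------------------

def _disc_mask(shape, cx, cy, r):
    h, w = shape
    x0, x1 = max(0, int(cx - r - 1)), min(w, int(cx + r + 2))
    y0, y1 = max(0, int(cy - r - 1)), min(h, int(cy + r + 2))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2, (y0, y1, x0, x1)


def measure_intensities(
    detections: list[CellDetection],
    gf_raster: np.ndarray,
    cf_raster: np.ndarray,
    annulus_gap_px: float = 2.0,
    annulus_width_px: float = 3.0,
) -> list[CellDetection]:
    """Attach background-corrected GF/CF intensities to each detection.

    Per channel: mean over the detection disc minus the median over a
    concentric annulus (inner radius ``r + annulus_gap``, width
    ``annulus_width``).  Annulus pixels inside any other detection's disc are
    excluded so touching cells do not bias each other's background.  A disc
    clipped by the image border is measured on the clipped region and flagged
    ``"edge"``; an annulus left empty falls back to the whole-image median and
    is flagged ``"no-annulus"``.
    """
    gf = np.asarray(gf_raster, dtype=float)
    cf = np.asarray(cf_raster, dtype=float)
    if gf.shape != cf.shape:
        raise ValueError("gf and cf rasters must share a shape")
    h, w = gf.shape

    occupied = np.zeros((h, w), dtype=bool)
    for d in detections:
        m, (y0, y1, x0, x1) = _disc_mask(
            (h, w), d.center_x_px, d.center_y_px, d.radius_px
        )
        occupied[y0:y1, x0:x1] |= m

    out: list[CellDetection] = []
    for d in detections:
        cx, cy, r = d.center_x_px, d.center_y_px, d.radius_px
        r_out = r + annulus_gap_px + annulus_width_px
        x0, x1 = max(0, int(cx - r_out - 1)), min(w, int(cx + r_out + 2))
        y0, y1 = max(0, int(cy - r_out - 1)), min(h, int(cy + r_out + 2))
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        disc = d2 <= r**2
        annulus = (d2 >= (r + annulus_gap_px) ** 2) & (d2 <= r_out**2)
        annulus &= ~occupied[y0:y1, x0:x1]

        flags = list(d.flags)
        if cx - r < 0 or cx + r > w - 1 or cy - r < 0 or cy + r > h - 1:
            flags.append("edge")
        if not disc.any():  # center off-raster after clipping
            flags.append("empty-disc")
            out.append(replace(d, gf_intensity=float("nan"),
                               cf_intensity=float("nan"), flags=tuple(flags)))
            continue

        vals = {}
        for name, ch in (("gf", gf), ("cf", cf)):
            sub = ch[y0:y1, x0:x1]
            if annulus.any():
                bg = float(np.median(sub[annulus]))
            else:
                bg = float(np.median(ch))
                if "no-annulus" not in flags:
                    flags.append("no-annulus")
            vals[name] = float(sub[disc].mean()) - bg
        out.append(
            replace(
                d,
                gf_intensity=vals["gf"],
                cf_intensity=vals["cf"],
                flags=tuple(flags),
            )
        )
    return out


# --------------------------------------------------------------------------
# File input (formats written by the synthetic-field generator)
# --------------------------------------------------------------------------

def load_field(tiff_path: str | Path) -> FieldImage:
    """Read a multi-page TIFF (pages BF, GF, CF) plus its JSON sidecar."""
    import tifffile

    tiff_path = Path(tiff_path)
    pages = tifffile.imread(tiff_path)
    if pages.ndim != 3 or pages.shape[0] != 3:
        raise ValueError(f"{tiff_path}: expected 3 pages (BF, GF, CF)")
    sidecar = tiff_path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())["field_spec"]
    return FieldImage(
        bf=pages[0],
        gf=pages[1],
        cf=pages[2],
        pixel_size_um=float(meta["pixel_size_um"]),
        depth_um=float(meta["depth_um"]),
        field_id=tiff_path.stem,
    )


def load_field_channels(
    bf_path: str | Path,
    gf_path: str | Path,
    cf_path: str | Path,
    pixel_size_um: float,
    depth_um: float,
) -> FieldImage:
    """Read one PNG (or any Pillow-readable image) per channel."""
    from PIL import Image

    def read(p):
        return np.asarray(Image.open(p), dtype=float)

    return FieldImage(
        bf=read(bf_path),
        gf=read(gf_path),
        cf=read(cf_path),
        pixel_size_um=pixel_size_um,
        depth_um=depth_um,
        field_id=Path(gf_path).stem,
    )
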