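"""Extract representative RGB values from strip photographs.

The human picks the pixel locations (a pad center, a reference swatch
center); the machine reads the color there, optionally averaging over a
small centered square neighborhood — 1, 3 or 5 pixels on a side — to
damp pixel-level noise. Reading the reference swatches from the *same*
photograph as the strip lets shared lighting effects cancel downstream.

Coordinates are 0-based with ``x`` the column (rightward) and ``y`` the
row (downward), origin at the top-left, matching raster conventions.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image

from .chart_model import ChartError, ReferenceChart, RGBColor

__all__ = [
    "ImageRaster",
    "SamplePoint",
    "CoordinatesError",
    "load_image",
    "sample_rgb",
    "read_coordinates",
    "write_coordinates",
    "resample_chart_from_image",
    "VALID_WINDOWS",
]

log = logging.getLogger(__name__)

VALID_WINDOWS = (1, 3, 5)

COORD_HEADER = ["role", "analyte", "level_label", "x", "y", "window"]


class CoordinatesError(ValueError):
    """Malformed coordinates CSV; message carries the line number."""


@dataclass(frozen=True)
class ImageRaster:
    """An 8-bit, 3-channel image held as a read-only (H, W, 3) array."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) pixel array, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must be at least 1x1")
        px = px.astype(np.uint8, copy=False)
        px.setflags(write=False)
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def contains(self, x: int, y: int) -> bool:
        return 0 <= x < self.width and 0 <= y < self.height


@dataclass(frozen=True)
class SamplePoint:
    """A human-selected sampling location.

    ``role`` is ``"test"`` for a reacted pad or ``"reference"`` for a chart
    swatch; reference points must carry the ``level_label`` they depict.
    """

    role: str
    analyte: str
    x: int
    y: int
    window: int = 1
    level_label: str = ""

    def __post_init__(self) -> None:
        if self.role not in ("test", "reference"):
            raise ValueError(f"role must be 'test' or 'reference', got {self.role!r}")
        if self.window not in VALID_WINDOWS:
            raise ValueError(f"window must be 1, 3 or 5, got {self.window}")
        if self.role == "reference" and not self.level_label:
            raise ValueError(f"reference point for {self.analyte!r} is missing level_label")


def load_image(path: str | Path) -> ImageRaster:
    """Load a PNG or JPEG as an 8-bit RGB raster.

    Alpha is dropped; palette and 16-bit images are converted/rescaled to
    8-bit RGB. JPEG input is accepted with a logged warning, since lossy
    compression perturbs the very colors being measured.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            if (im.format or "").upper() == "JPEG":
                log.warning("%s is JPEG; lossy compression perturbs sampled colors", path)
            if im.mode in ("I", "I;16", "I;16B", "I;16L"):
                # 16-bit grayscale: rescale to 8-bit before RGB expansion
                wide = np.asarray(im, dtype=np.uint32)
                arr = np.repeat((wide // 257).astype(np.uint8)[..., None], 3, axis=2)
            else:
                converted = im.convert("RGB")
                arr = np.asarray(converted, dtype=np.uint8)
    except FileNotFoundError:
        raise
    except (OSError, ValueError) as e:
        raise OSError(f"cannot read image {path}: {e}") from e
    return ImageRaster(arr)


def sample_rgb(img: ImageRaster, point: SamplePoint) -> RGBColor:
    """Mean color over the window x window square centered at the point.

    The square is intersected with the raster bounds (edge clipping shrinks
    it; no padding is invented). The mean is real-valued and deliberately
    not re-rounded — rounding would discard the noise reduction that the
    averaging buys. Window 1 returns the raw pixel exactly.
    """
    x, y, w = point.x, point.y, point.window
    if not img.contains(x, y):
        raise ValueError(
            f"sample point ({x}, {y}) outside {img.width}x{img.height} raster"
        )
    half = w // 2
    block = img.pixels[
        max(0, y - half) : min(img.height, y + half + 1),
        max(0, x - half) : min(img.width, x + half + 1),
    ]
    mean = block.reshape(-1, 3).mean(axis=0, dtype=np.float64)
    return RGBColor(float(mean[0]), float(mean[1]), float(mean[2]))


def read_coordinates(path: str | Path) -> list[SamplePoint]:
    """Read sample points from a coordinates CSV.

    Normative header: ``role,analyte,level_label,x,y,window`` with
    ``level_label`` empty on test rows. Errors report the 1-based line
    number of the offending row.
    """
    points: list[SamplePoint] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != COORD_HEADER:
            raise CoordinatesError(
                f"{path}: expected header {','.join(COORD_HEADER)!r}, got {header!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 6:
                raise CoordinatesError(f"{path}:{lineno}: expected 6 fields, got {len(row)}")
            role, analyte, label, xs, ys, ws = (c.strip() for c in row)
            try:
                x, y, window = int(xs), int(ys), int(ws)
            except ValueError:
                raise CoordinatesError(
                    f"{path}:{lineno}: x, y and window must be integers"
                ) from None
            if window not in VALID_WINDOWS:
                raise CoordinatesError(f"{path}:{lineno}: window must be 1, 3 or 5, got {window}")
            try:
                points.append(
                    SamplePoint(role=role, analyte=analyte, level_label=label, x=x, y=y, window=window)
                )
            except ValueError as e:
                raise CoordinatesError(f"{path}:{lineno}: {e}") from None
    return points


def write_coordinates(points: list[SamplePoint], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(COORD_HEADER)
        for p in points:
            writer.writerow([p.role, p.analyte, p.level_label, p.x, p.y, p.window])


def resample_chart_from_image(
    img: ImageRaster, chart: ReferenceChart, points: list[SamplePoint]
) -> ReferenceChart:
    """Replace chart colors with colors sampled off this photograph.

    Every ``reference`` point must name an (analyte, level_label) present
    in the chart; the matching level keeps its concentration but takes the
    sampled color. Analytes with no reference points keep their file
    colors. This realizes same-image comparison: test pads and reference
    swatches then share the photograph's lighting, which cancels out of
    the distance ranking under uniform illumination changes.
    """
    sampled: dict[str, dict[str, RGBColor]] = {}
    for p in points:
        if p.role != "reference":
            continue
        if p.analyte not in chart:
            raise ChartError(f"reference point names unknown analyte {p.analyte!r}")
        key = chart[p.analyte]
        try:
            key.level_by_label(p.level_label)
        except KeyError as e:
            raise ChartError(str(e)) from None
        sampled.setdefault(p.analyte, {})[p.level_label] = sample_rgb(img, p)

    out = chart
    for analyte, colors in sampled.items():
        key = chart[analyte]
        new_levels = tuple(
            replace(lv, color=colors.get(lv.label, lv.color)) for lv in key.levels
        )
        out = out.with_key(replace(key, levels=new_levels))
    return out
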