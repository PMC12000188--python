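"""Synthetic strip photographs with known ground truth.

Field photographs of reacted strips are not reproducible inputs, so this
module renders them: a canvas holding one colored pad per analyte (its
color determined by a known true concentration through the chart's color
key) next to the chart's reference swatches, the whole canvas passed
through a parameterized lighting model (per-channel gain and offset, a
linear shadow ramp, per-pixel Gaussian noise) before 8-bit quantization.
Because the reference swatches are rendered *in* the image, the
same-image sampling protocol — and the lighting cancellation it buys —
can be exercised end to end.

The forward color model is the piecewise-linear blend between adjacent
chart colors. That is exactly the model under which IDW interpolation is
the correct inverse, so noiseless recovery of the generating
concentration is a sharp correctness test of the whole pipeline rather
than a fuzzy one.

What this emulates about real data: known concentrations, shared
illumination between pad and chart, mild shadowing, sensor noise,
quantization. What it does not: strip chemistry (reaction kinetics,
temperature), perspective and lens distortion, JPEG artifacts,
non-linear camera response.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from PIL import Image

from .chart_model import AnalyteKey, ReferenceChart, RGBColor
from .color_sampling import ImageRaster, SamplePoint, sample_rgb, write_coordinates
from .quant_core import quantify
from .color_sampling import resample_chart_from_image
from .validation_stats import pearson_r, PairedSeries

__all__ = [
    "LightingModel",
    "Rect",
    "SyntheticScene",
    "conc_to_color",
    "make_scene",
    "render_array",
    "render_scene",
    "sample_points_for_scene",
    "recover_scene",
    "recovery_experiment",
    "default_chart",
]

BACKGROUND = (235, 235, 235)


@dataclass(frozen=True)
class LightingModel:
    """Global illumination and sensor perturbations applied to a canvas.

    ``gain``/``offset`` act per channel (``pixel*gain + offset``); the
    shadow multiplies all channels by ``1 - strength*s`` where ``s`` runs
    linearly from 0 to 1 across the canvas along ``shadow_direction``.
    Gaussian noise (``noise_sd``, 8-bit intensity units) is added per
    pixel per channel after lighting; everything is then clipped to
    [0, 255] and quantized. The default is the identity.
    """

    gain: tuple[float, float, float] = (1.0, 1.0, 1.0)
    offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    shadow_direction: tuple[float, float] = (1.0, 0.0)
    shadow_strength: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(g <= 0 for g in self.gain):
            raise ValueError("gain factors must be positive")
        if not 0.0 <= self.shadow_strength < 1.0:
            raise ValueError("shadow_strength must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @classmethod
    def uniform(cls, gain: float = 1.0, offset: float = 0.0, **kw) -> "LightingModel":
        """Same gain and offset on every channel (clip-free affine light)."""
        return cls(gain=(gain,) * 3, offset=(offset,) * 3, **kw)


@dataclass(frozen=True)
class Rect:
    """Axis-aligned pixel rectangle, origin top-left, half-open extents."""

    x: int
    y: int
    w: int
    h: int

    @property
    def center(self) -> tuple[int, int]:
        return self.x + self.w // 2, self.y + self.h // 2

    def overlaps(self, other: "Rect") -> bool:
        return not (
            self.x + self.w <= other.x
            or other.x + other.w <= self.x
            or self.y + self.h <= other.y
            or other.y + other.h <= self.y
        )


@dataclass(frozen=True)
class SyntheticScene:
    """Complete recipe for one renderable strip photograph.

    ``pad_rects`` maps analyte -> pad rectangle; ``swatch_rects`` maps
    (analyte, level_label) -> swatch rectangle. Truths must lie within
    each analyte's chart range, and all rectangles must be disjoint and
    in bounds.
    """

    chart: ReferenceChart
    truths: dict[str, float]
    pad_rects: dict[str, Rect]
    swatch_rects: dict[tuple[str, str], Rect]
    width: int
    height: int
    lighting: LightingModel = field(default_factory=LightingModel)

    def __post_init__(self) -> None:
        for analyte, v in self.truths.items():
            lo, hi = self.chart[analyte].conc_range
            if not lo <= v <= hi:
                raise ValueError(
                    f"truth {v} for {analyte!r} outside chart range [{lo}, {hi}]"
                )
        rects = list(self.pad_rects.values()) + list(self.swatch_rects.values())
        for r in rects:
            if r.x < 0 or r.y < 0 or r.x + r.w > self.width or r.y + r.h > self.height:
                raise ValueError(f"rectangle {r} out of {self.width}x{self.height} bounds")
        for i, a in enumerate(rects):
            for b in rects[i + 1 :]:
                if a.overlaps(b):
                    raise ValueError(f"rectangles {a} and {b} overlap")


def conc_to_color(key: AnalyteKey, v: float) -> RGBColor:
    """Forward model: chart color for a concentration.

    Locates the bracketing levels by concentration and blends their
    colors componentwise at ``t = (v - V1)/(V2 - V1)``; a reference
    concentration returns that reference color exactly.
    """
    concs = key.concentrations
    if not concs[0] <= v <= concs[-1]:
        raise ValueError(
            f"{key.analyte!r}: concentration {v} outside chart range [{concs[0]}, {concs[-1]}]"
        )
    i = int(np.searchsorted(concs, v, side="right")) - 1
    if i >= len(concs) - 1:
        return key.levels[-1].color
    lo, hi = key.levels[i], key.levels[i + 1]
    t = (v - lo.concentration) / (hi.concentration - lo.concentration)
    return RGBColor(
        *(a + t * (b - a) for a, b in zip(lo.color, hi.color))
    )


def make_scene(
    chart: ReferenceChart,
    truths: Mapping[str, float],
    lighting: LightingModel | None = None,
    pad_size: int = 12,
    gap: int = 4,
    margin: int = 8,
) -> SyntheticScene:
    """Lay out a scene: one row per analyte, pad at the left, the chart's
    reference swatches to its right (all rendered into the same image)."""
    lighting = lighting or LightingModel()
    truths = dict(truths)
    pad_rects: dict[str, Rect] = {}
    swatch_rects: dict[tuple[str, str], Rect] = {}
    step = pad_size + gap
    y = margin
    max_levels = 0
    for key in chart:
        if key.analyte not in truths:
            continue
        pad_rects[key.analyte] = Rect(margin, y, pad_size, pad_size)
        x = margin + step + gap  # extra gap separates pad from swatch strip
        for lv in key.levels:
            swatch_rects[(key.analyte, lv.label)] = Rect(x, y, pad_size, pad_size)
            x += step
        max_levels = max(max_levels, len(key.levels))
        y += step
    if not pad_rects:
        raise ValueError("no truths matched any chart analyte")
    width = margin * 2 + step + gap + max_levels * step
    height = y - gap + margin
    return SyntheticScene(
        chart=chart,
        truths=truths,
        pad_rects=pad_rects,
        swatch_rects=swatch_rects,
        width=width,
        height=height,
        lighting=lighting,
    )


def _shadow_field(scene: SyntheticScene) -> np.ndarray:
    lm = scene.lighting
    if lm.shadow_strength == 0.0:
        return np.ones((scene.height, scene.width, 1))
    dx, dy = lm.shadow_direction
    norm = float(np.hypot(dx, dy))
    if norm == 0.0:
        return np.ones((scene.height, scene.width, 1))
    xs = np.arange(scene.width) / max(scene.width - 1, 1)
    ys = np.arange(scene.height) / max(scene.height - 1, 1)
    proj = (dx / norm) * xs[None, :] + (dy / norm) * ys[:, None]
    lo, hi = proj.min(), proj.max()
    s = (proj - lo) / (hi - lo) if hi > lo else np.zeros_like(proj)
    return (1.0 - lm.shadow_strength * s)[..., None]


def render_array(scene: SyntheticScene) -> np.ndarray:
    """Render the scene to an (H, W, 3) uint8 array.

    Paint order: background, analyte pads at their truth colors, chart
    swatches at their chart colors; then gain/offset, shadow, noise,
    clip, quantize. Deterministic for a fixed lighting seed.
    """
    canvas = np.empty((scene.height, scene.width, 3), dtype=np.float64)
    canvas[:] = BACKGROUND
    for analyte, rect in scene.pad_rects.items():
        color = conc_to_color(scene.chart[analyte], scene.truths[analyte])
        canvas[rect.y : rect.y + rect.h, rect.x : rect.x + rect.w] = color
    for (analyte, label), rect in scene.swatch_rects.items():
        color = scene.chart[analyte].level_by_label(label).color
        canvas[rect.y : rect.y + rect.h, rect.x : rect.x + rect.w] = color

    lm = scene.lighting
    canvas = canvas * np.asarray(lm.gain) + np.asarray(lm.offset)
    canvas *= _shadow_field(scene)
    if lm.noise_sd > 0:
        rng = np.random.default_rng(lm.seed)
        canvas += rng.normal(0.0, lm.noise_sd, canvas.shape)
    return np.clip(np.rint(canvas), 0, 255).astype(np.uint8)


def sample_points_for_scene(scene: SyntheticScene, window: int = 5) -> list[SamplePoint]:
    """Window-``window`` sample points at every pad and swatch center."""
    pts = []
    for analyte, rect in scene.pad_rects.items():
        cx, cy = rect.center
        pts.append(SamplePoint(role="test", analyte=analyte, x=cx, y=cy, window=window))
    for (analyte, label), rect in scene.swatch_rects.items():
        cx, cy = rect.center
        pts.append(
            SamplePoint(
                role="reference", analyte=analyte, level_label=label, x=cx, y=cy, window=window
            )
        )
    return pts


def render_scene(scene: SyntheticScene, out_dir: str | Path) -> dict[str, Path]:
    """Render to disk: PNG image, coordinates CSV, truth CSV, scene JSON.

    The scene JSON records the lighting parameters and seed so every
    output is reproducible bit for bit from it.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    arr = render_array(scene)
    image_path = out_dir / "strip.png"
    Image.fromarray(arr, mode="RGB").save(image_path)

    coords_path = out_dir / "coordinates.csv"
    write_coordinates(sample_points_for_scene(scene), coords_path)

    truth_path = out_dir / "truth.csv"
    pd.DataFrame(
        [{"analyte": a, "true_concentration": v} for a, v in scene.truths.items()]
    ).to_csv(truth_path, index=False)

    lm = scene.lighting
    meta_path = out_dir / "scene.json"
    meta_path.write_text(
        json.dumps(
            {
                "seed": lm.seed,
                "gain": list(lm.gain),
                "offset": list(lm.offset),
                "shadow_direction": list(lm.shadow_direction),
                "shadow_strength": lm.shadow_strength,
                "noise_sd": lm.noise_sd,
                "width": scene.width,
                "height": scene.height,
                "truths": scene.truths,
            },
            indent=2,
        )
    )
    return {"image": image_path, "coordinates": coords_path, "truth": truth_path, "scene": meta_path}


def recover_scene(
    scene: SyntheticScene,
    window: int = 5,
    resample_chart: bool = True,
    arr: np.ndarray | None = None,
) -> dict[str, float]:
    """Run the full sample -> resample-chart -> quantify pipeline on a
    rendered scene, returning per-analyte concentration estimates."""
    raster = ImageRaster(render_array(scene) if arr is None else arr)
    points = sample_points_for_scene(scene, window=window)
    chart = scene.chart
    if resample_chart:
        chart = resample_chart_from_image(raster, chart, points)
    readings = {
        p.analyte: sample_rgb(raster, p) for p in points if p.role == "test"
    }
    results = quantify(chart, readings)
    return {a: r.concentration for a, r in results.items()}


TruthSampler = Callable[[np.random.Generator, AnalyteKey], float]


def uniform_truth_sampler(rng: np.random.Generator, key: AnalyteKey) -> float:
    """Default truth distribution: uniform over the analyte's chart range."""
    lo, hi = key.conc_range
    return float(rng.uniform(lo, hi))


def recovery_experiment(
    chart: ReferenceChart,
    n_strips: int,
    lighting: LightingModel | None = None,
    truth_sampler: TruthSampler = uniform_truth_sampler,
    seed: int = 0,
    window: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """In-silico validation: render strips, recover, compare to truth.

    Renders ``n_strips`` scenes with truths drawn per analyte from
    ``truth_sampler``, pushes each through the full pipeline and joins
    estimates to truths. Returns ``(table, summary)``: the long table of
    (strip, analyte, truth, estimate) and a per-analyte summary with
    bias, RMSE and Pearson r between truth and estimate. Fully
    reproducible from (chart, lighting, seed).
    """
    if n_strips < 2:
        raise ValueError("need at least 2 strips")
    base = lighting or LightingModel()
    rng = np.random.default_rng(seed)

    # draw all truths up front so a bad sampler is rejected before rendering
    rejected = 0
    all_truths: list[dict[str, float]] = []
    strip_seeds: list[int] = []
    for _ in range(n_strips):
        truths = {}
        for key in chart:
            v = truth_sampler(rng, key)
            lo, hi = key.conc_range
            if not lo <= v <= hi:
                rejected += 1
            truths[key.analyte] = v
        all_truths.append(truths)
        strip_seeds.append(int(rng.integers(0, 2**31 - 1)))
    if rejected:
        raise ValueError(
            f"truth sampler produced {rejected} out-of-range value(s); fix the sampler"
        )

    rows = []
    for i, (truths, strip_seed) in enumerate(zip(all_truths, strip_seeds)):
        scene = make_scene(
            chart,
            truths,
            lighting=LightingModel(
                gain=base.gain,
                offset=base.offset,
                shadow_direction=base.shadow_direction,
                shadow_strength=base.shadow_strength,
                noise_sd=base.noise_sd,
                seed=strip_seed,
            ),
        )
        estimates = recover_scene(scene, window=window)
        for analyte, est in estimates.items():
            rows.append(
                {"strip": i, "analyte": analyte, "truth": truths[analyte], "estimate": est}
            )
    table = pd.DataFrame(rows)

    summaries = []
    for analyte, sub in table.groupby("analyte", sort=False):
        err = sub["estimate"] - sub["truth"]
        r = pearson_r(
            PairedSeries("truth", "estimate", tuple(sub["truth"]), tuple(sub["estimate"]))
        )
        summaries.append(
            {
                "analyte": analyte,
                "n": len(sub),
                "bias": float(err.mean()),
                "rmse": float(np.sqrt((err**2).mean())),
                "r": r,
            }
        )
    return table, pd.DataFrame(summaries)


# ---------------------------------------------------------------------------
# Default synthetic chart
# ---------------------------------------------------------------------------

# Eleven analytes typical of 16-in-one drinking-water strips, with
# plausible level ladders. The swatch colors are synthetic: hand-chosen
# monotone ramps with pairwise within-key distances >= 30 so the keys are
# well separable. They are NOT a transcription of any manufacturer sheet.
_DEFAULT_CHART_SPEC: dict[str, tuple[str, list[tuple[tuple[int, int, int], float]]]] = {
    "Total Chlorine": ("mg/L", [
        ((250, 250, 210), 0.0), ((230, 240, 160), 0.5), ((180, 220, 120), 1.0),
        ((120, 190, 110), 3.0), ((60, 150, 120), 5.0), ((20, 100, 110), 10.0),
    ]),
    "Free Chlorine": ("mg/L", [
        ((250, 245, 220), 0.0), ((240, 220, 160), 0.25), ((230, 180, 120), 0.5),
        ((210, 130, 110), 1.0), ((180, 80, 110), 2.0), ((140, 40, 100), 5.0),
    ]),
    "Iron": ("mg/L", [
        ((250, 240, 220), 0.0), ((240, 190, 150), 0.3), ((225, 140, 100), 0.5),
        ((200, 90, 60), 1.0), ((160, 50, 30), 2.0),
    ]),
    "Total Hardness": ("mg/L", [
        ((90, 160, 200), 0.0), ((120, 140, 190), 25.0), ((150, 120, 180), 50.0),
        ((175, 95, 165), 120.0), ((195, 70, 145), 250.0), ((210, 45, 120), 425.0),
    ]),
    "Lead": ("mg/L", [
        ((245, 235, 200), 0.0), ((215, 210, 150), 0.005), ((180, 185, 110), 0.015),
        ((140, 160, 80), 0.03), ((100, 135, 60), 0.05),
    ]),
    "pH": ("", [
        ((220, 60, 40), 6.0), ((230, 110, 40), 6.4), ((235, 160, 45), 6.8),
        ((230, 210, 60), 7.2), ((180, 215, 70), 7.6), ((120, 200, 90), 8.0),
        ((60, 170, 110), 8.4),
    ]),
    "Total Alkalinity": ("mg/L", [
        ((230, 230, 120), 0.0), ((190, 215, 110), 40.0), ((150, 200, 110), 80.0),
        ((110, 180, 120), 120.0), ((75, 155, 130), 180.0), ((45, 125, 135), 240.0),
    ]),
    "Nitrite": ("mg/L", [
        ((250, 250, 250), 0.0), ((250, 220, 230), 0.5), ((245, 180, 205), 1.0),
        ((235, 135, 180), 3.0), ((220, 90, 150), 5.0), ((200, 50, 120), 10.0),
    ]),
    "Nitrate": ("mg/L", [
        ((252, 250, 248), 0.0), ((250, 215, 220), 10.0), ((245, 175, 190), 25.0),
        ((235, 130, 155), 50.0), ((220, 85, 120), 100.0), ((200, 45, 90), 250.0),
    ]),
    "Copper": ("mg/L", [
        ((240, 225, 200), 0.0), ((210, 200, 150), 0.2), ((170, 180, 120), 0.5),
        ((120, 160, 110), 1.0), ((70, 135, 105), 2.0),
    ]),
    "Cyanuric Acid": ("mg/L", [
        ((250, 250, 240), 0.0), ((225, 235, 200), 30.0), ((195, 220, 170), 50.0),
        ((160, 200, 150), 100.0), ((120, 175, 135), 150.0), ((80, 150, 125), 240.0),
    ]),
}


def default_chart() -> ReferenceChart:
    """The synthetic 11-analyte chart used throughout tests and examples."""
    from .chart_model import chart_from_dict

    decimals = {"Lead": 4, "Copper": 3, "Iron": 3, "Free Chlorine": 3}
    return chart_from_dict(
        {
            "metadata": {
                "source": "synthetic 11-analyte chart (not a manufacturer transcription)",
                "version": "1",
            },
            "analytes": [
                {
                    "name": name,
                    "units": units,
                    "decimals": decimals.get(name, 2),
                    "levels": [
                        {"color": list(color), "concentration": conc, "label": f"L{i}"}
                        for i, (color, conc) in enumerate(levels)
                    ],
                }
                for name, (units, levels) in _DEFAULT_CHART_SPEC.items()
            ],
        }
    )
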