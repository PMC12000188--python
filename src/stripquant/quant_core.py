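"""Color-to-concentration quantification.

The method mirrors what a careful human does with a reference chart, then
goes one step further. A sampled pad color is first matched to the
reference swatch at minimum Euclidean distance in RGB space,

    D = sqrt((R1-R2)^2 + (G1-G2)^2 + (B1-B2)^2),

which yields the discrete chart level a person would read off. To recover
a *continuous* estimate, the color is then interpolated between a
bracketing pair of reference levels — one at lower, one at higher
concentration — by inverse distance weighting (IDW):

    W_i = 1 / D_i,    V = (W1*V1 + W2*V2) / (W1 + W2),

where V1, V2 are the bracket concentrations and D1, D2 the color
distances to the bracket swatches. When the pad color lies on the RGB
segment joining the bracket colors at fraction t, IDW reduces exactly to
linear interpolation V1 + t*(V2 - V1); in general the estimate always
stays within [V1, V2] (no extrapolation beyond the chart).

Bracket choice: the partner of the nearest level is whichever of its
concentration-adjacent neighbors (the level immediately below or above it
in the sorted key) is closer in color. Taking the *globally* second-
nearest color instead could pick a level on the same concentration side,
which would not give a lower/higher pair on non-monotone color keys.

Zero distance short-circuits to the exact reference concentration — the
IDW limit as D_i -> 0 — so the estimator is continuous. Exact distance
ties are broken toward the lower concentration (conservative for
contaminants) and flagged.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .chart_model import AnalyteKey, ReferenceChart, ReferenceLevel, RGBColor

__all__ = [
    "MatchResult",
    "color_distance",
    "nearest_level",
    "select_bracket",
    "idw_interpolate",
    "quantify",
    "write_results_csv",
    "RESULTS_HEADER",
]

RESULTS_HEADER = [
    "analyte",
    "units",
    "concentration",
    "nearest_label",
    "nearest_distance",
    "partner_label",
    "partner_distance",
    "exact_match",
    "endpoint",
    "tie_broken",
]


@dataclass(frozen=True)
class MatchResult:
    """Full audit trail of one analyte's quantification.

    ``nearest`` is the minimum-distance reference level; ``partner`` the
    other half of the bracket (absent only on an exact match, where no
    interpolation happens). ``endpoint`` flags colors matched to the first
    or last chart level, whose estimates should be read as "<= lowest" /
    ">= highest" rather than as interior interpolations.
    """

    analyte: str
    test_color: RGBColor
    nearest: ReferenceLevel
    nearest_distance: float
    concentration: float
    partner: ReferenceLevel | None = None
    partner_distance: float | None = None
    weights: tuple[float, float] | None = None
    exact_match: bool = False
    endpoint: bool = False
    tie_broken: bool = False

    def rounded_concentration(self, decimals: int = 2) -> float:
        return round(self.concentration, decimals)


def color_distance(a: RGBColor, b: RGBColor) -> float:
    """Euclidean distance between two colors in device RGB space."""
    return math.dist(a, b)


def nearest_level(key: AnalyteKey, c: RGBColor) -> tuple[ReferenceLevel, float, bool]:
    """Minimum-distance reference level for a test color.

    Returns ``(level, distance, tie_broken)``. On an exact distance tie
    the lower-concentration level wins (levels are concentration-sorted,
    so the first minimum encountered is the lower one).
    """
    if len(key.levels) < 2:
        raise ValueError(f"key for {key.analyte!r} needs at least 2 levels")
    distances = [color_distance(c, lv.color) for lv in key.levels]
    dmin = min(distances)
    i = distances.index(dmin)
    tie = distances.count(dmin) > 1
    return key.levels[i], dmin, tie


def select_bracket(
    key: AnalyteKey, c: RGBColor
) -> tuple[ReferenceLevel, ReferenceLevel, bool]:
    """Pick the lower/higher concentration pair to interpolate between.

    Anchored at the nearest level; the partner is its closer (in color)
    concentration-adjacent neighbor. An endpoint nearest level has a
    single neighbor, which becomes the partner, and the endpoint flag is
    set. Returns ``(low, high, endpoint)`` ordered by concentration.
    """
    r1, _, _ = nearest_level(key, c)
    i = key.levels.index(r1)
    endpoint = i == 0 or i == len(key.levels) - 1
    if i == 0:
        partner = key.levels[1]
    elif i == len(key.levels) - 1:
        partner = key.levels[i - 1]
    else:
        below, above = key.levels[i - 1], key.levels[i + 1]
        partner = (
            below
            if color_distance(c, below.color) <= color_distance(c, above.color)
            else above
        )
    low, high = (r1, partner) if r1.concentration < partner.concentration else (partner, r1)
    return low, high, endpoint


def idw_interpolate(
    c: RGBColor, low: ReferenceLevel, high: ReferenceLevel
) -> tuple[float, tuple[float, float] | None, bool]:
    """Inverse-distance-weighted concentration between a bracket pair.

    Returns ``(concentration, (W1, W2) or None, exact_match)``. A zero
    distance to either anchor short-circuits to that anchor's
    concentration (the continuous limit of the formula).
    """
    if not low.concentration < high.concentration:
        raise ValueError("bracket must satisfy low.concentration < high.concentration")
    d1 = color_distance(c, low.color)
    d2 = color_distance(c, high.color)
    if d1 == 0.0:
        return low.concentration, None, True
    if d2 == 0.0:
        return high.concentration, None, True
    w1, w2 = 1.0 / d1, 1.0 / d2
    v = (w1 * low.concentration + w2 * high.concentration) / (w1 + w2)
    return v, (w1, w2), False


def quantify_one(key: AnalyteKey, c: RGBColor) -> MatchResult:
    """Run the full match -> bracket -> interpolate chain for one color."""
    nearest, d1, tie = nearest_level(key, c)
    low, high, endpoint = select_bracket(key, c)
    v, weights, exact = idw_interpolate(c, low, high)
    if exact:
        # the zero-distance anchor is by construction the nearest level
        return MatchResult(
            analyte=key.analyte,
            test_color=c,
            nearest=nearest,
            nearest_distance=d1,
            concentration=nearest.concentration,
            partner=low if nearest is high else high,
            partner_distance=color_distance(c, (low if nearest is high else high).color),
            exact_match=True,
            endpoint=endpoint,
            tie_broken=tie,
        )
    partner = high if nearest is low else low
    return MatchResult(
        analyte=key.analyte,
        test_color=c,
        nearest=nearest,
        nearest_distance=d1,
        concentration=v,
        partner=partner,
        partner_distance=color_distance(c, partner.color),
        weights=weights,
        endpoint=endpoint,
        tie_broken=tie,
    )


def quantify(
    chart: ReferenceChart, readings: Mapping[str, RGBColor]
) -> dict[str, MatchResult]:
    """Quantify a set of per-analyte test colors against a chart.

    Deterministic; every result carries the intermediate distances,
    weights and flags for audit. Unknown analytes raise ``KeyError``
    naming the analyte.
    """
    return {analyte: quantify_one(chart[analyte], c) for analyte, c in readings.items()}


def write_results_csv(
    results: Mapping[str, MatchResult], chart: ReferenceChart, path: str | Path
) -> None:
    """Write one row per analyte; concentrations rounded per the chart's
    per-analyte decimal count."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(RESULTS_HEADER)
        for analyte, res in results.items():
            key = chart[analyte]
            writer.writerow(
                [
                    analyte,
                    key.units,
                    f"{res.rounded_concentration(key.decimals):.{key.decimals}f}",
                    res.nearest.label,
                    f"{res.nearest_distance:.4f}",
                    res.partner.label if res.partner else "",
                    f"{res.partner_distance:.4f}" if res.partner_distance is not None else "",
                    res.exact_match,
                    res.endpoint,
                    res.tie_broken,
                ]
            )
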