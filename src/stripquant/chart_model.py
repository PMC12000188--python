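"""Reference chart model: the machine-readable color key for a test strip.

A reference chart maps each analyte (free chlorine, lead, pH, ...) to an
ordered list of reference levels, each pairing a swatch color with a known
concentration. It is the digital analog of the manufacturer's printed
reference parameter sheet that a human would hold a reacted strip against.

Charts are stored as JSON::

    {"metadata": {"source": str, "version": str},
     "analytes": [{"name": str, "units": str,
                   "levels": [{"color": [r, g, b],
                               "concentration": number,
                               "label": str}]}]}

Chart file colors are integers 0-255 per channel (transcribed from sRGB
photographs); colors produced by window averaging elsewhere in the package
are real-valued, so :class:`RGBColor` holds floats.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, NamedTuple

__all__ = [
    "RGBColor",
    "ReferenceLevel",
    "AnalyteKey",
    "ReferenceChart",
    "ChartError",
    "Violation",
    "load_chart",
    "save_chart",
    "chart_from_dict",
    "chart_to_dict",
    "validate_chart",
]

#: Two reference swatches closer than this in Euclidean RGB distance are
#: flagged as poorly separable (a warning, not an error).
SEPARABILITY_WARN_DISTANCE = 5.0


class ChartError(ValueError):
    """Raised when a chart file or structure violates the chart contract."""


class RGBColor(NamedTuple):
    """A color as a point in device RGB space, channels in [0, 255].

    Real-valued so that neighborhood-averaged samples keep their
    fractional precision; raw pixels and chart entries are whole numbers.
    """

    r: float
    g: float
    b: float

    def validate(self) -> "RGBColor":
        for name, v in zip("rgb", self):
            if not math.isfinite(v) or not (0.0 <= v <= 255.0):
                raise ChartError(f"channel {name}={v!r} outside [0, 255]")
        return self


@dataclass(frozen=True)
class ReferenceLevel:
    """One swatch of a color key: a color at a known concentration."""

    color: RGBColor
    concentration: float
    label: str = ""


@dataclass(frozen=True)
class AnalyteKey:
    """Ordered color key for one analyte.

    Levels are kept sorted by strictly increasing concentration; the
    bracketing logic in :mod:`stripquant.quant_core` relies on this order.
    ``decimals`` controls display rounding of reported concentrations.
    """

    analyte: str
    units: str
    levels: tuple[ReferenceLevel, ...]
    decimals: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(self.levels))

    @property
    def concentrations(self) -> tuple[float, ...]:
        return tuple(lv.concentration for lv in self.levels)

    @property
    def conc_range(self) -> tuple[float, float]:
        return self.levels[0].concentration, self.levels[-1].concentration

    def level_by_label(self, label: str) -> ReferenceLevel:
        for lv in self.levels:
            if lv.label == label:
                return lv
        raise KeyError(f"analyte {self.analyte!r} has no level labeled {label!r}")


@dataclass(frozen=True)
class ReferenceChart:
    """A full chart: mapping of analyte name to its color key, plus metadata."""

    analytes: dict[str, AnalyteKey] = field(default_factory=dict)
    metadata: dict[str, str] = field(default_factory=dict)

    def __iter__(self) -> Iterator[AnalyteKey]:
        return iter(self.analytes.values())

    def __contains__(self, analyte: str) -> bool:
        return analyte in self.analytes

    def __getitem__(self, analyte: str) -> AnalyteKey:
        try:
            return self.analytes[analyte]
        except KeyError:
            raise KeyError(f"analyte {analyte!r} not in chart") from None

    def with_key(self, key: AnalyteKey) -> "ReferenceChart":
        analytes = dict(self.analytes)
        analytes[key.analyte] = key
        return replace(self, analytes=analytes)


@dataclass(frozen=True)
class Violation:
    """One chart-invariant violation or warning."""

    analyte: str
    rule: str
    message: str
    fatal: bool = True


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ChartError(msg)


def _parse_level(analyte: str, i: int, obj: object) -> ReferenceLevel:
    _require(isinstance(obj, dict), f"analytes[{analyte!r}].levels[{i}] is not an object")
    assert isinstance(obj, dict)
    color = obj.get("color")
    _require(
        isinstance(color, (list, tuple)) and len(color) == 3,
        f"analytes[{analyte!r}].levels[{i}].color must be a 3-element array",
    )
    for ch in color:
        _require(
            isinstance(ch, (int, float)) and not isinstance(ch, bool),
            f"analytes[{analyte!r}].levels[{i}].color has non-numeric channel {ch!r}",
        )
    conc = obj.get("concentration")
    _require(
        isinstance(conc, (int, float)) and not isinstance(conc, bool),
        f"analytes[{analyte!r}].levels[{i}].concentration must be a number",
    )
    label = obj.get("label", "")
    _require(isinstance(label, str), f"analytes[{analyte!r}].levels[{i}].label must be a string")
    try:
        rgb = RGBColor(*(float(c) for c in color)).validate()
    except ChartError as e:
        raise ChartError(f"analytes[{analyte!r}].levels[{i}].color: {e}") from None
    return ReferenceLevel(color=rgb, concentration=float(conc), label=label)


def chart_from_dict(doc: object) -> ReferenceChart:
    """Build a :class:`ReferenceChart` from a parsed chart JSON document.

    Levels are canonically re-sorted by concentration; the file order is
    not meaningful. Raises :class:`ChartError` naming the offending field
    on schema violations and the offending analyte on invariant violations.
    """
    _require(isinstance(doc, dict), "chart document root must be an object")
    assert isinstance(doc, dict)
    meta = doc.get("metadata", {})
    _require(isinstance(meta, dict), "metadata must be an object")
    analytes_doc = doc.get("analytes")
    _require(isinstance(analytes_doc, list), "analytes must be an array")

    analytes: dict[str, AnalyteKey] = {}
    for entry in analytes_doc:
        _require(isinstance(entry, dict), "analytes[] entries must be objects")
        name = entry.get("name")
        _require(isinstance(name, str) and name != "", "analytes[].name must be a non-empty string")
        _require(name not in analytes, f"duplicate analyte name {name!r}")
        units = entry.get("units", "")
        _require(isinstance(units, str), f"analytes[{name!r}].units must be a string")
        levels_doc = entry.get("levels")
        _require(isinstance(levels_doc, list), f"analytes[{name!r}].levels must be an array")
        levels = [_parse_level(name, i, lv) for i, lv in enumerate(levels_doc)]
        levels.sort(key=lambda lv: lv.concentration)
        # auto-label unlabeled levels so images can reference them
        levels = [
            replace(lv, label=lv.label or f"L{i}") for i, lv in enumerate(levels)
        ]
        decimals = entry.get("decimals", 2)
        _require(
            isinstance(decimals, int) and not isinstance(decimals, bool) and decimals >= 0,
            f"analytes[{name!r}].decimals must be a non-negative integer",
        )
        analytes[name] = AnalyteKey(analyte=name, units=units, levels=tuple(levels), decimals=decimals)

    chart = ReferenceChart(analytes=analytes, metadata={str(k): str(v) for k, v in meta.items()})
    fatal = [v for v in validate_chart(chart) if v.fatal]
    if fatal:
        first = fatal[0]
        raise ChartError(f"chart invariant violated for analyte {first.analyte!r}: {first.message}")
    return chart


def load_chart(path: str | Path) -> ReferenceChart:
    """Load and validate a reference chart from a JSON file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"chart file not found: {path}")
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ChartError(f"chart file {path} is not valid JSON: {e}") from e
    return chart_from_dict(doc)


def chart_to_dict(chart: ReferenceChart) -> dict:
    return {
        "metadata": dict(chart.metadata),
        "analytes": [
            {
                "name": key.analyte,
                "units": key.units,
                "decimals": key.decimals,
                "levels": [
                    {
                        "color": [lv.color.r, lv.color.g, lv.color.b],
                        "concentration": lv.concentration,
                        "label": lv.label,
                    }
                    for lv in key.levels
                ],
            }
            for key in chart
        ],
    }


def save_chart(chart: ReferenceChart, path: str | Path) -> None:
    """Write a chart back to JSON (inverse of :func:`load_chart`)."""
    Path(path).write_text(json.dumps(chart_to_dict(chart), indent=2))


def validate_chart(chart: ReferenceChart) -> list[Violation]:
    """Check every chart invariant, returning one record per violation.

    Fatal violations: fewer than two levels, non-increasing concentrations,
    duplicate swatch colors within a key (nearest-color matching would be
    ambiguous), negative concentration for a non-pH analyte, empty analyte
    name. Non-fatal warnings: two swatches of one key closer than
    ``SEPARABILITY_WARN_DISTANCE`` in RGB distance (poorly separable key).
    """
    out: list[Violation] = []
    for name, key in chart.analytes.items():
        if not name:
            out.append(Violation(name, "empty-name", "analyte name is empty"))
        if len(key.levels) < 2:
            out.append(
                Violation(name, "too-few-levels", f"key has {len(key.levels)} level(s); at least 2 required")
            )
        concs = key.concentrations
        for lo, hi in zip(concs, concs[1:]):
            if not hi > lo:
                out.append(
                    Violation(
                        name,
                        "non-increasing-concentration",
                        f"concentrations not strictly increasing: {lo} then {hi}",
                    )
                )
        is_ph = name.strip().lower() == "ph" or key.units == ""
        for lv in key.levels:
            if not math.isfinite(lv.concentration):
                out.append(Violation(name, "non-finite-concentration", f"level {lv.label!r} non-finite"))
            elif lv.concentration < 0 and not is_ph:
                out.append(
                    Violation(name, "negative-concentration", f"level {lv.label!r} concentration {lv.concentration} < 0")
                )
        for i, a in enumerate(key.levels):
            for b in key.levels[i + 1 :]:
                d = math.dist(a.color, b.color)
                if d == 0.0:
                    out.append(
                        Violation(
                            name,
                            "duplicate-color",
                            f"levels {a.label!r} and {b.label!r} share color {tuple(a.color)}",
                        )
                    )
                elif d < SEPARABILITY_WARN_DISTANCE:
                    out.append(
                        Violation(
                            name,
                            "poorly-separable",
                            f"levels {a.label!r} and {b.label!r} only {d:.2f} apart in RGB",
                            fatal=False,
                        )
                    )
    return out
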