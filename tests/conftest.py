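import math

import pytest

from stripquant import (
    AnalyteKey,
    ReferenceChart,
    ReferenceLevel,
    RGBColor,
)
from stripquant.synthetic_data import default_chart


def make_key(analyte, colors, concs, units="mg/L"):
    levels = tuple(
        ReferenceLevel(color=RGBColor(*c), concentration=float(v), label=f"L{i}")
        for i, (c, v) in enumerate(zip(colors, concs))
    )
    return AnalyteKey(analyte=analyte, units=units, levels=levels)


@pytest.fixture
def two_level_key():
    """Smallest useful key: yellow at 0, blue at 10."""
    return make_key("Demo", [(255, 255, 0), (0, 0, 255)], [0.0, 10.0])


@pytest.fixture
def chart11():
    return default_chart()


def quantization_tol(key, gain=1.0):
    """Worst-case concentration error from 8-bit quantization of a
    window-averaged sample interpolated between adjacent chart levels.

    Each sampled color is off by at most 0.5 per channel after rounding,
    so each anchor distance shifts by at most sqrt(3)/2; the interpolation
    parameter t = D1/(D1+D2) then shifts by at most 2*sqrt(3)/(2L) per
    perturbed distance pair, giving a concentration error bound of
    2*sqrt(3) * dV / (gain * L) per bracket, maximized over brackets.
    """
    worst = 0.0
    for lo, hi in zip(key.levels, key.levels[1:]):
        dv = hi.concentration - lo.concentration
        L = math.dist(lo.color, hi.color)
        worst = max(worst, 2.0 * math.sqrt(3.0) * dv / (gain * L))
    return worst
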