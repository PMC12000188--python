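"""Small bundled datasets.

* ``example_chart.json`` — the synthetic 11-analyte reference chart
  (identical to :func:`stripquant.synthetic_data.default_chart`); shipped
  so the CLI and examples have a concrete chart file to point at.
* ``field_study_correlations.csv`` — the published field-study
  correlation table for an n = 34 stream survey: per analyte, the Pearson
  r of the visual-read and of the hybrid human-machine strip method
  against laboratory measurements, with the printed 95% CI bounds and
  significance stars. Used as input to the statistical-machinery
  regression checks (the underlying per-sample data are not public).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .chart_model import ReferenceChart, load_chart

__all__ = ["example_chart_path", "example_chart", "field_study_correlations"]


def _data_path(name: str) -> Path:
    return Path(resources.files("stripquant") / "data" / name)


def example_chart_path() -> Path:
    return _data_path("example_chart.json")


def example_chart() -> ReferenceChart:
    return load_chart(example_chart_path())


def field_study_correlations() -> pd.DataFrame:
    """Published r / CI / stars per analyte and method (n = 34 throughout)."""
    return pd.read_csv(_data_path("field_study_correlations.csv"))
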