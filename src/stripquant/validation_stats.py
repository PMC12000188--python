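"""Method-agreement statistics for paired measurement series.

Implements the validation protocol used to compare strip-derived
concentrations against an independent method (typically laboratory
measurements): Pearson correlations with Fisher-z 95% confidence
intervals and significance stars, Bland–Altman bias and limits of
agreement with a proportional-bias check, and min–max standardized
site series for spatial trend inspection.

Conventions (each configurable where it matters):

* CIs are Fisher-z: ``tanh(atanh(r) ± z_crit/sqrt(n-3))``.
* p-values come from the t transform ``t = r*sqrt(n-2)/sqrt(1-r^2)``
  with n-2 degrees of freedom, two-sided.
* Stars: ``***`` for p ≤ 0.001, ``**`` for p ≤ 0.01, ``*`` for p ≤ 0.05.
* Limits of agreement are bias ± 1.96·SD of the differences (sample SD,
  n-1 denominator).
* Proportional bias is the OLS slope of the differences on the pair
  means, with its t-test.
* No multiple-testing correction is applied across analytes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedSeries",
    "CorrelationResult",
    "BlandAltmanResult",
    "pearson_r",
    "fisher_ci",
    "correlation_p",
    "significance_stars",
    "correlate",
    "bland_altman",
    "minmax_scale",
    "site_series_table",
    "compare_methods",
    "render_comparison_text",
]


@dataclass(frozen=True)
class PairedSeries:
    """Two equal-length measurement series on the same samples."""

    label_a: str
    label_b: str
    values_a: tuple[float, ...]
    values_b: tuple[float, ...]

    def __post_init__(self) -> None:
        a = tuple(float(v) for v in self.values_a)
        b = tuple(float(v) for v in self.values_b)
        if len(a) != len(b):
            raise ValueError(f"series lengths differ: {len(a)} vs {len(b)}")
        if any(not math.isfinite(v) for v in a + b):
            raise ValueError("paired series must not contain missing/non-finite entries")
        object.__setattr__(self, "values_a", a)
        object.__setattr__(self, "values_b", b)

    @property
    def n(self) -> int:
        return len(self.values_a)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    ci_low: float
    ci_high: float
    p: float
    stars: str


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    multiplier: float
    prop_bias_slope: float
    prop_bias_p: float
    n: int


def pearson_r(s: PairedSeries) -> float:
    """Product-moment correlation between the two series."""
    if s.n < 3:
        raise ValueError(f"need at least 3 pairs, got {s.n}")
    a, b = np.asarray(s.values_a), np.asarray(s.values_b)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant series")
    return float(stats.pearsonr(a, b).statistic)


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a correlation coefficient.

    ``tanh(atanh(r) ± z_crit / sqrt(n - 3))`` with z_crit the standard
    normal quantile for the requested two-sided level (1.96 at 0.95).
    Degenerate |r| = 1 returns ``(r, r)`` with a warning.
    """
    if n < 4:
        raise ValueError(f"Fisher CI needs n >= 4, got {n}")
    if abs(r) >= 1.0:
        warnings.warn("|r| = 1: Fisher CI is degenerate", stacklevel=2)
        return (r, r)
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    z = math.atanh(r)
    hw = zcrit / math.sqrt(n - 3)
    return (math.tanh(z - hw), math.tanh(z + hw))


def correlation_p(r: float, n: int) -> float:
    """Two-sided p-value for r via the exact t transform (df = n - 2)."""
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def significance_stars(p: float) -> str:
    """Star code for a p-value: *** ≤0.001 < ** ≤0.01 < * ≤0.05 < ''."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def correlate(s: PairedSeries, level: float = 0.95) -> CorrelationResult:
    """Pearson r with Fisher CI, p-value and stars, in one record."""
    if s.n < 4:
        raise ValueError(f"need at least 4 pairs for a CI, got {s.n}")
    r = pearson_r(s)
    lo, hi = fisher_ci(r, s.n, level)
    p = correlation_p(r, s.n)
    return CorrelationResult(r=r, n=s.n, ci_low=lo, ci_high=hi, p=p, stars=significance_stars(p))


def bland_altman(s: PairedSeries, multiplier: float = 1.96) -> BlandAltmanResult:
    """Bland–Altman agreement analysis of method A against method B.

    Differences are ``a - b``; bias is their mean, limits of agreement
    bias ± multiplier·SD (sample SD). Proportional bias — dependence of
    the difference on the measured magnitude — is the OLS slope of the
    differences on the pair means ``(a + b)/2``, with its two-sided
    t-test p-value (p = 1 when the differences are constant).
    """
    if s.n < 3:
        raise ValueError(f"Bland-Altman needs at least 3 pairs, got {s.n}")
    a, b = np.asarray(s.values_a), np.asarray(s.values_b)
    d = a - b
    means = (a + b) / 2.0
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    if np.ptp(means) == 0 or np.ptp(d) == 0:
        slope, p = 0.0, 1.0
    else:
        fit = stats.linregress(means, d)
        slope, p = float(fit.slope), float(fit.pvalue)
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - multiplier * sd,
        loa_high=bias + multiplier * sd,
        multiplier=multiplier,
        prop_bias_slope=slope,
        prop_bias_p=p,
        n=s.n,
    )


def minmax_scale(values: Sequence[float]) -> list[float]:
    """Rescale a series to [0, 1] by its observed range.

    A constant series maps to all zeros with a warning (its range is
    empty, so any placement is a convention).
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot scale an empty series")
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        warnings.warn("constant series: min-max scaling maps it to all zeros", stacklevel=2)
        return [0.0] * arr.size
    return list((arr - lo) / (hi - lo))


def site_series_table(
    records: Iterable[tuple[int, str, float]] | pd.DataFrame,
    cumulative: bool = False,
) -> pd.DataFrame:
    """Min–max standardized concentrations along an ordered site transect.

    ``records`` holds (site_order, analyte, concentration) triples — site
    order 1..n along the stream. Each analyte is standardized
    independently (scales must not mix). With ``cumulative=True`` a
    running sum of the standardized values down the transect is added,
    one reading of a "cumulative concentration" display; the plain
    standardized series is always present.
    """
    if isinstance(records, pd.DataFrame):
        df = records.loc[:, ["site_order", "analyte", "concentration"]].copy()
    else:
        df = pd.DataFrame(records, columns=["site_order", "analyte", "concentration"])
    if df.empty:
        raise ValueError("no site records")
    dup = df.duplicated(subset=["site_order", "analyte"])
    if dup.any():
        pairs = df.loc[dup, ["site_order", "analyte"]].itertuples(index=False, name=None)
        raise ValueError(f"duplicate (site, analyte) pairs: {sorted(set(pairs))}")
    df = df.sort_values(["analyte", "site_order"], kind="stable").reset_index(drop=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-series warning surfaces per analyte below
        df["standardized"] = df.groupby("analyte")["concentration"].transform(
            lambda s: pd.Series(minmax_scale(s.to_numpy()), index=s.index)
        )
    if cumulative:
        df["cumulative"] = df.groupby("analyte")["standardized"].cumsum()
    return df


def compare_methods(
    table: pd.DataFrame, lab_method: str = "laboratory", level: float = 0.95
) -> pd.DataFrame:
    """Correlate every field method against the reference method, per analyte.

    ``table`` is long-form with columns sample_id, analyte, method, value.
    For each analyte and each non-reference method sharing >= 4 samples
    with the reference method, reports r, the Fisher CI, p and stars.
    Rows are ordered by descending r of the ``human_machine`` method when
    present (the conventional report ordering), else by best method r.
    """
    required = {"sample_id", "analyte", "method", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"comparison table missing columns: {sorted(missing)}")
    if lab_method not in set(table["method"]):
        raise ValueError(f"reference method {lab_method!r} not present in table")

    rows = []
    for analyte, sub in table.groupby("analyte", sort=False):
        wide = sub.pivot_table(index="sample_id", columns="method", values="value")
        if lab_method not in wide.columns:
            continue
        for method in wide.columns:
            if method == lab_method:
                continue
            both = wide[[method, lab_method]].dropna()
            if len(both) < 4:
                raise ValueError(
                    f"analyte {analyte!r}, method {method!r}: only {len(both)} shared "
                    f"samples with {lab_method!r}; need >= 4 for a CI"
                )
            res = correlate(
                PairedSeries(method, lab_method, tuple(both[method]), tuple(both[lab_method])),
                level=level,
            )
            rows.append(
                {
                    "analyte": analyte,
                    "method": method,
                    "n": res.n,
                    "r": res.r,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p": res.p,
                    "stars": res.stars,
                }
            )
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError("no comparable (analyte, method) pairs found")
    sort_method = "human_machine" if "human_machine" in set(out["method"]) else None
    if sort_method is not None:
        order = (
            out[out["method"] == sort_method]
            .set_index("analyte")["r"]
            .sort_values(ascending=False)
        )
    else:
        order = out.groupby("analyte")["r"].max().sort_values(ascending=False)
    rank = {a: i for i, a in enumerate(order.index)}
    out["_rank"] = out["analyte"].map(lambda a: rank.get(a, len(rank)))
    out = (
        out.sort_values(["_rank", "method"], kind="stable")
        .drop(columns="_rank")
        .reset_index(drop=True)
    )
    return out


def render_comparison_text(report: pd.DataFrame) -> str:
    """Aligned plain-text rendering of a compare_methods report."""
    lines = [f"{'analyte':<20} {'method':<16} {'n':>3}  {'r':>5}  {'95% CI':<14} stars"]
    for row in report.itertuples(index=False):
        ci = f"[{row.ci_low:.2f}, {row.ci_high:.2f}]"
        lines.append(
            f"{row.analyte:<20} {row.method:<16} {row.n:>3}  {row.r:>5.2f}  {ci:<14} {row.stars}"
        )
    return "\n".join(lines)
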