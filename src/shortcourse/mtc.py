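"""Multiplicity correction with estimation of the number of true nulls.

Besides Bonferroni and Benjamini–Hochberg, the module estimates m0 — the
number of tested genes for which the null holds — from the shape of the
p-value distribution, and plugs it into an adjusted (adaptive) BH procedure.
Two estimators are provided.  The p-value-plot estimator fits a line to the
Schweder–Spjøtvoll plot N_p versus 1−p (N_p = count of p-values exceeding p),
whose slope is m0 when all hypotheses are null; the fit region grows greedily
from the large-p end while the fit's R² does not degrade.  The CDF estimator
compares the expected area under a uniform p-value CDF (1/2) with the
observed area; their ratio estimates the null proportion pi0.  Operating
tables translate an m0 estimate into sensitivity/specificity/FDR estimates
per significance threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, UsageError

__all__ = [
    "PValueSet",
    "PValuePlotData",
    "M0Estimate",
    "bonferroni",
    "benjamini_hochberg",
    "adjusted_fdr",
    "pvalue_plot",
    "estimate_m0_pplot",
    "estimate_m0_cdf",
    "operating_table",
    "plot_data",
    "default_alpha_grid",
]


@dataclass
class PValueSet:
    """A collection of per-probe p-values."""

    probe_ids: list[str]
    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 1 or self.p.size < 1:
            raise ParameterError("p must be a non-empty 1-D array")
        if len(self.probe_ids) != self.p.size:
            raise ParameterError("probe_ids and p must have equal length")
        if not np.all(np.isfinite(self.p)) or np.any((self.p < 0) | (self.p > 1)):
            raise ParameterError("p-values must be finite and in [0, 1]")

    @property
    def m(self) -> int:
        return self.p.size

    @classmethod
    def from_values(cls, p) -> "PValueSet":
        p = np.asarray(p, dtype=float)
        return cls([f"p{i}" for i in range(p.size)], p)


def _as_pset(pset) -> PValueSet:
    if isinstance(pset, PValueSet):
        return pset
    return PValueSet.from_values(pset)


@dataclass
class PValuePlotData:
    """Points of the N_p vs 1−p step plot, plus the fitted line if estimated."""

    x: np.ndarray  # 1 - p, ascending
    y: np.ndarray  # N_p = #{p-values strictly greater than p}
    slope: float | None = None
    intercept: float | None = None
    r2: float | None = None
    fit_points: int | None = None


def bonferroni(pset) -> np.ndarray:
    """Family-wise correction p_adj = min(1, m·p), in input order."""
    ps = _as_pset(pset)
    return np.minimum(1.0, ps.m * ps.p)


def _step_up(p: np.ndarray, multiplier: float) -> np.ndarray:
    """BH-style step-up with an arbitrary null-count multiplier."""
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * multiplier / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def benjamini_hochberg(pset) -> np.ndarray:
    """BH step-up q-values, mapped back to input order."""
    ps = _as_pset(pset)
    return _step_up(ps.p, float(ps.m))


def adjusted_fdr(pset, m0: float) -> np.ndarray:
    """BH step-up with the estimated null count m0 in place of m.

    With m0 = m this reduces to plain BH; smaller m0 sharpens every q-value
    proportionally.
    """
    ps = _as_pset(pset)
    if not 0 <= m0 <= ps.m:
        raise ParameterError(f"m0 must lie in [0, m={ps.m}], got {m0}")
    return _step_up(ps.p, float(m0))


def pvalue_plot(pset) -> PValuePlotData:
    """Schweder–Spjøtvoll plot: N_p (strictly greater than) vs 1−p per distinct p."""
    ps = _as_pset(pset)
    if ps.m < 2:
        raise ParameterError("p-value plot needs at least 2 p-values")
    distinct = np.unique(ps.p)  # ascending p
    counts = ps.m - np.searchsorted(np.sort(ps.p), distinct, side="right")
    # order points by ascending x = 1 - p (descending p)
    x = (1.0 - distinct)[::-1]
    y = counts[::-1].astype(float)
    return PValuePlotData(x=x, y=y)


@dataclass
class M0Estimate:
    """An estimate of the number (m0) and proportion (pi0) of true nulls."""

    method: str
    m: int
    m0: float  # unrounded, clamped to [0, m]; use .rounded for reporting
    diagnostics: dict = field(default_factory=dict)

    @property
    def pi0(self) -> float:
        return self.m0 / self.m

    @property
    def rounded(self) -> int:
        return int(round(self.m0))


def _line_fit(x: np.ndarray, y: np.ndarray):
    """Least-squares line; returns (slope, intercept, r2). r2 = 1 for a zero-variance fit."""
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    if sxx == 0:
        return 0.0, ym, 0.0
    slope = np.sum((x - xm) * (y - ym)) / sxx
    intercept = ym - slope * xm
    ss_res = np.sum((y - slope * x - intercept) ** 2)
    ss_tot = np.sum((y - ym) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), float(r2)


def estimate_m0_pplot(pset, r2_drop_tol: float = 0.005) -> M0Estimate:
    """Estimate m0 from the slope of the linear region of the p-value plot.

    Points are taken from the large-p end (where true nulls dominate and the
    plot is linear) toward small p.  Starting from the largest-p quartile the
    fit region grows one point at a time while the line's R² stays within
    ``r2_drop_tol`` of the best R² seen; the final slope, clamped to [0, m],
    is the m0 estimate.
    """
    ps = _as_pset(pset)
    if ps.m < 10:
        raise ParameterError("p-value-plot m0 estimation needs at least 10 p-values")
    # Evaluate N_p on a fixed grid spanning all of [0, 1]: the linear null
    # region lives at large p whether or not p-values were observed there
    # (with every p tiny, the plot is flat at 0 over most of the range and
    # the slope — hence m0 — is near zero, as it should be).
    p_grid = np.linspace(0.0, 1.0, 101)
    p_sorted = np.sort(ps.p)
    n_p = ps.m - np.searchsorted(p_sorted, p_grid, side="right")
    x = (1.0 - p_grid)[::-1]  # ascending x, i.e. from largest p toward smallest
    y = n_p[::-1].astype(float)
    k = x.size
    n_start = max(2, math.ceil(0.25 * k))
    best_r2 = -np.inf
    n_used = n_start
    slope = intercept = r2 = None
    for n in range(n_start, k + 1):
        s, b, r = _line_fit(x[:n], y[:n])
        if r < best_r2 - r2_drop_tol:
            break
        best_r2 = max(best_r2, r)
        slope, intercept, r2 = s, b, r
        n_used = n
    m0 = float(np.clip(slope, 0.0, ps.m))
    plot = PValuePlotData(
        x=x, y=y, slope=slope, intercept=intercept, r2=r2, fit_points=n_used
    )
    return M0Estimate(
        "pplot",
        ps.m,
        m0,
        {"slope": slope, "intercept": intercept, "r2": r2, "fit_points": n_used,
         "plot": plot},
    )


def estimate_m0_cdf(pset) -> M0Estimate:
    """Estimate pi0 as (expected area 1/2) / (area under the empirical p CDF).

    The area under the empirical CDF step function on [0, 1] equals
    1 − mean(p).  Uniform (all-null) p-values give an area of 1/2 and hence
    pi0 ≈ 1; p-values piled near 0 push the area toward 1, so this estimator
    never reports pi0 below 1/2 — a documented floor, not a defect.
    """
    ps = _as_pset(pset)
    if ps.m < 10:
        raise ParameterError("CDF m0 estimation needs at least 10 p-values")
    area = 1.0 - float(ps.p.mean())
    pi0 = float(np.clip(0.5 / area, 0.0, 1.0))
    return M0Estimate("cdf", ps.m, pi0 * ps.m, {"area": area})


def default_alpha_grid() -> np.ndarray:
    """100 log-spaced significance levels from 1e-4 to 0.1."""
    return np.logspace(-4, -1, 100)


def operating_table(pset, m0: float, alphas: Sequence[float] | None = None) -> pd.DataFrame:
    """Estimated sensitivity, specificity and FDR at each significance level.

    At level alpha, S = #{p ≤ alpha} observed significant and F = m0·alpha
    expected false positives; sensitivity = clamp(S−F, 0, m−m0)/(m−m0)
    (NaN when m0 = m), specificity = 1−alpha, FDR = min(1, F/max(S, 1)).
    """
    ps = _as_pset(pset)
    if not 0 <= m0 <= ps.m:
        raise ParameterError(f"m0 must lie in [0, m={ps.m}]")
    a = default_alpha_grid() if alphas is None else np.asarray(alphas, dtype=float)
    if a.size < 1 or np.any((a <= 0) | (a >= 1)):
        raise ParameterError("alphas must lie strictly inside (0, 1)")
    p_sorted = np.sort(ps.p)
    s = np.searchsorted(p_sorted, a, side="right").astype(float)
    f = m0 * a
    m_alt = ps.m - m0
    if m_alt > 0:
        sens = np.clip(s - f, 0.0, m_alt) / m_alt
    else:
        sens = np.full_like(a, np.nan)
    spec = 1.0 - a
    fdr = np.minimum(1.0, f / np.maximum(s, 1.0))
    return pd.DataFrame(
        {"alpha": a, "n_significant": s.astype(int), "sensitivity": sens,
         "specificity": spec, "fdr": fdr}
    )


def plot_data(pset, m0: float | None = None, kind: str = "pplot") -> pd.DataFrame:
    """Plot-ready (x, y) series for the ROC, p-value or CDF diagnostics."""
    ps = _as_pset(pset)
    if kind == "pplot":
        plot = pvalue_plot(ps)
        return pd.DataFrame({"x": plot.x, "y": plot.y})
    if kind == "cdf":
        p_sorted = np.sort(ps.p)
        y = np.arange(1, ps.m + 1) / ps.m
        return pd.DataFrame({"x": p_sorted, "y": y})
    if kind == "roc":
        if m0 is None:
            raise ParameterError("ROC plot data requires an m0 estimate")
        if m0 >= ps.m:
            raise UsageError("sensitivity is undefined when m0 = m; no ROC available")
        table = operating_table(ps, m0)
        return pd.DataFrame({"x": 1.0 - table["specificity"], "y": table["sensitivity"]})
    raise ParameterError(f"unknown plot kind {kind!r}; choose roc, pplot or cdf")
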