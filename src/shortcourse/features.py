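"""Curve-summarization features for short expression time courses.

A profile with a handful of irregular time points is summarized by scalar
features — signed area under the curve, slopes, extrema and their times —
instead of being modelled.  Features keep the time ordering information,
tolerate missing points, and put every probe in a common feature space for
testing and clustering.  All evaluation happens on a user-chosen time grid;
values off the measured times are linearly interpolated, never extrapolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, RangeError, UsageError
from .io import Dataset

__all__ = [
    "Profile",
    "FeatureMatrix",
    "FEATURE_NAMES",
    "InterpolationWarning",
    "interpolate",
    "signed_auc",
    "slope",
    "value_at",
    "extrema",
    "steepest_slopes",
    "summarize_replicates",
    "relative_profile",
    "build_feature_matrix",
]

#: Stable tokens accepted by :func:`build_feature_matrix`.
FEATURE_NAMES = (
    "signed_auc",
    "slope",
    "time_point",
    "raw_expression",
    "max_expr",
    "min_expr",
    "t_of_max",
    "t_of_min",
    "steepest_pos_slope",
    "steepest_neg_slope",
)


class InterpolationWarning(UserWarning):
    """More than 10% of a requested grid had to be interpolated."""


@dataclass(frozen=True)
class Profile:
    """A single replicate's time course: strictly increasing times, log2 values."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or t.shape != v.shape:
            raise ParameterError("times and values must be 1-D and equal length")
        if t.size < 1:
            raise ParameterError("a profile needs at least one point")
        if np.any(np.diff(t) <= 0):
            raise ParameterError("profile times must be strictly increasing")

    @property
    def t_min(self) -> float:
        return float(self.times[0])

    @property
    def t_max(self) -> float:
        return float(self.times[-1])

    def covers(self, t_lo: float, t_hi: float | None = None) -> bool:
        if t_hi is None:
            t_hi = t_lo
        return self.t_min <= t_lo and t_hi <= self.t_max


def _check_range(profile: Profile, ts: Iterable[float]) -> None:
    for t in ts:
        if t < profile.t_min or t > profile.t_max:
            raise RangeError(
                f"time {t} outside observed range [{profile.t_min}, {profile.t_max}]; "
                "extrapolation is not supported"
            )


def interpolate(profile: Profile, query_times: Sequence[float]) -> Profile:
    """Evaluate the piecewise-linear curve at ``query_times``.

    Measured times return the measured value exactly.  A warning is emitted
    when more than 10% of the grid falls between measured points, since heavy
    interpolation assumes linearity the data cannot support.
    """
    q = np.asarray(query_times, dtype=float)
    if q.ndim != 1 or q.size < 1:
        raise ParameterError("query_times must be a non-empty 1-D sequence")
    if np.any(np.diff(q) <= 0):
        raise ParameterError("query times must be strictly increasing")
    _check_range(profile, q)
    vals = np.interp(q, profile.times, profile.values)
    n_interp = int(np.sum(~np.isin(q, profile.times)))
    if n_interp > 0.10 * q.size:
        warnings.warn(
            f"{n_interp}/{q.size} grid points interpolated (>10%); "
            "interpolated values assume local linearity",
            InterpolationWarning,
            stacklevel=2,
        )
    return Profile(q, vals)


def value_at(profile: Profile, t: float) -> float:
    """Measured or linearly interpolated log2 value at time ``t``."""
    _check_range(profile, [t])
    return float(np.interp(t, profile.times, profile.values))


def signed_auc(profile: Profile, t_start: float, t_end: float) -> float:
    """Trapezoidal integral of the log2 curve over [t_start, t_end].

    Negative log2 values contribute negatively, so the result is the net
    up/down change over the window.  Window endpoints are interpolated when
    they fall between measured times.
    """
    if t_start >= t_end:
        raise ParameterError("signed_auc requires t_start < t_end")
    _check_range(profile, [t_start, t_end])
    interior = profile.times[(profile.times > t_start) & (profile.times < t_end)]
    ts = np.concatenate(([t_start], interior, [t_end]))
    vs = np.interp(ts, profile.times, profile.values)
    return float(np.trapezoid(vs, ts))


def slope(profile: Profile, t1: float, t2: float) -> float:
    """Rate of change between two (possibly interpolated) time points."""
    if t1 == t2:
        raise ParameterError("slope requires two distinct time points")
    _check_range(profile, [t1, t2])
    v1 = np.interp(t1, profile.times, profile.values)
    v2 = np.interp(t2, profile.times, profile.values)
    return float((v2 - v1) / (t2 - t1))


def extrema(profile: Profile, grid: Sequence[float]):
    """(max_expr, min_expr, t_of_max, t_of_min) on the grid-evaluated curve.

    Ties are broken by the earliest grid time so results are deterministic.
    """
    g = np.asarray(grid, dtype=float)
    if g.size < 1:
        raise ParameterError("extrema requires a non-empty grid")
    ev = interpolate(profile, g)
    i_max = int(np.argmax(ev.values))
    i_min = int(np.argmin(ev.values))
    return (
        float(ev.values[i_max]),
        float(ev.values[i_min]),
        float(ev.times[i_max]),
        float(ev.times[i_min]),
    )


def steepest_slopes(profile: Profile, grid: Sequence[float]):
    """(steepest_pos_slope, steepest_neg_slope): max and min consecutive slope.

    The "negative" slot holds the minimum consecutive-segment slope, which is
    positive for a monotone increasing curve.
    """
    g = np.asarray(grid, dtype=float)
    if g.size < 2:
        raise ParameterError("steepest_slopes requires at least 2 grid points")
    ev = interpolate(profile, g)
    seg = np.diff(ev.values) / np.diff(ev.times)
    return float(np.max(seg)), float(np.min(seg))


def summarize_replicates(
    dataset: Dataset,
    probe: str,
    treatment: str,
    grid: Sequence[float],
    summary: str = "median",
) -> Profile:
    """Per-grid-time mean or median over the replicates that cover that time.

    Replicates whose observed range does not reach a grid time are excluded
    at that time only; if no replicate covers some grid time, that is an error
    naming the time.
    """
    if summary not in ("mean", "median"):
        raise ParameterError(f"summary must be 'mean' or 'median', got {summary!r}")
    g = np.asarray(grid, dtype=float)
    if g.size < 1:
        raise ParameterError("empty grid")
    reps = [
        r for r in dataset.replicates(treatment) if dataset.has_profile(probe, treatment, r)
    ]
    if not reps:
        raise UsageError(f"no profiles for probe {probe!r} in treatment {treatment!r}")
    profiles = [Profile(*dataset.profile(probe, treatment, r)) for r in reps]
    agg = np.mean if summary == "mean" else np.median
    out = np.empty(g.size)
    for i, t in enumerate(g):
        vals = [value_at(p, t) for p in profiles if p.covers(t)]
        if not vals:
            raise UsageError(
                f"no replicate of {probe!r}/{treatment!r} covers grid time {t}"
            )
        out[i] = agg(vals)
    return Profile(g, out)


def relative_profile(
    dataset: Dataset,
    probe: str,
    treatment_a: str,
    treatment_b: str,
    replicate: int,
    grid: Sequence[float],
) -> Profile:
    """Pointwise log2 difference a − b for one paired replicate on the grid.

    Because values are log2, the difference is the log ratio of raw
    expression.  Only defined for paired designs.
    """
    if not dataset.paired:
        raise UsageError("relative profiles require a paired design")
    for trt in (treatment_a, treatment_b):
        if not dataset.has_profile(probe, trt, replicate):
            raise UsageError(
                f"replicate {replicate} of probe {probe!r} absent from treatment {trt!r}"
            )
    g = np.asarray(grid, dtype=float)
    pa = Profile(*dataset.profile(probe, treatment_a, replicate))
    pb = Profile(*dataset.profile(probe, treatment_b, replicate))
    va = interpolate(pa, g).values
    vb = interpolate(pb, g).values
    return Profile(g, va - vb)


def _summarized_profile(
    dataset: Dataset,
    probe: str,
    treatment_spec,
    grid: np.ndarray,
    summary: str,
) -> Profile:
    """One grid profile per probe: replicate summary, or paired-difference summary."""
    if isinstance(treatment_spec, str):
        return summarize_replicates(dataset, probe, treatment_spec, grid, summary)
    trt_a, trt_b = treatment_spec
    reps = [
        r
        for r in dataset.replicates(trt_a)
        if dataset.has_profile(probe, trt_a, r)
        and dataset.has_profile(probe, trt_b, r)
        and Profile(*dataset.profile(probe, trt_a, r)).covers(grid[0], grid[-1])
        and Profile(*dataset.profile(probe, trt_b, r)).covers(grid[0], grid[-1])
    ]
    if not reps:
        raise UsageError(f"no paired replicate covers the grid for probe {probe!r}")
    diffs = np.vstack(
        [relative_profile(dataset, probe, trt_a, trt_b, r, grid).values for r in reps]
    )
    agg = np.mean if summary == "mean" else np.median
    return Profile(grid, agg(diffs, axis=0))


@dataclass
class FeatureMatrix:
    """Rectangular probe-by-feature matrix with an explicit scaling state."""

    data: pd.DataFrame
    scaling: str = "raw"  # raw | standardized

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ParameterError("feature matrix must not contain missing values")
        if self.scaling not in ("raw", "standardized"):
            raise ParameterError(f"unknown scaling state {self.scaling!r}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def _profile_features(
    prof: Profile, features: Sequence[str], grid: np.ndarray
) -> dict[str, float]:
    row: dict[str, float] = {}
    ex = None
    for name in features:
        if name == "signed_auc":
            row[name] = signed_auc(prof, float(grid[0]), float(grid[-1]))
        elif name == "slope":
            row[name] = slope(prof, float(grid[0]), float(grid[-1]))
        elif name == "time_point":
            # single-time value; the last grid time is the conventional choice
            row[name] = value_at(prof, float(grid[-1]))
        elif name == "raw_expression":
            ev = interpolate(prof, grid)
            for t, v in zip(ev.times, ev.values):
                row[f"raw_expression_t{t:g}"] = float(v)
        elif name in ("max_expr", "min_expr", "t_of_max", "t_of_min"):
            if ex is None:
                ex = extrema(prof, grid)
            row[name] = dict(
                zip(("max_expr", "min_expr", "t_of_max", "t_of_min"), ex)
            )[name]
        elif name in ("steepest_pos_slope", "steepest_neg_slope"):
            pos, neg = steepest_slopes(prof, grid)
            row[name] = pos if name == "steepest_pos_slope" else neg
        else:
            raise ParameterError(
                f"unknown feature {name!r}; choose from {FEATURE_NAMES}"
            )
    return row


def build_feature_matrix(
    dataset: Dataset,
    probes: Sequence[str],
    features: Sequence[str],
    grid: Sequence[float],
    summary: str = "median",
    treatment_spec=None,
):
    """Assemble the probe-by-feature matrix used for clustering.

    ``treatment_spec`` is a treatment name, or an (a, b) pair for the paired
    difference a − b.  ``raw_expression`` expands into one column per grid
    time.  Returns ``(FeatureMatrix, excluded)`` where ``excluded`` maps each
    unusable probe to the reason it was dropped.
    """
    if not features:
        raise ParameterError("at least one feature is required")
    for name in features:
        if name not in FEATURE_NAMES:
            raise ParameterError(f"unknown feature {name!r}; choose from {FEATURE_NAMES}")
    if treatment_spec is None:
        raise ParameterError("a treatment (or treatment pair) is required")
    g = np.asarray(grid, dtype=float)
    if g.size < 1 or np.any(np.diff(g) <= 0):
        raise ParameterError("grid must be non-empty and strictly increasing")
    if ("slope" in features or "steepest_pos_slope" in features
            or "steepest_neg_slope" in features or "signed_auc" in features) and g.size < 2:
        raise ParameterError("slope and AUC features need a grid of at least 2 times")

    rows: dict[str, dict[str, float]] = {}
    excluded: dict[str, str] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", InterpolationWarning)
        for probe in probes:
            try:
                prof = _summarized_profile(dataset, probe, treatment_spec, g, summary)
                rows[probe] = _profile_features(prof, features, g)
            except (UsageError, RangeError) as exc:
                excluded[probe] = str(exc)
    if not rows:
        raise UsageError("no probe has a usable profile for the requested grid")
    df = pd.DataFrame.from_dict(rows, orient="index")
    df = df.loc[[p for p in probes if p in rows]]
    return FeatureMatrix(df, scaling="raw"), excluded
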