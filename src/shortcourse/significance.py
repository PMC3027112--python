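"""Per-probe differential-expression tests on curve features.

Instead of testing the raw series point by point, each replicate's profile is
reduced to one scalar feature (signed AUC over a window, slope between two
times, or the value at one time), and the two treatment groups of feature
values are compared with standard two-sample, paired, or permutation tests.
Optional outlier screens can remove aberrant replicates — or drop the probe —
before testing.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, UsageError
from .features import Profile, signed_auc, slope, value_at
from .io import Dataset
from .outliers import OutlierReport, dixon_test, mean_median_outliers

__all__ = [
    "TestOutcome",
    "TestResult",
    "SIGNIFICANCE_FEATURES",
    "TESTS",
    "feature_per_replicate",
    "two_sample_test",
    "paired_test",
    "permutation_test",
    "run_screen",
    "results_table",
]

SIGNIFICANCE_FEATURES = ("signed_auc", "slope", "time_point")
TESTS = (
    "t",
    "paired_t",
    "wilcoxon_mw",
    "wilcoxon_signed_rank",
    "permutation_t",
    "permutation_paired_t",
)
_PAIRED_TESTS = {"paired_t", "wilcoxon_signed_rank", "permutation_paired_t"}

#: Exact permutation enumeration is used when the number of distinct
#: arrangements does not exceed this bound.
EXACT_LIMIT = 20_000

_MIN_GROUP = 2  # smallest group size still tested after outlier removal


class TestOutcome(NamedTuple):
    statistic: float
    pvalue: float
    degenerate: bool = False


@dataclass
class TestResult:
    """One probe's significance result."""

    probe: str
    symbol: str
    feature: str
    time_params: tuple
    test: str
    statistic: float
    pvalue: float
    n_a: int
    n_b: int
    outliers_removed: tuple = ()
    degenerate: bool = False


def feature_per_replicate(
    dataset: Dataset,
    probe: str,
    treatment: str,
    feature: str,
    time_params: Sequence[float],
):
    """One feature value per usable replicate of ``probe`` in ``treatment``.

    Replicates whose observed range does not cover the requested times are
    skipped with a warning.  Returns ``(values, replicate_labels)``.
    """
    if feature not in SIGNIFICANCE_FEATURES:
        raise ParameterError(
            f"feature must be one of {SIGNIFICANCE_FEATURES}, got {feature!r}"
        )
    tp = [float(t) for t in time_params]
    if feature in ("signed_auc", "slope") and len(tp) != 2:
        raise ParameterError(f"{feature} needs two time parameters")
    if feature == "time_point" and len(tp) != 1:
        raise ParameterError("time_point needs exactly one time parameter")
    values: list[float] = []
    labels: list[int] = []
    skipped: list[int] = []
    for rep in dataset.replicates(treatment):
        if not dataset.has_profile(probe, treatment, rep):
            continue
        prof = Profile(*dataset.profile(probe, treatment, rep))
        if not prof.covers(min(tp), max(tp)):
            skipped.append(rep)
            continue
        if feature == "signed_auc":
            values.append(signed_auc(prof, tp[0], tp[1]))
        elif feature == "slope":
            values.append(slope(prof, tp[0], tp[1]))
        else:
            values.append(value_at(prof, tp[0]))
        labels.append(rep)
    if skipped:
        warnings.warn(
            f"probe {probe!r}/{treatment!r}: replicates {skipped} do not cover "
            f"times {tp} and were skipped",
            stacklevel=2,
        )
    if not values:
        raise UsageError(
            f"no replicate of probe {probe!r} in treatment {treatment!r} covers times {tp}"
        )
    return np.array(values), labels


def _welch_t(a: np.ndarray, b: np.ndarray) -> float:
    """Welch t with explicit zero-variance conventions (0 for equal means, ±inf otherwise)."""
    va = a.var(ddof=1) if a.size > 1 else 0.0
    vb = b.var(ddof=1) if b.size > 1 else 0.0
    num = a.mean() - b.mean()
    den = math.sqrt(va / a.size + vb / b.size)
    if den == 0:
        return 0.0 if num == 0 else math.copysign(math.inf, num)
    return float(num / den)


def _paired_t_stat(d: np.ndarray) -> float:
    sd = d.std(ddof=1)
    if sd == 0:
        return 0.0 if d.mean() == 0 else math.copysign(math.inf, d.mean())
    return float(d.mean() / (sd / math.sqrt(d.size)))


def two_sample_test(a, b, test: str = "t") -> TestOutcome:
    """Unpaired two-group comparison: Welch's t or Mann–Whitney U, two-sided.

    Zero variance in both groups yields the degenerate conventions p = 1
    (equal means) or p = 0 (different means).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if test == "t":
        if a.size < 2 or b.size < 2:
            raise ParameterError("the t-test needs at least 2 values per group")
        t = _welch_t(a, b)
        if math.isinf(t):
            return TestOutcome(t, 0.0, True)
        if t == 0 and a.var(ddof=1) + b.var(ddof=1) == 0:
            return TestOutcome(0.0, 1.0, True)
        res = stats.ttest_ind(a, b, equal_var=False)
        return TestOutcome(float(res.statistic), float(res.pvalue), False)
    if test == "wilcoxon_mw":
        if a.size < 1 or b.size < 1:
            raise ParameterError("Mann-Whitney needs at least 1 value per group")
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return TestOutcome(float(res.statistic), float(res.pvalue), False)
    raise ParameterError(f"unknown unpaired test {test!r}")


def paired_test(a, b, test: str = "paired_t") -> TestOutcome:
    """Paired comparison on per-replicate differences, two-sided.

    Wilcoxon signed-rank drops zero differences; all-zero differences give
    the degenerate p = 1, and a constant nonzero difference gives p = 0 with
    the degenerate flag set (the t denominator vanishes).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise UsageError("paired tests need equal-length, replicate-matched groups")
    if a.size < 2:
        raise ParameterError("paired tests need at least 2 pairs")
    d = a - b
    if np.all(d == 0):
        return TestOutcome(0.0, 1.0, True)
    if test == "paired_t":
        t = _paired_t_stat(d)
        if math.isinf(t):
            return TestOutcome(t, 0.0, True)
        res = stats.ttest_rel(a, b)
        return TestOutcome(float(res.statistic), float(res.pvalue), False)
    if test == "wilcoxon_signed_rank":
        res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided")
        return TestOutcome(float(res.statistic), float(res.pvalue), False)
    raise ParameterError(f"unknown paired test {test!r}")


def _exact_count_unpaired(pooled: np.ndarray, n_a: int, t_obs: float):
    n = pooled.size
    count = total = 0
    thresh = abs(t_obs) - 1e-12
    for idx in itertools.combinations(range(n), n_a):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        t = _welch_t(pooled[mask], pooled[~mask])
        count += abs(t) >= thresh
        total += 1
    return count, total


def _exact_count_paired(d: np.ndarray, t_obs: float):
    n = d.size
    count = total = 0
    thresh = abs(t_obs) - 1e-12
    for signs in itertools.product((1.0, -1.0), repeat=n):
        t = _paired_t_stat(d * np.array(signs))
        count += abs(t) >= thresh
        total += 1
    return count, total


def permutation_test(
    a, b, paired: bool = False, n_perm: int = 10_000, seed: int | None = None
) -> TestOutcome:
    """Permutation t-test: group relabelings (unpaired) or sign flips (paired).

    The reference statistic is Welch's t (unpaired) or the paired t.  When
    the total number of arrangements is at most ``EXACT_LIMIT`` the null set
    is enumerated exactly and p is the exact tail fraction; otherwise
    ``n_perm`` arrangements are sampled with add-one smoothing,
    p = (exceedances + 1) / (n_perm + 1), so p is never zero.
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.size != b.size:
            raise UsageError("paired permutation test needs equal-length groups")
        if a.size < 2:
            raise ParameterError("paired permutation test needs at least 2 pairs")
        d = a - b
        t_obs = _paired_t_stat(d)
        if 2**d.size <= EXACT_LIMIT:
            count, total = _exact_count_paired(d, t_obs)
            return TestOutcome(t_obs, count / total, False)
        if seed is None:
            raise ParameterError("sampled permutation mode requires a seed")
        rng = np.random.default_rng(seed)
        signs = rng.choice((1.0, -1.0), size=(n_perm, d.size))
        exceed = sum(
            abs(_paired_t_stat(d * s)) >= abs(t_obs) - 1e-12 for s in signs
        )
        return TestOutcome(t_obs, (exceed + 1) / (n_perm + 1), False)

    if a.size < 2 or b.size < 2:
        raise ParameterError("unpaired permutation test needs >= 2 values per group")
    pooled = np.concatenate([a, b])
    t_obs = _welch_t(a, b)
    if math.comb(pooled.size, a.size) <= EXACT_LIMIT:
        count, total = _exact_count_unpaired(pooled, a.size, t_obs)
        return TestOutcome(t_obs, count / total, False)
    if seed is None:
        raise ParameterError("sampled permutation mode requires a seed")
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        t = _welch_t(perm[: a.size], perm[a.size :])
        exceed += abs(t) >= abs(t_obs) - 1e-12
    return TestOutcome(t_obs, (exceed + 1) / (n_perm + 1), False)


def _remove_outliers(values: np.ndarray, labels: list, method: str, z_threshold, alpha):
    """Apply one outlier screen; returns (kept values, kept labels, flagged labels, stat)."""
    if method == "none" or values.size < 3:
        return values, labels, [], float("nan")
    if method in ("sd", "mad"):
        idx, stat = mean_median_outliers(values, variance_method=method, z_threshold=z_threshold)
    elif method == "dixon":
        if values.size > 25:
            return values, labels, [], float("nan")
        idx, stat = dixon_test(values, alpha=alpha)
    else:
        raise ParameterError(f"unknown outlier method {method!r}")
    keep = [i for i in range(values.size) if i not in idx]
    return (
        values[keep],
        [labels[i] for i in keep],
        [labels[i] for i in idx],
        stat,
    )


def run_screen(
    dataset: Dataset,
    treatments: tuple[str, str],
    feature: str,
    time_params: Sequence[float],
    test: str = "t",
    outlier_method: str = "none",
    outlier_action: str = "remove-gene",
    z_threshold: float = 1.96,
    outlier_alpha: float = 0.05,
    n_perm: int = 10_000,
    seed: int | None = None,
    probes: Sequence[str] | None = None,
):
    """Screen every probe for differential expression between two treatments.

    Returns ``(results, outlier_reports, skipped)``.  With
    ``outlier_action='remove-gene'`` (default) any probe with a flagged
    replicate is excluded from the results and appears only in the outlier
    report; ``'remove-value'`` drops just the flagged replicates and tests
    the remainder.  Probes whose groups fall below 2 usable values are
    skipped with a reason.
    """
    trt_a, trt_b = treatments
    if trt_a == trt_b:
        raise UsageError("the two treatments to compare must differ")
    for trt in treatments:
        if trt not in dataset.treatments:
            raise UsageError(f"treatment {trt!r} not present in dataset")
    if test not in TESTS:
        raise ParameterError(f"unknown test {test!r}; choose from {TESTS}")
    paired = test in _PAIRED_TESTS
    if paired and not dataset.paired:
        raise UsageError(f"test {test!r} requires a paired design")
    if outlier_action not in ("remove-gene", "remove-value"):
        raise ParameterError("outlier_action must be 'remove-gene' or 'remove-value'")

    results: list[TestResult] = []
    reports: list[OutlierReport] = []
    skipped: dict[str, str] = {}
    probe_list = list(probes) if probes is not None else dataset.probe_ids
    min_group = max(_MIN_GROUP, 1)
    small_groups = 0

    for probe in probe_list:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                va, la = feature_per_replicate(dataset, probe, trt_a, feature, time_params)
                vb, lb = feature_per_replicate(dataset, probe, trt_b, feature, time_params)
        except UsageError as exc:
            skipped[probe] = str(exc)
            continue
        flagged_all: list[tuple[str, object]] = []
        va, la, fa, stat_a = _remove_outliers(va, la, outlier_method, z_threshold, outlier_alpha)
        vb, lb, fb, stat_b = _remove_outliers(vb, lb, outlier_method, z_threshold, outlier_alpha)
        for grp, flg, st in ((trt_a, fa, stat_a), (trt_b, fb, stat_b)):
            if flg:
                reports.append(
                    OutlierReport(probe=probe, group=grp, flagged=flg,
                                  method=outlier_method, statistic=st)
                )
                flagged_all.extend((grp, r) for r in flg)
        if flagged_all and outlier_action == "remove-gene":
            skipped[probe] = "outlier flagged; gene removed from testing"
            continue
        if paired:
            common = [r for r in la if r in lb]
            if len(common) < 2:
                skipped[probe] = "fewer than 2 matched pairs"
                continue
            pa = np.array([va[la.index(r)] for r in common])
            pb = np.array([vb[lb.index(r)] for r in common])
            if test == "paired_t":
                out = paired_test(pa, pb, "paired_t")
            elif test == "wilcoxon_signed_rank":
                if np.all(pa == pb):
                    out = TestOutcome(0.0, 1.0, True)
                else:
                    out = paired_test(pa, pb, "wilcoxon_signed_rank")
            else:
                out = permutation_test(pa, pb, paired=True, n_perm=n_perm, seed=seed)
            n_a = n_b = len(common)
        else:
            if va.size < min_group or vb.size < min_group:
                skipped[probe] = "group below minimum size after outlier removal"
                continue
            if va.size < 3 or vb.size < 3:
                small_groups += 1
            if test == "t":
                out = two_sample_test(va, vb, "t")
            elif test == "wilcoxon_mw":
                out = two_sample_test(va, vb, "wilcoxon_mw")
            else:
                out = permutation_test(va, vb, paired=False, n_perm=n_perm, seed=seed)
            n_a, n_b = va.size, vb.size
        results.append(
            TestResult(
                probe=probe,
                symbol=dataset.symbol(probe),
                feature=feature,
                time_params=tuple(float(t) for t in time_params),
                test=test,
                statistic=out.statistic,
                pvalue=out.pvalue,
                n_a=n_a,
                n_b=n_b,
                outliers_removed=tuple(flagged_all),
                degenerate=out.degenerate,
            )
        )
    if small_groups:
        warnings.warn(
            f"{small_groups} probe(s) tested with fewer than 3 replicates per group; "
            "at least 3 replicates are recommended",
            stacklevel=2,
        )
    return results, reports, skipped


def results_table(results: Sequence[TestResult]) -> pd.DataFrame:
    """Flatten screen results into the output table layout."""
    return pd.DataFrame(
        {
            "probe": [r.probe for r in results],
            "symbol": [r.symbol for r in results],
            "feature": [r.feature for r in results],
            "statistic": [r.statistic for r in results],
            "p_value": [r.pvalue for r in results],
            "n_a": [r.n_a for r in results],
            "n_b": [r.n_b for r in results],
            "outliers_removed": [
                ";".join(f"{g}:{rep}" for g, rep in r.outliers_removed) for r in results
            ],
        }
    )
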