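"""CNV genotyping from read depth, copy-phenotype association, and expression analyses.

Copy number is estimated by normalized read depth: twice the ratio of mean
depth in the CNV region to mean depth in a copy-neutral reference region, then
snapped to the nearest attainable diploid total {2, 3, 4, 5, 6, 8} (the totals
reachable from per-chromosome copy numbers {1, 2, 4}), rounding down on ties.

Expression analyses cover qPCR relative expression (2^-dCt against a reference
gene), allele-specific expression (cDNA allele ratios normalized by matched
gDNA ratios), and the associated rank-sum / t / trend tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .popgen_io import DepthTrack, GenomicRegion
from .synthetic_data import ATTAINABLE_DIPLOID_TOTALS, logistic_pigment_curve

__all__ = [
    "CopyCall",
    "ASERecord",
    "estimate_copy_number",
    "copy_phenotype_test",
    "pigment_copy_regression",
    "RegressionFit",
    "qpcr_relative_expression",
    "ase_normalize",
    "ase_tests",
    "ASETestResult",
]


@dataclass
class CopyCall:
    estimate: float  # continuous diploid copy estimate
    call: int  # nearest attainable diploid total
    cnv_region: GenomicRegion
    reference_region: GenomicRegion

    def __post_init__(self) -> None:
        if self.estimate < 0:
            raise ValueError("copy estimate must be nonnegative")
        if self.call not in ATTAINABLE_DIPLOID_TOTALS:
            raise ValueError(f"call {self.call} not in attainable set")


def _nearest_attainable(estimate: float) -> int:
    # nearest attainable total; ties round down
    best = ATTAINABLE_DIPLOID_TOTALS[0]
    best_d = abs(estimate - best)
    for c in ATTAINABLE_DIPLOID_TOTALS[1:]:
        d = abs(estimate - c)
        if d < best_d:
            best, best_d = c, d
    return best


def estimate_copy_number(
    depth: DepthTrack, cnv_region: GenomicRegion, reference_region: GenomicRegion
) -> CopyCall:
    """Diploid copy-number estimate from normalized read depth.

    estimate = 2 * mean(depth in CNV region) / mean(depth in reference region).
    Scale-invariant: multiplying the whole track by k > 0 leaves it unchanged.
    """
    ref_mean = depth.mean_in(reference_region)
    if ref_mean == 0:
        raise ValueError("reference region mean depth is zero")
    cnv_mean = depth.mean_in(cnv_region)
    estimate = 2.0 * cnv_mean / ref_mean
    return CopyCall(estimate, _nearest_attainable(estimate), cnv_region, reference_region)


def copy_phenotype_test(
    groups: Mapping[str, Sequence[float]], alternative: str = "two-sided"
) -> pd.DataFrame:
    """Pairwise rank-sum tests of copy number between phenotype categories.

    Returns one row per category pair with the Mann-Whitney U statistic, the
    raw p-value (exact when sample sizes permit), and Benjamini-Hochberg
    adjusted p-values across the pairs.
    """
    if len(groups) < 2:
        raise ValueError("need at least two phenotype groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, arr in arrays.items():
        if len(arr) == 0:
            raise ValueError(f"phenotype group {name!r} is empty")
    rows = []
    for (na, a), (nb, b) in combinations(arrays.items(), 2):
        if np.array_equal(np.sort(a), np.sort(b)):
            u, p = float(len(a) * len(b) / 2.0), 1.0
        else:
            u, p = stats.mannwhitneyu(a, b, alternative=alternative)
        rows.append({"group_a": na, "group_b": nb, "U": float(u), "p": float(p)})
    df = pd.DataFrame(rows)
    df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


@dataclass
class RegressionFit:
    model: str
    params: dict[str, float]
    predict: Callable[[np.ndarray], np.ndarray]
    r_squared: float


def pigment_copy_regression(
    area_percent: Sequence[float],
    copies: Sequence[float],
    model: str = "logistic",
) -> RegressionFit:
    """Least-squares fit of percent dark wing-shield area on CNV copy total.

    ``model="logistic"`` fits a saturating four-parameter logistic by nonlinear
    least squares; ``model="linear"`` fits ordinary least squares. r-squared is
    1 - SS_res / SS_tot in both cases.
    """
    y = np.asarray(area_percent, dtype=float)
    x = np.asarray(copies, dtype=float)
    if len(y) != len(x) or len(y) < 3:
        raise ValueError("need at least three paired observations")
    if np.ptp(x) == 0:
        raise ValueError("copy numbers do not vary")

    if model == "linear":
        res = stats.linregress(x, y)
        params = {"slope": float(res.slope), "intercept": float(res.intercept)}
        predict = lambda c: res.intercept + res.slope * np.asarray(c, dtype=float)
        yhat = predict(x)
    elif model == "logistic":
        def f(c, lower, upper, midpoint, rate):
            return logistic_pigment_curve(c, lower, upper, midpoint, rate)

        p0 = (float(y.min()), float(y.max()), float(np.median(x)), 1.0)
        popt, _ = optimize.curve_fit(f, x, y, p0=p0, maxfev=20000)
        params = dict(zip(("lower", "upper", "midpoint", "rate"), map(float, popt)))
        predict = lambda c: f(np.asarray(c, dtype=float), *popt)
        yhat = predict(x)
    else:
        raise ValueError("model must be 'logistic' or 'linear'")

    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return RegressionFit(model=model, params=params, predict=predict, r_squared=r2)


def qpcr_relative_expression(
    ct_target: Sequence[float],
    ct_reference: Sequence[float],
    ct_calibrator_target: Sequence[float] | None = None,
    ct_calibrator_reference: Sequence[float] | None = None,
) -> float:
    """Relative expression from qPCR cycle thresholds.

    Replicates are averaged first; the default is 2^-(dCt) with
    dCt = mean(target) - mean(reference). Supplying calibrator Cts switches to
    the calibrator-relative ddCt form 2^-(dCt_sample - dCt_calibrator).
    """
    t = np.asarray(ct_target, dtype=float)
    r = np.asarray(ct_reference, dtype=float)
    if len(t) == 0 or len(r) == 0:
        raise ValueError("replicate Ct sets must be nonempty")
    dct = t.mean() - r.mean()
    if ct_calibrator_target is not None or ct_calibrator_reference is not None:
        if ct_calibrator_target is None or ct_calibrator_reference is None:
            raise ValueError("supply both calibrator Ct sets or neither")
        ct_ = np.asarray(ct_calibrator_target, dtype=float)
        cr_ = np.asarray(ct_calibrator_reference, dtype=float)
        if len(ct_) == 0 or len(cr_) == 0:
            raise ValueError("calibrator replicate Ct sets must be nonempty")
        dct -= ct_.mean() - cr_.mean()
    return float(2.0 ** (-dct))


@dataclass
class ASERecord:
    bird: str
    copy_class: int  # CNV copies on the derived (checker) chromosome: 1, 2, or 4
    gdna_ratio: float
    cdna_ratio: float

    def __post_init__(self) -> None:
        if self.copy_class not in (1, 2, 4):
            raise ValueError("copy class must be 1, 2, or 4")
        if self.gdna_ratio <= 0 or self.cdna_ratio <= 0:
            raise ValueError("allele signal ratios must be positive")


def ase_normalize(record: ASERecord | tuple[float, float]) -> float:
    """cDNA allele ratio normalized by the matched gDNA ratio (amplification-bias control)."""
    if isinstance(record, ASERecord):
        gdna, cdna = record.gdna_ratio, record.cdna_ratio
    else:
        cdna, gdna = record
    if gdna <= 0:
        raise ValueError("gDNA ratio must be positive")
    return cdna / gdna


def _safe_ttest_1samp(values: np.ndarray, popmean: float) -> tuple[float, float]:
    if np.all(values == popmean):
        return 0.0, 1.0
    t, p = stats.ttest_1samp(values, popmean)
    return float(t), float(p)


@dataclass
class ASETestResult:
    t_1_vs_4: float
    p_1_vs_4: float
    trend_slope: float
    trend_p: float
    one_sample: dict[int, tuple[float, float]]  # class -> (t, p) vs a 1:1 ratio


def ase_tests(normalized_by_class: Mapping[int, Sequence[float]]) -> ASETestResult:
    """Statistical tests on normalized allele-expression ratios by CNV copy class.

    Runs a two-sample t-test between the 1- and 4-copy classes, a linear trend
    regression of ratio on copy count (slope test), and per-class one-sample
    t-tests against the balanced 1:1 ratio.
    """
    data = {int(k): np.asarray(v, dtype=float) for k, v in normalized_by_class.items()}
    if len(data) < 2:
        raise ValueError("trend test needs at least two copy classes")
    if 1 not in data or 4 not in data:
        raise ValueError("two-sample test needs both the 1- and 4-copy classes")
    for k, v in data.items():
        if len(v) < 2:
            raise ValueError(f"copy class {k} needs at least two observations")

    a, b = data[1], data[4]
    if np.array_equal(np.sort(a), np.sort(b)):
        t14, p14 = 0.0, 1.0
    else:
        t14, p14 = stats.ttest_ind(a, b)

    x = np.concatenate([np.full(len(v), k, dtype=float) for k, v in data.items()])
    y = np.concatenate(list(data.values()))
    if np.ptp(y) == 0:
        slope, p_slope = 0.0, 1.0
    else:
        res = stats.linregress(x, y)
        slope, p_slope = float(res.slope), float(res.pvalue)

    one_sample = {k: _safe_ttest_1samp(v, 1.0) for k, v in data.items()}
    return ASETestResult(
        t_1_vs_4=float(t14),
        p_1_vs_4=float(p14),
        trend_slope=slope,
        trend_p=p_slope,
        one_sample=one_sample,
    )
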