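"""Haplotype dating: pairwise differences, coalescent SNP-count dating, and
EHH/LD-decay age estimation.

Two complementary clocks are implemented. The mutation clock converts a SNP
count S observed between sequences over L bp into a divergence time
T = S / (2 * mu * L) generations. The recombination clock assumes a
star-shaped genealogy for carriers of a recently introduced haplotype: the
probability that two random carriers are homozygous out to genetic distance r
(Morgans) is Pr[homoz] = exp(-2 r g), so g = -100 * ln(Pr) / (2 * r_cM)
generations, with r supplied in centiMorgans. The confidence interval treats
the number of non-recombined carriers as binomial, N ~ Binom(n, p), and maps
exact binomial quantiles of N/n back through the age formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .popgen_io import MISSING, GenomicRegion, HaplotypeMatrix

__all__ = [
    "PairDiffSummary",
    "EHHCurve",
    "AgeEstimate",
    "pairwise_snp_counts",
    "variant_list_pairwise_diffs",
    "coalescent_time",
    "expected_snps",
    "similarity_percent",
    "divergence_vs_expectation_test",
    "cytb_divergence_time",
    "ehh_curve",
    "span_homozygosity",
    "SpanHomozygosity",
    "age_point",
    "age_ci",
    "generations_to_years",
    "estimate_haplotype_age",
    "genetic_distance_cm",
    "cross_pairs",
    "within_pairs",
]


# ---------------------------------------------------------------------------
# Pairwise SNP differences and the mutation clock


@dataclass
class PairDiffSummary:
    counts: dict[tuple[str, str], int]
    mean: float
    sd: float  # sample SD (ddof=1); 0 for a single pair
    total_segregating: int  # K over the region across all haplotypes

    def similarity_percent_per_pair(self) -> dict[tuple[str, str], float]:
        return {
            pair: similarity_percent(c, self.total_segregating)
            for pair, c in self.counts.items()
        }

    def mean_similarity_percent(self) -> float:
        """Mean of per-pair similarities (the group summaries quoted for real data)."""
        vals = list(self.similarity_percent_per_pair().values())
        return float(np.mean(vals))


def cross_pairs(a: Sequence[str], b: Sequence[str]) -> list[tuple[str, str]]:
    return list(product(a, b))


def within_pairs(a: Sequence[str]) -> list[tuple[str, str]]:
    return list(combinations(a, 2))


def _single_column(h: HaplotypeMatrix, name: str) -> int:
    cols = h.columns_for([name])
    if len(cols) != 1:
        raise ValueError(
            f"{name!r} resolves to a diploid sample; pairwise counting needs "
            "haplotype labels (e.g. 'sample|0')"
        )
    return int(cols[0])


def pairwise_snp_counts(
    h: HaplotypeMatrix, region: GenomicRegion, pairs: Sequence[tuple[str, str]]
) -> PairDiffSummary:
    """SNP difference counts between haplotype pairs inside a region.

    A difference is a site where both alleles are called and unequal
    (site-wise pairwise deletion for missing data). ``total_segregating`` is
    the number of sites in the region polymorphic across the whole matrix.
    """
    if not pairs:
        raise ValueError("pair list must be nonempty")
    mask = h.region_mask(region)
    sub = h.alleles[mask]
    has0 = (sub == 0).any(axis=1)
    has1 = (sub == 1).any(axis=1)
    K = int((has0 & has1).sum())

    counts: dict[tuple[str, str], int] = {}
    for a, b in pairs:
        ca, cb = _single_column(h, a), _single_column(h, b)
        va, vb = sub[:, ca], sub[:, cb]
        called = (va != MISSING) & (vb != MISSING)
        counts[(a, b)] = int(np.sum((va != vb) & called))
    values = np.array(list(counts.values()), dtype=float)
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return PairDiffSummary(counts, float(values.mean()), sd, K)


def variant_list_pairwise_diffs(
    list_a: Mapping[int, str], list_b: Mapping[int, str]
) -> int:
    """Count differences between two per-individual variant lists (position -> alt).

    Differences are variants private to one list plus shared positions whose
    alternate alleles disagree; a shared position with the same alternate
    allele contributes nothing.
    """
    for lst in (list_a, list_b):
        if not isinstance(lst, Mapping):
            raise TypeError("variant lists must map position -> alternate allele")
        for pos, alt in lst.items():
            if not isinstance(pos, (int, np.integer)) or not isinstance(alt, str) or not alt:
                raise ValueError(f"malformed variant entry: {pos!r} -> {alt!r}")
    keys_a, keys_b = set(list_a), set(list_b)
    private = len(keys_a ^ keys_b)
    shared_diff = sum(1 for k in keys_a & keys_b if list_a[k] != list_b[k])
    return private + shared_diff


def coalescent_time(S: float, mu: float, L: float) -> float:
    """Divergence time in generations from a SNP count: T = S / (2 * mu * L)."""
    if mu <= 0 or L <= 0:
        raise ValueError("mu and L must be positive")
    if S < 0:
        raise ValueError("SNP count must be nonnegative")
    return S / (2.0 * mu * L)


def expected_snps(T: float, mu: float, L: float) -> float:
    """Expected pairwise SNP count after T generations: 2 * mu * L * T."""
    if T < 0:
        raise ValueError("divergence time must be nonnegative")
    if mu <= 0 or L <= 0:
        raise ValueError("mu and L must be positive")
    return 2.0 * mu * L * T


def similarity_percent(S: float, K: float) -> float:
    """Percent shared segregating sites: 100 * (1 - S/K)."""
    if K <= 0:
        raise ValueError("total segregating sites must be positive")
    if S < 0 or S > K:
        raise ValueError("SNP count must satisfy 0 <= S <= K")
    return 100.0 * (1.0 - S / K)


def divergence_vs_expectation_test(
    observed: Sequence[float], expected: float
) -> tuple[float, float]:
    """One-sample t-test of observed pairwise counts against an expected constant."""
    obs = np.asarray(observed, dtype=float)
    if len(obs) < 2:
        raise ValueError("need at least two observed counts")
    if obs.std(ddof=1) == 0.0:
        return (0.0, 1.0) if obs[0] == expected else (math.inf, 0.0)
    t, p = stats.ttest_1samp(obs, expected)
    return float(t), float(p)


def cytb_divergence_time(d_percent: float, rate_percent_per_my: float) -> float:
    """Species divergence in MY from mitochondrial divergence and a clock rate."""
    if rate_percent_per_my <= 0:
        raise ValueError("divergence rate must be positive")
    if d_percent < 0:
        raise ValueError("divergence must be nonnegative")
    return d_percent / rate_percent_per_my


# ---------------------------------------------------------------------------
# EHH and the recombination clock


@dataclass
class EHHCurve:
    """Extended haplotype homozygosity decaying outward from a focal site.

    ``positions`` starts at the focal site (EHH = 1 there) and moves outward;
    ``n`` is the carrier count entering the denominator at the focal site.
    """

    side: str  # "left" or "right"
    positions: np.ndarray
    ehh: np.ndarray
    focal: int
    n: int

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ehh = np.asarray(self.ehh, dtype=float)
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if len(self.positions) != len(self.ehh):
            raise ValueError("positions and ehh must have equal length")
        if len(self.ehh) == 0 or not np.isclose(self.ehh[0], 1.0):
            raise ValueError("EHH must start at 1 at the focal site")
        if np.any((self.ehh < 0) | (self.ehh > 1)):
            raise ValueError("EHH values must lie in [0, 1]")


def ehh_curve(
    h: HaplotypeMatrix, focal: int, carriers: Sequence[str], side: str
) -> EHHCurve:
    """EHH of carrier haplotypes from a focal site outward on one side.

    At each site s outward, EHH = sum_g C(n_g, 2) / C(n, 2) where n_g are the
    sizes of groups of carriers identical over [focal..s]. A haplotype with a
    missing call anywhere in the span is excluded from numerator and
    denominator from that point on; the curve is truncated if fewer than two
    haplotypes remain. Carriers must share the core allele at the focal site.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    cols = h.columns_for(list(carriers))
    focal_idx = h.site_index(focal)

    core = h.alleles[focal_idx, cols]
    called = core != MISSING
    if len(set(core[called].tolist())) > 1:
        raise ValueError("carriers do not share a core allele at the focal site")
    active = np.flatnonzero(called)
    if len(active) < 2:
        raise ValueError("fewer than two carrier haplotypes with a called focal allele")

    step = -1 if side == "left" else 1
    idx_range = range(focal_idx + step, -1 if side == "left" else h.n_sites, step)

    n0 = len(active)
    denom = n0 * (n0 - 1) / 2.0
    group_ids = np.zeros(len(active), dtype=np.int64)  # all identical at the core
    positions = [int(h.positions[focal_idx])]
    values = [1.0]

    for i in idx_range:
        alleles = h.alleles[i, cols[active]]
        keep = alleles != MISSING
        active = active[keep]
        group_ids = group_ids[keep]
        if len(active) < 2:
            break
        # refine grouping: haplotypes stay together only if identical so far
        key = group_ids * 2 + h.alleles[i, cols[active]]
        _, group_ids = np.unique(key, return_inverse=True)
        _, sizes = np.unique(group_ids, return_counts=True)
        num = float((sizes * (sizes - 1) / 2.0).sum())
        positions.append(int(h.positions[i]))
        values.append(num / denom)

    return EHHCurve(side=side, positions=np.array(positions), ehh=np.array(values),
                    focal=focal, n=n0)


@dataclass
class SpanHomozygosity:
    p: float  # mean of left/right EHH at the boundary sites
    r_left_cm: float
    r_right_cm: float
    left_pos: int
    right_pos: int

    @property
    def r_mean_cm(self) -> float:
        return 0.5 * (self.r_left_cm + self.r_right_cm)


def genetic_distance_cm(
    pos_a: int,
    pos_b: int,
    rate_cm_per_bp: float | None = None,
    rec_map: pd.DataFrame | None = None,
) -> float:
    """Map distance in cM between two physical positions.

    Either a uniform rate (cM per bp) or a cumulative genetic map (columns
    ``pos`` and ``cM``) must be supplied; the map is interpolated linearly.
    """
    if rec_map is not None:
        cm = np.interp([pos_a, pos_b], rec_map["pos"], rec_map["cM"])
        return float(abs(cm[1] - cm[0]))
    if rate_cm_per_bp is None:
        raise ValueError("supply rate_cm_per_bp or rec_map")
    return abs(pos_b - pos_a) * rate_cm_per_bp


def span_homozygosity(
    left: EHHCurve,
    right: EHHCurve,
    threshold: float = 0.25,
    rate_cm_per_bp: float | None = None,
    rec_map: pd.DataFrame | None = None,
) -> SpanHomozygosity:
    """Haplotype boundary per side at the first site with EHH below threshold.

    Returns the non-recombination probability p (mean of the two sides' EHH at
    their boundary sites) and the focal-to-boundary map distances in cM.
    """
    bounds = {}
    for curve in (left, right):
        below = np.flatnonzero(curve.ehh < threshold)
        if len(below) == 0:
            raise ValueError(
                f"{curve.side} EHH never drops below {threshold}; extend the data span"
            )
        i = int(below[0])
        bounds[curve.side] = (int(curve.positions[i]), float(curve.ehh[i]))
    p = 0.5 * (bounds["left"][1] + bounds["right"][1])
    r_left = genetic_distance_cm(left.focal, bounds["left"][0], rate_cm_per_bp, rec_map)
    r_right = genetic_distance_cm(right.focal, bounds["right"][0], rate_cm_per_bp, rec_map)
    return SpanHomozygosity(
        p=p,
        r_left_cm=r_left,
        r_right_cm=r_right,
        left_pos=bounds["left"][0],
        right_pos=bounds["right"][0],
    )


def age_point(r_cm: float, pr: float) -> float:
    """Haplotype age in generations: g = -100 * ln(Pr[homoz]) / (2 * r_cM).

    The natural logarithm is forced by Pr = exp(-2 r g); the factor 100
    converts r from centiMorgans to Morgans.
    """
    if not (0.0 < pr <= 1.0):
        raise ValueError("homozygosity probability must be in (0, 1]")
    if r_cm <= 0:
        raise ValueError("map distance must be positive")
    return -100.0 * math.log(pr) / (2.0 * r_cm)


def age_ci(
    n: int, p: float, r_cm: float, level: float = 0.95
) -> tuple[float, float]:
    """Exact-binomial CI for the haplotype age in generations.

    N ~ Binom(n, p) is the number of carriers not recombined to the boundary;
    quantiles of N (smallest N with CDF >= target) give Pr bounds N/n which
    map through the age formula. A zero lower quantile leaves the upper age
    unbounded (returned as inf).
    """
    if not (0.0 < p < 1.0):
        raise ValueError("non-recombination probability must be in (0, 1)")
    if n < 2:
        raise ValueError("need at least two carrier haplotypes")
    tail = (1.0 - level) / 2.0
    n_lo = int(stats.binom.ppf(tail, n, p))
    n_hi = int(stats.binom.ppf(1.0 - tail, n, p))
    g_lo = age_point(r_cm, n_hi / n) if n_hi > 0 else math.inf
    g_hi = math.inf if n_lo == 0 else age_point(r_cm, n_lo / n)
    return g_lo, g_hi


def generations_to_years(g: float, generations_per_year: int) -> float:
    """Convert generations to years at 1 or 2 generations per year."""
    if generations_per_year not in (1, 2):
        raise ValueError("generations_per_year must be 1 or 2")
    if g < 0:
        raise ValueError("generation count must be nonnegative")
    return g / generations_per_year


@dataclass
class AgeEstimate:
    g: float
    ci: tuple[float, float]
    years_1gen: float
    years_2gen: float
    r_cm: float
    pr_homoz: float
    n: int

    def __post_init__(self) -> None:
        if self.g < 0:
            raise ValueError("age must be nonnegative")
        if self.ci[0] > self.ci[1]:
            raise ValueError("CI lower bound exceeds upper bound")


def estimate_haplotype_age(
    left: EHHCurve,
    right: EHHCurve,
    threshold: float = 0.25,
    rate_cm_per_bp: float | None = None,
    rec_map: pd.DataFrame | None = None,
    level: float = 0.95,
) -> AgeEstimate:
    """End-to-end LD-decay age estimate from two EHH curves.

    Boundary delineation and p follow :func:`span_homozygosity`; the point
    estimate uses the mean of the two sides' map distances, and the CI uses
    the carrier count from the curves.
    """
    span = span_homozygosity(left, right, threshold, rate_cm_per_bp, rec_map)
    n = min(left.n, right.n)
    g = age_point(span.r_mean_cm, span.p)
    ci = age_ci(n, span.p, span.r_mean_cm, level=level)
    return AgeEstimate(
        g=g,
        ci=ci,
        years_1gen=generations_to_years(g, 1),
        years_2gen=generations_to_years(g, 2),
        r_cm=span.r_mean_cm,
        pr_homoz=span.p,
        n=n,
    )
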