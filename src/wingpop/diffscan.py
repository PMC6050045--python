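"""Allele-frequency differentiation scan and minimal shared-haplotype delineation.

Per-site differentiation between two groups is a 1-df binomial likelihood-ratio
test on derived/alternate allele counts (an allele-count analogue of
probabilistic case/control differentiation scans). Genome-wide significance is
Bonferroni: alpha divided by the number of sites tested. Significant sites
separated by at most ``merge_gap`` bp are fused into candidate regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .popgen_io import MISSING, GenomicRegion, HaplotypeMatrix, PopulationPanel, SiteTable

__all__ = ["ScanResult", "site_lrt", "genome_scan", "minimal_shared_haplotype"]


def _binom_loglik(k: np.ndarray, n: np.ndarray, p: np.ndarray) -> np.ndarray:
    # Bernoulli log-likelihood without the combinatorial constant (cancels in the LRT).
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(k > 0, k * np.log(p), 0.0)
        term2 = np.where(n - k > 0, (n - k) * np.log(1.0 - p), 0.0)
    return term1 + term2


def site_lrt(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Binomial likelihood-ratio test for equal allele frequency in two groups.

    Returns ``(statistic, p)`` where the statistic is
    ``2 * [l(p1_hat, p2_hat) - l(p_pooled)]`` and the p-value comes from a
    chi-square distribution with 1 degree of freedom.
    """
    stat = _site_lrt_vec(np.array([k1]), np.array([n1]), np.array([k2]), np.array([n2]))[0]
    return float(stat), float(stats.chi2.sf(stat, df=1))


def _site_lrt_vec(k1, n1, k2, n2) -> np.ndarray:
    k1 = np.asarray(k1, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(n1 <= 0) or np.any(n2 <= 0):
        raise ValueError("allele totals must be positive in both groups")
    if np.any(k1 < 0) or np.any(k1 > n1) or np.any(k2 < 0) or np.any(k2 > n2):
        raise ValueError("allele counts must satisfy 0 <= k <= n")
    p1 = k1 / n1
    p2 = k2 / n2
    pp = (k1 + k2) / (n1 + n2)
    ll_alt = _binom_loglik(k1, n1, p1) + _binom_loglik(k2, n2, p2)
    ll_null = _binom_loglik(k1, n1, pp) + _binom_loglik(k2, n2, pp)
    return np.maximum(2.0 * (ll_alt - ll_null), 0.0)


@dataclass
class ScanResult:
    table: pd.DataFrame  # scaffold, pos, k1, n1, k2, n2, stat, p
    threshold: float  # Bonferroni genome-wide significance level
    regions: list[GenomicRegion]  # merged significant regions

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["p"] < self.threshold]

    def to_bed(self) -> pd.DataFrame:
        rows = [r.to_bed() for r in self.regions]
        return pd.DataFrame(rows, columns=["chrom", "chromStart", "chromEnd"])


def genome_scan(
    sites: SiteTable,
    h: HaplotypeMatrix,
    panel: PopulationPanel | tuple[list[str], list[str]],
    alpha: float = 0.05,
    merge_gap: int = 10_000,
) -> ScanResult:
    """Per-site differentiation scan between two sample groups.

    ``panel`` is either a :class:`PopulationPanel` (P1 vs P2 roles are
    contrasted) or an explicit ``(group1_ids, group2_ids)`` tuple. Sites where
    either group has no called allele are skipped; the Bonferroni threshold
    divides alpha by the number of sites actually tested.
    """
    if isinstance(panel, PopulationPanel):
        g1 = panel.samples_for_role("P1")
        g2 = panel.samples_for_role("P2")
    else:
        g1, g2 = panel
    cols1 = h.columns_for(g1)
    cols2 = h.columns_for(g2)

    sub1 = h.alleles[:, cols1]
    sub2 = h.alleles[:, cols2]
    n1 = (sub1 != MISSING).sum(axis=1)
    n2 = (sub2 != MISSING).sum(axis=1)
    k1 = (sub1 == 1).sum(axis=1)
    k2 = (sub2 == 1).sum(axis=1)
    tested = (n1 > 0) & (n2 > 0)
    if not tested.any():
        raise ValueError("no testable polymorphic sites")

    stat = np.full(h.n_sites, np.nan)
    stat[tested] = _site_lrt_vec(k1[tested], n1[tested], k2[tested], n2[tested])
    p = stats.chi2.sf(stat, df=1)
    n_tested = int(tested.sum())
    threshold = alpha / n_tested

    table = pd.DataFrame(
        {
            "scaffold": sites.scaffold,
            "pos": sites.positions,
            "k1": k1,
            "n1": n1,
            "k2": k2,
            "n2": n2,
            "stat": stat,
            "p": p,
        }
    )
    sig_pos = sites.positions[np.nan_to_num(p, nan=1.0) < threshold]
    regions = _merge_positions(sites.scaffold, sig_pos, merge_gap)
    return ScanResult(table=table, threshold=threshold, regions=regions)


def _merge_positions(scaffold: str, positions: np.ndarray, merge_gap: int) -> list[GenomicRegion]:
    if len(positions) == 0:
        return []
    positions = np.sort(positions)
    regions = []
    start = prev = int(positions[0])
    for pos in positions[1:]:
        pos = int(pos)
        if pos - prev > merge_gap:
            regions.append(GenomicRegion(scaffold, start, prev))
            start = pos
        prev = pos
    regions.append(GenomicRegion(scaffold, start, prev))
    return regions


def minimal_shared_haplotype(
    h: HaplotypeMatrix, carriers: list[str], focal: int
) -> GenomicRegion:
    """Maximal interval around ``focal`` over which all carriers are mutually identical.

    Missing alleles are wildcards: a site breaks the shared haplotype only if
    two carriers show different non-missing alleles there. Bounds are set at
    the sites adjacent to the nearest discordant site on each side (exclusive),
    or at the matrix extent when no discordance is found.
    """
    if not carriers:
        raise ValueError("carrier set must be nonempty")
    cols = h.columns_for(carriers)
    focal_idx = h.site_index(focal)

    sub = h.alleles[:, cols]
    has0 = (sub == 0).any(axis=1)
    has1 = (sub == 1).any(axis=1)
    discordant = has0 & has1

    if discordant[focal_idx]:
        raise ValueError(f"carriers are discordant at the focal position {focal}")

    left_disc = np.flatnonzero(discordant[:focal_idx])
    right_rel = np.flatnonzero(discordant[focal_idx + 1 :])
    start = h.positions[left_disc[-1] + 1] if len(left_disc) else h.positions[0]
    end = (
        h.positions[focal_idx + 1 + right_rel[0] - 1]
        if len(right_rel)
        else h.positions[-1]
    )
    return GenomicRegion(h.scaffold, int(start), int(end))
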