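"""Four-taxon D-statistics and triplet sequence-similarity scanning.

Site patterns use the frequency formulation: with derived-allele frequencies
(p1, p2, p3, pO) for the quartet (P1 recipient-ancestral, P2 recipient-derived,
P3 donor, O outgroup),

    ABBA weight = (1 - p1) * p2 * p3 * (1 - pO)
    BABA weight = p1 * (1 - p2) * p3 * (1 - pO)

and D = (sum ABBA - sum BABA) / (sum ABBA + sum BABA). Sites where the
outgroup carries the derived allele are retained with weight (1 - pO) rather
than dropped. An excess of ABBA (D > 0) indicates gene flow between P2 and P3.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .popgen_io import (
    GenomicRegion,
    HaplotypeMatrix,
    PopulationPanel,
    Window,
    informative_sites,
)

__all__ = [
    "SitePatternSums",
    "DResult",
    "site_patterns",
    "pattern_sums",
    "d_statistic",
    "windowed_d",
    "combo_mean_d",
    "block_bootstrap_ci",
    "triplet_similarity_scan",
]


@dataclass
class SitePatternSums:
    sum_abba: float
    sum_baba: float
    sites_used: int

    def __post_init__(self) -> None:
        if self.sum_abba < 0 or self.sum_baba < 0:
            raise ValueError("pattern weights must be nonnegative")


@dataclass
class DResult:
    D: float  # NaN when undefined (no informative patterns)
    window: GenomicRegion | None = None
    combo: tuple[str, str] | None = None
    ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not np.isnan(self.D) and not (-1.0 <= self.D <= 1.0):
            raise ValueError("D must lie in [-1, 1]")
        if self.ci is not None and self.ci[0] > self.ci[1]:
            raise ValueError("confidence interval lower bound exceeds upper bound")


def site_patterns(p1: float, p2: float, p3: float, pO: float) -> tuple[float, float]:
    """ABBA and BABA weights for one site from derived-allele frequencies."""
    for f in (p1, p2, p3, pO):
        if not (0.0 <= f <= 1.0):
            raise ValueError(f"frequency {f} outside [0, 1]")
    abba = (1.0 - p1) * p2 * p3 * (1.0 - pO)
    baba = p1 * (1.0 - p2) * p3 * (1.0 - pO)
    return abba, baba


def _pattern_weights(
    f1: np.ndarray, f2: np.ndarray, f3: np.ndarray, fO: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized weights; sites with any group entirely missing are excluded."""
    usable = ~(np.isnan(f1) | np.isnan(f2) | np.isnan(f3) | np.isnan(fO))
    abba = np.where(usable, (1 - f1) * f2 * f3 * (1 - fO), 0.0)
    baba = np.where(usable, f1 * (1 - f2) * f3 * (1 - fO), 0.0)
    return abba, baba, usable


def pattern_sums(
    h: HaplotypeMatrix,
    panel: PopulationPanel,
    mask: np.ndarray | None = None,
) -> SitePatternSums:
    """Aggregate ABBA/BABA weights over (a subset of) sites for a quartet panel."""
    panel.require_quartet()
    freqs = [
        h.derived_frequency(h.columns_for(panel.samples_for_role(role)))
        for role in ("P1", "P2", "P3", "O")
    ]
    abba, baba, usable = _pattern_weights(*freqs)
    if mask is not None:
        abba, baba, usable = abba[mask], baba[mask], usable[mask]
    return SitePatternSums(float(abba.sum()), float(baba.sum()), int(usable.sum()))


def d_statistic(s: SitePatternSums) -> float:
    """Patterson's D from aggregated pattern sums; NaN (not 0) when undefined."""
    total = s.sum_abba + s.sum_baba
    if total == 0:
        return float("nan")
    return (s.sum_abba - s.sum_baba) / total


def windowed_d(
    h: HaplotypeMatrix, panel: PopulationPanel, windows: list[Window]
) -> list[DResult]:
    """One D per window from within-window pattern sums; empty windows get NaN."""
    panel.require_quartet()
    freqs = [
        h.derived_frequency(h.columns_for(panel.samples_for_role(role)))
        for role in ("P1", "P2", "P3", "O")
    ]
    abba, baba, _ = _pattern_weights(*freqs)
    results = []
    for w in windows:
        m = h.region_mask(w.region)
        s = SitePatternSums(float(abba[m].sum()), float(baba[m].sum()), int(m.sum()))
        results.append(DResult(D=d_statistic(s), window=w.region))
    return results


def combo_mean_d(
    h: HaplotypeMatrix,
    panel: PopulationPanel,
    windows: list[Window],
    mode: str = "genotype",
) -> tuple[dict[tuple[str, str], float], float]:
    """Per-individual-combination window-mean D values and their grand mean.

    Every (P1 individual, P2 individual) pair is tested with the full P3 and O
    groups. ``mode="genotype"`` uses both haplotypes of each individual;
    ``mode="haplotype"`` uses only the first phase, mirroring analyses run on
    one sequence per individual. Combos with all-missing windows are excluded
    with a warning.
    """
    import warnings

    if mode not in ("genotype", "haplotype"):
        raise ValueError("mode must be 'genotype' or 'haplotype'")
    panel.require_quartet()
    f3 = h.derived_frequency(h.columns_for(panel.samples_for_role("P3")))
    fO = h.derived_frequency(h.columns_for(panel.samples_for_role("O")))

    def indiv_freq(sample: str) -> np.ndarray:
        cols = h.columns_for([sample])
        if mode == "haplotype":
            cols = cols[:1]
        return h.derived_frequency(cols)

    per_combo: dict[tuple[str, str], float] = {}
    for s1, s2 in product(panel.samples_for_role("P1"), panel.samples_for_role("P2")):
        abba, baba, _ = _pattern_weights(indiv_freq(s1), indiv_freq(s2), f3, fO)
        ds = []
        for w in windows:
            m = h.region_mask(w.region)
            tot = abba[m].sum() + baba[m].sum()
            if tot > 0:
                ds.append((abba[m].sum() - baba[m].sum()) / tot)
        if not ds:
            warnings.warn(f"combo {(s1, s2)} has no informative windows; excluded")
            continue
        per_combo[(s1, s2)] = float(np.mean(ds))
    if not per_combo:
        raise ValueError("no combination produced an informative window")
    grand = float(np.mean(list(per_combo.values())))
    return per_combo, grand


def block_bootstrap_ci(
    window_values: np.ndarray,
    replicates: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Moving-blocks bootstrap percentile CI for the mean of windowed values.

    Windows are the blocks: each replicate resamples n windows with
    replacement (n = number of non-missing windows) and records the mean.
    Deterministic for a fixed seed.
    """
    values = np.asarray(window_values, dtype=float)
    values = values[~np.isnan(values)]
    n = len(values)
    if n < 2:
        raise ValueError("need at least two non-missing windows for a bootstrap CI")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(replicates, n))
    means = values[idx].mean(axis=1)
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [tail, 1.0 - tail])
    return float(lo), float(hi)


def triplet_similarity_scan(
    h: HaplotypeMatrix,
    seq_a: str,
    seq_b: str,
    seq_c: str,
    window: int = 100,
    step: int = 1,
) -> pd.DataFrame:
    """Sliding pairwise percent identity for a haplotype triplet over informative sites.

    Windows contain a fixed number of triplet-informative sites (sites where
    the three alleles are not all equal and none missing). Returns a frame
    with the window-center bp coordinate and AB/AC/BC percent identities.
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be positive")
    mask = informative_sites(h, [seq_a, seq_b, seq_c])
    info_idx = np.flatnonzero(mask)
    if len(info_idx) < window:
        raise ValueError(
            f"only {len(info_idx)} informative sites; at least {window} required "
            "(reduce the window size or supply a longer region)"
        )
    cols = h.columns_for([seq_a, seq_b, seq_c])
    a = h.alleles[info_idx, cols[0]]
    b = h.alleles[info_idx, cols[1]]
    c = h.alleles[info_idx, cols[2]]
    pos = h.positions[info_idx]

    eq = {"ab": (a == b).astype(float), "ac": (a == c).astype(float), "bc": (b == c).astype(float)}
    starts = np.arange(0, len(info_idx) - window + 1, step)
    csum = {k: np.concatenate([[0.0], np.cumsum(v)]) for k, v in eq.items()}
    rows = {
        k: 100.0 * (csum[k][starts + window] - csum[k][starts]) / window for k in eq
    }
    centers = pos[starts + window // 2]
    return pd.DataFrame(
        {
            "pos": centers,
            "similarity_ab": rows["ab"],
            "similarity_ac": rows["ac"],
            "similarity_bc": rows["bc"],
        }
    )
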