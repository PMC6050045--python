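"""Data model and I/O for phased variants, sample panels, regions, and depth tracks.

Coordinates are 1-based inclusive throughout (VCF convention); BED exports
convert to 0-based half-open. Haplotype columns are ordered sample-major,
phase-minor, so results are reproducible across runs.

Allele codes in a :class:`HaplotypeMatrix` are ``0`` (reference or, after
polarization, ancestral), ``1`` (alternate/derived), and ``-1`` (missing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GenomicRegion",
    "SiteTable",
    "HaplotypeMatrix",
    "PopulationPanel",
    "DepthTrack",
    "Window",
    "read_phased_vcf",
    "write_phased_vcf",
    "polarize_by_outgroup",
    "informative_sites",
    "make_windows",
    "read_panel",
    "read_depth_tsv",
    "write_depth_tsv",
    "read_recombination_map",
]

logger = logging.getLogger(__name__)

MISSING = -1

QUARTET_ROLES = ("P1", "P2", "P3", "O")


@dataclass(frozen=True)
class GenomicRegion:
    """A 1-based inclusive interval on a scaffold."""

    scaffold: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"region start {self.start} > end {self.end} on {self.scaffold}"
            )
        if self.start < 1:
            raise ValueError("coordinates are 1-based; start must be >= 1")

    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.scaffold == other.scaffold
            and self.start <= other.end
            and other.start <= self.end
        )

    def to_bed(self) -> tuple[str, int, int]:
        """0-based half-open (chrom, chromStart, chromEnd)."""
        return (self.scaffold, self.start - 1, self.end)

    def __str__(self) -> str:
        return f"{self.scaffold}:{self.start}-{self.end}"


@dataclass
class SiteTable:
    """Per-site metadata for retained biallelic SNPs, positions strictly increasing."""

    scaffold: str
    positions: np.ndarray  # int64, 1-based
    ref: np.ndarray  # unicode single characters
    alt: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ref = np.asarray(self.ref)
        self.alt = np.asarray(self.alt)
        if len(self.positions) != len(self.ref) or len(self.ref) != len(self.alt):
            raise ValueError("positions, ref, alt must have equal length")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("site positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.positions)

    def subset(self, mask: np.ndarray) -> "SiteTable":
        return SiteTable(self.scaffold, self.positions[mask], self.ref[mask], self.alt[mask])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"scaffold": self.scaffold, "pos": self.positions, "ref": self.ref, "alt": self.alt}
        )


@dataclass
class HaplotypeMatrix:
    """Phased allele codes, sites x haplotypes.

    ``labels[2*i]`` and ``labels[2*i+1]`` are the two phases of diploid sample
    ``samples[i]`` (labels ``"<sample>|0"`` and ``"<sample>|1"``).
    ``positions`` mirrors the accompanying :class:`SiteTable` so haplotype-level
    operations (EHH, shared-haplotype delineation) are self-contained.
    """

    alleles: np.ndarray  # int8, sites x haplotypes, {0,1,MISSING}
    labels: list[str]
    positions: np.ndarray
    scaffold: str = "unknown"
    phased: bool = True

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D sites x haplotypes array")
        if self.alleles.shape[0] != len(self.positions):
            raise ValueError("row count must equal number of site positions")
        if self.alleles.shape[1] != len(self.labels):
            raise ValueError("column count must equal number of haplotype labels")
        bad = ~np.isin(self.alleles, (0, 1, MISSING))
        if bad.any():
            raise ValueError("allele codes must be 0, 1, or missing (-1)")

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[1]

    @property
    def samples(self) -> list[str]:
        return [lab.rsplit("|", 1)[0] for lab in self.labels[::2]]

    def columns_for(self, names: Iterable[str]) -> np.ndarray:
        """Column indices for haplotype labels or diploid sample ids (both phases)."""
        index = {lab: i for i, lab in enumerate(self.labels)}
        cols: list[int] = []
        for name in names:
            if name in index:
                cols.append(index[name])
            elif f"{name}|0" in index:
                cols.append(index[f"{name}|0"])
                cols.append(index[f"{name}|1"])
            else:
                raise KeyError(f"unknown haplotype or sample id: {name!r}")
        return np.asarray(cols, dtype=np.intp)

    def nearest_site(self, pos: int) -> int:
        """Position of the site closest to ``pos``."""
        if self.n_sites == 0:
            raise ValueError("matrix has no sites")
        i = int(np.searchsorted(self.positions, pos))
        candidates = [j for j in (i - 1, i) if 0 <= j < self.n_sites]
        best = min(candidates, key=lambda j: abs(int(self.positions[j]) - pos))
        return int(self.positions[best])

    def site_index(self, pos: int) -> int:
        i = int(np.searchsorted(self.positions, pos))
        if i >= len(self.positions) or self.positions[i] != pos:
            raise KeyError(f"no site at position {pos}")
        return i

    def region_mask(self, region: GenomicRegion) -> np.ndarray:
        return (self.positions >= region.start) & (self.positions <= region.end)

    def derived_frequency(self, cols: np.ndarray) -> np.ndarray:
        """Per-site derived (code 1) frequency over the given columns.

        Missing alleles are dropped site-wise (pairwise deletion); sites with
        no non-missing call get NaN.
        """
        sub = self.alleles[:, cols]
        called = sub != MISSING
        n = called.sum(axis=1)
        k = (sub == 1).sum(axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, k / np.maximum(n, 1), np.nan)


@dataclass
class PopulationPanel:
    """Named sample groups with optional four-taxon roles P1/P2/P3/O.

    Roles follow the gene-flow test arrangement: P1 recipient-ancestral (bar),
    P2 recipient-derived (checker), P3 donor species, O outgroup.
    """

    groups: dict[str, list[str]]
    roles: dict[str, str] = field(default_factory=dict)  # role -> group name

    def __post_init__(self) -> None:
        for role in self.roles:
            if role not in QUARTET_ROLES:
                raise ValueError(f"unknown quartet role {role!r}")
            if self.roles[role] not in self.groups:
                raise ValueError(f"role {role} points to unknown group {self.roles[role]!r}")
        assigned = [self.roles[r] for r in self.roles]
        members: set[str] = set()
        for g in assigned:
            ids = set(self.groups[g])
            if members & ids:
                raise ValueError("quartet role groups must be disjoint")
            members |= ids

    def samples_for_role(self, role: str) -> list[str]:
        if role not in self.roles:
            raise KeyError(f"quartet role {role} not assigned")
        ids = self.groups[self.roles[role]]
        if not ids:
            raise ValueError(f"group for role {role} is empty")
        return ids

    def require_quartet(self) -> None:
        for role in QUARTET_ROLES:
            self.samples_for_role(role)


@dataclass
class DepthTrack:
    """Read depth along a scaffold, per position or per bin start."""

    scaffold: str
    positions: np.ndarray  # 1-based position (or bin start)
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.depth = np.asarray(self.depth, dtype=float)
        if len(self.positions) != len(self.depth):
            raise ValueError("positions and depth must have equal length")
        if np.any(self.depth < 0):
            raise ValueError("depth must be nonnegative")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("depth coordinates must be sorted ascending")

    def mean_in(self, region: GenomicRegion) -> float:
        mask = (self.positions >= region.start) & (self.positions <= region.end)
        if not mask.any():
            raise ValueError(f"depth track has no coverage in {region}")
        return float(self.depth[mask].mean())


@dataclass(frozen=True)
class Window:
    region: GenomicRegion
    partial: bool = False


def make_windows(region: GenomicRegion, size: int, step: int) -> list[Window]:
    """Tile a region with (possibly overlapping) windows.

    Windows advance by ``step`` until one reaches the region end; a final
    short window is retained and flagged partial. With ``step == size`` the
    tiling covers every position exactly once.
    """
    if size <= 0 or step <= 0:
        raise ValueError("window size and step must be positive")
    windows: list[Window] = []
    start = region.start
    while start <= region.end:
        end = min(start + size - 1, region.end)
        windows.append(
            Window(GenomicRegion(region.scaffold, start, end), partial=(end - start + 1) < size)
        )
        if end >= region.end:
            break
        start += step
    return windows


# ---------------------------------------------------------------------------
# VCF I/O


def read_phased_vcf(
    path: str,
    region: GenomicRegion | None = None,
    samples: Sequence[str] | None = None,
    require_phased: bool = True,
) -> tuple[SiteTable, HaplotypeMatrix]:
    """Read biallelic SNP genotypes from a VCF into a site table and haplotype matrix.

    Indels and multiallelic records are dropped (with a logged count). When
    ``require_phased`` is set, any unphased non-missing diploid genotype raises,
    naming the offending record.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    available = list(vcf.samples)
    if samples is not None:
        missing = [s for s in samples if s not in available]
        if missing:
            raise KeyError(f"sample ids not in VCF: {missing}")
        vcf.close()
        vcf = VCF(path, samples=list(samples))
    sample_names = list(vcf.samples)

    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    rows: list[np.ndarray] = []
    scaffold: str | None = None
    n_dropped = 0

    for variant in vcf:
        if region is not None:
            if variant.CHROM != region.scaffold:
                continue
            if not (region.start <= variant.POS <= region.end):
                continue
        if len(variant.ALT) != 1 or len(variant.REF) != 1 or len(variant.ALT[0]) != 1:
            n_dropped += 1
            continue
        if scaffold is None:
            scaffold = variant.CHROM
        gts = variant.genotypes  # [[a0, a1, phased], ...]
        row = np.empty(2 * len(sample_names), dtype=np.int8)
        for i, gt in enumerate(gts):
            a0, a1, phased = gt[0], gt[1], bool(gt[-1])
            if require_phased and not phased and (a0 >= 0 and a1 >= 0) and len(gt) > 2:
                raise ValueError(
                    f"unphased genotype for sample {sample_names[i]} at "
                    f"{variant.CHROM}:{variant.POS}; phased GT required"
                )
            row[2 * i] = a0 if a0 >= 0 else MISSING
            row[2 * i + 1] = a1 if a1 >= 0 else MISSING
        positions.append(variant.POS)
        refs.append(variant.REF)
        alts.append(variant.ALT[0])
        rows.append(row)
    vcf.close()

    if n_dropped:
        logger.info("dropped %d non-biallelic-SNP records from %s", n_dropped, path)
    if scaffold is None:
        scaffold = region.scaffold if region is not None else "unknown"
    alleles = np.vstack(rows) if rows else np.zeros((0, 2 * len(sample_names)), dtype=np.int8)
    labels = [f"{s}|{p}" for s in sample_names for p in (0, 1)]
    sites = SiteTable(scaffold, np.array(positions, dtype=np.int64), np.array(refs), np.array(alts))
    hmat = HaplotypeMatrix(alleles, labels, sites.positions.copy(), scaffold=scaffold)
    return sites, hmat


def write_phased_vcf(sites: SiteTable, h: HaplotypeMatrix, path: str) -> None:
    """Write a minimal phased VCF v4.2 (GT-only) for the matrix.

    Round-trips exactly through :func:`read_phased_vcf`.
    """
    samples = h.samples
    if 2 * len(samples) != h.n_haplotypes:
        raise ValueError("matrix must hold diploid sample pairs to export as VCF")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={sites.scaffold}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for i in range(len(sites)):
            calls = []
            for j in range(len(samples)):
                a0, a1 = h.alleles[i, 2 * j], h.alleles[i, 2 * j + 1]
                s0 = "." if a0 == MISSING else str(int(a0))
                s1 = "." if a1 == MISSING else str(int(a1))
                calls.append(f"{s0}|{s1}")
            fh.write(
                f"{sites.scaffold}\t{sites.positions[i]}\t.\t{sites.ref[i]}\t{sites.alt[i]}"
                f"\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


# ---------------------------------------------------------------------------
# Site-level transforms


def polarize_by_outgroup(
    h: HaplotypeMatrix, outgroup: Iterable[str]
) -> tuple[HaplotypeMatrix, np.ndarray]:
    """Recode alleles so 1 = derived, using outgroup haplotypes as the ancestral proxy.

    Sites where the outgroup is polymorphic or entirely missing are dropped;
    their positions are returned. At every retained site the derived-allele
    frequency in the outgroup is 0.
    """
    cols = h.columns_for(list(outgroup))
    if len(cols) == 0:
        raise ValueError("outgroup haplotype set is empty")
    out = h.alleles[:, cols]
    has0 = (out == 0).any(axis=1)
    has1 = (out == 1).any(axis=1)
    keep = has0 ^ has1  # exactly one allele observed in outgroup
    flip = has1 & keep
    alleles = h.alleles[keep].copy()
    flip_rows = flip[keep]
    sub = alleles[flip_rows]
    nonmiss = sub != MISSING
    sub[nonmiss] = 1 - sub[nonmiss]
    alleles[flip_rows] = sub
    dropped = h.positions[~keep]
    polarized = HaplotypeMatrix(
        alleles, list(h.labels), h.positions[keep], scaffold=h.scaffold, phased=h.phased
    )
    return polarized, dropped


def informative_sites(h: HaplotypeMatrix, sequences: Sequence[str]) -> np.ndarray:
    """Mask of sites where three chosen haplotypes are not all identical and none missing."""
    if len(sequences) < 3:
        raise ValueError("three haplotypes are required")
    cols = h.columns_for(sequences)
    if len(cols) != 3:
        raise ValueError("exactly three haplotypes (not diploid samples) are required")
    sub = h.alleles[:, cols]
    complete = (sub != MISSING).all(axis=1)
    varies = ~np.all(sub == sub[:, [0]], axis=1)
    return complete & varies


# ---------------------------------------------------------------------------
# Tabular readers


def read_panel(path: str) -> PopulationPanel:
    """Read a sample panel TSV: sample_id <TAB> group <TAB> role (role '.' for none)."""
    groups: dict[str, list[str]] = {}
    roles: dict[str, str] = {}
    df = pd.read_csv(
        path, sep="\t", header=None, names=["sample_id", "group", "role"], comment="#", dtype=str
    )
    for _, row in df.iterrows():
        groups.setdefault(row["group"], []).append(row["sample_id"])
        role = row.get("role")
        if isinstance(role, str) and role not in (".", "", "-"):
            prev = roles.get(role)
            if prev is not None and prev != row["group"]:
                raise ValueError(f"role {role} assigned to two groups: {prev}, {row['group']}")
            roles[role] = row["group"]
    return PopulationPanel(groups, roles)


def read_depth_tsv(path: str) -> DepthTrack:
    """Read a per-position depth table (gdepth dialect): scaffold, pos, depth; header allowed."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = [c.lower() for c in df.columns]
    if not {"scaffold", "pos", "depth"}.issubset(cols):
        df = pd.read_csv(path, sep="\t", header=None, names=["scaffold", "pos", "depth"])
    else:
        df.columns = cols
    scaffolds = df["scaffold"].unique()
    if len(scaffolds) != 1:
        raise ValueError("depth table must cover a single scaffold")
    df = df.sort_values("pos")
    return DepthTrack(str(scaffolds[0]), df["pos"].to_numpy(), df["depth"].to_numpy())


def write_depth_tsv(track: DepthTrack, path: str) -> None:
    pd.DataFrame(
        {"scaffold": track.scaffold, "pos": track.positions, "depth": track.depth}
    ).to_csv(path, sep="\t", index=False)


def read_recombination_map(path: str) -> pd.DataFrame:
    """Read a 2-column genetic map TSV (pos, cM), cumulative map position in cM."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"pos", "cM"}.issubset(df.columns):
        df = pd.read_csv(path, sep="\t", header=None, names=["pos", "cM"])
    df = df.sort_values("pos").reset_index(drop=True)
    return df
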