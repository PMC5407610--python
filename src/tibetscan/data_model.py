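"""Core genomic containers: haplotype panels, site frequency tables, windows.

Coordinate conventions
----------------------
All internal arithmetic is 0-based half-open; every reported/printed
coordinate is 1-based inclusive (so a 200-kb window starts at
``k*200000 + 1``). Allele encoding is ``0`` = ancestral, ``1`` = derived,
``MISSING`` (= -1) = no call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MISSING: int = -1

__all__ = [
    "MISSING",
    "HaplotypePanel",
    "SiteFrequencyTable",
    "WindowTable",
    "IntervalCI",
    "allele_counts",
    "site_frequency_table",
    "partition_windows",
    "assign_windows",
    "merge_adjacent",
    "exact_binomial_ci",
]


class PopulationError(KeyError):
    """Raised when a population label is not present in a panel/table."""


@dataclass
class HaplotypePanel:
    """Phased 0/1 haplotype-by-site matrix with population bookkeeping.

    Parameters
    ----------
    chromosome :
        Chromosome label.
    positions :
        1-based physical positions (bp), strictly increasing, shape (S,).
    alleles :
        int8 matrix of shape (H, S); 0 ancestral, 1 derived, -1 missing.
    haplotype_individuals :
        Individual id for each haplotype row, shape (H,).
    individual_populations :
        Mapping individual id -> population label.
    genetic_positions :
        Optional map positions in cM, non-decreasing, shape (S,). When
        absent, statistics fall back to physical distance at 1 cM/Mb.
    """

    chromosome: str
    positions: np.ndarray
    alleles: np.ndarray
    haplotype_individuals: np.ndarray
    individual_populations: dict[str, str]
    genetic_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.haplotype_individuals = np.asarray(self.haplotype_individuals)
        if self.genetic_positions is not None:
            self.genetic_positions = np.asarray(self.genetic_positions, dtype=float)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D (haplotype x site)")
        H, S = self.alleles.shape
        if self.positions.shape != (S,):
            raise ValueError("positions length must match number of sites")
        if S > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if self.haplotype_individuals.shape != (H,):
            raise ValueError("one individual id per haplotype required")
        bad = ~np.isin(self.alleles, (0, 1, MISSING))
        if bad.any():
            raise ValueError("allele values restricted to {0, 1, missing}")
        for ind in np.unique(self.haplotype_individuals):
            if ind not in self.individual_populations:
                raise ValueError(f"individual {ind!r} has no population assignment")
        if self.genetic_positions is not None:
            if self.genetic_positions.shape != (S,):
                raise ValueError("genetic_positions length must match sites")
            if S > 1 and np.any(np.diff(self.genetic_positions) < 0):
                raise ValueError("genetic_positions must be non-decreasing")

    # -- derived views --------------------------------------------------
    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.haplotype_individuals:
            seen.setdefault(self.individual_populations[str(ind)], None)
        return list(seen)

    def haplotype_populations(self) -> np.ndarray:
        return np.array(
            [self.individual_populations[str(i)] for i in self.haplotype_individuals]
        )

    def population_haplotypes(self, population: str) -> np.ndarray:
        """Row indices of the haplotypes belonging to ``population``."""
        mask = self.haplotype_populations() == population
        if not mask.any():
            raise PopulationError(population)
        return np.flatnonzero(mask)

    def cm_positions(self) -> np.ndarray:
        """Genetic positions, falling back to 1 cM/Mb from physical bp."""
        if self.genetic_positions is not None:
            return self.genetic_positions
        return self.positions.astype(float) * 1e-6

    def subset(
        self,
        sites: np.ndarray | None = None,
        haplotypes: np.ndarray | None = None,
    ) -> "HaplotypePanel":
        sites = np.arange(self.n_sites) if sites is None else np.asarray(sites)
        haps = np.arange(self.n_haplotypes) if haplotypes is None else np.asarray(haplotypes)
        return HaplotypePanel(
            chromosome=self.chromosome,
            positions=self.positions[sites],
            alleles=self.alleles[np.ix_(haps, sites)],
            haplotype_individuals=self.haplotype_individuals[haps],
            individual_populations=dict(self.individual_populations),
            genetic_positions=None
            if self.genetic_positions is None
            else self.genetic_positions[sites],
        )


@dataclass
class SiteFrequencyTable:
    """Per-site derived-allele counts per population plus archaic/outgroup.

    Frequencies are always derived on demand from integer counts and never
    stored rounded. Archaic tracks are stored as (derived, total) chromosome
    counts (a missing archaic call at a site has total 0); the outgroup
    track is a single allele per site.
    """

    chromosome: str
    positions: np.ndarray
    derived: dict[str, np.ndarray]
    total: dict[str, np.ndarray]
    archaic: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    outgroup_allele: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        for pop in self.derived:
            d = np.asarray(self.derived[pop], dtype=np.int64)
            t = np.asarray(self.total[pop], dtype=np.int64)
            if np.any(d < 0) or np.any(d > t):
                raise ValueError(f"require 0 <= derived <= total for {pop!r}")
            self.derived[pop], self.total[pop] = d, t
        if self.outgroup_allele is None:
            # Ancestral polarity is known by construction for simulated data.
            self.outgroup_allele = np.zeros(len(self.positions), dtype=np.int8)
        else:
            self.outgroup_allele = np.asarray(self.outgroup_allele, dtype=np.int8)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def populations(self) -> list[str]:
        return list(self.derived)

    def _require(self, population: str) -> None:
        if population not in self.derived:
            raise PopulationError(population)

    def frequency(self, population: str) -> np.ndarray:
        """Derived-allele frequency; NaN where no chromosomes were called."""
        self._require(population)
        t = self.total[population].astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(t > 0, self.derived[population] / t, np.nan)

    def minor_allele_frequency(self, population: str) -> np.ndarray:
        f = self.frequency(population)
        return np.minimum(f, 1.0 - f)

    def archaic_frequency(self, track: str) -> np.ndarray:
        if track not in self.archaic:
            raise PopulationError(track)
        d, t = self.archaic[track]
        t = np.asarray(t, dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(t > 0, np.asarray(d, dtype=float) / t, np.nan)

    def outgroup_frequency(self) -> np.ndarray:
        out = self.outgroup_allele.astype(float)
        return np.where(out == MISSING, np.nan, out)

    def subset(self, sites: np.ndarray) -> "SiteFrequencyTable":
        sites = np.asarray(sites)
        return SiteFrequencyTable(
            chromosome=self.chromosome,
            positions=self.positions[sites],
            derived={p: c[sites] for p, c in self.derived.items()},
            total={p: c[sites] for p, c in self.total.items()},
            archaic={a: (d[sites], t[sites]) for a, (d, t) in self.archaic.items()},
            outgroup_allele=self.outgroup_allele[sites],
        )


def allele_counts(panel: HaplotypePanel, population: str) -> tuple[np.ndarray, np.ndarray]:
    """Derived and called chromosome counts per site for one population.

    Missing alleles are excluded from both numerator and denominator
    (per-site complete case).
    """
    rows = panel.population_haplotypes(population)
    sub = panel.alleles[rows]
    derived = (sub == 1).sum(axis=0).astype(np.int64)
    total = (sub != MISSING).sum(axis=0).astype(np.int64)
    return derived, total


def site_frequency_table(
    panel: HaplotypePanel,
    populations: list[str] | None = None,
    archaic: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
    outgroup_allele: np.ndarray | None = None,
) -> SiteFrequencyTable:
    """Tabulate per-population derived counts from a phased panel."""
    pops = populations if populations is not None else panel.populations
    derived: dict[str, np.ndarray] = {}
    total: dict[str, np.ndarray] = {}
    for pop in pops:
        derived[pop], total[pop] = allele_counts(panel, pop)
    return SiteFrequencyTable(
        chromosome=panel.chromosome,
        positions=panel.positions,
        derived=derived,
        total=total,
        archaic=dict(archaic or {}),
        outgroup_allele=outgroup_allele,
    )


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------


@dataclass
class WindowTable:
    """Fixed-width windows tiling a chromosome, 1-based inclusive bounds."""

    chromosome: str
    width: int
    table: pd.DataFrame  # columns: chrom, start, end (+ aggregates)

    def __len__(self) -> int:
        return len(self.table)

    def to_bed(self) -> pd.DataFrame:
        """BED-compatible 0-based half-open view."""
        bed = self.table.copy()
        bed["start"] = bed["start"] - 1
        return bed


def partition_windows(chromosome_length: int, width: int, chromosome: str = "1") -> WindowTable:
    """Tile ``[1, chromosome_length]`` with consecutive ``width``-bp windows.

    The last window may be short. Window k (0-based) reports 1-based
    inclusive bounds ``[k*width + 1, min((k+1)*width, length)]``.
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    if chromosome_length <= 0:
        raise ValueError("chromosome length must be positive")
    n = int(np.ceil(chromosome_length / width))
    start0 = np.arange(n, dtype=np.int64) * width
    end0 = np.minimum(start0 + width, chromosome_length)
    table = pd.DataFrame(
        {"chrom": chromosome, "start": start0 + 1, "end": end0}
    )
    return WindowTable(chromosome=chromosome, width=width, table=table)


def assign_windows(positions: np.ndarray, width: int) -> np.ndarray:
    """0-based window index for each 1-based position. Every site maps to
    exactly one window per width."""
    if width <= 0:
        raise ValueError("window width must be positive")
    return (np.asarray(positions, dtype=np.int64) - 1) // width


def merge_adjacent(
    windows: WindowTable,
    selected: np.ndarray,
    score: str | np.ndarray | None = None,
) -> pd.DataFrame:
    """Merge maximal runs of adjacent selected windows into intervals.

    The per-interval aggregate is the max of member scores (matching how
    merged top regions report their best window score).
    """
    selected = np.asarray(selected, dtype=bool)
    if selected.shape != (len(windows),):
        raise ValueError("selected flags must align with windows")
    tab = windows.table
    if isinstance(score, str):
        scores = tab[score].to_numpy(dtype=float)
    elif score is None:
        scores = np.full(len(windows), np.nan)
    else:
        scores = np.asarray(score, dtype=float)
    out: list[dict] = []
    idx = np.flatnonzero(selected)
    if idx.size == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "score", "n_windows"])
    run_start = idx[0]
    prev = idx[0]
    runs: list[tuple[int, int]] = []
    for i in idx[1:]:
        if i != prev + 1:
            runs.append((run_start, prev))
            run_start = i
        prev = i
    runs.append((run_start, prev))
    for a, b in runs:
        member = scores[a : b + 1]
        out.append(
            {
                "chrom": tab["chrom"].iloc[a],
                "start": int(tab["start"].iloc[a]),
                "end": int(tab["end"].iloc[b]),
                "score": np.nan if np.all(np.isnan(member)) else np.nanmax(member),
                "n_windows": b - a + 1,
            }
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Exact binomial interval
# ---------------------------------------------------------------------------


@dataclass
class IntervalCI:
    """Point estimate with a confidence interval."""

    point: float
    lower: float
    upper: float
    method: str = "exact-binomial"

    def __post_init__(self) -> None:
        if not (self.lower <= self.point <= self.upper):
            raise ValueError("require lower <= point <= upper")

    def __iter__(self):
        yield from (self.point, self.lower, self.upper)


def exact_binomial_ci(successes: int, trials: int, level: float = 0.95) -> IntervalCI:
    """Clopper-Pearson interval by inversion of the binomial CDF.

    ``lower = 0`` when ``successes = 0`` and ``upper = 1`` when
    ``successes = trials``.
    """
    if not 0 <= successes <= trials or trials <= 0:
        raise ValueError("require 0 <= successes <= trials, trials > 0")
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must be in (0, 1)")
    alpha = 1.0 - level
    k, n = successes, trials
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2.0, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return IntervalCI(point=k / n, lower=lower, upper=upper, method="exact-binomial")
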