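"""Core data model: genotype matrices, population maps and shared errors.

Genotypes are stored as small integer codes per sample and site:
``0`` homozygous reference, ``1`` heterozygous, ``2`` homozygous alternative,
and :data:`MISSING` (``-1``) for uncalled genotypes.  Site coordinates are
1-based (VCF convention); all internal window arithmetic converts to 0-based
half-open intervals at the point of use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

MISSING: int = -1

DIPLOID = "diploid"
HAPLOID_AS_DIPLOID = "haploid-as-diploid"

_VALID_CODES = frozenset({MISSING, 0, 1, 2})


class ArctosError(Exception):
    """Base class for package errors."""


class VcfParseError(ArctosError):
    """Raised when a VCF cannot be parsed."""


class EmptyMatrixError(ArctosError):
    """Raised when filtering or parsing leaves zero usable sites."""


class ConfigurationError(ArctosError):
    """Raised for inconsistent sample/population configuration."""


class UndefinedDistanceError(ArctosError):
    """Raised when a pairwise distance has an empty denominator."""


class ExtinctionError(ArctosError):
    """Raised when a simulated population size reaches zero."""


@dataclass
class GenotypeMatrix:
    """Samples x biallelic-sites genotype matrix.

    Parameters
    ----------
    sample_ids:
        Sample identifiers, one per matrix row.
    chrom:
        Per-site chromosome label (array of str).
    pos:
        Per-site 1-based coordinate; strictly increasing within a chromosome.
    genotypes:
        ``(n_samples, n_sites)`` int8 array of codes in ``{-1, 0, 1, 2}``.
    ploidy_flag:
        ``"diploid"`` or ``"haploid-as-diploid"``; the latter promises the
        matrix contains no heterozygous calls (haploid genotypes promoted to
        homozygous diploid codes).
    """

    sample_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    genotypes: np.ndarray
    ploidy_flag: str = DIPLOID

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ArctosError("genotypes must be a 2-D samples x sites array")
        if self.genotypes.shape != (len(self.sample_ids), self.pos.size):
            raise ArctosError(
                f"genotype array shape {self.genotypes.shape} does not match "
                f"{len(self.sample_ids)} samples x {self.pos.size} sites"
            )
        if self.chrom.size != self.pos.size:
            raise ArctosError("chrom and pos must have equal length")

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        codes = np.unique(self.genotypes)
        bad = set(codes.tolist()) - _VALID_CODES
        if bad:
            raise ArctosError(f"invalid genotype codes: {sorted(bad)}")
        for c in self.chromosomes():
            p = self.pos[self.chrom == c]
            if p.size > 1 and not np.all(np.diff(p) > 0):
                raise ArctosError(f"positions not strictly increasing on {c}")
        if self.ploidy_flag == HAPLOID_AS_DIPLOID and np.any(self.genotypes == 1):
            raise ArctosError("haploid-as-diploid matrix contains heterozygous calls")

    # -- basic properties ----------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return int(self.pos.size)

    def chromosomes(self) -> list[str]:
        """Chromosome labels in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def called(self) -> np.ndarray:
        """Boolean mask of called genotypes (same shape as ``genotypes``)."""
        return self.genotypes != MISSING

    # -- subsetting ----------------------------------------------------
    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            chrom=self.chrom[index],
            pos=self.pos[index],
            genotypes=self.genotypes[:, index],
            ploidy_flag=self.ploidy_flag,
        )

    def take_samples(self, index: Sequence[int]) -> "GenotypeMatrix":
        index = list(index)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in index],
            chrom=self.chrom,
            pos=self.pos,
            genotypes=self.genotypes[index, :],
            ploidy_flag=self.ploidy_flag,
        )

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise ConfigurationError(f"unknown sample {sample_id!r}") from None


@dataclass(frozen=True)
class SampleInfo:
    population: str
    sex: Optional[str] = None
    latitude: Optional[float] = None
    longitude: Optional[float] = None


@dataclass
class PopulationMap:
    """Mapping of sample id to population (plus optional sex and lat/lon)."""

    entries: dict[str, SampleInfo] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, info in self.entries.items():
            if not info.population:
                raise ConfigurationError(f"empty population label for sample {sid!r}")

    @classmethod
    def from_pairs(cls, pairs: Mapping[str, str] | Iterable[tuple[str, str]]) -> "PopulationMap":
        items = pairs.items() if isinstance(pairs, Mapping) else pairs
        return cls({sid: SampleInfo(pop) for sid, pop in items})

    def population(self, sample_id: str) -> str:
        try:
            return self.entries[sample_id].population
        except KeyError:
            raise ConfigurationError(f"sample {sample_id!r} missing from population map") from None

    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for info in self.entries.values():
            seen.setdefault(info.population, None)
        return list(seen)

    def samples(self, population: str) -> list[str]:
        return [s for s, info in self.entries.items() if info.population == population]

    def check_covers(self, gm: GenotypeMatrix) -> None:
        missing = [s for s in gm.sample_ids if s not in self.entries]
        if missing:
            raise ConfigurationError(f"samples missing from population map: {missing}")

    def coordinates(self, population: str) -> tuple[float, float]:
        """Centroid (latitude, longitude) of a population's samples."""
        lats = [i.latitude for i in self.entries.values()
                if i.population == population and i.latitude is not None]
        lons = [i.longitude for i in self.entries.values()
                if i.population == population and i.longitude is not None]
        if not lats or not lons:
            raise ConfigurationError(f"no coordinates recorded for population {population!r}")
        return float(np.mean(lats)), float(np.mean(lons))


@dataclass(frozen=True)
class CalledSiteCounts:
    """Site-pattern counts for one sample pair (or a sample against itself).

    ``n0``: identical homozygous pairs (AA/AA), ``n1``: homozygote against
    heterozygote (AA/AT), ``n2he``: both heterozygous (AT/AT), ``n2ho``:
    opposite homozygotes (AA/TT).
    """

    n0: int
    n1: int
    n2he: int
    n2ho: int

    def __post_init__(self) -> None:
        if min(self.n0, self.n1, self.n2he, self.n2ho) < 0:
            raise ArctosError("site-pattern counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n0 + self.n1 + self.n2he + self.n2ho


def pair_counts(gm: GenotypeMatrix, i: int, j: int) -> CalledSiteCounts:
    """Site-pattern counts between samples ``i`` and ``j`` (indices).

    Only sites called in both members are counted.  ``i == j`` is the
    self-comparison whose distance equals half the sample's heterozygosity.
    """
    gi = gm.genotypes[i]
    gj = gm.genotypes[j]
    both = (gi != MISSING) & (gj != MISSING)
    gi = gi[both]
    gj = gj[both]
    het_i = gi == 1
    het_j = gj == 1
    n2he = int(np.count_nonzero(het_i & het_j))
    n1 = int(np.count_nonzero(het_i ^ het_j))
    hom_pairs = ~(het_i | het_j)
    n2ho = int(np.count_nonzero(hom_pairs & (gi != gj)))
    n0 = int(np.count_nonzero(hom_pairs & (gi == gj)))
    return CalledSiteCounts(n0=n0, n1=n1, n2he=n2he, n2ho=n2ho)
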