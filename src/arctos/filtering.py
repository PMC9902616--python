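"""SNP filtering and per-population allele frequencies.

Filter order follows the standard SNP-panel workflow: individuals with
excess missingness are removed first, then sites failing missingness or
minor-allele-count thresholds, and finally the panel is thinned to at most
one SNP per fixed-width genomic window (the first SNP in each window is
kept, which makes thinning deterministic and idempotent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    MISSING,
    ConfigurationError,
    EmptyMatrixError,
    GenotypeMatrix,
    PopulationMap,
)


def filter_snps(
    gm: GenotypeMatrix,
    max_snp_missing: float = 0.01,
    max_ind_missing: float = 0.1,
    min_mac: int = 2,
    thin_bp: int = 20_000,
) -> GenotypeMatrix:
    """Apply missingness, minor-allele-count and thinning filters.

    Parameters mirror the usual SNP-panel defaults: at most 10% missing
    genotypes per individual, at most 1% missing calls per site, minor
    allele count of at least 2, and one SNP retained per 20 kb window.
    Set ``thin_bp=0`` to skip thinning.
    """
    for name, v in (("max_snp_missing", max_snp_missing), ("max_ind_missing", max_ind_missing)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if min_mac < 0 or thin_bp < 0:
        raise ValueError("min_mac and thin_bp must be non-negative")

    # 1. individual missingness
    miss = gm.genotypes == MISSING
    ind_frac = miss.mean(axis=1)
    keep_samples = np.nonzero(ind_frac <= max_ind_missing)[0]
    if keep_samples.size == 0:
        raise EmptyMatrixError("all samples exceed the individual missingness threshold")
    gm = gm.take_samples(keep_samples.tolist())

    # 2. site missingness and minor allele count
    g = gm.genotypes
    called = g != MISSING
    n_called = called.sum(axis=0)
    site_miss = 1.0 - n_called / gm.n_samples
    alt = np.where(called, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mac = np.minimum(alt, 2 * n_called - alt)
    keep = (site_miss <= max_snp_missing) & (mac >= min_mac) & (n_called > 0)
    gm = gm.take_sites(np.nonzero(keep)[0])
    if gm.n_sites == 0:
        raise EmptyMatrixError("all sites removed; filtering thresholds too strict")

    # 3. thinning: first SNP per thin_bp window per chromosome
    if thin_bp > 0:
        keep_idx = []
        for c in gm.chromosomes():
            idx = np.nonzero(gm.chrom == c)[0]
            win = (gm.pos[idx] - 1) // thin_bp
            first = np.ones(idx.size, dtype=bool)
            first[1:] = win[1:] != win[:-1]
            keep_idx.append(idx[first])
        gm = gm.take_sites(np.sort(np.concatenate(keep_idx)))
    return gm


@dataclass
class PopAlleleFrequencies:
    """Per-population alternative-allele frequencies at shared sites.

    ``freq`` is ``(n_populations, n_sites)`` with NaN where a population has
    no called genotype; ``n_called`` counts called diploid genotypes.
    """

    populations: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    freq: np.ndarray
    n_called: np.ndarray

    def of(self, population: str) -> np.ndarray:
        try:
            return self.freq[self.populations.index(population)]
        except ValueError:
            raise ConfigurationError(f"unknown population {population!r}") from None

    def counts_of(self, population: str) -> np.ndarray:
        return self.n_called[self.populations.index(population)]


def allele_frequencies(gm: GenotypeMatrix, popmap: PopulationMap) -> PopAlleleFrequencies:
    """Alternative-allele frequency per population and site.

    freq = (n_het + 2 * n_hom_alt) / (2 * n_called); sites with no called
    genotype in a population are NaN (undefined).
    """
    popmap.check_covers(gm)
    pops = [p for p in popmap.populations() if any(s in gm.sample_ids for s in popmap.samples(p))]
    n_sites = gm.n_sites
    freq = np.full((len(pops), n_sites), np.nan)
    n_called = np.zeros((len(pops), n_sites), dtype=np.int64)
    for k, pop in enumerate(pops):
        rows = [gm.sample_ids.index(s) for s in popmap.samples(pop) if s in gm.sample_ids]
        g = gm.genotypes[rows]
        called = g != MISSING
        nc = called.sum(axis=0)
        alt = np.where(called, g, 0).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = alt / (2.0 * nc)
        freq[k] = np.where(nc > 0, f, np.nan)
        n_called[k] = nc
    return PopAlleleFrequencies(
        populations=pops, chrom=gm.chrom, pos=gm.pos, freq=freq, n_called=n_called
    )
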