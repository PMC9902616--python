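"""Uncorrected genetic distances, D_XY, SNP distances and isolation by distance.

Two families of distance live here.  The *uncorrected* distances ``d`` work
on site-pattern counts and estimate the mean per-site difference between two
randomly drawn haplotypes:

haploid pairs
    ``d = n1 / (n0 + n1)`` (fraction of dissimilar jointly-called sites);
diploid pairs
    ``d = (0.5*n1 + 0.5*n2he + n2ho) / (n0 + n1 + n2he + n2ho)``, so the
    self-comparison of a sample equals half its genome-wide heterozygosity.

The *SNP* distances (allele-sharing distance, Euclidean distance) compare
genotype-code vectors between individuals and feed the clustering stack.
"""

from __future__ import annotations

import numpy as np

from .core import (
    MISSING,
    CalledSiteCounts,
    ConfigurationError,
    GenotypeMatrix,
    PopulationMap,
    UndefinedDistanceError,
    pair_counts,
)


def d_haploid(a_sites: np.ndarray, b_sites: np.ndarray) -> float:
    """Uncorrected distance between two haploid allele vectors.

    Sites missing (:data:`MISSING`) in either vector are ignored.
    """
    a = np.asarray(a_sites)
    b = np.asarray(b_sites)
    if a.shape != b.shape:
        raise ValueError("haplotype vectors differ in length")
    both = (a != MISSING) & (b != MISSING)
    n = int(both.sum())
    if n == 0:
        raise UndefinedDistanceError("no jointly called sites")
    return float(np.count_nonzero(a[both] != b[both]) / n)


def d_diploid(counts: CalledSiteCounts) -> float:
    """Uncorrected diploid distance from site-pattern counts."""
    if counts.total == 0:
        raise UndefinedDistanceError("no jointly called sites")
    return (0.5 * counts.n1 + 0.5 * counts.n2he + counts.n2ho) / counts.total


def pairwise_d(gm: GenotypeMatrix, rng: np.random.Generator | None = None,
               n_sites: int | None = None) -> tuple[list[str], np.ndarray]:
    """Matrix of uncorrected diploid distances between all samples.

    The diagonal holds the self-comparison (half the sample heterozygosity),
    which is non-zero by construction.  ``n_sites`` randomly thins the site
    set first (seeded via ``rng``); default uses all sites.
    """
    if n_sites is not None and n_sites < gm.n_sites:
        rng = rng or np.random.default_rng()
        gm = gm.take_sites(np.sort(rng.choice(gm.n_sites, size=n_sites, replace=False)))
    n = gm.n_samples
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            d = d_diploid(pair_counts(gm, i, j))
            out[i, j] = out[j, i] = d
    return list(gm.sample_ids), out


def dxy(gm: GenotypeMatrix, popmap: PopulationMap, pop_a: str, pop_b: str) -> float:
    """Mean uncorrected distance over all cross-population sample pairs."""
    ia = [gm.sample_ids.index(s) for s in popmap.samples(pop_a) if s in gm.sample_ids]
    ib = [gm.sample_ids.index(s) for s in popmap.samples(pop_b) if s in gm.sample_ids]
    if not ia or not ib:
        raise ConfigurationError(f"no samples for {pop_a!r} or {pop_b!r}")
    vals = [d_diploid(pair_counts(gm, i, j)) for i in ia for j in ib if i != j or pop_a != pop_b]
    if not vals:
        raise UndefinedDistanceError("no sample pairs between populations")
    return float(np.mean(vals))


def dxy_matrix(gm: GenotypeMatrix, popmap: PopulationMap) -> tuple[list[str], np.ndarray]:
    """D_XY between all population pairs (diagonal left at zero)."""
    pops = [p for p in popmap.populations() if any(s in gm.sample_ids for s in popmap.samples(p))]
    n = len(pops)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = dxy(gm, popmap, pops[i], pops[j])
    return pops, out


def snp_distance(gm: GenotypeMatrix, metric: str = "allele-sharing") -> tuple[list[str], np.ndarray]:
    """Allele-sharing (ASD) or Euclidean (ED) distance between individuals.

    ASD is the mean over jointly-called SNPs of ``|g_i - g_j| / 2`` (het-het
    pairs count as zero difference).  ED is the Euclidean norm of the code
    difference with pairwise-complete handling: the squared sum over jointly
    called sites is rescaled by ``n_total / n_joint`` before the square root,
    so samples with missing data remain comparable.
    """
    if metric not in {"allele-sharing", "asd", "euclidean", "ed"}:
        raise ValueError(f"unknown metric {metric!r}")
    g = gm.genotypes.astype(np.float64)
    g[gm.genotypes == MISSING] = np.nan
    n = gm.n_samples
    out = np.zeros((n, n))
    n_total = gm.n_sites
    for i in range(n):
        diff = g - g[i]
        joint = ~np.isnan(diff)
        nj = joint.sum(axis=1)
        if np.any(nj[np.arange(n) != i] == 0):
            bad = [gm.sample_ids[k] for k in np.nonzero(nj == 0)[0] if k != i]
            raise UndefinedDistanceError(
                f"no shared called sites between {gm.sample_ids[i]} and {bad}")
        if metric in {"allele-sharing", "asd"}:
            out[i] = np.nansum(np.abs(diff), axis=1) / (2.0 * nj)
        else:
            out[i] = np.sqrt(np.nansum(diff**2, axis=1) * (n_total / nj))
    np.fill_diagonal(out, 0.0)
    return list(gm.sample_ids), (out + out.T) / 2.0


# -- isolation by distance -------------------------------------------------

_EARTH_RADIUS_KM = 6371.0088


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance between two points in kilometres."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2 - lon1)
    a = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return float(2 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def ibd_regression(
    dxy_mat: np.ndarray,
    coordinates: list[tuple[float, float]],
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Isolation-by-distance test: D_XY against great-circle distance.

    ``coordinates`` holds per-population ``(latitude, longitude)`` centroids
    in the row order of ``dxy_mat``.  Returns ``(r, slope, p)`` where ``r``
    and ``slope`` come from ordinary least squares over population pairs and
    ``p`` is a one-sided Mantel permutation p-value (is the observed
    correlation larger than under random relabelling of populations).
    """
    dxy_mat = np.asarray(dxy_mat, dtype=float)
    n = dxy_mat.shape[0]
    if n < 3:
        raise ValueError("isolation-by-distance needs at least 3 populations")
    if len(coordinates) != n:
        raise ConfigurationError("one coordinate pair per population required")
    geo = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            geo[i, j] = geo[j, i] = haversine_km(*coordinates[i], *coordinates[j])
    iu = np.triu_indices(n, k=1)
    x = geo[iu]
    y = dxy_mat[iu]
    r = float(np.corrcoef(x, y)[0, 1])
    slope = float(np.polyfit(x, y, 1)[0])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        r_p = np.corrcoef(geo[np.ix_(perm, perm)][iu], y)[0, 1]
        if r_p >= r:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return r, slope, p
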