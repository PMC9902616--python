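"""f3 / f4 admixture statistics, Weir & Cockerham Fst, and drift algebra.

The f3-statistic for a target population A with donors B and C is the mean
over sites of ``(a - b) * (a - c)`` where the letters are alternative-allele
frequencies.  It is negative if and only if A is systematically intermediate
between the donors, which is the classic admixture signal.  The raw per-site
score is bounded in ``[-0.25, 1]``; the optional heterozygosity-normalised
variant divides the summed numerator by the summed target heterozygosity
``2 a (1 - a)`` (ratio of sums), which is the scale on which window scores
can exceed +/-5 and on which post-admixture drift raises the score by
``1 / (4 Ne)`` per generation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ArctosError, GenotypeMatrix, PopulationMap
from .filtering import PopAlleleFrequencies, allele_frequencies


def _shared(*freqs: np.ndarray) -> np.ndarray:
    mask = np.ones(freqs[0].shape, dtype=bool)
    for f in freqs:
        mask &= ~np.isnan(f)
    return mask


def f3(a: np.ndarray, b: np.ndarray, c: np.ndarray, normalize: bool = False) -> float:
    """Aggregate f3(A; B, C) over sites with defined frequencies everywhere.

    ``normalize=True`` divides the summed per-site scores by the summed
    target heterozygosity ``2 a (1 - a)`` instead of averaging.
    """
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    mask = _shared(a, b, c)
    if not mask.any():
        raise ArctosError("no sites with defined frequencies in all three populations")
    a, b, c = a[mask], b[mask], c[mask]
    num = (a - b) * (a - c)
    if not normalize:
        return float(num.mean())
    het = 2.0 * a * (1.0 - a)
    denom = het.sum()
    if denom == 0:
        raise ArctosError("target population is monomorphic at every shared site")
    return float(num.sum() / denom)


def f3_per_site(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Per-site (a - b)(a - c); NaN where any frequency is undefined."""
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    return (a - b) * (a - c)


def f4(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Four-population statistic: mean over sites of ``(a - b)(c - d)``."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    mask = _shared(a, b, c, d)
    if not mask.any():
        raise ArctosError("no sites with defined frequencies in all four populations")
    return float(((a - b) * (c - d))[mask].mean())


@dataclass
class F3WindowResult:
    """Windowed f3 summary for one triplet (A; B, C)."""

    triplet: tuple[str, str, str]
    windows: pd.DataFrame  # chrom, start, end, n_sites, f3
    mean_f3: float         # mean over retained windows
    prop_negative: float   # over all defined windows
    n_excluded: int        # windows beyond +/- exclusion_bound
    n_windows: int         # defined windows

    def __post_init__(self) -> None:
        assert 0.0 <= self.prop_negative <= 1.0 or np.isnan(self.prop_negative)


def f3_windows(
    gm_or_freqs: GenotypeMatrix | PopAlleleFrequencies,
    popmap: PopulationMap | None,
    triplet: tuple[str, str, str],
    window_bp: int = 50_000,
    exclusion_bound: float = 5.0,
    normalize: bool = True,
) -> F3WindowResult:
    """Windowed f3 scan with the extreme-window exclusion rule.

    Windows are anchored at coordinate 0 of each chromosome (0-based
    half-open, last partial window retained).  Windows whose score falls
    outside ``+/- exclusion_bound`` are excluded from the genome-wide mean
    but still count towards the proportion of negative windows.  The bound
    only bites for normalised scores (raw per-site f3 is bounded by 1).
    """
    if isinstance(gm_or_freqs, GenotypeMatrix):
        if popmap is None:
            raise ArctosError("population map required with a genotype matrix")
        freqs = allele_frequencies(gm_or_freqs, popmap)
    else:
        freqs = gm_or_freqs
    pa, pb, pc = (freqs.of(p) for p in triplet)
    mask = _shared(pa, pb, pc)

    rows = []
    seen: dict[str, None] = {}
    for ch in freqs.chrom:
        seen.setdefault(ch, None)
    for ch in seen:
        on = (freqs.chrom == ch) & mask
        if not on.any():
            continue
        win_idx = (freqs.pos[on] - 1) // window_bp
        a, b, c = pa[on], pb[on], pc[on]
        for w in np.unique(win_idx):
            sel = win_idx == w
            aw, bw, cw = a[sel], b[sel], c[sel]
            num = ((aw - bw) * (aw - cw)).sum()
            if normalize:
                denom = (2.0 * aw * (1.0 - aw)).sum()
                score = num / denom if denom > 0 else np.nan
            else:
                score = num / sel.sum()
            rows.append((ch, int(w) * window_bp, (int(w) + 1) * window_bp, int(sel.sum()), score))
    windows = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites", "f3"])
    defined = windows["f3"].dropna()
    retained = defined[(defined >= -exclusion_bound) & (defined <= exclusion_bound)]
    return F3WindowResult(
        triplet=triplet,
        windows=windows,
        mean_f3=float(retained.mean()) if len(retained) else float("nan"),
        prop_negative=float((defined < 0).mean()) if len(defined) else float("nan"),
        n_excluded=int(len(defined) - len(retained)),
        n_windows=int(len(defined)),
    )


def wc_fst(
    gm_or_freqs: GenotypeMatrix,
    popmap: PopulationMap,
    pop_a: str,
    pop_b: str,
) -> float:
    """Weir & Cockerham (1984) theta for two populations, ratio of sums.

    Computed per site from sample sizes, allele frequencies and observed
    heterozygote proportions, then aggregated as sum(a) / sum(a + b + c)
    over all sites; negative estimates are reported as-is.
    """
    rows_a = [gm_or_freqs.sample_ids.index(s) for s in popmap.samples(pop_a)
              if s in gm_or_freqs.sample_ids]
    rows_b = [gm_or_freqs.sample_ids.index(s) for s in popmap.samples(pop_b)
              if s in gm_or_freqs.sample_ids]
    if not rows_a or not rows_b:
        raise ArctosError(f"no samples for {pop_a!r} or {pop_b!r}")
    g = gm_or_freqs.genotypes
    return wc_fst_from_genotypes(g[rows_a], g[rows_b])


def wc_fst_from_genotypes(ga: np.ndarray, gb: np.ndarray) -> float:
    """Weir & Cockerham theta from two genotype-code blocks (samples x sites)."""
    from .core import MISSING

    stats = []
    for g in (ga, gb):
        called = g != MISSING
        n = called.sum(axis=0).astype(float)
        alt = np.where(called, g, 0).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = alt / (2 * n)
            h = (g == 1).sum(axis=0) / n
        stats.append((n, p, h))
    (na, pa, ha), (nb, pb, hb) = stats
    ok = (na > 0) & (nb > 0)
    na, pa, ha, nb, pb, hb = (x[ok] for x in (na, pa, ha, nb, pb, hb))
    r = 2.0
    nbar = (na + nb) / r
    # nc degenerates when either sample is empty; guarded by `ok`
    nc = (r * nbar - (na**2 + nb**2) / (r * nbar)) / (r - 1)
    pbar = (na * pa + nb * pb) / (r * nbar)
    s2 = (na * (pa - pbar) ** 2 + nb * (pb - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (na * ha + nb * hb) / (r * nbar)
    valid = nbar > 1
    nbar, nc, pbar, s2, hbar = (x[valid] for x in (nbar, nc, pbar, s2, hbar))
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    denom = (a + b + c).sum()
    if denom == 0:
        raise ArctosError("dataset is monomorphic; Fst undefined")
    return float(a.sum() / denom)


def drift_time_to_positive(b: float, ne: float) -> float:
    """Generations of pure drift for an initial f3 of ``b`` to reach zero.

    Post-admixture drift raises the (normalised) f3-score linearly by
    ``1 / (4 Ne)`` per generation, so the crossing time is ``-b * 4 * Ne``.
    """
    if ne <= 0:
        raise ValueError("Ne must be positive")
    if b > 0:
        raise ValueError("initial f3 already positive; no drift time to compute")
    return float(-b * 4.0 * ne)
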