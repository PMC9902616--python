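"""Windowed heterozygosity counting, ROH detection and F_ROH summaries.

Heterozygous and homozygous calls are counted per sample in non-overlapping
fixed-width windows (20 kb by default); window heterozygosity is
``He = n_het / (n_hom + n_het)``.  Runs of homozygosity are contiguous
stretches of low-He windows: seeds are maximal runs of windows below the He
threshold (0.05% by default, 0.0025% for error-free simulated data), and
adjacent seeds separated by at most ``max_gap_windows`` above-threshold (or
undefined) windows are merged when the merged region's length-weighted mean
He still falls below the threshold.  Segments spanning at least
``min_windows`` windows (10 x 20 kb = 200 kb by default) are reported.

F_ROH is the fraction of the callable genome inside ROHs, where "callable"
means windows with at least one called site for that sample.  Its standard
deviation across chromosomes separates recent chance inbreeding (patchy,
high sd) from long-term small population size (uniform, low sd).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import ArctosError, GenotypeMatrix

WINDOW_COLUMNS = ["sample", "chrom", "start", "end", "n_hom", "n_het", "he"]


@dataclass(frozen=True)
class ROHSegment:
    sample: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    n_windows: int
    mean_he: float

    @property
    def length(self) -> int:
        return self.end - self.start


def count_windows(
    gm: GenotypeMatrix,
    window_bp: int = 20_000,
    chrom_lengths: Optional[Mapping[str, int]] = None,
    all_sites_called: bool = False,
) -> pd.DataFrame:
    """Per-sample, per-window counts of called hom/het sites and He.

    With ``all_sites_called=True`` (simulated error-free data, where the
    genotype matrix holds only segregating sites) every base of the window is
    treated as a called homozygous site unless it is heterozygous; this
    requires ``chrom_lengths``.  Otherwise counts come from the matrix alone
    and windows run to the last observed site.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if all_sites_called and chrom_lengths is None:
        raise ValueError("all_sites_called requires chrom_lengths")
    rows = []
    for c in gm.chromosomes():
        on = gm.chrom == c
        pos0 = gm.pos[on] - 1  # 0-based
        if pos0.size > 1 and not np.all(np.diff(pos0) > 0):
            raise ArctosError(f"sites not sorted on chromosome {c}")
        length = (chrom_lengths or {}).get(c, int(pos0.max()) + 1 if pos0.size else window_bp)
        n_win = max(1, math.ceil(length / window_bp))
        win_of_site = pos0 // window_bp
        g = gm.genotypes[:, on]
        for s, sid in enumerate(gm.sample_ids):
            het = np.bincount(win_of_site[g[s] == 1], minlength=n_win)
            if all_sites_called:
                starts = np.arange(n_win) * window_bp
                widths = np.minimum(starts + window_bp, length) - starts
                called = widths
            else:
                called = np.bincount(win_of_site[g[s] != -1], minlength=n_win)
            hom = called - het
            with np.errstate(divide="ignore", invalid="ignore"):
                he = np.where(called > 0, het / np.maximum(called, 1), np.nan)
            for w in range(n_win):
                rows.append((sid, c, w * window_bp, min((w + 1) * window_bp, length),
                             int(hom[w]), int(het[w]), he[w]))
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


def call_roh(
    wt: pd.DataFrame,
    he_threshold: float = 0.0005,
    min_windows: int = 10,
    max_gap_windows: int = 2,
) -> list[ROHSegment]:
    """Seed-and-merge ROH detection on a window table.

    Windows with undefined He (no called sites) act as gap windows: they can
    be bridged, count towards ``max_gap_windows``, and contribute nothing to
    the merged mean.  Output segments per sample are sorted and disjoint.
    """
    if he_threshold <= 0:
        raise ValueError("he_threshold must be positive")
    segments: list[ROHSegment] = []
    for (sample, chrom), grp in wt.groupby(["sample", "chrom"], sort=False):
        grp = grp.sort_values("start")
        he = grp["he"].to_numpy()
        het = grp["n_het"].to_numpy(dtype=float)
        called = (grp["n_hom"] + grp["n_het"]).to_numpy(dtype=float)
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        low = np.where(np.isnan(he), False, he < he_threshold)
        # maximal runs of low windows
        seeds = []
        i = 0
        n = low.size
        while i < n:
            if low[i]:
                j = i
                while j + 1 < n and low[j + 1]:
                    j += 1
                seeds.append([i, j])
                i = j + 1
            else:
                i += 1
        # merge across short gaps when the merged mean stays below threshold
        merged: list[list[int]] = []
        for seed in seeds:
            if merged:
                prev = merged[-1]
                gap = seed[0] - prev[1] - 1
                if gap <= max_gap_windows:
                    tot_called = called[prev[0]:seed[1] + 1].sum()
                    tot_het = het[prev[0]:seed[1] + 1].sum()
                    if tot_called > 0 and tot_het / tot_called < he_threshold:
                        prev[1] = seed[1]
                        continue
            merged.append(list(seed))
        for a, b in merged:
            n_windows = b - a + 1
            if n_windows < min_windows:
                continue
            tot_called = called[a:b + 1].sum()
            mean_he = float(het[a:b + 1].sum() / tot_called) if tot_called > 0 else 0.0
            segments.append(ROHSegment(
                sample=sample, chrom=chrom,
                start=int(starts[a]), end=int(ends[b]),
                n_windows=n_windows, mean_he=mean_he,
            ))
    segments.sort(key=lambda s: (s.sample, s.chrom, s.start))
    return segments


def callable_bp(wt: pd.DataFrame, sample: str) -> int:
    """Callable genome length for one sample: windows with >=1 called site."""
    grp = wt[wt["sample"] == sample]
    has = (grp["n_hom"] + grp["n_het"]) > 0
    return int((grp["end"][has] - grp["start"][has]).sum())


def froh(rohs: Sequence[ROHSegment], callable_genome_bp: int) -> float:
    """F_ROH: fraction of the callable genome inside ROHs."""
    if callable_genome_bp <= 0:
        raise ValueError("callable genome length must be positive")
    total = sum(s.length for s in rohs)
    f = total / callable_genome_bp
    if f > 1 + 1e-9:
        raise ArctosError("ROH total exceeds callable genome length")
    return min(f, 1.0)


def froh_by_chrom(
    wt: pd.DataFrame, rohs: Sequence[ROHSegment], sample: str
) -> tuple[pd.Series, float]:
    """Per-chromosome F_ROH for one sample, plus their standard deviation.

    Only chromosomes with at least one callable window enter; the sd (ddof=1,
    0 for a single chromosome) is the recent-inbreeding indicator.
    """
    grp = wt[wt["sample"] == sample]
    out = {}
    for chrom, cg in grp.groupby("chrom", sort=False):
        has = (cg["n_hom"] + cg["n_het"]) > 0
        cbp = int((cg["end"][has] - cg["start"][has]).sum())
        if cbp == 0:
            continue
        roh_bp = sum(s.length for s in rohs if s.sample == sample and s.chrom == chrom)
        if roh_bp > cg["end"].max() - cg["start"].min() + 1e-9:
            raise ArctosError(f"ROH coverage exceeds chromosome span on {chrom}")
        out[chrom] = roh_bp / cbp
    series = pd.Series(out, dtype=float)
    sd = float(series.std(ddof=1)) if len(series) > 1 else 0.0
    return series, sd


def he_excluding_roh(wt: pd.DataFrame, rohs: Sequence[ROHSegment]) -> pd.Series:
    """Mean He per sample over windows outside that sample's ROHs.

    Weighted by called sites; a sample without ROHs returns its genome-wide
    He, and excluding low-He regions can only raise the estimate.
    """
    out = {}
    for sample, grp in wt.groupby("sample", sort=False):
        mask = np.ones(len(grp), dtype=bool)
        starts = grp["start"].to_numpy()
        chroms = grp["chrom"].to_numpy()
        for s in rohs:
            if s.sample != sample:
                continue
            mask &= ~((chroms == s.chrom) & (starts >= s.start) & (starts < s.end))
        het = grp["n_het"].to_numpy(dtype=float)[mask].sum()
        called = (grp["n_hom"] + grp["n_het"]).to_numpy(dtype=float)[mask].sum()
        out[sample] = het / called if called > 0 else np.nan
    return pd.Series(out, dtype=float)


def genome_he(wt: pd.DataFrame) -> pd.Series:
    """Genome-wide He per sample (called-site weighted over all windows)."""
    het = wt.groupby("sample", sort=False)["n_het"].sum()
    called = het + wt.groupby("sample", sort=False)["n_hom"].sum()
    return het / called


def roh_length_spectrum(
    rohs: Sequence[ROHSegment], bins: Sequence[float] | int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of ROH lengths: (counts, bin edges)."""
    lengths = np.array([s.length for s in rohs], dtype=float)
    return np.histogram(lengths, bins=bins)


def expected_ibd_he(u: float, t: float) -> float:
    """Coalescent expectation of residual He inside an IBD tract: 2*u*t.

    ``u`` is the per-site per-generation mutation rate and ``t`` the age of
    the common ancestor of the two haplotypes in generations.
    """
    return 2.0 * u * t
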