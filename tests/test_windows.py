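"""Windowed heterozygosity counting, ROH detection and F_ROH summaries."""

import numpy as np
import pandas as pd
import pytest

from arctos.windows import (
    ROHSegment,
    call_roh,
    callable_bp,
    count_windows,
    expected_ibd_he,
    froh,
    froh_by_chrom,
    genome_he,
    he_excluding_roh,
    roh_length_spectrum,
)
from conftest import make_gm

W = 20_000


def window_table(he_values, sample="s", chrom="chr1", n_called=2000):
    """Window table with given per-window He (NaN = no called sites)."""
    rows = []
    for w, he in enumerate(he_values):
        if np.isnan(he):
            rows.append((sample, chrom, w * W, (w + 1) * W, 0, 0, np.nan))
        else:
            n_het = int(round(he * n_called))
            rows.append((sample, chrom, w * W, (w + 1) * W,
                         n_called - n_het, n_het, n_het / n_called))
    return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end",
                                       "n_hom", "n_het", "he"])


class TestCountWindows:
    def test_single_het_of_2000_called(self):
        g = np.zeros((1, 2000), dtype=np.int8)
        g[0, 10] = 1
        gm = make_gm(g, pos=np.arange(1, 2001) * 10)  # all within one window
        wt = count_windows(gm, window_bp=W)
        assert wt.iloc[0]["he"] == pytest.approx(1 / 2000)  # 0.05%

    def test_zero_called_sites_undefined(self):
        g = np.full((1, 5), -1, dtype=np.int8)
        gm = make_gm(g, pos=[1, 2, 3, 4, 5])
        wt = count_windows(gm, window_bp=W)
        assert np.isnan(wt.iloc[0]["he"])

    def test_conservation_of_called_sites(self, rng):
        g = rng.integers(-1, 3, size=(3, 400)).astype(np.int8)
        pos = np.sort(rng.choice(100_000, 400, replace=False)) + 1
        gm = make_gm(g, pos=pos)
        wt = count_windows(gm, window_bp=W)
        total = (wt["n_hom"] + wt["n_het"]).sum()
        assert total == int((g != -1).sum())

    def test_all_sites_called_mode_counts_window_span(self):
        g = np.zeros((1, 3), dtype=np.int8)
        g[0] = [1, 1, 0]
        gm = make_gm(g, pos=[100, 200, 25_000])
        wt = count_windows(gm, window_bp=W, chrom_lengths={"chr1": 30_000},
                           all_sites_called=True)
        assert wt.iloc[0]["n_het"] == 2
        assert wt.iloc[0]["n_hom"] + wt.iloc[0]["n_het"] == W
        assert wt.iloc[1]["n_hom"] + wt.iloc[1]["n_het"] == 10_000

    def test_unsorted_input_rejected(self):
        gm = make_gm(np.zeros((1, 2), np.int8), pos=[100, 50])
        with pytest.raises(Exception):
            count_windows(gm, window_bp=W)


class TestCallRoh:
    def test_ten_zero_windows_make_one_200kb_roh(self):
        wt = window_table([0.01] + [0.0] * 10 + [0.01])
        rohs = call_roh(wt, he_threshold=0.0005, min_windows=10)
        assert len(rohs) == 1
        seg = rohs[0]
        assert seg.end - seg.start == 200_000
        assert seg.n_windows == 10

    def test_nine_windows_below_minimum_gives_none(self):
        wt = window_table([0.01] + [0.0] * 9 + [0.01])
        assert call_roh(wt, he_threshold=0.0005, min_windows=10) == []

    def test_gap_merging_rule(self):
        he = [0.01] + [0.0] * 12 + [0.002] + [0.0] * 12 + [0.01]
        wt = window_table(he)
        merged = call_roh(wt, he_threshold=0.0005, min_windows=10, max_gap_windows=2)
        assert len(merged) == 1
        assert merged[0].end - merged[0].start == 500_000
        split = call_roh(wt, he_threshold=0.0005, min_windows=10, max_gap_windows=0)
        assert len(split) == 2
        assert all(s.end - s.start == 240_000 for s in split)

    def test_merge_refused_when_region_mean_exceeds_threshold(self):
        he = [0.0] * 12 + [0.2] + [0.0] * 12
        wt = window_table(he)
        rohs = call_roh(wt, he_threshold=0.0005, min_windows=10, max_gap_windows=2)
        assert len(rohs) == 2  # spike too hot to absorb

    def test_undefined_windows_count_as_gaps(self):
        he = [0.0] * 12 + [np.nan] + [0.0] * 12
        wt = window_table(he)
        rohs = call_roh(wt, he_threshold=0.0005, min_windows=10, max_gap_windows=2)
        assert len(rohs) == 1

    def test_invariant_to_chromosome_order_and_disjoint(self, rng):
        frames = []
        for chrom in ("chr2", "chr1"):
            he = rng.choice([0.0, 0.001, 0.01], size=40, p=[0.5, 0.2, 0.3])
            frames.append(window_table(he, chrom=chrom))
        wt = pd.concat(frames, ignore_index=True)
        r1 = call_roh(wt)
        r2 = call_roh(wt.iloc[::-1].reset_index(drop=True))
        assert r1 == r2
        for a, b in zip(r1, r1[1:]):
            if (a.sample, a.chrom) == (b.sample, b.chrom):
                assert a.end <= b.start

    def test_raising_threshold_only_grows_coverage(self, rng):
        he = rng.choice([0.0, 0.0004, 0.002, 0.01], size=200)
        wt = window_table(he)
        cov = []
        for thr in (0.0003, 0.0005, 0.003, 0.02):
            rohs = call_roh(wt, he_threshold=thr, min_windows=5)
            cov.append(sum(s.length for s in rohs))
        assert cov == sorted(cov)

    def test_recovers_planted_tracts(self, rng):
        """Planted zero-He tracts >= 300 kb are covered >= 95% by calls."""
        n = 500
        he = rng.uniform(0.002, 0.004, size=n)
        tracts = [(50, 70), (200, 230), (400, 417)]  # windows, >=300kb each
        for a, b in tracts:
            he[a:b] = 0.0
        wt = window_table(he.tolist())
        rohs = call_roh(wt, he_threshold=0.0005, min_windows=10)
        for a, b in tracts:
            covered = 0
            for s in rohs:
                covered += max(0, min(s.end, b * W) - max(s.start, a * W))
            assert covered >= 0.95 * (b - a) * W


class TestFroh:
    def test_trivial_extremes(self):
        assert froh([], 1_000_000) == 0.0
        seg = ROHSegment("s", "chr1", 0, 1_000_000, 50, 0.0)
        assert froh([seg], 1_000_000) == 1.0

    def test_callable_length_counts_windows_with_calls(self):
        wt = pd.concat([window_table([0.001] * 5),
                        window_table([np.nan] * 3, chrom="chr2")],
                       ignore_index=True)
        assert callable_bp(wt, "s") == 5 * W

    def test_concentrated_rohs_have_higher_chrom_sd_than_uniform(self):
        # same genome-wide F_ROH; one sample has all ROH on one chromosome
        frames = []
        for chrom in ("chr1", "chr2", "chr3", "chr4"):
            frames.append(window_table([0.002] * 25, sample="uniform", chrom=chrom))
            frames.append(window_table([0.002] * 25, sample="recent", chrom=chrom))
        wt = pd.concat(frames, ignore_index=True)
        uniform = [ROHSegment("uniform", c, 0, 200_000, 10, 0.0)
                   for c in ("chr1", "chr2", "chr3", "chr4")]
        recent = [ROHSegment("recent", "chr1", 0, 500_000, 25, 0.0),
                  ROHSegment("recent", "chr2", 0, 300_000, 15, 0.0)]
        _, sd_uniform = froh_by_chrom(wt, uniform, "uniform")
        _, sd_recent = froh_by_chrom(wt, recent, "recent")
        assert sum(s.length for s in uniform) == sum(s.length for s in recent)
        assert sd_recent > sd_uniform

    def test_roh_exceeding_chromosome_raises(self):
        wt = window_table([0.0] * 5)
        bad = [ROHSegment("s", "chr1", 0, 10 * W, 10, 0.0)]
        with pytest.raises(Exception):
            froh_by_chrom(wt, bad, "s")


class TestHeExcludingRoh:
    def test_sample_without_roh_equals_genome_he(self):
        wt = window_table([0.001, 0.002, 0.003])
        he_all = genome_he(wt)["s"]
        assert he_excluding_roh(wt, [])["s"] == pytest.approx(he_all)

    def test_half_genome_in_zero_he_rohs(self):
        h = 0.002
        he = [0.0] * 10 + [h] * 10
        wt = window_table(he)
        rohs = call_roh(wt, he_threshold=0.0005, min_windows=10)
        assert len(rohs) == 1
        excl = he_excluding_roh(wt, rohs)["s"]
        assert excl == pytest.approx(h)
        assert genome_he(wt)["s"] == pytest.approx(h / 2)

    def test_never_below_genome_wide_he(self, rng):
        he = rng.choice([0.0, 0.0002, 0.002, 0.005], size=100)
        wt = window_table(he.tolist())
        rohs = call_roh(wt, min_windows=5)
        assert he_excluding_roh(wt, rohs)["s"] >= genome_he(wt)["s"] - 1e-12


class TestSpectrumAndIbd:
    def test_expected_ibd_he_values(self):
        assert expected_ibd_he(1.2e-8, 0) == 0.0
        assert expected_ibd_he(1.2e-8, 1000) == pytest.approx(2.4e-5)

    def test_length_spectrum_counts(self):
        rohs = [ROHSegment("s", "chr1", 0, 200_000, 10, 0.0),
                ROHSegment("s", "chr1", 300_000, 800_000, 25, 0.0)]
        counts, edges = roh_length_spectrum(rohs, bins=[0, 250_000, 1_000_000])
        assert counts.tolist() == [1, 1]
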