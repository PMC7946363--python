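"""Sliding windows, FDR calibration, peak calling and recombination masking."""

import numpy as np
import pytest

from hapsweep.hapstats import HaplotypeMatrix, WindowStats
from hapsweep.scan import (
    NullDistribution,
    Peak,
    RecombinationMap,
    ScanConfig,
    apply_recomb_mask,
    call_peaks,
    fdr_cutoff,
    scan_genome,
    sliding_windows,
)
from hapsweep.simulate import make_fixture_genome


def uniform_matrix(n, l_sites, seed=0):
    rng = np.random.default_rng(seed)
    return HaplotypeMatrix(
        alleles=rng.integers(0, 2, size=(n, l_sites)).astype(np.int8),
        positions=np.arange(1, l_sites + 1, dtype=np.int64) * 10,
    )


def stats_with_h12(values, chrom="1"):
    return [
        WindowStats(h1=v, h2=0.0, h12=v, h2h1=0.0, n_distinct=1, chrom=chrom,
                    snp_start=i, snp_stop=i + 1, bp_start=100 * i + 1,
                    bp_stop=100 * i + 50)
        for i, v in enumerate(values)
    ]


class TestSlidingWindows:
    def test_window_start_grid(self):
        m = uniform_matrix(4, 1000)
        cfg = ScanConfig(window_snps=401, step_snps=50)
        wins = sliding_windows(m, cfg)
        assert [w.snp_start for w in wins] == list(range(0, 600, 50))
        assert len(wins) == 12
        assert all(w.snp_stop - w.snp_start == 401 for w in wins)

    def test_exactly_one_window(self):
        wins = sliding_windows(uniform_matrix(4, 401), ScanConfig())
        assert len(wins) == 1

    def test_too_few_snps_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            wins = sliding_windows(uniform_matrix(4, 400), ScanConfig())
        assert wins == []

    def test_bp_range_is_first_to_last_snp(self):
        m = uniform_matrix(4, 500)
        w = sliding_windows(m, ScanConfig(window_snps=401, step_snps=50))[0]
        assert (w.bp_start, w.bp_stop) == (10, 4010)


class TestFdrCutoff:
    def test_tenth_highest_in_10x_design(self):
        vals = np.arange(1, 1001) / 1000.0  # {0.001 ... 1.000}
        null = NullDistribution(values=vals, n_data_windows=100)
        assert fdr_cutoff(null) == pytest.approx(0.991)

    def test_equal_counts_give_the_maximum(self):
        with pytest.warns(UserWarning):  # < 10x design
            null = NullDistribution(values=[0.2, 0.5, 0.3], n_data_windows=3)
        assert fdr_cutoff(null) == 0.5

    def test_k_below_one_is_an_error(self):
        with pytest.warns(UserWarning):
            null = NullDistribution(values=[0.5], n_data_windows=3)
        with pytest.raises(ValueError):
            fdr_cutoff(null)


class TestCallPeaks:
    def test_hand_enumerated_runs(self):
        stats = stats_with_h12([0.05, 0.12, 0.15, 0.08, 0.20, 0.22, 0.09])
        peaks = call_peaks(stats, cutoff=0.10)
        assert len(peaks) == 2
        by_windows = sorted(peaks, key=lambda p: p.window_indices)
        assert by_windows[0].window_indices == (1, 2)
        assert by_windows[0].max_h12 == pytest.approx(0.15)
        assert by_windows[1].window_indices == (4, 5)
        assert by_windows[1].max_h12 == pytest.approx(0.22)
        # sorted by max H12 descending for top-N reporting
        assert peaks[0].max_h12 >= peaks[1].max_h12

    def test_no_peaks_below_cutoff(self):
        assert call_peaks(stats_with_h12([0.01, 0.02]), 0.10) == []

    def test_single_peak_spanning_everything(self):
        peaks = call_peaks(stats_with_h12([0.2, 0.3, 0.25]), 0.1)
        assert len(peaks) == 1
        assert peaks[0].window_indices == (0, 1, 2)

    def test_runs_do_not_cross_chromosomes(self):
        stats = stats_with_h12([0.2, 0.2], chrom="2L")
        stats += stats_with_h12([0.2], chrom="2R")
        peaks = call_peaks(stats, 0.1)
        assert len(peaks) == 2

    def test_raising_cutoff_shrinks_above_cutoff_windows_and_nests_peaks(self):
        """Higher cutoffs cover fewer windows, and every peak called at a
        higher cutoff lies within a peak called at any lower cutoff (a run
        can split in two, but never grow)."""
        rng = np.random.default_rng(5)
        stats = stats_with_h12(rng.random(200) * 0.4)
        cutoffs = np.linspace(0.0, 0.4, 9)
        covered = [
            set().union(*[p.window_indices for p in call_peaks(stats, c)] or [set()])
            for c in cutoffs
        ]
        for lo, hi in zip(covered, covered[1:]):
            assert hi <= lo
        low_peaks = call_peaks(stats, cutoffs[2])
        for p in call_peaks(stats, cutoffs[5]):
            assert any(
                set(p.window_indices) <= set(q.window_indices) for q in low_peaks
            )


class TestRecombMask:
    CFG = ScanConfig(min_rho=5e-7)

    def make_peak(self, midpoint=500):
        return Peak(
            window_indices=(0,), chrom="1", bp_start=1, bp_stop=1000,
            max_h12=0.5, h2h1_at_max=0.1, rep_index=0,
            rep_bp_start=midpoint - 100, rep_bp_stop=midpoint + 100,
        )

    def test_low_recombination_peak_is_masked(self):
        rmap = RecombinationMap([("1", 1, 1000, 4e-7)])
        kept, masked = apply_recomb_mask([self.make_peak()], rmap, self.CFG)
        assert kept == [] and len(masked) == 1

    def test_threshold_is_strict_lower_than(self):
        rmap = RecombinationMap([("1", 1, 1000, 5e-7)])
        kept, masked = apply_recomb_mask([self.make_peak()], rmap, self.CFG)
        assert len(kept) == 1 and masked == []

    def test_uncovered_position_with_default_rate_keeps_peak(self):
        rmap = RecombinationMap([], default_rate=5e-7)
        kept, masked = apply_recomb_mask([self.make_peak()], rmap, self.CFG)
        assert len(kept) == 1

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError):
            RecombinationMap([("1", 1, 100, 1e-7), ("1", 50, 200, 1e-7)])


class TestScanGenome:
    def null(self, values=None, n_data=10):
        values = values if values is not None else np.linspace(0.01, 0.2, 100)
        return NullDistribution(values=values, n_data_windows=n_data)

    def test_planted_sweep_yields_one_overlapping_peak(self):
        m = make_fixture_genome(
            n=50, n_windows=8, window_snps=101, sweep_window=3,
            kind="hard", f=0.9, seed=1,
        )
        cfg = ScanConfig(window_snps=101, step_snps=101)
        report = scan_genome({m.chrom: m}, None, None, cfg, cutoff=0.2)
        assert len(report.peaks) == 1
        peak = report.peaks[0]
        sweep_lo, sweep_hi = 3 * 101 * 25, 4 * 101 * 25
        assert peak.bp_start < sweep_hi and peak.bp_stop > sweep_lo

    def test_empty_input_gives_empty_report(self):
        report = scan_genome({}, self.null(), None, ScanConfig())
        assert len(report.windows) == 0 and report.peaks == []

    def test_scan_is_deterministic(self):
        m = make_fixture_genome(n=30, n_windows=5, window_snps=101,
                                sweep_window=2, kind="soft", seed=3)
        cfg = ScanConfig(window_snps=101, step_snps=50)
        r1 = scan_genome({m.chrom: m}, None, None, cfg, cutoff=0.15)
        r2 = scan_genome({m.chrom: m}, None, None, cfg, cutoff=0.15)
        assert r1.windows.equals(r2.windows)
        assert r1.peaks == r2.peaks
        assert r1.to_json() == r2.to_json()

    def test_sample_mismatch_across_chromosomes_rejected(self):
        m1 = uniform_matrix(4, 101, seed=1)
        m2 = HaplotypeMatrix(
            alleles=m1.alleles, positions=m1.positions, chrom="2",
            sample_ids=("a", "b", "c", "d"),
        )
        with pytest.raises(ValueError, match="sample"):
            scan_genome({"1": m1, "2": m2}, None, None,
                        ScanConfig(window_snps=101), cutoff=0.5)

    def test_every_reported_peak_exceeds_cutoff(self):
        m = make_fixture_genome(n=40, n_windows=10, window_snps=101,
                                sweep_window=5, kind="hard", f=0.95, seed=9)
        cfg = ScanConfig(window_snps=101, step_snps=101)
        report = scan_genome({m.chrom: m}, None, None, cfg, cutoff=0.3)
        assert all(p.max_h12 > 0.3 for p in report.peaks)


def test_planted_sweep_recovery_rate():
    """Top-1 peak contains the planted locus in >= 95% of seeded fixtures."""
    hits = 0
    n_trials = 100
    cfg = ScanConfig(window_snps=101, step_snps=101)
    for seed in range(n_trials):
        sweep_window = seed % 8
        m = make_fixture_genome(
            n=50, n_windows=8, window_snps=101, sweep_window=sweep_window,
            kind="hard", f=0.8, seed=seed,
        )
        report = scan_genome({m.chrom: m}, None, None, cfg, cutoff=0.2)
        if not report.peaks:
            continue
        top = report.peaks[0]
        lo, hi = sweep_window * 101 * 25, (sweep_window + 1) * 101 * 25
        if top.bp_start < hi and top.bp_stop > lo:
            hits += 1
    assert hits >= 95
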