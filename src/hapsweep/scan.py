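"""Genome scan: sliding SNP windows, null-calibrated cutoff, peak calling.

The scan slides windows of a fixed SNP count (401 by default, ~10 kb in
Drosophila) along each chromosome and computes H12 and companions per
window. A 1-per-genome false-discovery cutoff is calibrated by simulating
at least 10x as many neutral windows as the data contain and taking the
k-th highest simulated H12, k = round(n_sim / n_data) (the "tenth highest"
in the 10x design). Runs of consecutive above-cutoff windows are grouped
into peaks, each represented by its maximum-H12 window; regions of low
recombination are excluded only *after* peak calling, because low
recombination inflates haplotype homozygosity without selection.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hapstats import HaplotypeMatrix, WindowStats, window_stats

__all__ = [
    "ScanConfig",
    "NullDistribution",
    "Peak",
    "RecombinationMap",
    "ScanReport",
    "sliding_windows",
    "fdr_cutoff",
    "call_peaks",
    "apply_recomb_mask",
    "scan_genome",
]


@dataclass(frozen=True)
class ScanConfig:
    """Scan parameters.

    window_snps: SNPs per window (default 401). step_snps: SNP offset
    between window starts. min_rho: recombination threshold in cM/bp;
    peaks whose representative window sits in an interval with rate
    strictly below it are masked. top_n: outliers reported.
    """

    window_snps: int = 401
    step_snps: int = 50
    min_rho: float = 5e-7
    top_n: int = 50
    mask_mode: str = "midpoint"  # or "overlap"

    def __post_init__(self):
        if self.window_snps < 2:
            raise ValueError("window_snps must be >= 2")
        if not (1 <= self.step_snps <= self.window_snps):
            raise ValueError("step_snps must be in [1, window_snps]")
        if self.min_rho < 0:
            raise ValueError("min_rho must be >= 0")
        if self.mask_mode not in ("midpoint", "overlap"):
            raise ValueError("mask_mode must be 'midpoint' or 'overlap'")


@dataclass(frozen=True)
class NullDistribution:
    """H12 values from neutral simulations, sorted descending."""

    values: np.ndarray
    n_data_windows: int

    def __post_init__(self):
        vals = np.sort(np.asarray(self.values, dtype=float))[::-1]
        if vals.size < 1:
            raise ValueError("null distribution needs at least one value")
        if self.n_data_windows < 1:
            raise ValueError("n_data_windows must be >= 1")
        if vals.size < 10 * self.n_data_windows:
            warnings.warn(
                f"null has {vals.size} values for {self.n_data_windows} data "
                "windows; < 10x calibration design",
                stacklevel=2,
            )
        object.__setattr__(self, "values", vals)

    @property
    def n_sim_windows(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class Peak:
    """A maximal run of consecutive windows exceeding the cutoff."""

    window_indices: tuple[int, ...]
    chrom: str
    bp_start: int
    bp_stop: int
    max_h12: float
    h2h1_at_max: float
    rep_index: int  # index (into the window table) of the max-H12 window
    rep_bp_start: int = 0
    rep_bp_stop: int = 0


class RecombinationMap:
    """Non-overlapping (chrom, start, end, rate cM/bp) intervals, 1-based inclusive."""

    def __init__(self, intervals, default_rate: float | None = None):
        rows = []
        for chrom, start, end, rate in intervals:
            if rate < 0:
                raise ValueError("recombination rates must be >= 0")
            if end < start:
                raise ValueError("interval end before start")
            rows.append((str(chrom), int(start), int(end), float(rate)))
        rows.sort(key=lambda r: (r[0], r[1]))
        for a, b in zip(rows, rows[1:]):
            if a[0] == b[0] and b[1] <= a[2]:
                raise ValueError(f"overlapping intervals on {a[0]}: {a} / {b}")
        self.intervals = rows
        self.default_rate = default_rate

    @classmethod
    def from_tsv(cls, path, default_rate: float | None = None) -> "RecombinationMap":
        df = pd.read_csv(
            path, sep="\t", comment="#",
            names=["chrom", "start", "end", "rate_cM_per_bp"], dtype={"chrom": str},
        )
        return cls(df.itertuples(index=False, name=None), default_rate=default_rate)

    def rate_at(self, chrom: str, pos: int) -> float:
        for c, start, end, rate in self.intervals:
            if c == str(chrom) and start <= pos <= end:
                return rate
        if self.default_rate is not None:
            return self.default_rate
        warnings.warn(
            f"no recombination interval covers {chrom}:{pos}; treating as high-rate",
            stacklevel=2,
        )
        return float("inf")

    def min_rate_in(self, chrom: str, start: int, stop: int) -> float:
        rates = [
            r for c, s, e, r in self.intervals
            if c == str(chrom) and s <= stop and e >= start
        ]
        if not rates:
            return self.rate_at(chrom, (start + stop) // 2)
        return min(rates)


@dataclass
class ScanReport:
    """Per-window table, called peaks, and the calibration used."""

    windows: pd.DataFrame
    peaks: list[Peak]
    masked_peaks: list[Peak]
    cutoff: float
    config: ScanConfig

    @property
    def top_peaks(self) -> list[Peak]:
        return self.peaks[: self.config.top_n]

    def windows_tsv(self, path) -> None:
        self.windows.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def peaks_bed(self, path) -> None:
        """Peaks as BED (0-based half-open), score = max H12."""
        with open(path, "w") as fh:
            for i, p in enumerate(self.peaks):
                fh.write(
                    f"{p.chrom}\t{p.bp_start - 1}\t{p.bp_stop}\tpeak{i + 1}\t"
                    f"{p.max_h12:.6g}\n"
                )

    def to_json(self, path=None) -> str:
        payload = {
            "cutoff": self.cutoff,
            "config": {
                "window_snps": self.config.window_snps,
                "step_snps": self.config.step_snps,
                "min_rho": self.config.min_rho,
                "top_n": self.config.top_n,
            },
            "n_windows": int(len(self.windows)),
            "n_peaks": len(self.peaks),
            "n_masked_peaks": len(self.masked_peaks),
            "top_peaks": [
                {
                    "chrom": p.chrom,
                    "bp_start": p.bp_start,
                    "bp_stop": p.bp_stop,
                    "max_h12": p.max_h12,
                    "h2h1_at_max": p.h2h1_at_max,
                    "n_windows": len(p.window_indices),
                }
                for p in self.top_peaks
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def sliding_windows(matrix: HaplotypeMatrix, cfg: ScanConfig) -> list[WindowStats]:
    """All full windows at SNP starts 0, step, 2*step, ...; partials dropped."""
    if matrix.n_sites < cfg.window_snps:
        warnings.warn(
            f"{matrix.n_sites} SNPs < window of {cfg.window_snps}; no windows",
            stacklevel=2,
        )
        return []
    out = []
    for start in range(0, matrix.n_sites - cfg.window_snps + 1, cfg.step_snps):
        out.append(window_stats(matrix, (start, start + cfg.window_snps)))
    return out


def fdr_cutoff(null: NullDistribution) -> float:
    """The k-th highest simulated H12, k = round(n_sim / n_data).

    With the recommended 10x simulation design k = 10, giving ~1 expected
    false peak per genome.
    """
    k = int(round(null.n_sim_windows / null.n_data_windows))
    if k < 1:
        raise ValueError(
            f"too few simulations ({null.n_sim_windows}) for "
            f"{null.n_data_windows} data windows (k < 1)"
        )
    return float(null.values[k - 1])


def call_peaks(stats: list[WindowStats], cutoff: float) -> list[Peak]:
    """Group maximal runs of consecutive above-cutoff windows into peaks.

    Adjacency is on the window-index grid within a chromosome. Peaks are
    returned sorted by max H12 descending.
    """
    peaks: list[Peak] = []
    run: list[int] = []

    def flush(run_idx: list[int]) -> None:
        if not run_idx:
            return
        rep = max(run_idx, key=lambda i: (stats[i].h12, -i))
        peaks.append(
            Peak(
                window_indices=tuple(run_idx),
                chrom=stats[rep].chrom,
                bp_start=min(stats[i].bp_start for i in run_idx),
                bp_stop=max(stats[i].bp_stop for i in run_idx),
                max_h12=stats[rep].h12,
                h2h1_at_max=stats[rep].h2h1,
                rep_index=rep,
                rep_bp_start=stats[rep].bp_start,
                rep_bp_stop=stats[rep].bp_stop,
            )
        )

    for i, w in enumerate(stats):
        new_chrom = run and stats[run[-1]].chrom != w.chrom
        if w.h12 > cutoff and not new_chrom:
            run.append(i)
        else:
            flush(run)
            run = [i] if w.h12 > cutoff else []
    flush(run)
    peaks.sort(key=lambda p: -p.max_h12)
    return peaks


def apply_recomb_mask(
    peaks: list[Peak], rmap: RecombinationMap, cfg: ScanConfig
) -> tuple[list[Peak], list[Peak]]:
    """Partition peaks into (kept, masked) by recombination rate.

    Default mode masks a peak when the rate at its representative window's
    bp midpoint is strictly below ``cfg.min_rho``; "overlap" mode masks on
    any overlap of the representative window with a below-threshold
    interval. Masking is applied after peak formation, never before.
    """
    kept, masked = [], []
    for p in peaks:
        if cfg.mask_mode == "midpoint":
            rate = rmap.rate_at(p.chrom, (p.rep_bp_start + p.rep_bp_stop) // 2)
        else:
            rate = rmap.min_rate_in(p.chrom, p.rep_bp_start, p.rep_bp_stop)
        (masked if rate < cfg.min_rho else kept).append(p)
    return kept, masked


def _windows_frame(stats: list[WindowStats]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in stats],
            "bp_start": [w.bp_start for w in stats],
            "bp_stop": [w.bp_stop for w in stats],
            "snp_start": [w.snp_start for w in stats],
            "h1": [w.h1 for w in stats],
            "h2": [w.h2 for w in stats],
            "h12": [w.h12 for w in stats],
            "h2h1": [w.h2h1 for w in stats],
            "n_distinct": [w.n_distinct for w in stats],
        }
    )


def scan_genome(
    matrices: dict[str, HaplotypeMatrix],
    null: NullDistribution | None,
    rmap: RecombinationMap | None,
    cfg: ScanConfig,
    *,
    cutoff: float | None = None,
) -> ScanReport:
    """Scan per-chromosome matrices, call and mask peaks, build the report.

    Either a calibrated ``null`` or an explicit ``cutoff`` must be given.
    """
    samples = {m.sample_ids for m in matrices.values()}
    if len(samples) > 1:
        raise ValueError("sample sets differ across chromosomes")
    stats: list[WindowStats] = []
    for chrom in sorted(matrices):
        stats.extend(sliding_windows(matrices[chrom], cfg))
    if cutoff is None:
        if null is None:
            raise ValueError("need a null distribution or an explicit cutoff")
        cutoff = fdr_cutoff(null)
    peaks = call_peaks(stats, cutoff)
    if rmap is not None:
        peaks, masked = apply_recomb_mask(peaks, rmap, cfg)
    else:
        masked = []
    return ScanReport(
        windows=_windows_frame(stats),
        peaks=peaks,
        masked_peaks=masked,
        cutoff=cutoff,
        config=cfg,
    )
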