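"""Haplotype frequency spectra and homozygosity statistics.

The statistics operate on a window of phased haplotypes. With p_i the
frequency of the i-th most common haplotype in the window,

    H1    = sum_i p_i**2                      (haplotype homozygosity)
    H12   = (p1 + p2)**2 + sum_{i>=3} p_i**2  (top-two classes pooled)
    H2    = sum_{i>=2} p_i**2                 (most common class excluded)
    H2/H1                                      (sweep-softness ratio)

H12 detects both hard and soft sweeps; H2/H1, applied where H12 is already
high, separates them: a hard sweep leaves one dominant haplotype (low
H2/H1) while a soft sweep leaves several common ones (high H2/H1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Allele code marking a missing call.
MISSING = -1

__all__ = [
    "MISSING",
    "HaplotypeMatrix",
    "HaplotypeSpectrum",
    "WindowStats",
    "spectrum_from_window",
    "h1",
    "h2",
    "h12",
    "h2h1",
    "window_stats",
]


@dataclass(frozen=True)
class HaplotypeMatrix:
    """Phased haplotypes: an ``n_haplotypes x n_sites`` allele matrix.

    Allele codes are 0 (ancestral/reference), 1 (derived/alternate) and
    :data:`MISSING`. ``positions`` are physical bp coordinates, strictly
    increasing, one per site.
    """

    alleles: np.ndarray
    positions: np.ndarray
    chrom: str = "1"
    sample_ids: tuple[str, ...] = ()

    def __post_init__(self):
        alleles = np.asarray(self.alleles, dtype=np.int8)
        positions = np.asarray(self.positions, dtype=np.int64)
        if alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        if alleles.shape[0] < 2:
            raise ValueError("need at least 2 haplotypes")
        if positions.ndim != 1 or positions.size != alleles.shape[1]:
            raise ValueError(
                f"positions ({positions.size}) must match allele columns "
                f"({alleles.shape[1]})"
            )
        if positions.size and np.any(np.diff(positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        valid = (alleles == 0) | (alleles == 1) | (alleles == MISSING)
        if not valid.all():
            bad = np.unique(alleles[~valid])
            raise ValueError(f"invalid allele codes {bad.tolist()}; expected 0/1/{MISSING}")
        ids = tuple(self.sample_ids) or tuple(f"hap{i}" for i in range(alleles.shape[0]))
        if len(ids) != alleles.shape[0]:
            raise ValueError("sample_ids length must match haplotype count")
        object.__setattr__(self, "alleles", alleles)
        object.__setattr__(self, "positions", positions)
        object.__setattr__(self, "sample_ids", ids)

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]


@dataclass(frozen=True)
class HaplotypeSpectrum:
    """Descending haplotype frequencies within one window.

    ``frequencies[i] == counts[i] / n`` exactly; counts sum to ``n``.
    """

    frequencies: tuple[float, ...]
    counts: tuple[int, ...]
    n: int

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be positive")
        if len(self.frequencies) != len(self.counts):
            raise ValueError("frequencies and counts length mismatch")
        if sum(self.counts) != self.n:
            raise ValueError("counts must sum to n")
        if any(c < 1 for c in self.counts):
            raise ValueError("counts must be positive")
        if list(self.counts) != sorted(self.counts, reverse=True):
            raise ValueError("spectrum must be sorted descending")
        for f, c in zip(self.frequencies, self.counts):
            if abs(f - c / self.n) > 1e-12:
                raise ValueError("frequencies must equal counts / n")

    @property
    def p1(self) -> float:
        return self.frequencies[0]

    @property
    def p2(self) -> float:
        """Frequency of the second most common haplotype; 0 if monomorphic."""
        return self.frequencies[1] if len(self.frequencies) > 1 else 0.0


@dataclass(frozen=True)
class WindowStats:
    """Homozygosity statistics for one analysis window."""

    h1: float
    h2: float
    h12: float
    h2h1: float
    n_distinct: int
    chrom: str = "1"
    snp_start: int = 0
    snp_stop: int = 0  # exclusive
    bp_start: int = 0
    bp_stop: int = 0  # inclusive (position of last SNP)
    extra: dict = field(default_factory=dict, compare=False)


def spectrum_from_window(
    matrix: HaplotypeMatrix,
    site_range: tuple[int, int] | None = None,
    *,
    match_on_observed: bool = False,
) -> HaplotypeSpectrum:
    """Group identical haplotype strings over ``site_range`` into a spectrum.

    ``site_range`` is a half-open ``(start, stop)`` column interval; ``None``
    uses every site. Ties in frequency are broken by the lexicographic order
    of the haplotype string so the spectrum is deterministic.

    Missing-data policy: by default a missing call is a distinct allele
    state, so two haplotypes agree only if their missing patterns agree.
    With ``match_on_observed=True`` a haplotype joins a fully observed class
    when it matches that class at every non-missing site and exactly one
    such class exists; ambiguous or unmatched haplotypes stay singletons.
    """
    start, stop = (0, matrix.n_sites) if site_range is None else site_range
    if not (0 <= start < stop <= matrix.n_sites):
        raise ValueError(f"site range [{start}, {stop}) out of bounds or empty")
    block = matrix.alleles[:, start:stop]

    all_missing = np.all(block == MISSING, axis=1)
    if np.any(all_missing):
        who = matrix.sample_ids[int(np.flatnonzero(all_missing)[0])]
        raise ValueError(f"haplotype {who!r} has no observed calls in the window")

    keys = ["".join("x" if a == MISSING else str(a) for a in row) for row in block]

    if match_on_observed and any("x" in k for k in keys):
        complete: dict[str, None] = {k: None for k in keys if "x" not in k}
        resolved = []
        for k in keys:
            if "x" not in k:
                resolved.append(k)
                continue
            matches = [
                c
                for c in complete
                if all(a == "x" or a == b for a, b in zip(k, c))
            ]
            resolved.append(matches[0] if len(matches) == 1 else k)
        keys = resolved

    counter: dict[str, int] = {}
    for k in keys:
        counter[k] = counter.get(k, 0) + 1
    n = matrix.n_haplotypes
    ordered = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    counts = tuple(c for _, c in ordered)
    freqs = tuple(c / n for c in counts)
    return HaplotypeSpectrum(frequencies=freqs, counts=counts, n=n)


def h1(spec: HaplotypeSpectrum) -> float:
    """H1 = sum_i p_i**2."""
    return float(sum(p * p for p in spec.frequencies))


def h2(spec: HaplotypeSpectrum) -> float:
    """H2 = sum_{i>=2} p_i**2 (homozygosity excluding the top class)."""
    return float(sum(p * p for p in spec.frequencies[1:]))


def h12(spec: HaplotypeSpectrum) -> float:
    """H12 = (p1 + p2)**2 + sum_{i>=3} p_i**2."""
    top = spec.p1 + spec.p2
    return float(top * top + sum(p * p for p in spec.frequencies[2:]))


def h2h1(spec: HaplotypeSpectrum) -> float:
    """H2/H1; 0 for a monomorphic window, -> (k-1)/k for k equal classes."""
    return h2(spec) / h1(spec)


def window_stats(
    matrix: HaplotypeMatrix,
    site_range: tuple[int, int] | None = None,
    **spectrum_kwargs,
) -> WindowStats:
    """Compute all four statistics for one window of ``matrix``."""
    start, stop = (0, matrix.n_sites) if site_range is None else site_range
    spec = spectrum_from_window(matrix, (start, stop), **spectrum_kwargs)
    return WindowStats(
        h1=h1(spec),
        h2=h2(spec),
        h12=h12(spec),
        h2h1=h2h1(spec),
        n_distinct=len(spec.counts),
        chrom=matrix.chrom,
        snp_start=start,
        snp_stop=stop,
        bp_start=int(matrix.positions[start]),
        bp_stop=int(matrix.positions[stop - 1]),
    )


def sweep_footprint_bp(s: float, ne: float, rho_per_bp: float) -> float:
    """Expected bp extent of a hard-sweep footprint, s / [ln(Ne*s) * rho].

    ``rho_per_bp`` is the per-generation crossover probability per bp
    (cM/bp times 1e-2). Requires Ne*s > 1 so the log is positive.
    """
    if s <= 0 or ne <= 0 or rho_per_bp <= 0:
        raise ValueError("s, Ne and rho must be positive")
    nes = ne * s
    if nes <= 1:
        raise ValueError("Ne*s must exceed 1 for the footprint formula")
    return s / (np.log(nes) * rho_per_bp)
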