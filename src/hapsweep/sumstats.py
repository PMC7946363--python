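"""Genome-wide diversity and LD diagnostics for judging model fit.

Pi/bp (pairwise nucleotide diversity), S/bp (segregating-site density,
optionally with hypergeometric projection to a smaller sample size, the
standard device for handling missing data), pairwise r-squared and
distance-binned LD decay curves, and QQ/RMSE comparison of observed
versus simulated statistic distributions.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .hapstats import MISSING, HaplotypeMatrix
from .seeds import derive_rng

logger = logging.getLogger(__name__)

__all__ = [
    "FragmentSet",
    "LDCurve",
    "FitDiagnostics",
    "pi_per_bp",
    "s_per_bp",
    "site_projection_weight",
    "r2",
    "r2_pairs",
    "ld_decay",
    "qq_rmse",
]


@dataclass(frozen=True)
class FragmentSet:
    """Short putatively neutral fragments (emulating short introns) with
    their lengths in bp. Fragments shorter than 10 bp are rejected, the
    data-side filter for short-intron analyses."""

    fragments: tuple[tuple[HaplotypeMatrix, int], ...]

    def __post_init__(self):
        for _, length in self.fragments:
            if length < 10:
                raise ValueError("fragment lengths must be >= 10 bp")

    def pi_values(self) -> np.ndarray:
        return np.array([pi_per_bp(m, L) for m, L in self.fragments])

    def s_values(self, project_to: int | None = None) -> np.ndarray:
        return np.array(
            [s_per_bp(m, L, project_to=project_to) for m, L in self.fragments]
        )


def pi_per_bp(fragment: HaplotypeMatrix, length_bp: int) -> float:
    """Mean pairwise diversity per bp: sum over sites of
    2 p (1-p) n/(n-1), with p the derived-allele frequency among
    non-missing calls at the site."""
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    alleles = fragment.alleles
    obs = alleles != MISSING
    n_eff = obs.sum(axis=0)
    derived = (alleles == 1).sum(axis=0)
    total = 0.0
    for d, m in zip(derived, n_eff):
        if m >= 2:
            p = d / m
            total += 2.0 * p * (1.0 - p) * m / (m - 1)
    return total / length_bp


def site_projection_weight(n_derived: int, n_ancestral: int, m: int) -> float:
    """P(site polymorphic | hypergeometric draw of m from its calls)."""
    n = n_derived + n_ancestral
    if m > n:
        raise ValueError("cannot project to more calls than observed")
    mono = math.comb(n_ancestral, m) + math.comb(n_derived, m)
    return 1.0 - mono / math.comb(n, m)


def s_per_bp(
    fragment: HaplotypeMatrix, length_bp: int, project_to: int | None = None
) -> float:
    """Segregating sites per bp, optionally projected down to ``project_to``
    chromosomes: each site contributes its probability of remaining
    polymorphic in a hypergeometric subsample of that size. Sites with
    fewer non-missing calls than the projection size are dropped (logged)."""
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    alleles = fragment.alleles
    obs = alleles != MISSING
    n_eff = obs.sum(axis=0)
    derived = (alleles == 1).sum(axis=0)
    if project_to is None:
        s = int(np.sum((derived > 0) & (derived < n_eff)))
        return s / length_bp
    if project_to > fragment.n_haplotypes:
        raise ValueError("project_to exceeds the sample size")
    total = 0.0
    dropped = 0
    for d, m in zip(derived, n_eff):
        if m < project_to:
            dropped += 1
            continue
        if 0 < d < m:
            total += site_projection_weight(int(d), int(m - d), project_to)
    if dropped:
        logger.info("s_per_bp: dropped %d sites with < %d calls", dropped, project_to)
    return total / length_bp


def r2(col_a: np.ndarray, col_b: np.ndarray) -> float:
    """r^2 between two biallelic sites on complete haplotypes:
    (p_AB - p_A p_B)^2 / [p_A (1-p_A) p_B (1-p_B)]."""
    keep = (col_a != MISSING) & (col_b != MISSING)
    a = col_a[keep].astype(float)
    b = col_b[keep].astype(float)
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return float("nan")
    pab = float((a * b).mean())
    d = pab - pa * pb
    return d * d / (pa * (1 - pa) * pb * (1 - pb))


def _eligible_sites(matrix: HaplotypeMatrix, min_mac: int, max_missing: float):
    alleles = matrix.alleles
    n = matrix.n_haplotypes
    obs = alleles != MISSING
    miss_frac = 1 - obs.mean(axis=0)
    derived = (alleles == 1).sum(axis=0)
    mac = np.minimum(derived, obs.sum(axis=0) - derived)
    return np.flatnonzero((mac >= min_mac) & (miss_frac <= max_missing))


def r2_pairs(
    matrix: HaplotypeMatrix,
    n_pairs: int,
    distance_range: tuple[float, float] | None = None,
    seed: int = 0,
    *,
    min_mac: int = 2,
    max_missing: float = 0.2,
) -> np.ndarray:
    """Sample SNP pairs uniformly (within ``distance_range`` bp when given)
    and return their r^2 values. Singleton sites are excluded by default
    (``min_mac=2``): r^2 involving a singleton is degenerate."""
    idx = _eligible_sites(matrix, min_mac, max_missing)
    if idx.size < 2:
        warnings.warn("fewer than two eligible SNPs; no r2 pairs", stacklevel=2)
        return np.empty(0)
    rng = derive_rng(seed, "r2", matrix.chrom)
    pos = matrix.positions
    vals = []
    attempts = 0
    cap = 50 * max(n_pairs, 1)
    while len(vals) < n_pairs and attempts < cap:
        attempts += 1
        i, j = rng.choice(idx.size, size=2, replace=False)
        a, b = idx[i], idx[j]
        dist = abs(int(pos[a]) - int(pos[b]))
        if distance_range is not None and not (
            distance_range[0] <= dist <= distance_range[1]
        ):
            continue
        v = r2(matrix.alleles[:, a], matrix.alleles[:, b])
        if not math.isnan(v):
            vals.append(v)
    if not vals:
        warnings.warn("no eligible pairs in the distance range", stacklevel=2)
    return np.array(vals)


@dataclass(frozen=True)
class LDCurve:
    """Mean r^2 per distance bin; an empty bin has count 0 and NaN mean."""

    bin_edges: np.ndarray  # length n_bins + 1, contiguous
    mean_r2: np.ndarray
    pair_counts: np.ndarray

    def short_range_mean(self, limit: float = 1_000.0) -> float:
        """Pair-weighted mean r^2 over bins entirely within ``limit`` bp."""
        sel = self.bin_edges[1:] <= limit
        return self._weighted(sel)

    def long_range_mean(self, lo: float = 8_000.0, hi: float = 12_000.0) -> float:
        sel = (self.bin_edges[:-1] >= lo) & (self.bin_edges[1:] <= hi)
        return self._weighted(sel)

    def _weighted(self, sel: np.ndarray) -> float:
        counts = self.pair_counts[sel]
        if counts.sum() == 0:
            return float("nan")
        means = np.nan_to_num(self.mean_r2[sel])
        return float((means * counts).sum() / counts.sum())


def default_ld_bins(n_bins: int = 25) -> np.ndarray:
    """Geometric bins from 10 bp to 20 kb."""
    return np.geomspace(10, 2e4, n_bins + 1)


def ld_decay(
    matrices,
    bins: np.ndarray | None = None,
    n_pairs: int = 100_000,
    seed: int = 0,
    **pair_kwargs,
) -> LDCurve:
    """Distance-binned mean r^2 over one matrix or a replicate stream.

    Pairs are sampled uniformly per matrix (n_pairs split across
    matrices); each pair lands in the bin containing its bp distance.
    """
    if isinstance(matrices, HaplotypeMatrix):
        matrices = [matrices]
    else:
        matrices = list(matrices)
    edges = np.asarray(bins if bins is not None else default_ld_bins(), dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bins must be increasing edge positions")
    nb = edges.size - 1
    sums = np.zeros(nb)
    counts = np.zeros(nb, dtype=np.int64)
    per = max(1, n_pairs // max(len(matrices), 1))
    for mi, matrix in enumerate(matrices):
        idx = _eligible_sites(
            matrix,
            pair_kwargs.get("min_mac", 2),
            pair_kwargs.get("max_missing", 0.2),
        )
        if idx.size < 2:
            continue
        rng = derive_rng(seed, "ld", mi)
        pick_a = rng.integers(0, idx.size, size=per)
        pick_b = rng.integers(0, idx.size, size=per)
        ok = pick_a != pick_b
        for a, b in zip(idx[pick_a[ok]], idx[pick_b[ok]]):
            dist = abs(int(matrix.positions[a]) - int(matrix.positions[b]))
            k = int(np.searchsorted(edges, dist, side="right")) - 1
            if not 0 <= k < nb:
                continue
            v = r2(matrix.alleles[:, a], matrix.alleles[:, b])
            if not math.isnan(v):
                sums[k] += v
                counts[k] += 1
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LDCurve(bin_edges=edges, mean_r2=means, pair_counts=counts)


@dataclass(frozen=True)
class FitDiagnostics:
    """Matched quantile pairs and the RMSE of their identity fit."""

    observed_quantiles: np.ndarray
    simulated_quantiles: np.ndarray
    rmse: float


def qq_rmse(observed, simulated, n_quantiles: int = 100) -> FitDiagnostics:
    """Compare two samples by matched quantiles.

    Quantiles are taken at the midpoint probabilities (i - 0.5)/n using
    linear (type-7) interpolation; RMSE is the root-mean-square
    difference of the matched quantiles.
    """
    obs = np.asarray(observed, dtype=float)
    sim = np.asarray(simulated, dtype=float)
    if obs.size == 0 or sim.size == 0:
        raise ValueError("both samples must be nonempty")
    probs = (np.arange(1, n_quantiles + 1) - 0.5) / n_quantiles
    oq = np.quantile(obs, probs)
    sq = np.quantile(sim, probs)
    return FitDiagnostics(
        observed_quantiles=oq,
        simulated_quantiles=sq,
        rmse=float(np.sqrt(np.mean((oq - sq) ** 2))),
    )
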