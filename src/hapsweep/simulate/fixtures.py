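"""Deterministic planted-sweep fixtures.

These matrices emulate the haplotype-frequency-spectrum geometry of hard
and soft sweeps without running a simulator: a hard fixture plants one
haplotype class at frequency f on a random background; a soft fixture
splits f over k distinct classes; a neutral fixture is i.i.d. random
rows, which are all-unique with overwhelming probability once the number
of sites far exceeds log2(n).
"""

from __future__ import annotations

import logging

import numpy as np

from ..hapstats import HaplotypeMatrix
from ..seeds import derive_rng

logger = logging.getLogger(__name__)

__all__ = ["make_fixture", "make_fixture_genome"]


def _partition(total: int, k: int) -> list[int]:
    """Split ``total`` into k nearest-integer parts, largest first."""
    base = total // k
    rem = total % k
    parts = [base + (1 if i < rem else 0) for i in range(k)]
    if rem:
        logger.debug("count %d not divisible by %d classes; parts %s", total, k, parts)
    return parts


def make_fixture(
    kind: str,
    n: int = 145,
    l_snps: int = 401,
    *,
    f: float = 0.6,
    k: int = 3,
    seed: int = 0,
    bp_spacing: int = 25,
) -> HaplotypeMatrix:
    """A planted fixture matrix of ``n`` haplotypes over ``l_snps`` sites.

    kind "hard": one class carries round(f*n) copies of a shared
    haplotype; kind "soft": that mass is split over ``k`` distinct
    classes; kind "neutral": all rows independent. Deterministic given
    the seed.
    """
    if kind not in ("neutral", "hard", "soft"):
        raise ValueError(f"unknown fixture kind {kind!r}")
    rng = derive_rng(seed, "fixture", kind, n, l_snps, f, k)
    alleles = rng.integers(0, 2, size=(n, l_snps), dtype=np.int8)
    if kind != "neutral":
        n_sweep = int(round(f * n))
        classes = 1 if kind == "hard" else k
        counts = _partition(n_sweep, classes)
        rows = rng.permutation(n)[:n_sweep]
        offset = 0
        for c in counts:
            template = rng.integers(0, 2, size=l_snps, dtype=np.int8)
            alleles[rows[offset : offset + c]] = template
            offset += c
    positions = np.arange(1, l_snps + 1, dtype=np.int64) * bp_spacing
    return HaplotypeMatrix(alleles=alleles, positions=positions, chrom=kind)


def make_fixture_genome(
    n: int = 145,
    n_windows: int = 20,
    window_snps: int = 401,
    *,
    sweep_window: int | None = None,
    kind: str = "hard",
    f: float = 0.8,
    k: int = 3,
    seed: int = 0,
    chrom: str = "fix1",
    bp_spacing: int = 25,
) -> HaplotypeMatrix:
    """A one-chromosome fixture of ``n_windows`` juxtaposed windows with an
    optional planted sweep in window ``sweep_window`` (0-based)."""
    rng = derive_rng(seed, "fixture-genome", n, n_windows, window_snps, kind, f, k)
    total = n_windows * window_snps
    alleles = rng.integers(0, 2, size=(n, total), dtype=np.int8)
    if sweep_window is not None:
        if not 0 <= sweep_window < n_windows:
            raise ValueError("sweep_window out of range")
        sub = make_fixture(
            kind, n, window_snps, f=f, k=k,
            seed=derive_rng(seed, "fixture-genome", "sub").integers(2**31),
        )
        start = sweep_window * window_snps
        alleles[:, start : start + window_snps] = sub.alleles
    positions = np.arange(1, total + 1, dtype=np.int64) * bp_spacing
    return HaplotypeMatrix(alleles=alleles, positions=positions, chrom=chrom)
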