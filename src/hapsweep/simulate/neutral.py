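"""Neutral simulation via the exact coalescent (msprime)."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from ..demography import DemographicModel
from ..hapstats import HaplotypeMatrix
from ..seeds import derive_seed
from .config import SimulationConfig, rescale_model

__all__ = ["simulate_neutral", "sample_population_haplotypes", "central_window"]


def _tree_sequence(model, cfg, n_haplotypes, seed):
    import msprime

    q = cfg.rescale_q
    scaled = rescale_model(model, q)
    if scaled.reference_size is not None and scaled.reference_size < n_haplotypes / 2:
        raise ValueError(
            f"rescaled reference size {scaled.reference_size:.0f} is smaller "
            f"than the sample ({n_haplotypes} haplotypes); lower rescale_q"
        )
    dem = scaled.to_msprime()
    pop = scaled.sample_population or scaled.populations[0].name
    anc = msprime.sim_ancestry(
        samples={pop: n_haplotypes},
        ploidy=2,
        demography=dem,
        sequence_length=cfg.seq_length,
        recombination_rate=cfg.r_scaled,
        random_seed=(seed % (2**31 - 2)) + 1,
    )
    return msprime.sim_mutations(
        anc,
        rate=cfg.mu_scaled,
        model=msprime.BinaryMutationModel(),
        discrete_genome=True,
        random_seed=(derive_seed(seed, "mut") % (2**31 - 2)) + 1,
    )


def _matrix_from_ts(ts, n_haplotypes, chrom):
    geno = ts.genotype_matrix()  # sites x nodes
    positions = np.array([int(s.position) for s in ts.sites()], dtype=np.int64)
    # tskit guarantees one site per integer position with discrete_genome
    keep = (geno.sum(axis=1) > 0) & (geno.sum(axis=1) < geno.shape[1])
    geno = geno[keep][:, :n_haplotypes]
    positions = positions[keep]
    # drop sites that became monomorphic within the haplotype subsample
    seg = (geno.sum(axis=1) > 0) & (geno.sum(axis=1) < n_haplotypes)
    geno = geno[seg]
    positions = positions[seg]
    if positions.size and positions[0] == 0:
        positions = positions + 1  # 1-based bp coordinates
    return HaplotypeMatrix(
        alleles=np.ascontiguousarray(geno.T, dtype=np.int8),
        positions=positions,
        chrom=chrom,
    )


def sample_population_haplotypes(
    model: DemographicModel, cfg: SimulationConfig, n_haplotypes: int, seed: int,
    chrom: str = "sim",
) -> HaplotypeMatrix:
    """One coalescent sample of ``n_haplotypes`` phased chromosomes."""
    ts = _tree_sequence(model, cfg, n_haplotypes, seed)
    return _matrix_from_ts(ts, n_haplotypes, chrom)


def simulate_neutral(
    model: DemographicModel, cfg: SimulationConfig, reps: int
) -> Iterator[HaplotypeMatrix]:
    """Stream ``reps`` independent neutral replicates.

    Each replicate is an ``n_samples``-haplotype matrix with bp positions
    in [1, seq_length]. Replicate seeds derive from ``cfg.seed`` and the
    replicate index, so extending ``reps`` never changes earlier output.
    """
    for i in range(reps):
        seed = derive_seed(cfg.seed, "neutral", i)
        yield sample_population_haplotypes(
            model, cfg, cfg.n_samples, seed, chrom=f"rep{i}"
        )


def central_window(
    matrix: HaplotypeMatrix, window_snps: int, target_bp: int | None = None
) -> tuple[int, int]:
    """Half-open SNP range of the ``window_snps`` window centred nearest
    ``target_bp`` (default: midpoint of the spanned positions).

    Raises with the SNP deficit when the matrix is too short, so callers
    can resimulate with a longer chromosome.
    """
    n = matrix.n_sites
    if n < window_snps:
        raise ValueError(
            f"need {window_snps} SNPs, have {n} (deficit {window_snps - n})"
        )
    if target_bp is None:
        target_bp = int(matrix.positions[0] + matrix.positions[-1]) // 2
    mid = int(np.searchsorted(matrix.positions, target_bp))
    mid = min(max(mid, 0), n - 1)
    start = mid - window_snps // 2
    start = min(max(start, 0), n - window_snps)
    return start, start + window_snps
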