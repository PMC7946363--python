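"""Simulation parameter containers and population-size rescaling."""

from __future__ import annotations

from dataclasses import dataclass, replace

from ..demography import DemographicModel, Population, Epoch, Split, Admixture, Migration

__all__ = ["SimulationConfig", "SweepConfig", "rescale_model"]

#: cM/bp -> per-generation crossover probability per bp.
CM_PER_BP_TO_R = 1e-2


@dataclass(frozen=True)
class SimulationConfig:
    """Replicate-level parameters.

    Defaults follow the Drosophila scan setup: samples of 145 chromosomes,
    a neutral mutation rate of 1e-9 /bp/gen, recombination 5e-7 cM/bp, and
    chromosomes of 100 kb for neutral runs (350 kb for selection runs, so
    the central 401-SNP window fits even after the sweep removes
    diversity). ``rescale_q`` divides population sizes by Q while
    multiplying mu, r and s by Q, preserving theta, rho and 4*Ne*s.
    """

    n_samples: int = 145
    seq_length: int = 100_000
    mu: float = 1e-9
    rho_cM_per_bp: float = 5e-7
    rescale_q: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.seq_length < 1:
            raise ValueError("seq_length must be positive")
        if self.mu < 0 or self.rho_cM_per_bp < 0:
            raise ValueError("rates must be >= 0")
        if self.rescale_q < 1:
            raise ValueError("rescale_q must be >= 1")

    @property
    def r_per_bp(self) -> float:
        """Unrescaled crossover probability per bp per generation."""
        return self.rho_cM_per_bp * CM_PER_BP_TO_R

    @property
    def mu_scaled(self) -> float:
        return self.mu * self.rescale_q

    @property
    def r_scaled(self) -> float:
        return self.r_per_bp * self.rescale_q


@dataclass(frozen=True)
class SweepConfig:
    """Selection-scenario parameters.

    ``theta_a`` = 4*Ne*mu_A is the population-scaled adaptive mutation
    rate at the selected site (0.01 for the hard regime, 10 for soft);
    it is anchored to the reference/ancestral Ne of the model and is
    invariant under rescaling. ``s`` is the homozygote selection
    advantage; with ``dominance`` = 0.5 (co-dominance) a homozygote has
    twice the fitness advantage of a heterozygote. Selection starts
    ``onset_time`` generations before sampling; alternatively the run can
    stop when the adaptive allele reaches ``partial_freq``.
    ``site_position`` defaults to the chromosome centre.
    """

    theta_a: float
    s: float
    dominance: float = 0.5
    onset_time: float | None = None
    partial_freq: float | None = None
    site_position: int | None = None
    max_retries: int = 1000

    def __post_init__(self):
        if self.theta_a <= 0:
            raise ValueError("theta_a must be > 0")
        if not 0 < self.s <= 1:
            raise ValueError("s must lie in (0, 1]")
        if self.partial_freq is not None and not 0 < self.partial_freq <= 1:
            raise ValueError("partial_freq must lie in (0, 1]")
        if self.onset_time is not None and self.onset_time < 0:
            raise ValueError("onset_time must be >= 0")
        if self.onset_time is None and self.partial_freq is None:
            raise ValueError("need an onset_time or a partial_freq stop condition")


def rescale_model(model: DemographicModel, q: float) -> DemographicModel:
    """Divide sizes and times by Q (growth and migration rates scale by Q).

    Combined with mu -> mu*Q, r -> r*Q and s -> s*Q this preserves the
    dimensionless compound parameters theta = 4*Ne*mu, rho = 4*Ne*r and
    4*Ne*s, so sample statistics are invariant up to rescaling error.
    """
    if q == 1:
        return model
    pops = tuple(
        Population(
            p.name,
            tuple(
                Epoch(e.start_time / q, e.size / q, e.growth_rate * q)
                for e in p.epochs
            ),
        )
        for p in model.populations
    )
    return replace(
        model,
        populations=pops,
        splits=tuple(Split(s.child, s.parent, s.time / q) for s in model.splits),
        admixtures=tuple(
            Admixture(a.child, a.parent_a, a.parent_b, a.proportion, a.time / q)
            for a in model.admixtures
        ),
        migrations=tuple(
            Migration(m.source, m.dest, min(m.rate * q, 0.999),
                      m.start_time / q, m.end_time / q)
            for m in model.migrations
        ),
        reference_size=(model.reference_size / q
                        if model.reference_size is not None else None),
        founding_sizes={k: v / q for k, v in model.founding_sizes.items()},
    )
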