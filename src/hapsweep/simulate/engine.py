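"""Rescaled forward Wright-Fisher engine for sweep simulation.

The engine evolves a diploid population of N individuals (2N haplotypes)
with discrete generations: multinomial reproduction weighted by fitness,
per-gamete crossover (Poisson number of breakpoints, uniform within the
segment), infinite-sites neutral mutation, and recurrent adaptive
mutation at a single selected site. Co-dominant fitness is

    w(aa) = 1,  w(Aa) = 1 + dominance * s,  w(AA) = 1 + s,

so with the default dominance of 0.5 a homozygote has twice the fitness
advantage of a heterozygote.

Rescaling by Q maps Ne -> Ne/Q, mu -> mu*Q, r -> r*Q and s -> s*Q,
preserving theta = 4*Ne*mu, rho = 4*Ne*r and 4*Ne*s. The starting
population is a coalescent equilibrium sample of 2N haplotypes (msprime),
so no forward burn-in is needed; the forward phase covers only the
selection episode. When s*Q exceeds 1 the fitness weights remain valid
(they are relative weights), at the cost of the usual rescaling accuracy
caveats for very strong selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..demography import DemographicModel
from ..hapstats import HaplotypeMatrix
from ..seeds import derive_seed
from .config import SimulationConfig, SweepConfig
from .neutral import sample_population_haplotypes

__all__ = ["ForwardSimulator", "SweepResult", "simulate_sweep"]


class ForwardSimulator:
    """Forward WF evolution of a haplotype pool under selection at one site.

    Parameters are *already rescaled*: ``n_diploid`` individuals, per-bp
    per-generation rates ``mu`` and ``r``, homozygote advantage ``s``.
    """

    def __init__(
        self,
        haplotypes: np.ndarray,
        positions: np.ndarray,
        seq_length: int,
        *,
        mu: float,
        r: float,
        s: float,
        dominance: float,
        adaptive_pos: int,
        mu_adaptive: float,
        rng: np.random.Generator,
    ):
        hap = np.asarray(haplotypes, dtype=np.int8)
        if hap.shape[0] % 2:
            raise ValueError("need an even number of haplotypes (diploids)")
        self.n_diploid = hap.shape[0] // 2
        pos = np.asarray(positions, dtype=np.int64)
        # insert the adaptive site column (ancestral everywhere) if absent
        if adaptive_pos not in pos:
            idx = int(np.searchsorted(pos, adaptive_pos))
            pos = np.insert(pos, idx, adaptive_pos)
            hap = np.insert(hap, idx, 0, axis=1)
        self.hap = np.ascontiguousarray(hap)
        self.pos = pos
        self.seq_length = int(seq_length)
        self.mu = mu
        self.r = r
        self.s = s
        self.dominance = dominance
        self.adaptive_pos = int(adaptive_pos)
        self.mu_adaptive = mu_adaptive
        self.rng = rng
        self.generation = 0
        self.n_adaptive_origins = 0

    @property
    def adaptive_index(self) -> int:
        return int(np.searchsorted(self.pos, self.adaptive_pos))

    def adaptive_frequency(self) -> float:
        return float(self.hap[:, self.adaptive_index].mean())

    def _fitness(self) -> np.ndarray:
        g = (
            self.hap[0::2, self.adaptive_index].astype(np.float64)
            + self.hap[1::2, self.adaptive_index]
        )
        w = np.ones(self.n_diploid)
        w[g == 1] += self.dominance * self.s
        w[g == 2] += self.s
        return w

    def step(self) -> None:
        """Advance one generation."""
        rng = self.rng
        n2 = 2 * self.n_diploid
        w = self._fitness()
        parents = rng.choice(self.n_diploid, size=n2, p=w / w.sum())

        n_sites = self.pos.size
        n_cross = rng.poisson(self.r * self.seq_length, size=n2)
        which_first = rng.integers(0, 2, size=n2)
        child = np.empty_like(self.hap)
        # bulk-copy the (common) zero-crossover gametes
        no_cross = n_cross == 0
        child[no_cross] = self.hap[2 * parents[no_cross] + which_first[no_cross]]
        site_index = np.arange(n_sites)
        for i in np.flatnonzero(~no_cross):
            a = self.hap[2 * parents[i] + which_first[i]]
            b = self.hap[2 * parents[i] + 1 - which_first[i]]
            breaks = np.searchsorted(
                self.pos, rng.integers(1, self.seq_length + 1, size=n_cross[i])
            )
            use_b = (
                np.searchsorted(np.sort(breaks), site_index, side="right") % 2
            ).astype(bool)
            child[i] = np.where(use_b, b, a)

        # recurrent adaptive mutation (0 -> 1 at the selected site)
        hits = rng.random(n2) < self.mu_adaptive
        if hits.any():
            col = child[:, self.adaptive_index]
            new = hits & (col == 0)
            self.n_adaptive_origins += int(new.sum())
            col[new] = 1

        # neutral infinite-sites mutation: new segregating columns
        n_new = rng.poisson(self.mu * self.seq_length * n2)
        if n_new:
            taken = set(self.pos.tolist())
            new_pos = []
            while len(new_pos) < n_new:
                p = int(rng.integers(1, self.seq_length + 1))
                if p not in taken:
                    taken.add(p)
                    new_pos.append(p)
            new_pos = np.sort(np.array(new_pos, dtype=np.int64))
            cols = np.zeros((n2, n_new), dtype=np.int8)
            cols[rng.integers(0, n2, size=n_new), np.arange(n_new)] = 1
            insert_at = np.searchsorted(self.pos, new_pos)
            self.pos = np.insert(self.pos, insert_at, new_pos)
            child = np.insert(child, insert_at, cols, axis=1)

        self.hap = child
        self.generation += 1
        if self.generation % 10 == 0:
            self._drop_fixed()

    def _drop_fixed(self) -> None:
        """Drop monomorphic columns (keep the adaptive site always)."""
        counts = self.hap.sum(axis=0)
        seg = (counts > 0) & (counts < self.hap.shape[0])
        seg[self.adaptive_index] = True
        self.hap = np.ascontiguousarray(self.hap[:, seg])
        self.pos = self.pos[seg]

    def run(
        self,
        *,
        generations: int | None = None,
        stop_freq: float | None = None,
        max_generations: int = 10_000,
    ) -> None:
        """Run for a fixed number of generations and/or until the adaptive
        allele reaches ``stop_freq`` (whichever applies first/last: with
        both given, runs ``generations`` steps but stops early at the
        frequency)."""
        limit = generations if generations is not None else max_generations
        remaining = limit
        n2 = 2 * self.n_diploid
        while remaining > 0:
            # Fast-forward while the adaptive allele is absent: the starting
            # population is a coalescent equilibrium sample, and a neutral WF
            # population at stationarity is distributionally invariant under
            # further neutral generations, so generations before the first
            # adaptive origin can be skipped. The waiting time is geometric
            # in the per-generation probability of >= 1 origin.
            if (
                self.mu_adaptive > 0
                and self.hap[:, self.adaptive_index].sum() == 0
            ):
                p_any = -np.expm1(n2 * np.log1p(-self.mu_adaptive))
                wait = int(self.rng.geometric(p_any))
                if wait > remaining:
                    self.generation += remaining
                    return
                self.generation += wait
                remaining -= wait
                carrier = int(self.rng.integers(0, n2))
                self.hap[carrier, self.adaptive_index] = 1
                self.n_adaptive_origins += 1
                if remaining <= 0:
                    return
            self.step()
            remaining -= 1
            if stop_freq is not None and self.adaptive_frequency() >= stop_freq:
                return

    def sample(self, n_samples: int, chrom: str = "sweep") -> HaplotypeMatrix:
        """Sample haplotypes without replacement; segregating sites only."""
        self._drop_fixed()
        rows = self.rng.choice(self.hap.shape[0], size=n_samples, replace=False)
        sub = self.hap[np.sort(rows)]
        counts = sub.sum(axis=0)
        seg = (counts > 0) & (counts < n_samples)
        return HaplotypeMatrix(
            alleles=np.ascontiguousarray(sub[:, seg]),
            positions=self.pos[seg],
            chrom=chrom,
        )


@dataclass
class SweepResult:
    matrix: HaplotypeMatrix
    adaptive_pos: int
    final_frequency: float
    n_origins: int
    retries: int


def simulate_sweep(
    model: DemographicModel,
    cfg: SimulationConfig,
    sweep: SweepConfig,
    reps: int,
):
    """Stream ``reps`` sweep replicates conditioned on the adaptive allele
    segregating (or fixed) at sampling; failed establishments are redrawn
    up to ``sweep.max_retries`` times and the retry count is reported.

    The forward phase runs in the sampled population at its rescaled
    current size; the neutral background entering the forward phase is a
    coalescent equilibrium sample under the full (rescaled) model.
    theta_A is anchored to the model's reference Ne, so the per-gamete
    adaptive rate is theta_A / (4 * Ne_ref / Q) = theta_A * Q / (4 * Ne_ref)
    ... expressed with the rescaled population it is theta_A / (4 * N_r)
    scaled by N_r / Ne_r,ref when the sampled population's size differs
    from the reference.
    """
    q = cfg.rescale_q
    pop_name = model.sample_population or model.populations[0].name
    n_r = model.pop(pop_name).present_size / q  # rescaled current diploid size
    if n_r < cfg.n_samples:
        raise ValueError(
            f"rescaled population ({n_r:.0f} diploids) smaller than the "
            f"sample of {cfg.n_samples}; lower rescale_q"
        )
    ne_ref = (model.reference_size or model.pop(pop_name).present_size) / q
    n_diploid = int(round(n_r))
    mu_adaptive = sweep.theta_a / (4.0 * ne_ref)
    s_r = sweep.s * q
    adaptive_pos = (
        sweep.site_position
        if sweep.site_position is not None
        else cfg.seq_length // 2
    )
    onset_gens = (
        None if sweep.onset_time is None else max(1, int(round(sweep.onset_time / q)))
    )

    for i in range(reps):
        retries = 0
        while True:
            seed = derive_seed(cfg.seed, "sweep", i, retries)
            background = sample_population_haplotypes(
                model, cfg, 2 * n_diploid, seed, chrom=f"sweep{i}"
            )
            sim = ForwardSimulator(
                background.alleles,
                background.positions,
                cfg.seq_length,
                mu=cfg.mu_scaled,
                r=cfg.r_scaled,
                s=s_r,
                dominance=sweep.dominance,
                adaptive_pos=adaptive_pos,
                mu_adaptive=mu_adaptive,
                rng=np.random.default_rng(derive_seed(seed, "fwd")),
            )
            sim.run(generations=onset_gens, stop_freq=sweep.partial_freq)
            freq = sim.adaptive_frequency()
            if onset_gens is not None:
                established = freq > 0.0
            else:  # pure partial-frequency stop condition
                established = freq >= sweep.partial_freq
            if established:
                matrix = sim.sample(cfg.n_samples, chrom=f"sweep{i}")
                yield SweepResult(
                    matrix=matrix,
                    adaptive_pos=adaptive_pos,
                    final_frequency=freq,
                    n_origins=sim.n_adaptive_origins,
                    retries=retries,
                )
                break
            retries += 1
            if retries > sweep.max_retries:
                raise RuntimeError(
                    f"sweep replicate {i}: adaptive allele failed to establish "
                    f"after {sweep.max_retries} retries "
                    f"(theta_A={sweep.theta_a}, s={sweep.s}, Q={q})"
                )
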