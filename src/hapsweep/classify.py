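"""Approximate-Bayesian classification of detected peaks as hard or soft.

Reference sets of (H12, H2/H1) points are simulated under the two sweep
regimes — hard (theta_A = 0.01, effectively single-origin) and soft
(theta_A = 10, recurrent origins) — with nuisance parameters (selection
coefficient, partial frequency, sweep age) drawn from uniform priors.
The Bayes factor for an observed pair is the ratio of soft to hard
reference points lying within a Euclidean radius epsilon (default 0.1,
i.e. 10% of the unit square) of the observation:

    BF = P(H12_obs, H2/H1_obs | soft) / P(H12_obs, H2/H1_obs | hard).

BF > 1 favours a soft sweep; zero-count denominators are marked infinite
or undefined explicitly, never silently coerced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demography import DemographicModel
from .hapstats import window_stats
from .seeds import derive_rng, derive_seed
from .simulate import SimulationConfig, SweepConfig, central_window, simulate_sweep

__all__ = [
    "ReferenceSet",
    "BFResult",
    "build_reference",
    "bayes_factor",
    "bf_grid",
    "classify_peaks",
]


@dataclass(frozen=True)
class ReferenceSet:
    """Simulated (H12, H2/H1) points for one sweep regime."""

    label: str  # "hard" | "soft"
    points: np.ndarray  # n x 2 in the unit square
    priors: pd.DataFrame | None = None  # per-point (s, partial_freq, onset)
    model_key: str = ""
    seed: int = 0

    def __post_init__(self):
        if self.label not in ("hard", "soft"):
            raise ValueError("label must be 'hard' or 'soft'")
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.shape[1] != 2:
            raise ValueError("points must be n x 2 (H12, H2/H1)")
        if pts.size and (pts.min() < 0 or pts.max() > 1):
            raise ValueError("points must lie in the unit square")
        object.__setattr__(self, "points", pts)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.points, columns=["h12", "h2h1"])
        if self.priors is not None:
            df = pd.concat([df, self.priors.reset_index(drop=True)], axis=1)
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path, label: str) -> "ReferenceSet":
        df = pd.read_csv(path, sep="\t")
        prior_cols = [c for c in df.columns if c not in ("h12", "h2h1")]
        return cls(
            label=label,
            points=df[["h12", "h2h1"]].to_numpy(),
            priors=df[prior_cols] if prior_cols else None,
        )


def build_reference(
    model: DemographicModel,
    label: str,
    cfg: SimulationConfig,
    n_sims: int,
    *,
    theta_a: float | None = None,
    onset_upper: float | None = None,
    window_snps: int = 401,
    seed: int = 0,
    s_range: tuple[float, float] = (0.0, 1.0),
    pf_range: tuple[float, float] = (0.0, 1.0),
) -> ReferenceSet:
    """Simulate ``n_sims`` sweeps and collect central-window (H12, H2/H1).

    Priors: s ~ U(s_range) (default U(0, 1)), partial frequency
    ~ U(pf_range) (default U(0, 1)), and sweep onset ~ U[0, time of
    admixture] for admixture models; models without an admixture event
    need an explicit ``onset_upper`` bound in generations. theta_A
    defaults to 0.01 (hard) / 10 (soft). Runs at a rescaled population
    size should narrow ``s_range`` so the rescaled coefficient s*Q stays
    moderate.
    """
    if theta_a is None:
        theta_a = 0.01 if label == "hard" else 10.0
    t_admix = model.admixture_time
    if t_admix is None:
        if onset_upper is None:
            raise ValueError(
                "model has no admixture event: supply onset_upper (generations) "
                "as the sweep-age prior bound"
            )
        t_admix = onset_upper
    rng = derive_rng(seed, "reference", label)
    rows = []
    points = []
    for i in range(n_sims):
        s = float(rng.uniform(*s_range))
        pf = float(rng.uniform(*pf_range))
        onset = float(rng.uniform(0.0, t_admix))
        sweep = SweepConfig(
            theta_a=theta_a, s=max(s, 1e-6), onset_time=onset,
            partial_freq=max(pf, 1e-6),
        )
        rep_cfg = SimulationConfig(
            n_samples=cfg.n_samples,
            seq_length=cfg.seq_length,
            mu=cfg.mu,
            rho_cM_per_bp=cfg.rho_cM_per_bp,
            rescale_q=cfg.rescale_q,
            seed=derive_seed(seed, "reference", label, i),
        )
        result = next(iter(simulate_sweep(model, rep_cfg, sweep, 1)))
        try:
            rng_window = central_window(
                result.matrix, window_snps, target_bp=result.adaptive_pos
            )
        except ValueError:
            continue  # too few SNPs after an extreme sweep; skip the point
        w = window_stats(result.matrix, rng_window)
        points.append((w.h12, w.h2h1))
        rows.append({"s": s, "partial_freq": pf, "onset": onset})
    return ReferenceSet(
        label=label,
        points=np.array(points) if points else np.empty((0, 2)),
        priors=pd.DataFrame(rows),
        model_key=model.name,
        seed=seed,
    )


@dataclass(frozen=True)
class BFResult:
    observed: tuple[float, float]
    n_soft: int
    n_hard: int
    epsilon: float
    bf: float = field(init=False)
    status: str = field(init=False)  # "finite" | "infinite" | "undefined"

    def __post_init__(self):
        if self.n_soft < 0 or self.n_hard < 0:
            raise ValueError("match counts must be >= 0")
        if self.n_hard > 0:
            object.__setattr__(self, "bf", self.n_soft / self.n_hard)
            object.__setattr__(self, "status", "finite")
        elif self.n_soft > 0:
            object.__setattr__(self, "bf", math.inf)
            object.__setattr__(self, "status", "infinite")
        else:
            object.__setattr__(self, "bf", math.nan)
            object.__setattr__(self, "status", "undefined")


def _count_within(points: np.ndarray, obs: np.ndarray, epsilon: float) -> int:
    if points.size == 0:
        return 0
    d2 = ((points - obs) ** 2).sum(axis=1)
    return int(np.sum(d2 <= epsilon * epsilon))


def bayes_factor(
    obs: tuple[float, float],
    hard: ReferenceSet,
    soft: ReferenceSet,
    epsilon: float = 0.1,
    *,
    pseudocount: bool = False,
) -> BFResult:
    """Count reference points within Euclidean distance epsilon of ``obs``
    in the (H12, H2/H1) plane and form BF = n_soft / n_hard.

    ``pseudocount=True`` adds 1 to both counts (grid-rendering aid only).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if hard.label != "hard" or soft.label != "soft":
        raise ValueError("reference sets passed in the wrong order")
    o = np.asarray(obs, dtype=float)
    n_h = _count_within(hard.points, o, epsilon)
    n_s = _count_within(soft.points, o, epsilon)
    if pseudocount:
        n_h += 1
        n_s += 1
    return BFResult(observed=(float(o[0]), float(o[1])), n_soft=n_s, n_hard=n_h,
                    epsilon=epsilon)


def bf_grid(
    hard: ReferenceSet,
    soft: ReferenceSet,
    grid_resolution: int = 21,
    epsilon: float = 0.1,
    *,
    pseudocount: bool = False,
) -> pd.DataFrame:
    """BF at every node of a ``grid_resolution``-per-axis grid over the unit
    square; renderable as the hard-favoured (BF < 1) / soft-favoured
    (BF > 1) classification surface."""
    if grid_resolution < 2:
        raise ValueError("grid_resolution must be >= 2 per axis")
    axis = np.linspace(0.0, 1.0, grid_resolution)
    rows = []
    for h12 in axis:
        for h2h1 in axis:
            res = bayes_factor(
                (h12, h2h1), hard, soft, epsilon, pseudocount=pseudocount
            )
            rows.append(
                {
                    "h12": h12,
                    "h2h1": h2h1,
                    "n_soft": res.n_soft,
                    "n_hard": res.n_hard,
                    "bf": res.bf,
                    "status": res.status,
                }
            )
    return pd.DataFrame(rows)


def classify_peaks(
    peaks,
    hard: ReferenceSet,
    soft: ReferenceSet,
    epsilon: float = 0.1,
    threshold: float = 1.0,
) -> pd.DataFrame:
    """Label each peak soft (BF > threshold), hard (BF < 1/threshold) or
    undetermined (in between, or undefined BF — never silently dropped).

    ``peaks`` may be scan Peak objects or (H12, H2/H1) pairs; peaks
    should already be conditioned on high H12 by the scan cutoff.
    """
    if threshold < 1.0:
        raise ValueError("threshold must be >= 1")
    rows = []
    for p in peaks:
        if hasattr(p, "max_h12"):
            obs = (p.max_h12, p.h2h1_at_max)
        else:
            obs = (float(p[0]), float(p[1]))
        res = bayes_factor(obs, hard, soft, epsilon)
        if res.status == "undefined":
            label = "undetermined"
        elif res.bf > threshold:
            label = "soft"
        elif res.bf < 1.0 / threshold:
            label = "hard"
        else:
            label = "undetermined"
        rows.append(
            {
                "h12": obs[0],
                "h2h1": obs[1],
                "n_soft": res.n_soft,
                "n_hard": res.n_hard,
                "bf": res.bf,
                "status": res.status,
                "label": label,
            }
        )
    return pd.DataFrame(rows)
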