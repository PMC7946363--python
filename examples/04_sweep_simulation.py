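"""Forward Wright-Fisher sweep simulation: hard versus soft regimes.

Simulates sweeps at a rescaled population size (Q = 2700 against the
constant Ne = 2.7e6 model, so N = 1000 diploids with theta, rho and the
bp sweep footprint preserved). The hard regime (theta_A = 0.01) yields a
single adaptive origin and a single dominant haplotype; the soft regime
(theta_A = 10) yields recurrent origins and several common haplotypes.
Takes a minute or two.
"""

import numpy as np

from hapsweep import central_window, window_stats
from hapsweep.demography import get_model
from hapsweep.simulate import SimulationConfig, SweepConfig, simulate_sweep

model = get_model("B")
cfg = SimulationConfig(seq_length=30_000, rescale_q=2700, seed=5)

for label, theta_a in (("hard", 0.01), ("soft", 10.0)):
    sweep = SweepConfig(theta_a=theta_a, s=0.005, partial_freq=0.95)
    h12s, h2h1s, origins = [], [], []
    for r in simulate_sweep(model, cfg, sweep, 6):
        w = window_stats(
            r.matrix, central_window(r.matrix, 401, target_bp=r.adaptive_pos)
        )
        h12s.append(w.h12)
        h2h1s.append(w.h2h1)
        origins.append(r.n_origins)
    print(
        f"{label:4s} (theta_A={theta_a:>5}): mean H12={np.mean(h12s):.3f} "
        f"mean H2/H1={np.mean(h2h1s):.3f} mean origins={np.mean(origins):.1f}"
    )

print(
    "\nBoth regimes elevate H12 well above the neutral level (~0.01); the "
    "soft regime\nshows higher H2/H1 and multiple adaptive origins."
)
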