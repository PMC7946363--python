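"""Genome scan with a simulation-calibrated 1-per-genome FDR cutoff.

Simulates a small neutral null (constant Ne = 2.7e6), calibrates the
tenth-highest-H12 cutoff, scans a fixture chromosome with one planted
soft sweep, and prints the called peaks. The planted locus should be the
top peak; a neutral chromosome yields about one false peak per genome by
construction of the cutoff.
"""

import numpy as np

from hapsweep import (
    NullDistribution,
    ScanConfig,
    central_window,
    fdr_cutoff,
    scan_genome,
    window_stats,
)
from hapsweep.demography import get_model
from hapsweep.simulate import SimulationConfig, make_fixture_genome, simulate_neutral

WINDOW = 101  # SNPs per window (desk scale; the Drosophila scan used 401)
N_WINDOWS = 10

# Null: H12 in the central window of 10x as many neutral replicates
model = get_model("B")
cfg = SimulationConfig(n_samples=50, seq_length=4_000, seed=42)
null_h12 = [
    window_stats(m, central_window(m, WINDOW)).h12
    for m in simulate_neutral(model, cfg, 10 * N_WINDOWS)
]
null = NullDistribution(values=np.array(null_h12), n_data_windows=N_WINDOWS)
cutoff = fdr_cutoff(null)
print(f"1-per-genome FDR cutoff (10th highest of {len(null_h12)} sims): "
      f"H12 = {cutoff:.4f}")

genome = make_fixture_genome(
    n=50, n_windows=N_WINDOWS, window_snps=WINDOW,
    sweep_window=4, kind="soft", f=0.8, k=2, seed=3,
)
scan_cfg = ScanConfig(window_snps=WINDOW, step_snps=WINDOW, top_n=5)
report = scan_genome({genome.chrom: genome}, null, None, scan_cfg)

print(f"{len(report.windows)} windows scanned, {len(report.peaks)} peak(s):")
for i, p in enumerate(report.peaks, 1):
    print(
        f"  peak {i}: {p.chrom}:{p.bp_start}-{p.bp_stop} "
        f"max H12={p.max_h12:.3f} H2/H1={p.h2h1_at_max:.3f}"
    )
print("The planted sweep occupies window 4 "
      f"(bp {4 * WINDOW * 25 + 1}-{5 * WINDOW * 25}).")
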