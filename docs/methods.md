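# Methods

## Statistics

All four homozygosity statistics operate on the spectrum of haplotype
frequencies `p_1 ≥ p_2 ≥ …` within one window: `H1 = Σ p_i²`,
`H2 = Σ_{i≥2} p_i²`, `H12 = (p1+p2)² + Σ_{i≥3} p_i²`, and the ratio
H2/H1. The identities `H12 = H1 + 2 p1 p2` and `H2 = H1 − p1²` hold
exactly and are enforced by tests. For a monomorphic window `p2` is
defined as 0, so H12 = H1 = 1 and H2/H1 = 0. Spectra are deterministic:
ties in frequency are broken by the lexicographic order of the haplotype
string.

Missing data: the default policy treats a missing call as a distinct
allele state, so haplotypes join a class only when their missing patterns
agree — strict, simple, and reproducible. An optional `match_on_observed`
mode lets a partially observed haplotype join a fully observed class when
exactly one class matches it at every observed site; ambiguous haplotypes
remain singletons. Any fully missing haplotype is an error naming the
sample. Multiallelic sites are rejected at VCF ingest; split or drop them
upstream.

## Window scan and calibration

Windows contain a fixed number of SNPs (default 401, ≈10 kb at
*Drosophila* diversity) so that H12 does not covary with SNP count; in
regions of low diversity the same window spans more bp and hence more
recombination, which makes the scan conservative there. Window starts sit
on a step grid (default 50 SNPs); terminal partial windows are dropped
rather than shrunk so every H12 is computed on exactly `window_snps`
SNPs. Coordinates are 0-based half-open internally and 1-based inclusive
in reports (BED output is 0-based half-open).

The 1-per-genome FDR cutoff is the k-th highest H12 among simulated
neutral windows, `k = round(n_sim / n_data)`; the recommended design
simulates at least 10× the number of analysis windows (k = 10). A fresh
window exceeds the cutoff with probability ≈ k/(n_sim+1), so a genome of
`n_data` windows yields ≈1 false peak in expectation. Null windows are
drawn one per simulated replicate (the central 401 SNPs), so they are
independent. Peaks are maximal runs of consecutive above-cutoff windows
within a chromosome, represented by their maximum-H12 window; note that
raising the cutoff can split a run, so peak *counts* are not monotone in
the cutoff even though the set of above-cutoff windows is.

Low-recombination masking (< 5×10⁻⁷ cM/bp by default) happens strictly
after peak calling — masking first would hide genuinely swept regions
while failing to remove homozygosity generated by low recombination
elsewhere. The default masks on the rate at the representative window's
bp midpoint; an "overlap" mode masks on any overlap of that window with a
below-threshold interval.

## Demographic models

Models hold diploid sizes and times in generations everywhere;
simulator-scaled units appear only at the simulation boundary. This is a
deliberate guard against the class of bug the convention switch
documents: `scale_for_simulator(model, "harris")` divides *founding*
sizes by 4·Ne_anc while present-day sizes are divided by Ne_anc,
reproducing a published implementation whose founding bottlenecks came
out exactly 4-fold smaller than inferred; `"standard"` divides everything
by Ne_anc.

Only the two constant-size models (A: Ne = 10⁶; B: Ne = 2.7×10⁶, the
value fit to autosomal short-intron Watterson's θ) have fully published
parameters and build without configuration. The bottleneck and admixture
entries (C–K) require a user config, because their parameters come from
posterior distributions published elsewhere; the admixture topology
builder (Africa ancestral, Europe splitting off, North America founded by
admixture) accepts those parameters directly. Variant grids reproduce the
printed axes: 5 European × 5 North American fixed sizes (25 models),
2×3 European growth trajectories crossed with 2×3 North American ones
(36 models), and user-chosen admixture-proportion ([0, 0.9]) and
migration ([0, 0.75]) grids. Posterior-CI variants draw each parameter
independently (no joint posterior is available), seeded.

## Simulation

**Neutral.** Neutral replicates come from the exact coalescent (msprime)
under the model converted to an `msprime.Demography`, with a binary
mutation model on a discrete genome; sites monomorphic in the sample are
dropped. Defaults follow the study conditions: samples of n = 145
chromosomes, μ = 10⁻⁹ /bp/gen, ρ = 5×10⁻⁷ cM/bp (= 5×10⁻⁹ crossovers/
bp/gen), 100 kb chromosomes for neutral runs and 350 kb for selection
runs; statistics use the central 401-SNP window of each replicate. Mean
S/bp and Pi/bp match `θ·a_{n−1}` and `θ` within 5% in the tests.

**Selection.** Sweeps run in a forward Wright–Fisher diploid engine:
multinomial reproduction weighted by fitness, Poisson crossovers uniform
in the segment, infinite-sites neutral mutation (collisions redrawn), and
recurrent adaptive mutation at one site at per-gamete rate
θ_A/(4·Ne_ref). Fitness is co-dominant: 1, 1 + 0.5·s, 1 + s for 0/1/2
copies, so a homozygote has twice a heterozygote's advantage. The
starting population is a coalescent equilibrium sample of 2N haplotypes,
avoiding forward burn-in; generations before the first adaptive origin
are skipped by sampling the geometric waiting time directly, which is
distribution-preserving because a stationary neutral population is
invariant under further neutral generations. Replicates are conditioned
on the adaptive allele being present at sampling (or on reaching the
partial-frequency stop), redrawing up to 1,000 times with the retry count
reported.

**Rescaling.** `rescale_q = Q` maps Ne → Ne/Q, μ → μ·Q, r → r·Q,
s → s·Q and times t → t/Q, preserving θ = 4Neμ, ρ = 4Ner, 4Nes and —
importantly for window statistics — the bp extent of the sweep footprint
`s/[ln(Ne·s)·r]`. Two caveats, stated because they bound what rescaled
runs can show: (i) fitness weights remain valid for s·Q > 1, but discrete
generations floor the sweep duration, inflating per-sweep recombination
and mutation relative to the exact rescaling once s·Q ≫ 1; (ii) when
sweeps complete within a couple of generations, secondary adaptive
origins have no time to expand and the soft regime degenerates into the
hard one. Test- and acceptance-scale runs therefore use Q = 2700 against
the constant 2.7×10⁶ model (N = 1000 diploids) with s = 0.005
(s·Q = 13.5) and 30 kb chromosomes: large enough that hard sweeps show a
single origin and near-zero H2/H1 while the soft regime (θ_A = 10)
accumulates ~10–25 origins and clearly higher H2/H1, and small enough
that the ordering suite runs in about a minute. These sizes are the
package's own scaling choice; the full-scale defaults remain the study
conditions above.

**ms format.** The classic dialect (`//` separators, `segsites:`,
`positions:` fractions, 0/1 rows) round-trips exactly up to float
formatting. Fractional positions convert to strictly increasing integer
bp by rounding against the segment length and bumping collisions upward
by 1 bp.

**Fixtures.** Planted fixtures emulate sweep spectra without simulation:
a hard fixture plants `round(f·n)` copies of one haplotype on an i.i.d.
random background, a soft fixture splits that mass over k classes
(nearest-integer partition), and a neutral fixture is i.i.d. rows (all
unique with overwhelming probability for `L ≫ log₂ n`). They are the
substrate for scan-recovery and classifier-validation tests; they
reproduce the *geometry* of sweep haplotype spectra but none of the
linkage structure, physical footprint decay or frequency-spectrum
distortions of real sweeps — tests passing on fixtures validate the
statistics and decision machinery, not sweep detectability in real data.

## Diversity and LD diagnostics

Pi/bp sums `2p(1−p)·n/(n−1)` over sites (p among non-missing calls);
S/bp counts segregating sites, optionally projected to a smaller sample
size m by adding each site's hypergeometric probability of remaining
polymorphic in a draw of m — the standard device for missing data
(projection to 130 of 145 chromosomes in the original analysis). Sites
with fewer than m calls are dropped and logged. r² uses the classic
`(p_AB − p_A p_B)² / [p_A(1−p_A)p_B(1−p_B)]` on pairwise-complete
haplotypes; singleton sites are excluded by default (degenerate r²), and
sites with > 20% missing calls are excluded (configurable; simulated data
are complete). LD decay bins pairs geometrically from 10 bp to 20 kb;
the short-range summary averages pairs ≤ 1 kb and the long-range summary
pairs in 8–12 kb. Empty bins report a zero count and an undefined (NaN)
mean, never zero. QQ comparisons take quantiles at midpoint probabilities
`(i−0.5)/n` with linear (type-7) interpolation — stated because RMSE
values depend on the convention — and report the RMSE of the matched
quantiles.

## Gaussian bulk fit

Genome-wide H12 distributions in data show a roughly Gaussian bulk and an
elevated tail; sweeps live in the tail. The fit centres at the median and
estimates the bulk SD as half the spread between the ±1σ percentile
points of the data (mass Φ(1)−Φ(0) = 0.341345 on each side of the
median — the exact value behind the rounded "34.1%"). This percentile
half-width equals σ exactly for a Gaussian and is untouched by arbitrary
corruption of the top and bottom 10% of values. The alternative — the SD
of the values inside that range, corrected by the 0.5388 truncation
factor — is available behind a flag. Peak z-scores are
`(value − centre)/sd`, with a configurable highlight threshold (default
11 SD). The tail report compares the within-±1SD values against a seeded
Gaussian sample (analytic quantiles optional) and the full distribution
against the same Gaussian, and reports the fractions within 1 and 2 SD
and counts beyond given z thresholds. Trimming to ±1SD happens after
estimating the SD. A degenerate (all-identical) input yields sd = 0 with
an explicit flag; z-scores then refuse to compute rather than divide by
zero.

## Bayes-factor classification

Reference sets are sweep simulations at θ_A = 0.01 (hard) and θ_A = 10
(soft) with nuisance parameters drawn from uniform priors — selection
coefficient and partial frequency on (0, 1), sweep onset on [0, time of
admixture] (models without admixture need an explicit bound). Each
replicate contributes its central-window (H12, H2/H1). The BF for an
observation is the ratio of soft to hard reference points within
Euclidean distance ε of it; ε defaults to 0.1, read as an absolute radius
in the unit square since both axes live in [0, 1]. Zero-count
denominators produce explicit infinite/undefined markers — never a silent
0/0; a ±1 pseudo-count mode exists for rendering BF surfaces only.
Labels: soft if BF > threshold, hard if BF < 1/threshold (threshold
default 1, exposed because the original analyses did not print one),
undetermined otherwise. Classification presumes the caller has already
conditioned on high H12 via the scan cutoff; H2/H1 alone is
uninformative (an all-unique neutral window has H2/H1 ≈ 1). At rescaled
test scale the s prior must be narrowed (e.g. U(0, 0.005) at Q = 2700)
so the rescaled coefficient stays in the regime where hard and soft
dynamics differ; with the default U(0, 1) prior at full scale no such
restriction applies.

## Numerical and design notes

- All randomness derives from one root seed through labelled
  `SeedSequence` streams (`seeds.derive_seed`), so adding replicates never
  perturbs earlier ones and every CLI run is reproducible from its
  manifest.
- The FDR calibration test accounts for the shared-cutoff error term: the
  cutoff is a Beta(10, 10W−9) order statistic estimated once, giving the
  genome-wise mean false-peak count an irreducible SD of ≈ √10/10 ≈ 0.32
  regardless of the window count W, on top of between-genome noise.
- Calibration and closed-form tests use 12 kb replicate chromosomes
  (≈ 720 SNPs, comfortably above the 401-SNP window) rather than 100 kb;
  the calibration is an order-statistics property independent of window
  bp span.
- `central_window` clips at the matrix edges and raises with the SNP
  deficit when fewer than `window_snps` sites exist, so callers can
  resimulate with a longer chromosome.

## Known limitations

- The forward engine models a single panmictic population during the
  selection episode (the sampled population at its current size); the
  admixture history enters through the coalescent background. Sweeps
  spanning admixture events are not modelled.
- No background selection, linked selection, fluctuating selection, or
  X-chromosome scaling.
- G12/G2/G1, the unphased multilocus-genotype analogs, are out of scope;
  inputs must be phased.
- Real-data results (peak identities, known pesticide-resistance loci,
  data-side SD counts) require the original genome panel and are
  reproduced here as procedures validated on synthetic inputs only.
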