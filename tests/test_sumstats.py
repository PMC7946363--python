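"""Diversity statistics, projection, LD, and QQ diagnostics."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from hapsweep.hapstats import MISSING, HaplotypeMatrix
from hapsweep.simulate import SimulationConfig, simulate_neutral
from hapsweep.sumstats import (
    FragmentSet,
    ld_decay,
    pi_per_bp,
    qq_rmse,
    r2,
    r2_pairs,
    s_per_bp,
    site_projection_weight,
)

from conftest import random_matrix


def matrix(alleles, positions=None):
    alleles = np.asarray(alleles, dtype=np.int8)
    if positions is None:
        positions = np.arange(1, alleles.shape[1] + 1)
    return HaplotypeMatrix(alleles=alleles, positions=np.asarray(positions))


def brute_force_pi(m, length):
    """Oracle: mean pairwise differences over all haplotype pairs."""
    n = m.n_haplotypes
    total = 0.0
    for j in range(m.n_sites):
        col = m.alleles[:, j]
        obs = col[col != MISSING]
        k = obs.size
        if k < 2:
            continue
        d = int(obs.sum())
        total += d * (k - d) / (k * (k - 1) / 2)
    return total / length


class TestPi:
    def test_single_site_worked_example(self):
        m = matrix([[0], [0], [1], [1]])
        assert pi_per_bp(m, 1) == pytest.approx(2 * 0.25 * 4 / 3)

    def test_monomorphic_fragment_is_zero(self):
        m = matrix([[0, 0], [0, 0], [0, 0]])
        assert pi_per_bp(m, 100) == 0.0

    def test_brute_force_oracle_on_random_matrices(self, rng):
        for _ in range(1000):
            m = random_matrix(rng, missing_frac=float(rng.random() * 0.3))
            assert pi_per_bp(m, 50) == pytest.approx(
                brute_force_pi(m, 50), abs=1e-12
            )

    def test_bad_length_rejected(self):
        with pytest.raises(ValueError):
            pi_per_bp(matrix([[0], [1]]), 0)


def brute_force_projection(n_derived, n_ancestral, m):
    """Oracle: enumerate hypergeometric draws explicitly."""
    n = n_derived + n_ancestral
    p_poly = 0.0
    for k in range(0, m + 1):
        prob = (
            math.comb(n_derived, k) * math.comb(n_ancestral, m - k)
            / math.comb(n, m)
            if k <= n_derived and m - k <= n_ancestral
            else 0.0
        )
        if 0 < k < m:
            p_poly += prob
    return p_poly


class TestSPerBp:
    def test_raw_counts(self, rng):
        for _ in range(200):
            m = random_matrix(rng)
            counts = m.alleles.sum(axis=0)
            expected = int(np.sum((counts > 0) & (counts < m.n_haplotypes)))
            assert s_per_bp(m, 10) == pytest.approx(expected / 10)

    def test_singleton_projection_worked_example(self):
        # derived 1 / ancestral 144, projected to 130 of 145 chromosomes
        w = site_projection_weight(1, 144, 130)
        assert w == pytest.approx(1 - math.comb(144, 130) / math.comb(145, 130))
        assert w == pytest.approx(130 / 145)
        assert w == pytest.approx(0.8966, abs=5e-5)

    @pytest.mark.parametrize("d,a,m", [(1, 9, 5), (3, 7, 6), (5, 5, 4), (2, 20, 10)])
    def test_projection_against_enumeration_oracle(self, d, a, m):
        assert site_projection_weight(d, a, m) == pytest.approx(
            brute_force_projection(d, a, m), abs=1e-12
        )

    def test_projection_is_expectation_of_random_subsampling(self, rng):
        d, a, m = 4, 16, 8
        col = np.array([1] * d + [0] * a)
        hits = 0
        n_draws = 10_000
        for _ in range(n_draws):
            sub = rng.choice(col, size=m, replace=False)
            hits += 0 < sub.sum() < m
        mc = hits / n_draws
        se = math.sqrt(mc * (1 - mc) / n_draws)
        assert site_projection_weight(d, a, m) == pytest.approx(mc, abs=4 * se)

    def test_projection_to_n_is_identity(self, rng):
        m = random_matrix(rng, n=12)
        assert s_per_bp(m, 25, project_to=12) == pytest.approx(s_per_bp(m, 25))

    def test_monomorphic_site_contributes_zero(self):
        m = matrix([[0, 1], [0, 0], [0, 1]])
        assert s_per_bp(m, 1, project_to=2) == pytest.approx(
            site_projection_weight(2, 1, 2)
        )


class TestR2:
    def test_perfectly_linked_pair(self):
        a = np.array([0, 0, 1, 1], dtype=np.int8)
        assert r2(a, a) == pytest.approx(1.0)

    def test_exactly_balanced_independent_pair(self):
        a = np.array([0, 0, 1, 1], dtype=np.int8)
        b = np.array([0, 1, 0, 1], dtype=np.int8)
        assert r2(a, b) == pytest.approx(0.0)

    def test_four_haplotype_worked_example(self):
        a = np.array([0, 0, 1, 1], dtype=np.int8)
        b = np.array([0, 1, 1, 1], dtype=np.int8)
        assert r2(a, b) == pytest.approx(1 / 3)

    def test_invariant_to_allele_label_swap_and_reordering(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 20))
            a = rng.integers(0, 2, n).astype(np.int8)
            b = rng.integers(0, 2, n).astype(np.int8)
            if len(set(a)) < 2 or len(set(b)) < 2:
                continue
            base = r2(a, b)
            assert r2(1 - a, b) == pytest.approx(base, abs=1e-12)
            assert r2(a, 1 - b) == pytest.approx(base, abs=1e-12)
            perm = rng.permutation(n)
            assert r2(a[perm], b[perm]) == pytest.approx(base, abs=1e-12)

    def test_r2_pairs_excludes_singletons_by_default(self):
        alleles = np.zeros((6, 4), dtype=np.int8)
        alleles[0, 0] = 1  # singleton site
        alleles[:3, 1] = 1
        alleles[:3, 2] = 1
        alleles[2:5, 3] = 1
        m = matrix(alleles, positions=[10, 20, 30, 40])
        vals = r2_pairs(m, n_pairs=50, seed=1)
        assert vals.size > 0
        # the singleton column can never enter a pair: all values reproducible
        # from the three eligible columns
        eligible = {
            round(r2(m.alleles[:, i], m.alleles[:, j]), 10)
            for i, j in itertools.combinations([1, 2, 3], 2)
        }
        assert {round(v, 10) for v in vals} <= eligible

    def test_no_eligible_pairs_warns_and_returns_empty(self):
        alleles = np.zeros((4, 2), dtype=np.int8)
        alleles[0, 0] = 1
        alleles[1, 1] = 1
        m = matrix(alleles)
        with pytest.warns(UserWarning):
            vals = r2_pairs(m, n_pairs=10, seed=1)
        assert vals.size == 0


@pytest.fixture(scope="module")
def neutral_reps(model_b):
    cfg = SimulationConfig(seq_length=20_000, seed=123)
    return list(simulate_neutral(model_b, cfg, 25))


class TestLDDecay:
    def test_mean_r2_decays_with_distance(self, neutral_reps):
        bins = np.geomspace(10, 2e4, 21)
        curve = ld_decay(neutral_reps, bins, n_pairs=40_000, seed=4)
        ok = curve.pair_counts > 50
        assert ok.sum() >= 10
        mids = np.sqrt(curve.bin_edges[:-1] * curve.bin_edges[1:])[ok]
        rho = sps.spearmanr(mids, curve.mean_r2[ok]).statistic
        assert rho < 0

    def test_single_bin_gives_overall_mean(self, neutral_reps):
        m = neutral_reps[0]
        curve = ld_decay(m, np.array([0.0, 3e4]), n_pairs=2_000, seed=5)
        assert curve.pair_counts[0] > 0
        assert 0 <= curve.mean_r2[0] <= 1

    def test_zero_recombination_shows_no_decay(self, model_b):
        cfg = SimulationConfig(seq_length=20_000, rho_cM_per_bp=0.0, seed=9)
        reps = list(simulate_neutral(model_b, cfg, 12))
        curve = ld_decay(reps, np.array([10.0, 1e3, 8e3, 1.2e4, 2e4]),
                         n_pairs=30_000, seed=6)
        short, long_ = curve.short_range_mean(), curve.long_range_mean()
        assert abs(short - long_) < 0.12

    def test_empty_bin_recorded_with_zero_count_and_nan_mean(self):
        alleles = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.int8)
        m = matrix(alleles, positions=[10, 20])
        curve = ld_decay(m, np.array([0.0, 5.0, 50.0]), n_pairs=100, seed=7)
        assert curve.pair_counts[0] == 0
        assert math.isnan(curve.mean_r2[0])


class TestQQRmse:
    def test_identical_samples_zero_rmse(self, rng):
        x = rng.normal(size=5_000)
        assert qq_rmse(x, x).rmse == pytest.approx(0.0, abs=1e-14)

    def test_constant_shift_recovers_shift(self, rng):
        x = rng.normal(size=5_000)
        assert qq_rmse(x, x + 0.1).rmse == pytest.approx(0.1, abs=1e-12)

    def test_two_seeded_normal_samples_converge(self):
        r1 = np.random.default_rng(1).normal(size=100_000)
        r2_ = np.random.default_rng(2).normal(size=100_000)
        assert qq_rmse(r1, r2_).rmse < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            qq_rmse([], [1.0])


def test_fragment_set_rejects_short_fragments():
    m = matrix([[0, 1], [1, 0]])
    with pytest.raises(ValueError):
        FragmentSet(fragments=((m, 9),))
    fs = FragmentSet(fragments=((m, 10),))
    assert fs.pi_values().shape == (1,)
    assert fs.s_values(project_to=2).shape == (1,)
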