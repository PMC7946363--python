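"""Haplotype spectrum construction and homozygosity statistics."""

import numpy as np
import pytest

from hapsweep.hapstats import (
    MISSING,
    HaplotypeMatrix,
    HaplotypeSpectrum,
    h1,
    h2,
    h2h1,
    h12,
    spectrum_from_window,
    sweep_footprint_bp,
    window_stats,
)

from conftest import random_matrix


def brute_force_spectrum(matrix, start, stop):
    """Independent oracle: group haplotype strings with a dict."""
    counts = {}
    for row in matrix.alleles[:, start:stop]:
        key = tuple(int(a) for a in row)
        counts[key] = counts.get(key, 0) + 1
    n = matrix.n_haplotypes
    freqs = sorted((c / n for c in counts.values()), reverse=True)
    return freqs


def matrix_from_groups(group_sizes, l_sites=6):
    """n haplotypes forming classes of the given sizes, distinct strings."""
    rows = []
    for gi, size in enumerate(group_sizes):
        template = [(gi >> b) & 1 for b in range(l_sites)]
        rows.extend([template] * size)
    alleles = np.array(rows, dtype=np.int8)
    positions = np.arange(1, l_sites + 1, dtype=np.int64)
    return HaplotypeMatrix(alleles=alleles, positions=positions)


SPEC_4321 = HaplotypeSpectrum((0.4, 0.3, 0.2, 0.1), (4, 3, 2, 1), 10)
SPEC_MONO = HaplotypeSpectrum((1.0,), (5,), 5)
SPEC_145 = HaplotypeSpectrum(
    tuple([1 / 145] * 145), tuple([1] * 145), 145
)


@pytest.mark.parametrize(
    "spec,expected",
    [
        (SPEC_4321, {"h1": 0.30, "h12": 0.54, "h2": 0.14, "h2h1": 0.14 / 0.30}),
        (SPEC_MONO, {"h1": 1.0, "h12": 1.0, "h2": 0.0, "h2h1": 0.0}),
        (
            SPEC_145,
            {
                "h1": 1 / 145,
                "h12": 147 / 21025,
                "h2": 144 / 145**2,
                "h2h1": 144 / 145,
            },
        ),
        (
            HaplotypeSpectrum((0.5, 0.5), (2, 2), 4),
            {"h1": 0.5, "h12": 1.0, "h2": 0.25, "h2h1": 0.5},
        ),
    ],
)
def test_statistics_on_known_spectra(spec, expected):
    assert h1(spec) == pytest.approx(expected["h1"], abs=1e-12)
    assert h12(spec) == pytest.approx(expected["h12"], abs=1e-12)
    assert h2(spec) == pytest.approx(expected["h2"], abs=1e-12)
    assert h2h1(spec) == pytest.approx(expected["h2h1"], abs=1e-12)


def test_spectrum_from_grouped_matrix():
    m = matrix_from_groups([4, 3, 2, 1])
    spec = spectrum_from_window(m)
    assert spec.frequencies == (0.4, 0.3, 0.2, 0.1)
    assert spec.counts == (4, 3, 2, 1)


def test_identical_haplotypes_give_single_entry():
    m = matrix_from_groups([7])
    spec = spectrum_from_window(m)
    assert spec.frequencies == (1.0,)
    assert h12(spec) == h1(spec) == 1.0


def test_all_distinct_145_haplotypes():
    # 145 pairwise-distinct strings: binary encoding over 8+ sites
    rows = [[(i >> b) & 1 for b in range(9)] for i in range(145)]
    m = HaplotypeMatrix(
        alleles=np.array(rows, dtype=np.int8),
        positions=np.arange(1, 10, dtype=np.int64),
    )
    spec = spectrum_from_window(m)
    assert len(spec.frequencies) == 145
    assert all(f == 1 / 145 for f in spec.frequencies)
    assert h2h1(spec) == pytest.approx(144 / 145, abs=1e-12)


def test_brute_force_oracle_on_random_matrices(rng):
    """Exact agreement with string grouping + direct summation, 1000 draws."""
    for _ in range(1000):
        m = random_matrix(rng)
        start = int(rng.integers(0, m.n_sites))
        stop = int(rng.integers(start + 1, m.n_sites + 1))
        spec = spectrum_from_window(m, (start, stop))
        freqs = brute_force_spectrum(m, start, stop)
        assert np.allclose(spec.frequencies, freqs, atol=1e-12)
        assert h1(spec) == pytest.approx(sum(f * f for f in freqs), abs=1e-12)
        assert h2(spec) == pytest.approx(sum(f * f for f in freqs[1:]), abs=1e-12)
        p2 = freqs[1] if len(freqs) > 1 else 0.0
        assert h12(spec) == pytest.approx(
            (freqs[0] + p2) ** 2 + sum(f * f for f in freqs[2:]), abs=1e-12
        )


def test_statistic_identities_and_ordering(rng):
    """h2 <= h1 <= h12 <= 1; h12 - h1 = 2 p1 p2; h2 = h1 - p1^2; h2h1 < 1."""
    for _ in range(300):
        m = random_matrix(rng)
        spec = spectrum_from_window(m)
        v1, v2, v12 = h1(spec), h2(spec), h12(spec)
        assert v2 <= v1 <= v12 <= 1.0 + 1e-12
        assert v12 - v1 == pytest.approx(2 * spec.p1 * spec.p2, abs=1e-12)
        assert v2 == pytest.approx(v1 - spec.p1**2, abs=1e-12)
        assert h2h1(spec) < 1.0


def test_permutation_invariance(rng):
    for _ in range(50):
        m = random_matrix(rng, n=12, l_sites=8)
        spec = spectrum_from_window(m)
        perm_rows = HaplotypeMatrix(
            alleles=m.alleles[rng.permutation(12)], positions=m.positions
        )
        # site permutation must preserve position order; relabel positions
        cols = rng.permutation(8)
        perm_cols = HaplotypeMatrix(
            alleles=m.alleles[:, cols], positions=np.arange(1, 9, dtype=np.int64)
        )
        for other in (perm_rows, perm_cols):
            other_spec = spectrum_from_window(other)
            assert h1(other_spec) == pytest.approx(h1(spec), abs=1e-12)
            assert h12(other_spec) == pytest.approx(h12(spec), abs=1e-12)
            assert h2(other_spec) == pytest.approx(h2(spec), abs=1e-12)


def test_merging_top_two_classes_turns_h12_into_h1(rng):
    """h1 of the spectrum with the top two classes pooled equals h12."""
    for _ in range(100):
        m = random_matrix(rng)
        spec = spectrum_from_window(m)
        merged = sorted(
            [spec.p1 + spec.p2] + list(spec.frequencies[2:]), reverse=True
        )
        assert sum(f * f for f in merged) == pytest.approx(h12(spec), abs=1e-12)


def test_tie_break_is_deterministic():
    m = matrix_from_groups([2, 2, 2])
    s1 = spectrum_from_window(m)
    s2 = spectrum_from_window(m)
    assert s1 == s2
    assert s1.counts == (2, 2, 2)


class TestMissingData:
    def test_missing_is_distinct_state_by_default(self):
        alleles = np.array([[0, 1], [0, MISSING], [0, 1]], dtype=np.int8)
        m = HaplotypeMatrix(alleles=alleles, positions=np.array([1, 2]))
        spec = spectrum_from_window(m)
        assert spec.counts == (2, 1)

    def test_match_on_observed_joins_unique_completion(self):
        alleles = np.array([[0, 1], [0, MISSING], [0, 1]], dtype=np.int8)
        m = HaplotypeMatrix(alleles=alleles, positions=np.array([1, 2]))
        spec = spectrum_from_window(m, match_on_observed=True)
        assert spec.counts == (3,)

    def test_match_on_observed_ambiguous_stays_singleton(self):
        alleles = np.array(
            [[0, 1], [1, 1], [MISSING, 1]], dtype=np.int8
        )  # matches both complete classes
        m = HaplotypeMatrix(alleles=alleles, positions=np.array([1, 2]))
        spec = spectrum_from_window(m, match_on_observed=True)
        assert spec.counts == (1, 1, 1)

    def test_all_missing_haplotype_is_an_error_naming_the_sample(self):
        alleles = np.array([[0, 1], [MISSING, MISSING]], dtype=np.int8)
        m = HaplotypeMatrix(
            alleles=alleles, positions=np.array([1, 2]),
            sample_ids=("ok", "bad"),
        )
        with pytest.raises(ValueError, match="bad"):
            spectrum_from_window(m)


def test_empty_range_rejected():
    m = matrix_from_groups([2, 2])
    with pytest.raises(ValueError):
        spectrum_from_window(m, (3, 3))


def test_matrix_invariants_enforced():
    with pytest.raises(ValueError):
        HaplotypeMatrix(
            alleles=np.zeros((2, 2), dtype=np.int8),
            positions=np.array([5, 5]),  # not strictly increasing
        )
    with pytest.raises(ValueError):
        HaplotypeMatrix(
            alleles=np.full((2, 1), 7, dtype=np.int8), positions=np.array([1])
        )
    with pytest.raises(ValueError):
        HaplotypeMatrix(
            alleles=np.zeros((1, 1), dtype=np.int8), positions=np.array([1])
        )


def test_window_stats_carries_coordinates():
    m = matrix_from_groups([3, 2], l_sites=6)
    w = window_stats(m, (0, 4))
    assert (w.snp_start, w.snp_stop) == (0, 4)
    assert (w.bp_start, w.bp_stop) == (1, 4)
    assert w.n_distinct == 2


try:
    from hypothesis import given, settings, strategies as st

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        counts=st.lists(st.integers(min_value=1, max_value=30), min_size=1,
                        max_size=15)
    )
    def test_spectrum_invariants_hold_for_any_class_sizes(counts):
        """For any haplotype class-size composition: frequency ordering,
        unit mass, and the h2 <= h1 <= h12 chain with exact identities."""
        n = sum(counts)
        ordered = sorted(counts, reverse=True)
        spec = HaplotypeSpectrum(
            frequencies=tuple(c / n for c in ordered),
            counts=tuple(ordered),
            n=n,
        )
        assert abs(sum(spec.frequencies) - 1.0) < 1e-9
        v1, v2, v12 = h1(spec), h2(spec), h12(spec)
        assert v2 <= v1 <= v12 <= 1.0 + 1e-12
        assert abs(v12 - v1 - 2 * spec.p1 * spec.p2) < 1e-12
        assert abs(v2 - (v1 - spec.p1**2)) < 1e-12
        assert h2h1(spec) < 1.0

except ImportError:  # pragma: no cover - hypothesis is a test extra
    pass


def test_sweep_footprint_formula():
    # s = 0.05%, Ne = 1e6, rho = 5e-7 cM/bp = 5e-9 crossovers/bp/gen
    bp = sweep_footprint_bp(5e-4, 1e6, 5e-9)
    assert bp == pytest.approx(5e-4 / (np.log(500.0) * 5e-9))
    assert bp >= 10_000  # spans a 10 kb window
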