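"""Windowed diversity statistics against brute-force oracles."""

import numpy as np
import pytest

from peachpop.diversity import (
    fst_components,
    rod_track,
    site_diversity,
    tajima_constants,
    tajimas_d,
    windowed_fst,
    windowed_pi,
    windowed_tajimas_d,
)
from peachpop.genio import WindowSpec, make_windows
from .conftest import make_matrix, random_matrix


# ---------------------------------------------------------------- oracles
def brute_force_pi_sum(hap_counts):
    """Mean pairwise difference summed over sites, by explicit pair enumeration.

    ``hap_counts`` is a list of (alt_count, called_alleles).
    """
    total = 0.0
    for a, n in hap_counts:
        if n < 2:
            continue
        diffs = a * (n - a)  # unordered mixed pairs differ
        pairs = n * (n - 1) / 2
        total += diffs / pairs
    return total


def oracle_tajimas_d(pi_sum, s, n):
    """Independent textbook implementation of the D normalization."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi_sum - s / a1) / np.sqrt(e1 * s + e2 * s * (s - 1))


def oracle_fst_site(a1, n1, h1, a2, n2, h2):
    """Literal scalar transcription of the two-population variance components."""
    m1, m2 = n1 / 2, n2 / 2
    p1, p2 = a1 / n1, a2 / n2
    r = 2
    nbar = (m1 + m2) / r
    nc = (r * nbar - (m1**2 + m2**2) / (r * nbar)) / (r - 1)
    pbar = (m1 * p1 + m2 * p2) / (r * nbar)
    s2 = (m1 * (p1 - pbar) ** 2 + m2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (h1 + h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2
    return a, b, c


# ---------------------------------------------------------------- site pi
class TestSiteDiversity:
    @pytest.mark.parametrize("a,n,expected", [(0, 8, 0.0), (2, 4, 2 / 3), (4, 4, 0.0)])
    def test_examples(self, a, n, expected):
        assert site_diversity([a], [n])[0] == pytest.approx(expected)

    def test_matches_pair_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(2, 40))
            a = int(rng.integers(0, n + 1))
            assert site_diversity([a], [n])[0] == pytest.approx(
                brute_force_pi_sum([(a, n)]), abs=1e-12
            )


class TestWindowedPi:
    def test_single_site_per_bp(self):
        # one site with pi = 0.5 in a 100 kb window -> 5e-6 per bp
        geno = np.array([[0], [1]], dtype=np.int8)  # a=1, n=4 -> 2*1*3/(4*3) = 0.5
        g = make_matrix(geno, positions=[5000], chrom_len=100_000)
        track = windowed_pi(g, g.samples, [WindowSpec("chr1", 0, 100_000)])
        assert track.value[0] == pytest.approx(5.0e-6)

    def test_monomorphic_window_is_zero(self):
        g = make_matrix(np.zeros((4, 6), dtype=np.int8), chrom_len=1000)
        track = windowed_pi(g, g.samples, [WindowSpec("chr1", 0, 1000)])
        assert track.value[0] == 0.0
        assert track.n_sites[0] == 0

    def test_matches_bruteforce_on_random_windows(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            g = random_matrix(rng, n_samples=int(rng.integers(3, 10)), n_sites=20,
                              missing_rate=0.15, chrom_len=2000)
            track = windowed_pi(g, g.samples, [WindowSpec("chr1", 0, 2000)])
            alt, n = g.allele_counts()
            expected = brute_force_pi_sum(list(zip(alt, n))) / 2000
            assert track.value[0] == pytest.approx(expected, abs=1e-12)


class TestTajimasD:
    def test_zero_segregating_sites_masked(self):
        g = make_matrix(np.zeros((5, 4), dtype=np.int8), chrom_len=1000)
        track = windowed_tajimas_d(g, g.samples, [WindowSpec("chr1", 0, 1000)])
        assert not track.mask[0]
        assert np.isnan(track.value[0])

    def test_matches_textbook_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n_dip = int(rng.integers(3, 12))
            g = random_matrix(rng, n_samples=n_dip, n_sites=8, chrom_len=500)
            track = windowed_tajimas_d(g, g.samples, [WindowSpec("chr1", 0, 500)])
            alt, n = g.allele_counts()
            seg = (alt > 0) & (alt < n)
            s = int(seg.sum())
            if s == 0:
                assert not track.mask[0]
                continue
            pi_sum = brute_force_pi_sum([(a, m) for a, m in zip(alt[seg], n[seg])])
            expected = oracle_tajimas_d(pi_sum, s, 2 * n_dip)
            assert track.value[0] == pytest.approx(expected, abs=1e-10)

    def test_constants_reject_tiny_samples(self):
        with pytest.raises(ValueError):
            tajima_constants(3)
        assert np.isnan(tajimas_d(0.0, 0, 10))


class TestFst:
    def test_fixed_difference_is_one(self):
        a, b, c, ok = fst_components([10], [10], [0], [0], [10], [0])
        assert ok[0]
        assert a[0] / (a[0] + b[0] + c[0]) == pytest.approx(1.0)

    def test_identical_counts_nonpositive(self):
        # identical allele and heterozygote counts in both groups
        a, b, c, ok = fst_components([4], [20], [4], [4], [20], [4])
        assert a[0] / (a[0] + b[0] + c[0]) <= 0.0

    def test_components_match_scalar_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            n1, n2 = 2 * rng.integers(2, 15, size=2)
            a1 = int(rng.integers(0, n1 + 1))
            a2 = int(rng.integers(0, n2 + 1))
            h1 = int(rng.integers(0, min(a1, n1 - a1) + 1))
            h2 = int(rng.integers(0, min(a2, n2 - a2) + 1))
            got = fst_components([a1], [n1], [h1], [a2], [n2], [h2])
            exp = oracle_fst_site(a1, n1, h1, a2, n2, h2)
            for comp, ev in zip(got[:3], exp):
                assert comp[0] == pytest.approx(ev, abs=1e-12)

    def test_self_comparison_nonpositive_per_window(self, default_cohort):
        g, popmap, _ = default_cohort
        wild = popmap.samples_in("wild")
        wins = make_windows(g.chrom_lengths)
        track = windowed_fst(g, wild, wild, wins)
        vals = track.value[track.mask]
        assert (vals <= 1e-12).all()


class TestRod:
    def test_printed_ratio(self):
        num = _track([3.5e-3], n_sites=[10])
        den = _track([1.2e-3], n_sites=[10])
        rod = rod_track(num, den)
        assert rod.value[0] == pytest.approx(2.9167, abs=5e-5)
        assert round(rod.value[0], 2) == 2.92

    def test_equal_tracks_are_one(self):
        t = _track([2e-3, 3e-3, 1e-3], n_sites=[5, 5, 5])
        rod = rod_track(t, t)
        assert np.allclose(rod.value[rod.mask], 1.0)

    def test_zero_denominator_masked(self):
        num = _track([1e-3])
        den = _track([0.0])
        rod = rod_track(num, den)
        assert not rod.mask[0]

    def test_min_sites_masking(self):
        num = _track([1e-3], n_sites=[2])
        den = _track([1e-3], n_sites=[10])
        assert not rod_track(num, den, min_sites=3).mask[0]

    def test_window_mismatch_raises(self):
        a = _track([1.0])
        b = _track([1.0, 2.0], starts=[0, 10_000], n_sites=[5, 5])
        with pytest.raises(ValueError):
            rod_track(a, b)


def _track(values, starts=None, n_sites=None):
    from peachpop.diversity import WindowStatTrack

    k = len(values)
    starts = starts or [i * 10_000 for i in range(k)]
    return WindowStatTrack(
        chrom=np.array(["chr1"] * k, dtype=object),
        start=np.array(starts, dtype=np.int64),
        end=np.array(starts, dtype=np.int64) + 100_000,
        value=np.array(values, dtype=float),
        n_sites=np.array(n_sites if n_sites is not None else [10] * k, dtype=np.int64),
        n_samples_effective=np.full(k, 10.0),
        mask=np.ones(k, dtype=bool),
    )
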