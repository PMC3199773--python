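"""Unit and oracle tests for the diversity statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dzscan import sumstats


# ---------------------------------------------------------------------------
# independent brute-force oracles
# ---------------------------------------------------------------------------

def brute_pairwise_pi(seqs):
    """Mean pairwise differences by direct enumeration (complete data)."""
    n = len(seqs)
    tot = 0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            tot += sum(a != b for a, b in zip(seqs[i], seqs[j]))
            pairs += 1
    return tot / pairs


def brute_tajima_d(seqs):
    """Tajima's D computed from first principles on a complete alignment."""
    n = len(seqs)
    L = len(seqs[0])
    S = sum(1 for c in range(L) if len({s[c] for s in seqs}) > 1)
    if S == 0:
        return float("nan")
    piL = brute_pairwise_pi(seqs)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    var = c1 / a1 * S + c2 / (a1**2 + a2) * S * (S - 1)
    return (piL - S / a1) / var**0.5


FIXED_8x100 = None


def _fixed_alignment():
    global FIXED_8x100
    if FIXED_8x100 is None:
        r = np.random.default_rng(424242)
        base = r.integers(0, 4, 100)
        mat = np.tile(base, (8, 1))
        for col in r.choice(100, size=12, replace=False):
            carriers = r.choice(8, size=r.integers(1, 8), replace=False)
            mat[carriers, col] = (mat[carriers, col] + 1) % 4
        FIXED_8x100 = ["".join("ACGT"[b] for b in row) for row in mat]
    return FIXED_8x100


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "n,S,L,expected",
    [(50, 0, 500, 0.0), (2, 5, 100, 0.05), (4, 3, 100, 3 / (11 / 6 * 100))],
)
def test_watterson_theta_values(n, S, L, expected):
    assert sumstats.watterson_theta(n, S, L) == pytest.approx(expected, abs=1e-12)


def test_watterson_theta_undefined_below_two_sequences():
    assert np.isnan(sumstats.watterson_theta(1, 3, 100))


def test_nucleotide_diversity_examples():
    # two sequences differing at 2 of 100 sites
    counts = [{"A": 2}] * 98 + [{"A": 1, "T": 1}] * 2
    assert sumstats.pi_from_allele_counts(counts) == pytest.approx(0.02)
    # monomorphic locus
    assert sumstats.pi_from_allele_counts([{"A": 5}] * 10) == 0.0
    # unbiased per-site factor: n=4, counts (3,1), one site
    assert sumstats.pi_from_allele_counts([[3, 1]]) == pytest.approx(0.5)


def test_tajima_d_zero_numerator_and_na():
    assert np.isnan(sumstats.tajima_d(10, 0, 0.0))
    a1 = sumstats.harmonic(10)
    assert sumstats.tajima_d(10, 5, 5 / a1) == pytest.approx(0.0, abs=1e-12)


def test_tajima_d_matches_brute_force_oracle():
    seqs = _fixed_alignment()
    mat = np.array([[{"A": 0, "C": 1, "G": 2, "T": 3}[b] for b in s] for s in seqs])
    S = sum(1 for c in range(100) if np.unique(mat[:, c]).size > 1)
    piL = brute_pairwise_pi(seqs)
    assert sumstats.tajima_d(8, S, piL) == pytest.approx(brute_tajima_d(seqs), abs=1e-10)


def test_fay_wu_hand_computations():
    # n=4, one site with derived count 3
    th, tl, h = sumstats.fay_wu_from_sfs([0, 0, 1], 4)
    assert th == pytest.approx(1.5)
    assert h == pytest.approx(0.5 - 1.5)
    # n=10, five singletons: theta_H = 5 * 2 / 90, H > 0
    th, tl, h = sumstats.fay_wu_from_sfs([5, 0, 0, 0, 0, 0, 0, 0, 0], 10)
    assert th == pytest.approx(5 * 2 / 90)
    assert h > 0
    # S=0 -> Z undefined
    assert np.isnan(sumstats.fay_wu_z(np.zeros(9), 10))


@given(
    xi=st.lists(st.integers(min_value=0, max_value=30), min_size=9, max_size=9),
)
@settings(deadline=None, max_examples=50, derandomize=True)
def test_fay_wu_identity_pi_thetaH_thetaL(xi):
    """pi*L - theta_H == 2 (pi*L - theta_L) for every SFS."""
    n = 10
    piL = sumstats.sfs_pi(xi, n)
    th, tl, h = sumstats.fay_wu_from_sfs(xi, n)
    assert piL - th == pytest.approx(2 * (piL - tl), abs=1e-9)


def test_statistics_invariant_to_sequence_order(rng):
    xi = rng.poisson(2.0, size=19)
    n = 20
    s1 = sumstats.sfs_stats(xi, n)
    # reordering sequences permutes nothing in the SFS; check the matrix path
    mat = rng.integers(0, 2, size=(6, 40))
    perm = rng.permutation(6)
    f1, *_ = sumstats.fst_hudson(mat, np.array([1, 1, 1, 2, 2, 2]))
    f2, *_ = sumstats.fst_hudson(mat[perm], np.array([1, 1, 1, 2, 2, 2])[perm])
    assert f1 == pytest.approx(f2, abs=1e-12)
    assert s1 == sumstats.sfs_stats(xi, n)


def test_maf_bins():
    # n=8: minor count 1 -> MAF 0.125 -> first bin; 4/4 -> last bin
    assert np.allclose(sumstats.maf_bins_from_sfs([1, 0, 0, 0, 0, 0, 0], 8), [1, 0, 0, 0])
    assert np.allclose(sumstats.maf_bins_from_sfs([0, 0, 0, 1, 0, 0, 0], 8), [0, 0, 0, 1])
    # mixed fixture matches exhaustive per-site classification
    n = 16
    rng = np.random.default_rng(5)
    xi = rng.poisson(1.0, size=n - 1)
    bins = sumstats.maf_bins_from_sfs(xi, n)
    brute = np.zeros(4)
    for i, c in zip(range(1, n), xi):
        maf = min(i, n - i) / n
        for b, hi in enumerate([0.125, 0.25, 0.375, 0.5]):
            lo = [0, 0.125, 0.25, 0.375][b]
            if lo < maf <= hi:
                brute[b] += c
    assert np.allclose(bins, brute)
    assert sum(xi) == bins.sum()


def test_maf_bin_frequencies_sum_to_one_or_nan():
    freqs = sumstats.maf_bin_frequencies([0.1, 0.3, 0.5, 0.02])
    assert freqs.sum() == pytest.approx(1.0)
    assert np.all(np.isnan(sumstats.maf_bin_frequencies([])))


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------

def test_fst_hudson_trivials_and_oracle(rng):
    # identical composition -> ~0 (small negative bias of order 1/n allowed:
    # the within-group mean pairwise difference is an unbiased per-group
    # quantity while the between-group mean lacks the n/(n-1) factor)
    half = rng.integers(0, 2, size=(16, 50))
    mat_id = np.vstack([half, half])
    fst_id, *_ = sumstats.fst_hudson(mat_id, np.repeat([1, 2], 16))
    assert abs(fst_id) < 0.1
    groups = np.array([1, 1, 1, 1, 2, 2, 2, 2])
    # fixed difference between monomorphic groups -> 1
    mat2 = np.zeros((8, 10), dtype=int)
    mat2[4:, :] = 1
    fst2, *_ = sumstats.fst_hudson(mat2, groups)
    assert fst2 == pytest.approx(1.0)
    # random 4+4 fixture equals brute-force pairwise computation
    mat3 = rng.integers(0, 4, size=(8, 25))
    fst3, hw3, hb3 = sumstats.fst_hudson(mat3, groups)
    d = lambda i, j: np.sum(mat3[i] != mat3[j])
    within = []
    for g in (range(4), range(4, 8)):
        ds = [d(i, j) for i in g for j in g if i < j]
        within.append(np.mean(ds))
    hw_b = np.mean(within)
    hb_b = np.mean([d(i, j) for i in range(4) for j in range(4, 8)])
    assert hw3 == pytest.approx(hw_b, abs=1e-9)
    assert hb3 == pytest.approx(hb_b, abs=1e-9)
    assert fst3 == pytest.approx(1 - hw_b / hb_b, abs=1e-9)


def test_fst_weir_cockerham_trivials_and_hand_value():
    # equal frequencies in both groups -> ~0 (slightly negative allowed)
    fst, *_ = sumstats.fst_weir_cockerham([0.5, 0.2], [0.5, 0.2], 10, 10)
    assert fst < 0.05
    # fixed difference -> 1
    fst2, *_ = sumstats.fst_weir_cockerham([1.0], [0.0], 10, 12)
    assert fst2 == pytest.approx(1.0)
    # 2-site fixture vs hand-computed variance components (haploid, n1=n2=4)
    p1, p2, n1, n2 = np.array([0.75, 0.25]), np.array([0.25, 0.5]), 4.0, 4.0
    a_sum = ab_sum = 0.0
    for q1, q2 in zip(p1, p2):
        nbar, nc, r = 4.0, 4.0, 2.0
        pbar = (q1 + q2) / 2
        msp = 4 * ((q1 - pbar) ** 2 + (q2 - pbar) ** 2) / (r - 1)
        msg = 4 * (q1 * (1 - q1) + q2 * (1 - q2)) / (8 - 2)
        a_sum += (msp - msg) / nc
        ab_sum += (msp - msg) / nc + msg
    fst3, *_ = sumstats.fst_weir_cockerham(p1, p2, n1, n2)
    assert fst3 == pytest.approx(a_sum / ab_sum, abs=1e-9)


# ---------------------------------------------------------------------------
# Hudson's rho
# ---------------------------------------------------------------------------

def brute_hudson_rho(seqs):
    """Independently coded moment estimator (same published definition)."""
    from scipy import integrate, optimize

    mat = np.asarray(seqs)
    n = mat.shape[0]
    ks = [np.sum(mat[i] != mat[j]) for i in range(n) for j in range(i + 1, n)]
    theta = np.mean(ks)
    sk2 = np.var(ks)
    phi = lambda z: (z + 18) / (z * z + 13 * z + 18)
    gfun = lambda C: 1.0 if C <= 0 else 2 / C**2 * integrate.quad(lambda z: (C - z) * phi(z), 0, C, limit=200)[0]
    excess = (sk2 - theta) / theta**2
    if excess >= 1:
        return 0.0
    if excess <= 0:
        return sumstats.RHO_CAP
    hi = 1.0
    while gfun(hi) > excess:
        hi *= 2
    return optimize.brentq(lambda C: gfun(C) - excess, 1e-8, hi, xtol=1e-10, rtol=1e-12)


def test_hudson_rho_behaviour(rng):
    # perfect linkage (two haplotypes): variance of pairwise differences is
    # at or above the no-recombination expectation -> estimate truncated to 0
    hapA = np.zeros(20, dtype=int)
    hapB = np.ones(20, dtype=int)
    mat = np.array([hapA] * 3 + [hapB] * 7)
    assert sumstats.hudson_rho(mat) == 0.0
    # independent sites -> large estimate
    free = rng.integers(0, 2, size=(20, 60))
    assert sumstats.hudson_rho(free) > 50
    # oracle equivalence on a random fixture
    mat3 = rng.integers(0, 2, size=(10, 30))
    mine = sumstats.hudson_rho(mat3)
    oracle = brute_hudson_rho(mat3)
    assert mine == pytest.approx(oracle, abs=1e-9)
    # degenerate: < 2 segregating sites
    assert np.isnan(sumstats.hudson_rho(np.zeros((5, 10), dtype=int)))
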