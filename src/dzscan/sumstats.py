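"""Per-locus diversity and differentiation statistics.

Implements the classical site-frequency-spectrum summaries used throughout the
package: Watterson's theta, nucleotide diversity pi, Tajima's D, Fay & Wu's H
together with its standardized form (called Z here, following Zeng et al.'s
normalization of the high-frequency-derived-allele test), folded
minor-allele-frequency bin summaries, Hudson's and Weir & Cockerham's F_ST
estimators, and Hudson's (1987) moment estimator of the scaled recombination
rate.

Conventions
-----------
Samples are haploid-coded (inbred accessions).  ``n`` is the number of
sequences, ``L`` the number of analysed sites.  The unfolded site frequency
spectrum ``xi`` is indexed by derived-allele count ``i = 1 .. n-1``; functions
accepting ``xi`` also accept a 2-D array of shape ``(reps, n-1)`` and then
return vectorized results, which is how the coalescent null engine calls them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize

__all__ = [
    "harmonic",
    "harmonic2",
    "tajima_constants",
    "watterson_theta",
    "pi_from_allele_counts",
    "sfs_pi",
    "tajima_d",
    "fay_wu_from_sfs",
    "fay_wu_z",
    "sfs_stats",
    "maf_bin_frequencies",
    "maf_bins_from_sfs",
    "fst_hudson",
    "fst_weir_cockerham",
    "hudson_rho",
    "DiversityStats",
    "MAF_BIN_EDGES",
]

#: Right-closed folded-MAF bin edges; a singleton at n=8 (MAF 0.125) falls in
#: the first bin, MAF exactly 0.5 in the last.
MAF_BIN_EDGES = (0.0, 0.125, 0.25, 0.375, 0.5)


def harmonic(n: int) -> float:
    """a1 = sum_{i=1}^{n-1} 1/i."""
    return float(np.sum(1.0 / np.arange(1, n)))


def harmonic2(n: int) -> float:
    """b1 = sum_{i=1}^{n-1} 1/i^2."""
    return float(np.sum(1.0 / np.arange(1, n, dtype=float) ** 2))


def tajima_constants(n: int) -> dict[str, float]:
    """Tajima's (1989) normalization constants for sample size n."""
    if n < 2:
        raise ValueError("need n >= 2")
    a1 = harmonic(n)
    a2 = harmonic2(n)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return {"a1": a1, "a2": a2, "e1": e1, "e2": e2}


def watterson_theta(n: int, S: float, L: float) -> float:
    """Watterson's estimator S / (a1 * L), per base pair."""
    if n < 2:
        return math.nan
    if L < 1:
        raise ValueError("need L >= 1")
    return S / (harmonic(n) * L)


def pi_from_allele_counts(counts, L: float | None = None) -> float:
    """Nucleotide diversity from per-site allele counts.

    Parameters
    ----------
    counts : sequence of mappings or arrays
        One entry per site giving the counts of each allele observed there
        (e.g. ``{"A": 3, "T": 1}`` or ``[3, 1]``).  Per-site sample sizes may
        differ (missing data); each site uses its own unbiased factor
        n_s/(n_s - 1).
    L : float, optional
        Number of analysed sites to divide by.  Default: number of entries in
        ``counts`` (so monomorphic sites must be included for a per-bp value).
    """
    tot = 0.0
    nsites = 0
    for c in counts:
        vals = np.asarray(list(c.values()) if hasattr(c, "values") else c, dtype=float)
        ns = vals.sum()
        nsites += 1
        if ns < 2:
            continue
        het = 1.0 - np.sum((vals / ns) ** 2)
        tot += ns / (ns - 1.0) * het
    denom = float(L) if L is not None else float(nsites)
    if denom <= 0:
        return math.nan
    return tot / denom


def _as2d(xi) -> tuple[np.ndarray, bool]:
    xi = np.asarray(xi, dtype=float)
    if xi.ndim == 1:
        return xi[None, :], True
    return xi, False


def sfs_pi(xi, n: int):
    """Mean pairwise differences (pi * L) from an unfolded SFS."""
    x, squeeze = _as2d(xi)
    i = np.arange(1, n)
    piL = x @ (i * (n - i)) / (n * (n - 1) / 2.0)
    return float(piL[0]) if squeeze else piL


def tajima_d(n: int, S, piL):
    """Tajima's D from segregating sites and mean pairwise differences.

    Returns NaN where S == 0.  Accepts arrays.
    """
    c = tajima_constants(n)
    S = np.asarray(S, dtype=float)
    piL = np.asarray(piL, dtype=float)
    var = c["e1"] * S + c["e2"] * S * (S - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (piL - S / c["a1"]) / np.sqrt(var)
    d = np.where(S > 0, d, np.nan)
    return float(d) if d.ndim == 0 else d


def fay_wu_from_sfs(xi, n: int):
    """(theta_H, theta_L, H) from an unfolded SFS.

    theta_H = sum 2 xi_i i^2 / (n(n-1)); theta_L = sum i xi_i / (n-1);
    H = piL - theta_H = 2 (piL - theta_L).
    """
    x, squeeze = _as2d(xi)
    i = np.arange(1, n)
    th = x @ (2.0 * i * i) / (n * (n - 1.0))
    tl = x @ i.astype(float) / (n - 1.0)
    h = sfs_pi(x, n) - th
    if squeeze:
        return float(th[0]), float(tl[0]), float(h[0])
    return th, tl, h


def _z_var(n: int, S, theta_w, theta_sq):
    """Sampling variance of (pi - theta_L) under neutrality (Zeng et al. 2006)."""
    bn = harmonic2(n)
    bn1 = bn + 1.0 / (n * n)  # sum_{i=1}^{n} 1/i^2
    t1 = (n - 2.0) / (6.0 * (n - 1.0)) * theta_w
    num = 18.0 * n * n * (3.0 * n + 2.0) * bn1 - (88.0 * n**3 + 9.0 * n * n - 13.0 * n + 6.0)
    t2 = num / (9.0 * n * (n - 1.0) ** 2) * theta_sq
    return t1 + t2


def fay_wu_z(xi, n: int):
    """Standardized Fay & Wu statistic Z = (piL - theta_L) / sqrt(Var).

    Variance follows the standardized-H formulation with theta estimated by
    Watterson's theta (per locus, unscaled by L) and theta^2 by
    S(S-1)/(a1^2 + b1).  Returns NaN where the oriented S is 0.
    """
    x, squeeze = _as2d(xi)
    S = x.sum(axis=1)
    a1 = harmonic(n)
    b1 = harmonic2(n)
    piL = sfs_pi(x, n)
    _, tl, _ = fay_wu_from_sfs(x, n)
    tw = S / a1
    tsq = S * (S - 1.0) / (a1 * a1 + b1)
    var = _z_var(n, S, tw, tsq)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (piL - tl) / np.sqrt(var)
    z = np.where(S > 0, z, np.nan)
    return float(z[0]) if squeeze else z


def sfs_stats(xi, n: int):
    """Vectorized (S, piL, D, Z) from unfolded SFS rows.

    The workhorse for the simulation null: ``xi`` is ``(reps, n-1)``.
    """
    x, squeeze = _as2d(xi)
    S = x.sum(axis=1)
    piL = sfs_pi(x, n)
    D = tajima_d(n, S, piL)
    Z = fay_wu_z(x, n)
    if squeeze:
        return float(S[0]), float(piL[0]), float(D[0]), float(Z[0])
    return S, piL, D, Z


def maf_bins_from_sfs(xi, n: int):
    """Counts of polymorphic sites in the four folded-MAF bins.

    Bins are right-closed: (0, .125], (.125, .25], (.25, .375], (.375, .5].
    Accepts a single SFS or a matrix; returns shape (4,) or (reps, 4).
    """
    x, squeeze = _as2d(xi)
    i = np.arange(1, n)
    maf = np.minimum(i, n - i) / n
    # right-closed binning: searchsorted with side='left' on upper edges
    which = np.searchsorted(np.asarray(MAF_BIN_EDGES[1:]), maf, side="left")
    which = np.minimum(which, 3)
    out = np.zeros((x.shape[0], 4))
    for b in range(4):
        out[:, b] = x[:, which == b].sum(axis=1)
    return out[0] if squeeze else out


def maf_bin_frequencies(maf_values, weights=None):
    """Frequencies of the four folded-MAF bins from raw per-site MAF values.

    Returns a length-4 vector summing to 1, or NaNs if no sites.
    """
    maf = np.asarray(maf_values, dtype=float)
    maf = maf[maf > 0]
    if maf.size == 0:
        return np.full(4, np.nan)
    which = np.minimum(np.searchsorted(np.asarray(MAF_BIN_EDGES[1:]), maf, side="left"), 3)
    counts = np.bincount(which, minlength=4).astype(float)
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# F_ST estimators
# ---------------------------------------------------------------------------

def _pairwise_diff_matrix(seqs: np.ndarray) -> np.ndarray:
    """Pairwise difference counts between rows of a (n, L) site matrix.

    Sites coded as small ints; negative codes mean missing and are skipped
    pairwise.
    """
    n = seqs.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        a = seqs[i]
        for j in range(i + 1, n):
            b = seqs[j]
            ok = (a >= 0) & (b >= 0)
            d[i, j] = d[j, i] = np.sum(a[ok] != b[ok])
    return d


def fst_hudson(seqs: np.ndarray, groups: np.ndarray):
    """Hudson-style F_ST = 1 - Hw/Hb from sequence data.

    Hw is the unweighted average of the two within-group mean pairwise
    differences; Hb the mean pairwise difference between groups.

    Parameters
    ----------
    seqs : (n, L) integer site matrix (negative = missing)
    groups : length-n array of group labels (two distinct values)

    Returns
    -------
    (fst, Hw, Hb); fst is NaN when Hb == 0.
    """
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError("exactly two groups required")
    d = _pairwise_diff_matrix(np.asarray(seqs))
    idx1 = np.where(groups == labels[0])[0]
    idx2 = np.where(groups == labels[1])[0]
    if idx1.size < 2 or idx2.size < 2:
        raise ValueError("both groups need >= 2 sequences")

    def mean_within(idx):
        sub = d[np.ix_(idx, idx)]
        m = idx.size
        return sub[np.triu_indices(m, 1)].mean()

    hw = 0.5 * (mean_within(idx1) + mean_within(idx2))
    hb = d[np.ix_(idx1, idx2)].mean()
    fst = math.nan if hb == 0 else 1.0 - hw / hb
    return fst, hw, hb


def fst_weir_cockerham(freqs1, freqs2, n1, n2):
    """Weir & Cockerham variance-components F_ST for haploid biallelic sites.

    Parameters
    ----------
    freqs1, freqs2 : per-site allele frequencies of one (arbitrary) allele in
        each group; arrays of equal length.
    n1, n2 : per-site haploid sample sizes (scalars or arrays).

    Returns
    -------
    (fst, a_sum, ab_sum) where fst = sum(a) / sum(a+b) across sites (NaN if
    the denominator is 0).  ``a`` is the between-group variance component and
    ``b`` the within-group component (MSG), following the haploid analogue of
    the 1984 estimator.
    """
    p1 = np.atleast_1d(np.asarray(freqs1, dtype=float))
    p2 = np.atleast_1d(np.asarray(freqs2, dtype=float))
    n1 = np.broadcast_to(np.asarray(n1, dtype=float), p1.shape)
    n2 = np.broadcast_to(np.asarray(n2, dtype=float), p2.shape)
    r = 2.0
    nsum = n1 + n2
    nbar = nsum / r
    nc = (nsum - (n1**2 + n2**2) / nsum) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / nsum
    msp = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / (r - 1.0)
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (nsum - r)
    a = (msp - msg) / nc
    b = msg
    a_sum = float(np.sum(a))
    ab_sum = float(np.sum(a + b))
    fst = math.nan if ab_sum == 0 else a_sum / ab_sum
    return fst, a_sum, ab_sum


# ---------------------------------------------------------------------------
# Hudson's rho (1987 moment estimator)
# ---------------------------------------------------------------------------

def _pair_time_cov(z: float) -> float:
    # covariance of pairwise coalescence times at two sites rho=z apart
    return (z + 18.0) / (z * z + 13.0 * z + 18.0)


def _gfun(C: float) -> float:
    """Average two-site coalescence-time covariance over a locus of total rho C."""
    if C <= 0:
        return 1.0
    val, _ = integrate.quad(lambda z: (C - z) * _pair_time_cov(z), 0.0, C, limit=200)
    return 2.0 * val / (C * C)


#: Upper bound reported when the data look like free recombination.
RHO_CAP = 1e4


def hudson_rho(seqs: np.ndarray) -> float:
    """Hudson (1987) moment estimator of the per-locus scaled recombination rate.

    Equates the observed variance of pairwise difference counts, S_k^2, to its
    expectation theta + theta^2 * g(C) where theta is estimated by the mean
    pairwise difference and g(C) averages the two-site coalescence-time
    covariance (z+18)/(z^2+13z+18) over pairs of positions on a locus with
    total scaled recombination rate C.  The root is found by bisection;
    estimates are truncated at 0 and capped at ``RHO_CAP`` when the observed
    variance is at or below the free-recombination limit.

    Requires complete-data sites (strict mask).  Returns NaN with fewer than
    2 segregating sites.
    """
    seqs = np.asarray(seqs)
    poly = np.array([np.unique(col).size > 1 for col in seqs.T])
    if poly.sum() < 2:
        return math.nan
    d = _pairwise_diff_matrix(seqs)
    n = seqs.shape[0]
    iu = np.triu_indices(n, 1)
    k = d[iu]
    theta = k.mean()
    sk2 = k.var()
    if theta <= 0:
        return math.nan
    excess = (sk2 - theta) / (theta * theta)
    if excess >= _gfun(0.0):
        return 0.0
    if excess <= 0.0:
        return RHO_CAP
    f = lambda C: _gfun(C) - excess
    lo, hi = 1e-8, 1.0
    while f(hi) > 0 and hi < RHO_CAP:
        hi *= 2.0
    if hi >= RHO_CAP:
        return RHO_CAP
    return float(optimize.brentq(f, lo, hi, xtol=1e-10, rtol=1e-12))


# ---------------------------------------------------------------------------
# Per-locus summary container
# ---------------------------------------------------------------------------

@dataclass
class DiversityStats:
    """Per-locus diversity summary.

    ``n`` is the modal per-site sample size used for D and Z normalization;
    ``pi`` and ``theta_w`` are per base pair, ``theta_h``/``theta_l`` per
    locus on oriented sites.
    """

    n: int
    L: float
    S: int
    theta_w: float
    pi: float
    theta_h: float = math.nan
    theta_l: float = math.nan
    D: float = math.nan
    H: float = math.nan
    Z: float = math.nan
    S_oriented: int = 0
    oriented: bool = False
    a1: float = field(default=math.nan, repr=False)
    b1: float = field(default=math.nan, repr=False)
    e1: float = field(default=math.nan, repr=False)
    e2: float = field(default=math.nan, repr=False)
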