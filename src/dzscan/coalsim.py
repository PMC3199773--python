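"""Neutral coalescent simulation under exponential growth.

Single panmictic population, haploid-coded sample (inbred accessions), time
measured in coalescent units where a pair of lineages coalesces at rate 1 at
sampling time.  Exponential growth at rate ``g`` (forward in time) means the
backward-time population size is N(t) = N0 * exp(-g t), so the pairwise
coalescence rate at backward time t is exp(g t).  Mutations follow the
infinite-sites model: S ~ Poisson(theta_L * T_total / 2) mutations dropped
uniformly on the genealogy, where ``theta_L`` is the composite per-locus
mutation parameter (per-bp theta times length).

Two interfaces are provided:

* an object-level simulator (:func:`simulate_genealogy`,
  :func:`drop_mutations`) that materializes trees and haplotype matrices —
  used by the synthetic-data generator and in tests;
* a vectorized batch engine (:func:`batch_sfs`) that produces unfolded
  site-frequency spectra for many replicates at once, with per-replicate
  (theta, g) if desired — the workhorse behind the ABC sampler and the
  per-locus (D, Z) null distributions.

Both engines share the same waiting-time inverse transform and agree in
distribution; the batch engine never builds explicit trees, it only tracks
how many tips each ancestral lineage subtends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import sumstats

__all__ = [
    "GrowthModel",
    "SimConfig",
    "Genealogy",
    "coalescent_waiting_times",
    "simulate_genealogy",
    "drop_mutations",
    "apply_misorientation",
    "simulate_locus",
    "batch_sfs",
]


@dataclass
class GrowthModel:
    """Demographic null model: scaled mutation rate and expansion rate.

    theta : per-bp scaled mutation rate (coalescent units, haploid scaling)
    g : exponential growth rate in coalescent time units; g >= 0 means the
        population expanded forward in time (star-like genealogies, excess of
        rare alleles, negative Tajima's D).
    """

    theta: float
    g: float = 0.0

    def __post_init__(self):
        if self.theta <= 0:
            raise ValueError("theta must be > 0")


@dataclass
class SimConfig:
    """Per-locus simulation layout."""

    n: int
    L: int
    p_mis: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.n < 2 or self.L < 1 or not (0.0 <= self.p_mis <= 1.0):
            raise ValueError("invalid SimConfig")


def coalescent_waiting_times(n: int, g, e: np.ndarray) -> np.ndarray:
    """Transform Exp(1) draws into growth-model coalescence waiting times.

    ``e`` has shape (reps, n-1); column j holds the Exp(1) draw for the
    interval with k = n - j lineages.  ``g`` is scalar or shape (reps,).
    Returns waiting times of the same shape.  Inverse transform of the
    cumulative intensity C(k,2) * (exp(g(t+w)) - exp(g t)) / g.
    """
    reps = e.shape[0]
    g = np.broadcast_to(np.asarray(g, dtype=float), (reps,)).copy()
    small = np.abs(g) < 1e-12
    gsafe = np.where(small, 1.0, g)  # placeholder where the g=0 branch is taken
    w = np.empty_like(e)
    t = np.zeros(reps)
    for j, k in enumerate(range(n, 1, -1)):
        rate = k * (k - 1) / 2.0
        w_const = e[:, j] / rate
        # exp(-g t) <= 1, so the argument of log1p never overflows
        w_growth = np.log1p(gsafe * e[:, j] / rate * np.exp(-gsafe * t)) / gsafe
        w[:, j] = np.where(small, w_const, w_growth)
        t += w[:, j]
    return w


@dataclass
class Genealogy:
    """Binary coalescent tree: tips 0..n-1, internal nodes n..2n-2 (root last).

    parent[v] is the parent of node v (root's parent = -1); blen[v] the branch
    above v in coalescent time units; nleaves[v] the number of sample tips
    subtended by v.
    """

    n: int
    parent: np.ndarray
    blen: np.ndarray
    nleaves: np.ndarray

    @property
    def total_length(self) -> float:
        return float(self.blen.sum())

    @property
    def tmrca(self) -> float:
        # root depth: follow any tip to the root
        t = 0.0
        v = 0
        while self.parent[v] != -1:
            t += self.blen[v]
            v = self.parent[v]
        return t

    def leaf_sets(self) -> list[np.ndarray]:
        """Tip index set under each node (for assigning derived alleles).

        Internal nodes are created in coalescence order, so every parent has a
        larger index than its children and a single increasing pass suffices.
        """
        nn = 2 * self.n - 1
        sets: list[list[int]] = [[v] if v < self.n else [] for v in range(nn)]
        for v in range(nn - 1):
            sets[self.parent[v]].extend(sets[v])
        return [np.array(s, dtype=int) for s in sets]


def simulate_genealogy(n: int, g: float, rng: np.random.Generator) -> Genealogy:
    """Simulate one n-coalescent genealogy under exponential growth."""
    if n < 2 or g < 0:
        raise ValueError("need n >= 2 and g >= 0")
    e = rng.exponential(size=(1, n - 1))
    w = coalescent_waiting_times(n, g, e)[0]
    nn = 2 * n - 1
    parent = np.full(nn, -1, dtype=int)
    node_time = np.zeros(nn)
    nleaves = np.ones(nn, dtype=int)
    active = list(range(n))
    t = 0.0
    nxt = n
    for j, k in enumerate(range(n, 1, -1)):
        t += w[j]
        i1 = rng.integers(k)
        i2 = rng.integers(k - 1)
        if i2 >= i1:
            i2 += 1
        a, b = active[i1], active[i2]
        parent[a] = parent[b] = nxt
        node_time[nxt] = t
        nleaves[nxt] = nleaves[a] + nleaves[b]
        active = [v for v in active if v not in (a, b)] + [nxt]
        nxt += 1
    blen = np.zeros(nn)
    for v in range(nn - 1):
        blen[v] = node_time[parent[v]] - node_time[v]
    return Genealogy(n=n, parent=parent, blen=blen, nleaves=nleaves)


def drop_mutations(gen: Genealogy, theta_L: float, rng: np.random.Generator):
    """Place infinite-sites mutations on a genealogy.

    Returns ``(xi, carriers)`` where ``xi`` is the unfolded SFS (length n-1)
    and ``carriers`` is a list with, per mutation, the array of tip indices
    carrying the derived allele.
    """
    if theta_L < 0:
        raise ValueError("theta_L must be >= 0")
    nn = 2 * gen.n - 1
    S = rng.poisson(theta_L * gen.total_length / 2.0)
    xi = np.zeros(gen.n - 1, dtype=int)
    carriers: list[np.ndarray] = []
    if S == 0:
        return xi, carriers
    probs = gen.blen / gen.total_length
    branch = rng.choice(nn, size=S, p=probs)
    sets = gen.leaf_sets()
    for v in branch:
        c = sets[v]
        xi[len(c) - 1] += 1
        carriers.append(c)
    return xi, carriers


def apply_misorientation(xi, n: int, p_mis: float, rng: np.random.Generator):
    """Randomly flip ancestral/derived orientation of sites.

    Independently per segregating site, with probability ``p_mis`` a derived
    count i becomes n - i.  Accepts an SFS vector or a (reps, n-1) matrix.
    """
    if not (0.0 <= p_mis <= 1.0):
        raise ValueError("p_mis in [0, 1]")
    x = np.asarray(xi)
    squeeze = x.ndim == 1
    x = np.atleast_2d(x)
    if p_mis == 0.0:
        return x[0].copy() if squeeze else x.copy()
    flipped = rng.binomial(x.astype(np.int64), p_mis)
    out = x - flipped + flipped[:, ::-1]
    return out[0] if squeeze else out


def simulate_locus(model: GrowthModel, config: SimConfig, rng: np.random.Generator | None = None):
    """One replicate's summary statistics for a locus layout.

    Returns a dict with S, piL, D, Z and the 4 folded-MAF bin counts.  D and
    Z are NaN when S = 0 (the replicate still counts).  Deterministic given
    the config seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    xi = batch_sfs(config.n, model.theta * config.L, model.g, 1, rng, p_mis=config.p_mis)[0]
    S, piL, D, Z = sumstats.sfs_stats(xi, config.n)
    bins = sumstats.maf_bins_from_sfs(xi, config.n)
    return {"xi": xi, "S": S, "piL": piL, "D": D, "Z": Z, "maf_bins": bins}


def batch_sfs(
    n: int,
    theta_L,
    g,
    reps: int,
    rng: np.random.Generator,
    p_mis: float = 0.0,
    chunk: int = 50_000,
) -> np.ndarray:
    """Unfolded SFS for many independent coalescent replicates.

    ``theta_L`` (per-locus composite mutation parameter) and ``g`` may be
    scalars or arrays of length ``reps`` (per-replicate parameters, as needed
    when integrating over an ABC posterior).  Returns an int array of shape
    ``(reps, n-1)``.  Misorientation is applied independently per site with
    probability ``p_mis``.
    """
    theta_L = np.broadcast_to(np.asarray(theta_L, dtype=float), (reps,))
    g = np.broadcast_to(np.asarray(g, dtype=float), (reps,))
    out = np.empty((reps, n - 1), dtype=np.int64)
    for lo in range(0, reps, chunk):
        hi = min(lo + chunk, reps)
        out[lo:hi] = _batch_sfs_chunk(n, theta_L[lo:hi], g[lo:hi], rng, p_mis)
    return out


def _batch_sfs_chunk(n, theta_L, g, rng, p_mis):
    R = theta_L.shape[0]
    e = rng.exponential(size=(R, n - 1))
    w = coalescent_waiting_times(n, g, e)
    # Each lineage keeps a constant subtended-tip count from birth to the
    # merge that kills it, so class lengths accumulate from the lifetimes of
    # the two lineages dying at each merge: O(R n) instead of O(R n^2).
    sizes = np.ones((R, n), dtype=np.int64)
    births = np.zeros((R, n))
    class_len = np.zeros(R * n)  # slot c: total length of branches with c tips
    rows = np.arange(R)
    base = rows * n
    t = np.zeros(R)
    for j, k in enumerate(range(n, 1, -1)):
        t = t + w[:, j]
        # merge a uniform random pair (i1, i2) among the k active lineages
        i1 = rng.integers(0, k, size=R)
        i2 = rng.integers(0, k - 1, size=R)
        i2 = np.where(i2 >= i1, i2 + 1, i2)
        s1, s2 = sizes[rows, i1], sizes[rows, i2]
        idx = np.concatenate([base + s1, base + s2])
        life = np.concatenate([t - births[rows, i1], t - births[rows, i2]])
        class_len += np.bincount(idx, weights=life, minlength=R * n)
        sizes[rows, i1] = s1 + s2
        births[rows, i1] = t
        sizes[rows, i2] = sizes[rows, k - 1]
        births[rows, i2] = births[rows, k - 1]
    # slot c holds total branch length subtending c tips; c ranges 1..n-1
    # (the MRCA itself carries no branch), so slot 0 stays empty
    lens = class_len.reshape(R, n)[:, 1:]
    ttot = lens.sum(axis=1)
    S = rng.poisson(theta_L * ttot / 2.0)
    with np.errstate(invalid="ignore"):
        pvals = lens / ttot[:, None]
    pvals[ttot == 0] = 1.0 / (n - 1)
    xi = rng.multinomial(S, pvals)
    if p_mis > 0:
        xi = apply_misorientation(xi, n, p_mis, rng)
    return xi
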