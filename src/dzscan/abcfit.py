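"""Approximate Bayesian computation fit of the exponential-growth null model.

One ancestry group at a time: draw (theta, g) from uniform priors, simulate
the group's multilocus layout under the growth coalescent, summarize each
simulated dataset by the frequencies of four folded minor-allele-frequency
bins (uppers 0.125, 0.25, 0.375, 0.5) pooled over loci (each SNP counts
once), then accept the fraction of draws nearest the observed summaries and
apply the local-linear regression adjustment of Beaumont et al. on
tan-transformed parameters.  The adjusted draws are binned onto a 72 x 72
grid over the prior rectangle (5184 bins), which downstream code samples to
parametrize per-locus null simulations.

The tan transform u = tan(pi * ((x - a)/(b - a) - 1/2)) maps the bounded
prior interval (a, b) bijectively onto the real line, so regression-adjusted
draws can never leave the prior support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import coalsim, sumstats

__all__ = [
    "ABCConfig",
    "PosteriorGrid",
    "observed_summaries",
    "abc_sample",
    "abc_posterior",
    "sample_posterior",
]

log = logging.getLogger(__name__)

GRID_SIDE = 72  # 72 x 72 = 5184 posterior bins


@dataclass
class ABCConfig:
    """ABC settings for one group.

    ``n_sims`` defaults to a desk scale (1e5); the original analysis scale is
    1e7.  ``tolerance`` is the accepted fraction of simulations.  Priors are
    uniform; theta is per base pair.
    """

    n_sims: int = 100_000
    tolerance: float = 1e-3
    theta_prior: tuple[float, float] = (1e-4, 3e-2)
    g_prior: tuple[float, float] = (0.0, 200.0)
    adjust: bool = True

    def __post_init__(self):
        if not (0 < self.tolerance <= 1):
            raise ValueError("tolerance in (0, 1]")
        for a, b in (self.theta_prior, self.g_prior):
            if not (np.isfinite(a) and np.isfinite(b) and b > a):
                raise ValueError("prior ranges must be finite with positive width")


@dataclass
class PosteriorGrid:
    """Binned joint posterior over (theta, g)."""

    masses: np.ndarray  # (GRID_SIDE, GRID_SIDE), rows = theta bins
    theta_edges: np.ndarray
    g_edges: np.ndarray
    n_accepted: int = 0
    adjusted: bool = True

    def __post_init__(self):
        if self.masses.shape != (len(self.theta_edges) - 1, len(self.g_edges) - 1):
            raise ValueError("grid shape mismatch")
        tot = self.masses.sum()
        if tot <= 0:
            raise ValueError("empty posterior")
        self.masses = self.masses / tot

    @property
    def theta_mids(self) -> np.ndarray:
        return 0.5 * (self.theta_edges[:-1] + self.theta_edges[1:])

    @property
    def g_mids(self) -> np.ndarray:
        return 0.5 * (self.g_edges[:-1] + self.g_edges[1:])

    def marginal(self, param: str) -> np.ndarray:
        if param == "theta":
            return self.masses.sum(axis=1)
        if param == "g":
            return self.masses.sum(axis=0)
        raise ValueError(param)

    def mean(self) -> tuple[float, float]:
        return (
            float(self.marginal("theta") @ self.theta_mids),
            float(self.marginal("g") @ self.g_mids),
        )

    def central_interval(self, param: str, mass: float = 0.9) -> tuple[float, float]:
        """Central credible interval from the binned marginal."""
        m = self.marginal(param)
        edges = self.theta_edges if param == "theta" else self.g_edges
        cdf = np.concatenate([[0.0], np.cumsum(m)])
        lo_q, hi_q = (1 - mass) / 2, 1 - (1 - mass) / 2
        lo = np.interp(lo_q, cdf, edges)
        hi = np.interp(hi_q, cdf, edges)
        return float(lo), float(hi)

    def variance(self) -> tuple[float, float]:
        mt, mg = self.mean()
        vt = float(self.marginal("theta") @ (self.theta_mids - mt) ** 2)
        vg = float(self.marginal("g") @ (self.g_mids - mg) ** 2)
        return vt, vg

    def to_frame(self) -> pd.DataFrame:
        it, ig = np.meshgrid(np.arange(len(self.theta_mids)), np.arange(len(self.g_mids)), indexing="ij")
        return pd.DataFrame(
            {
                "theta_bin": self.theta_mids[it.ravel()],
                "g_bin": self.g_mids[ig.ravel()],
                "mass": self.masses.ravel(),
            }
        )


def observed_summaries(maf_values, total_sites: float | None = None) -> np.ndarray:
    """Pooled MAF-bin frequencies across a group's control loci.

    ``maf_values``: iterable of per-locus arrays of per-SNP folded minor
    allele frequencies.  Pooling is site-weighted: each SNP counts once,
    regardless of locus.

    With ``total_sites`` (the pooled number of analysed sites, the default
    used by the fitting pipeline) each bin count is divided by that total, so
    the four summaries sum to the overall SNP density S/L and jointly inform
    the mutation rate and the growth rate.  Without it the summaries are
    conditional frequencies among SNPs (they sum to 1); these describe only
    the spectrum's shape and cannot identify theta.
    """
    pooled = np.concatenate([np.asarray(v, dtype=float) for v in maf_values]) if maf_values else np.array([])
    pooled = pooled[pooled > 0]
    if pooled.size == 0:
        raise ValueError("no polymorphic sites in group; cannot form ABC summaries")
    if total_sites is None:
        return sumstats.maf_bin_frequencies(pooled)
    which = np.minimum(
        np.searchsorted(np.asarray(sumstats.MAF_BIN_EDGES[1:]), pooled, side="left"), 3
    )
    return np.bincount(which, minlength=4) / float(total_sites)


def abc_sample(
    config: ABCConfig,
    layout: list[tuple[int, int]],
    rng: np.random.Generator,
    per_snp: bool = False,
) -> pd.DataFrame:
    """Simulate the reference table: priors -> multilocus layout -> summaries.

    ``layout`` lists the group's per-locus (n, L).  Returns a DataFrame with
    columns theta, g, f1..f4.  Summaries are per-site bin frequencies
    (counts over the layout's total length) by default, matching
    :func:`observed_summaries` with ``total_sites``; with
    ``per_snp=True`` they are conditional frequencies among SNPs (NaN when a
    draw produced no polymorphism at all).
    """
    R = config.n_sims
    theta = rng.uniform(*config.theta_prior, size=R)
    g = rng.uniform(*config.g_prior, size=R)
    bin_counts = np.zeros((R, 4))
    for n_l, L_l in layout:
        xi = coalsim.batch_sfs(n_l, theta * L_l, g, R, rng)
        bin_counts += sumstats.maf_bins_from_sfs(xi, n_l)
    if per_snp:
        tot = bin_counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs = bin_counts / tot[:, None]
        freqs[tot == 0] = np.nan
    else:
        freqs = bin_counts / float(sum(L for _, L in layout))
    out = pd.DataFrame({"theta": theta, "g": g})
    for b in range(4):
        out[f"f{b + 1}"] = freqs[:, b]
    return out


def _tan_transform(x, a, b):
    return np.tan(np.pi * ((x - a) / (b - a) - 0.5))


def _tan_inverse(u, a, b):
    return a + (b - a) * (np.arctan(u) / np.pi + 0.5)


def abc_posterior(observed: np.ndarray, table: pd.DataFrame, config: ABCConfig) -> PosteriorGrid:
    """Rejection + local-linear regression adjustment -> binned posterior.

    Summaries are standardized by their Monte Carlo standard deviations
    before the Euclidean distance is computed; the nearest ``tolerance``
    fraction of rows is accepted; accepted parameters are tan-transformed,
    regression-adjusted with Epanechnikov weights, back-transformed, and
    binned with equal weights on the 72 x 72 grid.
    """
    obs = np.asarray(observed, dtype=float)
    cols = [f"f{b + 1}" for b in range(4)]
    sumstats_mat = table[cols].to_numpy()
    ok = np.all(np.isfinite(sumstats_mat), axis=1)
    S = sumstats_mat[ok]
    params = table.loc[ok, ["theta", "g"]].to_numpy()
    sd = S.std(axis=0)
    sd[sd == 0] = 1.0
    d = np.sqrt(np.sum(((S - obs) / sd) ** 2, axis=1))
    n_acc = max(int(np.ceil(config.tolerance * len(table))), 50)
    if n_acc > len(d):
        raise ValueError("fewer valid simulations than the acceptance count")
    order = np.argsort(d, kind="stable")[:n_acc]
    S_acc, p_acc, d_acc = S[order], params[order], d[order]

    u = np.column_stack(
        [
            _tan_transform(p_acc[:, 0], *config.theta_prior),
            _tan_transform(p_acc[:, 1], *config.g_prior),
        ]
    )
    adjusted = False
    if config.adjust:
        dmax = d_acc.max()
        w = 1.0 - (d_acc / dmax) ** 2 if dmax > 0 else np.ones_like(d_acc)
        w = np.maximum(w, 1e-12)
        # the 4 bin frequencies sum to 1, so drop the last (redundant) one
        Sc = (S_acc - obs)[:, :3]
        X = np.column_stack([np.ones(n_acc), Sc])
        if np.all(Sc.std(axis=0) < 1e-12):
            log.warning("zero summary variance among accepted draws; rejection-only posterior")
        else:
            sw = np.sqrt(w)
            beta, *_ = np.linalg.lstsq(X * sw[:, None], u * sw[:, None], rcond=None)
            u = u - Sc @ beta[1:]
            adjusted = True
    theta_adj = _tan_inverse(u[:, 0], *config.theta_prior)
    g_adj = _tan_inverse(u[:, 1], *config.g_prior)

    t_edges = np.linspace(*config.theta_prior, GRID_SIDE + 1)
    g_edges = np.linspace(*config.g_prior, GRID_SIDE + 1)
    H, _, _ = np.histogram2d(theta_adj, g_adj, bins=[t_edges, g_edges])
    return PosteriorGrid(masses=H, theta_edges=t_edges, g_edges=g_edges, n_accepted=n_acc, adjusted=adjusted)


def point_mass_grid(theta: float, g: float, config: ABCConfig | None = None) -> PosteriorGrid:
    """Degenerate posterior putting all mass in the bin containing (theta, g).

    Useful for calibration experiments where the generating parameters are
    known; downstream draws return the bin midpoints, so pick grid midpoints
    as the truth to avoid discretization offsets.
    """
    config = config or ABCConfig()
    t_edges = np.linspace(*config.theta_prior, GRID_SIDE + 1)
    g_edges = np.linspace(*config.g_prior, GRID_SIDE + 1)
    H = np.zeros((GRID_SIDE, GRID_SIDE))
    it = int(np.clip(np.searchsorted(t_edges, theta, side="right") - 1, 0, GRID_SIDE - 1))
    ig = int(np.clip(np.searchsorted(g_edges, g, side="right") - 1, 0, GRID_SIDE - 1))
    H[it, ig] = 1.0
    return PosteriorGrid(masses=H, theta_edges=t_edges, g_edges=g_edges, n_accepted=1, adjusted=False)


def sample_posterior(grid: PosteriorGrid, k: int, rng: np.random.Generator) -> np.ndarray:
    """Draw k (theta, g) pairs from the binned posterior (bin midpoints)."""
    flat = grid.masses.ravel()
    counts = rng.multinomial(k, flat)
    idx = np.repeat(np.arange(flat.size), counts)
    rng.shuffle(idx)
    it, ig = np.unravel_index(idx, grid.masses.shape)
    return np.column_stack([grid.theta_mids[it], grid.g_mids[ig]])
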