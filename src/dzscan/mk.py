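"""Poisson polymorphism/divergence models of purifying and positive selection.

Each gene i contributes four counts — synonymous and non-synonymous
polymorphisms (Ps, Pn) and fixed differences to the outgroup (Ds, Dn) — with
site totals Ls, Ln.  Counts are modelled as independent Poissons:

    Ps_i ~ Pois(theta_i * Ls_i)
    Pn_i ~ Pois(f_c * theta_i * Ln_i)
    Ds_i ~ Pois(d_i * Ls_i)
    Dn_i ~ Pois(f_c * d_i * Ln_i / (1 - alpha_c))

where ``f_c`` is the fraction of amino-acid mutations that are effectively
neutral in gene category c (so 1 - f is the fraction under strong purifying
selection) and ``alpha_c`` the proportion of non-synonymous divergence driven
by positive selection.  Per-gene nuisances (theta_i, d_i) are profiled
analytically, leaving a 0- to 6-dimensional optimization over the structural
parameters of six nested models:

    M0: f = 1, alpha = 0 (strict neutrality)
    M1: shared f, alpha = 0
    M2: f per category, alpha = 0
    M3: shared f, shared alpha
    M4: f per category, shared alpha
    M5: f and alpha per category

Models are compared by AIC; following the source analysis convention this
package's Akaike weights default to w ∝ exp(-ΔAIC) (the conventional
exp(-ΔAIC/2) is available via ``halved=True``), and parameter estimates are
model-averaged with those weights (shared parameters broadcast to all
categories; M0 contributes f = 1, alpha = 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps
from scipy.special import gammaln, xlogy

__all__ = [
    "MKGeneCounts",
    "MKModelFit",
    "MODELS",
    "CATEGORIES",
    "fit_model",
    "fit_all",
    "aic_compare",
    "model_average",
    "lrt",
]

CATEGORIES = (1, 2, 3)  # control, flowering, symbiotic
MODELS = ("M0", "M1", "M2", "M3", "M4", "M5")

ALPHA_MIN, ALPHA_MAX = -5.0, 1.0 - 1e-9
F_MIN = 1e-9


@dataclass
class MKGeneCounts:
    gene_id: str
    category: int
    Pn: int
    Ps: int
    Dn: int
    Ds: int
    Ln: float
    Ls: float

    def __post_init__(self):
        if min(self.Pn, self.Ps, self.Dn, self.Ds) < 0 or self.Ln <= 0 or self.Ls <= 0:
            raise ValueError("counts must be >= 0 and site totals > 0")


@dataclass
class MKModelFit:
    model_id: str
    f: dict[int, float]
    alpha: dict[int, float]
    logL: float
    k: int
    AIC: float
    delta_aic: float = math.nan
    weight: float = math.nan
    converged: bool = True
    theta: np.ndarray = field(default=None, repr=False)
    d: np.ndarray = field(default=None, repr=False)


def _stack(counts: list[MKGeneCounts]):
    arr = lambda attr: np.array([getattr(c, attr) for c in counts], dtype=float)
    cat = np.array([c.category for c in counts])
    return arr("Pn"), arr("Ps"), arr("Dn"), arr("Ds"), arr("Ln"), arr("Ls"), cat


def _profile_loglik(fc, ac, Pn, Ps, Dn, Ds, Ln, Ls):
    """Log-likelihood with per-gene theta_i, d_i at their conditional MLEs.

    ``fc``/``ac`` are per-gene vectors of the applicable f and alpha.
    """
    en = fc * Ln  # effective non-synonymous exposure for polymorphism
    ed = fc * Ln / (1.0 - ac)  # for divergence
    theta = (Pn + Ps) / (Ls + en)
    d = (Dn + Ds) / (Ls + ed)
    ll = 0.0
    for cnt, mean in ((Ps, theta * Ls), (Pn, theta * en), (Ds, d * Ls), (Dn, d * ed)):
        ll += np.sum(xlogy(cnt, mean) - mean - gammaln(cnt + 1.0))
    return float(ll), theta, d


# model structure: (f shared?, alpha shared?, alpha fixed at 0?)
_STRUCTURE = {
    "M0": dict(f_free=False, f_percat=False, a_free=False, a_percat=False),
    "M1": dict(f_free=True, f_percat=False, a_free=False, a_percat=False),
    "M2": dict(f_free=True, f_percat=True, a_free=False, a_percat=False),
    "M3": dict(f_free=True, f_percat=False, a_free=True, a_percat=False),
    "M4": dict(f_free=True, f_percat=True, a_free=True, a_percat=False),
    "M5": dict(f_free=True, f_percat=True, a_free=True, a_percat=True),
}


def _unpack(model_id: str, x: np.ndarray, cats_present: list[int]):
    s = _STRUCTURE[model_id]
    i = 0
    f = {}
    if not s["f_free"]:
        f = {c: 1.0 for c in CATEGORIES}
    elif s["f_percat"]:
        for c in cats_present:
            f[c] = x[i]
            i += 1
        for c in CATEGORIES:
            f.setdefault(c, math.nan)
    else:
        f = {c: x[i] for c in CATEGORIES}
        i += 1
    a = {}
    if not s["a_free"]:
        a = {c: 0.0 for c in CATEGORIES}
    elif s["a_percat"]:
        for c in cats_present:
            a[c] = x[i]
            i += 1
        for c in CATEGORIES:
            a.setdefault(c, math.nan)
    else:
        a = {c: x[i] for c in CATEGORIES}
        i += 1
    return f, a


def _n_free(model_id: str, n_cats: int) -> int:
    s = _STRUCTURE[model_id]
    k = 0
    if s["f_free"]:
        k += n_cats if s["f_percat"] else 1
    if s["a_free"]:
        k += n_cats if s["a_percat"] else 1
    return k


def fit_model(
    model_id: str,
    counts: list[MKGeneCounts],
    x0: np.ndarray | None = None,
    count_nuisance: bool = True,
) -> MKModelFit:
    """Maximum-likelihood fit of one model.

    ``k`` (for AIC) counts the structural parameters plus, when
    ``count_nuisance`` (default), the 2 x n_genes profiled nuisances; the
    nuisance contribution is identical across models so ΔAIC and the Akaike
    weights do not depend on this choice.
    """
    if model_id not in MODELS:
        raise ValueError(model_id)
    Pn, Ps, Dn, Ds, Ln, Ls, cat = _stack(counts)
    cats_present = sorted(set(cat.astype(int)))
    nfree = _n_free(model_id, len(cats_present))

    def expand(f, a):
        fv = np.array([f[c] for c in cat.astype(int)])
        av = np.array([a[c] for c in cat.astype(int)])
        return fv, av

    if nfree == 0:
        f, a = _unpack(model_id, np.array([]), cats_present)
        ll, theta, d = _profile_loglik(*expand(f, a), Pn, Ps, Dn, Ds, Ln, Ls)
        best_x, best_ll, ok = np.array([]), ll, True
    else:
        s = _STRUCTURE[model_id]
        bounds = []
        if s["f_free"]:
            bounds += [(F_MIN, 1.0)] * (len(cats_present) if s["f_percat"] else 1)
        if s["a_free"]:
            bounds += [(ALPHA_MIN, ALPHA_MAX)] * (len(cats_present) if s["a_percat"] else 1)

        def nll(x):
            f, a = _unpack(model_id, x, cats_present)
            ll, _, _ = _profile_loglik(*expand(f, a), Pn, Ps, Dn, Ds, Ln, Ls)
            return -ll

        starts = []
        if x0 is not None and len(x0) == nfree:
            starts.append(np.asarray(x0, dtype=float))
        default = np.array([0.2] * len([b for b in bounds if b[1] == 1.0]) + [0.1] * len([b for b in bounds if b[1] != 1.0]))
        starts.append(default[:nfree] if len(default) >= nfree else np.full(nfree, 0.2))
        starts.append(np.array([0.5 if b[1] == 1.0 else 0.0 for b in bounds]))
        best_ll, best_x, ok = -np.inf, None, False
        for st in starts:
            res = optimize.minimize(nll, st, method="L-BFGS-B", bounds=bounds)
            if -res.fun > best_ll:
                best_ll, best_x, ok = -res.fun, res.x, bool(res.success)
        f, a = _unpack(model_id, best_x, cats_present)
        _, theta, d = _profile_loglik(*expand(f, a), Pn, Ps, Dn, Ds, Ln, Ls)

    k = nfree + (2 * len(counts) if count_nuisance else 0)
    aic = -2.0 * best_ll + 2.0 * k
    return MKModelFit(
        model_id=model_id,
        f=f,
        alpha=a,
        logL=best_ll,
        k=k,
        AIC=aic,
        converged=ok,
        theta=theta,
        d=d,
    )


def fit_all(counts: list[MKGeneCounts], halved: bool = False) -> dict[str, MKModelFit]:
    """Fit M0..M5, warm-starting each model from its nested parent.

    Warm starts guarantee the nesting inequalities logL(M5) >= logL(M4) >=
    logL(M3) >= logL(M1) >= logL(M0) and logL(M5) >= logL(M2) >= logL(M1)
    up to optimizer tolerance.  Returns fits annotated with ΔAIC and Akaike
    weights.
    """
    cats_present = sorted({c.category for c in counts})
    nc = len(cats_present)
    fits: dict[str, MKModelFit] = {}
    fits["M0"] = fit_model("M0", counts)
    fits["M1"] = fit_model("M1", counts)
    f1 = fits["M1"].f[cats_present[0]]
    fits["M2"] = fit_model("M2", counts, x0=np.full(nc, f1))
    fits["M3"] = fit_model("M3", counts, x0=np.array([f1, 0.0]))
    f3, a3 = fits["M3"].f[cats_present[0]], fits["M3"].alpha[cats_present[0]]
    fits["M4"] = fit_model("M4", counts, x0=np.array([f3] * nc + [a3]))
    f4 = [fits["M4"].f[c] for c in cats_present]
    a4 = fits["M4"].alpha[cats_present[0]]
    fits["M5"] = fit_model("M5", counts, x0=np.array(f4 + [a4] * nc))
    aic_compare(list(fits.values()), halved=halved)
    return fits


def aic_compare(fits: list[MKModelFit], halved: bool = False) -> None:
    """Annotate fits in place with ΔAIC and Akaike weights.

    Default weighting is w_i ∝ exp(-ΔAIC_i); ``halved=True`` selects the
    textbook exp(-ΔAIC_i / 2).
    """
    if len(fits) < 2:
        raise ValueError("need >= 2 fits")
    aics = np.array([f.AIC for f in fits])
    delta = aics - aics.min()
    scale = 0.5 if halved else 1.0
    w = np.exp(-scale * delta)
    w = w / w.sum()
    for f, dd, ww in zip(fits, delta, w):
        f.delta_aic = float(dd)
        f.weight = float(ww)


def akaike_weights(delta_aic, halved: bool = False) -> np.ndarray:
    """Akaike weights from a ΔAIC vector alone (w ∝ exp(-ΔAIC) by default)."""
    delta = np.asarray(delta_aic, dtype=float)
    w = np.exp(-(0.5 if halved else 1.0) * (delta - delta.min()))
    return w / w.sum()


def model_average(fits: list[MKModelFit]) -> dict[str, dict[int, float]]:
    """Akaike-weighted averages of f and alpha per category over all fits."""
    wsum = sum(f.weight for f in fits)
    if not math.isclose(wsum, 1.0, abs_tol=1e-6):
        raise ValueError("weights must be normalized (run aic_compare first)")
    favg = {c: 0.0 for c in CATEGORIES}
    aavg = {c: 0.0 for c in CATEGORIES}
    for fit in fits:
        for c in CATEGORIES:
            fv = fit.f.get(c, math.nan)
            av = fit.alpha.get(c, math.nan)
            if math.isnan(fv) or math.isnan(av):
                continue
            favg[c] += fit.weight * fv
            aavg[c] += fit.weight * av
    return {"f": favg, "alpha": aavg}


def lrt(fit_reduced: MKModelFit, fit_full: MKModelFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested fits: (statistic, df, chi2 p-value)."""
    stat = 2.0 * (fit_full.logL - fit_reduced.logL)
    df = _n_free(fit_full.model_id, len(CATEGORIES)) - _n_free(fit_reduced.model_id, len(CATEGORIES))
    if df <= 0:
        # fall back to the difference in reported k (same data => nuisances cancel)
        df = max(fit_full.k - fit_reduced.k, 1)
    if stat < -1e-6:
        raise RuntimeError("negative LRT statistic: optimization failure")
    stat = max(stat, 0.0)
    return stat, df, float(sps.chi2.sf(stat, df))


def chi2_lrt_pvalue(stat: float, df: int = 1) -> float:
    """Upper-tail chi-square p-value for a likelihood-ratio statistic."""
    return float(sps.chi2.sf(stat, df))


def mk_counts(filtered, coding, gene_id: str, category: int) -> MKGeneCounts:
    """Build per-gene MK counts from a filtered locus and its coding-site labels.

    Pn/Ps come from within-ingroup coding polymorphisms; Dn/Ds from sites
    fixed in the ingroup whose allele differs from the outgroup.  A site
    polymorphic in the ingroup is never double-counted as divergence (the
    coding classifier only emits divergence labels at ingroup-fixed codons).

    Parameters
    ----------
    filtered : locus_io.FilteredLocus
    coding : locus_io.CodingSites
    """
    if coding.Ln + coding.Ls <= 0:
        raise ValueError(f"{gene_id}: no analysable coding sites")
    pn = sum(1 for v in coding.labels.values() if v == "non-synonymous")
    ps = sum(1 for v in coding.labels.values() if v == "synonymous")
    dn = sum(1 for v in coding.divergence_labels.values() if v == "non-synonymous")
    ds = sum(1 for v in coding.divergence_labels.values() if v == "synonymous")
    return MKGeneCounts(gene_id=gene_id, category=category, Pn=pn, Ps=ps, Dn=dn, Ds=ds, Ln=coding.Ln, Ls=coding.Ls)


def counts_frame(counts: list[MKGeneCounts]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "category": c.category,
                "Pn": c.Pn,
                "Ps": c.Ps,
                "Dn": c.Dn,
                "Ds": c.Ds,
                "Ln": c.Ln,
                "Ls": c.Ls,
            }
            for c in counts
        ]
    )


def fits_frame(fits: dict[str, MKModelFit]) -> pd.DataFrame:
    """Model-comparison table plus a model-averaged row."""
    rows = []
    for mid in MODELS:
        f = fits[mid]
        rows.append(
            {
                "model": mid,
                **{f"f{c}": f.f.get(c, math.nan) for c in CATEGORIES},
                **{f"alpha{c}": f.alpha.get(c, math.nan) for c in CATEGORIES},
                "logL": f.logL,
                "delta_aic": f.delta_aic,
                "weight": f.weight,
            }
        )
    avg = model_average(list(fits.values()))
    rows.append(
        {
            "model": "averaged",
            **{f"f{c}": avg["f"][c] for c in CATEGORIES},
            **{f"alpha{c}": avg["alpha"][c] for c in CATEGORIES},
            "logL": math.nan,
            "delta_aic": math.nan,
            "weight": math.nan,
        }
    )
    return pd.DataFrame(rows)
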