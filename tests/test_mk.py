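"""Poisson MK model family: likelihoods, AIC weighting, averaging, counts."""

import math

import numpy as np
import pytest

from dzscan import locus_io, mk


def simulate_counts(rng, n_genes, f_by_cat, alpha, cat_probs=(350 / 500, 104 / 500, 46 / 500)):
    """Genes under the Poisson MK model at survey-like count rates.

    Rates give ~5 synonymous polymorphisms and ~12 synonymous divergences
    per gene (a few dozen polymorphic sites per fragment, a congeneric
    outgroup at ~5% divergence); category proportions mirror the 37/11/5
    control/flowering/symbiotic design.
    """
    counts = []
    for i in range(n_genes):
        cat = int(rng.choice([1, 2, 3], p=cat_probs))
        Ls, Ln = 250.0, 750.0
        th = rng.gamma(2.0, 0.01)
        d = rng.gamma(2.0, 0.025)
        counts.append(
            mk.MKGeneCounts(
                gene_id=f"g{i}",
                category=cat,
                Pn=rng.poisson(f_by_cat[cat] * th * Ln),
                Ps=rng.poisson(th * Ls),
                Dn=rng.poisson(f_by_cat[cat] * d * Ln / (1.0 - alpha)),
                Ds=rng.poisson(d * Ls),
                Ln=Ln,
                Ls=Ls,
            )
        )
    return counts


def test_counts_validation():
    with pytest.raises(ValueError):
        mk.MKGeneCounts("g", 1, Pn=-1, Ps=0, Dn=0, Ds=0, Ln=10, Ls=10)
    with pytest.raises(ValueError):
        mk.MKGeneCounts("g", 1, Pn=0, Ps=0, Dn=0, Ds=0, Ln=0, Ls=10)


def test_single_gene_closed_forms():
    c = mk.MKGeneCounts("g", 1, Pn=10, Ps=100, Dn=20, Ds=100, Ln=500, Ls=500)
    fit = mk.fit_model("M3", [c])
    assert fit.f[1] == pytest.approx(0.1, abs=1e-5)
    assert fit.alpha[1] == pytest.approx(0.5, abs=1e-5)
    # Pn/Ps == Dn/Ds -> alpha = 0
    c2 = mk.MKGeneCounts("g", 1, Pn=10, Ps=100, Dn=5, Ds=50, Ln=500, Ls=500)
    fit2 = mk.fit_model("M3", [c2])
    assert fit2.alpha[1] == pytest.approx(0.0, abs=1e-5)
    # profile identity f = (Pn/Ps)(Ls/Ln) with unequal site totals
    c3 = mk.MKGeneCounts("g", 1, Pn=12, Ps=40, Dn=30, Ds=60, Ln=900, Ls=300)
    fit3 = mk.fit_model("M3", [c3])
    assert fit3.f[1] == pytest.approx((12 / 40) * (300 / 900), abs=1e-5)
    assert fit3.alpha[1] == pytest.approx(1 - (60 * 12) / (30 * 40), abs=1e-4)


def test_model_nesting_loglik_order(rng):
    counts = simulate_counts(rng, 200, {1: 0.1, 2: 0.15, 3: 0.08}, 0.3)
    fits = mk.fit_all(counts)
    ll = {m: fits[m].logL for m in mk.MODELS}
    tol = 1e-6
    assert ll["M5"] >= ll["M4"] - tol >= ll["M3"] - tol >= ll["M1"] - tol >= ll["M0"] - tol
    assert ll["M5"] >= ll["M2"] - tol >= ll["M1"] - tol
    weights = np.array([fits[m].weight for m in mk.MODELS])
    assert weights.sum() == pytest.approx(1.0)


def test_akaike_weights_rules():
    # equal delta-AIC -> equal weights
    assert np.allclose(mk.akaike_weights([2.0, 2.0, 2.0]), 1 / 3)
    # exponential-difference vs conventional halved rule
    delta = np.array([0.0, 2.0])
    w = mk.akaike_weights(delta)
    assert w[0] / w[1] == pytest.approx(np.exp(2.0))
    wh = mk.akaike_weights(delta, halved=True)
    assert wh[0] / wh[1] == pytest.approx(np.exp(1.0))


def test_model_average_trivials_and_brute_force(rng):
    counts = simulate_counts(rng, 120, {1: 0.1, 2: 0.15, 3: 0.08}, 0.3)
    fits = mk.fit_all(counts)
    avg = mk.model_average(list(fits.values()))
    # brute-force weighted sums (M0 contributes f=1, alpha=0)
    for c in (1, 2, 3):
        fsum = sum(fit.weight * fit.f[c] for fit in fits.values())
        asum = sum(fit.weight * fit.alpha[c] for fit in fits.values())
        assert avg["f"][c] == pytest.approx(fsum, abs=1e-12)
        assert avg["alpha"][c] == pytest.approx(asum, abs=1e-12)
    # a single fit with weight 1 averages to itself
    solo = mk.fit_model("M3", counts)
    solo.weight = 1.0
    a2 = mk.model_average([solo])
    assert a2["f"][1] == pytest.approx(solo.f[1])


def test_lrt_values(rng):
    counts = simulate_counts(rng, 100, {1: 0.1, 2: 0.15, 3: 0.08}, 0.3)
    fits = mk.fit_all(counts)
    stat, df, p = mk.lrt(fits["M2"], fits["M4"])
    assert df == 1 and stat >= 0 and 0 <= p <= 1
    # identical fits -> statistic 0, p = 1
    s0, _, p0 = mk.lrt(fits["M4"], fits["M4"])
    assert s0 == 0 and p0 == pytest.approx(1.0)
    assert mk.chi2_lrt_pvalue(3.84, 1) == pytest.approx(0.05, abs=0.005)


def test_mk_counts_from_constructed_gene():
    """Planted polymorphisms and divergences are recovered exactly."""
    # codons: ATG | ACT(pos 3 A/G poly, nonsyn) | GGA(pos 8 A/G poly, syn) | AAA (div to CAA, nonsyn)
    seqs = {
        "a": "ATGACTGGAAAA",
        "b": "ATGACTGGGAAA",
        "c": "ATGGCTGGAAAA",
        "d": "ATGACTGGAAAA",
    }
    out = "ATGACTGGACAA"
    loc = locus_io.AlignedLocus(
        "G1",
        seqs,
        {"tornata": out},
        exons=[(0, 12)],
        frames=[0],
        group_of={a: 1 for a in seqs},
        default_outgroup="tornata",
    )
    fl = locus_io.mask_sites(loc, locus_io.SiteFilterPolicy.strict())
    coding = locus_io.classify_coding_sites(loc, fl)
    counts = mk.mk_counts(fl, coding, "G1", 2)
    assert (counts.Pn, counts.Ps, counts.Dn, counts.Ds) == (1, 1, 1, 0)
    assert counts.category == 2
    # ingroup-polymorphic site is polymorphism, never divergence
    assert 3 not in coding.divergence_labels and 8 not in coding.divergence_labels


def test_fits_frame_contains_average_row(rng):
    counts = simulate_counts(rng, 80, {1: 0.1, 2: 0.15, 3: 0.08}, 0.3)
    fits = mk.fit_all(counts)
    frame = mk.fits_frame(fits)
    assert list(frame["model"]) == list(mk.MODELS) + ["averaged"]
    avg_row = frame.iloc[-1]
    assert 0 < avg_row["f1"] <= 1.0
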