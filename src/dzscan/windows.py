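"""Sliding-window diversity profiles along a locus.

Windows run on alignment coordinates (default 500 bp wide, 50 bp steps);
gap columns count toward the window span but not toward analysed sites.
Per window: S, non-synonymous Watterson's theta per non-synonymous site,
Weir & Cockerham F_ST between the two ancestry groups, and Tajima's D within
each group.  Only full-width windows are emitted (trailing partial windows
are dropped); a locus shorter than the window width yields a single
whole-locus window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import locus_io, sumstats

__all__ = ["WindowStats", "sliding_windows", "windows_frame"]


@dataclass
class WindowStats:
    start: int  # alignment bp, half-open
    end: int
    S: int
    theta_nonsyn: float
    fst_wc: float
    D_group1: float
    D_group2: float


def _group_d(m: np.ndarray, cols: np.ndarray) -> float:
    """Tajima's D for one group's sub-matrix over the window's kept columns."""
    if cols.size == 0 or m.shape[0] < 4:
        return math.nan
    S = 0
    pi_sum = 0.0
    ns_all = []
    for col in cols:
        obs = m[:, col][m[:, col] >= 0]
        if obs.size < 2:
            continue
        ns_all.append(obs.size)
        cnt = np.bincount(obs, minlength=4).astype(float)
        if np.sum(cnt > 0) > 1:
            S += 1
        pi_sum += obs.size / (obs.size - 1.0) * (1.0 - np.sum((cnt / obs.size) ** 2))
    if not ns_all or S == 0:
        return math.nan
    n_modal = max(int(np.bincount(ns_all).argmax()), 2)
    if n_modal < 4:
        return math.nan
    return sumstats.tajima_d(n_modal, S, pi_sum)


def sliding_windows(
    filtered: locus_io.FilteredLocus,
    coding: locus_io.CodingSites | None = None,
    width: int = 500,
    step: int = 50,
) -> list[WindowStats]:
    """Window statistics at offsets 0, step, 2*step, ... (full windows only)."""
    if not (1 <= step <= width):
        raise ValueError("need width >= step >= 1")
    L_aln = filtered.locus.length
    if width > L_aln:
        starts = [0]
        width = L_aln
    else:
        starts = list(range(0, L_aln - width + 1, step))

    m = filtered.locus.matrix(filtered.retained)
    m = np.where(m < 0, -1, m)
    groups = filtered.groups()
    kept = filtered.site_mask
    labels = coding.labels if coding is not None else {}
    nonsyn_cols = {c for c, v in labels.items() if v == "non-synonymous"}
    # per-coding-window site totals: spread Ln over the codon columns evenly
    ln_per_col = np.zeros(L_aln)
    if coding is not None and coding.Ln > 0:
        coding_cols = [c for cols in locus_io._codon_slots(filtered.locus) for c in cols if kept[c]]
        if coding_cols:
            ln_per_col[coding_cols] = coding.Ln / len(coding_cols)

    out = []
    for s in starts:
        e = s + width
        cols = np.where(kept[s:e])[0] + s
        S = 0
        fst_p1, fst_p2, fst_n1, fst_n2 = [], [], [], []
        S_nonsyn = 0
        for col in cols:
            obs = m[:, col][m[:, col] >= 0]
            if obs.size < 2:
                continue
            cnt = np.bincount(obs, minlength=4)
            alleles = np.where(cnt > 0)[0]
            if alleles.size < 2:
                continue
            S += 1
            if col in nonsyn_cols:
                S_nonsyn += 1
            if alleles.size == 2:
                a = alleles[0]
                g1 = m[groups == 1, col]
                g2 = m[groups == 2, col]
                g1 = g1[g1 >= 0]
                g2 = g2[g2 >= 0]
                if g1.size >= 2 and g2.size >= 2:
                    fst_p1.append(np.mean(g1 == a))
                    fst_p2.append(np.mean(g2 == a))
                    fst_n1.append(g1.size)
                    fst_n2.append(g2.size)
        ln_window = float(ln_per_col[s:e].sum())
        n_modal = m.shape[0]
        theta_nonsyn = (
            sumstats.watterson_theta(n_modal, S_nonsyn, ln_window) if ln_window > 0 else math.nan
        )
        fst = math.nan
        if fst_p1:
            fst, _, _ = sumstats.fst_weir_cockerham(fst_p1, fst_p2, fst_n1, fst_n2)
        d1 = _group_d(m[groups == 1], cols)
        d2 = _group_d(m[groups == 2], cols)
        out.append(WindowStats(start=s, end=e, S=S, theta_nonsyn=theta_nonsyn, fst_wc=fst, D_group1=d1, D_group2=d2))
    return out


def windows_frame(locus_id: str, windows: list[WindowStats]) -> pd.DataFrame:
    """Report table (1-based closed coordinates)."""
    return pd.DataFrame(
        [
            {
                "locus_id": locus_id,
                "start": w.start + 1,
                "end": w.end,
                "S": w.S,
                "theta_nonsyn": w.theta_nonsyn,
                "fst_wc": w.fst_wc,
                "D_g1": w.D_group1,
                "D_g2": w.D_group2,
            }
            for w in windows
        ]
    )


def plot_windows(locus_id: str, windows: list[WindowStats], exons, path) -> None:
    """Four-track window profile (S, theta_nonsyn, F_ST, per-group D) with exon shading."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mids = [(w.start + w.end) / 2 for w in windows]
    fig, axes = plt.subplots(4, 1, sharex=True, figsize=(8, 9))
    axes[0].plot(mids, [w.S for w in windows], color="k")
    axes[0].set_ylabel("S")
    axes[1].plot(mids, [w.theta_nonsyn for w in windows], color="tab:purple")
    axes[1].set_ylabel(r"$\theta_W$ non-syn")
    axes[2].plot(mids, [w.fst_wc for w in windows], color="tab:red")
    axes[2].set_ylabel(r"$F_{ST}$ (W&C)")
    axes[3].plot(mids, [w.D_group1 for w in windows], label="group 1")
    axes[3].plot(mids, [w.D_group2 for w in windows], label="group 2")
    axes[3].set_ylabel("Tajima's D")
    axes[3].set_xlabel("alignment position (bp)")
    axes[3].legend(frameon=False)
    for ax in axes:
        for s, e in exons:
            ax.axvspan(s, e, color="0.85", zorder=0)
    fig.suptitle(locus_id)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
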