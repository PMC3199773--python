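"""Synthetic study-shaped datasets with known ground truth.

Emulates the sampling design of a two-group resequencing survey of inbred
(haploid-coded) accessions: 53 loci (37 control, 11 flowering, 5 symbiotic)
of 287-8897 bp, two ancestry groups of 25 and 32 accessions simulated as
independent exponentially-growing populations, one outgroup sequence at
modest divergence, per-base missing data plus truncated sequences (to
exercise the sequence-span filter), ancestral-allele misorientation noise,
and sweep-like candidate loci whose site frequency spectra are tilted toward
high-frequency derived alleles.  Every generated locus's parameters are
recorded in a truth table, so each pipeline stage can be tested against
known inputs without any external download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coalsim, locus_io

__all__ = ["StudyDesign", "apply_sweep_tilt", "generate_locus", "generate_study"]

_BASES = np.array(list("ACGT"))


@dataclass
class StudyDesign:
    """Generator settings; defaults mirror the emulated study's design."""

    n_group1: int = 25
    n_group2: int = 32
    n_control: int = 37
    n_flowering: int = 11
    n_symbiotic: int = 5
    length_range: tuple[int, int] = (287, 8897)
    # (theta, g) calibrated so that the REALIZED within-group statistics match
    # the emulated survey: Watterson's theta 0.0032/0.0037 per bp and mean
    # Tajima's D about -0.73/-0.58 in groups 1/2 (growth shrinks realized
    # diversity below the sampling-time theta by a factor of ~0.43/0.56)
    model_group1: coalsim.GrowthModel = field(default_factory=lambda: coalsim.GrowthModel(theta=0.0074, g=4.0))
    model_group2: coalsim.GrowthModel = field(default_factory=lambda: coalsim.GrowthModel(theta=0.0066, g=2.0))
    outgroup_divergence: float = 0.05  # expected substitutions per bp (congeneric)
    outgroup_species: str = "tornata"
    p_mis: float = 0.00936
    missing_rate: float = 0.002  # isolated undefined base calls
    truncated_frac: float = 0.05  # accessions with a random truncated span
    sweep_tilt: float = 3.0
    n_swept_flowering: int = 4
    n_swept_symbiotic: int = 1
    exon_frac: float = 0.5  # approximate coding fraction of each locus
    seed: int = 0

    def __post_init__(self):
        if min(self.n_group1, self.n_group2, self.n_control) < 1:
            raise ValueError("counts must be >= 1")
        for r in (self.p_mis, self.missing_rate, self.truncated_frac):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must lie in [0, 1]")
        if self.sweep_tilt < 1.0:
            raise ValueError("sweep_tilt >= 1 (1 = neutral)")


def apply_sweep_tilt(xi: np.ndarray, n: int, tilt: float, rng: np.random.Generator) -> np.ndarray:
    """Tilt an unfolded SFS toward high-frequency derived alleles.

    Each segregating site with derived count i is independently moved, with
    probability 1 - tilt**(-i/n) (zero at tilt = 1, increasing with i), to a
    count drawn uniformly from the top frequency classes
    {ceil(0.85 n) .. n-1}.  Intermediate-frequency sites are depleted while
    singletons mostly stay, producing the joint excess of high-frequency
    derived alleles (negative Z) and of rare alleles (negative D) that a
    hitch-hiking sweep leaves behind.
    """
    if tilt < 1.0:
        raise ValueError("tilt >= 1")
    xi = np.asarray(xi, dtype=np.int64)
    if tilt == 1.0:
        return xi.copy()
    out = xi.copy()
    top_lo = min(max(math.ceil(0.85 * n), 1), n - 1)
    counts = np.arange(1, n)
    for i, c in zip(counts, xi):
        if c == 0:
            continue
        moved = rng.binomial(c, 1.0 - tilt ** (-i / n))
        if moved:
            out[i - 1] -= moved
            dest = rng.integers(top_lo, n, size=moved)
            np.add.at(out, dest - 1, 1)
    return out


def _random_exons(L: int, exon_frac: float, rng: np.random.Generator):
    """One or two exon intervals covering ~exon_frac of the locus, in frame 0."""
    total = max(3, int(L * exon_frac) // 3 * 3)
    if L < 30 or total < 6:
        return [(0, total)], [0]
    n_ex = 1 if L < 600 or rng.random() < 0.5 else 2
    if n_ex == 1:
        start = int(rng.integers(0, L - total + 1))
        return [(start, start + total)], [0]
    l1 = max(3, (total // 2) // 3 * 3)
    l2 = total - l1
    gap = int(rng.integers(10, max(11, (L - total) // 2 + 10)))
    s1 = int(rng.integers(0, max(1, L - total - gap)))
    e1 = s1 + l1
    s2 = min(e1 + gap, L - l2)
    return [(s1, e1), (s2, s2 + l2)], [0, (3 - l1 % 3) % 3]


def generate_locus(
    locus_id: str,
    L: int,
    design: StudyDesign,
    tilt: float,
    rng: np.random.Generator,
):
    """Simulate one locus's alignment (both groups + outgroup) and its truth.

    Each group's sample descends from an independent growth-coalescent
    genealogy; polymorphic columns are placed at distinct random positions.
    The outgroup starts from each group's ancestral sequence (groups share
    the ancestral base at non-segregating sites) and accrues
    Poisson(divergence * L) substitutions; with probability ``p_mis`` per
    segregating site the outgroup base is set to the derived allele instead,
    which is what misorients that site downstream.
    """
    anc = rng.integers(0, 4, size=L)
    seqs: dict[str, str] = {}
    group_of: dict[str, int] = {}
    out_seq = anc.copy()
    # outgroup divergence: substitutions at random positions
    n_sub = rng.poisson(design.outgroup_divergence * L)
    sub_pos = rng.choice(L, size=min(n_sub, L), replace=False)
    for p in sub_pos:
        out_seq[p] = (out_seq[p] + rng.integers(1, 4)) % 4

    free = np.ones(L, dtype=bool)
    free[sub_pos] = False  # keep divergence and polymorphism sites distinct
    truth_rows = []
    for gid, n_g, model in ((1, design.n_group1, design.model_group1), (2, design.n_group2, design.model_group2)):
        gen = coalsim.simulate_genealogy(n_g, model.g, rng)
        xi, carriers = coalsim.drop_mutations(gen, model.theta * L, rng)
        if tilt > 1.0 and carriers:
            # re-draw carriers to match the tilted SFS while keeping linkage simple
            xi_t = apply_sweep_tilt(xi, n_g, tilt, rng)
            carriers = _carriers_for_sfs(xi_t, n_g, rng)
        hap = np.tile(anc, (n_g, 1))
        avail = np.where(free)[0]
        take = min(len(carriers), avail.size)
        pos = rng.choice(avail, size=take, replace=False)
        free[pos] = False
        for p, carr in zip(pos, carriers[:take]):
            derived = (anc[p] + rng.integers(1, 4)) % 4
            hap[carr, p] = derived
            if rng.random() < design.p_mis:
                out_seq[p] = derived  # outgroup carries the derived state
        for j in range(n_g):
            acc = f"G{gid}_{j:03d}"
            seqs[acc] = "".join(_BASES[hap[j]])
            group_of[acc] = gid
        truth_rows.append(dict(locus_id=locus_id, group=gid, theta=model.theta, g=model.g, tilt=tilt, divergence=design.outgroup_divergence, n=n_g, L=L))

    # missing data: random per-base Ns plus a few truncated sequences
    accs = list(seqs)
    arr = np.array([list(seqs[a]) for a in accs], dtype="U1")
    if design.missing_rate > 0:
        mask = rng.random(arr.shape) < design.missing_rate
        arr[mask] = "N"
    n_trunc = rng.binomial(len(accs), design.truncated_frac)
    for idx in rng.choice(len(accs), size=n_trunc, replace=False):
        span = int(rng.integers(int(0.05 * L), int(0.6 * L) + 1)) if L >= 20 else L // 2
        if rng.random() < 0.5:
            arr[idx, span:] = "N"
        else:
            arr[idx, : L - span] = "N"
    seqs = {a: "".join(arr[i]) for i, a in enumerate(accs)}

    exons, frames = _random_exons(L, design.exon_frac, rng)
    locus = locus_io.AlignedLocus(
        locus_id=locus_id,
        sequences=seqs,
        outgroups={design.outgroup_species: "".join(_BASES[out_seq])},
        exons=exons,
        frames=frames,
        group_of=group_of,
        default_outgroup=design.outgroup_species,
    )
    return locus, truth_rows


def _carriers_for_sfs(xi: np.ndarray, n: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Independent random carrier sets matching an SFS (used for tilted loci).

    Linkage structure is not preserved for tilted sites; the sweep stand-in
    targets the frequency spectrum, not haplotype structure.
    """
    carriers = []
    for i, c in zip(range(1, n), xi):
        for _ in range(int(c)):
            carriers.append(rng.choice(n, size=i, replace=False))
    rng.shuffle(carriers)
    return carriers


def generate_study(design: StudyDesign, out_dir) -> dict:
    """Write the full synthetic bundle: FASTAs, metadata, annotation, truth.

    Returns a manifest dict with paths and the truth table.  Deterministic
    (byte-identical) for a fixed design seed.
    """
    out = Path(out_dir)
    (out / "loci").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(design.seed)

    categories = (
        [("control", 1)] * design.n_control
        + [("flowering", 2)] * design.n_flowering
        + [("symbiotic", 3)] * design.n_symbiotic
    )
    swept_ids = set()
    fl_ids = [i for i, (c, _) in enumerate(categories) if c == "flowering"]
    sy_ids = [i for i, (c, _) in enumerate(categories) if c == "symbiotic"]
    swept_ids |= set(fl_ids[: design.n_swept_flowering])
    swept_ids |= set(sy_ids[: design.n_swept_symbiotic])

    lo, hi = design.length_range
    truth = []
    ann_rows = []
    meta_done = False
    for k, (cat, code) in enumerate(categories):
        locus_id = f"{cat[:4].upper()}{k:03d}"
        # log-uniform lengths reproduce the study's wide 287-8897 bp spread
        L = int(round(float(np.exp(rng.uniform(np.log(lo), np.log(hi))))))
        tilt = design.sweep_tilt if k in swept_ids else 1.0
        locus, rows = generate_locus(locus_id, L, design, tilt, rng)
        locus_io.write_locus(locus, out / "loci" / f"{locus_id}.fasta")
        for r in rows:
            r["category"] = code
            truth.append(r)
        for (s, e), fr in zip(locus.exons, locus.frames):
            ann_rows.append(
                dict(locus_id=locus_id, exon_start=s + 1, exon_end=e, frame=fr, default_outgroup=design.outgroup_species)
            )
        if not meta_done:
            meta = pd.DataFrame(
                [{"accession_id": a, "group": g} for a, g in locus.group_of.items()]
            )
            meta.to_csv(out / "metadata.tsv", sep="\t", index=False)
            meta_done = True

    truth_df = pd.DataFrame(truth)
    truth_df.to_csv(out / "truth.tsv", sep="\t", index=False)
    ann_df = pd.DataFrame(ann_rows)
    ann_df.to_csv(out / "annotation.tsv", sep="\t", index=False)
    return {
        "loci_dir": out / "loci",
        "metadata": out / "metadata.tsv",
        "annotation": out / "annotation.tsv",
        "truth": out / "truth.tsv",
        "truth_table": truth_df,
    }
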