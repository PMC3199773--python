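"""Per-locus alignment ingestion, filtering and coding-site classification.

A locus is a multiple alignment of ingroup accessions plus one or more
outgroup sequences (record ids prefixed ``OUT|species``).  Filtering follows
the resequencing-survey conventions this package reimplements:

* sequences spanning (defined, non-gap) less than 25% of the longest
  sequence's defined length are removed (60% for synonymous/non-synonymous
  analyses); the boundary is kept (strictly-less-than removal);
* the designated default outgroup is used unless its defined length is less
  than 75% of the longest sequence's, in which case the longest alternative
  outgroup is used; loci with no admissible outgroup are "unoriented";
* site masks: the default mode keeps alignment columns with at least 70%
  defined data among retained ingroup sequences; the strict mode (used for
  coding-site classification, recombination estimation) keeps only columns
  with no undefined position.  Gap characters count as missing.

Coding sites are counted and polymorphisms labelled synonymous or
non-synonymous with the unweighted Nei–Gojobori pathway method; codons
differing at several positions are decomposed over minimal-change pathways
(pathways through stop codons are excluded when avoidable).

Coordinates are 0-based half-open internally, 1-based closed in reports.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import sumstats

__all__ = [
    "AlignedLocus",
    "SiteFilterPolicy",
    "FilteredLocus",
    "read_locus",
    "write_locus",
    "read_metadata",
    "read_annotation",
    "filter_sequences",
    "select_outgroup",
    "mask_sites",
    "classify_coding_sites",
    "locus_diversity",
    "EmptyLocusError",
]

log = logging.getLogger(__name__)

OUTGROUP_PREFIX = "OUT|"
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": -1, "-": -2}
_BASES = "ACGT"
_STOPS = set(standard_dna_table.stop_codons)


class EmptyLocusError(ValueError):
    """All sequences of a locus were removed by filtering."""


@dataclass
class SiteFilterPolicy:
    """Sequence-, outgroup- and site-level filtering thresholds."""

    min_seq_span_frac: float = 0.25
    min_site_defined_frac: float = 0.70
    outgroup_min_len_frac: float = 0.75

    def __post_init__(self):
        for v in (self.min_seq_span_frac, self.min_site_defined_frac, self.outgroup_min_len_frac):
            if not (0.0 <= v <= 1.0):
                raise ValueError("policy fractions must lie in [0, 1]")

    @classmethod
    def strict(cls) -> "SiteFilterPolicy":
        """Coding/recombination mode: 60% span rule and complete-data sites."""
        return cls(min_seq_span_frac=0.60, min_site_defined_frac=1.0)


@dataclass
class AlignedLocus:
    """One locus's alignment with annotation and group labels."""

    locus_id: str
    sequences: dict[str, str]  # accession -> aligned sequence
    outgroups: dict[str, str]  # species -> aligned sequence
    exons: list[tuple[int, int]] = field(default_factory=list)  # half-open, sorted
    frames: list[int] = field(default_factory=list)  # phase offset per exon
    group_of: dict[str, int] = field(default_factory=dict)
    default_outgroup: str | None = None

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()} | {len(s) for s in self.outgroups.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.locus_id}: ragged alignment {sorted(lengths)}")
        self.sequences = {k: _normalize(v) for k, v in self.sequences.items()}
        self.outgroups = {k: _normalize(v) for k, v in self.outgroups.items()}
        last = 0
        for s, e in self.exons:
            if not (0 <= s < e <= self.length) or s < last:
                raise ValueError(f"{self.locus_id}: bad exon ({s}, {e})")
            last = e
        missing = [a for a in self.sequences if a not in self.group_of]
        if missing:
            raise KeyError(f"{self.locus_id}: accessions without group label: {missing}")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    def matrix(self, accessions=None) -> np.ndarray:
        """(n, L) int codes: 0..3 bases, -1 undefined, -2 gap."""
        accs = list(self.sequences) if accessions is None else list(accessions)
        return np.array([[_CODE[b] for b in self.sequences[a]] for a in accs], dtype=np.int8)


def _normalize(seq: str) -> str:
    s = seq.upper()
    return "".join(b if b in _CODE else "N" for b in s)


def _defined_length(seq: str) -> int:
    return sum(1 for b in seq if b in _BASES)


@dataclass
class FilteredLocus:
    """The analysable view of a locus after all filters."""

    locus: AlignedLocus
    retained: list[str]
    outgroup: str | None  # chosen outgroup species, None = unoriented locus
    site_mask: np.ndarray  # bool over alignment columns
    ancestral: np.ndarray  # int8 per column: 0..3 ancestral base, -1 unoriented

    @property
    def L_analysed(self) -> int:
        return int(self.site_mask.sum())

    @property
    def oriented(self) -> bool:
        return self.outgroup is not None

    def site_matrix(self) -> np.ndarray:
        """(n_retained, L_analysed) int codes restricted to kept columns."""
        m = self.locus.matrix(self.retained)
        m = np.where(m < 0, -1, m)
        return m[:, self.site_mask]

    def groups(self) -> np.ndarray:
        return np.array([self.locus.group_of[a] for a in self.retained])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_metadata(path) -> pd.DataFrame:
    """Accession metadata TSV with columns accession_id, group."""
    df = pd.read_csv(path, sep="\t")
    if not {"accession_id", "group"} <= set(df.columns):
        raise ValueError("metadata must have accession_id and group columns")
    return df


def read_annotation(path) -> pd.DataFrame:
    """Locus annotation TSV: locus_id, exon_start, exon_end, frame, default_outgroup.

    Exon coordinates are 1-based closed in the file (report convention) and
    converted to 0-based half-open on read.
    """
    df = pd.read_csv(path, sep="\t")
    need = {"locus_id", "exon_start", "exon_end", "frame", "default_outgroup"}
    if not need <= set(df.columns):
        raise ValueError(f"annotation needs columns {sorted(need)}")
    return df


def read_locus(fasta_path, metadata: pd.DataFrame, annotation: pd.DataFrame | None = None, locus_id: str | None = None) -> AlignedLocus:
    """Read one locus FASTA (ingroup + ``OUT|species`` outgroup records)."""
    fasta_path = Path(fasta_path)
    locus_id = locus_id or fasta_path.stem
    seqs, outs = {}, {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id.startswith(OUTGROUP_PREFIX):
            outs[rec.id[len(OUTGROUP_PREFIX):]] = str(rec.seq)
        else:
            seqs[rec.id] = str(rec.seq)
    if not seqs:
        raise ValueError(f"{fasta_path}: no ingroup records")
    lengths = {len(s) for s in list(seqs.values()) + list(outs.values())}
    if len(lengths) != 1:
        raise ValueError(f"{fasta_path}: ragged alignment")
    group_of = dict(zip(metadata["accession_id"].astype(str), metadata["group"].astype(int)))
    missing = [a for a in seqs if a not in group_of]
    if missing:
        raise KeyError(f"{locus_id}: accessions missing from metadata: {missing}")
    exons, frames, default_out = [], [], None
    if annotation is not None:
        rows = annotation[annotation["locus_id"] == locus_id]
        for _, r in rows.iterrows():
            exons.append((int(r["exon_start"]) - 1, int(r["exon_end"])))
            frames.append(int(r["frame"]))
            default_out = str(r["default_outgroup"])
    return AlignedLocus(
        locus_id=locus_id,
        sequences=seqs,
        outgroups=outs,
        exons=exons,
        frames=frames,
        group_of={a: group_of[a] for a in seqs},
        default_outgroup=default_out,
    )


def write_locus(locus: AlignedLocus, fasta_path) -> None:
    """Write a locus back to FASTA (round-trips sequence content exactly)."""
    recs = [SeqRecord(Seq(s), id=a, description="") for a, s in locus.sequences.items()]
    recs += [SeqRecord(Seq(s), id=OUTGROUP_PREFIX + sp, description="") for sp, s in locus.outgroups.items()]
    SeqIO.write(recs, str(fasta_path), "fasta-2line")


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_sequences(locus: AlignedLocus, policy: SiteFilterPolicy) -> list[str]:
    """Retain accessions whose defined span reaches the policy fraction.

    The reference span is the maximum defined length over all sequences
    (ingroup and outgroup alike); a sequence is removed iff its defined
    length is strictly below ``min_seq_span_frac`` times that maximum.
    """
    all_defined = {a: _defined_length(s) for a, s in locus.sequences.items()}
    out_defined = [_defined_length(s) for s in locus.outgroups.values()]
    longest = max(list(all_defined.values()) + out_defined)
    cut = policy.min_seq_span_frac * longest
    kept = [a for a, d in all_defined.items() if d >= cut]
    if not kept:
        raise EmptyLocusError(f"{locus.locus_id}: all sequences removed by span filter")
    return kept


def select_outgroup(locus: AlignedLocus, policy: SiteFilterPolicy) -> str | None:
    """Choose the outgroup: default species unless too short, else longest.

    Returns None (locus unoriented) when no outgroup reaches the threshold
    or the locus has no outgroup sequence at all.
    """
    if not locus.outgroups:
        return None
    longest = max(
        [_defined_length(s) for s in locus.sequences.values()]
        + [_defined_length(s) for s in locus.outgroups.values()]
    )
    cut = policy.outgroup_min_len_frac * longest
    default = locus.default_outgroup
    if default in locus.outgroups and _defined_length(locus.outgroups[default]) >= cut:
        return default
    others = {sp: _defined_length(s) for sp, s in locus.outgroups.items() if sp != default}
    if not others:
        return None
    sp, d = max(others.items(), key=lambda kv: kv[1])
    return sp if d >= cut else None


def mask_sites(locus: AlignedLocus, policy: SiteFilterPolicy, retained: list[str] | None = None, outgroup: str | None = None) -> FilteredLocus:
    """Apply the site-level filter and call ancestral states.

    A column is kept when the fraction of retained ingroup sequences with a
    defined base is at least ``min_site_defined_frac`` (gaps count as
    undefined; with the strict policy this excludes any column containing a
    single N or gap).  At kept biallelic columns the ancestral state is the
    outgroup base when defined and matching one of the ingroup alleles;
    otherwise the site is unoriented (excluded from theta_H/theta_L/Z but
    kept for S, pi, D).
    """
    if retained is None:
        retained = filter_sequences(locus, policy)
    if outgroup is None:
        outgroup = select_outgroup(locus, policy)
    m = locus.matrix(retained)
    defined = m >= 0
    frac = defined.mean(axis=0)
    keep = frac >= policy.min_site_defined_frac if policy.min_site_defined_frac > 0 else frac > 0
    # guard: a kept column needs at least 2 defined sequences to be informative
    keep &= defined.sum(axis=0) >= 2
    anc = np.full(locus.length, -1, dtype=np.int8)
    if outgroup is not None:
        out_codes = np.array([_CODE[b] for b in locus.outgroups[outgroup]], dtype=np.int8)
        for col in np.where(keep)[0]:
            alleles = np.unique(m[defined[:, col], col])
            ob = out_codes[col]
            if ob >= 0 and (alleles.size <= 2) and ob in alleles:
                anc[col] = ob
    return FilteredLocus(locus=locus, retained=retained, outgroup=outgroup, site_mask=keep, ancestral=anc)


# ---------------------------------------------------------------------------
# Coding-site classification (unweighted Nei-Gojobori)
# ---------------------------------------------------------------------------

def _aa(codon: str) -> str | None:
    if codon in _STOPS:
        return "*"
    return standard_dna_table.forward_table.get(codon)


def _syn_fractions(codon: str) -> np.ndarray | None:
    """Fraction of the 3 possible changes at each position that are synonymous.

    Changes to stop codons count as non-synonymous; stop codons themselves
    are not counted (returns None).
    """
    if codon in _STOPS or any(b not in _BASES for b in codon):
        return None
    ref = _aa(codon)
    out = np.zeros(3)
    for pos in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt not in _STOPS and _aa(alt) == ref:
                syn += 1
        out[pos] = syn / 3.0
    return out


def _pathway_labels(c1: str, c2: str) -> dict[int, float] | None:
    """Average synonymous weight of each differing position between two codons.

    Enumerates the minimal-change pathways (orderings of the differing
    positions); pathways passing through a stop codon are dropped when at
    least one stop-free pathway exists.  Returns {position: syn_weight} or
    None when the codons cannot be compared.
    """
    if any(b not in _BASES for b in c1 + c2):
        return None
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return {}
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        labels = {}
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in _STOPS:
                through_stop = True
            labels[pos] = 1.0 if (_aa(cur) == _aa(nxt) and nxt not in _STOPS and cur not in _STOPS) else 0.0
            cur = nxt
        paths.append((through_stop, labels))
    clean = [lab for stop, lab in paths if not stop]
    use = clean if clean else [lab for _, lab in paths]
    out = {pos: float(np.mean([lab[pos] for lab in use])) for pos in diff}
    return out


@dataclass
class CodingSites:
    """Synonymous/non-synonymous site totals and per-site polymorphism labels."""

    Ln: float
    Ls: float
    labels: dict[int, str]  # alignment column -> "synonymous" | "non-synonymous"
    divergence_labels: dict[int, str]  # fixed differences to the outgroup
    excluded_codons: int = 0


def _codon_slots(locus: AlignedLocus):
    """Yield (columns triple) for each complete codon across exons."""
    coding = []
    for (s, e), frame in zip(locus.exons, locus.frames):
        coding.extend(range(s + frame, e))
    for i in range(0, len(coding) - 2, 3):
        yield coding[i], coding[i + 1], coding[i + 2]


def classify_coding_sites(locus: AlignedLocus, filtered: FilteredLocus) -> CodingSites:
    """Count synonymous/non-synonymous sites and label coding polymorphisms.

    Uses the strict site mask: codons containing any masked-out, undefined
    or gapped position in any retained sequence (or in the chosen outgroup,
    for divergence labels) are excluded and counted in ``excluded_codons``.
    Site totals are unweighted Nei-Gojobori fractions averaged over retained
    sequences.
    """
    if not locus.exons:
        return CodingSites(Ln=0.0, Ls=0.0, labels={}, divergence_labels={}, excluded_codons=0)
    seqs = {a: locus.sequences[a] for a in filtered.retained}
    out_seq = locus.outgroups.get(filtered.outgroup) if filtered.outgroup else None
    Ln = Ls = 0.0
    labels: dict[int, str] = {}
    div: dict[int, str] = {}
    excluded = 0
    mask = filtered.site_mask
    for cols in _codon_slots(locus):
        if not all(mask[c] for c in cols):
            excluded += 1
            continue
        codons = {}
        bad = False
        for a, s in seqs.items():
            cod = s[cols[0]] + s[cols[1]] + s[cols[2]]
            if any(b not in _BASES for b in cod):
                bad = True
                break
            codons[a] = cod
        if bad or not codons:
            excluded += 1
            continue
        uniq = sorted(set(codons.values()))
        if any(c in _STOPS for c in uniq):
            excluded += 1
            continue
        # site totals: average syn fraction across retained sequences
        fracs = [f for f in (_syn_fractions(c) for c in codons.values()) if f is not None]
        mean_frac = np.mean(fracs, axis=0)
        Ls += float(mean_frac.sum())
        Ln += float(3.0 - mean_frac.sum())
        # polymorphism labels
        poly_positions = [i for i in range(3) if len({c[i] for c in uniq}) > 1]
        if poly_positions:
            if len(uniq) > 2:
                # multi-allelic codon: compare the two most frequent codons
                counts = {}
                for c in codons.values():
                    counts[c] = counts.get(c, 0) + 1
                top2 = sorted(counts, key=lambda c: (-counts[c], c))[:2]
                lab = _pathway_labels(top2[0], top2[1])
                log.info("%s: multi-allelic codon at columns %s decomposed via top-2 codons", locus.locus_id, cols)
            else:
                lab = _pathway_labels(uniq[0], uniq[1])
            if lab:
                for pos, w in lab.items():
                    labels[cols[pos]] = "synonymous" if w >= 0.5 else "non-synonymous"
        # divergence labels: ingroup fixed, outgroup differs
        if out_seq is not None and len(uniq) == 1:
            ocod = out_seq[cols[0]] + out_seq[cols[1]] + out_seq[cols[2]]
            if all(b in _BASES for b in ocod) and ocod not in _STOPS and ocod != uniq[0]:
                lab = _pathway_labels(uniq[0], ocod)
                if lab:
                    for pos, w in lab.items():
                        div[cols[pos]] = "synonymous" if w >= 0.5 else "non-synonymous"
    return CodingSites(Ln=Ln, Ls=Ls, labels=labels, divergence_labels=div, excluded_codons=excluded)


# ---------------------------------------------------------------------------
# Per-locus diversity (bridges filtered loci to sumstats)
# ---------------------------------------------------------------------------

def locus_diversity(filtered: FilteredLocus, accessions: list[str] | None = None) -> sumstats.DiversityStats:
    """Diversity statistics for a filtered locus (optionally one group).

    pi uses per-site sample sizes (unbiased per site under the 70% rule);
    Tajima's D uses the modal per-site sample size n.  theta_H, theta_L and
    Z use oriented sites only; at sites whose sample size differs from the
    modal n the derived count is rescaled proportionally (a documented
    approximation that vanishes without missing data).
    """
    accs = filtered.retained if accessions is None else [a for a in filtered.retained if a in set(accessions)]
    if len(accs) < 2:
        raise ValueError("need >= 2 retained sequences")
    m = filtered.locus.matrix(accs)
    m = np.where(m < 0, -1, m)
    keep = np.where(filtered.site_mask)[0]
    L = keep.size
    if L == 0:
        return sumstats.DiversityStats(n=len(accs), L=0, S=0, theta_w=math.nan, pi=math.nan)

    S = 0
    pi_sum = 0.0
    ns_list = []
    xi: dict[int, float] = {}
    S_oriented = 0
    for col in keep:
        colv = m[:, col]
        obs = colv[colv >= 0]
        ns = obs.size
        if ns < 2:
            ns_list.append(ns)
            continue
        ns_list.append(ns)
        cnt = np.bincount(obs, minlength=4).astype(float)
        het = 1.0 - np.sum((cnt / ns) ** 2)
        pi_sum += ns / (ns - 1.0) * het
        alleles = np.where(cnt > 0)[0]
        if alleles.size > 1:
            S += 1
            anc = filtered.ancestral[col]
            if anc >= 0 and alleles.size == 2 and anc in alleles:
                derived = alleles[alleles != anc][0]
                xi[col] = cnt[derived]
                S_oriented += 1
    n_modal = int(np.bincount(ns_list).argmax()) if ns_list else len(accs)
    n_modal = max(n_modal, 2)
    theta_w = sumstats.watterson_theta(n_modal, S, L)
    pi = pi_sum / L

    # build the oriented SFS on the modal n (rescale off-modal sites)
    sfs = np.zeros(max(n_modal - 1, 1))
    for col, dcount in xi.items():
        colv = m[:, col]
        ns = int(np.sum(colv >= 0))
        i = dcount if ns == n_modal else round(dcount * n_modal / ns)
        i = int(min(max(i, 1), n_modal - 1))
        sfs[i - 1] += 1

    c = sumstats.tajima_constants(n_modal)
    D = sumstats.tajima_d(n_modal, S, pi_sum)
    stats = sumstats.DiversityStats(
        n=n_modal,
        L=L,
        S=S,
        theta_w=theta_w,
        pi=pi,
        D=D,
        S_oriented=S_oriented,
        oriented=filtered.oriented and S_oriented > 0,
        a1=c["a1"],
        b1=sumstats.harmonic2(n_modal),
        e1=c["e1"],
        e2=c["e2"],
    )
    if stats.oriented:
        th, tl, H = sumstats.fay_wu_from_sfs(sfs, n_modal)
        stats.theta_h = th
        stats.theta_l = tl
        # H and Z on oriented sites only, for comparability with the null
        piL_or = sumstats.sfs_pi(sfs, n_modal)
        stats.H = piL_or - th
        stats.Z = sumstats.fay_wu_z(sfs, n_modal)
    return stats
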