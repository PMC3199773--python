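"""Alignment ingestion, filtering rules and coding-site classification."""

import numpy as np
import pytest

from dzscan import locus_io, sumstats
from dzscan.locus_io import AlignedLocus, SiteFilterPolicy


def _locus(seqs, outs=None, exons=None, frames=None, groups=None, default_out="tornata"):
    groups = groups or {a: 1 if i % 2 == 0 else 2 for i, a in enumerate(seqs)}
    return AlignedLocus(
        locus_id="T",
        sequences=seqs,
        outgroups=outs or {},
        exons=exons or [],
        frames=frames or [],
        group_of=groups,
        default_outgroup=default_out,
    )


def test_ingestion_normalizes_and_validates():
    loc = _locus({"a": "acgtn-ryx", "b": "ACGTNACGT"})
    assert loc.sequences["a"] == "ACGTN-NNN"  # lowercase up, unknowns to N
    with pytest.raises(ValueError):
        _locus({"a": "ACGT", "b": "ACG"})
    with pytest.raises(KeyError):
        AlignedLocus("X", {"a": "ACGT"}, {}, [], [], group_of={}, default_outgroup=None)


def test_round_trip_is_byte_identical(small_bundle, tmp_path):
    import filecmp

    meta = locus_io.read_metadata(small_bundle["metadata"])
    ann = locus_io.read_annotation(small_bundle["annotation"])
    for src in sorted(small_bundle["loci_dir"].glob("*.fasta"))[:3]:
        loc = locus_io.read_locus(src, meta, ann)
        dst = tmp_path / src.name
        locus_io.write_locus(loc, dst)
        reread = locus_io.read_locus(dst, meta, ann)
        assert reread.sequences == loc.sequences
        assert reread.outgroups == loc.outgroups
        # writing the reread locus reproduces the bytes exactly
        dst2 = tmp_path / ("again_" + src.name)
        locus_io.write_locus(reread, dst2)
        assert filecmp.cmp(dst, dst2, shallow=False)


def test_sequence_span_filter_boundaries():
    # longest sequence defines 1000 bp; 240 defined -> removed, 250 -> kept
    long = "A" * 1000
    s240 = "A" * 240 + "N" * 760
    s250 = "A" * 250 + "-" * 750
    loc = _locus({"long": long, "x240": s240, "x250": s250})
    kept = locus_io.filter_sequences(loc, SiteFilterPolicy())
    assert "x240" not in kept and "x250" in kept and "long" in kept
    # 60% policy removes both
    kept60 = locus_io.filter_sequences(loc, SiteFilterPolicy.strict())
    assert kept60 == ["long"]
    # all removed -> empty-locus signal
    with pytest.raises(locus_io.EmptyLocusError):
        locus_io.filter_sequences(
            _locus({"a": "N" * 100}, outs={"o": "A" * 100}), SiteFilterPolicy()
        )


def test_filtering_is_idempotent():
    loc = _locus({"a": "A" * 100, "b": "A" * 30 + "N" * 70, "c": "N" * 90 + "A" * 10})
    pol = SiteFilterPolicy()
    once = locus_io.filter_sequences(loc, pol)
    sub = AlignedLocus(
        "T",
        {a: loc.sequences[a] for a in once},
        {},
        [],
        [],
        {a: loc.group_of[a] for a in once},
        None,
    )
    assert locus_io.filter_sequences(sub, pol) == once


def test_outgroup_selection_rules():
    pol = SiteFilterPolicy()
    base = {"a": "A" * 100, "b": "A" * 100}
    # default spans 80% -> kept
    loc = _locus(base, outs={"tornata": "A" * 80 + "N" * 20, "rigidula": "A" * 90 + "N" * 10})
    assert locus_io.select_outgroup(loc, pol) == "tornata"
    # default spans 50% -> longest alternative
    loc2 = _locus(base, outs={"tornata": "A" * 50 + "N" * 50, "rigidula": "A" * 90 + "N" * 10})
    assert locus_io.select_outgroup(loc2, pol) == "rigidula"
    # no admissible outgroup -> unoriented
    loc3 = _locus(base, outs={"tornata": "A" * 50 + "N" * 50})
    assert locus_io.select_outgroup(loc3, pol) is None
    assert locus_io.select_outgroup(_locus(base), pol) is None


def test_site_masks_strict_subset_of_default(toy_locus):
    default = locus_io.mask_sites(toy_locus, SiteFilterPolicy())
    strict = locus_io.mask_sites(
        toy_locus, SiteFilterPolicy(min_seq_span_frac=0.6, min_site_defined_frac=1.0)
    )
    assert set(np.where(strict.site_mask)[0]) <= set(np.where(default.site_mask)[0])
    # the N column (7) is excluded in strict mode, kept at 70%
    assert not strict.site_mask[7]
    assert default.site_mask[7]


def test_ancestral_calls_and_unoriented_sites(toy_locus):
    fl = locus_io.mask_sites(toy_locus, SiteFilterPolicy())
    # column 3: A/G in ingroup, outgroup A -> ancestral A (code 0)
    assert fl.ancestral[3] == 0
    # outgroup allele absent from the ingroup alleles -> unoriented site
    seqs = {"a": "AAAA", "b": "AAAA", "c": "ACAA", "d": "ACAA"}
    loc = _locus(seqs, outs={"tornata": "AGAA"})
    fl2 = locus_io.mask_sites(loc, SiteFilterPolicy())
    assert fl2.ancestral[1] == -1
    st = locus_io.locus_diversity(fl2)
    assert st.S == 1 and st.S_oriented == 0 and not st.oriented
    assert np.isnan(st.Z)


def test_coding_site_classification(toy_locus):
    strict = locus_io.mask_sites(
        toy_locus, SiteFilterPolicy(min_seq_span_frac=0.6, min_site_defined_frac=1.0)
    )
    coding = locus_io.classify_coding_sites(toy_locus, strict)
    # codon GAT spans the masked N column -> excluded
    assert coding.excluded_codons == 1
    # column 3 polymorphism ACT/GCT = Thr/Ala -> non-synonymous
    assert coding.labels[3] == "non-synonymous"
    # column 9 divergence AAA/CAA = Lys/Gln -> non-synonymous
    assert coding.divergence_labels[9] == "non-synonymous"
    # Ln + Ls equals the number of counted coding sites
    assert coding.Ln + coding.Ls == pytest.approx(9.0)  # 3 codons counted


def test_degeneracy_of_codon_positions():
    # 4-fold third position of GGA contributes 1.0 synonymous site
    frac = locus_io._syn_fractions("GGA")
    assert frac[2] == pytest.approx(1.0)
    # non-degenerate first position contributes 1.0 non-synonymous site
    assert frac[0] == pytest.approx(0.0)
    # GGA <-> GGG is synonymous (both Gly)
    lab = locus_io._pathway_labels("GGA", "GGG")
    assert lab == {2: 1.0}


def test_multi_step_pathway_decomposition():
    # TTA (Leu) <-> TCG (Ser): positions 1 and 2 differ; pathways average
    lab = locus_io._pathway_labels("TTA", "TCG")
    assert set(lab) == {1, 2}
    assert all(0.0 <= v <= 1.0 for v in lab.values())


def test_locus_diversity_basic(toy_locus):
    fl = locus_io.mask_sites(toy_locus, SiteFilterPolicy())
    st = locus_io.locus_diversity(fl)
    assert st.S == 1
    assert st.L == 12
    # single derived singleton at n=4: theta_w = 1/(a1 * 12)
    assert st.theta_w == pytest.approx(1 / (sumstats.harmonic(4) * 12))
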