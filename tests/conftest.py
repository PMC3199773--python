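import numpy as np
import pytest

from dzscan import locus_io, synth


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def toy_locus():
    """Hand-built 12-bp locus: 4 ingroup (2 per group), 1 outgroup, one exon.

    Columns (0-based): 3 is biallelic A/G with outgroup A (oriented, derived
    G carried by g2b); 7 has one N; 9 is a fixed difference to the outgroup.
    """
    seqs = {
        "g1a": "ATGACTGATAAA",
        "g1b": "ATGACTGATAAA",
        "g2a": "ATGACTGATAAA",
        "g2b": "ATGGCTGNTAAA",
    }
    out = "ATGACTGATCAA"
    return locus_io.AlignedLocus(
        locus_id="TOY",
        sequences=seqs,
        outgroups={"tornata": out},
        exons=[(0, 12)],
        frames=[0],
        group_of={"g1a": 1, "g1b": 1, "g2a": 2, "g2b": 2},
        default_outgroup="tornata",
    )


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """Small synthetic study bundle shared across tests (9 loci)."""
    d = tmp_path_factory.mktemp("bundle")
    design = synth.StudyDesign(
        seed=11,
        n_control=6,
        n_flowering=2,
        n_symbiotic=1,
        length_range=(287, 2000),
        n_swept_flowering=1,
        n_swept_symbiotic=0,
    )
    manifest = synth.generate_study(design, d)
    manifest["design"] = design
    manifest["dir"] = d
    return manifest
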