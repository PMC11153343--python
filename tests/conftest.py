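"""Shared fixtures: hand-built transcript models and simulated profiles."""

import pytest

from nebfish.splicing import TranscriptModel
from nebfish import synthetic as syn


@pytest.fixture(scope="session")
def crafted_transcript() -> TranscriptModel:
    """Three-exon model with hand-chosen sequences.

    exon1=ATGGCA, intron1=GTAACAG, exon2=ATAAGGATT, intron2=TAATAG
    (contains the in-frame stops TAA TAG), exon3=GGATAA.  The canonical
    mRNA (21 nt) reads ATG GCA ATA AGG ATT GGA TAA: one stop, at the end.
    A +5 donor shift on intron 1 inserts GTAAC, shifting exon 2 into a
    frame that reads ... GTA ACA TAA: a premature stop inside exon 2.
    """
    exon1, intron1 = "ATGGCA", "GTAACAG"
    exon2, intron2 = "ATAAGGATT", "TAATAG"
    exon3 = "GGATAA"
    seq = exon1 + intron1 + exon2 + intron2 + exon3
    exons = ((1, 6), (14, 22), (29, 34))
    tm = TranscriptModel(sequence=seq, exons=exons, strand="+",
                         cds_start_offset=0, transcript_id="crafted")
    assert tm.canonical_mrna() == exon1 + exon2 + exon3
    return tm


@pytest.fixture(scope="session")
def noiseless_single_unit():
    spec = syn.ProfileSimSpec(n_units=1, noise_sd=0.0, zbump_amplitude=0.0, seed=11)
    profile, truth, measurements = syn.generate_profile_train(spec)
    return spec, profile, truth, measurements


@pytest.fixture(scope="session")
def noiseless_train():
    spec = syn.ProfileSimSpec(n_units=8, sarcomere_length=2.0, rect_width=1.6,
                              sigma_left=0.15, sigma_right=0.15,
                              noise_sd=0.0, zbump_amplitude=0.0, seed=7)
    profile, truth, measurements = syn.generate_profile_train(spec)
    return spec, profile, truth, measurements
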